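"""qPCR standard curves, sample QC, and efficiency-corrected quantification.

Relative expression follows the efficiency-corrected comparative-Ct model

    expression = (1 + Eff.)^(-ddCt)

where Eff. is the gene's amplification efficiency estimated from a serial
dilution standard curve (perfect doubling: Eff. = 1), dCt is the target Ct
minus the mean Ct of the two reference genes (RPL13, RPL32), and ddCt
centres dCt on the control-group mean per gene.  Only the target gene's
efficiency enters the model — no reference-efficiency ratio — matching the
stated quantification formula.

A direct consequence of the control-mean centring is that the geometric
mean of expression over control animals is exactly 1 for every gene, which
the test suite uses as an invariant.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

DEFAULT_REFERENCES = ("RPL13", "RPL32")
RSQ_GATE = 0.990
OD_RANGE = (1.8, 2.2)
RIN_MIN = 7.0
REPLICATE_RANGE_WARN = 0.5  # Ct span across replicates that triggers a warning


@dataclass(frozen=True)
class StandardCurve:
    """Fitted dilution-series regression for one gene."""

    gene: str
    slope: float  # Ct per log10(relative concentration)
    intercept: float
    rsq: float
    efficiency: float

    @property
    def passes_rsq_gate(self) -> bool:
        return self.rsq > RSQ_GATE


@dataclass(frozen=True)
class SampleQC:
    """RNA quality record: OD260/OD280 purity ratio and RIN integrity."""

    sample_id: str
    od_ratio: float
    rin: float

    @property
    def passed(self) -> bool:
        return OD_RANGE[0] <= self.od_ratio <= OD_RANGE[1] and self.rin > RIN_MIN


@dataclass
class ExpressionMatrix:
    """Per-animal relative expression (replicates collapsed), with groups."""

    values: pd.DataFrame  # index: animal_id, columns: target genes
    groups: pd.Series  # index: animal_id -> group label

    def to_frame(self) -> pd.DataFrame:
        df = self.values.copy()
        df.insert(0, "group", self.groups)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        if "group" not in df.columns:
            raise ValueError("expression frame needs a 'group' column")
        groups = df["group"]
        return cls(df.drop(columns="group").astype(float), groups)

    def subset(self, genes: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values[list(genes)], self.groups)


def fit_standard_curve(dilution_table: pd.DataFrame, gene: str = "") -> StandardCurve:
    """OLS of mean Ct on log10(relative concentration).

    Efficiency is ``10^(-1/slope) - 1``; a slope of -3.3219 (one Ct lost per
    doubling) gives efficiency 1.  Requires >= 3 distinct positive
    concentrations and a negative slope.
    """
    if "relative_concentration" not in dilution_table or "ct" not in dilution_table:
        raise ValueError("dilution table needs relative_concentration and ct columns")
    gene = gene or (
        str(dilution_table["gene"].iloc[0]) if "gene" in dilution_table else ""
    )
    mean_ct = dilution_table.groupby("relative_concentration")["ct"].mean()
    if (mean_ct.index <= 0).any():
        raise ValueError("relative concentrations must be positive")
    if len(mean_ct) < 3:
        raise ValueError(
            f"need >= 3 distinct dilution levels, got {len(mean_ct)}"
        )
    x = np.log10(mean_ct.index.to_numpy(dtype=float))
    y = mean_ct.to_numpy(dtype=float)
    fit = stats.linregress(x, y)
    if fit.slope >= 0:
        raise ValueError(
            f"standard curve for {gene or 'gene'} has non-negative slope "
            f"({fit.slope:.4g}); Ct must increase with dilution"
        )
    efficiency = 10.0 ** (-1.0 / fit.slope) - 1.0
    return StandardCurve(
        gene=gene,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        rsq=float(fit.rvalue**2),
        efficiency=float(efficiency),
    )


def fit_standard_curves(dilution_table: pd.DataFrame) -> list[StandardCurve]:
    """Fit one standard curve per gene in a stacked dilution table."""
    return [
        fit_standard_curve(sub, gene=str(g))
        for g, sub in dilution_table.groupby("gene", sort=True)
    ]


def apply_sample_qc(
    qc: Union[pd.DataFrame, Iterable[SampleQC]], ct: pd.DataFrame
) -> pd.DataFrame:
    """Drop Ct rows from samples failing the RNA quality gates.

    A sample passes with OD260/OD280 in [1.8, 2.2] and RIN strictly > 7.0.
    Every sample in the Ct table must have a QC record.
    """
    if isinstance(qc, pd.DataFrame):
        qc_records = [
            SampleQC(str(r.sample_id), float(r.od_ratio), float(r.rin))
            for r in qc.itertuples()
        ]
    else:
        qc_records = list(qc)
    status = {r.sample_id: r.passed for r in qc_records}
    missing = set(ct["sample_id"].astype(str)) - set(status)
    if missing:
        raise ValueError(f"samples without QC records: {sorted(missing)}")
    keep = ct["sample_id"].astype(str).map(status)
    n_dropped = int((~keep).sum())
    if n_dropped:
        dropped = sorted(set(ct.loc[~keep, "sample_id"].astype(str)))
        logger.info(
            "sample QC removed %d rows from %d samples: %s",
            n_dropped, len(dropped), dropped,
        )
    return ct.loc[keep].reset_index(drop=True)


def _collapse_replicates(ct: pd.DataFrame) -> pd.DataFrame:
    """Mean Ct per (animal, group, gene); warn on wide replicate spread."""
    grouped = ct.groupby(["animal_id", "group", "gene"], sort=False)["ct"]
    spread = grouped.agg(lambda v: v.max() - v.min())
    wide = spread[spread > REPLICATE_RANGE_WARN]
    for (animal, _, gene), rng in wide.items():
        logger.warning(
            "replicate Ct range %.2f > %.1f for animal %s gene %s",
            rng, REPLICATE_RANGE_WARN, animal, gene,
        )
    return grouped.mean().reset_index()


def relative_expression(
    ct: pd.DataFrame,
    efficiencies: Union[Mapping[str, float], Iterable[StandardCurve]],
    refs: Sequence[str] = DEFAULT_REFERENCES,
    control_label: str = "control",
) -> ExpressionMatrix:
    """Efficiency-corrected relative expression per animal and target gene.

    Replicates are averaged; dCt subtracts the arithmetic-mean Ct of the
    reference genes; ddCt subtracts the control-group mean dCt per gene;
    expression is ``(1 + E_gene)^(-ddCt)``.
    """
    if not isinstance(efficiencies, Mapping):
        efficiencies = {c.gene: c.efficiency for c in efficiencies}
    collapsed = _collapse_replicates(ct)
    wide = collapsed.pivot(index="animal_id", columns="gene", values="ct")
    groups = collapsed.drop_duplicates("animal_id").set_index("animal_id")["group"]
    groups = groups.reindex(wide.index)

    for ref in refs:
        if ref not in wide.columns:
            raise ValueError(f"reference gene {ref} absent from Ct table")
        bad = wide.index[wide[ref].isna()]
        if len(bad):
            raise ValueError(
                f"missing reference gene {ref} measurement for animal(s) "
                f"{list(bad)}"
            )
    targets = [g for g in wide.columns if g not in refs]
    missing_eff = [g for g in targets if g not in efficiencies]
    if missing_eff:
        raise ValueError(f"no amplification efficiency for gene(s) {missing_eff}")

    control_mask = groups == control_label
    if not control_mask.any():
        raise ValueError(f"no animals in control group {control_label!r}")

    ref_ct = wide[list(refs)].mean(axis=1)
    dct = wide[targets].sub(ref_ct, axis=0)
    if dct.isna().any().any():
        bad = dct.columns[dct.isna().any()].tolist()
        raise ValueError(f"missing target Ct measurements for gene(s) {bad}")
    ddct = dct - dct.loc[control_mask].mean(axis=0)
    eff = np.array([efficiencies[g] for g in targets], dtype=float)
    expr = np.power(1.0 + eff, -ddct)
    return ExpressionMatrix(values=expr, groups=groups)
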