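"""Between-animal homogeneity metrics for candidate wound-age indicators.

For each (gene, contusion group) the dispersion of relative expression over
animals is summarised by four metrics:

* MD  — mean absolute deviation from the group mean;
* STD — sample standard deviation (n-1 denominator);
* d%  — relative average deviation, MD / mean x 100;
* CV  — coefficient of variation, STD / mean x 100.

Two gene-level statistics compress the per-group CVs:

* CVs (CV score) — at every contusion time point the genes are ranked by
  ascending CV and scored by quartile (smallest quarter 4 points, then 3,
  2, 1); a gene's CVs is the sum of its scores over the 12 contusion time
  points, so more homogeneous genes score higher.
* CV'CV — the coefficient of variation of a gene's CV values across time
  points, reported as a ratio; lower means the gene's between-animal
  spread is stable over the post-injury time course.

Scores use rank positions with ceiling cut points, which yields exact
quarters when the panel size is divisible by 4 (the 28-gene design) and a
deterministic convention otherwise; ties are broken by gene symbol.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .are_screen import GeneRecord
from .qpcr import ExpressionMatrix

logger = logging.getLogger(__name__)

SCORE_POINTS = (4, 3, 2, 1)


@dataclass(frozen=True)
class DispersionStats:
    """Dispersion of one gene's expression within one group of animals."""

    mean: float
    md: float
    std: float
    d_pct: float  # MD / mean x 100
    cv: float  # STD / mean x 100
    n: int
    gene: Optional[str] = None
    group: Optional[str] = None


def dispersion(values: Sequence[float], gene: str | None = None,
               group: str | None = None) -> DispersionStats:
    """MD, STD (n-1), d% and CV of a group of positive expression values."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError(f"need >= 2 values, got {x.size}")
    if (x <= 0).any():
        raise ValueError("expression values must be strictly positive")
    mean = float(x.mean())
    md = float(np.abs(x - mean).mean())
    std = float(x.std(ddof=1))
    return DispersionStats(
        mean=mean, md=md, std=std,
        d_pct=md / mean * 100.0, cv=std / mean * 100.0,
        n=int(x.size), gene=gene, group=group,
    )


def dispersion_table(expr: ExpressionMatrix) -> pd.DataFrame:
    """Per-(gene, group) dispersion metrics over animals, all groups."""
    rows = []
    for group, idx in expr.groups.groupby(expr.groups).groups.items():
        sub = expr.values.loc[idx]
        for gene in expr.values.columns:
            d = dispersion(sub[gene].to_numpy(), gene=gene, group=str(group))
            rows.append(
                {
                    "gene": gene, "group": group, "n": d.n, "mean": d.mean,
                    "md": d.md, "std": d.std, "d_pct": d.d_pct, "cv": d.cv,
                }
            )
    return pd.DataFrame(rows)


def cv_score(cv_matrix: pd.DataFrame) -> pd.Series:
    """Quartile-rank CV score per gene, summed over the scored time points.

    ``cv_matrix`` is genes x time points.  At each time point genes are
    ranked by ascending CV (ties broken by gene symbol); with N genes the
    first ceil(N/4) ranks score 4 points, ranks up to ceil(N/2) score 3,
    up to ceil(3N/4) score 2, and the rest 1.
    """
    n = len(cv_matrix.index)
    if n < 4:
        raise ValueError(f"quartile scoring needs >= 4 genes, got {n}")
    if cv_matrix.isna().any().any():
        raise ValueError("CV matrix contains missing values")
    cuts = (
        math.ceil(n / 4),
        math.ceil(n / 2),
        math.ceil(3 * n / 4),
    )
    points_by_rank = np.empty(n, dtype=int)
    points_by_rank[: cuts[0]] = 4
    points_by_rank[cuts[0] : cuts[1]] = 3
    points_by_rank[cuts[1] : cuts[2]] = 2
    points_by_rank[cuts[2] :] = 1

    total = pd.Series(0, index=cv_matrix.index, dtype=int)
    for col in cv_matrix.columns:
        # ascending CV, ties broken by gene symbol for determinism
        order = sorted(cv_matrix.index, key=lambda g: (cv_matrix.at[g, col], str(g)))
        for rank, gene in enumerate(order):
            total[gene] += points_by_rank[rank]
    return total


def cv_of_cv(cv_series: Sequence[float]) -> float:
    """Coefficient of variation of a gene's CV values across time points.

    Returned as a ratio (sample SD / mean), not a percentage.
    """
    x = np.asarray(cv_series, dtype=float)
    if x.size < 2:
        raise ValueError("CV'CV needs >= 2 time points")
    mean = x.mean()
    if mean <= 0:
        raise ValueError("CV series mean must be positive")
    return float(x.std(ddof=1) / mean)


def contusion_cv_matrix(
    disp: pd.DataFrame,
    control_label: str = "control",
    include_control: bool = False,
) -> pd.DataFrame:
    """Pivot the dispersion table to genes x time points of CV values."""
    sub = disp if include_control else disp[disp["group"] != control_label]
    mat = sub.pivot(index="gene", columns="group", values="cv")
    # preserve the time ordering of the groups as they appear in the table
    seen = [g for g in sub["group"].drop_duplicates() if g in mat.columns]
    return mat[seen]


def score_table(
    expr: ExpressionMatrix,
    control_label: str = "control",
    include_control: bool = False,
) -> pd.DataFrame:
    """Per-gene CVs and CV'CV over the contusion time points."""
    disp = dispersion_table(expr)
    mat = contusion_cv_matrix(disp, control_label, include_control)
    cvs = cv_score(mat)
    cvcv = mat.apply(lambda row: cv_of_cv(row.to_numpy()), axis=1)
    return pd.DataFrame({"cvs": cvs, "cv_of_cv": cvcv})


def aggregate_subgroups(
    disp: pd.DataFrame,
    scores: pd.DataFrame,
    records: Iterable[GeneRecord],
    control_label: str = "control",
    include_control: bool = False,
    units: str = "ratio",
) -> pd.DataFrame:
    """Subgroup-level homogeneity summary (one row per subgroup).

    Each metric is first averaged per gene across the scored groups, then
    averaged (unweighted) across the subgroup's member genes.  With
    ``units='ratio'`` d% and CV are reported as fractions (0.344-style);
    ``units='percent'`` keeps them on the 0-100 scale.
    """
    if units not in ("ratio", "percent"):
        raise ValueError("units must be 'ratio' or 'percent'")
    scale = 0.01 if units == "ratio" else 1.0
    sub_disp = disp if include_control else disp[disp["group"] != control_label]
    per_gene = sub_disp.groupby("gene")[["md", "std", "d_pct", "cv"]].mean()

    membership: dict[str, list[str]] = {}
    for rec in records:
        if rec.is_reference or rec.subgroup in (None, "excluded"):
            continue
        membership.setdefault(rec.subgroup, []).append(rec.symbol)

    rows = []
    for subgroup in sorted(membership):
        genes = [g for g in membership[subgroup] if g in per_gene.index]
        if not genes:
            logger.warning("subgroup %s has no scored genes; omitted", subgroup)
            continue
        block = per_gene.loc[genes]
        rows.append(
            {
                "subgroup": subgroup,
                "n_genes": len(genes),
                "md": block["md"].mean(),
                "std": block["std"].mean(),
                "d_pct": block["d_pct"].mean() * scale,
                "cv": block["cv"].mean() * scale,
                "cv_of_cv": scores.loc[genes, "cv_of_cv"].mean(),
                "cvs": scores.loc[genes, "cvs"].mean(),
            }
        )
    return pd.DataFrame(rows).set_index("subgroup")
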