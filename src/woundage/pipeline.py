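"""End-to-end orchestration: simulate -> screen -> quantify -> score -> model.

A single seeded run writes every table the screening framework produces:
the gene panel (candidate metadata), 3'UTR FASTA, the long-format Ct table,
dilution series, sample QC, the per-animal expression matrix, per-(gene,
group) dispersion metrics, per-gene CVs / CV'CV scores, the subgroup
homogeneity summary, and the discriminant-model summary with per-subset
confusion matrices, plus a JSON manifest recording the seed and row counts.
Identical config + seed reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .are_screen import call_are_status, DEFAULT_ARE_THRESHOLD
from .discriminant import discriminant_summary
from .homogeneity import aggregate_subgroups, dispersion_table, score_table
from .qpcr import (
    ExpressionMatrix,
    apply_sample_qc,
    fit_standard_curves,
    relative_expression,
)
from .synthetic import (
    CONTROL_LABEL,
    GenePanel,
    SimulationConfig,
    generate_gene_panel,
    simulate_ct_table,
    simulate_dilution_series,
    simulate_sample_qc,
)
from . import io as wio

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    out_dir: Path = Path("woundage_run")
    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    are_threshold: float = DEFAULT_ARE_THRESHOLD
    include_control_in_scores: bool = False
    ridge_epsilon: float = 0.0
    priors: str = "equal"
    units: str = "ratio"  # d%/CV dialect of the subgroup summary

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        self.simulation = dataclasses.replace(self.simulation, seed=self.seed)

    @classmethod
    def from_yaml(cls, path: Union[str, Path], **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        sim_raw = raw.pop("simulation", {})
        sim = SimulationConfig(**sim_raw)
        return cls(simulation=sim, **raw)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and write the result tables; returns the manifest."""
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "version": __version__, "stages": {}}

    def stage(name):
        logger.info("stage %s", name)
        return manifest["stages"].setdefault(name, {})

    # --- simulate -------------------------------------------------------
    info = stage("simulate")
    panel = generate_gene_panel(config.simulation)
    ct = simulate_ct_table(panel)
    qc = simulate_sample_qc(panel)
    dilutions = pd.concat(
        [
            simulate_dilution_series(rec, config=config.simulation)
            for rec in panel.records
        ],
        ignore_index=True,
    )
    wio.write_gene_metadata(panel.records, out / "gene_panel.csv")
    wio.write_fasta(panel.utr_sequences, out / "utrs.fasta")
    wio.write_ct_csv(ct, out / "ct.csv")
    qc.to_csv(out / "qc.csv", index=False)
    dilutions.to_csv(out / "dilutions.csv", index=False)
    info.update(n_genes=len(panel.records), n_ct_rows=len(ct))

    # --- ARE screen -----------------------------------------------------
    info = stage("arescan")
    calls = screen_panel(panel, threshold=config.are_threshold)
    calls.to_csv(out / "are_calls.csv", index=False)
    mismatch = [
        rec.symbol
        for rec, called in zip(panel.target_records,
                               calls.set_index("symbol").loc[
                                   [r.symbol for r in panel.target_records],
                                   "are_status",
                               ])
        if rec.are_status != called
    ]
    if mismatch:
        raise RuntimeError(
            f"stage arescan: planted ARE label not recovered for {mismatch}"
        )
    info.update(n_scanned=len(calls))

    # --- quantify -------------------------------------------------------
    info = stage("quantify")
    ct_clean = apply_sample_qc(qc, ct)
    curves = fit_standard_curves(dilutions)
    failing = [c.gene for c in curves if not c.passes_rsq_gate]
    if failing:
        logger.warning("standard curves below the Rsq gate: %s", failing)
    try:
        expr = relative_expression(
            ct_clean,
            curves,
            refs=tuple(panel.reference_symbols),
            control_label=CONTROL_LABEL,
        )
    except ValueError as exc:
        raise RuntimeError(f"stage quantify: {exc}") from exc
    expr.to_frame().to_csv(out / "expression.csv")
    info.update(n_animals=len(expr.values), n_targets=expr.values.shape[1])

    # --- homogeneity ----------------------------------------------------
    info = stage("homogeneity")
    disp = dispersion_table(expr)
    scores = score_table(
        expr, include_control=config.include_control_in_scores
    )
    summary = aggregate_subgroups(
        disp,
        scores,
        panel.records,
        include_control=config.include_control_in_scores,
        units=config.units,
    )
    disp.to_csv(out / "dispersion.csv", index=False)
    scores.to_csv(out / "gene_scores.csv")
    summary.to_csv(out / "subgroup_summary.csv")
    info.update(n_subgroups=len(summary))

    # --- discriminate ---------------------------------------------------
    info = stage("discriminate")
    table, confusions = discriminant_summary(
        expr,
        panel.records,
        priors=config.priors,
        ridge_epsilon=config.ridge_epsilon,
    )
    table.to_csv(out / "discriminant_summary.csv")
    safe = {"ARE+": "ARE_plus", "ARE-": "ARE_minus"}
    for name, conf in confusions.items():
        fname = name
        for k, v in safe.items():
            fname = fname.replace(k, v)
        conf.to_csv(out / f"confusion_{fname}.csv")
    info.update(n_models=len(table))

    manifest["stages"]["homogeneity"]["subgroup_rows"] = len(summary)
    manifest["stages"]["discriminate"]["model_rows"] = len(table)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def screen_panel(
    panel: GenePanel, threshold: float = DEFAULT_ARE_THRESHOLD
) -> pd.DataFrame:
    """Scan every panel UTR and call ARE class, score, and status."""
    from .are_screen import are_score, classify_are, scan_pentamers

    rows = []
    for rec in panel.records:
        seq = panel.utr_sequences[rec.symbol]
        are_class, _ = classify_are(seq)
        rows.append(
            {
                "symbol": rec.symbol,
                "n_pentamers": len(scan_pentamers(seq)),
                "are_class": are_class,
                "are_score": are_score(seq),
                "are_status": call_are_status(rec, seq, threshold=threshold),
            }
        )
    return pd.DataFrame(rows)


def run_synthetic_study(
    seed: int = 0, simulation: Optional[SimulationConfig] = None
) -> tuple[GenePanel, ExpressionMatrix]:
    """In-memory convenience: simulate a study and quantify expression."""
    sim = simulation or SimulationConfig()
    sim = dataclasses.replace(sim, seed=seed)
    panel = generate_gene_panel(sim)
    ct = simulate_ct_table(panel)
    eff = {r.symbol: r.efficiency for r in panel.records}
    expr = relative_expression(
        ct, eff, refs=tuple(panel.reference_symbols), control_label=CONTROL_LABEL
    )
    return panel, expr
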