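"""Synthetic study generator: determinism, design shape, and noise model."""

import math

import numpy as np
import pandas as pd
import pytest

from woundage.are_screen import scan_pentamers
from woundage.homogeneity import dispersion
from woundage.qpcr import fit_standard_curve, relative_expression
from woundage.synthetic import (
    SimulationConfig,
    generate_gene_panel,
    simulate_ct_table,
    simulate_dilution_series,
)

ALL_SUBGROUPS = ("ARE-CC", "ARE-BP", "ARE-MF", "ARE+CC", "ARE+BP", "ARE+MF")


class TestConfig:
    def test_default_panel_counts(self):
        cfg = SimulationConfig()
        assert sum(cfg.genes_per_subgroup.values()) == 28
        assert cfg.n_groups == 13 and cfg.n_per_group == 6

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_groups": 1},
            {"genes_per_subgroup": {"ARE-CC": 0}},
            {"subgroup_sigma": {"ARE-CC": -0.1}},
            {"efficiency_range": (0.5, 1.0)},
            {"efficiency_range": (0.9, 1.3)},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)


class TestGenePanel:
    def test_panel_size_and_subgroups(self, default_panel):
        assert len(default_panel.records) == 30  # 28 targets + 2 references
        counts = {}
        for rec in default_panel.target_records:
            counts[rec.subgroup] = counts.get(rec.subgroup, 0) + 1
        assert counts == {
            "ARE-CC": 6, "ARE-BP": 5, "ARE-MF": 5,
            "ARE+CC": 4, "ARE+BP": 4, "ARE+MF": 4,
        }
        assert default_panel.reference_symbols == ["RPL13", "RPL32"]

    def test_are_negative_utrs_are_pentamer_free(self, default_panel):
        for rec in default_panel.records:
            if rec.is_reference or rec.are_status == "ARE-":
                assert scan_pentamers(default_panel.utr_sequences[rec.symbol]) == []

    def test_are_positive_utrs_score_above_threshold(self, default_panel):
        for rec in default_panel.target_records:
            if rec.are_status == "ARE+":
                assert rec.are_score > 3.0
                assert rec.are_class in {"I", "II"}

    def test_reference_genes_have_flat_profiles(self, default_panel):
        for sym in default_panel.reference_symbols:
            assert np.all(default_panel.true_profiles[sym] == 0.0)

    def test_profiles_are_zero_at_control_and_hit_amplitude(self, default_panel):
        for rec in default_panel.target_records:
            prof = default_panel.true_profiles[rec.symbol]
            assert prof[0] == pytest.approx(0.0)
            assert np.max(np.abs(prof)) == pytest.approx(2.0 * math.log(2))

    def test_determinism(self):
        cfg = SimulationConfig(seed=42)
        a = generate_gene_panel(cfg)
        b = generate_gene_panel(cfg)
        assert a.utr_sequences == b.utr_sequences
        assert a.base_ct == b.base_ct
        for sym in a.true_profiles:
            assert np.array_equal(a.true_profiles[sym], b.true_profiles[sym])

    def test_efficiencies_within_range(self, default_panel):
        lo, hi = default_panel.config.efficiency_range
        for rec in default_panel.records:
            assert lo <= rec.efficiency <= hi


class TestCtTable:
    def test_row_count_is_design_product(self, default_panel):
        ct = simulate_ct_table(default_panel)
        assert len(ct) == 13 * 6 * 30 * 3

    def test_determinism(self, default_panel):
        a = simulate_ct_table(default_panel)
        b = simulate_ct_table(default_panel)
        pd.testing.assert_frame_equal(a, b)

    def test_zero_variation_gives_zero_cv(self):
        sim = SimulationConfig(
            subgroup_sigma={s: 0.0 for s in ALL_SUBGROUPS},
            technical_sd=0.0,
            reference_sigma=0.0,
            seed=5,
        )
        panel = generate_gene_panel(sim)
        ct = simulate_ct_table(panel)
        eff = {r.symbol: r.efficiency for r in panel.records}
        expr = relative_expression(ct, eff)
        for group, idx in expr.groups.groupby(expr.groups).groups.items():
            block = expr.values.loc[idx]
            for gene in block.columns:
                assert dispersion(block[gene]).cv == pytest.approx(0.0, abs=1e-9)

    def test_lognormal_sigma_sets_natural_scale_cv(self):
        # CV of exp(N(0, sigma^2)) is sqrt(exp(sigma^2) - 1); recover it
        # through the full Ct round trip with a large per-group sample.
        sigma = 0.2
        sim = SimulationConfig(
            n_groups=2,
            n_per_group=1500,
            genes_per_subgroup={"ARE-CC": 1},
            subgroup_sigma={"ARE-CC": sigma},
            technical_sd=0.0,
            reference_sigma=0.0,
            seed=7,
        )
        panel = generate_gene_panel(sim)
        ct = simulate_ct_table(panel)
        eff = {r.symbol: r.efficiency for r in panel.records}
        expr = relative_expression(ct, eff)
        expected = math.sqrt(math.exp(sigma**2) - 1.0)
        for group, idx in expr.groups.groupby(expr.groups).groups.items():
            cv = dispersion(expr.values.loc[idx].iloc[:, 0]).cv / 100.0
            assert cv == pytest.approx(expected, rel=0.05)

    def test_reference_genes_more_stable_than_targets(self, default_study):
        panel, expr = default_study
        # recompute expression including references via raw Ct round trip
        ct = simulate_ct_table(panel)
        eff = {r.symbol: r.efficiency for r in panel.records}
        collapsed = ct.groupby(["animal_id", "group", "gene"])["ct"].mean().reset_index()
        wide = collapsed.pivot(index="animal_id", columns="gene", values="ct")
        # reference Ct spread across animals of one group is far below targets'
        groups = collapsed.drop_duplicates("animal_id").set_index("animal_id")["group"]
        ref_sd = wide.loc[groups == "4h", ["RPL13", "RPL32"]].std().max()
        target = [r.symbol for r in panel.target_records]
        target_sd = wide.loc[groups == "4h", target].std().min()
        assert ref_sd < target_sd


class TestDilutionSeries:
    def test_perfect_doubling_step(self):
        from woundage.are_screen import GeneRecord

        table = simulate_dilution_series(GeneRecord("g", efficiency=1.0))
        steps = np.diff(table["ct"].to_numpy())
        assert np.allclose(steps, math.log2(5.0))

    @pytest.mark.parametrize("target", [0.85, 0.9, 1.0])
    def test_efficiency_round_trip(self, target):
        from woundage.are_screen import GeneRecord

        curve = fit_standard_curve(
            simulate_dilution_series(GeneRecord("g", efficiency=target))
        )
        assert curve.efficiency == pytest.approx(target, abs=1e-9)
        assert curve.rsq == pytest.approx(1.0)

    def test_minimum_levels(self, default_panel):
        with pytest.raises(ValueError):
            simulate_dilution_series(default_panel.records[0], levels=2)


def test_dispersion_ordering_recovered_across_seeds():
    """Subgroup sigma ordering shows up as the mean-CV ordering downstream."""
    from woundage.homogeneity import dispersion_table
    from woundage.pipeline import run_synthetic_study

    order = ["ARE-CC", "ARE-MF", "ARE-BP", "ARE+CC", "ARE+BP", "ARE+MF"]
    hits = 0
    n_runs = 20
    for seed in range(n_runs):
        panel, expr = run_synthetic_study(seed=seed)
        disp = dispersion_table(expr)
        disp = disp[disp["group"] != "control"]
        sub_of = {r.symbol: r.subgroup for r in panel.target_records}
        disp["subgroup"] = disp["gene"].map(sub_of)
        mean_cv = disp.groupby("subgroup")["cv"].mean()
        hits += list(mean_cv.sort_values().index) == order
    assert hits >= 0.95 * n_runs
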