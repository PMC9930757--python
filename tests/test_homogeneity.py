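"""Dispersion metrics, quartile CV scores, CV'CV, and subgroup aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from woundage.are_screen import GeneRecord
from woundage.homogeneity import (
    aggregate_subgroups,
    cv_of_cv,
    cv_score,
    dispersion,
)

positive_arrays = st.lists(
    st.floats(min_value=0.01, max_value=1e4, allow_nan=False), min_size=2, max_size=40
)


def brute_force_dispersion(x):
    n = len(x)
    mean = sum(x) / n
    md = sum(abs(v - mean) for v in x) / n
    var = sum((v - mean) ** 2 for v in x) / (n - 1)
    std = var**0.5
    return mean, md, std, md / mean * 100.0, std / mean * 100.0


class TestDispersion:
    def test_constant_group_has_zero_spread(self):
        d = dispersion([2.0] * 6)
        assert (d.md, d.std, d.d_pct, d.cv) == (0.0, 0.0, 0.0, 0.0)

    def test_hand_computed_example(self):
        d = dispersion([1.0, 2.0, 3.0])
        assert d.mean == pytest.approx(2.0)
        assert d.md == pytest.approx(2.0 / 3.0)
        assert d.std == pytest.approx(1.0)  # n-1 denominator
        assert d.d_pct == pytest.approx(100.0 / 3.0)
        assert d.cv == pytest.approx(50.0)

    @given(positive_arrays, st.floats(min_value=0.01, max_value=100.0))
    @settings(max_examples=100, deadline=None)
    def test_relative_metrics_are_scale_invariant(self, values, k):
        a = dispersion(values)
        b = dispersion([v * k for v in values])
        assert b.d_pct == pytest.approx(a.d_pct, rel=1e-9)
        assert b.cv == pytest.approx(a.cv, rel=1e-9)

    def test_agrees_with_brute_force_oracle(self, rng):
        for _ in range(1000):
            x = rng.uniform(0.01, 100.0, size=rng.integers(2, 20)).tolist()
            d = dispersion(x)
            mean, md, std, d_pct, cv = brute_force_dispersion(x)
            assert d.mean == pytest.approx(mean, rel=1e-12)
            assert d.md == pytest.approx(md, rel=1e-12)
            assert d.std == pytest.approx(std, rel=1e-12)
            assert d.d_pct == pytest.approx(d_pct, rel=1e-12)
            assert d.cv == pytest.approx(cv, rel=1e-12)

    @pytest.mark.parametrize("bad", [[1.0], [1.0, -2.0], [1.0, 0.0]])
    def test_invalid_inputs_rejected(self, bad):
        with pytest.raises(ValueError):
            dispersion(bad)


def cv_frame(values, genes=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i:02d}" for i in range(values.shape[0])]
    cols = [f"t{j}" for j in range(values.shape[1])]
    return pd.DataFrame(values, index=genes, columns=cols)


class TestCvScore:
    def test_eight_genes_quartile_pattern(self):
        mat = cv_frame(np.arange(8.0).reshape(8, 1))
        scores = cv_score(mat)
        assert scores.tolist() == [4, 4, 3, 3, 2, 2, 1, 1]

    def test_best_gene_scores_four_per_time_point(self, rng):
        mat = cv_frame(rng.uniform(10, 50, size=(28, 12)))
        mat.iloc[0] = 1.0  # smallest CV everywhere
        assert cv_score(mat)["g00"] == 48

    def test_column_sums_conserved_at_28_genes(self, rng):
        for _ in range(100):
            mat = cv_frame(rng.uniform(1, 100, size=(28, 12)))
            scores = cv_score(mat)
            # 7 genes per quartile x (4+3+2+1) per time point, 12 time points
            assert scores.sum() == 70 * 12

    def test_rank_based_hence_monotone_invariant(self, rng):
        mat = cv_frame(rng.uniform(1, 100, size=(12, 5)))
        transformed = np.exp(mat / 20.0)  # strictly monotone
        pd.testing.assert_series_equal(cv_score(mat), cv_score(transformed))

    def test_ties_break_by_gene_symbol(self):
        mat = cv_frame(np.ones((4, 1)), genes=["d", "c", "b", "a"])
        scores = cv_score(mat)
        assert scores["a"] == 4 and scores["d"] == 1

    def test_fewer_than_four_genes_rejected(self):
        with pytest.raises(ValueError, match=">= 4"):
            cv_score(cv_frame(np.ones((3, 2))))


class TestCvOfCv:
    def test_constant_series_is_zero(self):
        assert cv_of_cv([7.0] * 12) == 0.0

    def test_hand_computed_example(self):
        assert cv_of_cv([10.0, 20.0, 30.0]) == pytest.approx(0.5)

    @given(st.lists(st.floats(min_value=0.1, max_value=100.0), min_size=2, max_size=20),
           st.floats(min_value=0.01, max_value=50.0))
    @settings(max_examples=100, deadline=None)
    def test_scale_invariant(self, series, k):
        assert cv_of_cv([v * k for v in series]) == pytest.approx(
            cv_of_cv(series), rel=1e-9
        )

    def test_agrees_with_brute_force_oracle(self, rng):
        for _ in range(1000):
            x = rng.uniform(0.1, 100.0, size=rng.integers(2, 15))
            n = len(x)
            mean = x.sum() / n
            sd = (((x - mean) ** 2).sum() / (n - 1)) ** 0.5
            assert cv_of_cv(x) == pytest.approx(sd / mean, rel=1e-12)

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError):
            cv_of_cv([0.0, 0.0, 0.0])


class TestAggregateSubgroups:
    def _records(self):
        recs = []
        for i in range(6):
            recs.append(
                GeneRecord(f"g{i:02d}", are_status="ARE-",
                           go_category=("CC",), subgroup="ARE-CC")
            )
        recs.append(
            GeneRecord("solo", are_status="ARE+", go_category=("MF",),
                       subgroup="ARE+MF")
        )
        return recs

    def _tables(self, rng):
        genes = [f"g{i:02d}" for i in range(6)] + ["solo"]
        rows = []
        for g in genes:
            for t in ["4h", "8h"]:
                rows.append(
                    {"gene": g, "group": t, "n": 6, "mean": 1.0,
                     "md": rng.uniform(0.1, 0.5), "std": rng.uniform(0.1, 0.6),
                     "d_pct": rng.uniform(10, 40), "cv": rng.uniform(10, 50)}
                )
        disp = pd.DataFrame(rows)
        scores = pd.DataFrame(
            {"cvs": [40, 39, 38, 38, 37, 38, 20],
             "cv_of_cv": rng.uniform(0.2, 0.4, size=7)},
            index=genes,
        )
        return disp, scores

    def test_subgroup_means_and_units(self, rng):
        disp, scores = self._tables(rng)
        out = aggregate_subgroups(disp, scores, self._records(), units="ratio")
        member = [f"g{i:02d}" for i in range(6)]
        assert out.loc["ARE-CC", "cvs"] == pytest.approx(38.33, abs=0.01)
        expected_cv = disp[disp["gene"].isin(member)].groupby("gene")["cv"].mean().mean()
        assert out.loc["ARE-CC", "cv"] == pytest.approx(expected_cv / 100.0)
        pct = aggregate_subgroups(disp, scores, self._records(), units="percent")
        assert pct.loc["ARE-CC", "cv"] == pytest.approx(expected_cv)

    def test_single_gene_subgroup_equals_gene_metrics(self, rng):
        disp, scores = self._tables(rng)
        out = aggregate_subgroups(disp, scores, self._records())
        assert out.loc["ARE+MF", "cvs"] == 20
        solo_cv = disp[disp["gene"] == "solo"]["cv"].mean()
        assert out.loc["ARE+MF", "cv"] == pytest.approx(solo_cv / 100.0)

    def test_empty_subgroup_omitted(self, rng):
        disp, scores = self._tables(rng)
        recs = self._records() + [
            GeneRecord("ghost", are_status="ARE+", go_category=("BP",),
                       subgroup="ARE+BP")
        ]
        out = aggregate_subgroups(disp, scores, recs)
        assert "ARE+BP" not in out.index
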