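"""Regulation calling: preprocessing, Significance A, BH-FDR, fold-change gate."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import erfc
from scipy.stats import hypergeom

from csdstools.proteomics import (
    bh_adjust,
    call_regulated,
    enrichment_hypergeometric,
    filter_min_valid,
    preprocess,
    run_all_comparisons,
    significance_A,
)

DESIGN = pd.Series(
    {"c1": "control", "c2": "control", "r1": "resilient", "r2": "resilient",
     "s1": "susceptible", "s2": "susceptible"}
)


class TestPreprocess:
    def test_log2_then_center(self):
        m = pd.DataFrame({"a": [2.0, 8.0]}, index=["p1", "p2"])
        out = preprocess(m)
        assert list(out["a"]) == [-1.0, 1.0]

    def test_constant_sample_becomes_zero(self):
        m = pd.DataFrame({"a": [4.0, 4.0, 4.0]})
        assert (preprocess(m)["a"] == 0).all()

    def test_observed_median_is_exactly_zero(self):
        rng = np.random.default_rng(2)
        m = pd.DataFrame(rng.lognormal(3, 1, (51, 4)))
        m[m < 5] = np.nan
        out = preprocess(m)
        med = np.nanmedian(out.to_numpy(), axis=0)
        assert np.allclose(med, 0.0)

    def test_nonpositive_intensity_rejected(self):
        with pytest.raises(ValueError):
            preprocess(pd.DataFrame({"a": [2.0, -1.0]}))


class TestMinValidFilter:
    def _matrix(self):
        data = np.full((3, 6), 100.0)
        m = pd.DataFrame(data, index=["p1", "p2", "p3"], columns=DESIGN.index)
        m.loc["p2", "c2"] = np.nan  # only 1 valid control value
        return m

    def test_protein_below_two_in_one_group_removed(self):
        out, log = filter_min_valid(self._matrix(), DESIGN)
        assert "p2" not in out.index and len(out) == 2
        assert log == {"n_before": 3, "n_after": 2, "n_removed": 1}

    def test_any_group_scope_keeps_it(self):
        out, _ = filter_min_valid(self._matrix(), DESIGN, scope="any_group")
        assert "p2" in out.index

    def test_empty_matrix(self):
        empty = pd.DataFrame(columns=DESIGN.index, dtype=float)
        out, log = filter_min_valid(empty, DESIGN)
        assert len(out) == 0 and log["n_before"] == 0


class TestSignificanceA:
    def test_p_at_median_is_1(self):
        d = np.concatenate([np.linspace(-3, 3, 101)])
        p = significance_A(d)
        assert p[50] == pytest.approx(1.0)

    def test_p_one_sigma_right_matches_gaussian_tail(self):
        rng = np.random.default_rng(4)
        d = rng.normal(0, 1, 10001)
        m = np.percentile(d, 50)
        s_r = np.percentile(d, 84.13) - m
        d2 = np.append(d, m + s_r)  # exactly at z = 1
        p = significance_A(d2)
        assert p[-1] == pytest.approx(erfc(1 / np.sqrt(2)), rel=1e-3)
        assert p[-1] == pytest.approx(0.3173, abs=5e-4)

    def test_symmetric_values_get_symmetric_p(self):
        d = np.linspace(-2, 2, 41)  # symmetric around 0
        p = significance_A(d)
        assert np.allclose(p, p[::-1])

    def test_approximately_uniform_under_gaussian(self):
        rng = np.random.default_rng(8)
        p = significance_A(rng.normal(0, 1, 20000))
        assert np.mean(p < 0.05) == pytest.approx(0.05, abs=0.01)

    def test_degenerate_distribution_rejected(self):
        with pytest.raises(ValueError):
            significance_A(np.zeros(50))


def oracle_bh(p):
    """Textbook step-up BH adjusted values (independent implementation)."""
    p = np.asarray(p, float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        q[i] = running
    return q


class TestBH:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])

    def test_four_small_p_all_below_alpha(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert (q < 0.05).all()
        assert q == pytest.approx(oracle_bh([0.01, 0.02, 0.03, 0.04]))

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=60))
    @settings(max_examples=150, deadline=None)
    def test_matches_stepup_oracle(self, p):
        assert bh_adjust(p) == pytest.approx(oracle_bh(p), abs=1e-12)

    def test_sorted_q_nondecreasing(self):
        rng = np.random.default_rng(9)
        p = rng.random(200)
        q = bh_adjust(p)
        assert np.all(np.diff(q[np.argsort(p)]) >= -1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestRegulationCall:
    @pytest.mark.parametrize(
        "delta,q,regulated,direction",
        [(1.0, 0.049, True, "up"),      # inclusive two-fold boundary
         (0.9, 0.001, False, "up"),     # significant but below two-fold
         (-2.3, 0.01, True, "down"),    # strongly downregulated (>4-fold)
         (2.0, 0.05, False, "up")],     # FDR boundary is exclusive
    )
    def test_gate(self, delta, q, regulated, direction):
        idx = pd.Index(["p"])
        res = call_regulated(pd.Series([delta], index=idx),
                             pd.Series([q], index=idx))
        row = res.table.iloc[0]
        assert bool(row["regulated"]) is regulated
        assert row["direction"] == direction


class TestRunAllComparisons:
    def _matrix(self, rng, n=300):
        base = rng.normal(20, 2, n)
        vals = base[:, None] + rng.normal(0, 0.3, (n, len(DESIGN)))
        return pd.DataFrame(np.power(2.0, vals),
                            index=[f"p{i}" for i in range(n)],
                            columns=DESIGN.index)

    def test_permuting_samples_within_group_is_invariant(self):
        rng = np.random.default_rng(12)
        m = self._matrix(rng)
        res1 = run_all_comparisons(m, DESIGN)
        swapped = m.rename(columns={"c1": "c2", "c2": "c1"})[m.columns]
        res2 = run_all_comparisons(swapped, DESIGN)
        for tag in res1["comparisons"]:
            pd.testing.assert_series_equal(
                res1["comparisons"][tag].table["delta_log2"],
                res2["comparisons"][tag].table["delta_log2"])

    def test_small_group_rejected(self):
        design = DESIGN.drop("s2")
        m = self._matrix(np.random.default_rng(0))[design.index]
        with pytest.raises(ValueError, match="at least 2"):
            run_all_comparisons(m, design)


class TestEnrichment:
    def test_exact_hypergeometric_tail(self):
        universe = [f"g{i}" for i in range(20)]
        regulated = universe[:5]
        ann = pd.DataFrame({"term": ["T"] * 5, "id": universe[:5]})
        out = enrichment_hypergeometric(regulated, ann, universe)
        expected = hypergeom.sf(4, 20, 5, 5)  # all five drawn
        assert out.iloc[0]["p"] == pytest.approx(expected)
        # closed-form check: 1 / C(20,5)
        from math import comb
        assert expected == pytest.approx(1 / comb(20, 5))

    def test_disjoint_term_near_1(self):
        universe = [f"g{i}" for i in range(20)]
        ann = pd.DataFrame({"term": ["T"] * 5, "id": universe[10:15]})
        out = enrichment_hypergeometric(universe[:5], ann, universe)
        assert out.iloc[0]["p"] == pytest.approx(1.0)

    def test_empty_regulated_set(self):
        universe = [f"g{i}" for i in range(10)]
        ann = pd.DataFrame({"term": ["T"] * 3, "id": universe[:3]})
        out = enrichment_hypergeometric([], ann, universe)
        assert (out["p"] == 1.0).all()
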