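"""Tier-1 diagnostics: run filters, loess decomposition, sign test, correlations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trophiclink import association, synthgrid
from trophiclink.association import (
    Decomposition,
    binomial_sign_p,
    cell_slopes,
    decompose,
    longest_run,
    remainder_correlations,
    sign_agreement,
)
from trophiclink.errors import ValidationError


class TestLongestRun:
    def test_picks_longest_consecutive_stretch(self):
        years = [2001, 2002, 2003, 2005, 2006, 2007, 2008, 2009, 2010]
        vals = list(range(9))
        ys, vs = longest_run(years, vals, min_run=3)
        assert ys.tolist() == [2005, 2006, 2007, 2008, 2009, 2010]

    def test_short_runs_rejected_by_default_ten_year_rule(self):
        years = list(range(2000, 2009))  # 9 consecutive years
        assert longest_run(years, np.ones(9)) is None

    def test_zero_fraction_filter(self):
        years = list(range(2000, 2012))
        vals = [0] * 7 + [1] * 5  # 7/12 > 0.5
        assert longest_run(years, vals, min_run=10) is None
        vals = [0] * 6 + [1] * 6  # exactly 0.5 is allowed
        assert longest_run(years, vals, min_run=10) is not None

    def test_tie_broken_toward_most_recent(self):
        years = [2000, 2001, 2002, 2005, 2006, 2007]
        ys, _ = longest_run(years, np.ones(6), min_run=3)
        assert ys.tolist() == [2005, 2006, 2007]

    def test_missing_values_break_runs(self):
        years = list(range(2000, 2012))
        vals = np.ones(12)
        vals[5] = np.nan
        ys, _ = longest_run(years, vals, min_run=3)
        assert ys.tolist() == list(range(2006, 2012))


class TestDecompose:
    def test_identity_exact(self, rng):
        for _ in range(10):
            n = rng.integers(5, 40)
            vals = rng.normal(size=n).cumsum()
            d = decompose(np.arange(2000, 2000 + n), vals)
            assert np.abs(d.observed - d.trend - d.remainder).max() < 1e-12

    def test_linear_series_has_zero_remainder(self):
        years = np.arange(2000, 2015)
        vals = 0.5 * years - 3.0
        d = decompose(years, vals)
        assert np.abs(d.remainder).max() < 1e-10

    def test_constant_series(self):
        d = decompose(np.arange(2000, 2010), np.full(10, 4.2))
        assert np.allclose(d.trend, 4.2) and np.abs(d.remainder).max() < 1e-10

    def test_too_short_rejected(self):
        with pytest.raises(ValidationError, match="5"):
            decompose([2000, 2001, 2002, 2003], [1, 2, 3, 4])


def slopes_frame(slopes, scale=100_000):
    return pd.DataFrame({
        "scale_m": scale, "ix": np.arange(len(slopes)), "iy": 0,
        "slope": slopes, "var_slope": 0.01, "n_years": 10,
        "sign": ["increasing" if s > 0 else "decreasing" if s < 0 else "zero"
                 for s in slopes],
    })


class TestCellSlopes:
    def cell_series(self, per_cell):
        rows = []
        for c, (years, vals) in enumerate(per_cell):
            for y, v in zip(years, vals):
                rows.append((100_000, c, 0, y, v))
        return pd.DataFrame(rows, columns=["scale_m", "ix", "iy", "year", "value"])

    def test_ols_slope_of_line(self):
        cs = self.cell_series([(np.array([1, 2, 3]), np.array([1.0, 2.0, 3.0]))])
        out = cell_slopes(cs, method="ols")
        assert out["slope"].iloc[0] == pytest.approx(1.0)

    def test_single_cell_shrunk_equals_ols(self):
        cs = self.cell_series([(np.arange(5), np.array([1, 3, 2, 5, 4.0]))])
        a = cell_slopes(cs, method="ols")["slope"].iloc[0]
        b = cell_slopes(cs, method="shrunk")["slope"].iloc[0]
        assert a == pytest.approx(b)

    def test_shrunk_between_ols_and_grand_mean(self, rng):
        per_cell = [(np.arange(2000, 2012),
                     rng.normal(0, 0.3) * np.arange(12) + rng.normal(size=12))
                    for _ in range(8)]
        cs = self.cell_series(per_cell)
        ols = cell_slopes(cs, method="ols").set_index("ix")["slope"]
        shrunk = cell_slopes(cs, method="shrunk").set_index("ix")["slope"]
        grand = ols.mean()
        for i in ols.index:
            lo, hi = sorted([ols[i], grand])
            assert lo - 1e-12 <= shrunk[i] <= hi + 1e-12


def exact_two_sided_binomial(k, n):
    """Independent enumeration oracle: doubled smaller tail at p0 = 1/2."""
    from math import comb

    pmf = [comb(n, j) / 2 ** n for j in range(n + 1)]
    lower = sum(pmf[: k + 1])
    upper = sum(pmf[k:])
    return min(1.0, 2 * min(lower, upper))


class TestSignAgreement:
    def test_perfect_agreement_closed_form(self):
        a = slopes_frame([1.0] * 10)
        b = slopes_frame([2.0] * 10)
        res = sign_agreement(a, b)
        assert res.p_value == pytest.approx(2 * 0.5 ** 10)
        assert (res.n_cells, res.k_agree) == (10, 10)

    def test_nine_of_twelve_matches_enumeration(self):
        a = slopes_frame([1.0] * 12)
        b = slopes_frame([1.0] * 9 + [-1.0] * 3)
        res = sign_agreement(a, b)
        assert res.p_value == pytest.approx(exact_two_sided_binomial(9, 12), abs=1e-12)
        assert res.p_value == pytest.approx(0.1460, abs=5e-5)

    def test_small_n_capped_at_one(self):
        a = slopes_frame([1.0, 1.0])
        b = slopes_frame([1.0, -1.0])
        assert sign_agreement(a, b).p_value == 1.0

    def test_symmetry_and_sign_flip_invariance(self, rng):
        sa = slopes_frame(rng.normal(size=15))
        sb = slopes_frame(rng.normal(size=15))
        p1 = sign_agreement(sa, sb).p_value
        p2 = sign_agreement(sb, sa).p_value
        flipped_a = sa.assign(slope=-sa["slope"],
                              sign=sa["sign"].map({"increasing": "decreasing",
                                                   "decreasing": "increasing"}))
        flipped_b = sb.assign(slope=-sb["slope"],
                              sign=sb["sign"].map({"increasing": "decreasing",
                                                   "decreasing": "increasing"}))
        p3 = sign_agreement(flipped_a, flipped_b).p_value
        assert p1 == p2 == p3

    def test_no_matched_cells_rejected(self):
        a = slopes_frame([1.0])
        b = slopes_frame([1.0]).assign(ix=99)
        with pytest.raises(ValidationError, match="zero matched"):
            sign_agreement(a, b)

    @given(n=st.integers(1, 20), frac=st.floats(0, 1))
    @settings(max_examples=40, deadline=None)
    def test_matches_enumeration_for_all_small_n(self, n, frac):
        k = int(round(frac * n))
        assert binomial_sign_p(k, n) == pytest.approx(
            exact_two_sided_binomial(k, n), abs=1e-12)


def make_decomp(years, remainder):
    years = np.asarray(years)
    rem = np.asarray(remainder, dtype=float)
    return Decomposition(years=years, observed=rem, trend=np.zeros_like(rem), remainder=rem)


class TestRemainderCorrelations:
    def test_identical_vectors_give_unit_correlation(self, rng):
        rem = rng.normal(size=8)
        paired = {(100_000, 0, 0): (make_decomp(range(8), rem), make_decomp(range(8), rem))}
        out = remainder_correlations(paired)
        assert out.correlations[0] == pytest.approx(1.0)

    def test_constant_vector_skipped(self, rng):
        paired = {
            (100_000, 0, 0): (make_decomp(range(8), np.zeros(8)),
                              make_decomp(range(8), rng.normal(size=8))),
            (100_000, 1, 0): (make_decomp(range(8), rng.normal(size=8)),
                              make_decomp(range(8), rng.normal(size=8))),
        }
        out = remainder_correlations(paired)
        assert len(out.correlations) == 1

    def test_pearson_matches_bruteforce_formula(self, rng):
        a, b = rng.normal(size=12), rng.normal(size=12)
        paired = {(100_000, 0, 0): (make_decomp(range(12), a), make_decomp(range(12), b))}
        r = remainder_correlations(paired, min_overlap=5).correlations[0]
        brute = (np.mean(a * b) - a.mean() * b.mean()) / (a.std() * b.std())
        assert r == pytest.approx(brute, abs=1e-12)

    def test_ci_ordering(self, rng):
        paired = {
            (100_000, i, 0): (make_decomp(range(10), rng.normal(size=10)),
                              make_decomp(range(10), rng.normal(size=10)))
            for i in range(6)
        }
        out = remainder_correlations(paired)
        assert out.ci_low <= out.mean <= out.ci_high

    def test_no_qualifying_cells_rejected(self):
        paired = {(100_000, 0, 0): (make_decomp(range(3), np.ones(3)),
                                    make_decomp(range(3), np.ones(3)))}
        with pytest.raises(ValidationError, match="no qualifying"):
            remainder_correlations(paired)


def test_bottom_up_remainders_positively_correlated():
    """Strong coupling with low noise must leave a positive remainder signal."""
    cfg = synthgrid.scenario("bottom_up", n_cells_x=4, n_cells_y=4, years=25,
                             beta0=0.8, sigma_xi=0.05, seed=3)
    truth = synthgrid.simulate_latent_dynamics(cfg, synthgrid.simulate_weather(cfg))
    panel = synthgrid.truth_panel(truth)
    decomps = association.decompose_paired_panel(panel, min_run=10, max_zero_frac=1.0)
    out = remainder_correlations(decomps)
    assert out.mean > 0


def test_cross_cell_year_correlation_mode(rng):
    paired = {
        (100_000, i, 0): (make_decomp(range(10), rng.normal(size=10)),
                          make_decomp(range(10), rng.normal(size=10)))
        for i in range(5)
    }
    rs = association.cross_cell_year_correlations(paired)
    assert len(rs) == 10 and np.all(np.abs(rs) <= 1.0)
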