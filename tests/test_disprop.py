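"""The four disproportionality estimators against oracles and invariants."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from _oracles import bcpnn_monte_carlo, ebgm_quadrature
from pvsignals.contingency import ContingencyTable
from pvsignals.disprop import (
    DEFAULT_MGPS_START, MgpsHyperParams, bcpnn_stat, detect_signals,
    ebgm_stat, fit_mgps_prior, flags_from_row, mgps_marginal_loglik,
    needs_correction, prr_stat, ror_stat,
)

cells_strategy = st.tuples(
    st.integers(1, 500), st.integers(1, 5000),
    st.integers(1, 5000), st.integers(1, 100_000),
)


class TestRorPrr:
    def test_symmetric_table_is_null(self):
        t = ContingencyTable(10, 10, 10, 10)
        assert ror_stat(t)[0] == pytest.approx(1.0)
        prr, chi2 = prr_stat(t)
        assert prr == pytest.approx(1.0)
        assert chi2 == pytest.approx(0.0)

    def test_frozen_worked_example(self):
        """ad/(bc) = 11, Wald CI and Pearson χ² from direct arithmetic."""
        t = ContingencyTable(10, 90, 100, 9900)
        ror, lo, hi = ror_stat(t)
        assert ror == pytest.approx(11.0)
        assert lo == pytest.approx(5.5595, abs=1e-3)
        assert hi == pytest.approx(21.7645, abs=1e-3)
        prr, chi2 = prr_stat(t)
        assert prr == pytest.approx(10.0)
        assert chi2 == pytest.approx(74.4472, abs=1e-3)

    def test_zero_cell_gets_continuity_correction(self):
        t = ContingencyTable(0, 100, 50, 9850)
        assert needs_correction(t)
        ror, lo, hi = ror_stat(t)
        assert np.isfinite([ror, lo, hi]).all()
        assert ror < 1

    @given(cells_strategy)
    def test_ror_prr_sign_agreement(self, cells):
        """(ror−1) and (prr−1) share sign: ad>bc ⇔ a/(a+b) > c/(c+d)."""
        t = ContingencyTable(*cells)
        ror, lo, hi = ror_stat(t)
        prr, _ = prr_stat(t)
        assert lo <= ror <= hi
        assert (ror - 1) * (prr - 1) >= 0 or ror == pytest.approx(1.0)


class TestBcpnn:
    def test_independence_limit(self):
        ic, ic025 = bcpnn_stat(ContingencyTable(5000, 5000, 5000, 5000))
        assert abs(ic) < 0.001
        assert ic025 < ic

    def test_matches_monte_carlo(self, rng):
        for cells in [(10, 90, 100, 9900), (25, 300, 120, 50_000), (8, 8, 8, 8)]:
            ic, _ = bcpnn_stat(ContingencyTable(*cells))
            assert ic == pytest.approx(
                bcpnn_monte_carlo(*cells, rng=rng, n_draws=200_000), abs=0.02)

    @given(cells_strategy)
    def test_lower_bound_below_point(self, cells):
        ic, ic025 = bcpnn_stat(ContingencyTable(*cells))
        assert ic025 < ic


class TestEbgm:
    def test_shrinkage_vanishes_for_large_counts(self, start_prior):
        ebgm, ebgm05 = ebgm_stat(50_000, 10_000.0, start_prior)
        assert ebgm == pytest.approx(5.0, rel=1e-3)
        assert ebgm05 < ebgm

    def test_matches_quadrature_oracle(self, start_prior):
        for a, e in [(10, 1.0), (0, 0.1), (3, 10.0)]:
            ebgm, ebgm05 = ebgm_stat(a, e, start_prior)
            og, oq = ebgm_quadrature(a, e, start_prior)
            assert ebgm == pytest.approx(og, rel=1e-6)
            assert ebgm05 == pytest.approx(oq, rel=1e-6)

    def test_monotone_in_observed_count(self, start_prior):
        values = [ebgm_stat(a, 2.0, start_prior)[0] for a in range(0, 40, 3)]
        assert all(x < y for x, y in zip(values, values[1:]))

    def test_lower_bound_below_geometric_mean_sweep(self, rng, start_prior):
        for _ in range(25):
            a = int(rng.integers(0, 60))
            e = float(rng.uniform(0.1, 20))
            ebgm, ebgm05 = ebgm_stat(a, e, start_prior)
            assert ebgm05 < ebgm

    def test_zero_expected_rejected(self, start_prior):
        with pytest.raises(ValueError):
            ebgm_stat(3, 0.0, start_prior)


class TestMgpsFit:
    def _simulate(self, rng, n, params=DEFAULT_MGPS_START):
        a1, b1, a2, b2, p = params
        e = np.exp(rng.uniform(np.log(0.5), np.log(100.0), n))
        comp = rng.random(n) < p
        lam = np.where(comp, rng.gamma(a1, 1 / b1, n), rng.gamma(a2, 1 / b2, n))
        return rng.poisson(lam * e), e

    def test_loglik_improves_over_start(self, rng):
        a, e = self._simulate(rng, 5000)
        fit = fit_mgps_prior(a, e, include_zeros=True)
        assert fit.loglik >= mgps_marginal_loglik(DEFAULT_MGPS_START, a, e)

    def test_recovery_at_moderate_sample(self, rng):
        a, e = self._simulate(rng, 20_000)
        fit = fit_mgps_prior(a, e, include_zeros=True)
        for est, truth in zip(fit.as_tuple(), DEFAULT_MGPS_START):
            assert est == pytest.approx(truth, rel=0.35)

    def test_single_component_data_reaches_likelihood_parity(self, rng):
        """Data from one gamma component: the mixture fit is at least as good
        as the generating single component (identifiability limit)."""
        n = 10_000
        e = np.exp(rng.uniform(np.log(1.0), np.log(50.0), n))
        lam = rng.gamma(2.0, 1 / 4.0, n)
        a = rng.poisson(lam * e)
        fit = fit_mgps_prior(a, e, include_zeros=True)
        ll_true_single = mgps_marginal_loglik((2.0, 4.0, 2.0, 4.0, 0.5), a, e)
        assert fit.loglik >= ll_true_single - 1e-6

    def test_too_few_cells_rejected(self):
        with pytest.raises(ValueError):
            fit_mgps_prior([1] * 50, [1.0] * 50)

    def test_invalid_hyperparams_rejected(self):
        with pytest.raises(ValueError):
            MgpsHyperParams(0.0, 1.0, 1.0, 1.0, 0.5)
        with pytest.raises(ValueError):
            MgpsHyperParams(1.0, 1.0, 1.0, 1.0, 1.5)


class TestDetectSignals:
    def test_flags_and_sorting(self, small_db, start_prior):
        from pvsignals.contingency import count_pairs

        tables = count_pairs(small_db["cohort"], small_db["comparator"])
        df = detect_signals(tables, start_prior)
        assert list(df["a"]) == sorted(df["a"], reverse=True)
        planted = df[df.term == "event_20"].iloc[0]
        assert planted["any_signal"]
        # flags recomputable from the printed row
        flags = flags_from_row(planted)
        for key, val in flags.items():
            assert planted[key] == val

    def test_small_count_blocks_ror_prr_flags(self, start_prior):
        # a=1 below the 3-case minimum: ROR/PRR never flag, however extreme
        t = ContingencyTable(1, 1, 1, 100_000)
        df = detect_signals({"x": t}, start_prior)
        row = df.iloc[0]
        assert row.ror > 100
        assert not row.sig_ror and not row.sig_prr

    def test_statistics_depend_only_on_cells(self, start_prior):
        t = ContingencyTable(12, 34, 56, 7890)
        df1 = detect_signals({"first": t}, start_prior)
        df2 = detect_signals({"renamed": t}, start_prior)
        cols = ["ror", "prr", "chi2", "ic", "ic025", "ebgm", "ebgm05"]
        assert df1[cols].iloc[0].tolist() == df2[cols].iloc[0].tolist()
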