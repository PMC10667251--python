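import numpy as np
import pandas as pd
import pytest

from fluxcohort.network import parse_network_text
from fluxcohort.emu import TracerSpec, decompose_emu
from fluxcohort.fitting import (
    FitError,
    FitMeasurements,
    compare_flux_maps,
    compute_exchange_rates,
    estimate_growth_rate,
    fit_fluxes,
    goodness_of_fit,
    profile_confidence_interval,
)

HEADER = "id\tequation\treversible\tlb\tub\n"


class TestExchangeRates:
    def _frame(self, **kw):
        base = dict(patient="p", clone=1, replicate=1, condition="Ctrl",
                    metabolite="glucose", blank_mM=25.0, sample_mM=24.4,
                    hours=24.0, dna_mg=0.005)
        base.update(kw)
        return pd.DataFrame([base])

    def test_uptake_hand_arithmetic(self):
        out = compute_exchange_rates(self._frame())
        assert out["rate"].iloc[0] == pytest.approx((25 - 24.4) / 24 / 0.005)
        assert out["rate"].iloc[0] == pytest.approx(5.0)

    def test_secretion_is_negative(self):
        out = compute_exchange_rates(
            self._frame(metabolite="lactate", blank_mM=0.0, sample_mM=2.4,
                        dna_mg=0.01)
        )
        assert out["rate"].iloc[0] == pytest.approx(-10.0)

    def test_blank_equal_sample_gives_zero(self):
        out = compute_exchange_rates(self._frame(sample_mM=25.0))
        assert out["rate"].iloc[0] == 0.0

    def test_missing_glutamine_blank_assumes_medium_concentration(self):
        out = compute_exchange_rates(
            self._frame(metabolite="glutamine", blank_mM=np.nan, sample_mM=1.19)
        )
        assert out["blank_assumed"].iloc[0]
        assert out["rate"].iloc[0] == pytest.approx((1.25 - 1.19) / 24 / 0.005)

    def test_missing_blank_without_assumption_errors(self):
        with pytest.raises(FitError, match="blank"):
            compute_exchange_rates(self._frame(blank_mM=np.nan))


class TestGrowthRate:
    def test_constant_dna_gives_zero(self):
        assert estimate_growth_rate([(0, 1), (50, 1), (100, 1)]) == pytest.approx(0.0)

    def test_exact_doubling(self):
        pts = [(0, 1.0), (50, 2 ** 0.5), (100, 2.0)]
        assert estimate_growth_rate(pts) == pytest.approx(np.log(2) / 100)

    def test_nonpositive_dna_rejected(self):
        with pytest.raises(ValueError):
            estimate_growth_rate([(0, 1), (10, 0), (20, 2)])


class TestGoodnessOfFit:
    def test_accept_below_critical(self):
        res = goodness_of_fit(10.0, 10)
        assert res["accept"] and res["upper"] == pytest.approx(18.307, abs=0.01)

    def test_reject_above_critical(self):
        assert not goodness_of_fit(30.0, 10)["accept"]

    def test_zero_ssr_always_accepts(self):
        for dof in (1, 5, 50):
            assert goodness_of_fit(0.0, dof)["accept"]

    def test_overparameterized_model_rejected(self):
        with pytest.raises(ValueError):
            goodness_of_fit(1.0, 0)


class TestCompare:
    def _fit(self, net_fluxes, ci_open=None):
        from fluxcohort.fitting import FluxFitResult
        from fluxcohort.fluxmap import FluxMap

        return FluxFitResult(
            flux_map=FluxMap(net=net_fluxes), ssr=0.0, dof=1, chi2_accept=True,
            chi2_upper=3.84, restart_ssrs=[0.0], converged=True, seed=0,
            params=np.zeros(1), ci_open=ci_open or {},
        )

    def test_simple_fold(self):
        t = compare_flux_maps(self._fit({"r": 2.0}), self._fit({"r": 1.5}))
        assert t.loc["r", "fold"] == pytest.approx(0.75)
        assert not t.loc["r", "sign_inverted"]

    def test_sign_inversion_reported_negative(self):
        t = compare_flux_maps(self._fit({"r": 1.0}), self._fit({"r": -2.22}))
        assert t.loc["r", "fold"] == pytest.approx(-2.22)
        assert t.loc["r", "sign_inverted"]

    def test_identical_fits_give_unit_folds(self):
        t = compare_flux_maps(
            self._fit({"a": 1.0, "b": 2.0}), self._fit({"a": 1.0, "b": 2.0})
        )
        assert (t["fold"] == 1.0).all()

    def test_open_ci_marks_unreliable(self):
        t = compare_flux_maps(
            self._fit({"r": 1.0}, ci_open={"r": True}), self._fit({"r": 1.0})
        )
        assert t.loc["r", "not_reliably_determined"]

    def test_mismatched_networks_rejected(self):
        with pytest.raises(FitError):
            compare_flux_maps(self._fit({"a": 1.0}), self._fit({"b": 1.0}))


class TestProfileCI:
    def test_rate_only_fit_matches_gaussian_closed_form(self):
        """One free flux constrained by one Gaussian rate measurement: the
        profile CI must equal estimate +/- 1.96 SE."""
        text = (
            "#unbalanced\tA.x C.x\n" + HEADER
            + "GLC_up\tA.x (a) -> B (a)\t0\t0\t100\n"
            + "OUT\tB (a) -> C.x (a)\t0\t0\t100\n"
        )
        net = parse_network_text(text)
        system = decompose_emu(net, [("B", (0,))])
        sd = 0.2
        meas = FitMeasurements(
            mids={}, rates={"glucose": (5.0, sd)}, tracers=[TracerSpec("A.x")]
        )
        fit = fit_fluxes(net, meas, biomass={}, restarts=3, seed=0,
                         emu_system=system)
        assert fit.net_flux("GLC_up") == pytest.approx(5.0, abs=1e-6)
        lo, hi, info = profile_confidence_interval(fit, "GLC_up")
        assert lo == pytest.approx(5.0 - 1.959964 * sd, abs=1e-3)
        assert hi == pytest.approx(5.0 + 1.959964 * sd, abs=1e-3)
        assert not info["open_lower"] and not info["open_upper"]

    def test_redundant_parallel_route_has_open_ci(self):
        """Two indistinguishable parallel routes: individual fluxes are
        structurally non-identifiable, only their sum is pinned."""
        text = (
            "#unbalanced\tA.x C.x\n" + HEADER
            + "GLC_up\tA.x (a) -> B (a)\t0\t0\t100\n"
            + "alt\tA.x (a) -> B (a)\t0\t0\t100\n"
            + "OUT\tB (a) -> C.x (a)\t0\t0\t100\n"
        )
        net = parse_network_text(text)
        system = decompose_emu(net, [("B", (0,))])
        meas = FitMeasurements(
            mids={}, rates={"glucose": (5.0, 0.2)}, tracers=[TracerSpec("A.x")]
        )
        fit = fit_fluxes(net, meas, biomass={}, restarts=3, seed=0,
                         emu_system=system)
        lo, hi, info = profile_confidence_interval(fit, "alt")
        assert info["open_upper"] or info["open_lower"]
        assert np.isinf(hi) or np.isinf(lo)


class TestModelAdequacy:
    def test_structurally_wrong_model_rejected_by_chi_square(self, tca_network,
                                                             truth):
        """Data generated with active reductive carboxylation, fitted with a
        model that forbids it (irreversible IDH): chi-square rejects in the
        majority of runs, because the model cannot produce M5 citrate from
        glutamine."""
        from dataclasses import replace as dc_replace

        from fluxcohort.network import AtomTransitionNetwork
        from fluxcohort.emu import decompose_emu, full_fragment_targets
        from fluxcohort.cohort import (
            MEASURED_METABOLITES, FREE_FLUXES, pooled_noisy_measurements,
        )

        reactions = [
            dc_replace(r, reversible=False, lb=0.0) if r.id == "IDH" else r
            for r in tca_network.reactions
        ]
        wrong = AtomTransitionNetwork(
            reactions=reactions,
            metabolite_carbons=dict(tca_network.metabolite_carbons),
            unbalanced=set(tca_network.unbalanced),
            symmetric=set(tca_network.symmetric),
        )
        wrong.validate()
        system_w = decompose_emu(
            wrong, full_fragment_targets(wrong, MEASURED_METABOLITES)
        )
        fm = truth.flux_map(tca_network, "sPD")  # doubled reductive exchange
        rejections = 0
        n_runs = 8
        for s in range(n_runs):
            meas = pooled_noisy_measurements(
                tca_network, fm, truth, np.random.default_rng(40_000 + s),
            )
            fit = fit_fluxes(
                wrong, meas, truth.biomass_fluxes(), restarts=2, seed=s,
                emu_system=system_w, prefer_free=FREE_FLUXES,
                ls_options=dict(xtol=1e-8, ftol=1e-8, gtol=1e-8),
            )
            if not fit.chi2_accept:
                rejections += 1
        assert rejections > n_runs / 2

    def test_ci_width_shrinks_with_noise(self, tca_network, emu_system, truth):
        """The OGDHC profile CI narrows monotonically as MID noise drops."""
        from fluxcohort.cohort import (
            FREE_FLUXES, SyntheticTruth, pooled_noisy_measurements,
        )

        fm = truth.flux_map(tca_network, "Ctrl")
        widths = []
        for sd in (0.02, 0.01, 0.005):
            t = SyntheticTruth(seed=0, mid_noise_sd=sd)
            meas = pooled_noisy_measurements(
                tca_network, fm, t, np.random.default_rng(9), system=emu_system
            )
            fit = fit_fluxes(
                tca_network, meas, truth.biomass_fluxes(), restarts=2, seed=0,
                emu_system=emu_system, prefer_free=FREE_FLUXES,
                ls_options=dict(xtol=1e-8, ftol=1e-8, gtol=1e-8),
            )
            lo, hi, _ = profile_confidence_interval(fit, "OGDHC")
            widths.append(hi - lo)
        assert widths[0] > widths[1] > widths[2]


class TestFitBasics:
    def test_restart_failure_reports_diagnostics(self, tca_network, emu_system,
                                                 truth):
        # a rate keyed to a metabolite with no mapped reaction makes every
        # restart fail; the error carries the per-restart record
        with pytest.raises(FitError, match="no restart converged"):
            fit_fluxes(
                tca_network,
                FitMeasurements(
                    mids={}, rates={"unknown_met": (1.0, 0.1)},
                    tracers=truth.tracers(),
                ),
                biomass={"BM_Pyr": 0.25, "BM_AcCoA": 0.1, "BM_OAA": 0.9,
                         "BM_Glu": 0.1},
                restarts=2, seed=0, emu_system=emu_system,
            )
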