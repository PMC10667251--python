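import numpy as np
import pytest

from fluxcohort.cohort import (
    CohortDesign,
    MEASURED_METABOLITES,
    SyntheticTruth,
    generate_cohort,
    noisy_measurements,
    simulate_clinical_progression,
)
from fluxcohort.emu import simulate_mids_multi
from fluxcohort.io import validate_mid_frame
from fluxcohort.fluxmap import SteadyStateError


class TestTruthFluxMaps:
    def test_condition_maps_satisfy_steady_state(self, tca_network, truth):
        for cond in ("Ctrl", "sPD"):
            truth.flux_map(tca_network, cond).validate(tca_network)

    def test_effect_multipliers_are_exact(self, tca_network, truth,
                                          ctrl_flux, spd_flux):
        assert spd_flux.net["OGDHC"] / ctrl_flux.net["OGDHC"] == pytest.approx(0.64)
        assert spd_flux.net["GLC_up"] / ctrl_flux.net["GLC_up"] == pytest.approx(0.75)

    def test_glutamate_akg_net_flux_inverts(self, ctrl_flux, spd_flux):
        assert ctrl_flux.net["GDH"] > 0 > spd_flux.net["GDH"]

    def test_unit_multipliers_make_conditions_identical(self, tca_network):
        truth = SyntheticTruth(
            ogdhc_multiplier=1.0, glycolysis_multiplier=1.0,
            tca_entry_multiplier=1.0, gaba_shunt_multiplier=1.0,
            reductive_exchange_multiplier=1.0,
        )
        a = truth.flux_map(tca_network, "Ctrl")
        b = truth.flux_map(tca_network, "sPD")
        assert a.net == pytest.approx(b.net)
        assert a.exchange == pytest.approx(b.exchange)

    def test_growth_rate_sets_biomass_scale(self, truth):
        bm = truth.biomass_fluxes()
        assert bm["BM_Pyr"] == pytest.approx(0.001312 * 190.0)


class TestGeneration:
    def test_same_seed_is_bit_identical(self):
        design = CohortDesign(n_ctrl=2, n_spd=3, n_replicates=2)
        a = generate_cohort(design, SyntheticTruth(seed=11))
        b = generate_cohort(design, SyntheticTruth(seed=11))
        assert a.mids.df.equals(b.mids.df)
        assert a.rates.equals(b.rates)
        assert a.traces.equals(b.traces)
        c = generate_cohort(design, SyntheticTruth(seed=12))
        assert not a.mids.df.equals(c.mids.df)

    def test_zero_noise_replicates_equal_exact_simulation(
        self, tca_network, emu_system
    ):
        truth = SyntheticTruth(seed=3, mid_noise_sd=0.0, patient_sd=0.0,
                               conc_noise_sd=0.0, trace_noise_sd=0.0)
        data = generate_cohort(CohortDesign(n_ctrl=2, n_spd=3, n_replicates=2),
                               truth, network=tca_network)
        fm = truth.flux_map(tca_network, "Ctrl")
        sims = simulate_mids_multi(
            emu_system, fm.net_vector(tca_network),
            fm.exchange_vector(tca_network), truth.tracers(),
        )
        exact = {m: mid for (m, _), mid in sims[0].items()}
        sub = data.mids.df.query(
            "condition == 'Ctrl' and tracer == 'U13C-glucose'"
        )
        for (pat, rep, met), g in sub.groupby(["patient", "replicate",
                                               "metabolite"]):
            np.testing.assert_allclose(
                g.sort_values("mass_shift")["fraction"].to_numpy(),
                exact[met], atol=1e-12,
            )

    def test_generated_mids_satisfy_table_invariants(self):
        data = generate_cohort(CohortDesign(n_ctrl=2, n_spd=3, n_replicates=2),
                               SyntheticTruth(seed=5))
        validate_mid_frame(data.mids.df)
        assert set(data.mids.df["metabolite"]) == set(MEASURED_METABOLITES)

    def test_default_design_shape(self):
        data = generate_cohort(CohortDesign(), SyntheticTruth(seed=1))
        assert data.mids.df["patient"].nunique() == 12
        # 12 patients x 3 replicates x 2 tracers x sum(n_carbons+1)
        n_fracs = sum(
            len(g) for _, g in data.mids.df.groupby(
                ["patient", "replicate", "tracer", "metabolite"])
        )
        assert len(data.mids.df) == n_fracs
        assert data.traces.groupby("well")["meas_index"].count().eq(16).all()
        assert len(data.clinical) == 7
        assert sum(not r.followup_available for r in data.clinical) == 1

    def test_non_steady_truth_rejected_before_output(self, tca_network):
        truth = SyntheticTruth(seed=0)
        truth.ctrl_free["OGDHC"] = -2.0  # violates the OGDHC lower bound
        with pytest.raises(SteadyStateError):
            generate_cohort(CohortDesign(n_ctrl=2, n_spd=3), truth,
                            network=tca_network)

    def test_increasing_noise_increases_raw_misfit(self, tca_network,
                                                   emu_system, truth):
        """More measurement noise leaves a larger raw (unweighted) residual
        after fitting; the variance-weighted SSR itself is calibrated to stay
        chi-square distributed at any noise level."""
        from fluxcohort.fitting import fit_fluxes
        from fluxcohort.cohort import FREE_FLUXES
        from fluxcohort.emu import simulate_mids_multi

        fm = truth.flux_map(tca_network, "Ctrl")
        raw = {}
        for sd in (0.005, 0.02):
            t = SyntheticTruth(seed=0, mid_noise_sd=sd)
            totals = []
            for rep in range(3):
                meas = noisy_measurements(
                    tca_network, fm, t, np.random.default_rng(40 + rep),
                    system=emu_system,
                )
                fit = fit_fluxes(
                    tca_network, meas, truth.biomass_fluxes(), restarts=1,
                    seed=rep, emu_system=emu_system, prefer_free=FREE_FLUXES,
                    ls_options=dict(xtol=1e-8, ftol=1e-8, gtol=1e-8),
                )
                best = fit.flux_map
                sims = simulate_mids_multi(
                    emu_system, best.net_vector(tca_network),
                    best.exchange_vector(tca_network), t.tracers(),
                )
                tot = 0.0
                for (tid, met, pos), entry in meas.mids.items():
                    ti = 0 if tid == "U13C-glucose" else 1
                    tot += float(np.sum((sims[ti][(met, pos)] - entry[0]) ** 2))
                totals.append(tot)
            raw[sd] = np.mean(totals)
        assert raw[0.02] > raw[0.005]


class TestClinicalGenerator:
    def test_rho_minus_one_no_noise_is_exactly_linear(self):
        truth = SyntheticTruth()
        truth.clinical_rho = {k: -1.0 for k in truth.clinical_rho}
        flux = {f"P{i}": 1.0 + 0.1 * i for i in range(5)}
        recs = simulate_clinical_progression(
            flux, truth, np.random.default_rng(0), no_followup=frozenset()
        )
        d = np.array([r.d_hy for r in recs])
        f = np.array([flux[r.patient] for r in recs])
        assert np.corrcoef(d, f)[0, 1] == pytest.approx(-1.0)

    def test_zero_rho_uncorrelated_on_average(self):
        truth = SyntheticTruth()
        truth.clinical_rho = {k: 0.0 for k in truth.clinical_rho}
        flux = {f"P{i}": 1.0 + 0.05 * i for i in range(6)}
        rs = []
        rng = np.random.default_rng(1)
        for _ in range(400):
            recs = simulate_clinical_progression(flux, truth, rng,
                                                 no_followup=frozenset())
            d = np.array([r.d_hy for r in recs])
            f = np.array([flux[r.patient] for r in recs])
            rs.append(np.corrcoef(d, f)[0, 1])
        se = np.std(rs) / np.sqrt(len(rs))
        assert abs(np.mean(rs)) < 3 * se + 0.05

    def test_invalid_rho_rejected(self):
        truth = SyntheticTruth()
        truth.clinical_rho["dHY"] = -1.2
        with pytest.raises(ValueError):
            simulate_clinical_progression(
                {"a": 1.0, "b": 2.0, "c": 3.0}, truth,
                np.random.default_rng(0), no_followup=frozenset(),
            )

    def test_too_few_patients_rejected(self):
        truth = SyntheticTruth()
        with pytest.raises(ValueError):
            simulate_clinical_progression(
                {"a": 1.0, "b": 2.0}, truth, np.random.default_rng(0),
                no_followup=frozenset(),
            )
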