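"""Synthetic Ctrl/sPD cohort with known ground truth.

The generator emulates the study design end to end: 5 Ctrl and 7 sPD
patient-derived clones measured in triplicate, labeled in parallel with
U-13C glucose (21.25 mM) and U-13C glutamine (1.25 mM).  Condition-specific
truth flux maps encode the disease effect — glycolysis reduced 0.75-fold,
citrate synthase entry reduced by 19%, the alpha-ketoglutarate dehydrogenase
(OGDHC) step reduced by 36% (0.64-fold) with an upscaled GABA-shunt bypass and
doubled reductive isocitrate-dehydrogenase exchange; the net
glutamate<->alpha-ketoglutarate flux inverts as a consequence.  Patient-level
heterogeneity is lognormal scaling of the free fluxes; measured MIDs are exact
steady-state simulations perturbed by truncated-Gaussian noise and
renormalized; exchange rates derive from noisy medium concentrations;
mitochondrial stress-test traces and clinical progression deltas (correlated
with each patient's true OGDHC flux) complete the dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import AtomTransitionNetwork, parse_network
from .fluxmap import FluxMap, SteadyStateError
from .emu import TracerSpec, decompose_emu, simulate_mids_multi, full_fragment_targets
from .io import MidMeasurementTable, ClinicalRecord, validate_mid_frame, packaged_path
from .bioenergetics import InjectionSchedule, SeahorseTrace
from .fitting import _Parameterization, FitMeasurements

__all__ = [
    "CohortDesign",
    "SyntheticTruth",
    "CohortData",
    "toy_network",
    "generate_cohort",
    "simulate_seahorse_trace",
    "simulate_clinical_progression",
    "noisy_measurements",
    "pooled_noisy_measurements",
]

MEASURED_METABOLITES = ["AKG", "Cit", "Fum", "Gln", "Glu", "Mal", "Pyr", "Suc"]
TRACER_GLC = "U13C-glucose"
TRACER_GLN = "U13C-glutamine"
FREE_FLUXES = ["GLC_up", "PDH", "OGDHC", "GLU_sec", "GAD", "SUC_dil"]

# medium (blank) concentrations, mM; the glutamine blank is emitted as missing
# and downstream processing assumes the 1.25 mM medium concentration
BLANKS = {"glucose": 21.25, "lactate": 0.0, "glutamine": 1.25, "glutamate": 0.0}
BLANK_REPORTED_MISSING = {"glutamine"}


def toy_network() -> AtomTransitionNetwork:
    """The packaged TCA-toy atom-transition network."""
    return parse_network(packaged_path("tca_toy.tsv"))


@dataclass(frozen=True)
class CohortDesign:
    n_ctrl: int = 5
    n_spd: int = 7
    n_replicates: int = 3
    n_clones: int = 1

    def __post_init__(self):
        if self.n_ctrl < 2 or self.n_spd < 2:
            raise ValueError("need at least 2 patients per condition")

    @property
    def ctrl_ids(self) -> list[str]:
        return [f"Ctrl{i+1:02d}" for i in range(self.n_ctrl)]

    @property
    def spd_ids(self) -> list[str]:
        # the seven sPD donors of the clinical table, extended if asked for more
        base = ["J2C", "M89", "C99", "R66", "AY6", "PX7", "88H"]
        if self.n_spd <= len(base):
            return base[: self.n_spd]
        return base + [f"sPD{i+1:02d}" for i in range(self.n_spd - len(base))]


@dataclass
class SyntheticTruth:
    """Ground-truth parameters of the generator; regeneration from
    (seed, parameters) is bit-identical."""

    seed: int = 0
    growth_rate: float = 0.001312  # 1/h, exponential DNA growth
    biomass_coeff: dict = field(
        default_factory=lambda: {
            "BM_Pyr": 190.0, "BM_AcCoA": 76.0, "BM_OAA": 686.0, "BM_Glu": 76.0
        }
    )
    # Ctrl condition: free net fluxes (mM/h/mg DNA) and exchange fluxes;
    # SUC_dil is the unlabeled succinate inflow (pre-existing pools and
    # catabolism outside the model) that dilutes cycle labeling
    ctrl_free: dict = field(
        default_factory=lambda: {
            "GLC_up": 5.0, "PDH": 1.4, "OGDHC": 1.5, "GLU_sec": 0.05,
            "GAD": 0.15, "SUC_dil": 0.2,
        }
    )
    # GDH exchange is fast (transamination effectively equilibrates glutamate
    # with alpha-ketoglutarate, the usual justification for reading glutamate
    # labeling as the AKG proxy)
    ctrl_exchange: dict = field(
        default_factory=lambda: {
            "LDH": 0.5, "IDH": 0.3, "FH": 1.0, "GDH": 5.0, "GLU_sec": 0.05
        }
    )
    # disease effect sizes
    ogdhc_multiplier: float = 0.64
    glycolysis_multiplier: float = 0.75
    tca_entry_multiplier: float = 0.81
    gaba_shunt_multiplier: float = 1.5
    reductive_exchange_multiplier: float = 2.0
    # measurement model
    tracer_purity: float = 0.99
    mid_noise_sd: float = 0.01  # mole fraction, truncated Gaussian
    conc_noise_sd: float = 0.02  # mM on medium concentrations
    hours: float = 24.0
    dna_mg: float = 0.005
    patient_sd: float = 0.05  # lognormal SD of per-patient flux scaling
    # mitochondrial stress test (pmol O2/min resp. mpH/min, per mg DNA)
    trace_noise_sd: float = 3.0
    seahorse_ctrl: dict = field(
        default_factory=lambda: {
            "basal": 90.0, "leak": 30.0, "maximal": 140.0, "nonmito": 10.0,
            "ecar_basal": 50.0, "ecar_max": 80.0, "nonglyc": 5.0,
        }
    )
    respiration_multiplier: float = 0.77  # sPD ATP-linked & maximal scale
    # clinical progression: target Pearson correlation with true OGDHC flux
    clinical_rho: dict = field(
        default_factory=lambda: {
            "dHY": -0.93, "dUPDRS3": -0.89, "dLDopa_mg": -0.80, "dADL": 0.95
        }
    )
    clinical_mean: dict = field(
        default_factory=lambda: {
            "dHY": 2.0, "dUPDRS3": 20.0, "dLDopa_mg": 800.0, "dADL": -0.4
        }
    )
    clinical_sd: dict = field(
        default_factory=lambda: {
            "dHY": 1.0, "dUPDRS3": 20.0, "dLDopa_mg": 600.0, "dADL": 0.2
        }
    )

    # -- derived quantities -------------------------------------------------

    def biomass_fluxes(self) -> dict[str, float]:
        return {k: self.growth_rate * c for k, c in self.biomass_coeff.items()}

    def condition_free(self, condition: str) -> dict[str, float]:
        f = dict(self.ctrl_free)
        if condition == "sPD":
            bm_accoa = self.biomass_fluxes()["BM_AcCoA"]
            cs_ctrl = f["PDH"] - bm_accoa
            f["GLC_up"] *= self.glycolysis_multiplier
            f["PDH"] = cs_ctrl * self.tca_entry_multiplier + bm_accoa
            f["OGDHC"] *= self.ogdhc_multiplier
            f["GAD"] *= self.gaba_shunt_multiplier
        elif condition != "Ctrl":
            raise ValueError(f"unknown condition {condition!r}")
        return f

    def condition_exchange(self, condition: str) -> dict[str, float]:
        e = dict(self.ctrl_exchange)
        if condition == "sPD":
            e["IDH"] *= self.reductive_exchange_multiplier
        return e

    def flux_map(
        self,
        network: AtomTransitionNetwork,
        condition: str,
        free: dict | None = None,
        exchange: dict | None = None,
    ) -> FluxMap:
        free = free if free is not None else self.condition_free(condition)
        exchange = exchange if exchange is not None else self.condition_exchange(condition)
        param = _Parameterization(
            network, self.biomass_fluxes(), prefer_free=FREE_FLUXES
        )
        v_free = np.array([free[r] for r in param.free])
        net = param.net_vector(v_free)
        fm = FluxMap(
            net={r: float(net[j]) for j, r in enumerate(network.reaction_ids)},
            exchange=dict(exchange),
        )
        fm.validate(network)
        return fm

    def tracers(self) -> list[TracerSpec]:
        return [
            TracerSpec("Glc.x", purity=self.tracer_purity, id=TRACER_GLC),
            TracerSpec("Gln.x", purity=self.tracer_purity, id=TRACER_GLN),
        ]

    def true_rates(self, flux_map: FluxMap) -> dict[str, float]:
        return {
            "glucose": flux_map.net["GLC_up"],
            "lactate": -flux_map.net["LDH"],
            "glutamine": flux_map.net["GLN_up"],
            "glutamate": -flux_map.net["GLU_sec"],
        }

    @property
    def rate_sd(self) -> float:
        return self.conc_noise_sd / (self.hours * self.dna_mg)

    def seahorse_params(self, condition: str) -> dict[str, float]:
        p = dict(self.seahorse_ctrl)
        if condition == "sPD":
            atp_linked = (p["basal"] - p["leak"]) * self.respiration_multiplier
            p["basal"] = p["leak"] + atp_linked
            p["maximal"] *= self.respiration_multiplier
            p["ecar_basal"] *= self.glycolysis_multiplier
            p["ecar_max"] *= self.glycolysis_multiplier
        return p


@dataclass
class CohortData:
    mids: MidMeasurementTable
    rates: pd.DataFrame
    traces: pd.DataFrame
    schedule: InjectionSchedule
    clinical: list[ClinicalRecord]
    truth: SyntheticTruth
    design: CohortDesign
    patient_flux_maps: dict[str, FluxMap]
    patient_condition: dict[str, str]

    @property
    def true_ogdhc(self) -> dict[str, float]:
        return {p: fm.net["OGDHC"] for p, fm in self.patient_flux_maps.items()}


def _truncated_renormalized(mid: np.ndarray, sd: float, rng) -> np.ndarray:
    """Truncated-Gaussian measurement noise, then closure to sum 1.

    Each fraction receives Gaussian noise truncated below so the reported
    value stays nonnegative (inverse-CDF sampling of the truncated normal);
    the vector is then renormalized.
    """
    if sd <= 0:
        return mid.copy()
    from scipy.special import ndtr, ndtri

    z = mid / sd
    lo = ndtr(-z)  # CDF mass below the truncation point
    u = rng.uniform(0.0, 1.0, size=len(mid))
    noisy = mid + sd * ndtri(lo + u * (1.0 - lo))
    s = noisy.sum()
    return noisy / s


def simulate_seahorse_trace(
    params: dict[str, float],
    schedule: InjectionSchedule,
    noise_sd: float,
    rng=None,
    dna_mg: float = 1.0,
    celltype: str = "hNPC",
) -> SeahorseTrace:
    """Piecewise-constant stress-test trace plus Gaussian measurement noise.

    ``params`` are corrected segment values (basal, leak, maximal, nonmito,
    ecar_basal, ecar_max, nonglyc); the emitted raw OCR segments are
    basal+nonmito, leak+nonmito, maximal+nonmito, nonmito, nonmito.
    """
    if any(v < 0 for v in params.values()):
        raise ValueError("bioenergetic parameters must be nonnegative")
    rng = np.random.default_rng(0) if rng is None else rng
    s = schedule
    nm, ng = params["nonmito"], params["nonglyc"]
    ocr = np.concatenate(
        [
            np.full(s.n_basal, params["basal"] + nm),
            np.full(s.n_post_a, params["leak"] + nm),
            np.full(s.n_post_b, params["maximal"] + nm),
            np.full(s.n_post_c, nm),
            np.full(s.n_post_d, nm),
        ]
    )
    ecar = np.concatenate(
        [
            np.full(s.n_basal, params["ecar_basal"] + ng),
            np.full(s.n_post_a, params["ecar_max"] + ng),
            np.full(s.n_post_b, params["ecar_max"] + ng),
            np.full(s.n_post_c, params["ecar_max"] + ng),
            np.full(s.n_post_d, ng),
        ]
    )
    if noise_sd > 0:
        ocr = ocr + rng.normal(0.0, noise_sd, size=len(ocr))
        ecar = ecar + rng.normal(0.0, noise_sd, size=len(ecar))
    return SeahorseTrace(ocr=ocr, ecar=ecar, schedule=s, dna_mg=dna_mg,
                         celltype=celltype)


def simulate_clinical_progression(
    ogdhc_flux: dict[str, float],
    truth: SyntheticTruth,
    rng=None,
    no_followup: set[str] = frozenset({"R66"}),
) -> list[ClinicalRecord]:
    """Progression deltas as linear transforms of the true OGDHC flux.

    For target correlation rho, delta = mu + sd*(rho*z + sqrt(1-rho^2)*eps)
    with z the standardized flux and eps standard normal, so the expected
    Pearson correlation with the flux equals rho and rho = +/-1 with zero
    noise gives a sample correlation of exactly +/-1.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    for r in truth.clinical_rho.values():
        if abs(r) > 1:
            raise ValueError("|rho| must be <= 1")
    patients = sorted(ogdhc_flux)
    with_fu = [p for p in patients if p not in no_followup]
    if len(with_fu) < 3:
        raise ValueError("need at least 3 sPD patients with follow-up")
    flux = np.array([ogdhc_flux[p] for p in patients])
    z = (flux - flux.mean()) / (flux.std(ddof=0) or 1.0)
    deltas = {}
    for name, rho in truth.clinical_rho.items():
        eps = rng.normal(size=len(patients))
        deltas[name] = (
            truth.clinical_mean[name]
            + truth.clinical_sd[name] * (rho * z + np.sqrt(1 - rho**2) * eps)
        )
    records = []
    for i, p in enumerate(patients):
        if p in no_followup:
            records.append(
                ClinicalRecord(p, None, None, None, None, followup_available=False)
            )
        else:
            records.append(
                ClinicalRecord(
                    p,
                    d_hy=float(deltas["dHY"][i]),
                    d_updrs3=float(deltas["dUPDRS3"][i]),
                    d_ldopa_mg=float(deltas["dLDopa_mg"][i]),
                    d_adl=float(deltas["dADL"][i]),
                )
            )
    return records


def _patient_flux_map(
    network: AtomTransitionNetwork, truth: SyntheticTruth, condition: str, rng
) -> FluxMap:
    free = truth.condition_free(condition)
    exch = truth.condition_exchange(condition)
    if truth.patient_sd > 0:
        free = {k: v * rng.lognormal(0.0, truth.patient_sd) for k, v in free.items()}
        exch = {k: v * rng.lognormal(0.0, truth.patient_sd) for k, v in exch.items()}
    return truth.flux_map(network, condition, free=free, exchange=exch)


def generate_cohort(
    design: CohortDesign | None = None,
    truth: SyntheticTruth | None = None,
    network: AtomTransitionNetwork | None = None,
) -> CohortData:
    """Generate the full in-silico cohort; deterministic in ``truth.seed``."""
    design = design or CohortDesign()
    truth = truth or SyntheticTruth()
    network = network or toy_network()
    for cond in ("Ctrl", "sPD"):
        truth.flux_map(network, cond)  # raises before any output on bad truth
    ss = np.random.SeedSequence(truth.seed)
    rng_pat, rng_mid, rng_rate, rng_trace, rng_clin = (
        np.random.default_rng(c) for c in ss.spawn(5)
    )
    tracers = truth.tracers()
    targets = full_fragment_targets(network, MEASURED_METABOLITES)
    system = decompose_emu(network, targets)
    schedule = InjectionSchedule()

    patients = [(p, "Ctrl") for p in design.ctrl_ids] + [
        (p, "sPD") for p in design.spd_ids
    ]
    flux_maps: dict[str, FluxMap] = {}
    patient_condition: dict[str, str] = {}
    mid_rows, rate_rows, trace_rows = [], [], []
    well = 0
    for patient, cond in patients:
        fm = _patient_flux_map(network, truth, cond, rng_pat)
        flux_maps[patient] = fm
        patient_condition[patient] = cond
        nv, ev = fm.net_vector(network), fm.exchange_vector(network)
        sims = [
            {m: mid for (m, _), mid in s.items()}
            for s in simulate_mids_multi(system, nv, ev, tracers)
        ]
        true_rates = truth.true_rates(fm)
        sh_params = truth.seahorse_params(cond)
        if truth.patient_sd > 0:
            sh_params = {
                k: v * rng_pat.lognormal(0.0, truth.patient_sd)
                for k, v in sh_params.items()
            }
        for clone in range(1, design.n_clones + 1):
            for rep in range(1, design.n_replicates + 1):
                for tracer, sim in zip(tracers, sims):
                    for met in MEASURED_METABOLITES:
                        noisy = _truncated_renormalized(
                            sim[met], truth.mid_noise_sd, rng_mid
                        )
                        sd_col = max(truth.mid_noise_sd, 1e-9)  # table wants sd > 0
                        for i, frac in enumerate(noisy):
                            mid_rows.append(
                                (patient, clone, rep, cond, tracer.id, met,
                                 "full", i, frac, sd_col)
                            )
                for met, rate in true_rates.items():
                    blank = BLANKS[met]
                    sample = (
                        blank
                        - rate * truth.hours * truth.dna_mg
                        + rng_rate.normal(0.0, truth.conc_noise_sd)
                    )
                    rate_rows.append(
                        (patient, clone, rep, cond, met,
                         np.nan if met in BLANK_REPORTED_MISSING else blank,
                         sample, truth.hours, truth.dna_mg)
                    )
                trace = simulate_seahorse_trace(
                    sh_params, schedule, truth.trace_noise_sd, rng_trace
                )
                well += 1
                for i, (o, e) in enumerate(zip(trace.ocr, trace.ecar)):
                    trace_rows.append(
                        (f"W{well:03d}", patient, clone, rep, cond, "hNPC",
                         i, o, e)
                    )

    mids = pd.DataFrame(
        mid_rows,
        columns=["patient", "clone", "replicate", "condition", "tracer",
                 "metabolite", "fragment", "mass_shift", "fraction", "sd"],
    )
    validate_mid_frame(mids)
    rates = pd.DataFrame(
        rate_rows,
        columns=["patient", "clone", "replicate", "condition", "metabolite",
                 "blank_mM", "sample_mM", "hours", "dna_mg"],
    )
    traces = pd.DataFrame(
        trace_rows,
        columns=["well", "patient", "clone", "replicate", "condition",
                 "celltype", "meas_index", "ocr", "ecar"],
    )
    spd_ogdhc = {
        p: flux_maps[p].net["OGDHC"] for p, c in patients if c == "sPD"
    }
    clinical = simulate_clinical_progression(spd_ogdhc, truth, rng_clin)
    return CohortData(
        mids=MidMeasurementTable(mids),
        rates=rates,
        traces=traces,
        schedule=schedule,
        clinical=clinical,
        truth=truth,
        design=design,
        patient_flux_maps=flux_maps,
        patient_condition=patient_condition,
    )


def pooled_noisy_measurements(
    network: AtomTransitionNetwork,
    flux_map: FluxMap,
    truth: SyntheticTruth,
    rng,
    n_samples: int = 15,
    system=None,
) -> FitMeasurements:
    """Replicate-pooled measurements, the form the per-condition fit consumes.

    ``n_samples`` independent noisy samples (the default mirrors 5 clones x 3
    replicates) are averaged per MID vector and per rate; the weighting SD is
    the known measurement SD over sqrt(n), while the per-measurement noise
    scale is kept for the truncation-bias model.
    """
    tracers = truth.tracers()
    if system is None:
        targets = full_fragment_targets(network, MEASURED_METABOLITES)
        system = decompose_emu(network, targets)
    nv, ev = flux_map.net_vector(network), flux_map.exchange_vector(network)
    sims = simulate_mids_multi(system, nv, ev, tracers)
    mids = {}
    for tracer, sim in zip(tracers, sims):
        for (met, pos), mid in sim.items():
            draws = [
                _truncated_renormalized(mid, truth.mid_noise_sd, rng)
                for _ in range(n_samples)
            ]
            mids[(tracer.id, met, pos)] = (
                np.mean(draws, axis=0),
                np.full(len(mid), truth.mid_noise_sd / np.sqrt(n_samples)),
                np.full(len(mid), truth.mid_noise_sd),
            )
    rates = {}
    for met, rate in truth.true_rates(flux_map).items():
        vals = rate + rng.normal(0.0, truth.rate_sd, size=n_samples)
        rates[met] = (float(vals.mean()), truth.rate_sd / np.sqrt(n_samples))
    return FitMeasurements(mids=mids, rates=rates, tracers=tracers)


def noisy_measurements(
    network: AtomTransitionNetwork,
    flux_map: FluxMap,
    truth: SyntheticTruth,
    rng,
    system=None,
) -> FitMeasurements:
    """One biological sample's worth of noisy MIDs + rates, ready to fit.

    The reported SDs are the true generating SDs, so the fit's SSR is
    calibrated against chi-square under repeated sampling.
    """
    tracers = truth.tracers()
    if system is None:
        targets = full_fragment_targets(network, MEASURED_METABOLITES)
        system = decompose_emu(network, targets)
    nv, ev = flux_map.net_vector(network), flux_map.exchange_vector(network)
    sims = simulate_mids_multi(system, nv, ev, tracers)
    mids = {}
    for tracer, sim in zip(tracers, sims):
        for (met, pos), mid in sim.items():
            noisy = _truncated_renormalized(mid, truth.mid_noise_sd, rng)
            mids[(tracer.id, met, pos)] = (
                noisy, np.full(len(mid), truth.mid_noise_sd)
            )
    rates = {}
    for met, rate in truth.true_rates(flux_map).items():
        rates[met] = (rate + rng.normal(0.0, truth.rate_sd), truth.rate_sd)
    return FitMeasurements(mids=mids, rates=rates, tracers=tracers)
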