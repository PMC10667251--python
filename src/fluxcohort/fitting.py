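"""Flux estimation by variance-weighted least squares over the EMU model.

Measured MIDs (both tracers jointly) and extracellular exchange rates enter a
weighted residual vector; free parameters are a spanning set of net fluxes
(steady state is enforced exactly through the parameterization: the remaining
net fluxes are affine functions of the free ones) plus log10-transformed
exchange fluxes for reversible reactions.  Bound-constrained nonlinear least
squares is run from several seeded random feasible starts; goodness of fit is
judged by a one-sided upper-tail chi-square test on the SSR, and per-flux 95%
confidence intervals are traced by parameter continuation (profiling the SSR
while re-optimizing all other parameters).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .network import AtomTransitionNetwork
from .fluxmap import FluxMap
from .emu import (
    EmuSystem,
    TracerSpec,
    decompose_emu,
    simulate_mids_multi,
    simulate_targets_flat,
    target_locator,
)

__all__ = [
    "FitError",
    "FluxFitResult",
    "FitMeasurements",
    "compute_exchange_rates",
    "estimate_growth_rate",
    "fit_fluxes",
    "goodness_of_fit",
    "profile_confidence_interval",
    "compare_flux_maps",
    "RATE_REACTIONS",
]

MID_SD_FLOOR = 0.003  # mole-fraction floor preventing single-point dominance
LOG_EXCHANGE_BOUNDS = (-4.0, 4.0)  # exchange fluxes optimized as log10 on 1e-4..1e4
ASSUMED_BLANKS = {"glutamine": 1.25}  # mM; medium value assumed when blank is missing

# measured exchange metabolite -> (reaction id, sign); sign +1 when the
# reaction's forward direction is an uptake, -1 when it is a secretion
RATE_REACTIONS = {
    "glucose": ("GLC_up", 1),
    "lactate": ("LDH", -1),
    "glutamine": ("GLN_up", 1),
    "glutamate": ("GLU_sec", -1),
}


class FitError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# measurement model: nonnegative fractions closed to sum 1
#
# A measured fraction is the true fraction plus Gaussian noise truncated below
# so the reported value stays nonnegative, and the vector is renormalized to
# sum 1.  The fit therefore compares the data to the *expected measurement* of
# a simulated MID and whitens residuals with the matching truncation-closure
# covariance, keeping the SSR calibrated against chi-square.


def _truncated_moments(mu: np.ndarray, sd) -> tuple[np.ndarray, np.ndarray]:
    """Mean and variance of N(mu, sd^2) truncated below at 0, element-wise."""
    from scipy.special import ndtr

    mu = np.asarray(mu, dtype=float)
    sd = np.broadcast_to(np.asarray(sd, dtype=float), mu.shape)
    mean = mu.copy()
    var = np.zeros_like(mu)
    pos = sd > 0
    if pos.any():
        z = mu[pos] / sd[pos]
        phi = np.exp(-0.5 * z * z) / np.sqrt(2.0 * np.pi)
        Phi = np.maximum(ndtr(z), 1e-300)
        lam = phi / Phi  # inverse Mills ratio at the truncation point
        mean[pos] = mu[pos] + sd[pos] * lam
        var[pos] = sd[pos] ** 2 * (1.0 - z * lam - lam**2)
    return mean, var


def expected_measured_mid(sim: np.ndarray, censor_sd) -> np.ndarray:
    """Expected reported MID for a simulated true MID under the truncation +
    renormalization measurement model (identity when censor_sd is 0)."""
    mean, _ = _truncated_moments(sim, censor_sd)
    return mean / mean.sum()


def _debias_observed_mid(obs: np.ndarray, censor_sd) -> np.ndarray:
    """Plug-in true fractions by inverting the truncated-mean map.

    A raw observed fraction is upward-biased near zero (a truncated draw
    exceeds its untruncated mean); Newton steps use the identity
    d E[measured]/d mu = Var/sd^2, and the estimate is clipped at 0.
    """
    csd = np.broadcast_to(np.asarray(censor_sd, dtype=float), obs.shape)
    mu_hat = obs.copy()
    for _ in range(6):
        mean_c, var_c = _truncated_moments(mu_hat, csd)
        step = np.where(
            csd > 0, (mean_c - obs) * csd**2 / np.maximum(var_c, 1e-300), 0.0
        )
        mu_hat = np.maximum(mu_hat - step, 0.0)
    return mu_hat


_WHITENER_MC_DRAWS = 4000
_WHITENER_MC_SEED = 202411  # fixed internal stream; not data- or fit-dependent


def _mid_measurement_model(
    obs: np.ndarray, sd: np.ndarray, censor_sd, mu_hat: np.ndarray | None = None,
    floor: float = MID_SD_FLOOR,
) -> tuple[np.ndarray, np.ndarray]:
    """Whitening rows L and residual mean-correction delta for one MID vector.

    The covariance and residual mean of the truncation + closure measurement
    model are estimated by Monte Carlo at the de-biased plug-in fractions
    (truncation makes the noise non-Gaussian enough near zero that a delta
    method misstates the covariance).  The closure leaves m-1 informative
    directions; the null direction is dropped.  ``delta`` is the second-order
    difference between the Monte-Carlo measurement mean and the analytic
    first-order mean used on the model side of the residual.

    ``mu_hat`` overrides the plug-in true fractions (used when reweighting at
    the model prediction, which decouples the weights from the realized noise).
    """
    from scipy.special import ndtr, ndtri

    m = len(obs)
    csd = np.broadcast_to(np.asarray(censor_sd, dtype=float), obs.shape)
    sd = np.broadcast_to(np.asarray(sd, dtype=float), obs.shape)
    if not (csd > 1e-8).any():
        # exact measurements: diagonal floor variance under the closure
        A = np.eye(m) - np.outer(obs, np.ones(m))
        W = A @ np.diag(np.maximum(sd, floor) ** 2) @ A.T
        lam, U = np.linalg.eigh(W)
        keep = np.argsort(lam)[1:]
        return (U[:, keep] / np.sqrt(lam[keep])).T, np.zeros(m)

    if mu_hat is None:
        mu_hat = _debias_observed_mid(obs, csd)
    rng = np.random.default_rng(_WHITENER_MC_SEED)
    z = np.where(csd > 0, mu_hat / np.where(csd > 0, csd, 1.0), np.inf)
    lo = ndtr(-z)
    u = rng.uniform(0.0, 1.0, size=(_WHITENER_MC_DRAWS, m))
    draws = mu_hat + csd * ndtri(lo + u * (1.0 - lo))
    draws /= draws.sum(axis=1, keepdims=True)
    C_mc = np.cov(draws.T)
    mc_mean = draws.mean(axis=0)
    delta = mc_mean - expected_measured_mid(mu_hat, csd)
    # rescale to the reported (possibly pooled-SE) weighting SDs, keeping the
    # Monte-Carlo correlation structure and truncation deflation
    mc_sd = np.sqrt(np.maximum(np.diag(C_mc), 1e-300))
    # the floor applies per measurement; the ratio sd/censor_sd carries the
    # 1/sqrt(n) shrinkage when the observation is a pooled replicate mean
    pooling = sd / np.maximum(csd, 1e-300)
    scale = np.maximum(mc_sd, floor) * pooling
    R = C_mc / np.outer(mc_sd, mc_sd)
    W = R * np.outer(scale, scale)
    lam, U = np.linalg.eigh(W)
    keep = np.argsort(lam)[1:]
    lam_keep = np.maximum(lam[keep], 1e-12 * lam.max())
    return (U[:, keep] / np.sqrt(lam_keep)).T, delta


# ---------------------------------------------------------------------------
# exchange rates & growth


def compute_exchange_rates(
    df: pd.DataFrame, assumed_blanks: dict[str, float] | None = None
) -> pd.DataFrame:
    """Uptake/secretion rates from blank vs sample concentrations.

    rate = (blank - sample) / hours / dna_mg, in mM/h/mg DNA; positive is
    uptake, negative secretion.  A missing blank is only tolerated for
    metabolites listed in ``assumed_blanks`` (by default glutamine at 1.25 mM,
    the medium concentration).
    """
    if assumed_blanks is None:
        assumed_blanks = dict(ASSUMED_BLANKS)
    out = df.copy()
    blanks = out["blank_mM"].to_numpy(dtype=float).copy()
    assumed = np.zeros(len(out), dtype=bool)
    for i, (b, met) in enumerate(zip(blanks, out["metabolite"])):
        if np.isnan(b):
            if met in assumed_blanks:
                blanks[i] = assumed_blanks[met]
                assumed[i] = True
            else:
                raise FitError(
                    f"row {out.index[i]}: missing blank for {met!r} and no "
                    "assumed blank concentration configured"
                )
    out["blank_assumed"] = assumed
    out["rate"] = (blanks - out["sample_mM"]) / out["hours"] / out["dna_mg"]
    return out


def estimate_growth_rate(timecourse) -> float:
    """Exponential growth rate (1/h) from a (hours, dna_mg) timecourse."""
    arr = np.asarray(timecourse, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 3:
        raise ValueError("need at least 3 (hours, dna) points")
    hours, dna = arr[:, 0], arr[:, 1]
    if (dna <= 0).any():
        raise ValueError("DNA amounts must be positive")
    slope, _ = np.polyfit(hours, np.log(dna), 1)
    return float(slope)


# ---------------------------------------------------------------------------
# measurements container


@dataclass
class FitMeasurements:
    """Pooled measurements entering one flux fit.

    ``mids``: {(tracer id, metabolite, carbon tuple): (mid, sd) or
    (mid, sd, censor_sd)} — ``sd`` is the weighting SD of the tabulated value
    (an SE when replicates were pooled), ``censor_sd`` the per-measurement
    noise scale governing the censoring-at-zero bias of small fractions
    (defaults to ``sd``).  ``rates``: {metabolite: (rate, sd)}, uptake
    positive.
    """

    mids: dict[tuple[str, str, tuple[int, ...]], tuple]
    rates: dict[str, tuple[float, float]]
    tracers: list[TracerSpec]

    def n_independent(self) -> int:
        # one degree of freedom per MID vector is absorbed by the sum-to-one
        # closure of mass-isotopomer fractions
        n = sum(len(entry[0]) - 1 for entry in self.mids.values())
        return n + len(self.rates)


def pool_condition_measurements(
    mid_table,
    rates: pd.DataFrame,
    condition: str,
    tracers: list[TracerSpec],
    sd_floor: float = MID_SD_FLOOR,
) -> FitMeasurements:
    """Average replicate MIDs and rates within a condition (mean with SE)."""
    df = mid_table.df
    df = df[df["condition"] == condition]
    mids = {}
    for (tracer, met, frag), g in df.groupby(["tracer", "metabolite", "fragment"]):
        piv = g.pivot_table(
            index=["patient", "clone", "replicate"],
            columns="mass_shift",
            values="fraction",
        )
        mean = piv.mean(axis=0).to_numpy()
        se = piv.std(axis=0, ddof=1).to_numpy() / np.sqrt(len(piv))
        # per-measurement noise scale (drives the truncation bias model);
        # the pooled mean keeps the single-measurement bias
        censor = g.groupby("mass_shift")["sd"].mean().sort_index().to_numpy()
        frag_pos = tuple(int(x) for x in frag.split(":")[1].split(",")) if ":" in frag \
            else tuple(range(len(mean) - 1))
        mids[(tracer, met, frag_pos)] = (mean, np.maximum(se, sd_floor), censor)
    r = rates[rates["condition"] == condition]
    rate_map = {}
    for met, g in r.groupby("metabolite"):
        vals = g["rate"].to_numpy()
        rate_map[met] = (float(vals.mean()), float(vals.std(ddof=1) / np.sqrt(len(vals))))
    return FitMeasurements(mids=mids, rates=rate_map, tracers=tracers)


# ---------------------------------------------------------------------------
# steady-state parameterization


class _Parameterization:
    """Affine representation of steady-state net fluxes.

    Net fluxes of reactions in ``fixed`` are pinned; a spanning subset of the
    remaining reactions (preferring ``prefer_free``) acts as free coordinates,
    and the dependent reactions follow affinely so that S v = 0 exactly.
    """

    def __init__(
        self,
        network: AtomTransitionNetwork,
        fixed: dict[str, float],
        prefer_free: list[str] | None = None,
    ):
        self.network = network
        self.fixed = dict(fixed)
        S, _ = network.stoichiometric_matrix()
        rids = network.reaction_ids
        self.rids = rids
        free_candidates = [r for r in rids if r not in fixed]
        prefer_free = prefer_free or []
        # pivot order: try to pivot (make dependent) the non-preferred first
        order = sorted(
            free_candidates,
            key=lambda r: (r in prefer_free, free_candidates.index(r)),
        )
        idx = {r: j for j, r in enumerate(rids)}
        A = S[:, [idx[r] for r in order]]
        # greedy left-to-right pivot selection via QR rank updates
        pivots: list[int] = []
        rank = 0
        for j in range(A.shape[1]):
            cols = pivots + [j]
            if np.linalg.matrix_rank(A[:, cols]) > rank:
                pivots.append(j)
                rank += 1
            if rank == np.linalg.matrix_rank(A):
                pass
        self.dependent = [order[j] for j in pivots]
        self.free = [r for r in order if r not in self.dependent]
        # v_dep = -Ad^{-1} (Af v_free + Ax v_fixed)
        Ad = S[:, [idx[r] for r in self.dependent]]
        Af = S[:, [idx[r] for r in self.free]]
        Ax = S[:, [idx[r] for r in fixed]]
        vx = np.array([fixed[r] for r in fixed])
        AdInv = np.linalg.pinv(Ad)
        self._M = -AdInv @ Af
        self._c = -AdInv @ (Ax @ vx)
        resid = np.linalg.norm(Ad @ (self._M @ np.zeros(len(self.free)) + self._c)
                               + Ax @ vx)
        if resid > 1e-8:
            raise FitError(
                "fixed fluxes are inconsistent with steady state "
                f"(residual {resid:.2e}); check biomass effluxes"
            )
        self._idx = idx

    def net_vector(self, v_free: np.ndarray) -> np.ndarray:
        v = np.zeros(len(self.rids))
        for r, val in self.fixed.items():
            v[self._idx[r]] = val
        for r, val in zip(self.free, v_free):
            v[self._idx[r]] = val
        v_dep = self._M @ v_free + self._c
        for r, val in zip(self.dependent, v_dep):
            v[self._idx[r]] = val
        return v

    def free_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lb = np.array([self.network.reaction(r).lb for r in self.free])
        ub = np.array([self.network.reaction(r).ub for r in self.free])
        return lb, ub


# ---------------------------------------------------------------------------
# the fit problem


class _FitProblem:
    def __init__(
        self,
        network: AtomTransitionNetwork,
        emu_system: EmuSystem,
        measurements: FitMeasurements,
        biomass: dict[str, float],
        rate_reactions: dict[str, tuple[str, int]] | None = None,
        prefer_free: list[str] | None = None,
        bound_penalty: float = 1e3,
    ):
        self.network = network
        self.system = emu_system
        self.meas = measurements
        self.rate_reactions = rate_reactions or RATE_REACTIONS
        self.param = _Parameterization(network, biomass, prefer_free)
        self.rev_ids = [r.id for r in network.reactions if r.reversible]
        self.rev_idx = [network.reaction_ids.index(r) for r in self.rev_ids]
        self.n_free = len(self.param.free)
        self.n_exch = len(self.rev_ids)
        self.bound_penalty = bound_penalty
        self.tracers = measurements.tracers
        tracer_ids = [t.id or t.labeled_met for t in self.tracers]
        self._tracer_pos = {tid: i for i, tid in enumerate(tracer_ids)}
        # per-vector whitening against the truncation+closure measurement
        # covariance; measured fractions sum to 1 exactly, so each vector
        # carries m-1 independent residuals
        self._mid_keys = sorted(self.meas.mids)
        self._mid_obs = []
        self._mid_sd = []
        self._mid_L = []
        self._mid_censor = []
        self._mid_delta = []
        for key in self._mid_keys:
            entry = self.meas.mids[key]
            mid, sd = entry[0], entry[1]
            censor = entry[2] if len(entry) > 2 else sd
            obs = np.asarray(mid, dtype=float)
            L, delta = _mid_measurement_model(obs, np.asarray(sd), censor)
            self._mid_obs.append(obs)
            self._mid_sd.append(np.asarray(sd, dtype=float))
            self._mid_censor.append(
                np.broadcast_to(np.asarray(censor, dtype=float), obs.shape).copy()
            )
            self._mid_L.append(L)
            self._mid_delta.append(delta)
        # flat layout for one-shot evaluation of the measurement transform
        self._mid_offsets = np.cumsum([0] + [len(o) for o in self._mid_obs])
        self._censor_flat = (
            np.concatenate(self._mid_censor) if self._mid_censor else np.empty(0)
        )
        self._refresh_flat()
        locator = target_locator(emu_system)
        self._sim_order = [
            (self._tracer_pos[tid], *locator[(met, pos)])
            for tid, met, pos in self._mid_keys
        ]
        self._rate_keys = sorted(self.meas.rates)
        # dependent-reaction bound rows for the soft feasibility penalty
        dep = self.param.dependent
        self._dep_lb = np.array([network.reaction(r).lb for r in dep])
        self._dep_ub = np.array([network.reaction(r).ub for r in dep])
        self._dep_idx = [network.reaction_ids.index(r) for r in dep]

    def _refresh_flat(self):
        """(Re)build the flattened whitener after (re)weighting."""
        from scipy.linalg import block_diag

        if self._mid_obs:
            self._obs_flat = np.concatenate(self._mid_obs)
            self._delta_flat = np.concatenate(self._mid_delta)
            self._L_block = block_diag(*self._mid_L)
        else:
            self._obs_flat = np.empty(0)
            self._delta_flat = np.empty(0)
            self._L_block = np.empty((0, 0))

    # -- parameter vector: [free nets, log10 exchange fluxes]

    def bounds(self):
        lb_f, ub_f = self.param.free_bounds()
        lb = np.concatenate([lb_f, np.full(self.n_exch, LOG_EXCHANGE_BOUNDS[0])])
        ub = np.concatenate([ub_f, np.full(self.n_exch, LOG_EXCHANGE_BOUNDS[1])])
        return lb, ub

    def split(self, p: np.ndarray):
        v_free = p[: self.n_free]
        exch = np.zeros(len(self.network.reactions))
        exch[self.rev_idx] = 10.0 ** p[self.n_free :]
        return self.param.net_vector(v_free), exch

    def flux_map(self, p: np.ndarray) -> FluxMap:
        net, exch = self.split(p)
        rids = self.network.reaction_ids
        return FluxMap(
            net={r: float(net[j]) for j, r in enumerate(rids)},
            exchange={r: float(exch[self.network.reaction_ids.index(r)])
                      for r in self.rev_ids},
        )

    def residuals(self, p: np.ndarray, extra=None) -> np.ndarray:
        net, exch = self.split(p)
        if self._mid_keys:
            sim_flat = simulate_targets_flat(
                self.system, net, exch, self.tracers, self._sim_order
            )
            mean_flat, _ = _truncated_moments(sim_flat, self._censor_flat)
            sums = np.add.reduceat(mean_flat, self._mid_offsets[:-1])
            g_flat = mean_flat / np.repeat(
                sums, np.diff(self._mid_offsets)
            )
            res = [self._L_block @ (g_flat + self._delta_flat - self._obs_flat)]
        else:
            res = []
        rate_res = []
        for met in self._rate_keys:
            val, sd = self.meas.rates[met]
            rid, sign = self.rate_reactions[met]
            model = sign * net[self.network.reaction_ids.index(rid)]
            rate_res.append((model - val) / max(sd, 1e-6))
        # soft hinge keeping dependent net fluxes inside their declared bounds
        vdep = net[self._dep_idx]
        hinge = np.maximum(0.0, self._dep_lb - vdep) + np.maximum(
            0.0, vdep - self._dep_ub
        )
        out = np.concatenate(res + [rate_res, np.sqrt(self.bound_penalty) * hinge])
        if extra is not None:
            out = np.concatenate([out, extra(net, exch)])
        return out

    def ssr(self, p: np.ndarray) -> float:
        return float(np.sum(self.residuals(p) ** 2))

    def reweight_at(self, p: np.ndarray) -> None:
        """Rebuild the MID whiteners at the model prediction for ``p``.

        Whitening at the fitted model (rather than at the observed, noisy
        fractions) decouples the weights from the realized noise, which keeps
        the optimal SSR chi-square distributed under repeated sampling.
        """
        net, exch = self.split(p)
        sims = simulate_mids_multi(self.system, net, exch, self.tracers)
        for i, key in enumerate(self._mid_keys):
            tid, met, pos = key
            sim = sims[self._tracer_pos[tid]][(met, pos)]
            L, delta = _mid_measurement_model(
                self._mid_obs[i], self._mid_sd[i], self._mid_censor[i],
                mu_hat=sim,
            )
            self._mid_L[i] = L
            self._mid_delta[i] = delta
        self._refresh_flat()

    def random_start(self, rng: np.random.Generator) -> np.ndarray:
        lb, ub = self.bounds()
        scale = 2.0 * max(
            (abs(v) for v, _ in self.meas.rates.values()), default=5.0
        )
        lo = np.maximum(lb[: self.n_free], -scale)
        hi = np.minimum(ub[: self.n_free], scale)
        v_free = rng.uniform(lo, hi)
        log_ex = rng.uniform(-2.0, 1.0, size=self.n_exch)
        return np.concatenate([v_free, log_ex])

    def minimize(self, x0: np.ndarray, extra=None, fixed=None, **ls_kw):
        """Bound-constrained least squares; ``fixed=(index, value)`` pins one
        parameter exactly (used by profile-likelihood continuation)."""
        lb, ub = self.bounds()
        defaults = dict(method="trf", xtol=1e-10, ftol=1e-10, gtol=1e-10,
                        max_nfev=4000)
        defaults.update(ls_kw)
        if fixed is None:
            x0 = np.clip(x0, lb, ub)
            return optimize.least_squares(
                lambda p: self.residuals(p, extra=extra), x0, bounds=(lb, ub),
                **defaults,
            )
        j, value = fixed
        mask = np.ones(len(x0), dtype=bool)
        mask[j] = False

        def embed(q):
            p = np.empty(len(mask))
            p[mask] = q
            p[j] = value
            return p

        q0 = np.clip(np.asarray(x0)[mask], lb[mask], ub[mask])
        sol = optimize.least_squares(
            lambda q: self.residuals(embed(q), extra=extra), q0,
            bounds=(lb[mask], ub[mask]), **defaults,
        )
        sol.x = embed(sol.x)
        return sol


# ---------------------------------------------------------------------------
# public results


@dataclass
class FluxFitResult:
    flux_map: FluxMap
    ssr: float
    dof: int
    chi2_accept: bool
    chi2_upper: float
    restart_ssrs: list[float]
    converged: bool
    seed: int
    params: np.ndarray
    confidence_intervals: dict[str, tuple[float, float]] = field(default_factory=dict)
    ci_open: dict[str, bool] = field(default_factory=dict)
    problem: "_FitProblem" = None  # type: ignore

    def net_flux(self, rid: str) -> float:
        return self.flux_map.net[rid]


def _effective_parameters(prob: _FitProblem, x: np.ndarray, rtol: float = 1e-6) -> int:
    """Rank of the residual Jacobian at the optimum (redundancy analysis)."""
    r0 = prob.residuals(x)
    J = np.empty((len(r0), len(x)))
    for j in range(len(x)):
        dx = 1e-6 * max(abs(x[j]), 1e-3)
        xp = x.copy()
        xp[j] += dx
        J[:, j] = (prob.residuals(xp) - r0) / dx
    sv = np.linalg.svd(J, compute_uv=False)
    if sv.size == 0 or sv[0] == 0:
        return 0
    return int(np.sum(sv > rtol * sv[0]))


def goodness_of_fit(ssr: float, dof: int, alpha: float = 0.05):
    """One-sided upper-tail chi-square acceptance of the fit SSR."""
    if dof < 1:
        raise ValueError("dof < 1: model is over-parameterized for the data")
    upper = float(stats.chi2.ppf(1.0 - alpha, dof))
    return {"accept": bool(ssr <= upper), "ssr": ssr, "dof": dof, "upper": upper}


def fit_fluxes(
    network: AtomTransitionNetwork,
    measurements: FitMeasurements,
    biomass: dict[str, float],
    restarts: int = 5,
    seed: int = 0,
    emu_system: EmuSystem | None = None,
    prefer_free: list[str] | None = None,
    rate_reactions: dict[str, tuple[str, int]] | None = None,
    ls_options: dict | None = None,
    reweight: bool = True,
) -> FluxFitResult:
    """Variance-weighted least-squares flux fit from seeded random restarts.

    With ``reweight`` (default) the MID whitening is rebuilt once at the
    best-fit model prediction and the optimum re-polished, so the reported SSR
    uses weights that do not adapt to the realized noise.
    """
    if emu_system is None:
        targets = sorted({(m, pos) for (_, m, pos) in measurements.mids})
        emu_system = decompose_emu(network, list(targets))
    prob = _FitProblem(
        network, emu_system, measurements, biomass,
        rate_reactions=rate_reactions, prefer_free=prefer_free,
    )
    rng = np.random.default_rng(seed)
    best = None
    restart_ssrs = []
    n_ok = 0
    for _ in range(max(1, restarts)):
        x0 = prob.random_start(rng)
        try:
            sol = prob.minimize(x0, **(ls_options or {}))
        except Exception:
            restart_ssrs.append(float("nan"))
            continue
        ssr = float(2.0 * sol.cost)
        restart_ssrs.append(ssr)
        n_ok += 1
        if best is None or ssr < float(2.0 * best.cost):
            best = sol
    if best is None:
        raise FitError(
            f"no restart converged; per-restart SSRs: {restart_ssrs}"
        )
    if reweight:
        prob.reweight_at(best.x)
        best = prob.minimize(best.x, **(ls_options or {}))
    ssr = float(2.0 * best.cost)
    # redundancy analysis: structurally non-identifiable directions (zero
    # singular values of the residual Jacobian at the optimum) absorb no
    # degrees of freedom, so dof counts only the effective parameters
    n_eff = _effective_parameters(prob, best.x)
    dof = measurements.n_independent() - n_eff
    if dof >= 1:
        gof = goodness_of_fit(ssr, dof)
        accept, upper = gof["accept"], gof["upper"]
    else:  # saturated model: no residual degrees of freedom to test
        accept, upper = None, float("nan")
    return FluxFitResult(
        flux_map=prob.flux_map(best.x),
        ssr=ssr,
        dof=dof,
        chi2_accept=accept,
        chi2_upper=upper,
        restart_ssrs=restart_ssrs,
        converged=bool(best.success) and n_ok > 0,
        seed=seed,
        params=best.x,
        problem=prob,
    )


# ---------------------------------------------------------------------------
# profile-likelihood (parameter continuation) confidence intervals


def _pin_extra(prob: _FitProblem, rid: str, value: float, weight: float = 1e4):
    j = prob.network.reaction_ids.index(rid)

    def extra(net, exch):
        return np.array([(net[j] - value) * weight])

    return extra


def profile_confidence_interval(
    fit: FluxFitResult,
    rid: str,
    alpha: float = 0.05,
    max_steps: int = 40,
    rel_span: float = 10.0,
) -> tuple[float, float, dict]:
    """95% CI of a net flux by parameter continuation.

    Steps the target flux away from its optimum, re-optimizing all other
    parameters (warm-started), until the profiled SSR crosses
    SSR_min + chi2(1, 1-alpha); the crossing is then refined by bisection.
    Directions whose profile never crosses within ``rel_span`` times the flux
    scale are reported open (unidentifiable).
    """
    prob = fit.problem
    threshold = fit.ssr + float(stats.chi2.ppf(1.0 - alpha, 1))
    v_hat = fit.net_flux(rid)
    scale = max(abs(v_hat), 0.05)
    info = {"open_lower": False, "open_upper": False, "unreliable": False}

    free_idx = prob.param.free.index(rid) if rid in prob.param.free else None

    def profiled_ssr(value: float, x_warm: np.ndarray) -> tuple[float, np.ndarray]:
        if free_idx is not None:
            x_warm = x_warm.copy()
            x_warm[free_idx] = value
            sol = prob.minimize(
                x_warm, fixed=(free_idx, value),
                xtol=1e-6, ftol=1e-6, gtol=1e-6, max_nfev=120,
            )
            return float(np.sum(prob.residuals(sol.x) ** 2)), sol.x
        extra = _pin_extra(prob, rid, value)
        sol = prob.minimize(
            x_warm, extra=extra, xtol=1e-7, ftol=1e-7, gtol=1e-7, max_nfev=200
        )
        res = prob.residuals(sol.x)
        return float(np.sum(res**2)), sol.x

    crit = float(stats.chi2.ppf(1.0 - alpha, 1))
    bounds_ci = []
    for direction, open_key in ((-1, "open_lower"), (+1, "open_upper")):
        span = rel_span * scale
        x_warm = fit.params.copy()
        # first continuation step; its SSR rise estimates the local curvature,
        # which predicts the crossing distance sqrt(crit / curvature)
        v1 = v_hat + direction * 0.12 * scale
        s1, x_warm = profiled_ssr(v1, x_warm)
        v_in, f_in = v_hat, -crit  # innermost point below the threshold
        v_out = f_out = None  # closest point beyond it
        v, f = v1, s1 - threshold
        evals = 1
        while evals < max_steps:
            if f >= 0:
                if v_out is None or abs(v - v_hat) < abs(v_out - v_hat):
                    v_out, f_out = v, f
            else:
                if abs(v - v_hat) > abs(v_in - v_hat):
                    v_in, f_in = v, f
            if f_out is not None and (
                abs(f) < 0.05 or abs(v_out - v_in) < 1e-3 * scale
            ):
                break
            if v_out is None:
                # quadratic prediction of the crossing from the optimum
                curv = max((f + crit) / max((v - v_hat) ** 2, 1e-12), 1e-12)
                v_next = v_hat + direction * min(
                    1.05 * np.sqrt(crit / curv), abs(v - v_hat) * 4.0
                )
                if abs(v_next - v_hat) <= abs(v - v_hat):
                    v_next = v_hat + direction * 1.6 * abs(v - v_hat)
            else:
                # secant between the bracketing points
                denom = f_out - f_in
                v_next = v_out - f_out * (v_out - v_in) / denom \
                    if abs(denom) > 1e-12 else 0.5 * (v_in + v_out)
                lo, hi = sorted((v_in, v_out))
                if not (lo < v_next < hi):
                    v_next = 0.5 * (v_in + v_out)
            if abs(v_next - v_hat) > span:
                if v_out is None:
                    break  # profile never crossed within the span
                v_next = np.clip(v_next, *sorted((v_in, v_out)))
            s, x_warm = profiled_ssr(v_next, x_warm)
            v, f = v_next, s - threshold
            evals += 1
        if v_out is None:
            info[open_key] = True
            bounds_ci.append(-np.inf if direction < 0 else np.inf)
            continue
        # final estimate: secant interpolation between the bracket points
        if f_out != f_in:
            b = v_out - f_out * (v_out - v_in) / (f_out - f_in)
            lo, hi = sorted((v_in, v_out))
            b = float(np.clip(b, lo, hi))
        else:
            b = 0.5 * (v_in + v_out)
        bounds_ci.append(b)
    lower, upper = bounds_ci
    if not (lower <= v_hat <= upper):
        info["unreliable"] = True
    fit.confidence_intervals[rid] = (lower, upper)
    fit.ci_open[rid] = info["open_lower"] or info["open_upper"]
    return lower, upper, info


# ---------------------------------------------------------------------------
# condition comparison


def compare_flux_maps(
    fit_ctrl: FluxFitResult, fit_spd: FluxFitResult
) -> pd.DataFrame:
    """Per-reaction net-flux fold changes (sPD / Ctrl).

    When the two net fluxes have opposite signs the fold is reported negative
    (sign-inversion convention); reactions whose CI is open on either side are
    flagged not reliably determined.
    """
    n_ctrl = fit_ctrl.flux_map.net
    n_spd = fit_spd.flux_map.net
    if set(n_ctrl) != set(n_spd):
        raise FitError("flux maps come from different networks")
    rows = []
    for rid in n_ctrl:
        vc, vs = n_ctrl[rid], n_spd[rid]
        if vc == 0:
            fold = np.inf if vs != 0 else 1.0
        else:
            fold = vs / vc
        inverted = bool(vc * vs < 0)
        if inverted:
            fold = -abs(fold)
        unreliable = bool(
            fit_ctrl.ci_open.get(rid, False) or fit_spd.ci_open.get(rid, False)
        )
        rows.append(
            {
                "reaction": rid,
                "net_ctrl": vc,
                "net_spd": vs,
                "fold": fold,
                "sign_inverted": inverted,
                "not_reliably_determined": unreliable,
            }
        )
    return pd.DataFrame(rows).set_index("reaction")
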