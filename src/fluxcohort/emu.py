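"""Steady-state isotope-labeling simulation by elementary metabolite units.

An EMU is a subset of a metabolite's carbon atoms.  Backward traversal from the
observed fragments generates the minimal EMU set; balances of EMUs of equal
size form linear systems that are solved in order of increasing size, with
condensation reactions entering as convolutions of smaller, already-solved
EMUs.  The resulting mass isotopomer distributions (MIDs) are exact
steady-state solutions for the given net/exchange flux map and tracer.

Tracers are described by a per-carbon labeling probability for each unbalanced
(source) pool: a U-13C tracer of purity ``p`` labels each carbon independently
with probability ``p``; unlabeled co-substrates use probability 0 (corrected
MIDs) or the natural 13C abundance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .network import AtomTransitionNetwork, directed_variants
from .fluxmap import FluxMap

__all__ = [
    "TracerSpec",
    "EmuSystem",
    "EmuSimulationError",
    "decompose_emu",
    "simulate_mids",
    "convolve_mids",
]


class EmuSimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class TracerSpec:
    """Labeling of the unbalanced source pools.

    ``labeled_met`` gets per-carbon labeling probability ``purity``; every other
    source pool gets ``background`` (0 for natural-abundance-corrected data).
    """

    labeled_met: str
    purity: float = 1.0
    background: float = 0.0
    id: str = ""

    def source_probability(self, met: str) -> float:
        return self.purity if met == self.labeled_met else self.background


def convolve_mids(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Discrete convolution of two MIDs; the MID of a condensation product."""
    return np.convolve(np.asarray(a, float), np.asarray(b, float))


_BINOM_CACHE: dict[tuple[int, float], np.ndarray] = {}


def _binomial_mid(n: int, p: float) -> np.ndarray:
    """MID of n carbons labeled i.i.d. with probability p."""
    key = (n, p)
    if key not in _BINOM_CACHE:
        out = np.ones(1)
        step = np.array([1.0 - p, p])
        for _ in range(n):
            out = np.convolve(out, step)
        _BINOM_CACHE[key] = out
    return _BINOM_CACHE[key]


# ---------------------------------------------------------------------------
# decomposition


@dataclass
class _SizeSystem:
    size: int
    emus: list[tuple[str, tuple[int, ...]]]
    met_of_row: np.ndarray  # index into balanced metabolite list
    coup_rows: np.ndarray
    coup_cols: np.ndarray
    coup_dirs: np.ndarray
    coup_w: np.ndarray
    # known terms: list of (row, dir_idx, weight, parts); part = ("src", met, size)
    # or ("emu", size, index_in_that_size_system)
    known: list[tuple[int, int, float, tuple]]


@dataclass
class EmuSystem:
    network: AtomTransitionNetwork
    targets: list[tuple[str, tuple[int, ...]]]
    dir_index: dict[tuple[int, int], int]  # (reaction idx, direction) -> dirflux idx
    consumption: np.ndarray  # (n_balanced_mets, n_dir) occurrence counts
    systems: list[_SizeSystem] = field(default_factory=list)

    @property
    def emu_count(self) -> int:
        return sum(len(s.emus) for s in self.systems)

    def all_emus(self) -> list[tuple[str, tuple[int, ...]]]:
        out = []
        for s in self.systems:
            out.extend(s.emus)
        return out


def decompose_emu(
    network: AtomTransitionNetwork,
    targets: list[tuple[str, tuple[int, ...]]],
) -> EmuSystem:
    """Backward-trace the EMUs required to simulate the target fragments.

    ``targets`` are ``(metabolite, carbon index tuple)`` pairs (0-based).  The
    EMU ordering is deterministic: lexicographic by metabolite then carbon set.
    """
    network.validate()
    variants = directed_variants(network)
    dir_index: dict[tuple[int, int], int] = {}
    for j, direction, _, _, _ in variants:
        dir_index.setdefault((j, direction), len(dir_index))

    bal = network.balanced_metabolites
    bal_idx = {m: i for i, m in enumerate(bal)}
    consumption = np.zeros((len(bal), len(dir_index)))
    seen_dir = set()
    for j, direction, w, subs, prods in variants:
        if (j, direction) in seen_dir:
            continue
        seen_dir.add((j, direction))
        d = dir_index[(j, direction)]
        for m, _ in subs:
            if m in bal_idx:
                consumption[bal_idx[m], d] += 1

    # production terms per balanced metabolite occurrence
    # prod_terms[met] = list of (dir_idx, weight, product atom string, substrates)
    prod_terms: dict[str, list] = {m: [] for m in bal}
    for j, direction, w, subs, prods in variants:
        d = dir_index[(j, direction)]
        for m, atoms in prods:
            if m in bal_idx:
                prod_terms[m].append((d, w, atoms, subs))

    def trace(met: str, pos: tuple[int, ...]):
        """Production terms of EMU (met, pos): list of (dir, w, parts)."""
        terms = []
        for d, w, atoms, subs in prod_terms[met]:
            labels = {atoms[i] for i in pos}
            parts = []
            for smet, satoms in subs:
                ppos = tuple(i for i, ch in enumerate(satoms) if ch in labels)
                if ppos:
                    parts.append((smet, ppos))
            n_found = sum(len(p) for _, p in parts)
            if n_found != len(pos):  # pragma: no cover - guarded by atom balance
                raise EmuSimulationError(
                    f"EMU trace lost atoms for {met}{pos} via a producing reaction"
                )
            terms.append((d, w, tuple(parts)))
        if not terms:
            raise EmuSimulationError(
                f"target EMU {met}:{pos} is a dead end: {met!r} has no producing "
                "reaction reachable from any source"
            )
        return terms

    # BFS over internal EMUs
    internal: dict[tuple[str, tuple[int, ...]], list] = {}
    stack = [(m, tuple(sorted(p))) for m, p in targets]
    for m, p in stack:
        if m not in network.metabolite_carbons:
            raise EmuSimulationError(f"unknown target metabolite {m!r}")
        if m in network.unbalanced:
            raise EmuSimulationError(f"target {m!r} is an unbalanced source/sink pool")
        if any(i < 0 or i >= network.metabolite_carbons[m] for i in p):
            raise EmuSimulationError(f"target carbon subset {p} out of range for {m!r}")
    while stack:
        key = stack.pop()
        if key in internal:
            continue
        terms = trace(*key)
        internal[key] = terms
        for _, _, parts in terms:
            for smet, ppos in parts:
                if smet not in network.unbalanced and (smet, ppos) not in internal:
                    stack.append((smet, ppos))

    # group by size, deterministic order
    sizes = sorted({len(p) for _, p in internal})
    emus_by_size = {
        k: sorted([e for e in internal if len(e[1]) == k]) for k in sizes
    }
    row_of = {}
    for k in sizes:
        for i, e in enumerate(emus_by_size[k]):
            row_of[e] = (k, i)

    systems = []
    for k in sizes:
        emus = emus_by_size[k]
        met_of_row = np.array([bal_idx[m] for m, _ in emus], dtype=int)
        cr, cc, cd, cw = [], [], [], []
        known: list[tuple[int, int, float, tuple]] = []
        for row, e in enumerate(emus):
            for d, w, parts in internal[e]:
                if len(parts) == 1 and parts[0][0] not in network.unbalanced:
                    kk, idx = row_of[parts[0]]
                    assert kk == k
                    cr.append(row)
                    cc.append(idx)
                    cd.append(d)
                    cw.append(w)
                else:
                    spec = []
                    for smet, ppos in parts:
                        if smet in network.unbalanced:
                            spec.append(("src", smet, len(ppos)))
                        else:
                            kk, idx = row_of[(smet, ppos)]
                            spec.append(("emu", kk, idx))
                    known.append((row, d, w, tuple(spec)))
        systems.append(
            _SizeSystem(
                size=k,
                emus=emus,
                met_of_row=met_of_row,
                coup_rows=np.array(cr, dtype=int),
                coup_cols=np.array(cc, dtype=int),
                coup_dirs=np.array(cd, dtype=int),
                coup_w=np.array(cw, dtype=float),
                known=known,
            )
        )
    return EmuSystem(
        network=network,
        targets=[(m, tuple(sorted(p))) for m, p in targets],
        dir_index=dir_index,
        consumption=consumption,
        systems=systems,
    )


# ---------------------------------------------------------------------------
# simulation


def _dir_arrays(system: EmuSystem):
    """Cached (reaction index, sign) arrays aligned with the dirflux vector."""
    arrs = getattr(system, "_dir_arrays_cache", None)
    if arrs is None:
        n = len(system.dir_index)
        j_arr = np.empty(n, dtype=int)
        sgn = np.empty(n, dtype=int)
        for (j, direction), d in system.dir_index.items():
            j_arr[d] = j
            sgn[d] = direction
        arrs = (j_arr, sgn)
        system._dir_arrays_cache = arrs
    return arrs


def directed_fluxes_from_vectors(
    system: EmuSystem, net: np.ndarray, exch: np.ndarray
) -> np.ndarray:
    j_arr, sgn = _dir_arrays(system)
    vj = net[j_arr]
    return np.where(sgn > 0, np.maximum(vj, 0.0), np.maximum(-vj, 0.0)) + exch[j_arr]


def simulate_mids(
    system: EmuSystem,
    flux: FluxMap,
    tracer: TracerSpec,
    check_steady_state: bool = True,
) -> dict[tuple[str, tuple[int, ...]], np.ndarray]:
    """Solve the size-ordered EMU cascade; returns MIDs for the target EMUs.

    Each returned MID is nonnegative and sums to 1 (to ~1e-10).
    """
    if check_steady_state:
        flux.validate(system.network)
    net = flux.net_vector(system.network)
    exch = flux.exchange_vector(system.network)
    return simulate_mids_from_vectors(system, net, exch, tracer)


def simulate_mids_from_vectors(
    system: EmuSystem, net: np.ndarray, exch: np.ndarray, tracer: TracerSpec
) -> dict[tuple[str, tuple[int, ...]], np.ndarray]:
    """Fast path for fitting: flux vectors aligned with ``network.reactions``."""
    return simulate_mids_multi(system, net, exch, [tracer])[0]


def simulate_mids_multi(
    system: EmuSystem,
    net: np.ndarray,
    exch: np.ndarray,
    tracers: Sequence[TracerSpec],
) -> list[dict[tuple[str, tuple[int, ...]], np.ndarray]]:
    """Simulate several tracers in one pass.

    The size-k coefficient matrix depends only on the fluxes, so it is
    assembled and factorized once and reused across tracers.
    """
    solved = _solve_cascade(system, net, exch, tracers)
    size_index = {s.size: i for i, s in enumerate(system.systems)}
    results = []
    for t in range(len(tracers)):
        result = {}
        for m, p in system.targets:
            si = size_index[len(p)]
            row = system.systems[si].emus.index((m, p))
            mid = np.clip(solved[t][si][row], 0.0, None)
            result[(m, p)] = mid / mid.sum()
        results.append(result)
    return results


def _solve_cascade(
    system: EmuSystem,
    net: np.ndarray,
    exch: np.ndarray,
    tracers: Sequence[TracerSpec],
) -> list[list[np.ndarray]]:
    dirflux = directed_fluxes_from_vectors(system, net, exch)
    outflux = system.consumption @ dirflux  # per balanced metabolite
    # a pool whose throughput vanishes (a shunt pinned at zero during
    # continuation) has an ill-defined but irrelevant MID; pin it to the
    # unlabeled distribution so the linear solve stays well posed
    dead = outflux < 1e-9
    nt = len(tracers)

    # per tracer: list over sizes of solution matrices
    solved: list[list[np.ndarray]] = [[None] * len(system.systems) for _ in range(nt)]  # type: ignore
    size_index = {s.size: i for i, s in enumerate(system.systems)}

    for si, ss in enumerate(system.systems):
        n = len(ss.emus)
        k = ss.size
        A = np.zeros((n, n))
        A[np.arange(n), np.arange(n)] = -outflux[ss.met_of_row]
        if len(ss.coup_rows):
            np.add.at(
                A,
                (ss.coup_rows, ss.coup_cols),
                ss.coup_w * dirflux[ss.coup_dirs],
            )
        B = np.zeros((n, nt * (k + 1)))
        for t, tracer in enumerate(tracers):
            sl = slice(t * (k + 1), (t + 1) * (k + 1))
            conv_cache: dict[tuple, np.ndarray] = {}
            for row, d, w, parts in ss.known:
                coeff = w * dirflux[d]
                if coeff == 0.0:
                    continue
                if parts not in conv_cache:
                    mid = None
                    for part in parts:
                        if part[0] == "src":
                            pm = _binomial_mid(
                                part[2], tracer.source_probability(part[1])
                            )
                        else:
                            pm = solved[t][size_index[part[1]]][part[2]]
                        mid = pm if mid is None else np.convolve(mid, pm)
                    conv_cache[parts] = mid
                B[row, sl] += coeff * conv_cache[parts]
        dead_rows = np.where(dead[ss.met_of_row])[0]
        for row in dead_rows:
            A[row, :] = 0.0
            A[row, row] = -1.0
            B[row, :] = 0.0
            for t in range(nt):
                B[row, t * (k + 1)] = 1.0
        try:
            X = np.linalg.solve(A, -B)
        except np.linalg.LinAlgError:
            dead = [f"{m}:{p}" for m, p in ss.emus]
            raise EmuSimulationError(
                f"singular size-{k} EMU system (disconnected pool with zero "
                f"throughput) among {dead}"
            )
        for t in range(nt):
            Xt = X[:, t * (k + 1) : (t + 1) * (k + 1)]
            sums = Xt.sum(axis=1)
            if np.abs(sums - 1.0).max() > 1e-6:
                bad = ss.emus[int(np.argmax(np.abs(sums - 1)))]
                raise EmuSimulationError(
                    f"EMU solution for {bad} does not sum to 1 "
                    f"(sum={sums.max():.6f}); flux map is likely not at steady state"
                )
            solved[t][si] = Xt
    return solved


def simulate_targets_flat(
    system: EmuSystem,
    net: np.ndarray,
    exch: np.ndarray,
    tracers: Sequence[TracerSpec],
    order: Sequence[tuple[int, int, int]],
) -> np.ndarray:
    """Concatenated target MIDs in a caller-defined order (fitting hot path).

    ``order`` entries are (tracer position, size-system index, row index),
    e.g. prebuilt by :func:`target_locator`.
    """
    solved = _solve_cascade(system, net, exch, tracers)
    parts = []
    for t, si, row in order:
        mid = solved[t][si][row]
        if mid.min() < 0.0:
            mid = np.clip(mid, 0.0, None)
        parts.append(mid / mid.sum())
    return np.concatenate(parts)


def target_locator(system: EmuSystem) -> dict[tuple[str, tuple[int, ...]], tuple[int, int]]:
    """(metabolite, carbons) -> (size-system index, row index) lookup."""
    size_index = {s.size: i for i, s in enumerate(system.systems)}
    out = {}
    for m, p in system.targets:
        si = size_index[len(p)]
        out[(m, p)] = (si, system.systems[si].emus.index((m, p)))
    return out


def simulate_metabolite_mids(
    system: EmuSystem, flux: FluxMap, tracer: TracerSpec, **kw
) -> dict[str, np.ndarray]:
    """Convenience wrapper keyed by metabolite for full-backbone targets."""
    res = simulate_mids(system, flux, tracer, **kw)
    return {m: mid for (m, _), mid in res.items()}


def full_fragment_targets(
    network: AtomTransitionNetwork, metabolites: list[str]
) -> list[tuple[str, tuple[int, ...]]]:
    return [(m, tuple(range(network.metabolite_carbons[m]))) for m in metabolites]
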