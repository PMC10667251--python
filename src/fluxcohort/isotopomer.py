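"""Brute-force positional-isotopomer simulation (verification oracle).

Solves the full positional labeling-state balance of every balanced pool by
damped fixed-point iteration (Jacobi sweeps over pools), assuming well-mixed,
mutually independent pools — the same physical model the EMU cascade solves,
but through an independent numerical route that enumerates all 2^n positional
states per metabolite.  Intended for small fixtures only; refuses when the
total state space exceeds ``MAX_STATES``.
"""

from __future__ import annotations

import numpy as np

from .network import AtomTransitionNetwork, directed_variants
from .fluxmap import FluxMap
from .emu import TracerSpec, EmuSimulationError

__all__ = ["simulate_isotopomers_bruteforce", "MAX_STATES"]

MAX_STATES = 1 << 16


def _bit_extract(n_bits: int, positions: tuple[int, ...]) -> np.ndarray:
    """idx[s] = integer formed by the bits of s at ``positions`` (LSB first)."""
    s = np.arange(1 << n_bits)
    out = np.zeros_like(s)
    for j, p in enumerate(positions):
        out |= ((s >> p) & 1) << j
    return out


def simulate_isotopomers_bruteforce(
    network: AtomTransitionNetwork,
    flux: FluxMap,
    tracer: TracerSpec,
    targets: list[tuple[str, tuple[int, ...]]] | None = None,
    tol: float = 1e-13,
    max_iter: int = 50000,
) -> dict[tuple[str, tuple[int, ...]], np.ndarray]:
    """Return MIDs of the target fragments by full isotopomer enumeration."""
    network.validate()
    flux.validate(network)
    bal = network.balanced_metabolites
    ncar = network.metabolite_carbons
    total_states = sum(1 << ncar[m] for m in bal)
    if total_states > MAX_STATES:
        raise EmuSimulationError(
            f"state space too large for brute force: {total_states} > {MAX_STATES}"
        )
    if targets is None:
        targets = [(m, tuple(range(ncar[m]))) for m in bal]

    net = flux.net_vector(network)
    exch = flux.exchange_vector(network)

    def dflux(j: int, direction: int) -> float:
        return (max(net[j], 0.0) if direction > 0 else max(-net[j], 0.0)) + exch[j]

    # source pool positional distributions: independent Bernoulli per carbon
    def bernoulli_dist(n: int, p: float) -> np.ndarray:
        d = np.ones(1)
        for _ in range(n):
            d = np.concatenate([d * (1 - p), d * p])
        return d

    dists: dict[str, np.ndarray] = {}
    for m in network.metabolites:
        if m in network.unbalanced:
            dists[m] = bernoulli_dist(ncar[m], tracer.source_probability(m))
        else:
            d = np.zeros(1 << ncar[m])
            d[0] = 1.0
            dists[m] = d

    # production terms: met -> list of (flux_weight, [(sub_met, qidx, eidx, nq)])
    # qidx: extraction of substrate bits feeding this product occurrence;
    # eidx: extraction of the product's bits at the corresponding positions.
    terms: dict[str, list] = {m: [] for m in bal}
    outflux = {m: 0.0 for m in bal}
    seen_dir = set()
    for j, direction, w, subs, prods in directed_variants(network):
        f = dflux(j, direction)
        if (j, direction) not in seen_dir:
            seen_dir.add((j, direction))
            for m, _ in subs:
                if m in outflux:
                    outflux[m] += f
        if f * w == 0.0:
            continue
        for m, atoms in prods:
            if m not in terms:
                continue
            # map each product position to (substrate, substrate position)
            pieces = []
            for smet, satoms in subs:
                spos, mpos = [], []
                for i, ch in enumerate(atoms):
                    q = satoms.find(ch)
                    if q >= 0:
                        spos.append(q)
                        mpos.append(i)
                if spos:
                    pieces.append(
                        (
                            smet,
                            _bit_extract(ncar[smet], tuple(spos)),
                            _bit_extract(ncar[m], tuple(mpos)),
                            len(spos),
                        )
                    )
            terms[m].append((f * w, pieces))

    for m in bal:
        if outflux[m] <= 0:
            raise EmuSimulationError(f"pool {m!r} has zero throughput")

    for it in range(max_iter):
        worst = 0.0
        new = {}
        for m in bal:
            acc = np.zeros(1 << ncar[m])
            for f, pieces in terms[m]:
                contrib = np.full(1 << ncar[m], f)
                for smet, qidx, eidx, nq in pieces:
                    marg = np.bincount(qidx, weights=dists[smet], minlength=1 << nq)
                    contrib *= marg[eidx]
                acc += contrib
            acc /= outflux[m]
            new[m] = acc
        for m in bal:
            worst = max(worst, float(np.abs(new[m] - dists[m]).max()))
            dists[m] = new[m]
        if worst < tol:
            break
    else:
        raise EmuSimulationError(
            f"isotopomer fixed point did not converge (last change {worst:.2e})"
        )

    out = {}
    for m, pos in targets:
        pos = tuple(sorted(pos))
        qidx = _bit_extract(ncar[m], pos)
        marg = np.bincount(qidx, weights=dists[m], minlength=1 << len(pos))
        mid = np.zeros(len(pos) + 1)
        for s in range(1 << len(pos)):
            mid[bin(s).count("1")] += marg[s]
        out[(m, pos)] = mid / mid.sum()
    return out
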