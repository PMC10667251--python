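"""Shared fixtures: the TCA-toy network, ground-truth cohort parameters, and a
seeded generator of random atom-transition networks with feasible flux maps
(used to cross-check the EMU cascade against the brute-force isotopomer
oracle on arbitrary topologies)."""

from __future__ import annotations

import numpy as np
import pytest

from fluxcohort.network import AtomTransitionNetwork, Reaction
from fluxcohort.fluxmap import FluxMap
from fluxcohort.emu import TracerSpec, decompose_emu, full_fragment_targets
from fluxcohort.cohort import SyntheticTruth, toy_network, MEASURED_METABOLITES


@pytest.fixture(scope="session")
def tca_network():
    return toy_network()


@pytest.fixture(scope="session")
def truth():
    return SyntheticTruth(seed=0)


@pytest.fixture(scope="session")
def ctrl_flux(tca_network, truth):
    return truth.flux_map(tca_network, "Ctrl")


@pytest.fixture(scope="session")
def spd_flux(tca_network, truth):
    return truth.flux_map(tca_network, "sPD")


@pytest.fixture(scope="session")
def emu_system(tca_network):
    return decompose_emu(
        tca_network, full_fragment_targets(tca_network, MEASURED_METABOLITES)
    )


# ---------------------------------------------------------------------------
# random-network generator for oracle cross-checks


def random_network_and_flux(seed: int):
    """A random small atom-transition network plus a feasible flux map.

    Construction: random reactions (transfers, cleavages, condensations) over
    up to 5 balanced pools of 1-3 carbons with random atom permutations and
    random positive fluxes; per-pool imbalances are closed by explicit
    source/sink reactions, so the map satisfies steady state by construction.
    A couple of reactions are made reversible with random exchange fluxes.
    Returns (network, flux map, tracer).
    """
    rng = np.random.default_rng(seed)
    n_m = int(rng.integers(3, 6))
    carbons = {f"M{i}": int(rng.integers(1, 4)) for i in range(n_m)}
    mets = list(carbons)
    letters = "abcdefghijklmnop"

    reactions: list[Reaction] = []
    fluxes: dict[str, float] = {}
    exchange: dict[str, float] = {}
    ext_count = 0
    all_carbons = dict(carbons)

    def ext(n):
        nonlocal ext_count
        ext_count += 1
        name = f"X{ext_count}.x"
        all_carbons[name] = n
        return name

    n_r = int(rng.integers(n_m, n_m + 4))
    for j in range(n_r):
        n_sub = int(rng.integers(1, 3))
        subs_mets = list(rng.choice(mets, size=n_sub, replace=False))
        total = sum(carbons[m] for m in subs_mets)
        # split the substrate carbons over 1-2 products; a leftover goes to an
        # external sink so atoms balance
        prod_mets: list[tuple[str, int]] = []
        remaining = total
        cands = [m for m in mets if m not in subs_mets and carbons[m] <= remaining]
        rng.shuffle(cands)
        for m in cands[:2]:
            if carbons[m] <= remaining and (remaining - carbons[m] >= 0):
                if rng.random() < 0.7:
                    prod_mets.append((m, carbons[m]))
                    remaining -= carbons[m]
            if remaining == 0:
                break
        if remaining > 0:
            prod_mets.append((ext(remaining), remaining))
        # assign atom labels
        perm = rng.permutation(total)
        lab = letters[:total]
        subs, prods = [], []
        i0 = 0
        for m in subs_mets:
            subs.append((m, lab[i0 : i0 + carbons[m]]))
            i0 += carbons[m]
        shuffled = "".join(lab[i] for i in perm)
        i0 = 0
        for m, c in prod_mets:
            prods.append((m, shuffled[i0 : i0 + c]))
            i0 += c
        rev = bool(rng.random() < 0.3)
        rid = f"R{j}"
        reactions.append(
            Reaction(rid, tuple(subs), tuple(prods), reversible=rev,
                     lb=-100.0 if rev else 0.0, ub=100.0)
        )
        fluxes[rid] = float(rng.uniform(0.5, 3.0))
        if rev:
            exchange[rid] = float(rng.uniform(0.0, 1.5))

    # close the balances with explicit source/sink reactions
    net = AtomTransitionNetwork(
        reactions=list(reactions),
        metabolite_carbons=dict(all_carbons),
        unbalanced={m for m in all_carbons if m.endswith(".x")},
    )
    S, bal = net.stoichiometric_matrix()
    v = np.array([fluxes[r.id] for r in reactions])
    imbalance = S @ v
    for m, b in zip(bal, imbalance):
        lab = letters[: carbons[m]]
        if b >= 0:
            rid = f"OUT_{m}"
            reactions.append(
                Reaction(rid, ((m, lab),), ((ext(carbons[m]), lab),))
            )
            fluxes[rid] = float(b + 0.2)
            rid2 = f"IN_{m}"
            reactions.append(
                Reaction(rid2, ((ext(carbons[m]), lab),), ((m, lab),))
            )
            fluxes[rid2] = 0.2
        else:
            rid = f"IN_{m}"
            reactions.append(
                Reaction(rid, ((ext(carbons[m]), lab),), ((m, lab),))
            )
            fluxes[rid] = float(-b + 0.2)
            rid2 = f"OUT_{m}"
            reactions.append(
                Reaction(rid2, ((m, lab),), ((ext(carbons[m]), lab),))
            )
            fluxes[rid2] = 0.2

    network = AtomTransitionNetwork(
        reactions=reactions,
        metabolite_carbons=all_carbons,
        unbalanced={m for m in all_carbons if m.endswith(".x")},
    )
    network.validate()
    flux = FluxMap(net=fluxes, exchange=exchange)
    flux.validate(network)
    sources = sorted(
        {m for r in reactions for m, _ in r.substrates if m in network.unbalanced}
    )
    tracer = TracerSpec(str(rng.choice(sources)), purity=0.99, id="rand")
    return network, flux, tracer
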