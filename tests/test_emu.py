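import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fluxcohort.network import parse_network_text
from fluxcohort.fluxmap import FluxMap
from fluxcohort.emu import (
    TracerSpec,
    convolve_mids,
    decompose_emu,
    full_fragment_targets,
    simulate_mids,
)
from fluxcohort.isotopomer import simulate_isotopomers_bruteforce, MAX_STATES
from fluxcohort.emu import EmuSimulationError

from conftest import random_network_and_flux

HEADER = "id\tequation\treversible\tlb\tub\n"


def _net(text):
    return parse_network_text(text)


class TestDecomposition:
    def test_linear_chain_yields_one_emu_per_metabolite(self):
        text = (
            "#unbalanced\tS0 S4\n" + HEADER
            + "".join(
                f"r{i}\t{a} (ab) -> {b} (ab)\t0\t0\t100\n"
                for i, (a, b) in enumerate(
                    [("S0", "M1"), ("M1", "M2"), ("M2", "M3"), ("M3", "S4")]
                )
            )
        )
        net = _net(text)
        system = decompose_emu(net, [("M3", (0, 1))])
        # no cleavage, no condensation: one size-2 EMU per balanced metabolite
        assert [(m, p) for m, p in system.all_emus()] == [
            ("M1", (0, 1)), ("M2", (0, 1)), ("M3", (0, 1))
        ]

    def test_condensation_produces_convolution_parts(self):
        text = (
            "#unbalanced\tAx Bx Cx\n" + HEADER
            + "in_a\tAx (ab) -> A (ab)\t0\t0\t100\n"
            + "in_b\tBx (ab) -> B (ab)\t0\t0\t100\n"
            + "cond\tA (ab) + B (cd) -> C (abcd)\t0\t0\t100\n"
            + "out\tC (abcd) -> Cx (abcd)\t0\t0\t100\n"
        )
        net = _net(text)
        system = decompose_emu(net, [("C", (0, 1, 2, 3))])
        emus = set(system.all_emus())
        assert ("A", (0, 1)) in emus and ("B", (0, 1)) in emus
        assert ("C", (0, 1, 2, 3)) in emus
        size4 = [s for s in system.systems if s.size == 4][0]
        assert any(len(parts) == 2 for _, _, _, parts in size4.known)

    def test_toy_emu_count_matches_recursive_enumeration(self, tca_network):
        """Independent oracle: plain recursive backtrace with memoization."""
        from fluxcohort.network import directed_variants

        targets = full_fragment_targets(
            tca_network, ["Cit", "AKG", "Suc", "Fum", "Mal", "Glu"]
        )
        system = decompose_emu(tca_network, targets)

        variants = directed_variants(tca_network)
        seen = set()

        def trace(met, pos):
            key = (met, tuple(sorted(pos)))
            if key in seen or met in tca_network.unbalanced:
                return
            seen.add(key)
            for _, _, _, subs, prods in variants:
                for pm, atoms in prods:
                    if pm != met:
                        continue
                    labels = {atoms[i] for i in pos}
                    for sm, satoms in subs:
                        sub_pos = tuple(
                            i for i, ch in enumerate(satoms) if ch in labels
                        )
                        if sub_pos:
                            trace(sm, sub_pos)

        for m, p in targets:
            trace(m, p)
        assert system.emu_count == len(seen)

    def test_unreachable_target_errors(self):
        text = (
            "#unbalanced\tS\n" + HEADER
            + "r\tA (a) -> S (a)\t0\t0\t100\n"
            + "r2\tS (a) -> A (a)\t0\t0\t100\n"
        )
        net = _net(text)
        with pytest.raises(EmuSimulationError):
            decompose_emu(net, [("Missing", (0,))])


class TestSimulation:
    def _simple(self, reversible_mid=False):
        text = (
            "#unbalanced\tSrc Snk\n" + HEADER
            + "in\tSrc (ab) -> X (ab)\t0\t0\t100\n"
            + "out\tX (ab) -> Snk (ab)\t0\t0\t100\n"
        )
        return _net(text)

    def test_single_path_steady_state_equals_source(self):
        net = self._simple()
        system = decompose_emu(net, [("X", (0, 1))])
        flux = FluxMap(net={"in": 1.0, "out": 1.0})
        mid = simulate_mids(system, flux, TracerSpec("Src"))[("X", (0, 1))]
        np.testing.assert_allclose(mid, [0, 0, 1], atol=1e-12)

    def test_flux_weighted_mixture_of_sources(self):
        text = (
            "#unbalanced\tLab Unl Snk\n" + HEADER
            + "a\tLab (ab) -> X (ab)\t0\t0\t100\n"
            + "b\tUnl (ab) -> X (ab)\t0\t0\t100\n"
            + "out\tX (ab) -> Snk (ab)\t0\t0\t100\n"
        )
        net = _net(text)
        system = decompose_emu(net, [("X", (0, 1))])
        flux = FluxMap(net={"a": 1.0, "b": 1.0, "out": 2.0})
        mid = simulate_mids(system, flux, TracerSpec("Lab"))[("X", (0, 1))]
        np.testing.assert_allclose(mid, [0.5, 0, 0.5], atol=1e-12)

    def test_condensation_is_convolution(self):
        np.testing.assert_allclose(
            convolve_mids([0.5, 0, 0.5], [1, 0, 0]), [0.5, 0, 0.5, 0, 0]
        )

    def test_mid_invariant_under_uniform_flux_scaling(
        self, tca_network, ctrl_flux, emu_system, truth
    ):
        tracer = truth.tracers()[0]
        base = simulate_mids(emu_system, ctrl_flux, tracer, check_steady_state=False)
        scaled = simulate_mids(
            emu_system, ctrl_flux.scaled(3.7), tracer, check_steady_state=False
        )
        for k in base:
            np.testing.assert_allclose(base[k], scaled[k], atol=1e-10)

    def test_unlabeled_tracer_gives_unlabeled_mids(
        self, tca_network, ctrl_flux, emu_system
    ):
        res = simulate_mids(
            emu_system, ctrl_flux, TracerSpec("Glc.x", purity=0.0),
            check_steady_state=False,
        )
        for (m, p), mid in res.items():
            assert mid[0] == pytest.approx(1.0, abs=1e-10)


class TestConvolve:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ([1, 0], [1, 0], [1, 0, 0]),
            ([0, 1], [0, 1], [0, 0, 1]),
            ([0.5, 0.5], [0.5, 0.5], [0.25, 0.5, 0.25]),
        ],
    )
    def test_examples(self, a, b, expected):
        np.testing.assert_allclose(convolve_mids(a, b), expected)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(st.floats(0.01, 1.0), min_size=1, max_size=6),
        st.lists(st.floats(0.01, 1.0), min_size=1, max_size=6),
    )
    def test_convolution_preserves_normalization_and_length(self, a, b):
        a = np.array(a) / np.sum(a)
        b = np.array(b) / np.sum(b)
        c = convolve_mids(a, b)
        assert len(c) == len(a) + len(b) - 1
        assert c.sum() == pytest.approx(1.0)
        assert (c >= -1e-15).all()


class TestOracle:
    def test_toy_matches_bruteforce_both_tracers(
        self, tca_network, ctrl_flux, emu_system, truth
    ):
        for tracer in truth.tracers():
            emu_res = simulate_mids(
                emu_system, ctrl_flux, tracer, check_steady_state=False
            )
            bf = simulate_isotopomers_bruteforce(
                tca_network, ctrl_flux, tracer, targets=list(emu_res)
            )
            for k in emu_res:
                np.testing.assert_allclose(emu_res[k], bf[k], atol=1e-8)

    @pytest.mark.parametrize("seed", range(8))
    def test_random_networks_match_bruteforce(self, seed):
        net, flux, tracer = random_network_and_flux(seed)
        targets = [
            (m, tuple(range(net.metabolite_carbons[m])))
            for m in net.balanced_metabolites
        ]
        system = decompose_emu(net, targets)
        emu_res = simulate_mids(system, flux, tracer, check_steady_state=False)
        bf = simulate_isotopomers_bruteforce(net, flux, tracer, targets=targets)
        for k in emu_res:
            np.testing.assert_allclose(emu_res[k], bf[k], atol=1e-8)

    def test_symmetric_pool_scrambling_agrees_with_oracle(self):
        """Succinate/fumarate toy: production-side scrambling matches the
        full positional balance."""
        text = (
            "#unbalanced\tSrc Snk\n"
            + "#symmetric\tF\n" + HEADER
            + "in\tSrc (abcd) -> S (abcd)\t0\t0\t100\n"
            + "sf\tS (abcd) -> F (abcd)\t1\t-100\t100\n"
            + "out\tF (abcd) -> Snk (abcd)\t0\t0\t100\n"
        )
        net = _net(text)
        flux = FluxMap(net={"in": 1, "sf": 1, "out": 1}, exchange={"sf": 0.7})
        tracer = TracerSpec("Src", purity=0.6)
        targets = [("S", (0, 1, 2, 3)), ("F", (0, 1, 2, 3))]
        system = decompose_emu(net, targets)
        emu_res = simulate_mids(system, flux, tracer, check_steady_state=False)
        bf = simulate_isotopomers_bruteforce(net, flux, tracer, targets=targets)
        for k in emu_res:
            np.testing.assert_allclose(emu_res[k], bf[k], atol=1e-10)

    def test_bruteforce_refuses_oversized_state_space(self):
        # 17 one-carbon pools would be fine; a 17-carbon pool is not
        text = (
            "#unbalanced\tS T\n" + HEADER
            + "in\tS (abcdefghijklmnopq) -> B (abcdefghijklmnopq)\t0\t0\t100\n"
            + "out\tB (abcdefghijklmnopq) -> T (abcdefghijklmnopq)\t0\t0\t100\n"
        )
        net = _net(text)
        flux = FluxMap(net={"in": 1, "out": 1})
        assert 2 ** 17 > MAX_STATES
        with pytest.raises(EmuSimulationError, match="state space"):
            simulate_isotopomers_bruteforce(net, flux, TracerSpec("S"))
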