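"""Flux maps: net + exchange flux assignments over an atom-transition network.

A reversible reaction with net flux ``v`` and exchange flux ``e >= 0`` carries a
forward flux ``max(v, 0) + e`` and a backward flux ``max(-v, 0) + e``.  This
(net, exchange) split keeps the exchange parameter nonnegative and avoids sign
pathologies during fitting.  Units follow the convention of DNA-normalized
uptake/secretion rates: mM per hour per mg DNA.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import AtomTransitionNetwork

__all__ = ["FluxMap", "SteadyStateError"]


class SteadyStateError(ValueError):
    """Raised when a flux map violates stoichiometric steady state or bounds."""


@dataclass
class FluxMap:
    """Net flux per reaction id plus exchange flux per reversible reaction id."""

    net: dict[str, float]
    exchange: dict[str, float] = field(default_factory=dict)

    def net_vector(self, network: AtomTransitionNetwork) -> np.ndarray:
        try:
            return np.array([self.net[r.id] for r in network.reactions], dtype=float)
        except KeyError as exc:
            raise SteadyStateError(f"flux map missing reaction {exc.args[0]!r}") from exc

    def exchange_vector(self, network: AtomTransitionNetwork) -> np.ndarray:
        out = np.zeros(len(network.reactions))
        for j, r in enumerate(network.reactions):
            if r.reversible:
                out[j] = self.exchange.get(r.id, 0.0)
        return out

    def validate(self, network: AtomTransitionNetwork, tol: float = 1e-8) -> None:
        v = self.net_vector(network)
        S, mets = network.stoichiometric_matrix()
        resid = S @ v
        worst = np.argmax(np.abs(resid)) if len(resid) else 0
        if len(resid) and np.abs(resid).max() > tol:
            raise SteadyStateError(
                f"steady state violated at {mets[worst]!r}: imbalance {resid[worst]:.3e}"
            )
        for j, r in enumerate(network.reactions):
            if v[j] < r.lb - 1e-9 or v[j] > r.ub + 1e-9:
                raise SteadyStateError(
                    f"net flux of {r.id!r} = {v[j]:.4g} outside bounds "
                    f"[{r.lb:g}, {r.ub:g}]"
                )
            if not r.reversible and self.exchange.get(r.id, 0.0) != 0.0:
                raise SteadyStateError(
                    f"irreversible reaction {r.id!r} has nonzero exchange flux"
                )
        if any(e < 0 for e in self.exchange.values()):
            raise SteadyStateError("exchange fluxes must be nonnegative")

    def scaled(self, factor: float) -> "FluxMap":
        return FluxMap(
            net={k: factor * v for k, v in self.net.items()},
            exchange={k: factor * v for k, v in self.exchange.items()},
        )
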