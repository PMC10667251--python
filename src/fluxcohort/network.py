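"""Atom-transition metabolic networks.

A network is a list of carbon-mapped reactions over metabolite pools.  Each
reaction side is a list of ``(metabolite, atoms)`` pairs where ``atoms`` is a
string of single-letter carbon labels (e.g. ``"abcde"``); a label appearing on
the substrate side must reappear exactly once on the product side, which is the
atom-balance invariant underlying isotope-labeling simulation.

Pools are *balanced* (intracellular, subject to steady state) unless declared
unbalanced (extracellular sources/sinks, biomass drains).  Metabolites declared
*symmetric* (succinate, fumarate) are scrambled on production: every directed
reaction producing them is expanded into orientation variants at half weight.

The on-disk dialect is a TSV with columns ``id, equation, reversible, lb, ub``
plus two optional directive lines::

    #unbalanced<TAB>Glc.x Gln.x ...
    #symmetric<TAB>Suc Fum
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

__all__ = [
    "NetworkValidationError",
    "Reaction",
    "AtomTransitionNetwork",
    "parse_network",
    "parse_network_text",
    "serialize_network",
]


class NetworkValidationError(ValueError):
    """Raised when a network file violates a structural invariant."""


@dataclass(frozen=True)
class Reaction:
    id: str
    substrates: tuple[tuple[str, str], ...]  # (metabolite, atom labels)
    products: tuple[tuple[str, str], ...]
    reversible: bool = False
    lb: float = 0.0
    ub: float = 1000.0

    def equation(self) -> str:
        lhs = " + ".join(f"{m} ({a})" for m, a in self.substrates)
        rhs = " + ".join(f"{m} ({a})" for m, a in self.products)
        return f"{lhs} -> {rhs}"


@dataclass
class AtomTransitionNetwork:
    reactions: list[Reaction]
    metabolite_carbons: dict[str, int]
    unbalanced: set[str] = field(default_factory=set)
    symmetric: set[str] = field(default_factory=set)
    balanced_ok: bool = True

    @property
    def metabolites(self) -> list[str]:
        return sorted(self.metabolite_carbons)

    @property
    def balanced_metabolites(self) -> list[str]:
        return sorted(m for m in self.metabolite_carbons if m not in self.unbalanced)

    def reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def stoichiometric_matrix(self):
        """Rows = balanced metabolites (sorted), columns = reactions (file order)."""
        import numpy as np

        mets = self.balanced_metabolites
        idx = {m: i for i, m in enumerate(mets)}
        S = np.zeros((len(mets), len(self.reactions)))
        for j, r in enumerate(self.reactions):
            for m, _ in r.substrates:
                if m in idx:
                    S[idx[m], j] -= 1
            for m, _ in r.products:
                if m in idx:
                    S[idx[m], j] += 1
        return S, mets

    def validate(self) -> None:
        seen: set[str] = set()
        for r in self.reactions:
            if r.id in seen:
                raise NetworkValidationError(f"duplicate reaction id {r.id!r}")
            seen.add(r.id)
            sub_labels = "".join(a for _, a in r.substrates)
            prod_labels = "".join(a for _, a in r.products)
            if sorted(sub_labels) != sorted(prod_labels):
                raise NetworkValidationError(
                    f"reaction {r.id!r}: atom labels not conserved "
                    f"({sub_labels!r} vs {prod_labels!r})"
                )
            if len(set(sub_labels)) != len(sub_labels):
                raise NetworkValidationError(
                    f"reaction {r.id!r}: repeated atom label on substrate side"
                )
            for m, a in r.substrates + r.products:
                n = self.metabolite_carbons.get(m)
                if n is None:
                    raise NetworkValidationError(
                        f"reaction {r.id!r}: unknown metabolite {m!r}"
                    )
                if len(a) != n:
                    raise NetworkValidationError(
                        f"reaction {r.id!r}: {m} has {n} carbons but atom string "
                        f"{a!r} has length {len(a)}"
                    )
            if r.reversible and r.lb >= 0 and r.lb == r.ub:
                raise NetworkValidationError(
                    f"reaction {r.id!r}: reversible with degenerate bounds"
                )
        # every balanced metabolite must be both produced and consumed
        produced: set[str] = set()
        consumed: set[str] = set()
        for r in self.reactions:
            for m, _ in r.substrates:
                consumed.add(m)
                if r.reversible:
                    produced.add(m)
            for m, _ in r.products:
                produced.add(m)
                if r.reversible:
                    consumed.add(m)
        for m in self.balanced_metabolites:
            if m not in produced or m not in consumed:
                raise NetworkValidationError(
                    f"balanced metabolite {m!r} is not both produced and consumed"
                )


def _parse_side(text: str, rid: str) -> tuple[tuple[str, str], ...]:
    text = text.strip()
    if not text:
        raise NetworkValidationError(f"reaction {rid!r}: empty reaction side")
    out = []
    for term in text.split("+"):
        term = term.strip()
        if "(" not in term or not term.endswith(")"):
            raise NetworkValidationError(
                f"reaction {rid!r}: malformed term {term!r}; expected 'Met (atoms)'"
            )
        met, atoms = term[:-1].split("(")
        out.append((met.strip(), atoms.strip()))
    return tuple(out)


def parse_network_text(text: str) -> AtomTransitionNetwork:
    reactions: list[Reaction] = []
    unbalanced: set[str] = set()
    symmetric: set[str] = set()
    carbons: dict[str, int] = {}
    header_seen = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#unbalanced"):
            unbalanced.update(line.split("\t", 1)[1].split())
            continue
        if line.startswith("#symmetric"):
            symmetric.update(line.split("\t", 1)[1].split())
            continue
        if line.startswith("#"):
            continue
        fields = line.split("\t")
        if not header_seen:
            if [f.strip().lower() for f in fields[:5]] != [
                "id",
                "equation",
                "reversible",
                "lb",
                "ub",
            ]:
                raise NetworkValidationError(
                    f"line {lineno}: expected header 'id equation reversible lb ub'"
                )
            header_seen = True
            continue
        if len(fields) != 5:
            raise NetworkValidationError(
                f"line {lineno}: expected 5 tab-separated fields, got {len(fields)}"
            )
        rid, eq, rev, lb, ub = (f.strip() for f in fields)
        if "->" not in eq:
            raise NetworkValidationError(f"reaction {rid!r}: missing '->'")
        lhs, rhs = eq.split("->")
        subs = _parse_side(lhs, rid)
        prods = _parse_side(rhs, rid)
        for m, a in subs + prods:
            if m in carbons and carbons[m] != len(a):
                raise NetworkValidationError(
                    f"reaction {rid!r}: {m} previously declared with "
                    f"{carbons[m]} carbons, now {len(a)}"
                )
            carbons.setdefault(m, len(a))
        reactions.append(
            Reaction(
                id=rid,
                substrates=subs,
                products=prods,
                reversible=rev in ("1", "true", "True", "yes"),
                lb=float(lb),
                ub=float(ub),
            )
        )
    net = AtomTransitionNetwork(
        reactions=reactions,
        metabolite_carbons=carbons,
        unbalanced=unbalanced,
        symmetric=symmetric,
    )
    net.validate()
    return net


def parse_network(path) -> AtomTransitionNetwork:
    """Parse and validate a network TSV file."""
    with open(path, encoding="utf-8") as fh:
        return parse_network_text(fh.read())


def serialize_network(net: AtomTransitionNetwork) -> str:
    lines = []
    if net.unbalanced:
        lines.append("#unbalanced\t" + " ".join(sorted(net.unbalanced)))
    if net.symmetric:
        lines.append("#symmetric\t" + " ".join(sorted(net.symmetric)))
    lines.append("id\tequation\treversible\tlb\tub")
    for r in net.reactions:
        lines.append(
            "\t".join(
                [r.id, r.equation(), "1" if r.reversible else "0", repr(r.lb), repr(r.ub)]
            )
        )
    return "\n".join(lines) + "\n"


def directed_variants(net: AtomTransitionNetwork):
    """Expand reactions into directed, symmetry-scrambled variants.

    Returns a list of ``(reaction_index, direction, weight, substrates, products)``
    with ``direction`` +1 (forward) or -1 (backward).  Backward directions are
    emitted for every reaction: they carry flux ``max(-net, 0) + exchange``, so
    they are inactive for irreversible reactions inside their bounds but keep
    the labeling balance well defined when an optimizer transiently drives a
    net flux negative.  Symmetric metabolites appearing as products are emitted
    in both atom orientations at half weight each, which renders their pools
    positionally symmetric regardless of the consuming reaction's orientation.
    """
    out = []
    for j, r in enumerate(net.reactions):
        dirs = [(+1, r.substrates, r.products), (-1, r.products, r.substrates)]
        for direction, subs, prods in dirs:
            variants = [(1.0, list(prods))]
            for k, (m, a) in enumerate(prods):
                if m in net.symmetric and len(a) > 1:
                    new = []
                    for w, plist in variants:
                        fwd = list(plist)
                        rev = list(plist)
                        rev[k] = (m, a[::-1])
                        new.append((w / 2.0, fwd))
                        new.append((w / 2.0, rev))
                    variants = new
            for w, plist in variants:
                out.append((j, direction, w, subs, tuple(plist)))
    return out
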