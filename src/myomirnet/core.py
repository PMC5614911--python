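"""Reaction-network data model and mass-action propensity evaluation.

A :class:`ReactionNetwork` is the executable form of a gene-regulatory
circuit: species with integer initial molecule counts, zeroth- to
second-order mass-action reactions, a named parameter set, and optional
conservation groups (single-copy gene states).  The same network is
interpreted either as a continuous-time Markov jump process (SSA) or as
a system of mass-action ODEs; the engine, not the network, chooses the
interpretation.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Mapping, Sequence

__all__ = [
    "Species",
    "Reaction",
    "ParameterSet",
    "ReactionNetwork",
    "propensity",
    "validate_network",
    "apply_overrides",
    "NetworkConfigError",
]


class NetworkConfigError(ValueError):
    """Raised for unknown parameters/species or malformed reactions."""


@dataclass(frozen=True)
class Species:
    """A molecular species tracked in whole molecule counts.

    ``is_gene_state`` marks promoter-occupancy species (free or bound
    forms of a single-copy gene), which participate in conservation
    groups.
    """

    id: str
    description: str = ""
    initial_amount: int = 0
    is_gene_state: bool = False

    def __post_init__(self) -> None:
        if self.initial_amount < 0:
            raise NetworkConfigError(
                f"species {self.id!r}: initial_amount must be >= 0"
            )


@dataclass(frozen=True)
class Reaction:
    """A stoichiometric record with a mass-action rate law.

    ``reactants`` and ``products`` are multisets of species ids (tuples,
    repetition allowed).  At most two reactant tokens are permitted:
    zeroth-, first- and second-order mass action only.  The rate law is
    ``k`` (order 0), ``k*x`` (order 1), ``k*x*y`` (distinct reactants) or
    ``k*x*(x-1)/2`` (homodimerisation, SSA convention).
    """

    id: str
    reactants: tuple[str, ...]
    products: tuple[str, ...]
    rate_constant_name: str
    note: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "reactants", tuple(self.reactants))
        object.__setattr__(self, "products", tuple(self.products))

    @property
    def order(self) -> int:
        return len(self.reactants)


class ParameterSet(dict):
    """Ordered map of rate-constant name -> value.

    Units follow reaction order: molecules s^-1 (zeroth), s^-1 (first),
    molecules^-1 s^-1 (second).
    """

    def require(self, name: str) -> float:
        try:
            return self[name]
        except KeyError:
            raise NetworkConfigError(f"unknown parameter {name!r}") from None


@dataclass
class ReactionNetwork:
    name: str
    species: list[Species] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    parameters: ParameterSet = field(default_factory=ParameterSet)
    conserved_groups: list[frozenset[str]] = field(default_factory=list)
    # optional readout aliases: name -> tuple of species ids to sum
    readouts: dict[str, tuple[str, ...]] = field(default_factory=dict)

    # -- construction helpers -------------------------------------------------
    def add_species(
        self,
        sid: str,
        initial: int = 0,
        description: str = "",
        gene_state: bool = False,
    ) -> "ReactionNetwork":
        self.species.append(
            Species(sid, description, int(initial), gene_state)
        )
        return self

    def add_reaction(
        self,
        rid: str,
        reactants: Sequence[str],
        products: Sequence[str],
        rate: str,
        note: str = "",
    ) -> "ReactionNetwork":
        self.reactions.append(
            Reaction(rid, tuple(reactants), tuple(products), rate, note)
        )
        return self

    def add_conserved(self, *sids: str) -> "ReactionNetwork":
        self.conserved_groups.append(frozenset(sids))
        return self

    # -- views ----------------------------------------------------------------
    @property
    def species_ids(self) -> list[str]:
        return [s.id for s in self.species]

    def species_index(self) -> dict[str, int]:
        return {s.id: i for i, s in enumerate(self.species)}

    def initial_state(self) -> dict[str, int]:
        return {s.id: s.initial_amount for s in self.species}

    def get_species(self, sid: str) -> Species:
        for s in self.species:
            if s.id == sid:
                return s
        raise NetworkConfigError(f"unknown species {sid!r}")

    def copy(self) -> "ReactionNetwork":
        return copy.deepcopy(self)


def propensity(
    reaction: Reaction,
    state: Mapping[str, float],
    params: Mapping[str, float],
) -> float:
    """Mass-action propensity of ``reaction`` in ``state`` (s^-1).

    Zeroth order returns ``k``; first order ``k*x``; second order with
    distinct reactants ``k*x*y``; homodimerisation ``k*x*(x-1)/2``.
    Returns 0.0 whenever any reactant count is 0.
    """
    try:
        k = params[reaction.rate_constant_name]
    except KeyError:
        raise NetworkConfigError(
            f"reaction {reaction.id!r}: unknown parameter "
            f"{reaction.rate_constant_name!r}"
        ) from None
    n = len(reaction.reactants)
    if n == 0:
        return k
    if n == 1:
        return k * state[reaction.reactants[0]]
    if n == 2:
        a, b = reaction.reactants
        if a == b:
            x = state[a]
            return k * x * (x - 1) / 2.0
        return k * state[a] * state[b]
    raise NetworkConfigError(
        f"reaction {reaction.id!r}: mass action supports at most 2 reactants"
    )


def validate_network(net: ReactionNetwork) -> list[str]:
    """Structural validation; returns a list of human-readable issues.

    Empty list iff: species ids unique, initial counts non-negative, all
    reaction species exist, all rate constants resolve, reactant order
    <= 2, conservation groups are disjoint and reference known species.
    Side-effect free and idempotent.
    """
    issues: list[str] = []
    ids = net.species_ids
    known = set(ids)
    seen: set[str] = set()
    for sid in ids:
        if sid in seen:
            issues.append(f"duplicate species id {sid!r}")
        seen.add(sid)
    for s in net.species:
        if s.initial_amount < 0:
            issues.append(f"species {s.id!r}: negative initial amount")
    rids: set[str] = set()
    for r in net.reactions:
        if r.id in rids:
            issues.append(f"duplicate reaction id {r.id!r}")
        rids.add(r.id)
        if len(r.reactants) > 2:
            issues.append(
                f"reaction {r.id!r}: {len(r.reactants)} reactants exceeds "
                "mass-action order limit of 2"
            )
        for sid in (*r.reactants, *r.products):
            if sid not in known:
                issues.append(f"reaction {r.id!r}: unknown species {sid!r}")
        if r.rate_constant_name not in net.parameters:
            issues.append(
                f"reaction {r.id!r}: unresolved rate constant "
                f"{r.rate_constant_name!r}"
            )
    for pname, val in net.parameters.items():
        if val < 0:
            issues.append(f"parameter {pname!r}: negative value {val}")
    used: set[str] = set()
    init = {s.id: s.initial_amount for s in net.species}
    for group in net.conserved_groups:
        for sid in group:
            if sid not in known:
                issues.append(f"conserved group references unknown {sid!r}")
            elif sid in used:
                issues.append(
                    f"conserved groups not disjoint: {sid!r} appears twice"
                )
            used.add(sid)
        members = [s for s in net.species if s.id in group]
        total = sum(init.get(sid, 0) for sid in group)
        if members and all(s.is_gene_state for s in members) and total != 1:
            issues.append(
                f"conserved gene-state group {sorted(group)} sums to {total} "
                "at t=0, expected 1 (single-copy gene)"
            )
    for rname, sids in net.readouts.items():
        for sid in sids:
            if sid not in known:
                issues.append(f"readout {rname!r}: unknown species {sid!r}")
    return issues


def apply_overrides(
    net: ReactionNetwork,
    overrides: Mapping[str, float] | None,
) -> ReactionNetwork:
    """Deep copy of ``net`` with parameter / initial-amount overrides.

    Each key must name an existing parameter (value replaces the rate
    constant) or an existing species (value replaces the initial
    amount).  The original network is never modified.
    """
    out = net.copy()
    if not overrides:
        return out
    sidx = {s.id: i for i, s in enumerate(out.species)}
    unknown = [
        k for k in overrides if k not in out.parameters and k not in sidx
    ]
    if unknown:
        raise NetworkConfigError(
            f"unknown override keys {sorted(unknown)} for model {net.name!r}"
        )
    for key, val in overrides.items():
        if key in out.parameters:
            out.parameters[key] = float(val)
        else:
            i = sidx[key]
            old = out.species[i]
            out.species[i] = Species(
                old.id, old.description, int(round(val)), old.is_gene_state
            )
    return out
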