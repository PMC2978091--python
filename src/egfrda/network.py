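"""Reaction-network core: species, reactions, parameters, observables.

A :class:`ReactionNetwork` is a validated container for a biochemical
reaction system with mass-action and Michaelis-Menten kinetics.  Species
carry an explicit molecular composition (which base molecules, with which
modifications, make up each complex), so observables ("sigma-states":
sums over all species containing, say, phospho-EGFR) and per-molecule
mass balances can be derived mechanically instead of being maintained by
hand.

Concentrations are in arbitrary units (au); time is in minutes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

SCHEMA_VERSION = 1

COMPARTMENTS = ("EX", "PM", "EN", "LY", "CY")

RATE_LAWS = ("mass_action_irreversible", "mass_action_reversible", "michaelis_menten")

PARAM_ROLES = ("rate_constant", "initial_abundance", "michaelis_constant")

PARAM_GROUPS = (
    "binding",
    "dissociation",
    "phosphorylation",
    "dephosphorylation",
    "internalization",
    "ubiquitination",
    "deubiquitination",
    "degradation",
    "abundance",
    "other",
)


class NetworkValidationError(ValueError):
    """A network refers to undeclared species/parameters or breaks an invariant."""


@dataclass(frozen=True)
class Component:
    """One base molecule inside a (possibly complexed) species, with its
    modification state (``p`` = tyrosine phosphorylation, ``ub`` =
    ubiquitination, ``pt`` = Ser/Thr phosphorylation, ``active`` =
    non-covalent activation)."""

    base: str
    mods: frozenset = frozenset()

    def to_dict(self):
        return {"base": self.base, "mods": sorted(self.mods)}

    @classmethod
    def from_dict(cls, d):
        return cls(d["base"], frozenset(d["mods"]))


@dataclass(frozen=True)
class Species:
    id: str
    compartment: str
    components: tuple = ()

    def __post_init__(self):
        if self.compartment not in COMPARTMENTS:
            raise NetworkValidationError(
                f"species {self.id}: unknown compartment {self.compartment!r}"
            )
        if self.compartment == "EX":
            for c in self.components:
                if c.mods & {"p", "ub"}:
                    raise NetworkValidationError(
                        f"species {self.id}: extracellular species may not carry p/ub"
                    )

    @property
    def base_molecules(self):
        return [c.base for c in self.components]

    def count(self, base, mods=None):
        """Number of copies of ``base`` in this species, optionally requiring
        the given modifications to be present."""
        n = 0
        for c in self.components:
            if c.base == base and (mods is None or set(mods) <= c.mods):
                n += 1
        return n

    def to_dict(self):
        return {
            "id": self.id,
            "compartment": self.compartment,
            "components": [c.to_dict() for c in self.components],
        }

    @classmethod
    def from_dict(cls, d):
        return cls(
            d["id"],
            d["compartment"],
            tuple(Component.from_dict(c) for c in d["components"]),
        )


@dataclass(frozen=True)
class Parameter:
    id: str
    value: float
    role: str = "rate_constant"
    group: str = "other"
    wt_optimized: bool = True
    mutant_variable: bool = False

    def __post_init__(self):
        if self.role not in PARAM_ROLES:
            raise NetworkValidationError(f"parameter {self.id}: bad role {self.role!r}")
        if self.group not in PARAM_GROUPS:
            raise NetworkValidationError(f"parameter {self.id}: bad group {self.group!r}")
        if self.role == "initial_abundance":
            if self.value < 0:
                raise NetworkValidationError(f"parameter {self.id}: abundance < 0")
        elif self.value <= 0:
            raise NetworkValidationError(f"parameter {self.id}: value must be > 0")
        if self.mutant_variable and not self.wt_optimized:
            raise NetworkValidationError(
                f"parameter {self.id}: mutant-variable parameters are a subset "
                "of the WT-optimized set"
            )

    def to_dict(self):
        return {
            "id": self.id,
            "value": self.value,
            "role": self.role,
            "group": self.group,
            "wt_optimized": self.wt_optimized,
            "mutant_variable": self.mutant_variable,
        }

    @classmethod
    def from_dict(cls, d):
        return cls(**d)


@dataclass(frozen=True)
class Reaction:
    """reactants/products map species id -> stoichiometry (>= 1); modifiers
    are catalysts that enter the rate law (their concentrations are summed)
    but are not consumed."""

    id: str
    reactants: dict
    products: dict
    rate_law: str
    parameters: tuple
    modifiers: tuple = ()

    def __post_init__(self):
        if self.rate_law not in RATE_LAWS:
            raise NetworkValidationError(f"reaction {self.id}: bad rate law {self.rate_law!r}")
        for sto in list(self.reactants.values()) + list(self.products.values()):
            if int(sto) != sto or sto < 1:
                raise NetworkValidationError(
                    f"reaction {self.id}: stoichiometries must be positive integers"
                )
        n = len(self.parameters)
        need = {"mass_action_irreversible": 1, "mass_action_reversible": 2, "michaelis_menten": 2}
        if n != need[self.rate_law]:
            raise NetworkValidationError(
                f"reaction {self.id}: {self.rate_law} needs {need[self.rate_law]} "
                f"parameters, got {n}"
            )
        if self.rate_law == "michaelis_menten" and len(self.reactants) != 1:
            raise NetworkValidationError(
                f"reaction {self.id}: Michaelis-Menten requires a single substrate"
            )

    @property
    def reversible(self):
        return self.rate_law == "mass_action_reversible"

    def to_dict(self):
        return {
            "id": self.id,
            "reactants": dict(self.reactants),
            "products": dict(self.products),
            "rate_law": self.rate_law,
            "parameters": list(self.parameters),
            "modifiers": list(self.modifiers),
        }

    @classmethod
    def from_dict(cls, d):
        return cls(
            d["id"],
            dict(d["reactants"]),
            dict(d["products"]),
            d["rate_law"],
            tuple(d["parameters"]),
            tuple(d["modifiers"]),
        )


@dataclass(frozen=True)
class Observable:
    """A sigma-state: weighted sum of member species concentrations."""

    name: str
    members: tuple
    weights: tuple = None

    def __post_init__(self):
        if not self.members:
            raise NetworkValidationError(f"observable {self.name}: empty member list")
        if self.weights is None:
            object.__setattr__(self, "weights", tuple(1.0 for _ in self.members))
        if len(self.weights) != len(self.members):
            raise NetworkValidationError(f"observable {self.name}: weight/member mismatch")
        if any(w < 0 for w in self.weights):
            raise NetworkValidationError(f"observable {self.name}: negative weight")

    def to_dict(self):
        return {"name": self.name, "members": list(self.members), "weights": list(self.weights)}

    @classmethod
    def from_dict(cls, d):
        return cls(d["name"], tuple(d["members"]), tuple(d["weights"]))


class ParameterSet(dict):
    """A named positive parameter vector (parameter id -> value).

    Behaves as a plain dict; helpers convert to/from the ordered vector a
    compiled network expects.
    """

    def copy(self):
        return ParameterSet(self)

    def with_updates(self, updates):
        out = ParameterSet(self)
        out.update(updates)
        return out


@dataclass
class ReactionNetwork:
    name: str
    species: dict = field(default_factory=dict)  # id -> Species
    reactions: dict = field(default_factory=dict)  # id -> Reaction
    parameters: dict = field(default_factory=dict)  # id -> Parameter
    observables: dict = field(default_factory=dict)  # name -> Observable
    initial_abundance: dict = field(default_factory=dict)  # species id -> param id
    _compiled: object = field(default=None, repr=False, compare=False)

    # -- construction helpers -------------------------------------------------

    def add_species(self, sp: Species):
        if sp.id in self.species:
            raise NetworkValidationError(f"duplicate species id {sp.id}")
        self.species[sp.id] = sp
        return sp

    def add_parameter(self, p: Parameter):
        if p.id in self.parameters:
            raise NetworkValidationError(f"duplicate parameter id {p.id}")
        self.parameters[p.id] = p
        return p

    def add_reaction(self, r: Reaction):
        if r.id in self.reactions:
            raise NetworkValidationError(f"duplicate reaction id {r.id}")
        self.reactions[r.id] = r
        self._compiled = None
        return r

    def add_observable(self, o: Observable):
        self.observables[o.name] = o
        return o

    # -- queries --------------------------------------------------------------

    @property
    def species_ids(self):
        return list(self.species)

    @property
    def parameter_ids(self):
        return list(self.parameters)

    def parameter_subset(self, *, group=None, mutant_variable=None, wt_optimized=None,
                         exclude_groups=()):
        """Parameter ids filtered by group tag / optimization flags."""
        out = []
        for p in self.parameters.values():
            if group is not None and p.group != group:
                continue
            if p.group in exclude_groups:
                continue
            if mutant_variable is not None and p.mutant_variable != mutant_variable:
                continue
            if wt_optimized is not None and p.wt_optimized != wt_optimized:
                continue
            out.append(p.id)
        return out

    def default_parameters(self) -> ParameterSet:
        return ParameterSet({p.id: p.value for p in self.parameters.values()})

    def base_molecules(self):
        bases = []
        for sp in self.species.values():
            for b in sp.base_molecules:
                if b not in bases:
                    bases.append(b)
        return bases

    # -- validation -----------------------------------------------------------

    def validate(self):
        for r in self.reactions.values():
            for sid in list(r.reactants) + list(r.products) + list(r.modifiers):
                if sid not in self.species:
                    raise NetworkValidationError(
                        f"reaction {r.id}: unknown species {sid!r}"
                    )
            for pid in r.parameters:
                if pid not in self.parameters:
                    raise NetworkValidationError(
                        f"reaction {r.id}: unknown parameter {pid!r}"
                    )
        for o in self.observables.values():
            for sid in o.members:
                if sid not in self.species:
                    raise NetworkValidationError(
                        f"observable {o.name}: unknown species {sid!r}"
                    )
        for sid, pid in self.initial_abundance.items():
            if sid not in self.species:
                raise NetworkValidationError(f"initial abundance for unknown species {sid!r}")
            if pid not in self.parameters:
                raise NetworkValidationError(f"initial abundance references unknown parameter {pid!r}")
        return self

    # -- serialization --------------------------------------------------------

    def to_dict(self):
        return {
            "schema_version": SCHEMA_VERSION,
            "name": self.name,
            "species": [s.to_dict() for s in self.species.values()],
            "reactions": [r.to_dict() for r in self.reactions.values()],
            "parameters": [p.to_dict() for p in self.parameters.values()],
            "observables": [o.to_dict() for o in self.observables.values()],
            "initial_abundance": dict(self.initial_abundance),
        }

    @classmethod
    def from_dict(cls, d):
        version = d.get("schema_version")
        if version != SCHEMA_VERSION:
            raise NetworkValidationError(
                f"unknown model schema version {version!r} (expected {SCHEMA_VERSION})"
            )
        net = cls(name=d["name"])
        for s in d["species"]:
            net.add_species(Species.from_dict(s))
        for p in d["parameters"]:
            net.add_parameter(Parameter.from_dict(p))
        for r in d["reactions"]:
            net.add_reaction(Reaction.from_dict(r))
        for o in d["observables"]:
            net.add_observable(Observable.from_dict(o))
        net.initial_abundance = dict(d["initial_abundance"])
        return net.validate()

    def structurally_equal(self, other) -> bool:
        return self.to_dict() == other.to_dict()

    # -- compilation ----------------------------------------------------------

    def compiled(self):
        if self._compiled is None:
            from .simulate import compile_network

            self._compiled = compile_network(self.validate())
        return self._compiled

    def param_vector(self, params: ParameterSet) -> np.ndarray:
        order = self.compiled().param_order
        try:
            return np.array([params[p] for p in order], dtype=float)
        except KeyError as e:  # pragma: no cover - defensive
            raise KeyError(f"parameter set missing {e.args[0]!r}") from None
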