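"""Network data model, rule grammar, and tabular model-file I/O.

A model is two tables.  The species table declares each node with its time
constant ``tau``, maximal fractional activation ``Ymax``, initial value
``y0`` and a role: *input* species are clamped algebraic signals driven by a
stimulus schedule, *state* species obey the logic ODEs.

The reaction table holds weighted logic rules of the form::

    A & !B => C        # A AND (NOT B) drives C
    NE => B1AR         # single activator
    => PDE             # empty left side: constant (constitutive) source

Each reaction carries a weight ``W`` in [0, 1] and its own Hill parameters
``n`` and ``EC50`` (defaults 1, 1.4, 0.5).  Multiple reactions converging on
one target are OR-combined, except that a reaction whose terms are *all*
negated acts as a multiplicative brake on the target's total drive (an
OR-combined inhibitor could only ever raise activity).
"""

from __future__ import annotations

import dataclasses
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .kernels import KernelKind, solve_bk

__all__ = [
    "SpeciesSpec",
    "ReactionSpec",
    "NetworkModel",
    "RuleSyntaxError",
    "ModelValidationError",
    "parse_rule",
    "format_rule",
    "load_model",
    "write_model",
    "knockout",
]

_IDENT = re.compile(r"[A-Za-z][A-Za-z0-9_]*")

DEFAULT_TAU = 1.0
DEFAULT_YMAX = 1.0
DEFAULT_Y0 = 0.0
DEFAULT_WEIGHT = 1.0
DEFAULT_N = 1.4
DEFAULT_EC50 = 0.5

SPECIES_COLUMNS = ["name", "role", "tau", "Ymax", "y0"]
REACTION_COLUMNS = ["id", "rule", "weight", "n", "EC50"]


class RuleSyntaxError(ValueError):
    """Malformed rule text; carries the character position of the fault."""

    def __init__(self, message: str, text: str, pos: int):
        super().__init__(f"{message} at position {pos} in rule {text!r}")
        self.text = text
        self.pos = pos


class ModelValidationError(ValueError):
    """A structurally invalid model (bad reference, range or duplicate)."""


@dataclass(frozen=True)
class SpeciesSpec:
    """One network node.

    ``tau`` is the first-order relaxation time constant (model time units),
    ``Ymax`` the maximal fractional activation (1 = reference expression;
    below/above 1 models knock-down/overexpression), ``y0`` the initial
    fractional activation, and ``role`` is ``"input"`` or ``"state"``.
    """

    name: str
    role: str = "state"
    tau: float = DEFAULT_TAU
    Ymax: float = DEFAULT_YMAX
    y0: float = DEFAULT_Y0


@dataclass(frozen=True)
class ReactionSpec:
    """One weighted logic rule.

    ``activators``/``inhibitors`` are the plain and negated terms of the
    left-hand side in source order; an empty left side makes the reaction a
    constant source contributing ``weight`` to the target's drive.
    """

    id: str
    target: str
    activators: tuple[str, ...] = ()
    inhibitors: tuple[str, ...] = ()
    terms: tuple[tuple[str, bool], ...] = ()  # (name, negated), source order
    weight: float = DEFAULT_WEIGHT
    n: float = DEFAULT_N
    EC50: float = DEFAULT_EC50

    @property
    def rule(self) -> str:
        return format_rule(self)

    @property
    def is_source(self) -> bool:
        return not self.terms

    @property
    def is_pure_inhibitory(self) -> bool:
        return bool(self.terms) and all(neg for _, neg in self.terms)


def parse_rule(text: str) -> tuple[tuple[str, bool], ...]:
    """Parse a rule string into ((name, negated), ..., target).

    Grammar: ``rule := [term ("&" term)*] "=>" identifier`` with
    ``term := ["!"] identifier``.  Returns a tuple whose last element is the
    target name and whose preceding elements are (species, negated) pairs.
    """
    arrow = text.find("=>")
    if arrow < 0:
        raise RuleSyntaxError("missing '=>'", text, len(text))
    lhs, rhs = text[:arrow], text[arrow + 2 :]

    m = _IDENT.fullmatch(rhs.strip())
    if m is None:
        raise RuleSyntaxError("target is not a valid identifier", text, arrow + 2)
    target = m.group(0)

    terms: list[tuple[str, bool]] = []
    if lhs.strip():
        offset = 0
        for chunk in lhs.split("&"):
            stripped = chunk.strip()
            pos = offset + chunk.index(stripped[0]) if stripped else offset
            if not stripped:
                raise RuleSyntaxError("empty term", text, pos)
            negated = stripped.startswith("!")
            name = stripped[1:].strip() if negated else stripped
            if _IDENT.fullmatch(name) is None:
                raise RuleSyntaxError(f"bad term {stripped!r}", text, pos)
            terms.append((name, negated))
            offset += len(chunk) + 1
    return (*terms, target)


def format_rule(rxn: ReactionSpec) -> str:
    """Canonical text of a reaction; parse(format(r)) round-trips."""
    lhs = " & ".join(("!" if neg else "") + name for name, neg in rxn.terms)
    return f"{lhs} => {rxn.target}" if lhs else f"=> {rxn.target}"


def make_reaction(
    id: str,
    rule: str,
    weight: float = DEFAULT_WEIGHT,
    n: float = DEFAULT_N,
    ec50: float = DEFAULT_EC50,
) -> ReactionSpec:
    """Build a ReactionSpec from rule text."""
    *terms, target = parse_rule(rule)
    return ReactionSpec(
        id=id,
        target=target,
        activators=tuple(name for name, neg in terms if not neg),
        inhibitors=tuple(name for name, neg in terms if neg),
        terms=tuple(terms),
        weight=weight,
        n=n,
        EC50=ec50,
    )


@dataclass
class NetworkModel:
    """A validated logic network: ordered species + ordered reactions.

    ``sensitivity_set`` lists the species perturbed/measured in
    all-against-all sensitivity analysis (default: every species).
    ``kernel`` selects the scalar activation kernel for the whole model.
    """

    species: tuple[SpeciesSpec, ...]
    reactions: tuple[ReactionSpec, ...]
    sensitivity_set: tuple[str, ...] = ()
    kernel: KernelKind = field(default_factory=KernelKind)
    name: str = "model"

    def __post_init__(self) -> None:
        self.species = tuple(self.species)
        self.reactions = tuple(self.reactions)
        if not self.sensitivity_set:
            self.sensitivity_set = tuple(s.name for s in self.species)
        else:
            self.sensitivity_set = tuple(self.sensitivity_set)
        self.validate()

    # -- lookups ---------------------------------------------------------
    @property
    def species_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.species)

    @property
    def input_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.species if s.role == "input")

    @property
    def state_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.species if s.role == "state")

    def get_species(self, name: str) -> SpeciesSpec:
        for s in self.species:
            if s.name == name:
                return s
        raise KeyError(f"unknown species {name!r}")

    def get_reaction(self, rid: str) -> ReactionSpec:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(f"unknown reaction id {rid!r}")

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ModelValidationError(f"duplicate species names: {dupes}")
        roles = {s.name: s.role for s in self.species}
        for s in self.species:
            if _IDENT.fullmatch(s.name) is None:
                raise ModelValidationError(f"invalid species name {s.name!r}")
            if s.role not in ("input", "state"):
                raise ModelValidationError(f"{s.name}: role must be input or state")
            if not s.tau > 0:
                raise ModelValidationError(f"{s.name}: tau must be > 0, got {s.tau}")
            if s.Ymax < 0:
                raise ModelValidationError(f"{s.name}: Ymax must be >= 0, got {s.Ymax}")
            if not 0 <= s.y0 <= max(s.Ymax, 0):
                raise ModelValidationError(f"{s.name}: y0 must lie in [0, Ymax]")
        rids = [r.id for r in self.reactions]
        if len(set(rids)) != len(rids):
            dupes = sorted({i for i in rids if rids.count(i) > 1})
            raise ModelValidationError(f"duplicate reaction ids: {dupes}")
        for r in self.reactions:
            for name, _ in (*r.terms, (r.target, False)):
                if name not in roles:
                    raise ModelValidationError(
                        f"reaction {r.id}: unknown species {name!r}"
                    )
            if roles[r.target] != "state":
                raise ModelValidationError(
                    f"reaction {r.id}: target {r.target} is an input species"
                )
            if not 0.0 <= r.weight <= 1.0:
                raise ModelValidationError(
                    f"reaction {r.id}: weight {r.weight} outside [0, 1]"
                )
            if self.kernel.tag == "normalized_hill" and r.terms:
                solve_bk(r.n, r.EC50)  # raises for invalid (n, EC50)
        for name in self.sensitivity_set:
            if name not in roles:
                raise ModelValidationError(f"sensitivity_set: unknown species {name!r}")

    # -- copies ----------------------------------------------------------
    def with_reactions(self, reactions: Iterable[ReactionSpec]) -> "NetworkModel":
        return dataclasses.replace(self, reactions=tuple(reactions))

    def with_species(self, species: Iterable[SpeciesSpec]) -> "NetworkModel":
        return dataclasses.replace(self, species=tuple(species))

    def with_kernel(self, kernel: KernelKind) -> "NetworkModel":
        return dataclasses.replace(self, kernel=kernel)

    def with_defaults(self, n: float | None = None, ec50: float | None = None) -> "NetworkModel":
        """Copy with every reaction's n and/or EC50 replaced."""
        new = []
        for r in self.reactions:
            kw = {}
            if n is not None:
                kw["n"] = n
            if ec50 is not None:
                kw["EC50"] = ec50
            new.append(replace(r, **kw))
        return self.with_reactions(new)


def knockout(model: NetworkModel, reaction_id: str) -> NetworkModel:
    """Copy of ``model`` with one reaction's weight set to zero."""
    rxn = model.get_reaction(reaction_id)  # raises KeyError if unknown
    return model.with_reactions(
        replace(r, weight=0.0) if r.id == rxn.id else r for r in model.reactions
    )


# ---------------------------------------------------------------------------
# tabular I/O
# ---------------------------------------------------------------------------

def _read_table(path, columns: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#", sep=None, engine="python", skipinitialspace=True)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ModelValidationError(f"{path}: missing column(s) {missing}")
    return df


def _cell(row, col, default):
    v = row[col]
    return default if pd.isna(v) else v


def load_model(species_table, reaction_table, name: str = "model") -> NetworkModel:
    """Load and validate a model from species and reaction tables.

    Both files are CSV or TSV (delimiter sniffed), UTF-8, with ``#`` comment
    lines ignored and blank cells replaced by the documented defaults.
    Species order in the file fixes the model's species order.
    """
    sdf = _read_table(species_table, SPECIES_COLUMNS)
    species = tuple(
        SpeciesSpec(
            name=str(row["name"]).strip(),
            role=str(_cell(row, "role", "state")).strip(),
            tau=float(_cell(row, "tau", DEFAULT_TAU)),
            Ymax=float(_cell(row, "Ymax", DEFAULT_YMAX)),
            y0=float(_cell(row, "y0", DEFAULT_Y0)),
        )
        for _, row in sdf.iterrows()
    )
    rdf = _read_table(reaction_table, REACTION_COLUMNS)
    reactions = tuple(
        make_reaction(
            id=str(row["id"]).strip(),
            rule=str(row["rule"]).strip(),
            weight=float(_cell(row, "weight", DEFAULT_WEIGHT)),
            n=float(_cell(row, "n", DEFAULT_N)),
            ec50=float(_cell(row, "EC50", DEFAULT_EC50)),
        )
        for _, row in rdf.iterrows()
    )
    return NetworkModel(species=species, reactions=reactions, name=name)


def write_model(model: NetworkModel, species_table, reaction_table) -> None:
    """Write a model back to the two-table format (column order fixed)."""
    sdf = pd.DataFrame(
        [
            {"name": s.name, "role": s.role, "tau": s.tau, "Ymax": s.Ymax, "y0": s.y0}
            for s in model.species
        ],
        columns=SPECIES_COLUMNS,
    )
    rdf = pd.DataFrame(
        [
            {"id": r.id, "rule": r.rule, "weight": r.weight, "n": r.n, "EC50": r.EC50}
            for r in model.reactions
        ],
        columns=REACTION_COLUMNS,
    )
    sdf.to_csv(species_table, index=False)
    rdf.to_csv(reaction_table, index=False)
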