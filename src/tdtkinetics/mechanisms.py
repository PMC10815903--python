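"""Kinetic schemes of template-independent nucleotide incorporation by TdT.

Terminal deoxynucleotidyl transferase (TdT) binds an incoming (d)dNTP in two
sequential steps — an initial encounter complex followed by a conformational
adjustment of the active site — before the chemistry step attaches the
nucleotide to the single-stranded primer 3' end.  This module provides a
declarative representation of the three minimal mechanisms used throughout
the package:

* ``scheme1`` — ddNTP incorporation into a pre-formed enzyme–primer complex:
  two reversible binding stages, one irreversible chemistry step (``kpol``),
  and a second *binding-only* cycle on the extended primer (dideoxy termini
  cannot be extended further).
* ``scheme2`` — dNTP binding by the free enzyme (no primer): the two
  reversible binding stages alone.
* ``scheme3`` — multi-turnover incorporation of a fluorescent dNTP analogue:
  two binding stages, chemistry (``kpol``), a first-order transformation of
  the post-catalytic complex (``kt``), and an identical second cycle on the
  once-extended primer.

Mechanisms compile to mass-action ODE right-hand sides with analytic
Jacobians.  Conservation of enzyme, primer and nucleotide moieties is kept
explicit so that it can be verified analytically, independently of any
ODE solver.

Units are fixed at µM and s: unimolecular rate constants in s⁻¹,
bimolecular in µM⁻¹ s⁻¹.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Species",
    "Reaction",
    "Mechanism",
    "RateParameters",
    "EquilibriumSummary",
    "MissingRateError",
    "UndefinedEquilibriumError",
    "build_scheme",
    "derive_rhs",
    "conserved_moieties",
    "equilibrium_summary",
    "CompiledMechanism",
]

MOIETIES = ("enzyme", "primer", "nucleotide")

SCHEME_NAMES = ("scheme1", "scheme2", "scheme3")


class MissingRateError(KeyError):
    """A reaction references a rate constant that the parameter set lacks."""


class UndefinedEquilibriumError(ValueError):
    """Equilibrium constants are undefined (a reverse rate constant is zero)."""


@dataclass(frozen=True)
class Species:
    """One chemical species of a mechanism.

    ``composition`` counts how many enzyme, primer and nucleotide moieties the
    species carries (e.g. a ternary complex is {enzyme: 1, primer: 1,
    nucleotide: 1}).  ``n_incorporated`` counts nucleotides covalently
    attached to the primer — the quantity read out by quench-flow gels.
    """

    name: str
    role: str  # enzyme | enzyme_primer | nucleotide | complex | product_complex
    label: str = ""
    composition: Mapping[str, int] = field(default_factory=dict)
    n_incorporated: int = 0


@dataclass(frozen=True)
class Reaction:
    """An elementary (at most bimolecular) reaction step.

    ``k_fwd``/``k_rev`` are *names* of rate constants, resolved against a
    :class:`RateParameters` at compile time; ``k_rev=None`` marks an
    irreversible step.
    """

    reactants: tuple[str, ...]
    products: tuple[str, ...]
    k_fwd: str
    k_rev: str | None = None

    def __post_init__(self) -> None:
        if not 1 <= len(self.reactants) <= 2 or not 1 <= len(self.products) <= 2:
            raise ValueError("reactions must be at most bimolecular on each side")


@dataclass(frozen=True)
class RateParameters:
    """Per-scheme rate constants (µM⁻¹s⁻¹ for k1; s⁻¹ otherwise).

    ``kpol`` is the irreversible chemistry step (absent for the binding-only
    scheme2); ``kt`` the post-catalytic transformation of scheme3.  ``extra``
    holds optional independent second-cycle constants (``k1_2``, ...).
    """

    k1: float
    k_minus1: float
    k2: float
    k_minus2: float
    kpol: float | None = None
    kt: float | None = None
    extra: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("k1", "k_minus1", "k2", "k_minus2", "kpol", "kt"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"rate constant {name} must be >= 0, got {v}")
        for name, v in self.extra.items():
            if v < 0:
                raise ValueError(f"rate constant {name} must be >= 0, got {v}")

    def get(self, name: str) -> float:
        if name in self.extra:
            return float(self.extra[name])
        v = getattr(self, name, None)
        if v is None:
            raise MissingRateError(
                f"rate constant {name!r} is required by the mechanism but absent "
                "from the parameter set"
            )
        return float(v)


@dataclass(frozen=True)
class EquilibriumSummary:
    """Stepwise equilibrium constants and the overall dissociation constant."""

    K1: float  # µM⁻¹, association constant of the encounter complex
    K2: float  # dimensionless, equilibrium of the conformational adjustment
    Kd_total: float  # µM


@dataclass
class Mechanism:
    """A named reaction network (species + reactions)."""

    name: str
    species: list[Species]
    reactions: list[Reaction]
    options: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            raise ValueError("species names must be unique within a mechanism")
        declared = set(names)
        for r in self.reactions:
            for n in (*r.reactants, *r.products):
                if n not in declared:
                    raise ValueError(f"reaction references undeclared species {n!r}")

    @property
    def species_names(self) -> list[str]:
        return [s.name for s in self.species]

    def index(self, name: str) -> int:
        return self.species_names.index(name)

    def rate_names(self) -> list[str]:
        names: list[str] = []
        for r in self.reactions:
            for n in (r.k_fwd, r.k_rev):
                if n is not None and n not in names:
                    names.append(n)
        return names

    # -- plain-text config round-trip ------------------------------------
    def to_config(self) -> dict:
        if self.name in SCHEME_NAMES:
            return {"scheme": self.name, "options": dict(self.options)}
        return {
            "scheme": "custom",
            "name": self.name,
            "species": [
                {
                    "name": s.name,
                    "role": s.role,
                    "label": s.label,
                    "composition": dict(s.composition),
                    "n_incorporated": s.n_incorporated,
                }
                for s in self.species
            ],
            "reactions": [
                {
                    "reactants": list(r.reactants),
                    "products": list(r.products),
                    "k_fwd": r.k_fwd,
                    "k_rev": r.k_rev,
                }
                for r in self.reactions
            ],
        }

    @classmethod
    def from_config(cls, cfg: Mapping) -> "Mechanism":
        scheme = cfg["scheme"]
        if scheme in SCHEME_NAMES:
            return build_scheme(scheme, **cfg.get("options", {}))
        species = [
            Species(
                name=s["name"],
                role=s["role"],
                label=s.get("label", ""),
                composition=dict(s.get("composition", {})),
                n_incorporated=int(s.get("n_incorporated", 0)),
            )
            for s in cfg["species"]
        ]
        reactions = [
            Reaction(
                reactants=tuple(r["reactants"]),
                products=tuple(r["products"]),
                k_fwd=r["k_fwd"],
                k_rev=r.get("k_rev"),
            )
            for r in cfg["reactions"]
        ]
        return cls(name=cfg.get("name", "custom"), species=species, reactions=reactions)


# ---------------------------------------------------------------------------
# scheme construction
# ---------------------------------------------------------------------------


def _sp(name: str, role: str, label: str, e: int, p: int, n: int, inc: int = 0) -> Species:
    return Species(
        name=name,
        role=role,
        label=label,
        composition={"enzyme": e, "primer": p, "nucleotide": n},
        n_incorporated=inc,
    )


def build_scheme(
    name: str,
    *,
    second_cycle: bool = True,
    second_cycle_conformational: bool = False,
    shared_second_cycle: bool = True,
) -> Mechanism:
    """Construct one of the built-in TdT mechanisms.

    Parameters
    ----------
    name:
        ``scheme1`` (ddNTP single incorporation), ``scheme2`` (primer-free
        binding) or ``scheme3`` (processive analogue incorporation).
    second_cycle:
        Include the second nucleotide-binding cycle on the extended primer
        (schemes 1 and 3; ignored for scheme2).
    second_cycle_conformational:
        For scheme1 only: also include the conformational (second) binding
        stage in the second cycle.
    shared_second_cycle:
        Reuse cycle-1 rate constants in cycle 2 (default).  When False, the
        cycle-2 steps use independent constants named ``k1_2``, ``k_minus1_2``
        (and ``k2_2``, ``k_minus2_2``, ``kpol_2``, ``kt_2`` where relevant),
        supplied through :attr:`RateParameters.extra`.
    """
    if name not in SCHEME_NAMES:
        raise ValueError(
            f"unknown scheme {name!r}; valid schemes are: {', '.join(SCHEME_NAMES)}"
        )
    suffix = "" if shared_second_cycle else "_2"

    def c2name(base: str) -> str:
        return base + suffix

    options = {
        "second_cycle": second_cycle,
        "second_cycle_conformational": second_cycle_conformational,
        "shared_second_cycle": shared_second_cycle,
    }

    if name == "scheme2":
        species = [
            _sp("E", "enzyme", "E", 1, 0, 0),
            _sp("N", "nucleotide", "dNTP", 0, 0, 1),
            _sp("X1", "complex", "E·dNTP (1)", 1, 0, 1),
            _sp("X2", "complex", "E·dNTP (2)", 1, 0, 1),
        ]
        reactions = [
            Reaction(("E", "N"), ("X1",), "k1", "k_minus1"),
            Reaction(("X1",), ("X2",), "k2", "k_minus2"),
        ]
        return Mechanism("scheme2", species, reactions, {})

    if name == "scheme1":
        species = [
            _sp("ED", "enzyme_primer", "E·DNA", 1, 1, 0),
            _sp("N", "nucleotide", "ddNTP", 0, 0, 1),
            _sp("C1", "complex", "E·DNA·ddNTP (1)", 1, 1, 1),
            _sp("C2", "complex", "E·DNA·ddNTP (2)", 1, 1, 1),
            _sp("ED1", "product_complex", "E·DNA+1", 1, 1, 1, inc=1),
        ]
        reactions = [
            Reaction(("ED", "N"), ("C1",), "k1", "k_minus1"),
            Reaction(("C1",), ("C2",), "k2", "k_minus2"),
            Reaction(("C2",), ("ED1",), "kpol"),
        ]
        if second_cycle:
            species.append(_sp("C1b", "complex", "E·DNA+1·ddNTP (1)", 1, 1, 2, inc=1))
            reactions.append(
                Reaction(("ED1", "N"), ("C1b",), c2name("k1"), c2name("k_minus1"))
            )
            if second_cycle_conformational:
                species.append(
                    _sp("C2b", "complex", "E·DNA+1·ddNTP (2)", 1, 1, 2, inc=1)
                )
                reactions.append(
                    Reaction(("C1b",), ("C2b",), c2name("k2"), c2name("k_minus2"))
                )
        return Mechanism("scheme1", species, reactions, options)

    # scheme3
    species = [
        _sp("ED", "enzyme_primer", "E·DNA", 1, 1, 0),
        _sp("N", "nucleotide", "dNTP*", 0, 0, 1),
        _sp("C1", "complex", "E·DNA·dNTP* (1)", 1, 1, 1),
        _sp("C2", "complex", "E·DNA·dNTP* (2)", 1, 1, 1),
        _sp("P1", "product_complex", "post-catalytic E·DNA+1", 1, 1, 1, inc=1),
        _sp("ED1", "product_complex", "E·DNA+1", 1, 1, 1, inc=1),
    ]
    reactions = [
        Reaction(("ED", "N"), ("C1",), "k1", "k_minus1"),
        Reaction(("C1",), ("C2",), "k2", "k_minus2"),
        Reaction(("C2",), ("P1",), "kpol"),
        Reaction(("P1",), ("ED1",), "kt"),
    ]
    if second_cycle:
        species += [
            _sp("C1b", "complex", "E·DNA+1·dNTP* (1)", 1, 1, 2, inc=1),
            _sp("C2b", "complex", "E·DNA+1·dNTP* (2)", 1, 1, 2, inc=1),
            _sp("P2", "product_complex", "post-catalytic E·DNA+2", 1, 1, 2, inc=2),
            _sp("ED2", "product_complex", "E·DNA+2", 1, 1, 2, inc=2),
        ]
        reactions += [
            Reaction(("ED1", "N"), ("C1b",), c2name("k1"), c2name("k_minus1")),
            Reaction(("C1b",), ("C2b",), c2name("k2"), c2name("k_minus2")),
            Reaction(("C2b",), ("P2",), c2name("kpol")),
            Reaction(("P2",), ("ED2",), c2name("kt")),
        ]
    return Mechanism("scheme3", species, reactions, options)


# ---------------------------------------------------------------------------
# compilation to mass-action ODEs
# ---------------------------------------------------------------------------


class CompiledMechanism:
    """Mass-action right-hand side and Jacobian for a parameterised mechanism.

    Callable as ``f(c, t) -> dc/dt``; also exposes solve_ivp-style
    ``rhs_ivp(t, c)`` and ``jac_ivp(t, c)``.
    """

    def __init__(self, mechanism: Mechanism, params: RateParameters):
        self.mechanism = mechanism
        n = len(mechanism.species)
        idx = {s.name: i for i, s in enumerate(mechanism.species)}
        ks: list[float] = []
        r1: list[int] = []
        r2: list[int] = []  # index n = dummy "concentration 1.0" slot
        stoich_cols: list[np.ndarray] = []
        for r in mechanism.reactions:
            directions = [(r.reactants, r.products, r.k_fwd)]
            if r.k_rev is not None:
                directions.append((r.products, r.reactants, r.k_rev))
            for reac, prod, kname in directions:
                ks.append(params.get(kname))
                r1.append(idx[reac[0]])
                r2.append(idx[reac[1]] if len(reac) > 1 else n)
                col = np.zeros(n)
                for s in reac:
                    col[idx[s]] -= 1.0
                for s in prod:
                    col[idx[s]] += 1.0
                stoich_cols.append(col)
        self._k = np.array(ks)
        self._r1 = np.array(r1, dtype=int)
        self._r2 = np.array(r2, dtype=int)
        self._S = np.column_stack(stoich_cols) if stoich_cols else np.zeros((n, 0))
        self._n = n
        self._bimol = self._r2 < n

    def __call__(self, c: np.ndarray, t: float = 0.0) -> np.ndarray:
        ce = np.append(c, 1.0)
        flux = self._k * ce[self._r1] * ce[self._r2]
        return self._S @ flux

    def rhs_ivp(self, t: float, c: np.ndarray) -> np.ndarray:
        return self(c, t)

    def jac_ivp(self, t: float, c: np.ndarray) -> np.ndarray:
        ce = np.append(c, 1.0)
        m = self._k.size
        dflux = np.zeros((m, self._n))
        rows = np.arange(m)
        # d(flux)/d(c[r1]) = k * c[r2];  d(flux)/d(c[r2]) = k * c[r1]
        np.add.at(dflux, (rows, self._r1), self._k * ce[self._r2])
        bi = self._bimol
        np.add.at(dflux, (rows[bi], self._r2[bi]), self._k[bi] * ce[self._r1[bi]])
        return self._S @ dflux

    def jac_odeint(self, c: np.ndarray, t: float) -> np.ndarray:
        return self.jac_ivp(t, c)


def derive_rhs(mechanism: Mechanism, params: RateParameters) -> CompiledMechanism:
    """Compile a mechanism + parameter set into a mass-action ODE function.

    Raises :class:`MissingRateError` if a reaction references a rate constant
    that ``params`` does not provide.
    """
    return CompiledMechanism(mechanism, params)


def conserved_moieties(
    mechanism: Mechanism,
) -> list[tuple[str, dict[str, int]]]:
    """Enzyme, primer and nucleotide conservation vectors of a mechanism.

    Each returned weight vector annihilates the stoichiometry of every
    reaction; this is verified here analytically (a violation raises), so the
    invariant does not depend on any ODE solver.
    """
    out: list[tuple[str, dict[str, int]]] = []
    for moiety in MOIETIES:
        weights = {
            s.name: int(s.composition.get(moiety, 0))
            for s in mechanism.species
            if s.composition.get(moiety, 0)
        }
        if not weights:
            continue
        for r in mechanism.reactions:
            lhs = sum(weights.get(s, 0) for s in r.reactants)
            rhs = sum(weights.get(s, 0) for s in r.products)
            if lhs != rhs:
                raise ValueError(
                    f"moiety {moiety!r} is not conserved by reaction "
                    f"{r.reactants} -> {r.products}"
                )
        out.append((moiety, weights))
    return out


def equilibrium_summary(
    params: RateParameters, *, convention: str = "exact"
) -> EquilibriumSummary:
    """Stepwise equilibrium constants and the overall Kd of two-step binding.

    ``convention="exact"`` (default) uses the thermodynamically exact overall
    dissociation constant of sequential two-step binding,
    Kd = 1/(K1·(1+K2)): at equilibrium the bound pool is X1+X2 =
    [E][N]·K1·(1+K2).  ``convention="product"`` instead returns 1/(K1·K2),
    the limit in which only the final complex is counted as bound.
    """
    if params.k_minus1 <= 0 or params.k_minus2 <= 0:
        raise UndefinedEquilibriumError(
            "equilibrium constants are undefined when a reverse rate constant "
            "is zero"
        )
    K1 = params.k1 / params.k_minus1
    K2 = params.k2 / params.k_minus2
    if convention == "exact":
        Kd = 1.0 / (K1 * (1.0 + K2))
    elif convention == "product":
        if K2 == 0:
            raise UndefinedEquilibriumError(
                "the product convention requires K2 > 0"
            )
        Kd = 1.0 / (K1 * K2)
    else:
        raise ValueError(f"unknown Kd convention {convention!r}")
    return EquilibriumSummary(K1=K1, K2=K2, Kd_total=Kd)
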