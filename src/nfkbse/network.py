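"""Mass-action model of the IKK–IκB–NF-κB–A20 signaling network.

The network couples the IκB kinase module (IKKn/IKKa/IKKi), cytoplasmic and
nuclear NF-κB, three IκB isoforms (α, β, ϵ — each with free protein,
nuclear protein, mRNA, NF-κB complexes and IKKa complexes) and the A20
negative regulator.  The reaction list and both rate-constant columns ship
as a TSV resource (``data/rate_constants.tsv``); everything downstream —
the stoichiometry matrix, the ODE right-hand side and the compiled
integrator kernel — is derived from that single table.

Concentrations are in μM and time in seconds: with the tabulated constants
(e.g. total NF-κB 0.06, IKK activation rate ~3e-3 s⁻¹) this calibration
produces the hour-scale nuclear NF-κB oscillations the model is known for.
User-facing trajectory time is reported in hours.

Nucleo-cytoplasmic transport conserves molecule *amounts*, not
concentrations: a flux carrying material into the nucleus multiplies the
nuclear concentration gain by the cytoplasm:nucleus volume ratio Kv, and an
outbound flux divides by it.  Under this convention the volume-weighted
total NF-κB (cytoplasmic NF-κB species plus nuclear NF-κB species / Kv) is
conserved exactly by the right-hand side.
"""

from __future__ import annotations

import importlib.resources
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SPECIES",
    "NUCLEAR_SPECIES",
    "RATE_SYMBOLS",
    "SYMBOLS",
    "KNOCKOUT_GENES",
    "ParameterSet",
    "Genotype",
    "Reaction",
    "ReactionNetwork",
    "load_parameter_table",
    "write_parameter_table",
    "apply_knockout",
    "get_network",
    "species_index",
    "clamp_state",
]

ISOFORMS = ("a", "b", "e")

#: Canonical species ordering used by every trajectory array and output file.
SPECIES: tuple[str, ...] = (
    "IKKn", "IKKa", "IKKi",
    "NFkB", "NFkBn",
    "A20", "A20t",
) + tuple(
    name
    for i in ISOFORMS
    for name in (
        f"IkB{i}", f"IkB{i}n", f"IkB{i}t",
        f"IkB{i}_NFkB", f"IkB{i}n_NFkBn",
        f"IKKa_IkB{i}", f"IKKa_IkB{i}_NFkB",
    )
)

#: Species living in the nuclear compartment (everything else is cytoplasmic;
#: mRNAs are treated as cytoplasmic, their synthesis constants being
#: calibrated directly in cytoplasmic concentration units).
NUCLEAR_SPECIES: frozenset[str] = frozenset(
    {"NFkBn"} | {f"IkB{i}n" for i in ISOFORMS} | {f"IkB{i}n_NFkBn" for i in ISOFORMS}
)

#: Transport reactions whose product-side stoichiometry carries the Kv
#: volume correction (import: ×Kv, export: ÷Kv).
TRANSPORT_SYMBOLS: frozenset[str] = frozenset(
    {"I1", "K01"} | {f"{s}{i}" for s in "LQV" for i in ISOFORMS}
)

#: Cytoplasmic / nuclear NF-κB-containing species (conserved moiety).
NFKB_CYTOPLASMIC: tuple[str, ...] = ("NFkB",) + tuple(
    f"{p}{i}{s}" for p, s in (("IkB", "_NFkB"), ("IKKa_IkB", "_NFkB")) for i in ISOFORMS
)
NFKB_NUCLEAR: tuple[str, ...] = ("NFkBn",) + tuple(f"IkB{i}n_NFkBn" for i in ISOFORMS)

KNOCKOUT_GENES = ("IkBa", "IkBb", "IkBe", "A20")

_SPECIES_INDEX = {name: k for k, name in enumerate(SPECIES)}

_TABLE_RESOURCE = "rate_constants.tsv"


def species_index(name: str) -> int:
    """Position of *name* in the canonical :data:`SPECIES` ordering."""
    try:
        return _SPECIES_INDEX[name]
    except KeyError:
        raise KeyError(f"unknown species {name!r}") from None


def _read_table(source: str | Path | None) -> pd.DataFrame:
    if source is None:
        resource = importlib.resources.files("nfkbse.data") / _TABLE_RESOURCE
        with importlib.resources.as_file(resource) as path:
            df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    else:
        df = pd.read_csv(source, sep="\t", comment="#", dtype=str)
    expected = {"reaction", "symbol", "order_class", "nominal_value", "source_ref", "fitted_value"}
    missing = expected - set(df.columns)
    if missing:
        raise ValueError(f"parameter table missing columns: {sorted(missing)}")
    return df


def _collapse_symbols(df: pd.DataFrame, column: str) -> dict[str, float]:
    """One value per symbol; shared symbols (Dα, Gα, Hα, …) appear on several
    reaction rows and must agree — small printed-precision differences
    (≤0.5% relative) are tolerated, taking the first occurrence."""
    values: dict[str, float] = {}
    for _, row in df.iterrows():
        sym = row["symbol"]
        val = float(row[column])
        if sym in values:
            ref = values[sym]
            scale = max(abs(ref), abs(val))
            if scale > 0 and abs(val - ref) / scale > 5e-3:
                raise ValueError(
                    f"conflicting values for symbol {sym!r} in column {column!r}: {ref} vs {val}"
                )
        else:
            values[sym] = val
    return values


class ParameterSet(Mapping):
    """Immutable named vector of the model's kinetic constants.

    Holds one non-negative value per rate-constant symbol plus the two
    structural constants Kv (cytoplasm:nucleus volume ratio, dimensionless)
    and NFkB_total (total NF-κB concentration, μM).
    """

    __slots__ = ("_values",)

    def __init__(self, values: Mapping[str, float]):
        unknown = set(values) - set(SYMBOLS)
        if unknown:
            raise ValueError(f"unknown parameter symbols: {sorted(unknown)}")
        missing = set(SYMBOLS) - set(values)
        if missing:
            raise ValueError(f"missing parameter symbols: {sorted(missing)}")
        vals = {s: float(values[s]) for s in SYMBOLS}
        for sym, v in vals.items():
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"parameter {sym} must be finite and >= 0, got {v}")
        if vals["Kv"] <= 0:
            raise ValueError("Kv must be > 0")
        if vals["NFkB_total"] <= 0:
            raise ValueError("NFkB_total must be > 0")
        object.__setattr__(self, "_values", vals)

    def __getitem__(self, key: str) -> float:
        return self._values[key]

    def __iter__(self):
        return iter(self._values)

    def __len__(self) -> int:
        return len(self._values)

    def __eq__(self, other) -> bool:
        return isinstance(other, ParameterSet) and self._values == other._values

    def __repr__(self) -> str:
        return f"ParameterSet({len(self._values)} symbols, Kv={self['Kv']}, NFkB_total={self['NFkB_total']})"

    def replace(self, **updates: float) -> "ParameterSet":
        """New ParameterSet with the given symbols replaced."""
        vals = dict(self._values)
        for sym, v in updates.items():
            if sym not in vals:
                raise KeyError(f"unknown parameter symbol {sym!r}")
            vals[sym] = float(v)
        return ParameterSet(vals)

    def as_array(self, symbols: Iterable[str] = None) -> np.ndarray:
        syms = SYMBOLS if symbols is None else tuple(symbols)
        return np.array([self._values[s] for s in syms], dtype=float)

    @classmethod
    def from_array(cls, arr: np.ndarray, symbols: Iterable[str] = None) -> "ParameterSet":
        syms = SYMBOLS if symbols is None else tuple(symbols)
        return cls(dict(zip(syms, arr)))


@dataclass(frozen=True)
class Genotype:
    """Set of knocked-out genes; the empty set is wild type."""

    knockouts: frozenset[str] = frozenset()

    def __post_init__(self):
        unknown = set(self.knockouts) - set(KNOCKOUT_GENES)
        if unknown:
            raise ValueError(
                f"unknown knockout gene(s) {sorted(unknown)}; valid: {KNOCKOUT_GENES}"
            )
        object.__setattr__(self, "knockouts", frozenset(self.knockouts))

    @classmethod
    def wild_type(cls) -> "Genotype":
        return cls()

    @classmethod
    def parse(cls, genes: Iterable[str] | str) -> "Genotype":
        if isinstance(genes, str):
            genes = [g for g in genes.replace(",", " ").split() if g]
        return cls(frozenset(genes))

    @property
    def is_wild_type(self) -> bool:
        return not self.knockouts

    def label(self) -> str:
        return "wt" if self.is_wild_type else "-".join(sorted(self.knockouts)) + "_ko"


def load_parameter_table(
    source: str | Path | None = None, column: str = "fitted"
) -> ParameterSet:
    """Load a ParameterSet from the packaged rate-constant table.

    Parameters
    ----------
    source
        Path to a TSV in the packaged-table format, or None for the table
        shipped with the package.
    column
        ``"nominal"`` (literature-assembled reference values) or
        ``"fitted"`` (ensemble-average fit).
    """
    if column not in ("nominal", "fitted"):
        raise ValueError(f"column must be 'nominal' or 'fitted', got {column!r}")
    df = _read_table(source)
    values = _collapse_symbols(df, f"{column}_value")
    missing = set(SYMBOLS) - set(values)
    if missing:
        raise ValueError(f"parameter table is missing symbol(s): {sorted(missing)}")
    extra = set(values) - set(SYMBOLS)
    if extra:
        raise ValueError(f"parameter table has unknown symbol(s): {sorted(extra)}")
    return ParameterSet(values)


def write_parameter_table(params: ParameterSet, path: str | Path) -> None:
    """Write *params* in the packaged-table TSV format (fitted column holds
    the given values; reaction/nominal columns are copied from the packaged
    table so the file round-trips through :func:`load_parameter_table`)."""
    df = _read_table(None)
    df["fitted_value"] = [repr(params[s]) for s in df["symbol"]]
    df.to_csv(path, sep="\t", index=False)


def apply_knockout(params: ParameterSet, genotype: Genotype) -> ParameterSet:
    """Zero the mRNA synthesis channels of knocked-out genes.

    IκB isoform knockouts zero both the NF-κB-induced (U) and constitutive
    (Y) transcription rates; the A20 knockout zeroes C1 and C2.  The input
    is not mutated.
    """
    if not isinstance(genotype, Genotype):
        genotype = Genotype.parse(genotype)
    updates: dict[str, float] = {}
    for gene in genotype.knockouts:
        if gene == "A20":
            updates["C1"] = 0.0
            updates["C2"] = 0.0
        else:
            iso = gene[-1]  # "IkBa" -> "a"
            updates[f"U{iso}"] = 0.0
            updates[f"Y{iso}"] = 0.0
    return params.replace(**updates) if updates else params


# ---------------------------------------------------------------------------
# Reaction parsing and the mass-action right-hand side


@dataclass(frozen=True)
class Reaction:
    """One elementary reaction: flux = k · TR? · Π [reactant].

    ``stoich`` maps species name → (coefficient, kv_power); the numeric
    stoichiometric coefficient is coefficient · Kv**kv_power, which carries
    the amount-conserving volume correction for transport reactions.
    """

    table_row: int
    text: str
    symbol: str
    reactants: tuple[str, ...]
    stoich: tuple[tuple[str, float, int], ...]
    tr_scaled: bool = False


def _parse_side(side: str) -> list[str]:
    side = side.strip()
    if side == "0":
        return []
    return [tok.strip() for tok in side.split("+")]


def _parse_reaction_rows(df: pd.DataFrame) -> list[Reaction]:
    reactions: list[Reaction] = []
    for row_idx, row in df.iterrows():
        sym = row["symbol"]
        if sym in ("Kv", "NFkB_total"):
            continue  # structural constants, not reactions
        text = row["reaction"]
        lhs_txt, rhs_txt = text.split("->")
        # Rows like "IKKn, IKKa, or IKKi -> 0" or "IkBa, IkBan -> 0" group
        # several first-order reactions under one shared constant.
        lhs_txt = lhs_txt.replace(" or ", ",")
        lhs_groups = [g.strip() for g in lhs_txt.split(",") if g.strip()]
        for lhs_one in lhs_groups:
            reactants = tuple(_parse_side(lhs_one))
            products = _parse_side(rhs_txt)
            for name in (*reactants, *products):
                if name not in _SPECIES_INDEX:
                    raise ValueError(f"row {row_idx}: unknown species {name!r} in {text!r}")
            net: dict[str, float] = {}
            for name in reactants:
                net[name] = net.get(name, 0.0) - 1.0
            for name in products:
                net[name] = net.get(name, 0.0) + 1.0
            # Transport: the tabulated constant is the cytoplasm-referenced
            # rate; the nuclear-side stoichiometry carries ×Kv in both
            # directions, which conserves molecule amounts exactly.
            kv_pow: dict[str, int] = {}
            if sym in TRANSPORT_SYMBOLS:
                for name in net:
                    if name in NUCLEAR_SPECIES:
                        kv_pow[name] = 1
            stoich = tuple(
                (name, coeff, kv_pow.get(name, 0))
                for name, coeff in net.items()
                if coeff != 0.0
            )
            reactions.append(
                Reaction(
                    table_row=int(row_idx),
                    text=text if len(lhs_groups) == 1 else f"{lhs_one} -> 0",
                    symbol=sym,
                    reactants=reactants,
                    stoich=stoich,
                    tr_scaled=(sym == "K1"),
                )
            )
    return reactions


class ReactionNetwork:
    """The reaction system as data, with a plain-numpy mass-action RHS.

    This is the reference implementation: ``derivatives`` assembles
    stoichiometry-matrix × flux-vector with numpy.  The production
    integrator (:mod:`nfkbse._kernels`) code-generates an unrolled,
    numba-compiled equivalent from the same reaction list; the two paths
    are cross-checked in the test suite.
    """

    def __init__(self, table: pd.DataFrame):
        self.table = table
        self.reactions = _parse_reaction_rows(table)
        self.species = SPECIES
        self.n_species = len(SPECIES)
        self.n_reactions = len(self.reactions)

    def stoichiometry_matrix(self, params: ParameterSet) -> np.ndarray:
        """Dense (n_species × n_reactions) matrix with Kv volume factors resolved."""
        kv = params["Kv"]
        S = np.zeros((self.n_species, self.n_reactions))
        for j, rxn in enumerate(self.reactions):
            for name, coeff, kvp in rxn.stoich:
                S[_SPECIES_INDEX[name], j] = coeff * kv**kvp
        return S

    def flux(self, state: np.ndarray, params: ParameterSet, TR: float) -> np.ndarray:
        """Per-reaction mass-action flux vector (μM/s)."""
        v = np.empty(self.n_reactions)
        for j, rxn in enumerate(self.reactions):
            f = params[rxn.symbol]
            if rxn.tr_scaled:
                f *= TR
            for name in rxn.reactants:
                f *= state[_SPECIES_INDEX[name]]
            v[j] = f
        return v

    def derivatives(self, state: np.ndarray, params: ParameterSet, TR: float) -> np.ndarray:
        """d(state)/dt for the full network (reference numpy path)."""
        if TR < 0:
            raise ValueError("TR must be >= 0")
        state = clamp_state(np.asarray(state, dtype=float))
        return self.stoichiometry_matrix(params) @ self.flux(state, params, TR)

    def nfkb_weights(self, params: ParameterSet) -> np.ndarray:
        """Volume weights of the conserved NF-κB moiety (1 cytoplasmic, 1/Kv nuclear)."""
        w = np.zeros(self.n_species)
        for name in NFKB_CYTOPLASMIC:
            w[_SPECIES_INDEX[name]] = 1.0
        for name in NFKB_NUCLEAR:
            w[_SPECIES_INDEX[name]] = 1.0 / params["Kv"]
        return w

    def total_nfkb(self, state: np.ndarray, params: ParameterSet) -> float:
        """Volume-weighted total NF-κB of a state (conserved; equals NFkB_total
        along any trajectory started from the standard initial condition)."""
        return float(self.nfkb_weights(params) @ np.asarray(state, dtype=float))

    def initial_state(self, params: ParameterSet) -> np.ndarray:
        """Standard initial condition: all NF-κB free in the cytoplasm, all
        other species at zero."""
        y0 = np.zeros(self.n_species)
        y0[_SPECIES_INDEX["NFkB"]] = params["NFkB_total"]
        return y0


def clamp_state(state: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    """Clip integrator round-off negatives to zero; a concentration below
    -tol (in μM) indicates genuine divergence and raises."""
    lo = state.min()
    if lo < -tol:
        k = int(np.argmin(state))
        raise ValueError(
            f"negative concentration beyond clamp tolerance: {SPECIES[k]} = {lo:g}"
        )
    return np.clip(state, 0.0, None)


_network: ReactionNetwork | None = None


def get_network() -> ReactionNetwork:
    """The packaged reaction network (parsed once per process)."""
    global _network
    if _network is None:
        _network = ReactionNetwork(_read_table(None))
    return _network


#: All parameter symbols (rate constants + Kv + NFkB_total), in table order.
SYMBOLS: tuple[str, ...] = tuple(
    dict.fromkeys(_read_table(None)["symbol"])
)

#: Kinetic rate-constant symbols (excludes the structural constants).
RATE_SYMBOLS: tuple[str, ...] = tuple(
    s for s in SYMBOLS if s not in ("Kv", "NFkB_total")
)
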