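"""Metastable-equilibrium relative stability of proteomes on an Eh-pH grid.

Each per-residue proteome formula is written as a formation reaction from
six basis species (glutamine, glutamic acid, cysteine, H2O, H+, e-); the
stoichiometric coefficients are the unique solution of a 6x6 linear system
conserving C, H, N, O, S and charge.  The Gibbs energy of formation per
residue,

    dG = dG0_r + RT ln Q,

is evaluated with fixed activities for the first four basis species, with
a(H+) = 10^-pH and a(e-) = 10^-pe where pe = F*Eh / (ln10*R*T).  At each
(Eh, pH) node the proteome with the lowest dG per residue -- the least
unstable one -- wins.  Because dG is affine in both pH and pe, stability
boundaries are straight lines in (Eh, pH) with slope
-(d_nuHplus/d_nue) * ln10*R*T/F; for electrically neutral proteome
formulas nuH+ = nue-, so every boundary has exactly the Nernst slope and
Z_C-vs-Eh profiles at different pH collapse onto one curve under the Eh7
correction.

Standard Gibbs energies are consumed as data (a GibbsTable); deriving them
from group-additivity parameters is outside this package's scope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .composition import AminoAcidTally, ElementalFormula, formula_from_tally, \
    normalize_per_residue, zc_from_formula
from .geochem import FARADAY, LN10, R_GAS, nernst_slope

logger = logging.getLogger(__name__)

__all__ = [
    "BASIS_SPECIES",
    "BasisSet",
    "GibbsEntry",
    "GibbsTable",
    "StabilityGrid",
    "StepProfile",
    "balance_reaction",
    "delta_g_per_residue",
    "stability_grid",
    "water_limits",
    "zc_vs_eh_profile",
    "eh_to_pe",
]

#: Basis species names in canonical order.
BASIS_SPECIES = ("glutamine", "glutamic acid", "cysteine", "H2O", "H+", "e-")

#: ΔG°f of liquid water at 25 degC, 1 bar (J/mol); sets the oxygen line of
#: the water stability window at 1229 mV - 59.16*pH.
DG0_WATER = -237183.0

# (c, h, n, o, s, z) composition vectors; the electron carries charge only.
_BASIS_VECTORS = np.array(
    [
        [5, 10, 2, 3, 0, 0],   # glutamine
        [5, 9, 1, 4, 0, 0],    # glutamic acid
        [3, 7, 1, 2, 1, 0],    # cysteine
        [0, 2, 0, 1, 0, 0],    # H2O
        [0, 1, 0, 0, 0, 1],    # H+
        [0, 0, 0, 0, 0, -1],   # e-
    ],
    dtype=float,
)

_DEFAULT_LOG_ACTIVITY = {
    "glutamine": -3.2,
    "glutamic acid": -4.5,
    "cysteine": -3.6,
    "H2O": 0.0,
}


@dataclass(frozen=True)
class BasisSet:
    """The six thermodynamic components and their fixed log activities.

    H+ and e- activities are variables (set by pH and pe); the other four
    are held constant.  The 6x6 composition matrix over (C, H, N, O, S,
    charge) must be nonsingular so formation reactions have unique
    coefficients.
    """

    names: tuple[str, ...] = BASIS_SPECIES
    matrix: np.ndarray = field(default_factory=lambda: _BASIS_VECTORS.copy())
    fixed_log_activity: dict = field(
        default_factory=lambda: dict(_DEFAULT_LOG_ACTIVITY)
    )

    def __post_init__(self) -> None:
        if self.matrix.shape != (6, 6):
            raise ValueError("basis matrix must be 6x6")
        if abs(np.linalg.det(self.matrix)) < 1e-12:
            raise ValueError("basis composition matrix is singular")


def balance_reaction(target: ElementalFormula, basis: BasisSet | None = None) -> np.ndarray:
    """Stoichiometric coefficients forming ``target`` from the basis species.

    Solves conservation of C, H, N, O, S and charge exactly; the returned
    six-vector ``nu`` satisfies ``nu @ basis.matrix == target`` with residual
    norm below 1e-9 (scaled).
    """
    basis = basis or BasisSet()
    t = target.as_vector()
    nu = np.linalg.solve(basis.matrix.T, t)
    residual = np.linalg.norm(nu @ basis.matrix - t)
    scale = max(1.0, np.linalg.norm(t))
    if residual > 1e-9 * scale:
        raise ArithmeticError(f"reaction balancing residual {residual:.3e} too large")
    return nu


@dataclass(frozen=True)
class GibbsEntry:
    species: str
    kind: str                       # "basis" | "proteome"
    formula: ElementalFormula
    dG0_J_mol: float                # per mole (per residue for proteomes)
    log_activity: float | None = None


class GibbsTable:
    """Standard Gibbs energies (25 degC, 1 bar) for basis species and
    per-residue proteome formulas, consumed as data."""

    CSV_COLUMNS = [
        "species", "kind", "c", "h", "n", "o", "s", "charge",
        "dG0_J_mol", "log_activity",
    ]

    def __init__(self, entries: Sequence[GibbsEntry] = ()) -> None:
        self._entries: dict[str, GibbsEntry] = {}
        for e in entries:
            self.add(e)

    def add(self, entry: GibbsEntry) -> None:
        if entry.species in self._entries:
            raise KeyError(f"duplicate Gibbs entry for {entry.species!r}")
        self._entries[entry.species] = entry

    def __contains__(self, species: str) -> bool:
        return species in self._entries

    def get(self, species: str) -> GibbsEntry:
        if species not in self._entries:
            raise KeyError(f"no Gibbs energy entry for species {species!r}")
        return self._entries[species]

    def proteome_names(self) -> list[str]:
        return [e.species for e in self._entries.values() if e.kind == "proteome"]

    def basis_dg0(self, basis: BasisSet) -> np.ndarray:
        return np.array([self.get(name).dG0_J_mol for name in basis.names])

    def to_csv(self, path: str | Path) -> None:
        rows = []
        for e in self._entries.values():
            f = e.formula
            rows.append({
                "species": e.species, "kind": e.kind,
                "c": f.c, "h": f.h, "n": f.n, "o": f.o, "s": f.s, "charge": f.z,
                "dG0_J_mol": e.dG0_J_mol,
                "log_activity": "" if e.log_activity is None else e.log_activity,
            })
        pd.DataFrame(rows, columns=self.CSV_COLUMNS).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "GibbsTable":
        df = pd.read_csv(path)
        table = cls()
        for _, row in df.iterrows():
            log_a = row["log_activity"]
            log_a = None if pd.isna(log_a) else float(log_a)
            vec = [float(row[k]) for k in ("c", "h", "n", "o", "s")]
            if row["species"] == "e-":
                formula = _electron_formula(float(row["charge"]))
            else:
                formula = ElementalFormula(*vec, z=float(row["charge"]))
            table.add(GibbsEntry(
                species=str(row["species"]), kind=str(row["kind"]),
                formula=formula, dG0_J_mol=float(row["dG0_J_mol"]),
                log_activity=log_a,
            ))
        return table


def _electron_formula(z: float = -1.0) -> ElementalFormula:
    """The electron has no atoms; bypass the at-least-one-atom invariant."""
    f = object.__new__(ElementalFormula)
    for name, val in zip(("c", "h", "n", "o", "s", "z"), (0, 0, 0, 0, 0, z)):
        object.__setattr__(f, name, float(val))
    return f


def default_basis_entries(dg0: dict[str, float] | None = None) -> list[GibbsEntry]:
    """Gibbs entries for the six basis species.

    Default ΔG°f values (J/mol, 25 degC) are CODATA water plus aqueous
    amino-acid values of the magnitude found in standard compilations; H+
    and e- are zero by the SHE convention.
    """
    dg0 = dg0 or {
        "glutamine": -529000.0,
        "glutamic acid": -723800.0,
        "cysteine": -340000.0,
        "H2O": DG0_WATER,
        "H+": 0.0,
        "e-": 0.0,
    }
    entries = []
    for i, name in enumerate(BASIS_SPECIES):
        vec = _BASIS_VECTORS[i]
        if name == "e-":
            formula = _electron_formula(vec[5])
        else:
            formula = ElementalFormula(*vec[:5], z=vec[5])
        entries.append(GibbsEntry(
            species=name, kind="basis", formula=formula,
            dG0_J_mol=dg0[name],
            log_activity=_DEFAULT_LOG_ACTIVITY.get(name),
        ))
    return entries


def eh_to_pe(eh_mV: float | np.ndarray, T_C: float = 25.0) -> float | np.ndarray:
    """pe = F*Eh / (ln10*R*T) with Eh in mV."""
    T_K = T_C + 273.15
    return FARADAY * (np.asarray(eh_mV) / 1000.0) / (LN10 * R_GAS * T_K)


def _formula_for_target(
    species: str, gibbs: GibbsTable, tally: AminoAcidTally | None
) -> ElementalFormula:
    entry = gibbs.get(species)
    if tally is None:
        return entry.formula
    # per-residue convention: mean free amino-acid formula, charge from the
    # Gibbs entry (ionization treatment lives in the data, not recomputed)
    per_res = formula_from_tally(normalize_per_residue(tally), polymerized=True)
    return ElementalFormula(
        per_res.c, per_res.h, per_res.n, per_res.o, per_res.s, z=entry.formula.z
    )


def delta_g_per_residue(
    species: str,
    gibbs: GibbsTable,
    basis: BasisSet | None = None,
    eh_mV: float = 0.0,
    pH: float = 7.0,
    T_C: float = 25.0,
    tally: AminoAcidTally | None = None,
) -> float:
    """Gibbs energy (J/mol per residue) of forming a species from the basis.

    ``dG = dG0_r + RT ln Q``; the reaction is ``sum(nu_i * basis_i) ->
    target`` so a formation consuming electrons (a reduced target) is
    penalized as Eh rises.  The target activity is taken from its Gibbs
    entry when stored (basis species), else unity (proteomes), so a target
    identical to a basis species at its assigned activity sits at
    equilibrium (dG = 0).  If ``tally`` is given the target formula is its
    per-residue mean composition; otherwise the formula stored in the
    Gibbs table is used.
    """
    basis = basis or BasisSet()
    entry = gibbs.get(species)
    target = _formula_for_target(species, gibbs, tally)
    nu = balance_reaction(target, basis)
    dg0_r = entry.dG0_J_mol - float(nu @ gibbs.basis_dg0(basis))
    T_K = T_C + 273.15
    rt_ln10 = R_GAS * T_K * LN10
    log_a = np.array(
        [
            *[basis.fixed_log_activity[n] for n in basis.names[:4]],
            -pH,
            -float(eh_to_pe(eh_mV, T_C)),
        ]
    )
    log_a_target = entry.log_activity if entry.log_activity is not None else 0.0
    return dg0_r + rt_ln10 * (log_a_target - float(nu @ log_a))


def water_limits(pH: float | np.ndarray, T_C: float = 25.0) -> tuple:
    """Water stability window (Eh_min, Eh_max) in mV at 1 bar gas fugacity.

    Lower limit: 2H+ + 2e- = H2 (E0 = 0); upper: O2 + 4H+ + 4e- = 2H2O
    (E0 = 1229 mV at 25 degC from ΔG°f of water).  Both lines share the
    Nernst slope, so the window width is pH independent.
    """
    pH = np.asarray(pH, dtype=float)
    slope = nernst_slope(T_C)
    e0_o2 = -2.0 * DG0_WATER / (4.0 * FARADAY) * 1000.0  # mV
    eh_min = slope * pH
    eh_max = e0_o2 + slope * pH
    if pH.ndim == 0:
        return float(eh_min), float(eh_max)
    return eh_min, eh_max


@dataclass
class StepProfile:
    """Piecewise-constant winner Z_C along the Eh axis at fixed pH.

    ``edges`` has one more element than ``zc``; segment k spans
    [edges[k], edges[k+1]) with winner index ``winner[k]``.
    """

    edges: np.ndarray
    zc: np.ndarray
    winner: np.ndarray
    pH: float

    def __post_init__(self) -> None:
        if len(self.edges) != len(self.zc) + 1:
            raise ValueError("profile edges must bracket the segments")

    def lookup(self, eh_mV: float | np.ndarray) -> np.ndarray:
        eh = np.asarray(eh_mV, dtype=float)
        if np.any(eh < self.edges[0] - 1e-9) or np.any(eh > self.edges[-1] + 1e-9):
            raise ValueError("Eh outside profile domain")
        idx = np.clip(np.searchsorted(self.edges, eh, side="right") - 1,
                      0, len(self.zc) - 1)
        return self.zc[idx]

    @property
    def domain(self) -> tuple[float, float]:
        return float(self.edges[0]), float(self.edges[-1])

    @property
    def n_segments(self) -> int:
        return len(self.zc)


@dataclass
class StabilityGrid:
    """Winner-take-all stability diagram on an Eh (rows) x pH (columns) lattice.

    Also stores the per-proteome affine Gibbs coefficients so Z_C-Eh
    profiles can be extracted with exact (envelope-based) breakpoints.
    """

    eh_mV: np.ndarray
    pH: np.ndarray
    winner: np.ndarray               # (n_eh, n_pH) int
    dg_min: np.ndarray               # (n_eh, n_pH) J/mol per residue
    water_mask: np.ndarray           # True inside the water window
    proteomes: list[str]
    proteome_zc: np.ndarray
    T_C: float
    _const: np.ndarray = field(repr=False, default=None)   # (n_prot,)
    _nu_h: np.ndarray = field(repr=False, default=None)
    _nu_e: np.ndarray = field(repr=False, default=None)

    def winner_name(self, i_eh: int, j_ph: int) -> str:
        return self.proteomes[int(self.winner[i_eh, j_ph])]

    def to_frame(self) -> pd.DataFrame:
        eh, ph = np.meshgrid(self.eh_mV, self.pH, indexing="ij")
        return pd.DataFrame({
            "Eh_mV": eh.ravel(),
            "pH": ph.ravel(),
            "winner": [self.proteomes[k] for k in self.winner.ravel()],
            "winner_Zc": self.proteome_zc[self.winner.ravel()],
            "dG_min_J_mol": self.dg_min.ravel(),
            "in_water_window": self.water_mask.ravel(),
        })


def stability_grid(
    proteomes: Sequence[str],
    gibbs: GibbsTable,
    basis: BasisSet | None = None,
    eh_range_mV: tuple[float, float] = (-600.0, 1000.0),
    ph_range: tuple[float, float] = (0.0, 14.0),
    shape: tuple[int, int] = (256, 256),
    T_C: float = 25.0,
) -> StabilityGrid:
    """Identify the least-unstable proteome at every node of an Eh-pH grid.

    Ties at exactly equal dG go to the lowest input index (logged).  The
    default 256x256 lattice resolves boundary slopes to well under 1%.
    """
    basis = basis or BasisSet()
    if len(proteomes) < 1:
        raise ValueError("at least one proteome is required")
    if shape[0] < 2 or shape[1] < 2:
        raise ValueError("grid must be at least 2x2")
    T_K = T_C + 273.15
    rt_ln10 = R_GAS * T_K * LN10
    basis_dg0 = gibbs.basis_dg0(basis)
    fixed_log_a = np.array(
        [basis.fixed_log_activity[n] for n in basis.names[:4]] + [0.0, 0.0]
    )
    const = np.empty(len(proteomes))
    nu_h = np.empty(len(proteomes))
    nu_e = np.empty(len(proteomes))
    zc = np.empty(len(proteomes))
    for i, name in enumerate(proteomes):
        entry = gibbs.get(name)
        nu = balance_reaction(entry.formula, basis)
        dg0_r = entry.dG0_J_mol - float(nu @ basis_dg0)
        const[i] = dg0_r - rt_ln10 * float(nu @ fixed_log_a)
        nu_h[i] = nu[4]
        nu_e[i] = nu[5]
        zc[i] = zc_from_formula(entry.formula)

    eh = np.linspace(*eh_range_mV, shape[0])
    ph = np.linspace(*ph_range, shape[1])
    pe = eh_to_pe(eh, T_C)
    # dG[i] = const[i] + rt_ln10 * (nu_h[i]*pH + nu_e[i]*pe)
    dg = (
        const[:, None, None]
        + rt_ln10 * (nu_h[:, None, None] * ph[None, None, :]
                     + nu_e[:, None, None] * pe[None, :, None])
    )
    winner = np.argmin(dg, axis=0)
    dg_min = np.min(dg, axis=0)
    n_ties = int(((dg == dg_min[None]).sum(axis=0) > 1).sum())
    if n_ties:
        logger.info("%d grid nodes had dG ties; lowest index kept", n_ties)
    eh_min, eh_max = water_limits(ph, T_C)
    water_mask = (eh[:, None] >= eh_min[None, :]) & (eh[:, None] <= eh_max[None, :])
    return StabilityGrid(
        eh_mV=eh, pH=ph, winner=winner, dg_min=dg_min, water_mask=water_mask,
        proteomes=list(proteomes), proteome_zc=zc, T_C=T_C,
        _const=const, _nu_h=nu_h, _nu_e=nu_e,
    )


def zc_vs_eh_profile(grid: StabilityGrid, pH: float) -> StepProfile:
    """Winner Z_C as an exact step function of Eh at one pH.

    Breakpoints are computed analytically from the lower envelope of the
    per-proteome affine Gibbs lines, not read off lattice nodes.
    """
    if not grid.pH[0] <= pH <= grid.pH[-1]:
        raise ValueError(f"pH {pH} outside grid range "
                         f"[{grid.pH[0]}, {grid.pH[-1]}]")
    T_K = grid.T_C + 273.15
    rt_ln10 = R_GAS * T_K * LN10
    # dG_i(Eh_V) = alpha_i + beta_i * Eh_V
    alpha = grid._const + rt_ln10 * grid._nu_h * pH
    beta = FARADAY * grid._nu_e
    lo, hi = float(grid.eh_mV[0]), float(grid.eh_mV[-1])
    # winner sequence from a dense scan, then exact intersection refinement
    eh_dense = np.linspace(lo, hi, max(4096, 16 * len(alpha)))
    dg = alpha[:, None] + beta[:, None] * (eh_dense[None, :] / 1000.0)
    w = np.argmin(dg, axis=0)
    change = np.flatnonzero(np.diff(w)) + 1
    winners = [int(w[0])] + [int(w[k]) for k in change]
    edges = [lo]
    for prev, nxt in zip(winners[:-1], winners[1:]):
        if beta[prev] == beta[nxt]:     # parallel lines cannot cross
            continue
        eh_cross = (alpha[nxt] - alpha[prev]) / (beta[prev] - beta[nxt]) * 1000.0
        edges.append(float(np.clip(eh_cross, lo, hi)))
    edges.append(hi)
    return StepProfile(
        edges=np.array(edges),
        zc=grid.proteome_zc[np.array(winners)],
        winner=np.array(winners),
        pH=pH,
    )
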