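"""HINT hydropathic atom parameterization and pairwise interaction scoring.

The pair score is b_ij = a_i S_i a_j S_j T_ij e^(−r) + L_ij, where a is the
signed hydrophobic atom constant (positive hydrophobic, negative polar), S a
per-atom solvent-accessible surface area term, T ∈ {−1, 0, +1} fixes the sign
for Lewis acid/base pairings, and L is a short-range clash penalty.

The shipped atom constants are a rule-based default (sign- and class-faithful
to hydropathic conventions: aliphatic C/H positive; N, O and polar hydrogens
negative); they are derived from the CCD residue topology and can be replaced
wholesale from a TSV to use an externally parameterized table.
"""
from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .structures_io import StructureModel, ResidueView, _reference, _ref_adjacency

logger = logging.getLogger(__name__)


class PolarClass(str, enum.Enum):
    HYDROPHOBIC = "hydrophobic"
    ACID = "polar-acid"          # H-bond donor / Lewis acid
    BASE = "polar-base"          # H-bond acceptor / Lewis base
    NEUTRAL = "polar-neutral"    # donor+acceptor or weakly polar


class InteractionClass(str, enum.Enum):
    FAVORABLE_HYDROPHOBIC = "favorable_hydrophobic"
    UNFAVORABLE_HYDROPHOBIC = "unfavorable_hydrophobic"
    FAVORABLE_POLAR = "favorable_polar"
    UNFAVORABLE_POLAR = "unfavorable_polar"


@dataclass(frozen=True)
class HintAtomParams:
    a: float                  # signed hydrophobic atom constant
    S: float                  # SASA term, Å²
    polar_class: PolarClass

    def __post_init__(self):
        hydrophobic = self.polar_class is PolarClass.HYDROPHOBIC
        if (self.a > 0) != hydrophobic and self.a != 0.0:
            raise ValueError(
                f"sign of a={self.a} inconsistent with class {self.polar_class}")


@dataclass(frozen=True)
class PairScore:
    b: float
    r: float
    interaction_class: InteractionClass
    target_index: int = -1     # global atom index of the target sidechain atom
    env_index: int = -1        # global atom index of the environment atom
    env_is_lipid: bool = False


# ---------------------------------------------------------------------------
# default parameter table
# ---------------------------------------------------------------------------

#: magnitudes per broad chemotype; signs follow the polar class
_A_ALIPHATIC_C = 0.80
_A_AROMATIC_C = 0.30
_A_HETERO_C = 0.10       # sp3 C bonded to N/O
_A_CARBONYL_C = -0.30
_A_H_ON_C = 0.23
_A_H_POLAR = -0.20
_A_N_DONOR = -1.00
_A_N_ACCEPTOR = -0.90
_A_O_ACCEPTOR = -1.20
_A_O_HYDROXYL = -1.00
_A_S = 0.50

#: van der Waals radii (Å) for the LJ contact distance
VDW_RADII = {"H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
             "P": 1.80, "SE": 1.90}

#: entries for the simplified DPPC pseudo-lipid used in membrane systems
_LIPID_DEFAULTS = {
    "P": (-0.50, PolarClass.NEUTRAL),
    "N": (-1.00, PolarClass.BASE),
    "O": (-1.60, PolarClass.BASE),
    "C": (_A_ALIPHATIC_C, PolarClass.HYDROPHOBIC),
    "H": (_A_H_ON_C, PolarClass.HYDROPHOBIC),
}


def _classify_reference_atom(ref, adj, i) -> tuple[float, PolarClass]:
    """Rule-based (a, class) for atom i of a CCD reference residue."""
    elem = ref.element[i]
    bonds = ref.bonds.as_array()
    neighbors = adj[i]
    nb_elems = [ref.element[j] for j in neighbors]

    def bond_order(j):
        for b0, b1, t in bonds:
            if {int(b0), int(b1)} == {i, j}:
                return int(t)
        return 1

    if elem == "H":
        parent = nb_elems[0] if nb_elems else "C"
        if parent == "C":
            return _A_H_ON_C, PolarClass.HYDROPHOBIC
        return _A_H_POLAR, PolarClass.ACID
    if elem == "C":
        # aromatic: CCD bond type 5 = AROMATIC
        orders = [bond_order(j) for j in neighbors]
        if any(t >= 5 for t in orders):
            return _A_AROMATIC_C, PolarClass.HYDROPHOBIC
        if any(e in ("N", "O") and t == 2
               for e, t in zip(nb_elems, orders)):
            return _A_CARBONYL_C, PolarClass.NEUTRAL
        if any(e in ("N", "O") for e in nb_elems):
            return _A_HETERO_C, PolarClass.HYDROPHOBIC
        return _A_ALIPHATIC_C, PolarClass.HYDROPHOBIC
    if elem == "N":
        has_h = any(e == "H" for e in nb_elems)
        if has_h:
            return _A_N_DONOR, PolarClass.ACID
        return _A_N_ACCEPTOR, PolarClass.BASE
    if elem == "O":
        has_h = any(e == "H" for e in nb_elems)
        if has_h:
            return _A_O_HYDROXYL, PolarClass.NEUTRAL
        return _A_O_ACCEPTOR, PolarClass.BASE
    if elem == "S":
        return _A_S, PolarClass.HYDROPHOBIC
    # fallback: weakly polar
    return -0.10, PolarClass.NEUTRAL


class ParameterTable:
    """Map (residue_name, atom_name) → (a, polar_class).

    Defaults are generated from the CCD residue topology by chemotype rules;
    a TSV (columns: residue_name, atom_name, a, polar_class) can override or
    extend any entry.  DPPC-style pseudo-lipid atoms fall back to per-element
    defaults.
    """

    def __init__(self):
        self._table: dict[tuple[str, str], tuple[float, PolarClass]] = {}
        self._built: set[str] = set()

    def _build_residue(self, res_name: str) -> None:
        if res_name in self._built:
            return
        self._built.add(res_name)
        ref = _reference(res_name)
        if ref is None:
            return
        adj = _ref_adjacency(ref)
        for i in range(ref.array_length()):
            key = (res_name, str(ref.atom_name[i]))
            if key not in self._table:
                self._table[key] = _classify_reference_atom(ref, adj, i)
        # PDB v3 terminal hydrogens share the amide-H parameters
        if (res_name, "H") in self._table:
            for name in ("H1", "H2", "H3"):
                self._table.setdefault((res_name, name), self._table[(res_name, "H")])

    def resolve(self, res_name: str, atom_name: str,
                element: str = "", is_lipid: bool = False) -> tuple[float, PolarClass]:
        key = (res_name, atom_name)
        elem = element or atom_name[:1]
        if is_lipid:
            # lipid residues (DPPC and aliases) use per-element chemotypes
            # unless explicitly overridden
            if key in self._table:
                return self._table[key]
            return _LIPID_DEFAULTS.get(elem, (-0.10, PolarClass.NEUTRAL))
        if key not in self._table:
            self._build_residue(res_name)
        if key in self._table:
            return self._table[key]
        if elem in _LIPID_DEFAULTS:
            logger.debug("element fallback for %s/%s", res_name, atom_name)
            return _LIPID_DEFAULTS[elem]
        return -0.10, PolarClass.NEUTRAL

    def set(self, res_name: str, atom_name: str, a: float, polar_class: PolarClass):
        self._table[(res_name, atom_name)] = (float(a), PolarClass(polar_class))

    def load_tsv(self, path: str | Path) -> "ParameterTable":
        import pandas as pd
        df = pd.read_csv(path, sep="\t")
        for _, row in df.iterrows():
            self.set(row["residue_name"], row["atom_name"],
                     float(row["a"]), PolarClass(row["polar_class"]))
        return self

    def save_tsv(self, path: str | Path, residues=None) -> None:
        import pandas as pd
        if residues:
            for r in residues:
                self._build_residue(r)
        rows = [{"residue_name": rn, "atom_name": an, "a": a,
                 "polar_class": pc.value}
                for (rn, an), (a, pc) in sorted(self._table.items())]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# pair scoring
# ---------------------------------------------------------------------------

def resolve_T(ci: PolarClass, cj: PolarClass) -> int:
    """Sign convention for the exponential term.

    Acid-base pairings are favorable (+1 applied to |a_i S_i a_j S_j|),
    acid-acid and base-base unfavorable (−1); any pairing involving a
    hydrophobic atom takes T = +1, the sign being carried by the product of
    the signed atom constants (hydrophobic-polar products are negative).
    """
    polar = {PolarClass.ACID, PolarClass.BASE}
    if PolarClass.HYDROPHOBIC in (ci, cj):
        return 1
    if {ci, cj} == polar:
        return 1
    if ci == cj and ci in polar:
        return -1
    return 1   # neutral with anything polar: favorable


def classify_interaction(i: HintAtomParams | PolarClass,
                         j: HintAtomParams | PolarClass) -> InteractionClass:
    """Interaction class of a pair from its polar classes alone (sign taken
    from the exponential term of the score)."""
    ci = i.polar_class if isinstance(i, HintAtomParams) else i
    cj = j.polar_class if isinstance(j, HintAtomParams) else j
    if PolarClass.HYDROPHOBIC in (ci, cj):
        if ci is cj:
            return InteractionClass.FAVORABLE_HYDROPHOBIC
        return InteractionClass.UNFAVORABLE_HYDROPHOBIC
    if resolve_T(ci, cj) > 0:
        return InteractionClass.FAVORABLE_POLAR
    return InteractionClass.UNFAVORABLE_POLAR


def lj_clash(r: float, r_contact: float, epsilon: float = 0.1) -> float:
    """Clamped 6-12 clash penalty: 0 at and beyond the contact distance,
    −ε((r0/r)^6 − 1)² below it (monotone in the overlap)."""
    if r >= r_contact:
        return 0.0
    x = (r_contact / r) ** 6 - 1.0
    return -epsilon * x * x


def score_pair(i: HintAtomParams, j: HintAtomParams, r: float, *,
               T: int | None = None, lj_enabled: bool = True,
               lj_epsilon: float = 0.1,
               r_contact: float | None = None,
               elements: tuple[str, str] = ("C", "C")) -> PairScore:
    """b = a_i S_i a_j S_j T e^(−r) + L, with r in Å and unit decay constant."""
    if r <= 0:
        raise ValueError(f"interatomic distance must be positive, got {r}")
    if T is None:
        T = resolve_T(i.polar_class, j.polar_class)
    prod = i.a * i.S * j.a * j.S
    if {i.polar_class, j.polar_class} <= {PolarClass.ACID, PolarClass.BASE,
                                          PolarClass.NEUTRAL}:
        # polar-polar: T carries the sign, applied to the magnitude
        b = T * abs(prod) * np.exp(-r)
    else:
        b = T * prod * np.exp(-r)
    if lj_enabled:
        if r_contact is None:
            r_contact = (VDW_RADII.get(elements[0], 1.7)
                         + VDW_RADII.get(elements[1], 1.7))
        b += lj_clash(r, r_contact, lj_epsilon)
    base_class = classify_interaction(i, j)
    hydrophobic = base_class in (InteractionClass.FAVORABLE_HYDROPHOBIC,
                                 InteractionClass.UNFAVORABLE_HYDROPHOBIC)
    if hydrophobic:
        cls = (InteractionClass.FAVORABLE_HYDROPHOBIC if b > 0
               else InteractionClass.UNFAVORABLE_HYDROPHOBIC)
    else:
        cls = (InteractionClass.FAVORABLE_POLAR if b > 0
               else InteractionClass.UNFAVORABLE_POLAR)
    return PairScore(b=float(b), r=float(r), interaction_class=cls)


# ---------------------------------------------------------------------------
# residue-environment scoring
# ---------------------------------------------------------------------------

def atom_s_values(model: StructureModel, mode: str = "local",
                  probe: float = 1.4, points: int = 960) -> np.ndarray:
    """Per-atom S_i terms.

    "local" (default): Shrake-Rupley area with only the atom's own residue
    as occluder — the local-geometry convention, so buried residues keep
    their interaction strength.  "structure": area in full structural
    context.  "unit": S_i = 1 (parameter-sensitivity runs).
    """
    if mode == "unit":
        return np.ones(len(model))
    cache_key = ("_s_values", mode, probe, points)
    cached = getattr(model, "_s_cache", None)
    if cached is not None and cached[0] == cache_key:
        return cached[1]
    from .accessibility import atom_sasa, atom_sasa_local
    if mode == "local":
        s = atom_sasa_local(model, probe=probe)
    else:
        s = atom_sasa(model, probe=probe, points=points, occluders="all")
    s = np.where(np.isfinite(s), s, 0.0)
    model._s_cache = (cache_key, s)
    return s


def environment_scores(target: ResidueView, model: StructureModel, *,
                       include_lipids: bool = True, cutoff: float = 8.0,
                       table: ParameterTable | None = None,
                       s_values: np.ndarray | None = None,
                       s_mode: str = "sasa",
                       lj_enabled: bool = True,
                       lj_epsilon: float = 0.1) -> list[PairScore]:
    """Score all (target sidechain atom, environment atom) pairs within cutoff.

    The environment is every atom outside the target residue — protein,
    water, and (optionally) lipid.  The `include_lipids` switch produces the
    mL (True) versus mN (False) score variants.
    """
    table = table or ParameterTable()
    if s_values is None:
        s_values = atom_s_values(model, mode=s_mode)
    atoms = model.atoms
    lip = model.is_lipid
    side_idx = target.sidechain_indices
    if side_idx.size == 0:
        return []
    env_mask = np.ones(len(model), dtype=bool)
    env_mask[target.indices] = False
    if not include_lipids:
        env_mask &= ~lip
    env_idx = np.flatnonzero(env_mask)
    if env_idx.size == 0:
        return []
    tree = cKDTree(atoms.coord[env_idx])
    out: list[PairScore] = []
    for ti in side_idx:
        pi_a, pi_class = table.resolve(str(atoms.res_name[ti]),
                                       str(atoms.atom_name[ti]),
                                       str(atoms.element[ti]), bool(lip[ti]))
        params_i = HintAtomParams(pi_a, float(s_values[ti]), pi_class)
        hits = tree.query_ball_point(atoms.coord[ti], cutoff)
        for h in hits:
            ei = int(env_idx[h])
            r = float(np.linalg.norm(atoms.coord[ti] - atoms.coord[ei]))
            if r <= 0:
                continue
            pj_a, pj_class = table.resolve(str(atoms.res_name[ei]),
                                           str(atoms.atom_name[ei]),
                                           str(atoms.element[ei]), bool(lip[ei]))
            params_j = HintAtomParams(pj_a, float(s_values[ei]), pj_class)
            score = score_pair(params_i, params_j, r,
                               lj_enabled=lj_enabled, lj_epsilon=lj_epsilon,
                               elements=(str(atoms.element[ti]),
                                         str(atoms.element[ei])))
            out.append(PairScore(b=score.b, r=score.r,
                                 interaction_class=score.interaction_class,
                                 target_index=int(ti), env_index=ei,
                                 env_is_lipid=bool(lip[ei])))
    return out


def lipid_score_ratio(scores: list[PairScore]) -> float:
    """Σ|b| over lipid pairs / Σ|b| over all pairs, in [0, 1] (0 if no pairs)."""
    total = sum(abs(s.b) for s in scores)
    if total == 0:
        return 0.0
    lipid = sum(abs(s.b) for s in scores if s.env_is_lipid)
    return lipid / total
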