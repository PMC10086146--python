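"""Backbone/sidechain dihedrals, Ramachandran chessboard binning with
residue-specific grid shifts, χ1 parsing, and the canonical CA/CB/HA frame.

The chessboard is an 8x8 grid of 45°x45° cells over (φ, ψ); columns a→h run
along increasing φ and rows 1→8 along increasing ψ, with the per-residue-type
grid shift applied.  The orientation convention is fixed by two anchors:
ideal α-helix angles (−63°, −43°) land in c5 and ideal β-strand angles
(−110°, +130°) land in b1.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._geometry import dihedral, wrap_degrees, wrap_degrees_positive, DegenerateGeometryError
from .config import GRID_SHIFTS
from .structures_io import ResidueView

CELL = 45.0
COLUMNS = "abcdefgh"

#: Torsion atoms defining the parse angle ("χ1" of the parsing scheme).
#: ILE/LEU/PRO use the CA-CB-CG-CD* torsion; VAL the IUPAC N-CA-CB-CG1
#: torsion (computed but never used for parsing).
CHI1_ATOMS = {
    "ILE": ("CA", "CB", "CG1", "CD1"),
    "LEU": ("CA", "CB", "CG", "CD1"),
    "PRO": ("CA", "CB", "CG", "CD"),
    "VAL": ("N", "CA", "CB", "CG1"),
}

PARSE_NONE = "none"


class DihedralError(ValueError):
    """A required atom is missing or the torsion is degenerate."""


@dataclass(frozen=True)
class DihedralSet:
    phi: float       # (-180, 180]
    psi: float       # (-180, 180]
    omega: float     # (-180, 180]; stored, unused downstream
    chi1: float | None  # [0, 360), absent for ALA


@dataclass(frozen=True)
class BinKey:
    residue_type: str
    square: str          # a1..h8
    parse: str           # none | .60 | .180 | .300 | .30m | .30p

    @property
    def label(self) -> str:
        return self.square if self.parse == PARSE_NONE else f"{self.square}{self.parse}"

    def __str__(self):
        return f"{self.residue_type}:{self.label}"


@dataclass(frozen=True)
class CanonicalFrame:
    """Rigid transform x' = R x + t placing CA at the origin, CB on +z and
    HA in the yz-plane with positive y."""

    rotation: np.ndarray
    translation: np.ndarray

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation

    def compose(self, other: "CanonicalFrame") -> "CanonicalFrame":
        """self ∘ other: apply `other` first, then `self`."""
        return CanonicalFrame(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def inverse(self) -> "CanonicalFrame":
        rinv = self.rotation.T
        return CanonicalFrame(rinv, -rinv @ self.translation)


# ---------------------------------------------------------------------------
# dihedrals
# ---------------------------------------------------------------------------

def _coord(res: ResidueView, name: str) -> np.ndarray:
    try:
        return res.coord(name)
    except KeyError as exc:
        raise DihedralError(f"missing atom {name} in {res!r}") from exc


def compute_dihedrals(residue: ResidueView,
                      prev_residue: ResidueView,
                      next_residue: ResidueView) -> DihedralSet:
    """Standard φ/ψ/ω plus the residue type's parse torsion (see CHI1_ATOMS)."""
    try:
        c_prev = _coord(prev_residue, "C")
        n, ca, c = (_coord(residue, x) for x in ("N", "CA", "C"))
        n_next = _coord(next_residue, "N")
        ca_prev = _coord(prev_residue, "CA")
        phi = dihedral(c_prev, n, ca, c)
        psi = dihedral(n, ca, c, n_next)
        omega = dihedral(ca_prev, c_prev, n, ca)
        chi1 = None
        if residue.res_name in CHI1_ATOMS:
            pts = [_coord(residue, x) for x in CHI1_ATOMS[residue.res_name]]
            chi1 = wrap_degrees_positive(dihedral(*pts))
    except DegenerateGeometryError as exc:
        raise DihedralError(str(exc)) from exc
    return DihedralSet(phi=phi, psi=psi, omega=omega, chi1=chi1)


# ---------------------------------------------------------------------------
# chessboard binning
# ---------------------------------------------------------------------------

def chess_square(residue_type: str, phi: float, psi: float) -> str:
    """Map (φ, ψ) to its chess square under the residue type's grid shift.

    Cells are half-open (lower edge inclusive) and wrap periodically; the
    column origin sits at −180° − shift_φ and the row origin at 90° − shift_ψ,
    the unique placement consistent with the c5/b1 anchors.
    """
    shift_phi, shift_psi = GRID_SHIFTS[residue_type]
    col = int(wrap_degrees_positive(phi + 180.0 + shift_phi) // CELL) % 8
    row = int(wrap_degrees_positive(psi - 90.0 + shift_psi) // CELL) % 8
    return f"{COLUMNS[col]}{row + 1}"


def chi1_parse(residue_type: str, chi1: float | None) -> str:
    if residue_type in ("ALA", "VAL"):
        return PARSE_NONE
    if chi1 is None:
        raise DihedralError(f"{residue_type} requires a χ1 angle for parsing")
    chi1 = wrap_degrees_positive(chi1)
    if residue_type in ("ILE", "LEU"):
        if chi1 < 120.0:
            return ".60"
        if chi1 < 240.0:
            return ".180"
        return ".300"
    if residue_type == "PRO":
        return ".30m" if 180.0 <= chi1 < 360.0 else ".30p"
    return PARSE_NONE


def assign_bin(residue_type: str, dihedrals: DihedralSet) -> BinKey:
    return BinKey(
        residue_type=residue_type,
        square=chess_square(residue_type, dihedrals.phi, dihedrals.psi),
        parse=chi1_parse(residue_type, dihedrals.chi1),
    )


# ---------------------------------------------------------------------------
# canonical frame
# ---------------------------------------------------------------------------

def frame_from_coords(ca: np.ndarray, cb: np.ndarray, ha: np.ndarray) -> CanonicalFrame:
    ca, cb, ha = (np.asarray(p, dtype=float) for p in (ca, cb, ha))
    v_cb = cb - ca
    d = np.linalg.norm(v_cb)
    if d < 0.5:
        raise DegenerateGeometryError(f"CA-CB distance {d:.3f} Å is degenerate")
    e_z = v_cb / d
    v_ha = ha - ca
    perp = v_ha - (v_ha @ e_z) * e_z
    norm = np.linalg.norm(perp)
    if norm < 1e-8:
        raise DegenerateGeometryError("HA collinear with CA-CB axis")
    e_y = perp / norm
    e_x = np.cross(e_y, e_z)
    rotation = np.vstack([e_x, e_y, e_z])
    return CanonicalFrame(rotation=rotation, translation=-rotation @ ca)


def align_to_canonical_frame(residue: ResidueView) -> CanonicalFrame:
    """Frame of a residue from its CA, CB and HA atoms (PRO uses its own HA)."""
    try:
        ca = residue.coord("CA")
        cb = residue.coord("CB")
        ha = residue.coord("HA")
    except KeyError as exc:
        raise DihedralError(str(exc)) from exc
    return frame_from_coords(ca, cb, ha)


# ---------------------------------------------------------------------------
# per-residue conformation table
# ---------------------------------------------------------------------------

def conformation_table(model, candidates: list[ResidueView]):
    """TSV-ready per-residue conformation summary (one row per candidate)."""
    import pandas as pd

    rows = []
    for res in candidates:
        prev_res, next_res = model.flanking(res)
        dih = compute_dihedrals(res, prev_res, next_res)
        key = assign_bin(res.res_name, dih)
        rows.append({
            "pdb_id": model.source_id, "chain": res.chain_id,
            "resseq": res.res_id, "type": res.res_name,
            "phi": dih.phi, "psi": dih.psi, "omega": dih.omega,
            "chi1": dih.chi1 if dih.chi1 is not None else np.nan,
            "square": key.square, "parse": key.parse,
        })
    return pd.DataFrame(rows)
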