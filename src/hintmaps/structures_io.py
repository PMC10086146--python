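"""Structure reading/writing, geometric protonation, lipid trimming and
candidate-residue extraction.

The in-memory container wraps a :class:`biotite.structure.AtomArray` and adds
lipid/water flags plus residue-level views.  PDB parsing and writing go
through biotite (altlocs resolved to highest occupancy, first MODEL only);
hydrogen placement is purely geometric, transferring ideal hydrogen positions
from the CCD reference residue via a local least-squares frame.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import biotite.structure as struc
import biotite.structure.info as struc_info
import biotite.structure.io.pdb as pdb_io
from scipy.spatial import cKDTree

from ._geometry import kabsch, DegenerateGeometryError
from .config import PipelineConfig

logger = logging.getLogger(__name__)

BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}
BACKBONE_HYDROGENS = {"H", "H1", "H2", "H3", "HA", "HA2", "HA3", "HXT"}
#: CCD atoms that exist only on capped/terminal forms of a residue.
_TERMINAL_ONLY = {"OXT", "HXT", "H2"}

STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}


class StructureFormatError(ValueError):
    """File could not be parsed as PDB."""


class EmptyStructureError(ValueError):
    """Structure contains no protein atoms."""


@dataclass(frozen=True)
class AtomRecord:
    serial: int
    name: str
    element: str
    residue_name: str
    chain_id: str
    residue_seq: int
    ins_code: str
    xyz: tuple[float, float, float]
    is_lipid: bool
    is_water: bool
    is_hydrogen: bool


@dataclass
class ResidueView:
    """A single residue: global atom indices into its parent model."""

    model: "StructureModel"
    indices: np.ndarray
    chain_id: str
    res_id: int
    ins_code: str
    res_name: str
    chain_pos: int = -1          # position within the chain's residue list
    is_terminal: bool = False

    def __repr__(self):
        return f"<{self.res_name} {self.chain_id}{self.res_id}{self.ins_code.strip()}>"

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.res_id, self.ins_code)

    @property
    def atom_names(self) -> np.ndarray:
        return self.model.atoms.atom_name[self.indices]

    @property
    def coords(self) -> np.ndarray:
        return self.model.atoms.coord[self.indices]

    def has(self, name: str) -> bool:
        return name in self.atom_names

    def coord(self, name: str) -> np.ndarray:
        hit = self.indices[self.atom_names == name]
        if hit.size == 0:
            raise KeyError(f"atom {name} missing from {self!r}")
        return self.model.atoms.coord[hit[0]].astype(float)

    def atom_index(self, name: str) -> int:
        hit = self.indices[self.atom_names == name]
        if hit.size == 0:
            raise KeyError(f"atom {name} missing from {self!r}")
        return int(hit[0])

    @property
    def sidechain_indices(self) -> np.ndarray:
        """Global indices of sidechain atoms (CB onward, incl. sidechain H)."""
        names = self.atom_names
        elements = self.model.atoms.element[self.indices]
        mask = ~np.isin(names, sorted(BACKBONE_ATOMS | BACKBONE_HYDROGENS))
        # safety: never treat another element's stray names as sidechain
        return self.indices[mask & (elements != "")]

    @property
    def heavy_sidechain_indices(self) -> np.ndarray:
        idx = self.sidechain_indices
        return idx[self.model.atoms.element[idx] != "H"]


class StructureModel:
    """Flat atom container with lipid/water flags and residue views."""

    def __init__(self, atoms: struc.AtomArray, source_id: str = "",
                 lipid_names=("DPPC", "DPP", "PC"), water_names=("HOH", "WAT")):
        self.atoms = atoms
        self.source_id = source_id
        self.lipid_names = tuple(lipid_names)
        self.water_names = tuple(water_names)
        self._residues: list[ResidueView] | None = None
        self._by_key: dict | None = None

    # ---- masks -----------------------------------------------------------
    @property
    def is_lipid(self) -> np.ndarray:
        return np.isin(self.atoms.res_name, self.lipid_names)

    @property
    def is_water(self) -> np.ndarray:
        return np.isin(self.atoms.res_name, self.water_names)

    @property
    def is_hydrogen(self) -> np.ndarray:
        return self.atoms.element == "H"

    @property
    def is_protein(self) -> np.ndarray:
        return np.isin(self.atoms.res_name, sorted(STANDARD_AA))

    @property
    def coords(self) -> np.ndarray:
        return self.atoms.coord

    def __len__(self):
        return self.atoms.array_length()

    # ---- residues --------------------------------------------------------
    def residues(self) -> list[ResidueView]:
        if self._residues is None:
            starts = struc.get_residue_starts(
                self.atoms, add_exclusive_stop=True)
            views = []
            chain_counts: dict[str, int] = {}
            for lo, hi in zip(starts[:-1], starts[1:]):
                idx = np.arange(lo, hi)
                chain = str(self.atoms.chain_id[lo])
                view = ResidueView(
                    model=self,
                    indices=idx,
                    chain_id=chain,
                    res_id=int(self.atoms.res_id[lo]),
                    ins_code=str(self.atoms.ins_code[lo]),
                    res_name=str(self.atoms.res_name[lo]),
                )
                if view.res_name in STANDARD_AA:
                    view.chain_pos = chain_counts.get(chain, 0)
                    chain_counts[chain] = view.chain_pos + 1
                views.append(view)
            # terminal flags: first/last protein residue per chain
            for chain, n in chain_counts.items():
                for v in views:
                    if v.chain_id == chain and v.res_name in STANDARD_AA:
                        v.is_terminal = v.chain_pos in (0, n - 1)
            self._residues = views
            self._by_key = {v.key: v for v in views}
        return self._residues

    def protein_residues(self) -> list[ResidueView]:
        return [r for r in self.residues() if r.res_name in STANDARD_AA]

    def residue_by_key(self, chain_id: str, res_id: int, ins_code: str = "") -> ResidueView:
        self.residues()
        return self._by_key[(chain_id, res_id, ins_code)]

    def flanking(self, res: ResidueView) -> tuple[ResidueView | None, ResidueView | None]:
        """Previous/next protein residue in the same chain (by file order)."""
        chain = [r for r in self.protein_residues() if r.chain_id == res.chain_id]
        pos = next(i for i, r in enumerate(chain) if r.key == res.key)
        prev_res = chain[pos - 1] if pos > 0 else None
        next_res = chain[pos + 1] if pos < len(chain) - 1 else None
        return prev_res, next_res

    def to_records(self) -> list[AtomRecord]:
        a = self.atoms
        lip, wat, hyd = self.is_lipid, self.is_water, self.is_hydrogen
        return [
            AtomRecord(
                serial=i + 1, name=str(a.atom_name[i]), element=str(a.element[i]),
                residue_name=str(a.res_name[i]), chain_id=str(a.chain_id[i]),
                residue_seq=int(a.res_id[i]), ins_code=str(a.ins_code[i]),
                xyz=tuple(float(x) for x in a.coord[i]),
                is_lipid=bool(lip[i]), is_water=bool(wat[i]), is_hydrogen=bool(hyd[i]),
            )
            for i in range(len(self))
        ]

    def subset(self, mask: np.ndarray) -> "StructureModel":
        return StructureModel(self.atoms[mask], self.source_id,
                              self.lipid_names, self.water_names)


# ---------------------------------------------------------------------------
# reading / writing
# ---------------------------------------------------------------------------

def read_structure(path: str | Path, config: PipelineConfig | None = None) -> StructureModel:
    """Read a PDB file into a :class:`StructureModel`.

    Altlocs resolve to the highest-occupancy conformer (ties: first record);
    only the first MODEL of multi-model files is used.  Lipids and waters are
    flagged by residue name.
    """
    config = config or PipelineConfig()
    path = Path(path)
    try:
        pdb_file = pdb_io.PDBFile.read(str(path))
        atoms = pdb_file.get_structure(
            model=1, altloc="occupancy", extra_fields=["occupancy"])
    except Exception as exc:  # biotite raises various error types
        raise StructureFormatError(f"cannot parse {path}: {exc}") from exc
    if atoms.array_length() == 0:
        raise EmptyStructureError(f"{path} contains no atoms")
    # fill missing element symbols from atom names
    blank = atoms.element == ""
    if blank.any():
        atoms.element[blank] = struc.infer_elements(atoms[blank])
    model = StructureModel(atoms, source_id=path.stem,
                           lipid_names=tuple(config.lipid_names),
                           water_names=tuple(config.water_names))
    if not model.is_protein.any():
        raise EmptyStructureError(f"{path} contains no protein atoms")
    return model


def write_structure(model: StructureModel, path: str | Path) -> None:
    pdb_file = pdb_io.PDBFile()
    pdb_file.set_structure(model.atoms)
    pdb_file.write(str(path))


# ---------------------------------------------------------------------------
# geometric protonation
# ---------------------------------------------------------------------------

_N_H_LENGTH = 1.01  # Å amide N-H


def _reference(res_name: str):
    try:
        ref = struc_info.residue(res_name)
    except Exception:
        return None
    return ref


def _ref_adjacency(ref) -> dict[int, list[int]]:
    adj: dict[int, list[int]] = {i: [] for i in range(ref.array_length())}
    for i, j, _ in ref.bonds.as_array():
        adj[int(i)].append(int(j))
        adj[int(j)].append(int(i))
    return adj


def _place_amide_h(res: ResidueView, prev_c: np.ndarray) -> np.ndarray:
    n = res.coord("N")
    ca = res.coord("CA")
    u1 = (ca - n) / np.linalg.norm(ca - n)
    u2 = (prev_c - n) / np.linalg.norm(prev_c - n)
    direction = -(u1 + u2)
    direction /= np.linalg.norm(direction)
    return n + _N_H_LENGTH * direction


def _place_terminal_nh3(res: ResidueView) -> list[tuple[str, np.ndarray]]:
    """Three staggered H on a free N-terminus (anti reference: backbone C)."""
    from ._geometry import place_internal
    n, ca, c = res.coord("N"), res.coord("CA"), res.coord("C")
    out = []
    for name, torsion in (("H1", 180.0), ("H2", 60.0), ("H3", -60.0)):
        out.append((name, place_internal(c, ca, n, _N_H_LENGTH, 109.5, torsion)))
    return out


def protonate(model: StructureModel) -> StructureModel:
    """Add missing hydrogens at idealized geometry.

    Hydrogen positions come from the CCD reference residue, transferred by a
    local least-squares frame around each heavy atom; the backbone amide H is
    placed on the bisector opposite CA and the preceding carbonyl C.  Existing
    hydrogens are never moved.  Residues with unknown topology are skipped
    with a warning.
    """
    new_atoms: list[struc.Atom] = []  # (insert_after_index, Atom)
    additions: dict[int, list[struc.Atom]] = {}

    for res in model.protein_residues():
        ref = _reference(res.res_name)
        if ref is None:
            warnings.warn(f"unknown residue topology: {res.res_name}; skipped")
            continue
        adj = _ref_adjacency(ref)
        ref_names = list(ref.atom_name)
        obs_names = set(res.atom_names)
        added: list[tuple[str, np.ndarray]] = []

        prev_res, _ = model.flanking(res)
        # backbone amide hydrogens
        if res.res_name != "PRO" and not obs_names & {"H", "H1", "H2", "H3"}:
            if res.has("N") and res.has("CA") and res.has("C"):
                if prev_res is not None and prev_res.has("C"):
                    added.append(("H", _place_amide_h(res, prev_res.coord("C"))))
                else:
                    added.extend(_place_terminal_nh3(res))

        for xi, xname in enumerate(ref_names):
            if ref.element[xi] == "H" or xname in _TERMINAL_ONLY:
                continue
            if xname == "N" or xname not in obs_names:
                continue
            h_children = [j for j in adj[xi]
                          if ref.element[j] == "H"
                          and ref.atom_name[j] not in _TERMINAL_ONLY]
            missing = [j for j in h_children if ref.atom_name[j] not in obs_names]
            if not missing:
                continue
            # local frame: X + heavy neighbors, extended one shell if needed
            frame = [xi] + [j for j in adj[xi]
                            if ref.element[j] != "H" and ref.atom_name[j] in obs_names]
            if len(frame) < 3:
                for j in list(frame[1:]):
                    frame += [k for k in adj[j]
                              if k not in frame and ref.element[k] != "H"
                              and ref.atom_name[k] in obs_names]
            if len(frame) < 3:
                logger.info("cannot frame H on %s of %r", xname, res)
                continue
            ref_coords = ref.coord[frame]
            obs_coords = np.array([res.coord(ref.atom_name[j]) for j in frame])
            try:
                rot, trans = kabsch(ref_coords, obs_coords)
            except np.linalg.LinAlgError:
                continue
            for j in missing:
                pos = rot @ ref.coord[j] + trans
                added.append((str(ref.atom_name[j]), pos))

        if added:
            last = int(res.indices[-1])
            atom_list = []
            for name, pos in added:
                atom = struc.Atom(
                    pos, chain_id=res.chain_id, res_id=res.res_id,
                    ins_code=res.ins_code, res_name=res.res_name,
                    hetero=False, atom_name=name, element="H")
                atom_list.append(atom)
            additions[last] = atom_list

    if not additions:
        return model

    # splice new hydrogens directly after their residue
    pieces = []
    prev = 0
    order = sorted(additions)
    arr = model.atoms
    for pos in order:
        pieces.append(arr[prev:pos + 1])
        add_arr = struc.array(additions[pos])
        if "occupancy" in arr.get_annotation_categories():
            add_arr.set_annotation(
                "occupancy", np.ones(add_arr.array_length(), dtype=float))
        pieces.append(add_arr)
        prev = pos + 1
    pieces.append(arr[prev:])
    merged = pieces[0]
    for piece in pieces[1:]:
        if piece.array_length():
            merged += piece
    return StructureModel(merged, model.source_id,
                          model.lipid_names, model.water_names)


# ---------------------------------------------------------------------------
# lipid trimming & candidate extraction
# ---------------------------------------------------------------------------

def trim_lipids(model: StructureModel, cutoff: float = 6.0) -> StructureModel:
    """Drop lipid molecules whose nearest approach to protein exceeds `cutoff`.

    Whole-molecule removal only: a lipid is retained iff *any* of its atoms is
    within `cutoff` Å of any protein atom.  Idempotent.
    """
    lip_mask = model.is_lipid
    if not lip_mask.any():
        return model
    prot_coords = model.coords[model.is_protein]
    tree = cKDTree(prot_coords)
    keep = np.ones(len(model), dtype=bool)
    for res in model.residues():
        if not lip_mask[res.indices[0]]:
            continue
        dmin = tree.query(res.coords)[0].min()
        if dmin > cutoff:
            keep[res.indices] = False
    return model.subset(keep)


def extract_candidates(model: StructureModel,
                       residue_types: set[str] | tuple[str, ...]) -> list[ResidueView]:
    """All non-terminal residues of the requested types with complete backbone
    (N, CA, C, O) and complete heavy sidechain."""
    residue_types = set(residue_types)
    out = []
    for res in model.protein_residues():
        if res.res_name not in residue_types or res.is_terminal:
            continue
        names = set(res.atom_names)
        if not {"N", "CA", "C", "O"} <= names:
            logger.info("incomplete backbone: %r", res)
            continue
        ref = _reference(res.res_name)
        required = {
            str(n) for n, e in zip(ref.atom_name, ref.element)
            if e != "H" and n not in _TERMINAL_ONLY and n not in BACKBONE_ATOMS
        }
        if not required <= names:
            logger.info("incomplete sidechain: %r missing %s",
                        res, sorted(required - names))
            continue
        out.append(res)
    return out
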