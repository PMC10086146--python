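"""Bilayer-bound detection from lipid-phosphate bead planes and binning of
membrane-protein residues into soluble (mS), lipid-facing (mL) and core (mC)
sets.

Systems are assumed pre-oriented with the transmembrane axis along z (as in
MemProtMD exports).  A residue is in the membrane iff the z-coordinates of
all three backbone atoms N, CA and O lie inside the closed interval between
the two phosphate-plane means; membrane residues split into mC (pore-lining,
per the residue-wise CSV) and mL (otherwise).
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .structures_io import StructureModel, ResidueView, read_structure, StructureFormatError


class BilayerError(ValueError):
    """Bead planes cannot be determined."""


class ClassificationError(ValueError):
    """A residue lacks the backbone atoms needed for domain classification."""


@dataclass(frozen=True)
class BilayerBounds:
    z_upper: float
    z_lower: float
    sd_upper: float
    sd_lower: float

    def __post_init__(self):
        if not self.z_lower < self.z_upper:
            raise BilayerError("lower bound must lie below upper bound")

    def contains(self, z: float) -> bool:
        return self.z_lower <= z <= self.z_upper


DOMAIN_SOLUBLE = "mS"
DOMAIN_LIPID = "mL"
DOMAIN_CORE = "mC"


def bilayer_bounds_from_z(z: np.ndarray) -> BilayerBounds:
    """Split bead z-coordinates at their median into upper/lower planes and
    return per-plane mean ± sd."""
    z = np.asarray(z, dtype=float)
    mid = float(np.median(z))
    upper = z[z > mid]
    lower = z[z <= mid]
    if len(upper) < 3 or len(lower) < 3:
        raise BilayerError(
            f"need ≥3 beads per plane, got {len(upper)} upper / {len(lower)} lower")
    return BilayerBounds(
        z_upper=float(upper.mean()), z_lower=float(lower.mean()),
        sd_upper=float(upper.std()), sd_lower=float(lower.std()))


def bilayer_bounds(distortions: str | Path | StructureModel) -> BilayerBounds:
    """Bounds from a MemProtMD-style distortions PDB of phosphate beads."""
    if isinstance(distortions, StructureModel):
        z = distortions.coords[:, 2]
    else:
        import biotite.structure.io.pdb as pdb_io
        try:
            pdb_file = pdb_io.PDBFile.read(str(distortions))
            atoms = pdb_file.get_structure(model=1)
        except Exception as exc:
            raise StructureFormatError(
                f"cannot parse distortions file {distortions}: {exc}") from exc
        z = atoms.coord[:, 2]
    return bilayer_bounds_from_z(z)


def read_by_resid_csv(path: str | Path, *, chain_col: str = "chain",
                      resseq_col: str = "resseq",
                      pore_col: str = "pore_lining") -> dict[tuple[str, int], bool]:
    """Residue-wise pore-lining flags; column names are dialect-configurable."""
    df = pd.read_csv(path)
    flags = {}
    for _, row in df.iterrows():
        val = row[pore_col]
        if isinstance(val, str):
            val = val.strip().lower() in ("true", "1", "yes", "t")
        flags[(str(row[chain_col]), int(row[resseq_col]))] = bool(val)
    return flags


def classify_domain(residue: ResidueView, bounds: BilayerBounds,
                    pore_flag: bool = False) -> str:
    """mS / mL / mC label for one residue (closed membrane interval)."""
    try:
        zs = [residue.coord(name)[2] for name in ("N", "CA", "O")]
    except KeyError as exc:
        raise ClassificationError(str(exc)) from exc
    in_membrane = all(bounds.contains(z) for z in zs)
    if not in_membrane:
        return DOMAIN_SOLUBLE
    return DOMAIN_CORE if pore_flag else DOMAIN_LIPID


def classify_model(model: StructureModel, bounds: BilayerBounds,
                   pore_flags: dict[tuple[str, int], bool] | None = None
                   ) -> dict[tuple[str, int, str], str]:
    """Domain label per protein residue; residues absent from the pore CSV
    default to pore_flag = False."""
    pore_flags = pore_flags or {}
    out = {}
    for res in model.protein_residues():
        flag = pore_flags.get((res.chain_id, res.res_id), False)
        out[res.key] = classify_domain(res, bounds, flag)
    return out


def domain_table(labels: dict) -> pd.DataFrame:
    rows = [{"chain": k[0], "resseq": k[1], "ins_code": k[2], "domain": v}
            for k, v in labels.items()]
    return pd.DataFrame(rows)
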