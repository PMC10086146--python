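"""Per-residue sidechain SASA, In/Out burial flags, f_outside aggregation and
LASA (lipid-accessible surface area) reclassification.

SASA uses the Shrake-Rupley rolling-probe algorithm (probe 1.4 Å, 960 sphere
points by default) with protein atoms only as occluders — lipids and waters
are stripped before the calculation, mirroring submission of the bare protein
coordinates.  A residue is "In" when its sidechain area falls below 20% of
the residue type's free (random-coil) reference area, "Out" above 50%, and
indeterminate between; f_outside averages In→0, Out→1, indeterminate→0.5
over a residue collection.  A residue whose interaction score is >10% due to
lipid atoms has its SASA reclassified as a LASA.
"""
from __future__ import annotations

import functools
from dataclasses import dataclass

import numpy as np
import biotite.structure as struc

from .structures_io import StructureModel, ResidueView, _reference

IN, OUT, INDETERMINATE = "In", "Out", "indeterminate"
_FLAG_VALUE = {IN: 0.0, OUT: 1.0, INDETERMINATE: 0.5}


class RadiusError(ValueError):
    """An atom's van-der-Waals radius cannot be resolved."""


@dataclass(frozen=True)
class AccessibilityRecord:
    residue_key: tuple
    residue_type: str
    sasa: float              # sidechain area, Å²
    in_out: str              # In | Out | indeterminate
    lipid_ratio: float       # Σ|b| lipid pairs / Σ|b| all pairs
    is_lasa: bool


# ---------------------------------------------------------------------------
# raw Shrake-Rupley areas
# ---------------------------------------------------------------------------

def atom_sasa(model: StructureModel, probe: float = 1.4, points: int = 960,
              occluders: str = "protein") -> np.ndarray:
    """Per-atom SASA over the full model (non-occluding atoms get 0).

    occluders="protein" strips lipids/waters before the calculation;
    occluders="all" keeps every atom (used for the HINT S_i terms).
    """
    if occluders == "protein":
        mask = model.is_protein
    else:
        mask = np.ones(len(model), dtype=bool)
    sub = model.atoms[mask]
    try:
        areas = struc.sasa(sub, probe_radius=probe, point_number=points,
                           vdw_radii="Single", ignore_ions=False)
    except KeyError as exc:
        raise RadiusError(f"unknown van-der-Waals radius: {exc}") from exc
    out = np.zeros(len(model))
    out[np.flatnonzero(mask)] = np.nan_to_num(areas, nan=0.0)
    return out


def atom_sasa_local(model: StructureModel, probe: float = 1.4,
                    points: int = 240) -> np.ndarray:
    """Per-atom area with only the atom's own residue as occluder.

    This is the "local geometry" S_i term of the HINT score: it reflects how
    much of the atom's surface its bonded context leaves open, independent of
    burial in the protein, so buried residues still carry full interaction
    strength.
    """
    out = np.zeros(len(model))
    for res in model.residues():
        sub = model.atoms[res.indices]
        try:
            areas = struc.sasa(sub, probe_radius=probe, point_number=points,
                               vdw_radii="Single", ignore_ions=False)
        except KeyError as exc:
            raise RadiusError(f"unknown van-der-Waals radius: {exc}") from exc
        out[res.indices] = np.nan_to_num(areas, nan=0.0)
    return out


def compute_sasa(model: StructureModel, probe: float = 1.4,
                 points: int = 960) -> dict[tuple, float]:
    """Sidechain SASA (Å²) per protein residue, protein-only occluders."""
    areas = atom_sasa(model, probe=probe, points=points, occluders="protein")
    out = {}
    for res in model.protein_residues():
        idx = res.sidechain_indices
        out[res.key] = float(areas[idx].sum()) if idx.size else 0.0
    return out


# ---------------------------------------------------------------------------
# reference (free-residue) areas
# ---------------------------------------------------------------------------

@functools.lru_cache(maxsize=None)
def reference_sidechain_area(residue_type: str, probe: float = 1.4,
                             points: int = 960) -> float:
    """Sidechain SASA of the isolated ideal residue (CCD geometry), the
    random-coil denominator for the In/Out ratio."""
    ref = _reference(residue_type)
    if ref is None:
        raise KeyError(f"no reference residue for {residue_type}")
    keep = ~np.isin(ref.atom_name, ("OXT", "HXT", "H2"))
    arr = ref[keep]
    areas = struc.sasa(arr, probe_radius=probe, point_number=points,
                       vdw_radii="Single", ignore_ions=False)
    from .structures_io import BACKBONE_ATOMS, BACKBONE_HYDROGENS
    side = ~np.isin(arr.atom_name, sorted(BACKBONE_ATOMS | BACKBONE_HYDROGENS))
    return float(np.nan_to_num(areas, nan=0.0)[side].sum())


# ---------------------------------------------------------------------------
# records and aggregation
# ---------------------------------------------------------------------------

def in_out_flag(sasa: float, reference: float,
                in_threshold: float = 0.2, out_threshold: float = 0.5) -> str:
    if reference <= 0:
        return INDETERMINATE
    ratio = sasa / reference
    if ratio < in_threshold:
        return IN
    if ratio > out_threshold:
        return OUT
    return INDETERMINATE


def residue_accessibility(residue: ResidueView, sasa: float,
                          lipid_ratio: float = 0.0, *,
                          reference: float | None = None,
                          in_threshold: float = 0.2,
                          out_threshold: float = 0.5,
                          lasa_ratio: float = 0.1) -> AccessibilityRecord:
    """Assemble the accessibility record for one residue; the 0.1
    lipid-score-ratio rule reclassifies its SASA as a LASA."""
    if reference is None:
        reference = reference_sidechain_area(residue.res_name)
    return AccessibilityRecord(
        residue_key=residue.key, residue_type=residue.res_name,
        sasa=float(sasa),
        in_out=in_out_flag(sasa, reference, in_threshold, out_threshold),
        lipid_ratio=float(lipid_ratio),
        is_lasa=lipid_ratio > lasa_ratio)


def f_outside(records) -> float:
    """Buriedness of a residue collection: mean of In→0, Out→1,
    indeterminate→0.5."""
    records = list(records)
    if not records:
        raise ValueError("f_outside of an empty collection is undefined")
    values = [_FLAG_VALUE[r.in_out if isinstance(r, AccessibilityRecord) else r]
              for r in records]
    return float(np.mean(values))


def accessibility_table(records) -> "pd.DataFrame":
    import pandas as pd
    rows = [{"chain": r.residue_key[0], "resseq": r.residue_key[1],
             "type": r.residue_type, "sasa": r.sasa, "in_out": r.in_out,
             "lipid_ratio": r.lipid_ratio, "is_lasa": r.is_lasa}
            for r in records]
    return pd.DataFrame(rows)
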