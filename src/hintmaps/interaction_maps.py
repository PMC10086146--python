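"""Per-residue 3D interaction maps on residue-type boxes.

Each scored atom pair deposits a Gaussian peak of height b_ij at the pair's
midpoint (both atoms first transformed into the residue's canonical frame):

    rho(x, y, z) = sum_ij b_ij * exp(-[(x-x_ij)^2 + (y-y_ij)^2 + (z-z_ij)^2] / sigma)

with sigma = 0.5 (the quotient is taken in Å², exactly as the map formula is
defined).  Deposits are routed to one of four class grids (favorable /
unfavorable × hydrophobic / polar); favorable grids are everywhere ≥ 0 and
unfavorable grids ≤ 0.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .conformation import BinKey, CanonicalFrame
from .hint_core import InteractionClass, PairScore
from .structures_io import StructureModel

#: Box extents (Å) per residue type: ((x0,x1),(y0,y1),(z0,z1)); endpoints are
#: grid points.
BOX_RANGES = {
    "ALA": ((-7.5, 8.5), (-7.5, 8.5), (-7.5, 8.5)),
    "ILE": ((-9.0, 9.0), (-9.0, 9.0), (-7.5, 9.5)),
    "LEU": ((-9.0, 9.0), (-9.0, 9.0), (-7.5, 9.5)),
    "PRO": ((-9.5, 9.5), (-9.5, 9.5), (-7.0, 9.0)),
    "VAL": ((-8.5, 8.5), (-8.5, 8.5), (-7.5, 9.5)),
}

CLASSES = (InteractionClass.FAVORABLE_HYDROPHOBIC,
           InteractionClass.UNFAVORABLE_HYDROPHOBIC,
           InteractionClass.FAVORABLE_POLAR,
           InteractionClass.UNFAVORABLE_POLAR)


@dataclass(frozen=True)
class MapBox:
    residue_type: str
    x_range: tuple[float, float]
    y_range: tuple[float, float]
    z_range: tuple[float, float]
    spacing: float = 0.5

    def axis(self, dim: int) -> np.ndarray:
        lo, hi = (self.x_range, self.y_range, self.z_range)[dim]
        n = int(round((hi - lo) / self.spacing)) + 1
        return lo + self.spacing * np.arange(n)

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(len(self.axis(d)) for d in range(3))

    @property
    def n_points(self) -> int:
        return int(np.prod(self.shape))

    @property
    def volume(self) -> float:
        """Box volume in Å³ (product of axis extents)."""
        return float(np.prod([
            hi - lo for lo, hi in (self.x_range, self.y_range, self.z_range)]))


def make_box(residue_type: str, spacing: float = 0.5) -> MapBox:
    if residue_type not in BOX_RANGES:
        raise KeyError(f"no map box defined for residue type {residue_type}")
    xr, yr, zr = BOX_RANGES[residue_type]
    return MapBox(residue_type, xr, yr, zr, spacing)


@dataclass
class InteractionMapSet:
    """Four scalar class grids on a shared box, plus provenance metadata."""

    box: MapBox
    grids: dict[InteractionClass, np.ndarray]
    bin_key: BinKey | None = None
    residue_id: str = ""
    variant: str = "standard"      # standard | with_lipids | no_lipids

    @classmethod
    def zeros(cls, box: MapBox, **meta) -> "InteractionMapSet":
        grids = {c: np.zeros(box.shape) for c in CLASSES}
        return cls(box=box, grids=grids, **meta)

    def copy(self) -> "InteractionMapSet":
        return InteractionMapSet(
            box=self.box, grids={c: g.copy() for c, g in self.grids.items()},
            bin_key=self.bin_key, residue_id=self.residue_id,
            variant=self.variant)

    def __add__(self, other: "InteractionMapSet") -> "InteractionMapSet":
        out = self.copy()
        for c in CLASSES:
            out.grids[c] = out.grids[c] + other.grids[c]
        return out

    def __sub__(self, other: "InteractionMapSet") -> "InteractionMapSet":
        out = self.copy()
        for c in CLASSES:
            out.grids[c] = out.grids[c] - other.grids[c]
        return out

    def scale(self, factor: float) -> "InteractionMapSet":
        out = self.copy()
        for c in CLASSES:
            out.grids[c] = out.grids[c] * factor
        return out

    def concatenated(self) -> np.ndarray:
        return np.concatenate([self.grids[c].ravel() for c in CLASSES])

    def total_abs(self) -> float:
        return float(sum(np.abs(g).sum() for g in self.grids.values()))

    def character_fractions(self) -> dict[str, float]:
        """Σ|map| per class / Σ|map| over all classes."""
        total = self.total_abs()
        if total == 0:
            return {c.value: 0.0 for c in CLASSES}
        return {c.value: float(np.abs(self.grids[c]).sum() / total)
                for c in CLASSES}


def compute_maps(scores: list[PairScore], frame: CanonicalFrame,
                 box: MapBox, model: StructureModel, *,
                 sigma: float = 0.5, deposit_floor: float = 1e-8,
                 **meta) -> InteractionMapSet:
    """Deposit each pair's Gaussian at its canonical-frame midpoint.

    Grid points where the Gaussian factor falls below `deposit_floor`
    (≈ 3.0 Å from the midpoint at sigma = 0.5) are skipped; contributions
    outside the box are truncated.
    """
    maps = InteractionMapSet.zeros(box, **meta)
    if not scores:
        return maps
    coords = model.atoms.coord
    ax = [box.axis(d) for d in range(3)]
    r_cut = float(np.sqrt(-sigma * np.log(deposit_floor)))
    # pad the candidate slab by one cell so that float jitter in the slice
    # bounds cannot flip a boundary point in or out; the floor test below
    # decides deterministically
    r_search = r_cut + box.spacing
    for s in scores:
        pi = frame.apply(coords[s.target_index])
        pj = frame.apply(coords[s.env_index])
        mid = 0.5 * (pi + pj)
        sl = []
        local = []
        empty = False
        for d in range(3):
            lo = np.searchsorted(ax[d], mid[d] - r_search, side="left")
            hi = np.searchsorted(ax[d], mid[d] + r_search, side="right")
            if hi <= lo:
                empty = True
                break
            sl.append(slice(lo, hi))
            local.append(ax[d][lo:hi] - mid[d])
        if empty:
            continue
        dx2 = local[0][:, None, None] ** 2
        dy2 = local[1][None, :, None] ** 2
        dz2 = local[2][None, None, :] ** 2
        gauss = np.exp(-(dx2 + dy2 + dz2) / sigma)
        gauss[gauss < deposit_floor] = 0.0
        maps.grids[s.interaction_class][sl[0], sl[1], sl[2]] += s.b * gauss
    return maps


# ---------------------------------------------------------------------------
# export / import
# ---------------------------------------------------------------------------

def _meta_dict(m: InteractionMapSet) -> dict:
    return {
        "residue_type": m.box.residue_type,
        "x_range": list(m.box.x_range), "y_range": list(m.box.y_range),
        "z_range": list(m.box.z_range), "spacing": m.box.spacing,
        "bin": None if m.bin_key is None else
            {"residue_type": m.bin_key.residue_type,
             "square": m.bin_key.square, "parse": m.bin_key.parse},
        "residue_id": m.residue_id, "variant": m.variant,
    }


def write_dx(m: InteractionMapSet, cls: InteractionClass, path: str | Path) -> None:
    """OpenDX scalar-field export of one class grid."""
    nx, ny, nz = m.box.shape
    origin = (m.box.x_range[0], m.box.y_range[0], m.box.z_range[0])
    sp = m.box.spacing
    lines = [
        f"object 1 class gridpositions counts {nx} {ny} {nz}",
        f"origin {origin[0]:.3f} {origin[1]:.3f} {origin[2]:.3f}",
        f"delta {sp:.3f} 0 0", f"delta 0 {sp:.3f} 0", f"delta 0 0 {sp:.3f}",
        f"object 2 class gridconnections counts {nx} {ny} {nz}",
        f"object 3 class array type double rank 0 items {m.box.n_points} data follows",
    ]
    flat = m.grids[cls].ravel()
    for i in range(0, flat.size, 3):
        lines.append(" ".join(f"{v:.6e}" for v in flat[i:i + 3]))
    lines.append('attribute "dep" string "positions"')
    lines.append('object "density" class field')
    Path(path).write_text("\n".join(lines) + "\n")


def save_mapset(m: InteractionMapSet, stem: str | Path) -> None:
    """Flat float64 binary (.dat) + JSON sidecar (.json)."""
    stem = Path(stem)
    m.concatenated().astype("<f8").tofile(stem.with_suffix(".dat"))
    stem.with_suffix(".json").write_text(json.dumps(_meta_dict(m), indent=1))


def load_mapset(stem: str | Path) -> InteractionMapSet:
    stem = Path(stem)
    meta = json.loads(stem.with_suffix(".json").read_text())
    box = MapBox(meta["residue_type"], tuple(meta["x_range"]),
                 tuple(meta["y_range"]), tuple(meta["z_range"]),
                 meta["spacing"])
    flat = np.fromfile(stem.with_suffix(".dat"), dtype="<f8")
    per = box.n_points
    grids = {c: flat[i * per:(i + 1) * per].reshape(box.shape)
             for i, c in enumerate(CLASSES)}
    bin_key = None
    if meta["bin"] is not None:
        bin_key = BinKey(**meta["bin"])
    return InteractionMapSet(box=box, grids=grids, bin_key=bin_key,
                             residue_id=meta["residue_id"],
                             variant=meta["variant"])
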