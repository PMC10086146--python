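"""Log-domain map transform and pairwise map-map similarity.

Each grid value G is floored and compressed to A = sign(G) * log10(|G|/F)
when |G|/F > 1 and 0 otherwise (floor F = 1.0 by default), so that both
strong favorable and strong unfavorable interactions survive the transform.
Similarity D(m, n) is the Hodgkin index over the class-concatenated
transformed grids: D = 2 Σ A_m A_n / (Σ A_m² + Σ A_n²), which is exactly
1.0000 for identical maps and penalizes both shape and magnitude divergence.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .interaction_maps import InteractionMapSet, CLASSES, MapBox
from .conformation import BinKey


@dataclass
class TransformedMap:
    box: MapBox
    grids: dict         # per-class A grids
    floor: float = 1.0
    bin_key: BinKey | None = None
    residue_id: str = ""
    variant: str = "standard"

    def concatenated(self, weights: dict | None = None) -> np.ndarray:
        parts = []
        for c in CLASSES:
            w = 1.0 if weights is None else float(weights.get(c, 1.0))
            parts.append(w * self.grids[c].ravel())
        return np.concatenate(parts)


def transform_map(m: InteractionMapSet, F: float = 1.0) -> TransformedMap:
    """Pointwise A = sign(G)·log10(|G|/F) above the floor, else 0."""
    if F <= 0:
        raise ValueError("floor F must be positive")
    grids = {}
    for c in CLASSES:
        g = m.grids[c]
        mag = np.abs(g) / F
        with np.errstate(divide="ignore"):
            a = np.where(mag > 1.0, np.sign(g) * np.log10(np.maximum(mag, 1.0)), 0.0)
        grids[c] = a
    return TransformedMap(box=m.box, grids=grids, floor=F, bin_key=m.bin_key,
                          residue_id=m.residue_id, variant=m.variant)


def similarity(m: TransformedMap, n: TransformedMap,
               weights: dict | None = None) -> float:
    """Hodgkin similarity over the concatenated class grids, in [-1, 1].

    Two identically-zero maps are reported as 1.0 (with a warning); a zero
    map against a nonzero one scores 0.0.
    """
    if m.box.shape != n.box.shape:
        raise ValueError("maps live on different boxes")
    a = m.concatenated(weights)
    b = n.concatenated(weights)
    na = float(a @ a)
    nb = float(b @ b)
    if na == 0.0 and nb == 0.0:
        warnings.warn("similarity of two all-zero maps reported as 1.0")
        return 1.0
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float(2.0 * (a @ b) / (na + nb))


def similarity_matrix(maps: list[TransformedMap],
                      weights: dict | None = None) -> np.ndarray:
    """Symmetric pairwise D matrix with unit diagonal."""
    if not maps:
        raise ValueError("need at least one map")
    shapes = {m.box.shape for m in maps}
    if len(shapes) > 1:
        raise ValueError("maps live on mixed boxes")
    vectors = np.stack([m.concatenated(weights) for m in maps])
    norms = np.einsum("ij,ij->i", vectors, vectors)
    gram = vectors @ vectors.T
    denom = norms[:, None] + norms[None, :]
    n = len(maps)
    out = np.zeros((n, n))
    both_zero = (norms[:, None] == 0) & (norms[None, :] == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(denom > 0, 2.0 * gram / denom, 0.0)
    out[both_zero] = 1.0
    np.fill_diagonal(out, np.where(norms == 0, 1.0, np.diag(out)))
    # exact unit diagonal and exact symmetry
    np.fill_diagonal(out, 1.0)
    return (out + out.T) / 2.0


def export_matrix_tsv(matrix: np.ndarray, ids: list[str], path) -> None:
    import pandas as pd
    pd.DataFrame(matrix, index=ids, columns=ids).to_csv(path, sep="\t")
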