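"""Pipeline orchestration and table-style summaries.

`build_residue_maps` runs the full per-residue chain — candidate extraction,
dihedral binning, canonical-frame alignment, HINT environment scoring,
map deposition and accessibility — for one structure and one dataset variant
(with or without lipid interactions).  `cluster_dataset` clusters the
resulting maps per chess-square/parse bin and summarizes each cluster.
Cross-dataset cluster matching, population boards and the
character-vs-accessibility weighted fits mirror the study's table/figure
summaries.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import PipelineConfig, SUPPORTED_RESIDUES
from . import structures_io as sio
from . import conformation as conf
from . import hint_core
from . import interaction_maps as imaps
from . import map_similarity as msim
from . import clustering as clus
from . import accessibility as acc

logger = logging.getLogger(__name__)


@dataclass
class ResidueMapRecord:
    """Everything the clustering stage needs about one candidate residue."""
    residue_key: tuple
    residue_type: str
    dihedrals: conf.DihedralSet
    bin_key: conf.BinKey
    frame: conf.CanonicalFrame
    mapset: imaps.InteractionMapSet
    accessibility: acc.AccessibilityRecord
    lipid_ratio: float
    canonical_coords: dict          # atom name -> canonical-frame xyz
    domain: str | None = None       # mS/mL/mC for membrane datasets


@dataclass
class BinResult:
    bin_key: conf.BinKey
    records: list[ResidueMapRecord]
    solution: clus.ClusterSolution
    summaries: list[clus.ClusterSummary]


def prepare_model(model: sio.StructureModel,
                  config: PipelineConfig) -> sio.StructureModel:
    """Trim far lipids and add missing hydrogens per the config."""
    model = sio.trim_lipids(model, config.trim_cutoff)
    if config.protonate:
        model = sio.protonate(model)
    return model


def build_residue_maps(model: sio.StructureModel, config: PipelineConfig, *,
                       residue_types=SUPPORTED_RESIDUES,
                       include_lipids: bool = True,
                       variant: str = "standard",
                       candidates: list | None = None,
                       domains: dict | None = None,
                       prepared: bool = False) -> list[ResidueMapRecord]:
    """Per-residue interaction maps and accessibility for one variant.

    Counts in/out of every filtering stage are logged so attrition is
    auditable.
    """
    if not prepared:
        model = prepare_model(model, config)
    candidates = candidates if candidates is not None else \
        sio.extract_candidates(model, set(residue_types))
    logger.info("%s: %d candidate residues", model.source_id, len(candidates))
    table = hint_core.ParameterTable()
    s_values = hint_core.atom_s_values(model, mode=config.s_mode,
                                       probe=config.sasa_probe,
                                       points=config.sasa_points)
    sasa_by_res = acc.compute_sasa(model, probe=config.sasa_probe,
                                   points=config.sasa_points)
    records = []
    n_skipped = 0
    for res in candidates:
        prev_res, next_res = model.flanking(res)
        try:
            dih = conf.compute_dihedrals(res, prev_res, next_res)
            frame = conf.align_to_canonical_frame(res)
        except conf.DihedralError as exc:
            logger.info("skipping %r: %s", res, exc)
            n_skipped += 1
            continue
        bin_key = conf.assign_bin(res.res_name, dih)
        scores = hint_core.environment_scores(
            res, model, include_lipids=include_lipids,
            cutoff=config.pair_cutoff, table=table, s_values=s_values,
            lj_enabled=config.lj_enabled, lj_epsilon=config.lj_epsilon)
        lipid_ratio = hint_core.lipid_score_ratio(scores)
        box = imaps.make_box(res.res_name, config.grid_spacing)
        mapset = imaps.compute_maps(
            scores, frame, box, model, sigma=config.gaussian_sigma,
            deposit_floor=config.deposit_floor, bin_key=bin_key,
            residue_id=f"{model.source_id}:{res.chain_id}{res.res_id}",
            variant=variant)
        record = acc.residue_accessibility(
            res, sasa_by_res[res.key], lipid_ratio,
            in_threshold=config.in_threshold,
            out_threshold=config.out_threshold,
            lasa_ratio=config.lasa_ratio)
        names = res.atom_names
        coords = frame.apply(res.coords)
        canonical = {str(n): coords[i] for i, n in enumerate(names)}
        records.append(ResidueMapRecord(
            residue_key=res.key, residue_type=res.res_name, dihedrals=dih,
            bin_key=bin_key, frame=frame, mapset=mapset,
            accessibility=record, lipid_ratio=lipid_ratio,
            canonical_coords=canonical,
            domain=None if domains is None else domains.get(res.key)))
    logger.info("%s: %d residues mapped, %d skipped",
                model.source_id, len(records), n_skipped)
    return records


def _shared_coords(records: list[ResidueMapRecord],
                   heavy_only: bool) -> list[np.ndarray]:
    """Canonical sidechain coordinates on the atom set shared by all records."""
    name_sets = []
    for r in records:
        names = {n for n in r.canonical_coords
                 if n not in sio.BACKBONE_ATOMS | sio.BACKBONE_HYDROGENS}
        if heavy_only:
            names = {n for n in names if not n.startswith("H")}
        name_sets.append(names)
    shared = sorted(set.intersection(*name_sets)) if name_sets else []
    return [np.stack([r.canonical_coords[n] for n in shared])
            for r in records] if shared else None


def cluster_dataset(records: list[ResidueMapRecord], config: PipelineConfig,
                    seed: int | None = None) -> dict[str, BinResult]:
    """Group records by bin, cluster each bin and summarize the clusters."""
    seed = config.seed if seed is None else seed
    by_bin: dict[str, list[ResidueMapRecord]] = {}
    for r in records:
        by_bin.setdefault(r.bin_key.label, []).append(r)
    out = {}
    for label, recs in sorted(by_bin.items()):
        tmaps = [msim.transform_map(r.mapset, config.transform_floor)
                 for r in recs]
        solution = clus.cluster_bin(tmaps, recs[0].residue_type, seed,
                                    k_max=config.k_max,
                                    restarts=config.kmeans_restarts)
        if config.singleton_recovery:
            solution = clus.recover_singletons(
                solution, config.singleton_threshold_sd)
        summaries = clus.summarize_bin(
            solution,
            raw_maps=[r.mapset for r in recs],
            accessibility=[r.accessibility for r in recs],
            heavy_coords=_shared_coords(recs, heavy_only=True),
            all_coords=_shared_coords(recs, heavy_only=False))
        out[label] = BinResult(recs[0].bin_key, recs, solution, summaries)
    return out


# ---------------------------------------------------------------------------
# cross-dataset cluster matching
# ---------------------------------------------------------------------------

def match_clusters(src: list[clus.ClusterSummary],
                   dst: list[clus.ClusterSummary],
                   floor: float = 1.0) -> pd.DataFrame:
    """For each src cluster, the dst cluster with the most similar weighted
    average map, and that similarity.  Not commutative."""
    if not dst:
        raise ValueError("empty destination cluster set")
    dst_t = [msim.transform_map(s.average_map, floor) for s in dst]
    rows = []
    for s in src:
        st = msim.transform_map(s.average_map, floor)
        sims = [msim.similarity(st, dt) for dt in dst_t]
        best = int(np.argmax(sims))
        rows.append({
            "src_bin": str(s.bin_key), "src_cluster": s.name,
            "dst_bin": str(dst[best].bin_key), "dst_cluster": dst[best].name,
            "metric": float(sims[best]),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# character vs accessibility fits
# ---------------------------------------------------------------------------

def weighted_line_fit(x: np.ndarray, y: np.ndarray,
                      weights: np.ndarray) -> tuple[float, float]:
    """Population-weighted least-squares line y = slope·x + intercept."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if len(np.unique(x)) < 2:
        raise ValueError("need at least two distinct x values for a line fit")
    slope, intercept = np.polyfit(x, y, deg=1, w=np.sqrt(weights))
    return float(slope), float(intercept)


def character_vs_accessibility(summaries: list[clus.ClusterSummary],
                               classes=("favorable_hydrophobic",
                                        "unfavorable_hydrophobic")) -> dict:
    """Per-interaction-class weighted fit of character fraction vs f_outside
    (weights = cluster populations)."""
    x = np.array([s.f_outside for s in summaries])
    w = np.array([s.n_members for s in summaries], dtype=float)
    out = {}
    for cls in classes:
        y = np.array([s.character[cls] for s in summaries])
        slope, intercept = weighted_line_fit(x, y, w)
        out[cls] = {"slope": slope, "intercept": intercept,
                    "weights": w.tolist()}
    return out


# ---------------------------------------------------------------------------
# population boards
# ---------------------------------------------------------------------------

def population_table(records: list[ResidueMapRecord]) -> pd.DataFrame:
    """Per chess-square (and parse) population/accessibility board data."""
    by_bin: dict[str, list[ResidueMapRecord]] = {}
    for r in records:
        by_bin.setdefault(r.bin_key.label, []).append(r)
    rows = []
    for label, recs in sorted(by_bin.items()):
        n = len(recs)
        accs = [r.accessibility for r in recs]
        lasa_members = [a for a in accs if a.is_lasa]
        rows.append({
            "bin": label,
            "square": recs[0].bin_key.square,
            "parse": recs[0].bin_key.parse,
            "count": n,
            "log10_population": float(np.log10(n)),
            "fraction_exposed": acc.f_outside(accs),
            "lasa_fraction": len(lasa_members) / n,
        })
    return pd.DataFrame(rows)


def run_manifest(config: PipelineConfig, **extra) -> dict:
    import hintmaps
    return {"package_version": hintmaps.__version__,
            "parameters": config.to_dict(), **extra}
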