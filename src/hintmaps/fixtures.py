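"""Deterministic synthetic structures and maps for exercising the pipeline.

Peptides are grown residue-by-residue (NeRF) with exact target backbone
angles — (−63°, −43°) for the α-helix, (−110°, +130°) for the β-strand — and
sidechains transferred from the CCD ideal residue, then rotated to requested
rotamer torsions.  Membrane systems emulate a MemProtMD export: a four-helix
bundle spanning the bilayer, simplified DPPC pseudo-lipids packed around it,
phosphate-bead planes at z = ±w, and a residue-wise pore-lining CSV.
Archetype map sets provide planted ground truth for clustering recovery.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import biotite.structure as struc

from ._geometry import place_internal, rotation_about_axis, kabsch, dihedral, \
    wrap_degrees_positive
from .structures_io import StructureModel, _reference, write_structure
from .interaction_maps import make_box, InteractionMapSet, CLASSES
from .hint_core import InteractionClass

HELIX_ANGLES = (-63.0, -43.0)
STRAND_ANGLES = (-110.0, 130.0)

# backbone internal coordinates (Å / degrees)
_B_C_N, _B_N_CA, _B_CA_C, _B_C_O = 1.329, 1.458, 1.525, 1.231
_A_CA_C_N, _A_C_N_CA, _A_N_CA_C, _A_CA_C_O = 116.2, 121.7, 111.2, 120.8


@dataclass
class FixtureSpec:
    kind: str = "helix"                  # helix | strand
    n_residues: int = 18
    sequence: str | list[str] = "ALA"    # single code repeated, or list
    seed: int = 0
    noise_sd: float = 0.0                # Å, Gaussian coordinate noise
    bilayer_half_width: float = 15.0     # Å
    bead_sd: float = 0.0                 # z-noise of phosphate beads
    n_lipids_per_leaflet: int = 10
    include_hydrogens: bool = False
    chain_id: str = "A"
    #: target CA-CB-CG-CD parse torsion per residue type (ILE/LEU); PRO
    #: pucker is selected by the sign (".30m" → negative).
    parse_torsions: dict = field(default_factory=dict)


def _sequence_list(spec: FixtureSpec) -> list[str]:
    if isinstance(spec.sequence, str):
        return [spec.sequence] * spec.n_residues
    seq = list(spec.sequence)
    if len(seq) != spec.n_residues:
        raise ValueError("sequence length must equal n_residues")
    return seq


# ---------------------------------------------------------------------------
# peptide construction
# ---------------------------------------------------------------------------

def _backbone(phi_psi: tuple[float, float], n_res: int) -> list[dict]:
    """N/CA/C/O coordinates for every residue at exact (φ, ψ), ω = 180°."""
    phi, psi = phi_psi
    residues = []
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([_B_N_CA, 0.0, 0.0])
    ang = np.radians(180.0 - _A_N_CA_C)
    c0 = ca0 + _B_CA_C * np.array([np.cos(ang), np.sin(ang), 0.0])
    residues.append({"N": n0, "CA": ca0, "C": c0})
    for i in range(1, n_res):
        prev = residues[-1]
        n = place_internal(prev["N"], prev["CA"], prev["C"],
                           _B_C_N, _A_CA_C_N, psi)
        ca = place_internal(prev["CA"], prev["C"], n,
                            _B_N_CA, _A_C_N_CA, 180.0)
        c = place_internal(prev["C"], n, ca, _B_CA_C, _A_N_CA_C, phi)
        residues.append({"N": n, "CA": ca, "C": c})
    # carbonyl O: trans to the next N (or to the chain direction at the end)
    for i, res in enumerate(residues):
        if i + 1 < n_res:
            nxt_n = residues[i + 1]["N"]
            tor = dihedral(res["N"], res["CA"], res["C"], nxt_n) + 180.0
        else:
            tor = psi + 180.0
        res["O"] = place_internal(res["N"], res["CA"], res["C"],
                                  _B_C_O, _A_CA_C_O, tor)
    return residues


def _sidechain_atoms(res_name: str, backbone: dict, parse_target: float | None,
                     include_hydrogens: bool) -> list[tuple[str, str, np.ndarray]]:
    """(name, element, xyz) for sidechain (and optionally H) atoms, from the
    CCD ideal residue superposed on N/CA/C, with rotamer adjustments."""
    ref = _reference(res_name)
    if ref is None:
        return []
    keep = ~np.isin(ref.atom_name, ("OXT", "HXT", "H2"))
    if not include_hydrogens:
        keep &= ref.element != "H"
    ref = ref[keep]
    names = list(ref.atom_name)
    try:
        tri = [names.index(x) for x in ("N", "CA", "C")]
    except ValueError:
        return []
    rot, trans = kabsch(ref.coord[tri],
                        np.stack([backbone["N"], backbone["CA"], backbone["C"]]))
    coords = ref.coord @ rot.T + trans
    pos = {n: coords[i] for i, n in enumerate(names)}

    def rotate_beyond(axis_a: str, axis_b: str, moving: list[str], angle: float):
        axis = pos[axis_b] - pos[axis_a]
        rmat = rotation_about_axis(axis, angle)
        for n in moving:
            if n in pos:
                pos[n] = pos[axis_b] + rmat @ (pos[n] - pos[axis_b])

    if parse_target is not None and res_name in ("ILE", "LEU"):
        cg = "CG1" if res_name == "ILE" else "CG"
        moving = {"ILE": ["CD1", "HD11", "HD12", "HD13", "HG12", "HG13"],
                  "LEU": ["CD1", "CD2", "HG",
                          "HD11", "HD12", "HD13", "HD21", "HD22", "HD23"]}[res_name]
        current = dihedral(pos["CA"], pos["CB"], pos[cg], pos["CD1"])
        rotate_beyond("CB", cg, moving, current - parse_target)
        achieved = dihedral(pos["CA"], pos["CB"], pos[cg], pos["CD1"])
        if abs(((achieved - parse_target) + 180.0) % 360.0 - 180.0) > 1.0:
            rotate_beyond("CB", cg, moving, 2.0 * (parse_target - current))
    if parse_target is not None and res_name == "PRO":
        # pucker the ring: rotate CG about the CB-CD axis (preserves both of
        # CG's ring bonds) until CA-CB-CG-CD hits the target torsion
        axis_a, axis_b = pos["CB"], pos["CD"]
        best_angle, best_err = 0.0, np.inf
        for angle in np.arange(-90.0, 90.0, 0.25):
            rmat = rotation_about_axis(axis_b - axis_a, angle)
            cg_try = axis_a + rmat @ (pos["CG"] - axis_a)
            tor = dihedral(pos["CA"], pos["CB"], cg_try, pos["CD"])
            err = abs(((tor - parse_target) + 180.0) % 360.0 - 180.0)
            if err < best_err:
                best_err, best_angle = err, angle
        rmat = rotation_about_axis(axis_b - axis_a, best_angle)
        for nm in ("CG", "HG2", "HG3"):
            if nm in pos:
                pos[nm] = axis_a + rmat @ (pos[nm] - axis_a)

    skip = {"N", "CA", "C", "O"}
    out = []
    for i, n in enumerate(names):
        if n in skip:
            continue
        out.append((n, str(ref.element[i]), pos[n]))
    return out


def build_peptide(spec: FixtureSpec) -> StructureModel:
    """Ideal peptide with exact backbone angles and requested rotamers."""
    angles = HELIX_ANGLES if spec.kind == "helix" else STRAND_ANGLES
    seq = _sequence_list(spec)
    backbone = _backbone(angles, spec.n_residues)
    atoms = []
    for i, (res_name, bb) in enumerate(zip(seq, backbone), start=1):
        for name in ("N", "CA", "C", "O"):
            atoms.append(struc.Atom(bb[name], chain_id=spec.chain_id,
                                    res_id=i, res_name=res_name, hetero=False,
                                    atom_name=name, element=name[0]))
        parse = spec.parse_torsions.get(res_name)
        for name, element, xyz in _sidechain_atoms(
                res_name, bb, parse, spec.include_hydrogens):
            atoms.append(struc.Atom(xyz, chain_id=spec.chain_id, res_id=i,
                                    res_name=res_name, hetero=False,
                                    atom_name=name, element=element))
    arr = struc.array(atoms)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        arr.coord = arr.coord + rng.normal(0.0, spec.noise_sd, arr.coord.shape)
    return StructureModel(arr, source_id=f"fixture_{spec.kind}")


# ---------------------------------------------------------------------------
# membrane system
# ---------------------------------------------------------------------------

#: simplified DPPC: phosphate/choline head + glycerol + two 4-carbon tails,
#: built headgroup-up with the head N at the local origin
_LIPID_TEMPLATE = [
    ("N", "N", (0.0, 0.8, 0.5)),
    ("P", "P", (0.0, 0.0, -0.7)),
    ("O1", "O", (0.9, -0.6, -1.2)),
    ("O2", "O", (-0.9, -0.6, -1.2)),
    ("C1", "C", (0.0, 0.4, -2.2)),
    ("C2", "C", (-0.7, 0.0, -3.4)),
    ("C3", "C", (-0.7, 0.4, -4.8)),
    ("C4", "C", (-0.7, 0.0, -6.2)),
    ("C5", "C", (-0.7, 0.4, -7.6)),
    ("C6", "C", (0.7, 0.0, -3.4)),
    ("C7", "C", (0.7, 0.4, -4.8)),
    ("C8", "C", (0.7, 0.0, -6.2)),
    ("C9", "C", (0.7, 0.4, -7.6)),
]


def _helix_along_z(spec: FixtureSpec, seq: list[str], chain_id: str,
                   flip: bool) -> struc.AtomArray:
    sub = FixtureSpec(kind="helix", n_residues=len(seq), sequence=seq,
                      seed=spec.seed, include_hydrogens=spec.include_hydrogens,
                      chain_id=chain_id, parse_torsions=spec.parse_torsions)
    model = build_peptide(sub)
    arr = model.atoms
    ca = arr.coord[arr.atom_name == "CA"]
    axis = ca[-1] - ca[0]
    axis /= np.linalg.norm(axis)
    target = np.array([0.0, 0.0, -1.0 if flip else 1.0])
    v = np.cross(axis, target)
    s = np.linalg.norm(v)
    c = float(axis @ target)
    if s < 1e-9:
        rot = np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        rot = np.eye(3) + vx + vx @ vx * ((1 - c) / s ** 2)
    centroid = ca.mean(axis=0)
    arr.coord = (arr.coord - centroid) @ rot.T
    return arr


def build_membrane_system(spec: FixtureSpec
                          ) -> tuple[StructureModel, StructureModel, pd.DataFrame]:
    """Four-helix bundle + pseudo-lipids + phosphate-bead planes + pore CSV.

    The bundle spans z ∈ [−w−5, w+5] for bilayer half-width w; helices sit at
    radius 7.5 Å around the z-axis (chains A-D, antiparallel).  Lipids pack
    in two leaflets with headgroups near |z| = w; bead planes carry Gaussian
    z-noise of sd `spec.bead_sd`.  The CSV flags membrane residues whose
    sidechain points toward the bundle axis as pore-lining.
    """
    rng = np.random.default_rng(spec.seed)
    w = spec.bilayer_half_width
    span = 2.0 * (w + 5.0)
    n_res = max(8, int(round(span / 1.5)))
    base_seq = ["LEU", "ALA", "ILE", "VAL", "ALA", "LEU"]
    seq = [base_seq[i % len(base_seq)] for i in range(n_res)]

    radius = 7.5
    pieces = []
    for k, chain in enumerate("ABCD"):
        arr = _helix_along_z(spec, seq, chain, flip=(k % 2 == 1))
        theta = np.pi / 2.0 * k
        arr.coord = arr.coord + np.array(
            [radius * np.cos(theta), radius * np.sin(theta), 0.0])
        pieces.append(arr)
    bundle = pieces[0]
    for p in pieces[1:]:
        bundle += p

    # pseudo-lipids around the bundle
    lipid_atoms = []
    res_id = 1
    lipid_radius = radius + 7.0
    for leaflet, zsign in (("upper", 1.0), ("lower", -1.0)):
        for li in range(spec.n_lipids_per_leaflet):
            theta = 2.0 * np.pi * li / spec.n_lipids_per_leaflet
            origin = np.array([lipid_radius * np.cos(theta),
                               lipid_radius * np.sin(theta),
                               zsign * w])
            for name, element, local in _LIPID_TEMPLATE:
                local = np.array(local)
                if zsign < 0:
                    local = local * np.array([1.0, 1.0, -1.0])
                # "DPP": DPPC truncated to the PDB 3-character residue
                # field; it is in the default lipid-name whitelist
                lipid_atoms.append(struc.Atom(
                    origin + local, chain_id="L", res_id=res_id,
                    res_name="DPP", hetero=True, atom_name=name,
                    element=element))
            res_id += 1
    full = bundle + struc.array(lipid_atoms)
    if spec.noise_sd > 0:
        full.coord = full.coord + rng.normal(0.0, spec.noise_sd, full.coord.shape)
    model = StructureModel(full, source_id="fixture_membrane")

    # phosphate-bead distortion planes
    beads = []
    grid = np.arange(-lipid_radius - 4.0, lipid_radius + 4.1, 4.0)
    for zsign in (1.0, -1.0):
        for x in grid:
            for y in grid:
                z = zsign * w + rng.normal(0.0, spec.bead_sd)
                beads.append(struc.Atom(np.array([x, y, z]), chain_id="X",
                                        res_id=1, res_name="PO4", hetero=True,
                                        atom_name="P", element="P"))
    distortions = StructureModel(struc.array(beads),
                                 source_id="fixture_distortions")

    # pore-lining flags: membrane residues with CB pointing toward the axis
    rows = []
    for res in model.protein_residues():
        try:
            ca = res.coord("CA")
            cb = res.coord("CB")
        except KeyError:
            continue
        inward = np.array([-ca[0], -ca[1], 0.0])
        norm = np.linalg.norm(inward)
        pointing_in = norm > 0 and (cb - ca)[:2] @ inward[:2] > 0
        in_membrane = abs(ca[2]) <= w
        rows.append({"chain": res.chain_id, "resseq": res.res_id,
                     "pore_lining": bool(pointing_in and in_membrane)})
    by_resid = pd.DataFrame(rows)
    return model, distortions, by_resid


def write_membrane_fixture(spec: FixtureSpec, outdir: str | Path) -> dict[str, Path]:
    """Emit the PDB + distortions PDB + by-resid CSV trio."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    model, distortions, by_resid = build_membrane_system(spec)
    paths = {
        "structure": outdir / "membrane.pdb",
        "distortions": outdir / "membrane-distortions.pdb",
        "by_resid": outdir / "membrane-by-resid.csv",
    }
    write_structure(model, paths["structure"])
    write_structure(distortions, paths["distortions"])
    by_resid.to_csv(paths["by_resid"], index=False)
    return paths


# ---------------------------------------------------------------------------
# archetype maps
# ---------------------------------------------------------------------------

def _render_blobs(box, blobs) -> InteractionMapSet:
    maps = InteractionMapSet.zeros(box)
    ax = [box.axis(d) for d in range(3)]
    for cls, center, amplitude, width in blobs:
        dx2 = (ax[0][:, None, None] - center[0]) ** 2
        dy2 = (ax[1][None, :, None] - center[1]) ** 2
        dz2 = (ax[2][None, None, :] - center[2]) ** 2
        maps.grids[cls] += amplitude * np.exp(-(dx2 + dy2 + dz2) / width)
    return maps


def build_archetype_maps(k: int, n_per: int, seed: int, *,
                         residue_type: str = "ALA",
                         noise: float = 0.5,
                         n_blobs: int = 4
                         ) -> tuple[list[InteractionMapSet], np.ndarray]:
    """k smooth archetype map sets plus n_per noisy copies each.

    Copies jitter the archetype's Gaussian blob centers (sd = `noise` Å) and
    amplitudes (10% multiplicative), preserving each class grid's sign.
    Returns (maps, labels) with len(maps) == k * n_per.
    """
    if k < 1:
        raise ValueError("k must be ≥ 1")
    rng = np.random.default_rng(seed)
    box = make_box(residue_type)
    lo = np.array([box.x_range[0], box.y_range[0], box.z_range[0]]) + 2.0
    hi = np.array([box.x_range[1], box.y_range[1], box.z_range[1]]) - 2.0
    sign = {InteractionClass.FAVORABLE_HYDROPHOBIC: 1.0,
            InteractionClass.UNFAVORABLE_HYDROPHOBIC: -1.0,
            InteractionClass.FAVORABLE_POLAR: 1.0,
            InteractionClass.UNFAVORABLE_POLAR: -1.0}
    archetypes = []
    for _ in range(k):
        blobs = []
        for cls in CLASSES:
            for _ in range(n_blobs):
                center = rng.uniform(lo, hi)
                amplitude = sign[cls] * rng.uniform(20.0, 120.0)
                width = rng.uniform(1.0, 3.0)
                blobs.append((cls, center, amplitude, width))
        archetypes.append(blobs)
    maps, labels = [], []
    for ai, blobs in enumerate(archetypes):
        for ci in range(n_per):
            jittered = []
            amp_sd = 0.2 * noise   # amplitude jitter scales with blob jitter
            for cls, center, amplitude, width in blobs:
                c2 = center + rng.normal(0.0, noise, 3)
                a2 = amplitude * max(0.05, 1.0 + rng.normal(0.0, amp_sd))
                jittered.append((cls, c2, a2, width))
            m = _render_blobs(box, jittered)
            m.residue_id = f"arch{ai}_copy{ci}"
            maps.append(m)
            labels.append(ai)
    return maps, np.array(labels)


def render_archetype(blob_seed_maps: InteractionMapSet) -> InteractionMapSet:
    return blob_seed_maps


def build_archetypes_only(k: int, seed: int, *, residue_type: str = "ALA",
                          n_blobs: int = 4) -> list[InteractionMapSet]:
    """The noiseless archetype maps themselves (labels 0..k-1 in order)."""
    maps, _ = build_archetype_maps(k, 1, seed, residue_type=residue_type,
                                   noise=0.0, n_blobs=n_blobs)
    return maps
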