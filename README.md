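# hintmaps

Hydropathic 3D interaction-map libraries for the small aliphatic residues
(ALA, ILE, LEU, PRO, VAL) in soluble and membrane proteins.

Residue sidechains do not interact with their surroundings generically: each
backbone conformation and rotamer prefers a characteristic constellation of
favorable/unfavorable hydrophobic and polar contacts — a *hydropathic
valence*. `hintmaps` makes that constellation explicit. It scores every
sidechain–environment atom pair with the HINT hydropathic forcefield,
deposits the scores as 3D Gaussian peaks in a canonical residue frame, bins
residues by backbone conformation, clusters the resulting maps into averaged
interaction profiles, and — for membrane proteins — separates water-facing,
lipid-facing, and pore-facing residues, including lipid-accessible surface
area (LASA) bookkeeping. It is aimed at structural bioinformaticians
building backbone-dependent interaction libraries and at modellers who need
quantitative environment profiles for transmembrane residues.

## The model

**Pair scoring.** The HINT score for atoms *i* and *j* at distance *r* (Å):

    b_ij = a_i S_i a_j S_j T_ij e^(−r) + L_ij

where *a* is the signed hydrophobic atom constant (positive hydrophobic,
negative polar), *S* the atom's local solvent-accessible surface area,
*T_ij* ∈ {−1, 0, +1} fixes the sign for Lewis acid/base pairings, and
*L_ij* is a short-range 6-12 clash penalty. Pairs are labelled one of four
classes: favorable/unfavorable × hydrophobic/polar.

**Maps.** Each pair deposits a Gaussian at the pair midpoint, after both
atoms are moved into the canonical frame (CA at the origin, CA→CB along +z,
CA–HA in the yz-plane):

    rho(x,y,z) = Σ b_ij exp(−[(x−x_ij)² + (y−y_ij)² + (z−z_ij)²] / σ),  σ = 0.5

on residue-type-specific grids with 0.5 Å spacing (ALA: 35,937 points /
4096 Å³; ILE/LEU: 47,915; PRO: 50,193 / 5,776 Å³; VAL: 42,875), one grid
per interaction class.

**Binning.** Residues are binned on an 8×8 "chessboard" over the
Ramachandran plot (45° × 45° squares `a1`–`h8`; grid shifted by (−20°, −25°)
in (φ, ψ), (−35°, −5°) for proline), with ILE/LEU squares further parsed by
χ1 into `.60`/`.180`/`.300` and PRO into `.30p`/`.30m`. The ideal α-helix
(−63°, −43°) falls in `c5`; the β-strand (−110°, +130°) in `b1`.

**Similarity and clustering.** Maps are floored and log-compressed,
A = sign(G)·log10(|G|/F) for |G|/F > 1 (F = 1), and compared with the
Hodgkin index D(m,n) = 2ΣA_m A_n / (ΣA_m² + ΣA_n²), which is 1.0000 for
identical maps. Each bin's maps are k-means-clustered on the rows of their
similarity matrix (k ≤ 4 for ALA, 9 for ILE/LEU/VAL, 6 for PRO; bins of ≤ 4
maps are simply averaged). Cluster averages weight members by
w = exp(−d²/σ²) with σ = d_max/8, and each cluster is named by its
*exemplar*, the member closest to the centroid.

**Membrane domains and accessibility.** Bilayer extents come from the mean
z of lipid-phosphate bead planes (MemProtMD-style "distortions" files). A
residue is transmembrane iff N, CA and O all lie between those bounds;
pore-lining flags (residue-wise CSV) split transmembrane residues into core
(mC) vs lipid-facing (mL), everything else being mS. Sidechain SASA is
Shrake–Rupley; a residue whose interaction score is > 10 % due to lipid
atoms has its SASA reclassified as LASA. The `f_outside` buriedness of a
residue collection averages In→0, Out→1, indeterminate→0.5.

## Worked example

Everything runs on synthetic structures; no downloads are needed.

```python
import hintmaps as hm

cfg = hm.PipelineConfig()
model = hm.build_peptide(hm.FixtureSpec(kind="helix", n_residues=18,
                                        sequence="ALA", seed=0, noise_sd=0.05))
records = hm.build_residue_maps(model, cfg)
res = records[0]
print(f"{len(records)} candidate residues; first bin: {res.bin_key}")
print(f"phi={res.dihedrals.phi:.1f}  psi={res.dihedrals.psi:.1f}")

results = hm.cluster_dataset(records, cfg, seed=1)
for label, br in results.items():
    for s in br.summaries:
        print(f"bin {label}  cluster {s.name}: {s.relative_fraction:.1f}% "
              f"of bin, SASA {s.mean_sasa:.1f}±{s.sd_sasa:.1f} A^2, "
              f"heavy-atom RMSD {s.rmsd_heavy:.3f} A")
```

prints

```
16 candidate residues; first bin: ALA:c5
phi=-63.6  psi=-47.9
bin b5  cluster 2: 100.0% of bin, SASA 48.7±0.6 A^2, heavy-atom RMSD 0.089 A
bin c5  cluster 1: 15.4% of bin, SASA 65.7±0.9 A^2, heavy-atom RMSD 0.019 A
bin c5  cluster 8: 38.5% of bin, SASA 49.3±0.6 A^2, heavy-atom RMSD 0.078 A
bin c5  cluster 2: 7.7% of bin, SASA 52.7±0.0 A^2, heavy-atom RMSD 0.000 A
bin c5  cluster 11: 38.5% of bin, SASA 48.8±1.1 A^2, heavy-atom RMSD 0.101 A
```

The jittered polyalanine helix bins almost entirely into `c5` (one residue
crosses into `b5`), and the `c5` maps split into clusters that differ mainly
in how exposed the methyl sidechain is — the fractions sum to 100 % of the
bin, and the small heavy-atom RMSDs confirm tight geometric clusters.

The same pipeline is scriptable from the shell:

```sh
hintmaps fixtures --kind membrane --seed 3 --out fx     # PDB + distortions + CSV
hintmaps bin fx/membrane.pdb --out bins.tsv             # dihedrals + chess squares
hintmaps membrane fx/membrane.pdb fx/membrane-distortions.pdb \
    --by-resid fx/membrane-by-resid.csv --out domains.tsv
hintmaps cluster fx/membrane.pdb --seed 1 --out cl      # per-bin cluster tables
```

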