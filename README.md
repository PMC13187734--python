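# ldquant

Quantification suite for studies of selective motor-protein removal from
lipid droplets (LDs). LDs are the only cytosolic organelle bounded by a
phospholipid *monolayer*; a peptide that mimics a motor's monolayer-binding
domain can strip that motor from LDs while sparing bilayer organelles.
Testing that idea takes quantitative readouts at four scales — cells,
single reconstituted vesicles, molecular trajectories, and whole larvae —
and this package implements all of them as a tested, reusable library with
synthetic ground-truth generators for every input class.

## What it computes

**Radial droplet dispersal, `D_F`.** For a droplet centroid inside a
segmented cell, with Euclidean distance transforms `d_nuc` (distance to the
nucleus) and `d_bnd` (distance to the cell boundary),

```
D_F = d_nuc / (d_nuc + d_bnd)
```

so `D_F = 0` means perinuclear and `D_F = 1` means peripheral. In a
concentric circular cell (outer radius R, nucleus radius r) this reduces to
the radial fraction `(rho − r)/(R − r)`, but the distance-transform form
works for arbitrary cell shapes. A companion statistic reports the
peripheral-band to whole-cell intensity ratio of a second organelle channel.

**Bead-supported membrane retention.** Fluorescent membranes on latex beads
(supported lipid monolayers, SLM, or bilayers, SLB) are detected as rings;
the retention ratio per membrane type is

```
R = mean(ring intensity after treatment) / mean(ring intensity before)
```

with delta-method or bootstrap uncertainty. A monolayer holds half the
phospholipid of a bilayer at equal surface area (`monolayer_area_normalization`).

**Trajectory contact statistics.** From per-frame particle tables (native
CSV dialect or any MDAnalysis-readable format): the lipid occupancy `O_ij`
(time fraction residue *j* spends within 0.7 nm of any lipid of class *i*),
the class-averaged `⟨O⟩_j`, the monolayer-minus-bilayer difference
`Δ⟨O⟩_j` with a >5 % reporting filter, the lipid fraction
`L_f = L_n / N` and its distribution `P(L_f)`, area per lipid, membrane
thickness, Kabsch-superposed backbone RMSD, and secondary-structure content
summaries. Contacts use minimum-image periodicity in the membrane plane
only.

**Colocalization & morphometry.** Pearson and Manders M1/M2 coefficients,
Laplacian-of-Gaussian droplet counting, and fold changes of counts with
bootstrap CIs.

**Organism readouts.** Fluorescence calibration lines with inverse
prediction (peptide concentration from lysate fluorescence), larval track
metrics (total distance, mean angular speed during motion), first-stop
zones on concentric ring schemes, and pooling-design bookkeeping.

Every generator in `ldquant.synthetic` records ground truth (true per-droplet
dispersal, encoded retention, per-frame contact indicators, true path
lengths), so each measurement is tested by parameter recovery.

## Worked example

```python
import numpy as np
from ldquant import synthetic as S, dispersal as D, beads as B

for label, target in (("control (peripheral LDs)", 0.85), ("peptide-treated", 0.45)):
    scene = S.gen_cell_scene(S.CellSceneParams(n_cells=3, n_droplets_per_cell=40,
                                               dispersal_target=target, seed=11))
    cells, droplets = D.segment_scene(scene.image, scene.channel_roles)
    by_id = {c.cell_id: c for c in cells}
    for d in droplets:
        if d.cell_id in by_id:
            d.d_f = D.compute_df(by_id[d.cell_id], d.centroid)
    summary, _ = D.df_summary([d for d in droplets if np.isfinite(d.d_f)])
    print(f"{label}: mean D_F = {summary.mean_d_f.mean():.2f} "
          f"(SD {summary.sd_d_f.mean():.2f}, {int(summary.n.sum())} droplets)")

scene = S.gen_bead_scene(S.BeadSceneParams(n_beads=50, image_size=(1024, 1024),
                                           retention_true=0.23, noise_sd=5.0, seed=31))
det = [((r.row, r.col), r.radius) for r in scene.truth.itertuples()]
rr = B.retention_ratio(B.measure_beads(scene.before, det),
                       B.measure_beads(scene.after, det), label="R_SLM")
print(f"{rr.label} = {rr.ratio:.2f} (n = {rr.n_before} beads/arm)")
```

prints

```
control (peripheral LDs): mean D_F = 0.86 (SD 0.05, 64 droplets)
peptide-treated: mean D_F = 0.47 (SD 0.09, 60 droplets)
R_SLM = 0.24 (n = 50 beads/arm)
```

The first two lines recover the dispersal the generator planted (droplets
segmented from the rendered images, not read from the truth table): control
cells keep droplets peripheral (high `D_F`), treatment redistributes them
inward. The last line recovers the encoded kinesin retention of 0.23 from
50 noisy bead rings per arm — i.e. only ~23 % of the motor signal remains
on monolayer beads after treatment.

The same flows are scriptable from a shell, e.g.

```
ldquant fixtures cells --seed 3 --out scene/
ldquant dispersal run --image scene/scene.tif --channels scene/channels.json --out out/
ldquant organism pooling --per-replicate 30 --replicates 3 --conditions 3
```

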