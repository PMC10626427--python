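# mtlumen

Quantitative analysis of **luminal actin/cofilactin filaments inside
microtubules** from cryo-electron tomography-style data.

Microtubules in cellular cryo-tomograms occasionally contain a second
filament running inside their ~15 nm lumen. Deciding what that filament is —
bare F-actin or cofilin-decorated actin (cofilactin) — and quantifying how
often it occurs requires a chain of measurements on noisy, missing-wedge
corrupted 3D data: classifying each microtubule's protofilament number and
polarity from per-particle alignment votes, measuring filament cross-over
distances from layer lines in Fourier space, grid-searching helical symmetry
(twist/rise), and aggregating per-filament statistics across replicates.
`mtlumen` implements this pipeline as a tested Python library with a thin
CLI, together with a synthetic-data generator that produces every input with
known ground truth, so each stage can be validated end to end.

## The quantities at the core

* **Helical symmetry.** A filament is a 1-start helix: subunit *k* sits at
  azimuth *k*·twist and height *k*·rise. Cofilactin has twist ≈ −161.8° and
  rise ≈ 28.5 Å; bare F-actin has twist ≈ −167° and rise ≈ 27.5 Å. The
  symmetry of a density map is found by maximizing the real-space correlation
  between the map and itself rotated by the twist and shifted by the rise,
  over a twist ∈ [−200°, −100°] × rise ∈ [1, 40] Å grid inside a 120 Å
  cylinder (coarse 1°/0.5 Å, then local 0.1°/0.1 Å refinement).

* **Cross-over distance.** For 90° < |twist| < 180° the helix appears in
  projection as two strands crossing every
  *c* = rise · 180 / (180 − |twist|) along the axis (closed form used as the
  internal oracle: 28.19 nm for cofilactin, 38.1 nm for F-actin). The
  measured value comes from the filament's side-view projection: 28 nm
  Gaussian cylindrical mask, FT in a 512-pixel box binned 2× to 256, layer
  line found at L pixels from the equator, *c* = B·p/L with B = 256 and p the
  pixel size in nm.

* **Protofilament-number calling.** Each microtubule's particles carry a
  class vote (12–15 protofilaments × plus/minus polarity) and a
  cross-correlation (CC) score. The table is cleaned to the best-scoring
  80 %; a microtubule is assigned to its modal class if ≥ 65 % of its
  particles agree, or ≥ 50 % agree and the filament's mean CC ≥ 0.13;
  otherwise it is undetermined and excluded from all quantifications.

* **Morphology consensus.** Luminal-filament particles are classified as
  cofilactin / bare F-actin / other in nine independent runs (5, 10 or 20
  classes × reference twists −162°, −165°, −167°); per-run percentages are
  averaged per condition and replicate.

## Worked example

```python
import mtlumen as M

# render a noiseless cofilactin filament and recover its symmetry
vol = M.render_helical_filament(M.COFILACTIN, box=64, apix=5.9, decorated=True)
res = M.symmetry_grid_search(vol)
print(res.best)
# HelicalSymmetry(twist_deg=-161.8, rise_ang=28.45)

# the same filament at bin4 tomogram sampling: cross-over from the layer line
long = M.render_helical_filament(M.COFILACTIN, box=512, apix=11.81, decorated=True)
m = M.measure_crossover(long)
print(round(m.layer_line_px), round(m.crossover_nm, 2))
# 11 27.49

# simulate a classification-vote table and call every filament
spec = M.VoteSimSpec(
    class_fractions=M.fractions_over_pf({12: 0.028, 13: 0.933, 14: 0.036, 15: 0.003}),
    n_filaments=544, particles_per_filament=40, p_correct=0.85, seed=1,
)
table, truth = M.simulate_vote_table(spec)
calls = M.call_table(table)
assigned = calls[calls.assigned]
print(f"{100 * (assigned.n_pf == 13).mean():.1f}% called 13-protofilament")
# 92.3% called 13-protofilament
```

The recovered twist/rise match the generating symmetry to the fine grid
step; the cross-over (27.49 nm) sits within one Fourier pixel of the
closed-form 28.19 nm; and the 13-protofilament share recovered from the
noisy votes (92.3 %) reproduces the generating population (93.3 %) to
within binomial sampling error.

The same operations are available from the shell:

```sh
mtlumen simulate --kind filament --box 64 --apix 5.9 --out fil.mrc
mtlumen helixsearch fil.mrc
mtlumen crossover fil.mrc --diameter 28
mtlumen call particles.star --out calls.tsv
```

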