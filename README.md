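# axoquant

Quantification of axon collateral branching from fluorescence microscopy.

During development, spinal motor axons elaborate side branches
(collaterals) along their shaft; in zebrafish, caudal primary (CaP) motor
axons go from a few minor collaterals at 24 hpf to dense, ventrally biased
arborization at 48 hpf. `axoquant` turns a confocal stack of a single
motor axon plus a manually traced axon path into reproducible branching
numbers, for developmental biologists who trace axons in ImageJ and want
batch-processable, statistically comparable quantification.

## Pipeline

Starting from a single-channel TIFF stack and the axon path as an ImageJ
`.roi` segmented line (or a CSV point list):

1. **MIP** — maximum intensity projection over z.
2. **STR** — the MIP is resampled along the trace into a straightened band
   of fixed width *w* = 25 µm: rows follow arc length from the proximal
   (dorsal) end, columns are signed transverse offsets, with the shaft on
   the exact center column.
3. **MASK** — the STR is thresholded (Otsu), skeletonized, and every
   8-connected skeleton component whose geodesic length is not strictly
   greater than 0.5 µm is removed.
4. **Band excision** — a 5 µm wide longitudinal band around the shaft is
   excluded so only collateral signal is analyzed.
5. **Densities & profiles** — the mask is binned into cells of 4 px × 1 row
   and converted to collaterals/µm² (`count / (4·Δx·Δy)`); transverse and
   longitudinal mean profiles are pooled per group, and STR/MASK images of
   a group are stacked top-aligned with AVG/MAX projections.
6. **Branching metrics** — per axon: total collateral length divided by
   axon length *L*, and the same ratio for the dorsal region (first
   70 µm, normalized by 70 µm) and the ventral remainder (normalized by
   *L* − 70 µm).
7. **Statistics** — scalar group comparisons are Shapiro–Wilk-gated
   (Student *t* if both groups look normal, Mann–Whitney otherwise);
   profile comparisons run a two-sided Mann–Whitney per position with
   step-up FDR control at *q* = 5% (two-stage Benjamini–Krieger–Yekutieli
   by default, plain Benjamini–Hochberg selectable).

A seeded phantom generator renders synthetic axons (curved Gaussian-ridge
shaft, lateral collaterals of known position/length/side, optional
terminal arbor and noise) with exact ground truth, so every stage is
verifiable without real data.

## Worked example

```python
import axoquant as aq

spec = aq.preset("dense_48hpf", seed=3)      # a mature-regime phantom
image, trace, truth = aq.generate_phantom(spec)
result = aq.process_axon(image, trace)       # full pipeline, defaults

print(f"axon length     {result.summary.axon_length_um:.1f} um")
print(f"total branching {result.summary.total_branching:.3f}")
print(f"dorsal          {result.summary.dorsal_branching:.3f}")
print(f"ventral         {result.summary.ventral_branching:.3f}")
print(f"components      {result.summary.n_components}")
```

prints

```
axon length     131.8 um
total branching 0.266
dorsal          0.142
ventral         0.406
components      9
```

i.e. this simulated 131.8 µm axon carries 0.266 µm of collateral skeleton
per µm of shaft, branches almost three times more densely in its ventral
part than in its dorsal 70 µm, and shows 9 detected collateral components
(11 were simulated; the shortest do not reach past the excised shaft
band).

The same stages are available from the shell:

```bash
axoquant simulate --preset dense_48hpf --n 20 --seed 7 --out-dir sim/
axoquant straighten --image mip.tif --trace axon.roi --width-um 25 --out str.tif
axoquant mask --str str.tif --min-collateral-um 0.5 --out mask.tif
axoquant profiles --inputs 'masks/*.tif' --band-um 5 --bin-px 4 --axis both --out-prefix grp
axoquant metrics --masks 'masks/*.tif' --dorsal-um 70 --out metrics.tsv
axoquant compare --group-a a_transverse.tsv --group-b b_transverse.tsv --q 0.05 --out cmp.tsv
axoquant run-all --images 'raw/*.tif' --traces 'raw/*_trace.csv' --out-dir out/
```

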