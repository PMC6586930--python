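# endomapper

Object-based quantification of protein localization at endomembrane
compartments (endosomes, autophagosomes, trans-Golgi) in dual-channel
fluorescence microscopy, with a randomized pseudo-compartment null model
that corrects for colocalization occurring by chance, plus ratiometric
FRET-biosensor quantification of local GTPase activity.

## Who this is for

Cell biologists asking "what fraction of compartment X carries protein Y?"
from two-channel confocal images — one channel a compartment marker (e.g.
EEA1, Rab11, LC3, Rab6), the other an immunofluorescence or fusion signal
for the protein of interest. Overlay-based and correlation-based
colocalization (Pearson, Manders) depend on the relative signal strength
of the two channels; this method does not, because the marker channel is
used only to *segment* compartments and the protein channel only to
*measure* intensity inside them.

## The method

For a user-chosen ROI (default 300 × 300 px):

1. **Segment** compartments from the marker channel: Gaussian blur →
   threshold (Otsu by default) → morphological closing → hole filling →
   8-connected labeling → rejection of objects below a minimum area.
2. **Measure** the mean protein intensity *m_i* of each compartment.
3. **Positivity rule**: compartment *i* is positive iff
   *m_i* > *μ* + *k·σ*, where *μ*, *σ* are the mean and population SD of
   the protein intensity over the entire ROI (default *k* = 1). The
   summary statistic is the percentage of positive compartments.
4. **Null model**: *n* disks with the same area as the compartment class
   under study (defaults *n* = 1000, 1.2 µm² for endosome-scale;
   *n* = 10, 9.2 µm² for Golgi-scale) are placed uniformly at random in
   the ROI and measured identically. Because their placement is blind to
   the marker channel, their percent positive estimates chance
   colocalization.
5. **Statistics**: the per-region mean intensities of real vs pseudo
   compartments are compared with a two-sided Mann–Whitney U test; the
   protein is deemed genuinely localized only if real compartments
   measure significantly brighter than the null.

The FRET module computes per-pixel background-subtracted YFP/CFP emission
ratios (optionally 2×2 or 3×3 binned) and summarizes them over the whole
cell, a 1.67 µm band at the cell periphery, and marker-segmented
compartments.

A synthetic-data generator produces ground-truthed fixtures (disk-shaped
compartments over background, controllable enriched fraction and noise)
so every stage is testable without microscopy data.

## Worked example

```bash
# simulate a field with 50 compartments, half of them 10x enriched
endomapper simulate --seed 11 --fraction-enriched 0.5 --enrichment 10 \
    --noise-sd 1.0 --out-dir sim
# run the full analysis
endomapper map --input sim/image.tif --marker-ch 0 --protein-ch 1 \
    --pixel-size 0.1 --roi 0,0,300,300 --n-pseudo 1000 --pseudo-area 1.2 \
    --seed 0 --out-dir mapped
```

prints

```
Endomapper report
-----------------
compartments segmented : 50
pseudo-compartments    : 1000 (radius 6 px, seed 0)
positivity threshold   : 140.305 (ROI mean 65.6655 + 1 x SD 74.6397)
percent positive (real)  : 50.0%
percent positive (pseudo): 6.9%
Mann-Whitney real vs pseudo: U = 33977, p = 1.79e-05 (asymptotic)
reports written to mapped
```

Reading: exactly the 25 truly enriched compartments exceed the
ROI-mean + 1·SD threshold (50.0% positive), only 6.9% of the 1000 random
disks do so by chance, and the rank-sum test rejects equality of the two
mean-intensity distributions — the protein is genuinely at these
compartments. `mapped/` holds `real_compartments.csv` and
`pseudo_compartments.csv` (id, area_px, mean_intensity, sd_intensity),
`report.json` with all parameters and the seed, plus label-map TIFFs.

The same workflow is available as a library:

```python
from endomapper import ROI, SyntheticParams, generate_colocalization_fixture, run_endomapper

image, truth = generate_colocalization_fixture(
    SyntheticParams(seed=11, fraction_enriched=0.5, enrichment_factor=10, noise_sd=1.0))
report = run_endomapper(image, ROI(0, 0, 300, 300))
print(report.summary())
```

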