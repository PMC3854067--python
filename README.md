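# fmposthoc

Quantitative correlation of synaptic vesicle release efficiency with
presynaptic protein content, from FM1-43 destaining time-lapses and
*post-hoc* immunofluorescence of the same field.

## The problem

In cultured neuronal networks, individual presynaptic boutons release
their vesicle pool with very different efficiencies. One way to ask *why*
is to measure function first — load recycling vesicles with the styryl
dye FM1-43, stimulate, and record the fluorescence loss ("destaining") of
each bouton — then fix the culture, label it with antibodies against
candidate active-zone proteins (e.g. RIM1α, Munc13-1), re-image the same
field, and test whether boutons with more of the protein unloaded more
dye. `fmposthoc` implements the image-analysis half of that experiment as
a tested, scriptable pipeline, and ships a simulator that generates
complete synthetic experiments with known ground truth so every stage can
be verified without microscope data.

## The method

For each bouton (ROI) with mean-intensity trace `F(t)` the pipeline
computes the **unloaded fraction**

```
U = (F0 − ⟨F⟩_tail) / F0,      F0 = ⟨F⟩_baseline
```

the fraction of baseline fluorescence lost by the end of the recording.
The stages, in order:

1. **Segmentation** — ROIs are connected components of the destaining
   difference image `D = ⟨baseline⟩ − ⟨tail⟩` above a robust threshold
   (median + k·1.4826·MAD), watershed-split at local maxima of `D`, and
   area-filtered. The mask follows the responsive puncta themselves, so
   no manually drawn ROIs and no dead pixels.
2. **Kinetic quality control** — each trace is classified by baseline
   slope, baseline coefficient of variation, and unloading extent (all
   relative to `F0`); failing ROIs are excluded from all further analysis.
3. **Rolling-ball background subtraction** (12 px ball by default) on the
   immunofluorescence channels, implemented as grayscale opening with a
   spherical structuring function.
4. **Registration** — each post-hoc channel is aligned to the time-average
   of the FM baseline frames by the integer translation maximizing the
   normalized cross-correlation within ±20 px; ROIs touching pixels that
   lost their source in the shift are removed.
5. **Quantification** — per-ROI immunoreactivity (IR) is the integrated
   density (sum of background-subtracted intensities over ROI pixels),
   normalized by the channel mean; ROIs are grouped as `high`
   (normalized IR > 2), `low` (< 0.5) or `mid`.
6. **Statistics** — mean ± SEM unloaded fraction and normalized traces
   for the whole population, the high- and the low-IR groups; one-way
   ANOVA across those three (deliberately overlapping) samples plus
   Bonferroni-corrected pairwise t tests, and the disjoint
   high/mid/low variant alongside. A two-channel linearity control
   (normalized channel-B IR regressed on channel-A; slope ≈ 1, strong r)
   validates labelling and alignment.

## Worked example

`examples/02_full_pipeline.py` simulates a 500-bouton field whose marker
content is linearly coupled to release efficiency and analyses it end to
end:

```
candidate ROIs:        498
quality-passing:       497
after edge removal:    497
recovered shifts (px): {'marker_a': [5, -3], 'marker_b': [5, -3]}  (planted (5, -3))
two-channel linearity: slope 0.997, r 0.936 -> valid experiment

unloaded fraction by marker-A group (mean +/- SEM):
  whole: 31.00 +/- 0.56 %   (n = 497)
   high: 36.74 +/- 2.04 %   (n = 40)
    low: 24.58 +/- 1.19 %   (n = 99)

one-way ANOVA (whole/high/low): F = 16.48, p = 1.05e-07
```

High-IR boutons unload more dye than the population, low-IR boutons less,
and the ANOVA confirms the stratification — the planted coupling is
recovered through the full imaging and analysis chain. The companion
`examples/03_null_marker_control.py` runs the same analysis with zero
planted coupling and reports a non-significant ANOVA (p = 0.226), showing
the pipeline does not manufacture correlations. The other examples
demonstrate the simulator and the background/alignment stages in
isolation.

A command-line interface mirrors the stages
(`fmposthoc simulate | segment | align | analyze | report`); see
`fmposthoc --help`.

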