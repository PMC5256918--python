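# methylscope

Quantitative pipelines for detecting DNA demethylation in cultured cells
across three independent assays:

1. **Feulgen image cytometry** — chromatin-texture statistics from per-pixel
   nuclear absorbance maps: the condensed-chromatin area fraction **S_C %**
   and the average absorption ratio **AAR**. Chromatin decondensation (the
   phenotype that accompanies DNA demethylation, e.g. after treatment with
   the histone-deacetylase inhibitor valproic acid) shows up as *lower*
   S_C % with *higher* AAR.
2. **FT-IR microspectroscopy of extracted DNA** — baseline correction,
   replicate averaging, max-peak normalization, and Gaussian deconvolution
   of the 2992–2850 cm⁻¹ C–H/–CH₃ stretching window, whose band area tracks
   5-methylcytosine (5mC) abundance; plus the 1375/1492 cm⁻¹ absorbance
   ratio and DNA-quality checks (B-form marker at 1232–1225 cm⁻¹, the
   1707 cm⁻¹ non-denaturation shoulder, ν_as/ν_s PO₂⁻ ordering).
3. **5mC immunofluorescence** — per-nucleus mean intensity on 8-bit
   micrographs, with Otsu segmentation and background subtraction.

Group differences are tested with the two-sided Mann-Whitney U test (exact
for small tie-free samples, normal approximation with tie correction
otherwise). A synthetic-data module generates nuclei, IR spectra and IF
fields with known ground truth, so every stage is verifiable as a
parameter-recovery problem without access to instrument data.

## The statistics at the core

For one nucleus with pixel area `p²` (default scanning spot 0.5 μm):

```
S_T = (pixels above the 0.020 removal floor) · p²      total nuclear area
S_C = (nuclear pixels ≥ the 0.100 cutoff) · p²         condensed area
A_T, A_C = integrated absorbance over those pixel sets

S_C % = 100 · S_C / S_T
AAR   = (A_C / S_C) / (A_T / S_T)        (undefined when S_C = 0)
```

AAR ≥ 1 by construction: the mean absorbance of the above-cutoff subset
cannot fall below the whole-nucleus mean.

IR bands are Gaussians parameterized by FWHM, with closed-form area
`A = h · FWHM · √(π / (4 ln 2))`. Deconvolution is bounded nonlinear least
squares on a sum of such components, seeded by curvature (second-derivative)
peak detection whose sensitivity maps to a prominence threshold.

## Worked example

```python
import numpy as np
from methylscope import AbsorbanceImage, measure_nucleus

img = AbsorbanceImage(np.array([[0.05, 0.08],
                                [0.15, 0.25]]), pixel_um=0.5)
m = measure_nucleus(img)
print(f"S_C% = {m.Sc_percent:.1f}   AAR = {m.AAR:.4f}")
```

prints

```
S_C% = 50.0   AAR = 1.5094
```

Two of the four pixels (0.15, 0.25) reach the 0.100 condensed cutoff, so
S_C % = 50. With A_C = 0.40 over S_C = 0.5 μm² and A_T = 0.53 over
S_T = 1.0 μm², AAR = (0.40/0.5)/(0.53/1.0) = 1.5094: the condensed
compartment is 1.5× denser than the nuclear average.

The full demo pipeline (all-synthetic, three dose groups) runs from the
command line:

```
methylscope run --seed 7 --out-dir demo_out
```

and writes, among other tables, a deconvolution summary
(`ftir_summary.tsv`):

```
group     n_peaks  main_peak_frequency  main_peak_area  total_area
control   1        2934.83              14.57           14.57
vpa_1mM   1        2934.67               9.59            9.59
vpa_20mM  1        2934.41               6.03            6.03
```

The –CH₃-window band area falls monotonically across the simulated dose
series — the demethylation direction of effect — while the cytometry
comparison table shows the treated group's lower S_C % and higher AAR with
Mann-Whitney p-values.

Other entry points: `methylscope simulate {nuclei|spectra|if}`,
`methylscope cytometry`, `methylscope ftir {fit|ratio|qc}`,
`methylscope ifquant`, `methylscope compare`.

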