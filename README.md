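# mbspec

Analysis pipeline for ATR-FTIR spectra of brain tissue, built around the
question of whether mid-infrared absorbance spectra can separate
medulloblastoma (MB) — the most common malignant pediatric brain tumor —
from normal cerebellar tissue, and its histological subtypes (classic,
desmoplastic/nodular, large cell/anaplastic) from one another.  It is
aimed at spectroscopists and chemometricians working with
formalin-fixed, paraffin-embedded (FFPE) tissue spectra.

The package implements four analysis stages on absorbance spectra
A(ν), ν in cm⁻¹, recorded over 800–3500 cm⁻¹ (excluding 1800–2800 cm⁻¹):

1. **Preprocessing** — concave rubberband baseline correction with 64
   base points (segment minima + lower convex hull), vector
   normalization (mean-centered, unit Euclidean norm), replicate
   averaging, and Savitzky–Golay derivatives.
2. **Multivariate structure** — PCA and UPGMA (average-linkage)
   hierarchical clustering on second-derivative spectra in the
   fingerprint region 800–1800 cm⁻¹, with the paraffin window
   1350–1500 cm⁻¹ excised; Euclidean distances; outlier screening and
   cluster-purity evaluation.
3. **Amide I deconvolution** — the 1600–1700 cm⁻¹ protein C=O band is
   detrended, component positions are seeded at the minima of the
   second derivative, a sum of Gaussians is fitted by bounded least
   squares, and each component center is classified as β-sheet
   (<1645 or ≥1685 cm⁻¹), α-helix (1645–1662) or β-turn (1662–1685);
   the secondary-structure composition is reported as percent of total
   component area.
4. **Absorbance dynamics** — each patient's first derivative dA/dν is
   compared per wavenumber to a control envelope (mean ± SD across
   control spectra); a patient is *altered* at ν when
   |d_patient(ν) − d̄_control(ν)| > k·SD(ν) (default k = 2), and the
   discrimination probability P(ν) is the percentage of patients
   altered at ν, reported overall and per subtype with band-level
   min–max summaries.

Because no spectra are publicly deposited for this tissue system, the
package ships a first-class synthetic-spectrum generator
(`mbspec.synth`): sums of Gaussian bands at the reference atlas
positions with group-specific presence/absence (e.g. the 964 cm⁻¹
deoxyribose band in tumors only, 1125 cm⁻¹ in controls only,
1341 cm⁻¹ in the anaplastic subtype only), six amide I components
realizing each group's secondary-structure composition, paraffin bands,
a smooth concave baseline, additive noise, and per-sample jitter.  The
default cohort mirrors the emulated study: 4 controls and 40 tumors
(21 classic / 5 desmoplastic / 14 anaplastic), in triplicate.

## Worked example

Deconvolve a noiseless control amide I band and recover its secondary
structure:

```python
from mbspec import synth
from mbspec.amide1 import deconvolve

band = synth.amide_band("control")        # six Gaussians, 1580-1720 cm^-1
fit = deconvolve(band)
print({k: round(v, 1) for k, v in fit.composition.items()})
print(sorted(round(c.center) for c in fit.components))
```

prints

```
{'beta_sheet': 68.5, 'alpha_helix': 19.5, 'others': 12.0}
[1631, 1641, 1652, 1658, 1680, 1691]
```

i.e. the six reference component positions and the control composition
row (68.5% β-sheet, 19.5% α-helix, 12.0% others) are recovered exactly
from the synthesized band.

Run the whole pipeline on a simulated cohort from the shell:

```bash
mbspec run-all --seed 1 --out report/
```

The report bundle contains, among others, `cluster_purity.json`
(three-class purity 1.0: {controls}, {desmoplastic},
{classic ∪ anaplastic} — subtype separation beyond that three-class
structure is *not* achieved, matching the scientific finding),
`amide1_composition.csv`, `peak_presence.csv` (atlas-shaped
presence/absence and positions per group), and
`dynamics_markers.csv`, whose 1714–1716 cm⁻¹ row reads `100` in every
column: all simulated tumors, regardless of subtype, have altered
absorbance dynamics in that carbonyl band.

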