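# vasomech

Quantitative analysis of **passive arterial stiffness and wall remodeling**
for small-animal cardiovascular studies. The package turns the raw outputs
of the standard measurement battery — wire myography, pressure myography,
ECG-gated cine MRI, transit-time Doppler, and stained-section microscopy —
into the derived mechanical and structural readouts used to compare
genotype or treatment groups, together with a seeded synthetic-data
generator so every stage can be verified against known ground truth.

## What it computes

**Wire myography** (`vasomech.wire`). An aortic ring is stretched stepwise
while internal diameter *d* (µm) and wall tension *T* (mN/mm) are recorded.
The diameter–tension relationship is summarized by OLS: the slope is the
stiffness readout, the zero-tension intercept gives the unloaded diameter
*Y₀*, and intersecting the fitted line with the Laplace isobar
*T = P·d/2* at *P* = 100 mmHg estimates the diameter at physiological
pressure (*d₁₀₀*). Segments failing force-channel calibration QC are
excluded.

**Pressure myography** (`vasomech.pressure`). A cannulated mesenteric
artery in Ca²⁺-free medium is pressurized in steps (3–120 mmHg). From
inner/outer diameters the package derives wall thickness
WT = (Dₑ−Dᵢ)/2, wall:lumen, incremental distensibility (% diameter change
per mmHg), circumferential strain ε = (Dᵢ−D₀₀)/D₀₀ and stress
σ = P·Dᵢ/(2·WT) (1 mmHg = 133.4×10³ dyn/cm²), and fits the exponential
wall model

&nbsp;&nbsp;&nbsp;&nbsp;σ = σ_orig · e^(β·ε),&nbsp;&nbsp;&nbsp;E_inc = β·σ

per animal. β is the geometry-independent stiffness exponent; higher β
means a stiffer wall.

**Hemodynamics** (`vasomech.hemodynamics`). Lumen-area–time curves from
cine MRI are linearly resampled onto a 1 ms grid, truncated at 150 ms, and
reduced to the initial ascending slope (OLS over the first 20 ms), the
incremental area, the radial strain curve (r = √(A/π)) and the total
strain (time integral of strain). Transit-time pulse wave velocity is
path distance divided by the difference of the aortic and femoral
R-to-foot times (mm/ms ≡ m/s).

**Elastin waviness** (`vasomech.waviness`). Elastin autofluorescence
images are median-filtered, background-subtracted (rolling ball),
thresholded, skeletonized and decomposed into branches at junction
pixels; **rectilinearity** = Σ(endpoint chord)/Σ(geodesic length) over all
branches is 1 for straight lamellae and decreases with waviness.

**Histology** (`vasomech.histology`). Trichrome collagen/muscle area
fractions by hue classification, media thickness and lumen perimeter from
layer masks, polarized picrosirius thick(orange)/thin(green) collagen
classes, immunofluorescence intensity (mean, or Kapur maximum-entropy
threshold + integrated density) normalized to the control-group median,
SHG texture (signal amount/density, Pearson kurtosis and skewness), and
DAPI nuclei counts.

**Statistics** (`vasomech.stats`). Grubbs (maximum normalized residual)
outlier exclusion, Student/Welch t, Mann–Whitney U, one- and two-way
ANOVA with Šidák-adjusted comparisons, and regression-slope comparisons.

**Pipeline and CLI** (`vasomech.pipeline`, `vasomech` command). YAML-driven
end-to-end runs producing per-animal metric CSVs, group comparisons, audit
overlays, and a JSON manifest with versions, seeds, parameters and every
exclusion with its reason; re-runs are byte-identical.

## Worked example

```bash
vasomech simulate --out demo --seed 7      # synthetic two-group study
vasomech run --config demo/config.yaml
```

which prints

```
wrote synthetic study; config at demo/config.yaml
completed stages ['wire', 'pressure', 'mri', 'pwv', 'elastin'] with 0 exclusions; outputs in demo/out
```

`demo/out/comparisons.csv` then holds the group statistics; for seed 7 the
simulated "stiff" group differs from control with Šidák/raw p-values

```
metric                  design        p_adjusted  significant
elastin_rectilinearity  t             0.000052    True
mri_asc_slope           mann-whitney  0.028571    True
pressure_beta           t             0.000002    True
pwv                     t             0.000026    True
wire_slope              t             0.000015    True
```

i.e. the stiff group's straighter elastin, flatter systolic area upstroke,
higher β, faster pulse wave and steeper diameter–tension slope are all
detected at the planted effect sizes. The same analyses run from Python:

```python
from vasomech import synthetic, pressure

model = synthetic.VesselModel(beta=5.0, noise_sd_um=1.0, seed=0)
series = synthetic.make_pressure_series(model)
mech = pressure.analyze_series(series)
print(round(mech.fit.beta, 3))   # 5.036 — recovers the generating beta
```

## Layout

```
src/vasomech/     library modules (wire, pressure, hemodynamics, waviness,
                  histology, stats, synthetic, pipeline, cli, units)
tests/            pytest suite incl. acceptance properties
scripts/          acceptance script
docs/methods.md   models, conventions, parameter defaults, limitations
```
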