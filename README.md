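# drusensf

Pointwise structure–function analysis of macular drusen in intermediate
age-related macular degeneration (iAMD), for researchers working with
macular OCT, dual-wavelength fundus autofluorescence (FAF) and
mesopic/scotopic microperimetry.

Drusen — deposits between the retinal pigment epithelium (RPE) and
Bruch's membrane (BM) — locally elevate the RPE and degrade overlying
photoreceptors. This package quantifies that structural damage from raw
(linear-intensity) OCT volumes and relates it, location by location, to
microperimetric light sensitivity.

## The analysis

**Structural maps (OCT).** Per A-scan, the RPE is initialized as the
first normalized intensity peak above 0.4 closest to the BM, then
smoothed into a continuous surface. Two en-face maps follow:

* *RPE elevation* — RPE-E = (BM row − RPE row) · axial scale (µm), a
  drusen-thickness surrogate;
* *photoreceptor reflectivity ratio* — PRR = S₂₀ / S₆, where Sₖ is the
  linear sum of the A-scan from k pixels above the RPE to the image
  bottom. A dim photoreceptor band drives PRR toward 1.

**Macular pigment correction (FAF).** The pigment absorbs blue
(488 nm) but barely green (518 nm) excitation, so MPOD = green/blue per
pixel. The cyan (505 nm) scotopic stimulus is itself absorbed, at about
66% of the 488 nm absorption, so the measured cyan sensitivity receives

    C_dB = 10 · log10(0.66 · (MPOD − 1) + 1)

averaged over each Goldmann III stimulus disc (0.43° diameter), with
negative disc means set to zero.

**Normative models and sensitivity loss.** On healthy eyes, per test:
mesopic and scotopic-red sensitivity ~ eccentricity + age; scotopic-cyan
~ ln(ecc) + ln(ecc)², each with a per-eye random intercept (ML). Only
the fixed effects serve as the reference; sensitivity loss
SL = observed − predicted.

**Structure–function models.** SL ~ log₁₀ predictors (RPE-E, PRR, green
AF) with a per-eye random intercept: univariable fits, the
full-interaction multivariable fit, fixed-effect
R² = 1 − SS_res(fixed)/SS_tot, likelihood-ratio tests dropping each
predictor with its interactions, marginality-respecting backward AIC
reduction, and a subset analysis at locations whose RPE-E exceeds the
healthy 95th percentile (strict inequality).

A synthetic cohort generator (`drusensf.synthetic_data`) reproduces all
modalities with known ground truth — Gaussian drusen on an RPE floor,
correlated photoreceptor dimming, pigment-attenuated blue AF, misaligned
microperimeter frames, and staircase-quantized sensitivities (4-2
mesopic within 0–36 dB, 2-1 scotopic within 0–20 dB) over a 44-location
polar grid.

## Worked example

```python
from drusensf import faf_mpod, normative
from drusensf.datatypes import TEST_TYPES
from drusensf.structure_function import (
    fit_multivariable, log_transform_predictors, univariable_table,
    abnormal_threshold)
from drusensf.synthetic_data import SimConfig, simulate_location_records

cfg = SimConfig(random_seed=42)                      # 56 healthy + 43 drusen eyes
records = faf_mpod.compensate_records(simulate_location_records(cfg))
healthy = records[records["cohort"] == "healthy"]
models = {t: normative.fit_normative(healthy, t) for t in TEST_TYPES}
print("cyan normative:", {k: round(v, 2)
      for k, v in models["scotopic_cyan"].coefficients.items()})

drusen = log_transform_predictors(
    normative.apply_normative(records[records["cohort"] == "drusen"], models))
print(univariable_table(drusen[drusen["test_type"] == "mesopic"])
      [["predictor", "slope", "r2_fixed", "p_value"]].round(3).to_string(index=False))

full = fit_multivariable(drusen[drusen["test_type"] == "mesopic"])
print(f"multivariable fixed-effect R^2: {full.r2_fixed:.3f}")
thr = abnormal_threshold(healthy["rpe_e_mean_um"].to_numpy())
print(f"abnormal RPE-E threshold (healthy 95th pct): {thr:.2f} um")
```

prints

```
cyan normative: {'Intercept': 7.96, 'log_ecc': 3.11, 'log_ecc_sq': -0.56}
predictor  slope  r2_fixed  p_value
    rpe_e -2.452     0.384      0.0
      prr 10.073     0.027      0.0
      gaf  3.380     0.005      0.0
multivariable fixed-effect R^2: 0.413
abnormal RPE-E threshold (healthy 95th pct): 2.58 um
```

The fitted cyan normative coefficients recover the generating values
(8.0, 3.0, −0.5); the univariable slopes sit near the generating
structure–function effects (−2.5 dB per log₁₀ µm of elevation, +8 per
log₁₀ PRR, +4 per log₁₀ AF), with elevation the dominant predictor in
this synthetic cohort; and about 5% of healthy locations exceed the
abnormality threshold by construction of the percentile rule.

The `drusensf` console script exposes the same stages
(`simulate`, `oct-quant`, `faf-mpod`, `colocalize`, `normative`,
`sf-analysis`) for directory-based datasets.

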