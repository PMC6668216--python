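# onhvol

Volumetric analysis of the optic nerve head from radial OCT B-scans, and
its association with intracranial pressure (ICP).

Papilledema — swelling of the optic nerve head under elevated ICP — and the
accompanying anterior deflection of peripapillary Bruch's membrane (BM) are
measurable on OCT. `onhvol` turns six segmented radial B-scans (30° apart,
centered on the nerve head) into three volumes per eye:

- **ONHV** — optic nerve head volume: tissue between the internal limiting
  membrane (ILM) and a continuous BM boundary, cup regions excluded;
- **BMDV** — BM displacement volume: signed volume between BM and a
  per-scan secant through the outermost BM points (negative = anterior
  bowing, the high-ICP signature);
- **CV** — cup volume below the line joining the ILM points above the BM
  opening margins.

Because the BM image is unreliable beneath a swollen nerve head, each
volume can be computed under three BM representations: **traditional**
(chord between the rater-marked opening margins), **estimated** (chord
between the segmented BM points 1.6 mm to either side of the center) and
**excluded** (central 3.2 mm removed from the integration).

Each scan is split at the center into two half-scans, giving 12 half-scans;
heights are resampled onto a 511-node radial grid and summed as 510
trapezoidal prisms per wedge over the 12 wedges between adjacent
half-scans:

    V = Σ_wedges Σ_intervals base_area(r_i, r_{i+1}) · mean(4 corner heights)

with either planar-trapezoid (`chord`, default) or annular-sector
(`sector`) base areas — see `docs/methods.md`.

The package also measures the macular ganglion cell complex volume (GCCV,
3 mm disk about the fovea), generates analytic phantoms with closed-form
ground truth, simulates paired-eye ICP cohorts, and fits the association
models: linear GEE with exchangeable working correlation clustered by
subject (both eyes), one-eye linear regressions with Pearson r, and
pairwise correlations.

It is intended for researchers developing OCT-derived biomarkers of
intracranial pressure who have per-scan ILM/BM segmentations in hand;
segmentation itself and proprietary device formats are out of scope.

## Worked example

```python
from onhvol import (
    BMRepresentation, CohortParams, PhantomParams,
    compute_volumes, fit_gee, make_radial_phantom,
    phantom_oracle_volumes, simulate_cohort,
)

# a mildly swollen nerve head: 0.5 mm Gaussian ILM bump (sigma 0.8 mm),
# 0.1 mm posterior BM bow, 1.5 mm BM opening, 5.59 mm scan width
params = PhantomParams(bump_amp_mm=0.5, bump_sigma_mm=0.8, bm_bow_mm=0.1)
eye = make_radial_phantom(params, subject_id="DEMO", eye_id="OD")

for rep in ("traditional", "estimated", "excluded"):
    res = compute_volumes(eye, BMRepresentation(rep), base_mode="chord")
    truth = phantom_oracle_volumes(params, BMRepresentation(rep), "chord")
    print(f"{rep:12s} ONHV {res.onhv_mm3:6.3f} (truth {truth['onhv_mm3']:6.3f})  "
          f"BMDV {res.bmdv_mm3:6.3f} (truth {truth['bmdv_mm3']:6.3f})")

table = simulate_cohort(CohortParams(n_subjects=17, seed=1))
fit = fit_gee(table, "onhv_mm3", ["icp_cmH2O"])
t = fit.term("icp_cmH2O")
print(f"ONHV ~ ICP slope {t.coef:.3f} mm^3/cmH2O "
      f"(95% CI {t.ci_low:.3f}, {t.ci_high:.3f}), p={t.p_value:.4f}")
```

prints

```
traditional  ONHV  1.910 (truth  1.910)  BMDV  1.166 (truth  1.166)
estimated    ONHV  1.790 (truth  1.790)  BMDV  1.046 (truth  1.046)
excluded     ONHV  0.255 (truth  0.256)  BMDV  0.529 (truth  0.530)
ONHV ~ ICP slope 0.131 mm^3/cmH2O (95% CI 0.101, 0.161), p=0.0000
```

The estimated volumes track the quadrature ground truth to well under 1%.
Estimating BM trims the volumes (the 1.6 mm chord sits deeper into the
bowed membrane than the margin chord), and excluding the central 3.2 mm
removes most of the swelling signal — ONHV drops from 1.91 to 0.26 mm³ —
which is why the excluded representation is the least sensitive to ICP.
The GEE slope on a 17-subject synthetic cohort (0.131 mm³ per cm H₂O)
recovers the generating value 0.136 within its confidence interval while
accounting for two eyes per subject.

The same pipeline runs from the shell:

```sh
onhvol phantom --out eye.json --seed 1        # + eye.truth.json sidecar
onhvol volumes eye.json --out volumes.csv     # 3 reps x ONHV/BMDV/CV
onhvol cohort --out cohort.csv --seed 7
onhvol associate --table cohort.csv --outcome onhv_mm3 \
    --predictors icp_cmH2O --out coefficients.csv
```

Input/output schemas (radial segmentation JSON, macula CSV + sidecar, tidy
volume CSV) are documented in `src/onhvol/io.py`.

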