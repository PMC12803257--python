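# regenquant

Quantification of skeletal-muscle regeneration from immunofluorescence
sections, built around the **Regenerative Index (RI)** — the number of
regenerating myofibers divided by the number of necrotic ones:

```
RI = (# eMHC⁺ myofibers) / (# IgG⁺ myofibers)
```

In Duchenne muscular dystrophy (DMD), muscle cycles through necrosis and
regeneration whose absolute extent varies enormously within and between
biopsies. Because the RI is a ratio of the two processes measured in the
same section, it normalises that variability and tracks the *efficiency* of
regeneration rather than the amount of damage. The package is aimed at
researchers quantifying dystrophic histopathology who need a reproducible,
scriptable version of the usual semi-automated microscope-software
workflow:

- **Segmentation** — myofiber cross-sections are delineated by laminin
  immunostaining; fibers are traced strictly inside their basal-lamina
  boundary (Otsu threshold → morphological closing → connected interiors,
  with watershed re-splitting of merged fibers and replayable manual-edit
  operations).
- **Morphometry** — per-fiber cross-sectional area (CSA), minimal Feret
  diameter (MFF, the smallest distance between two parallel tangents,
  computed by rotating calipers on the convex hull) and circularity
  (4π·area/perimeter²).
- **Marker classification** — every fiber is counted (class 1); fibers with
  interior eMHC signal are regenerating (class 2) and fibers with interior
  IgG infiltration are necrotic (class 3). Nuclei are detected in DAPI and
  scored for Pax7 to count satellite cells per fiber.
- **Cohort statistics** — per-sample summaries (counts, percentages, RI),
  simple linear regression against age at biopsy (slope, R², p), and
  Welch's unequal-variance t-test between age groups.
- **Synthetic sections** — a phantom generator produces DMD-like
  multichannel images (laminin network, eMHC/IgG-positive fibers,
  peripheral/internal nuclei, Pax7⁺ sub-laminal subset) with per-fiber
  ground truth, so every stage is testable without patient data.

## Worked example

```python
import regenquant as rq

# a synthetic DMD-like section: 500 fibers, 12% regenerating, 2% necrotic
params = rq.PhantomParams(n_fibers=500, pixel_size=1.0, snr=8.0,
                          frac_emhc=0.12, frac_igg=0.02, seed=42)
phantom = rq.generate_phantom(params)
print("truth RI:", phantom.truth_ri)

from regenquant.pipeline import run_pipeline, PipelineConfig
result = run_pipeline(phantom, PipelineConfig(), sample_id="S", age=9)
print("pipeline RI:", result.summary.ri.value)
```

prints

```
truth RI: 4.461538461538462
pipeline RI: 4.461538461538462
```

— the pipeline recovered every one of the 58 eMHC⁺ and 13 IgG⁺ fibers that
the generator planted, so the measured ratio equals the ground-truth ratio.

The same stages are available on the command line
(`regenquant simulate / segment / measure / classify / summarize /
cohort-stats / pipeline`), and

```bash
regenquant reproduce-table2
```

recomputes the packaged 13-sample reference cohort (10 DMD boys aged 7–11
and 3 controls) from its raw fiber counts and checks every reported RI and
percentage, ending with the cohort statistics:

```
RI ~ age (DMD): R²=0.789, p=0.0006
RI 7-8 vs 9-11: t=5.25, df=7.91, p=0.0008
all 13 rows match the printed table
```

The negative slope with R² = 0.789 is the headline finding this pipeline
supports: regenerative capacity in DMD declines sharply between 7 and 11
years of age.

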