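# microquant

Automated single-cell quantification of nucleocytoplasmic protein
translocation from multi-channel fluorescence microscopy, built around a
marker-based watershed segmentation pipeline and a fully ground-truthed
synthetic image generator.

## The problem

In *C9orf72* repeat-expansion models of FTLD/ALS, a key pathological readout
is the redistribution of TDP-43 from the nucleus to the cytoplasm of
transfected cells. Quantifying it requires (i) segmenting individual nuclei
(DAPI) and cell bodies (a co-transfected ZsGreen1 reporter) in confocal
fields, (ii) summing the immunofluorescence signal (AF647) per compartment,
and (iii) classifying each cell into one of four translocation stages by
comparing its area-normalised nuclear and cytoplasmic signal against
thresholds measured on no-primary-antibody control fields. `microquant`
implements that pipeline, the companion single-cell marker quantification
(AF568, e.g. p62/LAMP2A), a phagocytosis overlap measure, and the
accompanying statistical procedures, and ships a synthetic scene generator
so every stage is testable without microscopy data.

## Method

Segmentation (all constants are 8-bit intensities or pixel counts):

1. **Nuclei** — iterated 2D median filter (10 passes, 7×7) on DAPI;
   threshold > 20; 8-connected components; discard components < 5,000 px
   (21.125 µm²); fill holes; split fused nuclei by watershed seeded at the
   regional extrema of the Euclidean distance transform.
2. **Cell bodies** — same smoothing on ZsGreen1; threshold > 0 (only true
   background is 0 in this channel); discard components < 3,000 px
   (12.675 µm²); fill holes; marker-based watershed seeded with the nucleus
   labels, so each body inherits its nucleus label.
3. **Exclusion** — remove cells that are dim (body mean ZsGreen1 < 6),
   apoptotic (a bright blob smaller than the nucleus concentrating ≥ 50% of
   the body's intensity), on the image border, or lacking a matched
   nucleus/body pair.

Per cell, with `S` a summed intensity and `A` a pixel area,

```
N_nuc  = S_nuc / A_nuc      N_cyt = (S_cell − S_nuc) / (A_cell − A_nuc)
N_cell = S_cell / A_cell    (S_cell = S_nuc + S_cyt exactly)
```

and the stage against control-field thresholds `B_nuc`, `B_cyt`:

| stage    | condition                                    |
|----------|----------------------------------------------|
| none     | N_cyt ≤ B_cyt                                |
| mild     | N_cyt > B_cyt, N_nuc > B_nuc, N_cyt < N_nuc  |
| moderate | N_cyt > B_cyt, N_nuc > B_nuc, N_cyt ≥ N_nuc  |
| severe   | N_cyt > B_cyt, N_nuc ≤ B_nuc                 |

Statistics follow the study's conventions: Shapiro–Wilk + Levene dispatch to
Student's/Welch's t or Mann–Whitney U (exact for small untied samples);
Fisher's exact test extended to r×c contingency tables (Freeman–Halton, by
complete enumeration or seeded Monte Carlo); Kruskal–Wallis with Dunn's
post hoc; percent-of-control and ΔΔCт normalisation.

## Worked example

```python
from dataclasses import replace
from microquant import RunConfig, run_pipeline
from microquant.synthetic import SceneParams, generate_scene, generate_background_field

base = SceneParams(fraction_apoptotic=0.0, fraction_dim=0.0, fraction_edge=0.0)
fields = [
    ("2R",  generate_scene(replace(base, stage_mix={"none": 0.7, "mild": 0.3}, seed=1))[0]),
    ("2R",  generate_scene(replace(base, stage_mix={"none": 0.7, "mild": 0.3}, seed=2))[0]),
    ("66R", generate_scene(replace(base, stage_mix={"mild": 0.3, "moderate": 0.4, "severe": 0.3}, seed=3))[0]),
    ("66R", generate_scene(replace(base, stage_mix={"mild": 0.3, "moderate": 0.4, "severe": 0.3}, seed=4))[0]),
]
controls = [generate_background_field(replace(base, seed=100 + i)) for i in range(2)]
res = run_pipeline(fields, controls, RunConfig(seed=0))
print(res.contingency)
print(res.stats["stage_independence"])
```

prints

```
           none  mild  moderate  severe
condition
2R            5     3         0       0
66R           0     1         5       2
{'p_value': 0.0012432012432012428, 'method': 'enumeration', 'mc_se': None}
```

i.e. all 16 synthetic cells were segmented and retained, every cell landed
in its programmed stage (the 2R fields were generated mostly stage "none",
the 66R fields shifted toward "moderate"/"severe"), and the exact 2×4
Freeman–Halton test rejects independence of condition and stage
(p ≈ 0.0012). The background thresholds measured on the two control fields
were B_nuc ≈ 3.14 and B_cyt ≈ 3.16. The same analysis is available from the
shell via `microquant simulate|segment|quantify|stage|stats|run`.

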