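# panmorph

Cross-species computational pathology asks a practical question: can a
single-cell H&E classifier trained on human tissue be trusted on tumours
from other species — dogs, Tasmanian devils, snakes, penguins — and if so,
on which samples?  `panmorph` implements the evaluation chain behind that
question as a tested, reusable Python library:

- **Nuclear morphometry** — 27 shape and staining features per nucleus from
  a label mask + intensity image (lengths in µm, intensities on 0–255).
- **Morphospace overlap (`port`)** — embed feature vectors with exact 2-D
  t-SNE (perplexity 50) and score, per cell class, the fraction of one
  group's morphospace lying inside another's.  For each embedding
  dimension *d* and quantile level α, the interval
  I<sub>α</sub>(G, d) = [Q<sub>α</sub>(G<sub>d</sub>), Q<sub>1−α</sub>(G<sub>d</sub>)] is formed;
  the score is the ladder-averaged ratio |I(A) ∩ I(B)| / |I(A)| multiplied
  across the two dimensions — an asymmetric overlap in [0, 1].
- **Balanced-accuracy evaluation** — one-to-one matching of pathologist
  annotations to detected centroids within a strict distance threshold,
  confusion matrices with explicit `other` and `missed` columns, and
  BCAcc = (sensitivity + specificity)/2 per class, averaged for the
  overall score; plus cohort statistics (tie-corrected Kruskal–Wallis with
  rank ε², bootstrap CIs, rank contrasts, correlations).
- **Tumour–immune colocalisation** — quadrat counts on a shared grid and
  the Morisita–Horn index
  MH = 2Σxᵢyᵢ / [(Σxᵢ²/X² + Σyᵢ²/Y²)·X·Y] ∈ [0, 1], reported ×100 as the
  prognostic covariate `coloc100`.
- **Survival prognostics** — VIF screening (keep VIF < 5), multivariate Cox
  proportional hazards (Efron ties) on coloc100 + age + lymphocyte %,
  lower-quartile dichotomisation, and (adjusted) Kaplan–Meier curves.
- **Synthetic data** — seeded generators for every input: rasterised
  nuclei with class-conditional morphology, classifier output with a known
  confusion matrix, Thomas-process point patterns with a colocalisation
  dial θ, and proportional-hazards survival cohorts — so every estimator
  can be validated against known ground truth.

A 20-species balanced-accuracy reference table ships with the package
(`panmorph.load_species_table()`), checksum-pinned, so the cohort-level
statistics are reproducible without any external data.

## Worked example

```python
>>> from panmorph import ColocSpec, gen_point_pattern, colocalization
>>> for theta in (0.0, 0.5, 1.0):
...     cancer, lymph = gen_point_pattern(ColocSpec(theta=theta), seed=42)
...     res = colocalization(cancer, lymph, width=250.0)
...     print(f"theta={theta:.1f}  MH={res.mh:.3f}  coloc100={res.coloc100:.1f}")
theta=0.0  MH=0.248  coloc100=24.8
theta=0.5  MH=0.690  coloc100=69.0
theta=1.0  MH=0.947  coloc100=94.7
```

θ is the probability that a lymphocyte attaches to a cancer cluster
rather than an independent one: at θ = 0 the immune cells sit in their own
territory (MH ≈ 0.25 residual overlap from shared quadrats), at θ = 1 they
infiltrate the tumour clusters and MH approaches 1.  `coloc100` is the
covariate a Cox model then relates to survival (see
`examples/06_survival.py`, where the fitted hazard ratio per coloc100
point recovers its generating value of 0.98).

The `examples/` directory holds one short narrative script per
capability: cohort statistics, morphometry, classifier evaluation,
morphospace overlap, colocalisation, survival modelling, and the
20-species overlap-vs-accuracy transfer experiment.

A thin CLI mirrors the stages for shell use:

```sh
panmorph cohort-stats --seed 1 --out out/
panmorph colocalize   --seed 3 --out out/
panmorph run --config my_run.yaml     # chain stages from a YAML config
```

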