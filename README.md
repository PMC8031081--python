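# cdpa — alignment-free binding-site shape descriptors and ligand classification

Comparing protein ligand-binding sites usually means either collapsing a 3-D
pocket to scalar summaries (volume, sphericity, radius of gyration) or
structurally aligning sites pair by pair — the first loses most of the shape
information, the second is computationally expensive and confines analysis
to pairwise similarity scores.  `cdpa` implements a middle road: each
binding site (the protein heavy atoms within 5.3 Å of a bound ligand) is
encoded as the **covariance matrix of its atoms' distances to the site's
three principal axes**.  Because distances to the principal axes do not
depend on the deposited coordinate frame, sites can be compared, modelled
and classified with no alignment step at all.

## The descriptor

For a site with atoms x₁ … xₙ ∈ ℝ³ and centroid x̄, the principal axes
u₁, u₂, u₃ are the eigenvectors (by decreasing eigenvalue) of the coordinate
covariance Sₓ = n⁻¹ Σᵢ (xᵢ − x̄)(xᵢ − x̄)′.  With dₖⱼ = ‖(xₖ − x̄) −
((xₖ − x̄)·uⱼ)uⱼ‖ the distance of atom k to axis j, the descriptor is

    S = Cov(d)   (3 × 3, symmetric positive semi-definite, Å²)

vectorised norm-preservingly as

    vecd(S) = (S₁₁, S₂₂, S₃₃, √2·S₁₂, √2·S₁₃, √2·S₂₃),   ‖vecd(S)‖² = ‖S‖²_F .

Each ligand group j is modelled by the sample mean v̄ⱼ and covariance Σ̂ⱼ of
its members' 6-vectors; a site v is compared to the group by the squared
Mahalanobis form Dⱼ = (v − v̄ⱼ)′ Σ̂ⱼ⁻¹ (v − v̄ⱼ).  Classification is by
nearest group mean (argminⱼ Dⱼ) or by multinomial logistic regression on
the whole profile (D₁ … D_J), which also yields per-site certainty
probabilities.  Robustness is validated by perturbing every atom coordinate
with N(0, τ²) noise and re-classifying against the original models over a
grid of τ values.

## Worked example

```python
import numpy as np, cdpa

# a benchmark-sized synthetic dataset: 9 ligand groups, 100 sites
dataset = cdpa.make_preset_dataset("default", seed=1)
vectors = cdpa.encode_sites(dataset.sites)          # 100 descriptor 6-vectors
models  = cdpa.fit_group_models(vectors, dataset.labels)
profiles = [cdpa.mahalanobis_profile(v, models) for v in vectors]
preds = [cdpa.nearest_mean_classify(p).label for p in profiles]
print(cdpa.evaluate(dataset.labels, preds).error_rate)
```

prints

```
0.0
```

— the nearest-mean training error on the separated preset: every one of the
100 sites is assigned to its own ligand group, because the nine generating
templates differ in their second-order shape and the descriptor preserves
exactly that information.  Running `examples/04_noise_validation.py`
continues with the noise validation and prints the error curve

```
tau (Å)   mean error   95% band
   0.1       0.158     [0.140, 0.175]
   ...
   1.0       0.564     [0.530, 0.585]
```

— classification degrades smoothly as Å-scale coordinate noise erodes the
sites' shape, while remaining well below the 8/9 chance level.  The other
scripts in `examples/` each demonstrate one capability end to end:
extraction from PDB text (01), group models and confusion matrices (02),
logistic certainty (03), and MDS diagnostics with reproducible outlier
flagging and subgroup splitting (05).

Real structures are handled by `cdpa.parse_structure` /
`cdpa.extract_binding_site` (PDB format, 5.3 Å cutoff, altloc and water
handling documented in `docs/methods.md`); reproducing the published
benchmark studies requires downloading structures and is documented in
`docs/benchmark_walkthrough.md`.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the package's main pipeline from scratch at the given seed —
generating the benchmark-sized synthetic dataset, encoding all sites,
fitting the group models, classifying with both classifiers and running the
Gaussian-noise validation — printing a summary to stderr and writing the
results JSON to `--out`.

## Layout

- `src/cdpa/structure_io.py` — PDB parsing, site extraction, coordinate tables
- `src/cdpa/core.py` — principal frames, axis distances, the descriptor, vecd, radius of gyration
- `src/cdpa/group_models.py` — group mean/covariance models, Mahalanobis profiles, nearest-mean, confusion matrices
- `src/cdpa/logit.py` — multinomial logistic classifier and certainty summaries
- `src/cdpa/robustness.py` — noise validation, outlier flagging, subgroup splitting, classical MDS
- `src/cdpa/synthetic.py` — synthetic site generator and presets
- `src/cdpa/pipeline.py` — encode/fit/classify/validate/mds orchestration with run metadata
- `docs/methods.md` — the model, conventions, numerical choices and limitations
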