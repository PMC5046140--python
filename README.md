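# pinehab

Habitat-suitability regionalization for a medicinal conifer (Masson's pine,
*Pinus massoniana*), whose needles are a source of shikimic acid,
procyanidins, total flavonoids and total lignans. Where the tree *grows*
well is not where its needles are *medicinally* best, so the pipeline
evaluates both and intersects them:

1. **Growth suitability** — a presence–background maximum-entropy (Maxent-
   style) species distribution model over ecological-factor rasters
   (monthly precipitation, monthly mean temperature, altitude): the Gibbs
   distribution q<sub>λ</sub>(x) = exp(λ·f(x))/Z over background cells that
   matches presence feature means, fitted by L1-penalized maximum
   likelihood. Evaluated by Mann–Whitney AUC; per-variable importance by
   permutation percent contribution; response curves give per-factor
   optimal ranges.
2. **Quality suitability** — a fuzzy matter-element evaluation: each factor
   x is standardized into a membership μ(x) ∈ [0, 1] by the K-t
   (K-th-parabolic) fuzzy distribution — zero outside (a, d), a power-K
   rising limb on (a, b), full membership on the plateau [b, c], a power-K
   falling limb on (c, d) — calibrated against an equal-weight *aggregative
   indicator* of the four normalized compound contents. Quality
   suitability is the weighted mean Σ wᵢ μᵢ(xᵢ).
3. **Regionalization** — growth and quality maps are combined (cellwise
   minimum by default), masked to the coniferous-forest land-cover class,
   cut into highly / marginally / unsuitable classes, and summarized as a
   class-area table. Accuracy is the RMSE between the quality map and the
   observed indicator at sample sites.

No field data ship with the package: a first-class synthetic-landscape
generator (`pinehab.synth`) produces autocorrelated factor rasters, land
cover, presence points and compound contents from a *known* ground truth,
so every stage can be tested for recovery of that truth.

## Worked example

```python
from pinehab.pipeline import run_synthetic_pipeline, recovery_metrics

res = run_synthetic_pipeline(seed=1)          # 100x100 grid, 200 samples
print(res.validation.summary())
print(recovery_metrics(res)[["factor", "b_true", "b_fit", "c_true", "c_fit",
                             "weight_true", "weight_fit"]].round(2).to_string(index=False))
```

prints

```
RMSE = 0.0777 over 200 points
      factor  b_true  b_fit  c_true   c_fit  weight_true  weight_fit
precip_april    98.8 127.79   113.8  128.29         0.03        0.03
 precip_june   149.2 149.62   194.2  198.20         0.14        0.13
    temp_feb     5.0   5.12     8.0    7.91         0.26        0.26
    temp_aug    22.0  22.01    24.0   23.96         0.44        0.45
    altitude   800.0 812.44  1181.0 1168.21         0.13        0.14
```

i.e. on one synthetic study the calibration recovers the generating
membership plateaus [b, c] and factor weights almost exactly for every
factor whose weight is large enough to leave a signature in the indicator
(the 3%-weight April-precipitation factor is at the edge of
identifiability — see `docs/methods.md`). The RMSE of the resulting
quality map at the sample sites is on the order of the content noise.

The same pipeline is available stage by stage from the shell:

```
pinehab all --out-dir run --seed 1          # or: simulate / sdm / fuzzy /
                                            # overlay / classify / validate
```

and as numbered drivers under `analysis/` (simulate → growth model →
quality model → overlay/classify → validate → multi-seed recovery study),
which write their tables under `results/`.

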