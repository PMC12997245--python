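# ilqsar

QSAR modelling of ionic-liquid (IL) toxicity toward the enzyme
acetylcholinesterase, using COSMO-RS sigma-profile descriptors.

Ionic liquids are salts of an organic cation and an organic/inorganic anion.
Their toxicity endpoint here is Log 1/EC50 (log µM, base-10 log of the
reciprocal half-maximal effective concentration — higher means more toxic).
The model is a multiple linear regression over sigma-profile descriptors of
the two ions:

    Log 1/EC50 = Σᵢ aᵢ·(CatDes)ᵢ + Σⱼ bⱼ·(AniDes)ⱼ + c

A sigma profile is the distribution of a molecule's screening surface over
surface charge density σ (e/Å²), tabulated on a fixed 61-point grid from
−0.030 to +0.030 at 0.001 steps. Descriptors are the profile values at
individual grid points, named `C-0.008` (cation profile at σ = −0.008) or
`A0.004` (anion profile at σ = +0.004).

The package is aimed at modellers who want a tested, reusable version of
the full GA-MLR workflow:

- **descriptors** — sigma-profile data model, CSV I/O, IL descriptor
  assembly from cation/anion pairs, descriptor intercorrelation analysis;
- **mlr** — OLS fitting and prediction; the published 11-descriptor model
  (8 cationic + 3 anionic bins, fit on 183 training ILs) ships as a
  packaged resource;
- **validation** — R², R²adj, F, S, RMSE, AAD, %AARD; leave-one-out and
  leave-many-out Q²; Y-scrambling; external metrics (Lin's CCC, Q²F1–F3,
  r²m average/delta);
- **domain** — applicability domain: hat-matrix leverages, critical
  leverage h\* = 3(p+1)/n, standardized residuals, Williams-plot tables;
- **selection** — genetic-algorithm descriptor-subset search (with an
  exhaustive-search oracle for small pools) and breaking-point analysis of
  model size;
- **synthetic** — generator for synthetic ion profiles and planted linear
  responses, so every stage is testable against known ground truth;
- **pipeline** — end-to-end study driver, packaged reference fixtures, and
  `reproduce_paper()`, which recomputes the published statistics.

## Worked example

Apply the packaged model to the two external ILs whose full descriptor rows
are packaged (neither was in the model's training or test sets):

```python
import ilqsar as q

model = q.published_model()           # 11 descriptors, intercept -2.6595
t7 = q.load_fixture("table7").set_index("il_id")
print(q.predict(model, t7[model.descriptor_names]).round(2))
```

```
il_id
NEW-1   -2.49
NEW-2   -0.68
Name: log_inv_ec50_pred, dtype: float64
```

`NEW-1` (1-(ethoxymethyl)-3-methylimidazolium chloride) is predicted at
−2.49 log 1/µM against a measured −2.61; `NEW-2`
(4-(dimethylamino)-1-butylpyridinium bis(trifluoromethylsulfonyl)amide) at
−0.68 against a measured −0.59 — the less negative value marks the more
toxic IL.

The full published-statistics comparison (fit, external validation and
applicability-domain threshold recomputed from the packaged 243-IL table)
prints from the CLI:

```
ilqsar reproduce-paper
```

which reports, e.g., training R² 0.8211 vs the published 0.821, test-set
CCC 0.8542 vs 0.853, and h\* 0.1967 vs 0.197, each with its tolerance and a
pass flag.

A synthetic study runs end to end with:

```python
from ilqsar import StudyConfig, SyntheticSpec, GAConfig, run_study
report = run_study(StudyConfig(synthetic=SyntheticSpec(seed=1),
                               ga=GAConfig(seed=1)))
```

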