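# cstlesion

Corticospinal-tract (CST) lesionometry from normative quantitative MRI:
voxelwise z-score mapping, lesion severity profiling along the whole motor
pathway, multi-site harmonization and clinical association models — with a
synthetic phantom generator so the entire chain runs end to end with no
imaging download.

## The problem

Motor deficits in people with multiple sclerosis (pwMS) are often
asymmetrical, pointing at focal lesions on the corresponding motor pathway.
Yet overall CST lesion load correlates only modestly with disability.  One
hypothesis is that only *severely demyelinated* lesions have functional
consequences.  Testing it requires (i) quantifying myelin along the whole
CST — from motor cortex through brainstem and cervical cord down to the
thoracic cord — via the magnetization transfer ratio

```
MTR = (MT0 − MT1) / MT0 × 100        (percent units; lower ⇒ demyelination)
```

or quantitative T1 (ms; higher ⇒ demyelination); (ii) referencing each
patient's map to a healthy-control (HC) normative atlas,

```
z = (individual map − mean HC map) / SD HC map ,
```

so a lesion is called **severe** when its tract-restricted mean z falls
below −1.96 (MTR) or above +1.96 (qT1), the two-sided P < 0.05 criterion;
and (iii) linking per-side lesion burden — lesion volume fraction
`LVF = lesion∩tract / tract × 100`, severity calls, per-slice damage
profiles — to per-limb outcomes: the mASIA motor score and the central
motor conduction time (CMCT), whose prolongation beyond z > 1.96 of the HC
distribution marks abnormal conduction.  Because the CST decussates, a
limb's *functional side* is the contralateral brain tract plus the
ipsilateral cord tract (cord extent limited to C1–C7 for upper limbs).

`cstlesion` implements this chain for researchers in quantitative
neuroimaging and neuro-biostatistics:

| module | contents |
| --- | --- |
| `cstlesion.phantom` | synthetic template spaces, tube-shaped CST masks with portion bands (brain, brainstem, C1–C7 incl. C4–C6, T1–T10 incl. T4–T6 / T9–T10), HC and patient cohorts with planted ellipsoidal lesions at controlled z-depth, per-limb outcome simulation, site effects, NIfTI/CSV dataset I/O |
| `cstlesion.maps` | MTR computation, HC normative atlas (n−1 SD, low-SD exclusion), voxelwise z-score maps |
| `cstlesion.tract` | 26-connected lesion components, lesion volume fractions, ROI means, severity calls, abnormal-area attribution, per-slice tract profiles, extra-lesional means, functional-side mapping, cohort severity summaries |
| `cstlesion.harmonization` | parametric empirical-Bayes (ComBat) site harmonization preserving age/sex/group (cross-validated against R's `sva::ComBat`) |
| `cstlesion.stats` | Welch t, Cohen's d, chi-square, partial Pearson correlations, P < 0.2 screening, standardized-β multivariable regression with VIF, logistic OR/CI/AUC, CMCT abnormality, log-LVF transform, Bonferroni thresholds |
| `cstlesion.pipeline` / `cstlesion.cli` | end-to-end orchestration, report bundles, profile plots, `cstlesion` command line |

## Worked example

Run the full synthetic study — 21 healthy controls, 35 patients (70
functional tract sides), two acquisition sites — and fit the lower-limb
CMCT logistic model:

```python
from cstlesion import pipeline

bundle = pipeline.run_pipeline(pipeline.PipelineConfig(seed=1))
print(bundle.tables["severity_summary"].iloc[0])
print(bundle.logit_result.summary().round(3))
```

which prints (seed 1):

```
profiles: 70  lesions: 212  severe: 62 (29.2%)
profiles with >=1 lesion: 95.7%   with >=1 severe: 58.6%
severe location: SC 72.6% (cervical 46.8%) vs brain 27.4%

                      OR  ci95_low  ci95_high      z      p
severe_sc         19.903     3.750    105.634  3.512  0.000
severe_brain       0.513     0.092      2.854 -0.762  0.446
log_lvf_sc         0.988     0.752      1.298 -0.086  0.932
log_lvf_brain     1.278      0.994      1.645  1.912  0.056
age               0.995      0.928      1.067 -0.139  0.890
sex_female        1.013      0.238      4.312  0.018  0.986
disease_duration  0.978      0.870      1.098 -0.384  0.701
AUC 0.835
```

About 29% of detected lesions are called severe (the generator plants 26%
severe, and overlapping planted lesions merge into deeper components),
severe lesions concentrate in the cervical cord, and the presence of a
severe cord lesion on the functional side is by far the strongest
predictor of an abnormal lower-limb CMCT — the cord-driven association the
synthetic cohort plants as ground truth.  The same run is available from
the shell:

```bash
cstlesion all --seed 1 --out results/demo        # every table + run log
cstlesion simulate --seed 1 --out results/data   # NIfTI + CSV dataset
```

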