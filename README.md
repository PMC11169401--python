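# batdisturb

Detecting researcher-caused disturbance of hibernating bats from nightly
cave-mouth acoustic counts.

## The problem

Population surveys of hibernating bats require researchers to enter caves
and count animals in torpor. The lights, noise and presence of a survey
crew can arouse bats, which then fly — burning winter fat reserves they
cannot replace. Passive acoustic detectors at cave mouths record
*cave-exiting flight* as nightly counts of echolocation call files, so a
survey's impact leaves a signature: a night of unusually high activity
immediately after the crew leaves.

`batdisturb` turns that idea into a tested three-stage pipeline for
biologists who monitor hibernacula (winter caves) of species such as
Townsend's big-eared bat (*Corynorhinus townsendii*, COTO) and western
small-footed myotis (*Myotis ciliolabrum*, MYCI):

1. **Seasonal activity model** (`batdisturb.gam`). For each
   cave-season-species the nightly call-file count *y<sub>i</sub>* is
   modelled as a penalized-spline count regression,
   *y<sub>i</sub>* ~ Poisson(μ<sub>i</sub>), log μ<sub>i</sub> = β₀ +
   f(date<sub>i</sub>), fitted by penalized IRLS with GCV-selected
   smoothing; the quasipoisson family takes over automatically when the
   Pearson dispersion φ exceeds a threshold (counts of flying bats are
   usually overdispersed).
2. **Exceedance classification** (`batdisturb.exceedance`). The night
   following each survey is flagged when its weighted IRLS working
   residual exceeds 2 standard errors of the model-fit envelope —
   one-sided, because only *higher*-than-expected activity indicates
   disturbance. Each survey yields a binary outcome per species.
3. **Disturbance model** (`batdisturb.disturbance`). The outcomes are
   regressed on a *disturbance factor* DF = researchers × minutes in
   cave, plus mean overnight temperature T and wind speed:

   logit P(cave-exiting flight) = β₀ + β<sub>DF</sub>·DF + β<sub>T</sub>·T

   with Pearson screening of collinear covariates, all-subsets AIC
   ranking with Akaike weights, likelihood-ratio term tests, AUC, and a
   planning grid of predicted disturbance probability over crew size
   and survey duration.

A synthetic-data generator (`batdisturb.synthetic`) produces complete
activity/survey/weather bundles from a known disturbance law so every
stage can be verified against ground truth, and `batdisturb.table1`
packages a published 17-survey, 9-cave field table as a self-validating
fixture.

## Worked example

How risky is sending five people into a cave for 100 minutes on a
typical mid-winter night (−5.4 °C)?

```sh
$ batdisturb predict --researchers 5 --minutes 100 --temp -5.4
disturbance factor = 500, temperature = -5.4 C
probability = 0.53
```

A coin-flip chance of waking bats. Three people for the same 100
minutes (DF = 300) drop the probability below 0.10, which is why small
crews are the cheapest mitigation available.

Running the full modelling stage on the packaged survey table (survey
responses known from field observation, so the acoustic stages are
bypassed; overnight weather for those nights is not published, so the
candidate set reduces to the disturbance factor):

```python
from batdisturb import PipelineConfig, run_pipeline

report = run_pipeline(PipelineConfig(use_table1_fixture=True, outdir="out"))
print(report.selection_table)
```

```
         model  K       AIC     dAIC   weight status
   Disturbance  2 12.596669 0.000000 0.932368     ok
Intercept only  1 17.843975 5.247306 0.067632     ok
```

The disturbance-factor model wins decisively (ΔAIC = 5.2, Akaike weight
0.93): its likelihood-ratio test gives χ² = 7.25 on 1 d.f. (p = 0.007)
and the fitted probabilities separate responding from quiet surveys
with AUC = 0.881 — a good classifier. Of the 17 surveys, 14 (82%)
produced no flagged night for either species; the three that did had
disturbance factors of 300–700 (mean 511) versus a mean of 219 for the
quiet ones.

Synthetic end-to-end run with known truth:

```sh
batdisturb simulate --seed 1 --out data/
batdisturb fit --activity data/activity.csv --out run/
batdisturb classify --fits run/fits.csv --surveys data/surveys.csv \
    --weather data/weather.csv --out run/
batdisturb model --outcomes run/outcomes.csv --out run/
```

`data/truth.csv` records every latent response draw so the recovered
outcomes and coefficients can be checked against the generating law.

## Layout

```
src/batdisturb/
  io.py           delimited-table reading/writing/validation
  table1.py       packaged survey fixture with self-checks
  synthetic.py    ground-truth data generator
  gam.py          penalized-spline Poisson/quasipoisson count smooths
  exceedance.py   2-SE residual classification of post-survey nights
  disturbance.py  logistic modelling, AIC selection, AUC, planning grid
  pipeline.py     end-to-end orchestration
  cli.py          `batdisturb` command-line interface
docs/methods.md   modelling assumptions, defaults and limitations
```
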