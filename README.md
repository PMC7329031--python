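# paleodyn

Palaeodemographic reconstruction and population-dynamics modelling from
radiocarbon dates, built around the Rapa Nui (Easter Island) case: a
population proxy from summed probability distributions (SPDs) of ¹⁴C dates,
Ricker-logistic growth models whose carrying capacity is driven by vegetation
(palm-pollen %) and climate (SOI-like index) covariates, AICc model selection,
and Monte-Carlo uncertainty quantification. A synthetic-data generator with
known ground truth makes every stage testable by parameter recovery, so the
whole pipeline runs without any external downloads.

Intended users: archaeologists and palaeoecologists analysing radiocarbon
compilations as demographic proxies, and population ecologists fitting
discrete-time logistic models to reconstructed time series.

## The model

The population proxy N_t (SPD units, relative) follows the exponential
(Ricker) form of the discrete logistic:

```
N_t = N_{t-1} · exp( r_max · (1 − N_{t-1} / K) )
```

where `r_max` is the maximum per-capita reproductive rate per 30-yr step
(roughly one generation) and the carrying capacity is constant or linear in
the lagged covariates:

```
K(F, C) = k0 + k_f·F + k_c·C            F = palm pollen %, C = climate index
```

Fitting works on realized per-capita growth rates `R_t = ln N_t − ln N_{t-1}`
by nonlinear least squares on

```
R_t = r_max · (1 − N_{t-1} / K(F_{t-1}, C_{t-1}))
```

The four candidate capacity forms (constant, palm, SOI, palm+SOI) are ranked
by AICc and Akaike weights; trajectory uncertainty comes from multivariate-
normal resampling of the estimates with percentile bands. Vegetation dynamics
are modelled in the other direction by OLS:
`F = α + β·N + γ·C + ω·(N·C) + ε`.

The SPD itself is built the standard way: each date's likelihood is
calibrated against a curve (terrestrial, marine with a ΔR reservoir offset,
or a diet-weighted mixture), same-site dates whose calibrated medians cluster
within 50 years are down-weighted to one bin, the weighted densities are
summed per calendar year, smoothed with a 100-yr rolling mean, and coarsened
to 30-yr interval means. A Monte-Carlo null test flags calendar years whose
SPD cannot be explained by a fitted linear (or exponential) trend.

## Worked example

Generate a synthetic study (boom–bust population under declining palm cover)
and run the full pipeline:

```
paleodyn synth --outdir demo --seed 5
cat > demo/config.yaml <<EOF
curve_terrestrial: demo/curve.txt
dates: demo/dates.csv
covariates: demo/covariates.csv
outdir: demo/out
n_sim: 100
drop_modern: false
seed: 11
EOF
paleodyn run --config demo/config.yaml
python - <<'PY'
import json
rep = json.load(open("demo/out/report.json"))
for f in rep["fits"]:
    print(f"{f['k_form']:9s} AICc={f['aicc']:8.2f} w={f['akaike_weight']:.3f} "
          f"predR2={f['pred_r2']:.3f}")
PY
```

which prints (seed 5 fixture, seed 11 pipeline):

```
constant  AICc= -101.29 w=0.000 predR2=-0.122
palm      AICc= -124.46 w=0.830 predR2=0.781
soi       AICc= -111.86 w=0.002 predR2=0.726
palm_soi  AICc= -121.27 w=0.168 predR2=0.772
```

The fixture's generating model is the palm-driven carrying capacity; it wins
most of the Akaike weight, and the covariate-driven models predict the
observed 30-yr series well (prediction R² ≈ 0.73–0.78) while the constant-K
logistic predicts worse than the series mean (negative R²). Artifacts (SPD,
demographic series, fit report, null-test envelope, trajectory bands, ratio
and vegetation regressions) land in `demo/out/` as CSV/JSON.

Real analyses use the same commands with published calibration-curve files
(e.g. SHCal13/Marine13 in the standard 3-column layout), a date table CSV and
covariate series; see `paleodyn --help` for the stage-by-stage subcommands
(`calibrate`, `spd`, `nulltest`, `fit`, `simulate`, `vegfit`).

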