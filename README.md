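# qrfcost

Quantile-regression-forest analysis of high-cost care episodes.

Healthcare expenditures are strongly right-skewed: a small group of
high-cost patients carries a disproportionate share of total spending,
and the covariates that drive the 90th percentile of cost are not the
ones that matter at the median. `qrfcost` implements a pipeline for
identifying and quantifying those upper-tail cost drivers, built around
episode-level oncology spending data (one row per 6-month chemotherapy
episode with eleven risk-adjustment covariates and a dollar cost), and
ships a calibrated synthetic episode generator with closed-form
conditional quantiles so every stage can be validated against known
ground truth.

The pipeline, for episode cost Y and covariates x:

1. **Quantile regression forest (QRF).** A regression forest is grown as
   usual, but each leaf keeps all response values. A query point x gives
   every training point i the weight
   w_i(x) = (1/T) Σ_t m_ti · 1{i ∈ leaf_t(x)} / M_t(leaf_t(x)),
   with m_ti the bootstrap multiplicity and M_t the leaf's in-bag mass;
   the conditional quantile is
   Q̂(τ|x) = inf{y : Σ_i w_i(x)·1{Y_i ≤ y} ≥ τ}.
2. **Out-of-bag model selection.** Backward stepwise elimination: at each
   step the covariate with the smallest permutation importance is
   dropped, the forest refit, and the out-of-bag average quantile loss
   AQL(τ) = mean ρ_τ(Y_i − Q̂_OOB(τ|x_i)) recorded at τ = 0.9 (the
   conventional high-cost threshold), where ρ_τ is the pinball loss.
   The optimal covariate set minimizes the recorded AQL; the share of
   the null-to-optimal AQL reduction attributable to each selected
   covariate is its relative importance (shares telescope to 1).
   Goodness of fit is R1 = 1 − Σρ_τ(model)/Σρ_τ(null quantile).
3. **Effect quantification.** Linear quantile regression of cost on the
   selected covariates at τ ∈ {0.1, 0.25, 0.5, 0.75, 0.9}, in thousands
   of dollars with 95% paired-bootstrap intervals, plus 3-df natural
   cubic spline fits for smoothed age / regional-cost effect curves.

See `docs/methods.md` for the model details, calibration, and design
decisions.

## Worked example

Run the full pipeline on a generated study-sized table (2,938 episodes,
200 trees; a few minutes on one CPU):

```bash
cat > run.yaml <<EOF
generator: {}
n_trees: 200
bootstrap_B: 200
seed: 1
EOF
qrfcost run --config run.yaml --out-dir run1
```

which prints

```
optimal set: chemo_drug, surgery, insurance, radiation, comorbidity_cat, clean_period_cat
OOB AQL 1994.3, R1 0.508 at tau 0.9
artifacts in run1
```

The selection kept six of the eight planted cost determinants and
discarded all three planted null covariates (sex, trial participation,
institutional status). `run1/relative_importance.csv` shows the
drug-class covariate dominating the upper tail — 93.8% of the
null-to-optimal AQL reduction:

```
variable,delta_aql,share
chemo_drug,1940.9,0.9384
insurance,27.9,0.0135
clean_period_cat,2.5,0.0012
radiation,57.4,0.0277
surgery,37.1,0.0179
comorbidity_cat,2.7,0.0013
```

and `run1/effect_table.csv` quantifies the tail amplification: the
Part B (infused chemotherapy) contrast versus Part D (oral/endocrine)
grows from $7.6k at the 10th percentile to $46.9k (95% CI 44.7–49.0) at
the 90th, and a short (1–61 day) chemotherapy clean period costs ~$0
extra at the 10th percentile but $5.5k (CI 3.8–6.7) at the 90th.
`run1/elbow.tsv` holds the AQL-versus-model-size series for the elbow
plot, and `run1/age_spline_curves.csv` the spline age-effect curves
(when age is selected).

Individual stages are also exposed (`qrfcost simulate`, `select`,
`effects`, `report`), and the library API mirrors them
(`qrfcost.generate_episodes`, `qrfcost.forest.fit_forest`,
`qrfcost.selection.backward_stepwise`, `qrfcost.effects.effect_table`).

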