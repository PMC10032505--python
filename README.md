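# cardreg

Exact L0-cardinality-constrained sparse regression for survival and
classification models, with grouped "kit" selection and cost-aware model
evaluation.

`cardreg` fits Cox proportional hazards (Breslow tie handling), logistic and
linear models under a hard bound `||beta||_0 <= K` on the number of nonzero
coefficients.  The discontinuous constraint is handled exactly through its
difference-of-convex reformulation with the largest-k norm,
`||beta||_1 - |||beta|||_[K] = 0`, turned into a penalty and minimized by a
DCA-style descent scheme (linearize the concave part, solve the convex
subproblem by accelerated proximal gradient with soft thresholding) under
geometric escalation of the penalty parameter.  An incremental multi-start
path algorithm produces one solution per cardinality `i = 1..K_max`, seeding
each stage from single-coordinate substitutions between the previous sparse
solution and the dense optimum.

Features that are measured together in clinical practice can be grouped into
kits with a single price; the cardinality constraint then counts kits rather
than features, and the evaluation layer prices models by charging each
touched kit once.  A packaged clinical laboratory kit table (prices
standardized so the PSA kit costs 100) ships with the package.

## Modules

- `cardreg.likelihoods` — model families (Cox/logistic/Gaussian), losses,
  gradients, Harrell's C-index, ROC-AUC, risk-set index construction.
- `cardreg.dc_penalty` — L0 pseudonorm, largest-k norm, the exact DC
  penalty, kit-grouped variants, subgradients.
- `cardreg.nsopt` — the DC descent solver, penalty escalation, restricted
  smooth refits.
- `cardreg.path` — the incremental multi-start cardinality path, starting
  point generation, screening acceleration for high dimensions.
- `cardreg.evaluation` — cross-validation (mean ± SEM per cardinality),
  bootstrap selection frequencies, kit costs, Pareto fronts of cost vs
  accuracy, SEM-based cardinality choice, greedy forward baseline.
- `cardreg.synthetic_io` — synthetic censored survival / binary data with
  known sparse ground truth, dataset and kit-table readers/writers.

## CLI

```sh
# simulate censored survival data with 3 true effects out of p=20
cardreg simulate --out data.csv --n 500 --p 20 --effects 1,1,1 --censoring 0.3 --seed 1

# fit the cardinality path up to 5 features
cardreg fit data.csv --out path.csv --kmax 5 --family cox --seed 1

# cross-validate, bootstrap, price a feature set, flag Pareto-dominated models
cardreg cv data.csv --out cv.csv --kmax 5 --folds 5 --seed 1
cardreg bootstrap data.csv --out freq.csv --kmax 5 -B 100 --seed 1
cardreg cost --features PSA,HB,ALP
cardreg pareto models.csv --out flagged.csv
```

Grouped selection: pass `--kits kits.csv` (columns `feature,kit,cost`) to
`fit`/`cv`/`bootstrap`; features absent from the table become free singleton
kits.  Solver knobs: `--rho-init/--rho-mult/--rho-max`, `--gamma` (starting
point screening fraction), `--standardize/--no-standardize`.

## Python API

```python
import cardreg as cr

data, truth = cr.simulate_cox_data(cr.SimulationSpec(n=500, p=20, seed=1))
path = cr.fit_path(data, "cox", K_max=5)
path.support(3)                      # selected features at cardinality 3
cv = cr.cross_validate(data, "cox", K_max=5, folds=5, seed=1)
cr.select_cardinality_sem(cv)        # sparsest model within one SEM of the best
cr.kit_cost({"PSA", "HB"}, cr.clinical_kits())
```

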