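# petomics

Radiogenomic analysis of colorectal cancer: integration of dynamic
F-18-FDG-PET kinetic measurements with paired tumor/normal gene expression,
composite-signature selection, and gene-signature survival stratification —
implemented as a tested, fully synthetic-data-driven pipeline.

## Who this is for

Researchers studying how quantitative PET kinetics relate to tumor
transcriptomics, and anyone who needs a reproducible, ground-truth-backed
sandbox for the statistical machinery of such studies: compartment-model
fitting, moderated paired differential expression, Multiple Factor Analysis
of mixed blocks, repeated cross-validation with feature selection, and
median-dichotomized signature survival analysis.

## The models at the core

**Two-tissue compartment FDG kinetics.** Tracer in a volume of interest is
described by a free pool C1 and a phosphorylated pool C2 exchanging with
plasma Cp:

    dC1/dt = k1·Cp − (k2 + k3)·C1 + k4·C2
    dC2/dt = k3·C1 − k4·C2
    Cmodel(t) = (1 − VB)·(C1 + C2) + VB·Cp(t)

with transport rates k1, k2, phosphorylation rate k3, dephosphorylation rate
k4 (all 1/min) and fractional blood volume VB. The net influx constant is
Ki = k1·k3/(k2 + k3). The model is solved analytically (biexponential
convolution) and fitted to 28-frame/60-min time-activity curves by
multi-start bounded nonlinear least squares (`TwoTissueModel.fit()` returns
a results object with estimates, standard errors and a `summary()`). Two
non-compartmental descriptors complete the 8-variable PET block: the
standardized uptake value (SUV) and a box-counting fractal dimension (FD) of
the time-activity curve.

**Downstream statistics.** Paired tumor-vs-normal differential expression
uses an empirical-Bayes moderated paired t with Benjamini-Hochberg control;
gene-PET association uses a Spearman screen (|rho| ≥ 0.6, p < .05); block
structure is quantified by Multiple Factor Analysis (each standardized block
weighted by its leading singular value); feature sets are compared under
repeated stratified 10-fold cross-validation with random forests and
compacted by an aggregated lasso (per-seed lambda.1se, selection frequency
≥ 0.5); the resulting gene signature is median-binarized, split into two
gene groups on normal-sample correlation structure, and the High/Low Group2
strata are compared by Kaplan-Meier curves, the log-rank test and a Cox
proportional-hazards model.

Every generator plants a recoverable ground truth (differential genes, a
latent tumor-metabolism factor coupling {SUV, k3, FD, Ki} to a gene subset
while {k1, k2, k4, VB} stay orthogonal, and a survival hazard ratio), so
each stage's statistical behaviour is testable.

## Worked example

```python
from petomics import CohortConfig, feng_input_function, fit_two_tissue
from petomics.synthetic import simulate_patient_kinetics

cfg = CohortConfig(n_patients=10, seed=7)
tacs, pet, truth = simulate_patient_kinetics(cfg)
cp = feng_input_function()
fit = fit_two_tissue(tacs[0], cp, seed=0)      # tumor curve of patient P001
true = truth.true_kinetics["P001"]
print(f"k3 true {true.k3:.4f}  fitted {fit.k3:.4f}")
print(f"Ki true {true.ki:.4f}  fitted {fit.ki:.4f}")
```

prints (exactly, for this seed):

```
k3 true 0.1217  fitted 0.1807
Ki true 0.0348  fitted 0.0407
```

This patient's curve carries heavy simulated measurement noise (its latent
metabolism factor is high, which in this generator also raises frame noise),
so the individual rate constants wobble while the compound influx constant
Ki — the quantity the k's exist to deliver — comes back within ~17%. On
noise-free curves the fit recovers every parameter to better than 1%
(`tests/test_acceptance.py`).
The full pipeline runs from the command line:

```bash
petomics run --seed 1 --outdir demo_run
```

which simulates the cohort, performs the three DE comparisons and their
consensus intersection, screens genes against the 8 PET variables, runs MFA,
evaluates Genes-only / PET-only / Composite classifiers, derives the compact
signature by aggregated lasso, scores the TCGA-like cohort and writes KM
curves, the log-rank p and the Group2 hazard ratio, plus a JSON run report
with per-file SHA-256 hashes (two runs with the same seed are byte-identical).

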