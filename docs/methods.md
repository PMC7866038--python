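# Methods

## Plasma pharmacokinetics

5-FU kinetics during a cycle follow a linear two-compartment model,

    dσ_B/dt = −k12·σ_B − σ_B·Cl/V + k21·σ_P + R·BSA/(Δt·V)
    dσ_P/dt =  k12·σ_B − k21·σ_P

with σ_B(0) = D·BSA/V when a bolus is given (else 0) and σ_P(0) = 0.
Parameters: k12 = 5.35 h⁻¹, k21 = 5.69 h⁻¹, Cl = 65.3 L/h (literature values
for 5-FU), V = (3.29·BSA − 1.229) L from the empirical blood-volume relation.
Concentrations are carried internally in mg/L and reported as µg/mL
(numerically identical). The bolus enters only through the initial condition
and the infusion only through the constant forcing term R·BSA/(Δt·V): the
clinical sequence is a D = 400 mg/m² push followed essentially immediately by
the R = 2400 mg/m² infusion over Δt = 46 h, which we treat as concomitant.

Two solution paths exist and are cross-validated against each other:

* `simulate_cycle` — adaptive stiff-capable integration (LSODA,
  rtol 1e−10, atol 1e−9), infusion and washout legs integrated separately
  because the forcing is discontinuous at Δt;
* `analytic_cycle` — the exact bi-exponential solution via the
  eigendecomposition of the 2×2 system matrix (matrix-exponential of the
  augmented affine system as fallback for degenerate or singular cases, e.g.
  k21 = 0).

The analytic path is the default inside the cohort pipeline; the numerical
path is validated against it to ≲1e−10 relative error.

Cycles are far apart relative to drug washout (slowest eigenvalue ≈ 3.7 h⁻¹
at default parameters against a 14-day FOLFOX interval), so each cycle is
simulated from a drug-free state over the full cycle interval (default 336 h)
and carry-over is neglected; the interval is configurable. AUC_i is the
trapezoidal integral of σ_B over that window, which captures the washout tail
and hence approximates total per-cycle exposure (D+R)·BSA/Cl. The default
grid step is 0.01 h: the bolus decays on a ≈0.05 h time scale and composite
trapezoid error grows with (rate·step)², so 0.01 h keeps the AUC error near
0.03% (0.1 h would already cost ≈3%). Cycle averages are
σ̄_B,i = AUC_i/Δt and σ̿_B = Σ AUC_i/(N·Δt), the latter computed by the sum
form and identical to the mean of the σ̄_B,i by construction.

## Perfusion surrogate

The blood volume fraction is approximated by the ratio of trapezoidal AUCs of
baseline-subtracted Hounsfield-unit enhancement in tumor and surrounding
liver over the three CT phases. Phase acquisition times are not part of an
ROI record; the default (0, 35, 70) s is standard three-phase liver timing
and cancels out of the ratio whenever both sites share times. The exact AUC
construction used on the original scans is not fully specified by its
sources, so trapezoid-over-three-phases is this package's documented
convention. Raw ratios outside [0, 1] (possible for hypervascular lesions or
noisy ROIs) are clamped to the model domain with a QC flag rather than
rejected; negative enhancement is retained with a warning.

## Transport model and eTSCC

`fkill_full` implements the closed-form cylindrical-geometry kill fraction
with scipy's K0/K1; underflow of K1(ρ/√BVF) at small BVF is the correct
limit and is silenced explicitly. The BVF = 0 and BVF = 1 endpoints use their
limiting values (0 and f_kill0). `penalty_factor` evaluates
2·K1(ρ)/(ρ·K0(ρ)) with exponentially scaled Bessel functions so it remains
finite for large ρ. At the default geometry r_b = 10 µm, L = 100 µm
(ρ = 0.1) it equals ≈81.2 (≈40.6 without the leading 2); the factor is
patient-independent and is removed by the normalisation convention below, so
its absolute value never enters the estimates.

Proportionality relations are promoted to equalities under one convention:

    ⟨σ_T,B⟩ = σ̿_B · (N·Δt/t) · (CEA_ref/CEA),     ⟨σ_T⟩ = ⟨σ_T,B⟩ · BVF

with CEA_ref = 13.4 ng/mL (the cohort-median CEA), which keeps the burden
factor dimensionless and eTSCC on the plasma-concentration scale. λ = N/t
uses t in hours, so λ·Δt is a duty cycle in [0, 1] (warned when above 1).
CEA, not lesion size, carries the burden scaling, since serum CEA summarises
total burden across multiple lesions. Because the original normalisation
constants are not recoverable, absolute eTSCC values (and therefore any fixed
discrimination threshold, or the plasma-to-tumor ratio) are meaningful only
relative to this convention; the classifier always re-derives its threshold
from the data at hand instead of hard-coding a published cut-off.

## Classification

Responder = TRG 1–2. This cut makes the per-class accuracy arithmetic
consistent with a 6/27 responder/non-responder split (5/6 = 83.3%,
22/27 = 81.5%, pooled 27/33 = 81.8%); it is configurable.

The ROC curve is the empirical one over all distinct score cuts
(rule: score > threshold → responder); its trapezoidal AUC equals the
Mann-Whitney concordance with half credit for ties — asserted exactly in the
tests. The discrimination threshold maximises pooled accuracy; accuracy ties
between cut intervals are broken toward the lowest interval's midpoint
(reproducible, favours sensitivity), with the below-minimum/above-maximum
cuts offset by half the smallest score gap. Because the logistic transform is
monotone, cutting raw eTSCC and cutting fitted probability give identical
partitions, so raw-score cuts are used. The logistic fit itself is IRLS
maximum likelihood; on separable data the iteration is capped and the fit
flagged rather than refused.

LOOCV runs n folds: each re-derives ROC and threshold on n−1 patients
(id bookkeeping asserts the held-out point is never trained on), classifies
the held-out score, and the n pooled predictions give the cross-validated
accuracies alongside mean ± SD of fold AUCs. Single-class training folds are
handled by majority rule with a warning.

The ordinal companion model is a proportional-odds cumulative-logit fit,
logit P(TRG ≤ i) = α_i + β′X, with α_i non-decreasing in i (the sign/order
convention implied by cumulative probabilities increasing in i). It is fit by
statsmodels' ordinal MLE, with parameters translated into this convention and
threshold standard errors obtained by the delta method; the intercept-only
model uses its closed form α_i = logit(cumulative proportions). Categorical
covariates are indicator-coded with reference levels female, metachronous
presentation, no extrahepatic disease, right-colon primary. A constant or
otherwise collinear covariate makes the model unidentified; the fit refuses
rank-deficient designs and names the collinear columns.

## Synthetic cohorts

The generator emulates the study's assumed structure: lesion size uniform on
1–10 cm; CEA = 0.6 + 4.0·size + N(0, 5) ng/mL truncated at 1 (median ≈13.4
at the median size 3.2 cm); BVF = 0.45 − 0.035·size + N(0, 0.05) clamped to
(0.01, 0.99) — a config whose clamping rate exceeds 50% is rejected as
infeasible; BSA ~ N(1.8, 0.2); 1–9 cycles peaked at 4; treatment span
(N−1)·336 h + 46 h + a 2–8-week lag to surgery; regimen labels mixed
25:1:7 (all sharing the 5-FU backbone, which is the only modelled drug). The
slope/intercept values are chosen to land CEA and perfusion inside the
published cohort ranges; they are synthetic settings, not estimates of any
fitted regression. CT ROI rows are back-computed from a fixed liver
enhancement template (55→125→115 HU) with the tumor curve scaled by BVF, so
reading the written table reproduces each patient's BVF exactly.

TRG is generated *from* eTSCC (the causal direction of the model): a latent
u = log⟨σ_T⟩ + N(0, 0.9) is cut at descending thresholds
(−1.3, −2.35, −3.35, −4.8), giving ≈6/12/22/38/21% across grades 1–5 and a
responder-classification AUC ≈0.9 at the defaults; sending the noise SD to
infinity decouples TRG from eTSCC and drives the AUC to 0.5. All randomness
flows from a single numpy Generator seeded once.

The deterministic 33-patient reference cohort uses fixed sorted sequences
for size, age, lesion count and cycles with the published medians and
ranges; CEA is exactly linear in size and BVF exactly linear-decreasing;
categorical counts match the published table exactly and an automated audit
(`audit_fixture`) checks every marginal. TRG is assigned by descending eTSCC
rank in the published counts 2/4/8/13/6, which makes the fixture perfectly
separable (AUC = 1) — useful as a pipeline oracle, not as a realism claim.

What the synthetic data do not emulate: real CEA kinetics over time, scanner
physics and ROI-placement noise, regimen-specific pharmacology beyond 5-FU,
correlated clinical covariates, and the unknown true joint distribution of
the original cohort. Passing tests therefore demonstrate internal
correctness and qualitative reproduction of the study's structure (strong
eTSCC–response discrimination, hypovascular perfusion, negative
size–perfusion and eTSCC–TRG associations), not clinical performance on real
patients.

## Problem sizes and numerical choices

The test suite and acceptance script use: 100-draw randomized PK sweeps
against the closed-form oracle (tolerance 1e−6 relative, normalised by the
profile peak); 1% exposure-conservation tolerance on 336-h grids; a
100×100 (ρ, BVF) grid for kill-fraction bounds; 1000 random data sets for
the AUC/Mann-Whitney and threshold/enumeration identities; n = 1000 for
logistic and ordinal parameter recovery (3-SE criterion); 50 replicates of
n = 200 cohorts for the null-link AUC → 0.5 ± 0.03 check; and n = 2000 for
structural-correlation sign checks. These sizes make the full suite run in
about two minutes on one CPU while keeping the Monte-Carlo checks
well-resolved.

## Known limitations

* The eTSCC scale depends on the normalisation convention (CEA_ref, dropped
  penalty factor), so absolute thresholds do not transfer between data sets;
  only the re-derived threshold and rank-based quantities (AUC) do.
* Linear PK only: no saturable elimination, DPD pharmacogenetics, or
  companion-drug (oxaliplatin/irinotecan/leucovorin/bevacizumab) modelling.
* The perfusion surrogate consumes ROI mean-HU tables; it does not model
  acquisition, segmentation, or deconvolution-based perfusion.
* Spatially resolved intratumoral concentration fields and interstitial
  pressure are outside the closed-form cylindrical solution used here.
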