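# Methods

This note documents the model, its numerical treatment, the virtual-trial
and biomarker conventions, and the design decisions taken where more than
one reasonable choice existed. Units throughout: cells for cell counts, nM
for soluble species, molecules/cell for surface species, day for time, cm
for diameters, L for pharmacokinetic volumes.

## Model structure

The system couples nine compartments: central (blood), peripheral, four
tumors (primary; two lung metastases; one "other" metastasis pooling all
non-lung sites) and three tumor-draining lymph nodes (primary, lung,
other; both lung lesions drain into the single lung node). It is a
reduced-order system: one governing ODE per biological species (about 230
states), assembled exclusively from a small set of mechanism classes —
Gompertz growth, first-order turnover, Hill activation/inhibition, and
competitive binding at quasi-equilibrium. Two lung lesions are modelled
because response evaluation tracks at most two target lesions per organ.

### Cancer cells and vasculature

Each tumor holds five cancer clones. Clone c grows as

    dN_c/dt = k_c N_c ln(K / max(N, 1)),   N = Σ_c N_c,

a modified Gompertz law against a shared dynamic carrying capacity K. When
the burden exceeds K the logarithm is negative (net cell loss); its
magnitude is capped at `ln_cap` = 10 to bound stiffness. K itself follows

    dK/dt = k_Kg · K · A/(A + EC50_A) − k_Kd · K,

driven by angiogenic factors A secreted by cancer cells and M2
macrophages; K is floored at `K_min` so the Gompertz term stays defined,
and the floor also makes the empty system (all cell counts zero, K at the
floor) an exact fixed point of the assembled right-hand side. There is no
upper cap on K: in progressing patients the capacity can outrun the burden
and growth approaches exponential at rate k_c·ln_cap-bounded log terms;
this is a known idealization that only affects the magnitude (not the
classification) of progressive disease.

Cancer cells die by first-order apoptosis, by T-cell killing and by M1
phagocytosis; total killing is apportioned across clones in proportion to
clone abundance, because cytotoxic T cells of any specificity are assumed
to recognize every clone. Dying cells release neo-antigens according to a
per-tumor binary clone-by-epitope expression matrix (five clones × eight
epitopes) plus a self-antigen, feeding the presentation chain.

### Antigen presentation and T-cell activation

The intracellular processing chain is collapsed to a quasi-steady-state
presentation level per epitope,

    pMHC_e = Ag_e / (Ag_e + α · Kd_pMHC),

retaining the dependence on the peptide-MHC dissociation constant that the
sensitivity analysis varies. Immature APCs are recruited by tumor CCL2,
mature on antigen (enhanced by IL-12, inhibited by IL-10) and migrate to
the draining lymph node. Naive CD8 activation there is

    act_e = k_act · (n_clono/n_ref) · N8_LN · f_APC · H_TCR(pMHC_e),

with H_TCR a Hill function (coefficient 2). The clonotype number per
specificity scales precursor availability. Activated cells expand by
2^n divisions with

    n = d_TCR·H_TCR + d_CD28·f_CD28 + d_IL2·f_IL2,

where f_CD28 is the CD28 occupancy from a two-receptor/one-ligand
competitive equilibrium (CTLA-4 competes for the CD80/86 pool; CTLA-4
level is a fixed parameter since CTLA-4-directed therapy is out of scope)
and f_IL2 saturates in lymph-node IL-2 secreted by helper T cells. Helper
T cells respond to the pooled neo-epitope presentation and regulatory
T cells to self-antigen presentation, with the same division program.
Effectors egress to blood and infiltrate tumors at a rate scaling with
lesion volume and the vascular factor K/(K + K_half).

### Checkpoint, killing, exhaustion

PD-1 occupancy is a competitive quasi-equilibrium among PD-L1, PD-L2
(surface species, subject to depletion) and the antibody (reservoir, no
depletion), solved inside every right-hand-side evaluation. Surface
densities convert to synapse concentrations by a single constant
(`conv_surf`, nM per molecule/cell) — a documented unit bridge, not a
fitted quantity. The Hill term H_PD1 of ligand-bound PD-1 suppresses both
killing and phagocytosis and drives exhaustion. Killing is
ratio-dependent:

    kill = k_kill · C · R/(R + R_half) · (1 − H_PD1) · Π_s EC50_s/(EC50_s + s),

R = T/C, with independent inhibitory factors for TGF-β, arginase-I and NO.
Exhausted cytotoxic T cells retain no killing activity (design choice).
Exhaustion has a PD-1-driven and an IL-10-driven component; TGF-β and
arginase-I trans-differentiate helper T cells into Tregs. PD-L1 relaxes
toward a baseline plus an IFN-γ-saturating induction, gated on
cancer-cell presence so the empty system remains stationary.

### Myeloid compartment

M1 macrophages and MDSCs are recruited by tumor CCL2 (saturating, scaled
by the vascular factor); M1↔M2 polarization is reversible with IL-10/TGF-β
pushing toward M2 and IL-12/IFN-γ back toward M1; phagocytosis by M1 is
inhibited by IL-10, PD-1 ligation and a fixed SIRPα ("don't-eat-me")
factor. MDSCs secrete arginase-I and NO; M1 secrete IL-12; M2 secrete
IL-10, TGF-β and angiogenic factors; cancer cells secrete CCL2; active
T cells secrete IFN-γ.

### Pharmacokinetics

Pembrolizumab follows a linear mammillary model on drug amounts:
clearance from central, central↔peripheral and central↔tumor exchange, and
unidirectional tumor→lymph-node→central lymphatic transport. Every matrix
column sums to zero except central (−k_clear), so total mass plus the
clearance integral is conserved — a tested invariant. Dosing is an
instantaneous bolus (negligible error at 3-week spacing); there is no
target-mediated disposition. Defaults are literature-typical for
pembrolizumab (CL ≈ 0.22 L/day, V_central 3.5 L, MW 149 kDa); a 200 mg
dose gives ≈ 384 nM in central, far above the ~0.03 nM dissociation
constant, so PD-1 is essentially saturated throughout a 3-week cycle —
response heterogeneity is immunological, not pharmacokinetic, which
matches the clinical picture for this antibody.

## Parameter defaults

All constants live in one table (`tnbcqsp.params.KINETIC_FIELDS`) with
units, and can be overridden from YAML. Defaults were chosen to place the
default patient in a clinically plausible regime rather than fitted to any
dataset: metastases grow from a ~100-cell inoculum to the centimeter scale
in roughly one to two years; tumor-infiltrating lymphocytes reach a few
percent to ~15% of cells; baseline ligand-bound PD-1 is high (strong
exhaustion) so checkpoint blockade produces a large relief factor in
immunologically "hot" patients and little change in "cold" ones. The
killing half-max ratio (`KD_ratio_half` = 1.5) and the activation-rate
median were set so that a default cohort splits into a minority of deep
responders and a majority of progressors, consistent with response rates
reported for pembrolizumab monotherapy in previously treated metastatic
TNBC (KEYNOTE-119-like, ORR of order 10%).

## Virtual population

The generator emulates a previously treated metastatic TNBC population:

* the primary tumor is resected (cancer count zero) unless
  `primary_tumor_intact` is set, in which case it seeds at day zero;
* up to two lung and one other metastasis seed at log-normal times
  (medians 300/180 days by default; the lung median is the calibration
  handle for lung-metastasis prevalence);
* ~17 parameters vary across patients by Latin hypercube sampling with
  log-normal marginals centred on the kinetic defaults (killing rate,
  activation rate, clonotype number, exhaustion rate, peptide-MHC
  affinity, infiltration, suppressor secretion, target diameter, growth
  scale), and five vary independently per tumor (PD-L1 baseline,
  recruitment rates, polarization) to create tumor-to-tumor heterogeneity;
* clone composition is symmetric Dirichlet(1) per tumor, clone growth
  multipliers log-normal (σ_log 0.3), epitope expression Bernoulli(0.5)
  per clone-epitope pair;
* the seeding inoculum is 100 cells;
* the untreated model integrates from the earliest seeding event until any
  metastatic lesion reaches the patient's sampled target diameter
  (log-normal, median 1.65 cm — the second calibration handle); patients
  that never reach it within `max_burnin_days` (1500) are discarded, and
  solver failures are flagged separately from filter rejections. Lesions
  whose seeding time falls beyond the burn-in stop never establish, which
  is what makes the lung-metastasis prevalence an emergent, calibratable
  quantity.

What the generator does **not** emulate: mechanistic dissemination (seeding
times are sampled, not caused), plausibility filtering on species ranges,
non-target/new lesions, and any patient-level clinical covariates. Tests
passing on these cohorts therefore validate the machinery and its stated
statistical behaviour, not the clinical accuracy of any particular rate
constant.

## Trial and response scoring

Treatment is 200 mg every 3 weeks (config-overridable); default horizon
730 days, with a 400-day preset used for primary-vs-metastasis comparisons
in the intact-primary cohort. Diameters derive from cancer-cell counts as
spheres of summed cell volume (immune/stromal volume ignored — a
systematic, documented simplification), assessed every 9 weeks. RECIST
v1.1 thresholds are taken from the standard: PR at ≤70% of baseline sum,
PD at ≥120% of the nadir **and** ≥5 mm absolute increase, CR when every
lesion is below a 2 mm disappearance threshold (such lesions contribute
zero to the sum); stable disease requires a non-PD assessment at or after
24 weeks from treatment start with no earlier PD, otherwise the patient is
PD by default. No confirmation scan is required; best overall response is
reported. Time to response is the first CR/PR assessment; duration of
response runs to the first subsequent PD or, for patients who never
progress, to the end of simulation. Trial endpoints (ORR over evaluable
patients; median DoR/TTR over CR/PR patients only) carry percentile
bootstrap 95% CIs over patient resampling (1000 resamples, seeded).

## Biomarker analysis

Responders are CR/PR/SD; nonresponders PD. Candidates are extracted from
the baseline state, averaging tumor-level quantities over the patient's
established metastatic lesions and lymph-node quantities over their
draining nodes. The registry covers densities and concentrations per
compartment class, derived ratios and fractions (including the TIL
fraction and the suppressive:activating ratio, aggregated as
(Treg+M2+MDSC)/(Tcyt+Th+M1)), PD-L1, the clonotype count, the initial
tumor diameter, and diversity profiles. APC density pools mature and
immature cells. Diversity uses richness S (classes above a 1-cell
extinction threshold, since ODE abundances never reach exact zero),
Shannon index H = −Σ p_k ln p_k in nats over surviving classes, and
evenness J = H/ln S (undefined for S ≤ 1). Cytotoxic T-cell diversity is
computed over the eight neo-epitope specificities; clonotype-level
richness multiplies by the per-specificity clonotype number.

Subgroups use 8 uniformly spaced cutoffs per candidate, taken as the
*interior* grid points of the observed range (the extremes themselves
always define an empty or singleton subgroup); each cutoff defines an
"above" (≥) and "below" (<) subgroup, overlapping by construction, and
subgroups under 20 patients are discarded. Patients with an absent value
(e.g. an undefined ratio) are excluded pairwise. Candidate pairs use
conjunctions of one condition per candidate (≤256 combinations per pair)
and also report the percent change of the pair's best score against the
better constituent single. Bootstrap CIs resample patients with thresholds
held fixed; ties in ranking break by larger subgroup, then name, for
reproducibility.

## Sensitivity analysis

Varied parameters are ranked by reusing the subgroup machinery with the
per-patient parameter values as candidates (15 cutoffs, minimum subgroup
20). Fixed parameters are perturbed multiplicatively (0.5–1.5) and the
identical cohort is re-simulated *from the unchanged baseline states*
(perturbing the burn-in too would change the baselines and conflate
population shifts with treatment-response shifts); outputs are the ORR per
factor and the PD/SD/PR-CR transition matrix against the unperturbed run,
which is diagonal at factor 1 by construction.

## Calibration

Metastasis immune content: recruitment rates of M1/MDSC/APC and the M1→M2
polarization rate (per site: lung lesions or the "other" lesion) are
fitted so that simulated relative abundances — cell-type fraction of all
cells in the metastasis divided by the same fraction in the matched
primary tumor of one reference patient, both snapshots taken when the
lesion reaches a matching 1 cm diameter — match a target ratio table. The
loss is the mean squared log-ratio error (ratios are multiplicative);
optimization is bounded Nelder–Mead in log10-multiplier space (default
budget 200 evaluations), returning the best-seen point. The shipped target
table (`data/abundance_targets_synthetic.csv`) is a synthetic stand-in
encoding the qualitative pattern of reduced lymphocyte content in
metastases with wide tolerances; users with transcriptome-deconvolution
estimates substitute their own CSV. MDSC targets are monocyte-proxied by
upstream-tool convention.

Trial-level handles: the target-diameter median passes through the
acceptance filter almost unchanged, so a proportional update converges in
one or two 200-patient cohort evaluations; the lung seeding-time median is
solved by bisection on the log median (prevalence decreases monotonically
as lung lesions seed later), with each evaluation averaged over two cohort
replicates and an internal stopping tolerance of 40% of the acceptance
tolerance, so that a freshly seeded 200-patient cohort still lands within
±5 percentage points of the 65% prevalence target (seed-to-seed standard
deviation of the prevalence at fixed median is ≈2.4 points at this cohort
size, reduced below the binomial value by the Latin hypercube
stratification).

## Numerics

* Integration: `scipy.integrate.solve_ivp` with LSODA (stiffness-
  switching; the compiled right-hand side makes its internal finite-
  difference Jacobian cheap), rtol 1e-6, per-species atol (1e-3 cells,
  1e-9 nM). BDF with a cached, perturbation-probed Jacobian sparsity
  pattern is available as an alternative. Output is recorded on a 1-day
  grid during treatment; step size is left to the error control (a hard
  1-day step cap would make cohort-scale simulation needlessly slow
  without changing results at these tolerances — the Gompertz closed-form
  test pins the accuracy).
* The right-hand side is a single kernel written in an njit-compatible
  subset of Python, compiled with numba when available (~2 µs per
  evaluation) and executed as plain Python otherwise; the mechanism-layer
  functions are the reference implementations and the test suite
  cross-checks assembled derivative entries against them.
* The checkpoint and synapse equilibria use a safeguarded Newton iteration
  on the free-receptor (or free-ligand) concentration, bracketed by
  closed-form bounds; tests verify <1e-8 agreement with an independent
  mass-balance root finder.
* Negativity: rate laws read the state clipped at zero; returned
  trajectories are clipped post hoc. Excursions are logged as warnings
  only beyond ten times the larger of the absolute tolerance and the
  local-error scale rtol·max|y| — below that they are expected roundoff
  of the error-controlled solver (IL-2 and IFN-γ, with fast turnover,
  touch ≈ −1e-7 nM routinely).
* Dose events restart the integrator; a zero-dose regimen is bitwise
  identical to an untreated continuation (tested).
* Determinism: every stochastic step (sampling, seeding, bootstrap,
  fitting) is seeded; reruns are byte-identical.

## Problem sizes

The shipped test suite and the reproduction script run cohorts of 12–200
patients and treatment horizons of 189–567 days; these sizes give stable
statistics (the two calibrated trial targets are reproduced on fresh seeds
well within their tolerances) while keeping a full run in minutes on one
CPU. Full-scale studies (1000 sampled patients, 730-day horizons, pair
rankings over the complete candidate registry) use the same code paths and
scale linearly in patients.

## Known limitations

* The supplementary-scale equation system of the source platform class
  (hundreds of equations with individually referenced constants) is
  deliberately reduced to one equation per species; defaults are
  representative, not data-fitted, so absolute response rates should be
  read as regime-level, not predictive.
* No non-target or new-lesion progression; PD can only arise from target
  lesions.
* No chemotherapy module; the pretreated-population state is emulated only
  through the immune-content calibration hooks.
* Diameters count cancer-cell volume only.
* Carrying capacity is uncapped (see above).
* Tumors are well-mixed; no spatial structure, CAFs, B cells or tertiary
  lymphoid structures.
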