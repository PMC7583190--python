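# Methods

This note records the models the package implements, the assumptions
behind them, the places where the design was genuinely open and what we
chose, and what the synthetic-data tests do and do not demonstrate.

## Cell growth / kill model

Untreated PANC-1 cells grow exponentially with net rate constant
`k_G = 0.0225 /h` (doubling time 30.8 h). Each drug adds a cytotoxic
signal, a Hill function of its constant medium concentration,

    S0_x = K_max,x · C_x / (Ψ · KC50,x + C_x),    x ∈ {B, P},

routed through `n` first-order transit compartments (rate `n/τ` each,
so τ is the mean transit time at any depth) before it removes cells:
`dN/dt = (k_G − S_B[n] − S_P[n])·N`. Defaults: `K_max,P = 0.0233 /h`,
`KC50,P = 18.3 nM`, `K_max,B = 0.0153 /h`, `KC50,B = 277 nM`. Because
`K_max,P > k_G > K_max,B`, saturating PTX can eradicate the culture
while saturating BRP only slows it — a structural property the tests
assert. Ψ multiplies both drugs' `KC50` symmetrically in combination
arms (Ψ = 0.69 cuts each effective `KC50` by 31%) and is pinned to 1
for single-agent arms.

With constant concentrations the system is solvable in closed form: the
chain output is `S0·P(n, rt)` (regularized lower incomplete gamma, i.e.
an Erlang CDF) and its time integral is analytic, so `N(t)` needs no
numerical integration. The closed form is the default simulation path;
an LSODA integration of the same ODEs is kept as an independent route
and the two agree to 1e-6 in the tests.

Open choices: the transit-chain depth and τ are not identifiable from
the package's own defaults (the original estimates live outside the
main-text record), so the synthetic ground truth uses `n = 3`,
`τ_B = τ_P = 24 h`, configurable; AIC over depths 0–5 is available in
`fit_growth(n_transit="auto")`. The SRB polyploidy correction
`CF = (N_dip + N_poly)/(N_dip + w·N_poly)` uses weight `w = 2`
(polyploid cells carry twice the protein), configurable.

## Protein interaction network

Each of the ten proteins is a fold-change relative to time-matched
vehicle control, with baseline exactly 1, following an indirect-response
model whose synthesis side carries all regulation:

    dP_i/dt = k_deg,i (1+Sti_i)(1−Inh_i) Π_j P_j^γ_ij − k_deg,i (1−InhDeg_i) P_i.

Since baseline = 1, `k_syn = k_deg`; `k_deg` therefore describes the
turnover of the fold-change signal, not of the molecules themselves.
Drug inputs at the reference exposure (100 nM BRP / 10 nM PTX):
cIAP1 synthesis ×(1−0.967) under BRP; ELYS synthesis ×(1+2.22) under
PTX; IRAK4 synthesis ×(1+0.960) under any treatment; pJNK degradation
fully blocked (the sole degradation-side effect) under the combination
only. Regulatory powers: pNF-κB ⊣ cIAP1 (−0.298); BAX ← pNF-κB (1.85)
with self-feedback −9.55; Bcl2 ← pNF-κB (0.768), ← pSTAT3 (1.33),
⊣ VDAC1 (−4.16); pSTAT3 ← IRAK4 (1.0), ⊣ pJNK (−2.30); VDAC1 ← pJNK
(1.0); ELYS self-feedback −6.10; ASPP2 ← ELYS (1.0).

Structural consequences the tests verify: the untreated network is
exactly stationary; the no-drug state is a global attractor (washout
relaxes any perturbation back to 1); ELYS saturates at
`(1+2.22)^{1/7.1} ≈ 1.18`; pNF-κB rises to `0.033^{−0.298} ≈ 2.76`
under BRP; Bcl2 falls below baseline at 48–72 h only under the
combination (the pJNK → VDAC1 ⊣ Bcl2 route).

`fit_network` fits log2 fold-changes under a constant error model in
ten sequential stages ordered by signal flow (direct drug targets
first, their downstream readouts afterwards, Bcl2 — fed by three
branches — last), freezing every upstream estimate. Replicate-level
residuals are the default; profile means are an option.

## Cell-cycle / apoptosis model

Compartments G0/G1 → S → G2/M with rate constants `k12 = 4.48e-2`,
`k23 = 0.129`, `k31 = 8.07e-2 /h`; division returns `2·k31·M` cells to
G0/G1. Contact inhibition multiplies `k12` by the Gompertz factor
`I0 = ln(N_max·live0) − ln(live)` with `N_max = 7.43` and
`live0 = 2e5`, where `live = G1+S+M+MA+PL` (all adherent,
resource-consuming cells). Cycling cells die spontaneously at
`k_ap·cIAP^{−0.532}` (`k_ap = 2.18e-3 /h`); the apoptotic pool clears
at the unmodified `k_ap`. ELYS above baseline gates mitotic arrest,
`k_ma = k_ma0·ELYS³·(ELYS>1)`; arrested cells either die at
`k_apm = k_apm0·ASPP2_delayed·cIAP^{−0.0772}·BAX^{0.208}/Bcl2`
(`k_apm0 = 0.111 /h`, ASPP2 delayed through a 3-stage transit chain,
τ = 24 h default) or slip into the absorbing, apoptosis-resistant
polyploid pool at `k_pl = 1.97e-2 /h`. The bookkeeping identity
`d(total)/dt = k31·M − k_ap·Apo` (division the only source, clearance
the only sink) holds algebraically and is checked numerically.

The ELYS gate is implemented as the exact indicator rather than a
smoothed switch: any smooth gate is nonzero at ELYS = 1 and would leak
cells into mitotic arrest in control simulations, violating the
requirement that the drug machinery be exactly inert at baseline.
Under PTX the gate switches once at t = 0⁺, which LSODA handles
without difficulty.

The initial phase distribution at T0 was fitted in the original
analysis but not published; the package's default is the dominant
eigenvector of the cycling subsystem at seeding density — the mix a
culture growing at that density settles into — which gives
G1/S/G2M ≈ 44/25/31%, consistent with the partially synchronized,
G2/M-rich cultures the assay format produces. `fit_cycle` re-fits the
3-vector per dataset. The T0 apoptotic fraction defaults to 0.

Two printed checkpoints do not reproduce from the printed parameter
set and are documented rather than forced. First, the doubling-time
formula `1/(k12·I0) + 1/k23 + 1/(2·k31)` evaluated after 72 h of
simulated control growth gives 50.5 h against the published 53.6 h
(5.9% low); the gap traces to the unpublished T0 phase distribution,
and the published prose is itself inconsistent here (it reports the
culture both at the 7.43-fold capacity at 72 h, which implies an
infinite formula value, and at 53.6 h, which implies 4.23-fold).
Second, the combination-arm `k_apm(72 h)` computes to ≈ 0.57 /h, not
the published 0.29 /h: the printed formula with the printed parameters
would need Bcl2(72 h) ≈ 0.61, whereas the network (and the published
expression data) put Bcl2 near 0.3–0.4, so the printed value appears
inconsistent with the printed formula. The package follows the
formulas.

Concentration extrapolation converts each fitted effect magnitude to a
Michaelis–Menten form. Inhibition (unit ceiling):
`IC50 = C_ref(1−E)/E`, e.g. 3.41 nM for BRP on cIAP1. Stimulation is
underdetermined by a single reference point; the package keeps the
fitted magnitude as the ceiling and treats the reference exposure as
96.7%-saturating (the saturation fraction of the one pinned-down
case), so `EC50 = C_ref·0.0341`. The combination-only pJNK effect
scales as the product of the two occupancies; IRAK4 is
dose-independent. The 96-well plate context sets `N_max = 30` and
`k_ma0 → 1.67e-2 /h` as absolute values (idempotent).

## Estimation

Gaussian maximum likelihood with two error models: constant
(`Var = δ²`; percentages, log2 fold-changes) and affine-proportional
(`Var = (δ+σY)²`; densities, counts); mixed-observable fits (cycle
model) stack blocks with per-block variance. δ and σ are co-estimated
wherever the data support it and assumed shared across arms.
Optimization is derivative-free Nelder–Mead on transformed parameters
(log for positive rates and variance terms, logistic for boxes; power
coefficients unconstrained), objective tolerance 1e-8 (relaxed to 1e-6
for ODE-backed objectives so the simplex does not chase integrator
noise), 5000 iterations per start. Multi-start is seeded: a random
pre-scan (10·dim candidates, two jitter scales in transformed space)
ranks starting points and the best ones seed independent simplex runs,
followed by a restart at the incumbent — this reliably escapes the
plateau that post-equilibration protein time courses create in the
turnover rate. CV% comes from the inverse of a central finite-difference
observed-information matrix — the standard asymptotic ML approximation,
which the original report does not specify; Ψ additionally gets a
seeded parametric-bootstrap CI (200 replicates) as an option. AIC
(−2·loglik + 2·n_free) selects the transit depth, ties toward fewer
compartments. Sequential fitting freezes all upstream estimates and
refuses stage orders that precede a declared dependency.

## Temporal proteomics

Quantile normalization maps every sample's sorted intensities onto the
mean-quantile reference (ranks preserved, ties averaged); it is
idempotent. Fold changes are log2 of treated over time-matched control
group means (normalization to each arm's own T0 is available). Plain
seeded k-means on the log2 profile vectors replaces the original
STEM-based workflow — the published account describes the method as
k-means, and STEM's model-profile machinery is deliberately not
reproduced. The cluster count minimizes the maximum member-to-centroid
deviation with a parsimony rule: raw minimization is monotone in k, so
the selected k is the smallest whose deviation is within 15% of the
best seen over the scan range (the tolerance absorbs the ~10%
run-to-run jitter that k-means restarts leave in adjacent-k maxima).

## Synthetic data

Generators draw every input kind from the fitted models at the
published estimates (Ψ = 0.69 ground truth) with the study's designs:
6 PTX × 4 BRP levels plus all 24 combinations, triplicates, 24–120 h
for growth; the four reference arms at 0/17/48/72 h for cell cycle;
{B, P, BP} at 6/24/48/72 h for protein profiles. Noise magnitudes are
not published; the defaults (density δ = 0.05, σ = 0.1; percentages
δ = 2 points, renormalized to sum 100; counts δ = 5e3, σ = 0.05,
negative draws redrawn; log2 fold-changes δ = 0.2) give replicate
scatter comparable to the published error bars. Fixed seed means
byte-identical output.

The clustering matrix emulates the two-experiment structure of the
original proteome study: treatment arms in one batch, the unperturbed
control time course in a separate batch, so every control-matched
fold-change crosses the batch boundary. 3325 proteins carry one of 9
temporal archetypes (balanced up/down patterns, cluster sizes drawn in
30–508); the baseline batch adds a saturating detector response plus
per-sample loading factors — rank-preserving, hence exactly removable
by quantile normalization, but biasing raw cross-batch ratios by an
abundance-dependent offset. On this design normalization is
load-bearing: planted-label recovery (adjusted Rand index) is ≈ 0.9
with it and ≈ 0.37 without.

What the synthetic tests show — and what they do not: parameter
recovery and pipeline correctness are demonstrated against data whose
generating process *is* the model, with independent Gaussian noise.
Real cultures violate this in known ways (replicate correlation within
plates, drug instability past 72 h, SRB linearity limits, cell-cycle
deconvolution error, peptide-level MS noise), so passing tests certify
the software and the identifiability of the design, not the biological
adequacy of the model.

## Problem sizes

The default test and acceptance workloads are deliberately desk-scale:
525-point growth tables (35 arms × 5 times × 3 replicates), 72-hour
ODE horizons, the full 3325 × 48 clustering matrix, and 10·dim
pre-scan points per fit stage; each fit completes in seconds to tens
of seconds on one core.
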