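# Methods

This note documents the model as implemented: its structure, assumptions,
parameter provenance, numerical choices, and what the shipped tests do and
do not establish.

## Scope and philosophy

The package is a reduced, fully open re-expression of a liver QST
architecture: ordinary differential equations plus algebraic expressions
linking drug exposure to hepatocyte health and plasma biomarkers. Every
rate constant is either (i) anchored to a printed measurement (partition
anchors, chip endpoint percentages, clinical Cmax), (ii) derived from a
baseline balance so that the drug-free state is a steady state by
construction, or (iii) a tuned gain whose value was fixed once against the
categorical clinical pattern (cohort ULN-category outcomes and
sensitivity-scan orderings) and then frozen. No parameter is fitted at run
time except the explicit calibration operations.

## Exposure

Two-compartment macromolecule PK with parallel linear and saturable
elimination, per kg of body weight. Tocilizumab defaults
(Vc 0.034 L/kg, Vp 0.045 L/kg, Q 0.006 L/h/kg, CL 2.2·10⁻⁴ L/h/kg,
TMDD Vmax 2.5·10⁻³ conc·L/h/kg, Km 3 µg/mL) are design values chosen so
that 8 mg/kg IV every 4 weeks reaches a steady-state Cmax ≈ 233 µg/mL with
a trough of a few µg/mL and target-mediated elimination dominating at low
concentrations. GGF2 is given a ~12 h terminal half-life (single-dose
protocol only). Acetaminophen uses standard one-compartment oral PK
(ka 1.5 /h, CL/F 21 L/h, V/F 60 L) evaluated in closed form with a
geometric-series superposition, so cost is independent of dose count.

The hepatic interstitial concentration is a quasi-steady, pointwise
function of plasma: C_int = C·r(C). The ratio models (log-linear for
tocilizumab, Langmuir-type for GGF2) are fitted exactly through the printed
anchor pairs; outside the anchor range ±1 decade the ratio is clamped to
avoid unphysical extrapolation. A dynamic tissue compartment was considered
and rejected: the printed anchors are steady-state values and constrain
only the ratio.

## Liver model

39 ODE states: per-zone viable fraction and ATP (periportal, midzonal,
centrilobular; mass fractions 0.35/0.35/0.30), whole-liver ROS, GSH and
triglyceride as intensive (per viable cell) pools, plasma ALT, CYP3A4/2E1
activity, six transporter-regulation multipliers, a macrophage pool, four
bilirubin pools, fourteen bile acid pools, free NAPQI and its protein
adduct.

**ALT.** dALT/dt = k_in + R·(necrosis flux + leak) − k_out·ALT with
baseline 25 U/L, half-life 47 h, ULN 40 U/L, and release gain
R = 2375 U/L per unit liver fraction lost (≈3× ULN peak for ~4 % acute
loss). A small quadratic "leak" term (3·10⁻⁴ /h at full ATP deficit)
represents sub-lethal membrane permeability; it makes the biomarker respond
smoothly (and strictly monotonically) to graded stress below the necrosis
threshold. The baseline construction accounts for it exactly.

**Necrosis and regeneration.** Necrosis is k_nec·viable·H(d) with
d = max(0, 1 − ATP/0.6) and H a saturable response H(d) = d/(d + 0.3)
(k_nec = 8.4·10⁻³ /h). The saturable (exponent-1) form was chosen over a
steeper sigmoid after exploring both: the cohort's categorical pattern
(graded 1×/3×/5× ULN outcomes across individuals under three different
insults) requires a broad graded regime; steep sigmoids flip between
no-response and liver destruction. Regeneration is
k_reg·(whole-liver deficit)·(IL-6 regeneration multiplier)·viable with
k_reg = 4·10⁻³ /h, giving ~days-to-weeks recovery; blocking IL-6 signaling
roughly doubles recovery time in the elevated-IL-6 setting.

**Oxidative stress.** ROS relaxes quickly (t½ 1 h) toward total
production/clearance; production = baseline + drug term + lipotoxicity +
NAPQI term; clearance is scaled by a GSH availability factor that is 1
above GSH 0.7 and degrades linearly to a floor of 0.2 — below ~70 % GSH,
oxidant disposal capacity is lost and ROS amplifies. GSH resynthesis is
first order toward its baseline (0.25 /h); it is consumed
stoichiometrically by NAPQI conjugation and (mass-action, only above ROS
2.5× baseline) by severe oxidative stress. The threshold placement keeps
the chip-calibrated day-10 ROS readouts exactly equal to the analytic
production ratio while preserving GSH-collapse amplification under
acetaminophen load. Triglyceride turnover t½ is 12 h, so the 10-day chip
readout is an effective steady state (within ~0.1 point of the analytic
value).

**ATP.** Per-zone ATP relaxes (0.5 /h) toward
1/(1 + mito_sensitivity·Σ stress terms): ROS excess above 1.5× baseline
(gain 1.0), the centrilobular bile acid signal (gain 3.0, CL zone only),
circulating bile acid burden (gain 0.006), and the NAPQI adduct (gain 0.4).

## Bile acids and bilirubin

Two amidated species (CDCA-amidated ↔ GCDCA, CA-amidated ↔ TCA) plus one
lumped unamidated pool. All rate constants are derived from a baseline
balance with these design targets: synthesis 1 µmol-eq/h split CDCA:CA
55:45; 90 % of unamidated flux amidated; serial sinusoidal extraction 0.2
per zone (PP→MZ→CL); biliary:basolateral export 80:20/70:30/50:50 by zone;
biliary export saturable with per-zone Km 0.15/0.10/0.05 (relative
concentration); enterohepatic return 0.95 of gut outflow (gut transit 5 h),
with disposal split 80 % fecal / 20 % renal-extrahepatic; hepatic conjugate
pool turnover 2 h. The zonal export split and deep centrilobular biliary
saturation are the load-bearing structural choices: they make basolateral
(MRP4) export the centrilobular overflow valve, so that strong MRP4
down-regulation produces steep pericentral amidated-CDCA accumulation
(and ALT), while BSEP or NTCP down-regulation only shifts bile acids to
blood (renal valve) or lowers hepatic load, mildly depressing ATP. Flat
zonal splits were explored first and cannot reproduce this asymmetry —
blood-pool feedback self-corrects a basolateral block almost completely.

Bile acid toxicity is a Hill signal on centrilobular CDCA-amidated
concentration (EC50 2.1× baseline, n = 8): negligible at baseline,
saturating at ~2.5× accumulation. The sharp exponent encodes a
threshold-like cholestatic insult and separates the "toxic" (MRP4) from
the "sub-lethal" (NTCP/BSEP) regimes observed in the one-at-a-time scans.

Transporter regulation is an indirect response on each pathway's
multiplier: dm/dt = kout·(target(C_int) − m), target = 1 ∓ Emax·C/(EC50+C),
with protein turnover t½ 12 h and EC50 10 ng/mL. Shipped Emax values
(NTCP 0.50, MRP4 0.24, BSEP 0.22, amidation 0.50, OATP1B3 0.22, MRP3 1.0
up) start from the direction of reported transcriptional changes and were
optimized once against the categorical clinical pattern; transcript
magnitude was deliberately not equated with functional magnitude.

Bilirubin: production → plasma unconjugated → OATP1B3 uptake (viable- and
multiplier-scaled) → conjugation → 80 % MRP2 biliary / 20 % MRP3
basolateral export, plasma conjugated bilirubin partially re-taken up and
partially cleared. Baselines 0.45 + 0.15 = 0.6 mg/dL; constants solved
from the balance. Bile-flow-coupled bilirubin excretion is intentionally
not represented.

In-vitro-like mode reuses the identical liver model with flow-through
topology: blood-side pools are clamped at baseline (fresh media), the gut
pool drains to effluent, and no enterohepatic return occurs. The secretion
readout integrates biliary + basolateral conjugate efflux over a stated
window against a parallel control run.

## IL-6 pathway

Competitive IL-6/tocilizumab binding to soluble IL-6R is solved by a
bracketed root-find (tolerance 10⁻¹²); the drug–receptor complex is
signaling-incapable. Downstream signaling uses an effective IL-6 pool:
IL-6 scaled by unblocked membrane receptor with IC50 derived from a 2.9 nM
drug–receptor Kd (≈0.42 µg/mL). CYP suppression is an indirect response
(Imax 0.6, SC50 1 ng/mL, turnover t½ 36 h): IL-6 at 3 ng/mL suppresses
CYP3A4 below 0.7; co-treatment with 232 µg/mL tocilizumab rescues it above
0.95. Healthy IL-6 is 0.005 ng/mL; the elevated (rheumatoid-arthritis
proxy) setting uses 10 ng/mL. Macrophage modulation of injury is capped at
10 %.

## Acetaminophen / NAPQI

Only the interaction logic is modeled: NAPQI formation
k_met·C_liver·(0.7·CYP2E1 + 0.3·CYP3A4), second-order GSH conjugation
(>90 % of disposition at baseline GSH), residual NAPQI producing ROS and a
slowly repaired adduct. In the elevated-IL-6 setting, CYP suppression
lowers NAPQI; tocilizumab's CYP de-suppression raises it — the
drug–drug-interaction axis. The second axis is additive ROS crossing the
damage threshold, which keeps the combination worse than acetaminophen
alone even when CYP changes are excluded.

## Cohorts and susceptibility

Susceptibility is multiplicative overrides, tuned once and shipped:
the n=4 elevated-IL-6 cohort uses ROS damage gains 1.28/1.31/1.34/1.75
with GSH synthesis capacity 0.25/0.22 for the two responders. Reduced
synthesis capacity (not reduced resting GSH) is the responder phenotype:
resting GSH is normal, but sustained NAPQI load collapses the pool and
amplifies ROS. The n=16 healthy cohort is the baseline human, 12 subjects
on a bile-acid-toxicity-EC50 × mitochondrial-sensitivity × ROS-gain grid
(0.70/0.78/0.88 × 1.15/1.40 × 1.10/1.30), and 3 desensitized subjects;
under a single 1.5 mg/kg GGF2 dose, 4 of 16 exceed 1× ULN ALT with peaks
spanning ~45–126 U/L and total bilirubin ~0.77 mg/dL — inter-individual
variability around a mostly-tolerant population.

The `tune` utility is the seeded, derivative-free search used to fix free
gains against categorical constraints (slack-minimizing random search with
the defaults as first candidate); the shipped values are its committed
output and are regression-tested.

## Numerical choices

- Integration: LSODA, rtol 10⁻⁸ / atol 10⁻¹⁰ by default, hourly output
  grid. Cohort-scale studies use rtol 10⁻⁶ / atol 10⁻⁹, which changes peak
  ALT by ≪1 U/L while keeping the three 12-week scenarios within a few
  minutes on one core.
- The drug-free baseline is constructed analytically (all balances close by
  construction; integration drift over 1000 days is at rounding level), so
  no relaxation or root-polish is needed in practice; construction failure
  (e.g. susceptibility multipliers that put baseline ATP below the death
  threshold) raises immediately.
- Mass conservation of the closed bile acid system is a linear invariant
  and is preserved by the integrator to ~10⁻¹⁵ relative.
- Two-point saturable fits use the exact double-reciprocal solution;
  infeasible anchors (equal or decreasing responses) raise a fit error
  rather than returning boundary values. The three-anchor Langmuir ratio
  fit reduces to a one-dimensional bracketed root-find (tolerance 10⁻¹²).
- Study sizes: in-vitro runs are 10 days; clinical scenarios 12 weeks;
  sensitivity scans 6 weeks (the single-dose GGF2 transient completes
  within ~3 weeks); recovery studies 8 weeks.

## What the synthetic chip fixtures do and do not show

The fixture generator produces per-chip endpoint tables with multiplicative
lognormal noise (mean exactly 1, configurable CV) around model-derived
truth, at the published group sizes. It reproduces the *structure* of
chip datasets — not plate effects, temporal autocorrelation, chip dropout,
or assay-specific detection limits. Passing recovery tests therefore show
that the calibration pipeline is correct and that group-mean endpoints are
re-estimable at the stated noise; they do not show robustness to real
assay artifacts.

One identifiability fact is worth stating plainly: the steatosis IC50
(0.365 µg/mL) cannot be recovered from endpoint data at the two calibrated
interstitial concentrations (52.4 and 166.3 µg/mL) — the inhibition curve
is >99.3 % saturated at both, so the 1-point difference between the two
anchors is far inside sampling noise at CV 20 % with ~14 chips per group.
The steady-state effect size (steatosis % of control) is recovered well;
the half-max constant is not, and additional low-concentration data would
be required to pin it.

## Known limitations

- Severity beyond the categorical ULN thresholds is not calibrated: a
  12-week combination exposure in a high-susceptibility individual drives
  the simulated liver far past any clinically tolerated state (dosing is
  never stopped adaptively).
- ROS, GSH and triglyceride are whole-liver pools; only bile acid toxicity
  and viable fraction are zonated.
- Apoptosis vs necrosis, additional biomarkers (AST, GLDH, HMGB1,
  keratin-18), FXR/FGF19 feedback on bile acid synthesis, adaptive immune
  mechanisms and bile-flow-dependent bilirubin excretion are out of scope.
- The GGF2 interstitial:media ratio >1 is reproduced empirically by the
  saturable ratio model without mechanistic commitment.
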