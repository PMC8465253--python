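# Methods

`diazepbpk` is a whole-body physiologically based pharmacokinetic
(PBPK) model of diazepam in healthy adults, built to predict plasma
concentration–time profiles after intravenous, oral, intranasal and
rectal dosing and to qualify those predictions against compiled
clinical PK parameters. This note documents the model, its
assumptions, the defaults that matter, and the limits of what the test
suite can show.

## Model structure

The body is twelve well-stirred, perfusion-limited tissue compartments
(adipose, bone, brain, gut, heart, kidney, liver, lung, muscle,
pancreas, skin, spleen) plus venous and arterial blood pools, with the
lung in series with cardiac output. Each non-eliminating tissue obeys

    dA_t/dt = Q_t (C_art − C_t · BP / Kp_t),

with A in ng, Q in L/h and concentrations on a blood basis (BP is the
blood:plasma ratio, Kp the tissue:plasma partition coefficient). Gut,
pancreas and spleen drain into the portal vein; the liver receives
hepatic arterial plus portal inflow and is the only eliminating organ.
Reported plasma concentrations are venous blood concentration divided
by BP.

Assumptions: perfusion-limited distribution everywhere (no
permeability-limited tissues), linear binding, instantaneous mixing in
each compartment, single-dose regimens, no metabolite tracking, no
renal or extrahepatic clearance (the compound's elimination is
essentially fully CYP-mediated).

## Distribution

Tissue:plasma partition coefficients come from a tissue-composition
method for neutral-to-very-weakly-ionized compounds: drug distributes
into extra/intracellular water according to Henderson–Hasselbalch
ionization at each compartment's pH, into neutral lipid and neutral
phospholipid in proportion to lipophilicity (P = 10^logP; adipose uses
the vegetable-oil distribution coefficient, logD_vo = 1.115·logP −
1.35), and associates with extravascular protein with an affinity
back-calculated from the measured plasma fraction unbound, so the
method is self-consistent with fu. Diazepam's conjugate-acid pKa of
3.4 leaves it >99.99 % un-ionized at pH 7.4, so no ionized-species
membrane-permeability correction is applied — for this compound such a
correction is numerically a no-op, which is why the neutral/weak-base
protein-binding branch (not the acidic-phospholipid branch used for
moderate-to-strong bases) is the right one.

The composition table (water/lipid fractions, intracellular pH,
tissue:plasma albumin ratio per tissue) ships as a versioned CSV
(`data/tissue_composition.csv`) so it can be revised without touching
code. The erythrocyte partition is derived from BP and hematocrit as
Kp_rbc = (BP − (1 − Hct))/Hct, clamped at zero.

With the shipped tables the full pipeline gives Vss ≈ 0.69 L/kg for
diazepam (adipose Kp ≈ 1.6, muscle ≈ 0.3), inside the 0.59–1 L/kg span
of reported values.

## Elimination (IVIVE)

Per-isoform Michaelis–Menten kinetics (vmax in pmol/min per pmol
isoform, Km in µM, both for CYP2B6/2C19/3A4/3A5 across N-demethylation
and 3-hydroxylation) are scaled to the whole liver via enzyme
abundance × MPPGL × liver weight, with the microsomal binding
correction applied as an effective concentration c_u/fu_mic. In the
ODE the saturable rate is driven by the unbound concentration of the
liver's emergent plasma (fu · C_liver/Kp_liver); at therapeutic
diazepam concentrations (≲2 µM against Km of 32–2235 µM) the system is
deep in the linear regime, and the closed-form well-stirred clearance
CLh = Q·fu_B·CLint/(Q + fu_B·CLint) serves as an analytic oracle that
the ODE must match within 5 %.

Scaling defaults (deliberate calibration knobs, config-exposed):
CYP3A4 137, CYP2C19 14, CYP2B6 17 pmol/mg; CYP3A5 20 pmol/mg as an
effective population mean folding in the expresser fraction; MPPGL
40 mg/g; liver 1650 g at 70 kg, scaled linearly with body weight.
These give whole-liver unbound CLint ≈ 104 L/h and plasma clearance
≈ 2.9 L/h, inside the 2.29–9.57 L/h span that the compiled study arms
imply (that span is wide because the compiled CL column is
dose/AUC0–t at each study's own truncation time, not a true terminal
clearance).

## Absorption

* **IV**: bolus into venous blood (infusions supported as zero-order
  input).
* **Oral**: a 7-segment linear transit chain replaces a full
  dissolution/absorption gut model. Each segment absorbs into the
  portal stream at ka = 2·Peff/R_si (R_si = 1.75 cm) and passes drug
  downstream at kt = 7/3.32 h⁻¹ (3.32 h mean small-intestinal transit);
  the last segment's transit flux is unabsorbed loss. The chain has the
  closed form Fa = 1 − (kt/(ka + kt))^7 used as its oracle. Dropping
  dissolution is justified for this compound: small doses, high
  permeability. This is the package's main structural simplification.
* **Intranasal**: first-order depot of fa·dose (fa = 0.7, deposition
  and drainage losses folded into fa) emptying with ka = 1.6 h⁻¹ (3.2
  for supersaturated solutions, which permeate faster during their
  short residence) directly into venous blood — no first pass.
* **Rectal**: first-order depot (fa = 0.9, ka = 1.5 h⁻¹ — calibratable,
  not literature-fixed) split between the portal vein and systemic
  circulation with a configurable portal-bypass fraction (default 0.5,
  reflecting lower-rectal venous drainage that bypasses the liver).

Effective jejunal permeability can be predicted from polar surface
area and hydrogen-bond donor count via log10 Peff[cm/s] = −2.54602 −
0.011·PSA − 0.278·HBD, which reproduces the reference diazepam value
12.434 × 10⁻⁴ cm/s at PSA 32.67 Å², HBD 0.

### Bioavailability accounting

F = Fa·Fg·Fh is decomposed from flux ledgers: Fa = absorbed/dose; Fg
from gut-wall metabolism (disabled by default, so Fg = 1); Fh = 1 −
E_h applied to the portally routed share, with E_h the liver's
cumulative extraction ratio (eliminated/throughput — in a linear
system this equals the per-pass extraction). Simulated oral F is
≈ 0.95 (Fa ≈ 1.0, Fh ≈ 0.95), inside the predicted 76–97 % range.
Intranasal F is 0.70 by construction (fa = 0.7 and no first pass);
the 81–97 % intranasal range quoted alongside the clinical comparisons
cannot arise from these absorption parameters — the clinical AUC
ratios themselves (intranasal/IV ≈ 0.70 at equal dose) support 0.70 —
so that range should be read as an availability report that excludes
the nasal deposition loss. The package reports the loss-inclusive
value.

## Virtual populations

Per study arm, subjects are sampled around a 70-kg reference adult
whose volumes and flows ship as a versioned CSV
(`data/reference_physiology.csv`; cardiac output is defined as the sum
of systemic flows, ≈ 357 L/h). Body weight is uniform over the
compiled range (lognormal, CV 15 %, around the mean when only a mean
is compiled; reference adult with a warning when nothing is). Volumes
scale linearly with weight, flows with weight^0.75. Between-subject
variability is lognormal with CV 30 % on enzyme abundances and 20 % on
flows (cardiac output re-derived as their sum), 0 % on Kp — typical
population-PBPK settings, all config-exposed. Females get a 15 %
reduction in liver weight and cardiac output as a simple default. Sex
is Bernoulli(female proportion); subject i is driven by the i-th spawn
of the trial seed, making populations and trials bit-reproducible.

Trial summaries report pointwise mean, 5th/95th percentiles
(linear-interpolation quantile convention) and min/max across
subjects, the overlay statistics used for visual predictive checks.

## NCA and qualification statistics

Cmax/Tmax are the sampled maximum; AUC0–t is the linear trapezoid
(consistent with the CL = dose/AUC0–t identity embedded in the
compiled table); AUCinf adds C_last/λz when a terminal log-linear fit
with ≥ 3 points and r² ≥ 0.9 exists (best adjusted-r² window after
Tmax); CL = dose/AUC0–t, reported as CL/F for extravascular routes.

Qualification follows the published recipe: per-row observed/predicted
ratios (recomputed from the observed and predicted columns at full
precision — using the pre-rounded ratio column does not reproduce the
published AFE values), arithmetic mean ratio with a two-sided
t-interval (mean ± t_{n−1,0.975}·sd/√n; this convention was chosen
because it reproduces the published 95 % CIs, e.g. 0.75–1.13 for IV
AUC), average fold error AFE = 10^mean(log10 R) (the geometric mean),
and the two-fold acceptance range [0.5, 2.0] inclusive. Published
rounding is inconsistent in places (oral CL 1.14 vs 1.15, IV Cmax 0.95
vs 0.96, intranasal Cmax 0.91 vs 0.92, rectal AUC 1.18 vs 1.19 between
the text and the summary table); the implementation keeps full
precision and rounds only for display, and its values agree with both
variants within ±0.01.

The compiled observed/predicted table ships as
`data/observed_predicted_pk.csv` (20 profiles × 3 parameters). One
compiled row (IV 7.5 mg) has a predicted CL that deviates 3.8 % from
dose/AUC0–t; all other 19 rows agree within 1 %.

## Synthetic data

Observed concentration–time profiles were digitized from published
figures and are not redistributable, so the `synthetic` module
generates stand-in datasets with known truth: exact two-compartment
closed forms (bi-exponential IV, tri-exponential first-order
absorption), lognormal between-subject variability on CL/V/ka
(CV 30 %) and multiplicative lognormal residual error (CV 15 %),
diazepam-like defaults (CL 3 L/h, Vc 30 L, Vp 40 L, Q 20 L/h). The
generator validates the NCA/evaluation pipeline (e.g. mean dose/AUCinf
over 100 subjects recovers the generating clearance within 5 %); it
emulates the multi-phasic shape and noise level of real profiles but
not their study-specific sampling schedules, assay limits of
quantification, or any specific published curve — passing recovery
tests therefore demonstrates pipeline correctness, not clinical
predictive accuracy.

## Numerical choices

* Stiff-capable integrator (LSODA), rtol 1e−8, atol 0.01 ng, piecewise
  integration across infusion breakpoints; solutions interpolated onto
  the requested sampling grid.
* Mass balance (body + eliminated + unabsorbed = scheduled dose) is
  checked at every output time; residuals above 1e−6 relative raise.
* Default sampling grids are geometric over [0, duration] (dense early).
* Study horizons (AUC0–t truncation times) are not compiled per arm;
  the shipped per-arm values were chosen to be consistent with how
  complete each compiled AUC0–t is relative to dose/CL and are plain
  fixture metadata.
* Quantiles: linear interpolation between order statistics.
* Degenerate inputs: zero-width weight ranges sample lognormally around
  the mean; ka equal to a disposition exponent in the closed-form
  generator is perturbed by 1e−7 to avoid the removable singularity;
  protein-binding back-calculation clamps at zero when plasma lipid
  partitioning alone explains 1/fu.
* Problem sizes: virtual trials default to 100 subjects per arm (the
  published evaluation's population size); structural-oracle tests use
  the reference adult or ≤ 20 subjects, which is sufficient because
  those checks are deterministic.

## Known limitations

* The transit-chain gut model has no dissolution or particle-size
  effects; oral absorption of this high-permeability compound is
  near-complete and fast (simulated oral Tmax ≈ 0.2 h is earlier than
  typical clinical 0.5–1.5 h values — a known consequence of the
  permeability-derived segment ka with no dissolution delay).
* IV Cmax at the first instants is the undistributed venous-pool
  concentration and exceeds clinically sampled peaks; comparisons
  should use AUC/CL or post-distribution concentrations.
* Enzyme abundances, MPPGL, liver weight and the rectal absorption
  parameters are literature-standard calibration knobs, not compiled
  values; downstream clearance comparisons are therefore span checks,
  not point reproductions.
* Population system parameters are simplified (no age-dependence of
  organs, two-point sex effect, no CYP2C19/3A5 polymorphism
  structure); drug–drug interactions, metabolites, multiple dosing and
  pediatric/disease extrapolation are out of scope.
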