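# Methods

This note records the models, conventions, numerical choices and known
limitations of the package — the information a maintainer or reviewer needs
to judge what the pipelines compute and what the passing tests do and do not
demonstrate.

## Units and constants

Forces in pN, lengths in nm, time in s, loading rates in pN/s, energies in
kJ/mol.  The thermal energy at 298 K is fixed at k_BT = 4.114 pN·nm and is
the single source of truth (`forcebind.constants.thermal_energy`); other
temperatures scale linearly.  R = 8.314462618 J mol⁻¹ K⁻¹; the Arrhenius
prefactor defaults to A = 10⁶ Hz; the reference loading rate to
10 nN/s = 10⁴ pN/s.  All are overridable through `RunConfig`.

The transition-state distance χ is stored and reported in **nanometres**
everywhere.  Sub-ångström χ values are sometimes quoted in Å in the
literature; for the native/K7A parameter sets used in the tests
(χ = 0.38/0.24, ΔG = 42/25.7 kJ/mol, F(10 nN/s) = 110/50 pN) only the nm
reading closes the Bell–Evans/Arrhenius loop self-consistently, which is why
the package insists on explicit nm units at every χ interface.

## SMFS chain

**Sign convention.** Tensile (adhesive) force is positive; the compressive
contact branch is negative.  A rupture is a sharp negative step.

**Baseline and contact.** A straight line fitted to the final 30 % of the
retract (the far-from-surface tail) is subtracted.  The contact point is the
zero crossing that terminates the initial compressive branch (threshold
max(5σ, 10 pN), σ estimated from robust first differences of the tail);
curves with no compressive branch anchor the contact at the first sample.
Tip–sample separation = piezo displacement − force/spring-constant.

**Rupture detection.** The trace is smoothed with a `window`-sample moving
average (default 15).  A step statistic — mean over the preceding window
minus mean over the following window — is computed on both the raw and the
smoothed traces; candidates must exceed max(nσ·σ·√(2/w), 20 pN) in *both*
(default n = 6) and coincide within one window (the correlation criterion).
The edge is then refined to the sharpest raw single-sample drop near the
candidate: without this refinement the force readout bias grows with
retract speed (coarser force-per-sample), which measurably tilts the
Bell–Evans slope.  The rupture force is read from the raw trace at the last
point before the drop.

**WLC characterization.** The stretch segment between consecutive events is
fitted with the Marko–Siggia interpolation (trust-region least squares;
L_p ∈ [0.01, 50] nm, L_c ∈ [1.02, 25]·max separation; x/L_c capped at 0.999
inside the optimizer so trial contour lengths below the data range stay
finite).  Separations below `contact_exclusion` (default 10 nm) are dropped
from the fit when at least 8 points remain: non-specific contact adhesion
lives within ~10 nm of the surface while the tether force there is < 1 pN,
so the exclusion removes a contamination term at no information cost.
`fit_quality` is the R² of the fit clipped to [0, 1]; non-convergence flags
the event unfit (quality 0) rather than raising.  The apparent loading rate
is the slope of a linear force-vs-time fit over the final 10 % of the
segment (≥ 5 points); events without a positive rate are discarded as
artifacts.

**Specificity.** An event is specific iff fit quality ≥ 0.8 and the rupture
distance lies within [0.5, 1.5]× the nominal linker contour length (35 nm
for a 5 kDa PEG tether), with a positive loading rate.  Both the window and
the threshold are configurable and echoed into every report.

**Experiment QC.** An experiment (one loading-rate condition) is kept iff
the fraction of curves showing a specific interaction reaches the
per-peptide cutoff (defaults: 4 % native, 2.5 % K7A — the lower K7A cutoff
accommodates its overall lower interaction frequency).  Discards are logged
with their fractions, never silently dropped.

**Most probable force.** Gaussian fit to the Freedman–Diaconis histogram of
specific rupture forces (floor: 50 events, configurable).  `auto` mode fits
one and two components and accepts bimodality only when the two-component
AIC improves by > 10 *and* the peaks are resolved (|μ₁−μ₂| > σ₁+σ₂); a
skewed unimodal histogram is otherwise fit marginally better by two
overlapping Gaussians, which would misplace the mode.  Ties break toward
unimodal.  If bimodal, the lower-mean component is the MPF (the upper peak
is attributed to unresolved multiple-bond ruptures).

**Bell–Evans regression.** Ordinary least squares of MPF against
ln(loading rate) (statsmodels; optional 1/err² weighting).  Slope = k_BT/χ;
k_off solves the force law at the fitted line.  Standard errors propagate
from the regression covariance (delta method for k_off).  The per-experiment
abscissa is the mean apparent loading rate of its specific events.  With
fewer than three distinct rates, or a non-positive slope, the fit refuses.

## QCM-D chain

**Alignment and display smoothing.** Traces are aligned to the injection
point (time origin and per-channel offsets zeroed; offsets are medians over
the 60 s before injection).  A 4-minute centered moving average is applied
for display only; all accounting uses unsmoothed data.

**Frequency change.** Δf between injection and end of wash (standard) or
end of adsorption (wash-excluded, for ionic-strength series where the bulk
shift on washing corrupts the endpoint).  Endpoints are medians over a
terminal 60 s window, which makes them robust to the short bulk-shift
spikes recorded at solution changes.  The ninth overtone is the default
reporting channel.

**Voinova model.** First-order small-load expressions for one viscoelastic
film under semi-infinite Newtonian liquid, referenced to the liquid-loaded
baseline (the bulk term cancels in baseline-referenced data and is available
via `include_bulk`).  The frequency expression was verified to agree with
the exact one-layer transfer-matrix small-load solution to first order in
film thickness; the dissipation prefactor was fixed against the same exact
mechanics (anchored by the Kanazawa liquid-loading results: −717 Hz and
ΔD = 2.9·10⁻⁴ for water at 5 MHz) and is twice the value a widely
reproduced closed form yields.  The exact solution also serves as the
independent oracle in the tests.

**Voigt inversion.** Per time point, (h₁, μ₁, η₁) are fitted in log space to
the observed Δf/ΔD across all overtones with ≥ 2 dissipation channels
(bounds h ∈ [10⁻⁴ nm, 1 µm], μ ∈ [10², 10⁹] Pa, η ∈ [10⁻⁵, 1] Pa·s), with
the film density fixed at 1100 kg/m³; the reported quantity is the areal
density h₁ρ₁, which stays well-determined even where μ and η individually
are not (thin or rigid films).  Each point is solved from two starts — the
previous solution (continuity) and a fresh Sauerbrey-informed guess —
because the first-order response admits a spurious soft-film branch in
which the mass and viscoelastic frequency terms cancel; between near-equal
fits the thinner film wins (parsimony).  A continuity pass then flags
points jumping more than 3× above their 5-point running median (+0.5 nm)
as spurious-branch solutions; flagged and non-converged points are
interpolated, and a run fails if more than 10 % of points are flagged.
Without dissipation data the pipeline falls back to Sauerbrey and flags the
report.

**Stage accounting.** Areal-density changes are computed
endpoint-to-endpoint within each stage (adsorption, wash) with 60 s-median
endpoints, then summed; a spike exactly at a stage boundary therefore
affects neither stage.  The molar surface concentration divides the total
(ng/cm²) by the average molecular weight (g/mol), giving nmol/cm² directly.
No correction is made for water trapped in the film: the reported mass is
the hydrated (acoustic) mass.

## Peptide bookkeeping

Integer net charge at neutral pH: +1 per Lys/Arg, −1 per Asp/Glu, His
neutral (appropriate at pH ~7.2), free termini +1/−1.  A
Henderson–Hasselbalch fractional mode exists for sensitivity checks but the
integer model is the default.  Masses are average residue masses plus one
water; surface-concentration bookkeeping is the reason average (not
monoisotopic) masses are used.  Alanine-scan derivatives are named XNA with
1-based positions; positions already holding alanine are skipped.

## Synthetic data: what it emulates, what it does not

`sample_rupture_forces` draws from the exact first-passage distribution of
a single bond under constant loading, S(F) = exp[−(k_off·k_BT/(χr))·
(e^{χF/k_BT}−1)], via the closed-form inverse CDF; the mode of this density
is exactly the Bell–Evans force law, which is what makes it the right
validation target for the MPF/regression chain.

`simulate_force_curve` renders a 500 nm retract: a compressive contact
branch (200 pN applied force), with probability 0.3 a non-specific contact
peak (exponential decay, 5 nm scale, releasing within 8 nm of the surface),
and with configurable probability a WLC tether stretch (35 nm contour,
0.38 nm persistence — a 5 kDa PEG) terminating at a sampled rupture force,
plus Gaussian noise (σ = 5 pN).  The tether branch is generated in
separation space and mapped through z = s + F/k so that curve shape,
cantilever compliance (0.05 N/m default) and the sampled force are mutually
consistent; the ground-truth loading rate is the retract speed times the
series stiffness of cantilever and tether at the rupture force (the
distribution itself is sampled at the rate evaluated at the distribution
mode — a fixed-point shortcut iterated twice).  The sample spacing is
clamped to [0.1, 0.2] nm across speeds, mirroring instruments that scale
acquisition rate with retract speed.  Defaults follow the emulated study
conditions: 4000 curves per experiment, 8 % specific probability.

`simulate_qcm_adsorption` grows areal density as Γ_max(1−e^{−kt})
(defaults Γ_max = 550 ng/cm², k = 3·10⁻⁴ s⁻¹, so most growth happens within
the first two hours of an 18 h adsorption stage), lets a 20 % fraction
desorb first-order during wash, renders Γ(t) through the Voinova model at
fixed film density for overtones 3–13, and adds noise (0.5 Hz; 3·10⁻⁸ in
dissipation, a post-averaging instrument figure).  Optional short bulk-shift
spikes at stage boundaries exercise the endpoint-median robustness.

Not modelled: cantilever hydrodynamics and thermal dynamics, multi-bond
rupture cascades, surface roughness, film heterogeneity, overtone-dependent
film properties, flow-cell exchange dynamics.  Passing the round-trip tests
therefore shows the *estimators invert their own forward models* under
realistic noise — it does not certify performance on instrument data whose
physics deviates from these forward models.

## Test and validation scales

The simulation-based checks run at desk scale: parameter recovery uses
5 loading rates × 2000 sampled ruptures; detection statistics use 500
curves at 1 µm/s; QCM-D round trips use a compressed schedule (10 min
baseline, 2 h adsorption at k = 5·10⁻⁴ s⁻¹, 30 min wash) sampled every
10–60 s.  These sizes give the statistical resolution the asserted
tolerances need (e.g. binomial error well below the 95 % recall bound)
while keeping the suite fast; the estimators themselves carry no
scale-dependent shortcuts.

## Known limitations

* The rupture detector is re-specified from its published description
  (smooth, threshold, raw/smoothed coincidence); window and threshold
  defaults are declared engineering choices, not values inferred from the
  original implementation.
* Whether the original analysis reads rupture force from the raw or the
  smoothed trace is unknown; this implementation reads raw at the detected
  index (after edge refinement).
* The Voigt inversion fits all overtones jointly with a single film; real
  films can violate overtone consistency, which would surface as flagged
  points and inflated residuals rather than a warning about the model.
* The Gaussian-fit MPF of a skewed first-passage histogram carries a small
  systematic offset toward the heavy tail (a few pN, roughly constant in
  units of k_BT/χ); it cancels in the slope (χ) and contributes ≲ 1 kJ/mol
  to the barrier at the default conditions.
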