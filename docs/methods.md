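# Methods

## The measurement model

spICP-TOF-MS records, every acquisition window (default t_acq = 1 ms), ion
counts for a panel of up to 22 metals. Dissolved analyte contributes a
stationary Poisson background; a particle that survives transport to the
plasma deposits its whole element inventory in one (occasionally two)
windows. The package's quantification chain inverts this process, and its
synthetic instrument implements the process itself:

- **Dissolved response.** Element X at concentration C (µg L⁻¹) yields
  Poisson counts with mean S_X · C per acquisition. S_X is fitted by
  ordinary least squares of mean counts against the seven calibration
  levels (0, 0.05, 0.1, 0.5, 1, 5, 10 µg L⁻¹), the blank (0) level
  anchoring the intercept. Unweighted OLS is the default: after averaging
  thousands of acquisitions per level the means are near-homoscedastic; a
  1/variance-weighted option is exposed.
- **Particle response.** A particle of element mass m_X that reaches the
  plasma produces Poisson counts with mean m_X · S_X / (η · q · t_acq).
  The 1/η factor arises because the dissolved sensitivity already contains
  the transport loss, while a particle that arrives at all is counted in
  full. Inverting gives the per-particle mass formula
  m_X = I_net · η · q · t_acq / S_X (femtograms, with q converted from
  mL min⁻¹ to L s⁻¹).
- **Transport efficiency.** Default estimator is the event-frequency
  method on a monodisperse 50 nm Au number-concentration standard:
  η = N_detected / (q · duration · C_N / dilution). It needs no dissolved
  sensitivity and matches how a number-concentration standard is used. The
  signal-based (size) method, η = m_ref · S_Au / (Ī · q · t_acq) with
  m_ref = (π/6) d³ ρ, serves as an independent cross-check; the two agree
  within combined counting error on self-consistent data.
- **Detection limits.** Mass LOD per element is multiplier · σ_blank
  converted through the counts→mass factor (3σ default; the multiplier is
  configurable). The size LOD is the equivalent-sphere diameter at the
  host-element mass LOD under the declared phase.

## Event detection

Backgrounds are estimated per element by iterative sigma-clipping: drop
acquisitions above µ + k·σ, re-estimate, repeat until stable (≤ 20
iterations; streams shorter than 100 acquisitions are refused). Two
positivity criteria are provided:

- *iterative-sigma* (default, k = 5): count > µ_B + k·σ_B, the
  conventional compromise between false positives and small-particle
  sensitivity;
- *poisson-quantile* (α default 10⁻⁶): count ≥ T, where T is the smallest
  integer with P(X ≥ T | Poisson(µ_B)) ≤ α. This bounds the per-element
  false-positive rate exactly; on long runs (10⁵–10⁶ acquisitions) it is
  the appropriate choice, because even a 5σ rule admits ≈ 7·10⁻⁵ false
  positives per acquisition on low-mean Poisson backgrounds, which is
  material when true events number in the hundreds.

An acquisition is event-positive when any element exceeds its threshold;
maximal positive runs (bridging up to `merge_gap` sub-threshold windows)
form one multi-element event, which also absorbs signals split across an
acquisition boundary. Net counts are gross window counts minus
window_length · µ_B, floored at zero. When a matched blank run is supplied
its background replaces the in-run estimate.

Only elements flagged above threshold within the window are attributed to
the particle: converting sub-threshold net counts would turn background
fluctuations into spurious accessory masses and systematically depress the
single-metal-Fe proportion (by ~2 % at typical settings). A mass is then
detected if it also reaches the element's LOD (strict rule: mass < LOD is
masked; mass = LOD counts as detected).

## Composition and sizing

Fe mass fraction is m_Fe over the summed detected-metal masses — oxygen is
not measured and never enters the denominator. Classes: *Fe-containing*
(Fe detected), *Fe-rich* (fraction strictly > 0.40), *single-metal-Fe*
(Fe the only detected metal, fraction exactly 1), otherwise *multi-metal*.
Sizing assumes a homogeneous sphere of a single declared phase; for
magnetite the host mass fraction w_Fe = 3·M(Fe)/(3·M(Fe)+4·M(O)) ≈ 0.7236
and ρ = 5170 kg m⁻³, so d = (6·(m_Fe/w_Fe)/(π·ρ))^(1/3). The phase is
configurable (hematite bundled, arbitrary stoichiometries supported); all
magnetic-fraction particles in one analysis share one phase — no
multi-phase deconvolution within a particle.

## Cohort statistics

Number concentration: C_N = N_detected · dilution / (η · q · duration)
per mL of suspension, convertible to per-gram/per-mL matrix via the
declared suspension volume and matrix quantity (unit declarations are
mandatory). Enrichment factor: exposed/control ratio of a concentration
metric, with delta-method propagation of replicate standard errors.
Retention: 100 · burden / administered dose on a declared basis; the dose
is either supplied directly or assembled as air concentration × ventilation
× schedule × deposition fraction × magnetic-Fe fraction — the form used is
always reported, since ventilation constants are study inputs, not
derivable quantities. Group comparison uses Welch's unequal-variance t
(degenerate zero-variance identical groups return p = 1 by convention); no
multiple-testing correction by default, Benjamini–Hochberg available for
element panels.

## The synthetic instrument

What it emulates: Poisson dissolved backgrounds (optionally with a
constant reagent blank so LODs are non-degenerate), lognormal particle
size distributions, magnetite-dominated compositions with independent
lognormal accessory-element fractions riding on the host mass, Poisson
particle arrivals with binomial transport thinning, boundary-split events
(uniform count partition with configurable probability), and exposed/
control cohort structure with per-tissue enrichment factors, size medians
and single-metal proportions (the latter implemented as an exact
two-population mixture). Every generated particle is logged in a
ground-truth ledger with its exact masses, landing window, thinning
outcome and coincidence status.

What it does not emulate: plasma physics, ion optics, spectral
interferences, isotope patterns, flicker or dead-time noise, signal drift,
or plume shapes beyond the two-window split. Counting noise is pure
Poisson. Consequently, passing tests demonstrate the correctness of the
data-reduction chain under the stated statistical model — not robustness
to matrix effects or drift in real acquisitions.

Two particles landing in the same (or adjacent) window are generated
faithfully but cannot be resolved downstream; they are flagged in the
ledger, and recovery comparisons use single-particle windows. This mirrors
the real measurement, where samples are diluted until the occupancy is a
few events per thousand windows; the bundled scenarios do the same
(occupancy ≲ 0.01), keeping the coincidence bias on number concentrations
below ~1 %.

## Numerical choices

- Sigma-clipping comparisons carry a 10⁻⁹ absolute slack so that exactly
  constant (noise-free) float streams converge instead of oscillating on
  last-bit rounding of the running mean.
- Net counts are floored at zero after background subtraction (masses
  cannot be negative; the bias is negligible at event-level counts).
- counts→mass is exactly linear through the origin; linearity holds to
  double-precision rounding (≈ 10⁻¹⁵ relative).
- The noise-free simulation mode replaces Poisson draws by their exact
  means (fractional counts), making the full chain invertible to ≈ 10⁻⁹
  relative — the basis of the forward/inverse consistency tests.
- Detected events suspected of coincidence are flagged by window length
  (> 2 acquisitions), a heuristic; the ledger carries the true flag.

## Problem sizes used in the test suite

Unit and property tests run on streams of 10²–10⁵ acquisitions. The
recovery suites use: 7 calibration levels × 10⁴ acquisitions and ~5000
detected reference particles per seed over 20 seeds (sensitivity within
1 %, η within 3 %); a 10⁶-acquisition pure-background stream for
false-positive control; and an exposed/control cohort of 4 tissues × 2
groups × 8 replicates at ~700 control events per 1.2·10⁶-acquisition run
for enrichment and composition recovery. These sizes put counting error
well inside the stated tolerance bands while the whole suite stays in the
low minutes on a single core.

## Known limitations

- No deconvolution of overlapping particle plumes, no within-run drift
  correction, no isobaric-interference correction.
- The frequency-based η estimator is biased low by the coincidence rate;
  at the recommended occupancy this is < 0.5 %, but concentrated standards
  will underestimate η (and sigma-clipping may fail outright to find the
  background when a large fraction of windows carry particles — dilute the
  standard instead).
- Retention rates are only as meaningful as the supplied dose model;
  deposition fractions and ventilation rates must come from the study
  design.
- The Fe-fraction denominator covers detected metals only; undetected
  light elements (O, C) are invisible by design, so "single-metal" means
  single detected metal.
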