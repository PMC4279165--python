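# Methods

## The capture model

The assay measures the protein left in solution after immobilised,
nucleotide-free GroEL beads are spun out. The model behind the analysis is
the minimal mass-action scheme

    N  ⇌(k_u, k_f)  I  →(k_c·[EL])  C
    I + I  →(k_agg)  A

with species in µM and time in minutes: `N` native, `I` the transiently
populated chaperonin-binding conformer, `C` the bead-captured pool, `A`
aggregate in monomer units. The ODE system is

    dN/dt = −k_u N + k_f I
    dI/dt =  k_u N − k_f I − k_c[EL] I − 2 k_agg I²
    dC/dt =  k_c[EL] I
    dA/dt =  2 k_agg I²

starting all-native (`N(0) = protein0`). The observable is the soluble
fraction `(N + I)/protein0` — both `C` (on beads) and `A` (pelleted) are
removed by the brief spin.

Assumptions worth stating explicitly:

* **Capture is irreversible.** Nucleotide-free GroEL binds its substrates
  with sub-nanomolar affinity; over a one-hour assay there is no release
  term. The chaperonin is a kinetic trap, not a folding catalyst here.
* **Site multiplicity is absorbed into `k_c`.** A GroEL oligomer has two
  binding cavities; rather than track site occupancy, `[EL]` is the oligomer
  concentration and `k_c` is an effective per-oligomer association rate.
  With the chaperonin in large excess over the transient intermediate pool
  (the relevant comparison — not total protein), `[EL]` is treated as
  constant.
* **Aggregation is second order in `I`.** The true order is unknown;
  dimerisation-nucleated growth is the minimal choice that makes the
  aggregation extent depend on starting concentration, which is the
  experimentally observed behaviour. The factor 2 keeps `A` in monomer
  units so mass is conserved.
* **Temperature has no explicit role.** It enters only through the choice
  of rate constants; `temperature_c` and `urea_m` are metadata.

Under a quasi-steady state for `I` (valid when `k_f + k_c[EL] ≫ k_u`), the
soluble pool decays as a single exponential with

    k_app = k_u · k_c[EL] / (k_f + k_c[EL])

after a short induction lag `τ = 1/(k_f + k_c[EL])`. `k_app` → `k_u` as
`[EL]` → ∞: at saturating chaperonin, unfolding is rate-limiting. The
relative error of this closed form is O(k_u/(k_f + k_c[EL])). For the
variant presets below that ratio reaches ~0.06 for I154F at 0.5 µM
chaperonin, so closed-form and integrated trajectories can disagree by a
couple of percent at low chaperonin concentrations even though they agree
to well under 1% at 3 µM; the exponential approximation should be read with
that gradation in mind.

## Fitting

**Decay fits** (`FirstOrderDecay`) minimise least squares of
`S(t) = S∞ + (S₀−S∞)e^(−k_app t)` (lmfit/Levenberg–Marquardt), weighted by
`1/sd²` when replicate SDs exist. Initialisation: `k_app` from the
half-crossing time (`ln 2 / t_half`), `S₀`/`S∞` from the first/last points;
three log-spaced restarts guard against bad starts, and the best
finite-χ² solution is kept even when the optimizer's tolerance heuristics
complain (near-flat wild-type series trip them at perfectly good minima).
A constant series returns `k_app = 0` with a degenerate-flat flag rather
than an error. `S∞` is free by default; `fix_plateau_zero` forces decay to
zero. Free-plateau fits on slow decays (less than ~half complete within the
observation window) absorb curvature into `S∞` and bias `k_app` low — the
saturation analysis below tolerates this, but single-condition rate
estimates from incomplete decays should be treated with caution.

**Saturation fits** (`SaturationCurve`) fit
`k_app([EL]) = k_max[EL]/(k_half+[EL])`; `k_max` estimates `k_u` and
`k_half` estimates `k_f/k_c`. At least three distinct positive
concentrations are required; an all-zero profile is a degenerate-profile
error; a fitted `k_half` above 10× the largest tested concentration sets a
"saturation not reached" flag (the plateau is then extrapolation, as for
the D122Y series whose profile is not complete).

**Melt fits** (`TwoStateMelt`) use the two-state van 't Hoff model with
ΔCp = 0 (no printed enthalpies justify more), R = 1.987×10⁻³
kcal·mol⁻¹·K⁻¹, temperatures converted to kelvin internally and reported in
°C. The observed signal is the population-weighted sum of two linear
baselines. Tm is initialised at the maximum of the Savitzky–Golay-smoothed
derivative and bounded to the scanned range; baselines are initialised from
linear fits to the outer 15% of points. Equilibrium curves already
normalised to fraction unfolded are fit with baselines fixed at 0 and 1.
Post-transition DSF signal decay (dye release) is not modelled; a
`truncate_post_max` option drops points past the signal maximum instead. A
fit whose transition amplitude falls below 5× the residual RMS raises a
no-transition error (this also catches flat and featureless-ramp inputs);
a Tm within 5% of either scan edge sets an edge-flag warning.

**Identifiability note.** With all six parameters free, the precision of Tm
depends on how much baseline flanks the transition. A transition sitting
near the cold end of the scan (the I154F DSF case: Tm ≈ 39 °C on a 25–80 °C
scan, ~14 °C-wide transition) leaves only a few degrees of folded baseline,
and the folded-baseline parameters become strongly correlated with Tm. At
1% amplitude noise the resulting Tm uncertainty is of the same order as
0.3 °C — seed-to-seed recovery scatter at that level is the information
content of such a trace, not an optimizer deficiency (the fits reproduce
independent global least-squares solutions). Mid-scan transitions (wild
type, D122Y) recover roughly twice as precisely, and fixed-baseline
equilibrium fits an order of magnitude better.

**ΔTm and trends.** `delta_tm` is plain `Tm − Tm(control)` on converged
fits. `stabilization_trend` is the OLS slope of Tm vs osmolyte
concentration with a ±2-standard-error sign classification. The package
ships the published reference DSF Tm table for the three frataxin variants
(control, trehalose and TMAO series). Several of that table's printed ΔTm
entries do not equal Tm − control as printed — the D122Y trehalose shifts
are consistent with a ~46.2 °C reference rather than the printed 48.8 °C
control, and the low-concentration TMAO rows disagree in sign —
`dtm_consistency_report()` surfaces these rows; the package recomputes all
shifts from the Tm column and does not attempt to repair the printed ones.

## Spectra and solubility

Protein is quantified as `A(280) − A(350)` (linear interpolation on the
grid): a two-point subtraction that cancels any wavelength-independent
drift exactly. It only partially removes curved Rayleigh-type scatter
(`c·λ⁻⁴` normalised to A350 = 0.05 leaves a ~0.07 AU excess at 280 nm) —
which is deliberate: the two-point readout reproduces the assay's exact
procedure, and the scatter diagnostics are kept separate. Those fit
`log A = log c − β log λ` over 320–400 nm, report β only when
A350 > 3× the noise floor (default 0.002 AU), and classify a pair of
spectra as aggregating when ΔA350 exceeds 0.01 AU (a package default; the
assay itself is qualitative). The blue edge of the default window carries a
~3% tail of a 280/σ15 nm protein band, which inflates β by ~0.2 when a
strong band is present; shrink the window if that matters.

Solubility is `S/(S+P)` per gel lane, averaged over replicates (SD with
n−1), and `log2(fraction/fraction_control)` per condition. Band
intensities are taken as given; no image processing is implemented.

## Synthetic data and calibration

The generators emulate the study conditions; all are pure functions of
their parameters and an explicit seed.

**Variant presets.** Published values: DSF Tm 55.1/48.8/39.1 °C and
equilibrium Tm 66.3/50.4/50.7 °C for WT/D122Y/I154F. Calibrated values
(not published; chosen here so the printed endpoints emerge from the
forward model and then frozen):

| preset | k_u (min⁻¹) | k_f (min⁻¹) | k_c (µM⁻¹min⁻¹) | k_agg (µM⁻¹min⁻¹) |
|--------|------------|-------------|------------------|--------------------|
| WT     | 1×10⁻⁴     | 1.0         | 0.30             | 0                  |
| D122Y  | 0.015      | 0.450       | 0.30             | 0.005              |
| I154F  | 0.030      | 0.300       | 0.35             | 0.02               |

These give, at 3 µM chaperonin and 2 µM protein after 60 min, ~25% (I154F)
and ~55% (D122Y) soluble, with wild type essentially unpartitioned (<1%
loss), and I154F slowly losing solubility without chaperonin via the
aggregation channel. `ΔH_vH = 45 kcal/mol` for all variants (a ~10–14 °C
transition width, typical of a small single-domain protein; no enthalpies
are published) and the DSF baselines (1000, +1, 9000, −4 a.u.) are package
constants kept in one place.

**Noise defaults** are likewise package choices, exposed as parameters:
2% SD per time-course replicate (three replicates, matching the triplicate
spectroscopic reads), 1% of transition amplitude for melt curves, 0.002 AU
for spectra, 10% CV for densitometry bands. Time courses sample
0–60 min on the assay's grid (densest at early times); melts scan
25–80 °C (DSF) or 40–85 °C (equilibrium) at 0.5 °C — the scan interval is
not published; 0.5 °C is assumed.

**What the generators do not emulate:** bead-transport limitation of the
capture step, burst-phase partitioning within the first minute,
dye-induced destabilisation during DSF (beyond the truncation option),
instrument-specific file formats, and small-aggregate escape from the
spin-down — the last is available as an explicit `aggregate_escape_frac`
option but defaults to full aggregate removal. Passing recovery tests on
these synthetics therefore demonstrates correctness of the estimators
under the stated noise model, not robustness to every real-data artefact.

## Numerical choices

* ODE integration: LSODA (stiff-safe), rtol 10⁻⁸, atol 10⁻¹⁰ µM; mass
  `N+I+C+A` is conserved to 10⁻⁶ µM on every output grid and asserted in
  tests; integration-level negative excursions are clipped at 0.
* Optimisation: Levenberg–Marquardt throughout, with the initialisations
  above; convergence flags are reported, never silently dropped.
* Grids: analysis and validation use 61–241-point time grids over
  0–60 min and 0.5 °C melt grids — sizes chosen so every fit and
  simulation completes in well under a second.
* Reported precision: CSV output at 6 significant figures; round-trips are
  lossless at that precision.

## Known limitations

* Absolute microscopic rates for the real variants are not recoverable
  from this package's inputs; the presets are calibrated to endpoints, so
  only endpoint-level and ordering-level conclusions transfer.
* The single-exponential decay model ignores the burst phase suggested by
  sharp first-minute drops; residual structure is the user's cue.
* One effective capture constant cannot distinguish site multiplicity,
  bead-surface accessibility and intrinsic association kinetics.
* The two-state melt model with ΔCp = 0 is inadequate far from Tm and for
  irreversible, scan-rate-dependent unfolding; heating rate is metadata
  only.
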