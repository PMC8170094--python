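# Methods

`bc1sox` is a post-simulation inference chain for a specific scientific
question: how fast does the cytochrome bc1 complex produce superoxide
through a stray electron transfer to an O2 molecule bound near the
Q_o-site while a semiquinone radical anion (Q•−) is present?  The package
does not run quantum chemistry or molecular dynamics; it consumes the
tables such simulations produce (fragment spin densities, distance time
series, energy-gap samples, alchemical work samples) and turns them into
classified reactions, binding times, free-energy parameters and rates.

## Electron-transfer classification from spin densities

A geometry-optimized QC snapshot of the Q_o-site reports one local spin
density per fragment.  Ground-state O2 is a triplet (|s| = 2); superoxide
carries |s| = 1.  Snapshots therefore fall into two discrete outcomes,
and the classifier thresholds |s(O2)| at 1.5, the midpoint.  Values below
0.5, or with a sign contradicting the prepared O2 spin orientation, are
anomalies routed to the outlier bin.  For transferred snapshots, the
donor is read from the spin-density change Δs relative to the mean over
no-transfer snapshots: the donated electron is anti-parallel to the O2
spins, so the compensating |Δs| ≈ 1 sits either on the semiquinone
(model I, Q•− + O2 → Q + O2•−) or distributed over the Fe2S2 cluster
fragments (model II, Fe2S2⁻ + O2 → Fe2S2 + O2•−).  The winning donor
pool is the one with the larger summed |Δs| (exact ties go to model II —
arbitrary but deterministic); weights are the normalized |Δs| within the
pool, and a snapshot where both pools sum below 0.5 is unattributable and
becomes an outlier.

Energy outliers — snapshots whose total energy deviates from the median
of their (spin orientation, label) group by more than a threshold — are
flagged after donor attribution, so the median is computed within an
energetically homogeneous class.  The default threshold is 50 kcal/mol:
class standard deviations in ensembles of this kind are 11–15 kcal/mol,
so 50 corresponds to 3–4 sd.  Class statistics are reported relative to
the no-transfer mean with the sample (n−1) standard deviation, matching
the small-N character of snapshot ensembles; single-member classes carry
no sd, and outlier rows carry a count only.  The per-class Gaussian
"fit" is deliberately moment-matched (mean, sd), not a free fit.
Unconverged records are dropped with a logged count.

## Binding kinetics

Binding events in a ligand–Fe2S2 distance trace are segmented with a
hysteresis rule: an event opens when the distance first drops below 9 Å,
survives excursions beyond 13 Å, and closes — at the last frame the
ligand was within 13 Å — only once 20 Å is reached.  Boundary semantics
are fixed deterministically: "within 9" is d < 9, "within 13" is
d ≤ 13, "reaching 20" is d ≥ 20.  A trace that starts bound opens at
frame 0 (the product-state simulations begin with superoxide bound); an
event still open at trace end is flagged unresolved and excluded from
survival fitting.  Dwell times build the survival count N_b(t) = number
of events with dwell ≥ t, modeled as N0·exp(−t/τ).  Two τ estimators
are provided: nonlinear least squares on the survival histogram with
(N0, τ) free (the default, matching how such curves are usually
presented) and the exponential maximum-likelihood estimate (the sample
mean, N0 fixed), which is the statistically efficient choice.  Input dt
is in ps; dwell times and τ are reported in ns.  When a membrane-normal
coordinate accompanies the trace, the escape side is the sign of z at
the first post-event frame with |z| beyond a 20 Å shell (positive = the
intermembrane space side).

## Linear-response free energy along the energy gap

The vertical energy gap ΔU = U_product − U_reactant (same coordinates,
different charge assignments; negative ΔG0 = favorable reaction) serves
as reaction coordinate.  Each state's sampled ΔU histogram gives an
empirical branch G = −kBT ln ρ(ΔU) (Freedman–Diaconis binning by
default, empty bins dropped, minimum shifted to 0); Gaussian statistics
give the extrapolating parabola with curvature kBT/(2σ²) and vertex at
⟨ΔU⟩.  The product branch is shifted to make the curves intersect at
ΔU = 0, after which ΔG0 is the difference of the minima and the
reorganization energies follow from parabola geometry, Λp = a_p(Δv)²
and Λr = a_r(Δv)² with Δv the vertex separation.  This geometric
definition is used rather than the equal-variance identity σ² = 2ΛkBT,
because sampled gap distributions routinely violate global Gaussian
statistics (Λp ≠ Λr); the identity serves only as a test oracle on
synthetic data, where ΔG0 → (m_r + m_p)/2 and Λ → σ²/(2kBT) hold in
closed form.  A skewness beyond |0.5| raises a normality warning.
Default temperature is 300 K (kB = 0.0019872 kcal/mol/K), configurable.

## Alchemical free energy (FEP/BAR)

The reaction free energy is alternatively assembled from two alchemical
legs — discharging the reactant electrostatics (FEP1) and recharging the
product (FEP2), each a ladder of 16 equal λ windows by default, run
forward and backward.  Per window the increment is the exponential
(Zwanzig) average ΔΔG = −kBT ln⟨e^(−ΔU/kBT)⟩, computed via log-sum-exp
so that |ΔU|/kBT up to the exp overflow limit (~700) cannot overflow, or
the Bennett acceptance ratio, which solves

    mean_F f((W_F − C)/kBT) = mean_B f((W_B + C)/kBT),
    C = ΔG + kBT ln(n_B/n_F),  f(x) = 1/(1 + e^x),

by Brent root finding (tolerance 1e-8 kcal/mol) on a bracket grown
around the midpoint of the two exponential estimates; the asymptotic
variance is reported from the standard second-moment expression.  BAR is
the default (minimum-variance); the exponential totals of the forward
and reversed transformations are always evaluated and their residual
|ΔG_fwd + ΔG_bwd| kept as the hysteresis diagnostic.  Leg totals add,
uncertainties add in quadrature, and legs must belong to the same
electron-transfer model.  Restraint corrections for the O2 confinement
spheres used in such simulations are out of scope; work samples are
consumed as given.

## Rates

The Moser–Dutton ruler, log10 k_et = 15 − 0.6·R − 3.1(ΔG+Λ)²/Λ
(energies in eV, R in Å), is the default rate expression because it
needs no electronic coupling.  The nonadiabatic Marcus rate
k = (2π/ℏ)|T_AB|²(4πΛkBT)^(−1/2)·exp(−(Λ+ΔG0)²/(4ΛkBT)) is available
when a coupling is supplied.  Energies are carried in kcal/mol and
converted with 23.0609 kcal/mol per eV; kB = 8.6173×10⁻⁵ eV/K and
ℏ = 6.5821×10⁻¹⁶ eV·s.  Over a per-snapshot distance series the ruler
is averaged arithmetically (not in log space): because the rate is
exponential in −R, close-approach snapshots dominate, which is the
physically intended behavior for a fluctuating donor–acceptor pair.
The default chain uses the product-state reorganization energy Λp
(maximal overlap argument); Λr is available and lowers model I's rate
by roughly two orders of magnitude.  The production rate while the site
holds a semiquinone is k = k_bind·k_et/(k_et + k_unbind), bounded above
by k_bind, optionally scaled by the semiquinone occupancy fraction to a
per-complex rate.  Binding/unbinding rates are configuration inputs, not
estimated from trajectories.

## Synthetic data

The generators exist to make every estimator testable by parameter
recovery; each derives an independent random substream from
(seed, generator id), so outputs are reproducible and uncoupled.

- **Gap samples**: reactant/product means at ΔG0 ± Λ with the reactant
  sd fixed by the equal-variance identity √(2ΛkBT) and the product sd
  scaled by a ratio (≠ 1 produces the Λp ≠ Λr regime).  Defaults mirror
  the model I scale (ΔG0 = −20 kcal/mol, Λ ≈ 84 kcal/mol).
- **FEP work**: forward ~ N(ΔG_i + σ²/2kBT, σ), backward ~
  N(−ΔG_i + σ²/2kBT, σ), which satisfies the Crooks relation with
  free-energy difference ΔG_i exactly — verified in tests by binned
  regression of the work-density log-ratio (slope 1/kBT within 5%).
- **Dwell times**: i.i.d. exponential; default scale ~4.5 ns.
- **Distance traces**: baseline 25 Å with scheduled drops to 5 Å;
  uniform noise (default amplitude 0.5 Å) truncated per-frame so it can
  never cross the 9 or 20 Å thresholds, keeping the noiseless
  segmentation the exact ground truth.  An optional per-event escape
  schedule attaches a z channel ramping to ±25 Å after unbinding.
- **Spin tables**: idealized class patterns with spin conservation
  (Σ Δs = 0) plus Gaussian spin noise (default sd 0.02) and per-class
  energies; default counts and moments follow the O2 spin-up ensemble of
  the reference study (77/0/44/6; model II ~39 kcal/mol below the
  no-transfer mean).  Non-outlier energies are truncated at 3 sd so the
  classes stay decidable under the 50 kcal/mol outlier rule; outliers
  are drawn ~150 kcal/mol below the anchor.

What the generators do *not* emulate: correlated (non-i.i.d.) gap
samples, non-Gaussian work distributions, diffusive distance dynamics
with threshold-straddling noise, or spin delocalization beyond the
canonical fragments.  Passing recovery tests therefore demonstrates
estimator correctness under the stated models, not robustness to every
pathology of real trajectories.

## Problem sizes and numerical choices

Recovery tests use 1e5 gap samples (bootstrap SE for the 3-SE bands),
100 seeded 16-window transformations at 1e4 work samples per side for
BAR, 1e4 dwell times, 1e3 random traces against a brute-force
segmentation oracle, and ~1e3-record spin ensembles — sizes at which the
asymptotic tolerances are meaningful while the whole suite runs in well
under a minute of estimator time.  Degenerate inputs are handled
explicitly: zero-sd work samples reduce all estimators to the constant,
zero-width λ windows contribute exactly 0, equal parabola vertices
return Λ = 0 with a warning, and all-identical gap samples reject the
histogram path.

## Known limitations

- The reference free-energy parameters and rates bundled for the demo
  chain derive from simulations this package does not re-run; the
  package validates internal consistency of the rate chain around them,
  not their values.
- The BAR variance is the standard asymptotic estimate; it understates
  the error when forward/backward distributions barely overlap.
- The escape-side rule uses a single shell crossing; re-crossing events
  after deep excursions are not re-examined.
- Marcus mode requires a user-supplied |T_AB|; none is estimated.
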