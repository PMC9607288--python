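# Methods

`mannoload` analyses the quantitative chain of a macrophage-targeted
drug-delivery experiment: how strongly a mannosylated carrier binds its
receptor, how much drug the carrier loads, and how the drug partitions
between solution, cell wall and cell interior with and without an
efflux-inhibiting adjuvant. This note records the models, the defaults
and the reasoning behind every genuinely open design choice.

## 1. Binding analysis (Hill model)

### Model

A receptor binding n ligand molecules in one cooperative step,
R + nL ⇌ R·L<sub>n</sub>, with dissociation constant
K<sub>d</sub> = [L]<sup>n</sup>[R]/[R·L<sub>n</sub>], produces for any
analytical signal ξ linear in the bound fraction θ:

    ξ(L) = ξ0 + (ξ∞ − ξ0) · L^n / (L^n + K^n),        K = Kd^(1/n)

K is the per-site midpoint concentration (M); K<sub>d</sub> = K<sup>n</sup>
carries units of M<sup>n</sup>, which is why results are reported as the
dimensionless −lg K<sub>d</sub>. The linearized (Hill-plot) form is

    lg(θ / (1 − θ)) = n·lg[L] − lg Kd,      θ = |(ξ − ξ0)/(ξ∞ − ξ0)|

The absolute value makes θ sign-agnostic: protein amide-band intensities
*decrease* on complexation, so ξ∞ < ξ0 is the common case.

### Estimation: the two-stage fit

1. **Nonlinear stage** — least squares of the four-parameter isotherm in
   (ξ0, ξ∞, lg K, n), with an analytic Jacobian and a small multistart
   (n ∈ {0.7, 1, 1.5, 2.5} × two lg K offsets around the half-range
   concentration). The multistart matters: when a titration does not
   reach saturation the sum-of-squares surface has a long flat valley in
   which a single start stalls.
2. **Linear stage** — ordinary least squares of the Hill plot using the
   stage-1 asymptotes. The reported stoichiometry n is the slope and the
   reported −lg K<sub>d</sub> is the intercept (at lg L = 0 the logit
   equals −lg K<sub>d</sub>), with standard errors from the regression.
   On noiseless data the two stages agree to machine precision
   (lg K<sub>d</sub> = n·lg K).

### Clipping of the Hill plot

The logit diverges as θ → 0 or 1, so near-asymptote points must be
excluded. Defaults:

* a static band: keep 0.01 < θ < 0.99. The static floor must be this
  low because a titration that spans only the foot of the isotherm can
  have just three points above θ = 0.01 — a wider conventional cut
  (e.g. 2%) would make noiseless, perfectly collinear designs unfittable;
* a noise-adaptive floor: points within 3 residual SDs (from stage 1) of
  either asymptote are also excluded, capped at 0.3 per side. At the
  asymptotes the "bound fraction" of a noisy point is |ε|/(ξ∞−ξ0) —
  pure noise — and because of the absolute value these points pile up at
  a logit floor that flattens the slope and biases −lg K<sub>d</sub>
  downward by *orders of magnitude* if included. At zero noise the
  adaptive floor vanishes and the static band alone applies.

### Identifiability: the titration must bracket the transition

If the largest concentration sits well below the midpoint K, the data
follow the power law ξ ≈ ξ∞(L/K)<sup>n</sup> in which only the ratio
ξ∞/K<sup>n</sup> is identified: n is recoverable (log–log slope) but ξ∞
and K<sub>d</sub> separately are not. The fit flags any titration whose
observed θ span is below 0.3 (`transition_bracketed=False`, with a
warning), and rejects series in which fewer than 3 informative points
survive clipping. Note that the synthetic-titration defaults
(n = 1.5, −lg K<sub>d</sub> = 6.5 on 12 concentrations from 1e−8 to
1e−5 M) put the midpoint at 4.6e−5 M, *above* the largest concentration:
the generated curve reaches only θ = 0.09. Noiseless data in that design
are still fit exactly (the model is exact and four points determine it),
but at realistic noise the estimator rightly reports most replicates as
uninformative — a property of that experimental design, not of the
estimator. Parameter sets whose midpoint lies inside the grid (e.g.
n = 1.2, −lg K<sub>d</sub> = 6.0) are recovered accurately at 2% noise
(200-replicate mean within ±0.1 of truth).

Equilibrium ligand concentration is approximated by total added ligand
(ligand in large excess over receptor-bound ligand in the studied
regime); a depletion correction [L] = L_tot − n·θ·C_receptor can be
applied upstream where that assumption fails.

## 2. Spectral processing

The signal-extraction chain mirrors standard FTIR practice: blank
subtraction (identical grids required — no implicit resampling),
baseline correction by the least-squares line through anchor-region
means, min–max normalization, Savitzky–Golay smoothing (5 points,
quadratic), and Savitzky–Golay second differentiation (9-point window,
quadratic polynomial). Conventions:

* second derivative d²A/dν² annihilates any linear baseline exactly and
  commutes with scalar scaling; absorption maxima appear as *minima* of
  the derivative, which sharpens overlapping bands — hence the
  derivative-spectrum readout picks minima;
* peak positions are refined by a 3-point parabola through the extremum,
  the minimal sub-grid estimator, because complexation shifts are often
  a fraction of the 1 cm⁻¹ grid step;
* an extremum on the region boundary is flagged as possibly truncated,
  not silently reported;
* wavenumber grids may arrive ascending or descending and are normalized
  to ascending; all operators preserve grid and length.

Atmospheric-compensation and instrument-vendor corrections are out of
scope; blank subtraction is assumed to absorb them. Whether the
analytical signal ξ is taken from native or second-derivative spectra,
as intensity or as position, is a pipeline configuration option — both
occur in practice and the chain supports all four combinations.

## 3. Drug-loading equilibrium

A carrier with N equivalent independent sites at total concentration
C<sub>L</sub> loads drug at total C<sub>M</sub> with per-site constant
K<sub>d</sub>:

    Kd = N (C_M − C_b)(C_L − C_b/N) / C_b
    ⇒  C_b² − (C_M + N·C_L + Kd)·C_b + N·C_L·C_M = 0

The smaller quadratic root is the physical one: the product of the roots
is N·C<sub>L</sub>·C<sub>M</sub> and the larger root always exceeds
min(C<sub>M</sub>, N·C<sub>L</sub>), i.e. would bind more drug than
exists or more than the sites can hold. The root is evaluated in the
numerically stable form 2ac/(−b+√(b²−4ac)) and checked at runtime
against the physical interval; tests verify it against a bisection
oracle run in 50-digit decimal arithmetic (a binary-float oracle loses
~8 digits to cancellation near the root and would be *less* accurate
than the solver it checks).

Derived quantities: EE (%) = 100·C_b/C_M (entrapment efficiency) and
LC (%) = 100·N·m_drug/m_carrier (loading capacity, concentration-
independent). The moxifloxacin molar mass defaults to the free base
(401.4 g/mol) with the hydrochloride (437.9 g/mol) selectable; both land
inside the printed uncertainty of the published LC values, the free base
marginally closer for the heaviest carrier.

Site counts: cyclodextrin-torus sites are N_CD = 0.9 × (torus count) —
the 0.9 occupancy factor is an empirical convention kept as a named
constant (`CD_TORUS_OCCUPANCY`), not a derived quantity. Polymer-matrix
sites are estimated from the drug:carrier mole ratio R at which the
equilibrium bound fraction equals a target θ* (default 0.95), with the
carrier loaded to capacity (N = R, C_M = R·C_L); the quadratic then
collapses to K_d·C_b = (C_M − C_b)², giving the closed form
R = K_d·θ*/((1−θ*)²·C_L), verified against a grid scan. Under this
reading R → 0 as K_d → 0 (stoichiometric loading needs no excess) and
θ* = 1 is unattainable at finite concentrations (rejected). Carriers
with both CD and polymer sites are modelled with a single effective
N = N_CD + N_polymer and one K_d; a two-site-class model is out of scope
because the source data report one constant per system.

## 4. Uptake partitioning

`UptakeTable` holds time-resolved (solution, wall-adsorbed, absorbed)
concentrations per analyte plus the dose. Statistics: mass-balance
recovery per time (flagging rows outside ±10% of dose — wide enough to
pass measurement scatter, tight enough to surface genuine losses such as
late-incubation cell lysis, which is deliberately *not* modelled or
corrected); absorbed fraction of dose; peak intracellular concentration
(ties → earliest time); enhancement of the peak versus a control arm;
and the per-time retention ratio (undefined-at-zero-control rows are
flagged, not raised). Mixed min/h time units are normalized to minutes
on ingest. Headline percentages are reported at full precision alongside
a one-significant-figure rounding (`round_to_sig`), the convention that
turns a computed 57.1% enhancement into the quoted "60%".

## 5. Synthetic data

The generators provide ground-truth-known inputs for every stage:

* **Titrations** — Hill signal plus additive Gaussian noise, default
  sd 0.02 = 2% of the unit dynamic range (the minimal noise model when
  only parameter-level ±SD is known). Default design: 12 log-spaced
  concentrations 1e−8–1e−5 M, ξ0 = 0, ξ∞ = 1, n = 1.5,
  −lg K<sub>d</sub> = 6.5 (see the identifiability caveat in §1).
* **Spectra** — Gaussian bands on a linear baseline; default bands at
  1650 and 1550 cm⁻¹ (amide I/II analogues), width 25 cm⁻¹, on a
  900–3000 cm⁻¹ grid at 1 cm⁻¹. Band heights (and optionally centres)
  interpolate linearly between free and bound endpoint values with θ.
* **Uptake** — the closed three-compartment scheme S ⇌ W → I → S with
  first-order rates; with the adjuvant, internalization is boosted by
  (1 + perm_boost) and efflux is reduced by inh_frac after a step onset
  (default 30 min — pump inhibition develops over tens of minutes, not
  instantly). Rates are piecewise constant, so trajectories are computed
  with matrix exponentials: exact, and mass-conserving to machine
  precision (every column of the rate generator sums to zero). Default
  rates (k_on = 0.15, k_off = 0.01, k_in = 0.03, k_out = 0.2 min⁻¹,
  perm_boost = 0.6, inh_frac = 0.8) were chosen once to reproduce the
  qualitative shape of the measured distribution tables — early
  intracellular maximum in the control arm, higher peak and ≥2×
  retention after inhibition onset in the adjuvant arm — and are
  emulation parameters, not estimates of the real system. A
  least-squares routine (`kinetics.fit_rates`) recovers all rates and
  inh_frac exactly from noiseless two-arm tables.

What the generators deliberately do **not** emulate: instrument drift,
atmospheric bands, correlated or multiplicative noise, receptor/ligand
depletion, cell growth and lysis, and any saturation of adsorption
sites. Tests passing on synthetic data therefore demonstrate
correctness of the *computational chain*, not robustness to every
artefact of real measurements.

## 6. Numerical conventions

* Nonlinear fits: `scipy.optimize.least_squares` (trf), tolerances at
  float epsilon, bounded n ∈ [0.05, 10], lg K within ±6 of the
  concentration window.
* Floats are serialized to CSV with 12 significant digits; round trips
  are lossless to 1e−11 relative.
* Peak ties and plateaus: `argmax`/`argmin` take the first extremum;
  parabolic refinement degenerates gracefully to the grid point when
  the three-point curvature is zero.
* Degenerate inputs are rejected with specific messages (constant
  spectrum for min–max, identical asymptotes for θ, N = 0 sites warns
  and returns zero bound drug, negative rates, non-uniform grids for
  differentiation).
* All randomness flows through `numpy.random.default_rng(seed)`; a
  fixed seed reproduces outputs bit for bit.

## 7. Known limitations

* The Hill analysis fits each analytical signal separately; no rule is
  offered for combining several signals (amide I and II intensity and
  position) into one constant, because no such rule is defined in the
  source protocol — the spread across signals is the honest uncertainty.
* K<sub>d</sub> in M<sup>n</sup> is not comparable across systems with
  different n except through −lg K<sub>d</sub> at a stated n.
* The uptake scheme is closed (no degradation/lysis sink), so it cannot
  reproduce late-time net losses; such rows are flagged by mass balance
  instead.
* The loading model assumes equivalent independent sites and one
  constant per carrier; cooperative or heterogeneous-site loading is out
  of scope.
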