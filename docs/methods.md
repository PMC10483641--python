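# Methods

This note records the model assumptions, parameter choices and numerical
conventions behind `dvmflux`, and what the synthetic tests do and do not
demonstrate about real profiler records.

## The inference chain and its assumptions

The estimator answers one question: how much nitrate is being removed
*biologically* below the euphotic zone, given a single mooring that sees
internal waves and horizontal advection superposed on the uptake signal.

**Isopycnal transform.** Internal waves displace tracers together with the
density surfaces they ride on. Each profile is therefore interpolated —
linearly, in density — onto uniform density bins (0.02 kg m⁻³), and all
results are expressed against each bin's time-mean depth. Linear rather
than spline interpolation is deliberate: the nitracline rises from
undetectable nitrate to >10 mmol m⁻³ over a few metres and splines
overshoot at such kinks. Weak density inversions are reordered by sorting;
profiles with inversions larger than 0.05 kg m⁻³ are flagged unusable
instead (both thresholds configurable). The transform assumes tracers are
carried kinematically by the isopycnals — valid for fast (hours)
internal-wave motion, not for diapycnal mixing, which the method ignores.

**Water-mass tracking.** On one isopycnal, parcels are distinguished by
spice in 0.005 kg m⁻³ bins. Spice is computed as the linearized
density-orthogonal combination α′T + β′S (α′ = 0.20 kg m⁻³ °C⁻¹,
β′ = 0.78 kg m⁻³ per salinity unit, matching the linear equation of state
used throughout); the formulation is pluggable. Contiguous occurrences of a
(density bin, spice bin) key — bridging gaps up to 2 grid steps — are
collapsed into single visits (median time, mean nitrate, SE =
sensor precision/√n). Consecutive visits form observation pairs, subject to
a minimum separation of 2 h (noise jitter across a bin edge is not a
reappearance, and ln-ratio rates over minutes are hopelessly
ill-conditioned — the minimum keeps junk-only averaging windows out of the
composite) and a maximum of 2 d (beyond which same-spice ≠ same-parcel).
The key physical assumption inherited by everything downstream: uptake is
horizontally uniform on the scale of the advective excursions, so the loss
seen between two visits of a parcel equals the local loss.

**Rate model.** Pairs give r = ln(N₂/N₁)/Δt exactly; multi-point visit
series use least squares of ln N against time. Values at or below the
detection limit (default 0.5 mmol m⁻³) refuse the estimate rather than
entering a log fit. Rates are assigned to the window containing the pair
midpoint on a uniform δt grid (default the native 15-min step),
inverse-variance averaged within windows, and linearly interpolated across
gaps up to 1 d; longer gaps and the regions before the first/after the last
estimate stay flagged — no extrapolation. The forward recursion
N̂(t+δt) = N̂(t)·e^{rδt} starts from the first unflagged observation per
bin; ρNO₃ = −r·N̂ is the instantaneous rate (positive = loss; positive-r
supply events are retained in the field and reported as a fraction in the
summary), and Nloss is *defined* as the cumulative trapezoid of ρNO₃, so
re-integration reproduces it identically. Once a bin's nitrate falls below
detection its rate becomes unconstrained: ρ cells are flagged, N̂ is held,
and the accumulated Nloss remains defined (a lower bound — any further
trickle of uptake on sub-detection nitrate is invisible to the method).

**Error propagation.** All uncertainties are first-order. The independent
random inputs are the pair-level rate estimates (delta-method SEs from the
assumed sensor precision, default 0.3 mmol m⁻³) and the initial nitrate per
bin. Every derived field — windowed rates, interpolated cells, N̂, ρNO₃,
Nloss, depth integrals — is expressed as an explicit linear map of those
inputs, and variances flow through the actual weights. This matters: a
naive per-grid-cell independence assumption would understate the Nloss SE
by roughly √(window length/δt), because neighbouring cells share the same
pair estimates. Bins are treated as mutually independent (their pairs are
disjoint); the predicted-nitrate path is held fixed when differentiating
ρ = −rN̂ (second-order terms dropped). Depth integrals combine bin SEs in
quadrature with trapezoid weights.

**Depth integration.** Trapezoid over the mean-isopycnal-depth axis,
default 0–33 m. Rate-like fields integrate over strictly valid cells;
cumulative fields use the once-constrained-always-defined mask. A time step
with under half its bins valid is flagged. Biomass integrals additionally
pad the integrand to the exact bounds with edge values: the density axis
cannot resolve the weakly stratified surface layer, but the chlorophyll it
carries is real and would otherwise be clipped out. Loss fields are *not*
padded — absence of a rate estimate is not a measured zero.

**Climatology and deficit.** Nitrate–temperature samples are binned at
0.25 °C × 1 mmol m⁻³; the cold-branch line (T < 14 °C) is fitted by
count-weighted least squares of each bin's mean nitrate against its mean
observed temperature (bin centres would leave a binning bias; an
alternative fitting per-bin modes would emphasize the high-density ridge
instead). The deficit of an observation is max(0, predicted(T) − N), with
the prediction clipped at zero and the deficit undefined — not zero — at or
above the cutoff. In the self-contained pipeline the "climatology" is
fitted to the first day of the record, before appreciable uptake; with a
real multi-decade bottle climatology the same fit applies unchanged.

**Bloom metrics.** The descending chlorophyll layer is tracked as the
centroid of the chlorophyll *excess* above each profile's 75th-percentile
value — subtracting the threshold baseline keeps the near-uniform
background from dragging the centroid toward mid-column — and the descent
speed is the OLS slope of centroid depth against time over one night's
window. Loss–biomass correlations are computed on daily-binned series:
integrated chlorophyll carries a strong diel signal as the migrating layer
sweeps across the integration boundary, and binning isolates the
accumulation the comparison is about ("increase" = value minus window
start; a first-difference mode exists). The N:Chl yield divides the growth
of depth-integrated Nloss by the growth of depth-integrated chlorophyll
over the *same* end-member windows, in mmol N per mg Chl by default (a
mass-per-mass mode is labelled in the output).

## The synthetic ocean

The generator builds everything in a material vertical coordinate ζ that
rides the internal-wave displacement and maps to the fixed depth grid at
the end, so "truth" lives on the same mean-isopycnal axis the estimator
reports on.

Defaults (all in `ScenarioConfig`, units in the docstrings): 0–100 m at
1 m / 15 min for 14 d; background σθ = 24.40 kg m⁻³ at the surface rising
to 25.70 through a tanh pycnocline at 24 m (width 7 m) plus a
0.008 kg m⁻³ m⁻¹ linear gradient so the near-surface layer is still
resolvable in density; temperature co-generated (19 °C surface, tanh step
8 °C) and salinity solved from a linear equation of state
(α = 0.20 kg m⁻³ °C⁻¹, β = 0.78). Nitrate is the climatological line
N = −5.9 T + 80.94 (clipped at zero) minus accumulated uptake, which
places the nitracline near 26–30 m. One semidiurnal internal-wave mode
(amplitude 10 m → ~20 m peak-to-trough, first-baroclinic sine shape);
an 18-h spice oscillation of amplitude 0.04 kg m⁻³ built from
density-compensated (δT, δS); because nitrate is a function of temperature
including the spice anomaly, nitrate is exactly a function of
(density, spice) — the generator embodies the estimator's
horizontally-uniform-uptake assumption by construction.

The DVM layer (Gaussian, σ = 3 m) resides at 2 m by day, descends at
380 μm s⁻¹ from 18:00 local until it reaches the 30-m floor (≈22 h, matching
observed 18–24 h descents), dwells until the next 06:00, and returns at
4× the descent speed; the solar day is fixed at 06:00–18:00 with no
ephemeris. The Gaussian is renormalized wherever it is truncated at the
surface so layer mass is conserved (organisms accumulate at the boundary
rather than vanish). Uptake is Michaelis–Menten in nitrate (half-saturation
0.5 mmol m⁻³) at up to 6 mmol N m⁻³ d⁻¹, confined to the half-open
20–40 m range, scaled by biomass overlap (a `prescribed` mode drops the
biomass factor for uniform-layer recovery experiments, and `none` switches
biology off). Chlorophyll amplitude grows by 0.19 mg Chl per mmol N taken
up (so the built-in N:Chl is 5.3); backscatter is affine in chlorophyll;
PAR is a sinusoidal 06–18 h surface cycle attenuated by
k_d = 0.12 + 0.035·Chl m⁻¹ (turbid bloom water; euphotic depth ≈ 20–25 m),
and daytime fluorescence is quenched by up to 40% where PAR exceeds 100
units so the NPQ correction has something to correct. Sensor noise is
i.i.d. Gaussian per gridded sample: 0.3 mmol m⁻³ nitrate (typical UV
nitrate sensor precision), 0.1 mg m⁻³ chlorophyll, 0.002 °C / 0.002
salinity (CTD-class), added after ground truth is frozen; density is
recomputed from the noisy T and S.

Bookkeeping details worth knowing: the uptake state is advanced by forward
Euler on the 15-min grid with the accumulated loss kept monotone (uptake
simply stops while the advected supply minus accumulated loss is
non-positive); the exported true loss rate is the instantaneous rate at
each grid time and the exported cumulative loss is its trapezoid integral,
so the two are consistent to machine precision and agree with the realized
nitrate drawdown to O(δt).

**What the generator does not emulate** — and hence what passing tests do
not establish about the field: no diapycnal mixing or nitrate resupply, no
vertical shear of the advective signal (a single-period, depth-coherent
spice oscillation), no nitrification/remineralization, no multi-species
community, no sensor drift or biofouling, no gaps or asynchronous sampling,
and internal waves implemented purely as heaving (no strain-driven
mixing). Recovery accuracies quoted by the tests are specific to these
idealized conditions.

## Known limitations

* Below the detection limit the method is blind: in depletion scenarios the
  estimated cumulative loss is a lower bound (the default bloom scenario
  recovers ~70–80% of the true loss for exactly this reason, and its
  measured N:Chl ratio of ~3.6 correspondingly underestimates the
  generator's 5.3 — part of the loss also accrues below the 33-m
  integration bound).
* Reappearance pairing assumes parcels conserve spice between visits;
  mixing along the spice axis would alias as apparent uptake or supply.
* The whole-record time-mean isopycnal depth is a finite-amplitude
  approximation; for a depth-dependent wave mode the time-mean depth of an
  isopycnal is biased from its rest depth at second order in amplitude
  (~0.5 m at the default 10-m amplitude).
* Supply events (r > 0) are retained but not modelled; a record dominated
  by resupply would need the omitted physics.

## Problem sizes

The default grids (101 depths × 1345 times, ~40 density bins, ~20k pairs)
were chosen to mirror the native resolution of two weeks of 1-m / 15-min
profiling; the full test suite and the acceptance script each complete in
well under a minute on a single core at these sizes.
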