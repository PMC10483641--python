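# dvmflux

Quantifying the nitrate drawdown caused by vertically migrating
dinoflagellates in moored-profiler time series.

Dense red tides of motile dinoflagellates (e.g. *Lingulodinium polyedra*)
can sustain themselves in strongly stratified coastal water by diel vertical
migration (DVM): the cells photosynthesize near the surface by day and swim
tens of metres down at night to take up nitrate below the euphotic zone.
Detecting that uptake in a single-mooring record requires separating three
signals that all move nitrate past the sensors:

1. **internal-wave heaving** — removed by remapping every profile onto
   uniform potential-density bins (0.02 kg m⁻³) and working against the
   time-mean depth of each isopycnal;
2. **horizontal advection** — removed by identifying water parcels on each
   isopycnal through their spice (0.005 kg m⁻³ bins) and comparing nitrate
   only within reappearances of the *same* parcel;
3. **biological uptake** — what remains.

For each parcel reappearance separated by Δt, the nitrate-specific rate of
change r is obtained from the exponential model

    N(t + Δt) = N(t) · exp(r Δt)   ⇒   r = ln(N₂/N₁)/Δt

The per-isopycnal rates are composited onto a uniform time grid δt
(inverse-variance averaging within windows, linear interpolation across
short gaps), iterated forward from the first observed nitrate to give the
predicted concentration N̂, the volumetric loss rate ρNO₃ = −r·N̂
(mmol N m⁻³ d⁻¹, positive = loss) and its cumulative integral
Nloss (mmol N m⁻³). Trapezoidal integration over the mean-isopycnal-depth
axis (default 0–33 m) yields the depth-integrated loss and flux, with
first-order standard errors propagated from the pair-level estimates
through every stage. A nitrate–temperature climatology (0.25 °C × 1 mmol m⁻³
bins, weighted least squares below 14 °C) provides an independent deficit
estimate, and bloom metrics (descent speed of the chlorophyll layer,
loss–biomass correlations, N:Chl yield) close the loop back to the
organisms.

Because the method's headline numbers depend on a specific field record, the
package ships a **synthetic ocean generator** that emulates the study
conditions — stratification heaved by ±10 m internal waves, an 18-h
along-isopycnal advection cycle carried by spice anomalies, a chlorophyll
layer descending at 380 μm s⁻¹ from 18:00 local, saturating deep nitrate
uptake, sensor noise — and records full ground truth (displacement, true
uptake rate field, true cumulative loss, layer trajectory) so every stage
of the inference can be scored.

## Worked example

```python
from dvmflux import ScenarioConfig, NitrateLossModel, generate_scenario

profiles, truth = generate_scenario(ScenarioConfig(seed=1))
model = NitrateLossModel.from_profiles(profiles)   # QC → isopycnal → pairs
results = model.fit()
print(results.summary())
```

```
Nitrate loss model (exponential water-mass pairs)
==========================================================
pairs fitted                 18470
density bins                    41
time steps (dt=15 min)   1345
median sigma_r              0.0430  d-1
fraction r > 0               0.449
avg flux 0-33 m            8.09 +/- 0.13  mmol N m-2 d-1
                             113.3 +/- 1.8  mg N m-2 d-1
final integrated Nloss       53.34  mmol N m-2
```

Reading this: 18 470 parcel reappearances on 41 isopycnals gave rate
estimates with a median uncertainty of 0.043 d⁻¹; about half the raw rates
are positive (noise plus supply events), but composited and integrated over
0–33 m the record shows a mean biological drawdown of ~8 mmol N m⁻² d⁻¹
(≈113 mg N m⁻² d⁻¹) and a cumulative removal of ~53 mmol N m⁻² over the
two simulated weeks — the expected signature of a migrating layer taking up
nitrate in the nitracline. `results.depth_integrated("nloss")` returns the
error-barred time series, `results.loss` the full gridded fields, and
`dvmflux.plotting` draws them.

The same chain runs from the shell:

```bash
dvmflux run-all --seed 1 --out rundir       # all stages + summary.json
dvmflux simulate --seed 1 --out simdir      # generator only
```

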