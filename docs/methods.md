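# Methods

`frosthatch` simulates wintertime soil temperatures at a single point under
three kinds of surface cover — bare mineral soil, a seasonal snowpack, and a
prostrate crop-residue (thatch) layer — and turns the simulated series into
risk statistics for miscanthus rhizome winterkill.  This note documents the
model, its parameters, its numerics, and its limits.

## Model structure

Each simulation is a one-dimensional column driven hourly:

1. **Synthetic weather** supplies daily series (tmax, tmin, precipitation,
   relative humidity, wind, solar) which are disaggregated to hourly forcing.
2. A **surface energy balance** solves for the skin temperature of the top of
   the stack from net shortwave, net longwave, neutral bulk-aerodynamic
   sensible/latent heat, and conduction into the top slab.
3. **1-D heat conduction** advances temperatures through the slab stack —
   optional snow, optional residue, then 11 soil layers to 250 cm
   (5, 5, 10, 10, 10, 20, 20, 20, 50, 50, 50 cm) — with an implicit
   finite-volume scheme and an enthalpy treatment of soil freezing.
4. **Snow** accumulates when hourly air temperature is at or below 1.1 °C
   (ties are snow) and melts when surface or internal energy would raise the
   bulk pack above 0 °C; a **bucket** moves liquid water through the soil.
5. Daily means of the 10 cm temperature (interpolated between the 7.5 and
   15 cm layer nodes) feed the risk statistics: per winter year (Jul 1 –
   Jun 30, labelled by the ending year) the minimum of the centred 3-day
   running mean, threshold exceedance at −3.5 / −6.0 °C, thickness response
   curves, quadratic bias correction, and OLS trends.

## Synthetic weather generator

The generator emulates mid-latitude continental (Midwest-style) climate; it
stands in for station-interpolated gridded data, which is not redistributable.
Daily mean temperature is

    T(d) = T̄ − A·cos(2π(d − d_cold)/365) + a(d) + o(d) + trend,

with annual mean `T̄`, seasonal half-amplitude `A`, coldest day `d_cold`
(default Jan 15), AR(1) anomalies `a` (marginal SD 3.2–4.0 °C, lag-1
autocorrelation 0.75), and Poisson-arriving winter cold outbreaks `o`:
half-sine pulses of 3–6 days whose peak magnitude is Gamma(2) with mean
7–10 °C, arriving 1.5–4 times per Nov–Mar winter depending on the site.
The expected outbreak cooling is added back as a uniform offset so the
closed-form mean of the model equals `T̄` exactly (this keeps the sampling
oracle clean); an optional linear trend is centred on the series midpoint so
it is mean-preserving.  With the cold presets this produces multi-day air
excursions to −25…−40 °C, the qualitative signature of Arctic outbreaks.

Precipitation is Bernoulli wet days with Gamma(0.75) amounts, seasonally
modulated so a chosen fraction of the annual total falls in the 90 days
around the coldest day; the rain/snow split is made hourly at the 1.1 °C
threshold.  Humidity, wind (Weibull, mean 4 m/s) and solar (seasonal
clear-sky curve times a wet/dry cloud factor) complete the six drivers.
Eight named site presets span a cold/snowy-north to mild-south gradient;
`north-plains` is the cold-continental reference used by the shipped
analyses (annual mean 4 °C, amplitude 18.5 °C).

Hourly disaggregation uses a piecewise-cosine diurnal temperature shape
(minimum at sunrise, maximum at 14:30) tied to the neighbouring days,
clamped to the day's [tmin, tmax]; shortwave follows a half-cosine over
daylight hours normalised to conserve the daily total; longwave down uses
the Brutsaert clear-sky emissivity with a cloud correction tied to the
wet-day flag; precipitation occupies a contiguous block of hours with a
deterministic start.  On days followed by an abrupt cooling the clamp takes
precedence over exact midnight continuity — a deliberate trade-off, since
the daily extremes are the calibrated quantities.

The generator (with fixed seed) is the only source of randomness anywhere;
identical seeds give byte-identical series, daily outputs and summaries.
Sweeps use common random numbers: every member consumes the same weather
realisation, so member differences are purely parametric.

**What the generator does not emulate:** spatial correlation, observed-site
microclimate, freezing rain, mixed-phase storms resolved below the threshold
rule, inter-variable dependences beyond the wet-day flag, and multi-decadal
variability beyond a linear trend.  Passing tests therefore demonstrate the
model's internal physics and statistics on realistic forcing, not agreement
with any particular station record.

## Soil column

Each layer carries a USDA texture class; the shipped CSV table
(`src/frosthatch/data/texture_table.csv`, version 1) lists
Clapp–Hornberger-style hydraulic parameters, Rawls-style field
capacity/wilting point, and Johansen-style thermal parameters for the 11
classes.  Users can substitute their own table values.

Thermal conductivity interpolates between dry and saturated values with a
Kersten number — `log10(Sr) + 1` unfrozen, `Sr` frozen, blended by liquid
share — and the saturated conductivity is a geometric mean of solids
(2.2–6.9 W/m/K by class), water (0.57) and ice (2.2).  Volumetric heat
capacity is the volume-weighted sum of solids (2.13 MJ/m³/K), liquid water
(4.18), ice (1.9) and air.

Hydrology is a field-capacity cascade bucket: infiltration fills layers to
porosity, excess above field capacity drains downward within the step, the
bottom layer drains freely, and evaporation draws the top layer to wilting
point.  Frozen layers are hydrologically inert — they accept no
infiltration, and water reaching one backs up and then runs off.  This
replaces a Richards-equation solution; the simplification is acceptable for
winter extremes because they respond mainly to antecedent moisture (set at
field capacity initially), not to infiltration dynamics.  It is the
package's largest stated fidelity trade-off on the water side.

## Freezing: apparent heat capacity / enthalpy

Soil water freezes over a 0.5 K range below 0 °C: the unfrozen fraction
ramps linearly from 1 at 0 °C to 0 at −0.5 °C.  Each layer's volumetric
enthalpy (liquid-at-0 °C reference) is piecewise — linear above 0 °C,
quadratic inside the range (the mixed-phase heat capacity varies with the
split, and the latent term `L·ρ_w·θ` dominates), linear below — and
analytically invertible, so phase updates conserve energy and water mass
exactly and freeze/thaw cycles are reversible to round-off.  The 0.5 K
range is a numerical regularisation that keeps 60-min steps stable; it also
produces the physically expected zero-curtain plateau while a wet layer
freezes through.

## Conduction numerics

The stack solve is finite-volume with interface conductances from series
(harmonic-mean) resistances, zero flux at 250 cm, and a θ-weighted implicit
scheme (backward Euler default, Crank–Nicolson selectable for the analytic
tests).  Each step solves `H(T') − H(T) = dt·F(T')` by Newton iteration on
the enthalpy form; a step that would cross an enthalpy kink (0 or −0.5 °C)
is clamped just inside the destination piece so the next iteration
linearises with the correct slope — this prevents the classic latent-heat
overshoot oscillation and converges in a handful of iterations.  At
convergence the step conserves energy to iteration tolerance (1e-9 °C).

The skin temperature couples to the top slab implicitly: the surface energy
balance (solved by safeguarded Newton to |residual| < 0.01 W/m²) is
fixed-point iterated against the end-of-step top-slab temperature, and
enters the conduction solve as a Dirichlet condition through the half-slab
conductance.  This keeps centimetre-thin residue slabs stable and reduces
the time-splitting error enough that halving the step to 30 min moves the
annual extreme minimum by less than 0.1 °C.

A Dirichlet test mode (prescribed top/bottom temperatures) exists solely so
the analytic oracles — the series-resistance steady state and the
`exp(−z/d)` damping-depth solution — are expressible.

## Snowpack

A single bulk layer with constant density 250 kg/m³, chosen to represent a
settled seasonal pack rather than fresh snowfall (the depth/SWE ratio and
the density–conductivity relation `k = 0.021 + 2.5(ρ/1000)²` ≈ 0.18 W/m/K
both follow from it).  Snowfall mixes enthalpy into the pack at the capped
air temperature; positive energy first warms the pack to 0 °C, then melts
at 334 kJ/kg; meltwater routes to infiltration.  Fractional cover ramps
linearly to 1 at 5 cm depth; partial cover scales the pack's thermal
resistance by the covered fraction and enters the albedo as an area weight
(snow albedo 0.75 over the residue/soil mosaic).  Snow sits on top of the
residue layer.  Not modelled: densification, metamorphism, wind transport,
stubble trapping, sublimation, rain-on-snow refreezing (rain falls
through).  The single bulk layer captures what the extreme-minimum
statistic needs — depth × conductivity insulation — and the stack slot
allows a multi-layer upgrade.

## Residue layer

A prostrate slab parameterised by field-measured biophysical values
(shipped presets): maize stover 5 cm, conductivity 0.126 W/m/K, bulk
density 36.4 kg/m³, specific heat 1900 J/kg/K, albedo 0.25, cover 0.95;
miscanthus straw (scenario thickness), conductivity 0.08, bulk density
22.0, cellulose density 1350, specific heat 1335, albedo 0.32, cover 0.90.
The layer persists year-round, an additional slab above the unmodified
mineral grid (for the 5 cm no-till case this reproduces the insulating
effect of a modified top soil layer while keeping the grid fixed).
Fractional cover below 1 is handled by parallel two-column averaging:
covered and bare columns run independently under identical forcing and
their daily outputs combine by area weight — an explicit interpretation,
since how partial cover enters the conduction path is not settled.
The tabulated miscanthus porosity (0.96) is used wherever porosity is
required even though 1 − 22/1350 ≈ 0.984; both are exposed and a
consistency diagnostic is provided.  Porosity sweeps vary bulk density at
fixed cellulose density, which changes the slab's heat capacity only — its
conductivity is an independent measured input — and accordingly has a much
smaller effect than albedo, matching expectation.  Residue wetting is off
by default; decomposition and wind redistribution are out of scope.

## Surface energy balance details

Neutral bulk transfer with κ²/ln(z_ref/z0)² at z_ref = 10 m; roughness
lengths 0.005 m (soil), 0.012 / 0.0065 m (maize / miscanthus residue),
0.002 m (snow); emissivity 0.97; a 0.5 m/s wind floor stands in for free
convection.  Latent heat uses a soil-moisture β factor and is suppressed
whenever the surface is snow-covered, residue-covered or frozen, and
clamped non-negative (no dew/frost deposition mass path) — a minimal,
winter-focused treatment.  Stability corrections to the transfer
coefficients are omitted; extreme minima are driven by radiation and
conduction, and this is a documented fidelity limit.

## Scenarios, spin-up and problem sizes

Named scenarios reduce management to winter surface states (bare tilled
maize; 5 cm no-till stover; 1/2.5/5 cm miscanthus straw); crop growth,
phenology and carbon allocation are not simulated because every analysed
statistic is a wintertime extreme.  Runs start from uniform temperature at
the site annual mean, moisture at field capacity, no snow, and discard one
spin-up year — point-scale thermal equilibrium is fast, and the spin-up
length is configurable for users who want the conservative multi-year
treatment.  The shipped analyses use 30 winters on the cold-continental
preset with a 5-thickness sweep plus bare reference; these sizes give
stable 30-year statistics while keeping a full sweep around a minute of
compute.

## Statistics

- **Running mean**: centred, window 3 by default; boundary days are
  excluded rather than padded.  Smoothing is deliberately conservative —
  the smoothed minimum is never below the raw daily minimum.
- **Winter years**: Jul 1 – Jun 30 labelled by the ending year, so one cold
  season is never split; calendar-year mode is available behind a flag.
  Incomplete boundary years are dropped.
- **Exceedance**: "at or below", ties count.
- **Bias correction**: least-squares quadratic of observed on simulated,
  evaluated at simulated values; refuses extrapolation more than 2 °C
  beyond the fitted range.  Pseudo-observations (known quadratic + Gaussian
  noise) substitute for a real station network in calibration tests.
- **Trend**: OLS, slope rescaled to °C per decade, two-sided t-test at
  P < 0.05, no autocorrelation correction (an AR(1)-aware user can supply
  pre-whitened series).
- An asymmetric convention — comparing smoothed simulated extremes against
  raw daily observed extremes — is computable by passing `window=1` for the
  observed side; the package does not resolve which convention is right.

## Calendar

365-day years (no Feb 29), so every year and winter has identical length;
dates are real calendar dates with leap days skipped.  The statistics are
insensitive to one day.

## Known limitations

Beyond the items flagged above: point scale only (no spatial fields or
interpolation); no canopy radiative transfer or momentum budget; neutral
surface layer; constant snow density; the texture table is a class-mean
parameterisation, not site soil data.  Conservation is enforced and tested
— energy ledger closure within 0.5 % of cumulative surface flux over
multi-year runs (typically ~0.03 %), water budget to 1e-6 mm per step, SWE
to 1e-9 mm — but agreement with any specific land-surface model's numerics
is not claimed.
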