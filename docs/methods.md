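# Methods

## Problem and scope

An intracorporeal inhalation catheter aerosolizes a perfluorocarbon
liquid (PFD or FC75) by discharging it into a high-speed annular air
jet at the catheter tip. The quantity of clinical interest is the
aerodynamic size distribution of the droplets some tens of millimetres
downstream, where an aerodynamic particle sizer samples them. This
package models the downstream leg of that chain: given the measured
droplet population at an injection plane 2 mm from the tip, it
transports droplet parcels through a surrogate jet, applies secondary
breakup, and reduces the outlet-crossing droplets to the standard
aerosol statistics. Primary atomization (inside and just outside the
catheter), droplet coalescence and evaporation/condensation are out of
scope — the latter two deliberately, which is what makes liquid mass
conservation an exact bookkeeping check.

## Carrier flow: calibrated self-similar round jet

The continuous phase is not solved. Downstream of the tip the annular
discharge behaves as a turbulent round jet, described here by the
classical self-similar correlation:

* centerline axial velocity: constant `U0` inside a potential core of
  length `x_c` (default 2 mm), then `U0 · x_c / x`;
* radial profile: Gaussian, `u(x, r) = u_c(x) exp(-r²/2σ²)` with
  `σ = S·max(x, x_c)` and spreading rate `S = 0.075`, which matches the
  textbook half-velocity spreading `r_1/2 ≈ 0.09 x`;
* radial velocity from continuity, in closed form for the Gaussian
  profile: `v = -u_c (S/η)[1 - (1 + η²) e^{-η²/2}]`, `η = r/σ` —
  outward near the axis, entrainment inflow at large `η`. Including it
  keeps slowly moving off-axis parcels from artificially accumulating.

`U0` is the single calibrated constant: it is set so the centerline
velocity at the injection plane (x = 2 mm) equals the measured
injector-plane value, 247 m/s at 4 bar and 293 m/s at 5 bar driving
pressure. The measured peak velocities at the tip itself (391/455 m/s)
are *not* targets; the discrete phase never samples the flow upstream
of the injection plane in normal runs. Compressibility is not modelled:
the droplets need velocities, not thermodynamic state.

Turbulence quantities feed only the dispersion model: turbulent kinetic
energy from a local-intensity profile, `k = 1.5 (I·u)²` with `I = 0.10`
by default (round-jet turbulence intensities are 5–25% depending on
position; the dispersion displacement scales only as `I√τ_int`, so the
choice is not critical), and dissipation from the duct-flow closure
`ε = C_µ^{1/2} k^{3/2} / l_ε`, `l_ε = 0.07 L`, `C_µ = 0.09`. The
annulus width `L` defaults to 1e-4 m; the catheter lumen geometry is
not publicly specified, so `L`, the injection-line length (1e-4 m) and
the core length are configuration parameters.

Gas properties default to air at 20 °C (ρ = 1.204 kg/m³,
µ = 1.81e-5 Pa·s).

## Discrete phase

Each parcel carries `n` identical droplets (position, velocity,
diameter, TAB distortion state). Forces: drag only, with the
Schiller–Naumann coefficient `C_D = 24/Re (1 + 0.15 Re^0.687)` up to
Re = 1000 and 0.44 beyond. Virtual mass, Basset history and
pressure-gradient forces are negligible at liquid/gas density ratios of
~1500; gravity is insignificant against the jet's velocity gradients
and is available only behind a flag for testing. Force routines work
with the product `C_D·Re` so the Stokes limit is finite.

**Integration.** Over a substep the local gas velocity and the
linearized drag response time `τ* = τ_p / (1 + 0.15 Re^0.687)`
(`τ_p = ρ_l D_p²/18µ`) are frozen and the update is exact:
`v → u + (v-u)e^{-h/τ*}`, with the matching exact position integral.
This is unconditionally stable for micrometre droplets (τ_p down to
~1e-7 s) at any step. The binding accuracy constraint is therefore not
drag stiffness but resolving the 1/x jet decay, so the global step
(1e-4 s) is divided into displacement-limited substeps such that no
parcel moves more than ~2 mm per substep (about 13 substeps while
parcels move at injection speed).

**Turbulent dispersion.** Discrete-random-walk eddy interaction: each
parcel sees a fluctuation velocity drawn per-component from
N(0, 2k/3), for an interaction time `min(τ_e, τ_cross)` with eddy
lifetime `τ_e = l_ε/u'`, `u' = (2k/3)^{1/2}`, and crossing time
`-τ* ln(1 - l_ε/(τ*|v_rel|))` (capture → lifetime). Because `l_ε` is
tiny here (7e-6 m), eddy lifetimes (~1e-7 s) are far below the substep;
applying one sampled eddy per substep would overstate dispersion by
`√(h/τ_int)`. The applied fluctuation is therefore scaled by
`min(1, √(τ_int/h))`, the standard diffusion-limit correction that
preserves the random-walk displacement variance `u'² τ_int t`.

**Coupling.** One-way. The original study used two-way momentum
coupling, but a prescribed analytic field cannot receive momentum
sources; the solver instead accumulates the axial momentum the parcels
exchange with the gas as a diagnostic, reported with every mass-balance
report, so the size of the neglected back-reaction can be judged
against the jet momentum flux for any given run.

**Boundaries.** Parcels are emitted at x = 2 mm, uniformly along the
injection line in radius with random azimuth (3-D Cartesian state with
axisymmetric field lookup avoids axis singularities), at the local gas
velocity. Crossing x = domain length (60 mm for PFD, 52 mm for FC75 —
the experimental sampling distances) records an outlet event (time,
diameter, droplet count, mass, radius); x < 0 and r > r_max record
losses. Emission is exactly mass-balanced each step: parcels are
allocated to injectors proportionally to mass flow by largest-remainder
rounding (each active injector gets at least one parcel), and droplet
counts are chosen so the emitted mass equals `ṁ·dt` identically.

## TAB secondary breakup

Distortion dynamics in the normalized displacement `y`:

    ÿ = (C_F/C_b)·ρ_g u²/(ρ_l r²) − (C_k σ/ρ_l r³)·y − (C_d µ_l/ρ_l r²)·ẏ

with the canonical constants C_F = 1/3, C_b = 0.5, C_k = 8, C_d = 5
(the original study names the model but not its constants; these are
the values its cited formulation defines and commercial codes use).
The update over a substep is the exact solution of the forced damped
oscillator — trigonometric when underdamped, a numerically stable
two-exponential form when overdamped (sub-micron droplets), and the
critically damped limit in between. Breakup triggers at y > 1.

On breakup the child Sauter mean diameter follows the TAB
surface-plus-oscillation energy balance with K = 10/3:

    d_parent/d32 = 1 + 8K y²/20 + ρ_l r³ ẏ²/σ · (6K−5)/120

Child diameters are drawn from a Rosin–Rammler mass distribution
(exponent q = 3.5, configurable; the distribution family is prescribed,
its spread is not) with scale set by `d32 = X/Γ(1−1/q)`, truncated at
the parent diameter. The child count is the parent/child mass ratio
clipped to [2, 10] (bounded parcel growth); each child parcel receives
an equal mass share and a droplet count computed from its own sampled
diameter, so child mass equals parent mass to machine precision.
Children inherit the parent velocity and start undistorted.

Surface tension and liquid viscosity for PFD (0.019 N/m, 5.1 mPa·s)
and FC75 (0.015 N/m, 1.4 mPa·s) are externally sourced datasheet-style
values, not derived from any measurement modelled here; both are plain
configuration values.

## Aerosol statistics

* `Dg = Da √(ρ₀/ρ)` with ρ₀ = 1 g/cm³ (and its inverse).
* Cumulative mass distribution Y_dg: normalized cumulative histogram
  over log-spaced bins, interpolated linearly in log-diameter.
* MMAD: the 50% crossing of Y_dg (log-linear within the crossing bin);
  for unbinned particle sets, a mass-weighted quantile with the
  midpoint convention (the upper-edge convention biases the median low
  by up to one bin width).
* GSD: `√(d_84.1/d_15.9)` on mass-weighted quantiles — robust for
  binned data, instrument-convention, and equal to `exp(sd(ln d))` for
  lognormal inputs (verified in tests). Heterodisperse above 1.25.
* Aerosolization rate: `(m_before − m_after)/(t_pulse · ρ)` in mL/min.
* Four-event classification: <0.5 µm / 0.5–20 µm / coincident / >20 µm,
  coincidence taking precedence; coincidence is an input flag, not an
  optical model.

## Grid-convergence verification

Observed order `p = ln((v3−v2)/(v2−v1))/ln r`, Richardson extrapolation
`v1 + (v1−v2)/(r^p−1)`, and `GCI = Fs|Δv|/|v_ref|/(r^p−1)·100` with
Fs = 1.25. Two conventions deserve note, both following the source
study's own arithmetic: the refinement ratio is taken as r = 2 (the
order formula divides by ln 2 even though the cell counts imply a
slightly different per-dimension ratio), and each GCI is normalized by
the **coarser** solution of its pair — this reproduces the reported
GCI23 = 3.65 exactly, where fine-normalization gives 3.46. A
consequence worth knowing: on exactly p-th-order data the
asymptotic-range ratio `GCI23/(r^p GCI12)` equals `v2/v3` identically,
and approaches 1 only as the grid-to-grid change becomes small relative
to the solution — which is precisely the asymptotic range the check is
meant to detect.

## Synthetic data

Heterodisperse aerosols are generated as mass-weighted lognormals
(MMAD, GSD are the lognormal's sufficient parameters): diameters drawn
number-weighted via the Hatch–Choate relation
`CMD = MMAD·exp(−3 ln²σ_g)` and weighted by d³ for mass statistics,
then classified into the four events and binned into 52 log-uniform
intervals over 0.5–20 µm (the instrument's true bin edges are
proprietary). Note that truncation to the measuring range shifts the
in-range statistics: for MMAD 7.2 µm / GSD 1.9, 5.6% of the mass lies
above 20 µm and the in-range MMAD is analytically 6.88 µm — tests
compare against the truncated closed form. Generators are pure
functions of (spec, seed).

What the synthetic samples do **not** emulate: time-of-flight signal
processing, concentration-dependent coincidence physics (coincidence is
a Bernoulli flag), sampling bias of the inlet flow, and any departure
of real sprays from lognormality. Passing recovery tests therefore
demonstrates the correctness of the statistics and rebinning machinery,
not instrument fidelity.

## Study conditions and problem sizes

Default runs use the measured injector tables, dt = 1e-4 s, 500 parcels
per step, 0.06 s of physical time with the final 0.01 s analyzed (the
aerosol cone is developed well before that). The packaged acceptance
checks use scaled runs — 0.02 s of physical time, which is several
times the ~4 ms parcel residence time, so the outlet flux is
statistically steady over the final 0.01 s window; the parcel-count
study spans 100/500/1000 parcels per step over six seeds. These sizes
are the package's chosen desk-scale study conditions.

## Numerical choices and edge cases

* All randomness flows from one `numpy` PCG64 generator per run; equal
  seeds give byte-identical outputs.
* Degenerate inputs fail loudly: non-positive lengths/steps, unknown
  compound/pressure cases (with the valid options listed), zero-mass
  distributions, oscillatory or converged mesh triples.
* Monodisperse limits are exact (GSD = 1, MMAD = the common diameter).
* The drag correlation's two branches meet within ~0.3% at Re = 1000;
  parcels here rarely exceed Re ≈ 300.

## Known limitations

* The carrier field is a calibrated correlation, not a flow solution:
  no nozzle flow, no compressibility, no wake of the catheter body.
  Downstream velocity profiles are plausible but not validated.
* One-way coupling (see diagnostic above).
* Breakup child velocities inherit the parent's (no transverse kick);
  child count capping coarsens the child-size statistics per event.
* With the surrogate field, PFD at 4 bar stays below the TAB breakup
  threshold (maximum We ≈ 29); the other three scenarios do break up.
  All four remain well inside the We < 100 validity regime.
* Aerosol statistics at the outlet describe the simulated population;
  agreement of their *machinery* with closed forms is tested, but the
  simulated size distributions themselves depend on the surrogate-field
  and TAB-constant choices.
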