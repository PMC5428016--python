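# Methods

`mstdesign` models the three physical constraints that decide whether a
microfluidic sample trap (MST) — a well or recess adjacent to a channel
that holds one submicroliter 3D tissue — can trap, sustain and release
its sample without biasing viability. This note records the models, their
assumptions, the numerical choices, and what the package deliberately
does not model.

## Tissue, trap and medium

The tissue is an equivalent sphere: diameter `d`, mass density `rho_T`
(default 1020 kg/m³, a typical spheroid), cellular density `rho_cell`
(default 2.8e5 cells/µL). The trap is a square-section well of width `w`
and depth `h` next to a channel of cross-section `A` and inter-trap
separation `L`; the medium volume available to one trap is `V_M` (≈ `A·L`
when traps are far apart). The medium is aqueous (`rho_M` = 1000 kg/m³,
`eta` = 1e-3 Pa·s) and the trapping force is a generic volume force
`(rho_T − rho_M) V_T g_eff`; `g_eff` defaults to gravity (9.81 m/s²) but
any body force (e.g. dielectrophoretic) can be expressed through it.

Internally everything is SI with concentrations in mol/m³ (numerically
mM) — the formulas in this domain invite unit errors, so conversion
happens once, at the configuration boundary (`units.py`).

## Sedimentation trapping

A sphere settling along the axis of a reservoir of comparable width feels
enhanced drag. We use the classical wall-corrected result: the confined
velocity is the Stokes velocity `(1/18)(Δρ/η) g_eff d²` divided by the
rational drag factor

    K(λ) = (1 − 0.76 λ⁵) / (1 − 2.1 λ + 2.1 λ³ − 1.7 λ⁵ + 0.73 λ⁶),

λ = d/w. Settling time is `h / v_set`, an upper bound on trapping time
(bottom-wall retardation is neglected). The fit is accepted for λ < 0.9
(hard error beyond); note it loses monotonicity at λ ≈ 0.83, an artifact
of the rational approximation near its edge — physically relevant
confinements sit well below that, and the monotonicity property is
asserted on [0, 0.8].

Settling time scales as `K(λ)/λ²` at fixed `w = h`, so the minimizing
confinement is a pure property of `K`: a grid scan plus bounded local
refinement gives λ* ≈ 0.431, inside the practical 0.3–0.7 window. It is
independent of trap size, density contrast and viscosity.

## Operating windows

Two critical channel flow rates bracket safe operation of a trapped,
non-adherent tissue (cubic trap, d/w = 0.5; a warning is logged when the
formulas are applied outside that fitted regime):

    Q_shear = tau_max w³ / (9.6 η)           (damaging shear reached)
    Q_lift  = √d · w² · √((4/3) g_eff (rho_T/rho_M − 1))   (ejection)

`tau_max` defaults to 1 Pa, a conservative physiological damage
threshold. The 9.6 prefactor is an empirical constant from 3D flow
simulations of this geometry and is used as given. Since `Q_shear ∝ w³`
falls faster than `Q_lift ∝ w^2.5` under downscaling, the curves cross at

    w_min = (2/3)(9.6)² g_eff η² (rho_T/rho_M − 1) / tau_max²,

below which flow damages tissues before ejecting them. We use the exact
crossing prefactor 61.44 (often quoted rounded to 61) so that
`Q_shear(w_min) = Q_lift(w_min)` holds to machine precision; at the
default parameters w_min ≈ 12 µm. Regime classification is conservative
at boundaries: a flow exactly at `Q_shear` counts as damaging.

## Nutrient supply

Uptake follows Michaelis–Menten kinetics, `q(c) = q_max c/(c + k_M)` per
cell; the metabolic threshold is `c = k_M`, where uptake has halved.
Literature parameters for a fully characterized line (EMT6/Ro-like) ship
as min/typical/max presets; glucose diffusivities are not part of that
table, so standard aqueous/tissue literature values (6.7e-6 and
1.1e-6 cm²/s) are the defaults, user-overridable. Glucose carries no
phase partition (c_sat = c0 on both sides); oxygen partitions with
c_sat,T/c_sat,M = 1.02/0.21.

**Anoxia limit (continuous supply).** For oxygen supplied through
gas-permeable walls, a worst-case series-resistance balance of zero-order
consumption against diffusion in tissue and medium gives

    d_max = 2 √( 3/(q_max ρ_cell) · [1/(2 D_T c_sat,T) + 1/(D_M c_sat,M)]⁻¹ ),

≈ 511 µm at typical parameters. A `glass_bottom`-style device (bonded to
an impermeable slide) roughly halves available oxygen; that 3D conjugate
problem is out of scope here and the package only surfaces the analytic
criterion and the qualitative warning.

**Finite-nutrient depletion.** Glucose is only replenished by medium
change. The 3D trap + channel geometry is reduced to a volume-matched
concentric sphere-in-shell: tissue (radius d/2, diffusivity D_T, MM sink)
centred in a medium shell of volume `V_M` (D_M, no sink), closed outer
boundary, everything initialized at `c0`. The reduction is justified in
the regime the design rules target — when the channel is short enough
that transport is not diffusion-limited, shape barely matters, and the
Damköhler check below guards the approximation. The paper-level periodic
inlet/outlet condition (neighbouring traps) maps to the same zero-net-
exchange contract as the closed shell.

Numerics: conservative finite-volume method of lines in the normalized
concentration `u = c/c_sat` (so interface continuity of `c/c_sat` is
continuity of the state, and flux continuity follows from the
distance-weighted harmonic transmissibility `κ = D·c_sat`). Default grid:
80 uniform cells in the tissue, 120 quadratically stretched cells in the
shell (fine at the interface; a run errors below 4 cells per region).
Stiff BDF integration with a tridiagonal sparsity pattern plus one
cumulative-uptake state; `rtol` 1e-6. The stop condition — centre
concentration hits `k_M` (the centre is the minimum in this geometry) —
is located by the integrator's event root-finding. Mass balance
(inventory + integrated uptake vs. initial inventory) drifts by ~1e-14
at defaults, asserted < 1e-3; doubling the grid moves the threshold time
by < 0.5%.

**Replenishment law.** Outside the diffusion-limited regime the threshold
time is linear in the volume ratio:

    t = a · (c0/(q_max ρ_cell)) · (V_M/V_T) + b.

`sweep_and_fit_replenishment` runs the solver over V_M/V_T ∈ [10, 1000]
(12 log-spaced points by default, matching the ratio range spanned by
published devices) on a reference 375 µm tissue and fits (a, b) by least
squares; points with shell Damköhler number ≥ 1 are excluded with a
warning. At defaults a ≈ 0.96, b ≈ 0.35 h, r² > 0.9999. The slope is
below 1 because the tissue core reaches `k_M` while the mean pool is
still above it (quasi-steady gradients of order `qρR²/6D_T` in the tissue
and `qρR²/3D_M` across the shell). `V_M = 100 V_T` sustains a 375 µm
tissue for ≈ 27 h — the basis of the "100× volume for a day" rule.

**Channel-length limit.** The linear law requires diffusion along the
channel to outrun total uptake: `Da₀ = (L²/8D_M)/(c0 (V_M/V_T)/(q_max
ρ_cell)) < 1`, i.e. `L < L_max = √(8 c0 D_M (V_M/V_T)/(q_max ρ_cell))`
(≈ 4.45 mm for oxygen parameters at ratio 100). Inside the reduced
sphere-in-shell sweep, where no channel exists, the shell thickness
stands in as the diffusion length; at every default sweep point Da₀ ≪ 1,
so the check is a guard, not an active constraint.

## Design rules and literature validation

`recommend_design` applies the near-optimal rule of thumb — `w = 2d`,
`h = 0.9w`, `V_M = 100 V_T` (raised when a longer replenishment schedule
is requested through the fitted law) — and warns when `d > d_max`
(anoxia) or `w < w_min` (not ejectable by flow). `check_design` audits
arbitrary pairings against the established ranges: settling
`1.2d < w < 6.7d`, safe ejection `1.1d < w < 3.3d`, aspect ratio
`0.6w < h < 1.1w`, a practical 30 µm minimum width, and the V_M rule.
These ranges derive from large 3D flow-simulation sweeps and are encoded
as constants; the analytically computable rules are recomputed live. The
`w ≤ 1.4d` single-sample bound is informational (a wider trap is valid,
it just admits multiple samples).

The packaged survey of 13 published trap devices (14 rows; one
publication contributes two tissue sizes) records each device's sample
diameter, V_M/V_T and experimental replenishment interval. Devices are
classified against the fitted law as perfused / replenished within the
model time / within 20% above it (brief dips below `k_M`) / under-
replenished. With the default fit the tallies match the survey: 5
perfused and exactly one under-replenished device (the 600 µm spheroid at
ratio 52, whose 24 h schedule is roughly twice the modelled ~14 h).
Inverting the law at that device's fixed medium volume gives a maximum
spheroid of ≈ 503 µm for a 24 h schedule. One caveat: the fit is made on
the 375 µm reference tissue, while surveyed samples range from 16 µm
cells to 600 µm spheroids; the intercept and core-gradient corrections
are size-dependent at the few-percent level, which is part of why
modelled times for the smallest devices are approximate.

## Limitations

- No Navier–Stokes solving: recirculation structure, aspect-ratio and
  size-variance windows come in as rule constants, not recomputed fields.
- The 9.6 shear prefactor and the rule ranges inherit the uncertainty of
  the simulations they were fitted to; `Q_lift` assumes a fully
  non-adherent sample (adhesion raises the real ejection flow).
- The depletion model is spherically symmetric: it cannot place the
  concentration minimum off-centre (in a real trap the side far from the
  channel is poorest) and does not model oxygen through device walls.
- Thresholding at `k_M` is deliberately conservative; real cultures
  tolerate longer intervals before viability is affected.
- No proliferation or death kinetics: a growing tissue shrinks its own
  V_M/V_T, so schedules should be re-evaluated at the largest expected
  size.
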