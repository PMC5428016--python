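"""Nutrient supply models: Michaelis-Menten uptake, the anoxia diameter
limit, finite-nutrient depletion times, the linear replenishment law and
the Damköhler channel-length limit.

The tissue consumes a nutrient with saturating Michaelis-Menten kinetics

    q(c) = q_max * c / (c + k_M)          [mol/(cell s)]

and the working threshold for "metabolism affected" is the instant the
minimum concentration anywhere in the tissue falls to k_M, where uptake
has dropped to half its maximum.  Two supply situations are modelled:

* Continuously replenished nutrients (oxygen through gas-permeable device
  walls): a steady diffusion-reaction balance yields the maximum tissue
  diameter ``max_viable_diameter`` whose core escapes anoxia.
* Finite nutrients (glucose in a sealed channel): a tissue sphere of
  volume V_T centred in a closed medium shell of volume V_M is depleted
  from a uniform initial concentration c0.  ``depletion_time_pde`` solves
  the spherically symmetric diffusion-reaction problem with a conservative
  finite-volume discretization; ``depletion_time_well_mixed`` is the
  lumped (fast-diffusion) limit with an exact implicit solution.

Outside the diffusion-limited regime the depletion time grows linearly in
the medium-to-tissue volume ratio,

    t = a * (c0 / (q_max rho_cell)) * (V_M / V_T) + b,

and ``sweep_and_fit_replenishment`` recovers the lumped constants (a, b)
from a sweep of full solver runs.  The regime boundary itself is a
zero-order Damköhler number Da0 = t_diff / t_up, giving the maximum
channel length ``max_channel_length`` for which the linear law holds.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.integrate import solve_ivp

from .params import MetaboliteParams, TissueSample, tissue_volume

__all__ = [
    "DepletionResult",
    "ReplenishmentFit",
    "DepletionWarning",
    "mm_uptake_rate",
    "max_viable_diameter",
    "zero_order_depletion_time",
    "depletion_time_well_mixed",
    "depletion_time_pde",
    "sweep_and_fit_replenishment",
    "replenishment_time",
    "damkohler_number",
    "max_channel_length",
]


class DepletionWarning(UserWarning):
    """Degenerate or regime-violating depletion setup."""


def mm_uptake_rate(c: float | np.ndarray, metabolite: MetaboliteParams,
                   rho_cell: float) -> float | np.ndarray:
    """Volumetric Michaelis-Menten sink q_max rho_cell c/(c + k_M).

    ``c`` in mol/m^3, ``rho_cell`` in cells/m^3; result in mol/(m^3 s).
    Monotone in c and bounded by the zero-order rate q_max rho_cell.
    """
    c_arr = np.asarray(c, dtype=float)
    if np.any(c_arr < 0):
        raise ValueError("concentration must be non-negative")
    out = metabolite.q_max * rho_cell * c_arr / (c_arr + metabolite.k_M)
    return float(out) if np.isscalar(c) or c_arr.ndim == 0 else out


def max_viable_diameter(oxygen: MetaboliteParams, rho_cell: float) -> float:
    """Largest tissue diameter whose core avoids anoxia, m.

    Steady zero-order consumption balanced against diffusion through the
    tissue (conductivity D_T c_sat_T) in series with the surrounding
    medium (D_M c_sat_M):

        d_max = 2 sqrt( 3/(q_max rho_cell) *
                        [ 1/(2 D_T c_sat_T) + 1/(D_M c_sat_M) ]^-1 )
    """
    if rho_cell <= 0:
        raise ValueError("cell density must be positive")
    series_resistance = (
        1.0 / (2.0 * oxygen.D_T * oxygen.c_sat_T)
        + 1.0 / (oxygen.D_M * oxygen.c_sat_M)
    )
    return 2.0 * math.sqrt(
        3.0 / (oxygen.q_max * rho_cell) / series_resistance
    )


@dataclass(frozen=True)
class DepletionResult:
    """Outcome of one finite-nutrient depletion run.

    ``t_threshold`` is the time (s) at which the minimum tissue
    concentration first reaches k_M.  For spatially resolved runs,
    ``radii``/``c_profile`` hold the radial concentration snapshot at the
    threshold instant and ``min_location`` the radius of its minimum
    (centre, for the concentric geometry).  ``mass_balance_error`` is the
    relative drift of (dissolved inventory + integrated uptake) from the
    initial inventory.
    """

    t_threshold: float
    radii: np.ndarray | None = None
    c_profile: np.ndarray | None = None
    min_location: float | None = None
    mass_balance_error: float = 0.0


def zero_order_depletion_time(tissue: TissueSample, V_M: float,
                              metabolite: MetaboliteParams) -> float:
    """Pool-exhaustion time c0 (V_M + V_T) / (q_max rho_cell V_T), s.

    The whole dissolved inventory consumed at the zero-order rate; the
    natural timescale of the depletion problem.
    """
    if V_M < 0:
        raise ValueError("medium volume must be non-negative")
    V_T = tissue.V_T
    return (
        metabolite.c0 * (V_M + V_T)
        / (metabolite.q_max * tissue.rho_cell * V_T)
    )


def depletion_time_well_mixed(tissue: TissueSample, V_M: float,
                              metabolite: MetaboliteParams) -> DepletionResult:
    """Depletion time in the fast-diffusion (uniform-pool) limit.

    The shared pool of volume V_M + V_T obeys

        dc/dt = -(V_T/(V_M + V_T)) q_max rho_cell c/(c + k_M),

    whose implicit solution gives the time to reach c = k_M in closed
    form:  t = [(c0 - k_M) + k_M ln(c0/k_M)] / A  with
    A = q_max rho_cell V_T/(V_M + V_T).  Exceeds the zero-order pool time
    only by the O(k_M ln(c0/k_M)/c0) Michaelis-Menten tail.
    """
    c0, k_M = metabolite.c0, metabolite.k_M
    if c0 <= k_M:
        warnings.warn(
            "c0 <= k_M: metabolism is limited from the start (t = 0)",
            DepletionWarning, stacklevel=2,
        )
        return DepletionResult(t_threshold=0.0)
    V_T = tissue.V_T
    A = metabolite.q_max * tissue.rho_cell * V_T / (V_M + V_T)
    t = ((c0 - k_M) + k_M * math.log(c0 / k_M)) / A
    return DepletionResult(t_threshold=t, min_location=0.0)


def _shell_outer_radius(R_T: float, V_M: float) -> float:
    """Outer radius of a concentric medium shell of volume V_M."""
    return (R_T**3 + 3.0 * V_M / (4.0 * math.pi)) ** (1.0 / 3.0)


def _build_grid(R_T: float, R_out: float, n_tissue: int, n_medium: int):
    """Cell faces for the composite sphere: uniform in the tissue,
    quadratically stretched in the shell (fine at the interface)."""
    tissue_faces = np.linspace(0.0, R_T, n_tissue + 1)
    s = np.linspace(0.0, 1.0, n_medium + 1)
    medium_faces = R_T + (R_out - R_T) * s**2
    return np.concatenate([tissue_faces, medium_faces[1:]])


def depletion_time_pde(
    tissue: TissueSample,
    V_M: float,
    metabolite: MetaboliteParams,
    n_tissue: int = 80,
    n_medium: int = 120,
    rtol: float = 1e-6,
) -> DepletionResult:
    """Finite-nutrient depletion of a tissue sphere in a closed medium shell.

    Spherically symmetric diffusion-reaction: the tissue (radius d/2,
    diffusivity D_T, Michaelis-Menten sink) sits at the centre of a
    medium shell of volume V_M (diffusivity D_M, no sink); no flux through
    the outer boundary; the interface carries continuity of c/c_sat and of
    diffusive flux; everything starts at the reservoir concentration c0.

    Discretized with a conservative finite-volume method of lines in the
    normalized concentration u = c/c_sat (so the interface continuity
    condition is just continuity of the state) and integrated with a
    stiff BDF scheme.  Integration stops when the centre concentration —
    the tissue minimum in this geometry — reaches k_M; the crossing time
    is located by the integrator's event root-finding.
    """
    if V_M <= 0:
        raise ValueError("medium volume must be positive")
    if n_tissue < 4 or n_medium < 4:
        raise ValueError(
            "grid too coarse: need at least 4 cells in each region "
            f"(got n_tissue={n_tissue}, n_medium={n_medium})"
        )
    c0, k_M = metabolite.c0, metabolite.k_M
    if c0 <= k_M:
        warnings.warn(
            "c0 <= k_M: metabolism is limited from the start (t = 0)",
            DepletionWarning, stacklevel=2,
        )
        return DepletionResult(t_threshold=0.0)

    R_T = tissue.d / 2.0
    R_out = _shell_outer_radius(R_T, V_M)
    faces = _build_grid(R_T, R_out, n_tissue, n_medium)
    centers = 0.5 * (faces[:-1] + faces[1:])
    volumes = 4.0 * math.pi / 3.0 * (faces[1:] ** 3 - faces[:-1] ** 3)
    n = centers.size
    in_tissue = np.arange(n) < n_tissue

    # interface conductivity kappa = D * c_sat; flux = -kappa * A * du/dr
    c_sat = np.where(in_tissue, metabolite.c_sat_T, metabolite.c_sat_M)
    kappa = np.where(in_tissue, metabolite.D_T * metabolite.c_sat_T,
                     metabolite.D_M * metabolite.c_sat_M)

    # distance-weighted harmonic transmissibility at each interior face
    r_f = faces[1:-1]
    area = 4.0 * math.pi * r_f**2
    dl = r_f - centers[:-1]
    dr = centers[1:] - r_f
    trans = area / (dl / kappa[:-1] + dr / kappa[1:])

    q_vol = metabolite.q_max * tissue.rho_cell  # zero-order volumetric rate
    cap = c_sat * volumes                        # moles per unit u, per cell
    sink_cap = np.where(in_tissue, volumes, 0.0)

    def rhs(_t: float, y: np.ndarray) -> np.ndarray:
        u = y[:-1]
        flux = trans * (u[:-1] - u[1:])          # moles/s, from cell i to i+1
        c = u * c_sat
        s = q_vol * c / (c + k_M)                # volumetric sink, tissue only
        dy = np.empty_like(y)
        net = np.zeros(n)
        net[:-1] -= flux
        net[1:] += flux
        uptake = s * sink_cap
        dy[:-1] = (net - uptake) / cap
        dy[-1] = uptake.sum()
        return dy

    # tridiagonal coupling for u plus the cumulative-uptake row
    pattern = sparse.lil_matrix((n + 1, n + 1), dtype=np.int8)
    idx = np.arange(n)
    pattern[idx, idx] = 1
    pattern[idx[:-1], idx[:-1] + 1] = 1
    pattern[idx[1:], idx[1:] - 1] = 1
    pattern[n, : n] = 1

    u0 = np.where(in_tissue, c0 / metabolite.c_sat_T, c0 / metabolite.c_sat_M)
    y0 = np.append(u0, 0.0)
    M0 = float((u0 * cap).sum())

    def centre_at_threshold(_t: float, y: np.ndarray) -> float:
        return y[0] * metabolite.c_sat_T - k_M

    centre_at_threshold.terminal = True
    centre_at_threshold.direction = -1

    t_scale = zero_order_depletion_time(tissue, V_M, metabolite)
    t_diff = R_out**2 / min(metabolite.D_M, metabolite.D_T)
    t_max = 5.0 * t_scale + 10.0 * t_diff

    sol = solve_ivp(
        rhs, (0.0, t_max), y0,
        method="BDF",
        events=centre_at_threshold,
        jac_sparsity=pattern.tocsr(),
        rtol=rtol,
        atol=rtol * 1e-2 * max(c0 / metabolite.c_sat_T, 1.0),
    )
    if not sol.success:
        raise RuntimeError(f"depletion solver failed: {sol.message}")
    if not sol.t_events[0].size:
        raise RuntimeError(
            "centre concentration never reached k_M within "
            f"{t_max:.3g} s; check the parameter regime"
        )

    t_hit = float(sol.t_events[0][0])
    y_hit = sol.y_events[0][0]
    u_hit = y_hit[:-1]
    c_hit = u_hit * c_sat
    inventory = float((u_hit * cap).sum())
    balance_err = abs(inventory + float(y_hit[-1]) - M0) / M0
    i_min = int(np.argmin(c_hit[in_tissue]))
    return DepletionResult(
        t_threshold=t_hit,
        radii=centers.copy(),
        c_profile=c_hit,
        min_location=float(centers[i_min]) if i_min else 0.0,
        mass_balance_error=balance_err,
    )


@dataclass(frozen=True)
class ReplenishmentFit:
    """Fitted linear replenishment law t = a * tau0 * (V_M/V_T) + b.

    ``tau0 = c0/(q_max rho_cell)`` is the single-volume zero-order
    depletion timescale of the metabolite; ``a`` and ``b`` lump the
    geometry effects (a < 1 because the tissue core crosses k_M before the
    mean pool does).  ``sweep`` holds the (ratio, t_threshold [s]) pairs
    the law was fitted to.
    """

    a: float
    b: float
    r_squared: float
    tau0: float
    metabolite: str = "glucose"
    sweep: tuple[tuple[float, float], ...] = field(default_factory=tuple)

    def predict(self, ratio: float) -> float:
        """Replenishment interval (s) at a given V_M/V_T ratio."""
        if ratio < 0:
            raise ValueError("volume ratio must be non-negative")
        return self.a * self.tau0 * ratio + self.b

    def ratio_for_time(self, t: float) -> float:
        """Invert the law: V_M/V_T needed for a replenishment interval t (s)."""
        if t <= self.b:
            raise ValueError(
                f"schedule {t:.3g} s is below the fitted intercept "
                f"{self.b:.3g} s: no feasible volume ratio"
            )
        return (t - self.b) / (self.a * self.tau0)


def sweep_and_fit_replenishment(
    tissue: TissueSample,
    metabolite: MetaboliteParams,
    ratios: np.ndarray | None = None,
    n_tissue: int = 80,
    n_medium: int = 120,
) -> ReplenishmentFit:
    """Fit the linear replenishment law to full depletion-solver runs.

    Sweeps V_M/V_T over ``ratios`` (default: 12 log-spaced points in
    [10, 1000]), solves the sphere-in-shell depletion problem at each, and
    least-squares fits t = a tau0 ratio + b.  Points in the
    diffusion-limited regime (shell Damköhler number >= 1) are excluded
    with a warning — the linear law does not apply there.
    """
    if ratios is None:
        ratios = np.geomspace(10.0, 1000.0, 12)
    ratios = np.asarray(ratios, dtype=float)
    if ratios.size < 3:
        raise ValueError("need at least 3 sweep points to fit the law")

    tau0 = metabolite.c0 / (metabolite.q_max * tissue.rho_cell)
    R_T = tissue.d / 2.0
    kept: list[tuple[float, float]] = []
    for ratio in ratios:
        V_M = ratio * tissue.V_T
        # shell-thickness Damköhler check against the uptake time
        L_eff = _shell_outer_radius(R_T, V_M) - R_T
        da = (L_eff**2 / (8.0 * metabolite.D_M)) / (tau0 * ratio)
        if da >= 1.0:
            warnings.warn(
                f"V_M/V_T = {ratio:.3g} is diffusion-limited (Da0 = "
                f"{da:.2f}); excluded from the linear fit",
                DepletionWarning, stacklevel=2,
            )
            continue
        res = depletion_time_pde(tissue, V_M, metabolite,
                                 n_tissue=n_tissue, n_medium=n_medium)
        kept.append((float(ratio), res.t_threshold))
    if len(kept) < 3:
        raise RuntimeError("fewer than 3 sweep points outside the "
                           "diffusion-limited regime; cannot fit")

    x = np.array([tau0 * r for r, _ in kept])
    y = np.array([t for _, t in kept])
    a, b = np.polyfit(x, y, 1)
    resid = y - (a * x + b)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot
    return ReplenishmentFit(
        a=float(a), b=float(b), r_squared=r2, tau0=tau0,
        metabolite=metabolite.name, sweep=tuple(kept),
    )


def replenishment_time(fit: ReplenishmentFit, ratio: float,
                       metabolite: MetaboliteParams | None = None) -> float:
    """Conservative replenishment interval t_rep (s) at a volume ratio.

    Evaluates the fitted linear law.  When a ``metabolite`` is passed it
    must be the nutrient the law was fitted for; the check guards against
    mixing an oxygen fit into a glucose schedule.
    """
    if ratio < 0:
        raise ValueError("volume ratio must be non-negative")
    if metabolite is not None and metabolite.name != fit.metabolite:
        raise ValueError(
            f"fit was made for {fit.metabolite!r}, not {metabolite.name!r}"
        )
    return fit.predict(ratio)


def damkohler_number(L: float, metabolite: MetaboliteParams, ratio: float,
                     rho_cell: float = 2.8e14) -> float:
    """Zero-order Damköhler number Da0 = t_diff / t_up for a channel.

    t_diff = L^2/(8 D_M) is the diffusion time along the half-channel and
    t_up = c0 (V_M/V_T) / (q_max rho_cell) the total uptake time.  The
    linear replenishment law requires Da0 < 1 (not diffusion-limited).
    """
    if L <= 0 or ratio <= 0:
        raise ValueError("channel length and volume ratio must be positive")
    t_diff = L**2 / (8.0 * metabolite.D_M)
    t_up = metabolite.c0 * ratio / (metabolite.q_max * rho_cell)
    return t_diff / t_up


def max_channel_length(metabolite: MetaboliteParams, ratio: float,
                       rho_cell: float = 2.8e14) -> float:
    """Longest inter-trap channel keeping Da0 < 1, m.

    L_max = sqrt(8 c0 D_M (V_M/V_T) / (q_max rho_cell)); beyond it the
    channel medium cannot diffuse to the tissue fast enough and the linear
    replenishment law breaks down.
    """
    if ratio <= 0:
        raise ValueError("volume ratio must be positive")
    return math.sqrt(
        8.0 * metabolite.c0 * metabolite.D_M * ratio
        / (metabolite.q_max * rho_cell)
    )
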