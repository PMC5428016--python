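"""Design rules, density-sensitivity summaries and literature validation.

This module sits on top of the two physics modules and turns them into
actionable device-design advice:

* ``recommend_design`` applies the rule-of-thumb optimum — a near-cubic
  trap of side twice the tissue diameter with 100x the tissue volume of
  medium per trap — and annotates it with the physical warnings (anoxia
  above the viable diameter, non-ejectable below the minimum trap width).
* ``check_design`` audits an arbitrary tissue/trap pairing against the
  established dimension ranges for settling, safe ejection, aspect ratio,
  single-sample trapping and medium provisioning.
* ``density_sensitivity_table`` summarizes how settling time, minimum
  trap width and the critical flows move with tissue mass density.
* ``evaluate_literature_device`` and the packaged survey of thirteen
  published trap devices compare each publication's replenishment
  schedule against the fitted depletion law.

The dimension ranges (e.g. 1.1 d < w < 3.3 d for safe ejection,
0.6 w < h < 1.1 w for the aspect ratio, the 30 um practical minimum
width) originate from large 3D flow-simulation sweeps and are encoded
here as constants; the analytically computable rules (settling optimum,
minimum width, channel-length limit) are recomputed live.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from . import hydrodynamics as hydro
from .diffusion_reaction import (
    ReplenishmentFit,
    max_channel_length,
    max_viable_diameter,
)
from .params import (
    MediumProperties,
    MetaboliteParams,
    TissueSample,
    TrapGeometry,
    default_parameters,
)

__all__ = [
    "DesignRecommendation",
    "DesignReport",
    "RuleResult",
    "LiteratureDevice",
    "LiteratureEvaluation",
    "DesignWarning",
    "recommend_design",
    "check_design",
    "density_sensitivity_table",
    "load_literature_devices",
    "evaluate_literature_device",
    "evaluate_literature_table",
    "max_sample_size_for_schedule",
    "round_to_one_significant",
    "SETTLING_WIDTH_RANGE",
    "EJECTION_WIDTH_RANGE",
    "ASPECT_RATIO_RANGE",
    "SINGLE_SAMPLE_WIDTH_FACTOR",
    "RECOMMENDED_WIDTH_FACTOR",
    "RECOMMENDED_HEIGHT_FACTOR",
    "RECOMMENDED_VOLUME_RATIO",
    "PRACTICAL_MIN_WIDTH",
]

# dimension ranges from the 3D flow-simulation sweeps (multiples of d or w)
SETTLING_WIDTH_RANGE = (1.2, 6.7)      # w/d keeping settling times near-minimal
EJECTION_WIDTH_RANGE = (1.1, 3.3)      # w/d with ejection before damaging shear
ASPECT_RATIO_RANGE = (0.6, 1.1)        # h/w preserving the ejection window
SINGLE_SAMPLE_WIDTH_FACTOR = 1.4       # w <= 1.4 d guarantees one sample/trap
RECOMMENDED_WIDTH_FACTOR = 2.0         # w = 2 d
RECOMMENDED_HEIGHT_FACTOR = 0.9        # h = 0.9 w
RECOMMENDED_VOLUME_RATIO = 100.0       # V_M = 100 V_T sustains >= 24 h
PRACTICAL_MIN_WIDTH = 30e-6            # m; simulated minimum for 1.02 g/cm^3

#: classification margin: an experimental interval within 20% above the
#: modelled one only briefly dips below the metabolic threshold
WITHIN_MARGIN = 0.20


class DesignWarning(UserWarning):
    """A requested design violates a physical limit (anoxia, ejection)."""


@dataclass(frozen=True)
class RuleResult:
    """Outcome of one design rule check."""

    passed: bool
    detail: str


@dataclass(frozen=True)
class DesignRecommendation:
    """Rule-of-thumb trap design for one tissue."""

    w: float                  # trap width, m
    h: float                  # trap depth, m
    V_M: float                # medium volume per trap, m^3
    L_max: float              # maximum inter-trap channel length, m
    single_sample_w: float    # width bound guaranteeing one sample per trap
    warnings: tuple[str, ...] = field(default_factory=tuple)


@dataclass(frozen=True)
class DesignReport:
    """Rule-by-rule audit of a tissue/trap pairing."""

    rules: dict[str, RuleResult]
    single_sample_guaranteed: bool

    @property
    def passed(self) -> bool:
        return all(r.passed for r in self.rules.values())


def recommend_design(
    tissue: TissueSample,
    medium: MediumProperties | None = None,
    oxygen: MetaboliteParams | None = None,
    glucose: MetaboliteParams | None = None,
    schedule: float | None = None,
    fit: ReplenishmentFit | None = None,
    tau_max: float = hydro.TAU_MAX_DEFAULT,
) -> DesignRecommendation:
    """Recommend trap dimensions and medium provisioning for a tissue.

    Applies w = 2d, h = 0.9w and V_M = 100 V_T; when a replenishment
    ``schedule`` (s) is given, the medium volume is raised (never lowered)
    to the ratio the fitted linear law requires for that interval.  The
    channel-length limit comes from the Damköhler criterion for the
    provisioning nutrient (glucose by default).

    Hard physical limits are surfaced as both a `DesignWarning` and an
    entry in the returned ``warnings``: a tissue above the anoxia diameter
    cannot be kept viable at any provisioning, and a trap narrower than
    the minimum width cannot eject its sample by flow.
    """
    medium = medium or MediumProperties()
    oxygen = oxygen or default_parameters("typical", "oxygen")
    glucose = glucose or default_parameters("typical", "glucose")

    notes: list[str] = []
    d_max = max_viable_diameter(oxygen, tissue.rho_cell)
    if tissue.d > d_max:
        msg = (
            f"tissue diameter {tissue.d * 1e6:.0f} um exceeds the anoxia "
            f"limit d_max = {d_max * 1e6:.0f} um: the core will be anoxic "
            "regardless of medium provisioning"
        )
        warnings.warn(msg, DesignWarning, stacklevel=2)
        notes.append(msg)

    w = RECOMMENDED_WIDTH_FACTOR * tissue.d
    h = RECOMMENDED_HEIGHT_FACTOR * w

    w_min = hydro.minimum_trap_width(medium, tissue.rho_T / medium.rho_M, tau_max)
    if w < w_min:
        msg = (
            f"recommended width {w * 1e6:.1f} um is below the minimum trap "
            f"width {w_min * 1e6:.1f} um: tissues would not be extractable "
            "by applying flow (shear damage occurs before lift)"
        )
        warnings.warn(msg, DesignWarning, stacklevel=2)
        notes.append(msg)

    ratio = RECOMMENDED_VOLUME_RATIO
    if schedule is not None:
        if fit is not None:
            ratio = max(ratio, fit.ratio_for_time(schedule))
        else:
            # zero-order inversion; slightly under-provisions (a < 1)
            tau0 = glucose.c0 / (glucose.q_max * tissue.rho_cell)
            ratio = max(ratio, schedule / tau0)
            notes.append(
                "schedule converted with the zero-order law (no fitted "
                "replenishment law supplied); provision ~5-10% extra medium"
            )
    V_M = ratio * tissue.V_T
    L_max = max_channel_length(glucose, V_M / tissue.V_T, tissue.rho_cell)

    return DesignRecommendation(
        w=w,
        h=h,
        V_M=V_M,
        L_max=L_max,
        single_sample_w=SINGLE_SAMPLE_WIDTH_FACTOR * tissue.d,
        warnings=tuple(notes),
    )


def check_design(
    tissue: TissueSample,
    trap: TrapGeometry,
    medium: MediumProperties | None = None,
    tau_max: float = hydro.TAU_MAX_DEFAULT,
) -> DesignReport:
    """Audit a tissue/trap pairing against the established design rules.

    Checks the settling-time width range, the safe-ejection width and
    aspect-ratio ranges, the minimum ejectable width (the larger of the
    analytic crossing and the 30 um practical bound) and, when the trap
    declares a medium volume, the V_M >= 100 V_T provisioning rule.  The
    single-sample bound is reported separately: a wide trap is not a rule
    violation, it just admits more than one sample.
    """
    medium = medium or MediumProperties()
    d, w, h = tissue.d, trap.w, trap.h
    rules: dict[str, RuleResult] = {}

    lo, hi = SETTLING_WIDTH_RANGE
    rules["settling_width"] = RuleResult(
        lo * d < w < hi * d,
        f"need {lo}d < w < {hi}d (w/d = {w / d:.2f})",
    )
    lo, hi = EJECTION_WIDTH_RANGE
    rules["ejection_width"] = RuleResult(
        lo * d < w < hi * d,
        f"need {lo}d < w < {hi}d for ejection before damaging shear "
        f"(w/d = {w / d:.2f})",
    )
    lo, hi = ASPECT_RATIO_RANGE
    rules["aspect_ratio"] = RuleResult(
        lo * w < h < hi * w,
        f"need {lo}w < h < {hi}w (h/w = {h / w:.2f})",
    )

    w_min = max(
        hydro.minimum_trap_width(medium, tissue.rho_T / medium.rho_M, tau_max),
        PRACTICAL_MIN_WIDTH,
    )
    rules["minimum_width"] = RuleResult(
        w > w_min,
        f"need w > {w_min * 1e6:.0f} um so flow can eject before shear "
        f"damage (w = {w * 1e6:.0f} um)",
    )

    if trap.V_M is not None:
        rules["medium_volume"] = RuleResult(
            trap.V_M >= RECOMMENDED_VOLUME_RATIO * tissue.V_T,
            f"need V_M >= {RECOMMENDED_VOLUME_RATIO:.0f} V_T for a full "
            f"day of optimal metabolism (V_M/V_T = {trap.V_M / tissue.V_T:.0f})",
        )

    return DesignReport(
        rules=rules,
        single_sample_guaranteed=w <= SINGLE_SAMPLE_WIDTH_FACTOR * d,
    )


def round_to_one_significant(x: float) -> float:
    """Round to one significant figure (sensitivity tables are reported
    as orders of magnitude)."""
    if x == 0:
        return 0.0
    exp = math.floor(math.log10(abs(x)))
    return round(x, -exp)


def density_sensitivity_table(
    densities: tuple[float, ...] = (1010.0, 1100.0, 2000.0),
    d: float = 250e-6,
    medium: MediumProperties | None = None,
    tau_max: float = hydro.TAU_MAX_DEFAULT,
) -> pd.DataFrame:
    """How device operation shifts with tissue mass density.

    For each density (kg/m^3, must exceed the medium's) the table reports
    the settling time in a w = h = 2d trap, the minimum ejectable trap
    width, and the two critical flow rates, each raw and rounded to one
    significant figure.  Only quantities involving sample motion respond
    to density; the shear limit does not.
    """
    medium = medium or MediumProperties()
    rows = []
    w = 2.0 * d
    trap = TrapGeometry(w=w, h=w)
    for rho in densities:
        if rho <= medium.rho_M:
            raise ValueError(
                f"density {rho} kg/m^3 does not exceed the medium's "
                f"{medium.rho_M} kg/m^3: sample would not settle"
            )
        tissue = TissueSample(d=d, rho_T=rho)
        t_settle = hydro.settling_time(tissue, trap, medium)
        w_min = hydro.minimum_trap_width(medium, rho / medium.rho_M, tau_max)
        q_lift = hydro.critical_lift_flow(tissue, trap, medium)
        q_shear = hydro.critical_shear_flow(trap, medium, tau_max)
        ml_min = 6e7  # m^3/s -> mL/min
        rows.append({
            "density_g_cm3": rho / 1000.0,
            "settling_time_s": t_settle,
            "settling_time_approx_s": round_to_one_significant(t_settle),
            "min_width_um": w_min * 1e6,
            "min_width_approx_um": round_to_one_significant(w_min * 1e6),
            "ejection_flow_ml_min": q_lift * ml_min,
            "ejection_flow_approx_ml_min": round_to_one_significant(q_lift * ml_min),
            "shear_flow_ml_min": q_shear * ml_min,
            "shear_flow_approx_ml_min": round_to_one_significant(q_shear * ml_min),
        })
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class LiteratureDevice:
    """One published trap device, as surveyed.

    ``t_exp_h`` is the publication's replenishment interval in hours, or
    None for continuously perfused devices.  ``t_model_published_h`` is
    the modelled interval the survey reported for that device, kept for
    reference alongside what this package computes.
    """

    reference: str
    trapping_mechanism: str
    cell_lines: str
    diameter_um: float
    vm_over_vt: float
    t_exp_h: float | None
    t_model_published_h: float | None
    sample_kind: str

    def __post_init__(self) -> None:
        if self.diameter_um <= 0 or self.vm_over_vt <= 0:
            raise ValueError("diameter and volume ratio must be positive")


@dataclass(frozen=True)
class LiteratureEvaluation:
    """Model replenishment time and schedule classification for a device."""

    device: LiteratureDevice
    t_model_h: float
    classification: str  # perfused | replenished_within_model |
    #                      within_20pct | under_replenished


def load_literature_devices() -> list[LiteratureDevice]:
    """The packaged survey of published microfluidic trap devices."""
    with resources.files("mstdesign.data").joinpath("table4_devices.csv").open() as fh:
        df = pd.read_csv(fh)
    devices = []
    for rec in df.to_dict("records"):
        t_exp = rec["t_exp_h"]
        t_pub = rec["t_model_published_h"]
        devices.append(LiteratureDevice(
            reference=rec["reference"],
            trapping_mechanism=rec["trapping_mechanism"],
            cell_lines=rec["cell_lines"],
            diameter_um=float(rec["diameter_um"]),
            vm_over_vt=float(rec["vm_over_vt"]),
            t_exp_h=None if pd.isna(t_exp) else float(t_exp),
            t_model_published_h=None if pd.isna(t_pub) else float(t_pub),
            sample_kind=rec["sample_kind"],
        ))
    return devices


def evaluate_literature_device(
    device: LiteratureDevice, fit: ReplenishmentFit
) -> LiteratureEvaluation:
    """Compare a published replenishment schedule with the fitted law.

    The modelled interval is the fitted law at the device's V_M/V_T.
    Perfused devices always satisfy it.  Otherwise the experimental
    interval is classified as within the model time, within 20% above it
    (nutrients briefly dip below the metabolic threshold), or
    under-replenished (schedule well beyond what the medium can supply).
    """
    t_model_h = fit.predict(device.vm_over_vt) / 3600.0
    if device.t_exp_h is None:
        cls = "perfused"
    elif device.t_exp_h <= t_model_h:
        cls = "replenished_within_model"
    elif device.t_exp_h <= (1.0 + WITHIN_MARGIN) * t_model_h:
        cls = "within_20pct"
    else:
        cls = "under_replenished"
    return LiteratureEvaluation(device=device, t_model_h=t_model_h,
                                classification=cls)


def evaluate_literature_table(fit: ReplenishmentFit) -> pd.DataFrame:
    """Evaluate every surveyed device; one row per publication entry."""
    rows = []
    for dev in load_literature_devices():
        ev = evaluate_literature_device(dev, fit)
        rows.append({
            "reference": dev.reference,
            "trapping_mechanism": dev.trapping_mechanism,
            "diameter_um": dev.diameter_um,
            "vm_over_vt": dev.vm_over_vt,
            "t_exp_h": dev.t_exp_h,
            "t_model_h": ev.t_model_h,
            "t_model_published_h": dev.t_model_published_h,
            "classification": ev.classification,
        })
    return pd.DataFrame(rows)


def max_sample_size_for_schedule(
    V_M: float, schedule: float, fit: ReplenishmentFit
) -> float:
    """Largest tissue diameter a fixed medium volume can sustain, m.

    Inverts the fitted law for the V_M/V_T ratio matching the schedule
    (s), then converts the ratio back to a diameter at fixed V_M:
    d = (6 V_M / (pi ratio))^(1/3).  Growing tissue in a device shrinks
    its effective ratio, so this is the size at which the device's
    schedule stops keeping the core metabolically unrestricted.
    """
    if V_M <= 0:
        raise ValueError("medium volume must be positive")
    ratio = fit.ratio_for_time(schedule)
    return (6.0 * V_M / (math.pi * ratio)) ** (1.0 / 3.0)
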