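"""Parameter containers and literature presets for trap-design models.

Every model in the package consumes the four containers defined here:

``MetaboliteParams``
    Uptake and transport constants for one nutrient (glucose or oxygen).
``TissueSample``
    A spherical 3D tissue (spheroid, aggregate or micro-dissected sample).
``MediumProperties``
    The carrier fluid plus the effective volume-force acceleration that
    drives trapping (gravity by default, but any volume force — e.g. a
    dielectrophoretic body force — can stand in through ``g_eff``).
``TrapGeometry``
    A square-section well of width ``w`` and depth ``h`` adjacent to a
    channel of cross-section ``A`` with inter-trap separation ``L``.

Internal units are SI throughout, with concentrations kept in mol/m^3
(numerically equal to mM) and cellular densities in cells/m^3.  The
``load_parameters`` loader accepts YAML/JSON documents whose values may be
unit-suffixed strings ("250 um", "1.02 g/cm3"); presets mirror the
min/typical/max literature spread for an EMT6/Ro-like tissue.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path
from typing import Any

import yaml

from .units import parse_quantity

__all__ = [
    "MetaboliteParams",
    "TissueSample",
    "MediumProperties",
    "TrapGeometry",
    "ParameterBundle",
    "ParameterWarning",
    "default_parameters",
    "metabolite_preset",
    "tissue_volume",
    "load_parameters",
    "PRESET_LEVELS",
    "METABOLITES",
]

PRESET_LEVELS = ("minimum", "typical", "maximum")
METABOLITES = ("glucose", "oxygen")

#: defaults not tabulated in the literature preset file
DEFAULT_MEDIUM_DENSITY = 1000.0    # kg/m^3, aqueous culture medium
DEFAULT_VISCOSITY = 1.0e-3         # Pa s, water at ~20 C
DEFAULT_G_EFF = 9.81               # m/s^2, gravity as the trapping force
DEFAULT_TISSUE_DENSITY = 1020.0    # kg/m^3, typical spheroid (1.02 g/cm^3)


class ParameterWarning(UserWarning):
    """Non-fatal parameter issue (e.g. k_M >= c0 makes depletion trivial)."""


def tissue_volume(d: float) -> float:
    """Volume of a spherical tissue of diameter ``d`` (m), in m^3."""
    if d <= 0:
        raise ValueError(f"tissue diameter must be positive, got {d}")
    return math.pi * d**3 / 6.0


@dataclass(frozen=True)
class MetaboliteParams:
    """Uptake and transport constants for one nutrient.

    Parameters
    ----------
    q_max : float
        Maximum cellular uptake rate, mol/(cell s).
    k_M : float
        Michaelis-Menten half-saturation concentration, mol/m^3 (= mM).
    D_M, D_T : float
        Diffusion constant in the medium / in the tissue, m^2/s.
    c_sat_M, c_sat_T : float
        Saturation concentration in medium / tissue, mol/m^3.  The ratio
        c_sat_T/c_sat_M is the partition coefficient across the interface
        (1 for glucose, ~4.9 for oxygen).
    c0 : float
        Initial (reservoir) concentration in the medium, mol/m^3.
    """

    name: str
    q_max: float
    k_M: float
    D_M: float
    D_T: float
    c_sat_M: float
    c_sat_T: float
    c0: float

    def __post_init__(self) -> None:
        for f_name in ("q_max", "k_M", "D_M", "D_T", "c_sat_M", "c_sat_T", "c0"):
            v = getattr(self, f_name)
            if not (v > 0):
                raise ValueError(f"{self.name}.{f_name} must be positive, got {v}")
        if self.k_M >= self.c0:
            warnings.warn(
                f"{self.name}: k_M ({self.k_M} mM) >= c0 ({self.c0} mM); "
                "the depletion problem is degenerate (threshold met at t=0)",
                ParameterWarning,
                stacklevel=2,
            )


@dataclass(frozen=True)
class TissueSample:
    """Spherical 3D tissue sample.

    ``d`` is the diameter (m), ``rho_T`` the volumetric mass density
    (kg/m^3) and ``rho_cell`` the cellular density (cells/m^3).
    """

    d: float
    rho_T: float = DEFAULT_TISSUE_DENSITY
    rho_cell: float = 2.8e14

    def __post_init__(self) -> None:
        if self.d <= 0:
            raise ValueError(f"tissue diameter must be positive, got {self.d}")
        if self.rho_T <= 0 or self.rho_cell <= 0:
            raise ValueError("tissue densities must be positive")

    @property
    def V_T(self) -> float:
        """Tissue volume pi d^3/6, m^3."""
        return tissue_volume(self.d)


@dataclass(frozen=True)
class MediumProperties:
    """Culture medium and the effective trapping acceleration."""

    rho_M: float = DEFAULT_MEDIUM_DENSITY
    eta: float = DEFAULT_VISCOSITY
    g_eff: float = DEFAULT_G_EFF

    def __post_init__(self) -> None:
        if self.eta <= 0:
            raise ValueError(f"viscosity must be positive, got {self.eta}")
        if self.rho_M <= 0:
            raise ValueError("medium density must be positive")
        if self.g_eff < 0:
            raise ValueError("effective acceleration must be non-negative")

    def volume_force(self, tissue: TissueSample) -> float:
        """Net trapping force (gravity minus buoyancy), N; positive pulls down."""
        return (tissue.rho_T - self.rho_M) * tissue.V_T * self.g_eff


@dataclass(frozen=True)
class TrapGeometry:
    """Square-section trap plus adjacent channel segment.

    ``w``: trap width (square side), ``h``: trap depth, ``L``: inter-trap
    channel length, ``A``: channel cross-section area.  ``V_M`` is the
    available medium volume per trap; it defaults to ``A * L`` (channel
    volume per trap) when not given explicitly.
    """

    w: float
    h: float
    L: float | None = None
    A: float | None = None
    V_M: float | None = None

    def __post_init__(self) -> None:
        if self.w <= 0 or self.h <= 0:
            raise ValueError("trap width and depth must be positive")
        for f_name in ("L", "A", "V_M"):
            v = getattr(self, f_name)
            if v is not None and v <= 0:
                raise ValueError(f"trap {f_name} must be positive when given")
        if self.V_M is None and self.L is not None and self.A is not None:
            object.__setattr__(self, "V_M", self.A * self.L)

    def confinement_ratio(self, tissue: TissueSample) -> float:
        """lambda = d/w; must lie in (0, 1) for a trappable pairing."""
        lam = tissue.d / self.w
        if not (0 < lam < 1):
            raise ValueError(
                f"confinement ratio d/w = {lam:.3g} outside (0, 1): "
                "tissue does not fit the trap"
            )
        return lam

    def medium_volume(self) -> float:
        """V_M with a clear error when underdetermined."""
        if self.V_M is None:
            raise ValueError(
                "medium volume V_M is not set; give V_M or both A and L"
            )
        return self.V_M


@dataclass
class ParameterBundle:
    """A complete, validated parameter set for one design study."""

    tissue: TissueSample
    medium: MediumProperties
    trap: TrapGeometry
    metabolites: dict[str, MetaboliteParams] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        """Plain-dict form (SI numbers) suitable for YAML/JSON round-trip."""
        return {
            "tissue": asdict(self.tissue),
            "medium": asdict(self.medium),
            "trap": {k: v for k, v in asdict(self.trap).items() if v is not None},
            "metabolites": {k: asdict(v) for k, v in self.metabolites.items()},
        }


def _preset_table() -> dict[str, Any]:
    text = resources.files("mstdesign.data").joinpath("table1_presets.json").read_text()
    return json.loads(text)


def _pick(node: Any, level: str) -> float:
    """Presets store either a scalar or a {minimum,typical,maximum} map."""
    if isinstance(node, dict):
        return float(node[level])
    return float(node)


def metabolite_preset(level: str, name: str) -> MetaboliteParams:
    """Literature preset for one metabolite at one level.

    ``level`` is one of ``minimum``/``typical``/``maximum`` (the literature
    spread); ``name`` is ``glucose`` or ``oxygen``.  Values are converted
    from their printed units (mM, cm^2/s, cells/uL) to internal SI.
    """
    if level not in PRESET_LEVELS or name not in METABOLITES:
        raise KeyError(
            f"unknown preset ({level!r}, {name!r}); valid levels: "
            f"{PRESET_LEVELS}, metabolites: {METABOLITES}"
        )
    table = _preset_table()[name]
    return MetaboliteParams(
        name=name,
        q_max=_pick(table["q_max_mol_per_cell_s"], level),
        k_M=_pick(table["k_M_mM"], level),
        D_M=_pick(table["D_M_cm2_per_s"], level) * 1e-4,
        D_T=_pick(table["D_T_cm2_per_s"], level) * 1e-4,
        c_sat_M=_pick(table["c_sat_M_mM"], level),
        c_sat_T=_pick(table["c_sat_T_mM"], level),
        c0=_pick(table["c0_mM"], level),
    )


def default_parameters(level: str = "typical", metabolite: str | None = None):
    """Full preset bundle, or a single metabolite preset.

    With ``metabolite`` given, returns that nutrient's ``MetaboliteParams``
    at the requested level.  Otherwise returns a ``ParameterBundle`` with
    both nutrients, a 250 um / 1.02 g/cm^3 tissue, water-like medium under
    gravity, and the rule-of-thumb trap (w = 2d, h = 0.9w, V_M = 100 V_T).
    """
    if metabolite is not None:
        return metabolite_preset(level, metabolite)
    if level not in PRESET_LEVELS:
        raise KeyError(f"unknown preset level {level!r}; valid: {PRESET_LEVELS}")
    rho_cell = _pick(_preset_table()["cell_density_cells_per_uL"], level) * 1e9
    tissue = TissueSample(d=250e-6, rho_T=DEFAULT_TISSUE_DENSITY, rho_cell=rho_cell)
    trap = TrapGeometry(
        w=2 * tissue.d,
        h=0.9 * 2 * tissue.d,
        V_M=100 * tissue.V_T,
    )
    return ParameterBundle(
        tissue=tissue,
        medium=MediumProperties(),
        trap=trap,
        metabolites={m: metabolite_preset(level, m) for m in METABOLITES},
    )


# config fields -> (attribute, dimension) for the unit parser
_TISSUE_FIELDS = {"d": "length", "rho_T": "mass_density", "rho_cell": "cell_density"}
_MEDIUM_FIELDS = {"rho_M": "mass_density", "eta": "viscosity", "g_eff": "acceleration"}
_TRAP_FIELDS = {"w": "length", "h": "length", "L": "length", "A": "area", "V_M": "volume"}
_METABOLITE_FIELDS = {
    "q_max": "uptake_rate",
    "k_M": "concentration",
    "D_M": "diffusivity",
    "D_T": "diffusivity",
    "c_sat_M": "concentration",
    "c_sat_T": "concentration",
    "c0": "concentration",
}


def load_parameters(document: dict | str | Path | None = None) -> ParameterBundle:
    """Build a bundle from a YAML/JSON document, falling back to presets.

    ``document`` may be a mapping, a path to a YAML/JSON file, a YAML
    string, or None/empty (pure "typical" defaults).  Recognized sections:
    ``tissue``, ``medium``, ``trap``, ``metabolites.{glucose,oxygen}``.
    Every field is optional; values may be numbers (internal SI units) or
    unit-suffixed strings.
    """
    if document is None:
        doc: dict[str, Any] = {}
    elif isinstance(document, dict):
        doc = document
    else:
        p = Path(document)
        text = p.read_text() if p.exists() else str(document)
        loaded = yaml.safe_load(text)
        if loaded is None:
            doc = {}
        elif isinstance(loaded, dict):
            doc = loaded
        else:
            raise ValueError("config document must be a mapping at top level")

    unknown = set(doc) - {"tissue", "medium", "trap", "metabolites"}
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")

    base = default_parameters("typical")

    def section(name: str, fields: dict[str, str], defaults: dict[str, Any]) -> dict:
        raw = doc.get(name, {}) or {}
        bad = set(raw) - set(fields)
        if bad:
            raise ValueError(f"unknown fields in [{name}]: {sorted(bad)}")
        out = dict(defaults)
        for key, dim in fields.items():
            if key in raw:
                out[key] = parse_quantity(raw[key], dim)
        return out

    tissue = TissueSample(**section("tissue", _TISSUE_FIELDS, asdict(base.tissue)))
    medium = MediumProperties(**section("medium", _MEDIUM_FIELDS, asdict(base.medium)))

    trap_defaults = {k: v for k, v in asdict(base.trap).items()}
    raw_trap = doc.get("trap", {}) or {}
    if raw_trap:
        # an explicit trap section replaces the derived default wholesale so
        # that a user-set width is not silently paired with the preset V_M
        trap_defaults = {"w": None, "h": None, "L": None, "A": None, "V_M": None}
    trap_kwargs = section("trap", _TRAP_FIELDS, trap_defaults)
    if trap_kwargs["w"] is None or trap_kwargs["h"] is None:
        if raw_trap:
            raise ValueError("trap section must set both w and h")
    trap = TrapGeometry(**trap_kwargs)

    metabolites: dict[str, MetaboliteParams] = {}
    raw_mets = doc.get("metabolites", {}) or {}
    bad = set(raw_mets) - set(METABOLITES)
    if bad:
        raise ValueError(f"unknown metabolites: {sorted(bad)}")
    for m in METABOLITES:
        defaults = asdict(base.metabolites[m])
        raw = raw_mets.get(m, {}) or {}
        raw = {k: v for k, v in raw.items() if k != "name"}
        bad = set(raw) - set(_METABOLITE_FIELDS)
        if bad:
            raise ValueError(f"unknown fields in metabolites.{m}: {sorted(bad)}")
        for key, dim in _METABOLITE_FIELDS.items():
            if key in raw:
                defaults[key] = parse_quantity(raw[key], dim)
        metabolites[m] = MetaboliteParams(**defaults)

    return ParameterBundle(tissue=tissue, medium=medium, trap=trap, metabolites=metabolites)
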