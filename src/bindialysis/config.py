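"""Parameter containers, unit conversions and configuration I/O.

Clinical units (mg/dL, g/dL, mL/min, hours) appear only at the I/O
boundary.  Internally the package uses SI for geometry and pressure,
mL/min for flow rates and membrane conductances (so the flow-adjustment
law needs no extra unit conversion factor), and molar concentrations
inside the binding arithmetic.
"""

from __future__ import annotations

import hashlib
from dataclasses import MISSING, dataclass, fields, replace
from importlib import resources
from pathlib import Path

import yaml

__all__ = [
    "ConfigError",
    "SchemaError",
    "ValidationError",
    "DialyzerGeometry",
    "FluidProperties",
    "SoluteSystem",
    "OperatingPoint",
    "TransportCoefficients",
    "Setup",
    "clinical_to_molar",
    "molar_to_clinical",
    "load_setup",
    "builtin_setup",
    "builtin_setup_names",
    "MU_AQUEOUS_37C",
    "MW_BILIRUBIN",
    "MW_BSA",
]

# Aqueous viscosity at 37 degC; the bench fluid on both sides is albumin
# dissolved in dialysate, so a single aqueous value is used for both.
MU_AQUEOUS_37C = 6.9e-4  # Pa.s
MW_BILIRUBIN = 584.66  # g/mol
MW_BSA = 66430.0  # g/mol


class ConfigError(ValueError):
    """Base class for configuration problems."""


class SchemaError(ConfigError):
    """A required field is missing or an unknown key is present."""


class ValidationError(ConfigError):
    """A field value violates a physical invariant."""


# ---------------------------------------------------------------------------
# Unit conversions
# ---------------------------------------------------------------------------

_PER_DL_TO_PER_L = {"mg/dL": 0.01, "g/dL": 10.0}  # -> g/L


def clinical_to_molar(c: float, mw: float, unit: str = "mg/dL") -> float:
    """Convert a clinical mass concentration to molarity.

    Parameters
    ----------
    c : concentration in ``unit`` (mg/dL for toxins, g/dL for albumin).
    mw : molar mass in g/mol.
    unit : "mg/dL" or "g/dL".
    """
    if mw <= 0:
        raise ValidationError(f"molar mass must be positive, got {mw}")
    if c < 0:
        raise ValidationError(f"concentration must be non-negative, got {c}")
    try:
        factor = _PER_DL_TO_PER_L[unit]
    except KeyError:
        raise SchemaError(f"unknown concentration unit {unit!r}") from None
    return c * factor / mw


def molar_to_clinical(c: float, mw: float, unit: str = "mg/dL") -> float:
    """Inverse of :func:`clinical_to_molar` (exact to round-off)."""
    if mw <= 0:
        raise ValidationError(f"molar mass must be positive, got {mw}")
    try:
        factor = _PER_DL_TO_PER_L[unit]
    except KeyError:
        raise SchemaError(f"unknown concentration unit {unit!r}") from None
    return c * mw / factor


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DialyzerGeometry:
    """Hollow-fiber dialyzer geometry and membrane properties.

    ``area_nominal`` is the manufacturer's nominal membrane area and is
    used only for conductance rescaling between dialyzers; where a
    geometric lumen area is needed it is computed as 2*pi*ri*L*n (the
    two disagree for the dialyzers studied; both are carried).
    """

    n_fibers: int
    r_inner: float  # m
    r_outer: float  # m
    fiber_length: float  # m
    housing_radius: float  # m
    area_nominal: float  # m^2
    Lp: float  # m s^-1 Pa^-1 (hydraulic permeability)
    sigma: float = 0.0  # reflection coefficient (0 = freely convected)

    def __post_init__(self) -> None:
        if self.n_fibers < 1:
            raise ValidationError("n_fibers must be >= 1")
        for name in ("r_inner", "r_outer", "fiber_length", "housing_radius", "area_nominal"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.r_inner >= self.r_outer:
            raise ValidationError("r_inner must be smaller than r_outer")
        if not 0.0 <= self.sigma <= 1.0:
            raise ValidationError("sigma must lie in [0, 1]")
        if self.Lp < 0:
            raise ValidationError("Lp must be non-negative")
        if self.n_fibers * self.r_outer**2 >= self.housing_radius**2:
            raise ValidationError("fiber bundle does not fit inside the housing")


@dataclass(frozen=True)
class FluidProperties:
    mu_blood: float = MU_AQUEOUS_37C  # Pa.s
    mu_dialysate: float = MU_AQUEOUS_37C  # Pa.s

    def __post_init__(self) -> None:
        if self.mu_blood <= 0 or self.mu_dialysate <= 0:
            raise ValidationError("viscosities must be positive")


@dataclass(frozen=True)
class SoluteSystem:
    """Single-site binder/toxin pair (albumin-bilirubin by default)."""

    KB: float  # 1/M, primary-site binding constant
    mw_toxin: float = MW_BILIRUBIN  # g/mol
    mw_binder: float = MW_BSA  # g/mol

    def __post_init__(self) -> None:
        if self.KB <= 0:
            raise ValidationError("KB must be positive")
        if self.mw_toxin <= 0 or self.mw_binder <= 0:
            raise ValidationError("molar masses must be positive")


@dataclass(frozen=True)
class OperatingPoint:
    """Flows, reservoir volumes, starting composition and duration."""

    Qb_in: float  # mL/min
    Qd_in: float  # mL/min
    Vb: float  # mL, blood-side reservoir
    Vd: float  # mL, dialysate-side reservoir
    Cb_toxin0: float  # mg/dL total toxin, blood reservoir at t=0
    Cb_albumin: float  # g/dL binder, blood side
    Cd_albumin: float  # g/dL binder, dialysate side
    Cd_toxin0: float = 0.0  # mg/dL total toxin, dialysate reservoir at t=0
    duration: float = 5.0  # h

    def __post_init__(self) -> None:
        if self.Qb_in <= 0 or self.Qd_in <= 0:
            raise ValidationError("flow rates must be positive")
        if self.Vb <= 0 or self.Vd <= 0:
            raise ValidationError("reservoir volumes must be positive")
        for name in ("Cb_toxin0", "Cb_albumin", "Cd_albumin", "Cd_toxin0"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        if self.duration <= 0:
            raise ValidationError("duration must be positive")


@dataclass(frozen=True)
class TransportCoefficients:
    """Free-toxin membrane conductance and its flow dependence.

    ``KfreeA_at_500`` is the mass-transfer-area coefficient for unbound
    toxin at the 500 mL/min reference dialysate flow; ``beta_Qd`` is the
    fractional change of that coefficient per 300 mL/min change in
    dialysate flow.  With flows fixed to mL/min internally the
    adjustment law needs no separate unit-conversion constant.
    """

    KfreeA_at_500: float  # mL/min
    beta_Qd: float = 0.05544

    def __post_init__(self) -> None:
        if self.KfreeA_at_500 <= 0:
            raise ValidationError("KfreeA_at_500 must be positive")
        if not 0.0 <= self.beta_Qd <= 0.6:
            raise ValidationError("beta_Qd must lie in [0, 0.6]")


@dataclass(frozen=True)
class Setup:
    """A complete, validated experiment/simulation configuration."""

    geometry: DialyzerGeometry
    fluids: FluidProperties
    solute: SoluteSystem
    operating: OperatingPoint
    transport: TransportCoefficients
    name: str = ""

    def with_params(
        self,
        KB: float | None = None,
        KfreeA_at_500: float | None = None,
        beta_Qd: float | None = None,
        **operating_overrides: float,
    ) -> "Setup":
        """Return a copy with selected model parameters replaced."""
        solute = self.solute if KB is None else replace(self.solute, KB=KB)
        transport = self.transport
        if KfreeA_at_500 is not None:
            transport = replace(transport, KfreeA_at_500=KfreeA_at_500)
        if beta_Qd is not None:
            transport = replace(transport, beta_Qd=beta_Qd)
        operating = (
            replace(self.operating, **operating_overrides)
            if operating_overrides
            else self.operating
        )
        return replace(
            self, solute=solute, transport=transport, operating=operating
        )


# ---------------------------------------------------------------------------
# YAML I/O
# ---------------------------------------------------------------------------

# unit-annotated YAML key -> (dataclass field, scale factor to internal unit)
_GEOMETRY_KEYS = {
    "n_fibers": ("n_fibers", 1),
    "r_inner_um": ("r_inner", 1e-6),
    "r_outer_um": ("r_outer", 1e-6),
    "fiber_length_cm": ("fiber_length", 1e-2),
    "housing_radius_mm": ("housing_radius", 1e-3),
    "area_nominal_m2": ("area_nominal", 1.0),
    "Lp_m_per_s_Pa": ("Lp", 1.0),
    "sigma": ("sigma", 1.0),
}
_FLUID_KEYS = {
    "mu_blood_Pa_s": ("mu_blood", 1.0),
    "mu_dialysate_Pa_s": ("mu_dialysate", 1.0),
}
_SOLUTE_KEYS = {
    "KB_per_M": ("KB", 1.0),
    "mw_toxin_g_mol": ("mw_toxin", 1.0),
    "mw_binder_g_mol": ("mw_binder", 1.0),
}
_OPERATING_KEYS = {
    "Qb_mL_min": ("Qb_in", 1.0),
    "Qd_mL_min": ("Qd_in", 1.0),
    "Vb_mL": ("Vb", 1.0),
    "Vd_mL": ("Vd", 1.0),
    "Cb_toxin0_mg_dL": ("Cb_toxin0", 1.0),
    "Cb_albumin_g_dL": ("Cb_albumin", 1.0),
    "Cd_albumin_g_dL": ("Cd_albumin", 1.0),
    "Cd_toxin0_mg_dL": ("Cd_toxin0", 1.0),
    "duration_h": ("duration", 1.0),
}
_TRANSPORT_KEYS = {
    "KfreeA_at_500_mL_min": ("KfreeA_at_500", 1.0),
    "beta_Qd": ("beta_Qd", 1.0),
}

_SECTIONS = {
    "dialyzer": (DialyzerGeometry, _GEOMETRY_KEYS),
    "fluids": (FluidProperties, _FLUID_KEYS),
    "solute": (SoluteSystem, _SOLUTE_KEYS),
    "operating": (OperatingPoint, _OPERATING_KEYS),
    "transport": (TransportCoefficients, _TRANSPORT_KEYS),
}


def _build_section(section: str, raw: dict) -> object:
    cls, keymap = _SECTIONS[section]
    if not isinstance(raw, dict):
        raise SchemaError(f"section {section!r} must be a mapping")
    unknown = set(raw) - set(keymap)
    if unknown:
        raise SchemaError(
            f"unknown key(s) in section {section!r}: {sorted(unknown)}"
        )
    kwargs = {}
    for key, value in raw.items():
        name, scale = keymap[key]
        if not isinstance(value, (int, float)) or isinstance(value, bool):
            raise SchemaError(f"{section}.{key} must be a number, got {value!r}")
        kwargs[name] = value if scale == 1 else float(value) * scale
    required = {
        f.name
        for f in fields(cls)
        if f.default is MISSING and f.default_factory is MISSING
    }
    missing = required - set(kwargs)
    if missing:
        inv = {v[0]: k for k, v in keymap.items()}
        raise SchemaError(
            f"section {section!r} is missing required field(s): "
            f"{sorted(inv[m] for m in missing)}"
        )
    return cls(**kwargs)


def load_setup(path: str | Path) -> Setup:
    """Load and validate a YAML setup file.

    Every key carries its unit in its name; unknown keys are rejected,
    missing required keys raise :class:`SchemaError` naming the field,
    and physically invalid values raise :class:`ValidationError`.
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise SchemaError(f"{path}: top level must be a mapping")
    unknown = set(raw) - set(_SECTIONS) - {"name"}
    if unknown:
        raise SchemaError(f"{path}: unknown section(s) {sorted(unknown)}")
    missing = {"dialyzer", "solute", "operating", "transport"} - set(raw)
    if missing:
        raise SchemaError(f"{path}: missing section(s) {sorted(missing)}")
    parts = {}
    for section in _SECTIONS:
        if section in raw:
            parts[section] = _build_section(section, raw[section])
        elif section == "fluids":
            parts[section] = FluidProperties()
    return Setup(
        geometry=parts["dialyzer"],
        fluids=parts["fluids"],
        solute=parts["solute"],
        operating=parts["operating"],
        transport=parts["transport"],
        name=str(raw.get("name", path.stem)),
    )


def builtin_setup_names() -> list[str]:
    """Names of the shipped bench-study setup fixtures."""
    pkg = resources.files("bindialysis") / "configs"
    return sorted(p.stem for p in pkg.iterdir() if p.name.endswith(".yaml"))


def builtin_setup(name: str) -> Setup:
    """Load one of the shipped setup fixtures by name (e.g. ``f3_qd150``)."""
    pkg = resources.files("bindialysis") / "configs" / f"{name}.yaml"
    if not pkg.is_file():
        raise SchemaError(
            f"no builtin setup {name!r}; available: {builtin_setup_names()}"
        )
    with resources.as_file(pkg) as path:
        return load_setup(path)


def config_digest(path: str | Path) -> str:
    """SHA-256 digest of a configuration file (for run manifests)."""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
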