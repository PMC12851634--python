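"""Species parameterizations: validated records and YAML persistence.

Each species is described by a flat set of life-history and allometric
parameters plus two thermal-scaling blocks (one for food intake, one for
maintenance metabolism).  The five shipped parameter files live in the
``species/`` data directory next to this module and are validated on load:
a file that would give a degenerate thermal performance curve anywhere in
the species' operating mass range is a configuration error, not a runtime
surprise.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, fields, asdict
from importlib import resources
from pathlib import Path

import yaml

__all__ = [
    "ThermalScaling",
    "SpeciesParams",
    "SpeciesSchemaError",
    "SpeciesValidationError",
    "available_species",
    "load_species",
    "save_species",
    "VALIDATION_MASSES",
]


class SpeciesSchemaError(ValueError):
    """A species config file has a missing, extra or mistyped field."""


class SpeciesValidationError(ValueError):
    """A species record violates a physiological invariant."""


#: Masses (g) at which thermal-curve sanity is checked at registry load,
#: spanning egg mass to a 10 kg cap (roughly twice the largest shipped
#: maturation length converted to mass).
VALIDATION_MASSES = (1.0, 100.0, 10_000.0)


@dataclass(frozen=True)
class ThermalScaling:
    """Size-scaling coefficients of one thermal performance curve.

    The optimum and maximum temperatures and the Q10-like steepness Q all
    scale with total body mass w (g) as power laws:

        T_opt(w) = gamma_opt * w**v_opt        (deg C)
        T_max(w) = gamma_max * w**v_max        (deg C)
        Q(w)     = theta_coef * w**theta_exp   (dimensionless)
    """

    gamma_opt: float
    v_opt: float
    gamma_max: float
    v_max: float
    theta_coef: float
    theta_exp: float

    def __post_init__(self) -> None:
        for name in ("gamma_opt", "gamma_max", "theta_coef"):
            v = getattr(self, name)
            if not (v > 0):
                raise SpeciesValidationError(f"{name} must be > 0, got {v!r}")
        for f in fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v):
                raise SpeciesValidationError(f"{f.name} must be finite, got {v!r}")


@dataclass(frozen=True)
class SpeciesParams:
    """Complete parameter set for one species.

    Units follow the shipped tables: masses in g, lengths in cm, times in
    days, temperatures in deg C.  ``q_j``/``q_a`` are the maximum
    reserve-to-structure ratios of juveniles/adults; ``q_r`` is the spawning
    threshold condition (equal to ``q_j`` for every shipped species).
    """

    name: str
    w_b: float            # egg mass (g)
    q_j: float            # juvenile maximum condition y/x
    q_a: float            # adult maximum condition y/x
    q_r: float            # threshold condition for spawning
    k_r: float            # gonad-to-offspring conversion efficiency
    E_d: int              # duration of egg period (days)
    A_f: int              # age at first feeding (days)
    L_m: float            # maturation length (cm)
    lambda1: float        # length allometry scalar (cm g^-lambda2)
    lambda2: float        # length allometry exponent
    d1: float             # intake allometry scalar
    d2: float             # intake allometry exponent
    rho1: float           # maintenance allometry scalar
    rho2: float           # maintenance allometry exponent
    k_e: float            # resource-energy conversion efficiency
    intake_thermal: ThermalScaling
    maintenance_thermal: ThermalScaling
    max_lifespan_years: int

    def __post_init__(self) -> None:
        self._validate()

    # -- validation ------------------------------------------------------

    def _validate(self) -> None:
        for name in ("w_b", "q_j", "q_a", "L_m", "lambda1", "lambda2",
                     "d1", "rho1"):
            v = getattr(self, name)
            if not (v > 0):
                raise SpeciesValidationError(f"{name} must be > 0, got {v!r}")
        for name in ("w_b", "q_j", "q_a", "q_r", "k_r", "L_m", "lambda1",
                     "lambda2", "d1", "d2", "rho1", "rho2", "k_e"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise SpeciesValidationError(f"{name} must be finite, got {v!r}")
        if not (self.q_j <= self.q_a):
            raise SpeciesValidationError(
                f"q_j must not exceed q_a (got q_j={self.q_j}, q_a={self.q_a})")
        if not (0 < self.k_e <= 1):
            raise SpeciesValidationError(f"k_e must be in (0, 1], got {self.k_e}")
        if not (0 < self.k_r <= 1):
            raise SpeciesValidationError(f"k_r must be in (0, 1], got {self.k_r}")
        if self.max_lifespan_years < 1:
            raise SpeciesValidationError(
                f"max_lifespan_years must be a positive integer, "
                f"got {self.max_lifespan_years}")
        if self.q_r != self.q_j:
            warnings.warn(
                f"species {self.name!r}: q_r ({self.q_r}) differs from q_j "
                f"({self.q_j}); the fecundity rule uses q_j",
                stacklevel=3)
        self._validate_thermal()

    def _validate_thermal(self) -> None:
        masses = (self.w_b, *VALIDATION_MASSES)
        for proc, s in (("intake", self.intake_thermal),
                        ("maintenance", self.maintenance_thermal)):
            for w in masses:
                t_opt = s.gamma_opt * w ** s.v_opt
                t_max = s.gamma_max * w ** s.v_max
                q = s.theta_coef * w ** s.theta_exp
                if not (t_max > t_opt):
                    raise SpeciesValidationError(
                        f"species {self.name!r}, {proc} scaling: "
                        f"T_max({w} g) = {t_max:.4g} must exceed "
                        f"T_opt({w} g) = {t_opt:.4g}")
                if not (q > 1):
                    raise SpeciesValidationError(
                        f"species {self.name!r}, {proc} scaling: "
                        f"Q({w} g) = {q:.4g} must exceed 1")


# -- file I/O ------------------------------------------------------------

_THERMAL_FIELDS = tuple(f.name for f in fields(ThermalScaling))
_SCALAR_FIELDS = tuple(f.name for f in fields(SpeciesParams)
                       if f.name not in ("intake_thermal", "maintenance_thermal"))
_INT_FIELDS = ("E_d", "A_f", "max_lifespan_years")


def _species_dir():
    return resources.files("thermofish") / "species"


def available_species() -> list[str]:
    """Names of the shipped species parameter files."""
    return sorted(p.name[:-5] for p in _species_dir().iterdir()
                  if p.name.endswith(".yaml"))


def _coerce_number(field: str, value, where: str):
    if isinstance(value, bool) or not isinstance(value, (int, float)):
        raise SpeciesSchemaError(
            f"field {where}{field!r} must be a number, got {value!r}")
    if field in _INT_FIELDS:
        if int(value) != value:
            raise SpeciesSchemaError(
                f"field {field!r} must be an integer day/year count, "
                f"got {value!r}")
        return int(value)
    return float(value)


def _parse_thermal(block, where: str) -> ThermalScaling:
    if not isinstance(block, dict):
        raise SpeciesSchemaError(f"section {where!r} must be a mapping")
    extra = set(block) - set(_THERMAL_FIELDS)
    if extra:
        raise SpeciesSchemaError(
            f"unknown field(s) in {where!r}: {sorted(extra)}")
    missing = set(_THERMAL_FIELDS) - set(block)
    if missing:
        raise SpeciesSchemaError(
            f"missing field(s) in {where!r}: {sorted(missing)}")
    kwargs = {k: _coerce_number(k, block[k], f"{where}.") for k in _THERMAL_FIELDS}
    return ThermalScaling(**kwargs)


def load_species(path_or_name: str | Path) -> SpeciesParams:
    """Load a species record by shipped name or from a YAML file path.

    Raises :class:`SpeciesSchemaError` for malformed files (missing, extra
    or mistyped fields) and :class:`SpeciesValidationError` when the values
    violate a physiological invariant.
    """
    name = str(path_or_name)
    if "/" not in name and "\\" not in name and not name.endswith(".yaml"):
        ref = _species_dir() / f"{name}.yaml"
        if not ref.is_file():
            raise KeyError(
                f"unknown species {name!r}; shipped: {available_species()}")
        raw = yaml.safe_load(ref.read_text())
    else:
        raw = yaml.safe_load(Path(path_or_name).read_text())
    if not isinstance(raw, dict):
        raise SpeciesSchemaError("species file must contain a mapping")

    expected = set(_SCALAR_FIELDS) | {"intake_thermal", "maintenance_thermal"}
    extra = set(raw) - expected
    if extra:
        raise SpeciesSchemaError(f"unknown field(s): {sorted(extra)}")
    missing = expected - set(raw)
    if missing:
        raise SpeciesSchemaError(f"missing field(s): {sorted(missing)}")

    kwargs: dict = {}
    for k in _SCALAR_FIELDS:
        if k == "name":
            if not isinstance(raw[k], str) or not raw[k]:
                raise SpeciesSchemaError("field 'name' must be a non-empty string")
            kwargs[k] = raw[k]
        else:
            kwargs[k] = _coerce_number(k, raw[k], "")
    kwargs["intake_thermal"] = _parse_thermal(raw["intake_thermal"],
                                              "intake_thermal")
    kwargs["maintenance_thermal"] = _parse_thermal(raw["maintenance_thermal"],
                                                   "maintenance_thermal")
    return SpeciesParams(**kwargs)


def save_species(p: SpeciesParams, path: str | Path) -> None:
    """Write ``p`` to a YAML file such that ``load_species`` round-trips it
    exactly (floats serialized with full repr precision)."""
    doc = asdict(p)

    def _check_finite(d, prefix=""):
        for k, v in d.items():
            if isinstance(v, dict):
                _check_finite(v, f"{k}.")
            elif isinstance(v, float) and not math.isfinite(v):
                raise SpeciesValidationError(
                    f"field {prefix}{k!r} is not finite: {v!r}")

    _check_finite(doc)
    text = yaml.safe_dump(doc, sort_keys=False, default_flow_style=False)
    Path(path).write_text(text)
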