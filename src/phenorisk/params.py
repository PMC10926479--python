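"""Species parameter file: schema, parsing, validation, serialization.

The parameter file dialect is plain ``key = value`` lines with ``#``
comments.  Keys use the conventional camel/snake codes of degree-day risk
models (``eggLDT``, ``coldstress_units_max1``, ...); they map onto the
snake_case fields of :class:`SpeciesParams`.  A packaged default file for
emerald ash borer ships with the library and fills any keys a user file
omits.
"""

from __future__ import annotations

import dataclasses
import json
from importlib import resources
from pathlib import Path
from typing import Iterable

__all__ = [
    "SpeciesParams",
    "ParamValidationError",
    "load_params",
    "default_params",
    "parse_params_text",
    "serialize_params",
]

#: Life-stage codes, in the canonical simulation order.
STAGES = ("OL", "P", "A", "E", "L")

# file code -> dataclass field
_CODE_TO_FIELD = {
    "eggLDT": "egg_ldt",
    "larvaeLDT": "larvae_ldt",
    "pupaeLDT": "pupae_ldt",
    "adultLDT": "adult_ldt",
    "eggUDT": "egg_udt",
    "larvaeUDT": "larvae_udt",
    "pupaeUDT": "pupae_udt",
    "adultUDT": "adult_udt",
    "eggDD": "egg_dd",
    "larvaeDD": "larvae_dd",
    "pupDD": "pup_dd",
    "adultDD": "adult_dd",
    "eggEventDD": "egg_event_dd",
    "larvaeEventDD": "larvae_event_dd",
    "pupaeEventDD": "pupae_event_dd",
    "adultEventDD": "adult_event_dd",
    "coldstress_threshold": "coldstress_threshold",
    "coldstress_units_max1": "coldstress_units_max1",
    "coldstress_units_max2": "coldstress_units_max2",
    "heatstress_threshold": "heatstress_threshold",
    "heatstress_units_max1": "heatstress_units_max1",
    "heatstress_units_max2": "heatstress_units_max2",
    "distro_mean": "distro_mean",
    "distro_var": "distro_var",
    "xdist1": "xdist1",
    "xdist2": "xdist2",
    "distro_shape": "distro_shape",
    "n_cohorts": "n_cohorts",
    "stgorder": "stgorder",
    "obligate_diapause": "obligate_diapause",
    "calctype": "calctype",
}
_FIELD_TO_CODE = {v: k for k, v in _CODE_TO_FIELD.items()}

# OWEventDD is listed in parameter tables as "varies": it is always derived
# from the cohort distribution, never read from a file.
_DERIVED_CODES = {"OWEventDD"}


class ParamValidationError(ValueError):
    """A parameter file value is malformed or violates an invariant."""


@dataclasses.dataclass(frozen=True)
class SpeciesParams:
    """Validated species parameter set.

    Temperatures are degrees C; stage durations and event offsets are
    degree-days C.  ``ow_event_dd`` (the overwintering-stage completion
    requirement) is intentionally absent: it varies per cohort and is
    carried by :class:`phenorisk.cohorts.CohortSet`.
    """

    egg_ldt: float
    larvae_ldt: float
    pupae_ldt: float
    adult_ldt: float
    egg_udt: float
    larvae_udt: float
    pupae_udt: float
    adult_udt: float
    egg_dd: float
    larvae_dd: float
    pup_dd: float
    adult_dd: float
    egg_event_dd: float
    larvae_event_dd: float
    pupae_event_dd: float
    adult_event_dd: float
    coldstress_threshold: float
    coldstress_units_max1: float
    coldstress_units_max2: float
    heatstress_threshold: float
    heatstress_units_max1: float
    heatstress_units_max2: float
    distro_mean: float
    distro_var: float
    xdist1: float
    xdist2: float
    distro_shape: str
    n_cohorts: int
    stgorder: tuple[str, ...]
    obligate_diapause: bool
    calctype: str

    def __post_init__(self) -> None:
        self.validate()

    # -- threshold lookup ------------------------------------------------
    def stage_thresholds(self, stage: str) -> tuple[float, float]:
        """Return (LDT, UDT) for a stage code; ``OL`` uses larval thresholds."""
        key = {"OL": "larvae", "P": "pupae", "A": "adult", "E": "egg", "L": "larvae"}
        try:
            prefix = key[stage]
        except KeyError:
            raise ValueError(f"unknown stage code {stage!r}") from None
        return (getattr(self, f"{prefix}_ldt"), getattr(self, f"{prefix}_udt"))

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        for st in ("egg", "larvae", "pupae", "adult"):
            ldt = getattr(self, f"{st}_ldt")
            udt = getattr(self, f"{st}_udt")
            if not ldt < udt:
                raise ParamValidationError(
                    f"{st}LDT ({ldt}) must be below {st}UDT ({udt})"
                )
        for fld in (
            "egg_dd",
            "larvae_dd",
            "pup_dd",
            "adult_dd",
            "egg_event_dd",
            "larvae_event_dd",
            "pupae_event_dd",
            "adult_event_dd",
        ):
            if not getattr(self, fld) > 0:
                raise ParamValidationError(
                    f"{_FIELD_TO_CODE[fld]} must be positive, got {getattr(self, fld)}"
                )
        if not (self.xdist1 < self.distro_mean < self.xdist2):
            raise ParamValidationError(
                "cohort distribution requires xdist1 < distro_mean < xdist2, got "
                f"{self.xdist1}, {self.distro_mean}, {self.xdist2}"
            )
        if not self.distro_var > 0:
            raise ParamValidationError(f"distro_var must be positive, got {self.distro_var}")
        if not self.coldstress_units_max1 < self.coldstress_units_max2:
            raise ParamValidationError(
                "coldstress_units_max1 must be below coldstress_units_max2"
            )
        if not self.heatstress_units_max1 < self.heatstress_units_max2:
            raise ParamValidationError(
                "heatstress_units_max1 must be below heatstress_units_max2"
            )
        if sorted(self.stgorder) != sorted(STAGES) or self.stgorder[0] != "OL":
            raise ParamValidationError(
                f"stgorder must be a permutation of {STAGES} starting with OL, "
                f"got {self.stgorder}"
            )
        if self.n_cohorts < 1:
            raise ParamValidationError(f"n_cohorts must be >= 1, got {self.n_cohorts}")
        if self.distro_shape != "lognormal":
            raise ParamValidationError(
                f"unsupported distro_shape {self.distro_shape!r} (only 'lognormal')"
            )
        if self.calctype != "triangle":
            raise ParamValidationError(
                f"unsupported calctype {self.calctype!r} (only 'triangle')"
            )

    # -- derived convenience ---------------------------------------------
    def replace(self, **changes) -> "SpeciesParams":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stgorder"] = list(self.stgorder)
        return d

    def to_json(self) -> str:
        """JSON export of the validated parameter set (provenance logging)."""
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


def _parse_value(field: str, raw: str):
    raw = raw.strip()
    if field == "stgorder":
        return tuple(s.strip() for s in raw.split(",") if s.strip())
    if field in ("distro_shape", "calctype"):
        return raw
    if field == "n_cohorts":
        try:
            return int(raw)
        except ValueError:
            raise ParamValidationError(f"n_cohorts: expected integer, got {raw!r}") from None
    if field == "obligate_diapause":
        if raw in ("1", "true", "True", "TRUE"):
            return True
        if raw in ("0", "false", "False", "FALSE"):
            return False
        raise ParamValidationError(f"obligate_diapause: expected 0/1 boolean, got {raw!r}")
    try:
        return float(raw)
    except ValueError:
        raise ParamValidationError(
            f"{_FIELD_TO_CODE.get(field, field)}: expected number, got {raw!r}"
        ) from None


def parse_params_text(text: str) -> tuple[dict, list[str]]:
    """Parse key=value text into a field dict; returns (fields, unknown_keys)."""
    fields: dict = {}
    unknown: list[str] = []
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ParamValidationError(f"line {lineno}: expected 'key = value', got {line!r}")
        key, raw = (s.strip() for s in line.split("=", 1))
        if key in _DERIVED_CODES:
            continue
        if key not in _CODE_TO_FIELD:
            unknown.append(key)
            continue
        field = _CODE_TO_FIELD[key]
        fields[field] = _parse_value(field, raw)
    return fields, unknown


def _default_fields() -> dict:
    text = resources.files("phenorisk.data").joinpath("eab.params").read_text()
    fields, unknown = parse_params_text(text)
    assert not unknown, f"packaged defaults contain unknown keys: {unknown}"
    return fields


def default_params() -> SpeciesParams:
    """The packaged emerald ash borer defaults."""
    return SpeciesParams(**_default_fields())


def load_params(path: str | Path, on_unknown=None) -> SpeciesParams:
    """Load and validate a parameter file; missing keys fall back to defaults.

    Parameters
    ----------
    path
        Parameter file (``key = value`` lines, ``#`` comments).
    on_unknown
        Optional callable invoked with the list of unrecognized keys; by
        default they are reported via a ``UserWarning``.
    """
    path = Path(path)
    fields, unknown = parse_params_text(path.read_text())
    if unknown:
        if on_unknown is not None:
            on_unknown(unknown)
        else:
            import warnings

            warnings.warn(f"ignoring unknown parameter keys: {unknown}", stacklevel=2)
    merged = {**_default_fields(), **fields}
    return SpeciesParams(**merged)


def serialize_params(params: SpeciesParams) -> str:
    """Canonical ``key = value`` form (stable key order, one pair per line)."""
    lines = []
    for code in _CODE_TO_FIELD:
        value = getattr(params, _CODE_TO_FIELD[code])
        if isinstance(value, tuple):
            value = ", ".join(value)
        elif isinstance(value, bool):
            value = int(value)
        elif isinstance(value, float) and value == int(value):
            value = int(value)
        lines.append(f"{code} = {value}")
    return "\n".join(lines) + "\n"
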