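"""Parameter handling: shipped defaults, override files, validation.

The default parameter set lives in ``data/params_default.yml`` as flat
key/value pairs grouped under section headers; the section structure is
documentation only — names are globally unique and the in-memory
:class:`ParameterSet` is a flat namespace.  Override documents may either
redefine every constant or declare ``inherit: default`` and list only the
entries they change (the usual way to run, e.g., the scavenger-inhibition
conditions ``{GR_scale: 0.15, TrxR_scale: 0.22}``).
"""

from __future__ import annotations

import hashlib
import io
import json
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import yaml

from .units import CompartmentLayout

#: parameters that may legitimately be zero (activity scale factors and
#: optional conductances); everything else must be strictly positive.
ZERO_ALLOWED: frozenset[str] = frozenset({
    "GR_scale", "TrxR_scale",
    "k_PCoA", "k_GSH_transport",
})

#: parameters that must be positive integers
INTEGER_PARAMS: frozenset[str] = frozenset({"pcoa_uncoupling_exponent"})


def _read_default_doc() -> dict[str, Any]:
    text = resources.files("mitobetaox.data").joinpath(
        "params_default.yml").read_text()
    return yaml.safe_load(text)


def _flatten(doc: Mapping[str, Any]) -> dict[str, float]:
    flat: dict[str, float] = {}
    for key, value in doc.items():
        if key == "inherit":
            continue
        if isinstance(value, Mapping):
            for name, v in value.items():
                if name in flat:
                    raise ValueError(f"duplicate parameter name {name!r}")
                flat[name] = v
        else:
            if key in flat:
                raise ValueError(f"duplicate parameter name {key!r}")
            flat[key] = value
    return flat


class ParameterSet:
    """Validated, immutable-by-convention flat parameter namespace."""

    def __init__(self, values: dict[str, float]):
        self.__dict__["_values"] = dict(values)

    def __getattr__(self, name: str) -> float:
        try:
            return self._values[name]
        except KeyError as exc:
            raise AttributeError(f"unknown parameter {name!r}") from exc

    def __setattr__(self, name: str, value: Any) -> None:
        raise TypeError(
            "ParameterSet is read-only; use .replace(name=value) instead")

    def __getitem__(self, name: str) -> float:
        return self._values[name]

    def __contains__(self, name: str) -> bool:
        return name in self._values

    def keys(self):
        return self._values.keys()

    def as_dict(self) -> dict[str, float]:
        return dict(self._values)

    def replace(self, **overrides: float) -> "ParameterSet":
        """Return a new set with the given entries replaced (validated)."""
        unknown = set(overrides) - set(self._values)
        if unknown:
            raise ValueError(f"unknown parameter name(s): {sorted(unknown)}")
        merged = {**self._values, **overrides}
        _validate(merged, reference=set(self._values))
        return ParameterSet(merged)

    @property
    def layout(self) -> CompartmentLayout:
        return CompartmentLayout(
            matrix_volume_fraction=1.0,
            extra_matrix_volume_fraction=self.volume_ratio_extra_to_matrix,
            mito_volume_per_mg_protein=self.mito_volume_per_mg_protein,
            membrane_capacitance=self.membrane_capacitance,
        )

    def provenance_hash(self) -> str:
        """Stable hash of the full parameter set, for output sidecars."""
        payload = json.dumps(self._values, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def __repr__(self) -> str:
        return f"ParameterSet({len(self._values)} parameters)"


def _validate(flat: dict[str, float], reference: set[str]) -> None:
    unknown = set(flat) - reference
    if unknown:
        raise ValueError(f"unknown parameter name(s): {sorted(unknown)}")
    missing = reference - set(flat)
    if missing:
        raise ValueError(f"missing parameter(s): {sorted(missing)}")
    for name, value in flat.items():
        if not isinstance(value, (int, float)) or isinstance(value, bool):
            raise ValueError(f"parameter {name!r} is not numeric: {value!r}")
        if name in INTEGER_PARAMS:
            if int(value) != value or value <= 0:
                raise ValueError(
                    f"parameter {name!r} must be a positive integer, "
                    f"got {value!r}")
        elif name in ZERO_ALLOWED:
            if value < 0:
                raise ValueError(
                    f"parameter {name!r} must be non-negative, got {value!r}")
        elif value <= 0:
            raise ValueError(
                f"parameter {name!r} must be strictly positive, got {value!r}")


def load_parameters(
    source: str | Path | Mapping[str, Any] | io.TextIOBase | None = None,
) -> ParameterSet:
    """Load and validate a parameter set.

    ``source`` may be None (shipped defaults), a mapping, a YAML path or an
    open text stream.  A document that declares ``inherit: default`` is
    merged over the shipped defaults; otherwise it must define every
    parameter.  Unknown names and non-positive constants are rejected with
    the offending name.
    """
    default_doc = _read_default_doc()
    default_flat = _flatten(default_doc)
    reference = set(default_flat)
    _validate(default_flat, reference)

    if source is None:
        return ParameterSet(default_flat)

    if isinstance(source, Mapping):
        doc: dict[str, Any] = dict(source)
    elif isinstance(source, io.TextIOBase):
        doc = yaml.safe_load(source.read()) or {}
    else:
        doc = yaml.safe_load(Path(source).read_text()) or {}

    flat = _flatten(doc)
    if doc.get("inherit") == "default":
        merged = {**default_flat, **flat}
    elif "inherit" in doc:
        raise ValueError(f"unknown inheritance target {doc['inherit']!r}")
    else:
        merged = flat
    _validate(merged, reference)
    return ParameterSet(merged)


def default_parameters() -> ParameterSet:
    return load_parameters(None)
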