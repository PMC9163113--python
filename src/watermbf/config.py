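"""Build configuration objects from plain dictionaries (YAML-friendly)."""

from __future__ import annotations

from dataclasses import fields, replace
from typing import Any

from .misalign import MisalignmentSpec
from .study import StudyConfig, enumerate_conditions
from .synth import AifParams, PhantomSpec, TruthParams

__all__ = ["phantom_spec_from_dict", "study_config_from_dict"]


def _tupled(value: Any) -> Any:
    return tuple(value) if isinstance(value, list) else value


def phantom_spec_from_dict(data: dict[str, Any]) -> PhantomSpec:
    """A :class:`PhantomSpec` from a (possibly partial) mapping.

    Unknown keys raise; ``territory_truth`` maps territory names to
    parameter mappings, ``aif`` is a mapping of AIF parameters.
    """
    data = dict(data)
    known = {f.name for f in fields(PhantomSpec)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown phantom spec keys: {sorted(unknown)}")
    if "territory_truth" in data:
        data["territory_truth"] = {
            name: TruthParams(**params)
            for name, params in data["territory_truth"].items()
        }
    if "aif" in data:
        data["aif"] = AifParams(**data["aif"])
    for key in (
        "grid_shape",
        "lv_outer_semiaxes_mm",
        "rv_center_offset_mm",
        "rv_semiaxes_mm",
    ):
        if key in data:
            data[key] = _tupled(data[key])
    return PhantomSpec(**data)


def study_config_from_dict(data: dict[str, Any]) -> StudyConfig:
    """A :class:`StudyConfig` from a mapping; nested phantom spec allowed.

    ``conditions`` may list mappings with ``dx_mm/dy_mm/dz_mm/label`` or
    bare labels drawn from the standard eleven-condition set.
    """
    data = dict(data)
    known = {f.name for f in fields(StudyConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown study config keys: {sorted(unknown)}")
    if "base_spec" in data:
        data["base_spec"] = phantom_spec_from_dict(data["base_spec"])
    if "conditions" in data:
        std = {c.label: c for c in enumerate_conditions()}
        conds = []
        for item in data["conditions"]:
            if isinstance(item, str):
                if item not in std:
                    raise ValueError(f"unknown condition label {item!r}")
                conds.append(std[item])
            else:
                conds.append(MisalignmentSpec(**item))
        data["conditions"] = tuple(conds)
    if "global_mbf_range" in data:
        data["global_mbf_range"] = _tupled(data["global_mbf_range"])
    return StudyConfig(**data)
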