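"""File-format glue: TIFF phantoms, trace/cohort CSV, metrics JSON.

Phantoms are written as two-page grayscale TIFF (page 1 autofluorescence,
page 2 second harmonic) with the physical pixel sizes stored in the TIFF
resolution tags (pixels per centimeter) and echoed in a sidecar JSON
ground-truth file. Output JSON documents are validated against the
schema files shipped under ``ectimetry/schemas``.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import numpy as np
import tifffile

from .errors import SchemaError
from .phantom import GroundTruth
from .trace import BoundaryTrace, CrossSection

__all__ = [
    "write_phantom",
    "read_phantom",
    "write_trace_csv",
    "write_metrics_json",
    "write_cohort_csv",
    "read_cohort_csv",
    "load_schema",
    "validate_json",
]

_UM_PER_CM = 10_000.0


def write_phantom(path, section: CrossSection, truth: GroundTruth | None = None) -> Path:
    """Write a cross-section as a two-page TIFF plus a sidecar JSON.

    The resolution tags carry pixels/cm (1e4 / pixel size in μm) for
    exact round-tripping; the sidecar ``<stem>.truth.json`` stores the
    pixel sizes and, when given, the ground truth.
    """
    path = Path(path)
    res = (_UM_PER_CM / section.px_lateral, _UM_PER_CM / section.px_axial)
    tifffile.imwrite(
        path,
        np.stack([section.channel_af, section.channel_shg]),
        resolution=res, resolutionunit="CENTIMETER",
        photometric="minisblack",
    )
    sidecar = {"px_lateral_um": section.px_lateral, "px_axial_um": section.px_axial}
    if truth is not None:
        sidecar["ground_truth"] = truth.to_dict()
    validate_json(sidecar, load_schema("groundtruth"))
    path.with_suffix(".truth.json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_phantom(path) -> CrossSection:
    """Read a two-page phantom TIFF; pixel sizes from the sidecar JSON if
    present, else from the TIFF resolution tags."""
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        pages = [p.asarray() for p in tf.pages]
        tags = tf.pages[0].tags
        xres, yres = tags["XResolution"].value, tags["YResolution"].value
    if len(pages) == 1 and pages[0].ndim == 3:
        pages = list(pages[0])
    if len(pages) != 2:
        raise ValueError(f"{path}: expected a two-page (AF, SHG) TIFF")
    sidecar = path.with_suffix(".truth.json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        px_lat, px_ax = meta["px_lateral_um"], meta["px_axial_um"]
    else:
        px_lat = _UM_PER_CM * xres[1] / xres[0]
        px_ax = _UM_PER_CM * yres[1] / yres[0]
    return CrossSection(channel_af=pages[0], channel_shg=pages[1],
                        px_lateral=px_lat, px_axial=px_ax)


def write_trace_csv(path, trace: BoundaryTrace) -> Path:
    """Trace polyline as CSV with columns column_x_um, depth_z_um."""
    import pandas as pd

    path = Path(path)
    pd.DataFrame(trace.points, columns=["column_x_um", "depth_z_um"]).to_csv(
        path, index=False, float_format="%.6f")
    return path


def write_metrics_json(path, trace: BoundaryTrace, seed: int | None = None,
                       extra: dict | None = None) -> Path:
    """Per-site metrics record {l_um, L_um, delta_L_um, delta_L_norm,
    parameters, seed}, validated against the metrics schema."""
    path = Path(path)
    record = trace.metrics_dict()
    record["parameters"] = {k: v for k, v in trace.meta.items()}
    record["seed"] = seed
    if extra:
        record.update(extra)
    validate_json(record, load_schema("metrics"))
    path.write_text(json.dumps(record, indent=1, sort_keys=True))
    return path


def write_cohort_csv(path, frame) -> Path:
    path = Path(path)
    frame.to_csv(path, index=False, float_format="%.6f")
    return path


def read_cohort_csv(path):
    import pandas as pd

    frame = pd.read_csv(path)
    required = {"site_id", "group", "delta_linearity"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: cohort CSV missing columns {sorted(missing)}")
    return frame


# --------------------------------------------------------------------------
# minimal JSON-schema validation (type / properties / required / items / enum)
# --------------------------------------------------------------------------

def load_schema(name: str) -> dict:
    """Load a published schema shipped with the package."""
    ref = resources.files("ectimetry") / "schemas" / f"{name}.schema.json"
    return json.loads(ref.read_text())


_TYPES = {
    "object": dict, "array": list, "string": str,
    "number": (int, float), "integer": int, "boolean": bool,
    "null": type(None),
}


def validate_json(obj, schema: dict, path: str = "$") -> None:
    """Validate ``obj`` against the subset of JSON Schema used by the
    published output schemas; raises :class:`SchemaError` on mismatch."""
    t = schema.get("type")
    if t is not None:
        types = t if isinstance(t, list) else [t]
        if not any(isinstance(obj, _TYPES[tt]) and not
                   (tt in ("number", "integer") and isinstance(obj, bool))
                   for tt in types):
            raise SchemaError(f"{path}: expected type {t}, got {type(obj).__name__}")
    if "enum" in schema and obj not in schema["enum"]:
        raise SchemaError(f"{path}: {obj!r} not in enum {schema['enum']}")
    if isinstance(obj, dict):
        for key in schema.get("required", []):
            if key not in obj:
                raise SchemaError(f"{path}: missing required key {key!r}")
        props = schema.get("properties", {})
        for key, sub in props.items():
            if key in obj:
                validate_json(obj[key], sub, f"{path}.{key}")
        if schema.get("additionalProperties") is False:
            extra = set(obj) - set(props)
            if extra:
                raise SchemaError(f"{path}: unexpected keys {sorted(extra)}")
    if isinstance(obj, list) and "items" in schema:
        for i, item in enumerate(obj):
            validate_json(item, schema["items"], f"{path}[{i}]")
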