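"""Exception hierarchy for the ectimetry pipeline.

Every operational failure raises a subclass of :class:`EctimetryError` so
that callers (and the CLI) can distinguish pipeline failures from
programming errors.
"""


class EctimetryError(Exception):
    """Base class for all ectimetry pipeline errors."""


class GeometryError(EctimetryError):
    """Inconsistent physical geometry (boundary below field of view,
    boundary above surface, zero-length chord, ...)."""


class PackingError(EctimetryError):
    """Requested hard-core nucleus density is infeasible or placement
    failed to converge."""


class DegenerateImageError(EctimetryError):
    """Image content does not support the requested operation
    (constant image under automatic thresholding, dark image under
    surface detection)."""


class ExtractionError(EctimetryError):
    """Per-column boundary candidate extraction failed (too many gap
    columns)."""


class TracingError(EctimetryError):
    """Minimal-cost boundary tracing failed (no path, or a gap wider
    than the bridging ceiling)."""


class UnsupportedModelError(EctimetryError):
    """Analytic operation requested on a stochastic boundary model."""


class ConfigError(EctimetryError):
    """Invalid run configuration (unknown key, missing seed, bad value)."""


class SchemaError(EctimetryError):
    """A JSON document does not conform to its published schema."""
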