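"""Synthetic phantoms with known ECTI geometry and simulated cohorts.

The generators here stand in for in-vivo two-channel nonlinear-microscopy
data: cross-sectional frames carrying an autofluorescence channel
(keratin band, epithelium, lamina propria) and a second-harmonic channel
that is dark above the epithelial-connective tissue interface (ECTI) and
textured below it, en-face frames of bright cytoplasm with dark nuclei,
and per-site ΔLinearity cohorts drawn from published group distributions.
Every phantom carries a :class:`GroundTruth` record so downstream
extraction stages can be tested against an analytic oracle.

Geometry convention: x is lateral (columns), z is depth (rows), z
increases downward from the tissue surface at z = 0; physical positions
are in μm via (px_lateral, px_axial).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage, stats

from .errors import GeometryError, PackingError, UnsupportedModelError, ConfigError

__all__ = [
    "BoundaryModel",
    "NoiseModel",
    "PhantomParams",
    "GroundTruth",
    "CohortSpec",
    "CohortSample",
    "IMAGING_COHORT_SPECS",
    "HISTOLOGY_COHORT_SPECS",
    "boundary_profile",
    "true_delta_linearity",
    "curve_delta_linearity",
    "render_phantom",
    "render_enface",
    "sample_cohort",
]


# --------------------------------------------------------------------------
# boundary model
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class BoundaryModel:
    """Analytic depth profile z(x) of the ECTI below the tissue surface.

    The profile is a flat baseline plus a sinusoidal undulation plus
    Gaussian "rete ridge" bumps, all directed deeper into the tissue
    (positive sine crests and positive bump amplitudes increase depth),
    optionally with small-scale Gaussian jitter.

    Parameters
    ----------
    baseline_depth:
        Depth in μm of the flat interface below the surface (z = 0).
    sine_amplitude, sine_period:
        Amplitude and period in μm of the sinusoidal undulation; the
        crest of the sine goes *deeper* (larger z).
    bumps:
        Tuple of ``(center_um, amplitude_um, width_um)`` Gaussian
        protrusions directed downward into the lamina propria.
    roughness_sd:
        Standard deviation in μm of per-sample jitter; 0 gives a fully
        analytic (deterministic) model.
    """

    baseline_depth: float
    sine_amplitude: float = 0.0
    sine_period: float = 0.0
    bumps: tuple[tuple[float, float, float], ...] = ()
    roughness_sd: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.baseline_depth) or self.baseline_depth <= 0:
            raise ValueError("baseline_depth must be positive and finite")
        if self.sine_amplitude > 0 and self.sine_period <= 0:
            raise ValueError("sine_period must be positive when sine_amplitude > 0")
        if self.sine_amplitude < 0 or self.roughness_sd < 0:
            raise ValueError("amplitudes and roughness_sd must be non-negative")
        for center, amp, width in self.bumps:
            if width <= 0:
                raise ValueError("bump widths must be positive")
            if not np.isfinite([center, amp, width]).all():
                raise ValueError("bump parameters must be finite")

    @property
    def is_stochastic(self) -> bool:
        return self.roughness_sd > 0

    def depth(self, x: np.ndarray) -> np.ndarray:
        """Deterministic part of the depth profile, μm."""
        x = np.asarray(x, dtype=float)
        z = np.full_like(x, self.baseline_depth)
        if self.sine_amplitude > 0:
            z = z + self.sine_amplitude * np.sin(2.0 * np.pi * x / self.sine_period)
        for center, amp, width in self.bumps:
            z = z + amp * np.exp(-0.5 * ((x - center) / width) ** 2)
        return z

    def slope(self, x: np.ndarray) -> np.ndarray:
        """Analytic derivative dz/dx of the deterministic profile."""
        x = np.asarray(x, dtype=float)
        s = np.zeros_like(x)
        if self.sine_amplitude > 0:
            k = 2.0 * np.pi / self.sine_period
            s = s + self.sine_amplitude * k * np.cos(k * x)
        for center, amp, width in self.bumps:
            u = (x - center) / width
            s = s - amp * u / width * np.exp(-0.5 * u * u)
        return s


def boundary_profile(
    model: BoundaryModel,
    x_positions: np.ndarray,
    fov_width: float | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Evaluate the boundary depth (μm) at lateral positions ``x_positions``.

    Jitter (``roughness_sd``) is added only when a generator is supplied;
    without one the evaluation is deterministic.

    Raises
    ------
    GeometryError
        If any position is negative or, when ``fov_width`` is given,
        outside ``[0, fov_width]``.
    """
    x = np.atleast_1d(np.asarray(x_positions, dtype=float))
    if np.any(x < 0) or (fov_width is not None and np.any(x > fov_width)):
        raise GeometryError("lateral position outside the field of view")
    z = model.depth(x)
    if model.roughness_sd > 0 and rng is not None:
        z = z + rng.normal(0.0, model.roughness_sd, size=x.shape)
    return z


def curve_delta_linearity(depth_fn, slope_fn, width: float, n: int = 200_001) -> float:
    """(arc − chord)/chord for a depth profile on [0, width] by quadrature.

    The arc length is the trapezoid integral of sqrt(1 + z'(x)^2) on
    ``n`` uniformly spaced samples; the chord joins the curve endpoints.
    """
    x = np.linspace(0.0, width, n)
    arc = np.trapezoid(np.sqrt(1.0 + np.asarray(slope_fn(x)) ** 2), x)
    z0, z1 = float(depth_fn(np.array([0.0]))[0]), float(depth_fn(np.array([width]))[0])
    chord = float(np.hypot(width, z1 - z0))
    return (arc - chord) / chord


def true_delta_linearity(model: BoundaryModel, fov_width: float, n: int = 200_001) -> float:
    """Quadrature oracle for the ΔLinearity statistic of an analytic model.

    Computes arc length by dense numerical quadrature of
    sqrt(1 + (dz/dx)^2) over [0, fov_width] using the model's analytic
    derivative, and returns (arc − chord)/chord, the normalized deviation
    of the interface from a straight line.

    Raises
    ------
    UnsupportedModelError
        For stochastic models (``roughness_sd > 0``).
    """
    if model.is_stochastic:
        raise UnsupportedModelError("ΔLinearity oracle requires roughness_sd = 0")
    if fov_width <= 0:
        raise GeometryError("fov_width must be positive")
    if n < 100_000:
        n = 100_001
    return curve_delta_linearity(model.depth, model.slope, fov_width, n=n)


# --------------------------------------------------------------------------
# raster phantoms
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class NoiseModel:
    """Detector noise: additive Gaussian plus signal-dependent shot noise.

    ``poisson_gain`` is the intensity step per detected photon; the shot
    component replaces each pixel value v by gain * Poisson(v / gain).
    Either component can be disabled by setting it to 0.
    """

    gaussian_sd: float = 2.0
    poisson_gain: float = 0.25

    def apply(self, img: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        out = np.asarray(img, dtype=float)
        if self.poisson_gain > 0:
            out = self.poisson_gain * rng.poisson(np.clip(out, 0, None) / self.poisson_gain)
        if self.gaussian_sd > 0:
            out = out + rng.normal(0.0, self.gaussian_sd, size=out.shape)
        return out


@dataclass(frozen=True)
class PhantomParams:
    """Acquisition geometry and intensity levels of a synthetic frame.

    Defaults reproduce the acquisition used throughout: 512×512 pixels at
    0.625 μm/pixel lateral (320×320 μm field of view), 1 μm axial steps,
    8-bit intensities, and a ~10 μm keratin band at the surface.
    """

    fov_width: float = 320.0
    fov_depth: float = 320.0
    px_lateral: float = 0.625
    px_axial: float = 1.0
    keratin_thickness: float = 10.0
    level_keratin: float = 220.0
    level_epithelium: float = 110.0
    level_lamina_af: float = 90.0
    level_lamina_shg: float = 140.0
    noise: NoiseModel = field(default_factory=NoiseModel)
    texture_sd: float = 0.25
    render_nuclei: bool = False
    bit_depth: int = 8
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fov_width", "fov_depth", "px_lateral", "px_axial"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("level_keratin", "level_epithelium", "level_lamina_af", "level_lamina_shg"):
            v = getattr(self, name)
            if not 0 <= v <= 255:
                raise ValueError(f"{name} must lie in [0, 255]")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        for fov, px, axis in ((self.fov_width, self.px_lateral, "lateral"),
                              (self.fov_depth, self.px_axial, "axial")):
            npix = fov / px
            if abs(npix - round(npix)) > 1e-9 or round(npix) < 1:
                raise ValueError(f"{axis} FOV is not an integer number of pixels")

    @property
    def shape(self) -> tuple[int, int]:
        """(rows, cols) = (depth, lateral) raster dimensions."""
        return int(round(self.fov_depth / self.px_axial)), int(round(self.fov_width / self.px_lateral))


@dataclass
class GroundTruth:
    """Analytic truth attached to a phantom, the oracle for recovery tests."""

    boundary_model: BoundaryModel | None = None
    true_delta_linearity: float = float("nan")
    true_surface_depth: np.ndarray | None = None     # μm per lateral position
    true_thickness_profile: np.ndarray | None = None  # μm per lateral position
    true_nucleus_centers: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))

    def to_dict(self) -> dict:
        d = {
            "true_delta_linearity": None if np.isnan(self.true_delta_linearity)
            else float(self.true_delta_linearity),
            "true_nucleus_centers": np.asarray(self.true_nucleus_centers).tolist(),
        }
        if self.boundary_model is not None:
            m = self.boundary_model
            d["boundary_model"] = {
                "baseline_depth": m.baseline_depth,
                "sine_amplitude": m.sine_amplitude,
                "sine_period": m.sine_period,
                "bumps": [list(b) for b in m.bumps],
                "roughness_sd": m.roughness_sd,
            }
        if self.true_surface_depth is not None:
            d["true_surface_depth"] = np.asarray(self.true_surface_depth).tolist()
        if self.true_thickness_profile is not None:
            d["true_thickness_profile"] = np.asarray(self.true_thickness_profile).tolist()
        return d


def _texture(shape: tuple[int, int], sd: float, rng: np.random.Generator,
             corr_px: float = 2.0) -> np.ndarray:
    """Smooth multiplicative fibrous texture field with mean ~1."""
    if sd <= 0:
        return np.ones(shape)
    raw = rng.normal(0.0, 1.0, size=shape)
    sm = ndimage.gaussian_filter(raw, corr_px)
    sm *= sd / max(sm.std(), 1e-12)
    return np.clip(1.0 + sm, 0.2, 1.8)


def _quantize(img: np.ndarray, bit_depth: int) -> np.ndarray:
    if bit_depth == 8:
        return np.clip(np.rint(img), 0, 255).astype(np.uint8)
    # 16-bit output keeps the 8-bit level scale in the low byte range
    return np.clip(np.rint(img), 0, 65535).astype(np.uint16)


def render_phantom(params: PhantomParams, model: BoundaryModel):
    """Render a two-channel cross-sectional phantom with known geometry.

    Channel 1 (autofluorescence): bright keratin band at the surface,
    moderate epithelium, textured lamina propria below the boundary.
    Channel 2 (second harmonic): exactly zero above the true boundary
    before noise, textured fibrous band below it.

    Returns
    -------
    (CrossSection, GroundTruth)
        The rendered section and its analytic truth. Identical params
        (including ``rng_seed``) give bit-identical output.
    """
    from .trace import CrossSection  # local import to avoid a cycle

    nz, nx = params.shape
    if nz < 64 or nx < 64:
        raise ValueError("raster dimensions must be at least 64x64")
    if params.keratin_thickness >= model.baseline_depth:
        raise GeometryError("keratin_thickness must be smaller than baseline_depth")

    rng = np.random.default_rng(params.rng_seed)
    x = (np.arange(nx) + 0.5) * params.px_lateral
    z = (np.arange(nz) + 0.5) * params.px_axial
    b = boundary_profile(model, x, fov_width=params.fov_width, rng=rng)
    if np.max(b) >= params.fov_depth:
        raise GeometryError("boundary reaches below the field of view")
    if np.min(b) <= params.keratin_thickness:
        raise GeometryError("boundary rises into the keratin band")

    zz = z[:, None]
    below = zz >= b[None, :]

    af = np.where(zz < params.keratin_thickness, params.level_keratin,
                  params.level_epithelium)
    af = np.where(below, params.level_lamina_af * _texture((nz, nx), params.texture_sd, rng), af)
    if params.render_nuclei:
        af = _stamp_cross_section_nuclei(af, below, zz, params, rng)
    # partial-volume weighting at the interface: a detector pixel integrates
    # signal over its axial extent, so the boundary-crossing pixel carries the
    # covered fraction; pixels wholly above the boundary stay exactly zero
    frac_below = np.clip((zz - b[None, :]) / params.px_axial + 0.5, 0.0, 1.0)
    shg = params.level_lamina_shg * _texture((nz, nx), params.texture_sd, rng) * frac_below

    af = _quantize(params.noise.apply(af, rng), params.bit_depth)
    shg = _quantize(params.noise.apply(shg, rng), params.bit_depth)

    truth = GroundTruth(
        boundary_model=model,
        true_delta_linearity=(true_delta_linearity(model, params.fov_width)
                              if not model.is_stochastic else float("nan")),
        true_surface_depth=np.zeros(nx),
        true_thickness_profile=b.copy(),
    )
    section = CrossSection(channel_af=af, channel_shg=shg,
                           px_lateral=params.px_lateral, px_axial=params.px_axial)
    return section, truth


def _stamp_cross_section_nuclei(af, below, zz, params, rng):
    """Optionally sprinkle dark elliptical nuclei through the epithelium."""
    nz, nx = af.shape
    n = max(1, int(nz * nx * params.px_lateral * params.px_axial / 4000))
    xs = rng.uniform(0, nx, n)
    zs = rng.uniform(params.keratin_thickness / params.px_axial, nz, n)
    xx = np.arange(nx)[None, :]
    out = af.astype(float).copy()
    for cx, cz in zip(xs, zs):
        mask = (((xx - cx) / (5.0 / params.px_lateral)) ** 2
                + ((zz / params.px_axial - cz) / (3.0 / params.px_axial)) ** 2) <= 1.0
        mask &= ~below
        out[mask] = 0.45 * params.level_epithelium
    return out


# --------------------------------------------------------------------------
# en-face phantoms (nuclei)
# --------------------------------------------------------------------------

_MAX_PACKING_FRACTION = 0.45  # practical hard-core dart-throwing limit


def render_enface(
    density: float,
    nucleus_diameter: tuple[float, float],
    fov: float,
    params: PhantomParams,
):
    """Render an en-face frame: bright cytoplasm with dark hard-core nuclei.

    Parameters
    ----------
    density:
        Expected nuclei per 100 μm².
    nucleus_diameter:
        (min, max) nucleus diameter in μm; each nucleus draws a uniform
        diameter from this range.
    fov:
        Side length of the square frame in μm.

    Returns
    -------
    (raster, GroundTruth)
        8/16-bit raster and the true nucleus centers in μm.

    Raises
    ------
    PackingError
        If the requested density exceeds the hard-core feasibility bound
        (area fraction > 0.45 at the maximum diameter) or placement fails.
    """
    dmin, dmax = float(nucleus_diameter[0]), float(nucleus_diameter[1])
    if density < 0:
        raise ValueError("density must be non-negative")
    if dmin <= 0 or dmax < dmin:
        raise ValueError("nucleus diameters must be positive with min <= max")
    npx = fov / params.px_lateral
    if abs(npx - round(npx)) > 1e-9:
        raise ValueError("fov is not an integer number of pixels")
    npx = int(round(npx))

    n_target = int(round(density * fov * fov / 100.0))
    frac = n_target * np.pi * (dmax / 2.0) ** 2 / (fov * fov)
    if frac > _MAX_PACKING_FRACTION:
        raise PackingError(
            f"hard-core packing infeasible: area fraction {frac:.2f} "
            f"exceeds {_MAX_PACKING_FRACTION}")

    rng = np.random.default_rng(params.rng_seed)
    centers: list[tuple[float, float]] = []
    diams: list[float] = []
    r_margin = dmax / 2.0
    attempts = 0
    while len(centers) < n_target:
        attempts += 1
        if attempts > 2000 * max(n_target, 1):
            raise PackingError("hard-core placement did not converge")
        p = rng.uniform(r_margin, fov - r_margin, 2)
        if all((p[0] - c[0]) ** 2 + (p[1] - c[1]) ** 2 >= dmax * dmax for c in centers):
            centers.append((p[0], p[1]))
            diams.append(rng.uniform(dmin, dmax))

    bg = 200.0
    img = bg * _texture((npx, npx), params.texture_sd * 0.4, rng, corr_px=4.0)
    if centers:
        yy, xx = np.meshgrid((np.arange(npx) + 0.5) * params.px_lateral,
                             (np.arange(npx) + 0.5) * params.px_lateral,
                             indexing="ij")
        for (cx, cy), d in zip(centers, diams):
            r = d / 2.0
            dist = np.hypot(xx - cx, yy - cy)
            # soft 1 μm rim so nuclei are dark blobs, not hard disks
            w = np.clip((r - dist) / 1.0, 0.0, 1.0)
            img = img * (1 - w) + 55.0 * w

    img = _quantize(params.noise.apply(img, rng), params.bit_depth)
    truth = GroundTruth(true_nucleus_centers=np.array(centers).reshape(-1, 2))
    return img, truth


# --------------------------------------------------------------------------
# cohort simulation
# --------------------------------------------------------------------------

_GROUPS = ("normal", "mild", "moderate", "severe", "dysplasia-pooled")
_FAMILIES = ("truncated-gaussian", "lognormal", "point-mass")


@dataclass(frozen=True)
class CohortSpec:
    """Target ΔLinearity distribution for one histological group."""

    group_name: str
    n_sites: int
    distribution_family: str
    target_mean: float
    target_sd: float
    modality: str = "imaging"

    def __post_init__(self) -> None:
        if self.group_name not in _GROUPS:
            raise ConfigError(f"unknown group name: {self.group_name!r}")
        if self.distribution_family not in _FAMILIES:
            raise ConfigError(f"unknown distribution family: {self.distribution_family!r}")
        if self.n_sites < 1:
            raise ConfigError("n_sites must be >= 1")
        if self.target_sd < 0:
            raise ConfigError("target_sd must be >= 0")
        if self.distribution_family == "lognormal" and self.target_mean <= 0:
            raise ConfigError("lognormal target_mean must be > 0")
        if self.distribution_family == "point-mass" and self.target_sd > 0:
            raise ConfigError("point-mass family requires target_sd = 0")


@dataclass(frozen=True)
class CohortSample:
    """One imaged site: group label and its measured quantities."""

    site_id: str
    group: str
    delta_linearity: float
    thickness_um: float | None = None
    modality: str = "imaging"


# Published group distribution parameters (mean, SD) of ΔLinearity for the
# pooled normal-vs-dysplasia comparison, per imaging and histology readouts.
IMAGING_COHORT_SPECS = (
    CohortSpec("normal", 33, "truncated-gaussian", 0.11, 0.04, modality="imaging"),
    CohortSpec("dysplasia-pooled", 27, "lognormal", 0.41, 0.24, modality="imaging"),
)
HISTOLOGY_COHORT_SPECS = (
    CohortSpec("normal", 33, "truncated-gaussian", 0.09, 0.03, modality="histology"),
    CohortSpec("dysplasia-pooled", 27, "lognormal", 0.28, 0.16, modality="histology"),
)

# Per-grade means/SDs as printed alongside the pooled values; exposed as
# alternative generator settings (the two sets are not mutually consistent
# for every grade and are deliberately both available).
PER_GRADE_IMAGING = {
    "normal": (0.11, 0.04), "mild": (0.31, 0.17),
    "moderate": (0.45, 0.29), "severe": (0.41, 0.22),
}
PER_GRADE_HISTOLOGY = {
    "normal": (0.09, 0.03), "mild": (0.14, 0.04),
    "moderate": (0.29, 0.10), "severe": (0.38, 0.19),
}


def _draw(spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    m, s, n = spec.target_mean, spec.target_sd, spec.n_sites
    if spec.distribution_family == "point-mass":
        return np.full(n, m)
    if spec.distribution_family == "truncated-gaussian":
        if s == 0:
            return np.full(n, m)
        a = (0.0 - m) / s  # truncate at 0; (m, s) are the parent parameters
        return stats.truncnorm.rvs(a, np.inf, loc=m, scale=s, size=n, random_state=rng)
    # lognormal, moment-matched so the *untruncated* mean and sd hit targets
    sigma2 = np.log1p((s / m) ** 2)
    mu = np.log(m) - sigma2 / 2.0
    return rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=n)


def sample_cohort(specs, seed: int | np.random.Generator) -> list[CohortSample]:
    """Draw per-site ΔLinearity values for each group spec.

    Values are non-negative by construction (truncation at 0 for the
    Gaussian family, support of the lognormal) and reproducible for a
    fixed seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    samples: list[CohortSample] = []
    for spec in specs:
        values = _draw(spec, rng)
        for i, v in enumerate(values):
            samples.append(CohortSample(
                site_id=f"{spec.modality[:4]}-{spec.group_name}-{i:03d}",
                group=spec.group_name,
                delta_linearity=float(v),
                modality=spec.modality,
            ))
    return samples


def cohort_to_frame(samples) -> "pandas.DataFrame":  # noqa: F821
    """Tabulate a cohort as the CSV row layout used by the statistics stage."""
    import pandas as pd

    return pd.DataFrame(
        [(s.site_id, s.group, s.modality, s.delta_linearity, s.thickness_um)
         for s in samples],
        columns=["site_id", "group", "modality", "delta_linearity", "thickness_um"],
    )
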