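"""Synthetic axial brain-slice phantoms and simulated index cohorts.

Nothing in a retrospective neonatal imaging study ships with reusable data,
so this module provides two synthetic stand-ins that make every other
module testable end to end:

* :func:`make_phantom` draws a single axial slice: a bright elliptical
  "brain" on a dark background, containing dark CSF-filled lateral-ventricle
  structures (paired tapered anterior-horn wedges, paired parallel body
  bands whose medial margins form the caudate-level walls).  The ventricular
  geometry is parameterized directly by the physical spans that the
  morphometric indices measure, so the ground-truth index values are known
  in closed form.  The gray-level scene is smoothed by a small Gaussian PSF
  (emulating partial volume at structure boundaries), modulated by a smooth
  multiplicative bias field, and corrupted by additive Gaussian noise.  The
  ground-truth masks are noise-free and depend only on the geometry.

* :func:`sample_cohort` draws per-subject index values from per-group
  normal distributions (mean/SD per index), reproducing the statistical
  structure of a reported two-group neonatal cohort; built-in reference
  parameters for a congenital-heart-disease group (n=150) and a control
  group (n=50) are provided.  :func:`simulate_raters` adds two noisy rater
  columns with a known generating intraclass correlation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import ndimage

from .morphometry import IndexMeasurements
from .segmentation import GrayImage

logger = logging.getLogger(__name__)


class PhantomError(ValueError):
    """Raised when a phantom specification is geometrically infeasible."""


# ---------------------------------------------------------------------------
# single-slice phantom
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and appearance of one synthetic axial slice.

    Distances are in mm; intensities in gray levels.  Rows run
    anterior (row 0) to posterior; spans run left-right along rows.

    The four ventricular spans map one-to-one onto the morphometric
    numerators: ``frontal_horn_span`` -> F, ``body_outer_span`` -> D,
    ``caudate_span`` -> C (medial wall-to-wall), ``max_frontal_width`` ->
    the Evans numerator (must equal the widest ventricular span, which with
    this geometry is the horn span).
    """

    image_height: int = 128
    image_width: int = 128
    pixel_spacing: float = 1.0
    brain_semi_axes: tuple[float, float] = (55.0, 40.0)  # (AP, transverse) mm
    frontal_horn_span: float = 20.0
    body_outer_span: float = 18.0
    caudate_span: float = 10.0
    max_frontal_width: float = 20.0
    horn_level_row: int = 31
    ventricle_top_row: int = 25
    body_top_row: int = 35
    body_bottom_row: int = 61
    horn_thickness: float = 3.0  # wedge wall thickness, mm
    tissue_intensity: int = 150
    csf_intensity: int = 60
    background_intensity: int = 15
    noise_sigma: float = 8.0
    bias_amplitude: float = 0.05
    psf_sigma: float = 1.0  # partial-volume smoothing, mm
    gray_levels: int = 256
    seed: int = 0

    def __post_init__(self) -> None:
        a, b = self.brain_semi_axes
        if self.pixel_spacing <= 0:
            raise PhantomError("pixel_spacing must be positive")
        if a <= 0 or b <= 0:
            raise PhantomError("brain semi-axes must be positive")
        if not self.csf_intensity < self.tissue_intensity:
            raise PhantomError("csf_intensity must be below tissue_intensity")
        if self.noise_sigma < 0 or self.bias_amplitude < 0 or self.psf_sigma < 0:
            raise PhantomError("noise, bias and PSF parameters must be >= 0")
        for name in ("tissue_intensity", "csf_intensity", "background_intensity"):
            v = getattr(self, name)
            if not 0 <= v < self.gray_levels:
                raise PhantomError(f"{name} outside [0, {self.gray_levels - 1}]")
        rows_ok = (
            0
            <= self.ventricle_top_row
            < self.horn_level_row
            < self.body_top_row
            <= self.body_bottom_row
            < self.image_height
        )
        if not rows_ok:
            raise PhantomError("landmark rows must be ordered within the image")
        for name in (
            "frontal_horn_span",
            "body_outer_span",
            "caudate_span",
            "max_frontal_width",
        ):
            if getattr(self, name) <= 0:
                raise PhantomError(f"{name} must be positive")
        if self.caudate_span >= self.body_outer_span:
            raise PhantomError("caudate_span must be smaller than body_outer_span")
        if self.max_frontal_width < self.frontal_horn_span:
            raise PhantomError("max_frontal_width below frontal_horn_span")
        # every span must fit inside the brain ellipse at its level
        for name, row in (
            ("frontal_horn_span", self.horn_level_row),
            ("body_outer_span", self.body_top_row),
        ):
            w = self.brain_width_at(row)
            if getattr(self, name) >= w:
                raise PhantomError(
                    f"{name}={getattr(self, name):.2f} mm does not fit inside the "
                    f"brain (width {w:.2f} mm at row {row})"
                )

    # -- analytic geometry ---------------------------------------------------

    @property
    def row_center(self) -> float:
        return (self.image_height - 1) / 2.0

    @property
    def col_center(self) -> float:
        return (self.image_width - 1) / 2.0

    def brain_width_at(self, row: int) -> float:
        """Transverse brain diameter (mm) of the ellipse at an image row."""
        a, b = self.brain_semi_axes
        d = (row - self.row_center) * self.pixel_spacing
        inside = 1.0 - (d / a) ** 2
        if inside <= 0:
            raise PhantomError(f"row {row} lies outside the brain ellipse")
        return 2.0 * b * math.sqrt(inside)

    def measurement_row(self) -> int:
        """The row where D and C are defined: first body row in the posterior
        window of the ventricular extent (mirrors the measurement rule)."""
        extent = self.body_bottom_row - self.ventricle_top_row + 1
        post_start = self.ventricle_top_row + math.ceil(extent / 3.0)
        if post_start <= self.horn_level_row:
            raise PhantomError("horn level falls outside the anterior third")
        if post_start > self.body_bottom_row:
            raise PhantomError("posterior window empty; extend the body segment")
        return max(self.body_top_row, post_start)

    def true_indices(self) -> IndexMeasurements:
        """Closed-form ground-truth ratios implied by the specification."""
        mrow = self.measurement_row()
        return IndexMeasurements(
            f_ratio=self.frontal_horn_span / self.brain_width_at(self.horn_level_row),
            d_ratio=self.body_outer_span / self.brain_width_at(mrow),
            c_ratio=self.caudate_span / self.brain_width_at(mrow),
            evans=self.max_frontal_width / (2.0 * self.brain_semi_axes[1]),
        )


@dataclass(frozen=True)
class Phantom:
    """A rendered slice plus its noise-free ground truth."""

    image: GrayImage
    brain_mask: np.ndarray
    ventricle_mask: np.ndarray
    true_indices: IndexMeasurements
    landmark_rows: dict = field(default_factory=dict)


def _even_px(span_mm: float, spacing: float) -> int:
    """Nearest even pixel count realizing a span, at least 2.

    Structures are centered on the inter-column midline ``(W - 1) / 2``; an
    even pixel count keeps them mirror-symmetric on an even-width grid.
    """
    return max(2, 2 * int(round(span_mm / (2.0 * spacing))))


def make_phantom(spec: PhantomSpec) -> Phantom:
    """Render a phantom slice and its ground-truth masks from a spec.

    The masks are purely geometric: independent of noise_sigma, bias, PSF
    and seed.  The image is the three-level scene (background / tissue /
    CSF) smoothed by the PSF, multiplied by a left-right symmetric smooth
    bias field of relative amplitude ``bias_amplitude``, plus zero-mean
    Gaussian noise of SD ``noise_sigma``, quantized to integer gray levels.
    """
    H, W, sp = spec.image_height, spec.image_width, spec.pixel_spacing
    a, b = spec.brain_semi_axes
    r = np.arange(H)[:, None]
    c = np.arange(W)[None, :]
    r0, c0 = spec.row_center, spec.col_center

    brain = ((r - r0) * sp / a) ** 2 + ((c - c0) * sp / b) ** 2 <= 1.0

    dc = np.abs(c - c0)  # half-integer distances from the midline
    vent = np.zeros((H, W), dtype=bool)

    # anterior horns: paired wedges tapering from a point to the horn span
    k_f = _even_px(spec.frontal_horn_span, sp)
    thick_px = max(2.0, spec.horn_thickness / sp)
    n_wedge = spec.horn_level_row - spec.ventricle_top_row
    for row in range(spec.ventricle_top_row, spec.horn_level_row + 1):
        frac = (row - spec.ventricle_top_row) / n_wedge if n_wedge else 1.0
        outer_half = 0.5 + ((k_f - 1) / 2.0 - 0.5) * frac
        inner_half = max(outer_half - thick_px, 0.5)
        vent[row] |= (dc[0] >= inner_half - 1e-9) & (dc[0] <= outer_half + 1e-9)

    # bodies: paired parallel bands; medial margins are the caudate walls
    k_d = _even_px(spec.body_outer_span, sp)
    k_c = _even_px(spec.caudate_span, sp)
    if k_d - k_c < 2:
        raise PhantomError(
            f"body_outer_span={spec.body_outer_span:.2f} mm leaves no room for "
            f"a body wall outside caudate_span={spec.caudate_span:.2f} mm"
        )
    band = (dc[0] >= (k_c - 1) / 2.0 - 1e-9) & (dc[0] <= (k_d - 1) / 2.0 + 1e-9)
    vent[spec.body_top_row : spec.body_bottom_row + 1] |= band

    if np.any(vent & ~brain):
        raise PhantomError(
            "ventricle structures leave the brain ellipse; shrink "
            "frontal_horn_span/body_outer_span or the landmark rows"
        )

    scene = np.full((H, W), float(spec.background_intensity))
    scene[brain] = spec.tissue_intensity
    scene[vent] = spec.csf_intensity
    if spec.psf_sigma > 0:
        scene = ndimage.gaussian_filter(scene, sigma=spec.psf_sigma / sp)
    if spec.bias_amplitude > 0:
        bias = 1.0 + spec.bias_amplitude * (
            np.cos(np.pi * (r - r0) / (H - 1)) * np.cos(np.pi * (c - c0) / (W - 1))
        )
        scene = scene * bias
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        scene = scene + rng.normal(0.0, spec.noise_sigma, size=scene.shape)
    values = np.clip(np.round(scene), 0, spec.gray_levels - 1).astype(np.int64)

    mrow = spec.measurement_row()
    return Phantom(
        image=GrayImage(values, pixel_spacing=sp, gray_levels=spec.gray_levels),
        brain_mask=brain,
        ventricle_mask=vent,
        true_indices=spec.true_indices(),
        landmark_rows={
            "horn": spec.horn_level_row,
            "body": mrow,
            "caudate": mrow,
        },
    )


def spec_from_ratios(
    f_ratio: float,
    d_ratio: float,
    c_ratio: float,
    evans: float,
    reconcile: bool = True,
    **overrides,
) -> PhantomSpec:
    """Construct a PhantomSpec whose ground-truth ratios approximate targets.

    The Evans denominator is the widest brain diameter while F' is the brain
    width at the horn level, so requesting both ``f_ratio`` and ``evans``
    fixes the horn row: ``w(horn) / w_max = evans / f_ratio``.  Spans are
    then snapped to even pixel counts, which moves the realized ratios by at
    most one pixel relative to the request; the returned spec's
    :meth:`PhantomSpec.true_indices` are exact for the snapped geometry.

    Independently drawn index values can be jointly infeasible: the Evans
    numerator is the *maximal* ventricular span, so it can never fall below
    the body span implied by ``d_ratio``, and the caudate gap must fit
    inside the bodies.  With ``reconcile=True`` (the default) Evans and C
    are nudged to the nearest feasible values while F and D are realized
    exactly; with ``reconcile=False`` infeasible requests raise.

    ``overrides`` may adjust any appearance field (noise_sigma, seed, ...)
    and the wedge/body layout (``wedge_rows``, ``horn_body_gap``,
    ``body_rows``).
    """
    wedge_rows = int(overrides.pop("wedge_rows", 6))
    horn_body_gap = int(overrides.pop("horn_body_gap", 4))
    body_rows = int(overrides.pop("body_rows", 26))
    base = PhantomSpec(**overrides) if overrides else PhantomSpec()

    if not 0 < evans <= f_ratio < 1:
        raise PhantomError("need 0 < evans <= f_ratio < 1")
    if not 0 < c_ratio < d_ratio < 1:
        raise PhantomError("need 0 < c_ratio < d_ratio < 1")
    a, b = base.brain_semi_axes
    sp = base.pixel_spacing
    w_max = 2.0 * b

    evans_eff = evans
    for _ in range(4):
        # horn row from the evans/f_ratio width ratio
        rel = min(evans_eff / f_ratio, 0.999)
        d_mm = a * math.sqrt(max(0.0, 1.0 - rel * rel))
        horn_row = int(round(base.row_center - d_mm / sp))
        vtop = horn_row - wedge_rows
        body_top = horn_row + horn_body_gap
        body_bot = horn_row + body_rows
        k_f = _even_px(evans_eff * w_max, sp)
        trial = replace(
            base,
            frontal_horn_span=k_f * sp,
            max_frontal_width=k_f * sp,
            body_outer_span=k_f * sp * 0.9,  # provisional; fixed below
            caudate_span=k_f * sp * 0.45,
            horn_level_row=horn_row,
            ventricle_top_row=vtop,
            body_top_row=body_top,
            body_bottom_row=body_bot,
        )
        mrow = trial.measurement_row()
        w_m = trial.brain_width_at(mrow)
        k_d = _even_px(d_ratio * w_m, sp)
        if k_d <= k_f:
            break
        if not reconcile:
            raise PhantomError(
                "requested d_ratio would make the bodies wider than the horns"
            )
        evans_eff = k_d * sp / w_max
    else:
        raise PhantomError("could not reconcile evans with d_ratio")

    if k_d < 4:
        raise PhantomError("requested d_ratio leaves no room for body walls")
    k_c = _even_px(c_ratio * w_m, sp)
    if k_c > k_d - 2:
        if not reconcile:
            raise PhantomError("requested c_ratio/d_ratio leave no caudate gap")
        k_c = k_d - 2
    return replace(
        trial,
        body_outer_span=k_d * sp,
        caudate_span=k_c * sp,
    )


def sample_specs(
    n: int,
    seed: int,
    noise_sigma: float = 0.0,
    bias_amplitude: float = 0.0,
    **overrides,
) -> list[PhantomSpec]:
    """Draw ``n`` feasible phantom specs with index ratios spread over the
    physiologically plausible range (roughly 0.1-0.4)."""
    rng = np.random.default_rng(seed)
    specs: list[PhantomSpec] = []
    while len(specs) < n:
        f = rng.uniform(0.22, 0.40)
        ev = f * rng.uniform(0.78, 0.97)
        d = max(0.12, ev * rng.uniform(0.60, 0.90))
        c = float(np.clip(d * rng.uniform(0.35, 0.65), 0.05, d - 0.06))
        try:
            spec = spec_from_ratios(
                f,
                d,
                c,
                ev,
                noise_sigma=noise_sigma,
                bias_amplitude=bias_amplitude,
                seed=int(rng.integers(0, 2**31 - 1)),
                **overrides,
            )
            make_phantom(replace(spec, noise_sigma=0.0))  # feasibility probe
        except PhantomError:
            continue
        specs.append(spec)
    return specs


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupSpec:
    """Per-group normal distribution parameters for the four indices."""

    name: str
    n: int
    f_mean: float
    f_sd: float
    d_mean: float
    d_sd: float
    c_mean: float
    c_sd: float
    evans_mean: float
    evans_sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise PhantomError("group size must be >= 2")
        for idx in ("f", "d", "c", "evans"):
            mean = getattr(self, f"{idx}_mean")
            sd = getattr(self, f"{idx}_sd")
            if not 0.0 < mean < 1.0:
                raise PhantomError(f"{idx} mean must lie in (0, 1)")
            if not sd > 0:
                raise PhantomError(f"{idx} SD must be positive")

    def params(self) -> dict[str, tuple[float, float]]:
        return {
            "f_ratio": (self.f_mean, self.f_sd),
            "d_ratio": (self.d_mean, self.d_sd),
            "c_ratio": (self.c_mean, self.c_sd),
            "evans": (self.evans_mean, self.evans_sd),
        }


#: Built-in reference cohort parameters: a congenital-heart-disease
#: (septal-defect) neonatal group and a healthy-imaging control group,
#: mean +/- SD per ventricular index.
REFERENCE_CHD = GroupSpec(
    name="CHD",
    n=150,
    f_mean=0.301,
    f_sd=0.035,
    d_mean=0.261,
    d_sd=0.039,
    c_mean=0.138,
    c_sd=0.018,
    evans_mean=0.239,
    evans_sd=0.052,
)

REFERENCE_CONTROL = GroupSpec(
    name="control",
    n=50,
    f_mean=0.296,
    f_sd=0.031,
    d_mean=0.234,
    d_sd=0.032,
    c_mean=0.124,
    c_sd=0.015,
    evans_mean=0.233,
    evans_sd=0.025,
)


def reference_groups() -> list[GroupSpec]:
    """The built-in two-group reference cohort (CHD n=150, control n=50)."""
    return [REFERENCE_CHD, REFERENCE_CONTROL]


_CLIP_EPS = 1e-6


def sample_cohort(groups: Iterable[GroupSpec], seed: int) -> pd.DataFrame:
    """Draw per-subject index values from each group's normal distributions.

    Values are clipped to the open unit interval (they are ratios); at the
    reference parameters clipping is a <<0.1% tail event, and any clipped
    draw is counted and logged.  Reproducible for a fixed seed.
    """
    groups = list(groups)
    if not groups:
        raise PhantomError("need at least one group")
    rng = np.random.default_rng(seed)
    frames = []
    clipped = 0
    for g in groups:
        data: dict[str, object] = {
            "subject_id": [f"{g.name}-{i:04d}" for i in range(g.n)],
            "group": g.name,
        }
        for col, (mean, sd) in g.params().items():
            draws = rng.normal(mean, sd, size=g.n)
            clipped += int(np.sum((draws <= 0.0) | (draws >= 1.0)))
            data[col] = np.clip(draws, _CLIP_EPS, 1.0 - _CLIP_EPS)
        frames.append(pd.DataFrame(data))
    if clipped:
        logger.info("sample_cohort clipped %d draws to (0, 1)", clipped)
    out = pd.concat(frames, ignore_index=True)
    out.attrs["clipped"] = clipped
    return out


def simulate_raters(
    cohort: pd.DataFrame,
    rater_noise_sd: float,
    rater_bias: float = 0.0,
    seed: int = 0,
    index: str = "d_ratio",
) -> pd.DataFrame:
    """Add two rater columns for one index: truth + bias_k + Normal noise.

    Rater 1 is unbiased; rater 2 carries ``rater_bias``.  With
    between-subject variance s_b^2 and rater noise s_e^2 (zero bias), the
    generating intraclass correlation is ``s_b^2 / (s_b^2 + s_e^2)``.
    """
    if len(cohort) == 0:
        raise PhantomError("empty cohort")
    if rater_noise_sd < 0:
        raise PhantomError("rater_noise_sd must be >= 0")
    if index not in cohort.columns:
        raise PhantomError(f"cohort has no column {index!r}")
    rng = np.random.default_rng(seed)
    truth = cohort[index].to_numpy(dtype=float)
    out = cohort.copy()
    out["rater1"] = truth + rng.normal(0.0, rater_noise_sd, size=truth.size)
    out["rater2"] = (
        truth + rater_bias + rng.normal(0.0, rater_noise_sd, size=truth.size)
    )
    return out


def generating_icc(between_sd: float, rater_noise_sd: float) -> float:
    """The intraclass correlation implied by the simulation parameters."""
    sb2 = between_sd**2
    se2 = rater_noise_sd**2
    if sb2 + se2 == 0:
        raise PhantomError("total variance is zero")
    return sb2 / (sb2 + se2)


def rater_noise_for_icc(between_sd: float, icc: float) -> float:
    """Rater noise SD giving a target generating ICC for a known between-SD."""
    if not 0 < icc <= 1:
        raise PhantomError("icc must lie in (0, 1]")
    return between_sd * math.sqrt(1.0 / icc - 1.0)
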