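"""Synthetic fluorescence scenes with planted ground truth.

Every generator follows one physical rendering rule so that downstream
calibration algebra holds exactly in expectation:

* membrane areal fluorescence density ``rho`` is defined per bilayer area;
* a tubule of outer diameter ``d`` contributes ``rho * pi * d`` fluorescence
  units per nm of length (bilayer circumference times areal density);
* a flat film contributes ``rho * pixel_size**2`` per pixel (one bilayer);
* a GUV is rendered as its equatorial rim, a thin shell projected to 2D;
* the protein channel re-renders the same geometry with areal density
  ``protein_enrichment * protein_reference_density``.

Deposited fluorescence is blurred with an isotropic Gaussian PSF (which
preserves integrals, so sub-resolution tubules keep their fluorescence per
unit length), then Poisson shot noise (after photon conversion) and
additive Gaussian read noise are applied. Coordinates are (y, x) in nm,
0-based, row-major; pixel (i, j) is centered at ((i+0.5), (j+0.5)) times
the pixel size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from memtube.frap import FRAPTrace

__all__ = [
    "OpticsModel",
    "MembraneObjectSpec",
    "SceneTruth",
    "FluorImage",
    "SceneGenerationError",
    "DEFAULT_OPTICS",
    "NOISELESS_OPTICS",
    "COVERED_ENRICHMENT_THRESHOLD",
    "render_scene",
    "make_tubulation_scene",
    "make_guv_tubule_scene",
    "make_scaffold_scene",
    "make_flat_film_scene",
    "make_frap_trace",
]

LABEL_BACKGROUND = 0
LABEL_TUBULE = 1
LABEL_VESICLE = 2

#: protein enrichment above which a planted segment is flagged "covered".
#: Arbitrary but fixed; the analysis-side threshold is configured separately.
COVERED_ENRICHMENT_THRESHOLD = 2.0

#: effective projected rim width of a GUV equatorial shell (nm). The factor
#: cancels in every ratio the rim participates in (sorting ratio), so its
#: exact value only shapes how bright the rim looks.
GUV_RIM_WIDTH_NM = 500.0

DEFAULT_PIXEL_SIZE_NM = 100.0
DEFAULT_LIPID_DENSITY = 5.0
DEFAULT_PROTEIN_DENSITY = 2.0


class SceneGenerationError(RuntimeError):
    """Raised when a requested scene cannot be realized (e.g. packing fails)."""


@dataclass(frozen=True)
class OpticsModel:
    """Forward model of the microscope: Gaussian PSF plus a two-stage noise model."""

    psf_sigma_nm: float = 150.0
    photons_per_unit: float = 0.01
    read_noise_sd: float = 5.0
    background_level: float = 200.0

    def __post_init__(self) -> None:
        if self.psf_sigma_nm <= 0:
            raise ValueError("psf_sigma_nm must be > 0")
        if self.photons_per_unit < 0 or self.read_noise_sd < 0 or self.background_level < 0:
            raise ValueError("noise parameters must be >= 0")

    @property
    def noiseless(self) -> bool:
        return self.photons_per_unit == 0 and self.read_noise_sd == 0


DEFAULT_OPTICS = OpticsModel()
NOISELESS_OPTICS = OpticsModel(
    psf_sigma_nm=150.0, photons_per_unit=0.0, read_noise_sd=0.0, background_level=0.0
)


@dataclass
class MembraneObjectSpec:
    """One membrane object in a scene.

    ``center_nm``/``radius_nm`` describe vesicles and GUVs; tubules carry a
    polyline ``centerline_nm`` (shape (N, 2), (y, x) nm) and an outer
    ``diameter_nm``. A flat film fills the whole frame (or ``film_rect_nm``).
    """

    kind: str
    lipid_density: float = DEFAULT_LIPID_DENSITY
    protein_enrichment: float = 1.0
    center_nm: tuple[float, float] | None = None
    radius_nm: float | None = None
    centerline_nm: np.ndarray | None = None
    diameter_nm: float | None = None
    film_rect_nm: tuple[float, float, float, float] | None = None  # y0, x0, y1, x1

    def __post_init__(self) -> None:
        if self.kind not in ("vesicle", "tubule", "guv", "flat_film"):
            raise ValueError(f"unknown object kind {self.kind!r}")
        if self.lipid_density < 0:
            raise ValueError("lipid_density must be >= 0")
        if self.protein_enrichment < 0:
            raise ValueError("protein_enrichment must be >= 0")
        if self.kind in ("vesicle", "guv"):
            if self.center_nm is None or self.radius_nm is None or self.radius_nm <= 0:
                raise ValueError(f"{self.kind} needs center_nm and radius_nm > 0")
        if self.kind == "tubule":
            if self.centerline_nm is None or self.diameter_nm is None:
                raise ValueError("tubule needs centerline_nm and diameter_nm")
            self.centerline_nm = np.asarray(self.centerline_nm, dtype=float)
            if self.centerline_nm.ndim != 2 or self.centerline_nm.shape[0] < 2:
                raise ValueError("centerline_nm must be an (N>=2, 2) array")
            if self.diameter_nm <= 0:
                raise ValueError("diameter_nm must be > 0")


@dataclass
class FluorImage:
    """One 2D fluorescence channel plus its physical pixel size."""

    pixels: np.ndarray
    pixel_size_nm: float
    channel: str = "lipid"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2D array")
        if np.any(self.pixels < 0):
            raise ValueError("pixel values must be >= 0")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class SceneTruth:
    """Planted ground truth emitted alongside every synthetic scene."""

    objects: list[MembraneObjectSpec]
    true_label_map: np.ndarray
    true_tubulation_ratio: float | None
    true_diameters_nm: list[float]
    true_sorting_ratio: float | None
    seed: int
    pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM
    covered_flags: list[bool] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def to_jsonable(self) -> dict:
        """Scalar summary (without the label map) for sidecar JSON output."""
        return {
            "seed": self.seed,
            "pixel_size_nm": self.pixel_size_nm,
            "true_tubulation_ratio": self.true_tubulation_ratio,
            "true_diameters_nm": list(self.true_diameters_nm),
            "true_sorting_ratio": self.true_sorting_ratio,
            "covered_flags": list(self.covered_flags),
            "n_objects": len(self.objects),
            "object_kinds": [o.kind for o in self.objects],
            "meta": {
                k: (v.tolist() if isinstance(v, np.ndarray) else v)
                for k, v in self.meta.items()
            },
        }


# ---------------------------------------------------------------------------
# low-level rasterization


def _bilinear_splat(canvas: np.ndarray, rows: np.ndarray, cols: np.ndarray, masses: np.ndarray) -> None:
    """Deposit point masses at fractional pixel coordinates, conserving mass."""
    h, w = canvas.shape
    r0 = np.floor(rows).astype(int)
    c0 = np.floor(cols).astype(int)
    fr = rows - r0
    fc = cols - c0
    for dr, dc, wt in (
        (0, 0, (1 - fr) * (1 - fc)),
        (0, 1, (1 - fr) * fc),
        (1, 0, fr * (1 - fc)),
        (1, 1, fr * fc),
    ):
        rr = r0 + dr
        cc = c0 + dc
        ok = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        np.add.at(canvas, (rr[ok], cc[ok]), masses[ok] * wt[ok])


def _resample_polyline(pts: np.ndarray, step: float) -> tuple[np.ndarray, np.ndarray]:
    """Resample a polyline at ``step`` spacing; returns (points, unit tangents)."""
    pts = np.asarray(pts, dtype=float)
    seg = np.diff(pts, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    keep = seg_len > 1e-12
    seg, seg_len = seg[keep], seg_len[keep]
    starts = pts[:-1][keep]
    if seg.shape[0] == 0:
        raise ValueError("degenerate polyline")
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = cum[-1]
    n = max(int(math.ceil(total / step)), 1)
    s = (np.arange(n) + 0.5) * (total / n)
    idx = np.clip(np.searchsorted(cum, s, side="right") - 1, 0, seg.shape[0] - 1)
    frac = (s - cum[idx]) / seg_len[idx]
    points = starts[idx] + seg[idx] * frac[:, None]
    tangents = seg[idx] / seg_len[idx][:, None]
    return points, tangents


def polyline_length(pts: np.ndarray) -> float:
    pts = np.asarray(pts, dtype=float)
    return float(np.hypot(*np.diff(pts, axis=0).T).sum())


def _deposit_line_mass(
    canvas: np.ndarray,
    centerline_nm: np.ndarray,
    width_nm: float,
    mass_per_nm: float,
    pixel_size_nm: float,
) -> None:
    """Spread ``mass_per_nm`` (units per nm of length) uniformly across
    ``width_nm`` around the centerline. Exact integral conservation holds
    for any width, including sub-pixel widths."""
    if mass_per_nm == 0:
        return
    step = pixel_size_nm / 4.0
    points, tangents = _resample_polyline(centerline_nm, step)
    total = polyline_length(centerline_nm)
    ds = total / points.shape[0]
    normals = np.stack([-tangents[:, 1], tangents[:, 0]], axis=1)
    n_off = max(int(math.ceil(width_nm / step)), 1)
    offsets = (np.arange(n_off) + 0.5) / n_off * width_nm - width_nm / 2.0
    mass = mass_per_nm * ds / n_off
    for off in offsets:
        p = points + normals * off
        rows = p[:, 0] / pixel_size_nm - 0.5
        cols = p[:, 1] / pixel_size_nm - 0.5
        _bilinear_splat(canvas, rows, cols, np.full(points.shape[0], mass))


def _deposit_disk(
    canvas: np.ndarray,
    center_nm: tuple[float, float],
    radius_nm: float,
    areal_intensity: float,
    pixel_size_nm: float,
    supersample: int = 4,
) -> None:
    """Fill a disk with ``areal_intensity`` units per nm^2 using antialiased
    per-pixel coverage fractions."""
    h, w = canvas.shape
    cy, cx = center_nm
    r_px = radius_nm / pixel_size_nm
    cy_px, cx_px = cy / pixel_size_nm, cx / pixel_size_nm
    i0 = max(int(cy_px - r_px) - 1, 0)
    i1 = min(int(cy_px + r_px) + 2, h)
    j0 = max(int(cx_px - r_px) - 1, 0)
    j1 = min(int(cx_px + r_px) + 2, w)
    if i0 >= i1 or j0 >= j1:
        return
    ss = supersample
    sub = (np.arange(ss) + 0.5) / ss
    yy = (np.arange(i0, i1)[:, None] + sub[None, :]).reshape(-1)  # (ny*ss,)
    xx = (np.arange(j0, j1)[:, None] + sub[None, :]).reshape(-1)
    inside = (yy[:, None] - cy_px) ** 2 + (xx[None, :] - cx_px) ** 2 <= r_px**2
    cover = inside.reshape(i1 - i0, ss, j1 - j0, ss).mean(axis=(1, 3))
    canvas[i0:i1, j0:j1] += areal_intensity * pixel_size_nm**2 * cover


def _circle_polyline(center_nm: tuple[float, float], radius_nm: float, n: int = 720) -> np.ndarray:
    th = np.linspace(0.0, 2 * np.pi, n + 1)
    cy, cx = center_nm
    return np.stack([cy + radius_nm * np.sin(th), cx + radius_nm * np.cos(th)], axis=1)


def _polyline_dist_mask(
    shape: tuple[int, int], pixel_size_nm: float, polyline_nm: np.ndarray, radius_nm: float
) -> np.ndarray:
    """Boolean mask of pixels whose center lies within ``radius_nm`` of the polyline."""
    h, w = shape
    pts = np.asarray(polyline_nm, dtype=float)
    pad = radius_nm + 2 * pixel_size_nm
    i0 = max(int((pts[:, 0].min() - pad) / pixel_size_nm), 0)
    i1 = min(int((pts[:, 0].max() + pad) / pixel_size_nm) + 1, h)
    j0 = max(int((pts[:, 1].min() - pad) / pixel_size_nm), 0)
    j1 = min(int((pts[:, 1].max() + pad) / pixel_size_nm) + 1, w)
    mask = np.zeros(shape, dtype=bool)
    if i0 >= i1 or j0 >= j1:
        return mask
    yy = (np.arange(i0, i1) + 0.5) * pixel_size_nm
    xx = (np.arange(j0, j1) + 0.5) * pixel_size_nm
    py = np.repeat(yy, j1 - j0)
    px = np.tile(xx, i1 - i0)
    p = np.stack([py, px], axis=1)  # (M, 2)
    best = np.full(p.shape[0], np.inf)
    a = pts[:-1]
    b = pts[1:]
    ab = b - a
    ab_len2 = (ab**2).sum(axis=1)
    for k in range(a.shape[0]):
        if ab_len2[k] < 1e-12:
            d2 = ((p - a[k]) ** 2).sum(axis=1)
        else:
            t = np.clip(((p - a[k]) @ ab[k]) / ab_len2[k], 0.0, 1.0)
            proj = a[k] + t[:, None] * ab[k]
            d2 = ((p - proj) ** 2).sum(axis=1)
        best = np.minimum(best, d2)
    mask[i0:i1, j0:j1] = (best <= radius_nm**2).reshape(i1 - i0, j1 - j0)
    return mask


def _disk_mask(
    shape: tuple[int, int], pixel_size_nm: float, center_nm: tuple[float, float], radius_nm: float
) -> np.ndarray:
    h, w = shape
    yy = (np.arange(h) + 0.5) * pixel_size_nm
    xx = (np.arange(w) + 0.5) * pixel_size_nm
    return (yy[:, None] - center_nm[0]) ** 2 + (xx[None, :] - center_nm[1]) ** 2 <= radius_nm**2


def _ring_mask(
    shape: tuple[int, int],
    pixel_size_nm: float,
    center_nm: tuple[float, float],
    radius_nm: float,
    half_width_nm: float,
) -> np.ndarray:
    h, w = shape
    yy = (np.arange(h) + 0.5) * pixel_size_nm
    xx = (np.arange(w) + 0.5) * pixel_size_nm
    d = np.sqrt((yy[:, None] - center_nm[0]) ** 2 + (xx[None, :] - center_nm[1]) ** 2)
    return np.abs(d - radius_nm) <= half_width_nm


# ---------------------------------------------------------------------------
# scene rendering


def _channel_density(obj: MembraneObjectSpec, channel: str, protein_reference_density: float) -> float:
    if channel == "lipid":
        return obj.lipid_density
    if channel == "protein":
        return obj.protein_enrichment * protein_reference_density
    raise ValueError(f"unknown channel {channel!r}")


def _deposit_object(
    canvas: np.ndarray, obj: MembraneObjectSpec, density: float, pixel_size_nm: float
) -> None:
    if obj.kind == "flat_film":
        if obj.film_rect_nm is None:
            canvas += density * pixel_size_nm**2
        else:
            y0, x0, y1, x1 = obj.film_rect_nm
            i0, i1 = int(y0 / pixel_size_nm), int(math.ceil(y1 / pixel_size_nm))
            j0, j1 = int(x0 / pixel_size_nm), int(math.ceil(x1 / pixel_size_nm))
            canvas[i0:i1, j0:j1] += density * pixel_size_nm**2
    elif obj.kind == "vesicle":
        # flattened vesicle footprint: top + bottom bilayer
        _deposit_disk(canvas, obj.center_nm, obj.radius_nm, 2.0 * density, pixel_size_nm)
    elif obj.kind == "tubule":
        mass_per_nm = density * math.pi * obj.diameter_nm
        _deposit_line_mass(canvas, obj.centerline_nm, obj.diameter_nm, mass_per_nm, pixel_size_nm)
    elif obj.kind == "guv":
        ring = _circle_polyline(obj.center_nm, obj.radius_nm)
        mass_per_nm = density * math.pi * GUV_RIM_WIDTH_NM
        _deposit_line_mass(canvas, ring, GUV_RIM_WIDTH_NM, mass_per_nm, pixel_size_nm)


def _object_label_mask(
    obj: MembraneObjectSpec, shape: tuple[int, int], pixel_size_nm: float
) -> tuple[int, np.ndarray] | None:
    if obj.kind == "vesicle":
        return LABEL_VESICLE, _disk_mask(shape, pixel_size_nm, obj.center_nm, obj.radius_nm)
    if obj.kind == "tubule":
        r = max(obj.diameter_nm / 2.0, pixel_size_nm / 2.0)
        return LABEL_TUBULE, _polyline_dist_mask(shape, pixel_size_nm, obj.centerline_nm, r)
    if obj.kind == "guv":
        hw = max(GUV_RIM_WIDTH_NM / 2.0, pixel_size_nm / 2.0)
        return LABEL_VESICLE, _ring_mask(shape, pixel_size_nm, obj.center_nm, obj.radius_nm, hw)
    return None  # flat_film is calibration-only, not part of the 3-class map


def _check_bounds(obj: MembraneObjectSpec, shape: tuple[int, int], pixel_size_nm: float) -> None:
    h_nm = shape[0] * pixel_size_nm
    w_nm = shape[1] * pixel_size_nm
    if obj.kind in ("vesicle", "guv"):
        cy, cx = obj.center_nm
        r = obj.radius_nm
        if not (0 <= cy - r and cy + r <= h_nm and 0 <= cx - r and cx + r <= w_nm):
            raise ValueError(f"{obj.kind} at {obj.center_nm} exceeds image bounds")
    elif obj.kind == "tubule":
        pts = obj.centerline_nm
        if pts[:, 0].min() < 0 or pts[:, 0].max() > h_nm or pts[:, 1].min() < 0 or pts[:, 1].max() > w_nm:
            raise ValueError("tubule centerline exceeds image bounds")


def render_scene(
    objects: list[MembraneObjectSpec],
    optics: OpticsModel,
    image_shape: tuple[int, int],
    pixel_size_nm: float,
    channels: tuple[str, ...] = ("lipid",),
    seed: int = 0,
    protein_reference_density: float = DEFAULT_PROTEIN_DENSITY,
) -> tuple[dict[str, FluorImage], SceneTruth]:
    """Render a scene into one :class:`FluorImage` per channel plus ground truth.

    The noiseless pre-PSF image obeys the rendering rule documented at module
    level; blur and noise are then applied per channel with independent,
    seed-derived random substreams.
    """
    if pixel_size_nm <= 0:
        raise ValueError("pixel_size_nm must be > 0")
    for obj in objects:
        _check_bounds(obj, image_shape, pixel_size_nm)

    sigma_px = optics.psf_sigma_nm / pixel_size_nm
    streams = np.random.SeedSequence(seed).spawn(len(channels))
    images: dict[str, FluorImage] = {}
    for ch, ss in zip(channels, streams):
        canvas = np.zeros(image_shape, dtype=float)
        for obj in objects:
            _deposit_object(canvas, obj, _channel_density(obj, ch, protein_reference_density), pixel_size_nm)
        canvas = ndimage.gaussian_filter(canvas, sigma=sigma_px, mode="constant")
        canvas += optics.background_level
        rng = np.random.default_rng(ss)
        if optics.photons_per_unit > 0:
            canvas = rng.poisson(np.maximum(canvas, 0.0) * optics.photons_per_unit) / optics.photons_per_unit
        if optics.read_noise_sd > 0:
            canvas = canvas + rng.normal(0.0, optics.read_noise_sd, size=canvas.shape)
        images[ch] = FluorImage(np.maximum(canvas, 0.0), pixel_size_nm, channel=ch)

    label = np.zeros(image_shape, dtype=np.uint8)
    for obj in objects:
        lm = _object_label_mask(obj, image_shape, pixel_size_nm)
        if lm is not None:
            cls, mask = lm
            label[mask] = cls
    n_tub = int((label == LABEL_TUBULE).sum())
    n_ves = int((label == LABEL_VESICLE).sum())
    ratio = n_tub / (n_tub + n_ves) if (n_tub + n_ves) > 0 else None

    truth = SceneTruth(
        objects=list(objects),
        true_label_map=label,
        true_tubulation_ratio=ratio,
        true_diameters_nm=[o.diameter_nm for o in objects if o.kind == "tubule"],
        true_sorting_ratio=None,
        seed=seed,
        pixel_size_nm=pixel_size_nm,
        covered_flags=[
            o.protein_enrichment > COVERED_ENRICHMENT_THRESHOLD
            for o in objects
            if o.kind == "tubule"
        ],
    )
    return images, truth


# ---------------------------------------------------------------------------
# scene factories


def _random_tubule_centerline(
    rng: np.random.Generator,
    length_nm: float,
    bounds_nm: tuple[float, float],
    margin_nm: float,
    n_segments: int = 5,
    max_turn_rad: float = 0.5,
) -> np.ndarray | None:
    """A gently curving random polyline of the given arclength, or None if it
    wanders out of bounds."""
    h_nm, w_nm = bounds_nm
    start = np.array(
        [
            rng.uniform(margin_nm, h_nm - margin_nm),
            rng.uniform(margin_nm, w_nm - margin_nm),
        ]
    )
    theta = rng.uniform(0, 2 * np.pi)
    pts = [start]
    seg_len = length_nm / n_segments
    p = start
    for _ in range(n_segments):
        p = p + seg_len * np.array([math.sin(theta), math.cos(theta)])
        if not (margin_nm <= p[0] <= h_nm - margin_nm and margin_nm <= p[1] <= w_nm - margin_nm):
            return None
        pts.append(p.copy())
        theta += rng.uniform(-max_turn_rad, max_turn_rad)
    return np.asarray(pts)


def _truncate_polyline(pts: np.ndarray, new_length_nm: float) -> np.ndarray:
    """Prefix of a polyline with the requested arclength."""
    seg = np.diff(pts, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    if new_length_nm >= cum[-1]:
        return pts.copy()
    k = int(np.searchsorted(cum, new_length_nm, side="right") - 1)
    frac = (new_length_nm - cum[k]) / seg_len[k]
    end = pts[k] + seg[k] * frac
    return np.vstack([pts[: k + 1], end])


def make_tubulation_scene(
    target_ratio: float,
    n_objects: int,
    optics: OpticsModel = DEFAULT_OPTICS,
    seed: int = 0,
    image_shape: tuple[int, int] = (384, 384),
    pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM,
    lipid_density: float = DEFAULT_LIPID_DENSITY,
    tubule_width_nm: float = 300.0,
    max_attempts: int = 400,
) -> tuple[FluorImage, SceneTruth]:
    """Random non-overlapping field of vesicle disks and curved tubules whose
    planted tubule-area fraction lands within +/-0.02 of ``target_ratio``.

    The planted ratio is verified by pixel counting on the emitted label map;
    after initial placement the largest object of the over-represented class
    is shrunk iteratively until the pixel-counted ratio converges.
    """
    if not 0.0 <= target_ratio <= 1.0:
        raise ValueError("target_ratio must be in [0, 1]")
    if n_objects < 1:
        raise ValueError("n_objects must be >= 1")
    rng = np.random.default_rng(seed)
    h, w = image_shape
    h_nm, w_nm = h * pixel_size_nm, w * pixel_size_nm
    margin_nm = 4 * pixel_size_nm

    if target_ratio == 0.0:
        n_tub = 0
    elif target_ratio == 1.0:
        n_tub = n_objects
    else:
        n_tub = int(np.clip(round(n_objects * target_ratio), 1, n_objects - 1))
    n_ves = n_objects - n_tub

    # size budget: ~7% of the frame as foreground, split per target ratio
    area_budget_nm2 = 0.07 * h * w * pixel_size_nm**2
    tub_area = area_budget_nm2 * target_ratio
    ves_area = area_budget_nm2 - tub_area
    tub_lengths = None
    if n_tub:
        raw = rng.uniform(0.7, 1.3, n_tub)
        tub_lengths = np.clip(raw / raw.sum() * tub_area / tubule_width_nm, 1500.0, 0.45 * min(h_nm, w_nm))
    ves_radii = None
    if n_ves:
        raw = rng.uniform(0.7, 1.3, n_ves)
        ves_radii = np.sqrt(np.clip(raw / raw.sum() * ves_area, math.pi * 250.0**2, None) / math.pi)
        ves_radii = np.clip(ves_radii, 250.0, 0.12 * min(h_nm, w_nm))

    placed: list[dict] = []  # {"spec","mask"}
    occupied = np.zeros(image_shape, dtype=bool)
    clearance_px = max(int(round(2 * optics.psf_sigma_nm / pixel_size_nm)), 2)

    def try_place(make_candidate) -> bool:
        for _ in range(max_attempts):
            cand = make_candidate()
            if cand is None:
                continue
            spec, mask = cand
            grown = ndimage.binary_dilation(mask, iterations=clearance_px)
            if not np.any(grown & occupied):
                occupied[grown] = True
                placed.append({"spec": spec, "mask": mask})
                return True
        return False

    order = []
    if n_tub:
        order += [("tubule", ln) for ln in tub_lengths]
    if n_ves:
        order += [("vesicle", r) for r in ves_radii]
    rng.shuffle(order)

    for kind, size in order:
        if kind == "tubule":
            def cand_tub(size=size):
                cl = _random_tubule_centerline(rng, size, (h_nm, w_nm), margin_nm)
                if cl is None:
                    return None
                spec = MembraneObjectSpec(
                    kind="tubule",
                    centerline_nm=cl,
                    diameter_nm=tubule_width_nm,
                    lipid_density=lipid_density,
                )
                mask = _polyline_dist_mask(image_shape, pixel_size_nm, cl, tubule_width_nm / 2.0)
                return spec, mask

            ok = try_place(cand_tub)
        else:
            def cand_ves(size=size):
                c = (
                    rng.uniform(margin_nm + size, h_nm - margin_nm - size),
                    rng.uniform(margin_nm + size, w_nm - margin_nm - size),
                )
                spec = MembraneObjectSpec(
                    kind="vesicle", center_nm=c, radius_nm=size, lipid_density=lipid_density
                )
                return spec, _disk_mask(image_shape, pixel_size_nm, c, size)

            ok = try_place(cand_ves)
        if not ok:
            raise SceneGenerationError(
                f"could not place {kind} after {max_attempts} attempts; "
                f"too many objects for a {image_shape} frame"
            )

    # shrink-only adjustment toward the target pixel ratio
    def pixel_ratio() -> float:
        at = sum(int(p["mask"].sum()) for p in placed if p["spec"].kind == "tubule")
        av = sum(int(p["mask"].sum()) for p in placed if p["spec"].kind == "vesicle")
        if at + av == 0:
            return 0.0
        return at / (at + av)

    if 0.0 < target_ratio < 1.0:
        for _ in range(60):
            r = pixel_ratio()
            if abs(r - target_ratio) <= 0.01:
                break
            at = sum(int(p["mask"].sum()) for p in placed if p["spec"].kind == "tubule")
            av = sum(int(p["mask"].sum()) for p in placed if p["spec"].kind == "vesicle")
            if r > target_ratio:
                # too much tubule: shrink the longest tubule
                cands = [p for p in placed if p["spec"].kind == "tubule"]
                victim = max(cands, key=lambda p: p["mask"].sum())
                want = target_ratio / (1 - target_ratio) * av
                delta = at - want
                a = victim["mask"].sum()
                frac = max((a - delta) / a, 0.3)
                cl = _truncate_polyline(
                    victim["spec"].centerline_nm,
                    polyline_length(victim["spec"].centerline_nm) * frac,
                )
                victim["spec"].centerline_nm = cl
                victim["mask"] = _polyline_dist_mask(image_shape, pixel_size_nm, cl, tubule_width_nm / 2.0)
            else:
                cands = [p for p in placed if p["spec"].kind == "vesicle"]
                victim = max(cands, key=lambda p: p["mask"].sum())
                want = (1 - target_ratio) / target_ratio * at
                delta = av - want
                a = victim["mask"].sum()
                frac = max((a - delta) / a, 0.2)
                new_r = victim["spec"].radius_nm * math.sqrt(frac)
                victim["spec"].radius_nm = max(new_r, 200.0)
                victim["mask"] = _disk_mask(
                    image_shape, pixel_size_nm, victim["spec"].center_nm, victim["spec"].radius_nm
                )

    images, truth = render_scene(
        [p["spec"] for p in placed],
        optics,
        image_shape,
        pixel_size_nm,
        channels=("lipid",),
        seed=seed,
    )
    achieved = truth.true_tubulation_ratio if truth.true_tubulation_ratio is not None else 0.0
    if n_objects > 0 and abs(achieved - target_ratio) > 0.02:
        raise SceneGenerationError(
            f"planted ratio {achieved:.3f} missed target {target_ratio:.3f} by > 0.02"
        )
    return images["lipid"], truth


def make_guv_tubule_scene(
    guv_radius_um: float,
    tubule_diameter_nm: float,
    enrichment: float,
    optics: OpticsModel = DEFAULT_OPTICS,
    seed: int = 0,
    image_shape: tuple[int, int] = (256, 384),
    pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM,
    lipid_density: float = DEFAULT_LIPID_DENSITY,
    protein_reference_density: float = DEFAULT_PROTEIN_DENSITY,
) -> tuple[FluorImage, FluorImage, SceneTruth]:
    """GUV equatorial ring with one straight pulled tubule; two channels.

    The protein areal density on the tubule is ``enrichment`` times the
    density on the GUV, so the planted sorting ratio equals ``enrichment``.
    """
    if enrichment < 0:
        raise ValueError("enrichment must be >= 0")
    guv_radius_nm = guv_radius_um * 1000.0
    if not tubule_diameter_nm < 0.2 * guv_radius_nm:
        raise ValueError("tubule diameter must be well below the GUV radius")
    h, w = image_shape
    h_nm, w_nm = h * pixel_size_nm, w * pixel_size_nm
    margin = 12 * pixel_size_nm
    center = (h_nm / 2.0, margin + guv_radius_nm)
    if center[1] + guv_radius_nm > 0.6 * w_nm or 2 * guv_radius_nm > h_nm - 2 * margin:
        raise ValueError("GUV does not fit the requested frame")
    tube_start = (center[0], center[1] + guv_radius_nm)
    tube_end = (center[0], w_nm - margin)
    centerline = np.array([tube_start, tube_end])

    guv = MembraneObjectSpec(
        kind="guv",
        center_nm=center,
        radius_nm=guv_radius_nm,
        lipid_density=lipid_density,
        protein_enrichment=1.0,
    )
    tub = MembraneObjectSpec(
        kind="tubule",
        centerline_nm=centerline,
        diameter_nm=tubule_diameter_nm,
        lipid_density=lipid_density,
        protein_enrichment=enrichment,
    )
    images, truth = render_scene(
        [guv, tub],
        optics,
        image_shape,
        pixel_size_nm,
        channels=("lipid", "protein"),
        seed=seed,
        protein_reference_density=protein_reference_density,
    )
    truth.true_sorting_ratio = enrichment
    inset = 3 * optics.psf_sigma_nm + GUV_RIM_WIDTH_NM + 5 * pixel_size_nm
    truth.meta = {
        "guv_center_nm": list(center),
        "guv_radius_nm": guv_radius_nm,
        "tubule_centerline_nm": centerline,
        "analysis_centerline_nm": np.array(
            [(center[0], tube_start[1] + inset), (center[0], tube_end[1] - 3 * optics.psf_sigma_nm)]
        ),
    }
    return images["lipid"], images["protein"], truth


def make_scaffold_scene(
    segments: list[tuple[float, float, float]],
    optics: OpticsModel = DEFAULT_OPTICS,
    seed: int = 0,
    pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM,
    lipid_density: float = DEFAULT_LIPID_DENSITY,
    protein_reference_density: float = DEFAULT_PROTEIN_DENSITY,
    height_px: int = 48,
    margin_nm: float = 2000.0,
) -> tuple[FluorImage, FluorImage, SceneTruth]:
    """One horizontal tubule whose diameter and protein enrichment change
    stepwise per ``(length_nm, diameter_nm, protein_enrichment)`` segment.
    """
    if len(segments) < 1:
        raise ValueError("need at least one segment")
    for ln, d, enr in segments:
        if ln <= 0:
            raise ValueError("segment length must be > 0")
        if d <= 0:
            raise ValueError("segment diameter must be > 0")
        if enr < 0:
            raise ValueError("segment protein_enrichment must be >= 0")
    total = sum(s[0] for s in segments)
    width_px = int(math.ceil((total + 2 * margin_nm) / pixel_size_nm))
    image_shape = (height_px, width_px)
    y = height_px * pixel_size_nm / 2.0

    objects = []
    x = margin_nm
    boundaries = [x]
    for ln, d, enr in segments:
        objects.append(
            MembraneObjectSpec(
                kind="tubule",
                centerline_nm=np.array([[y, x], [y, x + ln]]),
                diameter_nm=d,
                lipid_density=lipid_density,
                protein_enrichment=enr,
            )
        )
        x += ln
        boundaries.append(x)

    images, truth = render_scene(
        objects,
        optics,
        image_shape,
        pixel_size_nm,
        channels=("lipid", "protein"),
        seed=seed,
        protein_reference_density=protein_reference_density,
    )
    inset = 3 * optics.psf_sigma_nm
    truth.meta = {
        "segment_boundaries_x_nm": np.asarray(boundaries),
        "centerline_nm": np.array([[y, boundaries[0]], [y, boundaries[-1]]]),
        "analysis_centerline_nm": np.array(
            [[y, boundaries[0] + inset], [y, boundaries[-1] - inset]]
        ),
    }
    return images["lipid"], images["protein"], truth


def make_flat_film_scene(
    optics: OpticsModel = DEFAULT_OPTICS,
    seed: int = 0,
    image_shape: tuple[int, int] = (128, 128),
    pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM,
    lipid_density: float = DEFAULT_LIPID_DENSITY,
    film_fraction: float = 0.7,
) -> tuple[FluorImage, SceneTruth]:
    """Flat lipid film covering the left ``film_fraction`` of the frame; the
    remaining strip is film-free for background estimation."""
    h, w = image_shape
    rect = (0.0, 0.0, h * pixel_size_nm, film_fraction * w * pixel_size_nm)
    film = MembraneObjectSpec(kind="flat_film", lipid_density=lipid_density, film_rect_nm=rect)
    images, truth = render_scene([film], optics, image_shape, pixel_size_nm, channels=("lipid",), seed=seed)
    truth.meta = {"film_rect_nm": np.asarray(rect), "lipid_density": lipid_density}
    return images["lipid"], truth


def make_frap_trace(
    mobile_fraction: float,
    tau_s: float,
    prebleach_level: float,
    bleach_depth: float,
    background: float,
    noise_sd: float,
    times_s: np.ndarray,
    seed: int = 0,
) -> FRAPTrace:
    """Synthetic FRAP trace: bleach at t = 0, single-exponential recovery.

    Samples with ``t < 0`` form the prebleach plateau at
    ``background + prebleach_level``; from t = 0 on the trace follows
    ``I_post + mobile_fraction * (prebleach - I_post) * (1 - exp(-t/tau))``
    (plus background and Gaussian noise), with
    ``I_post = prebleach_level * (1 - bleach_depth)``.
    """
    if not 0.0 <= mobile_fraction <= 1.0:
        raise ValueError("mobile_fraction must be in [0, 1]")
    if tau_s <= 0:
        raise ValueError("tau_s must be > 0")
    if not 0.0 < bleach_depth <= 1.0:
        raise ValueError("bleach_depth must be in (0, 1]")
    t = np.asarray(times_s, dtype=float)
    if t.ndim != 1 or not np.all(np.diff(t) > 0):
        raise ValueError("times_s must be strictly increasing")
    bleach_index = int(np.searchsorted(t, 0.0))
    pre = np.full(t.shape, prebleach_level, dtype=float)
    i_post = prebleach_level * (1.0 - bleach_depth)
    post_t = t[bleach_index:]
    recovery = i_post + mobile_fraction * (prebleach_level - i_post) * (1.0 - np.exp(-post_t / tau_s))
    signal = pre.copy()
    signal[bleach_index:] = recovery
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sd, size=t.shape) if noise_sd > 0 else 0.0
    return FRAPTrace(
        time_s=t,
        intensity=signal + background + noise,
        bleach_index=bleach_index,
        background=background,
    )
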