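"""Line-profile quantification: flat-film calibration, tubule radius from
fluorescence per unit length, curvature sorting ratios, and scaffold-segment
analysis.

The quantitative backbone is the calibration identity

    r = F_l / (2 * pi * rho0)

where ``rho0`` is the membrane fluorescence density per nm^2 of bilayer
measured on a flat lipid film (counted as ONE bilayer), and ``F_l`` is the
background-corrected total fluorescence per nm of tubule length. The
sorting ratio is

    S = (F_protein / F_lipid)_tubule / (F_protein / F_lipid)_GUV

from integrated plot profiles, with no polarization correction applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from memtube.synthgen import FluorImage, _resample_polyline, polyline_length

__all__ = [
    "LineProfile",
    "FlatFilmCalibration",
    "TubuleMeasurement",
    "SortingRatioResult",
    "ChannelValidationError",
    "extract_profile",
    "estimate_rho0",
    "estimate_radius",
    "measure_tubule_fl",
    "sorting_ratio",
    "analyze_scaffold_tubule",
    "arc_polyline",
]


class ChannelValidationError(ValueError):
    """Raised when a channel's content contradicts its declared role."""


@dataclass
class LineProfile:
    """Perpendicular-integrated intensity sampled along a polyline.

    ``values[i]`` is the cross-section integral of bilinearly interpolated
    pixel values at arclength ``positions_nm[i]``, expressed in pixel-length
    units: on a constant image of value ``c`` with an integration width of
    ``w`` pixels, every value equals ``c * w``.
    """

    polyline_nm: np.ndarray
    positions_nm: np.ndarray
    values: np.ndarray
    step_nm: float
    width_nm: float
    background_per_px: float
    pixel_size_nm: float
    channel: str = ""

    def __post_init__(self) -> None:
        if self.step_nm <= 0 or self.width_nm <= 0:
            raise ValueError("step_nm and width_nm must be > 0")

    @property
    def corrected_values(self) -> np.ndarray:
        """Values after subtracting the flanking-band background across the width."""
        return self.values - self.background_per_px * (self.width_nm / self.pixel_size_nm)

    @property
    def f_l_values(self) -> np.ndarray:
        """Background-corrected fluorescence per nm of length at each position."""
        return self.corrected_values / self.pixel_size_nm

    def integrated(self, corrected: bool = True) -> float:
        vals = self.corrected_values if corrected else self.values
        return float(vals.sum() * self.step_nm)


@dataclass
class FlatFilmCalibration:
    """Membrane fluorescence density from a flat single-bilayer lipid film."""

    rho0: float  # intensity units per nm^2 of bilayer
    background: float
    roi: tuple[int, int, int, int]
    channel: str = "lipid"

    def __post_init__(self) -> None:
        if self.rho0 <= 0:
            raise ValueError("rho0 must be > 0")


@dataclass
class TubuleMeasurement:
    """Fluorescence per unit length and the calibrated radius of one tubule
    (or one segment of a tubule)."""

    f_l_per_nm: float
    radius_nm: float
    diameter_nm: float
    segment_class: str = "n/a"  # "covered" | "uncovered" | "n/a"
    start_nm: float = 0.0
    end_nm: float = 0.0
    n_samples: int = 0
    degenerate: bool = False


@dataclass
class SortingRatioResult:
    f_protein_tubule: float
    f_lipid_tubule: float
    f_protein_guv: float
    f_lipid_guv: float
    sorting_ratio: float
    diameter_nm: float | None = None


# ---------------------------------------------------------------------------
# profiles


def extract_profile(
    image: FluorImage,
    polyline_nm: np.ndarray,
    width_nm: float,
    step_nm: float | None = None,
    background_gap_nm: float | None = None,
    background_band_nm: float | None = None,
) -> LineProfile:
    """Integrate interpolated intensity across the polyline's cross-section.

    The background is the median interpolated value in two flanking bands
    outside the integration width (per-pixel units). ``width_nm`` should
    span the full blurred cross-section (>= 6 PSF sigmas recommended).
    """
    px = image.pixel_size_nm
    if step_nm is None:
        step_nm = px / 2.0
    if background_gap_nm is None:
        background_gap_nm = 2.0 * px
    if background_band_nm is None:
        background_band_nm = 3.0 * px
    if width_nm <= 0 or step_nm <= 0:
        raise ValueError("width_nm and step_nm must be > 0")

    points, tangents = _resample_polyline(np.asarray(polyline_nm, dtype=float), step_nm)
    normals = np.stack([-tangents[:, 1], tangents[:, 0]], axis=1)
    h, w = image.pixels.shape

    sub = px / 4.0
    n_off = max(int(math.ceil(width_nm / sub)), 2)
    offsets = (np.arange(n_off) + 0.5) / n_off * width_nm - width_nm / 2.0

    # (n_pos, n_off, 2) sample coordinates in nm -> fractional pixel coords
    samples = points[:, None, :] + normals[:, None, :] * offsets[None, :, None]
    rows = samples[..., 0] / px - 0.5
    cols = samples[..., 1] / px - 0.5
    if rows.min() < -0.5 or rows.max() > h - 0.5 or cols.min() < -0.5 or cols.max() > w - 0.5:
        raise ValueError("profile integration window exits the image")
    interp = ndimage.map_coordinates(
        image.pixels, [rows.ravel(), cols.ravel()], order=1, mode="nearest"
    ).reshape(rows.shape)
    ds_px = (width_nm / n_off) / px
    values = interp.sum(axis=1) * ds_px

    # flanking background bands on both sides of the integration window
    n_bg = max(int(math.ceil(background_band_nm / sub)), 1)
    bg_off = background_gap_nm + (np.arange(n_bg) + 0.5) / n_bg * background_band_nm
    bg_offsets = np.concatenate([width_nm / 2.0 + bg_off, -width_nm / 2.0 - bg_off])
    bg_samples = points[:, None, :] + normals[:, None, :] * bg_offsets[None, :, None]
    bg_rows = np.clip(bg_samples[..., 0] / px - 0.5, 0, h - 1)
    bg_cols = np.clip(bg_samples[..., 1] / px - 0.5, 0, w - 1)
    bg_vals = ndimage.map_coordinates(
        image.pixels, [bg_rows.ravel(), bg_cols.ravel()], order=1, mode="nearest"
    )
    background = float(np.median(bg_vals))

    positions = np.arange(points.shape[0]) * polyline_length(polyline_nm) / points.shape[0]
    return LineProfile(
        polyline_nm=np.asarray(polyline_nm, dtype=float),
        positions_nm=positions,
        values=values,
        step_nm=step_nm,
        width_nm=width_nm,
        background_per_px=background,
        pixel_size_nm=px,
        channel=image.channel,
    )


# ---------------------------------------------------------------------------
# calibration and radius


def estimate_rho0(
    film_image: FluorImage,
    roi: tuple[int, int, int, int],
    background_roi: tuple[int, int, int, int] | None = None,
    background: float | None = None,
) -> FlatFilmCalibration:
    """Membrane fluorescence density from a flat-film image.

    ``rho0 = (mean ROI intensity - background) / pixel_size_nm**2``, the film
    counted as one bilayer. ROIs are (row0, col0, row1, col1) pixel bounds;
    background comes from ``background_roi`` (off-film) or a scalar.
    """
    r0, c0, r1, c1 = roi
    patch = film_image.pixels[r0:r1, c0:c1]
    if patch.size == 0:
        raise ValueError("empty calibration ROI")
    if background_roi is not None:
        b0, bc0, b1, bc1 = background_roi
        bg_patch = film_image.pixels[b0:b1, bc0:bc1]
        if bg_patch.size == 0:
            raise ValueError("empty background ROI")
        bg = float(bg_patch.mean())
    else:
        bg = float(background or 0.0)
    rho0 = (float(patch.mean()) - bg) / film_image.pixel_size_nm**2
    if rho0 <= 0:
        raise ValueError("rho0 <= 0 after background subtraction; check the ROIs")
    return FlatFilmCalibration(rho0=rho0, background=bg, roi=tuple(roi), channel=film_image.channel)


def estimate_radius(f_l: float, calib: FlatFilmCalibration) -> TubuleMeasurement:
    """Tubule radius from fluorescence per unit length: ``r = F_l / (2 pi rho0)``."""
    if calib is None:
        raise ValueError("calibration is required to convert F_l to a radius")
    if f_l < 0:
        raise ValueError("F_l must be background-corrected and >= 0")
    radius = f_l / (2.0 * math.pi * calib.rho0)
    return TubuleMeasurement(
        f_l_per_nm=f_l,
        radius_nm=radius,
        diameter_nm=2.0 * radius,
        degenerate=(f_l == 0.0),
    )


def measure_tubule_fl(
    image: FluorImage,
    centerline_nm: np.ndarray,
    width_nm: float = 1800.0,
    step_nm: float | None = None,
) -> tuple[float, LineProfile]:
    """Mean background-corrected fluorescence per nm along one tubule."""
    prof = extract_profile(image, centerline_nm, width_nm=width_nm, step_nm=step_nm)
    return float(prof.f_l_values.mean()), prof


# ---------------------------------------------------------------------------
# sorting ratio


def _integrated_or_raise(profile: LineProfile, what: str) -> float:
    total = profile.integrated(corrected=True)
    if total <= 0:
        raise ValueError(f"integrated {what} fluorescence is <= 0 after background correction")
    return total


def sorting_ratio(
    tubule_protein: LineProfile,
    tubule_lipid: LineProfile,
    guv_protein: LineProfile,
    guv_lipid: LineProfile,
    diameter_nm: float | None = None,
) -> SortingRatioResult:
    """Curvature sorting ratio from four integrated plot profiles.

    ``S = (F_prot/F_lip)_tubule / (F_prot/F_lip)_GUV``; invariant to any
    global gain applied to either channel and to correctly subtracted
    background offsets. No polarization correction is applied.
    """
    fpt = _integrated_or_raise(tubule_protein, "tubule protein")
    flt = _integrated_or_raise(tubule_lipid, "tubule lipid")
    fpg = _integrated_or_raise(guv_protein, "GUV protein")
    flg = _integrated_or_raise(guv_lipid, "GUV lipid")
    s = (fpt / flt) / (fpg / flg)
    return SortingRatioResult(
        f_protein_tubule=fpt,
        f_lipid_tubule=flt,
        f_protein_guv=fpg,
        f_lipid_guv=flg,
        sorting_ratio=s,
        diameter_nm=diameter_nm,
    )


def arc_polyline(
    center_nm: tuple[float, float], radius_nm: float, theta0: float, theta1: float, n: int = 64
) -> np.ndarray:
    """Polyline along a circular arc (angles in radians, (y, x) convention)."""
    th = np.linspace(theta0, theta1, n)
    cy, cx = center_nm
    return np.stack([cy + radius_nm * np.sin(th), cx + radius_nm * np.cos(th)], axis=1)


# ---------------------------------------------------------------------------
# scaffold segments


def _runs(mask: np.ndarray) -> list[tuple[int, int, bool]]:
    """Maximal runs of equal boolean value: (start, stop, value), stop exclusive."""
    out = []
    start = 0
    for i in range(1, mask.size + 1):
        if i == mask.size or mask[i] != mask[start]:
            out.append((start, i, bool(mask[start])))
            start = i
    return out


def _merge_short_runs(runs: list[tuple[int, int, bool]], min_len: int) -> list[tuple[int, int, bool]]:
    runs = list(runs)
    while len(runs) > 1:
        lengths = [stop - start for start, stop, _ in runs]
        shortest = int(np.argmin(lengths))
        if lengths[shortest] >= min_len:
            break
        start, stop, _ = runs.pop(shortest)
        if shortest == 0:
            nstart, nstop, nval = runs[0]
            runs[0] = (start, nstop, nval)
        elif shortest == len(runs):
            pstart, pstop, pval = runs[-1]
            runs[-1] = (pstart, stop, pval)
        else:
            prev_len = runs[shortest - 1][1] - runs[shortest - 1][0]
            next_len = runs[shortest][1] - runs[shortest][0]
            if prev_len >= next_len:
                pstart, pstop, pval = runs[shortest - 1]
                runs[shortest - 1] = (pstart, stop, pval)
            else:
                nstart, nstop, nval = runs[shortest]
                runs[shortest] = (start, nstop, nval)
        # merge adjacent runs that now share a value
        merged: list[tuple[int, int, bool]] = []
        for r in runs:
            if merged and merged[-1][2] == r[2]:
                merged[-1] = (merged[-1][0], r[1], r[2])
            else:
                merged.append(r)
        runs = merged
    return runs


def analyze_scaffold_tubule(
    lipid: FluorImage,
    protein: FluorImage,
    centerline_nm: np.ndarray,
    calib: FlatFilmCalibration,
    covered_threshold: float = 2.0,
    min_run_nm: float = 500.0,
    width_nm: float = 1800.0,
    edge_exclude_nm: float = 600.0,
    max_lipid_step_ratio: float = 4.0,
) -> list[TubuleMeasurement]:
    """Split one tubule into protein-covered vs uncovered segments and
    convert each segment's lipid fluorescence into a diameter.

    Covered positions are those whose protein profile exceeds
    ``covered_threshold`` times the median protein intensity; runs shorter
    than ``min_run_nm`` are merged into their larger neighbor. Segment lipid
    means exclude ``edge_exclude_nm`` at each run end to avoid PSF mixing
    across boundaries.

    Raises
    ------
    ChannelValidationError
        If the lipid profile shows step contrast larger than
        ``max_lipid_step_ratio`` (90th/10th percentile), which indicates the
        protein channel was passed as the lipid channel.
    ValueError
        If the centerline is shorter than ``min_run_nm``.
    """
    if lipid.pixel_size_nm != protein.pixel_size_nm or lipid.shape != protein.shape:
        raise ValueError("lipid and protein channels must share geometry")
    if polyline_length(centerline_nm) < min_run_nm:
        raise ValueError("centerline shorter than the minimum run length")

    lip_prof = extract_profile(lipid, centerline_nm, width_nm=width_nm)
    prot_prof = extract_profile(protein, centerline_nm, width_nm=width_nm)
    lip_vals = lip_prof.f_l_values
    prot_vals = prot_prof.corrected_values

    pos = np.maximum(lip_vals[lip_vals > 0], 1e-12)
    if pos.size and float(np.percentile(pos, 90)) / float(np.percentile(pos, 10)) > max_lipid_step_ratio:
        raise ChannelValidationError(
            "lipid profile shows strong step contrast typical of a protein "
            "scaffold channel; are the channels swapped?"
        )

    med = float(np.median(prot_vals))
    covered = prot_vals > covered_threshold * med
    step = lip_prof.step_nm
    min_run_samples = max(int(round(min_run_nm / step)), 1)
    runs = _merge_short_runs(_runs(covered), min_run_samples)

    edge = int(round(edge_exclude_nm / step))
    out: list[TubuleMeasurement] = []
    for start, stop, is_cov in runs:
        lo, hi = start, stop
        if hi - lo > 2 * edge + 3:
            lo, hi = lo + edge, hi - edge
        f_l = float(np.mean(lip_vals[lo:hi]))
        meas = estimate_radius(max(f_l, 0.0), calib)
        meas.segment_class = "covered" if is_cov else "uncovered"
        meas.start_nm = start * step
        meas.end_nm = stop * step
        meas.n_samples = stop - start
        out.append(meas)
    return out
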