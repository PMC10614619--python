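"""FRAP trace normalization and recovery-metric estimation.

Traces are background corrected and normalized so that the prebleach
plateau averages to exactly 1, then post-bleach recovery is fit with a
single-exponential model ``I(t) = I0 + A * (1 - exp(-t/tau))`` measured
from the first post-bleach sample. The mobile fraction is ``A / (1 - I0)``
and the half time is ``tau * ln 2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "FRAPTrace",
    "FRAPResult",
    "FRAPFitError",
    "normalize_trace",
    "recovery_metrics",
]

MIN_PREBLEACH_SAMPLES = 3
MIN_POSTBLEACH_SAMPLES = 10
#: minimum normalized bleach depth below which a fit is considered degenerate
MIN_BLEACH_DEPTH = 0.05


class FRAPFitError(RuntimeError):
    """Raised when the recovery fit is degenerate or fails to converge."""


@dataclass
class FRAPTrace:
    """A single ROI intensity time course around one bleach event.

    Parameters
    ----------
    time_s : array
        Strictly increasing acquisition times in seconds.
    intensity : array
        Raw ROI mean intensities, same length as ``time_s``.
    bleach_index : int
        Index of the first post-bleach sample. At least
        ``MIN_PREBLEACH_SAMPLES`` samples must precede it.
    background : float or array
        Background intensity, scalar or per-sample vector.
    """

    time_s: np.ndarray
    intensity: np.ndarray
    bleach_index: int
    background: float | np.ndarray = 0.0

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.time_s.ndim != 1 or self.intensity.shape != self.time_s.shape:
            raise ValueError("time_s and intensity must be 1-D arrays of equal length")
        if not np.all(np.diff(self.time_s) > 0):
            raise ValueError("time vector must be strictly increasing")
        if not (MIN_PREBLEACH_SAMPLES <= self.bleach_index < self.time_s.size):
            raise ValueError(
                f"bleach_index must leave >= {MIN_PREBLEACH_SAMPLES} prebleach "
                f"samples and lie within the trace"
            )
        bg = np.asarray(self.background, dtype=float)
        if bg.ndim not in (0, 1) or (bg.ndim == 1 and bg.shape != self.time_s.shape):
            raise ValueError("background must be a scalar or match the trace length")
        self.background = bg

    @property
    def prebleach(self) -> np.ndarray:
        return self.intensity[: self.bleach_index]

    @property
    def postbleach(self) -> np.ndarray:
        return self.intensity[self.bleach_index :]


@dataclass
class FRAPResult:
    """Recovery metrics from a normalized trace."""

    mobile_fraction: float
    half_time_s: float
    tau_s: float
    plateau: float
    floor: float
    rmse: float
    clipped: bool = False
    fit_params: dict = field(default_factory=dict)


def normalize_trace(trace: FRAPTrace) -> FRAPTrace:
    """Background-correct and normalize so the prebleach mean equals 1.

    ``out(t) = (I(t) - bg) / (mean prebleach I - bg)``. The returned trace
    carries ``background = 0``; normalizing it again is the identity.

    Raises
    ------
    ValueError
        If the prebleach mean does not exceed the background.
    """
    corrected = trace.intensity - trace.background
    pre_mean = float(np.mean(corrected[: trace.bleach_index]))
    if pre_mean <= 0:
        raise ValueError("prebleach mean must exceed the background level")
    return FRAPTrace(
        time_s=trace.time_s.copy(),
        intensity=corrected / pre_mean,
        bleach_index=trace.bleach_index,
        background=0.0,
    )


def _model(t: np.ndarray, i0: float, amp: float, tau: float) -> np.ndarray:
    return i0 + amp * (1.0 - np.exp(-t / tau))


def recovery_metrics(trace: FRAPTrace) -> FRAPResult:
    """Fit the post-bleach recovery of a *normalized* trace.

    The time axis is referenced to the first post-bleach sample, so the
    estimates are invariant to uniform time offsets.

    Raises
    ------
    FRAPFitError
        If no bleach is detectable (post-bleach start within
        ``MIN_BLEACH_DEPTH`` of the prebleach plateau) or the
        least-squares fit does not converge.
    """
    post_t = trace.time_s[trace.bleach_index :]
    post_i = trace.intensity[trace.bleach_index :]
    if post_t.size < MIN_POSTBLEACH_SAMPLES:
        raise ValueError(
            f"need >= {MIN_POSTBLEACH_SAMPLES} post-bleach samples, got {post_t.size}"
        )
    t = post_t - post_t[0]

    i0_guess = float(post_i[0])
    if 1.0 - i0_guess < MIN_BLEACH_DEPTH:
        raise FRAPFitError(
            f"degenerate trace: first post-bleach sample ({i0_guess:.3f}) is within "
            f"{MIN_BLEACH_DEPTH} of the prebleach plateau; no bleach to recover from"
        )

    amp_guess = max(float(post_i[-1]) - i0_guess, 1e-3)
    tau_guess = max(float(t[-1]) / 5.0, 1e-3)
    # tau is capped at twice the observation window: an unbounded tau is
    # degenerate with the amplitude (both fit an arbitrarily shallow ramp)
    # and inflates the mobile fraction on immobile traces
    tau_max = 2.0 * float(t[-1])
    try:
        popt, _ = curve_fit(
            _model,
            t,
            post_i,
            p0=(i0_guess, amp_guess, tau_guess),
            bounds=([-0.5, 0.0, 1e-6], [1.2, 2.0, tau_max]),
            maxfev=20000,
        )
    except RuntimeError as exc:  # pragma: no cover - scipy convergence failure
        raise FRAPFitError(f"recovery fit did not converge: {exc}") from exc

    i0, amp, tau = (float(v) for v in popt)
    bleach_depth = 1.0 - i0
    mobile = amp / bleach_depth
    clipped = not (0.0 <= mobile <= 1.0)
    mobile = float(np.clip(mobile, 0.0, 1.0))
    resid = post_i - _model(t, *popt)
    return FRAPResult(
        mobile_fraction=mobile,
        half_time_s=tau * np.log(2.0),
        tau_s=tau,
        plateau=i0 + amp,
        floor=i0,
        rmse=float(np.sqrt(np.mean(resid**2))),
        clipped=clipped,
        fit_params={"i0": i0, "amplitude": amp, "tau_s": tau},
    )
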