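"""Dose-profile analysis: peak, FWHM, range integrals, comparison stats.

The FWHM of a dose profile D(x) is x2 - x1, where x1 < x_peak < x2 are the
positions nearest the peak at which D crosses half the maximum, located by
linear interpolation between bracketing samples. Scan-range integrals are
slice sums (a slice contributes iff its center lies inside the range), and
the "tail" is the in-range dose outside the [x1, x2] peak interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dosimetry import SliceDoseProfile

__all__ = [
    "ProfileMetrics",
    "NoPeakError",
    "UndefinedFWHMError",
    "find_peak",
    "compute_fwhm",
    "integrate_range",
    "tail_dose",
    "profile_metrics",
    "percent_reduction",
    "fold_change",
]


class NoPeakError(ValueError):
    """The profile has no usable peak (all-zero or constant)."""


class UndefinedFWHMError(ValueError):
    """The profile never falls below half-max on one side of the peak."""

    def __init__(self, side: str):
        self.side = side
        super().__init__(f"profile never falls below half-max on the "
                         f"{side} side of the peak")


def _as_xy(profile):
    if isinstance(profile, SliceDoseProfile):
        return profile.positions_mm, profile.D_mGy
    x, y = profile
    return np.asarray(x, dtype=float), np.asarray(y, dtype=float)


def find_peak(profile):
    """Global maximum of a profile: (x_peak [mm], D_max [mGy]).

    Ties are broken toward the smallest position. A flat or all-zero
    profile raises NoPeakError.
    """
    x, y = _as_xy(profile)
    if x.size == 0:
        raise NoPeakError("empty profile")
    i = int(np.argmax(y))  # argmax returns the first (smallest-x) maximum
    if y[i] <= 0 or (x.size > 1 and np.all(y == y[0])):
        raise NoPeakError("profile has no peak (constant or all zero)")
    return float(x[i]), float(y[i])


def compute_fwhm(profile):
    """Half-max crossings and width: (x1 [mm], x2 [mm], FWHM [mm]).

    x1 and x2 are the crossings nearest the global peak on each side,
    linearly interpolated between the bracketing samples; secondary peaks
    above half-max inside [x1, x2] are permitted.
    """
    x, y = _as_xy(profile)
    xp, dmax = find_peak(profile)
    half = 0.5 * dmax
    ip = int(np.argmax(y))

    i = ip
    while i > 0 and y[i - 1] >= half:
        i -= 1
    if i == 0 and y[0] >= half:
        raise UndefinedFWHMError("cranial")
    x1 = x[i - 1] + (x[i] - x[i - 1]) * (half - y[i - 1]) / (y[i] - y[i - 1])

    j = ip
    n = x.size
    while j < n - 1 and y[j + 1] >= half:
        j += 1
    if j == n - 1 and y[n - 1] >= half:
        raise UndefinedFWHMError("caudal")
    x2 = x[j] + (x[j + 1] - x[j]) * (half - y[j]) / (y[j + 1] - y[j])
    return float(x1), float(x2), float(x2 - x1)


def integrate_range(profile, start_mm: float, end_mm: float,
                    warn_empty: bool = True) -> float:
    """Sum of slice doses with centers in [start_mm, end_mm] (mGy)."""
    if start_mm >= end_mm:
        raise ValueError("need start < end")
    x, y = _as_xy(profile)
    sel = (x >= start_mm - 1e-9) & (x <= end_mm + 1e-9)
    if not sel.any():
        if warn_empty:
            import warnings
            warnings.warn("no slice centers inside the requested range",
                          stacklevel=2)
        return 0.0
    return float(y[sel].sum())


def tail_dose(profile, start_mm: float, end_mm: float) -> float:
    """In-range dose with the FWHM peak interval [x1, x2] excluded (mGy)."""
    x, y = _as_xy(profile)
    x1, x2, _ = compute_fwhm(profile)
    sel = (x >= start_mm - 1e-9) & (x <= end_mm + 1e-9) \
        & ~((x >= x1) & (x <= x2))
    return float(y[sel].sum())


@dataclass
class ProfileMetrics:
    """Peak/FWHM/integral summary of one organ's dose profile."""

    organ: str
    D_max_mGy: float
    x_peak_mm: float
    x1_mm: float
    x2_mm: float
    fwhm_mm: float
    range_dose_mGy: float
    tail_dose_mGy: float


def profile_metrics(profile, start_mm: float, end_mm: float,
                    organ: str = "") -> ProfileMetrics:
    if isinstance(profile, SliceDoseProfile) and not organ:
        organ = profile.organ
    xp, dmax = find_peak(profile)
    x1, x2, fwhm = compute_fwhm(profile)
    return ProfileMetrics(
        organ=organ, D_max_mGy=dmax, x_peak_mm=xp, x1_mm=x1, x2_mm=x2,
        fwhm_mm=fwhm,
        range_dose_mGy=integrate_range(profile, start_mm, end_mm),
        tail_dose_mGy=tail_dose(profile, start_mm, end_mm))


def percent_reduction(reference: float, value: float) -> float:
    """100 x (reference - value) / reference."""
    if reference <= 0:
        raise ValueError("reference must be > 0")
    return 100.0 * (reference - value) / reference


def fold_change(a: float, b: float) -> float:
    """Dose ratio a / b."""
    if b <= 0:
        raise ValueError("denominator must be > 0")
    return a / b
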