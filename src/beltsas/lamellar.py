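"""Lamellar Bragg-peak detection and repeat-distance analysis.

Periodically stacked membranes diffract at momentum transfers
s = n·2π/d, where d is the lamellar repeat distance (one bilayer plus
the intermembrane space) and n the diffraction order.  This module
detects Bragg peaks on a power-law background in one-dimensional
patterns, assigns orders, and converts first-order positions to mean
repeat distances with d = 2π/s.

Units: s is kept in whatever inverse-length unit the pattern uses
(nm⁻¹ by convention here); d comes out in the corresponding direct
unit, so a pattern in Å⁻¹ yields d in Å.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks, peak_widths


@dataclass
class DiffractionPattern:
    """One-dimensional diffraction pattern I(s)."""

    s: np.ndarray
    intensity: np.ndarray
    wavelength: float | None = None  # Å, optional instrument metadata

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if np.any(np.diff(self.s) <= 0):
            raise ValueError("s must be strictly increasing")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensities must be finite")


@dataclass
class BraggPeakSet:
    """Detected peaks with assigned diffraction orders."""

    positions: np.ndarray                 # s of each peak
    heights: np.ndarray
    widths: np.ndarray
    orders: np.ndarray = field(default=None)   # int order, 0 = unassigned
    d_spacings: np.ndarray = field(default=None)  # 2π/(s/n) per assigned peak

    @property
    def n_peaks(self) -> int:
        return len(self.positions)

    @property
    def repeat_distance(self) -> float | None:
        """Mean repeat distance from the first-order peak, if present."""
        if self.orders is None:
            return None
        first = self.orders == 1
        if not first.any():
            return None
        return repeat_distance(float(self.positions[first][0]))


def s_from_theta(theta: float, wavelength: float) -> float:
    """Momentum transfer s = 4π sinθ / λ (θ in radians, λ and s⁻¹ in
    matching units)."""
    if wavelength <= 0:
        raise ValueError("wavelength must be positive")
    return 4.0 * np.pi * np.sin(theta) / wavelength


def repeat_distance(s):
    """Mean lamellar repeat distance d = 2π/s.

    Units are the inverse of the s unit: s in nm⁻¹ gives d in nm.
    """
    s = np.asarray(s, dtype=float)
    if np.any(s <= 0):
        raise ValueError("s must be positive")
    out = 2.0 * np.pi / s
    return float(out) if out.ndim == 0 else out


def _power_law_background(s, intensity, mask):
    """Least-squares A·s^(-p) + B on masked (peak-free) points.

    The exponent p is scanned on a grid and (A, B) solved linearly per
    candidate, minimising relative residuals so the high-s tail (small
    intensities) is fitted as carefully as the low-s rise.
    """
    su, yu = s[mask], intensity[mask]
    if len(yu) < 5:
        return np.zeros_like(s)
    w = 1.0 / np.maximum(np.abs(yu), 1e-12)
    best = None
    for p in np.linspace(0.0, 6.0, 61):
        X = np.column_stack([su**-p, np.ones_like(su)])
        coef, *_ = np.linalg.lstsq(X * w[:, None], yu * w, rcond=None)
        ssr = float(np.sum(((X @ coef - yu) * w) ** 2))
        if best is None or ssr < best[0]:
            best = (ssr, p, coef)
    _, p, coef = best
    return np.column_stack([s**-p, np.ones_like(s)]) @ coef


def find_bragg_peaks(
    pattern: DiffractionPattern,
    min_prominence: float | None = None,
    order_tolerance: float = 0.025,
) -> BraggPeakSet:
    """Detect Bragg peaks above a power-law + constant background.

    The background is fitted by least squares, candidate peak regions
    are masked, and the fit repeated.  Peaks are found on the
    background-relative residual (I − bg)/bg, which keeps detection
    uniform when the noise scales with the signal; maxima must exceed
    ``min_prominence`` (default 8 × the robust σ of the relative
    baseline, from the MAD — Bragg peaks sit orders of magnitude above
    this) and span at least two grid points.  A broad
    or featureless pattern yields an empty set — a valid result.
    """
    s, y = pattern.s, pattern.intensity
    if len(s) < 20:
        raise ValueError("pattern too short (need >= 20 points)")

    mask = np.ones(len(s), bool)
    bg = _power_law_background(s, y, mask)
    for _ in range(3):
        rel = (y - bg) / np.maximum(bg, 1e-12)
        sigma = 1.4826 * _mad(rel[mask])
        mask = rel < 3.0 * sigma
        if mask.sum() < 10:
            break
        bg = _power_law_background(s, y, mask)

    bg_floor = np.maximum(bg, 1e-12)
    rel = (y - bg) / bg_floor
    sigma = 1.4826 * (_mad(rel[mask]) if mask.sum() else _mad(rel))
    prom = min_prominence if min_prominence is not None else 8.0 * max(sigma, 1e-12)
    # a minimum separation of 8 samples keeps noise from splitting one
    # Bragg reflection into two adjacent detections
    idx, props = find_peaks(rel, prominence=prom, width=2, distance=8)
    resid = y - bg
    if len(idx) == 0:
        return BraggPeakSet(
            positions=np.empty(0), heights=np.empty(0), widths=np.empty(0),
            orders=np.empty(0, int), d_spacings=np.empty(0),
        )
    widths_pts = peak_widths(rel, idx, rel_height=0.5)[0]
    ds = float(np.mean(np.diff(s)))
    positions = np.array([_refine_peak(s, resid, i) for i in idx])
    peaks = BraggPeakSet(
        positions=positions,
        heights=resid[idx],
        widths=widths_pts * ds,
    )
    return assign_orders(peaks, tolerance=order_tolerance)


def _refine_peak(s: np.ndarray, y: np.ndarray, i: int, half: int = 6) -> float:
    """Sub-grid peak position from a local quadratic fit around sample i."""
    lo, hi = max(i - half, 0), min(i + half + 1, len(s))
    if hi - lo < 3:
        return float(s[i])
    a, b, _ = np.polyfit(s[lo:hi] - s[i], y[lo:hi], 2)
    if a >= 0:
        return float(s[i])
    vertex = -b / (2.0 * a)
    halfwidth = s[hi - 1] - s[i] if hi - 1 > i else s[i] - s[lo]
    if abs(vertex) > abs(halfwidth):
        return float(s[i])
    return float(s[i] + vertex)


def _mad(x: np.ndarray) -> float:
    return float(np.median(np.abs(x - np.median(x))))


def assign_orders(peaks: BraggPeakSet, tolerance: float = 0.025) -> BraggPeakSet:
    """Assign diffraction orders: the smallest-s peak is order 1 and a
    peak at s is order n when |s − n·s₁|/(n·s₁) ≤ tolerance; peaks that
    fit no order are flagged with order 0.  First-order d = 2π/s₁."""
    if peaks.n_peaks == 0:
        raise ValueError("no peaks to assign")
    order = np.argsort(peaks.positions)
    pos = peaks.positions[order]
    s1 = pos[0]
    orders = np.zeros(len(pos), int)
    d_spacings = np.full(len(pos), np.nan)
    orders[0] = 1
    d_spacings[0] = repeat_distance(s1)
    for i in range(1, len(pos)):
        n = int(round(pos[i] / s1))
        if n >= 1 and abs(pos[i] - n * s1) / (n * s1) <= tolerance:
            orders[i] = n
            d_spacings[i] = repeat_distance(pos[i] / n)
    return BraggPeakSet(
        positions=pos,
        heights=peaks.heights[order],
        widths=peaks.widths[order],
        orders=orders,
        d_spacings=d_spacings,
    )


def load_pattern(path) -> DiffractionPattern:
    """Read a 2+-column text pattern (s, I[, sigma]); '#' comments.

    s is taken at face value; derived d values carry the inverse unit
    (s in Å⁻¹ gives d in Å, 10× the nm result for the same data).
    """
    data = np.loadtxt(path, comments="#", ndmin=2)
    return DiffractionPattern(s=data[:, 0], intensity=data[:, 1])
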