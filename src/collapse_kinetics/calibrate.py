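"""Photometric calibration: fluorescence intensity -> integer myosin count.

Fitted peak intensities from one kymograph are histogrammed and the
histogram is fitted by least squares to a sum of Gaussians with increasing
means (one component per occupancy class).  The component means are then
regressed against the count index -- a straight line through the means is
the hallmark of unit-brightness fluorophores -- and each class is assigned
the intensity band ``mean +/- 2 x SD``.  An observed intensity maps to the
class whose band contains it; where neighbouring bands overlap, the boundary
is the mid-point between the two means (nearest-mean rule); intensities
outside every band are UNASSIGNED and treated as missing downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.optimize import least_squares
from scipy.signal import find_peaks
from scipy.stats import linregress

__all__ = [
    "UNASSIGNED",
    "CalibrationModel",
    "CalibrationError",
    "fit_intensity_mixture",
    "fit_calibration_line",
    "build_calibration_model",
    "assign_count",
    "assign_counts",
    "plot_calibration",
]

UNASSIGNED = -1

_SQRT2PI = float(np.sqrt(2.0 * np.pi))


class CalibrationError(RuntimeError):
    """Raised when the intensity mixture or line fit cannot be computed."""


def fit_intensity_mixture(
    intensities: np.ndarray,
    n_components: int,
    bins: str | int = "fd",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Least-squares fit of an intensity histogram to a sum of Gaussians.

    Parameters
    ----------
    intensities : array_like
        Fitted peak intensities (>= 50 values required).
    n_components : int
        Number of Gaussian components (occupancy classes) to fit.
    bins : str or int
        Histogram binning rule; Freedman-Diaconis by default.

    Returns
    -------
    means, sds, weights : ndarray
        Ordered by increasing mean; weights normalised to sum to 1.
        Components the data cannot support come back with near-zero weight
        rather than raising.
    """
    x = np.asarray(intensities, dtype=np.float64).ravel()
    x = x[np.isfinite(x)]
    if x.size < 50:
        raise CalibrationError(f"need >= 50 intensity values, got {x.size}")
    if n_components < 1:
        raise CalibrationError("n_components must be >= 1")
    counts, edges = np.histogram(x, bins=bins)
    if isinstance(bins, str) and counts.size < 10 * n_components:
        # rule-based binning can come out too coarse for well-separated
        # multimodal data; guarantee ~10 bins per component
        counts, edges = np.histogram(x, bins=10 * n_components)
    centers = 0.5 * (edges[:-1] + edges[1:])
    if 3 * n_components > centers.size:
        raise CalibrationError(
            f"{n_components} components need {3 * n_components} parameters but the "
            f"histogram has only {centers.size} bins"
        )
    rng_lo, rng_hi = float(x.min()), float(x.max())
    span = max(rng_hi - rng_lo, 1e-9)
    binw = float(edges[1] - edges[0])

    # seed means from histogram peaks, extrapolating by the typical spacing
    # if fewer peaks are resolvable than components requested
    smooth = gaussian_filter1d(counts.astype(np.float64), 1.0)
    pk, props = find_peaks(smooth, height=max(smooth.max() * 0.05, 1.0))
    order = np.argsort(props["peak_heights"])[::-1][:n_components]
    mean0 = np.sort(centers[pk[np.sort(order)]]) if pk.size else np.array([])
    if mean0.size == 0:
        mean0 = np.linspace(rng_lo + span / (n_components + 1), rng_hi,
                            n_components, endpoint=False)
    while mean0.size < n_components:
        spacing = float(np.median(np.diff(mean0))) if mean0.size >= 2 else span / n_components
        spacing = max(spacing, binw)
        mean0 = np.append(mean0, mean0[-1] + spacing)
    mean0 = mean0[:n_components]
    # keep every seed inside the optimiser bounds and strictly increasing
    hi_cap = rng_hi + 0.9 * span
    for k in range(n_components - 1, -1, -1):
        mean0[k] = min(mean0[k], hi_cap - (n_components - 1 - k) * binw)
    for k in range(1, n_components):
        mean0[k] = max(mean0[k], mean0[k - 1] + 0.25 * binw)

    sd0 = np.full(n_components, max(span / (6.0 * n_components), binw))
    amp0 = np.interp(mean0, centers, smooth)
    amp0 = np.clip(amp0, 1.0, None)

    p0 = np.column_stack([amp0, mean0, sd0]).ravel()
    lo = np.tile([0.0, rng_lo - span, binw / 4.0], n_components)
    hi = np.tile([counts.max() * 4.0 + 10.0, rng_hi + span, span], n_components)

    def resid(p):
        model = np.zeros_like(centers)
        for k in range(n_components):
            a, m, s = p[3 * k:3 * k + 3]
            model += a * np.exp(-((centers - m) ** 2) / (2.0 * s * s))
        return model - counts

    res = least_squares(resid, p0, bounds=(lo, hi), max_nfev=20000)
    if not res.success:
        raise CalibrationError("intensity mixture fit did not converge")
    p = res.x.reshape(n_components, 3)
    order = np.argsort(p[:, 1])
    amps, means, sds = p[order, 0], p[order, 1], p[order, 2]
    mass = amps * sds * _SQRT2PI
    total = mass.sum()
    weights = mass / total if total > 0 else np.full(n_components, 1.0 / n_components)
    return means, sds, weights


def fit_calibration_line(
    means: np.ndarray, counts: np.ndarray | None = None
) -> tuple[float, float, float]:
    """Ordinary least squares of mean intensity vs count index (1, 2, ...)."""
    means = np.asarray(means, dtype=np.float64)
    if means.size < 2:
        raise CalibrationError("need >= 2 component means for a line fit")
    if np.allclose(means, means[0]):
        raise CalibrationError("degenerate (identical) means")
    x = np.arange(1, means.size + 1, dtype=np.float64) if counts is None \
        else np.asarray(counts, dtype=np.float64)
    fit = linregress(x, means)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue ** 2)


@dataclass(frozen=True)
class CalibrationModel:
    """Intensity -> myosin-count mapping for one kymograph.

    ``component_means[k]`` is the mean intensity of count class
    ``first_count + k`` and ``bands`` are the ``mean +/- 2 SD`` assignment
    intervals.  ``first_count=0`` describes models whose lowest class is
    background (zero binders), as in mixture fits of raw pixel intensities.
    """

    component_means: tuple[float, ...]
    component_sds: tuple[float, ...]
    line_slope: float
    line_intercept: float
    r_squared: float
    first_count: int = 1

    def __post_init__(self) -> None:
        m = np.asarray(self.component_means)
        if m.size == 0:
            raise CalibrationError("empty calibration model")
        if not np.all(np.diff(m) > 0):
            raise CalibrationError("component means must be strictly increasing")
        if np.isfinite(self.r_squared) and not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise CalibrationError("r_squared outside [0, 1]")

    @property
    def bands(self) -> list[tuple[float, float]]:
        return [(m - 2.0 * s, m + 2.0 * s)
                for m, s in zip(self.component_means, self.component_sds)]

    def _effective_intervals(self) -> list[tuple[float, float]]:
        """2-SD bands with overlaps resolved at the mid-point between means.

        The resulting intervals are disjoint and ordered, which makes count
        assignment monotone in intensity by construction.
        """
        m = np.asarray(self.component_means)
        raw = self.bands
        eff = []
        for k, (lo, hi) in enumerate(raw):
            if k > 0 and raw[k - 1][1] > lo:  # overlap with the class below
                lo = 0.5 * (m[k - 1] + m[k])
            if k + 1 < len(raw) and raw[k + 1][0] < hi:  # overlap above
                hi = 0.5 * (m[k] + m[k + 1])
            eff.append((lo, hi))
        return eff

    def to_json(self, path: str | Path) -> None:
        payload = {
            "component_means": list(self.component_means),
            "component_sds": list(self.component_sds),
            "line_slope": self.line_slope,
            "line_intercept": self.line_intercept,
            "r_squared": self.r_squared,
            "first_count": self.first_count,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationModel":
        d = json.loads(Path(path).read_text())
        return cls(
            component_means=tuple(d["component_means"]),
            component_sds=tuple(d["component_sds"]),
            line_slope=d["line_slope"],
            line_intercept=d["line_intercept"],
            r_squared=d["r_squared"],
            first_count=d.get("first_count", 1),
        )


def build_calibration_model(
    means: np.ndarray,
    sds: np.ndarray,
    first_count: int = 1,
) -> CalibrationModel:
    """Assemble a CalibrationModel, fitting the means-vs-count line.

    The line is fitted against the count indices of the non-background
    classes; a free intercept is used.
    """
    means = np.asarray(means, dtype=np.float64)
    sds = np.asarray(sds, dtype=np.float64)
    counts = np.arange(first_count, first_count + means.size, dtype=np.float64)
    keep = counts >= 1  # the background class does not constrain the line
    if keep.sum() >= 2:
        slope, intercept, r2 = fit_calibration_line(means[keep], counts[keep])
    else:
        slope = intercept = r2 = float("nan")
    return CalibrationModel(
        component_means=tuple(means), component_sds=tuple(sds),
        line_slope=slope, line_intercept=intercept, r_squared=r2,
        first_count=first_count,
    )


def assign_count(intensity: float, model: CalibrationModel) -> int:
    """Map one intensity to an integer myosin count, or UNASSIGNED.

    Returns class ``k`` when the intensity lies inside class ``k``'s 2-SD
    band only; when bands overlap the class whose mean is nearest wins;
    intensities outside all bands return UNASSIGNED.
    """
    if not np.isfinite(intensity):
        return UNASSIGNED
    for k, (lo, hi) in enumerate(model._effective_intervals()):
        if lo <= intensity <= hi:
            return model.first_count + k
    return UNASSIGNED


def assign_counts(intensities: np.ndarray, model: CalibrationModel) -> np.ndarray:
    """Vectorised :func:`assign_count` (returns int array with UNASSIGNED = -1)."""
    x = np.asarray(intensities, dtype=np.float64)
    out = np.full(x.shape, UNASSIGNED, dtype=np.int64)
    for k, (lo, hi) in enumerate(model._effective_intervals()):
        sel = (x >= lo) & (x <= hi)
        out[sel] = model.first_count + k
    return out


def plot_calibration(model: CalibrationModel, path: str | Path) -> None:
    """Means +/- 2 SD against myosin count, with the fitted line."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    counts = np.arange(model.first_count,
                       model.first_count + len(model.component_means))
    means = np.asarray(model.component_means)
    errs = 2.0 * np.asarray(model.component_sds)
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.errorbar(counts, means, yerr=errs, fmt="o", capsize=3, label="class mean ± 2 SD")
    if np.isfinite(model.line_slope):
        xx = np.linspace(counts.min(), counts.max(), 50)
        ax.plot(xx, model.line_slope * xx + model.line_intercept, "-",
                label=f"line fit (R²={model.r_squared:.3f})")
    ax.set_xlabel("myosin count")
    ax.set_ylabel("intensity (counts)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
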