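"""Picking one solution off the Pareto front.

Three strategies: the minimum-f1 (sparsest) solution, the minimum-f2
(best-reconstructing) solution, and the *knee* — the best-trade-off
region where the front bends hardest.  The knee detector normalizes the
front into the unit square, fits a lightly smoothed parametric B-spline
through the sorted points, resamples it evenly, computes the analytic
curvature kappa = |x'y'' - y'x''| / (x'^2 + y'^2)^(3/2) from the spline
derivatives, and returns the archive solution nearest (Euclidean, in
normalized space) to the curve sample of maximum curvature.

Fronts of near-constant curvature (a straight line, a circular arc)
have no meaningful knee; the argmax point is still returned but a
low-confidence warning is emitted when max(kappa)/mean(kappa) < 1.5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import interpolate

from .nsga2 import ParetoArchive

__all__ = [
    "STRATEGIES",
    "SelectionResult",
    "normalize_front",
    "smooth_and_resample",
    "curvature",
    "select",
]

STRATEGIES = ("min_f1", "min_f2", "knee")

#: below this max/mean curvature ratio the knee is flagged low-confidence
KNEE_CONFIDENCE_RATIO = 1.5


@dataclass
class SelectionResult:
    """Chosen archive member plus knee diagnostics.

    ``diagnostics`` holds, for the knee strategy: the normalized front,
    the resampled curve and its curvature, the per-point curvature at
    the nearest curve sample, the indices of the three points closest to
    the maximum-curvature sample, and the confidence ratio.
    """

    index: int
    alpha: np.ndarray
    f1: float
    f2: float
    strategy: str
    diagnostics: dict = field(default_factory=dict)


def normalize_front(F: np.ndarray) -> np.ndarray:
    """Min-max scale each objective over the front into [0, 1].

    A zero-range objective maps to 0 for every point.
    """
    F = np.asarray(F, dtype=float)
    lo = F.min(axis=0)
    rng = F.max(axis=0) - lo
    out = np.zeros_like(F)
    nz = rng > 0
    out[:, nz] = (F[:, nz] - lo[nz]) / rng[nz]
    return out


def _sorted_unique(Fn: np.ndarray) -> np.ndarray:
    """Sort ascending by f1; collapse duplicate f1 to the smaller f2."""
    order = np.lexsort((Fn[:, 1], Fn[:, 0]))
    pts = Fn[order]
    keep = np.ones(len(pts), dtype=bool)
    keep[1:] = np.diff(pts[:, 0]) > 0  # first of each f1 run has min f2
    return pts[keep]


def smooth_and_resample(
    points: np.ndarray,
    n_samples: int = 100,
    smoothing: float | None = None,
):
    """Fit a parametric B-spline near the sorted front and resample it.

    Cubic where at least 4 distinct points exist, else the degree drops
    to fit.  ``smoothing`` is FITPACK's residual budget ``s``; the
    default scales with front size (1e-3 per point), so noisy evolved
    fronts are approximated rather than interpolated.  Returns
    ``(curve, tck)`` with ``curve`` of shape (n_samples, 2) evaluated at
    evenly spaced parameter values.
    """
    points = np.asarray(points, dtype=float)
    if len(points) < 2:
        raise ValueError("need at least 2 distinct points to fit a curve")
    k = min(3, len(points) - 1)
    s = smoothing if smoothing is not None else 1e-3 * len(points)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # FITPACK chatter on tiny fronts
        tck, _ = interpolate.splprep([points[:, 0], points[:, 1]], k=k, s=s)
    u = np.linspace(0.0, 1.0, n_samples)
    x, y = interpolate.splev(u, tck)
    return np.column_stack([x, y]), tck


def curvature(tck, n_samples: int = 100) -> np.ndarray:
    """Curvature of a parametric spline at evenly spaced parameters.

    kappa(t) = |x'y'' - y'x''| / (x'^2 + y'^2)^(3/2); degenerate
    (zero-speed) samples get kappa = 0.
    """
    u = np.linspace(0.0, 1.0, n_samples)
    dx, dy = interpolate.splev(u, tck, der=1)
    ddx, ddy = interpolate.splev(u, tck, der=2)
    speed_sq = np.asarray(dx) ** 2 + np.asarray(dy) ** 2
    num = np.abs(np.asarray(dx) * np.asarray(ddy) - np.asarray(dy) * np.asarray(ddx))
    with np.errstate(divide="ignore", invalid="ignore"):
        kappa = np.where(speed_sq > 0, num / speed_sq**1.5, 0.0)
    return kappa


def _argmin_lex(primary: np.ndarray, secondary: np.ndarray) -> int:
    """Index minimizing primary, ties by secondary, then by position."""
    return int(np.lexsort((secondary, primary))[0])


def select(
    archive: ParetoArchive,
    strategy: str = "knee",
    n_samples: int = 100,
    smoothing: float | None = None,
) -> SelectionResult:
    """Choose one solution from a Pareto archive.

    ``min_f1`` / ``min_f2`` minimize that objective (ties broken by the
    other objective, then by index).  ``knee`` runs the curvature-based
    detector described in the module docstring.  A singleton archive is
    returned unchanged for every strategy.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; pick from {STRATEGIES}")
    F = np.asarray(archive.F, dtype=float)
    if len(F) == 0:
        raise ValueError("empty archive")

    diagnostics: dict = {}
    if len(F) == 1:
        idx = 0
    elif strategy == "min_f1":
        idx = _argmin_lex(F[:, 0], F[:, 1])
    elif strategy == "min_f2":
        idx = _argmin_lex(F[:, 1], F[:, 0])
    else:
        idx, diagnostics = _knee_index(F, n_samples, smoothing)

    return SelectionResult(
        index=idx,
        alpha=np.asarray(archive.alphas[idx], dtype=float),
        f1=float(F[idx, 0]),
        f2=float(F[idx, 1]),
        strategy=strategy,
        diagnostics=diagnostics,
    )


def _knee_index(F, n_samples, smoothing):
    Fn = normalize_front(F)
    pts = _sorted_unique(Fn)
    if len(pts) < 2:
        # all points collapse after normalization: no geometry to exploit
        return _argmin_lex(F[:, 0], F[:, 1]), {"degenerate": True}
    curve, tck = smooth_and_resample(pts, n_samples=n_samples, smoothing=smoothing)
    kappa = curvature(tck, n_samples=n_samples)
    j = int(np.argmax(kappa))
    target = curve[j]

    dists = np.linalg.norm(Fn - target, axis=1)
    idx = _argmin_lex(dists, np.arange(len(Fn)))
    top3 = np.argsort(dists, kind="stable")[:3]

    mean_kappa = kappa.mean()
    # a numerically flat profile (straight front) has no knee at all;
    # without the guard, noise at the 1e-10 level can fake a sharp ratio
    if kappa.max() <= 1e-8 or mean_kappa <= 0:
        ratio = 0.0
    else:
        ratio = float(kappa.max() / mean_kappa)
    low_confidence = ratio < KNEE_CONFIDENCE_RATIO
    if low_confidence:
        warnings.warn(
            "Pareto front has near-constant curvature "
            f"(max/mean = {ratio:.3g}); knee selection is low-confidence",
            UserWarning,
            stacklevel=3,
        )
    # curvature attributed to each archive point: its nearest curve sample
    nearest_sample = np.argmin(
        np.linalg.norm(Fn[:, None, :] - curve[None, :, :], axis=2), axis=1
    )
    diagnostics = {
        "normalized_front": Fn,
        "curve": curve,
        "kappa": kappa,
        "point_kappa": kappa[nearest_sample],
        "max_kappa_sample": j,
        "top3": top3,
        "confidence_ratio": ratio,
        "low_confidence": low_confidence,
    }
    return idx, diagnostics
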