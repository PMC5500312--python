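"""Longitudinal/transversal decomposition and Gaussian-fit diffusion.

Dendrites are thin, elongated structures, so receptor motion in the imaging
plane is constrained: diffusion along the dendrite's main extension (the
longitudinal axis) can be much faster than across it. Trajectories are
decomposed along a longitudinal and a transversal direction — either taken
from a known dendrite geometry, or estimated as the major axis of the
trajectory's second-moment ellipse — and per-axis single-frame displacement
distributions are fitted with Gaussians. With the per-frame update
``x_{t+dt} = x_t + sqrt(2 D dt) φ + μ dt`` the fitted mean m and variance σ²
give the drift ``μ = m/dt`` and diffusion ``D = σ²/(2 dt)``; the ``paper``
convention uses ``D = σ²/dt``, matching scripts whose update rule omits the
factor 2 (then exactly D_paper = 2 × D_standard on the same data).

Only consecutive-frame steps enter the fits; displacements spanning blink
gaps are excluded, because the update rule is a per-dt relation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from dendrospt.geometry import DendriteGeometry
from dendrospt.metrics import InsufficientDataError

#: Minimum fraction of point-cloud variance on the major axis for a
#: trajectory to count as exploring a "fairly linear" dendrite stretch.
LINEARITY_THRESHOLD = 0.8


class DegenerateCloudError(ValueError):
    """All points coincide; no axis can be estimated."""


@dataclass(frozen=True)
class AxisDecomposition:
    """A trajectory's steps in the dendrite's local frame."""

    axis_origin: tuple[float, float]
    axis_direction: tuple[float, float]  # unit vector, longitudinal
    steps_long: np.ndarray  # μm, consecutive-frame steps only
    steps_trans: np.ndarray
    dt: float
    linearity: float  # fraction of variance on the major axis, [0.5, 1]
    n_steps: int
    axis_source: str  # "geometry" | "pca"


@dataclass(frozen=True)
class GaussianFitResult:
    """Gaussian fit of a single-step displacement distribution."""

    m: float  # μm, mean step
    sigma2: float  # μm², step variance
    mu: float  # μm/s, drift = m / dt
    D: float  # μm²/s, convention-dependent
    n_steps: int
    convention: str  # "standard" | "paper"


def estimate_axis(
    traj: pd.DataFrame,
    geometry: DendriteGeometry | None = None,
    dt: float = 0.05,
) -> AxisDecomposition:
    """Decompose a trajectory into longitudinal/transversal steps.

    If ``geometry`` is given its axis is used directly; otherwise the
    longitudinal direction is the principal (major) axis of the point
    cloud's second-moment ellipse. The linearity score is the fraction of
    total variance carried by the major axis (1.0 for a perfectly collinear
    cloud, 0.5 for an isotropic one).
    """
    if len(traj) < 10:
        raise InsufficientDataError(
            f"axis estimation needs >= 10 points, got {len(traj)}"
        )
    grp = traj.sort_values("frame")
    frames = grp["frame"].to_numpy(dtype=int)
    xy = grp[["x_um", "y_um"]].to_numpy(dtype=float)

    center = xy.mean(axis=0)
    centered = xy - center
    cov = centered.T @ centered / len(xy)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    total = float(evals.sum())
    if total <= 0:
        raise DegenerateCloudError("all points identical; no principal axis")
    linearity = float(evals[1] / total)

    if geometry is not None:
        direction = np.asarray(geometry.axis, dtype=float)
        origin = tuple(geometry.origin)
        source = "geometry"
    else:
        direction = evecs[:, 1]
        # Deterministic sign: point towards positive x (then positive y).
        if direction[0] < 0 or (direction[0] == 0 and direction[1] < 0):
            direction = -direction
        origin = (float(center[0]), float(center[1]))
        source = "pca"

    normal = np.array([-direction[1], direction[0]])
    consecutive = np.diff(frames) == 1
    d = np.diff(xy, axis=0)[consecutive]
    return AxisDecomposition(
        axis_origin=origin,
        axis_direction=(float(direction[0]), float(direction[1])),
        steps_long=d @ direction,
        steps_trans=d @ normal,
        dt=dt,
        linearity=linearity,
        n_steps=int(consecutive.sum()),
        axis_source=source,
    )


def fit_gaussian_displacements(
    steps: np.ndarray,
    dt: float = 0.05,
    convention: str = "standard",
    min_steps: int = 30,
    method: str = "moments",
    bins: int = 20,
) -> GaussianFitResult:
    """Fit a Gaussian to single-frame displacements; derive μ and D.

    ``method="moments"`` (default) uses the maximum-likelihood estimates —
    the sample mean and (population) variance. ``method="histogram"`` fits a
    Gaussian curve to the binned step histogram by least squares, for
    fidelity to curve-fitting workflows; it needs a sensible ``bins`` count
    and is noisier.
    """
    steps = np.asarray(steps, dtype=float)
    if steps.size < min_steps:
        raise InsufficientDataError(
            f"Gaussian fit needs >= {min_steps} steps, got {steps.size}"
        )
    if convention not in ("standard", "paper"):
        raise ValueError("convention must be 'standard' or 'paper'")

    if method == "moments":
        m = float(steps.mean())
        sigma2 = float(steps.var(ddof=0))
    elif method == "histogram":
        m, sigma2 = _histogram_gaussian_fit(steps, bins)
    else:
        raise ValueError("method must be 'moments' or 'histogram'")

    mu = m / dt
    D = sigma2 / dt if convention == "paper" else sigma2 / (2.0 * dt)
    return GaussianFitResult(
        m=m,
        sigma2=sigma2,
        mu=mu,
        D=max(D, 0.0),
        n_steps=int(steps.size),
        convention=convention,
    )


def _histogram_gaussian_fit(steps: np.ndarray, bins: int) -> tuple[float, float]:
    """Least-squares Gaussian curve fit to a step histogram."""
    from scipy.optimize import curve_fit

    counts, edges = np.histogram(steps, bins=bins, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])

    def gauss(x, a, m, s):
        return a * np.exp(-0.5 * ((x - m) / s) ** 2)

    m0, s0 = float(steps.mean()), float(steps.std() or 1e-3)
    popt, _ = curve_fit(
        gauss, centers, counts, p0=[1.0 / (s0 * np.sqrt(2 * np.pi)), m0, s0],
        maxfev=10000,
    )
    return float(popt[1]), float(popt[2]) ** 2


def compare_axes(
    trajectories: pd.DataFrame,
    geometry: DendriteGeometry | None = None,
    dt: float = 0.05,
    convention: str = "standard",
    linearity_threshold: float = LINEARITY_THRESHOLD,
    min_steps: int = 30,
) -> tuple[pd.DataFrame, dict | None]:
    """Paired per-axis diffusion estimates across a trajectory set.

    For each track that passes the linearity threshold (skipped when a
    geometry is supplied, since the axis is then known a priori) and has
    enough consecutive-frame steps, estimates (D_long, D_trans, mu_long,
    mu_trans). Returns the per-track table and, when n >= 2, a two-sided
    paired Wilcoxon signed-rank comparison of D_long vs D_trans.
    """
    rows = []
    for tid, grp in trajectories.groupby("track_id"):
        try:
            dec = estimate_axis(grp, geometry=geometry, dt=dt)
        except (InsufficientDataError, DegenerateCloudError):
            continue
        if geometry is None and dec.linearity < linearity_threshold:
            continue
        try:
            fit_l = fit_gaussian_displacements(
                dec.steps_long, dt=dt, convention=convention, min_steps=min_steps
            )
            fit_t = fit_gaussian_displacements(
                dec.steps_trans, dt=dt, convention=convention, min_steps=min_steps
            )
        except InsufficientDataError:
            continue
        rows.append(
            {
                "track_id": tid,
                "axis_x": dec.axis_direction[0],
                "axis_y": dec.axis_direction[1],
                "linearity": dec.linearity,
                "D_long": fit_l.D,
                "D_trans": fit_t.D,
                "mu_long": fit_l.mu,
                "mu_trans": fit_t.mu,
                "n_steps": dec.n_steps,
                "convention": convention,
            }
        )
    table = pd.DataFrame(rows)
    if table.empty:
        raise InsufficientDataError(
            "no trajectory passed the linearity/step-count requirements"
        )
    test = None
    if len(table) >= 2 and not np.allclose(table["D_long"], table["D_trans"]):
        stat, p = stats.wilcoxon(
            table["D_long"], table["D_trans"], alternative="two-sided"
        )
        test = {
            "test": "wilcoxon_paired",
            "statistic": float(stat),
            "p_value": float(p),
            "n": int(len(table)),
        }
    return table, test
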