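"""MSD curves, diffusion coefficients, compartments, dwell and transitions.

The mean squared displacement of a trajectory at lag ``n`` frames is the
average of ``(X_{i+n}-X_i)^2 + (Y_{i+n}-Y_i)^2`` over every ordered pair of
localizations ``n`` frames apart. Lags are frame-indexed, so pairs spanning
blink gaps contribute whenever both endpoints exist; the per-lag pair count
is reported. The *instantaneous* diffusion coefficient is the slope of a
least-squares line through the first four MSD points divided by 4 (planar
diffusion, MSD = 4·D·t). The fit includes an intercept, which absorbs the
static localization-noise offset (≈ 4σ²); a ``paper_convention`` switch
forces the fit through the origin instead.

Compartment logic: a localization is *synaptic* when it falls inside the
effective region of a synapse (punctum + 2-pixel dilation, boundary
inclusive; overlaps resolved by nearest centre), otherwise *extrasynaptic*.
A *dwell episode* is a maximal synaptic run. An *inter-synaptic transition*
is a passage from one synapse to a different one with no intervening visit
to a third synapse; its transition time runs from the last frame inside the
source to the first frame inside the target. Excursions that return to the
same synapse are not transitions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from dendrospt.geometry import SynapseMap

EXTRASYNAPTIC = -1

#: Default mobile/immobile threshold on D, μm²/s. The mobile receptor
#: population is commonly reported without an explicit cutoff; this value is
#: configurable wherever it is used.
MOBILE_D_THRESHOLD = 0.0075


class InsufficientDataError(ValueError):
    """Trajectory too short (or curve too sparse) for the requested metric."""


@dataclass(frozen=True)
class MSDCurve:
    """MSD versus lag time for one trajectory."""

    lags: np.ndarray  # s, strictly increasing multiples of dt
    msd: np.ndarray  # μm²
    n_pairs: np.ndarray  # pairs per lag
    dt: float  # s

    def __post_init__(self) -> None:
        for name in ("lags", "msd", "n_pairs"):
            object.__setattr__(self, name, np.asarray(getattr(self, name)))


@dataclass(frozen=True)
class DiffusionEstimate:
    """Diffusion coefficient with provenance."""

    D: float  # μm²/s, clamped to >= 0
    method: str  # "msd_fit" | "gaussian_fit"
    axis: str  # "planar" | "longitudinal" | "transversal"
    n_obs: int
    drift: float | None = None  # μm/s, gaussian_fit only
    intercept: float | None = None  # μm², msd_fit only
    confined: bool = False  # set when the raw slope was <= 0


@dataclass(frozen=True)
class TransitionEvent:
    """One synapse-to-different-synapse passage."""

    source_id: int
    target_id: int
    exit_frame: int
    entry_frame: int
    transition_time: float  # s

    def __post_init__(self) -> None:
        if self.source_id == self.target_id:
            raise ValueError("transition requires distinct synapses")
        if self.entry_frame <= self.exit_frame:
            raise ValueError("entry must follow exit")


@dataclass(frozen=True)
class DwellEpisode:
    """One uninterrupted visit to a synaptic compartment."""

    synapse_id: int
    start_frame: int
    end_frame: int
    duration: float  # s


def compute_msd(traj: pd.DataFrame, max_lag: int | None = None, dt: float = 0.05) -> MSDCurve:
    """MSD curve of one trajectory, frame-indexed and gap-aware.

    Parameters
    ----------
    traj
        Trajectory table with columns ``frame, x_um, y_um`` (one track).
    max_lag
        Largest lag in frames; defaults to span // 2 (at least 4).
    dt
        Frame interval in seconds.
    """
    if len(traj) < 5:
        raise InsufficientDataError(
            f"trajectory has {len(traj)} localizations; at least 5 required"
        )
    frames = traj["frame"].to_numpy(dtype=int)
    order = np.argsort(frames, kind="stable")
    frames = frames[order]
    if np.any(np.diff(frames) <= 0):
        raise ValueError("trajectory frames must be strictly increasing")
    xy = traj[["x_um", "y_um"]].to_numpy(dtype=float)[order]

    span = int(frames[-1] - frames[0])
    if max_lag is None:
        max_lag = max(span // 2, 4)
    max_lag = min(max_lag, span)

    # Scatter positions onto the frame grid; NaN marks dark frames.
    grid = np.full((span + 1, 2), np.nan)
    grid[frames - frames[0]] = xy

    lags = np.arange(1, max_lag + 1)
    msd = np.empty(len(lags))
    n_pairs = np.empty(len(lags), dtype=int)
    for k, lag in enumerate(lags):
        d = grid[lag:] - grid[:-lag]
        sq = d[:, 0] ** 2 + d[:, 1] ** 2
        valid = ~np.isnan(sq)
        n_pairs[k] = int(valid.sum())
        msd[k] = float(np.nanmean(sq)) if n_pairs[k] else np.nan
    return MSDCurve(lags=lags * dt, msd=msd, n_pairs=n_pairs, dt=dt)


def fit_diffusion_msd(
    curve: MSDCurve,
    n_points: int = 4,
    paper_convention: bool = False,
) -> DiffusionEstimate:
    """Instantaneous D from a linear fit of the first MSD points.

    Fits a least-squares line (with intercept, unless ``paper_convention``
    forces it through the origin) to the MSD values at lags 1..``n_points``
    frames and returns ``D = slope / 4``. A non-positive slope clamps D to 0
    and sets the ``confined`` flag.
    """
    usable = (curve.n_pairs[:n_points] > 0) & ~np.isnan(curve.msd[:n_points])
    if len(curve.lags) < n_points or not usable.all():
        raise InsufficientDataError(
            f"MSD fit needs populated lags 1..{n_points}"
        )
    t = curve.lags[:n_points]
    y = curve.msd[:n_points]
    if paper_convention:
        slope = float(t @ y / (t @ t))
        intercept = 0.0
    else:
        A = np.column_stack([t, np.ones_like(t)])
        (slope, intercept), *_ = np.linalg.lstsq(A, y, rcond=None)
    D = slope / 4.0
    # tolerance absorbs floating-point noise in an exactly-flat fit
    confined = D <= 1e-12
    if confined:
        D = 0.0
    n_obs = int(curve.n_pairs[:n_points].sum())
    return DiffusionEstimate(
        D=max(float(D), 0.0),
        method="msd_fit",
        axis="planar",
        n_obs=n_obs,
        intercept=float(intercept),
        confined=bool(confined),
    )


def classify_points(traj: pd.DataFrame, synapse_map: SynapseMap) -> np.ndarray:
    """Per-localization compartment labels.

    Returns an int array aligned with ``traj`` rows: the synapse id when the
    point lies inside that synapse's effective region (boundary inclusive;
    overlapping regions resolved by nearest centre), else ``EXTRASYNAPTIC``
    (-1).
    """
    xy = traj[["x_um", "y_um"]].to_numpy(dtype=float)
    labels = np.full(len(xy), EXTRASYNAPTIC, dtype=int)
    if len(synapse_map) == 0 or len(xy) == 0:
        return labels
    centers = synapse_map.centers
    radii = synapse_map.effective_radii
    ids = np.array([s.synapse_id for s in synapse_map], dtype=int)
    # distances: (n_points, n_synapses)
    d = np.hypot(xy[:, 0:1] - centers[:, 0], xy[:, 1:2] - centers[:, 1])
    inside = d <= radii + 1e-12
    any_inside = inside.any(axis=1)
    if any_inside.any():
        d_masked = np.where(inside, d, np.inf)
        labels[any_inside] = ids[np.argmin(d_masked[any_inside], axis=1)]
    return labels


def _runs(labels: np.ndarray) -> list[tuple[int, int, int]]:
    """Maximal runs of equal labels as (label, start_index, end_index)."""
    runs = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            runs.append((int(labels[start]), start, i - 1))
            start = i
    return runs


def detect_transitions(
    labels: np.ndarray,
    frames: np.ndarray,
    dt: float = 0.05,
) -> list[TransitionEvent]:
    """Inter-synaptic transitions from a compartment label series.

    For each maximal synaptic run at synapse A whose next synaptic run is at
    B ≠ A, emit one event: exit at the last frame in A, entry at the first
    frame in B, transition time ``(entry - exit) * dt``. Re-entries
    (A → extrasynaptic → A) emit nothing, and by construction no third
    synapse is visited inside the event interval.
    """
    labels = np.asarray(labels)
    frames = np.asarray(frames, dtype=int)
    if labels.shape != frames.shape:
        raise ValueError("labels and frames must align")
    syn_runs = [r for r in _runs(labels) if r[0] != EXTRASYNAPTIC]
    events = []
    for (a, _, a_end), (b, b_start, _) in zip(syn_runs, syn_runs[1:]):
        if a == b:
            continue
        exit_frame = int(frames[a_end])
        entry_frame = int(frames[b_start])
        events.append(
            TransitionEvent(
                source_id=a,
                target_id=b,
                exit_frame=exit_frame,
                entry_frame=entry_frame,
                transition_time=(entry_frame - exit_frame) * dt,
            )
        )
    return events


def dwell_episodes(
    labels: np.ndarray,
    frames: np.ndarray,
    dt: float = 0.05,
) -> list[DwellEpisode]:
    """Dwell episodes: one per maximal synaptic run.

    Duration counts localizations in the run times ``dt`` (each localization
    represents one sampling interval, so a single-frame visit lasts one
    frame interval). Dark frames inside a compartment are not counted.
    """
    labels = np.asarray(labels)
    frames = np.asarray(frames, dtype=int)
    if labels.shape != frames.shape:
        raise ValueError("labels and frames must align")
    episodes = []
    for label, start, end in _runs(labels):
        if label == EXTRASYNAPTIC:
            continue
        episodes.append(
            DwellEpisode(
                synapse_id=label,
                start_frame=int(frames[start]),
                end_frame=int(frames[end]),
                duration=(end - start + 1) * dt,
            )
        )
    return episodes


def msd_steady_state(
    curve: MSDCurve,
    window: tuple[float, float] | None = None,
) -> tuple[float, bool]:
    """Late-lag MSD plateau value (confinement area readout).

    Averages the MSD over a late-lag window (default: the last quarter of
    computed lags). Returns ``(steady_state, is_plateau)``; the plateau flag
    is cleared when the MSD still grows materially across the window (late
    rise exceeding 10% of the window mean), which indicates free rather than
    confined diffusion.
    """
    valid = ~np.isnan(curve.msd)
    lags = curve.lags[valid]
    msd = curve.msd[valid]
    if window is None:
        start = lags[0] + 0.75 * (lags[-1] - lags[0])
        window = (float(start), float(lags[-1]))
    sel = (lags >= window[0]) & (lags <= window[1])
    if not sel.any():
        raise InsufficientDataError("steady-state window contains no MSD values")
    value = float(msd[sel].mean())
    if sel.sum() >= 2 and value > 0:
        slope = np.polyfit(lags[sel], msd[sel], 1)[0]
        rise = slope * (lags[sel][-1] - lags[sel][0])
        is_plateau = abs(rise) <= 0.10 * value
    else:
        is_plateau = True
    return value, bool(is_plateau)


def analyze_tracks(
    traj: pd.DataFrame,
    synapse_map: SynapseMap,
    dt: float = 0.05,
    min_points: int = 5,
    msd_fit_points: int = 4,
    mobile_threshold: float = MOBILE_D_THRESHOLD,
    paper_convention: bool = False,
) -> dict[str, pd.DataFrame]:
    """Per-track diffusion + compartment analysis of a trajectory table.

    Returns three tables: ``tracks`` (one row per analyzable track:
    ``track_id, n_points, D_msd_um2s, intercept_um2, confined_flag, mobile,
    synaptic_fraction, n_transitions``), ``transitions`` and ``dwells``.
    Tracks with fewer than ``min_points`` localizations are skipped.
    """
    track_rows, event_rows, dwell_rows = [], [], []
    for tid, grp in traj.groupby("track_id"):
        grp = grp.sort_values("frame")
        frames = grp["frame"].to_numpy(dtype=int)
        labels = classify_points(grp, synapse_map)
        events = detect_transitions(labels, frames, dt=dt)
        dwells = dwell_episodes(labels, frames, dt=dt)
        for e in events:
            event_rows.append(
                {
                    "track_id": tid,
                    "source_id": e.source_id,
                    "target_id": e.target_id,
                    "exit_frame": e.exit_frame,
                    "entry_frame": e.entry_frame,
                    "transition_s": e.transition_time,
                }
            )
        for ep in dwells:
            dwell_rows.append(
                {
                    "track_id": tid,
                    "synapse_id": ep.synapse_id,
                    "start_frame": ep.start_frame,
                    "end_frame": ep.end_frame,
                    "duration_s": ep.duration,
                }
            )
        if len(grp) < min_points:
            continue
        try:
            curve = compute_msd(grp, dt=dt)
            est = fit_diffusion_msd(
                curve, n_points=msd_fit_points, paper_convention=paper_convention
            )
        except InsufficientDataError:
            continue
        track_rows.append(
            {
                "track_id": tid,
                "n_points": len(grp),
                "D_msd_um2s": est.D,
                "intercept_um2": est.intercept,
                "confined_flag": est.confined,
                "mobile": est.D > mobile_threshold,
                "synaptic_fraction": float((labels != EXTRASYNAPTIC).mean()),
                "n_transitions": len(events),
            }
        )
    return {
        "tracks": pd.DataFrame(
            track_rows,
            columns=[
                "track_id", "n_points", "D_msd_um2s", "intercept_um2",
                "confined_flag", "mobile", "synaptic_fraction", "n_transitions",
            ],
        ),
        "transitions": pd.DataFrame(
            event_rows,
            columns=[
                "track_id", "source_id", "target_id",
                "exit_frame", "entry_frame", "transition_s",
            ],
        ),
        "dwells": pd.DataFrame(
            dwell_rows,
            columns=["track_id", "synapse_id", "start_frame", "end_frame", "duration_s"],
        ),
    }
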