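"""Ground-truthed receptor trajectory simulation on dendrite segments.

Receptor motion is anisotropic Brownian motion with drift in the dendrite's
local frame, updated once per camera frame::

    u_{t+dt} = u_t + sqrt(2 * D_long * dt) * phi + mu_long * dt
    v_{t+dt} = v_t + sqrt(2 * D_trans * dt) * phi + mu_trans * dt

with ``phi`` standard normal. The per-axis step variance follows the
standard convention ``2*D*dt`` (planar MSD = 4*D*t). A ``paper_convention``
switch replaces it by ``D*dt`` — the literal discrete update rule of some
SPT scripts whose Gaussian-fit estimator is ``D = sigma^2/dt`` — so that the
two conventions can be cross-checked against each other.

Three extra layers turn ideal Brownian paths into realistic quantum-dot SPT
data:

* **Trapping** — inside a synaptic compartment the receptor is slowed
  (``D * trap_D_factor``) until it escapes the trapped state with a fixed
  per-frame probability; an escaped receptor diffuses freely until it leaves
  the compartment, after which it can be re-trapped on re-entry.
* **Blinking** — a two-state visible/dark Markov chain per frame; dark
  frames emit no localization, creating the gaps the track linker must
  close.
* **Localization noise** — isotropic Gaussian error (default 40 nm per
  axis) added to visible positions.

Dendrite edges are reflecting: receptors stay on the membrane strip.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from dendrospt.geometry import PIXEL_SIZE_UM, DendriteGeometry, SynapseMap

STATE_FREE = "free"
STATE_TRAPPED = "trapped"


@dataclass(frozen=True)
class SimulationParams:
    """Parameters of one simulated recording.

    Defaults emulate a 1-minute recording: 1200 frames at 20 Hz (dt = 50 ms),
    ~40 nm localization precision and a 160 nm camera pixel.
    """

    D_long: float = 0.066  # μm²/s, longitudinal diffusion coefficient
    D_trans: float = 0.066  # μm²/s, transversal diffusion coefficient
    drift_long: float = 0.0  # μm/s
    drift_trans: float = 0.0  # μm/s
    dt: float = 0.05  # s, frame interval
    n_frames: int = 1200
    loc_noise_sd: float = 0.040  # μm per axis
    pixel_size: float = PIXEL_SIZE_UM
    trap_D_factor: float = 1.0  # D multiplier while trapped, in (0, 1]
    trap_escape_prob: float = 1.0  # per-frame escape probability
    blink_on_prob: float = 1.0  # dark -> visible per frame
    blink_off_prob: float = 0.0  # visible -> dark per frame
    seed: int | None = None
    paper_convention: bool = False

    def __post_init__(self) -> None:
        if self.D_long < 0 or self.D_trans < 0:
            raise ValueError("diffusion coefficients must be nonnegative")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_frames < 2:
            raise ValueError("n_frames must be at least 2")
        if not 0 < self.trap_D_factor <= 1:
            raise ValueError("trap_D_factor must lie in (0, 1]")
        for name in ("trap_escape_prob", "blink_on_prob", "blink_off_prob"):
            p = getattr(self, name)
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.loc_noise_sd < 0:
            raise ValueError("loc_noise_sd must be nonnegative")

    def step_sd(self, D: float) -> float:
        """Per-axis step standard deviation for diffusion coefficient ``D``."""
        var = D * self.dt if self.paper_convention else 2.0 * D * self.dt
        return float(np.sqrt(var))

    def with_seed(self, seed: int) -> "SimulationParams":
        return replace(self, seed=seed)


def _reflect(value: float, lo: float, hi: float) -> float:
    """Fold a coordinate back into [lo, hi] by specular reflection."""
    if hi <= lo:
        return lo
    width = hi - lo
    y = (value - lo) % (2.0 * width)
    if y > width:
        y = 2.0 * width - y
    return lo + y


def _fold(values: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Vectorized specular fold of an array of coordinates into [lo, hi]."""
    width = hi - lo
    y = np.mod(values - lo, 2.0 * width)
    return lo + np.where(y > width, 2.0 * width - y, y)


def _simulate_blinking(
    n: int, params: SimulationParams, rng: np.random.Generator
) -> np.ndarray:
    """Visible/dark state per frame from a two-state Markov chain."""
    visible = np.ones(n, dtype=bool)
    if params.blink_off_prob == 0.0:
        return visible
    vis = True
    draws = rng.random(n)
    for t in range(n):
        visible[t] = vis
        if vis:
            if draws[t] < params.blink_off_prob:
                vis = False
        elif draws[t] < params.blink_on_prob:
            vis = True
    return visible


def _emit(
    uv: np.ndarray,
    states: np.ndarray,
    trapped_at: np.ndarray,
    geometry: DendriteGeometry,
    params: SimulationParams,
    rng: np.random.Generator,
    receptor_id: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply blinking + localization noise; build the two output tables."""
    n = uv.shape[0]
    visible = _simulate_blinking(n, params, rng)
    world = geometry.to_world(uv)
    truth = pd.DataFrame(
        {
            "receptor_id": receptor_id,
            "frame": np.arange(n),
            "true_x_um": world[:, 0],
            "true_y_um": world[:, 1],
            "state": states,
            "visible": visible,
            "trapped_synapse": trapped_at,
        }
    )
    vis_idx = np.where(visible)[0]
    noise = rng.normal(0.0, params.loc_noise_sd, size=(vis_idx.size, 2))
    locs = pd.DataFrame(
        {
            "track_id": receptor_id,
            "frame": vis_idx,
            "x_um": world[vis_idx, 0] + noise[:, 0],
            "y_um": world[vis_idx, 1] + noise[:, 1],
        }
    )
    return locs, truth


def simulate_trajectory(
    geometry: DendriteGeometry,
    synapses: SynapseMap | None,
    params: SimulationParams,
    rng: np.random.Generator | None = None,
    receptor_id: int = 0,
    start_uv: tuple[float, float] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one receptor–QD complex for ``params.n_frames`` frames.

    Returns
    -------
    localizations : DataFrame
        Columns ``track_id, frame, x_um, y_um`` — the *emitted* data: visible
        frames only, with localization noise applied. ``track_id`` is the
        receptor id (ground-truth identity; the linker re-derives its own).
    ground_truth : DataFrame
        Columns ``receptor_id, frame, true_x_um, true_y_um, state, visible``
        for every frame, noise-free and blink-free.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    if synapses is None:
        synapses = SynapseMap(pixel_size=params.pixel_size)

    centers_uv = (
        geometry.to_local(synapses.centers) if len(synapses) else np.empty((0, 2))
    )
    radii = synapses.effective_radii if len(synapses) else np.empty(0)
    syn_ids = np.array([s.synapse_id for s in synapses], dtype=int)

    n = params.n_frames
    uv = np.empty((n, 2))
    states = np.empty(n, dtype=object)
    trapped_at = np.full(n, -1, dtype=int)

    if start_uv is None:
        u = rng.uniform(0.0, geometry.length)
        v = rng.uniform(-geometry.half_width, geometry.half_width)
    else:
        u, v = float(start_uv[0]), float(start_uv[1])

    trapping_active = len(synapses) > 0 and params.trap_D_factor < 1.0
    if not trapping_active and params.drift_long == 0.0 and params.drift_trans == 0.0:
        # Vectorized free-diffusion path. Folding the unreflected cumulative
        # path into the domain has the law of reflected diffusion for
        # symmetric (drift-free) increments.
        steps = rng.standard_normal((n - 1, 2))
        steps[:, 0] *= params.step_sd(params.D_long)
        steps[:, 1] *= params.step_sd(params.D_trans)
        free = np.concatenate([[[u, v]], steps]).cumsum(axis=0)
        uv[:, 0] = _fold(free[:, 0], 0.0, geometry.length)
        uv[:, 1] = _fold(free[:, 1], -geometry.half_width, geometry.half_width)
        states[:] = STATE_FREE
        return _emit(uv, states, trapped_at, geometry, params, rng, receptor_id)

    def containing_synapse(u: float, v: float) -> int:
        """Index into the map of the compartment containing (u, v), else -1."""
        if len(radii) == 0:
            return -1
        d = np.hypot(centers_uv[:, 0] - u, centers_uv[:, 1] - v)
        inside = d <= radii + 1e-12
        if not inside.any():
            return -1
        # Overlaps resolved by nearest centre.
        cand = np.where(inside)[0]
        return int(cand[np.argmin(d[cand])])

    trapped = False
    trapped_syn = -1  # index into the map
    sd_long_free = params.step_sd(params.D_long)
    sd_trans_free = params.step_sd(params.D_trans)
    sd_long_trap = params.step_sd(params.D_long * params.trap_D_factor)
    sd_trans_trap = params.step_sd(params.D_trans * params.trap_D_factor)

    here = containing_synapse(u, v)
    if here >= 0 and params.trap_D_factor < 1.0:
        trapped, trapped_syn = True, here

    for t in range(n):
        uv[t] = (u, v)
        if trapped:
            states[t] = STATE_TRAPPED
            trapped_at[t] = syn_ids[trapped_syn]
        else:
            states[t] = STATE_FREE
        if t == n - 1:
            break

        if trapped:
            sd_l, sd_t = sd_long_trap, sd_trans_trap
        else:
            sd_l, sd_t = sd_long_free, sd_trans_free
        du = sd_l * rng.standard_normal() + params.drift_long * params.dt
        dv = sd_t * rng.standard_normal() + params.drift_trans * params.dt
        u = _reflect(u + du, 0.0, geometry.length)
        v = _reflect(v + dv, -geometry.half_width, geometry.half_width)

        here = containing_synapse(u, v)
        if trapped:
            if here != trapped_syn:
                # Left the compartment: trapping ends regardless of escape.
                trapped, trapped_syn = False, -1
                if here >= 0:  # stepped straight into another compartment
                    trapped, trapped_syn = True, here
            elif rng.random() < params.trap_escape_prob:
                trapped = False  # untrapped but still inside; free until exit
        else:
            prev_inside = trapped_syn  # -1 unless refractory
            if here >= 0 and here != prev_inside:
                trapped, trapped_syn = True, here
            elif here < 0:
                trapped_syn = -1  # refractory period over once outside
        if trapped and params.trap_D_factor >= 1.0:
            trapped, trapped_syn = False, -1  # trapping disabled

    return _emit(uv, states, trapped_at, geometry, params, rng, receptor_id)


def simulate_many(
    n_receptors: int,
    geometry: DendriteGeometry,
    synapses: SynapseMap | None,
    params: SimulationParams,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate ``n_receptors`` independent receptors with one seed stream."""
    if n_receptors < 1:
        raise ValueError("n_receptors must be at least 1")
    rng = np.random.default_rng(params.seed)
    locs, truths = [], []
    for rid in range(n_receptors):
        l, t = simulate_trajectory(geometry, synapses, params, rng=rng, receptor_id=rid)
        locs.append(l)
        truths.append(t)
    return (
        pd.concat(locs, ignore_index=True),
        pd.concat(truths, ignore_index=True),
    )


def emit_dataset(
    n_receptors: int,
    geometry: DendriteGeometry,
    synapses: SynapseMap,
    params: SimulationParams,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write trajectory, synapse and ground-truth CSVs for one dataset.

    Returns the paths of the three files. Ids are consistent across files:
    ``track_id`` in the trajectory table equals ``receptor_id`` in the
    ground-truth table.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    locs, truth = simulate_many(n_receptors, geometry, synapses, params)
    paths = {
        "trajectories": out / "trajectories.csv",
        "synapses": out / "synapses.csv",
        "ground_truth": out / "ground_truth.csv",
    }
    locs.to_csv(paths["trajectories"], index=False, float_format="%.6f")
    synapses.write_csv(paths["synapses"])
    truth_out = truth.copy()
    truth_out["visible"] = truth_out["visible"].astype(int)
    truth_out.to_csv(paths["ground_truth"], index=False, float_format="%.6f")
    return paths
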