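"""Dendrite geometry and synapse maps.

A dendrite segment is modelled as a rectangle: a longitudinal axis (the main
extension of the dendrite) of given length and a transversal half-width.
Synapses are circular puncta placed on the segment; the *effective* synaptic
compartment is the punctum dilated by two camera pixels (2 × 160 nm), the
convention used to define synaptic localizations from a presynaptic marker.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Camera pixel size in μm (EMCCD at 100x).
PIXEL_SIZE_UM = 0.160

#: Number of pixels by which a punctum is dilated to form the synaptic
#: compartment.
COMPARTMENT_DILATION_PX = 2


class CapacityError(ValueError):
    """Requested synapses do not fit inside the dendrite geometry."""


@dataclass(frozen=True)
class DendriteGeometry:
    """Rectangular dendrite segment in the imaging plane.

    Parameters
    ----------
    origin
        World coordinates (μm) of the start of the longitudinal axis.
    axis
        Unit vector of the longitudinal direction.
    length
        Longitudinal extent in μm.
    half_width
        Transversal half-extent in μm; the membrane strip spans
        ``[-half_width, +half_width]`` across the axis.
    """

    origin: tuple[float, float] = (0.0, 0.0)
    axis: tuple[float, float] = (1.0, 0.0)
    length: float = 10.0
    half_width: float = 1.0

    def __post_init__(self) -> None:
        norm = math.hypot(*self.axis)
        if not math.isclose(norm, 1.0, rel_tol=0, abs_tol=1e-9):
            if norm == 0:
                raise ValueError("axis must be a nonzero vector")
            object.__setattr__(self, "axis", (self.axis[0] / norm, self.axis[1] / norm))
        if self.length <= 0:
            raise ValueError("length must be positive")
        if self.half_width <= 0:
            raise ValueError("half_width must be positive")

    @property
    def normal(self) -> tuple[float, float]:
        """Unit vector of the transversal direction (axis rotated +90°)."""
        ax, ay = self.axis
        return (-ay, ax)

    def to_local(self, xy: np.ndarray) -> np.ndarray:
        """Project world coordinates onto (longitudinal, transversal) axes."""
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        rel = xy - np.asarray(self.origin)
        u = rel @ np.asarray(self.axis)
        v = rel @ np.asarray(self.normal)
        return np.column_stack([u, v])

    def to_world(self, uv: np.ndarray) -> np.ndarray:
        """Inverse of :meth:`to_local`."""
        uv = np.atleast_2d(np.asarray(uv, dtype=float))
        ax = np.asarray(self.axis)
        nv = np.asarray(self.normal)
        return np.asarray(self.origin) + np.outer(uv[:, 0], ax) + np.outer(uv[:, 1], nv)

    def contains(self, xy: np.ndarray, atol: float = 1e-9) -> np.ndarray:
        """Boolean mask of points inside the rectangle (boundary inclusive)."""
        uv = self.to_local(xy)
        return (
            (uv[:, 0] >= -atol)
            & (uv[:, 0] <= self.length + atol)
            & (np.abs(uv[:, 1]) <= self.half_width + atol)
        )


@dataclass(frozen=True)
class Synapse:
    """One synaptic punctum with its dilated effective compartment."""

    synapse_id: int
    type: str  # "inhibitory" | "excitatory"
    center: tuple[float, float]  # μm, world frame
    punctum_radius: float  # μm

    def effective_radius(self, pixel_size: float = PIXEL_SIZE_UM) -> float:
        return self.punctum_radius + COMPARTMENT_DILATION_PX * pixel_size


@dataclass
class SynapseMap:
    """Collection of labelled synaptic compartments.

    The effective region of each synapse is a disk: the punctum dilated by
    ``COMPARTMENT_DILATION_PX`` pixels. Overlapping regions are resolved by
    nearest centre during classification.
    """

    synapses: list[Synapse] = field(default_factory=list)
    pixel_size: float = PIXEL_SIZE_UM

    def __post_init__(self) -> None:
        ids = [s.synapse_id for s in self.synapses]
        if len(ids) != len(set(ids)):
            raise ValueError("synapse ids must be unique")

    def __len__(self) -> int:
        return len(self.synapses)

    def __iter__(self):
        return iter(self.synapses)

    @property
    def centers(self) -> np.ndarray:
        if not self.synapses:
            return np.empty((0, 2))
        return np.array([s.center for s in self.synapses], dtype=float)

    @property
    def effective_radii(self) -> np.ndarray:
        return np.array([s.effective_radius(self.pixel_size) for s in self.synapses])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "synapse_id": [s.synapse_id for s in self.synapses],
                "type": [s.type for s in self.synapses],
                "x_um": [s.center[0] for s in self.synapses],
                "y_um": [s.center[1] for s in self.synapses],
                "punctum_radius_um": [s.punctum_radius for s in self.synapses],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, pixel_size: float = PIXEL_SIZE_UM) -> "SynapseMap":
        synapses = [
            Synapse(
                synapse_id=int(row.synapse_id),
                type=str(row.type),
                center=(float(row.x_um), float(row.y_um)),
                punctum_radius=float(row.punctum_radius_um),
            )
            for row in df.itertuples(index=False)
        ]
        return cls(synapses=synapses, pixel_size=pixel_size)

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path, pixel_size: float = PIXEL_SIZE_UM) -> "SynapseMap":
        return cls.from_frame(pd.read_csv(path), pixel_size=pixel_size)


def make_synapse_map(
    geometry: DendriteGeometry,
    n_inhibitory: int,
    n_excitatory: int = 0,
    spacing: tuple[float, float] = (2.0, 4.0),
    punctum_radius: float = 0.2,
    seed: int | None = None,
    pixel_size: float = PIXEL_SIZE_UM,
) -> SynapseMap:
    """Place synapses along a dendrite segment.

    Inhibitory synapses sit on the longitudinal axis with consecutive
    centre-to-centre distances drawn uniformly from ``spacing`` (μm); typical
    inhibitory synapses lie 2–4 μm apart. Excitatory synapses are placed at
    uniformly random longitudinal positions with a transversal offset, away
    from the axis line occupied by inhibitory puncta.

    Raises
    ------
    CapacityError
        If the requested puncta cannot fit inside the geometry.
    """
    if n_inhibitory < 0 or n_excitatory < 0:
        raise ValueError("synapse counts must be nonnegative")
    lo, hi = float(spacing[0]), float(spacing[1])
    if lo <= 0 or hi < lo:
        raise ValueError("spacing range must be positive and ordered")

    rng = np.random.default_rng(seed)
    synapses: list[Synapse] = []

    if n_inhibitory > 0:
        # Worst case: first punctum margin + (n-1) maximal gaps + last margin.
        min_needed = 2 * punctum_radius + (n_inhibitory - 1) * lo
        if min_needed > geometry.length:
            raise CapacityError(
                f"{n_inhibitory} inhibitory synapses at minimum spacing {lo} μm "
                f"need {min_needed:.2f} μm but dendrite is {geometry.length} μm"
            )
        while True:
            gaps = rng.uniform(lo, hi, size=max(n_inhibitory - 1, 0))
            span = float(gaps.sum())
            if punctum_radius * 2 + span <= geometry.length:
                break
        start_max = geometry.length - punctum_radius - span
        u0 = rng.uniform(punctum_radius, start_max) if start_max > punctum_radius else punctum_radius
        u_positions = u0 + np.concatenate([[0.0], np.cumsum(gaps)])
        for i, u in enumerate(u_positions):
            center = geometry.to_world([[u, 0.0]])[0]
            synapses.append(
                Synapse(i, "inhibitory", (float(center[0]), float(center[1])), punctum_radius)
            )
    if punctum_radius > geometry.half_width and n_excitatory > 0:
        raise CapacityError("excitatory punctum radius exceeds dendrite half-width")
    for j in range(n_excitatory):
        u = rng.uniform(punctum_radius, geometry.length - punctum_radius)
        v_max = geometry.half_width - punctum_radius
        v = rng.uniform(0.3 * v_max, v_max) * rng.choice([-1.0, 1.0]) if v_max > 0 else 0.0
        center = geometry.to_world([[u, v]])[0]
        synapses.append(
            Synapse(
                n_inhibitory + j,
                "excitatory",
                (float(center[0]), float(center[1])),
                punctum_radius,
            )
        )

    return SynapseMap(synapses=synapses, pixel_size=pixel_size)
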