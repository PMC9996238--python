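"""Activating-function readout along nerve-fiber trajectories.

The activating function — the second spatial difference of the
extracellular potential sampled at node-of-Ranvier spacing along a fiber —
is the classical first-order indicator of stimulation: positive values
drive membrane depolarization. It is computed here from a solved potential
field as a readout; it plays no part in the steering optimization itself.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.ndimage import map_coordinates

from .exceptions import CordsteerError
from .phantom import VoxelPhantom
from .solver import PotentialField


@dataclass(frozen=True)
class FiberPath:
    """Uniformly spaced sample points (mm) along a fiber trajectory."""

    points: np.ndarray  # (n, 3) mm
    spacing: float  # mm between consecutive samples

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        object.__setattr__(self, "points", pts)
        if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 3:
            raise CordsteerError("fiber path needs >= 3 points of shape (n, 3)")
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        if np.abs(seg - self.spacing).max() > 1e-9:
            raise CordsteerError(
                "fiber path sample points must be uniformly spaced along arclength"
            )


def straight_fiber(
    start: Sequence[float],
    direction: Sequence[float],
    length: float,
    spacing: float = 1.0,
) -> FiberPath:
    """Straight fiber from ``start`` along ``direction``; default 1 mm node
    spacing (twice the 0.5 mm half-internodal scale)."""
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    n = int(np.floor(length / spacing)) + 1
    if n < 3:
        raise CordsteerError("fiber too short for three nodes")
    pts = np.asarray(start, dtype=float) + np.arange(n)[:, None] * spacing * d
    return FiberPath(points=pts, spacing=spacing)


@dataclass
class ActivationProfile:
    """Activating values at interior fiber nodes, with sampled potentials."""

    path: FiberPath
    potentials: np.ndarray  # (n,) volts at every node
    values: np.ndarray  # (n - 2,) V/mm^2 at interior nodes

    def interior_points(self) -> np.ndarray:
        return self.path.points[1:-1]

    def to_text(self) -> str:
        """Delimited profile: position_mm, potential_V, activating_V_per_mm2."""
        s = np.concatenate(
            [[0.0], np.cumsum(np.full(len(self.potentials) - 1, self.path.spacing))]
        )
        act = np.full(len(self.potentials), np.nan)
        act[1:-1] = self.values
        buf = io.StringIO()
        buf.write("position_mm\tpotential_V\tactivating_V_per_mm2\n")
        for pos, pot, a in zip(s, self.potentials, act):
            a_str = "" if np.isnan(a) else repr(float(a))
            buf.write(f"{pos!r}\t{float(pot)!r}\t{a_str}\n")
        return buf.getvalue()


def sample_potential(
    fld: PotentialField, phantom: VoxelPhantom, path: FiberPath
) -> np.ndarray:
    """Trilinear interpolation of the nodal potential at the path points."""
    coords = []
    for a in range(3):
        c = (path.points[:, a] - phantom.origin[a]) / phantom.spacing[a] - 0.5
        if c.min() < 0 or c.max() > phantom.shape[a] - 1:
            raise CordsteerError(
                f"fiber path leaves the grid along axis {a} "
                f"(index range {c.min():.2f}..{c.max():.2f})"
            )
        coords.append(c)
    return map_coordinates(fld.values, np.array(coords), order=1, mode="nearest")


def activating_values(potentials: np.ndarray, spacing: float) -> np.ndarray:
    """Second differences (f_{k-1} - 2 f_k + f_{k+1}) / spacing^2 (V/mm^2)."""
    if spacing <= 0:
        raise CordsteerError(f"node spacing must be positive, got {spacing}")
    f = np.asarray(potentials, dtype=float)
    if f.size < 3:
        raise CordsteerError("need at least three potential samples")
    return (f[:-2] - 2.0 * f[1:-1] + f[2:]) / spacing**2


def activation_profile(
    fld: PotentialField, phantom: VoxelPhantom, path: FiberPath
) -> ActivationProfile:
    pot = sample_potential(fld, phantom, path)
    return ActivationProfile(
        path=path, potentials=pot, values=activating_values(pot, path.spacing)
    )
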