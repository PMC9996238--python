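"""Synthetic spine-segment phantoms: labeled voxel grids, leads, targets.

The anatomy is reduced to concentric circular shells extruded along z —
grey matter inside white matter inside cerebrospinal fluid inside epidural
fat, wrapped by vertebral bone, muscle, thorax, subcutaneous fat and skin —
which preserves the conductivity contrasts that drive current steering
while staying desk-scale. Two epidural leads are carved into the fat layer
as cylinders of insulating lead body with equipotential metal contacts.

Coordinate convention: 0-based voxel indices; the center of voxel
``(i, j, k)`` sits at ``origin + (i + 0.5, j + 0.5, k + 0.5) * spacing``;
z runs along the spinal cord. All lengths in mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .exceptions import GeometryError, PlacementError, TargetError
from .materials import MaterialTable, material_table

EXTERIOR = "exterior"

#: Default shell outer radii (mm), innermost first. Representative values for
#: a thoracic spine segment; every one is configurable.
DEFAULT_SHELLS: tuple[tuple[str, float], ...] = (
    ("grey_matter", 1.5),
    ("white_matter", 4.0),
    ("csf", 6.0),
    ("epidural_fat", 9.0),
    ("vertebral_bone", 12.0),
    ("muscle", 15.0),
    ("thorax", 17.0),
    ("fat", 18.5),
    ("skin", 19.5),
)

CORD_LABELS = ("grey_matter", "white_matter")


@dataclass
class VoxelPhantom:
    """Labeled 3-D voxel grid with per-label anisotropic conductivities.

    ``labels`` holds integer codes into ``label_names``; ``label_names[0]``
    is always the insulating exterior, which does not belong to the
    conduction domain.
    """

    labels: np.ndarray  # (nx, ny, nz) integer codes
    label_names: list[str]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]
    materials: MaterialTable

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3 or min(self.labels.shape) < 3:
            raise GeometryError(
                f"phantom grid must be 3-D with every dimension >= 3, "
                f"got shape {self.labels.shape}"
            )
        if any(h <= 0 for h in self.spacing):
            raise GeometryError(f"voxel spacing must be positive, got {self.spacing}")
        if self.label_names[0] != EXTERIOR:
            raise GeometryError("label_names[0] must be the insulating exterior")
        self.validate_materials()

    def validate_materials(self) -> None:
        used = np.unique(self.labels)
        for code in used:
            name = self.label_names[code]
            if name != EXTERIOR and name not in self.materials:
                raise GeometryError(f"label {name!r} has no conductivity entry")

    # -- label bookkeeping -------------------------------------------------
    def code(self, name: str) -> int:
        return self.label_names.index(name)

    def ensure_label(self, name: str) -> int:
        if name not in self.label_names:
            if name != EXTERIOR and name not in self.materials:
                raise GeometryError(f"label {name!r} has no conductivity entry")
            self.label_names.append(name)
        return self.label_names.index(name)

    def codes_of(self, names: Sequence[str]) -> list[int]:
        return [self.code(n) for n in names if n in self.label_names]

    # -- geometry ----------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        hx, hy, hz = self.spacing
        return hx * hy * hz

    def centers(self, axis: int) -> np.ndarray:
        n = self.shape[axis]
        h = self.spacing[axis]
        return self.origin[axis] + (np.arange(n) + 0.5) * h

    def center_grids(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return np.meshgrid(
            self.centers(0), self.centers(1), self.centers(2), indexing="ij"
        )

    def voxel_centers(self, flat_indices: np.ndarray) -> np.ndarray:
        """Centers (n, 3) in mm of C-order flat voxel indices."""
        idx = np.unravel_index(np.asarray(flat_indices), self.shape)
        return np.stack(
            [self.origin[a] + (idx[a] + 0.5) * self.spacing[a] for a in range(3)],
            axis=-1,
        )

    def containing_voxel(self, point: Sequence[float]) -> tuple[int, int, int]:
        idx = []
        for a in range(3):
            i = int(np.floor((point[a] - self.origin[a]) / self.spacing[a]))
            if not 0 <= i < self.shape[a]:
                raise GeometryError(f"point {tuple(point)} lies outside the grid")
            idx.append(i)
        return tuple(idx)  # type: ignore[return-value]

    # -- material access ---------------------------------------------------
    def conductivity_per_label(self) -> np.ndarray:
        """(n_labels, 3) conductivities in S/m; exterior row is zero."""
        return self.materials.as_array(tuple(self.label_names))

    def active_mask(self) -> np.ndarray:
        """Boolean mask of voxels in the conduction domain (non-exterior)."""
        return self.labels != self.code(EXTERIOR)


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry parameters of the concentric-shell phantom.

    ``shells`` lists (label, outer radius mm) innermost first; radii must be
    strictly increasing. ``disc_band_period``, if set, periodically replaces
    vertebral bone by inter-vertebral disc material in z bands of width
    ``disc_band_width``.
    """

    spacing: tuple[float, float, float] = (0.5, 0.5, 1.0)
    shells: tuple[tuple[str, float], ...] = DEFAULT_SHELLS
    z_length: float = 40.0
    transverse_pad: float = 0.25
    disc_band_period: float | None = None
    disc_band_width: float = 2.0

    def __post_init__(self) -> None:
        radii = [r for _, r in self.shells]
        if not radii or any(b <= a for a, b in zip(radii, radii[1:])):
            raise GeometryError("shell radii must be strictly increasing")
        if any(h <= 0 for h in self.spacing) or self.z_length <= 0:
            raise GeometryError("spacing and z_length must be positive")


def build_phantom(
    config: PhantomConfig, materials: MaterialTable | None = None
) -> VoxelPhantom:
    """Build the concentric-shell phantom for ``config``.

    Deterministic for a given config. Raises :class:`GeometryError` when a
    requested shell captures no voxel at the given resolution, or when the
    epidural fat layer is thinner than two voxels (too coarse to host a
    lead).
    """
    materials = materials or material_table()
    hx, hy, hz = config.spacing
    names = [name for name, _ in config.shells]
    radii = np.array([r for _, r in config.shells])

    half = radii[-1] + config.transverse_pad
    nx = 2 * int(np.ceil(half / hx))
    ny = 2 * int(np.ceil(half / hy))
    nz = max(3, int(np.ceil(config.z_length / hz)))
    origin = (-nx * hx / 2.0, -ny * hy / 2.0, -nz * hz / 2.0)

    x = origin[0] + (np.arange(nx) + 0.5) * hx
    y = origin[1] + (np.arange(ny) + 0.5) * hy
    rho = np.sqrt(x[:, None] ** 2 + y[None, :] ** 2)

    # shell index: first shell whose outer radius >= rho; beyond -> exterior
    shell_idx = np.searchsorted(radii, rho, side="left")
    label_names = [EXTERIOR] + names
    codes2d = np.where(shell_idx < len(radii), shell_idx + 1, 0).astype(np.int16)
    labels = np.repeat(codes2d[:, :, None], nz, axis=2)

    phantom = VoxelPhantom(
        labels=labels,
        label_names=label_names,
        spacing=config.spacing,
        origin=origin,
        materials=materials,
    )

    for i, name in enumerate(names):
        if not np.any(codes2d == i + 1):
            raise GeometryError(
                f"shell {name!r} vanishes at spacing {config.spacing}; "
                "refine the grid or widen the layer"
            )

    if "epidural_fat" in names:
        k = names.index("epidural_fat")
        inner = radii[k - 1] if k > 0 else 0.0
        if (radii[k] - inner) / min(hx, hy) < 2.0:
            raise GeometryError("epidural fat layer thinner than two voxels")

    if config.disc_band_period is not None and "vertebral_bone" in names:
        z = phantom.centers(2)
        band = np.mod(z - z[0], config.disc_band_period) < config.disc_band_width
        disc = phantom.ensure_label("disc")
        bone = phantom.code("vertebral_bone")
        mask = (phantom.labels == bone) & band[None, None, :]
        phantom.labels[mask] = disc

    return phantom


@dataclass(frozen=True)
class LeadLayout:
    """Two parallel epidural leads, each a z-extruded cylinder of contacts.

    ``centers`` are the transverse (x, y) lead axes in mm; ``stagger``
    shifts lead B longitudinally in multiples of 0.5 mm. ``pitch`` is the
    contact center-to-center distance; contacts of length
    ``electrode_length`` are separated by insulating lead body.
    """

    centers: tuple[tuple[float, float], ...] = ((-1.5, 8.0), (1.5, 8.0))
    stagger: float = 0.0
    n_electrodes: int = 8
    electrode_length: float = 2.0
    pitch: float = 4.0
    lead_radius: float = 0.6
    tip_margin: float = 1.0
    z_center: float = 0.0
    lead_names: tuple[str, ...] = ("A", "B")

    def __post_init__(self) -> None:
        if abs(self.stagger / 0.5 - round(self.stagger / 0.5)) > 1e-9:
            raise PlacementError(
                f"stagger must be a multiple of 0.5 mm, got {self.stagger}"
            )
        if self.pitch < self.electrode_length:
            raise PlacementError("electrode pitch smaller than electrode length")
        if self.n_electrodes < 1 or self.lead_radius <= 0:
            raise PlacementError("need >= 1 electrode and positive lead radius")
        if len(self.centers) != len(self.lead_names):
            raise PlacementError("one lead name per lead center required")

    def electrode_z_centers(self, lead: int) -> np.ndarray:
        base = self.z_center + (
            np.arange(self.n_electrodes) - (self.n_electrodes - 1) / 2.0
        ) * self.pitch
        return base + (self.stagger if lead > 0 else 0.0)

    def with_separation(self, separation: float, depth_y: float) -> "LeadLayout":
        """Layout with leads at x = -+separation/2, both at depth ``depth_y``."""
        return replace(
            self, centers=((-separation / 2.0, depth_y), (separation / 2.0, depth_y))
        )


@dataclass
class ElectrodeSet:
    """Ordered electrode identifiers with voxel membership and centroids.

    Ordering is lead-major, then by index along +z (A1..An, B1..Bn).
    """

    ids: tuple[str, ...]
    voxels: dict[str, np.ndarray]  # flat C-order voxel indices
    centroids: dict[str, np.ndarray]  # (3,) mm

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for eid in self.ids:
            vox = self.voxels[eid]
            if vox.size == 0:
                raise PlacementError(f"electrode {eid} has an empty voxel set")
            overlap = seen.intersection(vox.tolist())
            if overlap:
                raise PlacementError(f"electrode {eid} overlaps another contact")
            seen.update(vox.tolist())

    def __len__(self) -> int:
        return len(self.ids)

    def index(self, eid: str) -> int:
        return self.ids.index(eid)

    def lead_of(self, eid: str) -> str:
        return eid.rstrip("0123456789")

    @property
    def leads(self) -> tuple[str, ...]:
        out: list[str] = []
        for eid in self.ids:
            lead = self.lead_of(eid)
            if lead not in out:
                out.append(lead)
        return tuple(out)

    def centroid_array(self) -> np.ndarray:
        return np.stack([self.centroids[eid] for eid in self.ids])


def place_leads(phantom: VoxelPhantom, layout: LeadLayout) -> ElectrodeSet:
    """Carve the leads of ``layout`` into ``phantom``; return the contacts.

    Lead-body voxels take the insulating "lead" label and contact voxels the
    metal "contact" label. Every carved voxel must previously be epidural
    fat; anything else raises :class:`PlacementError`.
    """
    fat = phantom.code("epidural_fat")
    lead_code = phantom.ensure_label("lead")
    contact_code = phantom.ensure_label("contact")

    x = phantom.centers(0)
    y = phantom.centers(1)
    z = phantom.centers(2)

    ids: list[str] = []
    voxels: dict[str, np.ndarray] = {}
    centroids: dict[str, np.ndarray] = {}

    for li, ((cx, cy), name) in enumerate(zip(layout.centers, layout.lead_names)):
        trans = (x[:, None] - cx) ** 2 + (y[None, :] - cy) ** 2 <= (
            layout.lead_radius**2
        )
        if not trans.any():
            raise PlacementError(
                f"lead {name} captures no voxels at radius {layout.lead_radius}"
            )
        zc = layout.electrode_z_centers(li)
        half = layout.electrode_length / 2.0
        zmask = (z >= zc[0] - half - layout.tip_margin) & (
            z <= zc[-1] + half + layout.tip_margin
        )
        body = trans[:, :, None] & zmask[None, None, :]
        if not np.all(phantom.labels[body] == fat):
            raise PlacementError(
                f"lead {name} leaves the epidural fat layer; adjust its "
                "position or radius"
            )
        phantom.labels[body] = lead_code

        for ei in range(layout.n_electrodes):
            emask = body & (
                (z >= zc[ei] - half) & (z < zc[ei] + half)
            )[None, None, :]
            flat = np.flatnonzero(emask)
            eid = f"{name}{ei + 1}"
            if flat.size == 0:
                raise PlacementError(
                    f"electrode {eid} captures no voxels; refine the z spacing"
                )
            phantom.labels[emask] = contact_code
            ids.append(eid)
            voxels[eid] = flat
            centroids[eid] = phantom.voxel_centers(flat).mean(axis=0)

    return ElectrodeSet(ids=tuple(ids), voxels=voxels, centroids=centroids)


@dataclass
class TargetRegion:
    """Cylindrical stimulation target inside the grey/white matter.

    Membership is by voxel-center-in-cylinder test; when the cylinder is
    smaller than one voxel the single cord voxel nearest the center is used
    (ties broken by lowest flat index).
    """

    center: tuple[float, float, float]
    diameter: float
    length: float
    axis: int
    voxels: np.ndarray  # flat C-order voxel indices

    def __post_init__(self) -> None:
        if np.asarray(self.voxels).size == 0:
            raise TargetError("target region is empty")


def define_target(
    phantom: VoxelPhantom,
    center: Sequence[float],
    diameter: float = 0.5,
    length: float | None = None,
    axis: int = 2,
) -> TargetRegion:
    """Define the cylindrical target region around ``center`` (mm).

    ``diameter`` defaults to 0.5 mm — about half the internodal distance of
    a large myelinated fiber; ``length`` defaults to the diameter. The
    center must lie inside grey or white matter.
    """
    if length is None:
        length = diameter
    if diameter <= 0 or length <= 0:
        raise TargetError("target diameter and length must be positive")

    cord_codes = phantom.codes_of(CORD_LABELS)
    if not cord_codes:
        raise TargetError("phantom has no grey/white matter to target")
    i, j, k = phantom.containing_voxel(center)
    if phantom.labels[i, j, k] not in cord_codes:
        raise TargetError(
            f"target center {tuple(center)} lies in "
            f"{phantom.label_names[phantom.labels[i, j, k]]!r}, not in grey or "
            "white matter"
        )

    cord = np.isin(phantom.labels, cord_codes)
    grids = phantom.center_grids()
    trans_axes = [a for a in range(3) if a != axis]
    r2 = sum((grids[a] - center[a]) ** 2 for a in trans_axes)
    inside = (
        cord
        & (r2 <= (diameter / 2.0) ** 2)
        & (np.abs(grids[axis] - center[axis]) <= length / 2.0)
    )
    flat = np.flatnonzero(inside)
    if flat.size == 0:
        # documented fallback: single nearest cord voxel (lowest index wins)
        cord_flat = np.flatnonzero(cord)
        d2 = ((phantom.voxel_centers(cord_flat) - np.asarray(center)) ** 2).sum(1)
        flat = cord_flat[[int(np.argmin(d2))]]
    return TargetRegion(
        center=tuple(float(c) for c in center),
        diameter=float(diameter),
        length=float(length),
        axis=axis,
        voxels=flat,
    )
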