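"""Tissue and hardware conductivities for the spine volume-conductor model.

Conductivities are axis-aligned triples ``(sigma_x, sigma_y, sigma_z)`` in
S/m, with the z axis along the spinal cord and the x-y plane transverse to
it. White matter and skeletal muscle conduct several-fold better along the
fiber direction (z) than across it; every other tissue is isotropic. The
lead body is a near-perfect insulator and the metal contacts near-perfect
conductors, so that each contact is effectively equipotential.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from types import MappingProxyType
from typing import Iterator, Mapping

import numpy as np

Triple = tuple[float, float, float]

#: Conductive labels of the standard phantom, from innermost shell outwards,
#: followed by the implant materials. "exterior" (air) is deliberately not a
#: material: exterior voxels are excluded from the conduction domain.
STANDARD_LABELS = (
    "grey_matter",
    "white_matter",
    "csf",
    "epidural_fat",
    "vertebral_bone",
    "disc",
    "muscle",
    "thorax",
    "fat",
    "skin",
    "lead",
    "contact",
)


@dataclass(frozen=True)
class MaterialTable:
    """Mapping from tissue/hardware label to a conductivity triple in S/m.

    Invariants: all components strictly positive and finite; isotropic
    entries have all three components equal by construction.
    """

    conductivities: Mapping[str, Triple]

    def __post_init__(self) -> None:
        frozen = {}
        for label, triple in self.conductivities.items():
            arr = tuple(float(v) for v in np.broadcast_to(triple, (3,)))
            if not all(math.isfinite(v) and v > 0 for v in arr):
                raise ValueError(
                    f"conductivity for {label!r} must be strictly positive "
                    f"and finite, got {triple!r}"
                )
            frozen[label] = arr
        object.__setattr__(self, "conductivities", MappingProxyType(frozen))

    def __getitem__(self, label: str) -> Triple:
        return self.conductivities[label]

    def __contains__(self, label: str) -> bool:
        return label in self.conductivities

    def __iter__(self) -> Iterator[str]:
        return iter(self.conductivities)

    def __len__(self) -> int:
        return len(self.conductivities)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(self.conductivities)

    def is_isotropic(self, label: str) -> bool:
        sx, sy, sz = self[label]
        return sx == sy == sz

    def as_array(self, label_names: tuple[str, ...]) -> np.ndarray:
        """Per-label conductivity array in S/m, shape (len(label_names), 3).

        Labels absent from the table (e.g. "exterior") get zero rows; callers
        must exclude such voxels from the conduction domain.
        """
        out = np.zeros((len(label_names), 3), dtype=float)
        for i, name in enumerate(label_names):
            if name in self:
                out[i] = self[name]
        return out

    def replace(self, **overrides: Triple | float) -> "MaterialTable":
        merged = dict(self.conductivities)
        for label, value in overrides.items():
            merged[label] = value  # type: ignore[assignment]
        return MaterialTable(merged)


def material_table() -> MaterialTable:
    """Standard 12-entry material table of the spine model.

    Values are the literature conductivities used throughout this package;
    white matter and muscle carry anisotropic (x, y, z) triples with the
    high-conductivity axis along the cord.
    """
    return MaterialTable(
        {
            "grey_matter": (0.23, 0.23, 0.23),
            "white_matter": (0.083, 0.083, 0.6),
            "csf": (1.7, 1.7, 1.7),
            "epidural_fat": (0.04, 0.04, 0.04),
            "vertebral_bone": (0.02, 0.02, 0.02),
            "disc": (0.6, 0.6, 0.6),
            "muscle": (0.08, 0.08, 0.5),
            "thorax": (0.25, 0.25, 0.25),
            "skin": (0.0025, 0.0025, 0.0025),
            "fat": (0.04, 0.04, 0.04),
            "lead": (1e-16, 1e-16, 1e-16),
            "contact": (4e6, 4e6, 4e6),
        }
    )
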