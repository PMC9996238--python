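"""Plain-text exports: legacy VTK structured points and matrix JSON files.

The VTK writer emits the legacy ASCII STRUCTURED_POINTS dialect (voxel
centers as points), which every VTK-based viewer reads; arrays are written
in x-fastest order as the format requires.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np

from .exceptions import ConfigurationError
from .solver import ConductanceMatrix, QuadraticForms


def write_structured_points(
    path: str | Path,
    shape: tuple[int, int, int],
    origin: tuple[float, float, float],
    spacing: tuple[float, float, float],
    fields: Mapping[str, np.ndarray],
    title: str = "cordsteer export",
) -> None:
    """Write scalar voxel arrays as a legacy ASCII VTK structured-points file."""
    nx, ny, nz = shape
    n = nx * ny * nz
    lines = [
        "# vtk DataFile Version 3.0",
        title,
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {nx} {ny} {nz}",
        f"ORIGIN {origin[0] + spacing[0] / 2} {origin[1] + spacing[1] / 2} "
        f"{origin[2] + spacing[2] / 2}",
        f"SPACING {spacing[0]} {spacing[1]} {spacing[2]}",
        f"POINT_DATA {n}",
    ]
    for name, arr in fields.items():
        arr = np.asarray(arr)
        if arr.shape != shape:
            raise ValueError(f"field {name!r} has shape {arr.shape}, expected {shape}")
        kind = "int" if np.issubdtype(arr.dtype, np.integer) else "float"
        lines.append(f"SCALARS {name} {kind} 1")
        lines.append("LOOKUP_TABLE default")
        flat = arr.ravel(order="F")  # x fastest per the VTK convention
        lines.extend(" ".join(map(str, flat[i : i + 9])) for i in range(0, n, 9))
    Path(path).write_text("\n".join(lines) + "\n")


def save_matrices(
    path: str | Path, Y: ConductanceMatrix, forms: QuadraticForms | None = None
) -> None:
    """Serialize Y (and optionally C, C0) with their electrode ordering."""
    if forms is not None and forms.ids != Y.ids:
        raise ConfigurationError("electrode ordering of Y and C/C0 disagree")
    payload: dict = {
        "electrode_order": list(Y.ids),
        "Y_S": Y.matrix.tolist(),
        "Y_asymmetry": Y.asymmetry,
    }
    if forms is not None:
        payload["C"] = forms.C.tolist()
        payload["C0"] = forms.C0.tolist()
    Path(path).write_text(json.dumps(payload, indent=1))


def load_matrices(
    path: str | Path,
) -> tuple[ConductanceMatrix, QuadraticForms | None]:
    """Load matrices written by :func:`save_matrices` (enables optimizer-only
    runs from externally computed field solutions)."""
    payload = json.loads(Path(path).read_text())
    ids = tuple(payload["electrode_order"])
    Y = ConductanceMatrix(
        matrix=np.asarray(payload["Y_S"], dtype=float),
        ids=ids,
        asymmetry=float(payload.get("Y_asymmetry", 0.0)),
    )
    forms = None
    if "C" in payload and "C0" in payload:
        forms = QuadraticForms(
            C=np.asarray(payload["C"], dtype=float),
            C0=np.asarray(payload["C0"], dtype=float),
            ids=ids,
        )
    return Y, forms
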