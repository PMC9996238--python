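"""End-to-end orchestration: phantom -> fields -> matrices -> steering.

``run_pipeline`` chains the full computation for a validated
:class:`~cordsteer.config.RunConfig` and optionally writes the solution
JSON, a plain-text UI rendering, the serialized matrices, VTK volumes and
an activating-function profile. Every step is deterministic for a fixed
config and seed, so repeated runs produce byte-identical JSON.
"""

from __future__ import annotations

import json
import logging
from contextlib import contextmanager
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .activation import ActivationProfile, activation_profile, straight_fiber
from .config import RunConfig
from .exceptions import CordsteerError
from .phantom import ElectrodeSet, TargetRegion, VoxelPhantom, build_phantom, define_target, place_leads
from .solver import (
    BasisFieldSet,
    ConductanceMatrix,
    DiscreteOperator,
    PotentialField,
    QuadraticForms,
    assemble_quadratic_forms,
    assemble_system,
    conductance_matrix,
    current_density,
    solve_basis_fields,
)
from .steering import (
    SteeringSolution,
    select_active_electrodes,
    solve_one_sided,
    solve_with_floating,
)
from .vtkio import save_matrices, write_structured_points

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    config: RunConfig
    phantom: VoxelPhantom
    electrodes: ElectrodeSet
    operator: DiscreteOperator
    basis: BasisFieldSet
    Y: ConductanceMatrix
    target: TargetRegion
    forms: QuadraticForms
    active: tuple[str, ...]
    floating: tuple[str, ...]
    solution: SteeringSolution

    def optimal_field(self) -> PotentialField:
        """Potential of the optimal excitation, by superposition of the
        basis fields (the discrete system is linear in the voltages)."""
        values = sum(
            v * f.values for v, f in zip(self.solution.voltages, self.basis.fields)
        )
        return PotentialField(
            values=values,
            electrode_voltages=self.solution.voltages.copy(),
            provenance="optimal excitation (superposed basis)",
        )

    def default_fiber_profile(self) -> ActivationProfile:
        """Activating function along the z-aligned dorsal-column fiber
        through the target center, 1 mm node spacing."""
        hz = self.phantom.spacing[2]
        z0 = self.phantom.origin[2]
        nz = self.phantom.shape[2]
        start = (self.target.center[0], self.target.center[1], z0 + hz)
        length = nz * hz - 2 * hz
        fiber = straight_fiber(start, (0.0, 0.0, 1.0), length, spacing=1.0)
        return activation_profile(self.optimal_field(), self.phantom, fiber)


@contextmanager
def _stage(name: str):
    try:
        yield
    except CordsteerError as exc:
        raise type(exc)(f"[{name}] {exc}") from exc


def run_pipeline(
    config: RunConfig,
    outdir: str | Path | None = None,
    write_vtk: bool = False,
) -> PipelineResult:
    """Run the configured steering computation end to end."""
    with _stage("phantom"):
        phantom = build_phantom(
            config.geometry.to_phantom_config(), config.materials.to_table()
        )
        electrodes = place_leads(phantom, config.leads.to_layout())
        target = define_target(
            phantom,
            config.target.center,
            diameter=config.target.diameter,
            length=config.target.length,
        )

    with _stage("field_solver"):
        op = assemble_system(phantom, electrodes, config.solver.to_options())
        basis = solve_basis_fields(op)
        Y = conductance_matrix(op, basis)
        forms = assemble_quadratic_forms(phantom, basis, target)

    with _stage("steering"):
        active, auto_floating = select_active_electrodes(
            electrodes, target, k=min(config.steering.k_active, len(electrodes))
        )
        user_floating = tuple(config.steering.floating)
        unknown = [e for e in user_floating if e not in electrodes.ids]
        if unknown:
            raise CordsteerError(f"unknown floating electrode ids {unknown}")
        floating = tuple(
            e for e in electrodes.ids if e in auto_floating or e in user_floating
        )
        working = tuple(e for e in active if e not in floating)
        center = np.asarray(target.center)
        cathode = min(
            working,
            key=lambda e: (float(np.linalg.norm(electrodes.centroids[e] - center)), e),
        )
        cathode_index = electrodes.index(cathode)

        variant = config.steering.variant
        if variant in ("two_sided", "floating"):
            solution = solve_with_floating(
                forms, Y, floating, cathode_index=cathode_index
            )
            # keep the user-facing variant tag even when the clinical
            # selection already forces the floating formulation
            solution.variant = variant
        else:
            solution = solve_one_sided(
                forms,
                Y,
                working,
                ground_max=config.steering.ground_max,
                n_starts=config.steering.n_starts,
                seed=config.seed,
            )

    result = PipelineResult(
        config=config,
        phantom=phantom,
        electrodes=electrodes,
        operator=op,
        basis=basis,
        Y=Y,
        target=target,
        forms=forms,
        active=working,
        floating=floating,
        solution=solution,
    )

    if outdir is not None:
        write_outputs(result, Path(outdir), write_vtk=write_vtk)
    return result


# -- serialization ---------------------------------------------------------
def solution_to_dict(result: PipelineResult) -> dict:
    sol = result.solution
    cfg = result.config
    return {
        "variant": sol.variant,
        "objective_lambda": float(sol.objective),
        "eigen_gap": float(sol.eigen_gap),
        "stable": bool(sol.stable),
        "normalization_VtC0V": float(sol.normalization),
        "sign_convention": sol.sign_convention,
        "electrodes": sol.by_electrode(),
        "selection": {"active": list(result.active), "floating": list(result.floating)},
        "provenance": {
            "config_hash": cfg.config_hash(),
            "seed": cfg.seed,
            "solver_rtol": cfg.solver.rtol,
            "config": json.loads(cfg.model_dump_json()),
        },
    }


def solution_from_dict(payload: dict) -> SteeringSolution:
    entries = payload["electrodes"]
    return SteeringSolution(
        ids=tuple(e["id"] for e in entries),
        voltages=np.array([e["voltage_V"] for e in entries]),
        currents=np.array([e["current_A"] for e in entries]),
        objective=payload["objective_lambda"],
        roles=tuple(e["role"] for e in entries),
        percents=np.array([e["percent"] for e in entries], dtype=int),
        variant=payload["variant"],
        eigen_gap=payload["eigen_gap"],
        stable=payload["stable"],
        normalization=payload["normalization_VtC0V"],
        sign_convention=payload["sign_convention"],
    )


GLYPHS = {"source": "+", "sink": "-", "ground": "G", "floating": "."}


def render_ui_text(solution: SteeringSolution) -> str:
    """Two-column lead diagram with per-electrode glyph and percent.

    Glyphs: ``+`` anodic source, ``-`` cathodic sink, ``G`` ground,
    ``.`` floating; percentages are per-polarity and rounded to integers.
    """
    by_lead: dict[str, list[int]] = {}
    for i, eid in enumerate(solution.ids):
        by_lead.setdefault(eid.rstrip("0123456789"), []).append(i)
    leads = list(by_lead)
    n_rows = max(len(v) for v in by_lead.values())

    def cell(i: int | None) -> str:
        if i is None:
            return " " * 14
        eid = solution.ids[i]
        glyph = GLYPHS[solution.roles[i]]
        pct = solution.percents[i]
        body = f"{eid:<3} {glyph}"
        if solution.roles[i] in ("source", "sink", "ground") and pct:
            body += f"{pct:>4d}%"
        return f"{body:<14}"

    lines = [f"variant: {solution.variant}   lambda* = {solution.objective:.6g}"]
    header = "".join(f"lead {lead:<9}" for lead in leads)
    lines.append(header)
    for row in range(n_rows - 1, -1, -1):  # distal electrode on top
        cells = []
        for lead in leads:
            idx = by_lead[lead]
            cells.append(cell(idx[row] if row < len(idx) else None))
        lines.append("".join(cells).rstrip())
    lines.append("legend: + source  - sink  G ground  . floating")
    return "\n".join(lines) + "\n"


def write_outputs(
    result: PipelineResult, outdir: Path, write_vtk: bool = False
) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    payload = solution_to_dict(result)
    (outdir / "solution.json").write_text(
        json.dumps(payload, indent=2, sort_keys=True) + "\n"
    )
    (outdir / "report.txt").write_text(render_ui_text(result.solution))
    save_matrices(outdir / "matrices.json", result.Y, result.forms)
    (outdir / "activation_profile.tsv").write_text(
        result.default_fiber_profile().to_text()
    )
    if write_vtk:
        phantom = result.phantom
        fld = result.optimal_field()
        J = current_density(fld, phantom)
        write_structured_points(
            outdir / "phantom.vtk",
            phantom.shape,
            phantom.origin,
            phantom.spacing,
            {"label": phantom.labels.astype(np.int32)},
            title="cordsteer phantom labels",
        )
        write_structured_points(
            outdir / "field.vtk",
            phantom.shape,
            phantom.origin,
            phantom.spacing,
            {
                "potential": fld.values,
                "J_magnitude": np.linalg.norm(J, axis=-1),
            },
            title="cordsteer optimal field",
        )
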