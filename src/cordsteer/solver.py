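"""Anisotropic quasi-static field solver on the voxel phantom.

The conductive Poisson equation div(sigma grad f) = 0 is discretized with a
flux-conservative 7-point finite-volume stencil on the structured grid:
each face between two conduction-domain voxels carries the harmonic mean of
the two adjacent axis-component conductivities, faces to the exterior (and
the grid boundary) carry zero flux, and electrode contact voxels are
equipotential Dirichlet node sets. Conductivities are converted from S/m to
S/mm internally so that, with all lengths in mm, face conductances come out
in siemens and electrode currents in amperes.

Electrode currents are extracted by the matrix-reaction method (applying
the assembled operator to the full solution and summing the residual over
an electrode's Dirichlet rows), which makes Kirchhoff's current law hold to
solver tolerance and the conductance matrix reciprocal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .exceptions import SolverError, TargetError
from .phantom import ElectrodeSet, TargetRegion, VoxelPhantom

logger = logging.getLogger(__name__)

S_PER_M_TO_S_PER_MM = 1e-3

#: labels excluded from current-density energy integrals: the lead body is
#: (numerically) insulating and the metal contacts are equipotential, so a
#: pointwise sigma*grad(f) there is a discretization artifact, not tissue
#: current density.
NON_TISSUE_LABELS = ("lead", "contact")


@dataclass(frozen=True)
class SolverOptions:
    """Linear-solver knobs.

    ``method``: "auto" factorizes directly below ``direct_limit`` free nodes
    and otherwise runs ILU-preconditioned conjugate gradients on the
    Jacobi-scaled system; "direct"/"cg" force one path.
    """

    method: str = "auto"
    rtol: float = 1e-10
    direct_limit: int = 60_000
    ilu_drop_tol: float = 1e-4
    ilu_fill_factor: float = 10.0
    maxiter_per_cbrt: float = 50.0

    def __post_init__(self) -> None:
        if self.method not in ("auto", "direct", "cg"):
            raise ValueError(f"unknown solver method {self.method!r}")


@dataclass
class PotentialField:
    """Nodal potentials (V) over the full grid; zero outside the domain."""

    values: np.ndarray  # (nx, ny, nz) volts
    electrode_voltages: np.ndarray  # the Dirichlet vector that produced it
    provenance: str = ""


@dataclass
class BasisFieldSet:
    """Unit-voltage basis solutions phi_q, one per electrode."""

    fields: list[PotentialField]
    ids: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.fields)


@dataclass
class ConductanceMatrix:
    """N x N electrode conductance matrix Y (siemens): I = Y V."""

    matrix: np.ndarray
    ids: tuple[str, ...]
    asymmetry: float = 0.0  # relative asymmetry recorded before symmetrizing


@dataclass
class QuadraticForms:
    """Target/off-target energy matrices of the steering objective.

    ``C[p, q] = sum over target voxels of (sigma grad phi_p).(sigma grad
    phi_q) * voxel volume`` and ``C0`` likewise over the rest of the tissue
    domain, so that for any electrode voltage vector V, ``V' C V`` is the
    integrated squared current density of the superposed field in the
    target.
    """

    C: np.ndarray
    C0: np.ndarray
    ids: tuple[str, ...]


@dataclass
class DiscreteOperator:
    """Assembled symmetric system with Dirichlet (electrode) bookkeeping."""

    matrix: sp.csr_matrix  # over conduction-domain voxels
    active_flat: np.ndarray  # flat voxel index per equation
    electrodes: ElectrodeSet
    electrode_eq: list[np.ndarray]  # equation indices per electrode
    free: np.ndarray  # equation indices of free nodes
    dirichlet: np.ndarray  # equation indices of Dirichlet nodes
    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    options: SolverOptions = field(default_factory=SolverOptions)
    _cache: dict = field(default_factory=dict, repr=False)

    @property
    def n_active(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_free(self) -> int:
        return self.free.size

    def submatrices(self) -> tuple[sp.csr_matrix, sp.csr_matrix]:
        if "Aff" not in self._cache:
            A = self.matrix.tocsr()
            self._cache["Aff"] = A[self.free][:, self.free].tocsc()
            self._cache["Afd"] = A[self.free][:, self.dirichlet].tocsr()
        return self._cache["Aff"], self._cache["Afd"]

    # -- linear solve ------------------------------------------------------
    def _free_solver(self):
        """Callable rhs -> solution on free nodes, cached across solves."""
        if "solve" in self._cache:
            return self._cache["solve"]
        Aff, _ = self.submatrices()
        n = Aff.shape[0]
        opts = self.options
        method = opts.method
        if method == "auto":
            method = "direct" if n <= opts.direct_limit else "cg"

        if method == "direct":
            lu = spla.splu(Aff)
            solve = lu.solve
        else:
            d = Aff.diagonal()
            if np.any(d <= 0):
                raise SolverError("non-positive diagonal in assembled system")
            s = 1.0 / np.sqrt(d)
            S = sp.diags(s)
            As = (S @ Aff @ S).tocsc()
            maxiter = max(200, int(opts.maxiter_per_cbrt * n ** (1.0 / 3.0)))
            try:
                # symmetric-mode ILU of the Jacobi-scaled operator; the ILU
                # factors are not exactly symmetric, so the Krylov solver is
                # BiCGSTAB rather than plain CG
                ilu = spla.spilu(
                    As,
                    drop_tol=opts.ilu_drop_tol,
                    fill_factor=opts.ilu_fill_factor,
                    permc_spec="MMD_AT_PLUS_A",
                    diag_pivot_thresh=0.0,
                    options={"SymmetricMode": True},
                )
                M = spla.LinearOperator(As.shape, ilu.solve)
            except (RuntimeError, MemoryError) as exc:  # pragma: no cover
                logger.warning("ILU failed (%s); falling back to Jacobi", exc)
                M = None

            def solve(b: np.ndarray) -> np.ndarray:
                bs = s * b
                y, info = spla.bicgstab(
                    As, bs, rtol=min(1e-12, opts.rtol * 1e-2), atol=0.0,
                    maxiter=maxiter, M=M,
                )
                if info != 0:
                    res = np.linalg.norm(As @ y - bs) / np.linalg.norm(bs)
                    if res > opts.rtol:
                        raise SolverError(
                            f"iterative solve stopped (info={info}) with "
                            f"relative residual {res:.3e} > {opts.rtol:.1e}"
                        )
                return s * y

        self._cache["solve"] = solve
        return solve


def assemble_system(
    phantom: VoxelPhantom,
    electrodes: ElectrodeSet,
    options: SolverOptions | None = None,
) -> DiscreteOperator:
    """Assemble the 7-point finite-volume operator over the phantom.

    Off-diagonal stencil weight between axis neighbors is
    ``-harmonic_mean(sigma_a, sigma_b) * face_area / spacing`` (siemens);
    exterior voxels and the grid boundary receive the insulating zero-flux
    treatment by omission.
    """
    sig_label = phantom.conductivity_per_label() * S_PER_M_TO_S_PER_MM
    if not np.all(np.isfinite(sig_label)):
        raise SolverError("non-finite conductivity in material table")
    sig = sig_label[phantom.labels]  # (nx, ny, nz, 3) S/mm

    active = phantom.active_mask()
    n_total = active.size
    eq_index = np.full(n_total, -1, dtype=np.int64)
    active_flat = np.flatnonzero(active.ravel())
    eq_index[active_flat] = np.arange(active_flat.size)
    eq_grid = eq_index.reshape(phantom.shape)

    h = phantom.spacing
    rows, cols, vals = [], [], []
    for axis in range(3):
        lo = [slice(None)] * 3
        hi = [slice(None)] * 3
        lo[axis] = slice(0, -1)
        hi[axis] = slice(1, None)
        lo_t, hi_t = tuple(lo), tuple(hi)

        both = active[lo_t] & active[hi_t]
        sa = sig[..., axis][lo_t][both]
        sb = sig[..., axis][hi_t][both]
        area = h[(axis + 1) % 3] * h[(axis + 2) % 3]
        g = (2.0 * sa * sb / (sa + sb)) * (area / h[axis])

        ea = eq_grid[lo_t][both]
        eb = eq_grid[hi_t][both]
        rows.extend((ea, eb, ea, eb))
        cols.extend((eb, ea, ea, eb))
        vals.extend((-g, -g, g, g))

    n = active_flat.size
    A = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    ).tocsr()

    electrode_eq = []
    for eid in electrodes.ids:
        eq = eq_index[electrodes.voxels[eid]]
        if np.any(eq < 0):
            raise SolverError(f"electrode {eid} has voxels outside the domain")
        electrode_eq.append(eq)
    dirichlet = np.concatenate(electrode_eq) if electrode_eq else np.array([], int)
    free_mask = np.ones(n, dtype=bool)
    free_mask[dirichlet] = False

    return DiscreteOperator(
        matrix=A,
        active_flat=active_flat,
        electrodes=electrodes,
        electrode_eq=electrode_eq,
        free=np.flatnonzero(free_mask),
        dirichlet=dirichlet,
        shape=phantom.shape,
        spacing=phantom.spacing,
        options=options or SolverOptions(),
    )


def solve_field(
    op: DiscreteOperator,
    electrode_voltages: np.ndarray,
    provenance: str = "",
) -> PotentialField:
    """Solve for the potential with the given per-electrode voltages (V).

    Dirichlet values are exact by construction; the free-node relative
    residual is verified against ``op.options.rtol`` and a
    :class:`SolverError` raised on failure.
    """
    v = np.asarray(electrode_voltages, dtype=float)
    if v.shape != (len(op.electrodes),):
        raise SolverError(
            f"expected {len(op.electrodes)} electrode voltages, got shape {v.shape}"
        )
    u = np.zeros(op.n_active)
    for volt, eq in zip(v, op.electrode_eq):
        u[eq] = volt

    Aff, Afd = op.submatrices()
    b = -(Afd @ u[op.dirichlet])
    bnorm = np.linalg.norm(b)
    if bnorm > 0:
        x = op._free_solver()(b)
        res = np.linalg.norm(b - Aff @ x) / bnorm
        if res > op.options.rtol:
            raise SolverError(
                f"free-node relative residual {res:.3e} exceeds "
                f"{op.options.rtol:.1e}"
            )
        u[op.free] = x
    # bnorm == 0 with nonzero Dirichlet values means every electrode is at
    # the same voltage c and the constant field u = c is the exact solution.
    elif np.any(v != 0):
        u[op.free] = v[0]

    values = np.zeros(int(np.prod(op.shape)))
    values[op.active_flat] = u
    return PotentialField(
        values=values.reshape(op.shape),
        electrode_voltages=v.copy(),
        provenance=provenance,
    )


def solve_basis_fields(op: DiscreteOperator) -> BasisFieldSet:
    """Solve the N unit-voltage basis fields phi_q (one electrode at 1 V,
    all others grounded)."""
    n = len(op.electrodes)
    if n < 2:
        raise SolverError("need at least two electrodes for basis fields")
    fields = []
    for q, eid in enumerate(op.electrodes.ids):
        v = np.zeros(n)
        v[q] = 1.0
        try:
            fields.append(solve_field(op, v, provenance=f"basis:{eid}"))
        except SolverError as exc:
            raise SolverError(f"basis solve for electrode {eid} failed: {exc}")
    return BasisFieldSet(fields=fields, ids=op.electrodes.ids)


def electrode_currents(op: DiscreteOperator, fld: PotentialField) -> np.ndarray:
    """Per-electrode current (A) by the matrix-reaction method.

    Positive current is sourced into the tissue (anodic); the currents of
    any solved field sum to zero to solver tolerance.
    """
    u = fld.values.reshape(-1)[op.active_flat]
    r = op.matrix @ u
    return np.array([r[eq].sum() for eq in op.electrode_eq])


def conductance_matrix(op: DiscreteOperator, basis: BasisFieldSet) -> ConductanceMatrix:
    """Electrode conductance matrix Y from the basis fields.

    Column q holds the electrode currents of phi_q. Reciprocity makes Y
    symmetric up to discretization error; the matrix is symmetrized by
    averaging and the observed relative asymmetry recorded. Asymmetry
    beyond 1e-4 signals a broken discretization and raises.

    Charge conservation (Y 1 = 0, a constant voltage drives no current) is
    exact for the discrete Schur complement of the assembled operator, so
    residual row/column sums left by the iterative solves are deflated out;
    the deflation magnitude is of the order of the solver tolerance.
    """
    cols = [electrode_currents(op, f) for f in basis.fields]
    Y = np.column_stack(cols)
    scale = np.abs(Y).max()
    asym = np.abs(Y - Y.T).max() / scale if scale > 0 else 0.0
    if asym > 1e-4:
        raise SolverError(f"conductance matrix asymmetry {asym:.3e} exceeds 1e-4")
    Y = (Y + Y.T) / 2.0
    n = Y.shape[0]
    r = Y.sum(axis=1, keepdims=True) / n
    Y = Y - r - r.T + r.sum() / n
    return ConductanceMatrix(matrix=Y, ids=basis.ids, asymmetry=asym)


def masked_gradient(
    values: np.ndarray, active: np.ndarray, spacing: tuple[float, float, float]
) -> np.ndarray:
    """Gradient (per mm) with central differences where both axis neighbors
    are inside the domain, one-sided at domain/grid boundaries, zero where a
    voxel has no in-domain neighbor along an axis."""
    grad = np.zeros(values.shape + (3,))
    for axis in range(3):
        h = spacing[axis]
        vplus = np.zeros_like(values)
        vminus = np.zeros_like(values)
        has_p = np.zeros(values.shape, dtype=bool)
        has_m = np.zeros(values.shape, dtype=bool)

        lo = [slice(None)] * 3
        hi = [slice(None)] * 3
        lo[axis] = slice(0, -1)
        hi[axis] = slice(1, None)
        lo_t, hi_t = tuple(lo), tuple(hi)

        vplus[lo_t] = values[hi_t]
        has_p[lo_t] = active[hi_t]
        vminus[hi_t] = values[lo_t]
        has_m[hi_t] = active[lo_t]

        g = np.zeros_like(values)
        central = has_p & has_m
        g[central] = (vplus[central] - vminus[central]) / (2.0 * h)
        fwd = has_p & ~has_m
        g[fwd] = (vplus[fwd] - values[fwd]) / h
        bwd = has_m & ~has_p
        g[bwd] = (values[bwd] - vminus[bwd]) / h
        g[~active] = 0.0
        grad[..., axis] = g
    return grad


def current_density(fld: PotentialField, phantom: VoxelPhantom) -> np.ndarray:
    """Per-voxel vector field J = sigma grad f in A/mm^2, shape (nx,ny,nz,3).

    Sign convention: J carries the sign of grad f (the physical current
    density is its negative); downstream uses only depend on ``|J|``.
    Component-wise anisotropic scaling; zero outside the conduction domain.
    """
    sig = (phantom.conductivity_per_label() * S_PER_M_TO_S_PER_MM)[phantom.labels]
    grad = masked_gradient(fld.values, phantom.active_mask(), phantom.spacing)
    return sig * grad


def assemble_quadratic_forms(
    phantom: VoxelPhantom,
    basis: BasisFieldSet,
    target: TargetRegion,
) -> QuadraticForms:
    """Assemble the target (C) and off-target (C0) energy matrices.

    Integration runs over conductive tissue voxels (lead body and metal
    contacts excluded — see :data:`NON_TISSUE_LABELS`); C0 covers the full
    tissue complement of the target.
    """
    if np.asarray(target.voxels).size == 0:
        raise TargetError("target region is empty")

    exclude = phantom.codes_of(NON_TISSUE_LABELS)
    domain = phantom.active_mask() & ~np.isin(phantom.labels, exclude)
    dom_flat = domain.ravel()

    t_mask = np.zeros(dom_flat.size, dtype=bool)
    t_mask[target.voxels] = True
    if not np.all(dom_flat[target.voxels]):
        raise TargetError("target voxels fall outside the tissue domain")
    c_mask = dom_flat & ~t_mask

    w = np.sqrt(phantom.voxel_volume)
    n = len(basis)
    Jt = np.empty((n, int(t_mask.sum()) * 3))
    Jc = np.empty((n, int(c_mask.sum()) * 3))
    for q, fld in enumerate(basis.fields):
        J = current_density(fld, phantom).reshape(-1, 3)
        Jt[q] = (J[t_mask] * w).ravel()
        Jc[q] = (J[c_mask] * w).ravel()
    C = Jt @ Jt.T
    C0 = Jc @ Jc.T
    return QuadraticForms(C=C, C0=C0, ids=basis.ids)
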