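"""Current-steering optimization over the electrode conductance model.

The steering objective maximizes the integrated squared current density in
the target region relative to the rest of the tissue: with target and
off-target energy matrices C and C0 over electrode voltages V, the optimum
of the Rayleigh quotient V'CV / V'C0V is the top eigenpair of the
generalized eigenproblem C V = lambda C0 V, normalized to V'C0V = 1, and
the electrode currents follow from the conductance matrix, I = Y V.

Three variants are provided:

* two-sided sources: the unconstrained eigenproblem;
* disconnected (floating) electrodes: currents through a floating subset
  are pinned to zero by restricting V to the null space of the floating
  rows of Y (orthonormal basis Bw from a QR factorization), giving the
  reduced problem D a = lambda D0 a with D = Bw'C Bw;
* one-sided (anodic-only) sources: enumerate ground/source partitions of
  the working electrodes, delete grounded rows/columns, and maximize the
  reduced quotient subject to nonnegative source currents by multistart
  SLSQP — a locally optimal search, since the sign constraint breaks the
  eigenstructure.

Eigenvector sign is inherently ambiguous; the convention here orients the
solution so the working electrode nearest the target carries cathodic
(negative) current, the physiologically conventional reading.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import scipy.linalg as sla
from scipy.optimize import minimize

from .exceptions import SteeringError
from .phantom import ElectrodeSet, TargetRegion
from .solver import ConductanceMatrix, QuadraticForms

logger = logging.getLogger(__name__)

ROLE_SOURCE = "source"
ROLE_SINK = "sink"
ROLE_GROUND = "ground"
ROLE_FLOATING = "floating"

#: relative eigenvalue gap below which a solution is flagged numerically
#: unstable (nearly degenerate optimum).
EIGEN_GAP_FLAG = 1e-6

DEFAULT_SEED = 20230223

SIGN_CONVENTION = (
    "oriented so the working electrode nearest the target carries cathodic "
    "(negative) current"
)


@dataclass
class SteeringSolution:
    """Optimal electrode excitation pattern for one steering variant."""

    ids: tuple[str, ...]
    voltages: np.ndarray  # V*, normalized to V'C0V = 1
    currents: np.ndarray  # I* = Y V*, amperes
    objective: float  # lambda*
    roles: tuple[str, ...]
    percents: np.ndarray  # integer percent per electrode (per polarity)
    variant: str
    eigen_gap: float
    stable: bool
    normalization: float  # V*' C0 V* as returned
    sign_convention: str = SIGN_CONVENTION

    def by_electrode(self) -> list[dict]:
        return [
            {
                "id": eid,
                "role": self.roles[i],
                "current_A": float(self.currents[i]),
                "percent": int(self.percents[i]),
                "voltage_V": float(self.voltages[i]),
            }
            for i, eid in enumerate(self.ids)
        ]


@dataclass
class FloatingConstraint:
    """Null-space reduction enforcing zero current on floating electrodes."""

    floating: tuple[int, ...]
    basis: np.ndarray  # Bw, (N, N - m), orthonormal columns
    D: np.ndarray | None = None
    D0: np.ndarray | None = None


@dataclass
class GroundSourcePartition:
    """One ground/source split of the working electrodes (one-sided solve)."""

    ground: tuple[int, ...]
    sources: tuple[int, ...]
    objective: float = float("nan")


def _as_indices(ids_or_idx, ids: tuple[str, ...]) -> list[int]:
    out = []
    for e in ids_or_idx:
        out.append(ids.index(e) if isinstance(e, str) else int(e))
    return out


def _ridge(C0: np.ndarray) -> np.ndarray:
    """Regularize C0 when near-singular (cond > 1e12)."""
    w = np.linalg.eigvalsh(C0)
    if w[0] <= 0 or w[-1] / max(w[0], np.finfo(float).tiny) > 1e12:
        n = C0.shape[0]
        eps = 1e-10 * np.trace(C0) / n
        if eps <= 0:
            raise SteeringError("off-target matrix C0 is singular")
        return C0 + eps * np.eye(n)
    return C0


def _top_eigpair(
    C: np.ndarray, C0: np.ndarray, pick_vector: np.ndarray | None = None
) -> tuple[float, np.ndarray, float]:
    """Top generalized eigenpair of (C, C0) with deterministic tie-break.

    Returns (lambda*, v with v'C0v = 1, relative eigen-gap). Within a
    degenerate top eigenspace the combination maximizing |pick_vector . v|
    is returned (``pick_vector`` is typically the conductance row of the
    electrode nearest the target).
    """
    C = np.asarray(C, float)
    C0r = _ridge(np.asarray(C0, float))
    try:
        w, vecs = sla.eigh(C, C0r)
    except sla.LinAlgError as exc:
        raise SteeringError(f"generalized eigensolve failed: {exc}")
    lam = w[-1]
    scale = max(abs(lam), np.finfo(float).tiny)
    gap = (w[-1] - w[-2]) / scale if len(w) > 1 else np.inf

    degenerate = np.flatnonzero(w >= lam - 1e-10 * scale)
    if len(degenerate) > 1 and pick_vector is not None:
        W = vecs[:, degenerate]  # C0r-orthonormal columns
        beta = W.T @ pick_vector
        nb = np.linalg.norm(beta)
        v = W @ (beta / nb) if nb > 0 else vecs[:, -1]
    else:
        v = vecs[:, -1]
    # eigh normalizes against the (possibly ridged) C0r; renormalize exactly
    q = float(v @ np.asarray(C0, float) @ v)
    if q <= 0:
        raise SteeringError("eigenvector has non-positive off-target energy")
    return float(lam), v / np.sqrt(q), float(gap)


def _gauge_fix(
    v: np.ndarray, C: np.ndarray, C0: np.ndarray, lam: float
) -> np.ndarray:
    """Remove the common-mode (constant) voltage and renormalize.

    For volume-conductor instances the potential is defined up to an
    additive constant: a constant V drives no current (Y 1 = 0) and no
    current density (C 1 = C0 1 = 0 up to solver tolerance), so the
    eigensolve leaves the common mode arbitrary and the zero-mean gauge is
    canonical. For general matrix pairs the constant direction need not be
    null; the projection is kept only when it leaves the Rayleigh quotient
    unchanged to 1e-6 relative.
    """
    w = v - v.mean()
    q = float(w @ C0 @ w)
    if not np.isfinite(q) or q <= 0:
        return v
    w = w / np.sqrt(q)
    if abs(float(w @ C @ w) - lam) > 1e-6 * max(abs(lam), np.finfo(float).tiny):
        return v
    return w


def _orient(
    v: np.ndarray, I: np.ndarray, cathode_index: int | None
) -> tuple[np.ndarray, np.ndarray]:
    """Fix the eigenvector sign: cathodic current at the reference electrode
    (fallback: at the largest-magnitude electrode)."""
    idx = cathode_index
    if idx is None or abs(I[idx]) <= 1e-12 * max(np.abs(I).max(), 1e-300):
        idx = int(np.argmax(np.abs(I)))
    if I[idx] > 0:
        return -v, -I
    return v, I


def _roles_from_currents(
    I: np.ndarray, floating: set[int], ground: set[int]
) -> tuple[str, ...]:
    roles = []
    scale = np.abs(I).max()
    for p, current in enumerate(I):
        if p in floating:
            roles.append(ROLE_FLOATING)
        elif p in ground:
            roles.append(ROLE_GROUND)
        elif current > 0:
            roles.append(ROLE_SOURCE)
        elif current < 0:
            roles.append(ROLE_SINK)
        else:
            roles.append(ROLE_SINK if scale == 0 else ROLE_SOURCE)
    return tuple(roles)


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.floor(np.abs(x) + 0.5) * np.sign(x)


def to_percentages(I: np.ndarray, roles: tuple[str, ...] | None = None) -> np.ndarray:
    """Integer per-electrode percentages, per polarity.

    Source percentages are 100*I_p / (sum of positive currents) rounded
    half-away-from-zero; sink percentages likewise on magnitudes, so each
    polarity sums to 100 up to rounding slack. Floating/zero electrodes get
    0. Raises :class:`SteeringError` on an all-zero current vector.
    """
    I = np.asarray(I, float)
    if np.abs(I).max() == 0:
        raise SteeringError("cannot compute percentages of an all-zero current vector")
    eps = 1e-12 * np.abs(I).max()
    masked = I.copy()
    if roles is not None:
        masked[[r == ROLE_FLOATING for r in roles]] = 0.0
    pct = np.zeros(I.size, dtype=int)
    pos = masked > eps
    if pos.any():
        pct[pos] = _round_half_away(100.0 * masked[pos] / masked[pos].sum()).astype(int)
    neg = masked < -eps
    if neg.any():
        mags = -masked[neg]
        pct[neg] = _round_half_away(100.0 * mags / mags.sum()).astype(int)
    return pct


def solve_two_sided(
    forms: QuadraticForms,
    Y: ConductanceMatrix,
    cathode_index: int | None = None,
) -> SteeringSolution:
    """Unconstrained two-sided steering: top eigenpair of C V = lambda C0 V."""
    lam, v, gap = _top_eigpair(
        forms.C,
        forms.C0,
        pick_vector=None if cathode_index is None else Y.matrix[cathode_index],
    )
    v = _gauge_fix(v, forms.C, forms.C0, lam)
    I = Y.matrix @ v
    v, I = _orient(v, I, cathode_index)
    roles = _roles_from_currents(I, floating=set(), ground=set())
    return SteeringSolution(
        ids=forms.ids,
        voltages=v,
        currents=I,
        objective=lam,
        roles=roles,
        percents=to_percentages(I, roles),
        variant="two_sided",
        eigen_gap=gap,
        stable=gap >= EIGEN_GAP_FLAG,
        normalization=float(v @ forms.C0 @ v),
    )


def reduce_floating(Y: ConductanceMatrix, floating) -> FloatingConstraint:
    """Orthonormal basis Bw of the subspace with zero floating-electrode
    current (null space of the floating rows Yf), via QR factorization."""
    n = Y.matrix.shape[0]
    fl = sorted(_as_indices(floating, Y.ids))
    m = len(fl)
    if m > n - 2:
        raise SteeringError(
            f"{m} floating electrodes leave fewer than two working electrodes"
        )
    if m == 0:
        return FloatingConstraint(floating=(), basis=np.eye(n))
    Yf = Y.matrix[fl, :]
    Q, R = sla.qr(Yf.T, mode="full")
    rank = np.sum(np.abs(np.diag(R)) > np.abs(R).max() * max(Yf.shape) * 1e-14)
    if rank < m:
        raise SteeringError("floating constraint rows of Y are rank deficient")
    Bw = Q[:, m:]
    resid = np.abs(Yf @ Bw).max()
    if resid > 1e-10 * max(np.abs(Yf).max(), 1.0):
        raise SteeringError(f"null-space residual {resid:.3e} too large")
    return FloatingConstraint(floating=tuple(fl), basis=Bw)


def solve_with_floating(
    forms: QuadraticForms,
    Y: ConductanceMatrix,
    floating,
    cathode_index: int | None = None,
) -> SteeringSolution:
    """Steering with the given electrodes disconnected (zero current).

    Solves the reduced eigenproblem D a = lambda D0 a with D = Bw'C Bw and
    maps back via V* = Bw a*; an empty floating set reproduces the
    two-sided solution.
    """
    constraint = reduce_floating(Y, floating)
    Bw = constraint.basis
    D = Bw.T @ forms.C @ Bw
    D0 = Bw.T @ forms.C0 @ Bw
    constraint.D, constraint.D0 = D, D0
    pick = None
    if cathode_index is not None:
        pick = Bw.T @ Y.matrix[cathode_index]
    lam, alpha, gap = _top_eigpair(D, D0, pick_vector=pick)
    v = Bw @ alpha
    # the constant vector lies in null(Yf) (Y 1 = 0), so the zero-mean gauge
    # preserves the floating constraint exactly
    v = _gauge_fix(v, forms.C, forms.C0, lam)
    I = Y.matrix @ v
    fl = set(constraint.floating)
    v, I = _orient(v, I, cathode_index if cathode_index not in fl else None)
    roles = _roles_from_currents(I, floating=fl, ground=set())
    variant = "two_sided" if not fl else "floating"
    return SteeringSolution(
        ids=forms.ids,
        voltages=v,
        currents=I,
        objective=lam,
        roles=roles,
        percents=to_percentages(I, roles),
        variant=variant,
        eigen_gap=gap,
        stable=gap >= EIGEN_GAP_FLAG,
        normalization=float(v @ forms.C0 @ v),
    )


def _one_sided_partition(
    C: np.ndarray,
    C0: np.ndarray,
    Ym: np.ndarray,
    ground: list[int],
    sources: list[int],
    floating: list[int],
    rng: np.random.Generator,
    n_starts: int,
) -> tuple[float, np.ndarray] | None:
    """Best local optimum for one ground/source split.

    Variables are the non-ground voltages reduced onto the floating null
    space; the anodic constraint is nonnegative current at the source
    electrodes (grounds sink the return current, floats carry none).
    """
    rest = sorted(sources + floating)  # non-ground electrodes
    Cr = C[np.ix_(rest, rest)]
    C0r = C0[np.ix_(rest, rest)]
    if floating:
        Yf = Ym[np.ix_(floating, rest)]
        Q, R = sla.qr(Yf.T, mode="full")
        Bw = Q[:, len(floating):]
    else:
        Bw = np.eye(len(rest))
    if Bw.shape[1] == 0:
        return None
    D = Bw.T @ Cr @ Bw
    D0 = _ridge(Bw.T @ C0r @ Bw)
    src_pos = [rest.index(s) for s in sources]
    M = Ym[np.ix_(sources, rest)] @ Bw  # source currents = M @ alpha

    def objective(a):
        return -a @ D @ a

    def objective_grad(a):
        return -2.0 * (D @ a)

    constraints = [
        {
            "type": "eq",
            "fun": lambda a: a @ D0 @ a - 1.0,
            "jac": lambda a: 2.0 * (D0 @ a),
        },
        {"type": "ineq", "fun": lambda a: M @ a, "jac": lambda a: M},
    ]

    def normalized(a):
        q = a @ D0 @ a
        return a / np.sqrt(q) if q > 0 else None

    starts = []
    try:
        _, a0, _ = _top_eigpair(D, D0)
        for cand in (a0, -a0):
            feas = M @ cand
            if feas.min() >= -1e-12:
                starts.append(cand)
                break
        else:
            # project the eigenvector's source currents onto the cone
            c = np.maximum(M @ a0, 0.0)
            if c.max() <= 0:
                c = np.maximum(-(M @ a0), 0.0)
            a = np.linalg.lstsq(M, c, rcond=None)[0]
            a = normalized(a)
            if a is not None:
                starts.append(a)
    except (SteeringError, np.linalg.LinAlgError):
        pass
    while len(starts) < n_starts:
        c = rng.uniform(0.1, 1.0, size=len(sources))
        a = np.linalg.lstsq(M, c, rcond=None)[0]
        a = normalized(a)
        if a is None:
            return None
        starts.append(a)

    best: tuple[float, np.ndarray] | None = None
    for a_start in starts:
        try:
            res = minimize(
                objective,
                a_start,
                jac=objective_grad,
                method="SLSQP",
                constraints=constraints,
                options={"maxiter": 200, "ftol": 1e-12},
            )
        except (ValueError, np.linalg.LinAlgError):  # pragma: no cover
            continue
        a = normalized(res.x)
        if a is None:
            continue
        feas = M @ a
        if feas.size and feas.min() < -1e-9 * max(np.abs(M @ a).max(), 1e-300):
            continue
        lam = float(a @ D @ a)
        if best is None or lam > best[0]:
            best = (lam, a)
    if best is None:
        logger.warning(
            "one-sided combination ground=%s produced no feasible optimum", ground
        )
        return None
    lam, a = best
    v_rest = Bw @ a
    v = np.zeros(C.shape[0])
    v[rest] = v_rest
    return lam, v


def solve_one_sided(
    forms: QuadraticForms,
    Y: ConductanceMatrix,
    working,
    ground_max: int = 4,
    n_starts: int = 5,
    seed: int = DEFAULT_SEED,
) -> SteeringSolution:
    """One-sided (anodic-only) steering over the working electrodes.

    Enumerates ground/source partitions of the working set (ground sets up
    to ``ground_max`` electrodes), solves each nonnegativity-constrained
    reduced problem by multistart SLSQP, and returns the best combination.
    Electrodes outside ``working`` are treated as floating.
    """
    ids = forms.ids
    n = len(ids)
    work = sorted(_as_indices(working, ids))
    if len(work) < 2:
        raise SteeringError("one-sided steering needs at least two working electrodes")
    floating = [p for p in range(n) if p not in work]
    rng = np.random.default_rng(seed)

    C, C0, Ym = forms.C, forms.C0, Y.matrix
    best: tuple[float, np.ndarray, GroundSourcePartition] | None = None
    partitions: list[GroundSourcePartition] = []
    for g_size in range(1, min(ground_max, len(work) - 1) + 1):
        for ground in combinations(work, g_size):
            sources = [p for p in work if p not in ground]
            part = GroundSourcePartition(ground=tuple(ground), sources=tuple(sources))
            result = _one_sided_partition(
                C, C0, Ym, list(ground), sources, floating, rng, n_starts
            )
            if result is None:
                partitions.append(part)
                continue
            lam, v = result
            part.objective = lam
            partitions.append(part)
            if best is None or lam > best[0]:
                best = (lam, v, part)
    if best is None:
        raise SteeringError("no feasible ground/source combination found")

    lam, v, part = best
    I = Ym @ v
    roles = _roles_from_currents(I, floating=set(floating), ground=set(part.ground))
    q = float(v @ C0 @ v)
    # gap is not meaningful for the constrained local search; report the
    # margin to the runner-up combination instead.
    lams = sorted(
        (p.objective for p in partitions if np.isfinite(p.objective)), reverse=True
    )
    gap = (lams[0] - lams[1]) / max(abs(lams[0]), 1e-300) if len(lams) > 1 else np.inf
    return SteeringSolution(
        ids=ids,
        voltages=v,
        currents=I,
        objective=lam,
        roles=roles,
        percents=to_percentages(I, roles),
        variant="one_sided",
        eigen_gap=float(gap),
        stable=gap >= EIGEN_GAP_FLAG,
        normalization=q,
        sign_convention="anodic sources (nonnegative source currents)",
    )


def select_active_electrodes(
    electrodes: ElectrodeSet, target: TargetRegion, k: int = 8
) -> tuple[tuple[str, ...], tuple[str, ...]]:
    """Clinical selection rule: the k/2 electrodes per lead nearest the
    target center are active; the rest float. Ties break toward the lower
    electrode index."""
    if k % 2 != 0:
        raise SteeringError(f"active electrode count k must be even, got {k}")
    if len(electrodes) < 2:
        raise SteeringError("need at least two electrodes")
    center = np.asarray(target.center)
    per_lead = k // 2
    active: list[str] = []
    for lead in electrodes.leads:
        members = [e for e in electrodes.ids if electrodes.lead_of(e) == lead]
        dists = [
            (float(np.linalg.norm(electrodes.centroids[e] - center)), i, e)
            for i, e in enumerate(members)
        ]
        dists.sort()
        active.extend(e for _, _, e in dists[:per_lead])
    active_t = tuple(e for e in electrodes.ids if e in active)
    floating_t = tuple(e for e in electrodes.ids if e not in active)
    return active_t, floating_t
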