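"""OEM and MEM online calibration of new GRM items.

Both methods are marginal maximum likelihood EM with the operational item
parameters held fixed at their known values.  For each examinee i who
answered new item j, the E-step forms posterior weights over the
quadrature grid,

    h_i(X_k) = L_i(X_k) A(X_k) / sum_k L_i(X_k) A(X_k),

where L_i is the likelihood of the examinee's operational responses (and,
from the second MEM cycle onward, of the response to the new item as
well).  The sufficient statistics are the expected category counts and
expected sample size at each node,

    rbar_tk = sum_i u_it h_i(X_k),      fbar_k = sum_i h_i(X_k),

with u_it the one-hot score indicator.  The M-step maximizes

    Q(a, b) = sum_k sum_t rbar_tk log p_t(X_k; a, b)

by a safeguarded Newton iteration in (log a, b_1, log-gaps of b), which
makes slope positivity and boundary monotonicity structural.  OEM runs
exactly one EM cycle with the operational-only posterior; MEM iterates,
replacing the posterior with the joint one, until the maximum absolute
parameter change between cycles falls below a threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .cat_engine import QuadratureGrid
from .grm_core import DEFAULT_D, GRMItem, PackedItems, category_probs

__all__ = [
    "CalibrationSettings",
    "CalibrationEvidence",
    "ExpectedCounts",
    "CalibrationResult",
    "operational_likelihood",
    "posterior_weights",
    "expected_counts",
    "mstep",
    "mstep_objective",
    "calibrate_oem",
    "calibrate_mem",
    "marginal_loglik",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CalibrationSettings:
    """Numerical settings shared by OEM and MEM."""

    newton_tol: float = 1e-4       # gradient max-norm at the M-step optimum
    max_newton_iter: int = 100
    em_tol: float = 1e-3           # max-abs parameter change between cycles
    max_cycles: int = 50
    min_sample: int = 30
    a_bounds: tuple[float, float] = (0.05, 5.0)
    b_bounds: tuple[float, float] = (-6.0, 6.0)
    min_gap: float = 1e-3


@dataclass
class CalibrationEvidence:
    """Everything the E-step needs about the examinees of one new item.

    ``op_loglik[i, k]`` is the (unnormalized) log-likelihood of examinee
    i's operational responses at grid node k; ``scores[i]`` the integer
    score 0..f on the new item.
    """

    scores: np.ndarray          # (N,) int
    op_loglik: np.ndarray       # (N, K)
    f: int

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, int)
        self.op_loglik = np.asarray(self.op_loglik, float)
        if self.op_loglik.shape[0] != len(self.scores):
            raise ValueError("scores and op_loglik disagree on N")
        if self.scores.min() < 0 or self.scores.max() > self.f:
            raise ValueError("scores outside 0..f")

    @property
    def n(self) -> int:
        return len(self.scores)


@dataclass
class ExpectedCounts:
    """E-step sufficient statistics for one new item."""

    r: np.ndarray        # (f+1, K) expected category counts
    fbar: np.ndarray     # (K,) expected sample size per node
    n: int


@dataclass
class CalibrationResult:
    item_id: str
    a: float
    b: np.ndarray
    n_em_cycles: int
    converged: bool
    max_change: float
    loglik_trace: list[float] = field(default_factory=list)
    degenerate: bool = False


# ---------------------------------------------------------------------------
# E-step pieces
# ---------------------------------------------------------------------------


def operational_likelihood(
    responses, grid: QuadratureGrid
) -> np.ndarray:
    """L_i(X_k) for one examinee's operational (item, score) pairs.

    Computed in log space with max subtraction, so only the ratios across
    nodes are meaningful (all the downstream quantities are invariant to
    a positive rescaling of L_i).
    """
    ll = np.zeros(len(grid))
    for item, score in responses:
        p = category_probs(item, grid.points)[:, score]
        with np.errstate(divide="ignore"):
            ll += np.log(np.maximum(p, 1e-300))
    m = ll.max()
    if not np.isfinite(m):
        raise ValueError("likelihood vanished at every grid node")
    return np.exp(ll - m)


def posterior_weights(L: np.ndarray, grid: QuadratureGrid) -> np.ndarray:
    """h(X_k) = L(X_k) A(X_k) / sum_k L(X_k) A(X_k)."""
    L = np.asarray(L, float)
    num = L * grid.weights
    denom = num.sum()
    if denom <= 0:
        raise ValueError("all-zero likelihood")
    return num / denom


def _new_item_logp(item: GRMItem, grid: QuadratureGrid) -> np.ndarray:
    """log p_t(X_k) for one item: (f+1, K)."""
    p = category_probs(item, grid.points)          # (K, f+1)
    with np.errstate(divide="ignore"):
        return np.log(np.maximum(p.T, 1e-300))


def expected_counts(
    evidence: CalibrationEvidence,
    grid: QuadratureGrid,
    include_new: bool = False,
    current_params: GRMItem | None = None,
) -> ExpectedCounts:
    """Expected category counts rbar and sample sizes fbar.

    With ``include_new`` (MEM cycles >= 2) the posterior of each examinee
    multiplies in the current-parameter likelihood of their new-item
    score; otherwise only the operational responses enter (OEM and the
    first MEM cycle).
    """
    if include_new and current_params is None:
        raise ValueError("include_new requires current_params")
    ll = evidence.op_loglik
    if include_new:
        ll = ll + _new_item_logp(current_params, grid)[evidence.scores]
    w = np.exp(ll - ll.max(axis=1, keepdims=True)) * grid.weights
    h = w / w.sum(axis=1, keepdims=True)                       # (N, K)
    onehot = np.zeros((evidence.n, evidence.f + 1))
    onehot[np.arange(evidence.n), evidence.scores] = 1.0
    r = onehot.T @ h                                           # (f+1, K)
    return ExpectedCounts(r, h.sum(axis=0), evidence.n)


# ---------------------------------------------------------------------------
# M-step
# ---------------------------------------------------------------------------


def _cat_probs_on_grid(a: float, b: np.ndarray, D: float,
                       points: np.ndarray) -> np.ndarray:
    """(f+1, K) category probabilities plus the CBRF matrix (f+2, K)."""
    z = D * a * (points[None, :] - b[:, None])                 # (f, K)
    ps = 0.5 * (1.0 + np.tanh(0.5 * z))
    full = np.vstack([np.ones_like(points), ps, np.zeros_like(points)])
    return full[:-1] - full[1:], full


def mstep_objective(counts: ExpectedCounts, a: float, b: np.ndarray,
                    D: float, grid: QuadratureGrid) -> float:
    """Q(a, b) = sum_k sum_t rbar_tk log p_t(X_k)."""
    p, _ = _cat_probs_on_grid(a, np.asarray(b, float), D, grid.points)
    with np.errstate(divide="ignore", invalid="ignore"):
        lp = np.log(np.maximum(p, 1e-300))
    return float(np.sum(counts.r * lp))


def _q_and_grad(zeta: np.ndarray, counts: ExpectedCounts, D: float,
                grid: QuadratureGrid):
    """Q and its gradient in zeta = (log a, b1, log gaps)."""
    a = np.exp(zeta[0])
    gaps = np.exp(zeta[2:])
    b = zeta[1] + np.concatenate([[0.0], np.cumsum(gaps)])
    X = grid.points
    p, full = _cat_probs_on_grid(a, b, D, X)                  # p:(f+1,K)
    with np.errstate(divide="ignore"):
        lp = np.log(np.maximum(p, 1e-300))
    Q = float(np.sum(counts.r * lp))
    # dQ/dP*_t = r_t/p_t - r_{t-1}/p_{t-1}, t = 1..f
    ratio = np.where(counts.r > 0, counts.r / np.maximum(p, 1e-300), 0.0)
    dP = ratio[1:] - ratio[:-1]                               # (f, K)
    Pst = full[1:-1]                                          # (f, K) inner CBRFs
    wlog = Pst * (1.0 - Pst)
    db = np.sum(dP * (-D * a) * wlog, axis=1)                 # (f,)
    da = float(np.sum(dP * (D * (X[None, :] - b[:, None])) * wlog))
    g = np.empty_like(zeta)
    g[0] = a * da
    g[1] = db.sum()
    # gap s contributes to b_t for t > s (0-based boundary index)
    tail = np.cumsum(db[::-1])[::-1]
    g[2:] = gaps * tail[1:]
    return Q, g


def _zeta_from_ab(a: float, b: np.ndarray, settings: CalibrationSettings):
    b = np.asarray(b, float)
    gaps = np.maximum(np.diff(b), settings.min_gap)
    return np.concatenate([[np.log(a), b[0]], np.log(gaps)])


def _ab_from_zeta(zeta: np.ndarray):
    a = np.exp(zeta[0])
    b = zeta[1] + np.concatenate([[0.0], np.cumsum(np.exp(zeta[2:]))])
    return a, b


def mstep(
    counts: ExpectedCounts,
    start: GRMItem,
    settings: CalibrationSettings = CalibrationSettings(),
    grid: QuadratureGrid | None = None,
) -> GRMItem:
    """Newton maximization of the M-step objective.

    Safeguards: analytic gradient, finite-difference Hessian, step
    halving so the objective never decreases, step-length cap, and box
    constraints applied through the (log a, b1, log-gap) coordinates.
    If a score level carries essentially no expected mass the gap floor
    keeps the adjacent boundaries separated instead of letting them
    collapse (the item is flagged by the callers).
    """
    if grid is None:
        raise ValueError("mstep requires the quadrature grid")
    f = counts.r.shape[0] - 1
    if len(start.b) != f:
        raise ValueError("start item boundary count disagrees with counts")
    D = start.D
    zeta = _zeta_from_ab(start.a, np.asarray(start.b), settings)
    Q, g = _q_and_grad(zeta, counts, D, grid)
    if not np.isfinite(Q):
        raise ValueError("non-finite objective at the starting values")
    scale = max(counts.n, 1)
    for _ in range(settings.max_newton_iter):
        if np.max(np.abs(g)) / scale < settings.newton_tol:
            break
        # finite-difference Hessian from the analytic gradient
        n_par = len(zeta)
        H = np.empty((n_par, n_par))
        eps = 1e-5
        for i in range(n_par):
            zp = zeta.copy()
            zp[i] += eps
            _, gp = _q_and_grad(zp, counts, D, grid)
            H[:, i] = (gp - g) / eps
        H = 0.5 * (H + H.T)
        # shift the Hessian negative definite (Levenberg-style) so the
        # Newton direction is always an ascent direction
        try:
            evals = np.linalg.eigvalsh(H)
            shift = max(0.0, float(evals.max())) + 1e-6 * max(
                1.0, float(np.abs(evals).max()))
            step = np.linalg.solve(H - shift * np.eye(n_par), -g)
        except np.linalg.LinAlgError:
            step = g / scale
        if not np.all(np.isfinite(step)) or np.dot(step, g) <= 0:
            step = g / scale          # fall back to (scaled) ascent
        nrm = np.max(np.abs(step))
        if nrm > 2.0:
            step *= 2.0 / nrm
        # step halving: never decrease Q
        improved = False
        for _ in range(40):
            cand = _clip_zeta(zeta + step, settings)
            Qc, gc = _q_and_grad(cand, counts, D, grid)
            if np.isfinite(Qc) and Qc > Q + 1e-12:
                zeta, Q, g = cand, Qc, gc
                improved = True
                break
            step *= 0.5
        if not improved:
            break
    a, b = _ab_from_zeta(_clip_zeta(zeta, settings))
    return GRMItem(start.item_id, float(a), tuple(b), D)


def _clip_zeta(zeta: np.ndarray, settings: CalibrationSettings) -> np.ndarray:
    z = zeta.copy()
    z[0] = np.clip(z[0], np.log(settings.a_bounds[0]), np.log(settings.a_bounds[1]))
    z[1] = np.clip(z[1], settings.b_bounds[0], settings.b_bounds[1])
    z[2:] = np.clip(z[2:], np.log(settings.min_gap), np.log(12.0))
    # keep the whole boundary vector inside the box: cap the total span,
    # then shift down if the top boundary still pokes out
    lo, hi = settings.b_bounds
    span = float(np.sum(np.exp(z[2:])))
    if span > hi - lo:
        z[2:] += np.log((hi - lo) / span)
        span = hi - lo
    if z[1] + span > hi:
        z[1] = hi - span
    return z


# ---------------------------------------------------------------------------
# OEM / MEM drivers
# ---------------------------------------------------------------------------


def marginal_loglik(
    evidence: CalibrationEvidence, item: GRMItem, grid: QuadratureGrid
) -> float:
    """Joint marginal log-likelihood of operational + new-item responses.

    sum_i log sum_k L_i(X_k) p_{j, s_i}(X_k) A(X_k), up to the additive
    constant absorbed in the unnormalized operational log-likelihoods.
    """
    ll = evidence.op_loglik + _new_item_logp(item, grid)[evidence.scores]
    m = ll.max(axis=1, keepdims=True)
    return float(np.sum(m[:, 0] + np.log(
        np.sum(np.exp(ll - m) * grid.weights, axis=1))))


def _check_degenerate(counts: ExpectedCounts) -> bool:
    return bool(np.any(counts.r.sum(axis=1) < 1e-8))


def calibrate_mem(
    evidence: CalibrationEvidence,
    grid: QuadratureGrid,
    init: tuple[float, np.ndarray],
    settings: CalibrationSettings = CalibrationSettings(),
    *,
    item_id: str = "new",
    D: float = DEFAULT_D,
    max_cycles: int | None = None,
) -> CalibrationResult:
    """Multiple EM cycle (MEM) calibration of one new item.

    Cycle 1 equals OEM (operational-only posterior); later cycles rebuild
    the posterior from the joint likelihood at the current parameters.
    Stops when the max-abs parameter change drops below ``em_tol`` or the
    cycle cap is reached.
    """
    if evidence.n < settings.min_sample:
        raise ValueError(
            f"calibration sample {evidence.n} below minimum {settings.min_sample}")
    cap = settings.max_cycles if max_cycles is None else max_cycles
    a0, b0 = init
    current = GRMItem(item_id, float(a0), tuple(np.asarray(b0, float)), D)
    degenerate = False
    trace: list[float] = []
    converged = False
    change = np.inf
    cycles = 0
    for cycle in range(1, cap + 1):
        counts = expected_counts(evidence, grid, include_new=cycle > 1,
                                 current_params=current)
        if _check_degenerate(counts):
            degenerate = True
        updated = mstep(counts, current, settings, grid)
        prev = np.concatenate([[current.a], current.b])
        new = np.concatenate([[updated.a], updated.b])
        change = float(np.max(np.abs(new - prev)))
        current = updated
        cycles = cycle
        trace.append(marginal_loglik(evidence, current, grid))
        if cycle > 1 and change < settings.em_tol:
            converged = True
            break
    if degenerate:
        logger.debug("item %s: empty score level, gap floor engaged", item_id)
    return CalibrationResult(item_id, current.a, np.asarray(current.b),
                             cycles, converged or cap == 1, change, trace,
                             degenerate)


def calibrate_oem(
    evidence: CalibrationEvidence,
    grid: QuadratureGrid,
    init: tuple[float, np.ndarray],
    settings: CalibrationSettings = CalibrationSettings(),
    *,
    item_id: str = "new",
    D: float = DEFAULT_D,
) -> CalibrationResult:
    """One EM cycle (OEM): a single operational-posterior E-step followed
    by a single Newton M-step.  Identical to MEM capped at one cycle."""
    return calibrate_mem(evidence, grid, init, settings, item_id=item_id,
                         D=D, max_cycles=1)
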