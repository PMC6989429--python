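"""Fixed-length adaptive test administration.

Operational items are selected by maximum Fisher information (MFI) at the
provisional ability estimate; the ability is re-estimated by expected a
posteriori (EAP) on a quadrature grid after every operational response.
New (pretest) items are seeded at scheduled positions and never enter the
ability estimate — their responses are logged for later calibration only.

Two administration paths are provided: :func:`administer_test` runs one
examinee at a time (the reference path, used by the adaptive seeding
design whose state evolves between examinees), and
:func:`simulate_operational_cats` runs a whole cohort in lockstep with
vectorized selection and scoring.  Both consume exactly one uniform per
administered item from a per-examinee random stream, so a cohort
simulation is reproducible examinee-by-examinee.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .grm_core import GRMItem, ItemPool, PackedItems, category_probs, fisher_information

__all__ = [
    "QuadratureGrid",
    "make_grid",
    "InfoTable",
    "ResponseRecord",
    "ExamineeLog",
    "ResponseLog",
    "eap_estimate",
    "select_mfi",
    "administer_test",
    "simulate_operational_cats",
    "BatchCATResult",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# quadrature
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QuadratureGrid:
    """Equally spaced quadrature points with normal-density prior weights."""

    points: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, float)
        wts = np.asarray(self.weights, float)
        if pts.ndim != 1 or len(pts) < 3:
            raise ValueError("grid needs at least 3 points")
        if np.any(np.diff(pts) <= 0):
            raise ValueError("grid points must be strictly increasing")
        if np.any(wts <= 0) or abs(wts.sum() - 1.0) > 1e-10:
            raise ValueError("weights must be positive and sum to 1")
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "weights", wts)

    def __len__(self) -> int:
        return len(self.points)


def make_grid(K: int = 61, lo: float = -4.0, hi: float = 4.0) -> QuadratureGrid:
    """K equally spaced points on [lo, hi], weights ~ standard normal pdf."""
    if K < 3:
        raise ValueError("K must be >= 3")
    if lo >= hi:
        raise ValueError("lo must be < hi")
    pts = np.linspace(lo, hi, K)
    w = stats.norm.pdf(pts)
    return QuadratureGrid(pts, w / w.sum())


# ---------------------------------------------------------------------------
# response logs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ResponseRecord:
    position: int
    item_id: str
    role: str          # "operational" | "new"
    score: int
    theta_hat_after: float


@dataclass
class ExamineeLog:
    examinee_id: int
    theta_true: float
    records: list[ResponseRecord] = field(default_factory=list)

    @property
    def theta_hat(self) -> float:
        """Final ability estimate (after the last operational item)."""
        for rec in reversed(self.records):
            if rec.role == "operational":
                return rec.theta_hat_after
        return 0.0

    def operational_records(self) -> list[ResponseRecord]:
        return [r for r in self.records if r.role == "operational"]


@dataclass
class ResponseLog:
    """Long-format log of a whole administration."""

    examinees: list[ExamineeLog]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"examinee_id": ex.examinee_id, "position": r.position,
             "item_id": r.item_id, "role": r.role, "score": r.score,
             "theta_hat_after": r.theta_hat_after}
            for ex in self.examinees for r in ex.records
        ]
        return pd.DataFrame(rows)

    def to_csv(self, path_or_buf) -> None:
        # default float formatting round-trips doubles exactly
        self.to_frame().to_csv(path_or_buf, index=False)

    @classmethod
    def from_csv(cls, path_or_buf, theta_true=None) -> "ResponseLog":
        df = pd.read_csv(path_or_buf, float_precision="round_trip")
        exs = []
        for eid, g in df.groupby("examinee_id", sort=True):
            g = g.sort_values("position")
            recs = [ResponseRecord(int(r.position), str(r.item_id), str(r.role),
                                   int(r.score), float(r.theta_hat_after))
                    for r in g.itertuples()]
            tt = np.nan if theta_true is None else theta_true[int(eid)]
            exs.append(ExamineeLog(int(eid), tt, recs))
        return cls(exs)


# ---------------------------------------------------------------------------
# EAP ability estimation
# ---------------------------------------------------------------------------


def _log_likelihood_on_grid(
    responses: Sequence[tuple[GRMItem, int]], grid: QuadratureGrid
) -> np.ndarray:
    ll = np.zeros(len(grid))
    for item, score in responses:
        p = category_probs(item, grid.points)[:, score]
        with np.errstate(divide="ignore"):
            ll += np.log(np.maximum(p, 1e-300))
    return ll


def eap_estimate(
    responses: Sequence[tuple[GRMItem, int]], grid: QuadratureGrid
) -> float:
    """Posterior-mean ability from (item, score) pairs.

    The posterior combines the grid's prior weights with the GRM
    likelihood of the given responses; with no responses this is the
    prior mean (0 on a symmetric grid).
    """
    ll = _log_likelihood_on_grid(responses, grid)
    w = np.exp(ll - ll.max()) * grid.weights
    return float(np.dot(grid.points, w) / w.sum())


# ---------------------------------------------------------------------------
# item selection
# ---------------------------------------------------------------------------


@dataclass
class InfoTable:
    """Fisher information of every operational item tabulated on a fine
    theta grid, so that repeated MFI selection is a row gather instead of
    a fresh evaluation.  The step (default 0.0025) is far below any
    meaningful ability resolution."""

    lo: float
    step: float
    values: np.ndarray  # (n_grid, J)

    @classmethod
    def build(cls, packed: PackedItems, lo: float = -4.0, hi: float = 4.0,
              step: float = 0.0025, chunk: int = 200) -> "InfoTable":
        pts = np.arange(lo, hi + step / 2, step)
        J = len(packed.a)
        vals = np.empty((len(pts), J))
        for s in range(0, J, chunk):
            sub = PackedItems(packed.a[s:s + chunk], packed.b[s:s + chunk],
                              packed.f[s:s + chunk], packed.D)
            vals[:, s:s + chunk] = sub.information(pts)
        return cls(lo, step, vals)

    def row_index(self, theta) -> np.ndarray:
        idx = np.rint((np.asarray(theta, float) - self.lo) / self.step)
        return np.clip(idx, 0, len(self.values) - 1).astype(np.intp)


def select_mfi(
    pool: ItemPool,
    administered: set[str],
    theta_hat: float,
    info_table: InfoTable | None = None,
) -> str:
    """Unadministered operational item with maximum information at
    ``theta_hat``; ties break to the smallest item_id."""
    best_id, best_info = None, -np.inf
    ops = [(it, k) for k, (it, role) in
           enumerate(zip(pool.items, pool.roles)) if role == "operational"]
    if info_table is not None:
        row = info_table.values[info_table.row_index(theta_hat)]
    for it, k in ops:
        if it.item_id in administered:
            continue
        info = row[k] if info_table is not None else float(
            fisher_information(it, theta_hat))
        if info > best_info or (info == best_info and best_id is not None
                                and it.item_id < best_id):
            best_id, best_info = it.item_id, info
    if best_id is None:
        raise RuntimeError("operational pool exhausted")
    return best_id


# ---------------------------------------------------------------------------
# single-examinee administration
# ---------------------------------------------------------------------------


def administer_test(
    theta_true: float,
    pool: ItemPool,
    seed_positions: Iterable[int],
    new_item_supplier: Callable[[float, int], GRMItem] | None,
    grid: QuadratureGrid,
    rng: np.random.Generator,
    *,
    test_length: int = 25,
    examinee_id: int = 0,
    info_table: InfoTable | None = None,
) -> ExamineeLog:
    """Administer one fixed-length adaptive test.

    At each seeding position the supplier is called with the current
    provisional ability and the seeding slot index; the returned new item
    is answered but does not update the ability estimate.  At every other
    position an operational item is chosen by MFI and the ability is
    re-estimated by EAP over the operational responses so far.  The
    provisional ability starts at 0.
    """
    from .grm_core import sample_response  # local import avoids cycle noise

    seed_positions = set(int(p) for p in seed_positions)
    if seed_positions and new_item_supplier is None:
        raise ValueError("seeding positions given without a supplier")
    if not seed_positions.issubset(range(1, test_length + 1)):
        raise ValueError("seed positions must lie in 1..test_length")

    log = ExamineeLog(examinee_id, float(theta_true))
    theta_hat = 0.0
    administered: set[str] = set()
    seen_new: set[str] = set()
    op_responses: list[tuple[GRMItem, int]] = []
    slot = 0
    for pos in range(1, test_length + 1):
        if pos in seed_positions:
            item = new_item_supplier(theta_hat, slot)
            slot += 1
            if item.item_id in seen_new:
                raise RuntimeError(
                    f"new item {item.item_id} repeated for examinee {examinee_id}")
            seen_new.add(item.item_id)
            score = sample_response(item, theta_true, rng)
            log.records.append(ResponseRecord(pos, item.item_id, "new",
                                              score, theta_hat))
        else:
            iid = select_mfi(pool, administered, theta_hat, info_table)
            item = pool[iid]
            administered.add(iid)
            score = sample_response(item, theta_true, rng)
            op_responses.append((item, score))
            theta_hat = eap_estimate(op_responses, grid)
            log.records.append(ResponseRecord(pos, iid, "operational",
                                              score, theta_hat))
    return log


# ---------------------------------------------------------------------------
# cohort (vectorized) administration of the operational part
# ---------------------------------------------------------------------------


@dataclass
class BatchCATResult:
    """Operational part of a cohort administration.

    Attributes
    ----------
    item_idx : (n, L) indices into the packed operational items, in
        administration order.
    scores : (n, L) integer scores.
    theta_hat_traj : (n, L) provisional EAP after each operational item.
    theta_hat : (n,) final ability estimates.
    op_loglik : (n, K) log-likelihood of each examinee's operational
        responses on the quadrature grid (unnormalized), reused verbatim
        by the calibration E-step.
    """

    item_idx: np.ndarray
    scores: np.ndarray
    theta_hat_traj: np.ndarray
    theta_hat: np.ndarray
    op_loglik: np.ndarray
    packed: PackedItems


def simulate_operational_cats(
    thetas: np.ndarray,
    operational: Sequence[GRMItem],
    grid: QuadratureGrid,
    uniforms: np.ndarray,
    *,
    n_administered: int = 20,
    info_table: InfoTable | None = None,
) -> BatchCATResult:
    """Administer ``n_administered`` MFI-selected operational items to every
    examinee in lockstep.

    ``uniforms`` has shape (n, n_administered); row i is the uniform
    stream of examinee i in administration order, so the result matches a
    per-examinee run with the same stream (identical selection, scoring
    and EAP arithmetic).
    """
    packed = PackedItems.from_items(list(operational))
    if info_table is None:
        info_table = InfoTable.build(packed, grid.points[0], grid.points[-1])
    n = len(thetas)
    L = n_administered
    if uniforms.shape != (n, L):
        raise ValueError("uniforms must have shape (n_examinees, n_administered)")
    K = len(grid)
    logp_tab = packed.log_category_probs(grid.points)   # (J, fmax+1, K)

    item_idx = np.empty((n, L), np.intp)
    scores = np.empty((n, L), np.int64)
    traj = np.empty((n, L))
    loglik = np.zeros((n, K))
    theta_hat = np.zeros(n)

    for p in range(L):
        vals = info_table.values[info_table.row_index(theta_hat)]  # (n, J)
        if p:
            vals[np.arange(n)[:, None], item_idx[:, :p]] = -np.inf
        sel = np.argmax(vals, axis=1)           # first max = smallest id
        item_idx[:, p] = sel
        # score the selected item at the true ability
        cp = packed.category_probs(thetas, sel)             # (n, fmax+1)
        cum = np.cumsum(cp, axis=1)
        s = np.sum(uniforms[:, p][:, None] > cum[:, :-1], axis=1)
        scores[:, p] = s
        # EAP update over operational responses so far
        loglik += logp_tab[sel, s, :]
        w = np.exp(loglik - loglik.max(axis=1, keepdims=True)) * grid.weights
        theta_hat = (w @ grid.points) / w.sum(axis=1)
        traj[:, p] = theta_hat

    return BatchCATResult(item_idx, scores, traj, theta_hat, loglik, packed)
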