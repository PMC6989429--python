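"""Seeding designs: which new item each examinee answers at each seeding
location.

The **random design** deals every new item to a quota of examinees
uniformly at random (each examinee sees five distinct new items), so each
item's calibration sample mirrors the examinee population.  The
**adaptive design** spends half of each quota on a random phase used to
pre-estimate the new items, then assigns the remaining examinees by the
match-b rule: at a seeding location the available new item whose mean
provisional boundary difficulty is closest to the examinee's current
ability estimate is chosen, and every item's provisional parameters are
re-estimated each time it accumulates 20 fresh responses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .cat_engine import (InfoTable, QuadratureGrid, administer_test,
                         simulate_operational_cats, BatchCATResult,
                         ExamineeLog)
from .em_calibration import (CalibrationEvidence, CalibrationSettings,
                             calibrate_mem, calibrate_oem,
                             operational_likelihood)
from .grm_core import GRMItem, ItemPool, PackedItems
from .initial_values import (CategoryPassRates, ScoreGroupedAbilities,
                             initial_params)

__all__ = [
    "AssignmentPlan",
    "build_random_plan",
    "matchb_select",
    "OnlineCalibrationData",
    "run_random_design",
    "run_adaptive_design",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# assignment plans
# ---------------------------------------------------------------------------


@dataclass
class AssignmentPlan:
    """Per-examinee new-item assignments (indices into the new-item list)."""

    assignments: np.ndarray       # (n_examinees, items_per_examinee) int
    quotas: np.ndarray            # (n_new,) int

    def __post_init__(self) -> None:
        self.assignments = np.asarray(self.assignments, int)
        self.quotas = np.asarray(self.quotas, int)

    @property
    def n_examinees(self) -> int:
        return self.assignments.shape[0]

    def counts(self) -> np.ndarray:
        return np.bincount(self.assignments.ravel(), minlength=len(self.quotas))

    def to_frame(self) -> pd.DataFrame:
        n, m = self.assignments.shape
        return pd.DataFrame(
            {"examinee_id": np.repeat(np.arange(n), m),
             "slot": np.tile(np.arange(1, m + 1), n),
             "item_index": self.assignments.ravel()})

    def to_csv(self, path_or_buf) -> None:
        self.to_frame().to_csv(path_or_buf, index=False)


def build_random_plan(
    n_new: int,
    per_item_quota: int,
    rng: np.random.Generator,
    items_per_examinee: int = 5,
) -> AssignmentPlan:
    """Uniform balanced assignment: every new item reaches exactly its
    quota of examinees and no examinee sees an item twice.

    Built by a shuffled deal followed by pairwise swap repair of rows
    holding duplicates (swaps preserve the per-item counts exactly).
    """
    total = n_new * per_item_quota
    if total % items_per_examinee:
        need = total / items_per_examinee
        raise ValueError(
            f"infeasible quota arithmetic: {n_new} items x quota "
            f"{per_item_quota} needs {need} examinees at "
            f"{items_per_examinee} items each; adjust the quota")
    if n_new < items_per_examinee and items_per_examinee > 1:
        raise ValueError("fewer new items than seeding slots per examinee")
    n_ex = total // items_per_examinee
    deck = np.repeat(np.arange(n_new), per_item_quota)
    rng.shuffle(deck)
    plan = deck.reshape(n_ex, items_per_examinee)

    def bad_rows():
        srt = np.sort(plan, axis=1)
        return np.nonzero((np.diff(srt, axis=1) == 0).any(axis=1))[0]

    for _ in range(100 * n_ex + 1000):
        bad = bad_rows()
        if len(bad) == 0:
            break
        r = int(bad[0])
        row = plan[r]
        # locate a duplicated value
        vals, cnts = np.unique(row, return_counts=True)
        v = vals[cnts > 1][0]
        c = int(np.nonzero(row == v)[0][1])
        # swap with a random cell whose value is absent from this row and
        # whose row does not already contain v
        for _ in range(1000):
            r2 = int(rng.integers(n_ex))
            c2 = int(rng.integers(items_per_examinee))
            w = plan[r2, c2]
            if r2 == r or w == v or w in row or v in plan[r2]:
                continue
            plan[r, c], plan[r2, c2] = w, v
            break
        else:  # pragma: no cover - pathological tiny cases
            rng.shuffle(deck)
            plan = deck.reshape(n_ex, items_per_examinee)
    else:  # pragma: no cover
        raise RuntimeError("could not repair assignment plan")
    return AssignmentPlan(plan, np.full(n_new, per_item_quota))


def matchb_select(
    mean_b: dict[int, float] | Sequence[float],
    theta_hat: float,
    available: Sequence[int],
) -> int:
    """Available new item minimizing |theta_hat - mean(b)|, ties to the
    smallest index."""
    if len(available) == 0:
        raise ValueError("no new items available for match-b selection")
    best, best_d = None, np.inf
    for j in sorted(available):
        d = abs(theta_hat - float(mean_b[j]))
        if d < best_d:
            best, best_d = j, d
    return best


# ---------------------------------------------------------------------------
# design runners
# ---------------------------------------------------------------------------


@dataclass
class OnlineCalibrationData:
    """Everything downstream calibration needs from one administration."""

    theta_hat: np.ndarray                  # (n,) final ability estimates
    op_loglik: np.ndarray                  # (n, K) operational log-likelihoods
    new_scores: dict[int, np.ndarray]      # item index -> scores
    new_examinees: dict[int, np.ndarray]   # item index -> examinee indices
    plan: AssignmentPlan | None = None
    batch: BatchCATResult | None = None
    fallback_assignments: int = 0
    update_counts: dict[int, int] | None = None  # adaptive re-estimations

    def evidence_for(self, j: int, f: int) -> CalibrationEvidence:
        idx = self.new_examinees[j]
        return CalibrationEvidence(self.new_scores[j], self.op_loglik[idx], f)


def _seed_positions_matrix(n: int, k: int, test_length: int,
                           rng: np.random.Generator) -> np.ndarray:
    """k distinct positions per examinee, uniform over 2..test_length
    (position 1 is always operational so selection starts from the prior
    mean)."""
    opts = test_length - 1
    order = np.argsort(rng.random((n, opts)), axis=1)[:, :k]
    return np.sort(order + 2, axis=1)


def _sample_scores(packed: PackedItems, idx: np.ndarray, thetas: np.ndarray,
                   uniforms: np.ndarray) -> np.ndarray:
    cp = packed.category_probs(thetas, idx)
    cum = np.cumsum(cp, axis=1)
    return np.sum(uniforms[:, None] > cum[:, :-1], axis=1)


def run_random_design(
    new_items: Sequence[GRMItem],
    operational: Sequence[GRMItem],
    thetas: np.ndarray,
    per_item_quota: int,
    grid: QuadratureGrid,
    rng: np.random.Generator,
    *,
    items_per_examinee: int = 5,
    test_length: int = 25,
    n_operational: int | None = None,
    info_table: InfoTable | None = None,
) -> OnlineCalibrationData:
    """Random-design administration of a whole cohort.

    New-item responses never touch the ability estimate, so the
    operational part runs vectorized for all examinees while the plan and
    the seeded responses are laid over it.  Examinee i's uniform stream
    is a spawned child of ``rng``, one draw per administered item in
    position order, which makes the cohort run reproducible
    examinee-by-examinee against :func:`administer_test`.
    """
    n_new = len(new_items)
    n_ex = len(thetas)
    expected = n_new * per_item_quota // items_per_examinee
    if n_ex != expected:
        raise ValueError(f"need exactly {expected} examinees for quota "
                         f"{per_item_quota}, got {n_ex}")
    n_op = test_length - items_per_examinee if n_operational is None else n_operational
    plan = build_random_plan(n_new, per_item_quota, rng, items_per_examinee)
    seed_pos = _seed_positions_matrix(n_ex, items_per_examinee, test_length, rng)
    children = rng.spawn(n_ex)
    U = np.stack([c.random(test_length) for c in children])
    seed_mask = np.zeros((n_ex, test_length), bool)
    seed_mask[np.arange(n_ex)[:, None], seed_pos - 1] = True
    U_op = U[~seed_mask].reshape(n_ex, n_op)
    U_new = U[seed_mask].reshape(n_ex, items_per_examinee)

    batch = simulate_operational_cats(thetas, operational, grid, U_op,
                                      n_administered=n_op,
                                      info_table=info_table)
    packed_new = PackedItems.from_items(list(new_items))
    scores = np.empty((n_ex, items_per_examinee), int)
    for s in range(items_per_examinee):
        scores[:, s] = _sample_scores(packed_new, plan.assignments[:, s],
                                      thetas, U_new[:, s])
    new_scores, new_exs = {}, {}
    for j in range(n_new):
        rows, cols = np.nonzero(plan.assignments == j)
        new_exs[j] = rows
        new_scores[j] = scores[rows, cols]
    return OnlineCalibrationData(batch.theta_hat, batch.op_loglik,
                                 new_scores, new_exs, plan, batch)


def _preestimate(
    j: int,
    item: GRMItem,
    data_thetas: np.ndarray,
    data_scores: np.ndarray,
    op_loglik: np.ndarray,
    grid: QuadratureGrid,
    initializer: str,
    method: str,
    settings: CalibrationSettings,
):
    """Initial values + the condition's calibration method on the
    responses accumulated so far; returns the provisional (a, b)."""
    f = item.f
    groups = ScoreGroupedAbilities.from_responses(data_thetas, data_scores, f)
    rates = CategoryPassRates.from_responses(data_thetas, data_scores, f)
    init = initial_params(initializer, groups, rates)
    ev = CalibrationEvidence(data_scores, op_loglik, f)
    cal = calibrate_oem if method == "oem" else calibrate_mem
    res = cal(ev, grid, init, settings, item_id=item.item_id, D=item.D)
    return float(res.a), np.asarray(res.b)


def run_adaptive_design(
    new_items: Sequence[GRMItem],
    operational: Sequence[GRMItem],
    thetas: np.ndarray,
    per_item_quota: int,
    grid: QuadratureGrid,
    rng: np.random.Generator,
    *,
    initializer: str = "poly-sq-ini",
    method: str = "mem",
    settings: CalibrationSettings = CalibrationSettings(),
    items_per_examinee: int = 5,
    test_length: int = 25,
    update_every: int = 20,
    info_table: InfoTable | None = None,
) -> OnlineCalibrationData:
    """Two-phase adaptive (match-b) administration.

    Phase 1 gives each item half its quota by the random design and
    pre-estimates its parameters.  Phase 2 processes examinees one at a
    time: at each seeding location the under-quota item not yet seen by
    the examinee whose provisional mean boundary difficulty best matches
    the current ability estimate is administered; items are re-estimated
    from all their responses after every ``update_every`` new ones.
    """
    if per_item_quota % 2:
        raise ValueError("adaptive design needs an even quota (1:1 phases)")
    n_new = len(new_items)
    q1 = per_item_quota // 2
    if (n_new * q1) % items_per_examinee:
        raise ValueError("phase-1 quota not dealable; adjust quota")
    n_ex1 = n_new * q1 // items_per_examinee
    n_ex = n_new * per_item_quota // items_per_examinee
    if len(thetas) != n_ex:
        raise ValueError(f"need exactly {n_ex} examinees, got {len(thetas)}")
    n_op = test_length - items_per_examinee
    pool = ItemPool(list(operational), ["operational"] * len(operational))
    if info_table is None:
        info_table = InfoTable.build(PackedItems.from_items(list(operational)),
                                     grid.points[0], grid.points[-1])

    # ---- phase 1: random half -------------------------------------------
    phase1 = run_random_design(new_items, operational, thetas[:n_ex1], q1,
                               grid, rng, items_per_examinee=items_per_examinee,
                               test_length=test_length, info_table=info_table)
    th_hat = list(phase1.theta_hat)
    op_ll = list(phase1.op_loglik)
    item_scores = {j: list(phase1.new_scores[j]) for j in range(n_new)}
    item_exs = {j: list(phase1.new_examinees[j]) for j in range(n_new)}

    prov_a = np.empty(n_new)
    prov_b: list[np.ndarray] = [None] * n_new
    for j, item in enumerate(new_items):
        idx = np.asarray(item_exs[j], int)
        prov_a[j], prov_b[j] = _preestimate(
            j, item, phase1.theta_hat[idx], np.asarray(item_scores[j]),
            phase1.op_loglik[idx], grid, initializer, method, settings)

    # ---- phase 2: match-b ------------------------------------------------
    counts = phase1.plan.counts().astype(int)
    since_update = np.zeros(n_new, int)
    n_updates = np.zeros(n_new, int)
    fallbacks = 0
    for i in range(n_ex1, n_ex):
        theta_true = thetas[i]
        positions = _seed_positions_matrix(1, items_per_examinee,
                                           test_length, rng)[0]
        child = rng.spawn(1)[0]
        chosen: list[int] = []

        def supplier(theta_hat: float, slot: int) -> GRMItem:
            nonlocal fallbacks
            under = [j for j in range(n_new)
                     if counts[j] < per_item_quota and j not in chosen]
            if under:
                mean_b = {j: float(np.mean(prov_b[j])) for j in under}
                j = matchb_select(mean_b, theta_hat, under)
            else:
                unseen = [j for j in range(n_new) if j not in chosen]
                j = int(unseen[int(rng.integers(len(unseen)))])
                fallbacks += 1
                logger.debug("match-b fallback for examinee %d", i)
            chosen.append(j)
            return new_items[j]

        log = administer_test(theta_true, pool, positions, supplier, grid,
                              child, test_length=test_length, examinee_id=i,
                              info_table=info_table)
        op_records = [(pool[r.item_id], r.score)
                      for r in log.operational_records()]
        ll = np.zeros(len(grid))
        for item, score in op_records:
            from .grm_core import category_probs
            with np.errstate(divide="ignore"):
                ll += np.log(np.maximum(
                    category_probs(item, grid.points)[:, score], 1e-300))
        th_hat.append(log.theta_hat)
        op_ll.append(ll)
        new_recs = [r for r in log.records if r.role == "new"]
        for slot, rec in enumerate(new_recs):
            j = chosen[slot]
            item_scores[j].append(rec.score)
            item_exs[j].append(i)
            counts[j] += 1
            since_update[j] += 1
        # re-estimate items that accumulated enough fresh responses
        for j in np.nonzero(since_update >= update_every)[0]:
            idx = np.asarray(item_exs[j], int)
            ll_mat = np.stack([op_ll[k] for k in idx])
            prov_a[j], prov_b[j] = _preestimate(
                j, new_items[j], np.asarray(th_hat)[idx],
                np.asarray(item_scores[j], int), ll_mat, grid,
                initializer, method, settings)
            since_update[j] = 0
            n_updates[j] += 1

    theta_hat = np.asarray(th_hat)
    op_loglik = np.stack(op_ll)
    return OnlineCalibrationData(
        theta_hat, op_loglik,
        {j: np.asarray(item_scores[j], int) for j in range(n_new)},
        {j: np.asarray(item_exs[j], int) for j in range(n_new)},
        phase1.plan, phase1.batch, fallbacks,
        {j: int(n_updates[j]) for j in range(n_new)})
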