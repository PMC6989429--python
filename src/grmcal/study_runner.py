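"""Replicated calibration experiments and the leave-one-out harness.

``run_condition`` simulates the complete workflow of one experimental
condition, replicated R times with independently spawned seeds: generate
an operational pool (1000 items, 2-5 boundaries) and 20 new items, draw
exactly ``n_new * quota / 5`` examinees, administer fixed-length 25-item
adaptive tests (20 operational + 5 seeded new items) under the requested
seeding design, compute initial values, calibrate every new item with
OEM or MEM, and pool recovery metrics over items and replications.

``run_study1`` crosses design x initializer x method (8 conditions,
3-boundary new items, quota 700); ``run_study2`` crosses calibration
sample size (300-700) with the new items' boundary count (2-5) under the
random design, poly-sq-ini starts and MEM.  ``run_loo_harness`` applies
the calibration machinery to a complete score matrix: items are held out
one at a time, abilities come from the remaining items, and held-out
estimates are scored against a full-matrix fit frozen as truth.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .cat_engine import InfoTable, QuadratureGrid, make_grid
from .em_calibration import (CalibrationEvidence, CalibrationSettings,
                             ExpectedCounts, calibrate_mem, calibrate_oem,
                             mstep)
from .evaluation import RecoveryTable
from .grm_core import (DEFAULT_D, GRMItem, ItemPool, PackedItems,
                       generate_abilities, generate_item_pool)
from .initial_values import (INITIALIZERS, CategoryPassRates,
                             ScoreGroupedAbilities, initial_params)
from .seeding_designs import run_adaptive_design, run_random_design

__all__ = [
    "ExperimentConfig",
    "StudyResult",
    "run_condition",
    "run_study1",
    "run_study2",
    "fit_grm_matrix",
    "run_loo_harness",
]

logger = logging.getLogger(__name__)

DESIGNS = ("random", "adaptive")
METHODS = ("oem", "mem")


@dataclass(frozen=True)
class ExperimentConfig:
    """One experimental condition."""

    design: str = "random"
    initializer: str = "poly-sq-ini"
    method: str = "mem"
    f_new: int = 3
    quota: int = 700
    replications: int = 100
    n_new: int = 20
    pool_size: int = 1000
    pool_f_values: tuple[int, ...] = (2, 3, 4, 5)
    test_length: int = 25
    items_per_examinee: int = 5
    seed: int = 1
    D: float = 1.7
    grid_K: int = 61
    grid_lo: float = -4.0
    grid_hi: float = 4.0
    update_every: int = 20
    em: CalibrationSettings = CalibrationSettings()

    def __post_init__(self) -> None:
        if self.design not in DESIGNS:
            raise ValueError(f"design must be one of {DESIGNS}")
        if self.initializer not in INITIALIZERS:
            raise ValueError(f"initializer must be one of {INITIALIZERS}")
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")
        if self.replications < 1:
            raise ValueError("replications must be >= 1")
        if (self.n_new * self.quota) % self.items_per_examinee:
            raise ValueError("n_new * quota must be divisible by "
                             "items_per_examinee")

    @property
    def n_examinees(self) -> int:
        return self.n_new * self.quota // self.items_per_examinee

    def grid(self) -> QuadratureGrid:
        return make_grid(self.grid_K, self.grid_lo, self.grid_hi)

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if "em" in d and isinstance(d["em"], dict):
            d["em"] = CalibrationSettings(**d["em"])
        for key in ("pool_f_values",):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass
class StudyResult:
    table: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def to_csv(self, path_or_buf) -> None:
        self.table.to_csv(path_or_buf, index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# one condition
# ---------------------------------------------------------------------------


def _simulate_replication(config: ExperimentConfig,
                          rep_seed: np.random.SeedSequence):
    """Pool generation and test administration for one replication.

    Each generation stage draws from its own child stream, so two
    conditions sharing a replication seed share their item pools exactly
    and their examinee populations as a nested prefix — a common-random-
    numbers pairing for sample-size comparisons."""
    s_pool, s_new, s_theta, s_design = rep_seed.spawn(4)
    rng = np.random.default_rng(s_design)
    grid = config.grid()
    pool = generate_item_pool(config.pool_size, config.pool_f_values,
                              np.random.default_rng(s_pool),
                              D=config.D, role="operational", id_prefix="op")
    new_items = generate_item_pool(config.n_new, config.f_new,
                                   np.random.default_rng(s_new),
                                   D=config.D, role="new", id_prefix="new")
    thetas = generate_abilities(config.n_examinees,
                                np.random.default_rng(s_theta)).thetas
    operational = pool.items
    info_table = InfoTable.build(PackedItems.from_items(operational),
                                 config.grid_lo, config.grid_hi)
    if config.design == "random":
        data = run_random_design(
            new_items.items, operational, thetas, config.quota, grid, rng,
            items_per_examinee=config.items_per_examinee,
            test_length=config.test_length, info_table=info_table)
    else:
        data = run_adaptive_design(
            new_items.items, operational, thetas, config.quota, grid, rng,
            initializer=config.initializer, method=config.method,
            settings=config.em,
            items_per_examinee=config.items_per_examinee,
            test_length=config.test_length,
            update_every=config.update_every, info_table=info_table)
    return new_items, data, grid


def _calibrate_all(config: ExperimentConfig, new_items, data, grid,
                   first_n: int | None = None):
    """Calibrate every new item, optionally on only the first ``first_n``
    responses per item (a nested subsample of its calibration sample)."""
    est_a = np.empty(config.n_new)
    est_b = np.empty((config.n_new, config.f_new))
    tru_a = np.empty(config.n_new)
    tru_b = np.empty((config.n_new, config.f_new))
    n_degenerate = 0
    cal = calibrate_oem if config.method == "oem" else calibrate_mem
    for j, item in enumerate(new_items.items):
        idx = data.new_examinees[j]
        scores = data.new_scores[j]
        if first_n is not None:
            idx, scores = idx[:first_n], scores[:first_n]
        ev = CalibrationEvidence(scores, data.op_loglik[idx], item.f)
        th = data.theta_hat[idx]
        groups = ScoreGroupedAbilities.from_responses(th, scores, item.f)
        rates = CategoryPassRates.from_responses(th, scores, item.f)
        init = initial_params(config.initializer, groups, rates)
        res = cal(ev, grid, init, config.em, item_id=item.item_id, D=config.D)
        est_a[j], est_b[j] = res.a, res.b
        tru_a[j], tru_b[j] = item.a, item.b
        n_degenerate += int(res.degenerate)
    return est_a, tru_a, est_b, tru_b, {"degenerate_items": n_degenerate}


def _replication_estimates(config: ExperimentConfig,
                           rep_seed: np.random.SeedSequence):
    """One replication: (est_a, tru_a, est_b, tru_b, diagnostics)."""
    new_items, data, grid = _simulate_replication(config, rep_seed)
    return _calibrate_all(config, new_items, data, grid)


def run_condition(config: ExperimentConfig,
                  label: dict | None = None) -> StudyResult:
    """Run one condition for ``config.replications`` replications and pool
    the recovery metrics.  Replication r uses a deterministically spawned
    child of the master seed, so any subset is independently
    reproducible."""
    t0 = time.time()
    R, M, f = config.replications, config.n_new, config.f_new
    est_a = np.empty((R, M))
    tru_a = np.empty((R, M))
    est_b = np.empty((R, M, f))
    tru_b = np.empty((R, M, f))
    diag = {"degenerate_items": 0}
    children = np.random.SeedSequence(config.seed).spawn(R)
    for r, child in enumerate(children):
        ea, ta, eb, tb, d = _replication_estimates(config, child)
        est_a[r], tru_a[r], est_b[r], tru_b[r] = ea, ta, eb, tb
        diag["degenerate_items"] += d["degenerate_items"]
        logger.info("condition %s: replication %d/%d done",
                    label or config.design, r + 1, R)
    table = RecoveryTable()
    lab = label or {"design": config.design, "initializer": config.initializer,
                    "method": config.method, "f": f, "quota": config.quota}
    table.add_condition(lab, est_a, tru_a, est_b, tru_b)
    meta = {"config": config.to_dict(), "runtime_s": time.time() - t0,
            "seed": config.seed, **diag}
    result = StudyResult(table.to_frame(), meta)
    result.estimates = (est_a, tru_a, est_b, tru_b)  # raw draws for reuse
    return result


# ---------------------------------------------------------------------------
# the two simulation studies
# ---------------------------------------------------------------------------


def run_study1(base: ExperimentConfig | None = None, **overrides) -> StudyResult:
    """2 x 2 x 2 grid (design x initializer x method), 3-boundary new
    items, quota 700."""
    base = base or ExperimentConfig()
    rows = []
    meta = {"conditions": []}
    for design in DESIGNS:
        for initializer in INITIALIZERS:
            for method in METHODS:
                cfg = dataclasses.replace(
                    base, design=design, initializer=initializer,
                    method=method, f_new=3, **overrides)
                res = run_condition(cfg)
                rows.append(res.table.iloc[0].to_dict())
                meta["conditions"].append(res.metadata)
    return StudyResult(pd.DataFrame(rows), meta)


def run_study2(base: ExperimentConfig | None = None,
               quotas: Sequence[int] = (300, 400, 500, 600, 700),
               f_values: Sequence[int] = (2, 3, 4, 5),
               nested: bool = True,
               **overrides) -> StudyResult:
    """Calibration sample size x boundary count grid under the random
    design, poly-sq-ini starts and MEM.

    With ``nested`` (the default), each replication administers the
    largest quota once and calibrates every smaller sample size on the
    first-``quota`` subset of each item's responses: the sample-size
    comparison is then paired item by item (common random numbers),
    which is how a monotone sample-size effect should be measured.
    ``nested=False`` runs every cell as an independent condition.
    """
    base = base or ExperimentConfig()
    rows = []
    meta = {"conditions": [], "nested": nested}
    quotas = sorted(quotas)
    for f in f_values:
        seed = base.seed + 1000 * f
        if not nested:
            for quota in quotas:
                cfg = dataclasses.replace(
                    base, design="random", initializer="poly-sq-ini",
                    method="mem", f_new=f, quota=quota, seed=seed,
                    **overrides)
                res = run_condition(cfg)
                rows.append(res.table.iloc[0].to_dict())
                meta["conditions"].append(res.metadata)
            continue
        t0 = time.time()
        cfg = dataclasses.replace(
            base, design="random", initializer="poly-sq-ini", method="mem",
            f_new=f, quota=max(quotas), seed=seed, **overrides)
        R, M = cfg.replications, cfg.n_new
        acc = {q: [np.empty((R, M)), np.empty((R, M)),
                   np.empty((R, M, f)), np.empty((R, M, f)), 0]
               for q in quotas}
        children = np.random.SeedSequence(cfg.seed).spawn(R)
        for r, child in enumerate(children):
            new_items, data, grid = _simulate_replication(cfg, child)
            for q in quotas:
                ea, ta, eb, tb, d = _calibrate_all(
                    cfg, new_items, data, grid,
                    first_n=None if q == max(quotas) else q)
                acc[q][0][r], acc[q][1][r] = ea, ta
                acc[q][2][r], acc[q][3][r] = eb, tb
                acc[q][4] += d["degenerate_items"]
            logger.info("study2 f=%d: replication %d/%d done", f, r + 1, R)
        for q in quotas:
            table = RecoveryTable()
            lab = {"design": "random", "initializer": "poly-sq-ini",
                   "method": "mem", "f": f, "quota": q}
            rows.append(table.add_condition(lab, acc[q][0], acc[q][1],
                                            acc[q][2], acc[q][3]))
            meta["conditions"].append(
                {"config": dataclasses.replace(cfg, quota=q).to_dict(),
                 "seed": seed, "degenerate_items": acc[q][4],
                 "runtime_s": time.time() - t0, "nested": True})
    return StudyResult(pd.DataFrame(rows), meta)


# ---------------------------------------------------------------------------
# full-matrix estimation + leave-one-out harness
# ---------------------------------------------------------------------------


def fit_grm_matrix(
    scores: np.ndarray,
    f_per_item: Sequence[int],
    grid: QuadratureGrid,
    settings: CalibrationSettings = CalibrationSettings(),
    D: float = DEFAULT_D,
    max_cycles: int = 100,
) -> list[GRMItem]:
    """Marginal maximum likelihood fit of all items of a complete score
    matrix (Bock-Aitkin EM with shared posteriors).

    Initial values come from the polyserial method with the standardized
    total score as the ability proxy.
    """
    scores = np.asarray(scores, int)
    N, J = scores.shape
    total = scores.sum(axis=1).astype(float)
    proxy = (total - total.mean()) / max(total.std(), 1e-12)
    items: list[GRMItem] = []
    for j in range(J):
        f = int(f_per_item[j])
        rates = CategoryPassRates.from_responses(proxy, scores[:, j], f)
        groups = ScoreGroupedAbilities.from_responses(proxy, scores[:, j], f)
        a0, b0 = initial_params("poly-sq-ini", groups, rates)
        items.append(GRMItem(f"item{j + 1}", a0, tuple(b0), D))

    K = len(grid)
    for _ in range(max_cycles):
        packed = PackedItems.from_items(items)
        logp = packed.log_category_probs(grid.points)    # (J, fmax+1, K)
        ll = np.zeros((N, K))
        for j in range(J):
            ll += logp[j, scores[:, j], :]
        w = np.exp(ll - ll.max(axis=1, keepdims=True)) * grid.weights
        h = w / w.sum(axis=1, keepdims=True)
        change = 0.0
        new_items = []
        for j in range(J):
            f = int(f_per_item[j])
            onehot = np.zeros((N, f + 1))
            onehot[np.arange(N), scores[:, j]] = 1.0
            cnt = ExpectedCounts(onehot.T @ h, h.sum(axis=0), N)
            upd = mstep(cnt, items[j], settings, grid)
            change = max(change, abs(upd.a - items[j].a),
                         float(np.max(np.abs(np.array(upd.b) -
                                             np.array(items[j].b)))))
            new_items.append(upd)
        items = new_items
        if change < settings.em_tol:
            break
    return items


def run_loo_harness(
    matrix: np.ndarray | pd.DataFrame,
    f_per_item: Sequence[int],
    rng: np.random.Generator,
    *,
    train_n: int = 300,
    method: str = "mem",
    initializer: str = "poly-sq-ini",
    grid: QuadratureGrid | None = None,
    settings: CalibrationSettings = CalibrationSettings(),
    D: float = DEFAULT_D,
) -> pd.DataFrame:
    """Leave-one-out calibration check on a complete score matrix.

    The examinees are split into a training part, whose full-matrix GRM
    fit is frozen as "truth", and a testing part.  Each item in turn
    plays the new item: abilities of the testing examinees are estimated
    from the remaining items at their frozen parameters, the held-out
    item is calibrated with the configured method, and the per-parameter
    RMSE of the held-out estimates against the frozen truth is reported.
    """
    scores = np.asarray(matrix, int) if not isinstance(matrix, pd.DataFrame) \
        else matrix.to_numpy(int)
    N, J = scores.shape
    if J < 2 or N < 50:
        raise ValueError("need at least 2 items and 50 examinees")
    if np.any(scores < 0):
        raise ValueError("matrix must be complete (non-negative scores)")
    grid = grid or make_grid()
    perm = rng.permutation(N)
    train, test = perm[:train_n], perm[train_n:]
    if len(test) < settings.min_sample:
        raise ValueError("testing part too small")

    truth = fit_grm_matrix(scores[train], f_per_item, grid, settings, D)
    cal = calibrate_oem if method == "oem" else calibrate_mem

    rows = []
    err_a, err_b = [], []
    for j in range(J):
        others = [k for k in range(J) if k != j]
        packed = PackedItems.from_items([truth[k] for k in others])
        logp = packed.log_category_probs(grid.points)
        ll = np.zeros((len(test), len(grid)))
        for pos, k in enumerate(others):
            ll += logp[pos, scores[test, k], :]
        w = np.exp(ll - ll.max(axis=1, keepdims=True)) * grid.weights
        theta_hat = (w @ grid.points) / w.sum(axis=1)
        f = int(f_per_item[j])
        sc = scores[test, j]
        groups = ScoreGroupedAbilities.from_responses(theta_hat, sc, f)
        rates = CategoryPassRates.from_responses(theta_hat, sc, f)
        init = initial_params(initializer, groups, rates)
        ev = CalibrationEvidence(sc, ll, f)
        res = cal(ev, grid, init, settings, item_id=truth[j].item_id, D=D)
        rows.append({"item": truth[j].item_id,
                     "a_true": truth[j].a, "a_hat": res.a,
                     **{f"b{t + 1}_true": truth[j].b[t] for t in range(f)},
                     **{f"b{t + 1}_hat": res.b[t] for t in range(f)}})
        err_a.append(res.a - truth[j].a)
        err_b.append(np.asarray(res.b) - np.asarray(truth[j].b))
    df = pd.DataFrame(rows)
    df.attrs["rmse_a"] = float(np.sqrt(np.mean(np.square(err_a))))
    fmax = max(int(x) for x in f_per_item)
    for t in range(fmax):
        errs = [e[t] for e, f in zip(err_b, f_per_item) if t < int(f)]
        df.attrs[f"rmse_b{t + 1}"] = float(np.sqrt(np.mean(np.square(errs))))
    return df
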