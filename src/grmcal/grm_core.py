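"""Core graded response model (GRM) primitives.

The GRM describes ordered polytomous item responses through category
boundary response functions (CBRFs).  For an item with ``f`` boundary
parameters ``b_1 < b_2 < ... < b_f`` and slope ``a``, the probability of
scoring at or above category ``t`` for an examinee with latent trait
``theta`` is the two-parameter logistic curve

    P*_t(theta) = 1 / (1 + exp(-D * a * (theta - b_t))),   t = 1..f,

with the conventions ``P*_0 = 1`` and ``P*_{f+1} = 0``.  The probability
of scoring exactly ``t`` is the difference of adjacent CBRFs,
``p_t = P*_t - P*_{t+1}``, so observable scores are integers ``0..f``.
An item with ``f = 1`` is exactly a two-parameter logistic (2PL)
dichotomous item.

This module also provides the random generators used by the simulation
studies: operational/new item pools with lognormal slopes and sorted
normal boundaries (both truncated by rejection sampling), and truncated
standard-normal ability samples.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GRMItem",
    "ItemPool",
    "AbilitySample",
    "boundary_prob",
    "category_probs",
    "fisher_information",
    "sample_response",
    "generate_item_pool",
    "generate_abilities",
    "truncated_draws",
]

#: default logistic scaling constant; 1.7 puts the logistic curves on the
#: normal-ogive metric, the metric the polyserial initializer is derived in
DEFAULT_D = 1.7

#: truncation intervals of the simulation studies
A_BOUNDS = (0.2, 2.5)
B_BOUNDS = (-3.0, 3.0)
THETA_BOUNDS = (-3.0, 3.0)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GRMItem:
    """A graded response model item.

    Parameters
    ----------
    item_id
        Opaque identifier, unique within a pool.
    a
        Slope (discrimination) on the logit metric; must be positive.
    b
        Strictly increasing vector of ``f`` boundary difficulties.
    D
        Logistic scaling constant (1.0 by default, 1.7 approximates the
        normal ogive metric).
    """

    item_id: str
    a: float
    b: tuple[float, ...]
    D: float = DEFAULT_D

    def __post_init__(self) -> None:
        b = tuple(float(x) for x in self.b)
        object.__setattr__(self, "b", b)
        if not np.isfinite(self.a) or self.a <= 0:
            raise ValueError(f"slope must be positive and finite, got {self.a}")
        if self.D <= 0:
            raise ValueError(f"scaling constant must be positive, got {self.D}")
        if len(b) < 1:
            raise ValueError("an item needs at least one boundary")
        if not all(np.isfinite(b)):
            raise ValueError(f"boundaries must be finite, got {b}")
        if any(b[i] >= b[i + 1] for i in range(len(b) - 1)):
            raise ValueError(f"boundaries must be strictly increasing, got {b}")

    @property
    def f(self) -> int:
        """Number of boundaries; observable scores are ``0..f``."""
        return len(self.b)


@dataclass
class ItemPool:
    """An ordered collection of items with operational/new role flags."""

    items: list[GRMItem]
    roles: list[str]  # "operational" | "new"

    def __post_init__(self) -> None:
        if len(self.items) != len(self.roles):
            raise ValueError("items and roles must have equal length")
        ids = [it.item_id for it in self.items]
        if len(set(ids)) != len(ids):
            raise ValueError("item_ids must be unique")
        bad = set(self.roles) - {"operational", "new"}
        if bad:
            raise ValueError(f"unknown roles: {bad}")
        # a pool used for administration needs operational items; a pure
        # batch of pretest items is a legitimate container too
        if "new" not in self.roles and "operational" not in self.roles:
            raise ValueError("pool needs at least one item")
        self._index = {iid: k for k, iid in enumerate(ids)}

    def __len__(self) -> int:
        return len(self.items)

    def __getitem__(self, item_id: str) -> GRMItem:
        return self.items[self._index[item_id]]

    @property
    def item_ids(self) -> list[str]:
        return [it.item_id for it in self.items]

    def subset(self, role: str) -> list[GRMItem]:
        return [it for it, r in zip(self.items, self.roles) if r == role]

    @property
    def operational_items(self) -> list[GRMItem]:
        return self.subset("operational")

    @property
    def new_items(self) -> list[GRMItem]:
        return self.subset("new")

    # -- delimited-text round trip ------------------------------------------

    def to_csv(self, path_or_buf) -> None:
        """Write the pool as CSV with 15 significant digits."""
        fmax = max(it.f for it in self.items)
        rows = []
        for it, role in zip(self.items, self.roles):
            row = {"item_id": it.item_id, "role": role, "f": it.f,
                   "a": it.a, "D": it.D}
            for t in range(fmax):
                row[f"b{t + 1}"] = it.b[t] if t < it.f else ""
            rows.append(row)
        pd.DataFrame(rows).to_csv(path_or_buf, index=False,
                                  float_format="%.15g")

    @classmethod
    def from_csv(cls, path_or_buf) -> "ItemPool":
        df = pd.read_csv(path_or_buf, dtype={"item_id": str})
        bcols = sorted((c for c in df.columns if c.startswith("b")),
                       key=lambda c: int(c[1:]))
        items, roles = [], []
        for _, row in df.iterrows():
            f = int(row["f"])
            b = tuple(float(row[bcols[t]]) for t in range(f))
            D = float(row["D"]) if "D" in df.columns else DEFAULT_D
            items.append(GRMItem(str(row["item_id"]), float(row["a"]), b, D))
            roles.append(str(row["role"]))
        return cls(items, roles)


@dataclass(frozen=True)
class AbilitySample:
    """Latent trait values drawn from a truncated standard normal."""

    thetas: np.ndarray
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "thetas", np.asarray(self.thetas, float))


# ---------------------------------------------------------------------------
# probabilities and information
# ---------------------------------------------------------------------------


def _sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def boundary_probs_all(item: GRMItem, theta) -> np.ndarray:
    """All CBRFs P*_0..P*_{f+1} at ``theta`` (scalar or array).

    Output shape is ``theta.shape + (f + 2,)`` with the constant first
    and last entries 1 and 0.
    """
    theta = np.asarray(theta, float)
    b = np.asarray(item.b)
    z = item.D * item.a * (theta[..., None] - b)
    core = _sigmoid(z)
    one = np.ones(theta.shape + (1,))
    zero = np.zeros(theta.shape + (1,))
    return np.concatenate([one, core, zero], axis=-1)


def boundary_prob(item: GRMItem, theta: float, t: int) -> float:
    """CBRF value P*_t(theta); P*_0 = 1 and P*_{f+1} = 0 by convention."""
    if not 0 <= t <= item.f + 1:
        raise IndexError(f"boundary index {t} outside 0..{item.f + 1}")
    if t == 0:
        return 1.0
    if t == item.f + 1:
        return 0.0
    return float(_sigmoid(item.D * item.a * (theta - item.b[t - 1])))


def category_probs(item: GRMItem, theta) -> np.ndarray:
    """Probabilities of scores 0..f, as adjacent CBRF differences."""
    ps = boundary_probs_all(item, theta)
    return ps[..., :-1] - ps[..., 1:]


def fisher_information(item: GRMItem, theta, literal: bool = False):
    """Fisher information of a GRM item at ``theta``.

    The default is the standard GRM information
    ``D^2 a^2 sum_{t=0..f} p_t (1 - P*_t - P*_{t+1})^2``, which is
    algebraically identical to Samejima's form
    ``sum_t (P*'_t - P*'_{t+1})^2 / p_t``.  With ``literal=True`` the
    sum runs over ``t = 1..f`` only and the ``D^2`` factor is dropped
    (an audit variant; not used by the selection engine).
    """
    ps = boundary_probs_all(item, theta)
    p = ps[..., :-1] - ps[..., 1:]
    w = (1.0 - ps[..., :-1] - ps[..., 1:]) ** 2
    terms = p * w
    if literal:
        return item.a**2 * np.sum(terms[..., 1:], axis=-1)
    return (item.D * item.a) ** 2 * np.sum(terms, axis=-1)


def sample_response(item: GRMItem, theta: float, rng: np.random.Generator) -> int:
    """Draw one score 0..f by inverse CDF; consumes exactly one uniform."""
    p = category_probs(item, float(theta))
    u = rng.random()
    return int(np.searchsorted(np.cumsum(p)[:-1], u, side="left"))


# ---------------------------------------------------------------------------
# random generation
# ---------------------------------------------------------------------------


def truncated_draws(draw, lo: float, hi: float, size: int,
                    max_iter: int = 1000) -> np.ndarray:
    """Rejection-sample ``size`` values from ``draw(n)`` inside [lo, hi].

    Rejection (redraw until inside), not clipping, so the stated
    distribution is preserved on the interval.
    """
    if lo >= hi:
        raise ValueError(f"empty truncation interval [{lo}, {hi}]")
    out = np.empty(size)
    filled = 0
    for _ in range(max_iter):
        need = size - filled
        cand = np.asarray(draw(max(2 * need, 16)))
        cand = cand[(cand >= lo) & (cand <= hi)][:need]
        out[filled:filled + cand.size] = cand
        filled += cand.size
        if filled == size:
            return out
    raise RuntimeError("rejection sampling did not converge; check bounds")


def generate_item_pool(
    n_items: int,
    f_values: int | Sequence[int],
    rng: np.random.Generator,
    *,
    a_bounds: tuple[float, float] = A_BOUNDS,
    b_bounds: tuple[float, float] = B_BOUNDS,
    D: float = DEFAULT_D,
    role: str = "operational",
    id_prefix: str = "item",
) -> ItemPool:
    """Generate a random GRM item pool.

    Slopes are lognormal(0, 1) truncated to ``a_bounds``; each boundary is
    an independent standard normal truncated to ``b_bounds``, then sorted
    ascending to satisfy the GRM monotonicity constraint.  ``f_values``
    is either a fixed boundary count or a sequence sampled uniformly per
    item (the operational pools of the studies mix 2-5).
    """
    if n_items < 1:
        raise ValueError("n_items must be >= 1")
    if isinstance(f_values, (int, np.integer)):
        fs = np.full(n_items, int(f_values))
    else:
        fs = rng.choice(np.asarray(list(f_values), int), size=n_items)
    a = truncated_draws(lambda n: rng.lognormal(0.0, 1.0, n),
                        a_bounds[0], a_bounds[1], n_items)
    items = []
    width = len(str(n_items))
    for j in range(n_items):
        f = int(fs[j])
        while True:
            b = np.sort(truncated_draws(lambda n: rng.normal(0.0, 1.0, n),
                                        b_bounds[0], b_bounds[1], f))
            if f == 1 or np.all(np.diff(b) > 0):  # ties have probability 0
                break
        items.append(GRMItem(f"{id_prefix}{j + 1:0{width}d}", float(a[j]),
                             tuple(b), D))
    return ItemPool(items, [role] * n_items)


def generate_abilities(
    n: int,
    rng: np.random.Generator,
    *,
    bounds: tuple[float, float] = THETA_BOUNDS,
) -> AbilitySample:
    """Draw ``n`` abilities from N(0, 1) truncated to ``bounds``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    thetas = truncated_draws(lambda m: rng.normal(0.0, 1.0, m),
                             bounds[0], bounds[1], n)
    return AbilitySample(thetas)


# ---------------------------------------------------------------------------
# packed (vectorized) pool views used by the simulation engine
# ---------------------------------------------------------------------------


@dataclass
class PackedItems:
    """Column-packed item parameters for vectorized evaluation.

    Boundary rows are padded with +inf so that padded CBRFs are exactly 0
    and padded categories carry zero probability; all vectorized formulas
    below then hold without masking.
    """

    a: np.ndarray          # (J,)
    b: np.ndarray          # (J, fmax) padded with +inf
    f: np.ndarray          # (J,) int
    D: float
    item_ids: list[str] = field(default_factory=list)

    @classmethod
    def from_items(cls, items: Sequence[GRMItem]) -> "PackedItems":
        if not items:
            raise ValueError("no items to pack")
        D = items[0].D
        if any(it.D != D for it in items):
            raise ValueError("packed items must share the scaling constant D")
        fmax = max(it.f for it in items)
        J = len(items)
        b = np.full((J, fmax), np.inf)
        f = np.empty(J, int)
        a = np.empty(J)
        for j, it in enumerate(items):
            a[j] = it.a
            f[j] = it.f
            b[j, :it.f] = it.b
        return cls(a, b, f, D, [it.item_id for it in items])

    @property
    def fmax(self) -> int:
        return self.b.shape[1]

    def category_probs(self, theta: np.ndarray, idx=None) -> np.ndarray:
        """Score probabilities, shape (..., fmax+1); padded categories 0.

        ``theta`` broadcasts against the selected items: with ``idx`` of
        shape (n,) and ``theta`` of shape (n,) or (n, K) the output is
        (n, fmax+1) or (n, K, fmax+1).
        """
        a = self.a if idx is None else self.a[idx]
        b = self.b if idx is None else self.b[idx]
        theta = np.asarray(theta, float)
        extra = theta.ndim - a.ndim  # trailing theta axes beyond one-per-item
        bb = b.reshape(b.shape[:-1] + (1,) * extra + (b.shape[-1],))
        aa = a.reshape(a.shape + (1,) * (extra + 1))
        z = self.D * aa * (theta[..., None] - bb)
        # sigmoid(-inf) = 0 without warnings via tanh
        core = 0.5 * (1.0 + np.tanh(0.5 * z))
        ps = np.concatenate(
            [np.ones(core.shape[:-1] + (1,)), core,
             np.zeros(core.shape[:-1] + (1,))], axis=-1)
        return ps[..., :-1] - ps[..., 1:]

    def information(self, theta: np.ndarray) -> np.ndarray:
        """Fisher information of every item at every theta: (T, J)."""
        theta = np.asarray(theta, float)
        z = self.D * self.a[None, :, None] * (theta[:, None, None] - self.b)
        ps = 0.5 * (1.0 + np.tanh(0.5 * z))           # (T, J, fmax)
        full = np.concatenate(
            [np.ones(ps.shape[:-1] + (1,)), ps,
             np.zeros(ps.shape[:-1] + (1,))], axis=-1)
        p = full[..., :-1] - full[..., 1:]
        w = (1.0 - full[..., :-1] - full[..., 1:]) ** 2
        return (self.D * self.a[None, :]) ** 2 * np.sum(p * w, axis=-1)

    def log_category_probs(self, grid_points: np.ndarray) -> np.ndarray:
        """log p_t(X_k) for all items: (J, fmax+1, K); padded rows -inf."""
        K = len(grid_points)
        p = self.category_probs(
            np.broadcast_to(grid_points, (len(self.a), K)))  # (J, K, fmax+1)
        with np.errstate(divide="ignore"):
            lp = np.log(np.maximum(p, 1e-300))
            lp[p <= 0] = -np.inf
        return np.swapaxes(lp, 1, 2)
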