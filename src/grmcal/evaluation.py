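"""Parameter-recovery metrics over replicated calibrations.

RMSE and bias pool estimation errors over replications r = 1..R and new
items j = 1..M:

    RMSE_x = sqrt( sum_r sum_j (xhat_j^(r) - x_j^(r))^2 / (R M) )
    bias_x =       sum_r sum_j (xhat_j^(r) - x_j^(r))    / (R M)

and the mean(b) aggregates additionally pool over the f boundaries of
each item (the studies hold f fixed within a condition, so the pooling
is rectangular).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["rmse", "bias", "mean_b_metrics", "RecoveryTable"]


def _check(estimates, truths):
    est = np.asarray(estimates, float)
    tru = np.asarray(truths, float)
    if est.shape != tru.shape:
        raise ValueError(f"shape mismatch: {est.shape} vs {tru.shape}")
    return est, tru


def rmse(estimates, truths, squared: bool = False) -> float:
    """Root mean squared error pooled over all cells.

    ``squared=True`` returns the mean squared error without the radical
    (audit variant)."""
    est, tru = _check(estimates, truths)
    ms = float(np.mean((est - tru) ** 2))
    return ms if squared else float(np.sqrt(ms))


def bias(estimates, truths) -> float:
    """Signed mean error pooled over all cells."""
    est, tru = _check(estimates, truths)
    return float(np.mean(est - tru))


def mean_b_metrics(estimates, truths, squared: bool = False):
    """(RMSE, bias) of the boundary parameters pooled over replications,
    items and the f categories.  Requires a rectangular (R, M, f) array,
    i.e. a fixed boundary count within the condition."""
    est, tru = _check(estimates, truths)
    if est.ndim != 3:
        raise ValueError("expected an (R, M, f) array; ragged boundary "
                         "counts cannot be pooled")
    return rmse(est, tru, squared), bias(est, tru)


@dataclass
class RecoveryTable:
    """Per-condition recovery summary mirroring the study tables."""

    rows: list[dict] = field(default_factory=list)

    def add_condition(self, label: dict, est_a, tru_a, est_b, tru_b) -> dict:
        """Append one condition; ``est_b``/``tru_b`` are (R, M, f)."""
        est_b = np.asarray(est_b, float)
        f = est_b.shape[2]
        row = dict(label)
        row["rmse_a"] = rmse(est_a, tru_a)
        row["bias_a"] = bias(est_a, tru_a)
        for t in range(f):
            row[f"rmse_b{t + 1}"] = rmse(est_b[:, :, t], tru_b[:, :, t])
            row[f"bias_b{t + 1}"] = bias(est_b[:, :, t], tru_b[:, :, t])
        row["rmse_mean_b"], row["bias_mean_b"] = mean_b_metrics(est_b, tru_b)
        self.rows.append(row)
        return row

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def to_csv(self, path_or_buf) -> None:
        self.to_frame().to_csv(path_or_buf, index=False, float_format="%.6g")
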