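"""Quantile loss and goodness-of-fit metrics.

The pinball (check) loss is the asymmetric absolute loss whose minimizing
constant is the tau-quantile; averaging it over observations gives the
average quantile loss (AQL) used out-of-bag as the model-selection
criterion.  R1 is one minus the ratio of a conditional quantile model's
total check loss to the total check loss of the unconditional
(intercept-only) quantile model — the tau-generalization of the
absolute-deviation fit ratio, which at tau = 0.5 reduces to the classic
median-regression fit measure.
"""

from __future__ import annotations

import numpy as np

#: quantile grid reported in effect tables
TAU_GRID: tuple[float, ...] = (0.1, 0.25, 0.5, 0.75, 0.9)
#: quantile level used for high-cost model selection
TAU_SELECTION: float = 0.9


def _check_tau(tau: float) -> None:
    if not 0.0 < tau < 1.0:
        raise ValueError(f"tau must be in (0, 1), got {tau}")


def pinball_loss(y, q, tau: float):
    """Check loss tau*(y-q) if y >= q else (1-tau)*(q-y); elementwise on arrays."""
    _check_tau(tau)
    y = np.asarray(y, dtype=float)
    q = np.asarray(q, dtype=float)
    u = y - q
    return np.where(u >= 0, tau * u, (tau - 1.0) * u)


def average_quantile_loss(y, q, tau: float) -> float:
    """Mean pinball loss over observations (AQL)."""
    y = np.asarray(y, dtype=float)
    q = np.asarray(q, dtype=float)
    if y.shape != q.shape:
        raise ValueError(f"length mismatch: y has shape {y.shape}, q has {q.shape}")
    if y.size == 0:
        raise ValueError("empty input")
    return float(np.mean(pinball_loss(y, q, tau)))


def sample_quantile_inf(y, tau: float) -> float:
    """Left-continuous (inf-ECDF) sample quantile: smallest y with ECDF >= tau."""
    _check_tau(tau)
    ys = np.sort(np.asarray(y, dtype=float))
    if ys.size == 0:
        raise ValueError("empty input")
    idx = int(np.ceil(tau * ys.size)) - 1
    return float(ys[max(idx, 0)])


def r1_goodness_of_fit(y, q_model, tau: float) -> float:
    """1 - (total check loss of the model) / (total check loss of the null quantile).

    The null predictor is the unconditional in-sample tau-quantile of ``y``
    (inf-ECDF convention).  Bounded above by 1; equals 1 only at zero total
    model loss.  Undefined when all responses are identical.
    """
    y = np.asarray(y, dtype=float)
    q_model = np.asarray(q_model, dtype=float)
    if y.shape != q_model.shape:
        raise ValueError("length mismatch between y and q_model")
    if y.size < 2:
        raise ValueError("need at least two observations")
    q_null = sample_quantile_inf(y, tau)
    null_loss = float(np.sum(pinball_loss(y, np.full_like(y, q_null), tau)))
    if null_loss == 0.0:
        raise ValueError("null quantile loss is zero (all responses equal); R1 undefined")
    model_loss = float(np.sum(pinball_loss(y, q_model, tau)))
    return 1.0 - model_loss / null_loss
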