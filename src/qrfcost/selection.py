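"""Backward stepwise covariate selection by out-of-bag average quantile loss.

Starting from the full covariate set, each step fits a quantile
regression forest, records its OOB average quantile loss (AQL) at the
selection level (default: the 90th percentile, the conventional
high-cost threshold), and removes the covariate with the smallest
permutation importance, until a single covariate remains.  The optimal
model is the recorded AQL minimum (ties favor the smaller model).
Relative importance of the selected covariates is the share of the
null-to-optimal AQL reduction each contributes when added in reverse
removal order; the shares telescope to exactly 1.

Importance is recomputed on each step's fresh fit (guarding against
masking effects among correlated covariates), and every step draws its
forest and permutation seeds from one splittable stream, so a trace is
reproducible from a single seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace, asdict

import numpy as np
import pandas as pd

from . import schema
from .forest import ForestParams, fit_forest, oob_quantile_predictions, permutation_importance
from .metrics import TAU_SELECTION, average_quantile_loss, sample_quantile_inf

__all__ = [
    "SelectionStep",
    "SelectionTrace",
    "backward_stepwise",
    "select_optimal",
    "relative_importance",
    "trace_to_frame",
]


@dataclass(frozen=True)
class SelectionStep:
    step_index: int
    variables_remaining: tuple[str, ...]
    removed_variable: str  # variable dropped after this step's fit
    oob_aql: float
    forest_seed: int


@dataclass
class SelectionTrace:
    steps: list[SelectionStep]
    null_aql: float
    tau: float
    importance_mode: str
    optimal_set: tuple[str, ...] = field(default=())

    def to_json(self, path=None) -> str:
        doc = {
            "tau": self.tau,
            "importance_mode": self.importance_mode,
            "null_aql": self.null_aql,
            "optimal_set": list(self.optimal_set),
            "steps": [asdict(s) for s in self.steps],
        }
        text = json.dumps(doc, indent=2, default=list)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text


def backward_stepwise(
    table: pd.DataFrame,
    tau: float = TAU_SELECTION,
    forest_params: ForestParams | None = None,
    importance_mode: str = "pinball",
    covariates: list[str] | None = None,
    response: str = schema.RESPONSE,
    seed_policy: str = "common",
    importance_repeats: int = 1,
) -> SelectionTrace:
    """Run the backward elimination loop and return the complete trace.

    The trace records one step per model from p covariates down to 1,
    plus the null (intercept-only) AQL computed with the unconditional
    tau-quantile as constant predictor — p + 1 AQL values in total.

    ``seed_policy="common"`` (default) reuses one forest seed for every
    step, so all steps share bootstrap draws and hence out-of-bag
    membership: the dominant resampling noise cancels when models are
    compared, which matters because the weakest informative covariates
    move the OOB AQL by far less than independent refit noise would.
    ``"fresh"`` draws an independent forest seed per step.
    """
    if seed_policy not in ("common", "fresh"):
        raise ValueError(f"seed_policy must be 'common' or 'fresh', got {seed_policy!r}")
    if forest_params is None:
        forest_params = ForestParams()
    if covariates is None:
        covariates = [c for c in schema.COVARIATES if c in table.columns]
        covariates += [
            c for c in table.columns if c not in covariates and c != response
        ]
    if not covariates:
        raise ValueError("empty covariate set")
    declaration_order = {c: k for k, c in enumerate(covariates)}
    y = pd.to_numeric(table[response]).to_numpy(dtype=float)
    q_null = sample_quantile_inf(y, tau)
    null_aql = average_quantile_loss(y, np.full_like(y, q_null), tau)

    p = len(covariates)
    step_seeds = np.random.SeedSequence(forest_params.seed).spawn(p + 1)
    common_seed = int(step_seeds[p].generate_state(1)[0] % 2**31)
    current = list(covariates)
    steps: list[SelectionStep] = []
    for k in range(p):
        forest_ss, perm_ss = step_seeds[k].spawn(2)
        if seed_policy == "common":
            forest_seed = common_seed
        else:
            forest_seed = int(forest_ss.generate_state(1)[0] % 2**31)
        perm_seed = int(perm_ss.generate_state(1)[0] % 2**31)
        fp = replace(forest_params, seed=forest_seed)
        forest = fit_forest(table, fp, covariates=current, response=response)
        pred, mask = oob_quantile_predictions(forest, tau)
        if not mask.any():
            raise RuntimeError(f"step {k}: no out-of-bag predictions available")
        aql = average_quantile_loss(y[mask], pred[mask], tau)
        if not np.isfinite(aql):
            raise RuntimeError(
                f"step {k} (variables {current}): non-finite OOB AQL {aql}"
            )
        if len(current) > 1:
            imp = permutation_importance(
                forest, mode=importance_mode, tau=tau, seed=perm_seed,
                n_repeats=importance_repeats,
            )
            # least important; ties broken by declaration order
            removed = min(current, key=lambda c: (imp[c], declaration_order[c]))
        else:
            removed = current[0]
        steps.append(
            SelectionStep(
                step_index=k,
                variables_remaining=tuple(current),
                removed_variable=removed,
                oob_aql=float(aql),
                forest_seed=forest_seed,
            )
        )
        current = [c for c in current if c != removed]

    trace = SelectionTrace(
        steps=steps,
        null_aql=float(null_aql),
        tau=tau,
        importance_mode=importance_mode,
    )
    trace.optimal_set = select_optimal(trace)
    return trace


def select_optimal(trace: SelectionTrace) -> tuple[str, ...]:
    """Covariate set at the smallest recorded model AQL; ties favor the
    smaller model."""
    best = None
    for step in trace.steps:
        if best is None or step.oob_aql <= best.oob_aql:
            best = step
    return tuple(best.variables_remaining)


def relative_importance(trace: SelectionTrace) -> pd.DataFrame:
    """AQL-reduction shares over the optimal set.

    Ordering the optimal set by reverse removal order (the survivor of
    the 1-variable model counts as added first, over the null), the k-th
    added variable's delta is AQL(k-1 variables) - AQL(k variables);
    its share is delta over the total null-to-optimal reduction, so the
    shares telescope to exactly 1.
    """
    optimal = trace.optimal_set or select_optimal(trace)
    m = len(optimal)
    if m == 0:
        raise ValueError("optimal set is empty")
    by_size = {len(s.variables_remaining): s for s in trace.steps}
    optimal_aql = by_size[m].oob_aql
    total = trace.null_aql - optimal_aql
    if total <= 0:
        raise ValueError(
            f"null AQL ({trace.null_aql}) does not exceed the optimal model AQL "
            f"({optimal_aql}); relative-importance shares are undefined"
        )
    rows = []
    for k in range(1, m + 1):
        step = by_size[k]
        added = step.removed_variable  # the variable distinguishing size k from k-1
        prev_aql = trace.null_aql if k == 1 else by_size[k - 1].oob_aql
        delta = prev_aql - step.oob_aql
        rows.append({"variable": added, "delta_aql": delta, "share": delta / total})
    return pd.DataFrame(rows)


def trace_to_frame(trace: SelectionTrace) -> pd.DataFrame:
    """Two-column elbow-plot series: model label and OOB AQL, null first."""
    rows = [{"model": "null", "n_variables": 0, "oob_aql": trace.null_aql}]
    for step in sorted(trace.steps, key=lambda s: len(s.variables_remaining)):
        k = len(step.variables_remaining)
        rows.append({"model": f"k={k}", "n_variables": k, "oob_aql": step.oob_aql})
    return pd.DataFrame(rows)
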