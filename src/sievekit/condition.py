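"""Condition index and the between-year allometry contrast.

The condition index is the residual of an individual's log weight from
the pooled log(weight) ~ log(length) ordinary least squares fit: positive
means heavier than expected for its length. Year differences in the
length-weight relationship are tested with the interaction model

    log W = a + b log L + c * year2 + d * year2 * log L

where ``c < 0`` together with ``d > 0`` is the anomalous-year pattern
(smaller fish lighter, larger fish unaffected). Natural logarithms
throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm


@dataclass
class ConditionResult:
    index: np.ndarray | None = None  # per-individual residual, log-g scale
    pooled_fit: dict | None = None  # intercept a, slope b, resid sd
    interaction_fit: pd.DataFrame | None = None  # term, estimate, se, t, p
    year_levels: tuple | None = None


def _validate_positive(lengths, weights):
    lengths = np.asarray(lengths, dtype=float)
    weights = np.asarray(weights, dtype=float)
    bad = np.where(~((lengths > 0) & (weights > 0)))[0]
    if bad.size:
        raise ValueError(
            f"non-positive length/weight at indices {bad[:10].tolist()}"
        )
    return lengths, weights


def condition_index(lengths, weights) -> ConditionResult:
    """Pooled OLS of log weight on log length; index = residuals."""
    lengths, weights = _validate_positive(lengths, weights)
    if len(lengths) < 3:
        raise ValueError("need at least 3 individuals")
    x = np.log(lengths)
    y = np.log(weights)
    design = sm.add_constant(x)
    fit = sm.OLS(y, design).fit()
    resid = y - fit.fittedvalues
    return ConditionResult(
        index=resid,
        pooled_fit={
            "a": float(fit.params[0]),
            "b": float(fit.params[1]),
            "resid_sd": float(np.sqrt(fit.scale)),
            "n": int(len(y)),
        },
    )


def year_allometry_test(lengths, weights, years) -> ConditionResult:
    """Interaction OLS contrasting the two years' allometric lines.

    ``year2`` indicates the later calendar year. Reports estimates and
    t-test p-values for the year main effect (c) and the year x log-length
    interaction (d), alongside the pooled condition index.
    """
    lengths, weights = _validate_positive(lengths, weights)
    years = np.asarray(list(years))
    levels = tuple(sorted(pd.unique(years)))
    if len(levels) != 2:
        raise ValueError(f"exactly two year groups required, got {levels}")
    for lev in levels:
        if (years == lev).sum() < 3:
            raise ValueError(f"year {lev} has fewer than 3 fish")
    pooled = condition_index(lengths, weights)
    x = np.log(lengths)
    y = np.log(weights)
    y2 = (years == levels[1]).astype(float)
    design = np.column_stack([np.ones_like(x), x, y2, y2 * x])
    fit = sm.OLS(y, design).fit()
    terms = ["intercept", "log_length", "year2", "year2:log_length"]
    table = pd.DataFrame(
        {
            "term": terms,
            "estimate": fit.params,
            "se": fit.bse,
            "t": fit.tvalues,
            "p": fit.pvalues,
        }
    )
    pooled.interaction_fit = table
    pooled.year_levels = levels
    return pooled


def condition_table(result: ConditionResult, meta: pd.DataFrame | None = None):
    """Per-individual condition index frame (optionally with ids/years)."""
    out = pd.DataFrame({"condition_index": result.index})
    if meta is not None:
        out.insert(0, "individual_id", meta["individual_id"].to_numpy())
        out.insert(1, "year", meta["year"].to_numpy())
    return out
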