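"""Method-comparison protocol for per-residue confidence predictions.

Two confidence methods are compared on a shared target set through:
per-target mean absolute LDDT errors; win/tie/loss counts with a 0.5-LDDT
tie margin, optionally restricted to targets where either method errs
substantially (mean error above 5.0); 4x4 row-normalized confusion matrices
over the standard confidence categories; a chi-squared test on the
correct-category counts; and per-target error deltas for ablation variants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .lddt import CATEGORIES, lddt_category

TIE_MARGIN = 0.5
SUBSTANTIAL_ERROR = 5.0


@dataclass(frozen=True)
class ComparisonSummary:
    """Win/tie/loss between methods A and B on per-target errors."""

    wins_a: int
    ties: int
    wins_b: int
    n_compared: int
    n_total: int
    tie_margin: float
    substantial: float | None

    @property
    def fractions(self) -> tuple[float, float, float]:
        n = max(self.n_compared, 1)
        return (self.wins_a / n, self.ties / n, self.wins_b / n)


def compare_methods(
    err_a: dict[str, float],
    err_b: dict[str, float],
    tie_margin: float = TIE_MARGIN,
    substantial: float | None = SUBSTANTIAL_ERROR,
) -> ComparisonSummary:
    """Count targets where A or B has the smaller error, with a tie band.

    A target is a tie when |err_a - err_b| < tie_margin; otherwise the
    smaller error wins.  With ``substantial`` set, only targets where
    max(err_a, err_b) > substantial are counted (pass ``None`` to disable).
    """
    if set(err_a) != set(err_b):
        extra = sorted(set(err_a) ^ set(err_b))
        raise ValueError(f"mismatched target sets: {extra}")
    wins_a = ties = wins_b = n = 0
    for t in err_a:
        a, b = err_a[t], err_b[t]
        if substantial is not None and max(a, b) <= substantial:
            continue
        n += 1
        if abs(a - b) < tie_margin:
            ties += 1
        elif a < b:
            wins_a += 1
        else:
            wins_b += 1
    return ComparisonSummary(wins_a, ties, wins_b, n, len(err_a), tie_margin, substantial)


def confusion_matrix(true_lddt, pred_lddt) -> pd.DataFrame:
    """Row-normalized 4x4 category confusion matrix (rows = true category).

    Rows with no residues in the true category are absent from the result,
    not zero-filled.
    """
    true_lddt = np.asarray(true_lddt, dtype=float)
    pred_lddt = np.asarray(pred_lddt, dtype=float)
    if true_lddt.size == 0 or true_lddt.shape != pred_lddt.shape:
        raise ValueError("need equal-length, non-empty true/pred values")
    counts = pd.DataFrame(0.0, index=CATEGORIES, columns=CATEGORIES)
    for t, p in zip(true_lddt, pred_lddt):
        counts.loc[lddt_category(t), lddt_category(p)] += 1
    support = counts.sum(axis=1)
    out = counts.loc[support > 0].div(support[support > 0], axis=0)
    return out


def category_chi2(
    correct_a: int, total_a: int, correct_b: int, total_b: int
) -> tuple[float, float]:
    """Pearson chi-squared (1 dof, no continuity correction) on a 2x2 table.

    The table is {correct, incorrect} x {method A, method B}; returns
    (statistic, p-value).  Degenerate margins (an expected cell of zero)
    are rejected.
    """
    if total_a <= 0 or total_b <= 0 or correct_a > total_a or correct_b > total_b:
        raise ValueError("invalid counts")
    obs = np.array(
        [[correct_a, correct_b], [total_a - correct_a, total_b - correct_b]], float
    )
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    expected = row * col / obs.sum()
    if (expected == 0).any():
        raise ValueError("degenerate margin: expected cell count of zero")
    stat = float(((obs - expected) ** 2 / expected).sum())
    return stat, float(chi2.sf(stat, df=1))


def ablation_delta(
    full_errors: dict[str, float], variant_errors: dict[str, float]
) -> pd.Series:
    """Per-target (variant - full) error differences; positive = variant worse.

    The returned series carries 25/50/75% quantiles in ``.attrs['quantiles']``
    for box-plot style summaries.
    """
    if set(full_errors) != set(variant_errors):
        raise ValueError("mismatched target sets")
    keys = sorted(full_errors)
    s = pd.Series(
        [variant_errors[k] - full_errors[k] for k in keys], index=keys, name="delta"
    )
    s.attrs["quantiles"] = {
        q: float(s.quantile(q / 100)) for q in (25, 50, 75)
    }
    return s
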