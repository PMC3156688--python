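"""Filtering and X:autosome fold-difference statistics.

The central quantity is the A:X fold — how much higher the median expression
of autosomal probes is than that of X-linked probes in a given sample class.
Equal X and autosomal output (fold ~ 1) is the signature of chromosome-wide
dosage compensation; a fold near 1.5 matches the dose-buffered, uncompensated
state, and a fold of 2 the raw hemizygous dose deficit.

Folds are computed as ``2**(median(log2 A) - median(log2 X))`` — the medians
are taken on the log2 distributions, matching how array intensity
distributions are summarized; a linear-scale-median variant is available via
``linear_medians=True``.  The fourth (dot) chromosome is never part of the
autosome class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import (
    AUTOSOME_ARMS,
    ExpressionMatrix,
    InsufficientDataError,
    RpkmTable,
)

logger = logging.getLogger("xchrom")

__all__ = [
    "XaResult",
    "filter_low_expression",
    "xa_fold_difference",
    "xa_fold_rpkm",
    "quantile_sweep",
    "between_group_shift",
    "dcc_impairment_ratio",
]


@dataclass(frozen=True)
class XaResult:
    """An autosome-over-X fold statistic with its Mann-Whitney test.

    ``fold_a_over_x`` is the linear fold by which autosomal median expression
    exceeds the X median (values < 1 mean the X is higher).  ``p_mw`` is the
    two-sided Mann-Whitney p-value contrasting per-probe X values with
    autosomal values (arm 4 excluded).
    """

    fold_a_over_x: float
    p_mw: float
    n_x: int
    n_a: int
    threshold_used: float | None = None


def _mannwhitney_p(x: np.ndarray, a: np.ndarray) -> float:
    # exact for small samples without ties; normal approximation with tie
    # correction otherwise (scipy's automatic policy)
    return float(stats.mannwhitneyu(x, a, alternative="two-sided").pvalue)


def filter_low_expression(
    matrix: ExpressionMatrix, threshold: float, conditions
) -> ExpressionMatrix:
    """Drop probes whose signal sits in the low (noise) mode everywhere.

    A probe is removed iff its replicate-mean log2 value is below
    ``threshold`` in *every* listed condition; probes clearing the bar in any
    one condition are kept with all of their samples.
    """
    conditions = list(conditions)
    if not conditions:
        raise ValueError("at least one condition is required")
    below_everywhere = np.ones(len(matrix.values), dtype=bool)
    for condition in conditions:
        below_everywhere &= (matrix.condition_means(condition) < threshold).to_numpy()
    kept = matrix.values.index[~below_everywhere]
    logger.info(
        "low-expression filter (log2 < %g in all of %s): %d of %d probes kept",
        threshold,
        conditions,
        len(kept),
        len(matrix.values),
    )
    return matrix.subset_probes(kept)


def _split_x_a(values: pd.Series, arms: pd.Series):
    x = values[arms == "X"].to_numpy()
    a = values[arms.isin(AUTOSOME_ARMS)].to_numpy()
    return x, a


def xa_fold_difference(
    matrix: ExpressionMatrix,
    condition: str,
    threshold_used: float | None = None,
    linear_medians: bool = False,
) -> XaResult:
    """Autosome-over-X median fold for one sample condition.

    Per-probe values are replicate means of log2 intensities.  By default the
    fold is ``2**(median log2 A - median log2 X)``; with
    ``linear_medians=True`` it is the ratio of medians of linear intensities
    (the two coincide up to monotonicity of the median).
    """
    values = matrix.condition_means(condition)
    x, a = _split_x_a(values, matrix.arms)
    if len(x) < 2 or len(a) < 2:
        raise InsufficientDataError(
            f"need >=2 probes per class, got {len(x)} X and {len(a)} autosomal"
        )
    if linear_medians:
        fold = float(np.median(np.exp2(a)) / np.median(np.exp2(x)))
    else:
        fold = float(np.exp2(np.median(a) - np.median(x)))
    return XaResult(
        fold_a_over_x=fold,
        p_mw=_mannwhitney_p(x, a),
        n_x=len(x),
        n_a=len(a),
        threshold_used=threshold_used,
    )


def xa_fold_rpkm(table: RpkmTable, min_rpkm: float = 1.0) -> XaResult:
    """Autosome-over-X median fold from a gene-level RPKM table.

    Genes with RPKM <= ``min_rpkm`` are excluded before the medians; folds
    below 1 indicate higher X than autosomal expression (the ovary pattern).
    """
    frame = table.frame[table.frame["rpkm"] > min_rpkm]
    x = frame.loc[frame["arm"] == "X", "rpkm"].to_numpy()
    a = frame.loc[frame["arm"].isin(AUTOSOME_ARMS), "rpkm"].to_numpy()
    if len(x) < 2 or len(a) < 2:
        raise InsufficientDataError(
            f"after RPKM > {min_rpkm} filter: {len(x)} X and {len(a)} autosomal genes"
        )
    fold = float(np.median(a) / np.median(x))
    return XaResult(
        fold_a_over_x=fold,
        p_mw=_mannwhitney_p(x, a),
        n_x=len(x),
        n_a=len(a),
        threshold_used=min_rpkm,
    )


def quantile_sweep(
    matrix: ExpressionMatrix, condition: str, n_quantiles: int = 10
) -> pd.DataFrame:
    """X-vs-autosome statistics over successively higher expression cuts.

    The pooled distribution of per-probe values (X plus autosomes, arm 4
    excluded) is divided into ``n_quantiles`` quantiles.  For each cut the row
    reports, over probes expressed at or above the cut: the X and autosomal
    counts, the X proportion, a Fisher's exact p contrasting composition
    above versus below the cut, the difference of medians (A - X, log2), and
    a Mann-Whitney p.  Ties at a boundary land in the upper (at-or-above)
    side of the cut.
    """
    if n_quantiles < 2:
        raise ValueError("n_quantiles must be >= 2")
    values = matrix.condition_means(condition)
    arms = matrix.arms
    mask = (arms == "X") | arms.isin(AUTOSOME_ARMS)
    values = values[mask]
    is_x = (arms[mask] == "X").to_numpy()
    vals = values.to_numpy()
    n_x_total, n_a_total = int(is_x.sum()), int((~is_x).sum())

    rows = []
    for i in range(n_quantiles):
        q = i / n_quantiles
        cut = np.quantile(vals, q)
        above = vals >= cut
        nx = int((above & is_x).sum())
        na = int((above & ~is_x).sum())
        below_x, below_a = n_x_total - nx, n_a_total - na
        if below_x + below_a == 0:
            p_fet = 1.0
        else:
            p_fet = float(
                stats.fisher_exact([[nx, na], [below_x, below_a]]).pvalue
            )
        x_above = vals[above & is_x]
        a_above = vals[above & ~is_x]
        rows.append(
            {
                "cut": f">q{int(round(100 * q))}",
                "threshold": float(cut),
                "n_x": nx,
                "n_a": na,
                "prop_x": nx / (nx + na),
                "p_fet": p_fet,
                "median_diff": float(np.median(a_above) - np.median(x_above)),
                "p_mw": _mannwhitney_p(x_above, a_above),
            }
        )
    return pd.DataFrame(rows).set_index("cut")


def between_group_shift(
    matrix: ExpressionMatrix, cond_a: str, cond_b: str
) -> dict:
    """Median per-probe expression shift between two conditions, by class.

    Computes the per-probe log2 difference ``cond_a - cond_b`` (replicate
    means), then the median of that distribution separately for X-linked and
    autosomal probes.  ``delta = median_a - median_x`` measures how much more
    the autosomes shift than the X; under loss of dosage compensation in
    ``cond_a`` only, delta approaches the log2 of the attenuation factor.
    """
    diff = matrix.condition_means(cond_a) - matrix.condition_means(cond_b)
    x, a = _split_x_a(diff, matrix.arms)
    if len(x) == 0 or len(a) == 0:
        raise InsufficientDataError("both chromosome classes must be non-empty")
    median_x, median_a = float(np.median(x)), float(np.median(a))
    return {
        "median_shift_x": median_x,
        "median_shift_a": median_a,
        "delta": median_a - median_x,
    }


def dcc_impairment_ratio(knockdown_fold: float, control_fold: float) -> float:
    """Fold reduction in relative X output attributable to DCC impairment.

    The A:X fold in compensation-impaired cells divided by the fold in
    control cells, e.g. a 1.51-fold knockdown deficit over a 1.15-fold
    control deficit is a 1.31-fold reduction in X-linked expression.
    """
    if control_fold <= 0:
        raise ValueError("control fold must be positive")
    return knockdown_fold / control_fold
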