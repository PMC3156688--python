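"""Factorial ANOVA with Type II sums of squares for transgene expression.

Reporter transgenes driven by a testis-specific autosomal promoter are
assayed by qPCR across factorial designs such as
``normalized Ct ~ sex * location * transgene`` (whole flies) or
``normalized Ct ~ stage * location * transgene`` (staged dissections).
The response is normalized Ct, so lower values mean higher expression; the
F statistics and p-values are unaffected by that sign convention.

Type II sums of squares respect marginality: the SS for a term is the
reduction in residual SS from adding it to the model containing every term
that does not include it.  Factors are coded with sum-to-zero contrasts,
under which Type II SS are invariant to level ordering and agree with the
standard ``car::Anova`` construction.  With a perfectly balanced design
Type I and Type II decompositions coincide term by term.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

logger = logging.getLogger("xchrom")

__all__ = ["fit_factorial_anova", "term_order"]


def term_order(factors) -> list[str]:
    """Model terms ordered main effects -> 2-way -> ... -> highest-order."""
    terms = []
    for k in range(1, len(factors) + 1):
        for combo in itertools.combinations(factors, k):
            terms.append(":".join(combo))
    return terms


def _formula(response: str, factors) -> str:
    encoded = "*".join(f"C({f}, Sum)" for f in factors)
    return f"{response} ~ {encoded}"


def fit_factorial_anova(
    data: pd.DataFrame,
    response: str,
    factors,
    ss_type: str = "II",
) -> pd.DataFrame:
    """Fit a fully crossed fixed-effects factorial ANOVA.

    Parameters
    ----------
    data : pandas.DataFrame
        One row per observation; ``response`` numeric, each factor
        categorical (any hashable levels).
    response, factors : str, sequence of str
        Column names; all interactions among ``factors`` are included.
    ss_type : {"I", "II"}
        Sequential or marginality-respecting sums of squares.

    Returns
    -------
    pandas.DataFrame
        Indexed by term (plain factor names, ``a:b`` for interactions, and a
        final ``Residual`` row) with columns ``sum_sq``, ``df``, ``F``, ``p``.
    """
    if ss_type not in ("I", "II"):
        raise ValueError("ss_type must be 'I' or 'II'")
    factors = list(factors)
    missing = [c for c in [response, *factors] if c not in data.columns]
    if missing:
        raise KeyError(f"column(s) not in data: {missing}")
    if not np.isfinite(pd.to_numeric(data[response])).all():
        raise ValueError("response must be finite")
    model = smf.ols(_formula(response, factors), data=data).fit()
    if model.df_resid <= 0:
        raise ValueError("no residual degrees of freedom")
    rank = np.linalg.matrix_rank(model.model.exog)
    if rank < model.model.exog.shape[1]:
        aliased = _aliased_terms(model)
        raise ValueError(
            f"rank-deficient design: aliased term(s) {aliased}; collapse or "
            "remove factor levels"
        )
    table = anova_lm(model, typ=2 if ss_type == "II" else 1)
    table = table.rename(
        columns={"PR(>F)": "p", "df": "df", "sum_sq": "sum_sq"}
    )
    # strip the contrast encoding out of term labels
    clean = {
        name: name.replace("C(", "").replace(", Sum)", "")
        for name in table.index
    }
    table = table.rename(index=clean)
    order = [t for t in term_order(factors) if t in table.index] + ["Residual"]
    table = table.loc[order, ["sum_sq", "df", "F", "p"]]
    table["df"] = table["df"].astype(int)
    return table


def _aliased_terms(model) -> list[str]:
    exog = model.model.exog
    names = model.model.exog_names
    rank = np.linalg.matrix_rank(exog)
    # greedy scan: a column not raising the rank of its predecessors is aliased
    aliased, kept = [], []
    for j, name in enumerate(names):
        trial = exog[:, [*kept, j]]
        if np.linalg.matrix_rank(trial) == len(kept):
            aliased.append(name)
        else:
            kept.append(j)
        if len(kept) == rank:
            aliased.extend(names[j + 1 :])
            break
    return aliased
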