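"""Stage-transition differential expression: tests, FDR, and arm summaries.

Probe-level two-sample t-tests compare log2 replicate values between
spermatogenesis stages for three transitions:

* ``early`` — premeiotic -> meiotic,
* ``late``  — meiotic -> postmeiotic,
* ``net``   — premeiotic -> postmeiotic.

Positive log2 fold-change means higher expression in the later stage.
Multiplicity is controlled genome-wide per transition with Benjamini-Hochberg
step-up q-values; a probe is called up/down when significant under the chosen
scheme (FDR 0.05/0.01/0.005, or an FDR-free |log2fc| >= 1 cutoff).  Per-arm
count summaries and median-magnitude summaries then contrast the X against
the pooled major autosomal arms with Fisher's exact and Mann-Whitney tests;
the dot fourth chromosome is tabulated on its own and never enters the
autosome aggregate.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_io import (
    ARMS,
    AUTOSOME_ARMS,
    ExpressionMatrix,
    format_count_percent,
)

logger = logging.getLogger("xchrom")

__all__ = [
    "TRANSITIONS",
    "SCHEMES",
    "TransitionCalls",
    "ArmSummary",
    "probe_t_tests",
    "bh_adjust",
    "classify_transitions",
    "arm_contingency_summary",
    "fisher_x_vs_a",
    "magnitude_summary",
    "render_arm_summary",
]

#: transition name -> (earlier stage, later stage)
TRANSITIONS = {
    "early": ("premeiotic", "meiotic"),
    "late": ("meiotic", "postmeiotic"),
    "net": ("premeiotic", "postmeiotic"),
}

#: scheme name -> FDR level (None for the fold-cutoff scheme)
SCHEMES = {"fdr05": 0.05, "fdr01": 0.01, "fdr005": 0.005, "fold2": None}


@dataclass
class TransitionCalls:
    """Per-probe direction calls for each stage transition.

    ``tables`` maps transition name to a frame indexed by probe with columns
    ``log2fc``, ``t``, ``p``, ``q``, ``direction`` (up/down/ns).  ``arms``
    carries the probe -> arm annotation; ``scheme`` records the significance
    scheme used.
    """

    tables: dict
    arms: pd.Series
    scheme: str


def probe_t_tests(
    matrix: ExpressionMatrix, stage1: str, stage2: str, equal_var: bool = False
) -> pd.DataFrame:
    """Two-sided two-sample t-test per probe between two stages.

    Welch's unequal-variance form by default (``equal_var=True`` selects the
    pooled-variance variant).  ``log2fc = mean(stage2) - mean(stage1)``.
    Probes with zero variance in both stages are untestable; they receive
    p = 1 (with a warning) so they can never be called significant.
    """
    a = matrix.values[matrix.sample_keys(stage1)].to_numpy()
    b = matrix.values[matrix.sample_keys(stage2)].to_numpy()
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("each stage needs >= 2 replicates for a t-test")
    log2fc = b.mean(axis=1) - a.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(b, a, axis=1, equal_var=equal_var)
    t, p = np.asarray(res.statistic), np.asarray(res.pvalue)
    degenerate = (a.var(axis=1) == 0) & (b.var(axis=1) == 0)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} probe(s) with zero variance in both "
            "stages; setting p = 1",
            stacklevel=2,
        )
        t = np.where(degenerate, np.nan, t)
        p = np.where(degenerate, 1.0, p)
    return pd.DataFrame(
        {"t": t, "p": p, "log2fc": log2fc}, index=matrix.values.index
    )


def bh_adjust(pvals, fdr: float = 0.05):
    """Benjamini-Hochberg step-up q-values and significance flags.

    Returns ``(qvals, flags)`` where ``flags[i]`` is True iff the step-up
    procedure at level ``fdr`` rejects hypothesis i (equivalently q <= fdr).
    """
    pvals = np.asarray(pvals, dtype=float)
    if ((pvals < 0) | (pvals > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    flags, qvals = multipletests(pvals, alpha=fdr, method="fdr_bh")[:2]
    return qvals, flags


def classify_transitions(
    matrix: ExpressionMatrix, scheme: str = "fdr05", equal_var: bool = False
) -> TransitionCalls:
    """Direction calls (up/down/ns) for the early, late and net transitions.

    Under the FDR schemes a probe is up (down) when its BH q-value clears the
    scheme's level and its log2fc is positive (negative).  Under ``fold2``
    significance is |log2fc| >= 1 regardless of p; q-values are still
    reported for reference.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"scheme must be one of {sorted(SCHEMES)}")
    fdr = SCHEMES[scheme]
    tables = {}
    for name, (stage1, stage2) in TRANSITIONS.items():
        table = probe_t_tests(matrix, stage1, stage2, equal_var=equal_var)
        table["q"] = bh_adjust(table["p"].to_numpy(), fdr or 0.05)[0]
        if fdr is None:
            significant = np.abs(table["log2fc"].to_numpy()) >= 1.0
        else:
            significant = table["q"].to_numpy() <= fdr
        direction = np.where(
            significant & (table["log2fc"].to_numpy() > 0),
            "up",
            np.where(significant & (table["log2fc"].to_numpy() < 0), "down", "ns"),
        )
        table["direction"] = direction
        tables[name] = table
        logger.info(
            "%s transition (%s): %d up, %d down of %d probes",
            name,
            scheme,
            (direction == "up").sum(),
            (direction == "down").sum(),
            len(direction),
        )
    return TransitionCalls(tables=tables, arms=matrix.arms.copy(), scheme=scheme)


# ---------------------------------------------------------------------------
# Arm summaries
# ---------------------------------------------------------------------------

_ARM_ROWS = ["2L", "2R", "3L", "3R", "4", "X", "A"]


@dataclass
class ArmSummary:
    """Per-arm up/down counts per transition, plus the pooled A row.

    ``counts`` is indexed by arm (including the aggregate ``A`` row, which
    sums 2L+2R+3L+3R and never includes arm 4) with a MultiIndex column
    ``(transition, {n_expressed, down, up})``.
    """

    counts: pd.DataFrame

    def n_expressed(self, arm: str) -> int:
        return int(self.counts.loc[arm, ("early", "n_expressed")])


def arm_contingency_summary(calls: TransitionCalls) -> ArmSummary:
    """Tabulate significant up/down calls per chromosome arm and transition."""
    arms = calls.arms
    unknown = set(arms) - set(ARMS)
    if unknown:
        raise ValueError(f"unknown arm(s) in annotation: {sorted(unknown)}")
    data = {}
    for transition, table in calls.tables.items():
        direction = table["direction"]
        for arm in ARMS:
            sel = arms == arm
            data.setdefault(arm, {})[transition] = (
                int(sel.sum()),
                int((direction[sel.to_numpy()] == "down").sum()),
                int((direction[sel.to_numpy()] == "up").sum()),
            )
    rows = {}
    for arm in ARMS:
        rows[arm] = {}
        for transition in calls.tables:
            n, down, up = data[arm][transition]
            rows[arm][(transition, "n_expressed")] = n
            rows[arm][(transition, "down")] = down
            rows[arm][(transition, "up")] = up
    rows["A"] = {
        key: sum(rows[arm][key] for arm in AUTOSOME_ARMS)
        for key in rows["2L"]
    }
    counts = pd.DataFrame.from_dict(rows, orient="index").loc[_ARM_ROWS]
    counts.columns = pd.MultiIndex.from_tuples(counts.columns)
    return ArmSummary(counts=counts)


def render_arm_summary(summary: ArmSummary) -> pd.DataFrame:
    """Format counts as ``"741 (38.1%)"`` cells for human-readable output."""
    out = {}
    for arm in summary.counts.index:
        row = {}
        transitions = summary.counts.columns.get_level_values(0).unique()
        row["n_expressed"] = int(summary.counts.loc[arm, (transitions[0], "n_expressed")])
        for transition in transitions:
            n = int(summary.counts.loc[arm, (transition, "n_expressed")])
            for direction in ("down", "up"):
                count = int(summary.counts.loc[arm, (transition, direction)])
                row[f"{transition}_{direction}"] = format_count_percent(count, n)
        out[arm] = row
    frame = pd.DataFrame.from_dict(out, orient="index")
    frame.index.name = "arm"
    return frame


def fisher_x_vs_a(summary: ArmSummary, transition: str, direction: str) -> float:
    """Two-sided Fisher's exact test: X versus pooled autosomes for one call.

    Tests the 2x2 table {X, A} x {direction, not-direction}, where the A row
    excludes arm 4.  Two-sidedness is the sum of table probabilities no
    larger than the observed table's.  A zero margin makes the test
    undefined; p = 1 is returned with a warning.
    """
    if direction not in ("down", "up"):
        raise ValueError("direction must be 'down' or 'up'")
    x_n = int(summary.counts.loc["X", (transition, "n_expressed")])
    x_dir = int(summary.counts.loc["X", (transition, direction)])
    a_n = int(summary.counts.loc["A", (transition, "n_expressed")])
    a_dir = int(summary.counts.loc["A", (transition, direction)])
    table = [[x_dir, x_n - x_dir], [a_dir, a_n - a_dir]]
    margins = [x_n, a_n, x_dir + a_dir, (x_n - x_dir) + (a_n - a_dir)]
    if min(margins) == 0:
        warnings.warn("zero margin in 2x2 table; Fisher p undefined, returning 1")
        return 1.0
    return float(stats.fisher_exact(table, alternative="two-sided").pvalue)


def magnitude_summary(calls: TransitionCalls) -> pd.DataFrame:
    """Median log2 fold-change magnitudes among called probes, per arm.

    For each arm and transition, reports the median log2fc among down-calls,
    among up-calls, and among all changed probes (up+down); empty call
    classes yield NaN.  Adds an ``X_vs_A_p`` row of Mann-Whitney p-values
    comparing X call magnitudes with pooled-autosome call magnitudes for the
    down and up columns.
    """
    arms = calls.arms
    columns = {}
    for transition, table in calls.tables.items():
        fc = table["log2fc"]
        direction = table["direction"]
        sets = {
            "down": direction == "down",
            "up": direction == "up",
            "up_down": direction != "ns",
        }
        for label, sel in sets.items():
            col = {}
            for arm in _ARM_ROWS:
                if arm == "A":
                    arm_sel = arms.isin(AUTOSOME_ARMS)
                else:
                    arm_sel = arms == arm
                vals = fc[sel.to_numpy() & arm_sel.to_numpy()]
                col[arm] = float(np.median(vals)) if len(vals) else np.nan
            if label in ("down", "up"):
                x_vals = fc[sel.to_numpy() & (arms == "X").to_numpy()]
                a_vals = fc[sel.to_numpy() & arms.isin(AUTOSOME_ARMS).to_numpy()]
                if len(x_vals) and len(a_vals):
                    col["X_vs_A_p"] = float(
                        stats.mannwhitneyu(
                            x_vals, a_vals, alternative="two-sided"
                        ).pvalue
                    )
                else:
                    col["X_vs_A_p"] = np.nan
            columns[(transition, label)] = col
    frame = pd.DataFrame(columns)
    frame.columns = pd.MultiIndex.from_tuples(frame.columns)
    return frame
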