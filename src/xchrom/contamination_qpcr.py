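"""qPCR sheath-contamination analysis.

Premeiotic dissections from the apical testis tip can retain the somatic,
dosage-compensated testis sheath, inflating apparent X-linked expression
relative to sheath-free meiotic dissections.  Three dissection classes are
compared: Ps (premeiotic with sheath), Pn (premeiotic, sheath removed) and
M (meiotic).  For each target gene:

* Ct values are normalized per (dissection, plate) by subtracting the mean
  Ct of the control genes on that plate;
* log2 fold-changes between dissections follow from the one-cycle-per-
  twofold inverse relation (fold of A over B = normCt_B - normCt_A);
* the **sheath effect** is the percentage of the apparent premeiotic ->
  meiotic change attributable to the sheath: ``100 * (Ps-Pn) / (Ps-M)``.

Significance comes from paired t-tests across plates (per gene and pooled
over genes x plates) and an exact binomial sign test on the number of genes
with Ps > Pn.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import CtTable

logger = logging.getLogger("xchrom")

__all__ = [
    "SheathEffectRecord",
    "normalize_ct",
    "stage_log2fold",
    "sheath_effect",
    "sheath_effect_table",
    "pooled_sheath_tests",
    "round_percent",
]


@dataclass(frozen=True)
class SheathEffectRecord:
    """Per-gene sheath-contamination statistics.

    ``ps_m`` and ``ps_pn`` are log2 fold-changes (positive = higher in Ps);
    ``effect_pct`` is ``100 * ps_pn / ps_m`` at full precision (may be
    negative); ``p_paired`` is the paired-t p-value for Ps vs Pn.
    """

    gene: str
    ps_m: float
    ps_pn: float
    effect_pct: float
    p_paired: float


def normalize_ct(table: CtTable) -> pd.DataFrame:
    """Subtract the mean control-gene Ct within each (dissection, plate).

    Returns the observation frame with a ``norm_ct`` column added.  Plate-
    wide additive offsets (template amount, efficiency drift) cancel exactly.
    """
    if not table.control_genes:
        raise ValueError("CtTable declares no control genes")
    obs = table.observations.copy()
    controls = obs[obs["gene"].isin(table.control_genes)]
    means = controls.groupby(["dissection", "plate"])["ct"].mean()
    keys = pd.MultiIndex.from_frame(obs[["dissection", "plate"]])
    obs["norm_ct"] = obs["ct"].to_numpy() - means.reindex(keys).to_numpy()
    return obs


def stage_log2fold(norm: pd.DataFrame, gene: str, diss_a: str, diss_b: str) -> float:
    """Log2 fold-change of ``diss_a`` over ``diss_b`` for one gene.

    Ct is inversely related to abundance, one cycle per log2 unit, so the
    fold of A over B is ``normCt_B - normCt_A``, averaged over plates.
    """
    sub = norm[norm["gene"] == gene]
    by_plate = sub.pivot_table(index="plate", columns="dissection", values="norm_ct")
    for diss in (diss_a, diss_b):
        if diss not in by_plate.columns or by_plate[diss].isna().all():
            raise KeyError(f"gene {gene!r} has no measurements for {diss!r}")
    return float((by_plate[diss_b] - by_plate[diss_a]).mean())


def sheath_effect(ps_m: float, ps_pn: float) -> float:
    """Fraction (percent) of the Ps-M change attributable to sheath tissue.

    ``100 * ps_pn / ps_m``, signed: both folds positive and similar means the
    whole apparent stage change is contamination (~100%).  Undefined when
    ``ps_m`` is zero (returns NaN).
    """
    if ps_m == 0:
        return float("nan")
    return 100.0 * ps_pn / ps_m


def round_percent(value: float) -> int:
    """Nearest-integer percent for display (round half away from zero)."""
    return int(math.floor(abs(value) + 0.5) * (1 if value >= 0 else -1))


def sheath_effect_table(
    table: CtTable, genes=None
) -> tuple[list[SheathEffectRecord], SheathEffectRecord]:
    """Per-gene sheath-effect records plus the pooled all-genes record.

    Target genes default to every non-control gene.  The pooled record uses
    the ratio of across-gene mean folds (mean Ps-Pn over mean Ps-M), not the
    mean of per-gene ratios, and the pooled paired-t over all genes x plates.
    """
    norm = normalize_ct(table)
    if genes is None:
        genes = [
            g
            for g in dict.fromkeys(norm["gene"])
            if g not in table.control_genes
        ]
    records = []
    for gene in genes:
        ps_m = stage_log2fold(norm, gene, "Ps", "M")
        ps_pn = stage_log2fold(norm, gene, "Ps", "Pn")
        p_paired = _paired_t_p(norm, [gene])
        records.append(
            SheathEffectRecord(
                gene=gene,
                ps_m=ps_m,
                ps_pn=ps_pn,
                effect_pct=sheath_effect(ps_m, ps_pn),
                p_paired=p_paired,
            )
        )
    mean_ps_m = float(np.mean([r.ps_m for r in records]))
    mean_ps_pn = float(np.mean([r.ps_pn for r in records]))
    pooled = SheathEffectRecord(
        gene="All genes",
        ps_m=mean_ps_m,
        ps_pn=mean_ps_pn,
        effect_pct=sheath_effect(mean_ps_m, mean_ps_pn),
        p_paired=_paired_t_p(norm, genes),
    )
    return records, pooled


def _paired_t_p(norm: pd.DataFrame, genes) -> float:
    """Two-sided paired t between Ps and Pn across plates for given genes."""
    sub = norm[norm["gene"].isin(genes)]
    wide = sub.pivot_table(
        index=["gene", "plate"], columns="dissection", values="norm_ct"
    )
    if "Ps" not in wide.columns or "Pn" not in wide.columns:
        return float("nan")
    paired = wide[["Ps", "Pn"]].dropna()
    if len(paired) < 2:
        return float("nan")
    diffs = (paired["Ps"] - paired["Pn"]).to_numpy()
    if np.allclose(diffs, 0.0):
        return 1.0  # no paired difference anywhere: nothing to detect
    return float(stats.ttest_rel(paired["Ps"], paired["Pn"]).pvalue)


def pooled_sheath_tests(table: CtTable, genes=None) -> dict:
    """Per-gene, pooled, and sign-test significance for the sheath effect.

    Returns a dict with ``per_gene`` (gene -> paired-t p across plates),
    ``pooled_p`` (paired t over all genes x plates), ``n_ps_greater`` and
    ``sign_test_p`` (two-sided exact binomial on the count of genes with
    Ps expression above Pn, i.e. positive Ps-Pn fold).  Genes with fewer
    than two plate pairs get NaN per-gene p but still enter the sign test.
    """
    norm = normalize_ct(table)
    if genes is None:
        genes = [
            g
            for g in dict.fromkeys(norm["gene"])
            if g not in table.control_genes
        ]
    per_gene = {gene: _paired_t_p(norm, [gene]) for gene in genes}
    folds = [stage_log2fold(norm, gene, "Ps", "Pn") for gene in genes]
    n_greater = int(sum(f > 0 for f in folds))
    n_nonzero = int(sum(f != 0 for f in folds))
    if n_nonzero == 0:
        sign_p = 1.0  # every gene tied: no evidence either way
    else:
        sign_p = float(
            stats.binomtest(
                n_greater, n_nonzero, 0.5, alternative="two-sided"
            ).pvalue
        )
    return {
        "per_gene": per_gene,
        "pooled_p": _paired_t_p(norm, genes),
        "n_ps_greater": n_greater,
        "n_genes": len(genes),
        "sign_test_p": sign_p,
    }
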