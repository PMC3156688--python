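"""Generative models of X-chromosome regulation in the male germline.

The generator produces stage-structured expression matrices, RPKM tables and
qPCR Ct tables under explicit, contrastable hypotheses about how the single
male X is regulated:

``full_dc``
    Chromosome-wide dosage compensation: the hemizygous X is hyper-transcribed
    so that X and autosomal output are equal (the somatic, MSL-mediated state).
``no_dc_buffered``
    No X-specific compensation, but a generic dose-buffering mechanism dampens
    the 2-fold dose difference to a smaller realized deficit — X expression is
    divided by ``attenuation_a`` (canonically ~1.5).
``no_dc_raw``
    No compensation and no buffering: the X shows the raw 2-fold dose deficit.

Two germline-specific effects are layered on top:

* **MSCI** — in meiotic samples a fraction ``phi`` of cells silence the X by a
  factor ``s``, multiplying bulk X signal by ``(1 - phi + phi/s)`` (linear).
* **Sheath contamination** — a premeiotic dissection that retains the somatic
  testis sheath measures a linear mixture ``(1-f)*germline + f*soma``, where
  the somatic signal is dosage compensated.

Generation is a pure function of ``(design, params, seed)``: a single
:class:`numpy.random.Generator` is consumed in a fixed, documented order
(baselines by arm, then stage effects by transition, then replicate noise).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core_io import (
    ARMS,
    AUTOSOME_ARMS,
    CtTable,
    ExpressionMatrix,
    RpkmTable,
    make_expression_matrix,
)

__all__ = [
    "RegulationParams",
    "StageDesign",
    "SCENARIOS",
    "TABLE1_GENES_PER_ARM",
    "simulate_expression",
    "mix_with_sheath",
    "simulate_ct",
    "simulate_rpkm",
    "scenario_params",
]

DC_MODES = ("full_dc", "no_dc_buffered", "no_dc_raw")

#: Expressed-gene counts per arm in the stage-dissection microarray data,
#: used as the default synthetic genome composition.
TABLE1_GENES_PER_ARM = {
    "X": 1943,
    "2L": 2204,
    "2R": 2356,
    "3L": 2335,
    "3R": 3009,
    "4": 58,
}


@dataclass(frozen=True)
class RegulationParams:
    """Parameters of the X-regulation generative model.

    Parameters
    ----------
    dc_mode : str
        One of ``full_dc``, ``no_dc_buffered``, ``no_dc_raw``.
    attenuation_a : float
        Realized X expression divisor under ``no_dc_buffered`` (>0).  Ignored
        (treated as 1) under ``full_dc``; the raw dose limit of 2 is used
        under ``no_dc_raw``.
    msci_fraction_phi : float
        Fraction of cells in a meiotic sample with a silenced X, in [0, 1].
    msci_silencing_s : float
        Fold silencing of the X within affected cells (>= 1).
    sheath_fraction_f : float
        Linear-scale weight of contaminating somatic (compensated) signal in
        a ``premeiotic_with_sheath`` dissection, in [0, 1].
    noise_sd : float
        Log2 measurement noise per replicate (>= 0).  The default 0.25
        matches typical replicate-array reproducibility; at three replicates
        it leaves stage effects of ~0.9 log2 individually detectable, as they
        are on real arrays.
    """

    dc_mode: str = "no_dc_buffered"
    attenuation_a: float = 1.5
    msci_fraction_phi: float = 0.0
    msci_silencing_s: float = 1.0
    sheath_fraction_f: float = 0.0
    noise_sd: float = 0.25

    def __post_init__(self) -> None:
        if self.dc_mode not in DC_MODES:
            raise ValueError(f"dc_mode must be one of {DC_MODES}")
        if not self.attenuation_a > 0:
            raise ValueError("attenuation_a must be > 0")
        if not 0.0 <= self.msci_fraction_phi <= 1.0:
            raise ValueError("msci_fraction_phi must lie in [0, 1]")
        if not self.msci_silencing_s >= 1.0:
            raise ValueError("msci_silencing_s must be >= 1")
        if not 0.0 <= self.sheath_fraction_f <= 1.0:
            raise ValueError("sheath_fraction_f must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def x_divisor(self) -> float:
        """Linear divisor applied to X expression in germline samples."""
        if self.dc_mode == "full_dc":
            return 1.0
        if self.dc_mode == "no_dc_raw":
            return 2.0  # raw hemizygous dose deficit
        return self.attenuation_a

    @property
    def msci_multiplier(self) -> float:
        """Bulk linear X multiplier in meiotic samples: ``1 - phi + phi/s``."""
        phi, s = self.msci_fraction_phi, self.msci_silencing_s
        return 1.0 - phi + phi / s


@dataclass(frozen=True)
class StageDesign:
    """Layout of the simulated experiment.

    ``stage_effect`` is a mixture of (weight, mean, sd) components for the
    per-gene log2 shift applied between consecutive stages; defaults follow
    the observed stage-transition behaviour (roughly 37% of genes down with
    median magnitude ~0.9, 31% up ~0.9, the rest unchanged).  ``noise_mode``
    holds the fraction and location of the low "unexpressed" intensity mode
    that makes array intensity distributions bimodal.
    """

    stages: tuple = ("premeiotic", "meiotic", "postmeiotic")
    replicates: int = 3
    genes_per_arm: dict = field(
        default_factory=lambda: dict(TABLE1_GENES_PER_ARM)
    )
    stage_effect: tuple = (
        (0.37, -0.86, 0.3),
        (0.31, 0.92, 0.3),
        (0.32, 0.0, 0.0),
    )
    expressed_mode: tuple = (10.0, 2.0)  # log2 mean, sd
    noise_mode: tuple = (4.0, 1.0)
    noise_mode_weight: float = 0.30

    def __post_init__(self) -> None:
        if self.replicates < 2:
            raise ValueError("replicates must be >= 2 (t-tests need pairs)")
        if not self.stages:
            raise ValueError("at least one stage is required")
        weights = [w for w, _, _ in self.stage_effect]
        if abs(sum(weights) - 1.0) > 1e-9 or min(weights) < 0:
            raise ValueError("stage-effect mixture weights must sum to 1")
        if not 0.0 <= self.noise_mode_weight <= 1.0:
            raise ValueError("noise_mode_weight must lie in [0, 1]")
        unknown = set(self.genes_per_arm) - set(ARMS)
        if unknown:
            raise ValueError(f"unknown arm(s) in genes_per_arm: {sorted(unknown)}")


#: Named scenarios for the regulation models contrasted in the analysis.
SCENARIOS = {
    "full_dc": RegulationParams(dc_mode="full_dc"),
    "no_dc": RegulationParams(dc_mode="no_dc_buffered", attenuation_a=1.5),
    "msci": RegulationParams(
        dc_mode="no_dc_buffered",
        attenuation_a=1.5,
        msci_fraction_phi=0.3,
        msci_silencing_s=10.0,
    ),
    "contaminated_premeiotic": RegulationParams(
        dc_mode="no_dc_buffered", attenuation_a=1.5, sheath_fraction_f=0.3
    ),
}


def scenario_params(name: str, **overrides) -> RegulationParams:
    """Look up a named scenario, optionally overriding fields."""
    try:
        base = SCENARIOS[name]
    except KeyError:
        raise KeyError(
            f"unknown scenario {name!r}; choose from {sorted(SCENARIOS)}"
        ) from None
    return replace(base, **overrides) if overrides else base


# ---------------------------------------------------------------------------
# Expression simulation
# ---------------------------------------------------------------------------


def _draw_baselines(design: StageDesign, rng: np.random.Generator) -> pd.DataFrame:
    """Per-gene baseline log2 level from the expressed/noise mixture."""
    frames = []
    for arm in ARMS:
        n = design.genes_per_arm.get(arm, 0)
        if n == 0:
            continue
        is_noise = rng.random(n) < design.noise_mode_weight
        mu_e, sd_e = design.expressed_mode
        mu_n, sd_n = design.noise_mode
        level = np.where(
            is_noise,
            rng.normal(mu_n, sd_n, n),
            rng.normal(mu_e, sd_e, n),
        )
        frames.append(
            pd.DataFrame(
                {
                    "probe_id": [f"{arm}_{i:05d}" for i in range(n)],
                    "arm": arm,
                    "baseline": level,
                }
            )
        )
    return pd.concat(frames, ignore_index=True).set_index("probe_id")


def _draw_stage_shifts(
    design: StageDesign, n_genes: int, rng: np.random.Generator
) -> np.ndarray:
    weights = np.array([w for w, _, _ in design.stage_effect])
    means = np.array([m for _, m, _ in design.stage_effect])
    sds = np.array([s for _, _, s in design.stage_effect])
    comp = rng.choice(len(weights), size=n_genes, p=weights)
    return rng.normal(means[comp], sds[comp])


def simulate_expression(
    design: StageDesign, params: RegulationParams, seed: int
) -> ExpressionMatrix:
    """Simulate a log2 expression matrix under an X-regulation model.

    The per-gene log2 signal in stage k is::

        baseline - [X] * log2(divisor) + sum(shifts[1..k])
                 + [X, meiotic] * log2(1 - phi + phi/s)

    where ``[X]`` indicates X-linked genes and ``divisor`` is the dose
    attenuation implied by ``params.dc_mode``.  A ``premeiotic_with_sheath``
    stage is a linear mixture of the corresponding germline premeiotic signal
    with the somatic (compensated, stage-effect-free baseline) signal at
    weight ``params.sheath_fraction_f``.  Replicate noise is
    ``Normal(0, noise_sd)`` in log2.
    """
    rng = np.random.default_rng(seed)
    base = _draw_baselines(design, rng)
    n = len(base)
    is_x = (base["arm"] == "X").to_numpy()

    # Somatic (sheath) profile: dosage compensated, no germline stage effects.
    soma_log2 = base["baseline"].to_numpy()
    germ0 = soma_log2 - np.where(is_x, np.log2(params.x_divisor), 0.0)

    # Cumulative per-gene trajectories over the distinct biological stages.
    # A premeiotic_with_sheath sample is the premeiotic cell population with
    # sheath contamination, so it shares the premeiotic germline trajectory
    # rather than receiving its own stage-transition shift.
    biological = {
        s: ("premeiotic" if s == "premeiotic_with_sheath" else s)
        for s in design.stages
    }
    bio_order = list(dict.fromkeys(biological.values()))
    level = germ0.copy()
    bio_log2 = {}
    for i, bio_stage in enumerate(bio_order):
        if i > 0:
            level = level + _draw_stage_shifts(design, n, rng)
        germ = level.copy()
        if bio_stage == "meiotic":
            germ = germ + np.where(is_x, np.log2(params.msci_multiplier), 0.0)
        bio_log2[bio_stage] = germ

    stage_log2 = {}
    for stage in design.stages:
        germ = bio_log2[biological[stage]]
        if stage == "premeiotic_with_sheath":
            stage_log2[stage] = np.log2(
                (1.0 - params.sheath_fraction_f) * np.exp2(germ)
                + params.sheath_fraction_f * np.exp2(soma_log2)
            )
        else:
            stage_log2[stage] = germ

    columns = {}
    for stage in design.stages:
        for rep in range(1, design.replicates + 1):
            noise = (
                rng.normal(0.0, params.noise_sd, n) if params.noise_sd > 0 else 0.0
            )
            columns[f"{stage}:{rep}"] = stage_log2[stage] + noise

    values = pd.DataFrame(columns, index=base.index)
    return make_expression_matrix(values, base["arm"])


def mix_with_sheath(germline: pd.Series, soma: pd.Series, f: float) -> pd.Series:
    """Linear-scale convex mixture of a germline and a somatic log2 column.

    Returns ``log2((1-f) * 2**germline + f * 2**soma)`` aligned on the probe
    index of ``germline``.
    """
    if not 0.0 <= f <= 1.0:
        raise ValueError("mixture fraction f must lie in [0, 1]")
    if not germline.index.equals(soma.index):
        raise ValueError("germline and soma columns must share the same probes")
    if f == 0.0:
        return germline.copy()
    if f == 1.0:
        return soma.copy()
    return np.log2((1.0 - f) * np.exp2(germline) + f * np.exp2(soma))


# ---------------------------------------------------------------------------
# qPCR simulation
# ---------------------------------------------------------------------------


def simulate_ct(
    expr: pd.DataFrame,
    c0: float = 30.0,
    plates: int = 4,
    noise_sd_ct: float = 0.0,
    seed: int = 0,
    control_genes=(),
) -> CtTable:
    """Generate a plate-replicated Ct table from linear expression levels.

    ``expr`` has genes on the index and dissection labels (Ps/Pn/M) as
    columns, holding strictly positive linear expression.  The measurement
    model is ``Ct = c0 - log2(expr) + Normal(0, noise_sd_ct)`` per plate —
    one qPCR cycle per twofold of template.  Control genes are forced to a
    common level across dissections (zero differential), as befits
    normalisation controls.
    """
    expr = expr.copy()
    if (expr.to_numpy() <= 0).any():
        raise ValueError("linear expression must be strictly positive")
    control_genes = frozenset(control_genes)
    missing = control_genes - set(expr.index)
    if missing:
        raise ValueError(f"control gene(s) not in expression table: {sorted(missing)}")
    for gene in control_genes:
        expr.loc[gene] = float(expr.loc[gene].iloc[0])
    rng = np.random.default_rng(seed)
    rows = []
    for plate in range(1, plates + 1):
        for diss in expr.columns:
            ct = c0 - np.log2(expr[diss].to_numpy())
            if noise_sd_ct > 0:
                ct = ct + rng.normal(0.0, noise_sd_ct, len(ct))
            rows.append(
                pd.DataFrame(
                    {
                        "gene": expr.index,
                        "dissection": diss,
                        "plate": plate,
                        "ct": ct,
                    }
                )
            )
    frame = pd.concat(rows, ignore_index=True)
    return CtTable(frame, control_genes)


# ---------------------------------------------------------------------------
# Transgene factorial designs
# ---------------------------------------------------------------------------


def simulate_transgene_design(
    seed: int = 0,
    inserts=None,
    replicates: int = 3,
    effects=None,
    noise_sd: float = 1.0,
) -> pd.DataFrame:
    """Replicate-level normalized-Ct table for a sex x location x transgene
    factorial, mimicking the reporter-insert experiment layout.

    ``inserts`` maps (transgene, location) to the number of independent
    insert lines; the default mirrors 8 X-linked + 8 autosomal lines for one
    construct and 6 + 5 for the other.  ``effects`` supplies additive Ct
    effects: ``sex`` (added for females), ``x_in_males`` (added for X-linked
    inserts in males — higher Ct = lower expression), ``transgene``.
    Observations get ``Normal(0, noise_sd)`` measurement noise.
    """
    inserts = inserts or {
        ("WOL", "X"): 8,
        ("WOL", "autosome"): 8,
        ("YLZ", "X"): 6,
        ("YLZ", "autosome"): 5,
    }
    effects = effects or {"sex": 8.0, "x_in_males": 2.3, "transgene": 0.5}
    rng = np.random.default_rng(seed)
    rows = []
    for (transgene, location), n_lines in inserts.items():
        for line in range(1, n_lines + 1):
            line_effect = rng.normal(0.0, 0.3)
            for sex in ("male", "female"):
                for _ in range(replicates):
                    ct = 10.0 + line_effect
                    if sex == "female":
                        ct += effects["sex"]
                    elif location == "X":
                        ct += effects["x_in_males"]
                    if transgene == "YLZ":
                        ct += effects["transgene"]
                    rows.append(
                        {
                            "normalized_ct": ct + rng.normal(0.0, noise_sd),
                            "sex": sex,
                            "location": location,
                            "transgene": transgene,
                            "insert_line": f"{transgene}_{location}_{line}",
                        }
                    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# RPKM simulation
# ---------------------------------------------------------------------------


def simulate_rpkm(
    params: RegulationParams,
    genes_per_arm: dict | None = None,
    seed: int = 0,
    log2_mean: float = 4.0,
    log2_sd: float = 2.0,
) -> RpkmTable:
    """Gene-level RPKM table with the X divided by the model's dose divisor.

    Baseline RPKM is log-normal (``2**Normal(log2_mean, log2_sd)``); X-linked
    genes are divided by ``params.x_divisor`` and the whole table receives
    multiplicative log2 noise of sd ``params.noise_sd``.
    """
    genes_per_arm = dict(genes_per_arm or TABLE1_GENES_PER_ARM)
    rng = np.random.default_rng(seed)
    frames = []
    for arm in ARMS:
        n = genes_per_arm.get(arm, 0)
        if n == 0:
            continue
        level = rng.normal(log2_mean, log2_sd, n)
        if arm == "X":
            level = level - np.log2(params.x_divisor)
        if params.noise_sd > 0:
            level = level + rng.normal(0.0, params.noise_sd, n)
        frames.append(
            pd.DataFrame(
                {
                    "gene_id": [f"{arm}g{i:05d}" for i in range(n)],
                    "arm": arm,
                    "rpkm": np.exp2(level),
                }
            )
        )
    return RpkmTable(pd.concat(frames, ignore_index=True))
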