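"""Condition summaries and the significance machinery of the screen.

Wells (not comets) are the unit of replication: each well contributes its
median % tail DNA, and conditions are compared on those well-level medians,
avoiding comet-level pseudoreplication.  Dose series are tested with a
one-way ANOVA followed by Dunnett many-to-one comparisons against the
shared vehicle; two-factor designs (e.g. genotype x time) use a two-way
ANOVA with Bonferroni-adjusted pairwise contrasts at each level of the
second factor; matched arms use a paired two-tailed t-test.  Genotoxicity
calls are one-directional: only *increases* in % tail DNA can score
positive, so crosslinker-suppressed migration never produces a call.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ConditionSummary",
    "summarize_condition",
    "DunnettOutcome",
    "dunnett_vs_control",
    "twoway_bonferroni",
    "paired_t",
    "ScreenCall",
    "call_genotoxicity",
]


@dataclass
class ConditionSummary:
    label: str
    well_medians: np.ndarray
    mean: float
    sem: float  # nan for a single well
    n_wells: int
    n_comets: int
    viability: float = 1.0
    qc_pass: bool = True

    @classmethod
    def from_well_values(
        cls,
        label: str,
        well_medians: Sequence[float],
        n_comets: int = 0,
        viability: float = 1.0,
        qc_pass: bool = True,
    ) -> "ConditionSummary":
        med = np.asarray(list(well_medians), dtype=float)
        if med.size == 0:
            raise ValueError("a condition needs at least one well")
        sem = float(med.std(ddof=1) / math.sqrt(med.size)) if med.size >= 2 else float("nan")
        return cls(
            label=label,
            well_medians=med,
            mean=float(med.mean()),
            sem=sem,
            n_wells=int(med.size),
            n_comets=int(n_comets),
            viability=float(viability),
            qc_pass=bool(qc_pass),
        )


def summarize_condition(
    records: pd.DataFrame,
    label: str = "",
    well_col: str = "well",
    value_col: str = "percent_tail",
    viability: float = 1.0,
) -> ConditionSummary:
    """Aggregate QC-filtered per-comet records into a condition summary.

    The well-level statistic is the median ``value_col``; mean and SEM are
    computed across wells.
    """
    if records.empty:
        raise ValueError("no records to summarize")
    if well_col not in records.columns:
        records = records.assign(**{well_col: 0})
    medians = records.groupby(well_col, sort=True)[value_col].median()
    return ConditionSummary.from_well_values(
        label=label,
        well_medians=medians.to_numpy(),
        n_comets=len(records),
        viability=viability,
    )


# ---------------------------------------------------------------------------
# Hypothesis tests
# ---------------------------------------------------------------------------


@dataclass
class DunnettOutcome:
    pvalues: np.ndarray  # adjusted, one per dose, in input order
    significant: np.ndarray  # pvalues < alpha
    alpha: float
    anova_p: float
    alternative: str
    method: str


def dunnett_vs_control(
    control: Sequence[float],
    doses: Sequence[Sequence[float]],
    alpha: float = 0.05,
    alternative: str = "greater",
    method: str = "mvt",
    n_permutations: int = 10_000,
    rng: Optional[np.random.Generator] = None,
) -> DunnettOutcome:
    """One-way ANOVA + Dunnett many-to-one comparisons on well medians.

    ``method='mvt'`` uses the multivariate-t quantile implementation;
    ``method='permutation'`` is a seeded max-t label-permutation fallback
    that agrees with it to Monte-Carlo accuracy on small designs.
    ``alternative='greater'`` tests for increases over the control (the
    direction of harm for strand breaks).
    """
    ctrl = np.asarray(list(control), dtype=float)
    groups = [np.asarray(list(g), dtype=float) for g in doses]
    if ctrl.size < 2 or any(g.size < 2 for g in groups):
        raise ValueError("every condition needs >= 2 wells")
    if rng is None:
        rng = np.random.default_rng()
    anova_p = float(sps.f_oneway(ctrl, *groups).pvalue)
    if method == "mvt":
        res = sps.dunnett(*groups, control=ctrl, alternative=alternative, rng=rng)
        pvals = np.asarray(res.pvalue, dtype=float)
    elif method == "permutation":
        pvals = _dunnett_permutation(ctrl, groups, alternative, n_permutations, rng)
    else:
        raise ValueError(f"unknown method {method!r}")
    return DunnettOutcome(
        pvalues=pvals,
        significant=pvals < alpha,
        alpha=alpha,
        anova_p=anova_p,
        alternative=alternative,
        method=method,
    )


def _t_stats(ctrl: np.ndarray, groups: List[np.ndarray]) -> np.ndarray:
    """Dunnett t statistics with the pooled within-group variance."""
    all_g = [ctrl] + groups
    n_tot = sum(g.size for g in all_g)
    df = n_tot - len(all_g)
    ss = sum(((g - g.mean()) ** 2).sum() for g in all_g)
    s2 = ss / df if df > 0 else float("nan")
    out = np.array(
        [
            (g.mean() - ctrl.mean()) / math.sqrt(s2 * (1 / g.size + 1 / ctrl.size))
            for g in groups
        ]
    )
    return out


def _dunnett_permutation(
    ctrl: np.ndarray,
    groups: List[np.ndarray],
    alternative: str,
    n_permutations: int,
    rng: np.random.Generator,
) -> np.ndarray:
    obs = _t_stats(ctrl, groups)
    if alternative == "greater":
        score = lambda t: t
    elif alternative == "less":
        score = lambda t: -t
    else:
        score = np.abs
    pooled = np.concatenate([ctrl] + groups)
    sizes = [ctrl.size] + [g.size for g in groups]
    splits = np.cumsum(sizes)[:-1]
    max_null = np.empty(n_permutations)
    for b in range(n_permutations):
        perm = rng.permutation(pooled)
        parts = np.split(perm, splits)
        max_null[b] = score(_t_stats(parts[0], parts[1:])).max()
    # adjusted p: fraction of permutations whose max statistic beats each dose
    return np.array(
        [
            (1.0 + float((max_null >= s).sum())) / (n_permutations + 1.0)
            for s in score(obs)
        ]
    )


def twoway_bonferroni(
    data: pd.DataFrame,
    value_col: str = "value",
    factor_a: str = "arm",
    factor_b: str = "level",
    alpha: float = 0.05,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Two-way ANOVA on well medians + Bonferroni contrasts per level.

    ``factor_a`` must have exactly two levels (the arms being compared,
    e.g. two genotypes); contrasts compare the arms at each level of
    ``factor_b`` (e.g. each repair time point) using the pooled residual
    variance of the full factorial model, with p-values multiplied by the
    number of contrasts.  Returns ``(anova table, contrast table)``.
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    df = data.rename(
        columns={value_col: "value", factor_a: "fa", factor_b: "fb"}
    )[["value", "fa", "fb"]].copy()
    arms = sorted(df["fa"].unique())
    levels = sorted(df["fb"].unique())
    if len(arms) != 2:
        raise ValueError("factor_a must have exactly two levels")
    counts = df.groupby(["fa", "fb"]).size().unstack()
    if counts.isna().any().any() or (counts < 2).any().any():
        raise ValueError("incomplete two-factor design (need >= 2 wells per cell)")

    model = ols("value ~ C(fa) * C(fb)", data=df).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    mse = float(model.mse_resid)
    dof = int(model.df_resid)
    m = len(levels)
    rows = []
    for lev in levels:
        a = df[(df["fa"] == arms[0]) & (df["fb"] == lev)]["value"].to_numpy()
        b = df[(df["fa"] == arms[1]) & (df["fb"] == lev)]["value"].to_numpy()
        diff = b.mean() - a.mean()
        se = math.sqrt(mse * (1 / a.size + 1 / b.size))
        t = diff / se
        p_raw = 2.0 * sps.t.sf(abs(t), dof)
        p_adj = min(1.0, m * p_raw)
        rows.append(
            {
                "level": lev,
                "diff": diff,
                "t": t,
                "p_raw": p_raw,
                "p_adj": p_adj,
                "significant": p_adj < alpha,
            }
        )
    return anova, pd.DataFrame(rows)


def paired_t(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Two-tailed paired t-test on matched well summaries.

    Degenerate inputs are resolved explicitly: identical vectors give
    (0, 1); constant nonzero differences have zero variance, reported as
    (inf-signed, 0) with a warning.
    """
    a = np.asarray(list(x), dtype=float)
    b = np.asarray(list(y), dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need >= 2 equal-length pairs")
    d = b - a
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d, 0.0):
            return 0.0, 1.0
        warnings.warn(
            "paired differences have zero variance; p-value degenerates to 0",
            RuntimeWarning,
            stacklevel=2,
        )
        return math.copysign(math.inf, float(d.mean())), 0.0
    res = sps.ttest_rel(b, a)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Genotoxicity calling
# ---------------------------------------------------------------------------


@dataclass
class ScreenCall:
    chemical: str
    arm: str  # "no_inhibitor" or "hu_arac"
    verdict: str  # "+" or "-"
    significant_doses: List[float] = field(default_factory=list)
    dose_range: str = ""
    excluded_doses: List[float] = field(default_factory=list)  # viability fails

    def __post_init__(self) -> None:
        if self.verdict == "+" and not self.significant_doses:
            raise ValueError("a positive verdict requires >= 1 significant dose")


def call_genotoxicity(
    chemical: str,
    arm: str,
    doses: Sequence[float],
    dunnett: DunnettOutcome,
    viability: Optional[Mapping[float, float]] = None,
    viability_threshold: Optional[float] = None,
    dose_unit: str = "",
) -> ScreenCall:
    """Turn per-dose Dunnett outcomes into a screen verdict.

    A chemical scores "+" iff at least one dose shows a significant
    *increase* over vehicle.  When ``viability_threshold`` is given, doses
    whose surviving fraction falls below it are excluded before the verdict
    (cytotoxic fragmentation can masquerade as genotoxicity).
    """
    doses = [float(d) for d in doses]
    if len(doses) != len(dunnett.pvalues):
        raise ValueError("doses and Dunnett outcome lengths differ")
    excluded: List[float] = []
    sig: List[float] = []
    for d, is_sig in zip(doses, dunnett.significant):
        if viability_threshold is not None and viability is not None:
            if viability.get(d, 1.0) < viability_threshold:
                excluded.append(d)
                continue
        if is_sig:
            sig.append(d)
    sig.sort()
    if sig:
        unit = f" {dose_unit}" if dose_unit else ""
        rng_txt = (
            f"{sig[0]:g}{unit}"
            if len(sig) == 1
            else f"{sig[0]:g}-{sig[-1]:g}{unit}"
        )
    else:
        rng_txt = ""
    return ScreenCall(
        chemical=chemical,
        arm=arm,
        verdict="+" if sig else "-",
        significant_doses=sig,
        dose_range=rng_txt,
        excluded_doses=excluded,
    )
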