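"""Statistical layer: rank correlation, ploidy comparisons and FDR.

Ordinal phenotype scores are compared pairwise with Kendall's tau-b (tie
corrected, with a normal-approximation two-sided p-value — the standard
choice for 0-5 rubric scores, which are guaranteed to be heavily tied).
Quantitative haploid-vs-diploid comparisons use Welch's unequal-variance
two-sample t-test across technical replicates, pooled per phenotype under
Benjamini-Hochberg FDR control, producing per-strain calls of
decrease / no_change / increase.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .exceptions import ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CorrelationResult:
    """Result of a pairwise association test or fit."""

    method: str  # "kendall_tau_b" or "ols"
    statistic: float  # tau, or slope for OLS
    n: int
    p_value: float | None = None
    r_squared: float | None = None
    intercept: float | None = None


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p_value: float


@dataclass(frozen=True)
class PloidyChangeCall:
    """Per-strain, per-phenotype haploid-vs-diploid classification."""

    strain: str
    phenotype: str
    haploid_mean: float
    diploid_mean: float
    t_statistic: float
    df: float
    p_value: float
    q_value: float
    call: str  # decrease | no_change | increase


def kendall_tau(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Kendall's tau-b between two ordinal/real vectors.

    Tie-corrected; the two-sided p-value uses the tie-corrected normal
    approximation. Equivalent to exhaustive concordant/discordant pair
    counting with the tau-b tie normalization.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape:
        raise ValidationError("vectors must have equal length")
    if xa.size < 2:
        raise ValidationError("need at least two observations")
    if np.all(xa == xa[0]) or np.all(ya == ya[0]):
        raise ValidationError("correlation undefined: a vector is constant")
    res = sps.kendalltau(xa, ya, variant="b", method="asymptotic")
    return CorrelationResult(
        method="kendall_tau_b",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n=int(xa.size),
    )


def welch_test(a: Sequence[float], b: Sequence[float]) -> WelchResult:
    """Welch's two-sided unequal-variance t-test.

    ``t = (mean_a - mean_b) / sqrt(s2_a/n_a + s2_b/n_b)`` with
    Welch-Satterthwaite degrees of freedom. Two zero-variance samples with
    equal means return t = 0, p = 1.
    """
    aa = np.asarray(a, dtype=float)
    bb = np.asarray(b, dtype=float)
    if aa.size < 2 or bb.size < 2:
        raise ValidationError("each sample needs at least two values")
    if aa.var(ddof=1) == 0 and bb.var(ddof=1) == 0 and aa.mean() == bb.mean():
        return WelchResult(t=0.0, df=float(aa.size + bb.size - 2), p_value=1.0)
    res = sps.ttest_ind(aa, bb, equal_var=False)
    return WelchResult(t=float(res.statistic), df=float(res.df), p_value=float(res.pvalue))


def fdr_adjust(
    p_values: Sequence[float], alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjustment.

    Returns (q_values, significant flags); a test is significant iff its
    adjusted value is at most ``alpha``. Adjusted values are monotone in
    the p-values and never smaller than them.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValidationError("empty p-value vector")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    if not 0 < alpha < 1:
        raise ValidationError("alpha must lie in (0, 1)")
    _, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return q, q <= alpha


def ols_fit(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Ordinary least-squares line fit: slope, intercept and R^2.

    A constant response is fit as a flat line with R^2 = 0 by convention.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape:
        raise ValidationError("vectors must have equal length")
    if xa.size < 2:
        raise ValidationError("need at least two observations")
    if np.all(xa == xa[0]):
        raise ValidationError("x is constant; slope undefined")
    if np.all(ya == ya[0]):
        return CorrelationResult(
            method="ols", statistic=0.0, r_squared=0.0,
            intercept=float(ya[0]), n=int(xa.size),
        )
    res = sps.linregress(xa, ya)
    return CorrelationResult(
        method="ols",
        statistic=float(res.slope),
        r_squared=float(res.rvalue**2),
        intercept=float(res.intercept),
        n=int(xa.size),
    )


def classify_ploidy_changes(
    panel: pd.DataFrame,
    phenotypes: Iterable[str] | None = None,
    alpha: float = 0.05,
) -> list[PloidyChangeCall]:
    """Classify each strain's diploid-vs-haploid change per phenotype.

    For every strain with at least two haploid and two diploid technical
    replicate values of a phenotype, a Welch test compares the replicate
    sets; p-values are BH-adjusted within each phenotype across strains,
    and significant strains are called ``increase`` or ``decrease`` by the
    sign of (diploid mean - haploid mean), else ``no_change``. Strains
    missing either ploidy are excluded with a logged warning.
    """
    tech = panel[panel["replicate_type"] == "technical"]
    if phenotypes is None:
        phenotypes = [p for p in tech["phenotype"].unique()]
    calls: list[PloidyChangeCall] = []
    for phen in phenotypes:
        sub = tech[tech["phenotype"] == phen]
        rows = []
        for strain, grp in sub.groupby("strain", sort=True):
            hap = grp.loc[grp["ploidy"] == "haploid", "value"].dropna().to_numpy()
            dip = grp.loc[grp["ploidy"] == "diploid", "value"].dropna().to_numpy()
            if hap.size < 2 or dip.size < 2:
                logger.warning(
                    "strain %s excluded for %s: needs >=2 replicates per ploidy",
                    strain, phen,
                )
                continue
            # diploid minus haploid so the t sign matches the call direction
            res = welch_test(dip, hap)
            rows.append((strain, hap.mean(), dip.mean(), res))
        if not rows:
            continue
        q, signif = fdr_adjust([r[3].p_value for r in rows], alpha=alpha)
        for (strain, hmean, dmean, res), qv, sig in zip(rows, q, signif):
            if not sig:
                call = "no_change"
            else:
                call = "increase" if dmean > hmean else "decrease"
            calls.append(
                PloidyChangeCall(
                    strain=strain,
                    phenotype=phen,
                    haploid_mean=float(hmean),
                    diploid_mean=float(dmean),
                    t_statistic=res.t,
                    df=res.df,
                    p_value=res.p_value,
                    q_value=float(qv),
                    call=call,
                )
            )
    return calls


def summarize_ploidy_changes(calls: Iterable[PloidyChangeCall]) -> pd.DataFrame:
    """Per-phenotype decrease / no_change / increase counts (the summary
    triple reported for each quantitative assay)."""
    frame = pd.DataFrame([c.__dict__ for c in calls])
    if frame.empty:
        return pd.DataFrame(
            columns=["phenotype", "n_strains", "n_decrease", "n_no_change", "n_increase"]
        )
    out = (
        frame.groupby("phenotype")
        .agg(
            n_strains=("strain", "nunique"),
            n_decrease=("call", lambda c: int((c == "decrease").sum())),
            n_no_change=("call", lambda c: int((c == "no_change").sum())),
            n_increase=("call", lambda c: int((c == "increase").sum())),
        )
        .reset_index()
    )
    return out


def calls_to_frame(calls: Iterable[PloidyChangeCall]) -> pd.DataFrame:
    """Tabulate calls for CSV export."""
    return pd.DataFrame([c.__dict__ for c in calls])
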