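"""Statistics for analyte panels and targeted expression panels.

Covers the cytokine-panel workflow — detection filtering, per-analyte
two-sample tests, the Benjamini–Krieger–Yekutieli (BKY) two-stage step-up
FDR, analyte ratios, median-relative display matrices — and the targeted
expression workflow (fold-change / volcano tables and threshold gene
lists).

The BKY two-stage procedure is the adaptive linear step-up of Benjamini,
Krieger & Yekutieli (2006): a first-pass step-up at q' = q/(1+q) estimates
the number of true nulls m0 = m - r1; the second pass is a step-up at
q' * m / m0.  Rejections come from the second pass; reported q-values are
the smallest nominal q at which each hypothesis is rejected, obtained by
bisection (the procedure's rejection set is monotone in q).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .containers import AnalytePanel, TestResult

__all__ = [
    "filter_detected",
    "welch_t_test",
    "mann_whitney_u",
    "bky_two_stage",
    "bh_adjust",
    "ratio_feature",
    "median_relative_matrix",
    "de_table",
    "threshold_gene_list",
    "panel_group_tests",
]

logger = logging.getLogger(__name__)


def filter_detected(panel: AnalytePanel, min_detected_frac: float = 0.5) -> AnalytePanel:
    """Keep analytes detected (above floor) in >= min_detected_frac of samples."""
    if not 0.0 <= min_detected_frac <= 1.0:
        raise ValueError("min_detected_frac must be in [0, 1]")
    detected_frac = 1.0 - panel.below_floor.mean(axis=0)
    keep = detected_frac >= min_detected_frac
    dropped = list(panel.values.columns[~keep])
    if dropped:
        logger.info("filter_detected: dropping %d analytes below %.0f%% detection: %s",
                    len(dropped), 100 * min_detected_frac, dropped)
    return panel.subset_analytes(list(panel.values.columns[keep]))


def welch_t_test(x, y) -> TestResult:
    """Welch's unequal-variance two-sample t-test (two-sided).

    Degenerate case — zero variance in both groups with equal means —
    returns t = 0, p = 1 rather than NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("welch_t_test requires >= 2 observations per group")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("welch_t_test requires finite observations")
    if x.var(ddof=1) == 0.0 and y.var(ddof=1) == 0.0:
        if x.mean() == y.mean():
            return TestResult(0.0, 1.0, "welch_t", n=(x.size, y.size))
        return TestResult(np.inf if x.mean() > y.mean() else -np.inf, 0.0, "welch_t", n=(x.size, y.size))
    t, p = sps.ttest_ind(x, y, equal_var=False)
    return TestResult(float(t), float(p), "welch_t", n=(x.size, y.size))


def mann_whitney_u(x, y, exact_max_n: int = 8) -> TestResult:
    """Mann–Whitney U test with midranks for ties.

    Exact two-sided p (full permutation null) when both groups have
    n <= exact_max_n and the pooled sample is tie-free; otherwise the
    normal approximation with tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("mann_whitney_u requires nonempty groups")
    pooled = np.concatenate([x, y])
    tie_free = np.unique(pooled).size == pooled.size
    exact = tie_free and x.size <= exact_max_n and y.size <= exact_max_n
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact" if exact else "asymptotic")
    return TestResult(
        float(res.statistic), float(min(res.pvalue, 1.0)),
        "mann_whitney_exact" if exact else "mann_whitney_normal",
        n=(x.size, y.size),
    )


def _step_up_rejections(pvals: np.ndarray, level: float) -> np.ndarray:
    """Linear (BH) step-up at the given level; boolean rejection vector."""
    m = pvals.size
    order = np.argsort(pvals, kind="stable")
    sorted_p = pvals[order]
    thresh = level * np.arange(1, m + 1) / m
    below = np.flatnonzero(sorted_p <= thresh)
    reject = np.zeros(m, dtype=bool)
    if below.size:
        reject[order[: below[-1] + 1]] = True
    return reject


def _bky_reject(pvals: np.ndarray, q: float) -> np.ndarray:
    m = pvals.size
    q1 = q / (1.0 + q)
    stage1 = _step_up_rejections(pvals, q1)
    r1 = int(stage1.sum())
    if r1 == 0:
        return stage1
    if r1 == m:
        return stage1
    return _step_up_rejections(pvals, q1 * m / (m - r1))


def bky_two_stage(pvals, q: float = 0.05) -> dict:
    """BKY two-stage adaptive step-up FDR.

    Returns a dict with the boolean rejection vector (``reject``), both
    stage levels, the stage-1 rejection count, and per-hypothesis
    ``q_values`` — the smallest nominal q at which each hypothesis would be
    rejected (1.0 if never), computed by bisection.
    """
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return {"reject": np.zeros(0, bool), "q_values": np.zeros(0), "r1": 0,
                "stage1_level": q / (1 + q), "stage2_level": None, "q": q}
    if np.any((pvals < 0) | (pvals > 1) | ~np.isfinite(pvals)):
        raise ValueError("p-values must lie in [0, 1]")
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")

    m = pvals.size
    q1 = q / (1.0 + q)
    r1 = int(_step_up_rejections(pvals, q1).sum())
    reject = _bky_reject(pvals, q)
    stage2 = None if r1 in (0, m) else q1 * m / (m - r1)

    q_values = np.ones(m)
    rejectable = _bky_reject(pvals, 1.0 - 1e-12)
    for i in range(m):
        if not rejectable[i]:
            continue
        lo, hi = 0.0, 1.0 - 1e-12
        for _ in range(50):
            mid = 0.5 * (lo + hi)
            if _bky_reject(pvals, mid)[i]:
                hi = mid
            else:
                lo = mid
        q_values[i] = hi
    return {"reject": reject, "q_values": q_values, "r1": r1,
            "stage1_level": q1, "stage2_level": stage2, "q": q}


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (linear step-up)."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals.copy()
    if np.any((pvals < 0) | (pvals > 1) | ~np.isfinite(pvals)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(pvals, method="fdr_bh")[1]


def ratio_feature(panel: AnalytePanel, numerator: str, denominator: str) -> pd.Series:
    """Per-sample ratio of two analytes.

    Samples whose denominator is zero or below the detection floor are
    excluded (logged), since the ratio is not quantifiable there.
    """
    for a in (numerator, denominator):
        if a not in panel.values.columns:
            raise KeyError(f"analyte {a!r} not in panel")
    den = panel.values[denominator]
    bad = (den <= 0) | panel.below_floor[denominator]
    if bad.any():
        logger.info("ratio_feature %s/%s: excluding %d samples with zero/below-floor denominator",
                    numerator, denominator, int(bad.sum()))
    num = panel.values.loc[~bad, numerator]
    return (num / den[~bad]).rename(f"{numerator}/{denominator}")


def median_relative_matrix(panel: AnalytePanel, group_order=None) -> pd.DataFrame:
    """Analytes x samples display matrix of log2(value / analyte median).

    Below-floor values are floored at the detection floor before the median
    and the ratio.  The per-analyte median is taken on the log scale
    (geometric interpolation for even sample counts), so each displayed row
    has median exactly 0.  Analytes with a nonpositive median are skipped
    with a warning.  Sample columns are ordered by the supplied group
    ordering (supervised display; no dendrogram).
    """
    values = panel.values.clip(lower=panel.detection_floor, axis=1)
    if group_order is None:
        group_order = list(pd.unique(panel.group))
    ordered_samples = [s for g in group_order for s in panel.samples if panel.group[s] == g]
    rows = {}
    for analyte in values.columns:
        v = values[analyte]
        if v.min() <= 0 or v.median() <= 0:
            logger.warning("median_relative_matrix: analyte %s has nonpositive values, skipped", analyte)
            continue
        log_v = np.log2(v)
        rows[analyte] = log_v - log_v.median()
    return pd.DataFrame(rows).T[ordered_samples]


def panel_group_tests(
    panel: AnalytePanel,
    group_a: str,
    group_b: str,
    q: float = 0.05,
    log_scale: bool = True,
) -> pd.DataFrame:
    """Per-analyte Welch t-tests between two groups with BKY two-stage FDR.

    Concentrations are log-transformed by default (lognormal assay
    convention); set ``log_scale=False`` to test raw values.  Returns one
    row per analyte with statistic, p, BKY q-value and rejection flag.
    """
    records = []
    for analyte in panel.values.columns:
        xa = panel.group_values(analyte, group_a)
        xb = panel.group_values(analyte, group_b)
        if log_scale:
            xa, xb = np.log(np.maximum(xa, 1e-12)), np.log(np.maximum(xb, 1e-12))
        res = welch_t_test(xa, xb)
        records.append({"analyte": analyte, "statistic": res.statistic, "p": res.p})
    table = pd.DataFrame(records)
    bky = bky_two_stage(table["p"].to_numpy(), q=q)
    table["q"] = bky["q_values"]
    table["reject"] = bky["reject"]
    return table


def de_table(
    expr: pd.DataFrame,
    groups: pd.Series,
    reference: str,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-gene fold change and Welch test against a reference group.

    ``expr`` is genes x samples normalized expression; ``groups`` labels
    each sample with exactly two levels, one being ``reference``.  Fold
    change = mean(test) / mean(reference) on the linear scale, with the
    pseudocount added to both means when either is zero, so log10 fold
    change is always defined.  q is Benjamini–Hochberg.
    """
    groups = groups.reindex(expr.columns)
    if groups.isna().any():
        raise ValueError("every expression column needs a group label")
    levels = list(pd.unique(groups))
    if reference not in levels:
        raise ValueError(f"reference group {reference!r} not among group labels {levels}")
    if len(levels) != 2:
        raise ValueError(f"de_table requires exactly two groups, got {levels}")
    test_level = next(g for g in levels if g != reference)
    ref_cols = groups.index[groups == reference]
    test_cols = groups.index[groups == test_level]

    rows = []
    for gene in expr.index:
        ref_vals = expr.loc[gene, ref_cols].to_numpy(float)
        test_vals = expr.loc[gene, test_cols].to_numpy(float)
        m_ref, m_test = ref_vals.mean(), test_vals.mean()
        if m_ref <= 0 or m_test <= 0:
            m_ref, m_test = m_ref + pseudocount, m_test + pseudocount
        fc = m_test / m_ref
        res = welch_t_test(test_vals, ref_vals)
        rows.append({
            "gene": gene, "mean_test": test_vals.mean(), "mean_ref": ref_vals.mean(),
            "fold_change": fc, "log10_fc": np.log10(fc), "p": res.p,
        })
    table = pd.DataFrame(rows)
    table["q"] = bh_adjust(table["p"].to_numpy())
    table["direction"] = np.where(table["fold_change"] > 1, "up",
                                  np.where(table["fold_change"] < 1, "down", "none"))
    return table


def threshold_gene_list(
    rows: pd.DataFrame,
    fc_min: float,
    p_max: float,
    use_q: bool = False,
) -> dict[str, list[str]]:
    """Partition a DE table into up/down gene lists by fold-change and p cutoffs.

    Up: fold_change >= fc_min; down: fold_change <= 1/fc_min; both require
    p (or q when ``use_q``) < p_max.  Lists ordered by |log10 fold change|
    descending (ties by gene symbol).
    """
    if fc_min <= 0 or p_max <= 0:
        raise ValueError("thresholds must be positive")
    if rows.empty:
        return {"up": [], "down": []}
    crit = rows["q"] if use_q else rows["p"]
    passing = rows[crit < p_max]
    up = passing[passing["fold_change"] >= fc_min]
    down = passing[passing["fold_change"] <= 1.0 / fc_min]

    def ordered(frame: pd.DataFrame) -> list[str]:
        frame = frame.assign(_mag=frame["log10_fc"].abs())
        return list(frame.sort_values(["_mag", "gene"], ascending=[False, True])["gene"])

    return {"up": ordered(up), "down": ordered(down)}
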