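"""Topographic nonparametric statistics on relative power.

Two maps are produced, mirroring the usual per-head dot displays:

* between-group: a two-sided Mann-Whitney test per electrode x band x
  condition comparing responder and non-responder RPW distributions;
* within-group reactivity: a two-sided one-sample Wilcoxon signed-rank test
  of each group's RPW against 0 (no change from baseline).

p-values are corrected with the Benjamini-Hochberg step-up FDR within each
band x condition family of 19 electrodes — each head is corrected
independently. Significance is declared at q <= alpha (default 0.05).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .core import BAND_NAMES, CONDITIONS, NONRESPONDER, RESPONDER

STATMAP_COLUMNS = [
    "group", "electrode", "band", "condition", "p", "q", "significant", "test",
]


def mann_whitney(group_a, group_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Uses the exact U distribution when the combined sample size is at most
    20 and there are no ties; otherwise the normal approximation with
    midranks and tie correction. Degenerate input (an empty group, or all
    values identical across both groups) yields p = 1 with a warning.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        warnings.warn("mann_whitney: empty group, returning p = 1", stacklevel=2)
        return float("nan"), 1.0
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        warnings.warn("mann_whitney: all values identical, returning p = 1",
                      stacklevel=2)
        return float(a.size * b.size / 2), 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pooled.size <= 20 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def wilcoxon_vs_zero(values) -> float:
    """Two-sided one-sample Wilcoxon signed-rank test against 0."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("wilcoxon_vs_zero needs at least 2 observations")
    if np.all(x == 0):
        warnings.warn("wilcoxon_vs_zero: all values zero, returning p = 1",
                      stacklevel=2)
        return 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sps.wilcoxon(x, alternative="two-sided", zero_method="wilcox")
    return float(res.pvalue)


def fdr_correct(pvals, method: str = "bh") -> np.ndarray:
    """Benjamini-Hochberg (or Benjamini-Yekutieli) adjusted q-values.

    The caller defines the correction family; in this pipeline that is the
    19 electrodes of one band x condition cell.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    sm_method = {"bh": "fdr_bh", "by": "fdr_by"}[method]
    _, q, _, _ = multipletests(p, alpha=0.05, method=sm_method)
    return np.minimum(q, 1.0)


def _iter_families(rpw: pd.DataFrame, family: str):
    """Yield (band, condition, sub-frame) correction families."""
    if family == "band_condition":
        keys = [(b, c) for b in BAND_NAMES for c in CONDITIONS]
        grouped = dict(tuple(rpw.groupby(["band", "condition"], sort=False)))
        for key in keys:
            if key in grouped:
                yield key[0], key[1], grouped[key]
    elif family == "condition":
        # alternative reading: all electrodes of one interval pooled over bands
        grouped = dict(tuple(rpw.groupby("condition", sort=False)))
        for cond in CONDITIONS:
            if cond in grouped:
                yield None, cond, grouped[cond]
    else:
        raise ValueError(f"unknown FDR family {family!r}")


def group_comparison_map(
    rpw: pd.DataFrame,
    labels: dict[str, str],
    alpha: float = 0.05,
    fdr_method: str = "bh",
    family: str = "band_condition",
) -> pd.DataFrame:
    """Responder vs. non-responder Mann-Whitney map with per-family FDR.

    Returns a tidy frame with one row per electrode x band x condition:
    raw p, BH-adjusted q, and a significance flag at q <= alpha.
    """
    lab = pd.Series(labels)
    present = set(lab[lab.index.isin(rpw["subject_id"].unique())])
    if not {RESPONDER, NONRESPONDER} <= present:
        raise ValueError("both classes must be present for a group comparison")
    wide = rpw.pivot_table(index="subject_id",
                           columns=["electrode", "band", "condition"],
                           values="rpw", aggfunc="first")
    is_resp = (lab.reindex(wide.index) == RESPONDER).to_numpy()
    A = wide.to_numpy()[is_resp].T  # cells x responders
    B = wide.to_numpy()[~is_resp].T
    n_comb = A.shape[1] + B.shape[1]
    if n_comb > 20:
        # every cell takes the tie-corrected normal approximation: one
        # vectorized call over all cells
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sps.mannwhitneyu(A, B, alternative="two-sided",
                                   method="asymptotic", axis=1)
            pvals = np.minimum(np.nan_to_num(res.pvalue, nan=1.0), 1.0)
        degenerate = np.ptp(np.concatenate([A, B], axis=1), axis=1) == 0
        pvals[degenerate] = 1.0
    else:
        pvals = np.array([mann_whitney(a, b)[1] for a, b in zip(A, B)])
    pser = pd.Series(pvals, index=wide.columns)

    rows = []
    for band, cond, sub in _iter_families(
            pser.index.to_frame(index=False).assign(p=pvals), family):
        qs = fdr_correct(sub["p"].to_numpy(), method=fdr_method)
        for (_, r), q in zip(sub.iterrows(), qs):
            rows.append(("both", r["electrode"], r["band"], r["condition"],
                         r["p"], q, bool(q <= alpha), "mann-whitney"))
    return pd.DataFrame(rows, columns=STATMAP_COLUMNS)


def baseline_reactivity_map(
    rpw: pd.DataFrame,
    labels: dict[str, str],
    alpha: float = 0.05,
    fdr_method: str = "bh",
    family: str = "band_condition",
) -> pd.DataFrame:
    """Per-group reactivity-vs-baseline map (signed-rank against 0).

    One row per group x electrode x band x condition; a significant cell
    means that group's RPW distribution is shifted away from 0, i.e. genuine
    synchronization or desynchronization relative to Rest1.
    """
    lab = pd.Series(labels)
    rows = []
    for group in (RESPONDER, NONRESPONDER):
        members = set(lab[lab == group].index)
        sub_all = rpw[rpw["subject_id"].isin(members)]
        if sub_all["subject_id"].nunique() < 2:
            raise ValueError(f"group {group} needs at least 2 subjects")
        for band, cond, sub in _iter_families(sub_all, family):
            cell = sub.pivot_table(index="subject_id",
                                   columns=["electrode", "band", "condition"],
                                   values="rpw", aggfunc="first")
            ps, meta = [], []
            for col in cell.columns:
                ps.append(wilcoxon_vs_zero(cell[col].to_numpy()))
                meta.append(col)
            qs = fdr_correct(ps, method=fdr_method)
            for (ele, b, c), p, q in zip(meta, ps, qs):
                rows.append((group, ele, b, c, p, q, bool(q <= alpha),
                             "wilcoxon"))
    return pd.DataFrame(rows, columns=STATMAP_COLUMNS)
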