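"""Group-level statistics of half-life and expression.

Pairwise Welch t tests with Bonferroni adjustment across functional
categories (groups below a minimum size are dropped), Pearson
correlations, bootstrap medians to control for unequal group sizes, and
the operon-position trend summarized by per-operon least-squares slopes
and a pooled sign test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ContractError


def group_tests(values: pd.Series, groups: pd.Series,
                min_group_size: int = 50) -> dict:
    """Pairwise Welch t tests over groups, Bonferroni-adjusted.

    Groups with <= ``min_group_size`` members are excluded (by default only
    cellular functions with more than 50 genes are compared).  The raw p value of
    each pair is multiplied by the number of pairs and capped at 1.
    """
    df = pd.DataFrame({"value": values, "group": groups}).dropna()
    sizes = df.groupby("group").size()
    kept = sizes.index[sizes > min_group_size]
    if len(kept) < 2:
        raise ContractError("fewer than 2 groups pass the size filter")
    data = {g: df.loc[df["group"] == g, "value"].to_numpy(float)
            for g in kept}
    names = sorted(data)
    n_pairs = len(names) * (len(names) - 1) // 2
    adj = pd.DataFrame(np.nan, index=names, columns=names)
    for i, a in enumerate(names):
        adj.loc[a, a] = 1.0
        for b in names[i + 1:]:
            if np.var(data[a]) == 0 and np.var(data[b]) == 0:
                p = 1.0 if np.mean(data[a]) == np.mean(data[b]) else 0.0
            else:
                p = float(stats.ttest_ind(data[a], data[b],
                                          equal_var=False).pvalue)
            padj = min(1.0, p * n_pairs)
            adj.loc[a, b] = padj
            adj.loc[b, a] = padj
    return {
        "groups": {g: {"n": int(len(data[g])),
                       "median": float(np.median(data[g]))} for g in names},
        "adjusted_p": adj,
        "min_group_size": min_group_size,
    }


def correlate(x: pd.Series, y: pd.Series, subset=None,
              log_x: bool = False) -> dict:
    """Pearson correlation of two per-gene metrics on an optional subset."""
    df = pd.DataFrame({"x": x, "y": y})
    if subset is not None:
        df = df.loc[df.index.intersection(pd.Index(subset))]
    df = df.replace([np.inf, -np.inf], np.nan).dropna()
    if log_x:
        df = df[df["x"] > 0]
        df["x"] = np.log10(df["x"])
    if len(df) < 3:
        raise ContractError("need >= 3 finite pairs")
    if df["x"].std() == 0 or df["y"].std() == 0:
        raise ContractError("undefined correlation: zero variance")
    r = float(stats.pearsonr(df["x"], df["y"]).statistic)
    return {"r": r, "n": int(len(df))}


def bootstrap_medians(values: pd.Series, groups: pd.Series,
                      resample_n: int | None = None, iters: int = 1000,
                      seed: int = 0) -> pd.DataFrame:
    """Median per group under resampling to a common size.

    Each group is resampled with replacement ``iters`` times at size
    ``resample_n`` (default: the smallest group size); reports the plain
    median, the mean of bootstrap medians and a 2.5-97.5 percentile
    interval.  Empty groups are excluded.
    """
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({"value": values, "group": groups}).dropna()
    sizes = df.groupby("group").size()
    sizes = sizes[sizes > 0]
    if resample_n is None:
        resample_n = int(sizes.min())
    rows = {}
    for g in sizes.index:
        v = df.loc[df["group"] == g, "value"].to_numpy(float)
        meds = np.median(rng.choice(v, size=(iters, resample_n),
                                    replace=True), axis=1)
        rows[g] = {"n": len(v), "resample_n": resample_n,
                   "median": float(np.median(v)),
                   "bootstrap_median": float(meds.mean()),
                   "ci_low": float(np.percentile(meds, 2.5)),
                   "ci_high": float(np.percentile(meds, 97.5))}
    return pd.DataFrame.from_dict(rows, orient="index")


def operon_trend(fits: pd.DataFrame, annotation: pd.DataFrame,
                 min_members: int = 3) -> dict:
    """Half-life vs position within each operon, pooled across operons.

    For every operon with at least ``min_members`` decay-class genes, the
    least-squares slope of half-life (min) on operon index is computed; the
    pooled summary is a binomial sign test of positive vs negative slopes.
    """
    ann = annotation.set_index("gene_id")
    decay = fits[fits["class"] == "decay"].join(
        ann[["operon_id", "operon_index"]], how="inner")
    decay = decay[decay["operon_id"].fillna("") != ""]
    slopes = {}
    for op, grp in decay.groupby("operon_id"):
        if len(grp) < min_members:
            continue
        idx = grp["operon_index"].to_numpy(float)
        if len(np.unique(idx)) < 2:
            continue
        slopes[op] = float(np.polyfit(idx, grp["t_half"].to_numpy(float), 1)[0])
    s = pd.Series(slopes, dtype=float)
    nonzero = s[s != 0]
    if len(nonzero):
        test = stats.binomtest(int((nonzero > 0).sum()), len(nonzero), 0.5,
                               alternative="greater")
        sign_p = float(test.pvalue)
    else:
        sign_p = 1.0
    return {"slopes": s, "n_operons": int(len(s)),
            "fraction_positive": float((s > 0).mean()) if len(s) else np.nan,
            "sign_test_p": sign_p,
            "median_slope": float(s.median()) if len(s) else np.nan}
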