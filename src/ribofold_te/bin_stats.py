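"""Per-bin differential reactivity between the high- and low-TE groups.

For each of the 60 meta-gene bins and each probing condition, the
high/low group means are compared with a two-sample Kolmogorov-Smirnov
test over per-transcript bin values; p-values are adjusted with the
Benjamini-Hochberg step-up within each condition's 60-bin family. The
delta profile (in vivo minus in vitro group mean, per bin) measures how
much structure rearranges inside cells relative to refolded RNA.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

#: above this product of sample sizes the asymptotic KS p-value is used
EXACT_LIMIT = 10_000


def ks_two_sample(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided two-sample KS test: D = sup |ECDF_x - ECDF_y| and its p.

    Exact p when |x|*|y| <= 10,000, asymptotic Kolmogorov approximation
    otherwise. Fewer than 2 observations on either side -> (nan, nan).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if x.size < 2 or y.size < 2:
        return math.nan, math.nan
    method = "exact" if x.size * y.size <= EXACT_LIMIT else "asymp"
    res = stats.ks_2samp(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def adjust_pvalues(p: Sequence[float], method: str = "bh") -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment, returned in input order.

    Missing entries (nan) pass through and do not count toward the family
    size m.
    """
    if method.lower() not in ("bh", "fdr_bh"):
        raise ValueError(f"unsupported adjustment method {method!r}")
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    vals = p[ok]
    if np.any((vals <= 0) | (vals > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    if vals.size:
        out[ok] = multipletests(vals, method="fdr_bh")[1]
    return out


def group_bin_means(profile_df: pd.DataFrame, labels: Mapping[str, str]) -> pd.DataFrame:
    """Per-bin mean over transcripts of each TE group (nan-aware).

    ``profile_df`` is the transcripts x bins matrix of one condition;
    ``labels`` maps transcript_id -> 'high' / 'low' (other labels are
    ignored). Returns a bins x {high, low} frame.
    """
    lab = pd.Series(labels).reindex(profile_df.index)
    out = {}
    for group in ("high", "low"):
        sub = profile_df.loc[lab == group]
        out[group] = sub.mean(axis=0, skipna=True) if len(sub) else pd.Series(np.nan, index=profile_df.columns)
    df = pd.DataFrame(out)
    df.index.name = "bin"
    return df


def bin_ks_table(profile_df: pd.DataFrame, labels: Mapping[str, str]) -> pd.DataFrame:
    """KS test per bin between high and low groups + BH adjustment.

    Returns bins x {mean_high, mean_low, ks_D, p_raw, p_adj,
    neglog10_padj}; bins with fewer than two observations in a group are
    missing and excluded from the adjustment family.
    """
    lab = pd.Series(labels).reindex(profile_df.index)
    hi = profile_df.loc[lab == "high"]
    lo = profile_df.loc[lab == "low"]
    n_bins = profile_df.shape[1]
    D = np.full(n_bins, np.nan)
    p = np.full(n_bins, np.nan)
    for k in range(n_bins):
        D[k], p[k] = ks_two_sample(hi.iloc[:, k], lo.iloc[:, k])
    p_adj = adjust_pvalues(p)
    means = group_bin_means(profile_df, labels)
    out = pd.DataFrame(
        {
            "bin_index": np.arange(n_bins),
            "mean_high": means["high"].to_numpy(),
            "mean_low": means["low"].to_numpy(),
            "ks_D": D,
            "p_raw": p,
            "p_adj": p_adj,
            "neglog10_padj": -np.log10(p_adj),
        }
    ).set_index("bin_index")
    return out


def delta_profile(
    vivo_df: pd.DataFrame, vitro_df: pd.DataFrame, labels: Mapping[str, str]
) -> pd.DataFrame:
    """Per-bin (vivo group mean - vitro group mean) for each TE group.

    Missing if either condition's group mean is missing for a bin.
    Returns bins x {high, low}.
    """
    mv = group_bin_means(vivo_df, labels)
    mt = group_bin_means(vitro_df, labels)
    delta = mv - mt
    delta.index.name = "bin"
    return delta


def bin_summary(
    vivo_df: pd.DataFrame, vitro_df: pd.DataFrame, labels: Mapping[str, str]
) -> pd.DataFrame:
    """Full per-bin summary over both conditions (long format, 120 rows).

    Columns: condition, bin_index, mean_high, mean_low, ks_D, p_raw,
    p_adj, neglog10_padj, delta_high, delta_low. BH adjustment is applied
    within each condition across its bins; delta columns repeat the
    per-group vivo-minus-vitro difference for the bin.
    """
    delta = delta_profile(vivo_df, vitro_df, labels)
    frames = []
    for cond, df in (("vivo", vivo_df), ("vitro", vitro_df)):
        tab = bin_ks_table(df, labels).reset_index()
        tab.insert(0, "condition", cond)
        tab["delta_high"] = delta["high"].to_numpy()
        tab["delta_low"] = delta["low"].to_numpy()
        frames.append(tab)
    return pd.concat(frames, ignore_index=True)


def transcript_profile_report(
    transcript_id: str, vivo_df: pd.DataFrame, vitro_df: pd.DataFrame
) -> pd.DataFrame:
    """Single-transcript per-bin vivo/vitro/delta table (for profile plots)."""
    in_vivo = transcript_id in vivo_df.index
    in_vitro = transcript_id in vitro_df.index
    if not (in_vivo or in_vitro):
        raise KeyError(f"unknown transcript {transcript_id!r}")
    n_bins = (vivo_df if in_vivo else vitro_df).shape[1]
    v = vivo_df.loc[transcript_id].to_numpy() if in_vivo else np.full(n_bins, np.nan)
    w = vitro_df.loc[transcript_id].to_numpy() if in_vitro else np.full(n_bins, np.nan)
    return pd.DataFrame(
        {"bin_index": np.arange(n_bins), "vivo": v, "vitro": w, "delta": v - w}
    ).set_index("bin_index")
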