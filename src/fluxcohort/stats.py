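"""Cohort statistical conventions.

Clones are averaged within patient and replicate, then replicates within
patient, so every test sees one value per individual.  Two-group comparisons
dispatch between the unpaired two-tailed t-test and the two-tailed
Mann-Whitney U test on a per-group normality check; multi-group comparisons
use one-way ANOVA with Sidak-adjusted planned contrasts; multiplicity across
features is controlled by Benjamini-Hochberg.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "aggregate_clones_to_patients",
    "two_group_test",
    "anova_sidak",
    "adjust_fdr",
    "correlate_deg_dep",
]


def aggregate_clones_to_patients(
    df: pd.DataFrame,
    value: str = "value",
    variable: str | None = None,
) -> pd.DataFrame:
    """Two-stage mean: clones within (patient, replicate), then replicates.

    Returns one row per patient (and per variable when given) with the
    aggregated value, the condition, and the number of contributing
    observations.
    """
    keys = ["patient"] + ([variable] if variable else [])
    cond = df.groupby(keys)["condition"].first() if "condition" in df else None
    stage1 = (
        df.groupby(keys + ["replicate"], dropna=False)[value]
        .mean()
        .reset_index()
    )
    out = stage1.groupby(keys)[value].mean().reset_index()
    n = df.dropna(subset=[value]).groupby(keys)[value].count().reset_index(name="n")
    out = out.merge(n, on=keys, how="left")
    out["n"] = out["n"].fillna(0).astype(int)
    if cond is not None:
        out = out.merge(cond.reset_index(), on=keys, how="left")
    return out


def two_group_test(a, b, mode: str = "auto") -> dict:
    """Unpaired two-tailed two-group comparison on per-patient values.

    ``auto`` checks each group with Shapiro-Wilk at alpha = 0.05 and uses the
    t-test when both look Gaussian, the Mann-Whitney U test otherwise.
    Identical constant groups return p = 1 with a degenerate flag.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 patients per group")
    if np.ptp(np.concatenate([a, b])) == 0:
        return {"test": "degenerate", "statistic": 0.0, "p_value": 1.0,
                "degenerate": True}
    chosen = mode
    if mode == "auto":
        normal = all(
            np.ptp(g) > 0 and sps.shapiro(g).pvalue >= 0.05 for g in (a, b)
        )
        chosen = "t" if normal else "mann_whitney"
    if chosen == "t":
        stat, p = sps.ttest_ind(a, b)
    elif chosen == "mann_whitney":
        stat, p = sps.mannwhitneyu(a, b, alternative="two-sided")
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return {"test": chosen, "statistic": float(stat), "p_value": float(p),
            "degenerate": False}


def anova_sidak(groups: list[np.ndarray], contrasts: list[tuple[int, int]]) -> dict:
    """One-way ANOVA with Sidak-adjusted pairwise planned contrasts.

    Adjusted p for m contrasts: 1 - (1 - p_raw)^m.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) < 2 for g in groups):
        raise ValueError("every group needs n >= 2")
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if np.ptp(np.concatenate(groups)) == 0:
        f_stat, anova_p = 0.0, 1.0
    else:
        f_stat, anova_p = sps.f_oneway(*groups)
    m = len(contrasts)
    rows = []
    for i, j in contrasts:
        gi, gj = groups[i], groups[j]
        if np.ptp(np.concatenate([gi, gj])) == 0:
            p_raw = 1.0
        else:
            _, p_raw = sps.ttest_ind(gi, gj)
        rows.append(
            {
                "contrast": (i, j),
                "p_raw": float(p_raw),
                "p_adjusted": float(1.0 - (1.0 - p_raw) ** m),
            }
        )
    return {"f_statistic": float(f_stat), "anova_p": float(anova_p),
            "contrasts": rows}


def adjust_fdr(p_values, method: str = "BH") -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if method != "BH":
        raise ValueError("only Benjamini-Hochberg is supported")
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]


def correlate_deg_dep(
    deg: pd.DataFrame, dep: pd.DataFrame, key: str = "gene", fold: str = "log2fc"
) -> dict:
    """Quadrant split and per-quadrant regression of transcript vs protein folds.

    Pairs are the identifiers common to both differential tables; quadrants are
    the four sign combinations of (transcript fold, protein fold).  Quadrants
    with fewer than 3 pairs skip the regression with a flag.
    """
    merged = deg[[key, fold]].merge(
        dep[[key, fold]], on=key, suffixes=("_deg", "_dep")
    )
    x = merged[f"{fold}_deg"].to_numpy()
    y = merged[f"{fold}_dep"].to_numpy()
    quadrants = {
        "down_down": (x < 0) & (y < 0),
        "up_up": (x > 0) & (y > 0),
        "down_up": (x < 0) & (y > 0),
        "up_down": (x > 0) & (y < 0),
    }
    out = {"n_pairs": len(merged), "quadrants": {}}
    for name, mask in quadrants.items():
        n = int(mask.sum())
        entry = {"n": n}
        if n >= 3 and np.ptp(x[mask]) > 0 and np.ptp(y[mask]) > 0:
            r, p = sps.pearsonr(x[mask], y[mask])
            entry |= {"r": float(r), "p_value": float(p), "skipped": False}
        else:
            entry |= {"r": None, "p_value": None, "skipped": True}
        out["quadrants"][name] = entry
    return out
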