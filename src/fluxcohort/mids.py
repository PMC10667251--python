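"""MID post-processing: natural-abundance correction, fractional contribution,
isotopologue-ratio flux diagnostics, and nested group comparison.

The four ratio diagnostics summarize citric-acid-cycle routing directly from
isotopologue fractions, without a flux fit:

* ``cycling_M4M2_citrate`` — M4/M2 citrate under U-13C glucose: multi-turn
  cycling of labeled oxaloacetate back through citrate synthase.
* ``oxidative_M3M5_glutamate`` — M3/M5 glutamate under U-13C glutamine: carbon
  that completed an oxidative turn versus first-pass glutamine carbon.
* ``reductive_M5cit_M5glu`` — M5 citrate / M5 glutamate under U-13C glutamine:
  reductive carboxylation of alpha-ketoglutarate toward citrate.
* ``ogdhc_M4suc_M5akg`` — M4 succinate / M5 alpha-ketoglutarate under U-13C
  glutamine: throughput of the alpha-ketoglutarate dehydrogenase complex.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "NATURAL_13C_ABUNDANCE",
    "RATIO_DIAGNOSTICS",
    "RatioDiagnostic",
    "correction_matrix",
    "correct_natural_abundance",
    "add_natural_abundance",
    "fractional_contribution",
    "compute_ratio",
    "ratio_table",
    "compare_groups_lmm",
]

NATURAL_13C_ABUNDANCE = 0.0107


def correction_matrix(n_carbons: int, abundance: float = NATURAL_13C_ABUNDANCE):
    """Lower-triangular matrix C with C[i, j] = P(observed shift i | j tracer
    carbons), from binomial natural 13C labeling of the n - j remaining
    backbone carbons.  Columns sum to <= 1 (shifts beyond n are truncated)."""
    if not (0.0 <= abundance < 0.5):
        raise ValueError("abundance must be in [0, 0.5)")
    n = n_carbons
    C = np.zeros((n + 1, n + 1))
    for j in range(n + 1):
        rest = n - j
        pmf = stats.binom.pmf(np.arange(rest + 1), rest, abundance)
        for k, p in enumerate(pmf):
            if j + k <= n:
                C[j + k, j] = p
    return C


def correct_natural_abundance(
    raw: np.ndarray, n_carbons: int, abundance: float = NATURAL_13C_ABUNDANCE
) -> np.ndarray:
    """Remove natural-abundance contamination from a measured MID.

    Solves ``raw ~ C x`` by nonnegative least squares and renormalizes x to
    sum 1; the exact inverse of :func:`add_natural_abundance` on noise-free
    data.
    """
    raw = np.asarray(raw, dtype=float)
    if len(raw) != n_carbons + 1:
        raise ValueError("MID length must be n_carbons + 1")
    C = correction_matrix(n_carbons, abundance)
    x, _ = optimize.nnls(C, raw)
    s = x.sum()
    if s <= 0:
        raise ValueError("correction produced an all-zero MID")
    return x / s


def add_natural_abundance(
    true_mid: np.ndarray, n_carbons: int, abundance: float = NATURAL_13C_ABUNDANCE
) -> np.ndarray:
    """Forward-contaminate a true MID with natural abundance (for round trips)."""
    C = correction_matrix(n_carbons, abundance)
    out = C @ np.asarray(true_mid, dtype=float)
    return out / out.sum()


def fractional_contribution(
    mid: np.ndarray, n_carbons: int, mode: str = "weighted"
) -> float:
    """Fraction of a metabolite's carbon derived from the labeled tracer.

    ``weighted`` (default): sum_i i*M_i / n — each isotopologue counts by how
    many labeled carbons it carries, so a fully labeled metabolite scores 1.
    ``as_stated``: sum_{i>=1} M_i / n — the labeled-fraction sum divided by the
    carbon count; kept selectable for literal reproduction of that convention.
    """
    if n_carbons < 1:
        raise ValueError("n_carbons must be >= 1")
    mid = np.asarray(mid, dtype=float)
    if mode == "weighted":
        return float(np.arange(len(mid)) @ mid / n_carbons)
    if mode == "as_stated":
        return float(mid[1:].sum() / n_carbons)
    raise ValueError(f"unknown mode {mode!r}")


@dataclass(frozen=True)
class RatioDiagnostic:
    name: str
    tracer: str  # tracer id required for this diagnostic
    numerator: tuple[str, int]  # (metabolite, mass shift)
    denominator: tuple[str, int]


RATIO_DIAGNOSTICS = {
    d.name: d
    for d in [
        RatioDiagnostic(
            "cycling_M4M2_citrate", "U13C-glucose", ("Cit", 4), ("Cit", 2)
        ),
        RatioDiagnostic(
            "oxidative_M3M5_glutamate", "U13C-glutamine", ("Glu", 3), ("Glu", 5)
        ),
        RatioDiagnostic(
            "reductive_M5cit_M5glu", "U13C-glutamine", ("Cit", 5), ("Glu", 5)
        ),
        RatioDiagnostic(
            "ogdhc_M4suc_M5akg", "U13C-glutamine", ("Suc", 4), ("AKG", 5)
        ),
    ]
}


def compute_ratio(
    name: str, mids: dict[str, np.ndarray], tracer: str
) -> float:
    """One diagnostic value for one sample's MIDs (keyed by metabolite).

    Returns NaN (an undefined-value signal, excluded pairwise downstream) when
    the denominator fraction is zero.
    """
    diag = RATIO_DIAGNOSTICS[name]
    if tracer != diag.tracer:
        raise ValueError(
            f"{name} is defined for tracer {diag.tracer!r}, got {tracer!r}"
        )
    num_met, num_i = diag.numerator
    den_met, den_i = diag.denominator
    num = float(mids[num_met][num_i])
    den = float(mids[den_met][den_i])
    if den == 0.0:
        return float("nan")
    return num / den


def ratio_table(mid_table) -> pd.DataFrame:
    """All applicable diagnostics per sample from a MidMeasurementTable."""
    df = mid_table.df
    rows = []
    keys = ["patient", "clone", "replicate", "condition", "tracer"]
    for sample_keys, g in df.groupby(keys, sort=True):
        tracer = sample_keys[-1]
        mids = {}
        for met, gm in g.groupby("metabolite"):
            mids[met] = gm.sort_values("mass_shift")["fraction"].to_numpy()
        for name, diag in RATIO_DIAGNOSTICS.items():
            if diag.tracer != tracer:
                continue
            if diag.numerator[0] not in mids or diag.denominator[0] not in mids:
                continue
            val = compute_ratio(name, mids, tracer)
            rows.append(dict(zip(keys, sample_keys)) | {"diagnostic": name, "value": val})
    return pd.DataFrame(rows)


def compare_groups_lmm(
    df: pd.DataFrame,
    value: str = "value",
    condition: str = "condition",
    group: str = "patient",
) -> dict:
    """Fixed condition effect with a random intercept per nesting unit.

    Fits value ~ condition + (1 | patient) by REML and tests the fixed effect
    with a Wald chi-square.  When the random-intercept variance is estimated at
    the boundary (zero), the model degenerates to ordinary regression with
    overcounted degrees of freedom; the comparison then falls back to a
    two-sample t-test on per-patient means and flags the fallback.
    """
    import warnings

    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    data = df[[value, condition, group]].dropna().copy()
    levels = sorted(data[condition].unique())
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 conditions, got {levels}")
    counts = data.groupby(condition)[value].count()
    if (counts < 2).any():
        raise ValueError("a condition has fewer than 2 observations")
    data["_y"] = data[value]
    data["_c"] = (data[condition] == levels[1]).astype(float)
    if data["_y"].std(ddof=0) == 0:
        return {
            "effect": 0.0, "p_value": 1.0, "fallback_ttest": False,
            "degenerate": True, "conditions": levels,
        }
    fit = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM.from_formula("_y ~ _c", groups=data[group], data=data)
        for method in ("lbfgs", "powell", "cg"):
            try:
                fit = model.fit(reml=True, method=method)
            except (np.linalg.LinAlgError, ValueError):
                continue
            if np.isfinite(fit.params["_c"]) and np.isfinite(fit.bse["_c"]):
                break
        else:
            fit = None
    if fit is None:
        # optimizer failure: degenerate likelihood surface; use the
        # per-patient-means fallback
        means = data.groupby([group, condition])["_y"].mean().reset_index()
        a = means.loc[means[condition] == levels[0], "_y"]
        b = means.loc[means[condition] == levels[1], "_y"]
        t, p = stats.ttest_ind(a, b)
        return {
            "effect": float(b.mean() - a.mean()),
            "p_value": float(p),
            "fallback_ttest": True,
            "degenerate": False,
            "conditions": levels,
        }
    re_var = float(fit.cov_re.iloc[0, 0]) if fit.cov_re.size else 0.0
    resid_var = float(fit.scale)
    boundary = re_var <= 1e-6 * max(resid_var, 1e-300)
    if boundary:
        means = data.groupby([group, condition])["_y"].mean().reset_index()
        a = means.loc[means[condition] == levels[0], "_y"]
        b = means.loc[means[condition] == levels[1], "_y"]
        t, p = stats.ttest_ind(a, b)
        return {
            "effect": float(b.mean() - a.mean()),
            "p_value": float(p),
            "fallback_ttest": True,
            "degenerate": False,
            "conditions": levels,
        }
    effect = float(fit.params["_c"])
    se = float(fit.bse["_c"])
    wald = (effect / se) ** 2
    p = float(stats.chi2.sf(wald, 1))
    return {
        "effect": effect,
        "p_value": p,
        "fallback_ttest": False,
        "degenerate": False,
        "conditions": levels,
        "random_effect_var": re_var,
    }
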