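"""Multiple-factor analysis (Escofier-Pages) over heterogeneous variable blocks.

Each active block is column-standardized (mean 0, population SD 1) and then
divided by its first singular value, so no single block can dominate the first
global axis; a global SVD of the weighted concatenation yields eigenvalues,
patient coordinates and per-block contributions.  Supplementary blocks (e.g. a
disease-state indicator) are projected onto the axes without influencing them.
With a single active block the first eigenvalue is exactly 1 by construction.

Also hosts the progression correlogram: pairwise-complete Pearson correlation
of per-patient features with clinical deltas, flagged significant at p < 0.1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import ClinicalRecord

__all__ = [
    "VariableBlock",
    "FactorModel",
    "multiple_factor_analysis",
    "group_contributions",
    "correlate_with_progression",
]


@dataclass
class VariableBlock:
    name: str
    data: pd.DataFrame  # patients x variables
    supplementary: bool = False


@dataclass
class FactorModel:
    eigenvalues: np.ndarray
    percent_variance: np.ndarray
    coordinates: pd.DataFrame  # patients x dims
    block_weights: dict[str, float]  # 1 / first singular value
    block_contributions: pd.DataFrame  # blocks x dims, percent
    supplementary_coordinates: dict[str, pd.DataFrame] = field(default_factory=dict)
    group_barycenters: pd.DataFrame | None = None

    @property
    def n_dims(self) -> int:
        return len(self.eigenvalues)


def _standardize(df: pd.DataFrame, block: str) -> np.ndarray:
    X = df.to_numpy(dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)  # population SD, canonical for this weighting
    if (sd == 0).any():
        bad = df.columns[np.where(sd == 0)[0][0]]
        raise ValueError(f"block {block!r}: constant column {bad!r}")
    return (X - mu) / sd


def multiple_factor_analysis(blocks: list[VariableBlock]) -> FactorModel:
    active = [b for b in blocks if not b.supplementary]
    if not active:
        raise ValueError("need at least one active block")
    index = active[0].data.index
    for b in blocks:
        if not b.data.index.equals(index):
            raise ValueError(f"block {b.name!r} has a mismatched patient index")
    if len(index) < 3:
        raise ValueError("need at least 3 patients")
    if any(b.data.isna().any().any() for b in active):
        raise ValueError("active blocks must not contain missing cells")

    weights: dict[str, float] = {}
    pieces = []
    col_block = []
    for b in active:
        Z = _standardize(b.data, b.name)
        s1 = np.linalg.svd(Z, compute_uv=False)[0]
        weights[b.name] = 1.0 / s1
        pieces.append(Z / s1)
        col_block.extend([b.name] * Z.shape[1])
    G = np.hstack(pieces)
    U, s, Vt = np.linalg.svd(G, full_matrices=False)
    keep = s > 1e-12 * s[0]
    U, s, Vt = U[:, keep], s[keep], Vt[keep]
    eig = s**2
    pct = 100.0 * eig / eig.sum()
    dims = [f"dim{k+1}" for k in range(len(eig))]
    coords = pd.DataFrame(U * s, index=index, columns=dims)

    # contribution of each block to each dimension: share of the axis inertia
    # carried by the block's columns
    col_block = np.array(col_block)
    contrib = np.zeros((len(active), len(eig)))
    for bi, b in enumerate(active):
        mask = col_block == b.name
        contrib[bi] = 100.0 * (Vt[:, mask] ** 2).sum(axis=1)
    block_contributions = pd.DataFrame(
        contrib, index=[b.name for b in active], columns=dims
    )

    model = FactorModel(
        eigenvalues=eig,
        percent_variance=pct,
        coordinates=coords,
        block_weights=weights,
        block_contributions=block_contributions,
    )

    for b in blocks:
        if not b.supplementary:
            continue
        df = b.data.copy()
        if df.select_dtypes(exclude="number").shape[1] > 0:
            # categorical supplementary group: barycenters of patient
            # coordinates per level (plus per-level coordinate covariance,
            # the numerical summary of a confidence ellipse)
            cat = df.iloc[:, 0].astype(str)
            rows = []
            for level, members in coords.groupby(cat):
                rows.append(
                    {"block": b.name, "level": level, "n": len(members)}
                    | {d: members[d].mean() for d in dims}
                )
            model.group_barycenters = pd.DataFrame(rows)
        else:
            Z = _standardize(df, b.name)
            s1 = np.linalg.svd(Z, compute_uv=False)[0]
            proj = (Z / s1).T @ U  # variable coordinates on the unit axes
            model.supplementary_coordinates[b.name] = pd.DataFrame(
                proj, index=df.columns, columns=dims
            )
    return model


def group_contributions(model: FactorModel, dim: int) -> pd.Series:
    """Percent contribution of each active block to dimension ``dim`` (1-based)."""
    if not 1 <= dim <= model.n_dims:
        raise ValueError(f"dimension {dim} outside 1..{model.n_dims}")
    return model.block_contributions[f"dim{dim}"]


def correlate_with_progression(
    features: pd.DataFrame,
    clinical: list[ClinicalRecord],
    spd_only: bool = True,
    conditions: pd.Series | None = None,
    alpha: float = 0.1,
) -> pd.DataFrame:
    """Correlogram of per-patient features against clinical deltas.

    Pairwise-complete Pearson R with two-sided p; patients without follow-up
    are excluded pairwise; cells with fewer than 3 complete pairs are marked
    not computable.  Significance is flagged at p < ``alpha`` (default 0.1).
    """
    clin = {
        r.patient: r.deltas() for r in clinical if r.followup_available
    }
    rows = []
    feats = features
    if spd_only and conditions is not None:
        feats = features.loc[conditions == "sPD"]
    delta_names = ["dHY", "dUPDRS3", "dLDopa_mg", "dADL"]
    for col in feats.columns:
        for dname in delta_names:
            x, y = [], []
            for pat in feats.index:
                if pat in clin and clin[pat][dname] is not None:
                    v = feats.loc[pat, col]
                    if not pd.isna(v):
                        x.append(float(v))
                        y.append(float(clin[pat][dname]))
            if len(x) < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
                rows.append(
                    {"feature": col, "delta": dname, "r": np.nan, "p_value": np.nan,
                     "n": len(x), "significant": False, "computable": False}
                )
                continue
            r, p = sps.pearsonr(x, y)
            rows.append(
                {"feature": col, "delta": dname, "r": float(r),
                 "p_value": float(p), "n": len(x),
                 "significant": bool(p < alpha), "computable": True}
            )
    return pd.DataFrame(rows)
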