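import numpy as np
import pandas as pd
import pytest

from fluxcohort.io import ClinicalRecord
from fluxcohort.mfa import (
    VariableBlock,
    correlate_with_progression,
    group_contributions,
    multiple_factor_analysis,
)


def _block(rng, n_pat=9, n_var=5, name="b"):
    idx = [f"P{i}" for i in range(n_pat)]
    return VariableBlock(
        name, pd.DataFrame(rng.normal(size=(n_pat, n_var)), index=idx,
                           columns=[f"{name}{j}" for j in range(n_var)])
    )


class TestEigenstructure:
    def test_single_block_first_eigenvalue_is_one(self):
        rng = np.random.default_rng(0)
        model = multiple_factor_analysis([_block(rng)])
        assert model.eigenvalues[0] == pytest.approx(1.0, abs=1e-12)

    def test_duplicated_block_first_eigenvalue_is_two(self):
        rng = np.random.default_rng(1)
        b = _block(rng)
        b2 = VariableBlock("copy", b.data.copy())
        model = multiple_factor_analysis([b, b2])
        assert model.eigenvalues[0] == pytest.approx(2.0, abs=1e-10)
        contrib = group_contributions(model, 1)
        assert contrib["b"] == pytest.approx(50.0, abs=1e-6)
        assert contrib["copy"] == pytest.approx(50.0, abs=1e-6)

    def test_three_block_fixture_matches_gram_matrix_oracle(self):
        """Eigenvalues/coordinates via an independent route: eigendecomposition
        of the Gram matrix of the weighted concatenation."""
        rng = np.random.default_rng(2)
        blocks = [_block(rng, name=n, n_var=v)
                  for n, v in (("a", 4), ("b", 6), ("c", 3))]
        model = multiple_factor_analysis(blocks)
        pieces = []
        for b in blocks:
            X = b.data.to_numpy()
            Z = (X - X.mean(0)) / X.std(0)
            pieces.append(Z / np.linalg.svd(Z, compute_uv=False)[0])
        G = np.hstack(pieces)
        lam, V = np.linalg.eigh(G @ G.T)
        lam = lam[::-1]
        keep = lam > 1e-10
        np.testing.assert_allclose(model.eigenvalues, lam[keep], atol=1e-8)
        # coordinates agree up to per-axis sign
        coords = model.coordinates.to_numpy()
        V = V[:, ::-1][:, keep]
        proj = V * np.sqrt(lam[keep])
        for k in range(coords.shape[1]):
            assert (
                np.allclose(coords[:, k], proj[:, k], atol=1e-8)
                or np.allclose(coords[:, k], -proj[:, k], atol=1e-8)
            )

    def test_percent_variance_sums_to_100(self):
        rng = np.random.default_rng(3)
        model = multiple_factor_analysis([_block(rng), _block(rng, name="c")])
        assert model.percent_variance.sum() == pytest.approx(100.0)

    def test_block_scaling_invariance(self):
        rng = np.random.default_rng(4)
        b = _block(rng)
        scaled = VariableBlock("b", b.data * 37.5)
        m1 = multiple_factor_analysis([b, _block(rng, name="c")])
        rng = np.random.default_rng(4)
        b = _block(rng)
        m2 = multiple_factor_analysis([scaled, _block(rng, name="c")])
        np.testing.assert_allclose(m1.eigenvalues, m2.eigenvalues, atol=1e-10)

    def test_patient_permutation_permutes_coordinates(self):
        rng = np.random.default_rng(5)
        b1, b2 = _block(rng), _block(rng, name="c")
        model = multiple_factor_analysis([b1, b2])
        perm = np.random.default_rng(0).permutation(len(b1.data))
        pb1 = VariableBlock("b", b1.data.iloc[perm])
        pb2 = VariableBlock("c", b2.data.iloc[perm])
        pmodel = multiple_factor_analysis([pb1, pb2])
        np.testing.assert_allclose(
            pmodel.coordinates.to_numpy(),
            model.coordinates.iloc[perm].to_numpy(),
            atol=1e-8,
        )

    def test_constant_column_rejected_by_name(self):
        rng = np.random.default_rng(6)
        b = _block(rng)
        b.data["b2"] = 1.0
        with pytest.raises(ValueError, match="b2"):
            multiple_factor_analysis([b])

    def test_mismatched_patient_index_rejected(self):
        rng = np.random.default_rng(7)
        a = _block(rng)
        c = _block(rng, name="c")
        c.data.index = [f"Q{i}" for i in range(len(c.data))]
        with pytest.raises(ValueError, match="index"):
            multiple_factor_analysis([a, c])

    def test_supplementary_group_projected_not_fitted(self):
        rng = np.random.default_rng(8)
        active = [_block(rng), _block(rng, name="c")]
        cat = VariableBlock(
            "disease",
            pd.DataFrame({"state": ["Ctrl"] * 4 + ["sPD"] * 5},
                         index=active[0].data.index),
            supplementary=True,
        )
        with_supp = multiple_factor_analysis(active + [cat])
        without = multiple_factor_analysis(active)
        np.testing.assert_allclose(
            with_supp.eigenvalues, without.eigenvalues, atol=1e-12
        )
        assert "disease" not in with_supp.block_contributions.index
        assert set(with_supp.group_barycenters["level"]) == {"Ctrl", "sPD"}

    def test_contribution_dimension_bounds(self):
        rng = np.random.default_rng(9)
        model = multiple_factor_analysis([_block(rng)])
        with pytest.raises(ValueError):
            group_contributions(model, model.n_dims + 1)


class TestProgressionCorrelation:
    def _records(self, vals):
        return [
            ClinicalRecord(p, d, 0.0 + i, 100.0 + i, -0.1 * i)
            for i, (p, d) in enumerate(vals.items())
        ]

    def test_perfectly_linear_feature_flagged_significant(self):
        pats = [f"P{i}" for i in range(6)]
        d_hy = {p: float(i) for i, p in enumerate(pats)}
        feats = pd.DataFrame({"f": [2.0 * i + 1 for i in range(6)]}, index=pats)
        table = correlate_with_progression(feats, self._records(d_hy),
                                           spd_only=False)
        row = table[(table.feature == "f") & (table.delta == "dHY")].iloc[0]
        assert row["r"] == pytest.approx(1.0)
        assert row["significant"]

    def test_missing_followup_excluded_pairwise(self):
        pats = [f"P{i}" for i in range(6)]
        recs = self._records({p: float(i) for i, p in enumerate(pats)})
        recs[2] = ClinicalRecord("P2", None, None, None, None,
                                 followup_available=False)
        feats = pd.DataFrame({"f": np.arange(6.0)}, index=pats)
        table = correlate_with_progression(feats, recs, spd_only=False)
        assert (table["n"] == 5).all()

    def test_too_few_pairs_not_computable(self):
        pats = ["P0", "P1", "P2"]
        recs = self._records({p: float(i) for i, p in enumerate(pats)})[:2]
        feats = pd.DataFrame({"f": [1.0, 2.0, 3.0]}, index=pats)
        table = correlate_with_progression(feats, recs, spd_only=False)
        assert not table["computable"].any()
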