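"""C/N derivation, feature assembly, and the topology-chemistry PCA."""

import numpy as np
import pandas as pd
import pytest

from micronet import (
    TopologyChemistryPCA,
    assemble_feature_matrix,
    cn_ratio,
    topology_chemistry_pca,
)
from micronet.chemlink import ChemistryError, aggregate_chemistry, validate_chemistry
from micronet.reference import PUBLISHED_CN, soil_chemistry


class TestCnRatio:
    def test_reference_spot_values(self):
        assert cn_ratio(86.4, 8.54) == pytest.approx(10.1, abs=0.05)  # mountain grassland
        assert cn_ratio(28.5, 2.12) == pytest.approx(13.4, abs=0.05)  # subalpine shrubland
        assert cn_ratio(5.0, 5.0) == 1.0

    def test_all_reference_ecosystems(self):
        chem = soil_chemistry()
        derived = cn_ratio(chem["OC"], chem["TN"])
        for eco, printed in PUBLISHED_CN.items():
            assert derived[eco] == pytest.approx(printed, abs=0.05)

    def test_nonpositive_tn_rejected(self):
        with pytest.raises(ChemistryError, match="nitrogen"):
            cn_ratio(10.0, 0.0)


class TestChemistryValidation:
    def test_texture_sum_bound(self):
        bad = pd.DataFrame({"ecosystem": ["x"], "sand": [800], "loam": [300],
                            "clay": [100], "pH": [7.0]})
        with pytest.raises(ChemistryError, match="1000"):
            validate_chemistry(bad)

    def test_cn_derived_when_missing(self):
        chem = pd.DataFrame({"ecosystem": ["x"], "OC": [20.0], "TN": [2.0], "pH": [7.0]})
        out = validate_chemistry(chem)
        assert out["CN"].iloc[0] == 10.0

    def test_replicates_average_per_ecosystem(self):
        chem = pd.DataFrame({
            "ecosystem": ["a", "a", "b"], "replicate": [0, 1, 0],
            "OC": [10.0, 20.0, 30.0], "TN": [1.0, 1.0, 2.0], "pH": [6, 7, 8],
        })
        agg = aggregate_chemistry(chem)
        assert agg.loc["a", "OC"] == 15.0
        assert agg.loc["b", "pH"] == 8.0


def make_inputs(n_eco=12):
    rng = np.random.default_rng(0)
    ecosystems = [f"eco{i}" for i in range(n_eco)]
    topo = pd.DataFrame({
        "n_nodes": rng.integers(100, 500, n_eco),
        "n_edges": rng.integers(200, 10000, n_eco),
        "average_degree": rng.uniform(3, 70, n_eco),
        "density": rng.uniform(0.01, 0.4, n_eco),
        "average_clustering": rng.uniform(0.1, 0.9, n_eco),
        "average_path_length": rng.uniform(1, 6, n_eco),
        "diameter": rng.integers(2, 12, n_eco),
        "modularity_Q": rng.uniform(0.2, 0.95, n_eco),
        "n_modules": rng.integers(2, 20, n_eco),
    }, index=pd.Index(ecosystems, name="ecosystem"))
    chem = pd.DataFrame({
        "ecosystem": np.repeat(ecosystems, 2),
        "pH": rng.uniform(5, 9, 2 * n_eco),
        "TN": rng.uniform(0.5, 10, 2 * n_eco),
        "OC": rng.uniform(5, 90, 2 * n_eco),
        "P2O5": rng.uniform(10, 280, 2 * n_eco),
    })
    div = pd.DataFrame({
        "shannon_bacteria": rng.uniform(2, 5, n_eco),
        "shannon_fungi": rng.uniform(1, 4, n_eco),
    }, index=pd.Index(ecosystems, name="ecosystem"))
    return topo, chem, div


class TestFeatureMatrix:
    def test_shape_contract(self):
        topo, chem, div = make_inputs()
        feats = assemble_feature_matrix(topo, chem, div)
        assert feats.shape == (12, 14)
        assert not feats.isna().any().any()

    def test_missing_ecosystem_named(self):
        topo, chem, div = make_inputs()
        chem = chem[chem["ecosystem"] != "eco3"]
        with pytest.raises(ChemistryError, match="eco3"):
            assemble_feature_matrix(topo, chem, div)

    def test_too_few_ecosystems(self):
        topo, chem, div = make_inputs(2)
        with pytest.raises(ChemistryError, match=">= 3"):
            assemble_feature_matrix(topo, chem, div)


class TestPca:
    def test_two_variable_closed_form(self):
        """z-scored pair with correlation r has ratios ((1+r)/2, (1-r)/2)."""
        rng = np.random.default_rng(3)
        x = rng.normal(size=400)
        y = 0.8 * x + np.sqrt(1 - 0.64) * rng.normal(size=400)
        df = pd.DataFrame({"x": x, "y": y})
        r = np.corrcoef(df["x"], df["y"])[0, 1]
        res = topology_chemistry_pca(df)
        expected = np.sort([(1 + r) / 2, (1 - r) / 2])[::-1]
        np.testing.assert_allclose(res.explained_variance_ratio, expected, atol=1e-8)

    def test_reconstruction_identity(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(12, 5)))
        est = TopologyChemistryPCA().fit(df)
        Z = (df.to_numpy() - est.mean_) / est.scale_
        recon = est.scores_.to_numpy() @ est.loadings_.to_numpy().T
        np.testing.assert_allclose(recon, Z, atol=1e-8)

    def test_loadings_orthonormal_and_sign_convention(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.normal(size=(20, 6)))
        est = TopologyChemistryPCA().fit(df)
        L = est.loadings_.to_numpy()
        np.testing.assert_allclose(L.T @ L, np.eye(L.shape[1]), atol=1e-8)
        for col in est.loadings_.columns:
            v = est.loadings_[col].to_numpy()
            assert v[np.abs(v).argmax()] > 0

    def test_ratios_non_increasing_and_bounded(self):
        topo, chem, div = make_inputs()
        res = topology_chemistry_pca(assemble_feature_matrix(topo, chem, div))
        evr = res.explained_variance_ratio
        assert np.all(np.diff(evr) <= 1e-12)
        assert np.all((evr >= 0) & (evr <= 1))
        assert evr.sum() <= 1 + 1e-9

    def test_row_order_invariance(self):
        topo, chem, div = make_inputs()
        feats = assemble_feature_matrix(topo, chem, div)
        r1 = topology_chemistry_pca(feats).explained_variance_ratio
        r2 = topology_chemistry_pca(feats.iloc[::-1]).explained_variance_ratio
        np.testing.assert_allclose(r1, r2, atol=1e-10)

    def test_duplicated_column_never_shrinks_top_eigenvalue(self):
        """The old correlation matrix interlaces the augmented one, so the
        leading eigenvalue cannot decrease when a column is duplicated; the
        PCA route must agree with a direct eigen-decomposition."""
        rng = np.random.default_rng(7)
        for _ in range(10):
            df = pd.DataFrame(rng.normal(size=(5, 4)), columns=list("abcd"))
            base_l1 = topology_chemistry_pca(df).explained_variance_ratio[0] * 4
            dup = df.copy()
            dup["a2"] = df["a"]
            with_dup_l1 = topology_chemistry_pca(dup).explained_variance_ratio[0] * 5
            # eigen-oracle on the correlation matrix agrees with the PCA route
            eig = np.linalg.eigvalsh(np.corrcoef(dup.to_numpy().T))[::-1]
            assert with_dup_l1 == pytest.approx(eig[0], abs=1e-8)
            assert with_dup_l1 >= base_l1 - 1e-10

    def test_constant_column_named(self):
        df = pd.DataFrame({"a": [1.0, 2, 3, 4], "flat": [5.0, 5, 5, 5]})
        with pytest.raises(ChemistryError, match="flat"):
            topology_chemistry_pca(df)

    def test_missing_values_located(self):
        df = pd.DataFrame({"a": [1.0, np.nan, 3, 4], "b": [1.0, 2, 3, 4]})
        with pytest.raises(ChemistryError, match="missing"):
            topology_chemistry_pca(df)

    def test_planted_chemistry_axis_clusters_connectivity_loadings(self):
        """When connectivity features are noisy linear functions of OC/TN,
        their PC1 loadings co-vary with the OC/TN loadings (same sign)."""
        rng = np.random.default_rng(42)
        n = 12
        oc = rng.uniform(5, 90, n)
        tn = oc / 10 + rng.normal(0, 0.5, n)
        feats = pd.DataFrame({
            "OC": oc,
            "TN": tn,
            "n_edges": 100 * oc + rng.normal(0, 60, n),
            "n_nodes": 5 * oc + rng.normal(0, 30, n),
            "average_degree": 0.8 * oc + rng.normal(0, 5, n),
            "pH": rng.uniform(5, 9, n),
        })
        res = topology_chemistry_pca(feats)
        pc1 = res.loadings["PC1"]
        planted = ["OC", "TN", "n_edges", "n_nodes", "average_degree"]
        signs = np.sign(pc1[planted])
        assert (signs == signs.iloc[0]).all()
        assert np.abs(pc1[planted]).min() > np.abs(pc1["pH"])
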