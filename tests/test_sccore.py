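import anndata as ad
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from lysompn import sccore, synthio


def _adata(x, genes, groups=None, cell_types=None, sample_ids=None):
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    obs = pd.DataFrame(index=[f"c{i}" for i in range(n)])
    obs["group"] = groups if groups is not None else ["g"] * n
    obs["cell_type"] = cell_types if cell_types is not None else ["t"] * n
    obs["sample_id"] = sample_ids if sample_ids is not None else ["s"] * n
    return ad.AnnData(
        X=sp.csr_matrix(x),
        obs=obs,
        var=pd.DataFrame(index=genes),
    )


class TestQC:
    def test_qc_metrics(self):
        x = [[5, 0, 5], [0, 0, 0], [2, 8, 0]]
        adata = sccore.compute_qc(_adata(x, ["MT-CO1", "A", "B"]))
        assert adata.obs["n_umi"].tolist() == [10, 0, 10]
        assert adata.obs["n_genes_detected"].tolist() == [2, 0, 2]
        np.testing.assert_allclose(adata.obs["pct_mito"], [0.5, 0.0, 0.2])

    def test_filter_reasons(self):
        x = [[200, 50], [1, 1], [0, 300]]
        adata = _adata(x, ["MT-CO1", "A"])
        kept, report = sccore.qc_filter(adata, min_umi=10, max_pct_mito=0.6)
        reasons = dict(zip(report["cell_id"], report["removed_reason"]))
        assert reasons == {"c0": "high_mito", "c1": "low_umi", "c2": ""}
        assert kept.n_obs == 1

    def test_all_removed_raises(self):
        adata = _adata([[1, 1]], ["A", "B"])
        with pytest.raises(ValueError, match="every cell"):
            sccore.qc_filter(adata, min_umi=100)

    def test_pca_outlier_removed(self):
        rng = np.random.default_rng(0)
        x = rng.poisson(50, size=(40, 10)).astype(float)
        x[0] = [5000, 0, 0, 0, 0, 0, 0, 0, 0, 0]  # grossly aberrant profile
        adata = _adata(x, [f"G{i}" for i in range(10)])
        _, report = sccore.qc_filter(adata, pca_outlier_z=8.0)
        assert report.loc[0, "removed_reason"] == "pca_outlier"


class TestLogNormalize:
    def test_formula(self):
        adata = _adata([[1, 3]], ["A", "B"])
        log = sccore.log_normalize(adata, scale=100)
        np.testing.assert_allclose(log[0], np.log1p([25.0, 75.0]))

    def test_zero_cell_safe(self):
        log = sccore.log_normalize(_adata([[0, 0]], ["A", "B"]))
        np.testing.assert_allclose(log, 0.0)


class TestAssignCellTypes:
    def test_planted_markers_recovered(self):
        rng = np.random.default_rng(0)
        x = rng.poisson(5, size=(60, 4)).astype(float)
        x[:30, 0] += 200  # type T1 marker M1
        x[30:, 2] += 200  # type T2 marker M2
        adata = _adata(x, ["M1", "A", "M2", "B"])
        typed = sccore.assign_cell_types(adata, {"T1": ["M1"], "T2": ["M2"]})
        assert (typed.obs["cell_type"][:30] == "T1").all()
        assert (typed.obs["cell_type"][30:] == "T2").all()

    def test_exact_tie_unassigned(self):
        # cell 0 sits at the mean of both markers: z = 0 for each type
        adata = _adata([[5, 5], [9, 1], [1, 9]], ["M1", "M2"])
        typed = sccore.assign_cell_types(adata, {"T1": ["M1"], "T2": ["M2"]})
        assert typed.obs["cell_type"].tolist() == ["unassigned", "T1", "T2"]

    def test_empty_markers_raise(self):
        with pytest.raises(ValueError, match="marker"):
            sccore.assign_cell_types(_adata([[1]], ["A"]), {})

    def test_missing_marker_warns(self):
        adata = _adata([[5, 1], [1, 5]], ["M1", "M2"])
        with pytest.warns(UserWarning, match="no marker"):
            sccore.assign_cell_types(adata, {"T1": ["M1"], "T2": ["ZZZ"]})


def _prop_adata(counts_a: dict, counts_b: dict):
    types = (
        [t for t, k in counts_a.items() for _ in range(k)]
        + [t for t, k in counts_b.items() for _ in range(k)]
    )
    n_a = sum(counts_a.values())
    groups = ["A"] * n_a + ["B"] * (len(types) - n_a)
    x = np.ones((len(types), 1))
    return _adata(x, ["G0"], groups=groups, cell_types=types)


class TestProportionTest:
    def test_label_swap_negates_log2fd(self):
        adata = _prop_adata({"t1": 80, "t2": 120}, {"t1": 120, "t2": 80})
        ab = sccore.proportion_test(adata, "A", "B", n_perm=200, n_boot=100, seed=0)
        ba = sccore.proportion_test(adata, "B", "A", n_perm=200, n_boot=100, seed=0)
        np.testing.assert_allclose(
            ab.set_index("cell_type")["log2fd"],
            -ba.set_index("cell_type")["log2fd"],
        )

    def test_strong_shift_called(self):
        adata = _prop_adata({"t1": 400, "t2": 100}, {"t1": 100, "t2": 400})
        out = sccore.proportion_test(adata, "A", "B", seed=1).set_index("cell_type")
        assert out.loc["t1", "call"] == "up" and out.loc["t2", "call"] == "down"

    def test_min_cells_raises(self):
        adata = _prop_adata({"t1": 10}, {"t1": 200})
        with pytest.raises(ValueError, match="cells"):
            sccore.proportion_test(adata, "A", "B")

    def test_deterministic_given_seed(self):
        adata = _prop_adata({"t1": 150, "t2": 150}, {"t1": 160, "t2": 140})
        a = sccore.proportion_test(adata, "A", "B", seed=3)
        b = sccore.proportion_test(adata, "A", "B", seed=3)
        pd.testing.assert_frame_equal(a, b)


class TestScDeg:
    def _planted(self):
        rng = np.random.default_rng(0)
        x = rng.poisson(5, size=(80, 6)).astype(float)
        x[:40, 0] *= 8  # gene G0 up in group A
        groups = ["A"] * 40 + ["B"] * 40
        return _adata(x, [f"G{i}" for i in range(6)], groups=groups,
                      cell_types=["t"] * 80)

    def test_planted_gene_up(self):
        out = sccore.sc_deg(self._planted(), "t", "A", "B").set_index("gene")
        assert out.loc["G0", "call"] == "up"

    def test_min_cells_raises(self):
        adata = self._planted()[:45]
        with pytest.raises(ValueError, match="cells per arm"):
            sccore.sc_deg(adata, "t", "A", "B")

    def test_q_at_least_p(self):
        out = sccore.sc_deg(self._planted(), "t", "A", "B")
        assert (out["q"] >= out["p"] - 1e-12).all()


class TestPseudobulk:
    def test_counts_conserved_per_sample(self):
        rng = np.random.default_rng(0)
        x = rng.poisson(4, size=(30, 5)).astype(float)
        samples = ["s1"] * 10 + ["s2"] * 20
        adata = _adata(x, [f"G{i}" for i in range(5)],
                       groups=["A"] * 30, sample_ids=samples)
        counts, meta = sccore.pseudobulk(adata)
        np.testing.assert_allclose(counts["s1"], x[:10].sum(axis=0))
        np.testing.assert_allclose(counts["s2"], x[10:].sum(axis=0))
        assert meta.set_index("sample_id").loc["s1", "n_cells"] == 10

    def test_cell_type_restriction(self):
        x = np.ones((20, 2))
        adata = _adata(x, ["G0", "G1"], cell_types=["t1"] * 5 + ["t2"] * 15)
        counts, _ = sccore.pseudobulk(adata, cell_type="t1")
        assert counts.sum().sum() == 10

    def test_pseudobulk_deg_on_synthetic(self, sc_data):
        adata, truth = sc_data
        out = sccore.pseudobulk_deg(
            adata, "Monocyte", "carrier", "noncarrier"
        ).set_index("gene")
        assert out.loc[truth.interaction["ligand"], "call"] == "up"


class TestInteraction:
    def test_probability_bounds_and_detection(self, sc_data, lr_db):
        adata, _ = sc_data
        out = sccore.interaction_probability(
            adata, lr_db, "Monocyte", "Erythroblast", "carrier"
        )
        assert ((out["prob"] >= 0) & (out["prob"] < 1)).all()
        assert out["passed_detection"].all()
        # only secreted-signaling pairs are scored
        secreted = set(
            map(tuple, lr_db.pairs.loc[
                lr_db.pairs["category"] == "secreted signaling",
                ["ligand", "receptor"]].values)
        )
        assert set(map(tuple, out[["ligand", "receptor"]].values)) <= secreted

    def test_absent_type_raises(self, sc_data, lr_db):
        adata, _ = sc_data
        with pytest.raises(ValueError, match="absent"):
            sccore.interaction_probability(
                adata, lr_db, "NoSuchType", "Erythroblast", "carrier"
            )

    def test_hill_monotone_in_kh(self, sc_data, lr_db):
        adata, _ = sc_data
        lo = sccore.interaction_probability(
            adata, lr_db, "Monocyte", "Erythroblast", "carrier", kh=0.25
        )
        hi = sccore.interaction_probability(
            adata, lr_db, "Monocyte", "Erythroblast", "carrier", kh=1.0
        )
        merged = lo.merge(hi, on=["ligand", "receptor"], suffixes=("_lo", "_hi"))
        assert (merged["prob_lo"] >= merged["prob_hi"]).all()


class TestModuleScores:
    def test_planted_regulon_module_up_in_carriers(self, sc_data, sim):
        adata, _ = sc_data
        stat1_targets = [f"STAT1_T{i:02d}" for i in range(sim.sc.targets_per_tf)]
        out = sccore.module_score_test(
            adata, {1: stat1_targets}, "Monocyte", "carrier", "healthy"
        )
        assert out.loc[0, "direction"] == "up"

    def test_too_small_module_skipped(self, sc_data):
        adata, _ = sc_data
        out = sccore.module_score_test(
            adata, {1: ["OSM"], 2: [f"BG{i:04d}" for i in range(5)]},
            "Monocyte", "carrier", "noncarrier",
        )
        assert out["module"].tolist() == [2]


class TestGrnActivity:
    def test_planted_ordering_and_ranks(self, sc_data, sim):
        adata, _ = sc_data
        out = sccore.grn_activity(adata, synthio.make_regulons(sim), "Monocyte")
        stat1 = out[out["tf"] == "STAT1"].set_index("group")["activity"]
        assert stat1["carrier"] > stat1["noncarrier"] > stat1["healthy"]
        assert (out["rank"] >= 1).all()
        # dense descending ranks within each group
        for _, sub in out.groupby("group"):
            ordered = sub.sort_values("activity", ascending=False)
            assert ordered["rank"].is_monotonic_increasing

    def test_min_targets_filter(self, sc_data):
        adata, _ = sc_data
        reg = pd.DataFrame({"tf": ["X"] * 2, "target": ["OSM", "OSMR"],
                            "mode": [1, 1]})
        out = sccore.grn_activity(adata, reg, "Monocyte")
        assert out.empty
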