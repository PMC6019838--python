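import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score
from statsmodels.stats.multitest import multipletests

from caprilinc.simulate import (
    CLUSTER_TEMPLATES,
    generate_time_course,
)
from caprilinc.temporal import (
    hierarchical_cluster,
    hypergeometric_enrichment,
    pairwise_de,
    pca_samples,
    spatiotemporal_overlap,
    time_specific_genes,
)
from oracles import bh_oracle, hypergeom_tail_oracle


def _time_matrix(values, n_rep=3):
    """values: feature -> 5 per-time-point FPKM levels, replicated exactly."""
    tps = ["May", "Jun", "Aug", "Sep", "Oct"]
    cols = [f"{tp}_r{r}" for tp in tps for r in range(1, n_rep + 1)]
    meta = pd.DataFrame(
        {
            "tissue": None,
            "time_point": [c.rsplit("_r", 1)[0] for c in cols],
            "replicate": [int(c.rsplit("_r", 1)[1]) for c in cols],
        },
        index=cols,
    )
    data = {
        f: [levels[tps.index(c.rsplit("_r", 1)[0])] for c in cols]
        for f, levels in values.items()
    }
    return pd.DataFrame(data, index=cols).T, meta


class TestBenjaminiHochberg:
    def test_step_up_example(self):
        q = multipletests([0.01, 0.02, 0.03], method="fdr_bh")[1]
        assert np.allclose(q, [0.03, 0.03, 0.03])

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(20):
            p = list(rng.uniform(size=rng.integers(1, 11)))
            q = multipletests(p, method="fdr_bh")[1]
            assert np.allclose(q, bh_oracle(p), atol=1e-12)

    def test_q_monotone_in_p_rank(self, rng):
        p = rng.uniform(size=50)
        q = multipletests(p, method="fdr_bh")[1]
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()
        assert (q >= p).all()


class TestPairwiseDe:
    def test_fourfold_change_is_significant(self):
        m, meta = _time_matrix({"f": [10, 10, 40, 40, 40]})
        results = pairwise_de(m, meta)
        r = next(x for x in results if x.comparison == ("May", "Aug"))
        assert r.log2_fold_change == pytest.approx(np.log2(40.1 / 10.1))
        assert r.significant

    def test_flat_feature_not_significant(self):
        m, meta = _time_matrix({"f": [10, 10, 10, 10, 10]})
        results = pairwise_de(m, meta)
        assert all(not r.significant for r in results)
        assert all(r.log2_fold_change == 0 for r in results)

    def test_all_ten_comparisons_produced(self):
        m, meta = _time_matrix({"f": [1, 2, 3, 4, 5]})
        results = pairwise_de(m, meta)
        assert len({r.comparison for r in results}) == 10

    def test_single_replicate_rejected(self):
        m, meta = _time_matrix({"f": [1, 2, 3, 4, 5]}, n_rep=1)
        with pytest.raises(ValueError, match="replicates"):
            pairwise_de(m, meta)

    def test_transition_subset_recovery_under_noise(self):
        """>=95 of 100 planted cross-block features land in the transition set."""
        matrix, meta, de_ids = generate_time_course(
            n_features=300, n_de=100, log2fc=2.0, noise_sd=0.1, seed=42
        )
        results = pairwise_de(matrix, meta)
        _specific, _counts, transition = time_specific_genes(results)
        assert len(set(de_ids) & transition) >= 95


class TestTimeSpecific:
    def test_single_cross_block_hit_in_transition_subset(self):
        m, meta = _time_matrix({"f": [10, 10, 40, 40, 40], "g": [5, 5, 5, 5, 5]})
        results = pairwise_de(m, meta)
        specific, counts, transition = time_specific_genes(results)
        assert "f" in specific and "f" in transition
        assert "g" not in specific
        assert counts["May_vs_Aug"] == 1

    def test_within_block_hit_excluded_from_transition(self):
        m, meta = _time_matrix({"f": [10, 10, 40, 10, 10]})
        results = pairwise_de(m, meta)
        specific, _counts, transition = time_specific_genes(results)
        assert "f" in specific and "f" not in transition


class TestPca:
    def test_collinear_samples_put_everything_on_pc1(self):
        # log10(FPKM+1) profiles are exactly linear in the time index, so the
        # samples lie on a line in feature space
        m, meta = _time_matrix({
            "a": list(10.0 ** np.arange(1, 6) - 1),
            "b": list(10.0 ** (2 * np.arange(1, 6)) - 1),
        })
        _scores, ratios = pca_samples(m, meta)
        assert ratios[0] == pytest.approx(1.0, abs=1e-9)

    def test_explained_variance_sums_to_one(self):
        matrix, meta, _ = generate_time_course(
            n_features=50, n_de=10, log2fc=2.0, noise_sd=0.3, seed=7
        )
        _scores, ratios = pca_samples(matrix, meta)
        assert ratios.sum() == pytest.approx(1.0, abs=1e-9)

    def test_constant_matrix_rejected(self):
        m, meta = _time_matrix({"f": [3, 3, 3, 3, 3]})
        with pytest.raises(ValueError, match="constant"):
            pca_samples(m, meta)

    def test_two_block_design_separates_on_pc1(self):
        """Cross-block shift on 30% of features: PC1 splits the blocks."""
        matrix, meta, _ = generate_time_course(
            n_features=200, n_de=60, log2fc=2.0, noise_sd=0.2, seed=11
        )
        scores, _ = pca_samples(matrix, meta)
        early = meta["time_point"].isin(["May", "Jun"]).to_numpy()
        pc1_early = scores["PC1"].to_numpy()[early]
        pc1_late = scores["PC1"].to_numpy()[~early]
        assert max(pc1_early) < min(pc1_late) or min(pc1_early) > max(pc1_late)


class TestHierarchicalClustering:
    def test_identical_profiles_cocluster(self):
        m, meta = _time_matrix({
            "a": [1, 2, 4, 8, 16],
            "b": [2, 4, 8, 16, 32],   # same shape on log scale
            "c": [16, 8, 4, 2, 1],    # anti-correlated
        })
        assignment = hierarchical_cluster(m, meta, k=2)
        assert assignment.labels["a"] == assignment.labels["b"]
        assert assignment.labels["a"] != assignment.labels["c"]

    def test_anticorrelated_profiles_at_distance_two(self):
        x = np.arange(1, 6, dtype=float)  # log-scale profile
        y = x[::-1]                       # mirror: exactly anti-correlated
        assert 1 - np.corrcoef(x, y)[0, 1] == pytest.approx(2.0, abs=1e-9)

    def test_zero_variance_profiles_dropped(self):
        m, meta = _time_matrix({
            "flat": [3, 3, 3, 3, 3],
            "a": [1, 2, 4, 8, 16],
            "b": [16, 8, 4, 2, 1],
        })
        assignment = hierarchical_cluster(m, meta, k=2)
        assert assignment.dropped == ("flat",)
        assert "flat" not in assignment.labels.index

    def test_template_recovery_ari(self):
        """5 planted templates x 40 features at noise 0.05: ARI >= 0.9."""
        rng = np.random.default_rng(23)
        tps = ["May", "Jun", "Aug", "Sep", "Oct"]
        rows, labels = {}, {}
        for name, template in CLUSTER_TEMPLATES.items():
            for i in range(40):
                base = rng.uniform(2, 5)
                log2 = base + 2.0 * np.array(template)
                fid = f"{name}_{i}"
                labels[fid] = name
                rows[fid] = list(2.0 ** log2)
        m, meta = _time_matrix(rows)
        noisy = np.exp2(np.log2(m + 1.0) + 0.05 * rng.standard_normal(m.shape)) - 1.0
        assignment = hierarchical_cluster(noisy.clip(lower=0), meta, k=5)
        ari = adjusted_rand_score(
            [labels[f] for f in assignment.labels.index], assignment.labels.to_numpy()
        )
        assert ari >= 0.9


class TestHypergeometricEnrichment:
    def test_complete_overlap_closed_form(self):
        universe = {f"g{i}" for i in range(10)}
        term = {f"g{i}" for i in range(5)}
        out = hypergeometric_enrichment(term, {"T": term}, universe)
        assert out.loc[0, "p"] == pytest.approx(1 / 252, abs=1e-12)

    def test_zero_overlap_gives_p_one(self):
        universe = {f"g{i}" for i in range(10)}
        out = hypergeometric_enrichment(
            {"g0"}, {"T": {"g9"}}, universe
        )
        assert out.loc[0, "p"] == pytest.approx(1.0)

    def test_matches_exact_enumeration(self, rng):
        for _ in range(20):
            n_u = int(rng.integers(4, 13))
            universe = {f"g{i}" for i in range(n_u)}
            term = set(rng.choice(sorted(universe), size=rng.integers(1, n_u),
                                  replace=False))
            cluster = set(rng.choice(sorted(universe), size=rng.integers(1, n_u),
                                     replace=False))
            out = hypergeometric_enrichment(cluster, {"T": term}, universe)
            expected = hypergeom_tail_oracle(
                len(cluster & term), n_u, len(term), len(cluster)
            )
            assert out.loc[0, "p"] == pytest.approx(expected, abs=1e-9)

    def test_null_pvalues_approximately_uniform(self):
        """Random clusters: the discrete p-value distribution tracks U(0,1)."""
        rng = np.random.default_rng(5)
        n_u, n_term, n_cluster = 2000, 500, 500
        universe = np.arange(n_u)
        term = set(rng.choice(universe, size=n_term, replace=False))
        gene_sets = {"T": {f"g{i}" for i in term}}
        named = {f"g{i}" for i in universe}
        ps = []
        for _ in range(2000):
            cluster = {
                f"g{i}" for i in rng.choice(universe, size=n_cluster, replace=False)
            }
            ps.append(
                hypergeometric_enrichment(cluster, gene_sets, named).loc[0, "p"]
            )
        ps = np.sort(ps)
        ecdf = np.arange(1, len(ps) + 1) / len(ps)
        d = np.max(np.abs(ecdf - ps))
        assert d < 0.06
        assert np.mean(np.array(ps) <= 0.05) <= 0.07

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            hypergeometric_enrichment(set(), {}, set())


class TestSpatiotemporalOverlap:
    def test_empty_hf_set_gives_empty_report(self):
        report = spatiotemporal_overlap(set(), {"x"}, None, [])
        assert report.empty

    def test_intersection_matches_set_arithmetic(self):
        from caprilinc.expression import PairRecord

        hf = {"a", "b", "c"}
        de = {"b", "c", "d"}
        report = spatiotemporal_overlap(hf, de, None, [PairRecord("b", "G", 10)])
        assert set(report["lincRNA"]) == hf & de
        assert report.loc[report.lincRNA == "b", "neighbor"].item() == "G"

    def test_planted_spatiotemporal_member_with_exact_r(self, noise_free_sim):
        from caprilinc.expression import find_neighbor_pairs

        truth = noise_free_sim["truth"]
        matrix, meta = noise_free_sim["matrix"], noise_free_sim["metadata"]
        pairs = find_neighbor_pairs(
            noise_free_sim["candidates"].subset(truth.st_pairs.keys()),
            noise_free_sim["reference"],
        )
        report = spatiotemporal_overlap(
            truth.hf_high, truth.expected_time_specific(), None, pairs,
            matrix, meta,
        )
        for linc, (gene, target_r) in truth.st_pairs.items():
            row = report[(report.lincRNA == linc) & (report.neighbor == gene)]
            assert len(row) == 1
            assert row["pearson_r"].item() == pytest.approx(target_r, abs=1e-9)
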