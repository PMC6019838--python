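import numpy as np
import pandas as pd
import pytest

from caprilinc.annotation import AnnotationSet, TranscriptModel
from caprilinc.expression import (
    PairRecord,
    classify_tissue_specific,
    compute_fpkm,
    detect_hf_high,
    find_neighbor_pairs,
    log_z_transform,
    pair_correlation_analysis,
    tissue_means,
)
from oracles import ks_oracle, pearson_oracle


def _meta(tissues):
    return pd.DataFrame(
        {"tissue": tissues, "time_point": None, "replicate": 1},
        index=[f"s{i}" for i in range(len(tissues))],
    )


class TestComputeFpkm:
    def test_closed_form(self):
        counts = pd.DataFrame({"s1": [10]}, index=["f"])
        fpkm = compute_fpkm(counts, pd.Series({"f": 1000}), pd.Series({"s1": 1e6}))
        assert fpkm.loc["f", "s1"] == 10.0

    def test_zero_counts_zero_fpkm(self):
        counts = pd.DataFrame({"s1": [0]}, index=["f"])
        fpkm = compute_fpkm(counts, pd.Series({"f": 500}), pd.Series({"s1": 2e6}))
        assert fpkm.loc["f", "s1"] == 0.0

    def test_doubling_depth_halves_fpkm(self):
        counts = pd.DataFrame({"s1": [7], "s2": [7]}, index=["f"])
        fpkm = compute_fpkm(
            counts, pd.Series({"f": 750}), pd.Series({"s1": 1e6, "s2": 2e6})
        )
        assert fpkm.loc["f", "s1"] == pytest.approx(2 * fpkm.loc["f", "s2"])

    def test_negative_counts_rejected(self):
        counts = pd.DataFrame({"s1": [-1]}, index=["f"])
        with pytest.raises(ValueError):
            compute_fpkm(counts, pd.Series({"f": 100}), pd.Series({"s1": 1e6}))


class TestLogZ:
    def test_zero_fpkm_maps_to_zero_log(self):
        m = pd.DataFrame({"s0": [0.0]}, index=["f"])
        out = log_z_transform(m, group_by=None)
        # single-value group has zero variance -> Z = 0, from log value 0
        assert out.loc["f", "s0"] == 0.0

    def test_zero_variance_group_is_zero(self):
        m = pd.DataFrame({"s0": [1.0, 1.0, 1.0]}, index=list("abc"))
        out = log_z_transform(m, group_by=None)
        assert (out["s0"] == 0.0).all()

    def test_columns_standardized(self, rng):
        m = pd.DataFrame(rng.uniform(0, 50, size=(30, 4)),
                         index=[f"f{i}" for i in range(30)],
                         columns=[f"s{i}" for i in range(4)])
        out = log_z_transform(m, group_by=None)
        assert np.allclose(out.mean(axis=0), 0, atol=1e-9)
        assert np.allclose(out.std(axis=0, ddof=0), 1, atol=1e-9)

    def test_tissue_grouping(self):
        meta = _meta(["kidney", "kidney", "liver"])
        m = pd.DataFrame([[1.0, 3.0, 7.0]], index=["f"], columns=meta.index)
        out = log_z_transform(m, metadata=meta, group_by="tissue")
        # kidney group: two cells standardized against each other
        assert out.loc["f", "s0"] == pytest.approx(-1.0)
        assert out.loc["f", "s1"] == pytest.approx(1.0)
        assert out.loc["f", "s2"] == 0.0  # singleton group


class TestTissueSpecific:
    def test_exclusive_expression_labelled_with_tissue(self):
        meta = _meta(["kidney", "liver", "brain"])
        m = pd.DataFrame([[5.0, 0.0, 0.0]], index=["f"], columns=meta.index)
        assert classify_tissue_specific(m, meta)["f"] == "kidney"

    def test_two_tissues_is_multi(self):
        meta = _meta(["kidney", "liver", "brain"])
        m = pd.DataFrame([[5.0, 5.0, 0.0]], index=["f"], columns=meta.index)
        assert classify_tissue_specific(m, meta)["f"] == "multi"

    def test_silent_feature_not_expressed(self):
        meta = _meta(["kidney", "liver"])
        m = pd.DataFrame([[0.0, 0.0]], index=["f"], columns=meta.index)
        assert classify_tissue_specific(m, meta)["f"] == "not_expressed"

    def test_threshold_boundary_inclusive(self):
        meta = _meta(["kidney", "liver"])
        m = pd.DataFrame([[0.5, 0.49]], index=["f"], columns=meta.index)
        assert classify_tissue_specific(m, meta)["f"] == "kidney"

    def test_noise_free_planted_recovery(self, noise_free_sim):
        truth = noise_free_sim["truth"]
        labels = classify_tissue_specific(
            noise_free_sim["matrix"], noise_free_sim["metadata"]
        )
        called = {
            f: l for f, l in labels.items()
            if l not in ("multi", "not_expressed") and f in truth.candidate_class
        }
        assert called == truth.tissue_specific  # precision = recall = 1


class TestHfHigh:
    def _case(self, hf, others):
        tissues = ["HF"] + [f"t{i}" for i in range(len(others))]
        meta = _meta(tissues)
        m = pd.DataFrame([[hf] + others], index=["f"], columns=meta.index)
        return detect_hf_high(m, meta)["f"]

    def test_clears_both_fold_rules(self):
        assert self._case(100.0, [1.0] * 9 + [35.0])

    def test_single_high_tissue_vetoes(self):
        assert not self._case(100.0, [1.0] * 9 + [45.0])

    def test_silent_in_hf_is_false(self):
        assert not self._case(0.0, [0.0] * 10)

    def test_zero_denominators_pass(self):
        assert self._case(10.0, [0.0] * 10)

    def test_missing_hf_tissue_rejected(self):
        meta = _meta(["kidney", "liver"])
        m = pd.DataFrame([[1.0, 1.0]], index=["f"], columns=meta.index)
        with pytest.raises(ValueError, match="HF"):
            detect_hf_high(m, meta)

    def test_noise_free_planted_recovery(self, noise_free_sim):
        truth = noise_free_sim["truth"]
        flags = detect_hf_high(noise_free_sim["matrix"], noise_free_sim["metadata"])
        called = set(flags.index[flags]) & set(truth.candidate_class)
        assert called == truth.hf_high


def _gene(gid, chrom, start, end, strand="+"):
    aset = AnnotationSet()
    aset.add(TranscriptModel(f"{gid}.t", gid, chrom, strand, ((start, end),)))
    return aset


def _merge(*sets):
    out = AnnotationSet()
    for s in sets:
        for tx in s:
            out.add(tx)
    return out


class TestNeighborPairs:
    def test_boundary_inclusive_at_ten_kb(self):
        lincs = _gene("L", "chr1", 500, 1000)
        codings = _gene("C", "chr1", 11_001, 12_000)
        pairs = find_neighbor_pairs(lincs, codings)
        assert len(pairs) == 1 and pairs[0].gap == 10_000

    def test_gap_over_ten_kb_excluded(self):
        lincs = _gene("L", "chr1", 500, 1000)
        codings = _gene("C", "chr1", 11_002, 12_000)
        assert find_neighbor_pairs(lincs, codings) == []

    def test_linc_flanked_by_two_genes_gives_two_pairs(self):
        lincs = _gene("L", "chr1", 20_000, 21_000)
        codings = _merge(
            _gene("C1", "chr1", 15_000, 16_000),
            _gene("C2", "chr1", 25_000, 26_000),
        )
        pairs = find_neighbor_pairs(lincs, codings)
        assert {p.coding_id for p in pairs} == {"C1", "C2"}

    def test_planted_pairs_are_found(self, noise_free_sim):
        truth = noise_free_sim["truth"]
        cand = noise_free_sim["candidates"]
        planted = dict(truth.pair_partner) | dict(truth.st_pairs)
        pairs = find_neighbor_pairs(
            cand.subset(planted.keys()), noise_free_sim["reference"]
        )
        found = {(p.linc_id, p.coding_id) for p in pairs}
        assert {(l, g) for l, (g, _r) in planted.items()} <= found


class TestPairCorrelation:
    def test_identical_profiles_give_r_one(self):
        meta = _meta(["a", "b", "c", "d", "e"])
        m = pd.DataFrame(
            [[1, 2, 3, 4, 5], [1, 2, 3, 4, 5]], index=["L", "C"],
            columns=meta.index, dtype=float,
        )
        analysis = pair_correlation_analysis(
            [PairRecord("L", "C", 100)], m, meta, n_random=0
        )
        assert analysis.pairs[0].pearson_r == pytest.approx(1.0)

    def test_zero_variance_pair_dropped(self):
        meta = _meta(["a", "b", "c"])
        m = pd.DataFrame(
            [[1, 1, 1], [1, 2, 3]], index=["L", "C"], columns=meta.index,
            dtype=float,
        )
        analysis = pair_correlation_analysis(
            [PairRecord("L", "C", 100)], m, meta, n_random=0
        )
        assert analysis.pairs == []

    def test_pearson_matches_textbook_formula(self, rng):
        x = list(rng.uniform(0, 10, size=5))
        y = list(rng.uniform(0, 10, size=5))
        assert np.corrcoef(x, y)[0, 1] == pytest.approx(
            pearson_oracle(x, y), abs=1e-12
        )

    def test_ks_statistic_matches_ecdf_sweep(self, rng):
        from scipy.stats import ks_2samp

        for _ in range(10):
            a = list(rng.normal(size=rng.integers(3, 20)))
            b = list(rng.normal(size=rng.integers(3, 20)))
            assert ks_2samp(a, b).statistic == pytest.approx(
                ks_oracle(a, b), abs=1e-12
            )
        assert ks_oracle([1, 2, 3], [10, 11, 12]) == 1.0
        assert ks_oracle([1, 2, 3], [1, 2, 3]) == 0.0

    def test_planted_correlation_dominates_random(self):
        """200 planted pairs at r=0.9 vs 200 random pairs: KS p < 1e-6."""
        rng = np.random.default_rng(17)
        n_pairs, n_tissues, rho = 200, 11, 0.9
        meta = _meta([f"t{i}" for i in range(n_tissues)])
        rows, index, pairs = [], [], []
        for i in range(n_pairs):
            z = rng.standard_normal(n_tissues)
            e = rng.standard_normal(n_tissues)
            linc = 3 + z
            coding = 3 + rho * z + np.sqrt(1 - rho ** 2) * e
            rows += [2.0 ** linc, 2.0 ** coding]
            index += [f"L{i}", f"C{i}"]
            pairs.append(PairRecord(f"L{i}", f"C{i}", 100))
        m = pd.DataFrame(rows, index=index, columns=meta.index)
        analysis = pair_correlation_analysis(
            pairs, m, meta, n_random=200, seed=1,
            linc_pool=[f"L{i}" for i in range(n_pairs)],
            coding_pool=[f"C{i}" for i in range(n_pairs)],
        )
        r_linc = analysis.r_values("linc-coding")
        r_rand = analysis.r_values("random")
        assert np.median(r_linc) > np.median(r_rand)
        # stochastic dominance at the quartiles
        assert np.percentile(r_linc, 25) > np.percentile(r_rand, 75)
        assert analysis.ks_vs_random[1] < 1e-6


class TestTissueMeans:
    def test_replicates_averaged_within_tissue(self):
        meta = _meta(["kidney", "kidney", "liver"])
        m = pd.DataFrame([[2.0, 4.0, 8.0]], index=["f"], columns=meta.index)
        means = tissue_means(m, meta)
        assert means.loc["f", "kidney"] == 3.0
        assert means.loc["f", "liver"] == 8.0
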