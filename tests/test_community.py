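import numpy as np
import pandas as pd
import pytest

from genopotential.community import (MarkerSet, bin_quality, cluster_rps3,
                                     dereplicate, global_identity,
                                     pairwise_identity, rank_abundance,
                                     relative_abundance,
                                     trim_concatenated_alignment)
from genopotential.core_model import (GenomeBin, MarkerSetError, ProfileHit,
                                      Thresholds)
from genopotential.synthetic_data import DNA, GUARD_AA, _mutate_string


def _rng(seed=0):
    return np.random.default_rng(seed)


def random_dna(rng, n):
    return "".join(rng.choice(list(DNA), size=n))


MARKERS_51 = MarkerSet("bacteria", tuple(f"m{i:02d}" for i in range(51)))


def marker_hits(bin_id, present, duplicated):
    hits = [ProfileHit(f"{bin_id}_g{m}", m, 200.0) for m in present]
    hits += [ProfileHit(f"{bin_id}_g{m}_copy2", m, 200.0) for m in duplicated]
    return hits


class TestBinQuality:
    def test_counting_oracle_43_present_3_duplicated(self):
        present = [f"m{i:02d}" for i in range(43)]
        hits = marker_hits("b", present, present[:3])
        comp, cont, hq = bin_quality(GenomeBin("b", {"s"}), hits, MARKERS_51)
        assert comp == pytest.approx(100 * 43 / 51)   # 84.31
        assert cont == pytest.approx(100 * 3 / 51)    # 5.88
        assert hq

    def test_perfect_bin(self):
        hits = marker_hits("b", MARKERS_51.markers, [])
        assert bin_quality(GenomeBin("b", {"s"}), hits, MARKERS_51) == \
            (100.0, 0.0, True)

    def test_below_seventy_percent_not_high_quality(self):
        hits = marker_hits("b", [f"m{i:02d}" for i in range(35)], [])
        comp, _, hq = bin_quality(GenomeBin("b", {"s"}), hits, MARKERS_51)
        assert comp == pytest.approx(100 * 35 / 51)
        assert not hq

    def test_boundaries_are_strict(self):
        ten = MarkerSet("bacteria", tuple(f"m{i}" for i in range(10)))
        b = GenomeBin("b", {"s"})
        # exactly 70% complete is not ">70%"
        assert bin_quality(b, marker_hits("b", ten.markers[:7], []), ten)[2] \
            is False
        assert bin_quality(b, marker_hits("b", ten.markers[:8], []), ten)[2] \
            is True
        # exactly 10% contamination is not "<10%"
        assert bin_quality(b, marker_hits("b", ten.markers,
                                          ten.markers[:1]), ten)[2] is False

    def test_empty_marker_set_rejected(self):
        with pytest.raises(MarkerSetError):
            MarkerSet("bacteria", ())


class TestPairwiseIdentity:
    def test_identical_bins(self):
        rng = _rng(1)
        scaffolds = {"s1": random_dna(rng, 3000), "s2": random_dna(rng, 2000)}
        assert pairwise_identity(scaffolds, dict(scaffolds)) == (1.0, 1.0)

    def test_mutated_replicate_within_binomial_bound(self):
        rng = _rng(2)
        source = {f"s{i}": random_dna(rng, 6000) for i in range(2)}
        rate = 0.05
        mutated, total_subs = {}, 0
        for sid, seq in source.items():
            mutated[f"r{sid}"], subs = _mutate_string(rng, seq, rate, DNA)
            total_subs += subs
        identity, aligned = pairwise_identity(source, mutated)
        assert aligned == 1.0
        assert identity == pytest.approx(0.95, abs=0.01)

    def test_unrelated_bins_share_nothing(self):
        rng = _rng(3)
        a = {"s1": random_dna(rng, 3000)}
        b = {"s2": random_dna(rng, 3000)}
        assert pairwise_identity(a, b) == (0.0, 0.0)

    def test_symmetry(self):
        rng = _rng(4)
        a = {"s1": random_dna(rng, 2500)}
        b = {"r1": _mutate_string(rng, a["s1"], 0.03, DNA)[0],
             "r2": random_dna(rng, 1000)}
        assert pairwise_identity(a, b) == pairwise_identity(b, a)

    def test_missing_scaffolds_rejected(self):
        with pytest.raises(ValueError, match="scaffolds"):
            pairwise_identity({}, {"s": "ACGT"})


class TestDereplicate:
    def _bins(self, ids, completeness=None):
        out = []
        for i, b in enumerate(ids):
            gb = GenomeBin(b, {f"{b}_s"})
            gb.completeness = (completeness or {}).get(b, 90.0)
            gb.contamination = 1.0
            out.append(gb)
        return out

    def test_pair_plus_singleton(self):
        bins = self._bins(["A", "B", "C"], {"A": 80.0, "B": 95.0})
        identities = {frozenset(("A", "B")): (0.995, 1.0),
                      frozenset(("A", "C")): (0.5, 0.1),
                      frozenset(("B", "C")): (0.5, 0.1)}
        result = dereplicate(bins, identities)
        assert sorted(map(sorted, result.clusters)) == [["A", "B"], ["C"]]
        assert result.representative_of("A") == "B"   # higher completeness

    def test_single_linkage_chains(self):
        bins = self._bins(["A", "B", "C"])
        identities = {frozenset(("A", "B")): (0.985, 1.0),
                      frozenset(("B", "C")): (0.985, 1.0),
                      frozenset(("A", "C")): (0.96, 1.0)}
        result = dereplicate(bins, identities)
        assert sorted(map(sorted, result.clusters)) == [["A", "B", "C"]]

    def test_aligned_fraction_also_gates(self):
        bins = self._bins(["A", "B"])
        identities = {frozenset(("A", "B")): (0.999, 0.2)}
        assert len(dereplicate(bins, identities).clusters) == 2


class TestClusterRps3:
    def test_identical_sequences_one_cluster(self):
        seq = "".join(_rng(5).choice(list(GUARD_AA), size=200))
        assert len(cluster_rps3({"a": seq, "b": seq})) == 1

    def test_divergent_sequences_split_at_99(self):
        rng = _rng(6)
        seq = "".join(rng.choice(list(GUARD_AA), size=200))
        far, _ = _mutate_string(rng, seq, 0.05, GUARD_AA)
        near, _ = _mutate_string(rng, seq, 0.005, GUARD_AA)
        clusters = cluster_rps3({"a": seq, "b": far, "c": near})
        members = sorted(sorted(m) for _, m in clusters)
        assert members == [["a", "c"], ["b"]]

    def test_empty_input(self):
        assert cluster_rps3({}) == []

    def test_threshold_one_keeps_all_but_exact_duplicates(self):
        rng = _rng(7)
        seqs = {f"g{i}": "".join(rng.choice(list(GUARD_AA), size=100))
                for i in range(6)}
        seqs["dup"] = seqs["g0"]
        thr = Thresholds(rps3_cluster_identity=1.0)
        clusters = cluster_rps3(seqs, thr)
        # oracle: exhaustive pairwise identity
        n_expected = len({s for s in seqs.values()})
        assert len(clusters) == n_expected
        for centroid, members in clusters:
            for m in members:
                assert global_identity(seqs[m], seqs[centroid]) == 1.0


class TestRankAbundance:
    def _setup(self, depths, binned):
        clusters = [(f"g{i}", [f"g{i}"]) for i in range(len(depths))]
        scaffold_of = {f"g{i}": f"s{i}" for i in range(len(depths))}
        coverage = pd.DataFrame({"sample_0": depths},
                                index=[f"s{i}" for i in range(len(depths))])
        bins = {"b": {f"s{i}" for i in binned}}
        return clusters, scaffold_of, coverage, bins

    def test_rank_order_and_normalization(self):
        clusters, scaffold_of, cov, bins = self._setup([30, 50, 20], [0, 1, 2])
        table, _ = rank_abundance(clusters, scaffold_of, cov, bins)
        assert list(table["relative_abundance"]) == [0.5, 0.3, 0.2]
        assert list(table["organism"]) == ["g1", "g0", "g2"]

    def test_binned_count_in_top_k(self):
        clusters, scaffold_of, cov, bins = self._setup([30, 50, 20], [0, 1])
        _, summary = rank_abundance(clusters, scaffold_of, cov, bins, top_k=3)
        assert summary["top_k_binned"] == 2
        assert summary["n_unbinned"] == 1

    def test_rare_unbinned_fraction(self):
        depths = [100.0] * 5 + [0.04]     # last organism ~0.08 % of total
        clusters, scaffold_of, cov, bins = self._setup(depths, range(5))
        _, summary = rank_abundance(clusters, scaffold_of, cov, bins)
        assert summary["frac_unbinned_below_rare"] == 1.0

    def test_all_zero_depths_rejected(self):
        clusters, scaffold_of, cov, bins = self._setup([0.0, 0.0], [0, 1])
        with pytest.raises(ValueError, match="zero"):
            rank_abundance(clusters, scaffold_of, cov, bins)


class TestRelativeAbundance:
    def test_single_bin_is_all_of_every_sample(self):
        bins = [GenomeBin("b", {"s1", "s2"})]
        cov = pd.DataFrame({"x": [5.0, 7.0], "y": [1.0, 9.9]},
                           index=["s1", "s2"])
        table = relative_abundance(bins, {"s1": 100, "s2": 300}, cov)
        assert np.allclose(table.values, 1.0)

    def test_scale_invariance_and_split(self):
        bins = [GenomeBin("a", {"s1"}), GenomeBin("b", {"s2"})]
        lengths = {"s1": 1000, "s2": 4000}
        cov = pd.DataFrame({"x": [10.0, 30.0]}, index=["s1", "s2"])
        table = relative_abundance(bins, lengths, cov)
        assert table.loc["a", "x"] == 0.25 and table.loc["b", "x"] == 0.75
        doubled = relative_abundance(bins, lengths, cov * 2)
        assert table.equals(doubled)

    def test_column_sums_and_order_invariance(self):
        rng = _rng(8)
        bins = [GenomeBin(f"b{i}", {f"b{i}_s0", f"b{i}_s1"})
                for i in range(5)]
        scaffolds = [s for b in bins for s in sorted(b.scaffold_ids)]
        lengths = {s: int(rng.integers(500, 5000)) for s in scaffolds}
        cov = pd.DataFrame(rng.uniform(0, 50, size=(10, 3)),
                           index=scaffolds, columns=list("xyz"))
        table = relative_abundance(bins, lengths, cov)
        assert np.allclose(table.sum(axis=0), 1.0, atol=1e-9)
        reordered = relative_abundance(bins[::-1], lengths, cov)
        assert table.sort_index().equals(reordered.sort_index())

    def test_zero_length_bin_rejected(self):
        bins = [GenomeBin("b", {"s1"})]
        cov = pd.DataFrame({"x": [1.0]}, index=["s1"])
        with pytest.raises(ValueError, match="length"):
            relative_abundance(bins, {"s1": 0}, cov)


class TestTrimAlignment:
    def test_gappy_columns_removed_at_strict_boundary(self):
        # 20 taxa; column 0 has 19 gaps (95% -> removed), column 1 has
        # exactly 18 gaps (90% -> kept)
        taxa = [f"t{i:02d}" for i in range(20)]
        block = {}
        for i, t in enumerate(taxa):
            col0 = "A" if i == 0 else "-"
            col1 = "A" if i < 2 else "-"
            block[t] = col0 + col1 + "AAAA"
        alignment, dropped, _ = trim_concatenated_alignment({"g": block})
        assert len(next(iter(alignment.values()))) == 5
        assert not dropped

    def test_low_coverage_taxon_dropped(self):
        block = {"full": "A" * 100, "half": "A" * 40 + "-" * 60}
        alignment, dropped, _ = trim_concatenated_alignment({"g": block})
        assert dropped == {"half"}
        assert set(alignment) == {"full"}

    def test_tree_eligibility_boundary_449_vs_450(self):
        block = {"rich": "A" * 500,
                 "edge449": "A" * 449 + "-" * 51,
                 "edge450": "A" * 450 + "-" * 50}
        alignment, dropped, eligible = trim_concatenated_alignment({"g": block})
        assert not dropped                      # all >=50% aligned
        assert eligible == {"rich", "edge450"}  # 449 non-gap is not enough

    def test_absent_taxon_filled_with_gaps_then_dropped(self):
        blocks = {"g1": {"a": "AAAA", "b": "CCCC"},
                  "g2": {"a": "GGGGGG"}}
        alignment, dropped, _ = trim_concatenated_alignment(blocks)
        assert dropped == {"b"}                 # 4 of 10 columns non-gap
        assert alignment["a"] == "AAAAGGGGGG"

    def test_idempotent_without_taxon_drop(self):
        rng = _rng(9)
        taxa = [f"t{i}" for i in range(8)]
        block = {t: "".join(rng.choice(list("ACDEF-"), size=120))
                 for t in taxa}
        first, dropped, _ = trim_concatenated_alignment({"g": block})
        assert not dropped
        second, dropped2, _ = trim_concatenated_alignment({"g": first})
        assert second == first and not dropped2

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="unequal"):
            trim_concatenated_alignment({"g": {"a": "AAA", "b": "AAAA"}})
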