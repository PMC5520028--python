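import random

import pytest

from genopotential.core_model import (GeneCall, GenomeBin, ProfileHit,
                                      Thresholds, assign_ordinals,
                                      parse_gene_calls, parse_profile_hits)
from genopotential.hydrogenase_typing import (assign_group,
                                              classify_hydrogenases,
                                              cooccurrence_stats,
                                              resolve_group_a,
                                              summarize_hydrogenases)
from genopotential.synthetic_data import (OperonLayout,
                                          generate_operon_fixture,
                                          layout_truth_label)


def hit(gene, profile, score=200.0):
    return ProfileHit(gene, profile, score, 1e-40)


class TestAssignGroup:
    def test_best_score_wins(self):
        result = assign_group([hit("g", "FeFe_GA", 200), hit("g", "FeFe_GB", 50)])
        assert result[:2] == ("FeFe", "A") and not result[2]

    def test_nife_group(self):
        assert assign_group([hit("g", "NiFe_G1", 80)])[:2] == ("NiFe", "1")

    def test_tie_breaks_lexicographically_and_flags(self):
        cofactor, group, ambiguous, best = assign_group(
            [hit("g", "FeFe_GB", 100), hit("g", "FeFe_GA", 100)])
        assert (cofactor, group) == ("FeFe", "A")
        assert ambiguous
        assert best.profile == "FeFe_GA"

    def test_non_family_hits_give_no_call(self):
        assert assign_group([hit("g", "hydB"), hit("g", "rpS3")]) is None


def operon(genes):
    """genes: list of (gene_id, strand, roles) in physical order."""
    calls = [GeneCall(g, "sc", 1 + i * 400, 300 + i * 400, s)
             for i, (g, s, _) in enumerate(genes)]
    assign_ordinals(calls)
    roles = {g: set(r) for g, _, r in genes if r}
    return calls, roles


class TestResolveGroupA:
    def test_co_oriented_hydbc_downstream_is_a3(self):
        calls, roles = operon([("cat", "+", ()), ("n1", "+", {"hydB"}),
                               ("n2", "+", {"hydC"})])
        subgroup, evidence = resolve_group_a(calls[0], calls, roles)
        assert subgroup == "A3"
        assert {r for _, r in evidence} == {"hydB", "hydC"}

    def test_full_window_without_evidence_is_a1(self):
        calls, roles = operon([("cat", "+", ()), ("x1", "+", ()),
                               ("x2", "+", ()), ("x3", "+", ())])
        assert resolve_group_a(calls[0], calls, roles)[0] == "A1"

    def test_scaffold_edge_is_unresolved(self):
        calls, roles = operon([("up", "+", ()), ("cat", "+", ())])
        assert resolve_group_a(calls[1], calls, roles)[0] == "A_unresolved"

    def test_hydb_without_hydc_in_full_window_is_a1(self):
        calls, roles = operon([("cat", "+", ()), ("n1", "+", {"hydB"}),
                               ("x1", "+", ()), ("x2", "+", ())])
        assert resolve_group_a(calls[0], calls, roles)[0] == "A1"

    def test_hydb_without_hydc_at_edge_is_unresolved(self):
        calls, roles = operon([("cat", "+", ()), ("n1", "+", {"hydB"})])
        assert resolve_group_a(calls[0], calls, roles)[0] == "A_unresolved"

    def test_counter_oriented_neighbors_are_not_evidence(self):
        calls, roles = operon([("cat", "+", ()), ("n1", "-", {"hydB"}),
                               ("n2", "-", {"hydC"}), ("x1", "+", ())])
        assert resolve_group_a(calls[0], calls, roles)[0] == "A1"

    def test_minus_strand_reads_downstream_leftwards(self):
        calls, roles = operon([("n2", "-", {"hydC"}), ("n1", "-", {"hydB"}),
                               ("cat", "-", ()), ("x1", "-", ())])
        assert resolve_group_a(calls[2], calls, roles)[0] == "A3"

    def test_evidence_beyond_window_is_ignored(self):
        calls, roles = operon([("cat", "+", ()), ("x1", "+", ()),
                               ("x2", "+", ()), ("x3", "+", ()),
                               ("n1", "+", {"hydB"}), ("n2", "+", {"hydC"})])
        assert resolve_group_a(calls[0], calls, roles)[0] == "A1"

    def test_gene_not_on_scaffold_is_an_error(self):
        calls, roles = operon([("cat", "+", ()), ("x1", "+", ())])
        stranger = GeneCall("other", "sc", 1, 10, "+")
        with pytest.raises(ValueError, match="other"):
            resolve_group_a(stranger, calls, roles)


class TestLayoutFixtures:
    def _classify(self, layouts, seed=0):
        gff, table, truth = generate_operon_fixture(layouts, seed=seed)
        calls = parse_gene_calls(gff)
        hits = parse_profile_hits(table, default_cutoff=50.0)
        typed = classify_hydrogenases(calls, hits)
        got = {}
        for c in typed:
            got[c.gene_id] = c.label
        expected = {gene: label
                    for per_scaffold in truth.hydrogenase_labels.values()
                    for gene, label in per_scaffold.items()}
        return got, expected

    def test_canonical_layouts_match_planted_truth(self):
        layouts = [
            OperonLayout("a3", neighbors=(("hydB", True), ("hydC", True))),
            OperonLayout("a1", neighbors=(("x", True),) * 3),
            OperonLayout("edge", neighbors=(), truncated=True),
            OperonLayout("b", catalytic="FeFe_GB"),
            OperonLayout("c", catalytic="FeFe_GC"),
            OperonLayout("nife", catalytic="NiFe_G1"),
        ]
        got, expected = self._classify(layouts)
        assert got == expected
        assert set(expected.values()) == {"A3", "A1", "A_unresolved", "B",
                                          "C", "NiFe_1"}

    def test_strand_symmetry(self):
        neighbors = (("hydB", True), ("hydC", True), ("x", False))
        for truncated in (False, True):
            plus = OperonLayout("p", strand="+", neighbors=neighbors,
                                truncated=truncated)
            minus = OperonLayout("m", strand="-", neighbors=neighbors,
                                 truncated=truncated)
            got, expected = self._classify([plus, minus])
            labels = set(got.values())
            assert len(labels) == 1           # same call on both strands
            assert labels == set(expected.values())

    def test_input_order_invariance(self):
        layouts = [OperonLayout("a3", neighbors=(("hydB", True),
                                                 ("hydC", True))),
                   OperonLayout("edge", neighbors=(("hydC", True),),
                                truncated=True)]
        gff, table, _ = generate_operon_fixture(layouts, seed=0)
        calls = parse_gene_calls(gff)
        hits = parse_profile_hits(table, default_cutoff=50.0)
        baseline = [(c.gene_id, c.label) for c in
                    classify_hydrogenases(calls, hits)]
        rng = random.Random(13)
        for _ in range(5):
            shuffled = calls[:]
            rng.shuffle(shuffled)
            shuffled_hits = hits[:]
            rng.shuffle(shuffled_hits)
            again = [(c.gene_id, c.label) for c in
                     classify_hydrogenases(shuffled, shuffled_hits)]
            assert again == baseline

    def test_a3_calls_carry_both_evidence_roles(self):
        gff, table, _ = generate_operon_fixture(
            [OperonLayout("a3", neighbors=(("hydB", True), ("hydC", True)))],
            seed=1)
        typed = classify_hydrogenases(parse_gene_calls(gff),
                                      parse_profile_hits(table,
                                                         default_cutoff=50.0))
        (call,) = [c for c in typed if c.subgroup == "A3"]
        assert {r for _, r in call.evidence} >= {"hydB", "hydC"}


class TestSummaryAndCooccurrence:
    def _summary(self, per_bin_labels, rnf_bins=()):
        bins = [GenomeBin(b, {f"{b}_s"}) for b in per_bin_labels]
        calls, gene_bins, hits = [], {}, []
        from genopotential.hydrogenase_typing import HydrogenaseCall
        for b, labels in per_bin_labels.items():
            for i, label in enumerate(labels):
                gene = f"{b}_h{i}"
                gene_bins[gene] = b
                sub = label if label in ("A1", "A3", "A_unresolved") else "n/a"
                group = "A" if sub != "n/a" else label
                calls.append(HydrogenaseCall(gene, "FeFe", group, sub))
            if b in rnf_bins:
                gene = f"{b}_rnf"
                gene_bins[gene] = b
                hits.append(hit(gene, "rnfC"))
        return summarize_hydrogenases(bins, calls, hits, gene_bins)

    def test_counts_and_flags(self):
        summary = self._summary({"b1": ["A3", "A3", "B"], "b2": []},
                                rnf_bins=["b1"])
        assert summary.has_bifurcating("b1") and summary.has_b("b1")
        assert summary.has_rnf["b1"] and not summary.has_rnf["b2"]
        assert summary.counts["b2"] == {}
        assert summary.total() == 3

    def test_seventy_percent_rnf(self):
        labels = {f"b{i}": ["A3"] for i in range(10)}
        summary = self._summary(labels, rnf_bins=[f"b{i}" for i in range(7)])
        _, frac_rnf, _ = cooccurrence_stats(summary)
        assert frac_rnf == 0.7

    def test_a1_always_with_a3(self):
        labels = {"b1": ["A1", "A3"], "b2": ["A1", "A3"], "b3": ["A1", "A3"],
                  "b4": ["A3"]}
        frac_a1, _, frac_b = cooccurrence_stats(self._summary(labels))
        assert frac_a1 == 1.0
        assert frac_b is None            # no Group B bins at all

    def test_no_a1_bins_gives_missing_fraction(self):
        frac_a1, _, _ = cooccurrence_stats(self._summary({"b1": ["A3"]}))
        assert frac_a1 is None
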