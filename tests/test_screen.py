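"""Identity computation, greedy clustering, and mislabel flagging."""

import random

import pytest

from conftest import make_entry, make_lineage
from mitoref.events import Reason
from mitoref.genes import CanonicalGene
from mitoref.screen import (FlagReport, IdentityParams, apply_adjudication,
                            flag_events, flag_mixed_clusters, greedy_cluster,
                            min_shared_words, pairwise_identity,
                            read_removal_list)
from oracles import greedy_cluster_oracle, identity_oracle


def _random_family(rng, n, length, divergence):
    base = "".join(rng.choices("ACGT", k=length))
    out = [base]
    for _ in range(n - 1):
        seq = list(base)
        for _ in range(max(1, int(divergence * length))):
            pos = rng.randrange(length)
            seq[pos] = rng.choice("ACGT")
        out.append("".join(seq))
    return out


class TestPairwiseIdentity:
    def test_identical(self):
        assert pairwise_identity("ACGT", "ACGT") == 1.0

    def test_three_of_four(self):
        assert pairwise_identity("ACGT", "ACGA") == 0.75

    def test_symmetric_and_substring_match(self):
        assert pairwise_identity("ACGTACGT", "TTACGTACGTTT") == 1.0
        a = "ACGTTGCAACGG"
        b = "ACGTTGCTACGGA"
        assert pairwise_identity(a, b) == pairwise_identity(b, a)

    def test_ambiguity_codes_are_mismatches(self):
        assert pairwise_identity("ACGT", "ACGN") == 0.75

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            pairwise_identity("", "ACGT")

    def test_agrees_with_dynamic_programming_oracle(self):
        """100 random pairs against the full-matrix alignment oracle."""
        rng = random.Random(1234)
        for i in range(100):
            la = rng.randint(5, 200)
            lb = rng.randint(5, 200)
            if i % 3 == 0:  # include related pairs, not just noise
                a = "".join(rng.choices("ACGT", k=la))
                b = list(a)
                for _ in range(rng.randint(0, 5)):
                    b[rng.randrange(len(b))] = rng.choice("ACGT")
                b = "".join(b)
            else:
                a = "".join(rng.choices("ACGT", k=la))
                b = "".join(rng.choices("ACGT", k=lb))
            assert pairwise_identity(a, b) == pytest.approx(
                identity_oracle(a, b), abs=1e-12)


class TestGreedyCluster:
    def test_identical_pair_one_cluster(self):
        entries = [make_entry("A.COI.1", "ACGTACGTACGT" * 10),
                   make_entry("B.COI.1", "ACGTACGTACGT" * 10)]
        clusters = greedy_cluster(entries)
        assert len(clusters) == 1 and len(clusters[0].members) == 2
        assert clusters[0].centroid == "A.COI.1"

    def test_dissimilar_pair_two_singletons(self):
        rng = random.Random(0)
        entries = [make_entry("A.COI.1", "".join(rng.choices("ACGT", k=200))),
                   make_entry("B.COI.1", "".join(rng.choices("ACGT", k=200)))]
        assert len(greedy_cluster(entries)) == 2

    def test_threshold_zero_limit_single_cluster(self):
        rng = random.Random(5)
        entries = [make_entry(f"S{i}.COI.1",
                              "".join(rng.choices("ACGT", k=100)))
                   for i in range(6)]
        clusters = greedy_cluster(entries, IdentityParams(threshold=1e-9))
        assert len(clusters) == 1

    def test_threshold_one_groups_exact_near_duplicates_only(self):
        entries = [make_entry("A.COI.1", "ACGT" * 50),
                   make_entry("B.COI.1", "ACGT" * 50),
                   make_entry("C.COI.1", "ACGT" * 49 + "ACGA")]
        clusters = greedy_cluster(entries, IdentityParams(threshold=1.0))
        sizes = sorted(len(c.members) for c in clusters)
        assert sizes == [1, 2]

    def test_mixed_genes_rejected(self):
        entries = [make_entry("A.COI.1", "ACGT" * 30),
                   make_entry("B.srRNA.1", "ACGT" * 60,
                              gene=CanonicalGene.srRNA)]
        with pytest.raises(ValueError):
            greedy_cluster(entries)

    def test_partition_property(self):
        rng = random.Random(7)
        entries = []
        for f in range(4):
            for j, seq in enumerate(_random_family(rng, 4, 150, 0.004)):
                entries.append(make_entry(f"F{f}S{j}.COI.1", seq))
        clusters = greedy_cluster(entries)
        ids = [sid for c in clusters for sid in c.member_ids]
        assert sorted(ids) == sorted(e.seqid for e in entries)
        assert len(ids) == len(set(ids))

    @pytest.mark.parametrize("threshold", [0.99, 0.95, 0.90])
    def test_matches_naive_oracle(self, threshold):
        """Prescreen + edlib equals exhaustive no-prescreen clustering."""
        rng = random.Random(int(threshold * 1000))
        for _ in range(8):
            entries = []
            i = 0
            for _f in range(rng.randint(1, 4)):
                fam = _random_family(rng, rng.randint(1, 6),
                                     rng.randint(60, 250),
                                     rng.choice([0.002, 0.01, 0.05]))
                for seq in fam:
                    entries.append(make_entry(f"S{i:03d}.COI.1", seq))
                    i += 1
            params = IdentityParams(threshold=threshold)
            got = [c.member_ids for c in greedy_cluster(entries, params)]
            assert got == greedy_cluster_oracle(entries, threshold)


class TestPrescreenBound:
    def test_bound_is_nonbinding_for_short_queries(self):
        assert min_shared_words(5, IdentityParams()) == 0

    def test_bound_never_excludes_admissible_pairs(self):
        """Mutate within threshold; shared words must reach the bound."""
        rng = random.Random(21)
        params = IdentityParams(threshold=0.95)
        for _ in range(50):
            m = rng.randint(50, 400)
            a = "".join(rng.choices("ACGT", k=m))
            d = rng.randint(0, int((1 - params.threshold) * m))
            b = list(a)
            for _ in range(d):
                b[rng.randrange(m)] = rng.choice("ACGT")
            b = "".join(b)
            if pairwise_identity(a, b) < params.threshold:
                continue
            kmers = {b[i:i + params.prescreen_k]
                     for i in range(m - params.prescreen_k + 1)}
            shared = sum(1 for i in range(m - params.prescreen_k + 1)
                         if a[i:i + params.prescreen_k] in kmers)
            assert shared >= min_shared_words(m, params)


class TestFlagging:
    def _clusters(self, lineages, seq="ACGT" * 50):
        entries = [make_entry(f"S{i}.COI.1", seq, lineage=lin)
                   for i, lin in enumerate(lineages)]
        return greedy_cluster(entries)

    def test_homogeneous_cluster_not_flagged(self):
        lin = make_lineage()
        report = flag_mixed_clusters(self._clusters([lin, lin]))
        assert not report.flagged
        assert report.counts[CanonicalGene.COI] == {
            "phylum": 0, "class": 0, "order": 0}

    def test_cross_order_mix_flagged_at_order_only(self):
        a = make_lineage(order="Diptera")
        b = make_lineage(order="Lepidoptera", family="Noctuidae",
                         genus="Noctua", species="Noctua pronuba")
        report = flag_mixed_clusters(self._clusters([a, b]))
        assert report.counts[CanonicalGene.COI] == {
            "phylum": 0, "class": 0, "order": 1}
        assert report.flagged[0].mixed_levels == ("order",)

    def test_cross_phylum_mix_counted_at_every_differing_level(self):
        a = make_lineage()
        b = make_lineage(phylum="Chordata", class_="Aves",
                         order="Passeriformes", family="Furnariidae",
                         genus="Automolus", species="Automolus rubiginosus")
        report = flag_mixed_clusters(self._clusters([a, b]))
        assert report.counts[CanonicalGene.COI] == {
            "phylum": 1, "class": 1, "order": 1}

    def test_placeholder_labels_ignored(self):
        a = make_lineage()
        b = make_lineage(order="Aedes_ord", family="Aedes_fam")
        report = flag_mixed_clusters(self._clusters([a, b]))
        assert not report.flagged

    def test_flag_events_name_every_member(self):
        a = make_lineage(order="Diptera")
        b = make_lineage(order="Lepidoptera", genus="Noctua",
                         species="Noctua pronuba")
        report = flag_mixed_clusters(self._clusters([a, b]))
        events = flag_events(report)
        assert {e.subject for e in events} == {"S0.COI.1", "S1.COI.1"}
        assert all(e.reason == Reason.MISLABEL_FLAGGED for e in events)


class TestAdjudication:
    def _flagged_setup(self):
        donor = make_entry("A.COI.1", "ACGT" * 50, lineage=make_lineage())
        mislabeled = make_entry(
            "B.COI.1", "ACGT" * 50,
            lineage=make_lineage(order="Lepidoptera", genus="Noctua",
                                 species="Noctua pronuba"))
        clean = make_entry("C.COI.1", "TTAA" * 60,
                           lineage=make_lineage(species="Aedes albopictus"))
        variant = [donor, mislabeled, clean]
        report = flag_mixed_clusters(greedy_cluster([donor, mislabeled]))
        return variant, report

    def test_empty_removal_list_is_identity(self):
        variant, report = self._flagged_setup()
        kept, events = apply_adjudication(variant, [], report)
        assert kept == variant and events == []

    def test_removal_eliminates_future_flags(self):
        variant, report = self._flagged_setup()
        kept, events = apply_adjudication(variant, ["B.COI.1"], report)
        assert len(kept) == len(variant) - 1
        assert events[0].reason == Reason.MISLABEL_REMOVED
        rescreen = flag_mixed_clusters(
            greedy_cluster([e for e in kept if e.gene is CanonicalGene.COI]))
        assert not rescreen.flagged

    def test_unknown_id_rejected(self):
        variant, report = self._flagged_setup()
        with pytest.raises(ValueError, match="not present"):
            apply_adjudication(variant, ["Z.COI.1"], report)

    def test_unflagged_id_rejected(self):
        variant, report = self._flagged_setup()
        with pytest.raises(ValueError, match="never flagged"):
            apply_adjudication(variant, ["C.COI.1"], report)

    def test_removal_list_parsing(self):
        text = "# adjudicated 2016-02-01\nA.COI.1\n\n  B.COI.1  \n"
        assert read_removal_list(text) == ["A.COI.1", "B.COI.1"]
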