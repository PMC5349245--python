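"""Lineage resolution, QC filters, conflict renaming, and the rank tree."""

import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_lineage
from mitoref.events import Reason
from mitoref.taxonomy import (Lineage, QCPolicy, TaxdumpIndex, build_rank_tree,
                              is_placeholder, qc_lineage,
                              resolve_lineage, resolve_name_conflicts)


def _index(missing_ranks=()):
    """A small taxdump: root → Eukaryota → Metazoa → ... → species."""
    rows = [(1, 1, "no rank", "root"),
            (2, 1, "superkingdom", "Eukaryota"),
            (3, 2, "kingdom", "Metazoa")]
    chain = [("phylum", "Chordata"), ("class", "Aves"),
             ("order", "Passeriformes"), ("family", "Furnariidae"),
             ("genus", "Automolus"), ("species", "Automolus rubiginosus")]
    parent = 3
    taxid = 3
    for rank, name in chain:
        if rank in missing_ranks:
            continue
        taxid += 1
        rows.append((taxid, parent, rank, name))
        parent = taxid
    nodes = "".join(f"{t}\t|\t{p}\t|\t{r}\t|\n" for t, p, r, _ in rows)
    names = "".join(f"{t}\t|\t{n}\t|\t\t|\tscientific name\t|\n"
                    for t, _, _, n in rows)
    return TaxdumpIndex.from_taxdump(nodes, names), taxid


class TestResolveLineage:
    def test_full_path(self):
        index, species_id = _index()
        lin = resolve_lineage(species_id, index)
        assert lin.levels() == ("Root", "Metazoa", "Chordata", "Aves",
                                "Passeriformes", "Furnariidae", "Automolus",
                                "Automolus rubiginosus")

    def test_missing_class_and_family_filled_with_placeholders(self):
        index, species_id = _index(missing_ranks=("class", "family"))
        lin = resolve_lineage(species_id, index)
        assert lin.class_ == "Passeriformes_cla"
        assert lin.family == "Automolus_fam"
        assert is_placeholder(lin.class_) and is_placeholder(lin.family)
        assert not is_placeholder(lin.order)

    def test_root_taxid_yields_all_placeholders_then_fails_qc(self):
        index, _ = _index()
        lin = resolve_lineage(1, index)
        assert all(is_placeholder(name) for name in lin.levels())
        assert qc_lineage(lin).reason == Reason.NO_SPECIES_RANK

    def test_unresolvable_taxid_raises(self):
        index, _ = _index()
        with pytest.raises(LookupError):
            resolve_lineage(999, index)

    def test_mapping_protocol_for_metazoa_filter(self):
        index, species_id = _index()
        assert "Metazoa" in index[species_id]
        with pytest.raises(KeyError):
            index[999]


class TestQC:
    def test_policy_defaults_match_published_lists(self):
        policy = QCPolicy()
        assert policy.forbidden_tokens == (
            "cf.", "aff.", "sp.", "environment", "undescribed", "uncultured",
            "complex", "unclassified", "nom.", "nud.", "unidentif")
        assert policy.blacklist_ids == ("sp0936BC", "MG98.09", "sp0942A",
                                        "EEG-2007")

    @pytest.mark.parametrize("species,reason,detail_token", [
        ("Gonodactylus cf. smithii", Reason.FORBIDDEN_TOKEN, "cf."),
        ("Lepidoptera EEG-2007", Reason.BLACKLISTED_ID, "EEG-2007"),
        ("Daphnia", Reason.NO_SPECIES_RANK, None),
        ("Calanus Sp. nov", Reason.FORBIDDEN_TOKEN, "sp."),
    ])
    def test_failing_species(self, species, reason, detail_token):
        lin = make_lineage(genus=species.split()[0], species=species)
        verdict = qc_lineage(lin)
        assert verdict.reason == reason
        if detail_token:
            assert detail_token in verdict.detail

    def test_clean_binomial_passes(self):
        assert qc_lineage(make_lineage(genus="Homo", species="Homo sapiens",
                                       family="Hominidae", order="Primates",
                                       class_="Mammalia",
                                       phylum="Chordata")) is None

    def test_forbidden_token_scans_all_ranks(self):
        lin = make_lineage(order="unclassified Diptera")
        assert qc_lineage(lin).reason == Reason.FORBIDDEN_TOKEN

    def test_placeholder_species_fails_binomial_check(self):
        lin = make_lineage(species="Aedes_spe")
        assert qc_lineage(lin).reason == Reason.NO_SPECIES_RANK

    def test_order_of_checks_is_binomial_first(self):
        # single token that also contains a forbidden token
        lin = make_lineage(species="uncultured")
        assert qc_lineage(lin).reason == Reason.NO_SPECIES_RANK


class TestConflicts:
    def _bird(self, genus="Automolus", species=None):
        return make_lineage(phylum="Chordata", class_="Aves",
                            order="Passeriformes", family="Furnariidae",
                            genus=genus, species=species or f"{genus} rubiginosus")

    def _beetle(self, genus="Automolus", species=None):
        return make_lineage(phylum="Arthropoda", class_="Insecta",
                            order="Coleoptera", family="Staphylinidae",
                            genus=genus, species=species or f"{genus} similis")

    def test_worked_example_second_occurrence_becomes_01(self):
        renamed, rename_map = resolve_name_conflicts(
            [self._bird(), self._beetle()])
        genera = sorted(l.genus for l in renamed)
        assert genera == ["Automolus", "Automolus01"]
        assert list(rename_map.values()) == ["Automolus01"]
        # the later parent path in sort order got the suffix
        renamed_by_phylum = {l.phylum: l.genus for l in renamed}
        assert renamed_by_phylum["Arthropoda"] == "Automolus"
        assert renamed_by_phylum["Chordata"] == "Automolus01"

    def test_species_binomial_follows_renamed_genus(self):
        renamed, _ = resolve_name_conflicts([self._bird(), self._beetle()])
        for lin in renamed:
            assert lin.species.split()[0] == lin.genus

    def test_no_duplicates_is_identity(self):
        lineages = [self._bird(), self._beetle(genus="Staphylinus")]
        renamed, rename_map = resolve_name_conflicts(lineages)
        assert renamed == lineages and rename_map == {}

    def test_three_way_clash_gets_01_and_02(self):
        third = make_lineage(phylum="Mollusca", class_="Gastropoda",
                             order="Stylommatophora", family="Helicidae",
                             genus="Automolus", species="Automolus terrestris")
        renamed, _ = resolve_name_conflicts([self._bird(), self._beetle(), third])
        assert sorted(l.genus for l in renamed) == \
            ["Automolus", "Automolus01", "Automolus02"]

    def test_idempotence(self):
        renamed, _ = resolve_name_conflicts([self._bird(), self._beetle()])
        again, rename_map = resolve_name_conflicts(renamed)
        assert again == renamed and rename_map == {}

    def test_cross_rank_conflict_detected(self):
        a = self._bird()
        b = self._beetle(genus="Passeriformes")  # order name reused as genus
        renamed, _ = resolve_name_conflicts([a, b])
        names = [(l.order, l.genus) for l in renamed]
        flat = [n for pair in names for n in pair]
        assert len(set(flat)) == len(set(("Passeriformes", "Passeriformes01",
                                          "Coleoptera", "Automolus")))

    def test_post_rename_triples_injective(self):
        renamed, _ = resolve_name_conflicts([self._bird(), self._beetle()])
        triples = set()
        for lin in renamed:
            levels = lin.levels()
            for depth in range(1, 7):
                triples.add((levels[depth], depth, levels[:depth]))
        names_at_rank = [(name, depth) for name, depth, _ in triples]
        assert len(names_at_rank) == len(set(names_at_rank))


class TestRankTree:
    def test_two_species_sharing_genus_gives_nine_nodes(self):
        a = make_lineage(species="Aedes aegypti")
        b = make_lineage(species="Aedes albopictus")
        assert len(build_rank_tree([a, b])) == 9

    def test_single_species_gives_eight_nodes(self):
        assert len(build_rank_tree([make_lineage()])) == 8

    def test_empty_input_gives_root_only(self):
        tree = build_rank_tree([])
        assert len(tree) == 1
        assert tree[0].rank == "rootrank" and tree[0].parent_taxid == -1

    def test_species_depth_is_seven_and_ids_dense(self):
        a = make_lineage(species="Aedes aegypti")
        b = make_lineage(genus="Culex", species="Culex pipiens")
        tree = build_rank_tree([a, b])
        assert [n.taxid for n in tree] == list(range(len(tree)))
        depth = {}
        for node in tree:
            depth[node.taxid] = 0 if node.parent_taxid < 0 \
                else depth[node.parent_taxid] + 1
        species_depths = {depth[n.taxid] for n in tree if n.rank == "species"}
        assert species_depths == {7}

    def test_residual_duplicate_is_hard_error(self):
        a = make_lineage()
        b = make_lineage(phylum="Chordata", class_="Aves",
                         order="Passeriformes", family="Furnariidae",
                         genus="Aedes", species="Aedes rubiginosus")
        with pytest.raises(ValueError, match="resolve_name_conflicts"):
            build_rank_tree([a, b])

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.integers(min_value=1, max_value=12))
    def test_node_count_bounds(self, n_species):
        lineages = [make_lineage(genus=f"Genus{i}",
                                 species=f"Genus{i} epithet")
                    for i in range(n_species)]
        tree = build_rank_tree(lineages)
        assert 8 <= len(tree) <= 1 + 7 * n_species
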