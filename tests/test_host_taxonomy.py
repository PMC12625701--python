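import numpy as np
import pandas as pd
import pytest

from cnpskit.host_taxonomy import (
    RANKS,
    UNCLASSIFIED,
    Lineage,
    link_hosts,
    parse_lineage,
    summarize_by_group,
)
from cnpskit.ontology import CycleMapping, ProcessDef
from cnpskit.process_abundance import PresenceVector
from cnpskit.table_io import (
    GeneAbundanceTable,
    GeneFunctionTable,
    GeneTaxonomyTable,
    InputBundle,
    KOTable,
)

from conftest import group_of


class TestParseLineage:
    def test_prefixed_full_lineage(self):
        ln = parse_lineage(
            "p__Firmicutes;c__Bacilli;o__Bacillales;f__Bacillaceae;"
            "g__Bacillus;s__Bacillus subtilis"
        )
        assert ln.phylum == "Firmicutes"
        assert ln.species == "Bacillus subtilis"

    def test_domain_and_kingdom_prefixes_discarded(self):
        ln = parse_lineage("d__Bacteria;p__Firmicutes;c__Bacilli")
        assert ln.phylum == "Firmicutes"
        assert ln.class_ == "Bacilli"
        assert ln.order == UNCLASSIFIED

    def test_plain_two_fields_pad_with_unclassified(self):
        ln = parse_lineage("Actinobacteria;Actinomycetia")
        assert ln.phylum == "Actinobacteria"
        assert ln.class_ == "Actinomycetia"
        assert all(ln.at(r) == UNCLASSIFIED for r in RANKS[2:])

    def test_prefixed_and_plain_dialects_agree(self):
        plain = parse_lineage("Firmicutes;Bacilli;Bacillales")
        prefixed = parse_lineage("p__Firmicutes;c__Bacilli;o__Bacillales")
        assert plain == prefixed

    def test_plain_seven_fields_drop_leading_domain(self):
        ln = parse_lineage("Bacteria;Firmicutes;Bacilli;Bacillales;Bacillaceae;Bacillus;Bacillus subtilis")
        assert ln.phylum == "Firmicutes"
        assert ln.species == "Bacillus subtilis"

    def test_empty_string_all_unclassified_with_warning(self):
        with pytest.warns(UserWarning):
            ln = parse_lineage("")
        assert ln == Lineage()


def _toy_bundle(genes, kos, lineages, abundance, samples):
    df = pd.DataFrame(abundance, index=pd.Index(genes, name="GeneID"), columns=samples)
    ko_ids = sorted(set(kos))
    ko_values = df.groupby(pd.Index(kos, name="KO")).sum().reindex(ko_ids)
    return InputBundle(
        ko=KOTable(values=ko_values, descriptions=pd.Series("", index=ko_values.index)),
        group=group_of(samples, ["A"] * len(samples)),
        gene=GeneFunctionTable(table=pd.DataFrame({"GeneID": genes, "KO": kos})),
        tax=GeneTaxonomyTable(assignments=pd.Series(lineages, index=genes)),
        abundance=GeneAbundanceTable(values=df),
    )


MAPPING = CycleMapping(
    processes=[
        ProcessDef("p1", "Process one", "C", ("K00001", "K00002")),
        ProcessDef("p2", "Process two", "C", ("K00003",)),
    ]
)


class TestLinkHosts:
    def test_single_gene_flows_to_its_phylum(self):
        bundle = _toy_bundle(
            ["g1"], ["K00001"], ["p__Firmicutes;c__Bacilli"], [[10.0]], ["s1"]
        )
        presence = PresenceVector("C", {"p1": True, "p2": False})
        profiles = link_hosts(bundle, MAPPING, "C", presence)
        phylum = next(p for p in profiles if p.rank == "phylum")
        assert phylum.table.loc["Firmicutes", "s1"] == 10.0
        # undetected process skipped entirely
        assert {p.process_id for p in profiles} == {"p1"}

    def test_same_phylum_different_species_aggregate(self):
        bundle = _toy_bundle(
            ["g1", "g2"],
            ["K00001", "K00002"],
            ["p__Firmicutes;c__Bacilli;o__X;f__Y;g__Z;s__A", "p__Firmicutes;c__Bacilli;o__X;f__Y;g__Z;s__B"],
            [[1.0], [2.0]],
            ["s1"],
        )
        presence = PresenceVector("C", {"p1": True, "p2": False})
        profiles = {p.rank: p for p in link_hosts(bundle, MAPPING, "C", presence)}
        assert profiles["phylum"].table.loc["Firmicutes", "s1"] == 3.0
        assert len(profiles["species"].table) == 2

    def test_matches_brute_force_join(self):
        rng = np.random.default_rng(21)
        taxa = [
            "p__A;c__A1;o__A2;f__A3;g__A4;s__A5",
            "p__B;c__B1;o__B2;f__B3;g__B4;s__B5",
            "p__A;c__A9;o__A8;f__A7;g__A6;s__A0",
        ]
        genes = [f"g{i}" for i in range(30)]
        kos = list(rng.choice(["K00001", "K00002", "K00003", "K00009"], size=30))
        lineages = list(rng.choice(taxa, size=30))
        samples = ["s1", "s2"]
        abundance = rng.lognormal(0, 1, size=(30, 2))
        bundle = _toy_bundle(genes, kos, lineages, abundance, samples)
        presence = PresenceVector("C", {"p1": True, "p2": True})
        profiles = link_hosts(bundle, MAPPING, "C", presence)

        for profile in profiles:
            proc = MAPPING.process(profile.process_id)
            expected: dict[str, np.ndarray] = {}
            for gi, g in enumerate(genes):
                if kos[gi] not in proc.ko_ids:
                    continue
                taxon = parse_lineage(lineages[gi]).at(profile.rank)
                expected.setdefault(taxon, np.zeros(2))
                expected[taxon] += abundance[gi]
            assert set(profile.table.index) == set(expected)
            for taxon, row in expected.items():
                assert profile.table.loc[taxon].to_numpy() == pytest.approx(row)

    def test_total_abundance_identical_across_ranks(self):
        rng = np.random.default_rng(4)
        genes = [f"g{i}" for i in range(12)]
        kos = ["K00001"] * 12
        taxa = ["p__A;c__B;o__C;f__D;g__E;s__F", "p__A;c__X", "p__Q"]
        lineages = list(rng.choice(taxa, size=12))
        abundance = rng.lognormal(0, 1, size=(12, 3))
        bundle = _toy_bundle(genes, kos, lineages, abundance, ["s1", "s2", "s3"])
        presence = PresenceVector("C", {"p1": True, "p2": False})
        profiles = link_hosts(bundle, MAPPING, "C", presence)
        totals = {p.rank: p.table.sum(axis=0).to_numpy() for p in profiles}
        reference = totals["phylum"]
        for rank in RANKS:
            assert totals[rank] == pytest.approx(reference)

    def test_gene_without_taxonomy_counts_unclassified(self):
        bundle = _toy_bundle(["g1"], ["K00001"], ["p__A"], [[5.0]], ["s1"])
        bundle.tax = GeneTaxonomyTable(assignments=pd.Series(dtype=object))
        presence = PresenceVector("C", {"p1": True, "p2": False})
        profiles = link_hosts(bundle, MAPPING, "C", presence)
        phylum = next(p for p in profiles if p.rank == "phylum")
        assert phylum.table.loc[UNCLASSIFIED, "s1"] == 5.0

    def test_multi_ko_gene_counts_once_per_process(self):
        # gene annotated to both KOs of p1: contributes its abundance once
        genes = ["g1", "g1"]
        bundle = _toy_bundle(
            ["g1"], ["K00001"], ["p__A"], [[7.0]], ["s1"]
        )
        bundle.gene = GeneFunctionTable(
            table=pd.DataFrame({"GeneID": genes, "KO": ["K00001", "K00002"]})
        )
        presence = PresenceVector("C", {"p1": True, "p2": False})
        phylum = next(
            p for p in link_hosts(bundle, MAPPING, "C", presence) if p.rank == "phylum"
        )
        assert phylum.table.loc["A", "s1"] == 7.0


class TestSummarizeByGroup:
    def test_relative_columns_sum_to_one(self):
        rng = np.random.default_rng(8)
        genes = [f"g{i}" for i in range(6)]
        bundle = _toy_bundle(
            genes,
            ["K00001"] * 6,
            ["p__A", "p__B", "p__A", "p__C", "p__B", "p__A"],
            rng.lognormal(0, 1, size=(6, 4)),
            ["s1", "s2", "s3", "s4"],
        )
        bundle.group = group_of(["s1", "s2", "s3", "s4"], ["A", "A", "B", "B"])
        presence = PresenceVector("C", {"p1": True, "p2": False})
        profile = next(
            p for p in link_hosts(bundle, MAPPING, "C", presence) if p.rank == "phylum"
        )
        profile = summarize_by_group(profile, bundle.group)
        rel_sample = profile.table / profile.table.sum(axis=0)
        assert rel_sample.sum(axis=0).to_numpy() == pytest.approx(np.ones(4))
        # group means of per-sample relative columns
        expected_a = rel_sample[["s1", "s2"]].mean(axis=1)
        assert profile.relative_by_group["A"].to_numpy() == pytest.approx(
            expected_a.to_numpy()
        )

    def test_identical_samples_group_column_equals_sample(self):
        bundle = _toy_bundle(
            ["g1", "g2"],
            ["K00001", "K00001"],
            ["p__A", "p__B"],
            [[2.0, 2.0], [6.0, 6.0]],
            ["s1", "s2"],
        )
        bundle.group = group_of(["s1", "s2"], ["A", "A"])
        presence = PresenceVector("C", {"p1": True, "p2": False})
        profile = next(
            p for p in link_hosts(bundle, MAPPING, "C", presence) if p.rank == "phylum"
        )
        profile = summarize_by_group(profile, bundle.group)
        assert profile.relative_by_group["A"].to_numpy() == pytest.approx([0.25, 0.75])
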