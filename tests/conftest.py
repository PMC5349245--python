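import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from mitoref.datasets import RefSeqEntry
from mitoref.genes import CanonicalGene
from mitoref.simulate import FixtureSpec, PlantedCounts, generate
from mitoref.taxonomy import Lineage


def make_lineage(phylum="Arthropoda", class_="Insecta", order="Diptera",
                 family="Culicidae", genus="Aedes", species=None,
                 kingdom="Metazoa") -> Lineage:
    if species is None:
        species = f"{genus} aegypti"
    return Lineage(kingdom=kingdom, phylum=phylum, class_=class_, order=order,
                   family=family, genus=genus, species=species)


def make_entry(seqid: str, sequence: str, gene=CanonicalGene.COI,
               lineage: Lineage | None = None, **lineage_kw) -> RefSeqEntry:
    return RefSeqEntry(seqid, gene, lineage or make_lineage(**lineage_kw),
                       sequence)


@pytest.fixture(scope="session")
def defect_bundle():
    """A mid-size fixture with every defect category planted once or twice."""
    spec = FixtureSpec(
        seed=20259, n_phyla=3, n_species_per_phylum=10,
        planted=PlantedCounts(
            non_binomial=2, forbidden_token=2, blacklisted=1, too_short=1,
            too_long=1, duplicate_name_conflicts=1, cross_order_mislabels=1,
            missing_rank=1, non_mito=1, non_metazoa=1))
    return spec, generate(spec)


@pytest.fixture(scope="session")
def clean_bundle():
    spec = FixtureSpec(seed=11, n_phyla=2, n_species_per_phylum=6)
    return spec, generate(spec)
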