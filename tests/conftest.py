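import numpy as np
import pytest

from rbptm.config import AnalysisConfig
from rbptm.types import ProteinRecord, PTMSite, SiteEvidence
from rbptm.vocabulary import default_vocabulary


@pytest.fixture(scope="session")
def vocabulary():
    return default_vocabulary()


@pytest.fixture()
def config():
    return AnalysisConfig(seed=0)


def make_site(accession, position, ptm_type="phosphorylation", residue="S",
              source="src", pmid=None, **context):
    return PTMSite(
        accession=accession, position=position, residue=residue, ptm_type=ptm_type,
        evidence=(SiteEvidence(source=source, pmid=pmid, **context),),
    )


def make_proteome(lengths, rbps=(), tags=None):
    """lengths: dict accession -> length."""
    tags = tags or {}
    return {
        acc: ProteinRecord(accession=acc, gene_name=f"g{acc}", length=length,
                           is_rbp=acc in rbps, family_tags=set(tags.get(acc, ())))
        for acc, length in lengths.items()
    }


def random_sites(rng, proteome, n, types=("phosphorylation", "acetylation")):
    accessions = sorted(proteome)
    sites = set()
    while len(sites) < n:
        acc = accessions[rng.integers(len(accessions))]
        pos = int(rng.integers(1, proteome[acc].length + 1))
        ptm = types[rng.integers(len(types))]
        sites.add((acc, pos, ptm))
    return [make_site(acc, pos, ptm) for acc, pos, ptm in sorted(sites)]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
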