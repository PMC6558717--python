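import numpy as np
import pytest

from bbxkit.evolution import codon_align, kaks
from bbxkit.homology import find_homologs
from bbxkit.simulate import SimulationConfig, make_family

FAMILY_SEED = 1


@pytest.fixture(scope="session")
def family():
    """The default synthetic two-genome family (fixed seed)."""
    return make_family(SimulationConfig(seed=FAMILY_SEED))


@pytest.fixture(scope="session")
def family_homologs(family):
    """(pairs, alignment cache) from RBH on the synthetic family."""
    return find_homologs(
        family.proteins["Do"], family.proteins["Pe"], genome_a="Do", genome_b="Pe"
    )


@pytest.fixture(scope="session")
def family_cds(family):
    return {r.id: r.seq for g in family.cds for r in family.cds[g]}


@pytest.fixture(scope="session")
def family_kaks(family_homologs, family_cds):
    pairs, cache = family_homologs
    results = {}
    for pair in pairs:
        aln = cache[pair.key]
        results[pair.key] = kaks(
            codon_align(family_cds[aln.id_a], family_cds[aln.id_b], aln)
        )
    return results


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
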