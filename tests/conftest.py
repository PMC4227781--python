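import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

import istronkit as ik

EXPECTED_COMPOSITION = {
    "intact": "ORF_A+ORF_B",
    "delta_orfA": "dORF_A+ORF_B",
    "phi_orfA": "phiORF_A+ORF_B",
    "orfB_only": "ORF_B_only",
    "orfless_emetic": "no_ORF",
}


@pytest.fixture(scope="session")
def refs():
    return ik.load_reference_orfs()


@pytest.fixture(scope="session")
def survey_sim():
    """The default 20-genome study set (survey-scale conditions)."""
    return ik.simulate_survey_genomes(seed=1)


@pytest.fixture(scope="session")
def survey_calls(survey_sim):
    """Pipeline calls per genome with the paired homologs supplied."""
    out = {}
    for g in survey_sim.genomes:
        homs = [h for h in survey_sim.homologs if h.id.split("|")[1] == g.id]
        out[g.id] = ik.call_istrons(g, homologs=homs)
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def locus_b():
    """One intact group-B locus with ground truth."""
    return ik.simulate_locus("B", seed=11)


@pytest.fixture(scope="session")
def locus_a():
    """One intact group-A locus with ground truth."""
    return ik.simulate_locus("A", seed=12)
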