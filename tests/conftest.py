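import numpy as np
import pytest

import codonscan as cs
from codonscan.filters import AminoAlignment, CodonAlignment


@pytest.fixture(scope="session")
def study_tree():
    """The 6-taxon fixture tree with the caecilian stem marked foreground."""
    return cs.fixture_tree()


@pytest.fixture(scope="session")
def null_alignment(study_tree):
    """A 200-codon alignment simulated without positive selection."""
    params = cs.BranchSiteParams(2.0, 0.5, 0.3, 0.2, 1.0)
    aln, truth = cs.simulate_codon_alignment(study_tree, params, 200, seed=77)
    return aln, truth


@pytest.fixture(scope="session")
def selected_alignment(study_tree):
    """A 300-codon alignment with strong foreground selection (omega2=8)."""
    params = cs.BranchSiteParams(2.0, 0.5, 0.2, 0.2, 8.0)
    aln, truth = cs.simulate_codon_alignment(study_tree, params, 300, seed=11)
    return aln, truth


def make_aa(rows: dict[str, str]) -> AminoAlignment:
    taxa = list(rows)
    return AminoAlignment(taxa, np.array([list(r) for r in rows.values()], dtype="<U1"))


def make_codon(rows: dict[str, str]) -> CodonAlignment:
    taxa = list(rows)
    mats = []
    for r in rows.values():
        assert len(r) % 3 == 0
        mats.append([r[i : i + 3] for i in range(0, len(r), 3)])
    return CodonAlignment(taxa, np.array(mats, dtype="<U3"))
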