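import pytest

from allobarcode.seqio import (
    AlignedLocusMatrix,
    SeqEntry,
    ground_truth_from_table,
    load_survey_table,
)
from allobarcode.synthdata import SynthParams, generate


def make_matrix(seqs, locus_id="locus", species=None):
    """Build a matrix from {sequence_id: residues}; optional species map."""
    species = species or {}
    return AlignedLocusMatrix(
        locus_id,
        [
            SeqEntry(sid, sid.split("|")[0], residues,
                     species_label=species.get(sid))
            for sid, residues in seqs.items()
        ],
    )


@pytest.fixture(scope="session")
def survey_table():
    return load_survey_table()


@pytest.fixture(scope="session")
def survey_truth(survey_table):
    return ground_truth_from_table(survey_table)


@pytest.fixture(scope="session")
def small_dataset():
    """A compact synthetic dataset reused across read-only tests."""
    return generate(SynthParams(seed=11, n_parent_a=12, n_parent_b=10,
                                n_hybrids=20))
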