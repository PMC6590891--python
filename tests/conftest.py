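import numpy as np
import pytest

from slc6kit.align import SubstitutionMatrix
from slc6kit.seqio import SequenceRecord

AA20 = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture(scope="session")
def blosum62() -> SubstitutionMatrix:
    return SubstitutionMatrix.load("BLOSUM62")


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20190624)


def random_protein(rng, length, alphabet=AA20, rec_id="p") -> SequenceRecord:
    return SequenceRecord(
        id=rec_id,
        residues="".join(rng.choice(list(alphabet), size=length)),
        alphabet="protein",
    )


def random_dna(rng, length, rec_id="d") -> SequenceRecord:
    return SequenceRecord(
        id=rec_id,
        residues="".join(rng.choice(list("ACGT"), size=length)),
        alphabet="dna",
    )


def jaccard(a, b) -> float:
    inter = max(0, min(a.end, b.end) - max(a.start, b.start) + 1)
    return inter / (len(a) + len(b) - inter)
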