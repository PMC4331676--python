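import numpy as np
import pytest

from pssmdt import ProteinSequence, PssmProfile
from pssmdt.profile_io import ALPHABET, AA_INDEX


@pytest.fixture
def rng():
    return np.random.default_rng(20150206)


def make_profile(scores, residues=None, seq_id="test"):
    """Build a PssmProfile from a score matrix, inventing residues if needed."""
    scores = np.asarray(scores, dtype=float)
    if residues is None:
        residues = "A" * scores.shape[0]
    return PssmProfile(
        sequence=ProteinSequence(id=seq_id, residues=residues), scores=scores
    )


def column_profile(column_values, aa="A", length=None, seq_id="test"):
    """Profile that is zero except for one amino-acid column."""
    column_values = np.asarray(column_values, dtype=float)
    length = length or len(column_values)
    scores = np.zeros((length, 20))
    scores[: len(column_values), AA_INDEX[aa]] = column_values
    return make_profile(scores, seq_id=seq_id)


def random_profile(rng, length, low=-5, high=10, seq_id="rand"):
    residues = "".join(rng.choice(list(ALPHABET), size=length))
    scores = rng.integers(low, high, size=(length, 20)).astype(float)
    return make_profile(scores, residues=residues, seq_id=seq_id)


@pytest.fixture
def small_random_profiles(rng):
    """A batch of small random profiles for oracle-equivalence spot checks."""
    return [
        random_profile(rng, int(rng.integers(10, 31)), seq_id=f"r{i}") for i in range(20)
    ]


# A well-formed two-row ASCII PSSM in the PSI-BLAST -out_ascii_pssm dialect.
TWO_ROW_PSSM = """
Last position-specific scoring matrix computed, weighted observed percentages rounded down, information per position, and relative weight of gapless real matches to pseudocounts
            A  R  N  D  C  Q  E  G  H  I  L  K  M  F  P  S  T  W  Y  V   A  R  N  D  C  Q  E  G  H  I  L  K  M  F  P  S  T  W  Y  V
    1 M    -1 -2 -3 -4  0 -1 -2 -3  1  2  2 -1  8 -2 -3 -1  0 -2 -1  1   0  0  0  0  0  0  0  0  0  0  0  0 100 0  0  0  0  0  0  0  0.70 0.30
    2 K    -1  2 -1 -2 -3  1  1 -2 -1 -3 -2  5 -1 -3 -1 -1 -1 -3 -2 -2   0  0  0  0  0  0  0  0  0  0  0 100  0  0  0  0  0  0  0  0  0.65 0.25

                      K         Lambda
Standard Ungapped    0.1347     0.3195
"""

TWO_ROW_SCORES = np.array(
    [
        [-1, -2, -3, -4, 0, -1, -2, -3, 1, 2, 2, -1, 8, -2, -3, -1, 0, -2, -1, 1],
        [-1, 2, -1, -2, -3, 1, 1, -2, -1, -3, -2, 5, -1, -3, -1, -1, -1, -3, -2, -2],
    ],
    dtype=float,
)


@pytest.fixture
def two_row_pssm_text():
    return TWO_ROW_PSSM
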