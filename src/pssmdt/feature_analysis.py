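"""Discriminant-weight analysis: which amino-acid pairs drive the decision.

Given a trained kernel SVM with per-sample signed dual weights
A = (alpha_1 y_1, ..., alpha_N y_N) (zero off the support) and the training
feature matrix M (N x d), the feature discriminant weight vector is the
linear read-out

    W = A^T · M,    i.e.  W_k = sum_i (alpha_i y_i) M_{i,k}.

For a linear kernel this is exactly the primal weight vector; for the RBF
kernel it is a first-order surrogate, not the true decision gradient, but it
is the conventional descriptor-ranking read-out for this model family and is
implemented as such.

Pair-level summaries restrict attention to descriptors enriched in the
positive class: the weight of an ordered amino-acid pair is the quadratic
sum of its per-lag W coordinates over the coordinates with W > 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .profile_io import AA_INDEX, ALPHABET, ProfileError, ProteinSequence
from .schema import DescriptorSchema, SchemaError
from .svm_engine import RbfSvmClassifier


def discriminant_weight_vector(model: RbfSvmClassifier, M: np.ndarray) -> np.ndarray:
    """W = A^T · M over the training feature matrix M (N samples x d)."""
    M = np.asarray(M, dtype=float)
    alpha = model.alpha_signed_
    if M.ndim != 2 or M.shape[0] != alpha.shape[0]:
        raise SchemaError(
            f"feature matrix has {M.shape[0] if M.ndim == 2 else '?'} rows but "
            f"the model was trained on {alpha.shape[0]} samples"
        )
    return alpha @ M


def pair_discriminant_weights(W: np.ndarray, schema: DescriptorSchema) -> np.ndarray:
    """20 x 20 matrix of per-pair quadratic sums over positive W coordinates.

    Entry [a1, a2] sums W_k^2 over that ordered pair's lags, restricted to
    descriptors with W_k > 0; the diagonal holds the same-pair block.
    """
    W = _check_w(W, schema)
    weights = np.zeros((20, 20))
    for w_k, (a1, a2, _lg) in zip(W, schema.entries):
        if w_k > 0:
            weights[AA_INDEX[a1], AA_INDEX[a2]] += w_k**2
    return weights


def per_lag_weights(W: np.ndarray, schema: DescriptorSchema, pair: tuple[str, str]) -> np.ndarray:
    """The raw (signed, unsquared) W coordinates of one ordered pair, in lag order."""
    W = _check_w(W, schema)
    a1, a2 = pair
    if a1 not in AA_INDEX or a2 not in AA_INDEX:
        raise SchemaError(f"unknown amino-acid pair {pair!r}")
    out = [w_k for w_k, (e1, e2, _lg) in zip(W, schema.entries) if (e1, e2) == (a1, a2)]
    if not out:
        raise SchemaError(f"pair {pair!r} has no descriptors in the {schema.scheme} schema")
    return np.array(out)


def ranked_pairs(pair_weights: np.ndarray) -> list[tuple[str, str, float]]:
    """All 400 ordered pairs sorted by discriminant weight, descending."""
    order = np.argsort(pair_weights, axis=None)[::-1]
    return [
        (ALPHABET[i // 20], ALPHABET[i % 20], float(pair_weights.flat[i])) for i in order
    ]


def _check_w(W: np.ndarray, schema: DescriptorSchema) -> np.ndarray:
    W = np.asarray(W, dtype=float)
    if W.shape != (len(schema),):
        raise SchemaError(
            f"weight vector of length {W.shape} does not match schema length {len(schema)}"
        )
    return W


@dataclass
class DiscriminantReport:
    """Full discriminant analysis of one trained model."""

    W: np.ndarray
    schema: DescriptorSchema
    pair_weights: np.ndarray
    ranked: list[tuple[str, str, float]]

    @classmethod
    def from_model(cls, model: RbfSvmClassifier, M: np.ndarray,
                   schema: DescriptorSchema) -> "DiscriminantReport":
        W = discriminant_weight_vector(model, M)
        pw = pair_discriminant_weights(W, schema)
        return cls(W=W, schema=schema, pair_weights=pw, ranked=ranked_pairs(pw))

    def per_lag(self, pair: tuple[str, str]) -> np.ndarray:
        return per_lag_weights(self.W, self.schema, pair)

    def top_pairs(self, k: int = 4) -> list[tuple[str, str]]:
        return [(a1, a2) for a1, a2, _w in self.ranked[:k]]

    def pair_weight_table(self) -> pd.DataFrame:
        """20 x 20 table, rows = first amino acid, columns = second."""
        return pd.DataFrame(self.pair_weights, index=list(ALPHABET), columns=list(ALPHABET))


def locate_descriptor_occurrences(
    seq: ProteinSequence, pair: tuple[str, str], lg: int
) -> list[tuple[int, int]]:
    """All 1-based position pairs (j, j+lg) where the sequence carries the pair.

    "Occurrence" is a literal residue match: position j holds the pair's
    first amino acid and position j+lg its second. Used to localize the most
    discriminative descriptors on a sequence of interest.
    """
    a1, a2 = pair
    for aa in (a1, a2):
        if aa not in AA_INDEX:
            raise ProfileError(f"invalid amino-acid letter {aa!r}")
    if lg < 1:
        raise ProfileError(f"lag must be >= 1, got {lg}")
    if lg >= len(seq):
        raise ProfileError(f"lag {lg} must be smaller than sequence length {len(seq)}")
    residues = seq.residues
    return [
        (j + 1, j + 1 + lg)
        for j in range(len(residues) - lg)
        if residues[j] == a1 and residues[j + lg] == a2
    ]


def occurrence_table(
    seq: ProteinSequence, descriptors: list[tuple[str, str, int]]
) -> pd.DataFrame:
    """Occurrences of several (aa1, aa2, lg) descriptors on one sequence."""
    rows = []
    for a1, a2, lg in descriptors:
        for pos1, pos2 in locate_descriptor_occurrences(seq, (a1, a2), lg):
            rows.append({"id": seq.id, "aa1": a1, "aa2": a2, "lg": lg,
                         "pos1": pos1, "pos2": pos2})
    return pd.DataFrame(rows, columns=["id", "aa1", "aa2", "lg", "pos1", "pos2"])
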