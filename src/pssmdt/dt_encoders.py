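"""PSSM distance-transformation encodings (the package's core method).

The distance transformation turns a variable-length L x 20 PSSM profile into
a fixed-length vector by, for every ordered amino-acid pair (a1, a2) and
every lag ``lg`` up to a maximum ``LG``, averaging the product of the two
log-odds scores over all positions ``j``::

    DT(a1, a2, lg) = ( sum_{j=1}^{L-lg} S[j, a1] * S[j+lg, a2] ) / (L - lg)

Because a PSSM score approximates how strongly an amino acid occurs at a
position, each coordinate approximates the co-occurrence propensity of the
pair at that separation. The same-pair block (a1 == a2, 20·LG features) is
the SDT encoding, the different-pair block (a1 != a2, 380·LG features) the
DDT encoding, and their concatenation (400·LG features) the DT encoding used
by the classifier.

Note on index conventions: ``S`` is indexed ``[position, amino-acid
column]`` and the sum runs over positions. A transposed reading (summing
over amino acids) silently produces wrong features; the orientation here is
pinned down by the oracle tests.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .profile_io import PssmProfile
from .schema import DescriptorSchema, FeatureVector, ddt_schema, dt_schema, sdt_schema

_SCHEMES = ("sdt", "ddt", "dt")


class EncodingError(ValueError):
    """Profile unsuitable for the requested encoding."""


def _check_profile(profile: PssmProfile, lg_max: int) -> None:
    if lg_max < 1:
        raise EncodingError(f"maximum lag LG must be >= 1, got {lg_max}")
    if profile.length <= lg_max:
        raise EncodingError(
            f"profile {profile.sequence.id!r} has length L={profile.length}, "
            f"which must exceed the maximum lag LG={lg_max}"
        )


def _lag_blocks(scores: np.ndarray, lg_max: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-lag same-pair vector (20,) and cross-pair matrix (20, 20).

    Returns arrays of shape (20, LG) and (20, 20, LG); the cross matrix entry
    [a1, a2, lg-1] averages S[j, a1] * S[j+lg, a2] over positions j.
    """
    length = scores.shape[0]
    same = np.empty((20, lg_max))
    cross = np.empty((20, 20, lg_max))
    for lg in range(1, lg_max + 1):
        head, tail = scores[:-lg], scores[lg:]
        denom = length - lg
        same[:, lg - 1] = np.einsum("ja,ja->a", head, tail) / denom
        cross[:, :, lg - 1] = head.T @ tail / denom
    return same, cross


def encode_sdt(profile: PssmProfile, lg_max: int) -> FeatureVector:
    """Same-pair distance transformation: 20·LG features."""
    _check_profile(profile, lg_max)
    same, _ = _lag_blocks(profile.scores, lg_max)
    return FeatureVector(values=same.ravel(), schema=sdt_schema(lg_max))


def encode_ddt(profile: PssmProfile, lg_max: int) -> FeatureVector:
    """Different-pair distance transformation: 380·LG features."""
    _check_profile(profile, lg_max)
    _, cross = _lag_blocks(profile.scores, lg_max)
    off_diag = ~np.eye(20, dtype=bool)
    return FeatureVector(values=cross[off_diag].ravel(), schema=ddt_schema(lg_max))


def encode_dt(profile: PssmProfile, lg_max: int) -> FeatureVector:
    """Concatenated distance transformation: 400·LG features, SDT block first."""
    _check_profile(profile, lg_max)
    same, cross = _lag_blocks(profile.scores, lg_max)
    off_diag = ~np.eye(20, dtype=bool)
    values = np.concatenate([same.ravel(), cross[off_diag].ravel()])
    return FeatureVector(values=values, schema=dt_schema(lg_max))


_ENCODERS = {"sdt": encode_sdt, "ddt": encode_ddt, "dt": encode_dt}
_SCHEMAS = {"sdt": sdt_schema, "ddt": ddt_schema, "dt": dt_schema}


class DistanceTransformEncoder(TransformerMixin, BaseEstimator):
    """Transform PSSM profiles into distance-transformation feature matrices.

    scikit-learn style transformer: ``X`` is a sequence of
    :class:`~pssmdt.profile_io.PssmProfile` objects and the output a dense
    ``(n_samples, n_features)`` array whose columns follow ``schema_``.

    Parameters
    ----------
    scheme:
        ``"sdt"`` (same pairs, 20·LG), ``"ddt"`` (different pairs, 380·LG)
        or ``"dt"`` (both, 400·LG; the default and the scheme used for
        DNA-binding protein identification).
    lg:
        Maximum lag LG >= 1. The default 5 is the operating point at which
        the concatenated encoding has 2000 coordinates.
    """

    def __init__(self, scheme: str = "dt", lg: int = 5):
        self.scheme = scheme
        self.lg = lg

    def fit(self, X=None, y=None) -> "DistanceTransformEncoder":
        if self.scheme not in _SCHEMES:
            raise EncodingError(
                f"unknown scheme {self.scheme!r}; valid schemes: {', '.join(_SCHEMES)}"
            )
        self.schema_ = _SCHEMAS[self.scheme](self.lg)
        self.n_features_out_ = len(self.schema_)
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "schema_"):
            self.fit()
        encode = _ENCODERS[self.scheme]
        return np.array([encode(profile, self.lg).values for profile in X])

    def encode_one(self, profile: PssmProfile) -> FeatureVector:
        if not hasattr(self, "schema_"):
            self.fit()
        return _ENCODERS[self.scheme](profile, self.lg)
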