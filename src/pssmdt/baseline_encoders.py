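"""Comparison PSSM encodings: AvePscore-20/400, Pscore-100 and the ACC transform.

These four schemes are the standard fixed-length PSSM summaries the distance
transformation is benchmarked against. Each is known in the literature by a
one-line description; this module freezes one precise reading per scheme:

* **AvePscore-20** — the mean of each of the 20 profile columns.
* **AvePscore-400** — the mean of each column restricted to the positions
  whose *sequence residue* is a given amino acid (0 when the residue never
  occurs), giving a 20 (residue) x 20 (column) table.
* **Pscore-100** — per column, the empirical percentiles at the quintile
  thresholds {0, 25, 50, 75, 100}% (linear interpolation between order
  statistics), the only 5-point grid consistent with 100 features over 20
  columns.
* **ACC transform** — per-column auto-covariance at lags 1..LG with divisor
  (L − lg), paralleling the distance-transformation denominator; covariance,
  not Pearson correlation, so constant columns contribute exactly zero.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .dt_encoders import EncodingError, _check_profile
from .profile_io import ALPHABET, PssmProfile
from .schema import DescriptorSchema, FeatureVector

_PERCENTILES = (0, 25, 50, 75, 100)


def _schema_avepscore20() -> DescriptorSchema:
    return DescriptorSchema(
        scheme="avepscore-20", entries=tuple(("*", a, 0) for a in ALPHABET)
    )


def _schema_avepscore400() -> DescriptorSchema:
    return DescriptorSchema(
        scheme="avepscore-400",
        entries=tuple((r, a, 0) for r in ALPHABET for a in ALPHABET),
    )


def _schema_pscore100() -> DescriptorSchema:
    return DescriptorSchema(
        scheme="pscore-100",
        entries=tuple((a, f"q{t}", 0) for a in ALPHABET for t in _PERCENTILES),
    )


def _schema_acc(lg_max: int) -> DescriptorSchema:
    return DescriptorSchema(
        scheme="acc",
        entries=tuple((a, a, lg) for a in ALPHABET for lg in range(1, lg_max + 1)),
        lg=lg_max,
    )


def avepscore20(profile: PssmProfile) -> FeatureVector:
    """Mean PSSM score per amino-acid column; 20 features."""
    return FeatureVector(values=profile.scores.mean(axis=0), schema=_schema_avepscore20())


def avepscore400(profile: PssmProfile) -> FeatureVector:
    """Per-residue-type column means; 400 features indexed (residue, column)."""
    values = np.zeros((20, 20))
    residues = np.array(list(profile.sequence.residues))
    for r_idx, r in enumerate(ALPHABET):
        mask = residues == r
        if mask.any():
            values[r_idx] = profile.scores[mask].mean(axis=0)
    return FeatureVector(values=values.ravel(), schema=_schema_avepscore400())


def pscore100(profile: PssmProfile) -> FeatureVector:
    """Quintile-boundary percentiles of each column; 100 features."""
    # shape (5, 20) -> column-major flatten so each column's 5 percentiles are contiguous
    pct = np.percentile(profile.scores, _PERCENTILES, axis=0, method="linear")
    return FeatureVector(values=pct.T.ravel(), schema=_schema_pscore100())


def acc_transform(profile: PssmProfile, lg_max: int) -> FeatureVector:
    """Per-column auto-covariance at lags 1..LG; 20·LG features."""
    _check_profile(profile, lg_max)
    scores = profile.scores
    centered = scores - scores.mean(axis=0)
    length = scores.shape[0]
    values = np.empty((20, lg_max))
    for lg in range(1, lg_max + 1):
        values[:, lg - 1] = (
            np.einsum("ja,ja->a", centered[:-lg], centered[lg:]) / (length - lg)
        )
    return FeatureVector(values=values.ravel(), schema=_schema_acc(lg_max))


_BASELINES = {
    "avepscore20": lambda p, lg: avepscore20(p),
    "avepscore400": lambda p, lg: avepscore400(p),
    "pscore100": lambda p, lg: pscore100(p),
    "acc": acc_transform,
}

_BASELINE_SCHEMAS = {
    "avepscore20": lambda lg: _schema_avepscore20(),
    "avepscore400": lambda lg: _schema_avepscore400(),
    "pscore100": lambda lg: _schema_pscore100(),
    "acc": _schema_acc,
}


class BaselineEncoder(TransformerMixin, BaseEstimator):
    """scikit-learn transformer over the four comparison encodings.

    ``scheme`` is one of ``avepscore20``, ``avepscore400``, ``pscore100`` or
    ``acc``; ``lg`` only affects the ACC transform.
    """

    def __init__(self, scheme: str = "avepscore20", lg: int = 5):
        self.scheme = scheme
        self.lg = lg

    def fit(self, X=None, y=None) -> "BaselineEncoder":
        if self.scheme not in _BASELINES:
            raise EncodingError(
                f"unknown scheme {self.scheme!r}; valid schemes: "
                f"{', '.join(sorted(_BASELINES))}"
            )
        self.schema_ = _BASELINE_SCHEMAS[self.scheme](self.lg)
        self.n_features_out_ = len(self.schema_)
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "schema_"):
            self.fit()
        encode = _BASELINES[self.scheme]
        return np.array([encode(profile, self.lg).values for profile in X])

    def encode_one(self, profile: PssmProfile) -> FeatureVector:
        if not hasattr(self, "schema_"):
            self.fit()
        return _BASELINES[self.scheme](profile, self.lg)
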