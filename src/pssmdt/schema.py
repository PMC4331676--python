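"""Descriptor schemas naming each coordinate of a feature encoding.

Every fixed-length encoding here carries a schema so downstream feature
analysis can map a weight-vector coordinate back to the amino-acid pair and
lag (or other identifier) it measures.

Ordering conventions (fixed, arbitrary but stable):

* same-pair (SDT) block — amino-acid-major, lag-minor:
  ``(A,A,1) ... (A,A,LG), (R,R,1) ... (V,V,LG)``;
* different-pair (DDT) block — ordered pairs ``(a1, a2)`` lexicographic in
  :data:`~pssmdt.profile_io.ALPHABET` order, lag-minor;
* concatenated (DT) schema — SDT block first, then DDT block.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

from .profile_io import ALPHABET

#: Descriptor identifier: (first amino acid, second amino acid, lag).
PairDescriptor = tuple[str, str, int]


class SchemaError(ValueError):
    """Schema construction or mismatch failure."""


@dataclass(frozen=True)
class DescriptorSchema:
    """An ordered list of descriptor identifiers for one encoding scheme.

    ``entries`` are ``(aa1, aa2, lg)`` triples for the pair/lag schemes and
    descriptive string tuples for the baseline schemes (lag 0 fills the slot
    where a scheme has no lag concept).
    """

    scheme: str
    entries: tuple[PairDescriptor, ...]
    lg: int = 0

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[PairDescriptor]:
        return iter(self.entries)

    def index_of(self, descriptor: PairDescriptor) -> int:
        try:
            return self.entries.index(descriptor)
        except ValueError:
            raise SchemaError(f"descriptor {descriptor!r} not in {self.scheme} schema") from None

    def to_records(self) -> list[dict]:
        return [
            {"index": i, "aa1": a1, "aa2": a2, "lg": lg}
            for i, (a1, a2, lg) in enumerate(self.entries)
        ]


def sdt_schema(lg_max: int) -> DescriptorSchema:
    """Schema of the 20·LG same-pair descriptors."""
    _check_lg(lg_max)
    entries = tuple((a, a, lg) for a in ALPHABET for lg in range(1, lg_max + 1))
    return DescriptorSchema(scheme="pssm-sdt", entries=entries, lg=lg_max)


def ddt_schema(lg_max: int) -> DescriptorSchema:
    """Schema of the 380·LG ordered different-pair descriptors."""
    _check_lg(lg_max)
    entries = tuple(
        (a1, a2, lg)
        for a1 in ALPHABET
        for a2 in ALPHABET
        if a1 != a2
        for lg in range(1, lg_max + 1)
    )
    return DescriptorSchema(scheme="pssm-ddt", entries=entries, lg=lg_max)


def dt_schema(lg_max: int) -> DescriptorSchema:
    """Schema of the 400·LG concatenated descriptors (same-pair block first)."""
    entries = sdt_schema(lg_max).entries + ddt_schema(lg_max).entries
    return DescriptorSchema(scheme="pssm-dt", entries=entries, lg=lg_max)


def _check_lg(lg_max: int) -> None:
    if lg_max < 1:
        raise SchemaError(f"maximum lag LG must be >= 1, got {lg_max}")


@dataclass(frozen=True)
class FeatureVector:
    """A fixed-length numeric encoding of one sequence, with its schema."""

    values: np.ndarray
    schema: DescriptorSchema

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1:
            raise SchemaError(f"feature values must be 1-D, got shape {values.shape}")
        if len(values) != len(self.schema):
            raise SchemaError(
                f"{len(values)} values for a {self.schema.scheme} schema of "
                f"length {len(self.schema)}"
            )
        if not np.all(np.isfinite(values)):
            raise SchemaError("feature vector contains non-finite entries")

    def __len__(self) -> int:
        return len(self.values)

    def __getitem__(self, descriptor: PairDescriptor) -> float:
        return float(self.values[self.schema.index_of(descriptor)])
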