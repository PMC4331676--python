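"""Seeded synthetic PSSM datasets with planted pair/lag signal.

The generator emulates the inputs of the real pipeline — labeled sets of
PSI-BLAST-style profiles — with a controllable, known ground truth, so that
encoding, training, evaluation and discriminant analysis are all testable
without any database search.

Background profiles draw each log-odds score independently from a
discretized normal distribution (default mean 0, SD 2, clipped to [−5, 9],
mimicking the integer range of real PSI-BLAST log-odds), with residues
uniform over the 20 amino acids. Positive-class profiles additionally carry
*planted* pair signal: for each planted (aa1, aa2, lag) triple, a
density-controlled subset of eligible positions j receives a simultaneous
boost of +effect_size to column aa1 at j and column aa2 at j+lag, and the
residues at those positions are set to aa1/aa2. Residues and scores are
planted coherently so both the PSSM-based encoders and the sequence-based
occurrence locator see the same signal.

The planted coordinates of the distance-transformation encoding therefore
have elevated expectation in positives, which is exactly the class of signal
the encoding is designed to detect.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .profile_io import AA_INDEX, ALPHABET, ProteinSequence, PssmProfile, write_ascii_pssm, write_fasta


class GenerationError(ValueError):
    """Invalid generator configuration."""


@dataclass(frozen=True)
class BackgroundModel:
    """Discretized-normal background for PSSM scores."""

    mean: float = 0.0
    sd: float = 2.0
    low: int = -5
    high: int = 9


@dataclass(frozen=True)
class PlantSpec:
    """Which (aa1, aa2, lag) descriptors carry signal, and how strongly.

    ``effect_size`` is the score boost added to each planted cell, in the
    same (log-odds) units as the background scores; ``density`` is the
    probability that an eligible position receives a plant.
    """

    pairs: tuple[tuple[str, str, int], ...] = (("R", "R", 4), ("P", "R", 2))
    effect_size: float = 6.0
    density: float = 0.15

    def __post_init__(self) -> None:
        if self.effect_size < 0:
            raise GenerationError("effect_size must be >= 0")
        if not 0 < self.density <= 1:
            raise GenerationError("density must lie in (0, 1]")
        for a1, a2, lg in self.pairs:
            if a1 not in AA_INDEX or a2 not in AA_INDEX:
                raise GenerationError(f"invalid amino acid in plant ({a1}, {a2}, {lg})")
            if lg < 1:
                raise GenerationError(f"planted lag must be >= 1, got {lg}")

    @property
    def max_lag(self) -> int:
        return max((lg for _a1, _a2, lg in self.pairs), default=0)

    @property
    def planted_pairs(self) -> list[tuple[str, str]]:
        return sorted({(a1, a2) for a1, a2, _lg in self.pairs})


@dataclass(frozen=True)
class GeneratorConfig:
    """Full specification of one synthetic labeled dataset."""

    n_pos: int = 30
    n_neg: int = 30
    length_range: tuple[int, int] = (60, 100)
    background: BackgroundModel = field(default_factory=BackgroundModel)
    plant: PlantSpec = field(default_factory=PlantSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise GenerationError("n_pos and n_neg must be >= 1")
        lo, hi = self.length_range
        if lo > hi or lo < 1:
            raise GenerationError(f"bad length_range {self.length_range}")
        if lo <= self.plant.max_lag:
            raise GenerationError(
                f"minimum length {lo} must exceed the largest planted lag "
                f"{self.plant.max_lag}"
            )


def generate_profile(
    length: int,
    background: BackgroundModel = BackgroundModel(),
    seed: int | np.random.Generator = 0,
    sequence_id: str = "synthetic",
) -> PssmProfile:
    """One pure-background profile: uniform residues, discretized-normal scores."""
    if length < 1:
        raise GenerationError(f"length must be >= 1, got {length}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    residues = "".join(rng.choice(list(ALPHABET), size=length))
    scores = np.clip(
        np.rint(rng.normal(background.mean, background.sd, size=(length, 20))),
        background.low,
        background.high,
    )
    seq = ProteinSequence(id=sequence_id, residues=residues)
    return PssmProfile(sequence=seq, scores=scores)


def _plant_signal(
    profile: PssmProfile, plant: PlantSpec, rng: np.random.Generator
) -> PssmProfile:
    residues = list(profile.sequence.residues)
    scores = profile.scores.copy()
    length = len(residues)
    for a1, a2, lg in plant.pairs:
        eligible = np.arange(length - lg)
        chosen = eligible[rng.random(len(eligible)) < plant.density]
        for j in chosen:
            residues[j] = a1
            residues[j + lg] = a2
            scores[j, AA_INDEX[a1]] += plant.effect_size
            scores[j + lg, AA_INDEX[a2]] += plant.effect_size
    seq = ProteinSequence(id=profile.sequence.id, residues="".join(residues))
    return PssmProfile(sequence=seq, scores=np.rint(scores))


def generate_dataset(config: GeneratorConfig) -> tuple[list[PssmProfile], np.ndarray]:
    """A labeled dataset: n_pos planted positives then n_neg background negatives.

    Fully deterministic given ``config.seed``; labels are +1 for the planted
    class and −1 for pure background.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.length_range
    profiles: list[PssmProfile] = []
    labels: list[int] = []
    for i in range(config.n_pos):
        length = int(rng.integers(lo, hi + 1))
        base = generate_profile(length, config.background, rng, sequence_id=f"pos{i:04d}")
        profiles.append(_plant_signal(base, config.plant, rng))
        labels.append(1)
    for i in range(config.n_neg):
        length = int(rng.integers(lo, hi + 1))
        profiles.append(
            generate_profile(length, config.background, rng, sequence_id=f"neg{i:04d}")
        )
        labels.append(-1)
    return profiles, np.array(labels, dtype=int)


def write_dataset(
    profiles: list[PssmProfile], labels: np.ndarray, out_dir: str | Path
) -> None:
    """Emit the dataset as FASTA + one ASCII-PSSM file per profile + labels TSV.

    Uses the same dialect as real PSI-BLAST output, so synthetic data
    exercises the real parsers end to end.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "sequences.fasta").write_text(
        write_fasta([p.sequence for p in profiles])
    )
    for profile in profiles:
        (out_dir / f"{profile.sequence.id}.pssm").write_text(write_ascii_pssm(profile))
    lines = ["id\tlabel"] + [
        f"{p.sequence.id}\t{label}" for p, label in zip(profiles, labels)
    ]
    (out_dir / "labels.tsv").write_text("\n".join(lines) + "\n")
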