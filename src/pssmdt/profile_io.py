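"""Reading and writing protein sequences and PSI-BLAST ASCII PSSM profiles.

A PSSM (position-specific scoring matrix) is the L x 20 profile that
PSI-BLAST emits for a query sequence after iterative database search: entry
(i, j) is an integer log-odds score for observing amino acid j at position i.
This module parses the ``-out_ascii_pssm`` dialect, keeping only the first 20
(log-odds) columns, and can optionally drive PSI-BLAST itself.

Column order everywhere downstream is the PSI-BLAST header order
``A R N D C Q E G H I L K M F P S T W Y V`` (:data:`ALPHABET`).
"""

from __future__ import annotations

import io
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
from Bio import SeqIO

#: Canonical amino-acid column order (PSI-BLAST ASCII PSSM header order).
ALPHABET: tuple[str, ...] = tuple("ARNDCQEGHILKMFPSTWYV")

#: Index of each amino-acid letter in :data:`ALPHABET`.
AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(ALPHABET)}

_VALID_RESIDUES = frozenset(ALPHABET)


class ProfileError(ValueError):
    """Malformed sequence or PSSM input."""


@dataclass(frozen=True)
class ProteinSequence:
    """A protein sequence over the 20 canonical one-letter codes.

    Ambiguity codes such as ``X`` are rejected outright: profiles and the
    pair-descriptor machinery are only defined for the 20 standard residues,
    so sequences carrying other letters are refused at construction.
    """

    id: str
    residues: str

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise ProfileError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - _VALID_RESIDUES
        if bad:
            raise ProfileError(
                f"sequence {self.id!r} contains non-canonical residue(s) "
                f"{sorted(bad)}; only the 20 standard amino acids are accepted"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class PssmProfile:
    """A per-sequence L x 20 log-odds score matrix plus its residue string.

    ``scores[i, j]`` is the (real-valued) log-odds score of amino acid
    ``alphabet_order[j]`` at position ``i``. Scores are stored as floats even
    though the PSI-BLAST dialect prints integers, so synthetic profiles may
    carry real values.
    """

    sequence: ProteinSequence
    scores: np.ndarray
    alphabet_order: tuple[str, ...] = ALPHABET

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        object.__setattr__(self, "scores", scores)
        if scores.ndim != 2 or scores.shape[1] != 20:
            raise ProfileError(
                f"profile {self.sequence.id!r}: score matrix must be L x 20, "
                f"got shape {scores.shape}"
            )
        if scores.shape[0] != len(self.sequence):
            raise ProfileError(
                f"profile {self.sequence.id!r}: {scores.shape[0]} score rows "
                f"for a sequence of length {len(self.sequence)}"
            )
        if sorted(self.alphabet_order) != sorted(ALPHABET):
            raise ProfileError("alphabet_order must permute the 20 canonical amino acids")
        if not np.all(np.isfinite(scores)):
            raise ProfileError(f"profile {self.sequence.id!r}: non-finite score values")

    @property
    def length(self) -> int:
        return self.scores.shape[0]


def validate_curation_length(seq: ProteinSequence, min_length: int = 50) -> ProteinSequence:
    """Optional dataset-curation filter: reject sequences shorter than 50 residues."""
    if len(seq) < min_length:
        raise ProfileError(
            f"sequence {seq.id!r} has {len(seq)} residues, below the curation "
            f"minimum of {min_length}"
        )
    return seq


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(text: str) -> list[ProteinSequence]:
    """Parse multi-record FASTA text into :class:`ProteinSequence` objects.

    Order is preserved; line wrapping and surrounding whitespace are
    normalized away. Records containing residues outside the 20-letter
    alphabet (e.g. ``X``) raise :class:`ProfileError` naming the record.
    """
    if not text.strip():
        raise ProfileError("empty FASTA input")
    records = list(SeqIO.parse(io.StringIO(text), "fasta"))
    if not records:
        raise ProfileError("input contains no FASTA records")
    return [ProteinSequence(id=rec.id, residues=str(rec.seq).upper()) for rec in records]


def read_fasta_file(path: str | Path) -> list[ProteinSequence]:
    return read_fasta(Path(path).read_text())


def write_fasta(sequences: Iterable[ProteinSequence], width: int = 60) -> str:
    chunks = []
    for seq in sequences:
        body = "\n".join(
            seq.residues[i : i + width] for i in range(0, len(seq.residues), width)
        )
        chunks.append(f">{seq.id}\n{body}\n")
    return "".join(chunks)


# ---------------------------------------------------------------------------
# ASCII PSSM
# ---------------------------------------------------------------------------

def parse_ascii_pssm(text: str, sequence_id: str = "query") -> PssmProfile:
    """Parse a PSI-BLAST ``-out_ascii_pssm`` file into a :class:`PssmProfile`.

    Only the first 20 columns (the log-odds scores) are kept; the 20
    weighted-percentage columns and the two trailing statistics are ignored.
    Columns are reordered into :data:`ALPHABET` order if the file's header
    lists them differently.
    """
    lines = text.splitlines()
    header_order: list[str] | None = None
    header_line_idx = -1
    for idx, line in enumerate(lines):
        fields = line.split()
        if len(fields) >= 40 and all(f in _VALID_RESIDUES and len(f) == 1 for f in fields[:40]):
            header_order = fields[:20]
            header_line_idx = idx
            break
    if header_order is None:
        raise ProfileError("missing amino-acid column-label line in ASCII PSSM")

    residues: list[str] = []
    rows: list[list[float]] = []
    for line in lines[header_line_idx + 1 :]:
        fields = line.split()
        if not fields:
            continue
        if not fields[0].isdigit():
            break  # trailing K/Lambda statistics block
        if len(fields) < 22:
            raise ProfileError(
                f"PSSM row {fields[0]}: expected at least 22 fields "
                f"(index, residue, 20 scores), got {len(fields)}"
            )
        pos, residue = fields[0], fields[1]
        try:
            scores = [float(v) for v in fields[2:22]]
        except ValueError as exc:
            raise ProfileError(f"PSSM row {pos}: non-numeric score cell ({exc})") from None
        if int(pos) != len(rows) + 1:
            raise ProfileError(
                f"PSSM row index {pos} out of order (expected {len(rows) + 1})"
            )
        residues.append(residue)
        rows.append(scores)

    if not rows:
        raise ProfileError("ASCII PSSM contains no score rows")

    raw = np.array(rows, dtype=float)
    perm = [header_order.index(aa) for aa in ALPHABET]
    seq = ProteinSequence(id=sequence_id, residues="".join(residues))
    return PssmProfile(sequence=seq, scores=raw[:, perm])


def write_ascii_pssm(profile: PssmProfile) -> str:
    """Serialize a profile in the ``-out_ascii_pssm`` dialect.

    Scores are printed rounded to integers (as PSI-BLAST does); the
    percentage columns and trailing statistics are written as zeros. The
    output round-trips through :func:`parse_ascii_pssm` up to that rounding.
    """
    out = [
        "",
        "Last position-specific scoring matrix computed, weighted observed "
        "percentages rounded down, information per position, and relative "
        "weight of gapless real matches to pseudocounts",
        "            " + "  ".join(ALPHABET) + "   " + "  ".join(ALPHABET),
    ]
    for i, (residue, row) in enumerate(zip(profile.sequence.residues, profile.scores), start=1):
        scores = " ".join(f"{int(round(v)):3d}" for v in row)
        pcts = " ".join(f"{0:3d}" for _ in range(20))
        out.append(f"{i:5d} {residue}  {scores}  {pcts}  0.00 0.00")
    out.append("")
    return "\n".join(out)


def read_profile_dir(
    fasta_path: str | Path, profile_dir: str | Path, suffix: str = ".pssm"
) -> list[tuple[ProteinSequence, PssmProfile]]:
    """Load a FASTA file plus one ``<id>.pssm`` per record from a directory.

    Raises :class:`ProfileError` listing every record with a missing profile.
    """
    sequences = read_fasta_file(fasta_path)
    profile_dir = Path(profile_dir)
    missing = [s.id for s in sequences if not (profile_dir / f"{s.id}{suffix}").exists()]
    if missing:
        raise ProfileError(f"missing PSSM profile(s) for record(s): {', '.join(missing)}")
    pairs = []
    for seq in sequences:
        profile = parse_ascii_pssm(
            (profile_dir / f"{seq.id}{suffix}").read_text(), sequence_id=seq.id
        )
        if profile.sequence.residues != seq.residues:
            raise ProfileError(
                f"profile residues for {seq.id!r} disagree with the FASTA record"
            )
        pairs.append((seq, profile))
    return pairs


# ---------------------------------------------------------------------------
# PSI-BLAST
# ---------------------------------------------------------------------------

def run_psiblast(
    seq: ProteinSequence,
    db_path: str | Path,
    iterations: int = 3,
    evalue_cutoff: float = 0.001,
    executable: str = "psiblast",
) -> PssmProfile:
    """Generate a PSSM for one sequence by running PSI-BLAST locally.

    Runs the stated number of iterations at the stated E-value cutoff against
    a formatted protein database and parses the emitted ASCII PSSM. This is a
    convenience only — nothing else in the package requires PSI-BLAST.
    """
    if shutil.which(executable) is None:
        raise ProfileError(
            f"PSI-BLAST executable {executable!r} not found on PATH; install "
            "NCBI BLAST+ or supply precomputed ASCII PSSM files instead"
        )
    with tempfile.TemporaryDirectory() as tmp:
        query = Path(tmp) / "query.fasta"
        pssm_out = Path(tmp) / "query.pssm"
        query.write_text(write_fasta([seq]))
        cmd = [
            executable,
            "-query", str(query),
            "-db", str(db_path),
            "-num_iterations", str(iterations),
            "-evalue", str(evalue_cutoff),
            "-out_ascii_pssm", str(pssm_out),
        ]
        result = subprocess.run(cmd, capture_output=True, text=True)
        if result.returncode != 0:
            raise ProfileError(
                f"PSI-BLAST exited with status {result.returncode}: {result.stderr.strip()}"
            )
        if not pssm_out.exists():
            raise ProfileError(
                f"PSI-BLAST produced no PSSM for {seq.id!r} (likely no database "
                "hits); supply a profile produced elsewhere for this sequence"
            )
        return parse_ascii_pssm(pssm_out.read_text(), sequence_id=seq.id)
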