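"""Reading, cleaning and compressing pairwise codon alignments.

Input alignments must contain exactly two in-frame sequences of equal
length (a multiple of 3).  Codon columns where either sequence carries a
gap, an ambiguity character or a stop codon are removed before analysis,
and the retained columns are compressed to site-pattern counts, which is
what the likelihood actually consumes.
"""

from __future__ import annotations

import io
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import TextIO

import numpy as np
from Bio import SeqIO

from .codon_model import STANDARD_CODE, CodonFrequencies

_VALID_NUCS = frozenset("ACGT")

#: Genes of 50 codons or fewer are excluded from genome screens.
MIN_CODONS_EXCLUSIVE = 50


class AlignmentFormatError(ValueError):
    """Raised when an input file is not a valid two-sequence codon alignment."""


@dataclass
class RawPairAlignment:
    """Two equal-length nucleotide sequences, as read from disk."""

    names: tuple[str, str]
    seq1: str
    seq2: str

    @property
    def n_codons(self) -> int:
        return len(self.seq1) // 3


@dataclass
class CleaningReport:
    sites_removed_gap_ambiguity: int
    excluded_short: bool
    stop_codons_removed: int = 0


@dataclass
class PairAlignment:
    """A cleaned pairwise codon alignment compressed to pattern counts."""

    names: tuple[str, str]
    codons1: list[str]
    codons2: list[str]
    patterns: dict[tuple[str, str], int] = field(default=None)

    def __post_init__(self) -> None:
        if len(self.codons1) != len(self.codons2):
            raise ValueError("sequences must have equal codon counts")
        if self.patterns is None:
            self.patterns = dict(Counter(zip(self.codons1, self.codons2)))

    @property
    def L_c(self) -> int:
        return len(self.codons1)

    @property
    def is_identical(self) -> bool:
        return all(a == b for (a, b) in self.patterns)

    def pattern_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Pattern codon indices (i, j) and counts, as arrays."""
        idx = STANDARD_CODE.index
        items = sorted(self.patterns.items())
        i = np.array([idx[a] for (a, _), _ in items], dtype=np.intp)
        j = np.array([idx[b] for (_, b), _ in items], dtype=np.intp)
        n = np.array([c for _, c in items], dtype=float)
        return i, j, n

    def to_fasta(self) -> str:
        return (
            f">{self.names[0]}\n{''.join(self.codons1)}\n"
            f">{self.names[1]}\n{''.join(self.codons2)}\n"
        )


def _normalize(seq: str) -> str:
    return seq.upper().replace("U", "T")


def read_pair_alignment(
    source: str | Path | TextIO, format: str = "fasta"
) -> RawPairAlignment:
    """Read a two-sequence alignment from FASTA or sequential PHYLIP."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            return read_pair_alignment(fh, format=format)
    if format == "fasta":
        records = list(SeqIO.parse(source, "fasta"))
        pairs = [(r.id, _normalize(str(r.seq))) for r in records]
    elif format == "phylip":
        pairs = _parse_phylip_pair(source)
    else:
        raise ValueError(f"unknown alignment format: {format!r}")
    if len(pairs) != 2:
        raise AlignmentFormatError(
            f"expected exactly 2 sequences, found {len(pairs)}"
        )
    (n1, s1), (n2, s2) = pairs
    if len(s1) != len(s2):
        raise AlignmentFormatError(
            f"sequences {n1!r} ({len(s1)} nt) and {n2!r} ({len(s2)} nt) "
            "have unequal lengths"
        )
    if len(s1) % 3 != 0:
        raise AlignmentFormatError(
            f"alignment length {len(s1)} of {n1!r}/{n2!r} is not a multiple of 3"
        )
    return RawPairAlignment(names=(n1, n2), seq1=s1, seq2=s2)


def _parse_phylip_pair(fh: TextIO) -> list[tuple[str, str]]:
    """Parse a sequential PHYLIP file with two sequences.

    Accepts both strict (10-character names) and relaxed
    (whitespace-delimited names) variants.
    """
    lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise AlignmentFormatError("empty PHYLIP file")
    header = lines[0].split()
    try:
        n_seq, n_sites = int(header[0]), int(header[1])
    except (IndexError, ValueError):
        raise AlignmentFormatError(f"bad PHYLIP header: {lines[0]!r}") from None
    if n_seq != 2:
        raise AlignmentFormatError(f"expected 2 sequences, header says {n_seq}")
    pairs: list[tuple[str, str]] = []
    i = 1
    for _ in range(n_seq):
        if i >= len(lines):
            raise AlignmentFormatError("truncated PHYLIP file")
        fields = lines[i].split(None, 1)
        name = fields[0]
        seq = "".join(fields[1].split()) if len(fields) > 1 else ""
        i += 1
        while len(seq) < n_sites and i < len(lines):
            seq += "".join(lines[i].split())
            i += 1
        if len(seq) != n_sites:
            raise AlignmentFormatError(
                f"sequence {name!r} has {len(seq)} sites, header says {n_sites}"
            )
        pairs.append((name, _normalize(seq)))
    return pairs


def clean_and_compress(
    raw: RawPairAlignment, min_codons: int | None = None
) -> tuple[PairAlignment, CleaningReport]:
    """Drop codon columns with gaps/ambiguities/stops; compress to patterns.

    ``min_codons`` only sets the ``excluded_short`` flag in the report (the
    batch driver acts on it); the alignment itself is always returned.
    """
    if min_codons is None:
        min_codons = MIN_CODONS_EXCLUSIVE
    code = STANDARD_CODE
    c1, c2 = [], []
    removed = 0
    stops = 0
    for k in range(raw.n_codons):
        a = raw.seq1[3 * k : 3 * k + 3]
        b = raw.seq2[3 * k : 3 * k + 3]
        if not (_VALID_NUCS.issuperset(a) and _VALID_NUCS.issuperset(b)):
            removed += 1
            continue
        if code.is_stop(a) or code.is_stop(b):
            stops += 1
            continue
        c1.append(a)
        c2.append(b)
    if stops:
        warnings.warn(
            f"removed {stops} codon site(s) containing stop codons", UserWarning
        )
    aln = PairAlignment(names=raw.names, codons1=c1, codons2=c2)
    if aln.L_c == 0:
        warnings.warn("no codon sites remain after cleaning", UserWarning)
    report = CleaningReport(
        sites_removed_gap_ambiguity=removed,
        excluded_short=aln.L_c <= min_codons,
        stop_codons_removed=stops,
    )
    return aln, report


def observed_codon_frequencies(aln: PairAlignment) -> CodonFrequencies:
    """F61 frequencies: observed codon usage pooled over both sequences."""
    if aln.L_c == 0:
        warnings.warn(
            "empty alignment: falling back to equal codon frequencies", UserWarning
        )
        return CodonFrequencies.equal()
    counts = np.zeros(STANDARD_CODE.n_states)
    for (a, b), n in aln.patterns.items():
        counts[STANDARD_CODE.index[a]] += n
        counts[STANDARD_CODE.index[b]] += n
    return CodonFrequencies.from_counts(counts)


def pair_alignment_from_strings(
    seq1: str, seq2: str, names: tuple[str, str] = ("seq1", "seq2")
) -> tuple[PairAlignment, CleaningReport]:
    """Convenience: build a cleaned PairAlignment from two nucleotide strings."""
    raw = read_pair_alignment(
        io.StringIO(f">{names[0]}\n{seq1}\n>{names[1]}\n{seq2}\n")
    )
    return clean_and_compress(raw)
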