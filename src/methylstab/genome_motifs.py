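"""Genome ingestion, palindromic motif scanning, spacing statistics and motif-free gaps.

Coordinates are 0-based half-open everywhere inside the package; exported
BED is likewise 0-based half-open, while any emitted GFF3 is 1-based
inclusive.  Overlapping motif occurrences are all reported (step-1 scan).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

DEFAULT_MOTIFS: tuple[str, ...] = ("GATC", "CATG")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_INVALID_CHAR = re.compile(r"[^ACGTN]")


def reverse_complement(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomeSequence:
    """A single nucleotide sequence with pre-computed composition statistics.

    ``gc_fraction`` uses only unambiguous bases in its denominator: N bases
    are excluded from the composition but still count toward ``length``.
    """

    id: str
    sequence: str
    length: int
    gc_fraction: float
    adenine_count_fwd: int
    thymine_count_fwd: int

    @classmethod
    def from_sequence(cls, seq_id: str, sequence: str) -> "GenomeSequence":
        sequence = sequence.upper()
        if not sequence:
            raise ValueError(f"empty sequence for record {seq_id!r}")
        bad = _INVALID_CHAR.search(sequence)
        if bad is not None:
            raise ValueError(
                f"non-IUPAC character {bad.group()!r} at position {bad.start()} "
                f"in record {seq_id!r} (only A/C/G/T/N supported)"
            )
        a = sequence.count("A")
        c = sequence.count("C")
        g = sequence.count("G")
        t = sequence.count("T")
        denom = a + c + g + t
        if denom == 0:
            raise ValueError(f"record {seq_id!r} contains no unambiguous bases")
        return cls(
            id=seq_id,
            sequence=sequence,
            length=len(sequence),
            gc_fraction=(g + c) / denom,
            adenine_count_fwd=a,
            thymine_count_fwd=t,
        )


@dataclass(frozen=True)
class MotifSite:
    """One strand's occurrence of a palindromic motif.

    ``start`` is always the 0-based forward-strand coordinate of the motif's
    first base; for palindromes the 4-mer is identical on both strands at a
    given start, so the two strand-sites of a locus share it.
    """

    motif: str
    strand: str  # "+" or "-"
    start: int
    locus_id: int


@dataclass(frozen=True)
class PalindromeLocus:
    """A palindromic motif occurrence with its paired two strand-sites."""

    locus_id: int
    motif: str
    start: int
    fwd_site: MotifSite
    rev_site: MotifSite


@dataclass(frozen=True)
class SpacingStats:
    """Descriptive spacing statistics for the loci of one motif.

    ``mean_interval`` is genome length / locus count (the "once every X bp"
    statistic).  ``dispersion_index`` is the population variance of successive
    inter-start distances divided by their mean; it is ``None`` (an explicit
    sentinel, not an exception) when fewer than two loci exist.
    """

    motif: str
    locus_count: int
    mean_interval: float | None
    gaps: tuple[int, ...]
    gap_mean: float | None
    gap_variance: float | None
    dispersion_index: float | None


@dataclass(frozen=True)
class GapRecord:
    """A maximal interval [start, end) containing no motif base of any scanned motif."""

    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ExpectedFrequencyModel:
    """Random-composition expectation for a motif's recurrence interval.

    Per-base probabilities are p_S = gc/2 for G or C and p_W = (1-gc)/2 for
    A or T; the motif probability is the product over its bases and the
    expected interval its reciprocal.
    """

    motif: str
    p_S: float
    p_W: float
    motif_probability: float
    expected_interval: float


def read_fasta(path: str | Path, record_id: str | None = None) -> GenomeSequence:
    """Read one record from a (multi-line, case-insensitive) FASTA file.

    Parameters
    ----------
    path
        FASTA file; must exist.
    record_id
        If given, select the record with this id; otherwise the file must
        contain the record of interest first (single-record files are the
        normal case).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    with open(path) as fh:
        for record in SeqIO.parse(fh, "fasta"):
            if record_id is None or record.id == record_id:
                return GenomeSequence.from_sequence(record.id, str(record.seq))
    if record_id is not None:
        raise ValueError(f"record {record_id!r} not found in {path}")
    raise ValueError(f"no FASTA records found in {path}")


def _find_occurrences(sequence: str, motif: str) -> list[int]:
    """All start positions of ``motif`` in ``sequence``, overlapping included."""
    out: list[int] = []
    i = sequence.find(motif)
    while i != -1:
        out.append(i)
        i = sequence.find(motif, i + 1)
    return out


def scan_motifs(
    genome: GenomeSequence, motifs: Sequence[str] = DEFAULT_MOTIFS
) -> list[PalindromeLocus]:
    """Scan both strands for palindromic motifs.

    Each forward-strand occurrence yields one :class:`PalindromeLocus`
    carrying a ``+`` and a ``-`` strand-site (palindromes occur at the same
    start on both strands).  Overlapping occurrences are all reported and
    N never matches.

    Raises
    ------
    ValueError
        If a motif is not its own reverse complement (strand pairing would
        be undefined).
    """
    hits: list[tuple[int, str]] = []
    for motif in motifs:
        motif = motif.upper()
        if reverse_complement(motif) != motif:
            raise ValueError(
                f"motif {motif!r} is not a reverse-complement palindrome; "
                "strand pairing is undefined"
            )
        hits.extend((start, motif) for start in _find_occurrences(genome.sequence, motif))
    hits.sort()
    loci = []
    for locus_id, (start, motif) in enumerate(hits):
        fwd = MotifSite(motif=motif, strand="+", start=start, locus_id=locus_id)
        rev = MotifSite(motif=motif, strand="-", start=start, locus_id=locus_id)
        loci.append(
            PalindromeLocus(locus_id=locus_id, motif=motif, start=start, fwd_site=fwd, rev_site=rev)
        )
    return loci


def spacing_stats(
    loci: Iterable[PalindromeLocus], genome: GenomeSequence, motif: str
) -> SpacingStats:
    """Spacing statistics for the loci of one motif.

    Loci of other motifs in ``loci`` are ignored.  With fewer than two loci
    the gap statistics are ``None``; with zero loci ``mean_interval`` is
    ``None`` as well.
    """
    starts = np.sort(np.array([l.start for l in loci if l.motif == motif.upper()], dtype=np.int64))
    n = int(starts.size)
    if n == 0:
        return SpacingStats(motif, 0, None, (), None, None, None)
    mean_interval = genome.length / n
    if n < 2:
        return SpacingStats(motif, n, mean_interval, (), None, None, None)
    gaps = np.diff(starts)
    gap_mean = float(gaps.mean())
    gap_variance = float(gaps.var())  # population variance
    return SpacingStats(
        motif=motif.upper(),
        locus_count=n,
        mean_interval=mean_interval,
        gaps=tuple(int(g) for g in gaps),
        gap_mean=gap_mean,
        gap_variance=gap_variance,
        dispersion_index=gap_variance / gap_mean,
    )


def motif_free_gaps(
    loci: Iterable[PalindromeLocus], genome: GenomeSequence, motif_length: int = 4
) -> list[GapRecord]:
    """All maximal motif-free intervals, position-sorted.

    A gap runs from the end of one motif occurrence (start + motif length)
    to the start of the next; the terminal segments before the first motif
    and after the last are included.  Zero-length gaps (motifs tiling
    back-to-back) are kept; overlapping occurrences never produce negative
    gaps.  With zero loci the whole genome is one gap.
    """
    starts = sorted({l.start for l in loci})
    if not starts:
        return [GapRecord(0, genome.length)]
    gaps: list[GapRecord] = []
    prev_end = 0
    for s in starts:
        if s >= prev_end:
            gaps.append(GapRecord(prev_end, s))
        prev_end = max(prev_end, s + motif_length)
    gaps.append(GapRecord(prev_end, max(prev_end, genome.length)))
    return gaps


def longest_motif_free_gap(
    loci: Iterable[PalindromeLocus], genome: GenomeSequence, motif_length: int = 4
) -> tuple[GapRecord, list[GapRecord]]:
    """The longest motif-free gap plus the full position-sorted gap list."""
    gaps = motif_free_gaps(loci, genome, motif_length=motif_length)
    longest = max(gaps, key=lambda g: g.length)
    return longest, gaps


def expected_interval(gc_fraction: float, motif: str) -> ExpectedFrequencyModel:
    """Expected recurrence interval of ``motif`` under i.i.d. composition.

    Raises
    ------
    ValueError
        If ``gc_fraction`` is outside [0, 1], or a base class required by
        the motif has probability zero (the expectation is undefined).
    """
    if not 0.0 <= gc_fraction <= 1.0:
        raise ValueError(f"gc_fraction must lie in [0, 1], got {gc_fraction}")
    motif = motif.upper()
    p_s = gc_fraction / 2.0
    p_w = (1.0 - gc_fraction) / 2.0
    prob = 1.0
    for base in motif:
        if base in "GC":
            p = p_s
        elif base in "AT":
            p = p_w
        else:
            raise ValueError(f"motif base {base!r} is not one of A/C/G/T")
        if p == 0.0:
            raise ValueError(
                f"motif {motif!r} requires base {base!r} but its probability is 0 "
                f"at gc_fraction={gc_fraction}"
            )
        prob *= p
    return ExpectedFrequencyModel(
        motif=motif,
        p_S=p_s,
        p_W=p_w,
        motif_probability=prob,
        expected_interval=1.0 / prob,
    )


def loci_to_bed(loci: Iterable[PalindromeLocus], path: str | Path, chrom: str) -> None:
    """Write strand-sites as BED6 (0-based half-open), two lines per locus."""
    with open(path, "w") as fh:
        for locus in loci:
            for site in (locus.fwd_site, locus.rev_site):
                fh.write(
                    f"{chrom}\t{site.start}\t{site.start + len(site.motif)}\t"
                    f"{site.motif}\t{site.locus_id}\t{site.strand}\n"
                )


def read_loci_bed(path: str | Path) -> list[PalindromeLocus]:
    """Reconstruct palindromic loci from a BED6 file written by :func:`loci_to_bed`."""
    seen: dict[tuple[int, str], int] = {}
    loci: list[PalindromeLocus] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"BED6 line with {len(fields)} fields: {line!r}")
            start, motif = int(fields[1]), fields[3]
            key = (start, motif)
            if key in seen:
                continue
            locus_id = int(fields[4])
            seen[key] = locus_id
            fwd = MotifSite(motif, "+", start, locus_id)
            rev = MotifSite(motif, "-", start, locus_id)
            loci.append(PalindromeLocus(locus_id, motif, start, fwd, rev))
    loci.sort(key=lambda l: l.start)
    return loci


def loci_to_tsv(loci: Iterable[PalindromeLocus], path: str | Path) -> None:
    """Tab-separated locus table (locus_id, motif, start, end)."""
    with open(path, "w") as fh:
        fh.write("locus_id\tmotif\tstart\tend\n")
        for locus in loci:
            fh.write(f"{locus.locus_id}\t{locus.motif}\t{locus.start}\t{locus.start + len(locus.motif)}\n")
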