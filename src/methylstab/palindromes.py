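"""Per-locus two-strand methylation state classification.

A palindrome is *fully methylated* when the cross-replicate mean
methylated-read fraction is strictly above the threshold (default 0.75) on
both strands, *hemimethylated* when exactly one strand exceeds it, and
*stochastic* otherwise.  A locus is additionally flagged *stably
non-methylated* when every replicate reported zero methylated reads on both
strands; such loci are necessarily a subset of the stochastic state.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from methylstab.enrichment import Gene
from methylstab.stability import StabilityRecord

FULLY_METHYLATED = "fully_methylated"
HEMIMETHYLATED = "hemimethylated"
STOCHASTIC = "stochastic"

STATES = (FULLY_METHYLATED, HEMIMETHYLATED, STOCHASTIC)

DEFAULT_THRESHOLD = 0.75


@dataclass(frozen=True)
class PalindromeRecord:
    """Two-strand methylation state of one palindromic locus."""

    locus_id: int
    motif: str
    start: int
    fwd_mean_frac: float
    rev_mean_frac: float
    state: str
    stably_nonmethylated_flag: bool


def classify_palindromes(
    records: Sequence[StabilityRecord], threshold: float = DEFAULT_THRESHOLD
) -> tuple[list[PalindromeRecord], dict[str, int]]:
    """Pair strand records per locus and classify the palindrome state.

    The comparison against ``threshold`` is strict (>), so a strand mean of
    exactly 0.75 does not count as methylated.

    Raises
    ------
    ValueError
        If a locus is missing one of its two strand records.
    """
    by_locus: dict[int, dict[str, StabilityRecord]] = {}
    for rec in records:
        by_locus.setdefault(rec.locus_id, {})[rec.strand] = rec
    out: list[PalindromeRecord] = []
    counts = {state: 0 for state in STATES}
    for locus_id in sorted(by_locus):
        pair = by_locus[locus_id]
        if set(pair) != {"+", "-"}:
            raise ValueError(
                f"locus {locus_id}: expected records for both strands, got {sorted(pair)}"
            )
        fwd, rev = pair["+"], pair["-"]
        fwd_high = fwd.mean_frac > threshold
        rev_high = rev.mean_frac > threshold
        if fwd_high and rev_high:
            state = FULLY_METHYLATED
        elif fwd_high or rev_high:
            state = HEMIMETHYLATED
        else:
            state = STOCHASTIC
        flag = all(f == 0.0 for f in fwd.frac_by_replicate) and all(
            f == 0.0 for f in rev.frac_by_replicate
        )
        counts[state] += 1
        out.append(
            PalindromeRecord(
                locus_id=locus_id,
                motif=fwd.motif,
                start=fwd.start,
                fwd_mean_frac=fwd.mean_frac,
                rev_mean_frac=rev.mean_frac,
                state=state,
                stably_nonmethylated_flag=flag,
            )
        )
    return out, counts


def stably_nonmethylated_loci(records: Sequence[PalindromeRecord]) -> list[PalindromeRecord]:
    """Loci with zero methylated reads on both strands in every replicate."""
    return [r for r in records if r.stably_nonmethylated_flag]


def gene_palindrome_report(
    palindromes: Sequence[PalindromeRecord],
    genes: Sequence[Gene],
    gene_ids: Sequence[str],
    motif_length: int = 4,
) -> dict[str, pd.DataFrame]:
    """Per-gene table of palindrome states, for loci wholly within the gene.

    A 4-mer that only partially overlaps the gene span is not assigned to it.
    Unknown gene ids raise an error listing the known ids.
    """
    by_id: Mapping[str, Gene] = {g.gene_id: g for g in genes}
    unknown = [gid for gid in gene_ids if gid not in by_id]
    if unknown:
        raise KeyError(
            f"unknown gene id(s) {unknown}; known ids: {sorted(by_id)}"
        )
    report: dict[str, pd.DataFrame] = {}
    for gid in gene_ids:
        gene = by_id[gid]
        rows = [
            {
                "gene_id": gid,
                "locus_id": p.locus_id,
                "motif": p.motif,
                "start": p.start,
                "fwd_mean_frac": p.fwd_mean_frac,
                "rev_mean_frac": p.rev_mean_frac,
                "state": p.state,
            }
            for p in sorted(palindromes, key=lambda p: p.start)
            if p.start >= gene.start and p.start + motif_length <= gene.end
        ]
        report[gid] = pd.DataFrame(
            rows,
            columns=[
                "gene_id",
                "locus_id",
                "motif",
                "start",
                "fwd_mean_frac",
                "rev_mean_frac",
                "state",
            ],
        )
    return report


def palindromes_to_tsv(records: Sequence[PalindromeRecord], path) -> None:
    """Palindrome table as TSV with a state column."""
    with open(path, "w") as fh:
        fh.write(
            "locus_id\tmotif\tstart\tfwd_mean_frac\trev_mean_frac\tstate\tstably_nonmethylated\n"
        )
        for r in records:
            fh.write(
                f"{r.locus_id}\t{r.motif}\t{r.start}\t{r.fwd_mean_frac}\t{r.rev_mean_frac}\t"
                f"{r.state}\t{int(r.stably_nonmethylated_flag)}\n"
            )
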