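"""Cross-replicate methylation-stability classification of motif strand-sites.

Every palindromic locus contributes two strand-sites (one target adenine per
strand).  For each strand-site the methylated-read fraction is collected
from every replicate — an absent call counts as 0.0 *in this stage only*,
on the grounds that a site not called modified is evidence of
non-methylation — and the site is binarised per replicate at a threshold
(default 0.5).  The count k of methylated replicates determines the
stability class:

    k == n_replicates  ->  stable_methylated
    k == 0             ->  stable_nonmethylated
    otherwise          ->  methylated_in_<k>

which with three replicates reproduces the four mean-fraction quadrants
(~0, ~1/3, ~2/3, ~1) as a crisp rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from methylstab.genome_motifs import PalindromeLocus
from methylstab.modcalls import ReplicateModSet, target_adenine_positions

_K_WORDS = {1: "one", 2: "two", 3: "three", 4: "four", 5: "five"}

STABLE_METHYLATED = "stable_methylated"
STABLE_NONMETHYLATED = "stable_nonmethylated"


def class_for_k(k: int, n_replicates: int) -> str:
    """Stability class name for k methylated replicates out of n."""
    if k == n_replicates:
        return STABLE_METHYLATED
    if k == 0:
        return STABLE_NONMETHYLATED
    return f"methylated_in_{_K_WORDS.get(k, str(k))}"


@dataclass(frozen=True)
class StabilityRecord:
    """Cross-replicate stability of one motif strand-site."""

    locus_id: int
    strand: str
    motif: str
    start: int  # locus start (motif's first base), 0-based
    position: int  # the target adenine's coordinate
    frac_by_replicate: tuple[float, ...]
    mean_frac: float
    sd_frac: float  # population SD (n denominator)
    k_methylated: int
    stability_class: str


@dataclass(frozen=True)
class StabilitySummary:
    """Class counts/fractions over all strand-sites plus motif composition."""

    total: int
    counts: dict[str, int]
    fractions: dict[str, float]
    variably_methylated_fraction: float
    motif_composition: dict[str, dict[str, float]]  # class -> motif -> share


def combine_replicates(
    replicates: Sequence[ReplicateModSet],
    loci: Sequence[PalindromeLocus],
    binarize: float = 0.5,
) -> list[StabilityRecord]:
    """Per strand-site mean/SD of methylFrac across replicates, plus class.

    An absent call contributes frac 0.0.  A frac exactly at the binarisation
    threshold counts as methylated (>=, deterministic tie-break).

    Raises
    ------
    ValueError
        With fewer than two replicates, or when replicate genome lengths
        disagree.
    """
    if len(replicates) < 2:
        raise ValueError(f"need >= 2 replicates, got {len(replicates)}")
    lengths = {r.genome_length for r in replicates if r.genome_length is not None}
    if len(lengths) > 1:
        raise ValueError(f"replicate genome-length mismatch: {sorted(lengths)}")

    positions, strands, _ = target_adenine_positions(loci)
    fracs = np.column_stack(
        [np.nan_to_num(rep.frac_lookup(positions, strands), nan=0.0) for rep in replicates]
    )
    means = fracs.mean(axis=1)
    sds = fracs.std(axis=1)  # population SD
    ks = (fracs >= binarize).sum(axis=1)
    n_reps = len(replicates)

    records: list[StabilityRecord] = []
    for i, locus in enumerate(loci):
        for j, strand in enumerate(("+", "-")):
            row = 2 * i + j
            records.append(
                StabilityRecord(
                    locus_id=locus.locus_id,
                    strand=strand,
                    motif=locus.motif,
                    start=locus.start,
                    position=int(positions[row]),
                    frac_by_replicate=tuple(float(f) for f in fracs[row]),
                    mean_frac=float(means[row]),
                    sd_frac=float(sds[row]),
                    k_methylated=int(ks[row]),
                    stability_class=class_for_k(int(ks[row]), n_reps),
                )
            )
    return records


def classify_stability(
    records: Sequence[StabilityRecord], binarize: float | None = None
) -> StabilitySummary:
    """Aggregate stability records into per-class counts and fractions.

    When ``binarize`` is given, k and class are recomputed from the stored
    per-replicate fractions at that threshold; otherwise the classes already
    on the records are used.
    """
    total = len(records)
    counts: dict[str, int] = {}
    motif_counts: dict[str, dict[str, int]] = {}
    variable = 0
    for rec in records:
        if binarize is not None:
            n = len(rec.frac_by_replicate)
            k = sum(1 for f in rec.frac_by_replicate if f >= binarize)
            cls = class_for_k(k, n)
        else:
            cls = rec.stability_class
        counts[cls] = counts.get(cls, 0) + 1
        motif_counts.setdefault(cls, {}).setdefault(rec.motif, 0)
        motif_counts[cls][rec.motif] += 1
        if cls not in (STABLE_METHYLATED, STABLE_NONMETHYLATED):
            variable += 1
    fractions = {cls: c / total for cls, c in counts.items()} if total else {}
    composition = {
        cls: {m: c / sum(mc.values()) for m, c in mc.items()} for cls, mc in motif_counts.items()
    }
    return StabilitySummary(
        total=total,
        counts=counts,
        fractions=fractions,
        variably_methylated_fraction=variable / total if total else 0.0,
        motif_composition=composition,
    )


def export_fig4_table(
    records: Sequence[StabilityRecord], path: str | Path | None = None
) -> pd.DataFrame:
    """Stability records as a flat table, ordered by (locus_id, strand).

    Per-replicate fractions are retained as ``frac_rep<i>`` columns so the
    palindrome stage can recover replicate-level evidence from the file.
    """
    ordered = sorted(records, key=lambda r: (r.locus_id, r.strand))
    n_reps = len(ordered[0].frac_by_replicate) if ordered else 0
    data: dict[str, list] = {
        "locus_id": [r.locus_id for r in ordered],
        "strand": [r.strand for r in ordered],
        "motif": [r.motif for r in ordered],
        "start": [r.start for r in ordered],
        "position": [r.position for r in ordered],
    }
    for j in range(n_reps):
        data[f"frac_rep{j + 1}"] = [r.frac_by_replicate[j] for r in ordered]
    data["mean_frac"] = [r.mean_frac for r in ordered]
    data["sd_frac"] = [r.sd_frac for r in ordered]
    data["k_methylated"] = [r.k_methylated for r in ordered]
    data["stability_class"] = [r.stability_class for r in ordered]
    table = pd.DataFrame(data)
    if path is not None:
        table.to_csv(path, sep="\t", index=False)
    return table


def read_stability_table(path: str | Path) -> list[StabilityRecord]:
    """Inverse of :func:`export_fig4_table`."""
    table = pd.read_csv(path, sep="\t")
    frac_cols = sorted(
        (c for c in table.columns if c.startswith("frac_rep")),
        key=lambda c: int(c.removeprefix("frac_rep")),
    )
    records = []
    for row in table.itertuples(index=False):
        d: Mapping[str, object] = row._asdict()
        records.append(
            StabilityRecord(
                locus_id=int(d["locus_id"]),
                strand=str(d["strand"]),
                motif=str(d["motif"]),
                start=int(d["start"]),
                position=int(d["position"]),
                frac_by_replicate=tuple(float(d[c]) for c in frac_cols),
                mean_frac=float(d["mean_frac"]),
                sd_frac=float(d["sd_frac"]),
                k_methylated=int(d["k_methylated"]),
                stability_class=str(d["stability_class"]),
            )
        )
    return records
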