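"""Sliding-window motif enrichment, gap depletion, region merging and gene annotation.

The ME score of a window is the number of palindromic loci wholly inside it
divided by the expected count (two for a 278-bp window: one occurrence of
each of GATC and CATG).  Depletion of a motif-free gap is the reciprocal of
the expected number of loci a gap of that length should contain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from methylstab.genome_motifs import GapRecord, GenomeSequence, PalindromeLocus

DEFAULT_WINDOW = 278
DEFAULT_EXPECTED = 2.0
DEFAULT_ME_THRESHOLD = 3.5

#: Ordinal coding of transcription classes for the density correlation.
#: "Unknown" is deliberately absent: unlabelled genes are excluded.
DEFAULT_CLASS_CODES: Mapping[str, float] = {"Early": 0.0, "Early-Late": 1.0, "Late": 2.0}


@dataclass(frozen=True)
class WindowScore:
    """One sliding window's motif counts and fold-enrichment (ME) score."""

    start: int
    end: int
    n_gatc: int
    n_catg: int
    me: float


@dataclass(frozen=True)
class DepletionRecord:
    """Fold-depletion of one motif-free gap.

    ``fold`` × ``expected_in_gap`` == 1 exactly; fold < 1 whenever the gap is
    longer than window/expected (139 bp at the defaults).
    """

    gap: GapRecord
    expected_in_gap: float
    fold: float


@dataclass(frozen=True)
class RegionReport:
    """A merged span of significant windows, optionally gene-annotated."""

    start: int
    end: int
    me: float  # max ME among merged member windows
    n_gatc: int
    n_catg: int
    gene_ids: tuple[str, ...] = ()
    annotations: tuple[str, ...] = ()
    classes: tuple[str, ...] = ()


@dataclass(frozen=True)
class Gene:
    """A gene feature with 0-based half-open coordinates."""

    seqid: str
    gene_id: str
    start: int
    end: int
    strand: str
    annotation: str = ""
    attributes: Mapping[str, str] = field(default_factory=dict)


def _starts_by_motif(loci: Iterable[PalindromeLocus]) -> dict[str, np.ndarray]:
    out: dict[str, list[int]] = {}
    for locus in loci:
        out.setdefault(locus.motif, []).append(locus.start)
    return {m: np.sort(np.array(s, dtype=np.int64)) for m, s in out.items()}


def count_loci_in_span(
    loci: Iterable[PalindromeLocus], start: int, end: int, motif_length: int = 4
) -> dict[str, int]:
    """Per-motif count of loci whose 4-mer lies wholly inside [start, end)."""
    by_motif = _starts_by_motif(loci)
    return {
        m: int(
            np.searchsorted(s, end - motif_length, side="right") - np.searchsorted(s, start, side="left")
        )
        for m, s in by_motif.items()
    }


def window_enrichment(
    genome: GenomeSequence,
    loci: Sequence[PalindromeLocus],
    window: int = DEFAULT_WINDOW,
    expected: float = DEFAULT_EXPECTED,
) -> list[WindowScore]:
    """Score every step-1 sliding window of size ``window``.

    A locus is counted when its 4-mer lies wholly inside the window; counting
    is of palindromic loci, not strand-sites.
    """
    if window < 4:
        raise ValueError(f"window must be >= motif length (4), got {window}")
    if window > genome.length:
        raise ValueError(f"window {window} exceeds genome length {genome.length}")
    by_motif = _starts_by_motif(loci)
    gatc = by_motif.get("GATC", np.empty(0, dtype=np.int64))
    catg = by_motif.get("CATG", np.empty(0, dtype=np.int64))
    n_windows = genome.length - window + 1
    ws = np.arange(n_windows, dtype=np.int64)
    last_ok = ws + window - 4  # last permissible locus start inside each window
    n_gatc = np.searchsorted(gatc, last_ok, side="right") - np.searchsorted(gatc, ws, side="left")
    n_catg = np.searchsorted(catg, last_ok, side="right") - np.searchsorted(catg, ws, side="left")
    me = (n_gatc + n_catg) / expected
    return [
        WindowScore(int(w), int(w) + window, int(g), int(c), float(m))
        for w, g, c, m in zip(ws, n_gatc, n_catg, me)
    ]


def merge_significant_windows(
    scores: Sequence[WindowScore | RegionReport],
    me_threshold: float = DEFAULT_ME_THRESHOLD,
    loci: Sequence[PalindromeLocus] | None = None,
) -> list[RegionReport]:
    """Merge overlapping windows with ME >= threshold into disjoint regions.

    Region ME is the max member ME.  When ``loci`` is supplied, per-motif
    counts are recomputed over the merged span (whole-containment rule);
    otherwise the counts of the max-ME member are kept.  Regions are sorted
    by ME descending, then start.  The operation is idempotent: feeding a
    merged report back in changes nothing.
    """
    qualifying = sorted((s for s in scores if s.me >= me_threshold), key=lambda s: s.start)
    merged: list[list] = []  # [start, end, me, n_gatc, n_catg]
    for s in qualifying:
        if merged and s.start < merged[-1][1]:
            cur = merged[-1]
            cur[1] = max(cur[1], s.end)
            if s.me > cur[2]:
                cur[2], cur[3], cur[4] = s.me, s.n_gatc, s.n_catg
        else:
            merged.append([s.start, s.end, s.me, s.n_gatc, s.n_catg])
    regions = []
    for start, end, me, n_gatc, n_catg in merged:
        if loci is not None:
            counts = count_loci_in_span(loci, start, end)
            n_gatc = counts.get("GATC", 0)
            n_catg = counts.get("CATG", 0)
        regions.append(RegionReport(start, end, me, n_gatc, n_catg))
    regions.sort(key=lambda r: (-r.me, r.start))
    return regions


def depletion_scan(
    gaps: Iterable[GapRecord],
    window: int = DEFAULT_WINDOW,
    expected: float = DEFAULT_EXPECTED,
) -> list[DepletionRecord]:
    """Score motif-free gaps: expected loci in the gap and the fold depletion.

    ``expected_in_gap`` = expected * length / window (the original recipe:
    gap length divided by the recurrence interval, times two to cover both
    motifs), and ``fold`` its reciprocal.  Zero-length gaps are omitted.
    """
    records = []
    for gap in gaps:
        if gap.length == 0:
            continue
        exp = expected * gap.length / window
        records.append(DepletionRecord(gap=gap, expected_in_gap=exp, fold=1.0 / exp))
    return records


def read_gff3_genes(
    path: str | Path, feature_types: Sequence[str] = ("gene",)
) -> list[Gene]:
    """Parse gene-like features from a GFF3 file into 0-based half-open Genes.

    Malformed lines are skipped with a warning rather than aborting the run.
    """
    genes: list[Gene] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                warnings.warn(f"{path}:{lineno}: expected 9 GFF3 columns, got {len(fields)}; skipped")
                continue
            if fields[2] not in feature_types:
                continue
            try:
                start1, end1 = int(fields[3]), int(fields[4])
            except ValueError:
                warnings.warn(f"{path}:{lineno}: non-integer coordinates; skipped")
                continue
            if start1 < 1 or end1 < start1:
                warnings.warn(f"{path}:{lineno}: bad coordinate range {start1}-{end1}; skipped")
                continue
            attrs: dict[str, str] = {}
            for item in fields[8].split(";"):
                if "=" in item:
                    k, v = item.split("=", 1)
                    attrs[k.strip()] = v.strip()
            gene_id = attrs.get("ID") or attrs.get("Name") or attrs.get("locus_tag") or f"feature{lineno}"
            annotation = attrs.get("product") or attrs.get("Note") or attrs.get("description") or ""
            genes.append(
                Gene(
                    seqid=fields[0],
                    gene_id=gene_id,
                    start=start1 - 1,
                    end=end1,
                    strand=fields[6],
                    annotation=annotation,
                    attributes=attrs,
                )
            )
    return genes


def annotate_regions(
    regions: Sequence[RegionReport],
    genes: Sequence[Gene],
    class_table: Mapping[str, str] | None = None,
) -> list[RegionReport]:
    """Join genes onto regions by any-bp overlap.

    A region may list several genes and a gene may repeat across regions.
    ``class_table`` optionally maps gene id to a transcription class label.
    """
    out = []
    for region in regions:
        hits = [g for g in genes if g.start < region.end and g.end > region.start]
        hits.sort(key=lambda g: g.start)
        out.append(
            replace(
                region,
                gene_ids=tuple(g.gene_id for g in hits),
                annotations=tuple(g.annotation for g in hits),
                classes=tuple(
                    (class_table or {}).get(g.gene_id, "Unknown") for g in hits
                ),
            )
        )
    return out


def gene_motif_density_correlation(
    genes: Sequence[Gene],
    loci: Sequence[PalindromeLocus],
    gene_class: Mapping[str, str],
    class_codes: Mapping[str, float] = DEFAULT_CLASS_CODES,
    motifs: Sequence[str] = ("GATC", "CATG"),
) -> dict[str, float | None]:
    """Pearson R between size-normalised per-gene locus density and class code.

    Genes without a label in ``class_codes`` (e.g. "Unknown") are excluded.
    Returns one R per motif; ``None`` when fewer than three labelled genes
    remain.  A zero-variance input (identical densities or a single class)
    yields R = 0 by convention.
    """
    labelled = [g for g in genes if gene_class.get(g.gene_id) in class_codes]
    result: dict[str, float | None] = {}
    for motif in motifs:
        if len(labelled) < 3:
            result[motif] = None
            continue
        starts = np.sort(
            np.array([l.start for l in loci if l.motif == motif], dtype=np.int64)
        )
        dens, codes = [], []
        for g in labelled:
            n = int(
                np.searchsorted(starts, g.end - 4, side="right")
                - np.searchsorted(starts, g.start, side="left")
            )
            dens.append(n / (g.end - g.start))
            codes.append(class_codes[gene_class[g.gene_id]])
        x = np.asarray(dens)
        y = np.asarray(codes)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            result[motif] = 0.0
        else:
            result[motif] = float(np.corrcoef(x, y)[0, 1])
    return result


def regions_to_tsv(regions: Sequence[RegionReport], path: str | Path) -> None:
    """Region report as TSV (start, end, n_gatc, n_catg, ME, genes, classes)."""
    with open(path, "w") as fh:
        fh.write("start\tend\tn_gatc\tn_catg\tme\tgenes\tclasses\tannotations\n")
        for r in regions:
            fh.write(
                f"{r.start}\t{r.end}\t{r.n_gatc}\t{r.n_catg}\t{r.me}\t"
                f"{','.join(r.gene_ids)}\t{','.join(r.classes)}\t{'|'.join(r.annotations)}\n"
            )
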