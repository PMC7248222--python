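"""Readers for PacBio-style base-modification outputs and genome-wide summaries.

Two dialects are supported:

* a modifications GFF3 in which the feature type is the modification class
  (``m6A``/``m4C``/``modified_base``), the score column is the Phred-scaled
  ModificationQV, and the attributes carry ``coverage``, ``IPDRatio`` and the
  optional ``frac``/``fracLow``/``fracUp`` methylated-read fraction;
* a per-strand-position modifications CSV with columns
  ``refName, tpl, strand, base, score, ipdRatio, coverage`` where ``tpl`` is
  1-based and strand is encoded 0 (forward) / 1 (reverse).

Parsers never invent data: a missing ``frac`` stays absent (NaN) rather than
becoming zero — only the stability stage substitutes 0.0 for absent calls.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from methylstab.genome_motifs import GenomeSequence, PalindromeLocus

GFF_TYPES = ("m6A", "m4C", "modified_base")
CSV_COLUMNS = ("refName", "tpl", "strand", "base", "score", "ipdRatio", "coverage")

_FRAME_COLUMNS = (
    "base",
    "ipd_ratio",
    "mod_qv",
    "coverage",
    "methyl_frac",
    "frac_low",
    "frac_up",
    "mod_type",
)


@dataclass(frozen=True)
class SiteModCall:
    """Modification evidence for one strand-position."""

    ref_id: str
    position: int  # 0-based forward-strand coordinate
    strand: str  # "+" or "-"
    base: str
    ipd_ratio: float
    mod_qv: int
    coverage: int
    methyl_frac: float | None = None
    frac_low: float | None = None
    frac_up: float | None = None
    mod_type: str = "none"

    def __post_init__(self) -> None:
        if self.ipd_ratio is not None and not math.isnan(self.ipd_ratio) and self.ipd_ratio < 0:
            raise ValueError(f"ipd_ratio must be >= 0, got {self.ipd_ratio}")
        if self.methyl_frac is not None and self.frac_low is not None and self.frac_up is not None:
            if not (self.frac_low <= self.methyl_frac <= self.frac_up):
                raise ValueError(
                    f"frac CI violated at {self.position}{self.strand}: "
                    f"{self.frac_low} <= {self.methyl_frac} <= {self.frac_up}"
                )


class ReplicateModSet:
    """One replicate's modification calls, keyed by (position, strand).

    Backed by a pandas frame indexed by a unique (position, strand)
    MultiIndex so that genome-scale sets (both strands of a ~330 kb genome)
    stay cheap to hold and query.
    """

    def __init__(
        self,
        replicate_id: str,
        frame: pd.DataFrame,
        genome_length: int | None = None,
        ref_id: str = "ref",
    ) -> None:
        if not frame.index.is_unique:
            dupes = frame.index[frame.index.duplicated()][:5].tolist()
            raise ValueError(f"duplicate (position, strand) keys: {dupes}")
        if genome_length is not None and len(frame):
            max_pos = int(frame.index.get_level_values(0).max())
            if max_pos >= genome_length:
                raise ValueError(
                    f"call at position {max_pos} outside genome of length {genome_length}"
                )
        self.replicate_id = replicate_id
        self.frame = frame.sort_index()
        self.genome_length = genome_length
        self.ref_id = ref_id

    @classmethod
    def from_calls(
        cls,
        replicate_id: str,
        calls: Iterable[SiteModCall],
        genome_length: int | None = None,
        ref_id: str | None = None,
    ) -> "ReplicateModSet":
        calls = list(calls)
        index = pd.MultiIndex.from_arrays(
            [
                np.array([c.position for c in calls], dtype=np.int64),
                np.array([c.strand for c in calls], dtype=object),
            ],
            names=("position", "strand"),
        )
        frame = pd.DataFrame(
            {
                "base": [c.base for c in calls],
                "ipd_ratio": [c.ipd_ratio for c in calls],
                "mod_qv": np.array([c.mod_qv for c in calls], dtype=float),
                "coverage": np.array([c.coverage for c in calls], dtype=float),
                "methyl_frac": [
                    np.nan if c.methyl_frac is None else c.methyl_frac for c in calls
                ],
                "frac_low": [np.nan if c.frac_low is None else c.frac_low for c in calls],
                "frac_up": [np.nan if c.frac_up is None else c.frac_up for c in calls],
                "mod_type": [c.mod_type for c in calls],
            },
            index=index,
        )
        if ref_id is None:
            ref_id = calls[0].ref_id if calls else "ref"
        return cls(replicate_id, frame, genome_length=genome_length, ref_id=ref_id)

    def __len__(self) -> int:
        return len(self.frame)

    def __contains__(self, key: tuple[int, str]) -> bool:
        return key in self.frame.index

    def get(self, position: int, strand: str) -> SiteModCall | None:
        """The call at one strand-position, or None when absent."""
        try:
            row = self.frame.loc[(position, strand)]
        except KeyError:
            return None
        return SiteModCall(
            ref_id=self.ref_id,
            position=position,
            strand=strand,
            base=row["base"],
            ipd_ratio=float(row["ipd_ratio"]),
            mod_qv=int(row["mod_qv"]),
            coverage=int(row["coverage"]),
            methyl_frac=None if pd.isna(row["methyl_frac"]) else float(row["methyl_frac"]),
            frac_low=None if pd.isna(row["frac_low"]) else float(row["frac_low"]),
            frac_up=None if pd.isna(row["frac_up"]) else float(row["frac_up"]),
            mod_type=row["mod_type"],
        )

    def _lookup(self, column: str, positions: Sequence[int], strands: Sequence[str]) -> np.ndarray:
        idx = pd.MultiIndex.from_arrays(
            [np.asarray(positions, dtype=np.int64), np.asarray(strands, dtype=object)],
            names=("position", "strand"),
        )
        return self.frame[column].reindex(idx).to_numpy(dtype=float)

    def frac_lookup(self, positions: Sequence[int], strands: Sequence[str]) -> np.ndarray:
        """methyl_frac per strand-position; NaN where absent or uncalled."""
        return self._lookup("methyl_frac", positions, strands)

    def qv_lookup(self, positions: Sequence[int], strands: Sequence[str]) -> np.ndarray:
        """ModificationQV per strand-position; NaN where no call exists."""
        return self._lookup("mod_qv", positions, strands)


@dataclass(frozen=True)
class ModSummary:
    """Genome-wide high-ipdRatio census."""

    high_ipd_count: int
    strand_positions: int
    high_ipd_fraction: float
    threshold: float
    motif_adenine_count: int | None = None
    fold_excess: float | None = None
    pct_adenines_methylated: float | None = None


@dataclass(frozen=True)
class MotifCallSummary:
    """Per-motif methylation call fractions at a QV threshold."""

    fraction_by_motif: dict[str, float]
    methylated_by_site: dict[tuple[int, str], bool]
    n_methylated: int
    n_strand_sites: int
    adenine_fraction_methylated: float | None


def _parse_gff_attributes(text: str) -> dict[str, str]:
    out = {}
    for item in text.split(";"):
        item = item.strip()
        if item and "=" in item:
            k, v = item.split("=", 1)
            out[k] = v
    return out


def read_modifications_gff(
    path: str | Path,
    replicate_id: str | None = None,
    genome_length: int | None = None,
) -> ReplicateModSet:
    """Read a PacBio-style modifications GFF3 into a ReplicateModSet.

    Coordinates are converted from 1-based inclusive to 0-based.  Unknown
    feature types are kept as ``modified_base`` with a warning; lines with
    bad coordinates are rejected.
    """
    path = Path(path)
    calls: list[SiteModCall] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns, got {len(fields)}")
            ref, _source, mod_type, start_s, end_s, score_s, strand, _phase, attr_s = fields
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start1 < 1 or end1 < start1:
                raise ValueError(f"{path}:{lineno}: bad coordinate range {start1}-{end1}")
            if strand not in "+-":
                raise ValueError(f"{path}:{lineno}: bad strand {strand!r}")
            if mod_type not in GFF_TYPES:
                warnings.warn(f"{path}:{lineno}: unknown type {mod_type!r}; kept as modified_base")
                mod_type = "modified_base"
            attrs = _parse_gff_attributes(attr_s)
            frac = float(attrs["frac"]) if "frac" in attrs else None
            calls.append(
                SiteModCall(
                    ref_id=ref,
                    position=start1 - 1,
                    strand=strand,
                    base={"m6A": "A", "m4C": "C"}.get(mod_type, "N"),
                    ipd_ratio=float(attrs.get("IPDRatio", "nan")),
                    mod_qv=int(round(float(score_s))),
                    coverage=int(attrs.get("coverage", 0)),
                    methyl_frac=frac,
                    frac_low=float(attrs["fracLow"]) if "fracLow" in attrs else None,
                    frac_up=float(attrs["fracUp"]) if "fracUp" in attrs else None,
                    mod_type=mod_type,
                )
            )
    return ReplicateModSet.from_calls(
        replicate_id or path.stem, calls, genome_length=genome_length
    )


def read_modifications_csv(
    path: str | Path,
    replicate_id: str | None = None,
    genome_length: int | None = None,
) -> ReplicateModSet:
    """Read a per-strand-position modifications CSV into a ReplicateModSet."""
    path = Path(path)
    table = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(
            f"{path}: header mismatch; missing columns {missing}, found {list(table.columns)}"
        )
    if not set(table["strand"].unique()) <= {0, 1}:
        bad = sorted(set(table["strand"].unique()) - {0, 1})
        raise ValueError(f"{path}: strand must be 0 (+) or 1 (-), found {bad}")
    dupes = table.duplicated(subset=["tpl", "strand"])
    if dupes.any():
        first = table.loc[dupes, ["tpl", "strand"]].iloc[0]
        raise ValueError(
            f"{path}: duplicate (position, strand) row at tpl={int(first['tpl'])}, "
            f"strand={int(first['strand'])}"
        )
    index = pd.MultiIndex.from_arrays(
        [
            table["tpl"].to_numpy(dtype=np.int64) - 1,
            np.where(table["strand"].to_numpy() == 0, "+", "-").astype(object),
        ],
        names=("position", "strand"),
    )
    frame = pd.DataFrame(
        {
            "base": table["base"].astype(str).to_numpy(dtype=object),
            "ipd_ratio": table["ipdRatio"].to_numpy(dtype=float),
            "mod_qv": table["score"].to_numpy(dtype=float),
            "coverage": table["coverage"].to_numpy(dtype=float),
            "methyl_frac": np.nan,
            "frac_low": np.nan,
            "frac_up": np.nan,
            "mod_type": "none",
        },
        index=index,
    )
    ref_id = str(table["refName"].iloc[0]) if len(table) else "ref"
    return ReplicateModSet(
        replicate_id or path.stem, frame, genome_length=genome_length, ref_id=ref_id
    )


def merge_modsets(csv_set: ReplicateModSet, gff_set: ReplicateModSet) -> ReplicateModSet:
    """Merge a per-position CSV set with a called-sites GFF set.

    The CSV supplies per-position kinetics for every strand-position; the GFF
    overrides QV/frac/mod_type at called sites and contributes any site
    missing from the CSV.
    """
    union = csv_set.frame.index.union(gff_set.frame.index)
    frame = csv_set.frame.reindex(union)
    only_gff = union.difference(csv_set.frame.index)
    if len(only_gff):
        frame.loc[only_gff] = gff_set.frame.loc[only_gff]
    gi = gff_set.frame.index
    for col in ("methyl_frac", "frac_low", "frac_up", "mod_type", "mod_qv"):
        frame.loc[gi, col] = gff_set.frame[col].to_numpy()
    return ReplicateModSet(
        csv_set.replicate_id,
        frame,
        genome_length=csv_set.genome_length or gff_set.genome_length,
        ref_id=csv_set.ref_id,
    )


def high_ipd_summary(
    modset: ReplicateModSet,
    threshold: float = 2.0,
    motif_adenine_count: int | None = None,
) -> ModSummary:
    """Census of strand-positions with ipdRatio strictly above ``threshold``.

    The fraction denominator is 2 × genome length (both strands, N positions
    included); the genome length must therefore be known.
    """
    if modset.genome_length is None:
        raise ValueError("genome_length unknown; high_ipd_summary needs it for the denominator")
    ipd = modset.frame["ipd_ratio"].to_numpy()
    high = int(np.sum(ipd > threshold))
    strand_positions = 2 * modset.genome_length
    return ModSummary(
        high_ipd_count=high,
        strand_positions=strand_positions,
        high_ipd_fraction=high / strand_positions,
        threshold=threshold,
        motif_adenine_count=motif_adenine_count,
        fold_excess=fold_excess(high, motif_adenine_count)
        if motif_adenine_count
        else None,
    )


def fold_excess(high_count: int, motif_adenine_count: int) -> float | None:
    """High-ipd sites per motif adenine, reported to one decimal.

    Returns ``None`` (undefined sentinel) for a zero denominator.
    """
    if motif_adenine_count == 0:
        return None
    return round(high_count / motif_adenine_count, 1)


def qv_to_pvalue(qv: float) -> float:
    """Phred-scaled QV to p-value: p = 10^(-qv/10)."""
    if qv < 0:
        raise ValueError(f"qv must be >= 0, got {qv}")
    return 10.0 ** (-qv / 10.0)


def pvalue_to_qv(p: float) -> float:
    """p-value to Phred-scaled QV: qv = -10 log10 p."""
    if not 0.0 < p <= 1.0:
        raise ValueError(f"p must lie in (0, 1], got {p}")
    return -10.0 * math.log10(p)


def target_adenine_positions(
    loci: Sequence[PalindromeLocus],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Strand-resolved target adenine coordinates of GATC/CATG loci.

    For both motifs the ``+`` strand adenine sits at start+1 and the ``-``
    strand adenine (complement of the forward-strand T) is reported at
    start+2 — one target adenine per strand of each palindrome.

    Returns (positions, strands, locus_ids) with the two strand-sites of a
    locus adjacent (+ before -).
    """
    n = len(loci)
    positions = np.empty(2 * n, dtype=np.int64)
    strands = np.empty(2 * n, dtype=object)
    locus_ids = np.empty(2 * n, dtype=np.int64)
    for i, locus in enumerate(loci):
        positions[2 * i] = locus.start + 1
        strands[2 * i] = "+"
        positions[2 * i + 1] = locus.start + 2
        strands[2 * i + 1] = "-"
        locus_ids[2 * i] = locus.locus_id
        locus_ids[2 * i + 1] = locus.locus_id
    return positions, strands, locus_ids


def motif_methylation_calls(
    modset: ReplicateModSet,
    loci: Sequence[PalindromeLocus],
    genome: GenomeSequence | None = None,
    qv_threshold: float = 30.0,
) -> MotifCallSummary:
    """Call each motif strand-site methylated iff a call with QV >= threshold
    exists at its target adenine.

    Only the strand-resolved adenine coordinates are ever queried, so calls
    at non-adenine motif bases can never be counted.  When ``genome`` is
    given, the fraction of the total adenine pool that is methylated
    (denominator: forward-strand A count + forward-strand T count) is
    reported as well.
    """
    positions, strands, locus_ids = target_adenine_positions(loci)
    length = modset.genome_length or (genome.length if genome else None)
    if length is not None and positions.size and int(positions.max()) >= length:
        raise ValueError(
            f"locus adenine position {int(positions.max())} outside genome of length {length}"
        )
    qv = modset.qv_lookup(positions, strands)
    methylated = np.nan_to_num(qv, nan=-1.0) >= qv_threshold
    by_site = {
        (int(lid), str(s)): bool(m) for lid, s, m in zip(locus_ids, strands, methylated)
    }
    motifs = np.array([l.motif for l in loci for _ in range(2)], dtype=object)
    fraction_by_motif = {}
    for motif in sorted(set(l.motif for l in loci)):
        mask = motifs == motif
        fraction_by_motif[motif] = float(methylated[mask].mean()) if mask.any() else float("nan")
    n_meth = int(methylated.sum())
    adenine_fraction = None
    if genome is not None:
        pool = genome.adenine_count_fwd + genome.thymine_count_fwd
        adenine_fraction = n_meth / pool if pool else None
    return MotifCallSummary(
        fraction_by_motif=fraction_by_motif,
        methylated_by_site=by_site,
        n_methylated=n_meth,
        n_strand_sites=int(positions.size),
        adenine_fraction_methylated=adenine_fraction,
    )
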