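"""Seeded generator of genomes and replicate modification files with planted truth.

The generator exists so that every pipeline stage is testable without any
download: it emits a genome FASTA (i.i.d. composition at a target GC, with
optional planted motif-free gaps and motif-enriched windows) and, per
replicate, PacBio-style modification GFF3/CSV files whose per-site evidence
is drawn from a binomial read-sampling model around planted methylation
states.

Two planting modes are supported:

``palindrome``
    each locus draws a two-strand state (fully / hemi / stochastic); the
    latent per-replicate methylation of each strand follows (fully: always
    methylated on both strands; hemi: one strand always, the other never;
    stochastic: an independent fair coin per strand and replicate);
``strand``
    each strand-site directly draws the number k of replicates in which it
    is methylated, from the configured stability proportions.

Ground truth records both the drawn labels and the *implied* classes — the
classification a noise-free observer of the latent draws would produce —
because a stochastic locus can legitimately come up methylated in all three
replicates of one strand and then *is* hemimethylated in the emitted data.
Recovery tests compare against the implied classes.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.stats import truncnorm

from methylstab.genome_motifs import (
    DEFAULT_MOTIFS,
    GenomeSequence,
    PalindromeLocus,
    loci_to_bed,
    scan_motifs,
)
from methylstab.modcalls import ReplicateModSet, target_adenine_positions
from methylstab.palindromes import FULLY_METHYLATED, HEMIMETHYLATED, STOCHASTIC
from methylstab.stability import class_for_k

_MOTIF_BYTES = (b"GATC", b"CATG")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class SimulationConfig:
    """All knobs of the synthetic genome + replicate generator.

    Defaults mirror the real system under study: a 330,611 bp genome at 40%
    GC, three replicates at 30x coverage, palindrome states split
    0.619/0.31/0.071 and strand stability classes 0.807/0.131/0.041/0.021
    (k = 3, 2, 1, 0 methylated replicates).
    """

    genome_length: int = 330_611
    gc: float = 0.4
    seed: int = 0
    n_replicates: int = 3
    coverage: int = 30
    palindrome_state_proportions: tuple[float, ...] = (0.619, 0.31, 0.071)
    strand_stability_proportions: tuple[float, ...] = (0.807, 0.131, 0.041, 0.021)
    pi_meth: float = 0.97
    pi_un: float = 0.02
    background_high_ipd_prob: float = 0.09
    planted_gap_length: int | None = None
    planted_gap_start: int | None = None
    planted_window_loci: int | None = None
    planted_window_start: int | None = None
    planted_window_size: int = 278
    planted_zero_loci: int = 0
    qv_meth_base: int = 30
    qv_jitter_p: float = 0.25
    qv_unmeth_max: int = 20
    ipd_meth_mean: float = 4.0
    ipd_meth_sd: float = 0.8
    ipd_unmeth_mean: float = 1.0
    ipd_unmeth_sd: float = 0.25

    def __post_init__(self) -> None:
        for name in ("palindrome_state_proportions", "strand_stability_proportions"):
            props = tuple(getattr(self, name))
            setattr(self, name, props)
            if abs(sum(props) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1, got {sum(props)!r}")
            if any(p < 0 for p in props):
                raise ValueError(f"{name} must be nonnegative")
        if not 0.0 <= self.pi_un < self.pi_meth <= 1.0:
            raise ValueError(
                f"need 0 <= pi_un < pi_meth <= 1, got pi_un={self.pi_un}, pi_meth={self.pi_meth}"
            )
        if not 0.0 <= self.gc <= 1.0:
            raise ValueError(f"gc must lie in [0, 1], got {self.gc}")
        if self.coverage <= 0:
            raise ValueError(f"coverage must be positive, got {self.coverage}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["palindrome_state_proportions"] = list(self.palindrome_state_proportions)
        data["strand_stability_proportions"] = list(self.strand_stability_proportions)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


@dataclass
class GroundTruth:
    """What the generator planted, for recovery tests.

    ``drawn_states`` are the sampled palindrome labels; ``states`` and
    ``strand_classes`` are the classes implied by the latent per-replicate
    methylation draws (what a perfect pipeline recovers).
    """

    gap: tuple[int, int] | None = None
    window: tuple[int, int, int] | None = None  # (start, end, planted locus count)
    drawn_states: dict[int, str] = field(default_factory=dict)
    states: dict[int, str] = field(default_factory=dict)
    strand_classes: dict[tuple[int, str], str] = field(default_factory=dict)
    latent: dict[tuple[int, str], tuple[bool, ...]] = field(default_factory=dict)
    zero_loci: list[int] = field(default_factory=list)


def _scrub_motifs(ba: bytearray, lo: int, hi: int, protected: frozenset[int]) -> None:
    """Mutate bases until no GATC/CATG starts in [lo, hi).

    Offending motifs are broken at their first base not inside a protected
    (planted) span; mutation loops because a substitution can create a new
    overlapping occurrence.
    """
    lo = max(lo, 0)
    hi = min(hi, len(ba))
    while True:
        dirty = False
        for motif in _MOTIF_BYTES:
            i = ba.find(motif, max(lo - 3, 0))
            while 0 <= i < hi:
                if lo <= i and i not in protected:
                    for j in range(i, i + 4):
                        if j not in protected:
                            ba[j] = ord("G") if ba[j] == ord("T") else ord("T")
                            break
                    dirty = True
                i = ba.find(motif, i + 1)
        if not dirty:
            return


def simulate_genome(config: SimulationConfig) -> tuple[GenomeSequence, GroundTruth]:
    """Draw an i.i.d. genome at the configured GC; plant optional features.

    A planted gap of length ``planted_gap_length`` is bounded by GATC
    occurrences on both sides and contains no motif 4-mer, so a scanner
    recovers exactly that gap.  A planted window rewrites a
    ``planted_window_size`` span to contain exactly ``planted_window_loci``
    GATC loci wholly inside it.
    """
    rng = np.random.default_rng(config.seed)
    L = config.genome_length
    p_s, p_w = config.gc / 2.0, (1.0 - config.gc) / 2.0
    lut = np.frombuffer(b"GCAT", dtype=np.uint8)
    idx = rng.choice(4, size=L, p=[p_s, p_s, p_w, p_w])
    ba = bytearray(lut[idx].tobytes())
    truth = GroundTruth()

    if config.planted_gap_length is not None:
        gap_len = config.planted_gap_length
        g0 = config.planted_gap_start if config.planted_gap_start is not None else L // 3
        a, b = g0 - 4, g0 + gap_len
        if a < 0 or b + 4 > L:
            raise ValueError(
                f"planted gap [{g0}, {g0 + gap_len}) with bounding motifs exceeds genome of length {L}"
            )
        ba[a : a + 4] = b"GATC"
        ba[b : b + 4] = b"GATC"
        protected = frozenset(range(a, a + 4)) | frozenset(range(b, b + 4))
        _scrub_motifs(ba, a + 1, b, protected)
        truth.gap = (g0, g0 + gap_len)

    if config.planted_window_loci is not None:
        k = config.planted_window_loci
        w = config.planted_window_size
        wstart = (
            config.planted_window_start
            if config.planted_window_start is not None
            else 2 * L // 3
        )
        if wstart < 0 or wstart + w > L:
            raise ValueError(f"planted window [{wstart}, {wstart + w}) exceeds genome of length {L}")
        if k * 4 > w:
            raise ValueError(f"cannot fit {k} non-overlapping 4-mers in a {w} bp window")
        starts = np.unique(np.linspace(wstart, wstart + w - 4, max(k, 1)).astype(int))[:k]
        protected_w = frozenset(j for s in starts for j in range(s, s + 4))
        for s in starts:
            ba[s : s + 4] = b"GATC"
        _scrub_motifs(ba, wstart, wstart + w - 3, protected_w)
        truth.window = (int(wstart), int(wstart + w), k)

    genome = GenomeSequence.from_sequence(f"synthetic_seed{config.seed}", ba.decode())
    return genome, truth


def _assign_latent(
    n_loci: int, config: SimulationConfig, mode: str, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Latent methylation matrix M[locus, strand, replicate] plus drawn labels."""
    R = config.n_replicates
    M = np.zeros((n_loci, 2, R), dtype=bool)
    drawn = np.empty(n_loci, dtype=object)
    if mode == "palindrome":
        probs = config.palindrome_state_proportions
        if len(probs) != 3:
            raise ValueError("palindrome_state_proportions must have 3 entries (fully, hemi, stochastic)")
        state_idx = rng.choice(3, size=n_loci, p=probs)
        labels = np.array([FULLY_METHYLATED, HEMIMETHYLATED, STOCHASTIC], dtype=object)
        drawn[:] = labels[state_idx]
        M[state_idx == 0] = True
        hemi = np.flatnonzero(state_idx == 1)
        hemi_strand = rng.integers(0, 2, size=hemi.size)
        M[hemi, hemi_strand, :] = True
        stoch = np.flatnonzero(state_idx == 2)
        M[stoch] = rng.random((stoch.size, 2, R)) < 0.5
    elif mode == "strand":
        probs = config.strand_stability_proportions
        if len(probs) != R + 1:
            raise ValueError(
                f"strand_stability_proportions needs {R + 1} entries (k = {R}..0) "
                f"for {R} replicates, got {len(probs)}"
            )
        k = rng.choice(np.arange(R, -1, -1), size=(n_loci, 2), p=probs)
        scores = rng.random((n_loci, 2, R))
        ranks = scores.argsort(axis=2).argsort(axis=2)
        M = ranks < k[..., None]
        drawn[:] = None
    else:
        raise ValueError(f"unknown planting mode {mode!r}")
    return M, drawn


def _trunc_normal(
    rng: np.random.Generator, mean: float, sd: float, lower: float, size: int
) -> np.ndarray:
    a = (lower - mean) / sd
    return truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size, random_state=rng)


def simulate_replicates(
    genome: GenomeSequence,
    loci: Sequence[PalindromeLocus],
    config: SimulationConfig,
    mode: str = "palindrome",
    include_background: bool = False,
    truth: GroundTruth | None = None,
) -> tuple[list[ReplicateModSet], GroundTruth]:
    """Emit per-replicate modification evidence around planted latent states.

    Per strand-site and replicate: methylFrac ~ Binomial(coverage, pi)/coverage
    with pi = pi_meth when the latent draw is methylated and pi_un otherwise;
    the QV is >= 30 (base + geometric jitter) iff the latent draw is
    methylated, else a uniform integer in [0, qv_unmeth_max]; ipdRatio is a
    truncated normal around 4.0 (methylated, lower bound 2) or 1.0.  When
    ``include_background`` is set, every non-motif strand-position gets a CSV
    row, high-ipd (uniform 2-6) with probability ``background_high_ipd_prob``.

    ``planted_zero_loci`` randomly chosen loci are forced to zero methylated
    reads on both strands in every replicate (stably non-methylated truth).
    """
    if config.coverage <= 0:
        raise ValueError("coverage must be positive")
    truth = truth or GroundTruth()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n = len(loci)
    R = config.n_replicates
    cov = config.coverage

    M, drawn = _assign_latent(n, config, mode, rng)

    zero_idx = np.array([], dtype=np.int64)
    if config.planted_zero_loci:
        if config.planted_zero_loci > n:
            raise ValueError(
                f"cannot plant {config.planted_zero_loci} zero loci among {n} loci"
            )
        zero_idx = rng.choice(n, size=config.planted_zero_loci, replace=False)
        M[zero_idx] = False

    pi = np.where(M, config.pi_meth, config.pi_un)
    pi[zero_idx, :, :] = 0.0

    # Ground truth: latent draws plus the classes they imply.
    k_latent = M.sum(axis=2)
    strand_mean_pi = pi.mean(axis=2)
    for i, locus in enumerate(loci):
        lid = locus.locus_id
        if drawn[i] is not None:
            truth.drawn_states[lid] = drawn[i]
        fwd_high = strand_mean_pi[i, 0] > 0.75
        rev_high = strand_mean_pi[i, 1] > 0.75
        if fwd_high and rev_high:
            truth.states[lid] = FULLY_METHYLATED
        elif fwd_high or rev_high:
            truth.states[lid] = HEMIMETHYLATED
        else:
            truth.states[lid] = STOCHASTIC
        for j, strand in enumerate(("+", "-")):
            truth.strand_classes[(lid, strand)] = class_for_k(int(k_latent[i, j]), R)
            truth.latent[(lid, strand)] = tuple(bool(x) for x in M[i, j])
    truth.zero_loci = sorted(loci[i].locus_id for i in zero_idx)

    positions, strands, _ = target_adenine_positions(loci)

    replicates: list[ReplicateModSet] = []
    seq_chars = comp_chars = None
    if include_background:
        seq_chars = np.array(list(genome.sequence), dtype=object)
        comp_chars = np.array(list(genome.sequence.translate(_COMPLEMENT)), dtype=object)

    for r in range(R):
        m = M[:, :, r].reshape(-1)  # locus-major, + before -
        p = pi[:, :, r].reshape(-1)
        frac = np.round(rng.binomial(cov, p) / cov, 6)
        qv_meth = config.qv_meth_base + rng.geometric(config.qv_jitter_p, size=m.size) - 1
        qv_un = rng.integers(0, config.qv_unmeth_max + 1, size=m.size)
        qv = np.where(m, qv_meth, qv_un)
        ipd_meth = _trunc_normal(rng, config.ipd_meth_mean, config.ipd_meth_sd, 2.0, m.size)
        ipd_un = _trunc_normal(rng, config.ipd_unmeth_mean, config.ipd_unmeth_sd, 0.0, m.size)
        ipd = np.round(np.where(m, ipd_meth, ipd_un), 3)
        half = 1.96 * np.sqrt(frac * (1.0 - frac) / cov)
        frac_low = np.round(np.clip(frac - half, 0.0, 1.0), 6)
        frac_up = np.round(np.clip(frac + half, 0.0, 1.0), 6)

        index = pd.MultiIndex.from_arrays([positions, strands], names=("position", "strand"))
        frame = pd.DataFrame(
            {
                "base": "A",
                "ipd_ratio": ipd,
                "mod_qv": qv.astype(float),
                "coverage": float(cov),
                "methyl_frac": frac,
                "frac_low": frac_low,
                "frac_up": frac_up,
                "mod_type": np.where(qv >= 30, "m6A", "none").astype(object),
            },
            index=index,
        )

        if include_background:
            L = genome.length
            occ_plus = np.zeros(L, dtype=bool)
            occ_plus[positions[strands == "+"]] = True
            occ_minus = np.zeros(L, dtype=bool)
            occ_minus[positions[strands == "-"]] = True
            bg_plus = np.flatnonzero(~occ_plus)
            bg_minus = np.flatnonzero(~occ_minus)
            n_bg = bg_plus.size + bg_minus.size
            high = rng.random(n_bg) < config.background_high_ipd_prob
            ipd_bg = np.where(
                high,
                rng.uniform(2.0, 6.0, n_bg),
                _trunc_normal(rng, config.ipd_unmeth_mean, config.ipd_unmeth_sd, 0.0, n_bg),
            )
            bg_index = pd.MultiIndex.from_arrays(
                [
                    np.concatenate([bg_plus, bg_minus]),
                    np.concatenate(
                        [np.full(bg_plus.size, "+", object), np.full(bg_minus.size, "-", object)]
                    ),
                ],
                names=("position", "strand"),
            )
            bg_frame = pd.DataFrame(
                {
                    "base": np.concatenate([seq_chars[bg_plus], comp_chars[bg_minus]]),
                    "ipd_ratio": np.round(ipd_bg, 3),
                    "mod_qv": rng.integers(0, config.qv_unmeth_max + 1, n_bg).astype(float),
                    "coverage": float(cov),
                    "methyl_frac": np.nan,
                    "frac_low": np.nan,
                    "frac_up": np.nan,
                    "mod_type": "none",
                },
                index=bg_index,
            )
            frame = pd.concat([frame, bg_frame])

        replicates.append(
            ReplicateModSet(
                replicate_id=f"rep{r + 1}",
                frame=frame,
                genome_length=genome.length,
                ref_id=genome.id,
            )
        )
    return replicates, truth


def write_pacbio_gff(
    modset: ReplicateModSet, path: str | Path, min_qv: float | None = 30.0
) -> None:
    """Write called sites in the modifications-GFF3 dialect (1-based inclusive).

    By default only calls with QV >= 30 are written, matching the upstream
    tool's called-sites file; pass ``min_qv=None`` to write every record.
    """
    frame = modset.frame
    if min_qv is not None:
        frame = frame[frame["mod_qv"] >= min_qv]
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##source methylstab synthetic replicate {modset.replicate_id}\n")
        for (position, strand), row in frame.iterrows():
            attrs = [f"coverage={int(row['coverage'])}", f"IPDRatio={row['ipd_ratio']!r}"]
            if not pd.isna(row["methyl_frac"]):
                attrs.append(f"frac={row['methyl_frac']!r}")
                attrs.append(f"fracLow={row['frac_low']!r}")
                attrs.append(f"fracUp={row['frac_up']!r}")
            mod_type = row["mod_type"] if row["mod_type"] != "none" else "modified_base"
            fh.write(
                f"{modset.ref_id}\tkinModCall\t{mod_type}\t{position + 1}\t{position + 1}\t"
                f"{int(row['mod_qv'])}\t{strand}\t.\t{';'.join(attrs)}\n"
            )


def write_modifications_csv(modset: ReplicateModSet, path: str | Path) -> None:
    """Write every record in the per-strand-position modifications CSV dialect."""
    frame = modset.frame
    positions = frame.index.get_level_values("position").to_numpy()
    strands = frame.index.get_level_values("strand").to_numpy()
    out = pd.DataFrame(
        {
            "refName": modset.ref_id,
            "tpl": positions + 1,
            "strand": np.where(strands == "+", 0, 1),
            "base": frame["base"].to_numpy(),
            "score": frame["mod_qv"].to_numpy(dtype=int),
            "ipdRatio": frame["ipd_ratio"].to_numpy(),
            "coverage": frame["coverage"].to_numpy(dtype=int),
        }
    )
    out.to_csv(path, index=False)


def write_genome_fasta(genome: GenomeSequence, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(f">{genome.id}\n")
        for i in range(0, genome.length, width):
            fh.write(genome.sequence[i : i + width] + "\n")


def write_truth_tsv(truth: GroundTruth, loci: Sequence[PalindromeLocus], path: str | Path) -> None:
    """Planted per-locus states and per-strand classes as a flat table."""
    with open(path, "w") as fh:
        fh.write(
            "locus_id\tmotif\tstart\tdrawn_state\timplied_state\t"
            "fwd_class\trev_class\tplanted_zero\n"
        )
        zero = set(truth.zero_loci)
        for locus in loci:
            lid = locus.locus_id
            fh.write(
                f"{lid}\t{locus.motif}\t{locus.start}\t"
                f"{truth.drawn_states.get(lid, '')}\t{truth.states.get(lid, '')}\t"
                f"{truth.strand_classes.get((lid, '+'), '')}\t"
                f"{truth.strand_classes.get((lid, '-'), '')}\t{int(lid in zero)}\n"
            )


def simulate_to_dir(
    config: SimulationConfig, outdir: str | Path, mode: str = "palindrome"
) -> dict[str, Path]:
    """End-to-end simulation writing genome.fa, per-replicate GFF/CSV and truth.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, truth = simulate_genome(config)
    loci = scan_motifs(genome, DEFAULT_MOTIFS)
    replicates, truth = simulate_replicates(
        genome, loci, config, mode=mode, include_background=True, truth=truth
    )
    paths: dict[str, Path] = {"genome": outdir / "genome.fa", "truth": outdir / "truth.tsv",
                              "loci": outdir / "loci.bed"}
    write_genome_fasta(genome, paths["genome"])
    loci_to_bed(loci, paths["loci"], chrom=genome.id)
    write_truth_tsv(truth, loci, paths["truth"])
    for i, rep in enumerate(replicates, start=1):
        gff = outdir / f"rep{i}.modifications.gff"
        csv = outdir / f"rep{i}.modifications.csv"
        write_pacbio_gff(rep, gff, min_qv=30.0)
        write_modifications_csv(rep, csv)
        paths[f"rep{i}.gff"] = gff
        paths[f"rep{i}.csv"] = csv
    return paths
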