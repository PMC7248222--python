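"""Tests for the PacBio-style readers, thresholds and genome-wide summaries."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from methylstab.genome_motifs import GenomeSequence, scan_motifs
from methylstab.modcalls import (
    ReplicateModSet,
    SiteModCall,
    fold_excess,
    high_ipd_summary,
    merge_modsets,
    motif_methylation_calls,
    pvalue_to_qv,
    qv_to_pvalue,
    read_modifications_csv,
    read_modifications_gff,
    target_adenine_positions,
)

GFF_LINE = "chr1\tkinModCall\tm6A\t10\t10\t41\t+\t.\tcoverage=30;IPDRatio=4.10;frac=0.97;fracLow=0.9;fracUp=1.0"


def _write_gff(tmp_path, lines, name="mods.gff"):
    p = tmp_path / name
    p.write_text("##gff-version 3\n" + "\n".join(lines) + ("\n" if lines else ""))
    return p


def _write_csv(tmp_path, rows, name="mods.csv"):
    p = tmp_path / name
    header = "refName,tpl,strand,base,score,ipdRatio,coverage"
    p.write_text(header + "\n" + "\n".join(rows) + ("\n" if rows else ""))
    return p


class TestReadGff:
    def test_dialect_fixture(self, tmp_path):
        ms = read_modifications_gff(_write_gff(tmp_path, [GFF_LINE]))
        call = ms.get(9, "+")
        assert call is not None
        assert call.position == 9
        assert call.strand == "+"
        assert call.mod_qv == 41
        assert call.methyl_frac == 0.97
        assert call.ipd_ratio == 4.10
        assert call.coverage == 30
        assert call.mod_type == "m6A"

    def test_empty_file(self, tmp_path):
        ms = read_modifications_gff(_write_gff(tmp_path, []))
        assert len(ms) == 0

    def test_missing_frac_stays_absent(self, tmp_path):
        line = "chr1\tkinModCall\tm6A\t5\t5\t35\t-\t.\tcoverage=30;IPDRatio=3.2"
        ms = read_modifications_gff(_write_gff(tmp_path, [line]))
        assert ms.get(4, "-").methyl_frac is None

    def test_unknown_type_kept_as_modified_base_with_warning(self, tmp_path):
        line = "chr1\tkinModCall\tm5C\t5\t5\t35\t+\t.\tcoverage=30;IPDRatio=3.2"
        with pytest.warns(UserWarning, match="m5C"):
            ms = read_modifications_gff(_write_gff(tmp_path, [line]))
        assert ms.get(4, "+").mod_type == "modified_base"

    def test_bad_coordinates_rejected(self, tmp_path):
        line = "chr1\tkinModCall\tm6A\t0\t0\t35\t+\t.\tcoverage=30;IPDRatio=3.2"
        with pytest.raises(ValueError, match="coordinate"):
            read_modifications_gff(_write_gff(tmp_path, [line]))


class TestReadCsv:
    def test_ten_row_fixture_and_strand_mapping(self, tmp_path):
        rows = [f"ref,{i + 1},{i % 2},A,20,1.0,30" for i in range(10)]
        ms = read_modifications_csv(_write_csv(tmp_path, rows))
        assert len(ms) == 10
        assert ms.get(0, "+") is not None  # strand 0 -> +
        assert ms.get(1, "-") is not None  # strand 1 -> -

    def test_tpl_one_is_position_zero(self, tmp_path):
        ms = read_modifications_csv(_write_csv(tmp_path, ["ref,1,0,A,20,1.0,30"]))
        assert ms.get(0, "+") is not None

    def test_duplicate_key_rejected_with_key(self, tmp_path):
        rows = ["ref,5,0,A,20,1.0,30", "ref,5,0,A,21,1.1,30"]
        with pytest.raises(ValueError, match="tpl=5"):
            read_modifications_csv(_write_csv(tmp_path, rows))

    def test_header_mismatch_reports_columns(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("refName,tpl,strand,base,score\nref,1,0,A,20\n")
        with pytest.raises(ValueError, match="ipdRatio"):
            read_modifications_csv(p)

    def test_bad_strand_value_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="strand"):
            read_modifications_csv(_write_csv(tmp_path, ["ref,1,2,A,20,1.0,30"]))


class TestMerge:
    def test_gff_overrides_called_sites(self, tmp_path):
        csv = read_modifications_csv(
            _write_csv(tmp_path, ["ref,10,0,A,20,4.1,30", "ref,11,0,C,5,1.0,30"])
        )
        gff = read_modifications_gff(_write_gff(tmp_path, [GFF_LINE]))
        merged = merge_modsets(csv, gff)
        call = merged.get(9, "+")
        assert call.methyl_frac == 0.97
        assert call.mod_qv == 41
        assert call.ipd_ratio == 4.1  # CSV kinetics preserved
        assert merged.get(10, "+").mod_qv == 5  # untouched CSV-only site

    def test_gff_only_sites_added(self, tmp_path):
        csv = read_modifications_csv(_write_csv(tmp_path, ["ref,2,0,A,5,1.0,30"]))
        gff = read_modifications_gff(_write_gff(tmp_path, [GFF_LINE]))
        merged = merge_modsets(csv, gff)
        assert len(merged) == 2
        assert merged.get(9, "+").mod_type == "m6A"


class TestHighIpd:
    def _modset(self, ipds, genome_length):
        calls = [
            SiteModCall("ref", i // 2, "+" if i % 2 == 0 else "-", "A", ipd, 10, 30)
            for i, ipd in enumerate(ipds)
        ]
        return ReplicateModSet.from_calls("r", calls, genome_length=genome_length)

    def test_fixture_count_and_fraction(self):
        ipds = [2.5, 2.5, 2.5, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0]
        s = high_ipd_summary(self._modset(ipds, genome_length=5))
        assert s.high_ipd_count == 3
        assert s.high_ipd_fraction == pytest.approx(0.3)

    def test_all_unmodified(self):
        s = high_ipd_summary(self._modset([1.0] * 10, genome_length=5))
        assert s.high_ipd_count == 0

    def test_threshold_is_strict(self):
        s = high_ipd_summary(self._modset([2.0, 2.0001], genome_length=1))
        assert s.high_ipd_count == 1

    def test_monotone_in_threshold(self):
        ms = self._modset([0.5, 1.5, 2.5, 3.5, 4.5, 5.5], genome_length=3)
        counts = [high_ipd_summary(ms, threshold=t).high_ipd_count for t in (0, 1, 2, 3, 4, 5)]
        assert counts == sorted(counts, reverse=True)

    def test_unknown_genome_length_rejected(self):
        calls = [SiteModCall("ref", 0, "+", "A", 3.0, 10, 30)]
        ms = ReplicateModSet.from_calls("r", calls)
        with pytest.raises(ValueError, match="genome_length"):
            high_ipd_summary(ms)


class TestFoldExcess:
    def test_published_arithmetic(self):
        assert fold_excess(72_170, 3_498) == 20.6

    def test_equal_counts(self):
        assert fold_excess(100, 100) == 1.0

    def test_hand_arithmetic(self):
        assert fold_excess(100, 4) == 25.0

    def test_zero_denominator_sentinel(self):
        assert fold_excess(10, 0) is None


class TestQvPvalue:
    def test_qv30_is_p001(self):
        assert qv_to_pvalue(30) == pytest.approx(0.001)

    def test_qv0_is_one(self):
        assert qv_to_pvalue(0) == 1.0

    def test_qv20_closed_form(self):
        assert qv_to_pvalue(20) == pytest.approx(0.01)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            qv_to_pvalue(-1)
        with pytest.raises(ValueError):
            pvalue_to_qv(0.0)
        with pytest.raises(ValueError):
            pvalue_to_qv(1.5)

    @given(st.floats(min_value=0.0, max_value=200.0))
    def test_inverse_round_trip(self, qv):
        assert pvalue_to_qv(qv_to_pvalue(qv)) == pytest.approx(qv, abs=1e-12)


class TestMotifMethylationCalls:
    def _make(self, seq, qv_by_site):
        g = GenomeSequence.from_sequence("x", seq)
        loci = scan_motifs(g)
        positions, strands, _ = target_adenine_positions(loci)
        calls = [
            SiteModCall("x", int(p), str(s), "A", 4.0, qv, 30, methyl_frac=0.9)
            for (p, s), qv in zip(zip(positions, strands), qv_by_site)
        ]
        return g, loci, ReplicateModSet.from_calls("r", calls, genome_length=g.length)

    def test_all_high_qv_gives_full_call(self, toy_genome):
        g, loci, ms = self._make("AAGATCAACATGAA", [41, 41, 41, 41])
        res = motif_methylation_calls(ms, loci, genome=g)
        assert res.fraction_by_motif == {"CATG": 1.0, "GATC": 1.0}
        assert res.n_methylated == 4

    def test_three_of_four_catg_sites(self):
        # two CATG loci -> 4 strand-sites; one below threshold -> 75%
        g, loci, ms = self._make("CCATGCCCATGCC", [41, 41, 41, 10])
        res = motif_methylation_calls(ms, loci, genome=g)
        assert res.fraction_by_motif["CATG"] == pytest.approx(0.75)

    def test_threshold_is_inclusive(self):
        g, loci, ms = self._make("CCATGCC", [30, 29])
        res = motif_methylation_calls(ms, loci)
        assert res.fraction_by_motif["CATG"] == pytest.approx(0.5)

    def test_absent_call_not_methylated(self):
        g = GenomeSequence.from_sequence("x", "CCATGCC")
        loci = scan_motifs(g)
        ms = ReplicateModSet.from_calls("r", [], genome_length=g.length)
        res = motif_methylation_calls(ms, loci, genome=g)
        assert res.n_methylated == 0

    def test_adenine_pool_fraction(self):
        g, loci, ms = self._make("AAGATCAACATGAA", [41, 41, 41, 41])
        res = motif_methylation_calls(ms, loci, genome=g)
        # 4 methylated target adenines over A_fwd + T_fwd = 8 + 2
        assert res.adenine_fraction_methylated == pytest.approx(4 / 10)

    def test_out_of_range_adenine_rejected(self, toy_genome):
        loci = scan_motifs(toy_genome)  # target adenines up to position 10
        ms = ReplicateModSet.from_calls("r", [], genome_length=3)
        with pytest.raises(ValueError, match="outside genome"):
            motif_methylation_calls(ms, loci)


class TestReplicateModSet:
    def test_duplicate_key_rejected(self):
        calls = [
            SiteModCall("ref", 0, "+", "A", 1.0, 10, 30),
            SiteModCall("ref", 0, "+", "A", 2.0, 11, 30),
        ]
        with pytest.raises(ValueError, match="duplicate"):
            ReplicateModSet.from_calls("r", calls)

    def test_position_outside_genome_rejected(self):
        calls = [SiteModCall("ref", 10, "+", "A", 1.0, 10, 30)]
        with pytest.raises(ValueError, match="outside genome"):
            ReplicateModSet.from_calls("r", calls, genome_length=10)

    def test_frac_ci_ordering_enforced(self):
        with pytest.raises(ValueError, match="CI"):
            SiteModCall("ref", 0, "+", "A", 1.0, 10, 30, methyl_frac=0.5, frac_low=0.6, frac_up=0.9)

    def test_lookup_absent_is_nan(self):
        ms = ReplicateModSet.from_calls(
            "r", [SiteModCall("ref", 3, "+", "A", 1.0, 10, 30, methyl_frac=0.8, frac_low=0.6, frac_up=0.95)]
        )
        fr = ms.frac_lookup([3, 4], ["+", "+"])
        assert fr[0] == 0.8
        assert math.isnan(fr[1])
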