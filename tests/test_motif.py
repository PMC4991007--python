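"""P1BS PWM construction, exact-p scanning, promoters and the PHR1 cascade."""

import itertools
import math

import numpy as np
import pytest

from pilnc.genomics_io import BedGraphSignal, GenomicsIOError, GenomicInterval, TranscriptModel
from pilnc.motif_regulation import (
    P1BS_CONSENSUS,
    extract_promoter,
    hits_table,
    iupac_to_pwm,
    motif_count_fold_trend,
    phr1_target_cascade,
    scan_promoter,
)

ALL_8MERS = ["".join(w) for w in itertools.product("ACGT", repeat=8)]


class TestPwmConstruction:
    def test_n_position_is_uniform(self):
        pwm = iupac_to_pwm(P1BS_CONSENSUS, pseudocount=0.05)
        assert np.allclose(pwm.probs[1], [0.25, 0.25, 0.25, 0.25])
        assert np.allclose(pwm.probs[6], [0.25, 0.25, 0.25, 0.25])

    def test_pseudocount_zero_limit_concentrates_mass(self):
        pwm = iupac_to_pwm(P1BS_CONSENSUS, pseudocount=0.0)
        assert np.allclose(pwm.probs[0], [0, 0, 1, 0])  # G

    def test_invalid_iupac_symbol(self):
        with pytest.raises(GenomicsIOError, match="IUPAC"):
            iupac_to_pwm("GNXTATNC")

    def test_consensus_word_scores_maximal(self):
        pwm = iupac_to_pwm(P1BS_CONSENSUS)
        best = max(ALL_8MERS, key=pwm.word_score)
        assert pwm.word_score("GAATATTC") == pytest.approx(pwm.word_score(best))


class TestExactPValues:
    def test_dp_tail_equals_exhaustive_enumeration(self):
        """DP tail probabilities match brute-force 4^8 enumeration to 1e-9."""
        pwm = iupac_to_pwm(P1BS_CONSENSUS)
        qs = np.array([pwm.word_qscore(w) for w in ALL_8MERS])
        for q in np.unique(qs):
            enum_tail = float(np.mean(qs >= q))  # uniform background
            assert abs(pwm.tail_probability(int(q)) - enum_tail) < 1e-9

    def test_zero_pseudocount_hit_set_is_exact_consensus(self):
        pwm = iupac_to_pwm(P1BS_CONSENSUS, pseudocount=1e-12)
        hits = [w for w in ALL_8MERS if pwm.word_p_value(w) <= 1e-3]
        assert len(hits) == 16
        assert all(
            w[0] == "G" and w[2:6] == "ATAT" and w[7] == "C" for w in hits
        )
        assert pwm.word_p_value("GAATATTC") == pytest.approx(16 / 65536)


class TestScanning:
    def _promoter_with_word(self, word, upstream_of_anchor, length=2000):
        base = ("ACT" * (length // 3 + 3))[:length]
        j = length - upstream_of_anchor
        return base[:j] + word + base[j + len(word):]

    def test_table1_style_offset_convention(self):
        """A word whose most-5' base is 122 nt upstream reports offset -122."""
        pwm = iupac_to_pwm(P1BS_CONSENSUS)
        prom = self._promoter_with_word("GAATATTC", 122)
        hits = scan_promoter(pwm, prom, "AtPAP10")
        offsets = {h.offset for h in hits}
        assert offsets == {-122}
        assert {h.word for h in hits} == {"GAATATTC"}

    def test_poly_g_sequence_has_no_hits(self):
        pwm = iupac_to_pwm(P1BS_CONSENSUS)
        assert scan_promoter(pwm, "G" * 500) == []

    def test_sequence_shorter_than_motif_is_empty(self):
        pwm = iupac_to_pwm(P1BS_CONSENSUS)
        assert scan_promoter(pwm, "GAATA") == []

    def test_strand_symmetry_under_reverse_complement(self, rng):
        from pilnc.genomics_io import revcomp

        pwm = iupac_to_pwm(P1BS_CONSENSUS)
        seq = self._promoter_with_word("GCATATTC", 400, length=800)
        fwd = scan_promoter(pwm, seq)
        rev = scan_promoter(pwm, revcomp(seq))
        n = len(seq)
        # window [j, j+8) maps to [n-j-8, n-j): offset j-n maps to -j-8
        mapped = {(-(h.offset + n) - 8, {"+": "-", "-": "+"}[h.strand]) for h in fwd}
        got = {(h.offset, h.strand) for h in rev}
        assert got == mapped

    def test_planted_consensus_recovery_on_synthetic_promoters(self, small_sim):
        """Every planted P1BS occurrence is recovered at p < 1e-3."""
        pwm = iupac_to_pwm(P1BS_CONSENSUS)
        truth = small_sim.truth.transcripts
        by_id = {t.transcript_id: t for t in small_sim.annotation + small_sim.candidates}
        checked = 0
        for tid, row in truth[truth.motif_count > 0].iterrows():
            t = by_id[tid]
            mode = "ATG" if row.biotype == "protein_coding" else "TSS"
            prom = extract_promoter(t, small_sim.genome, anchor_mode=mode)
            hits = scan_promoter(pwm, prom.sequence, tid)
            planted = {int(x) for x in str(row.motif_offsets).split(",")}
            found = {h.offset for h in hits}
            assert planted <= found, tid
            # sanitized promoters carry no accidental extra sites
            assert found == planted, tid
            checked += 1
        assert checked > 0


class TestPromoterExtraction:
    def _transcript(self, start, end, strand="+"):
        return TranscriptModel(
            "t1", "g1", (GenomicInterval("chr1", start, end, strand),), "novel"
        )

    def test_plus_strand_window(self):
        genome = {"chr1": "ACGT" * 2000}
        p = extract_promoter(self._transcript(3000, 3500), genome, 2000, "TSS")
        assert (p.start, p.end) == (1000, 3000)
        assert p.sequence == genome["chr1"][1000:3000]
        assert not p.truncated

    def test_truncation_at_chromosome_edge(self):
        genome = {"chr1": "ACGT" * 2000}
        p = extract_promoter(self._transcript(500, 900), genome, 2000, "TSS")
        assert (p.start, p.end) == (0, 500)
        assert len(p.sequence) == 500 and p.truncated

    def test_minus_strand_is_reverse_complement_of_slice(self):
        from pilnc.genomics_io import revcomp

        rng = np.random.default_rng(5)
        chrom = "".join("ACGT"[b] for b in rng.integers(0, 4, 6000))
        genome = {"chr1": chrom}
        p = extract_promoter(self._transcript(1000, 2500, "-"), genome, 2000, "TSS")
        assert p.sequence == revcomp(chrom[2500:4500])

    def test_atg_anchor_uses_first_atg(self):
        seq = "ACT" * 400 + "ATG" + "ACT" * 400
        genome = {"chr1": seq}
        t = self._transcript(1000, 1600)
        # first ATG of the spliced sequence sits 200 nt into the transcript,
        # at genomic position 1200
        p = extract_promoter(t, genome, 500, "ATG")
        assert p.anchor == 1200
        assert p.end == p.anchor and p.start == 700


class TestPhr1Cascade:
    def _setup(self):
        from pilnc.motif_regulation import MotifHit, Promoter

        prom = {
            tid: Promoter(tid, "chr1", i * 3000, i * 3000 + 2000, "+", i * 3000 + 2000, "A" * 2000, False)
            for i, tid in enumerate(["a", "b", "c"])
        }
        hit = lambda tid: [MotifHit(tid, -122, "+", "GAATATTC", 10.0, 2e-4)]
        hits = {"a": hit("a"), "b": hit("b")}
        dnase = BedGraphSignal([("chr1", 0, 2000, 5.0), ("chr1", 3000, 5000, 5.0)])
        return prom, hits, dnase

    def test_all_three_evidence_layers_required(self):
        prom, hits, dnase = self._setup()
        de = {"a": True, "b": False, "c": True}
        targets, excluded = phr1_target_cascade(hits, de, dnase, prom)
        by_id = {t.transcript_id: t for t in targets}
        assert by_id["a"].is_target  # motif + DE + accessible
        assert not by_id["b"].is_target  # no expression change
        assert not by_id["c"].is_target  # no motif
        assert excluded == []

    def test_transcript_without_promoter_excluded(self):
        prom, hits, dnase = self._setup()
        hits["zz"] = hits["a"]
        _, excluded = phr1_target_cascade(hits, {"a": True}, dnase, prom)
        assert excluded == ["zz"]


class TestMotifCountTrend:
    def test_planted_trend_is_monotone(self, rng):
        from pilnc.motif_regulation import RegTarget

        targets, fc = [], {}
        for i in range(200):
            k = int(rng.integers(0, 5))
            tid = f"t{i}"
            targets.append(RegTarget(tid, k, 1.0, True, True))
            fc[tid] = 1.0 + 0.8 * k + rng.normal(0, 0.1)
        df, monotone = motif_count_fold_trend(targets, fc)
        assert monotone
        assert list(df.n_motifs) == [0, 1, 2, 3, 4]

    def test_permuted_counts_break_trend(self, rng):
        from pilnc.motif_regulation import RegTarget

        ks = [int(rng.integers(0, 5)) for _ in range(200)]
        fc = {f"t{i}": 1.0 + 0.8 * k + rng.normal(0, 0.1) for i, k in enumerate(ks)}
        flags = []
        for _ in range(100):
            perm = rng.permutation(ks)
            targets = [RegTarget(f"t{i}", int(k), 1.0, True, True) for i, k in enumerate(perm)]
            flags.append(motif_count_fold_trend(targets, fc)[1])
        assert np.mean(flags) <= 0.05

    def test_single_bin_no_trend(self):
        from pilnc.motif_regulation import RegTarget

        targets = [RegTarget("t1", 0, 1.0, True, False)]
        df, monotone = motif_count_fold_trend(targets, {"t1": 1.0})
        assert len(df) == 1 and not monotone
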