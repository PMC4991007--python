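"""Filter cascade, ORF-based coding surrogate, and position classification."""

import numpy as np
import pytest

from pilnc.genomics_io import GenomicsIOError, GenomicInterval, TranscriptModel
from pilnc.lnc_discovery import (
    POSITION_CLASSES,
    classify_position,
    classify_positions,
    coding_potential_surrogate,
    filter_novel_lncrnas,
    longest_orf,
)

STOPS = {"TAA", "TAG", "TGA"}


def brute_force_longest_orf(seq):
    """Independent oracle: enumerate every ATG..stop span in 3 forward frames."""
    seq = seq.upper()
    best = 0
    for i in range(len(seq) - 2):
        if seq[i : i + 3] != "ATG":
            continue
        j = i + 3
        while j + 3 <= len(seq):
            if seq[j : j + 3] in STOPS:
                best = max(best, j + 3 - i)
                break
            j += 3
    return best


class TestCodingSurrogate:
    def test_matches_exhaustive_scan_on_random_sequences(self, rng):
        for _ in range(100):
            n = int(rng.integers(30, 400))
            seq = "".join("ACGT"[b] for b in rng.integers(0, 4, n))
            assert longest_orf(seq) == brute_force_longest_orf(seq)

    def test_stop_rich_sequence_scores_noncoding(self):
        # stops every <=30 nt in all frames, no usable ORF
        seq = ("ATGTAA" + "TAATTAACTAAC") * 20
        assert coding_potential_surrogate(seq) < 0

    def test_full_length_orf_scores_coding(self, rng):
        body = "".join(
            c for c in ["GCT", "GGA", "CTT", "CCA"] * 50
        )  # 198 non-stop codons
        seq = "ATG" + body[: 600 - 6] + "TAA"
        assert len(seq) == 600
        assert coding_potential_surrogate(seq) == pytest.approx(1 - 0.35)

    def test_empty_sequence_is_error(self):
        with pytest.raises(GenomicsIOError):
            coding_potential_surrogate("")


def _t(tid, chrom, spans, strand, biotype="novel"):
    return TranscriptModel(
        tid, tid, tuple(GenomicInterval(chrom, s, e, strand) for s, e in spans), biotype
    )


class TestFilterCascade:
    def test_empty_candidates(self):
        retained, rep = filter_novel_lncrnas([], [], {"chr1": "A" * 100})
        assert retained == [] and rep.n_input == 0 and rep.n_retained == 0

    def test_short_transcript_removal_reason(self):
        genome = {"chr1": "ACT" * 2000}
        cand = _t("c1", "chr1", [(100, 299)], "+")  # 199 nt
        retained, rep = filter_novel_lncrnas([cand], [], genome)
        assert rep.n_removed_short == 1
        assert rep.removal_reason["c1"] == "short"

    def test_overlap_rules_are_strand_aware(self):
        genome = {"chr1": "ACT" * 4000}
        coding = _t("g1", "chr1", [(1000, 2000)], "+", "protein_coding")
        lnc = _t("l1", "chr1", [(5000, 5500)], "+", "tair10_lncRNA")
        same_strand = _t("c1", "chr1", [(1500, 1900)], "+")
        antisense_coding = _t("c2", "chr1", [(1500, 1900)], "-")
        antisense_lnc = _t("c3", "chr1", [(5100, 5400)], "-")
        retained, rep = filter_novel_lncrnas(
            [same_strand, antisense_coding, antisense_lnc], [coding, lnc], genome
        )
        # coding-exon overlap counts same-strand only; lncRNA overlap counts
        # both strands
        assert rep.removal_reason["c1"] == "overlap_annotation"
        assert rep.removal_reason["c3"] == "overlap_annotation"
        assert [t.transcript_id for t in retained] == ["c2"]

    def test_intron_overlap_does_not_remove(self):
        genome = {"chr1": "ACT" * 4000}
        coding = _t("g1", "chr1", [(1000, 1200), (2000, 2200)], "+", "protein_coding")
        in_intron = _t("c1", "chr1", [(1300, 1900)], "+")
        retained, _ = filter_novel_lncrnas([in_intron], [coding], genome)
        assert [t.transcript_id for t in retained] == ["c1"]

    def test_external_coding_scores_override_surrogate(self):
        genome = {"chr1": "ACT" * 2000}
        cand = _t("c1", "chr1", [(100, 500)], "+")
        _, rep = filter_novel_lncrnas([cand], [], genome, coding_scores={"c1": 0.4})
        assert rep.removal_reason["c1"] == "coding_potential"

    def test_conservation_identity_on_synthetic_data(self, small_sim):
        retained, rep = filter_novel_lncrnas(
            small_sim.candidates, small_sim.annotation, small_sim.genome
        )
        assert (
            rep.n_removed_overlap + rep.n_removed_short + rep.n_removed_coding
            + rep.n_retained
            == rep.n_input
            == len(small_sim.candidates)
        )
        # the generator's planted novel lncRNAs all survive
        truth = small_sim.truth.transcripts
        planted = set(truth[truth.biotype == "novel"].index)
        assert {t.transcript_id for t in retained} == planted


def brute_force_position(lnc, annotation, cis_max_dist=500):
    """All-pairs oracle for the genomic position class."""
    kinds = set()
    for t in annotation:
        if t.biotype in ("pseudogene", "TE_related") and t.chrom == lnc.chrom:
            if t.start < lnc.end and lnc.start < t.end:
                kinds.add(t.biotype)
    if kinds:  # pseudogene outranks TE when both overlap
        return "pseudogenic" if "pseudogene" in kinds else "te_related"
    for t in annotation:
        if t.biotype != "protein_coding" or t.chrom != lnc.chrom or t.strand == lnc.strand:
            continue
        for e in lnc.exons:
            if t.start < e.end and e.start < t.end:
                return "antisense"
    dists = []
    for t in annotation:
        if t.biotype != "protein_coding" or t.chrom != lnc.chrom:
            continue
        if t.start < lnc.end and lnc.start < t.end:
            dists.append(0)
        elif t.end <= lnc.start:
            dists.append(lnc.start - t.end)
        else:
            dists.append(t.start - lnc.end)
    if dists and min(dists) <= cis_max_dist:
        return "cis"
    return "intergenic"


class TestPositionClassification:
    def test_antisense_overlap(self):
        coding = _t("g1", "chr1", [(1000, 3000)], "+", "protein_coding")
        lnc = _t("l1", "chr1", [(2000, 2500)], "-")
        assert classify_position(lnc, [coding]) == "antisense"

    def test_cis_within_500(self):
        coding = _t("g1", "chr1", [(1000, 3000)], "+", "protein_coding")
        lnc = _t("l1", "chr1", [(3400, 3900)], "+")
        assert classify_position(lnc, [coding]) == "cis"

    def test_intergenic_on_empty_annotation(self):
        lnc = _t("l1", "chr1", [(100, 600)], "+")
        assert classify_position(lnc, []) == "intergenic"

    def test_pseudogene_overlap_has_priority_over_antisense(self):
        pseudo = _t("p1", "chr1", [(1000, 2000)], "+", "pseudogene")
        coding = _t("g1", "chr1", [(1500, 3000)], "+", "protein_coding")
        lnc = _t("l1", "chr1", [(1600, 1900)], "-")
        assert classify_position(lnc, [pseudo, coding]) == "pseudogenic"

    def test_matches_brute_force_oracle_on_random_loci(self, rng):
        annotation = []
        for i in range(100):
            start = int(rng.integers(0, 50_000))
            length = int(rng.integers(200, 2000))
            strand = "+" if rng.random() < 0.5 else "-"
            biotype = ["protein_coding", "pseudogene", "TE_related"][
                int(rng.integers(0, 3)) if rng.random() < 0.3 else 0
            ]
            annotation.append(_t(f"a{i}", "chr1", [(start, start + length)], strand, biotype))
        for i in range(100):
            start = int(rng.integers(0, 52_000))
            length = int(rng.integers(200, 1500))
            strand = "+" if rng.random() < 0.5 else "-"
            lnc = _t(f"l{i}", "chr1", [(start, start + length)], strand)
            assert classify_position(lnc, annotation) == brute_force_position(
                lnc, annotation
            )

    def test_independent_of_annotation_order(self, rng):
        coding = _t("g1", "chr1", [(1000, 3000)], "+", "protein_coding")
        pseudo = _t("p1", "chr1", [(2500, 3500)], "-", "pseudogene")
        lnc = _t("l1", "chr1", [(2600, 3100)], "-")
        assert classify_position(lnc, [coding, pseudo]) == classify_position(
            lnc, [pseudo, coding]
        )

    def test_recovers_planted_classes_exactly(self, small_sim):
        truth = small_sim.truth.transcripts
        planted = truth[truth.position_class.isin(POSITION_CLASSES)]
        called = classify_positions(
            [t for t in small_sim.candidates if t.transcript_id in planted.index],
            small_sim.annotation,
        )
        assert all(called[tid] == planted.loc[tid, "position_class"] for tid in called)
        assert len(called) == len(planted)
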