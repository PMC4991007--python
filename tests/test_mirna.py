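"""miRNA target scoring, mimic detection, PCC and the ceRNA filter."""

import itertools
import math

import numpy as np
import pytest

from pilnc.genomics_io import GenomicsIOError, revcomp
from pilnc.mirna_network import (
    MirnaInteraction,
    _pair_penalty,
    build_cerna_network,
    detect_mimic,
    expression_pcc,
    score_target,
)

FLIP = {"A": "C", "C": "A", "G": "T", "T": "G"}  # non-pairing, non-wobble swap


def _random_mirna(rng, n=21):
    return "".join("ACGU"[b] for b in rng.integers(0, 4, n))


def _flank(rng, n):
    return "".join("ACGT"[b] for b in rng.integers(0, 4, n))


def brute_force_score(mirna, transcript, max_gaps=2):
    """Exhaustive oracle: every window x every <=2-gap alignment layout.

    Enumerates, for each alignment start, the placements of up to two
    single-base gaps (either an unpaired miRNA base or an unpaired target
    base) and scores the resulting pairing column by column.
    """
    m = mirna.upper().replace("U", "T")
    t = transcript.upper().replace("U", "T")
    L = len(m)
    mpos = [L - i for i in range(L)]  # miRNA position of rcm row i
    weights = [2.0 if p in range(2, 9) else 1.0 for p in mpos]

    best = math.inf

    def extend(i, j, gaps, cost):
        nonlocal best
        if cost >= best:
            return
        if i == L:
            best = min(best, cost)
            return
        w = weights[i]
        mb = m[mpos[i] - 1]
        if j < len(t):
            extend(i + 1, j + 1, gaps, cost + _pair_penalty(mb, t[j]) * w)
        if gaps < max_gaps:
            extend(i + 1, j, gaps + 1, cost + 2.0 * w)  # miRNA base unpaired
            if j < len(t):
                extend(i, j + 1, gaps + 1, cost + 2.0 * w)  # target bulge
    for start in range(len(t)):
        extend(0, start, 0, 0.0)
    return best


class TestScoreTarget:
    def test_perfect_site_scores_zero(self, rng):
        for _ in range(5):
            m = _random_mirna(rng)
            t = _flank(rng, 40) + revcomp(m.replace("U", "T")) + _flank(rng, 40)
            score, (s, e) = score_target(m, t)
            assert score == 0.0
            assert t[s:e] == revcomp(m.replace("U", "T"))

    def test_single_mismatch_penalties(self, rng):
        m = _random_mirna(rng)
        md = m.replace("U", "T")
        # miRNA position 15 (non-seed) pairs site index 21-15=6
        site = list(revcomp(md))
        site[6] = FLIP[site[6]]
        assert score_target(m, _flank(rng, 30) + "".join(site) + _flank(rng, 30))[0] == 1.0
        # miRNA position 5 (seed) pairs site index 16: penalty doubled
        site = list(revcomp(md))
        site[16] = FLIP[site[16]]
        assert score_target(m, _flank(rng, 30) + "".join(site) + _flank(rng, 30))[0] == 2.0

    def test_wobble_half_penalty(self):
        m = "A" * 10 + "G" + "A" * 10  # position 11, non-seed
        site = list(revcomp(m))
        site[10] = "T"  # G:U wobble against miRNA position 11
        t = "CCCCC" + "".join(site) + "CCCCC"
        assert score_target(m, t)[0] == 0.5

    def test_transcript_shorter_than_mirna_errors(self, rng):
        with pytest.raises(GenomicsIOError):
            score_target(_random_mirna(rng), "ACGT")

    def test_matches_exhaustive_alignment_oracle(self, rng):
        for _ in range(50):
            m = _random_mirna(rng, n=int(rng.integers(19, 25)))
            t = _flank(rng, int(rng.integers(len(m), 40)))
            assert score_target(m, t)[0] == pytest.approx(brute_force_score(m, t))


class TestExpressionPcc:
    def test_perfect_anticorrelation(self):
        assert expression_pcc([1, 2, 3, 4], [4, 3, 2, 1]) == pytest.approx(-1.0)

    def test_identity(self):
        assert expression_pcc([1, 2, 3, 4], [1, 2, 3, 4]) == pytest.approx(1.0)

    def test_matches_closed_form_covariance_ratio(self, rng):
        x = rng.normal(size=8)
        y = rng.normal(size=8)
        num = np.mean((x - x.mean()) * (y - y.mean()))
        assert expression_pcc(x, y) == pytest.approx(num / (x.std() * y.std()))

    def test_zero_variance_flagged_as_nan(self):
        assert math.isnan(expression_pcc([1, 1, 1, 1], [1, 2, 3, 4]))

    def test_too_few_samples_errors(self):
        with pytest.raises(GenomicsIOError):
            expression_pcc([1, 2], [2, 1])


def _edge(mid, tid, score, pcc, kind="cleavage_target"):
    return MirnaInteraction(mid, tid, score, 0, 21, pcc, kind)


class TestCernaNetwork:
    def test_score_and_correlation_gates(self):
        kept = build_cerna_network(
            [
                _edge("m", "kept", 4.8, -0.72),
                _edge("m", "score_gate", 6.0, -0.9),
                _edge("m", "pcc_gate", 3.0, 0.4),
            ]
        )
        assert [e.target_id for e in kept] == ["kept"]

    def test_whitelist_bypasses_pcc_only(self):
        kept = build_cerna_network(
            [_edge("m", "PHO2", 0.8, -0.37), _edge("m", "bad", 7.0, -0.37)],
            whitelist=[("m", "PHO2"), ("m", "bad")],
        )
        assert [e.target_id for e in kept] == ["PHO2"]
        assert kept[0].whitelisted

    def test_edges_subset_and_filter_order_independent(self, rng):
        edges = [
            _edge(f"m{i}", f"t{i}", float(rng.uniform(0, 8)), float(rng.uniform(-1, 1)))
            for i in range(50)
        ]
        kept = build_cerna_network(edges)
        ids = {(e.mirna_id, e.target_id) for e in kept}
        assert ids <= {(e.mirna_id, e.target_id) for e in edges}
        # independent re-filtering in the opposite order yields the same set
        manual = {
            (e.mirna_id, e.target_id)
            for e in edges
            if e.pcc <= -0.5 and e.target_score <= 5
        }
        assert ids == manual


class TestDetectMimic:
    def test_constructed_bulged_site_detected(self, rng):
        m = _random_mirna(rng)
        md = m.replace("U", "T")
        site = revcomp(md[10:]) + "CTA" + revcomp(md[:10])
        t = _flank(rng, 25) + site + _flank(rng, 25)
        assert detect_mimic(m, t) == (25, 25 + len(site))

    def test_perfect_complement_is_not_a_mimic(self, rng):
        m = _random_mirna(rng)
        t = _flank(rng, 25) + revcomp(m.replace("U", "T")) + _flank(rng, 25)
        assert detect_mimic(m, t) is None

    def test_seed_mismatch_disqualifies(self, rng):
        m = _random_mirna(rng)
        md = m.replace("U", "T")
        tail = list(revcomp(md[:10]))
        # miRNA position 5 pairs tail index 10-5=5
        tail[5] = FLIP[tail[5]]
        site = revcomp(md[10:]) + "CTA" + "".join(tail)
        t = _flank(rng, 25) + site + _flank(rng, 25)
        assert detect_mimic(m, t) is None

    def test_matches_window_and_insertion_enumeration(self, rng):
        """Agreement with a brute-force scan over windows x bulge placement."""

        def oracle(m, t):
            md = m.upper().replace("U", "T")
            td = t.upper().replace("U", "T")
            L = len(md)
            comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
            for j in range(len(td) - (L + 3) + 1):
                w = td[j : j + L + 3]
                seg1, seg2 = w[: L - 10], w[L - 7 :]
                mism = sum(comp[md[L - a - 1]] != seg1[a] for a in range(L - 10))
                seed_ok = all(comp[md[p - 1]] == seg2[10 - p] for p in range(2, 9))
                mism += sum(
                    comp[md[p - 1]] != seg2[10 - p] for p in (1, 9, 10)
                )
                if seed_ok and mism <= 3:
                    return (j, j + L + 3)
            return None

        hits = 0
        for trial in range(50):
            m = _random_mirna(rng)
            md = m.replace("U", "T")
            if trial % 2 == 0:
                # plant a bulged site with up to 3 mismatches in the segment
                # pairing miRNA positions 11..L (never the seed)
                site = list(revcomp(md[10:]) + "TGA" + revcomp(md[:10]))
                n_mm = int(rng.integers(0, 4))
                for p in rng.choice(len(md) - 10, size=n_mm, replace=False):
                    site[int(p)] = FLIP[site[int(p)]]
                t = _flank(rng, 20) + "".join(site) + _flank(rng, 20)
            else:
                t = _flank(rng, 70)
            expected = oracle(m, t)
            assert detect_mimic(m, t) == expected
            hits += expected is not None
        assert hits >= 10  # the planted half mostly detectable
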