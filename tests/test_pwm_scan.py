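"""Match-style scoring and scanning against independent brute-force oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from promnet import pwm_scan
from promnet.motif_io import PWMatrix, Promoter
from promnet.pwm_scan import (
    ThresholdProfile,
    calibrate_min_fp,
    core_window_start,
    information_vector,
    mss_score,
    scan_promoter,
)

from conftest import make_promoter, random_sequence

BASES = "ACGT"
COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


# ---------------------------------------------------------------------------
# Independent oracle: direct evaluation of the published scoring scheme.


def oracle_info(freqs):
    out = []
    for row in freqs:
        s = 0.0
        for f in row:
            if f > 0:
                s += f * math.log(4 * f)
        out.append(max(s, 0.0))
    return out


def oracle_mss(freqs, window):
    info = oracle_info(freqs)
    cur = sum(info[i] * freqs[i][BASES.index(b)]
              for i, b in enumerate(window))
    lo = sum(info[i] * min(freqs[i]) for i in range(len(freqs)))
    hi = sum(info[i] * max(freqs[i]) for i in range(len(freqs)))
    if hi == lo:
        return 1.0
    return (cur - lo) / (hi - lo)


def oracle_core_start(freqs):
    info = oracle_info(freqs)
    sums = [sum(info[i:i + 5]) for i in range(len(info) - 4)]
    return sums.index(max(sums))


def oracle_css(freqs, window, core_start):
    sub = freqs[core_start:core_start + 5]
    return oracle_mss(sub, window[core_start:core_start + 5])


def oracle_scan(pwm, promoter, core_cut, mat_cut):
    """Per-window re-scoring on both strands, no vectorisation."""
    freqs = pwm.freqs.tolist()
    L = len(freqs)
    hits = []
    seq = promoter.sequence
    for j in range(len(seq) - L + 1):
        window = seq[j:j + L]
        if "N" in window:
            continue
        for strand in "+-":
            w = window if strand == "+" else "".join(
                COMP[b] for b in reversed(window))
            mss = oracle_mss(freqs, w)
            css = oracle_css(freqs, w, pwm.core_start)
            if mss >= mat_cut and css >= core_cut:
                hits.append((j - promoter.tss_offset, strand,
                             round(mss, 12), round(css, 12)))
    return sorted(hits)


def random_pwm(rng, length, matrix_id="MR"):
    counts = rng.integers(0, 20, size=(length, 4)).astype(float)
    counts[counts.sum(axis=1) == 0, 0] = 1.0
    return PWMatrix.from_counts(matrix_id, counts, pseudocount=0.5)


# ---------------------------------------------------------------------------


class TestInformationVector:
    def test_limits_and_hand_value(self):
        info = information_vector(
            [[1, 0, 0, 0], [0.25, 0.25, 0.25, 0.25], [0.5, 0.5, 0, 0]])
        assert info[0] == pytest.approx(math.log(4))
        assert info[1] == pytest.approx(0.0, abs=1e-12)
        assert info[2] == pytest.approx(math.log(2))

    def test_negative_frequency_rejected(self):
        with pytest.raises(ValueError):
            information_vector([[-0.1, 0.4, 0.4, 0.3]])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.01, 10), min_size=4, max_size=4))
    def test_non_negative_and_bounded(self, raw):
        row = np.array(raw) / sum(raw)
        (i,) = information_vector([row])
        assert 0 <= i <= math.log(4) + 1e-12


class TestMssScore:
    def test_consensus_and_anticonsensus(self, one_hot_pwm):
        assert mss_score(one_hot_pwm, "AAACCGGG") == pytest.approx(1.0)
        # every position takes a minimum-frequency (non-consensus) base
        assert mss_score(one_hot_pwm, "CCCAACCC") == pytest.approx(0.0)

    def test_uniform_matrix_scores_one(self):
        pwm = PWMatrix.from_counts("U", np.ones((6, 4)), pseudocount=0.0)
        assert mss_score(pwm, "ACGTAC") == 1.0

    def test_length_mismatch(self, one_hot_pwm):
        with pytest.raises(ValueError):
            mss_score(one_hot_pwm, "ACGT")

    def test_matches_oracle_on_all_windows_of_5mer_matrix(self):
        freqs = [[0.7, 0.1, 0.1, 0.1]] * 5
        counts = np.array(freqs) * 10
        pwm = PWMatrix.from_counts("P5", counts, pseudocount=0.0)
        from itertools import product
        scores = {}
        for combo in product(BASES, repeat=5):
            window = "".join(combo)
            got = mss_score(pwm, window)
            want = oracle_mss(freqs, window)
            assert got == pytest.approx(want, abs=1e-12)
            scores[window] = got
        assert scores["AAAAC"] < scores["AAAAA"] == pytest.approx(1.0)
        assert min(scores.values()) == pytest.approx(0.0)
        assert all(0 <= s <= 1 for s in scores.values())


class TestCoreWindow:
    def test_information_peak(self):
        freqs = np.full((10, 4), 0.25)
        freqs[3:8] = [1.0, 0.0, 0.0, 0.0]
        assert core_window_start(information_vector(freqs)) == 3

    def test_uniform_tie_breaks_left(self):
        assert core_window_start(np.zeros(12)) == 0

    def test_matches_exhaustive_argmax(self, rng):
        for _ in range(20):
            pwm = random_pwm(rng, 12)
            assert pwm.core_start == oracle_core_start(pwm.freqs.tolist())


class TestScanPromoter:
    def test_planted_consensus_single_hit(self, one_hot_pwm):
        seq = "TTTTTTTTTT" + "AAACCGGG" + "TTTTTTTTTT"
        promoter = make_promoter(seq, tss_offset=0)
        profile = ThresholdProfile.uniform(["ONEHOT"], 0.9, 0.9)
        hits = scan_promoter(one_hot_pwm, promoter, profile)
        assert [(h.start, h.end, h.strand) for h in hits] == [(10, 18, "+")]
        assert hits[0].mss == pytest.approx(1.0)

    def test_zero_cutoffs_count_all_windows(self, one_hot_pwm, rng):
        n, L = 100, one_hot_pwm.length
        promoter = make_promoter(random_sequence(rng, n))
        profile = ThresholdProfile.uniform(["ONEHOT"], 0.0, 0.0)
        hits = scan_promoter(one_hot_pwm, promoter, profile)
        assert len(hits) == 2 * (n - L + 1)

    def test_n_windows_are_skipped(self, one_hot_pwm):
        promoter = make_promoter("ACGTNCGTACGTACGT", tss_offset=0)
        profile = ThresholdProfile.uniform(["ONEHOT"], 0.0, 0.0)
        hits = scan_promoter(one_hot_pwm, promoter, profile)
        assert all(h.start > 4 - 8 and "N" not in
                   promoter.sequence[h.start:h.end] for h in hits)
        # 8-mer windows starting at 0..4 contain the N at index 4
        assert len(hits) == 2 * (16 - 8 + 1 - 5)

    @pytest.mark.parametrize("cuts", [(0.0, 0.0), (0.75, 0.85), (0.9, 0.97)])
    def test_equals_naive_rescan(self, rng, cuts):
        pwm = random_pwm(rng, 8)
        promoter = make_promoter(random_sequence(rng, 150))
        profile = ThresholdProfile.uniform([pwm.matrix_id], *cuts)
        got = sorted((h.start, h.strand, round(h.mss, 12), round(h.css, 12))
                     for h in scan_promoter(pwm, promoter, profile))
        assert got == oracle_scan(pwm, promoter, *cuts)

    def test_strand_symmetry(self, rng):
        """Mirror symmetry of double-stranded scanning.

        Reverse-complementing the promoter alone reflects the hit set and
        swaps strands; reverse-complementing the matrix as well restores
        the original strand labels.
        """
        pwm = random_pwm(rng, 7)
        seq = random_sequence(rng, 120)
        fwd = make_promoter(seq, tss_offset=0)
        rc_seq = "".join(COMP[b] for b in reversed(seq))
        rc_prom = make_promoter(rc_seq, tss_offset=0, promoter_id="P1rc")
        profile = ThresholdProfile.uniform([pwm.matrix_id], 0.6, 0.7)
        fwd_hits = sorted((h.start, h.end, h.strand, round(h.mss, 9))
                          for h in scan_promoter(pwm, fwd, profile))
        n = len(seq)

        swapped = sorted(
            (n - h.end, n - h.start, "-" if h.strand == "+" else "+",
             round(h.mss, 9))
            for h in scan_promoter(pwm, rc_prom, profile))
        assert swapped == fwd_hits

        preserved = sorted(
            (n - h.end, n - h.start, h.strand, round(h.mss, 9))
            for h in scan_promoter(pwm.reverse_complement(), rc_prom, profile))
        assert preserved == fwd_hits

    def test_raising_cutoffs_never_adds_hits(self, rng):
        pwm = random_pwm(rng, 6)
        promoter = make_promoter(random_sequence(rng, 200))
        lo = scan_promoter(
            pwm, promoter, ThresholdProfile.uniform([pwm.matrix_id], 0.5, 0.6))
        hi = scan_promoter(
            pwm, promoter, ThresholdProfile.uniform([pwm.matrix_id], 0.7, 0.8))
        assert set(hi) <= set(lo)


class TestCalibration:
    def _background(self, rng, n=12, length=1000):
        return [make_promoter(random_sequence(rng, length), f"B{i}", f"B{i}")
                for i in range(n)]

    def test_huge_target_admits_every_window(self, rng, one_hot_pwm):
        bg = self._background(rng)
        scores = pwm_scan.background_scores(one_hot_pwm, bg)
        _, cut = calibrate_min_fp(one_hot_pwm, bg, target_fp_per_kb=1e9)
        assert cut == pytest.approx(scores.min())

    def test_zero_target_excludes_every_window(self, rng, one_hot_pwm):
        bg = self._background(rng)
        scores = pwm_scan.background_scores(one_hot_pwm, bg)
        _, cut = calibrate_min_fp(one_hot_pwm, bg, target_fp_per_kb=0.0)
        assert cut > scores.max()

    def test_matches_quantile_oracle(self, rng, one_hot_pwm):
        bg = self._background(rng)
        target = 0.1
        _, cut = calibrate_min_fp(one_hot_pwm, bg, target_fp_per_kb=target)
        scores = np.sort(pwm_scan.background_scores(one_hot_pwm, bg))
        total_kb = sum(p.length for p in bg) / 1000.0
        allowed = target * total_kb
        # smallest observed score whose >=-count stays within the budget,
        # or one ulp past the maximum when no observed score qualifies
        candidates = [s for s in np.unique(scores)
                      if (scores >= s).sum() <= allowed]
        if candidates:
            assert cut == pytest.approx(min(candidates))
        else:
            assert cut > scores.max()
        assert (scores >= cut).sum() <= allowed

    def test_monotone_in_target(self, rng, one_hot_pwm):
        bg = self._background(rng)
        cuts = [calibrate_min_fp(one_hot_pwm, bg, t)[1]
                for t in (0.01, 0.1, 1.0, 10.0)]
        assert cuts == sorted(cuts, reverse=True)

    def test_core_cutoff_is_fraction_of_matrix_cutoff(self, rng, one_hot_pwm):
        bg = self._background(rng)
        core, mat = calibrate_min_fp(one_hot_pwm, bg, 0.5, core_fraction=0.9)
        assert core == pytest.approx(min(1.0, 0.9 * mat))

    def test_empty_background_rejected(self, one_hot_pwm):
        with pytest.raises(ValueError):
            calibrate_min_fp(one_hot_pwm, [], 0.5)
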