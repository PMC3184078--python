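"""Match-style TFBS prediction.

Implements the information-vector-weighted matrix similarity score (MSS)
and core similarity score (CSS) scheme of the Match program:

    I(i)   = sum_b f(i,b) ln(4 f(i,b))          (0 ln 0 := 0)
    Current = sum_i I(i) f(i, s_i)
    MSS    = (Current - Min) / (Max - Min)

where Max and Min sum the per-position I-weighted maximum and minimum
frequencies.  The CSS applies the same normalisation to the 5 consecutive
positions of highest summed information (the core).  A window is reported
as a site when CSS >= core cutoff and MSS >= matrix cutoff.

Per-matrix cutoff pairs emulating a minimum-false-positive profile are
obtained by calibrating against a background promoter set: the matrix
cutoff is the smallest score whose background hit density does not exceed
a target rate per kilobase.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .motif_io import Promoter, PWMatrix

__all__ = [
    "SiteHit",
    "ThresholdProfile",
    "information_vector",
    "core_window_start",
    "mss_score",
    "css_score",
    "scan_promoter",
    "scan_promoters",
    "calibrate_min_fp",
    "calibrate_profile",
]

CORE_LENGTH = 5

_CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i

DEFAULT_CORE_FRACTION = 0.90
DEFAULT_TARGET_FP_PER_KB = 0.5


@dataclass(frozen=True)
class SiteHit:
    """One predicted binding site in promoter-relative coordinates."""

    matrix_id: str
    promoter_id: str
    start: int
    end: int
    strand: str
    mss: float
    css: float


@dataclass
class ThresholdProfile:
    """Per-matrix (core_cutoff, matrix_cutoff) pairs."""

    cutoffs: dict[str, tuple[float, float]]

    def __getitem__(self, matrix_id: str) -> tuple[float, float]:
        return self.cutoffs[matrix_id]

    def __contains__(self, matrix_id: str) -> bool:
        return matrix_id in self.cutoffs

    @classmethod
    def uniform(cls, matrix_ids: Iterable[str], core_cutoff: float,
                matrix_cutoff: float) -> "ThresholdProfile":
        return cls({m: (core_cutoff, matrix_cutoff) for m in matrix_ids})

    def write_tsv(self, path) -> None:
        with Path(path).open("w") as fh:
            fh.write("matrix_id\tcore_cutoff\tmatrix_cutoff\n")
            for matrix_id in sorted(self.cutoffs):
                core, mat = self.cutoffs[matrix_id]
                fh.write(f"{matrix_id}\t{core:.17g}\t{mat:.17g}\n")

    @classmethod
    def read_tsv(cls, path) -> "ThresholdProfile":
        cutoffs: dict[str, tuple[float, float]] = {}
        with Path(path).open() as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            for row in reader:
                cutoffs[row["matrix_id"]] = (
                    float(row["core_cutoff"]), float(row["matrix_cutoff"])
                )
        return cls(cutoffs)


# ---------------------------------------------------------------------------
# Scores


def information_vector(freqs) -> np.ndarray:
    """I(i) = sum_b f(i,b) ln(4 f(i,b)) per matrix position, with 0 ln 0 = 0.

    Zero for a uniform position, ln 4 for a one-hot position.
    """
    freqs = np.asarray(freqs, dtype=float)
    if np.any(freqs < 0):
        raise ValueError("negative frequency in matrix")
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = freqs * np.log(4.0 * freqs)
    terms[freqs == 0] = 0.0
    info = terms.sum(axis=-1)
    # clip the tiny negative round-off a near-uniform row can produce
    return np.maximum(info, 0.0)


def core_window_start(info) -> int:
    """Left edge of the 5-position window maximising summed information.

    Ties are broken towards the smallest start.
    """
    info = np.asarray(info, dtype=float)
    if info.shape[0] < CORE_LENGTH:
        raise ValueError("matrix shorter than the 5-position core")
    sums = np.convolve(info, np.ones(CORE_LENGTH), mode="valid")
    return int(np.argmax(sums))  # argmax returns the first maximum


def encode_sequence(sequence: str) -> np.ndarray:
    """Map A,C,G,T to 0..3 and anything else (N) to 4."""
    return _CODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]


def _weights(freqs: np.ndarray, info: np.ndarray) -> np.ndarray:
    """I-weighted frequency table with a NaN column for ambiguous bases.

    Any window touching an N picks up a NaN and fails every cutoff
    comparison, so N regions never yield sites.
    """
    w = np.empty((freqs.shape[0], 5))
    w[:, :4] = info[:, None] * freqs
    w[:, 4] = np.nan
    return w


def _normalised(current: np.ndarray, w: np.ndarray) -> np.ndarray:
    lo = w[:, :4].min(axis=1).sum()
    hi = w[:, :4].max(axis=1).sum()
    if hi - lo <= 0:
        return np.ones_like(current)  # fully uniform matrix
    return (current - lo) / (hi - lo)


def _window_sums(codes: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Sum of w[i, codes[j+i]] for every window start j."""
    L = w.shape[0]
    n = codes.shape[0] - L + 1
    if n <= 0:
        return np.empty(0)
    acc = np.zeros(n)
    for i in range(L):
        acc += w[i, codes[i:i + n]]
    return acc


def _score_windows(pwm: "PWMatrix", codes: np.ndarray,
                   rc: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """(mss, css) arrays over all window starts, NaN where N intrudes."""
    freqs = pwm.freqs[::-1, ::-1] if rc else pwm.freqs
    info = pwm.info[::-1] if rc else pwm.info
    core = (pwm.length - CORE_LENGTH - pwm.core_start) if rc else pwm.core_start
    w = _weights(freqs, info)
    mss = _normalised(_window_sums(codes, w), w)
    wc = w[core:core + CORE_LENGTH]
    core_sums = _window_sums(codes, wc)
    # align core sums to window starts: core window of window j starts at j+core
    n = mss.shape[0]
    css = _normalised(core_sums[core:core + n], wc)
    return mss, css


def mss_score(pwm: "PWMatrix", window: str) -> float:
    """Matrix similarity score of one window (must have length L)."""
    if len(window) != pwm.length:
        raise ValueError(
            f"window length {len(window)} != matrix length {pwm.length}"
        )
    codes = encode_sequence(window.upper())
    mss, _ = _score_windows(pwm, codes)
    return float(mss[0])


def css_score(pwm: "PWMatrix", window: str) -> float:
    """Core similarity score of one full-length window."""
    if len(window) != pwm.length:
        raise ValueError(
            f"window length {len(window)} != matrix length {pwm.length}"
        )
    codes = encode_sequence(window.upper())
    _, css = _score_windows(pwm, codes)
    return float(css[0])


# ---------------------------------------------------------------------------
# Scanning


def scan_promoter(pwm: "PWMatrix", promoter: "Promoter",
                  profile: ThresholdProfile) -> list[SiteHit]:
    """Predict sites of one matrix on both strands of one promoter.

    Minus-strand windows are scored against the reverse complement
    (equivalently, with the reverse-complemented matrix) but reported in
    forward promoter-relative coordinates.  Hits are sorted by start, then
    strand ('+' before '-').
    """
    if pwm.matrix_id not in profile:
        raise KeyError(f"no threshold for matrix {pwm.matrix_id!r}")
    core_cut, mat_cut = profile[pwm.matrix_id]
    codes = encode_sequence(promoter.sequence)
    hits: list[SiteHit] = []
    for strand, rc in (("+", False), ("-", True)):
        mss, css = _score_windows(pwm, codes, rc=rc)
        with np.errstate(invalid="ignore"):
            keep = (mss >= mat_cut) & (css >= core_cut)
        for j in np.flatnonzero(keep):
            start = int(j) - promoter.tss_offset
            hits.append(
                SiteHit(pwm.matrix_id, promoter.promoter_id,
                        start, start + pwm.length, strand,
                        float(mss[j]), float(css[j]))
            )
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def scan_promoters(pwms: Sequence["PWMatrix"],
                   promoters: Sequence["Promoter"],
                   profile: ThresholdProfile) -> list[SiteHit]:
    """Scan every matrix over every promoter; concatenated hit list."""
    hits: list[SiteHit] = []
    for pwm in pwms:
        for promoter in promoters:
            hits.extend(scan_promoter(pwm, promoter, profile))
    return hits


# ---------------------------------------------------------------------------
# Threshold calibration


def background_scores(pwm: "PWMatrix",
                      background: Sequence["Promoter"]) -> np.ndarray:
    """All finite MSS values over both strands of the background set."""
    chunks = []
    for promoter in background:
        codes = encode_sequence(promoter.sequence)
        for rc in (False, True):
            mss, _ = _score_windows(pwm, codes, rc=rc)
            chunks.append(mss[np.isfinite(mss)])
    if not chunks:
        return np.empty(0)
    return np.concatenate(chunks)


def calibrate_min_fp(
    pwm: "PWMatrix",
    background: Sequence["Promoter"],
    target_fp_per_kb: float = DEFAULT_TARGET_FP_PER_KB,
    core_fraction: float = DEFAULT_CORE_FRACTION,
) -> tuple[float, float]:
    """Background-quantile emulation of a minimum-false-positive profile.

    Returns (core_cutoff, matrix_cutoff) where the matrix cutoff is the
    smallest observed score s with background density of {MSS >= s} at most
    ``target_fp_per_kb`` hits per kilobase of background sequence (both
    strands counted against single-stranded length, matching how hits are
    reported).  The core cutoff is ``core_fraction * matrix_cutoff`` capped
    at 1.  A target of 0 places the cutoff just above the largest
    background score.
    """
    if not background:
        raise ValueError("background promoter set is empty")
    if target_fp_per_kb < 0:
        raise ValueError("target_fp_per_kb must be non-negative")
    total_kb = sum(p.length for p in background) / 1000.0
    if total_kb < 10.0:
        raise ValueError(
            f"background too small for calibration: {total_kb:.2f} kb < 10 kb"
        )
    scores = background_scores(pwm, background)
    if scores.size == 0:
        raise ValueError("background yields no scoreable windows")
    allowed = target_fp_per_kb * total_kb
    scores.sort()
    n = scores.size
    # count of scores >= scores[k] is n - k; want the smallest score with
    # count <= allowed, i.e. the smallest k with n - k <= allowed after
    # stepping left over ties.  When even the top score is too frequent the
    # cutoff lands one ulp above it (which may exceed 1 if a perfect-score
    # window exists in the background — then nothing can be admitted).
    k = max(0, int(math.ceil(n - allowed)))
    if k >= n:
        matrix_cutoff = float(np.nextafter(scores[-1], np.inf))
    else:
        cand = scores[k]
        # ties below k would inflate the count past `allowed`; move up to
        # the first strictly larger score if so
        first = int(np.searchsorted(scores, cand, side="left"))
        if n - first > allowed:
            above = scores[scores > cand]
            matrix_cutoff = (
                float(above[0]) if above.size
                else float(np.nextafter(cand, np.inf))
            )
        else:
            matrix_cutoff = float(cand)
    core_cutoff = min(1.0, core_fraction * matrix_cutoff)
    return core_cutoff, matrix_cutoff


def calibrate_profile(
    pwms: Sequence["PWMatrix"],
    background: Sequence["Promoter"],
    target_fp_per_kb: float = DEFAULT_TARGET_FP_PER_KB,
    core_fraction: float = DEFAULT_CORE_FRACTION,
) -> ThresholdProfile:
    """Calibrated cutoffs for every matrix in a library."""
    return ThresholdProfile({
        pwm.matrix_id: calibrate_min_fp(
            pwm, background, target_fp_per_kb, core_fraction
        )
        for pwm in pwms
    })
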