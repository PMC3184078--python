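"""Estrogen response element (ERE) prediction on promoters.

The canonical full ERE is the degenerate palindrome GGTCA-nnn-TGACC: two
5-bp half-sites on opposite strands separated by a 3-nt unconstrained
spacer.  The detector reports every 13-mer whose Hamming distance to the
consensus over the 10 half-site positions is at most ``max_mismatch``.
Because the consensus is its own reverse complement, each site is reported
once, on the + strand.  Ambiguous bases (N) at half-site positions count
as mismatches, so N-runs cannot produce hits.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .motif_io import GeneRecord, Promoter
from .pwm_scan import encode_sequence

__all__ = ["EreHit", "ERE_HALF_SITE_5P", "ERE_HALF_SITE_3P",
           "ere_consensus", "scan_ere", "flag_ere_genes"]

ERE_HALF_SITE_5P = "GGTCA"
ERE_HALF_SITE_3P = "TGACC"
DEFAULT_MAX_MISMATCH = 2
DEFAULT_SPACER = 3


@dataclass(frozen=True)
class EreHit:
    """One predicted ERE (0-based half-open, promoter-relative, + strand)."""

    promoter_id: str
    start: int
    end: int
    mismatches: int
    strand: str = "+"


def ere_consensus(spacer: int = DEFAULT_SPACER) -> str:
    """Consensus pattern with an ``spacer``-long run of N in the middle."""
    return ERE_HALF_SITE_5P + "N" * spacer + ERE_HALF_SITE_3P


def _constrained(spacer: int) -> tuple[np.ndarray, np.ndarray]:
    """(positions, expected base codes) of the two half-sites."""
    pattern = ere_consensus(spacer)
    codes = encode_sequence(pattern)
    positions = np.flatnonzero(codes < 4)
    return positions, codes[positions]


def scan_ere(
    promoter: Promoter,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    spacer: int = DEFAULT_SPACER,
    pwm_mode: bool = False,
    half_site_cutoff: float = 0.85,
) -> list[EreHit]:
    """All ERE hits on one promoter, sorted by start.

    ``max_mismatch`` counts over the 10 half-site positions only; the
    spacer is unconstrained.  Overlapping hits are all reported.

    With ``pwm_mode`` each half-site is scored as a sharp 5-position
    frequency matrix (matrix similarity score) and a window is a hit when
    both half-sites reach ``half_site_cutoff``; ``max_mismatch`` is then
    ignored, but the reported mismatch count is still the Hamming
    distance to the consensus half-sites.
    """
    if not 0 <= max_mismatch <= 4:
        raise ValueError("max_mismatch must be in [0, 4]")
    if spacer < 0:
        raise ValueError("spacer must be non-negative")
    positions, expected = _constrained(spacer)
    length = 10 + spacer
    codes = encode_sequence(promoter.sequence)
    n = codes.shape[0] - length + 1
    if n <= 0:
        return []
    mismatches = np.zeros(n, dtype=np.int32)
    for pos, base in zip(positions, expected):
        mismatches += codes[pos:pos + n] != base
    if pwm_mode:
        keep = _pwm_mode_keep(codes, n, spacer, half_site_cutoff)
    else:
        keep = mismatches <= max_mismatch
    hits = []
    for j in np.flatnonzero(keep):
        start = int(j) - promoter.tss_offset
        hits.append(
            EreHit(promoter.promoter_id, start, start + length,
                   int(mismatches[j]))
        )
    return hits


def _half_site_pwm(consensus: str):
    from .motif_io import PWMatrix

    counts = np.full((5, 4), 5.0)
    for i, b in enumerate(consensus):
        counts[i, "ACGT".index(b)] = 85.0
    return PWMatrix.from_counts(f"ERE_{consensus}", counts)


def _pwm_mode_keep(codes: np.ndarray, n: int, spacer: int,
                   cutoff: float) -> np.ndarray:
    from .pwm_scan import _score_windows

    keep = np.ones(n, dtype=bool)
    for offset, half in ((0, ERE_HALF_SITE_5P), (5 + spacer, ERE_HALF_SITE_3P)):
        mss, _ = _score_windows(_half_site_pwm(half), codes)
        scores = mss[offset:offset + n]
        with np.errstate(invalid="ignore"):
            keep &= scores >= cutoff
    return keep


def scan_promoters_ere(
    promoters: Sequence[Promoter],
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    spacer: int = DEFAULT_SPACER,
) -> list[EreHit]:
    hits: list[EreHit] = []
    for p in promoters:
        hits.extend(scan_ere(p, max_mismatch, spacer))
    return hits


def flag_ere_genes(genes: Sequence[GeneRecord],
                   hits: Iterable[EreHit]) -> list[GeneRecord]:
    """Set each gene's ere_predicted flag from promoter-level ERE hits.

    A gene is ERE-positive iff at least one of its promoters carries at
    least one hit.  A hit on a promoter not owned by any gene is an error.
    """
    owned = {p for g in genes for p in g.promoter_ids}
    hit_promoters = {h.promoter_id for h in hits}
    orphans = sorted(hit_promoters - owned)
    if orphans:
        raise ValueError(
            f"ERE hits reference {len(orphans)} unknown promoter(s): "
            f"{', '.join(orphans[:10])}"
        )
    return [
        replace(g, ere_predicted=any(
            p in hit_promoters for p in g.promoter_ids))
        for g in genes
    ]
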