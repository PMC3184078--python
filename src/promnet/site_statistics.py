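"""Positional statistics of predicted sites.

Covers three summaries used to characterise the regulatory landscape of a
promoter set: (1) the gap between each TFBS and its closest ERE on the
same promoter, with a fixed-width histogram and per-TF minima; (2) a
Gaussian-kernel density of TFBS positions relative to the TSS on an even
grid; (3) the fraction of genes in a group annotated with each functional
term (a plain summary over a user-supplied annotation table).
"""

from __future__ import annotations

import csv
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .ere_finder import EreHit
from .pwm_scan import SiteHit

__all__ = [
    "DistanceRecord",
    "interval_gap",
    "tfbs_ere_distances",
    "distance_summary",
    "DistanceSummary",
    "tss_positional_density",
    "silverman_bandwidth",
    "term_fractions",
]

TSS_WINDOW = (-1000.0, 200.0)


@dataclass(frozen=True)
class DistanceRecord:
    """A TFBS paired with its closest ERE on the same promoter.

    ``distance`` is the nucleotide gap between the two half-open
    intervals (0 when they intersect); ``complete_overlap`` means one
    interval contains the other.
    """

    matrix_id: str
    promoter_id: str
    tfbs_interval: tuple[int, int]
    ere_interval: tuple[int, int]
    distance: int
    complete_overlap: bool


def interval_gap(a: tuple[int, int], b: tuple[int, int]) -> int:
    """Gap between half-open intervals [a0,a1) and [b0,b1); 0 if they
    intersect."""
    return max(0, b[0] - a[1], a[0] - b[1])


def _contains(outer: tuple[int, int], inner: tuple[int, int]) -> bool:
    return outer[0] <= inner[0] and inner[1] <= outer[1]


def tfbs_ere_distances(
    tfbs_hits: Iterable[SiteHit],
    ere_hits: Iterable[EreHit],
) -> list[DistanceRecord]:
    """One record per TFBS on an ERE-bearing promoter: its closest ERE.

    Promoters without any ERE contribute nothing.  Ties between equally
    close EREs resolve to the ERE with the smaller start.
    """
    eres: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for e in ere_hits:
        eres[e.promoter_id].append((e.start, e.end))
    for intervals in eres.values():
        intervals.sort()
    records = []
    for h in tfbs_hits:
        candidates = eres.get(h.promoter_id)
        if not candidates:
            continue
        tfbs = (h.start, h.end)
        best = min(candidates, key=lambda iv: (interval_gap(tfbs, iv), iv[0]))
        gap = interval_gap(tfbs, best)
        records.append(
            DistanceRecord(
                h.matrix_id, h.promoter_id, tfbs, best, gap,
                _contains(best, tfbs) or _contains(tfbs, best),
            )
        )
    return records


@dataclass
class DistanceSummary:
    bin_edges: np.ndarray          # k+1 edges [0, w, 2w, ...]
    counts: np.ndarray             # k bin counts
    cumulative: np.ndarray         # running totals, non-decreasing
    per_matrix_min: dict[str, int]  # minimum distance per matrix / TF


def distance_summary(
    records: Sequence[DistanceRecord],
    bin_width: int = 50,
    matrix_tf_map: Mapping[str, Sequence[str]] | None = None,
) -> DistanceSummary:
    """Histogram of TFBS-to-closest-ERE distances in ``bin_width`` bins,
    cumulative counts, and the minimum distance per matrix (or per TF when
    a matrix->TF map is supplied)."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if not records:
        return DistanceSummary(np.array([0.0]), np.empty(0, dtype=int),
                               np.empty(0, dtype=int), {})
    distances = np.array([r.distance for r in records])
    top = (int(distances.max()) // bin_width + 1) * bin_width
    edges = np.arange(0, top + bin_width, bin_width, dtype=float)
    counts, _ = np.histogram(distances, bins=edges)
    minima: dict[str, int] = {}
    for r in records:
        keys = (matrix_tf_map[r.matrix_id] if matrix_tf_map is not None
                else (r.matrix_id,))
        for key in keys:
            if key not in minima or r.distance < minima[key]:
                minima[key] = r.distance
    return DistanceSummary(edges, counts, np.cumsum(counts), minima)


def silverman_bandwidth(values: np.ndarray) -> float:
    """Silverman's rule-of-thumb bandwidth (the R ``bw.nrd0`` variant):
    0.9 min(sd, IQR/1.34) n^{-1/5}, with fallbacks for degenerate spread."""
    values = np.asarray(values, dtype=float)
    n = values.size
    sd = float(values.std(ddof=1)) if n > 1 else 0.0
    q75, q25 = np.percentile(values, [75, 25])
    iqr = float(q75 - q25)
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    if spread <= 0:
        spread = sd if sd > 0 else max(abs(float(values[0])), 1.0)
    return 0.9 * spread * n ** (-0.2)


def tss_positional_density(
    hits: Sequence[SiteHit],
    grid_points: int = 512,
    bandwidth: float | None = None,
    window: tuple[float, float] = TSS_WINDOW,
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian-kernel density of TFBS midpoints relative to the TSS.

    Evaluated on an even ``grid_points`` grid over ``window`` and
    renormalised so the trapezoidal integral over the grid is exactly 1
    (kernel mass falling outside the window is folded back in).  The
    default bandwidth follows Silverman's rule.
    """
    if len(hits) < 2:
        raise ValueError("need at least 2 hits for a density estimate")
    mids = np.array([(h.start + h.end) / 2.0 for h in hits])
    h = silverman_bandwidth(mids) if bandwidth is None else float(bandwidth)
    if h <= 0:
        raise ValueError("bandwidth must be positive")
    grid = np.linspace(window[0], window[1], grid_points)
    z = (grid[None, :] - mids[:, None]) / h
    density = np.exp(-0.5 * z**2).sum(axis=0) / (
        mids.size * h * np.sqrt(2 * np.pi)
    )
    area = np.trapezoid(density, grid)
    if area <= 0:
        raise ValueError("all probability mass falls outside the window")
    return grid, density / area


def term_fractions(
    group_genes: Sequence[str],
    annotation: Mapping[str, Iterable[str]],
) -> dict[str, float]:
    """fraction(term) = |genes in group carrying term| / |group|.

    Genes absent from the annotation count as unannotated (they stay in
    the denominator).  Terms never seen on a group gene are omitted.
    """
    if not group_genes:
        raise ValueError("empty gene group")
    n = len(group_genes)
    counts: dict[str, int] = defaultdict(int)
    for gene in group_genes:
        for term in set(annotation.get(gene, ())):
            counts[term] += 1
    return {term: counts[term] / n for term in sorted(counts)}


# ---------------------------------------------------------------------------
# TSV output


def write_distance_records(records: Sequence[DistanceRecord], path) -> None:
    with Path(path).open("w") as fh:
        fh.write(
            "matrix_id\tpromoter_id\ttfbs_start\ttfbs_end\tere_start\t"
            "ere_end\tdistance\tcomplete_overlap\n"
        )
        for r in records:
            fh.write(
                f"{r.matrix_id}\t{r.promoter_id}\t{r.tfbs_interval[0]}\t"
                f"{r.tfbs_interval[1]}\t{r.ere_interval[0]}\t"
                f"{r.ere_interval[1]}\t{r.distance}\t"
                f"{int(r.complete_overlap)}\n"
            )


def write_distance_summary(summary: DistanceSummary, path) -> None:
    with Path(path).open("w") as fh:
        fh.write("bin_start\tbin_end\tcount\tcumulative\n")
        for i, (c, cum) in enumerate(zip(summary.counts, summary.cumulative)):
            fh.write(
                f"{int(summary.bin_edges[i])}\t"
                f"{int(summary.bin_edges[i + 1])}\t{c}\t{cum}\n"
            )


def write_density(grid: np.ndarray, density: np.ndarray, path) -> None:
    with Path(path).open("w") as fh:
        fh.write("position\tdensity\n")
        for x, d in zip(grid, density):
            fh.write(f"{x:.4f}\t{d:.8e}\n")


def write_term_fractions(fractions: Mapping[str, float], path) -> None:
    """Fractions to 2 decimals plus the rounded percentage."""
    with Path(path).open("w") as fh:
        fh.write("term\tfraction\tpercent\n")
        for term in sorted(fractions):
            f = fractions[term]
            fh.write(f"{term}\t{f:.2f}\t{round(100 * f):d}\n")


def read_annotation_table(path) -> dict[str, set[str]]:
    """Annotation TSV (gene_id, term; one row per pair) -> gene -> terms."""
    annotation: dict[str, set[str]] = defaultdict(set)
    with Path(path).open() as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            annotation[row["gene_id"]].add(row["term"])
    return dict(annotation)
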