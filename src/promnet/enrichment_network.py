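"""Motif over-representation, TF-gene network reconstruction and ranking.

The over-representation index (ORI) of a matrix compares its site density
and promoter coverage in a target promoter set against a background set:

    ORI = [(t + p) / T_kb] / [(b + p) / B_kb] * [(cov_t + e) / (cov_b + e)]

with t, b the hit counts, T_kb, B_kb the total promoter lengths in kb,
cov the fraction of promoters carrying at least one hit, p a pseudocount
(default 1) and e = 1 / (number of background promoters).  The density
ratio captures per-base enrichment, the coverage ratio guards against a
single promoter stacked with repeats; the pseudocounts keep the index
finite and scale-invariant.  Matrices with ORI >= 2 (default) are deemed
enriched and contribute edges TF -> gene wherever a mapped matrix has a
site on one of the gene's promoters.  TFs are then ranked by out-degree
(number of distinct putative target genes) and only TFs at or above the
80th percentile of the out-degree distribution are retained as candidate
regulators.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

from .motif_io import GeneRecord, Promoter
from .pwm_scan import SiteHit

__all__ = [
    "OriRecord",
    "NetworkEdge",
    "TfRanking",
    "compute_ori",
    "build_network",
    "rank_tfs",
    "tf_set_algebra",
    "nearest_rank_percentile",
    "write_ori_table",
    "write_edges",
    "write_ranking",
]

DEFAULT_ORI_THRESHOLD = 2.0
DEFAULT_PERCENTILE = 80.0


@dataclass(frozen=True)
class OriRecord:
    """Per-matrix enrichment summary of target versus background."""

    matrix_id: str
    target_hits: int
    background_hits: int
    target_len_kb: float
    background_len_kb: float
    target_coverage: float
    background_coverage: float
    ori: float
    enriched: bool


@dataclass(frozen=True)
class NetworkEdge:
    """TF -> gene link supported by >= 1 enriched matrix with a site."""

    tf_id: str
    gene_id: str
    supporting_matrix_ids: tuple[str, ...]


@dataclass(frozen=True)
class TfRanking:
    tf_id: str
    out_degree: int
    rank: int
    retained: bool


class TfSets(NamedTuple):
    common: list[str]
    unique_a: list[str]
    unique_b: list[str]
    union: list[str]


def compute_ori(
    target_hits: Iterable[SiteHit],
    target_promoters: Sequence[Promoter],
    background_hits: Iterable[SiteHit],
    background_promoters: Sequence[Promoter],
    pseudocount: float = 1.0,
    ori_threshold: float = DEFAULT_ORI_THRESHOLD,
) -> list[OriRecord]:
    """One OriRecord per matrix appearing in either hit list, sorted by
    descending ORI then matrix ID."""
    if not target_promoters or not background_promoters:
        raise ValueError("target and background promoter sets must be non-empty")
    t_kb = sum(p.length for p in target_promoters) / 1000.0
    b_kb = sum(p.length for p in background_promoters) / 1000.0
    if t_kb <= 0 or b_kb <= 0:
        raise ValueError("promoter sets have zero total length")
    eps = 1.0 / len(background_promoters)

    def tally(hits):
        counts: dict[str, int] = defaultdict(int)
        covered: dict[str, set[str]] = defaultdict(set)
        for h in hits:
            counts[h.matrix_id] += 1
            covered[h.matrix_id].add(h.promoter_id)
        return counts, covered

    t_counts, t_cov = tally(target_hits)
    b_counts, b_cov = tally(background_hits)
    records = []
    for matrix_id in sorted(set(t_counts) | set(b_counts)):
        t = t_counts.get(matrix_id, 0)
        b = b_counts.get(matrix_id, 0)
        cov_t = len(t_cov.get(matrix_id, ())) / len(target_promoters)
        cov_b = len(b_cov.get(matrix_id, ())) / len(background_promoters)
        density_ratio = ((t + pseudocount) / t_kb) / ((b + pseudocount) / b_kb)
        coverage_ratio = (cov_t + eps) / (cov_b + eps)
        ori = density_ratio * coverage_ratio
        records.append(
            OriRecord(matrix_id, t, b, t_kb, b_kb, cov_t, cov_b,
                      ori, ori >= ori_threshold)
        )
    records.sort(key=lambda r: (-r.ori, r.matrix_id))
    return records


def build_network(
    enriched: Sequence[OriRecord],
    target_hits: Iterable[SiteHit],
    matrix_tf_map: Mapping[str, Sequence[str]],
    genes: Sequence[GeneRecord],
) -> list[NetworkEdge]:
    """Edges (tf, gene) for every enriched matrix with a site on one of the
    gene's promoters; supporting matrices listed sorted.  Non-enriched
    records in ``enriched`` are ignored, so the full ORI table may be
    passed directly."""
    enriched_ids = {r.matrix_id for r in enriched if r.enriched}
    missing = sorted(m for m in enriched_ids if m not in matrix_tf_map)
    if missing:
        raise KeyError(
            f"enriched matrices missing from the matrix->TF map: "
            f"{', '.join(missing[:10])}"
        )
    promoter_gene: dict[str, set[str]] = defaultdict(set)
    for g in genes:
        for p in g.promoter_ids:
            promoter_gene[p].add(g.gene_id)
    support: dict[tuple[str, str], set[str]] = defaultdict(set)
    for h in target_hits:
        if h.matrix_id not in enriched_ids:
            continue
        for gene_id in promoter_gene.get(h.promoter_id, ()):
            for tf_id in matrix_tf_map[h.matrix_id]:
                support[(tf_id, gene_id)].add(h.matrix_id)
    return [
        NetworkEdge(tf, gene, tuple(sorted(mats)))
        for (tf, gene), mats in sorted(support.items())
    ]


def nearest_rank_percentile(values: Sequence[float], percentile: float) -> float:
    """Nearest-rank percentile: the ceil(p/100 * n)-th smallest value."""
    if not values:
        raise ValueError("empty value list")
    if not 0 < percentile <= 100:
        raise ValueError("percentile must be in (0, 100]")
    ordered = sorted(values)
    idx = max(1, math.ceil(percentile / 100.0 * len(ordered)))
    return ordered[idx - 1]


def rank_tfs(edges: Sequence[NetworkEdge],
             percentile: float = DEFAULT_PERCENTILE) -> list[TfRanking]:
    """Rank TFs by out-degree (distinct regulated genes), descending.

    Ties are ordered by TF ID for determinism.  A TF is retained iff its
    out-degree is at or above the nearest-rank ``percentile`` of the
    out-degree multiset; ties at the threshold are all retained.
    """
    if not edges:
        raise ValueError("empty edge list: no TFs to rank")
    targets: dict[str, set[str]] = defaultdict(set)
    for e in edges:
        targets[e.tf_id].add(e.gene_id)
    degrees = {tf: len(gs) for tf, gs in targets.items()}
    threshold = nearest_rank_percentile(list(degrees.values()), percentile)
    ordered = sorted(degrees.items(), key=lambda kv: (-kv[1], kv[0]))
    return [
        TfRanking(tf, deg, rank, deg >= threshold)
        for rank, (tf, deg) in enumerate(ordered, start=1)
    ]


def tf_set_algebra(set_a: Iterable[str], set_b: Iterable[str]) -> TfSets:
    """Common / unique / union decomposition of two TF ID collections."""
    a, b = set(set_a), set(set_b)
    return TfSets(
        common=sorted(a & b),
        unique_a=sorted(a - b),
        unique_b=sorted(b - a),
        union=sorted(a | b),
    )


# ---------------------------------------------------------------------------
# TSV output (column-stable for diff-based comparison)


def write_ori_table(records: Sequence[OriRecord], path) -> None:
    with Path(path).open("w") as fh:
        fh.write(
            "matrix_id\ttarget_hits\tbackground_hits\ttarget_len_kb\t"
            "background_len_kb\ttarget_coverage\tbackground_coverage\t"
            "ori\tenriched\n"
        )
        for r in records:
            fh.write(
                f"{r.matrix_id}\t{r.target_hits}\t{r.background_hits}\t"
                f"{r.target_len_kb:.4f}\t{r.background_len_kb:.4f}\t"
                f"{r.target_coverage:.6f}\t{r.background_coverage:.6f}\t"
                f"{r.ori:.6f}\t{int(r.enriched)}\n"
            )


def write_edges(edges: Sequence[NetworkEdge], path) -> None:
    with Path(path).open("w") as fh:
        fh.write("tf_id\tgene_id\tsupporting_matrix_ids\n")
        for e in edges:
            fh.write(
                f"{e.tf_id}\t{e.gene_id}\t"
                f"{','.join(e.supporting_matrix_ids)}\n"
            )


def read_edges(path) -> list[NetworkEdge]:
    import csv

    edges = []
    with Path(path).open() as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            edges.append(
                NetworkEdge(
                    row["tf_id"], row["gene_id"],
                    tuple(t for t in row["supporting_matrix_ids"].split(",")
                          if t),
                )
            )
    return edges


def write_ranking(ranking: Sequence[TfRanking], path) -> None:
    with Path(path).open("w") as fh:
        fh.write("tf_id\tout_degree\trank\tretained\n")
        for r in ranking:
            fh.write(f"{r.tf_id}\t{r.out_degree}\t{r.rank}\t{int(r.retained)}\n")
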