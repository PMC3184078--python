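"""Partition genes into four groups by ERE prediction and estrogen evidence.

Group 1: ERE predicted and experimental evidence of estrogen response.
Group 2: ERE predicted, no evidence.
Group 3: no ERE predicted, evidence.
Group 4: neither.

Groups 1 and 3 together form the experimentally estrogen-controlled set.
"""

from __future__ import annotations

from typing import Mapping, Sequence

from .motif_io import GeneRecord

__all__ = ["partition_genes", "experimental_union", "EXPERIMENTAL_GROUPS"]

GROUPS = (1, 2, 3, 4)
EXPERIMENTAL_GROUPS = (1, 3)


def partition_genes(genes: Sequence[GeneRecord]) -> dict[int, list[str]]:
    """Map group number -> sorted gene IDs; groups are disjoint and cover
    the input.  Raises if any gene has an unset flag or a duplicate ID.
    """
    seen: set[str] = set()
    out: dict[int, list[str]] = {g: [] for g in GROUPS}
    for gene in genes:
        if gene.gene_id in seen:
            raise ValueError(f"duplicate gene ID {gene.gene_id!r}")
        seen.add(gene.gene_id)
        out[gene.group].append(gene.gene_id)  # raises if a flag is unset
    for g in GROUPS:
        out[g].sort()
    return out


def experimental_union(groups: Mapping[int, Sequence[str]]) -> list[str]:
    """Sorted union of groups 1 and 3 (experimentally estrogen-controlled).

    The two groups must be disjoint (they are complementary in the ERE
    flag); an overlap indicates a corrupted partition and raises.
    """
    a = set(groups.get(1, ()))
    b = set(groups.get(3, ()))
    overlap = a & b
    if overlap:
        raise ValueError(
            f"groups 1 and 3 overlap on {len(overlap)} gene(s): "
            f"{', '.join(sorted(overlap)[:10])}"
        )
    return sorted(a | b)
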