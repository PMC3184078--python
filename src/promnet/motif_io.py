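"""Readers and writers for the pipeline's external formats.

Handles position-frequency-matrix libraries (JASPAR PFM and TRANSFAC flat
files, parsed through :mod:`Bio.motifs`), promoter FASTA, the gene table,
matrix-to-TF maps, and BED6 export of predicted sites.

Coordinate convention: all site positions are 0-based half-open intervals
relative to the transcription start site (TSS at 0, negative = upstream).
BED output shifts coordinates by +1000 so that a standard [-1000, +200]
promoter window maps onto non-negative coordinates.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import motifs as bio_motifs

from .pwm_scan import core_window_start, information_vector

ALPHABET = "ACGT"
_VALID_CHARS = frozenset("ACGTN")

__all__ = [
    "ALPHABET",
    "PWMatrix",
    "Promoter",
    "GeneRecord",
    "PwmParseError",
    "read_pwm_library",
    "read_promoters",
    "read_gene_table",
    "read_matrix_tf_map",
    "write_sites_bed",
    "read_sites_bed",
    "write_gene_groups",
]


class PwmParseError(ValueError):
    """Raised when a matrix library record cannot be interpreted."""


@dataclass
class PWMatrix:
    """A position-frequency matrix with its derived scanning quantities.

    ``counts`` is an L x 4 array over A,C,G,T.  ``freqs`` is the
    pseudocount-regularised row normalisation of ``counts``, ``info`` the
    per-position information vector I(i) = sum_b f(i,b) ln(4 f(i,b)), and
    ``core_start`` the left edge of the most informative 5-position window
    (ties broken towards the 5' end).
    """

    matrix_id: str
    counts: np.ndarray
    freqs: np.ndarray
    info: np.ndarray
    core_start: int
    tf_ids: tuple[str, ...] = ()
    name: str = ""

    CORE_LENGTH = 5

    @classmethod
    def from_counts(
        cls,
        matrix_id: str,
        counts,
        pseudocount: float = 0.01,
        tf_ids: Sequence[str] = (),
        name: str = "",
    ) -> "PWMatrix":
        counts = np.asarray(counts, dtype=float)
        if counts.ndim != 2 or counts.shape[1] != 4:
            raise PwmParseError(
                f"matrix {matrix_id!r}: expected an L x 4 count array, "
                f"got shape {counts.shape}"
            )
        if counts.shape[0] < cls.CORE_LENGTH:
            raise PwmParseError(
                f"matrix {matrix_id!r}: length {counts.shape[0]} < "
                f"{cls.CORE_LENGTH} (no core window exists)"
            )
        if np.any(counts < 0):
            raise PwmParseError(f"matrix {matrix_id!r}: negative counts")
        reg = counts + pseudocount
        row_sums = reg.sum(axis=1)
        if np.any(row_sums <= 0):
            bad = int(np.flatnonzero(row_sums <= 0)[0]) + 1
            raise PwmParseError(
                f"matrix {matrix_id!r}: position {bad} has zero total count "
                "and pseudocount 0"
            )
        freqs = reg / row_sums[:, None]
        info = information_vector(freqs)
        return cls(
            matrix_id=matrix_id,
            counts=counts,
            freqs=freqs,
            info=info,
            core_start=core_window_start(info),
            tf_ids=tuple(tf_ids),
            name=name,
        )

    @property
    def length(self) -> int:
        return self.counts.shape[0]

    def reverse_complement(self) -> "PWMatrix":
        """The matrix scoring the reverse-complement strand.

        Frequencies are mirrored exactly (no re-normalisation) so forward
        and reverse scores agree bit-for-bit.
        """
        return PWMatrix(
            matrix_id=self.matrix_id,
            counts=self.counts[::-1, ::-1].copy(),
            freqs=self.freqs[::-1, ::-1].copy(),
            info=self.info[::-1].copy(),
            core_start=self.length - self.CORE_LENGTH - self.core_start,
            tf_ids=self.tf_ids,
            name=self.name,
        )


@dataclass
class Promoter:
    """One promoter sequence with the TSS anchored at ``tss_offset``.

    The relative coordinate of sequence index j is j - tss_offset; the
    default window [-1000, +200] therefore has tss_offset 1000.
    """

    promoter_id: str
    gene_id: str
    sequence: str
    tss_offset: int = 1000

    def __post_init__(self) -> None:
        if not 0 <= self.tss_offset <= len(self.sequence):
            raise ValueError(
                f"promoter {self.promoter_id!r}: tss_offset "
                f"{self.tss_offset} outside sequence of length "
                f"{len(self.sequence)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class GeneRecord:
    """A gene with its promoters and the two estrogen-related flags.

    ``evidence`` marks documented estrogen responsiveness (curated input
    data); ``ere_predicted`` is derived from promoter scanning.  The group
    label follows (ERE, evidence): (T,T)->1, (T,F)->2, (F,T)->3, (F,F)->4.
    """

    gene_id: str
    promoter_ids: tuple[str, ...]
    evidence: bool | None = None
    ere_predicted: bool | None = None

    @property
    def group(self) -> int:
        if self.ere_predicted is None or self.evidence is None:
            missing = [
                n for n, v in (
                    ("ere_predicted", self.ere_predicted),
                    ("evidence", self.evidence),
                ) if v is None
            ]
            raise ValueError(
                f"gene {self.gene_id!r}: flag(s) {', '.join(missing)} unset; "
                "group is undefined"
            )
        return {(True, True): 1, (True, False): 2,
                (False, True): 3, (False, False): 4}[
                    (self.ere_predicted, self.evidence)]

    def with_flags(self, *, ere_predicted=None, evidence=None) -> "GeneRecord":
        out = self
        if ere_predicted is not None:
            out = replace(out, ere_predicted=bool(ere_predicted))
        if evidence is not None:
            out = replace(out, evidence=bool(evidence))
        return out


# ---------------------------------------------------------------------------
# PWM libraries


def read_pwm_library(
    path,
    format: str = "jaspar",
    pseudocount: float = 0.01,
) -> list[PWMatrix]:
    """Read a matrix library in JASPAR PFM or TRANSFAC flat-file format.

    Every matrix is regularised by adding ``pseudocount`` to each cell
    before row normalisation; file order is preserved.
    """
    fmt = format.lower()
    if fmt not in ("jaspar", "transfac"):
        raise ValueError(f"unknown PWM library format {format!r}")
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    path = Path(path)
    with path.open() as handle:
        try:
            parsed = bio_motifs.parse(
                handle, "jaspar" if fmt == "jaspar" else "TRANSFAC"
            )
            parsed = list(parsed)
        except PwmParseError:
            raise
        except Exception as exc:  # noqa: BLE001 - re-raise with file context
            raise PwmParseError(f"{path}: malformed {fmt} record: {exc}") from exc
    out: list[PWMatrix] = []
    for idx, motif in enumerate(parsed, start=1):
        if fmt == "jaspar":
            matrix_id = getattr(motif, "matrix_id", None) or motif.name
            name = motif.name or ""
        else:
            matrix_id = motif.get("AC") or motif.get("ID")
            name = motif.get("ID") or ""
        if not matrix_id:
            raise PwmParseError(f"{path}: record {idx} has no identifier")
        counts = np.column_stack([motif.counts[b] for b in ALPHABET])
        out.append(
            PWMatrix.from_counts(
                str(matrix_id), counts, pseudocount=pseudocount, name=str(name)
            )
        )
    if not out:
        raise PwmParseError(f"{path}: no matrix records found")
    return out


def write_pwm_library_jaspar(matrices: Iterable[PWMatrix], path) -> None:
    """Write matrices as JASPAR PFM text (integer-rounded counts)."""
    with Path(path).open("w") as fh:
        for m in matrices:
            fh.write(f">{m.matrix_id} {m.name or m.matrix_id}\n")
            for b, col in zip(ALPHABET, m.counts.T):
                cells = " ".join(f"{int(round(c)):6d}" for c in col)
                fh.write(f"{b} [{cells} ]\n")


# ---------------------------------------------------------------------------
# Promoters


def read_promoters(path, tss_offset: int = 1000) -> list[Promoter]:
    """Read promoter FASTA; IDs are ``geneID|promoterID`` or a plain
    promoter ID (then the gene ID defaults to the promoter ID).

    Sequences are upper-cased; characters outside A,C,G,T,N are rejected.
    """
    from Bio import SeqIO

    path = Path(path)
    promoters: list[Promoter] = []
    seen: set[str] = set()
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq).upper()
        bad = set(seq) - _VALID_CHARS
        if bad:
            raise ValueError(
                f"{path}: record {record.id!r} contains invalid characters "
                f"{sorted(bad)}"
            )
        if "|" in record.id:
            gene_id, promoter_id = record.id.split("|", 1)
        else:
            gene_id = promoter_id = record.id
        if promoter_id in seen:
            raise ValueError(f"{path}: duplicate promoter ID {promoter_id!r}")
        seen.add(promoter_id)
        promoters.append(Promoter(promoter_id, gene_id, seq, tss_offset))
    if not promoters:
        raise ValueError(f"{path}: no FASTA records found")
    return promoters


def write_promoters(promoters: Iterable[Promoter], path) -> None:
    with Path(path).open("w") as fh:
        for p in promoters:
            header = (
                p.promoter_id if p.gene_id == p.promoter_id
                else f"{p.gene_id}|{p.promoter_id}"
            )
            fh.write(f">{header}\n")
            for i in range(0, len(p.sequence), 70):
                fh.write(p.sequence[i:i + 70] + "\n")


# ---------------------------------------------------------------------------
# Tables


def read_gene_table(path, known_promoter_ids=None) -> list[GeneRecord]:
    """Read the gene table TSV (gene_id, promoter_ids, evidence).

    ``promoter_ids`` is comma-separated; ``evidence`` is 0/1.  If
    ``known_promoter_ids`` is given, any reference to an unknown promoter
    raises with the full offender list.
    """
    path = Path(path)
    genes: list[GeneRecord] = []
    with path.open() as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"gene_id", "promoter_ids", "evidence"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ValueError(
                f"{path}: expected columns {sorted(required)}, "
                f"got {reader.fieldnames}"
            )
        for row in reader:
            promoter_ids = tuple(
                p for p in row["promoter_ids"].split(",") if p
            )
            genes.append(
                GeneRecord(
                    gene_id=row["gene_id"],
                    promoter_ids=promoter_ids,
                    evidence=bool(int(row["evidence"])),
                )
            )
    if known_promoter_ids is not None:
        known = set(known_promoter_ids)
        offenders = [
            (g.gene_id, p)
            for g in genes for p in g.promoter_ids if p not in known
        ]
        if offenders:
            listing = ", ".join(f"{g}->{p}" for g, p in offenders[:20])
            raise ValueError(
                f"{path}: {len(offenders)} unknown promoter reference(s): "
                f"{listing}"
            )
    return genes


def write_gene_table(genes: Iterable[GeneRecord], path) -> None:
    with Path(path).open("w") as fh:
        fh.write("gene_id\tpromoter_ids\tevidence\n")
        for g in genes:
            fh.write(
                f"{g.gene_id}\t{','.join(g.promoter_ids)}\t"
                f"{int(bool(g.evidence))}\n"
            )


def write_gene_groups(genes: Iterable[GeneRecord], path) -> None:
    """Group-assignment TSV: gene_id, ere_predicted, evidence, group."""
    with Path(path).open("w") as fh:
        fh.write("gene_id\tere_predicted\tevidence\tgroup\n")
        for g in sorted(genes, key=lambda g: g.gene_id):
            fh.write(
                f"{g.gene_id}\t{int(bool(g.ere_predicted))}\t"
                f"{int(bool(g.evidence))}\t{g.group}\n"
            )


def read_matrix_tf_map(path) -> dict[str, tuple[str, ...]]:
    """Read the matrix->TF map TSV (matrix_id, tf_ids comma-separated)."""
    path = Path(path)
    mapping: dict[str, tuple[str, ...]] = {}
    with path.open() as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"matrix_id", "tf_ids"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ValueError(
                f"{path}: expected columns {sorted(required)}, "
                f"got {reader.fieldnames}"
            )
        for row in reader:
            mapping[row["matrix_id"]] = tuple(
                t for t in row["tf_ids"].split(",") if t
            )
    return mapping


def write_matrix_tf_map(mapping: dict[str, Sequence[str]], path) -> None:
    with Path(path).open("w") as fh:
        fh.write("matrix_id\ttf_ids\n")
        for matrix_id in sorted(mapping):
            fh.write(f"{matrix_id}\t{','.join(mapping[matrix_id])}\n")


# ---------------------------------------------------------------------------
# BED site export

BED_SHIFT = 1000


def write_sites_bed(hits, path, shift: int = BED_SHIFT) -> None:
    """Write site hits as BED6 in shifted promoter coordinates.

    Accepts TFBS hits (score column = round(1000 * matrix similarity)) and
    ERE hits (score column = mismatch count); both carry 0-based half-open
    promoter-relative intervals which are shifted by ``shift`` so starts
    are non-negative for the standard [-1000, +200] window.
    """
    with Path(path).open("w") as fh:
        for h in hits:
            if hasattr(h, "mss"):
                name, score = h.matrix_id, int(round(1000 * h.mss))
            else:
                name, score = "ERE", int(h.mismatches)
            fh.write(
                f"{h.promoter_id}\t{h.start + shift}\t{h.end + shift}\t"
                f"{name}\t{score}\t{h.strand}\n"
            )


def read_sites_bed(path, shift: int = BED_SHIFT):
    """Read a BED6 site file back into plain tuples.

    Returns (promoter_id, start, end, name, score, strand) with
    promoter-relative coordinates (the +shift of the writer undone) and the
    raw integer score column.
    """
    rows = []
    with Path(path).open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            chrom, start, end, name, score, strand = line.split("\t")
            rows.append(
                (chrom, int(start) - shift, int(end) - shift,
                 name, int(score), strand)
            )
    return rows
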