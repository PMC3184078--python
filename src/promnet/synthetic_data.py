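"""Seeded synthetic cohorts with planted motifs, EREs and evidence flags.

The generator emulates the statistical structure the analysis assumes:
background promoters are i.i.d. draws from a stated base composition;
each matrix's consensus is planted into the background at a Poisson rate
per kilobase and into a designated fraction of target promoters at that
rate times an enrichment ratio; full EREs (consensus with at most one
mutated half-site base) are planted into a fraction of target promoters;
estrogen-evidence flags are drawn Bernoulli conditional on ERE-carrier
status.  Every planted site and flag is recorded in a truth ledger so
recovery can be measured against ground truth.

Promoters of non-ERE-carrier target genes are scrubbed of chance ERE
matches (within the detector's mismatch tolerance) so that, in
deterministic-flag mode, the scanned four-group partition reproduces the
configured group sizes exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .ere_finder import ERE_HALF_SITE_3P, ERE_HALF_SITE_5P, ere_consensus
from .motif_io import (
    GeneRecord,
    Promoter,
    PWMatrix,
    write_gene_table,
    write_matrix_tf_map,
    write_promoters,
    write_pwm_library_jaspar,
)
from .pwm_scan import encode_sequence

__all__ = [
    "MatrixSpec",
    "CohortSpec",
    "Cohort",
    "generate_cohort",
    "reference_cohort_spec",
    "random_consensus_set",
]

BASES = "ACGT"
_PLACEMENT_TRIES = 200
_SCRUB_ROUNDS = 60

# Count profile used when turning a consensus into a position-frequency
# matrix: the consensus base is strongly but not perfectly preferred, so
# thresholded scanning (not just exact matching) is exercised.
CONSENSUS_COUNT = 85
OFF_CONSENSUS_COUNT = 5


@dataclass(frozen=True)
class MatrixSpec:
    """Planting parameters for one matrix/TF pair.

    ``background_rate_per_kb`` is the Poisson planting rate in every
    background promoter; carrier target promoters (a random
    ``fraction_of_targets_carrying`` share) receive the rate multiplied by
    ``target_enrichment_ratio``.  ``designated`` marks matrices planted at
    high enrichment whose recovery the cohort is meant to test.
    """

    matrix_id: str
    tf_id: str
    consensus: str
    background_rate_per_kb: float
    target_enrichment_ratio: float
    fraction_of_targets_carrying: float
    designated: bool = False

    def __post_init__(self) -> None:
        if set(self.consensus) - set(BASES):
            raise ValueError(
                f"matrix {self.matrix_id}: consensus must be over ACGT"
            )
        if self.background_rate_per_kb < 0 or self.target_enrichment_ratio < 0:
            raise ValueError(
                f"matrix {self.matrix_id}: rates/ratios must be >= 0"
            )
        if not 0 <= self.fraction_of_targets_carrying <= 1:
            raise ValueError(
                f"matrix {self.matrix_id}: carrying fraction must be in [0,1]"
            )


@dataclass
class CohortSpec:
    """Full description of a synthetic cohort; seeded runs are
    bit-reproducible."""

    n_target_genes: int
    n_background_promoters: int
    promoter_length: int = 1200
    tss_offset: int = 1000
    base_composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    matrices: tuple[MatrixSpec, ...] = ()
    ere_fraction_of_targets: float = 0.2
    evidence_rate_given_ere: float = 0.2
    evidence_rate_given_no_ere: float = 0.25
    seed: int = 0
    deterministic_flags: bool = False
    site_mutation_prob: float = 0.1
    ere_mutation_prob: float = 0.5
    ere_spacer: int = 3
    ere_scrub_max_mismatch: int = 2

    def __post_init__(self) -> None:
        self.base_composition = tuple(float(p) for p in self.base_composition)
        self.matrices = tuple(
            m if isinstance(m, MatrixSpec) else MatrixSpec(**m)
            for m in self.matrices
        )
        if abs(sum(self.base_composition) - 1.0) > 1e-9:
            raise ValueError("base_composition must sum to 1")
        if len(self.base_composition) != 4:
            raise ValueError("base_composition needs 4 probabilities")
        for frac in (self.ere_fraction_of_targets,
                     self.evidence_rate_given_ere,
                     self.evidence_rate_given_no_ere):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must be in [0, 1]")
        if not 0 <= self.tss_offset <= self.promoter_length:
            raise ValueError("tss_offset outside promoter window")

    # -- config round-trip -------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["base_composition"] = list(self.base_composition)
        d["matrices"] = [dataclasses.asdict(m) for m in self.matrices]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        return cls(**d)

    def to_yaml(self, path) -> None:
        with Path(path).open("w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CohortSpec":
        with Path(path).open() as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class Cohort:
    """In-memory cohort plus the truth ledger of everything planted."""

    spec: CohortSpec
    pwms: list[PWMatrix]
    target_promoters: list[Promoter]
    background_promoters: list[Promoter]
    genes: list[GeneRecord]
    matrix_tf_map: dict[str, tuple[str, ...]]
    ledger: pd.DataFrame

    def write(self, outdir) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "pwm_library": outdir / "pwm_library.jaspar",
            "target_fasta": outdir / "target_promoters.fasta",
            "background_fasta": outdir / "background_promoters.fasta",
            "gene_table": outdir / "gene_table.tsv",
            "matrix_tf_map": outdir / "matrix_tf_map.tsv",
            "truth_ledger": outdir / "truth_ledger.tsv",
            "spec": outdir / "cohort_spec.yaml",
        }
        write_pwm_library_jaspar(self.pwms, paths["pwm_library"])
        write_promoters(self.target_promoters, paths["target_fasta"])
        write_promoters(self.background_promoters, paths["background_fasta"])
        write_gene_table(self.genes, paths["gene_table"])
        write_matrix_tf_map(self.matrix_tf_map, paths["matrix_tf_map"])
        self.ledger.to_csv(paths["truth_ledger"], sep="\t", index=False)
        self.spec.to_yaml(paths["spec"])
        return paths


# ---------------------------------------------------------------------------
# Consensus helpers


def consensus_to_counts(consensus: str) -> np.ndarray:
    counts = np.full((len(consensus), 4), OFF_CONSENSUS_COUNT, dtype=float)
    for i, b in enumerate(consensus):
        counts[i, BASES.index(b)] = CONSENSUS_COUNT
    return counts


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def _contains_ere_half_site(seq: str) -> bool:
    return ERE_HALF_SITE_5P in seq or ERE_HALF_SITE_3P in seq


def random_consensus_set(
    n: int,
    length: int,
    rng: np.random.Generator,
    min_distance: int = 3,
) -> list[str]:
    """Random consensus words, pairwise-dissimilar and ERE-free.

    Every pair (including reverse complements) differs in at least
    ``min_distance`` aligned positions, so one matrix cannot detect
    another's planted sites; ERE half-sites are excluded so motif planting
    cannot fabricate estrogen response elements.
    """
    chosen: list[str] = []
    for _ in range(20000):
        if len(chosen) == n:
            break
        word = "".join(BASES[i] for i in rng.integers(0, 4, size=length))
        if _contains_ere_half_site(word) or _contains_ere_half_site(_revcomp(word)):
            continue
        ok = True
        for other in chosen:
            for variant in (other, _revcomp(other)):
                dist = sum(a != b for a, b in zip(word, variant))
                if dist < min_distance:
                    ok = False
                    break
            if not ok:
                break
        if ok:
            chosen.append(word)
    if len(chosen) < n:
        raise RuntimeError("could not build a dissimilar consensus set")
    return chosen


# ---------------------------------------------------------------------------
# Sequence-level planting


def _plant(
    codes: np.ndarray,
    protected: np.ndarray,
    site_codes: np.ndarray,
    rng: np.random.Generator,
) -> int | None:
    """Write ``site_codes`` at a random position not touching protected
    bases; returns the start or None if no slot was found."""
    L = site_codes.shape[0]
    n = codes.shape[0]
    if n < L:
        return None
    for _ in range(_PLACEMENT_TRIES):
        start = int(rng.integers(0, n - L + 1))
        if not protected[start:start + L].any():
            codes[start:start + L] = site_codes
            protected[start:start + L] = True
            return start
    return None


def _mutate_one(site_codes: np.ndarray, positions: Sequence[int],
                rng: np.random.Generator) -> int:
    """Mutate one of ``positions`` to a different base; returns position."""
    pos = int(rng.choice(np.asarray(positions)))
    old = site_codes[pos]
    site_codes[pos] = (old + 1 + rng.integers(0, 3)) % 4
    return pos


def _scrub_ere(
    codes: np.ndarray,
    protected: np.ndarray,
    rng: np.random.Generator,
    max_mismatch: int,
    spacer: int,
) -> None:
    """Destroy every chance ERE match with <= max_mismatch mismatches.

    Mutates half-site positions that currently match the consensus,
    preferring unprotected bases so planted motif sites survive.
    """
    pattern = encode_sequence(ere_consensus(spacer))
    constrained = np.flatnonzero(pattern < 4)
    length = pattern.shape[0]
    n = codes.shape[0] - length + 1
    if n <= 0:
        return
    for _ in range(_SCRUB_ROUNDS):
        mismatches = np.zeros(n, dtype=np.int32)
        for pos in constrained:
            mismatches += codes[pos:pos + n] != pattern[pos]
        starts = np.flatnonzero(mismatches <= max_mismatch)
        if starts.size == 0:
            return
        for j in starts:
            need = max_mismatch + 1 - int(mismatches[j])
            if need <= 0:
                continue
            # positions inside this window still matching the consensus
            matching = [int(j + pos) for pos in constrained
                        if codes[j + pos] == pattern[pos]]
            free = [p for p in matching if not protected[p]]
            pool = free if len(free) >= need else matching
            pool = rng.permutation(np.asarray(pool, dtype=int))
            for p in pool[:need]:
                base = int(codes[p])
                codes[p] = (base + 1 + int(rng.integers(0, 3))) % 4
    raise RuntimeError("ERE scrubbing did not converge")


def _codes_to_str(codes: np.ndarray) -> str:
    return "".join(BASES[c] for c in codes)


# ---------------------------------------------------------------------------
# Cohort generation


def generate_cohort(spec: CohortSpec, outdir=None) -> Cohort:
    """Generate a full cohort from ``spec``; optionally write it to disk.

    Raises if planted sites cannot be placed without overlap (sequence
    capacity exceeded).
    """
    rng = np.random.default_rng(spec.seed)
    comp = np.asarray(spec.base_composition)
    n_targets = spec.n_target_genes
    length = spec.promoter_length

    pwms = [
        PWMatrix.from_counts(
            m.matrix_id, consensus_to_counts(m.consensus),
            tf_ids=(m.tf_id,), name=m.tf_id,
        )
        for m in spec.matrices
    ]
    matrix_tf_map = {m.matrix_id: (m.tf_id,) for m in spec.matrices}

    # -- flags -------------------------------------------------------------
    order = rng.permutation(n_targets)
    if spec.deterministic_flags:
        n_ere = int(round(spec.ere_fraction_of_targets * n_targets))
        ere_carrier = np.zeros(n_targets, dtype=bool)
        ere_carrier[order[:n_ere]] = True
        evidence = np.zeros(n_targets, dtype=bool)
        carriers = np.flatnonzero(ere_carrier)
        noncarriers = np.flatnonzero(~ere_carrier)
        n_ev_c = int(round(spec.evidence_rate_given_ere * carriers.size))
        n_ev_n = int(round(spec.evidence_rate_given_no_ere * noncarriers.size))
        evidence[rng.permutation(carriers)[:n_ev_c]] = True
        evidence[rng.permutation(noncarriers)[:n_ev_n]] = True
    else:
        ere_carrier = rng.random(n_targets) < spec.ere_fraction_of_targets
        p_ev = np.where(ere_carrier, spec.evidence_rate_given_ere,
                        spec.evidence_rate_given_no_ere)
        evidence = rng.random(n_targets) < p_ev

    ledger_rows: list[dict] = []
    carrier_fractions = {
        m.matrix_id: rng.random(n_targets) < m.fraction_of_targets_carrying
        for m in spec.matrices
    }

    def build_promoter(promoter_id, gene_id, is_target, idx):
        codes = rng.choice(4, size=length, p=comp).astype(np.int8)
        protected = np.zeros(length, dtype=bool)
        for m in spec.matrices:
            rate = m.background_rate_per_kb
            if is_target:
                rate = (rate * m.target_enrichment_ratio
                        if carrier_fractions[m.matrix_id][idx] else 0.0)
            n_sites = int(rng.poisson(rate * length / 1000.0))
            site_base = encode_sequence(m.consensus)
            for _ in range(n_sites):
                site = site_base.copy()
                strand = "+" if rng.random() < 0.5 else "-"
                mutated = 0
                if rng.random() < spec.site_mutation_prob:
                    _mutate_one(site, range(len(site)), rng)
                    mutated = 1
                planted = site if strand == "+" else (3 - site)[::-1]
                start = _plant(codes, protected, planted, rng)
                if start is None:
                    raise ValueError(
                        f"promoter {promoter_id}: cannot place site of "
                        f"{m.matrix_id} without overlap (capacity exceeded)"
                    )
                ledger_rows.append({
                    "record_type": "motif_site", "id": m.matrix_id,
                    "gene_id": gene_id, "promoter_id": promoter_id,
                    "start": start - spec.tss_offset,
                    "end": start - spec.tss_offset + len(site),
                    "strand": strand, "value": mutated,
                })
        if is_target:
            if ere_carrier[idx]:
                half5 = encode_sequence(ERE_HALF_SITE_5P)
                half3 = encode_sequence(ERE_HALF_SITE_3P)
                spacer = rng.choice(4, size=spec.ere_spacer).astype(np.int8)
                site = np.concatenate([half5, spacer, half3])
                mism = 0
                if rng.random() < spec.ere_mutation_prob:
                    half_positions = list(range(5)) + list(
                        range(5 + spec.ere_spacer, 10 + spec.ere_spacer))
                    _mutate_one(site, half_positions, rng)
                    mism = 1
                start = _plant(codes, protected, site, rng)
                if start is None:
                    raise ValueError(
                        f"promoter {promoter_id}: cannot place ERE "
                        "(capacity exceeded)"
                    )
                ledger_rows.append({
                    "record_type": "ere_site", "id": "ERE",
                    "gene_id": gene_id, "promoter_id": promoter_id,
                    "start": start - spec.tss_offset,
                    "end": start - spec.tss_offset + len(site),
                    "strand": "+", "value": mism,
                })
            else:
                _scrub_ere(codes, protected, rng,
                           spec.ere_scrub_max_mismatch, spec.ere_spacer)
        return Promoter(promoter_id, gene_id, _codes_to_str(codes),
                        spec.tss_offset)

    width = max(4, len(str(max(n_targets, spec.n_background_promoters))))
    targets, genes = [], []
    for i in range(n_targets):
        gene_id = f"G{i + 1:0{width}d}"
        promoter_id = f"P{i + 1:0{width}d}"
        targets.append(build_promoter(promoter_id, gene_id, True, i))
        genes.append(GeneRecord(gene_id, (promoter_id,),
                                evidence=bool(evidence[i])))
        if ere_carrier[i]:
            ledger_rows.append({
                "record_type": "ere_carrier", "id": "ERE",
                "gene_id": gene_id, "promoter_id": promoter_id,
                "start": -1, "end": -1, "strand": ".", "value": 1,
            })
        if evidence[i]:
            ledger_rows.append({
                "record_type": "evidence_flag", "id": "evidence",
                "gene_id": gene_id, "promoter_id": promoter_id,
                "start": -1, "end": -1, "strand": ".", "value": 1,
            })

    background = [
        build_promoter(f"B{i + 1:0{width}d}", f"B{i + 1:0{width}d}", False, -1)
        for i in range(spec.n_background_promoters)
    ]

    ledger = pd.DataFrame(
        ledger_rows,
        columns=["record_type", "id", "gene_id", "promoter_id",
                 "start", "end", "strand", "value"],
    )
    cohort = Cohort(spec, pwms, targets, background, genes,
                    matrix_tf_map, ledger)
    if outdir is not None:
        cohort.write(outdir)
    return cohort


# ---------------------------------------------------------------------------
# The study-scale reference cohort


def reference_cohort_spec(seed: int = 0) -> CohortSpec:
    """A cohort shaped like the ovarian-cancer promoter study.

    323 target genes with deterministic flag counts chosen so the scanned
    four-group partition is exactly (11, 54, 66, 192): 65 ERE carriers of
    which 11 carry evidence, and 66 evidence genes among the 258
    non-carriers.  The background holds 200 promoters of 1200 nt, a
    desk-scale stand-in for a genome-wide background set.  Twenty-five
    matrix/TF pairs are planted: five designated TFs at high enrichment
    (ratio 5 in 90% of targets) and twenty at moderate enrichment (ratio
    4.5 in 55%), all over a 0.3 sites/kb background rate.  The carrier
    fractions are kept well apart because per-matrix threshold
    calibration quantises detection rates, and the moderate tier is broad
    (20 TFs) so the nearest-rank percentile threshold is insensitive to a
    single marginally-enriched matrix dropping out of the ranking.
    """
    consensus_rng = np.random.default_rng(9001)  # fixed: consensi are constants
    words = random_consensus_set(25, 9, consensus_rng)
    matrices = []
    for i, word in enumerate(words):
        strong = i < 5
        matrices.append(MatrixSpec(
            matrix_id=f"M{i + 1:03d}",
            tf_id=f"TF{i + 1:03d}",
            consensus=word,
            background_rate_per_kb=0.3,
            target_enrichment_ratio=5.0 if strong else 4.5,
            fraction_of_targets_carrying=0.90 if strong else 0.55,
            designated=strong,
        ))
    return CohortSpec(
        n_target_genes=323,
        n_background_promoters=200,
        promoter_length=1200,
        tss_offset=1000,
        matrices=tuple(matrices),
        ere_fraction_of_targets=65 / 323,
        evidence_rate_given_ere=11 / 65,
        evidence_rate_given_no_ere=66 / 258,
        seed=seed,
        deterministic_flags=True,
    )


def designated_tf_ids(spec: CohortSpec) -> list[str]:
    """TF IDs of the designated (high-enrichment) planted matrices."""
    return sorted({m.tf_id for m in spec.matrices if m.designated})
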