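"""End-to-end orchestration of the promoter analysis.

Stages: read inputs -> predict EREs and partition genes into the four
estrogen groups -> calibrate per-matrix cutoffs on the background ->
predict TFBSs on target and background promoters -> compute
over-representation per analysis scope (full set, each group, the
experimental union of groups 1 and 3) -> build TF-gene networks and rank
TFs by out-degree with the percentile retention rule -> TFBS-ERE distance
statistics, TSS positional density, and optional annotation-term
fractions.  Every stage's tables are written before the next begins and
the log records the counts at each stage.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import (
    cohort_grouping,
    enrichment_network as net,
    ere_finder,
    motif_io,
    pwm_scan,
    site_statistics as stats,
)

__all__ = ["PipelineConfig", "PipelineResult", "run_full"]

SCOPE_FULL = "full"
SCOPE_EXPERIMENTAL = "experimental"


@dataclass
class PipelineConfig:
    """All paths and tunables of one full run; YAML round-trippable."""

    pwm_library: str
    target_fasta: str
    background_fasta: str
    gene_table: str
    matrix_tf_map: str
    out_dir: str
    pwm_format: str = "jaspar"
    annotation_table: str | None = None
    threshold_profile: str | None = None
    pwm_pseudocount: float = 0.01
    target_fp_per_kb: float = pwm_scan.DEFAULT_TARGET_FP_PER_KB
    core_fraction: float = pwm_scan.DEFAULT_CORE_FRACTION
    ere_max_mismatch: int = ere_finder.DEFAULT_MAX_MISMATCH
    ere_spacer: int = ere_finder.DEFAULT_SPACER
    ori_pseudocount: float = 1.0
    ori_threshold: float = net.DEFAULT_ORI_THRESHOLD
    percentile: float = net.DEFAULT_PERCENTILE
    tss_offset: int = 1000
    seed: int = 0

    def to_yaml(self, path) -> None:
        with Path(path).open("w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with Path(path).open() as fh:
            data = yaml.safe_load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config field(s): {sorted(unknown)}")
        missing = {
            f.name for f in dataclasses.fields(cls)
            if f.default is dataclasses.MISSING
            and f.default_factory is dataclasses.MISSING
        } - set(data)
        if missing:
            raise ValueError(f"config missing required field(s): {sorted(missing)}")
        return cls(**data)


@dataclass
class PipelineResult:
    genes: list
    groups: dict[int, list[str]]
    experimental_genes: list[str]
    profile: pwm_scan.ThresholdProfile
    target_hits: list
    background_hits: list
    ere_hits: list
    ori: dict[str, list]
    edges: dict[str, list]
    rankings: dict[str, list]
    distance_records: list
    distance_summary: object
    density: tuple | None
    term_fractions: dict[int, dict[str, float]]
    counts: dict[str, int] = field(default_factory=dict)


def _retained(ranking) -> list[str]:
    return sorted(r.tf_id for r in ranking if r.retained)


def run_full(config: PipelineConfig) -> PipelineResult:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []
    counts: dict[str, int] = {}

    def log(msg: str) -> None:
        log_lines.append(msg)

    def flush_log() -> None:
        (out / "log.txt").write_text("\n".join(log_lines) + "\n")

    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            log(f"ERROR at stage {name}: {exc}")
            flush_log()
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    # -- inputs ------------------------------------------------------------
    def load():
        pwms = motif_io.read_pwm_library(
            config.pwm_library, config.pwm_format, config.pwm_pseudocount)
        targets = motif_io.read_promoters(config.target_fasta, config.tss_offset)
        background = motif_io.read_promoters(
            config.background_fasta, config.tss_offset)
        genes = motif_io.read_gene_table(
            config.gene_table,
            known_promoter_ids=[p.promoter_id for p in targets])
        tf_map = motif_io.read_matrix_tf_map(config.matrix_tf_map)
        return pwms, targets, background, genes, tf_map

    pwms, targets, background, genes, tf_map = stage("load_inputs", load)
    counts["genes"] = len(genes)
    counts["target_promoters"] = len(targets)
    counts["background_promoters"] = len(background)
    counts["matrices"] = len(pwms)
    log(f"loaded {len(genes)} genes, {len(targets)} target promoters, "
        f"{len(background)} background promoters, {len(pwms)} matrices")

    # -- EREs and grouping -------------------------------------------------
    def eres():
        hits = ere_finder.scan_promoters_ere(
            targets, config.ere_max_mismatch, config.ere_spacer)
        flagged = ere_finder.flag_ere_genes(genes, hits)
        groups = cohort_grouping.partition_genes(flagged)
        experimental = cohort_grouping.experimental_union(groups)
        motif_io.write_sites_bed(hits, out / "ere_sites.bed")
        motif_io.write_gene_groups(flagged, out / "gene_groups.tsv")
        return hits, flagged, groups, experimental

    ere_hits, genes, groups, experimental = stage("ere_prediction", eres)
    counts["ere_hits"] = len(ere_hits)
    counts["ere_promoters"] = len({h.promoter_id for h in ere_hits})
    for g in (1, 2, 3, 4):
        counts[f"group{g}_genes"] = len(groups[g])
    counts["experimental_genes"] = len(experimental)
    log(f"predicted {counts['ere_hits']} EREs on {counts['ere_promoters']} "
        f"promoters; groups (1,2,3,4) = "
        f"({', '.join(str(len(groups[g])) for g in (1, 2, 3, 4))}); "
        f"experimental union {len(experimental)} genes")

    # -- thresholds and scanning -------------------------------------------
    def thresholds():
        if config.threshold_profile:
            return pwm_scan.ThresholdProfile.read_tsv(config.threshold_profile)
        profile = pwm_scan.calibrate_profile(
            pwms, background, config.target_fp_per_kb, config.core_fraction)
        return profile

    profile = stage("threshold_calibration", thresholds)
    profile.write_tsv(out / "threshold_profile.tsv")

    def scan():
        t_hits = pwm_scan.scan_promoters(pwms, targets, profile)
        b_hits = pwm_scan.scan_promoters(pwms, background, profile)
        motif_io.write_sites_bed(t_hits, out / "tfbs_target.bed")
        motif_io.write_sites_bed(b_hits, out / "tfbs_background.bed")
        return t_hits, b_hits

    target_hits, background_hits = stage("tfbs_scan", scan)
    counts["tfbs_target_hits"] = len(target_hits)
    counts["tfbs_background_hits"] = len(background_hits)
    log(f"predicted {len(target_hits)} TFBSs on targets and "
        f"{len(background_hits)} on background")

    # -- enrichment, network, ranking per scope -----------------------------
    gene_by_id = {g.gene_id: g for g in genes}
    promoter_by_id = {p.promoter_id: p for p in targets}

    def scope_members(scope: str) -> list[str]:
        if scope == SCOPE_FULL:
            return [g.gene_id for g in genes]
        if scope == SCOPE_EXPERIMENTAL:
            return experimental
        return groups[int(scope.removeprefix("group"))]

    scopes = [SCOPE_FULL, "group1", "group2", "group3", "group4",
              SCOPE_EXPERIMENTAL]
    ori_by_scope: dict[str, list] = {}
    edges_by_scope: dict[str, list] = {}
    rankings_by_scope: dict[str, list] = {}

    def enrich_and_rank():
        for scope in scopes:
            members = scope_members(scope)
            scope_promoters = [
                promoter_by_id[p]
                for gid in members for p in gene_by_id[gid].promoter_ids
            ]
            scope_promoter_ids = {p.promoter_id for p in scope_promoters}
            scope_hits = [h for h in target_hits
                          if h.promoter_id in scope_promoter_ids]
            if not scope_promoters:
                log(f"scope {scope}: no genes; skipped")
                ori_by_scope[scope] = []
                edges_by_scope[scope] = []
                rankings_by_scope[scope] = []
                continue
            ori = net.compute_ori(
                scope_hits, scope_promoters, background_hits, background,
                config.ori_pseudocount, config.ori_threshold)
            net.write_ori_table(ori, out / f"ori_{scope}.tsv")
            scope_genes = [gene_by_id[gid] for gid in members]
            edges = net.build_network(ori, scope_hits, tf_map, scope_genes)
            net.write_edges(edges, out / f"edges_{scope}.tsv")
            ranking = (net.rank_tfs(edges, config.percentile)
                       if edges else [])
            net.write_ranking(ranking, out / f"ranking_{scope}.tsv")
            ori_by_scope[scope] = ori
            edges_by_scope[scope] = edges
            rankings_by_scope[scope] = ranking
            n_enriched = sum(r.enriched for r in ori)
            n_ret = sum(r.retained for r in ranking)
            log(f"scope {scope}: {len(members)} genes, {len(scope_hits)} "
                f"TFBSs, {n_enriched} enriched matrices, {len(edges)} edges, "
                f"{len(ranking)} TFs ranked, {n_ret} retained")

    stage("enrichment_network", enrich_and_rank)
    counts["enriched_matrices_full"] = sum(
        r.enriched for r in ori_by_scope[SCOPE_FULL])
    counts["edges_full"] = len(edges_by_scope[SCOPE_FULL])
    counts["retained_tfs_full"] = sum(
        r.retained for r in rankings_by_scope[SCOPE_FULL])
    counts["retained_tfs_experimental"] = sum(
        r.retained for r in rankings_by_scope[SCOPE_EXPERIMENTAL])

    # -- TF set comparisons -------------------------------------------------
    def comparisons():
        rows = []
        pairs = [("group1", "group3"),
                 (SCOPE_EXPERIMENTAL, "group2"),
                 (SCOPE_EXPERIMENTAL, "group4"),
                 (SCOPE_FULL, SCOPE_EXPERIMENTAL)]
        for a, b in pairs:
            sets = net.tf_set_algebra(_retained(rankings_by_scope[a]),
                                      _retained(rankings_by_scope[b]))
            rows.append((a, b, sets))
            log(f"retained TFs {a} vs {b}: {len(sets.common)} common, "
                f"{len(sets.unique_a)} unique to {a}, "
                f"{len(sets.unique_b)} unique to {b}, "
                f"union {len(sets.union)}")
        with (out / "tf_comparisons.tsv").open("w") as fh:
            fh.write("scope_a\tscope_b\tcommon\tunique_a\tunique_b\tunion\n")
            for a, b, s in rows:
                fh.write(f"{a}\t{b}\t{','.join(s.common)}\t"
                         f"{','.join(s.unique_a)}\t{','.join(s.unique_b)}\t"
                         f"{','.join(s.union)}\n")
        return rows

    stage("tf_comparisons", comparisons)

    # -- distance statistics -------------------------------------------------
    def distances():
        exp_promoters = {
            p for gid in experimental
            for p in gene_by_id[gid].promoter_ids
        }
        exp_hits = [h for h in target_hits if h.promoter_id in exp_promoters]
        exp_eres = [e for e in ere_hits if e.promoter_id in exp_promoters]
        records = stats.tfbs_ere_distances(exp_hits, exp_eres)
        summary = stats.distance_summary(records, matrix_tf_map=tf_map)
        stats.write_distance_records(records, out / "tfbs_ere_distances.tsv")
        stats.write_distance_summary(summary, out / "distance_histogram.tsv")
        return records, summary

    distance_records, summary = stage("distance_statistics", distances)
    counts["distance_records"] = len(distance_records)
    counts["complete_overlaps"] = sum(
        r.complete_overlap for r in distance_records)
    log(f"{len(distance_records)} TFBS-ERE distance records, "
        f"{counts['complete_overlaps']} complete overlaps")

    # -- positional density ---------------------------------------------------
    def density():
        if len(target_hits) < 2:
            log("fewer than 2 TFBSs; density skipped")
            return None
        grid, dens = stats.tss_positional_density(target_hits)
        stats.write_density(grid, dens, out / "tss_density.tsv")
        return grid, dens

    dens = stage("tss_density", density)

    # -- term fractions -------------------------------------------------------
    fractions: dict[int, dict[str, float]] = {}

    def terms():
        if not config.annotation_table:
            return
        annotation = stats.read_annotation_table(config.annotation_table)
        for g in (1, 2, 3, 4):
            if not groups[g]:
                continue
            frac = stats.term_fractions(groups[g], annotation)
            stats.write_term_fractions(frac, out / f"term_fractions_group{g}.tsv")
            fractions[g] = frac

    stage("term_fractions", terms)

    log("counts: " + ", ".join(f"{k}={v}" for k, v in counts.items()))
    flush_log()
    return PipelineResult(
        genes=genes, groups=groups, experimental_genes=experimental,
        profile=profile, target_hits=target_hits,
        background_hits=background_hits, ere_hits=ere_hits,
        ori=ori_by_scope, edges=edges_by_scope, rankings=rankings_by_scope,
        distance_records=distance_records, distance_summary=summary,
        density=dens, term_fractions=fractions, counts=counts,
    )
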