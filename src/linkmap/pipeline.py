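"""End-to-end orchestration: screens → distances → maps → hotspots →
pericentric and chromatin summaries, with a config echo and run log."""

from __future__ import annotations

import dataclasses
import logging
import math
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from . import chromatin as chromatin_mod
from . import hotspots as hotspots_mod
from . import pericentric as peri_mod
from .distances import (
    DistanceConfig,
    PairDistance,
    clip_R_array,
    normalize_R_array,
    pair_distance,
    recombinant_fraction_array,
)
from .io_formats import (
    FitnessScreenTable,
    GenomeAnnotation,
    ScreenTable,
    read_annotation,
    read_fitness_screens,
    read_sites,
    read_track,
    write_distance_matrix,
)
from .linkage import (
    DEFAULT_CONSOLIDATION_EXCLUDE,
    LinkageMatrix,
    apply_masks,
    build_linkage_matrix,
    chromosome_genetic_length,
    consolidate,
    read_mask_rules,
)

logger = logging.getLogger("linkmap")

__all__ = [
    "ConfigError",
    "DataError",
    "PipelineConfig",
    "estimate_pair_distances",
    "build_maps",
    "run_pipeline",
]


class ConfigError(ValueError):
    pass


class DataError(ValueError):
    pass


@dataclass
class PipelineConfig:
    annotation: str = ""
    screens_dir: str = ""
    tracks_dir: str = ""
    reference_hotspots: str = ""
    mask_file: str = ""
    out_dir: str = "linkmap_out"
    # distance mapping
    mapping_mode: str = "haldane_capped"
    cap_sga_gd: float = 50.0
    r_clip_low: float = 0.0
    r_clip_high: float = 0.5
    self_normalization: str = "affine_R"
    # map construction
    bin_size: int = 5000
    consolidation_exclude: list[str] = field(
        default_factory=lambda: sorted(DEFAULT_CONSOLIDATION_EXCLUDE)
    )
    # hotspot analysis
    profile_window_bins: int = 5  # 25 kb at 5-kb bins
    smooth_window: int = 5
    hotspot_min_separation: float = 0.0
    hotspot_tolerance: float = 10_000.0
    # pericentric analysis
    extent_threshold: float = 50.0
    extent_bin_kb: float = 5.0
    size_correlation_exclude: list[str] = field(default_factory=list)
    trans_unavailable: list[str] = field(default_factory=list)
    # chromatin
    oligo_threshold: float = 3000.0
    cohesin_window: int = 25
    seed: int = 0

    def distance_config(self) -> DistanceConfig:
        return DistanceConfig(
            mapping_mode=self.mapping_mode,
            cap_sga_gd=self.cap_sga_gd,
            r_clip=(self.r_clip_low, self.r_clip_high),
            self_normalization=self.self_normalization,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def estimate_pair_distances(
    screens: Mapping[str, FitnessScreenTable],
    config: DistanceConfig = DistanceConfig(),
) -> dict[str, list[PairDistance]]:
    """Colony-size screens → per-chromosome pair distances.

    Per screen row the raw recombinant fraction is estimated for every array
    column; the row is re-anchored so its query-self residual maps to R = 0
    (affine_R mode); replicate rows of the same query are then averaged on
    the R scale before clipping and distance mapping.
    """
    out: dict[str, list[PairDistance]] = {}
    for chrom, table in screens.items():
        R = recombinant_fraction_array(
            table.f_query[:, None], table.f_array[None, :], table.f_double
        )
        col_of = {aid: j for j, aid in enumerate(table.array_ids)}
        keep_rows = np.ones(len(table.query_ids), dtype=bool)
        if config.self_normalization == "affine_R":
            for i, qid in enumerate(table.query_ids):
                j = col_of.get(qid)
                if j is None or not math.isfinite(R[i, j]):
                    continue
                self_R = float(R[i, j])
                if self_R >= 0.5:
                    warnings.warn(
                        f"{chrom}: screen for {qid} has self R = {self_R:.3f} >= 0.5; "
                        "screen dropped as uninformative",
                        stacklevel=2,
                    )
                    keep_rows[i] = False
                    continue
                R[i, :] = normalize_R_array(R[i, :], self_R)
        # replicate averaging on the R scale, in first-appearance order
        order: list[str] = []
        rows_by_query: dict[str, list[int]] = {}
        for i, qid in enumerate(table.query_ids):
            if not keep_rows[i]:
                continue
            rows_by_query.setdefault(qid, []).append(i)
            if qid not in order:
                order.append(qid)
        pairs: list[PairDistance] = []
        for qid in order:
            rows = R[rows_by_query[qid], :]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                mean_R = np.nanmean(rows, axis=0)
            for j, aid in enumerate(table.array_ids):
                if math.isfinite(mean_R[j]):
                    pairs.append(pair_distance(qid, aid, float(mean_R[j]), config))
        out[chrom] = pairs
    return out


def build_maps(
    pairs_by_chrom: Mapping[str, list[PairDistance]],
    annotation: GenomeAnnotation,
    bin_size: int = 5000,
    consolidation_exclude=DEFAULT_CONSOLIDATION_EXCLUDE,
    mask_rules=(),
) -> dict[str, LinkageMatrix]:
    """Binned matrices, direction consolidation and mask application."""
    maps = {}
    for chrom, pairs in pairs_by_chrom.items():
        lm = build_linkage_matrix(pairs, annotation, chrom, bin_size)
        lm = consolidate(lm, exclude=consolidation_exclude)
        lm = apply_masks(lm, list(mask_rules))
        maps[chrom] = lm
    return maps


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage present in the config; returns a report dict and
    writes all outputs under ``config.out_dir``."""
    t0 = time.time()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_path = out_dir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    report: dict = {}
    try:
        if not config.annotation or not Path(config.annotation).exists():
            raise ConfigError(f"annotation path missing: {config.annotation!r}")
        config.to_yaml(out_dir / "config_echo.yaml")
        annotation = read_annotation(config.annotation)
        logger.info(
            "annotation: %d chromosomes, %d genes",
            len(annotation.chromosomes),
            len(annotation.genes),
        )

        screens: dict[str, FitnessScreenTable] = {}
        if config.screens_dir:
            sdir = Path(config.screens_dir)
            if not sdir.is_dir():
                raise ConfigError(f"screens_dir missing: {config.screens_dir!r}")
            for chrom in annotation.chromosome_names:
                prefix = sdir / chrom
                if (sdir / f"{chrom}.fij.tsv").exists():
                    screens[chrom] = read_fitness_screens(prefix, chromosome=chrom)
            if not screens:
                raise DataError(f"no screen files found in {sdir}")
            logger.info("screens: %d chromosomes", len(screens))

        if screens:
            dist_cfg = config.distance_config()
            pairs = estimate_pair_distances(screens, dist_cfg)
            mask_rules = read_mask_rules(config.mask_file) if config.mask_file else []
            if mask_rules:
                logger.info("mask rules: %d", len(mask_rules))
            maps = build_maps(
                pairs,
                annotation,
                bin_size=config.bin_size,
                consolidation_exclude=set(config.consolidation_exclude),
                mask_rules=mask_rules,
            )
            maps_dir = out_dir / "maps"
            maps_dir.mkdir(exist_ok=True)
            for chrom, lm in maps.items():
                labels = [f"bin{k}" for k in range(lm.n)]
                write_distance_matrix(
                    ScreenTable(chrom, labels, labels, lm.consolidated),
                    maps_dir / f"{chrom}.gprime.tsv",
                )
            try:
                fit = chromosome_genetic_length(maps, annotation, cap=config.cap_sga_gd)
                report["size_fit"] = {"a": fit.a, "b": fit.b, "per_chromosome": fit.per_chromosome}
            except ValueError as exc:
                logger.info("size fit skipped: %s", exc)

            profiles = {}
            for chrom, lm in maps.items():
                prof = hotspots_mod.local_rate_profile(lm, config.profile_window_bins)
                profiles[chrom] = hotspots_mod.smooth(prof, config.smooth_window)
            avg_profiles = [
                p for c, p in profiles.items() if c not in set(config.consolidation_exclude)
            ] or list(profiles.values())
            genome_avg = hotspots_mod.genome_average_rate(avg_profiles)
            report["genome_avg_rate"] = genome_avg
            calls = []
            for chrom, prof in profiles.items():
                calls.extend(
                    hotspots_mod.call_hotspots(prof, genome_avg, config.hotspot_min_separation)
                )
            hotspots_mod.write_hotspots_bed(calls, out_dir / "hotspots.bed", config.bin_size)
            report["n_hotspots"] = len(calls)
            logger.info("hotspots: %d calls (genome avg %.4f)", len(calls), genome_avg)
            if config.reference_hotspots:
                reference = read_sites(config.reference_hotspots, format="bed")
                precision, sensitivity, _ = hotspots_mod.compare_hotspot_sets(
                    calls, reference, config.hotspot_tolerance
                )
                report["hotspot_precision"] = precision
                report["hotspot_sensitivity"] = sensitivity

            peri_rows = []
            extents_trans: dict[str, float] = {}
            extents_cis: dict[str, float] = {}
            for chrom, plist in pairs.items():
                known = {g.gene_id for g in annotation.genes_on(chrom)}
                usable = [p for p in plist if p.query_id in known and p.array_id in known]
                if not usable:
                    continue
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    classes = peri_mod.classify_pairs(usable, annotation)
                cl = peri_mod.centromere_linkage_from_pairs(
                    list(zip(classes, [p.sga_gd for p in usable])),
                    chrom,
                    bin_size_kb=config.extent_bin_kb,
                    threshold=config.extent_threshold,
                )
                if chrom in set(config.trans_unavailable):
                    cl.extent_trans = math.nan
                peri_rows.append(cl)
                extents_trans[chrom] = cl.extent_trans
                extents_cis[chrom] = cl.extent_cis
            if peri_rows:
                with open(out_dir / "pericentric.tsv", "w", encoding="utf-8") as fh:
                    fh.write("chromosome\tlength_bp\textent_cis_kb\textent_trans_kb\tmethod\n")
                    for cl in peri_rows:
                        length = annotation.chromosome(cl.chromosome).length
                        fh.write(
                            f"{cl.chromosome}\t{length}\t{cl.extent_cis}\t"
                            f"{cl.extent_trans}\t{cl.method}\n"
                        )
                corr_rows = []
                for label, vals in (("trans", extents_trans), ("cis", extents_cis)):
                    for excl in ([], config.size_correlation_exclude):
                        try:
                            sc = peri_mod.size_correlation(
                                vals, annotation, excluded=excl, variable=f"extent_{label}"
                            )
                            corr_rows.append(sc)
                        except ValueError as exc:
                            logger.info("correlation (%s, excl=%s) skipped: %s", label, excl, exc)
                report["size_correlations"] = [
                    {"variable": s.variable, "R": s.R, "p": s.p, "n": s.n,
                     "excluded": sorted(s.excluded)}
                    for s in corr_rows
                ]
                with open(out_dir / "size_correlations.tsv", "w", encoding="utf-8") as fh:
                    fh.write("variable\tR\tp\tn\texcluded\n")
                    for s in corr_rows:
                        fh.write(
                            f"{s.variable}\t{s.R}\t{s.p}\t{s.n}\t{','.join(sorted(s.excluded))}\n"
                        )

        if config.tracks_dir:
            tdir = Path(config.tracks_dir)
            if not tdir.is_dir():
                raise ConfigError(f"tracks_dir missing: {config.tracks_dir!r}")
            report.update(_chromatin_stage(config, annotation, tdir, out_dir))

        logger.info("pipeline finished in %.2f s", time.time() - t0)
    finally:
        logger.removeHandler(handler)
        handler.close()
    return report


def _chromatin_stage(config: PipelineConfig, annotation, tdir: Path, out_dir: Path) -> dict:
    report: dict = {}
    spo11, rec8, mcd1 = {}, {}, {}
    for chrom in annotation.chromosome_names:
        for kind, store in (("spo11", spo11), ("rec8", rec8), ("mcd1", mcd1)):
            path = tdir / f"{kind}_{chrom}.tsv"
            if path.exists():
                store[chrom] = read_track(path, format="two_column", chromosome=chrom)
    if spo11:
        with open(out_dir / "dsb_regions.tsv", "w", encoding="utf-8") as fh:
            fh.write("chromosome\tleft_kb\tright_kb\ttotal_kb\tasymmetry_kb\n")
            widths = {}
            for chrom, track in spo11.items():
                c = annotation.chromosome(chrom)
                region = chromatin_mod.dsb_repressed_region(
                    track, c.centromere, config.oligo_threshold, chromosome_length=c.length
                )
                widths[chrom] = region.total
                fh.write(
                    f"{chrom}\t{region.left_extent}\t{region.right_extent}\t"
                    f"{region.total}\t{chromatin_mod.asymmetry_score(region)}\n"
                )
        report["dsb_total_kb"] = widths
    for kind, tracks in (("rec8", rec8), ("mcd1", mcd1)):
        if not tracks:
            continue
        gga = chromatin_mod.compute_gga(tracks.values(), config.cohesin_window)
        widths = {}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for chrom, track in tracks.items():
                peak = chromatin_mod.cohesin_peak_width(
                    track, annotation.chromosome(chrom).centromere, gga, config.cohesin_window
                )
                widths[chrom] = peak.width_kb
        with open(out_dir / f"{kind}_peaks.tsv", "w", encoding="utf-8") as fh:
            fh.write("chromosome\tpeak_width_kb\tgga\n")
            for chrom, w in widths.items():
                fh.write(f"{chrom}\t{w}\t{gga}\n")
        report[f"{kind}_width_kb"] = widths
    return report
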