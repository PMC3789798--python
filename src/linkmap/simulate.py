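"""Synthetic data with known ground truth for every pipeline input.

A crossover-rate map (cM/kb) is built per chromosome from a base rate,
multiplicative hotspot enrichments and a pericentric suppression zone whose
radius may scale with chromosome length.  Crossovers between two loci follow
a Poisson model: with m = expected crossovers per meiosis in the interval,
the true recombinant fraction is R = 0.5·(1 − e^(−m)).  Colony-size screens
are generated as f_ij = f_i·f_j·(R/0.5) (so the pipeline's estimator inverts
them exactly in the noise-free case), with optional multiplicative lognormal
noise, fitness interactions, residual query-self colonies, replicate rows and
a compressive saturation transform f → f^γ.

Signal tracks (Spo11-oligo counts, Rec8/Mcd1 binding), hotspot site lists and
a classical-style genetic map are generated from the same rate maps.  All
outputs are deterministic functions of the seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .io_formats import (
    Chromosome,
    Gene,
    GenomeAnnotation,
    FitnessScreenTable,
    GenomicTrack,
    Site,
    SiteList,
    write_annotation,
    write_fitness_screens,
    write_sites,
    write_track,
)

__all__ = [
    "SimConfig",
    "SimTruth",
    "RateMap",
    "Simulation",
    "yeast_like_genome",
    "build_rate_map",
    "pair_true_R",
    "simulate_screens",
    "simulate_tracks",
    "write_simulation",
]


def yeast_like_genome(n: int = 16) -> list[tuple[int, int]]:
    """(length, centromere) for n chromosomes spanning ~0.23–1.5 Mb."""
    out = []
    for k in range(n):
        frac = k / max(n - 1, 1)
        length = int(230_000 + frac * (1_530_000 - 230_000))
        cen = int(length * (0.35 + 0.1 * ((k * 7919) % 13) / 13.0))
        out.append((length, cen))
    return out


@dataclass
class SimConfig:
    seed: int = 0
    genome: list[tuple[int, int]] = field(default_factory=yeast_like_genome)
    n_genes_per_chromosome: int = 30
    gene_spacing_bp: float | None = None  # constant gene density overrides the count
    bin_size: int = 5000
    base_rate: float = 1.43  # cM/kb; 50 cM ~ 35 kb
    # explicit hotspots: chromosome -> [(position bp, fold, width bp)]
    hotspots: dict[str, list[tuple[int, float, int]]] = field(default_factory=dict)
    # or auto-placed hotspots per chromosome
    hotspots_per_chromosome: int = 0
    hotspot_fold: float = 3.0
    hotspot_width_bp: int = 8000
    hotspot_min_separation_bp: int = 25_000
    # pericentric suppression: radius rho = rho0 + coupling * L(Mb)
    pericentric_radius_kb: float = 0.0
    pericentric_residual: float = 0.0
    size_coupling_kb_per_mb: float = 0.0
    # "positional": the rate map itself is suppressed around the centromere
    # (cis pairs overlapping the zone are slowed too); "trans_only": only
    # centromere-spanning pairs lose the zone's crossovers, leaving cis pairs
    # as a clean suppression-free null (tracks stay positionally suppressed)
    suppression_scope: str = "positional"
    # screen noise model
    noise_sd: float = 0.0  # lognormal sigma on every observed colony size
    residual_colony: float = 0.0  # observed f_ij of query-self cells
    interaction_rate: float = 0.0
    interaction_sd: float = 0.25
    replicate_count: int = 1
    gamma: float = 1.0  # saturation compression on observed sizes
    gene_jitter: float = 0.2  # uniform jitter, fraction of gene spacing
    # tracks
    grid_bp: int = 250
    track_step_bp: int = 1000
    oligos_per_cm: float = 400.0
    track_background: float = 1.0
    track_noise_sd: float = 0.0
    rec8_width0_kb: float = 20.0
    rec8_size_coupling_kb_per_mb: float = 0.0
    rec8_peak_height: float = 3.0
    mcd1_width_kb: float = 20.0
    mcd1_peak_height: float = 3.0

    def __post_init__(self) -> None:
        if self.base_rate < 0 or self.noise_sd < 0:
            raise ValueError("rates and noise must be >= 0")
        if not (0.0 <= self.pericentric_residual <= 1.0):
            raise ValueError("pericentric_residual must be in [0, 1]")
        if not (0.0 < self.gamma <= 1.0):
            raise ValueError("gamma must be in (0, 1]")
        if self.suppression_scope not in ("positional", "trans_only"):
            raise ValueError(f"unknown suppression_scope: {self.suppression_scope}")

    def chromosome_names(self) -> list[str]:
        return [f"chr{k + 1:02d}" for k in range(len(self.genome))]


@dataclass
class RateMap:
    """Piecewise-constant crossover rate (cM/kb) on a regular grid."""

    chromosome: str
    edges: np.ndarray  # bp, grid boundaries from 0 to L
    rate: np.ndarray  # cM/kb per grid cell (len(edges) - 1)
    cum_cm: np.ndarray  # cumulative cM at each edge

    def cm_at(self, position):
        """Cumulative genetic-map position (cM) at a physical position."""
        return np.interp(position, self.edges, self.cum_cm)

    def cm_between(self, a: float, b: float) -> float:
        return abs(float(self.cm_at(b)) - float(self.cm_at(a)))

    def rate_at(self, position):
        idx = np.clip(
            np.searchsorted(self.edges, position, side="right") - 1, 0, len(self.rate) - 1
        )
        return self.rate[idx]

    @property
    def total_cm(self) -> float:
        return float(self.cum_cm[-1])


@dataclass
class SimTruth:
    """Ground truth generated alongside the synthetic data."""

    annotation: GenomeAnnotation
    rate_maps: dict[str, RateMap]
    gene_ids: dict[str, list[str]]
    gene_midpoints: dict[str, np.ndarray]
    gene_cm: dict[str, np.ndarray]
    true_cm: dict[str, np.ndarray]  # genes × genes pairwise genetic distance, cM
    true_R: dict[str, np.ndarray]  # genes × genes per chromosome
    pericentric_radius_kb: dict[str, float]
    hotspots: SiteList
    rec8_width_kb: dict[str, float] = field(default_factory=dict)
    mcd1_width_kb: dict[str, float] = field(default_factory=dict)

    def pair_R(self, chromosome: str, query_id: str, array_id: str) -> float:
        ids = self.gene_ids[chromosome]
        return float(self.true_R[chromosome][ids.index(query_id), ids.index(array_id)])

    def pair_sga_gd(self, chromosome: str, query_id: str, array_id: str, cap: float = 50.0) -> float:
        ids = self.gene_ids[chromosome]
        i, j = ids.index(query_id), ids.index(array_id)
        return min(cap, float(self.true_cm[chromosome][i, j]))


def _rho_kb(config: SimConfig, length_bp: int) -> float:
    return config.pericentric_radius_kb + config.size_coupling_kb_per_mb * length_bp / 1e6


def build_rate_map(
    config: SimConfig,
    hotspots: Mapping[str, Sequence[tuple[int, float, int]]] | None = None,
) -> dict[str, RateMap]:
    """True crossover-rate maps: base rate × hotspot fold × suppression.

    Overlapping hotspots merge by taking the maximum fold.  The suppression
    factor equals ``pericentric_residual`` within the (possibly
    size-coupled) radius of the centromere and 1 outside.
    """
    if hotspots is None:
        hotspots = config.hotspots
    maps: dict[str, RateMap] = {}
    for name, (length, cen) in zip(config.chromosome_names(), config.genome):
        edges = np.append(np.arange(0.0, length, config.grid_bp), float(length))
        centers = 0.5 * (edges[:-1] + edges[1:])
        rate = np.full(len(centers), config.base_rate)
        mult = np.ones(len(centers))
        for pos, fold, width in hotspots.get(name, []):
            inside = np.abs(centers - pos) <= width / 2.0
            mult[inside] = np.maximum(mult[inside], fold)
        rate *= mult
        rho = _rho_kb(config, length)
        if rho > 0:
            inside = np.abs(centers - cen) <= rho * 1000.0
            rate[inside] *= config.pericentric_residual
        widths_kb = np.diff(edges) / 1000.0
        cum = np.concatenate([[0.0], np.cumsum(rate * widths_kb)])
        maps[name] = RateMap(chromosome=name, edges=edges, rate=rate, cum_cm=cum)
    return maps


def pair_true_R(rate_map: RateMap, gene_a: float, gene_b: float) -> float:
    """Poisson-model recombinant fraction between two positions.

    m = (cM between the loci)/50 expected crossovers; R = 0.5·(1 − e^(−m))."""
    m = rate_map.cm_between(gene_a, gene_b) / 50.0
    return 0.5 * (1.0 - math.exp(-m))


class Simulation:
    """Deterministic generator tying annotation, rate maps, screens and
    tracks to one seed.  Independent RNG substreams per product keep
    screens/tracks individually reproducible."""

    def __init__(self, config: SimConfig):
        self.config = config
        rng = np.random.default_rng([config.seed, 0])
        names = config.chromosome_names()
        hotspots = dict(config.hotspots)
        if config.hotspots_per_chromosome > 0 and not hotspots:
            hotspots = self._place_hotspots(rng)
        self.hotspot_spec = hotspots
        self.rate_maps = build_rate_map(config, hotspots)
        if config.suppression_scope == "trans_only":
            import dataclasses as _dc

            cfg0 = _dc.replace(
                config, pericentric_radius_kb=0.0, size_coupling_kb_per_mb=0.0
            )
            self._pair_maps = build_rate_map(cfg0, hotspots)
        else:
            self._pair_maps = self.rate_maps

        genes: list[Gene] = []
        self.gene_ids: dict[str, list[str]] = {}
        self.gene_mids: dict[str, np.ndarray] = {}
        chroms = []
        for name, (length, cen) in zip(names, config.genome):
            chroms.append(Chromosome(name, length, cen))
            if config.gene_spacing_bp:
                n = max(2, int(round(length / config.gene_spacing_bp)))
            else:
                n = config.n_genes_per_chromosome
            spacing = length / (n + 1)
            mids = (np.arange(1, n + 1) * spacing)
            if config.gene_jitter > 0:
                mids = mids + rng.uniform(-1, 1, n) * config.gene_jitter * spacing
            mids = np.sort(np.clip(np.round(mids), 502, length - 501))
            ids = [f"{name}_g{k:04d}" for k in range(n)]
            self.gene_ids[name] = ids
            self.gene_mids[name] = mids
            for gid, mid in zip(ids, mids):
                genes.append(Gene(gid, name, int(mid) - 500, int(mid) + 500))
        self.annotation = GenomeAnnotation(chromosomes=chroms, genes=genes)

        true_R: dict[str, np.ndarray] = {}
        true_cm: dict[str, np.ndarray] = {}
        gene_cm: dict[str, np.ndarray] = {}
        radii: dict[str, float] = {}
        hotspot_sites: list[Site] = []
        for name, (length, cen) in zip(names, config.genome):
            rm = self._pair_maps[name]
            mids = self.gene_mids[name]
            cm = np.asarray(rm.cm_at(mids), dtype=float)
            gene_cm[name] = cm
            cm_mat = np.abs(cm[:, None] - cm[None, :])
            radii[name] = _rho_kb(config, length)
            if config.suppression_scope == "trans_only" and radii[name] > 0:
                # centromere-spanning pairs lose the zone's crossovers
                rho_bp = radii[name] * 1000.0
                lo = np.minimum(mids[:, None], mids[None, :])
                hi = np.maximum(mids[:, None], mids[None, :])
                spans = (lo < cen) & (hi > cen)
                ov_lo = np.maximum(lo, cen - rho_bp)
                ov_hi = np.minimum(hi, cen + rho_bp)
                cm_ov = np.clip(
                    np.asarray(rm.cm_at(ov_hi)) - np.asarray(rm.cm_at(ov_lo)), 0.0, None
                )
                cm_mat = cm_mat - (1.0 - config.pericentric_residual) * np.where(
                    spans, cm_ov, 0.0
                )
            true_cm[name] = cm_mat
            true_R[name] = 0.5 * (1.0 - np.exp(-cm_mat / 50.0))
            for pos, fold, _w in self.hotspot_spec.get(name, []):
                hotspot_sites.append(Site(name, float(pos), float(fold)))
        self.truth = SimTruth(
            annotation=self.annotation,
            rate_maps=self.rate_maps,
            gene_ids=self.gene_ids,
            gene_midpoints=self.gene_mids,
            gene_cm=gene_cm,
            true_cm=true_cm,
            true_R=true_R,
            pericentric_radius_kb=radii,
            hotspots=SiteList(hotspot_sites),
        )

    def _place_hotspots(self, rng: np.random.Generator):
        cfg = self.config
        out: dict[str, list[tuple[int, float, int]]] = {}
        for name, (length, cen) in zip(cfg.chromosome_names(), cfg.genome):
            rho_bp = _rho_kb(cfg, length) * 1000.0
            margin = cfg.hotspot_width_bp
            placed: list[int] = []
            attempts = 0
            while len(placed) < cfg.hotspots_per_chromosome and attempts < 10_000:
                attempts += 1
                pos = int(rng.uniform(margin, length - margin))
                if abs(pos - cen) <= rho_bp + cfg.hotspot_width_bp:
                    continue
                if all(abs(pos - q) >= cfg.hotspot_min_separation_bp for q in placed):
                    placed.append(pos)
            out[name] = [(p, cfg.hotspot_fold, cfg.hotspot_width_bp) for p in sorted(placed)]
        return out

    # -- screens ------------------------------------------------------------

    def screens(self) -> dict[str, FitnessScreenTable]:
        cfg = self.config
        rng = np.random.default_rng([cfg.seed, 1])
        out: dict[str, FitnessScreenTable] = {}
        for name in cfg.chromosome_names():
            ids = self.gene_ids[name]
            n = len(ids)
            R = self.truth.true_R[name]
            f_single = rng.uniform(0.7, 1.1, n)

            def _noisy(arr):
                if cfg.noise_sd > 0:
                    arr = arr * rng.lognormal(0.0, cfg.noise_sd, arr.shape)
                return arr

            f_array = _noisy(f_single.copy())
            rep = cfg.replicate_count
            query_ids = [gid for gid in ids for _ in range(rep)]
            qidx = np.repeat(np.arange(n), rep)
            f_query = _noisy(f_single[qidx].copy())
            expected = f_single[qidx, None] * f_single[None, :] * (R[qidx, :] / 0.5)
            expected[np.arange(len(qidx)), qidx] = cfg.residual_colony
            f_double = _noisy(expected)
            if cfg.interaction_rate > 0:
                hit = rng.random(f_double.shape) < cfg.interaction_rate
                f_double = np.where(
                    hit, f_double * rng.lognormal(0.0, cfg.interaction_sd, f_double.shape), f_double
                )
            if cfg.gamma != 1.0:
                f_query = f_query**cfg.gamma
                f_array = f_array**cfg.gamma
                f_double = f_double**cfg.gamma
            out[name] = FitnessScreenTable(
                chromosome=name,
                query_ids=query_ids,
                array_ids=list(ids),
                f_query=f_query,
                f_array=f_array,
                f_double=f_double,
            )
        return out

    # -- tracks -------------------------------------------------------------

    def tracks(self) -> dict[str, object]:
        cfg = self.config
        rng = np.random.default_rng([cfg.seed, 2])
        spo11: dict[str, GenomicTrack] = {}
        rec8: dict[str, GenomicTrack] = {}
        mcd1: dict[str, GenomicTrack] = {}
        map_sites: list[Site] = []
        for name, (length, cen) in zip(cfg.chromosome_names(), cfg.genome):
            rm = self.rate_maps[name]
            centers = np.arange(cfg.track_step_bp / 2.0, length, cfg.track_step_bp)
            step_kb = cfg.track_step_bp / 1000.0
            lam = np.asarray(rm.rate_at(centers)) * step_kb * cfg.oligos_per_cm
            spo11[name] = GenomicTrack(name, centers, rng.poisson(lam).astype(float))

            def _peak_track(width_kb: float, height: float) -> GenomicTrack:
                vals = np.full(len(centers), cfg.track_background)
                vals[np.abs(centers - cen) <= width_kb * 500.0] += height
                if cfg.track_noise_sd > 0:
                    vals = vals * rng.lognormal(0.0, cfg.track_noise_sd, len(vals))
                return GenomicTrack(name, centers.copy(), vals)

            w_rec8 = cfg.rec8_width0_kb + cfg.rec8_size_coupling_kb_per_mb * length / 1e6
            rec8[name] = _peak_track(w_rec8, cfg.rec8_peak_height)
            mcd1[name] = _peak_track(cfg.mcd1_width_kb, cfg.mcd1_peak_height)
            self.truth.rec8_width_kb[name] = w_rec8
            self.truth.mcd1_width_kb[name] = cfg.mcd1_width_kb
            for gid, mid in zip(self.gene_ids[name], self.gene_mids[name]):
                map_sites.append(Site(name, float(mid), float(rm.cm_at(mid))))
        return {
            "spo11": spo11,
            "rec8": rec8,
            "mcd1": mcd1,
            "hotspots": self.truth.hotspots,
            "genetic_map": SiteList(map_sites),
        }


def simulate_screens(config: SimConfig) -> tuple[dict[str, FitnessScreenTable], SimTruth]:
    sim = Simulation(config)
    return sim.screens(), sim.truth


def simulate_tracks(config: SimConfig) -> tuple[dict[str, object], SimTruth]:
    sim = Simulation(config)
    return sim.tracks(), sim.truth


def write_simulation(sim: Simulation, outdir: str | Path) -> None:
    """Write every fixture in the dialects the readers consume, plus a
    truth.json sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_annotation(sim.annotation, outdir / "annotation.tsv")
    screens = sim.screens()
    (outdir / "screens").mkdir(exist_ok=True)
    for name, table in screens.items():
        write_fitness_screens(table, outdir / "screens" / name)
    tracks = sim.tracks()
    (outdir / "tracks").mkdir(exist_ok=True)
    for kind in ("spo11", "rec8", "mcd1"):
        for name, track in tracks[kind].items():
            write_track(track, outdir / "tracks" / f"{kind}_{name}.tsv", format="two_column")
    write_sites(tracks["hotspots"], outdir / "hotspots.bed", format="bed")
    write_sites(tracks["genetic_map"], outdir / "genetic_map.tsv", format="loci")

    truth = sim.truth
    payload = {
        "seed": sim.config.seed,
        "pericentric_radius_kb": truth.pericentric_radius_kb,
        "rec8_width_kb": truth.rec8_width_kb,
        "mcd1_width_kb": truth.mcd1_width_kb,
        "gene_ids": truth.gene_ids,
        "gene_midpoints": {k: v.tolist() for k, v in truth.gene_midpoints.items()},
        "gene_cm": {k: v.tolist() for k, v in truth.gene_cm.items()},
        "true_cm": {k: v.tolist() for k, v in truth.true_cm.items()},
        "true_R": {k: v.tolist() for k, v in truth.true_R.items()},
        "hotspots": [
            {"chromosome": s.chromosome, "position": s.position, "fold": s.score}
            for s in truth.hotspots
        ],
    }
    with open(outdir / "truth.json", "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1)
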