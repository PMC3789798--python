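"""Binned per-chromosome linkage matrices.

Chromosomes are split into consecutive non-overlapping bins (default 5 kb).
A linkage map G is the n × n matrix of mean genetic distances for query-bin ×
array-bin gene pairs; the consolidated map G' averages the two measurement
directions, G' = (G + Gᵀ)/2, except on chromosomes excluded from
consolidation.  Cells with no data are NaN — never 0, which means measured
complete linkage.  ``mask`` is True where a cell is excluded from every
downstream average (marker-linkage regions, whole-chromosome exclusions).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .distances import PairDistance
from .io_formats import FormatError, GenomeAnnotation

__all__ = [
    "LinkageMatrix",
    "MaskRule",
    "ChromosomeFit",
    "DEFAULT_CONSOLIDATION_EXCLUDE",
    "assign_bin",
    "build_linkage_matrix",
    "consolidate",
    "apply_masks",
    "read_mask_rules",
    "write_mask_rules",
    "bin_pairs_by_distance",
    "chromosome_genetic_length",
]

#: chromosome III plays a special role in the SGA selection scheme and is not
#: direction-consolidated by default.
DEFAULT_CONSOLIDATION_EXCLUDE = frozenset({"chrIII"})


@dataclass
class LinkageMatrix:
    chromosome: str
    bin_size: int
    n: int
    G: np.ndarray
    counts: np.ndarray
    mask: np.ndarray  # True = excluded cell
    G_prime: np.ndarray | None = None

    def __post_init__(self) -> None:
        for name in ("G", "counts", "mask"):
            arr = getattr(self, name)
            if arr.shape != (self.n, self.n):
                raise ValueError(f"{name} has shape {arr.shape}, expected {(self.n, self.n)}")

    @property
    def consolidated(self) -> np.ndarray:
        if self.G_prime is None:
            raise ValueError(
                f"chromosome {self.chromosome}: matrix not consolidated yet"
            )
        return self.G_prime

    def valid_values(self, use_prime: bool = True) -> np.ndarray:
        """Unmasked, finite cell values (consolidated if available)."""
        M = self.G_prime if (use_prime and self.G_prime is not None) else self.G
        keep = ~self.mask & np.isfinite(M)
        return M[keep]


@dataclass(frozen=True)
class MaskRule:
    """Exclude an interval (1-based, inclusive, bp) of a chromosome."""

    chromosome: str
    start: int
    end: int
    reason: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"mask rule on {self.chromosome}: start > end")


@dataclass
class ChromosomeFit:
    """Per-chromosome genetic length and the linear fit total = a·L + b."""

    per_chromosome: dict[str, tuple[float, float, float]]  # name -> (L_kb, total_gd, rate)
    a: float  # SGA-GD per kb
    b: float  # SGA-GD


def assign_bin(position: float, bin_size: int, chromosome_length: int | None = None) -> int:
    """0-based bin index of a 1-based position; bin k covers
    [k·bin_size + 1, (k+1)·bin_size]."""
    if position < 1:
        raise ValueError(f"position {position} < 1")
    if chromosome_length is not None and position > chromosome_length:
        raise ValueError(f"position {position} beyond chromosome length {chromosome_length}")
    return int((position - 1) // bin_size)


def n_bins(chromosome_length: int, bin_size: int) -> int:
    return int(math.ceil(chromosome_length / bin_size))


def build_linkage_matrix(
    pairs: Sequence[PairDistance],
    annotation: GenomeAnnotation,
    chromosome: str,
    bin_size: int = 5000,
) -> LinkageMatrix:
    """Average pair distances into a query-bin × array-bin matrix.

    Gene positions are gene midpoints; every pair must have both genes
    annotated on ``chromosome``.
    """
    chrom = annotation.chromosome(chromosome)
    n = n_bins(chrom.length, bin_size)
    sums = np.zeros((n, n))
    counts = np.zeros((n, n), dtype=int)
    for p in pairs:
        if not math.isfinite(p.sga_gd):
            continue
        bi = _gene_bin(p.query_id, annotation, chromosome, bin_size, chrom.length)
        bj = _gene_bin(p.array_id, annotation, chromosome, bin_size, chrom.length)
        sums[bi, bj] += p.sga_gd
        counts[bi, bj] += 1
    with np.errstate(invalid="ignore"):
        G = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return LinkageMatrix(
        chromosome=chromosome,
        bin_size=bin_size,
        n=n,
        G=G,
        counts=counts,
        mask=np.zeros((n, n), dtype=bool),
    )


def _gene_bin(gene_id, annotation, chromosome, bin_size, length) -> int:
    try:
        gene = annotation.gene(gene_id)
    except KeyError:
        raise KeyError(f"gene {gene_id} absent from annotation") from None
    if gene.chromosome != chromosome:
        raise ValueError(f"gene {gene_id} is on {gene.chromosome}, not {chromosome}")
    return assign_bin(gene.midpoint, bin_size, length)


def consolidate(
    lm: LinkageMatrix, exclude: Iterable[str] = DEFAULT_CONSOLIDATION_EXCLUDE
) -> LinkageMatrix:
    """Average the query→array and array→query directions, G' = (G + Gᵀ)/2.

    Cells where only one direction was measured keep that direction's value.
    Chromosomes in ``exclude`` keep G' = G untouched.
    """
    if lm.chromosome in set(exclude):
        return replace(lm, G_prime=lm.G.copy())
    G, Gt = lm.G, lm.G.T
    both = np.isfinite(G) & np.isfinite(Gt)
    either = np.isfinite(G) | np.isfinite(Gt)
    G_prime = np.full_like(G, np.nan)
    G_prime[both] = 0.5 * (G[both] + Gt[both])
    only = either & ~both
    G_prime[only] = np.where(np.isfinite(G[only]), G[only], Gt[only])
    return replace(lm, G_prime=G_prime)


def apply_masks(lm: LinkageMatrix, rules: Sequence[MaskRule]) -> LinkageMatrix:
    """Mask every cell whose row or column bin overlaps a rule interval.

    Rules for other chromosomes are ignored; overlapping rules union."""
    mask = lm.mask.copy()
    for rule in rules:
        if rule.chromosome != lm.chromosome:
            continue
        first = assign_bin(max(rule.start, 1), lm.bin_size)
        last = min(assign_bin(rule.end, lm.bin_size), lm.n - 1)
        if first > lm.n - 1:
            continue
        mask[first : last + 1, :] = True
        mask[:, first : last + 1] = True
    return replace(lm, mask=mask)


def read_mask_rules(path: str | Path) -> list[MaskRule]:
    """TSV: chromosome, start, end, [reason]."""
    rules = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: expected ≥3 fields")
            reason = parts[3] if len(parts) > 3 else ""
            rules.append(MaskRule(parts[0], int(parts[1]), int(parts[2]), reason))
    return rules


def write_mask_rules(rules: Sequence[MaskRule], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for r in rules:
            fh.write(f"{r.chromosome}\t{r.start}\t{r.end}\t{r.reason}\n")


def bin_pairs_by_distance(
    distances_kb: np.ndarray,
    values: np.ndarray,
    bin_size_kb: float = 5.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Bin (physical distance, value) pairs into fixed-width distance bins.

    Returns (bin center kb, mean value, pair count) for non-empty bins,
    sorted by distance.  NaN values are skipped.
    """
    d = np.asarray(distances_kb, dtype=float)
    v = np.asarray(values, dtype=float)
    keep = np.isfinite(d) & np.isfinite(v)
    d, v = d[keep], v[keep]
    if len(d) == 0:
        return np.array([]), np.array([]), np.array([], dtype=int)
    idx = np.floor(d / bin_size_kb).astype(int)
    uniq, inverse = np.unique(idx, return_inverse=True)
    sums = np.zeros(len(uniq))
    counts = np.zeros(len(uniq), dtype=int)
    np.add.at(sums, inverse, v)
    np.add.at(counts, inverse, 1)
    centers = (uniq + 0.5) * bin_size_kb
    return centers, sums / counts, counts


def chromosome_genetic_length(
    maps: Mapping[str, LinkageMatrix],
    annotation: GenomeAnnotation,
    cap: float = 50.0,
) -> ChromosomeFit:
    """Per-chromosome total genetic length and the linear size model.

    The per-chromosome rate (SGA-GD/kb) is the mean over unmasked,
    off-diagonal cells within the linear range (value < ``cap``) of
    cell value / physical bin separation; total = rate × length.  The least
    squares fit of total on length gives (a, b).
    """
    per: dict[str, tuple[float, float, float]] = {}
    for name, lm in maps.items():
        M = lm.G_prime if lm.G_prime is not None else lm.G
        i, j = np.indices(M.shape)
        sep_kb = np.abs(i - j) * lm.bin_size / 1000.0
        keep = (~lm.mask) & np.isfinite(M) & (i != j) & (M < cap)
        if not keep.any():
            continue
        rates = M[keep] / sep_kb[keep]
        rate = float(np.mean(rates))
        L_kb = annotation.chromosome(name).length / 1000.0
        per[name] = (L_kb, rate * L_kb, rate)
    if len(per) < 3:
        raise ValueError(f"need >= 3 chromosomes with data for the size fit, got {len(per)}")
    L = np.array([v[0] for v in per.values()])
    total = np.array([v[1] for v in per.values()])
    a, b = np.polyfit(L, total, 1)
    return ChromosomeFit(per_chromosome=per, a=float(a), b=float(b))
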