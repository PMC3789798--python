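"""Readers and writers for every external table and track the pipeline touches.

Coordinate conventions
----------------------
All positions are 1-based and inclusive internally (SGD style).  bedGraph
input, which is 0-based half-open, is converted to interval midpoints at the
reader boundary and never leaks further.

Missing values are represented as ``NaN`` — never 0, because a genetic
distance of 0 means complete linkage, which is data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Chromosome",
    "Gene",
    "GenomeAnnotation",
    "ScreenTable",
    "FitnessScreenTable",
    "GenomicTrack",
    "Site",
    "SiteList",
    "read_annotation",
    "write_annotation",
    "read_screen_matrix",
    "write_distance_matrix",
    "read_fitness_screens",
    "write_fitness_screens",
    "read_track",
    "read_track_set",
    "write_track",
    "read_sites",
    "write_sites",
]


class FormatError(ValueError):
    """Raised when an input file does not parse under the declared dialect."""


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Chromosome:
    name: str
    length: int
    centromere: int

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"chromosome {self.name}: length must be > 0")
        if not (1 <= self.centromere < self.length):
            raise ValueError(
                f"chromosome {self.name}: centromere {self.centromere} outside "
                f"[1, {self.length})"
            )


@dataclass(frozen=True)
class Gene:
    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start {self.start} > end {self.end}")

    @property
    def midpoint(self) -> float:
        """Representative position used for binning and distances."""
        return 0.5 * (self.start + self.end)


@dataclass
class GenomeAnnotation:
    """Chromosome sizes, centromere midpoints and gene coordinates."""

    chromosomes: list[Chromosome]
    genes: list[Gene] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [c.name for c in self.chromosomes]
        if len(names) != len(set(names)):
            raise ValueError("duplicate chromosome names")
        self._by_name = {c.name: c for c in self.chromosomes}
        ids = [g.gene_id for g in self.genes]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate gene ids")
        self._gene_by_id = {g.gene_id: g for g in self.genes}
        for g in self.genes:
            if g.chromosome not in self._by_name:
                raise ValueError(f"gene {g.gene_id}: unknown chromosome {g.chromosome}")
            if g.end > self._by_name[g.chromosome].length:
                raise ValueError(
                    f"gene {g.gene_id}: end {g.end} beyond chromosome "
                    f"{g.chromosome} length"
                )

    def chromosome(self, name: str) -> Chromosome:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"unknown chromosome: {name}") from None

    def gene(self, gene_id: str) -> Gene:
        try:
            return self._gene_by_id[gene_id]
        except KeyError:
            raise KeyError(f"unknown gene: {gene_id}") from None

    def genes_on(self, chromosome: str) -> list[Gene]:
        return [g for g in self.genes if g.chromosome == chromosome]

    @property
    def chromosome_names(self) -> list[str]:
        return [c.name for c in self.chromosomes]


def read_annotation(path: str | Path, format: str = "sgd_tab") -> GenomeAnnotation:
    """Read a genome annotation.

    ``sgd_tab`` is a chromosomal-features style table with columns
    ``feature_type  name  chromosome  start  end  strand`` where
    ``feature_type`` is one of ``chromosome``, ``centromere`` or ``gene``.
    ``gff3`` accepts a GFF3 subset with ``region``/``chromosome``,
    ``centromere`` and ``gene`` features (gene IDs from the ``ID=`` tag).
    Every chromosome must carry exactly one centromere record.
    """
    path = Path(path)
    if format == "sgd_tab":
        chroms, cens, genes = _parse_sgd_tab(path)
    elif format == "gff3":
        chroms, cens, genes = _parse_gff3(path)
    else:
        raise ValueError(f"unknown annotation format: {format}")

    chromosomes = []
    for name, length in chroms:
        if name not in cens:
            raise FormatError(f"{path}: no centromere record for chromosome {name}")
        chromosomes.append(Chromosome(name, length, cens[name]))
    return GenomeAnnotation(chromosomes=chromosomes, genes=genes)


def _parse_sgd_tab(path: Path):
    chroms: list[tuple[str, int]] = []
    cens: dict[str, int] = {}
    genes: list[Gene] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                raise FormatError(f"{path}:{lineno}: expected ≥5 tab fields")
            ftype, name, chrom, start_s, end_s = parts[:5]
            strand = parts[5] if len(parts) > 5 and parts[5] else "+"
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from None
            if ftype == "chromosome":
                chroms.append((name, end))
            elif ftype == "centromere":
                cens[chrom] = (start + end) // 2
            elif ftype == "gene":
                genes.append(Gene(name, chrom, start, end, strand))
            else:
                raise FormatError(f"{path}:{lineno}: unknown feature type {ftype!r}")
    return chroms, cens, genes


def _parse_gff3(path: Path):
    chroms: list[tuple[str, int]] = []
    cens: dict[str, int] = {}
    genes: list[Gene] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GFF3 fields")
            seqid, _source, ftype, start_s, end_s, _score, strand, _phase, attrs = parts
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from None
            if ftype in ("region", "chromosome"):
                chroms.append((seqid, end))
            elif ftype == "centromere":
                cens[seqid] = (start + end) // 2
            elif ftype == "gene":
                gene_id = _gff3_attr(attrs, "ID")
                if gene_id is None:
                    raise FormatError(f"{path}:{lineno}: gene feature without ID tag")
                genes.append(Gene(gene_id, seqid, start, end, strand or "+"))
    return chroms, cens, genes


def _gff3_attr(attrs: str, key: str) -> str | None:
    for item in attrs.split(";"):
        if "=" in item:
            k, v = item.split("=", 1)
            if k.strip() == key:
                return v.strip()
    return None


def write_annotation(ann: GenomeAnnotation, path: str | Path) -> None:
    """Write the ``sgd_tab`` dialect (round-trips through read_annotation)."""
    with open(path, "w", encoding="utf-8") as fh:
        for c in ann.chromosomes:
            fh.write(f"chromosome\t{c.name}\t{c.name}\t1\t{c.length}\t+\n")
            fh.write(f"centromere\tCEN_{c.name}\t{c.name}\t{c.centromere}\t{c.centromere}\t+\n")
        for g in ann.genes:
            fh.write(f"gene\t{g.gene_id}\t{g.chromosome}\t{g.start}\t{g.end}\t{g.strand}\n")


# ---------------------------------------------------------------------------
# screen matrices (File S1 dialect)
# ---------------------------------------------------------------------------


@dataclass
class ScreenTable:
    """One per-chromosome query × array matrix.

    Duplicate entries in ``query_ids`` are replicate screens and are kept in
    file order.  Missing cells are NaN.
    """

    chromosome: str
    query_ids: list[str]
    array_ids: list[str]
    values: np.ndarray
    value_kind: str = "raw_distance"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.query_ids), len(self.array_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.query_ids)} queries × {len(self.array_ids)} arrays"
            )


def _parse_matrix(path: Path):
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().split("\n")
    if lines and lines[-1] == "":
        lines.pop()
    if not lines:
        raise FormatError(f"{path}: empty file")
    header = lines[0].split("\t")
    array_ids = header[1:]
    query_ids: list[str] = []
    rows: list[list[float]] = []
    for idx, line in enumerate(lines[1:], start=1):
        parts = line.split("\t")
        if len(parts) != len(array_ids) + 1:
            raise FormatError(
                f"{path}: row {idx} has {len(parts) - 1} cells, expected {len(array_ids)}"
            )
        query_ids.append(parts[0])
        row = []
        for cell in parts[1:]:
            cell = cell.strip()
            if cell == "" or cell.upper() in ("NA", "NAN"):
                row.append(math.nan)
            else:
                row.append(float(cell))
        rows.append(row)
    values = np.array(rows, dtype=float) if rows else np.empty((0, len(array_ids)))
    return query_ids, array_ids, values


def read_screen_matrix(path: str | Path, chromosome: str | None = None) -> ScreenTable:
    """Read a File S1 style matrix: header row of array ids, first column
    query ids, tab-delimited numeric cells, empty cell = missing."""
    path = Path(path)
    query_ids, array_ids, values = _parse_matrix(path)
    return ScreenTable(
        chromosome=chromosome or path.stem,
        query_ids=query_ids,
        array_ids=array_ids,
        values=values,
        value_kind="raw_distance",
    )


def _fmt(x: float) -> str:
    if isinstance(x, float) and math.isnan(x):
        return ""
    return repr(float(x))


def write_distance_matrix(table: ScreenTable, path: str | Path) -> None:
    """Write the File S1 dialect; ``read_screen_matrix`` inverts it exactly."""
    if table.value_kind != "raw_distance":
        raise ValueError(f"expected raw_distance table, got {table.value_kind}")
    _write_matrix(table.query_ids, table.array_ids, table.values, path)


def _write_matrix(query_ids, array_ids, values, path) -> None:
    try:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("\t".join([""] + list(array_ids)) + "\n")
            for qid, row in zip(query_ids, values):
                fh.write("\t".join([qid] + [_fmt(v) for v in row]) + "\n")
    except OSError as exc:
        raise OSError(f"cannot write matrix to {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# fitness screens (triples)
# ---------------------------------------------------------------------------


@dataclass
class FitnessScreenTable:
    """Per-chromosome normalized colony sizes: a double-mutant matrix plus the
    matching single-mutant fitness of every query row and array column.

    The (row, column) cell together with ``f_query[row]`` and
    ``f_array[column]`` forms one fitness triple.  Duplicate query rows are
    replicate screens.
    """

    chromosome: str
    query_ids: list[str]
    array_ids: list[str]
    f_query: np.ndarray
    f_array: np.ndarray
    f_double: np.ndarray
    value_kind: str = "fitness_triple_set"

    def __post_init__(self) -> None:
        self.f_query = np.asarray(self.f_query, dtype=float)
        self.f_array = np.asarray(self.f_array, dtype=float)
        self.f_double = np.asarray(self.f_double, dtype=float)
        nq, na = len(self.query_ids), len(self.array_ids)
        if self.f_query.shape != (nq,) or self.f_array.shape != (na,):
            raise ValueError("single-mutant fitness vectors do not match id lists")
        if self.f_double.shape != (nq, na):
            raise ValueError("double-mutant matrix shape mismatch")


def write_fitness_screens(table: FitnessScreenTable, prefix: str | Path) -> None:
    """Write ``<prefix>.fij.tsv`` (matrix dialect) plus two sidecar fitness
    tables ``<prefix>.fq.tsv`` / ``<prefix>.fa.tsv``."""
    prefix = str(prefix)
    _write_matrix(table.query_ids, table.array_ids, table.f_double, prefix + ".fij.tsv")
    with open(prefix + ".fq.tsv", "w", encoding="utf-8") as fh:
        for qid, f in zip(table.query_ids, table.f_query):
            fh.write(f"{qid}\t{_fmt(f)}\n")
    with open(prefix + ".fa.tsv", "w", encoding="utf-8") as fh:
        for aid, f in zip(table.array_ids, table.f_array):
            fh.write(f"{aid}\t{_fmt(f)}\n")


def read_fitness_screens(prefix: str | Path, chromosome: str | None = None) -> FitnessScreenTable:
    prefix = str(prefix)
    query_ids, array_ids, f_double = _parse_matrix(Path(prefix + ".fij.tsv"))

    def _read_singles(path, ids):
        vals = []
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh):
                parts = line.rstrip("\n").split("\t")
                if len(parts) != 2:
                    raise FormatError(f"{path}:{lineno + 1}: expected 2 fields")
                vals.append(float(parts[1]) if parts[1] else math.nan)
        if len(vals) != len(ids):
            raise FormatError(f"{path}: {len(vals)} entries for {len(ids)} ids")
        return np.array(vals)

    return FitnessScreenTable(
        chromosome=chromosome or Path(prefix).name,
        query_ids=query_ids,
        array_ids=array_ids,
        f_query=_read_singles(prefix + ".fq.tsv", query_ids),
        f_array=_read_singles(prefix + ".fa.tsv", array_ids),
        f_double=f_double,
    )


# ---------------------------------------------------------------------------
# genomic tracks
# ---------------------------------------------------------------------------


@dataclass
class GenomicTrack:
    """Sparse per-position signal (Spo11-oligo counts, cohesin binding, ...)."""

    chromosome: str
    positions: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.positions.shape != self.values.shape:
            raise ValueError("positions and values differ in length")
        if len(self.positions) and np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")

    def __len__(self) -> int:
        return len(self.positions)


def _collapse(positions: np.ndarray, values: np.ndarray, duplicates: str):
    order = np.argsort(positions, kind="stable")
    positions, values = positions[order], values[order]
    uniq, inverse, counts = np.unique(positions, return_inverse=True, return_counts=True)
    summed = np.zeros(len(uniq))
    np.add.at(summed, inverse, values)
    if duplicates == "mean":
        summed = summed / counts
    elif duplicates != "sum":
        raise ValueError(f"unknown duplicate policy: {duplicates}")
    return uniq, summed


def read_track_set(
    path: str | Path, format: str = "bedgraph", duplicates: str = "sum"
) -> dict[str, GenomicTrack]:
    """Read a (possibly multi-chromosome) track file into per-chromosome tracks.

    bedGraph intervals become midpoint positions; duplicate positions are
    summed by default (count semantics) or averaged with ``duplicates="mean"``
    (ratio semantics, e.g. ChIP enrichment).
    """
    path = Path(path)
    per: dict[str, tuple[list[float], list[float]]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if format == "bedgraph":
                if len(parts) < 4:
                    raise FormatError(f"{path}:{lineno}: expected 4 bedGraph fields")
                chrom, start, end, value = parts[0], float(parts[1]), float(parts[2]), float(parts[3])
                if start < 0 or end < 0:
                    raise FormatError(f"{path}:{lineno}: negative position")
                pos = 0.5 * (start + end)
            elif format == "two_column":
                if len(parts) < 2:
                    raise FormatError(f"{path}:{lineno}: expected 2 fields")
                chrom = path.stem
                pos, value = float(parts[0]), float(parts[1])
                if pos < 0:
                    raise FormatError(f"{path}:{lineno}: negative position")
            else:
                raise ValueError(f"unknown track format: {format}")
            per.setdefault(chrom, ([], []))[0].append(pos)
            per[chrom][1].append(value)
    out = {}
    for chrom, (pos, val) in per.items():
        p, v = _collapse(np.array(pos), np.array(val), duplicates)
        out[chrom] = GenomicTrack(chrom, p, v)
    return out


def read_track(
    path: str | Path,
    format: str = "two_column",
    chromosome: str | None = None,
    duplicates: str = "sum",
) -> GenomicTrack:
    """Read a single-chromosome track (see :func:`read_track_set`)."""
    path = Path(path)
    tracks = read_track_set(path, format=format, duplicates=duplicates)
    if not tracks:
        name = chromosome or path.stem
        return GenomicTrack(name, np.array([]), np.array([]))
    if chromosome is not None and format == "bedgraph":
        if chromosome not in tracks:
            raise FormatError(f"{path}: chromosome {chromosome} not present")
        return tracks[chromosome]
    if len(tracks) > 1:
        raise FormatError(
            f"{path}: multiple chromosomes ({sorted(tracks)}); use read_track_set"
        )
    track = next(iter(tracks.values()))
    if chromosome is not None:
        track.chromosome = chromosome
    return track


def write_track(track: GenomicTrack, path: str | Path, format: str = "two_column") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if format == "two_column":
            for p, v in zip(track.positions, track.values):
                fh.write(f"{_int_or_float(p)}\t{_fmt(v)}\n")
        elif format == "bedgraph":
            # emit 1-bp intervals whose midpoint reproduces the position
            for p, v in zip(track.positions, track.values):
                lo = p - 0.5
                fh.write(f"{track.chromosome}\t{_int_or_float(lo)}\t{_int_or_float(lo + 1)}\t{_fmt(v)}\n")
        else:
            raise ValueError(f"unknown track format: {format}")


def _int_or_float(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(float(x))


# ---------------------------------------------------------------------------
# site lists (hotspots, genetic-map loci)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Site:
    chromosome: str
    position: float
    score: float | None = None


@dataclass
class SiteList:
    sites: list[Site]

    def __iter__(self):
        return iter(self.sites)

    def __len__(self) -> int:
        return len(self.sites)

    def per_chromosome(self) -> dict[str, list[Site]]:
        out: dict[str, list[Site]] = {}
        for s in self.sites:
            out.setdefault(s.chromosome, []).append(s)
        for sites in out.values():
            sites.sort(key=lambda s: s.position)
        return out

    def validate(self, annotation: GenomeAnnotation) -> None:
        for s in self.sites:
            length = annotation.chromosome(s.chromosome).length
            if not (1 <= s.position <= length):
                raise ValueError(
                    f"site at {s.chromosome}:{s.position} outside chromosome bounds"
                )


def read_sites(path: str | Path, format: str = "bed") -> SiteList:
    """Read hotspot or genetic-map locus tables.

    ``bed``: ``chrom  start  end  [score]`` (interval midpoint kept);
    ``loci``: ``locus  chrom  position_bp  cM``.
    """
    path = Path(path)
    sites: list[Site] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if format == "bed":
                if len(parts) < 3:
                    raise FormatError(f"{path}:{lineno}: expected ≥3 BED fields")
                chrom = parts[0]
                pos = 0.5 * (float(parts[1]) + float(parts[2]))
                score = float(parts[3]) if len(parts) > 3 and parts[3] not in ("", ".") else None
                sites.append(Site(chrom, pos, score))
            elif format == "loci":
                if len(parts) < 4:
                    raise FormatError(f"{path}:{lineno}: expected 4 locus fields")
                sites.append(Site(parts[1], float(parts[2]), float(parts[3])))
            else:
                raise ValueError(f"unknown site format: {format}")
    return SiteList(sites)


def write_sites(sites: SiteList | Sequence[Site], path: str | Path, format: str = "bed") -> None:
    it: Iterable[Site] = sites.sites if isinstance(sites, SiteList) else sites
    with open(path, "w", encoding="utf-8") as fh:
        for i, s in enumerate(it):
            if format == "bed":
                lo = s.position - 0.5
                score = "." if s.score is None else _fmt(s.score)
                fh.write(f"{s.chromosome}\t{_int_or_float(lo)}\t{_int_or_float(lo + 1)}\t{score}\n")
            elif format == "loci":
                fh.write(
                    f"locus{i}\t{s.chromosome}\t{_int_or_float(s.position)}\t"
                    f"{_fmt(s.score if s.score is not None else math.nan)}\n"
                )
            else:
                raise ValueError(f"unknown site format: {format}")
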