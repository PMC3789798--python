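"""Core estimators: recombinant fraction from colony sizes and its mapping to
genetic distance.

The recombinant fraction of a double mutant is estimated from normalized
colony sizes as ``R = 0.5 * f_ij / (f_i * f_j)``, so that multiplicatively
neutral pairs (``f_ij = f_i * f_j``, independent segregation) land exactly at
R = 0.5.  R is converted to a genetic distance under a Poisson (no
interference) crossover model, ``m = -ln(1 - 2R)``, ``M = m / 2`` Morgans,
reported in SGA-GD units (1 SGA-GD = 0.01 Morgans equivalent) and capped at
50, which is the distance of independently segregating loci.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "FitnessTriple",
    "PairDistance",
    "DistanceConfig",
    "EstimationError",
    "recombinant_fraction",
    "recombinant_fraction_array",
    "clip_R",
    "clip_R_array",
    "haldane_morgans",
    "sga_gd",
    "sga_gd_array",
    "pair_distance",
    "normalize_self_zero",
    "normalize_R_array",
    "unlinked_distance_threshold",
]


class EstimationError(ValueError):
    pass


@dataclass(frozen=True)
class FitnessTriple:
    """Normalized colony sizes of two single mutants and their double mutant
    (dimensionless, wild type = 1)."""

    f_i: float
    f_j: float
    f_ij: float

    def __post_init__(self) -> None:
        if self.f_i < 0 or self.f_j < 0 or self.f_ij < 0:
            raise ValueError("colony sizes must be >= 0")


@dataclass
class PairDistance:
    """Estimated linkage between one query/array gene pair."""

    query_id: str
    array_id: str
    R: float  # recombinant fraction after clipping, in [0, 0.5]
    m: float  # mean crossovers per meiosis in the interval
    M: float  # Morgans
    sga_gd: float  # SGA-GD units (cM-equivalent), capped
    clamped: bool = False


@dataclass(frozen=True)
class DistanceConfig:
    """Distance-mapping settings.

    mapping_mode:
      * ``haldane_capped`` (default) — Poisson-model correction with the
        output capped at ``cap_sga_gd``; R >= 0.5 maps to the cap.
      * ``linear`` — complete-interference mapping 100·R.
    Both map R = 0 to 0 and R = 0.5 to 50.
    """

    mapping_mode: str = "haldane_capped"
    cap_sga_gd: float = 50.0
    r_clip: tuple[float, float] = (0.0, 0.5)
    self_normalization: str = "affine_R"

    def __post_init__(self) -> None:
        if self.mapping_mode not in ("haldane_capped", "linear"):
            raise ValueError(f"unknown mapping_mode: {self.mapping_mode}")
        if self.cap_sga_gd <= 0:
            raise ValueError("cap_sga_gd must be > 0")
        lo, hi = self.r_clip
        if not (0.0 <= lo < hi <= 0.5):
            raise ValueError("r_clip must be a sub-interval of [0, 0.5]")
        if self.self_normalization not in ("affine_R", "none"):
            raise ValueError(f"unknown self_normalization: {self.self_normalization}")


def recombinant_fraction(t: FitnessTriple) -> float:
    """Raw (unclipped) recombinant-fraction estimate 0.5·f_ij/(f_i·f_j)."""
    if t.f_i <= 0 or t.f_j <= 0:
        raise EstimationError(
            "single-mutant colony size is zero (dead or missing mutant); "
            "recombinant fraction undefined"
        )
    return 0.5 * t.f_ij / (t.f_i * t.f_j)


def recombinant_fraction_array(
    f_i: np.ndarray, f_j: np.ndarray, f_ij: np.ndarray
) -> np.ndarray:
    """Vectorized estimator; non-positive single fitness yields NaN."""
    f_i = np.asarray(f_i, dtype=float)
    f_j = np.asarray(f_j, dtype=float)
    f_ij = np.asarray(f_ij, dtype=float)
    denom = f_i * f_j
    with np.errstate(divide="ignore", invalid="ignore"):
        R = 0.5 * f_ij / denom
    return np.where(denom > 0, R, np.nan)


def clip_R(R: float, config: DistanceConfig = DistanceConfig()) -> tuple[float, bool]:
    if not math.isfinite(R):
        raise EstimationError(f"non-finite recombinant fraction: {R}")
    lo, hi = config.r_clip
    clipped = min(max(R, lo), hi)
    return clipped, clipped != R


def clip_R_array(R: np.ndarray, config: DistanceConfig = DistanceConfig()):
    R = np.asarray(R, dtype=float)
    lo, hi = config.r_clip
    clipped = np.clip(R, lo, hi)
    with np.errstate(invalid="ignore"):
        clamped = np.isfinite(R) & (clipped != R)
    return clipped, clamped


def haldane_morgans(R: float) -> tuple[float, float]:
    """Map recombinant fraction to (m, M): crossovers per meiosis and Morgans.

    Defined for 0 <= R < 0.5 only; callers with possibly saturated R must go
    through :func:`sga_gd`, which absorbs the domain edge with the cap.
    """
    if not (0.0 <= R < 0.5):
        raise ValueError(f"R = {R} outside Haldane domain [0, 0.5)")
    m = -math.log1p(-2.0 * R)
    return m, 0.5 * m


def sga_gd(R: float, config: DistanceConfig = DistanceConfig()) -> float:
    """Map a recombinant fraction to SGA-GD under the configured mode."""
    R_c, _ = clip_R(R, config)
    if config.mapping_mode == "linear":
        return 100.0 * R_c
    if R_c >= 0.5:
        return config.cap_sga_gd
    _, M = haldane_morgans(R_c)
    return min(config.cap_sga_gd, 100.0 * M)


def sga_gd_array(R: np.ndarray, config: DistanceConfig = DistanceConfig()) -> np.ndarray:
    R_c, _ = clip_R_array(R, config)
    if config.mapping_mode == "linear":
        return 100.0 * R_c
    out = np.full(R_c.shape, np.nan)
    finite = np.isfinite(R_c)
    sub = finite & (R_c < 0.5)
    with np.errstate(divide="ignore"):
        out[sub] = np.minimum(config.cap_sga_gd, -50.0 * np.log1p(-2.0 * R_c[sub]))
    out[finite & (R_c >= 0.5)] = config.cap_sga_gd
    return out


def pair_distance(
    query_id: str, array_id: str, R: float, config: DistanceConfig = DistanceConfig()
) -> PairDistance:
    """Package a raw R estimate into a fully derived :class:`PairDistance`."""
    R_c, clamped = clip_R(R, config)
    if R_c < 0.5:
        m, M = haldane_morgans(R_c)
    else:
        m, M = math.inf, math.inf
    return PairDistance(
        query_id=query_id,
        array_id=array_id,
        R=R_c,
        m=m,
        M=M,
        sga_gd=sga_gd(R, config),
        clamped=clamped,
    )


def normalize_R_array(R: np.ndarray, self_R: float) -> np.ndarray:
    """Affine self-normalization on the R scale.

    Anchors the query-self residual colony at R' = 0 and independent
    segregation at R' = 0.5:  R' = 0.5·(R − self_R)/(0.5 − self_R).
    """
    if not (0.0 <= self_R < 0.5):
        raise EstimationError(
            f"self recombinant fraction {self_R} >= 0.5: screen uninformative"
        )
    return 0.5 * (np.asarray(R, dtype=float) - self_R) / (0.5 - self_R)


def normalize_self_zero(
    pairs: Sequence[PairDistance],
    self_R: float,
    config: DistanceConfig = DistanceConfig(),
) -> list[PairDistance]:
    """Re-anchor a screen so that the query-self distance is exactly zero.

    In ``affine_R`` mode every pair's R is remapped through
    :func:`normalize_R_array` (then re-clipped and re-converted); ``none``
    mode returns the input unchanged.
    """
    if config.self_normalization == "none":
        return list(pairs)
    out = []
    for p in pairs:
        R_new = float(normalize_R_array(np.array(p.R), self_R))
        q = pair_distance(p.query_id, p.array_id, R_new, config)
        q.clamped = q.clamped or p.clamped
        out.append(q)
    return out


def unlinked_distance_threshold(
    profile: Sequence[tuple[float, float]], threshold: float = 50.0
) -> float:
    """Smallest physical distance (kb) at which the mean genetic distance
    reaches ``threshold``, linearly interpolated between bracketing bins.

    ``profile`` is a sequence of (physical distance kb, mean SGA-GD) bins.
    Returns NaN with a warning when the threshold is never reached.
    """
    pts = sorted((float(d), float(g)) for d, g in profile)
    if not pts:
        raise ValueError("empty distance profile")
    for i, (d, g) in enumerate(pts):
        if g >= threshold:
            if i == 0:
                return d
            d0, g0 = pts[i - 1]
            if g == g0:
                return d
            return d0 + (threshold - g0) * (d - d0) / (g - g0)
    warnings.warn(
        f"mean genetic distance never reaches {threshold}; unlinked distance "
        "threshold unavailable",
        stacklevel=2,
    )
    return math.nan
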