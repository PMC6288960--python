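"""Synthetic continental populations and shotgun reads.

Generates the study design the pipeline expects — three diverged continental
populations, each sampled as error-bearing short reads at a configurable
number of bases per sample — so every stage can be exercised end to end
without downloads. Evolution is substitution-only on a star phylogeny
(root → continent ancestors → individuals); a "chain" phylogeny variant
links continents serially with branch lengths scaled by the great-circle
separation of their centers, producing isolation-by-distance structure.

This is deliberately not a coalescent model: it produces the hierarchical
divergence the provenance analysis assumes, nothing more.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .sequence_io import ReadSet, SampleMeta

__all__ = [
    "SimulationConfig",
    "simulate_root_genome",
    "evolve",
    "simulate_samples",
    "sequence_reads",
    "inject_errors",
    "simulate_readsets",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i

#: Continent labels paired with the default centers below.
DEFAULT_CONTINENTS = ("NA", "EU", "AS")
DEFAULT_CENTERS = ((40.0, -95.0), (48.0, 10.0), (45.0, 125.0))

_KM_PER_DEG_LAT = 111.32


@dataclass
class SimulationConfig:
    """All parameters of the population / read generator.

    Defaults are the desk-scale preset: a 200 kb genome, 12 individuals in
    each of 3 continents diverged at 2% (continental) and 0.2% (individual)
    substitution rates, 100 bp reads totalling 200 kb per sample at a 0.1%
    per-base error rate — a scaled stand-in for a ~0.8 Gb genome, 92 samples
    and 50–300 Mbp of sequence per sample.
    """

    genome_length: int = 200_000
    n_continents: int = 3
    delta_continental: float = 0.02
    delta_individual: float = 0.002
    n_individuals: int = 12
    read_length: int = 100
    bases_per_sample: int = 200_000
    error_rate: float = 0.001
    gc_content: float = 0.5
    seed: int = 0
    continent_centers: tuple[tuple[float, float], ...] = DEFAULT_CENTERS
    within_spread_km: float = 300.0
    phylogeny: str = "star"

    def __post_init__(self) -> None:
        for name in ("delta_continental", "delta_individual", "error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not 0.0 <= self.gc_content <= 1.0:
            raise ValueError("gc_content outside [0, 1]")
        if self.genome_length < self.read_length:
            raise ValueError("genome_length must be >= read_length")
        if len(self.continent_centers) < self.n_continents:
            raise ValueError("need a center for every continent")
        if self.phylogeny not in ("star", "chain"):
            raise ValueError(f"unknown phylogeny {self.phylogeny!r}")
        if self.delta_individual >= self.delta_continental:
            warnings.warn(
                "delta_individual >= delta_continental: continents will not be separable",
                stacklevel=2,
            )

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


def _codes_to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode()


def _str_to_codes(seq: str) -> np.ndarray:
    codes = _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)].astype(np.int8)
    if (codes < 0).any():
        raise ValueError("sequence contains non-ACGT characters")
    return codes


def simulate_root_genome(L: int, gc_content: float = 0.5, seed: int = 0) -> str:
    """I.i.d. random genome with P(G)=P(C)=gc/2 and P(A)=P(T)=(1−gc)/2."""
    if L < 1:
        raise ValueError("genome length must be >= 1")
    if not 0.0 <= gc_content <= 1.0:
        raise ValueError("gc_content outside [0, 1]")
    rng = np.random.default_rng(seed)
    at, gc = (1 - gc_content) / 2, gc_content / 2
    codes = rng.choice(4, size=L, p=[at, gc, gc, at]).astype(np.int8)
    return _codes_to_str(codes)


def _mutate_codes(codes: np.ndarray, delta: float, rng: np.random.Generator) -> np.ndarray:
    """Independent per-site substitution, uniform over the 3 alternative bases."""
    out = codes.copy()
    hit = rng.random(codes.size) < delta
    n = int(hit.sum())
    if n:
        offsets = rng.integers(1, 4, size=n).astype(np.int8)
        valid = out[hit] >= 0  # never mutate N positions
        idx = np.nonzero(hit)[0][valid]
        out[idx] = (out[idx] + offsets[valid]) % 4
    return out


def evolve(seq: str, delta: float, seed: int = 0) -> str:
    """Substitute each site independently with probability ``delta``.

    Substituted bases are drawn uniformly from the three alternatives, with
    no transition/transversion bias; length is preserved.
    """
    if not 0.0 <= delta <= 1.0:
        raise ValueError("delta outside [0, 1]")
    rng = np.random.default_rng(seed)
    return _codes_to_str(_mutate_codes(_str_to_codes(seq), delta, rng))


def _scatter_coords(
    center: tuple[float, float], spread_km: float, rng: np.random.Generator
) -> tuple[float, float]:
    lat0, lon0 = center
    dlat = rng.normal(0.0, spread_km) / _KM_PER_DEG_LAT
    dlon = rng.normal(0.0, spread_km) / (_KM_PER_DEG_LAT * max(0.1, math.cos(math.radians(lat0))))
    lat = min(90.0, max(-90.0, lat0 + dlat))
    lon = ((lon0 + dlon + 180.0) % 360.0) - 180.0
    if lon == -180.0:
        lon = 180.0
    return lat, lon


def _continent_label(i: int) -> str:
    return DEFAULT_CONTINENTS[i] if i < len(DEFAULT_CONTINENTS) else f"C{i + 1}"


def simulate_samples(cfg: SimulationConfig) -> tuple[dict[str, str], list[SampleMeta]]:
    """Individual genomes plus metadata for all continents.

    Star phylogeny: each continent ancestor is the root evolved at
    ``delta_continental``; each individual is its ancestor evolved at
    ``delta_individual``. Chain phylogeny: continent ancestors form a serial
    chain with branch lengths proportional to the great-circle separation of
    consecutive continent centers (isolation by distance).
    """
    rng = np.random.default_rng(cfg.seed)
    root = _str_to_codes(simulate_root_genome(cfg.genome_length, cfg.gc_content, cfg.seed))
    ancestors: list[np.ndarray] = []
    if cfg.phylogeny == "star":
        for _ in range(cfg.n_continents):
            ancestors.append(_mutate_codes(root, cfg.delta_continental, rng))
    else:
        from .geostats import great_circle

        centers = cfg.continent_centers[: cfg.n_continents]
        steps = [great_circle(*centers[i], *centers[i + 1]) for i in range(len(centers) - 1)]
        ref = max(steps) if steps else 1.0
        current = _mutate_codes(root, cfg.delta_continental, rng)
        ancestors.append(current)
        for step in steps:
            current = _mutate_codes(current, cfg.delta_continental * step / ref, rng)
            ancestors.append(current)

    genomes: dict[str, str] = {}
    metas: list[SampleMeta] = []
    for c in range(cfg.n_continents):
        label = _continent_label(c)
        center = cfg.continent_centers[c]
        for i in range(cfg.n_individuals):
            sid = f"{label}_{i:02d}"
            genomes[sid] = _codes_to_str(
                _mutate_codes(ancestors[c], cfg.delta_individual, rng)
            )
            lat, lon = _scatter_coords(center, cfg.within_spread_km, rng)
            metas.append(
                SampleMeta(sample_id=sid, continent=label, latitude=lat, longitude=lon)
            )
    return genomes, metas


def sequence_reads(
    genome: str,
    read_length: int,
    bases_per_sample: int,
    error_rate: float = 0.0,
    seed: int = 0,
    sample_id: str = "",
) -> ReadSet:
    """Shotgun reads from one genome.

    Start positions uniform over the genome, strand uniform (reverse
    complement with probability ½), independent per-base substitution errors;
    reads accumulate until the total reaches ``bases_per_sample``.
    """
    codes = _str_to_codes(genome)
    L = codes.size
    if read_length > L:
        raise ValueError("read_length exceeds genome length")
    rng = np.random.default_rng(seed)
    n_reads = -(-bases_per_sample // read_length)  # ceil
    starts = rng.integers(0, L - read_length + 1, size=n_reads)
    flips = rng.random(n_reads) < 0.5
    reads: list[str] = []
    for start, flip in zip(starts, flips):
        r = codes[start : start + read_length]
        if flip:
            r = (3 - r)[::-1]
        if error_rate > 0:
            r = _mutate_codes(r, error_rate, rng)
        reads.append(_codes_to_str(r))
    return ReadSet(sample_id=sample_id, reads=reads)


def inject_errors(rs: ReadSet, rate: float = 0.05, seed: int = 0) -> ReadSet:
    """Additional uniform substitution errors at ``rate`` per base.

    Emulates adding simulated sequencing error on top of whatever error the
    reads already carry; N bases are left untouched and read count/lengths
    are preserved.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate outside [0, 1]")
    rng = np.random.default_rng(seed)
    out: list[str] = []
    for read in rs.reads:
        codes = _CODE[np.frombuffer(read.encode(), dtype=np.uint8)].astype(np.int8)
        mutated = _mutate_codes(codes, rate, rng)
        chars = np.where(codes >= 0, _BASES[np.clip(mutated, 0, 3)], ord("N")).astype(np.uint8)
        out.append(chars.tobytes().decode())
    return ReadSet(sample_id=rs.sample_id, reads=out)


def simulate_readsets(
    cfg: SimulationConfig,
) -> tuple[dict[str, ReadSet], list[SampleMeta]]:
    """Full synthetic cohort: genomes, then shotgun reads for every sample.

    Per-sample read seeds are drawn from the config seed so the whole cohort
    is reproducible from the one config.
    """
    genomes, metas = simulate_samples(cfg)
    seed_rng = np.random.default_rng(cfg.seed + 1)
    readsets: dict[str, ReadSet] = {}
    for sid in genomes:
        readsets[sid] = sequence_reads(
            genomes[sid],
            cfg.read_length,
            cfg.bases_per_sample,
            cfg.error_rate,
            seed=int(seed_rng.integers(0, 2**31 - 1)),
            sample_id=sid,
        )
    return readsets, metas
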