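"""Reading, subsampling and annotating shotgun read sets.

Shotgun samples arrive as FASTA/FASTQ files (optionally gzipped) of short
reads. Because mean k-mer dissimilarities drift with sequencing quantity,
samples are down-sampled to a fixed total number of bases before profiling;
disjoint partitions of one read pool drive the NGS-confidence score.
Continent labels are derived from country / longitude metadata.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "ReadSet",
    "SampleMeta",
    "InsufficientDataError",
    "FormatError",
    "read_sequences",
    "write_sequences",
    "downsample_reads",
    "partition_reads",
    "assign_continent",
    "read_metadata",
    "write_metadata",
]

CONTINENTS = ("NA", "EU", "AS")

#: Countries whose samples are North American regardless of longitude.
NORTH_AMERICAN_COUNTRIES = frozenset({"usa", "united states", "united states of america", "canada"})

#: Longitude (degrees east) splitting Europe from Asia.
EU_AS_LONGITUDE_SPLIT = 60.0


class FormatError(ValueError):
    """Unreadable or unrecognised sequence / matrix file format."""


class InsufficientDataError(ValueError):
    """A sample does not carry enough bases for the requested operation."""


@dataclass
class ReadSet:
    """An ordered collection of DNA reads for one sample.

    Reads are upper-case strings over ``{A, C, G, T, N}``; ``total_bases``
    is always the sum of read lengths.
    """

    sample_id: str
    reads: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.reads = [r.upper() for r in self.reads]
        bad = set("".join(self.reads)) - set("ACGTN")
        if bad:
            raise ValueError(f"invalid characters in reads: {sorted(bad)}")

    @property
    def total_bases(self) -> int:
        return sum(len(r) for r in self.reads)

    @property
    def n_reads(self) -> int:
        return len(self.reads)

    @property
    def max_read_length(self) -> int:
        return max((len(r) for r in self.reads), default=0)


@dataclass
class SampleMeta:
    """Metadata for one sample: identity, origin label and coordinates."""

    sample_id: str
    continent: str = "UNKNOWN"
    latitude: float | None = None
    longitude: float | None = None
    country: str = ""

    def __post_init__(self) -> None:
        if self.continent not in (*CONTINENTS, "UNKNOWN"):
            raise ValueError(f"unknown continent label {self.continent!r}")
        if self.latitude is not None and not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude {self.latitude} out of [-90, 90]")
        if self.longitude is not None and not -180.0 < self.longitude <= 180.0:
            raise ValueError(f"longitude {self.longitude} out of (-180, 180]")


def _detect_format(path: Path) -> str:
    suffixes = [s.lower() for s in path.suffixes]
    if suffixes and suffixes[-1] in (".gz", ".gzip"):
        suffixes = suffixes[:-1]
    if not suffixes:
        raise FormatError(f"cannot detect sequence format of {path}")
    ext = suffixes[-1]
    if ext in (".fa", ".fasta", ".fna", ".ffn"):
        return "fasta"
    if ext in (".fq", ".fastq"):
        return "fastq"
    raise FormatError(f"unrecognised sequence file extension {ext!r} ({path})")


def _open_text(path: Path):
    if path.suffix.lower() in (".gz", ".gzip"):
        return gzip.open(path, "rt")
    return open(path)


def read_sequences(path: str | Path, format: str = "auto", sample_id: str | None = None) -> ReadSet:
    """Read all reads from a FASTA/FASTQ file (gzip allowed) in file order.

    Parameters
    ----------
    path:
        Sequence file. With ``format="auto"`` the format is taken from the
        extension (``.fa/.fasta/.fna`` vs ``.fq/.fastq``, ``.gz`` allowed).
    sample_id:
        Defaults to the file name without sequence/compression extensions.

    FASTQ quality strings are read and discarded; no quality filtering is
    applied. An empty file yields an empty :class:`ReadSet` with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "auto":
        format = _detect_format(path)
    if format not in ("fasta", "fastq"):
        raise FormatError(f"unsupported format {format!r}")
    if sample_id is None:
        sample_id = path.name
        for ext in (".gz", ".gzip", ".fa", ".fasta", ".fna", ".ffn", ".fq", ".fastq"):
            if sample_id.lower().endswith(ext):
                sample_id = sample_id[: -len(ext)]
    with _open_text(path) as fh:
        reads = [str(rec.seq).upper() for rec in SeqIO.parse(fh, format)]
    if not reads:
        warnings.warn(f"no reads found in {path}", stacklevel=2)
    return ReadSet(sample_id=sample_id, reads=reads)


def write_sequences(rs: ReadSet, path: str | Path, format: str = "auto") -> Path:
    """Write a read set as FASTA or FASTQ (constant quality); gzip by extension."""
    path = Path(path)
    if format == "auto":
        format = _detect_format(path)
    lines: list[str] = []
    for i, read in enumerate(rs.reads):
        name = f"{rs.sample_id}_r{i}"
        if format == "fasta":
            lines.append(f">{name}\n{read}\n")
        else:
            lines.append(f"@{name}\n{read}\n+\n{'I' * len(read)}\n")
    opener = gzip.open if path.suffix.lower() in (".gz", ".gzip") else open
    with opener(path, "wt") as fh:
        fh.write("".join(lines))
    return path


def downsample_reads(rs: ReadSet, target_bases: int, seed: int) -> ReadSet:
    """Random subset of whole reads totalling at least ``target_bases``.

    Reads are drawn uniformly without replacement until the running total
    first reaches or exceeds the target, so the output total lies in
    ``[target_bases, target_bases + max read length)``. Deterministic for a
    given seed. Reads are never trimmed.
    """
    if target_bases <= 0:
        raise ValueError("target_bases must be positive")
    if target_bases > rs.total_bases:
        raise InsufficientDataError(
            f"sample {rs.sample_id}: requested {target_bases} bases "
            f"but only {rs.total_bases} available"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(rs.reads))
    chosen: list[str] = []
    total = 0
    for idx in order:
        chosen.append(rs.reads[idx])
        total += len(rs.reads[idx])
        if total >= target_bases:
            break
    return ReadSet(sample_id=rs.sample_id, reads=chosen)


def partition_reads(rs: ReadSet, n_parts: int, part_bases: int, seed: int) -> list[ReadSet]:
    """Split a read pool into up to ``n_parts`` disjoint subsets of ~``part_bases``.

    Reads are permuted once and assigned greedily: each part accumulates whole
    reads until its total reaches ``part_bases``. If the pool is exhausted
    before all parts are complete, the completed parts are returned with a
    warning; an incomplete trailing part is discarded.
    """
    if n_parts <= 0 or part_bases <= 0:
        raise ValueError("n_parts and part_bases must be positive")
    if part_bases > rs.total_bases:
        raise InsufficientDataError(
            f"sample {rs.sample_id}: part size {part_bases} exceeds total {rs.total_bases}"
        )
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(len(rs.reads)))
    parts: list[ReadSet] = []
    current: list[str] = []
    total = 0
    while order and len(parts) < n_parts:
        idx = order.pop()
        current.append(rs.reads[idx])
        total += len(rs.reads[idx])
        if total >= part_bases:
            parts.append(
                ReadSet(sample_id=f"{rs.sample_id}_part{len(parts)}", reads=current)
            )
            current, total = [], 0
    if len(parts) < n_parts:
        warnings.warn(
            f"sample {rs.sample_id}: read pool exhausted after {len(parts)} of "
            f"{n_parts} requested parts",
            stacklevel=2,
        )
    return parts


def assign_continent(meta: SampleMeta) -> str:
    """Continent label from country / longitude.

    United States and Canada samples are North America (NA); otherwise
    samples west of 60°E longitude are Europe (EU) and samples east of it
    are Asia (AS). The country check takes precedence so NA samples are
    classified correctly at any longitude.
    """
    if meta.country and meta.country.strip().lower() in NORTH_AMERICAN_COUNTRIES:
        return "NA"
    if meta.longitude is not None:
        return "EU" if meta.longitude < EU_AS_LONGITUDE_SPLIT else "AS"
    raise ValueError(
        f"sample {meta.sample_id}: neither a recognised country nor a longitude available"
    )


def read_metadata(path: str | Path) -> list[SampleMeta]:
    """Read the tab-separated metadata table.

    Columns: ``sample_id``, ``country``, ``latitude``, ``longitude``,
    ``continent``. A blank continent is derived via :func:`assign_continent`;
    the literal string ``UNKNOWN`` marks query samples.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"sample_id", "country", "latitude", "longitude", "continent"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"metadata table {path} missing columns {sorted(missing)}")
    metas: list[SampleMeta] = []
    for row in df.itertuples(index=False):
        lat = float(row.latitude) if row.latitude.strip() else None
        lon = float(row.longitude) if row.longitude.strip() else None
        meta = SampleMeta(
            sample_id=row.sample_id,
            continent=row.continent.strip() or "UNKNOWN",
            latitude=lat,
            longitude=lon,
            country=row.country.strip(),
        )
        if not row.continent.strip():
            meta.continent = assign_continent(meta)
        metas.append(meta)
    return metas


def write_metadata(metas: Iterable[SampleMeta], path: str | Path) -> Path:
    """Write sample metadata as the tab-separated table read_metadata expects."""
    rows = [
        {
            "sample_id": m.sample_id,
            "country": m.country,
            "latitude": "" if m.latitude is None else repr(m.latitude),
            "longitude": "" if m.longitude is None else repr(m.longitude),
            "continent": m.continent,
        }
        for m in metas
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return Path(path)


def labels_from_metas(metas: Sequence[SampleMeta]) -> dict[str, str]:
    """Convenience ``sample_id -> continent`` map (UNKNOWN entries excluded)."""
    return {m.sample_id: m.continent for m in metas if m.continent != "UNKNOWN"}
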