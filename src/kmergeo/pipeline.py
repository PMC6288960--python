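"""End-to-end orchestration: reads → profiles → matrix → classification/statistics.

One :func:`run_pipeline` call produces a run directory with the distance
matrix, nearest-neighbor link table, cross-validated accuracy table,
permutation-test results, PCoA coordinates, geographic-correlation summary
and per-sample reference-confidence scores, plus a manifest recording the
configuration and seed so the run can be reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .dissimilarity import (
    DissimilarityMatrix,
    SampleKmerData,
    build_sample_data,
    pairwise_matrix,
    write_matrix,
)
from .geoclassify import evaluate_splits, nn_link_table, reference_confidence
from .geostats import geo_correlation, pcoa, permutation_test
from .kmer_profile import default_k_m
from .sequence_io import (
    ReadSet,
    SampleMeta,
    downsample_reads,
    labels_from_metas,
    read_metadata,
    read_sequences,
)
from .synthetic_data import SimulationConfig, simulate_readsets

logger = logging.getLogger("kmergeo")

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "stage_seed"]

_STAGES = (
    "simulate",
    "downsample",
    "profiles",
    "matrix",
    "links",
    "crossval",
    "permtest",
    "pcoa",
    "geocorr",
    "confidence",
)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed.

    Combines the master seed with a CRC32 hash of the stage name modulo
    2^31, so any stage can be rerun in isolation with the same randomness.
    """
    return (master_seed * 0x9E3779B1 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class RunConfig:
    """Parameters of one pipeline run.

    ``k``/``m`` default to the genome-scale pairing k=12, m=10 (filled by the
    k = m + 2 rule if only one is given); the simulate preset drops to the
    desk-scale k=8, m=2.
    """

    k: int | None = None
    m: int | None = None
    measure: str = "d2star"
    strand: str = "both"
    bases: int | None = None
    K_values: tuple[int, ...] = (1, 2, 3, 4, 5)
    train_size: int | None = None
    n_splits: int = 100
    B_permutations: int = 10_000
    B_bootstrap: int = 200
    seed: int = 0
    reads_dir: str | Path | None = None
    metadata: str | Path | None = None
    simulate: SimulationConfig | None = None

    def resolved_km(self) -> tuple[int, int]:
        if self.simulate is not None and self.k is None and self.m is None:
            return 8, 2
        return default_k_m(self.k, self.m)


def _load_readsets(cfg: RunConfig) -> tuple[dict[str, ReadSet], list[SampleMeta]]:
    if cfg.simulate is not None:
        sim = cfg.simulate.with_seed(stage_seed(cfg.seed, "simulate"))
        return simulate_readsets(sim)
    if cfg.reads_dir is None or cfg.metadata is None:
        raise PipelineError("stage input: need reads_dir and metadata, or a simulate config")
    meta_path = Path(cfg.metadata)
    if not meta_path.exists():
        raise PipelineError(f"stage input: metadata file not found: {meta_path}")
    metas = read_metadata(meta_path)
    reads_dir = Path(cfg.reads_dir)
    readsets: dict[str, ReadSet] = {}
    for meta in metas:
        matches = sorted(
            p
            for p in reads_dir.iterdir()
            if p.name.startswith(meta.sample_id + ".")
        )
        if not matches:
            raise PipelineError(
                f"stage input: no sequence file for sample {meta.sample_id} in {reads_dir}"
            )
        readsets[meta.sample_id] = read_sequences(matches[0], sample_id=meta.sample_id)
    return readsets, metas


def run_pipeline(cfg: RunConfig, out_dir: str | Path) -> dict[str, Path]:
    """Run every stage and write one directory of TSV/PHYLIP outputs.

    Returns a map from stage name to the main file it produced. A stage
    failure raises :class:`PipelineError` naming the stage; outputs written
    before the failure are retained alongside an ``INCOMPLETE`` marker file.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    incomplete = out / "INCOMPLETE"
    incomplete.touch()
    produced: dict[str, Path] = {}
    k, m = cfg.resolved_km()
    manifest = {
        "version": __version__,
        "config": _manifest_config(cfg),
        "k": k,
        "m": m,
        "stage_seeds": {s: stage_seed(cfg.seed, s) for s in _STAGES},
    }

    stage = "input"
    try:
        readsets, metas = _load_readsets(cfg)
        labels = labels_from_metas(metas)
        logger.info("loaded %d samples", len(readsets))

        if cfg.bases is not None:
            stage = "downsample"
            ds_seed = stage_seed(cfg.seed, "downsample")
            readsets = {
                sid: downsample_reads(rs, cfg.bases, ds_seed + i)
                for i, (sid, rs) in enumerate(sorted(readsets.items()))
            }

        stage = "profiles"
        samples = [
            build_sample_data(readsets[sid], k=k, m=m, measure=cfg.measure, strand=cfg.strand)
            for sid in sorted(readsets)
        ]

        stage = "matrix"
        dm = pairwise_matrix(samples, cfg.measure)
        produced["matrix"] = write_matrix(dm, out / "matrix.phylip", "phylip")
        write_matrix(dm, out / "matrix.tsv", "tsv")

        stage = "links"
        links = nn_link_table(dm, labels)
        produced["links"] = out / "nn_links.tsv"
        links.to_csv(produced["links"], sep="\t", index=False)

        stage = "crossval"
        n = len(dm)
        train_size = cfg.train_size if cfg.train_size is not None else n - 1
        acc = evaluate_splits(
            dm,
            labels,
            train_size=train_size,
            K_values=cfg.K_values,
            n_splits=cfg.n_splits,
            seed=stage_seed(cfg.seed, "crossval"),
        )
        produced["crossval"] = out / "accuracy.tsv"
        acc.to_csv(produced["crossval"], sep="\t", index=False)

        stage = "permtest"
        perm_rows = []
        groups = sorted(set(labels.values()))
        for group in [*groups, "ALL"]:
            res = permutation_test(
                dm, labels, group=group, B=cfg.B_permutations, seed=stage_seed(cfg.seed, "permtest")
            )
            perm_rows.append(dataclasses.asdict(res))
        produced["permtest"] = out / "permtest.tsv"
        pd.DataFrame(perm_rows).to_csv(produced["permtest"], sep="\t", index=False)

        stage = "pcoa"
        ord_res = pcoa(dm)
        produced["pcoa"] = out / "pcoa_coords.tsv"
        ord_res.to_dataframe().to_csv(produced["pcoa"], sep="\t", index=False)
        pd.DataFrame(
            {
                "eigenvalue": ord_res.eigenvalues,
                "variance_explained": ord_res.variance_explained,
            }
        ).to_csv(out / "pcoa_eigenvalues.tsv", sep="\t", index=False)

        stage = "geocorr"
        have_coords = all(
            m_.latitude is not None and m_.longitude is not None for m_ in metas
        )
        if have_coords:
            corr = geo_correlation(dm, metas)
            produced["geocorr"] = out / "geocorr.tsv"
            pd.DataFrame([dataclasses.asdict(corr)]).to_csv(
                produced["geocorr"], sep="\t", index=False
            )

        stage = "confidence"
        conf_rows = []
        rc_seed = stage_seed(cfg.seed, "confidence")
        for sid in dm.sample_ids:
            rc = reference_confidence(
                dm, labels, sid, K_values=(1, 3), B=cfg.B_bootstrap, seed=rc_seed
            )
            conf_rows.append({"sample_id": sid, "RC_K1": rc[1], "RC_K3": rc[3]})
        produced["confidence"] = out / "confidence.tsv"
        pd.DataFrame(conf_rows).to_csv(produced["confidence"], sep="\t", index=False)
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    incomplete.unlink()
    return produced


def _manifest_config(cfg: RunConfig) -> dict:
    d = dataclasses.asdict(cfg)
    if d.get("simulate") is not None:
        d["simulate"] = dataclasses.asdict(cfg.simulate)
    for key in ("reads_dir", "metadata"):
        if d.get(key) is not None:
            d[key] = str(d[key])
    return d
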