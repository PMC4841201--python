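"""End-to-end workflows: whole-community comparison and within-genome scans.

Each run writes its resolved configuration as JSON next to the outputs, so
any artifact set can be regenerated byte-for-byte. Progress and stage
timings go to the logger (stderr under the CLI); files carry only results.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import comparison, kmer_core, window_analysis
from .sequence_io import (
    Genome,
    ValidationError,
    apply_labels,
    read_fasta,
    read_labels,
    write_matrix,
    write_newick,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Resolved parameters of a pipeline run; serialized beside every output."""

    k: int = 4
    canonicalize: bool = True
    universality_filter: bool = True
    window_size: int = 2000
    step: int = 500
    pca_log: bool = True
    expected_denominator: str = "length"
    seed: int = 0

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


def _timed(stage: str, t0: float) -> float:
    t1 = time.perf_counter()
    logger.info("stage %s: %.2f s", stage, t1 - t0)
    return t1


def compute_vectors(genomes: list[Genome], config: RunConfig) -> list[kmer_core.UsageVector]:
    """Usage vectors for a genome collection under a run configuration."""
    vectors = [
        kmer_core.usage_deviation(g, config.k, config.expected_denominator) for g in genomes
    ]
    if config.canonicalize:
        vectors = [kmer_core.canonicalize(v) for v in vectors]
    if config.universality_filter:
        n_before = len(vectors[0].words)
        vectors = kmer_core.filter_universal(vectors)
        logger.info(
            "universality filter removed %d of %d words",
            n_before - len(vectors[0].words),
            n_before,
        )
    return vectors


def vectors_to_table(vectors: list[kmer_core.UsageVector]) -> pd.DataFrame:
    """Deviation table: one row per genome, one column per retained word."""
    return pd.DataFrame(
        np.vstack([v.deviation_array() for v in vectors]),
        index=[v.source_id for v in vectors],
        columns=list(vectors[0].words),
    )


def run_compare(
    fasta: str | Path,
    outdir: str | Path,
    labels: str | Path | None = None,
    config: RunConfig | None = None,
) -> dict[str, Path]:
    """Full comparison workflow: TUD table, distances, trees, PCA, monophyly.

    With only 2 genomes the trees are skipped (neighbor joining needs 3
    leaves) but the deviation table and distance matrix are still written.
    Returns a mapping from artifact name to path.
    """
    config = config or RunConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    t0 = time.perf_counter()

    genomes = read_fasta(fasta)
    if len(genomes) < 2:
        raise ValidationError("run_compare requires at least 2 genomes")
    label_map = read_labels(labels) if labels else None
    if label_map:
        apply_labels(genomes, label_map)
    t0 = _timed("read", t0)

    vectors = compute_vectors(genomes, config)
    table = vectors_to_table(vectors)
    outputs["tud"] = outdir / "tud.tsv"
    table.to_csv(outputs["tud"], sep="\t", index_label="genome_id")
    t0 = _timed("tud", t0)

    dm = comparison.distance_matrix(vectors)
    outputs["dist"] = outdir / "dist.tsv"
    write_matrix(dm, outputs["dist"])
    t0 = _timed("distances", t0)

    trees = {}
    if len(genomes) >= 3:
        trees["nj"] = comparison.neighbor_joining(dm)
        outputs["nj"] = outdir / "nj.nwk"
        write_newick(trees["nj"], outputs["nj"])
    else:
        logger.info("only 2 genomes: neighbor joining skipped")
    trees["average"] = comparison.average_linkage(dm)
    outputs["average"] = outdir / "average.nwk"
    write_newick(trees["average"], outputs["average"])
    t0 = _timed("trees", t0)

    result = comparison.pca(vectors, log_transform=config.pca_log)
    n_comp = result.scores.shape[1]
    pcs = [f"PC{i+1}" for i in range(n_comp)]
    outputs["pca_scores"] = outdir / "pca_scores.tsv"
    pd.DataFrame(result.scores, index=result.ids, columns=pcs).to_csv(
        outputs["pca_scores"], sep="\t", index_label="genome_id"
    )
    outputs["pca_variance"] = outdir / "pca_variance.tsv"
    pd.DataFrame(
        {"component": pcs, "variance_fraction": result.variance_fraction}
    ).to_csv(outputs["pca_variance"], sep="\t", index=False)
    t0 = _timed("pca", t0)

    if label_map:
        rows = []
        for name, tree in trees.items():
            leaf_labels = {g.id: g.label or "unlabeled" for g in genomes}
            mono = comparison.monophyly_check(tree, leaf_labels)
            for group in sorted(mono):
                rows.append({"tree": name, "group": group, "monophyletic": mono[group]})
        outputs["monophyly"] = outdir / "monophyly.tsv"
        pd.DataFrame(rows).to_csv(outputs["monophyly"], sep="\t", index=False)
        t0 = _timed("monophyly", t0)

    outputs["config"] = outdir / "config.json"
    config.to_json(outputs["config"])
    return outputs


def run_windows(
    fasta: str | Path,
    genome_id: str,
    outdir: str | Path,
    config: RunConfig | None = None,
    z: float = 3.0,
) -> dict[str, Path]:
    """Within-genome scan: window profile, heatmap + mask, outlier calls (BED)."""
    config = config or RunConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    t0 = time.perf_counter()

    genomes = read_fasta(fasta)
    by_id = {g.id: g for g in genomes}
    if genome_id not in by_id:
        raise ValidationError(
            f"genome {genome_id!r} not in FASTA; available: {sorted(by_id)}"
        )
    genome = by_id[genome_id]
    t0 = _timed("read", t0)

    profile = window_analysis.window_profile(
        genome, k=config.k, window_size=config.window_size, step=config.step
    )
    table = pd.DataFrame(
        np.vstack([v.deviation_array() for v in profile.vectors]),
        index=profile.starts,
        columns=list(profile.vectors[0].words),
    )
    outputs["profile"] = outdir / "profile.tsv"
    table.to_csv(outputs["profile"], sep="\t", index_label="start")
    t0 = _timed("profile", t0)

    heatmap = window_analysis.window_heatmap(profile)
    outputs["heatmap"] = outdir / "heatmap.tsv"
    pd.DataFrame(heatmap.distances, index=heatmap.starts, columns=heatmap.starts).to_csv(
        outputs["heatmap"], sep="\t", index_label="start"
    )
    outputs["mask"] = outdir / "mask.tsv"
    pd.DataFrame(
        heatmap.overlap_mask.astype(int), index=heatmap.starts, columns=heatmap.starts
    ).to_csv(outputs["mask"], sep="\t", index_label="start")
    t0 = _timed("heatmap", t0)

    calls = window_analysis.call_outlier_windows(heatmap, z=z)
    outputs["calls"] = outdir / "calls.bed"
    with open(outputs["calls"], "w") as fh:
        for idx, (start, end) in enumerate(calls):
            end = min(end, genome.length)
            fh.write(f"{genome.id}\t{start}\t{end}\tanomaly_{idx}\n")
    t0 = _timed("calls", t0)

    outputs["config"] = outdir / "config.json"
    config.to_json(outputs["config"])
    return outputs
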