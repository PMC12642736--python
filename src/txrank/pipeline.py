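"""End-to-end pipeline: counts in, ranked outliers and run artifacts out."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .config import RunConfig
from .errors import ValidationError
from .matrix import (
    DownsampleDecision,
    ExpressionMatrix,
    build_expression_matrix,
    compute_tpm,
    downsample_records,
    read_classification,
    read_long_counts,
    write_wide_tsv,
)
from .ranking import build_rank_matrices, rank_all
from .stats import compute_all_statistics

log = logging.getLogger(__name__)


@dataclass
class Artifacts:
    """In-memory results of a pipeline run (plus file paths when written)."""

    config: RunConfig
    matrix: ExpressionMatrix
    stats_long: pd.DataFrame
    z_long: pd.DataFrame
    ranked: pd.DataFrame
    rank_matrices: dict[tuple[str, str], pd.DataFrame] | None = None
    decisions: list[DownsampleDecision] = field(default_factory=list)
    manifest: dict | None = None
    paths: dict[str, Path] = field(default_factory=dict)


def analyze_records(
    records: pd.DataFrame,
    config: RunConfig | None = None,
    *,
    with_rank_matrices: bool = False,
) -> Artifacts:
    """Run matrix build -> TPM -> statistics -> z-scores -> ranking in memory."""
    cfg = config or RunConfig()
    matrix = compute_tpm(build_expression_matrix(records))
    stats_long = compute_all_statistics(
        matrix,
        bin1_proportion=cfg.bin1_proportion,
        min_phased_reads=cfg.min_phased_reads,
        min_phased_fraction=cfg.min_phased_fraction,
    )
    z_long, ranked = rank_all(stats_long, percentile=cfg.percentile)
    matrices = build_rank_matrices(ranked, stats_long) if with_rank_matrices else None
    log.info(
        "scored %d individuals, %d statistic rows, %d retained outliers",
        len(matrix.individuals), len(stats_long), len(ranked),
    )
    return Artifacts(
        config=cfg,
        matrix=matrix,
        stats_long=stats_long,
        z_long=z_long,
        ranked=ranked,
        rank_matrices=matrices,
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> Artifacts:
    """Execute the full pipeline from a counts TSV and write all outputs.

    Stages: read/validate -> optional depth downsampling -> expression matrix
    -> TPM -> test statistics -> z-scores -> percentile filter -> ranking ->
    rank matrices, with a JSON manifest recording the config, seed, and
    SHA-256 checksums of the input and every output.
    """
    if config.counts is None:
        raise ValidationError("config.counts is required for run_pipeline")
    records = read_long_counts(config.counts)

    classification = None
    if config.classification is not None:
        classification = read_classification(config.classification)

    decisions: list[DownsampleDecision] = []
    if config.downsample:
        records, decisions = downsample_records(
            records,
            config.seed,
            target=config.downsample_target,
            threshold=config.downsample_threshold,
        )

    art = analyze_records(records, config, with_rank_matrices=True)
    art.decisions = decisions

    ranked = art.ranked
    if classification is not None and len(ranked):
        cat = classification.set_index("isoform_id")["structural_category"]
        ranked = ranked.copy()
        ranked["structural_category"] = ranked["feature_id"].map(cat)
        art.ranked = ranked

    if config.output_dir is not None:
        _write_outputs(art)
    return art


def _write_outputs(art: Artifacts) -> None:
    out = Path(art.config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def save(name: str, path: Path) -> None:
        paths[name] = path

    p = out / "counts_matrix.tsv"
    write_wide_tsv(art.matrix.isoform_counts, p)
    save("counts_matrix", p)
    p = out / "gene_counts_matrix.tsv"
    write_wide_tsv(art.matrix.gene_counts, p)
    save("gene_counts_matrix", p)
    p = out / "tpm_matrix.tsv"
    write_wide_tsv(art.matrix.isoform_tpm, p)
    save("tpm_matrix", p)
    p = out / "gene_tpm_matrix.tsv"
    write_wide_tsv(art.matrix.gene_tpm, p)
    save("gene_tpm_matrix", p)
    p = out / "haplotype_counts.tsv"
    write_wide_tsv(art.matrix.isoform_hap, p)
    save("haplotype_counts", p)

    p = out / "statistics.tsv"
    art.stats_long.to_csv(p, sep="\t", index=False)
    save("statistics", p)
    p = out / "zscores.tsv"
    art.z_long.to_csv(p, sep="\t", index=False)
    save("zscores", p)
    p = out / "top_hits.tsv"
    art.ranked.sort_values(
        ["individual_id", "test", "level", "rank"], kind="mergesort"
    ).to_csv(p, sep="\t", index=False)
    save("top_hits", p)

    ranked_dir = out / "ranked"
    matrix_dir = out / "rank_matrix"
    ranked_dir.mkdir(exist_ok=True)
    matrix_dir.mkdir(exist_ok=True)
    for (test, level), mat in (art.rank_matrices or {}).items():
        stem = f"{test}_{level}"
        sub = art.ranked[(art.ranked["test"] == test) & (art.ranked["level"] == level)]
        p = ranked_dir / f"{stem}.tsv"
        sub.to_csv(p, sep="\t", index=False)
        save(f"ranked/{stem}", p)
        p = matrix_dir / f"{stem}.tsv"
        mat.to_csv(p, sep="\t", na_rep="")
        save(f"rank_matrix/{stem}", p)

    manifest = {
        "version": __version__,
        "seed": art.config.seed,
        "config": art.config.to_dict(),
        "input_checksums": {"counts": _sha256(Path(art.config.counts))},
        "downsample_decisions": [
            {
                "individual_id": d.individual_id,
                "condition": d.condition,
                "n_reads": d.n_reads,
                "p": d.p,
                "applied": d.applied,
                "seed": d.seed,
            }
            for d in art.decisions
        ],
        "output_checksums": {name: _sha256(p) for name, p in sorted(paths.items())},
    }
    manifest_path = out / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    paths["manifest"] = manifest_path
    art.manifest = manifest
    art.paths = paths


def summarize_individual(art: Artifacts, individual_id: str) -> pd.DataFrame:
    """Per-individual report of all retained features across tests.

    Each row carries the statistic, z-score, rank, and the supporting input
    quantities (TPM values, cohort context, haplotype counts, bin counts)
    joined back from the statistics table.  Unknown individuals are an error;
    an individual with no retained features yields an empty frame with the
    full header.
    """
    if individual_id not in art.matrix.individuals:
        raise ValidationError(f"unknown individual {individual_id!r}")
    hits = art.ranked[art.ranked["individual_id"] == individual_id]
    prov = art.stats_long.drop(columns=["statistic", "filtered"])
    merged = hits.merge(
        prov, on=["individual_id", "feature_id", "level", "test"], how="left"
    )
    return merged.sort_values(["test", "level", "rank"], kind="mergesort").reset_index(drop=True)
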