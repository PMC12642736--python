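"""Cohort expression-matrix construction from long-format isoform counts.

The input is one row per (isoform, gene, individual, condition, haplotype)
carrying a raw full-length-read count, as produced by a long-read isoform
collapse/quantification step joined with haplotype assignments.  This module
validates and aggregates those rows, optionally downsamples deep libraries,
and builds a dense cohort matrix of raw counts and TPM at both isoform and
gene level, keeping haplotype-resolved untreated counts for the
allelic-imbalance statistic.

TPM here is a pure count proportion scaled to one million: each full-length
non-chimeric read is one transcript observation, so no transcript-length
normalization applies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .config import DEFAULTS
from .errors import ConsistencyError, ValidationError

log = logging.getLogger(__name__)

CONDITIONS = ("cyclo", "noncyclo")
HAPLOTYPES = ("H1", "H2", "unphased")
RECORD_COLUMNS = ("isoform_id", "gene_id", "individual_id", "condition", "haplotype", "count")
KEY_COLUMNS = RECORD_COLUMNS[:-1]
HAP_FIELDS = ("h1", "h2", "total")

_SCALE = 1_000_000  # TPM denominator scale


def read_long_counts(path) -> pd.DataFrame:
    """Read and validate a long-format count TSV (``#`` lines are comments)."""
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except pd.errors.ParserError as exc:
        raise ValidationError(f"malformed TSV {path}: {exc}") from exc
    except pd.errors.EmptyDataError as exc:
        raise ValidationError(f"empty TSV {path}") from exc
    return validate_records(df)


def read_classification(path) -> pd.DataFrame:
    """Read an optional isoform classification TSV (isoform_id, gene_id, structural_category)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"isoform_id", "structural_category"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"classification TSV missing columns: {sorted(missing)}")
    return df.drop_duplicates("isoform_id")


def validate_records(records) -> pd.DataFrame:
    """Validate record rows and aggregate duplicate keys by summation.

    Checks column presence, condition/haplotype vocabularies, non-negative
    integral counts, and that each isoform maps to exactly one gene.
    """
    df = pd.DataFrame(records).copy()
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"missing required columns: {missing}")
    df = df.loc[:, list(RECORD_COLUMNS)]
    if df.empty:
        raise ValidationError("no count records supplied")

    count = pd.to_numeric(df["count"], errors="coerce")
    bad = count.isna() | (count < 0) | (count != np.floor(count))
    if bad.any():
        row = df.index[bad][0]
        raise ValidationError(
            f"invalid count at input row {row}: {df.loc[row, 'count']!r} "
            "(counts must be non-negative integers)"
        )
    df["count"] = count.astype(np.int64)

    for col, allowed in (("condition", CONDITIONS), ("haplotype", HAPLOTYPES)):
        bad = ~df[col].isin(allowed)
        if bad.any():
            row = df.index[bad][0]
            raise ValidationError(
                f"invalid {col} at input row {row}: {df.loc[row, col]!r} (allowed: {allowed})"
            )

    gene_per_iso = df.groupby("isoform_id")["gene_id"].nunique()
    multi = gene_per_iso.index[gene_per_iso > 1]
    if len(multi):
        raise ConsistencyError(f"isoform(s) mapped to more than one gene: {list(multi[:5])}")

    out = df.groupby(list(KEY_COLUMNS), as_index=False, sort=True)["count"].sum()
    return out


@dataclass
class ExpressionMatrix:
    """Dense cohort matrix of raw counts (and TPM, once computed).

    ``*_counts`` / ``*_tpm`` frames are indexed by feature with a
    (individual_id, condition) column MultiIndex.  ``*_hap`` frames hold
    untreated (noncyclo) haplotype-resolved counts with a
    (individual_id, field) column MultiIndex over fields ``h1``, ``h2`` and
    ``total`` (phased-H1, phased-H2, all untreated reads).
    """

    isoform_counts: pd.DataFrame
    gene_counts: pd.DataFrame
    isoform_hap: pd.DataFrame
    gene_hap: pd.DataFrame
    iso_to_gene: pd.Series
    isoform_tpm: pd.DataFrame | None = None
    gene_tpm: pd.DataFrame | None = None

    @property
    def individuals(self) -> list[str]:
        return list(self.isoform_counts.columns.get_level_values(0).unique())

    def counts(self, level: str) -> pd.DataFrame:
        return self.gene_counts if level == "gene" else self.isoform_counts

    def tpm(self, level: str) -> pd.DataFrame:
        out = self.gene_tpm if level == "gene" else self.isoform_tpm
        if out is None:
            raise ValidationError("TPM not computed yet; call compute_tpm first")
        return out

    def hap(self, level: str) -> pd.DataFrame:
        return self.gene_hap if level == "gene" else self.isoform_hap


def build_expression_matrix(records) -> ExpressionMatrix:
    """Build the dense cohort matrix from (possibly unaggregated) records.

    Absent (feature, individual, condition) cells are completed with zero so
    that leave-one-out statistics see every individual for every feature.
    """
    df = validate_records(records)
    individuals = sorted(df["individual_id"].unique())
    isoforms = sorted(df["isoform_id"].unique())
    iso_to_gene = (
        df.drop_duplicates("isoform_id").set_index("isoform_id")["gene_id"].reindex(isoforms)
    )
    iso_to_gene.name = "gene_id"

    cols = pd.MultiIndex.from_product(
        [individuals, list(CONDITIONS)], names=["individual_id", "condition"]
    )
    piv = df.pivot_table(
        index="isoform_id",
        columns=["individual_id", "condition"],
        values="count",
        aggfunc="sum",
        fill_value=0,
    )
    isoform_counts = piv.reindex(index=isoforms, columns=cols, fill_value=0).astype(np.int64)

    non = df[df["condition"] == "noncyclo"]
    hap_cols = pd.MultiIndex.from_product([individuals, list(HAPLOTYPES)])
    hp = non.pivot_table(
        index="isoform_id",
        columns=["individual_id", "haplotype"],
        values="count",
        aggfunc="sum",
        fill_value=0,
    )
    hp = hp.reindex(index=isoforms, columns=hap_cols, fill_value=0).astype(np.int64)
    h1 = hp.xs("H1", axis=1, level=1)
    h2 = hp.xs("H2", axis=1, level=1)
    total = h1 + h2 + hp.xs("unphased", axis=1, level=1)
    isoform_hap = pd.concat({"h1": h1, "h2": h2, "total": total}, axis=1)
    isoform_hap = isoform_hap.swaplevel(axis=1).sort_index(axis=1)
    isoform_hap.columns.names = ["individual_id", "field"]

    gene_counts = isoform_counts.groupby(iso_to_gene).sum()
    gene_hap = isoform_hap.groupby(iso_to_gene).sum()
    gene_counts.index.name = gene_hap.index.name = "gene_id"
    isoform_counts.index.name = isoform_hap.index.name = "isoform_id"

    log.info(
        "built expression matrix: %d isoforms, %d genes, %d individuals",
        len(isoforms), len(gene_counts), len(individuals),
    )
    return ExpressionMatrix(
        isoform_counts=isoform_counts,
        gene_counts=gene_counts,
        isoform_hap=isoform_hap,
        gene_hap=gene_hap,
        iso_to_gene=iso_to_gene,
    )


def compute_tpm(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Fill in isoform and gene TPM (count proportion x 1e6 per library).

    The denominator is the total isoform count of that (individual,
    condition) library, combining both haplotypes and unphased reads.  An
    all-zero library yields TPM 0 for all its features, with a warning.
    """
    totals = matrix.isoform_counts.sum(axis=0)
    zero = totals == 0
    if zero.any():
        log.warning("all-zero librar%s %s: TPM set to 0",
                    "y" if zero.sum() == 1 else "ies", list(totals.index[zero]))
    denom = totals.astype(float).replace(0, np.nan)
    tpm = matrix.isoform_counts.div(denom, axis=1).fillna(0.0) * _SCALE
    matrix.isoform_tpm = tpm
    matrix.gene_tpm = tpm.groupby(matrix.iso_to_gene).sum()
    matrix.gene_tpm.index.name = "gene_id"
    return matrix


@dataclass(frozen=True)
class DownsampleDecision:
    """Outcome of the depth-capping rule for one library.

    Libraries above ``threshold`` reads are thinned read-by-read with
    probability ``p = target / n_reads`` (rounded to six decimal places), so
    the retained count is binomial with mean ``n_reads * p``.  Libraries at
    or below the threshold are left untouched.
    """

    n_reads: int
    p: float
    applied: bool
    seed: int
    individual_id: str | None = None
    condition: str | None = None


def downsample_probability(
    n_reads: int,
    *,
    target: int = DEFAULTS.downsample_target,
    threshold: int = DEFAULTS.downsample_threshold,
    seed: int = 0,
) -> DownsampleDecision:
    """Decide whether and how strongly to thin a library of ``n_reads`` reads."""
    if n_reads != int(n_reads) or n_reads < 1:
        raise ValidationError(f"n_reads must be a positive integer, got {n_reads!r}")
    n_reads = int(n_reads)
    applied = n_reads > threshold
    p = round(target / n_reads, 6) if applied else 1.0
    return DownsampleDecision(n_reads=n_reads, p=p, applied=applied, seed=seed)


def downsample_records(
    records,
    seed: int,
    *,
    target: int = DEFAULTS.downsample_target,
    threshold: int = DEFAULTS.downsample_threshold,
) -> tuple[pd.DataFrame, list[DownsampleDecision]]:
    """Apply the depth-capping rule per (individual, condition) library.

    Each retained read is kept independently with the library's probability
    ``p`` (binomial thinning of the aggregated counts).  Per-library seeds are
    derived deterministically from ``seed``.
    """
    df = validate_records(records)
    libs = sorted(set(zip(df["individual_id"], df["condition"])))
    children = np.random.SeedSequence(seed).spawn(len(libs))
    decisions: list[DownsampleDecision] = []
    out = df.copy()
    for (ind, cond), child in zip(libs, children):
        mask = (df["individual_id"] == ind) & (df["condition"] == cond)
        n = int(df.loc[mask, "count"].sum())
        if n == 0:
            continue
        lib_seed = int(child.generate_state(1)[0] % (2**31))
        dec = downsample_probability(n, target=target, threshold=threshold, seed=lib_seed)
        dec = replace(dec, individual_id=ind, condition=cond)
        decisions.append(dec)
        if dec.applied:
            rng = np.random.default_rng(dec.seed)
            out.loc[mask, "count"] = rng.binomial(df.loc[mask, "count"].to_numpy(), dec.p)
            log.info("downsampled %s/%s: %d reads, p=%.6f", ind, cond, n, dec.p)
    out = out[out["count"] > 0].reset_index(drop=True)
    return out, decisions


def write_wide_tsv(df: pd.DataFrame, path) -> None:
    """Write a matrix with a tuple column index as TSV (levels joined by ':')."""
    out = df.copy()
    out.columns = [":".join(map(str, c)) if isinstance(c, tuple) else str(c) for c in df.columns]
    out.to_csv(path, sep="\t", index_label=df.index.name or "feature_id")


def read_wide_tsv(path) -> pd.DataFrame:
    """Inverse of :func:`write_wide_tsv`."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.columns = pd.MultiIndex.from_tuples(tuple(c.split(":")) for c in df.columns)
    return df
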