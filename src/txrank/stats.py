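"""Functional-effect test statistics at gene and isoform level.

Six statistics quantify distinct transcript alterations for one individual
against the rest of the cohort, all on a log2 scale:

* **NMD** — stabilization under cycloheximide (CHX), i.e. transcripts that
  are degraded by nonsense-mediated decay at steady state:
  ``log2((cyclo+1)/(noncyclo+1)) * log2(cyclo+2)``.
* **NMD rare steady-state** (gene level only) — isoforms of a gene that are
  rare untreated but appear under CHX, contrasted via bin counts.
* **noncyclo LOE / GOE** — loss / gain of untreated expression relative to
  the min / max over the other individuals, scaled by their median.
* **cyclo GOE** — gain of expression in the CHX-treated condition.
* **allelic imbalance** — absolute log-ratio of phased untreated haplotype
  counts, weighted by phased-read support, subject to minimum phased-read
  and phased-fraction filters.

Each statistic is zero when the index value equals its comparison value and
signed so that the pattern of interest is positive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .config import DEFAULTS
from .errors import ConsistencyError, ValidationError
from .matrix import ExpressionMatrix

GENE_TESTS = (
    "NMD",
    "NMD_rare_steady_state",
    "noncyclo_LOE",
    "noncyclo_GOE",
    "cyclo_GOE",
    "allelic_imbalance",
)
ISOFORM_TESTS = ("NMD", "noncyclo_LOE", "noncyclo_GOE", "cyclo_GOE", "allelic_imbalance")
LEVELS = ("gene", "isoform")


def nmd_statistic(cyclo_tpm, noncyclo_tpm):
    """CHX-stabilization score; positive when treated expression exceeds untreated."""
    c = np.asarray(cyclo_tpm, dtype=float)
    n = np.asarray(noncyclo_tpm, dtype=float)
    return np.log2((c + 1.0) / (n + 1.0)) * np.log2(c + 2.0)


def _outlier_ratio(num, den, med):
    return np.log2((np.asarray(num, float) + 1.0) / (np.asarray(den, float) + 1.0)) * np.log2(
        np.asarray(med, float) + 2.0
    )


def _check_context(others) -> np.ndarray:
    arr = np.asarray(others, dtype=float)
    if arr.size == 0:
        raise ValidationError("cohort context is empty; need at least 2 individuals")
    return arr


def noncyclo_loe_statistic(noncyclo_tpm: float, others_noncyclo_tpm: Sequence[float]) -> float:
    """Loss-of-expression in the untreated condition vs the cohort minimum."""
    others = _check_context(others_noncyclo_tpm)
    return float(_outlier_ratio(others.min(), noncyclo_tpm, np.median(others)))


def noncyclo_goe_statistic(noncyclo_tpm: float, others_noncyclo_tpm: Sequence[float]) -> float:
    """Gain-of-expression in the untreated condition vs the cohort maximum."""
    others = _check_context(others_noncyclo_tpm)
    return float(_outlier_ratio(noncyclo_tpm, others.max(), np.median(others)))


def cyclo_goe_statistic(cyclo_tpm: float, others_cyclo_tpm: Sequence[float]) -> float:
    """Gain-of-expression in the CHX-treated condition vs the cohort maximum."""
    others = _check_context(others_cyclo_tpm)
    return float(_outlier_ratio(cyclo_tpm, others.max(), np.median(others)))


@dataclass(frozen=True)
class GeneBinCounts:
    """Per-(gene, individual) read counts split by untreated rarity bins.

    Bin 1 holds isoforms whose untreated proportion of the gene's untreated
    total falls below the configured rarity threshold (all isoforms when the
    untreated total is zero); bin 2 holds the rest.  Membership is decided by
    the untreated sample only and shared across conditions.
    """

    cyclo_bin1_count: int
    noncyclo_bin1_count: int
    noncyclo_bin2_count: int
    cyclo_total: int
    noncyclo_total: int


def assign_bins(
    noncyclo_counts: Sequence[int],
    cyclo_counts: Sequence[int],
    *,
    bin1_proportion: float = DEFAULTS.bin1_proportion,
) -> GeneBinCounts:
    """Assign one gene's isoforms to rarity bins and sum reads per bin/condition."""
    n = np.asarray(noncyclo_counts, dtype=np.int64)
    c = np.asarray(cyclo_counts, dtype=np.int64)
    if n.shape != c.shape:
        raise ValidationError("noncyclo and cyclo count vectors must align")
    if (n < 0).any() or (c < 0).any():
        raise ValidationError("bin counts must be non-negative")
    total_n = int(n.sum())
    prop = n / total_n if total_n > 0 else np.zeros_like(n, dtype=float)
    bin1 = prop < bin1_proportion
    return GeneBinCounts(
        cyclo_bin1_count=int(c[bin1].sum()),
        noncyclo_bin1_count=int(n[bin1].sum()),
        noncyclo_bin2_count=int(n[~bin1].sum()),
        cyclo_total=int(c.sum()),
        noncyclo_total=total_n,
    )


def nmd_rare_steady_state_statistic(bins: GeneBinCounts) -> float:
    """Rare-steady-state score from a gene's bin counts.

    Positive when rare (bin-1) isoforms carry proportionally more reads under
    CHX than untreated, and the gene also expresses common (bin-2) isoforms.
    """
    diff = bins.cyclo_bin1_count / (bins.cyclo_total + 1.0) - bins.noncyclo_bin1_count / (
        bins.noncyclo_total + 1.0
    )
    return float(
        diff * np.log2(bins.cyclo_bin1_count + 1.0) * np.log2(bins.noncyclo_bin2_count + 1.0)
    )


def allelic_imbalance_statistic(
    h1_noncyclo: int,
    h2_noncyclo: int,
    total_noncyclo_reads: int,
    *,
    min_phased_reads: int = DEFAULTS.min_phased_reads,
    min_phased_fraction: float = DEFAULTS.min_phased_fraction,
) -> float | None:
    """Haplotype-imbalance score from untreated phased counts, or ``None`` if filtered.

    Features with too few phased reads, or too small a phased fraction of all
    untreated reads, are filtered out entirely (they never enter ranking).
    """
    h1, h2, total = int(h1_noncyclo), int(h2_noncyclo), int(total_noncyclo_reads)
    if min(h1, h2, total) < 0:
        raise ValidationError("haplotype counts must be non-negative")
    phased = h1 + h2
    if phased > total:
        raise ConsistencyError(f"phased reads ({phased}) exceed total untreated reads ({total})")
    if phased < min_phased_reads:
        return None
    if total > 0 and phased / total < min_phased_fraction:
        return None
    return float(abs(np.log2((h1 + 1.0) / (h2 + 1.0))) * np.log2(max(phased, 1)))


def _loo(arr: np.ndarray, fn) -> np.ndarray:
    """Column-wise leave-one-out reduction over a features x individuals array."""
    out = np.empty(arr.shape, dtype=float)
    for j in range(arr.shape[1]):
        out[:, j] = fn(np.delete(arr, j, axis=1), axis=1)
    return out


def _condition_array(frame: pd.DataFrame, individuals, condition: str) -> np.ndarray:
    sub = frame.xs(condition, axis=1, level="condition")
    return sub.reindex(columns=individuals).to_numpy(dtype=float)


def _long(feats, individuals, level, test, stat, filtered=None, **provenance) -> pd.DataFrame:
    base = pd.DataFrame(stat, index=feats, columns=individuals)
    s = base.stack(future_stack=True)
    df = s.rename("statistic").rename_axis(["feature_id", "individual_id"]).reset_index()
    df.insert(2, "level", level)
    df.insert(3, "test", test)
    if filtered is None:
        df["filtered"] = False
    else:
        df["filtered"] = (
            pd.DataFrame(filtered, index=feats, columns=individuals)
            .stack(future_stack=True)
            .to_numpy()
        )
    for name, mat in provenance.items():
        df[name] = (
            pd.DataFrame(np.asarray(mat, float), index=feats, columns=individuals)
            .stack(future_stack=True)
            .to_numpy()
        )
    return df


def _rare_steady_state_frame(
    matrix: ExpressionMatrix, individuals, bin1_proportion: float
) -> pd.DataFrame:
    iso_n = matrix.isoform_counts.xs("noncyclo", axis=1, level="condition").reindex(
        columns=individuals
    )
    iso_c = matrix.isoform_counts.xs("cyclo", axis=1, level="condition").reindex(
        columns=individuals
    )
    genes = matrix.iso_to_gene
    order = matrix.gene_counts.index

    gene_n = iso_n.groupby(genes).sum().reindex(order)
    gene_c = iso_c.groupby(genes).sum().reindex(order)

    tot = gene_n.reindex(genes.to_numpy()).to_numpy(dtype=float)
    n_arr = iso_n.to_numpy(dtype=float)
    prop = np.divide(n_arr, np.where(tot > 0, tot, 1.0), where=True)
    prop = np.where(tot > 0, prop, 0.0)
    bin1 = prop < bin1_proportion

    cb1 = (
        pd.DataFrame(iso_c.to_numpy() * bin1, index=iso_c.index, columns=individuals)
        .groupby(genes)
        .sum()
        .reindex(order)
    )
    nb1 = (
        pd.DataFrame(n_arr * bin1, index=iso_n.index, columns=individuals)
        .groupby(genes)
        .sum()
        .reindex(order)
    )
    nb2 = gene_n - nb1
    diff = cb1 / (gene_c + 1.0) - nb1 / (gene_n + 1.0)
    stat = diff * np.log2(cb1 + 1.0) * np.log2(nb2 + 1.0)
    return _long(
        order,
        individuals,
        "gene",
        "NMD_rare_steady_state",
        stat.to_numpy(),
        cyclo_bin1_count=cb1.to_numpy(),
        noncyclo_bin1_count=nb1.to_numpy(),
        noncyclo_bin2_count=nb2.to_numpy(),
        cyclo_total=gene_c.to_numpy(),
        noncyclo_total=gene_n.to_numpy(),
    )


def compute_all_statistics(
    matrix: ExpressionMatrix,
    *,
    bin1_proportion: float = DEFAULTS.bin1_proportion,
    min_phased_reads: int = DEFAULTS.min_phased_reads,
    min_phased_fraction: float = DEFAULTS.min_phased_fraction,
) -> pd.DataFrame:
    """Compute every test statistic for every (individual, feature).

    Returns a long-format frame with columns ``feature_id, individual_id,
    level, test, statistic, filtered`` plus the input quantities each
    statistic consumed (TPM values, cohort min/max/median, haplotype counts,
    bin counts) for auditability.  Filtered allelic-imbalance entries carry
    ``statistic = NaN`` and ``filtered = True``.
    """
    individuals = matrix.individuals
    if len(individuals) < 2:
        raise ValidationError("need at least 2 individuals for leave-one-out statistics")

    frames: list[pd.DataFrame] = []
    for level in LEVELS:
        tpm = matrix.tpm(level)
        hap = matrix.hap(level)
        feats = tpm.index
        C = _condition_array(tpm, individuals, "cyclo")
        N = _condition_array(tpm, individuals, "noncyclo")

        min_n, max_n, med_n = _loo(N, np.min), _loo(N, np.max), _loo(N, np.median)
        max_c, med_c = _loo(C, np.max), _loo(C, np.median)

        frames.append(
            _long(feats, individuals, level, "NMD", nmd_statistic(C, N),
                  cyclo_tpm=C, noncyclo_tpm=N)
        )
        frames.append(
            _long(feats, individuals, level, "noncyclo_LOE", _outlier_ratio(min_n, N, med_n),
                  noncyclo_tpm=N, others_min=min_n, others_median=med_n)
        )
        frames.append(
            _long(feats, individuals, level, "noncyclo_GOE", _outlier_ratio(N, max_n, med_n),
                  noncyclo_tpm=N, others_max=max_n, others_median=med_n)
        )
        frames.append(
            _long(feats, individuals, level, "cyclo_GOE", _outlier_ratio(C, max_c, med_c),
                  cyclo_tpm=C, others_max=max_c, others_median=med_c)
        )

        H1 = hap.xs("h1", axis=1, level="field").reindex(columns=individuals).to_numpy(float)
        H2 = hap.xs("h2", axis=1, level="field").reindex(columns=individuals).to_numpy(float)
        T = hap.xs("total", axis=1, level="field").reindex(columns=individuals).to_numpy(float)
        if (H1 + H2 > T).any():
            raise ConsistencyError("phased reads exceed total untreated reads for some feature")
        phased = H1 + H2
        mag = np.abs(np.log2((H1 + 1.0) / (H2 + 1.0))) * np.log2(np.maximum(phased, 1.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            frac_ok = phased >= min_phased_fraction * T
        keep = (phased >= min_phased_reads) & frac_ok
        ai = np.where(keep, mag, np.nan)
        frames.append(
            _long(feats, individuals, level, "allelic_imbalance", ai, filtered=~keep,
                  h1_noncyclo=H1, h2_noncyclo=H2, total_noncyclo_reads=T)
        )

    frames.append(_rare_steady_state_frame(matrix, individuals, bin1_proportion))

    out = pd.concat(frames, ignore_index=True, sort=False)
    return out
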