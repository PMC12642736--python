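"""Median-based z-scores, percentile filtering, and within-individual ranking.

For each (test, level), the cohort of statistic values of one feature is
converted to a per-individual z-score::

    z = (statistic[index] - median(statistic of the other individuals))
        / sd(statistic of all individuals)      # sample sd, n-1 denominator

with ``z = 0`` wherever that standard deviation is zero.  Within each
individual and test, features whose z-score lies strictly above the
configured percentile of that individual's z distribution are retained and
ranked by descending test statistic (ties broken by feature identifier).
Features filtered out upstream (allelic imbalance support filters) carry NaN
statistics and are excluded before the percentile is computed, so the
percentile is over the features actually evaluated.
"""

from __future__ import annotations

import warnings
from typing import Mapping

import numpy as np
import pandas as pd

from .config import DEFAULTS
from .errors import ValidationError


def median_z_score(values_by_individual: Mapping[str, float], index: str) -> float:
    """z-score of one individual's statistic against the cohort.

    The median excludes the index individual; the standard deviation is the
    sample standard deviation over all individuals.
    """
    if index not in values_by_individual:
        raise ValidationError(f"index individual {index!r} absent from values")
    others = [float(v) for k, v in values_by_individual.items() if k != index]
    if not others:
        raise ValidationError("need at least 2 individuals for a z-score")
    allv = np.asarray([float(v) for v in values_by_individual.values()])
    sd = float(np.std(allv, ddof=1))
    if sd == 0.0 or not np.isfinite(sd):
        return 0.0
    return float((float(values_by_individual[index]) - float(np.median(others))) / sd)


def z_score_matrix(stats: pd.DataFrame) -> pd.DataFrame:
    """Vectorized :func:`median_z_score` over a features x individuals frame.

    NaN statistics (filtered features) stay NaN and are ignored when forming
    the leave-one-out median and the cohort standard deviation.  Rows with
    fewer than two scored individuals yield NaN everywhere.
    """
    A = stats.to_numpy(dtype=float)
    n_feat, n_ind = A.shape
    valid = np.isfinite(A)
    nv = valid.sum(axis=1)

    M = np.where(valid, A, 0.0)
    mean = M.sum(axis=1) / np.maximum(nv, 1)
    ss = (np.where(valid, A - mean[:, None], 0.0) ** 2).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        sd = np.sqrt(ss / np.maximum(nv - 1, 1))
    sd[nv < 2] = np.nan

    z = np.full_like(A, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        for j in range(n_ind):
            med = np.nanmedian(np.delete(A, j, axis=1), axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                z[:, j] = (A[:, j] - med) / sd
    z = np.where((sd == 0.0)[:, None] & valid, 0.0, z)
    z[~valid] = np.nan
    return pd.DataFrame(z, index=stats.index, columns=stats.columns)


def percentile_filter(
    z_by_feature: pd.Series, *, percentile: float = DEFAULTS.percentile
) -> pd.Index:
    """Features whose z lies strictly above the given percentile of scored z's.

    The percentile uses linear interpolation on the empirical distribution,
    so e.g. 1,000 distinct z-scores retain exactly the top 5 at the default
    threshold.  NaN entries (unscored features) are excluded beforehand.
    """
    zz = z_by_feature.dropna()
    if zz.empty:
        return zz.index
    thr = float(np.quantile(zz.to_numpy(dtype=float), percentile / 100.0))
    return zz.index[zz.to_numpy(dtype=float) > thr]


def rank_within_individual(retained_statistics: pd.Series) -> pd.DataFrame:
    """Rank retained features 1..k by descending statistic (ties: feature id)."""
    df = retained_statistics.rename("statistic").rename_axis("feature_id").reset_index()
    df = df.sort_values(
        ["statistic", "feature_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def rank_all(
    stats_long: pd.DataFrame, *, percentile: float = DEFAULTS.percentile
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score, filter, and rank every (test, level, individual).

    Parameters
    ----------
    stats_long
        Long-format output of :func:`txrank.stats.compute_all_statistics`.

    Returns
    -------
    z_long
        Long frame of (feature, individual, level, test, statistic, z) for
        every scored feature (volcano-plot style export).
    ranked
        Long frame of retained outliers with columns ``individual_id,
        feature_id, level, test, statistic, z, rank``.
    """
    z_frames: list[pd.DataFrame] = []
    ranked_frames: list[pd.DataFrame] = []
    for (test, level), sub in stats_long.groupby(["test", "level"], sort=True):
        piv = sub.pivot(index="feature_id", columns="individual_id", values="statistic")
        z = z_score_matrix(piv)

        zl = pd.concat(
            {
                "statistic": piv.stack(future_stack=True),
                "z": z.stack(future_stack=True),
            },
            axis=1,
        ).reset_index()
        zl.insert(2, "level", level)
        zl.insert(3, "test", test)
        z_frames.append(zl)

        for ind in piv.columns:
            retained = percentile_filter(z[ind], percentile=percentile)
            if len(retained) == 0:
                continue
            ranked = rank_within_individual(piv.loc[retained, ind])
            ranked["z"] = ranked["feature_id"].map(z[ind]).astype(float)
            ranked.insert(0, "individual_id", ind)
            ranked.insert(2, "level", level)
            ranked.insert(3, "test", test)
            ranked_frames.append(ranked)

    z_long = pd.concat(z_frames, ignore_index=True)
    cols = ["individual_id", "feature_id", "level", "test", "statistic", "z", "rank"]
    if ranked_frames:
        ranked_long = pd.concat(ranked_frames, ignore_index=True).loc[:, cols]
    else:
        ranked_long = pd.DataFrame(columns=cols)
    return z_long, ranked_long


def build_rank_matrices(
    ranked_long: pd.DataFrame, stats_long: pd.DataFrame | None = None
) -> dict[tuple[str, str], pd.DataFrame]:
    """One features x individuals rank matrix per (test, level).

    Unranked cells are NaN.  When ``stats_long`` is given, matrices cover
    every evaluated feature and individual (and every test, even if no
    feature was retained for it); otherwise only ranked entries define the
    extent.
    """
    matrices: dict[tuple[str, str], pd.DataFrame] = {}
    if stats_long is not None:
        groups = stats_long.groupby(["test", "level"], sort=True)
    else:
        groups = ranked_long.groupby(["test", "level"], sort=True)
    for (test, level), sub in groups:
        feats = sorted(sub["feature_id"].unique())
        inds = sorted(sub["individual_id"].unique())
        mat = pd.DataFrame(np.nan, index=pd.Index(feats, name="feature_id"), columns=inds)
        hits = ranked_long[(ranked_long["test"] == test) & (ranked_long["level"] == level)]
        for _, row in hits.iterrows():
            mat.loc[row["feature_id"], row["individual_id"]] = row["rank"]
        matrices[(test, level)] = mat
    return matrices
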