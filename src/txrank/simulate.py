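"""Seeded synthetic cohorts with spiked transcript alterations.

The generator emulates the statistical structure the ranking method assumes:
a cohort of mutually-control individuals, paired NMD-inhibited (cyclo) and
untreated (noncyclo) libraries from the same biology, two haplotypes plus an
unphased remainder, and gamma-Poisson (negative-binomial) count noise around
gene- and isoform-specific expected proportions.  Known alterations
("spikes") are injected into chosen individuals and features so that
recovery by the matching test can be scored against ground truth.

Spike kinds and their effect parameter:

* ``nmd_isoform`` — untreated expectation of one isoform multiplied by
  ``1 - effect`` (degradation fraction), treated condition untouched.
* ``rare_steady_state_gene`` — a novel isoform of one gene, expressed at
  ``effect`` x the gene's treated expectation but only ``secondary`` x its
  untreated expectation (present mainly under NMD inhibition).
* ``loss_of_expression`` — one haplotype's expectation divided by ``effect``
  in both conditions (a cis-acting expression loss).
* ``gain_of_expression_noncyclo`` / ``gain_of_expression_cyclo`` — one
  haplotype's expectation multiplied by ``effect`` in the named condition.
* ``allelic_imbalance`` — phased output skewed to give haplotype 1 a share
  ``effect`` of the phased total, at constant total expression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .config import DEFAULTS
from .errors import ValidationError
from .matrix import KEY_COLUMNS
from .pipeline import analyze_records

SPIKE_TEST: dict[str, tuple[str, str]] = {
    "nmd_isoform": ("NMD", "isoform"),
    "rare_steady_state_gene": ("NMD_rare_steady_state", "gene"),
    "loss_of_expression": ("noncyclo_LOE", "gene"),
    "gain_of_expression_noncyclo": ("noncyclo_GOE", "isoform"),
    "gain_of_expression_cyclo": ("cyclo_GOE", "isoform"),
    "allelic_imbalance": ("allelic_imbalance", "gene"),
}

#: Default effect size per spike kind (degradation fraction, fold-change,
#: treated share, or haplotype-1 share -- see module docstring).
DEFAULT_EFFECTS: dict[str, float] = {
    "nmd_isoform": 0.9,
    "rare_steady_state_gene": 0.3,
    "loss_of_expression": 8.0,
    "gain_of_expression_noncyclo": 8.0,
    "gain_of_expression_cyclo": 8.0,
    "allelic_imbalance": 1.0,
}

#: Untreated share of a rare-steady-state novel isoform (kept far below the
#: rarity bin threshold so the isoform is genuinely rare at steady state).
RARE_NONCYCLO_SHARE = 0.003

#: The five alteration classes used for recovery benchmarking (one per known
#: positive-control pattern: NMD-sensitive isoform, rare NMD isoform of a
#: gene, expression loss, expression gain, monoallelic expression).
DEFAULT_SPIKE_KINDS = (
    "nmd_isoform",
    "rare_steady_state_gene",
    "loss_of_expression",
    "gain_of_expression_noncyclo",
    "allelic_imbalance",
)


@dataclass(frozen=True)
class SpikeSpec:
    """One known alteration injected into a synthetic cohort."""

    kind: str
    individual_id: str
    feature_id: str
    effect: float | None = None
    secondary: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in SPIKE_TEST:
            raise ValidationError(f"unknown spike kind {self.kind!r}")
        if self.effect is None:
            object.__setattr__(self, "effect", DEFAULT_EFFECTS[self.kind])
        e = float(self.effect)
        if self.kind == "nmd_isoform" and not 0.0 <= e < 1.0:
            raise ValidationError("nmd_isoform degradation fraction must be in [0, 1)")
        if self.kind in ("loss_of_expression", "gain_of_expression_noncyclo",
                         "gain_of_expression_cyclo") and e < 1.0:
            raise ValidationError("fold-change effects must be >= 1")
        if self.kind == "allelic_imbalance" and not 0.0 <= e <= 1.0:
            raise ValidationError("allelic-imbalance haplotype share must be in [0, 1]")
        if self.kind == "rare_steady_state_gene":
            if not 0.0 < e <= 1.0:
                raise ValidationError("rare-steady-state treated share must be in (0, 1]")
            if self.secondary is None:
                object.__setattr__(self, "secondary", RARE_NONCYCLO_SHARE)

    @property
    def test(self) -> str:
        return SPIKE_TEST[self.kind][0]

    @property
    def level(self) -> str:
        return SPIKE_TEST[self.kind][1]


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Parameters of a simulated cohort.

    Defaults give a cohort of 11 mutually-control individuals sequenced to 5
    million full-length reads per condition over a reduced transcriptome of
    300 genes, with low inter-individual biological variability (cultured
    fibroblast-like) and a small condition-level noise so the NMD statistic
    has a realistic null spread.
    """

    n_individuals: int = 11
    n_genes: int = 300
    mean_isoforms_per_gene: float = 3.0
    depth_per_condition: float = 5_000_000
    gene_log_sd: float = 1.5
    isoform_dirichlet: float = 2.0
    biological_cv: float = 0.10
    condition_cv: float = 0.05
    phased_fraction: float = 0.8
    spikes: tuple[SpikeSpec, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 2:
            raise ValidationError("need at least 2 individuals")
        if self.n_genes < 1:
            raise ValidationError("need at least 1 gene")
        if self.mean_isoforms_per_gene < 1:
            raise ValidationError("mean_isoforms_per_gene must be >= 1")
        if self.depth_per_condition <= 0:
            raise ValidationError("depth_per_condition must be positive")
        for name in ("gene_log_sd", "isoform_dirichlet"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        for name in ("biological_cv", "condition_cv"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        if not 0.0 <= self.phased_fraction <= 1.0:
            raise ValidationError("phased_fraction must be in [0, 1]")
        object.__setattr__(self, "spikes", tuple(self.spikes))
        seen = set()
        for sp in self.spikes:
            key = (sp.individual_id, sp.test)
            if key in seen:
                raise ValidationError(f"more than one spike for individual/test {key}")
            seen.add(key)


@dataclass(frozen=True)
class CohortPlan:
    """Deterministic cohort structure shared by generation and spike targeting."""

    individuals: tuple[str, ...]
    gene_ids: np.ndarray
    isoform_ids: np.ndarray
    isoform_gene: np.ndarray
    proportions: np.ndarray
    genes_by_weight: np.ndarray  # gene ids, descending expected expression


def _plan(spec: SyntheticCohortSpec) -> CohortPlan:
    struct_seed, _ = np.random.SeedSequence(spec.seed).spawn(2)
    rng = np.random.default_rng(struct_seed)
    k = 1 + rng.poisson(max(spec.mean_isoforms_per_gene - 1.0, 0.0), spec.n_genes)
    w = rng.lognormal(0.0, spec.gene_log_sd, spec.n_genes)
    g = rng.gamma(spec.isoform_dirichlet, 1.0, int(k.sum()))
    starts = np.concatenate([[0], np.cumsum(k)[:-1]])
    shares = g / np.repeat(np.add.reduceat(g, starts), k)

    gene_ids = np.array([f"G{i + 1:04d}" for i in range(spec.n_genes)])
    isoform_gene = np.repeat(gene_ids, k)
    iso_num = np.concatenate([np.arange(1, ki + 1) for ki in k])
    isoform_ids = np.array([f"{gi}.{j}" for gi, j in zip(isoform_gene, iso_num)])
    proportions = np.repeat(w / w.sum(), k) * shares
    individuals = tuple(f"IND{i + 1:02d}" for i in range(spec.n_individuals))
    genes_by_weight = gene_ids[np.argsort(-w, kind="stable")]
    return CohortPlan(
        individuals=individuals,
        gene_ids=gene_ids,
        isoform_ids=isoform_ids,
        isoform_gene=isoform_gene,
        proportions=proportions,
        genes_by_weight=genes_by_weight,
    )


def default_spikes(
    spec: SyntheticCohortSpec, kinds: Sequence[str] = DEFAULT_SPIKE_KINDS
) -> tuple[SpikeSpec, ...]:
    """Deterministic default spike set: one alteration class per individual.

    Targets are well-expressed genes (below the very top of the expression
    distribution), assigned round-robin to the first individuals; isoform-
    level spikes hit the target gene's dominant isoform.
    """
    plan = _plan(spec)
    n_kinds = len(kinds)
    if spec.n_genes >= 10 + 4 * n_kinds:
        positions = [10 + 4 * i for i in range(n_kinds)]
    else:
        positions = np.linspace(0, spec.n_genes - 1, n_kinds).astype(int).tolist()
    spikes = []
    for i, kind in enumerate(kinds):
        gene = plan.genes_by_weight[positions[i]]
        individual = plan.individuals[i % spec.n_individuals]
        if SPIKE_TEST[kind][1] == "isoform" or kind == "nmd_isoform":
            mask = plan.isoform_gene == gene
            feature = plan.isoform_ids[mask][np.argmax(plan.proportions[mask])]
        else:
            feature = gene
        spikes.append(SpikeSpec(kind=kind, individual_id=individual, feature_id=str(feature)))
    return tuple(spikes)


def with_default_spikes(
    spec: SyntheticCohortSpec, kinds: Sequence[str] = DEFAULT_SPIKE_KINDS
) -> SyntheticCohortSpec:
    return replace(spec, spikes=default_spikes(spec, kinds))


def _spike_rows(spec_feature: str, plan: CohortPlan, iso_index: dict[str, int]) -> np.ndarray:
    """Row indices targeted by a spike feature (a gene id or an isoform id)."""
    if spec_feature in iso_index:
        return np.array([iso_index[spec_feature]])
    rows = np.nonzero(plan.isoform_gene == spec_feature)[0]
    if rows.size == 0:
        raise ValidationError(f"spike feature {spec_feature!r} not in cohort plan")
    return rows


def generate_cohort(spec: SyntheticCohortSpec) -> pd.DataFrame:
    """Draw one seeded cohort as a long-format record table.

    Counts are gamma-Poisson around per-isoform expectations: a lognormal
    biological factor shared between the two conditions of an individual (so
    the treated/untreated contrast is null for unspiked features), a small
    lognormal condition factor, and Poisson sampling at the library depth.
    Reads are split H1 / H2 / unphased by the phased fraction.  Identical
    specs (including the seed) produce byte-identical tables.
    """
    plan = _plan(spec)
    _, noise_seed = np.random.SeedSequence(spec.seed).spawn(2)
    rng = np.random.default_rng(noise_seed)

    n_iso = len(plan.isoform_ids)
    n_ind = spec.n_individuals
    sb = math.sqrt(math.log1p(spec.biological_cv**2))
    sc = math.sqrt(math.log1p(spec.condition_cv**2))
    bio = rng.lognormal(-sb**2 / 2.0, sb, (n_iso, n_ind))
    cond = rng.lognormal(-sc**2 / 2.0, sc, (n_iso, n_ind, 2))  # 0=cyclo, 1=noncyclo
    lam = spec.depth_per_condition * plan.proportions[:, None, None] * bio[:, :, None] * cond

    ind_index = {ind: j for j, ind in enumerate(plan.individuals)}
    iso_index = {iso: i for i, iso in enumerate(plan.isoform_ids)}
    for sp in spec.spikes:
        if sp.individual_id not in ind_index:
            raise ValidationError(f"spike individual {sp.individual_id!r} not in cohort")

    # Rare-steady-state spikes append a novel isoform before haplotype split.
    isoform_ids = plan.isoform_ids
    isoform_gene = plan.isoform_gene
    for sp in spec.spikes:
        if sp.kind != "rare_steady_state_gene":
            continue
        rows = np.nonzero(isoform_gene == sp.feature_id)[0]
        if rows.size == 0:
            raise ValidationError(f"spike gene {sp.feature_id!r} not in cohort plan")
        j = ind_index[sp.individual_id]
        new = np.zeros((1, n_ind, 2))
        new[0, j, 0] = float(sp.effect) * lam[rows, j, 0].sum()
        new[0, j, 1] = float(sp.secondary) * lam[rows, j, 1].sum()
        lam = np.concatenate([lam, new], axis=0)
        isoform_ids = np.append(isoform_ids, f"{sp.feature_id}.novel")
        isoform_gene = np.append(isoform_gene, sp.feature_id)
        iso_index[f"{sp.feature_id}.novel"] = len(isoform_ids) - 1

    pf = spec.phased_fraction
    hap_w = np.array([pf / 2.0, pf / 2.0, 1.0 - pf])  # H1, H2, unphased
    hlam = lam[..., None] * hap_w  # (iso, ind, condition, haplotype)

    for sp in spec.spikes:
        j = ind_index[sp.individual_id]
        e = float(sp.effect)
        if sp.kind == "rare_steady_state_gene":
            continue
        rows = _spike_rows(sp.feature_id, plan, iso_index)
        if sp.kind == "nmd_isoform":
            hlam[rows, j, 1, :] *= 1.0 - e
        elif sp.kind == "loss_of_expression":
            s = 1.0 / e
            hlam[rows, j, :, 0] *= s
            hlam[rows, j, :, 2] *= (1.0 + s) / 2.0
        elif sp.kind == "gain_of_expression_noncyclo":
            hlam[rows, j, 1, 0] *= e
            hlam[rows, j, 1, 2] *= (1.0 + e) / 2.0
        elif sp.kind == "gain_of_expression_cyclo":
            hlam[rows, j, 0, 0] *= e
            hlam[rows, j, 0, 2] *= (1.0 + e) / 2.0
        elif sp.kind == "allelic_imbalance":
            phased_total = hlam[rows, j, :, 0] + hlam[rows, j, :, 1]
            hlam[rows, j, :, 0] = e * phased_total
            hlam[rows, j, :, 1] = (1.0 - e) * phased_total

    counts = rng.poisson(hlam)

    i0, i1, i2, i3 = np.nonzero(counts)
    conds = np.array(["cyclo", "noncyclo"])
    haps = np.array(["H1", "H2", "unphased"])
    df = pd.DataFrame(
        {
            "isoform_id": isoform_ids[i0],
            "gene_id": isoform_gene[i0],
            "individual_id": np.array(plan.individuals)[i1],
            "condition": conds[i2],
            "haplotype": haps[i3],
            "count": counts[i0, i1, i2, i3],
        }
    )
    df = df.sort_values(list(KEY_COLUMNS), kind="mergesort").reset_index(drop=True)
    return df


def write_cohort(records: pd.DataFrame, path, spec: SyntheticCohortSpec) -> None:
    """Write a cohort TSV with a metadata comment header (seed included)."""
    with open(path, "w") as fh:
        fh.write(
            f"# seed={spec.seed} n_individuals={spec.n_individuals} "
            f"n_genes={spec.n_genes} depth_per_condition={spec.depth_per_condition} "
            f"phased_fraction={spec.phased_fraction} n_spikes={len(spec.spikes)}\n"
        )
        records.to_csv(fh, sep="\t", index=False)


def write_truth(spikes: Iterable[SpikeSpec], path, seed: int | None = None) -> None:
    """Write the spike ground truth as a TSV (for scoring recovery)."""
    rows = [
        {
            "kind": sp.kind,
            "individual_id": sp.individual_id,
            "feature_id": sp.feature_id,
            "effect": sp.effect,
            "secondary": sp.secondary,
            "test": sp.test,
            "level": sp.level,
        }
        for sp in spikes
    ]
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        pd.DataFrame(rows, columns=[
            "kind", "individual_id", "feature_id", "effect", "secondary", "test", "level",
        ]).to_csv(fh, sep="\t", index=False)


def score_recovery(ranked: pd.DataFrame, spikes: Sequence[SpikeSpec]) -> pd.DataFrame:
    """Where each spike landed in the matching test's ranking.

    Returns one row per spike with ``retained`` (passed the percentile
    filter) and ``rank`` (NaN when not retained).
    """
    rows = []
    for sp in spikes:
        feature = sp.feature_id
        hit = ranked[
            (ranked["individual_id"] == sp.individual_id)
            & (ranked["test"] == sp.test)
            & (ranked["level"] == sp.level)
            & (ranked["feature_id"] == feature)
        ]
        rank = float(hit["rank"].iloc[0]) if len(hit) else float("nan")
        rows.append(
            {
                "kind": sp.kind,
                "individual_id": sp.individual_id,
                "feature_id": feature,
                "test": sp.test,
                "level": sp.level,
                "retained": bool(len(hit)),
                "rank": rank,
            }
        )
    return pd.DataFrame(rows)


def _child_seeds(seed: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(seed).spawn(n)]


def spike_recovery(
    base_spec: SyntheticCohortSpec,
    replicates: int,
    kinds: Sequence[str] = DEFAULT_SPIKE_KINDS,
    *,
    percentile: float = DEFAULTS.percentile,
) -> pd.DataFrame:
    """Per-replicate spike recovery over seeded cohorts built from ``base_spec``."""
    out = []
    for rep, seed in enumerate(_child_seeds(base_spec.seed, replicates)):
        spec = with_default_spikes(replace(base_spec, seed=seed, spikes=()), kinds)
        art = analyze_records(generate_cohort(spec))
        rec = score_recovery(art.ranked, spec.spikes)
        rec.insert(0, "replicate", rep)
        out.append(rec)
    return pd.concat(out, ignore_index=True)


def titrate_design(
    base_spec: SyntheticCohortSpec,
    depths: Sequence[float],
    cohort_sizes: Sequence[int],
    replicates: int,
    kinds: Sequence[str] = DEFAULT_SPIKE_KINDS,
) -> pd.DataFrame:
    """Spike recovery across a read-depth x cohort-size grid.

    For each grid cell, ``replicates`` seeded cohorts are generated with the
    default spikes and the fraction of replicates in which each spike is
    retained, and ranked first, is recorded together with its median rank.
    """
    cells = [(n, d) for n in cohort_sizes for d in depths]
    seeds = _child_seeds(base_spec.seed, len(cells) * replicates)
    rows = []
    k = 0
    for n, depth in cells:
        for _ in range(replicates):
            spec = replace(
                base_spec, n_individuals=n, depth_per_condition=depth, seed=seeds[k], spikes=()
            )
            k += 1
            spec = with_default_spikes(spec, kinds)
            art = analyze_records(generate_cohort(spec))
            rec = score_recovery(art.ranked, spec.spikes)
            rec["n_individuals"] = n
            rec["depth"] = depth
            rows.append(rec)
    raw = pd.concat(rows, ignore_index=True)
    summary = (
        raw.groupby(["n_individuals", "depth", "kind"])
        .agg(
            retained_fraction=("retained", "mean"),
            rank1_fraction=("rank", lambda r: float(np.mean(r == 1.0))),
            median_rank=("rank", "median"),
        )
        .reset_index()
    )
    summary["replicates"] = replicates
    return summary


def null_top_rank_owners(
    base_spec: SyntheticCohortSpec, n_cohorts: int, *, level: str = "gene"
) -> pd.Series:
    """How often each individual owns the top z-score in spike-free cohorts.

    For each seeded null cohort and each test at the given level, the
    individual holding the maximum z-score is recorded.  Under the null every
    individual is exchangeable, so ownership should be uniform.
    """
    counts = {ind: 0 for ind in _plan(base_spec).individuals}
    for seed in _child_seeds(base_spec.seed, n_cohorts):
        spec = replace(base_spec, seed=seed, spikes=())
        art = analyze_records(generate_cohort(spec))
        zl = art.z_long[art.z_long["level"] == level].dropna(subset=["z"])
        for _, sub in zl.groupby("test"):
            owner = sub.loc[sub["z"].idxmax(), "individual_id"]
            counts[owner] += 1
    return pd.Series(counts, name="top_rank_count")
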