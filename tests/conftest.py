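import pandas as pd
import pytest

from txrank.matrix import build_expression_matrix, compute_tpm
from txrank.pipeline import analyze_records
from txrank.simulate import SyntheticCohortSpec, generate_cohort, with_default_spikes


def rec(isoform, gene, individual, condition, haplotype, count):
    return {
        "isoform_id": isoform,
        "gene_id": gene,
        "individual_id": individual,
        "condition": condition,
        "haplotype": haplotype,
        "count": count,
    }


@pytest.fixture
def toy_records() -> pd.DataFrame:
    """Two individuals, two genes, hand-checkable counts."""
    rows = [
        rec("i1", "g1", "A", "cyclo", "H1", 3),
        rec("i1", "g1", "A", "cyclo", "H1", 4),  # duplicate key, sums to 7
        rec("i1", "g1", "A", "noncyclo", "H1", 5),
        rec("i1", "g1", "A", "noncyclo", "H2", 2),
        rec("i1", "g1", "A", "noncyclo", "unphased", 3),
        rec("i2", "g1", "A", "cyclo", "unphased", 5),
        rec("i2", "g1", "A", "noncyclo", "unphased", 31),
        rec("i3", "g2", "A", "noncyclo", "H1", 12),
        rec("i1", "g1", "B", "cyclo", "H2", 10),
        rec("i1", "g1", "B", "noncyclo", "H1", 8),
        rec("i3", "g2", "B", "noncyclo", "H2", 2),
    ]
    return pd.DataFrame(rows)


@pytest.fixture
def toy_matrix(toy_records):
    return compute_tpm(build_expression_matrix(toy_records))


@pytest.fixture(scope="session")
def small_spec() -> SyntheticCohortSpec:
    """Small, fast cohort for simulation tests."""
    return SyntheticCohortSpec(n_individuals=6, n_genes=60, depth_per_condition=200_000, seed=11)


@pytest.fixture(scope="session")
def spiked_cohort():
    """One default-spiked cohort at study-like conditions, analyzed once."""
    spec = with_default_spikes(SyntheticCohortSpec(seed=5))
    records = generate_cohort(spec)
    art = analyze_records(records)
    return spec, records, art
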