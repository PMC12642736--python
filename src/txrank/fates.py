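"""Haplotype-resolved transcript-fate bookkeeping.

Paired untreated / NMD-inhibited long-read data lets one partition the
transcripts produced from each haplotype of a gene into fates (e.g. primary
polyadenylation, alternative polyadenylation, readthrough into a downstream
gene, exon skipping) and mark each fate as stable at steady state or as
degraded by NMD.  This module turns such per-haplotype fate fractions into
the residual fraction of stable, translatable transcript — the quantity that
matters for dosage-sensitive loss-of-function mechanisms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from .errors import ValidationError

_FRACTION_TOL = 1e-6


@dataclass(frozen=True)
class TranscriptFate:
    """One transcript fate on a haplotype: its fraction of that haplotype's
    output and whether the resulting transcript is stable at steady state."""

    label: str
    fraction: float
    stable: bool

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ValidationError(f"fate fraction must be in [0, 1], got {self.fraction}")


def haplotype_stable_fraction(fates: Sequence[TranscriptFate]) -> float:
    """Fraction of one haplotype's transcript output that is stable.

    The fate fractions must partition the haplotype's output (sum to 1).
    """
    if not fates:
        raise ValidationError("haplotype has no fates")
    total = sum(f.fraction for f in fates)
    if not math.isclose(total, 1.0, rel_tol=0, abs_tol=_FRACTION_TOL):
        raise ValidationError(f"fate fractions must sum to 1, got {total}")
    return sum(f.fraction for f in fates if f.stable)


def fate_summary(
    haplotype_fates: Mapping[str, Sequence[TranscriptFate]],
    weights: Mapping[str, float] | None = None,
) -> dict:
    """Summarize stable transcript output across haplotypes, in percent.

    ``weights`` gives each haplotype's share of total transcript output;
    by default haplotypes contribute equally.

    Returns a dict with ``haplotype_stable_pct`` (per haplotype),
    ``stable_pct`` and ``unstable_pct`` (gene-level, weighted).
    """
    if not haplotype_fates:
        raise ValidationError("no haplotypes supplied")
    if weights is None:
        weights = {h: 1.0 for h in haplotype_fates}
    missing = set(haplotype_fates) - set(weights)
    if missing:
        raise ValidationError(f"missing weights for haplotypes: {sorted(missing)}")
    wsum = sum(float(weights[h]) for h in haplotype_fates)
    if wsum <= 0:
        raise ValidationError("haplotype weights must sum to a positive value")

    per_hap = {h: 100.0 * haplotype_stable_fraction(f) for h, f in haplotype_fates.items()}
    stable = sum(per_hap[h] * float(weights[h]) for h in haplotype_fates) / wsum
    return {
        "haplotype_stable_pct": per_hap,
        "stable_pct": stable,
        "unstable_pct": 100.0 - stable,
    }
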