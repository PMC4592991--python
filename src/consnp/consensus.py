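"""Group-consensus SNP calling.

A SNP is a consensus SNP for a group when it is carried by (almost) every
sample of that group and by (at most ``absence_max``) samples of the other
group. Defaults: presence in at least group-size − 1 samples, absence strict.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence

from .core import GROUPS, Genotype, SampleManifest, VariantRecord

CARRIER_RULES = ("any-alt-allele", "homozygous-alt-only")
_CARRYING = {
    "any-alt-allele": {Genotype.HET, Genotype.HOM_ALT},
    "homozygous-alt-only": {Genotype.HOM_ALT},
}


@dataclass(frozen=True)
class ConsensusCall:
    """A variant concordant with one genotype group."""

    variant: VariantRecord
    group: str
    carriers_in_group: int
    group_size: int
    carriers_in_other: int

    @property
    def support(self) -> str:
        return f"{self.carriers_in_group}/{self.group_size}"


def count_carriers(
    variant: VariantRecord,
    samples: Sequence[str],
    carrier_rule: str = "any-alt-allele",
) -> int:
    """Number of samples carrying the alt allele under the given rule.

    Missing genotypes never count as carrying.
    """
    carrying = _CARRYING[carrier_rule]
    gmap = variant.genotype_map
    return sum(1 for s in samples if gmap.get(s, Genotype.MISSING) in carrying)


def count_missing(variant: VariantRecord, samples: Sequence[str]) -> int:
    gmap = variant.genotype_map
    return sum(1 for s in samples if gmap.get(s, Genotype.MISSING) is Genotype.MISSING)


def call_consensus(
    variants: Iterable[VariantRecord],
    manifest: SampleManifest,
    presence_min: Optional[int] = None,
    absence_max: int = 0,
    carrier_rule: str = "any-alt-allele",
    strict_missing: bool = False,
) -> List[ConsensusCall]:
    """Identify variants concordant with exactly one group.

    Parameters
    ----------
    presence_min
        Minimum carriers in the concordant group. Default: group size − 1
        (the "almost every sample" rule).
    absence_max
        Maximum carriers tolerated in the other group (default 0).
    carrier_rule
        ``any-alt-allele`` (het counts as carrying) or ``homozygous-alt-only``.
    strict_missing
        When True, any missing genotype in the candidate group fails the
        presence test for that group. Default: missing genotypes are simply
        not carriers and do not violate absence.
    """
    if carrier_rule not in CARRIER_RULES:
        raise ValueError(f"carrier_rule must be one of {CARRIER_RULES}")
    sizes = manifest.group_sizes()
    thresholds: Dict[str, int] = {}
    for g in GROUPS:
        t = sizes[g] - 1 if presence_min is None else presence_min
        if t > sizes[g]:
            raise ValueError(
                f"presence_min {t} exceeds size of group {g} ({sizes[g]})"
            )
        if t <= absence_max:
            raise ValueError(
                f"presence_min ({t}) must exceed absence_max ({absence_max}); "
                "the rule would not discriminate the groups"
            )
        thresholds[g] = t

    members = {g: manifest.samples_in(g) for g in GROUPS}
    calls: List[ConsensusCall] = []
    for variant in variants:
        carriers = {
            g: count_carriers(variant, members[g], carrier_rule) for g in GROUPS
        }
        for g in GROUPS:
            other = manifest.other(g)
            present = carriers[g] >= thresholds[g]
            if strict_missing and count_missing(variant, members[g]) > 0:
                present = False
            absent = carriers[other] <= absence_max
            if present and absent:
                calls.append(
                    ConsensusCall(
                        variant=variant,
                        group=g,
                        carriers_in_group=carriers[g],
                        group_size=sizes[g],
                        carriers_in_other=carriers[other],
                    )
                )
                break  # cannot satisfy both directions when absence_max < presence_min
    return calls


def summarize_concordance(calls: Iterable[ConsensusCall]) -> Dict[str, int]:
    """Per-group call totals: ``{QQ: n, qq: m, total: n + m}``."""
    counts = {g: 0 for g in GROUPS}
    for call in calls:
        counts[call.group] += 1
    counts["total"] = sum(counts[g] for g in GROUPS)
    return counts
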