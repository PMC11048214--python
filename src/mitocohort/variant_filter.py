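"""Retention rules and ploidy classification for mtDNA variant calls.

A call is retained when it is covered by at least ``min_depth`` reads,
has an aggregate mapping quality of at least ``min_quality``, does not
fall in a homopolymeric tract, is supported by reads on both strands,
and has a heteroplasmic fraction (HF) of at least ``min_hf``.  Retained
calls with HF >= 0.95 are homoplasmic; anything below is heteroplasmic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .mito_map import RegionAtlas

logger = logging.getLogger(__name__)

#: Fixed evaluation order of the retention rules.
RULE_ORDER = ("low_depth", "low_quality", "homopolymer", "single_strand", "low_hf")


@dataclass(frozen=True)
class FilterThresholds:
    """Rule parameters, defaulting to the published retention rules."""

    min_depth: int = 5
    min_quality: float = 25.0
    min_hf: float = 0.01
    hf_hom_threshold: float = 0.95
    min_strand_reads: int = 1


DEFAULT_THRESHOLDS = FilterThresholds()


@dataclass(frozen=True)
class MtVariantCall:
    """One mtDNA variant observation in one sample."""

    sample_id: str
    position: int
    ref: str
    alt: str
    hf: float
    depth: int
    alt_fwd: int
    alt_rev: int
    quality: float = 40.0
    hf_ci: tuple[float, float] = (0.0, 1.0)
    variant_class: str = "SNP"  # "SNP" | "indel"
    impact: Optional[str] = None
    maf: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.hf <= 1.0):
            raise ValueError(f"hf {self.hf} outside [0, 1]")
        lo, hi = self.hf_ci
        if not (lo <= self.hf <= hi):
            raise ValueError(f"hf {self.hf} outside its CI [{lo}, {hi}]")
        if self.alt_fwd + self.alt_rev > self.depth:
            raise ValueError(
                f"strand support {self.alt_fwd}+{self.alt_rev} exceeds depth {self.depth}"
            )

    @property
    def site_key(self) -> tuple[int, str, str]:
        return (self.position, self.ref, self.alt)


@dataclass(frozen=True)
class FilterVerdict:
    retained: bool
    reasons: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        assert self.retained == (len(self.reasons) == 0)


def filter_call(
    call: MtVariantCall,
    atlas: RegionAtlas,
    thresholds: FilterThresholds = DEFAULT_THRESHOLDS,
) -> FilterVerdict:
    """Apply all retention rules; every failing rule is reported."""
    reasons: list[str] = []
    if call.depth < thresholds.min_depth:
        reasons.append("low_depth")
    if call.quality < thresholds.min_quality:
        reasons.append("low_quality")
    if atlas.is_homopolymer(call.position):
        reasons.append("homopolymer")
    if (
        call.alt_fwd < thresholds.min_strand_reads
        or call.alt_rev < thresholds.min_strand_reads
    ):
        reasons.append("single_strand")
    if call.hf < thresholds.min_hf:
        reasons.append("low_hf")
    return FilterVerdict(retained=not reasons, reasons=tuple(reasons))


def filter_cohort(
    calls: Iterable[MtVariantCall],
    atlas: RegionAtlas,
    thresholds: FilterThresholds = DEFAULT_THRESHOLDS,
) -> tuple[list[MtVariantCall], list[tuple[MtVariantCall, FilterVerdict]]]:
    """Split calls into (retained, audited-verdicts-for-all)."""
    retained: list[MtVariantCall] = []
    audit: list[tuple[MtVariantCall, FilterVerdict]] = []
    for call in calls:
        verdict = filter_call(call, atlas, thresholds)
        audit.append((call, verdict))
        if verdict.retained:
            retained.append(call)
    return retained, audit


def classify_ploidy(hf: float, hom_threshold: float = 0.95) -> str:
    """"homoplasmic" iff hf >= hom_threshold (closed bound), else "heteroplasmic"."""
    if not (0.0 <= hf <= 1.0):
        raise ValueError(f"hf {hf} outside [0, 1]")
    return "homoplasmic" if hf >= hom_threshold else "heteroplasmic"


def dedupe_and_normalize(calls: Sequence[MtVariantCall]) -> list[MtVariantCall]:
    """One record per (sample, position, ref, alt), sorted by sample then position.

    On conflicting HF for an identical key the max-HF record is kept and a
    warning logged; otherwise the first-seen record wins.
    """
    best: dict[tuple[str, int, str, str], MtVariantCall] = {}
    for call in calls:
        key = (call.sample_id, call.position, call.ref, call.alt)
        prev = best.get(key)
        if prev is None:
            best[key] = call
        elif call.hf != prev.hf:
            logger.warning(
                "conflicting HF for %s at %d %s>%s: %.4f vs %.4f; keeping max",
                call.sample_id, call.position, call.ref, call.alt, prev.hf, call.hf,
            )
            if call.hf > prev.hf:
                best[key] = call
    return sorted(best.values(), key=lambda c: (c.sample_id, c.position, c.ref, c.alt))


def count_sites_and_observations(
    calls: Sequence[MtVariantCall],
) -> tuple[int, int]:
    """(n_observations, n_distinct_sites) over deduplicated calls."""
    n_obs = len(calls)
    n_sites = len({c.site_key for c in calls})
    return n_obs, n_sites
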