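"""Rare-variant prioritisation cascades and per-gene burden summaries.

Nuclear cascade (in order): drop LOW-impact observations; drop any site
observed in at least one control sample; keep MAF < ``maf_max`` or MAF
absent; keep CADD >= ``cadd_min``; keep caller PASS.  The mitochondrial
cascade applies the first three stages only.  Control-shared sites are
resolved against the full input call set, so the stage predicates
commute and the final retained set is order-independent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

IMPACT_CLASSES = ("HIGH", "MODERATE", "LOW", "MODIFIER")
WINDOW_PAD = 10_000


@dataclass(frozen=True)
class NuclearVariantCall:
    """One annotated nuclear-DNA variant observation in one sample."""

    sample_id: str
    chrom: str
    position: int
    ref: str
    alt: str
    impact: str
    maf: Optional[float] = None
    cadd: Optional[float] = None
    caller_filter: str = "PASS"
    predictor_labels: tuple[tuple[str, str], ...] = ()
    genes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.impact not in IMPACT_CLASSES:
            raise ValueError(f"unknown impact class {self.impact!r}")

    @property
    def site_key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.position, self.ref, self.alt)


@dataclass(frozen=True)
class GeneWindow:
    """A gene interval padded by ``window_pad`` on both sides (floored at 1)."""

    gene: str
    chrom: str
    start: int
    end: int
    window_pad: int = WINDOW_PAD

    @property
    def padded(self) -> tuple[int, int]:
        return (max(1, self.start - self.window_pad), self.end + self.window_pad)

    def contains(self, chrom: str, position: int) -> bool:
        lo, hi = self.padded
        return chrom == self.chrom and lo <= position <= hi


@dataclass
class PrioritizationReport:
    retained: list
    n_observations: int
    n_distinct_sites: int
    attrition: list[tuple[str, int]]  # (stage name, observations remaining)

    def __post_init__(self) -> None:
        counts = [n for _, n in self.attrition]
        assert counts == sorted(counts, reverse=True), "attrition must be non-increasing"


def _check_chrom_names(variant_chroms: set[str], window_chroms: set[str]) -> None:
    """Raise when variants and windows use different chromosome dialects."""

    def norm(name: str) -> str:
        return name.removeprefix("chr")

    missing = {
        c for c in variant_chroms
        if c not in window_chroms and norm(c) in {norm(w) for w in window_chroms}
    }
    if missing:
        raise ValueError(
            "chromosome naming mismatch between variants and gene windows: "
            f"{sorted(missing)} vs e.g. {sorted(window_chroms)[:3]}"
        )


def assign_gene_windows(
    variants: Sequence[NuclearVariantCall], windows: Sequence[GeneWindow]
) -> list[NuclearVariantCall]:
    """Tag each variant with every gene whose padded window contains it."""
    _check_chrom_names({v.chrom for v in variants}, {w.chrom for w in windows})
    by_chrom: dict[str, list[GeneWindow]] = {}
    for w in windows:
        by_chrom.setdefault(w.chrom, []).append(w)
    out = []
    for v in variants:
        genes = tuple(
            sorted(
                w.gene
                for w in by_chrom.get(v.chrom, [])
                if w.contains(v.chrom, v.position)
            )
        )
        out.append(
            NuclearVariantCall(
                sample_id=v.sample_id, chrom=v.chrom, position=v.position,
                ref=v.ref, alt=v.alt, impact=v.impact, maf=v.maf, cadd=v.cadd,
                caller_filter=v.caller_filter,
                predictor_labels=v.predictor_labels, genes=genes,
            )
        )
    return out


def _control_site_keys(variants: Sequence, design: dict[str, str]) -> set:
    unlabeled = {v.sample_id for v in variants} - set(design)
    if unlabeled:
        raise ValueError(f"samples missing from design: {sorted(unlabeled)}")
    return {v.site_key for v in variants if design[v.sample_id] == "control"}


def _distinct_sites(variants: Sequence) -> int:
    return len({v.site_key for v in variants})


def prioritize_nuclear(
    variants: Sequence[NuclearVariantCall],
    design: dict[str, str],
    maf_max: float = 0.01,
    cadd_min: float = 10.0,
    missing_cadd_passes: bool = False,
) -> PrioritizationReport:
    """Apply the five-stage nuclear prioritisation cascade."""
    control_sites = _control_site_keys(variants, design)
    stages = [
        ("input", lambda v: True),
        ("drop_low_impact", lambda v: v.impact != "LOW"),
        ("drop_control_shared", lambda v: v.site_key not in control_sites),
        ("maf_rare_or_absent", lambda v: v.maf is None or v.maf < maf_max),
        (
            "cadd_min",
            lambda v: (missing_cadd_passes if v.cadd is None else v.cadd >= cadd_min),
        ),
        ("caller_pass", lambda v: v.caller_filter == "PASS"),
    ]
    current = list(variants)
    attrition = []
    for name, pred in stages:
        current = [v for v in current if pred(v)]
        attrition.append((name, len(current)))
    return PrioritizationReport(
        retained=current,
        n_observations=len(current),
        n_distinct_sites=_distinct_sites(current),
        attrition=attrition,
    )


def prioritize_mito(
    variants: Sequence,
    design: dict[str, str],
    maf_max: float = 0.01,
) -> PrioritizationReport:
    """Mitochondrial cascade: LOW impact, control-shared, MAF only.

    Accepts any call records carrying sample_id, site_key, impact and maf
    (e.g. filtered MtVariantCall records annotated upstream).
    """
    control_sites = _control_site_keys(variants, design)
    stages = [
        ("input", lambda v: True),
        ("drop_low_impact", lambda v: v.impact != "LOW"),
        ("drop_control_shared", lambda v: v.site_key not in control_sites),
        ("maf_rare_or_absent", lambda v: v.maf is None or v.maf < maf_max),
    ]
    current = list(variants)
    attrition = []
    for name, pred in stages:
        current = [v for v in current if pred(v)]
        attrition.append((name, len(current)))
    return PrioritizationReport(
        retained=current,
        n_observations=len(current),
        n_distinct_sites=_distinct_sites(current),
        attrition=attrition,
    )


def gene_burden(
    report: PrioritizationReport, design: dict[str, str]
) -> dict[str, tuple[int, int]]:
    """gene -> (case samples carrying >= 1 retained variant, case samples total)."""
    n_cases = sum(1 for g in design.values() if g == "case")
    carriers: dict[str, set[str]] = {}
    for v in report.retained:
        if design.get(v.sample_id) != "case":
            continue
        for gene in getattr(v, "genes", ()) or ():
            carriers.setdefault(gene, set()).add(v.sample_id)
    return {g: (len(s), n_cases) for g, s in sorted(carriers.items())}
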