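"""Mitochondrial copy-number estimation from depth ratios.

Copy number per diploid cell is twice the ratio of mean mitochondrial
depth to mean autosomal depth.  Autosomal depth is the length-weighted
mean over a configurable autosome set; sex chromosomes are always
excluded (copy-number confound).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .enrichment_stats import GroupSummary, TestResult, t_test_from_summary

logger = logging.getLogger(__name__)

DEFAULT_AUTOSOMES = tuple(f"chr{i}" for i in range(1, 23))
SEX_CHROMOSOMES = frozenset({"chrX", "chrY", "X", "Y"})


@dataclass(frozen=True)
class ContigCoverage:
    contig: str
    length: int
    mean_depth: float


@dataclass(frozen=True)
class DepthSummary:
    sample_id: str
    mt_mean_depth: float
    auto_mean_depth: float


@dataclass(frozen=True)
class CnEstimate:
    sample_id: str
    cn: float


def estimate_cn(depths: DepthSummary) -> CnEstimate:
    """cn = 2 * mt_mean_depth / auto_mean_depth."""
    if depths.auto_mean_depth <= 0:
        raise ValueError(f"{depths.sample_id}: autosomal mean depth must be positive")
    if depths.mt_mean_depth == 0:
        logger.warning("%s: zero mitochondrial depth; cn = 0", depths.sample_id)
    return CnEstimate(
        sample_id=depths.sample_id,
        cn=2.0 * depths.mt_mean_depth / depths.auto_mean_depth,
    )


def depth_from_coverage_table(
    records: Iterable[ContigCoverage],
    sample_id: str = "sample",
    autosomes: Sequence[str] = DEFAULT_AUTOSOMES,
    mito_name: str = "chrM",
) -> DepthSummary:
    """Length-weighted autosomal mean depth plus the mitochondrial depth."""
    records = list(records)
    auto_set = set(autosomes)
    if auto_set & SEX_CHROMOSOMES:
        raise ValueError("sex chromosomes are not allowed in the autosome set")
    mt = [r for r in records if r.contig == mito_name]
    if not mt:
        raise ValueError(f"mitochondrial contig {mito_name!r} missing from coverage table")
    auto = [r for r in records if r.contig in auto_set]
    if not auto:
        raise ValueError("no autosome records found in coverage table")
    lengths = np.array([r.length for r in auto], dtype=float)
    depths = np.array([r.mean_depth for r in auto], dtype=float)
    auto_mean = float((lengths * depths).sum() / lengths.sum())
    return DepthSummary(
        sample_id=sample_id, mt_mean_depth=mt[0].mean_depth, auto_mean_depth=auto_mean
    )


def compare_groups(
    estimates: Sequence[CnEstimate],
    design: dict[str, str],
    groups: tuple[str, str] = ("case", "control"),
) -> TestResult:
    """Pooled t-test of copy number between the two design groups."""
    values: dict[str, list[float]] = {g: [] for g in groups}
    for est in estimates:
        group = design.get(est.sample_id)
        if group is None:
            raise ValueError(f"sample {est.sample_id!r} missing from design")
        if group in values:
            values[group].append(est.cn)
    summaries = []
    for g in groups:
        xs = values[g]
        if len(xs) < 2:
            raise ValueError(f"group {g!r} needs >= 2 samples, has {len(xs)}")
        arr = np.asarray(xs)
        summaries.append(GroupSummary(n=len(xs), mean=float(arr.mean()), sd=float(arr.std(ddof=1))))
    return t_test_from_summary(*summaries)
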