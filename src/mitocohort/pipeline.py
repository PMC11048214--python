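"""End-to-end orchestration and report rendering.

Chains filtering, region assignment, enrichment testing and copy-number
comparison over a cohort, and renders the stratified tables in the
``n/N (%)`` style of a descriptive-statistics summary with the test
method and p-value per block.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Optional, Sequence

from . import __version__
from .enrichment_stats import ContingencyTable, TestResult, build_tables, run_panel
from .mito_map import RegionAtlas, load_atlas
from .mtdna_cn import CnEstimate, compare_groups, depth_from_coverage_table, estimate_cn
from .variant_filter import (
    DEFAULT_THRESHOLDS,
    FilterThresholds,
    MtVariantCall,
    count_sites_and_observations,
    dedupe_and_normalize,
    filter_cohort,
)

logger = logging.getLogger(__name__)


def run_mt_pipeline(
    calls: Sequence[MtVariantCall],
    design: dict[str, str],
    atlas: Optional[RegionAtlas] = None,
    thresholds: FilterThresholds = DEFAULT_THRESHOLDS,
) -> dict:
    """Filter, stratify and test a cohort of mtDNA calls.

    Returns a dict with the retained calls, the audit, the stratified
    tables, test results and headline counts.
    """
    atlas = atlas or load_atlas()
    deduped = dedupe_and_normalize(list(calls))
    retained, audit = filter_cohort(deduped, atlas, thresholds)
    n_obs, n_sites = count_sites_and_observations(retained)
    tables = build_tables(retained, design, atlas, thresholds.hf_hom_threshold)
    results = run_panel(tables)
    return {
        "retained": retained,
        "audit": audit,
        "tables": tables,
        "results": results,
        "n_observations": n_obs,
        "n_distinct_sites": n_sites,
    }


def format_p(p: float) -> str:
    return "<0.0001" if p < 0.0001 else f"{p:.4f}"


def render_summary(
    tables: dict[str, ContingencyTable], results: dict[str, TestResult]
) -> str:
    """Render stratified tables as rows of ``label  n/N (%)  ...  p  method``."""
    lines = ["block\trow\t" + "\t".join(next(iter(tables.values())).col_labels) + "\tp\tmethod"]
    for name, table in tables.items():
        res = results.get(name)
        p = format_p(res.p) if res else ""
        method = res.method if res else "untested"
        totals = table.column_totals
        lines.append(f"{name}\t\t" + "\t" * len(totals) + f"{p}\t{method}")
        for i, row_label in enumerate(table.row_labels):
            cells = []
            for j, total in enumerate(totals):
                n = int(table.counts[i, j])
                if total == 0:
                    cells.append("0/0 (—)")
                else:
                    cells.append(f"{n}/{int(total)} ({round(100 * n / total)}%)")
            lines.append(f"{name}\t{row_label}\t" + "\t".join(cells) + "\t\t")
    return "\n".join(lines) + "\n"


def run_cn_stage(
    depth_records: dict[str, list],
    design: dict[str, str],
    mito_name: str = "chrM",
    autosomes: Optional[Sequence[str]] = None,
) -> dict:
    """Copy-number estimates per sample plus the group comparison."""
    from .mtdna_cn import DEFAULT_AUTOSOMES

    autosomes = autosomes or DEFAULT_AUTOSOMES
    estimates: list[CnEstimate] = []
    for sample, records in depth_records.items():
        summary = depth_from_coverage_table(
            records, sample_id=sample, autosomes=autosomes, mito_name=mito_name
        )
        estimates.append(estimate_cn(summary))
    comparison = compare_groups(estimates, design)
    return {"estimates": estimates, "comparison": comparison}


def build_manifest(
    input_paths: Sequence[str | Path], thresholds: FilterThresholds, seed: Optional[int]
) -> dict:
    """Machine-readable run manifest: version, thresholds, input digests."""
    digests = {}
    for p in input_paths:
        p = Path(p)
        if p.is_file():
            digests[str(p)] = hashlib.sha256(p.read_bytes()).hexdigest()
    return {
        "package": "mitocohort",
        "version": __version__,
        "thresholds": dataclasses.asdict(thresholds),
        "seed": seed,
        "inputs": digests,
    }


def write_report(outdir: str | Path, report: dict, manifest: dict) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "summary.tsv").write_text(
        render_summary(report["tables"], report["results"])
    )
    results_json = {
        name: {
            "method": r.method,
            "p": r.p,
            "statistic": r.statistic,
            "df": r.df,
            "note": r.note,
        }
        for name, r in report["results"].items()
    }
    results_json["_counts"] = {
        "n_observations": report["n_observations"],
        "n_distinct_sites": report["n_distinct_sites"],
    }
    (outdir / "test_results.json").write_text(json.dumps(results_json, indent=1, sort_keys=True))
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
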