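"""Readers and writers for the plain-text formats the pipeline consumes.

VCF parsing is backed by cyvcf2.  Heteroplasmy fractions are read from a
configurable FORMAT key (default ``HF``, falling back to ``AF``), strand
support from ``ADF``/``ADR``; nuclear annotations come from the INFO
keys ``IMPACT``, ``MAF``, ``CADD`` and ``GENES``.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Optional, Sequence

from cyvcf2 import VCF

from .mtdna_cn import ContigCoverage
from .prioritize import GeneWindow, NuclearVariantCall
from .variant_filter import FilterVerdict, MtVariantCall


def _fmt_scalar(variant, key: str):
    try:
        arr = variant.format(key)
    except KeyError:
        return None
    if arr is None:
        return None
    v = arr.flat[0]
    return None if v is None else float(v)


def read_mt_vcf(
    path: str | Path,
    sample_id: Optional[str] = None,
    hf_key: str = "HF",
) -> list[MtVariantCall]:
    """Read one single-sample mtDNA VCF into call records."""
    vcf = VCF(str(path))
    if sample_id is None:
        if len(vcf.samples) != 1:
            raise ValueError(f"{path}: expected a single-sample VCF, got {vcf.samples}")
        sample_id = vcf.samples[0]
    calls = []
    for v in vcf:
        hf = _fmt_scalar(v, hf_key)
        if hf is None:
            hf = _fmt_scalar(v, "AF")
        if hf is None:
            raise ValueError(f"{path}: no {hf_key}/AF for record at {v.POS}")
        depth = _fmt_scalar(v, "DP") or float(v.INFO.get("DP", 0))
        adf = _fmt_scalar(v, "ADF") or 0
        adr = _fmt_scalar(v, "ADR") or 0
        lo = _fmt_scalar(v, "CILOW")
        hi = _fmt_scalar(v, "CIUP")
        ref, alt = v.REF, v.ALT[0]
        calls.append(
            MtVariantCall(
                sample_id=sample_id,
                position=v.POS,
                ref=ref,
                alt=alt,
                hf=float(hf),
                depth=int(depth),
                alt_fwd=int(adf),
                alt_rev=int(adr),
                quality=float(v.QUAL) if v.QUAL is not None else 40.0,
                hf_ci=(lo if lo is not None else 0.0, hi if hi is not None else 1.0),
                variant_class="SNP" if len(ref) == 1 and len(alt) == 1 else "indel",
            )
        )
    return calls


def read_nuclear_vcf(path: str | Path, sample_id: Optional[str] = None) -> list[NuclearVariantCall]:
    """Read one single-sample annotated nuclear VCF."""
    vcf = VCF(str(path))
    if sample_id is None:
        if len(vcf.samples) != 1:
            raise ValueError(f"{path}: expected a single-sample VCF, got {vcf.samples}")
        sample_id = vcf.samples[0]
    calls = []
    for v in vcf:
        impact = v.INFO.get("IMPACT")
        if impact is None:
            raise ValueError(f"{path}: record at {v.POS} lacks IMPACT annotation")
        maf = v.INFO.get("MAF")
        cadd = v.INFO.get("CADD")
        genes = v.INFO.get("GENES")
        calls.append(
            NuclearVariantCall(
                sample_id=sample_id,
                chrom=v.CHROM,
                position=v.POS,
                ref=v.REF,
                alt=v.ALT[0],
                impact=str(impact),
                maf=float(maf) if maf is not None else None,
                cadd=float(cadd) if cadd is not None else None,
                caller_filter=v.FILTER or "PASS",
                genes=tuple(str(genes).split(",")) if genes else (),
            )
        )
    return calls


def read_design(path: str | Path) -> dict[str, str]:
    """sample -> group mapping from a two-column TSV (header: sample, group)."""
    design: dict[str, str] = {}
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or "sample" not in reader.fieldnames:
            raise ValueError(f"{path}: expected columns sample/group")
        for row in reader:
            design[row["sample"]] = row["group"]
    if not design:
        raise ValueError(f"{path}: empty design table")
    return design


def read_depth_tsv(path: str | Path) -> dict[str, list[ContigCoverage]]:
    """Per-sample coverage records from a sample/contig/length/mean_depth TSV."""
    out: dict[str, list[ContigCoverage]] = {}
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            out.setdefault(row["sample"], []).append(
                ContigCoverage(
                    contig=row["contig"],
                    length=int(row["length"]),
                    mean_depth=float(row["mean_depth"]),
                )
            )
    if not out:
        raise ValueError(f"{path}: empty coverage table")
    return out


def read_gene_windows(path: str | Path, dialect: str = "native") -> list[GeneWindow]:
    """Gene intervals from native TSV (gene/chrom/start/end, 1-based) or BED."""
    windows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if dialect == "native":
                if fields[0] == "gene":
                    continue
                gene, chrom, start, end = fields[:4]
                windows.append(GeneWindow(gene, chrom, int(start), int(end)))
            elif dialect == "bed":
                chrom, start, end, gene = fields[:4]
                windows.append(GeneWindow(gene, chrom, int(start) + 1, int(end)))
            else:
                raise ValueError(f"unknown gene-window dialect {dialect!r}")
    if not windows:
        raise ValueError(f"{path}: no gene windows found")
    return windows


def write_filter_audit(
    audit: Sequence[tuple[MtVariantCall, FilterVerdict]], path: str | Path
) -> None:
    """TSV of per-call verdicts (sample, site, HF, retained, reasons)."""
    with open(path, "w") as fh:
        fh.write("sample\tposition\tref\talt\thf\tdepth\tretained\treasons\n")
        for call, verdict in audit:
            fh.write(
                f"{call.sample_id}\t{call.position}\t{call.ref}\t{call.alt}\t"
                f"{call.hf:.6f}\t{call.depth}\t{int(verdict.retained)}\t"
                f"{';'.join(verdict.reasons) or 'PASS'}\n"
            )
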