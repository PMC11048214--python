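"""Synthetic case/control cohorts for exercising every pipeline stage.

Generates mtDNA variant calls with heteroplasmy and strand support,
annotated nuclear variant calls, and per-contig depth tables, together
with a truth ledger sufficient to score filtering, prioritisation,
enrichment and copy-number estimation downstream.  All output is a
deterministic function of the configuration (including its seed).

Observation model: a variant with true heteroplasmic fraction f at a
site sequenced to depth d yields alt reads ~ Binomial(d, f), split
between strands ~ Binomial(alt, 0.5); the observed HF is alt/d.  This is
a modelling choice reproducing coverage-driven detection differences,
not a published model.  With ``strict_clean`` (the default) clean draws
are constrained to satisfy every retention rule, so that only planted
contaminants are ever filtered; disable it for detection-power studies
where sampling noise should be allowed to drop calls.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .mito_map import RegionAtlas, load_atlas
from .prioritize import GeneWindow, NuclearVariantCall
from .mtdna_cn import ContigCoverage
from .variant_filter import MtVariantCall

TRANSVERSIONS = [
    ("A", "C"), ("A", "T"), ("C", "A"), ("C", "G"),
    ("G", "C"), ("G", "T"), ("T", "A"), ("T", "G"),
]

#: GRCh38 autosome lengths (bp), used for depth-table simulation.
HG38_AUTOSOME_LENGTHS = {
    "chr1": 248956422, "chr2": 242193529, "chr3": 198295559, "chr4": 190214555,
    "chr5": 181538259, "chr6": 170805979, "chr7": 159345973, "chr8": 145138636,
    "chr9": 138394717, "chr10": 133797422, "chr11": 135086622, "chr12": 133275309,
    "chr13": 114364328, "chr14": 107043718, "chr15": 101991189, "chr16": 90338345,
    "chr17": 83257441, "chr18": 80373285, "chr19": 58617616, "chr20": 64444167,
    "chr21": 46709983, "chr22": 50818468,
}
MT_LENGTH = 16569


@dataclass(frozen=True)
class CohortConfig:
    """Full parameterisation of a synthetic cohort."""

    seed: int = 0
    n_cases: int = 8
    n_controls: int = 4
    mean_variants_per_sample: float = 40.0
    cr_enrichment_odds: float = 1.0  # case-specific odds multiplier for CR placement
    het_fraction_beta: tuple[float, float] = (0.8, 3.0)
    p_heteroplasmic: float = 0.5
    transition_probs: dict = field(
        default_factory=lambda: {
            "A>G": 0.25, "C>T": 0.20, "G>A": 0.30, "T>C": 0.20, "transversion": 0.05,
        }
    )
    coverage_depth: float = 1000.0
    strand_bias_rate: float = 0.0
    homopolymer_rate: float = 0.0
    low_hf_rate: float = 0.0
    true_cn_case: float = 450.0
    true_cn_control: float = 360.0
    strict_clean: bool = True
    # nuclear cohort
    mean_nuclear_variants_per_sample: float = 50.0
    impact_probs: dict = field(
        default_factory=lambda: {
            "HIGH": 0.05, "MODERATE": 0.25, "LOW": 0.30, "MODIFIER": 0.40,
        }
    )
    maf_absent_prob: float = 0.15
    p_rare: float = 0.5  # probability a recorded MAF is below 0.01
    cadd_range: tuple[float, float] = (0.0, 40.0)
    pass_prob: float = 0.9
    control_shared_prob: float = 0.3  # case site also emitted in a control sample
    min_hf: float = 0.01  # retention threshold the clean draws must satisfy

    def __post_init__(self) -> None:
        for name in (
            "p_heteroplasmic", "strand_bias_rate", "homopolymer_rate",
            "low_hf_rate", "maf_absent_prob", "p_rare", "pass_prob",
            "control_shared_prob",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.cr_enrichment_odds <= 0:
            raise ValueError("cr_enrichment_odds must be positive")
        if self.strand_bias_rate + self.homopolymer_rate + self.low_hf_rate > 1:
            raise ValueError("contamination rates sum above 1")
        if abs(sum(self.transition_probs.values()) - 1.0) > 1e-9:
            raise ValueError("transition_probs must sum to 1")
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("need at least one case and one control")


@dataclass
class CohortBundle:
    config: CohortConfig
    design: dict[str, str]
    mt_calls: list[MtVariantCall] = field(default_factory=list)
    nuclear_calls: list[NuclearVariantCall] = field(default_factory=list)
    depth_records: dict[str, list[ContigCoverage]] = field(default_factory=dict)
    truth: dict = field(default_factory=dict)

    def write(self, outdir: str | Path) -> None:
        """Write the bundle as plain-text artifacts (VCF/TSV/JSON)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "design.tsv", "w") as fh:
            fh.write("sample\tgroup\n")
            for s, g in self.design.items():
                fh.write(f"{s}\t{g}\n")
        mtdir = outdir / "mt"
        mtdir.mkdir(exist_ok=True)
        for sample in self.design:
            calls = [c for c in self.mt_calls if c.sample_id == sample]
            write_mt_vcf(calls, sample, mtdir / f"{sample}.vcf")
        if self.nuclear_calls:
            ndir = outdir / "nuclear"
            ndir.mkdir(exist_ok=True)
            for sample in self.design:
                calls = [c for c in self.nuclear_calls if c.sample_id == sample]
                write_nuclear_vcf(calls, sample, ndir / f"{sample}.vcf")
        if self.depth_records:
            with open(outdir / "depth.tsv", "w") as fh:
                fh.write("sample\tcontig\tlength\tmean_depth\n")
                for sample, recs in self.depth_records.items():
                    for r in recs:
                        fh.write(f"{sample}\t{r.contig}\t{r.length}\t{r.mean_depth:.6f}\n")
        with open(outdir / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=1, sort_keys=True)


def make_design(config: CohortConfig) -> dict[str, str]:
    design = {f"ALS_{i + 1}": "case" for i in range(config.n_cases)}
    design.update({f"CNTR_{i + 1}": "control" for i in range(config.n_controls)})
    return design


# ---------------------------------------------------------------------
# mtDNA cohort


_POOL_CACHE: dict[int, tuple[list[int], list[int], list[int]]] = {}


def _atlas_position_pools(atlas: RegionAtlas) -> tuple[list[int], list[int], list[int]]:
    """(clean CR positions, clean non-CR positions, homopolymer positions)."""
    cached = _POOL_CACHE.get(id(atlas))
    if cached is not None:
        return cached
    cr, non_cr, homopolymer = [], [], []
    for pos in range(1, atlas.genome_length + 1):
        if atlas.is_homopolymer(pos):
            homopolymer.append(pos)
        elif atlas.assign(pos).top_level == "CR":
            cr.append(pos)
        else:
            non_cr.append(pos)
    _POOL_CACHE[id(atlas)] = (cr, non_cr, homopolymer)
    return cr, non_cr, homopolymer


def _true_hf(rng: np.random.Generator, config: CohortConfig) -> float:
    if rng.random() >= config.p_heteroplasmic:
        return 1.0
    a, b = config.het_fraction_beta
    for _ in range(1000):
        x = float(rng.beta(a, b))
        if 0.01 <= x < 0.95:
            return x
    return 0.5


def _draw_substitution(rng: np.random.Generator, config: CohortConfig) -> tuple[str, str]:
    classes = list(config.transition_probs)
    probs = np.array([config.transition_probs[c] for c in classes])
    klass = classes[rng.choice(len(classes), p=probs / probs.sum())]
    if klass == "transversion":
        return TRANSVERSIONS[rng.integers(len(TRANSVERSIONS))]
    ref, alt = klass.split(">")
    return ref, alt


def generate_mt_cohort(
    config: CohortConfig, atlas: Optional[RegionAtlas] = None
) -> CohortBundle:
    """Simulate per-sample mtDNA variant calls with a truth ledger."""
    atlas = atlas or load_atlas()
    rng = np.random.default_rng(config.seed)
    design = make_design(config)
    cr_pool, non_cr_pool, hp_pool = _atlas_position_pools(atlas)

    p_cr_base = len(cr_pool) / (len(cr_pool) + len(non_cr_pool))
    odds_base = p_cr_base / (1.0 - p_cr_base)

    calls: list[MtVariantCall] = []
    ledger: list[dict] = []
    p_contaminant = config.homopolymer_rate + config.strand_bias_rate + config.low_hf_rate

    for sample, group in design.items():
        odds = odds_base * (config.cr_enrichment_odds if group == "case" else 1.0)
        p_cr = odds / (1.0 + odds)
        n_vars = int(rng.poisson(config.mean_variants_per_sample))
        used: set[int] = set()
        for _ in range(n_vars):
            u = rng.random()
            if u < config.homopolymer_rate:
                contaminant = "homopolymer"
            elif u < config.homopolymer_rate + config.strand_bias_rate:
                contaminant = "single_strand"
            elif u < p_contaminant:
                contaminant = "low_hf"
            else:
                contaminant = None

            if contaminant == "homopolymer":
                pool = hp_pool
            else:
                pool = cr_pool if rng.random() < p_cr else non_cr_pool
            for _ in range(100):
                position = int(pool[rng.integers(len(pool))])
                if position not in used:
                    break
            else:
                continue
            used.add(position)

            ref, alt_base = _draw_substitution(rng, config)
            hf_true = _true_hf(rng, config)
            depth = int(rng.poisson(config.coverage_depth))

            if contaminant == "low_hf":
                depth = max(depth, 300)
                alt = max(1, int(depth * 0.004))
                while alt / depth >= config.min_hf:
                    depth += 100
            else:
                depth = max(depth, 5) if config.strict_clean else max(depth, 1)
                alt = int(rng.binomial(depth, hf_true))
                if config.strict_clean:
                    floor = max(2, math.ceil(config.min_hf * depth))
                    alt = min(depth, max(alt, floor))
                elif alt == 0:
                    ledger.append(
                        _truth_record(sample, position, ref, alt_base, hf_true,
                                      contaminant, atlas, detected=False)
                    )
                    continue

            if contaminant == "single_strand":
                alt = max(alt, 1)
                alt_fwd, alt_rev = alt, 0
            else:
                alt_fwd = int(rng.binomial(alt, 0.5))
                if config.strict_clean and alt >= 2:
                    alt_fwd = min(max(alt_fwd, 1), alt - 1)
                alt_rev = alt - alt_fwd

            hf_obs = alt / depth
            half = 1.96 * math.sqrt(max(hf_obs * (1 - hf_obs), 1e-12) / depth)
            calls.append(
                MtVariantCall(
                    sample_id=sample, position=position, ref=ref, alt=alt_base,
                    hf=hf_obs, depth=depth, alt_fwd=alt_fwd, alt_rev=alt_rev,
                    quality=40.0,
                    hf_ci=(max(0.0, hf_obs - half), min(1.0, hf_obs + half)),
                )
            )
            ledger.append(
                _truth_record(sample, position, ref, alt_base, hf_true,
                              contaminant, atlas, detected=True)
            )

    bundle = CohortBundle(config=config, design=design, mt_calls=calls)
    bundle.truth = {
        "config": _config_dict(config),
        "mt_variants": ledger,
        "cr_fraction_base": p_cr_base,
    }
    return bundle


def _truth_record(sample, position, ref, alt, hf_true, contaminant, atlas, detected):
    return {
        "sample": sample,
        "position": position,
        "ref": ref,
        "alt": alt,
        "true_hf": round(hf_true, 6),
        "true_ploidy": "homoplasmic" if hf_true >= 0.95 else "heteroplasmic",
        "contaminant": contaminant,
        "in_cr": atlas.assign(position).top_level == "CR",
        "detected": detected,
    }


def _config_dict(config: CohortConfig) -> dict:
    d = asdict(config)
    d["het_fraction_beta"] = list(config.het_fraction_beta)
    d["cadd_range"] = list(config.cadd_range)
    return d


# ---------------------------------------------------------------------
# nuclear cohort


def generate_nuclear_cohort(
    config: CohortConfig, gene_windows: Sequence[GeneWindow]
) -> CohortBundle:
    """Simulate annotated nuclear calls placed in/around supplied gene windows."""
    if not gene_windows:
        raise ValueError("gene windows are required")
    rng = np.random.default_rng(config.seed + 1)
    design = make_design(config)
    controls = [s for s, g in design.items() if g == "control"]
    impacts = list(config.impact_probs)
    probs = np.array([config.impact_probs[i] for i in impacts])
    probs = probs / probs.sum()
    lo_cadd, hi_cadd = config.cadd_range

    calls: list[NuclearVariantCall] = []
    ledger: list[dict] = []
    for sample, group in design.items():
        n_vars = int(rng.poisson(config.mean_nuclear_variants_per_sample))
        for k in range(n_vars):
            w = gene_windows[rng.integers(len(gene_windows))]
            lo, hi = w.padded
            position = int(rng.integers(lo, hi + 1))
            ref, alt = _draw_substitution(rng, config)
            impact = impacts[rng.choice(len(impacts), p=probs)]
            if rng.random() < config.maf_absent_prob:
                maf = None
            elif rng.random() < config.p_rare:
                maf = float(10 ** rng.uniform(-6, -2.01))
            else:
                maf = float(rng.uniform(0.01, 0.5))
            cadd = float(rng.uniform(lo_cadd, hi_cadd))
            caller_filter = "PASS" if rng.random() < config.pass_prob else "LowQual"
            call = NuclearVariantCall(
                sample_id=sample, chrom=w.chrom, position=position, ref=ref,
                alt=alt, impact=impact, maf=maf, cadd=cadd,
                caller_filter=caller_filter, genes=(w.gene,),
            )
            calls.append(call)
            shared = group == "case" and rng.random() < config.control_shared_prob
            if shared:
                ctrl = controls[rng.integers(len(controls))]
                calls.append(
                    NuclearVariantCall(
                        sample_id=ctrl, chrom=w.chrom, position=position, ref=ref,
                        alt=alt, impact=impact, maf=maf, cadd=cadd,
                        caller_filter=caller_filter, genes=(w.gene,),
                    )
                )
            ledger.append(
                {
                    "sample": sample,
                    "chrom": w.chrom,
                    "position": position,
                    "ref": ref,
                    "alt": alt,
                    "gene": w.gene,
                    "impact": impact,
                    "maf": maf,
                    "cadd": cadd,
                    "caller_filter": caller_filter,
                    "control_shared": shared,
                    "expect_survives": (
                        group == "case"
                        and impact != "LOW"
                        and not shared
                        and (maf is None or maf < 0.01)
                        and cadd >= 10.0
                        and caller_filter == "PASS"
                    ),
                }
            )
    bundle = CohortBundle(config=config, design=design, nuclear_calls=calls)
    bundle.truth = {"config": _config_dict(config), "nuclear_variants": ledger}
    return bundle


# ---------------------------------------------------------------------
# depth tables


def generate_depth_table(config: CohortConfig) -> CohortBundle:
    """Simulate per-contig mean depths with planted copy numbers."""
    rng = np.random.default_rng(config.seed + 2)
    design = make_design(config)
    records: dict[str, list[ContigCoverage]] = {}
    for sample, group in design.items():
        cn = config.true_cn_case if group == "case" else config.true_cn_control
        recs = []
        for contig, length in HG38_AUTOSOME_LENGTHS.items():
            # mean depth over the contig: total base coverage / length
            total = rng.poisson(config.coverage_depth * length)
            recs.append(ContigCoverage(contig, length, float(total / length)))
        mt_total = rng.poisson(config.coverage_depth * cn / 2.0 * MT_LENGTH)
        recs.append(ContigCoverage("chrM", MT_LENGTH, float(mt_total / MT_LENGTH)))
        records[sample] = recs
    bundle = CohortBundle(config=config, design=design, depth_records=records)
    bundle.truth = {
        "config": _config_dict(config),
        "true_cn": {
            s: (config.true_cn_case if g == "case" else config.true_cn_control)
            for s, g in design.items()
        },
    }
    return bundle


# ---------------------------------------------------------------------
# plain-text VCF writers (uncompressed VCF 4.2)


def write_mt_vcf(calls: Sequence[MtVariantCall], sample: str, path: str | Path) -> None:
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID=chrM,length={MT_LENGTH}>",
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=HF,Number=1,Type=Float,Description="Heteroplasmy fraction">',
        '##FORMAT=<ID=CILOW,Number=1,Type=Float,Description="HF CI lower bound">',
        '##FORMAT=<ID=CIUP,Number=1,Type=Float,Description="HF CI upper bound">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=ADF,Number=1,Type=Integer,Description="Alt forward reads">',
        '##FORMAT=<ID=ADR,Number=1,Type=Integer,Description="Alt reverse reads">',
        f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}",
    ]
    for c in sorted(calls, key=lambda c: (c.position, c.ref, c.alt)):
        fmt = (
            f"1:{c.hf:.6f}:{c.hf_ci[0]:.6f}:{c.hf_ci[1]:.6f}"
            f":{c.depth}:{c.alt_fwd}:{c.alt_rev}"
        )
        lines.append(
            f"chrM\t{c.position}\t.\t{c.ref}\t{c.alt}\t{c.quality:.1f}\t.\t"
            f"DP={c.depth}\tGT:HF:CILOW:CIUP:DP:ADF:ADR\t{fmt}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_nuclear_vcf(
    calls: Sequence[NuclearVariantCall], sample: str, path: str | Path
) -> None:
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=IMPACT,Number=1,Type=String,Description="Impact class">',
        '##INFO=<ID=MAF,Number=1,Type=Float,Description="Population allele frequency">',
        '##INFO=<ID=CADD,Number=1,Type=Float,Description="CADD phred score">',
        '##INFO=<ID=GENES,Number=.,Type=String,Description="Gene window tags">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FILTER=<ID=LowQual,Description="Failed caller filters">',
        f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}",
    ]
    for c in sorted(calls, key=lambda c: (c.chrom, c.position, c.ref, c.alt)):
        info = [f"IMPACT={c.impact}"]
        if c.maf is not None:
            info.append(f"MAF={c.maf:.8g}")
        if c.cadd is not None:
            info.append(f"CADD={c.cadd:.3f}")
        if c.genes:
            info.append("GENES=" + ",".join(c.genes))
        lines.append(
            f"{c.chrom}\t{c.position}\t.\t{c.ref}\t{c.alt}\t.\t{c.caller_filter}\t"
            f"{';'.join(info)}\tGT\t0/1"
        )
    Path(path).write_text("\n".join(lines) + "\n")
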