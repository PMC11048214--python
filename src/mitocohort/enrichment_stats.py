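"""Contingency-table construction and exact/asymptotic tests.

Builds the stratified case/control tables of a cohort summary (ploidy,
CR vs coding, CR sub-regions, CR functional domains, protein-coding
genes, rRNA/tRNA genes, substitution spectrum overall and per ploidy
class) and tests them: 2-row tables with the two-sided Fisher exact
test, 3+-row tables with the uncorrected chi-square test.  Group
summaries are compared with the pooled-variance two-tailed Student
t-test.  The counting unit throughout is the variant observation
(sample x site), not the distinct site.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .mito_map import RegionAtlas
from .variant_filter import MtVariantCall, classify_ploidy

logger = logging.getLogger(__name__)

TRANSITIONS = {("A", "G"): "A>G", ("C", "T"): "C>T", ("G", "A"): "G>A", ("T", "C"): "T>C"}
SPECTRUM_CLASSES = ("A>G", "C>T", "G>A", "T>C")

#: Relative tolerance when comparing hypergeometric point probabilities
#: for the two-sided Fisher tie rule.
FISHER_TIE_RTOL = 1e-7


@dataclass(frozen=True)
class TestResult:
    method: str  # "fisher_exact_2x2" | "chi_square" | "t_pooled"
    p: float
    statistic: Optional[float] = None
    df: Optional[int] = None
    note: str = ""


@dataclass(frozen=True)
class GroupSummary:
    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group summary needs n >= 2")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


@dataclass
class ContingencyTable:
    name: str
    row_labels: list[str]
    col_labels: list[str]
    counts: np.ndarray  # r x c non-negative ints

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("counts shape does not match labels")

    @property
    def column_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def drop_zero_rows(self) -> "ContingencyTable":
        keep = self.counts.sum(axis=1) > 0
        if keep.all():
            return self
        dropped = [l for l, k in zip(self.row_labels, keep) if not k]
        logger.info("table %s: dropping all-zero rows %s", self.name, dropped)
        return ContingencyTable(
            self.name,
            [l for l, k in zip(self.row_labels, keep) if k],
            list(self.col_labels),
            self.counts[keep],
        )


# ---------------------------------------------------------------------
# tests


def fisher_exact_2x2(table: Sequence[Sequence[int]] | ContingencyTable) -> TestResult:
    """Two-sided Fisher exact test on a 2x2 table.

    The p-value sums the hypergeometric probabilities, under fixed
    margins, of every table whose point probability does not exceed the
    observed one (up to a small relative tolerance for ties).
    """
    counts = table.counts if isinstance(table, ContingencyTable) else np.asarray(table, dtype=int)
    if counts.shape != (2, 2):
        raise ValueError(f"fisher_exact_2x2 requires a 2x2 table, got {counts.shape}")
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    a, b = counts[0]
    c, d = counts[1]
    n = a + b + c + d
    r1 = a + b
    c1 = a + c
    if n == 0:
        return TestResult(method="fisher_exact_2x2", p=1.0, note="empty table")
    # support of the top-left cell under fixed margins
    lo = max(0, r1 + c1 - n)
    hi = min(r1, c1)
    hyper = stats.hypergeom(n, r1, c1)
    p_obs = hyper.pmf(a)
    ks = np.arange(lo, hi + 1)
    pmf = hyper.pmf(ks)
    p = float(pmf[pmf <= p_obs * (1.0 + FISHER_TIE_RTOL)].sum())
    if p >= 1.0 - 1e-12:  # all tables included: p is exactly 1 up to float noise
        p = 1.0
    return TestResult(method="fisher_exact_2x2", p=min(p, 1.0))


def chi_square(table: Sequence[Sequence[int]] | ContingencyTable) -> TestResult:
    """Pearson chi-square test of independence, no continuity correction."""
    counts = table.counts if isinstance(table, ContingencyTable) else np.asarray(table, dtype=int)
    if counts.ndim != 2 or min(counts.shape) < 2:
        raise ValueError(f"chi_square requires an r x c table with r,c >= 2, got {counts.shape}")
    row_tot = counts.sum(axis=1)
    col_tot = counts.sum(axis=0)
    if (row_tot == 0).any() or (col_tot == 0).any():
        raise ValueError("zero row/column margin; prune the table first")
    n = counts.sum()
    expected = np.outer(row_tot, col_tot) / n
    statistic = float(((counts - expected) ** 2 / expected).sum())
    df = (counts.shape[0] - 1) * (counts.shape[1] - 1)
    note = ""
    if (expected < 5).any():
        note = "expected counts < 5; asymptotic p may be unreliable"
        logger.warning("chi_square: %s", note)
    p = float(stats.chi2.sf(statistic, df))
    return TestResult(method="chi_square", p=p, statistic=statistic, df=df, note=note)


def t_test_from_summary(a: GroupSummary, b: GroupSummary) -> TestResult:
    """Pooled-variance two-tailed Student t-test from group summaries."""
    df = a.n + b.n - 2
    pooled_var = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / df
    se = math.sqrt(pooled_var * (1.0 / a.n + 1.0 / b.n))
    if se == 0.0:
        t = 0.0 if a.mean == b.mean else math.inf
        p = 1.0 if a.mean == b.mean else 0.0
        return TestResult(method="t_pooled", p=p, statistic=t, df=df, note="zero variance")
    t = (a.mean - b.mean) / se
    p = float(2.0 * stats.t.sf(abs(t), df))
    return TestResult(method="t_pooled", p=p, statistic=float(t), df=df)


# ---------------------------------------------------------------------
# spectrum


def classify_substitution(ref: str, alt: str) -> str:
    """Spectrum class of a single-base substitution (light-strand notation)."""
    ref, alt = ref.upper(), alt.upper()
    bases = {"A", "C", "G", "T"}
    if len(ref) != 1 or len(alt) != 1 or ref not in bases or alt not in bases:
        raise ValueError(f"not a single-base substitution: {ref!r}>{alt!r}")
    if ref == alt:
        raise ValueError("ref and alt are identical")
    return TRANSITIONS.get((ref, alt), "transversion")


# ---------------------------------------------------------------------
# table construction

#: Genomic order of protein-coding gene rows in the summary tables.
_CODING_GENE_ORDER = [
    "MT-ND1", "MT-ND2", "MT-CO1", "MT-CO2", "MT-ATP8", "MT-ATP6", "MT-CO3",
    "MT-ND3", "MT-ND4L", "MT-ND4", "MT-ND5", "MT-ND6", "MT-CYB",
]
_DOMAIN_ORDER = ["CENTRAL_DOMAIN", "CSB", "ETAS", "LSP"]
_HV_ORDER = ["HV1", "HV2", "HV3", "no-HV"]


def build_tables(
    calls: Sequence[MtVariantCall],
    design: dict[str, str],
    atlas: RegionAtlas,
    hom_threshold: float = 0.95,
    groups: tuple[str, str] = ("case", "control"),
) -> dict[str, ContingencyTable]:
    """Build the nine stratified case/control tables from retained calls.

    *design* maps sample_id -> group label; *groups* fixes the column
    order (cases first).
    """
    unknown = {c.sample_id for c in calls} - set(design)
    if unknown:
        raise ValueError(f"samples missing from design: {sorted(unknown)}")
    col_of = {g: i for i, g in enumerate(groups)}

    def blank(rows: Sequence[str]) -> np.ndarray:
        return np.zeros((len(rows), len(groups)), dtype=int)

    ploidy = blank(["Het", "Hom"])
    dist = blank(["Control Region", "Coding Region"])
    hv = blank(_HV_ORDER)
    domains = blank(_DOMAIN_ORDER)
    genes_seen: dict[str, np.ndarray] = {}
    rrna = blank(["12S rRNA", "16S rRNA", "tRNA", "Non-coding nt"])
    spectra = {
        key: blank(SPECTRUM_CLASSES) for key in ("all", "het", "hom")
    }

    for call in calls:
        j = col_of[design[call.sample_id]]
        asg = atlas.assign(call.position)
        is_hom = classify_ploidy(call.hf, hom_threshold) == "homoplasmic"
        ploidy[1 if is_hom else 0, j] += 1
        if asg.top_level == "CR":
            dist[0, j] += 1
            hv[_HV_ORDER.index(asg.hv), j] += 1
            if asg.functional_domain != "none":
                domains[_DOMAIN_ORDER.index(asg.functional_domain), j] += 1
        else:
            dist[1, j] += 1
            if asg.top_level == "coding":
                cat = atlas.gene_category(asg.gene)
                if cat == "gene":
                    row = genes_seen.setdefault(asg.gene, np.zeros(len(groups), dtype=int))
                    row[j] += 1
                elif cat == "rRNA":
                    rrna[0 if asg.gene == "MT-RNR1" else 1, j] += 1
                elif cat == "tRNA":
                    rrna[2, j] += 1
            else:
                rrna[3, j] += 1
        # substitution spectrum: single-base substitutions only
        try:
            klass = classify_substitution(call.ref, call.alt)
        except ValueError:
            continue
        if klass == "transversion":
            continue
        i = SPECTRUM_CLASSES.index(klass)
        spectra["all"][i, j] += 1
        spectra["hom" if is_hom else "het"][i, j] += 1

    gene_rows = [g for g in _CODING_GENE_ORDER if g in genes_seen]
    gene_rows += sorted(set(genes_seen) - set(gene_rows))
    coding = (
        np.stack([genes_seen[g] for g in gene_rows])
        if gene_rows
        else np.zeros((0, len(groups)), dtype=int)
    )

    cols = list(groups)
    return {
        "type_of_variant": ContingencyTable("type_of_variant", ["Het", "Hom"], cols, ploidy),
        "distribution_of_variants": ContingencyTable(
            "distribution_of_variants", ["Control Region", "Coding Region"], cols, dist
        ),
        "cr_sites": ContingencyTable("cr_sites", list(_HV_ORDER), cols, hv),
        "cr_functional_domains": ContingencyTable(
            "cr_functional_domains", list(_DOMAIN_ORDER), cols, domains
        ),
        "coding_regions": ContingencyTable("coding_regions", gene_rows, cols, coding),
        "rrna_trna_genes": ContingencyTable(
            "rrna_trna_genes", ["12S rRNA", "16S rRNA", "tRNA", "Non-coding nt"], cols, rrna
        ),
        "substitution": ContingencyTable(
            "substitution", list(SPECTRUM_CLASSES), cols, spectra["all"]
        ),
        "substitution_het": ContingencyTable(
            "substitution_het", list(SPECTRUM_CLASSES), cols, spectra["het"]
        ),
        "substitution_hom": ContingencyTable(
            "substitution_hom", list(SPECTRUM_CLASSES), cols, spectra["hom"]
        ),
    }


def run_panel(tables: dict[str, ContingencyTable]) -> dict[str, TestResult]:
    """Test each table: 2 rows -> Fisher exact, 3+ rows -> chi-square.

    All-zero rows are pruned first; tables left untestable (fewer than
    two rows, or a zero column margin) are skipped with a note.
    """
    results: dict[str, TestResult] = {}
    for name, table in tables.items():
        pruned = table.drop_zero_rows()
        r = pruned.counts.shape[0]
        if r < 2 or (pruned.counts.sum(axis=0) == 0).any():
            logger.info("table %s untestable after pruning; skipped", name)
            continue
        if r == 2:
            results[name] = fisher_exact_2x2(pruned)
        else:
            results[name] = chi_square(pruned)
    return results
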