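"""Circular rCRS coordinate model and interval atlas.

Assigns every mitochondrial position its gene, control-region (CR)
sub-region, functional domain, secondary-structure elements and
homopolymer status.  Coordinates are 1-based inclusive; an interval with
``start > end`` wraps through the origin (16569 -> 1) of the circular
genome.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

RCRS_LENGTH = 16569

TOP_LEVEL_CATEGORIES = ("CR", "gene", "rRNA", "tRNA", "non_coding")
CATEGORIES = TOP_LEVEL_CATEGORIES + (
    "HV",
    "functional_domain",
    "structure_element",
    "homopolymer",
)

#: Domain-group reported in summary tables, keyed by bundled label prefix.
_DOMAIN_GROUPS = {
    "ETAS": "ETAS",
    "CSB": "CSB",
    "LSP": "LSP",
    "CENTRAL_DOMAIN": "CENTRAL_DOMAIN",
}


class AtlasError(ValueError):
    """Raised for malformed or inconsistent atlas input."""


@dataclass(frozen=True)
class Interval:
    """A labelled, possibly origin-wrapping interval on the circular genome."""

    label: str
    category: str
    start: int
    end: int

    def positions(self, genome_length: int = RCRS_LENGTH) -> Iterable[int]:
        if self.start <= self.end:
            return range(self.start, self.end + 1)
        # wraps through the origin
        return list(range(self.start, genome_length + 1)) + list(
            range(1, self.end + 1)
        )

    def __len__(self) -> int:
        if self.start <= self.end:
            return self.end - self.start + 1
        return (RCRS_LENGTH - self.start + 1) + self.end

    def contains(self, position: int) -> bool:
        if self.start <= self.end:
            return self.start <= position <= self.end
        return position >= self.start or position <= self.end


@dataclass(frozen=True)
class RegionAssignment:
    """Full annotation of one rCRS position."""

    position: int
    top_level: str  # "CR" | "coding" | "non_coding"
    gene: Optional[str]  # gene/rRNA/tRNA symbol, None in CR / non-coding
    hv: str  # "HV1" | "HV2" | "HV3" | "no-HV" | "n/a"
    functional_domain: str  # "ETAS" | "CSB" | "LSP" | "CENTRAL_DOMAIN" | "none"
    structure_elements: tuple[str, ...]
    homopolymer: bool


@dataclass
class RegionAtlas:
    """Interval atlas over the circular mitochondrial reference."""

    genome_length: int = RCRS_LENGTH
    intervals: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._by_category: dict[str, list[Interval]] = {}
        for iv in self.intervals:
            self._by_category.setdefault(iv.category, []).append(iv)
        self._validate()

    # -- construction -------------------------------------------------

    def _validate(self) -> None:
        if not self.intervals:
            raise AtlasError("atlas contains no intervals")
        seen: set[tuple[str, str]] = set()
        for iv in self.intervals:
            if iv.category not in CATEGORIES:
                raise AtlasError(f"unknown category {iv.category!r} for {iv.label!r}")
            for c in (iv.start, iv.end):
                if not (1 <= c <= self.genome_length):
                    raise AtlasError(
                        f"interval {iv.label!r} coordinate {c} outside "
                        f"1..{self.genome_length}"
                    )
            key = (iv.category, iv.label)
            if key in seen:
                raise AtlasError(f"duplicate label {iv.label!r} in category {iv.category!r}")
            seen.add(key)
        self._validate_top_level_partition()
        self._validate_cr_subsets()

    def _validate_top_level_partition(self) -> None:
        cover = [0] * (self.genome_length + 1)
        for cat in TOP_LEVEL_CATEGORIES:
            for iv in self._by_category.get(cat, []):
                for p in iv.positions(self.genome_length):
                    cover[p] += 1
        uncovered = [p for p in range(1, self.genome_length + 1) if cover[p] == 0]
        doubled = [p for p in range(1, self.genome_length + 1) if cover[p] > 1]
        if uncovered:
            raise AtlasError(
                f"top-level partition leaves {len(uncovered)} positions "
                f"uncovered (first: {uncovered[:5]})"
            )
        if doubled:
            raise AtlasError(
                f"overlapping top-level intervals at {len(doubled)} positions "
                f"(first: {doubled[:5]})"
            )

    def _validate_cr_subsets(self) -> None:
        cr = self._by_category.get("CR", [])
        if not cr:
            return
        for cat in ("HV", "functional_domain"):
            for iv in self._by_category.get(cat, []):
                for p in iv.positions(self.genome_length):
                    if not any(c.contains(p) for c in cr):
                        raise AtlasError(
                            f"{cat} interval {iv.label!r} leaves the CR at {p}"
                        )

    # -- queries ------------------------------------------------------

    def _check_position(self, position: int) -> None:
        if not (1 <= position <= self.genome_length):
            raise ValueError(
                f"position {position} outside 1..{self.genome_length}"
            )

    def is_homopolymer(self, position: int) -> bool:
        """True iff *position* lies in a bundled homopolymeric tract."""
        self._check_position(position)
        return any(
            iv.contains(position) for iv in self._by_category.get("homopolymer", [])
        )

    def assign(self, position: int) -> RegionAssignment:
        """Deterministically annotate one position."""
        self._check_position(position)

        in_cr = any(iv.contains(position) for iv in self._by_category.get("CR", []))
        gene = None
        top_level = "non_coding"
        if in_cr:
            top_level = "CR"
        else:
            for cat in ("gene", "rRNA", "tRNA"):
                for iv in self._by_category.get(cat, []):
                    if iv.contains(position):
                        gene = iv.label
                        top_level = "coding"
                        break
                if gene:
                    break

        if in_cr:
            hv = "no-HV"
            for iv in self._by_category.get("HV", []):
                if iv.contains(position):
                    hv = iv.label
                    break
            domain = "none"
            for iv in self._by_category.get("functional_domain", []):
                if iv.contains(position):
                    domain = _domain_group(iv.label)
                    break
        else:
            hv = "n/a"
            domain = "none"

        elements = tuple(
            sorted(
                iv.label.removeprefix("SSE_")
                for iv in self._by_category.get("structure_element", [])
                if iv.contains(position)
            )
        )
        return RegionAssignment(
            position=position,
            top_level=top_level,
            gene=gene,
            hv=hv,
            functional_domain=domain,
            structure_elements=elements,
            homopolymer=self.is_homopolymer(position),
        )

    def gene_category(self, gene: str) -> Optional[str]:
        """Category ("gene"/"rRNA"/"tRNA") of a coding-locus label."""
        for cat in ("gene", "rRNA", "tRNA"):
            for iv in self._by_category.get(cat, []):
                if iv.label == gene:
                    return cat
        return None

    def intervals_of(self, category: str) -> list[Interval]:
        return list(self._by_category.get(category, []))


def _domain_group(label: str) -> str:
    for prefix, group in _DOMAIN_GROUPS.items():
        if label.startswith(prefix):
            return group
    return "none"


# -- loading ----------------------------------------------------------


def load_atlas(
    path: Optional[str | Path] = None,
    *,
    dialect: str = "native",
    genome_length: int = RCRS_LENGTH,
) -> RegionAtlas:
    """Load an atlas from a table, or the bundled default if *path* is None.

    Parameters
    ----------
    path:
        TSV file.  ``dialect="native"`` expects columns
        label/category/start/end with 1-based inclusive coordinates.
        ``dialect="bed"`` expects BED-like columns
        chrom/start/end/label/category with 0-based half-open
        coordinates, converted on load.
    """
    if path is None:
        ref = importlib.resources.files("mitocohort.data") / "rcrs_atlas.tsv"
        with importlib.resources.as_file(ref) as p:
            return load_atlas(p, dialect="native", genome_length=genome_length)

    intervals: list[Interval] = []
    with open(path) as fh:
        header: Optional[list[str]] = None
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if dialect == "native":
                if header is None and fields[0] == "label":
                    header = fields
                    continue
                label, category, start, end = fields[:4]
                intervals.append(Interval(label, category, int(start), int(end)))
            elif dialect == "bed":
                _chrom, start, end, label, category = fields[:5]
                s, e = int(start) + 1, int(end)  # 0-based half-open -> 1-based incl.
                intervals.append(Interval(label, category, s, e))
            else:
                raise AtlasError(f"unknown atlas dialect {dialect!r}")
    if not intervals:
        raise AtlasError(f"no intervals found in {path}")
    return RegionAtlas(genome_length=genome_length, intervals=intervals)
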