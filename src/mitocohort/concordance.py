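"""Five-level concordance scoring of categorical pathogenicity predictions.

Heterogeneous predictor outputs are first simplified to deleterious (D),
benign (B) or NA via editable lexicons, then condensed per variant:

* ``+2`` — D from at least 4 predictors (no opposing B call)
* ``+1`` — D from 1-3 predictors (no opposing B call)
* ``0``  — no D/B call at all, or conflicting D and B calls
* ``-1`` — B from 1-3 predictors (no opposing D call)
* ``-2`` — B from at least 4 predictors (no opposing D call)

A profile containing both D and B calls is treated as conflicting (score
0); the +-1/+-2 levels therefore require unanimity among non-NA calls.
Set ``conflicts_are_zero=False`` to instead score the majority sign.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import yaml


@dataclass(frozen=True)
class Lexicons:
    deleterious: frozenset[str]
    benign: frozenset[str]


@dataclass(frozen=True)
class SimplifiedCall:
    predictor: str
    simplified: str  # "D" | "B" | "NA"


@dataclass(frozen=True)
class ConcordanceScore:
    value: int
    n_d: int
    n_b: int


def _normalize(label: str) -> str:
    return " ".join(label.strip().lower().replace("_", " ").replace("-", " ").split())


def load_lexicons(path: Optional[str | Path] = None) -> Lexicons:
    """Load D/B label lexicons (bundled defaults when *path* is None)."""
    if path is None:
        ref = importlib.resources.files("mitocohort.data") / "lexicons.yaml"
        with importlib.resources.as_file(ref) as p:
            return load_lexicons(p)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return Lexicons(
        deleterious=frozenset(_normalize(x) for x in raw["deleterious"]),
        benign=frozenset(_normalize(x) for x in raw["benign"]),
    )


DEFAULT_LEXICONS = load_lexicons()


def simplify_label(
    predictor: str, raw: str, lexicons: Lexicons = DEFAULT_LEXICONS
) -> SimplifiedCall:
    """Map one raw categorical label to D, B or NA."""
    norm = _normalize(raw or "")
    if norm in lexicons.deleterious:
        simplified = "D"
    elif norm in lexicons.benign:
        simplified = "B"
    else:
        simplified = "NA"
    return SimplifiedCall(predictor=predictor, simplified=simplified)


def score_counts(n_d: int, n_b: int, conflicts_are_zero: bool = True) -> int:
    """Concordance score from D/B counts."""
    if n_d < 0 or n_b < 0:
        raise ValueError("counts must be non-negative")
    if conflicts_are_zero and n_d >= 1 and n_b >= 1:
        return 0
    if not conflicts_are_zero:
        # majority-sign variant: score the dominant class, ties conflict
        if n_d == n_b:
            return 0
        n_win = max(n_d, n_b)
        sign = 1 if n_d > n_b else -1
        return sign * (2 if n_win >= 4 else 1)
    if n_d >= 4:
        return 2
    if 1 <= n_d <= 3:
        return 1
    if n_b >= 4:
        return -2
    if 1 <= n_b <= 3:
        return -1
    return 0


def score_variant(
    calls: Sequence[SimplifiedCall], conflicts_are_zero: bool = True
) -> ConcordanceScore:
    """Condense a variant's simplified predictor calls into one score."""
    n_d = sum(1 for c in calls if c.simplified == "D")
    n_b = sum(1 for c in calls if c.simplified == "B")
    return ConcordanceScore(
        value=score_counts(n_d, n_b, conflicts_are_zero), n_d=n_d, n_b=n_b
    )


def score_table(
    raw_labels: Iterable[dict],
    lexicons: Lexicons = DEFAULT_LEXICONS,
    id_fields: Sequence[str] = ("variant_id",),
) -> list[dict]:
    """Score rows of {id fields..., predictor: raw label, ...} mappings.

    Every key not in *id_fields* is treated as a predictor column.
    Returns the rows augmented with n_D, n_B and score.
    """
    out = []
    for row in raw_labels:
        calls = [
            simplify_label(k, str(v) if v is not None else "", lexicons)
            for k, v in row.items()
            if k not in id_fields
        ]
        score = score_variant(calls)
        rec = {k: row[k] for k in id_fields if k in row}
        rec.update(n_D=score.n_d, n_B=score.n_b, score=score.value)
        out.append(rec)
    return out
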