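"""Band-pattern filtering, dissimilarity scoring, and enzyme ranking.

The dissimilarity between two lanes is a shortest-path-root measure in
log-band space: band lengths are log10-transformed, the two descending
band lists are aligned by a monotone matching (a dynamic program over
match / gap moves), a matched pair costs the squared log-length
difference, an unmatched band costs gamma squared, and the dissimilarity
is the square root of the minimal total cost. gamma is the gap penalty
in log10-bp units: with the default 0.5, leaving a band unmatched costs
as much as matching it to a band half a decade away.

For 2-3 lanes the enzyme's aggregate score is the MINIMUM over all
pairwise dissimilarities — a diagnostic digest must separate every
identity from every other, so the least-distinguishable pair bounds its
utility.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from .digestion import BandPattern, SequenceRecord, digest
from .enzyme_db import EnzymeRecord

__all__ = [
    "BandPattern",
    "FilterSettings",
    "EnzymeReport",
    "apply_filters",
    "pattern_dissimilarity",
    "aggregate_score",
    "rank_enzymes",
    "report_tsv",
]


@dataclass(frozen=True)
class FilterSettings:
    """Filter and scoring settings.

    min_frags/max_frags: acceptable fragment count per lane (too few is
    not a pattern, too many is not distinguishable). min_len/max_len:
    fragment-length window in bp; fragments outside it are dropped
    before counting and scoring. cutoff_len: gel bottom cutoff in bp.
    gamma: gap penalty of the dissimilarity measure, log10-bp units.
    """

    min_frags: int = 2
    max_frags: int = 10
    min_len: int = 50
    max_len: int = 10_000
    cutoff_len: int = 50
    gamma: float = 0.5

    def __post_init__(self) -> None:
        if not (1 <= self.min_frags <= self.max_frags):
            raise ValueError("need 1 <= min_frags <= max_frags")
        if not (1 <= self.min_len <= self.max_len):
            raise ValueError("need 1 <= min_len <= max_len")
        if self.cutoff_len < 1:
            raise ValueError("cutoff_len must be >= 1")
        if not self.gamma > 0:
            raise ValueError("gamma must be > 0")


@dataclass(frozen=True)
class EnzymeReport:
    """Per-enzyme result: one (filtered) lane per input sequence, overall
    pass/fail, and the aggregate dissimilarity score (None if failed)."""

    enzyme: EnzymeRecord
    patterns: tuple[BandPattern, ...]
    passed: bool
    score: float | None = None


def apply_filters(
    pattern: BandPattern, settings: FilterSettings
) -> tuple[BandPattern, bool]:
    """Drop fragments outside [min_len, max_len], then check that the
    retained count lies in [min_frags, max_frags]."""
    kept = tuple(
        x for x in pattern.lengths if settings.min_len <= x <= settings.max_len
    )
    retained = replace(pattern, lengths=kept)
    passed = settings.min_frags <= len(kept) <= settings.max_frags
    return retained, passed


def pattern_dissimilarity(
    a: BandPattern | tuple[int, ...],
    b: BandPattern | tuple[int, ...],
    gamma: float = 0.5,
) -> float:
    """Shortest-path-root dissimilarity between two band patterns.

    Dynamic program over the descending log10 band lists: C[i][j] =
    min(match, gap-in-a, gap-in-b) with match cost (x_i - y_j)^2 and gap
    cost gamma^2; returns sqrt(C[m][n]). Symmetric, non-negative, zero
    iff the patterns are identical multisets.
    """
    xs = _log_bands(a)
    ys = _log_bands(b)
    m, n = len(xs), len(ys)
    g2 = gamma * gamma
    prev = [j * g2 for j in range(n + 1)]
    for i in range(1, m + 1):
        cur = [i * g2] + [0.0] * n
        xi = xs[i - 1]
        for j in range(1, n + 1):
            d = xi - ys[j - 1]
            cur[j] = min(prev[j - 1] + d * d, prev[j] + g2, cur[j - 1] + g2)
        prev = cur
    return math.sqrt(prev[n])


def _log_bands(p: BandPattern | tuple[int, ...]) -> list[float]:
    lengths = p.lengths if isinstance(p, BandPattern) else tuple(
        sorted(p, reverse=True)
    )
    return [math.log10(x) for x in lengths]


def aggregate_score(
    patterns: list[BandPattern] | tuple[BandPattern, ...], gamma: float = 0.5
) -> float:
    """Minimum pairwise dissimilarity over 2-3 lanes."""
    if len(patterns) < 2:
        raise ValueError("aggregate score needs at least 2 patterns")
    return min(
        pattern_dissimilarity(patterns[i], patterns[j], gamma)
        for i in range(len(patterns))
        for j in range(i + 1, len(patterns))
    )


def rank_enzymes(
    seqs: list[SequenceRecord],
    enzymes: list[EnzymeRecord],
    settings: FilterSettings | None = None,
    sort: str = "dissimilarity",
    reverse: bool = False,
) -> list[EnzymeReport]:
    """Digest every (sequence, enzyme) pair, filter, score, and order.

    Passing enzymes always precede failing ones. Within the passing
    group, sort="dissimilarity" orders by descending score (most
    distinct pattern first, name breaking ties) and sort="name" orders
    alphabetically (case-insensitive); the failing group is always
    alphabetical. ``reverse`` flips the order within each group.
    """
    if not 2 <= len(seqs) <= 3:
        raise ValueError(
            f"need 2 or 3 input sequences for a differential digest, got {len(seqs)}"
        )
    if not enzymes:
        raise ValueError("empty enzyme list")
    if sort not in ("dissimilarity", "name"):
        raise ValueError(f"unknown sort mode {sort!r}")
    settings = settings or FilterSettings()

    reports = []
    for enz in enzymes:
        filtered = []
        all_passed = True
        for rec in seqs:
            pat, ok = apply_filters(digest(rec, enz), settings)
            filtered.append(pat)
            all_passed = all_passed and ok
        score = (
            aggregate_score(filtered, settings.gamma) if all_passed else None
        )
        reports.append(
            EnzymeReport(enz, tuple(filtered), passed=all_passed, score=score)
        )

    passing = [r for r in reports if r.passed]
    failing = [r for r in reports if not r.passed]
    if sort == "dissimilarity":
        passing.sort(key=lambda r: (-r.score, r.enzyme.name.lower()))
    else:
        passing.sort(key=lambda r: r.enzyme.name.lower())
    failing.sort(key=lambda r: r.enzyme.name.lower())
    if reverse:
        passing.reverse()
        failing.reverse()
    return passing + failing


def report_tsv(reports: list[EnzymeReport], seq_ids: list[str]) -> str:
    """Serialize ranked reports as TSV: enzyme, passed, score (6 d.p.,
    empty if failed), then one semicolon-joined fragment list per lane."""
    header = ["enzyme", "passed", "score"] + list(seq_ids)
    lines = ["\t".join(header)]
    for r in reports:
        row = [
            r.enzyme.name,
            "true" if r.passed else "false",
            f"{r.score:.6f}" if r.score is not None else "",
        ]
        row += [";".join(str(x) for x in p.lengths) for p in r.patterns]
        lines.append("\t".join(row))
    return "\n".join(lines) + "\n"
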