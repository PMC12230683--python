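"""Independent brute-force oracles, kept deliberately naive and separate
from the package implementation."""

from __future__ import annotations

import math

IUPAC = {
    "A": set("A"), "C": set("C"), "G": set("G"), "T": set("T"),
    "R": set("AG"), "Y": set("CT"), "S": set("CG"), "W": set("AT"),
    "K": set("GT"), "M": set("AC"), "B": set("CGT"), "D": set("AGT"),
    "H": set("ACT"), "V": set("ACG"), "N": set("ACGT"),
}

COMP = {
    "A": "T", "T": "A", "C": "G", "G": "C", "R": "Y", "Y": "R",
    "S": "S", "W": "W", "K": "M", "M": "K", "B": "V", "V": "B",
    "D": "H", "H": "D", "N": "N",
}


def naive_match_at(target: str, site: str, pos: int) -> bool:
    if pos < 0 or pos + len(site) > len(target):
        return False
    return all(target[pos + i] in IUPAC[c] for i, c in enumerate(site))


def naive_scan(target: str, site: str) -> list[int]:
    """Character-set scan at every start position (overlaps included)."""
    return [
        p for p in range(len(target) - len(site) + 1)
        if naive_match_at(target, site, p)
    ]


def naive_revcomp(seq: str) -> str:
    return "".join(COMP[c] for c in reversed(seq))


def naive_cut_sites(
    seq: str, site: str, cut_top: int, cut_bottom: int, circular: bool
) -> list[int]:
    """Windowed both-strand scan, written straight from the rules:
    plus-strand window at w cuts at w + cut_top; minus-strand window at
    w cuts at w + len(site) - cut_bottom; circular coordinates wrap,
    linear cuts outside (0, n) are dropped."""
    n, L = len(seq), len(site)
    doubled = seq * (2 + L // max(n, 1)) if circular else seq
    starts = range(n) if circular else range(n - L + 1)
    rc = naive_revcomp(site)
    cuts = set()
    for w in starts:
        for s, rel in ((site, cut_top), (rc, L - cut_bottom)):
            if naive_match_at(doubled, s, w):
                c = w + rel
                if circular:
                    cuts.add(c % n)
                elif 1 <= c <= n - 1:
                    cuts.add(c)
    return sorted(cuts)


def brute_dissimilarity(xs: tuple[int, ...], ys: tuple[int, ...], gamma: float) -> float:
    """Enumerate every monotone alignment of the two descending band
    lists and take the minimal root cost."""
    lx = tuple(math.log10(v) for v in sorted(xs, reverse=True))
    ly = tuple(math.log10(v) for v in sorted(ys, reverse=True))
    g2 = gamma * gamma

    def rec(i: int, j: int) -> float:
        if i == len(lx) and j == len(ly):
            return 0.0
        best = math.inf
        if i < len(lx) and j < len(ly):
            best = min(best, (lx[i] - ly[j]) ** 2 + rec(i + 1, j + 1))
        if i < len(lx):
            best = min(best, g2 + rec(i + 1, j))
        if j < len(ly):
            best = min(best, g2 + rec(i, j + 1))
        return best

    return math.sqrt(rec(0, 0))
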