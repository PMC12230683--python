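"""Cut-site search and fragment-length computation for one enzyme on one
molecule.

Coordinates are 0-based bond indices: cut position ``p`` means the
phosphodiester bond 5' of the base at index ``p`` is cleaved on the top
strand. Only top-strand cut positions define fragment lengths — an
agarose gel resolves duplex length, so sticky-end overhangs are not
bookkept. Circular molecules are handled by prefix extension: the scan
runs over the sequence extended by its first ``len(site) - 1`` bases and
every resulting cut coordinate is reduced modulo the sequence length.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass
from enum import Enum

from .enzyme_db import (
    EnzymeRecord,
    IUPAC_SETS,
    InvalidIUPACError,
    iupac_to_matcher,
    reverse_complement,
)

logger = logging.getLogger(__name__)

_STRIP_RE = re.compile(r"[\s\d]+")


class Topology(str, Enum):
    LINEAR = "linear"
    CIRCULAR = "circular"


def clean_sequence(raw: str) -> str:
    """Normalize raw sequence text: drop whitespace/digits, uppercase,
    validate against the IUPAC alphabet."""
    seq = _STRIP_RE.sub("", raw).upper()
    for ch in seq:
        if ch not in IUPAC_SETS:
            raise InvalidIUPACError(f"invalid sequence character {ch!r}")
    return seq


@dataclass(frozen=True)
class SequenceRecord:
    """One input molecule: id, normalized sequence, topology flag."""

    id: str
    seq: str
    topology: Topology = Topology.LINEAR

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if len(self.seq) < 1:
            raise ValueError(f"{self.id}: empty sequence")

    @classmethod
    def from_raw(
        cls, id: str, raw: str, topology: Topology | str = Topology.LINEAR
    ) -> "SequenceRecord":
        return cls(id=id, seq=clean_sequence(raw), topology=Topology(topology))

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class CutSiteList:
    """Deduplicated, strictly increasing top-strand cut coordinates."""

    positions: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.positions, self.positions[1:])):
            raise ValueError("cut positions must be strictly increasing")

    def __len__(self) -> int:
        return len(self.positions)


@dataclass(frozen=True)
class BandPattern:
    """Multiset of fragment lengths (bp), one gel lane; sorted descending."""

    lengths: tuple[int, ...]
    source_id: str = ""
    uncut: bool = False

    def __post_init__(self) -> None:
        if any(x < 1 for x in self.lengths):
            raise ValueError("fragment lengths must be >= 1 bp")
        object.__setattr__(
            self, "lengths", tuple(sorted(self.lengths, reverse=True))
        )

    def __len__(self) -> int:
        return len(self.lengths)


def find_cut_sites(rec: SequenceRecord, enz: EnzymeRecord) -> CutSiteList:
    """All top-strand cut positions of ``enz`` on ``rec``, both strands.

    Overlapping recognition windows are all found (step-1 scan). On a
    linear molecule a cut whose coordinate falls on or beyond either end
    cleaves nothing and is dropped; on a circular molecule coordinates
    wrap modulo the sequence length.
    """
    n = len(rec.seq)
    L = len(enz.site)
    circular = rec.topology is Topology.CIRCULAR

    if circular:
        if n >= L:
            scan_seq = rec.seq + rec.seq[: L - 1]
        else:
            reps = math.ceil((n + L - 1) / n)
            scan_seq = (rec.seq * reps)[: n + L - 1]
    else:
        scan_seq = rec.seq

    plus = iupac_to_matcher(enz.site)
    minus = iupac_to_matcher(reverse_complement(enz.site))

    positions: set[int] = set()
    for matcher, rel_cut in (
        (plus, enz.cut_top),
        # minus-strand window at top-strand coord w: the bottom-strand cut
        # offset counts from the window's 3' (right) end in top coordinates.
        (minus, L - enz.cut_bottom),
    ):
        for w in matcher.scan(scan_seq):
            if circular and w >= n:
                continue
            cut = w + rel_cut
            if circular:
                positions.add(cut % n)
            elif 1 <= cut <= n - 1:
                positions.add(cut)
            else:
                logger.debug(
                    "%s window at %d on %s: cut %d falls off the linear end",
                    enz.name,
                    w,
                    rec.id,
                    cut,
                )
    return CutSiteList(tuple(sorted(positions)))


def fragments_from_cuts(
    cuts: CutSiteList, length: int, topology: Topology | str
) -> list[int]:
    """Fragment lengths implied by cut positions.

    Linear with k cuts -> k+1 fragments; circular with k >= 1 cuts -> k
    fragments including the wraparound piece; circular (or linear) with
    no cuts -> the full-length molecule. Fragments always sum to
    ``length``.
    """
    topology = Topology(topology)
    pos = list(cuts.positions)
    if any(p >= length or p < 0 for p in pos):
        raise ValueError("cut position outside [0, length)")
    if not pos:
        return [length]
    if topology is Topology.LINEAR:
        bounds = [0] + pos + [length]
        return [b - a for a, b in zip(bounds, bounds[1:])]
    frags = [b - a for a, b in zip(pos, pos[1:])]
    frags.append(length - pos[-1] + pos[0])
    return frags


def digest(rec: SequenceRecord, enz: EnzymeRecord) -> BandPattern:
    """Digest one molecule with one enzyme: cut-site search composed with
    fragment-length computation; fragments sorted descending."""
    cuts = find_cut_sites(rec, enz)
    frags = fragments_from_cuts(cuts, len(rec.seq), rec.topology)
    return BandPattern(
        lengths=tuple(frags), source_id=rec.id, uncut=len(cuts) == 0
    )
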