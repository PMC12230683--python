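"""Restriction-enzyme table parsing and IUPAC recognition-site matching.

Enzyme tables are a small TSV dialect (``name<TAB>site-with-cut-notation``):
a caret marks the top-strand cut inside the recognition site
(``G^AATTC``), while Type IIS-like outside cutters carry a ``(n/m)``
suffix giving the top/bottom cleavage offsets past the 3' end of the
site (``GGTCTC(1/5)``). Recognition sites may contain IUPAC ambiguity
codes; matching expands each code to its nucleotide set and scans both
strands (the caller supplies the reverse complement for the minus
strand).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from importlib import resources

logger = logging.getLogger(__name__)

# IUPAC ambiguity codes -> nucleotide sets. Sites may use any code; input
# (target) sequences only ever match on concrete A/C/G/T characters.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

_OUTSIDE_CUT_RE = re.compile(r"^([A-Za-z]+)\((-?\d+)/(-?\d+)\)$")

BUNDLED_TABLE = "enzymes_common.tsv"


class EnzymeTableError(ValueError):
    """Raised for malformed enzyme-table input."""


class InvalidIUPACError(ValueError):
    """Raised when a sequence contains a character outside the IUPAC codes."""


@dataclass(frozen=True)
class EnzymeRecord:
    """One restriction enzyme.

    ``cut_top``/``cut_bottom`` are bond offsets from the 5' end of the
    recognition window; they may be negative or exceed the site length
    for outside cutters.
    """

    name: str
    site: str
    cut_top: int
    cut_bottom: int

    def __post_init__(self) -> None:
        if not self.name:
            raise EnzymeTableError("enzyme name must be non-empty")
        if len(self.site) < 4:
            raise EnzymeTableError(
                f"{self.name}: recognition site {self.site!r} shorter than 4 bp"
            )
        for ch in self.site:
            if ch not in IUPAC_SETS:
                raise InvalidIUPACError(
                    f"{self.name}: invalid IUPAC code {ch!r} in site {self.site!r}"
                )


def reverse_complement(seq: str) -> str:
    """Reverse complement of an IUPAC string (ambiguity codes included)."""
    seq = seq.upper()
    for ch in seq:
        if ch not in IUPAC_SETS:
            raise InvalidIUPACError(f"invalid IUPAC character {ch!r}")
    return seq.translate(_COMPLEMENT)[::-1]


class SiteMatcher:
    """Scanner reporting every start position of an IUPAC site in a target.

    Overlapping occurrences are all reported (step-1 scan via a
    zero-width lookahead regex). Non-ACGT characters in the *target*
    never match any site character, so runs of N in an input sequence
    cannot produce spurious cut sites.
    """

    def __init__(self, site: str):
        site = site.upper()
        if not site:
            raise InvalidIUPACError("empty recognition site")
        parts = []
        for ch in site:
            try:
                allowed = IUPAC_SETS[ch]
            except KeyError:
                raise InvalidIUPACError(f"invalid IUPAC code {ch!r}") from None
            parts.append("[" + "".join(sorted(allowed)) + "]")
        self.site = site
        self._regex = re.compile("(?=" + "".join(parts) + ")")

    def __len__(self) -> int:
        return len(self.site)

    def scan(self, target: str) -> list[int]:
        """All 0-based start positions where the site matches ``target``."""
        return [m.start() for m in self._regex.finditer(target)]

    def matches_at(self, target: str, pos: int) -> bool:
        if pos < 0 or pos + len(self.site) > len(target):
            return False
        return all(
            target[pos + i] in IUPAC_SETS[c] for i, c in enumerate(self.site)
        )


def iupac_to_matcher(site: str) -> SiteMatcher:
    """Compile an IUPAC recognition site into a :class:`SiteMatcher`."""
    return SiteMatcher(site)


def _parse_site_field(name: str, field: str, lineno: int) -> EnzymeRecord:
    field = field.strip()
    m = _OUTSIDE_CUT_RE.match(field)
    if m:
        site = m.group(1).upper()
        n, cut_m = int(m.group(2)), int(m.group(3))
        return EnzymeRecord(name, site, len(site) + n, len(site) + cut_m)
    if "^" in field:
        if field.count("^") != 1:
            raise EnzymeTableError(
                f"line {lineno}: more than one caret in site {field!r}"
            )
        caret = field.index("^")
        site = field.replace("^", "").upper()
        return EnzymeRecord(name, site, caret, len(site) - caret)
    site = field.upper()
    # No cut notation: assume a midpoint cut. Band lengths shift by at most
    # len(site)/2 bp, which is invisible on an agarose gel.
    mid = len(site) // 2
    logger.warning(
        "enzyme %s has no cut notation; assuming midpoint cut at %d", name, mid
    )
    return EnzymeRecord(name, site, mid, len(site) - mid)


def parse_enzyme_table(text: str) -> list[EnzymeRecord]:
    """Parse the TSV enzyme-table dialect into :class:`EnzymeRecord` objects.

    Lines starting with ``#`` are comments; blank lines are ignored.
    Raises :class:`EnzymeTableError` with a line number on malformed
    lines, invalid IUPAC characters, or duplicate enzyme names.
    """
    records: list[EnzymeRecord] = []
    seen: set[str] = set()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise EnzymeTableError(
                f"line {lineno}: expected 2 tab-separated columns, got {len(fields)}"
            )
        name, site_field = fields[0].strip(), fields[1]
        if name in seen:
            raise EnzymeTableError(f"line {lineno}: duplicate enzyme name {name!r}")
        try:
            rec = _parse_site_field(name, site_field, lineno)
        except InvalidIUPACError as exc:
            raise EnzymeTableError(f"line {lineno}: {exc}") from exc
        seen.add(name)
        records.append(rec)
    return records


def serialize_enzyme_table(records: list[EnzymeRecord]) -> str:
    """Serialize records back to the TSV dialect (inverse of parsing)."""
    lines = []
    for r in records:
        L = len(r.site)
        if 0 <= r.cut_top <= L and r.cut_bottom == L - r.cut_top:
            lines.append(f"{r.name}\t{r.site[: r.cut_top]}^{r.site[r.cut_top :]}")
        else:
            lines.append(f"{r.name}\t{r.site}({r.cut_top - L}/{r.cut_bottom - L})")
    return "\n".join(lines) + "\n"


def load_bundled_table() -> list[EnzymeRecord]:
    """Load the bundled table of common commercially available enzymes."""
    text = (
        resources.files("diffdigest").joinpath("data", BUNDLED_TABLE).read_text()
    )
    return parse_enzyme_table(text)
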