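# Methods

## Digest model

A restriction enzyme is specified by an IUPAC recognition site and two
integer cut offsets in the coordinate frame of the recognition window:
`cut_top` for the top strand and `cut_bottom` for the bottom strand,
both counted in bonds from the window's 5′ end. Table notation follows
the REBASE-derived convention: a caret inside the site (`G^AATTC` →
`cut_top = 1`, `cut_bottom = len − 1 = 5`) for Type IIP enzymes, and a
`(n/m)` suffix (`GGTCTC(1/5)` → `cut_top = len + 1`,
`cut_bottom = len + 5`) for outside cutters. An entry with neither
notation is accepted with a midpoint cut and a logged warning rather
than rejected: the resulting band lengths differ from the truth by at
most half a site length, which no agarose gel resolves.

Matching uses one compiled character-class regex per strand wrapped in
a zero-width lookahead, so the scan advances one base at a time and
overlapping windows are all found. Global regex matching would skip a
window that overlaps the previous match; completeness was chosen over
replicating that behaviour. IUPAC codes are expanded only on the
*site* side: a non-ACGT character in an input sequence matches nothing,
so a run of Ns in a draft sequence can never fabricate cut sites.

All coordinates are 0-based bond indices: cut position *p* cleaves the
bond 5′ of base *p* on the top strand. Only top-strand cut positions
define fragment boundaries — a gel measures duplex length, and
bookkeeping sticky-end overhangs would change bands by at most a few
bases (see Limitations for the one observable consequence). A
plus-strand window at *w* cuts at `w + cut_top`; a minus-strand window
(found with the reverse-complemented site) cuts at
`w + L − cut_bottom`, which for palindromic sites coincides with the
plus-strand cut, so each palindromic site yields one position.

Circular molecules are scanned over the sequence extended by its first
`L − 1` bases (repeating the whole sequence when it is shorter than the
site); window starts are restricted to the original length and every
cut coordinate is reduced modulo the length, then deduplicated. This is
behaviourally equivalent to concatenating "last match to end" with
"start to first match" but easier to reason about. On a linear molecule
a cut landing on or beyond either terminus (possible for outside
cutters, or a caret at bond 0) cleaves nothing and is dropped with a
debug log line; consequently cut positions on linear molecules lie in
`[1, len − 1]` while position 0 remains meaningful for circular ones
(a single cut at the origin linearizes the plasmid into one full-length
band).

Fragment computation is pure arithmetic: *k* cuts give *k + 1*
fragments on a linear molecule and *k* on a circular one (successive
differences plus the wraparound piece); zero cuts give the full-length
molecule flagged uncut. The sum of fragments always equals the
molecule length — this conservation law is property-tested over a
thousand random digests.

## Filtering

Defaults: fragment count within 2–10 and fragment length within
50–10 000 bp. Fewer than two fragments is not a pattern; too many
fragments blur into unreadable lanes; fragments outside the length
window are invisible or unresolved on a standard gel. Length filtering
is applied per lane *before* counting and before scoring, so the score
always refers to what the rendered gel actually shows. An enzyme
passes only if every input lane passes. Failing enzymes stay in the
report (sorted after all passing ones) so the user can see why each
was excluded.

## Dissimilarity

Band lengths are log₁₀-transformed — matching how they migrate and how
the eye reads a gel — and the two descending band lists are aligned by
a dynamic program over match / gap moves. A matched pair costs the
squared log-length difference; an unmatched band costs γ². The
dissimilarity is the square root of the minimal total cost: the
shortest monotone matching path through log-band space, with the root
restoring the units of log-length. This measure is defined here,
self-contained; it is of the shortest-path-root family but not claimed
to be bit-identical to any previously published variant.

γ defaults to 0.5 log₁₀ units: leaving a band unmatched costs as much
as matching it to a band half a decade away. The measure is symmetric,
non-negative, zero exactly on identical filtered patterns, and
monotone non-decreasing in γ; all four properties are tested, and the
DP is checked against exhaustive enumeration of all monotone
alignments for every pattern pair with ≤ 6 bands per lane. One
consequence of the gap/match trade-off worth knowing: two single-band
lanes a full decade apart score √(2γ²) ≈ 0.71 at the default γ, not
1.0, because deleting both bands is cheaper than matching them.

For three input lanes the enzyme's aggregate score is the minimum over
the three pairwise dissimilarities: a diagnostic digest must separate
*every* identity from every other, so the least-separable pair is what
limits the enzyme. Ties in the ranking break alphabetically for
deterministic output, and the pass/fail grouping applies in both sort
modes (passing enzymes always precede failing ones; `reverse` flips
order within each group) so a failing enzyme can never displace a
usable one from the top of the list.

## Gel rendering

Vertical position is linear in log₁₀ length between the scale top
(default 10 000 bp, raised automatically to the largest band or ladder
rung so nothing is clipped into invisibility) and the cutoff (default
50 bp): `y = (log T − log x) / (log T − log C)`, clamped to [0, 1].
Bands shorter than the cutoff run off the gel and are not drawn; bands
longer than the scale top sit at the well. Topology-dependent mobility
(supercoiled vs relaxed vs linear) is deliberately not modelled; the
simulation targets the digested (linear-fragment) end state.

Bands in one lane closer than 1 % of the gel height merge into a
single band of doubled thickness carrying a `data-multiplicity`
attribute — mimicking how close bands fuse on a real gel — while the
report TSV keeps every exact length. The default ladder is a typical
commercial 1 kb ladder (100–10 000 bp, 13 rungs). Rendering is a pure
function: identical input yields byte-identical SVG.

## Synthetic fixtures

`generate_test_plasmid` draws a uniform ACGT background from a seeded
PCG64 generator and writes recognition sites verbatim at requested
non-overlapping positions (ambiguity codes are realized to concrete
bases with the same generator). After writing, each planted site is
re-verified in place by a brute-force scan, and accidental extra
occurrences of the planted sites — expected at rate ≈ length / 4^k per
strand for a k-bp site — are logged rather than forbidden, since real
plasmids also carry incidental sites. The generator emulates site
placement and topology only: real plasmids have biased base
composition, repeats, and functional elements, so passing tests
demonstrate the correctness of the digest arithmetic and ranking
logic, not performance on any particular vector family.

Test and validation problem sizes — molecules of tens of bases to a
few kilobases, 50–1000 random digests per property, 3 kb plasmid pairs
for ranking recovery — were chosen so the full suite illustrates every
code path in a few seconds; all the properties checked are
size-independent.

## Limitations

- **Linear terminal fragments are strand-convention-dependent for
  staggered cutters.** Reverse-complementing a sequence maps the cut
  set to its reflection shifted uniformly by the overhang length
  δ = `cut_bottom − cut_top`. All circular digests and all interior
  fragments of linear digests are therefore exactly invariant under
  strand flip, but the two *terminal* fragments of a linear digest
  shift by exactly ±δ (≤ a few bp; e.g. 4 for EcoRI) — physically,
  because a terminal fragment's top and bottom strands genuinely have
  different lengths and a single integer must be reported. No integer
  cut convention removes this: a blunt-equivalent midpoint would
  restore the symmetry only for enzymes with even `cut_top +
  cut_bottom` and places the boundary at a half-bond for the others
  (AlwNI, EcoNI). The exact terminal-shift law is unit-tested; the
  strict all-enzyme linear invariance check in the acceptance suite is
  expected to report these overhang-sized deviations.
- Partial digestion, star activity, methylation blocking and
  double-enzyme digests are out of scope; each candidate is a single
  enzyme cutting to completion.
- Band intensity (mass) and lane distortion are not modelled; the gel
  is a position-only diagram.
- The bundled enzyme table is a ~60-enzyme starter set of common
  commercially available enzymes, not a full REBASE mirror; any enzyme
  can be added as one TSV line.
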