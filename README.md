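# diffdigest

Pick the best restriction enzyme for a **differential digest** (also
called a test or diagnostic digest): the routine single-enzyme digest a
cloner runs on a picked bacterial colony to tell the wanted ligation
product apart from the recipient plasmid, a religated backbone, or a
reverse-orientation insert.

Given 2–3 DNA sequences (plain text or FASTA, each flagged linear or
circular), `diffdigest` simulates the digest of every enzyme in a
table of commercially available enzymes, filters out patterns that are
useless on a real gel, scores how *distinguishable* each enzyme's band
patterns are across the input molecules, ranks the enzymes
most-distinct-first, and renders a simulated agarose gel (SVG) for each
candidate. It is aimed at molecular-cloning benches, but works for any
task that compares DNA molecules by restriction pattern (RFLP typing,
contamination checks).

## Method

For an enzyme with IUPAC recognition site *S* (length *L*, top/bottom
cut offsets *c<sub>t</sub>*, *c<sub>b</sub>*), both *S* and its reverse
complement are scanned over the input with single-step resolution, so
overlapping sites are all found. A plus-strand window at position *w*
cuts the top strand at *w + c<sub>t</sub>*; a minus-strand window cuts
at *w + L − c<sub>b</sub>*. On circular molecules the scan wraps across
the origin and positions are reduced modulo the length; *k* cuts give
*k* fragments (circular) or *k + 1* (linear).

Each lane's fragments are filtered to the length window
[*min_len*, *max_len*] (defaults 50–10 000 bp) and the retained count
must lie in [*min_frags*, *max_frags*] (defaults 2–10). Two lanes
A = (x₁ ≥ … ≥ x<sub>m</sub>) and B = (y₁ ≥ … ≥ y<sub>n</sub>) of
log₁₀ band lengths are compared by a shortest-path-root dissimilarity:

    C[i][j] = min( C[i−1][j−1] + (xᵢ − yⱼ)²,
                   C[i−1][j]   + γ²,
                   C[i][j−1]   + γ² ),      D(A, B) = √C[m][n]

i.e. the minimal cost of a monotone matching of the two band lists,
where a matched pair costs its squared log-length difference and an
unmatched band costs the gap penalty γ² (γ = 0.5 log₁₀ units by
default). An enzyme's score for 2–3 lanes is the **minimum** pairwise
D — the least-separable pair of identities bounds its diagnostic value.
Gels use a pure log-length migration model with a ladder lane, cut off
below 50 bp.

## Worked example

Build a synthetic 3 kb recipient plasmid with planted XhoI, HindIII and
EcoRI sites, and a "final" plasmid that differs only by one extra EcoRI
site (as an insert would introduce), then ask which enzyme tells them
apart:

```sh
diffdigest make-fixture --length 3000 \
    --plant CTCGAG@200 --plant CTCGAG@1400 \
    --plant AAGCTT@700 --plant AAGCTT@2200 \
    --plant GAATTC@400 --plant GAATTC@1800 \
    --seed 11 --out recipient.fa
# final.fa: same backbone + GAATTC planted at 2600
diffdigest --seq recipient.fa:circular --seq final.fa:circular --out out
```

The run logs its settings and counts to standard error:

```
INFO diffdigest.cli_io: settings: min_frags=2 max_frags=10 min_len=50 max_len=10000 cutoff=50 gamma=0.5 sort=dissimilarity reverse=False
INFO diffdigest.cli_io: loaded 2 sequence(s), 66 enzyme(s)
INFO diffdigest.cli_io: evaluated 66 enzymes: 13 passed, 13 gel(s) rendered
```

and `out/report.tsv` begins:

```
enzyme   passed  score     recipient      final
EcoRI    true    0.505881  1400;955;645   1400;800;645;155
ApaI     true    0.000000  2604;396       2604;396
AvaI     true    0.000000  1565;651;549;227  1565;651;549;227
```

EcoRI ranks first: its extra cut splits the recipient's 955 bp fragment
into 800 + 155 bp, a difference obvious on a gel (score 0.506 in
log-band units), while every other passing enzyme produces identical
lanes (score 0). `out/EcoRI.svg` shows the simulated gel: a ladder lane
plus one colored lane per plasmid. Columns after `score` list each
lane's fragment sizes in bp, largest first.

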