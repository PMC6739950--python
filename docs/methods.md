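# Methods

## Coordinate conventions and band resolution

All coordinates are 0-based half-open, matching the UCSC `cytoBand.txt`
format the band tables are shipped in. The vendored tables (hg18, hg19,
GRCh38; 850-band resolution, canonical chromosomes only) are the UCSC
Genome Browser's own band tables. hg19 is the default assembly.

A band label resolves as follows:

* an exact table label returns that band's interval;
* a label coarser than the table (`q21` where the table holds
  q21.1/q21.2/…) returns the union of all bands whose label extends the
  query — equivalently the min start / max end over the matching set;
* a label finer than the table (`q21.311`) falls back to the covering
  band, since no sub-band interpolation is defensible at band
  resolution;
* `p10`/`q10` return the zero-length centromere point at the shared edge
  of the two `acen` bands. Using the single acen/acen boundary (hg19
  chr1: 125,000,000) rather than the midpoint of the full centromeric
  region makes whole-arm intervals exactly complementary: p = [0,
  boundary), q = [boundary, chrom_length).

Input chromosome names are normalized (`1`, `chr1`, `X`, `chrx` all
accepted); output always uses `chr1`…`chrX`, `chrY`. Band labels tolerate
internal whitespace and a stray dot after the arm letter (`q.21.31` →
`q21.31`), both common in transcribed karyotypes.

## Grammar and robustness

The parser is deliberately forgiving: karyotype archives contain decades
of dialect. Whitespace is insignificant everywhere (`+ 7` ≡ `+7`). Clones
split on `/` outside brackets; trailing `[n]` / `[cp n]` are cell counts.
The first comma-field is the modal number (integer, `a~b` range, optional
`<kn>` ploidy marker); the second, if composed only of X/Y symbols, is
the sex field. Every remaining field parses to a typed aberration or, if
nothing matches, an `unknown_term` that is skipped with a warning — never
an exception, so a thousand-row batch always completes. `?` marks are
recorded and otherwise ignored; a trailing `c` (constitutional) is
processed like an acquired aberration, with a warning. A trailing `xN`
multiplier expands to N copies of the term. `idem` in a later clone
prepends the stemline's aberration list; `sl`/`sdl` stemline shorthands
are not interpreted and degrade to warnings.

Modal-number consistency is never enforced. `46,XY,der(1;19)(q10;p10)`
implies 45 chromosomes as written, yet remains convertible; the
discrepancy is reported on the warnings channel only (and only for clones
without structural terms, where the count is actually checkable).

## Copy-number semantics

The unit of bookkeeping is a signed copy delta on an interval. The
breakpoint band is wholly included in the segment its event describes —
for a deletion the deleted span, for a derivative the retained span. This
single rule fixes every boundary: a terminal `del(c)(q21)` removes
[q21.start, qter); an interstitial `del(c)(b1b2)` removes [min start,
max end] of the two bands; the `+der(10)t(10;21)(p13;q21)` derivative
retains chr10 from the start of p13 through 10qter and gains chr21 from
the start of q21 to 21qter.

Per kind:

| term | without `+` | with `+` |
|---|---|---|
| `±N` | ∓/± 1 whole chromosome | — |
| `del` | −1 deleted span | same |
| `dup` / `trp` | +1 / +2 over the span | same |
| `i(cq)` | +1 q arm, −1 p arm (replaces a homolog) | +2 q arm (supernumerary) |
| `der(c1;c2)(q10;p10)` | −1 on each unretained arm | +1 on each retained arm |
| `der(c)t(…)…` | −1 base material not retained, +1 donor pieces | +1 all pieces |
| `add(c)(b)` | −1 distal to b (b retained); added material unknown, counts 0 | same |
| `r(c)(b1b2)` | −1 on both telomeric caps | same |
| `t`, `inv`, `ins` | 0 (balanced) | — |
| `mar`, `dmin`, `hsr` | 0, warning (content unknowable) | — |

Multi-segment derivatives (`der(1)t(1;3)(p32;q21)t(3;7)(q28;q11)`) are
assembled sequentially: the base piece, then each donor entered at its
breakpoint, an intermediate donor truncated where the next segment
attaches (both boundary bands included), the last donor running to its
breakpoint arm's telomere. `ider(c)(q10)` uses isochromosome arithmetic on
the named arm; an `ider` with trailing `t()` segments is a dialect we do
not fully interpret — it degrades to the iso arithmetic with a warning.

Deltas from all of a clone's terms are summed by an endpoint sweep into
maximal intervals of constant nonzero net delta; zero regions vanish, so
a `dup` and a `del` over the same span cancel to no output.

## Baselines and classification

Only explicit aberration terms generate deltas; the sex field and modal
number never do (`45,X` with no `-X` term yields no output, with a
warning). The baseline against which net change is classified is: ploidy
multiplier per autosome (default 2, `<3n>` → 3), and for a sex chromosome
the sex-field count plus one per non-`+` structural aberration based on
it — the ISCN sex field lists only intact homologs, so
`46,X,del(X)(q21.31q27.2)` has baseline 2 for chrX and the deletion is
hemizygous. Net copies clamp at zero: a delta deeper than −baseline is
still a homozygous loss, flagged as over-subtraction.

A consequence worth naming: a whole-chromosome `-Y` with sex field `X`
has baseline 0 for chrY and classifies as a homozygous loss of the full
chromosome. The output label (`Loss`) is unaffected; only the heatmap
zygosity color differs.

## Synthetic generator and what passing proves

The generator builds clones in an explicit homolog model: each chromosome
starts with baseline-many homologs, each a list of (chrom, start, end)
pieces; events edit piece lists (a deletion removes a span from one
homolog, a derivative replaces homologs with assembled pieces, donors of
unbalanced translocations contribute extra pieces without being
consumed). Ground truth is per-base piece coverage minus baseline,
computed by midpoint counting over elementary intervals — a different
algorithmic path from the engine's signed-delta sweep, which is what
makes the equivalence test meaningful. Self-contradictory stacks are
avoided by tracking which homologs remain normal; events that would need
an unavailable homolog are redrawn.

Default generator conditions: 1–2 clones per sample, 0–4 events per
clone, event-kind weights spread across the full term inventory
(gains/losses ≈ 28%, segmental events ≈ 50%, balanced ≈ 10%, derivatives
≈ 18%), cell counts 2–100, toy maps of 4 chromosomes × 4 bands per arm ×
200 kb unless an assembly map is passed. These are testing conditions,
not an attempt to match any empirical aberration frequency distribution;
real karyotypes also contain dialects (composite `cp` subclones, `ish`
FISH clauses, uncertain breakpoints) that the generator only partially
exercises via its whitespace/`?` noise mode, so a passing oracle suite
demonstrates the arithmetic is self-consistent, not that every archival
string will parse.

## Numerical and design choices

* Heatmap bins default to 1 Mb; a bin's color is the state covering the
  most bases in it, ties broken toward loss (visual conservatism). Both
  choices are display-only and stated in the figure legend.
* Sample totals for `k of N` cell strings sum only clones with known
  counts; clones without counts print `unknown` and a warning notes
  their exclusion from N.
* Duplicate sample names in a batch are uniquified with a `.k` suffix
  rather than merged or dropped.
* The clone suffix `_n` is always appended, including single-clone
  samples, so identifiers are stable across re-runs with added clones.
* Output rows are sorted by input sample order, clone ordinal, genomic
  chromosome order, start.
* `add` counts the unknown added material as nothing (neutral) while the
  material distal to the breakpoint is lost; the alternative reading
  (ignore the distal loss too) would under-report and was rejected.

## Problem sizes

The bundled verification runs use 320 random karyotypes for the oracle
agreement study and a 1,000-row mixed-validity batch; both finish in
under a second on a laptop-class core. The suite re-validates the three
vendored assembly tables on every run.

## Known limitations

* No liftover between assemblies; no non-human ISCN; no FISH (`ish`) or
  microarray (`arr`) nomenclature.
* Band-level resolution bounds precision: focal events smaller than a
  band are invisible, exactly as in the source karyotypes.
* Balanced rearrangements are deliberately absent from the output; a
  fusion-aware mode would need breakpoint orientation bookkeeping the
  nomenclature only partially provides.
* Three-way `der` assembly and `ider` handling follow the conventions
  above; other tools' dialects may differ on these rare forms.
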