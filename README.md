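# karyoconvert

Convert human karyotypes written in ISCN cytogenetic nomenclature into the
net chromosomal gains and losses they imply, as genomic coordinate
intervals.

Karyotypes such as `46,XY,der(1;19)(q10;p10)` summarize the chromosome
complement of a cell population at cytogenetic-band resolution. Modern
analyses — gene lookups, copy-number comparisons, cohort screens — work in
genomic coordinates instead. Large archives of tumor and clinical samples
exist only as karyotype strings, with no DNA left to re-assay.
`karyoconvert` bridges the two worlds: it parses ISCN strings (including
multi-clone karyotypes with per-clone cell counts), applies copy-number
arithmetic to every aberration term, and reports each clone's net gains
and losses on hg18, hg19 or GRCh38 coordinates, with a genome-wide
gain/loss heatmap.

## The conversion model

Each clone is processed independently:

1. **Parse** — the clone's modal number, ploidy marker `<kn>`, sex field,
   and comma-separated aberration terms are tokenized into typed events
   (whole-chromosome ±, `del`, `dup`, `trp`, `i`, `ider`, `der`, `add`,
   `t`, `inv`, `ins`, `r`, `+mar`, `dmin`, `hsr`, `idem`, …). Unrecognized
   terms degrade to warnings; a batch never aborts on one bad row.
2. **Map** — breakpoint bands resolve to coordinates through the UCSC
   850-band cytoBand tables (vendored for hg18/hg19/GRCh38). A named
   breakpoint band is wholly included in the segment its event describes;
   `p10`/`q10` denote the centromere point where the two `acen` bands
   meet.
3. **Sum** — every event contributes signed copy deltas on intervals
   (e.g. `i(17q)` replacing a normal 17: +1 on 17q, −1 on 17p;
   `+der(10)t(10;21)(p13;q21)`: +1 on 10p13→10qter and +1 on
   21q21→21qter). An endpoint sweep accumulates deltas into maximal
   segments of constant net change.
4. **Classify** — against the clone baseline (autosomes: ploidy, default
   2; sex chromosomes: sex-field count plus one per structural aberration
   based on them), net copies above baseline are a **Gain**, between zero
   and baseline a **hemizygous Loss**, at zero a **homozygous Loss**.

Balanced events (reciprocal translocations, inversions, insertions)
change no copy number and produce no output — only net gain and loss of
material relative to the baseline is reported.

## Worked example

```bash
karyoconvert --karyotype "46,X,del(X)(q21.31q27.2)[2]/46,XX[2]"
```

prints

```
Sample ID	Chr	Start	End	Type	Cells Present
sample_1_1	chrX	86200000	142100000	Loss	2 of 4
```

Clone 1 carries a deletion of Xq21.31 through Xq27.2: on hg19 that is
chrX:86,200,000–142,100,000. The clone retains one intact X (the sex
field) beside the deleted homolog, so the segment sits at one copy out of
a two-copy baseline — a hemizygous loss, shown in blue on the heatmap.
Clone 2 (`46,XX`, 2 cells) is normal and contributes no rows. Batch input
is a two-column TSV of sample name and karyotype:

```bash
karyoconvert --input samples.tsv --assembly hg19 --out result --plot
```

writes `result.tsv`, `result_warnings.tsv` and `result_heatmap.png`
(heatmap rows are clones; red = gain, blue = hemizygous loss, yellow =
homozygous loss).

The same pipeline is available as a library:

```python
from karyoconvert import load_assembly, convert_one

res = convert_one("49<2n>,XX,+3,+6,+8,+13,i(17q)", load_assembly("hg19"))
for row in res.rows:
    print(row.chrom, row.start, row.end, row.type_label)
```

```
chr3 0 198022430 Gain
chr6 0 171115067 Gain
chr8 0 146364022 Gain
chr13 0 115169878 Gain
chr17 0 24000000 Loss
chr17 24000000 81195210 Gain
```

— the four trisomies plus the 17q gain / 17p loss implied by `i(17q)`.

A synthetic-data module (`karyoconvert.synth`, CLI `karyoconvert synth`)
generates random valid karyotypes together with ground-truth copy-number
profiles built constructively from explicit homolog piece lists; the test
suite uses it as an independent oracle for the conversion engine.

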