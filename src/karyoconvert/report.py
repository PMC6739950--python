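"""Batch input reading, tabular gain/loss output, and the genome heatmap.

The output schema is one row per net gain/loss segment per clone:

    Sample ID   Chr   Start   End   Type   Cells Present

Clone identifiers append ``_n`` to the sample name for the n-th clone
(always, even for single-clone samples).  ``Cells Present`` reads
``k of N`` where N sums the known clone counts of the sample, or
``unknown`` when the clone's count was not given.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Sequence, TextIO

from .band_map import BandMap, chrom_sort_key
from .engine import CNProfile, build_profile, classify
from .iscn import Warning_, parse_karyotype

__all__ = [
    "ReportRow",
    "ConversionResult",
    "read_batch",
    "convert",
    "convert_one",
    "write_table",
    "cells_string",
    "render_heatmap",
    "HEADER",
]

HEADER = ("Sample ID", "Chr", "Start", "End", "Type", "Cells Present")


@dataclass(frozen=True)
class ReportRow:
    sample_clone_id: str
    chrom: str
    start: int
    end: int
    type_label: str          # "Gain" | "Loss"
    cells_present: str       # "k of N" | "unknown"
    zygosity: str = "not_applicable"


@dataclass
class ConversionResult:
    rows: list[ReportRow] = field(default_factory=list)
    profiles: list[CNProfile] = field(default_factory=list)
    warnings: list[tuple[str, Warning_]] = field(default_factory=list)  # (sample, w)


def cells_string(count: int | None, sample_total: int | None) -> str:
    """Format a clone's cell count against the sample total."""
    if count is None or sample_total is None:
        return "unknown"
    return f"{count} of {sample_total}"


def read_batch(stream: TextIO | Iterable[str]) -> list[tuple[str, str]]:
    """Read a two-column tab-delimited table of sample name + karyotype.

    A header row is auto-detected (second field with no digits is not a
    karyotype).  Duplicate sample names get a uniquifying suffix and a
    warning is attached by :func:`convert`.
    """
    rows: list[tuple[str, str]] = []
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n").rstrip("\r")
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(
                f"line {lineno}: expected 2 tab-separated columns, got {len(parts)}"
            )
        name, karyo = parts[0].strip(), parts[1].strip()
        if lineno == 1 and not any(ch.isdigit() for ch in karyo):
            continue          # header row
        rows.append((name, karyo))
    if not rows:
        raise ValueError("input table contains no data rows")
    return rows


def _uniquify(samples: list[tuple[str, str]]) -> tuple[list[tuple[str, str]], list[str]]:
    seen: dict[str, int] = {}
    out, dups = [], []
    for name, karyo in samples:
        if name in seen:
            seen[name] += 1
            dups.append(name)
            name = f"{name}.{seen[name]}"
        else:
            seen[name] = 1
        out.append((name, karyo))
    return out, dups


def convert_one(
    karyotype: str, bmap: BandMap, sample_id: str = "sample_1"
) -> ConversionResult:
    """Convert a single karyotype string; see :func:`convert`."""
    return convert([(sample_id, karyotype)], bmap)


def convert(samples: Sequence[tuple[str, str]], bmap: BandMap) -> ConversionResult:
    """Run the full pipeline over (sample, karyotype) pairs.

    Per sample: parse clones, build each clone's net copy-number profile,
    classify segments, and emit rows sorted by input order, clone ordinal,
    chromosome, start.  All parse/resolution problems surface as warnings,
    never exceptions.
    """
    result = ConversionResult()
    uniq, dups = _uniquify(list(samples))
    for name in dups:
        result.warnings.append(
            (name, Warning_(0, "", "duplicate sample name; suffix added"))
        )
    for sample_id, karyotype in uniq:
        try:
            rec = parse_karyotype(karyotype, sample_id)
        except ValueError as exc:
            result.warnings.append((sample_id, Warning_(0, karyotype, str(exc))))
            continue
        for w in rec.warnings:
            result.warnings.append((sample_id, w))
        known = [c.cells.count for c in rec.clones if c.cells.known]
        total = sum(known) if known else None
        if known and len(known) < len(rec.clones):
            result.warnings.append(
                (
                    sample_id,
                    Warning_(
                        0, "",
                        "clones without cell counts excluded from the sample total",
                    ),
                )
            )
        for clone in rec.clones:
            profile = build_profile(clone, bmap, sample_id)
            for w in profile.warnings:
                result.warnings.append((sample_id, w))
            result.profiles.append(profile)
            cells = cells_string(clone.cells.count, total)
            for seg in sorted(
                profile.segments, key=lambda s: (chrom_sort_key(s.chrom), s.start)
            ):
                cls = classify(seg.delta, profile.baseline.get(seg.chrom, 0))
                result.rows.append(
                    ReportRow(
                        profile.clone_id,
                        seg.chrom,
                        seg.start,
                        seg.end,
                        cls.label,
                        cells,
                        cls.zygosity,
                    )
                )
    return result


def write_table(rows: Sequence[ReportRow], pretty: bool = False) -> str:
    """Render rows as tab-delimited text with the standard 6-column header.

    ``pretty`` adds thousands separators to coordinates (display only; the
    plain format round-trips through :func:`read_batch`-style parsing).
    """

    def fmt(x: int) -> str:
        return f"{x:,}" if pretty else str(x)

    lines = ["\t".join(HEADER)]
    for r in rows:
        lines.append(
            "\t".join(
                (r.sample_clone_id, r.chrom, fmt(r.start), fmt(r.end),
                 r.type_label, r.cells_present)
            )
        )
    return "\n".join(lines) + "\n"


def write_warnings(warnings: Sequence[tuple[str, Warning_]]) -> str:
    lines = ["\t".join(("Sample", "Clone", "Term", "Message"))]
    for sample, w in warnings:
        lines.append("\t".join((sample, str(w.clone), w.term, w.message)))
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# heatmap

_STATE_NEUTRAL, _STATE_GAIN, _STATE_HEMI, _STATE_HOMO = 0, 1, 2, 3
_CMAP_COLORS = ["#f5f5f5", "#d62728", "#1f77b4", "#ffdf00"]  # bg/red/blue/yellow


def render_heatmap(
    profiles: Sequence[CNProfile],
    bmap: BandMap,
    image_path: str,
    bin_size: int = 1_000_000,
) -> None:
    """Genome-wide gain/loss heatmap: one row per clone, chr1→chrY on x.

    Bin color is the state covering the most bases in the bin (red gain,
    blue hemizygous loss, yellow homozygous loss); ties break toward loss.
    Output is deterministic for fixed input and bin size.
    """
    import numpy as np
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap
    from matplotlib.patches import Patch

    if not profiles:
        raise ValueError("no profiles to plot")
    chroms = bmap.chromosomes
    offsets: dict[str, int] = {}
    pos = 0
    for c in chroms:
        offsets[c] = pos
        pos += bmap.chrom_length(c)
    genome_len = pos
    if genome_len == 0:
        raise ValueError("zero-width genome")
    n_bins = (genome_len + bin_size - 1) // bin_size

    grid = np.zeros((len(profiles), n_bins), dtype=np.int8)
    for i, prof in enumerate(profiles):
        # per-bin coverage in bases for each non-neutral state
        cover = np.zeros((4, n_bins), dtype=np.int64)
        for seg in prof.segments:
            cls = classify(seg.delta, prof.baseline.get(seg.chrom, 0))
            state = (
                _STATE_GAIN
                if cls.label == "Gain"
                else (_STATE_HEMI if cls.zygosity == "hemizygous" else _STATE_HOMO)
            )
            g0 = offsets[seg.chrom] + seg.start
            g1 = offsets[seg.chrom] + seg.end
            b0, b1 = g0 // bin_size, (g1 - 1) // bin_size
            for b in range(b0, b1 + 1):
                lo = max(g0, b * bin_size)
                hi = min(g1, (b + 1) * bin_size)
                cover[state, b] += hi - lo
        occupied = cover[1:].sum(axis=0) > 0
        # dominant state; ties toward loss → compare with loss priority
        order = [_STATE_HOMO, _STATE_HEMI, _STATE_GAIN]   # checked in this order
        best = np.zeros(n_bins, dtype=np.int8)
        best_cov = np.zeros(n_bins, dtype=np.int64)
        for st in order:
            better = cover[st] > best_cov
            best[better] = st
            best_cov[better] = cover[st][better]
        grid[i, occupied] = best[occupied]

    fig_h = max(2.0, 0.4 * len(profiles) + 1.5)
    fig, ax = plt.subplots(figsize=(12, fig_h))
    ax.imshow(
        grid,
        aspect="auto",
        interpolation="nearest",
        cmap=ListedColormap(_CMAP_COLORS),
        vmin=0,
        vmax=3,
        extent=(0, genome_len, len(profiles) - 0.5, -0.5),
    )
    for c in chroms[1:]:
        ax.axvline(offsets[c], color="0.7", lw=0.5)
    mids = [offsets[c] + bmap.chrom_length(c) / 2 for c in chroms]
    ax.set_xticks(mids)
    ax.set_xticklabels([c[3:] for c in chroms], fontsize=7)
    ax.set_yticks(range(len(profiles)))
    ax.set_yticklabels([p.clone_id for p in profiles], fontsize=8)
    ax.set_xlabel("chromosome")
    ax.legend(
        handles=[
            Patch(color=_CMAP_COLORS[1], label="Gain"),
            Patch(color=_CMAP_COLORS[2], label="Hemizygous loss"),
            Patch(color=_CMAP_COLORS[3], label="Homozygous loss"),
        ],
        loc="upper right",
        fontsize=7,
        title=f"bin {bin_size // 1000} kb; bin color = state covering most bases,\n"
              "ties toward loss",
        title_fontsize=6,
    )
    fig.tight_layout()
    fig.savefig(image_path, dpi=120)
    plt.close(fig)


def read_table(text: str) -> list[ReportRow]:
    """Parse :func:`write_table` output back into rows (plain format)."""
    rows = []
    fh = io.StringIO(text)
    header = next(fh).rstrip("\n").split("\t")
    if tuple(header) != HEADER:
        raise ValueError("unexpected header")
    for line in fh:
        line = line.rstrip("\n")
        if not line:
            continue
        sid, chrom, start, end, label, cells = line.split("\t")
        rows.append(ReportRow(sid, chrom, int(start), int(end), label, cells))
    return rows
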