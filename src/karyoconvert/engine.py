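"""Copy-number arithmetic: aberration terms → signed interval deltas →
net per-clone gain/loss segments.

Each aberration kind maps to a small set of signed copy deltas on genomic
intervals (``event_deltas``).  The convention throughout is that a named
breakpoint band is *wholly included* in the segment the event describes —
the deleted span of a del, the retained/gained span of a derivative.
Deltas for all of a clone's aberrations are then summed by an endpoint
sweep (``accumulate``) into maximal constant-delta segments, and each
segment is classified against the clone's baseline copy count: above
baseline is a gain, below baseline but above zero a hemizygous loss, at or
below zero a homozygous loss.

Balanced events (translocations, inversions, insertions) produce no
deltas: only net gain and loss of material relative to the clone baseline
is reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .band_map import BandMap, BandResolutionError, GenomicInterval, chrom_sort_key
from .iscn import Aberration, CloneSpec, Kind, Op, STRUCTURAL_KINDS, Warning_

__all__ = [
    "CNDelta",
    "Segment",
    "CNProfile",
    "Classification",
    "event_deltas",
    "clone_baseline",
    "accumulate",
    "classify",
    "build_profile",
]


@dataclass(frozen=True)
class CNDelta:
    interval: GenomicInterval
    delta: int          # signed copies, never 0


@dataclass(frozen=True)
class Segment:
    chrom: str
    start: int
    end: int
    delta: int


@dataclass(frozen=True)
class Classification:
    label: str          # "Gain" | "Loss"
    zygosity: str       # "hemizygous" | "homozygous" | "not_applicable"


@dataclass
class CNProfile:
    """Net copy-number deltas for one clone, as maximal constant segments."""

    clone_id: str
    segments: list[Segment] = field(default_factory=list)
    baseline: dict[str, int] = field(default_factory=dict)
    warnings: list[Warning_] = field(default_factory=list)


# ---------------------------------------------------------------------------
# per-aberration deltas

def _arm_of(bmap: BandMap, chrom: str, label: str) -> str:
    if label and label[0] in "pq":
        return label[0]
    raise BandResolutionError(chrom, label)


def _retained_base(bmap: BandMap, chrom: str, label: str) -> GenomicInterval:
    """Piece of a derivative's base chromosome kept at breakpoint *label*:
    the centromere-containing side, breakpoint band wholly included."""
    b = bmap.resolve_band(chrom, label)
    if _arm_of(bmap, chrom, label) == "p":
        return GenomicInterval(chrom, b.start, bmap.chrom_length(chrom))
    return GenomicInterval(chrom, 0, b.end)


def _donor_piece(bmap: BandMap, chrom: str, label: str) -> GenomicInterval:
    """Translocated piece of a donor chromosome: breakpoint band to its own
    arm's telomere, band wholly included."""
    b = bmap.resolve_band(chrom, label)
    if _arm_of(bmap, chrom, label) == "p":
        return GenomicInterval(chrom, 0, b.end)
    return GenomicInterval(chrom, b.start, bmap.chrom_length(chrom))


def _span(bmap: BandMap, chrom: str, labels: tuple[str, ...]) -> GenomicInterval:
    ivs = [bmap.resolve_band(chrom, lb) for lb in labels]
    return GenomicInterval(
        chrom, min(i.start for i in ivs), max(i.end for i in ivs)
    )


def derivative_pieces(
    ab: Aberration, bmap: BandMap
) -> list[GenomicInterval]:
    """Assemble a der(c)t(…)… derivative as explicit chromosome pieces.

    The base piece runs from the first breakpoint (band included) through
    the centromere to the far telomere.  Each donor enters at its own
    breakpoint; an intermediate donor (three-way der) is truncated at the
    breakpoint where the next segment attaches, both boundary bands wholly
    included; the final donor runs to its breakpoint arm's telomere.
    """
    base = ab.chroms[0]
    pieces = [_retained_base(bmap, base, ab.breakpoints[0][0])]
    for chrom, bps in zip(ab.chroms[1:], ab.breakpoints[1:]):
        if len(bps) == 1:
            pieces.append(_donor_piece(bmap, chrom, bps[0]))
        else:           # entered at bps[0], exits at bps[1]
            pieces.append(_span(bmap, chrom, bps))
    return pieces


def event_deltas(
    ab: Aberration, bmap: BandMap, clone: CloneSpec
) -> tuple[list[CNDelta], list[Warning_]]:
    """Signed copy deltas implied by one aberration.

    Unresolvable bands or unsupported forms never raise: the aberration is
    skipped and a warning names the raw term.
    """
    warns: list[Warning_] = []
    try:
        deltas = _event_deltas_inner(ab, bmap, clone, warns)
    except BandResolutionError as exc:
        return [], [
            Warning_(clone.ordinal, ab.raw, f"unresolvable band ({exc}); term skipped")
        ]
    return deltas, warns


def _event_deltas_inner(
    ab: Aberration, bmap: BandMap, clone: CloneSpec, warns: list[Warning_]
) -> list[CNDelta]:
    k, op = ab.kind, ab.operator

    if k in (Kind.TRANSLOCATION, Kind.INVERSION, Kind.INSERTION):
        return []          # balanced: no net change
    if k in (Kind.MARKER, Kind.DMIN, Kind.HSR):
        warns.append(
            Warning_(clone.ordinal, ab.raw, f"{k.value} has undefined content; ignored")
        )
        return []
    if k is Kind.UNKNOWN or k is Kind.IDEM:
        return []

    if k is Kind.WHOLE_CHROM:
        sign = 1 if op is Op.PLUS else -1
        return [CNDelta(bmap.whole_chrom(ab.chroms[0]), sign)]

    if not ab.chroms:
        warns.append(
            Warning_(clone.ordinal, ab.raw, "no chromosome named; term ignored")
        )
        return []

    chrom = ab.chroms[0]
    bps = ab.breakpoints[0] if ab.breakpoints else ()

    if k is Kind.DEL:
        if len(bps) == 1:
            b = bmap.resolve_band(chrom, bps[0])
            if _arm_of(bmap, chrom, bps[0]) == "q":
                iv = GenomicInterval(chrom, b.start, bmap.chrom_length(chrom))
            else:
                iv = GenomicInterval(chrom, 0, b.end)
        else:
            iv = _span(bmap, chrom, bps)
        return [CNDelta(iv, -1)] if iv.length else []

    if k in (Kind.DUP, Kind.TRP):
        iv = _span(bmap, chrom, bps)
        amt = 1 if k is Kind.DUP else 2
        return [CNDelta(iv, amt)] if iv.length else []

    if k in (Kind.ISO, Kind.IDER):
        arm = bps[0][0]
        other = "q" if arm == "p" else "p"
        if k is Kind.IDER:
            warns.append(
                Warning_(
                    clone.ordinal, ab.raw,
                    "isoderivative treated with isochromosome arithmetic on "
                    "the base chromosome",
                )
            )
        if op is Op.PLUS:
            return [CNDelta(bmap.arm_interval(chrom, arm), 2)]
        return [
            CNDelta(bmap.arm_interval(chrom, arm), 1),
            CNDelta(bmap.arm_interval(chrom, other), -1),
        ]

    if k is Kind.DER_WHOLE_ARM:
        out = []
        for c, (bp,) in zip(ab.chroms, ab.breakpoints):
            named = bp[0]                       # retained arm
            other = "q" if named == "p" else "p"
            if op is Op.PLUS:
                out.append(CNDelta(bmap.arm_interval(c, named), 1))
            else:
                out.append(CNDelta(bmap.arm_interval(c, other), -1))
        return [d for d in out if d.interval.length]

    if k is Kind.DER_TRANSLOCATION:
        pieces = derivative_pieces(ab, bmap)
        if op is Op.PLUS:
            return [CNDelta(p, 1) for p in pieces if p.length]
        # replaces one normal base homolog: base piece kept (net 0),
        # the rest of the base chromosome lost, donor pieces gained
        out = []
        base_piece = pieces[0]
        length = bmap.chrom_length(chrom)
        if base_piece.start > 0:
            out.append(CNDelta(GenomicInterval(chrom, 0, base_piece.start), -1))
        if base_piece.end < length:
            out.append(CNDelta(GenomicInterval(chrom, base_piece.end, length), -1))
        out.extend(CNDelta(p, 1) for p in pieces[1:] if p.length)
        return out

    if k is Kind.ADD:
        b = bmap.resolve_band(chrom, bps[0])
        if _arm_of(bmap, chrom, bps[0]) == "q":
            iv = GenomicInterval(chrom, b.end, bmap.chrom_length(chrom))
        else:
            iv = GenomicInterval(chrom, 0, b.start)
        return [CNDelta(iv, -1)] if iv.length else []

    if k is Kind.RING:
        if len(bps) < 2:
            warns.append(
                Warning_(
                    clone.ordinal, ab.raw,
                    "ring without two breakpoints has undefined extent; ignored",
                )
            )
            return []
        b1 = bmap.resolve_band(chrom, bps[0])
        b2 = bmap.resolve_band(chrom, bps[1])
        length = bmap.chrom_length(chrom)
        out = []
        if b1.start > 0:
            out.append(CNDelta(GenomicInterval(chrom, 0, b1.start), -1))
        if b2.end < length:
            out.append(CNDelta(GenomicInterval(chrom, b2.end, length), -1))
        return out

    warns.append(Warning_(clone.ordinal, ab.raw, f"unsupported kind {k.value}"))
    return []


# ---------------------------------------------------------------------------
# baseline and accumulation

def clone_baseline(clone: CloneSpec, bmap: BandMap) -> dict[str, int]:
    """Reference copy count per chromosome for one clone.

    Autosomes carry the ploidy multiplier (2 unless a ``<kn>`` marker says
    otherwise).  A sex chromosome's baseline is its count in the sex field
    plus one for every non-"+" structural aberration based on it — the sex
    field lists only unmodified homologs, so ``46,X,del(X)(…)`` has two X's.
    """
    baseline: dict[str, int] = {}
    for chrom in bmap.chromosomes:
        if chrom in ("chrX", "chrY"):
            n = sum(1 for s in clone.sex_field if f"chr{s}" == chrom)
            n += sum(
                1
                for ab in clone.aberrations
                if ab.operator is not Op.PLUS
                and ab.kind in STRUCTURAL_KINDS
                and ab.base_chrom == chrom
            )
            if n > 0 or any(ab.base_chrom == chrom for ab in clone.aberrations):
                baseline[chrom] = n
        else:
            baseline[chrom] = clone.ploidy_multiplier
    return baseline


def accumulate(deltas: list[CNDelta]) -> list[Segment]:
    """Sum overlapping deltas into maximal nonzero constant segments.

    Endpoint sweep per chromosome; zero-delta regions are dropped and
    adjacent equal-delta segments merged.
    """
    by_chrom: dict[str, list[CNDelta]] = {}
    for d in deltas:
        by_chrom.setdefault(d.interval.chrom, []).append(d)
    segments: list[Segment] = []
    for chrom in sorted(by_chrom, key=chrom_sort_key):
        ds = by_chrom[chrom]
        points = sorted({d.interval.start for d in ds} | {d.interval.end for d in ds})
        run: Segment | None = None
        for a, b in zip(points, points[1:]):
            net = sum(
                d.delta for d in ds if d.interval.start <= a and d.interval.end >= b
            )
            if net == 0:
                if run is not None:
                    segments.append(run)
                    run = None
                continue
            if run is not None and run.end == a and run.delta == net:
                run = Segment(chrom, run.start, b, net)
            else:
                if run is not None:
                    segments.append(run)
                run = Segment(chrom, a, b, net)
        if run is not None:
            segments.append(run)
    return segments


def classify(delta: int, baseline: int) -> Classification:
    """Label a net delta against the baseline copy count.

    Net copies clamp at zero: a delta deeper than the baseline is still a
    homozygous loss.
    """
    net = baseline + delta
    if net > baseline:
        return Classification("Gain", "not_applicable")
    if net > 0:
        return Classification("Loss", "hemizygous")
    return Classification("Loss", "homozygous")


def build_profile(
    clone: CloneSpec, bmap: BandMap, sample_id: str = "sample_1"
) -> CNProfile:
    """Full per-clone pipeline: deltas for every aberration, accumulated
    into net segments, with baselines attached."""
    clone_id = f"{sample_id}_{clone.ordinal}"
    profile = CNProfile(clone_id=clone_id, baseline=clone_baseline(clone, bmap))
    all_deltas: list[CNDelta] = []
    for ab in clone.aberrations:
        ds, warns = event_deltas(ab, bmap, clone)
        all_deltas.extend(ds)
        profile.warnings.extend(warns)
    profile.segments = accumulate(all_deltas)
    for seg in profile.segments:
        base = profile.baseline.get(seg.chrom, 0)
        if base + seg.delta < 0:
            profile.warnings.append(
                Warning_(
                    clone.ordinal, "",
                    f"{seg.chrom}:{seg.start}-{seg.end} loses more copies than "
                    f"the baseline {base}; clamped at 0 (homozygous loss)",
                )
            )
    return profile
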