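"""Cytoband reference tables and band-label → coordinate resolution.

A :class:`BandMap` is loaded from a UCSC ``cytoBand.txt`` table (5-column
TSV: chrom, start, end, band name, Giemsa stain; 0-based half-open
coordinates).  Tables for hg18, hg19 and GRCh38 at 850-band resolution are
vendored as package data.  The map answers three kinds of query:

* ``arm_interval`` — the coordinate span of a whole p or q arm, with the
  arm boundary taken at the shared edge of the two centromeric (``acen``)
  bands;
* ``resolve_band`` — a band label such as ``q21.31`` to its interval, with
  prefix-union fallback when the query is coarser or finer than the table
  (``q21`` → union of q21.1/q21.2/…; ``q21.311`` → q21.31);
* chromosome lengths, taken from the end of the last band.

All coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, TextIO

__all__ = [
    "CytoBand",
    "BandMap",
    "GenomicInterval",
    "BandMapError",
    "BandResolutionError",
    "load_band_table",
    "load_assembly",
    "normalize_chrom",
    "ASSEMBLIES",
]

ASSEMBLIES = ("hg18", "hg19", "grch38")

_CANONICAL = tuple(f"chr{n}" for n in list(range(1, 23)) + ["X", "Y"])
_CANONICAL_SET = frozenset(_CANONICAL)
_CHROM_ORDER = {c: i for i, c in enumerate(_CANONICAL)}


class BandMapError(ValueError):
    """Raised when a band table is malformed or fails validation."""


class BandResolutionError(KeyError):
    """Raised when a (chromosome, band label) pair matches no band.

    Carries ``chrom`` and ``label`` so callers can downgrade the failure
    to a per-aberration warning.
    """

    def __init__(self, chrom: str, label: str):
        super().__init__(f"{chrom}: no band matching {label!r}")
        self.chrom = chrom
        self.label = label

    def __str__(self) -> str:  # KeyError quotes its arg; keep it readable
        return f"{self.chrom}: no band matching {self.label!r}"


def normalize_chrom(name: str) -> str:
    """Map '1', 'chr1', 'X', 'chrx' … onto canonical 'chr1'…'chrX','chrY'.

    Raises :class:`BandResolutionError` for anything non-canonical.
    """
    s = name.strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    s = s.upper()
    cand = f"chr{s}"
    if cand not in _CANONICAL_SET:
        raise BandResolutionError(name, "")
    return cand


def chrom_sort_key(chrom: str) -> int:
    return _CHROM_ORDER[chrom]


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if not (0 <= self.start <= self.end):
            raise ValueError(f"bad interval {self.chrom}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class CytoBand:
    chrom: str
    arm: str          # 'p' or 'q'
    label: str        # e.g. "q21.31" (includes the arm letter)
    start: int
    end: int
    stain: str

    @property
    def flat_label(self) -> str:
        """Label with the sub-band dot removed: q21.31 → q2131."""
        return self.label.replace(".", "")

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)


_LABEL_RE = re.compile(r"^([pq])(\d+(?:\.\d+)?)?$")


def _normalize_label(label: str) -> str:
    """Canonicalize a band label: strip whitespace and a stray leading dot
    after the arm letter ('q.21.31' → 'q21.31'), lowercase the arm."""
    s = re.sub(r"\s+", "", label)
    if len(s) >= 2 and s[1] == ".":
        s = s[0] + s[2:]
    if s and s[0] in "PQ":
        s = s[0].lower() + s[1:]
    return s


@dataclass
class BandMap:
    """Per-assembly lookup from (chromosome, band label) to coordinates."""

    assembly: str
    bands: dict[str, list[CytoBand]] = field(default_factory=dict)

    # -- derived tables ----------------------------------------------------
    def __post_init__(self):
        self.chrom_lengths: dict[str, int] = {
            c: bl[-1].end for c, bl in self.bands.items()
        }
        self._acen_boundary: dict[str, int] = {}
        for chrom, bl in self.bands.items():
            acen = [b for b in bl if b.stain == "acen"]
            if len(acen) != 2 or acen[0].arm != "p" or acen[1].arm != "q":
                raise BandMapError(
                    f"{chrom}: expected adjacent p/q acen band pair, got "
                    f"{[b.label for b in acen]}"
                )
            if acen[0].end != acen[1].start:
                raise BandMapError(f"{chrom}: acen bands are not adjacent")
            self._acen_boundary[chrom] = acen[0].end

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self.bands, key=chrom_sort_key)

    def chrom_length(self, chrom: str) -> int:
        chrom = normalize_chrom(chrom)
        try:
            return self.chrom_lengths[chrom]
        except KeyError:
            raise BandResolutionError(chrom, "") from None

    def acen_boundary(self, chrom: str) -> int:
        """Base position where the p and q arms meet."""
        chrom = normalize_chrom(chrom)
        try:
            return self._acen_boundary[chrom]
        except KeyError:
            raise BandResolutionError(chrom, "") from None

    def whole_chrom(self, chrom: str) -> GenomicInterval:
        chrom = normalize_chrom(chrom)
        return GenomicInterval(chrom, 0, self.chrom_length(chrom))

    def arm_interval(self, chrom: str, arm: str) -> GenomicInterval:
        chrom = normalize_chrom(chrom)
        b = self.acen_boundary(chrom)
        if arm == "p":
            return GenomicInterval(chrom, 0, b)
        if arm == "q":
            return GenomicInterval(chrom, b, self.chrom_length(chrom))
        raise ValueError(f"arm must be 'p' or 'q', got {arm!r}")

    def resolve_band(self, chrom: str, band_label: str) -> GenomicInterval:
        """Resolve a band label to its genomic interval.

        Exact labels return that band.  A label that is coarser than the
        table (``q21`` where the table holds q21.1/q21.2/…) returns the
        union of all bands extending it; a label finer than the table
        (``q21.311``) falls back to the covering band.  ``p10``/``q10``
        return the zero-length centromere point; a bare arm letter returns
        the whole arm.
        """
        chrom = normalize_chrom(chrom)
        label = _normalize_label(band_label)
        m = _LABEL_RE.match(label)
        if not m:
            raise BandResolutionError(chrom, band_label)
        arm, digits = m.group(1), m.group(2)
        if digits is None:
            return self.arm_interval(chrom, arm)
        if digits == "10":
            # ISCN centromere breakpoint on the named arm's side
            b = self.acen_boundary(chrom)
            return GenomicInterval(chrom, b, b)
        bl = self.bands.get(chrom)
        if bl is None:
            raise BandResolutionError(chrom, band_label)
        flat = arm + digits.replace(".", "")
        exact = [b for b in bl if b.label == label]
        if exact:
            iv = exact[0]
            return GenomicInterval(chrom, iv.start, iv.end)
        # coarser query: union of all finer bands extending the query
        sub = [b for b in bl if b.flat_label.startswith(flat)]
        if sub:
            return GenomicInterval(
                chrom, min(b.start for b in sub), max(b.end for b in sub)
            )
        # finer query than the table: fall back to the covering band
        for k in range(len(flat) - 1, 1, -1):
            cover = [b for b in bl if b.flat_label == flat[:k]]
            if cover:
                return GenomicInterval(chrom, cover[0].start, cover[0].end)
        raise BandResolutionError(chrom, band_label)

    def to_text(self) -> str:
        """Re-serialize in UCSC cytoBand.txt format (sorted rows)."""
        lines = []
        for chrom in self.chromosomes:
            for b in self.bands[chrom]:
                lines.append(f"{b.chrom}\t{b.start}\t{b.end}\t{b.label}\t{b.stain}")
        return "\n".join(lines) + "\n"


def load_band_table(stream: TextIO | Iterable[str], assembly: str = "custom") -> BandMap:
    """Parse a UCSC cytoBand.txt stream into a validated :class:`BandMap`.

    Non-canonical contigs (alts, randoms) are silently dropped.  Rows are
    sorted by chromosome then start; each chromosome's bands must tile
    [0, chrom_length] without gaps or overlaps.
    """
    rows: dict[str, list[CytoBand]] = {}
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 5:
            raise BandMapError(f"line {lineno}: expected 5 tab-separated fields")
        chrom, start_s, end_s, label, stain = parts
        if chrom not in _CANONICAL_SET:
            continue
        try:
            start, end = int(start_s), int(end_s)
        except ValueError:
            raise BandMapError(f"line {lineno}: non-integer coordinate") from None
        if not (0 <= start < end):
            raise BandMapError(f"line {lineno}: bad coordinates {start}-{end}")
        if not label or label[0] not in "pq":
            raise BandMapError(f"line {lineno}: band name {label!r} lacks arm letter")
        rows.setdefault(chrom, []).append(
            CytoBand(chrom, label[0], label, start, end, stain)
        )
    if not rows:
        raise BandMapError("empty band table")
    for chrom, bl in rows.items():
        bl.sort(key=lambda b: b.start)
        if bl[0].start != 0:
            raise BandMapError(f"{chrom}: bands do not start at 0")
        for a, b in zip(bl, bl[1:]):
            if a.end != b.start:
                raise BandMapError(
                    f"{chrom}: tiling gap/overlap between {a.label} and {b.label}"
                )
    return BandMap(assembly=assembly, bands=rows)


def load_assembly(assembly: str = "hg19") -> BandMap:
    """Load one of the vendored UCSC band tables (hg18, hg19, grch38)."""
    key = assembly.lower().replace("hg38", "grch38")
    if key not in ASSEMBLIES:
        raise ValueError(f"unknown assembly {assembly!r}; choose from {ASSEMBLIES}")
    ref = resources.files("karyoconvert.data").joinpath(f"cytoBand_{key}.txt")
    with ref.open("r") as fh:
        return load_band_table(fh, assembly=key)
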