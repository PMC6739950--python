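"""Parsing of ISCN karyotype strings into typed clone and aberration records.

A karyotype such as ``47,X,+X[30]/48,XX,+7,+9[50]`` describes one or more
clones separated by ``/``, each with a modal chromosome number, a sex-
chromosome field, a comma-separated list of aberration terms, and an
optional bracketed cell count.  This module tokenizes that grammar into
:class:`CloneSpec` / :class:`Aberration` records; anything it cannot type
degrades to an ``unknown_term`` with a warning rather than an error, so a
large batch never aborts on one bad row.

The parser is whitespace-insensitive (``+ 7`` ≡ ``+7``, ``i (17q)`` ≡
``i(17q)``) and tolerant of ``?`` uncertainty marks, which are recorded but
otherwise ignored.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from enum import Enum

from .band_map import BandResolutionError, normalize_chrom

__all__ = [
    "Op",
    "Kind",
    "CellCount",
    "Aberration",
    "CloneSpec",
    "KaryotypeRecord",
    "Warning_",
    "split_clones",
    "parse_clone",
    "parse_term",
    "parse_karyotype",
    "diagnostic_dump",
]


class Op(str, Enum):
    PLUS = "plus"
    MINUS = "minus"
    NONE = "none"


class Kind(str, Enum):
    WHOLE_CHROM = "whole_chrom"
    DEL = "del"
    DUP = "dup"
    TRP = "trp"
    ISO = "iso"
    IDER = "ider"
    DER_WHOLE_ARM = "der_whole_arm"
    DER_TRANSLOCATION = "der_translocation"
    ADD = "add"
    TRANSLOCATION = "translocation"
    INVERSION = "inversion"
    INSERTION = "insertion"
    RING = "ring"
    MARKER = "marker"
    DMIN = "dmin"
    HSR = "hsr"
    IDEM = "idem"
    UNKNOWN = "unknown_term"


#: aberration kinds that consume a normal homolog of their base chromosome
#: when written without "+" (used for sex-chromosome baselines)
STRUCTURAL_KINDS = frozenset(
    {
        Kind.DEL,
        Kind.DUP,
        Kind.TRP,
        Kind.ISO,
        Kind.IDER,
        Kind.DER_WHOLE_ARM,
        Kind.DER_TRANSLOCATION,
        Kind.ADD,
        Kind.RING,
    }
)


@dataclass(frozen=True)
class CellCount:
    count: int | None = None          # None = unknown
    composite: bool = False           # from "[cp n]"

    @property
    def known(self) -> bool:
        return self.count is not None


@dataclass(frozen=True)
class Aberration:
    operator: Op
    kind: Kind
    chroms: tuple[str, ...] = ()
    breakpoints: tuple[tuple[str, ...], ...] = ()   # aligned with chroms
    uncertain: bool = False
    constitutional: bool = False
    raw: str = ""

    @property
    def base_chrom(self) -> str | None:
        return self.chroms[0] if self.chroms else None


@dataclass
class CloneSpec:
    ordinal: int
    modal_low: int | None = None
    modal_high: int | None = None
    ploidy_multiplier: int = 2
    sex_field: tuple[str, ...] = ()
    aberrations: list[Aberration] = field(default_factory=list)
    cells: CellCount = field(default_factory=CellCount)
    idem_flag: bool = False


@dataclass(frozen=True)
class Warning_:
    clone: int            # 1-based ordinal, 0 = record level
    term: str
    message: str


@dataclass
class KaryotypeRecord:
    sample_id: str
    clones: list[CloneSpec] = field(default_factory=list)
    warnings: list[Warning_] = field(default_factory=list)


# ---------------------------------------------------------------------------
# clone splitting

_CELLS_RE = re.compile(r"\[\s*(cp)?\s*(\d+)\s*\]\s*$", re.IGNORECASE)


def _split_top_level(text: str, sep: str) -> list[str]:
    """Split on *sep* outside any (), [] nesting."""
    out, depth, cur = [], 0, []
    for ch in text:
        if ch in "([":
            depth += 1
        elif ch in ")]":
            depth = max(0, depth - 1)
        if ch == sep and depth == 0:
            out.append("".join(cur))
            cur = []
        else:
            cur.append(ch)
    out.append("".join(cur))
    return out


def split_clones(karyotype: str) -> list[tuple[str, CellCount]]:
    """Split a karyotype into per-clone texts with their cell counts.

    Splits on ``/`` outside brackets/parentheses; a trailing ``[n]`` or
    ``[cp n]`` becomes the clone's cell count (unknown when absent).
    """
    if not karyotype or not karyotype.strip():
        raise ValueError("empty karyotype string")
    clones = []
    for part in _split_top_level(karyotype, "/"):
        part = part.strip()
        m = _CELLS_RE.search(part)
        if m:
            cells = CellCount(count=int(m.group(2)), composite=bool(m.group(1)))
            part = part[: m.start()].strip()
        else:
            cells = CellCount()
        clones.append((part, cells))
    return clones


# ---------------------------------------------------------------------------
# term parsing

_WS_RE = re.compile(r"\s+")
_MULT_RE = re.compile(r"[x×](\d+)$")
_WHOLE_RE = re.compile(r"^([+-])(\d{1,2}|[XYxy])$")
_MODAL_RE = re.compile(
    r"^(\?)?(\d+)(?:[~-](\d+))?\s*(?:<\s*(\d+)n\s*>)?(\?)?$"
)
_SEX_RE = re.compile(r"^[XYxy]+$")
_BAND_RE = re.compile(r"[pq](?:\d+(?:\.\d+)?)?")
_PAREN_TERM_RE = re.compile(
    r"^([+-])?(del|dup|trp|ider|der|add|inv|ins|dic|i|t|r)\((.*)$",
    re.IGNORECASE,
)

_KIND_BY_NAME = {
    "del": Kind.DEL,
    "dup": Kind.DUP,
    "trp": Kind.TRP,
    "i": Kind.ISO,
    "ider": Kind.IDER,
    "add": Kind.ADD,
    "t": Kind.TRANSLOCATION,
    "inv": Kind.INVERSION,
    "ins": Kind.INSERTION,
    "r": Kind.RING,
}


def _paren_groups(text: str) -> list[str] | None:
    """Parse '(a)(b)t(c)…' into the flat list of top-level groups and any
    bare identifiers between them; returns None on unbalanced parens."""
    groups, depth, cur, between = [], 0, [], []
    for ch in text:
        if ch == "(":
            if depth == 0:
                if "".join(between).strip():
                    groups.append("".join(between).strip())
                between = []
                cur = []
            else:
                cur.append(ch)
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                return None
            if depth == 0:
                groups.append("(" + "".join(cur) + ")")
            else:
                cur.append(ch)
        elif depth > 0:
            cur.append(ch)
        else:
            between.append(ch)
    if depth != 0:
        return None
    if "".join(between).strip():
        groups.append("".join(between).strip())
    return groups


def _parse_bands(group: str) -> list[str] | None:
    """Split a breakpoint group like 'q21.31q27.2' into band labels."""
    g = group.replace("?", "")
    if not g:
        return None
    labels = _BAND_RE.findall(g)
    if not labels or "".join(labels) != g:
        return None
    return labels


def _norm_chroms(items: list[str]) -> list[str] | None:
    out = []
    for c in items:
        c = c.replace("?", "").strip()
        try:
            out.append(normalize_chrom(c))
        except BandResolutionError:
            return None
    return out


def _unknown(raw: str, uncertain: bool = False) -> Aberration:
    return Aberration(Op.NONE, Kind.UNKNOWN, raw=raw, uncertain=uncertain)


def parse_term(term: str) -> list[Aberration]:
    """Parse a single comma-field into one or more typed aberrations.

    Returns a list because a trailing multiplier (``del(5)(q13)x2``) is
    expanded by repetition.  Never raises: unrecognized terms come back as
    a single ``unknown_term`` carrying the raw text.
    """
    raw = term.strip()
    compact = _WS_RE.sub("", raw)
    if not compact:
        return [_unknown(raw)]

    mult = 1
    m = _MULT_RE.search(compact)
    if m:
        mult = int(m.group(1))
        compact = compact[: m.start()]

    uncertain = "?" in compact
    constitutional = False
    ab = _parse_single(compact, raw, uncertain)
    if ab.kind is Kind.UNKNOWN and compact.endswith("c") and len(compact) > 1:
        retry = _parse_single(compact[:-1], raw, uncertain)
        if retry.kind is not Kind.UNKNOWN:
            ab, constitutional = retry, True
    if constitutional:
        ab = replace(ab, constitutional=True)
    return [ab] * mult


def _parse_single(compact: str, raw: str, uncertain: bool) -> Aberration:
    text = compact.replace("?", "")
    if not text:
        return _unknown(raw, uncertain)
    low = text.lower()

    if low == "idem":
        return Aberration(Op.NONE, Kind.IDEM, raw=raw, uncertain=uncertain)
    if low in ("sl", "sdl", "sdl1", "sdl2"):
        return _unknown(raw, uncertain)
    if low in ("+mar", "mar") or re.fullmatch(r"\+?\d*mar", low):
        op = Op.PLUS if low.startswith("+") else Op.NONE
        return Aberration(op, Kind.MARKER, raw=raw, uncertain=uncertain)
    if re.fullmatch(r"\+?\d*[~-]?\d*dmin", low):
        return Aberration(Op.NONE, Kind.DMIN, raw=raw, uncertain=uncertain)
    if low.startswith("hsr"):
        return Aberration(Op.NONE, Kind.HSR, raw=raw, uncertain=uncertain)
    if low in ("r", "+r"):
        return Aberration(
            Op.PLUS if low[0] == "+" else Op.NONE, Kind.RING, raw=raw,
            uncertain=uncertain,
        )

    m = _WHOLE_RE.match(text)
    if m:
        op = Op.PLUS if m.group(1) == "+" else Op.MINUS
        try:
            chrom = normalize_chrom(m.group(2))
        except BandResolutionError:
            return _unknown(raw, uncertain)
        return Aberration(op, Kind.WHOLE_CHROM, (chrom,), ((),), uncertain, raw=raw)

    m = _PAREN_TERM_RE.match(text)
    if not m:
        return _unknown(raw, uncertain)
    op = {"+": Op.PLUS, "-": Op.MINUS, None: Op.NONE}[m.group(1)]
    name = m.group(2).lower()
    # re-attach the leading '(' consumed by the regex
    groups = _paren_groups("(" + m.group(3))
    if not groups or not groups[0].startswith("("):
        return _unknown(raw, uncertain)

    def inner(g: str) -> str:
        return g[1:-1] if g.startswith("(") and g.endswith(")") else g

    if name == "der":
        return _parse_der(op, groups, raw, uncertain)
    if name == "ider":
        return _parse_ider(op, groups, raw, uncertain)
    if name == "i":
        return _parse_iso(op, groups, raw, uncertain)
    if name == "dic":
        return _unknown(raw, uncertain)

    kind = _KIND_BY_NAME[name]

    first = inner(groups[0])
    if name in ("t", "ins"):
        chroms = _norm_chroms(first.split(";"))
        if chroms is None:
            return _unknown(raw, uncertain)
        bps: tuple[tuple[str, ...], ...] = tuple(() for _ in chroms)
        if len(groups) > 1:
            parts = inner(groups[1]).split(";")
            parsed = [_parse_bands(p) for p in parts]
            if len(parsed) == len(chroms) and all(p for p in parsed):
                bps = tuple(tuple(p) for p in parsed)  # type: ignore[misc]
        return Aberration(op, kind, tuple(chroms), bps, uncertain, raw=raw)

    # single-chromosome paren terms: del/dup/trp/add/inv/r
    chroms = _norm_chroms([first])
    if chroms is None:
        return _unknown(raw, uncertain)
    if len(groups) < 2:
        if name == "r":
            return Aberration(op, Kind.RING, tuple(chroms), ((),), uncertain, raw=raw)
        return _unknown(raw, uncertain)
    bands = _parse_bands(inner(groups[1]))
    if bands is None:
        return _unknown(raw, uncertain)
    return Aberration(op, kind, tuple(chroms), (tuple(bands),), uncertain, raw=raw)


def _parse_iso(op: Op, groups: list[str], raw: str, uncertain: bool) -> Aberration:
    """i(17q), i(17)(q10), i(Xp) …"""
    first = groups[0][1:-1]
    m = re.fullmatch(r"([0-9XYxy]{1,2})([pq])?", first)
    if not m:
        return _unknown(raw, uncertain)
    chroms = _norm_chroms([m.group(1)])
    if chroms is None:
        return _unknown(raw, uncertain)
    arm = m.group(2)
    if arm is None:
        if len(groups) < 2:
            return _unknown(raw, uncertain)
        bands = _parse_bands(groups[1][1:-1])
        if not bands or bands[0] not in ("p10", "q10"):
            return _unknown(raw, uncertain)
        arm = bands[0][0]
    return Aberration(
        op, Kind.ISO, tuple(chroms), ((f"{arm}10",),), uncertain, raw=raw
    )


def _parse_ider(op: Op, groups: list[str], raw: str, uncertain: bool) -> Aberration:
    first = groups[0][1:-1]
    chroms = _norm_chroms([first])
    if chroms is None or len(groups) < 2:
        return _unknown(raw, uncertain)
    bands = _parse_bands(groups[1][1:-1])
    if not bands or bands[0] not in ("p10", "q10"):
        return _unknown(raw, uncertain)
    return Aberration(
        op, Kind.IDER, tuple(chroms), ((bands[0],),), uncertain, raw=raw
    )


def _parse_der(op: Op, groups: list[str], raw: str, uncertain: bool) -> Aberration:
    """der(1;19)(q10;p10) whole-arm form, or der(c)t(c;d)(b;b)… form."""
    first = groups[0][1:-1]
    if ";" in first:
        chroms = _norm_chroms(first.split(";"))
        if chroms is None or len(groups) < 2:
            return _unknown(raw, uncertain)
        parts = groups[1][1:-1].split(";")
        parsed = [_parse_bands(p) for p in parts]
        if (
            len(parsed) != len(chroms)
            or any(not p or len(p) != 1 for p in parsed)
            or any(p[0] not in ("p10", "q10") for p in parsed)  # type: ignore[index]
        ):
            return _unknown(raw, uncertain)
        return Aberration(
            op,
            Kind.DER_WHOLE_ARM,
            tuple(chroms),
            tuple((p[0],) for p in parsed),  # type: ignore[index]
            uncertain,
            raw=raw,
        )
    base = _norm_chroms([first])
    if base is None:
        return _unknown(raw, uncertain)
    # expect: t (c;d) (b1;b2) [t (d;e) (b3;b4) …]
    rest = groups[1:]
    chroms = [base[0]]
    bps: list[tuple[str, ...]] = [()]
    i = 0
    n_segments = 0
    while i < len(rest):
        if rest[i].lower() != "t" or i + 2 >= len(rest):
            return _unknown(raw, uncertain)
        cg, bg = rest[i + 1], rest[i + 2]
        if not cg.startswith("(") or not bg.startswith("("):
            return _unknown(raw, uncertain)
        seg_chroms = _norm_chroms(cg[1:-1].split(";"))
        seg_bands = [_parse_bands(p) for p in bg[1:-1].split(";")]
        if (
            seg_chroms is None
            or len(seg_chroms) != 2
            or len(seg_bands) != 2
            or any(not b or len(b) != 1 for b in seg_bands)
        ):
            return _unknown(raw, uncertain)
        if n_segments == 0:
            if seg_chroms[0] != base[0]:
                # allow der(c)t(d;c) orientation: swap so base comes first
                if seg_chroms[1] == base[0]:
                    seg_chroms = [seg_chroms[1], seg_chroms[0]]
                    seg_bands = [seg_bands[1], seg_bands[0]]
                else:
                    return _unknown(raw, uncertain)
            bps[0] = (seg_bands[0][0],)  # type: ignore[index]
            chroms.append(seg_chroms[1])
            bps.append((seg_bands[1][0],))  # type: ignore[index]
        else:
            # sequential assembly: first chrom of this t is the previous donor
            if seg_chroms[0] != chroms[-1]:
                if seg_chroms[1] == chroms[-1]:
                    seg_chroms = [seg_chroms[1], seg_chroms[0]]
                    seg_bands = [seg_bands[1], seg_bands[0]]
                else:
                    return _unknown(raw, uncertain)
            bps[-1] = bps[-1] + (seg_bands[0][0],)  # type: ignore[operator]
            chroms.append(seg_chroms[1])
            bps.append((seg_bands[1][0],))  # type: ignore[index]
        n_segments += 1
        i += 3
    if n_segments == 0:
        return _unknown(raw, uncertain)
    return Aberration(
        op, Kind.DER_TRANSLOCATION, tuple(chroms), tuple(bps), uncertain, raw=raw
    )


# ---------------------------------------------------------------------------
# clone parsing

def parse_clone(clone_text: str, ordinal: int) -> tuple[CloneSpec, list[Warning_]]:
    """Parse one clone's text (cell count already stripped)."""
    clone = CloneSpec(ordinal=ordinal)
    warnings: list[Warning_] = []
    fields = [f.strip() for f in _split_top_level(clone_text, ",")]
    fields = [f for f in fields if f]
    if not fields:
        warnings.append(Warning_(ordinal, clone_text, "empty clone"))
        return clone, warnings

    idx = 0
    m = _MODAL_RE.match(_WS_RE.sub("", fields[0]))
    if m:
        clone.modal_low = int(m.group(2))
        clone.modal_high = int(m.group(3)) if m.group(3) else clone.modal_low
        if m.group(4):
            clone.ploidy_multiplier = int(m.group(4))
        idx = 1
    else:
        warnings.append(
            Warning_(ordinal, fields[0], "unparseable modal number; treated as unknown")
        )
        if _SEX_RE.match(_WS_RE.sub("", fields[0])) or _looks_like_term(fields[0]):
            idx = 0
        else:
            idx = 1

    if idx < len(fields):
        cand = _WS_RE.sub("", fields[idx])
        if _SEX_RE.match(cand):
            clone.sex_field = tuple(c.upper() for c in cand)
            idx += 1

    for f in fields[idx:]:
        for ab in parse_term(f):
            if ab.kind is Kind.IDEM:
                clone.idem_flag = True
                if ordinal == 1:
                    warnings.append(
                        Warning_(ordinal, f, "'idem' in stemline clone ignored")
                    )
                continue
            if ab.kind is Kind.UNKNOWN:
                warnings.append(Warning_(ordinal, f, "unrecognized term; skipped"))
            if ab.uncertain:
                warnings.append(
                    Warning_(ordinal, f, "uncertain ('?') term processed as written")
                )
            if ab.constitutional:
                warnings.append(
                    Warning_(ordinal, f, "constitutional ('c') aberration included")
                )
            clone.aberrations.append(ab)
    return clone, warnings


def _looks_like_term(text: str) -> bool:
    t = _WS_RE.sub("", text)
    return bool(_WHOLE_RE.match(t) or _PAREN_TERM_RE.match(t))


def parse_karyotype(karyotype: str, sample_id: str = "sample_1") -> KaryotypeRecord:
    """Parse a full (possibly multi-clone) karyotype string."""
    rec = KaryotypeRecord(sample_id=sample_id)
    for i, (text, cells) in enumerate(split_clones(karyotype), start=1):
        clone, warns = parse_clone(text, i)
        clone.cells = cells
        rec.clones.append(clone)
        rec.warnings.extend(warns)
    # expand "idem": prepend the stemline's aberrations
    stem = rec.clones[0]
    for clone in rec.clones[1:]:
        if clone.idem_flag:
            clone.aberrations = list(stem.aberrations) + clone.aberrations
    _check_modal_consistency(rec)
    return rec


def _check_modal_consistency(rec: KaryotypeRecord) -> None:
    """Warn (never error) when the modal number disagrees with the sex field
    plus whole-chromosome gains/losses. Structural terms are not counted —
    many legitimately leave the chromosome count unchanged."""
    for clone in rec.clones:
        if clone.modal_low is None:
            continue
        n = 22 * clone.ploidy_multiplier + len(clone.sex_field)
        has_structural = False
        for ab in clone.aberrations:
            if ab.kind is Kind.WHOLE_CHROM:
                n += 1 if ab.operator is Op.PLUS else -1
            elif ab.kind is not Kind.UNKNOWN:
                has_structural = True
                if ab.operator is Op.PLUS:
                    n += 1
        if not has_structural and not (clone.modal_low <= n <= clone.modal_high):
            rec.warnings.append(
                Warning_(
                    clone.ordinal,
                    "",
                    f"modal number {clone.modal_low} inconsistent with "
                    f"aberration list (implies {n})",
                )
            )


def diagnostic_dump(rec: KaryotypeRecord) -> str:
    """One line per term: clone ordinal, kind, fields — for dialect debugging."""
    lines = []
    for clone in rec.clones:
        for ab in clone.aberrations:
            lines.append(
                f"{rec.sample_id}\t{clone.ordinal}\t{ab.operator.value}\t"
                f"{ab.kind.value}\t{','.join(ab.chroms)}\t"
                f"{';'.join('/'.join(b) for b in ab.breakpoints)}\t{ab.raw}"
            )
    for w in rec.warnings:
        lines.append(f"{rec.sample_id}\t{w.clone}\tWARNING\t{w.term}\t{w.message}")
    return "\n".join(lines)
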