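"""Fixture generation: toy band maps, random valid karyotypes with
constructively-built ground-truth copy-number profiles, and an ISCN
renderer for round-trip tests.

The generator works in an explicit homolog model: every clone's genome is
a list of homologs per chromosome, each homolog a list of (chrom, start,
end) pieces.  Events are applied by editing piece lists — a deletion
removes a span from one homolog, a derivative replaces homologs with an
assembled piece list — and the ground-truth profile is obtained by
counting per-base piece coverage and subtracting the baseline.  Because
the truth is built from pieces rather than from signed interval deltas, it
is an independent oracle for the sweep-based engine.

Self-contradictory stacks (deleting the same homolog twice, losing a
chromosome that is no longer there) are avoided by tracking which
homologs are still normal and available.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .band_map import BandMap, CytoBand, GenomicInterval, load_band_table
from .iscn import Aberration, CellCount, CloneSpec, Kind, Op

__all__ = [
    "SynthSpec",
    "TruthSegment",
    "TruthProfile",
    "make_toy_bandmap",
    "render_term",
    "render_clone",
    "render_karyotype",
    "sample_karyotype",
    "sample_batch",
    "DEFAULT_WEIGHTS",
]


# ---------------------------------------------------------------------------
# toy band maps

def make_toy_bandmap(
    n_chroms: int,
    bands_per_arm: int,
    chrom_length: int,
    seed: int = 0,
    sub_bands: int = 1,
) -> BandMap:
    """Build a small valid band map for tests.

    Each chromosome has ``bands_per_arm`` bands per arm (including the
    centromeric ``acen`` band, labelled p11/q11) tiling ``[0,
    chrom_length]`` with the acen pair meeting at the midpoint.  Non-acen
    bands may be split into ``sub_bands`` dotted sub-bands.  Deterministic
    under ``seed``.
    """
    if min(n_chroms, bands_per_arm, chrom_length) < 1:
        raise ValueError("all sizes must be >= 1")
    rng = random.Random(seed)
    lines = []
    mid = chrom_length // 2
    for ci in range(1, n_chroms + 1):
        chrom = f"chr{ci}"
        for arm, lo, hi in (("p", 0, mid), ("q", mid, chrom_length)):
            edges = _arm_edges(rng, lo, hi, bands_per_arm)
            # bands in coordinate order; on p the acen band (p11) is last,
            # on q it is first, numbering increases away from the centromere
            for j, (a, b) in enumerate(zip(edges, edges[1:])):
                idx = bands_per_arm - j if arm == "p" else j + 1
                label = f"{arm}1{idx}"
                stain = "acen" if idx == 1 else ("gpos50" if idx % 2 else "gneg")
                if idx == 1 or sub_bands == 1 or (b - a) < sub_bands:
                    lines.append(f"{chrom}\t{a}\t{b}\t{label}\t{stain}")
                else:
                    sub = _arm_edges(rng, a, b, sub_bands)
                    subrange = range(sub_bands, 0, -1) if arm == "p" else range(1, sub_bands + 1)
                    for k, (sa, sb) in zip(subrange, zip(sub, sub[1:])):
                        lines.append(f"{chrom}\t{sa}\t{sb}\t{label}.{k}\t{stain}")
    return load_band_table(lines, assembly="toy")


def _arm_edges(rng: random.Random, lo: int, hi: int, n: int) -> list[int]:
    """n sub-intervals of [lo, hi): sorted distinct internal edges."""
    if n == 1:
        return [lo, hi]
    internal = sorted(rng.sample(range(lo + 1, hi), n - 1))
    return [lo] + internal + [hi]


# ---------------------------------------------------------------------------
# ISCN rendering

def _short(chrom: str) -> str:
    return chrom[3:]


def render_term(ab: Aberration) -> str:
    """Render a typed aberration back to ISCN text."""
    sign = {Op.PLUS: "+", Op.MINUS: "-", Op.NONE: ""}[ab.operator]
    k = ab.kind
    if k is Kind.WHOLE_CHROM:
        return f"{sign}{_short(ab.chroms[0])}"
    if k in (Kind.DEL, Kind.DUP, Kind.TRP, Kind.ADD, Kind.INVERSION, Kind.RING):
        name = {
            Kind.DEL: "del", Kind.DUP: "dup", Kind.TRP: "trp",
            Kind.ADD: "add", Kind.INVERSION: "inv", Kind.RING: "r",
        }[k]
        bands = "".join(ab.breakpoints[0]) if ab.breakpoints else ""
        if not bands:
            return f"{sign}{name}({_short(ab.chroms[0])})" if k is Kind.RING else ab.raw
        return f"{sign}{name}({_short(ab.chroms[0])})({bands})"
    if k in (Kind.ISO, Kind.IDER):
        name = "i" if k is Kind.ISO else "ider"
        return f"{sign}{name}({_short(ab.chroms[0])})({ab.breakpoints[0][0]})"
    if k is Kind.DER_WHOLE_ARM:
        cs = ";".join(_short(c) for c in ab.chroms)
        bs = ";".join(b[0] for b in ab.breakpoints)
        return f"{sign}der({cs})({bs})"
    if k is Kind.DER_TRANSLOCATION:
        out = f"{sign}der({_short(ab.chroms[0])})"
        prev_exit = ab.breakpoints[0][0]
        for i in range(1, len(ab.chroms)):
            entry = ab.breakpoints[i][0]
            out += (
                f"t({_short(ab.chroms[i - 1])};{_short(ab.chroms[i])})"
                f"({prev_exit};{entry})"
            )
            prev_exit = (
                ab.breakpoints[i][1] if len(ab.breakpoints[i]) > 1 else None
            )
        return out
    if k is Kind.TRANSLOCATION:
        cs = ";".join(_short(c) for c in ab.chroms)
        bs = ";".join("".join(b) for b in ab.breakpoints)
        return f"{sign}t({cs})({bs})" if bs.strip(";") else f"{sign}t({cs})"
    if k is Kind.MARKER:
        return "+mar"
    if k is Kind.DMIN:
        return "dmin"
    if k is Kind.HSR:
        return "hsr"
    if k is Kind.IDEM:
        return "idem"
    return ab.raw


def render_clone(clone: CloneSpec, modal: int | None = None) -> str:
    fields = []
    m = modal if modal is not None else clone.modal_low
    modal_s = str(m) if m is not None else "46"
    if clone.ploidy_multiplier != 2:
        modal_s += f"<{clone.ploidy_multiplier}n>"
    fields.append(modal_s)
    if clone.sex_field:
        fields.append("".join(clone.sex_field))
    fields.extend(render_term(ab) for ab in clone.aberrations)
    text = ",".join(fields)
    if clone.cells.known:
        cp = "cp " if clone.cells.composite else ""
        text += f"[{cp}{clone.cells.count}]"
    return text


def render_karyotype(clones: list[CloneSpec]) -> str:
    return "/".join(render_clone(c) for c in clones)


def add_dialect_noise(text: str, rng: random.Random) -> str:
    """Inject spaces after '+'/',' the way transcribed karyotypes do."""
    out = []
    for ch in text:
        out.append(ch)
        if ch in "+,()" and rng.random() < 0.4:
            out.append(" ")
    return "".join(out)


# ---------------------------------------------------------------------------
# random clone generation with constructive ground truth

@dataclass(frozen=True)
class TruthSegment:
    chrom: str
    start: int
    end: int
    delta: int


@dataclass
class TruthProfile:
    clone_id: str
    segments: list[TruthSegment] = field(default_factory=list)


DEFAULT_WEIGHTS: dict[str, float] = {
    "gain": 0.18,
    "loss": 0.10,
    "del_terminal": 0.12,
    "del_interstitial": 0.12,
    "dup": 0.09,
    "trp": 0.03,
    "iso": 0.08,
    "der_whole_arm": 0.06,
    "der_translocation": 0.10,
    "der_three_way": 0.02,
    "add": 0.06,
    "ring": 0.03,
    "translocation": 0.06,
    "inversion": 0.04,
    "marker": 0.01,
}


@dataclass
class SynthSpec:
    """Parameters of the random karyotype generator."""

    seed: int = 0
    n_samples: int = 10
    clones_per_sample: tuple[int, int] = (1, 2)
    events_per_clone: tuple[int, int] = (0, 4)
    event_kind_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_WEIGHTS)
    )
    bandmap: BandMap | None = None      # defaults to a toy map
    dialect_noise: bool = False

    def __post_init__(self):
        total = sum(self.event_kind_weights.values())
        if total <= 0:
            raise ValueError("event weights must sum to a positive number")
        self.event_kind_weights = {
            k: v / total for k, v in self.event_kind_weights.items()
        }
        if (
            self.clones_per_sample[0] > self.clones_per_sample[1]
            or self.events_per_clone[0] > self.events_per_clone[1]
        ):
            raise ValueError("empty range")


Piece = tuple[str, int, int]


class _CloneBuilder:
    """Homolog piece-list model of one clone under construction."""

    def __init__(self, bmap: BandMap, rng: random.Random, sex: str):
        self.bmap = bmap
        self.rng = rng
        self.autosomes = [c for c in bmap.chromosomes if c not in ("chrX", "chrY")]
        self.homologs: dict[str, list[list[Piece]]] = {}
        self.available: dict[str, int] = {}     # untouched normal homologs
        self.sex_listing = list(sex)            # rendered sex field
        self.consumed_sex: dict[str, int] = {"chrX": 0, "chrY": 0}
        self.aberrations: list[Aberration] = []
        for c in self.autosomes:
            self.homologs[c] = [self._full(c), self._full(c)]
            self.available[c] = 2
        for s in ("X", "Y"):
            chrom = f"chr{s}"
            if chrom in bmap.bands:
                n = sex.count(s)
                self.homologs[chrom] = [self._full(chrom) for _ in range(n)]
                self.available[chrom] = n

    def _full(self, chrom: str) -> list[Piece]:
        return [(chrom, 0, self.bmap.chrom_length(chrom))]

    # -- helpers -----------------------------------------------------------
    def _pick_chrom(self, pool: list[str], need_normal: bool = True) -> str | None:
        cands = [c for c in pool if not need_normal or self.available.get(c, 0) > 0]
        if not cands:
            return None
        return self.rng.choice(cands)

    def _take_normal(self, chrom: str) -> int:
        """Consume one untouched homolog of chrom; returns its index."""
        assert self.available[chrom] > 0
        self.available[chrom] -= 1
        if chrom in ("chrX", "chrY"):
            # structural events act on a homolog no longer listed in the
            # sex field; track it so the baseline stays consistent
            sym = chrom[3:]
            if sym in self.sex_listing:
                self.sex_listing.remove(sym)
            self.consumed_sex[chrom] += 1
        for i, h in enumerate(self.homologs[chrom]):
            if h == self._full(chrom):
                return i
        raise AssertionError("no normal homolog found")

    def _bands(self, chrom: str, arm: str | None = None) -> list[CytoBand]:
        bl = self.bmap.bands[chrom]
        return [b for b in bl if arm is None or b.arm == arm]

    def _rand_band(self, chrom: str, arm: str | None = None) -> CytoBand:
        return self.rng.choice(self._bands(chrom, arm))

    def _record(self, op: Op, kind: Kind, chroms: tuple[str, ...],
                bps: tuple[tuple[str, ...], ...]) -> None:
        ab = Aberration(op, kind, chroms, bps)
        self.aberrations.append(ab)

    # -- events ------------------------------------------------------------
    def apply_event(self, kind: str) -> bool:
        """Try to apply one event; returns False when impossible."""
        return getattr(self, f"_ev_{kind}")()

    def _ev_gain(self) -> bool:
        pool = list(self.homologs)
        chrom = self._pick_chrom(pool, need_normal=False)
        if chrom is None or not self.homologs[chrom]:
            chrom = self._pick_chrom(self.autosomes, need_normal=False)
        self.homologs[chrom].append(self._full(chrom))
        self.available[chrom] += 1
        self._record(Op.PLUS, Kind.WHOLE_CHROM, (chrom,), ((),))
        return True

    def _ev_loss(self) -> bool:
        chrom = self._pick_chrom(list(self.homologs))
        if chrom is None:
            return False
        self.available[chrom] -= 1
        if chrom in ("chrX", "chrY"):
            # whole-chromosome loss keeps the sex field listing; the lost
            # homolog was a listed one (net copies = listing - 1)
            pass
        i = next(
            i for i, h in enumerate(self.homologs[chrom]) if h == self._full(chrom)
        )
        del self.homologs[chrom][i]
        self._record(Op.MINUS, Kind.WHOLE_CHROM, (chrom,), ((),))
        return True

    def _structural_target(self) -> str | None:
        return self._pick_chrom(list(self.homologs))

    def _ev_del_terminal(self) -> bool:
        chrom = self._structural_target()
        if chrom is None:
            return False
        i = self._take_normal(chrom)
        b = self._rand_band(chrom)
        if b.arm == "q":
            self.homologs[chrom][i] = [(chrom, 0, b.start)] if b.start else []
        else:
            L = self.bmap.chrom_length(chrom)
            self.homologs[chrom][i] = [(chrom, b.end, L)] if b.end < L else []
        self._record(Op.NONE, Kind.DEL, (chrom,), ((b.label,),))
        return True

    def _two_band_span(self, chrom: str) -> tuple[CytoBand, CytoBand]:
        b1, b2 = self._rand_band(chrom), self._rand_band(chrom)
        if b1.start > b2.start:
            b1, b2 = b2, b1
        return b1, b2

    def _ev_del_interstitial(self) -> bool:
        chrom = self._structural_target()
        if chrom is None:
            return False
        i = self._take_normal(chrom)
        b1, b2 = self._two_band_span(chrom)
        L = self.bmap.chrom_length(chrom)
        kept = []
        if b1.start > 0:
            kept.append((chrom, 0, b1.start))
        if b2.end < L:
            kept.append((chrom, b2.end, L))
        self.homologs[chrom][i] = kept
        self._record(Op.NONE, Kind.DEL, (chrom,), ((b1.label, b2.label),))
        return True

    def _ev_dup(self, extra: int = 1, kind: Kind = Kind.DUP) -> bool:
        chrom = self._structural_target()
        if chrom is None:
            return False
        i = self._take_normal(chrom)
        b1, b2 = self._two_band_span(chrom)
        h = self.homologs[chrom][i]
        h.extend([(chrom, b1.start, b2.end)] * extra)
        self._record(Op.NONE, kind, (chrom,), ((b1.label, b2.label),))
        return True

    def _ev_trp(self) -> bool:
        return self._ev_dup(extra=2, kind=Kind.TRP)

    def _ev_iso(self) -> bool:
        chrom = self._structural_target()
        if chrom is None:
            return False
        arm = self.rng.choice("pq")
        iv = self.bmap.arm_interval(chrom, arm)
        supernumerary = self.rng.random() < 0.3
        if supernumerary:
            self.homologs[chrom].append([(chrom, iv.start, iv.end)] * 2)
            self._record(Op.PLUS, Kind.ISO, (chrom,), ((f"{arm}10",),))
        else:
            i = self._take_normal(chrom)
            self.homologs[chrom][i] = [(chrom, iv.start, iv.end)] * 2
            self._record(Op.NONE, Kind.ISO, (chrom,), ((f"{arm}10",),))
        return True

    def _ev_der_whole_arm(self) -> bool:
        cands = [c for c in self.autosomes if self.available[c] > 0]
        if len(cands) < 2:
            return False
        c1, c2 = self.rng.sample(cands, 2)
        a1, a2 = self.rng.choice("pq"), self.rng.choice("pq")
        i1, i2 = self._take_normal(c1), self._take_normal(c2)
        iv1, iv2 = self.bmap.arm_interval(c1, a1), self.bmap.arm_interval(c2, a2)
        # the derivative replaces one homolog of each participant
        self.homologs[c1][i1] = [(c1, iv1.start, iv1.end), (c2, iv2.start, iv2.end)]
        del self.homologs[c2][i2]
        self._record(
            Op.NONE, Kind.DER_WHOLE_ARM, (c1, c2), ((f"{a1}10",), (f"{a2}10",))
        )
        return True

    def _donor_piece(self, chrom: str, b: CytoBand) -> Piece:
        if b.arm == "p":
            return (chrom, 0, b.end)
        return (chrom, b.start, self.bmap.chrom_length(chrom))

    def _base_piece(self, chrom: str, b: CytoBand) -> Piece:
        if b.arm == "p":
            return (chrom, b.start, self.bmap.chrom_length(chrom))
        return (chrom, 0, b.end)

    def _ev_der_translocation(self, three_way: bool = False) -> bool:
        pool = [c for c in self.homologs if self.available.get(c, 0) > 0]
        others = [c for c in self.autosomes]
        if not pool or len(others) < (3 if three_way else 2):
            return False
        base = self.rng.choice(pool)
        donors = self.rng.sample([c for c in others if c != base],
                                 2 if three_way else 1)
        supernumerary = self.rng.random() < 0.4
        b0 = self._rand_band(base)
        pieces = [self._base_piece(base, b0)]
        bps: list[tuple[str, ...]] = [(b0.label,)]
        chroms = [base]
        if not three_way:
            d = donors[0]
            bd = self._rand_band(d)
            pieces.append(self._donor_piece(d, bd))
            chroms.append(d)
            bps.append((bd.label,))
        else:
            d1, d2 = donors
            entry = self._rand_band(d1)
            exit_ = self._rand_band(d1)
            lo = min(entry.start, exit_.start)
            hi = max(entry.end, exit_.end)
            pieces.append((d1, lo, hi))
            chroms.append(d1)
            bps.append((entry.label, exit_.label))
            bd2 = self._rand_band(d2)
            pieces.append(self._donor_piece(d2, bd2))
            chroms.append(d2)
            bps.append((bd2.label,))
        if supernumerary:
            self.homologs[base].append(pieces)
            op = Op.PLUS
        else:
            i = self._take_normal(base)
            self.homologs[base][i] = pieces
            op = Op.NONE
        self._record(op, Kind.DER_TRANSLOCATION, tuple(chroms), tuple(bps))
        return True

    def _ev_der_three_way(self) -> bool:
        return self._ev_der_translocation(three_way=True)

    def _ev_add(self) -> bool:
        chrom = self._structural_target()
        if chrom is None:
            return False
        i = self._take_normal(chrom)
        b = self._rand_band(chrom)
        # material distal to the breakpoint is replaced by unknown content
        self.homologs[chrom][i] = [self._base_piece(chrom, b)]
        self._record(Op.NONE, Kind.ADD, (chrom,), ((b.label,),))
        return True

    def _ev_ring(self) -> bool:
        chrom = self._structural_target()
        if chrom is None:
            return False
        i = self._take_normal(chrom)
        b1 = self._rand_band(chrom, "p")
        b2 = self._rand_band(chrom, "q")
        self.homologs[chrom][i] = [(chrom, b1.start, b2.end)]
        self._record(Op.NONE, Kind.RING, (chrom,), ((b1.label, b2.label),))
        return True

    def _ev_translocation(self) -> bool:
        cands = [c for c in self.autosomes if self.available[c] > 0]
        if len(cands) < 2:
            return False
        c1, c2 = self.rng.sample(cands, 2)
        # balanced: no material change; the homologs stop being "normal"
        self.available[c1] -= 1
        self.available[c2] -= 1
        b1, b2 = self._rand_band(c1), self._rand_band(c2)
        self._record(
            Op.NONE, Kind.TRANSLOCATION, (c1, c2), ((b1.label,), (b2.label,))
        )
        return True

    def _ev_inversion(self) -> bool:
        cands = [c for c in self.autosomes if self.available[c] > 0]
        if not cands:
            return False
        chrom = self.rng.choice(cands)
        self.available[chrom] -= 1
        b1, b2 = self._two_band_span(chrom)
        self._record(Op.NONE, Kind.INVERSION, (chrom,), ((b1.label, b2.label),))
        return True

    def _ev_marker(self) -> bool:
        self._record(Op.PLUS, Kind.MARKER, (), ())
        return True

    # -- outputs -----------------------------------------------------------
    def modal_number(self) -> int:
        n = sum(len(hs) for hs in self.homologs.values())
        n += sum(1 for ab in self.aberrations if ab.kind is Kind.MARKER)
        return n

    def baseline(self, chrom: str) -> int:
        if chrom in ("chrX", "chrY"):
            return self.sex_listing.count(chrom[3:]) + self.consumed_sex[chrom]
        return 2

    def truth_segments(self) -> list[TruthSegment]:
        """Per-base coverage minus baseline, by midpoint counting."""
        segs: list[TruthSegment] = []
        for chrom in self.bmap.chromosomes:
            if chrom not in self.homologs:
                continue
            pieces = [p for h in self.homologs[chrom] for p in h if p[0] == chrom]
            # pieces may name other chromosomes (derivatives): collect those too
            base = self.baseline(chrom)
            foreign = [
                p
                for c2, hs in self.homologs.items()
                if c2 != chrom
                for h in hs
                for p in h
                if p[0] == chrom
            ]
            pieces = pieces + foreign
            if not pieces and base == 0:
                continue
            points = sorted(
                {0, self.bmap.chrom_length(chrom)}
                | {p[1] for p in pieces}
                | {p[2] for p in pieces}
            )
            run: TruthSegment | None = None
            for a, b in zip(points, points[1:]):
                mid = (a + b) / 2
                cov = sum(1 for p in pieces if p[1] <= mid < p[2])
                delta = cov - base
                if delta == 0:
                    if run:
                        segs.append(run)
                        run = None
                    continue
                if run and run.end == a and run.delta == delta:
                    run = TruthSegment(chrom, run.start, b, delta)
                else:
                    if run:
                        segs.append(run)
                    run = TruthSegment(chrom, a, b, delta)
            if run:
                segs.append(run)
        return segs


def sample_karyotype(
    spec: SynthSpec, sample_id: str = "sample_1", rng: random.Random | None = None
) -> tuple[str, list[CloneSpec], list[TruthProfile]]:
    """Draw one (possibly multi-clone) karyotype with its ground truth.

    Returns the rendered ISCN string, the true clone specs, and the
    constructively-built truth profiles (one per clone).
    """
    rng = rng if rng is not None else random.Random(spec.seed)
    bmap = spec.bandmap if spec.bandmap is not None else make_toy_bandmap(
        4, 4, 200_000, seed=spec.seed, sub_bands=2
    )
    n_clones = rng.randint(*spec.clones_per_sample)
    kinds = sorted(spec.event_kind_weights)
    weights = [spec.event_kind_weights[k] for k in kinds]
    sex = rng.choice(["XX", "XY"]) if "chrY" in bmap.bands else "XX"
    clones: list[CloneSpec] = []
    truths: list[TruthProfile] = []
    for ordinal in range(1, n_clones + 1):
        builder = _CloneBuilder(bmap, rng, sex)
        n_events = rng.randint(*spec.events_per_clone)
        attempts = 0
        applied = 0
        while applied < n_events and attempts < n_events * 10:
            attempts += 1
            kind = rng.choices(kinds, weights=weights)[0]
            if builder.apply_event(kind):
                applied += 1
        clone = CloneSpec(
            ordinal=ordinal,
            modal_low=builder.modal_number(),
            modal_high=builder.modal_number(),
            sex_field=tuple(builder.sex_listing),
            aberrations=builder.aberrations,
            cells=CellCount(count=rng.randint(2, 100)),
        )
        clones.append(clone)
        truths.append(
            TruthProfile(
                clone_id=f"{sample_id}_{ordinal}",
                segments=builder.truth_segments(),
            )
        )
    text = render_karyotype(clones)
    if spec.dialect_noise:
        text = add_dialect_noise(text, rng)
    return text, clones, truths


def sample_batch(
    spec: SynthSpec,
) -> list[tuple[str, str, list[CloneSpec], list[TruthProfile]]]:
    """Draw ``spec.n_samples`` karyotypes: (sample_id, iscn, truth clones,
    truth profiles)."""
    rng = random.Random(spec.seed)
    out = []
    for i in range(1, spec.n_samples + 1):
        sid = f"S_{i}"
        text, clones, truths = sample_karyotype(spec, sid, rng)
        out.append((sid, text, clones, truths))
    return out
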