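"""Block-level karyotype model and rearrangement operators.

The model represents a gametic chromosome complement as ordered, oriented
segments of conserved genomic blocks, with exactly one active centromere per
chromosome.  The coordinate system is the 22 genomic blocks (A-X, with K-L
and M-N atomic) of the Ancestral Crucifer Karyotype (ACK, n = 8, AK1-AK8),
the inferred ancestral genome of crucifer Lineage I.

Rearrangement operators implemented:

* whole-genome duplication (WGD) - every chromosome duplicated as a second
  homeolog copy;
* end-to-end translocation (EET) - two chromosomes joined at their termini;
  the dicentric fusion is resolved by eliminating one named centromere;
* reciprocal translocation - exchange of the terminal (acentric) fragments
  distal to two breakpoints on two chromosomes;
* unequal translocation - a reciprocal translocation whose second breakpoint
  is a chromosome terminus, i.e. donation of a terminal fragment;
* pericentric inversion - reversal of an interval whose breakpoints flank
  the centromere.

Breakpoints may fall on segment boundaries or inside a block, in which case
the block is split into sub-blocks; sub-blocks are display-labelled a, b, c
in ancestral coordinate order per homeolog copy (Fa, Fb, Fc ...).

Every operator except WGD conserves the multiset of (block, copy,
sub-interval) coverage exactly; WGD doubles it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, NamedTuple, Sequence

#: The 22 genomic blocks of the ACK, in ancestral order.  "K-L" and "M-N"
#: are atomic identities (single painting units).
BLOCKS: tuple[str, ...] = (
    "A", "B", "C", "D", "E", "F", "G", "H", "I", "J",
    "K-L", "M-N", "O", "P", "Q", "R", "S", "T", "U", "V", "W", "X",
)

_BLOCK_SET = frozenset(BLOCKS)

HEAD = "head"
TAIL = "tail"

FORMAT_KARYOTYPE = "karyoploid-karyotype/1"
FORMAT_SCENARIO = "karyoploid-scenario/1"


class KaryotypeError(ValueError):
    """Raised when an operator precondition is violated."""


class ConfigError(ValueError):
    """Raised when a packaged or user-supplied table is malformed."""


class Segment(NamedTuple):
    """An oriented sub-interval of one homeolog copy of a genomic block.

    ``start``/``end`` are fractions of the ancestral block in [0, 1]
    (half-open [start, end)); ``orient`` is +1 when the segment is read in
    ancestral direction, -1 when reversed; ``copy`` is the homeolog index
    (1 before WGD, 1 or 2 after).
    """

    block: str
    copy: int
    start: float
    end: float
    orient: int

    def reversed_(self) -> "Segment":
        return Segment(self.block, self.copy, self.start, self.end, -self.orient)


class Chromosome(NamedTuple):
    """An ordered reading of segments with one centromere.

    ``cen`` counts the segments left of the centromere (0 < cen < number of
    segments: the centromere sits strictly between two segments at this
    block-level resolution).  ``history`` records e.g. eliminated
    centromeres; it never participates in structural equality.
    """

    name: str
    segments: tuple[Segment, ...]
    cen: int
    history: tuple[str, ...] = ()

    def validate(self) -> None:
        if not self.segments:
            raise KaryotypeError(f"chromosome {self.name!r} has no segments")
        if not (0 < self.cen < len(self.segments)):
            raise KaryotypeError(
                f"chromosome {self.name!r}: centromere index {self.cen} not "
                f"strictly inside 1..{len(self.segments) - 1}"
            )
        for seg in self.segments:
            if seg.block not in _BLOCK_SET:
                raise KaryotypeError(f"unknown block {seg.block!r}")
            if not (0.0 <= seg.start < seg.end <= 1.0):
                raise KaryotypeError(f"bad segment interval {seg}")


def reverse_fragment(segs: Sequence[Segment]) -> tuple[Segment, ...]:
    """Reverse a run of segments, flipping each orientation."""
    return tuple(s.reversed_() for s in reversed(segs))


def reverse_chromosome(c: Chromosome) -> Chromosome:
    """The same chromosome read from the other telomere."""
    return Chromosome(
        c.name, reverse_fragment(c.segments), len(c.segments) - c.cen, c.history
    )


_CEN_TOKEN = ("CEN",)


def normalize_chromosome(c: Chromosome) -> Chromosome:
    """Merge adjacent segments that continue the same block copy in
    ancestral order and orientation (never across the centromere).

    A cut that leaves both parts abutting in their original arrangement is
    physically invisible, so canonical comparison ignores it.
    """
    segs: list[Segment] = []
    cen = c.cen
    for i, s in enumerate(c.segments):
        if segs and i != c.cen:
            p = segs[-1]
            if (
                p.block == s.block
                and p.copy == s.copy
                and p.orient == s.orient
                and (
                    (s.orient > 0 and p.end == s.start)
                    or (s.orient < 0 and p.start == s.end)
                )
            ):
                lo = min(p.start, s.start)
                hi = max(p.end, s.end)
                segs[-1] = Segment(p.block, p.copy, lo, hi, p.orient)
                if i < c.cen:
                    cen -= 1
                continue
        segs.append(s)
    if len(segs) == len(c.segments):
        return c
    return Chromosome(c.name, tuple(segs), cen, c.history)


def _reading(c: Chromosome, copy_blind: bool) -> tuple:
    toks: list[tuple] = []
    for i, s in enumerate(c.segments):
        if i == c.cen:
            toks.append(_CEN_TOKEN)
        if copy_blind:
            toks.append((s.block, s.start, s.end, s.orient))
        else:
            toks.append((s.block, s.copy, s.start, s.end, s.orient))
    return tuple(toks)


def canonical_form(c: Chromosome, copy_blind: bool = True) -> tuple:
    """Orientation-free canonical token sequence of a chromosome.

    Returns the lexicographically smaller of the forward reading and the
    reversed reading with flipped orientations (centromere mirrored), so a
    chromosome and its full reversal map to the same key.  Trivial cuts
    (adjacent sub-blocks in unbroken ancestral arrangement) are merged
    first.
    """
    c = normalize_chromosome(c)
    fwd = _reading(c, copy_blind)
    rev = _reading(reverse_chromosome(c), copy_blind)
    return min(fwd, rev)


@dataclass(frozen=True)
class Karyotype:
    """A gametic (n) chromosome complement.

    The reported diploid number is always ``2 * n``; the stored complement
    itself is haploid-phase, matching how painting data are read off
    meiotic complements.
    """

    chromosomes: tuple[Chromosome, ...]

    def validate(self) -> "Karyotype":
        for c in self.chromosomes:
            c.validate()
        return self

    @property
    def n(self) -> int:
        return len(self.chromosomes)

    @property
    def two_n(self) -> int:
        return 2 * len(self.chromosomes)

    def get(self, name: str) -> Chromosome:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KaryotypeError(f"no chromosome named {name!r}")

    def names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.chromosomes)

    def replace_chromosomes(
        self, drop: Iterable[str], add: Iterable[Chromosome]
    ) -> "Karyotype":
        dropset = set(drop)
        kept = [c for c in self.chromosomes if c.name not in dropset]
        return Karyotype(tuple(kept) + tuple(add))

    def canonical_key(self, copy_blind: bool = True) -> tuple:
        """Sorted multiset of chromosome canonical forms (name-free)."""
        return tuple(
            sorted(canonical_form(c, copy_blind) for c in self.chromosomes)
        )

    def same_as(self, other: "Karyotype", copy_blind: bool = True) -> bool:
        """Structural equality: reversal-invariant, name-blind; copy-blind
        by default because painting cannot phase homeolog copies."""
        return self.canonical_key(copy_blind) == other.canonical_key(copy_blind)

    # -- sub-block labelling ------------------------------------------------

    def cut_table(self) -> dict[tuple[str, int], list[float]]:
        """Interior cut points per (block, copy), ancestral order."""
        cuts: dict[tuple[str, int], set[float]] = {}
        for c in self.chromosomes:
            for s in c.segments:
                key = (s.block, s.copy)
                pts = cuts.setdefault(key, set())
                if s.start > 0.0:
                    pts.add(s.start)
                if s.end < 1.0:
                    pts.add(s.end)
        return {k: sorted(v) for k, v in cuts.items()}

    def segment_label(self, seg: Segment, cuts=None) -> str:
        """Display label of a segment: block name, plus a/b/c when its
        block copy is cut (letters follow ancestral coordinate order)."""
        if cuts is None:
            cuts = self.cut_table()
        pts = cuts.get((seg.block, seg.copy), [])
        if not pts:
            return seg.block
        edges = [0.0] + pts + [1.0]
        rank = edges.index(seg.start)
        return f"{seg.block}{'abcdefgh'[rank]}"

    def labels(self, chrom: Chromosome, with_cen: bool = False) -> tuple[str, ...]:
        """Block-label reading of one chromosome (e.g. Fa, T, S, K-L, M-N)."""
        cuts = self.cut_table()
        out: list[str] = []
        for i, s in enumerate(chrom.segments):
            if with_cen and i == chrom.cen:
                out.append("CEN")
            out.append(self.segment_label(s, cuts))
        return tuple(out)

    def composition(self, chrom: Chromosome) -> str:
        """Printed-style composition string, e.g. ``Fa+T+S+(K-L)+(M-N)``."""
        def disp(lbl: str) -> str:
            return f"({lbl})" if lbl.startswith(("K-L", "M-N")) else lbl

        return "+".join(disp(l) for l in self.labels(chrom))

    # -- content accounting -------------------------------------------------

    def block_coverage(self) -> dict[tuple[str, int], float]:
        """Total covered fraction per (block, copy); 1.0 means the whole
        ancestral block copy is present."""
        cov: dict[tuple[str, int], float] = {}
        for c in self.chromosomes:
            for s in c.segments:
                key = (s.block, s.copy)
                cov[key] = cov.get(key, 0.0) + (s.end - s.start)
        return cov

    def content_multiset(self) -> tuple:
        """Sorted multiset of (block, copy, start, end) coverage intervals;
        conserved by every operator except WGD (which doubles it)."""
        return tuple(
            sorted(
                (s.block, s.copy, s.start, s.end)
                for c in self.chromosomes
                for s in c.segments
            )
        )


# ---------------------------------------------------------------------------
# ACK construction
# ---------------------------------------------------------------------------

#: chromosome -> (upper arm blocks, lower arm blocks); the arm split of the
#: ACK reference.  AK7 is taken as S,T | U (the alternative S | T,U yields
#: the same AK5/AK7 fusion once the AK7 centromere is eliminated); the
#: packaged TSV can be overridden by the user.
_ACK_RESOURCE = "ack_blocks.tsv"


def _load_ack_table(path=None) -> list[tuple[str, list[str], list[str]]]:
    if path is None:
        text = (
            resources.files("karyoploid.data").joinpath(_ACK_RESOURCE).read_text()
        )
    else:
        with open(path) as fh:
            text = fh.read()
    rows: list[tuple[str, list[str], list[str]]] = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ConfigError(f"ACK table row needs 3 tab fields: {line!r}")
        name, upper, lower = parts
        rows.append((name, upper.split(","), lower.split(",")))
    seen: list[str] = []
    for _, up, lo in rows:
        seen.extend(up + lo)
    if sorted(seen) != sorted(BLOCKS):
        raise ConfigError(
            "ACK table must place each of the 22 genomic blocks exactly once"
        )
    return rows


def build_ack(table_path=None) -> Karyotype:
    """The Ancestral Crucifer Karyotype: n = 8 (AK1-AK8), 22 genomic
    blocks, every block present in one copy.

    The block-to-arm table is packaged and user-overridable via
    ``table_path`` (TSV: chromosome, upper-arm blocks, lower-arm blocks).
    """
    chroms = []
    for name, upper, lower in _load_ack_table(table_path):
        segs = tuple(Segment(b, 1, 0.0, 1.0, 1) for b in upper + lower)
        chroms.append(Chromosome(name, segs, cen=len(upper)))
    return Karyotype(tuple(chroms)).validate()


# ---------------------------------------------------------------------------
# Breakpoints
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Breakpoint:
    """A cut position on a named chromosome.

    Either a terminus (``end`` = 'head'/'tail'), or an ancestral coordinate
    ``coord`` within ``block`` (``copy`` disambiguates when the chromosome
    carries both homeolog copies of the block).  ``coord`` strictly inside a
    segment splits the block; ``coord`` at a segment edge addresses the
    adjacent boundary.  When the same (block, copy) edge occurs at several
    positions of one chromosome (possible after inversions), ``occurrence``
    picks the match in reading order.
    """

    chrom: str
    block: str | None = None
    coord: float | None = None
    end: str | None = None
    copy: int | None = None
    occurrence: int | None = None

    def __post_init__(self) -> None:
        if self.end is not None:
            if self.end not in (HEAD, TAIL):
                raise KaryotypeError(f"breakpoint end must be head/tail: {self}")
        elif self.block is None or self.coord is None:
            raise KaryotypeError(f"breakpoint needs block+coord or end: {self}")


def _resolve_gap(c: Chromosome, bp: Breakpoint) -> tuple[Chromosome, int]:
    """Return (chromosome possibly with one segment split, gap index).

    Gap g lies between segments g-1 and g; cutting at the centromere gap is
    rejected.
    """
    if bp.end is not None:
        return c, (0 if bp.end == HEAD else len(c.segments))
    gaps: set[int] = set()
    split_at: list[tuple[int, float]] = []
    for i, s in enumerate(c.segments):
        if s.block != bp.block:
            continue
        if bp.copy is not None and s.copy != bp.copy:
            continue
        if not (s.start <= bp.coord <= s.end):
            continue
        if bp.coord == s.start:
            gaps.add(i if s.orient > 0 else i + 1)
        elif bp.coord == s.end:
            gaps.add(i + 1 if s.orient > 0 else i)
        else:
            split_at.append((i, bp.coord))
    if split_at and gaps:
        raise KaryotypeError(f"ambiguous breakpoint {bp} on {c.name!r}")
    if len(gaps) > 1 and bp.occurrence is not None:
        gaps = {sorted(gaps)[bp.occurrence]}
    if split_at:
        if len(split_at) > 1:
            raise KaryotypeError(
                f"breakpoint {bp} matches several segments on {c.name!r}; "
                "give a copy index"
            )
        i, coord = split_at[0]
        s = c.segments[i]
        left = Segment(s.block, s.copy, s.start, coord, 1)
        right = Segment(s.block, s.copy, coord, s.end, 1)
        if s.orient < 0:
            pair = (right.reversed_(), left.reversed_())
        else:
            pair = (left, right)
        segs = c.segments[:i] + pair + c.segments[i + 1 :]
        cen = c.cen + (1 if c.cen > i else 0)
        return Chromosome(c.name, segs, cen, c.history), i + 1
    if len(gaps) != 1:
        raise KaryotypeError(
            f"breakpoint {bp} resolves to {len(gaps)} positions on {c.name!r}"
        )
    return c, gaps.pop()


def _split(c: Chromosome, bp: Breakpoint):
    """Split at a breakpoint into (centric fragment, cen index, acentric
    fragment, side of the acentric fragment: HEAD or TAIL)."""
    c2, g = _resolve_gap(c, bp)
    if g == c2.cen:
        raise KaryotypeError(
            f"breakpoint {bp} falls at the centromere of {c.name!r}"
        )
    if g < c2.cen:
        return c2.segments[g:], c2.cen - g, c2.segments[:g], HEAD
    return c2.segments[:g], c2.cen, c2.segments[g:], TAIL


# ---------------------------------------------------------------------------
# Operators
# ---------------------------------------------------------------------------


def apply_wgd(k: Karyotype, suffixes: tuple[str, str] = ("a", "b")) -> Karyotype:
    """Whole-genome duplication: every chromosome gains a homeolog copy.

    Copy indices become 1/2 and names gain the given suffixes; the diploid
    number quadruples relative to the input's n.
    """
    if any(s.copy != 1 for c in k.chromosomes for s in c.segments):
        raise KaryotypeError("input is already polyploid (copy index 2 present)")
    out: list[Chromosome] = []
    for c in k.chromosomes:
        out.append(Chromosome(c.name + suffixes[0], c.segments, c.cen, c.history))
        dup = tuple(Segment(s.block, 2, s.start, s.end, s.orient) for s in c.segments)
        out.append(Chromosome(c.name + suffixes[1], dup, c.cen, c.history))
    return Karyotype(tuple(out))


def apply_eet(
    k: Karyotype,
    chr_a: str,
    end_a: str,
    chr_b: str,
    end_b: str,
    keep_centromere_of: str,
    name: str | None = None,
) -> Karyotype:
    """End-to-end translocation: join the named ends of two chromosomes.

    The dicentric fusion is resolved by keeping the centromere of
    ``keep_centromere_of``; the other centromere is eliminated (recorded in
    the fusion's history).  Complement size decreases by one.
    """
    if chr_a == chr_b:
        raise KaryotypeError("EET needs two distinct chromosomes")
    if keep_centromere_of not in (chr_a, chr_b):
        raise KaryotypeError(
            f"keep_centromere_of must be {chr_a!r} or {chr_b!r}"
        )
    a = k.get(chr_a)
    b = k.get(chr_b)
    # orient A so the joined end is its tail, B so the joined end is its head
    if end_a == HEAD:
        a = reverse_chromosome(a)
    elif end_a != TAIL:
        raise KaryotypeError(f"end_a must be head/tail, got {end_a!r}")
    if end_b == TAIL:
        b = reverse_chromosome(b)
    elif end_b != HEAD:
        raise KaryotypeError(f"end_b must be head/tail, got {end_b!r}")
    segs = a.segments + b.segments
    cen_a = a.cen
    cen_b = len(a.segments) + b.cen
    if keep_centromere_of == chr_a:
        cen, lost = cen_a, chr_b
    else:
        cen, lost = cen_b, chr_a
    hist = a.history + b.history + (f"centromere of {lost} eliminated",)
    fusion = Chromosome(name or f"{chr_a}/{chr_b}", segs, cen, hist)
    fusion.validate()
    return k.replace_chromosomes((chr_a, chr_b), (fusion,))


def apply_reciprocal_translocation(
    k: Karyotype,
    bp1: Breakpoint,
    bp2: Breakpoint,
    names: tuple[str | None, str | None] = (None, None),
) -> Karyotype:
    """Exchange the terminal fragments distal to two breakpoints.

    The fragment distal to each breakpoint is the acentric one, so both
    products are monocentric by construction.  ``names[0]`` renames the
    product that keeps ``bp1``'s centromere, ``names[1]`` the other.
    Argument order is symmetric.
    """
    if bp1.chrom == bp2.chrom:
        raise KaryotypeError("reciprocal translocation needs two chromosomes")
    c1 = k.get(bp1.chrom)
    c2 = k.get(bp2.chrom)
    cen1, ci1, ac1, side1 = _split(c1, bp1)
    cen2, ci2, ac2, side2 = _split(c2, bp2)

    def join(centric, ci, frag, side, fside, name, hist):
        # attach `frag` (removed from `fside` of its source) to `side` of
        # `centric`, reversing it when the cut ends would not abut
        if side == HEAD:
            frag2 = frag if fside == HEAD else reverse_fragment(frag)
            segs = frag2 + centric
            cen = ci + len(frag2)
        else:
            frag2 = frag if fside == TAIL else reverse_fragment(frag)
            segs = centric + frag2
            cen = ci
        prod = Chromosome(name, segs, cen, hist)
        prod.validate()
        return prod

    p1 = join(cen1, ci1, ac2, side1, side2, names[0] or bp1.chrom, c1.history)
    p2 = join(cen2, ci2, ac1, side2, side1, names[1] or bp2.chrom, c2.history)
    return k.replace_chromosomes((bp1.chrom, bp2.chrom), (p1, p2))


def apply_unequal_translocation(
    k: Karyotype,
    bp_interstitial: Breakpoint,
    target_chr: str,
    target_end: str,
    names: tuple[str | None, str | None] = (None, None),
) -> Karyotype:
    """Donate the terminal fragment distal to ``bp_interstitial`` to a
    (sub)telomeric end of ``target_chr``.

    Implemented as a reciprocal translocation whose second breakpoint is the
    target terminus (its distal fragment is empty).  ``names[0]`` renames
    the trimmed donor, ``names[1]`` the recipient.
    """
    bp2 = Breakpoint(chrom=target_chr, end=target_end)
    return apply_reciprocal_translocation(k, bp_interstitial, bp2, names)


def apply_pericentric_inversion(
    k: Karyotype,
    chrom: str,
    bp_left: Breakpoint,
    bp_right: Breakpoint,
    name: str | None = None,
) -> Karyotype:
    """Reverse the interval between two breakpoints flanking the centromere.

    Orientations inside the interval flip and the centromere position is
    mirrored within it.  Applying the same inversion twice restores the
    original chromosome.
    """
    c = k.get(chrom)
    n_before = len(c.segments)
    c, g1 = _resolve_gap(c, replace(bp_left, chrom=chrom))
    n_mid = len(c.segments)
    c, g2 = _resolve_gap(c, replace(bp_right, chrom=chrom))
    if len(c.segments) > n_mid and g2 - 1 < g1:
        g1 += 1  # second split lies left of the first gap
    lo, hi = min(g1, g2), max(g1, g2)
    if not (lo < c.cen < hi):
        raise KaryotypeError(
            f"not pericentric: breakpoints do not flank the centromere of {chrom!r}"
        )
    segs = c.segments[:lo] + reverse_fragment(c.segments[lo:hi]) + c.segments[hi:]
    cen = lo + (hi - c.cen)
    prod = Chromosome(name or c.name, segs, cen, c.history)
    prod.validate()
    return k.replace_chromosomes((chrom,), (prod,))


# ---------------------------------------------------------------------------
# Scenarios
# ---------------------------------------------------------------------------

WGD = "WGD"
EET = "EET"
RECIP_TRANSLOC = "RECIP_TRANSLOC"
UNEQ_TRANSLOC = "UNEQ_TRANSLOC"
PERI_INV = "PERI_INV"

EVENT_KINDS = (WGD, EET, RECIP_TRANSLOC, UNEQ_TRANSLOC, PERI_INV)


@dataclass(frozen=True)
class RearrangementEvent:
    """One rearrangement step: a kind, operator parameters, and free-text
    annotation (carried verbatim, e.g. Mb sizes or flanking gene IDs)."""

    kind: str
    params: dict
    annotation: str = ""

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise KaryotypeError(f"unknown event kind {self.kind!r}")


@dataclass(frozen=True)
class Scenario:
    """An ordered, deterministic list of rearrangement events."""

    events: tuple[RearrangementEvent, ...]
    start: str = "ACK"
    rename: dict = field(default_factory=dict)


def _bp(d: dict) -> Breakpoint:
    return Breakpoint(**d)


def apply_event(k: Karyotype, ev: RearrangementEvent) -> Karyotype:
    p = ev.params
    if ev.kind == WGD:
        return apply_wgd(k, tuple(p.get("suffixes", ("a", "b"))))
    if ev.kind == EET:
        return apply_eet(
            k, p["chr_a"], p["end_a"], p["chr_b"], p["end_b"],
            p["keep_centromere_of"], p.get("name"),
        )
    if ev.kind == RECIP_TRANSLOC:
        return apply_reciprocal_translocation(
            k, _bp(p["bp1"]), _bp(p["bp2"]), tuple(p.get("names", (None, None)))
        )
    if ev.kind == UNEQ_TRANSLOC:
        return apply_unequal_translocation(
            k, _bp(p["bp"]), p["target_chr"], p["target_end"],
            tuple(p.get("names", (None, None))),
        )
    if ev.kind == PERI_INV:
        return apply_pericentric_inversion(
            k, p["chrom"], _bp(p["bp_left"]), _bp(p["bp_right"]), p.get("name")
        )
    raise KaryotypeError(f"unknown event kind {ev.kind!r}")


def replay(
    scenario: Scenario, start: Karyotype | None = None
) -> tuple[Karyotype, list[Karyotype]]:
    """Deterministically replay a scenario; returns (final karyotype,
    per-step snapshots, one after each event).

    Operator errors propagate annotated with the failing step index.
    """
    if start is None:
        if scenario.start != "ACK":
            raise KaryotypeError(
                f"scenario starts from {scenario.start!r}; pass a start karyotype"
            )
        start = build_ack()
    k = start
    snaps: list[Karyotype] = []
    for i, ev in enumerate(scenario.events):
        try:
            k = apply_event(k, ev)
        except KaryotypeError as exc:
            raise KaryotypeError(f"step {i} ({ev.kind}): {exc}") from exc
        snaps.append(k)
    if scenario.rename:
        renamed = tuple(
            Chromosome(scenario.rename.get(c.name, c.name), c.segments, c.cen, c.history)
            for c in k.chromosomes
        )
        k = Karyotype(renamed)
        if snaps:
            snaps[-1] = k
    return k, snaps


def catolobus_scenario() -> Scenario:
    """The packaged ACK-to-Catolobus rearrangement scenario.

    WGD of the ACK (2n = 32); end-to-end translocation AK5b x AK7b keeping
    the AK5 centromere (n 16 -> 15, 2n = 30); reciprocal translocation of
    the fusion with AK3b (cuts F at mid and the U|T boundary) giving Cp15
    and the U+Fb+G+H product; a pericentric inversion of U+Fb+G+H (cuts in
    Fb and H) giving Cp14; a pericentric inversion of AK1a (cuts in A and
    C) giving Cp11; an unequal translocation donating Aa of AK1b to the
    upper-arm end of AK6b, giving Cp12 and Cp13.

    Within-block cut fractions are block-midpoint defaults; the physical
    sizes and flanking A. thaliana gene IDs ride along as annotations.
    """
    events = (
        RearrangementEvent(WGD, {}),
        RearrangementEvent(
            EET,
            {
                "chr_a": "AK7b", "end_a": HEAD, "chr_b": "AK5b", "end_b": HEAD,
                "keep_centromere_of": "AK5b", "name": "AK5/7b",
            },
            "fusion U+T+S+(K-L)+(M-N); AK7 centromere eliminated/inactivated",
        ),
        RearrangementEvent(
            RECIP_TRANSLOC,
            {
                "bp1": {"chrom": "AK3b", "block": "F", "coord": 0.5},
                "bp2": {"chrom": "AK5/7b", "block": "T", "coord": 1.0},
                "names": ("U+Fb+G+H", "Cp15"),
            },
            "products Cp15 [Fa+T+S+(K-L)+(M-N)] and U+Fb+G+H",
        ),
        RearrangementEvent(
            PERI_INV,
            {
                "chrom": "U+Fb+G+H",
                "bp_left": {"chrom": "U+Fb+G+H", "block": "F", "coord": 0.75},
                "bp_right": {"chrom": "U+Fb+G+H", "block": "H", "coord": 0.5},
                "name": "Cp14",
            },
            "8.21-Mb pericentric inversion; breakpoints in Fb between "
            "AT3G60970 (MRP15) and AT3G14220 (MLE3), and in H between "
            "AT2G18900 (F19F24) and AT2G19000 (T20K24)",
        ),
        RearrangementEvent(
            PERI_INV,
            {
                "chrom": "AK1a",
                "bp_left": {"chrom": "AK1a", "block": "A", "coord": 0.5},
                "bp_right": {"chrom": "AK1a", "block": "C", "coord": 0.5},
                "name": "Cp11",
            },
            "15.2-Mb pericentric inversion; breakpoints in A between "
            "AT1G12180 (T28K15) and AT1G12660 (T12C24), and in C between "
            "AT1G52240 (F9I5) and AT1G52450 (F6D8)",
        ),
        RearrangementEvent(
            UNEQ_TRANSLOC,
            {
                "bp": {"chrom": "AK1b", "block": "A", "coord": 0.5},
                "target_chr": "AK6b",
                "target_end": HEAD,
                "names": ("Cp12", "Cp13"),
            },
            "unequal reciprocal translocation; breakpoint in A between "
            "AT1G13500 (F13B4) and AT1G14220 (F7A19), to the subtelomeric "
            "region of the AK6 upper arm",
        ),
    )
    rename = {
        "AK2a": "Cp1", "AK2b": "Cp2", "AK3a": "Cp3", "AK4a": "Cp4",
        "AK4b": "Cp5", "AK5a": "Cp6", "AK6a": "Cp7", "AK7a": "Cp8",
        "AK8a": "Cp9", "AK8b": "Cp10",
    }
    return Scenario(events, start="ACK", rename=rename)


def cp13_private_inversion_scenario() -> Scenario:
    """Optional one-event scenario: the 3.54-Mb pericentric inversion of
    Cp13 private to a single eastern population; not part of the canonical
    scenario.  Replay it on the Catolobus karyotype."""
    ev = RearrangementEvent(
        PERI_INV,
        {
            "chrom": "Cp13",
            "bp_left": {"chrom": "Cp13", "block": "O", "coord": 0.5},
            "bp_right": {"chrom": "Cp13", "block": "Q", "coord": 0.5},
            "name": "Cp13inv",
        },
        "3.54-Mb pericentric inversion private to population 20",
    )
    return Scenario((ev,), start="Catolobus")


def catolobus_karyotype() -> Karyotype:
    """The Cp1-Cp15 complement obtained by replaying the packaged scenario."""
    final, _ = replay(catolobus_scenario())
    return final


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------


def summarize(k: Karyotype, reference: Karyotype | None = None) -> dict:
    """Complement summary and, against a reference complement, the number of
    reference chromosomes whose structure is absent from ``k`` (the
    'affected' chromosomes of the rearrangement history)."""
    cov = k.block_coverage()
    per_block: dict[str, int] = {b: 0 for b in BLOCKS}
    for (block, _copy), total in cov.items():
        if abs(total - 1.0) > 1e-9:
            raise KaryotypeError(
                f"block {block} copy coverage {total} is not a whole copy"
            )
        per_block[block] += 1
    out = {
        "n": k.n,
        "2n": k.two_n,
        "block_copy_numbers": per_block,
        "total_block_copies": len(cov),
    }
    if reference is not None:
        from collections import Counter

        have = Counter(canonical_form(c) for c in k.chromosomes)
        want = Counter(canonical_form(c) for c in reference.chromosomes)
        out["affected"] = sum((want - have).values())
    return out


# ---------------------------------------------------------------------------
# Serialization (versioned, JSON-compatible)
# ---------------------------------------------------------------------------


def _chrom_to_obj(k: Karyotype, c: Chromosome, cuts) -> dict:
    tokens: list[str] = []
    for i, s in enumerate(c.segments):
        if i == c.cen:
            tokens.append("CEN")
        lbl = k.segment_label(s, cuts)
        if lbl.startswith(("K-L", "M-N")):
            lbl = f"({lbl})"
        tokens.append(f"{lbl}{'+' if s.orient > 0 else '-'}@{s.copy}")
    obj = {"name": c.name, "tokens": tokens}
    if c.history:
        obj["history"] = list(c.history)
    return obj


def karyotype_to_json(k: Karyotype) -> str:
    """Serialize; the token grammar is label+orientation+copy (``Fa+@2``,
    ``(K-L)-@1``, ``CEN``) with block cut fractions in a side table so the
    reader/writer round-trip is bit-exact."""
    cuts = k.cut_table()
    obj = {
        "format": FORMAT_KARYOTYPE,
        "cuts": {
            f"{b}@{cp}": pts for (b, cp), pts in sorted(cuts.items()) if pts
        },
        "chromosomes": [_chrom_to_obj(k, c, cuts) for c in k.chromosomes],
    }
    return json.dumps(obj, indent=1, sort_keys=True)


def _parse_token(tok: str, cut_map) -> Segment:
    body, copy_s = tok.rsplit("@", 1)
    orient = 1 if body[-1] == "+" else -1
    lbl = body[:-1]
    if lbl.startswith("(") and lbl.endswith(")"):
        lbl = lbl[1:-1]
    if lbl in _BLOCK_SET:
        block, letter = lbl, None
    else:
        block, letter = lbl[:-1], lbl[-1]
        if block not in _BLOCK_SET:
            raise ConfigError(f"unknown block in token {tok!r}")
    copy = int(copy_s)
    pts = cut_map.get((block, copy), [])
    edges = [0.0] + list(pts) + [1.0]
    if letter is None:
        if pts:
            raise ConfigError(f"token {tok!r} lacks a sub-block letter but "
                              f"{block}@{copy} is cut")
        start, end = 0.0, 1.0
    else:
        rank = "abcdefgh".index(letter)
        if rank + 1 >= len(edges):
            raise ConfigError(f"token {tok!r}: no such sub-block")
        start, end = edges[rank], edges[rank + 1]
    return Segment(block, copy, start, end, orient)


def karyotype_from_json(text: str) -> Karyotype:
    obj = json.loads(text)
    if obj.get("format") != FORMAT_KARYOTYPE:
        raise ConfigError(f"not a {FORMAT_KARYOTYPE} document")
    cut_map: dict[tuple[str, int], list[float]] = {}
    for key, pts in obj.get("cuts", {}).items():
        b, cp = key.rsplit("@", 1)
        cut_map[(b, int(cp))] = [float(p) for p in pts]
    chroms = []
    for co in obj["chromosomes"]:
        segs: list[Segment] = []
        cen = None
        for tok in co["tokens"]:
            if tok == "CEN":
                if cen is not None:
                    raise ConfigError(
                        f"chromosome {co['name']!r} has two centromeres"
                    )
                cen = len(segs)
            else:
                segs.append(_parse_token(tok, cut_map))
        if cen is None:
            raise ConfigError(f"chromosome {co['name']!r} has no centromere")
        chroms.append(
            Chromosome(co["name"], tuple(segs), cen, tuple(co.get("history", ())))
        )
    return Karyotype(tuple(chroms)).validate()


def scenario_to_json(s: Scenario) -> str:
    obj = {
        "format": FORMAT_SCENARIO,
        "start": s.start,
        "rename": s.rename,
        "events": [
            {"kind": e.kind, "params": e.params, "annotation": e.annotation}
            for e in s.events
        ],
    }
    return json.dumps(obj, indent=1, sort_keys=True)


def scenario_from_json(text: str) -> Scenario:
    obj = json.loads(text)
    if obj.get("format") != FORMAT_SCENARIO:
        raise ConfigError(f"not a {FORMAT_SCENARIO} document")
    events = tuple(
        RearrangementEvent(e["kind"], e["params"], e.get("annotation", ""))
        for e in obj["events"]
    )
    return Scenario(events, obj.get("start", "ACK"), obj.get("rename", {}))
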