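"""Bounded parsimony search for rearrangement scenarios between karyotypes.

Reconstructs minimal event scenarios (end-to-end translocation, reciprocal
and unequal translocations, pericentric inversions) transforming one
block-level karyotype into another, formalizing the expert by-hand
reconstruction of rearrangement histories from painting data.

The search is iterative-deepening depth-first over operator applications
with canonical-form memoization and an admissible lower bound combining
three facts:

* each event rewrites at most two chromosomes, so at least
  ``ceil(mismatched / 2)`` events are needed;
* each event introduces at most two within-block cuts, no operator can
  ever merge sub-blocks back (a state carrying a cut absent from the
  target is dead), and the only complement-size-changing event (EET)
  introduces none, so at least ``(n_state - n_target) + ceil(cut_deficit
  / 2)`` events are needed;
* a state with fewer chromosomes than the target is dead (there is no
  fission operator).

Breakpoints are restricted to the cut points implied by the target (the
sub-block cut fractions visible in the target) plus all segment boundaries
and termini: a minimal scenario reaching the target can only use cuts the
target exhibits.  Whole-genome duplication is never searched; ploidy change
is observed, not inferred, and belongs in an explicit scenario prefix.

Internally the hot loop builds candidate products directly from segment
fragments and defers event/karyotype object construction to the children
that survive pruning; the returned scenarios replay through the ordinary
operator layer, which is asserted in tests.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field

from karyoploid.karyotype import (
    EET,
    HEAD,
    PERI_INV,
    RECIP_TRANSLOC,
    TAIL,
    UNEQ_TRANSLOC,
    Chromosome,
    Karyotype,
    RearrangementEvent,
    Scenario,
    canonical_form,
    reverse_fragment,
)

DEFAULT_OPERATORS = (EET, RECIP_TRANSLOC, UNEQ_TRANSLOC, PERI_INV)


@dataclass(frozen=True)
class SearchConfig:
    """Knobs of the bounded parsimony search.

    ``breakpoint_policy`` is ``target_implied`` (within-block cuts
    restricted to those visible in the target) or ``boundaries_only``.
    ``operand_policy`` controls which chromosomes events may touch:
    ``mismatch_only`` (default; every operand must currently differ from
    the target — the fast setting) or ``any``.  ``max_scenarios`` limits
    how many minimal scenarios are collected (``None`` collects all, at
    extra cost).
    """

    max_depth: int = 5
    allowed_operators: tuple[str, ...] = DEFAULT_OPERATORS
    breakpoint_policy: str = "target_implied"
    operand_policy: str = "mismatch_only"
    dedup: bool = True
    max_scenarios: int | None = None

    def __post_init__(self) -> None:
        if self.max_depth < 0:
            raise ValueError("max_depth must be >= 0")
        for op in self.allowed_operators:
            if op not in DEFAULT_OPERATORS:
                raise ValueError(f"operator {op!r} cannot be searched")
        if self.breakpoint_policy not in ("target_implied", "boundaries_only"):
            raise ValueError(f"bad breakpoint_policy {self.breakpoint_policy!r}")
        if self.operand_policy not in ("mismatch_only", "any"):
            raise ValueError(f"bad operand_policy {self.operand_policy!r}")


@dataclass
class SearchResult:
    """Outcome of a bounded search.

    ``distance`` is the minimal event count, or ``None`` when no scenario
    of length <= max_depth exists (reported explicitly, never silently).
    Every returned scenario replays start -> target under copy-blind
    canonical equality.
    """

    distance: int | None
    scenarios: list[Scenario] = field(default_factory=list)
    nodes_expanded: int = 0
    max_depth: int = 0

    @property
    def found(self) -> bool:
        return self.distance is not None

    def __str__(self) -> str:
        if not self.found:
            return f"not found <= max_depth {self.max_depth}"
        return f"distance {self.distance} ({len(self.scenarios)} scenario(s))"


def implied_breakpoints(target: Karyotype) -> dict[str, tuple[float, ...]]:
    """Within-block cut fractions visible in the target, per block
    (union over homeolog copies); search cuts are restricted to these."""
    out: dict[str, set[float]] = {}
    for (block, _copy), pts in target.cut_table().items():
        if pts:
            out.setdefault(block, set()).update(pts)
    return {b: tuple(sorted(v)) for b, v in out.items()}


def _ceil2(x: int) -> int:
    return (x + 1) // 2


# -- cut-deficit bookkeeping ------------------------------------------------


def _cut_sets(k: Karyotype) -> dict[tuple[str, int], frozenset]:
    """Interior cut fractions per (block, copy); empty sets omitted."""
    agg: dict[tuple[str, int], set] = {}
    for c in k.chromosomes:
        for s in c.segments:
            d = agg.setdefault((s.block, s.copy), set())
            if s.start > 0.0:
                d.add(s.start)
            if s.end < 1.0:
                d.add(s.end)
    return {key: frozenset(v) for key, v in agg.items() if v}


def _block_copies(k: Karyotype) -> dict[str, tuple[int, ...]]:
    copies: dict[str, set[int]] = {}
    for c in k.chromosomes:
        for s in c.segments:
            copies.setdefault(s.block, set()).add(s.copy)
    return {b: tuple(sorted(v)) for b, v in copies.items()}


def _junction_tokens(segments) -> tuple:
    """Copy-blind junction tokens of one chromosome reading.

    Each junction between consecutive segments is encoded as the unordered
    pair of abutting block edges, an edge being (block, ancestral
    coordinate, side of the coordinate the material lies on).  Tokens are
    invariant under reversal of the reading and under interval reversal
    away from the junction, so every rearrangement event changes at most
    the tokens at its breakpoints: EET creates exactly one new junction,
    a reciprocal translocation or pericentric inversion at most two, an
    unequal translocation one.
    """
    out = []
    for i in range(1, len(segments)):
        l = segments[i - 1]
        r = segments[i]
        el = (l.block, l.end if l.orient > 0 else l.start, -l.orient)
        er = (r.block, r.start if r.orient > 0 else r.end, r.orient)
        out.append((el, er) if el <= er else (er, el))
    return tuple(out)


def _block_deficit(ssets: list[frozenset], tsets: list[frozenset]) -> int | None:
    """Cuts still needed for one block under the best copy pairing, or
    None when a state cut cannot be mapped onto the target (dead state:
    sub-blocks never re-merge)."""
    best = None
    for perm in itertools.permutations(range(len(tsets))):
        miss = 0
        ok = True
        for si in range(len(ssets)):
            s, t = ssets[si], tsets[perm[si]]
            if not s <= t:
                ok = False
                break
            miss += len(t - s)
        if ok and (best is None or miss < best):
            best = miss
    return best


# -- breakpoint candidates --------------------------------------------------


def _bp_gaps(segments, block: str, coord: float, copy: int) -> list[int]:
    """All gap positions a (block, coord, copy) breakpoint resolves to;
    mirrors the operator-level breakpoint resolution."""
    gaps: set[int] = set()
    for i, s in enumerate(segments):
        if s.block != block or s.copy != copy:
            continue
        if coord == s.start:
            gaps.add(i if s.orient > 0 else i + 1)
        elif coord == s.end:
            gaps.add(i + 1 if s.orient > 0 else i)
    return sorted(gaps)


def _split_segment(s, f):
    left = type(s)(s.block, s.copy, s.start, f, 1)
    right = type(s)(s.block, s.copy, f, s.end, 1)
    return (right.reversed_(), left.reversed_()) if s.orient < 0 else (left, right)


def _chrom_candidates(c: Chromosome, implied):
    """Breakpoint candidates on one chromosome.

    Each candidate is a tuple ``(pos, bp, cut, centric, ci, acentric,
    side)``: ``pos`` orders the cut against the centromere (half-integer
    for within-segment splits), ``bp`` is the serializable breakpoint,
    ``cut`` the (block, copy, fraction) a split would introduce (or None),
    and the remaining fields are the precomputed translocation fragments —
    ``centric`` keeps the centromere at index ``ci`` while ``acentric`` is
    the fragment removed from ``side`` of the reading.  Termini are
    included with empty acentric fragments (the unequal-translocation
    recipient ends).
    """
    segs = c.segments
    cen = c.cen
    out = []
    for g in range(1, len(segs)):
        if g == cen:
            continue
        s = segs[g]
        coord = s.start if s.orient > 0 else s.end
        bp = {"chrom": c.name, "block": s.block, "coord": coord,
              "copy": s.copy}
        all_gaps = _bp_gaps(segs, s.block, coord, s.copy)
        if len(all_gaps) > 1:
            bp["occurrence"] = all_gaps.index(g)
        if g < cen:
            out.append((float(g), bp, None, segs[g:], cen - g, segs[:g], HEAD))
        else:
            out.append((float(g), bp, None, segs[:g], cen, segs[g:], TAIL))
    for i, s in enumerate(segs):
        for f in implied.get(s.block, ()):
            if not (s.start < f < s.end):
                continue
            pair = _split_segment(s, f)
            segs2 = segs[:i] + pair + segs[i + 1:]
            cen2 = cen + (1 if cen > i else 0)
            g = i + 1
            bp = {"chrom": c.name, "block": s.block, "coord": f,
                  "copy": s.copy}
            cut = (s.block, s.copy, f)
            if g < cen2:
                out.append((i + 0.5, bp, cut, segs2[g:], cen2 - g,
                            segs2[:g], HEAD))
            else:
                out.append((i + 0.5, bp, cut, segs2[:g], cen2,
                            segs2[g:], TAIL))
    # termini (empty acentric fragments): unequal-translocation recipients
    out.append((0.0, {"chrom": c.name, "end": HEAD}, None, segs, cen, (),
                HEAD))
    out.append((float(len(segs)), {"chrom": c.name, "end": TAIL}, None,
                segs, cen, (), TAIL))
    return out


def _join(centric, ci, frag, side, fside, name):
    """Attach ``frag`` (removed from ``fside`` of its source) to ``side``
    of the centric fragment so the cut ends abut."""
    if side == HEAD:
        frag2 = frag if fside == HEAD else reverse_fragment(frag)
        return Chromosome(name, frag2 + centric, ci + len(frag2))
    frag2 = frag if fside == TAIL else reverse_fragment(frag)
    return Chromosome(name, centric + frag2, ci)


def _invert(c: Chromosome, left, right):
    """Build the pericentric-inversion product for two candidates of
    ``_chrom_candidates`` flanking the centromere."""
    segs = list(c.segments)
    cen = c.cen
    pos_l, bp_l, cut_l = left
    pos_r, bp_r, cut_r = right
    # apply the right split first so left indices stay valid
    if pos_r != int(pos_r):
        i = int(pos_r)
        segs[i: i + 1] = list(_split_segment(segs[i], bp_r["coord"]))
        gr = i + 1
    else:
        gr = int(pos_r)
    if pos_l != int(pos_l):
        i = int(pos_l)
        segs[i: i + 1] = list(_split_segment(segs[i], bp_l["coord"]))
        gl = i + 1
        cen += 1
        gr += 1
    else:
        gl = int(pos_l)
    mid = reverse_fragment(segs[gl:gr])
    new = tuple(segs[:gl]) + mid + tuple(segs[gr:])
    return Chromosome(c.name, new, gl + (gr - cen))


# -- scenario dedup up to operand symmetry ----------------------------------


def _canon_event(ev: RearrangementEvent) -> tuple:
    p = ev.params

    def bpkey(d):
        return tuple(sorted((k, v) for k, v in d.items()))

    if ev.kind == RECIP_TRANSLOC:
        return (ev.kind,) + tuple(sorted((bpkey(p["bp1"]), bpkey(p["bp2"]))))
    if ev.kind == EET:
        ends = sorted(((p["chr_a"], p["end_a"]), (p["chr_b"], p["end_b"])))
        return (ev.kind, tuple(ends), p["keep_centromere_of"])
    if ev.kind == PERI_INV:
        return (ev.kind, p["chrom"]) + tuple(
            sorted((bpkey(p["bp_left"]), bpkey(p["bp_right"])))
        )
    if ev.kind == UNEQ_TRANSLOC:
        return (ev.kind, bpkey(p["bp"]), p["target_chr"], p["target_end"])
    return (ev.kind,)


# -- the search itself ------------------------------------------------------


def search(
    start: Karyotype, target: Karyotype, cfg: SearchConfig | None = None
) -> SearchResult:
    """Find minimal rearrangement scenarios from ``start`` to ``target``.

    Iterative-deepening search over operator applications; returns the
    minimal-length scenarios (deduplicated up to operand symmetry, sorted
    by serialized form) and the number of expanded nodes.  Distance 0 iff
    the two karyotypes are copy-blind canonically equal.  If no scenario of
    length <= ``cfg.max_depth`` exists the result says so explicitly.
    """
    cfg = cfg or SearchConfig()
    implied = (
        implied_breakpoints(target)
        if cfg.breakpoint_policy == "target_implied"
        else {}
    )
    n_target = target.n
    collect_all = cfg.max_scenarios is None

    canon_memo: dict = {}

    def canon(c: Chromosome):
        key = (c.segments, c.cen)
        v = canon_memo.get(key)
        if v is None:
            v = canonical_form(c)
            canon_memo[key] = v
        return v

    tcnt = Counter(canon(c) for c in target.chromosomes)

    def mismatch(chroms):
        avail: Counter = Counter()
        wrong: list[int] = []
        keys = []
        for i, c in enumerate(chroms):
            key = canon(c)
            keys.append(key)
            if avail[key] < tcnt[key]:
                avail[key] += 1
            else:
                wrong.append(i)
        return keys, wrong

    keys0, wrong0 = mismatch(start.chromosomes)
    if not wrong0:
        return SearchResult(0, [Scenario((), start="start")], 0, cfg.max_depth)

    # no operator changes block-copy content: unequal content is hopeless
    if start.block_coverage() != target.block_coverage():
        return SearchResult(None, [], 0, cfg.max_depth)
    if start.n < n_target or (
        start.n > n_target and EET not in cfg.allowed_operators
    ):
        return SearchResult(None, [], 0, cfg.max_depth)

    # cut-deficit bookkeeping against the target
    t_cut_sets = _cut_sets(target)
    copies = _block_copies(target)
    tprof = {
        b: [t_cut_sets.get((b, cp), frozenset()) for cp in cps]
        for b, cps in copies.items()
        if any(t_cut_sets.get((b, cp)) for cp in cps)
    }

    def block_def(cuts: dict, block: str) -> int | None:
        tsets = tprof.get(block)
        if tsets is None:
            return (
                0
                if not any(cuts.get((block, cp)) for cp in copies[block])
                else None
            )
        ssets = [cuts.get((block, cp), frozenset()) for cp in copies[block]]
        return _block_deficit(ssets, tsets)

    cuts0 = _cut_sets(start)
    deficit0 = 0
    for b in set(tprof) | {b for (b, _cp) in cuts0}:
        d = block_def(cuts0, b)
        if d is None:
            return SearchResult(None, [], 0, cfg.max_depth)
        deficit0 += d

    # adjacency bookkeeping: junctions present in the target but not in
    # the state must each be created by some event
    jt_memo: dict = {}

    def junctions(c: Chromosome):
        v = jt_memo.get(c.segments)
        if v is None:
            v = _junction_tokens(c.segments)
            jt_memo[c.segments] = v
        return v

    tadj: Counter = Counter()
    for c in target.chromosomes:
        tadj.update(junctions(c))
    adj0: Counter = Counter()
    for c in start.chromosomes:
        adj0.update(junctions(c))
    miss0 = sum((tadj - adj0).values())

    def bound(n_chroms: int, w: int, deficit: int, miss_adj: int) -> int | None:
        if n_chroms < n_target:
            return None  # dead: there is no fission operator
        dn = n_chroms - n_target
        # exactly dn EETs remain (only EET changes n); an EET creates one
        # junction, every other event at most two
        return max(
            _ceil2(w),
            dn + _ceil2(deficit),
            dn + _ceil2(max(0, miss_adj - dn)),
        )

    h0 = bound(start.n, len(wrong0), deficit0, miss0)
    if h0 is None or h0 > cfg.max_depth:
        return SearchResult(None, [], 0, cfg.max_depth)

    ops = cfg.allowed_operators
    do_eet = EET in ops
    do_recip = RECIP_TRANSLOC in ops
    do_uneq = UNEQ_TRANSLOC in ops
    do_inv = PERI_INV in ops

    nodes = 0
    for limit in range(max(h0, 1), cfg.max_depth + 1):
        solutions: list[tuple] = []
        visited: dict = {}
        counter = itertools.count(1)

        def dfs(chroms, keys, wrong_idx, w, cuts, deficit, adjcnt, miss_adj,
                depth, path) -> bool:
            nonlocal nodes
            nodes += 1
            cnt = Counter(keys)
            last_level = depth + 1 >= limit

            # per-node cut feasibility and deficit deltas
            cut_delta: dict[tuple, int | None] = {}

            def eval_cuts(new_cuts):
                """(deficit delta, updated cut dict) or (None, None)."""
                if not new_cuts:
                    return 0, cuts
                if (
                    len(new_cuts) == 2
                    and new_cuts[0][0] == new_cuts[1][0]
                    and new_cuts[0] != new_cuts[1]
                ):
                    # two cuts in one block: evaluate jointly
                    cc = dict(cuts)
                    base = block_def(cc, new_cuts[0][0])
                    for (b, cp, f) in new_cuts:
                        cc[(b, cp)] = cc.get((b, cp), frozenset()) | {f}
                    nd = block_def(cc, new_cuts[0][0])
                    if nd is None:
                        return None, None
                    return nd - base, cc
                delta = 0
                cc = None
                for cut in new_cuts:
                    d = cut_delta.get(cut, -2)
                    if d == -2:
                        b, cp, f = cut
                        trial = dict(cuts)
                        trial[(b, cp)] = trial.get((b, cp), frozenset()) | {f}
                        nd = block_def(trial, b)
                        d = None if nd is None else nd - block_def(cuts, b)
                        cut_delta[cut] = d
                    if d is None:
                        return None, None
                    delta += d
                    if cc is None:
                        cc = dict(cuts)
                    b, cp, f = cut
                    cc[(b, cp)] = cc.get((b, cp), frozenset()) | {f}
                return delta, cc

            def w_delta(removed_keys, added_keys):
                delta: dict = {}
                for key in removed_keys:
                    delta[key] = delta.get(key, 0) - 1
                for key in added_keys:
                    delta[key] = delta.get(key, 0) + 1
                dw = 0
                for key, d in delta.items():
                    if d:
                        before = cnt[key]
                        dw += max(0, before + d - tcnt[key]) - max(
                            0, before - tcnt[key]
                        )
                return dw

            # operand sets, deduplicated by canonical class (homeolog twins
            # and identical chromosomes generate identical children)
            if cfg.operand_policy == "mismatch_only":
                operand_idx = wrong_idx
            else:
                operand_idx = list(range(len(chroms)))
            singles = []
            seen_single = set()
            for i in operand_idx:
                if keys[i] not in seen_single:
                    seen_single.add(keys[i])
                    singles.append(i)
            pair_list = []
            seen_pair = set()
            for ii in range(len(operand_idx)):
                for jj in range(ii + 1, len(operand_idx)):
                    i, j = operand_idx[ii], operand_idx[jj]
                    ck = (min(keys[i], keys[j]), max(keys[i], keys[j]))
                    if ck not in seen_pair:
                        seen_pair.add(ck)
                        pair_list.append((i, j))

            children = []

            def consider(make_event, removed_idx, products, new_cuts):
                removed_keys = [keys[i] for i in removed_idx]
                added_keys = [canon(p) for p in products]
                dw = w_delta(removed_keys, added_keys)
                w_child = w + dw
                if w_child == 0:
                    solutions.append(path + (make_event(),))
                    return len(solutions) >= (cfg.max_scenarios or 0) and not \
                        collect_all
                if last_level:
                    return False
                ddelta, cuts_child = eval_cuts(new_cuts)
                if ddelta is None:
                    return False
                def_child = deficit + ddelta
                n_child = len(chroms) - len(removed_idx) + len(products)
                # adjacency delta
                adelta: dict = {}
                for i in removed_idx:
                    for t in junctions(chroms[i]):
                        adelta[t] = adelta.get(t, 0) - 1
                for p in products:
                    for t in junctions(p):
                        adelta[t] = adelta.get(t, 0) + 1
                miss_child = miss_adj
                for t, d in adelta.items():
                    if d:
                        before = adjcnt[t]
                        want = tadj[t]
                        miss_child += max(0, want - before - d) - max(
                            0, want - before
                        )
                hb = bound(n_child, w_child, def_child, miss_child)
                if hb is None or depth + 1 + hb > limit:
                    return False
                # greedy ordering: most progress first (fewest wrong
                # chromosomes, cuts and fusions outstanding), bound as tie-break
                progress = w_child + def_child + 2 * (n_child - n_target)
                removed_names = tuple(chroms[i].name for i in removed_idx)
                children.append(
                    ((progress, hb), make_event, removed_names, products,
                     cuts_child, def_child, w_child, adelta, miss_child)
                )
                return False

            stop = False
            cand_cache: dict[int, list] = {}

            def cands(i):
                v = cand_cache.get(i)
                if v is None:
                    v = _chrom_candidates(chroms[i], implied)
                    cand_cache[i] = v
                return v

            if do_eet and not stop:
                for i, j in pair_list:
                    a, b = chroms[i], chroms[j]
                    ra = reverse_fragment(a.segments)
                    rb = reverse_fragment(b.segments)
                    for ea in (HEAD, TAIL):
                        sa = ra if ea == HEAD else a.segments
                        ca = (len(a.segments) - a.cen) if ea == HEAD else a.cen
                        for eb in (HEAD, TAIL):
                            sb = b.segments if eb == HEAD else rb
                            cb = b.cen if eb == HEAD else len(b.segments) - b.cen
                            for keep in (0, 1):
                                cen = ca if keep == 0 else len(sa) + cb
                                if not (0 < cen < len(sa) + len(sb)):
                                    continue
                                name = f"x{next(counter)}"
                                fusion = Chromosome(name, sa + sb, cen)

                                def mk(a=a, b=b, ea=ea, eb=eb, keep=keep,
                                       name=name):
                                    return RearrangementEvent(EET, {
                                        "chr_a": a.name, "end_a": ea,
                                        "chr_b": b.name, "end_b": eb,
                                        "keep_centromere_of":
                                            (a.name, b.name)[keep],
                                        "name": name,
                                    })

                                stop = consider(mk, (i, j), (fusion,), ())
                                if stop:
                                    break
                            if stop:
                                break
                        if stop:
                            break
                    if stop:
                        break

            if (do_recip or do_uneq) and not stop:
                for i, j in pair_list:
                    a, b = chroms[i], chroms[j]
                    for pa, bpa, cua, cea, cia, aca, sda in cands(i):
                        a_term = "end" in bpa
                        for pb, bpb, cub, ceb, cib, acb, sdb in cands(j):
                            b_term = "end" in bpb
                            if a_term and b_term:
                                continue  # empty-for-empty exchange
                            kind = (
                                UNEQ_TRANSLOC if (a_term or b_term)
                                else RECIP_TRANSLOC
                            )
                            if kind == RECIP_TRANSLOC and not do_recip:
                                continue
                            if kind == UNEQ_TRANSLOC and not do_uneq:
                                continue
                            n1 = f"x{next(counter)}"
                            n2 = f"x{next(counter)}"
                            p1 = _join(cea, cia, acb, sda, sdb, n1)
                            p2 = _join(ceb, cib, aca, sdb, sda, n2)
                            new = tuple(x for x in (cua, cub) if x)

                            def mk(kind=kind, bpa=bpa, bpb=bpb, a=a, b=b,
                                   a_term=a_term, n1=n1, n2=n2):
                                if kind == RECIP_TRANSLOC:
                                    # names[0] keeps bp1's centromere
                                    return RearrangementEvent(
                                        kind, {"bp1": bpa, "bp2": bpb,
                                               "names": (n1, n2)}
                                    )
                                if a_term:
                                    # donor is b: trimmed donor keeps bpb's
                                    # centromere (n2); recipient is a (n1)
                                    return RearrangementEvent(kind, {
                                        "bp": bpb, "target_chr": a.name,
                                        "target_end": bpa["end"],
                                        "names": (n2, n1),
                                    })
                                return RearrangementEvent(kind, {
                                    "bp": bpa, "target_chr": b.name,
                                    "target_end": bpb["end"],
                                    "names": (n1, n2),
                                })

                            stop = consider(mk, (i, j), (p1, p2), new)
                            if stop:
                                break
                        if stop:
                            break
                    if stop:
                        break

            if do_inv and not stop:
                for i in singles:
                    c = chroms[i]
                    cl = cands(i)
                    lefts = [
                        (pos, bp, cut) for pos, bp, cut, *_ in cl
                        if pos < c.cen
                    ]
                    rights = [
                        (pos, bp, cut) for pos, bp, cut, *_ in cl
                        if pos > c.cen
                    ]
                    for left in lefts:
                        for right in rights:
                            if "end" in left[1] and "end" in right[1]:
                                continue  # full reversal: identity
                            prod = _invert(c, left, right)
                            new = tuple(
                                x for x in (left[2], right[2]) if x
                            )

                            def mk(c=c, bpl=left[1], bpr=right[1]):
                                return RearrangementEvent(PERI_INV, {
                                    "chrom": c.name, "bp_left": bpl,
                                    "bp_right": bpr,
                                })

                            stop = consider(mk, (i,), (prod,), new)
                            if stop:
                                break
                        if stop:
                            break
                    if stop:
                        break

            if stop:
                return True
            children.sort(key=lambda t: t[0])
            for (_key, mk, removed_names, products, cuts_child, def_child,
                 w_child, adelta, miss_child) in children:
                rm = set(removed_names)
                child_chroms = tuple(
                    c for c in chroms if c.name not in rm
                ) + tuple(products)
                if cfg.dedup:
                    key = tuple(sorted(canon(c) for c in child_chroms))
                    prev = visited.get(key)
                    if prev is not None and (
                        prev < depth + 1
                        or (prev == depth + 1 and not collect_all)
                    ):
                        continue
                    visited[key] = depth + 1
                ckeys, cwrong = mismatch(child_chroms)
                adj_child = adjcnt.copy()
                for t, d in adelta.items():
                    adj_child[t] += d
                if dfs(child_chroms, ckeys, cwrong, w_child, cuts_child,
                       def_child, adj_child, miss_child, depth + 1,
                       path + (mk(),)):
                    return True
            return False

        dfs(tuple(start.chromosomes), keys0, wrong0, len(wrong0), cuts0,
            deficit0, adj0, miss0, 0, ())
        if solutions:
            by_canon: dict[tuple, tuple] = {}
            for p in solutions:
                by_canon.setdefault(tuple(_canon_event(e) for e in p), p)
            scenarios = sorted(
                (Scenario(tuple(p), start="start") for p in by_canon.values()),
                key=lambda s: repr(s.events),
            )
            return SearchResult(limit, scenarios, nodes, cfg.max_depth)

    return SearchResult(None, [], nodes, cfg.max_depth)


def event_kind_multiset(scenario: Scenario) -> Counter:
    """Multiset of event kinds of a scenario (WGD prefix included)."""
    return Counter(e.kind for e in scenario.events)
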