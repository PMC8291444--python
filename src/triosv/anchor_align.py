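"""Anchor-based pairwise whole-genome alignment.

A desk-scale chain/net aligner in the UCSC tradition: exact k-mer-seeded
maximal-match anchors stand in for seeded local alignments; sparse dynamic
programming with affine gap costs forms maximally scoring colinear chains;
greedy netting keeps the best chains single-coverage on the target.  Chains
overlapping on the target *before* netting are preserved as evidence for
repeat (duplication) calls.

Anchors and blocks use strand-space query coordinates: for strand '-' the
query coordinate indexes into the reverse complement of the query
chromosome, which is also the MAF convention, so both target and query
coordinates strictly increase along any chain.

A final refinement pass extends netted blocks through inter-block gaps,
stepping over isolated substitutions, so that SV breakpoints are recovered
at base resolution even when a substitution near the true breakpoint
truncated the terminal exact-match anchor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from intervaltree import IntervalTree

from .models import Anchor, Block, Chain, GenomeSequence, MafBlock, MafSeq, Net, OverlapPair, revcomp

_CODE = np.full(256, 255, np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


@dataclass
class AlignConfig:
    """Aligner parameters.

    Scores count +1 per matched base inside anchors; an affine gap of total
    length g (target plus query side) costs ``gap_open + gap_extend * g``.
    ``min_chain_score`` is set below the 50 bp SV floor so that the short
    second chain produced by a minimal tandem duplication survives netting.
    """

    k: int = 15
    min_anchor_len: int = 20
    max_kmer_occ: int = 10
    gap_open: float = 10.0
    gap_extend: float = 0.05
    min_chain_score: float = 25.0
    chain_window: int = 64
    overlap_slack: int = 15
    tra_jump: int = 1_000_000
    refine: bool = True
    refine_skip_match: int = 4

    def validate(self) -> None:
        if self.k < 8:
            raise ValueError("k must be >= 8")
        if self.min_anchor_len < self.k:
            self.min_anchor_len = self.k


# --- k-mer machinery --------------------------------------------------------

def _codes(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode(), np.uint8)]


def _kmer_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Packed 2-bit k-mer codes and a validity mask (no N inside)."""
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, np.int64), np.empty(0, bool)
    valid_base = codes != 255
    cc = np.where(valid_base, codes, 0).astype(np.int64)
    out = np.zeros(n, np.int64)
    valid = np.ones(n, bool)
    for j in range(k):
        out = out * 4 + cc[j : j + n]
        valid &= valid_base[j : j + n]
    return out, valid


def banned_kmers(seqs: Sequence[GenomeSequence], k: int, max_occ: int) -> np.ndarray:
    """Sorted codes of k-mers occurring more than ``max_occ`` times in the
    genome (forward strands); such k-mers never seed anchors."""
    parts = []
    for gs in seqs:
        c, v = _kmer_codes(_codes(gs.seq), k)
        parts.append(c[v])
    if not parts:
        return np.empty(0, np.int64)
    allc = np.concatenate(parts)
    uniq, cnt = np.unique(allc, return_counts=True)
    return uniq[cnt > max_occ]


def _grouped_arange(starts: np.ndarray, counts: np.ndarray) -> np.ndarray:
    """Concatenate arange(s, s+c) for each (s, c) pair, vectorized."""
    total = int(counts.sum())
    if total == 0:
        return np.empty(0, np.int64)
    ends = np.cumsum(counts)
    out = np.ones(total, np.int64)
    out[0] = starts[0]
    heads = ends[:-1]
    out[heads] = starts[1:] - (starts[:-1] + counts[:-1] - 1)
    return np.cumsum(out)


def _seed_runs(
    t_codes, t_valid, q_codes, q_valid, banned: Optional[np.ndarray], max_occ: int
):
    """Match k-mer seeds and collapse them into diagonal runs.

    Returns (t_start, q_start, n_kmers) arrays, one row per run of
    consecutive matching seed positions on one diagonal.
    """
    qsel = np.flatnonzero(q_valid)
    if len(qsel) == 0:
        return np.empty((3, 0), np.int64)
    order = np.argsort(q_codes[qsel], kind="stable")
    qpos = qsel[order]
    qsorted = q_codes[qsel][order]
    tsel = np.flatnonzero(t_valid)
    tc = t_codes[tsel]
    if banned is not None and len(banned):
        keep = ~np.isin(tc, banned)
        tsel, tc = tsel[keep], tc[keep]
    left = np.searchsorted(qsorted, tc, "left")
    right = np.searchsorted(qsorted, tc, "right")
    cnt = right - left
    hit = (cnt > 0) & (cnt <= max_occ)
    tsel, left, cnt = tsel[hit], left[hit], cnt[hit]
    if len(tsel) == 0:
        return np.empty((3, 0), np.int64)
    t_rep = np.repeat(tsel, cnt)
    q_rep = qpos[_grouped_arange(left, cnt)]
    diag = t_rep - q_rep
    order = np.lexsort((t_rep, diag))
    t_rep, q_rep, diag = t_rep[order], q_rep[order], diag[order]
    new_run = np.ones(len(t_rep), bool)
    if len(t_rep) > 1:
        new_run[1:] = (diag[1:] != diag[:-1]) | (t_rep[1:] != t_rep[:-1] + 1)
    starts = np.flatnonzero(new_run)
    lengths = np.diff(np.append(starts, len(t_rep)))
    return np.stack([t_rep[starts], q_rep[starts], lengths])


def find_anchors(
    target: GenomeSequence,
    query: GenomeSequence,
    k: int = 15,
    cfg: Optional[AlignConfig] = None,
    banned_t: Optional[np.ndarray] = None,
    banned_q_fwd: Optional[np.ndarray] = None,
    banned_q_rev: Optional[np.ndarray] = None,
) -> list[Anchor]:
    """k-mer-seeded maximal exact-match anchors between two chromosomes.

    Both strands are searched; minus-strand anchors carry strand-space query
    coordinates (on the reverse complement of the query).  k-mers containing
    N never seed; over-represented k-mers (``max_kmer_occ``) are skipped.
    """
    cfg = cfg or AlignConfig(k=k)
    cfg.validate()
    k = cfg.k
    t_arr = _codes(target.seq)
    tk, tv = _kmer_codes(t_arr, k)
    anchors = []
    for strand in "+-":
        q_seq = query.seq if strand == "+" else revcomp(query.seq)
        q_arr = _codes(q_seq)
        qk, qv = _kmer_codes(q_arr, k)
        banned_parts = [
            b
            for b in (banned_t, banned_q_fwd if strand == "+" else banned_q_rev)
            if b is not None and len(b)
        ]
        banned = np.unique(np.concatenate(banned_parts)) if banned_parts else None
        runs = _seed_runs(tk, tv, qk, qv, banned, cfg.max_kmer_occ)
        seen = set()
        for t0, q0, n in runs.T:
            t0, q0, length = int(t0), int(q0), int(n) + k - 1
            # extend to a maximal exact match (k-mer dropouts from banned
            # seeds can split a single MEM into several runs)
            while t0 > 0 and q0 > 0 and t_arr[t0 - 1] == q_arr[q0 - 1] != 255:
                t0 -= 1
                q0 -= 1
                length += 1
            while (
                t0 + length < len(t_arr)
                and q0 + length < len(q_arr)
                and t_arr[t0 + length] == q_arr[q0 + length] != 255
            ):
                length += 1
            key = (t0, q0, strand)
            if length >= cfg.min_anchor_len and key not in seen:
                seen.add(key)
                anchors.append(Anchor(t0, q0, length, strand))
    anchors.sort(key=lambda a: (a.strand, a.t_start, a.q_start))
    return anchors


# --- chaining ---------------------------------------------------------------

def _gap_cost(cfg: AlignConfig, dt: int, dq: int) -> float:
    g = dt + dq
    return 0.0 if g == 0 else cfg.gap_open + cfg.gap_extend * g


def chain_anchors(
    anchors: Sequence[Anchor],
    gap_open: float = 10.0,
    gap_extend: float = 0.05,
    window: int = 64,
    overlap_slack: int = 15,
) -> list[Chain]:
    """Maximally scoring colinear chains by sparse dynamic programming.

    Anchors must come from one (target chrom, query chrom, strand) triple.
    The score of a chain is the sum of anchor lengths minus affine gap costs
    between consecutive anchors; ties break toward smaller target start,
    then smaller query start.  Anchors may overlap a successor by up to
    ``overlap_slack`` bases (junction micro-homology extends both flanking
    exact matches across an SV breakpoint); the successor is trimmed by the
    overlap.  ``window`` bounds the predecessor search (a banding heuristic;
    exact for instances smaller than the window).
    """
    cfg = AlignConfig(gap_open=gap_open, gap_extend=gap_extend, chain_window=window)
    anchors = sorted(anchors, key=lambda a: (a.t_start, a.q_start))
    n = len(anchors)
    f = [float(a.length) for a in anchors]
    bp = [-1] * n
    for i in range(n):
        b = anchors[i]
        for j in range(max(0, i - cfg.chain_window), i):
            a = anchors[j]
            o = max(a.t_end - b.t_start, a.q_end - b.q_start, 0)
            if o > overlap_slack or o >= b.length:
                continue
            cand = (
                f[j]
                + (b.length - o)
                - _gap_cost(cfg, b.t_start + o - a.t_end, b.q_start + o - a.q_end)
            )
            if cand > f[i]:
                f[i] = cand
                bp[i] = j
    order = sorted(range(n), key=lambda i: (-f[i], anchors[i].t_start, anchors[i].q_start))
    used = [False] * n
    chains = []
    for i in order:
        if used[i]:
            continue
        path = []
        j = i
        while j != -1 and not used[j]:
            path.append(j)
            used[j] = True
            j = bp[j]
        path.reverse()
        members: list[Anchor] = []
        for j in path:
            a = anchors[j]
            if members:
                o = max(members[-1].t_end - a.t_start, members[-1].q_end - a.q_start, 0)
                if o >= a.length:
                    continue
                if o > 0:
                    a = Anchor(a.t_start + o, a.q_start + o, a.length - o, a.strand)
            members.append(a)
        score = float(members[0].length)
        for a, b in zip(members, members[1:]):
            score += b.length - _gap_cost(cfg, b.t_start - a.t_end, b.q_start - a.q_end)
        chains.append(Chain("", "", members[0].strand, members, score))
    chains.sort(key=lambda c: (-c.score, c.anchors[0].t_start, c.anchors[0].q_start))
    return chains


# --- netting ----------------------------------------------------------------

def net_chains(
    chains: Sequence[Chain],
    min_chain_score: float = 25.0,
    t_sizes: Optional[dict[str, int]] = None,
    q_sizes: Optional[dict[str, int]] = None,
    gap_open: float = 10.0,
    gap_extend: float = 0.05,
) -> Net:
    """Greedy single-coverage (on target) selection of scored chains.

    Chains are taken in descending score order; anchor parts overlapping
    already-kept anchor bases are trimmed away, and a chain whose remaining
    score falls below ``min_chain_score`` is dropped.  Every trimmed-away
    target interval is recorded in ``overlap_pairs`` — the pre-net overlap
    evidence that repeat (duplication) calls are made from.
    """
    net = Net(t_sizes=dict(t_sizes or {}), q_sizes=dict(q_sizes or {}))
    ranked = sorted(
        chains,
        key=lambda c: (-c.score, c.t_chrom, c.anchors[0].t_start, c.anchors[0].q_start),
    )
    ranked = [c for c in ranked if c.score >= min_chain_score]
    trees: dict[str, IntervalTree] = {}
    for cid, chain in enumerate(ranked):
        chain.chain_id = cid
    for chain in ranked:
        tree = trees.setdefault(chain.t_chrom, IntervalTree())
        survivors = []
        overlaps = []
        for a in chain.anchors:
            cut = sorted(
                (max(iv.begin, a.t_start), min(iv.end, a.t_end), iv.data)
                for iv in tree.overlap(a.t_start, a.t_end)
            )
            pos = a.t_start
            for s, e, owner in cut:
                if s > pos:
                    survivors.append(
                        Anchor(pos, a.q_start + (pos - a.t_start), s - pos, a.strand)
                    )
                overlaps.append((owner, s, e))
                pos = max(pos, e)
            if pos < a.t_end:
                survivors.append(
                    Anchor(pos, a.q_start + (pos - a.t_start), a.t_end - pos, a.strand)
                )
        score = 0.0
        if survivors:
            score = float(survivors[0].length)
            for a, b in zip(survivors, survivors[1:]):
                g = (b.t_start - a.t_end) + (b.q_start - a.q_end)
                score += b.length - (0.0 if g == 0 else gap_open + gap_extend * g)
        kept = bool(survivors) and score >= min_chain_score
        for owner, s, e in overlaps:
            q0 = None
            for a in chain.anchors:
                if a.t_start <= s and e <= a.t_end:
                    q0 = a.q_start + (s - a.t_start)
                    break
            qf = (q0, q0 + (e - s)) if q0 is not None else (0, 0)
            if chain.strand == "-" and q0 is not None:
                qsize = net.q_sizes.get(chain.q_chrom, 0)
                qf = (qsize - qf[1], qsize - qf[0])
            net.overlap_pairs.append(
                OverlapPair(
                    kept_chain=owner,
                    dropped_chain=chain.chain_id,
                    t_chrom=chain.t_chrom,
                    t_start=s,
                    t_end=e,
                    q_chrom=chain.q_chrom,
                    q_start=qf[0],
                    q_end=qf[1],
                    strand=chain.strand,
                    q_size=net.q_sizes.get(chain.q_chrom, 0),
                )
            )
        if kept:
            new_chain = Chain(
                chain.t_chrom, chain.q_chrom, chain.strand, survivors, score, chain.chain_id
            )
            net.chains.append(new_chain)
            for a in survivors:
                tree.addi(a.t_start, a.t_end, chain.chain_id)
    net.blocks = [
        Block(
            c.t_chrom,
            a.t_start,
            a.t_end,
            c.q_chrom,
            a.q_start,
            a.q_end,
            c.strand,
            net.q_sizes.get(c.q_chrom, 0),
            c.chain_id,
        )
        for c in net.chains
        for a in c.anchors
    ]
    net.blocks.sort(key=lambda b: (b.t_chrom, b.t_start, b.t_end, b.q_chrom, b.q_start))
    return net


# --- breakpoint refinement --------------------------------------------------

def _extend_right(tseq, qseq, t, q, t_lim, q_lim, skip_match, stop=None):
    """Steps gained extending a block rightward, stepping over mismatches
    while a lookahead window still votes for continuing homology."""
    n = 0
    window = 2 * skip_match
    while t + n < t_lim and q + n < q_lim:
        if stop is not None and stop(t + n, q + n):
            break
        a, b = tseq[t + n], qseq[q + n]
        if a == b and a != "N":
            n += 1
            continue
        matches = avail = 0
        for r in range(1, window + 1):
            if t + n + r >= t_lim or q + n + r >= q_lim:
                break
            avail += 1
            if tseq[t + n + r] == qseq[q + n + r] != "N":
                matches += 1
        if avail >= skip_match and matches >= 0.6 * avail:
            n += 1
        else:
            break
    return n


def _extend_left(tseq, qseq, t, q, t_lim, q_lim, skip_match, stop=None):
    n = 0
    window = 2 * skip_match
    while t - n - 1 >= t_lim and q - n - 1 >= q_lim:
        if stop is not None and stop(t - n - 1, q - n - 1):
            break
        a, b = tseq[t - n - 1], qseq[q - n - 1]
        if a == b and a != "N":
            n += 1
            continue
        matches = avail = 0
        for r in range(1, window + 1):
            if t - n - 1 - r < t_lim or q - n - 1 - r < q_lim:
                break
            avail += 1
            if tseq[t - n - 1 - r] == qseq[q - n - 1 - r] != "N":
                matches += 1
        if avail >= skip_match and matches >= 0.6 * avail:
            n += 1
        else:
            break
    return n


def refine_blocks(
    net: Net,
    t_seqs: dict[str, str],
    q_axes: dict[tuple[str, str], str],
    skip_match: int = 4,
) -> None:
    """Extend netted blocks into inter-block gaps (in place).

    Each block edge advances along its own chain geometry while bases match,
    stepping over isolated mismatches; this restores SV breakpoints that
    anchor truncation (a substitution within a seed length of the true
    breakpoint) would otherwise shift.
    """
    by_chrom: dict[str, list[int]] = {}
    for i, b in enumerate(net.blocks):
        by_chrom.setdefault(b.t_chrom, []).append(i)
    # query bounds from same-chain neighbours: an extension may not re-consume
    # query sequence its own chain already aligns (tandem-duplication copies
    # would otherwise be absorbed into the bridging chain)
    chain_order: dict[int, list[int]] = {}
    for i, b in enumerate(net.blocks):
        chain_order.setdefault(b.chain_id, []).append(i)
    q_lo, q_hi = {}, {}
    for cid, idxs in chain_order.items():
        idxs.sort(key=lambda i: net.blocks[i].t_start)
        for r, i in enumerate(idxs):
            q_lo[i] = net.blocks[idxs[r - 1]].q_end if r > 0 else 0
            q_hi[i] = (
                net.blocks[idxs[r + 1]].q_start if r + 1 < len(idxs) else None
            )
    new_blocks = list(net.blocks)
    for chrom, idxs in by_chrom.items():
        tseq = t_seqs[chrom]
        for pos, i in enumerate(idxs):
            b = new_blocks[i]
            qseq = q_axes[(b.q_chrom, b.strand)]
            left_lim = new_blocks[idxs[pos - 1]].t_end if pos > 0 else 0
            right_lim = (
                new_blocks[idxs[pos + 1]].t_start
                if pos + 1 < len(idxs)
                else len(tseq)
            )
            q_left_lim = q_lo[i]
            q_right_lim = len(qseq) if q_hi[i] is None else min(len(qseq), q_hi[i])
            nl = _extend_left(
                tseq, qseq, b.t_start, b.q_start, left_lim, q_left_lim, skip_match
            )
            nr = _extend_right(
                tseq, qseq, b.t_end, b.q_end, right_lim, q_right_lim, skip_match
            )
            if nl or nr:
                new_blocks[i] = Block(
                    b.t_chrom,
                    b.t_start - nl,
                    b.t_end + nr,
                    b.q_chrom,
                    b.q_start - nl,
                    b.q_end + nr,
                    b.strand,
                    b.q_size,
                    b.chain_id,
                )
    net.blocks = new_blocks
    # keep chain anchor geometry in sync with the refined blocks
    members: dict[int, list[Block]] = {}
    for b in net.blocks:
        members.setdefault(b.chain_id, []).append(b)
    for c in net.chains:
        blocks = sorted(members.get(c.chain_id, []), key=lambda b: b.t_start)
        c.anchors = [Anchor(b.t_start, b.q_start, b.t_len, b.strand) for b in blocks]


def merge_overlap_pairs(
    net: Net,
    t_seqs: dict[str, str],
    q_axes: dict[tuple[str, str], str],
    min_gap: int = 50,
    skip_match: int = 4,
    min_raw_len: int = 20,
    max_extend: int = 2000,
) -> None:
    """Consolidate and sharpen pre-net overlap evidence (in place).

    Overlap intervals from the same (kept, dropped) chain pair are merged
    when separated by less than ``min_gap`` (substitutions fragment the
    dropped chain's anchors), then each merged interval is extended with the
    mismatch-skipping matcher so the duplicated footprint is recovered at
    base resolution.  Merged intervals shorter than ``min_raw_len`` are
    discarded: a few bases of chance overlap between unrelated chains is not
    duplication evidence, and extending it would manufacture one.
    ``max_extend`` bounds the sharpening to the scale of anchor truncation.
    """
    # kept-chain mapping per target position: extension stops where the
    # dropped chain's alignment coincides with the kept alignment (past the
    # duplicated copy the two chains align the same bases, which is no
    # longer duplication evidence)
    kept_idx: dict[tuple[str, str, str], list[tuple[int, int, int]]] = {}
    for b in net.blocks:
        kept_idx.setdefault((b.t_chrom, b.q_chrom, b.strand), []).append(
            (b.t_start, b.t_end, b.q_start)
        )
    for key in kept_idx:
        kept_idx[key].sort()

    def _coincides(key, t, q):
        import bisect as _bisect

        rows = kept_idx.get(key, ())
        i = _bisect.bisect_right(rows, (t, float("inf"), float("inf"))) - 1
        while i >= 0:
            ts, te, qs = rows[i]
            if te <= t:
                break
            if ts <= t < te and qs + (t - ts) == q:
                return True
            i -= 1
        return False

    groups: dict[tuple, list[OverlapPair]] = {}
    for op in net.overlap_pairs:
        groups.setdefault((op.kept_chain, op.dropped_chain, op.t_chrom, op.q_chrom, op.strand), []).append(op)
    merged: list[OverlapPair] = []
    for (kept, dropped, t_chrom, q_chrom, strand), ops in sorted(
        groups.items(), key=lambda kv: kv[0]
    ):
        ops.sort(key=lambda op: op.t_start)
        cur = ops[0]
        out = [cur]
        for op in ops[1:]:
            if op.t_start - out[-1].t_end < min_gap:
                prev = out[-1]
                out[-1] = OverlapPair(
                    kept, dropped, t_chrom, prev.t_start, max(prev.t_end, op.t_end),
                    q_chrom, min(prev.q_start, op.q_start), max(prev.q_end, op.q_end),
                    strand, op.q_size,
                )
            else:
                out.append(op)
        for op in out:
            if op.t_end - op.t_start < min_raw_len:
                continue
            tseq = t_seqs.get(t_chrom)
            qseq = q_axes.get((q_chrom, strand))
            if tseq is None or qseq is None:
                merged.append(op)
                continue
            # strand-space query start of the target interval
            qss = op.q_start if strand == "+" else op.q_size - op.q_end
            key = (t_chrom, q_chrom, strand)
            stop = lambda t, q: _coincides(key, t, q)  # noqa: E731
            nl = _extend_left(
                tseq, qseq, op.t_start, qss,
                max(0, op.t_start - max_extend), max(0, qss - max_extend),
                skip_match, stop,
            )
            nr = _extend_right(
                tseq, qseq, op.t_end, qss + (op.t_end - op.t_start),
                min(len(tseq), op.t_end + max_extend),
                min(len(qseq), qss + (op.t_end - op.t_start) + max_extend),
                skip_match, stop,
            )
            qss2, qee2 = qss - nl, qss + (op.t_end - op.t_start) + nr
            qf = (qss2, qee2) if strand == "+" else (op.q_size - qee2, op.q_size - qss2)
            merged.append(
                OverlapPair(
                    kept, dropped, t_chrom, op.t_start - nl, op.t_end + nr,
                    q_chrom, qf[0], qf[1], strand, op.q_size,
                )
            )
    merged.sort(key=lambda op: (op.t_chrom, op.t_start, op.t_end))
    net.overlap_pairs = merged


# --- full pairwise alignment ------------------------------------------------

def align_genomes(
    target: Sequence[GenomeSequence],
    query: Sequence[GenomeSequence],
    cfg: Optional[AlignConfig] = None,
) -> Net:
    """LASTZ→chain→net stand-in: anchor, chain and net two genomes."""
    cfg = cfg or AlignConfig()
    cfg.validate()
    banned_t = banned_kmers(target, cfg.k, cfg.max_kmer_occ)
    banned_q_fwd = banned_kmers(query, cfg.k, cfg.max_kmer_occ)
    banned_q_rev = banned_kmers(
        [GenomeSequence(gs.name, revcomp(gs.seq)) for gs in query],
        cfg.k,
        cfg.max_kmer_occ,
    )
    all_chains = []
    for t in target:
        for q in query:
            anchors = find_anchors(
                t, q, cfg.k, cfg, banned_t, banned_q_fwd, banned_q_rev
            )
            for strand in "+-":
                sub = [a for a in anchors if a.strand == strand]
                if not sub:
                    continue
                for c in chain_anchors(
                    sub, cfg.gap_open, cfg.gap_extend, cfg.chain_window, cfg.overlap_slack
                ):
                    c.t_chrom, c.q_chrom = t.name, q.name
                    all_chains.append(c)
    net = net_chains(
        all_chains,
        cfg.min_chain_score,
        {gs.name: len(gs.seq) for gs in target},
        {gs.name: len(gs.seq) for gs in query},
        cfg.gap_open,
        cfg.gap_extend,
    )
    if cfg.refine:
        t_seqs = {gs.name: gs.seq for gs in target}
        q_axes = {}
        for gs in query:
            q_axes[(gs.name, "+")] = gs.seq
            q_axes[(gs.name, "-")] = revcomp(gs.seq)
        refine_blocks(net, t_seqs, q_axes, cfg.refine_skip_match)
        merge_overlap_pairs(net, t_seqs, q_axes, skip_match=cfg.refine_skip_match)
    return net


def net_to_maf(
    net: Net,
    target: Sequence[GenomeSequence],
    query: Sequence[GenomeSequence],
    target_name: str = "target",
    query_name: str = "query",
) -> list[MafBlock]:
    """One MAF block per netted gapless block, sorted by target coordinate."""
    t_seqs = {gs.name: gs.seq for gs in target}
    q_axes = {}
    for gs in query:
        q_axes[(gs.name, "+")] = gs.seq
        q_axes[(gs.name, "-")] = revcomp(gs.seq)
    out = []
    for b in sorted(net.blocks, key=lambda b: (b.t_chrom, b.t_start, b.q_chrom, b.q_start)):
        t_text = t_seqs[b.t_chrom][b.t_start : b.t_end]
        q_text = q_axes[(b.q_chrom, b.strand)][b.q_start : b.q_end]
        out.append(
            MafBlock(
                MafSeq(
                    f"{target_name}.{b.t_chrom}",
                    b.t_start,
                    b.t_len,
                    "+",
                    len(t_seqs[b.t_chrom]),
                    t_text,
                ),
                MafSeq(
                    f"{query_name}.{b.q_chrom}",
                    b.q_start,
                    b.q_end - b.q_start,
                    b.strand,
                    b.q_size,
                    q_text,
                ),
                float(b.t_len),
            )
        )
    return out
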