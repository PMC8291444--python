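"""Dog-specific SVs and three-way shared/specific sequence content.

Both pairwise comparisons share the dog as target, so lineage-specific SVs
are derived by intersecting the dog–wolf and dog–dhole call sets directly on
dog coordinates: an SV present in both comparisons arose on the dog branch,
one present in only one comparison reflects change on the other lineage.
The base-level counterpart partitions every genome into
aligned-to-both / aligned-to-one / specific content from the three pairwise
alignments (the Venn view of shared sequence).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .models import GeneModel, GenomeSequence, MafBlock, SvCall


class LineageError(ValueError):
    pass


@dataclass
class LineageSvSet:
    dog_specific: list[SvCall]
    dog_wolf_only: list[SvCall]
    dog_dhole_only: list[SvCall]
    matching: list[tuple[SvCall, SvCall]]


def _sort_key(c: SvCall):
    return (c.t_chrom, c.t_start, c.t_end, c.sv_type, c.length, c.q_chrom, c.q_start)


def _indel_match(a: SvCall, b: SvCall, bp_tol: int, len_ratio: float) -> bool:
    if a.t_chrom != b.t_chrom:
        return False
    if abs(a.t_start - b.t_start) > bp_tol:
        return False
    lo, hi = sorted((a.length, b.length))
    return hi > 0 and lo / hi >= len_ratio


def _recip_overlap(a: SvCall, b: SvCall) -> float:
    if a.t_chrom != b.t_chrom:
        return 0.0
    ov = min(a.t_end, b.t_end) - max(a.t_start, b.t_start)
    if ov <= 0:
        return 0.0
    la, lb = a.t_end - a.t_start, b.t_end - b.t_start
    return min(ov / la if la else 0.0, ov / lb if lb else 0.0)


def derive_dog_specific(
    svs_dw: list[SvCall],
    svs_dd: list[SvCall],
    recip: float = 0.5,
    bp_tol: int = 50,
    len_ratio: float = 0.5,
) -> LineageSvSet:
    """Intersect the two dog-target call sets into a lineage-resolved set.

    Two calls match iff they have the same type and agree positionally:
    indels (whose target interval is a breakpoint for DEL) match on
    breakpoint distance <= ``bp_tol`` plus length ratio >= ``len_ratio``;
    INV/TRA match on reciprocal overlap >= ``recip``.  REP intervals are
    rotation-ambiguous (any length-L window of a tandem array represents
    the duplication), so two REP calls of matching length agree when their
    intervals sit within one copy length of each other, even without
    direct overlap.  Matched pairs are dog-branch events (reported at the
    dog–wolf coordinates); unmatched calls reflect wolf- or dhole-lineage
    change.  Deterministic under input permutation (inputs are canonically
    sorted first).
    """
    dw = sorted(svs_dw, key=_sort_key)
    dd = sorted(svs_dd, key=_sort_key)
    for c in dw + dd:
        if c.comparison and c.comparison not in ("dog_wolf", "dog_dhole"):
            raise LineageError(
                f"unexpected comparison label {c.comparison!r}: both inputs "
                "must be on dog coordinates"
            )
    used_dd = [False] * len(dd)
    matching: list[tuple[SvCall, SvCall]] = []
    dog_specific: list[SvCall] = []
    dw_only: list[SvCall] = []
    for a in dw:
        best, best_score = None, None
        for j, b in enumerate(dd):
            if used_dd[j] or b.sv_type != a.sv_type:
                continue
            if a.sv_type in ("INS", "DEL"):
                if not _indel_match(a, b, bp_tol, len_ratio):
                    continue
                score = -abs(a.t_start - b.t_start)
            elif a.sv_type == "REP":
                lo, hi = sorted((a.length, b.length))
                if a.t_chrom != b.t_chrom or hi == 0 or lo / hi < len_ratio:
                    continue
                if abs(a.t_start - b.t_start) > hi + bp_tol:
                    continue
                score = -abs(a.t_start - b.t_start)
            else:
                r = _recip_overlap(a, b)
                if r < recip:
                    continue
                score = r
            if best_score is None or score > best_score:
                best, best_score = j, score
        if best is None:
            dw_only.append(a)
        else:
            used_dd[best] = True
            matching.append((a, dd[best]))
            dog_specific.append(a)
    dd_only = [b for j, b in enumerate(dd) if not used_dd[j]]
    return LineageSvSet(dog_specific, dw_only, dd_only, matching)


# --- base-level Venn partition ----------------------------------------------


def aligned_masks(
    blocks: list[MafBlock], fill_gap: int = 50
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Per-chromosome aligned-base masks for both genomes of a pairwise MAF.

    Chromosome names are taken from the part of each row's ``src`` after the
    first dot.  Small gaps (< ``fill_gap`` on both sides) between colinear
    adjacent blocks are counted as aligned: they are substitution noise, not
    missing homology.
    """
    t_masks: dict[str, np.ndarray] = {}
    q_masks: dict[str, np.ndarray] = {}
    for b in blocks:
        tc = b.target.src.split(".", 1)[-1]
        qc = b.query.src.split(".", 1)[-1]
        if tc not in t_masks:
            t_masks[tc] = np.zeros(b.target.src_size, bool)
        if qc not in q_masks:
            q_masks[qc] = np.zeros(b.query.src_size, bool)
        t_masks[tc][b.target.start : b.target.start + b.target.size] = True
        qf = b.query.forward_interval()
        q_masks[qc][qf[0] : qf[1]] = True
    order = sorted(
        range(len(blocks)),
        key=lambda i: (blocks[i].target.src, blocks[i].target.start),
    )
    for i, j in zip(order, order[1:]):
        a, b = blocks[i], blocks[j]
        if a.target.src != b.target.src or a.query.src != b.query.src:
            continue
        if a.query.strand != b.query.strand:
            continue
        gT = b.target.start - (a.target.start + a.target.size)
        gQ = b.query.start - (a.query.start + a.query.size)
        if 0 <= gT < fill_gap and 0 <= gQ < fill_gap:
            tc = a.target.src.split(".", 1)[-1]
            t_masks[tc][a.target.start + a.target.size : b.target.start] = True
            qf_a = a.query.forward_interval()
            qf_b = b.query.forward_interval()
            qc = a.query.src.split(".", 1)[-1]
            lo, hi = min(qf_a[1], qf_b[1]), max(qf_a[0], qf_b[0])
            q_masks[qc][lo:hi] = True
    return t_masks, q_masks


@dataclass
class VennPartition:
    """Base counts for one genome against the other two."""

    genome: str
    shared_all: int
    shared_one: dict[str, int]
    specific: int
    n_bases: int
    total: int
    specific_mask: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    @property
    def assayable(self) -> int:
        return self.total - self.n_bases

    def check_conservation(self) -> None:
        got = self.shared_all + sum(self.shared_one.values()) + self.specific
        if got != self.assayable:
            raise LineageError(
                f"{self.genome}: partition categories sum to {got}, "
                f"expected {self.assayable}"
            )


def venn_partition(
    genomes: dict[str, list[GenomeSequence]],
    pair_masks: dict[tuple[str, str], dict[str, np.ndarray]],
) -> dict[str, VennPartition]:
    """Assign every non-N base of each genome to exactly one of four
    categories: aligned to both other genomes, aligned to exactly one
    (either), or genome-specific.

    ``pair_masks[(a, b)]`` is genome *a*'s aligned mask against genome *b*
    (as produced by :func:`aligned_masks`).
    """
    out = {}
    names = sorted(genomes)
    for g in names:
        others = [o for o in names if o != g]
        shared_all = 0
        shared_one = {o: 0 for o in others}
        specific = 0
        n_bases = 0
        total = 0
        spec_masks = {}
        for gs in genomes[g]:
            total += len(gs.seq)
            seq = np.frombuffer(gs.seq.encode(), np.uint8)
            non_n = seq != ord("N")
            n_bases += int((~non_n).sum())
            masks = []
            for o in others:
                m = pair_masks.get((g, o), {}).get(gs.name)
                if m is None:
                    m = np.zeros(len(gs.seq), bool)
                if len(m) != len(gs.seq):
                    raise LineageError(
                        f"mask length {len(m)} != chromosome length "
                        f"{len(gs.seq)} for {g}.{gs.name}"
                    )
                masks.append(m)
            both = masks[0] & masks[1] & non_n
            only = [
                (masks[0] & ~masks[1] & non_n),
                (masks[1] & ~masks[0] & non_n),
            ]
            spec = ~masks[0] & ~masks[1] & non_n
            shared_all += int(both.sum())
            shared_one[others[0]] += int(only[0].sum())
            shared_one[others[1]] += int(only[1].sum())
            specific += int(spec.sum())
            spec_masks[gs.name] = spec
        part = VennPartition(
            g, shared_all, shared_one, specific, n_bases, total, spec_masks
        )
        part.check_conservation()
        out[g] = part
    return out


def genes_in_specific_regions(
    partition: VennPartition, genes: list[GeneModel]
) -> list[str]:
    """Gene ids whose full transcript span lies in genome-specific bases."""
    out = []
    for g in genes:
        mask = partition.specific_mask.get(g.chrom)
        if mask is None:
            continue
        if g.tx_end <= len(mask) and bool(mask[g.tx_start : g.tx_end].all()):
            out.append(g.id)
    return out
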