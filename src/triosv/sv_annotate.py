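"""Genic annotation of SV calls and retrocopy-bearing insertions.

Each SV gets exactly one category by precedence CDS > UTR >
exon_noncoding > intron > intergenic over all overlapped gene models
(CDS-first is the conservative choice for asking how often SVs disturb
coding sequence).  Insertions that fully contain a gene are screened for
the retrocopy signature: near-identity of the covered gene's sequence to
the *spliced* transcript of a multi-exon gene elsewhere in the genome.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .models import GeneModel, GenomeSequence, SvAnnotation, SvCall

CATEGORIES = ("CDS", "UTR", "exon_noncoding", "intron", "intergenic")


def _sv_interval(sv: SvCall) -> tuple[int, int]:
    """Query interval of a call on the target genome; DEL breakpoints are
    widened to one base so interval lookup is well defined."""
    if sv.t_end > sv.t_start:
        return sv.t_start, sv.t_end
    return sv.t_start, sv.t_start + 1


def _feature_trees(genes: Sequence[GeneModel]) -> dict[str, dict[str, IntervalTree]]:
    trees: dict[str, dict[str, IntervalTree]] = {
        cat: {} for cat in ("CDS", "UTR", "exon_noncoding", "intron", "gene")
    }

    def add(cat: str, chrom: str, s: int, e: int, gid: str):
        if e > s:
            trees[cat].setdefault(chrom, IntervalTree()).addi(s, e, gid)

    for g in genes:
        add("gene", g.chrom, g.tx_start, g.tx_end, g.id)
        if g.cds:
            for s, e in g.cds:
                add("CDS", g.chrom, s, e, g.id)
            for s, e in g.utr:
                add("UTR", g.chrom, s, e, g.id)
        else:
            for s, e in g.exons:
                add("exon_noncoding", g.chrom, s, e, g.id)
        for s, e in g.introns:
            add("intron", g.chrom, s, e, g.id)
    return trees


def annotate_svs(
    svs: Sequence[SvCall],
    genes: Sequence[GeneModel],
    precedence: Sequence[str] = CATEGORIES,
) -> tuple[list[SvAnnotation], pd.DataFrame]:
    """Classify every SV's genic context; returns annotations plus a
    (sv_type x category) count table.

    Annotation is independent of gene input order, and per sv_type the
    category counts sum to the number of SVs.
    """
    trees = _feature_trees(sorted(genes, key=lambda g: (g.chrom, g.tx_start, g.id)))
    annotations = []
    for i, sv in enumerate(svs):
        s, e = _sv_interval(sv)
        category = "intergenic"
        for cat in precedence:
            if cat == "intergenic":
                break
            tree = trees.get(cat, {}).get(sv.t_chrom)
            if tree is not None and tree.overlap(s, e):
                category = cat
                break
        gene_tree = trees["gene"].get(sv.t_chrom)
        hits = sorted(iv.data for iv in gene_tree.overlap(s, e)) if gene_tree else []
        covers = any(
            iv.begin >= s and iv.end <= e
            for iv in (gene_tree.overlap(s, e) if gene_tree else ())
        )
        annotations.append(
            SvAnnotation(i, sv.sv_type, category, tuple(hits), covers)
        )
    table = pd.DataFrame(
        0,
        index=sorted({sv.sv_type for sv in svs}),
        columns=list(precedence),
        dtype=int,
    )
    for ann in annotations:
        table.loc[ann.sv_type, ann.category] += 1
    return annotations, table


@dataclass(frozen=True)
class RetroSignature:
    """Evidence that a covered gene is an intron-less copy of another."""

    covered_gene: str
    is_retrocopy: bool
    parent_gene: Optional[str] = None
    identity: float = 0.0
    introns_removed: int = 0


def find_gene_covering_insertions(
    svs: Sequence[SvCall],
    genes: Sequence[GeneModel],
    genome: Optional[Sequence[GenomeSequence]] = None,
    retro_ident: float = 0.98,
    containment_slack: int = 0,
) -> list[tuple[SvCall, GeneModel, RetroSignature]]:
    """Insertions whose target interval fully contains a gene.

    Containment means the transcript span lies inside the insertion
    (widened by ``containment_slack`` bases on each side).  When the genome
    sequence is supplied, each covered gene is compared against the spliced
    transcripts of all multi-exon genes: a match at >= ``retro_ident``
    identity with at least one removed intron is a retrocopy signature.
    """
    import edlib

    seqs = {gs.name: gs.seq for gs in genome} if genome else None
    out = []
    for sv in svs:
        if sv.sv_type != "INS":
            continue
        for g in sorted(genes, key=lambda g: (g.chrom, g.tx_start, g.id)):
            if g.chrom != sv.t_chrom:
                continue
            if not (
                g.tx_start >= sv.t_start - containment_slack
                and g.tx_end <= sv.t_end + containment_slack
            ):
                continue
            sig = RetroSignature(g.id, False)
            if seqs is not None:
                covered_seq = g.spliced_seq(seqs[g.chrom])
                best = None
                for h in genes:
                    if h.id == g.id or h.n_exons < 2 or h.chrom not in seqs:
                        continue
                    spliced = h.spliced_seq(seqs[h.chrom])
                    if abs(len(spliced) - len(covered_seq)) > (1 - retro_ident) * max(
                        len(spliced), len(covered_seq)
                    ):
                        continue
                    res = edlib.align(covered_seq, spliced, mode="NW", task="distance")
                    ident = 1 - res["editDistance"] / max(len(spliced), len(covered_seq))
                    if ident >= retro_ident and (best is None or ident > best[1]):
                        best = (h, ident)
                if best is not None:
                    sig = RetroSignature(
                        g.id, True, best[0].id, best[1], best[0].n_exons - g.n_exons
                    )
            out.append((sv, g, sig))
    return out
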