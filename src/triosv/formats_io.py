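"""Readers and writers for the external formats the pipeline touches.

Dialects (strict):

* FASTA — uppercase on read; only ``{A,C,G,T,N}`` accepted.
* MAF — exactly two ``s`` rows per block, target row first.  Minus-strand
  starts follow the MAF convention (counted on the reverse complement).
* BED / bedGraph — 0-based half-open, as on disk.
* GFF3 — 1-based inclusive on disk, converted to 0-based half-open in memory.
* TSV reports — versioned with a ``#`` header line; interval columns in
  report files meant for humans are printed 1-based inclusive where noted.

Parsing of FASTA/FASTQ/MAF is delegated to Biopython and GFF3 to gffutils;
this module enforces the stricter contracts (alphabet, row counts, coordinate
sanity) on top.
"""

from __future__ import annotations

import os
from typing import Iterable, Optional, Sequence

import numpy as np
from Bio import AlignIO, SeqIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import (
    BedRecord,
    CoverageTrack,
    GeneModel,
    GenomeSequence,
    MafBlock,
    MafSeq,
    SvCall,
    TruthRecord,
)

VALID_BASES = frozenset("ACGTN")


class ParseError(ValueError):
    """Malformed input file; the message names the file and location."""


# --- FASTA ------------------------------------------------------------------

def _find_bad_fasta_line(path: str) -> tuple[int, str]:
    """Locate the first offending line for a helpful error message."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(">"):
                continue
            if set(line.upper()) - VALID_BASES:
                return lineno, line
    return 0, ""


def read_fasta(path: str) -> list[GenomeSequence]:
    """Read a genome FASTA; sequences are uppercased and alphabet-checked."""
    out = []
    names = set()
    try:
        records = list(SeqIO.parse(path, "fasta"))
    except ValueError as exc:
        raise ParseError(f"{path}: malformed FASTA ({exc})") from exc
    for rec in records:
        seq = str(rec.seq).upper()
        if not rec.id:
            raise ParseError(f"{path}: record with empty header")
        if not seq:
            raise ParseError(f"{path}: empty sequence for {rec.id!r}")
        if set(seq) - VALID_BASES:
            lineno, _ = _find_bad_fasta_line(path)
            raise ParseError(
                f"{path}: invalid character outside ACGTN at line {lineno}"
            )
        if rec.id in names:
            raise ParseError(f"{path}: duplicate sequence name {rec.id!r}")
        names.add(rec.id)
        out.append(GenomeSequence(rec.id, seq))
    if not out and os.path.getsize(path) > 0:
        raise ParseError(f"{path}: no FASTA records found (malformed header?)")
    return out


def write_fasta(seqs: Iterable[GenomeSequence], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for gs in seqs:
            fh.write(f">{gs.name}\n")
            for i in range(0, len(gs.seq), width):
                fh.write(gs.seq[i : i + width] + "\n")


# --- MAF --------------------------------------------------------------------

def read_maf(path: str) -> list[MafBlock]:
    """Read a pairwise MAF; every block must have exactly two 's' rows."""
    blocks = []
    if os.path.getsize(path) == 0:
        return blocks
    for idx, aln in enumerate(AlignIO.parse(path, "maf")):
        if len(aln) != 2:
            raise ParseError(
                f"{path}: block {idx} has {len(aln)} sequence rows, expected 2"
            )
        rows = []
        for rec in aln:
            ann = rec.annotations
            strand = "+" if ann["strand"] in (1, "+") else "-"
            rows.append(
                MafSeq(
                    src=rec.id,
                    start=int(ann["start"]),
                    size=int(ann["size"]),
                    strand=strand,
                    src_size=int(ann["srcSize"]),
                    text=str(rec.seq).upper(),
                )
            )
        score = float(getattr(aln, "_annotations", {}).get("score", 0.0))
        blocks.append(MafBlock(target=rows[0], query=rows[1], score=score))
    return blocks


def write_maf(blocks: Sequence[MafBlock], path: str) -> None:
    alns = []
    for b in blocks:
        recs = []
        for row in (b.target, b.query):
            rec = SeqRecord(Seq(row.text), id=row.src, description="")
            rec.annotations = {
                "start": row.start,
                "size": row.size,
                "strand": 1 if row.strand == "+" else -1,
                "srcSize": row.src_size,
            }
            recs.append(rec)
        aln = MultipleSeqAlignment(recs)
        aln._annotations = {"score": repr(b.score)}
        alns.append(aln)
    with open(path, "w") as fh:
        if alns:
            AlignIO.write(alns, fh, "maf")
        # an empty MAF is an empty file


# --- BED / bedGraph ---------------------------------------------------------

def read_bed(path: str, chrom_sizes: Optional[dict[str, int]] = None) -> list[BedRecord]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ParseError(f"{path}:{lineno}: fewer than 3 BED columns")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            if start >= end or start < 0:
                raise ParseError(
                    f"{path}:{lineno}: inverted/negative interval {start}-{end}"
                )
            if chrom_sizes is not None:
                if chrom not in chrom_sizes:
                    raise ParseError(f"{path}:{lineno}: unknown chrom {chrom!r}")
                if end > chrom_sizes[chrom]:
                    raise ParseError(f"{path}:{lineno}: interval beyond chrom end")
            name = f[3] if len(f) > 3 else ""
            score = float(f[4]) if len(f) > 4 and f[4] not in (".", "") else None
            strand = f[5] if len(f) > 5 else "."
            out.append(BedRecord(chrom, start, end, name, score, strand))
    return out


def write_bed(records: Iterable[BedRecord], path: str) -> None:
    with open(path, "w") as fh:
        for r in records:
            score = "." if r.score is None else f"{r.score:g}"
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\t{score}\t{r.strand}\n")


def read_bedgraph(
    path: str,
    sample: Optional[str] = None,
    species: str = "",
    sample_seq_depth: float = 1.0,
) -> CoverageTrack:
    """Read a single-region bedGraph into a dense per-base coverage track.

    All lines must be on one chromosome; uncovered bases inside the spanned
    region get depth 0 (unsequenced bases are denoted 0).
    """
    rows = []
    chrom = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split()
            if len(f) != 4:
                raise ParseError(f"{path}:{lineno}: expected 4 bedGraph columns")
            c, s, e, v = f[0], int(f[1]), int(f[2]), float(f[3])
            if s >= e or s < 0:
                raise ParseError(f"{path}:{lineno}: inverted interval {s}-{e}")
            if chrom is None:
                chrom = c
            elif c != chrom:
                raise ParseError(
                    f"{path}:{lineno}: multiple chromosomes in one track"
                )
            rows.append((s, e, v))
    if not rows:
        raise ParseError(f"{path}: empty bedGraph")
    start = min(r[0] for r in rows)
    end = max(r[1] for r in rows)
    depth = np.zeros(end - start)
    for s, e, v in rows:
        depth[s - start : e - start] = v
    return CoverageTrack(
        sample=sample or os.path.splitext(os.path.basename(path))[0],
        species=species,
        chrom=chrom,
        start=start,
        end=end,
        depth=depth,
        sample_seq_depth=sample_seq_depth,
    )


def write_bedgraph(track: CoverageTrack, path: str) -> None:
    """Write a dense track as run-length-encoded bedGraph."""
    d = track.depth
    with open(path, "w") as fh:
        if len(d) == 0:
            return
        change = np.flatnonzero(np.diff(d)) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [len(d)]))
        for s, e in zip(starts, ends):
            fh.write(
                f"{track.chrom}\t{track.start + s}\t{track.start + e}\t{d[s]:g}\n"
            )


# --- GFF3 -------------------------------------------------------------------

def read_gff3_genes(path: str) -> list[GeneModel]:
    """Read gene models (gene/exon/CDS features) from GFF3.

    Disk coordinates are 1-based inclusive; in-memory models are 0-based
    half-open.
    """
    import gffutils

    db = gffutils.create_db(
        path,
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for g in db.features_of_type("gene", order_by=("seqid", "start")):
        exons = []
        cds = []
        for child in db.children(g.id, featuretype=("exon", "CDS")):
            iv = (child.start - 1, child.end)
            if iv[0] >= iv[1]:
                raise ParseError(f"{path}: inverted feature interval in {g.id}")
            (exons if child.featuretype == "exon" else cds).append(iv)
        if not exons:
            exons = [(g.start - 1, g.end)]
        genes.append(
            GeneModel(
                id=g.id,
                chrom=g.seqid,
                strand=g.strand if g.strand in "+-" else "+",
                tx_start=g.start - 1,
                tx_end=g.end,
                exons=tuple(sorted(exons)),
                cds=tuple(sorted(cds)),
            )
        )
    return genes


def write_gff3_genes(genes: Iterable[GeneModel], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\ttriosv\tgene\t{g.tx_start + 1}\t{g.tx_end}\t.\t"
                f"{g.strand}\t.\tID={g.id}\n"
            )
            mrna = f"{g.id}.t1"
            fh.write(
                f"{g.chrom}\ttriosv\tmRNA\t{g.tx_start + 1}\t{g.tx_end}\t.\t"
                f"{g.strand}\t.\tID={mrna};Parent={g.id}\n"
            )
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write(
                    f"{g.chrom}\ttriosv\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={mrna}.exon{i};Parent={mrna}\n"
                )
            for i, (s, e) in enumerate(g.cds, 1):
                fh.write(
                    f"{g.chrom}\ttriosv\tCDS\t{s + 1}\t{e}\t.\t{g.strand}\t0\t"
                    f"ID={mrna}.cds{i};Parent={mrna}\n"
                )


# --- FASTQ ------------------------------------------------------------------

def read_fastq(path: str) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(path, "fastq")]


def write_fastq(reads: Iterable[tuple[str, str]], path: str) -> None:
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


# --- SV / truth TSV reports -------------------------------------------------

SV_TSV_VERSION = "triosv.sv.v1"
_SV_COLS = (
    "sv_type t_chrom t_start t_end q_chrom q_start q_end length comparison".split()
)


def write_sv_tsv(calls: Sequence[SvCall], path: str) -> None:
    """Versioned TSV of SV calls (0-based half-open coordinates)."""
    with open(path, "w") as fh:
        fh.write(f"# {SV_TSV_VERSION} coords=0-based-half-open\n")
        fh.write("\t".join(_SV_COLS) + "\n")
        for c in calls:
            fh.write(
                f"{c.sv_type}\t{c.t_chrom}\t{c.t_start}\t{c.t_end}\t"
                f"{c.q_chrom}\t{c.q_start}\t{c.q_end}\t{c.length}\t{c.comparison}\n"
            )


def read_sv_tsv(path: str) -> list[SvCall]:
    out = []
    with open(path) as fh:
        header_seen = False
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if not header_seen:
                if f[: len(_SV_COLS)] != _SV_COLS:
                    raise ParseError(f"{path}:{lineno}: unexpected SV TSV header")
                header_seen = True
                continue
            out.append(
                SvCall(
                    sv_type=f[0],
                    t_chrom=f[1],
                    t_start=int(f[2]),
                    t_end=int(f[3]),
                    q_chrom=f[4],
                    q_start=int(f[5]),
                    q_end=int(f[6]),
                    length=int(f[7]),
                    comparison=f[8] if len(f) > 8 else "",
                )
            )
    return out


TRUTH_TSV_VERSION = "triosv.truth.v1"


def write_truth_tsv(records: Sequence[TruthRecord], path: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {TRUTH_TSV_VERSION} coords=0-based-half-open\n")
        fh.write(
            "event_id\tbranch\tsv_type\tlength\tanc_chrom\tanc_start\tanc_end"
            "\tis_retrocopy\tcoords\n"
        )
        for r in records:
            coords = ";".join(
                f"{g}:{c[0]}:{c[1]}:{c[2]}" for g, c in r.coords
            )
            fh.write(
                f"{r.event_id}\t{r.branch}\t{r.sv_type}\t{r.length}\t"
                f"{r.anc_chrom}\t{r.anc_start}\t{r.anc_end}\t"
                f"{int(r.is_retrocopy)}\t{coords}\n"
            )


def read_truth_tsv(path: str) -> list[TruthRecord]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("event_id\t"):
                continue
            f = line.split("\t")
            coords = []
            if len(f) > 8 and f[8]:
                for tok in f[8].split(";"):
                    g, c, s, e = tok.split(":")
                    coords.append((g, (c, int(s), int(e))))
            out.append(
                TruthRecord(
                    event_id=int(f[0]),
                    branch=f[1],
                    sv_type=f[2],
                    length=int(f[3]),
                    anc_chrom=f[4],
                    anc_start=int(f[5]),
                    anc_end=int(f[6]),
                    coords=tuple(coords),
                    is_retrocopy=bool(int(f[7])),
                )
            )
    return out
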