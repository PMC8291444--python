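"""Shared domain types for the trio SV pipeline.

Coordinates are 0-based half-open everywhere in memory.  On-disk formats keep
their native conventions (GFF3 1-based inclusive, MAF minus-strand starts
counted on the reverse complement); the readers/writers in
:mod:`triosv.formats_io` do the conversions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

SV_TYPES = ("INS", "DEL", "INV", "TRA", "REP")

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class GenomeSequence:
    """One chromosome/scaffold: uppercase DNA over {A,C,G,T,N}."""

    name: str
    seq: str

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class BedRecord:
    chrom: str
    start: int
    end: int
    name: str = ""
    score: Optional[float] = None
    strand: str = "."

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid BED interval {self.chrom}:{self.start}-{self.end}"
            )


@dataclass(frozen=True)
class MafSeq:
    """One 's' line of a MAF block.

    ``start`` follows the MAF convention: for strand '-', it counts from the
    start of the reverse complement of the source sequence.
    """

    src: str
    start: int
    size: int
    strand: str
    src_size: int
    text: str

    def forward_interval(self) -> tuple[int, int]:
        """Interval on the forward strand of the source sequence."""
        if self.strand == "+":
            return self.start, self.start + self.size
        return self.src_size - self.start - self.size, self.src_size - self.start


@dataclass(frozen=True)
class MafBlock:
    """A two-row alignment block; the first row is the target genome."""

    target: MafSeq
    query: MafSeq
    score: float = 0.0

    def __post_init__(self):
        if len(self.target.text) != len(self.query.text):
            raise ValueError("MAF block rows differ in aligned length")


@dataclass(frozen=True)
class GeneModel:
    """Transcript structure; exons/cds are sorted, non-overlapping intervals."""

    id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: tuple[tuple[int, int], ...]
    cds: tuple[tuple[int, int], ...] = ()

    def __post_init__(self):
        ex = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(ex, ex[1:]):
            if s2 < e1:
                raise ValueError(f"gene {self.id}: overlapping exons")

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def utr(self) -> tuple[tuple[int, int], ...]:
        """Exonic bases not covered by CDS (5' and 3' UTR combined)."""
        if not self.cds:
            return ()
        out = []
        for s, e in sorted(self.exons):
            pos = s
            for cs, ce in sorted(self.cds):
                if ce <= pos or cs >= e:
                    continue
                if cs > pos:
                    out.append((pos, cs))
                pos = max(pos, ce)
            if pos < e:
                out.append((pos, e))
        return tuple(out)

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        ex = sorted(self.exons)
        return tuple((a[1], b[0]) for a, b in zip(ex, ex[1:]) if b[0] > a[1])

    def spliced_seq(self, chrom_seq: str) -> str:
        """Concatenated exon sequence on the transcript's strand."""
        s = "".join(chrom_seq[a:b] for a, b in sorted(self.exons))
        return s if self.strand == "+" else revcomp(s)


@dataclass(frozen=True)
class SvCall:
    """A typed structural variant on target coordinates with query provenance.

    For INS the target interval is the inserted sequence; for DEL it is the
    (near-empty) breakpoint and ``length`` is the query-side gap.
    """

    sv_type: str
    t_chrom: str
    t_start: int
    t_end: int
    q_chrom: str
    q_start: int
    q_end: int
    length: int
    comparison: str = ""
    evidence: tuple[int, ...] = ()

    def __post_init__(self):
        if self.sv_type not in SV_TYPES:
            raise ValueError(f"unknown SV type {self.sv_type!r}")

    def with_comparison(self, comparison: str) -> "SvCall":
        return replace(self, comparison=comparison)


@dataclass(frozen=True)
class SvAnnotation:
    sv_index: int
    sv_type: str
    category: str
    genes_hit: tuple[str, ...] = ()
    fully_covers_gene: bool = False


@dataclass
class CoverageTrack:
    """Per-sample per-base read depth over one region.

    ``sample_seq_depth`` is the sample's genome-wide mean mapped depth, used
    for normalization.  Unsequenced bases carry depth 0.
    """

    sample: str
    species: str
    chrom: str
    start: int
    end: int
    depth: np.ndarray
    sample_seq_depth: float = 1.0

    def __post_init__(self):
        self.depth = np.asarray(self.depth, dtype=float)
        if len(self.depth) != self.end - self.start:
            raise ValueError(
                f"track {self.sample}: depth length {len(self.depth)} != "
                f"region length {self.end - self.start}"
            )
        if (self.depth < 0).any():
            raise ValueError(f"track {self.sample}: negative depth")

    @property
    def region(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one planted SV.

    ``coords`` maps each descendant genome name to the (chrom, start, end)
    manifestation of the event in that genome, where observable.  For a
    deletion the interval in the deleted genome is the breakpoint (start==end).
    """

    event_id: int
    branch: str
    sv_type: str
    length: int
    anc_chrom: str
    anc_start: int
    anc_end: int
    coords: tuple[tuple[str, tuple[str, int, int]], ...]
    is_retrocopy: bool = False

    def coord(self, genome: str) -> Optional[tuple[str, int, int]]:
        for name, c in self.coords:
            if name == genome:
                return c
        return None


# --- alignment geometry -----------------------------------------------------


@dataclass(frozen=True)
class Anchor:
    """A gapless exact-match anchor between one target and one query chrom.

    ``q_start`` is in *strand space*: for strand '-' it indexes into the
    reverse complement of the query chromosome (the MAF convention).
    """

    t_start: int
    q_start: int
    length: int
    strand: str = "+"

    @property
    def t_end(self) -> int:
        return self.t_start + self.length

    @property
    def q_end(self) -> int:
        return self.q_start + self.length


@dataclass
class Chain:
    """Colinear anchors on one (target chrom, query chrom, strand)."""

    t_chrom: str
    q_chrom: str
    strand: str
    anchors: list[Anchor]
    score: float = 0.0
    chain_id: int = -1

    @property
    def t_span(self) -> tuple[int, int]:
        return self.anchors[0].t_start, self.anchors[-1].t_end


@dataclass(frozen=True)
class Block:
    """One gapless aligned block inside a net, on target-forward coordinates.

    ``q_start``/``q_end`` are in strand space (see :class:`Anchor`);
    ``q_size`` allows conversion to forward-strand query coordinates.
    """

    t_chrom: str
    t_start: int
    t_end: int
    q_chrom: str
    q_start: int
    q_end: int
    strand: str
    q_size: int
    chain_id: int = -1

    @property
    def t_len(self) -> int:
        return self.t_end - self.t_start

    def q_forward(self) -> tuple[int, int]:
        if self.strand == "+":
            return self.q_start, self.q_end
        return self.q_size - self.q_end, self.q_size - self.q_start


@dataclass
class OverlapPair:
    """Evidence of two chains competing for one target interval (pre-net)."""

    kept_chain: int
    dropped_chain: int
    t_chrom: str
    t_start: int
    t_end: int
    q_chrom: str = ""
    q_start: int = 0  # forward query coordinates
    q_end: int = 0
    strand: str = "+"
    q_size: int = 0

    @property
    def length(self) -> int:
        return self.t_end - self.t_start


@dataclass
class Net:
    """Single-coverage (on target) hierarchy of best chains."""

    chains: list[Chain] = field(default_factory=list)
    blocks: list[Block] = field(default_factory=list)
    t_sizes: dict[str, int] = field(default_factory=dict)
    q_sizes: dict[str, int] = field(default_factory=dict)
    overlap_pairs: list[OverlapPair] = field(default_factory=list)
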