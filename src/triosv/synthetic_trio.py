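"""Synthetic genome-trio generator with known structural-variant truth.

An ancestral genome is evolved along the tree ``(dhole,(wolf,dog))``:
branch-specific substitutions plus planted SVs of five classes (INS, DEL,
INV, TRA, REP).  Because every event is placed in ancestor coordinates and
events never overlap, the simulator can emit *exact* truth alignments (MAF)
for every genome pair by composing each genome's coordinate map to the
ancestor, and exact per-genome coordinates for every event.

The generator also produces the downstream verification inputs: a
retro-inserted spliced gene copy on the dog branch carrying exactly one
diagnostic substitution, population coverage tracks for insertion carriers
vs. non-carriers, and RNA-seq reads from a pair of near-identical paralogs.

All randomness flows from the config seed; identical configs give
byte-identical outputs.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .models import (
    CoverageTrack,
    GeneModel,
    GenomeSequence,
    MafBlock,
    MafSeq,
    SV_TYPES,
    TruthRecord,
    revcomp,
)

GENOMES = ("dog", "wolf", "dhole")
BRANCHES = ("wolf_dog", "dog", "wolf", "dhole")
#: branches on the root-to-tip path of each genome
LINEAGES = {
    "dog": ("wolf_dog", "dog"),
    "wolf": ("wolf_dog", "wolf"),
    "dhole": ("dhole",),
}

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class SimulationError(ValueError):
    pass


def default_sv_counts(per_type: int = 20) -> dict[str, dict[str, int]]:
    """Per-branch per-type event counts: terminal branches only by default."""
    counts = {b: {t: 0 for t in SV_TYPES} for b in BRANCHES}
    for b in GENOMES:
        for t in SV_TYPES:
            counts[b][t] = per_type
    return counts


@dataclass
class TrioConfig:
    """Study conditions for the simulated trio.

    Defaults mirror the scale the pipeline is validated at: 3 chromosomes of
    500 kb, 20 events per type per terminal branch, per-branch substitution
    rate 0.005/site, log-normal SV lengths with median 200 bp truncated at
    the 50 bp SV floor.
    """

    seed: int
    n_chroms: int = 3
    chrom_length: int = 500_000
    subst_rate: float | dict[str, float] = 0.005
    sv_counts: dict[str, dict[str, int]] = field(default_factory=default_sv_counts)
    sv_len_median: float = 200.0
    sv_len_sigma: float = 0.7
    min_sv_len: int = 50
    max_sv_len: int = 3000
    #: minimum spacing between planted events so they stay separable
    min_event_gap: int = 500
    n_genes: int = 8
    retrocopy: bool = False

    def branch_rate(self, branch: str) -> float:
        if isinstance(self.subst_rate, dict):
            return float(self.subst_rate.get(branch, 0.0))
        return float(self.subst_rate)

    def validate(self) -> None:
        for b in BRANCHES:
            r = self.branch_rate(b)
            if not (0.0 <= r < 1.0):
                raise SimulationError(f"substitution rate for {b} not in [0,1)")
        for b, per_type in self.sv_counts.items():
            if b not in BRANCHES:
                raise SimulationError(f"unknown branch {b!r}")
            for t, n in per_type.items():
                if t not in SV_TYPES:
                    raise SimulationError(f"unknown SV type {t!r}")
                if n < 0:
                    raise SimulationError("negative event count")
                if t == "TRA" and n > 0 and self.n_chroms < 2:
                    raise SimulationError("TRA events need >= 2 chromosomes")
        if self.min_sv_len < 1:
            raise SimulationError("min_sv_len must be >= 1")
        if self.sv_len_median < self.min_sv_len:
            raise SimulationError("sv_len_median below min_sv_len")


@dataclass(frozen=True)
class RetrocopySpec:
    """Where and how a spliced gene copy is re-inserted."""

    source_gene: str
    insertion_site: tuple[str, int]
    diagnostic_offset: Optional[int] = None  # default: centre of the copy
    retro_base: Optional[str] = None  # default: transversion of parent base


@dataclass
class RetrocopyInfo:
    source_gene: str
    insertion: tuple[str, int, int]  # dog coords of the inserted copy
    diagnostic_offset: int
    parent_base: str
    retro_base: str
    parent_site: tuple[str, int]  # dog genomic coords of the parent allele
    retro_site: tuple[str, int]  # dog genomic coords of the retro allele
    parent_spliced: str
    retro_seq: str


@dataclass(frozen=True)
class _Event:
    event_id: int
    branch: str
    sv_type: str
    chrom: str
    start: int  # ancestor coords; for INS/TRA-dest this is the point
    length: int
    ins_seq: str = ""  # INS only (filled late for the retrocopy)
    dest: tuple[str, int] = ("", -1)  # TRA only
    is_retro: bool = False

    @property
    def end(self) -> int:
        return self.start if self.sv_type == "INS" else self.start + self.length


@dataclass(frozen=True)
class MapSeg:
    """Aligned segment between a genome and the ancestor (both forward for
    '+'; for '-' the genome interval is the reverse complement of the
    ancestor interval)."""

    g_chrom: str
    g_start: int
    g_end: int
    a_chrom: str
    a_start: int
    a_end: int
    strand: str


@dataclass
class Trio:
    config: TrioConfig
    genomes: dict[str, list[GenomeSequence]]
    maps: dict[str, list[MapSeg]]
    truth: list[TruthRecord]
    genes: list[GeneModel]  # dog coordinates
    anc_genes: list[GeneModel]
    retro: Optional[RetrocopyInfo] = None

    def genome_dict(self, name: str) -> dict[str, str]:
        return {gs.name: gs.seq for gs in self.genomes[name]}

    def chrom_sizes(self, name: str) -> dict[str, int]:
        return {gs.name: len(gs.seq) for gs in self.genomes[name]}


# --- placement --------------------------------------------------------------


class _Reservations:
    """Non-overlapping interval reservations per chromosome."""

    def __init__(self, chroms: dict[str, int], gap: int, end_margin: int):
        self.sizes = chroms
        self.gap = gap
        self.end_margin = end_margin
        self.starts: dict[str, list[int]] = {c: [] for c in chroms}
        self.ends: dict[str, list[int]] = {c: [] for c in chroms}

    def free(self, chrom: str, start: int, end: int) -> bool:
        if start < self.end_margin or end > self.sizes[chrom] - self.end_margin:
            return False
        s, e = start - self.gap, end + self.gap
        i = bisect.bisect_left(self.starts[chrom], e)
        return i == 0 or self.ends[chrom][i - 1] <= s

    def add(self, chrom: str, start: int, end: int) -> None:
        i = bisect.bisect_left(self.starts[chrom], start)
        self.starts[chrom].insert(i, start)
        self.ends[chrom].insert(i, end)


def _sample_length(rng: np.random.Generator, cfg: TrioConfig) -> int:
    for _ in range(1000):
        x = rng.lognormal(np.log(cfg.sv_len_median), cfg.sv_len_sigma)
        if cfg.min_sv_len <= x <= cfg.max_sv_len:
            return int(round(x))
    raise SimulationError("length distribution incompatible with bounds")


def _place(
    rng: np.random.Generator, res: _Reservations, chrom_names, width: int
) -> tuple[str, int]:
    for _ in range(2000):
        chrom = chrom_names[rng.integers(len(chrom_names))]
        hi = res.sizes[chrom] - width - res.end_margin
        if hi <= res.end_margin:
            continue
        pos = int(rng.integers(res.end_margin, hi))
        if res.free(chrom, pos, pos + width):
            res.add(chrom, pos, pos + width)
            return chrom, pos
    raise SimulationError(
        "chromosomes too short for the requested events (sizing error)"
    )


# --- core simulation --------------------------------------------------------


def _random_genome(rng, cfg) -> dict[str, np.ndarray]:
    return {
        f"chr{i + 1}": _BASES[rng.integers(0, 4, cfg.chrom_length)]
        for i in range(cfg.n_chroms)
    }


def _sample_genes(rng, cfg, res) -> list[GeneModel]:
    genes = []
    chroms = sorted(res.sizes)
    for i in range(cfg.n_genes):
        n_ex = int(rng.integers(2, 6))
        ex_lens = rng.integers(100, 301, n_ex)
        in_lens = rng.integers(120, 401, max(n_ex - 1, 0))
        span = int(ex_lens.sum() + in_lens.sum())
        chrom, start = _place(rng, res, chroms, span)
        exons = []
        pos = start
        for j in range(n_ex):
            exons.append((pos, pos + int(ex_lens[j])))
            pos += int(ex_lens[j])
            if j < n_ex - 1:
                pos += int(in_lens[j])
        # first/last 30 bp of the transcript are UTR
        cs, ce = start + 30, exons[-1][1] - 30
        cds = tuple(
            (max(s, cs), min(e, ce)) for s, e in exons if min(e, ce) > max(s, cs)
        )
        genes.append(
            GeneModel(
                id=f"gene{i + 1}",
                chrom=chrom,
                strand="+",
                tx_start=start,
                tx_end=exons[-1][1],
                exons=tuple(exons),
                cds=cds,
            )
        )
    return genes


def _sample_events(rng, cfg, res) -> list[_Event]:
    events = []
    chroms = sorted(res.sizes)
    eid = 0
    for branch in BRANCHES:
        per_type = cfg.sv_counts.get(branch, {})
        for sv_type in SV_TYPES:
            for _ in range(per_type.get(sv_type, 0)):
                length = _sample_length(rng, cfg)
                if sv_type == "INS":
                    chrom, pos = _place(rng, res, chroms, 1)
                    seq = "".join(
                        "ACGT"[b] for b in rng.integers(0, 4, length)
                    )
                    ev = _Event(eid, branch, "INS", chrom, pos, length, ins_seq=seq)
                elif sv_type == "TRA":
                    chrom, pos = _place(rng, res, chroms, length)
                    others = [c for c in chroms if c != chrom]
                    dchrom = others[rng.integers(len(others))]
                    dchrom, dpos = _place(rng, res, [dchrom], 1)
                    ev = _Event(
                        eid, branch, "TRA", chrom, pos, length, dest=(dchrom, dpos)
                    )
                else:
                    width = 2 * length if sv_type == "REP" else length
                    chrom, pos = _place(rng, res, chroms, width)
                    ev = _Event(eid, branch, sv_type, chrom, pos, length)
                events.append(ev)
                eid += 1
    return events


def _sample_substitutions(rng, cfg, anc) -> dict[str, dict[str, np.ndarray]]:
    """Per branch, per chrom: (positions, replacement base codes as offsets)."""
    subs: dict[str, dict[str, np.ndarray]] = {}
    for branch in BRANCHES:
        rate = cfg.branch_rate(branch)
        subs[branch] = {}
        for chrom in sorted(anc):
            L = len(anc[chrom])
            n = rng.binomial(L, rate)
            pos = np.sort(rng.choice(L, size=n, replace=False))
            shift = rng.integers(1, 4, size=n)  # never the same base
            subs[branch][chrom] = np.stack([pos, shift]) if n else np.empty((2, 0), int)
    return subs


_CODE = np.full(256, 255, np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


def _apply_subs(base: dict[str, np.ndarray], branch_subs) -> dict[str, np.ndarray]:
    out = {}
    for chrom, arr in base.items():
        arr = arr.copy()
        pos, shift = branch_subs[chrom]
        if len(pos):
            codes = _CODE[arr[pos]]
            arr[pos] = _BASES[(codes + shift) % 4]
        out[chrom] = arr
    return out


def _build_genome(
    name: str,
    base: dict[str, np.ndarray],
    events: Sequence[_Event],
) -> tuple[list[GenomeSequence], list[MapSeg], dict[int, tuple[str, int, int]]]:
    """Apply one lineage's events to its substituted ancestor sequence,
    tracking the genome<->ancestor coordinate map and per-event coordinates."""
    actions: dict[str, list[tuple[int, str, _Event]]] = {c: [] for c in base}
    for ev in events:
        if ev.sv_type == "TRA":
            actions[ev.chrom].append((ev.start, "tra_src", ev))
            actions[ev.dest[0]].append((ev.dest[1], "tra_dest", ev))
        else:
            actions[ev.chrom].append((ev.start, ev.sv_type.lower(), ev))
    seqs, segs, coords = [], [], {}
    for chrom in sorted(base):
        arr = base[chrom]
        s = arr.tobytes().decode()
        out: list[str] = []
        pos = 0  # ancestor cursor
        glen = 0  # genome length so far

        def copy_to(a_end: int):
            nonlocal pos, glen
            if a_end > pos:
                segs.append(MapSeg(chrom, glen, glen + a_end - pos, chrom, pos, a_end, "+"))
                out.append(s[pos:a_end])
                glen += a_end - pos
                pos = a_end

        for a_pos, kind, ev in sorted(actions[chrom], key=lambda t: t[0]):
            copy_to(a_pos)
            if kind == "ins":
                coords[ev.event_id] = (chrom, glen, glen + ev.length)
                out.append(ev.ins_seq)
                glen += ev.length
            elif kind == "del":
                coords[ev.event_id] = (chrom, glen, glen)
                pos = a_pos + ev.length
            elif kind == "inv":
                coords[ev.event_id] = (chrom, glen, glen + ev.length)
                segs.append(
                    MapSeg(chrom, glen, glen + ev.length, chrom, a_pos, a_pos + ev.length, "-")
                )
                out.append(revcomp(s[a_pos : a_pos + ev.length]))
                glen += ev.length
                pos = a_pos + ev.length
            elif kind == "rep":
                copy_to(a_pos + ev.length)  # original copy, mapped
                coords[ev.event_id] = (chrom, glen, glen + ev.length)
                segs.append(
                    MapSeg(chrom, glen, glen + ev.length, chrom, a_pos, a_pos + ev.length, "+")
                )
                out.append(s[a_pos : a_pos + ev.length])
                glen += ev.length
            elif kind == "tra_src":
                pos = a_pos + ev.length  # sequence moves elsewhere
            elif kind == "tra_dest":
                src = base[ev.chrom].tobytes().decode()[ev.start : ev.start + ev.length]
                coords[ev.event_id] = (chrom, glen, glen + ev.length)
                segs.append(
                    MapSeg(chrom, glen, glen + ev.length, ev.chrom, ev.start, ev.start + ev.length, "+")
                )
                out.append(src)
                glen += ev.length
        copy_to(len(s))
        seqs.append(GenomeSequence(chrom, "".join(out)))
    return seqs, segs, coords


def _anc_to_genome(segs_by_achrom, chrom: str, pos: int) -> tuple[str, int]:
    """Map an ancestor position into genome coordinates (plain '+' segments)."""
    segs = segs_by_achrom[chrom]
    i = bisect.bisect_right([sg.a_start for sg in segs], pos) - 1
    while i >= 0:
        sg = segs[i]
        if sg.a_start <= pos <= sg.a_end and sg.strand == "+" and sg.a_chrom == chrom:
            return sg.g_chrom, sg.g_start + (pos - sg.a_start)
        i -= 1
    raise SimulationError(f"ancestor position {chrom}:{pos} not mapped")


def _index_by_achrom(segs: Sequence[MapSeg]) -> dict[str, list[MapSeg]]:
    idx: dict[str, list[MapSeg]] = {}
    for sg in segs:
        idx.setdefault(sg.a_chrom, []).append(sg)
    for c in idx:
        idx[c].sort(key=lambda sg: (sg.a_start, sg.g_chrom, sg.g_start))
    return idx


def simulate_trio(config: TrioConfig) -> Trio:
    """Generate the three genomes, truth records, gene annotation and maps."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    anc = _random_genome(rng, config)
    res = _Reservations(
        {c: len(a) for c, a in anc.items()},
        gap=config.min_event_gap,
        end_margin=2 * config.max_sv_len,
    )
    anc_genes = _sample_genes(rng, config, res)
    events = _sample_events(rng, config, res)
    retro_event = None
    if config.retrocopy:
        src_gene = next((g for g in anc_genes if g.n_exons >= 2), None)
        if src_gene is None:
            raise SimulationError("retrocopy needs a multi-exon source gene")
        chrom, pos = _place(rng, res, sorted(anc), 1)
        retro_event = _Event(
            len(events), "dog", "INS", chrom, pos, 0, is_retro=True
        )  # length/seq filled after substitutions

    subs = _sample_substitutions(rng, config, anc)

    per_genome_base = {}
    for g in GENOMES:
        base = anc
        for branch in LINEAGES[g]:
            base = _apply_subs(base, subs[branch])
        per_genome_base[g] = base

    retro_info = None
    if retro_event is not None:
        src_gene = next(g for g in anc_genes if g.n_exons >= 2)
        dog_base = per_genome_base["dog"]
        spliced = src_gene.spliced_seq(dog_base[src_gene.chrom].tobytes().decode())
        off = len(spliced) // 2
        parent_base = spliced[off]
        retro_base = "ACGT"[("ACGT".index(parent_base) + 2) % 4]
        retro_seq = spliced[:off] + retro_base + spliced[off + 1 :]
        retro_event = _Event(
            retro_event.event_id,
            "dog",
            "INS",
            retro_event.chrom,
            retro_event.start,
            len(retro_seq),
            ins_seq=retro_seq,
            is_retro=True,
        )
        events = list(events) + [retro_event]

    genomes, maps, ev_coords = {}, {}, {}
    for g in GENOMES:
        lineage_events = [e for e in events if e.branch in LINEAGES[g]]
        seqs, segs, coords = _build_genome(g, per_genome_base[g], lineage_events)
        genomes[g], maps[g], ev_coords[g] = seqs, segs, coords

    idx = {g: _index_by_achrom(maps[g]) for g in GENOMES}
    truth = []
    for ev in events:
        coords = []
        for g in GENOMES:
            if ev.event_id in ev_coords[g]:
                coords.append((g, ev_coords[g][ev.event_id]))
            else:
                c1, p1 = _anc_to_genome(idx[g], ev.chrom, ev.start)
                if ev.sv_type == "INS":
                    coords.append((g, (c1, p1, p1)))
                else:
                    c2, p2 = _anc_to_genome(idx[g], ev.chrom, ev.end)
                    coords.append((g, (c1, p1, p2)))
        truth.append(
            TruthRecord(
                event_id=ev.event_id,
                branch=ev.branch,
                sv_type=ev.sv_type,
                length=ev.length,
                anc_chrom=ev.chrom,
                anc_start=ev.start,
                anc_end=ev.end,
                coords=tuple(coords),
                is_retrocopy=ev.is_retro,
            )
        )

    dog_genes = []
    for g in anc_genes:
        c, s = _anc_to_genome(idx["dog"], g.chrom, g.tx_start)
        shift = s - g.tx_start
        dog_genes.append(
            GeneModel(
                id=g.id,
                chrom=c,
                strand=g.strand,
                tx_start=g.tx_start + shift,
                tx_end=g.tx_end + shift,
                exons=tuple((a + shift, b + shift) for a, b in g.exons),
                cds=tuple((a + shift, b + shift) for a, b in g.cds),
            )
        )

    if retro_event is not None:
        src_gene = next(g for g in anc_genes if g.n_exons >= 2)
        dog_src = next(g for g in dog_genes if g.id == src_gene.id)
        rchrom, rs, re_ = ev_coords["dog"][retro_event.event_id]
        off = len(retro_event.ins_seq) // 2
        # genomic position of the parent allele: walk the spliced offset
        # back onto the exon structure (genes are '+' strand here)
        remaining = off
        parent_pos = None
        for a, b in dog_src.exons:
            if remaining < b - a:
                parent_pos = a + remaining
                break
            remaining -= b - a
        retro_gene = GeneModel(
            id=f"{src_gene.id}_retro",
            chrom=rchrom,
            strand="+",
            tx_start=rs,
            tx_end=re_,
            exons=((rs, re_),),
            cds=((rs, re_),),
        )
        dog_genes.append(retro_gene)
        # read the parent allele back out of the finished dog genome
        pseq = genomes["dog"][[gs.name for gs in genomes["dog"]].index(dog_src.chrom)]
        true_parent = pseq.seq[parent_pos]
        retro_info = RetrocopyInfo(
            source_gene=src_gene.id,
            insertion=(rchrom, rs, re_),
            diagnostic_offset=off,
            parent_base=true_parent,
            retro_base=retro_event.ins_seq[off],
            parent_site=(dog_src.chrom, parent_pos),
            retro_site=(rchrom, rs + off),
            parent_spliced=retro_event.ins_seq[:off]
            + true_parent
            + retro_event.ins_seq[off + 1 :],
            retro_seq=retro_event.ins_seq,
        )

    return Trio(
        config=config,
        genomes=genomes,
        maps=maps,
        truth=truth,
        genes=dog_genes,
        anc_genes=anc_genes,
        retro=retro_info,
    )


def _parent_base_of(retro_base: str) -> str:
    return "ACGT"[("ACGT".index(retro_base) + 2) % 4]


# --- truth alignments -------------------------------------------------------


def _seg_sub(seg: MapSeg, s: int, e: int) -> tuple[int, int]:
    """Genome interval for an ancestor sub-interval of a map segment."""
    if seg.strand == "+":
        return seg.g_start + (s - seg.a_start), seg.g_start + (e - seg.a_start)
    return seg.g_start + (seg.a_end - e), seg.g_start + (seg.a_end - s)


def truth_alignment(trio: Trio, target: str, query: str) -> list[MafBlock]:
    """Exact pairwise alignment blocks implied by the coordinate maps.

    One gapless block per intersected map segment, target row first and on
    the '+' strand; minus-strand query starts follow the MAF convention.
    """
    t_seqs, q_seqs = trio.genome_dict(target), trio.genome_dict(query)
    t_idx = _index_by_achrom(trio.maps[target])
    q_idx = _index_by_achrom(trio.maps[query])
    blocks = []
    for achrom in sorted(set(t_idx) | set(q_idx)):
        for ts in t_idx.get(achrom, []):
            for qs in q_idx.get(achrom, []):
                s = max(ts.a_start, qs.a_start)
                e = min(ts.a_end, qs.a_end)
                if e <= s:
                    continue
                t0, t1 = _seg_sub(ts, s, e)
                q0, q1 = _seg_sub(qs, s, e)
                # emitted target-forward, so the query row's strand is the
                # *relative* orientation of the two map segments
                strand = "+" if ts.strand == qs.strand else "-"
                t_text = t_seqs[ts.g_chrom][t0:t1]
                q_text = q_seqs[qs.g_chrom][q0:q1]
                q_size = len(q_seqs[qs.g_chrom])
                if strand == "+":
                    q_row = MafSeq(f"{query}.{qs.g_chrom}", q0, q1 - q0, "+", q_size, q_text)
                else:
                    q_row = MafSeq(
                        f"{query}.{qs.g_chrom}",
                        q_size - q1,
                        q1 - q0,
                        "-",
                        q_size,
                        revcomp(q_text),
                    )
                t_row = MafSeq(
                    f"{target}.{ts.g_chrom}",
                    t0,
                    t1 - t0,
                    "+",
                    len(t_seqs[ts.g_chrom]),
                    t_text,
                )
                blocks.append(MafBlock(t_row, q_row, float(t1 - t0)))
    blocks.sort(key=lambda b: (b.target.src, b.target.start, b.query.src, b.query.start))
    return blocks


# --- expected calls (what a perfect classifier should report) ---------------

#: how an event on the *query* lineage appears from the target's perspective
_DUAL = {"INS": "DEL", "DEL": "INS", "INV": "INV", "TRA": "TRA", "REP": "REP"}


@dataclass(frozen=True)
class ExpectedCall:
    event_id: int
    sv_type: str
    t_chrom: str
    t_start: int
    t_end: int
    length: int


def expected_calls(trio: Trio, target: str, query: str) -> list[ExpectedCall]:
    """Truth table for one ordered comparison: the typed calls, on target
    coordinates, that a perfect target-vs-query classification yields."""
    t_branches = set(LINEAGES[target])
    q_branches = set(LINEAGES[query])
    out = []
    for rec in trio.truth:
        if rec.branch in t_branches and rec.branch not in q_branches:
            sv_type = rec.sv_type
        elif rec.branch in q_branches and rec.branch not in t_branches:
            sv_type = _DUAL[rec.sv_type]
        else:
            continue  # shared or irrelevant branch: invisible in this pair
        chrom, s, e = rec.coord(target)
        out.append(ExpectedCall(rec.event_id, sv_type, chrom, s, e, rec.length))
    out.sort(key=lambda c: (c.t_chrom, c.t_start, c.sv_type))
    return out


def match_calls(calls, expected, tol: int = 0):
    """Greedy one-to-one matching of SV calls against expected calls.

    Returns (matches, recall, precision); a match requires the same type and
    breakpoints within ``tol`` (for indels, length within ``2 * tol``).
    Tandem-duplication junctions are rotation-ambiguous — the last bases of
    the new copy align equally well as flank sequence — so REP matches on
    locus overlap and copy length rather than exact junctions.
    """
    used = [False] * len(calls)
    matches = []
    for exp in expected:
        best, best_d = None, None
        for i, c in enumerate(calls):
            if used[i] or c.sv_type != exp.sv_type or c.t_chrom != exp.t_chrom:
                continue
            ds = abs(c.t_start - exp.t_start)
            if c.sv_type in ("INS", "DEL"):
                ok = ds <= tol and abs(c.length - exp.length) <= max(2 * tol, 1)
                d = ds
            elif c.sv_type == "REP":
                # a tandem duplication of identical copies is defined only
                # modulo rotation over the whole 2L duplicated region: any
                # length-L window inside it is an equivalent representation
                ok = (
                    abs(c.length - exp.length) <= 3 * tol
                    and c.t_start >= exp.t_start - exp.length - 3 * tol
                    and c.t_end <= exp.t_end + 3 * tol
                )
                d = ds
            else:
                de = abs(c.t_end - exp.t_end)
                ok = ds <= tol and de <= tol
                d = ds + de
            if ok and (best_d is None or d < best_d):
                best, best_d = i, d
        if best is not None:
            used[best] = True
            matches.append((exp, calls[best]))
    recall = len(matches) / len(expected) if expected else 1.0
    precision = sum(used) / len(calls) if calls else 1.0
    return matches, recall, precision


# --- retrocopy planting (standalone) ----------------------------------------


def plant_retrocopy(
    dog_genome: Sequence[GenomeSequence],
    source_gene: GeneModel,
    spec: RetrocopySpec,
    genes: Sequence[GeneModel] = (),
) -> tuple[list[GenomeSequence], TruthRecord]:
    """Insert a spliced (intron-less) copy of ``source_gene`` into a genome.

    The copy differs from the spliced parent at exactly one diagnostic site.
    Coordinates downstream of the insertion shift by the copy length; use the
    integrated ``TrioConfig(retrocopy=True)`` path when truth alignments must
    stay consistent.
    """
    if source_gene.n_exons < 2:
        raise SimulationError("retrocopy source gene must have >= 2 exons")
    chrom, pos = spec.insertion_site
    for g in genes:
        if g.chrom == chrom and g.tx_start <= pos < g.tx_end:
            raise SimulationError(
                f"insertion site {chrom}:{pos} lies inside gene {g.id}"
            )
    seqs = {gs.name: gs.seq for gs in dog_genome}
    if chrom not in seqs:
        raise SimulationError(f"unknown chromosome {chrom!r}")
    spliced = source_gene.spliced_seq(seqs[source_gene.chrom])
    off = spec.diagnostic_offset if spec.diagnostic_offset is not None else len(spliced) // 2
    if not (0 <= off < len(spliced)):
        raise SimulationError("diagnostic offset outside the spliced copy")
    retro_base = spec.retro_base or _parent_base_of(spliced[off])
    if retro_base == spliced[off]:
        raise SimulationError("diagnostic base equals the parent base")
    retro_seq = spliced[:off] + retro_base + spliced[off + 1 :]
    out = []
    for gs in dog_genome:
        if gs.name == chrom:
            out.append(GenomeSequence(chrom, gs.seq[:pos] + retro_seq + gs.seq[pos:]))
        else:
            out.append(gs)
    rec = TruthRecord(
        event_id=-1,
        branch="dog",
        sv_type="INS",
        length=len(retro_seq),
        anc_chrom=chrom,
        anc_start=pos,
        anc_end=pos,
        coords=(("dog", (chrom, pos, pos + len(retro_seq))),),
        is_retrocopy=True,
    )
    return out, rec


# --- population coverage ----------------------------------------------------


def simulate_population_coverage(
    region: tuple[str, int, int],
    insertion: tuple[int, int],
    n_carriers: int = 11,
    n_noncarriers: int = 12,
    mean_depths: Optional[Sequence[float]] = None,
    noise_fraction: float = 0.01,
    seed: int = 0,
) -> list[CoverageTrack]:
    """Per-sample read-depth tracks over an insertion plus two equal flanks.

    Carriers (dogs) have Poisson(sample depth) coverage throughout; for
    non-carriers (gray wolves) the insertion interior collapses to 0 apart
    from a configurable stray-coverage fraction.
    """
    if n_carriers < 1 or n_noncarriers < 1:
        raise SimulationError("need at least one sample in each group")
    chrom, rstart, rend = region
    istart, iend = insertion
    ilen = iend - istart
    if ilen <= 0:
        raise SimulationError("empty insertion interval")
    if istart - rstart != ilen or rend - iend != ilen:
        raise SimulationError(
            "region must be the insertion plus two flanks of the same length"
        )
    rng = np.random.default_rng(seed)
    n = n_carriers + n_noncarriers
    if mean_depths is None:
        mean_depths = rng.uniform(8.0, 25.0, n)
    elif len(mean_depths) != n:
        raise SimulationError("mean_depths must have one value per sample")
    tracks = []
    L = rend - rstart
    inner = slice(istart - rstart, iend - rstart)
    for i in range(n):
        mu = float(mean_depths[i])
        depth = rng.poisson(mu, L).astype(float)
        carrier = i < n_carriers
        if not carrier:
            depth[inner] = rng.poisson(mu * noise_fraction, ilen)
        tracks.append(
            CoverageTrack(
                sample=(f"dog{i + 1:02d}" if carrier else f"wolf{i - n_carriers + 1:02d}"),
                species="dog" if carrier else "wolf",
                chrom=chrom,
                start=rstart,
                end=rend,
                depth=depth,
                sample_seq_depth=mu,
            )
        )
    return tracks


# --- paralog RNA-seq reads --------------------------------------------------


def simulate_paralog_reads(
    parent_tx: str,
    retro_tx: str,
    expression_ratio: tuple[float, float] = (2.0, 1.0),
    read_len: int = 100,
    n_reads: int = 30_000,
    seed: int = 0,
    misplace_ambiguous: bool = True,
) -> tuple[list[tuple[str, str]], list[tuple[str, int, str]]]:
    """Uniform reads from two paralogous transcripts at a given ratio.

    The transcripts must be identical apart from one diagnostic site.
    Returns FASTQ-ready ``(id, seq)`` reads plus truth placements
    ``(axis, pos, seq)`` where axis is ``"parent"`` or ``"retro"``: reads
    covering the diagnostic site are placed on their true locus; ambiguous
    reads (which cannot be assigned) are placed on a random locus when
    ``misplace_ambiguous`` is set, emulating multi-mapping noise.
    """
    if len(parent_tx) != len(retro_tx):
        raise SimulationError("paralog transcripts differ in length")
    diffs = [i for i, (a, b) in enumerate(zip(parent_tx, retro_tx)) if a != b]
    if len(diffs) != 1:
        raise SimulationError(
            f"transcripts must differ at exactly one site (found {len(diffs)})"
        )
    site = diffs[0]
    if read_len > len(parent_tx):
        raise SimulationError("read length exceeds transcript length")
    if min(expression_ratio) < 0 or sum(expression_ratio) <= 0:
        raise SimulationError("invalid expression ratio")
    rng = np.random.default_rng(seed)
    p_parent = expression_ratio[0] / sum(expression_ratio)
    n_parent = int(rng.binomial(n_reads, p_parent))
    reads, placements = [], []
    for i in range(n_reads):
        from_parent = i < n_parent
        tx = parent_tx if from_parent else retro_tx
        pos = int(rng.integers(0, len(tx) - read_len + 1))
        seq = tx[pos : pos + read_len]
        covers = pos <= site < pos + read_len
        if covers or not misplace_ambiguous:
            axis = "parent" if from_parent else "retro"
        else:
            axis = "parent" if rng.integers(2) == 0 else "retro"
        rid = f"read{i:06d}"
        reads.append((rid, seq))
        placements.append((axis, pos, seq))
    return reads, placements


# --- synthetic population call sets -----------------------------------------


def simulate_population_callset(
    trio: Trio,
    jitter: int = 20,
    dropout: float = 0.05,
    extra_frac: float = 0.3,
    seed: int = 0,
):
    """Emulate read-pair/read-depth population calls on the dog reference.

    Wolf resequencing against the dog genome sees dog-branch insertions as
    wolf *deletions* and dog-branch deletions as wolf *insertions*.  Truth
    intervals are jittered, a sensitivity ``1 - dropout`` applied, and a
    fraction of random false calls added.
    """
    from .models import BedRecord

    rng = np.random.default_rng(seed)
    sizes = trio.chrom_sizes("dog")
    out = {"wolf_del": [], "wolf_ins": []}
    for rec in trio.truth:
        if rec.branch != "dog" or rec.sv_type not in ("INS", "DEL"):
            continue
        if rng.random() < dropout:
            continue
        chrom, s, e = rec.coord("dog")
        key = "wolf_del" if rec.sv_type == "INS" else "wolf_ins"
        j1, j2 = rng.integers(-jitter, jitter + 1, 2)
        s2, e2 = max(0, s + int(j1)), max(0, e + int(j2))
        if e2 <= s2:
            e2 = s2 + max(rec.length, 1)
        out[key].append(BedRecord(chrom, s2, min(e2, sizes[chrom]), f"pop{rec.event_id}"))
    for key in out:
        n_extra = int(len(out[key]) * extra_frac)
        chroms = sorted(sizes)
        for i in range(n_extra):
            chrom = chroms[rng.integers(len(chroms))]
            L = int(rng.integers(50, 500))
            s = int(rng.integers(0, sizes[chrom] - L))
            out[key].append(BedRecord(chrom, s, s + L, f"fp{key}{i}"))
        out[key].sort(key=lambda r: (r.chrom, r.start, r.end))
    return out
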