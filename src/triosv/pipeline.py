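"""End-to-end orchestration: simulate → align → call → intersect → annotate
→ verify → express, with one config and a deterministic summary report.

Every stage writes its outputs under the run directory; ``summary.tsv``
collects the headline numbers (SV counts and median sizes per type per
comparison, the dog-specific set, the three-way sequence-content partition,
the read-depth verification p-value and the paralog RPKM values) and is
byte-identical across runs with the same config and seed.
"""

from __future__ import annotations

import dataclasses
import logging
import os
import statistics
from dataclasses import dataclass, field


import yaml

from . import formats_io, popverify
from .anchor_align import AlignConfig, align_genomes, net_to_maf
from .lineage_specific import (
    aligned_masks,
    derive_dog_specific,
    genes_in_specific_regions,
    venn_partition,
)
from .models import BedRecord, SV_TYPES
from .paralog_expression import build_windows, quantify_paralogs
from .sv_annotate import annotate_svs, find_gene_covering_insertions
from .sv_classify import call_svs
from .synthetic_trio import (
    TrioConfig,
    simulate_paralog_reads,
    simulate_population_callset,
    simulate_population_coverage,
    simulate_trio,
    truth_alignment,
)

log = logging.getLogger("triosv")


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """One reproducible run: all stage parameters plus the master seed."""

    trio: TrioConfig = field(default_factory=lambda: TrioConfig(seed=0, retrocopy=True))
    align: AlignConfig = field(default_factory=AlignConfig)
    min_sv_len: int = 50
    recip: float = 0.5
    bp_tol: int = 50
    window: int = 200
    read_len: int = 100
    n_reads: int = 30_000
    expression_ratio: tuple[float, float] = (2.0, 1.0)
    n_carriers: int = 11
    n_noncarriers: int = 12
    coverage_noise: float = 0.01
    #: slack for "insertion fully covers gene": aligner breakpoints are
    #: accurate to a few bases, so strict containment would miss real cases
    containment_slack: int = 10

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        trio = TrioConfig(**raw.pop("trio", {"seed": 0}))
        align = AlignConfig(**raw.pop("align", {}))
        if "expression_ratio" in raw:
            raw["expression_ratio"] = tuple(raw["expression_ratio"])
        return cls(trio=trio, align=align, **raw)


def _median_size(calls) -> float:
    return float(statistics.median(c.length for c in calls)) if calls else 0.0


def _del_locus(call, pad: int = 25) -> BedRecord:
    return BedRecord(call.t_chrom, max(0, call.t_start - pad), call.t_start + pad)


def run_all(config: RunConfig, outdir: str, force: bool = False) -> dict:
    """Run the whole analysis into ``outdir``; returns the summary rows."""
    if os.path.isdir(outdir) and os.listdir(outdir) and not force:
        raise PipelineError(
            f"output directory {outdir!r} is not empty (use force to overwrite)"
        )
    os.makedirs(outdir, exist_ok=True)
    config.to_yaml(os.path.join(outdir, "config.yaml"))
    summary: list[tuple[str, str, str]] = []

    def add(section: str, key: str, value) -> None:
        if isinstance(value, float):
            value = f"{value:.6g}"
        summary.append((section, key, str(value)))

    # --- simulate -----------------------------------------------------------
    log.info("stage simulate: seed=%d", config.trio.seed)
    trio = simulate_trio(config.trio)
    for g, seqs in sorted(trio.genomes.items()):
        formats_io.write_fasta(seqs, os.path.join(outdir, f"{g}.fa"))
    formats_io.write_truth_tsv(trio.truth, os.path.join(outdir, "truth.tsv"))
    formats_io.write_gff3_genes(trio.genes, os.path.join(outdir, "dog_genes.gff3"))
    for a, b in (("dog", "wolf"), ("dog", "dhole"), ("wolf", "dhole")):
        formats_io.write_maf(
            truth_alignment(trio, a, b), os.path.join(outdir, f"truth_{a}_{b}.maf")
        )
    add("simulate", "n_truth_events", len(trio.truth))

    # --- align --------------------------------------------------------------
    nets, mafs = {}, {}
    for a, b in (("dog", "wolf"), ("dog", "dhole"), ("wolf", "dhole")):
        log.info("stage align: %s vs %s", a, b)
        net = align_genomes(trio.genomes[a], trio.genomes[b], config.align)
        nets[(a, b)] = net
        maf = net_to_maf(net, trio.genomes[a], trio.genomes[b], a, b)
        mafs[(a, b)] = maf
        formats_io.write_maf(maf, os.path.join(outdir, f"pair_{a}_{b}.maf"))
        add("align", f"{a}_{b}_blocks", len(maf))

    # --- call SVs ------------------------------------------------------------
    comparisons = {"dog_wolf": ("dog", "wolf"), "dog_dhole": ("dog", "dhole")}
    calls = {}
    for name, (a, b) in comparisons.items():
        log.info("stage callsv: %s", name)
        cs = call_svs(
            nets[(a, b)],
            min_sv_len=config.min_sv_len,
            tra_jump=config.align.tra_jump,
            comparison=name,
            target=trio.genomes[a],
            query=trio.genomes[b],
        )
        calls[name] = cs
        formats_io.write_sv_tsv(cs, os.path.join(outdir, f"svs_{name}.tsv"))
        for t in SV_TYPES:
            sub = [c for c in cs if c.sv_type == t]
            add(name, f"{t}_count", len(sub))
            add(name, f"{t}_median_size", _median_size(sub))

    # --- lineage-specific -----------------------------------------------------
    log.info("stage lineage: intersecting comparisons")
    lineage = derive_dog_specific(
        calls["dog_wolf"], calls["dog_dhole"], config.recip, config.bp_tol
    )
    formats_io.write_sv_tsv(
        lineage.dog_specific, os.path.join(outdir, "svs_dog_specific.tsv")
    )
    for t in SV_TYPES:
        sub = [c for c in lineage.dog_specific if c.sv_type == t]
        add("dog_specific", f"{t}_count", len(sub))
        add("dog_specific", f"{t}_median_size", _median_size(sub))

    # --- Venn partition -------------------------------------------------------
    log.info("stage venn: three-way sequence content")
    masks = {}
    for (a, b), maf in mafs.items():
        tm, qm = aligned_masks(maf, fill_gap=config.min_sv_len)
        masks[(a, b)] = tm
        masks[(b, a)] = qm
    parts = venn_partition(trio.genomes, masks)
    for g in sorted(parts):
        p = parts[g]
        add("venn", f"{g}_shared_all_bp", p.shared_all)
        for o in sorted(p.shared_one):
            add("venn", f"{g}_shared_{o}_only_bp", p.shared_one[o])
        add("venn", f"{g}_specific_bp", p.specific)
        add("venn", f"{g}_assayable_bp", p.assayable)
    spec_genes = genes_in_specific_regions(parts["dog"], trio.genes)
    add("venn", "dog_specific_region_genes", ",".join(spec_genes) or "none")

    # --- annotation -----------------------------------------------------------
    log.info("stage annotate: genic context of dog-specific SVs")
    annotations, table = annotate_svs(lineage.dog_specific, trio.genes)
    table.to_csv(os.path.join(outdir, "annotation_counts.tsv"), sep="\t")
    for t in sorted(table.index):
        for cat in table.columns:
            add("annotation", f"{t}_{cat}", int(table.loc[t, cat]))
    covering = find_gene_covering_insertions(
        lineage.dog_specific,
        trio.genes,
        trio.genomes["dog"],
        containment_slack=config.containment_slack,
    )
    retro_pairs = [(sv, g, sig) for sv, g, sig in covering if sig.is_retrocopy]
    add("annotation", "gene_covering_insertions", len(covering))
    add("annotation", "retrocopy_insertions", len(retro_pairs))

    # --- population verification ---------------------------------------------
    if trio.retro is not None:
        log.info("stage verify: read-depth around the retrocopy insertion")
        if retro_pairs:
            sv = retro_pairs[0][0]
            insertion = (sv.t_chrom, sv.t_start, sv.t_end)
        else:
            insertion = trio.retro.insertion
        chrom, s, e = insertion
        length = e - s
        region = (chrom, s - length, e + length)
        tracks = simulate_population_coverage(
            region,
            (s, e),
            config.n_carriers,
            config.n_noncarriers,
            noise_fraction=config.coverage_noise,
            seed=config.trio.seed + 1,
        )
        with open(os.path.join(outdir, "samples.tsv"), "w") as fh:
            fh.write("# triosv.samples.v1\nsample\tspecies\tsample_seq_depth\tbedgraph\n")
            for t in tracks:
                bg = f"coverage_{t.sample}.bedgraph"
                formats_io.write_bedgraph(t, os.path.join(outdir, bg))
                fh.write(f"{t.sample}\t{t.species}\t{t.sample_seq_depth:.6g}\t{bg}\n")
        report = popverify.verify_insertion(tracks, insertion)
        add("verify", "insertion", f"{chrom}:{s + 1}-{e}")  # 1-based inclusive
        for sp in sorted(report.interior_means):
            add("verify", f"{sp}_interior_mean", report.interior_means[sp])
            add("verify", f"{sp}_flank_mean", report.flank_means[sp])
        add("verify", "ranksum_U", report.ranksum.statistic)
        add("verify", "ranksum_p", report.ranksum.pvalue)
        add("verify", "ranksum_method", report.ranksum.method)

        popset = simulate_population_callset(trio, seed=config.trio.seed + 2)
        ins_bed = [
            BedRecord(c.t_chrom, c.t_start, c.t_end)
            for c in lineage.dog_specific
            if c.sv_type == "INS"
        ]
        del_bed = [_del_locus(c) for c in lineage.dog_specific if c.sv_type == "DEL"]
        if ins_bed and popset["wolf_del"]:
            add("verify", "ins_vs_wolf_del_overlap",
                popverify.overlap_ratio(ins_bed, popset["wolf_del"]))
        if del_bed and popset["wolf_ins"]:
            add("verify", "del_vs_wolf_ins_overlap",
                popverify.overlap_ratio(del_bed, popset["wolf_ins"]))

    # --- paralog expression ----------------------------------------------------
    if trio.retro is not None:
        log.info("stage xprs: diagnostic-site windowed RPKM")
        info = trio.retro
        reads, placements = simulate_paralog_reads(
            info.parent_spliced,
            info.retro_seq,
            config.expression_ratio,
            config.read_len,
            config.n_reads,
            seed=config.trio.seed + 3,
        )
        formats_io.write_fastq(reads, os.path.join(outdir, "rnaseq.fastq"))
        pw, rw = build_windows(
            ("parent", info.diagnostic_offset, info.parent_base),
            ("retro", info.diagnostic_offset, info.retro_base),
            config.window,
            {"parent": len(info.parent_spliced), "retro": len(info.retro_seq)},
        )
        parent_x, retro_x = quantify_paralogs(placements, pw, rw)
        add("xprs", "parent_window_reads", parent_x.read_count)
        add("xprs", "retro_window_reads", retro_x.read_count)
        add("xprs", "parent_rpkm", parent_x.rpkm)
        add("xprs", "retro_rpkm", retro_x.rpkm)
        if retro_x.rpkm > 0:
            add("xprs", "rpkm_ratio", parent_x.rpkm / retro_x.rpkm)

    with open(os.path.join(outdir, "summary.tsv"), "w") as fh:
        fh.write("# triosv.summary.v1\nsection\tkey\tvalue\n")
        for section, key, value in summary:
            fh.write(f"{section}\t{key}\t{value}\n")
    log.info("run complete: %s", outdir)
    return {(s, k): v for s, k, v in summary}
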