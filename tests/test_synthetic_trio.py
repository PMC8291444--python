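"""Trio simulator: determinism, bookkeeping, truth alignments, retrocopy,
population coverage and paralog reads."""

import numpy as np
import pytest

from triosv.models import GeneModel, GenomeSequence
from triosv.synthetic_trio import (
    GENOMES,
    RetrocopySpec,
    SimulationError,
    TrioConfig,
    default_sv_counts,
    plant_retrocopy,
    simulate_paralog_reads,
    simulate_population_coverage,
    simulate_trio,
    truth_alignment,
)

SV_TYPES = ("INS", "DEL", "INV", "TRA", "REP")


def _zero_counts():
    return {b: {t: 0 for t in SV_TYPES} for b in ("wolf_dog", "dog", "wolf", "dhole")}


def test_no_events_no_substitutions_gives_identical_genomes():
    cfg = TrioConfig(seed=1, n_chroms=1, chrom_length=60_000, subst_rate=0.0,
                     sv_counts=_zero_counts(), n_genes=0)
    trio = simulate_trio(cfg)
    seqs = {g: trio.genomes[g][0].seq for g in GENOMES}
    assert seqs["dog"] == seqs["wolf"] == seqs["dhole"]
    assert trio.truth == []
    blocks = truth_alignment(trio, "dog", "wolf")
    assert len(blocks) == 1
    assert blocks[0].target.size == 60_000 and blocks[0].query.strand == "+"


def test_single_insertion_length_bookkeeping():
    counts = _zero_counts()
    counts["dog"]["INS"] = 1
    cfg = TrioConfig(seed=3, n_chroms=1, chrom_length=60_000, subst_rate=0.0,
                     sv_counts=counts, n_genes=0)
    trio = simulate_trio(cfg)
    (rec,) = trio.truth
    assert rec.branch == "dog" and rec.sv_type == "INS"
    assert len(trio.genomes["dog"][0]) == 60_000 + rec.length
    assert len(trio.genomes["wolf"][0]) == 60_000
    assert len(trio.genomes["dhole"][0]) == 60_000
    # inserted sequence sits exactly at its recorded coordinates
    chrom, s, e = rec.coord("dog")
    assert e - s == rec.length


def test_deletion_conserves_sequence_content():
    counts = _zero_counts()
    counts["wolf"]["DEL"] = 3
    cfg = TrioConfig(seed=4, n_chroms=1, chrom_length=80_000, subst_rate=0.0,
                     sv_counts=counts, n_genes=0)
    trio = simulate_trio(cfg)
    removed = sum(r.length for r in trio.truth)
    assert len(trio.genomes["wolf"][0]) == 80_000 - removed
    assert len(trio.genomes["dog"][0]) == 80_000


def test_determinism_byte_identical():
    cfg = dict(seed=7, n_chroms=2, chrom_length=100_000,
               sv_counts=default_sv_counts(5), retrocopy=True)
    t1 = simulate_trio(TrioConfig(**cfg))
    t2 = simulate_trio(TrioConfig(**cfg))
    for g in GENOMES:
        assert [s.seq for s in t1.genomes[g]] == [s.seq for s in t2.genomes[g]]
    assert t1.truth == t2.truth
    assert truth_alignment(t1, "dog", "dhole") == truth_alignment(t2, "dog", "dhole")


def test_truth_alignment_blocks_differ_only_by_substitutions(small_trio):
    """Truth blocks must be gapless homologs: per-base differences at the
    combined branch substitution rate, never wholesale disagreement."""
    from triosv.models import revcomp

    for pair in (("dog", "wolf"), ("dog", "dhole")):
        total = mism = 0
        for b in truth_alignment(small_trio, *pair):
            t, q = b.target.text, b.query.text
            assert len(t) == len(q) == b.target.size
            total += len(t)
            mism += sum(1 for a, c in zip(t, q) if a != c)
        assert total > 0
        assert mism / total < 0.05


def test_truth_alignment_consistent_with_composed_maps(small_trio):
    """Aligned dog bases in dog-wolf equal the dog bases whose ancestor
    interval is mapped in both genomes (map composition through the root)."""
    sizes = small_trio.chrom_sizes("dog")
    via_blocks = {c: np.zeros(n, bool) for c, n in sizes.items()}
    for b in truth_alignment(small_trio, "dog", "wolf"):
        chrom = b.target.src.split(".", 1)[-1]
        via_blocks[chrom][b.target.start : b.target.start + b.target.size] = True
    # independent computation: intersect ancestor coverage of both maps
    anc_cov = {}
    for g in ("dog", "wolf"):
        cov = {}
        for seg in small_trio.maps[g]:
            cov.setdefault(seg.a_chrom, []).append((seg.a_start, seg.a_end))
        anc_cov[g] = cov
    for seg in small_trio.maps["dog"]:
        wolf_ivs = anc_cov["wolf"].get(seg.a_chrom, [])
        for ws, we in wolf_ivs:
            s, e = max(seg.a_start, ws), min(seg.a_end, we)
            if e <= s:
                continue
            if seg.strand == "+":
                g0 = seg.g_start + (s - seg.a_start)
                g1 = seg.g_start + (e - seg.a_start)
            else:
                g0 = seg.g_start + (seg.a_end - e)
                g1 = seg.g_start + (seg.a_end - s)
            assert via_blocks[seg.g_chrom][g0:g1].all()


def test_sizing_error_before_output():
    counts = _zero_counts()
    counts["dog"]["DEL"] = 50
    with pytest.raises(SimulationError, match="sizing"):
        simulate_trio(TrioConfig(seed=1, n_chroms=1, chrom_length=15_000,
                                 sv_counts=counts, n_genes=0))


def test_config_validation():
    with pytest.raises(SimulationError):
        TrioConfig(seed=1, subst_rate=1.5).validate()
    with pytest.raises(SimulationError):
        TrioConfig(seed=1, sv_counts={"dog": {"INS": -1}}).validate()
    with pytest.raises(SimulationError):
        TrioConfig(seed=1, n_chroms=1).validate()  # TRA needs 2 chroms


# --- retrocopy ---------------------------------------------------------------


@pytest.fixture()
def toy_gene_genome():
    rng = np.random.default_rng(11)
    seq = "".join(rng.choice(list("ACGT"), 3000))
    gene = GeneModel("src", "c1", "+", 200, 850,
                     exons=((200, 300), (700, 850)), cds=((220, 300), (700, 830)))
    return [GenomeSequence("c1", seq)], gene


def test_plant_retrocopy_length_is_exon_sum(toy_gene_genome):
    genome, gene = toy_gene_genome
    out, rec = plant_retrocopy(genome, gene, RetrocopySpec("src", ("c1", 2000)))
    assert rec.length == 100 + 150
    assert len(out[0].seq) == 3000 + 250


def test_plant_retrocopy_single_diagnostic_difference(toy_gene_genome):
    genome, gene = toy_gene_genome
    out, rec = plant_retrocopy(genome, gene, RetrocopySpec("src", ("c1", 2000)))
    spliced = gene.spliced_seq(genome[0].seq)
    chrom, s, e = rec.coord("dog")
    inserted = out[0].seq[s:e]
    diffs = sum(1 for a, b in zip(spliced, inserted) if a != b)
    assert diffs == 1


def test_plant_retrocopy_rejects_site_inside_gene(toy_gene_genome):
    genome, gene = toy_gene_genome
    with pytest.raises(SimulationError, match="inside gene"):
        plant_retrocopy(genome, gene, RetrocopySpec("src", ("c1", 250)), genes=[gene])


def test_plant_retrocopy_needs_multi_exon_gene(toy_gene_genome):
    genome, _ = toy_gene_genome
    single = GeneModel("s1", "c1", "+", 200, 400, exons=((200, 400),))
    with pytest.raises(SimulationError, match="2 exons"):
        plant_retrocopy(genome, single, RetrocopySpec("s1", ("c1", 2000)))


def test_simulated_retrocopy_differs_from_parent_at_one_site(small_trio):
    info = small_trio.retro
    assert info is not None
    diffs = [i for i, (a, b) in enumerate(zip(info.parent_spliced, info.retro_seq))
             if a != b]
    assert diffs == [info.diagnostic_offset]
    # the recorded genomic sites carry the recorded alleles
    dog = small_trio.genome_dict("dog")
    pc, pp = info.parent_site
    rc, rp = info.retro_site
    assert dog[pc][pp] == info.parent_base
    assert dog[rc][rp] == info.retro_base


# --- population coverage -----------------------------------------------------


def test_population_coverage_carrier_vs_noncarrier_shapes():
    region = ("chr14", 1000, 4000)
    tracks = simulate_population_coverage(region, (2000, 3000), 11, 12,
                                          noise_fraction=0.0, seed=5)
    assert len(tracks) == 23
    inner = slice(1000, 2000)
    for t in tracks[:11]:  # carriers
        assert abs(t.depth[inner].mean() - t.sample_seq_depth) < 0.2 * t.sample_seq_depth
    for t in tracks[11:]:  # non-carriers: interior identically zero at noise 0
        assert t.depth[inner].sum() == 0
        assert t.depth[:1000].mean() > 0


def test_population_coverage_validates_geometry_and_groups():
    with pytest.raises(SimulationError, match="flanks"):
        simulate_population_coverage(("c", 0, 3100), (1000, 2000), 2, 2)
    with pytest.raises(SimulationError, match="at least one"):
        simulate_population_coverage(("c", 0, 3000), (1000, 2000), 0, 2)


def test_population_coverage_deterministic():
    a = simulate_population_coverage(("c", 0, 300), (100, 200), 3, 3, seed=9)
    b = simulate_population_coverage(("c", 0, 300), (100, 200), 3, 3, seed=9)
    for x, y in zip(a, b):
        assert np.array_equal(x.depth, y.depth)


# --- paralog reads -----------------------------------------------------------


def _paralog_pair(n=1200, site=600, seed=0):
    rng = np.random.default_rng(seed)
    parent = "".join(rng.choice(list("ACGT"), n))
    retro_base = {"A": "G", "C": "T", "G": "A", "T": "C"}[parent[site]]
    retro = parent[:site] + retro_base + parent[site + 1:]
    return parent, retro, site


@pytest.mark.parametrize("ratio, allele_index", [((1, 0), 0), ((0, 1), 1)])
def test_paralog_reads_pure_ratios(ratio, allele_index):
    parent, retro, site = _paralog_pair()
    _, placements = simulate_paralog_reads(parent, retro, ratio, 100, 500, seed=1)
    alleles = {0: parent[site], 1: retro[site]}
    for axis, pos, seq in placements:
        if pos <= site < pos + 100:
            assert seq[site - pos] == alleles[allele_index]


def test_paralog_reads_allele_fraction_tracks_ratio():
    parent, retro, site = _paralog_pair()
    _, placements = simulate_paralog_reads(parent, retro, (2, 1), 100, 30_000, seed=2)
    parent_n = retro_n = 0
    for axis, pos, seq in placements:
        if pos <= site < pos + 100:
            if seq[site - pos] == parent[site]:
                parent_n += 1
            else:
                retro_n += 1
    n = parent_n + retro_n
    frac = parent_n / n
    se = np.sqrt((2 / 3) * (1 / 3) / n)
    assert abs(frac - 2 / 3) < 4 * se


def test_paralog_reads_errors():
    parent, retro, _ = _paralog_pair(n=80, site=40)
    with pytest.raises(SimulationError, match="read length"):
        simulate_paralog_reads(parent, retro, (1, 1), 100, 10)
    with pytest.raises(SimulationError, match="exactly one site"):
        simulate_paralog_reads(parent, parent, (1, 1), 50, 10)
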