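"""Lineage-specific SV derivation and the three-way Venn partition."""

import numpy as np
import pytest

from triosv.lineage_specific import (
    LineageError,
    aligned_masks,
    derive_dog_specific,
    genes_in_specific_regions,
    venn_partition,
)
from triosv.models import GeneModel, GenomeSequence, SvCall
from triosv.sv_classify import call_svs_from_truth_maf
from triosv.synthetic_trio import truth_alignment


def _ins(start, length, chrom="c1", comparison=""):
    return SvCall("INS", chrom, start, start + length, "q", 0, 0, length, comparison)


def test_identical_insertion_in_both_sets_is_specific():
    res = derive_dog_specific([_ins(100, 60)], [_ins(100, 60)])
    assert len(res.dog_specific) == 1
    assert not res.dog_wolf_only and not res.dog_dhole_only


def test_call_in_one_comparison_only_is_not_specific():
    # an INS seen only against the wolf is a wolf-lineage deletion
    res = derive_dog_specific([_ins(100, 60)], [])
    assert res.dog_specific == []
    assert len(res.dog_wolf_only) == 1


def test_breakpoint_tolerance_and_length_ratio():
    assert derive_dog_specific([_ins(100, 60)], [_ins(140, 60)], bp_tol=50).dog_specific
    assert not derive_dog_specific([_ins(100, 60)], [_ins(180, 60)], bp_tol=50).dog_specific
    assert not derive_dog_specific([_ins(100, 200)], [_ins(100, 60)]).dog_specific


def test_order_invariance():
    dw = [_ins(100, 60), _ins(500, 80), _ins(900, 70)]
    dd = [_ins(95, 62), _ins(905, 66)]
    a = derive_dog_specific(dw, dd)
    b = derive_dog_specific(dw[::-1], dd[::-1])
    assert a.dog_specific == b.dog_specific


def test_raising_recip_never_increases_specific_count():
    rng = np.random.default_rng(0)
    dw, dd = [], []
    for i in range(30):
        s = int(rng.integers(0, 50_000))
        ln = int(rng.integers(50, 400))
        dw.append(SvCall("INV", "c1", s, s + ln, "q", 0, 0, ln))
        jitter = int(rng.integers(-80, 80))
        dd.append(SvCall("INV", "c1", s + jitter, s + jitter + ln, "q", 0, 0, ln))
    sizes = [
        len(derive_dog_specific(dw, dd, recip=r).dog_specific)
        for r in (0.1, 0.3, 0.5, 0.7, 0.9)
    ]
    assert sizes == sorted(sizes, reverse=True)


def test_partition_of_inputs():
    dw = [_ins(100, 60), _ins(600, 90)]
    dd = [_ins(100, 60), _ins(2000, 70)]
    res = derive_dog_specific(dw, dd)
    assert len(res.dog_specific) + len(res.dog_wolf_only) == len(dw)
    assert len(res.dog_specific) + len(res.dog_dhole_only) == len(dd)


def test_truth_path_dog_specific_set_is_pure(small_trio):
    """All dog-branch events land in the dog-specific set; no wolf or dhole
    event leaks in (the biological point of the three-way intersection)."""
    from triosv.synthetic_trio import expected_calls, match_calls

    dw = call_svs_from_truth_maf(truth_alignment(small_trio, "dog", "wolf"))
    dd = call_svs_from_truth_maf(truth_alignment(small_trio, "dog", "dhole"))
    res = derive_dog_specific(dw, dd)
    dog_events = [
        r for r in small_trio.truth if r.branch == "dog"
    ]
    # every dog-branch event is recovered in the specific set
    exp = [e for e in expected_calls(small_trio, "dog", "wolf")
           if e.event_id in {r.event_id for r in dog_events}]
    _, recall, _ = match_calls(res.dog_specific, exp, tol=0)
    assert recall == 1.0
    # and nothing else is: every specific call matches a dog-branch event
    _, _, precision = match_calls(res.dog_specific, exp, tol=0)
    assert precision == 1.0


# --- Venn --------------------------------------------------------------------


def _mask(n, fill=True):
    return np.full(n, fill, dtype=bool)


def test_identical_genomes_have_zero_specific():
    g = {n: [GenomeSequence("c1", "ACGT" * 250)] for n in ("dog", "wolf", "dhole")}
    masks = {}
    for a in g:
        for b in g:
            if a != b:
                masks[(a, b)] = {"c1": _mask(1000)}
    parts = venn_partition(g, masks)
    for p in parts.values():
        assert p.specific == 0 and p.shared_all == 1000


def test_disjoint_genomes_are_fully_specific():
    g = {n: [GenomeSequence("c1", "ACGT" * 250)] for n in ("dog", "wolf", "dhole")}
    masks = {(a, b): {"c1": _mask(1000, False)} for a in g for b in g if a != b}
    parts = venn_partition(g, masks)
    for p in parts.values():
        assert p.specific == 1000 and p.shared_all == 0


def test_partition_conservation_excludes_n_bases():
    g = {n: [GenomeSequence("c1", "ACGT" * 100 + "N" * 40)]
         for n in ("dog", "wolf", "dhole")}
    masks = {(a, b): {"c1": _mask(440, False)} for a in g for b in g if a != b}
    parts = venn_partition(g, masks)
    for p in parts.values():
        assert p.n_bases == 40
        assert p.shared_all + sum(p.shared_one.values()) + p.specific == 400


def test_mask_length_mismatch_rejected():
    g = {n: [GenomeSequence("c1", "ACGT")] for n in ("dog", "wolf", "dhole")}
    masks = {(a, b): {"c1": _mask(10)} for a in g for b in g if a != b}
    with pytest.raises(LineageError, match="length"):
        venn_partition(g, masks)


def test_truth_venn_dog_specific_equals_inserted_content(small_trio):
    """Dog-specific bases = dog-branch insertion content (incl. the
    retrocopy), exactly, when masks come from truth alignments."""
    masks = {}
    for a, b in (("dog", "wolf"), ("dog", "dhole"), ("wolf", "dhole")):
        tm, qm = aligned_masks(truth_alignment(small_trio, a, b), fill_gap=0)
        masks[(a, b)] = tm
        masks[(b, a)] = qm
    parts = venn_partition(small_trio.genomes, masks)
    expected = sum(
        r.length for r in small_trio.truth if r.branch == "dog" and r.sv_type == "INS"
    )
    assert parts["dog"].specific == expected


def test_genes_in_specific_regions_containment(small_trio):
    masks = {}
    for a, b in (("dog", "wolf"), ("dog", "dhole"), ("wolf", "dhole")):
        tm, qm = aligned_masks(truth_alignment(small_trio, a, b), fill_gap=0)
        masks[(a, b)] = tm
        masks[(b, a)] = qm
    parts = venn_partition(small_trio.genomes, masks)
    found = genes_in_specific_regions(parts["dog"], small_trio.genes)
    # exactly the planted retrocopy gene lies wholly inside specific sequence
    retro_ids = [g.id for g in small_trio.genes if g.id.endswith("_retro")]
    assert found == retro_ids
    # a gene straddling the specific-region edge is excluded: the ordinary
    # genes overlap aligned sequence and never qualify
    assert not any(g in found for g in ("gene1", "gene2"))


def test_empty_specific_set_returns_no_genes():
    part_genomes = {n: [GenomeSequence("c1", "ACGT" * 250)]
                    for n in ("dog", "wolf", "dhole")}
    masks = {(a, b): {"c1": _mask(1000)} for a in part_genomes
             for b in part_genomes if a != b}
    parts = venn_partition(part_genomes, masks)
    gene = GeneModel("g", "c1", "+", 10, 200, exons=((10, 200),))
    assert genes_in_specific_regions(parts["dog"], [gene]) == []
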