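"""Anchor finding, chaining (vs brute force), netting and MAF emission."""

import itertools

import numpy as np
import pytest

from triosv import formats_io
from triosv.anchor_align import (
    AlignConfig,
    align_genomes,
    chain_anchors,
    find_anchors,
    net_chains,
    net_to_maf,
)
from triosv.models import Anchor, Chain, GenomeSequence, revcomp


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


# --- anchors -----------------------------------------------------------------


def test_identical_sequences_give_one_full_length_anchor():
    rng = np.random.default_rng(0)
    seq = _random_seq(rng, 1000)
    anchors = find_anchors(GenomeSequence("t", seq), GenomeSequence("q", seq))
    plus = [a for a in anchors if a.strand == "+"]
    assert len(plus) == 1
    assert (plus[0].t_start, plus[0].q_start, plus[0].length) == (0, 0, 1000)


def test_reverse_complement_query_yields_minus_anchors():
    rng = np.random.default_rng(1)
    seq = _random_seq(rng, 800)
    anchors = find_anchors(
        GenomeSequence("t", seq), GenomeSequence("q", revcomp(seq))
    )
    minus = [a for a in anchors if a.strand == "-"]
    assert len(minus) == 1
    assert minus[0].length == 800  # covers the sequence on '-'


def test_anchors_are_exact_matches():
    rng = np.random.default_rng(2)
    seq = list(_random_seq(rng, 2000))
    mutated = seq.copy()
    for pos in rng.choice(2000, 25, replace=False):
        mutated[pos] = "ACGT"[("ACGT".index(mutated[pos]) + 1) % 4]
    t, q = "".join(seq), "".join(mutated)
    anchors = find_anchors(GenomeSequence("t", t), GenomeSequence("q", q))
    assert anchors
    for a in anchors:
        if a.strand == "+":
            assert t[a.t_start : a.t_end] == q[a.q_start : a.q_end]
        else:
            assert t[a.t_start : a.t_end] == revcomp(q)[a.q_start : a.q_end]


def test_n_runs_never_seed_anchors():
    rng = np.random.default_rng(3)
    core = _random_seq(rng, 300)
    t = core + "N" * 50 + _random_seq(rng, 300)
    anchors = find_anchors(GenomeSequence("t", t), GenomeSequence("q", t))
    for a in anchors:
        assert "N" not in t[a.t_start : a.t_end]


def test_spurious_anchor_rate_between_random_sequences():
    """Expected chance k-mer seeds between unrelated 10 kb sequences:
    2*(L-k+1)^2/4^k < 1, so anchors at min length 20 are essentially absent."""
    rng = np.random.default_rng(4)
    L, k = 10_000, 15
    expectation = 2 * (L - k + 1) ** 2 / 4**k
    assert expectation < 1
    total = 0
    for rep in range(5):
        t = GenomeSequence("t", _random_seq(rng, L))
        q = GenomeSequence("q", _random_seq(rng, L))
        total += len(find_anchors(t, q, k))
    assert total <= 2  # a handful of chance 20-mers across 5 replicates at most


# --- chaining vs brute force -------------------------------------------------

GAP_OPEN, GAP_EXT = 10.0, 0.05


def _link_ok(a: Anchor, b: Anchor, slack: int = 15):
    o = max(a.t_end - b.t_start, a.q_end - b.q_start, 0)
    return o <= slack and o < b.length, o


def _pair_score(a: Anchor, b: Anchor) -> float:
    ok, o = _link_ok(a, b)
    g = (b.t_start + o - a.t_end) + (b.q_start + o - a.q_end)
    cost = 0.0 if g == 0 else GAP_OPEN + GAP_EXT * g
    return (b.length - o) - cost


def brute_force_best_chain_score(anchors: list[Anchor]) -> float:
    """Exhaustive search over all colinear subsets (oracle)."""
    anchors = sorted(anchors, key=lambda a: (a.t_start, a.q_start))
    best = 0.0
    n = len(anchors)
    for size in range(1, n + 1):
        for combo in itertools.combinations(range(n), size):
            score = float(anchors[combo[0]].length)
            valid = True
            for i, j in zip(combo, combo[1:]):
                ok, _ = _link_ok(anchors[i], anchors[j])
                if not ok:
                    valid = False
                    break
                score += _pair_score(anchors[i], anchors[j])
            if valid:
                best = max(best, score)
    return best


def _random_anchors(rng, n):
    out = []
    for _ in range(n):
        t = int(rng.integers(0, 400))
        q = int(rng.integers(0, 400))
        out.append(Anchor(t, q, int(rng.integers(10, 60)), "+"))
    return out


def test_two_colinear_anchors_one_chain():
    anchors = [Anchor(0, 0, 50), Anchor(60, 58, 50)]
    chains = chain_anchors(anchors, GAP_OPEN, GAP_EXT)
    assert len(chains) == 1 and len(chains[0].anchors) == 2


def test_crossing_anchors_stay_separate():
    anchors = [Anchor(0, 200, 50), Anchor(100, 0, 50)]
    chains = chain_anchors(anchors, GAP_OPEN, GAP_EXT)
    assert len(chains) == 2
    assert all(len(c.anchors) == 1 for c in chains)


@pytest.mark.parametrize("seed", range(30))
def test_chain_score_matches_exhaustive_search(seed):
    rng = np.random.default_rng(seed)
    anchors = _random_anchors(rng, int(rng.integers(2, 11)))
    chains = chain_anchors(anchors, GAP_OPEN, GAP_EXT)
    got = max(c.score for c in chains)
    assert got == pytest.approx(brute_force_best_chain_score(anchors))


# --- netting -----------------------------------------------------------------


def _chain(t_chrom, q_chrom, t0, q0, length, score, strand="+"):
    c = Chain(t_chrom, q_chrom, strand, [Anchor(t0, q0, length, strand)], score)
    return c


def test_net_single_chain_kept():
    net = net_chains([_chain("c1", "c1", 0, 0, 100, 100.0)])
    assert len(net.chains) == 1 and not net.overlap_pairs


def test_net_identical_spans_keep_higher_score_and_record_conflict():
    a = _chain("c1", "c1", 0, 0, 100, 100.0)
    b = _chain("c1", "c1", 0, 300, 100, 50.0)
    net = net_chains([a, b])
    assert len(net.chains) == 1
    assert net.chains[0].anchors[0].q_start == 0  # the score-100 chain
    assert len(net.overlap_pairs) == 1
    assert (net.overlap_pairs[0].t_start, net.overlap_pairs[0].t_end) == (0, 100)


def greedy_net_oracle(chains, min_score=25.0):
    """Independent reimplementation: greedy by score, base-level trimming.

    Returns (number of kept chains, set of covered target bases per chrom).
    """
    ranked = sorted(
        [c for c in chains if c.score >= min_score],
        key=lambda c: (-c.score, c.t_chrom, c.anchors[0].t_start, c.anchors[0].q_start),
    )
    covered: dict[str, set[int]] = {}
    n_kept = 0
    for c in ranked:
        cov = covered.setdefault(c.t_chrom, set())
        remaining = [
            t for a in c.anchors for t in range(a.t_start, a.t_end) if t not in cov
        ]
        if len(remaining) >= min_score:
            n_kept += 1
            cov.update(remaining)
    return n_kept, covered


@pytest.mark.parametrize("seed", range(20))
def test_netting_matches_greedy_oracle(seed):
    rng = np.random.default_rng(100 + seed)
    chains = []
    for _ in range(int(rng.integers(2, 9))):
        t0 = int(rng.integers(0, 500))
        length = int(rng.integers(30, 150))
        chains.append(
            _chain("c1", "c1", t0, int(rng.integers(0, 500)), length, float(length))
        )
    import copy

    net = net_chains(copy.deepcopy(chains))
    n_exp, cov_exp = greedy_net_oracle(copy.deepcopy(chains))
    cov_got = {
        t for c in net.chains for a in c.anchors for t in range(a.t_start, a.t_end)
    }
    assert len(net.chains) == n_exp
    assert cov_got == cov_exp.get("c1", set())


# --- MAF emission ------------------------------------------------------------


def test_identity_genomes_net_tiles_chromosome(tmp_path):
    rng = np.random.default_rng(8)
    seq = _random_seq(rng, 5000)
    g = [GenomeSequence("c1", seq)]
    net = align_genomes(g, g, AlignConfig())
    maf = net_to_maf(net, g, g, "t", "q")
    assert maf[0].target.start == 0
    covered = sum(b.target.size for b in maf)
    assert covered == 5000
    # round-trips through the MAF reader
    p = tmp_path / "x.maf"
    formats_io.write_maf(maf, str(p))
    assert formats_io.read_maf(str(p)) == maf


def test_empty_net_gives_empty_maf():
    rng = np.random.default_rng(9)
    t = [GenomeSequence("c1", _random_seq(rng, 2000))]
    q = [GenomeSequence("c1", _random_seq(rng, 2000))]
    net = align_genomes(t, q, AlignConfig())
    assert net_to_maf(net, t, q) == []


def test_minus_strand_maf_sequences_verify():
    """Re-extract the query sequence from minus-strand rows and compare."""
    rng = np.random.default_rng(10)
    seq = _random_seq(rng, 3000)
    inv = seq[:1000] + revcomp(seq[1000:2000]) + seq[2000:]
    t = [GenomeSequence("c1", seq)]
    q = [GenomeSequence("c1", inv)]
    net = align_genomes(t, q, AlignConfig())
    maf = net_to_maf(net, t, q, "t", "q")
    minus = [b for b in maf if b.query.strand == "-"]
    assert minus
    for b in maf:
        qf = b.query.forward_interval()
        forward = inv[qf[0] : qf[1]]
        expected = b.query.text if b.query.strand == "+" else revcomp(b.query.text)
        assert forward == expected
        assert b.target.text == seq[b.target.start : b.target.start + b.target.size]
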