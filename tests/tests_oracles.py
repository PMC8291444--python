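"""Independent oracles shared by the unit and acceptance tests.

Each function re-derives a result by a different route than the library
(exhaustive search, per-base scan, rank enumeration) so tests compare two
independent computations.
"""

import itertools

import numpy as np

from triosv.models import Anchor, GeneModel

GAP_OPEN, GAP_EXT = 10.0, 0.05


def _link_ok(a: Anchor, b: Anchor, slack: int = 15):
    o = max(a.t_end - b.t_start, a.q_end - b.q_start, 0)
    return o <= slack and o < b.length, o


def _pair_score(a: Anchor, b: Anchor) -> float:
    _, o = _link_ok(a, b)
    g = (b.t_start + o - a.t_end) + (b.q_start + o - a.q_end)
    cost = 0.0 if g == 0 else GAP_OPEN + GAP_EXT * g
    return (b.length - o) - cost


def brute_force_best_chain_score(anchors: list[Anchor]) -> float:
    """Exhaustive search over all colinear anchor subsets."""
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


def greedy_net_oracle(chains, min_score=25.0):
    """Independent netting reimplementation: greedy by descending score
    with base-level target trimming.  Returns (n kept, covered bases)."""
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


ANNOT_PRECEDENCE = ("CDS", "UTR", "exon_noncoding", "intron", "intergenic")


def brute_force_category(sv, genes) -> str:
    """Per-base scan with the same precedence order as the annotator."""
    s, e = (sv.t_start, sv.t_end) if sv.t_end > sv.t_start else (
        sv.t_start, sv.t_start + 1
    )
    present = set()
    for base in range(s, e):
        for g in genes:
            if g.chrom != sv.t_chrom or not (g.tx_start <= base < g.tx_end):
                continue
            in_exon = any(a <= base < b for a, b in g.exons)
            if in_exon:
                if g.cds:
                    in_cds = any(a <= base < b for a, b in g.cds)
                    present.add("CDS" if in_cds else "UTR")
                else:
                    present.add("exon_noncoding")
            else:
                present.add("intron")
    for cat in ANNOT_PRECEDENCE:
        if cat in present:
            return cat
    return "intergenic"


def random_genes(rng, n, span=20_000) -> list[GeneModel]:
    genes = []
    for i in range(n):
        start = int(rng.integers(0, span))
        n_ex = int(rng.integers(1, 4))
        exons = []
        pos = start
        for _ in range(n_ex):
            ln = int(rng.integers(30, 120))
            exons.append((pos, pos + ln))
            pos += ln + int(rng.integers(20, 150))
        coding = rng.integers(2) == 1
        cds = tuple((a + 10, b - 10) for a, b in exons if b - a > 25) if coding else ()
        genes.append(
            GeneModel(f"g{i}", "c1", "+", exons[0][0], exons[-1][1],
                      tuple(exons), cds)
        )
    return genes


def exact_two_sided_p(x, y) -> float:
    """Two-sided rank-sum p by enumeration of all rank assignments."""
    pooled = list(x) + list(y)
    n, nx = len(pooled), len(x)
    ranks = {v: r for r, v in enumerate(sorted(pooled), 1)}
    obs = sum(ranks[v] for v in x)
    stats = np.array(
        [sum(c) for c in itertools.combinations(range(1, n + 1), nx)], float
    )
    mean = stats.mean()
    return float(np.mean(np.abs(stats - mean) >= abs(obs - mean) - 1e-9))
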