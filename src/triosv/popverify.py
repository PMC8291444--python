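"""Population-level read-depth verification of candidate insertions.

Per-sample depth is normalized by the sample's genome-wide sequencing
depth, averaged base-by-base within species, and summarized as a regional
mean over the candidate interval; two flanks of the same length as the
insertion serve as coverage controls.  Carrier and non-carrier groups are
compared with the Mann–Whitney–Wilcoxon rank-sum test.  ``overlap_ratio``
cross-checks SV sets against independent population call sets.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .models import BedRecord, CoverageTrack


class PopVerifyError(ValueError):
    pass


def normalize_depth(track: CoverageTrack) -> np.ndarray:
    """Per-base depth divided by the sample's sequencing depth."""
    if track.sample_seq_depth <= 0:
        raise PopVerifyError(
            f"sample {track.sample}: sequencing depth must be positive"
        )
    return track.depth / track.sample_seq_depth


def species_profile(tracks: list[CoverageTrack]) -> np.ndarray:
    """Per-base mean of normalized depth across one species' samples."""
    if not tracks:
        raise PopVerifyError("need at least one coverage track")
    region = tracks[0].region
    for t in tracks:
        if t.region != region:
            raise PopVerifyError(
                f"track {t.sample} covers {t.region}, expected {region}"
            )
    return np.mean([normalize_depth(t) for t in tracks], axis=0)


def regional_mean(
    values: "CoverageTrack | np.ndarray",
    interval: tuple[int, int],
    region_start: int = 0,
) -> float:
    """Mean (normalized) depth over an interval.

    ``values`` is either a coverage track (normalized internally; interval
    in genome coordinates) or an already-normalized per-base vector with
    ``region_start`` giving its genomic offset.
    """
    if isinstance(values, CoverageTrack):
        region_start = values.start
        vec = normalize_depth(values)
    else:
        vec = np.asarray(values)
    s, e = interval[0] - region_start, interval[1] - region_start
    if e <= s:
        raise PopVerifyError("empty interval")
    if s < 0 or e > len(vec):
        raise PopVerifyError("interval outside the covered region")
    return float(vec[s:e].mean())


def flank_design(
    insertion: tuple[str, int, int], chrom_length: int | None = None
) -> tuple[tuple[int, int], tuple[int, int], tuple[int, int]]:
    """Two marginal regions of the same length as the insertion, contiguous
    with it: (left flank, insertion, right flank)."""
    chrom, s, e = insertion
    length = e - s
    if length <= 0:
        raise PopVerifyError("empty insertion interval")
    if s - length < 0:
        raise PopVerifyError(f"left flank of {chrom}:{s}-{e} runs off the chromosome")
    if chrom_length is not None and e + length > chrom_length:
        raise PopVerifyError(f"right flank of {chrom}:{s}-{e} runs off the chromosome")
    return (s - length, s), (s, e), (e, e + length)


@dataclass(frozen=True)
class RankSumResult:
    statistic: float
    pvalue: float
    method: str
    degenerate: bool = False


def ranksum_test(x, y) -> RankSumResult:
    """Two-sided Mann–Whitney–Wilcoxon rank-sum test.

    Exact enumeration of the U distribution when the pooled sample is small
    (n <= 12) and tie-free; otherwise the normal approximation with tie and
    continuity corrections.  Identical pooled values are degenerate:
    p = 1 with a flag rather than an error.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 1 or len(y) < 1:
        raise PopVerifyError("both groups need at least one observation")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return RankSumResult(float(len(x) * len(y) / 2), 1.0, "degenerate", True)
    ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= 12 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return RankSumResult(float(res.statistic), min(float(res.pvalue), 1.0), method)


@dataclass
class RegionReport:
    """Fig-4-style summary of one candidate insertion."""

    insertion: tuple[str, int, int]
    profiles: dict[str, np.ndarray]  # per-species normalized mean profile
    sample_means: dict[str, dict[str, float]]  # species -> sample -> regional mean
    flank_means: dict[str, float]  # species -> mean over both flanks
    interior_means: dict[str, float]
    ranksum: RankSumResult


def verify_insertion(
    tracks: list[CoverageTrack], insertion: tuple[str, int, int]
) -> RegionReport:
    """Full verification: profiles, per-sample regional means, flank
    contrast, and the rank-sum test between the two species groups."""
    species = sorted({t.species for t in tracks})
    if len(species) != 2:
        raise PopVerifyError(f"expected exactly two species, got {species}")
    left, inner, right = flank_design(insertion)
    profiles, sample_means, flank_means, interior_means = {}, {}, {}, {}
    groups = []
    for sp in species:
        sub = [t for t in tracks if t.species == sp]
        profiles[sp] = species_profile(sub)
        sample_means[sp] = {t.sample: regional_mean(t, inner) for t in sub}
        start = sub[0].start
        flank_means[sp] = float(
            np.mean(
                [
                    regional_mean(profiles[sp], left, start),
                    regional_mean(profiles[sp], right, start),
                ]
            )
        )
        interior_means[sp] = regional_mean(profiles[sp], inner, start)
        groups.append(list(sample_means[sp].values()))
    return RegionReport(
        insertion,
        profiles,
        sample_means,
        flank_means,
        interior_means,
        ranksum_test(groups[0], groups[1]),
    )


def overlap_ratio(set_a: list[BedRecord], set_b: list[BedRecord]) -> float:
    """Fraction of records in ``set_a`` overlapping (>= 1 bp) any record of
    ``set_b``; the denominator is |set_a|."""
    if not set_a:
        raise PopVerifyError("overlap ratio of an empty set is undefined")
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for r in set_b:
        by_chrom.setdefault(r.chrom, []).append((r.start, r.end))
    merged: dict[str, tuple[list[int], list[int]]] = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        starts, ends = [], []
        for s, e in ivs:
            if ends and s <= ends[-1]:
                ends[-1] = max(ends[-1], e)
            else:
                starts.append(s)
                ends.append(e)
        merged[chrom] = (starts, ends)
    hit = 0
    for r in set_a:
        starts, ends = merged.get(r.chrom, ([], []))
        i = bisect.bisect_right(starts, r.end - 1) - 1
        if i >= 0 and ends[i] > r.start:
            hit += 1
    return hit / len(set_a)
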