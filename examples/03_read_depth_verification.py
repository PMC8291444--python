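"""Verify an insertion at population level from per-sample read depth.

Carriers (dogs) have sequencing coverage across the insertion; samples
without it (gray wolves mapped to the dog reference) drop to zero inside
the insertion while matching the carriers on both flanks.  The per-sample
regional means are compared with the Mann-Whitney-Wilcoxon rank-sum test.
"""

from triosv.popverify import verify_insertion
from triosv.synthetic_trio import simulate_population_coverage

insertion = ("chr14", 31_644_130, 31_645_486)  # 1,356 bp candidate
length = insertion[2] - insertion[1]
region = (insertion[0], insertion[1] - length, insertion[2] + length)

tracks = simulate_population_coverage(
    region, insertion[1:], n_carriers=11, n_noncarriers=12,
    noise_fraction=0.01, seed=42,
)
report = verify_insertion(tracks, insertion)

for sp in sorted(report.interior_means):
    print(f"{sp:5s} normalized depth: insertion {report.interior_means[sp]:.3f}  "
          f"flanks {report.flank_means[sp]:.3f}")
print(f"rank-sum U = {report.ranksum.statistic:.0f}, "
      f"two-sided p = {report.ranksum.pvalue:.2e} ({report.ranksum.method})")
# interior ~1 for carriers vs ~0 for non-carriers, while the flanks agree,
# is the read-depth signature of a real lineage-specific insertion
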