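"""Differentially methylated region calling on a planted two-group design.

Simulates 3v3 replicates at 20x beta-binomial coverage with 40 planted DMRs
(|delta methylation| = 0.4), smooths, computes per-CpG t statistics, and
calls DMRs with the default quantile cutoffs. Recovery is scored with
reciprocal 50% overlap and matching direction.
"""

import numpy as np

from methylscape import call_dmrs, dmr_benchmark, per_cpg_t_statistic, smooth_methylome

group_a, group_b, truth = dmr_benchmark(seed=3, n_dmrs=40, n_chroms=1, chrom_size=3_500_000)
for m in group_a + group_b:
    smooth_methylome(m)

t_stats = per_cpg_t_statistic(group_a, group_b)
called = call_dmrs(t_stats, "demo")


def matches(x, y):
    ov = min(x.interval.end, y.interval.end) - max(x.interval.start, y.interval.start)
    return (x.direction == y.direction and ov >= 0.5 * len(x.interval)
            and ov >= 0.5 * len(y.interval))


sens = np.mean([any(matches(t, c) for c in called) for t in truth])
prec = np.mean([any(matches(c, t) for t in truth) for c in called])
print(f"planted DMRs: {len(truth)}  called DMRs: {len(called)}")
print(f"sensitivity {sens:.2f}  precision {prec:.2f}  (reciprocal-50% overlap)")
d = called[0]
print(f"example call: {d.interval.chrom}:{d.interval.start}-{d.interval.end} "
      f"{d.direction}, {d.n_cpgs} CpGs, mean diff {d.mean_diff:+.2f}, "
      f"area statistic {d.area_stat:.0f}")
print("hyper = methylation gained from group A to group B; hypo = lost.")
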