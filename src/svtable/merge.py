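"""Cross-sample SV integration.

Two calls of the same type on the same chromosome are considered the same SV
when their positional offset does not exceed

    M * sqrt(min(length_a, length_b))

with M a dimensionless tolerance constant (default 250).  Raising M widens
the tolerance for positional discrepancies between samples.  Clustering is
single-linkage chaining over position-sorted calls: adjacent calls are
linked when their gap is within the pairwise threshold, and clusters are the
connected components of that chain.  Breakends carry no length, so pairs of
breakends are compared against a fixed window of M bp instead.

Each cluster is summarized into one merged site holding a representative
position/length (the median over member calls, lower-middle for even
counts), population standard deviations of member positions and lengths
(STDEV_POS / STDEV_LEN), and a genotype for every cohort sample — 0/0 for
samples that contributed no call.
"""

from __future__ import annotations

import math
from collections import defaultdict

import numpy as np

from .model import Cohort, MergedSite, SVCall

__all__ = ["pair_threshold", "cluster_calls", "summarize_cluster", "merge_cohort"]

#: Alt-allele dosage, used to break ties toward the stronger genotype.
_GT_RANK = {"0/0": 0, "0/1": 1, "1/1": 2}


def pair_threshold(len_a: float, len_b: float, M: float = 250.0) -> float:
    """Maximum positional offset for two calls to merge: M * sqrt(min(lengths))."""
    if len_a < 0 or len_b < 0:
        raise ValueError("SV lengths must be non-negative")
    return M * math.sqrt(min(len_a, len_b))


def _link_threshold(a: SVCall, b: SVCall, M: float) -> float:
    if a.length is None or b.length is None:
        # breakends have no defined length; use a fixed M-bp window
        return M
    return pair_threshold(a.length, b.length, M)


def cluster_calls(calls: list[SVCall], M: float = 250.0) -> list[list[SVCall]]:
    """Partition same-chromosome, same-type calls into positional clusters.

    Calls are sorted by position; adjacent calls are linked when their gap is
    within the pairwise threshold, and clusters are the runs of linked calls.
    Every call lands in exactly one cluster.
    """
    if not calls:
        return []
    chroms = {c.chrom for c in calls}
    types = {c.sv_type for c in calls}
    if len(chroms) > 1 or len(types) > 1:
        raise ValueError("cluster_calls requires calls of one chromosome and one SV type")
    ordered = sorted(calls, key=lambda c: (c.pos, c.sample_id, c.length or 0))
    clusters: list[list[SVCall]] = [[ordered[0]]]
    for prev, cur in zip(ordered, ordered[1:]):
        if cur.pos - prev.pos <= _link_threshold(prev, cur, M):
            clusters[-1].append(cur)
        else:
            clusters.append([cur])
    return clusters


def _lower_median(values: list[int]) -> int:
    ordered = sorted(values)
    return ordered[(len(ordered) - 1) // 2]


def summarize_cluster(cluster: list[SVCall], cohort_samples: list[str]) -> MergedSite:
    """Collapse one cluster into a :class:`MergedSite`.

    The representative position and length are lower medians over the member
    calls; dispersions are population standard deviations (zero for
    singletons, so unjittered sites survive the default confidence filter).
    A sample contributing several calls is genotyped from the call nearest
    the representative position, ties going to the higher-dosage genotype.
    """
    if not cluster:
        raise ValueError("empty cluster")
    sv_type = cluster[0].sv_type
    chrom = cluster[0].chrom
    positions = [c.pos for c in cluster]
    pos = _lower_median(positions)
    stdev_pos = float(np.std(positions))
    lengths = [c.length for c in cluster if c.length is not None]
    if lengths:
        length = _lower_median(lengths)
        stdev_len = float(np.std(lengths))
    else:
        length, stdev_len = None, 0.0
    if sv_type == "INS" or length is None:
        end = pos
    else:
        end = pos + length
    by_sample: dict[str, list[SVCall]] = defaultdict(list)
    for c in cluster:
        by_sample[c.sample_id].append(c)
    genotypes = {s: "0/0" for s in cohort_samples}
    for sample, calls in by_sample.items():
        best = min(calls, key=lambda c: (abs(c.pos - pos), -_GT_RANK[c.genotype]))
        genotypes[sample] = best.genotype
    return MergedSite(
        chrom=chrom,
        pos=pos,
        sv_type=sv_type,
        length=length,
        end=end,
        stdev_pos=stdev_pos,
        stdev_len=stdev_len,
        precise=all(c.precise for c in cluster),
        genotypes=genotypes,
        members=sorted(cluster, key=lambda c: (c.pos, c.sample_id)),
    )


def merge_cohort(callsets: dict[str, list[SVCall]], M: float = 250.0) -> Cohort:
    """Integrate per-sample call sets into a cohort of merged sites.

    Calls are pooled, partitioned by (chromosome, SV type) — different SV
    types never share a merged site — clustered, and summarized.  The total
    number of member calls across sites equals the total number of input
    calls.
    """
    samples = list(callsets)
    if len(set(samples)) != len(samples):
        raise ValueError("duplicate sample ids")
    pools: dict[tuple[str, str], list[SVCall]] = defaultdict(list)
    for sample, calls in callsets.items():
        for c in calls:
            if c.sample_id != sample:
                c = SVCall(**{**c.__dict__, "sample_id": sample})
            pools[(c.chrom, c.sv_type)].append(c)
    sites: list[MergedSite] = []
    for key in sorted(pools):
        for cluster in cluster_calls(pools[key], M):
            sites.append(summarize_cluster(cluster, samples))
    return Cohort(samples=samples, sites=sites, merge_constant_M=M)
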