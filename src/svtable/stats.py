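"""Cohort-level summary analytics.

Per-chromosome counts and densities, per-sample type/zygosity tallies,
three-genotype sites (the preferred substrate for co-dominant indel
markers), length histograms, SV-type proportions, marker-candidate
selection, and genotype concordance against an external genotyping method.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .model import Cohort, MergedSite, ReferenceGenome

__all__ = [
    "ChromSummary",
    "SampleSummary",
    "chromosome_summary",
    "sample_summary",
    "hom_het_ratio",
    "length_histogram",
    "type_proportions",
    "select_marker_candidates",
    "genotype_concordance",
    "ConcordanceResult",
]


@dataclass
class ChromSummary:
    chrom: str
    n_sites: int
    length_bp: int
    n_three_genotype: int

    @property
    def density(self) -> float:
        """Sites per megabase (full precision; round for display)."""
        return self.n_sites / (self.length_bp / 1e6)


@dataclass
class SampleSummary:
    sample_id: str
    type_counts: dict[str, int] = field(default_factory=dict)
    n_hom: int = 0
    n_het: int = 0

    @property
    def total(self) -> int:
        return self.n_hom + self.n_het


def _is_three_genotype(site: MergedSite) -> bool:
    return {"0/0", "0/1", "1/1"} <= site.genotype_set()


def chromosome_summary(cohort: Cohort, genome: ReferenceGenome) -> list[ChromSummary]:
    """Per-chromosome site counts, densities, and three-genotype counts.

    The final entry (chrom="Total") aggregates counts over the whole genome;
    its density uses the summed contig lengths.
    """
    for site in cohort.sites:
        if site.chrom not in genome:
            raise KeyError(f"site chromosome {site.chrom!r} absent from reference")
    out = []
    total_sites = total_three = 0
    for chrom in genome.contig_names:
        sites = [s for s in cohort.sites if s.chrom == chrom]
        n_three = sum(1 for s in sites if _is_three_genotype(s))
        out.append(ChromSummary(chrom, len(sites), genome.length(chrom), n_three))
        total_sites += len(sites)
        total_three += n_three
    out.append(ChromSummary("Total", total_sites, genome.total_length(), total_three))
    return out


def sample_summary(cohort: Cohort) -> list[SampleSummary]:
    """Per-sample SV tallies over sites where the sample's genotype is not 0/0."""
    summaries = {s: SampleSummary(s) for s in cohort.samples}
    for site in cohort.sites:
        for sample in cohort.samples:
            gt = site.genotypes.get(sample, "0/0")
            if gt == "0/0":
                continue
            summ = summaries[sample]
            summ.type_counts[site.sv_type] = summ.type_counts.get(site.sv_type, 0) + 1
            if gt == "1/1":
                summ.n_hom += 1
            else:
                summ.n_het += 1
    return [summaries[s] for s in cohort.samples]


def hom_het_ratio(summary: SampleSummary) -> float:
    """Homozygous-to-heterozygous SV count ratio for one sample."""
    if summary.n_het == 0:
        raise ZeroDivisionError(
            f"sample {summary.sample_id}: no heterozygous SVs, ratio undefined"
        )
    return summary.n_hom / summary.n_het


def length_histogram(
    cohort: Cohort, bin_width: int = 50, overflow_at: int = 10000, min_length: int = 50
) -> list[tuple[tuple[int, int | None], int]]:
    """Histogram of site lengths; breakends (undefined length) are excluded.

    Regular bins are half-open ``[a, a + bin_width)`` starting at
    ``min_length``, except the last one, which closes at ``overflow_at``;
    a final overflow bin collects everything longer.  Returned as an ordered
    list of ((low, high), count); the overflow bin has high=None.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    edges = list(range(min_length, overflow_at + 1, bin_width))
    if edges[-1] != overflow_at:
        edges.append(overflow_at)
    n_bins = len(edges) - 1
    counts = [0] * (n_bins + 1)
    for site in cohort.sites:
        if site.length is None:
            continue
        if site.length > overflow_at:
            counts[n_bins] += 1
            continue
        idx = min((site.length - min_length) // bin_width, n_bins - 1)
        counts[max(idx, 0)] += 1
    bins: list[tuple[tuple[int, int | None], int]] = [
        ((edges[i], edges[i + 1]), counts[i]) for i in range(n_bins)
    ]
    bins.append(((overflow_at, None), counts[n_bins]))
    return bins


def type_proportions(cohort: Cohort) -> dict[str, float]:
    """Fraction of all sites per SV type (over every site, breakends included)."""
    if not cohort.sites:
        raise ValueError("empty cohort")
    n = len(cohort.sites)
    props: dict[str, float] = {}
    for site in cohort.sites:
        props[site.sv_type] = props.get(site.sv_type, 0) + 1
    return {t: c / n for t, c in sorted(props.items())}


def select_marker_candidates(
    cohort: Cohort,
    reference_sample: str | None = None,
    max_len: int = 1000,
    allowed_types: tuple[str, ...] = ("INS", "DEL"),
) -> list[MergedSite]:
    """Sites suitable as co-dominant PCR markers.

    Keeps insertions/deletions of at most ``max_len`` bp at which all three
    genotypes occur across the cohort (so one marker distinguishes every
    state on a gel).  When ``reference_sample`` is given — a sample whose
    reads built the reference genome, so a homozygous SV call in it is
    self-contradictory — sites where that sample is 1/1 are excluded.
    """
    if reference_sample is not None and reference_sample not in cohort.samples:
        raise KeyError(f"unknown reference sample {reference_sample!r}")
    out = []
    for site in cohort.sites:
        if site.sv_type not in allowed_types:
            continue
        if site.length is None or site.length > max_len:
            continue
        if not _is_three_genotype(site):
            continue
        if reference_sample is not None and site.genotypes.get(reference_sample) == "1/1":
            continue
        out.append(site)
    return out


@dataclass
class ConcordanceResult:
    per_marker: dict[str, float]
    mean: float
    mismatches: list[tuple[str, str, str, str]]  # (marker, sample, predicted, observed)


def genotype_concordance(predicted: pd.DataFrame, observed: pd.DataFrame) -> ConcordanceResult:
    """Agreement between two genotype grids (markers x samples).

    The per-marker rate is the fraction of samples whose genotypes match;
    the summary is the unweighted mean over markers.  Both grids must share
    the same marker/sample labels.  The measure is symmetric in its
    arguments.
    """
    if set(predicted.index) != set(observed.index) or set(predicted.columns) != set(
        observed.columns
    ):
        raise ValueError("genotype grids do not share the same markers and samples")
    observed = observed.loc[predicted.index, predicted.columns]
    per_marker: dict[str, float] = {}
    mismatches = []
    for marker in predicted.index:
        n_match = 0
        for sample in predicted.columns:
            p, o = predicted.at[marker, sample], observed.at[marker, sample]
            if p == o:
                n_match += 1
            else:
                mismatches.append((marker, sample, p, o))
        per_marker[marker] = n_match / len(predicted.columns)
    mean = sum(per_marker.values()) / len(per_marker)
    return ConcordanceResult(per_marker=per_marker, mean=mean, mismatches=mismatches)
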