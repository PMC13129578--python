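"""Flank extraction and gene-context classification for merged sites.

Sequences
---------
For every site, the 300 bp (default) of reference immediately upstream and
downstream of the variant are attached, for primer design across the
breakpoints.  For deletions/inversions/duplications the variant sequence is
the reference segment itself; for insertions it is the inserted sequence of
the member call nearest the representative position; breakends have none.
Flanks are truncated at contig boundaries rather than erroring, so sites
near chromosome ends degrade gracefully.

Gene context
------------
The gene track carries no strand column, so "upstream" is strandless and
means lower coordinates: the upstream region of a gene extends up to 2,000
bp (default) before its start, truncated at the end of the nearest
preceding gene.  A site is *genic* for every gene whose body it intersects
and *upstream* for every gene whose upstream region it intersects but whose
body it does not; each context also names the nearest genes wholly before
and after the site.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io import fetch_subsequence
from .model import GeneFeature, GeneTrack, MergedSite, ReferenceGenome

__all__ = ["GeneContext", "attach_sequences", "attach_all", "upstream_region", "classify_site"]


@dataclass(frozen=True)
class GeneContext:
    """One (site, gene) relationship: genic hit or upstream-region hit."""

    gene_id: str
    region: str  # "genic" | "upstream"
    upstream_gene_id: str | None
    downstream_gene_id: str | None
    annotation: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.region not in ("genic", "upstream"):
            raise ValueError(f"bad region label {self.region!r}")


def attach_sequences(
    site: MergedSite, genome: ReferenceGenome, flank: int = 300
) -> MergedSite:
    """Return a copy of ``site`` with sv/upstream/downstream sequences filled."""
    if site.chrom not in genome:
        raise KeyError(f"unknown contig {site.chrom!r}")
    pos, end = site.pos, site.end
    # the upstream flank ends at the anchor base `pos` itself, so that for
    # deletions upstream + sv + downstream reads off the reference contiguously
    upstream = fetch_subsequence(genome, site.chrom, pos - flank + 1, pos)
    if site.sv_type in ("DEL", "INV", "DUP"):
        sv_seq = fetch_subsequence(genome, site.chrom, pos + 1, end)
        downstream = fetch_subsequence(genome, site.chrom, end + 1, end + flank)
    elif site.sv_type == "INS":
        sv_seq = _nearest_member_alt(site)
        downstream = fetch_subsequence(genome, site.chrom, pos + 1, pos + flank)
    else:  # BND: no resolved variant sequence
        sv_seq = ""
        downstream = fetch_subsequence(genome, site.chrom, pos + 1, pos + flank)
    return site.with_sequences(sv_seq, upstream, downstream)


def _nearest_member_alt(site: MergedSite) -> str:
    candidates = [m for m in site.members if m.alt_seq]
    if not candidates:
        return ""
    best = min(candidates, key=lambda m: (abs(m.pos - site.pos), m.sample_id))
    return best.alt_seq


def attach_all(cohort, genome: ReferenceGenome, flank: int = 300):
    """Attach sequences to every site of a cohort, in place-order."""
    cohort.sites = [attach_sequences(s, genome, flank) for s in cohort.sites]
    return cohort


def upstream_region(gene: GeneFeature, track: GeneTrack, U: int = 2000) -> tuple[int, int]:
    """Strandless upstream window of a gene, 0-based half-open.

    ``[max(start - U, end of nearest preceding gene, 0), start)`` — at most
    U bp long, possibly empty when a neighboring gene abuts or overlaps.
    """
    lower = max(gene.start - U, 0)
    for other in track.on_chrom(gene.chrom):
        if other is gene or (other.gene_id == gene.gene_id and other.start == gene.start):
            continue
        if other.start < gene.start:
            lower = max(lower, min(other.end, gene.start))
    return lower, gene.start


def _site_interval(site: MergedSite) -> tuple[int, int]:
    # 0-based half-open footprint on the reference: the spanned segment for
    # length-resolved types, the 1-bp anchor for insertions and breakends
    if site.sv_type in ("DEL", "INV", "DUP") and site.length is not None:
        return site.pos - 1, site.end
    return site.pos - 1, site.pos


def _overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def classify_site(site: MergedSite, track: GeneTrack, U: int = 2000) -> list[GeneContext]:
    """Gene contexts of one site: genic hits, then upstream-region hits.

    Genic excludes upstream for the same gene.  Returns an empty list for
    sites that touch neither a gene body nor an upstream window.
    """
    interval = _site_interval(site)
    genes = track.on_chrom(site.chrom)
    prior = [g for g in genes if g.end <= interval[0]]
    later = [g for g in genes if g.start >= interval[1]]
    upstream_neighbor = max(prior, key=lambda g: (g.end, g.start)).gene_id if prior else None
    downstream_neighbor = min(later, key=lambda g: (g.start, g.end)).gene_id if later else None
    contexts: list[GeneContext] = []
    for gene in genes:
        if _overlaps(interval, (gene.start, gene.end)):
            region = "genic"
        elif _overlaps(interval, upstream_region(gene, track, U)):
            region = "upstream"
        else:
            continue
        contexts.append(
            GeneContext(
                gene_id=gene.gene_id,
                region=region,
                upstream_gene_id=upstream_neighbor,
                downstream_gene_id=downstream_neighbor,
                annotation=gene.annotation,
            )
        )
    return contexts
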