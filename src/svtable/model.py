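"""Domain types shared across the package.

Coordinate conventions
----------------------
SV calls and merged sites use 1-based positions, as in VCF.  Gene features
use 0-based half-open intervals, as in BED; the conversion happens exactly
once, when a gene track is read.  All interval logic downstream of the
readers sticks to the convention of the type it operates on.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "SV_TYPES",
    "GENOTYPES",
    "SVCall",
    "ReferenceGenome",
    "GeneFeature",
    "GeneTrack",
    "MergedSite",
    "Cohort",
]

#: SV type taxonomy of long-read callers: insertions, deletions, inversions,
#: duplications, and breakends (breakpoints of unresolved type/length).
SV_TYPES = ("INS", "DEL", "INV", "DUP", "BND")

#: The three genotype states of a biallelic SV relative to the reference:
#: no SV, heterozygous SV, homozygous SV.
GENOTYPES = ("0/0", "0/1", "1/1")


@dataclass(frozen=True)
class SVCall:
    """One structural-variant observation in one sample.

    ``pos`` is the 1-based anchor position.  ``length`` is always stored
    non-negative (callers emit negative SVLEN for deletions); it is ``None``
    for breakends, whose extent is unresolved.  ``alt_seq`` carries the
    inserted sequence for insertions.
    """

    sample_id: str
    chrom: str
    pos: int
    sv_type: str
    length: int | None
    end: int
    genotype: str
    precise: bool = True
    alt_seq: str | None = None

    def __post_init__(self) -> None:
        if self.sv_type not in SV_TYPES:
            raise ValueError(f"unknown SV type {self.sv_type!r}")
        if self.genotype not in GENOTYPES:
            raise ValueError(f"unknown genotype {self.genotype!r}")
        if self.sv_type != "BND":
            if self.length is None:
                raise ValueError(f"{self.sv_type} call requires a length")
            if self.length < 0:
                raise ValueError("SV length must be non-negative")


class ReferenceGenome:
    """Named contigs with in-memory sequences.

    Contig order is preserved; names must be unique and sequences are stored
    uppercase over the alphabet {A, C, G, T, N}.
    """

    def __init__(self, contigs: list[tuple[str, str]]):
        self._seqs: dict[str, str] = {}
        self._order: list[str] = []
        for name, seq in contigs:
            if not name:
                raise ValueError("empty contig name")
            if name in self._seqs:
                raise ValueError(f"duplicate contig name {name!r}")
            seq = seq.upper()
            bad = set(seq) - set("ACGTN")
            if bad:
                raise ValueError(
                    f"contig {name!r} contains non-nucleotide characters {sorted(bad)}"
                )
            self._seqs[name] = seq
            self._order.append(name)
        if not self._order:
            raise ValueError("reference genome has no contigs")

    @property
    def contig_names(self) -> list[str]:
        return list(self._order)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def sequence(self, chrom: str) -> str:
        if chrom not in self._seqs:
            raise KeyError(f"unknown contig {chrom!r}")
        return self._seqs[chrom]

    def length(self, chrom: str) -> int:
        return len(self.sequence(chrom))

    def total_length(self) -> int:
        return sum(len(s) for s in self._seqs.values())

    def __repr__(self) -> str:  # pragma: no cover
        parts = ", ".join(f"{n}:{len(s)}bp" for n, s in self._seqs.items())
        return f"ReferenceGenome({parts})"


@dataclass(frozen=True)
class GeneFeature:
    """A gene interval (0-based half-open) with free-text annotation fields."""

    chrom: str
    gene_id: str
    start: int
    end: int
    annotation: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("empty gene id")
        if self.start >= self.end:
            raise ValueError(
                f"gene {self.gene_id}: start {self.start} >= end {self.end}"
            )


@dataclass
class GeneTrack:
    """Gene features kept sorted by (chrom, start)."""

    features: list[GeneFeature] = field(default_factory=list)
    annotation_headers: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.features = sorted(self.features, key=lambda f: (f.chrom, f.start, f.end))

    def on_chrom(self, chrom: str) -> list[GeneFeature]:
        return [f for f in self.features if f.chrom == chrom]

    def __len__(self) -> int:
        return len(self.features)


@dataclass
class MergedSite:
    """One reference position housing the same SV across the cohort.

    ``genotypes`` covers every cohort sample (0/0 for samples with no member
    call).  ``members`` keeps every constituent per-sample call so that no
    input call is lost in the merge; dispersion statistics (``stdev_pos``,
    ``stdev_len``) are population standard deviations over the members.
    Sequence fields are empty until filled by the flank annotator.
    """

    chrom: str
    pos: int
    sv_type: str
    length: int | None
    end: int
    stdev_pos: float
    stdev_len: float
    precise: bool
    genotypes: dict[str, str]
    members: list[SVCall] = field(default_factory=list)
    sv_seq: str | None = None
    upstream_seq: str | None = None
    downstream_seq: str | None = None

    @property
    def key(self) -> str:
        """Stable site identifier, e.g. ``chr1-12345-DEL``."""
        return f"{self.chrom}-{self.pos}-{self.sv_type}"

    def genotype_set(self) -> set[str]:
        return set(self.genotypes.values())

    def has_sequences(self) -> bool:
        return (
            self.sv_seq is not None
            and self.upstream_seq is not None
            and self.downstream_seq is not None
        )

    def with_sequences(self, sv_seq: str, upstream: str, downstream: str) -> "MergedSite":
        return replace(self, sv_seq=sv_seq, upstream_seq=upstream, downstream_seq=downstream)


@dataclass
class Cohort:
    """A merged multi-sample call set: ordered samples and sorted sites."""

    samples: list[str]
    sites: list[MergedSite]
    merge_constant_M: float = 250.0

    def __post_init__(self) -> None:
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample ids in cohort")
        self.sites = sorted(self.sites, key=lambda s: (s.chrom, s.pos, s.sv_type))

    def __len__(self) -> int:
        return len(self.sites)
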