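"""Seeded synthetic cohorts: reference, gene track, planted SVs, VCFs.

The simulator emulates the upstream half of a long-read SV workflow so the
integration machinery is testable without reads, an aligner, or a caller:
a random reference genome, a cohort of samples sharing planted SVs at known
positions with known genotypes, and one caller-dialect VCF per sample.
Positional/length jitter and an imprecision rate emulate the discrepancies
real call sets show between samples (reference/sample divergence,
sequencing error, caller heuristics).

Planted sites are spaced at least ``min_spacing`` apart, and the planter
enforces ``min_spacing > M * sqrt(max_length)`` so that distinct planted
sites can never co-cluster under the default merge tolerance; recovery of
the truth is then a strict property, not a statistical one.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import write_sample_vcf
from .model import Cohort, GeneFeature, GeneTrack, ReferenceGenome, SVCall

__all__ = [
    "TruthSite",
    "TruthTable",
    "RecoveryScore",
    "simulate_reference",
    "simulate_gene_track",
    "plant_cohort",
    "emit_vcfs",
    "score_recovery",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")

#: SV-type mix modelled on long-read cohort call sets, where deletions and
#: insertions dominate and inversions/duplications are rare.
DEFAULT_TYPE_MIX = {"DEL": 0.48, "INS": 0.42, "INV": 0.05, "DUP": 0.05}

#: Per-sample genotype frequencies at a planted site; heterozygous SVs
#: outnumber homozygous ones, as is typical for outcrossing cohorts.
DEFAULT_GENOTYPE_FREQS = {"0/0": 0.45, "0/1": 0.35, "1/1": 0.20}


@dataclass(frozen=True)
class TruthSite:
    chrom: str
    pos: int
    sv_type: str
    length: int
    genotypes: dict[str, str]
    alt_seq: str | None = None


@dataclass
class TruthTable:
    samples: list[str]
    sites: list[TruthSite] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.sites)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode()


def simulate_reference(
    n_chrom: int, chrom_length: int, seed: int
) -> ReferenceGenome:
    """Uniform-random reference genome; deterministic for a fixed seed."""
    if chrom_length <= 0:
        raise ValueError("chrom_length must be positive")
    rng = np.random.default_rng(seed)
    contigs = [(f"chr{i + 1}", _random_seq(rng, chrom_length)) for i in range(n_chrom)]
    return ReferenceGenome(contigs)


def write_reference_fasta(genome: ReferenceGenome, path: str | os.PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in genome.contig_names:
            fh.write(f">{name}\n")
            seq = genome.sequence(name)
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def simulate_gene_track(
    genome: ReferenceGenome,
    n_genes: int,
    length_range: tuple[int, int] = (500, 3000),
    min_gap: int = 200,
    seed: int = 0,
) -> GeneTrack:
    """Non-overlapping genes per chromosome with gaps >= min_gap.

    Gap lengths are drawn from min_gap up to ~6 kb, so some fall under the
    2,000 bp upstream window and exercise its truncation rule.
    """
    rng = np.random.default_rng(seed)
    n_chrom = len(genome.contig_names)
    features: list[GeneFeature] = []
    per_chrom = [n_genes // n_chrom + (1 if i < n_genes % n_chrom else 0) for i in range(n_chrom)]
    idx = 0
    for chrom, count in zip(genome.contig_names, per_chrom):
        cursor = int(rng.integers(0, 1000))
        clen = genome.length(chrom)
        for _ in range(count):
            glen = int(rng.integers(length_range[0], length_range[1] + 1))
            gap = int(rng.integers(min_gap, max(min_gap + 1, 6000)))
            start = cursor + gap
            end = start + glen
            if end > clen:
                raise ValueError(
                    f"cannot pack {count} genes of up to {length_range[1]} bp on {chrom}"
                )
            idx += 1
            features.append(
                GeneFeature(chrom, f"g{idx:04d}", start, end, (f"annotation for g{idx:04d}",))
            )
            cursor = end
    return GeneTrack(features=features, annotation_headers=("description",))


def write_gene_bed(track: GeneTrack, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tgene_id\tstart\tend\t" + "\t".join(track.annotation_headers) + "\n")
        for f in track.features:
            fh.write("\t".join([f.chrom, f.gene_id, str(f.start), str(f.end), *f.annotation]) + "\n")


def plant_cohort(
    genome: ReferenceGenome,
    n_sites: int = 50,
    type_mix: dict[str, float] | None = None,
    length_range: tuple[int, int] = (50, 1000),
    n_samples: int = 5,
    genotype_freqs: dict[str, float] | None = None,
    min_spacing: int = 50000,
    seed: int = 0,
    M: float = 250.0,
) -> TruthTable:
    """Plant ``n_sites`` SVs with per-sample genotypes drawn independently.

    Every site is forced to have at least one non-0/0 sample (an SV nobody
    carries would be undetectable by construction).  Raises when the spacing
    guard ``min_spacing > M * sqrt(max_length)`` fails or the genome cannot
    hold the sites at that spacing.
    """
    type_mix = dict(type_mix or DEFAULT_TYPE_MIX)
    genotype_freqs = dict(genotype_freqs or DEFAULT_GENOTYPE_FREQS)
    max_len = length_range[1]
    if min_spacing <= M * np.sqrt(max_len):
        raise ValueError(
            f"min_spacing {min_spacing} must exceed M*sqrt(max_length) = "
            f"{M * np.sqrt(max_len):.0f} so planted sites cannot co-cluster"
        )
    rng = np.random.default_rng(seed)
    samples = [f"S{i + 1}" for i in range(n_samples)]
    margin = max_len + 500  # keep SVs clear of contig ends
    capacity = []
    for chrom in genome.contig_names:
        span = genome.length(chrom) - 2 * margin
        capacity.append(max(span // min_spacing + 1, 0) if span > 0 else 0)
    if sum(capacity) < n_sites:
        raise ValueError(
            f"genome can hold at most {sum(capacity)} sites at spacing {min_spacing}"
        )
    # allocate sites to chromosomes round-robin up to capacity
    alloc = [0] * len(capacity)
    i = 0
    remaining = n_sites
    while remaining:
        c = i % len(capacity)
        if alloc[c] < capacity[c]:
            alloc[c] += 1
            remaining -= 1
        i += 1
    types = list(type_mix)
    probs = np.array([type_mix[t] for t in types], dtype=float)
    probs = probs / probs.sum()
    gts = list(genotype_freqs)
    gt_probs = np.array([genotype_freqs[g] for g in gts], dtype=float)
    gt_probs = gt_probs / gt_probs.sum()
    sites: list[TruthSite] = []
    for chrom, count in zip(genome.contig_names, alloc):
        if count == 0:
            continue
        span = genome.length(chrom) - 2 * margin
        slack = span - (count - 1) * min_spacing
        offsets = np.sort(rng.integers(0, slack + 1, size=count))
        positions = margin + offsets + min_spacing * np.arange(count)
        for pos in positions:
            sv_type = str(rng.choice(types, p=probs))
            length = int(rng.integers(length_range[0], length_range[1] + 1))
            genotypes = {s: str(rng.choice(gts, p=gt_probs)) for s in samples}
            if all(g == "0/0" for g in genotypes.values()):
                forced = samples[int(rng.integers(0, n_samples))]
                genotypes[forced] = str(rng.choice(["0/1", "1/1"]))
            alt_seq = _random_seq(rng, length) if sv_type == "INS" else None
            sites.append(TruthSite(chrom, int(pos), sv_type, length, genotypes, alt_seq))
    sites.sort(key=lambda s: (s.chrom, s.pos))
    return TruthTable(samples=samples, sites=sites)


def _jittered_alt(alt_seq: str, new_len: int) -> str:
    if new_len <= len(alt_seq):
        return alt_seq[:new_len]
    reps = -(-new_len // len(alt_seq))
    return (alt_seq * reps)[:new_len]


def truth_calls(
    truth: TruthTable,
    pos_jitter_sd: float = 0.0,
    len_jitter_sd: float = 0.0,
    imprecise_rate: float = 0.0,
    seed: int = 0,
    min_length: int = 50,
) -> dict[str, list[SVCall]]:
    """Per-sample call sets derived from the truth, with optional jitter."""
    if not 0 <= imprecise_rate <= 1:
        raise ValueError("imprecise_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    callsets: dict[str, list[SVCall]] = {s: [] for s in truth.samples}
    for site in truth.sites:
        for sample in truth.samples:
            gt = site.genotypes[sample]
            if gt == "0/0":
                continue
            pos = site.pos + int(round(rng.normal(0, pos_jitter_sd))) if pos_jitter_sd else site.pos
            pos = max(pos, 2)
            length = site.length
            if len_jitter_sd:
                length = max(length + int(round(rng.normal(0, len_jitter_sd))), min_length)
            precise = not (imprecise_rate and rng.random() < imprecise_rate)
            alt_seq = _jittered_alt(site.alt_seq, length) if site.sv_type == "INS" else None
            end = pos if site.sv_type == "INS" else pos + length
            callsets[sample].append(
                SVCall(
                    sample_id=sample,
                    chrom=site.chrom,
                    pos=pos,
                    sv_type=site.sv_type,
                    length=length,
                    end=end,
                    genotype=gt,
                    precise=precise,
                    alt_seq=alt_seq,
                )
            )
    return callsets


def emit_vcfs(
    truth: TruthTable,
    genome: ReferenceGenome,
    out_dir: str | os.PathLike,
    pos_jitter_sd: float = 0.0,
    len_jitter_sd: float = 0.0,
    imprecise_rate: float = 0.0,
    seed: int = 0,
) -> dict[str, Path]:
    """Write one caller-dialect VCF per sample; returns sample -> path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    callsets = truth_calls(truth, pos_jitter_sd, len_jitter_sd, imprecise_rate, seed)
    contig_lengths = {c: genome.length(c) for c in genome.contig_names}
    paths: dict[str, Path] = {}
    for sample, calls in callsets.items():
        path = out_dir / f"{sample}.vcf"
        write_sample_vcf(calls, path, contig_lengths, sample_name=sample)
        paths[sample] = path
    return paths


def write_truth_tsv(truth: TruthTable, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tsv_type\tlength\t" + "\t".join(truth.samples) + "\n")
        for s in truth.sites:
            gts = [s.genotypes[x] for x in truth.samples]
            fh.write("\t".join([s.chrom, str(s.pos), s.sv_type, str(s.length), *gts]) + "\n")


@dataclass
class RecoveryScore:
    recall: float
    precision: float
    genotype_accuracy: float
    n_matched: int
    precision_undefined: bool = False


def score_recovery(truth: TruthTable, cohort: Cohort, match_window: int = 1000) -> RecoveryScore:
    """Compare a merged cohort against the planted truth.

    A merged site matches a truth site of the same chromosome and type when
    their positions differ by at most ``match_window`` bp; matching is
    greedy one-to-one by distance.  Genotype accuracy is measured over
    matched sites x samples.  An empty cohort yields recall 0 and — with
    nothing to be wrong about — precision reported as 1.0, flagged.
    """
    pairs = []
    for ti, tsite in enumerate(truth.sites):
        for mi, msite in enumerate(cohort.sites):
            if msite.chrom == tsite.chrom and msite.sv_type == tsite.sv_type:
                d = abs(msite.pos - tsite.pos)
                if d <= match_window:
                    pairs.append((d, ti, mi))
    pairs.sort()
    matched_t: set[int] = set()
    matched_m: set[int] = set()
    matches: list[tuple[int, int]] = []
    for _, ti, mi in pairs:
        if ti in matched_t or mi in matched_m:
            continue
        matched_t.add(ti)
        matched_m.add(mi)
        matches.append((ti, mi))
    recall = len(matches) / len(truth.sites) if truth.sites else 1.0
    if cohort.sites:
        precision = len(matches) / len(cohort.sites)
        undefined = False
    else:
        precision, undefined = 1.0, True
    n_cells = n_correct = 0
    for ti, mi in matches:
        tsite, msite = truth.sites[ti], cohort.sites[mi]
        for sample in truth.samples:
            n_cells += 1
            if msite.genotypes.get(sample, "0/0") == tsite.genotypes[sample]:
                n_correct += 1
    accuracy = n_correct / n_cells if n_cells else 1.0
    return RecoveryScore(
        recall=recall,
        precision=precision,
        genotype_accuracy=accuracy,
        n_matched=len(matches),
        precision_undefined=undefined,
    )
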