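"""Readers and writers for the three input formats.

FASTA goes through Biopython and SV VCFs through pysam; the BED-like gene
track is line-parsed so malformed rows can be skipped individually with a
warning.  The VCF dialect is the one long-read SV callers emit:
INFO keys ``SVTYPE``/``SVLEN``/``END``, flag-style ``PRECISE``/``IMPRECISE``,
and a single ``GT`` sample column.  Deletion records commonly carry negative
SVLEN; lengths are stored as absolute values.  For insertions the ALT field
carries the inserted sequence itself (``len(ALT) == SVLEN``).
"""

from __future__ import annotations

import logging
import os
from pathlib import Path

import pysam
from Bio import SeqIO

from .model import GeneFeature, GeneTrack, ReferenceGenome, SVCall

log = logging.getLogger(__name__)

__all__ = [
    "read_reference",
    "fetch_subsequence",
    "read_sample_calls",
    "read_gene_track",
    "write_sample_vcf",
    "write_merged_vcf",
]


def read_reference(path: str | os.PathLike) -> ReferenceGenome:
    """Read a (multi-record) FASTA file into a :class:`ReferenceGenome`.

    Record order is preserved and lowercase bases are uppercased.  Duplicate
    contig names and empty files are reported as errors.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"reference FASTA not found: {path}")
    contigs = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    if not contigs:
        raise ValueError(f"no FASTA records in {path}")
    return ReferenceGenome(contigs)


def fetch_subsequence(genome: ReferenceGenome, chrom: str, start: int, end: int) -> str:
    """Return reference bases ``start..end`` (1-based, inclusive).

    Requests running past a contig boundary are truncated to the valid
    range; a start beyond the contig (or an empty range) yields ``""``.
    Unknown contigs raise ``KeyError``.
    """
    seq = genome.sequence(chrom)
    if end < start:
        return ""
    lo = max(start, 1)
    hi = min(end, len(seq))
    if lo > len(seq) or hi < 1:
        return ""
    return seq[lo - 1 : hi]


def _info_scalar(value):
    # pysam returns tuples for Number=. INFO fields
    if isinstance(value, (tuple, list)):
        return value[0] if value else None
    return value


def _genotype_from_gt(gt: tuple | None) -> str:
    if gt is None:
        return "0/0"
    alleles = [a for a in gt if a is not None]
    if len(alleles) < len(gt or ()) or not alleles:
        # missing (./.) normalized to 0/0: the table's genotype vocabulary
        # has exactly three states
        log.warning("missing genotype ./." " normalized to 0/0")
        return "0/0"
    n_alt = sum(1 for a in alleles if a and a > 0)
    if len(alleles) == 1:  # haploid-style call
        return "1/1" if n_alt else "0/0"
    if n_alt == 0:
        return "0/0"
    if n_alt == 1:
        return "0/1"
    return "1/1"


def read_sample_calls(
    path: str | os.PathLike,
    sample_id: str,
    min_length: int = 50,
) -> list[SVCall]:
    """Read one sample's SV calls from a caller-style VCF.

    Records of non-BND type with length below ``min_length`` (default 50 bp,
    the conventional lower bound for a structural variant) are dropped;
    records lacking SVTYPE are skipped with a warning.  The drop counts are
    logged.  An absent PRECISE/IMPRECISE flag counts as precise, so that
    only positively flagged records can be removed downstream.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"VCF not found: {path}")
    calls: list[SVCall] = []
    n_short = n_malformed = 0
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            svtype = _info_scalar(rec.info.get("SVTYPE"))
            if svtype is None:
                n_malformed += 1
                log.warning("record %s:%s lacks SVTYPE; skipped", rec.chrom, rec.pos)
                continue
            svtype = str(svtype)
            precise = not rec.info.get("IMPRECISE", False)
            svlen = _info_scalar(rec.info.get("SVLEN"))
            alt = rec.alts[0] if rec.alts else None
            alt_seq = None
            if svtype == "BND":
                length = None
                end = rec.pos
            else:
                if svlen is not None:
                    length = abs(int(svlen))
                elif svtype != "INS":
                    length = max(rec.stop - rec.pos, 0)
                else:
                    length = len(alt) if alt and alt[0] != "<" else 0
                if length < min_length:
                    n_short += 1
                    continue
                end = rec.pos if svtype == "INS" else rec.pos + length
                if svtype == "INS" and alt and not alt.startswith("<"):
                    alt_seq = alt.upper()
            gt = None
            if rec.samples:
                gt = rec.samples[0].get("GT")
            genotype = _genotype_from_gt(gt)
            calls.append(
                SVCall(
                    sample_id=sample_id,
                    chrom=rec.chrom,
                    pos=rec.pos,
                    sv_type=svtype,
                    length=length,
                    end=end,
                    genotype=genotype,
                    precise=precise,
                    alt_seq=alt_seq,
                )
            )
    if n_short or n_malformed:
        log.info(
            "%s: dropped %d records below %d bp and %d malformed records",
            sample_id, n_short, min_length, n_malformed,
        )
    return calls


def read_gene_track(path: str | os.PathLike) -> GeneTrack:
    """Read a BED-like gene track: chrom, gene id, start, end, annotations...

    Coordinates are 0-based half-open per the BED standard.  Rows with fewer
    than four columns or with start >= end are rejected with a warning.
    An optional header line starting with ``#`` names the annotation columns.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"gene track not found: {path}")
    annotation_headers: tuple[str, ...] = ()
    features: list[GeneFeature] = []
    with open(path) as fh:
        first = True
        for raw in fh:
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if first:
                    cols = line.lstrip("#").split("\t")
                    if len(cols) > 4:
                        annotation_headers = tuple(cols[4:])
                first = False
                continue
            first = False
            cols = line.split("\t")
            if len(cols) < 4:
                log.warning("gene-track row with <4 columns rejected: %r", line)
                continue
            try:
                start, end = int(cols[2]), int(cols[3])
            except ValueError:
                log.warning("gene-track row with non-integer coordinates rejected: %r", line)
                continue
            if start >= end:
                log.warning("gene %s: start >= end, row rejected", cols[1])
                continue
            features.append(
                GeneFeature(
                    chrom=cols[0],
                    gene_id=cols[1],
                    start=start,
                    end=end,
                    annotation=tuple(cols[4:]),
                )
            )
    if annotation_headers == () and features:
        n_anno = max(len(f.annotation) for f in features)
        annotation_headers = tuple(f"annotation_{i + 1}" for i in range(n_anno))
    return GeneTrack(features=features, annotation_headers=annotation_headers)


# ---------------------------------------------------------------------------
# VCF writing (caller dialect)

_VCF_INFO_HEADER = """\
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">
##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Length of structural variant">
##INFO=<ID=END,Number=1,Type=Integer,Description="End position of structural variant">
##INFO=<ID=PRECISE,Number=0,Type=Flag,Description="Precise breakpoints">
##INFO=<ID=IMPRECISE,Number=0,Type=Flag,Description="Imprecise breakpoints">
##INFO=<ID=STDEV_POS,Number=1,Type=Float,Description="Standard deviation of member positions">
##INFO=<ID=STDEV_LEN,Number=1,Type=Float,Description="Standard deviation of member lengths">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""


def _vcf_header(contig_lengths: dict[str, int], sample_names: list[str]) -> str:
    lines = ["##fileformat=VCFv4.2"]
    for name, length in contig_lengths.items():
        lines.append(f"##contig=<ID={name},length={length}>")
    lines.append(_VCF_INFO_HEADER.rstrip("\n"))
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(sample_names)
    )
    return "\n".join(lines) + "\n"


def _call_record(call: SVCall, idx: int) -> str:
    precise = "PRECISE" if call.precise else "IMPRECISE"
    if call.sv_type == "BND":
        alt = f"N[{call.chrom}:{call.end}["
        info = f"{precise};SVTYPE=BND"
    elif call.sv_type == "INS":
        alt = call.alt_seq if call.alt_seq else "<INS>"
        info = f"{precise};SVTYPE=INS;SVLEN={call.length};END={call.end}"
    else:
        alt = f"<{call.sv_type}>"
        svlen = -call.length if call.sv_type == "DEL" else call.length
        info = f"{precise};SVTYPE={call.sv_type};SVLEN={svlen};END={call.end}"
    return "\t".join(
        [
            call.chrom,
            str(call.pos),
            f"sv{idx}",
            "N",
            alt,
            ".",
            "PASS",
            info,
            "GT",
            call.genotype,
        ]
    )


def write_sample_vcf(
    calls: list[SVCall],
    path: str | os.PathLike,
    contig_lengths: dict[str, int],
    sample_name: str = "SAMPLE",
) -> None:
    """Write one sample's calls in the caller dialect (round-trippable)."""
    ordered = sorted(calls, key=lambda c: (c.chrom, c.pos, c.sv_type))
    with open(path, "w") as fh:
        fh.write(_vcf_header(contig_lengths, [sample_name]))
        for i, call in enumerate(ordered):
            fh.write(_call_record(call, i) + "\n")


def write_merged_vcf(cohort, path: str | os.PathLike, contig_lengths: dict[str, int]) -> None:
    """Export a merged cohort as a multi-sample VCF (interoperability).

    INFO carries SVTYPE/SVLEN/END plus the cross-sample dispersion statistics
    STDEV_POS and STDEV_LEN; one GT column per cohort sample.
    """
    with open(path, "w") as fh:
        fh.write(_vcf_header(contig_lengths, list(cohort.samples)))
        for i, site in enumerate(cohort.sites):
            precise = "PRECISE" if site.precise else "IMPRECISE"
            parts = [f"{precise};SVTYPE={site.sv_type}"]
            if site.length is not None:
                svlen = -site.length if site.sv_type == "DEL" else site.length
                parts.append(f"SVLEN={svlen}")
            parts.append(f"END={site.end}")
            parts.append(f"STDEV_POS={site.stdev_pos:.6g};STDEV_LEN={site.stdev_len:.6g}")
            if site.sv_type == "INS" and site.sv_seq:
                alt = site.sv_seq
            elif site.sv_type == "BND":
                alt = f"N[{site.chrom}:{site.end}["
            else:
                alt = f"<{site.sv_type}>"
            gts = [site.genotypes.get(s, "0/0") for s in cohort.samples]
            fh.write(
                "\t".join(
                    [site.chrom, str(site.pos), f"site{i}", "N", alt, ".", "PASS",
                     ";".join(parts), "GT"] + gts
                )
                + "\n"
            )


def validate_gene_track(track: GeneTrack, genome: ReferenceGenome) -> None:
    """Check that every gene chromosome resolves against the genome."""
    missing = sorted({f.chrom for f in track.features if f.chrom not in genome})
    if missing:
        raise ValueError(f"gene-track chromosomes absent from reference: {missing}")
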