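"""The two tabular output formats and their spreadsheet export.

Site table (one row per merged site)
    position ("chrom-pos" with a hyphen separator), SV type, reliability
    (PRECISE/IMPRECISE), length, STDEV_POS, STDEV_LEN, one genotype column
    per sample in manifest order, then the SV sequence and its upstream and
    downstream reference flanks.

Gene table (one row per (site, gene context))
    the site-table columns plus gene name, upstream neighboring gene name,
    downstream neighboring gene name, region label (genic/upstream), and
    the pass-through annotation columns of the input gene track.  Only
    sites with at least one gene context appear.

Both are plain UTF-8 TSV: tab separator, no quoting, "\\n" line endings, a
single header line.  Undefined lengths serialize as the empty string (never
0, which would corrupt length histograms on re-read).  Output is
byte-deterministic for a given cohort.
"""

from __future__ import annotations

import os
from pathlib import Path

import pandas as pd

from .annotate import classify_site
from .model import Cohort, GeneTrack

__all__ = [
    "site_table",
    "gene_table",
    "write_site_table",
    "write_gene_table",
    "read_site_table",
    "export_spreadsheet",
]

_SITE_COLUMNS = ["position", "sv_type", "reliability", "length", "stdev_pos", "stdev_len"]
_SEQ_COLUMNS = ["sv_seq", "upstream_seq", "downstream_seq"]
_GENE_COLUMNS = ["gene", "upstream_gene", "downstream_gene", "region"]


def _fmt_stdev(v: float) -> str:
    return format(v, ".6g")


def _site_row(site, samples: list[str]) -> list[str]:
    if not site.has_sequences():
        raise ValueError(
            f"site {site.key} has no attached sequences; run the flank annotator first"
        )
    return (
        [
            f"{site.chrom}-{site.pos}",
            site.sv_type,
            "PRECISE" if site.precise else "IMPRECISE",
            "" if site.length is None else str(site.length),
            _fmt_stdev(site.stdev_pos),
            _fmt_stdev(site.stdev_len),
        ]
        + [site.genotypes.get(s, "0/0") for s in samples]
        + [site.sv_seq, site.upstream_seq, site.downstream_seq]
    )


def site_table(cohort: Cohort) -> pd.DataFrame:
    """Build the site table as a DataFrame (all cells text)."""
    header = _SITE_COLUMNS + list(cohort.samples) + _SEQ_COLUMNS
    rows = [_site_row(s, cohort.samples) for s in cohort.sites]
    return pd.DataFrame(rows, columns=header, dtype=str)


def gene_table(cohort: Cohort, track: GeneTrack, U: int = 2000) -> pd.DataFrame:
    """Build the gene table: one row per (site, gene context)."""
    header = (
        _SITE_COLUMNS
        + list(cohort.samples)
        + _SEQ_COLUMNS
        + _GENE_COLUMNS
        + list(track.annotation_headers)
    )
    n_anno = len(track.annotation_headers)
    rows = []
    for site in cohort.sites:
        base = None
        for ctx in classify_site(site, track, U):
            if base is None:
                base = _site_row(site, cohort.samples)
            anno = list(ctx.annotation[:n_anno]) + [""] * (n_anno - len(ctx.annotation))
            rows.append(
                base
                + [ctx.gene_id, ctx.upstream_gene_id or "", ctx.downstream_gene_id or "", ctx.region]
                + anno
            )
    return pd.DataFrame(rows, columns=header, dtype=str)


def _write_tsv(frame: pd.DataFrame, path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(frame.columns) + "\n")
        for row in frame.itertuples(index=False):
            fh.write("\t".join(row) + "\n")


def write_site_table(cohort: Cohort, path: str | os.PathLike) -> pd.DataFrame:
    """Write the site table as TSV; returns the DataFrame written."""
    frame = site_table(cohort)
    _write_tsv(frame, path)
    return frame


def write_gene_table(
    cohort: Cohort, track: GeneTrack, path: str | os.PathLike, U: int = 2000
) -> pd.DataFrame:
    """Write the gene table as TSV; returns the DataFrame written."""
    frame = gene_table(cohort, track, U)
    _write_tsv(frame, path)
    return frame


def read_site_table(path: str | os.PathLike) -> pd.DataFrame:
    """Re-read a site table written by :func:`write_site_table`."""
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def export_spreadsheet(table: pd.DataFrame, path: str | os.PathLike) -> None:
    """Cell-for-cell export of a table to an .xlsx workbook."""
    from openpyxl import Workbook

    path = Path(path)
    wb = Workbook()
    ws = wb.active
    ws.title = "svtable"
    ws.append(list(table.columns))
    for row in table.itertuples(index=False):
        ws.append(list(row))
    wb.save(str(path))
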