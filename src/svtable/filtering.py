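"""Confidence filtering of merged sites.

A merged site is removed when any of these holds:

1. the standard deviation of member positions (STDEV_POS) is at or above
   the threshold (default 1 bp),
2. the standard deviation of member lengths (STDEV_LEN) is at or above
   the threshold (default 1 bp),
3. the site is flagged imprecise (optional, on by default),
4. its representative length falls below the minimum SV length (default
   50 bp) — re-checked at site level because the merged median can shift.

Thresholds 1–2 use ">=" (a dispersion of exactly one is already out).  Each
removed site is attributed to the first failing rule in the order above, so
the report is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import MergedSite

__all__ = ["FilterReport", "filter_sites"]


@dataclass
class FilterReport:
    kept: int = 0
    removed_stdev_pos: int = 0
    removed_stdev_len: int = 0
    removed_imprecise: int = 0
    removed_short: int = 0

    @property
    def total(self) -> int:
        return (
            self.kept
            + self.removed_stdev_pos
            + self.removed_stdev_len
            + self.removed_imprecise
            + self.removed_short
        )


def filter_sites(
    sites: list[MergedSite],
    max_stdev_pos: float = 1.0,
    max_stdev_len: float = 1.0,
    drop_imprecise: bool = True,
    min_length: int = 50,
) -> tuple[list[MergedSite], FilterReport]:
    """Apply the confidence filter; returns (surviving sites, report).

    Survivor order is preserved.  Raising either dispersion threshold never
    decreases the kept count, and the filter is idempotent.
    """
    if max_stdev_pos < 0 or max_stdev_len < 0 or min_length < 0:
        raise ValueError("thresholds must be non-negative")
    kept: list[MergedSite] = []
    report = FilterReport()
    for site in sites:
        if site.stdev_pos >= max_stdev_pos:
            report.removed_stdev_pos += 1
        elif site.stdev_len >= max_stdev_len:
            report.removed_stdev_len += 1
        elif drop_imprecise and not site.precise:
            report.removed_imprecise += 1
        elif site.sv_type != "BND" and site.length is not None and site.length < min_length:
            report.removed_short += 1
        else:
            kept.append(site)
    report.kept = len(kept)
    return kept, report
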