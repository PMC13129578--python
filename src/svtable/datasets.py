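"""Published wet-lab validation data for the citrus marker study.

Nine co-dominant indel markers (one per chromosome of the Satsuma mandarin
reference) were designed from merged SV sites and scored on 14 citrus
cultivars twice: computationally from the merged long-read call set
(``PIPELINE_GENOTYPES``) and by PCR + gel electrophoresis
(``ELECTROPHORESIS_GENOTYPES``).  The grids are markers x cultivars with
genotypes in {0/0, 0/1, 1/1}; feeding both to
:func:`svtable.stats.genotype_concordance` reproduces the published
per-marker consistency rates and their 94.4% mean.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["validation_marker_grids", "CULTIVARS", "MARKERS"]

MARKERS = [f"marker{i}" for i in range(1, 10)]

CULTIVARS = [
    "Satsuma mandarin",
    "Kunenbo",
    "Kishu mikan",
    "Mediterranean mandarin",
    "Ponkan",
    "Dancy tangerine",
    "King mandarin",
    "Murcott tangor",
    "Iyokan",
    "Sweet orange",
    "Hassaku",
    "Grapefruit",
    "Pummelo",
    "Hyuganatsu",
]

# rows: cultivars (order above); columns: marker1..marker9
_PIPELINE = """
0/0 0/0 0/0 0/0 0/1 0/0 0/1 0/0 0/0
0/1 0/0 0/0 0/1 0/1 0/0 0/1 0/1 0/1
0/1 0/0 0/0 0/1 0/0 0/0 1/1 0/0 0/0
1/1 0/0 1/1 0/0 0/0 0/1 1/1 0/1 0/0
0/1 0/0 0/0 0/0 0/0 0/1 1/1 0/1 0/1
1/1 0/0 0/0 1/1 0/0 0/0 1/1 0/0 0/0
1/1 0/0 1/1 1/1 0/0 0/0 0/1 1/1 0/1
0/1 0/0 1/1 1/1 0/0 0/1 1/1 1/1 0/1
0/1 0/0 0/0 1/1 0/1 0/0 0/1 1/1 0/0
0/0 0/1 0/0 0/0 0/1 0/1 0/1 1/1 0/1
0/0 0/1 0/0 0/0 0/1 0/1 0/1 0/1 0/1
0/0 1/1 0/0 0/0 1/1 0/1 0/1 1/1 1/1
0/0 0/1 0/1 1/1 0/1 1/1 0/0 1/1 0/1
0/0 0/0 0/0 1/1 0/1 0/1 0/1 1/1 0/1
"""

_ELECTROPHORESIS = """
0/0 0/0 0/0 0/0 0/1 0/0 0/1 0/0 0/0
0/1 0/0 0/0 0/1 0/1 0/0 0/1 0/1 0/1
0/1 0/0 0/0 0/1 0/0 0/0 1/1 0/0 0/0
1/1 0/0 1/1 0/0 0/0 0/1 1/1 0/1 0/0
0/1 0/0 0/0 0/0 0/0 0/1 1/1 0/1 0/1
0/1 0/0 0/0 1/1 0/0 0/0 1/1 0/1 0/0
1/1 0/0 1/1 1/1 0/0 0/0 0/1 1/1 0/1
0/1 0/0 0/1 1/1 0/0 0/1 1/1 1/1 0/1
0/1 0/0 0/0 1/1 0/1 0/0 0/1 1/1 0/0
0/0 0/1 0/0 0/0 0/1 0/1 0/1 1/1 0/1
0/0 0/1 0/0 0/0 0/1 0/1 0/1 0/1 0/1
0/0 1/1 0/0 0/0 1/1 0/1 0/1 1/1 1/1
0/0 1/1 0/0 1/1 1/1 1/1 0/0 1/1 1/1
0/0 0/0 0/0 1/1 0/1 0/1 0/1 1/1 0/1
"""


def _grid(block: str) -> pd.DataFrame:
    rows = [line.split() for line in block.strip().splitlines()]
    frame = pd.DataFrame(rows, index=CULTIVARS, columns=MARKERS)
    return frame.T  # markers x cultivars


def validation_marker_grids() -> tuple[pd.DataFrame, pd.DataFrame]:
    """Return (pipeline, electrophoresis) genotype grids, markers x cultivars."""
    return _grid(_PIPELINE), _grid(_ELECTROPHORESIS)
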