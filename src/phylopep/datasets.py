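"""Bundled reference tables.

`zymo_community` carries the composition metadata of the ZymoBIOMICS
Microbial Community Standard D6300 (genomic DNA fractions, median genome
sizes, rough cell-volume estimates for the eight bacteria and two yeasts)
together with signature-fit TSM quantities reported for a deep metaproteomic
acquisition of that standard, and the derived percentage columns as reported
(rounded) for cross-checking the package's own arithmetic.
"""

from __future__ import annotations

import pandas as pd

_ZYMO_ROWS = [
    # species, dna_percent, genome_mb, volume_um3, signature_tsm,
    # reported cell-count ratio %, reported volume-proxy biomass,
    # reported signature biomass %
    ("Pseudomonas aeruginosa",   12, 6.58,  0.49,  271.3,  6.50,  3.19,  1.9),
    ("Escherichia coli",         12, 5.17,  0.65,  884.9,  8.27,  5.37,  6.4),
    ("Salmonella enterica",      12, 4.78,  0.96,  670.2,  8.95,  8.61,  4.8),
    ("Lactobacillus fermentum",  12, 1.99,  1.41, 3373.0, 21.49, 30.38, 24.2),
    ("Enterococcus faecalis",    12, 3.03,  0.52, 1002.8, 14.11,  7.39,  7.2),
    ("Staphylococcus aureus",    12, 2.85,  0.90, 2380.7, 15.01, 13.51, 17.1),
    ("Listeria monocytogenes",   12, 2.98,  0.27, 1163.2, 14.35,  3.85,  8.4),
    ("Bacillus subtilis",        12, 4.13,  2.69, 2946.1, 10.36, 27.90, 21.2),
    ("Saccharomyces cerevisiae",  2, 12.1, 33.51,  959.7,  0.59, 19.69,  6.9),
    ("Cryptococcus neoformans",   2, 19.05, 33.51, 267.9,  0.37, 12.54,  1.9),
]

_ZYMO_COLUMNS = [
    "species", "dna_percent", "genome_mb", "volume_um3", "signature_tsm",
    "reported_cell_count_ratio_pct", "reported_volume_proxy_biomass",
    "reported_signature_biomass_pct",
]


def zymo_community() -> pd.DataFrame:
    """ZymoBIOMICS D6300 composition metadata and signature TSM quantities."""
    return pd.DataFrame(_ZYMO_ROWS, columns=_ZYMO_COLUMNS)
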