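"""Published summary data for the reference human NumtS compilation (hg18).

These tables are the printed per-chromosome and validation bookkeeping of
the reference compilation of human nuclear mitochondrial sequences built
against hg18.  They serve as ready-made inputs for the statistics module
(correlations, percentage arithmetic) when the full per-fragment catalogue
is not at hand.

Note the published totals are internally inconsistent in two places, and
both figures are kept verbatim: the per-chromosome rows sum to 611 NumtS
over 625741 bp, while the companion text reports 585 assembled NumtS
covering 627410 bases.  No reconciliation is attempted here.
"""

from __future__ import annotations

import pandas as pd

#: Per-chromosome NumtS counts, chromosome lengths (hg18), summed NumtS
#: spans, and the published percentage of each chromosome covered.
HG18_CHROMOSOME_TABLE: tuple = (
    # (chrom, numts_count, chrom_length_bp, total_span_bp, span_percent)
    ("1", 46, 247249719, 57670, 0.023),
    ("2", 92, 242951149, 108317, 0.045),
    ("3", 39, 199501827, 24203, 0.012),
    ("4", 38, 191273063, 36179, 0.019),
    ("5", 24, 180857866, 40163, 0.022),
    ("6", 31, 170899992, 11708, 0.007),
    ("7", 35, 158821424, 51356, 0.032),
    ("8", 37, 146274826, 46805, 0.032),
    ("9", 28, 140273252, 36854, 0.026),
    ("10", 33, 135374737, 21445, 0.016),
    ("11", 28, 134452384, 26640, 0.020),
    ("12", 40, 132349534, 8551, 0.006),
    ("13", 19, 114142980, 11159, 0.010),
    ("14", 8, 106368585, 8991, 0.008),
    ("15", 12, 100338915, 9002, 0.009),
    ("16", 11, 88827254, 17205, 0.019),
    ("17", 17, 78774742, 24285, 0.031),
    ("18", 7, 76117153, 1340, 0.002),
    ("19", 15, 63811651, 19373, 0.030),
    ("20", 10, 62435964, 5905, 0.009),
    ("21", 8, 46944323, 7210, 0.015),
    ("22", 8, 49691432, 9025, 0.018),
    ("X", 13, 154913754, 30845, 0.020),
    ("Y", 12, 57772954, 11510, 0.020),
)


def hg18_chromosome_frame() -> pd.DataFrame:
    return pd.DataFrame(
        HG18_CHROMOSOME_TABLE,
        columns=["chrom", "numts_count", "chrom_length", "total_span", "span_percent"],
    )


#: Validation bookkeeping of the 585 assembled NumtS: how many were
#: confirmed by PCR, by sequencing, and/or in silico against HapMap
#: fosmid-end data, with the published percentages of the total.
VALIDATION_COUNTS: tuple = (
    ("PCR and HapMap", 5, 0.85),
    ("PCR and Seq", 26, 4.44),
    ("PCR, Seq and HapMap", 247, 42.22),
    ("HapMap only", 279, 47.69),
    ("PCR only", 1, 0.17),
    ("Not validated", 27, 4.62),
)

TOTAL_ASSEMBLED_NUMTS = 585
TOTAL_HSP_NUMTS = 766
SEQUENCED_HSP_NUMTS = 339
NOT_VALIDATED_NUMTS = 27


def validation_frame() -> pd.DataFrame:
    return pd.DataFrame(
        VALIDATION_COUNTS, columns=["validation_test", "count", "published_percent"]
    )
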