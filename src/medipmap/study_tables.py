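"""Published summary values for the four broiler MeDIP-seq libraries.

These are the printed per-library read-mapping counts, methylated-CGI
counts and bisulfite amplicon coordinates from the study whose design this
pipeline mirrors (high/low body-weight tails of the Recessive White Rock
and Xinhua breeds). They serve as inputs to the reporting helpers — e.g.
recomputing mapping percentages or methylated-CGI percentages from raw
counts — and as reference fixtures in tests.
"""

from __future__ import annotations

#: sample -> (total reads, mapped reads, uniquely mapped reads)
READ_MAPPING_COUNTS: dict[str, tuple[int, int, int]] = {
    "WRR_h": (36_734_694, 23_877_624, 13_087_223),
    "WRR_l": (33_399_566, 21_861_843, 12_287_910),
    "XH_h": (36_734_694, 23_472_733, 12_875_987),
    "XH_l": (36_734_694, 23_897_397, 13_728_925),
}

#: sample -> (methylated CGIs, total CGIs)
CGI_METHYLATION_COUNTS: dict[str, tuple[int, int]] = {
    "WRR_h": (4_406, 33_915),
    "WRR_l": (4_020, 33_915),
    "XH_h": (4_412, 33_915),
    "XH_l": (5_084, 33_915),
}

#: bisulfite amplicons: name -> (chrom, start_1based, end_1based, published length)
#: PM1 targets a low-methylation region, PM2-PM5 high-methylation regions.
#: PM3's published start coordinate is inconsistent with its 357 bp product
#: (likely a misprint); it is kept here verbatim and flagged.
BISULFITE_AMPLICONS: dict[str, tuple[str, int, int, int]] = {
    "PM1": ("chr9", 6_199_130, 6_199_544, 415),
    "PM2": ("chr6", 10_360_074, 10_360_427, 354),
    "PM3": ("chr6", 1_036_407, 10_360_763, 357),  # coordinates inconsistent with length
    "PM4": ("chrUn_Random", 45_286_930, 45_287_275, 346),
    "PM5": ("chrUn_Random", 45_287_248, 45_287_680, 433),
}

#: amplicons whose printed coordinates are internally consistent
CONSISTENT_AMPLICONS = ("PM1", "PM2", "PM4", "PM5")


def mapping_percentages(total: int, mapped: int, unique: int) -> tuple[float, float]:
    """(percent mapped, percent uniquely mapped) of total reads, to 2 dp —
    the rounding convention of per-library sequencing summaries."""
    return round(100.0 * mapped / total, 2), round(100.0 * unique / total, 2)
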