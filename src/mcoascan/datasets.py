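"""Published study inputs bundled with the package.

The sequencing-run summary (one row per horse of the ten-animal panel) and
the breed composition of the validation cohort are published numbers; they
are inputs to worked-example arithmetic, not simulated data.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .intervals import GenomicInterval

#: The mapped MCOA identity-by-descent interval on horse chromosome 6.
MCOA_REGION = GenomicInterval("chr6", 73_640_494, 73_848_154)

#: Positions of the two PMEL candidate SNPs (coding Arg625Cys, intronic).
CODING_SNP_POS = 73_665_304
INTRONIC_SNP_POS = 73_666_064

#: Breed composition of the genotyped validation cohort.
VALIDATION_COHORT_BREEDS: dict[str, int] = {
    "American Miniature Horse": 8,
    "Arabian Horse": 19,
    "Ardennes": 21,
    "Cold Blooded Trotter": 213,
    "Dole Horse": 16,
    "French Trotter": 56,
    "Gotland Pony": 29,
    "Icelandic Horse": 185,
    "Kentucky Mountain Horse": 23,
    "North Swedish Draft Horse": 38,
    "Rocky Mountain Horse": 17,
    "Shetland Pony": 30,
    "Standardbred": 174,
    "Swedish Warmblood": 70,
    "Thoroughbred": 37,
}


def sequencing_panel_stats() -> pd.DataFrame:
    """Per-horse sequencing yield/mapping/coverage table for the ten-animal panel."""
    ref = resources.files("mcoascan").joinpath("data/sequencing_panel_stats.tsv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


__all__ = [
    "MCOA_REGION", "CODING_SNP_POS", "INTRONIC_SNP_POS",
    "VALIDATION_COHORT_BREEDS", "sequencing_panel_stats",
]
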