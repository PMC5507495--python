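"""Small published reference inputs bundled with the package.

``soybean_library_reads`` returns the read-mapping statistics of the ten
soybean late-maturation RNA-seq libraries (stages 7.1 to 9, fresh and
rapidly dried, single-end reads mapped to the Williams 82 reference): the
post-trimming read total, the unambiguously mapped count, and the mapping
percentage as printed in the source study's QC table.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["soybean_library_reads"]

# sample, stage, daf, treatment, total_reads, mapped_reads, printed percent
_LIBRARY_READS = (
    ("7.1F", "7.1", 57, "fresh", 25_673_031, 24_112_015, 93.9),
    ("7.2aF", "7.2", 63, "fresh", 38_088_839, 34_971_702, 91.8),
    ("7.2bF", "7.2", 63, "fresh", 34_381_008, 31_799_644, 92.5),
    ("7.2aD", "7.2", 63, "dried", 14_259_082, 12_881_662, 90.3),
    ("7.2bD", "7.2", 63, "dried", 66_764_127, 60_626_937, 90.8),
    ("7.3F", "7.3", 69, "fresh", 22_267_371, 20_475_504, 92.0),
    ("8.1F", "8.1", 71, "fresh", 14_533_337, 13_392_050, 92.2),
    ("8.2F", "8.2", 73, "fresh", 22_057_408, 19_621_133, 89.0),
    ("9aF", "9", 77, "fresh", 28_824_583, 26_457_357, 91.8),
    ("9bF", "9", 77, "fresh", 23_064_604, 21_097_336, 91.5),
)


def soybean_library_reads() -> pd.DataFrame:
    """Published per-library read totals and mapped counts (ten libraries)."""
    return pd.DataFrame(
        _LIBRARY_READS,
        columns=["sample", "stage", "daf", "treatment",
                 "total_reads", "mapped_reads", "printed_percent"],
    )
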