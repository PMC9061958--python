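"""Bundled example data.

The BRCA2 nucleotide-count table is the worked example shipped with the
package: counts of the bases A, C, G, T in two counting groups from the
human BRCA2 tumour-suppressor gene region.  Group 1 is an observed count
of the gene sequence; group 2 is a simulated companion group with very
similar composition, so the homogeneity null is (by construction) hard to
reject.
"""

from __future__ import annotations

import numpy as np

from .counts import NUCLEOTIDES, CountTable

__all__ = ["brca2_counts", "BRCA2_CRITICAL_VALUE"]

# Tabulated critical value used in the published BRCA2 analysis
# (the chi-square 0.975 quantile at 3 degrees of freedom, rounded).
BRCA2_CRITICAL_VALUE = 9.35

_BRCA2_COUNTS = np.array(
    [
        [38514, 24631, 25685, 38249],  # group 1: observed
        [38550, 24635, 25700, 38288],  # group 2: simulated companion
    ],
    dtype=np.int64,
)


def brca2_counts() -> CountTable:
    """The 2x4 BRCA2 nucleotide-count table (groups x A,C,G,T)."""
    return CountTable(
        group_labels=("Count Group 1", "Count Group 2"),
        category_labels=NUCLEOTIDES,
        counts=_BRCA2_COUNTS.copy(),
    )
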