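"""Curated golden values from a published transgenic-rice miRNA survey.

A deep-sequencing comparison of developing seeds from six Bt/EPSPS
transgenic rice lines (pooled as one treatment group) against their
non-transgenic parent (CK) reported 568 detected conserved miRNAs, of which
21 were called differentially expressed: 7 up- and 14 down-regulated.  The
published table of those 21 miRNAs — group-mean TPM, control TPM, the
fold change as printed (2 decimal places), both published significance
columns, and the direction call — is reproduced here verbatim as a
regression fixture for the fold-change and DE-calling code.

The two published significance columns come from an unnamed test and are
carried for reference only; this package's own p-values are produced by
Fisher's exact test and are not expected to equal them.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

#: Number of conserved miRNAs detected in the published survey.
CONSERVED_MIRNAS_DETECTED = 568

UP = "UP"
DOWN = "DOWN"
NS = "NS"

_ROWS = [
    # (mirna_id, group_tpm, ck_tpm, published_fold_change, corrected_p, fdr, direction)
    ("miR156l-5p", 119.39, 11.00, 10.85, 8.83e-25, 1.88e-23, UP),
    ("miR166e-3p", 1131.35, 313.46, 3.61, 6.62e-111, 3.06e-109, UP),
    ("miR5337a", 37.83, 16.50, 2.29, 4.36e-03, 2.37e-02, UP),
    ("miR3979-3p", 48.07, 22.00, 2.19, 1.23e-03, 7.89e-03, UP),
    ("miR169e", 34.36, 16.50, 2.08, 1.22e-02, 5.64e-02, UP),
    ("miR2873c", 67.80, 33.00, 2.05, 4.43e-04, 3.32e-03, UP),
    ("miR1870-3p", 55.07, 27.50, 2.00, 2.09e-03, 1.27e-02, UP),
    ("miR2118e", 16.25, 33.00, 0.49, 3.30e-02, 1.23e-01, DOWN),
    ("miR5799", 16.21, 33.00, 0.49, 3.30e-02, 1.23e-01, DOWN),
    ("miR399i", 45.78, 93.49, 0.49, 6.36e-05, 5.78e-04, DOWN),
    ("miR1428d", 21.45, 43.99, 0.49, 9.29e-03, 4.52e-02, DOWN),
    ("miR2118o", 28.28, 60.49, 0.47, 9.91e-04, 6.61e-03, DOWN),
    ("miR1428e-5p", 14.60, 33.00, 0.44, 1.34e-02, 6.02e-02, DOWN),
    ("miR1874-5p", 2851.69, 6615.63, 0.43, 0.0, 0.0, DOWN),
    ("miR1874-3p", 6306.25, 15485.97, 0.41, 0.0, 0.0, DOWN),
    ("miR1846d-3p", 19.41, 49.49, 0.39, 4.47e-04, 3.30e-03, DOWN),
    ("miR2863a", 18.36, 49.49, 0.37, 2.49e-04, 2.00e-03, DOWN),
    ("miR1428b", 18.29, 49.49, 0.37, 2.49e-04, 2.00e-03, DOWN),
    ("miR1428c", 14.19, 38.49, 0.37, 1.51e-03, 9.52e-03, DOWN),
    ("miR1428f-5p", 11.66, 33.00, 0.35, 2.48e-03, 1.49e-02, DOWN),
    ("miR529b", 22.40, 71.49, 0.31, 4.96e-07, 6.54e-06, DOWN),
]

COLUMNS = [
    "group_tpm",
    "ck_tpm",
    "published_fold_change",
    "corrected_p",
    "fdr",
    "direction",
]


@dataclass(frozen=True)
class PublishedDERow:
    mirna_id: str
    group_tpm: float
    ck_tpm: float
    published_fold_change: float
    corrected_p: float
    fdr: float
    direction: str


def reference_de_table() -> pd.DataFrame:
    """The 21 published differentially expressed miRNAs, verbatim.

    Indexed by miRNA id, columns :data:`COLUMNS`.  TPM and fold-change
    values are exactly as printed (2 decimal places).
    """
    df = pd.DataFrame(_ROWS, columns=["mirna_id", *COLUMNS])
    return df.set_index("mirna_id")


def reference_de_rows() -> list[PublishedDERow]:
    return [PublishedDERow(*row) for row in _ROWS]
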