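"""Packaged TRBV/TRBJ gene tables used by the cohort simulator.

Gene symbols are family-level (the level at which usage preferences are
reported); weights are rough human TCRbeta usage proportions, adequate for
generating realistic-looking gene columns. They are not calibrated estimates.
"""

from __future__ import annotations

import numpy as np

# (gene, relative background usage weight)
TRBV_USAGE: list[tuple[str, float]] = [
    ("TRBV2", 0.050),
    ("TRBV3", 0.018),
    ("TRBV4", 0.055),
    ("TRBV5", 0.090),
    ("TRBV6", 0.095),
    ("TRBV7", 0.095),
    ("TRBV9", 0.040),
    ("TRBV10", 0.030),
    ("TRBV11", 0.045),
    ("TRBV12", 0.050),
    ("TRBV13", 0.015),
    ("TRBV14", 0.025),
    ("TRBV15", 0.030),
    ("TRBV16", 0.008),
    ("TRBV18", 0.015),
    ("TRBV19", 0.050),
    ("TRBV20", 0.090),
    ("TRBV24", 0.015),
    ("TRBV25", 0.020),
    ("TRBV27", 0.050),
    ("TRBV28", 0.055),
    ("TRBV29", 0.045),
    ("TRBV30", 0.014),
]

TRBJ_USAGE: list[tuple[str, float]] = [
    ("TRBJ1", 0.45),
    ("TRBJ2", 0.55),
]

TRBV_NAMES = np.array([g for g, _ in TRBV_USAGE])
TRBV_WEIGHTS = np.array([w for _, w in TRBV_USAGE])
TRBV_WEIGHTS = TRBV_WEIGHTS / TRBV_WEIGHTS.sum()

TRBJ_NAMES = np.array([g for g, _ in TRBJ_USAGE])
TRBJ_WEIGHTS = np.array([w for _, w in TRBJ_USAGE])
TRBJ_WEIGHTS = TRBJ_WEIGHTS / TRBJ_WEIGHTS.sum()

# One fixed codon per residue: deterministic reverse translation so that the
# emitted nucleotide column is self-consistent and round-trips exactly.
CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG",
    "M": "ATG", "N": "AAT", "P": "CCT", "Q": "CAG", "R": "CGT",
    "S": "AGC", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
    "*": "TAA",
}

_CODON_TABLE = {ord(aa): codon for aa, codon in CODON.items()}


def reverse_translate(aa_seq: str) -> str:
    """Map an amino-acid string to a deterministic nucleotide string."""
    return aa_seq.translate(_CODON_TABLE)
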