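"""Fixed amino-acid alphabet shared by every encoder in a run.

The 20 standard residues are ordered alphabetically by one-letter code.
The gap symbol ``-`` is not part of the residue alphabet; HLA tensors give
it a dedicated 21st channel (index :data:`GAP_CHANNEL`).
"""

from __future__ import annotations

#: The 20 standard residues, alphabetical by one-letter code.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

#: Gap character accepted in aligned HLA sequences.
GAP: str = "-"

#: Number of residue channels.
N_RESIDUES: int = len(AMINO_ACIDS)

#: Channel index of the gap in HLA tensors (placed after the 20 residues).
GAP_CHANNEL: int = N_RESIDUES

#: Fixed width of the HLA alignment the network consumes.
HLA_WIDTH: int = 372

#: Canonical class I peptide length handled by this package.
PEPTIDE_LENGTH: int = 9

_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


def residue_index(aa: str) -> int:
    """Return the channel index of a one-letter residue code.

    Raises :class:`KeyError` for anything outside the 20-letter alphabet
    (including the gap, 'X' and 'B').
    """
    return _INDEX[aa]


def is_residue(aa: str) -> bool:
    return aa in _INDEX
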