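"""One-hot tensor encoding of peptides and aligned HLA sequences.

A 9-mer peptide becomes a ``1 x 9 x 20`` tensor: one width column per
residue position, one channel per amino-acid type, a single 1 per column.
An aligned HLA sequence (gap character ``-``) becomes a ``1 x 372 x 21``
tensor whose 21st channel carries gaps; sequences shorter than 372 are
right-padded with gap columns so that alignment column indices are stable
from position 0. No physicochemical information is encoded — the network
downstream learns everything from residue identity alone.
"""

from __future__ import annotations

import numpy as np
from Bio import SeqIO

from .alphabet import (
    AMINO_ACIDS,
    GAP,
    GAP_CHANNEL,
    HLA_WIDTH,
    N_RESIDUES,
    PEPTIDE_LENGTH,
    is_residue,
    residue_index,
)
from .errors import AlphabetError, MalformedTensorError, SequenceLengthError

__all__ = [
    "encode_peptide",
    "encode_hla",
    "decode_peptide",
    "read_aligned_fasta",
]


def encode_peptide(seq: str) -> np.ndarray:
    """Encode a 9-mer peptide as a one-hot ``(1, 9, 20)`` tensor.

    Column ``j`` has its 1 at the channel of residue ``seq[j]``; channels
    are ordered alphabetically (A, C, D, ..., Y). Lower-case input is
    upper-cased before validation.

    Raises
    ------
    SequenceLengthError
        If the peptide is not exactly 9 residues long.
    AlphabetError
        If any character is outside the 20-letter alphabet (gaps and
        ambiguity codes such as 'X'/'B' are rejected).
    """
    seq = str(seq).upper()
    if len(seq) != PEPTIDE_LENGTH:
        raise SequenceLengthError(
            f"peptide must have length {PEPTIDE_LENGTH}, got {len(seq)}: {seq!r}"
        )
    t = np.zeros((1, PEPTIDE_LENGTH, N_RESIDUES), dtype=np.float32)
    for j, aa in enumerate(seq):
        if not is_residue(aa):
            raise AlphabetError(f"non-standard residue {aa!r} at position {j}")
        t[0, j, residue_index(aa)] = 1.0
    return t


def encode_hla(aligned_seq: str) -> np.ndarray:
    """Encode an aligned HLA sequence as a one-hot ``(1, 372, 21)`` tensor.

    Gap characters within the sequence, and every column beyond its length
    (right padding up to width 372), are hot at the gap channel (index 20).

    Raises
    ------
    SequenceLengthError
        If the aligned sequence is longer than 372.
    AlphabetError
        On any character that is neither a standard residue nor ``-``.
    """
    aligned_seq = str(aligned_seq).upper()
    if len(aligned_seq) > HLA_WIDTH:
        raise SequenceLengthError(
            f"aligned HLA sequence longer than {HLA_WIDTH}: {len(aligned_seq)}"
        )
    t = np.zeros((1, HLA_WIDTH, N_RESIDUES + 1), dtype=np.float32)
    for j, aa in enumerate(aligned_seq):
        if aa == GAP:
            t[0, j, GAP_CHANNEL] = 1.0
        elif is_residue(aa):
            t[0, j, residue_index(aa)] = 1.0
        else:
            raise AlphabetError(f"illegal character {aa!r} at alignment column {j}")
    t[0, len(aligned_seq):, GAP_CHANNEL] = 1.0
    return t


def decode_peptide(t: np.ndarray) -> str:
    """Invert :func:`encode_peptide` (round-trip guarantee).

    Raises :class:`MalformedTensorError` if the tensor is not a valid
    one-hot peptide tensor (wrong shape, non-binary entries, or a column
    without exactly one hot channel).
    """
    t = np.asarray(t)
    if t.shape != (1, PEPTIDE_LENGTH, N_RESIDUES):
        raise MalformedTensorError(
            f"expected shape (1, {PEPTIDE_LENGTH}, {N_RESIDUES}), got {t.shape}"
        )
    if not np.isin(t, (0.0, 1.0)).all():
        raise MalformedTensorError("peptide tensor entries must be 0 or 1")
    if not np.array_equal(t[0].sum(axis=1), np.ones(PEPTIDE_LENGTH)):
        raise MalformedTensorError("every column must have exactly one hot channel")
    return "".join(AMINO_ACIDS[c] for c in t[0].argmax(axis=1))


def read_aligned_fasta(path) -> dict[str, str]:
    """Read aligned HLA sequences from FASTA, keyed by record id.

    Record ids are allele names (e.g. ``HLA-A*02:01``); ``-`` is the only
    gap character accepted. Each sequence is validated by a trial encode
    so malformed records fail loudly at load time rather than mid-training.
    """
    index: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        encode_hla(seq)  # validation only
        index[rec.id] = seq
    return index
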