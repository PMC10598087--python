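"""Substitution scoring and Karlin–Altschul statistics.

The all-vs-all search scores local alignments with BLOSUM62 under affine gap
penalties and converts raw scores to E-values with the classical
Karlin–Altschul formula ``E = K * m * n * exp(-lambda * S)``.  The gapped
constants are fixed to the standard BLOSUM62/11/1 values rather than being
estimated per search, which keeps every cutoff deterministic and
reproducible; E-values here are used only as a filter threshold.

Gap convention: a gap of length ``L`` costs ``gap_open + (L - 1) * gap_extend``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import biotite.sequence as bseq
import biotite.sequence.align as balign

#: The 20 standard amino acids, alphabetically by one-letter code.
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

#: Karlin–Altschul parameters for gapped BLOSUM62 with 11/1 penalties.
DEFAULT_LAMBDA = 0.267
DEFAULT_KAPPA = 0.041


def default_matrix() -> balign.SubstitutionMatrix:
    """BLOSUM62 with ambiguous/non-standard residues scored as neutral 0.

    Input sequences are sanitized to the 24-letter protein alphabet with
    every non-standard residue mapped to ``X``; setting the ``X`` (and ``*``)
    rows to zero makes such positions score-neutral instead of penalized.
    """
    std = balign.SubstitutionMatrix.std_protein_matrix()
    arr = std.score_matrix().copy()
    alph = std.get_alphabet1()
    for sym in ("X", "*", "B", "Z"):
        i = alph.encode(sym)
        arr[i, :] = 0
        arr[:, i] = 0
    return balign.SubstitutionMatrix(alph, alph, arr)


@dataclass(frozen=True)
class ScoringScheme:
    """Alignment scoring parameters plus E-value statistics.

    Parameters
    ----------
    matrix
        Symmetric substitution matrix (default: BLOSUM62, neutral ``X``).
    gap_open, gap_extend
        Affine gap penalties (positive integers); a gap of length ``L``
        costs ``gap_open + (L - 1) * gap_extend``.
    lam, kappa
        Karlin–Altschul ``lambda`` and ``K`` for the raw-score scale.
    """

    matrix: balign.SubstitutionMatrix = field(default_factory=default_matrix)
    gap_open: int = 11
    gap_extend: int = 1
    lam: float = DEFAULT_LAMBDA
    kappa: float = DEFAULT_KAPPA

    def __post_init__(self) -> None:
        arr = self.matrix.score_matrix()
        if not np.array_equal(arr, arr.T):
            raise ValueError("substitution matrix must be symmetric")
        if not (self.gap_open >= self.gap_extend >= 1):
            raise ValueError("require gap_open >= gap_extend >= 1")
        if self.lam <= 0 or self.kappa <= 0:
            raise ValueError("lambda and kappa must be positive")

    @property
    def gap_penalty(self) -> tuple[int, int]:
        """Penalty tuple in the (negative) convention used by the aligner."""
        return (-self.gap_open, -self.gap_extend)

    def bit_score(self, raw_score: float) -> float:
        """Convert a raw alignment score to bits."""
        return (self.lam * raw_score - math.log(self.kappa)) / math.log(2)


def evalue(raw_score: float, m: int, n: int, scheme: ScoringScheme) -> float:
    """Expected number of chance alignments scoring >= ``raw_score``.

    ``m`` is the query length and ``n`` the total letters in the searched
    subject space (here: the summed length of the subject genome's
    proteome).  Strictly decreasing in the score and proportional to
    ``m * n``.
    """
    if m < 1 or n < 1:
        raise ValueError("search space dimensions must be >= 1")
    return scheme.kappa * m * n * math.exp(-scheme.lam * raw_score)


def sanitize(sequence: str) -> str:
    """Uppercase a protein sequence and map non-standard residues to X."""
    seq = sequence.upper()
    return "".join(c if c in STANDARD_AA else "X" for c in seq)


def as_protein(sequence: str) -> bseq.ProteinSequence:
    """Build an aligner-ready sequence, sanitizing non-standard residues."""
    if not sequence:
        raise ValueError("empty sequence")
    return bseq.ProteinSequence(sanitize(sequence))
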