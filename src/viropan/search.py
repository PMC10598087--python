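"""All-vs-all protein similarity search for a family's proteomes.

This stage plays the role a heuristic search tool (e.g. BLASTP) plays in a
conventional pangenome pipeline: every protein pair that passes a k-mer
prefilter is aligned with an optimal affine-gap local aligner, scored with
BLOSUM62, and kept if it clears the two canonical homology filters — an
E-value below 1e-5 and a query coverage of at least 75%.  Intra-genome
pairs are retained too, because in-paralog detection downstream needs them;
self-hits are excluded.

The hit table is a tidy DataFrame in BLAST outfmt-6-like column order
(``qseqid sseqid pident length mismatch gapopen qstart qend sstart send
evalue bitscore``) extended with ``raw_score qcov scov qgenome sgenome``.
Coverages are fractions of the full sequence length spanned by the local
alignment; only query coverage is filtered on.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
import biotite.sequence.align as balign

from .scoring import ScoringScheme, as_protein, evalue

HIT_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
    "raw_score", "qcov", "scov", "qgenome", "sgenome",
]


@dataclass(frozen=True)
class Hit:
    """One scored pairwise local alignment."""

    query_id: str
    subject_id: str
    raw_score: int
    bit_score: float
    evalue: float
    identity: float
    query_coverage: float
    subject_coverage: float


def align_pair(a: str, b: str, scheme: ScoringScheme | None = None) -> dict:
    """Optimal affine-gap local alignment of two sequences.

    Returns a dict with the raw DP optimum plus identity, coverage and
    BLAST-style bookkeeping derived from the traceback.  Empty sequences
    are an error; if no alignment has positive score the raw score is 0
    and the span fields are empty.
    """
    scheme = scheme or ScoringScheme()
    seq_a, seq_b = as_protein(a), as_protein(b)
    alns = balign.align_optimal(
        seq_a, seq_b, scheme.matrix,
        gap_penalty=scheme.gap_penalty, local=True, max_number=1,
    )
    aln = alns[0]
    trace = aln.trace
    if len(trace) == 0 or aln.score <= 0:
        return {
            "raw_score": 0, "length": 0, "pident": 0.0, "mismatch": 0,
            "gapopen": 0, "qstart": 0, "qend": 0, "sstart": 0, "send": 0,
            "qcov": 0.0, "scov": 0.0,
        }
    qpos = trace[:, 0]
    spos = trace[:, 1]
    both = (qpos >= 0) & (spos >= 0)
    matches = sum(
        1 for i in np.flatnonzero(both) if a[qpos[i]].upper() == b[spos[i]].upper()
    )
    n_cols = len(trace)
    gapopen = 0
    for col in (qpos, spos):
        is_gap = col < 0
        gapopen += int(((~is_gap[:-1]) & is_gap[1:]).sum() + (1 if is_gap[0] else 0))
    q_idx = qpos[qpos >= 0]
    s_idx = spos[spos >= 0]
    return {
        "raw_score": int(aln.score),
        "length": n_cols,
        "pident": 100.0 * matches / n_cols,
        "mismatch": int(both.sum()) - matches,
        "gapopen": gapopen,
        "qstart": int(q_idx.min()) + 1,
        "qend": int(q_idx.max()) + 1,
        "sstart": int(s_idx.min()) + 1,
        "send": int(s_idx.max()) + 1,
        "qcov": (int(q_idx.max()) - int(q_idx.min()) + 1) / len(a),
        "scov": (int(s_idx.max()) - int(s_idx.min()) + 1) / len(b),
    }


def _kmer_candidates(
    proteins: list[tuple[str, str]], k: int
) -> set[tuple[int, int]]:
    """Unordered index pairs sharing at least one k-mer."""
    index: dict[str, list[int]] = {}
    for i, (_, seq) in enumerate(proteins):
        for kmer in {seq[j : j + k] for j in range(len(seq) - k + 1)}:
            index.setdefault(kmer, []).append(i)
    pairs: set[tuple[int, int]] = set()
    for bucket in index.values():
        for ai in range(len(bucket)):
            for bi in range(ai + 1, len(bucket)):
                pairs.add((bucket[ai], bucket[bi]))
    return pairs


def filter_hits(
    hits: pd.DataFrame, max_evalue: float = 1e-5, min_query_cov: float = 0.75
) -> pd.DataFrame:
    """Apply the E-value and query-coverage filters to a hit table."""
    keep = (hits["evalue"] < max_evalue) & (hits["qcov"] >= min_query_cov)
    return hits.loc[keep].reset_index(drop=True)


def all_vs_all(
    proteomes: Mapping[str, list[tuple[str, str]]],
    scheme: ScoringScheme | None = None,
    max_evalue: float = 1e-5,
    min_query_cov: float = 0.75,
    prefilter_k: int = 4,
) -> pd.DataFrame:
    """Filtered all-vs-all hit table over a family's proteomes.

    Each unordered pair is aligned once (the raw local score is symmetric);
    both hit directions are then evaluated independently because E-value
    (subject search space = summed subject-proteome length) and query
    coverage are direction-specific.  ``prefilter_k = 0`` disables the
    k-mer prefilter and aligns every pair.
    """
    if len(proteomes) < 2:
        raise ValueError(
            "all-vs-all search needs at least 2 proteomes; families with "
            "fewer than 3 proteomes are excluded from pangenome analysis anyway"
        )
    scheme = scheme or ScoringScheme()
    proteins: list[tuple[str, str]] = []
    genome_of: list[str] = []
    for genome in sorted(proteomes):
        for pid, seq in proteomes[genome]:
            proteins.append((pid, seq))
            genome_of.append(genome)
    proteome_len = {
        g: sum(len(s) for _, s in proteomes[g]) for g in proteomes
    }

    if prefilter_k and prefilter_k > 0:
        candidates = _kmer_candidates(proteins, prefilter_k)
    else:
        n = len(proteins)
        candidates = {(i, j) for i in range(n) for j in range(i + 1, n)}

    rows = []
    for i, j in candidates:
        pid_i, seq_i = proteins[i]
        pid_j, seq_j = proteins[j]
        res = align_pair(seq_i, seq_j, scheme)
        if res["raw_score"] <= 0:
            continue
        bit = scheme.bit_score(res["raw_score"])
        for (qpid, qseq, qg), (spid, sseq, sg), qcov, scov, flip in (
            ((pid_i, seq_i, genome_of[i]), (pid_j, seq_j, genome_of[j]),
             res["qcov"], res["scov"], False),
            ((pid_j, seq_j, genome_of[j]), (pid_i, seq_i, genome_of[i]),
             res["scov"], res["qcov"], True),
        ):
            ev = evalue(res["raw_score"], len(qseq), proteome_len[sg], scheme)
            rows.append((
                qpid, spid, res["pident"], res["length"], res["mismatch"],
                res["gapopen"],
                res["sstart"] if flip else res["qstart"],
                res["send"] if flip else res["qend"],
                res["qstart"] if flip else res["sstart"],
                res["qend"] if flip else res["send"],
                ev, bit, res["raw_score"], qcov, scov, qg, sg,
            ))
    hits = pd.DataFrame(rows, columns=HIT_COLUMNS)
    hits = filter_hits(hits, max_evalue=max_evalue, min_query_cov=min_query_cov)
    return hits.sort_values(["qseqid", "sseqid"], kind="mergesort").reset_index(drop=True)
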