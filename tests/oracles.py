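"""Independent brute-force oracles used to validate the fast implementations.

Everything here is deliberately naive — exhaustive enumeration and
double-loop scans — and shares no code with the package internals beyond
the substitution matrix values.
"""

from __future__ import annotations

from itertools import combinations

import pandas as pd


def score_lookup(scheme) -> dict[tuple[str, str], int]:
    mat = scheme.matrix
    alph = list("ACDEFGHIKLMNPQRSTVWY")
    return {(a, b): int(mat.get_score(a, b)) for a in alph for b in alph}


def brute_force_local_score(a: str, b: str, scheme) -> int:
    """Optimal local alignment score by enumerating aligned-position subsets.

    A local alignment is an equal-length pair of strictly increasing index
    subsequences; unaligned residues between consecutive aligned columns
    are charged as affine gaps (length L costs open + (L-1)*extend, in each
    sequence independently).  Empty alignments score 0.
    """
    scores = score_lookup(scheme)
    go, ge = scheme.gap_open, scheme.gap_extend

    def gap(length: int) -> int:
        return 0 if length == 0 else go + (length - 1) * ge

    best = 0
    la, lb = len(a), len(b)
    for k in range(1, min(la, lb) + 1):
        for idx_a in combinations(range(la), k):
            for idx_b in combinations(range(lb), k):
                s = scores[(a[idx_a[0]], b[idx_b[0]])]
                for t in range(1, k):
                    s += scores[(a[idx_a[t]], b[idx_b[t]])]
                    s -= gap(idx_a[t] - idx_a[t - 1] - 1)
                    s -= gap(idx_b[t] - idx_b[t - 1] - 1)
                best = max(best, s)
    return best


def brute_force_best_hits(hits: pd.DataFrame) -> dict:
    """Best cross-genome hit per (query, subject genome), by double loop."""
    best: dict = {}
    for row in hits.itertuples():
        if row.qgenome == row.sgenome:
            continue
        key = (row.qseqid, row.sgenome)
        cur = best.get(key)
        if (
            cur is None
            or row.bitscore > cur[1]
            or (row.bitscore == cur[1] and row.sseqid < cur[0])
        ):
            best[key] = (row.sseqid, row.bitscore)
    return best


def brute_force_bbh(hits: pd.DataFrame) -> set[frozenset]:
    """Mutual best-hit pairs from the double-loop best-hit scan."""
    best = brute_force_best_hits(hits)
    genome = {}
    for row in hits.itertuples():
        genome[row.qseqid] = row.qgenome
        genome[row.sseqid] = row.sgenome
    edges = set()
    for (q, sg), (s, _) in best.items():
        back = best.get((s, genome[q]))
        if back is not None and back[0] == q:
            edges.add(frozenset((q, s)))
    return edges


def brute_force_triangle_clusters(
    edges: set[frozenset], genome_of: dict
) -> list[frozenset]:
    """Triangle enumeration + repeated merging until fixpoint."""
    triangles = []
    nodes = sorted({n for e in edges for n in e})
    for trio in combinations(nodes, 3):
        a, b, c = trio
        if len({genome_of[a], genome_of[b], genome_of[c]}) != 3:
            continue
        tri_edges = {frozenset((a, b)), frozenset((a, c)), frozenset((b, c))}
        if tri_edges <= edges:
            triangles.append(tri_edges)
    edge_sets = [set(t) for t in triangles]
    merged = True
    while merged:
        merged = False
        for i in range(len(edge_sets)):
            for j in range(i + 1, len(edge_sets)):
                if edge_sets[i] & edge_sets[j]:
                    edge_sets[i] |= edge_sets[j]
                    del edge_sets[j]
                    merged = True
                    break
            if merged:
                break
    out = [frozenset({n for e in es for n in e}) for es in edge_sets]
    return sorted(out, key=min)


def direct_compartment(occupancy: int, n_genomes: int) -> str:
    """The core/shell/cloud definition evaluated verbatim."""
    if occupancy / n_genomes >= 0.95:
        return "core"
    if occupancy in (1, 2):
        return "cloud"
    return "shell"


def random_hit_table(rng, n_proteins: int = 10, n_genomes: int = 4) -> pd.DataFrame:
    """A random symmetric-score hit table for clustering oracle tests."""
    genomes = [f"g{i}" for i in range(n_genomes)]
    pids = [f"p{i:02d}" for i in range(n_proteins)]
    genome_of = {p: genomes[rng.integers(n_genomes)] for p in pids}
    rows = []
    for i in range(n_proteins):
        for j in range(i + 1, n_proteins):
            if rng.random() < 0.45:
                score = float(rng.integers(20, 200))
                for q, s in ((pids[i], pids[j]), (pids[j], pids[i])):
                    rows.append(
                        dict(
                            qseqid=q, sseqid=s, bitscore=score,
                            qgenome=genome_of[q], sgenome=genome_of[s],
                            evalue=1e-10, qcov=1.0, scov=1.0,
                        )
                    )
    return pd.DataFrame(
        rows, columns=["qseqid", "sseqid", "bitscore", "qgenome", "sgenome",
                       "evalue", "qcov", "scov"]
    ), genome_of
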