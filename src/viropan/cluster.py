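"""Homolog clustering: BBH edges, COG triangles, in-paralogs, orphans.

The clustering rule follows the COG-triangles idea: bidirectional best hits
(BBH) between genomes are the only evidence considered; three proteins from
three distinct genomes that are pairwise BBH form a seed triangle, and
triangles sharing an edge are merged transitively into clusters.  Around
that core rule sit the steps a real family needs:

* *pair rescue* — BBH pairs (or chains) in no triangle become small
  clusters, so two-genome occupancy (cloud) is representable;
* *attachment* — proteins left over after triangle/pair clustering join the
  cluster of their best remaining filtered hit; this is what gathers
  within-genome paralog copies, whose cross-genome best hits are shadowed
  by the ortholog copy;
* *paralog groups* — leftover proteins whose only filtered hits are to each
  other (in practice same-genome duplicate pairs) form occupancy-1
  clusters;
* *orphans* — everything else becomes a singleton cluster.

Within each cluster and genome, the member with the highest summed bit
score to the cluster's other-genome members is the ortholog; any other
same-genome member is an in-paralog.  Ties break on the lexicographically
smallest protein id, and cluster ids are assigned by sorted smallest
member, so the whole stage is deterministic.
"""

from __future__ import annotations

import math
import re
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np
import pandas as pd
import biotite.sequence.align as balign

from .scoring import STANDARD_AA, ScoringScheme, as_protein, sanitize
from .simulate import BACKGROUND

ROLE_ORTHOLOG = "ortholog"
ROLE_INPARALOG = "inparalog"
ROLE_ORPHAN = "orphan"

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


class _DSU:
    def __init__(self) -> None:
        self.parent: dict = {}

    def find(self, x):
        parent = self.parent
        parent.setdefault(x, x)
        root = x
        while parent[root] != root:
            root = parent[root]
        while parent[x] != root:
            parent[x], x = root, parent[x]
        return root

    def union(self, a, b) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def best_hits(hits: pd.DataFrame) -> dict[tuple[str, str], tuple[str, float]]:
    """Best cross-genome hit per (query protein, subject genome).

    Best = highest bit score; ties broken by lexicographically smallest
    subject id.
    """
    cross = hits[hits["qgenome"] != hits["sgenome"]]
    ordered = cross.sort_values(
        ["qseqid", "sgenome", "bitscore", "sseqid"],
        ascending=[True, True, False, True],
        kind="mergesort",
    ).drop_duplicates(["qseqid", "sgenome"])
    return {
        (q, sg): (s, b)
        for q, sg, s, b in zip(
            ordered["qseqid"], ordered["sgenome"], ordered["sseqid"], ordered["bitscore"]
        )
    }


def bbh_edges(hits: pd.DataFrame) -> pd.DataFrame:
    """Mutual-best-hit edges between genomes.

    Columns: ``protein_a, protein_b, genome_a, genome_b, score`` with
    ``protein_a < protein_b``; ``score`` is the supporting hit's bit score.
    """
    best = best_hits(hits)
    genome = dict(zip(hits["qseqid"], hits["qgenome"]))
    genome.update(zip(hits["sseqid"], hits["sgenome"]))
    rows = []
    for (q, sg), (s, bit) in best.items():
        if q >= s:
            continue
        qg = genome[q]
        mutual = best.get((s, qg))
        if mutual is not None and mutual[0] == q:
            rows.append((q, s, qg, sg, max(bit, mutual[1])))
    edges = pd.DataFrame(
        rows, columns=["protein_a", "protein_b", "genome_a", "genome_b", "score"]
    )
    return edges.sort_values(["protein_a", "protein_b"], kind="mergesort").reset_index(drop=True)


def cog_triangles(edges: pd.DataFrame, genome_of: Mapping[str, str]) -> list[set[str]]:
    """Clusters from three-genome BBH triangles merged on shared edges.

    A triangle is three proteins from three distinct genomes, pairwise
    connected by BBH edges.  Any two triangles sharing an edge belong to the
    same cluster (transitively); proteins in no triangle stay unassigned.
    """
    adj: dict[str, set[str]] = {}
    for a, b in zip(edges["protein_a"], edges["protein_b"]):
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    dsu = _DSU()
    triangle_edges: set[frozenset[str]] = set()
    for a, b in zip(edges["protein_a"], edges["protein_b"]):
        common = adj[a] & adj[b]
        for c in common:
            if genome_of[c] in (genome_of[a], genome_of[b]):
                continue
            e_ab, e_ac, e_bc = (
                frozenset((a, b)), frozenset((a, c)), frozenset((b, c)),
            )
            triangle_edges.update((e_ab, e_ac, e_bc))
            dsu.union(e_ab, e_ac)
            dsu.union(e_ab, e_bc)
    components: dict = {}
    for edge in triangle_edges:
        components.setdefault(dsu.find(edge), set()).update(edge)
    return sorted(components.values(), key=lambda c: min(c))


def _components(pairs: Iterable[tuple[str, str]]) -> list[set[str]]:
    dsu = _DSU()
    nodes = set()
    for a, b in pairs:
        dsu.union(a, b)
        nodes.update((a, b))
    comps: dict = {}
    for n in nodes:
        comps.setdefault(dsu.find(n), set()).add(n)
    return sorted(comps.values(), key=lambda c: min(c))


def build_clusters(
    hits: pd.DataFrame, proteomes: Mapping[str, list[tuple[str, str]]]
) -> pd.DataFrame:
    """Full clustering of a family; returns the membership table.

    Columns: ``cluster_id, protein_id, genome_id, role``.  Every protein of
    the family appears exactly once (orphans as singleton clusters); roles
    are assigned by :func:`detect_inparalogs`.
    """
    genome_of = {
        pid: g for g, prots in proteomes.items() for pid, _ in prots
    }
    all_pids = sorted(genome_of)

    edges = bbh_edges(hits)
    clusters = cog_triangles(edges, genome_of)
    assigned = {pid for cl in clusters for pid in cl}

    # BBH pairs outside any triangle: components of the remaining BBH graph
    # (usually two-genome pairs) become small clusters.
    leftover_edges = [
        (a, b)
        for a, b in zip(edges["protein_a"], edges["protein_b"])
        if a not in assigned and b not in assigned
    ]
    for comp in _components(leftover_edges):
        clusters.append(comp)
        assigned |= comp

    # Attach remaining proteins to the cluster of their best filtered hit.
    cluster_of = {pid: i for i, cl in enumerate(clusters) for pid in cl}
    pending = [p for p in all_pids if p not in assigned]
    ranked = hits.sort_values(
        ["bitscore", "sseqid"], ascending=[False, True], kind="mergesort"
    )
    by_query: dict[str, list[str]] = {}
    for q, s in zip(ranked["qseqid"], ranked["sseqid"]):
        by_query.setdefault(q, []).append(s)
    changed = True
    while changed and pending:
        changed = False
        still = []
        for pid in pending:
            target = next(
                (cluster_of[s] for s in by_query.get(pid, []) if s in cluster_of),
                None,
            )
            if target is None:
                still.append(pid)
            else:
                clusters[target].add(pid)
                cluster_of[pid] = target
                assigned.add(pid)
                changed = True
        pending = still

    # Leftover proteins connected only to each other (same-genome duplicate
    # pairs, typically) form occupancy-1 clusters.
    residual_pairs = [
        (q, s)
        for q, s in zip(hits["qseqid"], hits["sseqid"])
        if q not in assigned and s not in assigned and q < s
    ]
    for comp in _components(residual_pairs):
        clusters.append(comp)
        assigned |= comp

    for pid in all_pids:  # orphans
        if pid not in assigned:
            clusters.append({pid})

    clusters.sort(key=lambda c: min(c))
    rows = []
    for i, cl in enumerate(clusters):
        cid = f"cls{i:05d}"
        for pid in sorted(cl):
            role = ROLE_ORPHAN if len(cl) == 1 else ROLE_ORTHOLOG
            rows.append((cid, pid, genome_of[pid], role))
    membership = pd.DataFrame(
        rows, columns=["cluster_id", "protein_id", "genome_id", "role"]
    )
    return detect_inparalogs(membership, hits)


def detect_inparalogs(membership: pd.DataFrame, hits: pd.DataFrame) -> pd.DataFrame:
    """Partition each cluster's members into orthologs and in-paralogs.

    Within a cluster and genome, the ortholog is the member with the highest
    summed bit score to the cluster's other-genome members (ties:
    lexicographically smallest protein id); the rest are in-paralogs.
    Singleton clusters keep the orphan role.
    """
    membership = membership.copy()
    score: dict[tuple[str, str], float] = {}
    for q, s, b in zip(hits["qseqid"], hits["sseqid"], hits["bitscore"]):
        key = (q, s)
        if b > score.get(key, -math.inf):
            score[key] = b

    for cid, group in membership.groupby("cluster_id"):
        if len(group) == 1:
            continue
        members = list(zip(group.index, group["protein_id"], group["genome_id"]))
        for genome in sorted({g for _, _, g in members}):
            same = [(idx, pid) for idx, pid, g in members if g == genome]
            if len(same) == 1:
                membership.loc[same[0][0], "role"] = ROLE_ORTHOLOG
                continue
            others = [pid for _, pid, g in members if g != genome]
            ranked = sorted(
                same,
                key=lambda item: (
                    -sum(score.get((item[1], o), 0.0) for o in others),
                    item[1],
                ),
            )
            membership.loc[ranked[0][0], "role"] = ROLE_ORTHOLOG
            for idx, _ in ranked[1:]:
                membership.loc[idx, "role"] = ROLE_INPARALOG
    return membership


def separate_orphans(membership: pd.DataFrame) -> pd.DataFrame:
    """Rows of the membership table that are singleton (orphan) clusters."""
    sizes = membership.groupby("cluster_id")["protein_id"].transform("size")
    return membership[sizes == 1].reset_index(drop=True)


def cluster_labels(membership: pd.DataFrame) -> pd.Series:
    """Protein -> cluster id, for comparison against a planted truth."""
    return membership.set_index("protein_id")["cluster_id"]


def global_identity(a: str, b: str) -> float:
    """Global (end-to-end) alignment identity: matches / alignment columns."""
    res = edlib.align(sanitize(a), sanitize(b), mode="NW", task="path")
    cols = sum(int(n) for n, _ in _CIGAR_RE.findall(res["cigar"]))
    return (cols - res["editDistance"]) / cols


def redundancy_filter(
    sequences: Sequence[tuple[str, str]], identity_threshold: float = 0.80
) -> list[str]:
    """Greedy redundancy removal at a global-identity threshold.

    Sequences are visited longest-first (ties: smallest id); a sequence is
    discarded when its global identity to an already retained representative
    strictly exceeds the threshold ("greater than 80%"), so a pair at
    exactly the threshold is kept whole.  Returns retained ids, input order
    of the greedy sweep.
    """
    order = sorted(sequences, key=lambda item: (-len(item[1]), item[0]))
    retained: list[tuple[str, str]] = []
    for pid, seq in order:
        if any(global_identity(seq, rep) > identity_threshold for _, rep in retained):
            continue
        retained.append((pid, seq))
    return [pid for pid, _ in retained]


def build_pssm(
    members: Sequence[tuple[str, str]],
    scheme: ScoringScheme | None = None,
    pseudocount: float = 1.0,
) -> tuple[str, np.ndarray]:
    """Position-specific scoring matrix from a star alignment of a cluster.

    The longest member (ties: smallest id) is the representative; every
    other member is locally aligned to it, and residues aligned to each
    representative position are counted.  Scores are natural-log odds
    against the Robinson–Robinson background, so the matrix's own
    Karlin–Altschul lambda is 1 by the standard scaling identity.

    Returns ``(representative_id, pssm)`` with ``pssm`` of shape
    ``(len(representative), 20)`` in ``STANDARD_AA`` order.
    """
    if len(members) < 2:
        raise ValueError("cannot build a profile from a single-member cluster")
    scheme = scheme or ScoringScheme()
    rep_id, rep_seq = sorted(members, key=lambda item: (-len(item[1]), item[0]))[0]
    aa_index = {a: i for i, a in enumerate(STANDARD_AA)}
    counts = np.zeros((len(rep_seq), 20))
    for i, res in enumerate(sanitize(rep_seq)):
        if res in aa_index:
            counts[i, aa_index[res]] += 1
    for pid, seq in members:
        if pid == rep_id:
            continue
        aln = balign.align_optimal(
            as_protein(rep_seq), as_protein(seq), scheme.matrix,
            gap_penalty=scheme.gap_penalty, local=True, max_number=1,
        )[0]
        if aln.score <= 0:
            continue
        for qpos, spos in aln.trace:
            if qpos >= 0 and spos >= 0:
                res_s = sanitize(seq)[spos]
                if res_s in aa_index:
                    counts[qpos, aa_index[res_s]] += 1
    totals = counts.sum(axis=1, keepdims=True)
    freqs = (counts + pseudocount * BACKGROUND[None, :]) / (totals + pseudocount)
    return rep_id, np.log(freqs / BACKGROUND[None, :])


def pssm_best_segment(pssm: np.ndarray, sequence: str) -> float:
    """Best ungapped segment score of ``sequence`` against the profile."""
    aa_index = {a: i for i, a in enumerate(STANDARD_AA)}
    seq = sanitize(sequence)
    cols = np.array([aa_index.get(c, -1) for c in seq])
    valid = cols >= 0
    score_mat = np.where(valid[None, :], pssm[:, np.clip(cols, 0, 19)], 0.0)
    best = 0.0
    n_pos, n_seq = score_mat.shape
    for offset in range(-(n_pos - 1), n_seq):
        diag = np.diagonal(score_mat, offset=offset)
        if diag.size == 0:
            continue
        # maximum-subarray (Kadane) on this diagonal
        csum = np.cumsum(diag)
        prefix_min = np.minimum.accumulate(np.concatenate(([0.0], csum[:-1])))
        best = max(best, float((csum - prefix_min).max(initial=0.0)))
    return best


def pssm_rescue(
    members: Sequence[tuple[str, str]],
    unassigned: Sequence[tuple[str, str]],
    scheme: ScoringScheme | None = None,
    max_evalue: float = 1e-3,
) -> pd.DataFrame:
    """Score unassigned proteins against a cluster profile; rescue E < cutoff.

    A simplified stand-in for profile-HMM search over distant homologs: the
    cluster PSSM (lambda = 1) scores each candidate's best ungapped segment
    and ``E = K * m * n * exp(-S)`` decides membership at the same cutoff
    semantics used by profile searches (default ``E < 1e-3``).

    Returns a DataFrame ``protein_id, score, evalue, rescued``.
    """
    scheme = scheme or ScoringScheme()
    _, pssm = build_pssm(members, scheme)
    rows = []
    for pid, seq in unassigned:
        s = pssm_best_segment(pssm, seq)
        ev = scheme.kappa * pssm.shape[0] * len(seq) * math.exp(-s)
        rows.append((pid, s, ev, ev < max_evalue))
    return pd.DataFrame(rows, columns=["protein_id", "score", "evalue", "rescued"])
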