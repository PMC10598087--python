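"""Synthetic per-family proteome sets with planted pangenome structure.

Real viral-family pangenomes are built from public proteome snapshots that
cannot be bundled or re-downloaded reproducibly, so every downstream stage
is exercised on simulated families instead.  A family is a star phylogeny:
each planted homolog cluster has one ancestor sequence, and every genome in
the cluster's occupancy set receives an independently mutated copy.
Occupancy is planted directly in the three pangenome compartments —
core (present in >= 95% of genomes), shell (intermediate), and cloud
(1–2 genomes) — plus within-genome paralog copies and per-genome orphan
proteins with no homolog anywhere.

The ground truth (protein -> planted cluster) is returned as a tidy table so
that recovered clusterings can be scored against it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
import numpy as np
import pandas as pd

from .scoring import STANDARD_AA, default_matrix

ORPHAN = "ORPHAN"

# Robinson & Robinson amino-acid background frequencies, in STANDARD_AA order.
_RR_FREQS = {
    "A": 0.07805, "C": 0.01925, "D": 0.05364, "E": 0.06295, "F": 0.03856,
    "G": 0.07377, "H": 0.02199, "I": 0.05142, "K": 0.05744, "L": 0.09019,
    "M": 0.02243, "N": 0.04487, "P": 0.05203, "Q": 0.04264, "R": 0.05129,
    "S": 0.07120, "T": 0.05841, "V": 0.06441, "W": 0.01330, "Y": 0.03216,
}
BACKGROUND = np.array([_RR_FREQS[a] for a in STANDARD_AA])
BACKGROUND = BACKGROUND / BACKGROUND.sum()


def _substitution_kernel() -> np.ndarray:
    """Conditional target distribution P(b | a), b != a, for substitutions.

    Weights are ``p_b * exp(lambda_u * s(a, b))`` with the BLOSUM62 score
    ``s`` in half-bit units (``lambda_u = ln2 / 2``), so mutated residues
    stay detectable by the same matrix used in the search stage.
    """
    mat = default_matrix()
    alph = mat.get_alphabet1()
    idx = [alph.encode(a) for a in STANDARD_AA]
    scores = mat.score_matrix()[np.ix_(idx, idx)].astype(float)
    lam_u = math.log(2) / 2
    w = BACKGROUND[None, :] * np.exp(lam_u * scores)
    np.fill_diagonal(w, 0.0)
    return w / w.sum(axis=1, keepdims=True)

_KERNEL = _substitution_kernel()
_AA_INDEX = {a: i for i, a in enumerate(STANDARD_AA)}


@dataclass(frozen=True)
class FamilySpec:
    """Parameters of one simulated viral family.

    ``divergence`` is the expected proportion of substituted positions
    between any two members of a cluster (pairwise, not per branch);
    ``paralog_rate`` is the probability of one extra same-genome copy per
    cluster-genome incidence; ``indel_rate`` is the per-position single
    residue insertion/deletion probability on each branch.
    """

    n_genomes: int
    n_core: int
    n_shell: int
    n_cloud: int
    paralog_rate: float = 0.0
    orphan_per_genome: int = 0
    seq_length_range: tuple[int, int] = (100, 200)
    divergence: float = 0.15
    indel_rate: float = 0.0
    seed: int = 0
    core_fraction: float = 0.95

    def __post_init__(self) -> None:
        if self.n_genomes < 3:
            raise ValueError("a family needs at least 3 genomes")
        if not 0 <= self.divergence <= 0.7:
            raise ValueError("divergence must lie in [0, 0.7]")
        if not 0 <= self.paralog_rate <= 1:
            raise ValueError("paralog_rate must lie in [0, 1]")
        if not 0 <= self.indel_rate < 0.5:
            raise ValueError("indel_rate must lie in [0, 0.5)")
        lo, hi = self.seq_length_range
        if not 1 <= lo <= hi:
            raise ValueError("invalid seq_length_range")
        if min(self.n_core, self.n_shell, self.n_cloud, self.orphan_per_genome) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def genome_ids(self) -> list[str]:
        return [f"g{i:02d}" for i in range(self.n_genomes)]

    @property
    def core_min_occupancy(self) -> int:
        return math.ceil(self.core_fraction * self.n_genomes)


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, *key]))


def random_protein(length: int, rng: np.random.Generator) -> str:
    """Draw an i.i.d. sequence from the Robinson–Robinson background."""
    return "".join(np.array(list(STANDARD_AA))[rng.choice(20, size=length, p=BACKGROUND)])


def mutate_sequence(
    ancestor: str,
    divergence: float,
    indel_rate: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> str:
    """Mutate ``ancestor``: substitutions at rate ``divergence``, then indels.

    Each position is substituted with probability ``divergence``; the target
    residue is drawn from the BLOSUM62-derived conditional distribution over
    the 19 other residues, so the realized substituted fraction is binomial
    with mean ``divergence``.  Indels are single-residue, each position
    suffering a deletion or gaining an insertion with probability
    ``indel_rate / 2`` apiece.  Deterministic for a fixed seed.
    """
    if not ancestor:
        raise ValueError("ancestor sequence is empty")
    if not 0 <= divergence <= 1:
        raise ValueError("divergence must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else _rng(int(seed), 0xA1)
    residues = list(ancestor)
    sub_mask = rng.random(len(residues)) < divergence
    for i in np.flatnonzero(sub_mask):
        src = _AA_INDEX[residues[i]]
        residues[i] = STANDARD_AA[rng.choice(20, p=_KERNEL[src])]
    if indel_rate > 0:
        out: list[str] = []
        for res in residues:
            r = rng.random()
            if r < indel_rate / 2:
                continue  # deletion
            out.append(res)
            if r > 1 - indel_rate / 2:
                out.append(STANDARD_AA[rng.choice(20, p=BACKGROUND)])
        residues = out if out else [residues[0]]
    return "".join(residues)


def plant_occupancy(spec: FamilySpec) -> dict[str, tuple[str, ...]]:
    """Assign each planted cluster the genome subset it will occupy.

    Core clusters draw occupancy uniformly from ``[ceil(0.95 N), N]``, cloud
    from ``{1, 2}``, and shell from the intermediate interval
    ``[3, ceil(0.95 N) - 1]``.  For very small families that interval can be
    empty (e.g. N = 3: core needs all 3 genomes and cloud covers 1–2), in
    which case requesting shell clusters is an error.
    """
    rng = _rng(spec.seed, 0x0C)
    n = spec.n_genomes
    core_min = spec.core_min_occupancy
    shell_lo, shell_hi = 3, core_min - 1
    if spec.n_shell > 0 and shell_lo > shell_hi:
        raise ValueError(
            f"shell occupancy interval [{shell_lo}, {shell_hi}] is empty for "
            f"{n} genomes (core needs >= {core_min}, cloud covers 1-2); "
            "set n_shell = 0 or add genomes"
        )
    genomes = np.array(spec.genome_ids)
    occupancy: dict[str, tuple[str, ...]] = {}

    def draw(cluster_id: str, size: int) -> None:
        members = rng.choice(genomes, size=size, replace=False)
        occupancy[cluster_id] = tuple(sorted(members))

    for i in range(spec.n_core):
        draw(f"core{i:04d}", int(rng.integers(core_min, n + 1)))
    for i in range(spec.n_shell):
        draw(f"shell{i:04d}", int(rng.integers(shell_lo, shell_hi + 1)))
    for i in range(spec.n_cloud):
        draw(f"cloud{i:04d}", int(rng.integers(1, min(2, n) + 1)))
    return occupancy


def generate_family(
    spec: FamilySpec,
) -> tuple[dict[str, list[tuple[str, str]]], pd.DataFrame]:
    """Generate one family: per-genome protein lists plus the truth table.

    Returns ``(proteomes, truth)`` where ``proteomes[genome_id]`` is a list
    of ``(protein_id, sequence)`` and ``truth`` has one row per generated
    protein with columns ``protein_id, genome_id, cluster_id, is_paralog``
    (``cluster_id == "ORPHAN"`` for planted orphans).

    Pairwise divergence ``D`` between cluster members is realized on the
    star phylogeny with per-branch substitution fraction
    ``p = 1 - sqrt(1 - D)`` (two independent branches of rate ``p`` differ
    at ~``1 - (1-p)^2`` of positions).  Paralog copies mutate from their
    genome's ortholog copy at rate ``p / 2``, which keeps in-paralogs
    scoring higher within-genome than between genomes.
    """
    occupancy = plant_occupancy(spec)
    rng = _rng(spec.seed, 0x5E)
    p_branch = 1.0 - math.sqrt(1.0 - spec.divergence)
    lo, hi = spec.seq_length_range

    proteomes: dict[str, list[tuple[str, str]]] = {g: [] for g in spec.genome_ids}
    rows: list[tuple[str, str, str, bool]] = []
    counters = {g: 0 for g in spec.genome_ids}

    def add(genome: str, seq: str, cluster: str, is_paralog: bool) -> None:
        pid = f"{genome}_{counters[genome]:04d}"
        counters[genome] += 1
        proteomes[genome].append((pid, seq))
        rows.append((pid, genome, cluster, is_paralog))

    for cluster_id in sorted(occupancy):
        length = int(rng.integers(lo, hi + 1))
        ancestor = random_protein(length, rng)
        for genome in occupancy[cluster_id]:
            ortholog = mutate_sequence(ancestor, p_branch, spec.indel_rate, rng)
            add(genome, ortholog, cluster_id, False)
            if rng.random() < spec.paralog_rate:
                paralog = mutate_sequence(ortholog, p_branch / 2, spec.indel_rate, rng)
                add(genome, paralog, cluster_id, True)
    for genome in spec.genome_ids:
        for _ in range(spec.orphan_per_genome):
            length = int(rng.integers(lo, hi + 1))
            add(genome, random_protein(length, rng), ORPHAN, False)

    truth = pd.DataFrame(rows, columns=["protein_id", "genome_id", "cluster_id", "is_paralog"])
    return proteomes, truth


def planted_labels(truth: pd.DataFrame) -> pd.Series:
    """Protein -> planted cluster label, with each orphan its own singleton."""
    labels = truth.set_index("protein_id")["cluster_id"].copy()
    orphan_mask = labels == ORPHAN
    labels[orphan_mask] = ["orphan_" + pid for pid in labels.index[orphan_mask]]
    return labels


def planted_compartments(
    truth: pd.DataFrame, core_fraction: float = 0.95, cloud_max_occupancy: int = 2
) -> pd.Series:
    """Compartment counts implied by the truth table.

    Every planted cluster — and every orphan, as an occupancy-1 singleton —
    is labelled core/shell/cloud by occupancy (distinct genomes), using the
    same definitions as the recovered partition.
    """
    labels = planted_labels(truth)
    occ = (
        truth.assign(label=labels.loc[truth["protein_id"]].to_numpy())
        .groupby("label")["genome_id"]
        .nunique()
    )
    n = truth["genome_id"].nunique()
    core_min = math.ceil(core_fraction * n)
    comp = pd.Series(
        np.where(occ >= core_min, "core", np.where(occ <= cloud_max_occupancy, "cloud", "shell")),
        index=occ.index,
    )
    return comp.value_counts().reindex(["core", "shell", "cloud"], fill_value=0)


def with_seed(spec: FamilySpec, seed: int) -> FamilySpec:
    """Copy of ``spec`` with a different seed."""
    return replace(spec, seed=seed)
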