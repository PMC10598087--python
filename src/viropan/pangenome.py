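"""Presence–absence matrix and core/shell/cloud partitioning.

The pangenome of a viral family is partitioned with thresholds adapted to
the divergent nature of viral sequences: the *core* holds clusters present
in at least 95% of the family's genomes (core + softcore together), the
*cloud* holds clusters present in only one or two genomes, and the *shell*
is everything in between.  With integer genome counts "at least 95%" means
occupancy >= ceil(0.95 N); the precedence order is core, then cloud, then
shell (for N >= 3 the core and cloud conditions cannot overlap).  Families
with fewer than three proteomes are excluded outright.

Occupancy counts distinct genomes, so paralog copies never inflate it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
import numpy as np
import pandas as pd

CORE, SHELL, CLOUD = "core", "shell", "cloud"


@dataclass(frozen=True)
class PartitionPolicy:
    """Compartment thresholds (defaults are the standard adapted values)."""

    core_fraction: float = 0.95
    cloud_max_occupancy: int = 2
    min_genomes: int = 3

    def __post_init__(self) -> None:
        if not 0 < self.core_fraction <= 1:
            raise ValueError("core_fraction must lie in (0, 1]")
        if self.cloud_max_occupancy < 1:
            raise ValueError("cloud_max_occupancy must be >= 1")

    def core_min(self, n_genomes: int) -> int:
        return math.ceil(self.core_fraction * n_genomes)


def validate_family(
    genomes: list[str], policy: PartitionPolicy | None = None
) -> bool:
    """Whether a family has enough proteomes for pangenome analysis."""
    policy = policy or PartitionPolicy()
    return len(genomes) >= policy.min_genomes


def presence_matrix(
    membership: pd.DataFrame, genomes: list[str] | None = None
) -> pd.DataFrame:
    """Cluster x genome member-count matrix (0 = absent).

    ``membership`` is the clustering output (``cluster_id, protein_id,
    genome_id, role``).  Passing ``genomes`` explicitly keeps columns for
    genomes that ended up with no clustered proteins.
    """
    counts = (
        membership.groupby(["cluster_id", "genome_id"]).size().unstack(fill_value=0)
    )
    if genomes is not None:
        counts = counts.reindex(columns=sorted(genomes), fill_value=0)
    return counts.sort_index()


def partition(
    matrix: pd.DataFrame, policy: PartitionPolicy | None = None
) -> pd.Series:
    """Label every cluster core / shell / cloud from its occupancy.

    Core iff occupancy >= ceil(core_fraction * N); otherwise cloud iff
    occupancy <= cloud_max_occupancy; otherwise shell.
    """
    policy = policy or PartitionPolicy()
    if matrix.empty:
        raise ValueError("empty presence-absence matrix")
    n = matrix.shape[1]
    if n < policy.min_genomes:
        raise ValueError(
            f"family has {n} proteomes; fewer than {policy.min_genomes} are excluded"
        )
    occupancy = (matrix > 0).sum(axis=1)
    core_min = policy.core_min(n)
    labels = np.where(
        occupancy >= core_min,
        CORE,
        np.where(occupancy <= policy.cloud_max_occupancy, CLOUD, SHELL),
    )
    return pd.Series(labels, index=matrix.index, name="compartment")


def summarize(
    membership: pd.DataFrame, labels: pd.Series, family: str = "family"
) -> pd.DataFrame:
    """Per-family compartment summary in the style of a cluster-accounting table.

    One row per family with total proteins, total clusters, and per
    compartment the number of clusters and the number of in-paralog
    sequences they contain.
    """
    lab = labels.loc[membership["cluster_id"]].to_numpy()
    df = membership.assign(compartment=lab)
    row: dict[str, object] = {
        "family": family,
        "n_genomes": df["genome_id"].nunique(),
        "total_proteins": len(df),
        "total_clusters": df["cluster_id"].nunique(),
    }
    for comp in (CORE, SHELL, CLOUD):
        sub = df[df["compartment"] == comp]
        row[f"{comp}_clusters"] = sub["cluster_id"].nunique()
        row[f"{comp}_inparalogs"] = int((sub["role"] == "inparalog").sum())
    return pd.DataFrame([row])


def compartment_counts(labels: pd.Series) -> pd.Series:
    """Cluster counts per compartment, in core/shell/cloud order."""
    return labels.value_counts().reindex([CORE, SHELL, CLOUD], fill_value=0)
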