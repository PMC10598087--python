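"""Screening pangenome clusters for oxygen-dependent enzyme domains.

A fixed catalog of strictly O2-dependent enzyme families, keyed by Pfam id
(ribonucleotide reductase R2, Erv1/Alr sulfhydryl oxidases, the 2OG-Fe(II)
oxygenase superfamily, Cu/Zn superoxide dismutase, and others), is matched
against the Pfam annotations of every family's clusters.  The result is a
Table-2-style matrix — enzyme family x viral family, each cell showing the
most conserved compartment where the domain occurs (Core > Shell > Cloud,
"x" if absent) — plus a long-format companion that retains every
(pfam, family, cluster, compartment) placement.

The catalog is authoritative: no oxygen dependence is inferred from
sequence.
"""

from __future__ import annotations

import warnings
from importlib import resources
from typing import Mapping

import pandas as pd

_PRECEDENCE = {"core": 0, "shell": 1, "cloud": 2}
_CELL = {"core": "Core", "shell": "Shell", "cloud": "Cloud"}
ABSENT = "x"


def load_catalog(path=None) -> pd.DataFrame:
    """The packaged oxygen-dependent enzyme catalog (or a user TSV)."""
    if path is None:
        path = resources.files("viropan") / "data" / "oxygen_catalog.tsv"
    catalog = pd.read_csv(path, sep="\t", comment="#")
    if catalog["pfam_id"].duplicated().any():
        raise ValueError("catalog Pfam ids must be unique")
    return catalog


def extract_oxy(
    per_family: Mapping[str, tuple[Mapping[str, frozenset[str]], pd.Series]],
    catalog: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tabulate catalog Pfams across families and compartments.

    ``per_family`` maps family name -> (cluster Pfam sets, cluster
    compartment labels).  Returns ``(matrix, long_table)``: the matrix has
    one row per catalog Pfam and one column per family with cells from
    {Core, Shell, Cloud, x}; the long table lists every placement with
    columns ``pfam_id, family, cluster_id, compartment``.
    """
    catalog = catalog if catalog is not None else load_catalog()
    families = sorted(per_family)
    long_rows = []
    for family in families:
        pfams_by_cluster, labels = per_family[family]
        for cid, pfams in sorted(pfams_by_cluster.items()):
            for pfam in sorted(pfams & set(catalog["pfam_id"])):
                long_rows.append((pfam, family, cid, labels[cid]))
    long_table = pd.DataFrame(
        long_rows, columns=["pfam_id", "family", "cluster_id", "compartment"]
    )

    matrix = pd.DataFrame(ABSENT, index=catalog["pfam_id"], columns=families)
    seen = set(long_table["pfam_id"])
    for pfam in catalog["pfam_id"]:
        if pfam not in seen:
            continue
        sub = long_table[long_table["pfam_id"] == pfam]
        for family, grp in sub.groupby("family"):
            best = min(grp["compartment"], key=_PRECEDENCE.__getitem__)
            matrix.loc[pfam, family] = _CELL[best]
    missing = set(catalog["pfam_id"]) - seen
    if missing and len(long_table):
        warnings.warn(
            f"catalog Pfams absent from all clusters: {sorted(missing)}",
            stacklevel=2,
        )
    return matrix, long_table


def count_oxy_clusters(long_table: pd.DataFrame) -> int:
    """Number of distinct (family, cluster) pairs carrying a catalog Pfam."""
    if long_table.empty:
        return 0
    return int(long_table.drop_duplicates(["family", "cluster_id"]).shape[0])
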