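"""Extended COG functional categories for pangenome clusters.

Clusters are mapped to one-letter COG categories through a Pfam -> category
table.  The classical vocabulary covers four general functions —
information storage and processing (A, B, J, K, L), cellular processes and
signaling (D, M, N, O, T, U, V, W, Y, Z), metabolism (C, E, F, G, H, I, P,
Q), and poorly characterized (R, S) — extended with two viral categories:
X for miscellaneous clusters whose domains span several unrelated general
functions, and Vc for capsid/virion-related clusters with no cellular
counterpart.

The Pfam -> category map and the cluster V/A/B/E domain-of-life flags are
plain input tables, not live database queries; the packaged copies are
small synthetic examples.
"""

from __future__ import annotations

from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd

INFORMATION = frozenset("ABJKL")
CELLULAR = frozenset("DMNOTUVWYZ")
METABOLISM = frozenset("CEFGHIPQ")
POORLY_CHARACTERIZED = frozenset("RS")
VOCABULARY = INFORMATION | CELLULAR | METABOLISM | POORLY_CHARACTERIZED | {"X", "Vc"}

#: Display order for heatmap rows.
LETTER_ORDER = [*"ABJKL", *"DMNOTUVWYZ", *"CEFGHIPQ", "R", "S", "X", "Vc"]

_GENERAL_GROUPS = {
    "information": INFORMATION,
    "cellular": CELLULAR,
    "metabolism": METABOLISM,
}


def load_category_map(path=None) -> dict[str, frozenset[str]]:
    """Read a Pfam -> COG-letter table (columns ``pfam_id``, ``category``).

    Multiple rows per Pfam accumulate into a letter set.  Letters outside
    the closed vocabulary are an error.  Without a path, the packaged
    synthetic example table is loaded.
    """
    if path is None:
        path = resources.files("viropan") / "data" / "example_pfam_to_cog.tsv"
    df = pd.read_csv(path, sep="\t", comment="#")
    mapping: dict[str, set[str]] = {}
    for pfam, letter in zip(df["pfam_id"], df["category"]):
        letter = str(letter)
        if letter not in VOCABULARY:
            raise ValueError(f"unknown COG category letter {letter!r} for {pfam}")
        mapping.setdefault(pfam, set()).add(letter)
    return {k: frozenset(v) for k, v in mapping.items()}


def cluster_pfams(
    membership: pd.DataFrame, annotations: pd.DataFrame
) -> dict[str, frozenset[str]]:
    """Union of member Pfam ids per cluster.

    ``annotations`` maps proteins to Pfam ids (columns ``protein_id``,
    ``pfam_id``); unannotated clusters get an empty set.
    """
    merged = membership.merge(annotations, on="protein_id", how="left")
    out: dict[str, frozenset[str]] = {}
    for cid, group in merged.groupby("cluster_id"):
        pfams = group["pfam_id"].dropna()
        out[cid] = frozenset(pfams)
    return out


def assign_category(
    pfam_ids: frozenset[str] | set[str],
    category_map: Mapping[str, frozenset[str]],
    cellular_flags: tuple[bool, bool, bool] | None = None,
    capsid: bool = False,
) -> frozenset[str]:
    """Category letters of one cluster.

    Rules, in order: a cluster with no identifiers at all is unknown (S); a
    cluster absent from every cellular domain (A/B/E flags all false) with a
    capsid/virion-associated annotation is capsid-related (Vc); identifiers
    that map to nothing are hypothetical (R); letters spanning two or more
    general-function groups with no majority group collapse to
    miscellaneous (X); otherwise the mapped letters stand.
    """
    if not pfam_ids:
        return frozenset({"S"})
    if capsid and cellular_flags is not None and not any(cellular_flags):
        return frozenset({"Vc"})
    letters: set[str] = set()
    for pfam in pfam_ids:
        letters |= category_map.get(pfam, frozenset())
    if not letters:
        return frozenset({"R"})
    spanned = [g for g in _GENERAL_GROUPS.values() if letters & g]
    if len(spanned) >= 2:
        biggest = max(len(letters & g) for g in spanned)
        if biggest <= len(letters) / 2:
            return frozenset({"X"})
    return frozenset(letters)


def heatmap_matrix(
    assignments: Mapping[str, frozenset[str]],
    labels: pd.Series,
    families: Mapping[str, str],
) -> pd.DataFrame:
    """log10-normalized category x (family, compartment) count matrix.

    Entries are ``log10(count + 1)`` so absent categories sit at exactly 0
    and the raw integer counts stay recoverable as ``10**v - 1``.
    """
    rows = []
    for cid, letters in assignments.items():
        for letter in letters:
            rows.append((letter, families[cid], labels[cid]))
    counts = (
        pd.DataFrame(rows, columns=["category", "family", "compartment"])
        .value_counts()
        .unstack(["family", "compartment"], fill_value=0)
        if rows
        else pd.DataFrame()
    )
    counts = counts.reindex(LETTER_ORDER, fill_value=0)
    return np.log10(counts.astype(float) + 1.0)


def invert_heatmap(matrix: pd.DataFrame) -> pd.DataFrame:
    """Recover the integer counts from a log10(count + 1) matrix."""
    return (np.power(10.0, matrix) - 1.0).round().astype(int)


def domain_distribution(flags: pd.DataFrame) -> pd.DataFrame:
    """Cluster counts and percentages per domain of life.

    ``flags`` is indexed by cluster with boolean columns ``V, A, B, E``
    (presence in viruses, Archaea, Bacteria, Eukarya).  A cluster counts
    toward every domain it is flagged in; percentages are taken over flag
    incidences, so they sum to 100.
    """
    cols = ["V", "A", "B", "E"]
    counts = flags[cols].sum(axis=0).astype(int)
    total = int(counts.sum())
    pct = 100.0 * counts / total if total else counts.astype(float)
    return pd.DataFrame({"clusters": counts, "percent": pct})
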