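"""End-to-end family pipeline: generate/read -> search -> cluster ->
partition -> rarefy -> classify -> oxygen screen.

One :class:`PipelineConfig` carries every threshold (defaults are the
standard adapted values: E < 1e-5 with 75% query coverage for homology,
E < 1e-3 for profile rescue, 80% identity for redundancy, 95% occupancy
for the core, occupancy <= 2 for the cloud, >= 3 proteomes per family) and
one top-level seed from which all randomness derives.  Every run writes a
JSON manifest echoing the configuration verbatim, so each output file is
re-derivable from the manifest alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .simulate import FamilySpec, generate_family
from .search import all_vs_all
from .cluster import build_clusters, pssm_rescue, redundancy_filter
from .pangenome import PartitionPolicy, partition, presence_matrix, summarize
from .rarefaction import fit_curves, permute_curves
from .categories import (
    assign_category,
    cluster_pfams,
    domain_distribution,
    heatmap_matrix,
    load_category_map,
)
from .oxygen import count_oxy_clusters, extract_oxy, load_catalog
from . import io as vio


@dataclass
class PipelineConfig:
    """Inputs, thresholds, and output location for one family run."""

    outdir: str = "viropan_out"
    family: str = "family"
    fasta_dir: str | None = None
    generator: FamilySpec | None = None
    annotations: str | None = None  # protein_id -> pfam_id TSV
    category_map: str | None = None  # pfam_id -> category TSV
    domain_flags: str | None = None  # cluster_id -> V/A/B/E flags TSV
    oxy_catalog: str | None = None
    max_evalue: float = 1e-5
    min_query_cov: float = 0.75
    rescue_evalue: float = 1e-3
    identity_threshold: float = 0.80
    core_fraction: float = 0.95
    cloud_max_occupancy: int = 2
    min_genomes: int = 3
    prefilter_k: int = 4
    n_perm: int = 200
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.generator is not None:
            d["generator"] = dataclasses.asdict(self.generator)
        return d


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage in order and write the result bundle.

    Returns a dict of in-memory results (proteomes, hits, membership,
    matrix, labels, summary, curves, fits, heatmap, oxy tables, manifest
    path).  Deterministic given the seed.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.generator is not None:
        spec = dataclasses.replace(config.generator, seed=config.seed)
        proteomes, truth = generate_family(spec)
        vio.write_proteomes(proteomes, outdir / "proteomes")
        vio.write_tsv(truth, outdir / "truth.tsv")
    elif config.fasta_dir is not None:
        proteomes = vio.read_proteomes(config.fasta_dir)
        truth = None
    else:
        raise ValueError("config needs either fasta_dir or a generator spec")

    policy = PartitionPolicy(
        core_fraction=config.core_fraction,
        cloud_max_occupancy=config.cloud_max_occupancy,
        min_genomes=config.min_genomes,
    )
    if len(proteomes) < policy.min_genomes:
        raise ValueError(
            f"family {config.family!r} has {len(proteomes)} proteomes; "
            f"families with fewer than {policy.min_genomes} are excluded"
        )

    hits = all_vs_all(
        proteomes,
        max_evalue=config.max_evalue,
        min_query_cov=config.min_query_cov,
        prefilter_k=config.prefilter_k,
    )
    vio.write_tsv(hits, outdir / "hits.tsv")

    membership = build_clusters(hits, proteomes)
    vio.write_tsv(membership, outdir / "membership.tsv")

    matrix = presence_matrix(membership, genomes=sorted(proteomes))
    vio.write_tsv(matrix.reset_index(), outdir / "matrix.tsv")
    labels = partition(matrix, policy)
    vio.write_tsv(labels.reset_index(), outdir / "partition.tsv")
    summary = summarize(membership, labels, family=config.family)
    vio.write_tsv(summary, outdir / "summary.tsv")

    curves = permute_curves(matrix, n_perm=config.n_perm, seed=config.seed)
    vio.write_tsv(curves, outdir / "curves.tsv")
    fits = fit_curves(curves)
    (outdir / "tettelin.json").write_text(json.dumps(fits, indent=2) + "\n")

    # functional classification
    if config.annotations is not None:
        annotations = vio.read_tsv(config.annotations)
    else:
        annotations = pd.DataFrame(columns=["protein_id", "pfam_id"])
    cat_map = load_category_map(config.category_map)
    pfams = cluster_pfams(membership, annotations)
    flags = (
        vio.read_tsv(config.domain_flags, index_col="cluster_id").astype(bool)
        if config.domain_flags
        else None
    )
    assignments = {}
    for cid in matrix.index:
        cf = None
        if flags is not None and cid in flags.index:
            cf = tuple(bool(flags.loc[cid, c]) for c in ("A", "B", "E"))
        assignments[cid] = assign_category(pfams[cid], cat_map, cellular_flags=cf)
    heatmap = heatmap_matrix(assignments, labels, {cid: config.family for cid in matrix.index})
    vio.write_tsv(heatmap.reset_index(), outdir / "heatmap.tsv")
    domains = domain_distribution(flags) if flags is not None else None
    if domains is not None:
        vio.write_tsv(domains.reset_index(names="domain"), outdir / "domains.tsv")

    catalog = load_catalog(config.oxy_catalog)
    oxy_matrix, oxy_long = extract_oxy({config.family: (pfams, labels)}, catalog)
    vio.write_tsv(oxy_matrix.reset_index(), outdir / "oxy_matrix.tsv")
    vio.write_tsv(oxy_long, outdir / "oxy_long.tsv")

    # enzyme-database construction: extract oxy-cluster sequences, drop
    # redundant copies (> identity_threshold), and probe orphans for distant
    # homologs with a per-cluster profile at the rescue cutoff
    seq_of = {pid: seq for prots in proteomes.values() for pid, seq in prots}
    members_of = membership.groupby("cluster_id")["protein_id"].apply(list)
    oxy_records: list[tuple[str, str]] = []
    rescue_frames = []
    orphan_ids = membership.loc[membership["role"] == "orphan", "protein_id"]
    orphan_seqs = [(pid, seq_of[pid]) for pid in sorted(orphan_ids)]
    for cid in sorted(set(oxy_long["cluster_id"])):
        members = [(pid, seq_of[pid]) for pid in sorted(members_of[cid])]
        for pid in redundancy_filter(members, config.identity_threshold):
            oxy_records.append((f"{cid}|{pid}", seq_of[pid]))
        if len(members) >= 2 and orphan_seqs:
            res = pssm_rescue(members, orphan_seqs, max_evalue=config.rescue_evalue)
            rescue_frames.append(res.assign(cluster_id=cid))
    vio.write_fasta(oxy_records, outdir / "oxy_sequences.faa")
    oxy_rescue = (
        pd.concat(rescue_frames, ignore_index=True)
        if rescue_frames
        else pd.DataFrame(columns=["protein_id", "score", "evalue", "rescued", "cluster_id"])
    )
    vio.write_tsv(oxy_rescue, outdir / "oxy_rescue.tsv")

    cfg = config.to_dict()
    manifest = {
        "package": "viropan",
        "version": __version__,
        "seed": config.seed,
        "config": cfg,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest(),
        "outputs": sorted(p.name for p in outdir.iterdir() if p.is_file()),
        "n_oxy_clusters": count_oxy_clusters(oxy_long),
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")

    return {
        "oxy_rescue": oxy_rescue,
        "proteomes": proteomes,
        "truth": truth,
        "hits": hits,
        "membership": membership,
        "matrix": matrix,
        "labels": labels,
        "summary": summary,
        "curves": curves,
        "fits": fits,
        "heatmap": heatmap,
        "domains": domains,
        "oxy_matrix": oxy_matrix,
        "oxy_long": oxy_long,
        "manifest": manifest_path,
    }
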