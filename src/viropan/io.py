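"""Readers and writers: FASTA proteomes and the pipeline's TSV tables.

All tables are tab-delimited UTF-8 with a header row and LF endings; FASTA
output is wrapped at 60 columns so that identical inputs give byte-identical
files.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

FASTA_WRAP = 60


def write_fasta(records: Iterable[tuple[str, str]], path: str | os.PathLike) -> None:
    """Write ``(protein_id, sequence)`` records, 60-column wrapped."""
    with open(path, "w", newline="\n") as fh:
        for pid, seq in records:
            fh.write(f">{pid}\n")
            for i in range(0, len(seq), FASTA_WRAP):
                fh.write(seq[i : i + FASTA_WRAP] + "\n")


def write_proteomes(
    proteomes: Mapping[str, list[tuple[str, str]]], outdir: str | os.PathLike
) -> list[Path]:
    """One FASTA per genome, named ``<genome_id>.faa``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for genome in sorted(proteomes):
        path = outdir / f"{genome}.faa"
        write_fasta(proteomes[genome], path)
        paths.append(path)
    return paths


def read_proteomes(indir: str | os.PathLike) -> dict[str, list[tuple[str, str]]]:
    """Read every ``*.faa`` / ``*.fasta`` / ``*.fa`` file as one genome."""
    indir = Path(indir)
    proteomes: dict[str, list[tuple[str, str]]] = {}
    paths = sorted(p for ext in ("*.faa", "*.fasta", "*.fa") for p in indir.glob(ext))
    if not paths:
        raise FileNotFoundError(f"no FASTA files found in {indir}")
    for path in paths:
        records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
        if records:
            proteomes[path.stem] = records
    return proteomes


def write_tsv(df: pd.DataFrame, path: str | os.PathLike, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, lineterminator="\n")


def read_tsv(path: str | os.PathLike, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)
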