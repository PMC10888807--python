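"""File formats: FASTQ streaming, TSV/BED/BEDPE tables, sparse matrices.

Conventions: genomic coordinates are 1-based inclusive in TSVs and 0-based
half-open in BED/BEDPE. All tables are written with fixed column orders and
headers so they round-trip losslessly.
"""

from __future__ import annotations

import gzip
import json
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
import scipy.io
import scipy.sparse as sp


# --------------------------------------------------------------------------
# FASTQ
# --------------------------------------------------------------------------

def _opener(path: str | Path, mode: str):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode + "t")
    return open(path, mode)


def read_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Stream (name, sequence, quality) records from plain or gzipped FASTQ."""
    with _opener(path, "r") as fh:
        record = 0
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline().rstrip("\n")
            plus = fh.readline()
            qual = fh.readline().rstrip("\n")
            if not qual and len(seq) > 0 or not plus.startswith("+"):
                raise ValueError(f"truncated or malformed FASTQ record {record} in {path}")
            if len(qual) != len(seq):
                raise ValueError(f"quality/sequence length mismatch at record {record} in {path}")
            if not header.startswith("@"):
                raise ValueError(f"malformed header at record {record} in {path}")
            yield header[1:].rstrip("\n"), seq, qual
            record += 1


def write_fastq(records: Iterable[tuple[str, str]], path: str | Path) -> int:
    """Write (name, sequence) records with uniform quality; returns count."""
    n = 0
    with _opener(path, "w") as fh:
        for name, seq in records:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")
            n += 1
    return n


def write_read_pairs(reads: pd.DataFrame, prefix: str | Path) -> tuple[Path, Path]:
    """Write simulator read pairs as <prefix>_R1/_R2.fastq.gz."""
    prefix = Path(prefix)
    p1 = prefix.parent / (prefix.name + "_R1.fastq.gz")
    p2 = prefix.parent / (prefix.name + "_R2.fastq.gz")
    write_fastq(((r.read_id, r.read1) for r in reads.itertuples(index=False)), p1)
    write_fastq(((r.read_id, r.read2) for r in reads.itertuples(index=False)), p2)
    return p1, p2


# --------------------------------------------------------------------------
# tables
# --------------------------------------------------------------------------

def write_tsv(df: pd.DataFrame, path: str | Path, force: bool = True) -> Path:
    path = Path(path)
    if path.exists() and not force:
        raise FileExistsError(f"{path} exists; pass force=True to overwrite")
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
    return path


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", keep_default_na=False,
                       na_values=[], dtype=None)


def insertions_to_bed(insertions: pd.DataFrame) -> pd.DataFrame:
    """BED6 of insertions: the 4-bp duplicated TTAA interval, 0-based
    half-open; name = bc1|bc2; strand encodes orientation (+ = top-CS2)."""
    return pd.DataFrame({
        "chrom": insertions["chrom"],
        "start": insertions["pos"] - 1,
        "end": insertions["pos"] + 3,
        "name": insertions["bc1"] + "|" + insertions["bc2"],
        "score": 0,
        "strand": ["+" if o == "top-CS2" else "-"
                   for o in insertions["orientation"]],
    })


def calls_to_bedpe(calls: pd.DataFrame) -> pd.DataFrame:
    """BEDPE with one anchor per parental insertion (0-based half-open)."""
    return pd.DataFrame({
        "chrom1": calls["chrom_a"], "start1": calls["pos_a"] - 1,
        "end1": calls["pos_a"] + 3,
        "chrom2": calls["chrom_b"], "start2": calls["pos_b"] - 1,
        "end2": calls["pos_b"] + 3,
        "name": calls["bc1"] + "|" + calls["bc2"],
        "score": calls["umi_count"],
        "strand1": ["+" if o == "top-CS2" else "-" for o in calls["orientation_a"]],
        "strand2": ["+" if o == "top-CS2" else "-" for o in calls["orientation_b"]],
        "sv_class": calls["sv_class"],
        "topology": calls["topology"],
    })


def write_bed(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, header=False)
    return path


def write_matrix_market(matrix: sp.spmatrix, pairs: list[tuple[str, str]],
                        cells: list[str], out_dir: str | Path) -> None:
    """Write an MTX triplet plus row (pairs) and column (cells) TSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(out / "matrix.mtx"), sp.coo_matrix(matrix))
    pd.DataFrame(pairs, columns=["bc1", "bc2"]).to_csv(
        out / "pairs.tsv", sep="\t", index=False)
    pd.DataFrame({"cell_bc": cells}).to_csv(
        out / "cells.tsv", sep="\t", index=False)


# --------------------------------------------------------------------------
# structured logging
# --------------------------------------------------------------------------

class JsonLogger:
    """JSON-lines stage logging with per-filter drop tallies."""

    def __init__(self, path: str | Path | None = None):
        self.path = Path(path) if path else None
        self.events: list[dict] = []

    def log(self, stage: str, **fields) -> None:
        event = {"stage": stage, **fields}
        self.events.append(event)
        if self.path:
            with open(self.path, "a") as fh:
                fh.write(json.dumps(event, default=str) + "\n")
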