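"""Readers and writers for the plain-text formats used across the pipeline.

Matrices are TSV with the feature id in the first column and one column per
sample; intervals are BED (0-based, half-open); PWMs are JASPAR-formatted;
gene sets are GMT.
"""

from __future__ import annotations

import io as _io
import json
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd


def write_matrix(df: pd.DataFrame, path: str | Path, index_name: str = "feature") -> None:
    out = df.copy()
    out.index.name = index_name
    out.to_csv(path, sep="\t", na_rep="NA")


def read_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    return df


def write_fasta(chromosomes: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in chromosomes.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    from pyfaidx import Fasta

    fa = Fasta(str(path), as_raw=True, sequence_always_upper=True)
    return {name: str(fa[name][:]) for name in fa.keys()}


def write_bed(intervals: pd.DataFrame, path: str | Path) -> None:
    """Write BED3+ from a DataFrame with columns chrom/start/end[/name[/score/strand]]."""
    cols = [c for c in ("chrom", "start", "end", "name", "score", "strand") if c in intervals.columns]
    intervals[cols].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str | Path) -> pd.DataFrame:
    names = ["chrom", "start", "end", "name", "score", "strand"]
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = names[: df.shape[1]]
    if (df["start"] < 0).any() or (df["start"] >= df["end"]).any():
        bad = int(np.flatnonzero((df["start"] < 0) | (df["start"] >= df["end"]))[0]) + 1
        raise ValueError(f"malformed interval at line {bad}: start/end out of order")
    return df


def write_jaspar(pwms: Iterable, path: str | Path, scale: int = 1000) -> None:
    """Write probability PWMs as JASPAR count matrices (probabilities x scale)."""
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.id} {pwm.id}\n")
            mat = np.asarray(pwm.matrix)
            for bi, base in enumerate("ACGT"):
                vals = " ".join(f"{v * scale:.2f}" for v in mat[:, bi])
                fh.write(f"{base}  [ {vals} ]\n")


def read_jaspar(path: str | Path):
    """Read JASPAR motifs into probability PWMs (rows renormalized to sum 1)."""
    from Bio import motifs as bio_motifs

    from .motif_driver_selection import PWM

    out = []
    with open(path) as fh:
        for m in bio_motifs.parse(fh, "jaspar"):
            counts = np.array([m.counts[b] for b in "ACGT"], dtype=float).T
            probs = counts / counts.sum(axis=1, keepdims=True)
            out.append(PWM(id=m.matrix_id or m.name, matrix=probs))
    return out


def write_gmt(gene_sets: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in gene_sets.items():
            fh.write("\t".join([name, "na", *genes]) + "\n")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_rnk(ranked: pd.Series, path: str | Path) -> None:
    ranked.to_csv(path, sep="\t", header=False)


def read_rnk(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", header=None, index_col=0)
    return df.iloc[:, 0]


def write_json(obj, path: str | Path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_default)
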