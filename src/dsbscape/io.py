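"""Readers and writers for the plain-text formats the pipeline speaks.

All coordinates are 0-based, half-open. Fragment tables travel as
8-column headerless BED-like TSV (chrom, start, end, name, score,
strand, q1, q2) where ``name`` is the replicate tag; hotspots as BED6+2
(chrom, start, end, name, strength, '.', center, qvalue); motif matches
as BED4; peaks/intervals as BED3/BED6. Lines starting with '#' are
ignored on input.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .fragments import FRAGMENT_COLUMNS, empty_fragments
from .hotspots import HOTSPOT_COLUMNS, empty_hotspots


def write_fasta(genome: dict[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a whole FASTA into memory (synthetic genomes are small)."""
    try:
        from pyfaidx import Fasta

        with Fasta(str(path), rebuild=True) as fa:
            return {name: str(fa[name][:]) for name in fa.keys()}
    except ImportError:  # pragma: no cover - pyfaidx is a hard dependency
        genome: dict[str, str] = {}
        name, chunks = None, []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip()
                if line.startswith(">"):
                    if name is not None:
                        genome[name] = "".join(chunks)
                    name, chunks = line[1:].split()[0], []
                elif line:
                    chunks.append(line)
        if name is not None:
            genome[name] = "".join(chunks)
        return genome


def _read_tsv(path: str | Path, n_cols: int) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#", dtype={0: str}
    )
    if df.shape[1] < n_cols:
        raise ValidationError(
            f"{path}: expected >= {n_cols} tab-separated columns, got {df.shape[1]}"
        )
    return df


def write_fragments(frags: pd.DataFrame, path: str | Path) -> None:
    out = pd.DataFrame({
        "chrom": frags["chrom"],
        "start": frags["start"],
        "end": frags["end"],
        "name": frags["replicate"],
        "score": 0,
        "strand": frags["strand"],
        "q1": frags["q1"],
        "q2": frags["q2"],
    })
    out.to_csv(path, sep="\t", header=False, index=False)


def read_fragments(path: str | Path) -> pd.DataFrame:
    try:
        df = _read_tsv(path, 8)
    except pd.errors.EmptyDataError:
        return empty_fragments()
    df = df.iloc[:, :8]
    df.columns = ["chrom", "start", "end", "name", "score", "strand", "q1", "q2"]
    frags = pd.DataFrame({
        "chrom": df["chrom"].astype(str),
        "start": df["start"].astype(np.int64),
        "end": df["end"].astype(np.int64),
        "strand": df["strand"].astype(str),
        "q1": df["q1"].astype(np.int64),
        "q2": df["q2"].astype(np.int64),
        "replicate": df["name"].astype(str),
    })
    return frags[FRAGMENT_COLUMNS]


def write_hotspots(hotspots: pd.DataFrame, path: str | Path) -> None:
    out = pd.DataFrame({
        "chrom": hotspots["chrom"],
        "start": hotspots["start"],
        "end": hotspots["end"],
        "name": [f"hotspot_{i + 1}" for i in range(len(hotspots))],
        "score": hotspots["strength"],
        "strand": ".",
        "center": hotspots["center"],
        "qvalue": hotspots["qvalue"],
    })
    out.to_csv(path, sep="\t", header=False, index=False)


def read_hotspots(path: str | Path) -> pd.DataFrame:
    try:
        df = _read_tsv(path, 8)
    except pd.errors.EmptyDataError:
        return empty_hotspots()
    df = df.iloc[:, :8]
    df.columns = ["chrom", "start", "end", "name", "score", "strand",
                  "center", "qvalue"]
    out = pd.DataFrame({
        "chrom": df["chrom"].astype(str),
        "start": df["start"].astype(np.int64),
        "end": df["end"].astype(np.int64),
        "center": df["center"].astype(np.int64),
        "strength": df["score"].astype(np.int64),
        "qvalue": df["qvalue"].astype(float),
    })
    return out[HOTSPOT_COLUMNS]


def write_bed(intervals: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in ["chrom", "start", "end", "name"] if c in intervals.columns]
    intervals[cols].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str | Path) -> pd.DataFrame:
    """BED3+ reader; returns chrom, start, end (extra columns dropped)."""
    try:
        df = _read_tsv(path, 3)
    except pd.errors.EmptyDataError:
        return pd.DataFrame({"chrom": [], "start": [], "end": []})
    out = df.iloc[:, :3].copy()
    out.columns = ["chrom", "start", "end"]
    out["chrom"] = out["chrom"].astype(str)
    out["start"] = out["start"].astype(np.int64)
    out["end"] = out["end"].astype(np.int64)
    return out


def write_truth(truth, outdir: str | Path) -> None:
    """TruthSet -> hotspots TSV + motif-site TSV + JSON summary."""
    outdir = Path(outdir)
    truth.hotspots.to_csv(outdir / "truth_hotspots.tsv", sep="\t", index=False)
    truth.motif_sites.to_csv(outdir / "truth_motif_sites.tsv", sep="\t", index=False)
    summary = {
        "n_hotspots": len(truth.hotspots),
        "n_gal4_hotspots": int(truth.hotspots["has_gal4"].sum()),
        "n_par_hotspots": int(truth.hotspots["in_par"].sum()),
        "par": (
            None
            if truth.par is None
            else {
                "chrom": truth.par.chrom,
                "start": truth.par.start,
                "end": truth.par.start + truth.par.width,
            }
        ),
    }
    with open(outdir / "truth_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)


def write_profile(profile, path: str | Path) -> None:
    profile.to_frame().to_csv(path, sep="\t", index=False)
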