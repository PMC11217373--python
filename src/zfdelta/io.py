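"""Readers and writers for the plain-text genomics formats used here.

Coordinates are 0-based half-open throughout (BED convention); bedGraph
values apply to half-open bins.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .chip_quant import ScaledTrack


def write_fasta(genome: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in genome.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def write_bed(intervals: pd.DataFrame, path) -> None:
    """Write BED6 from a frame with contig/start/end (+ optional name,
    score, strand)."""
    out = intervals.copy()
    if "name" not in out.columns:
        out["name"] = [f"iv{i}" for i in range(len(out))]
    if "score" not in out.columns:
        out["score"] = 0
    if "strand" not in out.columns:
        out["strand"] = "."
    cols = ["contig", "start", "end", "name", "score", "strand"]
    out[cols].to_csv(path, sep="\t", index=False, header=False)


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    names = ["contig", "start", "end", "name", "score", "strand"]
    df.columns = names[:df.shape[1]] + list(df.columns[len(names):])
    return df


def write_bedgraph(track: ScaledTrack, path) -> None:
    """Write binned coverage as bedGraph (zero bins omitted)."""
    with open(path, "w") as fh:
        for contig, vals in track.data.items():
            bs = track.bin_size
            for b in np.flatnonzero(vals):
                fh.write(f"{contig}\t{b * bs}\t{(b + 1) * bs}\t"
                         f"{vals[b]:.6g}\n")


def read_bedgraph(path, bin_size: int,
                  contig_lengths: dict[str, int] | None = None
                  ) -> ScaledTrack:
    """Read bedGraph into a fixed-bin track.

    Intervals must align to the bin grid; values fill every covered bin.
    ``contig_lengths`` (bp) sizes the vectors; otherwise the largest end
    coordinate seen per contig is used.
    """
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["contig", "start", "end", "value"])
    lengths = dict(contig_lengths or {})
    for contig, sub in df.groupby("contig"):
        lengths.setdefault(contig, int(sub["end"].max()))
    data = {c: np.zeros(-(-int(ln) // bin_size))
            for c, ln in lengths.items()}
    for row in df.itertuples(index=False):
        b0 = int(row.start) // bin_size
        b1 = -(-int(row.end) // bin_size)
        data[row.contig][b0:b1] = row.value
    return ScaledTrack(data, bin_size=bin_size, norm_state="raw")


def write_pfm_jaspar(pfm: np.ndarray, path, name: str = "motif") -> None:
    """Write a count PFM in JASPAR-style matrix text."""
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i, base in enumerate("ACGT"):
            vals = " ".join(f"{v:.2f}" for v in pfm[:, i])
            fh.write(f"{base} [ {vals} ]\n")


def read_pfm_jaspar(path) -> np.ndarray:
    rows = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(">"):
                continue
            base = line[0]
            inner = line[line.index("[") + 1:line.index("]")]
            rows[base] = [float(x) for x in inner.split()]
    return np.array([rows[b] for b in "ACGT"]).T
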