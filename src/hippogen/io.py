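"""File formats: FASTA (70 bases/line), base-count TSV, window-tree TSV,
and newick tree lists."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.SeqIO.FastaIO import FastaWriter

from .siteops import decode, encode
from .simcore import BaseCounts
from .consensify import PseudohaploidGenome
from .windowphylo import WindowTreeRecord

FASTA_WRAP = 70


def write_fasta(sequences: dict, path) -> None:
    """Write {name: uint8 codes or str} to FASTA, 70 bases per line."""
    records = []
    for name, seq in sequences.items():
        s = seq if isinstance(seq, str) else decode(seq)
        records.append(SeqRecord(Seq(s), id=name, description=""))
    with open(path, "w") as fh:
        writer = FastaWriter(fh, wrap=FASTA_WRAP)
        writer.write_file(records)


def read_fasta(path) -> dict:
    """Read FASTA into {name: uint8 codes}; ambiguity codes become N."""
    out = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        out[rec.id] = encode(str(rec.seq))
    return out


def write_genome_fasta(genome: PseudohaploidGenome, path) -> None:
    write_fasta(genome.sequences, path)


def write_base_counts(bc: BaseCounts, path) -> None:
    """Long-format TSV: scaffold, pos (1-based), individual, nA, nC, nG, nT."""
    frames = []
    for ind in sorted(bc.counts):
        arr = bc.counts[ind]
        frames.append(
            pd.DataFrame(
                {
                    "scaffold": bc.scaffold,
                    "pos": np.arange(1, arr.shape[0] + 1),
                    "individual": ind,
                    "nA": arr[:, 0],
                    "nC": arr[:, 1],
                    "nG": arr[:, 2],
                    "nT": arr[:, 3],
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_base_counts(path) -> BaseCounts:
    df = pd.read_csv(path, sep="\t")
    scaffolds = df["scaffold"].unique()
    if len(scaffolds) != 1:
        raise ValueError("expected a single scaffold per base-count file")
    L = int(df["pos"].max())
    counts = {}
    for ind, sub in df.groupby("individual"):
        arr = np.zeros((L, 4), dtype=np.int64)
        arr[sub["pos"].to_numpy() - 1] = sub[["nA", "nC", "nG", "nT"]].to_numpy()
        counts[ind] = arr
    return BaseCounts(scaffold=str(scaffolds[0]), counts=counts)


def write_window_records(records: list[WindowTreeRecord], tsv_path, trees_path=None) -> None:
    pd.DataFrame([r.__dict__ for r in records]).to_csv(tsv_path, sep="\t", index=False)
    if trees_path is not None:
        with open(trees_path, "w") as fh:
            for r in records:
                fh.write(r.newick.rstrip("\n") + "\n")


def read_window_records(tsv_path) -> list[WindowTreeRecord]:
    df = pd.read_csv(tsv_path, sep="\t")
    return [WindowTreeRecord(**row) for row in df.to_dict("records")]
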