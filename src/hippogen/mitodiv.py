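"""Mitochondrial alignment diversity statistics.

Given an aligned multi-FASTA of mitogenomes, every column containing a
gap, an N or any IUPAC ambiguity in any sequence is removed, and the
classical descriptors are computed on the remainder: segregating sites S,
nucleotide diversity pi (mean pairwise difference per retained column, no
sample-size correction, matching the convention of haplotype-network
software), and the pairwise Hamming matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from Bio import AlignIO


@dataclass
class MitoAlignment:
    ids: list[str]
    data: np.ndarray  # (n, L) array of single-byte characters, upper-case

    def __post_init__(self):
        if len(self.ids) < 2:
            raise ValueError("alignment needs >= 2 sequences")
        if self.data.ndim != 2 or self.data.shape[0] != len(self.ids):
            raise ValueError("data must be (n_sequences, n_columns)")

    @property
    def length(self) -> int:
        return self.data.shape[1]

    @classmethod
    def from_fasta(cls, path) -> "MitoAlignment":
        aln = AlignIO.read(path, "fasta")
        ids = [rec.id for rec in aln]
        data = np.array([list(str(rec.seq).upper()) for rec in aln])
        return cls(ids=ids, data=data)

    @classmethod
    def from_strings(cls, seqs: dict) -> "MitoAlignment":
        ids = list(seqs)
        data = np.array([list(s.upper()) for s in seqs.values()])
        return cls(ids=ids, data=data)


@dataclass
class MitoDiversity:
    L_filtered: int
    S: int
    pi: float
    pairwise: pd.DataFrame  # Hamming difference counts


def strip_ambiguous_columns(aln: MitoAlignment) -> tuple[MitoAlignment, int]:
    """Drop every column with any symbol outside {A,C,G,T} in any sequence."""
    ok = np.isin(aln.data, list("ACGT")).all(axis=0)
    if not ok.any():
        raise ValueError("all columns removed")
    out = MitoAlignment(ids=list(aln.ids), data=aln.data[:, ok])
    return out, int(ok.sum())


def segregating_sites(aln: MitoAlignment) -> int:
    """Columns with at least two distinct bases."""
    return int((aln.data != aln.data[0]).any(axis=0).sum())


def nucleotide_diversity(aln: MitoAlignment) -> float:
    """pi: mean pairwise Hamming difference divided by alignment length."""
    if aln.length == 0:
        raise ValueError("empty alignment")
    n = len(aln.ids)
    diffs = [
        (aln.data[i] != aln.data[j]).sum() for i, j in combinations(range(n), 2)
    ]
    return float(np.mean(diffs) / aln.length)


def pairwise_matrix(aln: MitoAlignment) -> pd.DataFrame:
    n = len(aln.ids)
    m = np.zeros((n, n), dtype=int)
    for i, j in combinations(range(n), 2):
        m[i, j] = m[j, i] = int((aln.data[i] != aln.data[j]).sum())
    return pd.DataFrame(m, index=aln.ids, columns=aln.ids)


def mito_diversity(aln: MitoAlignment) -> MitoDiversity:
    """Filter columns and compute S, pi and the pairwise matrix."""
    filtered, L = strip_ambiguous_columns(aln)
    return MitoDiversity(
        L_filtered=L,
        S=segregating_sites(filtered),
        pi=nucleotide_diversity(filtered),
        pairwise=pairwise_matrix(filtered),
    )
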