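"""Shared site-level primitives.

All sequence data in this package is carried as ``numpy.uint8`` arrays with
the encoding A=0, C=1, G=2, T=3, N=4.  Purines (A, G) share even codes, which
makes RY coding a parity test.  Coordinates are 0-based half-open internally
and 1-based inclusive in every file written for users.

The substitution classifier implements the damage-aware partition used
throughout the package: transitions (C/T, A/G) overlap with cytosine
deamination, G/T and C/A with oxidative damage, leaving A/T and C/G as the
only "clean" transversions that can be trusted in degraded ancient samples.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

A, C, G, T, N = 0, 1, 2, 3, 4

BASE_CODES = {"A": A, "C": C, "G": G, "T": T, "N": N}
CODE_BASES = np.array(list("ACGTN"))

_ENCODE_LUT = np.full(256, N, dtype=np.uint8)
for _b, _c in BASE_CODES.items():
    _ENCODE_LUT[ord(_b)] = _c
    _ENCODE_LUT[ord(_b.lower())] = _c
# IUPAC ambiguity codes and gaps are treated as missing on ingest.
for _b in "RYSWKMBDHVU-.":
    _ENCODE_LUT[ord(_b)] = N
    _ENCODE_LUT[ord(_b.lower())] = N


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string to uint8 codes (A=0,C=1,G=2,T=3,N=4).

    IUPAC ambiguity codes other than ACGTN, and gaps, become N.
    """
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    bad = ~np.isin(raw, np.frombuffer(b"ACGTNacgtnRYSWKMBDHVUryswkmbdhvu-.", dtype=np.uint8))
    if bad.any():
        sym = chr(raw[bad][0])
        raise ValueError(f"invalid sequence symbol {sym!r}")
    return _ENCODE_LUT[raw]


def decode(codes: np.ndarray) -> str:
    return "".join(CODE_BASES[np.asarray(codes)])


class SubstitutionClass(enum.Enum):
    """Damage-aware partition of unordered base pairs."""

    IDENTICAL = "identical"
    TRANSITION = "transition"          # C/T or A/G; overlaps deamination
    DAMAGE_LIKE = "damage_like"        # G/T or C/A; overlaps oxidation
    CLEAN_TRANSVERSION = "clean_transversion"  # A/T or C/G
    MASKED = "masked"                  # any comparison involving N


def classify_substitution(a, b) -> SubstitutionClass:
    """Classify the unordered pair (a, b); symmetric in its arguments.

    Accepts single-character bases or uint8 codes.
    """
    ca = BASE_CODES[a] if isinstance(a, str) else int(a)
    cb = BASE_CODES[b] if isinstance(b, str) else int(b)
    if not (0 <= ca <= 4 and 0 <= cb <= 4):
        raise ValueError(f"invalid base codes ({a!r}, {b!r})")
    if ca == N or cb == N:
        return SubstitutionClass.MASKED
    if ca == cb:
        return SubstitutionClass.IDENTICAL
    pair = frozenset((ca, cb))
    if pair in ({C, T}, {A, G}):
        return SubstitutionClass.TRANSITION
    if pair in ({G, T}, {C, A}):
        return SubstitutionClass.DAMAGE_LIKE
    return SubstitutionClass.CLEAN_TRANSVERSION  # {A,T} or {C,G}


def ry_code(seq: str) -> str:
    """Recode A,G -> R and C,T -> Y (N stays N); transitions become invisible."""
    out = []
    for ch in seq:
        if ch not in "ACGTN":
            raise ValueError(f"ry_code input must be over ACGTN, got {ch!r}")
        out.append("N" if ch == "N" else ("R" if ch in "AG" else "Y"))
    return "".join(out)


def ry_code_array(codes: np.ndarray) -> np.ndarray:
    """Vectorized RY coding on uint8 codes: returns 0 (R), 1 (Y), 4 (N)."""
    out = (np.asarray(codes) & 1).astype(np.uint8)
    out[np.asarray(codes) == N] = N
    return out


@dataclass
class SiteMatrix:
    """individuals x sites base matrix with genomic coordinates.

    ``data`` is (n_individuals, n_sites) uint8; ``positions`` are 0-based
    within ``scaffold``.
    """

    individuals: list[str]
    data: np.ndarray
    scaffold: str = "scaffold_1"
    positions: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.uint8)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.individuals):
            raise ValueError("data must be (n_individuals, n_sites)")
        if self.positions is None:
            self.positions = np.arange(self.data.shape[1])
        self.positions = np.asarray(self.positions)
        if self.positions.shape != (self.data.shape[1],):
            raise ValueError("positions length must equal site count")

    @property
    def n_sites(self) -> int:
        return self.data.shape[1]

    def row(self, individual: str) -> np.ndarray:
        return self.data[self.individuals.index(individual)]


def dump_filtered_sites(matrix: SiteMatrix, path) -> None:
    """Audit dump of retained site coordinates (1-based) as TSV."""
    import pandas as pd

    pd.DataFrame(
        {"scaffold": matrix.scaffold, "pos": np.asarray(matrix.positions) + 1}
    ).to_csv(path, sep="\t", index=False)


def filter_sites(matrix: SiteMatrix) -> tuple[SiteMatrix, int]:
    """Drop sites with any missing data and monomorphic (uninformative) sites.

    Returns the filtered matrix and the retained-site count, which downstream
    diversity statistics use as their shared normalization denominator.
    """
    if len(matrix.individuals) < 2:
        raise ValueError("filter_sites needs at least 2 individuals")
    if matrix.n_sites == 0:
        raise ValueError("empty site matrix")
    d = matrix.data
    complete = ~(d == N).any(axis=0)
    polymorphic = (d != d[0]).any(axis=0)
    keep = complete & polymorphic
    out = SiteMatrix(
        individuals=list(matrix.individuals),
        data=d[:, keep],
        scaffold=matrix.scaffold,
        positions=matrix.positions[keep],
    )
    return out, int(keep.sum())
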