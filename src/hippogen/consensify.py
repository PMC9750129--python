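"""Pseudohaploid calling from per-site base counts.

Two calling modes are supported, mirroring the two conventions in common
use for low-coverage ancient genomes:

* ``consensify`` — draw up to three observations without replacement at a
  site and emit the base seen at least twice, masking the site (N) when no
  base reaches a majority.  This suppresses singleton errors and residual
  deamination at the cost of masking low-depth sites.
* ``random`` — draw a single observation uniformly (the classic
  random-read pseudohaploid call).

Sites below ``min_depth`` or above ``max_depth`` are masked; ``max_depth``
defaults to twice the individual's empirical mean depth, which removes
collapsed repeats and mapping pile-ups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .siteops import N
from .simcore import BaseCounts


@dataclass(frozen=True)
class ConsensifyParams:
    """Depth gates and sample size for pseudohaploid calling.

    ``max_depth=None`` means "auto": floor(2 x empirical mean depth) per
    individual, computed over all sites of the scaffold.
    """

    max_depth: int | None = None
    min_depth: int = 2
    sample_size: int = 3

    def __post_init__(self):
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")
        if self.max_depth is not None and self.max_depth < self.min_depth:
            raise ValueError("max_depth must be >= min_depth")
        if self.sample_size < 2:
            raise ValueError("sample_size must be >= 2")


@dataclass
class PseudohaploidGenome:
    """One called sequence per scaffold for one individual, over
    {A,C,G,T,N} codes."""

    individual: str
    sequences: dict  # scaffold -> uint8 array
    provenance: dict = field(default_factory=dict)

    def scaffold_lengths(self) -> dict:
        return {k: len(v) for k, v in self.sequences.items()}


def _check_counts(counts) -> np.ndarray:
    arr = np.asarray(counts)
    if (arr < 0).any():
        raise ValueError("negative base counts")
    return arr


def call_consensify_site(counts, params: ConsensifyParams, rng) -> int:
    """Majority-of-sample pseudohaploid call at one site.

    ``counts`` is (nA, nC, nG, nT).  Returns a base code or N.  Ties in a
    sample larger than 3 (possible only for sample_size > 3) are masked.
    """
    arr = _check_counts(counts)
    rng = np.random.default_rng(rng)
    depth = int(arr.sum())
    max_depth = params.max_depth if params.max_depth is not None else depth
    if depth < params.min_depth or depth > max_depth:
        return N
    k = min(params.sample_size, depth)
    sample = rng.multivariate_hypergeometric(arr.astype(np.int64), k)
    top = int(sample.max())
    if top < 2 or (sample == top).sum() > 1:
        return N
    return int(sample.argmax())


def call_random_site(counts, params: ConsensifyParams, rng) -> int:
    """Random-read pseudohaploid call: one observation drawn uniformly."""
    arr = _check_counts(counts)
    rng = np.random.default_rng(rng)
    depth = int(arr.sum())
    max_depth = params.max_depth if params.max_depth is not None else depth
    if depth < params.min_depth or depth > max_depth:
        return N
    r = int(rng.integers(0, depth))
    cum = np.cumsum(arr)
    return int(np.searchsorted(cum, r, side="right"))


def _floyd_triple(depth: np.ndarray, u1, u2, u3) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized uniform 3-subset of read indices per site (depth >= 3).

    ``u1..u3`` are per-site uniforms; floor(u*k) has negligible rounding
    bias for the small per-site depths involved.
    """
    j1 = (u1 * depth).astype(np.int64)
    j2 = (u2 * (depth - 1)).astype(np.int64)
    j2 = j2 + (j2 >= j1)
    lo = np.minimum(j1, j2)
    hi = np.maximum(j1, j2)
    j3 = (u3 * (depth - 2)).astype(np.int64)
    j3 = j3 + (j3 >= lo)
    j3 = j3 + (j3 >= hi)
    return j1, j2, j3


def _index_to_base(counts: np.ndarray, j: np.ndarray) -> np.ndarray:
    cum = np.cumsum(counts.astype(np.int32), axis=1)
    return ((j[:, None] >= cum[:, :3]).sum(axis=1)).astype(np.uint8)


def _call_consensify_array(counts: np.ndarray, params: ConsensifyParams, max_depth: int, rng) -> np.ndarray:
    # Per-site uniforms are drawn for every site up front, so a site's call
    # depends only on its own counts and position in the random field:
    # changing the depth gates can mask/unmask sites but never alters the
    # base called at a site that stays called.
    depth = counts.sum(axis=1)
    L = counts.shape[0]
    u1, u2, u3 = rng.random(L), rng.random(L), rng.random(L)
    out = np.full(L, N, dtype=np.uint8)
    ok = (depth >= params.min_depth) & (depth <= max_depth)

    two = ok & (depth == 2)
    if two.any():
        sub = counts[two]
        hit = (sub == 2).any(axis=1)
        vals = np.where(hit, sub.argmax(axis=1), N).astype(np.uint8)
        out[two] = vals

    three = ok & (depth >= 3)
    if three.any():
        sub = counts[three]
        d = depth[three]
        j1, j2, j3 = _floyd_triple(d, u1[three], u2[three], u3[three])
        cum = np.cumsum(sub.astype(np.int32), axis=1)[:, :3]
        b1 = ((j1[:, None] >= cum).sum(axis=1)).astype(np.uint8)
        b2 = ((j2[:, None] >= cum).sum(axis=1)).astype(np.uint8)
        b3 = ((j3[:, None] >= cum).sum(axis=1)).astype(np.uint8)
        maj = np.full(len(d), N, dtype=np.uint8)
        m12 = b1 == b2
        m13 = b1 == b3
        m23 = b2 == b3
        maj[m23] = b2[m23]
        maj[m13] = b1[m13]
        maj[m12] = b1[m12]
        out[three] = maj
    return out


def _call_random_array(counts: np.ndarray, params: ConsensifyParams, max_depth: int, rng) -> np.ndarray:
    depth = counts.sum(axis=1)
    L = counts.shape[0]
    u = rng.random(L)
    out = np.full(L, N, dtype=np.uint8)
    ok = (depth >= params.min_depth) & (depth <= max_depth)
    if ok.any():
        sub = counts[ok]
        j = (u[ok] * depth[ok]).astype(np.int64)
        out[ok] = _index_to_base(sub, j)
    return out


def auto_max_depth(counts: np.ndarray) -> int:
    """floor(2 x empirical mean depth) over all sites of the individual."""
    return int(np.floor(2.0 * counts.sum(axis=1).mean()))


def call_genome(
    individual: str,
    counts_by_scaffold: dict,
    mode: str,
    params: ConsensifyParams,
    seed: int,
) -> PseudohaploidGenome:
    """Call a pseudohaploid genome for one individual.

    ``counts_by_scaffold`` maps scaffold name -> (L, 4) count matrix.
    Deterministic given ``seed``.
    """
    if mode not in ("consensify", "random"):
        raise ValueError(f"unknown calling mode {mode!r}")
    rng = np.random.default_rng(seed)
    if params.max_depth is None:
        total = np.concatenate([np.asarray(c) for c in counts_by_scaffold.values()], axis=0)
        max_depth = auto_max_depth(total)
        max_depth = max(max_depth, params.min_depth)
    else:
        max_depth = params.max_depth
    sequences = {}
    for scaffold in counts_by_scaffold:
        arr = _check_counts(counts_by_scaffold[scaffold])
        if mode == "consensify":
            if params.sample_size != 3:
                seq = np.array(
                    [call_consensify_site(row, params, rng) for row in arr], dtype=np.uint8
                )
            else:
                seq = _call_consensify_array(arr, params, max_depth, rng)
        else:
            seq = _call_random_array(arr, params, max_depth, rng)
        sequences[scaffold] = seq
    return PseudohaploidGenome(
        individual=individual,
        sequences=sequences,
        provenance={"mode": mode, "seed": seed, "max_depth": max_depth},
    )


def call_cohort(
    base_counts: BaseCounts, mode: str, params: ConsensifyParams, seed: int
) -> dict:
    """Call every individual in a BaseCounts set; per-individual seeds are
    derived deterministically from ``seed``."""
    genomes = {}
    for i, ind in enumerate(sorted(base_counts.counts)):
        genomes[ind] = call_genome(
            ind,
            {base_counts.scaffold: base_counts.counts[ind]},
            mode,
            params,
            seed=(seed + 1000003 * (i + 1)) % (2**31),
        )
    return genomes
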