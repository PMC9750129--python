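"""Damage-aware species-wide nuclear diversity from pseudohaploid genomes.

Relative diversity is estimated as the number of pairwise differences
between two pseudohaploid individuals, counting only the "clean"
transversions (A/T and C/G) that cannot be produced by cytosine
deamination (transitions) or oxidative G->T / C->A damage, divided by a
single cohort-wide denominator: the number of sites that survive the
joint missing-data/monomorphism filter across *all* individuals.  Sharing
one denominator across species is what makes the per-species means
comparable.

The absolute scale is arbitrary (pseudohaploids sample one allele per
site), but the statistic tracks true heterozygosity across species, which
``true_heterozygosity`` verifies against simulation truth.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .siteops import N, SiteMatrix, filter_sites
from .consensify import PseudohaploidGenome
from .simcore import TruthBundle

#: unordered substitution types, damage-relevant ones first
SPECTRUM_TYPES = ("C<->T", "A<->G", "G<->T", "C<->A", "A<->T", "C<->G")

_PAIR_TYPE = {
    frozenset((1, 3)): "C<->T",
    frozenset((0, 2)): "A<->G",
    frozenset((2, 3)): "G<->T",
    frozenset((0, 1)): "C<->A",
    frozenset((0, 3)): "A<->T",
    frozenset((1, 2)): "C<->G",
}

_CLEAN = (frozenset((0, 3)), frozenset((1, 2)))  # A/T, C/G


def cohort_matrix(genomes: dict, scaffold: str | None = None) -> SiteMatrix:
    """Stack a cohort of pseudohaploid genomes into one SiteMatrix."""
    inds = list(genomes)
    if not inds:
        raise ValueError("empty cohort")
    scaffolds = list(genomes[inds[0]].sequences)
    if scaffold is not None:
        scaffolds = [scaffold]
    data = np.concatenate(
        [np.stack([genomes[i].sequences[sc] for i in inds]) for sc in scaffolds], axis=1
    )
    return SiteMatrix(individuals=inds, data=data)


def pairwise_clean_differences(
    a: str, b: str, filtered: SiteMatrix
) -> tuple[int, int, float]:
    """Clean-transversion differences between two individuals over the
    jointly filtered sites.

    Returns (n_clean, n_sites, normalized); ``filtered`` must already have
    passed through ``filter_sites`` across the whole cohort.
    """
    if filtered.n_sites == 0:
        raise ValueError("zero filtered sites")
    ra, rb = filtered.row(a), filtered.row(b)
    lo = np.minimum(ra, rb)
    hi = np.maximum(ra, rb)
    clean = ((lo == 0) & (hi == 3)) | ((lo == 1) & (hi == 2))
    n_clean = int(clean.sum())
    return n_clean, filtered.n_sites, n_clean / filtered.n_sites


def raw_differences(a: str, b: str, filtered: SiteMatrix) -> int:
    """All differing sites between two individuals (no damage filter)."""
    return int((filtered.row(a) != filtered.row(b)).sum())


def substitution_spectrum(a: np.ndarray, b: np.ndarray) -> pd.Series:
    """Counts of differing comparable sites by unordered substitution type."""
    a = np.asarray(a, dtype=np.uint8)
    b = np.asarray(b, dtype=np.uint8)
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    comp = (a != N) & (b != N) & (a != b)
    lo = np.minimum(a[comp], b[comp])
    hi = np.maximum(a[comp], b[comp])
    key = lo * 4 + hi
    counts = np.bincount(key, minlength=16)
    out = {}
    for pair, name in _PAIR_TYPE.items():
        i, j = sorted(pair)
        out[name] = int(counts[i * 4 + j])
    return pd.Series(out).reindex(list(SPECTRUM_TYPES))


def diversity_table(genomes: dict, species_map: dict) -> pd.DataFrame:
    """All within-species pairwise clean-transversion diversities.

    ``genomes`` maps individual -> PseudohaploidGenome; ``species_map``
    maps individual -> species.  Sites are filtered jointly across the
    whole cohort once; every pair shares the same denominator.  Species
    with fewer than two individuals are skipped.
    """
    mat = cohort_matrix(genomes)
    filtered, n_sites = filter_sites(mat)
    rows = []
    by_species: dict[str, list[str]] = {}
    for ind, sp in species_map.items():
        if ind in genomes:
            by_species.setdefault(sp, []).append(ind)
    for sp, inds in sorted(by_species.items()):
        if len(inds) < 2:
            continue
        for a, b in itertools.combinations(sorted(inds), 2):
            n_clean, n_tot, norm = pairwise_clean_differences(a, b, filtered)
            rows.append(
                {
                    "species": sp,
                    "individual_a": a,
                    "individual_b": b,
                    "n_clean_differences": n_clean,
                    "n_filtered_sites": n_tot,
                    "normalized": norm,
                    "n_raw_differences": raw_differences(a, b, filtered),
                }
            )
    if not rows:
        raise ValueError("no species with >= 2 individuals")
    return pd.DataFrame(rows)


def species_means(table: pd.DataFrame) -> pd.Series:
    return table.groupby("species")["normalized"].mean()


def true_heterozygosity(truth: TruthBundle, individual: str) -> float:
    """Fraction of sites at which the individual's two true haplotypes
    differ (simulation truth only)."""
    haps = truth.concatenated_haplotypes(individual)
    if len(haps) < 2:
        raise ValueError(f"{individual!r} is haploid; heterozygosity undefined")
    return float((haps[0] != haps[1]).mean())
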