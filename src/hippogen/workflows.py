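"""High-level seeded workflows combining simulation, calling and the
analysis stages; used by the test-bench scenarios and the CLI alike."""

from __future__ import annotations

import numpy as np

from . import scenarios
from .consensify import ConsensifyParams, call_cohort
from .direction import DirectionConfig, DirectionResult, direction_from_records
from .dstat import DStatConfig, DStatResult, d_test
from .simcore import (
    BaseCounts,
    DamageCoverageParams,
    DemographicModel,
    TruthBundle,
    apply_damage_and_coverage,
    simulate_dataset,
)
from .windowphylo import WindowConfig, WindowTreeRecord, window_trees


def simulate_called_genomes(
    model: DemographicModel,
    n_windows: int,
    window_length: int,
    coverage: DamageCoverageParams,
    seed: int,
    mode: str = "consensify",
    params: ConsensifyParams | None = None,
) -> tuple[TruthBundle, dict]:
    """Simulate a dataset and pseudohaploid-call every individual."""
    truth, bc = simulate_dataset(model, n_windows, window_length, coverage, seed)
    genomes = call_cohort(bc, mode, params or ConsensifyParams(), seed=seed + 1)
    return truth, genomes


def dstat_replicate(
    f: float,
    seed: int,
    n_windows: int = scenarios.DSTAT_N_WINDOWS,
    window_length: int = scenarios.DSTAT_WINDOW_LENGTH,
    block_size: int = 1_000_000,
) -> DStatResult:
    """One D-statistic experiment under the high-ILS demography:
    (P1, P2, P3, O) = (sable, blue, roan, outgroup), roan->blue pulse of
    strength ``f``."""
    model = scenarios.dstat_model(f)
    truth, genomes = simulate_called_genomes(
        model, n_windows, window_length, scenarios.DSTAT_COVERAGE, seed
    )
    return d_test(
        genomes["sable_0"],
        genomes["blue_0"],
        genomes["roan_0"],
        genomes["outgroup_0"],
        DStatConfig(block_size=block_size),
    )


def window_records_for(
    genomes: dict, window_length: int, tol: float = 0.0
) -> list[WindowTreeRecord]:
    """Window trees over the simulated loci (one analysis window per
    simulated window: window_size = locus length, gap 0)."""
    inds = sorted(genomes)
    gdict = {ind: genomes[ind].sequences for ind in inds}
    species_of = {ind: ind.rsplit("_", 1)[0] for ind in inds}
    return window_trees(gdict, species_of, WindowConfig(window_size=window_length, gap=0), tol=tol)


def direction_replicate(
    direction: str | None,
    seed: int,
    n_windows: int = scenarios.DIRECTION_N_WINDOWS,
    window_length: int = scenarios.DIRECTION_WINDOW_LENGTH,
    config: DirectionConfig | None = None,
) -> DirectionResult:
    """One direction-inference experiment: simulate under a pulse (or
    none), call, build window trees, run the branch-length direction test."""
    model = (
        scenarios.direction_model(direction)
        if direction is not None
        else scenarios.direction_null_model()
    )
    truth, genomes = simulate_called_genomes(
        model, n_windows, window_length, scenarios.DIRECTION_COVERAGE, seed
    )
    records = window_records_for(genomes, window_length)
    cfg = config or DirectionConfig(min_windows=20, n_permutations=1000, n_boot=500)
    return direction_from_records(records, cfg, rng_seed=seed)


def diversity_base_counts(truth: TruthBundle, damaged: bool, seed: int) -> BaseCounts:
    """Observe the diversity cohort; if ``damaged``, the designated ancient
    individual is read through the heavy-damage model."""
    rng = np.random.default_rng(seed)
    counts = {}
    for ind in truth.model.individuals():
        p = (
            scenarios.DIVERSITY_DAMAGE
            if damaged and ind == scenarios.DIVERSITY_DAMAGED_INDIVIDUAL
            else scenarios.DIVERSITY_COVERAGE
        )
        counts[ind] = apply_damage_and_coverage(truth.concatenated_haplotypes(ind), p, rng)
    return BaseCounts(scaffold="scaffold_1", counts=counts)
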