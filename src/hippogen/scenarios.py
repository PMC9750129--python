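"""Named simulation scenarios: the study conditions under which each
pipeline stage is validated.

Each scenario fixes a demography and observation model once; tests and the
acceptance script both import from here so that "the conditions" are a
single point of truth.  Split times follow the dated species tree (blue/
sable 1.67 Ma, roan 2.86 Ma, outgroup 4.0 Ma at an 8-year generation
time).  Effective sizes, admixture fraction and mutation rate are free
simulator parameters — the source data constrain none of them directly —
chosen per scenario for the regime the stage under test needs (see
docs/methods.md for the reasoning).
"""

from __future__ import annotations

from .simcore import DamageCoverageParams, DemographicModel, Pulse

SPLIT_BS = 208_750.0  # generations: 1.67 Ma / 8 y
SPLIT_R = 357_500.0   # 2.86 Ma / 8 y
SPLIT_O = 500_000.0   # 4.0 Ma / 8 y


def calibration_model(T: float = 1.0, ne: float = 10_000.0) -> DemographicModel:
    """Quartet with the internal branch spanning exactly ``T`` coalescent
    units, for checking simulated discordance against (2/3)e^-T."""
    return DemographicModel(
        split_time_bs=100_000.0,
        split_time_r=100_000.0 + 2.0 * ne * T,
        split_time_o=100_000.0 + 2.0 * ne * T + 200_000.0,
        pop_size={k: ne for k in ("blue", "sable", "roan", "outgroup", "bs_anc", "bsr_anc", "root")},
    )


def dstat_model(f: float = 0.2, pulse_time: float = 50_000.0) -> DemographicModel:
    """High-ILS demography (ancestral Ne 250k, matching the observed ~50%
    window-tree concordance) with an optional roan->blue pulse; the regime
    in which the D statistic, not branch lengths, carries the signal."""
    ne = 50_000.0
    return DemographicModel(
        split_time_bs=SPLIT_BS,
        split_time_r=SPLIT_R,
        split_time_o=SPLIT_O,
        pop_size={"blue": ne, "sable": ne, "roan": ne, "outgroup": ne,
                  "bs_anc": 250_000.0, "bsr_anc": 250_000.0, "root": 250_000.0},
        pulse=Pulse("roan", "blue", pulse_time, f) if f > 0 else None,
        mu=1e-8,
        kappa=2.0,
    )


DSTAT_N_WINDOWS = 2000
DSTAT_WINDOW_LENGTH = 5000
DSTAT_COVERAGE = DamageCoverageParams(coverage=5.0)

DSTAT_NULL_N_WINDOWS = 200
DSTAT_NULL_BLOCK_SIZE = 100_000


def direction_model(direction: str | None, f: float = 0.2, roan_samples: int = 1) -> DemographicModel:
    """Low-ILS demography (Ne 25k throughout) where coalescent-time
    variance (~2Ne) is small against the split gap, so branch-length
    distributions are informative about gene-flow direction.  The pulse
    sits at 150 kgen, old enough that introgressed and resident blue
    lineages have comparable tip lengths (tree-length normalization stays
    unbiased) and older than the roan MRCA (relevant with two roans).

    ``direction`` is "roan_to_blue", "blue_to_roan" or None.
    """
    ne = 25_000.0
    if direction == "roan_to_blue":
        pulse = Pulse("roan", "blue", 150_000.0, f)
    elif direction == "blue_to_roan":
        pulse = Pulse("blue", "roan", 150_000.0, f)
    elif direction is None:
        pulse = None
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return DemographicModel(
        split_time_bs=SPLIT_BS,
        split_time_r=SPLIT_R,
        split_time_o=SPLIT_O,
        pop_size={k: ne for k in ("blue", "sable", "roan", "outgroup", "bs_anc", "bsr_anc", "root")},
        pulse=pulse,
        mu=2.5e-8,
        kappa=2.0,
        samples={"blue": 1, "sable": 1, "roan": roan_samples},
    )


def direction_null_model() -> DemographicModel:
    """f=0 demography for null calibration of the direction test, with the
    blue/sable ancestor widened (Ne 75k) so that enough ILS windows fall in
    the discordant class to run the test at all."""
    m = direction_model(None)
    m.pop_size = dict(m.pop_size, bs_anc=75_000.0)
    return m


DIRECTION_N_WINDOWS = 200
DIRECTION_WINDOW_LENGTH = 6000
DIRECTION_COVERAGE = DamageCoverageParams(coverage=5.0)


def diversity_model() -> DemographicModel:
    """Three species spanning three orders of magnitude of effective size
    (blue 10^3, sable 10^4, roan 10^5; the qualitative ordering of the
    empirical study), four diploids each.  The mutation rate is raised to
    1.5e-7 so a desk-scale 1.5 Mb genome carries genome-scale numbers of
    polymorphic sites; the jointly retained site set is then dominated by
    genuine polymorphism rather than observation noise."""
    return DemographicModel(
        split_time_bs=SPLIT_BS,
        split_time_r=SPLIT_R,
        split_time_o=SPLIT_O,
        pop_size={"blue": 1e3, "sable": 1e4, "roan": 1e5, "outgroup": 2.5e4,
                  "bs_anc": 2.5e4, "bsr_anc": 2.5e4, "root": 2.5e4},
        mu=1.5e-7,
        kappa=2.0,
        samples={"blue": 4, "sable": 4, "roan": 4},
    )


DIVERSITY_N_WINDOWS = 300
DIVERSITY_WINDOW_LENGTH = 5000

#: clean observation model: modern/historical genomes at 8x
DIVERSITY_COVERAGE = DamageCoverageParams(coverage=8.0, eps=0.002)

#: ancient-specimen observation model: heavy terminal deamination plus
#: 10%-per-read G->T oxidation, the pattern reported for the damaged
#: museum specimen
DIVERSITY_DAMAGE = DamageCoverageParams(
    delta_ss=0.3, lam=0.3, delta_ox=0.1, eps=0.002, coverage=8.0, read_len=60
)

#: the individual carrying damage in the damage-robustness comparison
DIVERSITY_DAMAGED_INDIVIDUAL = "blue_0"
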