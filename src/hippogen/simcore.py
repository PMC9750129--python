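"""Synthetic-data generator for the antelope introgression pipeline.

Simulates per-window genealogies of a four-species quartet
``(((blue, sable), roan), outgroup)`` under the multispecies coalescent with
an optional unidirectional introgression pulse, drops finite-site mutations
on each genealogy (a two-parameter Kimura model with transition/transversion
ratio ``kappa``), and pushes the resulting diploid genotypes through an
ancient-DNA observation model: Poisson sequencing depth, terminal C->T
deamination decaying exponentially from both fragment ends (single-stranded
library convention), uniform G->T oxidation, and uniform base error.

Windows are independent loci: free recombination between windows, none
within.  Every window carries its truth (genealogy, topology class, diploid
haplotypes, migrant lineages) so downstream estimators can be validated
without external data.

Time is measured in generations.  The default demography anchors the
blue/sable split at 1.67 Ma and the roan split at 2.86 Ma via an 8-year
generation time; effective sizes are free parameters of the simulator chosen
to place the quartet in a regime with appreciable incomplete lineage
sorting (see docs/methods.md).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .siteops import N

SPECIES = ("blue", "sable", "roan", "outgroup")

#: Default generation time (years) used only to convert the dated splits
#: into generations for the default scenario.
GENERATION_TIME = 8.0

_TRANSITION = np.array([2, 3, 0, 1], dtype=np.uint8)  # A<->G, C<->T


@dataclass(frozen=True)
class Pulse:
    """Instantaneous admixture: each recipient lineage alive at ``time``
    switches to the donor population independently with probability
    ``proportion``."""

    donor: str
    recipient: str
    time: float
    proportion: float


@dataclass
class DemographicModel:
    """Species-tree demography for the hippotragin quartet.

    Split times are in generations before present and must be nested:
    ``0 < split_time_bs < split_time_r < split_time_o``.  ``pop_size`` maps
    each branch (blue, sable, roan, outgroup, bs_anc, bsr_anc, root) to a
    diploid effective size.  ``samples`` maps ingroup species to diploid
    individual counts; the outgroup is always a single haploid lineage used
    for rooting and polarization.
    """

    split_time_bs: float = 1.67e6 / GENERATION_TIME
    split_time_r: float = 2.86e6 / GENERATION_TIME
    split_time_o: float = 4.0e6 / GENERATION_TIME
    pop_size: dict = field(
        default_factory=lambda: {
            "blue": 50_000.0,
            "sable": 50_000.0,
            "roan": 50_000.0,
            "outgroup": 50_000.0,
            "bs_anc": 250_000.0,
            "bsr_anc": 250_000.0,
            "root": 250_000.0,
        }
    )
    pulse: Pulse | None = None
    mu: float = 1.0e-8
    kappa: float = 2.0
    samples: dict = field(default_factory=lambda: {"blue": 1, "sable": 1, "roan": 1})

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if not (0 < self.split_time_bs < self.split_time_r < self.split_time_o):
            raise ValueError("split times must satisfy 0 < bs < r < o")
        for k in ("blue", "sable", "roan", "outgroup", "bs_anc", "bsr_anc", "root"):
            if self.pop_size.get(k, 0) <= 0:
                raise ValueError(f"pop_size[{k!r}] must be > 0")
        if self.mu < 0:
            raise ValueError("mu must be >= 0")
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        for sp, n in self.samples.items():
            if sp not in ("blue", "sable", "roan"):
                raise ValueError(f"samples key {sp!r} not an ingroup species")
            if n < 1:
                raise ValueError("each sampled species needs >= 1 individual")
        p = self.pulse
        if p is not None:
            if not 0.0 <= p.proportion <= 1.0:
                raise ValueError("pulse proportion must be in [0, 1]")
            if {p.donor, p.recipient} - {"blue", "sable", "roan"}:
                raise ValueError("pulse donor/recipient must be ingroup species")
            if p.donor == p.recipient:
                raise ValueError("pulse donor and recipient must differ")
            anc = self.split_time_bs if {p.donor, p.recipient} == {"blue", "sable"} else self.split_time_r
            if not 0 < p.time < anc:
                raise ValueError("pulse time must predate the donor/recipient common ancestor")

    def individuals(self) -> list[str]:
        out = []
        for sp in ("blue", "sable", "roan"):
            out.extend(f"{sp}_{i}" for i in range(self.samples.get(sp, 0)))
        out.append("outgroup_0")
        return out

    def internal_branch_coalescent_units(self) -> float:
        """(split_time_r - split_time_bs) / (2 Ne_bs_anc): the quantity that
        sets the incomplete-lineage-sorting level."""
        return (self.split_time_r - self.split_time_bs) / (2.0 * self.pop_size["bs_anc"])


class _SimNode:
    __slots__ = ("name", "time", "children", "parent")

    def __init__(self, name=None, time=0.0, children=None):
        self.name = name
        self.time = time
        self.children = children or []
        self.parent = None
        for c in self.children:
            c.parent = self


@dataclass
class GeneTree:
    """A coalescent genealogy: binary, ultrametric, branch lengths in
    generations.  Leaves are named ``<species>_<ind>_h<0|1>`` (the outgroup
    contributes the single haploid leaf ``outgroup_0_h0``)."""

    root: _SimNode

    def leaves(self) -> list[_SimNode]:
        out, stack = [], [self.root]
        while stack:
            n = stack.pop()
            if n.children:
                stack.extend(n.children)
            else:
                out.append(n)
        return out

    def leaf_names(self) -> list[str]:
        return sorted(l.name for l in self.leaves())

    def mrca_time(self, name_a: str, name_b: str) -> float:
        anc_a = {}
        node = self._find(name_a)
        while node is not None:
            anc_a[id(node)] = node
            node = node.parent
        node = self._find(name_b)
        while node is not None:
            if id(node) in anc_a:
                return node.time
            node = node.parent
        raise ValueError("leaves share no ancestor")

    def _find(self, name: str) -> _SimNode:
        for l in self.leaves():
            if l.name == name:
                return l
        raise KeyError(name)

    def newick(self) -> str:
        def fmt(node, parent_time):
            bl = parent_time - node.time
            if not node.children:
                return f"{node.name}:{bl:.6f}"
            inner = ",".join(fmt(c, node.time) for c in node.children)
            return f"({inner}):{bl:.6f}"

        inner = ",".join(fmt(c, self.root.time) for c in self.root.children)
        return f"({inner});"

    def topology_class(self) -> str:
        """Quartet topology class of the genealogy, read from the first
        haplotype of the first individual of each ingroup species: the
        species pair with the most recent cross-species common ancestor.

        Returns "BS" (blue+sable, the species topology), "BR" (blue+roan)
        or "RS" (roan+sable).
        """
        t = {
            "BS": self.mrca_time("blue_0_h0", "sable_0_h0"),
            "BR": self.mrca_time("blue_0_h0", "roan_0_h0"),
            "RS": self.mrca_time("roan_0_h0", "sable_0_h0"),
        }
        return min(t, key=t.get)


def expected_discordance(T: float) -> float:
    """Probability that a quartet genealogy is discordant with the species
    tree when the internal branch spans ``T`` coalescent units: (2/3) e^-T.
    """
    if T < 0:
        raise ValueError("T must be >= 0")
    return (2.0 / 3.0) * math.exp(-T)


def simulate_gene_tree(model: DemographicModel, rng) -> tuple[GeneTree, frozenset]:
    """Draw one genealogy under the piecewise-constant structured coalescent.

    ``rng`` is a ``numpy.random.Generator`` or an integer seed.  Returns the
    tree and the frozenset of leaf names that descend from a lineage that
    migrated through the pulse (empty when there is no pulse).
    """
    rng = np.random.default_rng(rng)
    model.validate()

    lineages: list[list] = []  # [node, population]
    for sp in ("blue", "sable", "roan"):
        for i in range(model.samples.get(sp, 0)):
            for h in (0, 1):
                lineages.append([_SimNode(name=f"{sp}_{i}_h{h}"), sp])
    lineages.append([_SimNode(name="outgroup_0_h0"), "outgroup"])

    migrant_leaves: set[str] = set()

    events: list[tuple[float, str]] = [
        (model.split_time_bs, "merge_bs"),
        (model.split_time_r, "merge_r"),
        (model.split_time_o, "merge_o"),
    ]
    if model.pulse is not None and model.pulse.proportion > 0:
        events.append((model.pulse.time, "pulse"))
    events.sort()

    def _leaf_names_under(node):
        out, stack = [], [node]
        while stack:
            n = stack.pop()
            if n.children:
                stack.extend(n.children)
            else:
                out.append(n.name)
        return out

    t = 0.0
    ev_idx = 0
    while True:
        horizon = events[ev_idx][0] if ev_idx < len(events) else math.inf
        # coalesce within populations until the next demographic event
        while len(lineages) > 1:
            pops: dict[str, list[int]] = {}
            for idx, (_, pop) in enumerate(lineages):
                pops.setdefault(pop, []).append(idx)
            rates, labels = [], []
            for pop, idxs in pops.items():
                k = len(idxs)
                if k >= 2:
                    rates.append(k * (k - 1) / (4.0 * model.pop_size[pop]))
                    labels.append(pop)
            total = sum(rates)
            if total == 0.0:
                t = horizon
                break
            dt = rng.exponential(1.0 / total)
            if t + dt >= horizon:
                t = horizon
                break
            t += dt
            pop = labels[int(rng.choice(len(labels), p=np.asarray(rates) / total))]
            i, j = rng.choice(len(pops[pop]), size=2, replace=False)
            ia, ib = pops[pop][int(i)], pops[pop][int(j)]
            parent = _SimNode(time=t, children=[lineages[ia][0], lineages[ib][0]])
            keep = [lineages[k] for k in range(len(lineages)) if k not in (ia, ib)]
            keep.append([parent, pop])
            lineages = keep
        if len(lineages) == 1:
            break
        kind = events[ev_idx][1]
        ev_idx += 1
        if kind == "pulse":
            p = model.pulse
            for lin in lineages:
                if lin[1] == p.recipient and rng.random() < p.proportion:
                    lin[1] = p.donor
                    migrant_leaves.update(_leaf_names_under(lin[0]))
        elif kind == "merge_bs":
            for lin in lineages:
                if lin[1] in ("blue", "sable"):
                    lin[1] = "bs_anc"
        elif kind == "merge_r":
            for lin in lineages:
                if lin[1] in ("bs_anc", "roan"):
                    lin[1] = "bsr_anc"
        elif kind == "merge_o":
            for lin in lineages:
                lin[1] = "root"

    return GeneTree(root=lineages[0][0]), frozenset(migrant_leaves)


def simulate_window_genotypes(
    tree: GeneTree, length: int, mu: float, kappa: float, rng
) -> dict[str, np.ndarray]:
    """Drop finite-site mutations on a genealogy; returns one uint8 sequence
    per haplotype leaf.

    Mutations arrive as a Poisson process with rate ``mu`` per site per
    generation along each branch; each mutation is a transition with
    probability kappa/(kappa+1), otherwise one of the two transversions
    chosen uniformly.  Sites hit more than once mutate sequentially
    (finite-site model).
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(rng)
    p_ts = kappa / (kappa + 1.0)

    ancestral = rng.integers(0, 4, size=length, dtype=np.uint8)
    out: dict[str, np.ndarray] = {}

    stack = [(tree.root, ancestral)]
    while stack:
        node, seq = stack.pop()
        for child in node.children:
            blen = node.time - child.time
            cseq = seq.copy()
            n_mut = rng.poisson(mu * blen * length)
            if n_mut:
                sites = rng.integers(0, length, size=n_mut)
                is_ts = rng.random(n_mut) < p_ts
                pick = rng.integers(0, 2, size=n_mut)
                for s, ts, k in zip(sites, is_ts, pick):
                    b = cseq[s]
                    if ts:
                        cseq[s] = _TRANSITION[b]
                    else:
                        # the two opposite-parity bases
                        cseq[s] = (1 - (b & 1)) + 2 * k
            if child.children:
                stack.append((child, cseq))
            else:
                out[child.name] = cseq
    return out


@dataclass(frozen=True)
class DamageCoverageParams:
    """Observation model for low-coverage ancient DNA.

    ``delta_ss``: C->T deamination probability at the fragment terminus;
    it decays as ``delta_ss * exp(-lam * p)`` with distance ``p`` from the
    nearer fragment end (both ends deaminate: single-stranded libraries).
    ``delta_ox``: position-independent G->T oxidation probability.
    ``eps``: uniform sequencing error.  ``coverage``: mean Poisson depth.
    """

    delta_ss: float = 0.0
    lam: float = 0.3
    delta_ox: float = 0.0
    eps: float = 0.0
    coverage: float = 5.0
    read_len: int = 60

    def __post_init__(self):
        for name in ("delta_ss", "delta_ox", "eps"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        if self.coverage < 0:
            raise ValueError("coverage must be >= 0")
        if self.read_len < 1:
            raise ValueError("read_len must be >= 1")


def apply_damage_and_coverage(
    haplotypes: list[np.ndarray], params: DamageCoverageParams, rng
) -> np.ndarray:
    """Observe an individual's haplotypes through the aDNA model.

    Per site, depth ~ Poisson(coverage); each observation samples a
    haplotype uniformly, a fragment offset p ~ Uniform{0..read_len-1} from
    the nearer end, then applies C->T deamination, G->T oxidation, and
    uniform error in that order.  Returns an (L, 4) int64 count matrix.
    """
    if not haplotypes:
        raise ValueError("need at least one haplotype")
    L = len(haplotypes[0])
    if any(len(h) != L for h in haplotypes):
        raise ValueError("haplotypes must have equal length")
    rng = np.random.default_rng(rng)

    depth = rng.poisson(params.coverage, size=L)
    n_reads = int(depth.sum())
    if n_reads == 0:
        return np.zeros((L, 4), dtype=np.int64)

    site = np.repeat(np.arange(L), depth)
    if len(haplotypes) > 1:
        haps = np.stack(haplotypes)
        h = rng.integers(0, len(haplotypes), size=n_reads)
        base = haps[h, site]
    else:
        base = haplotypes[0][site].copy()

    # deamination: C->T with probability decaying from the nearer fragment
    # end (randomness drawn only for reads that can be affected)
    if params.delta_ss > 0:
        decay = params.delta_ss * np.exp(-params.lam * np.arange(params.read_len))
        idx_c = np.flatnonzero(base == 1)
        p = rng.integers(0, params.read_len, size=idx_c.size)
        hit = rng.random(idx_c.size) < decay[p]
        base[idx_c[hit]] = 3
    # oxidation: G->T, uniform along the fragment
    if params.delta_ox > 0:
        idx_g = np.flatnonzero(base == 2)
        hit = rng.random(idx_g.size) < params.delta_ox
        base[idx_g[hit]] = 3
    # sequencing error: replace with one of the other three bases
    if params.eps > 0:
        err = np.flatnonzero(rng.random(n_reads) < params.eps)
        shift = rng.integers(1, 4, size=err.size)
        base[err] = (base[err] + shift) % 4

    counts = np.bincount(site * 4 + base, minlength=4 * L).reshape(L, 4)
    return counts.astype(np.int64)


@dataclass
class WindowTruth:
    """Ground truth for one simulated window."""

    tree: GeneTree
    topology_class: str
    haplotypes: dict[str, np.ndarray]  # leaf name -> uint8 sequence
    migrant_leaves: frozenset


@dataclass
class TruthBundle:
    """Simulation truth across windows: genealogies, genotypes, topology
    classes and migration flags, keyed to window coordinates on the
    synthetic scaffold."""

    model: DemographicModel
    window_length: int
    windows: list[WindowTruth]

    def genotypes(self, individual: str, window: int) -> list[np.ndarray]:
        w = self.windows[window]
        pref = individual + "_h"
        return [w.haplotypes[k] for k in sorted(w.haplotypes) if k.startswith(pref)]

    def concatenated_haplotypes(self, individual: str) -> list[np.ndarray]:
        n_h = len(self.genotypes(individual, 0))
        return [
            np.concatenate([self.genotypes(individual, i)[j] for i in range(len(self.windows))])
            for j in range(n_h)
        ]

    def topology_counts(self) -> dict[str, int]:
        out = {"BS": 0, "BR": 0, "RS": 0}
        for w in self.windows:
            out[w.topology_class] += 1
        return out


@dataclass
class BaseCounts:
    """Per-site A/C/G/T observation counts for a set of individuals on one
    synthetic scaffold."""

    scaffold: str
    counts: dict[str, np.ndarray]  # individual -> (L, 4) int64

    @property
    def length(self) -> int:
        return next(iter(self.counts.values())).shape[0]


def simulate_dataset(
    model: DemographicModel,
    n_windows: int,
    window_length: int,
    damage: DamageCoverageParams | None,
    seed: int,
    scaffold: str = "scaffold_1",
) -> tuple[TruthBundle, BaseCounts | None]:
    """Simulate ``n_windows`` independent windows and (optionally) observe
    them through the damage/coverage model.

    Windows are laid end-to-end on a single synthetic scaffold so that
    genomic blocking (e.g. the 1-Mb jackknife) has coordinates to work with.
    Same seed, same model => bit-identical output.
    """
    rng = np.random.default_rng(seed)
    windows: list[WindowTruth] = []
    for _ in range(n_windows):
        tree, migrants = simulate_gene_tree(model, rng)
        haps = simulate_window_genotypes(tree, window_length, model.mu, model.kappa, rng)
        windows.append(
            WindowTruth(
                tree=tree,
                topology_class=tree.topology_class(),
                haplotypes=haps,
                migrant_leaves=migrants,
            )
        )
    truth = TruthBundle(model=model, window_length=window_length, windows=windows)

    base_counts = None
    if damage is not None:
        counts: dict[str, np.ndarray] = {}
        for ind in model.individuals():
            haps = truth.concatenated_haplotypes(ind)
            counts[ind] = apply_damage_and_coverage(haps, damage, rng)
        base_counts = BaseCounts(scaffold=scaffold, counts=counts)
    return truth, base_counts
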