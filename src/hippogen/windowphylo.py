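"""Sliding-window quartet phylogenies and concordance factors.

Non-overlapping windows are cut from pseudohaploid genomes at a fixed
stride (window + gap), transversion-only p-distances are computed per
window, and a neighbor-joining tree is built for each.  Window trees are
classified by the sister pair they support among {blue, sable, roan}
relative to the outgroup — BS is the species topology, BR and RS the two
alternative quartet resolutions — giving gene concordance factors; a
site-level analogue counts decisive biallelic transversion patterns.

Distances deliberately use only transversions (via RY coding) so that
post-mortem deamination, which mimics C->T/G->A transitions, cannot move
windows between topology classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Phylo.BaseTree import Clade, Tree

from .siteops import N, SiteMatrix, ry_code_array

CLASSES = ("BS", "BR", "RS", "other")


@dataclass(frozen=True)
class WindowConfig:
    """Window tiling and filtering parameters.

    ``window_size`` and ``gap`` are in bp; windows start at position 1 and
    tile at stride window_size + gap.  A window is discarded when any
    taxon's missing fraction inside it exceeds ``missing_threshold``
    (per-taxon convention).  ``mode`` selects RY-coded transversion
    distances ("ry_binary") or plain nucleotide p-distances.
    """

    window_size: int = 20_000
    gap: int = 80_000
    missing_threshold: float = 0.5
    mode: str = "ry_binary"

    def __post_init__(self):
        if self.window_size < 1:
            raise ValueError("window_size must be >= 1")
        if self.gap < 0:
            raise ValueError("gap must be >= 0")
        if not 0.0 <= self.missing_threshold <= 1.0:
            raise ValueError("missing_threshold must be in [0, 1]")
        if self.mode not in ("ry_binary", "nucleotide"):
            raise ValueError("mode must be 'ry_binary' or 'nucleotide'")


@dataclass
class DistanceMatrix:
    labels: list[str]
    matrix: np.ndarray
    n_comparable: np.ndarray | None = None

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        k = len(self.labels)
        if self.matrix.shape != (k, k):
            raise ValueError("matrix shape must match labels")
        if not np.allclose(self.matrix, self.matrix.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.matrix) != 0):
            raise ValueError("diagonal must be zero")


@dataclass
class WindowTreeRecord:
    """One window's tree and its summaries.

    ``start``/``end`` are 1-based inclusive; ``rs_path_proportion`` is the
    roan-sable path length divided by the total tree length.
    """

    scaffold: str
    start: int
    end: int
    n_sites_used: int
    newick: str
    topology_class: str
    tree_length: float
    rs_path_proportion: float


def extract_windows(genomes: dict, config: WindowConfig) -> list[SiteMatrix]:
    """Cut aligned windows from a set of pseudohaploid genomes.

    ``genomes`` maps taxon name -> {scaffold: uint8 sequence}.  Partial
    terminal windows are discarded; so is any window where a taxon exceeds
    the missing-data threshold.
    """
    taxa = list(genomes)
    if not taxa:
        raise ValueError("no genomes given")
    scaffolds = list(genomes[taxa[0]])
    if not scaffolds:
        raise ValueError("no scaffolds")
    out = []
    stride = config.window_size + config.gap
    for sc in scaffolds:
        L = len(genomes[taxa[0]][sc])
        for t in taxa:
            if len(genomes[t][sc]) != L:
                raise ValueError(f"scaffold {sc!r} length mismatch for {t!r}")
        for start in range(0, L - config.window_size + 1, stride):
            block = np.stack([genomes[t][sc][start : start + config.window_size] for t in taxa])
            miss = (block == N).mean(axis=1)
            if (miss > config.missing_threshold).any():
                continue
            out.append(
                SiteMatrix(
                    individuals=taxa,
                    data=block,
                    scaffold=sc,
                    positions=np.arange(start, start + config.window_size),
                )
            )
    return out


def transversion_distance(a: np.ndarray, b: np.ndarray) -> tuple[float, int]:
    """Proportion of comparable sites whose RY codes differ.

    Pairwise deletion: sites with N in either sequence are dropped.
    Transitions (A/G, C/T) have identical RY codes and contribute 0.
    """
    a = np.asarray(a, dtype=np.uint8)
    b = np.asarray(b, dtype=np.uint8)
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    comp = (a != N) & (b != N)
    n = int(comp.sum())
    if n == 0:
        return float("nan"), 0
    ra, rb = ry_code_array(a[comp]), ry_code_array(b[comp])
    return float((ra != rb).mean()), n


def nucleotide_distance(a: np.ndarray, b: np.ndarray) -> tuple[float, int]:
    """Plain p-distance with pairwise deletion."""
    a = np.asarray(a, dtype=np.uint8)
    b = np.asarray(b, dtype=np.uint8)
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    comp = (a != N) & (b != N)
    n = int(comp.sum())
    if n == 0:
        return float("nan"), 0
    return float((a[comp] != b[comp]).mean()), n


def distance_matrix(matrix: SiteMatrix, mode: str = "ry_binary") -> DistanceMatrix:
    fn = transversion_distance if mode == "ry_binary" else nucleotide_distance
    k = len(matrix.individuals)
    d = np.zeros((k, k))
    nc = np.zeros((k, k), dtype=int)
    for i in range(k):
        for j in range(i + 1, k):
            dist, n = fn(matrix.data[i], matrix.data[j])
            d[i, j] = d[j, i] = dist
            nc[i, j] = nc[j, i] = n
    return DistanceMatrix(labels=list(matrix.individuals), matrix=d, n_comparable=nc)


def nj_tree(dm: DistanceMatrix) -> Tree:
    """Saitou-Nei neighbor joining; unrooted (trifurcating root).

    Exact on additive matrices; negative branch-length estimates are
    clamped to zero; ties in the Q matrix break to the smallest taxon
    index pair (row-major first minimum).
    """
    if len(dm.labels) < 3:
        raise ValueError("need >= 3 taxa")
    if not np.isfinite(dm.matrix).all():
        raise ValueError("non-finite distances")
    d = dm.matrix.astype(float).copy()
    nodes = [Clade(name=l) for l in dm.labels]
    while len(nodes) > 3:
        n = len(nodes)
        r = d.sum(axis=1)
        q = (n - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i, j = np.unravel_index(np.argmin(q), q.shape)
        i, j = (int(min(i, j)), int(max(i, j)))
        bi = 0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (n - 2))
        bj = d[i, j] - bi
        nodes[i].branch_length = max(bi, 0.0)
        nodes[j].branch_length = max(bj, 0.0)
        parent = Clade(clades=[nodes[i], nodes[j]])
        dnew = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(n) if k not in (i, j)]
        d2 = np.zeros((n - 1, n - 1))
        d2[: n - 2, : n - 2] = d[np.ix_(keep, keep)]
        d2[-1, : n - 2] = d2[: n - 2, -1] = dnew[keep]
        d = d2
        nodes = [nodes[k] for k in keep] + [parent]
    # resolve the final three around an internal node (three-point formulas)
    (a, b, c) = nodes
    dab, dac, dbc = d[0, 1], d[0, 2], d[1, 2]
    a.branch_length = max(0.5 * (dab + dac - dbc), 0.0)
    b.branch_length = max(0.5 * (dab + dbc - dac), 0.0)
    c.branch_length = max(0.5 * (dac + dbc - dab), 0.0)
    root = Clade(clades=[a, b, c])
    return Tree(root=root, rooted=False)


def tree_length(tree: Tree) -> float:
    return sum(cl.branch_length or 0.0 for cl in tree.find_clades() if cl is not tree.root)


def path_distance(tree: Tree, name_a: str, name_b: str) -> float:
    """Sum of branch lengths on the path between two named leaves."""
    return float(tree.distance(name_a, name_b))


def _species_sets(clade: Clade, species_of: dict) -> set:
    return {species_of[l.name] for l in clade.get_terminals()}


def _bipartitions(tree: Tree) -> dict:
    """Nontrivial bipartitions of the unrooted tree, as
    frozenset(smaller-side leaf names) -> summed branch length.

    A bifurcating root splits one edge in two; both halves map to the same
    bipartition and their lengths add, so rooted and unrooted encodings of
    the same topology agree.
    """
    all_leaves = frozenset(l.name for l in tree.get_terminals())
    out: dict = {}
    for clade in tree.find_clades(terminal=False):
        if clade is tree.root:
            continue
        side = frozenset(l.name for l in clade.get_terminals())
        if len(side) < 2 or len(side) > len(all_leaves) - 2:
            continue
        other = all_leaves - side
        key = min(side, other, key=sorted)
        out[key] = out.get(key, 0.0) + (clade.branch_length or 0.0)
    return out


def classify_topology(
    tree: Tree,
    species_of: dict,
    outgroup_species: str = "outgroup",
    tol: float = 0.0,
) -> str:
    """Classify a window tree by its supported sister pair.

    For the four-taxon case the single internal edge defines one
    bipartition; the species pair on the side away from the outgroup gives
    the class: BS (blue+sable, concordant with the species tree), BR
    (blue+roan) or RS (roan+sable).  An internal edge of length <= ``tol``
    is treated as unresolved ("other").

    With two roan individuals (five taxa) the class follows the sister
    group of blue after rooting on the outgroup: the full roan pair -> BR,
    a single roan (blue inside the roan clade) -> BR_nested, sable -> BS,
    the (roan, roan, sable) group -> RS.
    """
    leaves = [l.name for l in tree.get_terminals()]
    missing = set(leaves) - set(species_of)
    if missing:
        raise ValueError(f"leaves without species assignment: {sorted(missing)}")
    og_leaves = [n for n in leaves if species_of[n] == outgroup_species]
    if not og_leaves:
        raise ValueError("no outgroup leaf in tree")

    if len(leaves) == 4:
        bip = _bipartitions(tree)
        if not bip:
            return "other"
        (side, blen), = bip.items()
        if blen <= tol:
            return "other"
        og = og_leaves[0]
        pair = side if og not in side else frozenset(leaves) - side
        pair_species = {species_of[n] for n in pair}
        if pair_species == {"blue", "sable"}:
            return "BS"
        if pair_species == {"blue", "roan"}:
            return "BR"
        if pair_species == {"roan", "sable"}:
            return "RS"
        return "other"

    # general case: sister group of the single blue leaf, rooted on outgroup
    import copy

    t = copy.deepcopy(tree)
    t.root_with_outgroup(og_leaves[0])
    blue = [l for l in t.get_terminals() if species_of[l.name] == "blue"]
    if len(blue) != 1:
        raise ValueError("expected exactly one blue leaf")
    path = t.get_path(blue[0])
    if len(path) < 2:
        return "other"
    parent = path[-2]
    if (parent.branch_length or 0.0) <= tol:
        return "other"
    sisters = [c for c in parent.clades if c is not path[-1]]
    sister_species = set()
    n_sister_leaves = 0
    for s in sisters:
        sister_species |= _species_sets(s, species_of)
        n_sister_leaves += len(s.get_terminals())
    if sister_species == {"sable"}:
        return "BS"
    if sister_species == {"roan"}:
        n_roan_total = sum(1 for n in leaves if species_of[n] == "roan")
        return "BR" if n_sister_leaves == n_roan_total else "BR_nested"
    if sister_species == {"roan", "sable"}:
        return "RS"
    return "other"


def window_tree_record(
    matrix: SiteMatrix,
    species_of: dict,
    config: WindowConfig | None = None,
    outgroup_species: str = "outgroup",
    tol: float = 0.0,
    roan_taxon: str | None = None,
    sable_taxon: str | None = None,
) -> WindowTreeRecord:
    """Build the tree for one window and summarize it."""
    config = config or WindowConfig()
    dm = distance_matrix(matrix, config.mode)
    tree = nj_tree(dm)
    cls = classify_topology(tree, species_of, outgroup_species, tol)
    tl = tree_length(tree)
    roan_taxon = roan_taxon or next(n for n in sorted(species_of) if species_of[n] == "roan")
    sable_taxon = sable_taxon or next(n for n in sorted(species_of) if species_of[n] == "sable")
    rs_prop = path_distance(tree, roan_taxon, sable_taxon) / tl if tl > 0 else float("nan")
    if dm.n_comparable is not None:
        off_diag = dm.n_comparable[~np.eye(len(dm.labels), dtype=bool)]
        n_used = int(off_diag.min())
    else:
        n_used = matrix.n_sites
    from io import StringIO
    from Bio import Phylo

    buf = StringIO()
    Phylo.write(tree, buf, "newick")
    return WindowTreeRecord(
        scaffold=matrix.scaffold,
        start=int(matrix.positions[0]) + 1,
        end=int(matrix.positions[-1]) + 1,
        n_sites_used=n_used,
        newick=buf.getvalue().strip(),
        topology_class=cls,
        tree_length=tl,
        rs_path_proportion=rs_prop,
    )


def window_trees(genomes: dict, species_of: dict, config: WindowConfig | None = None, tol: float = 0.0) -> list[WindowTreeRecord]:
    config = config or WindowConfig()
    return [window_tree_record(m, species_of, config, tol=tol) for m in extract_windows(genomes, config)]


def topology_summary(records) -> dict:
    """Gene concordance factors: class proportions over all windows."""
    classes = [r.topology_class if isinstance(r, WindowTreeRecord) else r for r in records]
    if not classes:
        raise ValueError("no window records")
    total = len(classes)
    out = {c: classes.count(c) / total for c in CLASSES}
    extra = set(classes) - set(CLASSES)
    for c in sorted(extra):
        out[c] = classes.count(c) / total
    return out


def site_concordance(matrix: SiteMatrix, species_of: dict, species_pair=("blue", "sable")) -> float:
    """Site concordance factor over decisive biallelic transversion sites.

    Decisive sites have the 2+2 pattern xxyy/xyxy/xyyx across the four
    taxa; sCF is the fraction pairing the two species in ``species_pair``.
    """
    if len(matrix.individuals) != 4:
        raise ValueError("site concordance needs exactly 4 taxa")
    d = matrix.data
    called = ~(d == N).any(axis=0)
    i_a = matrix.individuals.index(next(n for n in matrix.individuals if species_of[n] == species_pair[0]))
    i_b = matrix.individuals.index(next(n for n in matrix.individuals if species_of[n] == species_pair[1]))
    others = [k for k in range(4) if k not in (i_a, i_b)]
    a, b = d[i_a], d[i_b]
    c, e = d[others[0]], d[others[1]]
    # 2+2 biallelic: the four calls form two pairs of two distinct alleles
    pair_ab = (a == b) & (c == e) & (a != c)
    pair_ac = (a == c) & (b == e) & (a != b)
    pair_ae = (a == e) & (b == c) & (a != b)
    decisive = called & (pair_ab | pair_ac | pair_ae)
    # exclude transition allele pairs
    hi = np.maximum(a, np.where(a == c, b, c))
    lo = np.minimum(a, np.where(a == c, b, c))
    is_ts = ((lo == 0) & (hi == 2)) | ((lo == 1) & (hi == 3))
    decisive &= ~is_ts
    n_dec = int(decisive.sum())
    if n_dec == 0:
        raise ValueError("no decisive sites")
    return float((pair_ab & decisive).sum() / n_dec)


def records_to_frame(records: list[WindowTreeRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])
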