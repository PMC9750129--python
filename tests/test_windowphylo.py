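"""Window extraction, transversion distances, neighbor joining and
concordance factors."""

import io

import numpy as np
import pytest
from Bio import Phylo

from hippogen.siteops import N, SiteMatrix, encode
from hippogen.windowphylo import (
    DistanceMatrix,
    WindowConfig,
    classify_topology,
    distance_matrix,
    extract_windows,
    nj_tree,
    path_distance,
    site_concordance,
    topology_summary,
    transversion_distance,
    tree_length,
    window_tree_record,
)

QUARTET_SPECIES = {"b": "blue", "s": "sable", "r": "roan", "o": "outgroup"}


def parse(nwk):
    return Phylo.read(io.StringIO(nwk), "newick")


def quartet_tree_distances(ta, tb, tc, td, ti):
    """Pairwise path distances of the quartet ((A,B),(C,D)) with tip
    lengths ta..td and internal edge ti."""
    return {
        ("A", "B"): ta + tb,
        ("A", "C"): ta + ti + tc,
        ("A", "D"): ta + ti + td,
        ("B", "C"): tb + ti + tc,
        ("B", "D"): tb + ti + td,
        ("C", "D"): tc + td,
    }


def dm_from_dict(d, labels=("A", "B", "C", "D")):
    k = len(labels)
    m = np.zeros((k, k))
    for (x, y), v in d.items():
        i, j = labels.index(x), labels.index(y)
        m[i, j] = m[j, i] = v
    return DistanceMatrix(labels=list(labels), matrix=m)


def least_squares_best_quartet(d):
    """Brute-force oracle: fit all three quartet topologies by ordinary
    least squares on the 6 pairwise distances; return the pairing of taxon
    0 in the best topology."""
    pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
    y = np.array([d[i, j] for i, j in pairs])
    best = None
    for mate in (1, 2, 3):
        others = [x for x in (1, 2, 3) if x != mate]
        cherry1, cherry2 = {0, mate}, set(others)
        # design matrix over edges (t0,t1,t2,t3,internal)
        X = np.zeros((6, 5))
        for row, (i, j) in enumerate(pairs):
            X[row, i] = X[row, j] = 1
            same = ({i, j} == cherry1) or ({i, j} == cherry2)
            if not same:
                X[row, 4] = 1
        beta, res, *_ = np.linalg.lstsq(X, y, rcond=None)
        ssq = ((X @ beta - y) ** 2).sum()
        if best is None or ssq < best[0]:
            best = (ssq, mate)
    return best[1]


class TestExtractWindows:
    def test_tiling_with_gap(self):
        L = 250_000
        g = {t: {"s1": np.zeros(L, dtype=np.uint8)} for t in "ab"}
        wins = extract_windows(g, WindowConfig(window_size=20_000, gap=80_000))
        starts = [int(w.positions[0]) + 1 for w in wins]
        ends = [int(w.positions[-1]) + 1 for w in wins]
        assert starts == [1, 100_001, 200_001]
        assert ends == [20_000, 120_000, 220_000]

    def test_window_count_formula(self):
        cfg = WindowConfig(window_size=1000, gap=500)
        for L in (999, 1000, 2499, 2500, 10_000):
            g = {t: {"s1": np.zeros(L, dtype=np.uint8)} for t in "ab"}
            n = len(extract_windows(g, cfg))
            expect = 0 if L < 1000 else (L - 1000) // 1500 + 1
            assert n == expect

    def test_missing_taxon_drops_window(self):
        a = np.zeros(1000, dtype=np.uint8)
        b = np.zeros(1000, dtype=np.uint8)
        b[:600] = N  # 60% missing
        g = {"x": {"s1": a}, "y": {"s1": b}}
        assert extract_windows(g, WindowConfig(window_size=1000, gap=0, missing_threshold=0.5)) == []
        b[:500] = 0
        b[:400] = N  # 40% missing: kept
        assert len(extract_windows(g, WindowConfig(window_size=1000, gap=0, missing_threshold=0.5))) == 1

    def test_no_overlap(self):
        g = {t: {"s1": np.zeros(10_000, dtype=np.uint8)} for t in "ab"}
        wins = extract_windows(g, WindowConfig(window_size=700, gap=300))
        spans = [(int(w.positions[0]), int(w.positions[-1])) for w in wins]
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert s2 > e1


class TestTransversionDistance:
    def test_transitions_are_invisible(self):
        d, n = transversion_distance(encode("ACGT"), encode("GTAC"))
        assert (d, n) == (0.0, 4)

    def test_identical_and_saturated(self):
        assert transversion_distance(encode("ACGT"), encode("ACGT")) == (0.0, 4)
        assert transversion_distance(encode("AAAA"), encode("TTTT")) == (1.0, 4)

    def test_pairwise_deletion(self):
        d, n = transversion_distance(encode("ANTA"), encode("TNTN"))
        assert n == 2  # sites 0 and 2
        assert d == pytest.approx(0.5)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            transversion_distance(encode("AA"), encode("AAA"))


class TestNeighborJoining:
    def test_recovers_additive_quartet_exactly(self):
        d = quartet_tree_distances(1.0, 2.0, 3.0, 4.0, 1.0)
        tree = nj_tree(dm_from_dict(d))
        for x, y in d:
            assert tree.distance(x, y) == pytest.approx(d[(x, y)], abs=1e-12)
        assert tree_length(tree) == pytest.approx(11.0, abs=1e-12)

    def test_star_matrix_collapses_internal_branch(self):
        m = np.ones((4, 4)) - np.eye(4)
        tree = nj_tree(DistanceMatrix(labels=list("ABCD"), matrix=m))
        species = {"A": "blue", "B": "sable", "C": "roan", "D": "outgroup"}
        assert classify_topology(tree, species, tol=0.0) == "other"

    def test_matches_least_squares_oracle_on_random_additive_input(self):
        """On additive quartets NJ picks the same topology as brute-force
        least squares, every time."""
        rng = np.random.default_rng(5)
        for _ in range(200):
            tips = rng.uniform(0.05, 2.0, size=4)
            internal = rng.uniform(0.05, 1.0)
            labels = list("ABCD")
            perm = rng.permutation(4)
            d = np.zeros((4, 4))
            base = quartet_tree_distances(*tips, internal)
            for (x, y), v in base.items():
                i, j = perm[labels.index(x)], perm[labels.index(y)]
                d[i, j] = d[j, i] = v
            mate_oracle = least_squares_best_quartet(d)
            tree = nj_tree(DistanceMatrix(labels=[f"t{i}" for i in range(4)], matrix=d))
            # NJ sister of taxon t0
            from hippogen.windowphylo import _bipartitions

            (side, _), = _bipartitions(tree).items()
            pair = side if "t0" in side else frozenset(f"t{i}" for i in range(4)) - side
            mate_nj = int(next(x for x in pair if x != "t0")[1])
            assert mate_nj == mate_oracle

    def test_five_taxon_additive_recovery(self):
        # caterpillar ((A,B),C),D plus E off the root edge, via path sums
        nwk = "((A:1.0,B:2.0):0.5,(C:1.5,D:0.7):0.4,E:2.2);"
        ref = parse(nwk)
        labels = list("ABCDE")
        m = np.array([[0 if i == j else ref.distance(x, y) for j, y in enumerate(labels)] for i, x in enumerate(labels)])
        tree = nj_tree(DistanceMatrix(labels=labels, matrix=m))
        for i, x in enumerate(labels):
            for y in labels[i + 1 :]:
                assert tree.distance(x, y) == pytest.approx(ref.distance(x, y), abs=1e-10)

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(labels=["a", "b"], matrix=np.zeros((2, 2))))
        m = np.full((4, 4), np.nan)
        np.fill_diagonal(m, 0)
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(labels=list("abcd"), matrix=m))


class TestTopologyClassification:
    def test_quartet_classes(self):
        species = {"blue": "blue", "sable": "sable", "roan": "roan", "oryx": "outgroup"}
        assert classify_topology(parse("((blue:1,sable:1):1,(roan:1,oryx:1):1);"), species) == "BS"
        assert classify_topology(parse("((blue:1,roan:1):1,(sable:1,oryx:1):1);"), species) == "BR"
        assert classify_topology(parse("((roan:1,sable:1):1,(blue:1,oryx:1):1);"), species) == "RS"

    def test_short_internal_branch_is_other(self):
        species = {"blue": "blue", "sable": "sable", "roan": "roan", "oryx": "outgroup"}
        t = parse("((blue:1,roan:1):0.0000001,sable:1,oryx:1);")
        assert classify_topology(t, species, tol=1e-5) == "other"
        assert classify_topology(t, species, tol=0.0) == "BR"

    def test_five_taxon_nested_vs_sister(self):
        species = {
            "roan1": "roan",
            "roan2": "roan",
            "blue": "blue",
            "sable": "sable",
            "oryx": "outgroup",
        }
        sister = parse("(((roan1:1,roan2:1):1,blue:2):1,(sable:1,oryx:1):1);")
        nested = parse("(((roan1:1,blue:1):1,roan2:2):1,(sable:1,oryx:1):1);")
        bs = parse("(((roan1:1,roan2:1):1,(blue:1,sable:1):1):1,oryx:1);")
        assert classify_topology(sister, species) == "BR"
        assert classify_topology(nested, species) == "BR_nested"
        assert classify_topology(bs, species) == "BS"

    def test_missing_outgroup_raises(self):
        species = {"blue": "blue", "sable": "sable", "roan": "roan", "oryx": "roan"}
        with pytest.raises(ValueError):
            classify_topology(parse("((blue:1,sable:1):1,(roan:1,oryx:1):1);"), species)


class TestSummaries:
    def test_topology_summary_proportions(self):
        classes = ["BS"] * 5 + ["BR"] * 3 + ["RS"] * 2
        s = topology_summary(classes)
        assert s["BS"] == pytest.approx(0.5)
        assert s["BR"] == pytest.approx(0.3)
        assert s["RS"] == pytest.approx(0.2)
        assert s["other"] == 0.0
        assert sum(s.values()) == pytest.approx(1.0)

    def test_all_concordant(self):
        s = topology_summary(["BS", "BS"])
        assert (s["BS"], s["BR"], s["RS"], s["other"]) == (1.0, 0.0, 0.0, 0.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            topology_summary([])

    def test_site_concordance_hand_built(self):
        """12 columns, 3 decisive 2+2 transversion sites of which 2 pair
        blue with sable -> sCF = 2/3."""
        #  decisive columns: 0 AATT (conc), 1 ATAT (disc), 2 CCGG (conc);
        #  columns 3-5 monomorphic, 6/7/8 are 3+1 splits, 9 has missing data
        b = "A A C AAA C T G N"
        s = "A T C AAA C T G A"
        r = "T A G AAA C T G A"
        o = "T T G AAA G C C A"
        rows = [x.replace(" ", "") for x in (b, s, r, o)]
        mat = SiteMatrix(
            individuals=["b", "s", "r", "o"],
            data=np.stack([encode(x) for x in rows]),
        )
        scf = site_concordance(mat, QUARTET_SPECIES, ("blue", "sable"))
        assert scf == pytest.approx(2.0 / 3.0)

    def test_site_concordance_pure_patterns(self):
        conc = SiteMatrix(
            individuals=["b", "s", "r", "o"],
            data=np.stack([encode("AAAA"), encode("AAAA"), encode("TTTT"), encode("TTTT")]),
        )
        assert site_concordance(conc, QUARTET_SPECIES, ("blue", "sable")) == 1.0
        thirds = SiteMatrix(
            individuals=["b", "s", "r", "o"],
            data=np.stack([encode("AAA"), encode("ATA"), encode("TAA"), encode("TTA")]),
        )
        # col0 xxyy conc, col1 xyxy disc, col2 monomorphic -> 1/2
        assert site_concordance(thirds, QUARTET_SPECIES, ("blue", "sable")) == 0.5

    def test_transition_sites_not_decisive(self):
        mat = SiteMatrix(
            individuals=["b", "s", "r", "o"],
            data=np.stack([encode("C"), encode("C"), encode("T"), encode("T")]),
        )
        with pytest.raises(ValueError):
            site_concordance(mat, QUARTET_SPECIES, ("blue", "sable"))


def test_window_tree_record_end_to_end(small_called):
    truth, genomes = small_called
    from hippogen.workflows import window_records_for

    records = window_records_for(genomes, truth.window_length)
    assert records, "no windows survived"
    for r in records:
        assert r.topology_class in ("BS", "BR", "RS", "other")
        assert 0.0 <= r.rs_path_proportion <= 1.0
        assert r.tree_length >= 0.0
        assert r.end - r.start + 1 == truth.window_length
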