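import itertools
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score

from dcmotif import divide, synth
from dcmotif.divide import (
    Cluster,
    SubmotifTree,
    agglomerative_divide,
    build_hierarchy,
    hierarchical_possibilistic,
    hypergeom_overlap,
    partition_to_clusters,
    pfcm,
    select_cluster_numbers,
    subtractive_divide,
    xie_beni,
)
from dcmotif.encode import PWMModel, build_pwm, score_sequence
from dcmotif.errors import ConfigurationError, SeparationZeroError, ValidationError
from dcmotif.seqio import BindingSite, SiteCollection, one_hot_encode

from .conftest import consensus_pwm, tight_mixture


def two_tight_groups():
    sites = [
        BindingSite("AAAAAAAAAA", "t1"),
        BindingSite("AAAAAAAAAC", "t2"),
        BindingSite("AAAAAAAAAG", "t3"),
        BindingSite("GGGGGGGGGG", "t4"),
        BindingSite("GGGGGGGGGC", "t5"),
        BindingSite("GGGGGGGGGA", "t6"),
    ]
    return one_hot_encode(SiteCollection(sites))


class TestPfcm:
    def test_membership_one_at_centroid(self):
        feats = two_tight_groups()
        part = pfcm(feats, 2, eta=1.0, seed=3)
        d2 = ((feats.data[:, None, :] - part.centroids[None]) ** 2).sum(-1)
        at_centroid = np.isclose(d2.min(axis=1), 0.0)
        if at_centroid.any():
            j = int(np.flatnonzero(at_centroid)[0])
            assert part.memberships[:, j].max() == pytest.approx(1.0)

    def test_single_cluster_centroid_is_weighted_mean(self):
        feats = two_tight_groups()
        part = pfcm(feats, 1, eta=1.0, seed=0, tol=1e-12, max_iter=2000)
        w = part.memberships[0] ** part.fuzzifier
        expected = (w[:, None] * feats.data).sum(0) / w.sum()
        np.testing.assert_allclose(part.centroids[0], expected, atol=1e-9)

    def test_fixed_point_oracle(self):
        """Independently coded fixed-point iteration agrees to 1e-8."""
        feats = two_tight_groups()
        part = pfcm(feats, 2, eta=1.0, m=2.0, seed=3, tol=1e-9)
        X = feats.data
        rng = np.random.default_rng(3)
        uniq = np.unique(X, axis=0)
        V = uniq[rng.choice(len(uniq), 2, replace=False)].astype(float)
        for _ in range(300):
            d2 = ((X[:, None, :] - V[None]) ** 2).sum(-1).T
            u = 1.0 / (1.0 + d2)
            u[d2 == 0.0] = 1.0
            V_new = (u**2 @ X) / (u**2).sum(axis=1, keepdims=True)
            if np.abs(V_new - V).max() < 1e-9:
                V = V_new
                break
            V = V_new
        d2 = ((X[:, None, :] - V[None]) ** 2).sum(-1).T
        u = 1.0 / (1.0 + d2)
        u[d2 == 0.0] = 1.0
        assert np.abs(u - part.memberships).max() < 1e-8
        assert np.abs(V - part.centroids).max() < 1e-8

    def test_c_exceeds_n(self):
        feats = two_tight_groups()
        with pytest.raises(ConfigurationError):
            pfcm(feats, 7, seed=0)

    def test_identical_features_degenerate(self):
        coll = SiteCollection([BindingSite("ACGT", f"s{i}") for i in range(4)])
        part = pfcm(one_hot_encode(coll), 2, eta=1.0, seed=0)
        assert not part.converged

    def test_seed_determinism(self):
        feats = two_tight_groups()
        a = pfcm(feats, 2, eta="auto", seed=42)
        b = pfcm(feats, 2, eta="auto", seed=42)
        np.testing.assert_array_equal(a.memberships, b.memberships)
        np.testing.assert_array_equal(a.centroids, b.centroids)

    def test_memberships_bounded_and_outlier_low(self):
        sites = [BindingSite("A" * 12, f"a{i}") for i in range(1)]
        sites += [BindingSite("A" * 11 + "C", "a2"), BindingSite("A" * 11 + "G", "a3")]
        sites += [BindingSite("C" * 12, "b1"), BindingSite("C" * 11 + "G", "b2"),
                  BindingSite("C" * 11 + "T", "b3")]
        sites.append(BindingSite("ACGTACGTACGT", "outlier"))
        feats = one_hot_encode(SiteCollection(sites))
        # seed chosen so the initial centroids land inside the two groups
        part = pfcm(feats, 2, eta=1.0, seed=0)
        assert (part.memberships <= 1.0).all() and (part.memberships >= 0.0).all()
        out_col = feats.site_ids.index("outlier")
        # possibilistic property: far-from-everything point belongs weakly
        assert part.memberships[:, out_col].sum() < 0.2


class TestXieBeni:
    def test_planted_two_groups_minimized_at_two(self):
        feats = two_tight_groups()
        vals = {}
        for c in (2, 3, 4):
            best = np.inf
            for s in range(5):
                part = pfcm(feats, c, eta=1.0, seed=s)
                try:
                    best = min(best, xie_beni(feats, part))
                except SeparationZeroError:
                    continue
            vals[c] = best
        assert vals[2] < vals[3] and vals[2] < vals[4]

    def test_coincident_centroids_error(self):
        feats = two_tight_groups()
        part = pfcm(feats, 2, eta=1.0, seed=0)
        part.centroids[1] = part.centroids[0]
        with pytest.raises(SeparationZeroError):
            xie_beni(feats, part)

    def test_scale_equivariance_of_argmin(self):
        coll, _ = tight_mixture(7, k=3)
        feats = one_hot_encode(coll)
        sel1 = select_cluster_numbers(feats, range(2, 6), runs_per_c=3, seed=1)
        feats.data = feats.data * 3.0
        sel2 = select_cluster_numbers(feats, range(2, 6), runs_per_c=3, seed=1)
        assert sel1 == sel2


class TestSelectClusterNumbers:
    def test_planted_three_groups(self):
        coll, _ = tight_mixture(11, k=3)
        assert select_cluster_numbers(
            one_hot_encode(coll), range(2, 7), runs_per_c=4, seed=2
        ) == [3]

    def test_single_candidate(self):
        coll = SiteCollection(
            [BindingSite("AAAA", "a"), BindingSite("CCCC", "b"),
             BindingSite("GGGG", "c")]
        )
        assert select_cluster_numbers(
            one_hot_encode(coll), [2], runs_per_c=2, seed=0
        ) == [2]

    def test_empty_range(self):
        coll, _ = tight_mixture(0)
        with pytest.raises(ConfigurationError):
            select_cluster_numbers(one_hot_encode(coll), [], seed=0)


class TestHypergeomOverlap:
    def test_p_zero_is_one(self):
        assert hypergeom_overlap(0, 3, 3, 10) == 1.0

    def test_full_forced_overlap(self):
        assert hypergeom_overlap(4, 4, 4, 4) == pytest.approx(1.0)

    def test_exact_enumeration_value(self):
        # P(X>=2) with h=n=3, g=6: 9/20 + 1/20 = 0.5
        assert hypergeom_overlap(2, 3, 3, 6) == pytest.approx(0.5)

    def test_inconsistent_counts(self):
        with pytest.raises(ValidationError):
            hypergeom_overlap(4, 3, 5, 10)

    @given(st.integers(2, 12), st.data())
    @settings(max_examples=40, deadline=None)
    def test_matches_enumeration_oracle(self, g, data):
        h = data.draw(st.integers(1, g))
        n = data.draw(st.integers(1, g))
        p = data.draw(st.integers(0, min(h, n)))
        # brute force over all h-subsets of range(g)
        marked = set(range(n))
        total = hits = 0
        for subset in itertools.combinations(range(g), h):
            total += 1
            hits += len(marked & set(subset)) >= p
        assert hypergeom_overlap(p, h, n, g) == pytest.approx(hits / total)

    @given(st.integers(2, 12), st.data())
    @settings(max_examples=30, deadline=None)
    def test_monotone_in_p(self, g, data):
        h = data.draw(st.integers(1, g))
        n = data.draw(st.integers(1, g))
        vals = [hypergeom_overlap(p, h, n, g) for p in range(min(h, n) + 1)]
        assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))


class TestBuildHierarchy:
    def test_disjoint_clusters_under_root(self):
        all_ids = [f"s{i}" for i in range(10)]
        cl = [
            Cluster(frozenset(all_ids[:5])),
            Cluster(frozenset(all_ids[5:])),
        ]
        tree = build_hierarchy(cl, all_ids, alpha_hier=0.01)
        kids = tree.nodes[tree.root].children
        assert len(kids) == 2
        assert all(tree.nodes[k].parent == tree.root for k in kids)

    def test_containment_chain(self):
        # B subset of A, A small relative to the universe, so containment
        # is hypergeometrically significant: PI = C(10,5)/C(40,5) ~ 4e-4
        all_ids = [f"s{i}" for i in range(40)]
        a = Cluster(frozenset(all_ids[:10]))
        b = Cluster(frozenset(all_ids[:5]))
        tree = build_hierarchy([a, b], all_ids, alpha_hier=0.05)
        big = next(n for n in tree.nodes.values() if n.size == 10)
        small = next(n for n in tree.nodes.values() if n.size == 5)
        assert big.parent == tree.root
        assert small.parent == big.node_id

    def test_json_roundtrip(self):
        all_ids = [f"s{i}" for i in range(6)]
        tree = build_hierarchy(
            [Cluster(frozenset(all_ids[:3])), Cluster(frozenset(all_ids[3:]))],
            all_ids,
        )
        back = SubmotifTree.from_json(tree.to_json())
        assert back.root == tree.root
        assert {k: v.member_ids for k, v in back.nodes.items()} == {
            k: v.member_ids for k, v in tree.nodes.items()
        }

    @given(st.data())
    @settings(max_examples=30, deadline=None)
    def test_acyclic_and_root_complete_random_pools(self, data):
        g = data.draw(st.integers(4, 20))
        all_ids = [f"s{i}" for i in range(g)]
        n_clusters = data.draw(st.integers(1, 6))
        pool = []
        for _ in range(n_clusters):
            size = data.draw(st.integers(1, g))
            members = data.draw(
                st.sets(st.sampled_from(all_ids), min_size=size, max_size=size)
            )
            pool.append(Cluster(frozenset(members)))
        tree = build_hierarchy(pool, all_ids, alpha_hier=0.05)
        assert tree.is_acyclic()
        assert tree.nodes[tree.root].member_ids == frozenset(all_ids)
        for k, node in tree.nodes.items():
            if k != tree.root:
                assert node.parent in tree.nodes


class TestAgglomerative:
    def test_two_groups(self):
        sites = [
            BindingSite("AAAAAAAAAA", "a1"), BindingSite("AAAAAAAAAC", "a2"),
            BindingSite("AAAAAAAACC", "a3"), BindingSite("GGGGGGGGGG", "b1"),
            BindingSite("GGGGGGGGGT", "b2"), BindingSite("GGGGGGGTGT", "b3"),
        ]
        cl = agglomerative_divide(one_hot_encode(SiteCollection(sites)))
        assert sorted(sorted(c.member_ids) for c in cl) == [
            ["a1", "a2", "a3"], ["b1", "b2", "b3"],
        ]

    def test_two_sites_huge_cutoff(self):
        coll = SiteCollection([BindingSite("AAAA", "a"), BindingSite("CCCC", "b")])
        cl = agglomerative_divide(one_hot_encode(coll), inconsistency_cutoff=100.0)
        assert len(cl) == 1

    def test_equally_spaced_chain_one_cluster(self):
        chain = [BindingSite("A" * (10 - i) + "C" * i, f"c{i}") for i in range(8)]
        cl = agglomerative_divide(one_hot_encode(SiteCollection(chain)))
        assert len(cl) == 1

    def test_identical_data_one_cluster(self):
        coll = SiteCollection([BindingSite("ACGT", f"s{i}") for i in range(4)])
        assert len(agglomerative_divide(one_hot_encode(coll))) == 1


def _subtractive_fixture(seed):
    """30 A-family + 10 B-family positives; negatives concentrated in the
    blend-score band between the two families (other-TF-like decoys)."""
    rng = np.random.default_rng(seed)
    A = consensus_pwm(rng, name="A")
    B = consensus_pwm(rng, name="B")
    a = synth.sample_sites(A, 30, seed=seed + 1, prefix="A")
    b = synth.sample_sites(B, 10, seed=seed + 2, prefix="B")
    pos = SiteCollection(a.sites + b.sites)
    blend = build_pwm(pos)
    weak = np.where(A.freqs == A.freqs.max(axis=0), 0.6, 0.4 / 3)
    W = PWMModel(freqs=weak / weak.sum(axis=0), name="W")
    negs, k, tries = [], 0, 0
    while len(negs) < 40 and tries < 300:
        tries += 1
        for s in synth.sample_sites(W, 20, seed=seed * 1000 + tries):
            if len(negs) < 40 and 0.80 <= score_sequence(blend, s.sequence) <= 0.90:
                negs.append(BindingSite(s.sequence, f"n{k}"))
                k += 1
    for i, s in enumerate(
        synth.sample_background(0, [0.25] * 4, 19, 20, seed + 6)
    ):
        negs.append(BindingSite(s, f"nbg{i}"))
    return pos, SiteCollection(negs)


class TestSubtractive:
    def test_single_planted_motif_one_cluster(self):
        rng = np.random.default_rng(4)
        A = consensus_pwm(rng, name="A")
        pos = synth.sample_sites(A, 30, seed=5, prefix="A")
        neg = SiteCollection(
            [BindingSite(s, f"n{i}") for i, s in
             enumerate(synth.sample_background(0, [0.25] * 4, 19, 40, 7))]
        )
        cl = subtractive_divide(pos, neg)
        assert len(cl) == 1
        assert cl[0].size >= 27  # >= 90% of the planted sites

    def test_two_dissimilar_motifs_recovered(self):
        pos, neg = _subtractive_fixture(0)
        cl = subtractive_divide(pos, neg)
        assign = {}
        for i, c in enumerate(cl):
            for s in c.member_ids:
                assign[s] = i
        truth = [0 if sid.startswith("A") else 1 for sid in pos.site_ids]
        pred = [assign.get(sid, -1) for sid in pos.site_ids]
        assert len(cl) >= 2
        assert adjusted_rand_score(truth, pred) >= 0.9

    def test_no_signal_empty_result(self):
        rng = np.random.default_rng(9)
        seqs = synth.sample_background(0, [0.25] * 4, 19, 30, 2)
        pos = SiteCollection([BindingSite(s, f"p{i}") for i, s in enumerate(seqs)])
        neg = SiteCollection([BindingSite(s, f"n{i}") for i, s in enumerate(seqs)])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert subtractive_divide(pos, neg) == []


class TestAgreementAcrossMethods:
    def test_all_methods_recover_planted_partition(self):
        coll, labels = tight_mixture(21, k=3)
        feats = one_hot_encode(coll)
        # pfcm hard assignments: rank restarts at the selection bandwidth,
        # extract from the same seed at the extraction bandwidth (as the
        # hierarchical driver does)
        best_seed, best_xb = None, np.inf
        for s in range(5):
            part = pfcm(feats, 3, eta="auto", seed=s)
            try:
                val = xie_beni(feats, part)
            except SeparationZeroError:
                continue
            if val < best_xb:
                best_seed, best_xb = s, val
        best_part = pfcm(feats, 3, eta="auto-max", seed=best_seed)
        cl_p = partition_to_clusters(best_part, feats.site_ids)
        # agglomerative
        # single-linkage inconsistency is scale-sensitive; the three-group
        # geometry needs a slightly tighter cutoff than the toolbox default
        cl_a = agglomerative_divide(feats, inconsistency_cutoff=1.0)
        for cl in (cl_p, cl_a):
            assign = {}
            for i, c in enumerate(cl):
                for s in c.member_ids:
                    assign[s] = i
            pred = [assign.get(sid, -1) for sid in feats.site_ids]
            assert adjusted_rand_score(labels, pred) >= 0.9


class TestHierarchicalDriver:
    def test_recovers_planted_families(self):
        coll, labels = tight_mixture(2, k=3)
        feats = one_hot_encode(coll)
        tree = hierarchical_possibilistic(feats, range(2, 7), runs_per_c=5, seed=8)
        assert tree.is_acyclic()
        assign = {}
        for i, node in enumerate(tree.leaves()):
            for sid in node.member_ids:
                assign[sid] = i
        pred = [assign.get(sid, -1) for sid in feats.site_ids]
        assert adjusted_rand_score(labels, pred) >= 0.9
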