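import itertools

import numpy as np
import pytest

from mcist import ensemble, synth
from mcist.ensemble import (
    ClusterLabels,
    ari,
    cluster_embedding,
    co_association,
    consensus_cluster,
    nmi,
    rsi,
    run_mcist,
    select_by_rsi,
)


def labels_of(arr):
    arr = np.asarray(arr)
    return ClusterLabels(
        spot_ids=np.array([f"s{j}" for j in range(len(arr))], dtype=object),
        labels=arr,
    )


def blobs(seed=0, n_per=25, d=3, sep=10.0, sigma=0.1):
    rng = np.random.default_rng(seed)
    centers = np.vstack([np.zeros(d), np.full(d, sep)])
    F = np.vstack([c + sigma * rng.standard_normal((n_per, d)) for c in centers])
    truth = np.repeat([0, 1], n_per)
    return F, truth


# ---------------------------------------------------------------------------
# cluster_embedding
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("method", ["gmm", "leiden"])
def test_separated_blobs_recovered(method):
    F, truth = blobs(seed=1)
    lab = cluster_embedding(F, method=method, n_clusters=2, seed=0)
    assert ari(lab, labels_of(truth)) == pytest.approx(1.0)


def test_clustering_deterministic():
    F, _ = blobs(seed=2)
    a = cluster_embedding(F, "gmm", 2, seed=7)
    b = cluster_embedding(F, "gmm", 2, seed=7)
    np.testing.assert_array_equal(a.labels, b.labels)


def test_n_clusters_exceeds_n():
    F, _ = blobs(n_per=3)
    with pytest.raises(ValueError, match="n_clusters"):
        cluster_embedding(F, "gmm", 10, seed=0)


def test_unknown_method():
    with pytest.raises(ValueError, match="method"):
        cluster_embedding(np.eye(4), "kmedoids", 2, seed=0)


# ---------------------------------------------------------------------------
# co_association
# ---------------------------------------------------------------------------


def test_co_association_identical_labelings():
    C = co_association([labels_of([0, 0, 1, 1])] * 3).C
    expected = np.array([
        [1, 1, 0, 0],
        [1, 1, 0, 0],
        [0, 0, 1, 1],
        [0, 0, 1, 1],
    ], dtype=float)
    np.testing.assert_allclose(C, expected)


def test_co_association_two_member_toy():
    C = co_association([labels_of([0, 0, 1]), labels_of([0, 1, 1])]).C
    assert C[0, 1] == pytest.approx(0.5)
    assert C[1, 2] == pytest.approx(0.5)
    assert C[0, 2] == pytest.approx(0.0)
    np.testing.assert_allclose(np.diag(C), 1.0)


def test_co_association_brute_force_equivalence():
    rng = np.random.default_rng(3)
    sets = [labels_of(rng.integers(0, 4, 15)) for _ in range(5)]
    C = co_association(sets).C
    for i, j in itertools.combinations(range(15), 2):
        expected = np.mean([s.labels[i] == s.labels[j] for s in sets])
        assert C[i, j] == pytest.approx(expected)
        assert C[j, i] == pytest.approx(expected)


def test_co_association_length_mismatch():
    with pytest.raises(ValueError, match="mismatch"):
        co_association([labels_of([0, 1]), labels_of([0, 1, 2])])


# ---------------------------------------------------------------------------
# consensus_cluster
# ---------------------------------------------------------------------------


def test_consensus_perfect_blocks():
    C = co_association([labels_of([0, 0, 0, 1, 1])] * 4)
    lab = consensus_cluster(C, 2)
    assert ari(lab, labels_of([0, 0, 0, 1, 1])) == pytest.approx(1.0)


def test_consensus_toy_tie_structure():
    # distances: d01 = d12 = 0.5, d02 = 1.0 -> first merge joins a 0.5 pair,
    # the remaining singleton stays out at 2 clusters
    C = co_association([labels_of([0, 0, 1]), labels_of([0, 1, 1])])
    lab = consensus_cluster(C, 2)
    sizes = sorted(np.bincount(lab.labels))
    assert sizes == [1, 2]
    again = consensus_cluster(C, 2)
    np.testing.assert_array_equal(lab.labels, again.labels)


def test_consensus_singletons_at_n():
    C = co_association([labels_of([0, 1, 2, 3])])
    lab = consensus_cluster(C, 4)
    assert lab.n_clusters == 4


def test_consensus_bounds():
    C = co_association([labels_of([0, 1])])
    with pytest.raises(ValueError, match="n_domains"):
        consensus_cluster(C, 5)


def test_consensus_invariant_to_member_order_and_spot_permutation():
    # noisy-block members: merge decisions are untied, so the dendrogram is
    # the same after shuffling members or (up to relabeling) permuting spots
    rng = np.random.default_rng(8)
    truth = np.repeat([0, 1, 2], 4)
    sets = []
    for i in range(7):
        lab = truth.copy()
        flip = rng.integers(0, 12)
        lab[flip] = (lab[flip] + 1 + i % 2) % 3
        sets.append(labels_of(lab))
    base = consensus_cluster(co_association(sets), 3)
    shuffled = consensus_cluster(co_association(sets[::-1]), 3)
    assert ari(base, shuffled) == pytest.approx(1.0)
    perm = rng.permutation(12)
    permuted_sets = [labels_of(s.labels[perm]) for s in sets]
    permuted = consensus_cluster(co_association(permuted_sets), 3)
    assert ari(labels_of(base.labels[perm]), permuted) == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# rsi / select_by_rsi
# ---------------------------------------------------------------------------


def test_rsi_ideal_clusters_score_one():
    F = np.array([[0.0, 0], [0, 0], [100, 0], [100, 0]])
    rep = rsi(F, labels_of([0, 0, 1, 1]))
    assert rep.rsi == pytest.approx(1.0)
    np.testing.assert_allclose(rep.per_sample_similarity, 1.0)
    np.testing.assert_allclose(rep.per_sample_residue, 1.0)


def test_rsi_hand_example_line():
    # points 0, 1, 10, 11 labeled [0,0,1,1]; direct evaluation gives 215/231
    F = np.array([[0.0], [1.0], [10.0], [11.0]])
    rep = rsi(F, labels_of([0, 0, 1, 1]))
    assert rep.rsi == pytest.approx(215 / 231, abs=1e-12)


def test_rsi_single_class_error():
    with pytest.raises(ValueError, match="one cluster"):
        rsi(np.eye(3), labels_of([0, 0, 0]))


def test_rsi_true_labels_beat_random():
    wins = 0
    for seed in range(20):
        F, truth = blobs(seed=seed, n_per=15, sigma=0.5)
        rng = np.random.default_rng(seed + 1000)
        random_lab = rng.permutation(np.repeat([0, 1], 15))
        if rsi(F, labels_of(truth)).rsi > rsi(F, labels_of(random_lab)).rsi:
            wins += 1
    assert wins >= 19


def test_select_by_rsi():
    F_good, truth = blobs(seed=4, sigma=0.1)
    rng = np.random.default_rng(4)
    shuffled = rng.permutation(truth)
    assert select_by_rsi([(F_good, labels_of(truth)),
                          (F_good, labels_of(shuffled))]) == 0
    assert select_by_rsi([(F_good, labels_of(truth))]) == 0
    # exact tie -> lowest index
    assert select_by_rsi([(F_good, labels_of(truth)),
                          (F_good, labels_of(truth))]) == 0


# ---------------------------------------------------------------------------
# nmi / ari
# ---------------------------------------------------------------------------


def test_agreement_metrics_known_values():
    a = labels_of([0, 0, 1, 1])
    assert nmi(a, a) == pytest.approx(1.0)
    assert ari(a, a) == pytest.approx(1.0)
    assert nmi(a, labels_of([0, 0, 0, 0])) == pytest.approx(0.0)
    # independent crossing partitions: MI = 0, ARI = -0.5 by direct evaluation
    b = labels_of([0, 1, 0, 1])
    assert nmi(a, b) == pytest.approx(0.0, abs=1e-12)
    assert ari(a, b) == pytest.approx(-0.5)


def test_metrics_length_mismatch():
    with pytest.raises(ValueError, match="mismatch"):
        nmi(labels_of([0, 1]), labels_of([0, 1, 2]))


# ---------------------------------------------------------------------------
# run_mcist end to end (small)
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def small_synth():
    from mcist import io_prep

    ds = synth.generate(synth.SynthConfig(
        grid=(8, 15), n_domains=4, n_genes=80, n_markers_per_domain=12,
        marker_log2fc=2.0, dropout_rate=0.05, seed=0))
    X = io_prep.qc_filter(ds.expression, 3, 5)
    X = io_prep.normalize_log(X)
    X = io_prep.select_hvg(X, n_top=80)
    return ds, X


def test_run_mcist_smoke_and_determinism(small_synth):
    ds, X = small_synth
    kw = dict(coords=ds.coords, n_domains=4, ks=(8, 5), seed=0)
    r1 = run_mcist(X, **kw)
    r2 = run_mcist(X, **kw)
    np.testing.assert_array_equal(r1.domains.labels, r2.domains.labels)
    assert r1.domains.n_clusters == 4
    assert len(r1.member_labelsets) == 3
    np.testing.assert_allclose(r1.co_association.C, r2.co_association.C)


def test_run_mcist_rsi_select_mode(small_synth):
    ds, X = small_synth
    res = run_mcist(X, coords=ds.coords, n_domains=4, ks=(8, 5),
                    mode="rsi_select", seed=0)
    assert res.selected_embedding is not None
    assert res.co_association is None
    assert res.domains.n_clusters == 4
    best = int(np.argmax([r.rsi for r in res.rsi_reports]))
    assert res.selected_embedding == best


def test_run_mcist_requires_processed_input(small_synth):
    ds, _ = small_synth
    with pytest.raises(ValueError, match="log-transformed"):
        run_mcist(ds.expression, coords=ds.coords, n_domains=4)


def test_nmi_improves_with_separation():
    """Mean recovery is non-decreasing as planted fold change grows."""
    from mcist import io_prep

    means = []
    for fc in (0.5, 3.0):
        vals = []
        for seed in range(10):
            ds = synth.generate(synth.SynthConfig(
                grid=(6, 12), n_domains=3, n_genes=60,
                n_markers_per_domain=10, marker_log2fc=fc,
                dropout_rate=0.05, seed=seed))
            X = io_prep.qc_filter(ds.expression, 3, 5)
            X = io_prep.normalize_log(X)
            res = run_mcist(X, coords=ds.coords, n_domains=3, ks=(6, 4),
                            seed=seed)
            vals.append(nmi(res.domains, ds.truth))
        means.append(np.mean(vals))
    assert means[1] >= means[0]
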