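"""Tied-covariance EM, model scan, and the clustering diagnostics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.mixture import GaussianMixture

from deupanel import mixture
from deupanel.mixture import TiedGMM, n_params_full, n_params_tied


def two_masses(n=20, sep=5.0, seed=0, sd=0.05):
    rng = np.random.default_rng(seed)
    a = rng.normal(0, sd, (n, 3))
    b = rng.normal(0, sd, (n, 3)) + sep
    return np.vstack([a, b]), np.r_[np.zeros(n, int), np.ones(n, int)]


def brute_force_ari(labels_a, labels_b):
    """Pair-counting ARI computed over all item pairs."""
    a, b, c, d = 0, 0, 0, 0
    for i, j in itertools.combinations(range(len(labels_a)), 2):
        sa = labels_a[i] == labels_a[j]
        sb = labels_b[i] == labels_b[j]
        if sa and sb:
            a += 1
        elif sa:
            b += 1
        elif sb:
            c += 1
        else:
            d += 1
    if b == 0 and c == 0:
        return 1.0
    return 2.0 * (a * d - b * c) / ((a + b) * (b + d) + (a + c) * (c + d))


def set_partitions(items):
    """All set partitions of a list (restricted-growth strings)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def partition_to_labels(partition, n):
    labels = np.empty(n, dtype=int)
    for k, block in enumerate(partition):
        for item in block:
            labels[item] = k
    return labels


# -- TiedGMM ----------------------------------------------------------------

def test_separated_masses_recovered_exactly():
    X, truth = two_masses()
    model = TiedGMM(n_components=2, random_state=0).fit(X)
    assert mixture.adjusted_rand_index(truth, model.labels_) == 1.0
    resp = model.responsibilities_
    assert np.all((resp > 0.999) | (resp < 0.001))
    centers = model.means_[np.argsort(model.means_[:, 0])]
    assert np.allclose(centers, [[0, 0, 0], [5, 5, 5]], atol=0.05)


def test_parameter_count_and_bic_consistency():
    assert n_params_tied(4, 3) == 21
    assert n_params_full(4, 3) == 39
    X, _ = two_masses(seed=1)
    model = TiedGMM(n_components=2, random_state=1).fit(X)
    assert model.n_params_ == n_params_tied(2, 3)
    assert model.bic_ == pytest.approx(
        -2 * model.log_likelihood_ + model.n_params_ * np.log(len(X)), abs=1e-10)


def test_em_invariants_on_random_data():
    """Log-likelihood monotone, responsibilities normalised, tied covariance
    symmetric positive definite — on every fit."""
    rng = np.random.default_rng(2)
    for k in (2, 3, 4):
        X = rng.normal(0, 1, (60, 3)) + rng.integers(0, 3, (60, 1))
        model = TiedGMM(n_components=k, n_init=3, random_state=int(rng.integers(1000))).fit(X)
        trace = model.loglik_trace_
        assert np.all(np.diff(trace) >= -1e-8)
        assert np.allclose(model.responsibilities_.sum(axis=1), 1.0)
        assert np.allclose(model.weights_.sum(), 1.0)
        cov = model.covariance_
        assert np.allclose(cov, cov.T)
        assert np.linalg.eigvalsh(cov).min() > 0


def test_tied_em_agrees_with_sklearn_reference():
    """On well-separated data both our EM and scikit-learn's tied-covariance
    mixture reach the same optimum (log-likelihood and BIC convention)."""
    X, _ = two_masses(n=30, seed=3)
    ours = TiedGMM(n_components=2, n_init=3, random_state=0).fit(X)
    theirs = GaussianMixture(n_components=2, covariance_type="tied",
                             n_init=3, random_state=0).fit(X)
    ll_theirs = theirs.score(X) * len(X)
    assert ours.log_likelihood_ == pytest.approx(ll_theirs, rel=1e-4)
    assert ours.bic_ == pytest.approx(theirs.bic(X), rel=1e-4)


def test_fit_validation_errors():
    X = np.random.default_rng(0).normal(size=(5, 3))
    with pytest.raises(ValueError):
        TiedGMM(n_components=1).fit(X)
    with pytest.raises(ValueError):
        TiedGMM(n_components=5).fit(X)


def test_predict_consistent_with_training_labels():
    X, _ = two_masses(seed=4)
    model = TiedGMM(n_components=2, random_state=4).fit(X)
    assert np.array_equal(model.predict(X), model.labels_)
    assert np.allclose(model.predict_proba(X), model.responsibilities_, atol=1e-9)


# -- k-means and silhouette -------------------------------------------------

def test_kmeans_two_masses_exact():
    X, truth = two_masses(seed=5)
    labels = mixture.fit_kmeans(X, 2, seed=0)
    assert mixture.adjusted_rand_index(truth, labels) == 1.0


def test_kmeans_matches_exhaustive_two_partition():
    rng = np.random.default_rng(6)
    X = rng.normal(0, 1, (6, 3))
    labels = mixture.fit_kmeans(X, 2, seed=0, n_restarts=20)

    def inertia(lab):
        return sum(((X[lab == c] - X[lab == c].mean(axis=0)) ** 2).sum()
                   for c in np.unique(lab))

    best = min(
        inertia(np.array(assign))
        for assign in itertools.product([0, 1], repeat=6)
        if 0 < sum(assign) < 6
    )
    assert inertia(labels) == pytest.approx(best)


def test_silhouette_limits_and_oracle():
    X, truth = two_masses(n=10, sep=50.0, seed=7)
    assert mixture.silhouette_mean(X, truth) > 0.98

    rng = np.random.default_rng(8)
    Y = rng.normal(0, 1, (8, 3))
    labels = np.array([0, 0, 0, 0, 1, 1, 1, 1])
    D = np.sqrt(((Y[:, None] - Y[None, :]) ** 2).sum(-1))
    vals = []
    for i in range(8):
        same = (labels == labels[i]) & (np.arange(8) != i)
        a = D[i, same].mean()
        b = D[i, labels != labels[i]].mean()
        vals.append((b - a) / max(a, b))
    assert mixture.silhouette_mean(Y, labels) == pytest.approx(np.mean(vals))
    with pytest.raises(ValueError):
        mixture.silhouette_mean(Y, np.zeros(8, int))


def test_random_labels_on_one_blob_score_near_zero():
    rng = np.random.default_rng(9)
    X = rng.normal(0, 1, (200, 3))
    labels = rng.integers(0, 2, 200)
    assert abs(mixture.silhouette_mean(X, labels)) < 0.1


# -- model scan -------------------------------------------------------------

def test_model_scan_table_and_determinism():
    rng = np.random.default_rng(10)
    X = rng.normal(0, 0.3, (40, 3)) + rng.integers(0, 3, (40, 1))
    scan1 = mixture.model_scan(X, k_range=range(2, 5), seed=3, n_restarts=2)
    scan2 = mixture.model_scan(X, k_range=range(2, 5), seed=3, n_restarts=2)
    pd.testing.assert_frame_equal(scan1, scan2)
    assert len(scan1) == 6  # 3 k values x 2 modes
    assert not scan1.duplicated(["k", "covariance_mode"]).any()
    assert scan1["bic_optimal"].sum() >= 1
    tied = scan1[scan1["covariance_mode"] == "tied"]
    for _, row in tied.iterrows():
        expected = mixture.bic_from_loglik(row["log_likelihood"], 40, row["k"], 3, "tied")
        assert row["bic"] == pytest.approx(expected)
    assert scan1["silhouette_mean"].dropna().between(-1, 1).all()


# -- Mahalanobis boundary ---------------------------------------------------

def test_mahalanobis_identity_covariance_is_euclidean():
    model = TiedGMM(n_components=2)
    model.means_ = np.array([[0.0, 0, 0], [10.0, 10, 10]])
    model.covariance_ = np.eye(3)
    model.weights_ = np.array([0.5, 0.5])
    X = np.array([[3.0, 0, 0], [10.0, 10, 10]])
    report = mixture.mahalanobis_boundary(model, X, ["a", "b"], threshold=2.42)
    assert report["mahalanobis"].tolist() == pytest.approx([3.0, 0.0])
    assert report["is_driver"].tolist() == [True, False]


def test_mahalanobis_anisotropic_matches_explicit_inverse():
    cov3 = np.array([[0.5, 0.2, 0.0], [0.2, 0.3, 0.1], [0.0, 0.1, 0.4]])
    model = TiedGMM(n_components=2)
    model.means_ = np.array([[0.0, 0, 0], [50.0, 50, 50]])
    model.covariance_ = cov3
    model.weights_ = np.array([0.5, 0.5])
    rng = np.random.default_rng(11)
    X = rng.normal(0, 1, (6, 3))
    report = mixture.mahalanobis_boundary(model, X)
    inv = np.linalg.inv(cov3)
    for x, d in zip(X, report["mahalanobis"]):
        assert d == pytest.approx(np.sqrt(x @ inv @ x))


# -- ARI --------------------------------------------------------------------

def test_ari_identical_and_permuted():
    labels = np.array([0, 0, 1, 1, 2, 2])
    assert mixture.adjusted_rand_index(labels, labels) == 1.0
    assert mixture.adjusted_rand_index(labels, (labels + 1) % 3) == 1.0
    with pytest.raises(ValueError):
        mixture.adjusted_rand_index(labels, labels[:-1])


def test_ari_crossed_pairs_value():
    # {12|34} vs {13|24}: brute-force pair counting gives -0.5
    a = np.array([0, 0, 1, 1])
    b = np.array([0, 1, 0, 1])
    assert brute_force_ari(a, b) == pytest.approx(-0.5)
    assert mixture.adjusted_rand_index(a, b) == pytest.approx(-0.5)


def test_ari_matches_brute_force_on_all_small_partitions():
    items = list(range(5))
    partitions = [partition_to_labels(p, 5) for p in set_partitions(items)]
    for pa in partitions:
        for pb in partitions:
            assert mixture.adjusted_rand_index(pa, pb) == pytest.approx(
                brute_force_ari(pa, pb), abs=1e-12)


# -- stability and transitions ----------------------------------------------

def test_loo_ari_bookkeeping_and_separated_limit():
    rng = np.random.default_rng(12)
    X = np.vstack([rng.normal(0, 0.01, (8, 3)),
                   rng.normal(5, 0.01, (8, 3)),
                   rng.normal(10, 0.01, (8, 3))])
    report = mixture.loo_ari(X, k_a=3, k_b=3, seed=0, n_restarts=3)
    assert len(report.table) == 24
    assert np.allclose(report.table[["ari_a", "ari_b"]], 1.0)
    assert report.mean_difference == pytest.approx(0.0)


def test_bridge_point_destabilizes_higher_order_model():
    """A planted point midway between two tight modules props up the third
    component of a k=3 fit; its removal forces a real module to split, so it
    ranks among the strongest destabilizers of the k=3 solution."""
    rng = np.random.default_rng(3)
    a = rng.normal(0, 0.03, (10, 3))
    b = rng.normal(0, 0.03, (10, 3)) + [0.5, 0, 0]
    X = np.vstack([a, b, [[0.25, 0.0, 0.0]]])
    ids = [f"g{i}" for i in range(20)] + ["bridge"]
    report = mixture.loo_ari(X, ids, k_a=3, k_b=2, seed=1, n_restarts=10)
    worst = report.destabilizers(3)
    assert "bridge" in set(worst["gene_id"])
    assert report.table.set_index("gene_id").loc["bridge", "ari_diff"] < 0


def test_transition_table_identity_and_split():
    labels = np.array([0, 0, 1, 1, 2, 2])
    trans = mixture.transition_table(labels, labels)
    assert np.array_equal(trans.counts.to_numpy(), np.diag([2, 2, 2]))
    assert trans.grand_total == 6

    split = np.array([0, 0, 1, 1, 2, 3])  # cluster 2 split in two
    trans2 = mixture.transition_table(labels, split)
    row = trans2.counts.loc[2]
    assert (row > 0).sum() == 2
    assert trans2.counts.sum(axis=1).tolist() == [2, 2, 2]
    links = trans2.sankey["links"]
    assert sum(l["value"] for l in links) == 6


def test_match_labels_recovers_permutation():
    truth = np.array([0, 0, 1, 1, 2, 2])
    shuffled = np.array([2, 2, 0, 0, 1, 1])
    assert np.array_equal(mixture.match_labels(shuffled, truth), truth)
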