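"""Tied-covariance Gaussian-mixture module discovery and its diagnostics.

The retained, outlier-free ratio profiles are modelled as a k-component
Gaussian mixture in which every component shares one covariance matrix Σ
(equal "tied" ellipsoids).  With d = 3 ratio axes the model has

    p = (k - 1) + k·d + d(d + 1)/2

free parameters and is scored by BIC = -2·L + p·ln(n), L the total
log-likelihood.  The tied constraint deliberately trades per-component
flexibility for parsimony: on ~90 genes full covariances raise L but pay a
much larger BIC penalty.

Around the fit sit the diagnostics used to choose and audit a model:
a (k, covariance-mode) scan with silhouette/BIC/log-likelihood, a k-means
baseline, Mahalanobis distances flagging boundary drivers, leave-one-out
ARI stability comparing two model orders, and cluster-transition tables for
Sankey export.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.special import logsumexp
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans, kmeans_plusplus
from sklearn.metrics import adjusted_rand_score, silhouette_score
from sklearn.mixture import GaussianMixture
from sklearn.utils.validation import check_array, check_is_fitted

from ._utils import derive_seed


def n_params_tied(k: int, d: int) -> int:
    """Free parameters of a tied-covariance mixture: (k-1) + k·d + d(d+1)/2."""
    return (k - 1) + k * d + d * (d + 1) // 2


def n_params_full(k: int, d: int) -> int:
    """Free parameters of a full-covariance mixture: (k-1) + k·d + k·d(d+1)/2."""
    return (k - 1) + k * d + k * (d * (d + 1) // 2)


def bic_from_loglik(loglik: float, n: int, k: int, d: int = 3, mode: str = "tied") -> float:
    """BIC = -2·L + p·ln(n) under the stated parameter-count convention."""
    p = n_params_tied(k, d) if mode == "tied" else n_params_full(k, d)
    return -2.0 * loglik + p * np.log(n)


class TiedGMM(ClusterMixin, BaseEstimator):
    """Gaussian mixture with one covariance matrix shared by all components.

    EM with exact E/M steps: the E-step computes responsibilities under the
    current (π, μ, Σ); the M-step re-estimates π and μ and sets Σ to the
    responsibility-weighted pooled scatter about the component means,
    regularised by a small ridge on the diagonal.  Means are initialised by
    k-means++ seeding; the best of ``n_init`` restarts (by final
    log-likelihood) is kept, with per-restart seeds derived deterministically
    from ``random_state``.

    Parameters
    ----------
    n_components : int
        Number of mixture components (k >= 2).
    n_init : int
        Independent restarts.
    tol : float
        Convergence threshold on the relative log-likelihood change.
    max_iter : int
        EM iteration cap; non-convergence warns and keeps the best iterate.
    reg_covar : float
        Ridge added to the diagonal of Σ each M-step.
    random_state : int or None
        Master seed for the restart streams.

    Attributes
    ----------
    weights_, means_, covariance_ : mixture parameters (Σ is 3x3, shared)
    responsibilities_ : (n, k) posterior membership of the training data
    labels_ : argmax responsibilities
    log_likelihood_ : total log-likelihood of the training data
    loglik_trace_ : per-iteration log-likelihood of the winning restart
    n_params_, bic_ : parameter count and BIC of the fit
    best_seed_ : seed of the winning restart
    """

    def __init__(self, n_components: int = 6, n_init: int = 5, tol: float = 1e-6,
                 max_iter: int = 500, reg_covar: float = 1e-6, random_state=None):
        self.n_components = n_components
        self.n_init = n_init
        self.tol = tol
        self.max_iter = max_iter
        self.reg_covar = reg_covar
        self.random_state = random_state

    # -- internals ---------------------------------------------------------

    def _log_prob(self, X, weights, means, cov):
        """Component-wise log π_k + log N(x | μ_k, Σ)."""
        n, d = X.shape
        try:
            chol = cho_factor(cov, lower=True)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError("singular tied covariance after regularization") from exc
        logdet = 2.0 * np.sum(np.log(np.diag(chol[0])))
        lp = np.empty((n, len(means)))
        for k, mu in enumerate(means):
            diff = X - mu
            maha = np.sum(diff * cho_solve(chol, diff.T).T, axis=1)
            lp[:, k] = -0.5 * (d * np.log(2 * np.pi) + logdet + maha)
        return lp + np.log(weights)

    def _em_once(self, X, seed):
        n, d = X.shape
        k = self.n_components
        # hard k-means++ assignment seeds the responsibilities, so the first
        # M-step pools within-cluster scatter rather than the global one
        centers, _ = kmeans_plusplus(X, n_clusters=k, random_state=seed)
        nearest = np.argmin(((X[:, None, :] - centers[None, :, :]) ** 2).sum(-1), axis=1)
        resp = np.zeros((n, k))
        resp[np.arange(n), nearest] = 1.0

        trace = []
        prev = -np.inf
        converged = False
        weights = means = cov = None
        for _ in range(self.max_iter):
            # M-step
            nk = resp.sum(axis=0) + 10 * np.finfo(float).eps
            weights = nk / n
            means = (resp.T @ X) / nk[:, None]
            cov = np.zeros((d, d))
            for j in range(k):
                diff = X - means[j]
                cov += (resp[:, j][:, None] * diff).T @ diff
            cov = cov / n + self.reg_covar * np.eye(d)
            # E-step
            log_prob = self._log_prob(X, weights, means, cov)
            log_norm = logsumexp(log_prob, axis=1)
            resp = np.exp(log_prob - log_norm[:, None])
            ll = float(log_norm.sum())
            trace.append(ll)
            if np.isfinite(prev) and abs(ll - prev) <= self.tol * max(1.0, abs(prev)):
                converged = True
                break
            prev = ll
        return {
            "weights": weights, "means": means, "cov": cov, "resp": resp,
            "loglik": trace[-1], "trace": np.asarray(trace), "converged": converged,
            "n_iter": len(trace), "seed": seed,
        }

    # -- sklearn API -------------------------------------------------------

    def fit(self, X, y=None):
        X = check_array(X, dtype=float)
        n, d = X.shape
        if self.n_components < 2:
            raise ValueError("n_components must be >= 2")
        if n <= self.n_components:
            raise ValueError("need more samples than components")
        master = 0 if self.random_state is None else int(self.random_state)
        best = None
        for i in range(max(1, self.n_init)):
            run = self._em_once(X, derive_seed(master, i))
            if best is None or run["loglik"] > best["loglik"]:
                best = run
        if not best["converged"]:
            warnings.warn(
                f"EM did not converge within {self.max_iter} iterations; "
                "returning the best iterate"
            )
        self.weights_ = best["weights"]
        self.means_ = best["means"]
        self.covariance_ = best["cov"]
        self.responsibilities_ = best["resp"]
        self.labels_ = best["resp"].argmax(axis=1)
        self.log_likelihood_ = best["loglik"]
        self.loglik_trace_ = best["trace"]
        self.converged_ = best["converged"]
        self.n_iter_ = best["n_iter"]
        self.best_seed_ = best["seed"]
        self.n_features_in_ = d
        self.n_params_ = n_params_tied(self.n_components, d)
        self.bic_ = bic_from_loglik(self.log_likelihood_, n, self.n_components, d, "tied")
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "means_")
        X = check_array(X, dtype=float)
        log_prob = self._log_prob(X, self.weights_, self.means_, self.covariance_)
        return np.exp(log_prob - logsumexp(log_prob, axis=1)[:, None])

    def predict(self, X):
        return self.predict_proba(X).argmax(axis=1)

    def score_samples(self, X):
        check_is_fitted(self, "means_")
        X = check_array(X, dtype=float)
        return logsumexp(self._log_prob(X, self.weights_, self.means_, self.covariance_), axis=1)

    def score(self, X, y=None):
        return float(self.score_samples(X).mean())


def fit_gmm_tied(profiles, k: int, seed: int = 0, n_restarts: int = 5,
                 tol: float = 1e-6, max_iter: int = 500) -> TiedGMM:
    """Fit a tied-covariance mixture to ratio profiles; returns the estimator."""
    X = _matrix(profiles)
    return TiedGMM(n_components=k, n_init=n_restarts, tol=tol,
                   max_iter=max_iter, random_state=seed).fit(X)


def fit_kmeans(profiles, k: int, seed: int = 0, n_restarts: int = 10) -> np.ndarray:
    """k-means baseline (Lloyd iterations, k-means++ seeding, best of restarts)."""
    if k < 2:
        raise ValueError("k must be >= 2")
    X = _matrix(profiles)
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed).fit(X)
    return km.labels_


def silhouette_mean(profiles, labels) -> float:
    """Mean Euclidean silhouette over genes (singleton clusters score 0)."""
    X = _matrix(profiles)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette undefined for a single cluster")
    return float(silhouette_score(X, labels))


def _matrix(profiles) -> np.ndarray:
    if isinstance(profiles, pd.DataFrame):
        cols = [c for c in ("r40", "r80", "r300") if c in profiles.columns]
        if cols:
            return profiles[cols].to_numpy(dtype=float)
        return profiles.to_numpy(dtype=float)
    return np.asarray(profiles, dtype=float)


def model_scan(profiles, k_range=range(2, 10), modes=("tied", "full"),
               seed: int = 0, n_restarts: int = 5) -> pd.DataFrame:
    """Scan component counts and covariance modes; one row per (k, mode).

    Tied fits use :class:`TiedGMM`; full-covariance fits delegate to
    scikit-learn's GaussianMixture (same BIC convention).  The returned table
    flags the BIC-optimal and silhouette-optimal rows.
    """
    X = _matrix(profiles)
    n = len(X)
    rows = []
    for k in k_range:
        for mode in modes:
            run_seed = derive_seed(seed, k, 0 if mode == "tied" else 1)
            if mode == "tied":
                model = TiedGMM(n_components=k, n_init=n_restarts, random_state=run_seed).fit(X)
                ll, bic, labels = model.log_likelihood_, model.bic_, model.labels_
            elif mode == "full":
                gm = GaussianMixture(n_components=k, covariance_type="full",
                                     n_init=n_restarts, random_state=run_seed).fit(X)
                ll = float(gm.score(X) * n)
                bic = float(gm.bic(X))
                labels = gm.predict(X)
            else:
                raise ValueError(f"unknown covariance mode {mode!r}")
            try:
                sil = silhouette_mean(X, labels)
            except ValueError:
                sil = np.nan
            rows.append({
                "k": k, "covariance_mode": mode, "silhouette_mean": sil,
                "bic": bic, "log_likelihood": ll,
                "n_restarts": n_restarts, "best_seed": run_seed,
            })
    scan = pd.DataFrame(rows)
    scan["bic_optimal"] = scan["bic"] == scan["bic"].min()
    scan["silhouette_optimal"] = scan["silhouette_mean"] == scan["silhouette_mean"].max()
    return scan


# ---------------------------------------------------------------------------
# diagnostics


def mahalanobis_boundary(model: TiedGMM, profiles, gene_ids=None,
                         threshold: float = 2.42) -> pd.DataFrame:
    """Mahalanobis distance of each gene from its assigned component mean.

    d_M = sqrt((x - μ)ᵀ Σ⁻¹ (x - μ)) under the shared covariance; genes with
    d_M above ``threshold`` are flagged as boundary drivers.
    """
    check_is_fitted(model, "means_")
    X = _matrix(profiles)
    labels = model.predict(X)
    chol = cho_factor(model.covariance_, lower=True)
    diff = X - model.means_[labels]
    d = np.sqrt(np.sum(diff * cho_solve(chol, diff.T).T, axis=1))
    if gene_ids is None:
        gene_ids = np.arange(len(X))
    return pd.DataFrame({
        "gene_id": np.asarray(gene_ids),
        "cluster": labels,
        "mahalanobis": d,
        "is_driver": d > threshold,
    })


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Chance-corrected partition agreement (pair-counting ARI)."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("label vectors must have equal length")
    return float(adjusted_rand_score(a, b))


@dataclass
class StabilityReport:
    """Leave-one-out ARI stability of two competing model orders.

    ``table`` holds one row per gene with the ARI of each model order after
    that gene's removal and their difference ari_a - ari_b; a negative
    ``mean_difference`` means order b reorganises less when genes drop out,
    i.e. is the more stable model.
    """

    k_a: int
    k_b: int
    table: pd.DataFrame
    mean_difference: float

    def stabilizers(self, n: int = 5) -> pd.DataFrame:
        """Most positive ari_diff: the k_a partition survives their removal
        while the k_b partition reorganises."""
        return self.table.nlargest(n, "ari_diff")

    def destabilizers(self, n: int = 5) -> pd.DataFrame:
        """Most negative ari_diff: their removal reorganises the k_a
        partition while the k_b one stays put."""
        return self.table.nsmallest(n, "ari_diff")


def loo_ari(profiles, gene_ids=None, k_a: int = 4, k_b: int = 6,
            seed: int = 0, n_restarts: int = 3) -> StabilityReport:
    """Leave-one-out clustering stability comparing two model orders.

    For every gene and each k the mixture is refit without that gene (seed
    derived from the master seed per (k, gene)), and the ARI between the
    baseline labels and the reduced fit is computed on the shared genes.
    The per-gene difference is ARI(k_a) - ARI(k_b); under that sign a
    negative mean says the k_b model is the more stable one.
    """
    X = _matrix(profiles)
    n = len(X)
    if n <= max(k_a, k_b) + 1:
        raise ValueError("too few genes for leave-one-out analysis")
    if gene_ids is None:
        gene_ids = np.arange(n)
    gene_ids = np.asarray(gene_ids)

    baselines = {}
    for k in (k_a, k_b):
        baselines[k] = TiedGMM(n_components=k, n_init=n_restarts,
                               random_state=derive_seed(seed, k)).fit(X).labels_

    rows = []
    for i in range(n):
        mask = np.arange(n) != i
        row = {"gene_id": gene_ids[i]}
        for k, col in ((k_a, "ari_a"), (k_b, "ari_b")):
            try:
                loo_labels = TiedGMM(
                    n_components=k, n_init=n_restarts,
                    random_state=derive_seed(seed, k, i + 1),
                ).fit(X[mask]).labels_
                row[col] = adjusted_rand_index(baselines[k][mask], loo_labels)
            except (ValueError, np.linalg.LinAlgError) as exc:
                warnings.warn(f"LOO refit failed for gene {gene_ids[i]} (k={k}): {exc}")
                row[col] = np.nan
        rows.append(row)
    table = pd.DataFrame(rows)
    table["ari_diff"] = table["ari_a"] - table["ari_b"]
    return StabilityReport(
        k_a=k_a, k_b=k_b, table=table,
        mean_difference=float(table["ari_diff"].mean(skipna=True)),
    )


@dataclass
class TransitionTable:
    """Cross-tabulation of two clusterings with marginals and Sankey export."""

    counts: pd.DataFrame
    sankey: dict

    @property
    def grand_total(self) -> int:
        return int(self.counts.to_numpy().sum())


def transition_table(labels_a, labels_b, name_a: str = "A", name_b: str = "B") -> TransitionTable:
    """Contingency table of cluster memberships between two models.

    Row/column marginals equal the cluster sizes; the Sankey form lists one
    node per cluster of each model and one link per nonzero cell.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("label vectors must have equal length")
    counts = pd.crosstab(pd.Series(a, name=name_a), pd.Series(b, name=name_b))
    nodes = []
    node_index = {}
    for cl in counts.index:
        node_index[(name_a, cl)] = len(nodes)
        nodes.append({"id": len(nodes), "label": f"{name_a}-{cl}",
                      "count": int(counts.loc[cl].sum())})
    for cl in counts.columns:
        node_index[(name_b, cl)] = len(nodes)
        nodes.append({"id": len(nodes), "label": f"{name_b}-{cl}",
                      "count": int(counts[cl].sum())})
    links = [
        {"source": node_index[(name_a, ra)], "target": node_index[(name_b, cb)],
         "value": int(counts.loc[ra, cb])}
        for ra in counts.index for cb in counts.columns
        if counts.loc[ra, cb] > 0
    ]
    return TransitionTable(counts=counts, sankey={"nodes": nodes, "links": links})


def match_labels(labels, reference, k_max: int = 9) -> np.ndarray:
    """Relabel ``labels`` to maximise overlap with ``reference``.

    Exhaustive search over component permutations (intended for k <= 9);
    used when comparing a fit against planted ground truth or another fit.
    """
    labels = np.asarray(labels)
    reference = np.asarray(reference)
    ids = np.unique(labels)
    ref_ids = np.unique(reference)
    if len(ids) > k_max:
        raise ValueError(f"exhaustive matching limited to k <= {k_max}")
    contingency = np.array([[np.sum((labels == i) & (reference == j)) for j in ref_ids]
                            for i in ids])
    best_perm, best_score = None, -1
    for perm in itertools.permutations(range(len(ref_ids)), len(ids)):
        score = sum(contingency[i, perm[i]] for i in range(len(ids)))
        if score > best_score:
            best_perm, best_score = perm, score
    mapping = {ids[i]: ref_ids[best_perm[i]] for i in range(len(ids))}
    return np.array([mapping[x] for x in labels])
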