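"""Model-based clustering of spine feature matrices.

Spines are assumed drawn from a finite mixture of multivariate Gaussians
f(x) = Σ_c π_c N(x | μ_c, Σ_c); the mixture is fitted by EM and the
number of components chosen by the Bayesian information criterion,
BIC = 2·logL − n_params·log(n) (higher is better). Clustering is soft:
each spine gets a posterior probability over components.

Interpretation tools: per-cluster log-determinant variance summaries,
Bhattacharyya distances between cluster Gaussians with a classical MDS
embedding, Monte-Carlo pairwise overlap (misclassification) probabilities,
and Pearson χ² tests of cluster-vs-metadata contingency tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp
from sklearn.base import BaseEstimator
from sklearn.mixture import GaussianMixture
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "MixtureModel",
    "MembershipMatrix",
    "SpineGaussianMixture",
    "fit_mixture",
    "memberships",
    "membership_threshold_table",
    "cluster_variance_summary",
    "bhattacharyya_distance",
    "bhattacharyya_matrix",
    "embed_mds",
    "overlap_probability",
    "overlap_matrix",
    "crosstab_chi2",
]


@dataclass
class MixtureModel:
    """Parameters of a fitted (or specified) Gaussian mixture.

    When the mixture was fitted on z-scored columns, ``standardize_mean``
    and ``standardize_scale`` record the per-column transform so samples
    can be mapped back to feature units.
    """

    weights: np.ndarray          # (C,) sums to 1
    means: np.ndarray            # (C, d)
    covariances: np.ndarray      # (C, d, d) symmetric PD
    log_likelihood: float = float("nan")
    n_params: int = 0
    feature_names: list = field(default_factory=list)
    standardize_mean: np.ndarray | None = None
    standardize_scale: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.means = np.atleast_2d(np.asarray(self.means, dtype=float))
        self.covariances = np.asarray(self.covariances, dtype=float)
        if self.covariances.ndim == 2:
            self.covariances = self.covariances[None, :, :]
        if not np.isclose(self.weights.sum(), 1.0):
            raise ValueError("mixture weights must sum to 1")
        if np.any(self.weights <= 0):
            raise ValueError("mixture weights must be positive")
        for c, cov in enumerate(self.covariances):
            if not np.allclose(cov, cov.T, atol=1e-8):
                raise ValueError(f"covariance {c} is not symmetric")

    @property
    def n_components(self) -> int:
        return len(self.weights)

    @property
    def n_features(self) -> int:
        return self.means.shape[1]

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Map raw feature rows into the model's (possibly z-scored) space."""
        X = np.asarray(X, dtype=float)
        if self.standardize_mean is None:
            return X
        return (X - self.standardize_mean) / self.standardize_scale

    def inverse_transform(self, Z: np.ndarray) -> np.ndarray:
        if self.standardize_mean is None:
            return np.asarray(Z, dtype=float)
        return np.asarray(Z, dtype=float) * self.standardize_scale + self.standardize_mean

    def component_log_density(self, X: np.ndarray) -> np.ndarray:
        """log N(x | μ_c, Σ_c) for every row and component, shape (n, C)."""
        Z = self.transform(X)
        out = np.empty((len(Z), self.n_components))
        for c in range(self.n_components):
            out[:, c] = stats.multivariate_normal.logpdf(
                Z, mean=self.means[c], cov=self.covariances[c],
                allow_singular=False,
            )
        return out

    # -- serialization ------------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "weights": self.weights.tolist(),
            "means": self.means.tolist(),
            "covariances": self.covariances.tolist(),
            "log_likelihood": self.log_likelihood,
            "n_params": self.n_params,
            "feature_names": list(self.feature_names),
            "standardize_mean": None if self.standardize_mean is None
            else self.standardize_mean.tolist(),
            "standardize_scale": None if self.standardize_scale is None
            else self.standardize_scale.tolist(),
        }
        text = json.dumps(payload)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "MixtureModel":
        if isinstance(source, Path) or (isinstance(source, str) and "{" not in source):
            source = Path(source).read_text()
        d = json.loads(source)
        return cls(
            weights=np.array(d["weights"]),
            means=np.array(d["means"]),
            covariances=np.array(d["covariances"]),
            log_likelihood=d.get("log_likelihood", float("nan")),
            n_params=d.get("n_params", 0),
            feature_names=d.get("feature_names", []),
            standardize_mean=None if d.get("standardize_mean") is None
            else np.array(d["standardize_mean"]),
            standardize_scale=None if d.get("standardize_scale") is None
            else np.array(d["standardize_scale"]),
        )


@dataclass
class MembershipMatrix:
    """Posterior cluster probabilities for a set of spines."""

    probabilities: np.ndarray  # (n, C), rows sum to 1

    @property
    def p_star(self) -> np.ndarray:
        """Maximum membership probability per spine."""
        return self.probabilities.max(axis=1)

    @property
    def labels(self) -> np.ndarray:
        """Hard assignment (argmax), clusters numbered from 0."""
        return self.probabilities.argmax(axis=1)


class SpineGaussianMixture(BaseEstimator):
    """Gaussian-mixture clustering with BIC model selection.

    scikit-learn style estimator: ``fit`` runs EM for every component
    count in ``[c_min, c_max]`` (``n_init`` seeded starts each, full
    covariances, ridge ``reg`` on the diagonals) and keeps the model
    with the highest BIC = 2·logL − k·log(n).

    Parameters
    ----------
    c_min, c_max : inclusive range of component counts to try.
    n_init : EM restarts per component count (k-means++ initialisation).
    reg : diagonal regularisation added to every covariance.
    covariance_type : "full" (default), "diag", "tied" or "spherical".
        Full covariances are the richest description but their BIC
        penalty (d(d+3)/2 parameters per component in 54 dimensions)
        needs several thousand spines per cluster to justify a split;
        "diag" is the practical choice for smaller studies.
    standardize : z-score columns before fitting (recorded in the model
        so samples map back to feature units).
    random_state : seed for initialisation.

    Attributes
    ----------
    model_ : MixtureModel of the selected fit.
    n_components_ : selected number of clusters.
    bic_curve_ : pandas Series, BIC per candidate component count.
    """

    def __init__(self, c_min: int = 2, c_max: int = 10, n_init: int = 10,
                 reg: float = 1e-6, tol: float = 1e-6, max_iter: int = 500,
                 covariance_type: str = "full", standardize: bool = True,
                 random_state: int | None = 0):
        self.c_min = c_min
        self.c_max = c_max
        self.n_init = n_init
        self.reg = reg
        self.tol = tol
        self.max_iter = max_iter
        self.covariance_type = covariance_type
        self.standardize = standardize
        self.random_state = random_state

    def fit(self, X: np.ndarray, y=None, feature_names: list | None = None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        if np.any(~np.isfinite(X)):
            raise ValueError("X contains missing or non-finite values")
        n = len(X)
        if self.c_min < 1 or self.c_max < self.c_min:
            raise ValueError("need 1 <= c_min <= c_max")
        if n <= 2 * self.c_max:
            raise ValueError(
                f"n = {n} too small for c_max = {self.c_max} (need n > 2·c_max)"
            )
        if self.standardize:
            mu0 = X.mean(axis=0)
            sd0 = X.std(axis=0, ddof=0)
            sd0 = np.where(sd0 < 1e-12, 1.0, sd0)
            Z = (X - mu0) / sd0
        else:
            mu0 = sd0 = None
            Z = X

        bics: dict[int, float] = {}
        best = None
        for C in range(self.c_min, self.c_max + 1):
            gmm = GaussianMixture(
                n_components=C, covariance_type=self.covariance_type,
                n_init=self.n_init, init_params="k-means++",
                reg_covar=self.reg, tol=self.tol,
                max_iter=self.max_iter, random_state=self.random_state,
            )
            try:
                gmm.fit(Z)
            except ValueError as exc:
                raise ValueError(
                    f"EM failed at C={C} (singular covariance?); "
                    f"increase reg (currently {self.reg}): {exc}"
                ) from exc
            bic = -float(gmm.bic(Z))  # sklearn's BIC is lower-is-better
            bics[C] = bic
            if best is None or bic > best[0]:
                best = (bic, C, gmm)
        _, C_sel, gmm = best
        self.bic_curve_ = pd.Series(bics, name="bic").sort_index()
        self.n_components_ = C_sel
        covs = gmm.covariances_
        if self.covariance_type == "diag":
            covs = np.array([np.diag(c) for c in covs])
        elif self.covariance_type == "tied":
            covs = np.tile(covs, (C_sel, 1, 1))
        elif self.covariance_type == "spherical":
            covs = np.array([v * np.eye(Z.shape[1]) for v in covs])
        self.model_ = MixtureModel(
            weights=gmm.weights_, means=gmm.means_, covariances=covs,
            log_likelihood=float(gmm.score(Z) * n),
            n_params=int(gmm._n_parameters()),
            feature_names=list(feature_names) if feature_names is not None else [],
            standardize_mean=mu0, standardize_scale=sd0,
        )
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "model_")
        return memberships(self.model_, X).probabilities

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)

    def sample(self, n: int, cluster: int | None = None,
               seed: int | None = None) -> np.ndarray:
        """Draw feature-space rows from the fitted mixture (or one component)."""
        check_is_fitted(self, "model_")
        m = self.model_
        rng = np.random.default_rng(seed)
        if cluster is None:
            counts = rng.multinomial(n, m.weights)
        else:
            counts = np.zeros(m.n_components, dtype=int)
            counts[cluster] = n
        rows = [rng.multivariate_normal(m.means[c], m.covariances[c], size=k)
                for c, k in enumerate(counts) if k > 0]
        Z = np.vstack(rows) if rows else np.empty((0, m.n_features))
        return m.inverse_transform(Z)


def fit_mixture(X: np.ndarray, c_range=range(2, 11), seed: int = 0,
                n_init: int = 10, reg: float = 1e-6,
                covariance_type: str = "full", standardize: bool = True,
                feature_names: list | None = None
                ) -> tuple[MixtureModel, pd.Series]:
    """Fit mixtures over ``c_range`` and return (best model by BIC, BIC curve)."""
    cs = sorted(c_range)
    est = SpineGaussianMixture(
        c_min=cs[0], c_max=cs[-1], n_init=n_init, reg=reg,
        covariance_type=covariance_type, standardize=standardize,
        random_state=seed,
    ).fit(X, feature_names=feature_names)
    return est.model_, est.bic_curve_


def memberships(model: MixtureModel, X: np.ndarray) -> MembershipMatrix:
    """Posterior p_ic = π_c N(x_i|μ_c,Σ_c) / Σ_k π_k N(x_i|μ_k,Σ_k)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"X has {X.shape[1]} columns, model expects {model.n_features}"
        )
    logp = model.component_log_density(X) + np.log(model.weights)[None, :]
    logp -= logsumexp(logp, axis=1, keepdims=True)
    return MembershipMatrix(probabilities=np.exp(logp))


def membership_threshold_table(mm: MembershipMatrix,
                               thresholds=(0.99, 0.9, 0.8, 0.7, 0.6, 0.5)
                               ) -> pd.DataFrame:
    """Count spines per cluster whose top membership exceeds each threshold."""
    labels = mm.labels
    p = mm.p_star
    C = mm.probabilities.shape[1]
    rows = {}
    for t in thresholds:
        rows[t] = [int(np.sum((labels == c) & (p > t))) for c in range(C)]
    df = pd.DataFrame.from_dict(
        rows, orient="index", columns=[f"cluster_{c + 1}" for c in range(C)]
    )
    df.index.name = "p_star_threshold"
    return df


def cluster_variance_summary(model: MixtureModel) -> np.ndarray:
    """|log10 det Σ_c| per cluster, via a stable factorisation."""
    out = []
    for c, cov in enumerate(model.covariances):
        sign, logdet = np.linalg.slogdet(cov)
        if sign <= 0:
            raise ValueError(f"covariance {c} is not positive definite")
        out.append(abs(logdet / np.log(10.0)))
    return np.array(out)


def bhattacharyya_distance(mean_a, cov_a, mean_b, cov_b) -> float:
    """Bhattacharyya distance between two multivariate Gaussians.

    D_B = (1/8)(μa−μb)ᵀ Σ̄⁻¹ (μa−μb) + (1/2) ln(det Σ̄ / √(det Σa det Σb)),
    Σ̄ = (Σa+Σb)/2. Symmetric, zero iff the Gaussians coincide.
    """
    mean_a = np.atleast_1d(np.asarray(mean_a, dtype=float))
    mean_b = np.atleast_1d(np.asarray(mean_b, dtype=float))
    cov_a = np.atleast_2d(np.asarray(cov_a, dtype=float))
    cov_b = np.atleast_2d(np.asarray(cov_b, dtype=float))
    if mean_a.shape != mean_b.shape or cov_a.shape != cov_b.shape:
        raise ValueError("dimension mismatch between the two Gaussians")
    pooled = 0.5 * (cov_a + cov_b)
    diff = mean_a - mean_b
    try:
        sol = np.linalg.solve(pooled, diff)
    except np.linalg.LinAlgError as exc:
        raise ValueError("pooled covariance is singular") from exc
    term1 = 0.125 * float(diff @ sol)
    s_p, ld_p = np.linalg.slogdet(pooled)
    s_a, ld_a = np.linalg.slogdet(cov_a)
    s_b, ld_b = np.linalg.slogdet(cov_b)
    if min(s_p, s_a, s_b) <= 0:
        raise ValueError("covariances must be positive definite")
    term2 = 0.5 * (ld_p - 0.5 * (ld_a + ld_b))
    return term1 + term2


def bhattacharyya_matrix(model: MixtureModel) -> np.ndarray:
    """Symmetric C×C matrix of pairwise Bhattacharyya distances."""
    C = model.n_components
    D = np.zeros((C, C))
    for i in range(C):
        for j in range(i + 1, C):
            D[i, j] = D[j, i] = bhattacharyya_distance(
                model.means[i], model.covariances[i],
                model.means[j], model.covariances[j],
            )
    return D


def embed_mds(D: np.ndarray, dim: int = 2) -> np.ndarray:
    """Classical (Torgerson) multidimensional scaling of a distance matrix.

    Double-centres −½D², takes the top-``dim`` eigenpairs; for a
    Euclidean-realizable D the embedding reproduces all pairwise
    distances. Negative eigenvalues (non-Euclidean D) are clamped to 0.
    """
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("D must be square")
    if not np.allclose(D, D.T, atol=1e-8) or not np.allclose(np.diag(D), 0, atol=1e-8):
        raise ValueError("D must be symmetric with zero diagonal")
    n = len(D)
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    w, V = np.linalg.eigh(B)
    order = np.argsort(w)[::-1][:dim]
    w_top = np.clip(w[order], 0.0, None)
    return V[:, order] * np.sqrt(w_top)[None, :]


def overlap_probability(model: MixtureModel, i: int, j: int,
                        n_samples: int = 100_000, seed: int = 0
                        ) -> tuple[float, float]:
    """Monte-Carlo ω_{j|i}: probability that a draw from component i is
    weighted-density-dominated by component j.

    ω_{j|i} = P[π_i N(x|μ_i,Σ_i) < π_j N(x|μ_j,Σ_j) | x ~ N(μ_i,Σ_i)].
    Returns (estimate, standard error ≤ 0.5/√n).
    """
    if i == j:
        raise ValueError("overlap is defined for distinct components")
    C = model.n_components
    if not (0 <= i < C and 0 <= j < C):
        raise ValueError("component index out of range")
    if n_samples < 100:
        raise ValueError("n_samples must be at least 100")
    rng = np.random.default_rng(seed)
    x = rng.multivariate_normal(model.means[i], model.covariances[i], size=n_samples)
    log_i = stats.multivariate_normal.logpdf(x, model.means[i], model.covariances[i])
    log_j = stats.multivariate_normal.logpdf(x, model.means[j], model.covariances[j])
    hits = (np.log(model.weights[i]) + log_i) < (np.log(model.weights[j]) + log_j)
    omega = float(np.mean(hits))
    se = float(np.sqrt(max(omega * (1 - omega), 1e-12) / n_samples))
    return omega, se


def overlap_matrix(model: MixtureModel, n_samples: int = 100_000,
                   seed: int = 0) -> np.ndarray:
    """ω_{j|i} for every ordered pair; entry [i, j] conditions on i."""
    C = model.n_components
    W = np.zeros((C, C))
    for i in range(C):
        for j in range(C):
            if i != j:
                W[i, j], _ = overlap_probability(
                    model, i, j, n_samples=n_samples, seed=seed + 1000 * i + j
                )
    return W


def crosstab_chi2(labels, groups, per_cluster: bool = False):
    """Pearson χ² independence test of cluster labels vs a categorical group.

    Returns a dict with the contingency table, statistic, dof and p-value;
    with ``per_cluster=True`` returns one such dict per cluster, each
    testing that cluster against the rest (2×g table).
    """
    labels = np.asarray(labels)
    groups = np.asarray(groups)
    if labels.shape != groups.shape:
        raise ValueError("labels and groups must have the same length")
    table = pd.crosstab(pd.Series(labels, name="cluster"),
                        pd.Series(groups, name="group"))
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("need at least 2 clusters and 2 groups")

    def run(t: pd.DataFrame) -> dict:
        chi2, p, dof, expected = stats.chi2_contingency(t.values, correction=False)
        result = {"table": t, "statistic": float(chi2), "df": int(dof),
                  "p_value": float(p)}
        if np.any(expected < 5):
            result["warning"] = "expected count below 5 in some cell"
        return result

    if not per_cluster:
        return run(table)
    out = {}
    for c in table.index:
        collapsed = pd.DataFrame(
            [table.loc[c], table.drop(index=c).sum(axis=0)],
            index=[f"cluster_{c}", "rest"],
        )
        out[c] = run(collapsed)
    return out
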