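"""Latent Dirichlet allocation: batch variational Bayes on count matrices.

The model: each sample (document) d draws topic proportions
theta_d ~ Dirichlet(alpha); each of its tokens draws a topic
z ~ Categorical(theta_d) and then a feature w ~ Categorical(phi_z), where
the K topic-feature rows phi_k carry a Dirichlet(eta) prior.  Inference is
standard batch variational Bayes with fixed-point updates: a per-document
E-step refining variational Dirichlet parameters gamma, and an M-step
refreshing the variational topic-feature Dirichlet lambda.  The evidence
lower bound (ELBO) is recorded every iteration and is non-decreasing up to
the tolerance of the finite inner loop.

Because LDA topics are exchangeable, fitted topics are canonicalized by
descending total corpus usage (expected token mass) before return so topic
identities are stable across runs with the same seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.special import gammaln, logsumexp, psi

from .config import AnalysisConfig, CountMatrix

_EPS = 1e-100


@dataclass
class TopicModel:
    """A fitted topic model: topic-feature probabilities plus fit metadata.

    ``phi`` is K x V; every row sums to 1 and every entry is strictly
    positive (guaranteed by eta > 0).
    """

    phi: np.ndarray
    alpha: float
    eta: float
    feature_ids: list
    fit_info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=float)
        if self.phi.ndim != 2 or self.phi.shape[1] != len(self.feature_ids):
            raise ValueError("phi must be K x len(feature_ids)")
        if not np.allclose(self.phi.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("phi rows must sum to 1")
        if (self.phi <= 0).any():
            raise ValueError("phi entries must be strictly positive")

    @property
    def n_topics(self) -> int:
        return self.phi.shape[0]

    # -- serialization -----------------------------------------------------

    def to_json(self) -> str:
        """Serialize to a single JSON document; round-trips bit-exactly."""
        return json.dumps(
            {
                "n_topics": self.n_topics,
                "alpha": self.alpha,
                "eta": self.eta,
                "feature_ids": list(self.feature_ids),
                "phi": self.phi.tolist(),
                "fit_info": self.fit_info,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "TopicModel":
        d = json.loads(text)
        return cls(
            phi=np.array(d["phi"], dtype=float),
            alpha=d["alpha"],
            eta=d["eta"],
            feature_ids=list(d["feature_ids"]),
            fit_info=d.get("fit_info", {}),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "TopicModel":
        with open(path) as fh:
            return cls.from_json(fh.read())


@dataclass
class MembershipMatrix:
    """Per-sample topic proportions theta; each row is a simplex point."""

    sample_ids: list
    theta: np.ndarray

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        if self.theta.shape[0] != len(self.sample_ids):
            raise ValueError("theta rows must match sample_ids")
        if (self.theta < 0).any() or not np.allclose(
            self.theta.sum(axis=1), 1.0, atol=1e-8
        ):
            raise ValueError("theta rows must be non-negative and sum to 1")

    @property
    def n_topics(self) -> int:
        return self.theta.shape[1]


# ---------------------------------------------------------------------------
# variational inference internals


def _dirichlet_elog(arr: np.ndarray) -> np.ndarray:
    """E[log x] under a Dirichlet with parameter rows ``arr``."""
    return psi(arr) - psi(arr.sum(axis=1))[:, None]


def _e_step(
    rows: np.ndarray,
    cols: np.ndarray,
    data: np.ndarray,
    shape: tuple,
    nd: np.ndarray,
    exp_elog_beta: np.ndarray,
    alpha: float,
    inner_max: int = 100,
    inner_tol: float = 1e-3,
):
    """Per-document fixed-point updates of gamma with topics held fixed.

    Counts are passed in COO form; the update touches only nonzero entries.
    Returns (gamma, sufficient statistics K x V).
    """
    D = shape[0]
    K = exp_elog_beta.shape[0]
    gamma = np.full((D, K), alpha) + nd[:, None] / K
    exp_etheta = np.exp(_dirichlet_elog(gamma))
    beta_cols = exp_elog_beta[:, cols].T  # nnz x K
    R = None
    for _ in range(inner_max):
        phinorm = (exp_etheta[rows] * beta_cols).sum(axis=1) + _EPS
        R = sparse.csr_matrix((data / phinorm, (rows, cols)), shape=shape)
        gamma_new = alpha + exp_etheta * (R @ exp_elog_beta.T)
        # convergence measured on the normalized (membership) scale
        delta = np.abs(
            gamma_new / gamma_new.sum(axis=1)[:, None]
            - gamma / gamma.sum(axis=1)[:, None]
        ).mean()
        gamma = gamma_new
        exp_etheta = np.exp(_dirichlet_elog(gamma))
        if delta < inner_tol:
            break
    phinorm = (exp_etheta[rows] * beta_cols).sum(axis=1) + _EPS
    R = sparse.csr_matrix((data / phinorm, (rows, cols)), shape=shape)
    sstats = (R.T @ exp_etheta).T * exp_elog_beta
    return gamma, sstats


def _approx_bound(
    rows, cols, data, gamma, lam, alpha, eta
) -> float:
    """Evidence lower bound of the variational posterior (nats)."""
    elog_theta = _dirichlet_elog(gamma)
    elog_beta = _dirichlet_elog(lam)
    temp = elog_theta[rows] + elog_beta[:, cols].T
    score = float((data * logsumexp(temp, axis=1)).sum())
    D, K = gamma.shape
    V = lam.shape[1]
    score += float(((alpha - gamma) * elog_theta).sum())
    score += float(gammaln(gamma).sum() - gammaln(gamma.sum(axis=1)).sum())
    score += D * float(gammaln(K * alpha) - K * gammaln(alpha))
    score += float(((eta - lam) * elog_beta).sum())
    score += float(gammaln(lam).sum() - gammaln(lam.sum(axis=1)).sum())
    score += K * float(gammaln(V * eta) - V * gammaln(eta))
    return score


def _fit_once(rows, cols, data, shape, nd, K, alpha, eta, seed,
              max_iter, tol, patience):
    """One variational fit from one random initialization."""
    V = shape[1]
    rng = np.random.default_rng(seed)
    lam = rng.gamma(100.0, 0.01, (K, V))
    bounds: list = []
    converged = False
    n_iter = 0
    n_small = 0
    gamma = None
    for it in range(max_iter):
        n_iter = it + 1
        exp_elog_beta = np.exp(_dirichlet_elog(lam))
        gamma, sstats = _e_step(rows, cols, data, shape, nd, exp_elog_beta, alpha)
        lam = eta + sstats
        bound = _approx_bound(rows, cols, data, gamma, lam, alpha, eta)
        bounds.append(bound)
        if it > 0 and abs(bounds[-1] - bounds[-2]) < tol * abs(bounds[-2]):
            n_small += 1
            if n_small >= patience:
                converged = True
                break
        else:
            n_small = 0
    return lam, gamma, bounds, converged, n_iter


def fit_lda(
    m: CountMatrix,
    cfg: AnalysisConfig,
    max_iter: int = 100,
    tol: float = 1e-6,
    patience: int = 3,
    n_init: int = 1,
) -> tuple[TopicModel, MembershipMatrix]:
    """Fit the topic model to a count matrix.

    Deterministic given ``cfg.seed``.  Stops when the relative ELBO change
    stays below ``tol`` for ``patience`` consecutive iterations (the bound
    can plateau early before topics separate, so a single small step is
    not treated as convergence) or after ``max_iter`` iterations.  With
    ``n_init > 1`` the fit is restarted from several seed-derived
    initializations and the run with the highest final evidence bound is
    kept — the usual guard against local optima of mixture models.
    Topics are re-ordered by descending total corpus usage before return,
    and the returned memberships are the transform of the training matrix
    under the final topics (so ``transform(model, m)`` reproduces them).
    """
    K = cfg.n_topics
    alpha, eta = cfg.alpha_, cfg.eta_
    X = m.to_csr().astype(float)
    D, V = X.shape
    total = X.sum()
    if total == 0:
        raise ValueError("count matrix is all zero")
    if K > D:
        warnings.warn(
            f"n_topics={K} exceeds the number of samples ({D}); proceeding anyway"
        )
    if n_init < 1:
        raise ValueError(f"n_init must be >= 1, got {n_init}")
    coo = X.tocoo()
    rows, cols, data = coo.row, coo.col, coo.data
    nd = np.asarray(X.sum(axis=1)).ravel()

    best = None
    restart_bounds = []
    for i in range(n_init):
        run = _fit_once(
            rows, cols, data, X.shape, nd, K, alpha, eta,
            cfg.seed + 100003 * i, max_iter, tol, patience,
        )
        restart_bounds.append(run[2][-1])
        if best is None or run[2][-1] > best[2][-1]:
            best = run
    lam, gamma, bounds, converged, n_iter = best

    phi = lam / lam.sum(axis=1)[:, None]
    # canonical topic order: descending expected token usage
    gamma_norm = gamma / gamma.sum(axis=1)[:, None]
    usage = (gamma_norm * nd[:, None]).sum(axis=0)
    order = np.argsort(-usage, kind="stable")
    phi = phi[order]

    model = TopicModel(
        phi=phi,
        alpha=alpha,
        eta=eta,
        feature_ids=list(m.feature_ids),
        fit_info={
            "n_iter": n_iter,
            "converged": converged,
            "bound_history": bounds,
            "final_bound": bounds[-1],
            "n_init": n_init,
            "restart_bounds": restart_bounds,
            "seed": cfg.seed,
            "config": cfg.to_dict(),
            "topic_order": [int(i) for i in order],
        },
    )
    memberships = transform(model, m)
    return model, memberships


def transform(model: TopicModel, m: CountMatrix) -> MembershipMatrix:
    """Posterior topic proportions of new samples under fixed topics.

    ``m``'s features must be a subset of the model's: missing features are
    treated as zero counts, unknown features are a schema error (silent
    misalignment of large positional vocabularies is the likeliest user
    bug).  An all-zero row gets the prior mean, uniform 1/K.
    """
    model_index = {f: i for i, f in enumerate(model.feature_ids)}
    unknown = [f for f in m.feature_ids if f not in model_index]
    if unknown:
        raise ValueError(
            f"{len(unknown)} features not in the model vocabulary "
            f"(e.g. {unknown[:3]}); refusing to transform"
        )
    X = m.to_csr().astype(float)
    if list(m.feature_ids) != list(model.feature_ids):
        proj = sparse.csr_matrix(
            (
                np.ones(len(m.feature_ids)),
                (np.arange(len(m.feature_ids)),
                 [model_index[f] for f in m.feature_ids]),
            ),
            shape=(len(m.feature_ids), len(model.feature_ids)),
        )
        X = (X @ proj).tocsr()
    coo = X.tocoo()
    nd = np.asarray(X.sum(axis=1)).ravel()
    exp_elog_beta = model.phi  # point-estimate topics: E-step with log(phi)
    gamma, _ = _e_step(
        coo.row, coo.col, coo.data, X.shape, nd, exp_elog_beta, model.alpha
    )
    theta = gamma / gamma.sum(axis=1)[:, None]
    return MembershipMatrix(sample_ids=list(m.sample_ids), theta=theta)
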