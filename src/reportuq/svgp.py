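"""Sparse variational Gaussian-process multiclass classifier.

The model places independent zero-mean GP priors with a shared ARD-RBF kernel
on one latent function per class, summarized at M inducing inputs.  Inference
maximizes the evidence lower bound

    ELBO = (n/|B|) * sum_{i in B} E_q[ log p(y_i | f_i) ] - KL(q(u) || p(u)),

with the expected log-likelihood estimated by Monte-Carlo over the marginal
latent Gaussians using the reparameterisation trick (softmax inverse link),
and trained stochastically with RMSProp.  The variational distribution is a
full-covariance Gaussian per latent function in *whitened* coordinates
(u = L_m v, K_mm = L_m L_m^T): the prior on v is standard normal, which makes
the KL closed-form and parameterisation-independent of the kernel, and keeps
the variational covariance unconditionally positive definite via its Cholesky
factor.

Interface follows the model/results convention: build
:class:`SparseGPClassifier` from a feature matrix and labels, call ``fit()``,
get a :class:`SparseGPResults` carrying the optimized state, the training
curve, ``predict`` and ``summary``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import scipy.optimize
from sklearn.cluster import KMeans

from . import _autodiff as ad
from ._autodiff import Tensor
from ._optim import RMSProp
from ._seeding import derive_seed, rng_for
from .corpus import LABELS
from .predictions import PredictiveDistribution

logger = logging.getLogger(__name__)


class NumericalError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# kernel
# ---------------------------------------------------------------------------

@dataclass
class KernelParams:
    """ARD-RBF kernel k(x, x') = sigma^2 exp(-1/2 sum_d (x_d - x'_d)^2 / l_d^2)."""

    signal_variance: float
    length_scales: np.ndarray

    def __post_init__(self):
        self.length_scales = np.asarray(self.length_scales, dtype=float)
        if self.signal_variance <= 0 or np.any(self.length_scales <= 0):
            raise ValueError("kernel parameters must be strictly positive")


def rbf_ard(x, x2, params: KernelParams) -> float:
    x, x2 = np.asarray(x, dtype=float), np.asarray(x2, dtype=float)
    if x.shape != x2.shape or x.shape != params.length_scales.shape:
        raise ValueError("dimension mismatch between inputs and length scales")
    z = (x - x2) / params.length_scales
    return float(params.signal_variance * np.exp(-0.5 * np.dot(z, z)))


def _kernel_matrix(Xa, Xb, log_sv: Tensor, log_ls: Tensor) -> Tensor:
    """Tape-aware ARD-RBF Gram block between row sets Xa (n,d) and Xb (m,d)."""
    ls = ad.exp(log_ls)
    A = ad.div(Xa, ls)
    B = ad.div(Xb, ls)
    a2 = ad.tsum(ad.mul(A, A), axis=1, keepdims=True)            # (n,1)
    b2 = ad.reshape(ad.tsum(ad.mul(B, B), axis=1), (1, -1))      # (1,m)
    cross = ad.matmul(A, ad.transpose(B))
    d2 = ad.add(ad.sub(a2, ad.mul(cross, 2.0)), b2)
    return ad.mul(ad.exp(log_sv), ad.exp(ad.mul(d2, -0.5)))


# ---------------------------------------------------------------------------
# variational state
# ---------------------------------------------------------------------------

@dataclass
class SvgpConfig:
    num_inducing: int = 300
    mc_train: int = 20
    mc_predict: int = 100
    learning_rate: float = 0.003
    batch_size: int = 500
    epochs: int | None = None  # None: max(2, enough for 200 updates)
    jitter: float = 1e-6
    optimize_inducing: bool = True
    seed: int = 0
    num_classes: int = 3


class SvgpState:
    """Trainable parameters: log kernel hyperparameters (shared across the C
    latent functions), inducing inputs Z, whitened variational means (M, C)
    and one raw Cholesky factor per latent function (strictly-lower part free,
    diagonal stored in log-space)."""

    def __init__(self, Z: np.ndarray, num_classes: int, signal_variance: float,
                 length_scales: np.ndarray, jitter: float = 1e-6,
                 optimize_inducing: bool = True, mc_samples: int = 20):
        M, d = Z.shape
        self.num_inducing = M
        self.num_classes = num_classes
        self.jitter = jitter
        self.mc_samples = mc_samples
        self.log_sv = Tensor(np.log(signal_variance), requires_grad=True)
        self.log_ls = Tensor(np.log(np.asarray(length_scales, dtype=float)), requires_grad=True)
        self.Z = Tensor(np.array(Z, dtype=float), requires_grad=optimize_inducing)
        self.m_w = Tensor(np.zeros((M, num_classes)), requires_grad=True)
        self.L_raw = [Tensor(np.zeros((M, M)), requires_grad=True) for _ in range(num_classes)]

    @property
    def params(self) -> list[Tensor]:
        ps = [self.log_sv, self.log_ls, self.m_w, *self.L_raw]
        if self.Z.requires_grad:
            ps.append(self.Z)
        return ps

    def chol_factor(self, c: int) -> Tensor:
        raw = self.L_raw[c]
        return ad.add(ad.tril(raw, k=-1), ad.diag_embed(ad.exp(ad.diag_part(raw))))

    def kernel_params(self) -> KernelParams:
        return KernelParams(signal_variance=float(np.exp(self.log_sv.value)),
                            length_scales=np.exp(self.log_ls.value))

    # -- KL ---------------------------------------------------------------
    def kl(self) -> Tensor:
        """KL(q(u) || p(u)), closed form in whitened coordinates, summed over
        the C latent functions: 1/2 (||m||^2 + ||L||_F^2 - M - 2 sum log diag L)."""
        M = self.num_inducing
        total = ad.mul(ad.tsum(ad.mul(self.m_w, self.m_w)), 0.5)
        for c in range(self.num_classes):
            L = self.chol_factor(c)
            log_diag = ad.diag_part(self.L_raw[c])
            term = ad.sub(ad.mul(ad.tsum(ad.mul(L, L)), 0.5),
                          ad.add(ad.tsum(log_diag), 0.5 * M))
            total = ad.add(total, term)
        return total

    # -- marginals ---------------------------------------------------------
    def _chol_kmm(self):
        jitter = self.jitter
        while jitter <= 1e-2:
            Kmm = _kernel_matrix(self.Z, self.Z, self.log_sv, self.log_ls)
            Kmm = ad.add(Kmm, Tensor(jitter * np.eye(self.num_inducing)))
            try:
                return ad.cholesky(Kmm)
            except np.linalg.LinAlgError:
                logger.warning("Cholesky failed at jitter %.1e; retrying x10", jitter)
                jitter *= 10.0
        raise NumericalError("inducing Gram matrix not positive definite after jitter ladder")

    def marginals(self, X: np.ndarray) -> tuple[Tensor, Tensor]:
        """Mean and variance of the latent marginals at X, per class: (B, C)."""
        Lm = self._chol_kmm()
        Kmn = _kernel_matrix(self.Z, Tensor(X), self.log_sv, self.log_ls)
        A = ad.solve_triangular(Lm, Kmn)                         # (M, B)
        mu = ad.matmul(ad.transpose(A), self.m_w)                # (B, C)
        knn = ad.exp(self.log_sv)
        a2 = ad.tsum(ad.mul(A, A), axis=0)                       # (B,)
        cols = []
        for c in range(self.num_classes):
            LA = ad.matmul(ad.transpose(self.chol_factor(c)), A)
            vc = ad.add(ad.sub(knn, a2), ad.tsum(ad.mul(LA, LA), axis=0))
            cols.append(ad.reshape(vc, (-1, 1)))
        return mu, ad.concat(cols, axis=1)


def kl_q_p(state: SvgpState) -> float:
    """Non-negative KL divergence between the variational distribution over the
    inducing variables and their GP prior (0 iff q equals the prior)."""
    return float(state.kl().value)


def gaussian_kl(m0, S0, m1, S1) -> float:
    """Closed-form KL(N(m0,S0) || N(m1,S1)); un-whitened cross-check route."""
    m0, m1 = np.atleast_1d(m0).astype(float), np.atleast_1d(m1).astype(float)
    S0, S1 = np.atleast_2d(S0).astype(float), np.atleast_2d(S1).astype(float)
    k = m0.size
    S1_inv = np.linalg.inv(S1)
    _, ld0 = np.linalg.slogdet(S0)
    _, ld1 = np.linalg.slogdet(S1)
    diff = m1 - m0
    return 0.5 * (np.trace(S1_inv @ S0) + diff @ S1_inv @ diff - k + ld1 - ld0)


def whitened_q_moments(state: SvgpState, c: int = 0) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Un-whitened q(u) mean/covariance for latent c plus the prior covariance
    K_mm (jittered); used to cross-check the whitened KL."""
    Lm = state._chol_kmm().value
    Lq = state.chol_factor(c).value
    mean = Lm @ state.m_w.value[:, c]
    cov = Lm @ (Lq @ Lq.T) @ Lm.T
    return mean, cov, Lm @ Lm.T


# ---------------------------------------------------------------------------
# ELBO
# ---------------------------------------------------------------------------

def elbo_minibatch(state: SvgpState, X_batch: np.ndarray, y_batch: np.ndarray,
                   n_total: int, rng: np.random.Generator | None = None,
                   eps: np.ndarray | None = None) -> Tensor:
    """Stochastic evidence lower bound on a minibatch.

    The expected log softmax likelihood is a reparameterised Monte-Carlo
    average over ``state.mc_samples`` draws of the marginal latents; the data
    term is rescaled by ``n_total / |batch|``.  ``eps`` may be supplied to fix
    the standard-normal draws (shape (S, B, C)); otherwise they come from
    ``rng``.
    """
    B = X_batch.shape[0]
    if B == 0 or n_total < B:
        raise ValueError("batch must be non-empty and no larger than n_total")
    mu, var = state.marginals(X_batch)
    if eps is None:
        if rng is None:
            raise ValueError("either rng or eps must be provided")
        eps = rng.standard_normal((state.mc_samples, B, state.num_classes))
    sd = ad.sqrt(ad.add(var, 1e-12))
    f = ad.add(mu, ad.mul(sd, Tensor(eps)))                      # (S, B, C)
    logp = ad.log_softmax(f, axis=-1)
    onehot = np.zeros((B, state.num_classes))
    onehot[np.arange(B), y_batch] = 1.0
    ell = ad.tmean(ad.tsum(ad.mul(logp, Tensor(onehot)), axis=-1), axis=0)  # (B,)
    data_term = ad.mul(ad.tsum(ell), n_total / B)
    return ad.sub(data_term, state.kl())


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

def _encode_labels(y) -> tuple[np.ndarray, list[str]]:
    y = list(y)
    if all(isinstance(v, (int, np.integer)) for v in y):
        classes = [str(c) for c in sorted(set(int(v) for v in y))]
        return np.array([int(v) for v in y]), classes
    classes = [lab for lab in LABELS if lab in set(y)]
    extra = sorted(set(y) - set(classes))
    classes += extra
    index = {c: i for i, c in enumerate(classes)}
    return np.array([index[v] for v in y]), classes


class SparseGPClassifier:
    """Sparse variational GP classifier over mean-pooled document features."""

    def __init__(self, X: np.ndarray, y, config: SvgpConfig | None = None):
        self.X = np.asarray(X, dtype=float)
        self.config = config or SvgpConfig()
        self.y, self.classes_ = _encode_labels(y)
        if len(self.classes_) != self.config.num_classes:
            raise ValueError(
                f"training labels cover {len(self.classes_)} classes "
                f"({self.classes_}); the {self.config.num_classes}-class likelihood "
                "requires every class to be present")

    def _init_state(self) -> SvgpState:
        cfg = self.config
        n, d = self.X.shape
        M = min(cfg.num_inducing, n)
        if M < cfg.num_inducing:
            logger.info("reducing inducing count %d -> %d (n=%d)", cfg.num_inducing, M, n)
        km_seed = derive_seed(cfg.seed, "svgp-kmeans")
        km = KMeans(n_clusters=M, random_state=km_seed, n_init=4).fit(self.X)
        Z = km.cluster_centers_
        std = np.maximum(self.X.std(axis=0), 1e-3)
        ls0 = std * math.sqrt(d)  # keeps initial scaled distances O(1)
        return SvgpState(Z, cfg.num_classes, signal_variance=1.0, length_scales=ls0,
                         jitter=cfg.jitter, optimize_inducing=cfg.optimize_inducing,
                         mc_samples=cfg.mc_train)

    def fit(self) -> "SparseGPResults":
        cfg = self.config
        n = self.X.shape[0]
        state = self._init_state()
        batch = min(cfg.batch_size, n)
        steps_per_epoch = max(1, math.ceil(n / batch))
        epochs = cfg.epochs if cfg.epochs is not None else max(2, math.ceil(200 / steps_per_epoch))
        opt = RMSProp(state.params, lr=cfg.learning_rate)
        rng = rng_for(cfg.seed, "svgp-train")
        history = []
        for epoch in range(epochs):
            order = rng.permutation(n)
            epoch_elbos = []
            for start in range(0, n, batch):
                idx = order[start:start + batch]
                opt.zero_grad()
                elbo = elbo_minibatch(state, self.X[idx], self.y[idx], n, rng=rng)
                if not np.isfinite(elbo.value):
                    raise NumericalError(
                        f"non-finite ELBO at epoch {epoch}, step {start // batch}; "
                        f"kernel={state.kernel_params()}")
                loss = ad.mul(elbo, -1.0)
                loss.backward()
                opt.step()
                epoch_elbos.append(float(elbo.value))
            history.append(float(np.mean(epoch_elbos)))
            logger.info("epoch %d/%d mean ELBO %.2f", epoch + 1, epochs, history[-1])
        return SparseGPResults(state=state, classes=self.classes_, config=cfg,
                               elbo_history=history)


@dataclass
class SparseGPResults:
    state: SvgpState
    classes: list[str]
    config: SvgpConfig
    elbo_history: list[float] = field(default_factory=list)

    def predict(self, X: np.ndarray) -> PredictiveDistribution:
        """Sparse predictive equations for the latent marginals, then a
        fixed-seed Monte-Carlo softmax expectation for class probabilities."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.state.Z.value.shape[1]:
            raise ValueError("feature dimension does not match the fitted state")
        mu_t, var_t = self.state.marginals(X)
        mu, var = mu_t.value, var_t.value
        rng = rng_for(self.config.seed, "svgp-predict")
        S = self.config.mc_predict
        eps = rng.standard_normal((S, *mu.shape))
        f = mu[None] + np.sqrt(np.maximum(var, 0.0))[None] * eps
        probs = ad.softmax_values(f, axis=-1).mean(axis=0)
        probs /= probs.sum(axis=1, keepdims=True)
        return PredictiveDistribution(probs=probs, latent_means=mu, latent_variances=var)

    def summary(self) -> str:
        kp = self.state.kernel_params()
        ls = kp.length_scales
        lines = [
            "Sparse variational GP classifier",
            "=" * 40,
            f"classes:            {', '.join(self.classes)}",
            f"inducing points:    {self.state.num_inducing}",
            f"signal variance:    {kp.signal_variance:.4f}",
            f"length scales:      min {ls.min():.3f} / median {np.median(ls):.3f} / max {ls.max():.3f}",
            f"KL(q || p):         {kl_q_p(self.state):.3f}",
            f"final epoch ELBO:   {self.elbo_history[-1]:.2f}" if self.elbo_history else "",
            f"training epochs:    {len(self.elbo_history)}",
        ]
        return "\n".join(filter(None, lines))


# ---------------------------------------------------------------------------
# Gaussian-likelihood verification path
# ---------------------------------------------------------------------------

def gaussian_elbo(state: SvgpState, X: np.ndarray, y: np.ndarray, noise_var: float) -> Tensor:
    """Deterministic ELBO under a Gaussian observation model (single latent).

    E_q[log N(y_i; f_i, s2)] = log N(y_i; mu_i, s2) - v_i / (2 s2), so the
    bound needs no Monte-Carlo.  Used to verify the variational machinery: at
    M = n inducing points placed on the data, the optimum equals the exact GP
    log marginal likelihood (the collapsed bound is tight).
    """
    mu, var = state.marginals(X)
    mu0 = ad.reshape(mu, (-1,))
    v0 = ad.reshape(var, (-1,))
    resid = ad.sub(Tensor(np.asarray(y, dtype=float)), mu0)
    n = len(y)
    const = -0.5 * n * math.log(2 * math.pi * noise_var)
    quad = ad.mul(ad.tsum(ad.mul(resid, resid)), -0.5 / noise_var)
    trace = ad.mul(ad.tsum(v0), -0.5 / noise_var)
    return ad.sub(ad.add(ad.add(quad, trace), const), state.kl())


def fit_gaussian_variational(X: np.ndarray, y: np.ndarray, kernel: KernelParams,
                             noise_var: float, jitter: float = 1e-8) -> tuple[float, SvgpState]:
    """Optimize the whitened variational parameters of a Gaussian-likelihood
    sparse GP with inducing points fixed at the data (kernel fixed), by
    L-BFGS on the engine's gradients.  Returns (optimal ELBO, state)."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    state = SvgpState(X, num_classes=1, signal_variance=kernel.signal_variance,
                      length_scales=kernel.length_scales, jitter=jitter,
                      optimize_inducing=False)
    state.log_sv.requires_grad = False
    state.log_ls.requires_grad = False

    def unpack(theta):
        state.m_w.value = theta[:n].reshape(n, 1)
        state.L_raw[0].value = theta[n:].reshape(n, n)

    def objective(theta):
        unpack(theta)
        for p in (state.m_w, state.L_raw[0]):
            p.zero_grad()
        elbo = gaussian_elbo(state, X, y, noise_var)
        loss = ad.mul(elbo, -1.0)
        loss.backward()
        grad = np.concatenate([state.m_w.grad.ravel(), state.L_raw[0].grad.ravel()])
        return float(loss.value), grad

    x0 = np.concatenate([np.zeros(n), np.zeros(n * n)])
    res = scipy.optimize.minimize(objective, x0, jac=True, method="L-BFGS-B",
                                  options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-10})
    unpack(res.x)
    return float(-res.fun), state
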