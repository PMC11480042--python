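"""Baseline uncertainty models: an isotonic-calibrated random forest and a
deep ensemble of adversarially trained multilayer perceptrons.

The forest (300 trees, max depth 40) emits tree-vote class frequencies that
are post-processed one-vs-rest by monotone isotonic maps fitted on a held-out
calibration split, then renormalized to the simplex.  The ensemble averages
the softmax outputs of five independently initialized MLPs (three hidden
layers of 200 units with batch normalization, Adam at 3e-3, 10 epochs); each
training batch mixes the clean cross-entropy with the cross-entropy on fast
gradient sign method (FGSM) perturbations of the inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.isotonic import IsotonicRegression

from . import _autodiff as ad
from ._autodiff import Tensor
from ._optim import Adam
from ._seeding import derive_seed, rng_for
from .predictions import PredictiveDistribution
from .svgp import _encode_labels

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# calibrated random forest
# ---------------------------------------------------------------------------

@dataclass
class ForestConfig:
    n_trees: int = 300
    max_depth: int = 40
    calibration: str = "isotonic"
    calibration_fit_policy: str = "validation-split"

    def __post_init__(self):
        if self.n_trees < 1 or self.max_depth < 1:
            raise ValueError("n_trees and max_depth must be >= 1")


class CalibratedForestClassifier:
    """Random forest + one-vs-rest isotonic probability calibration.

    The calibration split must be disjoint from the training data (fitting the
    monotone maps on training scores would leak the forest's overconfidence).
    """

    def __init__(self, X, y, config: ForestConfig | None = None, seed: int = 0):
        self.X = np.asarray(X, dtype=float)
        self.y, self.classes_ = _encode_labels(y)
        self.config = config or ForestConfig()
        self.seed = seed

    def fit(self, calibration_X, calibration_y) -> "CalibratedForestResults":
        cfg = self.config
        forest = RandomForestClassifier(
            n_estimators=cfg.n_trees, max_depth=cfg.max_depth,
            random_state=derive_seed(self.seed, "rf") % (2**32))
        forest.fit(self.X, self.y)
        cal_y, _ = _encode_labels(calibration_y)
        raw = forest.predict_proba(np.asarray(calibration_X, dtype=float))
        raw = self._expand(raw, forest)
        calibrators: list[IsotonicRegression | None] = []
        for c in range(len(self.classes_)):
            target = (cal_y == c).astype(float)
            if target.sum() == 0:
                logger.warning("calibration split lacks class %r; using identity map",
                               self.classes_[c])
                calibrators.append(None)
                continue
            iso = IsotonicRegression(y_min=0.0, y_max=1.0, out_of_bounds="clip")
            iso.fit(raw[:, c], target)
            calibrators.append(iso)
        return CalibratedForestResults(forest=forest, calibrators=calibrators,
                                       classes=self.classes_, config=cfg)

    def _expand(self, raw, forest):
        # forest may have seen a label subset; realign columns onto all classes
        out = np.zeros((raw.shape[0], len(self.classes_)))
        for j, c in enumerate(forest.classes_):
            out[:, int(c)] = raw[:, j]
        return out


def fit_forest(X, y, config: ForestConfig, calibration_X, calibration_y,
               seed: int = 0) -> "CalibratedForestResults":
    return CalibratedForestClassifier(X, y, config, seed=seed).fit(calibration_X, calibration_y)


@dataclass
class CalibratedForestResults:
    forest: RandomForestClassifier
    calibrators: list
    classes: list[str]
    config: ForestConfig

    def predict_raw(self, X) -> np.ndarray:
        raw = self.forest.predict_proba(np.asarray(X, dtype=float))
        out = np.zeros((raw.shape[0], len(self.classes)))
        for j, c in enumerate(self.forest.classes_):
            out[:, int(c)] = raw[:, j]
        return out

    def predict(self, X) -> PredictiveDistribution:
        raw = self.predict_raw(X)
        cal = np.empty_like(raw)
        for c, iso in enumerate(self.calibrators):
            cal[:, c] = raw[:, c] if iso is None else iso.predict(raw[:, c])
        totals = cal.sum(axis=1, keepdims=True)
        uniform = np.full_like(cal, 1.0 / cal.shape[1])
        cal = np.where(totals > 0, cal / np.where(totals > 0, totals, 1.0), uniform)
        return PredictiveDistribution(probs=cal)

    def summary(self) -> str:
        return "\n".join([
            "Calibrated random forest",
            "=" * 40,
            f"classes:      {', '.join(self.classes)}",
            f"trees:        {self.config.n_trees}, max depth {self.config.max_depth}",
            f"calibration:  {self.config.calibration} (one-vs-rest, "
            f"{self.config.calibration_fit_policy})",
        ])


# ---------------------------------------------------------------------------
# deep ensemble
# ---------------------------------------------------------------------------

@dataclass
class EnsembleConfig:
    n_members: int = 5
    hidden_layers: int = 3
    hidden_units: int = 200
    batch_norm: bool = True
    learning_rate: float = 3e-3
    epochs: int = 10
    batch_size: int = 100
    adversarial_epsilon: float | None = None  # None: 0.01 x per-feature IQR
    member_seeds: list[int] | None = None

    def __post_init__(self):
        if self.n_members < 2:
            raise ValueError("an ensemble needs at least 2 members")
        if self.member_seeds is not None and len(set(self.member_seeds)) != self.n_members:
            raise ValueError("member_seeds must be distinct, one per member")


def fgsm_perturb(x, loss_gradient, epsilon: float):
    """Fast gradient sign method step: x + epsilon * sign(grad), sign(0) = 0."""
    if epsilon < 0:
        raise ValueError("epsilon must be non-negative")
    return np.asarray(x, dtype=float) + epsilon * np.sign(np.asarray(loss_gradient, dtype=float))


class _MLP:
    """Plain MLP with optional batch normalization, built on the autodiff
    engine.  Batch statistics are used in training mode; exponential running
    statistics (momentum 0.9) in eval mode."""

    def __init__(self, d_in: int, d_hidden: int, n_hidden: int, d_out: int,
                 batch_norm: bool, rng: np.random.Generator):
        self.batch_norm = batch_norm
        self.weights: list[Tensor] = []
        self.biases: list[Tensor] = []
        self.gammas: list[Tensor] = []
        self.betas: list[Tensor] = []
        self.run_mean: list[np.ndarray] = []
        self.run_var: list[np.ndarray] = []
        dims = [d_in] + [d_hidden] * n_hidden + [d_out]
        for i in range(len(dims) - 1):
            fan_in = dims[i]
            w = rng.standard_normal((dims[i], dims[i + 1])) * np.sqrt(2.0 / fan_in)
            self.weights.append(Tensor(w, requires_grad=True))
            self.biases.append(Tensor(np.zeros(dims[i + 1]), requires_grad=True))
            if batch_norm and i < len(dims) - 2:
                self.gammas.append(Tensor(np.ones(dims[i + 1]), requires_grad=True))
                self.betas.append(Tensor(np.zeros(dims[i + 1]), requires_grad=True))
                self.run_mean.append(np.zeros(dims[i + 1]))
                self.run_var.append(np.ones(dims[i + 1]))

    @property
    def params(self) -> list[Tensor]:
        return [*self.weights, *self.biases, *self.gammas, *self.betas]

    def forward(self, x: Tensor, train: bool) -> Tensor:
        h = x
        n_layers = len(self.weights)
        for i in range(n_layers):
            h = ad.add(ad.matmul(h, self.weights[i]), self.biases[i])
            if i == n_layers - 1:
                break
            if self.batch_norm:
                if train:
                    mean = ad.tmean(h, axis=0, keepdims=True)
                    centered = ad.sub(h, mean)
                    var = ad.tmean(ad.mul(centered, centered), axis=0, keepdims=True)
                    self.run_mean[i] = 0.9 * self.run_mean[i] + 0.1 * mean.value.ravel()
                    self.run_var[i] = 0.9 * self.run_var[i] + 0.1 * var.value.ravel()
                else:
                    mean = Tensor(self.run_mean[i][None, :])
                    centered = ad.sub(h, mean)
                    var = Tensor(self.run_var[i][None, :])
                norm = ad.div(centered, ad.sqrt(ad.add(var, 1e-5)))
                h = ad.add(ad.mul(norm, self.gammas[i]), self.betas[i])
            h = ad.relu(h)
        return h

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        logits = self.forward(Tensor(np.asarray(X, dtype=float)), train=False)
        return ad.softmax_values(logits.value, axis=-1)


def _cross_entropy(logits: Tensor, onehot: np.ndarray) -> Tensor:
    logp = ad.log_softmax(logits, axis=-1)
    return ad.mul(ad.tmean(ad.tsum(ad.mul(logp, Tensor(onehot)), axis=-1)), -1.0)


class DeepEnsembleClassifier:
    """Deep ensemble with adversarial (FGSM) training."""

    def __init__(self, X, y, config: EnsembleConfig | None = None, seed: int = 0):
        self.X = np.asarray(X, dtype=float)
        self.y, self.classes_ = _encode_labels(y)
        self.config = config or EnsembleConfig()
        self.seed = seed

    def _epsilon(self) -> float:
        if self.config.adversarial_epsilon is not None:
            return self.config.adversarial_epsilon
        iqr = np.subtract(*np.percentile(self.X, [75, 25], axis=0))
        return 0.01 * float(np.mean(iqr))

    def fit(self) -> "DeepEnsembleResults":
        cfg = self.config
        seeds = cfg.member_seeds or [derive_seed(self.seed, f"ens-member-{k}")
                                     for k in range(cfg.n_members)]
        eps = self._epsilon()
        members = [self._fit_member(s, eps) for s in seeds]
        return DeepEnsembleResults(members=members, classes=self.classes_,
                                   config=cfg, member_seeds=list(seeds),
                                   adversarial_epsilon=eps)

    def _fit_member(self, member_seed: int, eps: float) -> _MLP:
        cfg = self.config
        n, d = self.X.shape
        C = len(self.classes_)
        rng = np.random.default_rng(member_seed)
        mlp = _MLP(d, cfg.hidden_units, cfg.hidden_layers, C, cfg.batch_norm, rng)
        opt = Adam(mlp.params, lr=cfg.learning_rate)
        onehot_all = np.zeros((n, C))
        onehot_all[np.arange(n), self.y] = 1.0
        batch = min(cfg.batch_size, n)
        for _ in range(cfg.epochs):
            order = rng.permutation(n)
            for start in range(0, n, batch):
                idx = order[start:start + batch]
                xb, ob = self.X[idx], onehot_all[idx]
                # pass 1: input gradient for FGSM (parameter grads discarded)
                x_in = Tensor(xb, requires_grad=True)
                loss = _cross_entropy(mlp.forward(x_in, train=True), ob)
                loss.backward()
                x_adv = fgsm_perturb(xb, x_in.grad, eps)
                opt.zero_grad()
                # pass 2: clean + adversarial loss, parameter update
                loss_clean = _cross_entropy(mlp.forward(Tensor(xb), train=True), ob)
                loss_adv = _cross_entropy(mlp.forward(Tensor(x_adv), train=True), ob)
                total = ad.mul(ad.add(loss_clean, loss_adv), 0.5)
                if not np.isfinite(total.value):
                    raise RuntimeError(f"member with seed {member_seed} diverged "
                                       "(non-finite loss)")
                total.backward()
                opt.step()
                opt.zero_grad()
        return mlp


def fit_ensemble(X, y, config: EnsembleConfig, seed: int = 0) -> "DeepEnsembleResults":
    return DeepEnsembleClassifier(X, y, config, seed=seed).fit()


@dataclass
class DeepEnsembleResults:
    members: list
    classes: list[str]
    config: EnsembleConfig
    member_seeds: list[int] = field(default_factory=list)
    adversarial_epsilon: float = 0.0

    def member_probs(self, X) -> np.ndarray:
        """(n_members, n, C) member predictive distributions."""
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.members[0].weights[0].value.shape[0]:
            raise ValueError("feature dimension does not match the fitted ensemble")
        return np.stack([m.predict_proba(X) for m in self.members])

    def predict(self, X) -> PredictiveDistribution:
        probs = self.member_probs(X).mean(axis=0)
        probs /= probs.sum(axis=1, keepdims=True)
        return PredictiveDistribution(probs=probs)

    def summary(self) -> str:
        cfg = self.config
        return "\n".join([
            "Deep ensemble (adversarially trained MLPs)",
            "=" * 40,
            f"classes:       {', '.join(self.classes)}",
            f"members:       {cfg.n_members} x MLP({cfg.hidden_layers} x {cfg.hidden_units}"
            f"{', batch norm' if cfg.batch_norm else ''})",
            f"training:      Adam lr={cfg.learning_rate}, {cfg.epochs} epochs",
            f"FGSM epsilon:  {self.adversarial_epsilon:.4g}",
        ])


def predict_ensemble(model: DeepEnsembleResults, X) -> PredictiveDistribution:
    return model.predict(X)
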