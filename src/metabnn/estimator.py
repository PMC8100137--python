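"""Scikit-learn style front end for metaplastic BNN training.

:class:`MetaplasticBNNClassifier` wraps the binarized network and the
metaplastic Adam optimizer behind the usual ``fit`` / ``partial_fit`` /
``predict`` surface so that it composes with sklearn tooling (``clone``,
pipelines, cross-validation).  ``partial_fit`` continues training without
re-initialization, which is the primitive the continual-learning protocols
build on; an optional batch-norm *slot* argument selects task-specific
normalization state.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted, check_X_y, check_array

from .consolidation import ewc_grads
from .network import Network, mlp_spec, softmax
from .optimizer import MetaplasticAdam

__all__ = ["MetaplasticBNNClassifier"]


class MetaplasticBNNClassifier(ClassifierMixin, BaseEstimator):
    """Binarized multi-layer perceptron trained with metaplastic Adam.

    Parameters
    ----------
    hidden_layer_sizes : tuple of int, default (128, 128)
        Sizes of the hidden binary layers.
    m : float, default 0.0
        Metaplasticity strength; 0 recovers conventional BNN training.
    variant : {"smooth", "hard_zero"}
        Shape of the attenuation function.
    hard_threshold : float or None
        Cut-off of the hard-zero variant (None = where the smooth function
        falls below 1e-3).
    learning_rate, betas, eps :
        Adam hyper-parameters.
    n_epochs : int, default 20
        Epochs per call to :meth:`fit` / :meth:`partial_fit`.
    batch_size : int, default 32
    binary : bool, default True
        False selects the full-precision control network (real weights,
        tanh hidden activation) trained with the same update rule.
    batch_norm : bool, default True
    dropout : float, default 0.0
        Drop probability on hidden-layer inputs.
    random_state : int or None
        Seeds initialization and data shuffling.

    Attributes
    ----------
    network_ : Network
    optimizer_ : MetaplasticAdam
    classes_ : ndarray
    loss_curve_ : list of float
        Mean training loss per epoch across all training calls.
    """

    def __init__(self, hidden_layer_sizes=(128, 128), m=0.0, variant="smooth",
                 hard_threshold=None, learning_rate=1e-3, betas=(0.9, 0.999),
                 eps=1e-8, n_epochs=20, batch_size=32, binary=True,
                 batch_norm=True, dropout=0.0, synapse="scalar",
                 chain_levels=4, chain_g0=0.01, chain_ratio=0.25,
                 random_state=None):
        self.hidden_layer_sizes = hidden_layer_sizes
        self.m = m
        self.variant = variant
        self.hard_threshold = hard_threshold
        self.learning_rate = learning_rate
        self.betas = betas
        self.eps = eps
        self.n_epochs = n_epochs
        self.batch_size = batch_size
        self.binary = binary
        self.batch_norm = batch_norm
        self.dropout = dropout
        self.synapse = synapse
        self.chain_levels = chain_levels
        self.chain_g0 = chain_g0
        self.chain_ratio = chain_ratio
        self.random_state = random_state

    # -- lifecycle ----------------------------------------------------------

    def _init_model(self, n_features: int, n_classes: int) -> None:
        seed = 0 if self.random_state is None else int(self.random_state)
        spec = mlp_spec((n_features, *self.hidden_layer_sizes, n_classes),
                        binary=self.binary, batch_norm=self.batch_norm,
                        dropout=self.dropout)
        self.network_ = Network(spec, seed)
        self.optimizer_ = MetaplasticAdam(
            self.network_, m=self.m, variant=self.variant,
            hard_threshold=self.hard_threshold, lr=self.learning_rate,
            betas=self.betas, eps=self.eps)
        self._shuffle_rng = np.random.default_rng(seed + 10_000)
        self.loss_curve_ = []
        self.n_features_in_ = n_features
        self.chains_ = None
        if self.synapse == "chain":
            from .multiscale import ChainSynapse
            self.chains_ = []
            for lyr in self.network_.weight_layers():
                chain = ChainSynapse.zeros(lyr.hidden.shape,
                                           n_levels=self.chain_levels,
                                           g0=self.chain_g0,
                                           ratio=self.chain_ratio)
                chain.u[0] = lyr.hidden
                lyr.hidden = chain.u[0]  # layer now trains the chain's top level
                self.chains_.append(chain)
        elif self.synapse != "scalar":
            raise ValueError(f"unknown synapse model {self.synapse!r}")

    def fit(self, X, y):
        """Train from a fresh initialization on ``(X, y)``."""
        X, y = check_X_y(X, y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        self._init_model(X.shape[1], len(self.classes_))
        self._run_epochs(X, y_idx, self.n_epochs)
        return self

    def partial_fit(self, X, y, classes=None, bn_slot=None, epochs=None,
                    lr=None, ewc_maps=None, grad_hook=None):
        """Continue training on new data without re-initialization.

        ``bn_slot`` selects (creating if needed) a task-specific batch-norm
        slot before training; ``ewc_maps`` adds the elastic-consolidation
        penalty gradient of the given importance maps; ``grad_hook`` is
        called with the weight gradients after every step (used by the
        path-integral tracker).
        """
        first = not hasattr(self, "network_")
        if first:
            X, y = check_X_y(X, y)
            if classes is None:
                classes = np.unique(y)
            self.classes_ = np.asarray(classes)
            self._init_model(X.shape[1], len(self.classes_))
        else:
            X, y = check_X_y(X, y)
        y_idx = np.searchsorted(self.classes_, y)
        if bn_slot is not None:
            self.network_.use_bn_slot(int(bn_slot))
        self._run_epochs(X, y_idx, self.n_epochs if epochs is None else epochs,
                         lr=lr, ewc_maps=ewc_maps, grad_hook=grad_hook)
        return self

    def _run_epochs(self, X, y_idx, epochs, lr=None, ewc_maps=None,
                    grad_hook=None):
        net, opt = self.network_, self.optimizer_
        bs = int(self.batch_size)
        for _ in range(epochs):
            perm = self._shuffle_rng.permutation(len(y_idx))
            losses = []
            for i in range(0, len(perm), bs):
                idx = perm[i:i + bs]
                if len(idx) < 2 and self.batch_norm:
                    continue  # undefined batch variance
                loss, wg, bg = net.loss_and_grad(X[idx], y_idx[idx], training=True)
                if ewc_maps:
                    for g, pg in zip(wg, ewc_grads(net, ewc_maps)):
                        g += pg
                opt.step(wg, bg, lr=lr)
                if self.chains_ is not None:
                    for chain in self.chains_:
                        chain.step(0.0)  # training update already applied to u_1
                if grad_hook is not None:
                    grad_hook(wg)
                losses.append(loss)
            self.loss_curve_.append(float(np.mean(losses)))

    # -- inference ----------------------------------------------------------

    def use_bn_slot(self, slot: int, create: bool = True):
        check_is_fitted(self, "network_")
        self.network_.use_bn_slot(int(slot), create=create)
        return self

    def decision_function(self, X):
        check_is_fitted(self, "network_")
        X = check_array(X)
        return self.network_.predict_scores(X)

    def predict_proba(self, X):
        return softmax(self.decision_function(X))

    def predict(self, X):
        return self.classes_[np.argmax(self.decision_function(X), axis=1)]

    def accuracy_percent(self, X, y) -> float:
        """Test accuracy in percent (the reporting convention used by the
        continual-learning metrics; ``score`` keeps sklearn's 0-1 scale)."""
        return 100.0 * float(np.mean(self.predict(X) == np.asarray(y)))
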