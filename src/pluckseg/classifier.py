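"""Posterior-probability classifier used at every auto-context iteration.

A single-hidden-layer perceptron (20 logistic units by default) with a
softmax output, trained on an L2-regularised cross-entropy loss. Any
deterministic-given-seed optimiser satisfies the contract; L-BFGS is used
because it is full-batch and therefore reproducible bit-for-bit for a
fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler


@dataclass
class PosteriorMLP:
    """Trainable K-class posterior estimator.

    Parameters
    ----------
    hidden_units : width of the single logistic hidden layer.
    l2 : L2 regularisation strength on the weights.
    max_iter : optimiser iteration cap.
    tol : convergence tolerance on the loss change.
    """

    hidden_units: int = 20
    l2: float = 1e-3
    max_iter: int = 500
    tol: float = 1e-5
    _clf: MLPClassifier | None = field(default=None, repr=False, compare=False)
    _num_classes: int = field(default=0, repr=False, compare=False)

    def fit(self, features: np.ndarray, labels: np.ndarray, seed: int) -> "PosteriorMLP":
        """Train on rows of ``features`` with labels in 1..K; deterministic given seed."""
        labels = np.asarray(labels, dtype=np.int64)
        self._num_classes = int(labels.max())
        mlp = MLPClassifier(
            hidden_layer_sizes=(self.hidden_units,),
            activation="logistic",
            solver="lbfgs",
            alpha=self.l2,
            max_iter=self.max_iter,
            tol=self.tol,
            random_state=int(seed),
        )
        # inputs mix bounded probabilities with squared wavelet responses
        # spanning orders of magnitude; standardise on training statistics
        self._clf = Pipeline([("scale", StandardScaler()), ("mlp", mlp)])
        import warnings

        with warnings.catch_warnings():
            # hitting the iteration cap is an accepted stopping rule here
            warnings.filterwarnings("ignore", message=".*Maximum iterations.*")
            warnings.filterwarnings("ignore", category=UserWarning,
                                    module="sklearn.neural_network")
            self._clf.fit(np.asarray(features), labels)
        return self

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        """Rows of valid K-class distributions, columns ordered class 1..K."""
        if self._clf is None:
            raise RuntimeError("classifier has not been trained")
        raw = self._clf.predict_proba(np.asarray(features))
        classes = self._clf.classes_.astype(int)
        k = max(self._num_classes, int(classes.max()))
        if raw.shape[1] == k and np.array_equal(classes, np.arange(1, k + 1)):
            return raw
        out = np.zeros((raw.shape[0], k))
        out[:, classes - 1] = raw
        return out

    @property
    def num_inputs(self) -> int:
        if self._clf is None:
            raise RuntimeError("classifier has not been trained")
        return int(self._clf.n_features_in_)
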