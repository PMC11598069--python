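"""Left-vs-right classification of feature-matrix columns.

Three classifiers are benchmarked on the pattern matrix: an RBF-kernel
support vector machine, Gaussian naive Bayes with equal class priors, and a
two-layer neural network (sigmoid hidden layer, softmax output) trained by
full-batch gradient descent on cross-entropy.  Evaluation is leave-one-out
cross-validation: Q folds for Q segments, each fold training on the other
Q−1 columns; features are z-scored using training-fold statistics only.
Class "L" is the positive class for the confusion-matrix metrics

    TPR = TP/(TP+FN),  TNR = TN/(TN+FP),  AC = (TP+TN)/(TP+TN+FP+FN)

and the cross-validation error CV is the held-out misclassification rate.

The SVM and naive Bayes are scikit-learn estimators; the two-layer network
is implemented here so its gradients can be verified against finite
differences and its training is reproducible from a seed alone.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy.special import expit, log_softmax, softmax
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import SVC

from .features import FeatureSet

__all__ = [
    "METHODS",
    "TwoLayerNet",
    "ClassificationReport",
    "train_nn",
    "fit_predict",
    "loocv",
]

METHODS = ("svm", "bayes", "nn")


@dataclasses.dataclass
class TwoLayerNet:
    """Two-layer feedforward network: sigmoid hidden layer, softmax output.

    Forward pass for a pattern matrix P (R×Q):

        A1 = sigmoid(W1 @ P + b1)      (S1×Q)
        A2 = softmax(W2 @ A1 + b2)     (S2×Q, columns sum to 1)
    """

    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray
    #: training-loss trace filled in by train_nn (accepted steps only)
    loss_history: list = dataclasses.field(default=None, repr=False, compare=False)

    @property
    def S1(self) -> int:
        return self.W1.shape[0]

    @property
    def S2(self) -> int:
        return self.W2.shape[0]

    @classmethod
    def zeros(cls, R: int, S1: int = 10, S2: int = 2) -> "TwoLayerNet":
        return cls(
            W1=np.zeros((S1, R)),
            b1=np.zeros(S1),
            W2=np.zeros((S2, S1)),
            b2=np.zeros(S2),
        )

    @classmethod
    def init_random(cls, R: int, S1: int = 10, S2: int = 2, seed: int = 0) -> "TwoLayerNet":
        """Glorot-style uniform init, biases zero, reproducible from the seed."""
        rng = np.random.default_rng(seed)

        def glorot(fan_out, fan_in):
            limit = np.sqrt(6.0 / (fan_in + fan_out))
            return rng.uniform(-limit, limit, size=(fan_out, fan_in))

        return cls(W1=glorot(S1, R), b1=np.zeros(S1), W2=glorot(S2, S1), b2=np.zeros(S2))

    def forward(self, P: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return hidden activations A1 and softmax outputs A2."""
        A1 = expit(self.W1 @ P + self.b1[:, None])
        A2 = softmax(self.W2 @ A1 + self.b2[:, None], axis=0)
        return A1, A2

    def loss(self, P: np.ndarray, T: np.ndarray) -> float:
        """Mean cross-entropy per column (numerically stable log-softmax)."""
        A1 = expit(self.W1 @ P + self.b1[:, None])
        logp = log_softmax(self.W2 @ A1 + self.b2[:, None], axis=0)
        return float(-(T * logp).sum() / P.shape[1])

    def gradients(self, P: np.ndarray, T: np.ndarray):
        """Analytic gradients of the mean cross-entropy w.r.t. all parameters."""
        Q = P.shape[1]
        A1, A2 = self.forward(P)
        dZ2 = (A2 - T) / Q
        dW2 = dZ2 @ A1.T
        db2 = dZ2.sum(axis=1)
        dZ1 = (self.W2.T @ dZ2) * A1 * (1.0 - A1)
        dW1 = dZ1 @ P.T
        db1 = dZ1.sum(axis=1)
        return dW1, db1, dW2, db2

    def predict(self, P: np.ndarray) -> np.ndarray:
        """Class label per column: 'L' for output row 1, 'R' for row 2."""
        _, A2 = self.forward(P)
        return np.where(np.argmax(A2, axis=0) == 0, "L", "R")


def train_nn(
    P: np.ndarray,
    T: np.ndarray,
    S1: int = 10,
    seed: int = 0,
    max_epochs: int = 2000,
    tol: float = 1e-6,
    lr: float = 0.1,
) -> TwoLayerNet:
    """Train the two-layer network by full-batch gradient descent.

    Backtracking on the learning rate keeps the training loss non-increasing
    across accepted steps; training stops when the loss improvement drops
    below ``tol`` or after ``max_epochs``.  Raises on a non-finite loss,
    reporting the epoch.
    """
    P = np.asarray(P, dtype=float)
    T = np.asarray(T, dtype=float)
    if P.shape[1] != T.shape[1]:
        raise ValueError("P and T must have the same number of columns")
    col_sums = T.sum(axis=0)
    if not (np.allclose(col_sums, 1.0) and np.all((T == 0) | (T == 1))):
        raise ValueError("columns of T must be one-hot")

    net = TwoLayerNet.init_random(P.shape[0], S1=S1, S2=T.shape[0], seed=seed)
    loss = net.loss(P, T)
    history = [loss]
    step = lr
    for epoch in range(max_epochs):
        if not np.isfinite(loss):
            raise RuntimeError(f"non-finite training loss at epoch {epoch}")
        grads = net.gradients(P, T)
        accepted = False
        for _ in range(40):  # backtrack until the step does not increase the loss
            trial = TwoLayerNet(
                W1=net.W1 - step * grads[0],
                b1=net.b1 - step * grads[1],
                W2=net.W2 - step * grads[2],
                b2=net.b2 - step * grads[3],
            )
            new_loss = trial.loss(P, T)
            if np.isfinite(new_loss) and new_loss <= loss:
                accepted = True
                break
            step /= 2.0
        if not accepted:
            break
        net = trial
        improvement = loss - new_loss
        loss = new_loss
        history.append(loss)
        step = min(step * 1.1, lr)  # recover after backtracking
        if improvement < tol:
            break
    net.loss_history = history
    return net


def _standardize(train: np.ndarray, test: np.ndarray):
    """Row-wise z-score using training statistics only (constant rows kept as-is)."""
    mu = train.mean(axis=1, keepdims=True)
    sd = train.std(axis=1, keepdims=True)
    sd = np.where(sd > 0, sd, 1.0)
    return (train - mu) / sd, (test - mu) / sd


def fit_predict(
    method: str,
    train_P: np.ndarray,
    train_labels: np.ndarray,
    test_P: np.ndarray,
    seed: int = 0,
    *,
    S1: int = 10,
    max_epochs: int = 2000,
    tol: float = 1e-6,
) -> np.ndarray:
    """Train one classifier and predict a class label per test column.

    Deterministic given (method, data, seed).  Raises on a single-class
    training set.
    """
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}, got {method!r}")
    train_labels = np.asarray(train_labels)
    if len(np.unique(train_labels)) < 2:
        raise ValueError("training set contains a single class")
    Xtr, Xte = _standardize(np.asarray(train_P, float), np.asarray(test_P, float))

    if method == "svm":
        clf = SVC(C=1.0, kernel="rbf", gamma="scale")
        clf.fit(Xtr.T, train_labels)
        return clf.predict(Xte.T)
    if method == "bayes":
        clf = GaussianNB(priors=[0.5, 0.5])
        clf.fit(Xtr.T, train_labels)
        return clf.predict(Xte.T)
    T = np.vstack([(train_labels == "L").astype(float), (train_labels == "R").astype(float)])
    net = train_nn(Xtr, T, S1=S1, seed=seed, max_epochs=max_epochs, tol=tol)
    return net.predict(Xte)


@dataclasses.dataclass
class ClassificationReport:
    """Confusion counts and derived metrics for one method on one recording.

    Class "L" is positive.  ``CV`` is the leave-one-out misclassification
    rate (1 − AC when every segment is held out exactly once).
    """

    method: str
    TP: int
    TN: int
    FP: int
    FN: int
    seed: int = 0
    individual_id: str = ""
    exercise_id: str = ""

    @property
    def n(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    @property
    def TPR(self) -> float:
        return self.TP / (self.TP + self.FN) if self.TP + self.FN else float("nan")

    @property
    def TNR(self) -> float:
        return self.TN / (self.TN + self.FP) if self.TN + self.FP else float("nan")

    @property
    def AC(self) -> float:
        return (self.TP + self.TN) / self.n

    @property
    def CV(self) -> float:
        return (self.FP + self.FN) / self.n

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "individual_id": self.individual_id,
            "exercise_id": self.exercise_id,
            "TP": self.TP,
            "TN": self.TN,
            "FP": self.FP,
            "FN": self.FN,
            "TPR": self.TPR,
            "TNR": self.TNR,
            "AC": self.AC,
            "CV": self.CV,
            "seed": self.seed,
        }

    def summary(self) -> str:
        return (
            f"{self.method}: AC {100 * self.AC:.1f} %  CV {self.CV:.2f}  "
            f"TPR {self.TPR:.3f}  TNR {self.TNR:.3f}  "
            f"(TP={self.TP} TN={self.TN} FP={self.FP} FN={self.FN})"
        )


def loocv(
    method: str,
    fs: FeatureSet,
    seed: int = 0,
    *,
    S1: int = 10,
    max_epochs: int = 2000,
    tol: float = 1e-6,
) -> ClassificationReport:
    """Leave-one-out cross-validation over the Q feature columns.

    Fold i trains on the other Q−1 columns and predicts column i; confusion
    counts accumulate over folds with "L" positive.  A fold whose training
    set degenerates to one class falls back to predicting the training
    majority class, with a warning.
    """
    labels = fs.labels
    Q = fs.Q
    if Q < 4:
        raise ValueError(f"need at least 4 segments for LOOCV, got {Q}")
    preds = np.empty(Q, dtype=labels.dtype)
    for i in range(Q):
        mask = np.ones(Q, dtype=bool)
        mask[i] = False
        tr_labels = labels[mask]
        uniq, counts = np.unique(tr_labels, return_counts=True)
        if len(uniq) < 2:
            warnings.warn(f"fold {i}: single-class training set, predicting prior class")
            preds[i] = uniq[np.argmax(counts)]
            continue
        preds[i] = fit_predict(
            method,
            fs.P[:, mask],
            tr_labels,
            fs.P[:, [i]],
            seed=seed,
            S1=S1,
            max_epochs=max_epochs,
            tol=tol,
        )[0]
    TP = int(np.sum((labels == "L") & (preds == "L")))
    FN = int(np.sum((labels == "L") & (preds == "R")))
    TN = int(np.sum((labels == "R") & (preds == "R")))
    FP = int(np.sum((labels == "R") & (preds == "L")))
    return ClassificationReport(method=method, TP=TP, TN=TN, FP=FP, FN=FN, seed=seed)
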