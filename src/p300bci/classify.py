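"""Target/non-target LDA and summed-score button selection.

A two-class linear discriminant is trained on flattened averaged epochs
(channels x samples features). Because the feature dimension (700 for
7 channels x 100 samples) far exceeds the number of averaged training
exemplars, the pooled within-class covariance is shrunk toward a scaled
identity with an analytic Ledoit-Wolf intensity before inversion. At
decision time every epoch of a selection is scored with the discriminant,
scores are summed per button, and the button with the largest sum wins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg
from sklearn.covariance import ledoit_wolf

from .preprocess import EpochSet

__all__ = [
    "ClassifierModel",
    "SelectionResult",
    "train_lda",
    "score_epochs",
    "decide_selection",
    "evaluate_accuracy",
]


@dataclass(frozen=True)
class ClassifierModel:
    """Linear discriminant over the flattened feature space.

    ``weights . x + bias`` is oriented so larger values mean more
    target-like. ``regularization`` records how the covariance was
    conditioned (shrinkage intensity or pseudo-inverse).
    """

    weights: np.ndarray
    bias: float
    feature_shape: tuple[int, int]
    regularization: str

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        if w.ndim != 1 or len(w) != int(np.prod(self.feature_shape)):
            raise ValueError("weights length must equal prod(feature_shape)")
        if not np.all(np.isfinite(w)) or not np.isfinite(self.bias):
            raise ValueError("model parameters must be finite")


@dataclass
class SelectionResult:
    """Outcome of one selection: per-button summed scores and the decision."""

    scores: np.ndarray
    predicted_button: int
    n_epochs_used: np.ndarray
    true_button: int | None = None
    selection_id: int = 0
    environment: str = "NA"

    @property
    def correct(self) -> bool | None:
        if self.true_button is None:
            return None
        return self.predicted_button == self.true_button


def _flatten(features: EpochSet) -> np.ndarray:
    return features.epochs.reshape(len(features), -1)


def train_lda(features: EpochSet, *, regularization: str = "ledoit-wolf") -> ClassifierModel:
    """Fit the two-class discriminant w = S^-1 (mu_target - mu_nontarget).

    ``regularization`` is either "ledoit-wolf" (default: pooled covariance
    shrunk toward (tr S / p) I with the analytic Ledoit-Wolf intensity) or
    "pseudo-inverse" (Moore-Penrose inverse of the raw pooled covariance).
    Training data with no within-class scatter at all (e.g. noise-free
    simulations) degrade to the matched filter w = mu_target - mu_nontarget,
    the limit of the shrunk solution as the scatter vanishes.
    """
    y = features.is_target
    if not (y.any() and (~y).any()):
        raise ValueError("training data must contain both target and non-target epochs")
    X = _flatten(features)
    n, p = X.shape
    mu0 = X[~y].mean(axis=0)
    mu1 = X[y].mean(axis=0)
    delta = mu1 - mu0
    Xc = X.copy()
    Xc[~y] -= mu0
    Xc[y] -= mu1

    trace_per_dim = float(np.einsum("ij,ij->", Xc, Xc)) / max(n - 2, 1) / p
    if trace_per_dim <= 0 or not np.isfinite(trace_per_dim):
        # Degenerate: no within-class variability; matched filter.
        w = delta.copy()
        descriptor = f"{regularization} (degenerate: zero scatter, identity covariance)"
    elif regularization == "ledoit-wolf":
        cov, intensity = ledoit_wolf(Xc, assume_centered=True)
        try:
            w = linalg.solve(cov, delta, assume_a="pos")
        except linalg.LinAlgError:
            w = np.linalg.pinv(cov) @ delta
        descriptor = f"ledoit-wolf(shrinkage={intensity:.4f})"
    elif regularization == "pseudo-inverse":
        cov = Xc.T @ Xc / max(n - 2, 1)
        w = np.linalg.pinv(cov, hermitian=True) @ delta
        descriptor = "pseudo-inverse"
    else:
        raise ValueError(f"unknown regularization {regularization!r}")

    bias = -0.5 * float(w @ (mu0 + mu1))
    return ClassifierModel(
        weights=w,
        bias=bias,
        feature_shape=(features.epochs.shape[1], features.epochs.shape[2]),
        regularization=descriptor,
    )


def score_epochs(model: ClassifierModel, features: EpochSet) -> np.ndarray:
    """Discriminant output per epoch: weights . flattened_epoch + bias."""
    if features.epochs.shape[1:] != model.feature_shape:
        raise ValueError(
            f"epoch shape {features.epochs.shape[1:]} does not match "
            f"model feature shape {model.feature_shape}"
        )
    return _flatten(features) @ model.weights + model.bias


def decide_selection(
    scores: np.ndarray,
    buttons: np.ndarray,
    *,
    n_buttons: int | None = None,
    true_button: int | None = None,
    selection_id: int = 0,
    environment: str = "NA",
) -> SelectionResult:
    """Sum per-epoch scores within each button; highest sum wins.

    Ties go to the lowest button index. Every button must contribute at
    least one scored epoch.
    """
    scores = np.asarray(scores, dtype=float)
    buttons = np.asarray(buttons, dtype=int)
    if scores.shape != buttons.shape:
        raise ValueError("scores and button labels must align")
    nb = int(buttons.max()) + 1 if n_buttons is None else n_buttons
    sums = np.zeros(nb)
    counts = np.zeros(nb, dtype=int)
    np.add.at(sums, buttons, scores)
    np.add.at(counts, buttons, 1)
    missing = np.flatnonzero(counts == 0)
    if missing.size:
        raise ValueError(f"no scored epochs for button(s) {missing.tolist()}")
    predicted = int(np.argmax(sums))  # argmax returns the first (lowest) index on ties
    return SelectionResult(
        scores=sums,
        predicted_button=predicted,
        n_epochs_used=counts,
        true_button=true_button,
        selection_id=selection_id,
        environment=environment,
    )


def evaluate_accuracy(results: list[SelectionResult]) -> float:
    """Percentage of selections decoded correctly, to 2 decimals."""
    if not results:
        raise ValueError("no selection results to evaluate")
    if any(r.true_button is None for r in results):
        raise ValueError("every result needs a true_button")
    n_correct = sum(bool(r.correct) for r in results)
    return round(100.0 * n_correct / len(results), 2)
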