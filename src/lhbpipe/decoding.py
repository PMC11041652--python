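"""Per-neuron decoding of trial-wise eyeblink from cue-evoked activity.

Each neuron's scalar cue-window AUC is used to predict whether the trial's
conditioned response fell below the session's 40th percentile or above its
60th percentile (the middle band is excluded, giving disjoint blink
classes).  Decoding uses an RBF-kernel support-vector classifier with a
small hyperparameter grid chosen by stratified inner cross-validation on
each training split; accuracy is the mean held-out score over repeated
stratified random splits.  Chance level is estimated by re-running the
identical procedure after a single random permutation of the labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.svm import SVC

from .core import InsufficientDataError

HIGH_BLINK = "high_blink"   # CR below the low percentile: eye more closed
LOW_BLINK = "low_blink"     # CR above the high percentile
EXCLUDED = "excluded"


@dataclass(frozen=True)
class DecoderConfig:
    low_pct: float = 40.0
    high_pct: float = 60.0
    n_repeats: int = 100
    test_fraction: float = 0.2
    c_grid: tuple = (0.1, 1.0, 10.0, 100.0)
    gamma_grid: tuple = ("scale", 0.01, 0.1, 1.0)
    inner_cv: int = 1  # 1 = single stratified holdout; k > 1 = k-fold
    min_trials_per_class: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.low_pct < self.high_pct < 100:
            raise ValueError("need 0 < low_pct < high_pct < 100")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


@dataclass
class DecodingResult:
    neuron_id: str
    accuracy: float
    shuffle_accuracy: float | None
    n_trials_used: int
    labels_dropped: int


@dataclass
class SignificanceReport:
    t_statistic: float
    df: int
    p_value: float
    mean_accuracy: float
    mean_shuffle: float


def make_blink_labels(
    cr_per_trial: np.ndarray, cfg: DecoderConfig | None = None
) -> np.ndarray:
    """Label trials by session-wise CR percentiles (linear interpolation):
    CR below the 40th percentile -> ``high_blink``, above the 60th ->
    ``low_blink``, the band in between -> ``excluded``."""
    cfg = cfg or DecoderConfig()
    cr = np.asarray(cr_per_trial, dtype=float)
    if cr.size < 10:
        raise InsufficientDataError("labeling needs at least 10 trials")
    lo, hi = np.percentile(cr, [cfg.low_pct, cfg.high_pct])
    labels = np.full(cr.size, EXCLUDED, dtype=object)
    labels[cr < lo] = HIGH_BLINK
    labels[cr > hi] = LOW_BLINK
    if not ((labels == HIGH_BLINK).any() and (labels == LOW_BLINK).any()):
        raise InsufficientDataError(
            "a blink class is empty after percentile banding"
        )
    return labels


def _stratified_split(
    rng: np.random.Generator, y: np.ndarray, test_fraction: float
) -> tuple[np.ndarray, np.ndarray]:
    train, test = [], []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        n_test = max(1, int(round(test_fraction * idx.size)))
        n_test = min(n_test, idx.size - 1)
        test.append(idx[:n_test])
        train.append(idx[n_test:])
    return np.concatenate(train), np.concatenate(test)


def _stratified_folds(
    rng: np.random.Generator, y: np.ndarray, k: int
) -> list[np.ndarray]:
    folds: list[list[int]] = [[] for _ in range(k)]
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        for j, i in enumerate(idx):
            folds[j % k].append(i)
    return [np.asarray(f) for f in folds]


def _fit_score(x_tr, y_tr, x_te, y_te, c, gamma) -> float:
    mu, sd = x_tr.mean(), x_tr.std() or 1.0
    clf = SVC(C=c, gamma=gamma, kernel="rbf")
    clf.fit((x_tr[:, None] - mu) / sd, y_tr)
    return float(np.mean(clf.predict((x_te[:, None] - mu) / sd) == y_te))


def decode_single_neuron(
    auc_per_trial: np.ndarray,
    labels: np.ndarray,
    cfg: DecoderConfig | None = None,
    neuron_id: str = "",
    rng: np.random.Generator | None = None,
) -> DecodingResult:
    """Mean held-out accuracy over repeated stratified random splits.

    On each split, the (C, gamma) pair is chosen on the training trials only
    (AUC standardized on the training statistics): by a single stratified
    holdout when ``inner_cv == 1`` (default), or by stratified ``inner_cv``-
    fold cross-validation.  The winner is refit on the full training split
    and scored on the held-out test split.
    """
    cfg = cfg or DecoderConfig()
    rng = rng or np.random.default_rng(cfg.seed)
    labels = np.asarray(labels, dtype=object)
    auc = np.asarray(auc_per_trial, dtype=float)
    keep = labels != EXCLUDED
    x, y = auc[keep], (labels[keep] == HIGH_BLINK).astype(int)
    n_per_class = np.bincount(y, minlength=2)
    if n_per_class.min() < cfg.min_trials_per_class:
        raise InsufficientDataError(
            f"{neuron_id or 'neuron'}: class sizes {n_per_class.tolist()} "
            f"too small for stratified splitting"
        )
    scores = np.empty(cfg.n_repeats)
    for rep in range(cfg.n_repeats):
        tr, te = _stratified_split(rng, y, cfg.test_fraction)
        x_tr, y_tr = x[tr], y[tr]
        if cfg.inner_cv <= 1:
            fit_idx, val_idx = _stratified_split(rng, y_tr, 1.0 / 3.0)
            splits = [(fit_idx, val_idx)]
        else:
            folds = _stratified_folds(rng, y_tr, cfg.inner_cv)
            splits = [
                (
                    np.concatenate(
                        [folds[j] for j in range(cfg.inner_cv) if j != f]
                    ),
                    folds[f],
                )
                for f in range(cfg.inner_cv)
            ]
        best, best_score = None, -1.0
        for c in cfg.c_grid:
            for gamma in cfg.gamma_grid:
                accs = [
                    _fit_score(x_tr[fit], y_tr[fit], x_tr[val], y_tr[val],
                               c, gamma)
                    for fit, val in splits
                    if np.unique(y_tr[fit]).size == 2 and val.size
                ]
                mean_acc = float(np.mean(accs)) if accs else -1.0
                if mean_acc > best_score:
                    best, best_score = (c, gamma), mean_acc
        scores[rep] = _fit_score(x_tr, y_tr, x[te], y[te], *best)
    return DecodingResult(
        neuron_id=neuron_id,
        accuracy=float(scores.mean()),
        shuffle_accuracy=None,
        n_trials_used=int(keep.sum()),
        labels_dropped=int((~keep).sum()),
    )


def shuffle_null(
    auc_per_trial: np.ndarray,
    labels: np.ndarray,
    cfg: DecoderConfig | None = None,
    neuron_id: str = "",
    rng: np.random.Generator | None = None,
    permutation: np.ndarray | None = None,
) -> float:
    """Accuracy of the identical decoding procedure after permuting the
    trial labels once (uniformly at random unless ``permutation`` is given)."""
    cfg = cfg or DecoderConfig()
    rng = rng or np.random.default_rng([cfg.seed, 1])
    labels = np.asarray(labels, dtype=object)
    if permutation is None:
        permutation = rng.permutation(labels.size)
    res = decode_single_neuron(
        auc_per_trial, labels[permutation], cfg, neuron_id=neuron_id, rng=rng
    )
    return res.accuracy


def decode_neuron(
    auc_per_trial: np.ndarray,
    cr_per_trial: np.ndarray,
    cfg: DecoderConfig | None = None,
    neuron_id: str = "",
) -> DecodingResult:
    """Label the session, decode, and attach the shuffle-null accuracy."""
    cfg = cfg or DecoderConfig()
    labels = make_blink_labels(cr_per_trial, cfg)
    res = decode_single_neuron(
        auc_per_trial, labels, cfg, neuron_id=neuron_id,
        rng=np.random.default_rng([cfg.seed, 0]),
    )
    res.shuffle_accuracy = shuffle_null(
        auc_per_trial, labels, cfg, neuron_id=neuron_id,
        rng=np.random.default_rng([cfg.seed, 1]),
    )
    return res


def decoding_significance(results: list[DecodingResult]) -> SignificanceReport:
    """Unpaired t-test of decoder accuracy versus shuffle accuracy across
    neurons."""
    if len(results) < 2:
        raise InsufficientDataError("need at least 2 neurons")
    acc = np.array([r.accuracy for r in results])
    shuf = np.array([r.shuffle_accuracy for r in results], dtype=float)
    if np.isnan(shuf).any():
        raise ValueError("every result needs a shuffle accuracy")
    if np.ptp(acc) == 0 and np.ptp(shuf) == 0:
        raise ValueError("degenerate test: zero variance in both groups")
    t, p = stats.ttest_ind(acc, shuf)
    return SignificanceReport(
        t_statistic=float(t),
        df=2 * len(results) - 2,
        p_value=float(p),
        mean_accuracy=float(acc.mean()),
        mean_shuffle=float(shuf.mean()),
    )
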