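"""Spatial SSVEP decoding: per-class CCA filter banks + multi-class LDA.

For each gaze target c the training trials are concatenated in time and
canonical correlation analysis between the multichannel EEG X and a
6-dimensional harmonic reference

    Y = [sin(2*pi*f t), cos(2*pi*f t), sin(4*pi*f t), cos(4*pi*f t),
         sin(6*pi*f t), cos(6*pi*f t)]

yields paired spatial filters A_c (EEG side) and B_c (reference side) that
maximise the correlations r_c = [rho_1 ... rho_M] of the projected signals.
A single trial is then described by the canonical correlations it attains
under *all four* filter pairs, concatenated to [r_1 r_2 r_3 r_4]; a linear
discriminant classifier on these features predicts the fixated target.
Reference phase is locked to stimulus onset via the epoch's ``t0``, so
training concatenation and single-trial feature extraction see identical
reference phase.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import linalg

from .epochs import CLASSES, EpochSet

__all__ = [
    "ReferenceSignal",
    "build_reference",
    "fit_cca",
    "FilterBank",
    "train_filter_bank",
    "extract_features",
    "LdaModel",
    "train_lda",
    "SsvepDecoder",
    "train_decoder",
    "crossval_accuracy",
]


@dataclass(frozen=True)
class ReferenceSignal:
    """Harmonic sine/cosine reference matrix, rows [sin f, cos f, sin 2f, ...]."""

    f_stim: float
    fs: float
    n_samples: int
    t0: float
    n_harmonics: int
    Y: np.ndarray = field(repr=False)  # (2*n_harmonics, n_samples)


def build_reference(
    f_stim: float, fs: float, n_samples: int, t0: float = 0.0, n_harmonics: int = 3
) -> ReferenceSignal:
    """Reference evaluated at t = t0 + i/fs (phase-locked to stimulus onset)."""
    if f_stim * n_harmonics >= fs / 2:
        raise ValueError(
            f"harmonic {n_harmonics}*{f_stim} Hz is at/above Nyquist ({fs / 2} Hz)"
        )
    t = t0 + np.arange(n_samples) / fs
    rows = []
    for h in range(1, n_harmonics + 1):
        w = 2 * np.pi * h * f_stim * t
        rows.append(np.sin(w))
        rows.append(np.cos(w))
    return ReferenceSignal(f_stim, fs, n_samples, t0, n_harmonics, np.array(rows))


def fit_cca(
    X: np.ndarray, Y: np.ndarray, ridge: float = 0.0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Canonical correlation analysis between row-variable matrices.

    Solves for weight rows a_k, b_k maximising corr(a_k X, b_k Y) with each
    component pair uncorrelated with the earlier ones, via Cholesky whitening
    of the covariance blocks and an SVD of the whitened cross-covariance.
    Rank-deficient covariances fall back to a ridge-regularised solve (with a
    warning). Sign convention: in each EEG-side weight vector the
    largest-magnitude element is positive (the reference-side vector is
    flipped along with it, so correlations are unchanged).

    Returns ``(A, B, rho)`` with A: (k, n_x), B: (k, n_y), rho descending
    in [0, 1], k = min(n_x, n_y).
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape[1] != Y.shape[1]:
        raise ValueError("X and Y must have the same number of time samples")
    T = X.shape[1]
    if T < X.shape[0] + Y.shape[0]:
        raise ValueError("need at least n_x + n_y time samples")
    Xc = X - X.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    Cxx = Xc @ Xc.T / (T - 1)
    Cyy = Yc @ Yc.T / (T - 1)
    Cxy = Xc @ Yc.T / (T - 1)

    Lx = _chol_with_ridge(Cxx, ridge, "X")
    Ly = _chol_with_ridge(Cyy, ridge, "Y")
    # K = Lx^-1 Cxy Ly^-T
    K = linalg.solve_triangular(Lx, Cxy, lower=True)
    K = linalg.solve_triangular(Ly, K.T, lower=True).T
    U, s, Vt = np.linalg.svd(K, full_matrices=False)
    A = linalg.solve_triangular(Lx, U, lower=True, trans="T").T
    B = linalg.solve_triangular(Ly, Vt.T, lower=True, trans="T").T
    rho = np.clip(s, 0.0, 1.0)

    for k in range(A.shape[0]):
        if A[k, np.argmax(np.abs(A[k]))] < 0:
            A[k] *= -1
            B[k] *= -1
    return A, B, rho


def _chol_with_ridge(C: np.ndarray, ridge: float, which: str) -> np.ndarray:
    scale = np.mean(np.diag(C)) or 1.0
    eps = ridge
    for _ in range(12):
        try:
            return linalg.cholesky(C + eps * scale * np.eye(C.shape[0]), lower=True)
        except linalg.LinAlgError:
            if eps == 0.0:
                warnings.warn(
                    f"{which}-side covariance is rank deficient; "
                    "applying ridge regularisation",
                    RuntimeWarning,
                    stacklevel=3,
                )
                eps = 1e-10
            else:
                eps *= 10.0
    raise linalg.LinAlgError("covariance could not be regularised")


@dataclass
class FilterBank:
    """Per-class CCA spatial filters plus the reference geometry they assume."""

    classes: tuple[str, ...]
    A: np.ndarray = field(repr=False)  # (n_classes, n_comp, n_channels)
    B: np.ndarray = field(repr=False)  # (n_classes, n_comp, 2*n_harmonics)
    rho: np.ndarray = field(repr=False)  # (n_classes, n_comp) training correlations
    f_stim: float = 15.0
    fs: float = 512.0
    n_samples: int = 1792
    t0: float = 0.5
    n_harmonics: int = 3
    feature_mode: str = "all"  # 'all': every component; 'first': rho_1 only

    def __post_init__(self) -> None:
        if self.feature_mode not in ("all", "first"):
            raise ValueError("feature_mode must be 'all' or 'first'")

    @property
    def n_components(self) -> int:
        return 1 if self.feature_mode == "first" else self.A.shape[1]

    @property
    def n_features(self) -> int:
        return len(self.classes) * self.n_components

    def reference(self) -> ReferenceSignal:
        return build_reference(
            self.f_stim, self.fs, self.n_samples, self.t0, self.n_harmonics
        )


def train_filter_bank(
    train: EpochSet,
    f_stim: float = 15.0,
    n_harmonics: int = 3,
    feature_mode: str = "all",
) -> FilterBank:
    """Fit one (A_c, B_c) pair per class on that class's concatenated trials.

    Each trial is concatenated with its own onset-locked reference copy in
    register, so covariances are sums over trials and the fit is invariant
    to trial order.
    """
    ref = build_reference(f_stim, train.fs, train.n_samples, train.t0, n_harmonics)
    A_list, B_list, r_list = [], [], []
    for c in CLASSES:
        trials = train.class_trials(c)
        if trials.shape[0] < 2:
            raise ValueError(f"class {c!r} has {trials.shape[0]} trials; need >= 2")
        X = np.concatenate(list(trials), axis=1)
        Yc = np.tile(ref.Y, (1, trials.shape[0]))
        A, B, rho = fit_cca(X, Yc)
        A_list.append(A)
        B_list.append(B)
        r_list.append(rho)
    return FilterBank(
        classes=CLASSES,
        A=np.stack(A_list),
        B=np.stack(B_list),
        rho=np.stack(r_list),
        f_stim=f_stim,
        fs=train.fs,
        n_samples=train.n_samples,
        t0=train.t0,
        n_harmonics=n_harmonics,
        feature_mode=feature_mode,
    )


def extract_features(trial: np.ndarray, bank: FilterBank) -> np.ndarray:
    """Canonical-correlation feature vector [r_1 r_2 r_3 r_4] for one trial.

    Entry (c, k) is the Pearson correlation between the trial projected by
    A_c row k and the reference projected by B_c row k. Correlations are
    rectified to their absolute value (the CCA weight sign is arbitrary) and
    clipped to [0, 1]; zero-variance projections map to 0.
    """
    trial = np.asarray(trial, dtype=float)
    if trial.shape[1] != bank.n_samples:
        raise ValueError(
            f"trial has {trial.shape[1]} samples; filter bank expects {bank.n_samples}"
        )
    ref = bank.reference()
    n_comp = bank.n_components
    feats = np.zeros(len(bank.classes) * n_comp)
    for ci in range(len(bank.classes)):
        U = bank.A[ci, :n_comp] @ trial  # (n_comp, n_samples)
        V = bank.B[ci, :n_comp] @ ref.Y
        U = U - U.mean(axis=1, keepdims=True)
        V = V - V.mean(axis=1, keepdims=True)
        num = (U * V).sum(axis=1)
        den = np.sqrt((U**2).sum(axis=1) * (V**2).sum(axis=1))
        r = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
        feats[ci * n_comp : (ci + 1) * n_comp] = np.clip(np.abs(r), 0.0, 1.0)
    return feats


@dataclass
class LdaModel:
    """Multi-class LDA with pooled, shrinkage-regularised covariance.

    The pooled within-class covariance S is shrunk towards a scaled identity,
    (1-gamma) S + gamma (tr S / d) I, so gamma = 1 yields a nearest-class-mean
    rule under equal priors. Prediction ties break to the lowest class index.
    """

    classes: tuple[str, ...]
    means: np.ndarray = field(repr=False)  # (n_classes, d)
    covariance: np.ndarray = field(repr=False)  # (d, d) after shrinkage
    priors: np.ndarray = field(repr=False)
    gamma: float = 1e-6
    coef_: np.ndarray = field(init=False, repr=False)
    intercept_: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not np.isclose(self.priors.sum(), 1.0):
            raise ValueError("priors must sum to 1")
        try:
            self.coef_ = np.linalg.solve(self.covariance, self.means.T).T
        except np.linalg.LinAlgError:
            # degenerate features (e.g. zero within-class scatter): fall back
            # to an identity metric so prediction reduces to prior/mean argmax
            d = self.covariance.shape[0]
            floor = np.trace(self.covariance) / d or 1.0
            self.coef_ = np.linalg.solve(
                self.covariance + 1e-9 * floor * np.eye(d), self.means.T
            ).T
        self.intercept_ = -0.5 * np.einsum(
            "cd,cd->c", self.means, self.coef_
        ) + np.log(self.priors)

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return X @ self.coef_.T + self.intercept_

    def predict(self, X: np.ndarray) -> np.ndarray:
        scores = self.decision_function(X)
        idx = np.argmax(scores, axis=1)  # ties -> lowest class index
        return np.array([self.classes[i] for i in idx], dtype=object)


def train_lda(
    features: np.ndarray,
    labels,
    gamma: float = 1e-6,
    priors: np.ndarray | None = None,
    classes: tuple[str, ...] | None = None,
) -> LdaModel:
    """Fit class means and pooled unbiased covariance with shrinkage gamma."""
    X = np.asarray(features, dtype=float)
    labels = np.asarray(labels, dtype=object)
    if classes is None:
        if set(labels) <= set(CLASSES):
            classes = tuple(c for c in CLASSES if c in labels)
        else:
            classes = tuple(np.unique(labels.astype(str)))
    missing = [c for c in classes if c not in labels]
    if missing:
        raise ValueError(f"classes absent from labels: {missing}")
    if len(classes) < 2:
        raise ValueError("need at least two classes")

    n, d = X.shape
    means = np.stack([X[labels == c].mean(axis=0) for c in classes])
    scatter = np.zeros((d, d))
    for ci, c in enumerate(classes):
        R = X[labels == c] - means[ci]
        scatter += R.T @ R
    dof = max(n - len(classes), 1)
    S = scatter / dof
    S = (1.0 - gamma) * S + gamma * (np.trace(S) / d) * np.eye(d)
    if priors is None:
        priors = np.array([(labels == c).mean() for c in classes])
    return LdaModel(classes=classes, means=means, covariance=S, priors=priors, gamma=gamma)


@dataclass
class SsvepDecoder:
    """Trained filter bank + LDA; maps a preprocessed trial to a gaze target."""

    bank: FilterBank
    lda: LdaModel

    def predict(self, trial: np.ndarray) -> str:
        return str(self.lda.predict(extract_features(trial, self.bank)[None, :])[0])

    def predict_set(self, e: EpochSet) -> np.ndarray:
        feats = np.stack([extract_features(tr, self.bank) for tr in e.data])
        return self.lda.predict(feats)

    def accuracy(self, e: EpochSet) -> float:
        return float(np.mean(self.predict_set(e) == e.labels))

    # -------------------------------------------------------- serialization
    FORMAT_VERSION = 1

    def save(self, path: str | Path) -> Path:
        path = Path(path).with_suffix(".npz")
        meta = {
            "format_version": self.FORMAT_VERSION,
            "classes": list(self.bank.classes),
            "f_stim": self.bank.f_stim,
            "fs": self.bank.fs,
            "n_samples": self.bank.n_samples,
            "t0": self.bank.t0,
            "n_harmonics": self.bank.n_harmonics,
            "feature_mode": self.bank.feature_mode,
            "gamma": self.lda.gamma,
        }
        np.savez(
            path,
            meta=np.array(json.dumps(meta)),
            A=self.bank.A,
            B=self.bank.B,
            rho=self.bank.rho,
            lda_means=self.lda.means,
            lda_cov=self.lda.covariance,
            lda_priors=self.lda.priors,
        )
        return path

    @classmethod
    def load(cls, path: str | Path) -> "SsvepDecoder":
        with np.load(Path(path), allow_pickle=False) as z:
            meta = json.loads(str(z["meta"]))
            if meta["format_version"] != cls.FORMAT_VERSION:
                raise ValueError(f"unsupported model format: {meta['format_version']}")
            bank = FilterBank(
                classes=tuple(meta["classes"]),
                A=z["A"],
                B=z["B"],
                rho=z["rho"],
                f_stim=meta["f_stim"],
                fs=meta["fs"],
                n_samples=meta["n_samples"],
                t0=meta["t0"],
                n_harmonics=meta["n_harmonics"],
                feature_mode=meta["feature_mode"],
            )
            lda = LdaModel(
                classes=tuple(meta["classes"]),
                means=z["lda_means"],
                covariance=z["lda_cov"],
                priors=z["lda_priors"],
                gamma=meta["gamma"],
            )
        return cls(bank=bank, lda=lda)


def train_decoder(
    train: EpochSet,
    f_stim: float = 15.0,
    n_harmonics: int = 3,
    feature_mode: str = "all",
    gamma: float = 1e-6,
) -> SsvepDecoder:
    """Fit the full pipeline (filter bank, features, LDA) on labelled trials."""
    bank = train_filter_bank(train, f_stim, n_harmonics, feature_mode)
    feats = np.stack([extract_features(tr, bank) for tr in train.data])
    lda = train_lda(feats, train.labels, gamma=gamma, classes=CLASSES)
    return SsvepDecoder(bank=bank, lda=lda)


def crossval_accuracy(
    epochs: EpochSet,
    k_folds: int = 10,
    seed: int = 0,
    **train_kwargs,
) -> float:
    """Stratified k-fold accuracy; filters and classifier are re-fit inside
    every training fold so no information leaks from the held-out trials."""
    from sklearn.model_selection import StratifiedKFold

    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    y = epochs.labels.astype(str)
    correct = 0
    for tr_idx, te_idx in skf.split(np.zeros(epochs.n_trials), y):
        dec = train_decoder(epochs.select(tr_idx), **train_kwargs)
        test = epochs.select(te_idx)
        correct += int(np.sum(dec.predict_set(test) == test.labels))
    return correct / epochs.n_trials
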