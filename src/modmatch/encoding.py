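"""Prediction-based model evaluation.

Voxel responses are modeled as a weighted sum of time-averaged feature
amplitudes, v_i = sum_k z_{k,i} a_k, fit by ridge regression with nested
cross-validation: 4 outer folds (9 test sounds each for 36 sounds), and
within each 27-sound training set 4 inner folds (7/7/7/6) that select the
regularization parameter from an octave-spaced grid 2^-100 .. 2^100 (201
values) by the noise-corrected NSE of the inner-fold predictions.  Fitting
from each response repetition separately yields two prediction samples per
test fold, which feed the separate-noise NSE correction.

Feature preprocessing (z-scoring across sounds, rescaling the cochlear and
modulation blocks to equal Frobenius norm, the unpenalized bias) is always
estimated on the training sounds only.

The same machinery supports cross-predictions (weights learned on one
stimulus set, evaluated on the other) and learning linear reconstruction
weights that map voxel responses onto canonical component response profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

LAMBDA_GRID = 2.0 ** np.arange(-100, 101)

_FULL_RATES = (0.5, 1.0, 2.0, 4.0, 8.0, 16.0, 32.0, 64.0, 128.0)
_FULL_SCALES = (0.25, 0.5, 1.0, 2.0, 4.0, 8.0)


# ----------------------------------------------------------------------
# feature enumeration for regression
def regression_feature_table(
    model_kind: str,
    n_channels: int = 217,
    rates: tuple = _FULL_RATES,
    scales: tuple = _FULL_SCALES,
) -> pd.DataFrame:
    """Enumerate the regression predictors for a model kind.

    The cochlear channels are always included.  The temporal model drops its
    DC filter (zero variance across time) and the very low rates; the
    spectral model keeps its DC "scale"; the spectrotemporal model crosses
    every rate with every scale *including* the spectral DC, in both
    orientations, and does not include the 1-D temporal-only/spectral-only
    features.
    """
    rows = [
        {"feature_kind": "cochlear", "rate": np.nan, "scale": np.nan,
         "orientation": "none", "channel": ch}
        for ch in range(n_channels)
    ]
    if model_kind == "cochlear":
        pass
    elif model_kind == "temporal":
        for r in rates:
            for ch in range(n_channels):
                rows.append({"feature_kind": "modulation", "rate": r, "scale": np.nan,
                             "orientation": "none", "channel": ch})
    elif model_kind == "spectral":
        for s in (0.0,) + tuple(scales):  # 0.0 denotes the spectral DC
            for ch in range(n_channels):
                rows.append({"feature_kind": "modulation", "rate": np.nan, "scale": s,
                             "orientation": "none", "channel": ch})
    elif model_kind == "spectrotemporal":
        for r in rates:
            for s in (0.0,) + tuple(scales):
                for orientation in ("up", "down"):
                    for ch in range(n_channels):
                        rows.append({"feature_kind": "modulation", "rate": r, "scale": s,
                                     "orientation": orientation, "channel": ch})
    else:
        raise ValueError(f"unknown model_kind {model_kind!r}")
    return pd.DataFrame(rows)


def design_matrix_n_features(model_kind: str, n_channels: int = 217) -> int:
    """Number of regression predictors (excluding the bias column)."""
    counts = {
        "cochlear": n_channels,
        "temporal": len(_FULL_RATES) * n_channels + n_channels,
        "spectral": (len(_FULL_SCALES) + 1) * n_channels + n_channels,
        "spectrotemporal": len(_FULL_RATES) * (len(_FULL_SCALES) + 1) * 2 * n_channels
        + n_channels,
    }
    if model_kind not in counts:
        raise ValueError(f"unknown model_kind {model_kind!r}")
    return counts[model_kind]


@dataclass
class DesignMatrix:
    """Sounds x features matrix plus the group labels used for rescaling.

    ``features`` holds the raw (unstandardized) amplitudes; standardization
    is deferred to fit time so it can be estimated on training folds only.
    ``standardized()`` returns the globally z-scored, group-rescaled,
    bias-augmented matrix for inspection.
    """

    features: np.ndarray
    groups: np.ndarray  # "cochlear" / "modulation" per column
    feature_table: pd.DataFrame
    model_kind: str

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def standardized(self) -> np.ndarray:
        Z, _ = _standardize(self.features, self.groups, np.arange(self.features.shape[0]))
        return np.hstack([Z, np.ones((Z.shape[0], 1))])


def build_design_matrix(stats_per_sound, model_kind: str) -> DesignMatrix:
    """Assemble the regression design from per-sound feature statistics.

    Applies the model-kind exclusions: the temporal model's DC filter and
    (for the spectrotemporal kind) the 1-D temporal-only/spectral-only
    features are not used as predictors.  Zero-variance columns other than
    those exclusions are dropped with a warning at fit time.
    """
    tables = [s.index for s in stats_per_sound]
    for t in tables[1:]:
        if not t.equals(tables[0]):
            raise ValueError("feature enumeration differs across sounds")
    table = tables[0].reset_index(drop=True)
    F = np.vstack([s.amplitudes for s in stats_per_sound])
    keep = np.ones(len(table), dtype=bool)
    labels = table["filter_label"].astype(str)
    is_cochlear = (table["feature_kind"] == "cochlear").to_numpy()
    # temporal-DC features are constant over time (zero SD): excluded
    keep &= ~labels.str.startswith("t=dc").to_numpy()
    if model_kind == "spectrotemporal":
        one_dim = labels.str.contains(r"t=all|s=all").to_numpy() & ~is_cochlear
        keep &= ~one_dim
    F = F[:, keep]
    table = table[keep].reset_index(drop=True)
    groups = np.where(is_cochlear[keep], "cochlear", "modulation")
    return DesignMatrix(F, groups, table, model_kind)


# ----------------------------------------------------------------------
# folds
def make_folds(n_items: int, n_folds: int, seed: int = 0) -> list:
    """Deterministic shuffled fold assignment; sizes differ by at most one."""
    if n_folds < 2 or n_folds > n_items:
        raise ValueError("fold count inconsistent with the number of items")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_items)
    return [np.sort(part) for part in np.array_split(order, n_folds)]


# ----------------------------------------------------------------------
# ridge machinery
def _standardize(F, groups, train_idx, warn_dropped=True):
    """Z-score by training statistics; rescale groups to equal norm.

    Returns the transformed full matrix and the surviving column mask.
    """
    mean = F[train_idx].mean(axis=0)
    sd = F[train_idx].std(axis=0)
    keep = sd > 0
    if warn_dropped and not keep.all():
        warnings.warn(f"dropping {np.sum(~keep)} zero-variance feature columns")
    Z = (F[:, keep] - mean[keep]) / sd[keep]
    g = np.asarray(groups)[keep]
    uniq = np.unique(g)
    if uniq.size > 1:
        for name in uniq:
            block = g == name
            norm = np.linalg.norm(Z[np.ix_(train_idx, block)])
            if norm > 0:
                Z[:, block] /= norm
    return Z, keep


def _ridge_predictions(Z, Y_train, train_idx, eval_idx, lambdas):
    """Ridge fit on (Z[train], Y_train) for every lambda.

    Y_train: (n_train, n_targets).  Returns (n_lambdas, n_eval, n_targets).
    The bias is the training mean of each target and is not penalized
    (features are train-centered by construction).
    """
    Xt = Z[train_idx]
    y_mean = Y_train.mean(axis=0)
    Yc = Y_train - y_mean
    U, s, Vt = np.linalg.svd(Xt, full_matrices=False)
    UtY = U.T @ Yc  # (r, n_targets)
    A_eval = Z[eval_idx] @ Vt.T  # (n_eval, r)
    preds = np.empty((len(lambdas), len(eval_idx), Yc.shape[1]))
    for i, lam in enumerate(lambdas):
        d = s / (s**2 + lam)
        preds[i] = A_eval @ (d[:, None] * UtY) + y_mean
    return preds


def _corrected_nse_separate(x1, x2, y1, y2):
    """Vectorized separate-noise corrected NSE; items on the last axis."""
    mu = lambda a: a.mean(axis=-1)
    mu_sx = 0.5 * (mu(x1) + mu(x2))
    mu_sy = 0.5 * (mu(y1) + mu(y2))
    mu_sxsy = 0.25 * (mu(x1 * y1) + mu(x1 * y2) + mu(x2 * y1) + mu(x2 * y2))
    mu_sx2 = 0.5 * (mu(x1**2) + mu(x2**2)) - 0.5 * mu((x1 - x2) ** 2)
    mu_sy2 = 0.5 * (mu(y1**2) + mu(y2**2)) - 0.5 * mu((y1 - y2) ** 2)
    num = mu_sx2 + mu_sy2 - 2 * mu_sxsy
    den = mu_sx2 + mu_sy2 - 2 * mu_sx * mu_sy
    out = np.full(np.shape(num), np.nan)
    ok = den != 0
    out = np.where(ok, num / np.where(ok, den, 1.0), np.nan)
    return out


@dataclass
class EncodingResult:
    predictions: np.ndarray  # (n_sounds, n_voxels, 2) cross-validated
    corrected_nse: np.ndarray  # per voxel, averaged over outer folds
    chosen_lambdas: np.ndarray  # (n_outer_folds, n_voxels)
    outer_folds: list
    inner_fold_sizes: list
    weights: np.ndarray | None = None  # (n_kept_features, n_voxels), full-data refit


def ridge_fit_predict_nested_cv(
    design: DesignMatrix,
    response_reps,
    train_response_reps=None,
    n_outer_folds: int = 4,
    n_inner_folds: int = 4,
    lambdas: np.ndarray = LAMBDA_GRID,
    seed: int = 0,
    refit_full_weights: bool = False,
) -> EncodingResult:
    """Nested-CV ridge evaluation of an encoding model.

    ``response_reps`` is a pair of (n_sounds, n_voxels) arrays (the two
    measurement repetitions used for evaluation).  If ``train_response_reps``
    is given, weights are learned from it instead (cross-prediction); it
    defaults to the evaluation responses (within-set prediction).
    """
    Y = [np.asarray(r, dtype=float) for r in response_reps]
    if len(Y) != 2 or Y[0].shape != Y[1].shape:
        raise ValueError("response_reps must be two equally shaped (sounds x voxels) arrays")
    Yt = Y if train_response_reps is None else [np.asarray(r, float) for r in train_response_reps]
    if Yt[0].shape != Y[0].shape:
        raise ValueError("train and test responses must share the sound and voxel axes")
    n_sounds, n_voxels = Y[0].shape
    if design.features.shape[0] != n_sounds:
        raise ValueError("design matrix and responses disagree on the number of sounds")
    outer = make_folds(n_sounds, n_outer_folds, seed)
    predictions = np.zeros((n_sounds, n_voxels, 2))
    chosen = np.zeros((len(outer), n_voxels))
    fold_nse = np.zeros((len(outer), n_voxels))
    inner_sizes = None
    for fi, test_idx in enumerate(outer):
        train_idx = np.setdiff1d(np.arange(n_sounds), test_idx)
        inner = make_folds(len(train_idx), n_inner_folds, seed + 1)
        inner_sizes = [len(p) for p in inner]
        # --- inner CV: corrected NSE per (lambda, voxel), averaged over folds
        score = np.zeros((len(lambdas), n_voxels))
        for val_local in inner:
            fit_local = np.setdiff1d(np.arange(len(train_idx)), val_local)
            fit_idx = train_idx[fit_local]
            val_idx = train_idx[val_local]
            Z, _ = _standardize(design.features, design.groups, fit_idx, warn_dropped=False)
            Ytrain = np.hstack([Yt[0][fit_idx], Yt[1][fit_idx]])
            preds = _ridge_predictions(Z, Ytrain, fit_idx, val_idx, lambdas)
            p1, p2 = preds[:, :, :n_voxels], preds[:, :, n_voxels:]
            x1 = Y[0][val_idx].T[None]  # (1, n_voxels, n_val)
            x2 = Y[1][val_idx].T[None]
            s = _corrected_nse_separate(
                x1, x2, p1.transpose(0, 2, 1), p2.transpose(0, 2, 1)
            )
            score += np.where(np.isfinite(s), s, 1e6)
        best = np.argmin(score, axis=0)
        chosen[fi] = lambdas[best]
        # --- refit on the full training set at each voxel's lambda
        Z, _ = _standardize(design.features, design.groups, train_idx, warn_dropped=False)
        Ytrain = np.hstack([Yt[0][train_idx], Yt[1][train_idx]])
        for lam_idx in np.unique(best):
            vox = np.where(best == lam_idx)[0]
            cols = np.concatenate([vox, vox + n_voxels])
            preds = _ridge_predictions(
                Z, Ytrain[:, cols], train_idx, test_idx, [lambdas[lam_idx]]
            )[0]
            ti, vi = np.ix_(test_idx, vox)
            predictions[ti, vi, 0] = preds[:, : len(vox)]
            predictions[ti, vi, 1] = preds[:, len(vox):]
        fold_nse[fi] = _corrected_nse_separate(
            Y[0][test_idx].T, Y[1][test_idx].T,
            predictions[test_idx, :, 0].T, predictions[test_idx, :, 1].T,
        )
    weights = None
    if refit_full_weights:
        all_idx = np.arange(n_sounds)
        Z, _ = _standardize(design.features, design.groups, all_idx, warn_dropped=False)
        lam = np.exp(np.mean(np.log(chosen), axis=0))  # per-voxel geometric mean
        weights = np.zeros((Z.shape[1], n_voxels))
        Ymean = 0.5 * (Yt[0] + Yt[1])
        U, s, Vt = np.linalg.svd(Z, full_matrices=False)
        UtY = U.T @ (Ymean - Ymean.mean(axis=0))
        for lam_val in np.unique(lam):
            vox = lam == lam_val
            d = s / (s**2 + lam_val)
            weights[:, vox] = Vt.T @ (d[:, None] * UtY[:, vox])
    return EncodingResult(
        predictions=predictions,
        corrected_nse=fold_nse.mean(axis=0),
        chosen_lambdas=chosen,
        outer_folds=outer,
        inner_fold_sizes=inner_sizes,
        weights=weights,
    )


def cross_predict(
    design: DesignMatrix,
    train_response_reps,
    test_response_reps,
    **kwargs,
) -> EncodingResult:
    """Learn voxel weights on one stimulus set, evaluate on the other."""
    return ridge_fit_predict_nested_cv(
        design, test_response_reps, train_response_reps=train_response_reps, **kwargs
    )


# ----------------------------------------------------------------------
@dataclass
class ComponentWeights:
    """Linear reconstruction weights from voxels to component responses."""

    weights: np.ndarray  # (n_voxels_used, n_components)
    intercepts: np.ndarray
    voxel_mask: np.ndarray
    chosen_lambdas: np.ndarray
    cv_nse: np.ndarray  # raw NSE per component on left-out sounds

    def reconstruct(self, voxel_responses: np.ndarray) -> np.ndarray:
        return voxel_responses[:, self.voxel_mask] @ self.weights + self.intercepts


def learn_reconstruction_weights(
    voxel_responses: np.ndarray,
    target_components: np.ndarray,
    n_folds: int = 5,
    lambdas: np.ndarray = LAMBDA_GRID,
    seed: int = 0,
    tsnr: np.ndarray | None = None,
    tsnr_threshold: float = 30.0,
) -> ComponentWeights:
    """Ridge-learn weights mapping voxel responses to component responses.

    The regularization parameter is chosen per component by the prediction
    NSE for left-out sounds (5-fold CV by default).  If a per-voxel temporal
    SNR vector is supplied, voxels at or below ``tsnr_threshold`` are
    excluded before fitting.
    """
    from .nse import nse as _nse

    V = np.asarray(voxel_responses, dtype=float)
    R = np.asarray(target_components, dtype=float)
    if R.ndim == 1:
        R = R[:, None]
    if V.shape[0] != R.shape[0]:
        raise ValueError("voxel responses and components must share the sound axis")
    if np.linalg.matrix_rank(R) < R.shape[1]:
        raise ValueError("target components are rank deficient")
    mask = np.ones(V.shape[1], dtype=bool) if tsnr is None else np.asarray(tsnr) > tsnr_threshold
    V = V[:, mask]
    n_sounds, n_comp = R.shape[0], R.shape[1]
    folds = make_folds(n_sounds, n_folds, seed)
    preds = np.zeros((len(lambdas), n_sounds, n_comp))
    for val_idx in folds:
        fit_idx = np.setdiff1d(np.arange(n_sounds), val_idx)
        mu, sd = V[fit_idx].mean(axis=0), V[fit_idx].std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        Z = (V - mu) / sd
        preds[:, val_idx] = _ridge_predictions(Z, R[fit_idx], fit_idx, val_idx, lambdas)
    cv_nse = np.zeros((len(lambdas), n_comp))
    for i in range(len(lambdas)):
        for k in range(n_comp):
            cv_nse[i, k] = _nse(R[:, k], preds[i, :, k])
    best = np.argmin(cv_nse, axis=0)
    # final fit on all sounds at the selected lambdas
    mu, sd = V.mean(axis=0), V.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    Z = (V - mu) / sd
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    Rc = R - R.mean(axis=0)
    UtR = U.T @ Rc
    W = np.zeros((Z.shape[1], n_comp))
    for k in range(n_comp):
        d = s / (s**2 + lambdas[best[k]])
        W[:, k] = Vt.T @ (d * UtR[:, k])
    W_raw = W / sd[:, None]
    intercepts = R.mean(axis=0) - mu @ W_raw
    return ComponentWeights(
        weights=W_raw,
        intercepts=intercepts,
        voxel_mask=mask,
        chosen_lambdas=lambdas[best],
        cv_nse=cv_nse[best, np.arange(n_comp)],
    )
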