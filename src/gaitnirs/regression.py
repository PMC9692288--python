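"""Estimating the GMFM-88 motor score from GLM β-values.

A wrapper (greedy forward) feature selection drives a Gaussian-process
regressor, evaluated under leave-one-subject-out (LOSO) cross-validation:
every subject's score is predicted by a model that never saw any of that
subject's rows.  Features and target are standardized inside each training
fold; the kernel is squared-exponential plus white noise with hyperparameters
set by marginal-likelihood maximization.  Reported metrics are the Pearson r
(with p) between pooled out-of-sample predictions and observed scores, and
the RMSE on the scale of the target column (stated explicitly in the
report — never silently normalized).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel

from .glm import BetaMap
from .stats import ClinicalRecord

__all__ = [
    "FeatureTable",
    "RegressionReport",
    "assemble_features",
    "wrapper_select",
    "loso_gpr",
]

LAYOUTS = ("per_timepoint", "concat_sessions", "delta")


@dataclass
class FeatureTable:
    """Feature matrix, target and subject grouping for LOSO regression.

    ``X`` columns are β features keyed by channel/chromophore(/session);
    ``groups`` holds the subject id of each row so that leave-one-subject-out
    folds hold out *all* rows of a subject together.  ``target_scale``
    documents the units of ``y`` (e.g. "GMFM-88 points, 0-100").
    """

    X: pd.DataFrame
    y: np.ndarray
    groups: np.ndarray
    target_scale: str = "GMFM-88 points (0-100)"

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.groups = np.asarray(self.groups)
        if len(self.X) != self.y.size or self.y.size != self.groups.size:
            raise ValueError("X, y and groups must align row-wise")
        if self.X.isna().any().any() or np.any(~np.isfinite(self.y)):
            raise ValueError("feature table contains missing cells")
        if self.X.columns.duplicated().any():
            raise ValueError("feature keys must be unique")

    @property
    def n_subjects(self) -> int:
        return len(np.unique(self.groups))


@dataclass
class RegressionReport:
    """LOSO prediction outcome."""

    selected_features: list[str]
    subjects: list[str]
    observed: np.ndarray
    predicted: np.ndarray
    r: float | None
    p_r: float | None
    rmse: float
    target_scale: str
    selection_mode: str = "fixed"
    per_fold_features: list[list[str]] | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"subject": self.subjects, "observed": self.observed, "predicted": self.predicted}
        )

    def to_dict(self) -> dict:
        return {
            "selected_features": self.selected_features,
            "r": self.r,
            "p_r": self.p_r,
            "rmse": self.rmse,
            "target_scale": self.target_scale,
            "selection_mode": self.selection_mode,
            "subjects": list(self.subjects),
            "observed": [float(v) for v in self.observed],
            "predicted": [float(v) for v in self.predicted],
        }


def _feature_key(channel: int, chromophore: str, session: str | None = None) -> str:
    key = f"ch{channel}_{chromophore}"
    return f"{key}_{session}" if session else key


def assemble_features(
    betamaps: list[BetaMap],
    clinical: list[ClinicalRecord],
    layout: str = "per_timepoint",
    sessions: tuple[str, str] = ("T0", "T2"),
) -> FeatureTable:
    """Build the regression table from per-subject/session β-maps.

    Layouts (the row/target pairing the study leaves open):

    * ``per_timepoint`` (default): one row per subject × timepoint; features
      are that timepoint's β-values, target that timepoint's GMFM-88.
    * ``concat_sessions``: one row per subject; features from both sessions
      (keys suffixed _T0/_T2), target the final GMFM-88.
    * ``delta``: one row per subject; features β(T2) − β(T0), target
      GMFM-88 change.
    """
    if layout not in LAYOUTS:
        raise ValueError(f"layout must be one of {LAYOUTS}")
    clin = {c.subject: c for c in clinical}
    maps: dict[tuple[str, str], BetaMap] = {(m.subject, m.session): m for m in betamaps}
    subjects = sorted({m.subject for m in betamaps})
    missing = [
        (s, sess) for s in subjects for sess in sessions if (s, sess) not in maps
    ]
    if missing:
        raise ValueError(f"missing sessions for feature assembly: {missing}")
    no_clin = [s for s in subjects if s not in clin]
    if no_clin:
        raise ValueError(f"subjects without clinical records: {no_clin}")
    if len(subjects) < 2:
        raise ValueError("need >= 2 subjects (leave-one-subject-out undefined)")

    def beta_row(m: BetaMap, session_key: str | None) -> dict[str, float]:
        return {
            _feature_key(ch, chrom, session_key): m.get(ch, chrom)
            for ch in m.channels
            for chrom in ("hbo", "hhb")
        }

    rows, targets, groups = [], [], []
    if layout == "per_timepoint":
        for s in subjects:
            for sess in sessions:
                rows.append(beta_row(maps[(s, sess)], None))
                targets.append(clin[s].gmfm88[sess])
                groups.append(s)
        scale = "GMFM-88 points (0-100)"
    elif layout == "concat_sessions":
        for s in subjects:
            row = {}
            for sess in sessions:
                row.update(beta_row(maps[(s, sess)], sess))
            rows.append(row)
            targets.append(clin[s].gmfm88[sessions[-1]])
            groups.append(s)
        scale = "GMFM-88 points (0-100)"
    else:  # delta
        for s in subjects:
            m0, m2 = maps[(s, sessions[0])], maps[(s, sessions[-1])]
            rows.append(
                {
                    _feature_key(ch, chrom): m2.get(ch, chrom) - m0.get(ch, chrom)
                    for ch in m0.channels
                    for chrom in ("hbo", "hhb")
                }
            )
            targets.append(clin[s].gmfm88[sessions[-1]] - clin[s].gmfm88[sessions[0]])
            groups.append(s)
        scale = "GMFM-88 change (points)"
    X = pd.DataFrame(rows)
    return FeatureTable(X=X, y=np.array(targets), groups=np.array(groups), target_scale=scale)


def _make_gpr(seed: int, n_restarts: int = 0) -> GaussianProcessRegressor:
    kernel = ConstantKernel(1.0, (1e-3, 1e3)) * RBF(1.0, (1e-2, 1e3)) + WhiteKernel(
        1e-1, (1e-6, 1e1)
    )
    return GaussianProcessRegressor(
        kernel=kernel,
        normalize_y=False,
        alpha=1e-10,
        n_restarts_optimizer=n_restarts,
        random_state=seed,
    )


def _inner_loo_rmse(X: np.ndarray, y: np.ndarray, seed: int) -> float:
    """Exact leave-one-out RMSE of the GP with hyperparameters fit once.

    Standardizes, maximizes the marginal likelihood on the full candidate
    set, then evaluates the closed-form LOO residuals
    r_i = [K⁻¹y]_i / [K⁻¹]_ii (with K including the fitted noise term).
    Used as the wrapper's inner objective; the outer LOSO loop always
    refits per fold.
    """
    mu_x, sd_x = X.mean(axis=0), X.std(axis=0)
    sd_x[sd_x == 0] = 1.0
    mu_y, sd_y = y.mean(), y.std()
    Xs = (X - mu_x) / sd_x
    ys = (y - mu_y) / sd_y
    gpr = _make_gpr(seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        gpr.fit(Xs, ys)
    K = gpr.kernel_(Xs) + gpr.alpha * np.eye(len(ys))
    k_inv = np.linalg.inv(K)
    resid = (k_inv @ ys) / np.diag(k_inv)
    return float(np.sqrt(np.mean(resid**2))) * sd_y


def wrapper_select(
    table: FeatureTable,
    seed: int = 0,
    max_features: int | None = None,
    min_improvement: float = 1e-9,
    exclude_groups: np.ndarray | None = None,
) -> list[str]:
    """Greedy forward wrapper selection with an inner leave-one-out objective.

    Starting from the empty (mean-predictor) model, repeatedly add the
    feature that most reduces the inner leave-one-out RMSE of the GP
    regressor; stop when no addition improves it.  Ties break toward the
    lowest column index.  ``exclude_groups`` restricts the search to a
    training subset (used when selection runs inside an outer LOSO fold).
    """
    X_df, y, groups = table.X, table.y, table.groups
    if exclude_groups is not None:
        keep = ~np.isin(groups, exclude_groups)
        X_df, y, groups = X_df[keep], y[keep], groups[keep]
    if X_df.shape[1] < 1:
        raise ValueError("need at least one candidate feature")
    if len(np.unique(groups)) < 3:
        raise ValueError("need >= 3 subjects for inner cross-validation")
    if np.std(y) == 0:
        raise ValueError("degenerate target: zero variance")
    if max_features is None:
        max_features = X_df.shape[1]

    cols = list(X_df.columns)
    Xall = X_df.to_numpy()
    # empty-model baseline: the same GP given no informative input (its LOO
    # predictions reduce to the shrunken training mean), so that adding a
    # feature must beat shrinkage itself, not just the raw sample mean
    best_err = _inner_loo_rmse(np.zeros((y.size, 1)), y, seed)

    selected: list[int] = []
    remaining = list(range(len(cols)))
    while remaining and len(selected) < max_features:
        errs = []
        for j in remaining:
            idx = selected + [j]
            errs.append(_inner_loo_rmse(Xall[:, idx], y, seed))
        k = int(np.argmin(errs))  # argmin keeps the lowest index on ties
        if errs[k] < best_err - min_improvement:
            best_err = errs[k]
            selected.append(remaining.pop(k))
        else:
            break
    return [cols[j] for j in selected]


def loso_gpr(
    table: FeatureTable,
    features: list[str] | None = None,
    seed: int = 0,
    n_restarts: int = 2,
    select_per_fold: bool = False,
    max_features: int | None = None,
) -> RegressionReport:
    """Leave-one-subject-out GP regression.

    For each subject, fit on the remaining subjects (standardizing features
    and target within the training fold) and predict the held-out rows; then
    report Pearson r and its p over the pooled out-of-sample predictions and
    the RMSE back on the target's input scale.  With ``select_per_fold`` the
    wrapper selection is re-run inside each training fold (leakage-safe); a
    fixed ``features`` list reproduces the simpler select-once variant.  A
    constant target yields constant predictions with r reported as undefined
    (None).
    """
    if table.n_subjects < 3:
        raise ValueError("need >= 3 subjects for leave-one-subject-out evaluation")
    if features is None and not select_per_fold:
        features = wrapper_select(table, seed=seed, max_features=max_features)
        if not features:
            raise ValueError("wrapper selected no features; supply them explicitly")
    if features is not None and len(features) == 0:
        raise ValueError("features must be non-empty")

    y, groups = table.y, table.groups
    preds = np.empty_like(y)
    fold_feats: list[list[str]] = []
    for g in np.unique(groups):
        test = groups == g
        train = ~test
        if select_per_fold:
            feats = wrapper_select(
                table, seed=seed, max_features=max_features, exclude_groups=np.array([g])
            )
            if not feats:
                feats = list(table.X.columns[:1])
        else:
            feats = list(features)
        fold_feats.append(feats)
        X = table.X[feats].to_numpy()
        mu_x, sd_x = X[train].mean(axis=0), X[train].std(axis=0)
        sd_x[sd_x == 0] = 1.0
        mu_y, sd_y = y[train].mean(), y[train].std()
        if sd_y == 0:
            preds[test] = mu_y
            continue
        gpr = _make_gpr(seed, n_restarts=n_restarts)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gpr.fit((X[train] - mu_x) / sd_x, (y[train] - mu_y) / sd_y)
        preds[test] = gpr.predict((X[test] - mu_x) / sd_x) * sd_y + mu_y

    rmse = float(np.sqrt(np.mean((preds - y) ** 2)))
    if np.std(y) == 0 or np.std(preds) == 0:
        r, p_r = None, None
    else:
        r_val, p_val = sps.pearsonr(preds, y)
        r, p_r = float(r_val), float(p_val)
    sel = sorted(set().union(*fold_feats)) if select_per_fold else list(features)
    return RegressionReport(
        selected_features=sel,
        subjects=[str(g) for g in groups],
        observed=y.copy(),
        predicted=preds,
        r=r,
        p_r=p_r,
        rmse=rmse,
        target_scale=table.target_scale,
        selection_mode="per_fold" if select_per_fold else "fixed",
        per_fold_features=fold_feats if select_per_fold else None,
    )
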