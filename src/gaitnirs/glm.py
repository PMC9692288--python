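"""Block-design general linear model for channel-wise activation estimates.

The measured series Y is modelled as Y = Xβ + ε with a design matrix X whose
first column is the task regressor — the active-block boxcar convolved with a
canonical double-gamma hemodynamic response function and normalized to unit
peak — followed by an intercept and optional polynomial drift terms.  β is
estimated by ordinary least squares; with the peak-1 task regressor the task
β reads directly as the peak response amplitude in µM.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .optics import HemoTimeSeries
from .paradigm import Paradigm

__all__ = [
    "canonical_hrf",
    "DesignMatrix",
    "GLMFit",
    "BetaMap",
    "build_design",
    "fit_glm",
    "fit_hemoglobin",
    "extract_betamap",
]

CHROMOPHORES = ("hbo", "hhb")


def canonical_hrf(
    t: np.ndarray,
    peak: float = 6.0,
    undershoot: float = 16.0,
    ratio: float = 1.0 / 6.0,
) -> np.ndarray:
    """Canonical double-gamma impulse response, unit peak.

    A gamma density peaking at ``peak`` s minus ``ratio`` times one peaking at
    ``undershoot`` s (both with unit scale), rescaled so max = 1.  Defaults
    follow the field-standard response (6 s peak, 16 s undershoot, 1:6 ratio);
    pediatric responses may deviate — the parameters are exposed for that.
    """
    t = np.asarray(t, dtype=float)
    h = sps.gamma.pdf(t, a=peak + 1.0, scale=1.0) - ratio * sps.gamma.pdf(
        t, a=undershoot + 1.0, scale=1.0
    )
    m = h.max()
    if m <= 0:
        raise ValueError("degenerate HRF parameters: non-positive peak")
    return h / m


@dataclass
class DesignMatrix:
    """n × p design with labelled columns; task regressor first."""

    X: np.ndarray
    names: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        if self.X.shape[1] != len(self.names):
            raise ValueError("names must match column count")
        if self.X.shape[1] >= self.X.shape[0]:
            raise ValueError("design needs p < n")
        norms = np.abs(self.X).max(axis=0)
        if np.any(norms == 0):
            dead = [self.names[i] for i in np.flatnonzero(norms == 0)]
            raise ValueError(f"all-zero design columns: {dead}")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]


def build_design(
    paradigm: Paradigm,
    fs: float,
    n_samples: int | None = None,
    hrf: str | None = "canonical",
    drift_order: int = 1,
    hrf_kwargs: dict | None = None,
) -> DesignMatrix:
    """Assemble the task + intercept + polynomial-drift design.

    ``hrf=None`` skips convolution (raw boxcar regressor).  Drift columns are
    Legendre-like centered polynomials of order 1..drift_order.
    """
    if n_samples is None:
        n_samples = paradigm.n_samples(fs)
    last_end = paradigm.block_onsets[-1] + paradigm.active_duration
    if last_end * fs > n_samples + 1e-9:
        raise ValueError(
            f"paradigm blocks extend to {last_end:.1f}s but series covers "
            f"{n_samples / fs:.1f}s"
        )
    box = paradigm.boxcar(fs, n_samples)
    if hrf is None:
        task = box
    elif hrf == "canonical":
        t_h = np.arange(0, 32.0, 1.0 / fs)
        kernel = canonical_hrf(t_h, **(hrf_kwargs or {}))
        task = np.convolve(box, kernel)[:n_samples] / fs
        task = task / task.max()
    else:
        raise ValueError(f"unknown hrf spec {hrf!r}")

    cols = [task, np.ones(n_samples)]
    names = ["task", "intercept"]
    x = np.linspace(-1.0, 1.0, n_samples)
    for k in range(1, drift_order + 1):
        cols.append(x**k)
        names.append(f"drift{k}")
    return DesignMatrix(X=np.column_stack(cols), names=names)


@dataclass
class GLMFit:
    """Least-squares fit of one channel series against a design."""

    beta: np.ndarray
    se: np.ndarray
    residuals: np.ndarray
    names: list[str]
    residual_var: float

    @property
    def task_beta(self) -> float:
        return float(self.beta[self.names.index("task")])

    @property
    def task_se(self) -> float:
        return float(self.se[self.names.index("task")])


def fit_glm(y: np.ndarray, design: DesignMatrix) -> GLMFit:
    """OLS fit: β = argmin ‖y − Xβ‖²; naive standard errors.

    Residuals are orthogonal to every design column; se comes from the
    residual variance and the diagonal of (XᵀX)⁻¹.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = design.X
    if y.size != design.n:
        raise ValueError(f"series length {y.size} != design rows {design.n}")
    rank = np.linalg.matrix_rank(X)
    if rank < design.p:
        # identify an offending column by leave-one-out rank
        for j in range(design.p):
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank:
                raise ValueError(
                    f"design is rank deficient; column {design.names[j]!r} is "
                    "collinear with the others"
                )
        raise ValueError("design is rank deficient")
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ (X.T @ y)
    resid = y - X @ beta
    dof = design.n - design.p
    sigma2 = float(resid @ resid / dof) if dof > 0 else 0.0
    se = np.sqrt(sigma2 * np.diag(xtx_inv))
    return GLMFit(beta=beta, se=se, residuals=resid, names=list(design.names), residual_var=sigma2)


@dataclass
class BetaMap:
    """Task-β estimates per channel × chromophore for one subject/session.

    ``beta``/``se``/``residual_var`` have shape (n_channels, 2) with
    chromophore order (HbO, HHb); ``channels`` holds 1-based channel numbers.
    """

    channels: list[int]
    beta: np.ndarray
    se: np.ndarray
    residual_var: np.ndarray
    subject: str = "S01"
    session: str = "T0"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.se = np.asarray(self.se, dtype=float)
        self.residual_var = np.asarray(self.residual_var, dtype=float)
        shape = (len(self.channels), len(CHROMOPHORES))
        for name in ("beta", "se", "residual_var"):
            if getattr(self, name).shape != shape:
                raise ValueError(f"{name} must have shape {shape}")
        if np.any(self.se < 0):
            raise ValueError("standard errors must be non-negative")

    def get(self, channel: int, chromophore: str) -> float:
        return float(
            self.beta[self.channels.index(channel), CHROMOPHORES.index(chromophore)]
        )

    def to_records(self) -> list[dict]:
        out = []
        for i, ch in enumerate(self.channels):
            for j, chrom in enumerate(CHROMOPHORES):
                out.append(
                    {
                        "subject": self.subject,
                        "session": self.session,
                        "channel": ch,
                        "chromophore": chrom,
                        "beta": float(self.beta[i, j]),
                        "se": float(self.se[i, j]),
                    }
                )
        return out


def extract_betamap(
    fits: dict[tuple[int, str], GLMFit],
    channels: list[int] | None = None,
    subject: str = "S01",
    session: str = "T0",
) -> BetaMap:
    """Assemble per-channel fits into a keyed β-map.

    ``fits`` maps (1-based channel, chromophore) to a fitted GLM; the result
    is independent of the dict's iteration order.  Missing channel ×
    chromophore combinations raise with the full list of gaps.
    """
    if channels is None:
        channels = sorted({ch for ch, _ in fits})
    missing = [
        (ch, chrom)
        for ch in channels
        for chrom in CHROMOPHORES
        if (ch, chrom) not in fits
    ]
    if missing:
        raise ValueError(f"missing channel fits: {missing}")
    shape = (len(channels), len(CHROMOPHORES))
    beta = np.zeros(shape)
    se = np.zeros(shape)
    rvar = np.zeros(shape)
    for i, ch in enumerate(channels):
        for j, chrom in enumerate(CHROMOPHORES):
            f = fits[(ch, chrom)]
            beta[i, j] = f.task_beta
            se[i, j] = f.task_se
            rvar[i, j] = f.residual_var
    return BetaMap(
        channels=list(channels), beta=beta, se=se, residual_var=rvar,
        subject=subject, session=session,
    )


def fit_hemoglobin(
    hemo: HemoTimeSeries,
    paradigm: Paradigm,
    drift_order: int = 1,
    hrf: str | None = "canonical",
    channel_numbers: list[int] | None = None,
    filter_spec=None,
) -> BetaMap:
    """Fit the GLM on every long channel and both chromophores of a series.

    ``filter_spec`` (a :class:`gaitnirs.preprocess.FilterSpec`) applies the
    same zero-phase band-pass used on the data to the task regressor —
    matched filtering, which removes the attenuation bias the high-pass edge
    would otherwise impose on β.  Intercept and drift columns stay unfiltered
    (they model exactly the components the band-pass leaves near zero).
    """
    design = build_design(
        paradigm, fs=hemo.fs, n_samples=hemo.time.size, hrf=hrf, drift_order=drift_order
    )
    if filter_spec is not None:
        from .preprocess import bandpass_1d

        X = design.X.copy()
        X[:, 0] = bandpass_1d(X[:, 0], hemo.fs, filter_spec)
        design = DesignMatrix(X=X, names=design.names)
    if channel_numbers is None:
        channel_numbers = list(range(1, hemo.n_long + 1))
    fits: dict[tuple[int, str], GLMFit] = {}
    for i, ch in enumerate(channel_numbers):
        fits[(ch, "hbo")] = fit_glm(hemo.hbo[:, i], design)
        fits[(ch, "hhb")] = fit_glm(hemo.hhb[:, i], design)
    return extract_betamap(
        fits, channels=channel_numbers, subject=hemo.subject, session=hemo.session
    )
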