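"""Longitudinal group statistics on β-values and clinical scales.

* Channel-wise one-way repeated-measures ANOVA across sessions with
  Greenhouse–Geisser sphericity correction (fractional degrees of freedom),
  Bonferroni-adjusted across channels.
* Bonferroni-corrected paired-t post-hoc contrasts between sessions.
* Exact Wilcoxon signed-rank test (full 2ⁿ enumeration of the signed-rank
  null for small n) for the nonparametric clinical-scale comparisons, with
  the tie-corrected normal approximation reported alongside.
* Shapiro–Wilk normality gate.

The β input convention throughout is a (n_subjects × k_sessions) array of
complete cases for one channel and chromophore.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ClinicalRecord",
    "AnovaResult",
    "PosthocResult",
    "WilcoxonResult",
    "StatsReport",
    "rm_anova",
    "posthoc_paired_t",
    "wilcoxon_exact",
    "shapiro_wilk",
    "significance_map",
    "channelwise_anova",
    "channelwise_posthoc",
]

MAS_LEVELS = (0.0, 1.0, 1.5, 2.0, 3.0, 4.0)  # ordinal grades; "1+" encoded as 1.5


@dataclass
class ClinicalRecord:
    """Per-subject clinical scores.

    ``gmfm88`` maps session label -> GMFM-88 total (0–100); ``mas`` maps
    joint ("hip"/"knee"/"ankle") -> {session: grade}, grades from
    {0, 1, 1.5, 2, 3, 4} with the ordinal "1+" encoded as 1.5.
    """

    subject: str
    gmfcs: int
    gmfm88: dict[str, float]
    mas: dict[str, dict[str, float]] | None = None

    def __post_init__(self) -> None:
        if not 1 <= self.gmfcs <= 5:
            raise ValueError("GMFCS level must be I-V (1-5)")
        for sess, v in self.gmfm88.items():
            if not 0 <= v <= 100:
                raise ValueError(f"GMFM-88 at {sess} outside [0, 100]: {v}")
        if self.mas:
            for joint, scores in self.mas.items():
                for sess, v in scores.items():
                    if v not in MAS_LEVELS:
                        raise ValueError(f"MAS {joint}@{sess}={v} not an allowed grade")


@dataclass
class AnovaResult:
    """Greenhouse–Geisser-corrected repeated-measures ANOVA for one channel."""

    channel: int
    chromophore: str
    F: float
    df1: float
    df2: float
    epsilon: float
    p_raw: float
    p_adjusted: float | None = None
    n_subjects: int = 0


@dataclass
class PosthocResult:
    """Paired-t contrast between two sessions, Bonferroni adjusted."""

    channel: int
    chromophore: str
    contrast: str
    t: float | None
    p_raw: float | None
    p_adjusted: float | None
    undefined: bool = False


@dataclass
class WilcoxonResult:
    """Signed-rank test: W⁺ statistic, normal-approximation z, and p-values."""

    w: float
    z: float
    p_exact: float | None
    p_approx: float
    n_effective: int
    method: str

    @property
    def p(self) -> float:
        return self.p_exact if self.p_exact is not None else self.p_approx


def rm_anova(betas: np.ndarray) -> AnovaResult:
    """One-way repeated-measures ANOVA (within factor: session).

    Parameters
    ----------
    betas
        (n_subjects, k_sessions) complete-case table.

    Returns the within-subject F, the Greenhouse–Geisser ε estimated from the
    session covariance matrix, the ε-corrected degrees of freedom
    df1 = ε(k−1), df2 = ε(k−1)(n−1), and the corrected p-value.  With all
    subjects identical across sessions the session effect is exactly zero
    and F = 0 is returned.
    """
    x = np.asarray(betas, dtype=float)
    if x.ndim != 2:
        raise ValueError("betas must be (n_subjects, k_sessions)")
    if np.any(~np.isfinite(x)):
        raise ValueError("incomplete cases: drop subjects with missing sessions first")
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError("need >= 2 subjects and >= 2 sessions")

    grand = x.mean()
    sess_means = x.mean(axis=0)
    subj_means = x.mean(axis=1)
    ss_sess = n * float(((sess_means - grand) ** 2).sum())
    ss_subj = k * float(((subj_means - grand) ** 2).sum())
    ss_total = float(((x - grand) ** 2).sum())
    ss_err = ss_total - ss_sess - ss_subj

    df_sess = k - 1
    df_err = (k - 1) * (n - 1)
    ms_err = ss_err / df_err
    if ss_sess <= 1e-300 or ms_err <= 0:
        f_stat = 0.0 if ss_sess <= 1e-300 else math.inf
    else:
        f_stat = (ss_sess / df_sess) / ms_err

    # Greenhouse-Geisser epsilon from the double-centered session covariance
    s = np.cov(x, rowvar=False, ddof=1)
    row = s.mean(axis=0)
    s_dc = s - row[None, :] - row[:, None] + s.mean()
    denom = (k - 1) * float((s_dc**2).sum())
    eps = float(np.trace(s_dc) ** 2 / denom) if denom > 0 else 1.0
    eps = float(np.clip(eps, 1.0 / (k - 1), 1.0))

    df1 = eps * df_sess
    df2 = eps * df_err
    p = float(sps.f.sf(f_stat, df1, df2)) if np.isfinite(f_stat) else 0.0
    return AnovaResult(
        channel=0, chromophore="", F=float(f_stat), df1=df1, df2=df2,
        epsilon=eps, p_raw=p, n_subjects=n,
    )


def posthoc_paired_t(
    betas: np.ndarray,
    session_labels: tuple[str, ...] = ("T0", "T1", "T2"),
    contrasts: list[tuple[int, int]] | None = None,
    family_size: int = 1,
) -> list[PosthocResult]:
    """Paired t-tests between sessions with Bonferroni correction.

    ``family_size`` multiplies each raw p (capped at 1); per the study
    convention it counts channels × contrasts per chromophore.  A
    zero-variance nonzero-mean difference is reported as undefined rather
    than propagating NaN; an all-zero difference gives t = 0, p = 1.
    """
    x = np.asarray(betas, dtype=float)
    n, k = x.shape
    if contrasts is None:
        contrasts = list(itertools.combinations(range(k), 2))
    if family_size < len(contrasts):
        raise ValueError("family_size smaller than the number of contrasts run")
    out: list[PosthocResult] = []
    for a, b in contrasts:
        d = x[:, b] - x[:, a]
        label = f"{session_labels[a]}v{session_labels[b]}"
        if np.allclose(d.std(ddof=1), 0.0):
            if np.allclose(d, 0.0):
                out.append(PosthocResult(0, "", label, 0.0, 1.0, 1.0))
            else:
                out.append(PosthocResult(0, "", label, None, None, None, undefined=True))
            continue
        t, p = sps.ttest_rel(x[:, b], x[:, a])
        out.append(
            PosthocResult(
                0, "", label, float(t), float(p), float(min(1.0, p * family_size))
            )
        )
    return out


def _exact_signed_rank_p(ranks: np.ndarray, w_pos: float) -> float:
    """Two-sided exact p by enumerating all 2^n sign assignments of the ranks."""
    n = ranks.size
    total = 2**n
    n_le = n_ge = 0
    for start in range(0, total, 1 << 16):  # chunked: keeps n = 20 tractable
        idx = np.arange(start, min(start + (1 << 16), total), dtype=np.int64)
        signs = ((idx[:, None] >> np.arange(n)[None, :]) & 1).astype(np.float64)
        w_all = signs @ ranks
        n_le += int(np.sum(w_all <= w_pos + 1e-12))
        n_ge += int(np.sum(w_all >= w_pos - 1e-12))
    return min(1.0, 2.0 * min(n_le, n_ge) / total)


def wilcoxon_exact(
    pre: np.ndarray,
    post: np.ndarray,
    zero_method: str = "wilcox",
    exact_max_n: int = 20,
) -> WilcoxonResult:
    """Wilcoxon signed-rank test with exact small-sample p-value.

    Differences post − pre are ranked by absolute value (midranks for ties);
    zero differences are dropped (``zero_method='wilcox'``) or kept in the
    ranking (``'pratt'``).  For n ≤ ``exact_max_n`` effective pairs the
    two-sided p is computed by full enumeration of the 2ⁿ equally likely
    sign assignments; the tie-corrected normal approximation (no continuity
    correction) is always reported as ``z``/``p_approx``.
    """
    pre = np.asarray(pre, dtype=float).ravel()
    post = np.asarray(post, dtype=float).ravel()
    if pre.shape != post.shape:
        raise ValueError("pre and post must be paired (same length)")
    d = post - pre
    if np.all(d == 0):
        warnings.warn("all paired differences are zero; p = 1", stacklevel=2)
        return WilcoxonResult(w=0.0, z=0.0, p_exact=1.0, p_approx=1.0,
                              n_effective=0, method="degenerate")
    if zero_method == "wilcox":
        d = d[d != 0]
        ranks = sps.rankdata(np.abs(d))
    elif zero_method == "pratt":
        ranks_all = sps.rankdata(np.abs(d))
        keep = d != 0
        d, ranks = d[keep], ranks_all[keep]
    else:
        raise ValueError(f"unknown zero_method {zero_method!r}")
    n = d.size
    w_pos = float(ranks[d > 0].sum())

    # normal approximation with tie correction
    mu = n * (n + 1) / 4.0
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = float((counts**3 - counts).sum()) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    z = (w_pos - mu) / math.sqrt(var) if var > 0 else 0.0
    p_approx = float(2 * sps.norm.sf(abs(z))) if var > 0 else 1.0

    p_exact = _exact_signed_rank_p(ranks, w_pos) if n <= exact_max_n else None
    method = "exact-enumeration" if p_exact is not None else "normal-approximation"
    return WilcoxonResult(
        w=w_pos, z=float(z), p_exact=p_exact, p_approx=p_approx,
        n_effective=n, method=method,
    )


def shapiro_wilk(scores: np.ndarray) -> tuple[float, float]:
    """Shapiro–Wilk normality test (W, p); gates parametric vs nonparametric."""
    x = np.asarray(scores, dtype=float).ravel()
    if not 3 <= x.size <= 5000:
        raise ValueError("Shapiro-Wilk defined for 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise ValueError("constant input: normality test undefined")
    w, p = sps.shapiro(x)
    return float(w), float(p)


def _beta_table(beta_df: pd.DataFrame, channel: int, chromophore: str) -> np.ndarray:
    sub = beta_df[(beta_df.channel == channel) & (beta_df.chromophore == chromophore)]
    table = sub.pivot(index="subject", columns="session", values="beta")
    table = table[sorted(table.columns, key=list(beta_df.session.unique()).index)]
    return table.to_numpy()


def channelwise_anova(
    beta_df: pd.DataFrame, family_size: int | None = None
) -> list[AnovaResult]:
    """RM-ANOVA per channel × chromophore from a tidy β table.

    ``beta_df`` columns: subject, session, channel, chromophore, beta.
    Bonferroni family defaults to the number of channels per chromophore.
    """
    channels = sorted(beta_df.channel.unique())
    results: list[AnovaResult] = []
    for chrom in sorted(beta_df.chromophore.unique()):
        fam = family_size if family_size is not None else len(channels)
        for ch in channels:
            res = rm_anova(_beta_table(beta_df, ch, chrom))
            res.channel = int(ch)
            res.chromophore = chrom
            res.p_adjusted = float(min(1.0, res.p_raw * fam))
            results.append(res)
    return results


def channelwise_posthoc(
    beta_df: pd.DataFrame, family_size: int | None = None
) -> list[PosthocResult]:
    """Paired-t contrasts per channel × chromophore, Bonferroni adjusted.

    The default family is channels × contrasts per chromophore (the most
    conservative reading of correcting for "channels and comparisons").
    """
    channels = sorted(beta_df.channel.unique())
    sessions = tuple(beta_df.session.unique())
    n_contrasts = len(sessions) * (len(sessions) - 1) // 2
    results: list[PosthocResult] = []
    for chrom in sorted(beta_df.chromophore.unique()):
        fam = family_size if family_size is not None else len(channels) * n_contrasts
        for ch in channels:
            for res in posthoc_paired_t(
                _beta_table(beta_df, ch, chrom), session_labels=sessions, family_size=fam
            ):
                res.channel = int(ch)
                res.chromophore = chrom
                results.append(res)
    return results


@dataclass
class StatsReport:
    """Channel-wise significance tables with Brodmann annotations."""

    anova: pd.DataFrame
    posthoc: pd.DataFrame

    def summary(self) -> str:
        lines = ["Channel-wise RM-ANOVA (Greenhouse-Geisser corrected)"]
        sig = self.anova[self.anova.corrected_significant]
        if sig.empty:
            lines.append("  no channel survives Bonferroni correction")
        for _, r in sig.iterrows():
            ba = f" [{r.brodmann}]" if r.brodmann else ""
            lines.append(
                f"  Ch{r.channel} {r.chromophore}{ba}: "
                f"F({r.df1:.3f}, {r.df2:.3f}) = {r.F:.3f}, adj p = {r.p_adjusted:.3f}"
            )
        sigp = self.posthoc[self.posthoc.corrected_significant.fillna(False)]
        lines.append("Post-hoc paired t (Bonferroni corrected)")
        if sigp.empty:
            lines.append("  no significant contrasts")
        for _, r in sigp.iterrows():
            lines.append(
                f"  Ch{r.channel} {r.chromophore} {r.contrast}: "
                f"t = {r.t:.3f}, adj p = {r.p_adjusted:.3f}"
            )
        return "\n".join(lines)


def significance_map(
    anova: list[AnovaResult],
    posthoc: list[PosthocResult],
    ba_lookup: dict[int, str | None],
    alpha: float = 0.05,
) -> StatsReport:
    """Tabulate raw- vs corrected-significant channels with Brodmann labels."""
    for res in anova + posthoc:
        if res.channel not in ba_lookup:
            raise ValueError(f"channel {res.channel} missing from Brodmann lookup")
    a_rows = [
        {
            "channel": r.channel,
            "chromophore": r.chromophore,
            "brodmann": ba_lookup[r.channel],
            "F": r.F,
            "df1": r.df1,
            "df2": r.df2,
            "epsilon": r.epsilon,
            "p_raw": r.p_raw,
            "p_adjusted": r.p_adjusted,
            "raw_significant": r.p_raw < alpha,
            "corrected_significant": (r.p_adjusted is not None and r.p_adjusted < alpha),
        }
        for r in anova
    ]
    p_rows = [
        {
            "channel": r.channel,
            "chromophore": r.chromophore,
            "brodmann": ba_lookup[r.channel],
            "contrast": r.contrast,
            "t": r.t,
            "p_raw": r.p_raw,
            "p_adjusted": r.p_adjusted,
            "undefined": r.undefined,
            "raw_significant": (r.p_raw is not None and r.p_raw < alpha),
            "corrected_significant": (r.p_adjusted is not None and r.p_adjusted < alpha),
        }
        for r in posthoc
    ]
    cols_a = ["channel", "chromophore", "brodmann", "F", "df1", "df2", "epsilon",
              "p_raw", "p_adjusted", "raw_significant", "corrected_significant"]
    cols_p = ["channel", "chromophore", "brodmann", "contrast", "t", "p_raw",
              "p_adjusted", "undefined", "raw_significant", "corrected_significant"]
    return StatsReport(
        anova=pd.DataFrame(a_rows, columns=cols_a),
        posthoc=pd.DataFrame(p_rows, columns=cols_p),
    )
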