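"""Seeded synthetic fNIRS recordings and cohorts with known ground truth.

The generator emulates the ingredients of a pediatric gait-training fNIRS
study so that every downstream stage is testable by parameter recovery:

* an HRF-locked activation term with per-channel, per-session amplitudes
  (the quantity the GLM must recover),
* physiological oscillations — cardiac (~1.5 Hz in children), Mayer waves
  (~0.1 Hz) and respiration (~0.3 Hz) with random phases and slow amplitude
  modulation,
* a superficial systemic component shared between short and long channels
  (what short-separation regression removes),
* spike and baseline-shift motion artifacts at Poisson-random times,
* sensor noise,

and, at the cohort level, a clinical table whose GMFM-88 change is linked to
the β change on designated informative channels.  Concentrations are
forward-mapped through the same modified Beer–Lambert law the ``optics``
module inverts, so the inversion is exact by construction (up to the
per-channel baseline constant absorbed by the GLM intercept).

All randomness flows from explicit integer seeds; identical seeds give
bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .glm import build_design
from .montage import Montage
from .optics import OpticalParameters, forward_mbll
from .paradigm import Paradigm
from .recording import Recording
from .stats import ClinicalRecord

__all__ = [
    "GroundTruth",
    "CohortSpec",
    "generate_recording",
    "generate_cohort",
    "generate_beta_cohort",
]

_MAS_LEVELS = (0.0, 1.0, 1.5, 2.0, 3.0, 4.0)


@dataclass
class GroundTruth:
    """True generative parameters for one subject's recordings.

    Attributes
    ----------
    beta_hbo
        Task HbO amplitude (µM) per session × long channel; the HHb
        amplitude is ``-hhb_ratio * beta_hbo`` (antiphase BOLD-like response).
    superficial_gain
        Per-long-channel coupling to the shared superficial signal (unitless;
        short channels couple with gain 1).
    noise_sd
        Additive white sensor noise, µM-equivalent.
    cardiac_amp, mayer_amp, resp_amp
        Oscillator amplitudes (µM) at ``cardiac_freq``/0.1/0.3 Hz.
    spike_rate, shift_rate
        Poisson rates (events/s) of transient spikes and baseline steps.
    artifact_times
        Filled in by :func:`generate_recording` (meta record of the injected
        onsets, seconds); may be pre-set to force specific onsets.
    age
        Participant age in years (drives the DPF).
    """

    beta_hbo: np.ndarray
    superficial_gain: np.ndarray
    hhb_ratio: float = 1.0 / 3.0
    noise_sd: float = 0.05
    cardiac_amp: float = 0.3
    cardiac_freq: float = 1.5
    mayer_amp: float = 0.25
    resp_amp: float = 0.15
    drift_amp: float = 0.2
    spike_rate: float = 5.0 / 600.0
    shift_rate: float = 1.0 / 600.0
    artifact_times: list[float] | None = None
    age: float = 10.0

    def __post_init__(self) -> None:
        self.beta_hbo = np.atleast_2d(np.asarray(self.beta_hbo, dtype=float))
        self.superficial_gain = np.asarray(self.superficial_gain, dtype=float)
        if self.hhb_ratio <= 0:
            raise ValueError("hhb_ratio must be positive (HHb response is -ratio * HbO)")
        if self.beta_hbo.shape[1] != self.superficial_gain.size:
            raise ValueError(
                "channel axis mismatch: beta_hbo has "
                f"{self.beta_hbo.shape[1]} channels, superficial_gain "
                f"{self.superficial_gain.size}"
            )

    @property
    def beta_hhb(self) -> np.ndarray:
        return -self.hhb_ratio * self.beta_hbo

    @property
    def n_sessions(self) -> int:
        return self.beta_hbo.shape[0]

    @classmethod
    def default(
        cls,
        montage: Montage,
        n_sessions: int = 1,
        seed: int = 0,
        **overrides,
    ) -> "GroundTruth":
        """A plausible truth: β in [0.5, 1.0] µM and gains in [0.5, 1.5]."""
        rng = np.random.default_rng(seed)
        n_long = montage.n_long
        beta = rng.uniform(0.5, 1.0, size=(n_sessions, n_long))
        gain = rng.uniform(0.5, 1.5, size=n_long)
        return cls(beta_hbo=beta, superficial_gain=gain, **overrides)


@dataclass(frozen=True)
class CohortSpec:
    """Design of a synthetic longitudinal cohort.

    ``gmfm_link_slope`` is the change in GMFM-88 (points) per unit change
    (µM) of the mean β on the informative channels; ``beta_step`` /
    ``beta_step_sd`` set the per-session-step β increase on those channels.
    """

    n_subjects: int = 8
    sessions: tuple[str, ...] = ("T0", "T1", "T2")
    gmfm_link_slope: float = 60.0
    gmfm_noise_sd: float = 3.0
    seed: int = 0
    informative_channels: tuple[int, ...] = (7, 12, 14)  # 1-based
    beta_step: float = 0.25
    beta_step_sd: float = 0.15

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2 (leave-one-subject-out undefined)")
        if len(self.sessions) == 0:
            raise ValueError("sessions must be non-empty")


def _superficial(t: np.ndarray, truth: GroundTruth, rng: np.random.Generator) -> np.ndarray:
    """Shared superficial systemic signal: Mayer + respiration + slow drift,
    each with random phase and slow amplitude modulation."""
    sys = np.zeros_like(t)
    for amp, freq in (
        (truth.mayer_amp, 0.1),
        (truth.resp_amp, 0.3),
        (truth.drift_amp, 0.005),
        (0.75 * truth.drift_amp, 0.002),
    ):
        phase = rng.uniform(0, 2 * np.pi)
        am = 1.0 + 0.3 * np.sin(2 * np.pi * 0.01 * t + rng.uniform(0, 2 * np.pi))
        sys += amp * am * np.sin(2 * np.pi * freq * t + phase)
    return sys


def _artifacts(
    t: np.ndarray, truth: GroundTruth, rng: np.random.Generator
) -> tuple[np.ndarray, list[float]]:
    """Common-mode artifact waveform (µM) and its onset times."""
    span = t[-1] - t[0] if t.size > 1 else 0.0
    wave = np.zeros_like(t)
    times: list[float] = []
    if truth.artifact_times is not None:
        spikes = list(truth.artifact_times)
        shifts: list[float] = []
    else:
        spikes = list(rng.uniform(0, span, size=rng.poisson(truth.spike_rate * span)))
        shifts = list(rng.uniform(0, span, size=rng.poisson(truth.shift_rate * span)))
    for t0 in spikes:
        width = rng.uniform(0.5, 2.0)
        amp = rng.choice([-1.0, 1.0]) * rng.uniform(2.0, 5.0)
        wave += amp * np.exp(-0.5 * ((t - t0) / (width / 4.0)) ** 2)
        times.append(float(t0))
    for t0 in shifts:
        amp = rng.choice([-1.0, 1.0]) * rng.uniform(0.2, 0.5)
        wave += amp * (t >= t0)
        times.append(float(t0))
    return wave, sorted(times)


def generate_recording(
    montage: Montage,
    paradigm: Paradigm,
    truth: GroundTruth,
    fs: float = 10.0,
    seed: int = 0,
    session_index: int = 0,
    subject: str = "S01",
    session: str = "T0",
    baseline_intensity: float = 1.0,
) -> Recording:
    """Simulate one two-wavelength recording.

    Long channels carry the HRF-locked activation plus superficial, cardiac,
    artifact and noise terms; short channels carry everything except the
    neural term.  Concentrations are forward-mapped through the MBLL of
    ``optics`` and exponentiated to intensities, so the optics chain inverts
    them exactly (up to the per-channel baseline constant).
    """
    if fs <= 2 * truth.cardiac_freq:
        raise ValueError(
            f"fs={fs} Hz must exceed twice the fastest oscillator "
            f"({truth.cardiac_freq} Hz)"
        )
    if truth.beta_hbo.shape[1] != montage.n_long:
        raise ValueError(
            "channel axis mismatch: truth.beta_hbo has "
            f"{truth.beta_hbo.shape[1]} channels, montage has {montage.n_long} long"
        )
    if not 0 <= session_index < truth.n_sessions:
        raise ValueError(
            f"session_index {session_index} out of range for "
            f"{truth.n_sessions} session(s) in truth"
        )
    rng = np.random.default_rng(seed)
    n = paradigm.n_samples(fs)
    t = np.arange(n) / fs

    design = build_design(paradigm, fs=fs, n_samples=n, hrf="canonical", drift_order=0)
    task = design.X[:, 0]

    sys_hbo = _superficial(t, truth, rng)
    sys_hhb = -0.4 * sys_hbo
    artifact, artifact_times = _artifacts(t, truth, rng)

    n_long, n_short = montage.n_long, montage.n_short
    beta_hbo = truth.beta_hbo[session_index]
    beta_hhb = truth.beta_hhb[session_index]

    def channel_bank(n_ch: int, neural_hbo, neural_hhb, gains) -> tuple[np.ndarray, np.ndarray]:
        hbo = np.empty((n, n_ch))
        hhb = np.empty((n, n_ch))
        for c in range(n_ch):
            phase = rng.uniform(0, 2 * np.pi)
            cardiac = truth.cardiac_amp * rng.uniform(0.8, 1.2) * np.sin(
                2 * np.pi * truth.cardiac_freq * t + phase
            )
            art = artifact * rng.uniform(0.5, 1.5)
            hbo[:, c] = (
                neural_hbo[c] * task
                + gains[c] * sys_hbo
                + cardiac
                + art
                + rng.normal(0, truth.noise_sd, n)
            )
            hhb[:, c] = (
                neural_hhb[c] * task
                + gains[c] * sys_hhb
                - 0.3 * cardiac
                - truth.hhb_ratio * art
                + rng.normal(0, truth.noise_sd, n)
            )
        return hbo, hhb

    hbo, hhb = channel_bank(n_long, beta_hbo, beta_hhb, truth.superficial_gain)
    zeros = np.zeros(n_short)
    s_hbo, s_hhb = channel_bank(n_short, zeros, zeros, np.ones(n_short))

    wavelengths = (760.0, 850.0)
    od = np.empty((n, montage.n_channels, 2))
    params_long = OpticalParameters.for_channels(
        montage.separations_mm(short=False), age=truth.age, wavelengths=wavelengths
    )
    od_long = forward_mbll(hbo, hhb, params_long)
    if n_short:
        params_short = OpticalParameters.for_channels(
            montage.separations_mm(short=True), age=truth.age, wavelengths=wavelengths
        )
        od_short = forward_mbll(s_hbo, s_hhb, params_short)
    long_idx = [i for i, c in enumerate(montage.channels) if not c.is_short]
    short_idx = [i for i, c in enumerate(montage.channels) if c.is_short]
    od[:, long_idx, :] = od_long
    if n_short:
        od[:, short_idx, :] = od_short

    intensity = baseline_intensity * np.exp(-od)
    return Recording(
        montage=montage,
        paradigm=paradigm,
        fs=fs,
        intensity=intensity,
        wavelengths=wavelengths,
        subject=subject,
        session=session,
        meta={
            "seed": seed,
            "session_index": session_index,
            "age": truth.age,
            "artifact_times": artifact_times,
        },
    )


def _subject_truth(
    spec: CohortSpec, montage: Montage, rng: np.random.Generator
) -> GroundTruth:
    n_long = montage.n_long
    k = len(spec.sessions)
    base = rng.normal(0.6, 0.15, size=n_long).clip(0.15, None)
    beta = np.tile(base, (k, 1))
    info = [c - 1 for c in spec.informative_channels]
    step = rng.normal(spec.beta_step, spec.beta_step_sd, size=len(info))
    for s in range(k):
        beta[s, info] = base[info] + step * s
    gain = rng.uniform(0.5, 1.5, size=n_long)
    age = float(rng.uniform(3.0, 18.0))
    return GroundTruth(beta_hbo=beta, superficial_gain=gain, age=age)


def generate_cohort(
    spec: CohortSpec,
    montage: Montage,
    paradigm: Paradigm,
    fs: float = 10.0,
) -> tuple[list[Recording], list[ClinicalRecord], dict[str, GroundTruth]]:
    """Simulate a full longitudinal cohort of recordings + clinical table.

    GMFM-88 at the last session equals the baseline score plus
    ``gmfm_link_slope`` × (mean HbO β change on the informative channels)
    plus Gaussian noise, clipped to [0, 100].
    """
    master = np.random.default_rng(spec.seed)
    rec_seeds = np.random.SeedSequence(spec.seed).generate_state(
        spec.n_subjects * len(spec.sessions)
    ) % (2**31)

    recordings: list[Recording] = []
    clinical: list[ClinicalRecord] = []
    truths: dict[str, GroundTruth] = {}
    info = [c - 1 for c in spec.informative_channels]
    for i in range(spec.n_subjects):
        subject = f"S{i + 1:02d}"
        truth = _subject_truth(spec, montage, master)
        truths[subject] = truth
        for j, session in enumerate(spec.sessions):
            recordings.append(
                generate_recording(
                    montage,
                    paradigm,
                    truth,
                    fs=fs,
                    seed=int(rec_seeds[i * len(spec.sessions) + j]),
                    session_index=j,
                    subject=subject,
                    session=session,
                )
            )
        dbeta = float(truth.beta_hbo[-1, info].mean() - truth.beta_hbo[0, info].mean())
        gmfm_t0 = float(master.uniform(10.0, 30.0))
        noise = float(master.normal(0, spec.gmfm_noise_sd)) if spec.gmfm_noise_sd else 0.0
        gmfm_t2 = float(np.clip(gmfm_t0 + spec.gmfm_link_slope * dbeta + noise, 0.0, 100.0))
        mas = {
            joint: {
                "T0": float(master.choice(_MAS_LEVELS)),
                "T2": float(master.choice(_MAS_LEVELS)),
            }
            for joint in ("hip", "knee", "ankle")
        }
        clinical.append(
            ClinicalRecord(
                subject=subject,
                gmfcs=int(master.integers(1, 6)),
                gmfm88={"T0": gmfm_t0, spec.sessions[-1]: gmfm_t2},
                mas=mas,
            )
        )
    return recordings, clinical, truths


def generate_beta_cohort(
    spec: CohortSpec,
    n_channels: int = 34,
    subject_sd: float = 0.15,
    beta_noise_sd: float = 0.08,
    hhb_ratio: float = 1.0 / 3.0,
):
    """Draw a cohort's β-table directly, bypassing the signal chain.

    Model per channel × chromophore: β = channel mean + subject random effect
    + session effect (informative channels only, antiphase for HHb) + noise.
    Intended for group-statistics and regression experiments where hundreds
    of cohorts are needed; the signal-level generator validates that the GLM
    actually delivers such tables.

    Returns a tidy :class:`pandas.DataFrame` (subject, session, channel,
    chromophore, beta) and the matching clinical records.
    """
    import pandas as pd

    rng = np.random.default_rng(spec.seed)
    k = len(spec.sessions)
    info = [c - 1 for c in spec.informative_channels if c <= n_channels]
    ch_mean = rng.normal(0.6, 0.1, size=n_channels)
    rows = []
    clinical = []
    for i in range(spec.n_subjects):
        subject = f"S{i + 1:02d}"
        subj_eff = rng.normal(0, subject_sd, size=n_channels)
        step = rng.normal(spec.beta_step, spec.beta_step_sd, size=len(info))
        dbeta_info = np.zeros(k)
        for s, session in enumerate(spec.sessions):
            beta_hbo = ch_mean + subj_eff + rng.normal(0, beta_noise_sd, n_channels)
            beta_hbo[info] += step * s
            beta_hhb = -hhb_ratio * beta_hbo + rng.normal(0, beta_noise_sd / 3, n_channels)
            dbeta_info[s] = beta_hbo[info].mean()
            for c in range(n_channels):
                rows.append((subject, session, c + 1, "hbo", beta_hbo[c]))
                rows.append((subject, session, c + 1, "hhb", beta_hhb[c]))
        gmfm_t0 = float(rng.uniform(10.0, 30.0))
        noise = float(rng.normal(0, spec.gmfm_noise_sd)) if spec.gmfm_noise_sd else 0.0
        gmfm_t2 = float(
            np.clip(
                gmfm_t0 + spec.gmfm_link_slope * (dbeta_info[-1] - dbeta_info[0]) + noise,
                0.0,
                100.0,
            )
        )
        clinical.append(
            ClinicalRecord(
                subject=subject,
                gmfcs=int(rng.integers(1, 6)),
                gmfm88={"T0": gmfm_t0, spec.sessions[-1]: gmfm_t2},
                mas=None,
            )
        )
    df = pd.DataFrame(rows, columns=["subject", "session", "channel", "chromophore", "beta"])
    return df, clinical
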