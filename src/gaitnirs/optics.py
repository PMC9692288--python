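"""Modified Beer–Lambert law (MBLL) chromophore inversion.

Raw two-wavelength intensities are converted to optical-density changes and
then to oxy-/deoxyhemoglobin concentration changes by solving, per channel and
sample, the 2×2 linear system

    ΔOD(λ) = [ε_HbO(λ)·ΔHbO + ε_HHb(λ)·ΔHHb] · d · DPF(λ)

with d the source–detector separation and DPF the age- and
wavelength-dependent differential pathlength factor.  Natural-log optical
densities are used throughout; the bundled extinction table (base-10
convention, as published) is converted by ln 10 on load.  Concentrations are
expressed in µM.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .montage import Montage
from .recording import Recording

__all__ = [
    "OpticalParameters",
    "HemoTimeSeries",
    "load_extinction_table",
    "compute_dpf",
    "intensity_to_od",
    "forward_mbll",
    "od_to_hemoglobin",
    "recording_to_hemoglobin",
]

_LN10 = float(np.log(10.0))


def load_extinction_table(natural_log: bool = True) -> dict[float, tuple[float, float]]:
    """Bundled molar extinction coefficients, wavelength -> (ε_HbO, ε_HHb).

    Units cm⁻¹/M.  The data file stores the published base-10 values; with
    ``natural_log`` (the package convention) they are multiplied by ln 10.
    """
    path = resources.files("gaitnirs.data") / "extinction_coefficients.csv"
    with path.open() as fh:
        rows = [r for r in csv.reader(fh) if r and not r[0].startswith("#")]
    table: dict[float, tuple[float, float]] = {}
    scale = _LN10 if natural_log else 1.0
    for row in rows[1:]:
        table[float(row[0])] = (float(row[1]) * scale, float(row[2]) * scale)
    return table


def _dpf_coefficients() -> dict:
    path = resources.files("gaitnirs.data") / "dpf_coefficients.json"
    return json.loads(path.read_text())


def compute_dpf(age: float, wavelength: float) -> float:
    """Differential pathlength factor from the general (λ, age) equation.

    A cubic polynomial in wavelength plus a power law in age, evaluated with
    the published coefficient set bundled under ``gaitnirs/data``.

    Parameters
    ----------
    age : years, in [0, 100]
    wavelength : nm, in [700, 900]
    """
    if not 0 <= age <= 100:
        raise ValueError(f"age {age} outside [0, 100] years")
    if not 700 <= wavelength <= 900:
        raise ValueError(f"wavelength {wavelength} nm outside [700, 900]")
    c = _dpf_coefficients()
    dpf = (
        c["alpha"]
        + c["beta"] * age ** c["gamma"]
        + c["delta"] * wavelength**3
        + c["epsilon"] * wavelength**2
        + c["zeta"] * wavelength
    )
    if dpf <= 0:
        raise ValueError("computed DPF is non-positive; inputs outside model validity")
    return float(dpf)


@dataclass
class OpticalParameters:
    """Everything the MBLL inversion needs for one set of channels.

    Attributes
    ----------
    wavelengths
        The two nominal wavelengths, nm.
    extinction
        2×2 matrix ε[wavelength, chromophore] with chromophore order
        (HbO, HHb), units cm⁻¹/M, natural-log convention.
    dpf
        Differential pathlength factor per wavelength (unitless).
    separation_mm
        Source–detector separation per channel, mm.
    """

    wavelengths: tuple[float, float]
    extinction: np.ndarray
    dpf: tuple[float, float]
    separation_mm: np.ndarray

    def __post_init__(self) -> None:
        self.extinction = np.asarray(self.extinction, dtype=float)
        self.separation_mm = np.atleast_1d(np.asarray(self.separation_mm, dtype=float))
        if self.extinction.shape != (2, 2):
            raise ValueError("extinction must be a 2x2 matrix (wavelength x chromophore)")
        if not np.isfinite(np.linalg.cond(self.extinction)) or np.linalg.cond(
            self.extinction
        ) > 1e12:
            raise ValueError("extinction matrix is singular or ill-conditioned")
        if any(d <= 0 for d in self.dpf):
            raise ValueError("DPF must be positive")
        if np.any(self.separation_mm <= 0):
            raise ValueError("separations must be positive")

    @classmethod
    def for_channels(
        cls,
        separation_mm: np.ndarray,
        age: float = 10.0,
        wavelengths: tuple[float, float] = (760.0, 850.0),
    ) -> "OpticalParameters":
        """Default parameters: bundled extinction table and per-age DPF."""
        table = load_extinction_table()
        try:
            eps = np.array([table[w] for w in wavelengths])
        except KeyError as exc:  # pragma: no cover - config error
            raise ValueError(f"no extinction entry for wavelength {exc}") from exc
        dpf = tuple(compute_dpf(age, w) for w in wavelengths)
        return cls(
            wavelengths=wavelengths, extinction=eps, dpf=dpf, separation_mm=separation_mm
        )


@dataclass
class HemoTimeSeries:
    """HbO/HHb concentration-change series (µM) for long and short channels.

    ``hbo``/``hhb`` have shape (n_samples, n_long); ``short_hbo``/``short_hhb``
    shape (n_samples, n_short).  ``time`` is uniform and strictly increasing.
    """

    time: np.ndarray
    hbo: np.ndarray
    hhb: np.ndarray
    short_hbo: np.ndarray
    short_hhb: np.ndarray
    subject: str = "S01"
    session: str = "T0"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        for name in ("hbo", "hhb", "short_hbo", "short_hhb"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.hbo.shape != self.hhb.shape:
            raise ValueError("hbo and hhb must share shape")
        if self.short_hbo.shape != self.short_hhb.shape:
            raise ValueError("short_hbo and short_hhb must share shape")
        dt = np.diff(self.time)
        if self.time.size > 1 and (np.any(dt <= 0) or not np.allclose(dt, dt[0])):
            raise ValueError("time must be strictly increasing and uniform")

    @property
    def fs(self) -> float:
        return 1.0 / float(self.time[1] - self.time[0])

    @property
    def n_long(self) -> int:
        return self.hbo.shape[1]

    @property
    def n_short(self) -> int:
        return self.short_hbo.shape[1]

    def copy(self) -> "HemoTimeSeries":
        return HemoTimeSeries(
            time=self.time.copy(),
            hbo=self.hbo.copy(),
            hhb=self.hhb.copy(),
            short_hbo=self.short_hbo.copy(),
            short_hhb=self.short_hhb.copy(),
            subject=self.subject,
            session=self.session,
            meta=dict(self.meta),
        )


def intensity_to_od(
    intensity: np.ndarray, baseline: slice | None = None
) -> np.ndarray:
    """Optical-density change from raw intensity, natural-log convention.

    OD(t) = −ln(I(t) / Ī_baseline), computed independently per trailing axis
    entry (channel, wavelength).  The baseline intensity Ī is the mean over
    ``baseline`` (a slice along the time axis; default: the whole series).
    A constant series maps to identically zero OD, and a global rescaling of
    the intensity leaves the OD unchanged.
    """
    intensity = np.asarray(intensity, dtype=float)
    ref = intensity if baseline is None else intensity[baseline]
    if ref.shape[0] == 0:
        raise ValueError("baseline window is empty")
    bad = intensity <= 0
    if np.any(bad):
        t, *rest = np.unravel_index(int(np.argmax(bad)), intensity.shape)
        raise ValueError(
            f"non-positive intensity at sample {t}, channel axis index {tuple(rest)}"
        )
    i0 = ref.mean(axis=0)
    return -np.log(intensity / i0)


def _pathlength_cm(params: OpticalParameters) -> np.ndarray:
    # (n_channels, 2): effective pathlength d·DPF per channel and wavelength, cm
    d_cm = params.separation_mm[:, None] / 10.0
    return d_cm * np.asarray(params.dpf)[None, :]


def forward_mbll(
    hbo: np.ndarray, hhb: np.ndarray, params: OpticalParameters
) -> np.ndarray:
    """Map concentration changes (µM) to optical densities.

    Parameters are per-channel; inputs have shape (n_samples, n_channels).
    Returns OD of shape (n_samples, n_channels, 2).
    """
    conc_molar = np.stack([hbo, hhb], axis=-1) * 1e-6  # (n, c, 2) in mol/L
    # OD[n, c, w] = sum_k eps[w, k] * conc[n, c, k] * L[c, w]
    od = np.einsum("wk,nck->ncw", params.extinction, conc_molar)
    return od * _pathlength_cm(params)[None, :, :]


def od_to_hemoglobin(od: np.ndarray, params: OpticalParameters) -> tuple[np.ndarray, np.ndarray]:
    """Invert the MBLL: OD (n_samples, n_channels, 2) -> (ΔHbO, ΔHHb) in µM.

    Exact inverse of :func:`forward_mbll` (a per-channel 2×2 solve).
    """
    od = np.asarray(od, dtype=float)
    if od.ndim != 3 or od.shape[2] != 2:
        raise ValueError("od must be (n_samples, n_channels, 2); missing wavelength axis?")
    if od.shape[1] != params.separation_mm.size:
        raise ValueError(
            f"channel axis mismatch: od has {od.shape[1]} channels, "
            f"params define {params.separation_mm.size} separations"
        )
    scaled = od / _pathlength_cm(params)[None, :, :]  # eps @ conc per (n, c)
    inv = np.linalg.inv(params.extinction)
    conc_molar = np.einsum("kw,ncw->nck", inv, scaled)
    return conc_molar[..., 0] * 1e6, conc_molar[..., 1] * 1e6


def recording_to_hemoglobin(
    recording: Recording,
    age: float = 10.0,
    baseline: slice | None = None,
) -> HemoTimeSeries:
    """Full optics chain for one recording: intensity → OD → HbO/HHb.

    Long and short channels are inverted with their own separations; the DPF
    is computed for the participant's age.
    """
    montage: Montage = recording.montage
    od = intensity_to_od(recording.intensity, baseline=baseline)
    long_idx = [i for i, c in enumerate(montage.channels) if not c.is_short]
    short_idx = [i for i, c in enumerate(montage.channels) if c.is_short]

    params_long = OpticalParameters.for_channels(
        montage.separations_mm(short=False), age=age, wavelengths=recording.wavelengths
    )
    hbo, hhb = od_to_hemoglobin(od[:, long_idx, :], params_long)

    if short_idx:
        params_short = OpticalParameters.for_channels(
            montage.separations_mm(short=True), age=age, wavelengths=recording.wavelengths
        )
        s_hbo, s_hhb = od_to_hemoglobin(od[:, short_idx, :], params_short)
    else:
        s_hbo = np.zeros((recording.n_samples, 0))
        s_hhb = np.zeros((recording.n_samples, 0))

    return HemoTimeSeries(
        time=recording.time,
        hbo=hbo,
        hhb=hhb,
        short_hbo=s_hbo,
        short_hhb=s_hhb,
        subject=recording.subject,
        session=recording.session,
        meta={"age": age, **recording.meta},
    )
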