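"""Waveform-to-spectrum preprocessing and linear-fit spectral features.

Raw A-lines sampled at 250 MHz are turned into calibrated 77x90 log-power
matrices: Welch PSD (Hamming window of 2500 samples, 90% overlap,
nfft = 2500, i.e. 0.1 MHz resolution), selection of the 90 bins at
1.0-9.9 MHz, division by the transducer frequency response and the
per-wavelength pulse-energy calibration in linear power, then 10*log10.

The conventional quantitative features are the parameters of an ordinary
least-squares line fitted to each 90-bin log-power vector: slope (dB/MHz),
intercept (dB) and the midband value ("median") — the fitted line evaluated
at the median analysis frequency, 5.45 MHz.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .synth import Cohort, RawSignalRecord, frequency_grid, wavelength_grid

__all__ = [
    "WelchConfig",
    "CalibrationProfile",
    "FitFeatures",
    "welch_power_spectrum",
    "band_select_and_calibrate",
    "assemble_spectrum_matrix",
    "linear_fit_features",
    "fit_features_matrix",
    "cohort_feature_table",
]


@dataclass(frozen=True)
class WelchConfig:
    """Welch estimator settings (defaults give exactly 0.1 MHz resolution)."""

    window: str = "hamming"
    window_length: int = 2500
    overlap: float = 0.90
    nfft: int = 2500
    fs: float = 250e6

    def validate(self) -> None:
        if not 0.0 <= self.overlap < 1.0:
            raise ValueError("overlap must be in [0, 1)")
        if self.nfft < self.window_length:
            raise ValueError("nfft must be >= window_length")

    @property
    def resolution_hz(self) -> float:
        return self.fs / self.nfft


@dataclass(frozen=True)
class CalibrationProfile:
    """Transducer frequency response (90 bins) and pulse-energy gain (77 wavelengths)."""

    transducer_response: np.ndarray = field(
        default_factory=lambda: np.ones(90)
    )
    wavelength_energy: np.ndarray = field(default_factory=lambda: np.ones(77))

    def validate(self) -> None:
        tr = np.asarray(self.transducer_response, dtype=float)
        we = np.asarray(self.wavelength_energy, dtype=float)
        if tr.shape != (90,) or we.shape != (77,):
            raise ValueError("calibration vectors must be sized 90 and 77")
        if np.any(tr <= 0) or np.any(we <= 0):
            raise ValueError("calibration entries must be positive")


@dataclass(frozen=True)
class FitFeatures:
    """First-order line fit of a band log-power vector."""

    slope: float  # dB/MHz
    intercept: float  # dB
    median: float  # dB, fitted value at the band median frequency
    wavelength: float | None = None  # nm


def welch_power_spectrum(
    record: RawSignalRecord | np.ndarray, cfg: WelchConfig = WelchConfig()
) -> tuple[np.ndarray, np.ndarray]:
    """One-sided Welch PSD (density scaling) of a waveform.

    Returns ``(freqs_hz, psd)``; the frequency axis spacing equals
    ``cfg.fs / cfg.nfft`` (0.1 MHz with the defaults).
    """
    cfg.validate()
    x = record.waveform if isinstance(record, RawSignalRecord) else np.asarray(record)
    fs = record.fs if isinstance(record, RawSignalRecord) else cfg.fs
    if x.size < cfg.window_length:
        raise ValueError(
            f"waveform has {x.size} samples; the Welch window requires at "
            f"least {cfg.window_length}"
        )
    noverlap = int(round(cfg.overlap * cfg.window_length))
    freqs, psd = signal.welch(
        x,
        fs=fs,
        window=signal.get_window(cfg.window, cfg.window_length),
        nperseg=cfg.window_length,
        noverlap=noverlap,
        nfft=cfg.nfft,
        detrend=False,
        scaling="density",
    )
    return freqs, psd


def band_select_and_calibrate(
    psd: np.ndarray,
    freqs_hz: np.ndarray,
    calib: CalibrationProfile = CalibrationProfile(),
    wavelength: float | None = None,
    band_start_mhz: float = 1.0,
) -> np.ndarray:
    """Select the 90 analysis bins and convert to calibrated dB.

    Output bin ``j`` corresponds to ``band_start_mhz + 0.1 j`` MHz
    (1.0-9.9 MHz by default) and equals
    ``10*log10(psd / (transducer_response * wavelength_energy))``.
    """
    calib.validate()
    psd = np.asarray(psd, dtype=float)
    freqs_hz = np.asarray(freqs_hz, dtype=float)
    band_hz = (band_start_mhz + 0.1 * np.arange(90)) * 1e6
    idx = np.searchsorted(freqs_hz, band_hz - 1.0)
    if idx.max() >= freqs_hz.size or np.any(
        np.abs(freqs_hz[idx] - band_hz) > 1e-3 * 1e6
    ):
        raise ValueError("PSD frequency axis does not cover the 1-10 MHz band")
    energy = 1.0
    if wavelength is not None:
        lam = wavelength_grid()
        pos = np.flatnonzero(np.isclose(lam, wavelength))
        if pos.size == 0:
            raise ValueError(f"wavelength {wavelength} nm is not on the grid")
        energy = float(np.asarray(calib.wavelength_energy)[pos[0]])
    band = psd[idx] / (np.asarray(calib.transducer_response, dtype=float) * energy)
    with np.errstate(divide="ignore"):
        return 10.0 * np.log10(band)


def assemble_spectrum_matrix(per_wavelength: dict[float, np.ndarray]) -> np.ndarray:
    """Stack 77 calibrated band vectors (keyed by wavelength, nm) into a matrix.

    Row ``i`` corresponds to grid wavelength ``i``; missing wavelengths
    raise an error listing the gaps.
    """
    lam = wavelength_grid()
    missing = [w for w in lam if not any(np.isclose(w, k) for k in per_wavelength)]
    if missing:
        raise ValueError(
            f"missing {len(missing)} wavelength(s): {missing[:5]}"
            + ("..." if len(missing) > 5 else "")
        )
    rows = []
    for w in lam:
        key = next(k for k in per_wavelength if np.isclose(k, w))
        vec = np.asarray(per_wavelength[key], dtype=float)
        if vec.shape != (90,):
            raise ValueError(f"band vector at {w} nm must have 90 bins")
        rows.append(vec)
    return np.stack(rows)


def linear_fit_features(
    band_vector: np.ndarray,
    frequencies_mhz: np.ndarray | None = None,
    wavelength: float | None = None,
) -> FitFeatures:
    """OLS line fit of a 90-bin log-power vector on frequency (MHz)."""
    y = np.asarray(band_vector, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("band vector must be finite")
    f = frequency_grid() if frequencies_mhz is None else np.asarray(frequencies_mhz)
    slope, intercept = np.polyfit(f, y, 1)
    f_med = float(np.median(f))
    return FitFeatures(
        slope=float(slope),
        intercept=float(intercept),
        median=float(slope * f_med + intercept),
        wavelength=wavelength,
    )


def fit_features_matrix(
    spectra: np.ndarray, frequencies_mhz: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised line fits for a stack of spectrum matrices.

    ``spectra`` is (..., 90); returns ``(slope, intercept, median)`` arrays of
    shape ``spectra.shape[:-1]``.
    """
    y = np.asarray(spectra, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("spectra must be finite")
    f = frequency_grid() if frequencies_mhz is None else np.asarray(frequencies_mhz)
    design = np.stack([f, np.ones_like(f)], axis=1)  # (90, 2)
    coef, *_ = np.linalg.lstsq(design, y.reshape(-1, f.size).T, rcond=None)
    slope = coef[0].reshape(y.shape[:-1])
    intercept = coef[1].reshape(y.shape[:-1])
    f_med = float(np.median(f))
    return slope, intercept, slope * f_med + intercept


def cohort_feature_table(cohort: Cohort):
    """Per-sample, per-wavelength slope/intercept/median features as a DataFrame."""
    import pandas as pd

    slope, intercept, median = fit_features_matrix(
        cohort.spectra, cohort.frequencies_mhz
    )
    n, n_lam = slope.shape
    return pd.DataFrame(
        {
            "sample_id": np.repeat(np.arange(n), n_lam),
            "patient_id": np.repeat(cohort.patient_id, n_lam),
            "system_id": np.repeat(cohort.system_id, n_lam),
            "label": np.repeat(cohort.labels, n_lam),
            "wavelength": np.tile(cohort.wavelengths_nm, n),
            "slope": slope.ravel(),
            "intercept": intercept.ravel(),
            "median": median.ravel(),
        }
    )
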