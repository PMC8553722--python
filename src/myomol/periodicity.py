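"""Sarcomeric striation periodicity by axial Fourier power spectrum.

Collapses a channel onto the cell's long axis (summing intensity over
cross-sections), computes a windowed, zero-padded power spectrum of the
axial profile, and reports a striation period when an in-band spectral
peak stands sufficiently far above the in-band background.  Cardiac
sarcomeres repeat every ~1.65–2 µm, i.e. spatial frequencies of
0.5–0.6 µm⁻¹; the default search band (0.3–0.8 µm⁻¹) brackets that.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import scipy.signal

from .localization import VoxelGrid, _principal_axis

__all__ = ["AxialProfile", "PeriodicityResult", "extract_axial_profile",
           "power_spectrum", "detect_period"]

MIN_SAMPLES = 16


@dataclass
class AxialProfile:
    """Summed intensity vs position along the cell's long axis (µm)."""

    positions: np.ndarray
    intensity: np.ndarray
    cell_id: str = "cell"

    def __post_init__(self) -> None:
        if self.positions.size != self.intensity.size:
            raise ValueError("positions and intensity must align")
        if self.positions.size < MIN_SAMPLES:
            raise ValueError(f"profile needs >= {MIN_SAMPLES} samples for spectral analysis")
        steps = np.diff(self.positions)
        if np.any(steps <= 0):
            raise ValueError("positions must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
            raise ValueError("profile must be uniformly sampled")

    @property
    def step(self) -> float:
        return float(self.positions[1] - self.positions[0])


@dataclass
class PeriodicityResult:
    """Axial power spectrum and, when present, the detected striation peak."""

    frequencies: np.ndarray
    power: np.ndarray
    peak_frequency: float | None = None
    period: float | None = None
    prominence_ratio: float | None = None
    band: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if np.any(self.frequencies < 0):
            raise ValueError("frequencies must be nonnegative")
        if self.peak_frequency is not None and self.period is not None:
            if not np.isclose(self.period, 1.0 / self.peak_frequency):
                raise ValueError("period must be the reciprocal of the peak frequency")


def extract_axial_profile(grid: VoxelGrid, channel: str, cell_mask: np.ndarray,
                          cell_id: str = "cell") -> AxialProfile:
    """Sum a channel over cross-sections perpendicular to the long axis.

    The long axis is the principal second-moment axis of the cell mask;
    intensities of mask voxels are binned along it at the in-plane voxel
    pitch, with positions measured from the cell's proximal end.
    """
    img = grid.channel(channel)
    if not np.any(cell_mask):
        raise ValueError("cell mask is empty")
    _, proj = _principal_axis(cell_mask, grid.voxel_size)
    step = grid.voxel_size[2]
    t = proj - proj.min()
    n_bins = int(np.floor(t.max() / step)) + 1
    if n_bins < MIN_SAMPLES:
        raise ValueError("cell mask spans too few axial bins")
    which = np.minimum((t / step).astype(int), n_bins - 1)
    vals = img[cell_mask].astype(float)
    profile = np.bincount(which, weights=vals, minlength=n_bins)
    positions = (np.arange(n_bins) + 0.5) * step
    return AxialProfile(positions=positions, intensity=profile, cell_id=cell_id)


def power_spectrum(profile: AxialProfile, pad_factor: int = 4,
                   window: str = "hann") -> PeriodicityResult:
    """Magnitude-squared spectrum of the detrended, windowed axial profile.

    Linear detrend (which also removes the mean), a Hann window to control
    leakage, and zero-padding to ``pad_factor`` times the length so the
    frequency grid is fine enough (<= 0.01 µm⁻¹ for a 100 µm cell).
    """
    if pad_factor < 1:
        raise ValueError("pad_factor must be >= 1")
    y = scipy.signal.detrend(profile.intensity.astype(float), type="linear")
    w = scipy.signal.get_window(window, y.size, fftbins=True)
    n_fft = int(pad_factor * y.size)
    spec = np.fft.rfft(y * w, n=n_fft)
    freqs = np.fft.rfftfreq(n_fft, d=profile.step)
    return PeriodicityResult(frequencies=freqs, power=np.abs(spec) ** 2)


def detect_period(result: PeriodicityResult, band: tuple[float, float] = (0.3, 0.8),
                  min_prominence: float = 12.0) -> PeriodicityResult:
    """Report the striation period if an in-band peak is prominent enough.

    The peak is the in-band argmax of the power spectrum and is reported
    only when its power is at least ``min_prominence`` times the median
    in-band power.  Because periodogram bins of an unstructured profile
    are exponentially distributed, their in-band maximum already sits
    ~5–8× above the median for the ~40–50 independent bins a 100 µm cell
    yields; the default of 12 keeps the false-alarm probability at the
    percent level while genuine sarcomeric combs score far higher.
    """
    lo, hi = band
    if not (0 <= lo < hi):
        raise ValueError("band must satisfy 0 <= lo < hi")
    nyquist = float(result.frequencies[-1])
    if hi > nyquist + 1e-12:
        raise ValueError(f"band upper edge {hi} exceeds the Nyquist frequency {nyquist:.3f}")
    sel = (result.frequencies >= lo) & (result.frequencies <= hi)
    if not np.any(sel):
        raise ValueError("no spectral bins inside the band")
    p = result.power[sel]
    f = result.frequencies[sel]
    i = int(np.argmax(p))
    med = float(np.median(p))
    ratio = float(p[i] / med) if med > 0 else np.inf
    if med > 0 and ratio < min_prominence:
        return replace(result, peak_frequency=None, period=None,
                       prominence_ratio=ratio, band=(lo, hi))
    if p[i] <= 0:
        return replace(result, peak_frequency=None, period=None,
                       prominence_ratio=None, band=(lo, hi))
    return replace(result, peak_frequency=float(f[i]), period=float(1.0 / f[i]),
                   prominence_ratio=ratio, band=(lo, hi))
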