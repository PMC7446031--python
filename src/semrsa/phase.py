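"""Morlet-wavelet phase TFRs and circular-distance RDMs.

Oscillatory phase is estimated per item and electrode on a log-spaced
frequency grid (default 4-190 Hz, 60 steps, wavelet cycles rising 5 -> 15)
at a set of output times (default 200-400 ms in 20 ms steps).  At each
(frequency, time) grid point, the item x item dissimilarity is the mean
over electrodes of the circular distance between item phases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import ItemData
from .semantic import RDM


class PhaseRDMError(ValueError):
    pass


@dataclass(frozen=True)
class BandSpec:
    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (0 < self.lo < self.hi):
            raise ValueError(f"invalid band {self.name}: [{self.lo}, {self.hi}]")


#: theta/alpha/beta/low-gamma/high-gamma frequency bands (Hz).
DEFAULT_BANDS = (
    BandSpec("theta", 4.0, 8.0),
    BandSpec("alpha", 9.0, 14.0),
    BandSpec("beta", 15.0, 30.0),
    BandSpec("low_gamma", 30.0, 70.0),
    BandSpec("high_gamma", 70.0, 150.0),
)


@dataclass
class PhaseTFR:
    """Phase angles per (item, electrode, frequency, time)."""

    items: list[str]
    electrodes: list[str]
    freqs: np.ndarray     # Hz, strictly increasing
    times: np.ndarray     # ms
    phases: np.ndarray    # radians in (-pi, pi]
    cycles: np.ndarray    # per-frequency wavelet cycle counts
    undefined: np.ndarray | None = field(default=None)  # mask where amplitude ~ 0

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.phases = np.asarray(self.phases, dtype=float)
        self.cycles = np.asarray(self.cycles, dtype=float)
        expected = (len(self.items), len(self.electrodes), len(self.freqs), len(self.times))
        if self.phases.shape != expected:
            raise ValueError(f"phases shape {self.phases.shape} != {expected}")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")
        if self.undefined is None:
            self.undefined = np.zeros(expected, dtype=bool)


def make_freq_grid(lo: float = 4.0, hi: float = 190.0, n: int = 60) -> np.ndarray:
    """Log-spaced frequency grid: f_i = lo * (hi/lo)**(i/(n-1))."""
    if not (0 < lo < hi) or n < 2:
        raise PhaseRDMError("need 0 < lo < hi and n >= 2")
    return lo * (hi / lo) ** (np.arange(n) / (n - 1))


def cycle_ramp(n: int, first: float = 5.0, last: float = 15.0) -> np.ndarray:
    """Wavelet cycles increasing linearly with frequency index (log-frequency)."""
    return first + (last - first) * np.arange(n) / (n - 1)


def morlet_phase(data: ItemData, freqs: np.ndarray | None = None,
                 times_out: np.ndarray | None = None,
                 cycles: np.ndarray | None = None) -> PhaseTFR:
    """Morlet-wavelet phase at each (item, electrode, frequency, output time).

    The epoch must be long enough that the lowest-frequency wavelet fits
    around every output time (5 cycles at 4 Hz spans 1.25 s).
    """
    from mne.time_frequency import tfr_array_morlet

    freqs = make_freq_grid() if freqs is None else np.asarray(freqs, dtype=float)
    cycles = cycle_ramp(len(freqs)) if cycles is None else np.asarray(cycles, dtype=float)
    if times_out is None:
        times_out = np.arange(200.0, 400.0 + 1e-9, 20.0)
    times_out = np.asarray(times_out, dtype=float)

    half_span_ms = cycles[0] / freqs[0] / 2.0 * 1000.0
    if (times_out.min() - half_span_ms < data.times[0]
            or times_out.max() + half_span_ms > data.times[-1]):
        raise PhaseRDMError(
            f"epoch too short: lowest-frequency wavelet needs +/-{half_span_ms:.0f} ms "
            f"around every output time")

    tfr = tfr_array_morlet(data.values, sfreq=data.fs, freqs=freqs,
                           n_cycles=cycles, output="complex", verbose="error")
    cols = np.array([data.time_index(t) for t in times_out])
    sub = tfr[:, :, :, cols]
    amp = np.abs(sub)
    undefined = amp < np.finfo(float).tiny * 1e3
    phases = np.angle(sub)
    return PhaseTFR(list(data.items), list(data.electrodes), freqs, times_out,
                    phases, cycles, undefined)


def circular_distance(a, b):
    """Shortest angular separation, in [0, pi]: d = pi - |pi - |a - b| mod 2pi|."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return np.pi - np.abs(np.pi - np.abs(a - b) % (2 * np.pi))


def phase_rdm_grid(tfr: PhaseTFR) -> list[list[RDM]]:
    """freq x time grid of circular-distance RDMs.

    dissimilarity(i, j) at each grid point = mean over electrodes of the
    circular distance between the two items' phases there.
    """
    n_items = len(tfr.items)
    if n_items < 2:
        raise PhaseRDMError("need >= 2 items")
    values = _phase_rdm_values(tfr)
    grid: list[list[RDM]] = []
    for fi in range(len(tfr.freqs)):
        grid.append([RDM(list(tfr.items), values[fi, ti], "circular")
                     for ti in range(len(tfr.times))])
    return grid


def _phase_rdm_values(tfr: PhaseTFR) -> np.ndarray:
    """(n_freqs, n_times, n_items, n_items) circular RDM array (vectorized)."""
    ph = tfr.phases  # (items, elec, freq, time)
    if np.any(tfr.undefined):
        per_pair_ok = (~tfr.undefined[:, None] & ~tfr.undefined[None, :]).any(axis=2)
        if not per_pair_ok.all():
            raise PhaseRDMError("undefined phase (zero amplitude) leaves item "
                                "pairs fully masked at some grid points")
    d = circular_distance(ph[:, None], ph[None, :])      # (i, j, elec, freq, time)
    vals = d.mean(axis=2)                                 # (i, j, freq, time)
    vals = np.moveaxis(vals, (2, 3), (0, 1))              # (freq, time, i, j)
    vals = (vals + vals.transpose(0, 1, 3, 2)) / 2.0
    idx = np.arange(vals.shape[-1])
    vals[:, :, idx, idx] = 0.0
    return vals


def band_average(values: np.ndarray, freqs: np.ndarray, times: np.ndarray,
                 band: BandSpec, window=(200.0, 400.0)) -> float:
    """Unweighted mean of a per-(freq, time) grid over a band and closed window."""
    values = np.asarray(values, dtype=float)
    fsel = (freqs >= band.lo) & (freqs <= band.hi)
    tsel = (times >= window[0]) & (times <= window[1])
    if not fsel.any():
        raise PhaseRDMError(f"no grid frequencies in band {band.name} "
                            f"[{band.lo}, {band.hi}] Hz")
    if not tsel.any():
        raise PhaseRDMError(f"no grid times in window {window}")
    return float(values[np.ix_(fsel, tsel)].mean())
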