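"""ECoG preprocessing: notch filtering, baseline correction, bad-channel
detection, common average referencing, ICA-based saccade-component removal,
and repetition averaging into per-item epochs.

All operations are pure: they return new containers and never mutate input.
Times are milliseconds relative to stimulus onset throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

ROI_VOCABULARY = ("MTG", "ITG", "TP", "Fus", "PRC", "other")


class PreprocessError(ValueError):
    pass


@dataclass
class TrialData:
    """Trial x electrode x time voltage epochs with metadata."""

    items: np.ndarray       # (n_trials,) concept name per trial
    sessions: np.ndarray    # (n_trials,) session id per trial
    electrodes: list[str]
    times: np.ndarray       # ms relative to stimulus onset
    fs: float               # Hz
    values: np.ndarray      # (n_trials, n_electrodes, n_times)
    good_mask: np.ndarray | None = None  # per-electrode boolean

    def __post_init__(self) -> None:
        self.items = np.asarray(self.items)
        self.sessions = np.asarray(self.sessions)
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.good_mask is None:
            self.good_mask = np.ones(len(self.electrodes), dtype=bool)
        self.good_mask = np.asarray(self.good_mask, dtype=bool)
        n_tr, n_el, n_t = self.values.shape
        if n_tr != len(self.items) or n_el != len(self.electrodes) or n_t != len(self.times):
            raise ValueError("values shape inconsistent with metadata")
        dt = np.diff(self.times)
        if len(dt) and not np.allclose(dt, 1000.0 / self.fs, atol=1e-6):
            raise ValueError("times must be evenly spaced at 1000/fs ms")

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    def time_index(self, t_ms: float) -> int:
        return int(np.argmin(np.abs(self.times - t_ms)))


@dataclass
class ItemData:
    """Repetition-averaged item x electrode x time epochs."""

    items: list[str]
    electrodes: list[str]
    times: np.ndarray
    fs: float
    values: np.ndarray  # (n_items, n_electrodes, n_times)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.items)) != len(self.items):
            raise ValueError("duplicate items")
        if self.values.shape != (len(self.items), len(self.electrodes), len(self.times)):
            raise ValueError("values shape inconsistent with metadata")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite values")

    def time_index(self, t_ms: float) -> int:
        return int(np.argmin(np.abs(self.times - t_ms)))


@dataclass
class ElectrodeTable:
    """Electrode ids with MNI coordinates and ROI labels."""

    frame: pd.DataFrame  # columns: id, x, y, z, roi, good

    def __post_init__(self) -> None:
        required = {"id", "x", "y", "z", "roi", "good"}
        if not required.issubset(self.frame.columns):
            raise ValueError(f"electrode table needs columns {sorted(required)}")
        if self.frame["id"].duplicated().any():
            raise ValueError("duplicate electrode ids")
        bad = set(self.frame["roi"]) - set(ROI_VOCABULARY)
        if bad:
            raise ValueError(f"unknown ROI labels: {sorted(bad)}")

    def ids_in_roi(self, roi: str, good_only: bool = True) -> list[str]:
        df = self.frame
        sel = df["roi"] == roi
        if good_only:
            sel &= df["good"].astype(bool)
        return list(df.loc[sel, "id"])

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ElectrodeTable":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


@dataclass
class SaccadeTemplate:
    """Waveform convolved with IC activations to detect saccade events."""

    waveform: np.ndarray
    fs: float
    description: str = ""

    def __post_init__(self) -> None:
        self.waveform = np.asarray(self.waveform, dtype=float)
        if self.waveform.size < 3:
            raise ValueError("template must have >= 3 samples")
        if not np.any(self.waveform != 0):
            raise ValueError("template has zero energy")

    @classmethod
    def biphasic(cls, fs: float, w_fast_ms: float = 5.0, w_slow_ms: float = 15.0,
                 duration_ms: float = 120.0) -> "SaccadeTemplate":
        """Biphasic transient: difference of two Gaussians of opposite polarity.

        Emulates the sharp deflection plus slower rebound of a saccadic spike
        potential; widths are Gaussian sigmas in ms.
        """
        t = np.arange(-duration_ms / 2, duration_ms / 2 + 1e-9, 1000.0 / fs)
        fast = np.exp(-0.5 * (t / w_fast_ms) ** 2)
        slow = np.exp(-0.5 * (t / w_slow_ms) ** 2)
        wave = fast - 0.5 * slow
        wave -= wave.mean()
        return cls(wave / np.max(np.abs(wave)), fs, "biphasic difference-of-Gaussians")

    @classmethod
    def from_file(cls, path: str | Path) -> "SaccadeTemplate":
        """Single-column text file; first line '# fs <Hz>'."""
        lines = Path(path).read_text().splitlines()
        if not lines or not lines[0].startswith("# fs"):
            raise ValueError("template file must start with '# fs <Hz>'")
        fs = float(lines[0].split()[2])
        return cls(np.array([float(x) for x in lines[1:] if x.strip()]), fs)

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# fs {self.fs}\n")
            fh.writelines(f"{float(x)!r}\n" for x in self.waveform)


def notch_filter(data: TrialData, line_freqs=(60.0, 120.0, 180.0),
                 width: float = 1.5, order: int = 4) -> TrialData:
    """Zero-phase Butterworth band-stop at each line frequency (width in Hz each side)."""
    nyq = data.fs / 2.0
    if max(line_freqs) >= nyq:
        raise PreprocessError(f"line frequency >= Nyquist ({nyq} Hz)")
    out = data.values
    for f0 in line_freqs:
        sos = signal.butter(order, [f0 - width, f0 + width], btype="bandstop",
                            fs=data.fs, output="sos")
        out = signal.sosfiltfilt(sos, out, axis=-1)
    return replace(data, values=out)


def bandpass_filter(values: np.ndarray, fs: float, lo: float, hi: float,
                    order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the last axis."""
    hi = min(hi, fs / 2.0 * 0.99)
    sos = signal.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, values, axis=-1)


def baseline_correct(data: TrialData, window=(-500.0, 0.0)) -> TrialData:
    """Subtract the mean over the pre-stimulus window per trial and electrode."""
    lo, hi = window
    sel = (data.times >= lo) & (data.times <= hi)
    if not sel.any():
        raise PreprocessError(f"empty baseline window {window}")
    base = data.values[:, :, sel].mean(axis=-1, keepdims=True)
    return replace(data, values=data.values - base)


def detect_bad_channels(data: TrialData, z_thresh: float = 4.0) -> np.ndarray:
    """Good-channel mask: flags robust-z outliers of log total variance and
    any channel containing non-finite samples.  Returns a *good* boolean mask."""
    if len(data.electrodes) < 3:
        raise PreprocessError("need >= 3 electrodes")
    finite = np.all(np.isfinite(data.values), axis=(0, 2))
    var = np.nanvar(data.values, axis=(0, 2))
    logv = np.log(np.where(var > 0, var, np.nan))
    med = np.nanmedian(logv)
    mad = np.nanmedian(np.abs(logv - med))
    scale = 1.4826 * mad if mad > 0 else np.nanstd(logv) or 1.0
    z = (logv - med) / scale
    outlier = np.abs(np.nan_to_num(z, nan=np.inf)) > z_thresh
    return finite & ~outlier


def common_average_reference(data: TrialData) -> TrialData:
    """Subtract the mean over good electrodes at every (trial, time) sample.

    Bad electrodes are excluded from the average but re-referenced too.
    """
    good = data.good_mask
    if good.sum() < 2:
        raise PreprocessError("need >= 2 good electrodes for CAR")
    avg = data.values[:, good, :].mean(axis=1, keepdims=True)
    return replace(data, values=data.values - avg)


def count_saccade_events(activation: np.ndarray, template: SaccadeTemplate,
                         fs: float, n_sd: float = 3.0,
                         min_sep_ms: float = 50.0) -> float:
    """Saccade events/s of one IC activation: peaks of the rectified
    template convolution above mean + n_sd * SD, min separation min_sep_ms."""
    conv = np.abs(np.convolve(activation, template.waveform, mode="same"))
    thresh = conv.mean() + n_sd * conv.std()
    peaks, _ = signal.find_peaks(conv, height=thresh,
                                 distance=max(1, int(round(min_sep_ms / 1000.0 * fs))))
    return len(peaks) / (len(activation) / fs)


def remove_saccade_components(data: TrialData, template: SaccadeTemplate,
                              frac_components: float = 0.75,
                              band=(20.0, 190.0), n_drop: int = 2,
                              seed: int = 0, max_iter: int = 500,
                              tol: float = 1e-4) -> tuple[TrialData, dict]:
    """ICA-based removal of saccade-related components.

    1. FastICA with N = round(frac_components * n_good) components on the
       good channels, concatenated across trials;
    2. a copy of the activations is band-pass filtered to ``band`` (the
       range where saccadic spike potentials dominate ECoG);
    3. filtered activations are convolved with the saccade template and
       suprathreshold peaks counted as events/s;
    4. the ``n_drop`` components with most events/s are subtracted from the
       data, which otherwise keeps its unfiltered content.

    Returns the cleaned data plus a report of per-component event rates and
    dropped indices.
    """
    good_idx = np.flatnonzero(data.good_mask)
    n_good = len(good_idx)
    if n_good < int(np.ceil(1.0 / frac_components)):
        raise PreprocessError(f"too few good electrodes ({n_good}) for ICA")
    n_comp = int(round(frac_components * n_good))
    if n_comp < n_drop + 1:
        raise PreprocessError(f"N={n_comp} components < n_drop+1={n_drop + 1}")
    n_tr, _, n_t = data.values.shape
    X = data.values[:, good_idx, :].transpose(1, 0, 2).reshape(n_good, n_tr * n_t)

    ica = FastICA(n_components=n_comp, random_state=seed, max_iter=max_iter,
                  tol=tol, whiten="unit-variance")
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        S = ica.fit_transform(X.T).T          # (n_comp, samples)
    converged = not any(issubclass(w.category, ConvergenceWarning) for w in caught)
    A = ica.mixing_                            # (n_good, n_comp)
    if not (np.all(np.isfinite(S)) and np.all(np.isfinite(A))):
        raise PreprocessError("ICA produced non-finite unmixing (diverged); "
                              f"n_components={n_comp}, seed={seed}")

    filtered = bandpass_filter(S, data.fs, band[0], band[1])
    rates = np.array([count_saccade_events(f, template, data.fs) for f in filtered])
    dropped = list(np.argsort(-rates)[:n_drop])

    clean = data.values.copy()
    if dropped:
        removed = (A[:, dropped] @ S[dropped]).reshape(n_good, n_tr, n_t)
        clean[:, good_idx, :] -= removed.transpose(1, 0, 2)
    report = {"event_rates": rates.tolist(), "dropped": [int(i) for i in dropped],
              "n_components": n_comp, "seed": seed, "converged": bool(converged),
              "activations": S, "mixing": A}
    return replace(data, values=clean), report


def average_repetitions(data: TrialData, keep_items: list[str]) -> ItemData:
    """Mean over all repetitions of each kept item, combined across sessions.

    Output item order follows ``keep_items``; other items are dropped.
    """
    rows = []
    for item in keep_items:
        sel = data.items == item
        if not sel.any():
            raise PreprocessError(f"item {item!r} has zero trials")
        rows.append(data.values[sel].mean(axis=0))
    return ItemData(list(keep_items), list(data.electrodes), data.times.copy(),
                    data.fs, np.asarray(rows))


def epoch_continuous(values: np.ndarray, fs: float, onsets_ms: np.ndarray,
                     items: np.ndarray, sessions: np.ndarray,
                     electrodes: list[str], window=(-1500.0, 3000.0)) -> TrialData:
    """Cut continuous (electrode x time) data into stimulus-locked epochs."""
    lo, hi = window
    n_lo = int(round(lo / 1000.0 * fs))
    n_hi = int(round(hi / 1000.0 * fs))
    times = np.arange(n_lo, n_hi + 1) / fs * 1000.0
    trials = []
    for onset in onsets_ms:
        c = int(round(onset / 1000.0 * fs))
        if c + n_lo < 0 or c + n_hi >= values.shape[1]:
            raise PreprocessError(f"epoch at onset {onset} ms out of bounds")
        trials.append(values[:, c + n_lo:c + n_hi + 1])
    return TrialData(np.asarray(items), np.asarray(sessions), list(electrodes),
                     times, fs, np.asarray(trials))
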