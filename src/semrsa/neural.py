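"""Sliding-window spatiotemporal neural RDMs.

For each time point, an item's pattern is the concatenation of all ROI
electrodes' samples within +/-half ms of the point; item x item cosine
distances give one RDM per time point across the analysis range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import ElectrodeTable, ItemData
from .semantic import RDM, cosine_rdm


class NeuralRDMError(ValueError):
    pass


@dataclass
class RDMSeries:
    """Time-indexed list of cosine RDMs sharing one item order."""

    items: list[str]
    times: np.ndarray          # ms centers
    rdms: list[RDM]
    roi: str = ""
    window_half_ms: float = 50.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if len(self.rdms) != len(self.times):
            raise ValueError("one RDM per time point required")
        for r in self.rdms:
            if r.items != self.items:
                raise ValueError("all RDMs must share the series item order")

    def stacked(self) -> np.ndarray:
        """(n_times, n_items, n_items) array of the series."""
        return np.stack([r.values for r in self.rdms])

    def vectorized(self) -> np.ndarray:
        """(n_times, n_pairs) strictly-lower-triangle vectors."""
        return np.stack([r.vectorize() for r in self.rdms])


def roi_select(data: ItemData, table: ElectrodeTable, roi: str) -> ItemData:
    """Retain good electrodes labelled with the given ROI, order preserved."""
    from .preprocess import ROI_VOCABULARY
    if roi not in ROI_VOCABULARY:
        raise NeuralRDMError(f"unknown ROI {roi!r}; expected one of {ROI_VOCABULARY}")
    wanted = set(table.ids_in_roi(roi, good_only=True))
    idx = [i for i, e in enumerate(data.electrodes) if e in wanted]
    if not idx:
        raise NeuralRDMError(f"empty-roi: no good electrodes in {roi!r}")
    return ItemData(list(data.items), [data.electrodes[i] for i in idx],
                    data.times.copy(), data.fs, data.values[:, idx, :])


def _window_slice(data: ItemData, t_center: float, half: float) -> slice:
    half_n = int(round(half / 1000.0 * data.fs))
    c = data.time_index(t_center)
    lo, hi = c - half_n, c + half_n
    if lo < 0 or hi >= len(data.times):
        raise NeuralRDMError(
            f"window [{t_center - half}, {t_center + half}] ms outside epoch "
            f"[{data.times[0]}, {data.times[-1]}] ms")
    return slice(lo, hi + 1)


def spatiotemporal_pattern(data: ItemData, t_center: float, half: float = 50.0) -> np.ndarray:
    """Item x p matrix; p = n_electrodes * n_window_samples (closed window)."""
    sl = _window_slice(data, t_center, half)
    n_items = len(data.items)
    return data.values[:, :, sl].reshape(n_items, -1)


def rdm_timecourse(data: ItemData, t_range=(-100.0, 1000.0), half: float = 50.0,
                   roi: str = "") -> RDMSeries:
    """One cosine RDM per recording sample in the closed range ``t_range``."""
    if len(data.items) < 2:
        raise NeuralRDMError("need >= 2 items")
    lo_i = data.time_index(t_range[0])
    hi_i = data.time_index(t_range[1])
    half_n = int(round(half / 1000.0 * data.fs))
    if lo_i - half_n < 0 or hi_i + half_n >= len(data.times):
        raise NeuralRDMError("t_range plus window margins outside epoch")
    centers = np.arange(lo_i, hi_i + 1)
    # windows: (n_times_out, n_items, n_elec * n_win) via stride tricks
    n_items, n_el, _ = data.values.shape
    win = 2 * half_n + 1
    sw = np.lib.stride_tricks.sliding_window_view(data.values, win, axis=-1)
    # sw: (items, elec, starts, win); starts index = center - half_n
    rdms = []
    for c in centers:
        pat = sw[:, :, c - half_n, :].reshape(n_items, n_el * win)
        norms = np.linalg.norm(pat, axis=1)
        if np.any(norms == 0):
            bad = data.items[int(np.flatnonzero(norms == 0)[0])]
            raise NeuralRDMError(f"zero-pattern: item {bad!r} at t={data.times[c]} ms")
        rdms.append(cosine_rdm(list(data.items), pat))
    return RDMSeries(list(data.items), data.times[centers], rdms, roi=roi,
                     window_half_ms=half)


def window_rdm(series_taus: np.ndarray, times: np.ndarray, window=(200.0, 400.0)):
    """Convenience alias: delegates to rsa_inference.window_average_test.

    RSA effects are averaged over time (tau values, not RDMs) within the
    closed window before group testing.
    """
    from .inference import window_average_test
    return window_average_test(series_taus, times, window)
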