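"""Array-container (HDF5) I/O for trial/item data and RDM series."""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np

from .neural import RDMSeries
from .preprocess import ItemData, TrialData
from .semantic import RDM


def _str_array(values) -> np.ndarray:
    return np.array([str(v) for v in values], dtype=h5py.string_dtype())


def _decode(ds) -> list[str]:
    return [x.decode() if isinstance(x, bytes) else str(x) for x in ds[()]]


def save_trial_data(path: str | Path, data: TrialData) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=data.values)
        f.create_dataset("times", data=data.times)
        f.create_dataset("items", data=_str_array(data.items))
        f.create_dataset("sessions", data=np.asarray(data.sessions, dtype=int))
        f.create_dataset("electrodes", data=_str_array(data.electrodes))
        f.create_dataset("good_mask", data=data.good_mask)
        f.attrs["fs"] = data.fs
        f.attrs["kind"] = "trials"


def load_trial_data(path: str | Path) -> TrialData:
    with h5py.File(path, "r") as f:
        return TrialData(np.array(_decode(f["items"])), f["sessions"][()],
                         _decode(f["electrodes"]), f["times"][()],
                         float(f.attrs["fs"]), f["values"][()],
                         f["good_mask"][()])


def save_item_data(path: str | Path, data: ItemData) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=data.values)
        f.create_dataset("times", data=data.times)
        f.create_dataset("items", data=_str_array(data.items))
        f.create_dataset("electrodes", data=_str_array(data.electrodes))
        f.attrs["fs"] = data.fs
        f.attrs["kind"] = "items"


def load_item_data(path: str | Path) -> ItemData:
    with h5py.File(path, "r") as f:
        return ItemData(_decode(f["items"]), _decode(f["electrodes"]),
                        f["times"][()], float(f.attrs["fs"]), f["values"][()])


def save_rdm_series(path: str | Path, series: RDMSeries) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("rdms", data=series.stacked())
        f.create_dataset("times", data=series.times)
        f.create_dataset("items", data=_str_array(series.items))
        f.attrs["roi"] = series.roi
        f.attrs["window_half_ms"] = series.window_half_ms


def load_rdm_series(path: str | Path) -> RDMSeries:
    with h5py.File(path, "r") as f:
        items = _decode(f["items"])
        stacked = f["rdms"][()]
        rdms = [RDM(items, m, "cosine") for m in stacked]
        return RDMSeries(items, f["times"][()], rdms, roi=str(f.attrs["roi"]),
                         window_half_ms=float(f.attrs["window_half_ms"]))
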