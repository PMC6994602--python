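"""HDF5 / TSV serialization of recordings and derived containers.

Raw recordings and band-power epochs are stored as HDF5 (signal matrix,
sampling rate, channel table); task designs as BIDS-style events TSV;
electrode layouts as plain TSV.  Every file written by the pipeline is
stamped with the configuration hash and master seed for provenance.
"""

from __future__ import annotations

import json

import h5py
import numpy as np
import pandas as pd

from .containers import BandPowerEpochs, ElectrodeLayout, RawRecording

__all__ = [
    "save_raw",
    "load_raw",
    "save_band_power",
    "load_band_power",
]


def _write_layout(grp: h5py.Group, layout: ElectrodeLayout) -> None:
    grp.attrs["layout_json"] = layout.table.to_json(orient="records")


def _read_layout(grp: h5py.Group) -> ElectrodeLayout:
    from io import StringIO

    table = pd.read_json(StringIO(grp.attrs["layout_json"]), orient="records")
    return ElectrodeLayout(table=table)


def save_raw(path, raw: RawRecording, *, provenance: dict | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("signal", data=raw.signal, compression="gzip")
        f.attrs["fs"] = raw.fs
        f.attrs["reference"] = raw.reference
        _write_layout(f, raw.layout)
        if provenance:
            f.attrs["provenance"] = json.dumps(provenance)


def load_raw(path) -> RawRecording:
    with h5py.File(path, "r") as f:
        return RawRecording(
            signal=f["signal"][()],
            fs=float(f.attrs["fs"]),
            layout=_read_layout(f),
            reference=str(f.attrs.get("reference", "none")),
        )


def save_band_power(path, bp: BandPowerEpochs, *, provenance: dict | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=bp.data, compression="gzip")
        f.create_dataset("times", data=bp.times)
        f.create_dataset(
            "categories", data=np.array([c.encode() for c in bp.categories])
        )
        f.attrs["channel_names"] = json.dumps(bp.channel_names)
        f.attrs["fs"] = bp.fs
        f.attrs["band"] = bp.band
        f.attrs["baseline_window"] = bp.baseline_window
        f.attrs["smoothing_ms"] = bp.smoothing_ms
        if bp.layout is not None:
            _write_layout(f, bp.layout)
        if provenance:
            f.attrs["provenance"] = json.dumps(provenance)


def load_band_power(path) -> BandPowerEpochs:
    with h5py.File(path, "r") as f:
        layout = _read_layout(f) if "layout_json" in f.attrs else None
        return BandPowerEpochs(
            data=f["data"][()],
            times=f["times"][()],
            categories=np.array([c.decode() for c in f["categories"][()]]),
            channel_names=json.loads(f.attrs["channel_names"]),
            fs=float(f.attrs["fs"]),
            band=str(f.attrs["band"]),
            baseline_window=tuple(f.attrs["baseline_window"]),
            smoothing_ms=float(f.attrs["smoothing_ms"]),
            layout=layout,
        )
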