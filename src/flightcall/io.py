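"""HDF5 serialization for features and context tensors."""

from __future__ import annotations

import json
from dataclasses import asdict

import h5py

from .context import ContextTensor
from .frontend import PcenParams, TimeFreqMatrix


def save_features(path, tfm: TimeFreqMatrix,
                  pcen_params: PcenParams | None = None,
                  context: ContextTensor | None = None) -> None:
    """Write a time-frequency matrix (and optional context tensor) to HDF5."""
    with h5py.File(path, "w") as fh:
        d = fh.create_dataset("features", data=tfm.values)
        d.attrs["frame_rate"] = tfm.frame_rate
        d.attrs["start_time"] = tfm.start_time
        d.attrs["representation"] = tfm.representation
        fh.create_dataset("band_centers", data=tfm.band_centers)
        if pcen_params is not None:
            d.attrs["pcen_params"] = json.dumps(asdict(pcen_params))
        if context is not None:
            c = fh.create_dataset("context", data=context.values)
            c.attrs["window_span"] = context.window_span
            c.attrs["frame_period"] = context.frame_period
            fh.create_dataset("context_times", data=context.frame_times)
            fh.create_dataset("context_bands", data=context.band_centers)
            fh.create_dataset("quantile_levels", data=context.quantile_levels)


def load_features(path):
    """Read back (TimeFreqMatrix, PcenParams | None, ContextTensor | None)."""
    with h5py.File(path, "r") as fh:
        d = fh["features"]
        tfm = TimeFreqMatrix(values=d[()],
                             frame_rate=float(d.attrs["frame_rate"]),
                             band_centers=fh["band_centers"][()],
                             representation=str(d.attrs["representation"]),
                             start_time=float(d.attrs["start_time"]))
        params = None
        if "pcen_params" in d.attrs:
            params = PcenParams(**json.loads(d.attrs["pcen_params"]))
        context = None
        if "context" in fh:
            c = fh["context"]
            context = ContextTensor(values=c[()],
                                    frame_times=fh["context_times"][()],
                                    band_centers=fh["context_bands"][()],
                                    quantile_levels=fh["quantile_levels"][()],
                                    window_span=float(c.attrs["window_span"]),
                                    frame_period=float(c.attrs["frame_period"]))
    return tfm, params, context
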