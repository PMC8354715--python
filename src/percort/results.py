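"""Results HDF5 serialization for the main analysis products."""

from __future__ import annotations

import h5py
import numpy as np

from .connectivity import ISPCMap
from .phase_locking import ITPCMap
from .timefreq import PowerMap, Spectrum

__all__ = ["save_powermap", "save_spectrum", "save_itpc", "save_ispc", "save_pcist"]


def _attrs(group: h5py.Group, params: dict) -> None:
    for k, v in params.items():
        group.attrs[k] = str(v) if isinstance(v, (tuple, list, dict)) else v


def save_powermap(path, pm: PowerMap) -> None:
    with h5py.File(path, "a") as f:
        g = f.require_group("tf")
        for name in ("power_db", "mask"):
            if name in g:
                del g[name]
        g.create_dataset("power_db", data=pm.values)
        if pm.mask is not None:
            g.create_dataset("mask", data=pm.mask)
        g.create_dataset("frequencies_hz", data=pm.frequencies) if "frequencies_hz" not in g else None
        g.create_dataset("time_s", data=pm.time_axis) if "time_s" not in g else None
        _attrs(g, {"baseline": pm.baseline, **pm.params})


def save_spectrum(path, spec: Spectrum) -> None:
    with h5py.File(path, "a") as f:
        if "spectrum" in f:
            del f["spectrum"]
        g = f.create_group("spectrum")
        g.create_dataset("frequencies_hz", data=spec.frequencies)
        g.create_dataset("power", data=spec.power)
        g.attrs["n_epochs"] = spec.n_epochs
        g.attrs["normalization"] = "|FFT/N|^2, one-sided reading of the two-sided spectrum"


def save_itpc(path, itpc: ITPCMap, drop_s: np.ndarray | None = None) -> None:
    with h5py.File(path, "a") as f:
        if "itpc" in f:
            del f["itpc"]
        g = f.create_group("itpc")
        g.create_dataset("values", data=itpc.values)
        if itpc.mask is not None:
            g.create_dataset("mask", data=itpc.mask)
        if drop_s is not None:
            g.create_dataset("drop_s", data=drop_s)
        g.create_dataset("frequencies_hz", data=itpc.frequencies)
        g.create_dataset("time_s", data=itpc.time_axis)
        _attrs(g, itpc.params)


def save_ispc(path, ispc: ISPCMap, cd: dict | None = None) -> None:
    with h5py.File(path, "a") as f:
        if "ispc" in f:
            del f["ispc"]
        g = f.create_group("ispc")
        g.create_dataset("values", data=ispc.values)
        if ispc.corrected is not None:
            g.create_dataset("corrected_masked", data=ispc.corrected)
        if ispc.excluded is not None:
            g.create_dataset("excluded", data=ispc.excluded)
        g.create_dataset("pairs", data=np.asarray(ispc.pairs))
        g.create_dataset("frequencies_hz", data=ispc.frequencies)
        g.create_dataset("time_s", data=ispc.time_axis)
        _attrs(g, ispc.params)
        if cd:
            gc = f.require_group("cd")
            for key, val in cd.items():
                if key in gc:
                    del gc[key]
                gc.create_dataset(key, data=np.asarray(val))


def save_pcist(path, result, timecourse=None) -> None:
    with h5py.File(path, "a") as f:
        if "pcist" in f:
            del f["pcist"]
        g = f.create_group("pcist")
        g.attrs["value"] = result.value
        g.attrs["n_components"] = result.n_components
        g.create_dataset("nst", data=result.dnst)
        g.create_dataset("snr", data=result.snr)
        _attrs(g, {
            "baseline_window": result.params.baseline_window,
            "response_window": result.params.response_window,
            "snr_min": result.params.snr_min,
            "max_var": result.params.max_var,
        })
        if timecourse is not None:
            g.create_dataset("timecourse_starts_s", data=timecourse.starts_s)
            g.create_dataset("timecourse", data=timecourse.values)
            g.attrs["fixed_window_value"] = timecourse.fixed_value
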