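"""HDF5 / TSV / JSON serialisation of the pipeline's artifacts."""

from __future__ import annotations

import json

import h5py
import numpy as np
import pandas as pd

from .signals import EEGEpochs, RoiSeries
from .tf import TFRepresentation


def save_signals(path, epochs: EEGEpochs, roi_series: dict,
                 truth: pd.DataFrame | None = None) -> None:
    """Write EEG epochs, ROI BOLD series and ground truth to one HDF5 file."""
    with h5py.File(path, "w") as f:
        g = f.create_group("eeg")
        g.create_dataset("data", data=epochs.data)
        g.create_dataset("time", data=epochs.times)
        g.create_dataset("channels",
                         data=np.array(epochs.channels, dtype="S"))
        g.create_dataset("trial_index", data=epochs.trial_index)
        g.attrs["srate_hz"] = epochs.srate_hz
        g.attrs["lock"] = epochs.lock
        b = f.create_group("bold")
        for label, series in roi_series.items():
            rg = b.create_group(label)
            rg.create_dataset("values", data=series.values)
            rg.create_dataset("n_volumes_per_session",
                              data=np.asarray(series.n_volumes_per_session))
            if series.spike_flags is not None:
                rg.create_dataset("spike_flags", data=series.spike_flags)
            rg.attrs["tr_s"] = series.tr_s
        if truth is not None:
            t = f.create_group("truth")
            for col in truth.columns:
                vals = truth[col].to_numpy()
                if vals.dtype == object:
                    vals = vals.astype("S")
                t.create_dataset(col, data=vals)


def load_signals(path):
    """Inverse of :func:`save_signals`; returns (epochs, roi_series, truth)."""
    with h5py.File(path, "r") as f:
        g = f["eeg"]
        epochs = EEGEpochs(
            data=g["data"][...], srate_hz=float(g.attrs["srate_hz"]),
            times=g["time"][...],
            channels=tuple(c.decode() for c in g["channels"][...]),
            lock=str(g.attrs["lock"]), trial_index=g["trial_index"][...])
        roi_series = {}
        for label in f["bold"]:
            rg = f["bold"][label]
            roi_series[label] = RoiSeries(
                label=label, values=rg["values"][...],
                tr_s=float(rg.attrs["tr_s"]),
                n_volumes_per_session=list(rg["n_volumes_per_session"][...]),
                spike_flags=(rg["spike_flags"][...]
                             if "spike_flags" in rg else None))
        truth = None
        if "truth" in f:
            cols = {}
            for col in f["truth"]:
                vals = f["truth"][col][...]
                if vals.dtype.kind == "S":
                    vals = np.char.decode(vals)
                cols[col] = vals
            truth = pd.DataFrame(cols)
    return epochs, roi_series, truth


def save_tfr(path, tfr: TFRepresentation) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("tf")
        g.create_dataset("power", data=tfr.power)
        g.create_dataset("freqs", data=tfr.freqs)
        g.create_dataset("times", data=tfr.times)
        g.create_dataset("channels", data=np.array(tfr.channels, dtype="S"))
        if tfr.trial_index is not None:
            g.create_dataset("trial_index", data=tfr.trial_index)
        g.attrs["unit"] = tfr.unit
        g.attrs["lock"] = tfr.lock
        g.attrs["window_len_s"] = tfr.window_len_s


def load_tfr(path) -> TFRepresentation:
    with h5py.File(path, "r") as f:
        g = f["tf"]
        return TFRepresentation(
            power=g["power"][...], freqs=g["freqs"][...],
            times=g["times"][...],
            channels=tuple(c.decode() for c in g["channels"][...]),
            unit=str(g.attrs["unit"]), lock=str(g.attrs["lock"]),
            window_len_s=float(g.attrs["window_len_s"]),
            trial_index=(g["trial_index"][...] if "trial_index" in g
                         else None))


def save_bmaps(path, bmaps: list) -> None:
    """Write per-participant b-maps: ``bmap/<regressor>/weights`` stacked
    over participants, plus shared axes."""
    with h5py.File(path, "w") as f:
        if not bmaps:
            return
        ref = bmaps[0]
        g = f.create_group("bmap")
        g.create_dataset("freqs", data=ref.freqs)
        g.create_dataset("times", data=ref.times)
        g.create_dataset("channels", data=np.array(ref.channels, dtype="S"))
        g.create_dataset("participants",
                         data=np.array([str(b.participant) for b in bmaps],
                                       dtype="S"))
        for reg in ref.regressors:
            rg = g.create_group(reg)
            rg.create_dataset(
                "weights", data=np.stack([b.weights[reg] for b in bmaps]))
        g.attrs["standardized"] = ref.standardized
        g.attrs["fisher_z"] = ref.fisher_z


def cluster_result_to_dict(res) -> dict:
    """JSON-serialisable summary of a ClusterResult."""
    null = np.asarray(res.null_max_mass)
    return {
        "p_value": res.p_value,
        "observed_max_mass": res.observed_max_mass,
        "threshold_t": res.threshold_t,
        "n_perm": int(res.n_perm),
        "exact": bool(res.exact),
        "null_quantiles": {q: float(np.quantile(null, float(q)))
                           for q in ("0.5", "0.95", "0.99")} if len(null)
                          else {},
        "clusters": [
            {"mass": c.mass, "extent": c.extent,
             "bins": c.bins.tolist()} for c in res.clusters[:20]
        ],
    }


def save_cluster_results(path, results: dict) -> None:
    with open(path, "w") as f:
        json.dump({k: cluster_result_to_dict(v) for k, v in results.items()},
                  f, indent=2, sort_keys=True)
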