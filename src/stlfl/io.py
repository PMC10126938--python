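"""HDF5 / JSON persistence for epochs, sessions and fitted models."""

from __future__ import annotations

import dataclasses
import json

import h5py
import numpy as np

from .discriminant import StlflModel
from .drbm import DrbmModel
from .epochs import EpochSet
from .synthetic import EVENT_DTYPE, ParadigmSpec, SpellerSession

_EPOCH_FIELDS = ("labels", "codes", "char_index", "repetition_index")


def write_epochs(epochs: EpochSet, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data)
        for name in _EPOCH_FIELDS:
            f.create_dataset(name, data=getattr(epochs, name))
        f.attrs["fs"] = epochs.fs
        f.attrs["channel_names"] = json.dumps(epochs.channel_names)


def read_epochs(path) -> EpochSet:
    with h5py.File(path, "r") as f:
        missing = [k for k in ("data", *_EPOCH_FIELDS) if k not in f]
        if missing or "fs" not in f.attrs:
            missing += ["fs"] if "fs" not in f.attrs else []
            raise ValueError(f"epoch file schema violation, missing: {missing}")
        kwargs = {name: f[name][()] for name in _EPOCH_FIELDS}
        names = json.loads(f.attrs.get("channel_names", "[]"))
        return EpochSet(data=f["data"][()], fs=float(f.attrs["fs"]),
                        channel_names=names, **kwargs)


def _paradigm_to_json(p: ParadigmSpec) -> str:
    d = dataclasses.asdict(p)
    d["alphabet"] = list(d["alphabet"])
    return json.dumps(d)


def _paradigm_from_json(s: str) -> ParadigmSpec:
    d = json.loads(s)
    d["alphabet"] = tuple(d["alphabet"])
    return ParadigmSpec(**d)


def write_session(session: SpellerSession, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("signal", data=session.continuous_signal)
        f.create_dataset("events", data=session.events)
        f.attrs["fs"] = session.fs
        f.attrs["paradigm"] = _paradigm_to_json(session.paradigm)
        f.attrs["truth"] = json.dumps(session.truth)
        f.attrs["meta"] = json.dumps(session.meta)


def read_session(path) -> SpellerSession:
    with h5py.File(path, "r") as f:
        for key in ("signal", "events"):
            if key not in f:
                raise ValueError(f"session file schema violation, missing: {key}")
        return SpellerSession(
            continuous_signal=f["signal"][()],
            events=f["events"][()].astype(EVENT_DTYPE),
            paradigm=_paradigm_from_json(f.attrs["paradigm"]),
            truth=json.loads(f.attrs["truth"]),
            fs=float(f.attrs["fs"]),
            meta=json.loads(f.attrs.get("meta", "{}")),
        )


def write_events_csv(session: SpellerSession, path) -> None:
    import pandas as pd

    pd.DataFrame(session.events).to_csv(path, index=False)


def write_stlfl_model(model: StlflModel, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("W", data=model.W)
        f.create_dataset("V", data=model.V)
        f.create_dataset("eigvals_spatial", data=model.eigvals_spatial)
        f.create_dataset("eigvals_temporal", data=model.eigvals_temporal)
        f.create_dataset("convergence_trace", data=np.asarray(model.convergence_trace))
        for key in ("alpha", "beta", "h", "n_iter", "converged", "ridge_eps"):
            f.attrs[key] = getattr(model, key)


def read_stlfl_model(path) -> StlflModel:
    with h5py.File(path, "r") as f:
        return StlflModel(
            W=f["W"][()], V=f["V"][()],
            alpha=float(f.attrs["alpha"]), beta=float(f.attrs["beta"]),
            h=int(f.attrs["h"]),
            eigvals_spatial=f["eigvals_spatial"][()],
            eigvals_temporal=f["eigvals_temporal"][()],
            n_iter=int(f.attrs["n_iter"]),
            converged=bool(f.attrs["converged"]),
            ridge_eps=float(f.attrs["ridge_eps"]),
            convergence_trace=[tuple(row) for row in f["convergence_trace"][()]],
        )


def write_drbm_model(model: DrbmModel, path) -> None:
    with h5py.File(path, "w") as f:
        for key in ("Wvh", "Uyh", "b_v", "c_h", "d_y", "feat_mean", "feat_sd"):
            f.create_dataset(key, data=getattr(model, key))
        f.create_dataset("loss_trace", data=np.asarray(model.loss_trace))


def read_drbm_model(path) -> DrbmModel:
    with h5py.File(path, "r") as f:
        return DrbmModel(
            **{k: f[k][()] for k in
               ("Wvh", "Uyh", "b_v", "c_h", "d_y", "feat_mean", "feat_sd")},
            loss_trace=list(f["loss_trace"][()]),
        )
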