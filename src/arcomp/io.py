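"""Readers and writers for recordings, tensors, models, and tables.

Recordings travel as a plain ``.npy`` array (channels x samples,
microvolts) with a ``.json`` sidecar holding sampling rate, channel
names/positions, segment boundaries and reference. Tensors, lead
fields, fitted models and ground truth use HDF5 containers with named
datasets and attribute metadata; tables are TSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .headmodel import HeadModel, LeadFieldModel, SourceGrid
from .parafac import Parafac, ParafacResults
from .simulate import GroundTruth
from .spectral import EEGRecording, SpectralTensor

__all__ = [
    "save_recording",
    "load_recording",
    "save_spectral_tensor",
    "load_spectral_tensor",
    "save_leadfield",
    "load_leadfield",
    "save_parafac_results",
    "load_parafac_results",
    "save_ground_truth",
    "load_ground_truth",
    "save_table",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def save_recording(recording: EEGRecording, path) -> None:
    path = Path(path).with_suffix(".npy")
    np.save(path, recording.data)
    meta = {
        "sampling_rate": recording.sampling_rate,
        "channel_names": list(recording.channel_names),
        "channel_positions": recording.channel_positions.tolist(),
        "segment_boundaries": recording.segment_boundaries.tolist(),
        "reference": recording.reference,
        "units": "uV",
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def load_recording(path) -> EEGRecording:
    path = Path(path).with_suffix(".npy")
    data = np.load(path)
    meta = json.loads(_sidecar(path).read_text())
    return EEGRecording(
        data=data,
        sampling_rate=meta["sampling_rate"],
        channel_names=meta["channel_names"],
        channel_positions=np.asarray(meta["channel_positions"]),
        segment_boundaries=np.asarray(meta["segment_boundaries"], dtype=int),
        reference=meta.get("reference", "average"),
    )


def save_spectral_tensor(tensor: SpectralTensor, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=tensor.values, compression="gzip")
        f.create_dataset("freqs", data=tensor.freqs)
        f.create_dataset("window_centers", data=tensor.window_centers)
        f.attrs["space_kind"] = tensor.space_kind
        f.attrs["units"] = tensor.units


def load_spectral_tensor(path) -> SpectralTensor:
    with h5py.File(path, "r") as f:
        return SpectralTensor(
            values=f["values"][()],
            freqs=f["freqs"][()],
            window_centers=f["window_centers"][()],
            space_kind=f.attrs["space_kind"],
            units=f.attrs["units"],
        )


def save_leadfield(leadfield: LeadFieldModel, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("gain", data=leadfield.gain)
        f.create_dataset("source_coords", data=leadfield.grid.coords)
        f.create_dataset("adjacency_pairs", data=leadfield.grid.adjacency_pairs)
        f.create_dataset(
            "region_labels",
            data=np.array(leadfield.grid.region_labels, dtype="S32"),
        )
        f.create_dataset("channel_positions", data=leadfield.channel_positions)
        f.attrs["r_adj"] = leadfield.grid.r_adj
        f.attrs["gain_scale"] = leadfield.gain_scale
        f.attrs["shell_radii"] = leadfield.head.radii
        f.attrs["conductivities"] = leadfield.head.conductivities
        f.attrs["channel_names"] = json.dumps(leadfield.channel_names)


def load_leadfield(path) -> LeadFieldModel:
    with h5py.File(path, "r") as f:
        grid = SourceGrid(
            coords=f["source_coords"][()],
            adjacency_pairs=f["adjacency_pairs"][()],
            region_labels=f["region_labels"][()].astype(str),
            r_adj=float(f.attrs["r_adj"]),
        )
        head = HeadModel(
            radii=tuple(f.attrs["shell_radii"]),
            conductivities=tuple(f.attrs["conductivities"]),
        )
        return LeadFieldModel(
            gain=f["gain"][()],
            grid=grid,
            head=head,
            channel_positions=f["channel_positions"][()],
            channel_names=json.loads(f.attrs["channel_names"]),
            gain_scale=float(f.attrs.get("gain_scale", 1.0)),
        )


def save_parafac_results(results: ParafacResults, path) -> None:
    with h5py.File(path, "w") as f:
        for name, mat in zip(("A", "B", "C"), results.factors):
            f.create_dataset(name, data=mat)
        f.attrs["K"] = results.K
        f.attrs["fit"] = results.fit
        f.attrs["corcondia"] = results.corcondia
        f.attrs["n_iterations"] = results.n_iterations
        f.attrs["converged"] = results.converged
        f.attrs["residual_norm"] = results.residual_norm
        f.attrs["fixed_modes"] = json.dumps(list(results.fixed_modes))
        f.create_dataset("fit_history", data=results.fit_history)
        if results.model.freqs is not None:
            f.create_dataset("freqs", data=results.model.freqs)
        if results.model.window_centers is not None:
            f.create_dataset("window_centers", data=results.model.window_centers)
        f.create_dataset("data", data=results.model.data, compression="gzip")


def load_parafac_results(path) -> ParafacResults:
    with h5py.File(path, "r") as f:
        model = Parafac(f["data"][()], rank=int(f.attrs["K"]))
        if "freqs" in f:
            model.freqs = f["freqs"][()]
        if "window_centers" in f:
            model.window_centers = f["window_centers"][()]
        res = ParafacResults(
            model=model,
            factors=[f["A"][()], f["B"][()], f["C"][()]],
            fit=float(f.attrs["fit"]),
            fit_history=f["fit_history"][()],
            n_iterations=int(f.attrs["n_iterations"]),
            converged=bool(f.attrs["converged"]),
            residual_norm=float(f.attrs["residual_norm"]),
            start_index=0,
        )
        res._corcondia = float(f.attrs["corcondia"])
        return res


def save_ground_truth(truth: GroundTruth, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("frequency_profiles", data=truth.true_frequency_profiles)
        f.create_dataset("spatial_profiles", data=truth.true_spatial_profiles)
        if truth.true_channel_profiles is not None:
            f.create_dataset("channel_profiles", data=truth.true_channel_profiles)
        f.create_dataset("temporal_profiles", data=truth.true_temporal_profiles)
        f.create_dataset("freqs", data=truth.freqs)
        f.create_dataset("window_centers", data=truth.window_centers)
        f.attrs["labels"] = json.dumps(list(truth.labels))
        if truth.loadings is not None:
            g = f.create_group("loadings")
            for k, v in truth.loadings.items():
                g.create_dataset(k, data=v)


def load_ground_truth(path) -> GroundTruth:
    with h5py.File(path, "r") as f:
        loadings = None
        if "loadings" in f:
            loadings = {k: f["loadings"][k][()] for k in f["loadings"]}
        return GroundTruth(
            labels=json.loads(f.attrs["labels"]),
            true_frequency_profiles=f["frequency_profiles"][()],
            true_spatial_profiles=f["spatial_profiles"][()],
            true_channel_profiles=(
                f["channel_profiles"][()] if "channel_profiles" in f else None
            ),
            true_temporal_profiles=f["temporal_profiles"][()],
            freqs=f["freqs"][()],
            window_centers=f["window_centers"][()],
            loadings=loadings,
        )


def save_table(table: pd.DataFrame, path, index: bool = False) -> None:
    table.to_csv(path, sep="\t", index=index)
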