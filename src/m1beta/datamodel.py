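"""Shared domain types and spike/LFP I/O.

The pipeline's universal currency is the :class:`SpikeTrainSet`: per-neuron
spike times in seconds together with population/layer labels and 3-D soma
positions (x, z horizontal; y = cortical depth from the pia, increasing
downward, all in micrometres).  Extracellular recordings travel as
:class:`LFPRecording` objects.

Two on-disk representations are supported for spikes:

* a plain CSV table, one row per spike
  (``neuron_id,time_s,population,layer,x_um,y_um,z_um``);
* an NWB-style HDF5 layout (a ``units`` group holding ragged
  ``spike_times``/``spike_times_index`` datasets plus aligned label columns),
  read and written directly through :mod:`h5py`.

Spike times are stored as 64-bit floats in seconds and compared at 1 µs
tolerance, which is finer than any analysis bin used downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "SpikeTrainSet",
    "LFPRecording",
    "AnalysisWindow",
    "FormatError",
    "read_spikes",
    "write_spikes",
    "read_lfp",
    "write_lfp",
    "slice_window",
]

#: resolution (seconds) at which spike times are considered identical
TIME_RESOLUTION = 1e-6

#: canonical population vocabulary used across the package
KNOWN_POPULATIONS = (
    "IT2/3", "IT4", "IT5A", "IT5B", "PT5B", "IT6", "CT6",
    "PV2/3", "PV5A", "PV5B", "PV6",
    "SOM2/3", "SOM5A", "SOM5B", "SOM6",
)


class FormatError(ValueError):
    """Raised when a spike or LFP file lacks the expected structure."""


@dataclass(frozen=True)
class AnalysisWindow:
    """Half-open time interval ``[t_start, t_stop)`` in seconds."""

    t_start: float
    t_stop: float

    def __post_init__(self) -> None:
        if not self.t_stop > self.t_start:
            raise ValueError(
                f"t_stop ({self.t_stop}) must exceed t_start ({self.t_start})"
            )

    @property
    def duration(self) -> float:
        return self.t_stop - self.t_start

    def intersect(self, other: "AnalysisWindow") -> "AnalysisWindow":
        lo = max(self.t_start, other.t_start)
        hi = min(self.t_stop, other.t_stop)
        if hi <= lo:
            raise ValueError(f"windows {self} and {other} do not overlap")
        return AnalysisWindow(lo, hi)


@dataclass
class SpikeTrainSet:
    """Per-neuron spike trains with labels and soma positions.

    Parameters
    ----------
    neurons
        Table with one row per neuron; columns ``neuron_id`` (int),
        ``population``, ``layer`` (str) and ``x_um``, ``y_um``, ``z_um``
        (float, micrometres; y is depth from the pia).
    spike_neuron_ids, spike_times
        Flat, aligned arrays; times in seconds, sorted within each neuron.
    window
        Observation interval; all spikes lie inside it.
    """

    neurons: pd.DataFrame
    spike_neuron_ids: np.ndarray
    spike_times: np.ndarray
    window: AnalysisWindow = field(default_factory=lambda: AnalysisWindow(0.0, 1.0))

    NEURON_COLUMNS = ("neuron_id", "population", "layer", "x_um", "y_um", "z_um")

    def __post_init__(self) -> None:
        self.neurons = self.neurons.reset_index(drop=True)
        for col in ("neuron_id", "population"):
            if col not in self.neurons.columns:
                raise ValueError(f"neuron table missing column {col!r}")
        for col in ("layer",):
            if col not in self.neurons.columns:
                self.neurons[col] = ""
        for col in ("x_um", "y_um", "z_um"):
            if col not in self.neurons.columns:
                self.neurons[col] = 0.0
        self.spike_neuron_ids = np.asarray(self.spike_neuron_ids, dtype=np.int64)
        self.spike_times = np.asarray(self.spike_times, dtype=np.float64)
        if self.spike_neuron_ids.shape != self.spike_times.shape:
            raise ValueError("spike id and time arrays must be aligned")
        # canonical order: by neuron, then time
        order = np.lexsort((self.spike_times, self.spike_neuron_ids))
        self.spike_neuron_ids = self.spike_neuron_ids[order]
        self.spike_times = self.spike_times[order]
        self._validate()

    def _validate(self) -> None:
        ids = set(self.neurons["neuron_id"].to_numpy())
        if len(ids) != len(self.neurons):
            raise ValueError("duplicate neuron_id in neuron table")
        if self.spike_times.size:
            stray = set(np.unique(self.spike_neuron_ids)) - ids
            if stray:
                raise ValueError(f"spikes reference unknown neurons {sorted(stray)[:5]}")
            lo, hi = self.spike_times.min(), self.spike_times.max()
            if lo < self.window.t_start - TIME_RESOLUTION or hi > self.window.t_stop + TIME_RESOLUTION:
                raise ValueError(
                    f"spike times [{lo}, {hi}] fall outside window {self.window}"
                )
            same = np.diff(self.spike_neuron_ids) == 0
            if np.any(same & (np.diff(self.spike_times) < TIME_RESOLUTION / 2)):
                raise ValueError("duplicate (neuron_id, time) pair at stored resolution")

    # -- accessors ---------------------------------------------------------

    @property
    def n_neurons(self) -> int:
        return len(self.neurons)

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)

    @property
    def populations(self) -> list[str]:
        return sorted(self.neurons["population"].unique())

    def spike_times_for(self, neuron_id: int) -> np.ndarray:
        mask = self.spike_neuron_ids == neuron_id
        return self.spike_times[mask]

    def trains(self) -> dict[int, np.ndarray]:
        """Spike times keyed by neuron id (neurons with no spikes included)."""
        out: dict[int, np.ndarray] = {
            int(i): np.empty(0) for i in self.neurons["neuron_id"]
        }
        if self.spike_times.size:
            ids, starts = np.unique(self.spike_neuron_ids, return_index=True)
            bounds = np.append(starts, self.spike_times.size)
            for i, nid in enumerate(ids):
                out[int(nid)] = self.spike_times[bounds[i]:bounds[i + 1]]
        return out

    def select(self, populations: Iterable[str]) -> "SpikeTrainSet":
        pops = set(populations)
        tab = self.neurons[self.neurons["population"].isin(pops)]
        keep = np.isin(self.spike_neuron_ids, tab["neuron_id"].to_numpy())
        return SpikeTrainSet(tab, self.spike_neuron_ids[keep],
                             self.spike_times[keep], self.window)

    def to_dataframe(self) -> pd.DataFrame:
        """Flat one-row-per-spike table with neuron annotations attached."""
        spikes = pd.DataFrame({
            "neuron_id": self.spike_neuron_ids,
            "time_s": self.spike_times,
        })
        return spikes.merge(self.neurons, on="neuron_id", how="left")

    @classmethod
    def from_trains(
        cls,
        trains: Mapping[int, Sequence[float]],
        window: AnalysisWindow,
        neurons: pd.DataFrame | None = None,
        population: str = "synthetic",
    ) -> "SpikeTrainSet":
        """Build from a ``{neuron_id: spike_times}`` mapping."""
        if neurons is None:
            neurons = pd.DataFrame({
                "neuron_id": sorted(trains),
                "population": population,
                "layer": "",
                "x_um": 0.0, "y_um": 0.0, "z_um": 0.0,
            })
        ids = np.concatenate(
            [np.full(len(trains[k]), k, dtype=np.int64) for k in sorted(trains)]
        ) if trains else np.empty(0, dtype=np.int64)
        ts = np.concatenate(
            [np.asarray(trains[k], dtype=float) for k in sorted(trains)]
        ) if trains else np.empty(0)
        return cls(neurons, ids, ts, window)


@dataclass
class LFPRecording:
    """Multi-depth extracellular potential time series.

    ``samples`` is ``(n_samples, n_channels)`` in millivolts; channels are
    ordered by electrode depth (µm from the pia).  ``sigma`` is the assumed
    extracellular conductivity in mS/mm.
    """

    electrode_depths_um: np.ndarray
    samples: np.ndarray
    fs: float
    sigma: float = 0.3
    t_start: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim == 1:
            self.samples = self.samples[:, None]
        self.electrode_depths_um = np.atleast_1d(
            np.asarray(self.electrode_depths_um, dtype=float)
        )
        if self.samples.ndim != 2:
            raise ValueError("samples must be 2-D (time x channel)")
        if self.samples.shape[1] != self.electrode_depths_um.size:
            raise ValueError("one depth per channel required")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        order = np.argsort(self.electrode_depths_um, kind="stable")
        self.electrode_depths_um = self.electrode_depths_um[order]
        self.samples = self.samples[:, order]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]

    @property
    def times(self) -> np.ndarray:
        return self.t_start + np.arange(self.samples.shape[0]) / self.fs


# ---------------------------------------------------------------------------
# spike I/O
# ---------------------------------------------------------------------------

_HDF5_SUFFIXES = {".nwb", ".h5", ".hdf5"}


def _is_hdf5(path: Path) -> bool:
    if path.suffix.lower() in _HDF5_SUFFIXES:
        return True
    try:
        return h5py.is_hdf5(str(path))
    except OSError:
        return False


def read_spikes(
    path: str | Path,
    population_filter: Iterable[str] | None = None,
) -> SpikeTrainSet:
    """Read a :class:`SpikeTrainSet` from CSV or an NWB-style HDF5 file.

    Unknown populations in ``population_filter`` trigger a warning and are
    dropped; the window is taken from file metadata when present, else
    ``(0, max spike time)``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if _is_hdf5(path):
        sts = _read_spikes_hdf5(path)
    else:
        sts = _read_spikes_csv(path)
    if population_filter is not None:
        wanted = set(population_filter)
        present = set(sts.neurons["population"].unique())
        missing = wanted - present
        if missing:
            warnings.warn(
                f"populations {sorted(missing)} not present in {path.name}; excluded",
                stacklevel=2,
            )
        sts = sts.select(wanted & present)
    return sts


def _read_spikes_csv(path: Path) -> SpikeTrainSet:
    df = pd.read_csv(path)
    required = {"neuron_id", "time_s", "population"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: spike CSV needs columns {sorted(required)}")
    meta_cols = [c for c in SpikeTrainSet.NEURON_COLUMNS if c in df.columns]
    if df.empty:
        neurons = pd.DataFrame(columns=list(SpikeTrainSet.NEURON_COLUMNS))
        neurons = neurons.astype({"neuron_id": np.int64})
        return SpikeTrainSet(neurons, [], [], AnalysisWindow(0.0, TIME_RESOLUTION))
    neurons = df[meta_cols].drop_duplicates("neuron_id")
    window = AnalysisWindow(0.0, float(df["time_s"].max()) + TIME_RESOLUTION)
    return SpikeTrainSet(
        neurons, df["neuron_id"].to_numpy(), df["time_s"].to_numpy(), window
    )


def _read_spikes_hdf5(path: Path) -> SpikeTrainSet:
    with h5py.File(path, "r") as f:
        units = f.get("units")
        if units is None or "spike_times" not in units:
            raise FormatError(f"{path}: no units table with spike times")
        times = units["spike_times"][()]
        index = units["spike_times_index"][()] if "spike_times_index" in units \
            else np.array([len(times)])
        ids = units["id"][()] if "id" in units else np.arange(len(index))
        n = len(index)
        # label columns are discovered at runtime: deposited files may use
        # different column names for the population annotation
        def column(*names, default):
            for name in names:
                if name in units:
                    col = units[name][()]
                    if col.dtype.kind in "OS":
                        col = np.array([v.decode() if isinstance(v, bytes) else str(v)
                                        for v in col])
                    return col
            return np.full(n, default)

        pop = column("population", "cell_type", "pop", "location", default="unknown")
        layer = column("layer", default="")
        x = column("x_um", "x", default=0.0).astype(float)
        y = column("y_um", "y", default=0.0).astype(float)
        z = column("z_um", "z", default=0.0).astype(float)
        t_start = float(units.attrs.get("t_start", f.attrs.get("t_start", 0.0)))
        t_stop = units.attrs.get("t_stop", f.attrs.get("t_stop", None))

    if len(times) == 0 and n == 0:
        neurons = pd.DataFrame(columns=list(SpikeTrainSet.NEURON_COLUMNS))
        neurons = neurons.astype({"neuron_id": np.int64})
        return SpikeTrainSet(neurons, [], [], AnalysisWindow(0.0, TIME_RESOLUTION))

    neurons = pd.DataFrame({
        "neuron_id": np.asarray(ids, dtype=np.int64),
        "population": pop, "layer": layer,
        "x_um": x, "y_um": y, "z_um": z,
    })
    starts = np.concatenate([[0], index[:-1]]).astype(np.int64)
    spike_ids = np.repeat(np.asarray(ids, dtype=np.int64), np.asarray(index) - starts)
    if t_stop is None:
        t_stop = (times.max() if len(times) else 0.0) + TIME_RESOLUTION
    window = AnalysisWindow(t_start, float(t_stop))
    return SpikeTrainSet(neurons, spike_ids, times, window)


def write_spikes(sts: SpikeTrainSet, path: str | Path) -> Path:
    """Write spikes to CSV or to the NWB-style HDF5 units layout."""
    path = Path(path)
    if path.suffix.lower() in _HDF5_SUFFIXES:
        _write_spikes_hdf5(sts, path)
    else:
        sts.to_dataframe().to_csv(path, index=False)
    return path


def _write_spikes_hdf5(sts: SpikeTrainSet, path: Path) -> None:
    trains = sts.trains()
    ids = sorted(trains)
    flat = np.concatenate([trains[i] for i in ids]) if ids else np.empty(0)
    index = np.cumsum([len(trains[i]) for i in ids]).astype(np.int64)
    tab = sts.neurons.set_index("neuron_id").loc[ids] if ids else sts.neurons
    str_dt = h5py.string_dtype()
    with h5py.File(path, "w") as f:
        f.attrs["t_start"] = sts.window.t_start
        f.attrs["t_stop"] = sts.window.t_stop
        units = f.create_group("units")
        units.create_dataset("id", data=np.asarray(ids, dtype=np.int64))
        units.create_dataset("spike_times", data=flat)
        units.create_dataset("spike_times_index", data=index)
        units.create_dataset("population", data=tab["population"].astype(str).to_numpy(),
                             dtype=str_dt)
        units.create_dataset("layer", data=tab["layer"].astype(str).to_numpy(),
                             dtype=str_dt)
        for col in ("x_um", "y_um", "z_um"):
            units.create_dataset(col, data=tab[col].to_numpy(dtype=float))


# ---------------------------------------------------------------------------
# LFP I/O
# ---------------------------------------------------------------------------

def read_lfp(path: str | Path) -> LFPRecording:
    """Read an :class:`LFPRecording` from an NWB-style HDF5 file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with h5py.File(path, "r") as f:
        grp = None
        for candidate in ("acquisition/LFP", "processing/ecephys/LFP", "LFP"):
            if candidate in f:
                grp = f[candidate]
                break
        if grp is None or "data" not in grp:
            raise FormatError(f"{path}: no LFP electrical series found")
        data = grp["data"][()]
        if data.ndim == 1:
            data = data[:, None]
        if "rate" not in grp["data"].attrs and "rate" not in grp.attrs:
            raise FormatError(f"{path}: LFP series lacks rate metadata")
        fs = float(grp["data"].attrs.get("rate", grp.attrs.get("rate")))
        depths = grp["electrode_depths_um"][()] if "electrode_depths_um" in grp \
            else np.arange(data.shape[1], dtype=float)
        sigma = float(grp.attrs.get("sigma_mS_per_mm", 0.3))
        t_start = float(grp["data"].attrs.get("starting_time", 0.0))
    return LFPRecording(depths, data, fs, sigma=sigma, t_start=t_start)


def write_lfp(lfp: LFPRecording, path: str | Path) -> Path:
    path = Path(path)
    with h5py.File(path, "a") as f:
        if "acquisition/LFP" in f:
            del f["acquisition/LFP"]
        grp = f.require_group("acquisition").create_group("LFP")
        d = grp.create_dataset("data", data=lfp.samples)
        d.attrs["rate"] = lfp.fs
        d.attrs["starting_time"] = lfp.t_start
        d.attrs["unit"] = "mV"
        grp.create_dataset("electrode_depths_um", data=lfp.electrode_depths_um)
        grp.attrs["sigma_mS_per_mm"] = lfp.sigma
    return path


# ---------------------------------------------------------------------------
# windowing
# ---------------------------------------------------------------------------

def slice_window(sts: SpikeTrainSet, window: AnalysisWindow) -> SpikeTrainSet:
    """Restrict spikes to ``window`` (half-open), keeping the neuron roster.

    ``window`` must lie within ``sts.window``; slicing twice equals slicing
    by the intersection of the two windows.
    """
    if window.t_start < sts.window.t_start - TIME_RESOLUTION or \
            window.t_stop > sts.window.t_stop + TIME_RESOLUTION:
        raise ValueError(f"window {window} outside data window {sts.window}")
    keep = (sts.spike_times >= window.t_start) & (sts.spike_times < window.t_stop)
    return SpikeTrainSet(
        sts.neurons.copy(), sts.spike_neuron_ids[keep], sts.spike_times[keep], window
    )
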