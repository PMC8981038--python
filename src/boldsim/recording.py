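"""Uniformly sampled multi-variable recordings.

A :class:`TimeSeries` is the common container for everything the package
records or reads: hemodynamic model variables, monitor input signals, and
externally supplied activity traces.  Samples live on a fixed time grid
(``t0 + k*dt``, ``dt`` in milliseconds) so that recordings from different
monitors attached to the same simulation are trivially aligned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class TimeSeries:
    """A uniformly sampled record of named variables.

    Parameters
    ----------
    dt:
        Sampling interval in ms.
    t0:
        Time of the first sample in ms.
    names:
        Variable names, one per column of ``data``.
    data:
        Array of shape ``(n_steps, len(names))``.
    """

    dt: float
    t0: float
    names: list[str]
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim == 1:
            self.data = self.data[:, None]
        if self.data.shape[1] != len(self.names):
            raise ValueError(
                f"data has {self.data.shape[1]} columns for {len(self.names)} names"
            )
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def n_steps(self) -> int:
        return self.data.shape[0]

    @property
    def time(self) -> np.ndarray:
        """Sample times in ms."""
        return self.t0 + self.dt * np.arange(self.n_steps)

    def __getitem__(self, name: str) -> np.ndarray:
        try:
            j = self.names.index(name)
        except ValueError:
            raise KeyError(f"no variable named {name!r} (have {self.names})") from None
        return self.data[:, j]

    def window(self, t_start: float, t_end: float) -> "TimeSeries":
        """Sub-series with t_start <= t < t_end (ms, absolute times)."""
        mask = (self.time >= t_start) & (self.time < t_end)
        idx = np.nonzero(mask)[0]
        if idx.size == 0:
            raise ValueError(f"window [{t_start}, {t_end}) ms contains no samples")
        return TimeSeries(self.dt, float(self.time[idx[0]]), list(self.names),
                          self.data[idx])

    def mean(self, name: str, t_start: float | None = None,
             t_end: float | None = None) -> float:
        """Time average of one variable, optionally over [t_start, t_end) ms."""
        if t_start is None and t_end is None:
            return float(self[name].mean())
        t_start = self.t0 if t_start is None else t_start
        t_end = self.t0 + self.dt * self.n_steps if t_end is None else t_end
        return float(self.window(t_start, t_end)[name].mean())

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.data, columns=self.names)
        df.insert(0, "time_ms", self.time)
        return df

    def to_csv(self, path) -> None:
        """Write as CSV, first column ``time_ms``."""
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TimeSeries":
        df = pd.read_csv(path)
        if "time_ms" not in df.columns:
            raise ValueError("CSV is missing the 'time_ms' column")
        t = df["time_ms"].to_numpy(float)
        if len(t) < 2:
            raise ValueError("need at least two samples to recover the grid")
        dt = float(t[1] - t[0])
        if not np.allclose(np.diff(t), dt, rtol=0, atol=1e-6 * max(dt, 1.0)):
            raise ValueError("CSV samples are not on a uniform grid")
        names = [c for c in df.columns if c != "time_ms"]
        return cls(dt=dt, t0=float(t[0]), names=names,
                   data=df[names].to_numpy(float))

    def to_hdf5(self, path, group: str = "recording") -> None:
        import h5py

        with h5py.File(path, "a") as f:
            if group in f:
                del f[group]
            g = f.create_group(group)
            g.attrs["dt"] = self.dt
            g.attrs["t0"] = self.t0
            g.attrs["names"] = [n.encode() for n in self.names]
            g.create_dataset("data", data=self.data)

    @classmethod
    def from_hdf5(cls, path, group: str = "recording") -> "TimeSeries":
        import h5py

        with h5py.File(path, "r") as f:
            g = f[group]
            names = [n.decode() if isinstance(n, bytes) else str(n)
                     for n in g.attrs["names"]]
            return cls(dt=float(g.attrs["dt"]), t0=float(g.attrs["t0"]),
                       names=names, data=g["data"][...])


def average_timeseries(series: list[TimeSeries]) -> TimeSeries:
    """Arithmetic mean of several aligned recordings (e.g., across seeds).

    All series must share dt, t0, variable names and length.
    """
    if not series:
        raise ValueError("no series to average")
    ref = series[0]
    for s in series[1:]:
        if (s.dt != ref.dt or s.t0 != ref.t0 or s.names != ref.names
                or s.n_steps != ref.n_steps):
            raise ValueError("series are not aligned (dt/t0/names/length differ)")
    data = np.mean([s.data for s in series], axis=0)
    return TimeSeries(ref.dt, ref.t0, list(ref.names), data)
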