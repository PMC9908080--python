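"""Epoched-EEG container with an HDF5 serialization.

Layout of the HDF5 file: datasets ``/data`` (channels x samples x trials,
microvolts, float32), ``/times`` (s, relative to the alignment event),
``/channels`` (names), ``/positions`` (n_channels x 2 head-plane
coordinates) and a ``/trial_table`` group with one dataset per column;
root attributes ``alignment`` ("stimulus" or "response"), ``sfreq`` (Hz)
and ``baseline_corrected``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

__all__ = ["EpochedEEG"]


@dataclass
class EpochedEEG:
    data: np.ndarray  # (n_channels, n_samples, n_trials), microvolts
    times: np.ndarray  # (n_samples,), seconds relative to alignment
    sfreq: float
    ch_names: list[str]
    positions: np.ndarray  # (n_channels, 2)
    trial_table: pd.DataFrame
    alignment: str  # "stimulus" | "response"
    baseline_corrected: bool = False

    def __post_init__(self) -> None:
        n_ch, n_samp, n_trials = self.data.shape
        if len(self.ch_names) != n_ch or self.positions.shape[0] != n_ch:
            raise ValueError("channel metadata does not match data")
        if len(self.times) != n_samp:
            raise ValueError("times length does not match data")
        if len(self.trial_table) != n_trials:
            raise ValueError("trial table rows must equal trial count")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.alignment not in ("stimulus", "response"):
            raise ValueError("alignment must be 'stimulus' or 'response'")

    @property
    def n_trials(self) -> int:
        return self.data.shape[2]

    def time_mask(self, tmin: float, tmax: float) -> np.ndarray:
        return (self.times >= tmin - 1e-9) & (self.times <= tmax + 1e-9)

    def pick_trials(self, idx) -> "EpochedEEG":
        return EpochedEEG(
            data=self.data[:, :, idx],
            times=self.times,
            sfreq=self.sfreq,
            ch_names=list(self.ch_names),
            positions=self.positions,
            trial_table=self.trial_table.iloc[idx].reset_index(drop=True),
            alignment=self.alignment,
            baseline_corrected=self.baseline_corrected,
        )

    def baseline_correct(self, tmin: float, tmax: float) -> "EpochedEEG":
        """Subtract the per-channel, per-trial mean over [tmin, tmax]."""
        m = self.time_mask(tmin, tmax)
        base = self.data[:, m, :].mean(axis=1, keepdims=True)
        out = EpochedEEG(
            data=self.data - base, times=self.times, sfreq=self.sfreq,
            ch_names=list(self.ch_names), positions=self.positions,
            trial_table=self.trial_table, alignment=self.alignment,
            baseline_corrected=True,
        )
        return out

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=self.data.astype(np.float32))
            f.create_dataset("times", data=self.times)
            f.create_dataset(
                "channels", data=np.array(self.ch_names, dtype="S16")
            )
            f.create_dataset("positions", data=self.positions)
            g = f.create_group("trial_table")
            for col in self.trial_table.columns:
                vals = self.trial_table[col].to_numpy()
                if vals.dtype == object:
                    vals = vals.astype("S32")
                g.create_dataset(col, data=vals)
            g.attrs["columns"] = np.array(
                list(self.trial_table.columns), dtype="S32"
            )
            f.attrs["alignment"] = self.alignment
            f.attrs["sfreq"] = self.sfreq
            f.attrs["baseline_corrected"] = self.baseline_corrected

    @classmethod
    def from_hdf5(cls, path) -> "EpochedEEG":
        with h5py.File(path, "r") as f:
            cols = [c.decode() for c in f["trial_table"].attrs["columns"]]
            table = {}
            for col in cols:
                vals = f["trial_table"][col][()]
                if vals.dtype.kind == "S":
                    vals = np.char.decode(vals)
                table[col] = vals
            return cls(
                data=f["data"][()].astype(np.float64),
                times=f["times"][()],
                sfreq=float(f.attrs["sfreq"]),
                ch_names=[c.decode() for c in f["channels"][()]],
                positions=f["positions"][()],
                trial_table=pd.DataFrame(table),
                alignment=str(f.attrs["alignment"]),
                baseline_corrected=bool(f.attrs["baseline_corrected"]),
            )
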