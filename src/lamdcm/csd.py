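"""Cross-spectral density container and file formats.

A CSD is a complex channel-by-channel matrix per frequency: the
frequency-resolved second moment between laminar channels.  It is both the
data feature fitted by the inversion machinery and the output of the
spectral forward model.  Files are written either as HDF5 (datasets
``/freqs``, ``/csd_re``, ``/csd_im``, ``/channels``) or as long-format CSV
(``freq, ch_i, ch_j, re, im``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

FORMAT_VERSION = "1.0"

__all__ = ["CrossSpectralDensity", "validate_frequency_grid", "FORMAT_VERSION"]


def validate_frequency_grid(freqs: np.ndarray, nyquist: float | None = None) -> np.ndarray:
    """Return a validated strictly increasing, positive frequency grid (Hz)."""
    f = np.asarray(freqs, dtype=float).reshape(-1)
    if f.size == 0 or f[0] <= 0:
        raise ValueError("frequency grid must be positive")
    if np.any(np.diff(f) <= 0):
        raise ValueError("frequency grid must be strictly increasing")
    if nyquist is not None and f[-1] > nyquist:
        raise ValueError(f"grid max {f[-1]} Hz exceeds Nyquist {nyquist} Hz")
    return f


@dataclass
class CrossSpectralDensity:
    """Complex CSD matrices on a frequency grid.

    ``values`` has shape (n_freq, n_chan, n_chan), is Hermitian at every
    frequency and has real non-negative diagonals.
    """

    freqs: np.ndarray
    values: np.ndarray
    channels: tuple = ()
    condition: str = ""

    def __post_init__(self):
        self.freqs = validate_frequency_grid(self.freqs)
        self.values = np.asarray(self.values, dtype=complex)
        if self.values.ndim != 3 or self.values.shape[0] != self.freqs.size \
                or self.values.shape[1] != self.values.shape[2]:
            raise ValueError("values must have shape (n_freq, n_chan, n_chan)")
        if not self.channels:
            self.channels = tuple(f"ch{i+1}" for i in range(self.values.shape[1]))
        self.channels = tuple(self.channels)
        if len(self.channels) != self.values.shape[1]:
            raise ValueError("channel labels do not match matrix size")

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    def is_hermitian(self, atol: float = 1e-10) -> bool:
        sym = np.abs(self.values - np.conj(np.swapaxes(self.values, 1, 2)))
        diag_im = np.abs(np.imag(np.diagonal(self.values, axis1=1, axis2=2)))
        scale = max(np.abs(self.values).max(), 1.0)
        return bool(sym.max() <= atol * scale and diag_im.max() <= atol * scale)

    def validate(self, atol: float = 1e-10) -> "CrossSpectralDensity":
        if not self.is_hermitian(atol):
            raise ValueError("CSD is not Hermitian")
        diag = np.real(np.diagonal(self.values, axis1=1, axis2=2))
        if np.any(diag < -atol * max(np.abs(self.values).max(), 1.0)):
            raise ValueError("CSD has negative auto-spectra")
        return self

    def auto_spectrum(self, channel: int) -> np.ndarray:
        return np.real(self.values[:, channel, channel])

    def swap_channels(self) -> "CrossSpectralDensity":
        """Relabel a two-channel CSD (transpose-conjugate of the matrix order)."""
        if self.n_channels != 2:
            raise ValueError("swap_channels is defined for two-channel CSDs")
        perm = [1, 0]
        vals = self.values[:, perm][:, :, perm]
        return CrossSpectralDensity(self.freqs.copy(), vals,
                                    channels=(self.channels[1], self.channels[0]),
                                    condition=self.condition)

    def scaled(self, factor: float) -> "CrossSpectralDensity":
        return CrossSpectralDensity(self.freqs.copy(), self.values * factor,
                                    channels=self.channels, condition=self.condition)

    # -- HDF5 ---------------------------------------------------------------
    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as h:
            # track_times=False keeps files byte-identical across runs
            h.create_dataset("freqs", data=self.freqs, track_times=False)
            h.create_dataset("csd_re", data=np.real(self.values), track_times=False)
            h.create_dataset("csd_im", data=np.imag(self.values), track_times=False)
            h.create_dataset("channels", track_times=False,
                             data=np.array(self.channels, dtype=h5py.string_dtype()))
            h.attrs["condition"] = self.condition
            h.attrs["format_version"] = FORMAT_VERSION

    @classmethod
    def from_hdf5(cls, path) -> "CrossSpectralDensity":
        with h5py.File(path, "r") as h:
            freqs = h["freqs"][:]
            vals = h["csd_re"][:] + 1j * h["csd_im"][:]
            channels = tuple(s.decode() if isinstance(s, bytes) else str(s)
                             for s in h["channels"][:])
            condition = str(h.attrs.get("condition", ""))
        return cls(freqs, vals, channels=channels, condition=condition)

    # -- CSV ----------------------------------------------------------------
    def to_csv(self, path) -> None:
        rows = []
        for i, f in enumerate(self.freqs):
            for a in range(self.n_channels):
                for b in range(self.n_channels):
                    rows.append((f, self.channels[a], self.channels[b],
                                 self.values[i, a, b].real, self.values[i, a, b].imag))
        df = pd.DataFrame(rows, columns=["freq", "ch_i", "ch_j", "re", "im"])
        df.attrs["condition"] = self.condition
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, condition: str = "") -> "CrossSpectralDensity":
        df = pd.read_csv(path)
        channels = tuple(pd.unique(df["ch_i"]))
        idx = {c: i for i, c in enumerate(channels)}
        freqs = np.sort(pd.unique(df["freq"]))
        fidx = {f: i for i, f in enumerate(freqs)}
        vals = np.zeros((freqs.size, len(channels), len(channels)), dtype=complex)
        for _, row in df.iterrows():
            vals[fidx[row["freq"]], idx[row["ch_i"]], idx[row["ch_j"]]] = row["re"] + 1j * row["im"]
        return cls(freqs, vals, channels=channels, condition=condition)
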