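"""Photon-stream container and Photon-HDF5 style file I/O.

A :class:`PhotonStream` is the raw observation sequence of a diffusion-based
single-molecule FRET measurement with pulsed interleaved excitation (PIE):
time-ordered photon arrivals, each tagged with its detection channel
(donor / acceptor) and the excitation period it fell in (donor laser /
acceptor laser).  Arrival times are stored as integer multiples of the
instrument clock period (``tick``), matching time-correlated single-photon
counting hardware.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

__all__ = ["DONOR", "ACCEPTOR", "DEX", "AEX", "PhotonStream"]

#: detection-channel codes
DONOR, ACCEPTOR = 0, 1
#: excitation-period codes
DEX, AEX = 0, 1

#: default clock period, 25 ns (40 MHz sync rate)
DEFAULT_TICK = 25e-9


@dataclass
class PhotonStream:
    """Time-ordered photon arrivals with channel and excitation tags.

    Parameters
    ----------
    ticks : ndarray of int64
        Arrival times in clock-tick units, nondecreasing.
    channel : ndarray of uint8
        ``DONOR`` (0) or ``ACCEPTOR`` (1) per photon.
    excitation : ndarray of uint8
        ``DEX`` (0, donor-laser period) or ``AEX`` (1, acceptor-laser period).
    tick : float
        Clock period in seconds.
    """

    ticks: np.ndarray
    channel: np.ndarray
    excitation: np.ndarray
    tick: float = DEFAULT_TICK
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ticks = np.asarray(self.ticks, dtype=np.int64)
        self.channel = np.asarray(self.channel, dtype=np.uint8)
        self.excitation = np.asarray(self.excitation, dtype=np.uint8)
        if not (len(self.ticks) == len(self.channel) == len(self.excitation)):
            raise ValueError("ticks, channel and excitation must have equal length")
        if self.tick <= 0:
            raise ValueError("tick must be positive")
        if self.ticks.size and np.any(np.diff(self.ticks) < 0):
            raise ValueError("photon arrival times must be nondecreasing")
        bad = (self.channel > 1).any() or (self.excitation > 1).any()
        if bad:
            raise ValueError("channel/excitation tags must be 0 or 1")

    def __len__(self) -> int:
        return len(self.ticks)

    @property
    def times(self) -> np.ndarray:
        """Arrival times in seconds."""
        return self.ticks * self.tick

    def slice(self, i0: int, i1: int) -> "PhotonStream":
        """Sub-stream of photons ``i0:i1`` (metadata shared)."""
        return PhotonStream(
            self.ticks[i0:i1],
            self.channel[i0:i1],
            self.excitation[i0:i1],
            tick=self.tick,
            meta=self.meta,
        )

    # ------------------------------------------------------------------ I/O
    def to_hdf5(self, path) -> None:
        """Write a minimal Photon-HDF5 compatible file.

        Layout follows the Photon-HDF5 convention: ``/photon_data/timestamps``
        (tick units) with ``timestamps_specs/timestamps_unit``, and
        ``/photon_data/detectors``.  The PIE excitation tag is stored as the
        extra integer dataset ``/photon_data/excitation`` (0 = donor laser,
        1 = acceptor laser) since no nanotimes are simulated.
        """
        with h5py.File(path, "w") as f:
            g = f.create_group("photon_data")
            g.create_dataset("timestamps", data=self.ticks)
            g.create_dataset("detectors", data=self.channel)
            g.create_dataset("excitation", data=self.excitation)
            g.create_group("timestamps_specs").create_dataset(
                "timestamps_unit", data=float(self.tick)
            )
            f.attrs["format"] = "photonhmm/photon-hdf5-minimal"

    @classmethod
    def from_hdf5(cls, path) -> "PhotonStream":
        with h5py.File(path, "r") as f:
            g = f["photon_data"]
            return cls(
                g["timestamps"][()],
                g["detectors"][()],
                g["excitation"][()],
                tick=float(g["timestamps_specs/timestamps_unit"][()]),
            )
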