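"""Core domain types for PLV brain-network analysis.

The objects here carry the data that flows through the pipeline: a
multichannel :class:`Recording` (sensor- or region-space EEG, microvolts),
a :class:`Parcellation` grouping cortical regions into large-scale
networks, narrowband :class:`BandSpec` definitions, and the symmetric
:class:`ConnectivityMatrix` of phase-locking values produced per subject
and band.  All invariants are checked at construction time so that any
pipeline output can be asserted valid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "Recording",
    "Parcellation",
    "BandSpec",
    "ConnectivityMatrix",
    "DEFAULT_BANDS",
    "default_parcellation",
]


class DataError(ValueError):
    """Raised when input data violate a structural invariant."""


class FormatError(ValueError):
    """Raised when a file lacks required structure or metadata."""


@dataclass
class Recording:
    """A channel/region x sample amplitude matrix with metadata.

    Parameters
    ----------
    data : ndarray, shape (n_rows, n_samples)
        Amplitudes in microvolts.  Rows are sensors (``space="sensor"``)
        or cortical regions (``space="region"``).
    fs : float
        Sampling rate in Hz, strictly positive.
    labels : sequence of str
        Ordered, unique row names; one per data row.
    space : {"sensor", "region"}
    retained_mask : ndarray of bool, optional
        Per-sample mask of samples surviving artifact rejection.
    """

    data: np.ndarray
    fs: float
    labels: Sequence[str]
    space: str = "sensor"
    retained_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise DataError(f"data must be 2-D, got shape {self.data.shape}")
        self.labels = list(self.labels)
        if len(self.labels) != self.data.shape[0]:
            raise DataError(
                f"{len(self.labels)} labels for {self.data.shape[0]} rows"
            )
        if len(set(self.labels)) != len(self.labels):
            raise DataError("labels must be unique")
        if not self.fs > 0:
            raise DataError(f"sampling rate must be > 0, got {self.fs}")
        if self.space not in ("sensor", "region"):
            raise DataError(f"space must be 'sensor' or 'region', got {self.space!r}")
        if not np.all(np.isfinite(self.data)):
            raise DataError("amplitudes contain non-finite values")
        if self.retained_mask is not None:
            self.retained_mask = np.asarray(self.retained_mask, dtype=bool)
            if self.retained_mask.shape != (self.data.shape[1],):
                raise DataError("retained_mask length must equal sample count")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Total duration in seconds."""
        return self.n_samples / self.fs

    @property
    def retained_seconds(self) -> float:
        """Seconds surviving rejection (full duration if no mask)."""
        if self.retained_mask is None:
            return self.duration
        return float(self.retained_mask.sum()) / self.fs

    def copy(self) -> "Recording":
        return Recording(
            data=self.data.copy(),
            fs=self.fs,
            labels=list(self.labels),
            space=self.space,
            retained_mask=None if self.retained_mask is None else self.retained_mask.copy(),
        )

    def row(self, label: str) -> np.ndarray:
        try:
            return self.data[self.labels.index(label)]
        except ValueError:
            raise KeyError(f"label {label!r} not in recording") from None


@dataclass
class BandSpec:
    """A named frequency band with edges in Hz (0 < low < high)."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not 0 < self.low < self.high:
            raise DataError(f"need 0 < low < high, got ({self.low}, {self.high})")

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.low + self.high)


#: Canonical theta / alpha / beta bands used throughout the pipeline.
DEFAULT_BANDS: tuple[BandSpec, ...] = (
    BandSpec("theta", 4.0, 8.0),
    BandSpec("alpha", 8.0, 14.0),
    BandSpec("beta", 14.0, 30.0),
)


def get_band(name: str) -> BandSpec:
    """Return the canonical band with the given name."""
    for b in DEFAULT_BANDS:
        if b.name == name:
            return b
    raise KeyError(f"unknown band {name!r}; known: theta, alpha, beta")


@dataclass
class Parcellation:
    """An exhaustive, disjoint grouping of cortical regions into networks."""

    regions: Sequence[str]
    network_of: Mapping[str, str]
    networks: Sequence[str] = field(default=())

    def __post_init__(self) -> None:
        self.regions = list(self.regions)
        if len(set(self.regions)) != len(self.regions):
            raise DataError("duplicate region in parcellation")
        self.network_of = dict(self.network_of)
        missing = [r for r in self.regions if r not in self.network_of]
        if missing:
            raise DataError(f"regions without a network: {missing[:5]}")
        extra = set(self.network_of) - set(self.regions)
        if extra:
            raise DataError(f"network map contains unknown regions: {sorted(extra)[:5]}")
        if not self.networks:
            # Preserve first-appearance order of network labels.
            seen: list[str] = []
            for r in self.regions:
                n = self.network_of[r]
                if n not in seen:
                    seen.append(n)
            self.networks = seen
        else:
            self.networks = list(self.networks)
            used = {self.network_of[r] for r in self.regions}
            if used - set(self.networks):
                raise DataError("network_of uses labels absent from networks list")

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    def members(self, network: str) -> list[str]:
        """Regions belonging to one network, in parcellation order."""
        return [r for r in self.regions if self.network_of[r] == network]

    def indices(self, network: str) -> np.ndarray:
        """Row/column indices of one network's regions."""
        return np.array(
            [i for i, r in enumerate(self.regions) if self.network_of[r] == network],
            dtype=int,
        )

    def network_pairs(self) -> list[tuple[str, str]]:
        """All unordered pairs of distinct networks, in canonical order."""
        nets = list(self.networks)
        return [(nets[i], nets[j]) for i in range(len(nets)) for j in range(i + 1, len(nets))]


# Network sizes for the packaged 78-region / 5-network cortical split.
_DEFAULT_SPLIT: tuple[tuple[str, int], ...] = (
    ("SMN", 14),
    ("DAN", 14),
    ("SN", 14),
    ("DMN", 22),
    ("CEN", 14),
)


def default_parcellation() -> Parcellation:
    """The packaged 78-region parcellation grouped into five networks.

    Regions are named ``R01``..``R78`` and assigned in blocks to the
    sensorimotor (SMN, 14), dorsal attention (DAN, 14), salience (SN, 14),
    default mode (DMN, 22) and central executive (CEN, 14) networks.
    Anatomical labels play no role in any computation, only the partition
    structure does.
    """
    regions: list[str] = []
    network_of: dict[str, str] = {}
    k = 0
    for net, size in _DEFAULT_SPLIT:
        for _ in range(size):
            k += 1
            name = f"R{k:02d}"
            regions.append(name)
            network_of[name] = net
    return Parcellation(regions=regions, network_of=network_of,
                        networks=[n for n, _ in _DEFAULT_SPLIT])


@dataclass
class ConnectivityMatrix:
    """Symmetric matrix of phase-locking values for one subject and band.

    Invariants checked on construction: square, symmetric, unit diagonal,
    off-diagonal values in [0, 1].
    """

    values: np.ndarray
    band: str
    subject_id: str = ""
    labels: Sequence[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.ndim != 2 or self.values.shape != (n, n):
            raise DataError(f"connectivity matrix must be square, got {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise DataError("connectivity matrix contains non-finite values")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise DataError("connectivity matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 1.0, atol=1e-12):
            raise DataError("connectivity matrix diagonal must be 1")
        off = self.values[~np.eye(n, dtype=bool)]
        if off.size and (off.min() < -1e-12 or off.max() > 1 + 1e-12):
            raise DataError("off-diagonal PLV values must lie in [0, 1]")
        if self.labels is not None:
            self.labels = list(self.labels)
            if len(self.labels) != n:
                raise DataError("label count must match matrix dimension")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]
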