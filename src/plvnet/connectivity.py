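"""Band decomposition, instantaneous phase, and PLV connectivity.

The phase-locking value between regions i and j over T samples is

    PLV = | (1/T) Σ_t exp(i (φ_i(t) − φ_j(t))) |

with φ the instantaneous Hilbert phase of the band-limited signal.
PLV lies in [0, 1]: 1 means a perfectly stable phase relation, 0 a
uniformly wandering one.  All pairwise values are assembled into a
symmetric unit-diagonal matrix and averaged within / between the
parcellation's networks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import signal as sps

from .core import BandSpec, ConnectivityMatrix, DataError, Parcellation, Recording, get_band
from .preprocess import bandpass_filter

__all__ = [
    "PhaseSeries",
    "NetworkSummary",
    "instantaneous_phase",
    "plv",
    "plv_matrix",
    "connectivity_matrix",
    "network_summary",
    "summary_table",
]


@dataclass
class PhaseSeries:
    """Per-region instantaneous phase, wrapped to (−π, π]."""

    phases: np.ndarray  # regions × samples, radians
    fs: float
    band: str
    labels: list[str]

    def __post_init__(self) -> None:
        self.phases = np.asarray(self.phases, dtype=float)
        if self.phases.ndim != 2:
            raise DataError("phases must be regions × samples")
        if not np.all(np.isfinite(self.phases)):
            raise DataError("phases contain non-finite values")


def instantaneous_phase(rec: Recording, band: BandSpec | str,
                        edge_trim: float = 1.0) -> PhaseSeries:
    """Band-pass to ``band``, take the analytic-signal angle, trim edges.

    ``edge_trim`` seconds are removed from each end to suppress the
    Hilbert transform's boundary transients.  A row that is (numerically)
    all zero has no defined phase and raises.
    """
    if isinstance(band, str):
        band = get_band(band)
    trim = int(round(edge_trim * rec.fs))
    if rec.n_samples <= 2 * trim + 1:
        raise DataError(
            f"recording of {rec.n_samples} samples too short for "
            f"{edge_trim} s edge trim per side")
    filtered = bandpass_filter(rec, band.low, band.high)
    rms = np.sqrt((filtered.data ** 2).mean(axis=1))
    dead = [filtered.labels[i] for i in np.nonzero(rms < 1e-12)[0]]
    if dead:
        raise DataError(f"rows with no in-band signal, phase undefined: {dead}")
    analytic = sps.hilbert(filtered.data, axis=1)
    phases = np.angle(analytic)
    if trim > 0:
        phases = phases[:, trim:-trim]
    return PhaseSeries(phases=phases, fs=rec.fs, band=band.name,
                       labels=list(rec.labels))


def plv(phase_i: np.ndarray, phase_j: np.ndarray) -> float:
    """Phase-locking value of two phase series of equal length T ≥ 2.

    Computed on the complex unit circle, so the wrapping convention of
    the inputs is irrelevant.
    """
    phase_i = np.asarray(phase_i, dtype=float)
    phase_j = np.asarray(phase_j, dtype=float)
    if phase_i.shape != phase_j.shape or phase_i.ndim != 1:
        raise DataError("phase series must be 1-D and of equal length")
    if phase_i.size < 2:
        raise DataError("need at least 2 samples")
    return float(np.abs(np.exp(1j * (phase_i - phase_j)).mean()))


def plv_matrix(phases: np.ndarray) -> np.ndarray:
    """All-pairs PLV of an (n × T) phase array via one Gram product.

    With Z = exp(iφ)/√T, the matrix |Z Z*ᵀ| holds every pairwise
    |mean exp(i(φ_i − φ_j))|; the diagonal is exactly 1.
    """
    phases = np.asarray(phases, dtype=float)
    n, T = phases.shape
    if T < 2:
        raise DataError("need at least 2 samples")
    Z = np.exp(1j * phases).astype(np.complex128) / np.sqrt(T)
    G = np.abs(Z @ Z.conj().T)
    G = np.minimum((G + G.T) / 2, 1.0)
    np.fill_diagonal(G, 1.0)
    return G


def connectivity_matrix(rec: Recording, band: BandSpec | str,
                        parcellation: Parcellation,
                        subject_id: str = "",
                        edge_trim: float = 1.0) -> ConnectivityMatrix:
    """PLV matrix of a region-space recording for one band.

    The recording's rows must match the parcellation's regions exactly
    (same names, same order).
    """
    if rec.space != "region":
        raise DataError("connectivity_matrix expects a region-space recording")
    if list(rec.labels) != list(parcellation.regions):
        raise DataError("recording labels do not match the parcellation regions")
    ps = instantaneous_phase(rec, band, edge_trim=edge_trim)
    values = plv_matrix(ps.phases)
    return ConnectivityMatrix(values=values, band=ps.band,
                              subject_id=subject_id,
                              labels=list(parcellation.regions))


@dataclass
class NetworkSummary:
    """Mean PLV between and within networks for one subject and band.

    ``inter`` maps the unordered network pair (as a frozenset) to the mean
    PLV over all cross-network region pairs; ``intra`` maps each network
    to the mean PLV over its within-network region pairs (the "activity"
    reading of single-network level).  A network with fewer than two
    regions has no intra value and is reported as missing (NaN).
    """

    inter: Mapping[frozenset, float]
    intra: Mapping[str, float]
    band: str
    subject_id: str = ""


def network_summary(mat: ConnectivityMatrix,
                    parcellation: Parcellation) -> NetworkSummary:
    """Aggregate a region-level PLV matrix to network level."""
    if mat.n_regions != parcellation.n_regions:
        raise DataError(
            f"matrix is {mat.n_regions}×{mat.n_regions} but parcellation "
            f"has {parcellation.n_regions} regions")
    V = mat.values
    idx = {net: parcellation.indices(net) for net in parcellation.networks}
    inter: dict[frozenset, float] = {}
    for a, b in parcellation.network_pairs():
        block = V[np.ix_(idx[a], idx[b])]
        inter[frozenset((a, b))] = float(block.mean())
    intra: dict[str, float] = {}
    for net in parcellation.networks:
        ii = idx[net]
        if len(ii) < 2:
            intra[net] = float("nan")
            continue
        block = V[np.ix_(ii, ii)]
        tri = block[np.triu_indices(len(ii), k=1)]
        intra[net] = float(tri.mean())
    return NetworkSummary(inter=inter, intra=intra, band=mat.band,
                          subject_id=mat.subject_id)


def summary_table(summaries: list[NetworkSummary]) -> pd.DataFrame:
    """Long-format table: subject, band, metric_type, name, value.

    Inter-network metrics are named ``A-B`` with the two networks in
    alphabetical order; intra metrics carry the bare network name.
    """
    rows: list[dict] = []
    for s in summaries:
        for key, v in s.inter.items():
            name = "-".join(sorted(key))
            rows.append({"subject_id": s.subject_id, "band": s.band,
                         "metric_type": "inter", "name": name, "value": v})
        for net, v in s.intra.items():
            rows.append({"subject_id": s.subject_id, "band": s.band,
                         "metric_type": "intra", "name": net, "value": v})
    return pd.DataFrame(rows, columns=["subject_id", "band", "metric_type",
                                       "name", "value"])
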