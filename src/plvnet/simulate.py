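"""Synthetic region-level EEG with controlled phase coupling.

The generator produces narrowband oscillations whose pairwise
phase-locking values (PLV) are set by construction, so every downstream
stage — filtering, Hilbert phase extraction, connectivity, permutation
statistics — can be tested against known ground truth.

Coupling model
--------------
Each region ``r`` emits ``x_r(t) = A cos(2π f_c t + φ_r(t)) + noise``
with ``f_c`` the band midpoint.  Phase offsets between coupled regions
are i.i.d. von Mises(0, κ) across time, which gives the closed-form
asymptotic PLV ``I1(κ)/I0(κ)`` (ratio of modified Bessel functions);
:func:`kappa_for_plv` inverts that relation.  Cohort-level simulations
additionally couple the five network hub phases through a wrapped
Gaussian process (PLV ``exp(-Var/2)``), which lets all ten inter-network
mean PLV targets be set independently — something pairwise von Mises
links alone cannot do.

With ``phase_hold > 0`` the offsets are redrawn every ``phase_hold``
seconds and held constant in between.  The marginal law (and hence the
expected PLV) is unchanged, but the modulation becomes narrowband enough
to survive band-pass filtering and Hilbert phase extraction; the price
is a smaller effective sample count (one per hold block).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special

from .core import BandSpec, DataError, Parcellation, Recording, get_band

__all__ = [
    "OscillatorSpec",
    "ArtifactSpec",
    "CohortSpec",
    "kappa_for_plv",
    "expected_plv",
    "simulate_region_signals",
    "inject_artifacts",
    "simulate_cohort",
    "simulate_edge_cohort",
]


def expected_plv(kappa: float) -> float:
    """Asymptotic PLV of a von Mises(μ, κ) phase difference: I1(κ)/I0(κ)."""
    if kappa < 0:
        raise DataError("concentration must be >= 0")
    return float(special.i1e(kappa) / special.i0e(kappa))


def kappa_for_plv(rho: float) -> float:
    """Concentration κ whose Bessel ratio I1(κ)/I0(κ) equals ``rho``.

    Solved to |I1(κ)/I0(κ) − rho| ≤ 1e-6.  ``rho`` must lie in [0, 1);
    perfect locking (rho = 1) is attainable only in the κ → ∞ limit and
    is handled by callers as an identical-phase special case.
    """
    if not 0 <= rho < 1:
        raise DataError(f"target PLV must be in [0, 1), got {rho}")
    if rho == 0:
        return 0.0
    hi = 2.0
    while expected_plv(hi) < rho:
        hi *= 2.0
        if hi > 1e8:  # pragma: no cover - rho this close to 1 is rejected above
            raise DataError(f"target PLV {rho} too close to 1")
    return float(optimize.brentq(lambda k: expected_plv(k) - rho, 0.0, hi,
                                 xtol=1e-9, rtol=1e-12))


@dataclass
class OscillatorSpec:
    """Generative description of one multi-region oscillator recording.

    ``pair_plv`` maps unordered region-index pairs to target PLV values;
    the pair graph must be acyclic (targets on a cycle cannot all be
    realised exactly).  ``base_plv`` is the target for every unlinked
    pair, realised by giving each region a von Mises offset of
    concentration κ(√base) around a shared reference so that unlinked
    pairs lock at (√base)² = base.
    """

    n_regions: int
    fs: float = 256.0
    duration: float = 120.0
    band: BandSpec | str = "alpha"
    base_plv: float = 0.0
    pair_plv: Mapping[tuple[int, int], float] = field(default_factory=dict)
    amplitude: float = 10.0
    noise_sd: float | None = None  # default 0.1 × amplitude
    phase_hold: float = 0.0  # seconds; 0 → i.i.d. per sample
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.band, str):
            self.band = get_band(self.band)
        if self.n_regions < 1:
            raise DataError("need at least one region")
        if self.duration * self.fs < 2:
            raise DataError("need at least 2 samples (duration × fs ≥ 2)")
        if not 0 <= self.base_plv <= 1:
            raise DataError("base_plv must be in [0, 1]")
        for pair, rho in self.pair_plv.items():
            if not 0 <= rho <= 1:
                raise DataError(f"pair {pair} target {rho} outside [0, 1]")
        if self.noise_sd is None:
            self.noise_sd = 0.1 * self.amplitude

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.fs))


def _normalise_pairs(pair_plv: Mapping[tuple[int, int], float],
                     n: int) -> dict[tuple[int, int], float]:
    """Canonicalise pair keys to (lo, hi); reject conflicts and self-pairs."""
    out: dict[tuple[int, int], float] = {}
    for (i, j), rho in pair_plv.items():
        if i == j:
            raise DataError(f"self-pair ({i},{i}) has no PLV target")
        if not (0 <= i < n and 0 <= j < n):
            raise DataError(f"pair ({i},{j}) outside region range 0..{n-1}")
        key = (min(i, j), max(i, j))
        if key in out and out[key] != rho:
            raise DataError(f"conflicting targets for pair {key}: {out[key]} vs {rho}")
        out[key] = rho
    return out


def _coupling_forest(pairs: dict[tuple[int, int], float],
                     n: int) -> list[tuple[int, int, float]]:
    """Orient the pair graph as a forest (parent, child, target).

    Children are emitted in BFS order from the lowest-index root of each
    component.  A cycle in the pair graph is an error: the three targets
    around a cycle over-determine the phase offsets.
    """
    adj: dict[int, list[tuple[int, float]]] = {}
    for (i, j), rho in pairs.items():
        adj.setdefault(i, []).append((j, rho))
        adj.setdefault(j, []).append((i, rho))
    seen: set[int] = set()
    edges: list[tuple[int, int, float]] = []
    for root in sorted(adj):
        if root in seen:
            continue
        seen.add(root)
        queue = [root]
        parent = {root: -1}
        while queue:
            u = queue.pop(0)
            for v, rho in sorted(adj[u]):
                if v == parent[u]:
                    continue
                if v in seen:
                    raise DataError(
                        "pair_plv graph contains a cycle; cyclic PLV targets "
                        "cannot all be realised exactly"
                    )
                seen.add(v)
                parent[v] = u
                edges.append((u, v, rho))
                queue.append(v)
    return edges


def _draw_offsets(rng: np.random.Generator, kappa: float, n_samples: int,
                  hold_samples: int) -> np.ndarray:
    """Von Mises(0, κ) offsets, i.i.d. per sample or held in blocks."""
    if hold_samples <= 1:
        return rng.vonmises(0.0, kappa, size=n_samples)
    n_blocks = -(-n_samples // hold_samples)
    draws = rng.vonmises(0.0, kappa, size=n_blocks)
    return np.repeat(draws, hold_samples)[:n_samples]


def _uniform_phase(rng: np.random.Generator, n_samples: int,
                   hold_samples: int) -> np.ndarray:
    if hold_samples <= 1:
        return rng.uniform(-np.pi, np.pi, size=n_samples)
    n_blocks = -(-n_samples // hold_samples)
    draws = rng.uniform(-np.pi, np.pi, size=n_blocks)
    return np.repeat(draws, hold_samples)[:n_samples]


def simulate_region_phases(spec: OscillatorSpec) -> np.ndarray:
    """Modulating phase series φ_r(t) for every region, shape (n, T).

    These are the offsets from the common carrier; the pairwise PLV of
    two regions' full phases equals the PLV of these series because the
    carrier cancels in the difference.
    """
    rng = np.random.default_rng(spec.seed)
    n, T = spec.n_regions, spec.n_samples
    hold = int(round(spec.phase_hold * spec.fs))
    pairs = _normalise_pairs(dict(spec.pair_plv), n)
    forest = _coupling_forest(pairs, n)

    phases = np.empty((n, T))
    if spec.base_plv > 0:
        kappa_b = kappa_for_plv(np.sqrt(spec.base_plv)) if spec.base_plv < 1 else None
        for r in range(n):
            if kappa_b is None:
                phases[r] = 0.0  # base 1 → everything locked to the reference
            else:
                phases[r] = _draw_offsets(rng, kappa_b, T, hold)
    else:
        for r in range(n):
            phases[r] = _uniform_phase(rng, T, hold)

    # Tree edges overwrite the child's phase relative to its parent, so the
    # edge's phase difference is exactly the drawn von Mises series.
    for parent, child, rho in forest:
        if rho >= 1.0:
            phases[child] = phases[parent].copy()
        else:
            kappa = kappa_for_plv(rho)
            phases[child] = phases[parent] + _draw_offsets(rng, kappa, T, hold)
    return phases


def simulate_region_signals(spec: OscillatorSpec,
                            return_phases: bool = False):
    """Synthesise a region-space :class:`Recording` from ``spec``.

    Each region carries ``amplitude · cos(2π f_c t + φ_r(t))`` plus white
    Gaussian noise of ``noise_sd`` μV, with ``f_c`` the band midpoint.
    Deterministic given ``spec.seed``.  With ``return_phases=True`` the
    modulating phases are returned alongside the recording.
    """
    phases = simulate_region_phases(spec)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0x5E1F]))
    t = np.arange(spec.n_samples) / spec.fs
    carrier = 2 * np.pi * spec.band.midpoint * t
    data = spec.amplitude * np.cos(carrier[None, :] + phases)
    if spec.noise_sd > 0:
        data = data + rng.normal(0.0, spec.noise_sd, size=data.shape)
    rec = Recording(data=data, fs=spec.fs,
                    labels=[f"R{i+1:02d}" for i in range(spec.n_regions)],
                    space="region")
    if return_phases:
        return rec, phases
    return rec


# ---------------------------------------------------------------------------
# Artifacts
# ---------------------------------------------------------------------------

@dataclass
class ArtifactSpec:
    """Rates and amplitudes of injected artifacts.

    Blinks are low-frequency, high-amplitude Gaussian-shaped transients
    on designated frontal rows; line noise is a sinusoid on every row;
    spikes are brief excursions exceeding the ±70 μV rejection threshold.
    """

    blink_rate: float = 0.0   # events / minute
    blink_amp: float = 150.0  # μV
    line_freq: float = 50.0   # Hz
    line_amp: float = 0.0     # μV
    spike_rate: float = 0.0   # events / minute
    spike_amp: float = 120.0  # μV, > 70 so rejection can see them

    def __post_init__(self) -> None:
        if min(self.blink_rate, self.spike_rate) < 0:
            raise DataError("artifact rates must be >= 0")


def inject_artifacts(rec: Recording, spec: ArtifactSpec, seed: int = 0,
                     frontal_labels: Sequence[str] | None = None
                     ) -> tuple[Recording, pd.DataFrame]:
    """Return a copy of ``rec`` with artifacts added, plus an event log."""
    out = rec.copy()
    rng = np.random.default_rng(seed)
    events: list[dict] = []
    T, fs = rec.n_samples, rec.fs
    minutes = T / fs / 60.0
    t = np.arange(T) / fs

    if frontal_labels is None:
        frontal_rows = [0]
    else:
        frontal_rows = [out.labels.index(l) for l in frontal_labels]

    n_blinks = rng.poisson(spec.blink_rate * minutes) if spec.blink_rate > 0 else 0
    for _ in range(n_blinks):
        centre = rng.uniform(0.3, max(T / fs - 0.3, 0.3))
        shape = spec.blink_amp * np.exp(-0.5 * ((t - centre) / 0.1) ** 2)
        for row in frontal_rows:
            out.data[row] += shape
        events.append({"kind": "blink", "time": centre, "amplitude": spec.blink_amp})

    if spec.line_amp > 0:
        out.data += spec.line_amp * np.sin(2 * np.pi * spec.line_freq * t)[None, :]
        events.append({"kind": "line", "time": 0.0, "amplitude": spec.line_amp})

    n_spikes = rng.poisson(spec.spike_rate * minutes) if spec.spike_rate > 0 else 0
    if spec.spike_rate > 0 and n_spikes == 0:
        n_spikes = 1  # a positive rate must be observable in short fixtures
    for _ in range(n_spikes):
        idx = int(rng.integers(0, T))
        row = int(rng.integers(0, out.n_channels))
        sign = 1.0 if rng.random() < 0.5 else -1.0
        out.data[row, idx] += sign * spec.spike_amp
        events.append({"kind": "spike", "time": idx / fs, "amplitude": sign * spec.spike_amp})

    log = pd.DataFrame(events, columns=["kind", "time", "amplitude"])
    return out, log


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclass
class CohortSpec:
    """Generative description of a two-group, three-condition cohort.

    ``effect_map`` keys are ``(group, condition, target)`` where target is
    either a network-pair string ``"A-B"`` (inter-network PLV offset) or a
    single network name (intra-network offset).  ``behavior_means`` keys
    are ``(dimension, group, condition)`` → ``(mean, sd)``; scores are
    drawn normal, rounded, and truncated to the 10–50 PANAS range.
    """

    parcellation: Parcellation
    groups: Mapping[str, int] = field(default_factory=lambda: {"ScD": 15, "HC": 15})
    conditions: Sequence[str] = ("NEC", "REI", "VR-EI")
    effect_map: Mapping[tuple[str, str, str], float] = field(default_factory=dict)
    behavior_means: Mapping[tuple[str, str, str], tuple[float, float]] = field(
        default_factory=dict)
    base_inter: float = 0.25
    base_intra: float = 0.45
    fs: float = 256.0
    duration: float = 120.0
    band: BandSpec | str = "alpha"
    amplitude: float = 10.0
    noise_sd: float | None = None
    phase_hold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.band, str):
            self.band = get_band(self.band)
        for g, size in self.groups.items():
            if size <= 0:
                raise DataError(f"group {g!r} size must be > 0")
        if self.noise_sd is None:
            self.noise_sd = 0.1 * self.amplitude


def _cell_targets(spec: CohortSpec, group: str, condition: str
                  ) -> tuple[dict[str, float], dict[frozenset, float], list[str]]:
    """Intra- and inter-network PLV targets for one design cell."""
    nets = list(spec.parcellation.networks)
    intra = {n: spec.base_intra for n in nets}
    inter = {frozenset((a, b)): spec.base_inter
             for a, b in spec.parcellation.network_pairs()}
    warnings_: list[str] = []
    for (g, c, target), off in spec.effect_map.items():
        if (g, c) != (group, condition):
            continue
        if "-" in target:
            a, b = target.split("-", 1)
            key = frozenset((a, b))
            if key not in inter:
                raise DataError(f"unknown network pair {target!r}")
            inter[key] += off
        else:
            if target not in intra:
                raise DataError(f"unknown network {target!r}")
            intra[target] += off
    for d in (intra, inter):
        for k, v in d.items():
            if not 0 <= v <= 1:
                clipped = min(max(v, 0.0), 0.999)
                warnings_.append(f"target {k} = {v:.3f} clipped to {clipped:.3f}")
                d[k] = clipped
    return intra, inter, warnings_


def _nearest_correlation(C: np.ndarray) -> np.ndarray:
    """Project a symmetric matrix to the PSD cone and restore unit diagonal."""
    w, V = np.linalg.eigh((C + C.T) / 2)
    C2 = (V * np.maximum(w, 1e-10)) @ V.T
    d = np.sqrt(np.diag(C2))
    return C2 / np.outer(d, d)


def _simulate_cell_phases(spec: CohortSpec, intra: dict[str, float],
                          inter: dict[frozenset, float],
                          rng: np.random.Generator) -> np.ndarray:
    """Two-level phase construction for one subject.

    Region offsets are von Mises around their network's hub phase with
    concentration κ(√intra), so within-network pair PLV = intra.  The five
    hub phases are wrapped Gaussian with covariance chosen so that hub
    pair PLV = inter / √(intra_A · intra_B), making the cross-network
    region-pair PLV equal the inter target.
    """
    parc = spec.parcellation
    nets = list(parc.networks)
    T = int(round(spec.duration * spec.fs))
    hold = int(round(spec.phase_hold * spec.fs))
    n_blocks = -(-T // hold) if hold > 1 else T

    # Hub PLV targets, bounded above by 1 (an inter target cannot exceed
    # the geometric mean of the two intra targets under this hierarchy).
    k = len(nets)
    H = np.ones((k, k))
    for key, p_ab in inter.items():
        a, b = sorted(key)
        ia, ib = nets.index(a), nets.index(b)
        bound = np.sqrt(intra[a] * intra[b])
        H[ia, ib] = H[ib, ia] = min(p_ab / bound, 1.0) if bound > 0 else 1.0

    with np.errstate(divide="ignore"):
        neg_log = -np.log(np.clip(H, 1e-12, 1.0))
    sigma2 = max(neg_log.max(), 0.25)
    C = 1.0 - neg_log / sigma2
    C = _nearest_correlation(C)
    L = np.linalg.cholesky(C + 1e-12 * np.eye(k))
    z = rng.standard_normal((k, n_blocks))
    hubs = np.sqrt(sigma2) * (L @ z)  # wrapped Gaussian hub phases
    if hold > 1:
        hubs = np.repeat(hubs, hold, axis=1)[:, :T]

    phases = np.empty((parc.n_regions, T))
    for net in nets:
        p_n = intra[net]
        idx = parc.indices(net)
        hub = hubs[nets.index(net)]
        if p_n >= 1.0:
            for i in idx:
                phases[i] = hub
            continue
        kappa = kappa_for_plv(np.sqrt(p_n))
        for i in idx:
            phases[i] = hub + _draw_offsets(rng, kappa, T, hold)
    return phases


@dataclass
class CohortData:
    """Output of :func:`simulate_cohort`."""

    subjects: pd.DataFrame          # subject_id, group, condition
    recordings: dict[str, Recording]
    behavior: pd.DataFrame          # subject_id, group, condition, dimension, score
    manifest: dict


def simulate_cohort(spec: CohortSpec) -> CohortData:
    """Simulate recordings and behavioral scores for a full design cohort.

    Every subject of every (group, condition) cell receives a region-space
    recording whose network-level PLV targets are the bases plus the
    cell's ``effect_map`` offsets, and one behavioral score per dimension
    in ``behavior_means``.  Deterministic given ``spec.seed``; the
    manifest records all targets and any clipping events.
    """
    parc = spec.parcellation
    root = np.random.SeedSequence(spec.seed)
    recordings: dict[str, Recording] = {}
    subj_rows: list[dict] = []
    behav_rows: list[dict] = []
    manifest: dict = {
        "seed": spec.seed,
        "base_inter": spec.base_inter,
        "base_intra": spec.base_intra,
        "fs": spec.fs,
        "duration": spec.duration,
        "band": spec.band.name,
        "phase_hold": spec.phase_hold,
        "cells": {},
        "warnings": [],
    }
    t = np.arange(int(round(spec.duration * spec.fs))) / spec.fs
    carrier = 2 * np.pi * spec.band.midpoint * t

    cell_seeds = root.spawn(len(spec.groups) * len(spec.conditions))
    ci = 0
    for group, size in spec.groups.items():
        for condition in spec.conditions:
            intra, inter, warns = _cell_targets(spec, group, condition)
            cell_key = f"{group}/{condition}"
            manifest["cells"][cell_key] = {
                "n": size,
                "intra": dict(intra),
                "inter": {"-".join(sorted(kk)): v for kk, v in inter.items()},
            }
            for w in warns:
                warnings.warn(f"{cell_key}: {w}")
                manifest["warnings"].append(f"{cell_key}: {w}")
            subject_seeds = cell_seeds[ci].spawn(size)
            ci += 1
            for s in range(size):
                sid = f"{group}-{condition}-{s+1:02d}"
                rng = np.random.default_rng(subject_seeds[s])
                phases = _simulate_cell_phases(spec, intra, inter, rng)
                data = spec.amplitude * np.cos(carrier[None, :] + phases)
                if spec.noise_sd > 0:
                    data = data + rng.normal(0.0, spec.noise_sd, size=data.shape)
                recordings[sid] = Recording(data=data, fs=spec.fs,
                                            labels=list(parc.regions),
                                            space="region")
                subj_rows.append({"subject_id": sid, "group": group,
                                  "condition": condition})
                for (dim, g, c), (mean, sd) in spec.behavior_means.items():
                    if (g, c) != (group, condition):
                        continue
                    score = float(np.clip(np.round(rng.normal(mean, sd)), 10, 50))
                    behav_rows.append({"subject_id": sid, "group": group,
                                       "condition": condition,
                                       "dimension": dim, "score": score})
    return CohortData(
        subjects=pd.DataFrame(subj_rows),
        recordings=recordings,
        behavior=pd.DataFrame(behav_rows,
                              columns=["subject_id", "group", "condition",
                                       "dimension", "score"]),
        manifest=manifest,
    )


def simulate_behavior_only(spec: CohortSpec) -> pd.DataFrame:
    """Draw only the behavioral table of :func:`simulate_cohort`.

    Identical distributional model (normal → rounded → truncated 10–50)
    without synthesising any EEG, for statistics-level calibration runs.
    """
    rng = np.random.default_rng(spec.seed)
    rows: list[dict] = []
    for group, size in spec.groups.items():
        for condition in spec.conditions:
            for s in range(size):
                sid = f"{group}-{condition}-{s+1:02d}"
                for (dim, g, c), (mean, sd) in spec.behavior_means.items():
                    if (g, c) != (group, condition):
                        continue
                    score = float(np.clip(np.round(rng.normal(mean, sd)), 10, 50))
                    rows.append({"subject_id": sid, "group": group,
                                 "condition": condition, "dimension": dim,
                                 "score": score})
    return pd.DataFrame(rows, columns=["subject_id", "group", "condition",
                                       "dimension", "score"])


def simulate_edge_cohort(n_subjects: int, n_regions: int, base: float = 0.3,
                         noise_sd: float = 0.1,
                         edge_offsets: Mapping[tuple[int, int], float] | None = None,
                         seed: int = 0) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Draw per-subject PLV edge values directly, without signal synthesis.

    Each subject's value on edge (i, j) is Normal(base + offset, noise_sd)
    clipped to [0, 1].  This is the edge-level shortcut of the full
    generator, used for statistical calibration where hundreds of cohorts
    are needed.  Returns (subjects × edges array, ordered edge list).
    """
    if n_subjects < 2 or n_regions < 2:
        raise DataError("need at least 2 subjects and 2 regions")
    rng = np.random.default_rng(seed)
    pairs = [(i, j) for i in range(n_regions) for j in range(i + 1, n_regions)]
    mu = np.full(len(pairs), float(base))
    if edge_offsets:
        index = {p: k for k, p in enumerate(pairs)}
        for (i, j), off in edge_offsets.items():
            key = (min(i, j), max(i, j))
            if key not in index:
                raise DataError(f"edge {key} outside region range")
            mu[index[key]] += off
    X = rng.normal(mu[None, :], noise_sd, size=(n_subjects, len(pairs)))
    return np.clip(X, 0.0, 1.0), pairs
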