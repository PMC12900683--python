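"""Inferential layer: t-tests, NBS permutation correction, factorial
ANOVA with partial eta-squared, Bonferroni post-hocs, Pearson
correlation, and a priori power analysis.

The two procedures with real internal state — the network-based
statistic and the 2×3 between-subjects ANOVA — are exposed as model
classes (:class:`NetworkBasedStatistic`, :class:`FactorialANOVA`) whose
``fit()`` returns a results object carrying estimates, p-values and a
``summary()`` table.  Flat convenience functions (:func:`nbs`,
:func:`two_way_anova`) wrap them for pipeline use.

All two-sample tests use Student's pooled-variance t with
df = n_a + n_b − 2: back-computing the published baseline comparisons
from their printed summary statistics matches the pooled form.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sst

from .core import DataError

__all__ = [
    "TResult",
    "CorrResult",
    "PowerQuery",
    "ttest_ind",
    "ttest_from_summary",
    "pearson",
    "bonferroni_posthoc",
    "power_min_n",
    "NetworkBasedStatistic",
    "NBSResults",
    "nbs",
    "FactorialANOVA",
    "AnovaResults",
    "two_way_anova",
    "two_way_anova_from_summary",
]


# ---------------------------------------------------------------------------
# t-tests
# ---------------------------------------------------------------------------

@dataclass
class TResult:
    """Pooled-variance two-sample t-test result."""

    t: float
    df: float
    p: float
    mean_diff: float
    pooled_sd: float

    def __iter__(self):
        yield from (self.t, self.p)


def _pooled(mean_a, sd_a, n_a, mean_b, sd_b, n_b) -> TResult:
    if min(n_a, n_b) < 2:
        raise DataError("each sample needs n >= 2")
    df = n_a + n_b - 2
    sp2 = ((n_a - 1) * sd_a**2 + (n_b - 1) * sd_b**2) / df
    if sp2 <= 0:
        raise DataError("zero pooled variance; t-statistic undefined")
    se = np.sqrt(sp2 * (1 / n_a + 1 / n_b))
    t = (mean_a - mean_b) / se
    p = 2 * sst.t.sf(abs(t), df)
    return TResult(t=float(t), df=float(df), p=float(p),
                   mean_diff=float(mean_a - mean_b), pooled_sd=float(np.sqrt(sp2)))


def ttest_ind(a: Sequence[float], b: Sequence[float]) -> TResult:
    """Student's pooled two-sided independent-samples t-test."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return _pooled(a.mean(), a.std(ddof=1), a.size, b.mean(), b.std(ddof=1), b.size)


def ttest_from_summary(mean_a: float, sd_a: float, n_a: int,
                       mean_b: float, sd_b: float, n_b: int) -> TResult:
    """Pooled t-test from summary statistics (means, SDs, group sizes).

    Agrees exactly with :func:`ttest_ind` applied to the raw samples.
    """
    if min(sd_a, sd_b) <= 0:
        raise DataError("standard deviations must be > 0")
    return _pooled(mean_a, sd_a, n_a, mean_b, sd_b, n_b)


# ---------------------------------------------------------------------------
# Pearson correlation
# ---------------------------------------------------------------------------

@dataclass
class CorrResult:
    r: float
    p: float
    n: int


def pearson(x: Sequence[float], y: Sequence[float]) -> CorrResult:
    """Sample Pearson correlation with two-sided p via the t transform."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise DataError("x and y must have the same length")
    if x.size < 3:
        raise DataError("need n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise DataError("correlation undefined for constant input")
    r, p = sst.pearsonr(x, y)
    return CorrResult(r=float(r), p=float(p), n=int(x.size))


# ---------------------------------------------------------------------------
# Bonferroni post-hoc
# ---------------------------------------------------------------------------

def bonferroni_posthoc(cells: Mapping[str, Sequence[float]],
                       family: Sequence[tuple[str, str]]) -> pd.DataFrame:
    """Pairwise pooled t-tests with Bonferroni-adjusted p-values.

    ``family`` lists the contrasts (pairs of cell labels) forming one
    correction family; raw p-values are multiplied by the family size and
    capped at 1.
    """
    if not family:
        raise DataError("empty contrast family")
    m = len(family)
    rows = []
    for a, b in family:
        res = ttest_ind(cells[a], cells[b])
        rows.append({"contrast": f"{a} vs {b}", "t": res.t, "df": res.df,
                     "p_raw": res.p, "p_adj": min(res.p * m, 1.0)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Power analysis
# ---------------------------------------------------------------------------

@dataclass
class PowerQuery:
    """A priori power query for a two-sample t or fixed-effects F test.

    ``effect_size`` is Cohen's d (t-test) or Cohen's f (F-test).  For the
    F test, ``n_groups`` is the number of design cells and ``df_num`` the
    numerator degrees of freedom of the effect of interest.
    """

    test: str = "two_sample_t"
    effect_size: float = 0.8
    alpha: float = 0.05
    power: float = 0.95
    n_groups: int = 2
    df_num: int | None = None

    def __post_init__(self) -> None:
        if self.effect_size <= 0:
            raise DataError("effect size must be > 0")
        if not (0 < self.alpha < 1 and 0 < self.power < 1):
            raise DataError("alpha and power must lie in (0, 1)")
        if self.test not in ("two_sample_t", "anova_f"):
            raise DataError(f"unknown test {self.test!r}")


def achieved_power(query: PowerQuery, n_total: int) -> float:
    """Power of the query's test at total sample size ``n_total``.

    Two-sample t: equal groups n = N/2, noncentrality d·√(n/2),
    df = N − 2, two-sided rejection region.  ANOVA F: noncentrality
    λ = f²·N, df = (df_num, N − n_groups).
    """
    if query.test == "two_sample_t":
        n = n_total // 2
        df = n_total - 2
        if df < 1 or n < 2:
            return 0.0
        ncp = query.effect_size * np.sqrt(n / 2)
        tc = sst.t.ppf(1 - query.alpha / 2, df)
        return float(sst.nct.sf(tc, df, ncp) + sst.nct.cdf(-tc, df, ncp))
    df_num = query.df_num if query.df_num is not None else query.n_groups - 1
    df_den = n_total - query.n_groups
    if df_den < 1:
        return 0.0
    lam = query.effect_size**2 * n_total
    fc = sst.f.ppf(1 - query.alpha, df_num, df_den)
    return float(sst.ncf.sf(fc, df_num, df_den, lam))


def power_min_n(query: PowerQuery, n_max: int = 1_000_000) -> int:
    """Smallest total sample size whose achieved power meets the request.

    For the two-sample t-test, N is even (equal allocation) and the
    search steps by 2; for the F test it steps by 1.  Raises when the
    requested power is not reached by ``n_max``.
    """
    if query.test == "two_sample_t":
        start, step = 4, 2
    else:
        df_num = query.df_num if query.df_num is not None else query.n_groups - 1
        start, step = query.n_groups + df_num + 1, 1
    n = start
    while n <= n_max:
        if achieved_power(query, n) >= query.power:
            return n
        n += step
    raise DataError(f"requested power not attainable below N = {n_max}")


# ---------------------------------------------------------------------------
# Network-based statistic
# ---------------------------------------------------------------------------

def _edge_t(X: np.ndarray, idx_a: np.ndarray, idx_b: np.ndarray) -> np.ndarray:
    """Pooled t across all edge columns for one labelling."""
    a, b = X[idx_a], X[idx_b]
    na, nb = len(idx_a), len(idx_b)
    va = a.var(axis=0, ddof=1)
    vb = b.var(axis=0, ddof=1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    sp2 = np.maximum(sp2, 1e-300)
    return (a.mean(axis=0) - b.mean(axis=0)) / np.sqrt(sp2 * (1 / na + 1 / nb))


class _UnionFind:
    __slots__ = ("parent",)

    def __init__(self, nodes):
        self.parent = {n: n for n in nodes}

    def find(self, x):
        p = self.parent
        while p[x] != x:
            p[x] = p[p[x]]
            x = p[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb


def _components(pairs: Sequence[tuple[int, int]],
                supra: np.ndarray) -> list[list[int]]:
    """Connected components of the suprathreshold graph, as edge-index lists."""
    edge_idx = np.nonzero(supra)[0]
    if edge_idx.size == 0:
        return []
    nodes = set()
    for e in edge_idx:
        i, j = pairs[e]
        nodes.add(i)
        nodes.add(j)
    uf = _UnionFind(nodes)
    for e in edge_idx:
        i, j = pairs[e]
        uf.union(i, j)
    comps: dict[int, list[int]] = {}
    for e in edge_idx:
        root = uf.find(pairs[e][0])
        comps.setdefault(root, []).append(int(e))
    return list(comps.values())


@dataclass
class NBSComponent:
    """One suprathreshold connected component.

    ``sign`` is +1 for components of edges where group A exceeds group B,
    −1 for the reverse, 0 when components pool both directions.
    """

    edges: list[tuple[int, int]]
    size: int
    p: float
    significant: bool
    sign: int = 0


@dataclass
class NBSResults:
    """Results of a fitted :class:`NetworkBasedStatistic`.

    ``observed_components`` are all suprathreshold components with their
    permutation p-values; ``null_max_sizes`` is the permutation null
    distribution of the maximum component size.
    """

    model: "NetworkBasedStatistic"
    edge_t: np.ndarray
    edge_p: np.ndarray
    observed_components: list[NBSComponent]
    null_max_sizes: np.ndarray
    seed: int

    @property
    def significant_components(self) -> list[NBSComponent]:
        return [c for c in self.observed_components if c.significant]

    def summary(self) -> pd.DataFrame:
        rows = []
        for k, c in enumerate(self.observed_components):
            rows.append({"component": k, "size": c.size, "sign": c.sign,
                         "p": c.p, "significant": c.significant,
                         "edges": ";".join(f"{i}-{j}" for i, j in c.edges)})
        return pd.DataFrame(rows, columns=["component", "size", "sign", "p",
                                           "significant", "edges"])


class NetworkBasedStatistic:
    """Permutation test for differential subnetworks between two groups.

    Edges with a two-sided pooled-t p below ``edge_alpha`` form a
    suprathreshold graph; the size of each connected component (edge
    count by default) is referred to the permutation null distribution of
    the maximum component size under group-label exchange.  Component
    p-values use the +1 convention, p = (1 + #{null ≥ size}) / (1 + n_perm),
    so they can never be exactly zero.

    With ``sign_split=True`` (the default) components are formed within
    each contrast direction separately — a differential subnetwork is a
    set of edges coherently stronger or weaker in one group — and the
    null records the maximum size over both directions, preserving
    family-wise control over the whole two-sided family.  Pooling both
    signs into one graph is available with ``sign_split=False`` but has
    markedly lower power for direction-coherent effects.

    Parameters
    ----------
    edges_a, edges_b : ndarray, (subjects × edges)
        Per-subject edge values (e.g. PLV) for the two groups, columns
        aligned across groups.
    pairs : list of (i, j), optional
        Region-index pair of each column; defaults to the upper triangle
        of the smallest complete graph with that many edges.
    """

    def __init__(self, edges_a: np.ndarray, edges_b: np.ndarray,
                 pairs: Sequence[tuple[int, int]] | None = None,
                 edge_alpha: float = 0.05, component_alpha: float = 0.05,
                 n_perm: int = 2000, component_size: str = "edges",
                 sign_split: bool = True):
        self.edges_a = np.atleast_2d(np.asarray(edges_a, dtype=float))
        self.edges_b = np.atleast_2d(np.asarray(edges_b, dtype=float))
        if self.edges_a.shape[1] != self.edges_b.shape[1]:
            raise DataError("edge column counts differ between groups")
        if min(self.edges_a.shape[0], self.edges_b.shape[0]) < 2:
            raise DataError("each group needs at least 2 subjects")
        if n_perm < 1:
            raise DataError("n_perm must be >= 1")
        if component_size not in ("edges", "nodes"):
            raise DataError("component_size must be 'edges' or 'nodes'")
        E = self.edges_a.shape[1]
        if pairs is None:
            # infer n from E = n(n-1)/2
            n = int(round((1 + np.sqrt(1 + 8 * E)) / 2))
            if n * (n - 1) // 2 != E:
                raise DataError(f"{E} edges is not a full upper triangle; pass pairs")
            pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
        if len(pairs) != E:
            raise DataError("pairs length must match edge count")
        self.pairs = [tuple(p) for p in pairs]
        self.edge_alpha = edge_alpha
        self.component_alpha = component_alpha
        self.n_perm = int(n_perm)
        self.component_size = component_size
        self.sign_split = bool(sign_split)

    def _size(self, comp: list[int]) -> int:
        if self.component_size == "edges":
            return len(comp)
        return len({x for e in comp for x in self.pairs[e]})

    def _signed_components(self, t: np.ndarray,
                           tcrit: float) -> list[tuple[int, list[int]]]:
        """(sign, edge-index list) for every suprathreshold component."""
        if not self.sign_split:
            return [(0, c) for c in _components(self.pairs, np.abs(t) > tcrit)]
        out: list[tuple[int, list[int]]] = []
        for sgn in (1, -1):
            out.extend((sgn, c) for c in _components(self.pairs, sgn * t > tcrit))
        return out

    def fit(self, seed: int = 0) -> NBSResults:
        """Run the observed test and the permutation null; deterministic
        given ``seed``."""
        na, nb = self.edges_a.shape[0], self.edges_b.shape[0]
        X = np.vstack([self.edges_a, self.edges_b])
        n = na + nb
        df = n - 2
        tcrit = sst.t.ppf(1 - self.edge_alpha / 2, df)

        t_obs = _edge_t(X, np.arange(na), np.arange(na, n))
        p_obs = 2 * sst.t.sf(np.abs(t_obs), df)
        comps = self._signed_components(t_obs, tcrit)

        rng = np.random.default_rng(seed)
        null_max = np.empty(self.n_perm, dtype=int)
        for k in range(self.n_perm):
            perm = rng.permutation(n)
            t_p = _edge_t(X, perm[:na], perm[na:])
            sizes = [self._size(c) for _, c in
                     self._signed_components(t_p, tcrit)]
            null_max[k] = max(sizes, default=0)

        observed: list[NBSComponent] = []
        for sgn, c in comps:
            size = self._size(c)
            p = (1 + int((null_max >= size).sum())) / (1 + self.n_perm)
            observed.append(NBSComponent(
                edges=[self.pairs[e] for e in c], size=size, p=p,
                significant=p < self.component_alpha, sign=sgn))
        observed.sort(key=lambda c: (-c.size, c.p))
        return NBSResults(model=self, edge_t=t_obs, edge_p=p_obs,
                          observed_components=observed,
                          null_max_sizes=null_max, seed=seed)


def nbs(edges_a, edges_b, edge_alpha: float = 0.05,
        component_alpha: float = 0.05, n_perm: int = 2000, seed: int = 0,
        pairs=None, component_size: str = "edges",
        sign_split: bool = True) -> NBSResults:
    """Fit a :class:`NetworkBasedStatistic` in one call."""
    model = NetworkBasedStatistic(edges_a, edges_b, pairs=pairs,
                                  edge_alpha=edge_alpha,
                                  component_alpha=component_alpha,
                                  n_perm=n_perm, component_size=component_size,
                                  sign_split=sign_split)
    return model.fit(seed=seed)


# ---------------------------------------------------------------------------
# Two-way between-subjects ANOVA
# ---------------------------------------------------------------------------

@dataclass
class AnovaEffect:
    F: float
    df_num: float
    df_den: float
    p: float
    partial_eta_sq: float
    ss: float


@dataclass
class AnovaResults:
    """Balanced two-way between-subjects factorial decomposition.

    Effects are keyed ``"A"`` (first factor), ``"B"`` (second factor)
    and ``"A:B"`` (interaction); partial η² = SS_effect / (SS_effect +
    SS_error).
    """

    effects: dict[str, AnovaEffect]
    ss_error: float
    ss_total: float
    factor_names: tuple[str, str]
    cell_means: pd.DataFrame = field(default=None)

    def __getitem__(self, key: str) -> AnovaEffect:
        return self.effects[key]

    def summary(self) -> pd.DataFrame:
        a, b = self.factor_names
        pretty = {"A": a, "B": b, "A:B": f"{a}:{b}"}
        rows = []
        for key, e in self.effects.items():
            rows.append({"effect": pretty[key], "SS": e.ss, "df": e.df_num,
                         "F": e.F, "p": e.p, "partial_eta_sq": e.partial_eta_sq})
        rows.append({"effect": "error", "SS": self.ss_error,
                     "df": self.effects["A:B"].df_den, "F": np.nan,
                     "p": np.nan, "partial_eta_sq": np.nan})
        return pd.DataFrame(rows)


def _anova_from_cells(cells: np.ndarray) -> AnovaResults:
    """Closed-form balanced decomposition; ``cells`` has shape (a, b, n)."""
    a, b, n = cells.shape
    if n < 2:
        raise DataError("need n >= 2 per cell")
    gm = cells.mean()
    means = cells.mean(axis=2)
    ss_a = b * n * ((means.mean(axis=1) - gm) ** 2).sum()
    ss_b = a * n * ((means.mean(axis=0) - gm) ** 2).sum()
    ss_cells = n * ((means - gm) ** 2).sum()
    ss_ab = ss_cells - ss_a - ss_b
    ss_err = ((cells - means[:, :, None]) ** 2).sum()
    ss_total = ((cells - gm) ** 2).sum()
    df_err = a * b * (n - 1)
    out: dict[str, AnovaEffect] = {}
    for key, ss, df in (("A", ss_a, a - 1), ("B", ss_b, b - 1),
                        ("A:B", ss_ab, (a - 1) * (b - 1))):
        ms_err = ss_err / df_err
        F = (ss / df) / ms_err if ms_err > 0 else np.inf
        p = float(sst.f.sf(F, df, df_err)) if np.isfinite(F) else 0.0
        out[key] = AnovaEffect(F=float(F), df_num=float(df), df_den=float(df_err),
                               p=p, partial_eta_sq=float(ss / (ss + ss_err))
                               if (ss + ss_err) > 0 else 0.0, ss=float(ss))
    return AnovaResults(effects=out, ss_error=float(ss_err),
                        ss_total=float(ss_total), factor_names=("A", "B"))


class FactorialANOVA:
    """Two-way between-subjects ANOVA for a balanced factorial design.

    Built from a long-format DataFrame with one row per subject; the two
    factor columns define the cells.  Unbalanced designs are rejected
    with a listing of the observed cell counts: the decomposition below
    is the balanced closed form and would silently change meaning
    otherwise.
    """

    def __init__(self, df: pd.DataFrame, value: str,
                 between: tuple[str, str] = ("group", "condition")):
        self.value = value
        self.between = between
        fa, fb = between
        for col in (value, fa, fb):
            if col not in df.columns:
                raise DataError(f"column {col!r} missing from data")
        self.levels_a = list(pd.unique(df[fa]))
        self.levels_b = list(pd.unique(df[fb]))
        counts = df.groupby([fa, fb], sort=False, observed=True)[value].count()
        sizes = set(counts.values)
        if len(counts) != len(self.levels_a) * len(self.levels_b) or len(sizes) != 1:
            raise DataError(f"unbalanced design; cell counts: {counts.to_dict()}")
        n = sizes.pop()
        cells = np.empty((len(self.levels_a), len(self.levels_b), n))
        for i, la in enumerate(self.levels_a):
            for j, lb in enumerate(self.levels_b):
                vals = df.loc[(df[fa] == la) & (df[fb] == lb), value].to_numpy(float)
                cells[i, j] = vals
        self.cells = cells

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, value: str,
                       between: tuple[str, str] = ("group", "condition")
                       ) -> "FactorialANOVA":
        return cls(df, value, between)

    def fit(self) -> AnovaResults:
        res = _anova_from_cells(self.cells)
        res.factor_names = self.between
        res.cell_means = pd.DataFrame(self.cells.mean(axis=2),
                                      index=self.levels_a, columns=self.levels_b)
        return res


def two_way_anova(df: pd.DataFrame, value: str,
                  between: tuple[str, str] = ("group", "condition")
                  ) -> AnovaResults:
    """Fit a balanced 2×k between-subjects ANOVA in one call."""
    return FactorialANOVA.from_dataframe(df, value, between).fit()


def two_way_anova_from_summary(means: np.ndarray, sds: np.ndarray,
                               n: int) -> AnovaResults:
    """Factorial decomposition from printed cell means and SDs.

    ``means`` and ``sds`` have shape (levels_A, levels_B); every cell has
    ``n`` subjects.  Between-cell sums of squares come from the means;
    SS_error = Σ (n−1)·sd², exactly as if the raw data had been seen.
    """
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    if means.shape != sds.shape or means.ndim != 2:
        raise DataError("means and sds must be matching 2-D arrays")
    if n < 2:
        raise DataError("need n >= 2 per cell")
    a, b = means.shape
    gm = means.mean()
    ss_a = b * n * ((means.mean(axis=1) - gm) ** 2).sum()
    ss_b = a * n * ((means.mean(axis=0) - gm) ** 2).sum()
    ss_cells = n * ((means - gm) ** 2).sum()
    ss_ab = ss_cells - ss_a - ss_b
    ss_err = ((n - 1) * sds**2).sum()
    df_err = a * b * (n - 1)
    out: dict[str, AnovaEffect] = {}
    for key, ss, df in (("A", ss_a, a - 1), ("B", ss_b, b - 1),
                        ("A:B", ss_ab, (a - 1) * (b - 1))):
        F = (ss / df) / (ss_err / df_err)
        out[key] = AnovaEffect(F=float(F), df_num=float(df), df_den=float(df_err),
                               p=float(sst.f.sf(F, df, df_err)),
                               partial_eta_sq=float(ss / (ss + ss_err)), ss=float(ss))
    return AnovaResults(effects=out, ss_error=float(ss_err),
                        ss_total=float(ss_cells + ss_err),
                        factor_names=("A", "B"))
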