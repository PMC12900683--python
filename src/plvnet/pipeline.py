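"""End-to-end orchestration: simulate/load → preprocess → connectivity →
network summaries → statistics, with reproducible manifests.

Two entry points mirror the study's two designs:

* :func:`run_baseline_comparison` — two groups, one condition; per-band
  network-metric t-tests and a region-level NBS permutation test.
* :func:`run_intervention_analysis` — 2 groups × 3 conditions; per-metric
  factorial ANOVA with partial η², Bonferroni post-hocs, behavioral cell
  summaries, and brain–behavior correlations on post − pre changes.

Every run can write its result bundle (TSV tables + JSON manifest) to an
output directory; identical configurations and seeds produce
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .behavioral import change_scores
from .connectivity import connectivity_matrix, network_summary, summary_table
from .core import DataError, Parcellation, Recording
from .io import load_parcellation, read_recording, write_results
from .preprocess import PreprocessConfig, RetentionError, preprocess
from .simulate import CohortData, CohortSpec, simulate_cohort
from .stats import bonferroni_posthoc, nbs, pearson, ttest_ind, two_way_anova

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_baseline_comparison", "run_intervention_analysis"]


def _stringify_keys(obj):
    """Make nested mappings JSON-safe (tuple keys become 'a/b/c')."""
    if isinstance(obj, Mapping):
        return {("/".join(map(str, k)) if isinstance(k, tuple) else str(k)):
                _stringify_keys(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_stringify_keys(v) for v in obj]
    return obj


@dataclass
class RunConfig:
    """One run's complete configuration.

    In ``simulate`` mode, ``simulate`` holds :class:`CohortSpec` keyword
    arguments (the parcellation and master seed are filled in from this
    config).  In ``files`` mode, ``subjects_file`` points to a TSV with
    columns ``subject_id, group, condition, path`` and ``behavior_file``
    optionally to a long-format behavioral TSV.
    """

    mode: str = "simulate"
    seed: int = 0
    out_dir: str | None = None
    bands: Sequence[str] = ("theta", "alpha", "beta")
    parcellation: str = "builtin"
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    edge_alpha: float = 0.05
    component_alpha: float = 0.05
    n_perm: int = 2000
    metric_adjust: str = "bonferroni"  # within each band's 15-metric family
    corr_cell: tuple[str, str] = ("ScD", "VR-EI")
    simulate: dict = field(default_factory=dict)
    subjects_file: str | None = None
    behavior_file: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "files"):
            raise DataError(f"mode must be 'simulate' or 'files', got {self.mode!r}")
        if self.mode == "files" and self.subjects_file is None:
            raise DataError("files mode requires subjects_file")
        if isinstance(self.preprocess, Mapping):
            self.preprocess = PreprocessConfig(**self.preprocess)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "corr_cell" in raw:
            raw["corr_cell"] = tuple(raw["corr_cell"])
        return cls(**raw)

    def manifest(self) -> dict:
        cfg = dataclasses.asdict(self)
        cfg.pop("out_dir", None)  # keep runs byte-comparable across targets
        cfg["preprocess"] = dataclasses.asdict(self.preprocess) \
            if dataclasses.is_dataclass(self.preprocess) else self.preprocess
        cfg = _stringify_keys(cfg)
        blob = json.dumps(cfg, sort_keys=True, default=str)
        return {
            "config": cfg,
            "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
            "seed": self.seed,
            "versions": {"plvnet": _pkg_version, "numpy": np.__version__},
        }


# ---------------------------------------------------------------------------
# Cohort acquisition
# ---------------------------------------------------------------------------

def _cohort_spec(config: RunConfig, parc: Parcellation, **overrides) -> CohortSpec:
    kwargs = dict(config.simulate)
    kwargs.update(overrides)
    kwargs.setdefault("seed", config.seed)
    return CohortSpec(parcellation=parc, **kwargs)


def _load_files_cohort(config: RunConfig) -> CohortData:
    subjects = pd.read_csv(config.subjects_file, sep="\t")
    required = {"subject_id", "group", "condition", "path"}
    if not required <= set(subjects.columns):
        raise DataError(f"subjects file needs columns {sorted(required)}")
    base = Path(config.subjects_file).parent
    recordings: dict[str, Recording] = {}
    for row in subjects.itertuples():
        p = Path(row.path)
        recordings[str(row.subject_id)] = read_recording(p if p.is_absolute() else base / p)
    behavior = pd.DataFrame(columns=["subject_id", "group", "condition",
                                     "dimension", "score"])
    if config.behavior_file:
        behavior = pd.read_csv(config.behavior_file, sep="\t")
    return CohortData(subjects=subjects[["subject_id", "group", "condition"]],
                      recordings=recordings, behavior=behavior,
                      manifest={"source": "files"})


# ---------------------------------------------------------------------------
# Shared stages
# ---------------------------------------------------------------------------

def _preprocess_cohort(cohort: CohortData, config: RunConfig
                       ) -> tuple[dict[str, Recording], pd.DataFrame]:
    """Run the cleaning chain per subject; excluded subjects are reported."""
    cleaned: dict[str, Recording] = {}
    rows = []
    for sid, rec in cohort.recordings.items():
        try:
            out, report = preprocess(rec, config.preprocess)
            cleaned[sid] = out
            rows.append({"subject_id": sid, "excluded": False,
                         "retained_seconds": report["retained_seconds"]})
        except RetentionError as exc:
            rows.append({"subject_id": sid, "excluded": True,
                         "retained_seconds": exc.report["retained_seconds"]})
            log.warning("subject %s excluded: %s", sid, exc)
    report_df = pd.DataFrame(rows, columns=["subject_id", "excluded",
                                            "retained_seconds"])
    n_out = int(report_df["excluded"].sum()) if len(report_df) else 0
    log.info("preprocessing: %d subjects in, %d excluded",
             len(cohort.recordings), n_out)
    return cleaned, report_df


def _connectivity_stage(cleaned: Mapping[str, Recording], config: RunConfig,
                        parc: Parcellation):
    """Per-band PLV matrices and network summaries for every subject."""
    matrices = {}
    summaries = []
    for band in config.bands:
        for sid, rec in cleaned.items():
            mat = connectivity_matrix(rec, band, parc, subject_id=sid)
            matrices[(sid, band)] = mat
            summaries.append(network_summary(mat, parc))
    return matrices, summary_table(summaries)


def _metric_frame(summaries: pd.DataFrame, subjects: pd.DataFrame) -> pd.DataFrame:
    """Merge network metrics with the design columns (group, condition)."""
    return summaries.merge(subjects, on="subject_id", how="left")


def _edge_matrix(matrices: Mapping, sids: Sequence[str], band: str,
                 n_regions: int) -> tuple[np.ndarray, list[tuple[int, int]]]:
    iu = np.triu_indices(n_regions, k=1)
    pairs = list(zip(iu[0].tolist(), iu[1].tolist()))
    X = np.empty((len(sids), len(pairs)))
    for k, sid in enumerate(sids):
        X[k] = matrices[(sid, band)].values[iu]
    return X, pairs


# ---------------------------------------------------------------------------
# Baseline comparison (two groups, one condition)
# ---------------------------------------------------------------------------

def run_baseline_comparison(config: RunConfig,
                            cohort: CohortData | None = None) -> dict:
    """Group comparison of per-band network metrics plus region-level NBS.

    Returns a result bundle (tables and manifest); writes it to
    ``config.out_dir`` when set.
    """
    parc = load_parcellation(config.parcellation)
    if cohort is None:
        if config.mode == "simulate":
            cohort = simulate_cohort(_cohort_spec(config, parc))
        else:
            cohort = _load_files_cohort(config)
    groups = list(dict.fromkeys(cohort.subjects["group"]))
    if len(groups) != 2:
        raise DataError(f"baseline comparison needs exactly 2 groups, got {groups}")

    cleaned, prep_report = _preprocess_cohort(cohort, config)
    kept = cohort.subjects[cohort.subjects["subject_id"].isin(cleaned)]
    matrices, summaries = _connectivity_stage(cleaned, config, parc)
    metrics = _metric_frame(summaries, kept)

    # Per-metric group t-tests, Bonferroni-adjusted within each band.
    t_rows = []
    for band in config.bands:
        sub = metrics[metrics["band"] == band]
        names = sub[["metric_type", "name"]].drop_duplicates().to_records(index=False)
        fam = len(names)
        for mtype, name in names:
            cell = sub[(sub["metric_type"] == mtype) & (sub["name"] == name)]
            a = cell.loc[cell["group"] == groups[0], "value"].to_numpy(float)
            b = cell.loc[cell["group"] == groups[1], "value"].to_numpy(float)
            res = ttest_ind(a, b)
            adj = min(res.p * fam, 1.0) if config.metric_adjust == "bonferroni" else res.p
            t_rows.append({"band": band, "metric_type": mtype, "name": name,
                           "t": res.t, "df": res.df, "p": res.p, "p_adj": adj,
                           "mean_diff": res.mean_diff})
    ttests = pd.DataFrame(t_rows)

    # Region-level NBS per band.
    nbs_rows, nbs_detail = [], {}
    sids_a = kept.loc[kept["group"] == groups[0], "subject_id"].tolist()
    sids_b = kept.loc[kept["group"] == groups[1], "subject_id"].tolist()
    for band in config.bands:
        Xa, pairs = _edge_matrix(matrices, sids_a, band, parc.n_regions)
        Xb, _ = _edge_matrix(matrices, sids_b, band, parc.n_regions)
        res = nbs(Xa, Xb, edge_alpha=config.edge_alpha,
                  component_alpha=config.component_alpha,
                  n_perm=config.n_perm, seed=config.seed, pairs=pairs)
        for k, comp in enumerate(res.observed_components):
            nbs_rows.append({"band": band, "component": k, "size": comp.size,
                             "p": comp.p, "significant": comp.significant})
        nbs_detail[band] = {
            "n_components": len(res.observed_components),
            "significant": [c.edges for c in res.significant_components],
        }
    nbs_table = pd.DataFrame(nbs_rows, columns=["band", "component", "size",
                                                "p", "significant"])

    bundle = {
        "network_metrics": metrics,
        "metric_ttests": ttests,
        "nbs_components": nbs_table,
        "preprocess_report": prep_report,
        "manifest": {**config.manifest(), "analysis": "baseline_comparison",
                     "groups": groups, "nbs": nbs_detail,
                     "cohort": cohort.manifest},
    }
    if config.out_dir:
        write_results(bundle, config.out_dir)
    return bundle


# ---------------------------------------------------------------------------
# Intervention analysis (2 groups × 3 conditions)
# ---------------------------------------------------------------------------

def run_intervention_analysis(config: RunConfig,
                              cohort: CohortData | None = None,
                              pre_cohort: CohortData | None = None) -> dict:
    """Factorial analysis of the 2×3 design plus brain–behavior coupling.

    ``cohort`` holds the post-intervention measurements.  When a paired
    ``pre_cohort`` is supplied (or simulated: in simulate mode a
    pre-intervention cohort with no intervention effects is generated
    from the same subject ids), post − pre change scores feed the Pearson
    correlations within ``config.corr_cell``; otherwise correlations are
    computed on the post measurements alone and flagged as such.
    """
    parc = load_parcellation(config.parcellation)
    if cohort is None:
        if config.mode == "simulate":
            cohort = simulate_cohort(_cohort_spec(config, parc))
            if pre_cohort is None:
                pre_cohort = simulate_cohort(_cohort_spec(
                    config, parc, effect_map={},
                    seed=int(np.random.SeedSequence([config.seed, 0xB45E])
                             .generate_state(1)[0] % (2**31))))
        else:
            cohort = _load_files_cohort(config)

    cells = cohort.subjects.groupby(["group", "condition"]).size()
    if cells.nunique() != 1:
        raise DataError(f"unbalanced design cells: {cells.to_dict()}")

    cleaned, prep_report = _preprocess_cohort(cohort, config)
    kept = cohort.subjects[cohort.subjects["subject_id"].isin(cleaned)]
    matrices, summaries = _connectivity_stage(cleaned, config, parc)
    metrics = _metric_frame(summaries, kept)

    # Per-metric 2×3 ANOVA with partial η²; Bonferroni post-hocs across
    # conditions within each group when the interaction is significant.
    anova_rows, posthoc_rows = [], []
    for (band, mtype, name), cell in metrics.groupby(["band", "metric_type", "name"]):
        try:
            res = two_way_anova(cell, "value", between=("group", "condition"))
        except DataError:
            continue
        for eff_key, eff in res.effects.items():
            anova_rows.append({"band": band, "metric_type": mtype, "name": name,
                               "effect": {"A": "group", "B": "condition",
                                          "A:B": "group:condition"}[eff_key],
                               "F": eff.F, "df_num": eff.df_num,
                               "df_den": eff.df_den, "p": eff.p,
                               "partial_eta_sq": eff.partial_eta_sq})
        if res.effects["A:B"].p < 0.05:
            for group, gcell in cell.groupby("group"):
                conds = list(dict.fromkeys(gcell["condition"]))
                fam = [(c1, c2) for i, c1 in enumerate(conds)
                       for c2 in conds[i + 1:]]
                data = {c: gcell.loc[gcell["condition"] == c, "value"].to_numpy(float)
                        for c in conds}
                ph = bonferroni_posthoc(data, fam)
                ph.insert(0, "band", band)
                ph.insert(1, "metric", f"{mtype}:{name}")
                ph.insert(2, "group", group)
                posthoc_rows.append(ph)
    posthoc_table = (pd.concat(posthoc_rows, ignore_index=True)
                     if posthoc_rows else
                     pd.DataFrame(columns=["band", "metric", "group",
                                           "contrast", "t", "df", "p_raw", "p_adj"]))

    # Behavioral cell summaries and factorial ANOVA per dimension.
    behav = cohort.behavior
    behav_summary = (behav.groupby(["dimension", "group", "condition"])["score"]
                     .agg(["mean", "std", "count"]).reset_index()
                     if len(behav) else
                     pd.DataFrame(columns=["dimension", "group", "condition",
                                           "mean", "std", "count"]))
    for dim, dcell in behav.groupby("dimension"):
        res = two_way_anova(dcell, "score", between=("group", "condition"))
        for eff_key, eff in res.effects.items():
            anova_rows.append({"band": "", "metric_type": "behavior", "name": dim,
                               "effect": {"A": "group", "B": "condition",
                                          "A:B": "group:condition"}[eff_key],
                               "F": eff.F, "df_num": eff.df_num,
                               "df_den": eff.df_den, "p": eff.p,
                               "partial_eta_sq": eff.partial_eta_sq})
    anova_table = pd.DataFrame(anova_rows)

    # Brain–behavior correlations within the chosen cell.
    corr_table, corr_mode = _brain_behavior(config, parc, cohort, pre_cohort,
                                            metrics, matrices)

    bundle = {
        "network_metrics": metrics,
        "metric_anova": anova_table,
        "posthoc": posthoc_table,
        "behavior_summary": behav_summary,
        "correlations": corr_table,
        "preprocess_report": prep_report,
        "manifest": {**config.manifest(), "analysis": "intervention",
                     "correlation_mode": corr_mode,
                     "cohort": cohort.manifest},
    }
    if config.out_dir:
        write_results(bundle, config.out_dir)
    return bundle


def _brain_behavior(config, parc, cohort, pre_cohort, post_metrics, matrices):
    """Pearson r of (Δ)network metrics vs (Δ)PA and NA in one design cell."""
    group, condition = config.corr_cell
    sel = cohort.subjects[(cohort.subjects["group"] == group)
                          & (cohort.subjects["condition"] == condition)]
    sids = sel["subject_id"].tolist()
    if len(sids) < 3 or not len(cohort.behavior):
        return (pd.DataFrame(columns=["band", "metric", "dimension", "r",
                                      "p", "n"]), "skipped")

    def metric_wide(metrics_df):
        sub = metrics_df[metrics_df["subject_id"].isin(sids)].copy()
        sub["metric"] = (sub["band"] + ":" + sub["metric_type"]
                         + ":" + sub["name"])
        return sub.pivot_table(index="subject_id", columns="metric",
                               values="value").reset_index()

    def behav_wide(behav_df):
        sub = behav_df[behav_df["subject_id"].isin(sids)]
        return sub.pivot_table(index="subject_id", columns="dimension",
                               values="score").reset_index()

    post_m = metric_wide(post_metrics)
    post_b = behav_wide(cohort.behavior)
    if pre_cohort is not None:
        pre_cleaned, _ = _preprocess_cohort(
            CohortData(subjects=pre_cohort.subjects,
                       recordings={s: pre_cohort.recordings[s] for s in sids
                                   if s in pre_cohort.recordings},
                       behavior=pre_cohort.behavior,
                       manifest=pre_cohort.manifest), config)
        pre_mats, pre_sum = _connectivity_stage(pre_cleaned, config, parc)
        pre_m = metric_wide(_metric_frame(pre_sum, pre_cohort.subjects))
        pre_b = behav_wide(pre_cohort.behavior)
        d_m, _ = change_scores(pre_m, post_m)
        d_b, _ = change_scores(pre_b, post_b)
        mode = "delta"
    else:
        d_m, d_b, mode = post_m, post_b, "post_only"

    merged = d_m.merge(d_b, on="subject_id")
    rows = []
    for col in [c for c in d_m.columns if c != "subject_id"]:
        for dim in [c for c in d_b.columns if c != "subject_id"]:
            x = merged[col].to_numpy(float)
            y = merged[dim].to_numpy(float)
            if np.std(x) == 0 or np.std(y) == 0:
                continue
            res = pearson(x, y)
            band, mtype, name = col.split(":", 2)
            rows.append({"band": band, "metric": f"{mtype}:{name}",
                         "dimension": dim, "r": res.r, "p": res.p, "n": res.n})
    return pd.DataFrame(rows, columns=["band", "metric", "dimension",
                                       "r", "p", "n"]), mode
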