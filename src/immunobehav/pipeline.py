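"""End-to-end orchestration.

Fixed stage order: cohort ingest/simulation -> schema validation and
exclusion of treated subjects without follow-up -> detection-limit
filtering -> per-batch min-max/log transform -> empirical-Bayes batch
adjustment of baseline concentrations (with PCA batch checks before and
after) -> sparse CCA on discovery-set change scores with permutation
inference -> frozen-weight confirmation on the validation set and null
check on the placebo control set -> covariation-plane clustering and
group change statistics -> baseline prediction with and without cytokine
features.

Everything stochastic draws from named child seeds of one global seed, so
two runs of the same config are identical.
"""

from __future__ import annotations


import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import cohort as ch
from . import predict as pr
from .cluster import PlaneClustering, group_change_stats, select_k_hubert
from .preprocess import ComBat, MinMaxLog, lod_filter, pca_batch_check
from .scca import (permutation_test, score_permutation_p,
                   select_budgets, sensitivity_partial)
from .stats import spearman_fdr

logger = logging.getLogger("immunobehav")

__all__ = ["RunConfig", "RunReport", "run_pipeline", "validate_schema"]

REQUIRED_COLUMNS = ["subject_id", "set", "arm", "batch", "visit", "sex",
                    "age_months", "bmi", "CARS_total"] + ch.CARS_SUBSCALES


@dataclass
class RunConfig:
    """Complete, serializable description of one analysis run."""

    sim: Optional[ch.SimConfig] = None          # synthetic input ...
    input_dir: Optional[str] = None             # ... or a cohort directory
    seed: int = 0
    lod_theta: float = 0.0
    combat_mean_only: bool = False
    c1: Optional[float] = None                  # fixed budgets, or None to
    c2: Optional[float] = None                  # cross-validate over the grid
    budget_grid_c2: Tuple[float, ...] = (1.2, 1.5, 1.8)
    n_perm: int = 5000
    k: Optional[int] = None                     # None: Hubert elbow
    k_range: Tuple[int, ...] = tuple(range(2, 9))
    pooled_clustering: bool = False             # cluster disc+val together
    labelings: Tuple[str, ...] = ("best", "least", "cutoff2.5", "cutoff2")
    m_features: int = 10
    n_boot: int = 100
    out_dir: Optional[str] = None

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.sim is not None:
            d["sim"] = self.sim.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if d.get("sim") is not None:
            d["sim"] = ch.SimConfig.from_dict(d["sim"])
        for key in ("budget_grid_c2", "k_range", "labelings"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class RunReport:
    """Stage-by-stage summary; every number traces to a stage artifact."""

    config: dict
    n_subjects: int
    excluded_subjects: List[str]
    kept_analytes: List[str]
    pairwise_q05_count: int
    batch_score_before: float
    batch_score_after: float
    budgets: Tuple[float, float]
    budget_table: Optional[dict]
    discovery_r: float
    discovery_p_perm: float
    n_perm: int
    weights_behaviour: Dict[str, float]
    weights_cytokine: Dict[str, float]
    active_set: List[str]
    validation_r: Optional[float]
    validation_p: Optional[float]
    control_r: Optional[float]
    control_p: Optional[float]
    sensitivity_partial_r: Optional[float]
    sensitivity_partial_p: Optional[float]
    chosen_k: int
    hubert_elbow_k: int
    k_low_confidence: bool
    group_sizes: Dict[str, int]
    prediction: Dict[str, dict]
    leak_audit_passed: bool
    control_skipped: bool = False

    def to_json(self, **kw) -> str:
        return json.dumps(asdict(self), indent=2, default=_jsonable, **kw)


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not serializable: {type(o)}")


def validate_schema(table: pd.DataFrame) -> List[str]:
    """All schema violations of a cohort table (empty list = ok)."""
    errors: List[str] = []
    for c in REQUIRED_COLUMNS:
        if c not in table.columns:
            errors.append(f"missing required column: {c}")
    if errors:
        return errors
    bad_visits = set(table["visit"]) - {"baseline", "month3"}
    if bad_visits:
        errors.append(f"unknown visit labels: {sorted(bad_visits)}")
    out_of_range = table.loc[(table["CARS_total"] < 15) | (table["CARS_total"] > 60),
                             "subject_id"]
    for sid in out_of_range.unique():
        errors.append(f"CARS_total outside [15, 60] for subject {sid}")
    fixed = set(REQUIRED_COLUMNS) | {"SRS_total"} | set(ch.ADOS_SUBSCALES) | set(ch.SRS_SUBSCALES)
    analyte_cols = [c for c in table.columns if c not in fixed]
    numeric = table[analyte_cols].select_dtypes("number")
    if (numeric < 0).any().any():
        bad = [c for c in numeric.columns if (numeric[c] < 0).any()]
        errors.append(f"negative concentrations in: {bad}")
    base_ids = set(table.loc[table.visit == "baseline", "subject_id"])
    m3_ids = set(table.loc[table.visit == "month3", "subject_id"])
    treated = set(table.loc[table.arm == "drug", "subject_id"])
    for sid in sorted(treated & base_ids - m3_ids):
        errors.append(f"treated subject {sid} lacks the month-3 visit")
    return errors


def _child_seeds(seed: int, n: int) -> List[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]


def run_pipeline(config: Optional[RunConfig] = None) -> RunReport:
    cfg = config or RunConfig()
    seeds = dict(zip(["budgets", "perm", "score_perm", "cluster", "predict"],
                     _child_seeds(cfg.seed, 5)))

    # ------------------------------------------------------------ ingest
    if cfg.input_dir is not None:
        cohort = ch.read_cohort(cfg.input_dir)
    else:
        sim = cfg.sim or ch.SimConfig(seed=cfg.seed)
        cohort = ch.generate_cohort(sim)
    errors = validate_schema(cohort)
    fatal = [e for e in errors if not e.startswith("treated subject")]
    if fatal:
        raise ValueError("schema violations:\n" + "\n".join(fatal))
    excluded = [e.split()[2] for e in errors if e.startswith("treated subject")]
    if excluded:
        logger.info("excluding treated subjects without follow-up: %s", excluded)
        cohort = cohort[~cohort["subject_id"].isin(excluded)]

    info = ch.subject_info(cohort)
    analytes = ch.analyte_names(cohort)
    ranges = ch.detection_ranges(cohort)
    sets = {name: info.index[info["set"] == name] for name in
            ("discovery", "validation", "control")}
    treated_ids = info.index[info["arm"] == "drug"]

    # -------------------------------------------------------- preprocess
    all_conc = cohort[["subject_id"] + analytes].set_index("subject_id")
    kept, _ = lod_filter(all_conc[analytes], ranges, theta=cfg.lod_theta)
    logger.info("LOD filter kept %d of %d analytes", len(kept), len(analytes))

    base_conc = ch.baseline_matrix(cohort, kept)
    batches = info.loc[base_conc.index, "batch"]
    mml_base = MinMaxLog().fit(base_conc, batches)
    base_norm = mml_base.transform(base_conc, batches)
    combat = ComBat(mean_only=cfg.combat_mean_only).fit(base_norm, batches)
    base_adj = combat.transform(base_norm, batches)
    score_before, _ = pca_batch_check(base_norm, batches)
    score_after, _ = pca_batch_check(base_adj, batches)

    chg_conc = ch.cytokine_change(cohort, kept)
    chg_norm = MinMaxLog().fit_transform(chg_conc, info.loc[chg_conc.index, "batch"])
    cars_chg = ch.cars_change(cohort)

    # ---------------------------------------------- univariate screen
    # pairwise Spearman of the CARS-total change against each analyte
    # change, BH-FDR corrected (typically empty at this design size; the
    # multivariate analysis below is the primary lens)
    disc = sets["discovery"]
    delta_total = ch.cars_change(cohort, include_total=True)["CARS_total"]
    screen = spearman_fdr(chg_norm.loc[disc], delta_total.loc[disc])
    pairwise_hits = int((screen["q"] < 0.05).sum())

    # ------------------------------------------------------- sparse CCA
    X1 = cars_chg.loc[disc]
    X2 = chg_norm.loc[disc]
    budget_table = None
    if cfg.c2 is None:
        grid = [(float(np.sqrt(X1.shape[1])), c2) for c2 in cfg.budget_grid_c2]
        (c1, c2), budget_table = select_budgets(X1, X2, grid, seed=seeds["budgets"])
    else:
        c1 = cfg.c1 if cfg.c1 is not None else float(np.sqrt(X1.shape[1]))
        c2 = cfg.c2
    p_perm, model = permutation_test(X1, X2, c1=c1, c2=c2,
                                     n_perm=cfg.n_perm, seed=seeds["perm"])

    def frozen_scores(ids):
        return model.transform(cars_chg.loc[ids], chg_norm.loc[ids])

    val = sets["validation"]
    validation_r = validation_p = None
    sens_r = sens_p = None
    if len(val):
        s1v, s2v = frozen_scores(val)
        validation_r, validation_p = score_permutation_p(
            s1v, s2v, n_perm=cfg.n_perm, seed=seeds["score_perm"])
        covs = pd.DataFrame({
            "age": info.loc[val, "age_months"].astype(float),
            "sex": (info.loc[val, "sex"] == "F").astype(float),
            "bmi": info.loc[val, "bmi"].astype(float),
            # canonical variables of the baseline blocks, frozen weights
            "beh_base": ch.baseline_matrix(cohort, model.x_names_).loc[val]
                        .to_numpy() @ model.x_weights_,
            "cyt_base": base_adj.loc[val, model.y_names_].to_numpy()
                        @ model.y_weights_,
        })
        sens_r, sens_p = sensitivity_partial(s1v, s2v, covs)

    ctl = sets["control"]
    control_r = control_p = None
    if len(ctl):
        s1c, s2c = frozen_scores(ctl)
        control_r, control_p = score_permutation_p(
            s1c, s2c, n_perm=cfg.n_perm, seed=seeds["score_perm"])

    # -------------------------------------------------------- clustering
    fit_ids = treated_ids if cfg.pooled_clustering else disc
    s1f, s2f = frozen_scores(fit_ids)
    plane_fit = np.column_stack([s2f, s1f])  # (cytokine, behaviour)
    # the Hubert elbow is always computed (it is the k used unless the
    # config fixes one, and a diagnostic otherwise)
    elbow_k, elbow_table = select_k_hubert(plane_fit, cfg.k_range,
                                           seed=seeds["cluster"])
    clus = PlaneClustering(k=cfg.k if cfg.k is not None else elbow_k,
                           k_range=cfg.k_range,
                           random_state=seeds["cluster"]).fit(plane_fit)
    clus.low_confidence_ = elbow_table.attrs["low_confidence"]
    labels = pd.Series(clus.labels_, index=fit_ids)
    rest = treated_ids.difference(fit_ids)
    if len(rest):
        s1r, s2r = frozen_scores(rest)
        labels = pd.concat([labels, pd.Series(
            clus.predict(np.column_stack([s2r, s1r])), index=rest)])
    labels = labels.loc[treated_ids]

    stats_vars = pd.concat([
        ch.cars_change(cohort, include_total=True)
          .loc[treated_ids, ["CARS_total"] + ch.CARS_SUBSCALES],
        ch.cytokine_change(cohort, model.active_set_).loc[treated_ids],
    ], axis=1)
    # groups too small for a one-sample t are excluded from the table only
    sizes = labels.value_counts()
    stat_groups = sizes.index[sizes >= 3]
    if len(stat_groups) < len(sizes):
        logger.info("groups excluded from the change table (n < 3): %s",
                    sorted(sizes.index[sizes < 3]))
    in_stats = labels.isin(stat_groups)
    if len(stat_groups) >= 2:
        group_table = group_change_stats(stats_vars.loc[in_stats.index[in_stats]],
                                         labels[in_stats])
    else:
        group_table = pd.DataFrame()

    # -------------------------------------------------------- prediction
    prediction: Dict[str, dict] = {}
    leak_ok = True
    if len(val):
        for mode in cfg.labelings:
            y = pr.make_labels(cohort, mode, cluster_labels=labels)
            y = y.reindex(treated_ids).astype(int)
            if y.loc[disc].nunique() < 2 or y.loc[val].nunique() < 2:
                prediction[mode] = {"skipped": "single-class labeling"}
                continue
            comp = pr.compare_feature_sets(
                cohort, y, kept, list(disc), list(val), labeling=mode,
                seed=seeds["predict"], m_features=cfg.m_features,
                n_boot=cfg.n_boot, baseline_cytokines=base_adj)
            leak_ok &= pr.audit_no_leak(comp["audit"], list(val))
            prediction[mode] = {
                "mean_auc_with": comp["mean_auc_with"],
                "mean_auc_without": comp["mean_auc_without"],
                "auc_diff_ci": comp["auc_diff_ci"],
                "per_family_auc": {
                    ("with" if inc else "without"): {r.family: r.auc for r in res}
                    for inc, res in comp["results"].items()},
                "positive_fraction": float(y.mean()),
            }

    report = RunReport(
        config=cfg.to_dict(),
        n_subjects=int(info.shape[0]),
        excluded_subjects=excluded,
        kept_analytes=kept,
        pairwise_q05_count=pairwise_hits,
        batch_score_before=score_before,
        batch_score_after=score_after,
        budgets=(float(c1), float(c2)),
        budget_table=None if budget_table is None else budget_table.to_dict("list"),
        discovery_r=model.r_,
        discovery_p_perm=float(p_perm),
        n_perm=cfg.n_perm,
        weights_behaviour=dict(zip(model.x_names_, model.x_weights_)),
        weights_cytokine={n: w for n, w in zip(model.y_names_, model.y_weights_)
                          if abs(w) > 1e-10},
        active_set=model.active_set_,
        validation_r=validation_r,
        validation_p=validation_p,
        control_r=control_r,
        control_p=control_p,
        sensitivity_partial_r=sens_r,
        sensitivity_partial_p=sens_p,
        chosen_k=clus.k_,
        hubert_elbow_k=int(elbow_k),
        k_low_confidence=clus.low_confidence_,
        group_sizes=labels.value_counts().to_dict(),
        prediction=prediction,
        leak_audit_passed=bool(leak_ok),
        control_skipped=not len(ctl),
    )

    if cfg.out_dir is not None:
        _write_artifacts(cfg, cohort, report, model, labels,
                         plane_fit, fit_ids, group_table, base_adj, chg_norm)
    return report


def _write_artifacts(cfg, cohort, report, model, labels, plane_fit, fit_ids,
                     group_table, base_adj, chg_norm) -> None:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "run_config.yaml", "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh)
    with open(out / "report.json", "w") as fh:
        fh.write(report.to_json())
    pd.DataFrame({"subject": fit_ids, "cyt_score": plane_fit[:, 0],
                  "beh_score": plane_fit[:, 1]}).to_csv(
        out / "plane_coordinates.csv", index=False)
    labels.rename("cluster").to_csv(out / "cluster_labels.csv")
    group_table.to_csv(out / "group_change_stats.csv")
    base_adj.to_csv(out / "baseline_adjusted.csv")
    chg_norm.to_csv(out / "changes_normalized.csv")
    weights = pd.concat([
        pd.Series(model.x_weights_, index=model.x_names_, name="weight"),
        pd.Series(model.y_weights_, index=model.y_names_, name="weight"),
    ])
    weights.to_csv(out / "canonical_weights.csv")
    if cfg.input_dir is None:
        ch.write_cohort(cohort, out / "cohort")
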