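"""Synthetic three-set cohort generator.

Emulates a small two-arm longitudinal drug study in young autistic
children: a discovery set (n=37, drug), a validation set (n=42, drug) and
a control set (n=37, placebo), each assayed in its own batch for a
48-analyte plasma cytokine panel (35 of which sit inside their detection
range) and assessed with CARS / ADOS / SRS at baseline and month 3.

Planted structure, recoverable by the downstream analysis:

* a latent 2-D "covariation plane" per subject: a cytokine-change score
  and a behaviour-change score whose population correlation in the
  treated arm is calibrated so that the canonical correlation between the
  observed active-cytokine block and the CARS-subscale-change block
  equals ``rho_latent`` (default 0.46);
* a 3-component Gaussian mixture on that plane (the response clusters);
  the mixture is whitened and recoloured by a linear map so the plane
  correlation is exact while Gaussian cluster separability (which is
  invariant under invertible linear maps) is preserved;
* only ``active_cytokines`` analytes load on the cytokine score; the
  placebo arm has coupling ``placebo_coupling`` (default 0) and an
  attenuated mean CARS change;
* additive location and multiplicative scale batch effects on the log
  concentration scale (the model empirical-Bayes batch adjustment assumes);
* a baseline "inflammatory signature" on a few non-active analytes that
  carries cluster information, so baseline cytokines help predict the
  response subgroup.

Everything is deterministic given ``SimConfig.seed``.
"""

from __future__ import annotations

from collections import namedtuple
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SimConfig",
    "generate_cohort",
    "ground_truth",
    "GroundTruth",
    "detection_ranges",
    "write_cohort",
    "read_cohort",
    "cars_change",
    "cytokine_change",
    "baseline_matrix",
    "treated_subjects",
    "CARS_SUBSCALES",
    "ADOS_SUBSCALES",
    "SRS_SUBSCALES",
]

CARS_SUBSCALES = ["CARS_S", "CARS_N", "CARS_D"]
ADOS_SUBSCALES = ["ADOS_S", "ADOS_C", "ADOS_P", "ADOS_I"]
SRS_SUBSCALES = ["SRS_AWA", "SRS_COG", "SRS_COM", "SRS_MOT", "SRS_MANN"]

# Named exemplar analytes; the remainder get generic panel names.
_EXEMPLAR_ANALYTES = ["MIG", "IFN-g", "IFN-a2", "IL-1b", "IL-4", "IL-6", "IL-8", "TNF-a"]
_EXEMPLAR_MEDIANS = {  # pg/ml, plausible plasma mid-range levels
    "MIG": 1100.0, "IFN-g": 30.0, "IFN-a2": 55.0, "IL-1b": 4.0,
    "IL-4": 6.0, "IL-6": 12.0, "IL-8": 25.0, "TNF-a": 40.0,
}

# Fraction of each observed change-score variance explained by its block's
# latent plane score (per-variable loading^2 on the standardized scale).
_LOADING_R2 = 0.8

GroundTruth = namedtuple("GroundTruth", ["active_analytes", "cluster_labels", "factors"])


@dataclass
class SimConfig:
    """Study-design parameters of the synthetic cohort."""

    n_discovery: int = 37
    n_validation: int = 42
    n_control: int = 37
    n_analytes: int = 48
    n_detectable: int = 35
    rho_latent: float = 0.46
    active_cytokines: int = 3
    cluster_props: Tuple[float, float, float] = (0.215, 0.557, 0.228)
    # (cytokine-score, behaviour-score) centroids, pre-recolouring, listed
    # best / medium / least responder first-to-last.
    cluster_centroids: Tuple[Tuple[float, float], ...] = (
        (0.9, 1.3), (0.25, -0.2), (-1.3, -0.95))
    within_cluster_sd: float = 0.3
    batch_shift: Tuple[float, float, float] = (0.0, 0.5, -0.4)
    batch_scale: Tuple[float, float, float] = (1.0, 1.4, 0.75)
    placebo_coupling: float = 0.0
    placebo_attenuation: float = 0.5
    baseline_cluster_effect: float = 0.5  # log-units, on signature analytes
    cytokine_change_scale: float = 0.5    # SD of log-scale changes
    baseline_log_sd: float = 0.4          # between-subject SD of log baseline
    mcar_rate: float = 0.0                # optional MCAR mask on ADOS/SRS baseline
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.cluster_props) - 1.0) > 1e-9:
            raise ValueError("cluster_props must sum to 1")
        if self.n_detectable > self.n_analytes:
            raise ValueError("n_detectable cannot exceed n_analytes")
        if not 0.0 <= self.rho_latent <= 1.0:
            raise ValueError("rho_latent must lie in [0, 1]")
        if self.active_cytokines < 1 or self.active_cytokines > self.n_detectable:
            raise ValueError("active_cytokines must lie in [1, n_detectable]")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        for key in ("cluster_props", "batch_shift", "batch_scale"):
            if key in d:
                d[key] = tuple(d[key])
        if "cluster_centroids" in d:
            d["cluster_centroids"] = tuple(tuple(c) for c in d["cluster_centroids"])
        return cls(**d)


def _block_r(m: int, r2: float = _LOADING_R2) -> float:
    """Multiple correlation between a block's latent score and its m
    observed variables under equal loadings."""
    return float(np.sqrt(m * r2 / (m * r2 + (1.0 - r2))))


def _plane_rho(target: float, m_beh: int, m_cyt: int) -> float:
    """Plane-score correlation needed for the observed-block canonical
    correlation to equal `target`; errors when the loadings make the
    target infeasible."""
    rho = target / (_block_r(m_beh) * _block_r(m_cyt))
    if abs(rho) > 0.999:
        raise ValueError(
            f"rho_latent={target} is infeasible for the configured loadings "
            f"(required plane correlation {rho:.3f} exceeds 1)")
    return rho


def _mixture_moments(props: np.ndarray, cents: np.ndarray, sd_w: float):
    mu = props @ cents
    centered = cents - mu
    cov = (props[:, None, None] * np.einsum("ki,kj->kij", centered, centered)).sum(axis=0)
    cov += sd_w**2 * np.eye(2)
    return mu, cov


def _recolour(rho: float, mu: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """Linear map sending the mixture covariance to corr-rho unit-variance."""
    l_mix = np.linalg.cholesky(cov)
    l_target = np.linalg.cholesky(np.array([[1.0, rho], [rho, 1.0]]))
    return l_target @ np.linalg.inv(l_mix)


def _analyte_names(n: int) -> List[str]:
    names = list(_EXEMPLAR_ANALYTES[:n])
    names += [f"CYT{i:02d}" for i in range(len(names) + 1, n + 1)]
    return names


def _draw_bounded(rng: np.random.Generator, means, sds, n: int,
                  total_offset: float, lo: float, hi: float) -> np.ndarray:
    """Draw CARS subscales with the implied total in [lo, hi]."""
    means = np.asarray(means)
    sds = np.asarray(sds)
    out = means + sds * rng.normal(size=(n, means.size))
    for _ in range(100):
        tot = out.sum(axis=1) + total_offset
        bad = (tot < lo) | (tot > hi)
        if not bad.any():
            break
        out[bad] = means + sds * rng.normal(size=(int(bad.sum()), means.size))
    return out


def generate_cohort(config: Optional[SimConfig] = None) -> pd.DataFrame:
    """Generate one cohort table, one row per subject per visit.

    The returned frame carries hidden ground truth (active analyte set,
    cluster labels, plane scores), the detection-range table and the
    config in ``DataFrame.attrs``; analysis stages must not read these.
    """
    cfg = config or SimConfig()
    rng = np.random.default_rng(cfg.seed)

    sets = (["discovery"] * cfg.n_discovery + ["validation"] * cfg.n_validation
            + ["control"] * cfg.n_control)
    n = len(sets)
    set_arr = np.array(sets)
    arm = np.where(set_arr == "control", "placebo", "drug")
    batch_of_set = {"discovery": 0, "validation": 1, "control": 2}
    batch_idx = np.array([batch_of_set[s] for s in sets])
    subject_id = np.array([f"S{i + 1:03d}" for i in range(n)])

    props = np.asarray(cfg.cluster_props, dtype=float)
    cents = np.asarray(cfg.cluster_centroids, dtype=float)
    cluster = rng.choice(len(props), size=n, p=props)

    # --- latent covariation plane ------------------------------------
    mu_mix, cov_mix = _mixture_moments(props, cents, cfg.within_cluster_sd)
    rho_drug = _plane_rho(cfg.rho_latent, len(CARS_SUBSCALES), cfg.active_cytokines)
    rho_plac = _plane_rho(cfg.placebo_coupling, len(CARS_SUBSCALES), cfg.active_cytokines)
    t_drug = _recolour(rho_drug, mu_mix, cov_mix)
    t_plac = _recolour(rho_plac, mu_mix, cov_mix)

    raw = cents[cluster] + cfg.within_cluster_sd * rng.normal(size=(n, 2))
    plane = np.empty((n, 2))
    is_drug = arm == "drug"
    plane[is_drug] = (raw[is_drug] - mu_mix) @ t_drug.T
    plane[~is_drug] = (raw[~is_drug] - mu_mix) @ t_plac.T
    score_cyt, score_beh = plane[:, 0], plane[:, 1]

    # Named clusters, ordered by the transformed centroids' behaviour mean.
    cents_t = (cents - mu_mix) @ t_drug.T
    order = np.argsort(-cents_t[:, 1])
    name_of = {int(k): nm for k, nm in zip(order, ["best", "medium", "least"])}
    cluster_named = np.array([name_of[int(k)] for k in cluster])

    # --- demographics --------------------------------------------------
    sex = np.where(rng.random(n) < 0.19, "F", "M")
    age = np.clip(np.round(rng.normal(50, 16, n)), 36, 120)
    bmi = np.round(np.clip(rng.normal(16.9, 3.5, n), 12, 30), 1)

    # --- CARS ----------------------------------------------------------
    sub_means = np.array([22.5, 7.1, 7.4])
    sub_sds = np.array([2.4, 0.9, 0.95])
    offset = 1.0  # remaining-items constant; total = S + N + D + offset
    cars_base = _draw_bounded(rng, sub_means, sub_sds, n, offset, 30.0, 60.0)

    a = np.sqrt(_LOADING_R2)
    b = np.sqrt(1.0 - _LOADING_R2)
    chg_means = np.array([1.0, 0.35, 0.40])
    chg_sds = np.array([1.0, 0.55, 0.45])
    mean_scale = np.where(is_drug, 1.0, cfg.placebo_attenuation)[:, None]
    delta_cars = (mean_scale * chg_means
                  + chg_sds * (a * score_beh[:, None]
                               + b * rng.normal(size=(n, 3))))
    cars_month3 = cars_base - delta_cars

    # --- ADOS / SRS (weakly tied to the cytokine plane score) ----------
    r_aux = 0.25
    b_aux = np.sqrt(1 - r_aux**2)

    def aux_block(means, sds):
        means = np.asarray(means)
        sds = np.asarray(sds)
        z = r_aux * score_cyt[:, None] + b_aux * rng.normal(size=(n, means.size))
        return np.round(np.clip(means + sds * z, 0, None), 1)

    ados_base = aux_block([6.6, 10.0, 2.4, 2.1], [2.7, 2.7, 1.4, 2.0])
    ados_month3 = np.round(np.clip(ados_base - rng.normal(0.3, 0.8, (n, 4)), 0, None), 1)
    srs_base = aux_block([10.0, 16.0, 28.0, 13.0, 12.0], [4.5, 6.5, 12.0, 5.5, 7.0])

    # --- cytokines ------------------------------------------------------
    analytes = _analyte_names(cfg.n_analytes)
    active = analytes[:cfg.active_cytokines]
    detectable = analytes[:cfg.n_detectable]
    # Baseline cluster signature sits on non-active detectable analytes so
    # the planted change-block structure stays clean.
    n_sig = min(4, cfg.n_detectable - cfg.active_cytokines)
    signature = analytes[cfg.active_cytokines:cfg.active_cytokines + n_sig]

    log_mu = np.array([
        np.log(_EXEMPLAR_MEDIANS[nm]) if nm in _EXEMPLAR_MEDIANS
        else rng.uniform(np.log(5.0), np.log(1500.0))
        for nm in analytes])

    cluster_dir = np.zeros(n)
    cluster_dir[cluster_named == "best"] = 1.0
    cluster_dir[cluster_named == "least"] = -1.0

    log_base = log_mu[None, :] + cfg.baseline_log_sd * rng.normal(size=(n, cfg.n_analytes))
    for nm in signature:
        log_base[:, analytes.index(nm)] += cfg.baseline_cluster_effect * cluster_dir

    dlog = cfg.cytokine_change_scale * rng.normal(size=(n, cfg.n_analytes))
    for nm in active:
        j = analytes.index(nm)
        dlog[:, j] = cfg.cytokine_change_scale * (
            a * score_cyt + b * rng.normal(size=n))
    log_month3 = log_base + dlog

    # Batch location/scale effects on the log scale (the empirical-Bayes
    # adjustment model), applied identically at both visits.
    shift = np.asarray(cfg.batch_shift)[batch_idx][:, None]
    scale = np.asarray(cfg.batch_scale)[batch_idx][:, None]
    conc_base = np.exp(log_mu[None, :] + shift + scale * (log_base - log_mu[None, :]))
    conc_month3 = np.exp(log_mu[None, :] + shift + scale * (log_month3 - log_mu[None, :]))

    # Detection ranges: detectable analytes sit comfortably inside theirs;
    # the remainder fall below the lower limit.
    lower = np.where(np.isin(analytes, detectable),
                     np.exp(log_mu - 8.0), np.exp(log_mu + 6.0))
    ranges = pd.DataFrame({"analyte": analytes, "lower": lower,
                           "upper": lower * 1e5})

    # --- assemble long table --------------------------------------------
    def visit_frame(visit, cars, ados, srs, conc):
        d = {
            "subject_id": subject_id, "set": set_arr, "arm": arm,
            "batch": np.array([f"batch{i + 1}" for i in batch_idx]),
            "visit": visit, "sex": sex, "age_months": age, "bmi": bmi,
        }
        for i, c in enumerate(CARS_SUBSCALES):
            d[c] = np.round(cars[:, i], 2)
        d["CARS_total"] = np.round(cars.sum(axis=1) + offset, 2)
        for i, c in enumerate(ADOS_SUBSCALES):
            d[c] = ados[:, i]
        for i, c in enumerate(SRS_SUBSCALES):
            d[c] = srs[:, i] if srs is not None else np.nan
        d["SRS_total"] = srs.sum(axis=1) if srs is not None else np.nan
        for j, nm in enumerate(analytes):
            d[nm] = conc[:, j]
        return pd.DataFrame(d)

    base_df = visit_frame("baseline", cars_base, ados_base, srs_base, conc_base)
    m3_df = visit_frame("month3", cars_month3, ados_month3, None, conc_month3)

    if cfg.mcar_rate > 0:
        mask_cols = ADOS_SUBSCALES + SRS_SUBSCALES + ["SRS_total"]
        m = rng.random((n, len(mask_cols))) < cfg.mcar_rate
        for i, c in enumerate(mask_cols):
            base_df.loc[m[:, i], c] = np.nan

    cohort = pd.concat([base_df, m3_df], ignore_index=True)

    truth = pd.DataFrame({
        "subject_id": subject_id,
        "cluster": cluster_named,
        "score_cyt": score_cyt,
        "score_beh": score_beh,
    })
    cohort.attrs["ground_truth"] = {
        "active_analytes": list(active),
        "signature_analytes": list(signature),
        "truth": truth,
    }
    cohort.attrs["detection_ranges"] = ranges
    cohort.attrs["config"] = cfg.to_dict()
    cohort.attrs["analytes"] = list(analytes)
    return cohort


def ground_truth(cohort: pd.DataFrame) -> GroundTruth:
    """Hidden generator fields, for recovery tests only."""
    gt = cohort.attrs.get("ground_truth")
    if gt is None:
        raise ValueError("cohort carries no ground truth "
                         "(not produced by generate_cohort, or lost in I/O; "
                         "use read_cohort on a written cohort directory)")
    truth = gt["truth"]
    return GroundTruth(
        active_analytes=list(gt["active_analytes"]),
        cluster_labels=truth.set_index("subject_id")["cluster"],
        factors=truth.set_index("subject_id")[["score_cyt", "score_beh"]],
    )


def detection_ranges(cohort: pd.DataFrame) -> pd.DataFrame:
    ranges = cohort.attrs.get("detection_ranges")
    if ranges is None:
        raise ValueError("cohort carries no detection-range table")
    return ranges


def analyte_names(cohort: pd.DataFrame) -> List[str]:
    return list(cohort.attrs["analytes"])


# ---------------------------------------------------------------------------
# table utilities

def treated_subjects(cohort: pd.DataFrame) -> pd.DataFrame:
    return cohort[cohort["arm"] == "drug"]


def _wide(cohort: pd.DataFrame, cols: Sequence[str]) -> Tuple[pd.DataFrame, pd.DataFrame]:
    base = cohort[cohort["visit"] == "baseline"].set_index("subject_id")
    m3 = cohort[cohort["visit"] == "month3"].set_index("subject_id")
    m3 = m3.reindex(base.index)
    base, m3 = base[list(cols)].copy(), m3[list(cols)].copy()
    base.attrs = {}
    m3.attrs = {}
    return base, m3


def cars_change(cohort: pd.DataFrame, include_total: bool = False) -> pd.DataFrame:
    """CARS change scores, improvement positive: baseline minus month 3."""
    cols = CARS_SUBSCALES + (["CARS_total"] if include_total else [])
    base, m3 = _wide(cohort, cols)
    return base - m3


def cytokine_change(cohort: pd.DataFrame, analytes: Sequence[str]) -> pd.DataFrame:
    """Cytokine change scores: month 3 minus baseline (pg/ml)."""
    base, m3 = _wide(cohort, analytes)
    return m3 - base


def baseline_matrix(cohort: pd.DataFrame, cols: Sequence[str]) -> pd.DataFrame:
    base = cohort[cohort["visit"] == "baseline"].set_index("subject_id")
    out = base[list(cols)].copy()
    out.attrs = {}
    return out


def subject_info(cohort: pd.DataFrame) -> pd.DataFrame:
    """One row per subject: id, set, arm, batch, demographics."""
    base = cohort[cohort["visit"] == "baseline"]
    out = base[["subject_id", "set", "arm", "batch", "sex", "age_months",
                "bmi"]].set_index("subject_id").copy()
    out.attrs = {}
    return out


# ---------------------------------------------------------------------------
# I/O

def write_cohort(cohort: pd.DataFrame, out_dir) -> None:
    """Cohort CSV + config sidecar + hidden truth in a separate file."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.to_csv(out / "cohort.csv", index=False)
    detection_ranges(cohort).to_csv(out / "detection_ranges.csv", index=False)
    with open(out / "sim_config.yaml", "w") as fh:
        yaml.safe_dump(cohort.attrs["config"], fh)
    gt = cohort.attrs["ground_truth"]
    gt["truth"].to_csv(out / "ground_truth.csv", index=False)
    with open(out / "ground_truth.yaml", "w") as fh:
        yaml.safe_dump({"active_analytes": gt["active_analytes"],
                        "signature_analytes": gt["signature_analytes"]}, fh)


def read_cohort(in_dir) -> pd.DataFrame:
    src = Path(in_dir)
    cohort = pd.read_csv(src / "cohort.csv")
    rng_path = src / "detection_ranges.csv"
    if rng_path.exists():
        cohort.attrs["detection_ranges"] = pd.read_csv(rng_path)
    cfg_path = src / "sim_config.yaml"
    if cfg_path.exists():
        with open(cfg_path) as fh:
            cohort.attrs["config"] = yaml.safe_load(fh)
    truth_path = src / "ground_truth.csv"
    meta_path = src / "ground_truth.yaml"
    if truth_path.exists() and meta_path.exists():
        with open(meta_path) as fh:
            meta = yaml.safe_load(fh)
        cohort.attrs["ground_truth"] = {
            "active_analytes": meta["active_analytes"],
            "signature_analytes": meta["signature_analytes"],
            "truth": pd.read_csv(truth_path),
        }
    fixed = [c for c in cohort.columns if c in {
        "subject_id", "set", "arm", "batch", "visit", "sex", "age_months",
        "bmi", "CARS_total", "SRS_total"} or c.startswith(("CARS_", "ADOS_", "SRS_"))]
    cohort.attrs["analytes"] = [c for c in cohort.columns if c not in fixed]
    return cohort
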