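"""End-to-end orchestration: simulate -> relaxometry -> loops -> maps -> stats.

Two analysis granularities are provided.  ``run_subject`` is the full
voxelwise path producing the nine whole-volume parameter maps.
``run_subject_regional`` averages the raw signals within each VOI of the
healthy hemisphere first and fits one curve pair per region — the
standard region-of-interest shortcut for dynamic contrast studies — and
is the default for whole-cohort statistical runs, where only VOI means
enter the analysis anyway.

A cohort run produces a long-format table with one row per
(subject, VOI, parameter), joined to demographics, and the statistical
battery returns one row per test with FDR-adjusted q-values within each
parameter's group-comparison family.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .acquisition import AcquisitionParams
from .maps import (
    HemisphereSpec,
    PARAMETER_NAMES,
    PhysicalConstants,
    assemble_maps,
    compute_q,
    compute_vsi,
    hemisphere_split,
    normalize_rcbv,
    rcbv_integral,
)
from .relaxometry import (
    compute_delta_r,
    estimate_baseline,
    fit_gamma_variate,
    leakage_correct,
)
from .simulate import REGION_LABELS, CohortSpec, SubjectData, simulate_cohort
from .stats import (
    OutlierConfig,
    StatResult,
    bh_fdr,
    partial_correlation,
    rout_outliers,
    two_group_compare,
    voi_mean,
)
from .vhl import compute_vhl_parameters

__all__ = [
    "RunConfig",
    "SubjectResult",
    "run_subject",
    "run_subject_regional",
    "run_cohort",
    "cohort_statistics",
]

log = logging.getLogger("vamkit")


@dataclass(frozen=True)
class RunConfig:
    """Resolved configuration of one analysis run (fully serializable)."""

    acq: AcquisitionParams = field(default_factory=AcquisitionParams)
    constants: PhysicalConstants = field(default_factory=PhysicalConstants)
    r2_min: float = 0.6
    peak_snr_k: float = 3.0
    leakage_correction: bool = True
    alpha: float = 0.05
    fdr_q: float = 0.05
    rout_q: float = 0.01
    adjust_correlations: bool = False
    strata: tuple[str, ...] = ("all", "F", "M")
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "acq" in d and isinstance(d["acq"], dict):
            d["acq"] = AcquisitionParams(**d["acq"])
        if "constants" in d and isinstance(d["constants"], dict):
            d["constants"] = PhysicalConstants(**d["constants"])
        if "strata" in d:
            d["strata"] = tuple(d["strata"])
        return cls(**d)


@dataclass
class SubjectResult:
    """Per-subject output: nine maps, VOI means, and stage counters.

    ``quality`` holds per-voxel fit-diagnostic maps (r2 of each echo's
    gamma-variate fit) on the same grid as the parameter maps.
    """

    subject_id: str
    maps: dict[str, np.ndarray] = field(repr=False)
    voi_table: pd.DataFrame = field(repr=False)
    counters: dict[str, int] = field(default_factory=dict)
    quality: dict[str, np.ndarray] = field(default_factory=dict, repr=False)


def _fit_curve_pair(sig_ge, sig_se, reference, config: RunConfig):
    """Signals -> (fit_se, fit_ge, corrected dR2* curve) for one voxel/region."""
    acq = config.acq
    times = acq.times
    s0_ge = estimate_baseline(sig_ge, acq.n_baseline)
    s0_se = estimate_baseline(sig_se, acq.n_baseline)
    if s0_ge <= 0 or s0_se <= 0:
        return None
    try:
        dr2s = compute_delta_r(sig_ge, s0_ge, acq.te_ge)
        dr2 = compute_delta_r(sig_se, s0_se, acq.te_se)
    except ValueError:
        return None
    if config.leakage_correction and reference is not None:
        dr2s, _ = leakage_correct(dr2s, reference, times)
    kw = dict(n_baseline=acq.n_baseline, peak_snr_k=config.peak_snr_k,
              r2_min=config.r2_min)
    fit_ge = fit_gamma_variate(dr2s, times, **kw)
    fit_se = fit_gamma_variate(dr2, times, **kw)
    return fit_se, fit_ge, dr2s


def _parameters_from_fits(fit_se, fit_ge, dr2s_curve, config: RunConfig):
    """The nine scalars (rCBV still un-normalized) or None if invalid."""
    if not (fit_se.valid and fit_ge.valid):
        return None
    vhl = compute_vhl_parameters(fit_se, fit_ge)
    pk_se, pk_ge = fit_se.peak, fit_ge.peak
    return {
        "I": vhl.i, "VTI": vhl.vti, "VIPS": vhl.vips, "CGI": vhl.cgi,
        "CBI": vhl.cbi, "BVF": vhl.bvf,
        "VSI": compute_vsi(pk_ge, pk_se, config.constants),
        "Q": compute_q(pk_se, pk_ge),
        "rCBV": rcbv_integral(dr2s_curve, config.acq.times, config.acq.n_baseline),
    }


def _reference_curve(subject: SubjectData, healthy: np.ndarray,
                     config: RunConfig) -> np.ndarray | None:
    """Whole-brain (healthy hemisphere) mean dR2* curve for leakage fits."""
    acq = config.acq
    brain = (subject.voi_mask > 0) & healthy
    sig = subject.signal_ge[brain]
    mean_sig = sig.mean(axis=0)
    s0 = estimate_baseline(mean_sig, acq.n_baseline)
    try:
        return compute_delta_r(mean_sig, s0, acq.te_ge)
    except ValueError:
        return None


def _hemisphere(subject: SubjectData) -> HemisphereSpec:
    return HemisphereSpec(lesion_side=subject.lesion_side,
                          midline_index=subject.shape[0] // 2)


def run_subject(subject: SubjectData, config: RunConfig) -> SubjectResult:
    """Full voxelwise analysis of one subject.

    Every healthy-hemisphere brain voxel is fitted independently; the
    nine maps get NaN where a fit failed, NaN outside the brain mask,
    and zeros over the whole lesioned hemisphere.  VOI means are taken
    over valid healthy-hemisphere voxels only.
    """
    hemi = _hemisphere(subject)
    healthy, _ = hemisphere_split(subject.shape, hemi)
    reference = _reference_curve(subject, healthy, config)
    brain = subject.voi_mask > 0
    todo = np.nonzero(brain & healthy)
    n_vox = len(todo[0])

    values = {name: np.full(subject.shape, np.nan) for name in PARAMETER_NAMES}
    quality = {name: np.full(subject.shape, np.nan)
               for name in ("fit_r2_GE", "fit_r2_SE")}
    n_ok = 0
    for i in range(n_vox):
        idx = (todo[0][i], todo[1][i], todo[2][i])
        pair = _fit_curve_pair(subject.signal_ge[idx], subject.signal_se[idx],
                               reference, config)
        if pair is None:
            continue
        fit_se, fit_ge, _ = pair
        quality["fit_r2_GE"][idx] = fit_ge.r2
        quality["fit_r2_SE"][idx] = fit_se.r2
        params = _parameters_from_fits(*pair, config)
        if params is None:
            continue
        n_ok += 1
        for name, val in params.items():
            values[name][idx] = val

    healthy_brain = brain & healthy
    if np.any(np.isfinite(values["rCBV"][healthy_brain])):
        values["rCBV"] = normalize_rcbv(values["rCBV"], healthy_brain)
    maps = assemble_maps(values, brain, hemi)

    rows = []
    for label, region in REGION_LABELS.items():
        if not np.any((subject.voi_mask == label) & healthy):
            continue
        for name in PARAMETER_NAMES:
            stats = voi_mean(maps[name], subject.voi_mask, label,
                             valid_mask=healthy)
            if stats["n_voxels"] == 0:
                log.info("subject %s: VOI %s has no valid voxels for %s",
                         subject.subject_id, region, name)
                continue
            rows.append({"subject_id": subject.subject_id, "voi": region,
                         "parameter": name, "mean_value": stats["mean"],
                         "sd": stats["sd"], "n_voxels": stats["n_voxels"]})
    counters = {"voxels_in": n_vox, "voxels_valid": n_ok}
    log.info("subject %s: %d/%d voxels valid", subject.subject_id, n_ok, n_vox)
    return SubjectResult(subject.subject_id, maps, pd.DataFrame(rows), counters,
                         quality=quality)


def run_subject_regional(subject: SubjectData, config: RunConfig) -> pd.DataFrame:
    """Region-averaged analysis: one fitted curve pair per healthy VOI.

    Signals are averaged across the VOI's voxels before relaxometry,
    boosting SNR by sqrt(n_voxels); rCBV is normalized by the mean
    integral across the healthy-hemisphere VOIs (voxel-count weighted),
    the regional analogue of the whole-brain normalization.
    """
    hemi = _hemisphere(subject)
    healthy, _ = hemisphere_split(subject.shape, hemi)
    reference = _reference_curve(subject, healthy, config)
    rows = []
    raw_rcbv: dict[str, float] = {}
    weights: dict[str, int] = {}
    region_params: dict[str, dict] = {}
    for label, region in REGION_LABELS.items():
        sel = (subject.voi_mask == label) & healthy
        n_vox = int(sel.sum())
        if n_vox == 0:
            continue
        mean_ge = subject.signal_ge[sel].mean(axis=0)
        mean_se = subject.signal_se[sel].mean(axis=0)
        pair = _fit_curve_pair(mean_ge, mean_se, reference, config)
        if pair is None:
            continue
        params = _parameters_from_fits(*pair, config)
        if params is None:
            continue
        region_params[region] = params
        raw_rcbv[region] = params["rCBV"]
        weights[region] = n_vox
    if raw_rcbv:
        vals = np.array([raw_rcbv[r] for r in raw_rcbv])
        wts = np.array([weights[r] for r in raw_rcbv], dtype=float)
        fin = np.isfinite(vals)
        ref_int = float(np.average(vals[fin], weights=wts[fin])) if fin.any() else np.nan
        for region, params in region_params.items():
            if np.isfinite(ref_int) and ref_int > 0:
                params["rCBV"] = params["rCBV"] / ref_int
            for name in PARAMETER_NAMES:
                rows.append({"subject_id": subject.subject_id, "voi": region,
                             "parameter": name, "mean_value": params[name]})
    return pd.DataFrame(rows)


def run_cohort(
    spec: CohortSpec,
    config: RunConfig,
    shape: tuple[int, int, int] = (24, 24, 6),
    mode: str = "regional",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate and analyze a whole cohort.

    Returns ``(cohort_table, demographics)``; the cohort table is
    long-format with one row per (subject, VOI, parameter) joined to
    age/sex/BMI.  ``mode`` selects the voxelwise (``"voxel"``) or
    region-averaged (``"regional"``, default) analysis path.
    """
    tables = []
    demo_rows = []
    for subject, row in simulate_cohort(spec, config.acq, shape=shape):
        demo_rows.append(row)
        if mode == "voxel":
            tab = run_subject(subject, config).voi_table
        elif mode == "regional":
            tab = run_subject_regional(subject, config)
        else:
            raise ValueError(f"unknown mode {mode!r}")
        tables.append(tab)
    demographics = pd.DataFrame(demo_rows).reset_index(drop=True)
    table = pd.concat(tables, ignore_index=True)
    table = table.merge(
        demographics[["subject_id", "age_years", "sex", "bmi"]],
        on="subject_id", how="left",
    )
    return table, demographics


# ---------------------------------------------------------------------------
# statistical battery


def cohort_statistics(table: pd.DataFrame, config: RunConfig | None = None
                      ) -> pd.DataFrame:
    """Run the full battery on a long-format cohort table.

    Per (parameter, VOI) column: ROUT outlier flags (excluded, not
    dropped — flagged rows are recorded in the ``outlier`` column of the
    returned input echo), a sex comparison via the normality gate, and
    age partial correlations controlling BMI within each configured
    stratum.  Group-comparison p-values are BH-adjusted within each
    parameter across VOIs; correlations are reported unadjusted unless
    ``config.adjust_correlations`` is set.
    """
    config = config or RunConfig()
    rout_cfg = OutlierConfig(rout_q=config.rout_q)
    results: list[StatResult] = []
    families: dict[str, list[int]] = {}

    for parameter, ptab in table.groupby("parameter", sort=True):
        fam_idx: list[int] = []
        for voi, vtab in ptab.groupby("voi", sort=True):
            vtab = vtab.dropna(subset=["mean_value"])
            vals = vtab["mean_value"].to_numpy()
            with np.errstate(all="ignore"):
                flags = (rout_outliers(vals, rout_cfg) if len(vals) >= 10
                         else np.zeros(len(vals), dtype=bool))
            keep = vtab.loc[~flags]
            cid = f"{parameter}|{voi}"
            # sex comparison
            res = two_group_compare(
                keep.loc[keep.sex == "F", "mean_value"].to_numpy(),
                keep.loc[keep.sex == "M", "mean_value"].to_numpy(),
                comparison_id=f"{cid}|F-vs-M",
            )
            if res is not None:
                fam_idx.append(len(results))
                results.append(res)
            # age correlations (partial, controlling BMI) per stratum
            for stratum in config.strata:
                sub = keep if stratum == "all" else keep.loc[keep.sex == stratum]
                res = partial_correlation(
                    sub["age_years"].to_numpy(), sub["mean_value"].to_numpy(),
                    sub["bmi"].to_numpy(),
                    comparison_id=f"{cid}|age-partial|{stratum}",
                )
                if res is not None:
                    if config.adjust_correlations:
                        fam_idx.append(len(results))
                    results.append(res)
        families[parameter] = fam_idx

    for parameter, idx in families.items():
        if not idx:
            continue
        pvals = np.array([results[i].p_value for i in idx])
        _, qvals = bh_fdr(pvals, q=config.fdr_q)
        for i, qv in zip(idx, qvals):
            results[i].q_value = float(max(qv, results[i].p_value))

    out = pd.DataFrame([dataclasses.asdict(r) for r in results])
    if not out.empty:
        parts = out["comparison_id"].str.split("|", expand=True)
        out.insert(0, "parameter", parts[0])
        out.insert(1, "voi", parts[1])
        out.insert(2, "comparison", parts.iloc[:, 2:].fillna("").agg("|".join, axis=1).str.rstrip("|"))
    return out
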