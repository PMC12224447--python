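"""Forward simulation of dual-echo bolus signals and synthetic cohorts.

The generator inverts the measurement model: a ground-truth gamma-variate
relaxation-rate curve per echo is converted to signal via
``S(t) = S0 * exp(-TE * dR(t))``, optionally contaminated by a contrast
leakage term on the gradient echo, and additive Gaussian noise is placed
on the magnitude signal.  Subjects are small 3D phantoms with mirrored
volume-of-interest labels in both hemispheres and a lesion-side flag;
cohorts draw per-subject demographics (age, sex, BMI) and plant linear
age effects on chosen truth fields in chosen regions and sex strata.

Ground truth is retained for every voxel region so that downstream
recovery can be scored against it.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .acquisition import AcquisitionParams
from .relaxometry import gamma_scale_from_peak, gamma_variate

__all__ = [
    "VoxelTruth",
    "Effect",
    "CohortSpec",
    "SubjectData",
    "REGION_LABELS",
    "REGION_DEFAULTS",
    "simulate_voxel",
    "default_voi_mask",
    "simulate_subject",
    "simulate_cohort",
    "write_subject",
]

#: label -> region name for the eight analyzed volumes of interest
REGION_LABELS = {
    1: "cortical_gm",
    2: "white_matter",
    3: "caudate_nucleus",
    4: "putamen",
    5: "globus_pallidus",
    6: "thalamus",
    7: "insula",
    8: "hippocampus",
}


@dataclass(frozen=True)
class VoxelTruth:
    """Ground-truth generative parameters for one voxel (or region).

    Peak relaxation-rate changes (1/s) and continuous times-to-peak (s)
    are specified per echo; the bolus shape is shared, with the arrival
    time per echo derived from ``ttp = t0 + alpha*beta``.  ``leak_k1``
    scales the intravascular curve and ``leak_k2`` (1/s) the leakage
    drift; ``noise_sd`` is the additive signal noise standard deviation
    in the same arbitrary units as ``s0``.
    """

    amplitude_ge: float = 20.0
    amplitude_se: float = 4.0
    ttp_ge: float = 26.0
    ttp_se: float = 25.6
    shape_alpha: float = 3.0
    shape_beta: float = 3.0
    leak_k1: float = 1.0
    leak_k2: float = 0.0
    s0_ge: float = 1000.0
    s0_se: float = 800.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.amplitude_ge < 0 or self.amplitude_se < 0:
            raise ValueError("amplitudes must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.shape_alpha <= 0 or self.shape_beta <= 0:
            raise ValueError("gamma shape parameters must be positive")

    def t0(self, echo: str) -> float:
        ttp = self.ttp_ge if echo == "ge" else self.ttp_se
        return ttp - self.shape_alpha * self.shape_beta

    def ideal_curve(self, echo: str, times: np.ndarray) -> np.ndarray:
        """Noise- and leakage-free dR(t) for one echo on ``times``."""
        amp = self.amplitude_ge if echo == "ge" else self.amplitude_se
        if amp == 0:
            return np.zeros_like(np.asarray(times, dtype=float))
        a = gamma_scale_from_peak(amp, self.shape_alpha, self.shape_beta)
        return gamma_variate(times, a, self.t0(echo), self.shape_alpha,
                             self.shape_beta)

    def replace(self, **kw) -> "VoxelTruth":
        return dataclasses.replace(self, **kw)


def simulate_voxel(
    truth: VoxelTruth,
    acq: AcquisitionParams,
    reference_curve: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Paired (GE, SE) signal series for one voxel.

    The gradient echo receives the leakage term
    ``leak_k1*ideal - leak_k2*cumtrapz(reference)``; a reference curve
    must be supplied when leakage parameters are active.  Validation of
    the truth window and signal positivity happens here so that corrupt
    parameter sets fail loudly rather than producing unusable series.
    """
    times = acq.times
    for echo in ("ge", "se"):
        amp = truth.amplitude_ge if echo == "ge" else truth.amplitude_se
        ttp = truth.ttp_ge if echo == "ge" else truth.ttp_se
        if amp > 0 and not (0.0 < ttp <= acq.duration):
            raise ValueError(f"ttp_{echo}={ttp} outside acquisition window")
    if truth.s0_ge <= 0 or truth.s0_se <= 0:
        raise ValueError("baseline signals S0 must be positive")

    dr_ge = truth.ideal_curve("ge", times)
    dr_se = truth.ideal_curve("se", times)
    if truth.leak_k2 != 0.0 or truth.leak_k1 != 1.0:
        if reference_curve is None:
            raise ValueError("leakage parameters set but no reference curve given")
        from scipy.integrate import cumulative_trapezoid

        cum = cumulative_trapezoid(np.asarray(reference_curve, float), times,
                                   initial=0.0)
        dr_ge = truth.leak_k1 * dr_ge - truth.leak_k2 * cum

    signals = []
    for dr, te, s0 in ((dr_ge, acq.te_ge, truth.s0_ge),
                       (dr_se, acq.te_se, truth.s0_se)):
        atten = te * np.max(dr) if len(dr) else 0.0
        if atten > 30.0:
            raise ValueError(
                f"relaxation change too large (TE*dR={atten:.1f}); signal underflows"
            )
        s = s0 * np.exp(-te * dr)
        if truth.noise_sd > 0:
            if rng is None:
                rng = np.random.default_rng()
            s = s + rng.normal(0.0, truth.noise_sd, size=s.shape)
        signals.append(s)
    return signals[0], signals[1]


# ---------------------------------------------------------------------------
# subject phantoms

#: per-region defaults: (amplitude_ge, amplitude_se, vips seconds)
#: chosen so peak dR2* ~ 14-30 1/s, dR2 ~ 3-5 1/s and Q lands in the
#: physiological 3-6 x10^2 ms^(-1/3) range; most regions have the spin
#: echo peaking first (negative vips), the globus pallidus the reverse.
REGION_DEFAULTS = {
    1: (26.0, 4.2, -0.42),
    2: (14.0, 3.2, -0.32),
    3: (22.0, 3.3, -0.43),
    4: (18.0, 3.5, -0.26),
    5: (14.0, 3.3, +0.35),
    6: (22.0, 4.1, -0.05),
    7: (28.0, 4.0, -0.06),
    8: (30.0, 3.6, -0.50),
}


def default_region_truths(noise_sd: float = 5.0) -> dict[int, VoxelTruth]:
    """One VoxelTruth per labelled region using the physiological defaults."""
    truths = {}
    for label, (amp_ge, amp_se, vips) in REGION_DEFAULTS.items():
        truths[label] = VoxelTruth(
            amplitude_ge=amp_ge, amplitude_se=amp_se,
            ttp_ge=26.0, ttp_se=26.0 + vips, noise_sd=noise_sd,
        )
    return truths


def default_voi_mask(shape: tuple[int, int, int] = (24, 24, 6)) -> np.ndarray:
    """Integer label volume with the 8 regions mirrored in both hemispheres.

    Regions are y-bands of equal height placed symmetrically about the
    first-axis midline, with a one-voxel background rim.
    """
    nx, ny, nz = shape
    if nx < 8 or ny < 8 or nz < 3:
        raise ValueError(f"grid {shape} too small for the 8-region phantom")
    mask = np.zeros(shape, dtype=np.int16)
    mid = nx // 2
    band = ny // 8
    if band < 1:
        raise ValueError("grid too small in y for 8 regions")
    x_ranges = [(1, mid - 1), (mid + 1, nx - 1)]  # left, right blocks
    for label in range(1, 9):
        y0, y1 = (label - 1) * band, label * band
        for x0, x1 in x_ranges:
            mask[x0:x1, y0:y1, 1 : nz - 1] = label
    return mask


@dataclass
class SubjectData:
    """One simulated subject: 4D echo pair, labels, truth, provenance."""

    subject_id: str
    signal_ge: np.ndarray = field(repr=False)
    signal_se: np.ndarray = field(repr=False)
    voi_mask: np.ndarray = field(repr=False)
    lesion_side: str = "left"
    truths: dict[int, VoxelTruth] = field(default_factory=dict)
    reference_curve: np.ndarray | None = field(default=None, repr=False)

    @property
    def shape(self) -> tuple:
        return self.voi_mask.shape


def simulate_subject(
    truths: dict[int, VoxelTruth],
    acq: AcquisitionParams,
    shape: tuple[int, int, int] = (24, 24, 6),
    lesion_side: str = "left",
    subject_id: str = "sub-000",
    rng: np.random.Generator | None = None,
    voi_mask: np.ndarray | None = None,
    amplitude_jitter: float = 0.05,
) -> SubjectData:
    """Simulate one subject phantom on a small 3D grid.

    Every labelled voxel draws its signals from the region's truth, with
    a multiplicative per-voxel amplitude jitter (lognormal-like spatial
    heterogeneity, default 5%).  The stored ``reference_curve`` is the
    label-weighted mean of the ideal (leak-free) gradient-echo curves,
    the curve a leakage model would regress against.
    """
    rng = rng if rng is not None else np.random.default_rng()
    if voi_mask is None:
        voi_mask = default_voi_mask(shape)
    else:
        voi_mask = np.asarray(voi_mask)
        shape = voi_mask.shape
    labels = [int(l) for l in np.unique(voi_mask) if l != 0]
    missing = [l for l in labels if l not in truths]
    if missing:
        raise ValueError(f"no VoxelTruth for mask labels {missing}")

    times = acq.times
    counts = {l: int(np.sum(voi_mask == l)) for l in labels}
    total = sum(counts.values())
    reference = np.zeros_like(times)
    for l in labels:
        reference += counts[l] * truths[l].ideal_curve("ge", times)
    reference /= max(total, 1)

    sig_ge = np.zeros(shape + (acq.n_frames,))
    sig_se = np.zeros(shape + (acq.n_frames,))
    for l in labels:
        tr = truths[l]
        idx = np.nonzero(voi_mask == l)
        n_vox = len(idx[0])
        base_ge, base_se = simulate_voxel(tr.replace(noise_sd=0.0), acq,
                                          reference_curve=reference)
        # per-voxel heterogeneity enters as a signal-exponent scale:
        # S = S0 * (S_base/S0)**f  <=>  dR scaled by factor f
        if amplitude_jitter > 0:
            fac = rng.normal(1.0, amplitude_jitter, size=n_vox).clip(0.5, 1.5)
        else:
            fac = np.ones(n_vox)
        ge = tr.s0_ge * (base_ge[None, :] / tr.s0_ge) ** fac[:, None]
        se = tr.s0_se * (base_se[None, :] / tr.s0_se) ** fac[:, None]
        if tr.noise_sd > 0:
            ge = ge + rng.normal(0.0, tr.noise_sd, size=ge.shape)
            se = se + rng.normal(0.0, tr.noise_sd, size=se.shape)
        sig_ge[idx] = ge
        sig_se[idx] = se
    # background voxels: flat baseline signal (plus noise) so the volume
    # looks like an image, but they carry label 0 and are never analyzed
    bg = voi_mask == 0
    any_truth = truths[labels[0]]
    sig_ge[bg] = any_truth.s0_ge
    sig_se[bg] = any_truth.s0_se
    if any_truth.noise_sd > 0:
        nbg = int(bg.sum())
        sig_ge[bg] += rng.normal(0, any_truth.noise_sd, size=(nbg, acq.n_frames))
        sig_se[bg] += rng.normal(0, any_truth.noise_sd, size=(nbg, acq.n_frames))

    return SubjectData(
        subject_id=subject_id, signal_ge=sig_ge, signal_se=sig_se,
        voi_mask=voi_mask, lesion_side=lesion_side, truths=dict(truths),
        reference_curve=reference,
    )


# ---------------------------------------------------------------------------
# cohorts


@dataclass(frozen=True)
class Effect:
    """A planted linear age effect on one truth field.

    ``slope_per_decade`` is the relative change of ``parameter`` per
    decade of age, centred on the cohort reference age: the field is
    multiplied by ``1 + slope*(age - age_ref)/10``.  ``regions`` may be
    a tuple of labels or "all"; ``sex`` one of "F", "M", "both".
    """

    parameter: str
    slope_per_decade: float
    regions: tuple[int, ...] | str = "all"
    sex: str = "both"

    def __post_init__(self) -> None:
        if self.sex not in ("F", "M", "both"):
            raise ValueError(f"sex must be F/M/both, got {self.sex}")
        if self.parameter not in {f.name for f in dataclasses.fields(VoxelTruth)}:
            raise ValueError(f"unknown truth field {self.parameter!r}")

    def applies(self, sex: str, label: int) -> bool:
        if self.sex != "both" and sex != self.sex:
            return False
        return self.regions == "all" or label in tuple(self.regions)  # type: ignore[arg-type]


@dataclass(frozen=True)
class CohortSpec:
    """Design of a synthetic cohort.

    Demographics emulate the study population: 42 women / 30 men aged
    20-70 (truncated normal, mean 37.6, SD 12), sex-specific BMI with a
    positive BMI-age slope in men only, and an even left/right split of
    lesioned hemispheres.  Between-subject vascular variability is a
    common amplitude factor (both echoes, SD ``subject_cv``) plus an
    independent gradient-echo-only factor (SD ``ratio_cv``) that moves
    the large-to-small-vessel ratio, and a time-to-peak jitter.
    """

    n_female: int = 42
    n_male: int = 30
    age_range: tuple[float, float] = (20.0, 70.0)
    age_mean: float = 37.6
    age_sd: float = 12.0
    bmi_female: tuple[float, float] = (24.8, 4.2)
    bmi_male: tuple[float, float] = (26.3, 3.2)
    bmi_male_age_slope: float = 0.115
    subject_cv: float = 0.08
    ratio_cv: float = 0.12
    ttp_jitter_sd: float = 0.08
    noise_sd: float = 5.0
    effects: tuple[Effect, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_female < 0 or self.n_male < 0 or self.n_female + self.n_male == 0:
            raise ValueError("cohort must contain at least one subject")
        for eff in self.effects:
            if eff.sex == "F" and self.n_female == 0:
                raise ValueError("effect references empty female stratum")
            if eff.sex == "M" and self.n_male == 0:
                raise ValueError("effect references empty male stratum")

    @property
    def age_ref(self) -> float:
        return self.age_mean


def _draw_ages(spec: CohortSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """Truncated-normal ages within the cohort range (rejection sampling)."""
    ages = np.empty(0)
    while len(ages) < n:
        draw = rng.normal(spec.age_mean, spec.age_sd, size=2 * n)
        draw = draw[(draw >= spec.age_range[0]) & (draw <= spec.age_range[1])]
        ages = np.concatenate([ages, draw])
    return ages[:n]


def sample_demographics(spec: CohortSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Demographics table: subject_id, age_years, sex, bmi, lesion_hemisphere."""
    n = spec.n_female + spec.n_male
    sexes = np.array(["F"] * spec.n_female + ["M"] * spec.n_male)
    ages = np.empty(n)
    ages[: spec.n_female] = _draw_ages(spec, spec.n_female, rng)
    ages[spec.n_female:] = _draw_ages(spec, spec.n_male, rng)
    bmi = np.empty(n)
    mu_f, sd_f = spec.bmi_female
    mu_m, sd_m = spec.bmi_male
    bmi[: spec.n_female] = rng.normal(mu_f, sd_f, size=spec.n_female)
    resid_sd = sd_m * np.sqrt(max(1.0 - 0.52**2, 0.0))
    bmi[spec.n_female:] = (
        mu_m
        + spec.bmi_male_age_slope * (ages[spec.n_female:] - spec.age_mean)
        + rng.normal(0.0, resid_sd, size=spec.n_male)
    )
    bmi = bmi.clip(16.0, 45.0)
    # even left/right lesion split, as in the study population
    sides = np.array(["left", "right"])[np.arange(n) % 2]
    rng.shuffle(sides)
    return pd.DataFrame(
        {
            "subject_id": [f"sub-{i:03d}" for i in range(n)],
            "age_years": np.round(ages, 1),
            "sex": sexes,
            "bmi": np.round(bmi, 1),
            "lesion_hemisphere": sides,
        }
    )


def _subject_truths(
    spec: CohortSpec, age: float, sex: str, rng: np.random.Generator
) -> dict[int, VoxelTruth]:
    """Region truths for one subject: biological variation + planted effects."""
    base = default_region_truths(noise_sd=spec.noise_sd)
    common = rng.normal(1.0, spec.subject_cv)
    ratio = rng.normal(1.0, spec.ratio_cv)
    common, ratio = float(np.clip(common, 0.5, 1.5)), float(np.clip(ratio, 0.5, 1.5))
    dt = float(rng.normal(0.0, spec.ttp_jitter_sd))
    out: dict[int, VoxelTruth] = {}
    decades = (age - spec.age_ref) / 10.0
    for label, tr in base.items():
        fields = {
            "amplitude_ge": tr.amplitude_ge * common * ratio,
            "amplitude_se": tr.amplitude_se * common,
            "ttp_ge": tr.ttp_ge + dt,
            "ttp_se": tr.ttp_se + dt,
        }
        for eff in spec.effects:
            if eff.applies(sex, label):
                cur = fields.get(eff.parameter, getattr(tr, eff.parameter))
                fields[eff.parameter] = cur * (1.0 + eff.slope_per_decade * decades)
        out[label] = tr.replace(**fields)
    return out


def simulate_cohort(
    spec: CohortSpec,
    acq: AcquisitionParams,
    shape: tuple[int, int, int] = (24, 24, 6),
):
    """Yield ``(SubjectData, demographics_row)`` for every cohort subject.

    A generator keeps whole-cohort memory flat; the demographics table
    is available up-front via the first yielded element's companion
    :func:`sample_demographics` output (also returned by
    :func:`vamkit.pipeline.run_cohort`).  Fixing ``spec.seed`` makes the
    output bit-reproducible.
    """
    rng = np.random.default_rng(spec.seed)
    demo = sample_demographics(spec, rng)
    subj_seeds = rng.integers(0, 2**31 - 1, size=len(demo))
    for i, row in demo.iterrows():
        srng = np.random.default_rng(int(subj_seeds[i]))
        truths = _subject_truths(spec, float(row.age_years), str(row.sex), srng)
        subj = simulate_subject(
            truths, acq, shape=shape, lesion_side=str(row.lesion_hemisphere),
            subject_id=str(row.subject_id), rng=srng,
        )
        yield subj, row


# ---------------------------------------------------------------------------
# on-disk artifact layout


def write_subject(subject: SubjectData, acq: AcquisitionParams,
                  out_dir: str | Path, voxel_size=(2.0, 2.0, 5.4)) -> Path:
    """Write one subject as NIfTI echo pairs + label mask + truth JSON."""
    out_dir = Path(out_dir) / subject.subject_id
    out_dir.mkdir(parents=True, exist_ok=True)
    affine = np.diag(list(voxel_size) + [1.0])
    affine[0, 3] = -subject.shape[0] / 2.0 * voxel_size[0]  # x=0 at midline
    nib.save(nib.Nifti1Image(subject.signal_ge.astype(np.float64), affine),
             out_dir / "echo_ge.nii.gz")
    nib.save(nib.Nifti1Image(subject.signal_se.astype(np.float64), affine),
             out_dir / "echo_se.nii.gz")
    nib.save(nib.Nifti1Image(subject.voi_mask.astype(np.int16), affine),
             out_dir / "voi_mask.nii.gz")
    truth = {
        "subject_id": subject.subject_id,
        "lesion_side": subject.lesion_side,
        "acquisition": dataclasses.asdict(acq),
        "regions": {
            str(label): dataclasses.asdict(tr) for label, tr in subject.truths.items()
        },
    }
    (out_dir / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True))
    return out_dir
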