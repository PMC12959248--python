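"""Synthetic tumour masks and survival cohorts with known ground truth.

The real study material (whole-slide images and a multi-centre cohort of 745
melanoma patients) is not publicly available, so every stage of the pipeline
is exercised against simulated data of known structure:

* :func:`generate_shape` rasterizes tumour-like shapes (ellipses, nodular
  blobs with a perturbed boundary, thin superficial-spreading strips,
  fragmented lesions with satellite nests) whose analytic area, axis lengths
  and nodularity index are known exactly for zero boundary noise.

* :func:`generate_cohort` draws a per-case cohort whose statistical structure
  matches the published study: log-normal biomarker marginals coupled by a
  Gaussian copula (rank correlation between the digital Breslow thickness and
  gold-standard Breslow thickness targeted at 0.89), covariate marginals
  P(age >= 50) = 0.76, P(male) = 0.50, P(central site) = 0.50, survival times
  from a Weibull proportional-hazards model whose default log-hazard
  coefficients equal the published adjusted hazard ratios (OS: area 1.48,
  perimeter 1.86, major axis 1.88, NI 1.77, dBT 2.04; MSS: NI 2.34,
  dBT 2.59), and censoring calibrated so the observed cohort reproduces a
  median follow-up of 5.7 years (maximum 33.7) with 30% deaths.

One designated biomarker drives the hazard per generated cohort, matching
the one-model-per-parameter analysis design.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps

from .errors import GeneratorError
from .mask_io import SegmentationMask, write_cohort_table, write_mask

__all__ = [
    "SyntheticShapeSpec",
    "SyntheticCohortSpec",
    "CohortTruth",
    "generate_shape",
    "generate_cohort",
    "make_fixture_suite",
    "MORPH_VARS",
    "COPULA_VARS",
]

MORPH_VARS = ("area", "perimeter", "major", "dbt", "ni")
COPULA_VARS = MORPH_VARS + ("breslow",)

#: Log-normal marginals for the biomarkers and gold-standard Breslow (mm-based
#: units).  Medians: area 10 mm², perimeter 20 mm, major axis 8 mm, dBT 2.2 mm,
#: NI 0.28, Breslow 2.0 mm — chosen to mimic a mixed superficial-spreading /
#: nodular melanoma case mix (Breslow marginal reproduces the study's
#: <=1 / 1–2 / 2–4 / >4 mm band fractions to within a few percent).
DEFAULT_LOG_MEANS = {"area": 2.30, "perimeter": 3.00, "major": 2.08,
                     "dbt": 0.80, "ni": -1.27, "breslow": 0.70}
DEFAULT_LOG_SDS = {"area": 0.90, "perimeter": 0.55, "major": 0.50,
                   "dbt": 0.65, "ni": 0.45, "breslow": 0.60}

#: Target Spearman rank-correlation matrix over (area, perimeter, major, dbt,
#: ni, breslow).  Size measures are mutually highly correlated; NI is
#: size-independent by construction (mildly negative with elongation);
#: the dBT–Breslow entry is 0.89.
DEFAULT_SPEARMAN = np.array([
    # area  perim  major   dbt     ni   breslow
    [1.00, 0.90, 0.85, 0.75, 0.15, 0.70],
    [0.90, 1.00, 0.92, 0.65, -0.05, 0.60],
    [0.85, 0.92, 1.00, 0.50, -0.30, 0.45],
    [0.75, 0.65, 0.50, 1.00, 0.55, 0.89],
    [0.15, -0.05, -0.30, 0.55, 1.00, 0.50],
    [0.70, 0.60, 0.45, 0.89, 0.50, 1.00],
])

#: Adjusted hazard-ratio defaults per endpoint (the generating ground truth).
#: MSS values for area/perimeter/major are not published; they take the OS
#: value scaled by the dBT MSS/OS log-ratio and are non-reference defaults.
_MSS_SCALE = np.log(2.59) / np.log(2.04)
DEFAULT_HR = {
    "os": {"area": 1.48, "perimeter": 1.86, "major": 1.88, "ni": 1.77, "dbt": 2.04},
    "mss": {"area": float(np.exp(np.log(1.48) * _MSS_SCALE)),
            "perimeter": float(np.exp(np.log(1.86) * _MSS_SCALE)),
            "major": float(np.exp(np.log(1.88) * _MSS_SCALE)),
            "ni": 2.34, "dbt": 2.59},
}

DEFAULT_SEED = 20260304


# ---------------------------------------------------------------------------
# shapes

@dataclass
class SyntheticShapeSpec:
    """Parameters of one synthetic tumour shape.

    ``mpp`` is in mm per pixel here (shape scale is specified in mm);
    the produced mask carries the equivalent microns-per-pixel calibration.
    ``boundary_noise_amp`` perturbs the radial boundary by a smooth periodic
    field with that relative amplitude (0 = exact ellipse).
    """

    family: str = "ellipse"  # ellipse | nodular_blob | superficial_strip | fragmented
    a: float = 10.0          # semi-major, mm
    b: float = 5.0           # semi-minor, mm
    rotation: float = 0.0    # degrees
    boundary_noise_amp: float = 0.0
    n_fragments: int = 0
    mpp: float = 0.02        # mm / pixel
    seed: int = 0
    canvas_mm: float | None = None
    case_id: str = ""

    def __post_init__(self) -> None:
        if not (self.a >= self.b > 0):
            raise GeneratorError(f"need a >= b > 0, got ({self.a}, {self.b})")
        if not (0 <= self.boundary_noise_amp <= 0.2):
            raise GeneratorError("boundary_noise_amp must be in [0, 0.2]")
        if self.mpp <= 0:
            raise GeneratorError("mpp must be positive")


def _noise_field(rng: np.random.Generator, amp: float):
    """Smooth periodic radial perturbation with max |value| == amp."""
    if amp == 0:
        return lambda phi: np.zeros_like(np.asarray(phi, dtype=float))
    ks = np.arange(2, 6)
    c = rng.normal(size=len(ks)) / ks
    s = rng.normal(size=len(ks)) / ks

    def raw(phi):
        phi = np.asarray(phi, dtype=float)[..., None]
        return (c * np.cos(ks * phi) + s * np.sin(ks * phi)).sum(axis=-1)

    grid = np.linspace(0, 2 * np.pi, 720, endpoint=False)
    scale = amp / max(np.abs(raw(grid)).max(), 1e-12)
    return lambda phi: scale * raw(phi)


def generate_shape(spec: SyntheticShapeSpec) -> tuple[SegmentationMask, dict]:
    """Rasterize the shape; return the mask and its ground-truth record.

    Ground truth carries the analytic values of the noiseless ellipse
    (area = πab, major = 2a, minor = 2b, NI = b/a); with boundary noise they
    are approximate to O(amplitude).  Satellite fragments are each below 50%
    of the main shape's area, so the largest-piece rule must ignore them.
    """
    rng = np.random.default_rng(spec.seed)
    noise = _noise_field(rng, spec.boundary_noise_amp)
    ext = max(spec.a, spec.b) * (1 + spec.boundary_noise_amp) + 2 * spec.mpp
    frag_r = 0.25 * np.sqrt(spec.a * spec.b)
    need = 2 * ext + (2.5 * ext + 2 * frag_r if spec.n_fragments else 0) + 4 * spec.mpp
    canvas = spec.canvas_mm if spec.canvas_mm is not None else need
    if canvas < need:
        raise GeneratorError(
            f"shape (extent {need:.1f} mm) exceeds canvas of {canvas:.1f} mm")

    npx = int(np.ceil(canvas / spec.mpp))
    cx = cy = canvas / 2.0
    jj, ii = np.meshgrid(np.arange(npx), np.arange(npx))
    x = (jj + 0.5) * spec.mpp - cx
    y = (ii + 0.5) * spec.mpp - cy

    th = np.radians(spec.rotation)
    xr = np.cos(th) * x + np.sin(th) * y
    yr = -np.sin(th) * x + np.cos(th) * y
    rho = np.sqrt((xr / spec.a) ** 2 + (yr / spec.b) ** 2)
    phi = np.arctan2(yr / spec.b, xr / spec.a)
    inside = rho <= 1.0 + noise(phi)

    centres = []
    for k in range(spec.n_fragments):
        # evenly spread angles keep satellites disjoint from each other
        ang = 2 * np.pi * (k + 0.3 * rng.random()) / spec.n_fragments
        dist = ext + frag_r + 2 * spec.mpp + rng.uniform(0, 0.3 * ext)
        fx, fy = dist * np.cos(ang), dist * np.sin(ang)
        fx = np.clip(fx, -(canvas / 2 - frag_r - 2 * spec.mpp),
                     canvas / 2 - frag_r - 2 * spec.mpp)
        fy = np.clip(fy, -(canvas / 2 - frag_r - 2 * spec.mpp),
                     canvas / 2 - frag_r - 2 * spec.mpp)
        inside |= (x - fx) ** 2 + (y - fy) ** 2 <= frag_r ** 2
        centres.append((fx, fy))

    mask = SegmentationMask(inside, spec.mpp * 1000.0, spec.mpp * 1000.0,
                            spec.case_id or f"{spec.family}_{spec.seed}")
    truth = {
        "case_id": mask.case_id,
        "family": spec.family,
        "area": np.pi * spec.a * spec.b,
        "perimeter": _ellipse_perimeter(spec.a, spec.b),
        "major": 2 * spec.a,
        "dbt": 2 * spec.b,
        "ni": spec.b / spec.a,
        "rotation": spec.rotation,
        "boundary_noise_amp": spec.boundary_noise_amp,
        "n_fragments": spec.n_fragments,
        "exact": spec.boundary_noise_amp == 0,
    }
    return mask, truth


def _ellipse_perimeter(a: float, b: float) -> float:
    """Exact ellipse circumference via the complete elliptic integral."""
    from scipy.special import ellipe

    e2 = 1.0 - (b / a) ** 2
    return float(4 * a * ellipe(e2))


# ---------------------------------------------------------------------------
# cohorts

@dataclass
class SyntheticCohortSpec:
    """Generating parameters of a synthetic survival cohort.

    ``hazard_param`` / ``hazard_endpoint`` designate the single biomarker
    whose published adjusted hazard ratio drives the latent death time (the
    endpoint selects which coefficient table supplies it).  Nuisance hazard
    ratios (age 1.03 / year, male 1.3, central site 1.2) are plausible
    non-reference defaults.
    """

    n: int = 2000
    hazard_param: str = "dbt"
    hazard_endpoint: str = "os"
    morph_log_means: dict = field(default_factory=lambda: dict(DEFAULT_LOG_MEANS))
    morph_log_sds: dict = field(default_factory=lambda: dict(DEFAULT_LOG_SDS))
    spearman_target: np.ndarray = field(
        default_factory=lambda: DEFAULT_SPEARMAN.copy())
    p_age_ge50: float = 0.76
    p_male: float = 0.50
    p_central: float = 0.50
    age_sd: float = 15.0
    hr: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_HR.items()})
    hr_age: float = 1.03
    hr_sex: float = 1.30
    hr_site: float = 1.20
    weibull_shape: float = 1.1
    max_followup: float = 33.7
    target_median_followup: float = 5.7
    target_death_fraction: float = 0.30
    melanoma_death_fraction: float = 0.75
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.n < 4:
            raise GeneratorError("cohort size must be >= 4")
        for p in (self.p_age_ge50, self.p_male, self.p_central,
                  self.melanoma_death_fraction):
            if not 0 <= p <= 1:
                raise GeneratorError(f"probability out of [0, 1]: {p}")
        if self.hazard_param not in MORPH_VARS:
            raise GeneratorError(f"unknown hazard parameter {self.hazard_param!r}")
        if self.hazard_endpoint not in ("os", "mss"):
            raise GeneratorError(f"unknown endpoint {self.hazard_endpoint!r}")
        self.spearman_target = np.asarray(self.spearman_target, dtype=float)

    @classmethod
    def null(cls, **kw) -> "SyntheticCohortSpec":
        """All hazard coefficients zero (no covariate affects survival)."""
        spec = cls(**kw)
        spec.hr = {e: {p: 1.0 for p in MORPH_VARS} for e in ("os", "mss")}
        spec.hr_age = spec.hr_sex = spec.hr_site = 1.0
        return spec

    @property
    def beta(self) -> float:
        """Generating log hazard ratio of the designated parameter."""
        return float(np.log(self.hr[self.hazard_endpoint][self.hazard_param]))


@dataclass
class CohortTruth:
    """Sealed generating truth, for testing only (never read by analysis)."""

    spec: SyntheticCohortSpec
    beta: float
    beta_age: float
    beta_sex: float
    beta_site: float
    weibull_scale: float
    censor_power: float
    latent_time: np.ndarray
    censor_time: np.ndarray
    melanoma_cause: np.ndarray

    def to_json(self) -> str:
        d = {
            "hazard_param": self.spec.hazard_param,
            "hazard_endpoint": self.spec.hazard_endpoint,
            "beta": self.beta,
            "hr": float(np.exp(self.beta)),
            "beta_age": self.beta_age,
            "beta_sex": self.beta_sex,
            "beta_site": self.beta_site,
            "weibull_shape": self.spec.weibull_shape,
            "weibull_scale": self.weibull_scale,
            "censor_power": self.censor_power,
            "seed": self.spec.seed,
        }
        return json.dumps(d, indent=2)


def _pearson_from_spearman(rho: np.ndarray) -> np.ndarray:
    """Gaussian-copula latent correlation giving the target Spearman."""
    return 2.0 * np.sin(np.pi * rho / 6.0)


def generate_cohort(spec: SyntheticCohortSpec
                    ) -> tuple[pd.DataFrame, CohortTruth]:
    """Draw one cohort table plus its sealed generating truth.

    Steps: (1) correlated log-normal biomarkers and gold Breslow via a
    Gaussian copula; (2) covariates age / sex / site; (3) a latent Weibull
    proportional-hazards death time driven by the designated biomarker plus
    the nuisance covariates; (4) right censoring ``C = c_max * U^p`` with the
    baseline scale and censor power solved on the realized draws so that the
    observed death fraction and median follow-up equal their targets.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n

    R = _pearson_from_spearman(spec.spearman_target)
    np.fill_diagonal(R, 1.0)
    w, _ = np.linalg.eigh(R)
    if w.min() < -1e-10:
        raise GeneratorError(
            f"copula correlation matrix not positive semi-definite "
            f"(min eigenvalue {w.min():.3g})")
    L = np.linalg.cholesky(R + 1e-12 * np.eye(len(R)))
    Z = rng.standard_normal((n, len(COPULA_VARS))) @ L.T

    cols = {}
    for j, v in enumerate(COPULA_VARS):
        cols[v] = np.exp(spec.morph_log_means[v] + spec.morph_log_sds[v] * Z[:, j])
    cols["ni"] = np.minimum(cols["ni"], 1.0)  # NI is a ratio <= 1 by definition

    # age calibrated so P(age >= 50) hits the target; truncation is negligible
    age_mean = 50.0 + spec.age_sd * sps.norm.ppf(spec.p_age_ge50)
    age = np.clip(rng.normal(age_mean, spec.age_sd, size=n), 18.0, 95.0)
    male = rng.random(n) < spec.p_male
    central = rng.random(n) < spec.p_central

    beta = spec.beta
    b_age, b_sex, b_site = (np.log(spec.hr_age), np.log(spec.hr_sex),
                            np.log(spec.hr_site))
    logx = np.log(cols[spec.hazard_param])
    eta = (beta * (logx - spec.morph_log_means[spec.hazard_param])
           + b_age * (age - 60.0) + b_sex * male + b_site * central)

    k = spec.weibull_shape
    expo = rng.exponential(size=n)
    W = (expo / np.exp(eta)) ** (1.0 / k)   # latent time for unit scale
    U = rng.random(n)

    lam, power = _calibrate_censoring(W, U, spec)
    T = lam * W
    C = spec.max_followup * U ** power
    event_os = T <= C
    time_os = np.minimum(T, C)

    is_mel = rng.random(n) < spec.melanoma_death_fraction
    event_mss = event_os & is_mel
    df = pd.DataFrame({
        "case_id": [f"S{i:04d}" for i in range(n)],
        "area": cols["area"],
        "perimeter": cols["perimeter"],
        "major": cols["major"],
        "dbt": cols["dbt"],
        "ni": cols["ni"],
        "breslow": cols["breslow"],
        "age": age,
        "sex": np.where(male, "male", "female"),
        "site": np.where(central, "central", "peripheral"),
        "time_os": time_os,
        "event_os": event_os.astype(int),
        "time_mss": time_os,
        "event_mss": event_mss.astype(int),
    })
    truth = CohortTruth(
        spec=spec, beta=beta, beta_age=b_age, beta_sex=b_sex, beta_site=b_site,
        weibull_scale=lam, censor_power=power,
        latent_time=T, censor_time=C, melanoma_cause=is_mel,
    )
    return df, truth


def _calibrate_censoring(W: np.ndarray, U: np.ndarray,
                         spec: SyntheticCohortSpec) -> tuple[float, float]:
    """Solve (Weibull scale, censor power) on the realized draws.

    Censoring is ``C = c_max * U^p`` (right-skewed for p > 1, reproducing a
    short median but long maximum follow-up).  For fixed p the death fraction
    is monotone decreasing in the scale, so the scale is bisected to the
    death-fraction target inside an outer bisection of p to the
    median-follow-up target.
    """
    c_max = spec.max_followup

    def death(lam: float, p: float) -> float:
        return float(np.mean(lam * W <= c_max * U ** p))

    def med(lam: float, p: float) -> float:
        return float(np.median(np.minimum(lam * W, c_max * U ** p)))

    lo, hi = 1e-3, 1e6

    def lam_for(p: float) -> float:
        if not (death(lo, p) >= spec.target_death_fraction >= death(hi, p)):
            raise GeneratorError(
                f"cannot reach death fraction {spec.target_death_fraction:.2f}; "
                f"achievable range ({death(hi, p):.3f}, {death(lo, p):.3f})")
        return optimize.brentq(
            lambda l: death(l, p) - spec.target_death_fraction, lo, hi,
            xtol=1e-9, rtol=1e-12)

    def g(p: float) -> float:
        return med(lam_for(p), p) - spec.target_median_followup

    p_lo, p_hi = 0.2, 10.0
    g_lo, g_hi = g(p_lo), g(p_hi)
    if g_lo * g_hi > 0:
        raise GeneratorError(
            f"cannot reach median follow-up {spec.target_median_followup}; "
            f"achieved range ({min(g_lo, g_hi) + spec.target_median_followup:.2f}, "
            f"{max(g_lo, g_hi) + spec.target_median_followup:.2f})")
    power = optimize.brentq(g, p_lo, p_hi, xtol=1e-6)
    lam = lam_for(power)

    achieved = death(lam, power)
    if abs(achieved - spec.target_death_fraction) > 0.02:
        raise GeneratorError(
            f"censoring calibration missed the death-fraction target: "
            f"achieved {achieved:.3f}")
    return lam, power


# ---------------------------------------------------------------------------
# fixture suite

_FIXTURE_FAMILIES = ("ellipse", "nodular_blob", "superficial_strip", "fragmented")


def make_fixture_suite(out_dir: str | Path, seed: int = DEFAULT_SEED) -> dict:
    """Write a deterministic fixture tree: ~20 mask PNGs (+ calibration
    sidecars), their ground-truth CSV, and one default cohort CSV.

    Bit-identical for identical seeds.  Returns a manifest dict.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        masks_dir = out / "masks"
        masks_dir.mkdir(exist_ok=True)
    except OSError as e:
        raise GeneratorError(f"cannot create fixture directory {out}: {e}") from e

    rng = np.random.default_rng(seed)
    rows = []
    files = []
    idx = 0
    for family in _FIXTURE_FAMILIES:
        for _ in range(5):
            if family == "ellipse":
                a = rng.uniform(6, 14)
                b = rng.uniform(0.35, 0.9) * a
                noise, frags = 0.0, 0
            elif family == "nodular_blob":
                a = rng.uniform(4, 9)
                b = rng.uniform(0.8, 1.0) * a
                noise, frags = rng.uniform(0.05, 0.15), 0
            elif family == "superficial_strip":
                a = rng.uniform(10, 16)
                b = rng.uniform(0.08, 0.2) * a
                noise, frags = rng.uniform(0.0, 0.05), 0
            else:
                a = rng.uniform(5, 10)
                b = rng.uniform(0.4, 0.8) * a
                noise, frags = 0.0, int(rng.integers(1, 4))
            shape = SyntheticShapeSpec(
                family=family, a=float(a), b=float(b),
                rotation=float(rng.uniform(0, 180)),
                boundary_noise_amp=float(noise), n_fragments=frags,
                mpp=0.05, seed=int(rng.integers(0, 2**31 - 1)),
                case_id=f"fix_{idx:03d}_{family}")
            mask, truth = generate_shape(shape)
            path = masks_dir / f"{mask.case_id}.png"
            write_mask(mask, path)
            files.append(path)
            rows.append(truth)
            idx += 1

    gt = pd.DataFrame(rows)
    gt.to_csv(out / "ground_truth.csv", index=False, float_format="%.6g")

    cohort, truth = generate_cohort(SyntheticCohortSpec(seed=seed))
    write_cohort_table(cohort.round(6), out / "cohort.csv")
    (out / "cohort_truth.json").write_text(truth.to_json())
    return {"masks": [str(f) for f in files],
            "ground_truth": str(out / "ground_truth.csv"),
            "cohort": str(out / "cohort.csv")}
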