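"""Synthetic cohort generation.

Builds a seeded cohort of stroke patients treated with mechanical
thrombectomy (MT), structured like the study population the package
evaluates: a screened pool with exclusions, an enrolled set, a subset
showing post-interventional cerebral hyperdensities (PCHDs), and within the
PCHD set a latent hemorrhagic-transformation (HT) versus contrast
extravasation (CE) outcome together with a latent RMDV-positivity
indicator.  Covariates are drawn per outcome group from published marginal
summaries (Bernoulli for categorical variables, truncated normal for
mean +/- SD variables, log-normal matched to median/IQR for skewed ones).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

from .errors import ConfigurationError

__all__ = [
    "CohortConfig",
    "PatientRecord",
    "apply_enrollment_filter",
    "sample_cohort",
    "default_covariate_specs",
]

HT = "HT"
CE = "CE"

_Z75 = stats.norm.ppf(0.75)  # quartile z-score used for the median/IQR fit


@dataclass(frozen=True)
class BinaryCovariate:
    """Bernoulli covariate with per-group frequencies (HT, CE, pooled)."""

    p_ht: float
    p_ce: float
    p_overall: float


@dataclass(frozen=True)
class NormalCovariate:
    """Truncated-normal covariate; (mean, sd) per group plus hard bounds."""

    ht: tuple[float, float]
    ce: tuple[float, float]
    overall: tuple[float, float]
    bounds: tuple[float, float]
    integer: bool = False


@dataclass(frozen=True)
class MedianIqrCovariate:
    """Log-normal covariate matched to a printed median and IQR per group."""

    ht: tuple[float, float, float]  # (median, q1, q3)
    ce: tuple[float, float, float]
    overall: tuple[float, float, float]
    bounds: tuple[float, float]
    integer: bool = False


@dataclass(frozen=True)
class CategoricalCovariate:
    """Multinomial covariate; per-group level counts are normalized."""

    levels: tuple[str, ...]
    counts_ht: tuple[float, ...]
    counts_ce: tuple[float, ...]
    counts_overall: tuple[float, ...]


def default_covariate_specs() -> dict:
    """Covariate distributions matching the study's group-wise summaries.

    Binary frequencies are count/n with n_HT = 58 and n_CE = 45; pooled
    frequencies use the PCHD column (n = 103).
    """

    def b(ht: float, ce: float, tot: float) -> BinaryCovariate:
        return BinaryCovariate(ht / 58.0, ce / 45.0, tot / 103.0)

    return {
        "sex_male": b(34, 33, 67),
        "hypertension": b(34, 15, 49),
        "diabetes": b(20, 8, 28),
        "previous_stroke": b(15, 8, 23),
        "atrial_fibrillation": b(32, 22, 54),
        "smoking": b(21, 20, 41),
        "coronary_heart_disease": b(18, 8, 26),
        "hyperlipidemia": b(17, 15, 32),
        "anticoagulant_use": b(5, 6, 11),
        "antiplatelet_drug": b(9, 5, 14),
        "intravenous_thrombolytic": b(30, 18, 48),
        "mtici_ge_2b": b(44, 39, 83),
        "stent_passes_gt3": b(21, 13, 34),
        "balloon_dilatation": b(8, 12, 20),
        "tirofiban_use": b(5, 8, 13),
        "mrs_gt2_3month": b(40, 24, 64),
        "death": b(13, 5, 18),
        "occlusion_site": CategoricalCovariate(
            levels=("mca", "ica", "posterior"),
            counts_ht=(41, 14, 3),
            counts_ce=(25, 13, 8),
            counts_overall=(66, 27, 11),
        ),
        "toast_class": CategoricalCovariate(
            levels=("cardioembolic", "large_artery", "other"),
            counts_ht=(34, 23, 1),
            counts_ce=(20, 23, 2),
            counts_overall=(54, 46, 3),
        ),
        "age": NormalCovariate(
            ht=(70.72, 9.19), ce=(66.56, 13.74), overall=(68.90, 11.53),
            bounds=(18, 120), integer=True,
        ),
        "systolic_bp": NormalCovariate(
            ht=(150.78, 20.33), ce=(149.07, 22.43), overall=(150.03, 21.18),
            bounds=(70, 260), integer=True,
        ),
        "diastolic_bp": NormalCovariate(
            ht=(88.97, 13.92), ce=(85.07, 14.43), overall=(87.26, 14.21),
            bounds=(40, 160), integer=True,
        ),
        "baseline_nihss": MedianIqrCovariate(
            ht=(16, 14, 20), ce=(16, 10, 22), overall=(16, 12, 20),
            bounds=(0, 42), integer=True,
        ),
        "aspects": MedianIqrCovariate(
            ht=(8, 7, 9), ce=(8, 7, 9), overall=(8, 7, 9),
            bounds=(0, 10), integer=True,
        ),
        "onset_to_recanalization_min": MedianIqrCovariate(
            ht=(240, 180, 300), ce=(240, 150, 300), overall=(240, 180, 300),
            bounds=(30, 1440), integer=True,
        ),
        "procedure_time_min": MedianIqrCovariate(
            ht=(110, 82, 140), ce=(100, 82, 175), overall=(110, 83, 150),
            bounds=(10, 720), integer=True,
        ),
        "reperfusion_to_ct_min": MedianIqrCovariate(
            ht=(20, 19, 23), ce=(20, 18, 22), overall=(20, 18, 22),
            bounds=(5, 180), integer=True,
        ),
    }


@dataclass
class CohortConfig:
    """Parameters of the simulated study population.

    Defaults reproduce the study flow: 162 screened, exclusions (3, 8, 7)
    for severe artifacts / missing immediate scan / missing follow-up scan,
    PCHD prevalence 103/144 among the enrolled, HT prevalence 58/103 among
    PCHD patients, and RMDV-positivity rates 52/58 (HT) and 11/45 (CE).
    """

    n_screened: int = 162
    exclusion_counts: tuple[int, int, int] = (3, 8, 7)
    p_pchd: float = 103 / 144
    p_ht_given_pchd: float = 58 / 103
    p_pos_given_ht: float = 52 / 58
    p_pos_given_nonht: float = 11 / 45
    n_ht_without_pchd: int = 2
    covariate_freqs: dict = field(default_factory=default_covariate_specs)
    seed: int = 0

    def validate(self) -> None:
        probs = {
            "p_pchd": self.p_pchd,
            "p_ht_given_pchd": self.p_ht_given_pchd,
            "p_pos_given_ht": self.p_pos_given_ht,
            "p_pos_given_nonht": self.p_pos_given_nonht,
        }
        for name, p in probs.items():
            if not (0.0 <= p <= 1.0):
                raise ConfigurationError(f"{name}={p} is not a probability in [0, 1]")
        if self.n_screened < 0:
            raise ConfigurationError("n_screened must be non-negative")
        if len(self.exclusion_counts) != 3 or any(c < 0 for c in self.exclusion_counts):
            raise ConfigurationError("exclusion_counts must be three non-negative counts")
        if sum(self.exclusion_counts) > self.n_screened:
            raise ConfigurationError(
                f"exclusion counts {self.exclusion_counts} exceed n_screened={self.n_screened}"
            )
        if self.n_ht_without_pchd < 0:
            raise ConfigurationError("n_ht_without_pchd must be non-negative")


@dataclass
class PatientRecord:
    """One screened patient with exclusion flags, latent truth and covariates."""

    patient_id: str
    excluded_artifact: bool = False
    excluded_no_immediate: bool = False
    excluded_no_followup: bool = False
    enrolled: bool = False
    has_pchd: bool = False
    true_outcome: Optional[str] = None  # HT or CE; None when undefined
    rmdv_positive: Optional[bool] = None
    covariates: dict = field(default_factory=dict)

    @property
    def excluded(self) -> bool:
        return (
            self.excluded_artifact
            or self.excluded_no_immediate
            or self.excluded_no_followup
        )


def apply_enrollment_filter(
    screened: list[PatientRecord], config: CohortConfig
) -> list[PatientRecord]:
    """Drop screened patients carrying any exclusion flag, preserving order."""
    config.validate()
    enrolled = [r for r in screened if not r.excluded]
    for r in enrolled:
        r.enrolled = True
    return enrolled


def _lognormal_params(median: float, q1: float, q3: float) -> tuple[float, float]:
    mu = math.log(median)
    sigma = math.log(q3 / q1) / (2.0 * _Z75) if q3 > q1 else 0.0
    return mu, sigma


def _draw_group_covariates(
    rng: np.random.Generator, specs: dict, group: Optional[str], n: int
) -> dict[str, np.ndarray]:
    """Vectorized covariate draw for n patients of one outcome group."""
    out: dict[str, np.ndarray] = {}
    for name, spec in specs.items():
        if isinstance(spec, BinaryCovariate):
            p = {HT: spec.p_ht, CE: spec.p_ce, None: spec.p_overall}[group]
            out[name] = rng.random(n) < p
        elif isinstance(spec, CategoricalCovariate):
            counts = {
                HT: spec.counts_ht,
                CE: spec.counts_ce,
                None: spec.counts_overall,
            }[group]
            p = np.asarray(counts, dtype=float)
            p = p / p.sum()
            idx = rng.choice(len(spec.levels), size=n, p=p)
            out[name] = np.asarray(spec.levels, dtype=object)[idx]
        elif isinstance(spec, NormalCovariate):
            mean, sd = {HT: spec.ht, CE: spec.ce, None: spec.overall}[group]
            lo, hi = spec.bounds
            a, b = (lo - mean) / sd, (hi - mean) / sd
            vals = stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)
            out[name] = np.rint(vals).astype(int) if spec.integer else vals
        elif isinstance(spec, MedianIqrCovariate):
            med, q1, q3 = {HT: spec.ht, CE: spec.ce, None: spec.overall}[group]
            mu, sigma = _lognormal_params(med, q1, q3)
            vals = rng.lognormal(mu, sigma, size=n)
            vals = np.clip(vals, *spec.bounds)
            out[name] = np.rint(vals).astype(int) if spec.integer else vals
        else:  # pragma: no cover - guarded by default_covariate_specs
            raise ConfigurationError(f"unknown covariate spec for {name!r}")
    return out


def _assign_covariates(
    rng: np.random.Generator,
    specs: dict,
    records: list[PatientRecord],
    group: Optional[str],
) -> None:
    if not records:
        return
    draws = _draw_group_covariates(rng, specs, group, len(records))
    for i, rec in enumerate(records):
        rec.covariates = {
            k: (v[i].item() if isinstance(v[i], np.generic) else v[i])
            for k, v in draws.items()
        }


def _pick(rng: np.random.Generator, n: int, k: int) -> np.ndarray:
    """k distinct indices out of n, order-independent of k (seeded)."""
    return rng.permutation(n)[:k]


def sample_cohort(
    config: CohortConfig,
    seed: Optional[int] = None,
    exact_counts: bool = False,
) -> list[PatientRecord]:
    """Sample a full screened cohort.

    Parameters
    ----------
    config
        Cohort parameters; defaults reproduce the study conditions.
    seed
        Overrides ``config.seed``. The same (config, seed) pair always
        yields an identical cohort.
    exact_counts
        When True, group sizes are fixed to the rounded expectations
        (e.g. the default config yields exactly 103 PCHD cases, 58 HT,
        52 and 11 RMDV-positive) rather than Bernoulli-sampled; membership
        is still randomized by the seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_screened
    records = [PatientRecord(patient_id=f"P{i:05d}") for i in range(n)]

    flags = ("excluded_artifact", "excluded_no_immediate", "excluded_no_followup")
    order = rng.permutation(n)
    start = 0
    for flag, count in zip(flags, config.exclusion_counts):
        for j in order[start:start + count]:
            setattr(records[j], flag, True)
        start += count

    enrolled = [r for r in records if not r.excluded]
    for r in enrolled:
        r.enrolled = True
    n_enr = len(enrolled)

    if exact_counts:
        n_pchd = round(config.p_pchd * n_enr)
        pchd_idx = set(_pick(rng, n_enr, n_pchd).tolist())
        for i, r in enumerate(enrolled):
            r.has_pchd = i in pchd_idx
    else:
        draws = rng.random(n_enr) < config.p_pchd
        for r, d in zip(enrolled, draws):
            r.has_pchd = bool(d)

    pchd = [r for r in enrolled if r.has_pchd]
    non_pchd = [r for r in enrolled if not r.has_pchd]

    if exact_counts:
        n_ht = round(config.p_ht_given_pchd * len(pchd))
        ht_idx = set(_pick(rng, len(pchd), n_ht).tolist())
        for i, r in enumerate(pchd):
            r.true_outcome = HT if i in ht_idx else CE
    else:
        draws = rng.random(len(pchd)) < config.p_ht_given_pchd
        for r, d in zip(pchd, draws):
            r.true_outcome = HT if d else CE

    ht_group = [r for r in pchd if r.true_outcome == HT]
    ce_group = [r for r in pchd if r.true_outcome == CE]
    for group, p_pos in ((ht_group, config.p_pos_given_ht),
                         (ce_group, config.p_pos_given_nonht)):
        if exact_counts:
            n_pos = round(p_pos * len(group))
            pos_idx = set(_pick(rng, len(group), n_pos).tolist())
            for i, r in enumerate(group):
                r.rmdv_positive = i in pos_idx
        else:
            draws = rng.random(len(group)) < p_pos
            for r, d in zip(group, draws):
                r.rmdv_positive = bool(d)

    # A small number of HT cases present without any hyperdensity on the
    # immediate scan; they count toward overall HT prevalence but are
    # outside the PCHD analysis set.
    k = min(config.n_ht_without_pchd, len(non_pchd))
    for i in _pick(rng, len(non_pchd), k):
        non_pchd[i].true_outcome = HT

    specs = config.covariate_freqs
    _assign_covariates(rng, specs, ht_group, HT)
    _assign_covariates(rng, specs, ce_group, CE)
    _assign_covariates(rng, specs, non_pchd, None)
    excluded = [r for r in records if r.excluded]
    _assign_covariates(rng, specs, excluded, None)
    return records
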