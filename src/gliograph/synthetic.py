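"""Synthetic resting-state cohorts with planted group connectivity effects.

The generator emulates ROI-level BOLD timeseries for three groups — healthy
controls (HC), low-grade glioma (LGG) and high-grade glioma (HGG) patients
with left-hemispheric tumors.  Each subject's series is a stationary Gaussian
AR(1) process whose cross-sectional covariance is a block structure over the
parcellation: strong within-lobe coupling, strong homotopic (left/right
mirror) coupling, weak within-hemisphere inter-lobe coupling and a small
cross-hemisphere background.  Group effects are planted as signed increments
("deltas") on selected coupling blocks:

* LGG — increased left intra-hemispheric inter-lobe coupling together with
  decreased left within-lobe coupling, i.e. a shift from local cliquishness
  toward long-range integration of the tumor hemisphere;
* HGG — a uniform attenuation of right (contralateral) intra-hemispheric
  coupling, the remote-disconnection pattern.

Effect magnitudes are calibrated so the planted signatures are recoverable
at the study's sample sizes (30/30/20 subjects, 160 volumes at TR 2.5 s);
they are not claims about clinically realistic effect sizes.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import InvalidArgumentError, SimulationError
from .parcellation import ParcellationTable

logger = logging.getLogger(__name__)

GROUPS = ("HC", "LGG", "HGG")

_R_LIMIT = 0.95  # all planted correlations must stay inside (-0.95, 0.95)


@dataclass(frozen=True)
class EffectSpec:
    """Signed correlation increments planted for one group.

    ``delta_left_global`` is added to left intra-hemispheric inter-lobe
    couplings, ``delta_local`` to left within-lobe couplings and
    ``delta_right`` to all right intra-hemispheric couplings.  When
    ``tumor_location`` is set, the two left-hemisphere deltas are restricted
    to couplings involving that lobe (within the lobe for ``delta_local``,
    lobe-to-rest for ``delta_left_global``); subjects carry the location as
    their tumor label.
    """

    group: str
    tumor_location: str | None = None
    delta_left_global: float = 0.0
    delta_right: float = 0.0
    delta_local: float = 0.0

    def __post_init__(self):
        if self.group not in GROUPS:
            raise InvalidArgumentError(f"group must be one of {GROUPS}")
        if self.group == "HC" and (
            self.delta_left_global or self.delta_right or self.delta_local
        ):
            raise InvalidArgumentError("HC must have all deltas = 0")


#: Calibrated default planted effects reproducing the qualitative group
#: signatures (see module docstring) at the default cohort sizes.
DEFAULT_EFFECTS: dict[str, EffectSpec] = {
    "HC": EffectSpec(group="HC"),
    "LGG": EffectSpec(group="LGG", delta_left_global=0.06, delta_local=-0.10),
    "HGG": EffectSpec(group="HGG", delta_right=-0.04),
}

#: Default tumor-location label distribution per patient group, proportional
#: to the study's single-label location counts.
DEFAULT_LOCATION_WEIGHTS: dict[str, dict[str, float]] = {
    "LGG": {"frontal": 15, "temporal": 13, "parietal": 4, "insular": 12},
    "HGG": {"frontal": 5, "temporal": 16, "parietal": 11, "insular": 5},
}

#: Group age distributions (years): mean per group, shared sd.
AGE_MEANS = {"HC": 48.0, "LGG": 40.0, "HGG": 62.0}
AGE_SD = 10.0
#: Tumor size (cm^2, product of perpendicular diameters): Gaussian truncated
#: below at 0.5.
TUMOR_SIZE_MEAN = 12.0
TUMOR_SIZE_SD = 6.0
TUMOR_SIZE_MIN = 0.5


@dataclass(frozen=True)
class CohortSpec:
    """Cohort-level simulation parameters.

    Baseline correlations define the block covariance; ``ar_coeff`` sets the
    AR(1) temporal autocorrelation of every ROI series.  Defaults follow the
    emulated acquisition (160 volumes, TR 2.5 s) and group sizes (30 LGG,
    30 HGG, 20 HC).
    """

    n_hc: int = 20
    n_lgg: int = 30
    n_hgg: int = 30
    T: int = 160
    TR: float = 2.5
    base_r_within_lobe: float = 0.35
    base_r_within_hemi: float = 0.02
    base_r_homotopic: float = 0.50
    base_r_background: float = 0.02
    ar_coeff: float = 0.3
    master_seed: int = 0

    def __post_init__(self):
        if self.T < 10:
            raise InvalidArgumentError("T must be >= 10")
        if min(self.n_hc, self.n_lgg, self.n_hgg) < 2:
            raise InvalidArgumentError("each group needs >= 2 subjects")
        if not 0 <= self.ar_coeff < 1:
            raise InvalidArgumentError("ar_coeff must be in [0, 1)")
        for name in ("base_r_within_lobe", "base_r_within_hemi",
                     "base_r_homotopic", "base_r_background"):
            if not -_R_LIMIT < getattr(self, name) < _R_LIMIT:
                raise InvalidArgumentError(f"{name} outside (-0.95, 0.95)")

    @property
    def n_per_group(self) -> dict[str, int]:
        return {"HC": self.n_hc, "LGG": self.n_lgg, "HGG": self.n_hgg}


@dataclass(frozen=True)
class SubjectTimeseries:
    """One subject's T x N ROI signal matrix plus metadata."""

    data: np.ndarray = field(repr=False)
    subject_id: str = ""
    group: str = "HC"
    tumor_location: str | None = None
    age: float = float("nan")
    tumor_size: float = float("nan")
    seed: int = 0

    def __post_init__(self):
        if not np.all(np.isfinite(self.data)):
            raise InvalidArgumentError("timeseries contains non-finite values")


def subject_seed(master_seed: int, subject_id: str) -> int:
    """Per-subject seed: master seed plus a stable hash of the subject id.

    Stable across processes (CRC32, not Python's salted ``hash``) so any
    subject can be regenerated without replaying the whole cohort.
    """
    return (int(master_seed) + zlib.crc32(subject_id.encode())) % (2**31)


def _nearest_pd(cov: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Clip negative eigenvalues and rescale back to unit diagonal."""
    vals, vecs = np.linalg.eigh(cov)
    vals = np.clip(vals, eps, None)
    repaired = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(repaired))
    repaired = repaired / np.outer(d, d)
    np.fill_diagonal(repaired, 1.0)
    return repaired


def build_covariance(
    parcellation: ParcellationTable,
    spec: CohortSpec,
    effect: EffectSpec,
) -> np.ndarray:
    """Block correlation matrix for one group's planted structure.

    Entry (i, j) is the baseline for the pair's block (within-lobe,
    within-hemisphere inter-lobe, homotopic, or cross-hemisphere background)
    plus any planted delta.  The result is symmetric with unit diagonal and
    positive definite; an indefinite construction is repaired by eigenvalue
    clipping (logged) or rejected if the repair distorts entries.
    """
    n = parcellation.n_roi
    hemi = parcellation.hemisphere_of()
    lobe = parcellation.lobe_of()

    same_hemi = hemi[:, None] == hemi[None, :]
    same_lobe = lobe[:, None] == lobe[None, :]

    cov = np.full((n, n), spec.base_r_background, dtype=float)
    cov[same_hemi & ~same_lobe] = spec.base_r_within_hemi
    cov[same_hemi & same_lobe] = spec.base_r_within_lobe
    for li, ri in parcellation.homotopic_pairs():
        cov[li, ri] = cov[ri, li] = spec.base_r_homotopic

    left = hemi == "L"
    right = hemi == "R"
    if effect.tumor_location is None:
        in_lobe = left  # hemisphere-wide effect
    else:
        in_lobe = left & (lobe == effect.tumor_location)

    # Left within-lobe couplings (delta_local).
    local_mask = in_lobe[:, None] & in_lobe[None, :] & same_lobe
    # Left intra-hemispheric inter-lobe couplings touching the effect region.
    global_mask = (
        (in_lobe[:, None] & left[None, :] | left[:, None] & in_lobe[None, :])
        & same_hemi
        & ~same_lobe
    )
    right_mask = right[:, None] & right[None, :]

    cov[local_mask] += effect.delta_local
    cov[global_mask] += effect.delta_left_global
    cov[right_mask] += effect.delta_right
    np.fill_diagonal(cov, 1.0)

    off = cov[~np.eye(n, dtype=bool)]
    if np.any(np.abs(off) >= _R_LIMIT):
        raise InvalidArgumentError(
            "effect deltas push correlations outside (-0.95, 0.95)"
        )

    min_eig = float(np.linalg.eigvalsh(cov)[0])
    if min_eig <= 0:
        logger.warning(
            "covariance for group %s indefinite (min eigenvalue %.3g); "
            "applying nearest-PD repair", effect.group, min_eig,
        )
        repaired = _nearest_pd(cov)
        if np.max(np.abs(repaired - cov)) > 0.05:
            raise SimulationError(
                "covariance repair distorts planted structure beyond 0.05"
            )
        cov = repaired
    return cov


def simulate_timeseries(
    cov: np.ndarray,
    T: int,
    ar_coeff: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Stationary Gaussian series with cross-sectional covariance ``cov``.

    The process is x_t = phi * x_{t-1} + sqrt(1 - phi^2) * e_t with
    e_t ~ N(0, cov) and x_0 drawn from the stationary distribution, so the
    marginal covariance is ``cov`` exactly and each series has lag-1
    autocorrelation ``ar_coeff``.
    """
    from scipy.signal import lfilter

    if T < 1:
        raise InvalidArgumentError("T must be >= 1")
    if not 0 <= ar_coeff < 1:
        raise InvalidArgumentError("ar_coeff must be in [0, 1)")
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise SimulationError("covariance is not positive definite") from exc
    rng = np.random.default_rng(seed)
    innovations = rng.standard_normal((T, cov.shape[0])) @ chol.T
    if ar_coeff == 0.0:
        return innovations
    innovations[1:] *= np.sqrt(1.0 - ar_coeff**2)
    out = lfilter([1.0], [1.0, -ar_coeff], innovations, axis=0)
    return np.ascontiguousarray(out)


def _draw_age(rng: np.random.Generator, group: str) -> float:
    return float(rng.normal(AGE_MEANS[group], AGE_SD))


def _draw_tumor_size(rng: np.random.Generator) -> float:
    # Rejection sampling of the truncated Gaussian; acceptance ~0.97.
    for _ in range(1000):
        x = rng.normal(TUMOR_SIZE_MEAN, TUMOR_SIZE_SD)
        if x > TUMOR_SIZE_MIN:
            return float(x)
    return TUMOR_SIZE_MIN  # pragma: no cover


def _effect_list(effects, group: str) -> list[EffectSpec]:
    spec = effects.get(group) if effects is not None else None
    if spec is None:
        spec = DEFAULT_EFFECTS[group]
    if isinstance(spec, EffectSpec):
        return [spec]
    return list(spec)


def generate_cohort(
    parcellation: ParcellationTable,
    spec: CohortSpec,
    effects: dict[str, EffectSpec | list[EffectSpec]] | None = None,
) -> list[SubjectTimeseries]:
    """Simulate the full three-group cohort.

    ``effects`` maps each group to one EffectSpec or a list (subjects are
    then split round-robin across the list, each carrying its spec's tumor
    location).  Generation is a pure function of (parcellation, spec,
    effects, master_seed): per-subject seeds are derived from the master
    seed, and ages / tumor sizes come from the subject's own stream.
    """
    subjects: list[SubjectTimeseries] = []
    for group in GROUPS:
        group_effects = _effect_list(effects, group)
        for eff in group_effects:
            if eff.group != group:
                raise InvalidArgumentError(
                    f"effect for group slot {group} is labelled {eff.group}"
                )
        covs = [build_covariance(parcellation, spec, eff) for eff in group_effects]
        n = spec.n_per_group[group]
        for k in range(n):
            sid = f"{group}_{k:03d}"
            seed = subject_seed(spec.master_seed, sid)
            rng = np.random.default_rng(seed)
            eff = group_effects[k % len(group_effects)]
            cov = covs[k % len(group_effects)]
            data = simulate_timeseries(cov, spec.T, spec.ar_coeff, seed=rng.integers(2**31))
            age = _draw_age(rng, group)
            if group == "HC":
                location, size = None, float("nan")
            else:
                size = _draw_tumor_size(rng)
                if eff.tumor_location is not None:
                    location = eff.tumor_location
                else:
                    weights = DEFAULT_LOCATION_WEIGHTS[group]
                    labels = list(weights)
                    p = np.array([weights[l] for l in labels], dtype=float)
                    location = labels[rng.choice(len(labels), p=p / p.sum())]
            subjects.append(
                SubjectTimeseries(
                    data=data,
                    subject_id=sid,
                    group=group,
                    tumor_location=location,
                    age=age,
                    tumor_size=size,
                    seed=seed,
                )
            )
    return subjects


def null_effects() -> dict[str, EffectSpec]:
    """All-zero effects for every group (null cohorts for calibration)."""
    return {g: EffectSpec(group=g) for g in GROUPS}


def with_location(effect: EffectSpec, location: str) -> EffectSpec:
    """Restrict an effect's left-hemisphere deltas to one lobe."""
    return replace(effect, tumor_location=location)
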