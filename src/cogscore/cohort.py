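"""Synthetic cohort generation under a linear two-mediator path model.

The generator emulates the statistical structure the downstream analysis
assumes: three diagnostic groups — cognitively healthy advanced-age adults
(HC), adults with subjective cognitive decline (SCD) and adults with mild
cognitive impairment (MCI) — with group-dependent age and education
distributions, and sub-scores produced as

    score = intercept + c_direct * stage + b_age * age + b_edu * education + noise

where ``stage`` is the diagnostic severity (HC=0, SCD=1, MCI=2). Because the
mediators (age, education) are drawn from group-specific distributions, the
diagnosis -> mediator paths of the mediation model are the group mean
differences; :func:`pair_config` exposes the conventional
(a_age, a_edu, b_age, b_edu, c_direct) path parameterisation directly for
two-group designs.

Default demographics and group sizes (20/29/31) mirror a typical
memory-clinic validation sample of this design; default sub-score effects are
moderate, with the severity gradient strongest for inhibition/switching,
flexibility and episodic-memory error counts.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import norm

from .battery import SubtaskSpec, default_battery

GROUPS = ("HC", "SCD", "MCI")
#: diagnostic severity stage used as the path-model predictor
GROUP_STAGE = {"HC": 0, "SCD": 1, "MCI": 2}

#: canonical group pairs analysed, ordered (focal, comparison)
PAIRS = (("SCD", "HC"), ("SCD", "MCI"), ("HC", "MCI"))


class CohortError(ValueError):
    """Domain error for cohort generation or I/O."""


@dataclass(frozen=True)
class PathEffect:
    """Generating coefficients for one sub-score.

    ``c_direct`` is the direct diagnosis effect per severity stage on the raw
    score scale; ``b_age``/``b_edu`` are mediator slopes per year;
    ``noise_sd`` the residual spread.
    """

    intercept: float
    c_direct: float
    b_age: float = 0.0
    b_edu: float = 0.0
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise CohortError("noise_sd must be > 0")


# Moderate default effects. Per-subtask severity steps (c_direct) are the
# average printed per-step direct effects of the pairwise contrasts, and the
# residual spreads are the spreads those contrasts' standard errors imply
# (sigma ~= SE / sqrt(1/n_a + 1/n_b) at the reported group sizes). Residual
# age/education slopes are kept small: the battery is designed to be largely
# demographics-free.
DEFAULT_EFFECTS: dict[str, PathEffect] = {
    "WMCUT_S1": PathEffect(5.0, -0.11, b_age=-0.010, b_edu=0.015, noise_sd=0.90),
    "WMCUT_S2": PathEffect(8.0, -0.58, b_age=-0.010, b_edu=0.020, noise_sd=0.90),
    "WMCUT_S3": PathEffect(12.0, -1.52, b_age=-0.020, b_edu=0.030, noise_sd=2.40),
    "ACT": PathEffect(40.0, 4.84, b_age=0.120, b_edu=-0.100, noise_sd=6.70),
    "ICT_RST_12": PathEffect(60.0, 8.49, b_age=0.150, b_edu=-0.150, noise_sd=9.00),
    "ICT_RST_SE": PathEffect(2.0, 0.80, b_age=0.008, b_edu=-0.010, noise_sd=0.84),
    "ICT_RST_FS": PathEffect(2.0, 1.13, b_age=0.010, b_edu=-0.015, noise_sd=1.50),
    "CFT": PathEffect(10.0, 2.92, b_age=0.060, b_edu=-0.050, noise_sd=3.00),
    "CFT2_A": PathEffect(1.5, 0.98, b_age=0.010, b_edu=-0.010, noise_sd=1.85),
    "CFT2_B": PathEffect(1.5, 1.41, b_age=0.012, b_edu=-0.012, noise_sd=1.87),
    "CFT2_C": PathEffect(2.5, 0.91, b_age=0.015, b_edu=-0.012, noise_sd=2.00),
    "VFT": PathEffect(10.0, -1.30, b_age=-0.020, b_edu=0.025, noise_sd=1.96),
    "EMTW_A": PathEffect(3.0, 1.61, b_age=0.010, b_edu=-0.012, noise_sd=2.45),
    "EMTW_B": PathEffect(5.0, 0.88, b_age=0.012, b_edu=-0.010, noise_sd=2.00),
}

#: per-group (mean, sd) for age in years; SCD spread follows the sample text
DEFAULT_AGE_PARAMS = {"HC": (61.60, 6.58), "SCD": (61.17, 7.00), "MCI": (68.67, 8.43)}
#: per-group (mean, sd) for education in years
DEFAULT_EDUCATION_PARAMS = {
    "HC": (16.30, 3.04),
    "SCD": (13.31, 4.20),
    "MCI": (13.45, 4.31),
}
DEFAULT_GROUP_SIZES = {"HC": 20, "SCD": 29, "MCI": 31}
#: per-group probability of female gender, mirroring typical clinic samples
DEFAULT_FEMALE_FRACTION = {"HC": 14 / 20, "SCD": 20 / 29, "MCI": 24 / 31}


@dataclass(frozen=True)
class CohortConfig:
    """Full description of a synthetic cohort; identical config + seed give a
    byte-identical cohort."""

    group_sizes: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_SIZES)
    )
    age_params: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_AGE_PARAMS)
    )
    education_params: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_EDUCATION_PARAMS)
    )
    effects: Mapping[str, PathEffect] = field(
        default_factory=lambda: dict(DEFAULT_EFFECTS)
    )
    female_fraction: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FEMALE_FRACTION)
    )
    score_noise_family: str = "gaussian"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.group_sizes:
            raise CohortError("group_sizes must be non-empty")
        for g, n in self.group_sizes.items():
            if g not in GROUP_STAGE:
                raise CohortError(f"unknown group {g!r}")
            if n < 2:
                raise CohortError(f"group {g} needs >= 2 participants, got {n}")
        for params in (self.age_params, self.education_params):
            for g in self.group_sizes:
                mean, sd = params[g]
                if sd <= 0:
                    raise CohortError(f"spread for group {g} must be > 0")
        if self.score_noise_family not in ("gaussian", "truncated_gaussian"):
            raise CohortError(
                f"unknown score_noise_family {self.score_noise_family!r}"
            )


@dataclass
class Cohort:
    """A labelled participant table.

    ``frame`` has columns id, group, age, education, gender and one column
    per sub-score; ``clipped`` counts per-subtask values clipped to their
    documented bounds during generation.
    """

    frame: pd.DataFrame
    provenance: str = "synthetic"
    seed: int | None = None
    clipped: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.frame["id"].duplicated().any():
            raise CohortError("participant ids must be unique")
        unknown = set(self.frame["group"]) - set(GROUPS)
        if unknown:
            raise CohortError(f"unknown groups {sorted(unknown)}")

    @property
    def groups(self) -> list[str]:
        return [g for g in GROUPS if g in set(self.frame["group"])]

    def subset_pair(self, pair: tuple[str, str]) -> pd.DataFrame:
        """Rows of the two groups of ``pair``, in stable order."""
        a, b = pair
        for g in pair:
            if g not in set(self.frame["group"]):
                raise CohortError(f"group {g} absent from cohort")
        return self.frame[self.frame["group"].isin([a, b])].reset_index(drop=True)


def generate_cohort(
    config: CohortConfig, battery: Iterable[SubtaskSpec] | None = None
) -> Cohort:
    """Draw a cohort from the linear path model described by ``config``.

    Bounded sub-scores are clipped to their documented range; the number of
    clipped values per subtask is recorded on the returned cohort so callers
    can verify clipping stays negligible.
    """
    specs = {s.id: s for s in (default_battery() if battery is None else battery)}
    for sid in config.effects:
        if sid not in specs:
            raise CohortError(f"effect refers to unknown subtask {sid!r}")
    rng = np.random.default_rng(config.seed)
    rows: list[dict] = []
    clipped: dict[str, int] = {}
    counter = 0
    for g in GROUPS:
        if g not in config.group_sizes:
            continue
        n = config.group_sizes[g]
        stage = GROUP_STAGE[g]
        age_mu, age_sd = config.age_params[g]
        edu_mu, edu_sd = config.education_params[g]
        ages = rng.normal(age_mu, age_sd, n)
        edus = np.clip(rng.normal(edu_mu, edu_sd, n), 0.0, None)
        p_f = config.female_fraction.get(g, 0.5)
        genders = np.where(rng.random(n) < p_f, "F", "M")
        scores: dict[str, np.ndarray] = {}
        for sid, eff in config.effects.items():
            spec = specs[sid]
            mean = (
                eff.intercept
                + eff.c_direct * stage
                + eff.b_age * ages
                + eff.b_edu * edus
            )
            vals = mean + rng.normal(0.0, eff.noise_sd, n)
            if spec.bounded:
                lo, hi = spec.min_score, spec.max_score
                n_clip = int(np.sum((vals < lo) | (vals > hi)))
                if n_clip:
                    clipped[sid] = clipped.get(sid, 0) + n_clip
                vals = np.clip(vals, lo, hi)
            scores[sid] = vals
        for i in range(n):
            counter += 1
            row = {
                "id": f"P{counter:04d}",
                "group": g,
                "age": ages[i],
                "education": edus[i],
                "gender": genders[i],
            }
            for sid in config.effects:
                row[sid] = scores[sid][i]
            rows.append(row)
    frame = pd.DataFrame(rows)
    return Cohort(frame=frame, provenance="synthetic", seed=config.seed, clipped=clipped)


def pair_config(
    pair: tuple[str, str] = ("SCD", "HC"),
    *,
    n_per_group: int | tuple[int, int] = (30, 30),
    subtasks: Mapping[str, Mapping] | None = None,
    age_base: float = 62.0,
    age_sd: float = 7.0,
    edu_base: float = 14.0,
    edu_sd: float = 4.0,
    a_age: float = 0.0,
    a_edu: float = 0.0,
    seed: int = 0,
) -> CohortConfig:
    """Two-group config in the explicit path parameterisation.

    The cognitively worse group of ``pair`` gets age mean ``age_base + a_age``
    and education mean ``edu_base + a_edu``; per-subtask entries accept the
    keys of :class:`PathEffect` with ``c_direct`` the worse-vs-better direct
    effect. With the 0/1 diagnosis coding used by the mediation stage, the
    generating paths are then exactly (a_age, a_edu, b_age, b_edu, c_direct).
    """
    worse = pair[0] if GROUP_STAGE[pair[0]] > GROUP_STAGE[pair[1]] else pair[1]
    better = pair[0] if worse == pair[1] else pair[1]
    if isinstance(n_per_group, int):
        n_per_group = (n_per_group, n_per_group)
    stage_b, stage_w = GROUP_STAGE[better], GROUP_STAGE[worse]
    step = stage_w - stage_b
    # default to an unbounded registry sub-score so no clipping interferes
    subtasks = subtasks or {"ICT_RST_12": {"c_direct": 1.0}}
    effects = {}
    for sid, kw in subtasks.items():
        kw = dict(kw)
        # rescale so one better->worse transition applies the requested paths
        c = kw.pop("c_direct", 0.0) / step
        intercept = kw.pop("intercept", 0.0) - c * stage_b * step
        effects[sid] = PathEffect(intercept=intercept, c_direct=c, **kw)
    return CohortConfig(
        group_sizes={better: n_per_group[0], worse: n_per_group[1]},
        age_params={
            better: (age_base, age_sd),
            worse: (age_base + a_age, age_sd),
        },
        education_params={
            better: (edu_base, edu_sd),
            worse: (edu_base + a_edu, edu_sd),
        },
        effects=effects,
        female_fraction={better: 0.5, worse: 0.5},
        seed=seed,
    )


def binormal_auc(mu_a: float, sd_a: float, mu_b: float, sd_b: float) -> float:
    """Closed-form AUC for two independent normal score distributions.

    Returns P(B > A) = Phi((mu_b - mu_a) / sqrt(sd_a^2 + sd_b^2)); used as the
    analytic oracle for ROC recovery tests.
    """
    if sd_a <= 0 or sd_b <= 0:
        raise CohortError("spreads must be > 0")
    return float(norm.cdf((mu_b - mu_a) / np.hypot(sd_a, sd_b)))


SCORE_COLUMNS_PREFIX = ("id", "group", "age", "education", "gender")


def write_cohort_csv(cohort: Cohort, path) -> None:
    """One row per participant; missing scores as empty fields."""
    cols = list(SCORE_COLUMNS_PREFIX) + [
        c for c in cohort.frame.columns if c not in SCORE_COLUMNS_PREFIX
    ]
    cohort.frame.to_csv(path, index=False, columns=cols)


def read_cohort_csv(path, provenance: str = "file") -> Cohort:
    frame = pd.read_csv(path)
    missing = set(SCORE_COLUMNS_PREFIX) - set(frame.columns)
    if missing:
        raise CohortError(f"cohort file missing columns {sorted(missing)}")
    return Cohort(frame=frame, provenance=provenance, seed=None)


def worse_group(pair: tuple[str, str]) -> str:
    """The cognitively worse (higher-stage) member of a pair."""
    return max(pair, key=lambda g: GROUP_STAGE[g])


def pair_subtasks(config: CohortConfig | None = None) -> list[str]:
    cfg = config or CohortConfig()
    return list(cfg.effects)
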