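"""Parallel two-mediator path model for pairwise group contrasts.

For one pair of diagnostic groups and one outcome sub-score the model is the
standard parallel-mediator decomposition with age and education as mediators:

    age       = i_a + a_age * diag
    education = i_e + a_edu * diag
    outcome   = i_y + c' * diag + b_age * age + b_edu * education

with ``diag`` coded 0 for the cognitively better group of the pair and 1 for
the worse group. The direct effect is c'; each indirect effect is the product
of its two path coefficients (a * b); in this linear system the total effect
(coefficient of ``diag`` in the outcome-only regression) decomposes exactly
as total = direct + indirect_age + indirect_education.

Point estimates come from per-path ordinary least squares; the direct-effect
p-value uses the asymptotic normal z = b/se. Indirect effects are assessed by
a nonparametric bootstrap (participants resampled with replacement within the
pooled pair): percentile confidence interval, and a two-sided p-value from
the bootstrap z (point estimate over bootstrap standard deviation). Sub-score
selection keeps outcomes whose group difference is purely direct: direct
effect significant at alpha, neither indirect effect significant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm

from .battery import default_battery
from .cohort import Cohort, worse_group


class SingularFitError(ValueError):
    """Raised when a design variable is constant and the fit is degenerate."""


@dataclass(frozen=True)
class EffectEstimate:
    b: float
    se: float
    z: float
    p: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class MediationResult:
    pair: tuple[str, str]
    outcome: str
    direct: EffectEstimate
    indirect_age: EffectEstimate
    indirect_education: EffectEstimate
    total: float
    n_obs: int
    n_boot: int
    alpha: float

    @property
    def direct_significant(self) -> bool:
        return self.direct.p < self.alpha

    @property
    def any_indirect_significant(self) -> bool:
        return (
            self.indirect_age.p < self.alpha
            or self.indirect_education.p < self.alpha
        )


@dataclass
class MediationTable:
    pair: tuple[str, str]
    alpha: float
    results: list[MediationResult]
    errors: dict[str, str] = field(default_factory=dict)

    def __iter__(self):
        return iter(self.results)


@dataclass
class SelectionResult:
    pair: tuple[str, str]
    selected: list[str]
    table: MediationTable
    warning: str | None = None


def default_alpha(n_outcomes: int) -> float:
    """Bonferroni per-test level 0.05/n, rounded to 3 decimals.

    For a 13-outcome family this is the conventional 0.004; a single outcome
    needs no correction (0.05).
    """
    if n_outcomes < 1:
        raise ValueError("n_outcomes must be >= 1")
    return round(0.05 / n_outcomes, 3)


def _normal_estimate(b: float, se: float) -> EffectEstimate:
    z = b / se if se > 0 else np.inf * np.sign(b)
    p = 2.0 * norm.sf(abs(z))
    half = norm.ppf(0.975) * se
    return EffectEstimate(b=b, se=se, z=float(z), p=float(p),
                          ci_low=b - half, ci_high=b + half)


def _design(cohort: Cohort, pair: tuple[str, str], outcome: str) -> pd.DataFrame:
    df = cohort.subset_pair(pair)
    if outcome not in df.columns:
        raise KeyError(f"outcome {outcome!r} not observed in cohort")
    df = df[["group", "age", "education", outcome]].dropna().reset_index(drop=True)
    for g in pair:
        if (df["group"] == g).sum() < 3:
            raise SingularFitError(
                f"group {g} has fewer than 3 complete records for {outcome}"
            )
    worse = worse_group(pair)
    df["diag"] = (df["group"] == worse).astype(float)
    for var in ("age", "education", outcome):
        if np.ptp(df[var].to_numpy()) == 0.0:
            raise SingularFitError(f"variable {var!r} is constant in the pair")
    return df


def fit_mediation(
    cohort: Cohort,
    pair: tuple[str, str],
    outcome: str,
    n_boot: int = 1000,
    seed: int = 0,
    alpha: float = 0.004,
    stratified: bool = False,
) -> MediationResult:
    """Fit the two-mediator path model for one outcome and one group pair.

    ``stratified`` resamples within each diagnostic group instead of over the
    pooled pair (the pooled scheme is the default). Deterministic given seed.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    df = _design(cohort, pair, outcome)
    n = len(df)
    y = df[outcome].to_numpy(float)
    diag = df["diag"].to_numpy(float)
    age = df["age"].to_numpy(float)
    edu = df["education"].to_numpy(float)

    X_out = sm.add_constant(np.column_stack([diag, age, edu]))
    fit_out = sm.OLS(y, X_out).fit()
    X_m = sm.add_constant(diag)
    fit_age = sm.OLS(age, X_m).fit()
    fit_edu = sm.OLS(edu, X_m).fit()
    fit_tot = sm.OLS(y, X_m).fit()

    direct = _normal_estimate(float(fit_out.params[1]), float(fit_out.bse[1]))
    a_age, a_edu = float(fit_age.params[1]), float(fit_edu.params[1])
    b_age, b_edu = float(fit_out.params[2]), float(fit_out.params[3])

    boot_age, boot_edu = _bootstrap_indirects(
        y, diag, age, edu, n_boot=n_boot, seed=seed, stratified=stratified
    )
    indirect_age = _bootstrap_estimate(a_age * b_age, boot_age)
    indirect_edu = _bootstrap_estimate(a_edu * b_edu, boot_edu)

    return MediationResult(
        pair=pair,
        outcome=outcome,
        direct=direct,
        indirect_age=indirect_age,
        indirect_education=indirect_edu,
        total=float(fit_tot.params[1]),
        n_obs=n,
        n_boot=n_boot,
        alpha=alpha,
    )


def _bootstrap_estimate(point: float, draws: np.ndarray) -> EffectEstimate:
    se = float(np.std(draws, ddof=1)) if len(draws) > 1 else 0.0
    z = point / se if se > 0 else 0.0
    p = 2.0 * norm.sf(abs(z)) if se > 0 else 1.0
    lo, hi = np.percentile(draws, [2.5, 97.5])
    return EffectEstimate(b=point, se=se, z=float(z), p=float(p),
                          ci_low=float(lo), ci_high=float(hi))


def _bootstrap_indirects(
    y: np.ndarray,
    diag: np.ndarray,
    age: np.ndarray,
    edu: np.ndarray,
    n_boot: int,
    seed: int,
    stratified: bool,
) -> tuple[np.ndarray, np.ndarray]:
    """Bootstrap draws of the two indirect-effect products.

    Solves the batched per-resample normal equations directly; resamples in
    which a regressor collapses to a constant are redrawn.
    """
    rng = np.random.default_rng(seed)
    n = len(y)
    if stratified:
        idx0 = np.flatnonzero(diag == 0.0)
        idx1 = np.flatnonzero(diag == 1.0)
        idx = np.concatenate(
            [
                idx0[rng.integers(0, len(idx0), size=(n_boot, len(idx0)))],
                idx1[rng.integers(0, len(idx1), size=(n_boot, len(idx1)))],
            ],
            axis=1,
        )
    else:
        idx = rng.integers(0, n, size=(n_boot, n))
        # redraw resamples containing a single group (vanishing probability)
        for _ in range(100):
            d = diag[idx]
            bad = np.flatnonzero((d.sum(axis=1) == 0) | (d.sum(axis=1) == n))
            if len(bad) == 0:
                break
            idx[bad] = rng.integers(0, n, size=(len(bad), n))

    d_b = diag[idx]
    age_b = age[idx]
    edu_b = edu[idx]
    y_b = y[idx]

    # mediator models: slope on a binary regressor = group mean difference
    n1 = d_b.sum(axis=1)
    n0 = n - n1
    a_age = (age_b * d_b).sum(axis=1) / n1 - (age_b * (1 - d_b)).sum(axis=1) / n0
    a_edu = (edu_b * d_b).sum(axis=1) / n1 - (edu_b * (1 - d_b)).sum(axis=1) / n0

    X = np.stack([np.ones_like(d_b), d_b, age_b, edu_b], axis=2)  # (B, n, 4)
    xtx = np.einsum("bni,bnj->bij", X, X)
    xty = np.einsum("bni,bn->bi", X, y_b)
    try:
        beta = np.linalg.solve(xtx, xty[..., None])[..., 0]
    except np.linalg.LinAlgError:
        beta = np.stack(
            [np.linalg.lstsq(X[i], y_b[i], rcond=None)[0] for i in range(len(X))]
        )
    return a_age * beta[:, 2], a_edu * beta[:, 3]


def mediation_table(
    cohort: Cohort,
    pair: tuple[str, str],
    outcomes: Sequence[str],
    n_boot: int = 1000,
    seed: int = 0,
    alpha: float | None = None,
    stratified: bool = False,
) -> MediationTable:
    """One mediation fit per outcome, errors collected without aborting.

    Per-outcome bootstrap seeds are spawned deterministically from the master
    seed; ``alpha=None`` applies the Bonferroni default for the family size.
    """
    if not outcomes:
        raise ValueError("outcomes must be non-empty")
    if alpha is None:
        alpha = default_alpha(len(outcomes))
    children = np.random.SeedSequence(seed).spawn(len(outcomes))
    results: list[MediationResult] = []
    errors: dict[str, str] = {}
    for outcome, child in zip(outcomes, children):
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        try:
            results.append(
                fit_mediation(
                    cohort, pair, outcome,
                    n_boot=n_boot, seed=sub_seed, alpha=alpha,
                    stratified=stratified,
                )
            )
        except (SingularFitError, KeyError) as exc:
            errors[outcome] = str(exc)
    return MediationTable(pair=pair, alpha=alpha, results=results, errors=errors)


def select_subtasks(table: MediationTable) -> SelectionResult:
    """Keep outcomes whose pairwise difference is purely direct.

    A sub-score is selected when its direct effect is significant at the
    table's alpha and neither indirect path is. Order follows the battery
    registry; an empty selection returns a warning rather than raising.
    """
    order = {s.id: i for i, s in enumerate(default_battery())}
    selected = [
        r.outcome
        for r in table.results
        if r.direct_significant and not r.any_indirect_significant
    ]
    selected.sort(key=lambda sid: order.get(sid, len(order)))
    warning = None
    if not selected:
        warning = (
            f"no subtask shows a purely direct group effect at alpha={table.alpha}"
        )
    return SelectionResult(pair=table.pair, selected=selected, table=table,
                           warning=warning)


def mediation_frame(table: MediationTable) -> pd.DataFrame:
    """Long-format report mirroring the direct/indirect effect tables:
    one 'direct' row per outcome and one row per mediator path."""
    rows = []
    for r in table.results:
        rows.append(
            {
                "pair": "-".join(r.pair), "outcome": r.outcome,
                "effect": "direct", "mediator": "",
                "b": r.direct.b, "se": r.direct.se, "z": r.direct.z,
                "p": r.direct.p, "ci_low": r.direct.ci_low,
                "ci_high": r.direct.ci_high,
                "significant": r.direct_significant,
            }
        )
        for name, est in (
            ("age", r.indirect_age),
            ("education", r.indirect_education),
        ):
            rows.append(
                {
                    "pair": "-".join(r.pair), "outcome": r.outcome,
                    "effect": "indirect", "mediator": name,
                    "b": est.b, "se": est.se, "z": est.z, "p": est.p,
                    "ci_low": est.ci_low, "ci_high": est.ci_high,
                    "significant": est.p < table.alpha,
                }
            )
    return pd.DataFrame(rows)
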