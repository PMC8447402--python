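"""Monthly progression-risk profiles from right-censored cohorts.

A profile is the survival curve S(0..H) on an integer monthly grid together
with the derived unconditional monthly progression-probability mass
p_m = S(m-1) - S(m) and cumulative risk F(t) = 1 - S(t).  Three sources are
supported: Kaplan-Meier (nonparametric reference), a random-survival-forest
ensemble averaged over out-of-bag per-patient curves (the risk-adjusted
cohort curve), and the synthetic generator's exact marginal (an oracle for
estimator tests).

"Each month's progression probability" here is incidence mass, not the
conditional hazard: the masses sum to the cumulative risk curve.  The
conditional hazard h_m = p_m / S(m-1) is exposed as a derived accessor.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from sklearn.ensemble._forest import (
    _generate_unsampled_indices,
    _get_n_samples_bootstrap,
)
from sksurv.ensemble import RandomSurvivalForest

from .cohort import Cohort
from .synthetic import GeneratorConfig


@dataclass
class MonthlyRiskProfile:
    """Survival curve on the monthly grid 0..H plus derived quantities."""

    survival: np.ndarray  # S(0), S(1), ..., S(H); S(0) = 1, nonincreasing
    source: str = "km"  # {"km", "rsf", "true_generator"}

    def __post_init__(self) -> None:
        self.survival = np.asarray(self.survival, float)
        if self.survival.ndim != 1 or len(self.survival) < 2:
            raise ValueError("survival must be a 1-D array S(0..H), H >= 1")
        if abs(self.survival[0] - 1.0) > 1e-12:
            raise ValueError("S(0) must equal 1")
        if (np.diff(self.survival) > 1e-12).any():
            raise ValueError("survival must be nonincreasing")
        if (self.survival < -1e-12).any() or (self.survival > 1 + 1e-12).any():
            raise ValueError("survival values must lie in [0, 1]")
        self.survival = np.clip(self.survival, 0.0, 1.0)

    @property
    def horizon(self) -> int:
        return len(self.survival) - 1

    @property
    def mass(self) -> np.ndarray:
        """p_1..p_H: unconditional progression probability per month."""
        return -np.diff(self.survival)

    @property
    def cumulative(self) -> np.ndarray:
        """F(0..H) = 1 - S."""
        return 1.0 - self.survival

    @property
    def conditional_hazard(self) -> np.ndarray:
        """h_1..h_H with h_m = p_m / S(m-1); 0 where no one is left at risk."""
        s_prev = self.survival[:-1]
        with np.errstate(divide="ignore", invalid="ignore"):
            h = np.where(s_prev > 0, self.mass / s_prev, 0.0)
        return h

    @classmethod
    def from_mass(cls, mass: np.ndarray, source: str) -> "MonthlyRiskProfile":
        mass = np.asarray(mass, float)
        survival = 1.0 - np.concatenate([[0.0], np.cumsum(mass)])
        return cls(survival, source=source)

    def peak_month(self) -> int:
        """1-based month of maximal monthly mass (earliest on ties)."""
        return int(np.argmax(self.mass)) + 1

    def to_frame(self) -> pd.DataFrame:
        months = np.arange(self.horizon + 1)
        mass = np.concatenate([[0.0], self.mass])
        return pd.DataFrame(
            {
                "month": months,
                "survival": self.survival,
                "mass": mass,
                "cumulative": self.cumulative,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, source: str = "km") -> "MonthlyRiskProfile":
        df = pd.read_csv(path).sort_values("month")
        return cls(df["survival"].to_numpy(float), source=source)


@dataclass
class RSFConfig:
    """Random-survival-forest hyperparameters.

    The source analysis states none, so defaults follow standard forest
    practice: 1,000 trees, sqrt-of-features split candidates, minimum
    terminal-node size 15, bootstrap resampling.
    """

    n_trees: int = 1000
    features_per_split: int | None = None  # None -> ceil(sqrt(n_features))
    min_node_size: int = 15
    bootstrap: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees <= 0 or self.min_node_size <= 0:
            raise ValueError("n_trees and min_node_size must be positive")
        if self.features_per_split is not None and self.features_per_split <= 0:
            raise ValueError("features_per_split must be positive")


def km_profile(cohort: Cohort, horizon: int = 36) -> MonthlyRiskProfile:
    """Kaplan-Meier survival evaluated at integer months 0..horizon."""
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    if cohort.n_events == 0:
        raise ValueError("cohort has no observed events; profile undefined")
    kmf = KaplanMeierFitter()
    kmf.fit(cohort.data["pfs_months"], cohort.data["event"])
    months = np.arange(horizon + 1)
    surv = kmf.survival_function_at_times(months).to_numpy(float)
    surv[0] = 1.0
    return MonthlyRiskProfile(surv, source="km")


def _step_interp(unique_times: np.ndarray, values: np.ndarray, months: np.ndarray) -> np.ndarray:
    """Right-continuous step interpolation of survival curves onto months.

    values: (n_subjects, n_times) at unique_times; S = 1 before the first time.
    """
    idx = np.searchsorted(unique_times, months, side="right") - 1
    out = np.ones((values.shape[0], len(months)))
    inside = idx >= 0
    out[:, inside] = values[:, idx[inside]]
    return out


def rsf_oob_curves(
    cohort: Cohort, config: RSFConfig | None = None, horizon: int = 36
) -> np.ndarray:
    """Per-patient out-of-bag survival curves on the monthly grid.

    Fits a random survival forest (log-rank splits, Nelson-Aalen terminal-node
    estimates) on bootstrap samples of the cohort; each patient's curve
    averages only the trees whose bootstrap sample excluded that patient.
    Returns an (n_patients, horizon+1) matrix.
    """
    if config is None:
        config = RSFConfig()
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    if cohort.n_events == 0:
        raise ValueError("cohort has no observed events")
    if cohort.n_events < config.min_node_size:
        raise ValueError(
            f"only {cohort.n_events} events but min_node_size="
            f"{config.min_node_size}; use a smaller node size"
        )
    X = cohort.covariates_onehot().to_numpy(float)
    n, n_features = X.shape
    max_features = config.features_per_split or math.ceil(math.sqrt(n_features))
    max_features = min(max_features, n_features)
    y = np.empty(n, dtype=[("event", "?"), ("time", "f8")])
    y["event"] = cohort.data["event"].to_numpy(bool)
    y["time"] = cohort.data["pfs_months"].to_numpy(float)

    forest = RandomSurvivalForest(
        n_estimators=config.n_trees,
        min_samples_leaf=config.min_node_size,
        max_features=max_features,
        bootstrap=config.bootstrap,
        random_state=config.seed,
        n_jobs=1,
    )
    forest.fit(X, y)

    months = np.arange(horizon + 1, dtype=float)
    total = np.zeros((n, horizon + 1))
    counts = np.zeros(n)
    if config.bootstrap:
        n_boot = _get_n_samples_bootstrap(n, forest.max_samples, None)
    for tree in forest.estimators_:
        if config.bootstrap:
            oob = _generate_unsampled_indices(tree.random_state, n, n_boot, None)
        else:
            oob = np.arange(n)
        if len(oob) == 0:
            continue
        surv = tree.predict_survival_function(X[oob], return_array=True)
        surv = np.asarray(surv).reshape(len(oob), -1)  # 1-D when one unique time
        total[oob] += _step_interp(tree.unique_times_, surv, months)
        counts[oob] += 1

    never_oob = counts == 0
    if never_oob.any():
        # with very few trees a patient can be in-bag everywhere;
        # fall back to the full-forest curve for those patients
        surv = forest.predict_survival_function(X[never_oob], return_array=True)
        surv = np.asarray(surv).reshape(int(never_oob.sum()), -1)
        total[never_oob] = _step_interp(forest.unique_times_, surv, months)
        counts[never_oob] = 1.0
    curves = total / counts[:, None]
    curves[:, 0] = 1.0
    # enforce monotonicity against step-grid rounding
    return np.minimum.accumulate(curves, axis=1)


def rsf_profile(
    cohort: Cohort, config: RSFConfig | None = None, horizon: int = 36
) -> MonthlyRiskProfile:
    """Risk-adjusted cohort profile: unweighted mean of per-patient OOB curves."""
    curves = rsf_oob_curves(cohort, config, horizon)
    return MonthlyRiskProfile(curves.mean(axis=0), source="rsf")


def true_profile(config: GeneratorConfig, horizon: int | None = None) -> MonthlyRiskProfile:
    """The generator's exact population marginal on the monthly grid.

    With zero covariate effects this is the calibrated baseline itself; with
    effects it is the exact mixture over the (independent) effect-bearing
    covariates, obtained by enumerating their joint patterns.
    """
    H = horizon or config.horizon_months
    hazards = config.conditional_hazards()[:H]
    if not config.covariate_log_effects:
        surv = np.concatenate([[1.0], np.cumprod(1.0 - hazards)])
        return MonthlyRiskProfile(surv, source="true_generator")

    beta_bar = config.mean_linear_predictor()
    # group effect keys: binaries are independent Bernoullis; levels of one
    # categorical column are mutually exclusive and form a single group
    groups: list[list[tuple[float, float]]] = []  # [(weight, beta), ...] per group
    cat_groups: dict[str, dict[str, float]] = {}
    for name, beta in config.covariate_log_effects.items():
        if name in config.binary_prevalences:
            q = config.binary_prevalences[name]
            groups.append([(1.0 - q, 0.0), (q, beta)])
        else:
            for col, level_probs in config.categorical_prevalences.items():
                match = next(
                    (a for a in level_probs if name == f"{col}_{a}"), None
                )
                if match is not None:
                    cat_groups.setdefault(col, {})[match] = beta
                    break
            else:
                raise KeyError(f"unknown covariate in log effects: {name!r}")
    for col, betas in cat_groups.items():
        level_probs = config.categorical_prevalences[col]
        norm = sum(level_probs.values())
        groups.append(
            [(q / norm, betas.get(level, 0.0)) for level, q in level_probs.items()]
        )

    surv_mix = np.zeros(H + 1)
    for combo in itertools.product(*groups):
        weight = math.prod(w for w, _ in combo)
        r = math.exp(sum(b for _, b in combo) - beta_bar)
        hx = np.clip(hazards * r, 0.0, 1.0)
        surv_mix += weight * np.concatenate([[1.0], np.cumprod(1.0 - hx)])
    surv_mix[0] = 1.0
    return MonthlyRiskProfile(surv_mix, source="true_generator")
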