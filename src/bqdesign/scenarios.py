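"""Simulation truth: correlated toxicity/efficacy outcome generation.

Outcomes are generated from a latent bivariate-normal model.  For each
patient at dose j a pair (x~, y~) is drawn with means (0, mu_j),
variances (1, sigma^2) and covariance rho*sigma.  Toxicity is the
indicator x~ > Phi^-1(1 - pi_j), which makes the marginal toxicity rate
exactly pi_j.  The efficacy endpoint is

* continuous: y~ itself,
* ordinal:    the bin of y~ among strictly increasing cutoffs
              gamma_1 < ... < gamma_{K-1} (categories 0..K-1),
* binary:     the indicator (y~ - mu_j)/sigma > Phi^-1(1 - piE_j), with
              per-dose efficacy rate piE_j.

The module ships a library of benchmark scenarios — ten continuous, six
ordinal and six binary dose-response shapes plus flat null curves — each
labelled with its true minimum effective dose and maximum utility dose
for scoring operating characteristics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml
from scipy.optimize import minimize
from scipy.stats import norm

__all__ = [
    "Scenario",
    "builtin_scenarios",
    "get_scenario",
    "fit_ordinal_cutoffs",
    "load_scenario",
    "save_scenario",
]


@dataclass
class Scenario:
    """True per-dose outcome distributions for one simulation scenario.

    ``efficacy`` holds per-dose mean efficacies for continuous/ordinal
    endpoints, or per-dose efficacy *rates* for binary endpoints.  For
    ordinal endpoints ``latent_means`` are the means of the latent normal
    and ``cutoffs`` the K-1 strictly increasing bin boundaries (required
    before outcomes can be drawn).  ``true_med``/``true_mud`` are 1-based
    arm indices used for scoring; ``utility_weight`` and ``delta`` record
    the tradeoff weight and target efficacy difference under which those
    labels are the correct answers.
    """

    name: str
    endpoint_type: str
    tox_rates: tuple[float, ...]
    efficacy: tuple[float, ...]
    rho: float = 0.3
    sigma: float = 1.0
    cutoffs: tuple[float, ...] | None = None
    latent_means: tuple[float, ...] | None = None
    true_med: int | None = None
    true_mud: int | None = None
    utility_weight: float | None = None
    delta: float | None = None
    default_stage_sizes: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        self.tox_rates = tuple(float(p) for p in self.tox_rates)
        self.efficacy = tuple(float(m) for m in self.efficacy)
        if len(self.tox_rates) != len(self.efficacy):
            raise ValueError("tox_rates and efficacy must have equal lengths")
        if any(not 0.0 <= p <= 1.0 for p in self.tox_rates):
            raise ValueError("toxicity rates must lie in [0, 1]")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not -1.0 < self.rho < 1.0:
            raise ValueError("|rho| must be < 1")
        if self.endpoint_type == "binary" and any(
            not 0.0 <= p <= 1.0 for p in self.efficacy
        ):
            raise ValueError("binary efficacy rates must lie in [0, 1]")
        if self.cutoffs is not None:
            self.cutoffs = tuple(float(g) for g in self.cutoffs)
            if any(b <= a for a, b in zip(self.cutoffs, self.cutoffs[1:])):
                raise ValueError("ordinal cutoffs must be strictly increasing")

    @property
    def n_arms(self) -> int:
        return len(self.tox_rates)

    @property
    def declared_bounds(self) -> tuple[float, float] | None:
        if self.endpoint_type == "binary":
            return (0.0, 1.0)
        if self.endpoint_type == "ordinal":
            if self.cutoffs is None:
                return None
            return (0.0, float(len(self.cutoffs)))
        return None

    # -- generation -----------------------------------------------------

    def draw_outcomes(self, dose_index: int, n: int, rng: np.random.Generator
                      ) -> tuple[np.ndarray, np.ndarray]:
        """Draw n correlated (toxicity, efficacy) outcome pairs at a dose."""
        j = dose_index - 1
        if not 0 <= j < self.n_arms:
            raise ValueError(f"dose_index {dose_index} out of range")
        z1 = rng.standard_normal(n)
        z2 = rng.standard_normal(n)
        x_lat = z1
        y_std = self.rho * z1 + np.sqrt(1.0 - self.rho**2) * z2  # std latent efficacy

        tox = (x_lat > norm.ppf(1.0 - self.tox_rates[j])).astype(np.int64)

        if self.endpoint_type == "continuous":
            eff = self.efficacy[j] + self.sigma * y_std
        elif self.endpoint_type == "binary":
            eff = (y_std > norm.ppf(1.0 - self.efficacy[j])).astype(np.float64)
        elif self.endpoint_type == "ordinal":
            if self.cutoffs is None:
                raise ValueError(
                    f"ordinal scenario {self.name!r} has no cutoffs; supply them "
                    "or fit them with fit_ordinal_cutoffs()"
                )
            mean = (self.latent_means or self.efficacy)[j]
            y_lat = mean + self.sigma * y_std
            eff = np.searchsorted(np.asarray(self.cutoffs), y_lat, side="left").astype(np.float64)
        else:
            raise ValueError(f"unknown endpoint type {self.endpoint_type!r}")
        return tox, eff

    def with_cutoffs(self, cutoffs) -> "Scenario":
        d = asdict(self)
        d["cutoffs"] = tuple(float(g) for g in cutoffs)
        return Scenario(**d)

    # -- (de)serialization ----------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("tox_rates", "efficacy", "cutoffs", "latent_means", "default_stage_sizes"):
            if d[key] is not None:
                d[key] = list(d[key])
        return d


def save_scenario(scenario: Scenario, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(scenario.to_dict(), fh, sort_keys=False)


def load_scenario(path) -> Scenario:
    with open(path, "r", encoding="utf-8") as fh:
        d = yaml.safe_load(fh)
    for key in ("tox_rates", "efficacy", "cutoffs", "latent_means", "default_stage_sizes"):
        if d.get(key) is not None:
            d[key] = tuple(d[key])
    return Scenario(**d)


def fit_ordinal_cutoffs(
    latent_means, target_means, sigma: float = 1.0, n_categories: int = 5,
    min_gap: float = 0.2,
) -> np.ndarray:
    """Fit one shared cutoff vector so per-dose ordinal means approximate targets.

    The mean of the binned variable is sum_k Pr(y~ > gamma_k); a single
    shared cutoff vector cannot in general match every dose's target mean
    exactly, so the fit minimizes the summed squared error (least squares
    over a monotone parametrization).  The result is approximate by
    construction.  ``min_gap`` enforces a minimum category width on the
    latent scale: the unconstrained optimum can collapse adjacent cutoffs,
    which would merge categories.
    """
    latent_means = np.asarray(latent_means, dtype=float)
    target_means = np.asarray(target_means, dtype=float)
    K = int(n_categories)
    if min_gap <= 0:
        raise ValueError("min_gap must be positive")

    def expected_means(gammas):
        z = (gammas[None, :] - latent_means[:, None]) / sigma
        return norm.sf(z).sum(axis=1)

    def unpack(params):
        return np.concatenate(
            [[params[0]], params[0] + np.cumsum(min_gap + np.exp(params[1:]))]
        )

    x0 = np.concatenate([[latent_means.min() - sigma],
                         np.full(K - 2, np.log(0.5))])
    res = minimize(
        lambda p: float(((expected_means(unpack(p)) - target_means) ** 2).sum()),
        x0,
        method="Nelder-Mead",
        options={"maxiter": 5000, "xatol": 1e-8, "fatol": 1e-12},
    )
    return unpack(res.x)


# ---------------------------------------------------------------------------
# Built-in scenario library
# ---------------------------------------------------------------------------

_CONT_STAGES = (100, 25, 25, 25, 25)
_ORD_STAGES = (120, 30, 30, 30, 30)
_BIN_STAGES = (80, 20, 20, 20, 20)

# (mean efficacies, toxicity rates, true MED arm, true MUD arm), w = 2, delta = 0.4
_CONTINUOUS = [
    ((0.20, 0.57, 0.70, 0.76, 0.80), (0.05, 0.10, 0.11, 0.30, 0.34), 2, 3),
    ((0.20, 0.44, 0.57, 0.67, 0.75), (0.05, 0.07, 0.22, 0.34, 0.45), 3, 2),
    ((0.20, 0.21, 0.58, 0.77, 0.77), (0.05, 0.10, 0.18, 0.20, 0.45), 3, 4),
    ((0.20, 0.20, 0.20, 0.22, 0.60), (0.05, 0.06, 0.08, 0.10, 0.24), 5, 5),
    ((0.20, 0.34, 0.68, 0.76, 0.78), (0.05, 0.12, 0.14, 0.35, 0.45), 3, 3),
    ((0.20, 0.21, 0.72, 0.75, 0.80), (0.05, 0.06, 0.15, 0.24, 0.28), 3, 3),
    ((0.20, 0.24, 0.41, 0.68, 0.78), (0.05, 0.06, 0.10, 0.12, 0.32), 4, 4),
    ((0.20, 0.23, 0.32, 0.65, 0.79), (0.05, 0.08, 0.10, 0.32, 0.45), 4, 3),
    ((0.20, 0.23, 0.25, 0.72, 0.80), (0.05, 0.06, 0.08, 0.15, 0.34), 4, 4),
    ((0.20, 0.20, 0.22, 0.54, 0.80), (0.05, 0.06, 0.08, 0.18, 0.20), 4, 5),
]

# ordinal scenarios: printed target means on the 0..4 scale; the latent
# normal means reuse continuous shapes 1, 3, 4, 5, 7, 8.  Implied tradeoff
# weight in the printed utilities is 4; implied delta 0.75.
_ORDINAL = [
    ((0.80, 1.55, 1.80, 1.92, 2.00), 0, 2, 3),
    ((0.80, 0.83, 1.56, 1.93, 1.94), 2, 3, 4),
    ((0.80, 0.80, 0.80, 0.83, 1.60), 3, 5, 5),
    ((0.80, 1.08, 1.76, 1.92, 1.96), 4, 3, 3),
    ((0.80, 0.87, 1.22, 1.75, 1.95), 6, 4, 4),
    ((0.80, 0.86, 1.04, 1.70, 1.98), 7, 4, 3),
]

# binary scenarios: per-dose efficacy rates; toxicity reuses continuous
# shapes 1, 3, 4, 5, 7, 8.  Implied tradeoff weight 1; implied delta 0.2.
_BINARY = [
    ((0.20, 0.39, 0.45, 0.48, 0.50), 0, 2, 3),
    ((0.20, 0.21, 0.39, 0.48, 0.48), 2, 3, 4),
    ((0.20, 0.20, 0.20, 0.21, 0.40), 3, 5, 5),
    ((0.20, 0.27, 0.44, 0.48, 0.49), 4, 3, 3),
    ((0.20, 0.22, 0.30, 0.44, 0.49), 6, 4, 4),
    ((0.20, 0.22, 0.26, 0.43, 0.50), 7, 4, 3),
]


def builtin_scenarios() -> dict[str, Scenario]:
    """The benchmark scenario library, keyed ``continuous/s1`` ... ``null/binary``."""
    lib: dict[str, Scenario] = {}
    for i, (eff, tox, med, mud) in enumerate(_CONTINUOUS, start=1):
        lib[f"continuous/s{i}"] = Scenario(
            name=f"continuous/s{i}", endpoint_type="continuous",
            tox_rates=tox, efficacy=eff, true_med=med, true_mud=mud,
            utility_weight=2.0, delta=0.4, default_stage_sizes=_CONT_STAGES,
        )
    for i, (eff, src, med, mud) in enumerate(_ORDINAL, start=1):
        base_eff, base_tox, _, _ = _CONTINUOUS[src]
        lib[f"ordinal/s{i}"] = Scenario(
            name=f"ordinal/s{i}", endpoint_type="ordinal",
            tox_rates=base_tox, efficacy=eff, latent_means=base_eff,
            true_med=med, true_mud=mud,
            utility_weight=4.0, delta=0.75, default_stage_sizes=_ORD_STAGES,
        )
    for i, (eff, src, med, mud) in enumerate(_BINARY, start=1):
        _, base_tox, _, _ = _CONTINUOUS[src]
        lib[f"binary/s{i}"] = Scenario(
            name=f"binary/s{i}", endpoint_type="binary",
            tox_rates=base_tox, efficacy=eff,
            true_med=med, true_mud=mud,
            utility_weight=1.0, delta=0.2, default_stage_sizes=_BIN_STAGES,
        )
    lib["null/continuous"] = Scenario(
        name="null/continuous", endpoint_type="continuous",
        tox_rates=(0.05,) * 5, efficacy=(0.2,) * 5,
        utility_weight=2.0, delta=0.4, default_stage_sizes=_CONT_STAGES,
    )
    lib["null/binary"] = Scenario(
        name="null/binary", endpoint_type="binary",
        tox_rates=(0.05,) * 5, efficacy=(0.2,) * 5,
        utility_weight=1.0, delta=0.2, default_stage_sizes=_BIN_STAGES,
    )
    return lib


def get_scenario(name: str) -> Scenario:
    lib = builtin_scenarios()
    if name not in lib:
        raise KeyError(f"unknown scenario {name!r}; available: {sorted(lib)}")
    return lib[name]
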