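"""Design configuration: priors, decision cutoffs, utility and staging.

All tunable parameters of the design live in one dataclass so that a trial,
a simulation study and a calibration run share a single source of truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import yaml

from .data import BetaParams

__all__ = ["UtilitySpec", "DesignConfig"]


@dataclass(frozen=True)
class UtilitySpec:
    """Benefit-risk tradeoff U = mu - w1*pi - w2*pi*1(pi > rho).

    The simple linear tradeoff U = mu - w*pi is the special case w2 = 0
    (then ``w1`` plays the role of w and ``rho`` is irrelevant).
    """

    w1: float = 2.0
    w2: float = 0.0
    rho: float = 0.0

    def __call__(self, mu, pi):
        from .decisions import utility_extended

        return utility_extended(mu, pi, rho=self.rho, w1=self.w1, w2=self.w2)


@dataclass
class DesignConfig:
    """All decision parameters of the dose-ranging design.

    Parameters
    ----------
    n_arms
        Number of arms J including the placebo/control arm 1.
    delta
        Clinically relevant efficacy difference over placebo used to define
        the minimum effective dose (original endpoint scale).
    pi_bar
        Highest acceptable excess toxicity over placebo in the safety rule
        Pr(pi_j > pi_1 + pi_bar) < CT.
    ct, ce
        Probability cutoffs of the safety and futility admissibility rules.
    c_poc
        Posterior-probability cutoff for establishing proof-of-concept;
        normally obtained by calibration on a null scenario.
    utility
        Benefit-risk tradeoff specification.
    tau
        Weight on MED-targeting (vs MUD-targeting) in adaptive
        randomization; tau = 1 targets the MED only, tau = 0 the MUD only.
    nu
        Adaptiveness exponent of the randomization rule; nu = 0 gives equal
        randomization among admissible doses.
    stage_sizes
        Patients enrolled per stage (c_1, ..., c_S).
    tox_prior, eff_prior
        Beta hyperparameters of the toxicity rate and the standardized
        conditional efficacy means (identical across doses and toxicity
        strata by default; vague Beta(1, 1)).
    n_draws
        Number of Monte-Carlo posterior draws T.
    isotonic_toxicity, isotonic_efficacy
        Whether to monotonize the toxicity / marginal-efficacy posterior
        draws across doses.
    require_mud_ge_med
        Optionally constrain the selected MUD to be at least the MED.
    endpoint_type, declared_bounds
        Efficacy endpoint type and, for bounded types, its boundaries.
    """

    n_arms: int = 5
    delta: float = 0.4
    pi_bar: float = 0.3
    ct: float = 0.9
    ce: float = 0.7
    c_poc: float = 0.95
    utility: UtilitySpec = field(default_factory=UtilitySpec)
    tau: float = 0.5
    nu: float = 1.0
    stage_sizes: tuple[int, ...] = (100, 25, 25, 25, 25)
    tox_prior: BetaParams = field(default_factory=lambda: BetaParams(1.0, 1.0))
    eff_prior: BetaParams = field(default_factory=lambda: BetaParams(1.0, 1.0))
    n_draws: int = 4000
    isotonic_toxicity: bool = True
    isotonic_efficacy: bool = True
    require_mud_ge_med: bool = False
    endpoint_type: str = "continuous"
    declared_bounds: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.n_arms < 2:
            raise ValueError("n_arms must be >= 2 (arm 1 is placebo/control)")
        for name in ("ct", "ce", "c_poc"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0 + 1e-12:
                raise ValueError(f"{name} must lie in (0, 1], got {v}")
        if not 0.0 <= self.tau <= 1.0:
            raise ValueError("tau must lie in [0, 1]")
        if self.nu < 0:
            raise ValueError("nu must be nonnegative")
        self.stage_sizes = tuple(int(c) for c in self.stage_sizes)
        if any(c <= 0 for c in self.stage_sizes):
            raise ValueError("stage sizes must be positive integers")
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")

    @property
    def n_stages(self) -> int:
        return len(self.stage_sizes)

    @property
    def max_patients(self) -> int:
        return sum(self.stage_sizes)

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["utility"] = asdict(self.utility)
        d["tox_prior"] = [self.tox_prior.alpha, self.tox_prior.beta]
        d["eff_prior"] = [self.eff_prior.alpha, self.eff_prior.beta]
        d["stage_sizes"] = list(self.stage_sizes)
        if self.declared_bounds is not None:
            d["declared_bounds"] = list(self.declared_bounds)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DesignConfig":
        d = dict(d)
        if "utility" in d and isinstance(d["utility"], dict):
            d["utility"] = UtilitySpec(**d["utility"])
        for key in ("tox_prior", "eff_prior"):
            if key in d and not isinstance(d[key], BetaParams):
                a, b = d[key]
                d[key] = BetaParams(float(a), float(b))
        if d.get("declared_bounds") is not None:
            lo, hi = d["declared_bounds"]
            d["declared_bounds"] = (float(lo), float(hi))
        if "stage_sizes" in d:
            d["stage_sizes"] = tuple(d["stage_sizes"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "DesignConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
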