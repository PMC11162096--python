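"""Dose-selection decision rules.

Given matched posterior draws across doses, this module screens doses for
admissibility (safety and futility), tests for proof-of-concept (PoC),
selects the minimum effective dose (MED) and the maximum utility dose
(MUD), and turns per-draw target-dose frequencies into adaptive
randomization probabilities.

All posterior probabilities are estimated as draw proportions with strict
inequalities.  Arm 1 is the placebo/control; only arms 2..J compete for
admissibility and target-dose status.  Ties in argmin/argmax break toward
the lower dose index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json

import numpy as np

from .config import DesignConfig, UtilitySpec
from .posteriors import PosteriorDraws

__all__ = [
    "utility_simple",
    "utility_extended",
    "AdmissibleSet",
    "DoseDecision",
    "admissible_set",
    "analyze",
    "poc_test",
    "poc_statistic",
    "select_med",
    "select_mud",
    "target_dose_probabilities",
    "randomization_probabilities",
    "DesignConfig",
    "UtilitySpec",
]


def utility_simple(mu, pi, w: float):
    """Linear benefit-risk tradeoff: a unit of toxicity costs w units of efficacy."""
    return np.asarray(mu, dtype=float) - w * np.asarray(pi, dtype=float)


def utility_extended(mu, pi, rho: float, w1: float, w2: float):
    """Tradeoff with an extra penalty w2 once the toxicity rate exceeds rho."""
    mu = np.asarray(mu, dtype=float)
    pi = np.asarray(pi, dtype=float)
    return mu - w1 * pi - w2 * pi * (pi > rho)


@dataclass(frozen=True)
class AdmissibleSet:
    """Treatment doses (1-based indices in 2..J) currently considered usable."""

    members: tuple[int, ...]
    n_arms: int

    def __post_init__(self) -> None:
        if any(not 2 <= j <= self.n_arms for j in self.members):
            raise ValueError("admissible doses must lie in 2..J")

    def __contains__(self, j: int) -> bool:
        return j in self.members

    def __len__(self) -> int:
        return len(self.members)

    @property
    def empty(self) -> bool:
        return len(self.members) == 0

    def indices0(self) -> np.ndarray:
        """0-based column indices into T x J draw matrices."""
        return np.asarray(self.members, dtype=np.int64) - 1


@dataclass
class DoseDecision:
    """Bundle of one analysis' decision outputs (serializable to JSON)."""

    admissible: AdmissibleSet
    poc_established: bool | None = None
    med: int | None = None
    mud: int | None = None
    utility_estimates: np.ndarray | None = None
    p_med: np.ndarray | None = None
    p_mud: np.ndarray | None = None
    randomization: np.ndarray | None = None

    def to_dict(self) -> dict:
        def arr(a):
            return None if a is None else [float(v) for v in a]

        return {
            "admissible": list(self.admissible.members),
            "poc_established": self.poc_established,
            "med": self.med,
            "mud": self.mud,
            "utility_estimates": arr(self.utility_estimates),
            "p_med": arr(self.p_med),
            "p_mud": arr(self.p_mud),
            "randomization": arr(self.randomization),
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def analyze(draws: PosteriorDraws, config: DesignConfig, final: bool = False) -> DoseDecision:
    """Run one full analysis and bundle the outputs.

    An interim analysis (default) computes the admissible set, target-dose
    probabilities and the randomization vector; a final analysis
    additionally tests proof-of-concept and, if established, selects the
    MED and MUD.
    """
    A = admissible_set(draws, config)
    decision = DoseDecision(admissible=A)
    decision.utility_estimates = _utility_draws(draws, config).mean(axis=0)
    if not A.empty:
        p1, p2 = target_dose_probabilities(draws, A, config)
        decision.p_med = p1
        decision.p_mud = p2
        decision.randomization = randomization_probabilities(p1, p2, A, config)
    if final:
        decision.poc_established = poc_test(draws, config)
        if decision.poc_established and not A.empty:
            decision.med = select_med(draws, A, config)
            decision.mud = select_mud(
                draws, A, config,
                min_dose=decision.med if config.require_mud_ge_med else None,
            )
    return decision


def admissible_set(draws: PosteriorDraws, config: DesignConfig) -> AdmissibleSet:
    """Screen doses 2..J by the safety and futility rules.

    Dose j stays admissible iff Pr(pi_j > pi_1 + pi_bar) < CT and
    Pr(mu_j <= mu_1) < CE, both estimated as draw proportions.
    """
    pi, mu = draws.pi, draws.mu
    unsafe = (pi[:, 1:] > pi[:, [0]] + config.pi_bar).mean(axis=0)
    futile = (mu[:, 1:] <= mu[:, [0]]).mean(axis=0)
    keep = (unsafe < config.ct) & (futile < config.ce)
    members = tuple(int(j) for j in np.nonzero(keep)[0] + 2)
    return AdmissibleSet(members, draws.n_arms)


def poc_statistic(draws: PosteriorDraws) -> float:
    """max_j Pr(mu_j > mu_1 | data) over treatment arms — the PoC statistic."""
    mu = draws.mu
    probs = (mu[:, 1:] > mu[:, [0]]).mean(axis=0)
    return float(probs.max())


def poc_test(draws: PosteriorDraws, config: DesignConfig) -> bool:
    """Proof-of-concept: some arm's Pr(mu_j > mu_1) exceeds the cutoff."""
    return poc_statistic(draws) > config.c_poc


def _utility_draws(draws: PosteriorDraws, config: DesignConfig) -> np.ndarray:
    u = config.utility
    return utility_extended(draws.mu, draws.pi, rho=u.rho, w1=u.w1, w2=u.w2)


def select_med(draws: PosteriorDraws, A: AdmissibleSet, config: DesignConfig) -> int | None:
    """MED: admissible dose whose posterior mean efficacy is closest to
    the placebo mean plus the clinically relevant difference."""
    if A.empty:
        return None
    mu_hat = draws.mu.mean(axis=0)
    target = mu_hat[0] + config.delta
    cols = A.indices0()
    return int(A.members[int(np.argmin(np.abs(mu_hat[cols] - target)))])


def select_mud(draws: PosteriorDraws, A: AdmissibleSet, config: DesignConfig,
               min_dose: int | None = None) -> int | None:
    """MUD: admissible dose maximizing the posterior-mean utility.

    ``min_dose`` optionally restricts the search to doses >= that index
    (used for the MUD >= MED variant); if no admissible dose satisfies the
    restriction it is ignored.
    """
    if A.empty:
        return None
    u_hat = _utility_draws(draws, config).mean(axis=0)
    members = A.members
    if min_dose is not None:
        restricted = tuple(j for j in members if j >= min_dose)
        if restricted:
            members = restricted
    cols = np.asarray(members, dtype=np.int64) - 1
    return int(members[int(np.argmax(u_hat[cols]))])


def target_dose_probabilities(
    draws: PosteriorDraws, A: AdmissibleSet, config: DesignConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior probabilities that each dose is the MED / the MUD.

    The MED and MUD selection rules are applied draw-by-draw, restricted
    to the admissible set; the returned length-J vectors are the draw
    proportions (zero outside A, each summing to 1 when A is nonempty).
    """
    J = draws.n_arms
    p1 = np.zeros(J)
    p2 = np.zeros(J)
    if A.empty:
        return p1, p2
    cols = A.indices0()
    mu, pi = draws.mu, draws.pi
    T = draws.n_draws

    dist = np.abs(mu[:, cols] - (mu[:, [0]] + config.delta))
    med_t = cols[np.argmin(dist, axis=1)]  # argmin takes the first (lowest dose) on ties

    util = _utility_draws(draws, config)[:, cols]
    mud_t = cols[np.argmax(util, axis=1)]

    p1[:] = np.bincount(med_t, minlength=J) / T
    p2[:] = np.bincount(mud_t, minlength=J) / T
    return p1, p2


def randomization_probabilities(
    p1: np.ndarray, p2: np.ndarray, A: AdmissibleSet, config: DesignConfig
) -> np.ndarray:
    """Adaptive randomization vector over all J arms.

    Admissible doses score tau*p1^nu + (1-tau)*p2^nu; the most-likely MED
    and most-likely MUD are each boosted to p_max (the largest entry among
    the target-dose probabilities, p1 only if tau = 1, p2 only if tau = 0);
    the control receives min(p_max, 1/(J-1)); scores are normalized.
    """
    if A.empty:
        raise ValueError("cannot randomize with an empty admissible set")
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    J = config.n_arms
    cols = A.indices0()

    scores = np.zeros(J)
    scores[cols] = config.tau * p1[cols] ** config.nu + (1.0 - config.tau) * p2[cols] ** config.nu

    if config.tau == 1.0:
        pmax = p1[cols].max()
    elif config.tau == 0.0:
        pmax = p2[cols].max()
    else:
        pmax = max(p1[cols].max(), p2[cols].max())

    if config.tau > 0.0:
        scores[cols[np.argmax(p1[cols])]] = pmax
    if config.tau < 1.0:
        scores[cols[np.argmax(p2[cols])]] = pmax
    scores[0] = min(pmax, 1.0 / (J - 1))

    total = scores.sum()
    if total <= 0:
        # degenerate (all target probabilities zero): equal among control + A
        scores[0] = 1.0
        scores[cols] = 1.0
        total = scores.sum()
    return scores / total
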