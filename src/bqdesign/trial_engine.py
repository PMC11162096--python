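"""Group-sequential conduct of a single adaptive dose-ranging trial.

Stage 1 randomizes equally across all arms.  At each subsequent stage the
posteriors are refreshed from all accumulated data, inadmissible doses are
dropped, and the stage's patients are randomized by independent
multinomial sampling from the adaptive randomization vector (frozen for
the stage).  If every treatment dose has been dropped the trial stops
early.  At the final analysis proof-of-concept is tested and, if
established, the MED and MUD are selected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json

import numpy as np

from .config import DesignConfig
from .data import TrialData
from .posteriors import sample_posterior
from .decisions import (
    AdmissibleSet,
    admissible_set,
    utility_extended,
    poc_statistic,
    select_med,
    select_mud,
    target_dose_probabilities,
    randomization_probabilities,
)

__all__ = ["TrialResult", "run_trial", "allocate_equally"]


@dataclass
class TrialResult:
    """Outcome of one simulated or conducted trial."""

    poc_established: bool
    med: int | None
    mud: int | None
    stopped_early: bool
    stop_stage: int | None
    enrollment: np.ndarray  # per-arm patient counts
    poc_stat: float  # max_j Pr(mu_j > mu_1) at the last analysis (0 if stopped)
    mu_hat: np.ndarray | None = None
    pi_hat: np.ndarray | None = None
    utility_hat: np.ndarray | None = None
    data: TrialData | None = None

    @property
    def n_enrolled(self) -> int:
        return int(self.enrollment.sum())

    def to_dict(self) -> dict:
        def arr(a):
            return None if a is None else [float(v) for v in a]

        return {
            "poc_established": self.poc_established,
            "med": self.med,
            "mud": self.mud,
            "stopped_early": self.stopped_early,
            "stop_stage": self.stop_stage,
            "enrollment": [int(v) for v in self.enrollment],
            "poc_stat": self.poc_stat,
            "mu_hat": arr(self.mu_hat),
            "pi_hat": arr(self.pi_hat),
            "utility_hat": arr(self.utility_hat),
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def allocate_equally(c: int, n_arms: int, rng: np.random.Generator) -> np.ndarray:
    """Split c patients over arms as evenly as possible.

    Every arm gets floor(c/J); the remainder goes to arms drawn uniformly
    without replacement, so counts differ by at most one.
    """
    if c <= 0 or n_arms <= 0:
        raise ValueError("c and n_arms must be positive")
    counts = np.full(n_arms, c // n_arms, dtype=np.int64)
    rem = c % n_arms
    if rem:
        counts[rng.choice(n_arms, size=rem, replace=False)] += 1
    return counts


def run_trial(
    outcome_source,
    config: DesignConfig,
    seed: int | np.random.SeedSequence | None = None,
    keep_data: bool = False,
) -> TrialResult:
    """Conduct one trial against an outcome source.

    ``outcome_source`` must expose
    ``draw_outcomes(dose_index, n, rng) -> (toxicity array, efficacy array)``
    (scenarios from :mod:`bqdesign.scenarios` do).  Outcome generation and
    posterior sampling consume two independent random streams derived from
    ``seed``, so the design's Monte-Carlo noise is isolated from the
    simulated patients' outcomes.
    """
    seq = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    design_ss, outcome_ss = seq.spawn(2)
    design_rng = np.random.default_rng(design_ss)
    outcome_rng = np.random.default_rng(outcome_ss)

    J = config.n_arms
    data = TrialData(J, config.endpoint_type, config.declared_bounds)
    enrollment = np.zeros(J, dtype=np.int64)

    def enroll(counts: np.ndarray) -> None:
        for j in range(J):
            if counts[j] == 0:
                continue
            tox, eff = outcome_source.draw_outcomes(j + 1, int(counts[j]), outcome_rng)
            data.add_arrays(np.full(counts[j], j + 1, dtype=np.int64), tox, eff)
        enrollment[:] += counts

    enroll(allocate_equally(config.stage_sizes[0], J, design_rng))

    for stage in range(2, config.n_stages + 1):
        draws = sample_posterior(data, config, rng=design_rng)
        A = admissible_set(draws, config)
        if A.empty:
            return TrialResult(
                poc_established=False, med=None, mud=None,
                stopped_early=True, stop_stage=stage - 1,
                enrollment=enrollment, poc_stat=0.0,
                data=data if keep_data else None,
            )
        p1, p2 = target_dose_probabilities(draws, A, config)
        probs = randomization_probabilities(p1, p2, A, config)
        counts = design_rng.multinomial(config.stage_sizes[stage - 1], probs)
        enroll(counts)

    draws = sample_posterior(data, config, rng=design_rng)
    A = admissible_set(draws, config)
    stat = poc_statistic(draws)
    poc = stat > config.c_poc
    med = mud = None
    if poc and not A.empty:
        med = select_med(draws, A, config)
        mud = select_mud(draws, A, config,
                         min_dose=med if config.require_mud_ge_med else None)
    u = config.utility
    return TrialResult(
        poc_established=poc,
        med=med,
        mud=mud,
        stopped_early=False,
        stop_stage=None,
        enrollment=enrollment,
        poc_stat=stat,
        mu_hat=draws.mu.mean(axis=0),
        pi_hat=draws.pi.mean(axis=0),
        utility_hat=utility_extended(draws.mu, draws.pi, rho=u.rho, w1=u.w1, w2=u.w2).mean(axis=0),
        data=data if keep_data else None,
    )
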