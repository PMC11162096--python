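"""Patient-level trial data and its per-dose sufficient statistics.

The design engine only ever touches the data through a handful of
sufficient statistics: per-dose patient counts ``n_j``, toxicity counts
``m_j``, the toxicity-stratified counts ``n_jk`` and standardized
pseudo-event sums ``s_jk``, and (for continuous endpoints) the observed
per-dose efficacy range used to map outcomes onto [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PatientRecord",
    "TrialData",
    "BetaParams",
    "read_patient_table",
]

ENDPOINT_TYPES = ("binary", "ordinal", "continuous")


@dataclass(frozen=True)
class PatientRecord:
    """A single patient's outcome: assigned dose, toxicity flag, efficacy value.

    ``dose_index`` is 1-based with dose 1 the placebo/control arm.
    """

    dose_index: int
    toxicity: int
    efficacy: float

    def __post_init__(self) -> None:
        if self.dose_index < 1:
            raise ValueError(f"dose_index must be >= 1, got {self.dose_index}")
        if self.toxicity not in (0, 1):
            raise ValueError(f"toxicity must be 0 or 1, got {self.toxicity}")


@dataclass
class BetaParams:
    """Parameters of a Beta distribution, used as prior/posterior for rates."""

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and self.beta > 0):
            raise ValueError(f"Beta parameters must be positive, got ({self.alpha}, {self.beta})")

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)

    @property
    def variance(self) -> float:
        s = self.alpha + self.beta
        return self.alpha * self.beta / (s * s * (s + 1.0))


class TrialData:
    """Accumulated patient-level outcomes for a J-arm trial.

    Parameters
    ----------
    n_arms
        Number of arms J (arm 1 is placebo/control).
    endpoint_type
        One of ``"binary"``, ``"ordinal"``, ``"continuous"``.
    declared_bounds
        Fixed endpoint boundaries for bounded endpoints (e.g. ``(0, 1)``
        for binary, ``(0, 4)`` for a five-level ordinal score). Ignored for
        continuous endpoints, whose standardization bounds are the per-dose
        observed minima/maxima.
    """

    def __init__(
        self,
        n_arms: int,
        endpoint_type: str = "continuous",
        declared_bounds: tuple[float, float] | None = None,
    ) -> None:
        if n_arms < 2:
            raise ValueError("a trial needs at least a control and one treatment arm")
        if endpoint_type not in ENDPOINT_TYPES:
            raise ValueError(f"endpoint_type must be one of {ENDPOINT_TYPES}")
        if endpoint_type in ("binary", "ordinal"):
            if declared_bounds is None:
                declared_bounds = (0.0, 1.0) if endpoint_type == "binary" else None
            if declared_bounds is None:
                raise ValueError("ordinal endpoints require declared_bounds")
            lo, hi = declared_bounds
            if not hi > lo:
                raise ValueError("declared_bounds must satisfy upper > lower")
        self.n_arms = int(n_arms)
        self.endpoint_type = endpoint_type
        self.declared_bounds = declared_bounds
        self._dose: list[np.ndarray] = []
        self._tox: list[np.ndarray] = []
        self._eff: list[np.ndarray] = []

    # -- accumulation -------------------------------------------------

    def add_records(self, records: Iterable[PatientRecord]) -> None:
        recs = list(records)
        if not recs:
            return
        self.add_arrays(
            np.array([r.dose_index for r in recs], dtype=np.int64),
            np.array([r.toxicity for r in recs], dtype=np.int64),
            np.array([r.efficacy for r in recs], dtype=np.float64),
        )

    def add_arrays(self, dose: np.ndarray, toxicity: np.ndarray, efficacy: np.ndarray) -> None:
        dose = np.asarray(dose, dtype=np.int64)
        toxicity = np.asarray(toxicity, dtype=np.int64)
        efficacy = np.asarray(efficacy, dtype=np.float64)
        if not (dose.shape == toxicity.shape == efficacy.shape):
            raise ValueError("dose, toxicity, efficacy must have identical shapes")
        if dose.size == 0:
            return
        if dose.min() < 1 or dose.max() > self.n_arms:
            raise ValueError("dose indices out of range")
        if not np.isin(toxicity, (0, 1)).all():
            raise ValueError("toxicity values must be 0/1")
        if self.declared_bounds is not None:
            lo, hi = self.declared_bounds
            if efficacy.min() < lo or efficacy.max() > hi:
                raise ValueError("efficacy outside declared bounds")
        self._dose.append(dose)
        self._tox.append(toxicity)
        self._eff.append(efficacy)

    # -- views ---------------------------------------------------------

    @property
    def n_patients(self) -> int:
        return int(sum(a.size for a in self._dose))

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        if not self._dose:
            z = np.zeros(0)
            return z.astype(np.int64), z.astype(np.int64), z
        return (
            np.concatenate(self._dose),
            np.concatenate(self._tox),
            np.concatenate(self._eff),
        )

    def to_frame(self) -> pd.DataFrame:
        dose, tox, eff = self.arrays()
        return pd.DataFrame(
            {
                "patient_id": np.arange(1, dose.size + 1),
                "dose_index": dose,
                "toxicity": tox,
                "efficacy": eff,
            }
        )

    # -- sufficient statistics -----------------------------------------

    def toxicity_counts(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-dose (n_j, m_j): patients treated and toxicities observed."""
        dose, tox, _ = self.arrays()
        J = self.n_arms
        n = np.bincount(dose - 1, minlength=J).astype(np.int64)
        m = np.bincount(dose - 1, weights=tox, minlength=J).astype(np.int64)
        return n, m

    def standardization_bounds(self) -> np.ndarray:
        """Per-dose (lower, upper) bounds of the [0,1] standardization map.

        Bounded endpoints use the declared boundaries at every dose.
        Continuous endpoints use the per-dose observed min/max; a dose with
        fewer than two distinct values falls back to the pooled observed
        min/max across all doses.  A still-degenerate pair (all observed
        values identical) is returned as-is and handled downstream.
        """
        J = self.n_arms
        if self.declared_bounds is not None:
            lo, hi = self.declared_bounds
            return np.tile([lo, hi], (J, 1)).astype(np.float64)
        dose, _, eff = self.arrays()
        bounds = np.empty((J, 2))
        if eff.size == 0:
            bounds[:] = (0.0, 1.0)
            return bounds
        pooled = (float(eff.min()), float(eff.max()))
        for j in range(J):
            y = eff[dose == j + 1]
            if y.size >= 2 and y.min() < y.max():
                bounds[j] = (y.min(), y.max())
            else:
                bounds[j] = pooled
        return bounds

    def efficacy_strata(self, bounds: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Per-dose, per-toxicity-stratum (n_jk, s_jk).

        Returns two (J, 2) arrays: patient counts ``n_jk`` and standardized
        pseudo-event sums ``s_jk`` (fractional for non-binary endpoints),
        with k indexing the toxicity outcome 0/1.
        """
        if bounds is None:
            bounds = self.standardization_bounds()
        dose, tox, eff = self.arrays()
        J = self.n_arms
        n_jk = np.zeros((J, 2), dtype=np.int64)
        s_jk = np.zeros((J, 2), dtype=np.float64)
        if dose.size == 0:
            return n_jk, s_jk
        span = bounds[:, 1] - bounds[:, 0]
        for j in range(J):
            at_j = dose == j + 1
            if span[j] > 0:
                y_star = (eff[at_j] - bounds[j, 0]) / span[j]
            else:
                # all observed efficacies identical trial-wide: uninformative
                y_star = np.full(np.count_nonzero(at_j), 0.5)
            t = tox[at_j]
            for k in (0, 1):
                sel = t == k
                n_jk[j, k] = int(sel.sum())
                s_jk[j, k] = float(y_star[sel].sum())
        return n_jk, s_jk


def read_patient_table(path, n_arms: int, endpoint_type: str = "continuous",
                       declared_bounds: tuple[float, float] | None = None,
                       sep: str | None = None) -> TrialData:
    """Load patient records from a delimited text table.

    The table must contain columns ``patient_id``, ``dose_index`` (1-based),
    ``toxicity`` and ``efficacy``; the separator is sniffed unless given.
    """
    df = pd.read_csv(path, sep=sep, engine="python")
    required = {"dose_index", "toxicity", "efficacy"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"patient table missing columns: {sorted(missing)}")
    data = TrialData(n_arms, endpoint_type, declared_bounds)
    data.add_arrays(
        df["dose_index"].to_numpy(),
        df["toxicity"].to_numpy(),
        df["efficacy"].to_numpy(dtype=float),
    )
    return data
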