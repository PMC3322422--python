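"""Age-related penetrance by Kaplan-Meier substitution.

Age at symptom onset stands in for survival time: affected carriers are
events at their onset age, unaffected carriers are censored at their last
known age.  Penetrance at age t is 1 - S(t) with S the product-limit
estimator, so it reads as the probability that a mutation carrier has
manifested disease by age t.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .io import Subject

__all__ = [
    "PenetranceCurve",
    "LogrankResult",
    "km_curve",
    "age_at_penetrance",
    "logrank_test",
    "onset_and_censor_ages",
    "penetrance_by_group",
]

logger = logging.getLogger(__name__)


@dataclass
class PenetranceCurve:
    """Product-limit penetrance curve over onset ages.

    ``event_ages`` are the sorted distinct onset ages; ``n_risk`` and
    ``d_events`` the at-risk and event counts at each; ``survival`` the KM
    survivor function S(t) evaluated at the event ages, ``penetrance`` its
    complement, and ``greenwood_var`` Greenwood's variance estimate of S(t).
    Censoring ages are kept for plotting tick marks.
    """

    event_ages: np.ndarray
    n_risk: np.ndarray
    d_events: np.ndarray
    survival: np.ndarray
    penetrance: np.ndarray
    greenwood_var: np.ndarray
    censor_marks: np.ndarray

    def survival_at(self, age: float) -> float:
        """S(age): step function, right-continuous, 1 before the first event."""
        idx = np.searchsorted(self.event_ages, age, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def penetrance_at(self, age: float) -> float:
        return 1.0 - self.survival_at(age)


def km_curve(
    onset_ages: Sequence[float], censor_ages: Sequence[float] = ()
) -> PenetranceCurve:
    """Kaplan-Meier curve with onset age substituted for survival time.

    At a tied event/censoring age the event is processed first (the censored
    subject remains in the risk set for that event age).
    """
    events = np.asarray(onset_ages, dtype=float)
    cens = np.asarray(censor_ages, dtype=float)
    if events.size == 0:
        raise ValueError("at least one onset event is required")
    if (events <= 0).any() or (cens.size and (cens <= 0).any()):
        raise ValueError("ages must be > 0")

    t = np.unique(events)
    d = np.array([(events == ti).sum() for ti in t], dtype=float)
    # at risk at t: events at ages >= t plus censored at ages >= t
    n = np.array(
        [(events >= ti).sum() + (cens >= ti).sum() for ti in t], dtype=float
    )
    frac = 1.0 - d / n
    surv = np.cumprod(frac)
    # Greenwood: Var[S(t)] = S(t)^2 * sum_{t_i<=t} d_i / (n_i (n_i - d_i));
    # once the curve hits 0 the summand diverges and the variance is set to 0
    terms = np.divide(
        d, n * (n - d), out=np.zeros_like(d), where=n > d
    )
    gw = surv**2 * np.cumsum(terms)
    gw[surv == 0.0] = 0.0
    return PenetranceCurve(
        event_ages=t,
        n_risk=n,
        d_events=d,
        survival=surv,
        penetrance=1.0 - surv,
        greenwood_var=gw,
        censor_marks=np.sort(cens),
    )


def age_at_penetrance(curve: PenetranceCurve, q: float) -> float | None:
    """Smallest event age at which penetrance reaches q; None if never."""
    if not 0 < q < 1:
        raise ValueError(f"q must be in (0, 1), got {q}")
    hit = np.nonzero(curve.penetrance >= q)[0]
    if hit.size == 0:
        return None
    return float(curve.event_ages[hit[0]])


@dataclass
class LogrankResult:
    statistic: float
    df: int
    p_value: float


def logrank_test(
    groups: Sequence[tuple[Sequence[float], Sequence[float]]],
) -> LogrankResult:
    """k-sample log-rank test over pooled onset ages.

    Each group is a ``(onset_ages, censor_ages)`` pair.  The statistic is the
    quadratic form of the observed-minus-expected event counts of the first
    k-1 groups against the hypergeometric covariance of the pooled risk
    sets, referred to chi-square with k-1 degrees of freedom.
    """
    k = len(groups)
    if k < 2:
        raise ValueError("log-rank test requires at least two groups")
    ev = [np.asarray(e, dtype=float) for e, _ in groups]
    ce = [np.asarray(c, dtype=float) for _, c in groups]
    if sum(e.size for e in ev) == 0:
        raise ValueError("at least one event is required")
    times = np.unique(np.concatenate([e for e in ev if e.size]))
    O = np.zeros(k)
    E = np.zeros(k)
    V = np.zeros((k, k))
    for t in times:
        n_g = np.array(
            [(e >= t).sum() + (c >= t).sum() for e, c in zip(ev, ce)],
            dtype=float,
        )
        d_g = np.array([(e == t).sum() for e in ev], dtype=float)
        n_tot = n_g.sum()
        d_tot = d_g.sum()
        if n_tot <= 0 or d_tot == 0:
            continue
        O += d_g
        E += d_tot * n_g / n_tot
        if n_tot > 1:
            factor = d_tot * (n_tot - d_tot) / (n_tot - 1) / n_tot**2
            V += factor * (np.diag(n_g * n_tot) - np.outer(n_g, n_g))
    z = (O - E)[:-1]
    v = V[:-1, :-1]
    stat = float(z @ np.linalg.pinv(v) @ z) if z.size else 0.0
    from scipy.stats import chi2

    return LogrankResult(
        statistic=stat, df=k - 1, p_value=float(chi2.sf(stat, k - 1))
    )


def onset_and_censor_ages(
    subjects: Iterable[Subject], carriers_only: bool = True
) -> tuple[list[float], list[float]]:
    """Split subjects into event (onset) and censoring (last-seen) ages.

    Affected subjects (ALS/FTD diagnosis) contribute their onset age as an
    event; unaffected subjects contribute their last known age as censoring.
    Subjects missing the relevant age are dropped listwise with a logged
    count.
    """
    events: list[float] = []
    cens: list[float] = []
    dropped = 0
    for s in subjects:
        if carriers_only and s.carrier is not True:
            continue
        if s.diagnosis in ("ALS", "FTD"):
            if s.age_onset_y is None:
                dropped += 1
            else:
                events.append(s.age_onset_y)
        else:
            if s.age_last_y is None:
                dropped += 1
            else:
                cens.append(s.age_last_y)
    if dropped:
        logger.info("penetrance: dropped %d subjects with missing ages", dropped)
    return events, cens


def penetrance_by_group(
    subjects: Sequence[Subject],
    by: str | None = None,
    carriers_only: bool = True,
) -> tuple[dict[str, PenetranceCurve], LogrankResult | None]:
    """Penetrance curves per level of a grouping field, with a log-rank test.

    ``by`` may be ``"familial"``, ``"diagnosis"`` or ``"sex"``; ``None``
    pools everyone into a single curve (no test).
    """
    if by is None:
        e, c = onset_and_censor_ages(subjects, carriers_only)
        return {"all": km_curve(e, c)}, None
    if by not in {"familial", "diagnosis", "sex"}:
        raise ValueError(f"unsupported grouping field {by!r}")
    levels: dict[str, list[Subject]] = {}
    for s in subjects:
        levels.setdefault(str(getattr(s, by)), []).append(s)
    curves = {}
    groups = []
    for level in sorted(levels):
        e, c = onset_and_censor_ages(levels[level], carriers_only)
        if e:
            curves[level] = km_curve(e, c)
            groups.append((e, c))
    test = logrank_test(groups) if len(groups) >= 2 else None
    return curves, test
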