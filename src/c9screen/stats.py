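"""Cohort frequency tables, exact binomial intervals and contingency tests."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist
from scipy.stats import chi2 as chi2_dist

from .io import Subject

__all__ = [
    "PropCI",
    "ChiSquareResult",
    "clopper_pearson",
    "frequency_table",
    "chi_square_test",
    "demographics_table",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PropCI:
    """Exact (Clopper-Pearson) binomial confidence interval for k of n."""

    k: int
    n: int
    conf: float
    lower: float
    upper: float

    @property
    def p_hat(self) -> float:
        return self.k / self.n


def clopper_pearson(k: int, n: int, conf: float = 0.95) -> PropCI:
    """Exact binomial confidence interval by inverting the binomial tails.

    The bounds are the beta quantiles ``Beta(alpha/2; k, n-k+1)`` and
    ``Beta(1-alpha/2; k+1, n-k)``, with the conventional endpoints lower=0
    when k=0 and upper=1 when k=n.  Coverage is conservative (>= conf).
    """
    if n < 1 or not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n with n >= 1, got k={k}, n={n}")
    if not 0 < conf < 1:
        raise ValueError("conf must be in (0, 1)")
    alpha = 1.0 - conf
    lower = 0.0 if k == 0 else float(beta_dist.ppf(alpha / 2, k, n - k + 1))
    upper = 1.0 if k == n else float(beta_dist.ppf(1 - alpha / 2, k + 1, n - k))
    return PropCI(k=int(k), n=int(n), conf=conf, lower=lower, upper=upper)


def frequency_table(
    subjects: Iterable[Subject],
    strata: Sequence[str],
    conf: float = 0.95,
) -> pd.DataFrame:
    """Carrier-frequency table by strata, with exact CIs and total rows.

    ``strata`` lists Subject fields (e.g. ``["region", "familial",
    "diagnosis"]``).  Subjects with unknown carrier status are excluded with
    a logged count.  A ``__total__`` row aggregates each table, so stratum
    carrier counts always sum to the total row.
    """
    if not strata:
        raise ValueError("at least one stratification field is required")
    rows = []
    excluded = 0
    for s in subjects:
        if s.carrier is None:
            excluded += 1
            continue
        rows.append(
            {f: str(getattr(s, f)) for f in strata} | {"carrier": s.carrier}
        )
    if excluded:
        logger.info("frequency_table: excluded %d subjects with unknown "
                    "carrier status", excluded)
    if not rows:
        raise ValueError("no subjects with known carrier status")
    df = pd.DataFrame(rows)
    grouped = (
        df.groupby(list(strata), sort=True)["carrier"]
        .agg(k="sum", n="count")
        .reset_index()
    )
    total = {f: "__total__" for f in strata} | {
        "k": int(df["carrier"].sum()),
        "n": int(len(df)),
    }
    grouped = pd.concat([grouped, pd.DataFrame([total])], ignore_index=True)
    cis = [clopper_pearson(int(r.k), int(r.n), conf) for r in grouped.itertuples()]
    grouped["p_hat"] = [ci.p_hat for ci in cis]
    grouped["ci_lower"] = [ci.lower for ci in cis]
    grouped["ci_upper"] = [ci.upper for ci in cis]
    return grouped


@dataclass
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float
    expected: np.ndarray
    low_expected: bool  # any expected cell count < 5
    yates: bool


def chi_square_test(table, yates: bool = True) -> ChiSquareResult:
    """Pearson chi-square test of independence on an r x c count table.

    Yates' continuity correction is applied to 2x2 tables only (default on,
    matching common practice for small counts); larger tables are always
    uncorrected.  A flag reports expected counts below 5.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("table must be at least 2x2")
    if (obs < 0).any() or not np.allclose(obs, np.round(obs)):
        raise ValueError("table must contain non-negative integer counts")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if (row == 0).any() or (col == 0).any():
        raise ValueError("every row and column margin must be > 0")
    expected = np.outer(row, col) / obs.sum()
    diff = np.abs(obs - expected)
    use_yates = yates and obs.shape == (2, 2)
    if use_yates:
        diff = np.maximum(diff - 0.5, 0.0)
    stat = float((diff**2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return ChiSquareResult(
        statistic=stat,
        df=df,
        p_value=float(chi2_dist.sf(stat, df)),
        expected=expected,
        low_expected=bool((expected < 5).any()),
        yates=use_yates,
    )


def _onset_summary(ages: list[float]) -> dict:
    if not ages:
        return {"onset_mean": None, "onset_min": None, "onset_max": None,
                "onset_sd": None, "onset_n": 0}
    a = np.asarray(ages)
    sd = float(a.std(ddof=1)) if a.size > 1 else 0.0
    return {
        "onset_mean": float(a.mean()),
        "onset_min": float(a.min()),
        "onset_max": float(a.max()),
        "onset_sd": sd,
        "onset_n": int(a.size),
    }


def demographics_table(subjects: Sequence[Subject]) -> pd.DataFrame:
    """Demographic/clinical summary by diagnosis x carrier status.

    For each (diagnosis, carrier) group: mean onset age with range and SD,
    male count and percentage, positive-family-history count and percentage,
    site-of-onset and FTD-presentation breakdowns, and per-field missing
    counts (percentages are of the non-missing denominator).
    """
    if not subjects:
        raise ValueError("no subjects")
    groups: dict[tuple[str, str], list[Subject]] = {}
    for s in subjects:
        if s.carrier is None or s.diagnosis == "control":
            continue
        key = (s.diagnosis, "carrier" if s.carrier else "non_carrier")
        groups.setdefault(key, []).append(s)
    rows = []
    for (dx, status), members in sorted(groups.items()):
        n = len(members)
        onset = [m.age_onset_y for m in members if m.age_onset_y is not None]
        sex_known = [m for m in members if m.sex != "unknown"]
        males = sum(m.sex == "male" for m in sex_known)
        fam = sum(m.familial for m in members)
        site_known = [m for m in members if m.onset_site is not None]
        pres_known = [m for m in members if m.ftd_presentation is not None]
        row = {
            "diagnosis": dx,
            "carrier_status": status,
            "n": n,
            **_onset_summary(onset),
            "onset_missing": n - len(onset),
            "male_k": males,
            "male_pct": 100 * males / len(sex_known) if sex_known else None,
            "sex_missing": n - len(sex_known),
            "familial_k": fam,
            "familial_pct": 100 * fam / n,
            "bulbar_k": sum(m.onset_site == "bulbar" for m in site_known),
            "limb_k": sum(m.onset_site == "limb" for m in site_known),
            "site_missing": n - len(site_known),
            "behavioural_k": sum(
                m.ftd_presentation == "behavioural" for m in pres_known
            ),
            "pnfa_k": sum(m.ftd_presentation == "pnfa" for m in pres_known),
            "semantic_k": sum(
                m.ftd_presentation == "semantic" for m in pres_known
            ),
            "presentation_missing": n - len(pres_known),
        }
        rows.append(row)
    return pd.DataFrame(rows)
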