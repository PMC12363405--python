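"""Clinical outcome statistics: contingency, Kaplan–Meier, log-rank, MH hazard ratio.

Implemented from first principles (sums over the pooled event-time table)
so every intermediate — at-risk counts, observed/expected events, the
hypergeometric variance — is available to the reporting layer:

* Fisher's exact test for 2x2 tables, two-sided by the minimum-likelihood
  rule (the sum of hypergeometric probabilities no larger than the observed
  table's).
* Product-limit (Kaplan–Meier) survival with events preceding censorings
  at tied times.
* Log-rank test: U = sum(O - E) over pooled event times with the
  hypergeometric variance, chi-square on 1 df.
* Mantel–Haenszel hazard ratio (O_A/E_A)/(O_B/E_B) with a log-scale CI.
* Reverse-censor Kaplan–Meier for median potential follow-up.
* Pearson product-moment correlation.

These feed the stratified reports linking early molecular response and MRD
to end-of-treatment response and progression-free survival.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

COHORT_COLUMNS = [
    "patient_id", "emr", "mrd_status", "eot_response",
    "pfs_months", "pfs_event", "os_months", "os_event",
    "baseline_hge_ml", "ldh_uln", "r_ipi",
]

RESPONSES = {"CMR", "PR", "PD/ED", "NA"}


def validate_cohort(df: pd.DataFrame) -> pd.DataFrame:
    """Schema-check a cohort table (see COHORT_COLUMNS) and coerce dtypes."""
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table missing columns: {missing}")
    bad = set(df["eot_response"]) - RESPONSES
    if bad:
        raise ValueError(f"unknown EOT response values: {sorted(bad)}")
    if (df["pfs_months"] < 0).any() or (df["os_months"] < 0).any():
        raise ValueError("negative survival times")
    out = df.copy()
    out["emr"] = out["emr"].astype(bool)
    out["pfs_event"] = out["pfs_event"].astype(bool)
    out["os_event"] = out["os_event"].astype(bool)
    return out


def read_cohort_csv(path) -> pd.DataFrame:
    # keep_default_na: the EOT response level "NA" is a category, not a null
    return validate_cohort(pd.read_csv(path, keep_default_na=False, na_values=[""]))


# ---------------------------------------------------------------------------
# contingency & correlation
# ---------------------------------------------------------------------------


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Two-sided Fisher exact test; returns (p-value, odds ratio).

    The two-sided p sums hypergeometric probabilities, at fixed margins, of
    every table whose probability does not exceed the observed one.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a 2x2 table of non-negative counts")
    a, b = t[0]
    c, d = t[1]
    n = a + b + c + d
    r1, c1 = a + b, a + c
    if min(r1, c1, n - r1, n - c1) < 0 or n == 0 or r1 == 0 or c1 == 0 or r1 == n or c1 == n:
        raise ValueError("degenerate margins")
    support = np.arange(max(0, r1 + c1 - n), min(r1, c1) + 1)
    pmf = stats.hypergeom.pmf(support, n, r1, c1)
    p_obs = stats.hypergeom.pmf(a, n, r1, c1)
    p = float(pmf[pmf <= p_obs * (1 + 1e-9)].sum())
    odds = (a * d) / (b * c) if b * c > 0 else np.inf
    return min(p, 1.0), float(odds)


def pearson_r(x, y) -> float:
    """Pearson product-moment correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired vectors of length >= 3")
    xm, ym = x - x.mean(), y - y.mean()
    sx, sy = np.sqrt((xm**2).sum()), np.sqrt((ym**2).sum())
    if sx == 0 or sy == 0:
        raise ValueError("zero variance")
    return float((xm * ym).sum() / (sx * sy))


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------


@dataclass
class SurvivalFit:
    """Product-limit estimate: step function over distinct event times."""

    event_times: np.ndarray  # distinct times with >= 1 event
    at_risk: np.ndarray
    events: np.ndarray
    survival: np.ndarray  # S(t) just after each event time
    n: int

    def survival_at(self, t: float) -> float:
        """S(t); 1 before the first event."""
        idx = np.searchsorted(self.event_times, t, side="right")
        return 1.0 if idx == 0 else float(self.survival[idx - 1])

    @property
    def median(self) -> float:
        """First time where S(t) <= 0.5; NaN when never reached."""
        below = np.flatnonzero(self.survival <= 0.5 + 1e-12)
        return float(self.event_times[below[0]]) if len(below) else float("nan")


def km_fit(times, events) -> SurvivalFit:
    """Kaplan–Meier product-limit estimator.

    Ties are handled with events before censorings at equal times: subjects
    censored at t remain at risk for events at t.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if len(times) == 0 or len(times) != len(events):
        raise ValueError("need equal-length non-empty times and event flags")
    if (times < 0).any():
        raise ValueError("negative times")
    et = np.unique(times[events])
    at_risk = np.array([(times >= t).sum() for t in et], dtype=np.int64)
    d = np.array([((times == t) & events).sum() for t in et], dtype=np.int64)
    surv = np.cumprod(1.0 - d / at_risk) if len(et) else np.zeros(0)
    return SurvivalFit(et, at_risk, d, surv, n=len(times))


def _pooled_oe(times_a, events_a, times_b, events_b):
    """Observed/expected events and hypergeometric variance per pooled event time."""
    ta = np.asarray(times_a, dtype=float)
    ea = np.asarray(events_a, dtype=bool)
    tb = np.asarray(times_b, dtype=float)
    eb = np.asarray(events_b, dtype=bool)
    all_t = np.concatenate([ta, tb])
    all_e = np.concatenate([ea, eb])
    et = np.unique(all_t[all_e])
    O_a = E_a = O_b = E_b = V = 0.0
    for t in et:
        n_a = float((ta >= t).sum())
        n_b = float((tb >= t).sum())
        n = n_a + n_b
        if n_a == 0 or n_b == 0:
            # only one group at risk: no information in this table
            d_a = float(((ta == t) & ea).sum())
            d_b = float(((tb == t) & eb).sum())
            O_a += d_a
            O_b += d_b
            E_a += d_a if n_b == 0 else 0.0
            E_b += d_b if n_a == 0 else 0.0
            continue
        d_a = float(((ta == t) & ea).sum())
        d_b = float(((tb == t) & eb).sum())
        d = d_a + d_b
        O_a += d_a
        O_b += d_b
        E_a += d * n_a / n
        E_b += d * n_b / n
        if n > 1:
            V += d * (n_a / n) * (n_b / n) * (n - d) / (n - 1)
    return O_a, E_a, O_b, E_b, V


def logrank_test(times_a, events_a, times_b, events_b) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p-value)."""
    O_a, E_a, O_b, E_b, V = _pooled_oe(times_a, events_a, times_b, events_b)
    if O_a + O_b == 0 or V <= 0:
        if O_a + O_b == 0:
            warnings.warn("no events in either group; log-rank p = 1")
        return 0.0, 1.0
    chi2 = (O_a - E_a) ** 2 / V
    return float(chi2), float(stats.chi2.sf(chi2, 1))


def mh_hazard_ratio(
    times_a, events_a, times_b, events_b, conf: float = 0.95
) -> tuple[float, tuple[float, float]]:
    """Mantel–Haenszel hazard ratio (group A vs B) with log-scale CI.

    HR = (O_A/E_A) / (O_B/E_B); the CI uses se(log HR) = sqrt(1/E_A + 1/E_B).
    With zero events in one group the point estimate degenerates to 0 or
    inf and a one-sided interval is returned with a warning.
    """
    O_a, E_a, O_b, E_b, V = _pooled_oe(times_a, events_a, times_b, events_b)
    z = stats.norm.ppf(0.5 + conf / 2)
    if E_a <= 0 or E_b <= 0:
        warnings.warn("a group contributes no expected events; HR undefined")
        return float("nan"), (float("nan"), float("nan"))
    se = np.sqrt(1.0 / E_a + 1.0 / E_b)
    if O_a == 0 or O_b == 0:
        warnings.warn("zero observed events in one group; one-sided CI")
        if O_a == 0:
            hr_up = ((O_a + 0.5) / E_a) / ((O_b - 0.5) / E_b) if O_b > 0.5 else np.inf
            return 0.0, (0.0, float(hr_up * np.exp(z * se)))
        hr_lo = ((O_a - 0.5) / E_a) / ((O_b + 0.5) / E_b)
        return float("inf"), (float(hr_lo * np.exp(-z * se)), float("inf"))
    hr = (O_a / E_a) / (O_b / E_b)
    return float(hr), (float(hr * np.exp(-z * se)), float(hr * np.exp(z * se)))


def reverse_km_followup(times, events) -> float:
    """Median potential follow-up: KM median with the censor flag inverted."""
    events = np.asarray(events, dtype=bool)
    return km_fit(times, ~events).median


# ---------------------------------------------------------------------------
# stratified reporting
# ---------------------------------------------------------------------------

STRATIFIERS = ("emr", "mrd", "baseline_burden", "r_ipi")
BURDEN_SPLIT_LOG10 = 2.5


def _strata(cohort: pd.DataFrame, stratifier: str) -> tuple[pd.Series, str, str]:
    if stratifier == "emr":
        return cohort["emr"], "EMR", "no EMR"
    if stratifier == "mrd":
        return cohort["mrd_status"].eq("positive"), "MRD+", "MRD-"
    if stratifier == "baseline_burden":
        high = np.log10(cohort["baseline_hge_ml"].clip(lower=1e-12)) >= BURDEN_SPLIT_LOG10
        return high, f">= {BURDEN_SPLIT_LOG10} log10 hGE/mL", "below"
    if stratifier == "r_ipi":
        return cohort["r_ipi"].eq("poor"), "R-IPI poor", "R-IPI good"
    raise ValueError(f"unknown stratifier {stratifier!r}")


def stratify_and_report(cohort: pd.DataFrame, stratifier: str = "emr") -> dict:
    """One analysis bundle for a stratified cohort.

    Emits the stratum x CMR contingency table with Fisher's exact test
    (EOT-NA patients are excluded from the contingency, as response is
    unassessable), per-stratum KM fits of PFS, the log-rank p, the MH
    hazard ratio, and 24-month survival estimates.  Comparisons with an
    empty stratum are skipped with a warning.
    """
    cohort = validate_cohort(cohort)
    flag, name_a, name_b = _strata(cohort, stratifier)
    ga, gb = cohort[flag], cohort[~flag]
    out: dict = {"stratifier": stratifier, "groups": (name_a, name_b),
                 "n": (len(ga), len(gb))}
    if len(ga) < 2 or len(gb) < 2:
        warnings.warn(f"stratum with < 2 patients; {stratifier} comparisons skipped")
        out["skipped"] = True
        return out

    evaluable = cohort[cohort["eot_response"] != "NA"]
    fa, _, _ = _strata(evaluable, stratifier)
    ea, eb = evaluable[fa], evaluable[~fa]
    tab = np.array(
        [
            [int((ea["eot_response"] == "CMR").sum()), int((ea["eot_response"] != "CMR").sum())],
            [int((eb["eot_response"] == "CMR").sum()), int((eb["eot_response"] != "CMR").sum())],
        ]
    )
    out["cmr_table"] = tab
    out["cmr_rate"] = (
        tab[0, 0] / tab[0].sum() if tab[0].sum() else float("nan"),
        tab[1, 0] / tab[1].sum() if tab[1].sum() else float("nan"),
    )
    try:
        out["fisher_p"], out["odds_ratio"] = fisher_exact_2x2(tab)
    except ValueError:
        out["fisher_p"], out["odds_ratio"] = float("nan"), float("nan")

    fit_a = km_fit(ga["pfs_months"], ga["pfs_event"])
    fit_b = km_fit(gb["pfs_months"], gb["pfs_event"])
    chi2, p = logrank_test(ga["pfs_months"], ga["pfs_event"], gb["pfs_months"], gb["pfs_event"])
    hr, ci = mh_hazard_ratio(ga["pfs_months"], ga["pfs_event"], gb["pfs_months"], gb["pfs_event"])
    out.update(
        {
            "km": (fit_a, fit_b),
            "logrank_chi2": chi2,
            "logrank_p": p,
            "hazard_ratio": hr,
            "hazard_ratio_ci": ci,
            "pfs_24m": (fit_a.survival_at(24.0), fit_b.survival_at(24.0)),
            "median_pfs": (fit_a.median, fit_b.median),
            "median_followup": reverse_km_followup(cohort["os_months"], cohort["os_event"]),
        }
    )
    return out
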