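"""Actuarial relative-survival engine with cohort and period analysis.

Follow-up is divided into annual intervals ``j = 1..k`` on the half-open
scale ``[j-1, j)`` years since diagnosis.  For each interval the engine
tabulates the classical life-table quantities — numbers at risk at the
interval start, late entrants (period analysis only), deaths, and
withdrawals — and computes:

* conditional observed survival by the actuarial estimator
  ``p_j = 1 - d_j / n'_j`` with effective denominator
  ``n'_j = n_j + e_j/2 - c_mid_j/2`` (mid-interval withdrawals and late
  entrants both take half weight; withdrawals at exactly the interval end
  were exposed for the whole interval and keep full weight);
* conditional expected survival by the Ederer II method: the mean of the
  population life-table annual survival probabilities over the patients at
  risk at the interval start, with the same half weights;
* cumulative observed, expected, and relative survival
  ``R_j = S_j / S*_j`` (never capped at 1);
* Greenwood standard errors,
  ``Var(S_k) = S_k^2 * sum_j d_j / (n'_j (n'_j - d_j))`` and
  ``se(R_k) = se(S_k) / S*_k``.

Period analysis restricts each patient's person-time to a recent calendar
window (left truncation at the window opening, censoring at its close), so
the estimates reflect the survival experience of that window rather than of
old diagnosis cohorts.  The window ``[start, end]`` covers calendar time
``[start-01-01, (end+1)-01-01)``; diagnosis dates are placed mid-month.

Survival times arrive as whole months.  A death in follow-up month ``m`` is
dated mid-month, ``(m - 0.5)/12`` years — within follow-up year
``ceil(m/12)``, so a death recorded at an exact year boundary (m = 12j)
belongs to the earlier interval j, and month-grid death dates compare
symmetrically against the continuous calendar edges of a period window.
Censoring times are completed months, ``m/12``; a withdrawal at exactly an
interval boundary was exposed for the whole interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import PatientRecord, records_to_frame
from .lifetable import MAX_AGE, PopulationLifeTable

# -- domain types ----------------------------------------------------------


@dataclass
class AnalysisWindow:
    """Analysis mode plus the calendar years it covers.

    ``mode='cohort'`` follows patients *diagnosed* in [start, end] from
    diagnosis; ``mode='period'`` keeps the person-time of any patient that
    falls inside the calendar window, with delayed entry.  ``k`` is the
    number of annual follow-up intervals (5 for 5-year survival).
    """

    mode: str
    start: int
    end: int
    k: int = 5

    def __post_init__(self) -> None:
        if self.mode not in ("period", "cohort"):
            raise ValueError(f"unknown analysis mode {self.mode!r}")
        if self.start > self.end:
            raise ValueError("window start after end")
        if self.k < 1:
            raise ValueError("k must be >= 1")

    @property
    def close(self) -> float:
        """Exclusive calendar upper edge: Jan 1 of the year after ``end``."""
        return float(self.end + 1)

    @property
    def label(self) -> str:
        return f"{self.start}-{self.end}"


@dataclass
class RiskSetTable:
    """Per-interval life-table counts for one cohort and window.

    ``withdrawals`` counts every censoring in the interval;
    ``withdrawals_at_end`` is the subset censored exactly at the interval
    boundary (fully exposed, so not down-weighted in ``eff_n``).
    """

    k: int
    n: np.ndarray  # at risk at interval start
    entrants: np.ndarray  # late entries during interval (period mode)
    deaths: np.ndarray
    withdrawals: np.ndarray
    withdrawals_at_end: np.ndarray
    expected_p: np.ndarray  # Ederer II conditional expected survival
    flags: list[str] = field(default_factory=list)

    @property
    def eff_n(self) -> np.ndarray:
        mid = self.withdrawals - self.withdrawals_at_end
        return self.n + self.entrants / 2.0 - mid / 2.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "interval": np.arange(1, self.k + 1),
            "n": self.n, "entrants": self.entrants, "deaths": self.deaths,
            "withdrawals": self.withdrawals,
            "withdrawals_at_end": self.withdrawals_at_end,
            "eff_n": self.eff_n, "expected_p": self.expected_p,
        })


@dataclass
class SurvivalEstimate:
    """Conditional and cumulative observed/expected/relative survival."""

    k: int
    p: np.ndarray  # conditional observed survival per interval
    pstar: np.ndarray  # conditional expected survival (Ederer II)
    S: np.ndarray  # cumulative observed
    Sstar: np.ndarray  # cumulative expected
    se_S: np.ndarray  # Greenwood SE of S
    eff_n: np.ndarray
    deaths: np.ndarray
    flags: list[str] = field(default_factory=list)

    @property
    def r(self) -> np.ndarray:
        """Conditional (interval) relative survival, uncapped."""
        return self.p / self.pstar

    @property
    def R(self) -> np.ndarray:
        """Cumulative relative survival, uncapped."""
        return self.S / self.Sstar

    @property
    def se_R(self) -> np.ndarray:
        return self.se_S / self.Sstar

    def defined(self, k: int | None = None) -> bool:
        k = self.k if k is None else k
        return bool(np.all(np.isfinite(self.p[:k])))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "interval": np.arange(1, self.k + 1),
            "p": self.p, "pstar": self.pstar, "r": self.r,
            "S": self.S, "Sstar": self.Sstar, "R": self.R,
            "se_S": self.se_S, "se_R": self.se_R,
            "eff_n": self.eff_n,
        })


# -- person-time ------------------------------------------------------------

def _to_arrays(patients) -> dict[str, np.ndarray]:
    if isinstance(patients, pd.DataFrame):
        df = patients
    else:
        df = records_to_frame(list(patients))
    if len(df) == 0:
        return {"n": 0}
    dx_month = pd.to_numeric(df["dx_month"], errors="coerce").to_numpy(float)
    frac = np.where(np.isnan(dx_month), 0.5, (dx_month - 0.5) / 12.0)
    dx_year = df["dx_year"].to_numpy(int)
    dead = (df["vital_status"] == "dead").to_numpy()
    months = df["survival_months"].to_numpy(float)
    # deaths dated mid-month within the fatal month; censorings at the
    # completed month
    t = np.where(dead, (months - 0.5) / 12.0, months / 12.0)
    return {
        "n": len(df),
        "dx_year": dx_year,
        "dx_date": dx_year + frac,
        "t": t,
        "dead": dead,
        "age": df["age_dx"].to_numpy(int),
        "sex": df["sex"].to_numpy(object),
        "race": df["race"].to_numpy(object),
    }


def person_time(patients, window: AnalysisWindow):
    """(entry, exit, dies) follow-up triples of the contributing patients.

    Entry and exit are in years since diagnosis, already intersected with
    the calendar window (period mode), capped at ``k`` years, with deaths
    kept only when the death date falls inside the window and before the
    cap.  Returns the triples plus the positional index of each
    contributing patient in the input.
    """
    arr = _to_arrays(patients)
    if arr["n"] == 0:
        return (np.empty(0), np.empty(0), np.empty(0, bool),
                np.empty(0, int), arr)
    t, dead, dx_date = arr["t"], arr["dead"], arr["dx_date"]
    k = float(window.k)

    if window.mode == "cohort":
        in_scope = (arr["dx_year"] >= window.start) & (arr["dx_year"] <= window.end)
        entry = np.zeros(arr["n"])
        exit_ = np.minimum(t, k)
        dies = dead & (t <= k)
    else:
        in_scope = np.ones(arr["n"], bool)
        entry = np.maximum(0.0, window.start - dx_date)
        window_exit = window.close - dx_date
        exit_ = np.minimum.reduce([t, window_exit, np.full(arr["n"], k)])
        dies = dead & (t < window_exit) & (t <= k)

    keep = in_scope & (exit_ > entry)
    idx = np.flatnonzero(keep)
    return entry[idx], exit_[idx], dies[idx], idx, arr


# -- risk sets ---------------------------------------------------------------

def build_risk_sets(
    patients, window: AnalysisWindow, lifetable: PopulationLifeTable
) -> RiskSetTable:
    """Tabulate annual risk sets and Ederer II expected survival."""
    entry, exit_, dies, idx, arr = person_time(patients, window)
    k = window.k
    n = np.zeros(k)
    e = np.zeros(k)
    d = np.zeros(k)
    c = np.zeros(k)
    c_end = np.zeros(k)
    pstar = np.full(k, np.nan)
    flags: list[str] = []

    if len(idx) == 0:
        flags.append("empty: no person-time intersects the window")
        return RiskSetTable(k, n, e, d, c, c_end, pstar, flags)

    age = arr["age"][idx]
    dx_date = arr["dx_date"][idx]
    sex = arr["sex"][idx]
    race = arr["race"][idx]
    combo_codes, combo_keys = pd.factorize(
        pd.Series(sex).astype(str) + "\x1f" + pd.Series(race).astype(str)
    )
    combo_pairs = [tuple(s.split("\x1f")) for s in combo_keys]

    for j in range(1, k + 1):
        at_start = (entry <= j - 1) & (exit_ > j - 1)
        entrant = (entry > j - 1) & (entry <= j)
        leaves = (exit_ > j - 1) & (exit_ <= j)
        death_j = leaves & dies
        censor_j = leaves & ~dies
        censor_end = censor_j & (exit_ == j)
        censor_mid = censor_j & ~censor_end

        n[j - 1] = at_start.sum()
        e[j - 1] = entrant.sum()
        d[j - 1] = death_j.sum()
        c[j - 1] = censor_j.sum()
        c_end[j - 1] = censor_end.sum()

        # Ederer II: weighted mean of population annual survival over the
        # at-risk set, mirroring the actuarial denominator weights.
        w = at_start * 1.0 + entrant * 0.5 - censor_mid * 0.5
        active = w > 0
        wsum = w[active].sum()
        if wsum > 0:
            att_age = np.minimum(age + (j - 1), MAX_AGE)
            att_year = np.floor(dx_date + (j - 1)).astype(int)
            p_pop = np.zeros(len(w))
            for g, (sx, rc) in enumerate(combo_pairs):
                m = active & (combo_codes == g)
                if m.any():
                    p_pop[m] = lifetable.lookup(att_age[m], att_year[m], sx, rc)
            pstar[j - 1] = float(np.sum(w[active] * p_pop[active]) / wsum)
        else:
            flags.append(f"interval {j}: empty at-risk set")

    return RiskSetTable(k, n, e, d, c, c_end, pstar, flags)


def conditional_observed_survival(rs: RiskSetTable, j: int) -> float:
    """Actuarial conditional survival ``1 - d_j/n'_j`` for interval j (1-based)."""
    nprime = rs.eff_n[j - 1]
    if nprime <= 0:
        return float("nan")
    return 1.0 - rs.deaths[j - 1] / nprime


def ederer2_conditional_expected(at_risk, lifetable: PopulationLifeTable) -> float:
    """Weighted mean population survival over an at-risk set.

    ``at_risk`` is an iterable of ``(age, year, sex, race)`` or
    ``(age, year, sex, race, weight)`` tuples; patients entering or
    withdrawing mid-interval carry weight 0.5, everyone else 1.
    """
    num = den = 0.0
    for item in at_risk:
        if len(item) == 5:
            age, year, sex, race, w = item
        else:
            (age, year, sex, race), w = item, 1.0
        num += w * lifetable.lookup(age, year, sex, race)
        den += w
    if den <= 0:
        return float("nan")
    return num / den


def compute_estimate(rs: RiskSetTable) -> SurvivalEstimate:
    """Conditional/cumulative survival with Greenwood errors from risk sets."""
    k = rs.k
    eff_n = rs.eff_n
    p = np.where(eff_n > 0, 1.0 - rs.deaths / np.where(eff_n > 0, eff_n, 1.0),
                 np.nan)
    flags = list(rs.flags)
    for j in np.flatnonzero(~(eff_n > 0)):
        flags.append(f"interval {j + 1}: effective denominator <= 0")

    S = np.cumprod(p)
    Sstar = np.cumprod(rs.expected_p)

    # Greenwood variance terms; undefined where n' - d <= 0 with deaths
    denom = eff_n * (eff_n - rs.deaths)
    term = np.where(rs.deaths > 0,
                    np.where(denom > 0, rs.deaths / np.where(denom > 0, denom, 1.0),
                             np.nan),
                    0.0)
    for j in np.flatnonzero(np.isnan(term)):
        flags.append(f"interval {j + 1}: Greenwood variance undefined")
    se_S = S * np.sqrt(np.cumsum(term))

    return SurvivalEstimate(
        k=k, p=p, pstar=rs.expected_p, S=S, Sstar=Sstar, se_S=se_S,
        eff_n=eff_n, deaths=rs.deaths, flags=flags,
    )


def cumulative_relative_survival(est: SurvivalEstimate, k: int) -> float:
    """``R_k = S_k / S*_k``; NaN (with flags on the estimate) if undefined."""
    if not est.defined(k):
        return float("nan")
    return float(est.R[k - 1])


def greenwood_se(rs: RiskSetTable, k: int) -> tuple[float, float]:
    """(se of S_k, se of R_k) by the Greenwood formula."""
    est = compute_estimate(rs)
    return float(est.se_S[k - 1]), float(est.se_R[k - 1])


def estimate_survival(
    patients, window: AnalysisWindow, lifetable: PopulationLifeTable
) -> SurvivalEstimate:
    """Risk sets plus survival estimate in one call."""
    return compute_estimate(build_risk_sets(patients, window, lifetable))
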