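"""Independent brute-force oracles and random mini-cohort generators.

The risk-set oracle re-derives every life-table count per patient and per
interval directly from the definitions, in pure Python, with no shared code
with the vectorised engine.
"""

from __future__ import annotations

import random

from periodsurv.cohort import PatientRecord


def patient_person_time(rec: PatientRecord, window) -> tuple[float, float, bool] | None:
    """(entry, exit, dies) in follow-up years, or None if non-contributing."""
    dx = rec.dx_year + ((rec.dx_month - 0.5) / 12.0 if rec.dx_month else 0.5)
    dead = rec.vital_status == "dead"
    t = (rec.survival_months - 0.5) / 12.0 if dead else rec.survival_months / 12.0
    k = float(window.k)
    if window.mode == "cohort":
        if not (window.start <= rec.dx_year <= window.end):
            return None
        entry = 0.0
        exit_ = min(t, k)
        dies = dead and t <= k
    else:
        wclose = window.end + 1.0
        entry = max(0.0, window.start - dx)
        exit_ = min(t, wclose - dx, k)
        dies = dead and t < wclose - dx and t <= k
    if exit_ <= entry:
        return None
    return entry, exit_, dies


def oracle_risk_sets(records, window) -> dict[str, list[float]]:
    """Interval bucketing by explicit per-patient membership checks."""
    triples = [pt for rec in records
               if (pt := patient_person_time(rec, window)) is not None]
    out = {key: [0.0] * window.k
           for key in ("n", "entrants", "deaths", "withdrawals",
                       "withdrawals_at_end")}
    for j in range(1, window.k + 1):
        for entry, exit_, dies in triples:
            if entry <= j - 1 < exit_:
                out["n"][j - 1] += 1
            if j - 1 < entry <= j:
                out["entrants"][j - 1] += 1
            if j - 1 < exit_ <= j:
                if dies:
                    out["deaths"][j - 1] += 1
                else:
                    out["withdrawals"][j - 1] += 1
                    if exit_ == j:
                        out["withdrawals_at_end"][j - 1] += 1
    return out


def random_mini_cohort(rng: random.Random, n_max: int = 20,
                       races=("white", "black")) -> list[PatientRecord]:
    """Small random cohort exercising every person-time edge case."""
    n = rng.randint(1, n_max)
    recs = []
    for i in range(n):
        dead = rng.random() < 0.5
        recs.append(PatientRecord(
            id=f"r{i}",
            sex=rng.choice(["male", "female"]),
            race=rng.choice(list(races)),
            age_dx=rng.randint(16, 95),
            dx_year=rng.randint(2000, 2018),
            dx_month=rng.choice([None] + list(range(1, 13))),
            survival_months=rng.randint(0, 250),
            vital_status="dead" if dead else "alive",
        ))
    return recs
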