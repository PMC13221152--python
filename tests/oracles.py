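"""Independent oracles used by the test suite.

These deliberately re-derive results through different representations
than the library: integer day-grid simulation for exposure periods, and
factorial-table hypergeometric enumeration for Fisher's exact test.
"""

from __future__ import annotations

import math

# covered-days table used by the oracle, independent of the catalog object
ORACLE_DAYS_PER_UNIT = {"G03AA12": 28, "G03AC09": 28, "G03AC03": 35}
ORACLE_IUD_DAYS = {"13.5 mg": 1095, "19.5 mg": 1835, "52 mg": 2190}


def oracle_covered_days(key: str, dosage: float, label=None) -> int:
    if key == "G02BA03":
        return ORACLE_IUD_DAYS[label]
    if key == "G03AC08":
        return 1095
    return int(math.floor(dosage * ORACLE_DAYS_PER_UNIT[key] + 0.5))


def day_grid_periods(purchases, gap_days=90, horizon=None, pregnancy_days=()):
    """Day-by-day coverage simulation on an integer day grid.

    ``purchases``: iterable of ``(day, key, covered_days)``; same-day
    purchases of the same formulation accumulate coverage.  Returns a list
    of ``(key, start_day, end_day, censor)`` with censor in
    {"none", "formulation_switch", "study_end", "pregnancy"}.
    """
    events: dict[int, list] = {}
    for day, key, cd in purchases:
        events.setdefault(day, []).append((key, cd))
    if not events:
        return []
    last_day = max(events)

    raw = []
    cur_key = None
    cur_start = covered_until = last_purchase = -1
    for day in range(0, last_day + 1):
        for key, cd in events.get(day, []):
            if cur_key is None:
                cur_key, cur_start, covered_until, last_purchase = key, day, day + cd - 1, day
            elif key == cur_key and day == last_purchase:
                covered_until += cd
            elif key == cur_key and day - last_purchase < gap_days:
                covered_until, last_purchase = day + cd - 1, day
            elif key == cur_key:
                raw.append([cur_key, cur_start, covered_until, "none"])
                cur_key, cur_start, covered_until, last_purchase = key, day, day + cd - 1, day
            else:
                if day - 1 < covered_until:
                    raw.append([cur_key, cur_start, max(cur_start, day - 1), "formulation_switch"])
                else:
                    raw.append([cur_key, cur_start, covered_until, "none"])
                cur_key, cur_start, covered_until, last_purchase = key, day, day + cd - 1, day
    raw.append([cur_key, cur_start, covered_until, "none"])

    if horizon is not None:
        for p in raw:
            if p[2] > horizon and p[3] == "none":
                p[2], p[3] = max(p[1], horizon), "study_end"

    preg = sorted(pregnancy_days)
    for p in raw:
        for d in preg:
            if p[1] <= d <= p[2]:
                p[2], p[3] = d, "pregnancy"
                break
    return [tuple(p) for p in raw]


def fisher_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Exact two-sided Fisher p via N!/(a!b!c!d!) weight enumeration.

    Enumerates every table with the observed margins; weights are exact
    integers so tie handling is unambiguous.
    """
    r1, r2, c1 = a + b, c + d, a + c
    n = a + b + c + d
    f = [math.factorial(k) for k in range(n + 1)]

    def weight(x):
        # proportional to the hypergeometric probability of table
        # (x, r1-x, c1-x, r2-(c1-x))
        return f[n] // (f[x] * f[r1 - x] * f[c1 - x] * f[r2 - c1 + x])

    w_obs = weight(a)
    num = tot = 0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        w = weight(x)
        tot += w
        if w <= w_obs:
            num += w
    return num / tot
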