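"""Independent oracles used by the test suite.

These deliberately avoid the implementation's code paths: the timestamp
oracle is a split-and-check parser (the validator uses a single regular
expression) and the edit-distance oracle is the memoized textbook
recursion (the implementation uses a C alignment library).
"""

from __future__ import annotations

import functools
import random

_MONTHS = {"jan", "feb", "mar", "apr", "may", "jun", "jul", "aug", "sep", "oct", "nov", "dec"}


def _ascii_digits(s: str) -> bool:
    return bool(s) and all("0" <= c <= "9" for c in s)


def oracle_timestamp(value: str) -> bool:
    """Split-based check of the accepted date/timestamp forms."""
    s = value.strip()

    def year(t: str) -> bool:
        return _ascii_digits(t) and len(t) == 4

    def day_free(t: str) -> bool:  # 1-2 digits, 1..31
        return _ascii_digits(t) and len(t) in (1, 2) and 1 <= int(t) <= 31

    def mm(t: str) -> bool:  # zero-padded 01..12
        return _ascii_digits(t) and len(t) == 2 and 1 <= int(t) <= 12

    def dd(t: str) -> bool:  # zero-padded 01..31
        return _ascii_digits(t) and len(t) == 2 and 1 <= int(t) <= 31

    if year(s):
        return True
    parts = s.split("-")
    if len(parts) == 2:
        mon, yr = parts
        if mon.lower() in _MONTHS and year(yr):
            return True
        return year(parts[0]) and mm(parts[1])
    if len(parts) == 3:
        if day_free(parts[0]) and parts[1].lower() in _MONTHS and year(parts[2]):
            return True
        if not (year(parts[0]) and mm(parts[1])):
            return False
        last = parts[2]
        if dd(last):
            return True
        date, sep, clock = last.partition("T")
        if not sep or not dd(date):
            return False
        hms = clock.split(":")
        if len(hms) != 3 or not all(_ascii_digits(x) and len(x) == 2 for x in hms):
            return False
        h, mi, se = (int(x) for x in hms)
        return h <= 23 and mi <= 59 and se <= 59
    return False


def generate_timestamp_candidates(n: int, seed: int) -> list[str]:
    """Date-like strings mixing valid and broken components."""
    rng = random.Random(seed)
    months = ["Jan", "Feb", "Mar", "Apr", "May", "Jun", "Jul", "Aug", "Sep", "Oct", "Nov", "Dec",
              "jan", "NOV", "dec", "Janu", "Nvo", "Jen", "January", "13", "00"]
    days = [str(d) for d in range(0, 33)] + ["01", "09", "31", "32", "001"]
    years = ["1800", "1999", "2000", "2017", "99", "20000", "two thousand"]
    mms = [f"{m:02d}" for m in range(0, 14)] + ["1", "5", "11"]
    dds = [f"{d:02d}" for d in range(0, 33)] + ["3", "31", "32"]
    delims = ["-", "/", " "]
    out = []
    for _ in range(n):
        shape = rng.randrange(8)
        d1, d2 = rng.choice(delims), rng.choice(delims)
        if shape == 0:
            out.append(f"{rng.choice(days)}{d1}{rng.choice(months)}{d2}{rng.choice(years)}")
        elif shape == 1:
            out.append(f"{rng.choice(months)}{d1}{rng.choice(years)}")
        elif shape == 2:
            out.append(rng.choice(years))
        elif shape == 3:
            out.append(f"{rng.choice(years)}{d1}{rng.choice(mms)}")
        elif shape == 4:
            out.append(f"{rng.choice(years)}{d1}{rng.choice(mms)}{d2}{rng.choice(dds)}")
        elif shape == 5:
            h = rng.choice(["00", "12", "23", "24", "7", "99"])
            mi = rng.choice(["00", "30", "59", "60", "5"])
            se = rng.choice(["00", "59", "61", "9"])
            out.append(f"{rng.choice(years)}-{rng.choice(mms)}-{rng.choice(dds)}T{h}:{mi}:{se}")
        elif shape == 6:
            out.append(rng.choice(["no description", "unspecified", "missing", "", " ",
                                   "1800/2014", "Jan-Feb 2009", "2000-11-20T17:30", "--"]))
        else:  # valid-looking with surrounding whitespace
            out.append(f"  {rng.choice(days)}-{rng.choice(months)}-{rng.choice(years)} ")
    return out


@functools.lru_cache(maxsize=None)
def oracle_levenshtein(s: str, t: str) -> int:
    """Memoized textbook recursion for the unit-cost edit distance."""
    if not s:
        return len(t)
    if not t:
        return len(s)
    cost = 0 if s[-1] == t[-1] else 1
    return min(
        oracle_levenshtein(s[:-1], t) + 1,
        oracle_levenshtein(s, t[:-1]) + 1,
        oracle_levenshtein(s[:-1], t[:-1]) + cost,
    )
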