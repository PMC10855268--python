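"""Paired study designs.

The study arranges 24 fish as 12 day-pairs: on each experimental day one
treated and one control individual are processed together, six days per
exposure time (3 h and 24 h), and every fish is sampled at up to four
anatomical sites. The day-pair is the unit that both the batch-removal
preprocessing and the cross-validation folds are built on.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd

SITES = ("muscle", "skin", "gills", "eye")
#: sites with 16S microbiome sampling
MICROBIOME_SITES = ("skin", "gills", "eye")
GROUPS = ("control", "treated")
TIMES = ("t3h", "t24h")

DESIGN_COLUMNS = ("sample_id", "fish_id", "day", "group", "time", "site")


class DesignError(ValueError):
    """Raised when a sample design violates the paired-day layout."""


def generate_design(n_days_per_time: int = 6,
                    sites: Iterable[str] = SITES) -> pd.DataFrame:
    """Build a complete paired factorial design table.

    One control and one treated fish per day, ``n_days_per_time`` days for
    each exposure time, each fish sampled at every site in ``sites``. With
    the defaults this yields 24 fish across 12 day-pairs.

    Returns a DataFrame with columns ``sample_id, fish_id, day, group,
    time, site``; ``sample_id`` is ``<fish_id>_<site>``.
    """
    if n_days_per_time < 2:
        raise DesignError(
            f"n_days_per_time={n_days_per_time}: at least 2 day-pairs per "
            "time point are required (cross-validation needs >= 2 folds)")
    sites = tuple(sites)
    if not sites:
        raise DesignError("at least one site is required")
    rows = []
    day = 0
    fish = 0
    for time in TIMES:
        for _ in range(n_days_per_time):
            day += 1
            for group in GROUPS:
                fish += 1
                fish_id = f"F{fish:02d}"
                for site in sites:
                    rows.append({
                        "sample_id": f"{fish_id}_{site}",
                        "fish_id": fish_id,
                        "day": day,
                        "group": group,
                        "time": time,
                        "site": site,
                    })
    return pd.DataFrame(rows, columns=list(DESIGN_COLUMNS))


def validate_design(design: pd.DataFrame) -> None:
    """Check the paired-design invariants; raise :class:`DesignError` if broken."""
    missing = set(DESIGN_COLUMNS) - set(design.columns)
    if missing:
        raise DesignError(f"design table missing columns: {sorted(missing)}")
    if design["sample_id"].duplicated().any():
        dups = design.loc[design["sample_id"].duplicated(), "sample_id"]
        raise DesignError(f"duplicate sample_id values: {sorted(set(dups))}")
    bad_group = set(design["group"]) - set(GROUPS)
    if bad_group:
        raise DesignError(f"unknown group labels: {sorted(bad_group)}")
    for (day, time, site), sub in design.groupby(["day", "time", "site"]):
        counts = sub["group"].value_counts()
        if counts.get("control", 0) != 1 or counts.get("treated", 0) != 1:
            raise DesignError(
                f"day {day} ({time}, {site}) is not a control/treated pair "
                f"(got {dict(counts)})")


def subset(design: pd.DataFrame, time: str | None = None,
           site: str | None = None) -> pd.DataFrame:
    """Restrict a design to one analysis set (a time point and/or a site)."""
    out = design
    if time is not None:
        if time not in TIMES:
            raise DesignError(f"unknown time point {time!r}; expected {TIMES}")
        out = out[out["time"] == time]
    if site is not None:
        out = out[out["site"] == site]
    if out.empty:
        raise DesignError(f"no samples for time={time!r}, site={site!r}")
    return out.reset_index(drop=True)


def day_pairs(design: pd.DataFrame) -> dict[int, tuple[str, str]]:
    """Map each day to its ``(control sample_id, treated sample_id)`` pair.

    The design must already be restricted to a single site (one row per
    fish-day), otherwise days contain more than two samples.
    """
    pairs: dict[int, tuple[str, str]] = {}
    for day, sub in design.groupby("day"):
        ctrl = sub.loc[sub["group"] == "control", "sample_id"]
        trt = sub.loc[sub["group"] == "treated", "sample_id"]
        if len(ctrl) != 1 or len(trt) != 1:
            raise DesignError(
                f"day {day} does not contain exactly one control and one "
                f"treated sample ({len(ctrl)} control, {len(trt)} treated); "
                "restrict the design to a single site first")
        pairs[int(day)] = (ctrl.iloc[0], trt.iloc[0])
    return pairs


def class_vector(design: pd.DataFrame,
                 coding: Mapping[str, float] | None = None) -> pd.Series:
    """Numeric class response for PLS-DA: control=+1, treated=-1 by default."""
    coding = dict(coding) if coding is not None else {"control": 1.0,
                                                      "treated": -1.0}
    y = design.set_index("sample_id")["group"].map(coding)
    if y.isna().any():
        raise DesignError("group labels not covered by the class coding")
    return y.astype(float)
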