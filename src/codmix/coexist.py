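"""Multi-scale coexistence statistics for the two ecotypes.

Assigned fish are grouped at nested spatial levels — the whole coast, the
15 geographic regions, the beach-seine stations, and individual hauls
(station x year). For each group, the North-Sea fraction and Simpson's
index of diversity (the probability that two randomly drawn fish are of
different ecotypes) are computed; summaries average diversity weighted by
group sample size and report the proportion of groups containing both
ecotypes. A weighted linear regression relates station-level North-Sea
fraction to distance inland from the outer coast.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "ScaleSummary",
    "DistanceRegression",
    "simpson",
    "mixture_by_level",
    "scale_summary",
    "distance_regression",
    "annual_counts",
]

LEVELS = ("total", "region", "station", "haul")


@dataclass(frozen=True)
class ScaleSummary:
    level: str
    n_groups: int
    mean_diversity: float  # sample-size weighted
    sd_diversity: float
    prop_both_types: float  # over groups passing the min-n filter; NaN if none
    n_groups_filtered: int  # groups entering the both-types proportion
    min_n_filter: int


@dataclass(frozen=True)
class DistanceRegression:
    slope: float
    intercept: float
    slope_se: float
    t_value: float
    p_value: float
    n_stations: int


def simpson(freq: float) -> float:
    """Simpson's index of diversity for a two-type mixture.

    ``1 - f^2 - (1-f)^2``: the probability that two randomly drawn
    individuals are of different types. 0 at fixation, maximum 0.5 at
    ``f = 0.5``.
    """
    f = float(freq)
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"frequency must lie in [0, 1]; got {freq!r}")
    return 1.0 - f * f - (1.0 - f) * (1.0 - f)


def _attach_stations(assignments: pd.DataFrame, stations: pd.DataFrame) -> pd.DataFrame:
    known = set(stations["station"])
    orphans = sorted(set(assignments["station"]) - known)
    if orphans:
        raise ValueError(f"fish reference unknown stations: {orphans[:10]}"
                         + ("..." if len(orphans) > 10 else ""))
    return assignments.merge(stations[["station", "region"]], on="station", how="left")


def mixture_by_level(
    assignments: pd.DataFrame,
    stations: pd.DataFrame,
    level: str,
) -> pd.DataFrame:
    """Group assigned fish at a spatial level and compute mixture statistics.

    ``assignments`` needs columns station, year, label (unassigned rows are
    excluded from all counts); ``stations`` maps station -> region. ``level``
    is one of 'total', 'region', 'station', 'haul' (haul = station x year).

    Returns a frame with columns group, n, n_ns, freq_ns, diversity,
    both_present.
    """
    if level not in LEVELS:
        raise ValueError(f"level must be one of {LEVELS}; got {level!r}")
    df = _attach_stations(assignments, stations)
    df = df[df["label"].isin(["fjord", "northsea"])]
    if level == "total":
        keys = pd.Series("total", index=df.index, name="group")
    elif level == "region":
        keys = df["region"].rename("group")
    elif level == "station":
        keys = df["station"].rename("group")
    else:
        keys = (df["station"].astype(str) + ":" + df["year"].astype(str)).rename("group")
    g = df.groupby(keys, sort=True)
    out = g.agg(n=("label", "size"),
                n_ns=("label", lambda s: int((s == "northsea").sum())))
    out["freq_ns"] = out["n_ns"] / out["n"]
    out["diversity"] = [simpson(f) for f in out["freq_ns"]]
    out["both_present"] = (out["n_ns"] > 0) & (out["n_ns"] < out["n"])
    out = out.reset_index()
    out.attrs["level"] = level
    return out


def scale_summary(groups: pd.DataFrame, min_n: int = 6) -> ScaleSummary:
    """Summarize group mixtures at one level.

    Weighted mean diversity uses sample sizes as weights; the weighted SD is
    the population form ``sqrt(sum w (d - d̄)^2 / sum w)``. The min-n filter
    applies only to the both-types proportion; diversity averages use all
    groups.
    """
    if len(groups) == 0:
        raise ValueError("empty group table")
    level = str(groups.attrs.get("level", ""))
    w = groups["n"].to_numpy(float)
    d = groups["diversity"].to_numpy(float)
    mean = float(np.average(d, weights=w))
    sd = float(np.sqrt(np.average((d - mean) ** 2, weights=w)))
    big = groups[groups["n"] >= min_n]
    prop = float(big["both_present"].mean()) if len(big) else float("nan")
    return ScaleSummary(
        level=level,
        n_groups=len(groups),
        mean_diversity=mean,
        sd_diversity=sd,
        prop_both_types=prop,
        n_groups_filtered=len(big),
        min_n_filter=min_n,
    )


def distance_regression(
    assignments: pd.DataFrame,
    stations: pd.DataFrame,
    min_n: int = 5,
) -> DistanceRegression:
    """Weighted regression of station North-Sea fraction on distance inland.

    Stations with fewer than ``min_n`` assigned fish are excluded; the
    remaining station fractions are regressed on distance (metres) by
    weighted least squares with station sample sizes as weights, and the
    slope tested with a two-sided t-test on ``n_stations - 2`` df.
    """
    mix = mixture_by_level(assignments, stations, "station")
    mix = mix[mix["n"] >= min_n].merge(
        stations[["station", "distance_m"]], left_on="group", right_on="station"
    )
    if len(mix) < 3:
        raise ValueError(f"need >=3 stations after the min-n filter, have {len(mix)}")
    x = mix["distance_m"].to_numpy(float)
    if np.ptp(x) == 0:
        raise ValueError("all station distances identical: singular design")
    X = sm.add_constant(x)
    fit = sm.WLS(mix["freq_ns"].to_numpy(float), X, weights=mix["n"].to_numpy(float)).fit()
    return DistanceRegression(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        slope_se=float(fit.bse[1]),
        t_value=float(fit.tvalues[1]),
        p_value=float(fit.pvalues[1]),
        n_stations=len(mix),
    )


def annual_counts(assignments: pd.DataFrame) -> pd.DataFrame:
    """Per-year assignment accounting with a totals row.

    Columns: year, n_genotyped, n_unassigned, n_ns, n_fjord, freq_ns; the
    'total' row holds the column sums, with freq_ns recomputed from the
    summed assigned counts.
    """
    df = assignments.copy()
    g = df.groupby("year", sort=True)
    out = g.agg(
        n_genotyped=("label", "size"),
        n_unassigned=("label", lambda s: int((s == "unassigned").sum())),
        n_ns=("label", lambda s: int((s == "northsea").sum())),
        n_fjord=("label", lambda s: int((s == "fjord").sum())),
    ).reset_index()
    out["year"] = out["year"].astype(str)
    totals = out[["n_genotyped", "n_unassigned", "n_ns", "n_fjord"]].sum()
    out = pd.concat(
        [out, pd.DataFrame([{"year": "total", **totals.to_dict()}])],
        ignore_index=True,
    )
    assigned = out["n_ns"] + out["n_fjord"]
    with np.errstate(invalid="ignore"):
        out["freq_ns"] = np.where(assigned > 0, out["n_ns"] / assigned, np.nan)
    return out
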