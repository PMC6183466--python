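"""Published summary counts from the 14-year Skagerrak beach-seine survey.

These are the survey's reported per-region and per-year accounting tables
(counts of stations, fish caught, and genetic assignments). They are inputs
to the accounting checks: the pipeline's own bookkeeping recomputes totals
and mixture fractions from these printed rows and must agree with the
printed marginals.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["regional_summary", "annual_summary"]

# region, n_stations, n_fish, freq_ns (reported, averaged over 2000-2015)
_REGIONS = [
    ("Torvefjord", 3, 323, 0.25),
    ("Topdalsfjord", 7, 577, 0.20),
    ("Lillesand", 8, 620, 0.37),
    ("Grimstad", 5, 491, 0.60),
    ("Flodevigen", 3, 115, 0.36),
    ("Tvedestrand", 4, 297, 0.19),
    ("Sandnesfjorden", 8, 478, 0.42),
    ("Nordfjorden", 8, 401, 0.11),
    ("Risor skerries", 4, 467, 0.51),
    ("Kragero", 11, 387, 0.09),
    ("Grenland", 8, 315, 0.16),
    ("Hvasser", 13, 596, 0.59),
    ("Holmestrand", 7, 402, 0.20),
    ("Oslofjord", 18, 319, 0.15),
    ("Hvaler", 19, 695, 0.56),
]

# year, n_stations, n_genotyped, n_unassigned, n_northsea, n_fjord, freq_ns
_YEARS = [
    (2000, 68, 816, 4, 178, 634, 0.22),
    (2001, 43, 259, 0, 98, 161, 0.38),
    (2003, 44, 1038, 6, 404, 628, 0.39),
    (2004, 21, 98, 0, 44, 54, 0.45),
    (2005, 11, 167, 2, 70, 95, 0.42),
    (2006, 17, 397, 1, 249, 147, 0.63),
    (2007, 37, 782, 6, 132, 644, 0.17),
    (2008, 40, 166, 0, 48, 118, 0.29),
    (2009, 27, 409, 8, 151, 250, 0.38),
    (2010, 20, 437, 9, 82, 346, 0.19),
    (2011, 11, 825, 13, 441, 371, 0.54),
    (2013, 49, 415, 2, 100, 313, 0.24),
    (2014, 34, 191, 48, 30, 113, 0.21),
    (2015, 44, 483, 1, 211, 271, 0.44),
]

#: Reported marginals for cross-checks.
TOTAL_FISH = 6483
TOTAL_STATIONS = 126
TOTAL_ASSIGNED = 6383  # fish passing both QC filters (min loci, min score)
TOTAL_NORTHSEA = 2238
TOTAL_FJORD = 4145
TOTAL_FREQ_NS = 0.35


def regional_summary() -> pd.DataFrame:
    """Reported per-region station, catch and North-Sea-fraction table."""
    return pd.DataFrame(
        _REGIONS, columns=["region", "n_stations", "n_fish", "freq_ns"]
    )


def annual_summary() -> pd.DataFrame:
    """Reported per-year genotyping and assignment accounting table."""
    return pd.DataFrame(
        _YEARS,
        columns=["year", "n_stations", "n_genotyped", "n_unassigned",
                 "n_northsea", "n_fjord", "freq_ns"],
    )
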