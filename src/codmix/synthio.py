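"""Synthetic beach-seine survey generator.

Generates every input the analysis pipeline consumes, with the statistical
structure the analysis assumes, so that all stages are testable without the
archived survey data:

* two reference populations with divergent allele frequencies at ~26
  biallelic loci, calibrated to a target mean G_ST (default 0.20);
* coastal stations whose North-Sea-type probability declines linearly with
  distance inland (default slope -1.85e-5 per metre, intercept 0.55,
  clamped to [0.01, 0.99]);
* individual log lengths drawn from the selected mixed model, using the
  published coefficient estimates as generating truth, with a region random
  effect whose variance share is 8% at the defaults;
* daily otolith increment series consistent with a Feb 5 - May 3 hatch
  window and mean daily growth in 0.46-0.86 mm/day.

All randomness flows from the single config seed through named substreams,
so each product is reproducible independently of call order.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .markerpanel import gst

__all__ = [
    "GeneratorConfig",
    "DEFAULT_LMM_TRUTH",
    "SURVEY_YEARS",
    "gen_reference_freqs",
    "gen_reference_genotypes",
    "gen_station_metadata",
    "gen_survey",
    "gen_otoliths",
    "generate_all",
]

#: The 14 survey years (no sampling in 2002 and 2012).
SURVEY_YEARS: tuple[int, ...] = (2000, 2001, 2003, 2004, 2005, 2006, 2007,
                                 2008, 2009, 2010, 2011, 2013, 2014, 2015)

#: Generating truth for the length model: the selected model's published
#: coefficient estimates (log-cm scale; reference cell = year 2000,
#: eelgrass, fjord type). Years absent from the mapping have effect 0.
DEFAULT_LMM_TRUTH: dict = {
    "intercept": 2.355,
    "year": {2001: -0.040, 2003: -0.050, 2004: 0.143, 2005: -0.017,
             2006: -0.103, 2007: -0.120, 2008: 0.016, 2009: 0.092,
             2010: 0.058, 2011: -0.119, 2013: -0.072, 2014: 0.016,
             2015: 0.040},
    "we": 0.070,
    "vt_macroalgae": -0.034,
    "vc": -0.014,
    "co_northsea": 0.149,
    "we_co": -0.023,
    "vt_co": -0.023,
    "vc_co": 0.0,
}

_MAX_GST = 0.95  # achievable ceiling with frequencies kept inside (0.01, 0.99)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic survey.

    Defaults reproduce the sampling design the analysis assumes: 26 panel
    loci at mean G_ST 0.20, 125 stations in 15 regions over 14 survey years,
    a linear decline of the North-Sea fraction with distance inland, the
    published length-model coefficients as truth with an 8% region variance
    share, and otolith growth between 0.46 and 0.86 mm/day.
    """

    n_loci: int = 26
    n_ref_per_pop: int = 300
    mean_gst_target: float = 0.20
    n_regions: int = 15
    n_stations: int = 125
    years: tuple[int, ...] = SURVEY_YEARS
    mixture_intercept: float = 0.55
    mixture_slope: float = -1.85e-5  # per metre of distance inland
    mixture_model: str = "linear"  # 'linear' (clamped) or 'logistic'
    lmm_truth: dict = field(default_factory=lambda: dict(DEFAULT_LMM_TRUTH))
    region_sd: float = 0.059  # log-cm
    residual_sd: float = 0.20  # log-cm
    hatch_window: tuple[dt.date, dt.date] = (dt.date(2015, 2, 5), dt.date(2015, 5, 3))
    growth_range: tuple[float, float] = (0.46, 0.86)  # mm/day
    catch_mean: float = 14.0
    catch_dispersion: float = 1.0
    haul_rate: float = 0.26  # probability a station is seined in a year
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        if not 0.0 <= self.mean_gst_target < 1.0:
            raise ValueError("mean_gst_target must lie in [0, 1)")
        if self.mean_gst_target > _MAX_GST:
            raise ValueError(
                f"mean G_ST target {self.mean_gst_target} unreachable with "
                f"frequencies in (0.01, 0.99); maximum is {_MAX_GST}")
        if self.n_stations < self.n_regions:
            raise ValueError("need at least one station per region")
        if self.mixture_model not in ("linear", "logistic"):
            raise ValueError("mixture_model must be 'linear' or 'logistic'")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must lie in [0, 1]")

    def rng(self, stream: int) -> np.random.Generator:
        """Named substream of the config seed (stable across call order)."""
        return np.random.default_rng([int(self.seed) % (2**31), stream])


def mixture_probability(config: GeneratorConfig, distance_m) -> np.ndarray:
    """North-Sea probability at a distance inland, clamped to [0.01, 0.99]."""
    d = np.asarray(distance_m, dtype=float)
    if config.mixture_model == "linear":
        p = config.mixture_intercept + config.mixture_slope * d
    else:
        eta = np.log(config.mixture_intercept / (1 - config.mixture_intercept))
        p = 1.0 / (1.0 + np.exp(-(eta + 4.0 * config.mixture_slope * d)))
    return np.clip(p, 0.01, 0.99)


def _solve_delta(midpoint: float, target: float) -> float:
    """Frequency gap d with gst(m - d/2, m + d/2) = target (symmetric-pair
    identity: d = sqrt(target) at m = 0.5)."""
    if target == 0.0:
        return 0.0
    d_max = 2.0 * min(midpoint, 1.0 - midpoint) - 0.02
    if d_max <= 0:
        return -1.0
    f = lambda d: gst(midpoint - d / 2, midpoint + d / 2) - target
    if f(d_max) < 0:
        return -1.0  # unreachable at this midpoint
    return brentq(f, 0.0, d_max, xtol=1e-12)


def gen_reference_freqs(config: GeneratorConfig) -> pd.DataFrame:
    """Per-locus allele-frequency pairs for the two reference populations.

    Each locus receives the configured divergence target exactly: a random
    midpoint frequency is drawn and the symmetric frequency gap solved so
    that the locus G_ST equals ``mean_gst_target`` (midpoints are pulled
    toward 0.5 when the target is unreachable at the drawn midpoint), so the
    realized mean G_ST matches the target by construction.
    """
    rng = config.rng(1)
    rows = []
    for i in range(config.n_loci):
        m = float(rng.uniform(0.40, 0.60))
        if config.mean_gst_target == 0.0:
            p = float(rng.uniform(0.10, 0.90))
            rows.append((f"snp{i + 1:03d}", p, p))
            continue
        d = _solve_delta(m, config.mean_gst_target)
        tries = 0
        while d < 0 and tries < 200:
            m = 0.5 + 0.8 * (m - 0.5)
            d = _solve_delta(m, config.mean_gst_target)
            tries += 1
        if d < 0:
            raise ValueError(
                f"mean G_ST target {config.mean_gst_target} unreachable")
        lo, hi = m - d / 2, m + d / 2
        if rng.random() < 0.5:  # randomize which population holds the high allele
            lo, hi = hi, lo
        rows.append((f"snp{i + 1:03d}", lo, hi))
    return pd.DataFrame(rows, columns=["locus_id", "p_fjord", "p_northsea"])


def _draw_genotypes(rng, freqs: pd.DataFrame, pop: str, n: int, prefix: str,
                    missing_rate: float) -> pd.DataFrame:
    p = freqs[f"p_{pop}"].to_numpy(float)
    dos = rng.binomial(2, p, size=(n, p.size)).astype(float)
    if missing_rate > 0:
        dos[rng.random(dos.shape) < missing_rate] = np.nan
    ids = [f"{prefix}{i + 1:04d}" for i in range(n)]
    return pd.DataFrame(dos, index=ids, columns=freqs["locus_id"])


def gen_reference_genotypes(
    freqs: pd.DataFrame,
    n_per_pop: int,
    config: GeneratorConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """HWE genotype matrices (dosage ~ Binomial(2, p)) for the two references."""
    for col in ("p_fjord", "p_northsea"):
        p = freqs[col].to_numpy(float)
        if ((p < 0) | (p > 1)).any():
            raise ValueError("frequencies must lie in [0, 1]")
    rng = config.rng(2)
    g_f = _draw_genotypes(rng, freqs, "fjord", n_per_pop, "fjord_", config.missing_rate)
    g_n = _draw_genotypes(rng, freqs, "northsea", n_per_pop, "ns_", config.missing_rate)
    return g_f, g_n


def gen_station_metadata(config: GeneratorConfig) -> pd.DataFrame:
    """Station table: region, distance inland, wave exposure, vegetation.

    Stations are spread along the coast with distances stratified over
    [0, 25000] m (the outermost station pinned to 0 so the survey always
    spans the full gradient) and regions assigned round-robin so every
    region contains both outer and inner stations. Wave exposure (significant
    wave height, m) decays with distance inland; vegetation type and cover
    are station-level habitat covariates, constant across years.
    """
    rng = config.rng(3)
    n = config.n_stations
    dist = 25000.0 * (np.arange(n) + rng.uniform(0, 1, n)) / n
    dist[0] = 0.0
    region = 1 + (np.arange(n) % config.n_regions)
    wave = np.exp(np.log(0.5) - 1.2 * dist / 25000.0 + rng.normal(0, 0.3, n))
    veg_type = rng.choice(["eelgrass", "macroalgae"], size=n)
    veg_cover = rng.integers(1, 6, size=n)
    return pd.DataFrame({
        "station": [f"st{i + 1:03d}" for i in range(n)],
        "region": region,
        "distance_m": dist,
        "wave_exposure": wave,
        "veg_type": veg_type,
        "veg_cover": veg_cover,
    })


def _linear_predictor(truth: dict, year, log_we, is_macro, veg_cover, is_ns):
    return (truth["intercept"]
            + np.asarray([truth["year"].get(int(y), 0.0) for y in np.atleast_1d(year)])
            + truth["we"] * log_we
            + truth["vt_macroalgae"] * is_macro
            + truth["vc"] * veg_cover
            + is_ns * (truth["co_northsea"]
                       + truth.get("we_co", 0.0) * log_we
                       + truth.get("vt_co", 0.0) * is_macro
                       + truth.get("vc_co", 0.0) * veg_cover))


def gen_survey(
    config: GeneratorConfig,
    stations: pd.DataFrame,
    freqs: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate hauls, fish ecotypes, genotypes and lengths.

    Each year a station is seined with probability ``haul_rate``; haul catch
    sizes are negative binomial (mean ``catch_mean``, dispersion
    ``catch_dispersion``). A fish's true ecotype is Bernoulli in the
    station's clamped mixture probability, its genotype is drawn from that
    ecotype's reference frequencies, and its log length from the generating
    length model plus region and residual noise. Returns ``(survey,
    genotypes)``: one fish per row, lengths in cm.
    """
    rng = config.rng(4)
    region_ids = np.arange(1, config.n_regions + 1)
    region_eff = dict(zip(region_ids, rng.normal(0.0, config.region_sd,
                                                 config.n_regions)))
    p_ns_by_station = dict(zip(stations["station"],
                               mixture_probability(config, stations["distance_m"])))
    k = config.catch_dispersion
    mu = config.catch_mean
    p_nb = k / (k + mu)

    recs = []
    genos = []
    fish_no = 0
    p_f = freqs["p_fjord"].to_numpy(float)
    p_n = freqs["p_northsea"].to_numpy(float)
    for year in config.years:
        seined = rng.random(len(stations)) < config.haul_rate
        for st in stations[seined].itertuples(index=False):
            catch = int(rng.negative_binomial(k, p_nb))
            if catch == 0:
                continue
            p_ns = p_ns_by_station[st.station]
            is_ns = rng.random(catch) < p_ns
            log_we = np.log(st.wave_exposure)
            eta = _linear_predictor(
                config.lmm_truth, year, log_we,
                float(st.veg_type == "macroalgae"), float(st.veg_cover),
                is_ns.astype(float))
            eta = eta + region_eff[st.region] + rng.normal(0, config.residual_sd, catch)
            pmat = np.where(is_ns[:, None], p_n[None, :], p_f[None, :])
            dos = rng.binomial(2, pmat).astype(float)
            if config.missing_rate > 0:
                dos[rng.random(dos.shape) < config.missing_rate] = np.nan
            for j in range(catch):
                fish_no += 1
                fid = f"fish{fish_no:06d}"
                recs.append({
                    "fish_id": fid, "station": st.station, "year": year,
                    "region": st.region, "distance_m": st.distance_m,
                    "wave_exposure": st.wave_exposure, "veg_type": st.veg_type,
                    "veg_cover": int(st.veg_cover),
                    "ecotype_true": "northsea" if is_ns[j] else "fjord",
                    "p_ns_true": p_ns,
                    "length_cm": float(np.exp(eta[j])),
                })
                genos.append((fid, dos[j]))
    survey = pd.DataFrame(recs)
    genotypes = pd.DataFrame(
        [g for _, g in genos],
        index=[f for f, _ in genos],
        columns=freqs["locus_id"],
    )
    return survey, genotypes


def gen_otoliths(
    n_fish: int,
    capture_dates: list[dt.date],
    config: GeneratorConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Daily increment series with known hatch dates and growth targets.

    Per fish: hatch date uniform in the hatch window; a fish-specific target
    growth rate uniform in ``growth_range``; capture length equal to the
    biological-intercept length plus rate x age, so the back-calculated mean
    daily growth recovers the target exactly. Increment widths vary from day
    to day (lognormal jitter on a slowly rising profile); the otolith capture
    radius is the intercept radius plus their sum.

    Returns ``(fish_table, increments)`` with increments in long format
    (fish_id, day_index, increment_width_um).
    """
    rng = config.rng(5)
    lo, hi = config.hatch_window
    if len(capture_dates) not in (1, n_fish):
        raise ValueError("capture_dates must have length 1 or n_fish")
    caps = list(capture_dates) * (n_fish if len(capture_dates) == 1 else 1)
    window_days = (hi - lo).days
    fish_rows, inc_rows = [], []
    for i in range(n_fish):
        cap = caps[i]
        if cap < hi + dt.timedelta(days=1):
            raise ValueError(
                f"capture date {cap} precedes the end of the hatch window {hi}")
        hatch = lo + dt.timedelta(days=int(rng.integers(0, window_days + 1)))
        age = (cap - hatch).days
        g = float(rng.uniform(*config.growth_range))
        length_mm = 4.5 + g * age
        day = np.arange(age)
        profile = 1.0 + 1.5 * day / max(age - 1, 1)  # increments widen with age
        widths = profile * rng.lognormal(mean=0.0, sigma=0.25, size=age)
        widths *= (4.0 * age) / widths.sum()  # mean width ~4 um/day
        fid = f"oto{i + 1:03d}"
        fish_rows.append({
            "fish_id": fid, "capture_date": cap, "hatch_date_true": hatch,
            "age_days_true": age, "growth_target_mm_day": g,
            "length_capture_mm": length_mm,
            "o_capture_um": 9.0 + widths.sum(),
        })
        inc_rows.extend(
            {"fish_id": fid, "day_index": int(t + 1),
             "increment_width_um": float(w)}
            for t, w in enumerate(widths)
        )
    return pd.DataFrame(fish_rows), pd.DataFrame(inc_rows)


def generate_all(config: GeneratorConfig) -> dict:
    """Generate the full input bundle for an end-to-end pipeline run."""
    freqs = gen_reference_freqs(config)
    ref_f, ref_n = gen_reference_genotypes(freqs, config.n_ref_per_pop, config)
    stations = gen_station_metadata(config)
    survey, genotypes = gen_survey(config, stations, freqs)
    capture = max(config.hatch_window).replace(month=9, day=21)
    oto_fish, oto_inc = gen_otoliths(26, [capture], config)
    labels = pd.Series(
        ["fjord"] * len(ref_f) + ["northsea"] * len(ref_n),
        index=list(ref_f.index) + list(ref_n.index),
        name="population",
    )
    return {
        "config": config,
        "freqs": freqs,
        "ref_genotypes": pd.concat([ref_f, ref_n]),
        "ref_labels": labels,
        "stations": stations,
        "survey": survey,
        "genotypes": genotypes,
        "otolith_fish": oto_fish,
        "otolith_increments": oto_inc,
    }
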