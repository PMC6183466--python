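"""Likelihood-based assignment of individuals to two reference populations.

Each individual's multilocus genotype is scored against per-locus allele
counts from a fjord and a North Sea reference sample. The default criterion
is the Rannala–Mountain Bayesian genotype probability (a Dirichlet(1/2, 1/2)
prior on allele frequencies integrated over the posterior given the observed
reference counts); an HWE plug-in frequency criterion is available as an
alternative. Scores are normalized likelihoods expressed in percent.

Quality rules mirror the survey protocol: individuals scored at fewer than
20 loci, or whose best score is below 80%, are left unassigned.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ReferencePanel",
    "AssignmentResult",
    "genotype_loglik_rm",
    "genotype_loglik_freq",
    "assign_individual",
    "assign_cohort",
]

POPULATIONS = ("fjord", "northsea")


@dataclass(frozen=True)
class ReferencePanel:
    """Per-locus allele counts for the two reference populations.

    ``counts`` is a frame indexed by locus with columns
    ``n1_fjord, n2_fjord, n1_northsea, n2_northsea`` — counts of allele 1
    (the allele whose dosage is recorded) and allele 2, each equal to twice
    the number of scored genotypes in that population.
    """

    counts: pd.DataFrame

    def __post_init__(self):
        need = {"n1_fjord", "n2_fjord", "n1_northsea", "n2_northsea"}
        missing = need - set(self.counts.columns)
        if missing:
            raise ValueError(f"reference panel missing columns: {sorted(missing)}")
        if (self.counts[sorted(need)] < 0).any().any():
            raise ValueError("allele counts must be nonnegative")

    @property
    def loci(self) -> pd.Index:
        return self.counts.index

    @classmethod
    def from_genotypes(cls, genotypes: pd.DataFrame, labels: pd.Series) -> "ReferencePanel":
        """Tabulate allele counts from labelled reference genotypes (NaN = missing)."""
        labels = labels.reindex(genotypes.index)
        cols = {}
        for pop in POPULATIONS:
            g = genotypes.loc[labels == pop]
            scored = g.notna().sum(axis=0)
            n1 = g.sum(axis=0, skipna=True)
            cols[f"n1_{pop}"] = n1
            cols[f"n2_{pop}"] = 2 * scored - n1
        return cls(pd.DataFrame(cols))

    def frequencies(self) -> pd.DataFrame:
        """Plug-in allele-1 frequency per locus and population (NaN if unscored)."""
        out = {}
        for pop in POPULATIONS:
            tot = self.counts[f"n1_{pop}"] + self.counts[f"n2_{pop}"]
            with np.errstate(invalid="ignore"):
                out[pop] = self.counts[f"n1_{pop}"] / tot
        return pd.DataFrame(out)


@dataclass(frozen=True)
class AssignmentResult:
    individual: str
    n_loci_scored: int
    loglik_fjord: float
    loglik_northsea: float
    score_best: float  # percent in [0, 100]
    label: str  # 'fjord' | 'northsea' | 'unassigned'
    reason: str  # 'ok' | 'too_few_loci' | 'low_score'


def genotype_loglik_rm(dosage: int, n1: float, n2: float) -> float:
    """Rannala–Mountain log genotype probability at one locus.

    With reference allele counts ``n1`` (allele 1) and ``n2`` (allele 2),
    ``n = n1 + n2`` and a Dirichlet(1/2, 1/2) prior, the posterior-predictive
    probability of drawing an unordered genotype is

    * heterozygote:      ``2 (n1+1/2)(n2+1/2) / ((n+1)(n+2))``
    * homozygote for a:  ``(na+1/2)(na+3/2) / ((n+1)(n+2))``

    Defined for any counts, including ``n = 0`` (pure prior).
    """
    n = n1 + n2
    denom = (n + 1.0) * (n + 2.0)
    if dosage == 1:
        p = 2.0 * (n1 + 0.5) * (n2 + 0.5) / denom
    elif dosage == 2:
        p = (n1 + 0.5) * (n1 + 1.5) / denom
    elif dosage == 0:
        p = (n2 + 0.5) * (n2 + 1.5) / denom
    else:
        raise ValueError(f"dosage must be 0, 1 or 2; got {dosage!r}")
    return math.log(p)


def genotype_loglik_freq(dosage: int, p_hat: float, epsilon: float = 0.001) -> float:
    """HWE plug-in log genotype probability at one locus.

    Genotype probabilities ``p̂², 2p̂(1-p̂), (1-p̂)²`` with ``p̂`` clipped to
    ``[epsilon, 1-epsilon]`` so fixed reference loci never yield -inf.
    """
    if not 0.0 <= p_hat <= 1.0:
        raise ValueError(f"frequency must lie in [0, 1]; got {p_hat!r}")
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    p = min(max(p_hat, epsilon), 1.0 - epsilon)
    if dosage == 2:
        return 2.0 * math.log(p)
    if dosage == 0:
        return 2.0 * math.log(1.0 - p)
    if dosage == 1:
        return math.log(2.0 * p * (1.0 - p))
    raise ValueError(f"dosage must be 0, 1 or 2; got {dosage!r}")


def _scores_percent(ll_f: float, ll_n: float) -> tuple[float, float]:
    """Normalize two log-likelihoods to percentages, stably in log space."""
    m = max(ll_f, ll_n)
    wf = math.exp(ll_f - m)
    wn = math.exp(ll_n - m)
    tot = wf + wn
    return 100.0 * wf / tot, 100.0 * wn / tot


def assign_individual(
    dosages: pd.Series,
    panel: ReferencePanel,
    method: str = "rm",
    min_loci: int = 20,
    score_threshold: float = 80.0,
    epsilon: float = 0.001,
) -> AssignmentResult:
    """Assign one individual to 'fjord' or 'northsea', or leave it unassigned.

    ``dosages`` is a locus-indexed series of 0/1/2 with NaN for missing. The
    log-likelihood for each population sums per-locus genotype log
    probabilities over the loci that are both scored in the individual and
    present in the panel — the same locus set for both populations. Filters
    apply in order: locus count, then score (>= threshold is kept).
    """
    if method not in ("rm", "freq"):
        raise ValueError(f"method must be 'rm' or 'freq'; got {method!r}")
    shared = dosages.index.intersection(panel.loci)
    d = dosages.loc[shared].dropna()
    n_scored = len(d)
    name = str(dosages.name) if dosages.name is not None else ""
    if n_scored < min_loci:
        return AssignmentResult(name, n_scored, math.nan, math.nan, math.nan,
                                "unassigned", "too_few_loci")

    counts = panel.counts.loc[d.index]
    freqs = panel.frequencies().loc[d.index] if method == "freq" else None
    ll = {}
    for pop in POPULATIONS:
        if method == "rm":
            n1 = counts[f"n1_{pop}"].to_numpy(float)
            n2 = counts[f"n2_{pop}"].to_numpy(float)
            ll[pop] = sum(
                genotype_loglik_rm(int(g), a, b)
                for g, a, b in zip(d.to_numpy(), n1, n2)
            )
        else:
            p = freqs[pop].fillna(0.5).to_numpy(float)
            ll[pop] = sum(
                genotype_loglik_freq(int(g), ph, epsilon)
                for g, ph in zip(d.to_numpy(), p)
            )

    s_f, s_n = _scores_percent(ll["fjord"], ll["northsea"])
    best_pop, best_score = ("fjord", s_f) if s_f >= s_n else ("northsea", s_n)
    if best_score < score_threshold:
        return AssignmentResult(name, n_scored, ll["fjord"], ll["northsea"],
                                best_score, "unassigned", "low_score")
    return AssignmentResult(name, n_scored, ll["fjord"], ll["northsea"],
                            best_score, best_pop, "ok")


def assign_cohort(
    genotypes: pd.DataFrame,
    panel: ReferencePanel,
    method: str = "rm",
    min_loci: int = 20,
    score_threshold: float = 80.0,
    epsilon: float = 0.001,
) -> tuple[pd.DataFrame, dict]:
    """Row-wise assignment of a genotype matrix.

    Returns ``(table, summary)`` where ``table`` mirrors
    :class:`AssignmentResult` per individual and ``summary`` counts
    ``n_genotyped``, ``n_unassigned``, ``n_fjord``, ``n_northsea``
    (``n_genotyped = n_unassigned + n_fjord + n_northsea``).
    """
    rows = []
    for ind, dos in genotypes.iterrows():
        dos = dos.rename(ind)
        res = assign_individual(dos, panel, method, min_loci, score_threshold, epsilon)
        rows.append(res.__dict__)
    cols = ["individual", "n_loci_scored", "loglik_fjord", "loglik_northsea",
            "score_best", "label", "reason"]
    table = pd.DataFrame(rows, columns=cols)
    summary = {
        "n_genotyped": len(table),
        "n_unassigned": int((table["label"] == "unassigned").sum()),
        "n_fjord": int((table["label"] == "fjord").sum()),
        "n_northsea": int((table["label"] == "northsea").sum()),
    }
    return table, summary
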