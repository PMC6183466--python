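"""Diagnostic SNP panel construction.

Candidate biallelic SNPs are ranked by Nei's coefficient of gene
differentiation (G_ST) between the two reference populations and pruned by
composite linkage disequilibrium (CLD): a locus is kept only if its CLD to
every higher-ranked kept locus does not exceed a threshold (default 0.5).
CLD is measured as the absolute Pearson correlation of genotype dosages
(the Burrows composite-disequilibrium estimator on unphased data), with an
``r^2`` option.

The pooled reference sample (both populations together) is the default LD
estimation set; a per-population max-CLD mode is available because pooling
divergent populations inflates apparent LD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LocusStats",
    "PanelSelection",
    "gst",
    "cld",
    "locus_stats",
    "select_panel",
]


@dataclass(frozen=True)
class LocusStats:
    """Per-locus differentiation summary between the two references.

    ``h_s`` is the mean within-population expected heterozygosity,
    ``h_t`` the total expected heterozygosity at the mean allele frequency;
    ``gst = (h_t - h_s) / h_t`` (0 when ``h_t == 0``).
    """

    locus_id: str
    p_fjord: float
    p_northsea: float
    h_s: float
    h_t: float
    gst: float


@dataclass
class PanelSelection:
    """Result of the greedy G_ST-ranked, CLD-pruned panel selection."""

    kept: list[str]
    dropped: list[tuple[str, str, str | None]]  # (locus, reason, offending locus)
    cld_threshold: float
    panel_size: int
    stats: pd.DataFrame = field(repr=False, default=None)

    def as_frame(self) -> pd.DataFrame:
        """Panel table: locus_id, p_fjord, p_northsea, gst, kept, drop_reason."""
        df = self.stats.copy()
        dropped = {loc: reason for loc, reason, _ in self.dropped}
        df["kept"] = df["locus_id"].isin(self.kept)
        df["drop_reason"] = df["locus_id"].map(dropped).fillna("")
        return df


def gst(p1: float, p2: float) -> float:
    """Nei's G_ST for a biallelic locus between two populations.

    With within-population expected heterozygosities averaged with equal
    weights: ``H_S = mean(2 p1 (1-p1), 2 p2 (1-p2))``, and total expected
    heterozygosity at the mean frequency ``H_T = 2 p̄ (1-p̄)``, returns
    ``(H_T - H_S) / H_T``; 0 when ``H_T == 0`` (both populations fixed for
    the same allele).
    """
    p1 = float(p1)
    p2 = float(p2)
    if not (0.0 <= p1 <= 1.0 and 0.0 <= p2 <= 1.0):
        raise ValueError(f"allele frequencies must lie in [0, 1]; got {p1!r}, {p2!r}")
    h_s = (2.0 * p1 * (1.0 - p1) + 2.0 * p2 * (1.0 - p2)) / 2.0
    p_bar = (p1 + p2) / 2.0
    h_t = 2.0 * p_bar * (1.0 - p_bar)
    if h_t == 0.0:
        return 0.0
    return (h_t - h_s) / h_t


def cld(dosages_a, dosages_b, *, squared: bool = False) -> float:
    """Composite LD between two loci from genotype dosages.

    Absolute Pearson correlation of 0/1/2 dosages after pairwise deletion of
    missing entries (NaN). ``squared=True`` returns r² instead of |r|.
    A monomorphic (zero-variance) locus has undefined LD; treated as 0 with
    a warning.
    """
    a = np.asarray(dosages_a, dtype=float)
    b = np.asarray(dosages_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("dosage vectors must have equal length")
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    if a.size < 3:
        raise ValueError(f"need >=3 complete genotype pairs, have {a.size}")
    va = a - a.mean()
    vb = b - b.mean()
    denom = np.sqrt((va @ va) * (vb @ vb))
    if denom == 0.0:
        warnings.warn("zero dosage variance at a locus: CLD undefined, using 0",
                      RuntimeWarning, stacklevel=2)
        return 0.0
    r = float(va @ vb / denom)
    r = min(max(r, -1.0), 1.0)
    return r * r if squared else abs(r)


def allele_frequencies(genotypes: pd.DataFrame) -> pd.Series:
    """Allele-1 frequency per locus by counting over non-missing dosages.

    ``genotypes``: individuals x loci frame of 0/1/2 dosages with NaN missing.
    Loci with no scored genotypes get NaN.
    """
    counts = genotypes.sum(axis=0, skipna=True)
    scored = genotypes.notna().sum(axis=0)
    with np.errstate(invalid="ignore"):
        return counts / (2.0 * scored)


def locus_stats(genotypes: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Per-locus frequencies and G_ST from pooled labelled reference genotypes.

    ``labels`` maps individual id -> 'fjord' | 'northsea'. Returns a frame
    with columns locus_id, p_fjord, p_northsea, h_s, h_t, gst.
    """
    labels = labels.reindex(genotypes.index)
    pops = set(labels.dropna().unique())
    if pops != {"fjord", "northsea"}:
        raise ValueError(f"labels must contain exactly 'fjord' and 'northsea'; got {sorted(pops)}")
    p_f = allele_frequencies(genotypes.loc[labels == "fjord"])
    p_n = allele_frequencies(genotypes.loc[labels == "northsea"])
    rows = []
    for locus in genotypes.columns:
        pf, pn = p_f[locus], p_n[locus]
        if np.isnan(pf) or np.isnan(pn):
            rows.append((locus, pf, pn, np.nan, np.nan, np.nan))
            continue
        h_s = (2 * pf * (1 - pf) + 2 * pn * (1 - pn)) / 2.0
        p_bar = (pf + pn) / 2.0
        h_t = 2 * p_bar * (1 - p_bar)
        rows.append((locus, pf, pn, h_s, h_t, gst(pf, pn)))
    return pd.DataFrame(
        rows, columns=["locus_id", "p_fjord", "p_northsea", "h_s", "h_t", "gst"]
    )


def select_panel(
    genotypes: pd.DataFrame,
    labels: pd.Series,
    panel_size: int = 40,
    cld_threshold: float = 0.5,
    *,
    squared: bool = False,
    per_population: bool = False,
) -> PanelSelection:
    """Greedy G_ST-ranked, CLD-pruned panel selection.

    Loci are visited in descending G_ST order (ties broken by column order);
    a locus is kept iff its CLD to every already-kept locus is <= threshold.
    Selection stops once ``panel_size`` loci are kept. Loci monomorphic in
    both references (or unscorable in either) are dropped first with reason
    ``monomorphic``.

    ``per_population=True`` computes CLD within each reference population and
    prunes on the maximum of the two, instead of on the pooled sample.
    """
    stats = locus_stats(genotypes, labels)
    order_index = {locus: i for i, locus in enumerate(genotypes.columns)}

    dropped: list[tuple[str, str, str | None]] = []
    candidates = []
    for row in stats.itertuples(index=False):
        if not np.isfinite(row.gst) or row.h_t == 0.0:
            dropped.append((row.locus_id, "monomorphic", None))
        else:
            candidates.append(row.locus_id)
    if not candidates:
        raise ValueError("no polymorphic locus available: empty panel")

    gst_by_locus = dict(zip(stats["locus_id"], stats["gst"]))
    candidates.sort(key=lambda l: (-gst_by_locus[l], order_index[l]))

    labels = labels.reindex(genotypes.index)
    if per_population:
        pools = [genotypes.loc[labels == "fjord"], genotypes.loc[labels == "northsea"]]
    else:
        pools = [genotypes]

    def pair_cld(a: str, b: str) -> float:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return max(cld(pool[a], pool[b], squared=squared) for pool in pools)

    kept: list[str] = []
    for locus in candidates:
        if len(kept) >= panel_size:
            dropped.append((locus, "panel_full", None))
            continue
        offender = next((k for k in kept if pair_cld(locus, k) > cld_threshold), None)
        if offender is None:
            kept.append(locus)
        else:
            dropped.append((locus, "ld_pruned", offender))

    return PanelSelection(
        kept=kept,
        dropped=dropped,
        cld_threshold=cld_threshold,
        panel_size=panel_size,
        stats=stats,
    )
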