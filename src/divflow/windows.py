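"""Windowed population-genetic statistics and genome-scan classification.

Non-overlapping windows (default 30 kb) tile each chromosome from position
1; the last, possibly partial, window is retained and flagged.  Per window
the module computes nucleotide diversity (pi) and Tajima's D per species,
absolute divergence D_XY and Weir-Cockerham F_ST between species, and flags
early-diverged windows (``W_early``) as those with D_XY at or above a
threshold (default 0.35, on the per-variant-site scale).

Only variant sites are observed here, so the default D_XY denominator is
the number of usable variant sites in the window, the scale on which the
0.35 early-divergence threshold is meaningful; a per-bp (``window_length``)
denominator is available for both pi and D_XY when the variant density is
interpretable as per-base.

The module also provides the genome-wide rare-allele sharing statistic:
the fraction of rare SNPs (global minor-allele count 2-5) whose minor
allele occurs in both species — a signal of recent gene flow.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import sqrt

import numpy as np
import pandas as pd
from scipy.stats import norm

from .variants import VariantTable

__all__ = [
    "WindowStat",
    "RareShareResult",
    "scan",
    "window_pi",
    "tajimas_d",
    "dxy",
    "fst_wc",
    "classify_early",
    "mann_whitney",
    "rare_shared_fraction",
]

WINDOW_SIZE = 30_000
EARLY_DXY_THRESHOLD = 0.35
MAX_MISSING_FOR_D = 0.20  # per-population call missingness cap for Tajima's D


@dataclass
class WindowStat:
    """One window's statistics (coordinates half-open, 0-based start)."""

    chrom: str
    start: int
    end: int
    n_var: int
    pi1: float
    pi2: float
    td1: float
    td2: float
    dxy: float
    fst: float
    early: bool
    partial: bool = False


@dataclass
class RareShareResult:
    count_range: tuple[int, int]
    n_rare: int
    n_shared: int

    @property
    def proportion(self) -> float:
        return self.n_shared / self.n_rare if self.n_rare else float("nan")


# ---- per-site kernels -------------------------------------------------

def _pop_counts(vt: VariantTable, idx: np.ndarray):
    """Alt allele count, non-missing allele total, and call stats per site."""
    gt = vt.gt[:, idx, :]
    good = gt >= 0
    alt = (gt == 1).sum(axis=(1, 2))
    tot = good.sum(axis=(1, 2))
    called = good.all(axis=2)  # complete diploid call
    het = called & (gt[..., 0] != gt[..., 1])
    return alt, tot, called.sum(axis=1), het.sum(axis=1)


def _site_het(alt: np.ndarray, tot: np.ndarray) -> np.ndarray:
    """Unbiased per-site heterozygosity 2 j (n-j) / (n (n-1))."""
    with np.errstate(invalid="ignore", divide="ignore"):
        h = 2.0 * alt * (tot - alt) / (tot * (tot - 1.0))
    return np.where(tot >= 2, h, np.nan)


def _windows_of(vt: VariantTable, window_size: int):
    """Per-site window assignment plus the full tiled window list."""
    rows = []  # (chrom, start)
    site_win = np.full(vt.n_sites, -1, dtype=int)
    for chrom in dict.fromkeys(vt.chrom):
        mask = vt.chrom == chrom
        pos0 = vt.pos[mask] - 1
        n_win = int(pos0.max() // window_size) + 1 if mask.any() else 0
        base = len(rows)
        rows += [(chrom, w * window_size) for w in range(n_win)]
        site_win[np.nonzero(mask)[0]] = base + pos0 // window_size
    return site_win, rows


def _aggregate(site_win, n_windows, values, usable):
    """Sum ``values`` over usable sites per window; also usable-site counts."""
    sums = np.zeros(n_windows)
    counts = np.zeros(n_windows, dtype=int)
    ok = usable & (site_win >= 0)
    np.add.at(sums, site_win[ok], values[ok])
    np.add.at(counts, site_win[ok], 1)
    return sums, counts


# ---- Tajima's D constants ---------------------------------------------

def _tajima_constants(n: int):
    if n < 4:
        raise ValueError("Tajima's D needs at least 4 sampled alleles")
    i = np.arange(1, n)
    a1 = (1.0 / i).sum()
    a2 = (1.0 / i**2).sum()
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return a1, e1, e2


def _tajima_d_from_sums(pi_sum: float, S: int, n: int) -> float:
    if S < 1:
        return float("nan")
    a1, e1, e2 = _tajima_constants(n)
    var = e1 * S + e2 * S * (S - 1)
    if var <= 0:
        return float("nan")
    return (pi_sum - S / a1) / sqrt(var)


# ---- public per-statistic operations ----------------------------------

def window_pi(
    vt: VariantTable,
    population: str,
    window_size: int = WINDOW_SIZE,
    denominator: str = "window_length",
) -> pd.Series:
    """Nucleotide diversity per window for one population.

    Sums the unbiased per-site heterozygosity over usable sites (>= 2
    non-missing alleles in the population) and divides by the window length
    in bp (``window_length``) or by the usable-site count
    (``genotyped_sites``).  Windows without usable sites are NaN.
    """
    idx = vt.pop_index(population)
    alt, tot, _, _ = _pop_counts(vt, idx)
    het = _site_het(alt, tot)
    usable = tot >= 2
    site_win, rows = _windows_of(vt, window_size)
    sums, counts = _aggregate(site_win, len(rows), np.nan_to_num(het), usable)
    if denominator == "window_length":
        vals = sums / window_size
    elif denominator == "genotyped_sites":
        with np.errstate(invalid="ignore"):
            vals = sums / counts
    else:
        raise ValueError("denominator must be 'window_length' or 'genotyped_sites'")
    vals = np.where(counts > 0, vals, np.nan)
    return pd.Series(vals, index=pd.MultiIndex.from_tuples(rows, names=["chrom", "start"]))


def tajimas_d(
    vt: VariantTable, population: str, window_size: int = WINDOW_SIZE
) -> pd.Series:
    """Tajima's D per window.

    ``n`` is the population's full haploid sample size; sites with more than
    20% missing calls in the population are excluded from both the
    segregating-site count and the diversity sum, so the fixed-n variance
    formula stays applicable.  Windows with no segregating site are NaN.
    """
    idx = vt.pop_index(population)
    n = 2 * len(idx)
    if n < 4:
        _, rows = _windows_of(vt, window_size)
        return pd.Series(
            np.full(len(rows), np.nan),
            index=pd.MultiIndex.from_tuples(rows, names=["chrom", "start"]),
        )
    alt, tot, called, _ = _pop_counts(vt, idx)
    het = _site_het(alt, tot)
    seg = (alt > 0) & (alt < tot)
    low_missing = (len(idx) - called) <= MAX_MISSING_FOR_D * len(idx)
    usable = seg & low_missing & (tot >= 2)
    site_win, rows = _windows_of(vt, window_size)
    pi_sums, S = _aggregate(site_win, len(rows), np.nan_to_num(het), usable)
    vals = np.array(
        [_tajima_d_from_sums(p, int(s), n) for p, s in zip(pi_sums, S)]
    )
    return pd.Series(vals, index=pd.MultiIndex.from_tuples(rows, names=["chrom", "start"]))


def dxy(
    vt: VariantTable,
    window_size: int = WINDOW_SIZE,
    denominator: str = "variant_sites",
    pop1: str = "sp1",
    pop2: str = "sp2",
) -> pd.Series:
    """Absolute divergence D_XY per window.

    Per site ``d = p1 (1 - p2) + p2 (1 - p1)`` with ``p`` the alt-allele
    frequency in each species over non-missing alleles; the window value is
    the sum over usable sites (>= 1 allele observed in each species) divided
    by the usable-site count (``variant_sites``, default) or the window
    length in bp (``window_length``).
    """
    a1, t1, _, _ = _pop_counts(vt, vt.pop_index(pop1))
    a2, t2, _, _ = _pop_counts(vt, vt.pop_index(pop2))
    usable = (t1 >= 1) & (t2 >= 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = a1 / t1
        p2 = a2 / t2
    d = p1 * (1 - p2) + p2 * (1 - p1)
    site_win, rows = _windows_of(vt, window_size)
    sums, counts = _aggregate(site_win, len(rows), np.nan_to_num(d), usable)
    if denominator == "variant_sites":
        with np.errstate(invalid="ignore"):
            vals = sums / counts
    elif denominator == "window_length":
        vals = sums / window_size
    else:
        raise ValueError("denominator must be 'variant_sites' or 'window_length'")
    vals = np.where(counts > 0, vals, np.nan)
    return pd.Series(vals, index=pd.MultiIndex.from_tuples(rows, names=["chrom", "start"]))


def _wc_components(vt: VariantTable, pop1: str, pop2: str):
    """Per-site Weir-Cockerham (1984) variance components a, b, c."""
    comps = []
    for pop in (pop1, pop2):
        alt, tot, called, het = _pop_counts(vt, vt.pop_index(pop))
        with np.errstate(invalid="ignore", divide="ignore"):
            p = alt / tot
            h = het / called
        comps.append((called.astype(float), p, h))
    n1, p1, h1 = comps[0]
    n2, p2, h2 = comps[1]
    usable = (n1 >= 2) & (n2 >= 2)
    r = 2.0
    nbar = (n1 + n2) / r
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2
            - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
        )
        c = hbar / 2.0
    return a, b, c, usable


def fst_wc(
    vt: VariantTable,
    window_size: int = WINDOW_SIZE,
    pop1: str = "sp1",
    pop2: str = "sp2",
) -> pd.Series:
    """Weir-Cockerham F_ST per window (ratio of sums of a over a+b+c).

    Sites need at least two complete diploid calls per species.  A window
    whose summed denominator is zero (or that has no usable site) is NaN.
    """
    a, b, c, usable = _wc_components(vt, pop1, pop2)
    site_win, rows = _windows_of(vt, window_size)
    num, counts = _aggregate(site_win, len(rows), np.nan_to_num(a), usable)
    den, _ = _aggregate(
        site_win, len(rows), np.nan_to_num(a + b + c), usable
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = num / den
    vals = np.where((counts > 0) & (den != 0), vals, np.nan)
    return pd.Series(vals, index=pd.MultiIndex.from_tuples(rows, names=["chrom", "start"]))


def fst_wc_sitewise(vt: VariantTable, pop1: str = "sp1", pop2: str = "sp2"):
    """Per-site Weir-Cockerham components (a, a+b+c, usable mask)."""
    a, b, c, usable = _wc_components(vt, pop1, pop2)
    return a, a + b + c, usable


# ---- scan, classification, contrasts ----------------------------------

def scan(
    vt: VariantTable,
    pop1: str = "sp1",
    pop2: str = "sp2",
    window_size: int = WINDOW_SIZE,
    dxy_threshold: float = EARLY_DXY_THRESHOLD,
    pi_denominator: str = "window_length",
    dxy_denominator: str = "variant_sites",
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Full genome scan: one row per window with all statistics.

    ``chrom_lengths`` (bp) marks trailing partial windows; without it the
    last window containing data is conservatively flagged partial.
    """
    p1 = window_pi(vt, pop1, window_size, pi_denominator)
    p2 = window_pi(vt, pop2, window_size, pi_denominator)
    t1 = tajimas_d(vt, pop1, window_size)
    t2 = tajimas_d(vt, pop2, window_size)
    dx = dxy(vt, window_size, dxy_denominator, pop1, pop2)
    fs = fst_wc(vt, window_size, pop1, pop2)

    site_win, rows = _windows_of(vt, window_size)
    n_var = np.zeros(len(rows), dtype=int)
    np.add.at(n_var, site_win[site_win >= 0], 1)

    df = pd.DataFrame({
        "chrom": [r[0] for r in rows],
        "start": [r[1] for r in rows],
        "end": [r[1] + window_size for r in rows],
        "n_var": n_var,
        "pi1": p1.values, "pi2": p2.values,
        "td1": t1.values, "td2": t2.values,
        "dxy": dx.values, "fst": fs.values,
    })
    partial = np.zeros(len(df), dtype=bool)
    for chrom, grp in df.groupby("chrom", sort=False):
        last = grp.index[-1]
        if chrom_lengths and chrom in chrom_lengths:
            partial[grp.index] = grp["end"] > chrom_lengths[chrom]
            df.loc[grp.index[grp["end"] > chrom_lengths[chrom]], "end"] = \
                chrom_lengths[chrom]
        else:
            partial[last] = True
    df["partial"] = partial
    return classify_early(df, dxy_threshold)


def classify_early(stats: pd.DataFrame, threshold: float = EARLY_DXY_THRESHOLD) -> pd.DataFrame:
    """Flag early-diverged windows: ``dxy >= threshold`` (boundary included)."""
    out = stats.copy()
    out["early"] = out["dxy"] >= threshold
    return out


def mann_whitney(x, y) -> tuple[float, float, float]:
    """Mann-Whitney U with midrank ties; returns ``(U, z, two-sided p)``.

    ``U`` counts (x, y) pairs with x above y (ties half).  When both samples
    have at most 8 values the two-sided p comes from exact enumeration of
    all label assignments (doubled smaller tail); otherwise from the normal
    approximation with tie-corrected variance and continuity correction.
    If every value across both lists is tied, p = 1.
    """
    x = np.asarray([v for v in np.ravel(x) if not np.isnan(v)], dtype=float)
    y = np.asarray([v for v in np.ravel(y) if not np.isnan(v)], dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must contain at least one value")
    pooled = np.concatenate([x, y])
    order = pooled.argsort(kind="mergesort")
    ranks = np.empty(n1 + n2)
    sorted_vals = pooled[order]
    # midranks
    i = 0
    while i < n1 + n2:
        j = i
        while j + 1 < n1 + n2 and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i:j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    R1 = ranks[:n1].sum()
    U = R1 - n1 * (n1 + 1) / 2.0

    mean_u = n1 * n2 / 2.0
    N = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum()
    var_u = n1 * n2 / 12.0 * ((N + 1) - tie_term / (N * (N - 1.0)))
    if var_u == 0:  # everything tied
        return U, 0.0, 1.0
    z = (U - mean_u - 0.5 * np.sign(U - mean_u)) / sqrt(var_u)

    if n1 <= 8 and n2 <= 8:
        from itertools import combinations

        us = []
        idx = range(N)
        for comb in combinations(idx, n1):
            r = ranks[list(comb)].sum()
            us.append(r - n1 * (n1 + 1) / 2.0)
        us = np.asarray(us)
        lo = (us <= U + 1e-12).mean()
        hi = (us >= U - 1e-12).mean()
        p = min(1.0, 2.0 * min(lo, hi))
    else:
        p = float(2.0 * norm.sf(abs(z)))
    return float(U), float(z), float(p)


def rare_shared_fraction(
    vt: VariantTable,
    count_range: tuple[int, int] = (2, 5),
    pop1: str = "sp1",
    pop2: str = "sp2",
) -> RareShareResult:
    """Fraction of rare SNPs whose minor allele occurs in both species.

    A site is rare when its global minor-allele count over all non-missing
    alleles lies in ``count_range`` (inclusive); it is shared when that
    minor allele is observed at least once in each species.  With an exact
    50:50 split the alt allele is taken as minor.
    """
    alt, tot = vt.allele_counts()
    minor_count = np.minimum(alt, tot - alt)
    lo, hi = count_range
    rare = (minor_count >= lo) & (minor_count <= hi)
    minor_is_alt = alt <= tot - alt

    a1, t1, _, _ = _pop_counts(vt, vt.pop_index(pop1))
    a2, t2, _, _ = _pop_counts(vt, vt.pop_index(pop2))
    minor1 = np.where(minor_is_alt, a1, t1 - a1)
    minor2 = np.where(minor_is_alt, a2, t2 - a2)
    shared = rare & (minor1 >= 1) & (minor2 >= 1)
    return RareShareResult(
        (int(lo), int(hi)), int(rare.sum()), int(shared.sum())
    )
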