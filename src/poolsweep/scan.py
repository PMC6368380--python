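"""Windowed Fst / Hp genome scan and selected-region calling.

Statistics
----------
For a biallelic site with read-pooled group frequencies ``p_A`` and ``p_B``:

    pi_S = (2 p_A (1 - p_A) + 2 p_B (1 - p_B)) / 2      within-group diversity
    pi_T = 2 pbar (1 - pbar),  pbar = (p_A + p_B) / 2   total diversity
    Fst  = (pi_T - pi_S) / pi_T                         (0 when pi_T = 0)

Windows aggregate as a ratio of sums, ``sum(pi_T - pi_S) / sum(pi_T)``, which
weighs sites by their diversity instead of averaging unstable per-site
ratios.  Pooled heterozygosity of a window in one pool group is

    Hp = 2 * sum(n_MAJ) * sum(n_MIN) / (sum(n_MAJ) + sum(n_MIN))^2

with per-site major/minor read counts defined within that group; Hp lies in
[0, 0.5] and collapses toward 0 in swept regions.

Selection
---------
A window is called selected when its Fst falls within the top-k values
genome-wide AND its Hp falls within the bottom-l values for at least one of
the two compared groups (k = 200, l = 400 at the scale of a ~923 Mb genome;
:meth:`SelectionRule.scaled` shrinks both proportionally for smaller
scans).  Rank thresholds are value-based, so ties at the boundary are all
admitted and the result is independent of input order.  Selected windows on
the same chromosome that overlap or abut merge into continuous regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .variant_io import PooledSiteCounts, SiteTable

__all__ = [
    "Comparison",
    "SelectionRule",
    "ScanSummary",
    "make_windows",
    "site_hp_terms",
    "window_hp",
    "site_fst",
    "window_fst",
    "scan_genome",
    "select_windows",
    "merge_regions",
    "site_statistics",
]

#: 40-kb bins in the ~923 Mb chromosome-anchored reference the default
#: top-200 / bottom-400 thresholds were defined against.
REFERENCE_WINDOW_COUNT = 23_075


@dataclass(frozen=True)
class Comparison:
    """An ordered pair of pool groups, e.g. M vs the pooled AS populations."""

    label_a: str
    pools_a: tuple[str, ...]
    label_b: str
    pools_b: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.pools_a or not self.pools_b:
            raise ConfigError("both comparison groups need at least one pool")
        if set(self.pools_a) & set(self.pools_b):
            raise ConfigError("comparison groups must be disjoint")

    @property
    def name(self) -> str:
        return f"{self.label_a}_vs_{self.label_b}"


@dataclass
class SelectionRule:
    """Joint rank thresholds: top-k Fst and bottom-l Hp windows."""

    top_k_fst: int = 200
    bottom_l_hp: int = 400

    def __post_init__(self) -> None:
        if self.top_k_fst < 1 or self.bottom_l_hp < 1:
            raise ConfigError("selection ranks must be >= 1")

    @classmethod
    def scaled(
        cls,
        n_windows: int,
        reference_windows: int = REFERENCE_WINDOW_COUNT,
        top_k_fst: int = 200,
        bottom_l_hp: int = 400,
    ) -> "SelectionRule":
        """Shrink the genome-scale ranks proportionally to a smaller scan."""
        f = n_windows / reference_windows
        return cls(
            top_k_fst=max(1, round(top_k_fst * f)),
            bottom_l_hp=max(1, round(bottom_l_hp * f)),
        )


@dataclass
class ScanSummary:
    """Moments of the retained-window statistics plus genome-wide Hp per group."""

    n_windows: int
    n_retained: int
    fst_mean: float
    fst_std: float
    hp_mean: dict[str, float]
    hp_std: dict[str, float]
    genome_hp: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("n_windows", self.n_windows),
            ("n_retained", self.n_retained),
            ("fst_mean", self.fst_mean),
            ("fst_std", self.fst_std),
        ]
        for g in self.hp_mean:
            rows += [
                (f"hp_mean_{g}", self.hp_mean[g]),
                (f"hp_std_{g}", self.hp_std[g]),
                (f"genome_hp_{g}", self.genome_hp[g]),
            ]
        return pd.DataFrame(rows, columns=["statistic", "value"])


# ---------------------------------------------------------------------------
# Windows


def make_windows(
    chrom_lengths: Mapping[str, int],
    window: int = 40_000,
    step: int = 20_000,
) -> pd.DataFrame:
    """Sliding windows per chromosome (0-based half-open).

    Windows start at 0 and advance by ``step``; the final window is
    truncated at the chromosome end, and truncated windows no longer than
    one step are dropped (they are wholly contained in their predecessor).
    """
    if step <= 0 or window < step:
        raise ConfigError("require window >= step > 0")
    rows = []
    for chrom, length in chrom_lengths.items():
        if length <= 0:
            raise ConfigError(f"non-positive length for {chrom!r}")
        start = 0
        while start < length:
            end = min(start + window, length)
            if end - start > step or end - start == window:
                rows.append((chrom, start, end))
            start += step
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


# ---------------------------------------------------------------------------
# Scalar statistics (formula-level API)


def _group_site_counts(site: PooledSiteCounts, pools: Sequence[str]) -> tuple[int, int]:
    r = a = 0
    for p in pools:
        c = site.counts.get(p)
        if c is not None:
            r += c[0]
            a += c[1]
    return r, a


def site_hp_terms(site: PooledSiteCounts, pools: str | Sequence[str]) -> tuple[int, int]:
    """Major/minor read counts of one site within a pool (or pool group)."""
    if isinstance(pools, str):
        pools = (pools,)
    r, a = _group_site_counts(site, pools)
    if r + a == 0:
        raise DataError(f"zero depth at {site.chrom}:{site.pos} for {tuple(pools)}")
    return (r, a) if r >= a else (a, r)


def window_hp(sites: Iterable[PooledSiteCounts], pools: str | Sequence[str]) -> float:
    """Pooled heterozygosity of a window: 2 sum(maj) sum(min) / (sum(maj)+sum(min))^2."""
    if isinstance(pools, str):
        pools = (pools,)
    maj_sum = min_sum = 0
    usable = 0
    for site in sites:
        r, a = _group_site_counts(site, pools)
        if r + a == 0:
            continue
        usable += 1
        maj_sum += max(r, a)
        min_sum += min(r, a)
    if usable == 0:
        raise DataError("window has no usable sites for Hp")
    total = maj_sum + min_sum
    return 2.0 * maj_sum * min_sum / (total * total)


def _site_freqs(site: PooledSiteCounts, pools_a: Sequence[str], pools_b: Sequence[str]) -> tuple[float, float] | None:
    ra, aa = _group_site_counts(site, pools_a)
    rb, ab = _group_site_counts(site, pools_b)
    if ra + aa == 0 or rb + ab == 0:
        return None
    return aa / (ra + aa), ab / (rb + ab)


def site_fst(site: PooledSiteCounts, pools_a: Sequence[str], pools_b: Sequence[str]) -> float:
    """Classical (pi_T - pi_S) / pi_T on the two groups' read frequencies."""
    fr = _site_freqs(site, pools_a, pools_b)
    if fr is None:
        raise DataError(f"missing group depth at {site.chrom}:{site.pos}")
    p_a, p_b = fr
    pbar = 0.5 * (p_a + p_b)
    pi_t = 2.0 * pbar * (1.0 - pbar)
    if pi_t == 0.0:
        return 0.0
    pi_s = (2.0 * p_a * (1.0 - p_a) + 2.0 * p_b * (1.0 - p_b)) / 2.0
    return (pi_t - pi_s) / pi_t


def window_fst(sites: Iterable[PooledSiteCounts], pools_a: Sequence[str], pools_b: Sequence[str]) -> float:
    """Ratio-of-sums window Fst: sum(pi_T - pi_S) / sum(pi_T) over usable sites."""
    num = den = 0.0
    usable = 0
    for site in sites:
        fr = _site_freqs(site, pools_a, pools_b)
        if fr is None:
            continue
        usable += 1
        p_a, p_b = fr
        pbar = 0.5 * (p_a + p_b)
        pi_t = 2.0 * pbar * (1.0 - pbar)
        pi_s = (2.0 * p_a * (1.0 - p_a) + 2.0 * p_b * (1.0 - p_b)) / 2.0
        num += pi_t - pi_s
        den += pi_t
    if usable == 0:
        raise DataError("window has no usable sites for Fst")
    if den == 0.0:
        warnings.warn("window monomorphic across both groups; Fst reported as 0")
        return 0.0
    return num / den


# ---------------------------------------------------------------------------
# Vectorized scan


def _check_sorted(chrom: np.ndarray, pos: np.ndarray) -> None:
    # sites must be coordinate-sorted within each chromosome block
    change = np.flatnonzero(chrom[1:] != chrom[:-1])
    bounds = np.concatenate(([0], change + 1, [len(pos)]))
    seen: set = set()
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        if lo == hi:
            continue
        c = chrom[lo]
        if c in seen:
            raise DataError(f"sites for chromosome {c!r} are not contiguous")
        seen.add(c)
        if np.any(np.diff(pos[lo:hi]) < 0):
            raise DataError(f"sites on {c!r} are not coordinate-sorted")


def scan_genome(
    table: SiteTable,
    comparison: Comparison,
    windows: pd.DataFrame,
    min_snps: int = 10,
) -> tuple[pd.DataFrame, ScanSummary]:
    """Compute n_snps, Fst and per-group Hp for every window.

    Only biallelic SNPs enter the scan.  Windows with ``n_snps <= min_snps``
    are flagged ``excluded`` and play no part in summary moments or rank
    selection.  Input must be coordinate-sorted (no silent sorting).
    """
    _check_sorted(table.chrom, table.pos)
    eligible = table.is_biallelic & ~table.is_indel
    snp = table.subset(eligible)

    ra, aa = snp.group_counts(comparison.pools_a)
    rb, ab = snp.group_counts(comparison.pools_b)
    da, db = ra + aa, rb + ab
    usable = (da > 0) & (db > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        pa = np.where(da > 0, aa / np.maximum(da, 1), 0.0)
        pb = np.where(db > 0, ab / np.maximum(db, 1), 0.0)
    pbar = 0.5 * (pa + pb)
    pi_t = 2.0 * pbar * (1.0 - pbar)
    pi_s = pa * (1.0 - pa) + pb * (1.0 - pb)
    num = np.where(usable, pi_t - pi_s, 0.0)
    den = np.where(usable, pi_t, 0.0)

    group_cols = {}
    for label, pools in ((comparison.label_a, comparison.pools_a),
                         (comparison.label_b, comparison.pools_b)):
        r, a = (ra, aa) if pools == comparison.pools_a else (rb, ab)
        maj = np.maximum(r, a).astype(float)
        mnr = np.minimum(r, a).astype(float)
        group_cols[label] = (maj, mnr)

    # per-chromosome cumulative sums, window sums via searchsorted
    out_rows = []
    chroms = pd.unique(windows["chrom"])
    chrom_arr = snp.chrom
    for chrom in chroms:
        mask = chrom_arr == chrom
        pos0 = snp.pos[mask] - 1
        def csum(x: np.ndarray) -> np.ndarray:
            return np.concatenate(([0.0], np.cumsum(x[mask])))
        c_ones = csum(np.ones(len(snp)))
        c_num, c_den = csum(num), csum(den)
        c_hp = {g: (csum(m), csum(n)) for g, (m, n) in group_cols.items()}
        wsub = windows[windows["chrom"] == chrom]
        lo = np.searchsorted(pos0, wsub["start"].to_numpy(), side="left")
        hi = np.searchsorted(pos0, wsub["end"].to_numpy(), side="left")
        n_snps = (c_ones[hi] - c_ones[lo]).astype(int)
        wnum = c_num[hi] - c_num[lo]
        wden = c_den[hi] - c_den[lo]
        with np.errstate(invalid="ignore", divide="ignore"):
            fst = np.where(wden > 0, wnum / np.where(wden > 0, wden, 1.0), 0.0)
        row = {
            "chrom": wsub["chrom"].to_numpy(),
            "start": wsub["start"].to_numpy(),
            "end": wsub["end"].to_numpy(),
            "n_snps": n_snps,
            "fst": fst,
        }
        for g, (cm, cn) in c_hp.items():
            m = cm[hi] - cm[lo]
            n_ = cn[hi] - cn[lo]
            tot = m + n_
            with np.errstate(invalid="ignore", divide="ignore"):
                hp = np.where(tot > 0, 2.0 * m * n_ / np.where(tot > 0, tot, 1.0) ** 2, np.nan)
            row[f"hp_{g}"] = hp
        out_rows.append(pd.DataFrame(row))
    stats = pd.concat(out_rows, ignore_index=True) if out_rows else pd.DataFrame(
        columns=["chrom", "start", "end", "n_snps", "fst"])
    stats["excluded"] = stats["n_snps"] <= min_snps

    retained = stats[~stats["excluded"]]
    hp_cols = [c for c in stats.columns if c.startswith("hp_")]
    summary = ScanSummary(
        n_windows=len(stats),
        n_retained=len(retained),
        fst_mean=float(retained["fst"].mean()) if len(retained) else float("nan"),
        fst_std=float(retained["fst"].std(ddof=0)) if len(retained) else float("nan"),
        hp_mean={c[3:]: float(retained[c].mean()) if len(retained) else float("nan")
                 for c in hp_cols},
        hp_std={c[3:]: float(retained[c].std(ddof=0)) if len(retained) else float("nan")
                for c in hp_cols},
        genome_hp=_genome_hp(group_cols),
    )
    return stats, summary


def _genome_hp(group_cols: dict[str, tuple[np.ndarray, np.ndarray]]) -> dict[str, float]:
    out = {}
    for g, (maj, mnr) in group_cols.items():
        tot = maj.sum() + mnr.sum()
        out[g] = float(2.0 * maj.sum() * mnr.sum() / (tot * tot)) if tot > 0 else float("nan")
    return out


def site_statistics(table: SiteTable, comparison: Comparison) -> pd.DataFrame:
    """Per-SNP Fst, per-group Hp and |delta AF| (for single-SNP plots/tables)."""
    eligible = table.is_biallelic & ~table.is_indel
    snp = table.subset(eligible)
    ra, aa = snp.group_counts(comparison.pools_a)
    rb, ab = snp.group_counts(comparison.pools_b)
    da, db = ra + aa, rb + ab
    usable = (da > 0) & (db > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        pa = np.where(da > 0, aa / np.maximum(da, 1), np.nan)
        pb = np.where(db > 0, ab / np.maximum(db, 1), np.nan)
    pbar = 0.5 * (pa + pb)
    pi_t = 2.0 * pbar * (1.0 - pbar)
    pi_s = pa * (1.0 - pa) + pb * (1.0 - pb)
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where(pi_t > 0, (pi_t - pi_s) / np.where(pi_t > 0, pi_t, 1.0), 0.0)
    fst = np.where(usable, fst, np.nan)

    def hp(r: np.ndarray, a: np.ndarray) -> np.ndarray:
        tot = r + a
        maj = np.maximum(r, a).astype(float)
        mnr = np.minimum(r, a).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot > 0, 2.0 * maj * mnr / np.where(tot > 0, tot, 1) ** 2, np.nan)

    return pd.DataFrame({
        "chrom": snp.chrom, "pos": snp.pos,
        "fst": fst,
        f"hp_{comparison.label_a}": hp(ra, aa),
        f"hp_{comparison.label_b}": hp(rb, ab),
        "delta_af": np.abs(pa - pb),
    })


# ---------------------------------------------------------------------------
# Selection and merging


def select_windows(stats: pd.DataFrame, rule: SelectionRule) -> pd.DataFrame:
    """Windows in the Fst top-k AND the Hp bottom-l of at least one group.

    Thresholds are the k-th largest Fst value and the l-th smallest Hp value
    per group over retained windows, so boundary ties are all admitted and
    the output does not depend on row order.  If fewer windows are retained
    than k or l, the thresholds clamp to all windows with a warning.
    """
    retained = stats[~stats["excluded"]] if "excluded" in stats else stats
    hp_cols = [c for c in retained.columns if c.startswith("hp_")]
    if len(hp_cols) != 2:
        raise ConfigError(f"expected two hp_<group> columns, found {hp_cols}")
    n = len(retained)
    if n == 0:
        return retained.copy()
    k, l = rule.top_k_fst, rule.bottom_l_hp
    if n < k or n < l:
        warnings.warn(f"only {n} retained windows; clamping selection ranks to all windows")
        k, l = min(k, n), min(l, n)

    fst = retained["fst"].to_numpy(dtype=float)
    fst_thr = np.sort(fst)[::-1][k - 1]
    crit_fst = fst >= fst_thr

    crit_hp = np.zeros(n, dtype=bool)
    for col in hp_cols:
        hp = retained[col].to_numpy(dtype=float)
        finite = np.sort(hp[~np.isnan(hp)])
        if len(finite) == 0:
            continue
        thr = finite[min(l, len(finite)) - 1]
        with np.errstate(invalid="ignore"):
            crit_hp |= np.where(np.isnan(hp), False, hp <= thr)

    selected = retained[crit_fst & crit_hp].copy()
    selected.attrs["fst_threshold"] = float(fst_thr)
    return selected


def merge_regions(selected: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping or abutting selected windows into continuous regions.

    Returns one row per region with member window ids (the input index
    labels), the maximum member Fst and the minimum member Hp over both
    groups; regions come out sorted and non-overlapping.
    """
    hp_cols = [c for c in selected.columns if c.startswith("hp_")]
    rows = []
    for chrom, sub in selected.groupby("chrom", sort=True):
        sub = sub.sort_values("start")
        cur: dict | None = None
        for idx, w in sub.iterrows():
            w_hp = np.nanmin([w[c] for c in hp_cols]) if hp_cols else np.nan
            if cur is not None and w["start"] <= cur["end"]:
                cur["end"] = max(cur["end"], int(w["end"]))
                cur["windows"].append(idx)
                cur["max_fst"] = max(cur["max_fst"], float(w["fst"]))
                cur["min_hp"] = np.nanmin([cur["min_hp"], w_hp])
            else:
                if cur is not None:
                    rows.append(cur)
                cur = {
                    "chrom": chrom, "start": int(w["start"]), "end": int(w["end"]),
                    "windows": [idx], "max_fst": float(w["fst"]), "min_hp": float(w_hp),
                }
        if cur is not None:
            rows.append(cur)
    out = pd.DataFrame(rows, columns=["chrom", "start", "end", "windows", "max_fst", "min_hp"])
    out["n_windows"] = out["windows"].map(len) if len(out) else []
    return out
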