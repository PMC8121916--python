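"""Pool-seq strain-differentiation scan: filters, F_ST, Woolf and CMH tests.

Replicated pools of E-trapped and Z-trapped males (one E/Z pair per
collection site) give per-site allele read counts.  After coverage and
minor-allele filters, differentiation between the pheromone strains is
summarized two ways: windowed F_ST between the pools of each pair, and a
Cochran-Mantel-Haenszel test that combines the per-site 2x2 (pool x allele)
tables across collection sites, applied only to sites whose odds ratios are
homogeneous across sites by a Woolf test.  P values are FDR-corrected
genome-wide (Benjamini-Hochberg).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .io_formats import PoolCounts, ValidationError
from .hwescan import bh_fdr


@dataclass
class PoolScanSettings:
    min_cov: int = 10
    max_cov: int = 200
    min_count: int = 2
    indel_window_bp: int = 5
    woolf_alpha: float = 0.05  # sites with Woolf p > alpha proceed to CMH
    continuity: bool = True
    #: rescale read counts to the effective pool coverage
    #: 1/(1/coverage + 1/haploid_pool_size) before the Woolf/CMH tests, so
    #: the tests see both read noise and individual-sampling noise; without
    #: it the CMH is badly anticonservative whenever depth approaches or
    #: exceeds the haploid pool size
    effective_size: bool = True
    window_bp: int = 1000
    q_threshold: float = 0.01


@dataclass
class PoolScanResult:
    sites: pd.DataFrame
    windows: pd.DataFrame
    settings: PoolScanSettings = field(default_factory=PoolScanSettings)


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def filter_sites(
    pc: PoolCounts,
    min_cov: int = 10,
    max_cov: int = 200,
    min_count: int = 2,
    indel_window_bp: int = 5,
    indel_positions: list[tuple[str, int]] | None = None,
) -> np.ndarray:
    """Boolean pass flag per site.

    A site passes iff every pool's coverage lies in [min_cov, max_cov], the
    site-wide minor allele appears at least ``min_count`` times in each
    population (the summed E+Z pools of each collection site), and no known
    indel lies within ``indel_window_bp``.
    """
    cov = pc.coverage  # (n_sites, n_pools)
    ok = ((cov >= min_cov) & (cov <= max_cov)).all(axis=1)
    totals = pc.counts.sum(axis=1)  # (n_sites, 2)
    minor_is_alt = totals[:, 1] <= totals[:, 0]
    for _, ke, kz in pc.pool_pairs():
        per_pop = pc.counts[:, ke, :] + pc.counts[:, kz, :]
        minor = np.where(minor_is_alt, per_pop[:, 1], per_pop[:, 0])
        ok &= minor >= min_count
    if indel_positions:
        chrom = np.array([s.chrom for s in pc.sites])
        pos = np.array([s.pos for s in pc.sites], dtype=np.int64)
        for ic, ip in indel_positions:
            ok &= ~((chrom == ic) & (np.abs(pos - ip) <= indel_window_bp))
    return ok


# ---------------------------------------------------------------------------
# F_ST
# ---------------------------------------------------------------------------

def site_fst(
    p_E: float | np.ndarray,
    p_Z: float | np.ndarray,
    cov_E: float | np.ndarray,
    cov_Z: float | np.ndarray,
    pool_size_E: int,
    pool_size_Z: int,
) -> float | np.ndarray:
    """Classic pool-seq F_ST: (pi_total - pi_within) / pi_total.

    Heterozygosity pi = 2p(1-p) is corrected by n/(n-1) with
    n = min(coverage, haploid pool size); pi_within averages the two pools
    and pi_total uses the mean frequency with the smaller of the two
    corrected sizes.  Undefined (NaN) where pi_total = 0; clipped to [0,1].
    """
    p_E = np.asarray(p_E, dtype=float)
    p_Z = np.asarray(p_Z, dtype=float)
    n_E = np.minimum(np.asarray(cov_E, dtype=float), pool_size_E)
    n_Z = np.minimum(np.asarray(cov_Z, dtype=float), pool_size_Z)
    with np.errstate(invalid="ignore", divide="ignore"):
        pi_E = 2 * p_E * (1 - p_E) * n_E / np.maximum(n_E - 1, 1e-300)
        pi_Z = 2 * p_Z * (1 - p_Z) * n_Z / np.maximum(n_Z - 1, 1e-300)
        pi_within = (pi_E + pi_Z) / 2.0
        p_t = (p_E + p_Z) / 2.0
        n_t = np.minimum(n_E, n_Z)
        pi_total = 2 * p_t * (1 - p_t) * n_t / np.maximum(n_t - 1, 1e-300)
        fst = np.where(pi_total > 0,
                       (pi_total - pi_within) / np.where(pi_total > 0,
                                                         pi_total, 1.0),
                       np.nan)
    out = np.clip(fst, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def pair_fst_track(pc: PoolCounts, mask: np.ndarray | None = None) -> pd.DataFrame:
    """Per-site F_ST for each E/Z pool pair (long frame: site_label, fst)."""
    if mask is None:
        mask = np.ones(len(pc.sites), dtype=bool)
    cov = pc.coverage
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(cov > 0, pc.counts[:, :, 1] / np.maximum(cov, 1), np.nan)
    frames = []
    for label, ke, kz in pc.pool_pairs():
        fst = site_fst(freq[:, ke], freq[:, kz], cov[:, ke], cov[:, kz],
                       pc.pools[ke].haploid_size, pc.pools[kz].haploid_size)
        frames.append(pd.DataFrame({
            "chrom": [s.chrom for s in pc.sites],
            "pos": [s.pos for s in pc.sites],
            "site_label": label,
            "fst": np.where(mask, fst, np.nan),
        }))
    return pd.concat(frames, ignore_index=True)


def window_fst(track: pd.DataFrame, window_bp: int = 1000) -> pd.DataFrame:
    """Mean F_ST in non-overlapping windows tiling [1, max pos] per chrom.

    Means are per pool pair and, in ``mean_fst``, averaged across pairs
    (over pairs with a defined window mean).  Empty windows are NaN.
    """
    labels = sorted(track["site_label"].unique())
    frames = []
    for chrom, sub in track.groupby("chrom", sort=True):
        top = int(sub["pos"].max())
        starts = np.arange(1, top + 1, window_bp, dtype=np.int64)
        win_of = (sub["pos"] - 1) // window_bp
        per_pair = (sub.assign(win=win_of)
                    .pivot_table(index="win", columns="site_label",
                                 values="fst", aggfunc="mean"))
        per_pair = per_pair.reindex(index=np.arange(len(starts)),
                                    columns=labels)
        df = pd.DataFrame({
            "chrom": chrom,
            "start": starts,
            "end": starts + window_bp - 1,
        })
        for label in labels:
            df[f"fst_{label}"] = per_pair[label].to_numpy()
        vals = per_pair.to_numpy(dtype=float)
        cnt = (~np.isnan(vals)).sum(axis=1)
        tot = np.nansum(vals, axis=1)
        df["mean_fst"] = np.where(cnt > 0, tot / np.maximum(cnt, 1), np.nan)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Woolf heterogeneity and CMH
# ---------------------------------------------------------------------------

def woolf_test(tables: np.ndarray) -> float:
    """Woolf chi-square test of odds-ratio homogeneity across strata.

    ``tables`` is (K, 2, 2); the Haldane-Anscombe correction (+0.5 to every
    cell) removes zero cells.  The statistic is the inverse-variance
    weighted dispersion of log odds ratios, chi-square with K-1 df.
    """
    t = np.asarray(tables, dtype=float)
    if t.ndim != 3 or t.shape[1:] != (2, 2):
        raise ValidationError("expected K x 2 x 2 tables")
    if t.shape[0] < 2:
        raise ValidationError("Woolf test needs at least 2 strata")
    t = t + 0.5
    ln_or = np.log(t[:, 0, 0] * t[:, 1, 1] / (t[:, 0, 1] * t[:, 1, 0]))
    w = 1.0 / (1.0 / t[:, 0, 0] + 1.0 / t[:, 0, 1]
               + 1.0 / t[:, 1, 0] + 1.0 / t[:, 1, 1])
    mean_lor = (w * ln_or).sum() / w.sum()
    stat = (w * (ln_or - mean_lor) ** 2).sum()
    return float(chi2.sf(stat, df=t.shape[0] - 1))


def cmh_test(
    tables: np.ndarray, continuity: bool = True
) -> tuple[float, float]:
    """Cochran-Mantel-Haenszel test across K 2x2 strata.

    Returns (statistic, p).  With hypergeometric stratum means and
    variances, stat = (|sum(a - E a)| - 0.5*continuity)^2 / sum(Var a),
    chi-square with 1 df.  All-degenerate margins give (NaN, NaN).
    """
    t = np.asarray(tables, dtype=float)
    if t.ndim != 3 or t.shape[1:] != (2, 2):
        raise ValidationError("expected K x 2 x 2 tables")
    a = t[:, 0, 0]
    r1 = t[:, 0, :].sum(1)
    r2 = t[:, 1, :].sum(1)
    c1 = t[:, :, 0].sum(1)
    c2 = t[:, :, 1].sum(1)
    n = t.sum(axis=(1, 2))
    ok = n > 1
    with np.errstate(invalid="ignore", divide="ignore"):
        e = np.where(ok, r1 * c1 / np.maximum(n, 1), 0.0)
        v = np.where(ok, r1 * r2 * c1 * c2
                     / np.maximum(n * n * (n - 1), 1e-300), 0.0)
    var = v.sum()
    if var <= 0:
        return float("nan"), float("nan")
    num = abs((a - e).sum()) - (0.5 if continuity else 0.0)
    num = max(num, 0.0)
    stat = num * num / var
    return float(stat), float(chi2.sf(stat, df=1))


def site_tables(pc: PoolCounts, effective_size: bool = False) -> np.ndarray:
    """(n_sites, K, 2, 2) read-count tables, rows E/Z pool, cols ref/alt.

    With ``effective_size`` the counts of each pool are scaled down to the
    effective coverage 1/(1/coverage + 1/haploid_pool_size), the variance-
    matched sample size of pooled sequencing.
    """
    pairs = pc.pool_pairs()
    tabs = np.empty((len(pc.sites), len(pairs), 2, 2), dtype=float)
    for k, (_, ke, kz) in enumerate(sorted(pairs)):
        tabs[:, k, 0, :] = pc.counts[:, ke, :]
        tabs[:, k, 1, :] = pc.counts[:, kz, :]
        if effective_size:
            for row, kp in ((0, ke), (1, kz)):
                cov = pc.counts[:, kp, :].sum(axis=1).astype(float)
                n_h = pc.pools[kp].haploid_size
                with np.errstate(divide="ignore", invalid="ignore"):
                    eff = np.where(cov > 0,
                                   1.0 / (1.0 / np.maximum(cov, 1e-300)
                                          + 1.0 / n_h), 0.0)
                    scale = np.where(cov > 0, eff / np.maximum(cov, 1e-300), 0.0)
                tabs[:, k, row, :] *= scale[:, None]
    return tabs


def scan_pools(
    pc: PoolCounts,
    settings: PoolScanSettings | None = None,
    indel_positions: list[tuple[str, int]] | None = None,
) -> PoolScanResult:
    """Full pool scan: filter -> Woolf -> CMH -> BH FDR -> windowed F_ST."""
    st = settings or PoolScanSettings()
    if len(pc.sites) == 0:
        empty = pd.DataFrame(columns=[
            "chrom", "pos", "pass_filter", "woolf_p", "woolf_pass",
            "cmh_stat", "cmh_p", "neg_log10_p", "q"])
        return PoolScanResult(sites=empty, windows=pd.DataFrame(
            columns=["chrom", "start", "end", "mean_fst"]), settings=st)
    ok = filter_sites(pc, st.min_cov, st.max_cov, st.min_count,
                      st.indel_window_bp, indel_positions)
    tabs = site_tables(pc, effective_size=st.effective_size)
    n_sites = len(pc.sites)
    woolf_p = np.full(n_sites, np.nan)
    cmh_stat = np.full(n_sites, np.nan)
    cmh_p = np.full(n_sites, np.nan)
    for j in np.flatnonzero(ok):
        woolf_p[j] = woolf_test(tabs[j])
        if woolf_p[j] > st.woolf_alpha:
            cmh_stat[j], cmh_p[j] = cmh_test(tabs[j], st.continuity)
    q = np.full(n_sites, np.nan)
    tested = ~np.isnan(cmh_p)
    if tested.any():
        q[tested] = bh_fdr(np.clip(cmh_p[tested], 1e-300, 1.0))
    with np.errstate(divide="ignore"):
        nlp = np.where(tested, -np.log10(np.clip(cmh_p, 1e-300, None)), np.nan)
    sites_df = pd.DataFrame({
        "chrom": [s.chrom for s in pc.sites],
        "pos": [s.pos for s in pc.sites],
        "pass_filter": ok,
        "woolf_p": woolf_p,
        "woolf_pass": np.where(np.isnan(woolf_p), False,
                               woolf_p > st.woolf_alpha),
        "cmh_stat": cmh_stat,
        "cmh_p": cmh_p,
        "neg_log10_p": nlp,
        "q": q,
    })
    windows = window_fst(pair_fst_track(pc, mask=ok), st.window_bp)
    return PoolScanResult(sites=sites_df, windows=windows, settings=st)
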