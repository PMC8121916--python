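"""Signal-locus linkage-disequilibrium scan with empirical nulls.

The first signature of positive assortative mating is statistical
association (r²) between alleles at the autosomal signal locus and alleles
at the Z-linked preference locus, despite their physical independence.  The
scan computes, for every Z-linked variant, the maximum r² against a set of
focal signal-locus variants (the nonsynonymous signal-gene SNPs), and
locates that maximum relative to an empirical null distribution built from
physically unlinked variant pairs (different chromosomes, or at least 1 Mb
apart).

Pairwise r² on unphased diploid genotypes is obtained by maximum-likelihood
haplotype-frequency estimation: a two-locus EM (expectation over the phase
of double heterozygotes) that is exact for pairwise r² and replaces any
external phasing step.  The EM runs from three starts (linkage equilibrium
and both Lewontin bounds) and keeps the highest-likelihood solution, which
makes it robust to the occasional second mode of the two-locus likelihood.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import MISSING, GenotypeMatrix, ValidationError, VariantSite

logger = logging.getLogger("assortscan")

DEFAULT_MIN_N = 10


@dataclass
class HaplotypeFreqs:
    """Two-locus haplotype-frequency estimate and derived LD statistics."""

    pA: float
    pB: float
    pAB: float
    D: float
    r2: float  # NaN when either locus is monomorphic
    n_eff: int
    converged: bool
    iterations: int

    @property
    def defined(self) -> bool:
        return not np.isnan(self.r2)


@dataclass
class LDScanResult:
    """Per-target-site maximum r² against the focal set."""

    target_sites: list[VariantSite]
    max_r2: np.ndarray
    argmax_focal: list[VariantSite | None]
    n_eff: np.ndarray
    null_threshold: float | None = None
    null_percentile: float | None = None
    flags: np.ndarray | None = None

    def apply_threshold(self, threshold: float, percentile: float | None = None):
        self.null_threshold = float(threshold)
        self.null_percentile = percentile
        with np.errstate(invalid="ignore"):
            self.flags = np.nan_to_num(self.max_r2, nan=-1.0) > threshold
        return self

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "chrom": [s.chrom for s in self.target_sites],
            "pos": [s.pos for s in self.target_sites],
            "max_r2": self.max_r2,
            "focal_chrom": [None if f is None else f.chrom
                            for f in self.argmax_focal],
            "focal_pos": [None if f is None else f.pos
                          for f in self.argmax_focal],
            "n_eff": self.n_eff,
            "flag": (self.flags if self.flags is not None
                     else np.zeros(len(self.target_sites), bool)),
        })


# ---------------------------------------------------------------------------
# EM core (vectorized over many 3x3 genotype count tables)
# ---------------------------------------------------------------------------

def _em_batch(tables: np.ndarray, tol: float = 1e-12, max_iter: int = 1000):
    """Run the two-locus EM on a batch of 3x3 genotype count tables.

    ``tables[p, i, j]`` counts samples with dosage i at locus A and j at
    locus B.  Returns (pA, pB, pAB, converged, iterations) arrays; entries
    with a monomorphic margin get pAB = pA*pB (r² is NaN downstream).
    """
    t = np.asarray(tables, dtype=float)
    if t.ndim == 2:
        t = t[None]
    n = t.sum(axis=(1, 2))
    twoN = np.maximum(2.0 * n, 1.0)
    # haplotype counts fully determined by non-double-heterozygous cells
    nAB0 = 2 * t[:, 2, 2] + t[:, 2, 1] + t[:, 1, 2]
    nAb0 = 2 * t[:, 2, 0] + t[:, 2, 1] + t[:, 1, 0]
    naB0 = 2 * t[:, 0, 2] + t[:, 0, 1] + t[:, 1, 2]
    nab0 = 2 * t[:, 0, 0] + t[:, 0, 1] + t[:, 1, 0]
    ndh = t[:, 1, 1]
    pA = (2 * t[:, 2, :].sum(1) + t[:, 1, :].sum(1)) / twoN
    pB = (2 * t[:, :, 2].sum(1) + t[:, :, 1].sum(1)) / twoN

    lo = np.maximum(0.0, pA + pB - 1.0)
    hi = np.minimum(pA, pB)
    eps = 1e-9
    starts = [
        pA * pB,
        np.clip(hi - 1e-3, lo + eps, hi - eps),
        np.clip(lo + 1e-3, lo + eps, hi - eps),
    ]

    def loglik(pAB):
        f = np.stack([pAB, pA - pAB, pB - pAB, 1 - pA - pB + pAB])
        f = np.clip(f, 1e-300, None)
        cis = f[0] * f[3] + f[1] * f[2]
        return (nAB0 * np.log(f[0]) + nAb0 * np.log(f[1])
                + naB0 * np.log(f[2]) + nab0 * np.log(f[3])
                + ndh * np.log(np.clip(cis, 1e-300, None)))

    best_pAB = np.full_like(pA, np.nan)
    best_ll = np.full_like(pA, -np.inf)
    best_iters = np.zeros(pA.shape, dtype=int)
    best_conv = np.zeros(pA.shape, dtype=bool)
    for s0 in starts:
        pAB = np.clip(s0, lo, hi)
        conv = np.zeros(pA.shape, dtype=bool)
        iters = np.zeros(pA.shape, dtype=int)
        for it in range(1, max_iter + 1):
            pAb = pA - pAB
            paB = pB - pAB
            pab = 1.0 - pA - pB + pAB
            num = pAB * pab
            den = num + pAb * paB
            pcis = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.5)
            new = (nAB0 + ndh * pcis) / twoN
            new = np.clip(new, lo, hi)
            moved = ~conv
            delta = np.abs(new - pAB)
            pAB = np.where(moved, new, pAB)
            iters = np.where(moved, it, iters)
            conv = conv | (delta < tol)
            if conv.all():
                break
        ll = loglik(pAB)
        take = ll > best_ll + 1e-12
        best_pAB = np.where(take, pAB, best_pAB)
        best_ll = np.where(take, ll, best_ll)
        best_iters = np.where(take, iters, best_iters)
        best_conv = np.where(take, conv, best_conv)
    return pA, pB, best_pAB, best_conv, best_iters, n.astype(int)


def _r2_from(pA, pB, pAB):
    with np.errstate(invalid="ignore", divide="ignore"):
        D = pAB - pA * pB
        var = pA * (1 - pA) * pB * (1 - pB)
        r2 = np.where(var > 0, D * D / np.where(var > 0, var, 1.0), np.nan)
    return D, r2


def em_haplotype_freqs(
    dosA: np.ndarray,
    dosB: np.ndarray,
    tol: float = 1e-12,
    max_iter: int = 1000,
) -> HaplotypeFreqs:
    """Maximum-likelihood haplotype frequencies and r² for one locus pair.

    Missing calls are excluded pairwise.  A monomorphic locus yields an
    undefined (NaN) r² rather than an exception.
    """
    dosA = np.asarray(dosA)
    dosB = np.asarray(dosB)
    if dosA.shape != dosB.shape:
        raise ValidationError("dosage vectors differ in length")
    ok = (dosA != MISSING) & (dosB != MISSING)
    if ok.sum() < 2:
        raise ValidationError("fewer than 2 pairwise-complete samples")
    table = np.zeros((3, 3))
    np.add.at(table, (dosA[ok], dosB[ok]), 1)
    pA, pB, pAB, conv, iters, n = _em_batch(table, tol=tol, max_iter=max_iter)
    D, r2 = _r2_from(pA, pB, pAB)
    return HaplotypeFreqs(
        pA=float(pA[0]), pB=float(pB[0]), pAB=float(pAB[0]),
        D=float(D[0]), r2=float(r2[0]), n_eff=int(n[0]),
        converged=bool(conv[0]), iterations=int(iters[0]),
    )


def haplotype_r2(hapA: np.ndarray, hapB: np.ndarray) -> float:
    """r² as the squared Pearson correlation of known haplotype indicators."""
    hapA = np.asarray(hapA, float).ravel()
    hapB = np.asarray(hapB, float).ravel()
    ok = (hapA != MISSING) & (hapB != MISSING)
    a, b = hapA[ok], hapB[ok]
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1] ** 2)


# ---------------------------------------------------------------------------
# pair machinery
# ---------------------------------------------------------------------------

def _ld_dosage(G: GenotypeMatrix) -> np.ndarray:
    """Dosage matrix for LD with hemizygous calls masked out.

    The scans treat every call as diploid; a hemizygous (single-haplotype)
    female Z call would bias the genotype table, so such entries are
    excluded pairwise, with a logged count.
    """
    dos = G.dosage.copy()
    if G.phase is not None:
        hemi = (G.phase[:, 0, :] != MISSING) & (G.phase[:, 1, :] == MISSING)
        n_hemi = int(hemi.sum())
        if n_hemi:
            logger.warning(
                "excluding %d hemizygous calls from LD estimation", n_hemi)
            dos[hemi] = MISSING
    return dos


def _pair_r2(dosA: np.ndarray, dosB: np.ndarray, min_n: int = DEFAULT_MIN_N):
    """r² for aligned column pairs: dosA[:, p] versus dosB[:, p]."""
    tables = np.zeros((dosA.shape[1], 3, 3))
    for i in range(3):
        ai = dosA == i
        for j in range(3):
            tables[:, i, j] = (ai & (dosB == j)).sum(axis=0)
    pA, pB, pAB, conv, iters, n = _em_batch(tables)
    _, r2 = _r2_from(pA, pB, pAB)
    r2 = np.where(n >= min_n, r2, np.nan)
    return r2, n


def focal_ld_scan(
    G: GenotypeMatrix,
    focal_sites: list[tuple[str, int]],
    target_chrom: str,
    min_n: int = DEFAULT_MIN_N,
    include_focal_chrom_targets: bool = False,
) -> LDScanResult:
    """Maximum r² between each target-chromosome site and the focal set.

    ``focal_sites`` are (chrom, pos) pairs, e.g. the nonsynonymous variants
    of the signal gene; focal sites absent from the matrix or with
    all-missing data are skipped with a logged count.  Ties for the argmax
    focal partner go to the lowest (chrom, pos).
    """
    if not focal_sites:
        raise ValidationError("focal site list is empty")
    dos = _ld_dosage(G)
    keys = {(s.chrom, s.pos): j for j, s in enumerate(G.sites)}
    focal_idx = []
    n_skipped = 0
    for chrom, pos in sorted(set(focal_sites)):
        j = keys.get((chrom, pos))
        if j is None or (dos[:, j] == MISSING).all():
            n_skipped += 1
            continue
        focal_idx.append(j)
    if n_skipped:
        logger.warning("skipped %d focal sites lacking coverage", n_skipped)
    if not focal_idx:
        raise ValidationError("no focal site has any genotype data")
    target_idx = [j for j, s in enumerate(G.sites)
                  if s.chrom == target_chrom
                  and (include_focal_chrom_targets or j not in focal_idx)]
    if not target_idx:
        raise ValidationError(f"no target sites on {target_chrom!r}")

    A = dos[:, focal_idx]  # (n, F)
    B = dos[:, target_idx]  # (n, T)
    F, T = A.shape[1], B.shape[1]
    tables = np.zeros((F, T, 3, 3))
    for i in range(3):
        ai = (A == i).astype(float)
        for j in range(3):
            bj = (B == j).astype(float)
            tables[:, :, i, j] = ai.T @ bj
    pA, pB, pAB, conv, iters, n = _em_batch(tables.reshape(F * T, 3, 3))
    _, r2 = _r2_from(pA, pB, pAB)
    r2 = r2.reshape(F, T)
    n = n.reshape(F, T)
    r2 = np.where(n >= min_n, r2, np.nan)

    all_nan = np.isnan(r2).all(axis=0)
    max_r2 = np.full(T, np.nan)
    arg = np.zeros(T, dtype=int)
    cols = ~all_nan
    if cols.any():
        with np.errstate(all="ignore"):
            max_r2[cols] = np.nanmax(r2[:, cols], axis=0)
            # first (lowest chrom,pos) focal index attaining the max
            hit = np.isnan(r2[:, cols]) | (r2[:, cols] < max_r2[cols] - 0.0)
            arg[cols] = np.argmin(hit, axis=0)
    argmax_focal: list[VariantSite | None] = []
    n_eff = np.zeros(T, dtype=int)
    for tj in range(T):
        if all_nan[tj]:
            argmax_focal.append(None)
        else:
            argmax_focal.append(G.sites[focal_idx[arg[tj]]])
            n_eff[tj] = n[arg[tj], tj]
    return LDScanResult(
        target_sites=[G.sites[j] for j in target_idx],
        max_r2=max_r2,
        argmax_focal=argmax_focal,
        n_eff=n_eff,
    )


def empirical_null_threshold(
    G: GenotypeMatrix,
    percentile: float = 99.99,
    min_dist_bp: int = 1_000_000,
    min_pairs: int = 10_000,
    max_pairs: int = 10_000,
    min_n: int = DEFAULT_MIN_N,
    seed: int = 0,
    return_values: bool = False,
):
    """r² threshold at a percentile of the unlinked-pair null distribution.

    Qualifying pairs are separated by at least ``min_dist_bp`` on the same
    chromosome or lie on different chromosomes.  When more than
    ``max_pairs`` qualify, a seeded uniform subsample is scored.  The
    percentile uses linear interpolation between order statistics.
    """
    if not 0.0 < percentile < 100.0:
        raise ValidationError("percentile must be in (0, 100)")
    dos = _ld_dosage(G)
    chroms = np.array([s.chrom for s in G.sites])
    pos = np.array([s.pos for s in G.sites], dtype=np.int64)
    ii, jj = np.triu_indices(len(G.sites), k=1)
    qual = (chroms[ii] != chroms[jj]) | (np.abs(pos[ii] - pos[jj]) >= min_dist_bp)
    ii, jj = ii[qual], jj[qual]
    if len(ii) < min_pairs:
        raise ValidationError(
            f"only {len(ii)} qualifying unlinked pairs (< {min_pairs})")
    if len(ii) > max_pairs:
        take = np.random.default_rng(seed).choice(
            len(ii), size=max_pairs, replace=False)
        ii, jj = ii[take], jj[take]
    r2, _ = _pair_r2(dos[:, ii], dos[:, jj], min_n=min_n)
    r2 = r2[~np.isnan(r2)]
    if r2.size == 0:
        raise ValidationError("no defined r² among qualifying pairs")
    thr = float(np.percentile(r2, percentile, method="linear"))
    return (thr, r2) if return_values else thr


def distance_ld_profile(
    G: GenotypeMatrix,
    chrom: str,
    region_len_bp: int = 15_000,
    n_regions: int = 57,
    min_n: int = DEFAULT_MIN_N,
    seed: int = 0,
    max_tries: int = 100_000,
) -> pd.DataFrame:
    """Within-region pairwise r² versus bp separation on one chromosome.

    ``n_regions`` non-overlapping regions of ``region_len_bp`` are sampled
    uniformly (seeded) along the chromosome span; all within-region site
    pairs are scored.  Returns a frame with columns region, distance, r2.
    """
    dos = _ld_dosage(G)
    on = [j for j, s in enumerate(G.sites) if s.chrom == chrom]
    if not on:
        raise ValidationError(f"no sites on chromosome {chrom!r}")
    pos = np.array([G.sites[j].pos for j in on], dtype=np.int64)
    lo, hi = int(pos.min()), int(pos.max())
    if region_len_bp > hi - lo + 1:
        raise ValidationError("region longer than the chromosome span")
    rng = np.random.default_rng(seed)
    starts: list[int] = []
    tries = 0
    while len(starts) < n_regions:
        tries += 1
        if tries > max_tries:
            raise ValidationError(
                f"could not place {n_regions} non-overlapping regions")
        s = int(rng.integers(lo, hi - region_len_bp + 2))
        if all(abs(s - t) >= region_len_bp for t in starts):
            starts.append(s)
    rows_i, rows_j, region_of = [], [], []
    for r, s in enumerate(sorted(starts)):
        in_reg = np.flatnonzero((pos >= s) & (pos < s + region_len_bp))
        for a in range(len(in_reg)):
            for b in range(a + 1, len(in_reg)):
                rows_i.append(on[in_reg[a]])
                rows_j.append(on[in_reg[b]])
                region_of.append(r)
    if not rows_i:
        return pd.DataFrame(columns=["region", "distance", "r2"])
    r2, _ = _pair_r2(dos[:, rows_i], dos[:, rows_j], min_n=min_n)
    dist = np.abs(np.array([G.sites[j].pos for j in rows_j])
                  - np.array([G.sites[i].pos for i in rows_i]))
    return pd.DataFrame({"region": region_of, "distance": dist, "r2": r2})


def fraction_at_distance(
    profile: pd.DataFrame, distance: int, r2_ref: float
) -> float:
    """Fraction of pairs at exactly this separation with r² >= r2_ref.

    NaN when no pair sits at that distance (undefined).
    """
    at = profile[(profile["distance"] == distance) & profile["r2"].notna()]
    if len(at) == 0:
        return float("nan")
    return float((at["r2"] >= r2_ref).mean())


def sliding_window_r2(
    result: LDScanResult,
    window_bp: int = 1000,
    step_bp: int = 100,
) -> pd.DataFrame:
    """Sliding-window arithmetic mean of max r² along the scanned chromosome.

    Windows are half-open [start, start + window); empty windows are emitted
    with NaN means.
    """
    pos = np.array([s.pos for s in result.target_sites], dtype=np.int64)
    vals = np.asarray(result.max_r2, dtype=float)
    chrom = result.target_sites[0].chrom if result.target_sites else ""
    if len(pos) == 0:
        return pd.DataFrame(columns=["chrom", "start", "end", "mean_r2"])
    first = int(pos.min()) - window_bp + 1
    first = max(1, first - (first - 1) % step_bp)
    starts = np.arange(first, int(pos.max()) + 1, step_bp, dtype=np.int64)
    order = np.argsort(pos)
    pos_s, vals_s = pos[order], vals[order]
    csum = np.concatenate([[0.0], np.nancumsum(vals_s)])
    ccnt = np.concatenate([[0], np.cumsum(~np.isnan(vals_s))])
    left = np.searchsorted(pos_s, starts, side="left")
    right = np.searchsorted(pos_s, starts + window_bp, side="left")
    n_def = ccnt[right] - ccnt[left]
    total = csum[right] - csum[left]
    with np.errstate(invalid="ignore"):
        mean = np.where(n_def > 0, total / np.maximum(n_def, 1), np.nan)
    return pd.DataFrame({
        "chrom": chrom,
        "start": starts,
        "end": starts + window_bp - 1,  # 1-based inclusive
        "mean_r2": mean,
    })
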