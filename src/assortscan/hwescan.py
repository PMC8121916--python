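"""Genome-wide heterozygote-deficit scan (exact Hardy-Weinberg test).

Sampling across two partially isolated mating pools depresses heterozygosity
at every locus whose allele frequencies differ between the pools (the
Wahlund effect), and depresses it most strongly at the loci that determine
the assortment itself.  The scan therefore runs a one-sided exact test for
too few heterozygotes at every polymorphic site of the pooled sample,
controls the FDR genome-wide (Benjamini-Hochberg), and aggregates the
deviant sites per gene interval.

The exact test conditions on the observed allele count: given n diploids
and n_A copies of allele A, the probability of observing h heterozygotes is

    Pr(h) = C * n! 2^h / (n_AA! h! n_aa!),   n_AA = (n_A - h)/2,

with C the normalizing constant over all h of matching parity.  The deficit
P value sums Pr(h') over h' <= h_observed.  Everything is computed in log
space, so counts up to ~1e5 are safe.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from .io_formats import GeneInterval, GenotypeMatrix, ValidationError
from .ldscan import _ld_dosage

DEFAULT_MIN_N = 10


def _het_support(n: int, n_A: int) -> np.ndarray:
    """All heterozygote counts compatible with n diploids and n_A alleles."""
    n_a = 2 * n - n_A
    h_max = min(n_A, n_a)
    h = np.arange(n_A % 2, h_max + 1, 2)
    return h


def _log_probs(n: int, n_A: int) -> tuple[np.ndarray, np.ndarray]:
    h = _het_support(n, n_A)
    n_AA = (n_A - h) // 2
    n_aa = (2 * n - n_A - h) // 2
    lp = (h * np.log(2.0) - gammaln(n_AA + 1) - gammaln(h + 1)
          - gammaln(n_aa + 1))
    lp -= logsumexp(lp)
    return h, lp


def exact_het_deficit(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """One-sided exact P for a deficit of heterozygotes.

    Monomorphic sites, and sites at or beyond maximal heterozygosity for
    their allele count, return 1.
    """
    return exact_hwe(n_AA, n_Aa, n_aa, alternative="deficit")


def exact_hwe(
    n_AA: int, n_Aa: int, n_aa: int, alternative: str = "deficit"
) -> float:
    """Exact Hardy-Weinberg test conditioned on the observed allele count.

    ``alternative``: "deficit" (too few heterozygotes, the directional
    prediction of assortative mating), "excess", or "two-sided" (sum of all
    configurations no more probable than the observed one).
    """
    for c in (n_AA, n_Aa, n_aa):
        if c < 0 or int(c) != c:
            raise ValidationError("genotype counts must be non-negative ints")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValidationError("empty genotype table")
    n_A = 2 * n_AA + n_Aa
    h, lp = _log_probs(n, n_A)
    obs = np.flatnonzero(h == n_Aa)[0]
    if alternative == "deficit":
        tail = lp[: obs + 1]
    elif alternative == "excess":
        tail = lp[obs:]
    elif alternative == "two-sided":
        tail = lp[lp <= lp[obs] + 1e-12]
    else:
        raise ValidationError(f"unknown alternative {alternative!r}")
    return float(min(1.0, np.exp(logsumexp(tail))))


def bh_fdr(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1) | np.isnan(p)):
        raise ValidationError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def f_is(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Inbreeding coefficient 1 - observed/expected heterozygosity."""
    n = n_AA + n_Aa + n_aa
    if n == 0:
        return float("nan")
    p = (2 * n_AA + n_Aa) / (2 * n)
    exp_het = 2 * p * (1 - p)
    if exp_het == 0:
        return float("nan")
    return 1.0 - (n_Aa / n) / exp_het


def site_genotype_counts(G: GenotypeMatrix) -> np.ndarray:
    """(n_sites, 3) counts of hom-ref / het / hom-alt diploid calls.

    Hemizygous calls (single-haplotype female Z genotypes) are excluded:
    the exact test applies to diploid genotypes only.
    """
    dos = _ld_dosage(G)
    return np.stack([(dos == k).sum(axis=0) for k in range(3)], axis=1)


def scan_het_deficit(
    G: GenotypeMatrix,
    intervals: list[GeneInterval] | None = None,
    q_threshold: float = 0.01,
    min_n: int = DEFAULT_MIN_N,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Exact heterozygote-deficit test at every polymorphic site.

    Returns a per-site frame (chrom, pos, n_AA, n_Aa, n_aa, p_deficit, q,
    f_is) over sites with >= ``min_n`` diploid calls and both alleles
    observed, and a per-gene summary (min_p, n_significant at
    q < ``q_threshold``, rank) for the given intervals; genes are ranked by
    n_significant, ties broken by min_p.
    """
    counts = site_genotype_counts(G)
    n_eff = counts.sum(axis=1)
    n_A = 2 * counts[:, 0] + counts[:, 1]  # ref-allele copies
    poly = (n_eff >= min_n) & (n_A > 0) & (n_A < 2 * n_eff)
    idx = np.flatnonzero(poly)
    rows = []
    cache: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = {}
    for j in idx:
        n_rr, n_ra, n_aa = (int(counts[j, 0]), int(counts[j, 1]),
                            int(counts[j, 2]))
        n = n_rr + n_ra + n_aa
        nA = 2 * n_rr + n_ra
        key = (n, nA)
        if key not in cache:
            cache[key] = _log_probs(n, nA)
        h, lp = cache[key]
        obs = np.flatnonzero(h == n_ra)[0]
        p = float(min(1.0, np.exp(logsumexp(lp[: obs + 1]))))
        s = G.sites[j]
        rows.append((s.chrom, s.pos, n_rr, n_ra, n_aa, p,
                     f_is(n_rr, n_ra, n_aa)))
    site_df = pd.DataFrame(
        rows, columns=["chrom", "pos", "n_AA", "n_Aa", "n_aa",
                       "p_deficit", "f_is"])
    if len(site_df):
        site_df["q"] = bh_fdr(site_df["p_deficit"].to_numpy())
    else:
        site_df["q"] = pd.Series(dtype=float)
    site_df = site_df[["chrom", "pos", "n_AA", "n_Aa", "n_aa",
                       "p_deficit", "q", "f_is"]]

    gene_rows = []
    for g in intervals or []:
        inside = site_df[(site_df["chrom"] == g.chrom)
                         & (site_df["pos"] >= g.start)
                         & (site_df["pos"] <= g.end)]
        gene_rows.append((
            g.name, g.chrom, g.start, g.end,
            float(inside["p_deficit"].min()) if len(inside) else np.nan,
            int((inside["q"] < q_threshold).sum()),
            len(inside),
        ))
    gene_df = pd.DataFrame(
        gene_rows, columns=["gene", "chrom", "start", "end", "min_p",
                            "n_significant", "n_sites"])
    if len(gene_df):
        gene_df = gene_df.sort_values(
            ["n_significant", "min_p"], ascending=[False, True],
            kind="mergesort").reset_index(drop=True)
        gene_df["rank"] = np.arange(1, len(gene_df) + 1)
    else:
        gene_df["rank"] = pd.Series(dtype=int)
    return site_df, gene_df
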