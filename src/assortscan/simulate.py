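"""Forward-time simulator of two pheromone strains under assortative mating.

The model emulates a pair of partially isolated moth demes (an E-like and a
Z-like strain) segregating for two focal loci: an autosomal biallelic
*signal* locus determining the female pheromone blend, and a Z-linked
biallelic *preference* locus determining which blend a male accepts.
Inheritance follows lepidopteran ZW genetics — males are ZZ, females ZW
(single Z, inherited from the father) — and meiosis is achiasmatic in
females, so recombination happens only through males.

Each generation: a fraction ``migration`` of individuals is exchanged
between demes; every female then draws candidate males uniformly with
replacement until one accepts her blend (acceptance 1 on a matching
preference, ``assort_alpha`` on a mismatch, capped at 100 draws after which
mating is random); offspring replace the parents.  Background SNPs start at
deme-specific frequencies and evolve by drift alone.

Outputs are a phased :class:`~assortscan.io_formats.GenotypeMatrix`,
pheromone-trap sample metadata (with a configurable trap error rate) and
binomially sampled pool-seq read counts, so every downstream scan can be
exercised on data whose truth is known.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    MISSING,
    NUCLEOTIDES,
    GenotypeMatrix,
    PoolCounts,
    PoolSpec,
    SampleMeta,
    ValidationError,
    VariantSite,
)

#: female-blend / male-preference phenotype classes
E_CLASS, INTERMEDIATE, Z_CLASS = 0, 1, 2

MATE_DRAW_CAP = 100


@dataclass(frozen=True)
class ChromSpec:
    name: str
    length: int
    is_z: bool = False


@dataclass
class SimConfig:
    """Parameters of the two-deme forward simulation.

    Defaults are calibrated so that pheromone-trapped males are
    concordant signal/preference double homozygotes roughly 80% of the
    time, the genotype structure observed in field samples of the two
    corn-borer strains.
    """

    n_females: int = 1000
    n_males: int = 1000
    migration: float = 0.005
    assort_alpha: float = 0.1
    het_pref: str = "indifferent"  # {"indifferent", "E-like", "Z-like"}
    trap_error: float = 0.05
    chrom_map: tuple[ChromSpec, ...] = (
        ChromSpec("aut1", 20_000_000, False),
        ChromSpec("Z", 21_000_000, True),
    )
    signal_locus: tuple[str, int] = ("aut1", 5_000_000)
    pref_locus: tuple[str, int] = ("Z", 18_710_000)
    n_background_snps: int = 2000
    #: per-deme initial alt frequency at background SNPs
    background_freqs: tuple[float, float] = (0.25, 0.75)
    #: per-deme initial alt frequency at the two focal loci
    init_focal_freqs: tuple[float, float] = (0.0, 1.0)
    rec_rate_male: float = 1e-8  # crossovers per bp per male meiosis
    generations: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("migration", "assort_alpha", "trap_error"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}={v} outside [0, 1]")
        if self.n_females < 1 or self.n_males < 1:
            raise ValidationError("population sizes must be positive")
        if self.het_pref not in ("indifferent", "E-like", "Z-like"):
            raise ValidationError(f"unknown het_pref {self.het_pref!r}")
        chroms = {c.name: c for c in self.chrom_map}
        sig_c, _ = self.signal_locus
        pref_c, _ = self.pref_locus
        if sig_c not in chroms or chroms[sig_c].is_z:
            raise ValidationError("signal locus must lie on an autosome")
        if pref_c not in chroms or not chroms[pref_c].is_z:
            raise ValidationError("preference locus must lie on the Z")

    @classmethod
    def random_mating(cls, **kw) -> "SimConfig":
        """A panmictic null: no assortment, full mixing, shared frequencies."""
        kw.setdefault("assort_alpha", 1.0)
        kw.setdefault("migration", 0.5)
        kw.setdefault("background_freqs", (0.5, 0.5))
        kw.setdefault("init_focal_freqs", (0.5, 0.5))
        kw.setdefault("trap_error", 0.5)
        return cls(**kw)


@dataclass
class SimResult:
    """Final-generation population with per-individual truth.

    Haplotype convention: ``haps[i, 0]`` is the maternal gamete and
    ``haps[i, 1]`` the paternal gamete; a female's maternal gamete carries
    the W, so her Z-linked loci are :data:`MISSING` in slot 0 and her single
    Z (paternal) sits in slot 1.  Male Z dosage is therefore in {0,1,2} and
    female Z dosage in {0,1} (hemizygous coding).
    """

    config: SimConfig
    sites: list[VariantSite]
    haps: np.ndarray  # (n_individuals, 2, n_loci) int8
    is_female: np.ndarray  # bool
    deme: np.ndarray  # int
    signal_idx: int
    pref_idx: int
    trajectory: np.ndarray  # (generations+1, 2 demes, 2 loci) alt freq

    @property
    def n_individuals(self) -> int:
        return self.haps.shape[0]

    @property
    def male_indices(self) -> np.ndarray:
        return np.flatnonzero(~self.is_female)

    def dosage(self, idx: np.ndarray | None = None) -> np.ndarray:
        h = self.haps if idx is None else self.haps[idx]
        return np.where(h == MISSING, 0, h).sum(axis=1).astype(np.int8)

    def pref_class(self, idx: np.ndarray) -> np.ndarray:
        """Preference phenotype class of the given males."""
        dos = self.dosage(idx)[:, self.pref_idx]
        het = {"indifferent": INTERMEDIATE, "E-like": E_CLASS,
               "Z-like": Z_CLASS}[self.config.het_pref]
        return np.select([dos == 0, dos == 1], [E_CLASS, het], Z_CLASS)

    def sample_ids(self, idx: np.ndarray) -> list[str]:
        return [f"ind{int(i):05d}" for i in idx]

    def genotype_matrix(self, idx: np.ndarray) -> GenotypeMatrix:
        """Phased genotype matrix for the given individuals.

        Hemizygous female Z calls are emitted with their single haplotype in
        slot 0 so they serialize as haploid VCF genotypes.
        """
        idx = np.asarray(idx)
        h = self.haps[idx]
        dosage = np.where(h == MISSING, 0, h).sum(axis=1).astype(np.int8)
        dosage[(h == MISSING).all(axis=1)] = MISSING
        phase = h.copy()
        hemi = (phase[:, 0, :] == MISSING) & (phase[:, 1, :] != MISSING)
        phase[:, 0, :] = np.where(hemi, phase[:, 1, :], phase[:, 0, :])
        phase[:, 1, :] = np.where(hemi, MISSING, phase[:, 1, :])
        return GenotypeMatrix(
            sites=list(self.sites),
            samples=self.sample_ids(idx),
            dosage=dosage,
            phase=phase,
        )

    def truth_table(self) -> pd.DataFrame:
        dos = self.dosage()
        return pd.DataFrame({
            "sample_id": self.sample_ids(np.arange(self.n_individuals)),
            "sex": np.where(self.is_female, "F", "M"),
            "deme": self.deme,
            "signal_dosage": dos[:, self.signal_idx],
            "pref_dosage": dos[:, self.pref_idx],
        })


# ---------------------------------------------------------------------------
# genome layout
# ---------------------------------------------------------------------------

def _build_sites(cfg: SimConfig, rng: np.random.Generator):
    """Place background SNPs plus the two focal loci; assign ref/alt bases."""
    lengths = np.array([c.length for c in cfg.chrom_map], dtype=float)
    n_per = np.floor(lengths / lengths.sum() * cfg.n_background_snps).astype(int)
    n_per[0] += cfg.n_background_snps - n_per.sum()
    focal = {cfg.signal_locus, cfg.pref_locus}
    loci: list[tuple[int, int]] = []  # (chrom index, pos)
    for ci, (chrom, n) in enumerate(zip(cfg.chrom_map, n_per)):
        taken = {pos for (c, pos) in focal if c == chrom.name}
        pos = set()
        while len(pos) < n:
            draw = rng.integers(1, chrom.length + 1, size=n - len(pos))
            pos.update(int(p) for p in draw if p not in taken)
        loci.extend((ci, p) for p in pos)
    name_to_ci = {c.name: i for i, c in enumerate(cfg.chrom_map)}
    loci.append((name_to_ci[cfg.signal_locus[0]], cfg.signal_locus[1]))
    loci.append((name_to_ci[cfg.pref_locus[0]], cfg.pref_locus[1]))
    # sort the way the containers do: lexically by chromosome name, then pos
    loci.sort(key=lambda cp: (cfg.chrom_map[cp[0]].name, cp[1]))
    sites = []
    for ci, pos in loci:
        ref, alt = rng.choice(4, size=2, replace=False)
        sites.append(VariantSite(cfg.chrom_map[ci].name, pos,
                                 NUCLEOTIDES[ref], NUCLEOTIDES[alt], "SNP"))
    chrom_of = np.array([ci for ci, _ in loci])
    positions = np.array([p for _, p in loci], dtype=float)
    signal_idx = loci.index((name_to_ci[cfg.signal_locus[0]], cfg.signal_locus[1]))
    pref_idx = loci.index((name_to_ci[cfg.pref_locus[0]], cfg.pref_locus[1]))
    return sites, chrom_of, positions, signal_idx, pref_idx


# ---------------------------------------------------------------------------
# meiosis
# ---------------------------------------------------------------------------

def _paternal_gametes(haps, fathers, positions, chrom_of, chrom_lengths,
                      rate, rng):
    """Recombinant gametes from male meiosis (Poisson crossovers)."""
    m = len(fathers)
    n_loci = haps.shape[2]
    gam = np.empty((m, n_loci), dtype=np.int8)
    for ci, length in enumerate(chrom_lengths):
        mask = chrom_of == ci
        pos = positions[mask]
        k = rng.poisson(rate * length, size=m)
        kmax = int(k.max()) if m else 0
        start = rng.integers(0, 2, size=m)
        if kmax == 0:
            src = np.broadcast_to(start[:, None], (m, mask.sum()))
        else:
            u = rng.random((m, kmax)) * length
            slot = np.arange(kmax)[None, :] < k[:, None]
            xpos = np.where(slot, u, np.inf)
            nbefore = (xpos[:, :, None] < pos[None, None, :]).sum(axis=1)
            src = (start[:, None] + nbefore) % 2
        ph = haps[fathers][:, :, mask]
        gam[:, mask] = np.take_along_axis(ph, src[:, None, :], axis=1)[:, 0, :]
    return gam


def _maternal_gametes(haps, mothers, child_is_female, chrom_of, z_chrom_mask,
                      rng):
    """Non-recombinant gametes from achiasmatic female meiosis.

    Whole chromosomes are passed intact.  The mother's single Z always sits
    in haplotype slot 1, so the Z pick is forced; daughters receive the W
    instead (Z loci set to missing).
    """
    m = len(mothers)
    n_chrom = len(z_chrom_mask)
    bits = rng.integers(0, 2, size=(m, n_chrom))
    bits[:, z_chrom_mask] = 1
    src = bits[:, chrom_of]
    gam = np.take_along_axis(haps[mothers], src[:, None, :], axis=1)[:, 0, :]
    z_loci = z_chrom_mask[chrom_of]
    gam[np.ix_(child_is_female, z_loci)] = MISSING
    return gam


# ---------------------------------------------------------------------------
# mating
# ---------------------------------------------------------------------------

def _acceptance_matrix(alpha: float) -> np.ndarray:
    """P(male accepts) by (female blend class, male preference class).

    Pure matches are accepted at 1, pure mismatches at ``alpha``;
    indifferent males and intermediate-blend females court at the mean of
    the two pure-blend probabilities, (1 + alpha) / 2.
    """
    mid = (1.0 + alpha) / 2.0
    return np.array([
        [1.0, mid, alpha],
        [mid, mid, mid],
        [alpha, mid, 1.0],
    ])


def _choose_fathers(blend, pref, alpha, rng):
    """Vectorized draw-until-accept mating with a cap of 100 draws.

    An accepted father is distributed proportionally to his acceptance
    probability; with probability (1 - mean acceptance)^100 all draws fail
    and the female mates randomly.
    """
    acc = _acceptance_matrix(alpha)[blend[:, None], pref[None, :]]
    pbar = acc.mean(axis=1)
    fail = rng.random(len(blend)) < (1.0 - pbar) ** MATE_DRAW_CAP
    cw = acc.cumsum(axis=1)
    tot = cw[:, -1]
    r = rng.random(len(blend)) * np.where(tot > 0, tot, 1.0)
    fathers = np.minimum((cw < r[:, None]).sum(axis=1), acc.shape[1] - 1)
    fathers[tot <= 0] = 0
    n_fail = int(fail.sum())
    if n_fail:
        fathers[fail] = rng.integers(0, acc.shape[1], size=n_fail)
    return fathers


# ---------------------------------------------------------------------------
# main loop
# ---------------------------------------------------------------------------

def simulate_population(config: SimConfig) -> SimResult:
    """Run the forward simulation and return the final generation."""
    cfg = config
    root = np.random.SeedSequence(cfg.seed)
    ss_layout, ss_init, ss_gens, _ss_spare = root.spawn(4)
    rng_layout = np.random.default_rng(ss_layout)
    sites, chrom_of, positions, signal_idx, pref_idx = _build_sites(
        cfg, rng_layout)
    n_loci = len(sites)
    z_chrom_mask = np.array([c.is_z for c in cfg.chrom_map])
    z_loci = z_chrom_mask[chrom_of]
    chrom_lengths = [c.length for c in cfg.chrom_map]

    rng_init = np.random.default_rng(ss_init)
    nf, nm = cfg.n_females, cfg.n_males
    females = []  # per deme (nf, 2, L)
    males = []
    for d in range(2):
        freqs = np.full(n_loci, cfg.background_freqs[d])
        freqs[signal_idx] = cfg.init_focal_freqs[d]
        freqs[pref_idx] = cfg.init_focal_freqs[d]
        fh = (rng_init.random((nf, 2, n_loci)) < freqs).astype(np.int8)
        mh = (rng_init.random((nm, 2, n_loci)) < freqs).astype(np.int8)
        fh[:, 0, z_loci] = MISSING  # females: W in the maternal slot
        females.append(fh)
        males.append(mh)

    traj = np.empty((cfg.generations + 1, 2, 2))

    def record(g):
        for d in range(2):
            for li, locus in enumerate((signal_idx, pref_idx)):
                h = np.concatenate([females[d][:, :, locus].ravel(),
                                    males[d][:, :, locus].ravel()])
                h = h[h != MISSING]
                traj[g, d, li] = h.mean() if h.size else np.nan

    record(0)
    gen_rng = np.random.default_rng(ss_gens)
    for g in range(cfg.generations):
        # migration: symmetric exchange of round(m * n) per sex
        kf = int(round(cfg.migration * nf))
        km = int(round(cfg.migration * nm))
        if kf:
            i0 = gen_rng.choice(nf, size=kf, replace=False)
            i1 = gen_rng.choice(nf, size=kf, replace=False)
            females[0][i0], females[1][i1] = (females[1][i1].copy(),
                                              females[0][i0].copy())
        if km:
            i0 = gen_rng.choice(nm, size=km, replace=False)
            i1 = gen_rng.choice(nm, size=km, replace=False)
            males[0][i0], males[1][i1] = (males[1][i1].copy(),
                                          males[0][i0].copy())
        for d in range(2):
            fh, mh = females[d], males[d]
            blend = fh[:, 1, signal_idx] + fh[:, 0, signal_idx]  # autosomal
            pref_dos = mh[:, :, pref_idx].sum(axis=1)
            het = {"indifferent": INTERMEDIATE, "E-like": E_CLASS,
                   "Z-like": Z_CLASS}[cfg.het_pref]
            pref = np.select([pref_dos == 0, pref_dos == 1],
                             [E_CLASS, het], Z_CLASS)
            fathers_of_female = _choose_fathers(blend, pref,
                                                cfg.assort_alpha, gen_rng)
            n_off = nf + nm
            mothers = gen_rng.integers(0, nf, size=n_off)
            fathers = fathers_of_female[mothers]
            child_is_female = np.zeros(n_off, dtype=bool)
            child_is_female[:nf] = True
            mat = _maternal_gametes(fh, mothers, child_is_female, chrom_of,
                                    z_chrom_mask, gen_rng)
            pat = _paternal_gametes(mh, fathers, positions, chrom_of,
                                    chrom_lengths, cfg.rec_rate_male, gen_rng)
            children = np.stack([mat, pat], axis=1)
            females[d] = children[:nf]
            males[d] = children[nf:]
        record(g + 1)

    haps = np.concatenate([females[0], males[0], females[1], males[1]])
    is_female = np.concatenate([
        np.ones(nf, bool), np.zeros(nm, bool),
        np.ones(nf, bool), np.zeros(nm, bool),
    ])
    deme = np.concatenate([
        np.zeros(nf + nm, int), np.ones(nf + nm, int)])
    return SimResult(
        config=cfg, sites=sites, haps=haps, is_female=is_female, deme=deme,
        signal_idx=signal_idx, pref_idx=pref_idx, trajectory=traj,
    )


# ---------------------------------------------------------------------------
# sampling stages
# ---------------------------------------------------------------------------

_PGFAR_CLASS = {0: "EE", 1: "EZ", 2: "ZZ"}


def sample_traps(
    result: SimResult,
    n_per_trap: int,
    eps: float | None = None,
    seed: int | None = None,
    site_label: str = "site1",
    exclude: np.ndarray | None = None,
) -> tuple[list[SampleMeta], np.ndarray]:
    """Pheromone-trap sampling of males from the pooled demes.

    Each male enters the trap matching his preference with probability
    ``1 - eps`` and the opposite trap with ``eps``; indifferent males choose
    uniformly.  Exactly ``n_per_trap`` males are retained per trap by
    uniform subsampling.  Returns metadata rows and the male indices
    (E trap first), aligned.
    """
    if eps is None:
        eps = result.config.trap_error
    rng = np.random.default_rng(
        result.config.seed + 1_000_003 if seed is None else seed)
    males = result.male_indices
    if exclude is not None:
        males = np.setdiff1d(males, exclude)
    pref = result.pref_class(males)
    u = rng.random(len(males))
    goes_e = np.where(
        pref == INTERMEDIATE, u < 0.5,
        np.where(pref == E_CLASS, u >= eps, u < eps))
    chosen: list[np.ndarray] = []
    meta: list[SampleMeta] = []
    sig_dos = result.dosage(males)[:, result.signal_idx]
    for trap, in_trap in (("E", goes_e), ("Z", ~goes_e)):
        avail = np.flatnonzero(in_trap)
        if len(avail) < n_per_trap:
            raise ValidationError(
                f"only {len(avail)} males in {trap} trap, need {n_per_trap}")
        pick = rng.choice(avail, size=n_per_trap, replace=False)
        pick.sort()
        chosen.append(males[pick])
        for i in pick:
            meta.append(SampleMeta(
                sample_id=f"ind{int(males[i]):05d}",
                trap=trap,
                site=site_label,
                pgfar_class=_PGFAR_CLASS[int(sig_dos[i])],
            ))
    return meta, np.concatenate(chosen)


def simulate_poolseq(
    result: SimResult,
    meta: Sequence[SampleMeta],
    indices: np.ndarray,
    depth_lambda: float = 50.0,
    seq_error: float = 0.001,
    seed: int | None = None,
) -> PoolCounts:
    """Pool-seq read counts for trapped males, one pool per trap per site.

    Mirroring the field design, pool membership is restricted to
    signal-locus homozygotes concordant with their trap (E-trap pools keep
    EE males, Z-trap pools keep ZZ males).  Per site and pool, coverage is
    Poisson(``depth_lambda``) and alt reads are Binomial(coverage, f')
    where f' folds the symmetric sequencing error rate into the pool allele
    frequency f.
    """
    rng = np.random.default_rng(
        result.config.seed + 2_000_003 if seed is None else seed)
    indices = np.asarray(indices)
    groups: dict[tuple[str, str], list[int]] = {}
    for m, idx in zip(meta, indices):
        want = "EE" if m.trap == "E" else "ZZ"
        if m.pgfar_class == want:
            groups.setdefault((m.site, m.trap), []).append(int(idx))
    pools: list[PoolSpec] = []
    counts = []
    n_sites = len(result.sites)
    for (site_label, trap), members in sorted(groups.items()):
        if not members:
            raise ValidationError(f"empty pool {site_label}/{trap}")
        dos = result.dosage(np.array(members))
        f = dos.sum(axis=0) / (2.0 * len(members))
        f_err = f * (1.0 - seq_error) + (1.0 - f) * seq_error
        cov = rng.poisson(depth_lambda, size=n_sites)
        alt = rng.binomial(cov, f_err)
        counts.append(np.stack([cov - alt, alt], axis=1))
        pools.append(PoolSpec(site_label, trap, 2 * len(members)))
    if not pools:
        raise ValidationError("no pool members after the homozygote screen")
    return PoolCounts(
        sites=list(result.sites),
        pools=pools,
        counts=np.stack(counts, axis=1),
    )


def sample_multisite(
    result: SimResult,
    n_per_trap: int,
    site_labels: Sequence[str],
    eps: float | None = None,
    seed: int | None = None,
) -> tuple[list[SampleMeta], np.ndarray]:
    """Disjoint trap samples for several collection sites (pool replicates)."""
    base_seed = result.config.seed + 3_000_017 if seed is None else seed
    rng = np.random.default_rng(base_seed)
    taken: np.ndarray | None = None
    all_meta: list[SampleMeta] = []
    all_idx: list[np.ndarray] = []
    for label in site_labels:
        meta, idx = sample_traps(
            result, n_per_trap, eps=eps,
            seed=int(rng.integers(0, 2**31 - 1)),
            site_label=label, exclude=taken)
        all_meta.extend(meta)
        all_idx.append(idx)
        taken = idx if taken is None else np.concatenate([taken, idx])
    return all_meta, np.concatenate(all_idx)
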