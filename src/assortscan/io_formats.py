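"""Readers, writers and the in-memory data model for the scan pipeline.

The pipeline touches four standard inputs: VCF 4.x diploid genotypes,
Popoolation2-style ``sync`` tables of pooled read counts, tab-delimited
sample metadata (trap label, collection site, signal-locus genotype class)
and tab-delimited gene interval tables.  Everything downstream consumes the
containers defined here: :class:`GenotypeMatrix` for individual genotypes
and :class:`PoolCounts` for pooled allele counts.

Coordinate dialect: all intervals are 1-based inclusive internally (the VCF
convention); :func:`bed_to_intervals` converts 0-based half-open BED rows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

logger = logging.getLogger("assortscan")

#: dosage / haplotype code for a missing call
MISSING = -1

NUCLEOTIDES = ("A", "T", "C", "G")

#: column order of a Popoolation2 sync count string
SYNC_ALLELES = ("A", "T", "C", "G", "N", "del")


class FormatError(ValueError):
    """Malformed input file (message names the offending line)."""


class ValidationError(ValueError):
    """Structurally valid input that violates a pipeline invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariantSite:
    """A biallelic variant: SNP, small indel, or SV coded presence/absence."""

    chrom: str
    pos: int  # 1-based
    ref_allele: str
    alt_allele: str
    var_class: str = "SNP"  # {"SNP", "indel", "SV"}

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"pos must be >= 1, got {self.pos}")
        if self.ref_allele == self.alt_allele:
            raise ValidationError(
                f"ref and alt alleles identical at {self.chrom}:{self.pos}"
            )

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chrom, self.pos, self.alt_allele)


def classify_alleles(ref: str, alt: str) -> str:
    if alt.startswith("<") or len(ref) > 50 or len(alt) > 50:
        return "SV"
    if len(ref) != len(alt):
        return "indel"
    return "SNP"


@dataclass(frozen=True)
class SampleMeta:
    """Per-sample metadata: trap phenotype, site, signal-locus class."""

    sample_id: str
    trap: str  # {"E", "Z"}
    site: str
    pgfar_class: str = "unknown"  # {"EE", "ZZ", "EZ", "unknown"}


@dataclass(frozen=True)
class GeneInterval:
    """1-based inclusive genomic interval."""

    chrom: str
    start: int
    end: int
    name: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(
                f"interval {self.name}: start {self.start} > end {self.end}"
            )

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end


@dataclass
class GenotypeMatrix:
    """Samples x sites dosage matrix with optional known phase.

    ``dosage[s, j]`` counts alt alleles ({0,1,2}; females are hemizygous on
    the Z, {0,1}); :data:`MISSING` marks no-calls.  ``phase``, when present,
    is ``(n_samples, 2, n_sites)`` haplotype alleles with :data:`MISSING`
    both for no-calls and for the absent second haplotype of a hemizygous
    sample.
    """

    sites: list[VariantSite]
    samples: list[str]
    dosage: np.ndarray
    phase: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (len(self.samples), len(self.sites)):
            raise ValidationError(
                f"dosage shape {self.dosage.shape} != "
                f"({len(self.samples)}, {len(self.sites)})"
            )
        full_keys = [s.key for s in self.sites]
        if len(set(full_keys)) != len(full_keys):
            raise ValidationError("duplicate (chrom, pos, alt) sites")
        keys = [(s.chrom, s.pos) for s in self.sites]
        if self.phase is not None:
            self.phase = np.asarray(self.phase, dtype=np.int8)
            if self.phase.shape != (len(self.samples), 2, len(self.sites)):
                raise ValidationError("phase shape mismatch")
            hap_sum = np.where(self.phase == MISSING, 0, self.phase).sum(axis=1)
            known = self.phase[:, 0, :] != MISSING
            ok = ~known | (self.dosage == MISSING) | (hap_sum == self.dosage)
            if not ok.all():
                raise ValidationError("haplotype sums disagree with dosage")
        if not _is_sorted(keys):
            logger.warning("sites not sorted by (chrom, pos); re-sorting")
            order = sorted(range(len(keys)), key=lambda j: keys[j])  # stable
            self.sites = [self.sites[j] for j in order]
            self.dosage = self.dosage[:, order]
            if self.phase is not None:
                self.phase = self.phase[:, :, order]

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def site_index(self, chrom: str, pos: int) -> int:
        for j, s in enumerate(self.sites):
            if s.chrom == chrom and s.pos == pos:
                return j
        raise KeyError(f"no site at {chrom}:{pos}")

    def alt_freq(self) -> np.ndarray:
        """Alt-allele frequency per site over non-missing calls.

        Hemizygous (single-haplotype) calls contribute one allele when phase
        is available; otherwise every non-missing call is assumed diploid.
        """
        dos = self.dosage
        obs = dos != MISSING
        if self.phase is not None:
            ploidy = (self.phase != MISSING).sum(axis=1)
            ploidy = np.where(obs, np.where(ploidy > 0, ploidy, 2), 0)
        else:
            ploidy = np.where(obs, 2, 0)
        alt = np.where(obs, dos, 0).sum(axis=0)
        tot = ploidy.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot > 0, alt / np.maximum(tot, 1), np.nan)

    def minor_allele_freq(self) -> np.ndarray:
        p = self.alt_freq()
        return np.minimum(p, 1.0 - p)

    def subset_sites(self, idx: Sequence[int]) -> "GenotypeMatrix":
        idx = list(idx)
        return GenotypeMatrix(
            sites=[self.sites[j] for j in idx],
            samples=list(self.samples),
            dosage=self.dosage[:, idx],
            phase=None if self.phase is None else self.phase[:, :, idx],
        )

    def subset_samples(self, idx: Sequence[int]) -> "GenotypeMatrix":
        idx = list(idx)
        return GenotypeMatrix(
            sites=list(self.sites),
            samples=[self.samples[i] for i in idx],
            dosage=self.dosage[idx, :],
            phase=None if self.phase is None else self.phase[idx, :, :],
        )

    def equals(self, other: "GenotypeMatrix") -> bool:
        if self.sites != other.sites or self.samples != other.samples:
            return False
        if not np.array_equal(self.dosage, other.dosage):
            return False
        a, b = self.phase, other.phase
        if (a is None) != (b is None):
            return False
        return a is None or np.array_equal(a, b)


@dataclass(frozen=True)
class PoolSpec:
    """One pooled library: collection site, trap label, haploid pool size."""

    site_label: str
    trap: str
    haploid_size: int


@dataclass
class PoolCounts:
    """Per-site biallelic read counts for a set of E/Z pool pairs."""

    sites: list[VariantSite]
    pools: list[PoolSpec]
    counts: np.ndarray  # (n_sites, n_pools, 2) = (ref_reads, alt_reads)
    discarded: np.ndarray | None = None  # depth lost to non-ref/alt alleles

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.sites), len(self.pools), 2):
            raise ValidationError(
                f"counts shape {self.counts.shape} != "
                f"({len(self.sites)}, {len(self.pools)}, 2)"
            )
        if (self.counts < 0).any():
            raise ValidationError("negative read counts")

    @property
    def coverage(self) -> np.ndarray:
        return self.counts.sum(axis=2)

    def pool_pairs(self) -> list[tuple[str, int, int]]:
        """(site_label, E pool index, Z pool index) per collection site."""
        by_site: dict[str, dict[str, int]] = {}
        for k, p in enumerate(self.pools):
            by_site.setdefault(p.site_label, {})[p.trap] = k
        pairs = []
        for label, traps in by_site.items():
            if set(traps) != {"E", "Z"}:
                raise ValidationError(
                    f"pools for site {label!r} are not an E/Z pair"
                )
            pairs.append((label, traps["E"], traps["Z"]))
        return pairs


def _is_sorted(keys: list[tuple]) -> bool:
    return all(keys[i] <= keys[i + 1] for i in range(len(keys) - 1))


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(
    path: str | Path,
    maf_min: float | None = None,
    keep_missing: bool = True,
) -> GenotypeMatrix:
    """Read a VCF 4.x into a :class:`GenotypeMatrix`.

    Parameters
    ----------
    path
        VCF file with GT fields; multi-allelic records are split into one
        biallelic record per alt allele.
    maf_min
        If given, drop sites whose minor-allele frequency (over non-missing
        calls) is not strictly above this threshold.
    keep_missing
        If False, drop sites containing any missing call.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    try:
        vcf = VCF(str(path), gts012=False)
    except Exception as exc:  # pragma: no cover - cyvcf2 error text varies
        raise FormatError(f"cannot parse VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    sites: list[VariantSite] = []
    dos_cols: list[np.ndarray] = []
    hapA: list[np.ndarray] = []
    hapB: list[np.ndarray] = []
    any_phase = False
    for rec in vcf:
        gts = rec.genotypes  # per sample: [a0, (a1,) phased]
        for ai, alt in enumerate(rec.ALT, start=1):
            dos = np.full(len(samples), MISSING, dtype=np.int8)
            h0 = np.full(len(samples), MISSING, dtype=np.int8)
            h1 = np.full(len(samples), MISSING, dtype=np.int8)
            for s, g in enumerate(gts):
                alleles = [int(a) for a in g[:-1]]
                phased = bool(g[-1])
                if any(a < 0 for a in alleles):
                    continue
                coded = [1 if a == ai else 0 for a in alleles]
                dos[s] = sum(coded)
                if phased or len(coded) == 1:
                    any_phase = True
                    h0[s] = coded[0]
                    h1[s] = coded[1] if len(coded) > 1 else MISSING
            sites.append(
                VariantSite(rec.CHROM, rec.POS, rec.REF, alt,
                            classify_alleles(rec.REF, alt))
            )
            dos_cols.append(dos)
            hapA.append(h0)
            hapB.append(h1)
    vcf.close()
    if not sites:
        return GenotypeMatrix(sites=[], samples=samples,
                              dosage=np.zeros((len(samples), 0), np.int8))
    dosage = np.column_stack(dos_cols)
    phase = None
    if any_phase:
        phase = np.stack([np.column_stack(hapA), np.column_stack(hapB)], axis=1)
    gm = GenotypeMatrix(sites=sites, samples=samples, dosage=dosage, phase=phase)
    keep = np.ones(gm.n_sites, dtype=bool)
    if not keep_missing:
        keep &= ~(gm.dosage == MISSING).any(axis=0)
    if maf_min is not None:
        maf = gm.minor_allele_freq()
        keep &= np.nan_to_num(maf, nan=0.0) > maf_min
    if not keep.all():
        gm = gm.subset_sites(np.flatnonzero(keep))
    return gm


def write_vcf(
    matrix: GenotypeMatrix,
    meta: Sequence[SampleMeta] | None,
    path: str | Path,
    extra_header: Iterable[str] = (),
) -> None:
    """Write a :class:`GenotypeMatrix` as VCF 4.2.

    Genotypes use the phased separator ``|`` only where phase is known;
    hemizygous calls (single known haplotype) are written haploid.  Sample
    metadata, if given, is embedded as ``##SAMPLE`` header lines so a
    simulator VCF is self-describing.
    """
    path = Path(path)
    meta_by_id = {m.sample_id: m for m in (meta or [])}
    lines = ["##fileformat=VCFv4.2", "##source=assortscan"]
    lines += list(extra_header)
    for chrom in dict.fromkeys(s.chrom for s in matrix.sites):
        lines.append(f"##contig=<ID={chrom}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for sid in matrix.samples:
        m = meta_by_id.get(sid)
        if m is not None:
            lines.append(
                f"##SAMPLE=<ID={sid},Trap={m.trap},Site={m.site},"
                f"PgfarClass={m.pgfar_class}>"
            )
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(matrix.samples)
    )
    for j, site in enumerate(matrix.sites):
        gts = []
        for s in range(matrix.n_samples):
            d = matrix.dosage[s, j]
            if matrix.phase is not None and matrix.phase[s, 0, j] != MISSING:
                h0 = matrix.phase[s, 0, j]
                h1 = matrix.phase[s, 1, j]
                gts.append(str(h0) if h1 == MISSING else f"{h0}|{h1}")
            elif d == MISSING:
                gts.append("./.")
            else:
                gts.append(("0/0", "0/1", "1/1")[d])
        lines.append(
            f"{site.chrom}\t{site.pos}\t.\t{site.ref_allele}\t"
            f"{site.alt_allele}\t.\tPASS\t.\tGT\t" + "\t".join(gts)
        )
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Popoolation2 sync
# ---------------------------------------------------------------------------

def read_sync(path: str | Path, pool_spec: Sequence[PoolSpec]) -> PoolCounts:
    """Read a Popoolation2 ``sync`` table into :class:`PoolCounts`.

    Each pool column is an ``A:T:C:G:N:del`` count string.  Sites are reduced
    to biallelic: the ref allele plus the non-ref nucleotide with the highest
    count summed across pools (ties broken in A,T,C,G order).  Depth on other
    alleles is kept as ``discarded``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    pools = list(pool_spec)
    sites: list[VariantSite] = []
    counts: list[np.ndarray] = []
    discarded: list[np.ndarray] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3 + len(pools):
                raise FormatError(
                    f"{path}:{ln}: expected {3 + len(pools)} columns, "
                    f"got {len(fields)}"
                )
            chrom, pos_s, ref = fields[:3]
            ref = ref.upper()
            tab = np.zeros((len(pools), 6), dtype=np.int64)
            for k, cell in enumerate(fields[3:]):
                parts = cell.split(":")
                if len(parts) != 6:
                    raise FormatError(
                        f"{path}:{ln}: count string {cell!r} has "
                        f"{len(parts)} fields, expected 6"
                    )
                tab[k] = [int(x) for x in parts]
            totals = tab.sum(axis=0)
            # highest-count non-ref nucleotide, A,T,C,G order on ties
            alt, alt_i, best = None, None, -1
            for i, nt in enumerate(NUCLEOTIDES):
                if nt == ref:
                    continue
                if totals[i] > best:
                    alt, alt_i, best = nt, i, totals[i]
            ref_i = SYNC_ALLELES.index(ref) if ref in NUCLEOTIDES else None
            if ref_i is None:
                raise FormatError(f"{path}:{ln}: ref allele {ref!r} not ACGT")
            ref_reads = tab[:, ref_i]
            alt_reads = tab[:, alt_i]
            sites.append(VariantSite(chrom, int(pos_s), ref, alt, "SNP"))
            counts.append(np.stack([ref_reads, alt_reads], axis=1))
            discarded.append(tab.sum(axis=1) - ref_reads - alt_reads)
    pc = PoolCounts(
        sites=sites,
        pools=pools,
        counts=(np.stack(counts) if sites
                else np.zeros((0, len(pools), 2), np.int64)),
        discarded=np.stack(discarded) if sites else None,
    )
    pc.pool_pairs()  # validates E/Z pairing
    return pc


def write_sync(pc: PoolCounts, path: str | Path) -> None:
    """Write :class:`PoolCounts` back to sync format (ref/alt columns only)."""
    path = Path(path)
    with open(path, "w") as fh:
        for j, site in enumerate(pc.sites):
            cells = []
            for k in range(len(pc.pools)):
                col = [0] * 6
                col[SYNC_ALLELES.index(site.ref_allele)] = int(pc.counts[j, k, 0])
                col[SYNC_ALLELES.index(site.alt_allele)] = int(pc.counts[j, k, 1])
                cells.append(":".join(str(c) for c in col))
            fh.write(f"{site.chrom}\t{site.pos}\t{site.ref_allele}\t"
                     + "\t".join(cells) + "\n")


def read_pool_spec(path: str | Path) -> list[PoolSpec]:
    """Tab-delimited pool table: site_label, trap, haploid_size (with header)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"site_label", "trap", "haploid_size"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"pool spec {path} missing columns {required - set(df.columns)}"
        )
    return [
        PoolSpec(str(r.site_label), str(r.trap), int(r.haploid_size))
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# intervals and sample metadata
# ---------------------------------------------------------------------------

def read_intervals(path: str | Path) -> list[GeneInterval]:
    """Read a tab-delimited interval table (chrom, start, end, name).

    Coordinates are 1-based inclusive (this tool's dialect; use
    :func:`bed_to_intervals` for true BED input).  Duplicate names are
    rejected; overlapping intervals are allowed.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    out: list[GeneInterval] = []
    seen: set[str] = set()
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("chrom\t"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(f"{path}:{ln}: expected 4 columns")
            chrom, start, end, name = fields[:4]
            if name in seen:
                raise ValidationError(f"{path}:{ln}: duplicate name {name!r}")
            seen.add(name)
            out.append(GeneInterval(chrom, int(start), int(end), name))
    return out


def bed_to_intervals(rows: Iterable[tuple[str, int, int, str]]) -> list[GeneInterval]:
    """Convert 0-based half-open BED rows to 1-based inclusive intervals."""
    return [GeneInterval(c, s + 1, e, n) for c, s, e, n in rows]


def read_sample_meta(path: str | Path) -> list[SampleMeta]:
    """Tab-delimited metadata: sample_id, trap, site, pgfar_class (header row)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"sample_id", "trap", "site"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"metadata {path} missing columns {required - set(df.columns)}"
        )
    if df["sample_id"].duplicated().any():
        raise ValidationError(f"metadata {path}: duplicate sample ids")
    out = []
    for r in df.itertuples():
        out.append(SampleMeta(
            sample_id=str(r.sample_id),
            trap=str(r.trap),
            site=str(r.site),
            pgfar_class=str(getattr(r, "pgfar_class", "unknown") or "unknown"),
        ))
    return out


def write_sample_meta(meta: Sequence[SampleMeta], path: str | Path) -> None:
    df = pd.DataFrame(
        [(m.sample_id, m.trap, m.site, m.pgfar_class) for m in meta],
        columns=["sample_id", "trap", "site", "pgfar_class"],
    )
    df.to_csv(path, sep="\t", index=False)


def check_meta_matches(matrix: GenotypeMatrix, meta: Sequence[SampleMeta]) -> None:
    """Every sample must have exactly one metadata row."""
    ids = [m.sample_id for m in meta]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate sample ids in metadata")
    missing = set(matrix.samples) - set(ids)
    if missing:
        raise ValidationError(f"samples without metadata: {sorted(missing)}")
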