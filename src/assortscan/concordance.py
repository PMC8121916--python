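"""Two-locus genotype cross-tabulation and signal-preference concordance.

The most direct readout of signal-preference coupling is the 3x3 genotype
table of the autosomal signal locus against the Z-linked preference site,
overall and split by pheromone trap.  The summaries here mirror how such
tables are reported in the field: the percentage of signal-locus
homozygotes that carry the strain-matched preference homozygote, the
percentage of trapped males that are fully concordant multilocus
homozygotes, and the overall two-locus concordance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import MISSING, GenotypeMatrix, SampleMeta, ValidationError

logger = logging.getLogger("assortscan")

#: row/column order of the 3x3 tables
CLASSES = ("hom-E", "het", "hom-Z")


@dataclass
class TwoLocusCrosstab:
    """3x3 signal x preference genotype table, pooled and per trap.

    Rows index the signal-locus genotype and columns the preference-site
    genotype, both in (strain-E homozygote, heterozygote, strain-Z
    homozygote) order under the configured allele mapping (by default the
    E strain carries the reference allele at both loci, the Fig.-style
    E<->C / Z<->T pairing).
    """

    counts: np.ndarray  # (3, 3) pooled
    per_trap: dict[str, np.ndarray] = field(default_factory=dict)
    n_excluded: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (3, 3) or (self.counts < 0).any():
            raise ValidationError("counts must be a non-negative 3x3 table")
        if self.per_trap:
            total = sum(self.per_trap.values())
            if not np.array_equal(np.asarray(total), self.counts):
                raise ValidationError("per-trap tables do not sum to pooled")

    @property
    def n_total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(CLASSES),
                            columns=list(CLASSES))


def _dosage_class(dosage: np.ndarray, e_is_alt: bool) -> np.ndarray:
    """Map dosages to class index 0/1/2 = hom-E/het/hom-Z."""
    cls = dosage.astype(int)  # dosage counts alt; hom-ref -> 0
    if e_is_alt:
        cls = 2 - cls
    return cls


def crosstab(
    G: GenotypeMatrix,
    meta: list[SampleMeta],
    signal_site: tuple[str, int],
    pref_site: tuple[str, int],
    signal_e_is_alt: bool = False,
    pref_e_is_alt: bool = False,
) -> TwoLocusCrosstab:
    """Cross-tabulate the two focal sites, pooled and per trap.

    Samples missing a genotype at either site are excluded with a logged
    count.  The ``*_e_is_alt`` switches say which allele belongs to the E
    strain at each locus.
    """
    js = G.site_index(*signal_site)
    jp = G.site_index(*pref_site)
    meta_by_id = {m.sample_id: m for m in meta}
    pooled = np.zeros((3, 3), dtype=np.int64)
    per_trap: dict[str, np.ndarray] = {}
    n_excluded = 0
    for i, sid in enumerate(G.samples):
        ds, dp = int(G.dosage[i, js]), int(G.dosage[i, jp])
        if ds == MISSING or dp == MISSING:
            n_excluded += 1
            continue
        r = _dosage_class(np.array(ds), signal_e_is_alt)
        c = _dosage_class(np.array(dp), pref_e_is_alt)
        pooled[r, c] += 1
        trap = meta_by_id[sid].trap if sid in meta_by_id else "?"
        per_trap.setdefault(trap, np.zeros((3, 3), np.int64))[r, c] += 1
    if n_excluded:
        logger.warning("crosstab: excluded %d samples with missing genotypes",
                       n_excluded)
    return TwoLocusCrosstab(counts=pooled, per_trap=per_trap,
                            n_excluded=n_excluded)


def class_concordance(ct: TwoLocusCrosstab, signal_class: str) -> int:
    """Percent of a signal-genotype row carrying the matched preference
    homozygote, to the nearest integer.

    The matched cell is hom-E preference for the hom-E signal row and hom-Z
    preference for the hom-Z row.
    """
    r = CLASSES.index(signal_class)
    if signal_class == "het":
        raise ValidationError("no matched homozygote for the het row")
    row = ct.counts[r]
    if row.sum() == 0:
        raise ValidationError(f"empty {signal_class} row")
    return int(round(100.0 * row[r] / row.sum()))


def trap_homozygote_fraction(ct: TwoLocusCrosstab, trap: str) -> int:
    """Percent of males in a trap that are trap-matched double homozygotes.

    E-trap males match the (hom-E, hom-E) cell; Z-trap males the
    (hom-Z, hom-Z) cell.  Nearest integer percent.
    """
    if trap not in ct.per_trap or ct.per_trap[trap].sum() == 0:
        raise ValidationError(f"no samples in trap {trap!r}")
    tab = ct.per_trap[trap]
    cell = tab[0, 0] if trap == "E" else tab[2, 2]
    return int(round(100.0 * cell / tab.sum()))


def overall_concordance(ct: TwoLocusCrosstab) -> float:
    """Percent of all samples in the two concordant double-homozygote cells."""
    if ct.n_total == 0:
        raise ValidationError("empty crosstab")
    return float(100.0 * (ct.counts[0, 0] + ct.counts[2, 2]) / ct.n_total)


def concordance_report(ct: TwoLocusCrosstab) -> pd.DataFrame:
    """Tidy one-row-per-summary report of the concordance percentages."""
    rows = [
        ("hom-E signal, matched pref homozygote (%)",
         class_concordance(ct, "hom-E")),
        ("hom-Z signal, matched pref homozygote (%)",
         class_concordance(ct, "hom-Z")),
        ("overall double-homozygote concordance (%)",
         round(overall_concordance(ct), 1)),
    ]
    for trap in sorted(ct.per_trap):
        if trap in ("E", "Z") and ct.per_trap[trap].sum() > 0:
            rows.append((f"{trap}-trap matched multilocus homozygotes (%)",
                         trap_homozygote_fraction(ct, trap)))
    return pd.DataFrame(rows, columns=["summary", "value"])
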