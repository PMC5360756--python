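"""SNP record filtering, substitution classification and summary statistics.

A call set is reduced to per-site :class:`VariantRecord` objects (single-base
reference, one or more single-base alternatives). Sites pass the
high-quality filter when the phred-scaled calling quality is at least 30
and the read depth at least 10, both thresholds inclusive. Biallelic sites
are classified as transitions (A<->G, C<->T) or transversions; sites with
more than one alternative allele form their own "multiallelic" category and
are excluded from the transition/transversion tally, so the three category
totals always partition the record count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from clovermark.report import percent

logger = logging.getLogger(__name__)

_BASES = frozenset("ACGT")
_TRANSITIONS = (frozenset("AG"), frozenset("CT"))
#: Unordered substitution pairs in canonical report order.
TRANSITION_PAIRS = ("A<->G", "C<->T")
TRANSVERSION_PAIRS = ("A<->C", "C<->G", "G<->T", "T<->A")

_PAIR_ORDER = {
    frozenset("AG"): "A<->G",
    frozenset("CT"): "C<->T",
    frozenset("AC"): "A<->C",
    frozenset("CG"): "C<->G",
    frozenset("GT"): "G<->T",
    frozenset("AT"): "T<->A",
}


@dataclass
class VariantRecord:
    """One SNP site: alleles, calling quality and read depth.

    ``qual`` or ``depth`` of ``None`` marks an unfilterable record: it can
    never enter the high-quality set but is still classified and counted.
    Positions are 1-based as in VCF.
    """

    seq_id: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    qual: float | None = None
    depth: int | None = None
    high_quality: bool = field(default=False)

    def __post_init__(self) -> None:
        self.ref = self.ref.upper()
        self.alts = tuple(a.upper() for a in self.alts)
        if self.ref not in _BASES:
            raise ValueError(f"non-ACGT reference allele {self.ref!r} at {self.seq_id}:{self.pos}")
        if not self.alts:
            raise ValueError(f"no alternative allele at {self.seq_id}:{self.pos}")
        for alt in self.alts:
            if alt not in _BASES:
                raise ValueError(f"non-ACGT alternative allele {alt!r} at {self.seq_id}:{self.pos}")
        if self.ref in self.alts:
            raise ValueError(f"reference allele repeated among alternatives at {self.seq_id}:{self.pos}")
        if len(set(self.alts)) != len(self.alts):
            raise ValueError(f"duplicate alternative alleles at {self.seq_id}:{self.pos}")
        if self.pos < 1:
            raise ValueError(f"position must be 1-based positive, got {self.pos}")

    @property
    def unfilterable(self) -> bool:
        return self.qual is None or self.depth is None

    @property
    def klass(self) -> str:
        return classify_substitution(self)


def classify_substitution(record: VariantRecord) -> str:
    """Classify a record as transition, transversion or multiallelic.

    Transitions are the purine<->purine and pyrimidine<->pyrimidine
    exchanges A<->G and C<->T; every other single exchange is a
    transversion; more than one alternative allele is multiallelic.
    """
    if len(record.alts) > 1:
        return "multiallelic"
    pair = frozenset((record.ref, record.alts[0]))
    return "transition" if pair in _TRANSITIONS else "transversion"


def flag_high_quality(
    records: Iterable[VariantRecord],
    min_qual: float = 30.0,
    min_depth: int = 10,
) -> list[VariantRecord]:
    """Return records with ``high_quality`` set; order preserved.

    A record passes when ``qual >= min_qual`` and ``depth >= min_depth``
    (both inclusive). Records with missing quality or depth fail.
    Pass/fail counts are logged.
    """
    out: list[VariantRecord] = []
    n_pass = 0
    for rec in records:
        ok = (
            rec.qual is not None
            and rec.depth is not None
            and rec.qual >= min_qual
            and rec.depth >= min_depth
        )
        n_pass += ok
        out.append(replace(rec, high_quality=ok))
    logger.info(
        "high-quality filter (qual>=%s, depth>=%s): %d pass, %d fail",
        min_qual, min_depth, n_pass, len(out) - n_pass,
    )
    return out


def composition_from_counts(
    pair_counts: Mapping[str, int],
    n_multiallelic: int = 0,
) -> pd.DataFrame:
    """Substitution composition table from per-pair counts.

    *pair_counts* maps unordered pair labels ("A<->G", ...) to biallelic
    site counts. Returns a table with one row per substitution pair, class
    total rows, and a multiallelic row; within-class and whole-set
    percentages are rounded to 2 decimals. Class totals plus the
    multiallelic count sum to the full record count.
    """
    for key in pair_counts:
        if key not in TRANSITION_PAIRS + TRANSVERSION_PAIRS:
            raise ValueError(f"unknown substitution pair {key!r}")
    ts = {p: int(pair_counts.get(p, 0)) for p in TRANSITION_PAIRS}
    tv = {p: int(pair_counts.get(p, 0)) for p in TRANSVERSION_PAIRS}
    ts_total = sum(ts.values())
    tv_total = sum(tv.values())
    grand = ts_total + tv_total + n_multiallelic

    rows: list[dict] = []

    def _add(category: str, label: str, count: int, class_total: int) -> None:
        rows.append(
            {
                "category": category,
                "pair": label,
                "count": count,
                "pct_within_class": percent(count, class_total, 2) if class_total else 0.0,
                "pct_of_total": percent(count, grand, 2) if grand else 0.0,
            }
        )

    for label, count in ts.items():
        _add("transition", label, count, ts_total)
    _add("transition", "Total", ts_total, grand)
    for label, count in tv.items():
        _add("transversion", label, count, tv_total)
    _add("transversion", "Total", tv_total, grand)
    _add("multiallelic", "Total", n_multiallelic, grand)
    # class-total rows carry the whole-set percentage in both columns
    return pd.DataFrame(rows)


def composition_table(records: Sequence[VariantRecord]) -> pd.DataFrame:
    """Substitution composition of a classified record set (Table-4 layout)."""
    pair_counts: dict[str, int] = {}
    n_multi = 0
    for rec in records:
        if len(rec.alts) > 1:
            n_multi += 1
            continue
        label = _PAIR_ORDER[frozenset((rec.ref, rec.alts[0]))]
        pair_counts[label] = pair_counts.get(label, 0) + 1
    return composition_from_counts(pair_counts, n_multi)


def density_stats(
    n_snps: int, total_cds_bp: float, n_genes: int
) -> tuple[float | None, float | None]:
    """SNP density: (bp per SNP, SNPs per gene), each rounded to 1 decimal.

    Returns ``(None, None)`` for an empty call set instead of dividing.
    """
    if total_cds_bp <= 0 or n_genes <= 0:
        raise ValueError("total_cds_bp and n_genes must be positive")
    if n_snps == 0:
        return None, None
    return round(total_cds_bp / n_snps, 1), round(n_snps / n_genes, 1)
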