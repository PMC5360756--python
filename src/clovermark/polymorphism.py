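"""Polymorphism information content for pooled and individual genotypes.

Pooled PIC (pPIC)
-----------------
Outcrossing forage crops are usually genotyped as pooled DNA samples (here
16 plants per variety), scored on a gel as dominant band presence/absence.
Exact allele frequencies are then unavailable, so the classical PIC cannot
be computed. pPIC instead estimates the probability that two randomly
drawn pooled samples differ at the marker.

Varieties are split into G1 (at least one amplified band) and G0 (no
product). Within G1, with f_i the frequency of band i among G1 profiles,

    pPIC1 = 1 - prod_i (1 - 2 f_i (1 - f_i))

is the probability that two G1-like profiles differ in at least one band,
treating bands as independent. Two G0 samples are indistinguishable
(pPIC0 = 0) and a G1 sample always differs from a G0 sample. Weighting by
the group proportions p1 = N1/(N1+N0), p0 = 1 - p1:

    pPIC = p1^2 * pPIC1 + 2 p1 p0

Botstein PIC
------------
For codominant SNP genotypes with known allele frequencies p_i,

    PIC = 1 - sum_i p_i^2 - sum_{i<j} 2 p_i^2 p_j^2

maximal at equifrequent alleles (0.375 for a biallelic locus at p = 0.5).
Tetraploid dosage-class counts (RRRR..AAAA) yield the alternative-allele
frequency as mean dosage / 4.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import AbstractSet, Iterable, Mapping, Sequence

import numpy as np

from clovermark.formats import BandMatrix, GenotypeCountTable


@dataclass(frozen=True)
class PooledMarkerStats:
    """Per-marker pPIC decomposition."""

    marker_id: str
    band_freqs: tuple[float, ...]  # within G1, all > 0
    n1: int
    n0: int
    ppic1: float
    ppic: float

    @property
    def p1(self) -> float:
        return self.n1 / (self.n1 + self.n0)

    @property
    def p0(self) -> float:
        return self.n0 / (self.n1 + self.n0)


@dataclass(frozen=True)
class AlleleFrequencies:
    """Allele frequency vector for one locus; sums to 1."""

    locus_id: str
    freqs: tuple[float, ...]

    def __post_init__(self) -> None:
        if any(f < 0 for f in self.freqs):
            raise ValueError(f"locus {self.locus_id!r}: negative allele frequency")
        if abs(sum(self.freqs) - 1.0) > 1e-9:
            raise ValueError(f"locus {self.locus_id!r}: frequencies must sum to 1")


def ppic1_from_freqs(freqs: Iterable[float]) -> float:
    """P(two profiles differ in >= 1 band) for independent Bernoulli bands.

    A fixed band (f = 0 or 1) contributes a factor of 1, i.e. no
    information; the explicit loop keeps that code path visible.
    """
    prod = 1.0
    for f in freqs:
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"band frequency {f} outside [0, 1]")
        prod *= 1.0 - 2.0 * f * (1.0 - f)
    return 1.0 - prod


def ppic(
    profiles: Mapping[str, AbstractSet[str]] | Sequence[AbstractSet[str]],
    marker_id: str = "",
) -> PooledMarkerStats:
    """pPIC for one marker from per-variety band sets.

    *profiles* maps variety labels to the set of bands scored present (a
    plain sequence of sets is also accepted). Band frequencies are computed
    within the amplified group G1 only; a band absent from all of G1 does
    not exist. With an empty G1 the marker carries no information and both
    pPIC1 and pPIC are 0.
    """
    if hasattr(profiles, "values"):
        sets = list(profiles.values())
    else:
        sets = list(profiles)
    if not sets:
        raise ValueError("ppic needs at least one variety profile")
    g1 = [s for s in sets if s]
    n1, n0 = len(g1), len(sets) - len(g1)
    if n1 == 0:
        return PooledMarkerStats(marker_id, (), 0, n0, 0.0, 0.0)
    bands = sorted(set().union(*g1))
    freqs = tuple(sum(b in s for s in g1) / n1 for b in bands)
    p1 = n1 / (n1 + n0)
    p0 = n0 / (n1 + n0)
    ppic1 = ppic1_from_freqs(freqs)
    return PooledMarkerStats(
        marker_id=marker_id,
        band_freqs=freqs,
        n1=n1,
        n0=n0,
        ppic1=ppic1,
        ppic=p1 * p1 * ppic1 + 2.0 * p1 * p0,
    )


def ppic_from_band_matrix(bands: BandMatrix, marker: str) -> PooledMarkerStats:
    """pPIC for one marker of a band matrix."""
    profiles = {v: bands.profile(marker, v) for v in bands.varieties}
    return ppic(profiles, marker_id=marker)


def pic(freqs: AlleleFrequencies | Sequence[float]) -> float:
    """Botstein polymorphic information content of one locus."""
    if isinstance(freqs, AlleleFrequencies):
        p = np.asarray(freqs.freqs, dtype=float)
    else:
        p = np.asarray(freqs, dtype=float)
        if (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("allele frequencies must be non-negative and sum to 1")
    s2 = float(np.sum(p**2))
    s4 = float(np.sum(p**4))
    # sum_{i<j} 2 p_i^2 p_j^2 == (sum p^2)^2 - sum p^4
    return 1.0 - s2 - (s2 * s2 - s4)


def freqs_from_tetraploid_counts(table: GenotypeCountTable) -> list[AlleleFrequencies]:
    """Allele frequencies per locus from tetraploid dosage-class counts.

    freq(A) is the mean alternative-allele dosage divided by the ploidy:
    (0*n_RRRR + 1*n_RRRA + 2*n_RRAA + 3*n_RAAA + 4*n_AAAA) / (4 * total).
    Frequencies are returned in (R, A) order.
    """
    out: list[AlleleFrequencies] = []
    for locus_id, counts in table.loci:
        total = sum(counts)
        dosage = sum(k * c for k, c in enumerate(counts))
        q = dosage / (4 * total)
        out.append(AlleleFrequencies(locus_id, (1.0 - q, q)))
    return out


def distribution_summary(
    values: Sequence[float], thresholds: Sequence[float] = ()
) -> dict:
    """min/max/mean/median (3 decimals) and counts strictly above thresholds.

    The median of an even count is the mean of the two central order
    statistics. An empty value list yields an empty summary.
    """
    if any(not 0.0 <= v <= 1.0 for v in values):
        raise ValueError("values must lie in [0, 1]")
    if not values:
        return {"n": 0}
    arr = np.asarray(values, dtype=float)
    summary: dict = {
        "n": int(arr.size),
        "min": round(float(arr.min()), 3),
        "max": round(float(arr.max()), 3),
        "mean": round(float(arr.mean()), 3),
        "median": round(float(np.median(arr)), 3),
    }
    summary["above"] = {
        float(t): int(np.count_nonzero(arr > t)) for t in thresholds
    }
    return summary
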