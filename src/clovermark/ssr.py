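"""Microsatellite (SSR) mining in coding sequences.

Detects maximal perfect tandem repeats with a primitive 1-6 bp motif:
monomers repeated at least 12 times, dimers at least 6, tri-/tetramers at
least 4 and penta-/hexamers at least 3 (the default thresholds). Nearby
simple repeats are merged into complex (compound) loci; a simplified
primer-feasibility screen checks whether flanking primers near a 55 degC
melting temperature can frame a 100-350 bp product.

Coordinates are 1-based inclusive. Motifs are reported on the given strand,
normalized to the lexicographically smallest cyclic rotation (coding
sequences are stranded, so no reverse-complement merging). Runs containing
N are split at the N: an ambiguous base cannot certify a perfect repeat.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from clovermark.formats import SequenceSet
from clovermark.report import percent

CLASS_NAMES = {1: "mono", 2: "di", 3: "tri", 4: "tetra", 5: "penta", 6: "hexa"}

DEFAULT_MIN_REPEATS: dict[int, int] = {1: 12, 2: 6, 3: 4, 4: 4, 5: 3, 6: 3}


@dataclass(frozen=True)
class SsrParams:
    """Mining and primer-screen parameters.

    min_repeats
        Minimum repeat count per motif period (1..6 bp).
    target_tm, tm_tolerance
        Primer melting-temperature target and acceptance half-width, degC.
    product_range
        Acceptable PCR product length, bp, inclusive.
    max_complex_gap
        Maximum gap (bp) between simple repeats merged into a complex locus.
    primer_len_range
        Primer length window, bp, inclusive.
    """

    min_repeats: Mapping[int, int] = field(default_factory=lambda: dict(DEFAULT_MIN_REPEATS))
    target_tm: float = 55.0
    tm_tolerance: float = 3.0
    product_range: tuple[int, int] = (100, 350)
    max_complex_gap: int = 10
    primer_len_range: tuple[int, int] = (18, 24)

    def __post_init__(self) -> None:
        for period in range(1, 7):
            if period not in self.min_repeats:
                raise ValueError(f"min_repeats missing period {period}")
            if self.min_repeats[period] < 2:
                raise ValueError("min_repeats must all be >= 2")
        if not self.product_range[0] < self.product_range[1]:
            raise ValueError("product_range lower bound must be below upper bound")
        if not self.primer_len_range[0] <= self.primer_len_range[1]:
            raise ValueError("invalid primer_len_range")


@dataclass(frozen=True)
class SsrLocus:
    """One detected microsatellite (simple or complex), 1-based inclusive.

    For simple loci ``end - start + 1 == len(motif) * repeats`` and the
    motif is primitive (not a power of a shorter motif). Complex loci carry
    their simple components; their motif is the dash-joined component
    motifs and ``repeats`` the component total.
    """

    seq_id: str
    start: int
    end: int
    motif: str
    repeats: int
    klass: str
    components: tuple["SsrLocus", ...] = ()
    primer_designable: bool | None = None

    @property
    def span(self) -> int:
        return self.end - self.start + 1

    @property
    def length_frame_preserving(self) -> bool:
        """Whether the locus length is a multiple of 3 (reading-frame safe)."""
        return self.span % 3 == 0


def primitive_motif(motif: str) -> bool:
    """True iff *motif* is not an integer power of a shorter string."""
    n = len(motif)
    for d in range(1, n):
        if n % d == 0 and motif == motif[:d] * (n // d):
            return False
    return True


def canonical_rotation(motif: str) -> str:
    """Lexicographically smallest cyclic rotation (same strand)."""
    return min(motif[i:] + motif[:i] for i in range(len(motif)))


def _resolve_overlaps(candidates: list[SsrLocus]) -> list[SsrLocus]:
    """Greedy overlap resolution: longer span wins, ties to smaller period."""
    order = sorted(
        candidates, key=lambda c: (-c.span, len(c.motif), c.start)
    )
    accepted: list[SsrLocus] = []
    for cand in order:
        if all(cand.end < a.start or cand.start > a.end for a in accepted):
            accepted.append(cand)
    accepted.sort(key=lambda c: c.start)
    return accepted


def find_perfect_runs(
    seq: str, params: SsrParams | None = None, seq_id: str = ""
) -> list[SsrLocus]:
    """All maximal perfect tandem runs meeting the repeat thresholds.

    For each period 1-6, maximal stretches where the sequence equals itself
    shifted by the period are located; a stretch of length L anchors
    ``floor(L / period)`` full repeats at its left end. Only primitive
    motifs are kept (a run of ATAT... is a dimer, never a tetramer), so
    each repeated span is reported once at its smallest period.
    Overlapping runs of different periods are resolved by keeping the
    longer span, ties going to the smaller period. Output is sorted by
    start position.
    """
    params = params or SsrParams()
    seq = seq.upper()
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    n = arr.size
    valid = (
        (arr == ord("A")) | (arr == ord("C")) | (arr == ord("G")) | (arr == ord("T"))
    )
    candidates: list[SsrLocus] = []
    for period in range(1, 7):
        min_len = period * params.min_repeats[period]
        if n < min_len:
            continue
        match = (arr[:-period] == arr[period:]) & valid[:-period] & valid[period:]
        # maximal True stretches of `match`
        padded = np.concatenate(([False], match, [False]))
        edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
        for a, b in zip(edges[::2].tolist(), edges[1::2].tolist()):
            # stretch covers characters [a, b + period)
            run_len = (b - a) + period
            repeats = run_len // period
            if repeats < params.min_repeats[period]:
                continue
            motif = seq[a : a + period]
            if not primitive_motif(motif):
                continue
            candidates.append(
                SsrLocus(
                    seq_id=seq_id,
                    start=a + 1,
                    end=a + period * repeats,
                    motif=canonical_rotation(motif),
                    repeats=repeats,
                    klass=CLASS_NAMES[period],
                )
            )
    return _resolve_overlaps(candidates)


def merge_complex(loci: Sequence[SsrLocus], params: SsrParams | None = None) -> list[SsrLocus]:
    """Merge consecutive simple loci separated by small gaps into complex loci.

    Loci must be sorted by start and share one seq_id. Groups of two or
    more simple runs with pairwise inter-locus gaps of at most
    ``max_complex_gap`` bp become a single complex locus carrying its
    components; isolated runs pass through unchanged.
    """
    params = params or SsrParams()
    loci = list(loci)
    if not loci:
        return []
    if len({lc.seq_id for lc in loci}) > 1:
        raise ValueError("merge_complex expects loci from a single sequence")
    if any(loci[i].start > loci[i + 1].start for i in range(len(loci) - 1)):
        raise ValueError("loci must be sorted by start")

    out: list[SsrLocus] = []
    group: list[SsrLocus] = [loci[0]]
    for locus in loci[1:]:
        gap = locus.start - group[-1].end - 1
        if gap <= params.max_complex_gap:
            group.append(locus)
        else:
            out.append(_collapse(group))
            group = [locus]
    out.append(_collapse(group))
    return out


def _collapse(group: list[SsrLocus]) -> SsrLocus:
    if len(group) == 1:
        return group[0]
    return SsrLocus(
        seq_id=group[0].seq_id,
        start=group[0].start,
        end=group[-1].end,
        motif="-".join(c.motif for c in group),
        repeats=sum(c.repeats for c in group),
        klass="complex",
        components=tuple(group),
    )


# ---------------------------------------------------------------------------
# Primer feasibility


@dataclass(frozen=True)
class PrimerDesign:
    """Outcome of the flanking-primer screen for one locus."""

    feasible: bool
    reason: str = ""
    left: tuple[int, int] | None = None   # 1-based inclusive primer window
    right: tuple[int, int] | None = None
    tm_left: float | None = None
    tm_right: float | None = None
    product_len: int | None = None


def wallace_tm(n_at: int, n_gc: int) -> float:
    """Wallace rule 2(A+T) + 4(G+C), used for primers up to 20 bases."""
    return 2.0 * n_at + 4.0 * n_gc


def gc_fraction_tm(n_at: int, n_gc: int) -> float:
    """Marmur-style GC-fraction estimate 64.9 + 41*(GC - 16.4)/N for longer primers."""
    n = n_at + n_gc
    return 64.9 + 41.0 * (n_gc - 16.4) / n


def estimate_tm(n_at: int, n_gc: int) -> float:
    return wallace_tm(n_at, n_gc) if n_at + n_gc <= 20 else gc_fraction_tm(n_at, n_gc)


def primer_feasible(
    seq: str, locus: SsrLocus, params: SsrParams | None = None
) -> PrimerDesign:
    """Exhaustive screen for a feasible flanking primer pair.

    Feasible when left and right flanking windows within the primer length
    range exist whose estimated melting temperatures fall within the Tm
    tolerance of the target and whose implied product length (left primer
    start to right primer end) lies in the product range. The returned pair
    minimizes the summed Tm deviation, ties going to the shortest product
    (then leftmost/shortest windows, for determinism).
    """
    params = params or SsrParams()
    seq = seq.upper()
    n = len(seq)
    if not (1 <= locus.start <= locus.end <= n):
        raise ValueError("locus does not lie within the sequence")
    len_lo, len_hi = params.primer_len_range
    prod_lo, prod_hi = params.product_range
    left_room = locus.start - 1
    right_room = n - locus.end
    if left_room < len_lo or right_room < len_lo or n < prod_lo:
        return PrimerDesign(False, reason="insufficient flank")

    is_gc = np.array([c in "GC" for c in seq], dtype=np.int32)
    is_acgt = np.array([c in "ACGT" for c in seq], dtype=np.int32)
    gc = np.concatenate(([0], np.cumsum(is_gc)))
    acgt = np.concatenate(([0], np.cumsum(is_acgt)))

    def window_tm(a: int, b: int) -> float | None:
        """Tm of 1-based inclusive window [a, b]; None if it contains N."""
        length = b - a + 1
        if acgt[b] - acgt[a - 1] != length:
            return None
        n_gc = int(gc[b] - gc[a - 1])
        return estimate_tm(length - n_gc, n_gc)

    tol = params.tm_tolerance
    target = params.target_tm

    # right windows grouped by end coordinate: best (dev, length, start)
    best_right: dict[int, tuple[float, int, int]] = {}
    for b in range(locus.end + len_lo, n + 1):
        for length in range(len_lo, len_hi + 1):
            a = b - length + 1
            if a < locus.end + 1:
                continue
            tm = window_tm(a, b)
            if tm is None or abs(tm - target) > tol:
                continue
            entry = (abs(tm - target), length, a)
            if b not in best_right or entry < best_right[b]:
                best_right[b] = entry

    best: tuple[float, int, int, int, int, int, float, float] | None = None
    # left windows must start late enough that some product <= prod_hi exists
    min_left_start = max(1, locus.end + len_lo - prod_hi + 1)
    for a in range(min_left_start, locus.start - len_lo + 2):
        for length in range(len_lo, len_hi + 1):
            b = a + length - 1
            if b > locus.start - 1:
                continue
            tm_l = window_tm(a, b)
            if tm_l is None or abs(tm_l - target) > tol:
                continue
            dev_l = abs(tm_l - target)
            for r_end in range(a + prod_lo - 1, a + prod_hi):
                entry = best_right.get(r_end)
                if entry is None:
                    continue
                dev_r, r_len, r_start = entry
                product = r_end - a + 1
                tm_r = window_tm(r_start, r_end)
                key = (dev_l + dev_r, product, a, length, r_start, r_len, tm_l, tm_r)
                if best is None or key[:6] < best[:6]:
                    best = key

    if best is None:
        return PrimerDesign(False, reason="no primer pair within Tm and product constraints")
    _, product, a, length, r_start, r_len, tm_l, tm_r = best
    return PrimerDesign(
        True,
        left=(a, a + length - 1),
        right=(r_start, r_start + r_len - 1),
        tm_left=tm_l,
        tm_right=tm_r,
        product_len=product,
    )


# ---------------------------------------------------------------------------
# Whole-set mining and summary


def mine(
    seqs: SequenceSet,
    params: SsrParams | None = None,
    merge: bool = True,
    primer_check: bool = True,
) -> list[SsrLocus]:
    """Mine every sequence: perfect runs, complex merging, primer screen."""
    params = params or SsrParams()
    out: list[SsrLocus] = []
    for seq_id, seq in seqs:
        loci = find_perfect_runs(seq, params, seq_id=seq_id)
        if merge:
            loci = merge_complex(loci, params)
        if primer_check:
            loci = [
                replace(lc, primer_designable=primer_feasible(seq, lc, params).feasible)
                for lc in loci
            ]
        out.extend(loci)
    return out


@dataclass(frozen=True)
class SsrSummary:
    """Mining report: class counts, primer feasibility, density, multiplicity."""

    n_loci: int
    class_counts: dict[str, int]
    n_designable: int
    designable_pct: float | None
    n_sequences: int
    n_sequences_with_locus: int
    sequences_with_locus_pct: float | None
    density_bp_per_marker: float | None
    multiplicity_histogram: dict[int, int]
    frame_preserving_pct: float | None

    def to_frame(self) -> pd.DataFrame:
        rows = [("n_loci", self.n_loci)]
        rows += [(f"n_{k}", v) for k, v in self.class_counts.items()]
        rows += [
            ("n_designable", self.n_designable),
            ("designable_pct", self.designable_pct),
            ("n_sequences", self.n_sequences),
            ("n_sequences_with_locus", self.n_sequences_with_locus),
            ("sequences_with_locus_pct", self.sequences_with_locus_pct),
            ("density_bp_per_marker", self.density_bp_per_marker),
            ("frame_preserving_pct", self.frame_preserving_pct),
        ]
        rows += [
            (f"n_sequences_with_{k}_loci", v)
            for k, v in sorted(self.multiplicity_histogram.items())
        ]
        return pd.DataFrame(rows, columns=["statistic", "value"])


def ssr_summary(
    loci: Iterable[SsrLocus], total_cds_bp: int, n_sequences: int
) -> SsrSummary:
    """Summarize a mined locus set.

    Density is total coding length per primer-designable marker (reported
    NA when nothing is designable); percentages are rounded to 1 decimal.
    The multiplicity histogram counts sequences by their number of loci.
    The frame-preserving fraction is the share of simple non-trimeric loci
    whose total length is divisible by 3 (selection in coding sequence
    tends to preserve reading frame).
    """
    if total_cds_bp <= 0:
        raise ValueError("total_cds_bp must be positive")
    loci = list(loci)
    class_counts = {k: 0 for k in [*CLASS_NAMES.values(), "complex"]}
    per_seq: dict[str, int] = {}
    n_designable = 0
    n_frame_candidates = 0
    n_frame_preserving = 0
    for lc in loci:
        class_counts[lc.klass] += 1
        per_seq[lc.seq_id] = per_seq.get(lc.seq_id, 0) + 1
        if lc.primer_designable:
            n_designable += 1
        if lc.klass not in ("tri", "complex"):
            n_frame_candidates += 1
            n_frame_preserving += lc.length_frame_preserving
    multiplicity: dict[int, int] = {}
    for count in per_seq.values():
        multiplicity[count] = multiplicity.get(count, 0) + 1
    n_with = len(per_seq)
    return SsrSummary(
        n_loci=len(loci),
        class_counts=class_counts,
        n_designable=n_designable,
        designable_pct=percent(n_designable, len(loci)) if loci else None,
        n_sequences=n_sequences,
        n_sequences_with_locus=n_with,
        sequences_with_locus_pct=percent(n_with, n_sequences) if n_sequences else None,
        density_bp_per_marker=(
            round(total_cds_bp / n_designable, 1) if n_designable else None
        ),
        multiplicity_histogram=multiplicity,
        frame_preserving_pct=(
            percent(n_frame_preserving, n_frame_candidates) if n_frame_candidates else None
        ),
    )
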