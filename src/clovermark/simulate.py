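"""Synthetic inputs with known generating truth for every pipeline stage.

The generators emulate the study conditions of a pooled-sample marker
survey in red clover: 50 varieties genotyped as pools of 16 plants, gel
band profiles per SSR marker, coding sequences with planted
microsatellites, a GATK-style SNP call set with a chosen
transition/transversion odds, and tetraploid dosage genotypes drawn from
per-locus allele frequencies.

A single integer seed drives one root random stream; per-generator
sub-streams are spawned from it so adding a generator never perturbs the
others. Identical configurations produce byte-identical outputs.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from clovermark.formats import (
    BandMatrix,
    GenotypeCountTable,
    SequenceSet,
)
from clovermark.report import atomic_write
from clovermark.ssr import SsrParams, find_perfect_runs, SsrLocus

#: Transition/transversion odds of the red clover coding-sequence call set
#: this package emulates (217,894 transitions to 121,068 transversions).
DEFAULT_TS_TV_ODDS = 217894 / 121068

_TRANSITION_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSION_PARTNERS = {
    "A": ("C", "T"), "C": ("A", "G"), "G": ("C", "T"), "T": ("A", "G"),
}


@dataclass(frozen=True)
class MarkerModel:
    """Generating model for one dominant SSR marker.

    band_freqs
        Per-band presence probabilities for an amplified pooled sample.
    amplification_prob
        Probability a variety's pooled sample yields any PCR product.
    """

    band_freqs: tuple[float, ...]
    amplification_prob: float = 1.0

    def __post_init__(self) -> None:
        if not self.band_freqs:
            raise ValueError("marker needs at least one band")
        if any(not 0.0 <= f <= 1.0 for f in self.band_freqs):
            raise ValueError("band frequencies must lie in [0, 1]")
        if not 0.0 <= self.amplification_prob <= 1.0:
            raise ValueError("amplification_prob must lie in [0, 1]")
        if self.amplification_prob > 0 and all(f == 0.0 for f in self.band_freqs):
            raise ValueError("an amplifiable marker needs a band with positive frequency")

    @property
    def n_bands(self) -> int:
        return len(self.band_freqs)

    def conditional_band_freqs(self) -> tuple[float, ...]:
        """Expected band frequencies among amplified profiles.

        Amplified profiles are conditioned on showing at least one band
        (a pooled sample in G1 by definition has a product), which raises
        each marginal from f_i to f_i / (1 - prod_j (1 - f_j)).
        """
        p_none = float(np.prod([1.0 - f for f in self.band_freqs]))
        return tuple(f / (1.0 - p_none) for f in self.band_freqs)


@dataclass(frozen=True)
class SnpModel:
    """Generating model for a synthetic SNP call set.

    Biallelic sites are transitions with odds ``ts_tv_odds`` (default: the
    odds of the red clover call set, ~1.80); a fraction ``multiallelic_frac``
    of sites carries two alternative alleles. QUAL is drawn from a normal
    distribution and depth from a Poisson, both chosen to straddle the
    30 / 10 high-quality thresholds the way a real call set does.
    """

    n_snps: int = 10_000
    ts_tv_odds: float = DEFAULT_TS_TV_ODDS
    multiallelic_frac: float = 0.0119
    qual_mean: float = 45.0
    qual_sd: float = 12.0
    depth_mean: float = 18.0

    def __post_init__(self) -> None:
        if self.n_snps < 1:
            raise ValueError("n_snps must be positive")
        if self.ts_tv_odds <= 0:
            raise ValueError("ts_tv_odds must be positive")
        if not 0.0 <= self.multiallelic_frac <= 1.0:
            raise ValueError("multiallelic_frac must lie in [0, 1]")


@dataclass(frozen=True)
class TetraploidModel:
    """Generating model for tetraploid dosage genotypes.

    Per locus an alternative-allele frequency q is drawn uniformly from
    ``allele_freq_range``; each plant's dosage is Binomial(4, q).
    """

    n_loci: int = 500
    n_plants: int = 20
    allele_freq_range: tuple[float, float] = (0.05, 0.95)


@dataclass(frozen=True)
class SimConfig:
    """Study-scale simulation configuration.

    Defaults mirror the emulated survey: 50 varieties, pools of 16 plants,
    and per-marker band counts between 1 and 17. ``markers=None`` draws
    marker models from the stream (band count uniform on 1..17, band
    frequencies uniform on [0.05, 0.95], amplification probability uniform
    on [0.6, 1.0]); pass explicit :class:`MarkerModel` objects for
    controlled truth.
    """

    seed: int = 0
    n_varieties: int = 50
    pool_size: int = 16
    n_markers: int = 95
    markers: tuple[MarkerModel, ...] | None = None
    n_sequences: int = 100
    seq_len: int = 600
    planted_ssrs: tuple[tuple[str, int, int], ...] = (("AAG", 4, 301),)
    snp_model: SnpModel = field(default_factory=SnpModel)
    tetraploid_model: TetraploidModel = field(default_factory=TetraploidModel)
    ssr_params: SsrParams = field(default_factory=SsrParams)

    def __post_init__(self) -> None:
        if self.n_varieties < 1 or self.pool_size < 1:
            raise ValueError("n_varieties and pool_size must be positive")
        if self.n_sequences < 1 or self.seq_len < 1:
            raise ValueError("n_sequences and seq_len must be positive")


def _streams(cfg: SimConfig) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(cfg.seed).spawn(4)
    names = ("bands", "cds", "variants", "genotypes")
    return {name: np.random.default_rng(ss) for name, ss in zip(names, children)}


# ---------------------------------------------------------------------------
# Band matrices


def simulate_band_matrix(cfg: SimConfig) -> tuple[BandMatrix, tuple[MarkerModel, ...]]:
    """Bernoulli band-presence matrix plus the generating marker models.

    Per marker and variety, amplification succeeds with the marker's
    amplification probability; on success each band is present
    independently with its frequency, rejection-resampled so an amplified
    profile always shows at least one band (conditioning on a product).
    A failed amplification leaves the variety's row all zero.
    """
    rng = _streams(cfg)["bands"]
    if cfg.markers is not None:
        models = tuple(cfg.markers)
    else:
        models = tuple(
            MarkerModel(
                band_freqs=tuple(
                    rng.uniform(0.05, 0.95, size=rng.integers(1, 18)).round(6)
                ),
                amplification_prob=round(float(rng.uniform(0.6, 1.0)), 6),
            )
            for _ in range(cfg.n_markers)
        )
    varieties = tuple(f"variety_{i + 1:03d}" for i in range(cfg.n_varieties))
    presence: dict[str, dict[str, dict[str, int]]] = {}
    markers: list[str] = []
    for m_idx, model in enumerate(models):
        marker = f"marker_{m_idx + 1:03d}"
        markers.append(marker)
        freqs = np.asarray(model.band_freqs)
        amplified = rng.random(cfg.n_varieties) < model.amplification_prob
        profiles = (rng.random((cfg.n_varieties, freqs.size)) < freqs).astype(np.int8)
        # rejection-resample amplified all-zero rows until every one has a band
        while True:
            empty = amplified & (profiles.sum(axis=1) == 0)
            if not empty.any():
                break
            k = int(empty.sum())
            profiles[empty] = (rng.random((k, freqs.size)) < freqs).astype(np.int8)
        profiles[~amplified] = 0
        presence[marker] = {
            f"band_{b + 1:02d}": {
                v: int(profiles[i, b]) for i, v in enumerate(varieties)
            }
            for b in range(freqs.size)
        }
    bands = BandMatrix(varieties=varieties, markers=tuple(markers), presence=presence)
    return bands, models


# ---------------------------------------------------------------------------
# Coding sequences with planted SSRs


def simulate_cds_with_ssrs(cfg: SimConfig) -> tuple[SequenceSet, list[SsrLocus]]:
    """Random coding sequences with planted microsatellites at known spots.

    Background bases are i.i.d. uniform ACGT. Each sequence receives every
    planted (motif, repeats, 1-based position) run. Bases adjacent to a
    planted run are fixed so the run cannot extend, keeping truth
    coordinates exact; chance runs meeting the mining thresholds outside
    the planted intervals are broken by replacing their last base.
    """
    rng = _streams(cfg)["cds"]
    bases = np.array(list("ACGT"))
    truth: list[SsrLocus] = []
    records: list[tuple[str, str]] = []
    for s_idx in range(cfg.n_sequences):
        seq_id = f"cds_{s_idx + 1:05d}"
        seq = rng.choice(bases, size=cfg.seq_len)
        intervals: list[tuple[int, int]] = []  # 0-based half-open
        for motif, repeats, pos in cfg.planted_ssrs:
            motif = motif.upper()
            run = (motif * repeats)
            a = pos - 1
            b = a + len(run)
            if b > cfg.seq_len or a < 0:
                raise ValueError(f"planted run {motif}x{repeats} at {pos} exceeds seq_len")
            for prev_a, prev_b in intervals:
                if a < prev_b + 1 and b > prev_a - 1:
                    raise ValueError("planted intervals overlap or touch")
            seq[a:b] = list(run)
            period = len(motif)
            # block periodic extension on either side of the run
            if a > 0:
                left_clash = seq[a + period - 1]
                seq[a - 1] = _other_base(left_clash, rng)
            if b < cfg.seq_len:
                right_clash = seq[b - period]
                seq[b] = _other_base(right_clash, rng)
            intervals.append((a, b))
            truth.append(
                SsrLocus(
                    seq_id=seq_id,
                    start=a + 1,
                    end=b,
                    motif=_canonical(motif),
                    repeats=repeats,
                    klass=_klass(period),
                )
            )
        _break_chance_runs(seq, intervals, cfg.ssr_params, rng)
        records.append((seq_id, "".join(seq)))
    return SequenceSet(tuple(records)), truth


def _other_base(base: str, rng: np.random.Generator) -> str:
    choices = [b for b in "ACGT" if b != base]
    return choices[int(rng.integers(0, 3))]


def _canonical(motif: str) -> str:
    from clovermark.ssr import canonical_rotation

    return canonical_rotation(motif)


def _klass(period: int) -> str:
    from clovermark.ssr import CLASS_NAMES

    return CLASS_NAMES[period]


def _break_chance_runs(
    seq: np.ndarray,
    planted: list[tuple[int, int]],
    params: SsrParams,
    rng: np.random.Generator,
    max_rounds: int = 50,
) -> None:
    """Mutate chance runs meeting thresholds outside planted intervals."""
    planted_spans = {(a + 1, b) for a, b in planted}
    for _ in range(max_rounds):
        found = find_perfect_runs("".join(seq), params)
        chance = [
            lc for lc in found if (lc.start, lc.end) not in planted_spans
        ]
        # a run overlapping a planted interval only via resolution is still
        # chance if its own span is not a planted span
        dirty = False
        for lc in chance:
            for pos in range(lc.end - 1, lc.start - 2, -1):  # 0-based from the end
                if not any(a <= pos < b for a, b in planted):
                    seq[pos] = _other_base(seq[pos], rng)
                    dirty = True
                    break
        if not dirty:
            return
    raise RuntimeError("could not break chance SSR runs; lower the simulated length")


# ---------------------------------------------------------------------------
# Variant call sets


def simulate_variants(
    cfg: SimConfig, path: str | os.PathLike
) -> list[dict]:
    """Write a synthetic VCF and return the per-site generating truth.

    Each site is multiallelic with the configured fraction; biallelic
    sites are transitions with probability odds/(1+odds). QUAL ~ Normal
    (truncated at 0, 1 decimal) and depth ~ Poisson. Truth records the
    class and the expected high-quality flag of every site.
    """
    rng = _streams(cfg)["variants"]
    model = cfg.snp_model
    n = model.n_snps
    p_ts = model.ts_tv_odds / (1.0 + model.ts_tv_odds)
    refs = rng.choice(np.array(list("ACGT")), size=n)
    is_multi = rng.random(n) < model.multiallelic_frac
    is_ts = rng.random(n) < p_ts
    quals = np.clip(rng.normal(model.qual_mean, model.qual_sd, size=n), 0, None).round(1)
    depths = rng.poisson(model.depth_mean, size=n)
    positions = np.sort(rng.choice(np.arange(1, n * 150), size=n, replace=False))

    truth: list[dict] = []
    with atomic_write(path) as out:
        out.write("##fileformat=VCFv4.2\n")
        out.write("##source=clovermark-simulate\n")
        out.write(f"##contig=<ID=synthetic_cds,length={int(positions[-1]) + 100}>\n")
        out.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        out.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Sample depth">\n')
        out.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tpool\n")
        for i in range(n):
            ref = str(refs[i])
            if is_multi[i]:
                alts = [b for b in "ACGT" if b != ref]
                alt_list = sorted(rng.choice(alts, size=2, replace=False))
                klass = "multiallelic"
            elif is_ts[i]:
                alt_list = [_TRANSITION_PARTNER[ref]]
                klass = "transition"
            else:
                partners = _TRANSVERSION_PARTNERS[ref]
                alt_list = [partners[int(rng.integers(0, 2))]]
                klass = "transversion"
            qual = float(quals[i])
            depth = int(depths[i])
            expected_pass = qual >= 30.0 and depth >= 10
            out.write(
                f"synthetic_cds\t{int(positions[i])}\t.\t{ref}\t{','.join(alt_list)}"
                f"\t{qual}\t.\tDP={depth}\tDP\t{depth}\n"
            )
            truth.append(
                {
                    "pos": int(positions[i]),
                    "ref": ref,
                    "alts": tuple(alt_list),
                    "klass": klass,
                    "qual": qual,
                    "depth": depth,
                    "expected_pass": expected_pass,
                }
            )
    return truth


# ---------------------------------------------------------------------------
# Tetraploid genotypes


def simulate_tetraploid_genotypes(
    cfg: SimConfig,
) -> tuple[GenotypeCountTable, list[float]]:
    """Dosage-class counts per locus plus the generating allele frequencies."""
    rng = _streams(cfg)["genotypes"]
    model = cfg.tetraploid_model
    lo, hi = model.allele_freq_range
    loci: list[tuple[str, tuple[int, int, int, int, int]]] = []
    truth: list[float] = []
    for l_idx in range(model.n_loci):
        q = float(rng.uniform(lo, hi))
        dosages = rng.binomial(4, q, size=model.n_plants)
        counts = tuple(int(np.count_nonzero(dosages == k)) for k in range(5))
        loci.append((f"locus_{l_idx + 1:05d}", counts))  # type: ignore[arg-type]
        truth.append(q)
    return GenotypeCountTable(tuple(loci)), truth
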