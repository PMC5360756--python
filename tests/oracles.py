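"""Independent reference implementations used to cross-check the package.

Everything here is deliberately written against the *definitions* (triple
enumeration, explicit double sums, Monte-Carlo simulation) and shares no
code path with the implementations under test.
"""

from __future__ import annotations

import numpy as np


# ---------------------------------------------------------------------------
# Brute-force SSR scanner


def _is_power_of_shorter(motif: str) -> bool:
    for d in range(1, len(motif)):
        if len(motif) % d == 0 and motif == motif[:d] * (len(motif) // d):
            return True
    return False


def _smallest_rotation(motif: str) -> str:
    return min(motif[i:] + motif[:i] for i in range(len(motif)))


def brute_force_ssr(seq: str, min_repeats: dict[int, int]) -> list[tuple]:
    """Enumerate every (start, period, length) triple and keep maximal runs.

    Returns tuples (start, end, motif, repeats, period), 1-based inclusive,
    after the same longer-span / smaller-period overlap resolution rule,
    re-implemented independently with an interval sweep.
    """
    seq = seq.upper()
    n = len(seq)
    candidates = []
    for period, min_rep in min_repeats.items():
        for start in range(n - period * min_rep + 1):
            motif = seq[start : start + period]
            if any(c not in "ACGT" for c in motif):
                continue
            # left-maximal: the shifted-match condition must fail just before
            if start > 0 and seq[start - 1] == seq[start - 1 + period] and seq[start - 1] in "ACGT":
                continue
            # grow char by char while the run stays periodic
            length = period
            while start + length < n and seq[start + length] == seq[start + length - period] and seq[start + length] in "ACGT":
                length += 1
            repeats = length // period
            if repeats < min_rep:
                continue
            if _is_power_of_shorter(motif):
                continue
            end = start + period * repeats  # exclusive
            candidates.append(
                (start + 1, end, _smallest_rotation(motif), repeats, period)
            )
    # overlap resolution: longer span wins; ties to smaller period
    candidates.sort(key=lambda c: (-(c[1] - c[0] + 1), c[4], c[0]))
    kept: list[tuple] = []
    for cand in candidates:
        if all(cand[1] < k[0] or cand[0] > k[1] for k in kept):
            kept.append(cand)
    kept.sort(key=lambda c: c[0])
    return kept


# ---------------------------------------------------------------------------
# PIC by exhaustive index enumeration


def pic_double_sum(freqs) -> float:
    total = 1.0
    for p in freqs:
        total -= p * p
    k = len(freqs)
    for i in range(k):
        for j in range(i + 1, k):
            total -= 2.0 * freqs[i] ** 2 * freqs[j] ** 2
    return total


# ---------------------------------------------------------------------------
# Monte-Carlo pPIC


def ppic_monte_carlo(
    band_freqs,
    p_amplified: float,
    n_pairs: int,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Estimate P(two pooled samples differ) by simulation.

    Each sample amplifies with probability ``p_amplified``; amplified
    samples carry independent Bernoulli(f_i) bands (unconditioned — this
    checks the closed-form product formula and the 2*p1*p0 cross term).
    Returns (estimate, standard error).
    """
    f = np.asarray(band_freqs, dtype=float)
    amp = rng.random((2, n_pairs)) < p_amplified
    bands_a = rng.random((n_pairs, f.size)) < f
    bands_b = rng.random((n_pairs, f.size)) < f
    band_diff = (bands_a != bands_b).any(axis=1)
    differ = (amp[0] != amp[1]) | (amp[0] & amp[1] & band_diff)
    p_hat = float(differ.mean())
    se = float(np.sqrt(p_hat * (1.0 - p_hat) / n_pairs))
    return p_hat, se


# ---------------------------------------------------------------------------
# Cophenetic matrix of a clovermark tree (for UPGMA cross-checks)


def cophenetic_matrix(tree, labels) -> np.ndarray:
    pairs = tree.cophenetic()
    n = len(labels)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = pairs[frozenset((labels[i], labels[j]))]
    return out
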