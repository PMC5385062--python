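"""Independent reference implementations used as test oracles.

Each oracle deliberately takes a different route from the package code it
checks: brute-force enumeration, direct textbook formulas, or exhaustive
permutation, at sizes where that is affordable.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

COMPLEMENT = str.maketrans("ACGT", "TGCA")


# ---------------------------------------------------------------------------
# Gapless free-overhang alignment (substitution-only optimum)
# ---------------------------------------------------------------------------


def best_gapless_alignment(seq_a: str, seq_b: str) -> tuple[int, int, int]:
    """Best (score, matches, columns) over all gapless dovetail spans.

    A dovetail span starts at the 5' end of one sequence and stops at the
    3' end of one sequence (the overhangs are free); its score is
    matches - mismatches.  For substitution-only sequence pairs this is the
    optimum of a free-end-gap global alignment whose gap costs make
    internal gaps unprofitable and whose DP forbids adjacent
    insertion/deletion moves (so ends cannot be trimmed on both sequences
    at once).
    """
    len_a, len_b = len(seq_a), len(seq_b)
    best = (0, 0, 0)
    starts = [(i, 0) for i in range(len_a)] + [(0, j) for j in range(1, len_b)]
    for i, j in starts:
        for length in {len_a - i, len_b - j}:
            if length < 1 or i + length > len_a or j + length > len_b:
                continue
            matches = sum(
                1
                for k in range(length)
                if seq_a[i + k] == seq_b[j + k]
            )
            score = 2 * matches - length
            if score > best[0]:
                best = (score, matches, length)
    return best


# ---------------------------------------------------------------------------
# Connected components over an explicit link graph
# ---------------------------------------------------------------------------


def brute_force_components(ids: list[str], links: set[frozenset[str]]) -> list[list[str]]:
    """Connected components by repeated breadth-first search."""
    remaining = set(ids)
    components = []
    while remaining:
        seed = min(remaining)
        component = {seed}
        frontier = [seed]
        while frontier:
            node = frontier.pop()
            for other in list(remaining - component):
                if frozenset((node, other)) in links:
                    component.add(other)
                    frontier.append(other)
        components.append(sorted(component))
        remaining -= component
    return sorted(components, key=lambda c: c[0])


# ---------------------------------------------------------------------------
# Nearest-neighbor melting temperature (SantaLucia 1998 unified parameters)
# ---------------------------------------------------------------------------

_NN_PARAMS = {  # dH kcal/mol, dS cal/(mol K)
    "AA": (-7.9, -22.2),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7),
    "GT": (-8.4, -22.4),
    "CT": (-7.8, -21.0),
    "GA": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9),
}


def nn_melting_temperature(
    seq: str, dnac1: float = 250.0, dnac2: float = 250.0, Na: float = 50.0
) -> float:
    """Unified nearest-neighbor Tm with the SantaLucia entropy salt correction."""
    dh = ds = 0.0
    for terminal in (seq[0], seq[-1]):
        if terminal in "AT":
            dh += 2.3
            ds += 4.1
        else:
            dh += 0.1
            ds += -2.8
    for i in range(len(seq) - 1):
        pair = seq[i : i + 2]
        if pair not in _NN_PARAMS:
            pair = pair.translate(COMPLEMENT)[::-1]
        h, s = _NN_PARAMS[pair]
        dh += h
        ds += s
    ds += 0.368 * (len(seq) - 1) * math.log(Na / 1000.0)
    k = (dnac1 - dnac2 / 2.0) * 1e-9
    return dh * 1000.0 / (ds + 1.987 * math.log(k)) - 273.15


# ---------------------------------------------------------------------------
# Decamer substring scan
# ---------------------------------------------------------------------------


def scan_decamer_hits(decamer: str, sequences: list[str]) -> int:
    """Position-by-position exact substring scan on both strands."""
    rc = decamer.translate(COMPLEMENT)[::-1]
    hits = 0
    for seq in sequences:
        found = False
        for probe in (decamer, rc):
            for i in range(0, len(seq) - len(probe) + 1):
                if seq[i : i + len(probe)] == probe:
                    found = True
                    break
            if found:
                break
        hits += found
    return hits


# ---------------------------------------------------------------------------
# Levene W, direct textbook formula
# ---------------------------------------------------------------------------


def levene_w_formula(sample_a, sample_b, center: str = "mean") -> float:
    """W = (N-k)/(k-1) * sum n_i (Zbar_i - Zbar)^2 / sum sum (Z_ij - Zbar_i)^2."""
    groups = [np.asarray(sample_a, float), np.asarray(sample_b, float)]
    center_fn = np.mean if center == "mean" else np.median
    z = [np.abs(g - center_fn(g)) for g in groups]
    n = [len(g) for g in groups]
    big_n, k = sum(n), len(groups)
    zbar_i = [zi.mean() for zi in z]
    zbar = sum(zi.sum() for zi in z) / big_n
    numerator = sum(ni * (zi - zbar) ** 2 for ni, zi in zip(n, zbar_i))
    denominator = sum(((zi - zb) ** 2).sum() for zi, zb in zip(z, zbar_i))
    return ((big_n - k) / (k - 1)) * numerator / denominator


# ---------------------------------------------------------------------------
# Exhaustive permutation tail probability for the categorical G test
# ---------------------------------------------------------------------------


def g_statistic(observed: np.ndarray, expected: np.ndarray) -> float:
    mask = observed > 0
    return float(2.0 * np.sum(observed[mask] * np.log(observed[mask] / expected[mask])))


def exhaustive_permutation_p(weights: np.ndarray, codes: np.ndarray) -> float:
    """Exact P(G_perm >= G_obs) over all site-label permutations."""
    n_categories = int(codes.max()) + 1
    site_counts = np.bincount(codes, minlength=n_categories).astype(float)
    expected = weights.sum() * site_counts / site_counts.sum()
    observed = np.bincount(codes, weights=weights, minlength=n_categories)
    g_obs = g_statistic(observed, expected)
    tail = total = 0
    for perm in itertools.permutations(range(len(codes))):
        perm_obs = np.bincount(
            codes[list(perm)], weights=weights, minlength=n_categories
        )
        total += 1
        if g_statistic(perm_obs, expected) >= g_obs - 1e-12:
            tail += 1
    return tail / total
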