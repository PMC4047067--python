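"""Independent brute-force oracles used by the tests.

These deliberately re-derive the statistics from first principles (explicit
loops over pairs, direct solution of the nested ANOVA expectations) so they
share no code with the package implementation.
"""

from __future__ import annotations

import numpy as np


def brute_ssd(d: np.ndarray, idx: list[int]) -> float:
    """Sum of squared distances within a set, divided by its size."""
    total = 0.0
    for i in idx:
        for j in idx:
            if i < j:
                total += d[i, j] ** 2
    return total / len(idx)


def brute_one_level(d: np.ndarray, pops: list[list[int]]):
    """(sigma_a, sigma_w, phi_st) via explicit sums of squares."""
    all_idx = [i for p in pops for i in p]
    N = len(all_idx)
    P = len(pops)
    ssd_t = brute_ssd(d, all_idx)
    ssd_w = sum(brute_ssd(d, p) for p in pops)
    ssd_a = ssd_t - ssd_w
    ms_a = ssd_a / (P - 1)
    sigma_w = ssd_w / (N - P)
    n_c = (N - sum(len(p) ** 2 for p in pops) / N) / (P - 1)
    sigma_a = (ms_a - sigma_w) / n_c
    return sigma_a, sigma_w, sigma_a / (sigma_a + sigma_w)


def brute_two_level(d: np.ndarray, groups: list[list[list[int]]]):
    """(sigma_a, sigma_b, sigma_c, phi_ct, phi_sc, phi_st), nested design."""
    pops = [p for g in groups for p in g]
    all_idx = [i for p in pops for i in p]
    N = len(all_idx)
    P = len(pops)
    G = len(groups)
    group_idx = [[i for p in g for i in p] for g in groups]
    group_sizes = [len(ix) for ix in group_idx]

    ssd_t = brute_ssd(d, all_idx)
    ssd_wp = sum(brute_ssd(d, p) for p in pops)
    ssd_wg = sum(brute_ssd(d, ix) for ix in group_idx)
    ssd_ap = ssd_wg - ssd_wp
    ssd_ag = ssd_t - ssd_wg

    sum_npg2_over_ng = sum(
        sum(len(p) ** 2 for p in g) / ng for g, ng in zip(groups, group_sizes)
    )
    sum_np2_over_n = sum(len(p) ** 2 for p in pops) / N
    n1 = (N - sum_npg2_over_ng) / (P - G)
    n2 = (sum_npg2_over_ng - sum_np2_over_n) / (G - 1)
    n3 = (N - sum(ng**2 for ng in group_sizes) / N) / (G - 1)

    sigma_c = ssd_wp / (N - P)
    sigma_b = (ssd_ap / (P - G) - sigma_c) / n1
    sigma_a = (ssd_ag / (G - 1) - sigma_c - n2 * sigma_b) / n3
    total = sigma_a + sigma_b + sigma_c
    return (
        sigma_a,
        sigma_b,
        sigma_c,
        sigma_a / total,
        sigma_b / (sigma_b + sigma_c),
        (sigma_a + sigma_b) / total,
    )
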