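"""Independent oracles used across the test suite.

These deliberately avoid the library's own computation paths: posteriors by
exhaustive path enumeration, F_ST by the direct frequency formula, interval
sums by per-basepair expansion.
"""

import itertools

import numpy as np


def brute_posteriors(target, panel, genetic_cM, ne_eff, lam, min_switch=1e-8):
    """Copying-state posteriors by summing over every path explicitly."""
    panel = np.asarray(panel)
    H, T = panel.shape
    d = np.diff(np.asarray(genetic_cM, dtype=float)) / 100.0
    s = np.maximum(1.0 - np.exp(-4.0 * ne_eff * d / H), min_switch)
    post = np.zeros((T, H))
    total = 0.0
    for path in itertools.product(range(H), repeat=T):
        p = 1.0 / H
        for t in range(T):
            if t > 0:
                st = s[t - 1]
                p *= (1 - st) + st / H if path[t] == path[t - 1] else st / H
            p *= (1 - lam) if panel[path[t], t] == target[t] else lam
        total += p
        for t in range(T):
            post[t, path[t]] += p
    return post / total


def hudson_fst(freq1, freq2, n1, n2):
    """Hudson's F_ST estimator (ratio of averages) from sample frequencies."""
    p1 = np.asarray(freq1, dtype=float)
    p2 = np.asarray(freq2, dtype=float)
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return float(num.sum() / den.sum())


def per_bp_ancestry_fraction(tracks, hap_index, ancestry):
    """Genome fraction of one ancestry by brute-force per-basepair expansion
    (only sensible on toy chromosomes)."""
    lab = np.empty(tracks.length_bp, dtype=object)
    for s, e, a in zip(tracks.starts[hap_index], tracks.ends[hap_index],
                       tracks.labels[hap_index]):
        lab[s:e] = a
    return float(np.mean(lab == ancestry))


def paired_t_closed_form(diff):
    """Textbook paired t statistic from the difference vector."""
    d = np.asarray(diff, dtype=float)
    n = d.size
    return float(d.mean() / (d.std(ddof=1) / np.sqrt(n)))
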