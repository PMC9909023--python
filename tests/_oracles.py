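"""Independent reference implementations used to cross-check the package.

Everything here is deliberately written by a different route than the code it
validates: brute-force enumeration, closed forms, or explicit path walks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

# ---------------------------------------------------------------------------
# Ordinary least squares (closed form, mean-centered)
# ---------------------------------------------------------------------------

def ols(x, y):
    """Return (slope, intercept, r_squared) from the normal equations."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xm, ym = x.mean(), y.mean()
    sxx = ((x - xm) ** 2).sum()
    sxy = ((x - xm) * (y - ym)).sum()
    slope = sxy / sxx
    intercept = ym - slope * xm
    ss_res = ((y - (intercept + slope * x)) ** 2).sum()
    ss_tot = ((y - ym) ** 2).sum()
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return slope, intercept, r2


# ---------------------------------------------------------------------------
# Random placement: exact enumeration over every individual's landing spot
# ---------------------------------------------------------------------------

def enumerate_expected_richness(n_per_species, island_fracs):
    """Exact E(richness) per island by enumerating all (k+1)^N placements.

    ``island_fracs`` are a_j / A_T; each individual lands on island j with
    that probability or misses every island with the residual probability.
    """
    k = len(island_fracs)
    p_loc = list(island_fracs) + [1.0 - sum(island_fracs)]
    assert p_loc[-1] >= -1e-12
    species_of = [s for s, n in enumerate(n_per_species) for _ in range(int(n))]
    big_n = len(species_of)
    expected = [0.0] * k
    for outcome in itertools.product(range(k + 1), repeat=big_n):
        prob = 1.0
        present = [set() for _ in range(k)]
        for sp, loc in zip(species_of, outcome):
            prob *= p_loc[loc]
            if loc < k:
                present[loc].add(sp)
        for j in range(k):
            expected[j] += prob * len(present[j])
    return expected


# ---------------------------------------------------------------------------
# ACE (textbook formula, straight transcription)
# ---------------------------------------------------------------------------

def ace_formula(counts, rare_threshold=10):
    counts = [c for c in counts if c > 0]
    rare = [c for c in counts if c <= rare_threshold]
    s_abund = len(counts) - len(rare)
    s_rare = len(rare)
    n_rare = sum(rare)
    if s_rare == 0:
        return float(len(counts))
    f1 = sum(1 for c in rare if c == 1)
    c_ace = 1.0 - f1 / n_rare
    if c_ace == 0.0:
        f2 = sum(1 for c in rare if c == 2)
        return float(len(counts) + f1 * (f1 - 1) / (2.0 * (f2 + 1)))
    num = sum(i * (i - 1) * sum(1 for c in rare if c == i) for i in range(1, rare_threshold + 1))
    gamma = max((s_rare / c_ace) * num / (n_rare * (n_rare - 1)) - 1.0, 0.0) if n_rare > 1 else 0.0
    return s_abund + s_rare / c_ace + (f1 / c_ace) * gamma


# ---------------------------------------------------------------------------
# Log-series closed forms
# ---------------------------------------------------------------------------

def logseries_singleton_fraction(x):
    """P(abundance == 1) under a log-series with parameter x."""
    return -x / math.log(1.0 - x)


def paired_t_p_df2(t):
    """Two-sided p for Student's t with 2 df: 1 - t/sqrt(t^2+2)."""
    return 1.0 - abs(t) / math.sqrt(t * t + 2.0)


# ---------------------------------------------------------------------------
# UniFrac by explicit root-to-leaf path enumeration
# ---------------------------------------------------------------------------

def _edge_paths(root):
    """Map leaf name -> list of edge ids on its path; edge id -> length."""
    lengths = {}
    paths = {}

    def walk(node, path):
        if node.length is not None and node.parent is not None:
            path = path + [id(node)]
            lengths[id(node)] = float(node.length)
        if node.is_tip():
            paths[node.name] = path
        for ch in node.children:
            walk(ch, path)

    walk(root, [])
    return paths, lengths


def unifrac_path_oracle(tree_root, x, y, metric="unweighted", normalized=True):
    """UniFrac from per-leaf root paths (independent of postorder accumulation)."""
    paths, lengths = _edge_paths(tree_root)
    x = {k: v for k, v in x.items() if v > 0}
    y = {k: v for k, v in y.items() if v > 0}
    if metric == "unweighted":
        edges_x = set().union(*(paths[t] for t in x)) if x else set()
        edges_y = set().union(*(paths[t] for t in y)) if y else set()
        num = sum(lengths[e] for e in edges_x.symmetric_difference(edges_y))
        den = sum(lengths[e] for e in edges_x | edges_y)
        return num / den
    tot_x, tot_y = sum(x.values()), sum(y.values())
    px = {e: 0.0 for e in lengths}
    py = {e: 0.0 for e in lengths}
    for taxon, c in x.items():
        for e in paths[taxon]:
            px[e] += c / tot_x
    for taxon, c in y.items():
        for e in paths[taxon]:
            py[e] += c / tot_y
    raw = sum(lengths[e] * abs(px[e] - py[e]) for e in lengths)
    if not normalized:
        return raw
    den = sum(lengths[e] * (px[e] + py[e]) for e in lengths)
    return raw / den
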