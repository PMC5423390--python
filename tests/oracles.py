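"""Independent brute-force oracles used by the test suite.

Deliberately naive re-implementations — explicit loops, textbook
formulas — kept separate from the package so each check has two
independent routes.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
from scipy import stats


def brute_force_consensus(symbol_calls, design, min_animals=3, min_se_labs=4,
                          min_control_labs=6):
    """Recount every above-background tier flag by explicit loops."""
    calls = symbol_calls.calls
    table = design.table
    labs = sorted(table["lab_id"].unique())
    se_labs = sorted(table.loc[table["model"].isin(
        ("pilocarpine", "kainate", "SSSE")), "lab_id"].unique())
    conditions = ("control", "t1", "t2", "t3")
    lab_flags, cond_flags, overall = {}, {}, {}
    for sym in calls.index:
        for lab in labs:
            for cond in conditions:
                n_present = 0
                for sample in table.index:
                    if (table.loc[sample, "lab_id"] == lab
                            and table.loc[sample, "condition"] == cond
                            and calls.loc[sym, sample] == "P"):
                        n_present += 1
                lab_flags[(sym, lab, cond)] = n_present >= min_animals
        for cond in conditions:
            if cond == "control":
                pool, thresh = labs, min_control_labs
            else:
                pool, thresh = se_labs, min_se_labs
            n_true = sum(lab_flags[(sym, lab, cond)] for lab in pool)
            cond_flags[(sym, cond)] = n_true >= thresh
        overall[sym] = any(cond_flags[(sym, c)] for c in conditions)
    return lab_flags, cond_flags, overall


def brute_force_cv(lab_values):
    """Textbook percent CV: 100 * sample sd (n-1) / mean."""
    n = len(lab_values)
    mean = sum(lab_values) / n
    var = sum((v - mean) ** 2 for v in lab_values) / (n - 1)
    return 100.0 * math.sqrt(var) / mean


def brute_force_median(values):
    s = sorted(values)
    n = len(s)
    if n % 2:
        return s[n // 2]
    return (s[n // 2 - 1] + s[n // 2]) / 2.0


def paired_t_closed_form(differences):
    """Textbook paired t: mean difference over its standard error."""
    n = len(differences)
    mean = sum(differences) / n
    var = sum((d - mean) ** 2 for d in differences) / (n - 1)
    t = mean / math.sqrt(var / n)
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return t, p


def welch_t_closed_form(a, b):
    """Textbook Welch t with Welch-Satterthwaite degrees of freedom."""
    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    se2 = va / na + vb / nb
    t = (ma - mb) / math.sqrt(se2)
    df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * stats.t.sf(abs(t), df=df)
    return t, p


def bh_step_up(pvals, q):
    """Direct step-up: largest k with p_(k) <= k q / m; reject 1..k."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    k_max = 0
    for rank, i in enumerate(order, start=1):
        if pvals[i] <= rank * q / m:
            k_max = rank
    rejected = set(order[:k_max])
    return [i in rejected for i in range(m)]


def brute_force_complete_linkage(dist):
    """Naive agglomeration; returns merge heights and the partition trace.

    ``dist`` is a symmetric matrix (labels x labels).  At each step the
    pair of clusters with the smallest max-pairwise distance merges.
    """
    labels = list(dist.index)
    clusters = [frozenset([l]) for l in labels]
    heights = []
    merges = []
    while len(clusters) > 1:
        best = None
        for a, b in combinations(clusters, 2):
            d = max(dist.loc[x, y] for x in a for y in b)
            if best is None or d < best[0]:
                best = (d, a, b)
        d, a, b = best
        clusters.remove(a)
        clusters.remove(b)
        clusters.append(a | b)
        heights.append(d)
        merges.append(a | b)
    return heights, merges
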