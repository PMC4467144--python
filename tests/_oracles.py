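"""Independent brute-force oracles used only by the test suite.

Deliberately written in plain Python (loops, itertools, math) with no reuse
of the package's vectorized code paths, so agreement is a real cross-check.
"""

from __future__ import annotations

import itertools
import math


def brute_signed_fc(log2_a: float, log2_b: float) -> float:
    d = log2_a - log2_b
    if d >= 0:
        return 2.0 ** d
    return -(2.0 ** (-d))


def brute_consensus(clone_fcs) -> float | None:
    """Mean of sign-agreeing signed FCs; None on disagreement. A no-change
    clone (+1.0) only agrees with other +1.0 clones."""
    clone_fcs = list(clone_fcs)
    if len(clone_fcs) == 1:
        return clone_fcs[0]
    n_nochange = sum(1 for v in clone_fcs if v == 1.0)
    if 0 < n_nochange < len(clone_fcs):
        return None
    signs = {v > 0 for v in clone_fcs}
    if len(signs) > 1:
        return None
    return sum(clone_fcs) / len(clone_fcs)


def brute_association(kind: str, fc: float) -> float:
    if kind == "overexpression" or fc == 1.0:
        return fc
    return -fc


def brute_profile(models, matrix_df):
    """gene -> model -> association FC or None, computed cell by cell."""
    out = {}
    for gene in matrix_df.index:
        row = {}
        for model in models:
            ctrl = [matrix_df.at[gene, s] for s in model.control.sample_ids]
            ctrl_mean = sum(ctrl) / len(ctrl)
            clone_fcs = []
            for pop in model.manipulated:
                vals = [matrix_df.at[gene, s] for s in pop.sample_ids]
                clone_fcs.append(
                    brute_signed_fc(sum(vals) / len(vals), ctrl_mean))
            consensus = brute_consensus(clone_fcs)
            row[model.name] = (None if consensus is None
                               else brute_association(model.kind, consensus))
        out[gene] = row
    return out


# --- set-filter predicates (quoted rules, evaluated per gene) ----------------


def brute_specific(profile: dict, models, threshold: float):
    up, down = set(), set()
    for gene, row in profile.items():
        vals = [row.get(m) for m in models]
        if any(v is None for v in vals):
            continue
        if all(v >= threshold for v in vals):
            up.add(gene)
        if all(v <= -threshold for v in vals):
            down.add(gene)
    return up, down


def brute_shared(profile: dict, models, threshold: float, min_models: int):
    up, down = set(), set()
    for gene, row in profile.items():
        n_up = sum(1 for m in models
                   if row.get(m) is not None and row[m] >= threshold)
        n_down = sum(1 for m in models
                     if row.get(m) is not None and row[m] <= -threshold)
        if n_up >= min_models and n_down >= min_models:
            continue  # pathological double qualification: reported in neither
        if n_up >= min_models:
            up.add(gene)
        if n_down >= min_models:
            down.add(gene)
    return up, down


def brute_cascade(profile: dict, include_models, exclude_models,
                  include_fc: float, exclude_fc: float,
                  exclude_requires_all: bool):
    """Strict-comparator include/exclude phenotype rule."""
    up, down = set(), set()
    for gene, row in profile.items():
        for sign, target in ((+1, up), (-1, down)):
            vals = [row.get(m) for m in include_models]
            if any(v is None for v in vals):
                continue
            if not all(sign * v > include_fc for v in vals):
                continue
            hits = []
            for m in exclude_models:
                v = row.get(m)
                hits.append(v is not None and sign * v > exclude_fc)
            vetoed = all(hits) if exclude_requires_all else any(hits)
            if not vetoed:
                target.add(gene)
    return up, down


# --- statistical kernels -----------------------------------------------------


def mw_exact_enumeration(a, b):
    """Exact two-sided Mann-Whitney p by enumerating every assignment of
    the pooled ranks to group A (tie-free data only)."""
    pooled = sorted(list(a) + list(b))
    assert len(set(pooled)) == len(pooled), "tie-free inputs required"
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    n_a, n_b = len(a), len(b)
    ra = sum(ranks[v] for v in a)
    u_obs = ra - n_a * (n_a + 1) / 2
    mean_u = n_a * n_b / 2
    dev_obs = abs(u_obs - mean_u)
    total = 0
    extreme = 0
    for combo in itertools.combinations(range(1, n_a + n_b + 1), n_a):
        u = sum(combo) - n_a * (n_a + 1) / 2
        total += 1
        if abs(u - mean_u) >= dev_obs - 1e-12:
            extreme += 1
    return u_obs, extreme / total


def chi2_from_expected(tp, fp, fn, tn):
    """Pearson chi-square via observed-vs-expected counts."""
    obs = [[tp, fn], [fp, tn]]
    n = tp + fp + fn + tn
    rows = [tp + fn, fp + tn]
    cols = [tp + fp, fn + tn]
    chi2 = 0.0
    for i in range(2):
        for j in range(2):
            expected = rows[i] * cols[j] / n
            chi2 += (obs[i][j] - expected) ** 2 / expected
    return chi2


def pooled_t(a, b):
    """Hand-computed pooled-variance Student's t."""
    n1, n2 = len(a), len(b)
    m1 = sum(a) / n1
    m2 = sum(b) / n2
    s1 = sum((x - m1) ** 2 for x in a) / (n1 - 1)
    s2 = sum((x - m2) ** 2 for x in b) / (n2 - 1)
    sp = math.sqrt(((n1 - 1) * s1 + (n2 - 1) * s2) / (n1 + n2 - 2))
    return (m1 - m2) / (sp * math.sqrt(1 / n1 + 1 / n2))


def random_profile(rng, n_genes, model_names, na_rate=0.1):
    """Random association profile as a plain dict, with boundary values
    (exactly +-1.5, +-1.2, +-1.0) mixed in to exercise comparators."""
    special = [1.5, -1.5, 1.2, -1.2, 1.0, 1.6, -1.6, 1.21, -1.21]
    profile = {}
    for i in range(n_genes):
        row = {}
        for m in model_names:
            u = rng.random()
            if u < na_rate:
                row[m] = None
            elif u < na_rate + 0.3:
                row[m] = special[rng.integers(0, len(special))]
            else:
                mag = 1.0 + 2.5 * rng.random()
                row[m] = mag if rng.random() < 0.5 else -mag
        profile[f"G{i:04d}"] = row
    return profile


def profile_dict_to_frame(profile: dict, model_names):
    import numpy as np
    import pandas as pd
    data = {
        m: [np.nan if profile[g][m] is None else profile[g][m]
            for g in profile]
        for m in model_names
    }
    return pd.DataFrame(data, index=list(profile))
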