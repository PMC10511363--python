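"""Shared fixture builders and independent oracles for the test suite.

Oracles here are deliberately written from first principles (plain
probability space, explicit loops) so they stay independent of the
implementation paths they check.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from cismr.instruments import InstrumentPair
from cismr.sumstats import StudyMeta, SummaryStats, VariantKey


def make_stats(rows, trait_id="trait", trait_type="quantitative",
               default_n=None, case_fraction=None) -> SummaryStats:
    """Build a SummaryStats from a list of partial row dicts."""
    defaults = {
        "chrom": "1", "pos": 100, "effect_allele": "A", "other_allele": "G",
        "eaf": 0.3, "beta": 0.1, "se": 0.05, "pvalue": 0.05,
        "n": 10_000.0, "n_case": np.nan,
    }
    full = []
    for i, row in enumerate(rows):
        r = dict(defaults)
        r["pos"] = 100 + i * 1000
        r.update(row)
        full.append(r)
    meta = StudyMeta(trait_id=trait_id, trait_type=trait_type,
                     default_n=default_n, case_fraction=case_fraction)
    return SummaryStats(meta=meta, df=pd.DataFrame(full))


def make_pair(beta_exp, beta_out, se_exp=0.05, se_out=0.05, pos=100,
              eaf=0.3, n_exp=10_000.0, n_out=50_000.0) -> InstrumentPair:
    return InstrumentPair(
        key=VariantKey("1", pos, "A", "G"),
        beta_exp=beta_exp, se_exp=se_exp, beta_out=beta_out, se_out=se_out,
        eaf=eaf, p_exp=1e-10, p_out=0.01, n_exp=n_exp, n_out=n_out,
        action="unchanged",
    )


def make_pairs(beta_exp, beta_out, se_exp=None, se_out=None, **kw):
    beta_exp = np.asarray(beta_exp, dtype=float)
    beta_out = np.asarray(beta_out, dtype=float)
    se_exp = np.full(beta_exp.shape, 0.05) if se_exp is None else np.asarray(se_exp, float)
    se_out = np.full(beta_exp.shape, 0.05) if se_out is None else np.asarray(se_out, float)
    return [
        make_pair(bx, by, sx, sy, pos=100 + 1000 * i, **kw)
        for i, (bx, by, sx, sy) in enumerate(zip(beta_exp, beta_out, se_exp, se_out))
    ]


def coloc_enumeration_oracle(labf1, labf2, p1=1e-4, p2=1e-4, p12=1e-5):
    """Posterior hypothesis probabilities by explicit configuration enumeration.

    Works in plain probability space (suitable for |labf| up to ~300):
    each variant can be causal for study 1 only (prior p1), study 2 only
    (p2), or both (p12); summing Bayes-factor-weighted prior mass over all
    single-causal configurations per hypothesis class.
    """
    bf1 = np.exp(np.asarray(labf1, dtype=float))
    bf2 = np.exp(np.asarray(labf2, dtype=float))
    m = len(bf1)
    w_h0 = 1.0
    w_h1 = sum(p1 * bf1[i] for i in range(m))
    w_h2 = sum(p2 * bf2[j] for j in range(m))
    w_h3 = 0.0
    for i in range(m):
        for j in range(m):
            if i != j:
                w_h3 += p1 * p2 * bf1[i] * bf2[j]
    w_h4 = sum(p12 * bf1[i] * bf2[i] for i in range(m))
    weights = np.array([w_h0, w_h1, w_h2, w_h3, w_h4])
    return weights / weights.sum()


def greedy_clump_oracle(positions, pvalues, ld_r, r2_threshold, window):
    """Independent greedy clumping trace on one chromosome.

    Walks candidates in (p, position) order, accepting one when every
    previously accepted variant within ``window`` bases has squared
    correlation below ``r2_threshold``.  Returns accepted indices (input
    order indices, sorted by position).
    """
    order = sorted(range(len(positions)), key=lambda i: (pvalues[i], positions[i]))
    accepted = []
    for i in order:
        admissible = True
        for j in accepted:
            if abs(positions[i] - positions[j]) <= window and ld_r[i][j] ** 2 >= r2_threshold:
                admissible = False
        if admissible:
            accepted.append(i)
    return sorted(accepted, key=lambda i: positions[i])


def bh_oracle(pvalues):
    """Direct step-up definition: adj_i = min_{j >= i in sorted order} m p_(j) / j."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [None] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * pvalues[i] / rank)
        adjusted[i] = running
    return adjusted
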