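"""Levins' niche breadth and a shared-sequence dispersal proxy.

Levins' B for a taxon is the inverse Simpson concentration of its reads
across samples: B = 1 / sum_i q_i^2 with q_i the fraction of the taxon's
reads found in sample i. B ranges from 1 (single-habitat specialist) to
the number of samples (perfectly even generalist). The community-level
breadth Bcom of a sample is the mean B over the taxa present in it.

The dispersal proxy for a sample pair is the symmetric mean of each
member's fraction of reads belonging to jointly present taxa; a sample's
dispersal score is its average over all partners.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from plankton_assembly.io_tables import AsvTable, AsvTableError


def levins_breadth(t: AsvTable) -> pd.Series:
    """Levins' niche breadth B per taxon: 1 / sum of squared read fractions."""
    counts = t.counts.astype(float)
    totals = counts.sum(axis=0)
    zero = totals == 0
    if zero.any():
        warnings.warn(f"excluding {int(zero.sum())} taxa with zero total count")
    q = counts[:, ~zero] / totals[~zero]
    b = 1.0 / (q**2).sum(axis=0)
    return pd.Series(b, index=np.asarray(t.asv_ids)[~zero], name="levins_b")


def community_breadth(
    t: AsvTable, b: pd.Series, abundance_weighted: bool = False
) -> pd.Series:
    """Community-level niche breadth Bcom: per-sample mean of taxon B values.

    The mean is unweighted over the taxa present in the sample; set
    ``abundance_weighted=True`` to weight by the sample's read proportions.
    """
    taxa = [a for a in t.asv_ids if a in b.index]
    if not taxa:
        raise AsvTableError("no taxa with breadth values present in table")
    sub = t.data[taxa]
    out = {}
    for sid in t.sample_ids:
        row = sub.loc[sid]
        present = row[row > 0]
        if present.empty:
            raise AsvTableError(f"empty sample: {sid}")
        if abundance_weighted:
            w = present / present.sum()
            out[sid] = float((b.loc[present.index] * w).sum())
        else:
            out[sid] = float(b.loc[present.index].mean())
    return pd.Series(out, name="bcom")


def dispersal_proxy(t: AsvTable, method: str = "symmetric_mean") -> pd.Series:
    """Average pairwise shared proportion of sequence numbers per sample.

    For a pair (s, u), with A the taxa nonzero in both, the shared
    proportion is the mean of each sample's read fraction in A
    (``symmetric_mean``) or the sum over A of the elementwise minimum read
    proportions (``min_sum``). A sample's score averages over all partners;
    identical compositions give 1, disjoint taxa give 0.
    """
    if t.n_samples < 2:
        raise AsvTableError("need at least 2 samples")
    counts = t.counts.astype(float)
    row_sums = counts.sum(axis=1)
    if (row_sums == 0).any():
        bad = [s for s, z in zip(t.sample_ids, row_sums == 0) if z]
        raise AsvTableError(f"empty sample(s): {bad}")
    rel = counts / row_sums[:, None]
    present = counts > 0
    n = t.n_samples
    share = np.zeros((n, n))
    for s in range(n):
        for u in range(s + 1, n):
            both = present[s] & present[u]
            if method == "symmetric_mean":
                val = 0.5 * (rel[s, both].sum() + rel[u, both].sum())
            elif method == "min_sum":
                val = np.minimum(rel[s, both], rel[u, both]).sum()
            else:
                raise AsvTableError(f"unknown dispersal method: {method!r}")
            share[s, u] = share[u, s] = val
    means = share.sum(axis=1) / (n - 1)
    return pd.Series(means, index=t.sample_ids, name="dispersal")
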