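"""Sloan neutral community model: fitting, partitioning and summaries.

The model predicts the occurrence frequency of a taxon across local
communities from its mean relative abundance p in the metacommunity, the
local community size N (reads per sample after rarefaction) and the
immigration rate m. The taxon's local relative abundance is
Beta(N m p, N m (1 - p)) distributed; a sample of N reads then misses the
taxon with beta-binomial zero-class probability, giving the exact
occurrence frequency

    freq_pred(p) = 1 - B(N m p, N m (1 - p) + N) / B(N m p, N m (1 - p))

(``detection="exact"``, the default). The classic threshold approximation
freq_pred = 1 - BetaCDF(d; N m p, N m (1 - p)) with detection limit
d = 1/N is available as ``detection="threshold"``; it treats a read
sample as a hard detection cutoff and overestimates m by ~20-30% at
typical depths, which is why the exact zero-class form is the default.

m is estimated by nonlinear least squares of observed occurrence
frequencies on this curve. Taxa are then labelled above / neutral / below
according to a 95% confidence band (Wilson score interval with the number
of samples as the effective trial count) around the prediction, with a
half-step (1/2n) continuity correction for the discreteness of observed
frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.special
import scipy.stats

from plankton_assembly.io_tables import AsvTable, AsvTableError, TaxonomyMap

_MULTISTART = (0.01, 0.1, 0.5, 1.0)
_M_LOWER = 1e-6

PARTITION_LABELS = ("above", "neutral", "below")


@dataclass(frozen=True)
class NcmFit:
    """Fitted neutral community model.

    Attributes
    ----------
    m :
        Immigration estimate in (0, 1].
    r_squared :
        1 - SS_res / SS_tot of predicted vs observed occurrence frequency
        (can be negative when the model fits worse than the mean).
    N :
        Community size: reads per sample after rarefaction.
    d :
        Detection limit, 1/N.
    n_samples :
        Number of local communities the frequencies were computed over.
    table :
        Per-ASV frame with columns p, freq_obs, freq_pred, ci_lower,
        ci_upper (95% band unless refitted via :func:`partition_asvs`).
    """

    m: float
    r_squared: float
    N: int
    d: float
    n_samples: int
    table: pd.DataFrame


@dataclass(frozen=True)
class PartitionResult:
    """Above/neutral/below partition labels and richness/abundance summaries."""

    labels: pd.Series
    summary: pd.DataFrame
    by_lineage: pd.DataFrame | None = None


def occurrence_stats(t: AsvTable) -> pd.DataFrame:
    """Mean relative abundance and occurrence frequency per ASV.

    Requires a rarefied table (equal row sums). ASVs absent from every
    sample are dropped.
    """
    row_sums = t.data.sum(axis=1)
    if row_sums.nunique() != 1:
        raise AsvTableError("table must be rarefied (equal row sums)")
    depth = float(row_sums.iloc[0])
    if depth <= 0:
        raise AsvTableError("empty samples")
    rel = t.counts / depth
    p = rel.mean(axis=0)
    freq = (t.counts > 0).mean(axis=0)
    out = pd.DataFrame({"p": p, "freq_obs": freq}, index=t.asv_ids)
    out = out[out["p"] > 0]
    out.attrs["n_samples"] = t.n_samples
    return out


def predict_occurrence(
    m: float, p: np.ndarray, n_reads: int, detection: str = "exact"
) -> np.ndarray:
    """NCM-predicted occurrence frequency of taxa with source abundance p.

    ``detection="exact"`` uses the beta-binomial zero-class probability of
    missing the taxon in a sample of N reads; ``detection="threshold"``
    uses the classic upper Beta tail above d = 1/N.
    """
    p = np.asarray(p, dtype=float)
    a = n_reads * m * p
    b = n_reads * m * (1.0 - p)
    if detection == "exact":
        with np.errstate(invalid="ignore"):
            log_zero = scipy.special.betaln(a, b + n_reads) - scipy.special.betaln(a, b)
        return 1.0 - np.exp(log_zero)
    if detection == "threshold":
        return 1.0 - scipy.stats.beta.cdf(1.0 / n_reads, a, b)
    raise AsvTableError(f"unknown detection mode: {detection!r}")


def fit_ncm(
    stats: pd.DataFrame,
    N: int,
    n_samples: int | None = None,
    alpha: float = 0.05,
    detection: str = "exact",
) -> NcmFit:
    """Fit the immigration rate m by least squares on occurrence frequencies.

    Multi-start nonlinear least squares over m in (0, 1]; the fit minimizing
    the residual sum of squares wins. The returned table carries the Wilson
    confidence band at level 1 - alpha around each prediction, with
    ``n_samples`` (taken from ``stats.attrs`` when produced by
    :func:`occurrence_stats`) as the effective trial count.
    """
    if n_samples is None:
        n_samples = stats.attrs.get("n_samples")
    if n_samples is None:
        raise AsvTableError("n_samples required (not carried by the stats frame)")
    if len(stats) < 10:
        raise AsvTableError("need at least 10 ASVs to fit the NCM")
    if N < 2:
        raise AsvTableError("community size N must be >= 2")
    p = stats["p"].to_numpy(dtype=float)
    obs = stats["freq_obs"].to_numpy(dtype=float)
    if (p <= 0).any():
        raise AsvTableError("mean relative abundance must be positive")

    def residuals(m_arr: np.ndarray) -> np.ndarray:
        return predict_occurrence(float(m_arr[0]), p, N, detection) - obs

    best = None
    for start in _MULTISTART:
        try:
            res = scipy.optimize.least_squares(
                residuals, x0=[start], bounds=([_M_LOWER], [1.0])
            )
        except Exception:
            continue
        if res.success and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        raise AsvTableError("NCM optimizer failed to converge from all starts")
    m_hat = float(best.x[0])
    pred = predict_occurrence(m_hat, p, N, detection)
    ss_res = float(((obs - pred) ** 2).sum())
    ss_tot = float(((obs - obs.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    lo, hi = wilson_interval(pred, int(n_samples), alpha)
    table = pd.DataFrame(
        {
            "p": p,
            "freq_obs": obs,
            "freq_pred": pred,
            "ci_lower": lo,
            "ci_upper": hi,
        },
        index=stats.index,
    )
    return NcmFit(
        m=m_hat,
        r_squared=float(r2),
        N=int(N),
        d=1.0 / N,
        n_samples=int(n_samples),
        table=table,
    )


def wilson_interval(
    phat: np.ndarray, n: int, alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Wilson score interval for a proportion with n effective trials.

    ``phat`` may be non-integer-valued times n; the interval always
    contains ``phat`` and stays inside [0, 1].
    """
    if not 0.0 < alpha < 1.0:
        raise AsvTableError("alpha must be in (0, 1)")
    z = scipy.stats.norm.ppf(1.0 - alpha / 2.0)
    phat = np.asarray(phat, dtype=float)
    denom = 1.0 + z**2 / n
    center = (phat + z**2 / (2.0 * n)) / denom
    half = (z / denom) * np.sqrt(phat * (1.0 - phat) / n + z**2 / (4.0 * n**2))
    return np.clip(center - half, 0.0, 1.0), np.clip(center + half, 0.0, 1.0)


def partition_asvs(
    fit: NcmFit, alpha: float = 0.05, n_samples: int | None = None
) -> pd.Series:
    """Label each ASV above / neutral / below the NCM confidence band.

    The band is the Wilson score interval at level 1 - alpha around the
    predicted frequency, with the number of samples as the trial count.
    Observed frequencies are k/n for integer k, so a half-step (1/2n)
    continuity correction widens the band before comparison; without it a
    taxon seen in every sample would be called "above" whenever the band's
    upper limit falls a hair short of 1.
    """
    n = n_samples if n_samples is not None else fit.n_samples
    lo, hi = wilson_interval(fit.table["freq_pred"].to_numpy(), n, alpha)
    obs = fit.table["freq_obs"].to_numpy()
    cc = 1.0 / (2.0 * n)
    labels = np.where(
        obs > hi + cc, "above", np.where(obs < lo - cc, "below", "neutral")
    )
    return pd.Series(labels, index=fit.table.index, name="partition")


def partition_summary(
    labels: pd.Series, t: AsvTable, tax: TaxonomyMap | None = None
) -> PartitionResult:
    """Richness and abundance proportions per partition, optionally by lineage.

    Richness proportion is the share of ASVs per partition; abundance
    proportion is the share of sequence totals. The same two proportions
    are computed within each phylum-level lineage when a taxonomy is given.
    """
    asvs = [a for a in labels.index if a in t.data.columns]
    if not asvs:
        raise AsvTableError("no labelled ASVs found in the table")
    labels = labels.loc[asvs]
    totals = t.data[asvs].sum(axis=0)

    def _proportions(sub_labels: pd.Series, sub_totals: pd.Series) -> pd.DataFrame:
        rows = {}
        n_total = len(sub_labels)
        seq_total = float(sub_totals.sum())
        for part in PARTITION_LABELS:
            in_part = sub_labels == part
            rows[part] = {
                "n_asvs": int(in_part.sum()),
                "richness_prop": float(in_part.sum()) / n_total,
                "abundance_prop": float(sub_totals[in_part].sum()) / seq_total
                if seq_total > 0
                else 0.0,
            }
        return pd.DataFrame.from_dict(rows, orient="index").loc[list(PARTITION_LABELS)]

    summary = _proportions(labels, totals)
    by_lineage = None
    if tax is not None:
        missing = [a for a in asvs if a not in tax.data.index]
        if missing:
            raise AsvTableError(f"ASV(s) missing lineage annotation: {missing[:10]}")
        lineages = tax.data.loc[asvs, "lineage"]
        frames = []
        for lin in pd.unique(lineages):
            in_lin = lineages.index[lineages == lin]
            frame = _proportions(labels.loc[in_lin], totals.loc[in_lin])
            frame.insert(0, "lineage", lin)
            frames.append(frame.reset_index(names="partition"))
        by_lineage = pd.concat(frames, ignore_index=True)
    return PartitionResult(labels=labels, summary=summary, by_lineage=by_lineage)
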