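"""Community- and taxon-level statistics derived from the interaction tensor.

Analyses are restricted to *strong* interactions — ordered taxon pairs whose
coefficient magnitude and temporal occurrence both exceed data-driven
thresholds (upper 50% quantiles of their respective distributions) — to
reduce the influence of noise and false positives.  Per-taxon summaries
follow the taxon-as-source orientation by default: they describe a taxon's
outgoing effect on the rest of the community.
"""
from __future__ import annotations

from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .tensor import InteractionTensor

__all__ = [
    "strong_thresholds",
    "classify_pairs",
    "taxon_metrics",
    "select_keystones",
    "distribution_stats",
    "DistributionStats",
]


def _offdiag_mask(S: int) -> np.ndarray:
    return ~np.eye(S, dtype=bool)


def strong_thresholds(
    tensor: InteractionTensor,
    strength: float | None = None,
    occurrence: float | None = None,
) -> tuple[float, float]:
    """Data-driven strong-interaction thresholds (both overridable).

    strength threshold  : median of |nonzero coefficients| pooled over all
                          ordered off-diagonal taxon pairs and times;
    occurrence threshold: median of per-pair occurrence fractions
                          (fraction of time points with a nonzero
                          coefficient).

    Explicit values (e.g. the field study's realized 0.005 and 0.057) are
    returned verbatim when given.
    """
    if strength is not None and occurrence is not None:
        return float(strength), float(occurrence)
    J = tensor.valid_taxa_values()
    off = _offdiag_mask(tensor.n_taxa)
    coeffs = J[:, off]  # (T_valid, n_pairs)
    nonzero = coeffs[coeffs != 0]
    if nonzero.size == 0:
        raise ValueError("no nonzero coefficients; cannot derive thresholds")
    s_thr = float(np.median(np.abs(nonzero))) if strength is None else float(strength)
    occ = (coeffs != 0).mean(axis=0)
    o_thr = float(np.median(occ)) if occurrence is None else float(occurrence)
    return s_thr, o_thr


def classify_pairs(
    tensor: InteractionTensor,
    thresholds: tuple[float, float] | None = None,
    strength_stat: str = "nonzero_mean",
) -> pd.DataFrame:
    """Classify every ordered taxon pair as positive, negative or neutral.

    A pair is *strong* iff the magnitude of its strength statistic exceeds
    the strength threshold AND its occurrence exceeds the occurrence
    threshold; strong pairs get the sign of their all-times mean coefficient,
    the rest are neutral.  The strength statistic is the mean over nonzero
    instants by default (``strength_stat='nonzero_mean'``) so intermittent
    but strong links are not diluted; ``'overall_mean'`` uses the all-times
    mean instead.  Self-pairs and the temperature column are excluded.
    """
    if strength_stat not in ("nonzero_mean", "overall_mean"):
        raise ValueError(f"unknown strength_stat {strength_stat!r}")
    if thresholds is None:
        thresholds = strong_thresholds(tensor)
    s_thr, o_thr = thresholds
    if s_thr <= 0 or o_thr < 0:
        raise ValueError("thresholds must be positive")
    J = tensor.valid_taxa_values()
    S = tensor.n_taxa
    nz = J != 0
    occurrence = nz.mean(axis=0)
    nz_count = nz.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        nonzero_mean = np.where(nz_count > 0, J.sum(axis=0) / np.maximum(nz_count, 1), 0.0)
    overall_mean = J.mean(axis=0)
    stat = nonzero_mean if strength_stat == "nonzero_mean" else overall_mean
    strong = (np.abs(stat) > s_thr) & (occurrence > o_thr)
    ids = tensor.taxon_ids
    rows = []
    for i in range(S):
        for j in range(S):
            if i == j:
                continue
            is_strong = bool(strong[i, j])
            sign = "neutral"
            if is_strong:
                sign = "positive" if overall_mean[i, j] > 0 else "negative"
            rows.append(
                (
                    ids[i],
                    ids[j],
                    float(occurrence[i, j]),
                    float(overall_mean[i, j]),
                    float(nonzero_mean[i, j]),
                    is_strong,
                    sign,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "target",
            "source",
            "occurrence",
            "mean_strength",
            "nonzero_mean_strength",
            "strong",
            "sign",
        ],
    )


def taxon_metrics(
    classification: pd.DataFrame,
    taxon_ids,
    orientation: str = "source",
    mean_relabund: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-taxon interaction summaries from the pair classification.

    For each taxon (by default as *source*, i.e. its outgoing effect):

    - ``sum_strength``     : sum over its strong pairs of the time-mean
      coefficient (net interactive effect; signs can cancel),
    - ``sum_abs_strength`` : sum of absolute time-mean coefficients,
    - ``interactiveness``  : sqrt(sum_strength^2 + sum_abs_strength^2),
    - ``facilitation_pct`` : 100 * (sum of positive strengths) /
      sum_abs_strength; NaN when the taxon has no strong pairs,
    - ``n_partners``       : number of strong pairs in this orientation,
    - ``n_partners_either``: distinct partners strong in either direction.
    """
    if orientation not in ("source", "target"):
        raise ValueError("orientation must be 'source' or 'target'")
    other = "target" if orientation == "source" else "source"
    if len(classification) and "strong" in classification:
        strong = classification[classification["strong"]]
    else:
        strong = classification.iloc[0:0].reindex(columns=["target", "source", "mean_strength"])
    out = pd.DataFrame(
        index=pd.Index(taxon_ids, name="taxon"),
        data={
            "sum_strength": 0.0,
            "sum_abs_strength": 0.0,
            "n_partners": 0,
            "n_partners_either": 0,
            "pos_sum": 0.0,
        },
    )
    if len(strong):
        g = strong.groupby(orientation)["mean_strength"]
        out["sum_strength"] = g.sum().reindex(out.index).fillna(0.0)
        out["sum_abs_strength"] = (
            strong.assign(a=strong["mean_strength"].abs())
            .groupby(orientation)["a"]
            .sum()
            .reindex(out.index)
            .fillna(0.0)
        )
        out["pos_sum"] = (
            strong.assign(p=strong["mean_strength"].clip(lower=0))
            .groupby(orientation)["p"]
            .sum()
            .reindex(out.index)
            .fillna(0.0)
        )
        out["n_partners"] = g.count().reindex(out.index).fillna(0).astype(int)
        either = pd.concat(
            [
                strong[[orientation, other]].rename(columns={orientation: "a", other: "b"}),
                strong[[other, orientation]].rename(columns={other: "a", orientation: "b"}),
            ]
        ).drop_duplicates()
        out["n_partners_either"] = (
            either.groupby("a")["b"].nunique().reindex(out.index).fillna(0).astype(int)
        )
    out["interactiveness"] = np.hypot(out["sum_strength"], out["sum_abs_strength"])
    with np.errstate(invalid="ignore", divide="ignore"):
        out["facilitation_pct"] = np.where(
            out["sum_abs_strength"] > 0,
            100.0 * out["pos_sum"] / out["sum_abs_strength"],
            np.nan,
        )
    out = out.drop(columns="pos_sum")
    if mean_relabund is not None:
        out["mean_relabund"] = pd.Series(mean_relabund).reindex(out.index)
    return out


def select_keystones(metrics: pd.DataFrame, fraction: float = 0.10) -> pd.DataFrame:
    """Flag the top-``fraction`` most interactive taxa as keystones.

    Selects the top ``floor(fraction * n)`` taxa (never fewer than one) by
    interactiveness; ties break toward larger ``sum_abs_strength``, then
    lexicographic taxon id.  Returns a copy with ``rank`` (1-based) and
    ``keystone`` columns added.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    n = len(metrics)
    k = max(1, int(np.floor(fraction * n)))
    out = metrics.copy()
    order = out.reset_index().sort_values(
        by=["interactiveness", "sum_abs_strength", out.index.name or "index"],
        ascending=[False, False, True],
        kind="mergesort",
    )
    ranks = pd.Series(np.arange(1, n + 1), index=order.iloc[:, 0].to_numpy())
    out["rank"] = ranks.reindex(out.index).astype(int)
    out["keystone"] = out["rank"] <= k
    return out


class DistributionStats(NamedTuple):
    skewness: float
    kurtosis: float  # plain (normal = 3), not excess
    jb_stat: float
    jb_pvalue: float


def distribution_stats(values) -> DistributionStats:
    """Skewness, kurtosis and Jarque-Bera normality test for a value set.

    Uses the moment estimators g1 = m3/m2^1.5 and plain kurtosis
    g2 = m4/m2^2 (normal reference 3), with
    JB = n/6 * (g1^2 + (g2 - 3)^2 / 4), p from chi-square(2).
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 8:
        raise ValueError("need at least 8 values")
    if np.ptp(x) == 0:
        raise ValueError("zero-variance sample")
    g1 = float(stats.skew(x, bias=True))
    g2 = float(stats.kurtosis(x, fisher=False, bias=True))
    jb, p = stats.jarque_bera(x)
    return DistributionStats(g1, g2, float(jb), float(p))
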