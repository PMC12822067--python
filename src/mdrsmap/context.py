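"""Temperature-conditioned interaction analyses and profile ordination.

Interaction time points are sorted into integer-degree-C bins (round half
up), per-taxon instantaneous interactiveness and facilitation are averaged
per bin with standard errors, keystones are re-selected per bin to expose
turnover along the gradient, community-level distributions are compared
between bins with two-sample Kolmogorov-Smirnov tests summarised as a
compact letter display, and per-time interaction profiles are ordinated by
non-metric multidimensional scaling of Bray-Curtis dissimilarities.
"""
from __future__ import annotations

import itertools
import string
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .metrics import select_keystones
from .tensor import InteractionTensor

__all__ = [
    "bin_temperature",
    "enumerate_bins",
    "instantaneous_metrics",
    "per_bin_metrics",
    "per_bin_keystones",
    "percent_change",
    "compare_distributions",
    "interaction_profile_ordination",
    "TemperatureBinSummary",
    "KeystoneTurnover",
    "ComparisonResult",
    "OrdinationResult",
]


def bin_temperature(temps) -> np.ndarray:
    """Integer-degree-C bin labels by rounding half up (17.2 -> 17, 16.5 -> 17)."""
    t = np.asarray(temps, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("temperatures must be finite")
    return np.floor(t + 0.5).astype(int)


def enumerate_bins(labels) -> np.ndarray:
    """Inclusive range of integer bins spanning the observed labels."""
    labels = np.asarray(labels, dtype=int)
    return np.arange(labels.min(), labels.max() + 1)


def instantaneous_metrics(
    tensor: InteractionTensor, classification: pd.DataFrame
) -> dict[str, pd.DataFrame]:
    """Per-time-point taxon metrics restricted to the strong pairs.

    At each valid time t and taxon (as source) the strong-pair coefficients
    J[t, target, source] are summed (net, absolute, positive part), giving
    instantaneous interactiveness and facilitation %.  Returns DataFrames
    (taxa x valid times) keyed by metric name.
    """
    S = tensor.n_taxa
    ids = list(tensor.taxon_ids)
    pos = {t: k for k, t in enumerate(ids)}
    mask = np.zeros((S, S), dtype=bool)
    strong = classification[classification["strong"]]
    for tgt, src in zip(strong["target"], strong["source"]):
        mask[pos[tgt], pos[src]] = True
    J = tensor.valid_taxa_values()  # (T, S, S)
    Jm = np.where(mask[None], J, 0.0)
    ssum = Jm.sum(axis=1)  # (T, S): per-source net strength
    sabs = np.abs(Jm).sum(axis=1)
    spos = np.clip(Jm, 0, None).sum(axis=1)
    inter = np.hypot(ssum, sabs)
    with np.errstate(invalid="ignore", divide="ignore"):
        facil = np.where(sabs > 0, 100.0 * spos / sabs, np.nan)
    times = tensor.valid_time_indices
    return {
        "sum_strength": pd.DataFrame(ssum.T, index=ids, columns=times),
        "sum_abs_strength": pd.DataFrame(sabs.T, index=ids, columns=times),
        "interactiveness": pd.DataFrame(inter.T, index=ids, columns=times),
        "facilitation_pct": pd.DataFrame(facil.T, index=ids, columns=times),
    }


@dataclass
class TemperatureBinSummary:
    """Per-degree-C-bin per-taxon means and SEs plus community distributions."""

    bins: np.ndarray  # bin labels present, ascending
    n_points: pd.Series  # time points per bin
    interactiveness_mean: pd.DataFrame  # taxa x bins
    interactiveness_se: pd.DataFrame
    facilitation_mean: pd.DataFrame
    facilitation_se: pd.DataFrame

    def community_distribution(self, metric: str = "interactiveness") -> dict[int, np.ndarray]:
        """Per-bin distribution of per-taxon bin means (NaNs dropped)."""
        src = {
            "interactiveness": self.interactiveness_mean,
            "facilitation_pct": self.facilitation_mean,
        }[metric]
        return {int(b): src[b].dropna().to_numpy() for b in src.columns}


def _mean_se(block: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """NaN-aware column means and standard errors (SE = 0 when n = 1)."""
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="Mean of empty slice")
        n = np.sum(np.isfinite(block), axis=1)
        mean = np.where(n > 0, np.nanmean(np.where(np.isfinite(block), block, np.nan), axis=1), np.nan)
        sd = np.full(block.shape[0], 0.0)
        multi = n > 1
        if multi.any():
            sd[multi] = np.nanstd(block[multi], axis=1, ddof=1)
        se = np.where(n > 0, sd / np.sqrt(np.maximum(n, 1)), np.nan)
    return mean, se


def per_bin_metrics(
    tensor: InteractionTensor,
    classification: pd.DataFrame,
    bin_labels,
) -> TemperatureBinSummary:
    """Mean and SE of instantaneous metrics per taxon per temperature bin.

    ``bin_labels`` gives one integer bin per *valid* interaction time point
    (aligned with ``tensor.valid_time_indices``).
    """
    labels = np.asarray(bin_labels, dtype=int)
    valid = tensor.valid_time_indices
    if len(labels) != len(valid):
        raise ValueError(
            f"bin_labels length {len(labels)} != number of valid time points {len(valid)}"
        )
    inst = instantaneous_metrics(tensor, classification)
    bins = np.unique(labels)
    ids = list(tensor.taxon_ids)
    res = {}
    for name in ("interactiveness", "facilitation_pct"):
        arr = inst[name].to_numpy()  # taxa x T_valid
        means = np.empty((len(ids), len(bins)))
        ses = np.empty((len(ids), len(bins)))
        for k, b in enumerate(bins):
            means[:, k], ses[:, k] = _mean_se(arr[:, labels == b])
        res[name] = (
            pd.DataFrame(means, index=ids, columns=bins),
            pd.DataFrame(ses, index=ids, columns=bins),
        )
    n_points = pd.Series({int(b): int((labels == b).sum()) for b in bins})
    return TemperatureBinSummary(
        bins=bins,
        n_points=n_points,
        interactiveness_mean=res["interactiveness"][0],
        interactiveness_se=res["interactiveness"][1],
        facilitation_mean=res["facilitation_pct"][0],
        facilitation_se=res["facilitation_pct"][1],
    )


@dataclass
class KeystoneTurnover:
    membership: pd.DataFrame  # taxa x bins, bool
    global_keystones: list
    lost: pd.DataFrame  # global keystones x bins: True where not keystone in bin


def per_bin_keystones(
    summary: TemperatureBinSummary,
    fraction: float = 0.10,
    global_keystones=None,
) -> KeystoneTurnover:
    """Re-apply the top-``fraction`` keystone rule to each bin's mean
    interactiveness, exposing keystone turnover along the gradient."""
    ids = summary.interactiveness_mean.index
    membership = pd.DataFrame(False, index=ids, columns=summary.interactiveness_mean.columns)
    for b in membership.columns:
        df = pd.DataFrame(
            {
                "interactiveness": summary.interactiveness_mean[b].fillna(0.0),
                "sum_abs_strength": summary.interactiveness_mean[b].fillna(0.0),
            }
        )
        flagged = select_keystones(df, fraction=fraction)
        membership[b] = flagged["keystone"]
    gk = list(global_keystones) if global_keystones is not None else []
    lost = ~membership.loc[gk] if gk else pd.DataFrame(columns=membership.columns)
    return KeystoneTurnover(membership=membership, global_keystones=gk, lost=lost)


def percent_change(reference: float, comparison: float) -> float:
    """Percent decrease from ``reference`` to ``comparison``:
    ``100 * (reference - comparison) / reference`` (negative = increase)."""
    if reference == 0:
        raise ValueError("reference must be nonzero")
    return 100.0 * (reference - comparison) / reference


@dataclass
class ComparisonResult:
    pairs: pd.DataFrame  # a, b, statistic, pvalue, significant
    letters: dict  # label -> letter string


def compare_distributions(samples: dict, alpha: float = 0.05) -> ComparisonResult:
    """Pairwise two-sample KS tests between bins plus a compact letter display.

    Two bins share a letter iff their pairwise test is non-significant at
    ``alpha`` (insert-and-absorb letter assignment).  Constant (degenerate)
    samples get p = NaN against every partner and their own letter.
    """
    labels = sorted(samples)
    clean = {k: np.asarray(v, dtype=float) for k, v in samples.items()}
    clean = {k: v[np.isfinite(v)] for k, v in clean.items()}
    usable = [k for k in labels if len(clean[k]) >= 5]
    if len(usable) < 2:
        raise ValueError("need >= 2 bins with >= 5 values each")
    degenerate = {k for k in usable if np.ptp(clean[k]) == 0}
    rows = []
    sig_pairs = set()
    for a, b in itertools.combinations(usable, 2):
        if a in degenerate or b in degenerate:
            rows.append((a, b, np.nan, np.nan, False))
            continue
        res = stats.ks_2samp(clean[a], clean[b], method="auto")
        significant = bool(res.pvalue < alpha)
        if significant:
            sig_pairs.add((a, b))
        rows.append((a, b, float(res.statistic), float(res.pvalue), significant))
    pairs = pd.DataFrame(rows, columns=["a", "b", "statistic", "pvalue", "significant"])

    merged = [k for k in usable if k not in degenerate]
    letter_sets = [set(merged)] if merged else []
    for a, b in sorted(sig_pairs):
        new_sets = []
        for s in letter_sets:
            if a in s and b in s:
                new_sets.extend([s - {a}, s - {b}])
            else:
                new_sets.append(s)
        # absorb: keep maximal, distinct, nonempty sets
        new_sets = [s for s in new_sets if s]
        letter_sets = []
        for s in new_sets:
            if not any(s < t for t in new_sets) and s not in letter_sets:
                letter_sets.append(s)
    letter_sets.sort(key=lambda s: min(s))
    alphabet = list(string.ascii_lowercase)
    letters = {k: "" for k in usable}
    for idx, s in enumerate(letter_sets):
        sym = alphabet[idx % 26] * (idx // 26 + 1)
        for k in sorted(s):
            letters[k] += sym
    for idx, k in enumerate(sorted(degenerate)):
        sym = alphabet[(len(letter_sets) + idx) % 26] * ((len(letter_sets) + idx) // 26 + 1)
        letters[k] = sym
    return ComparisonResult(pairs=pairs, letters=letters)


@dataclass
class OrdinationResult:
    coords: pd.DataFrame  # taxon, time, dim1, dim2, point_stress, included
    stress: float
    included: bool
    stress_cutoff: float


def interaction_profile_ordination(
    tensor: InteractionTensor,
    taxa,
    stress_cutoff: float = 0.2,
    mode: str = "split",
    seed: int = 0,
    max_points: int | None = None,
) -> OrdinationResult:
    """NMDS of per-(taxon, time) interaction profiles under Bray-Curtis.

    Each profile is a taxon's outgoing coefficient vector at one time point.
    Bray-Curtis requires non-negative entries, so signed coefficients are
    made compatible either by splitting into concatenated positive and
    negative-magnitude blocks (``mode='split'``, the default) or by taking
    absolute values (``mode='abs'``); both are interpretations, flagged here.
    Pairs of all-zero profiles (undefined dissimilarity) are set to 0.

    The 2-d embedding comes from non-metric MDS minimising Kruskal stress-1;
    a configuration whose final stress exceeds ``stress_cutoff`` is excluded
    (its points carry no coordinates).  Per-point stress contributions (share
    of the squared embedding residual) are reported as a diagnostic.
    """
    from sklearn.manifold import MDS

    if mode not in ("split", "abs"):
        raise ValueError(f"unknown mode {mode!r}")
    taxa = list(taxa)
    if not taxa:
        raise ValueError("taxa subset must be non-empty")
    ids = list(tensor.taxon_ids)
    pos = {t: k for k, t in enumerate(ids)}
    J = tensor.valid_taxa_values()
    times = tensor.valid_time_indices
    if max_points is not None and len(times) * len(taxa) > max_points:
        step = int(np.ceil(len(times) * len(taxa) / max_points))
        keep = np.arange(0, len(times), step)
        J, times = J[keep], times[keep]
    profiles, meta = [], []
    for tx in taxa:
        j = pos[tx]
        others = [k for k in range(len(ids)) if k != j]
        for ti, t in enumerate(times):
            v = J[ti, others, j]  # outgoing effects of tx at time t
            if mode == "split":
                prof = np.concatenate([np.clip(v, 0, None), np.clip(-v, 0, None)])
            else:
                prof = np.abs(v)
            profiles.append(prof)
            meta.append((tx, int(t)))
    P = np.asarray(profiles)
    D = pdist(P, metric="braycurtis")
    D = np.nan_to_num(D, nan=0.0)  # all-zero profile pairs: dissimilarity 0, flagged
    Dsq = squareform(D)
    if np.all(D == 0):
        # no dissimilarity structure at all: every profile is identical, so
        # the exact zero-stress embedding puts all points at the origin
        emb = np.zeros((len(P), 2))
        stress = 0.0
    else:
        mds = MDS(
            n_components=2,
            metric=False,
            dissimilarity="precomputed",
            random_state=int(seed),
            n_init=4,
            normalized_stress=True,
            max_iter=300,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FutureWarning)
            emb = mds.fit_transform(Dsq)
        stress = float(mds.stress_)
    included = stress <= stress_cutoff
    ed = squareform(pdist(emb))
    resid = (ed - Dsq) ** 2
    denom = resid.sum()
    point_stress = resid.sum(axis=1) / denom if denom > 0 else np.zeros(len(emb))
    coords = pd.DataFrame(meta, columns=["taxon", "time"])
    if included:
        coords["dim1"], coords["dim2"] = emb[:, 0], emb[:, 1]
    else:
        coords["dim1"] = coords["dim2"] = np.nan
    coords["point_stress"] = point_stress
    coords["included"] = included
    return OrdinationResult(
        coords=coords, stress=stress, included=included, stress_cutoff=stress_cutoff
    )
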