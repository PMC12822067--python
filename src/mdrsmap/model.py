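"""The MDR S-map model: multiview distances + local regularized regressions.

The inference runs per target taxon in three steps: (i) sample and rank many
small delay-coordinate embeddings (*views*) of the community state and
average the top views' pairwise distances into a multiview distance between
time points; (ii) tune the locality (theta) and regularization (lambda)
hyperparameters by leave-one-out one-step forecast skill; (iii) around every
time point, fit a distance-weighted elastic-net regression predicting the
target's next standardized abundance from the current abundances of all
taxa plus temperature, and read the slope coefficients off as the local
Jacobian — the time-varying interaction network.

The model/results split follows the statsmodels convention:
``MDRSMap(data, temperature).fit()`` returns an :class:`MDRSMapResults`
carrying the :class:`~mdrsmap.tensor.InteractionTensor`, per-target
diagnostics, and the derived interaction metrics.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import context as context_mod
from . import metrics as metrics_mod
from .embedding import multiview_distance, rank_views
from .preprocess import BinnedSeries, standardize
from .smap import fit_local_regression, select_hyperparameters, smap_weights
from .tensor import InteractionTensor

logger = logging.getLogger(__name__)

__all__ = ["MDRConfig", "infer_interactions", "MDRSMap", "MDRSMapResults"]


@dataclass
class MDRConfig:
    """Tunable parameters of the MDR S-map.

    The defaults span global-linear (theta = 0) to strongly local fits and a
    wide regularization range; ``cv_stride`` thins the leave-one-out
    evaluation times during hyperparameter search (1 = score every point).
    """

    e_cap: int = 5
    tau: int = 1
    n_candidate_views: int = 200
    k_top: int = 15
    theta_grid: tuple = (0.0, 0.1, 0.5, 1.0, 2.0, 4.0)
    lambda_grid: tuple = tuple(float(x) for x in np.logspace(-4, 0, 8))
    alpha: float = 0.5
    cv: str = "loo"
    cv_stride: int = 1
    include_temperature: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.e_cap < 1 or self.tau < 1:
            raise ValueError("e_cap and tau must be >= 1")
        if not self.theta_grid or not self.lambda_grid:
            raise ValueError("theta and lambda grids must be non-empty")
        if self.k_top > self.n_candidate_views:
            raise ValueError("k_top must not exceed n_candidate_views")
        if not 0 <= self.alpha <= 1:
            raise ValueError("alpha must be in [0, 1]")
        if any(t < 0 for t in self.theta_grid) or any(l < 0 for l in self.lambda_grid):
            raise ValueError("theta and lambda values must be >= 0")

    def replace(self, **kwargs) -> "MDRConfig":
        return replace(self, **kwargs)


def infer_interactions(
    data: pd.DataFrame,
    temperature=None,
    config: MDRConfig | None = None,
    scale_record: pd.DataFrame | None = None,
    min_time_points: int = 40,
) -> InteractionTensor:
    """Infer the time-varying interaction tensor for every target taxon.

    ``data`` is a complete standardized time x taxa matrix; ``temperature``
    (optional, standardized internally) is included as a predictor and as an
    embedding variable but never as a target.  Targets whose forecast skill
    is undefined are recorded as failed (NaN coefficients); it is an error
    only if every target fails.
    """
    config = config or MDRConfig()
    Z = np.asarray(data, dtype=float)
    T, S = Z.shape
    if not np.all(np.isfinite(Z)):
        raise ValueError("data must be complete (no missing values)")
    if T < min_time_points:
        raise ValueError(f"need at least {min_time_points} time points; got {T}")
    taxon_ids = list(data.columns) if isinstance(data, pd.DataFrame) else [f"taxon_{i:03d}" for i in range(S)]
    times = data.index if isinstance(data, pd.DataFrame) else pd.RangeIndex(T)

    use_temp = config.include_temperature and temperature is not None
    if use_temp:
        temp = np.asarray(temperature, dtype=float)
        if len(temp) != T:
            raise ValueError("temperature must align with the data rows")
        tsd = temp.std()
        if tsd == 0:
            raise ValueError("temperature series has zero variance")
        temp_z = (temp - temp.mean()) / tsd
        M = np.column_stack([Z, temp_z])
    else:
        M = Z
    X = M  # predictors: all taxa (+ temperature) at time t

    t0 = (config.e_cap - 1) * config.tau
    fit_times = np.arange(t0, T - 1)
    n_src = X.shape[1]
    values = np.full((T, S, n_src), np.nan)
    intercepts = np.full((T, S), np.nan)
    diag_rows = []
    n_failed = 0
    for j in range(S):
        rng = np.random.default_rng([config.seed, j])
        views = rank_views(M, j, config.e_cap, config.tau, config.n_candidate_views, rng)
        top = views[: config.k_top]
        D, _ = multiview_distance(top, M, t0=t0)
        y = Z[:, j]
        try:
            theta, lam, rho = select_hyperparameters(
                y, X, D, t0, fit_times,
                config.theta_grid, config.lambda_grid, config.alpha,
                cv_stride=config.cv_stride,
            )
        except RuntimeError:
            n_failed += 1
            logger.warning("target %s: forecast skill undefined; skipped", taxon_ids[j])
            diag_rows.append((taxon_ids[j], np.nan, np.nan, np.nan, len(top), True))
            continue
        for t in fit_times:
            w = smap_weights(D[t - t0, fit_times - t0], theta)
            b0, b = fit_local_regression(y[fit_times + 1], X[fit_times], w, lam, config.alpha)
            values[t, j] = b
            intercepts[t, j] = b0
        diag_rows.append((taxon_ids[j], theta, lam, rho, len(top), False))
    if n_failed == S:
        raise RuntimeError("all targets failed (undefined forecast skill)")
    diagnostics = pd.DataFrame(
        diag_rows, columns=["target", "theta", "lambda", "rho", "n_views", "failed"]
    ).set_index("target")
    return InteractionTensor(
        values=values,
        intercepts=intercepts,
        taxon_ids=taxon_ids,
        times=pd.Index(times),
        t0=t0,
        has_temperature=use_temp,
        diagnostics=diagnostics,
        scale_record=scale_record,
    )


class MDRSMap:
    """Multiview distance regularized S-map model for a community time series.

    Parameters
    ----------
    data : DataFrame (time x taxa) or BinnedSeries
        Abundance series on a fixed-interval grid.  Non-standardized input
        is z-scored internally (population-SD convention) and the scale
        recorded for back-conversion of coefficients.
    temperature : array-like, optional
        Covariate aligned with the data rows (raw deg C; standardized
        internally for the regression, kept raw for context analyses).
    config : MDRConfig, optional
        Model settings; keyword arguments override individual fields.

    Examples
    --------
    >>> model = MDRSMap(z_scores, temperature=temps, k_top=10)
    >>> res = model.fit()
    >>> res.summary()
    """

    def __init__(self, data, temperature=None, config: MDRConfig | None = None, **config_kwargs):
        if isinstance(data, BinnedSeries):
            if not data.is_standardized:
                data = standardize(data)
            self.scale_record = data.scale_record
            frame = data.values.T  # -> time x taxa
        else:
            frame = pd.DataFrame(data)
            mu = frame.mean(axis=0)
            sd = frame.std(axis=0, ddof=0)
            if (sd <= 0).any():
                bad = ", ".join(map(str, frame.columns[sd <= 0][:5]))
                raise ValueError(f"zero-variance taxa cannot be standardized: {bad}")
            if not (np.allclose(mu, 0, atol=1e-8) and np.allclose(sd, 1, atol=1e-6)):
                frame = (frame - mu) / sd
                self.scale_record = pd.DataFrame({"mean": mu, "sd": sd})
            else:
                self.scale_record = None
        self.data = frame
        self.temperature = None if temperature is None else np.asarray(temperature, dtype=float)
        base = config or MDRConfig()
        self.config = base.replace(**config_kwargs) if config_kwargs else base

    @classmethod
    def from_abundance_table(
        cls,
        table: pd.DataFrame,
        temperature: pd.Series | None = None,
        detection: float = 0.001,
        occupancy: float = 0.5,
        detection_mode: str = "present_mean",
        bin_candidates=(4,),
        aggregator: str = "mean",
        **kwargs,
    ) -> "MDRSMap":
        """Build the model from a raw taxa x dated-samples table.

        Runs the full preprocessing chain: common-taxon filtering, bin-width
        selection, binning and standardization; a daily temperature series
        (DatetimeIndex) is averaged onto the same bins.
        """
        from .preprocess import bin_auxiliary, bin_series, filter_common_taxa, select_bin_width

        filtered = filter_common_taxa(
            table, detection=detection, occupancy=occupancy, detection_mode=detection_mode
        )
        width = select_bin_width(filtered.columns, bin_candidates)
        binned = bin_series(filtered, width, aggregator=aggregator)
        temp_binned = None
        if temperature is not None:
            temp_binned = bin_auxiliary(temperature, binned).to_numpy()
        return cls(binned, temperature=temp_binned, **kwargs)

    def fit(self) -> "MDRSMapResults":
        tensor = infer_interactions(
            self.data,
            temperature=self.temperature,
            config=self.config,
            scale_record=self.scale_record,
        )
        return MDRSMapResults(self, tensor)


class MDRSMapResults:
    """Fitted MDR S-map: the interaction tensor plus derived analyses."""

    def __init__(self, model: MDRSMap, tensor: InteractionTensor):
        self.model = model
        self.interactions = tensor
        self._thresholds = None
        self._classification = None

    @property
    def diagnostics(self) -> pd.DataFrame:
        return self.interactions.diagnostics

    def thresholds(self, strength=None, occurrence=None) -> tuple[float, float]:
        if self._thresholds is None or strength is not None or occurrence is not None:
            thr = metrics_mod.strong_thresholds(self.interactions, strength, occurrence)
            if strength is None and occurrence is None:
                self._thresholds = thr
            return thr
        return self._thresholds

    def classify_pairs(self, thresholds=None, strength_stat="nonzero_mean") -> pd.DataFrame:
        if thresholds is None and strength_stat == "nonzero_mean":
            if self._classification is None:
                self._classification = metrics_mod.classify_pairs(
                    self.interactions, self.thresholds()
                )
            return self._classification
        return metrics_mod.classify_pairs(self.interactions, thresholds, strength_stat)

    def taxon_metrics(self, orientation="source", mean_relabund=None, **kwargs) -> pd.DataFrame:
        return metrics_mod.taxon_metrics(
            self.classify_pairs(**kwargs),
            self.interactions.taxon_ids,
            orientation=orientation,
            mean_relabund=mean_relabund,
        )

    def keystones(self, fraction: float = 0.10, **kwargs) -> pd.DataFrame:
        return metrics_mod.select_keystones(self.taxon_metrics(**kwargs), fraction=fraction)

    def sign_fractions(self) -> pd.Series:
        cls = self.classify_pairs()
        return 100.0 * cls["sign"].value_counts(normalize=True).reindex(
            ["positive", "negative", "neutral"]
        ).fillna(0.0)

    def temperature_bin_summary(self, temperature=None, **kwargs):
        """Per-degree-C-bin metrics; ``temperature`` defaults to the model's
        raw covariate restricted to valid interaction times."""
        temp = self.model.temperature if temperature is None else np.asarray(temperature)
        if temp is None:
            raise ValueError("no temperature series available")
        labels = context_mod.bin_temperature(temp[self.interactions.valid_time_indices])
        return context_mod.per_bin_metrics(
            self.interactions, self.classify_pairs(), labels, **kwargs
        )

    def summary(self) -> str:
        """Plain-text summary of the fit and headline interaction statistics."""
        tensor = self.interactions
        diag = self.diagnostics
        ok = diag[~diag["failed"].astype(bool)]
        lines = [
            "MDR S-map interaction inference",
            "=" * 46,
            f"taxa:                    {tensor.n_taxa}",
            f"time points (fitted):    {len(tensor.valid_time_indices)}",
            f"temperature covariate:   {tensor.has_temperature}",
            f"targets fitted/failed:   {len(ok)}/{int(diag['failed'].sum())}",
        ]
        if len(ok):
            lines.append(f"median forecast skill:   {ok['rho'].median():.3f}")
        try:
            s_thr, o_thr = self.thresholds()
            frac = self.sign_fractions()
            ks = self.keystones()
            lines += [
                f"strength threshold:      {s_thr:.4g}",
                f"occurrence threshold:    {o_thr:.4g}",
                "pair signs (% of ordered pairs):",
                f"  positive {frac['positive']:.1f} / negative {frac['negative']:.1f}"
                f" / neutral {frac['neutral']:.1f}",
                f"keystone taxa ({int(ks['keystone'].sum())}): "
                + ", ".join(ks.index[ks["keystone"]][:8]),
            ]
        except ValueError:
            lines.append("no nonzero coefficients; metrics unavailable")
        return "\n".join(lines)

    def plot_interaction_matrix(self, ax=None):
        """Heatmap of the time-mean taxa x taxa coefficient matrix."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 5))
        Jm = self.interactions.time_mean()
        lim = np.nanmax(np.abs(Jm)) or 1.0
        im = ax.imshow(Jm, cmap="RdBu_r", vmin=-lim, vmax=lim)
        ax.set_xlabel("source taxon")
        ax.set_ylabel("target taxon")
        ax.figure.colorbar(im, ax=ax, label="mean coefficient")
        return ax
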