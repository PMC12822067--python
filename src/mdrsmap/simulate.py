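"""Temperature-forced multispecies community simulator with analytic Jacobians.

The generator produces Ricker-type (discrete log-linear) community dynamics

    N_i(t+1) = N_i(t) * exp( r_i(T_t) + sum_j A_ij N_j(t) + eps_i(t) ),

with a seasonally forced temperature driver ``T_t`` entering growth linearly
(and optionally scaling the interaction matrix), multiplicative process noise
``eps``, and an observation layer that emulates field sampling of amplicon
time series: periodic subsampling, random dropout, multiplicative lognormal
observation noise and compositional closure (rows renormalised to sum to 1).

Because the update map is available in closed form, the exact Jacobian

    J_ij(t) = d N_i(t+1) / d N_j(t) = exp(g_i) * (delta_ij + N_i * A_ij)

is returned along the realized trajectory, giving every downstream inference
stage an analytic ground truth.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CommunityParams",
    "SimulatedDataset",
    "random_interaction_matrix",
    "simulate_community",
    "true_jacobian",
    "standardize_jacobian",
    "observe",
    "temperature_series",
]

#: days represented by one simulator step (one observation bin)
STEP_DAYS = 4
DEFAULT_START = "2018-01-01"


def _as_vector(x, n: int, name: str) -> np.ndarray:
    arr = np.broadcast_to(np.asarray(x, dtype=float), (n,)).copy()
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite")
    return arr


@dataclass
class CommunityParams:
    """Parameters of the simulated community and its forcing.

    Parameters
    ----------
    n_taxa : int
        Community size S (>= 2).
    r0 : float or array
        Baseline per-step log-growth rate at the mean temperature.
    r_temp_sens : float or array
        Linear thermal sensitivity of log-growth (per deg C).
    A : (S, S) array or None
        Signed interaction coefficients (effect of taxon j's abundance on
        taxon i's log-growth).  Diagonal entries must be <= 0
        (self-limitation).  ``None`` means pure self-limitation of -0.4.
    sigma_proc : float
        SD of the Gaussian process noise added to log-growth.
    sigma_obs : float
        SD of multiplicative lognormal observation noise (used by
        :func:`observe`).
    temp_mean, temp_amplitude, temp_period, temp_noise_sd :
        Seasonal temperature forcing: mean (deg C), amplitude (deg C),
        period (steps; default one year of 4-day steps) and white-noise SD.
    a_temp_sens : float
        Optional linear temperature scaling of the interaction matrix,
        ``A_t = A * (1 + a_temp_sens * (T - temp_mean))``.  Default 0
        (temperature enters growth only).
    seed : int
        RNG seed; identical parameters + seed give bit-identical datasets.
    """

    n_taxa: int
    r0: object = 0.8
    r_temp_sens: object = 0.01
    A: np.ndarray | None = None
    sigma_proc: float = 0.05
    sigma_obs: float = 0.0
    temp_mean: float = 18.0
    temp_amplitude: float = 4.0
    temp_period: float = 365.25 / STEP_DAYS
    temp_noise_sd: float = 0.3
    a_temp_sens: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        S = int(self.n_taxa)
        if S < 2:
            raise ValueError("n_taxa must be >= 2")
        self.n_taxa = S
        self.r0 = _as_vector(self.r0, S, "r0")
        self.r_temp_sens = _as_vector(self.r_temp_sens, S, "r_temp_sens")
        if self.A is None:
            self.A = -0.4 * np.eye(S)
        self.A = np.asarray(self.A, dtype=float)
        if self.A.shape != (S, S):
            raise ValueError(f"A must be ({S}, {S}); got {self.A.shape}")
        if np.any(np.diag(self.A) > 0):
            raise ValueError("diagonal of A must be <= 0 (self-limitation)")
        if self.sigma_proc < 0 or self.sigma_obs < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.temp_period <= 0:
            raise ValueError("temp_period must be > 0")

    def growth_rate(self, temperature: float) -> np.ndarray:
        """Per-taxon intrinsic log-growth r_i(T) at temperature T."""
        return self.r0 + self.r_temp_sens * (temperature - self.temp_mean)

    def interaction_matrix(self, temperature: float) -> np.ndarray:
        """Interaction matrix at temperature T (possibly T-scaled)."""
        if self.a_temp_sens == 0.0:
            return self.A
        return self.A * (1.0 + self.a_temp_sens * (temperature - self.temp_mean))

    def replace(self, **kwargs) -> "CommunityParams":
        return dataclasses.replace(self, **kwargs)


def random_interaction_matrix(
    n_taxa: int,
    connectance: float = 0.10,
    strength_low: float = 0.05,
    strength_high: float = 0.25,
    frac_positive: float = 0.5,
    self_limit: float = 0.4,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Sparse signed interaction matrix with self-limitation on the diagonal.

    Off-diagonal entries are nonzero with probability ``connectance``; their
    magnitude is uniform in [strength_low, strength_high] and their sign is
    positive (facilitative) with probability ``frac_positive``, else negative
    (inhibitive).
    """
    rng = np.random.default_rng() if rng is None else rng
    S = int(n_taxa)
    A = np.zeros((S, S))
    off = ~np.eye(S, dtype=bool)
    links = off & (rng.random((S, S)) < connectance)
    mags = rng.uniform(strength_low, strength_high, size=(S, S))
    signs = np.where(rng.random((S, S)) < frac_positive, 1.0, -1.0)
    A[links] = (mags * signs)[links]
    A -= self_limit * np.eye(S)
    return A


@dataclass
class SimulatedDataset:
    """Simulated trajectory plus analytic ground truth.

    Attributes
    ----------
    N : (T, S) array
        Absolute abundances (strictly positive, arbitrary units).
    P : (T, S) array
        Relative abundances; every row sums to 1.
    temperature : (T,) array
        Temperature forcing per step (deg C).
    J_true : (T, S, S) array
        Analytic Jacobian of the *noiseless* one-step map evaluated on the
        realized trajectory: ``J_true[t, i, j] = dN_i(t+1)/dN_j(t)``.
    params : CommunityParams
        The generating parameters.
    """

    N: np.ndarray
    P: np.ndarray
    temperature: np.ndarray
    J_true: np.ndarray
    params: CommunityParams
    times: np.ndarray = field(default=None)  # integer step index

    def __post_init__(self):
        if self.times is None:
            self.times = np.arange(self.N.shape[0])

    @property
    def n_steps(self) -> int:
        return self.N.shape[0]

    @property
    def taxon_ids(self) -> list[str]:
        return [f"taxon_{i:03d}" for i in range(self.params.n_taxa)]

    def dates(self, start: str = DEFAULT_START, step_days: int = STEP_DAYS) -> pd.DatetimeIndex:
        return pd.Timestamp(start) + pd.to_timedelta(self.times * step_days, unit="D")

    def standardized_true_jacobian(self, sds: np.ndarray | None = None) -> np.ndarray:
        """Ground-truth Jacobians on the z-scored scale, J_ij * s_j / s_i.

        ``sds`` defaults to the per-taxon SDs (population convention) of the
        absolute-abundance trajectory, matching what standardization of this
        dataset would use.
        """
        s = np.std(self.N, axis=0) if sds is None else np.asarray(sds, float)
        if np.any(s <= 0):
            raise ValueError("all taxon SDs must be positive")
        return self.J_true * (s[None, None, :] / s[None, :, None])


def true_jacobian(params: CommunityParams, state: np.ndarray, temperature: float) -> np.ndarray:
    """Analytic Jacobian of the noiseless Ricker update at a given state.

    ``J[i, j]`` is the effect of taxon j's current abundance on taxon i's
    next-step abundance: ``exp(g_i) * (delta_ij + N_i * A_ij)`` with
    ``g_i = r_i(T) + sum_j A_ij N_j``.
    """
    N = np.asarray(state, dtype=float)
    if N.shape != (params.n_taxa,):
        raise ValueError(f"state must have length {params.n_taxa}")
    if np.any(N <= 0):
        raise ValueError("state must be strictly positive")
    A = params.interaction_matrix(temperature)
    g = params.growth_rate(temperature) + A @ N
    return np.exp(g)[:, None] * (np.eye(params.n_taxa) + N[:, None] * A)


def temperature_series(params: CommunityParams, n_steps: int, rng: np.random.Generator) -> np.ndarray:
    t = np.arange(n_steps)
    seasonal = params.temp_mean + params.temp_amplitude * np.sin(
        2.0 * np.pi * t / params.temp_period
    )
    return seasonal + rng.normal(0.0, params.temp_noise_sd, size=n_steps)


def simulate_community(
    params: CommunityParams,
    n_steps: int,
    N0: np.ndarray | None = None,
    burn_in: int = 0,
) -> SimulatedDataset:
    """Simulate the community for ``n_steps`` observed steps.

    An optional ``burn_in`` number of initial steps is simulated and
    discarded so the returned trajectory is close to its stationary regime.
    Raises ``RuntimeError`` naming the first bad step if the trajectory
    diverges (non-finite or astronomically large abundances).
    """
    if n_steps < 10:
        raise ValueError("n_steps must be >= 10")
    total = n_steps + burn_in
    rng = np.random.default_rng(params.seed)
    temp = temperature_series(params, total, rng)
    S = params.n_taxa
    if N0 is None:
        N0 = rng.uniform(0.8, 1.2, size=S)
    N = np.empty((total, S))
    J = np.empty((total, S, S))
    N[0] = np.asarray(N0, dtype=float)
    if np.any(N[0] <= 0):
        raise ValueError("initial abundances must be strictly positive")
    for t in range(total):
        A = params.interaction_matrix(temp[t])
        g = params.growth_rate(temp[t]) + A @ N[t]
        J[t] = np.exp(g)[:, None] * (np.eye(S) + N[t][:, None] * A)
        if t + 1 < total:
            eps = rng.normal(0.0, params.sigma_proc, size=S) if params.sigma_proc > 0 else 0.0
            nxt = N[t] * np.exp(g + eps)
            if not np.all(np.isfinite(nxt)) or np.any(nxt > 1e12) or np.any(nxt <= 0):
                raise RuntimeError(
                    f"trajectory diverged at step {t + 1}; "
                    "reduce r0 or the magnitudes in A"
                )
            N[t + 1] = nxt
    sl = slice(burn_in, total)
    Nw = N[sl]
    return SimulatedDataset(
        N=Nw,
        P=Nw / Nw.sum(axis=1, keepdims=True),
        temperature=temp[sl],
        J_true=J[sl],
        params=params,
        times=np.arange(n_steps),
    )


def standardize_jacobian(J: np.ndarray, sds: np.ndarray) -> np.ndarray:
    """Convert Jacobians to the z-scored scale: J_std_ij = J_ij * s_j / s_i."""
    s = np.asarray(sds, dtype=float)
    return np.asarray(J) * (s[None, :] / s[:, None])


def observe(
    dataset: SimulatedDataset,
    sample_interval: int = 1,
    missing_fraction: float = 0.0,
    seed: int = 0,
    relative: bool = True,
    start: str = DEFAULT_START,
    step_days: int = STEP_DAYS,
) -> pd.DataFrame:
    """Emulate the field observation process on a simulated trajectory.

    Subsamples every ``sample_interval``-th step, drops ``missing_fraction``
    of the retained samples at random, applies multiplicative lognormal
    observation noise with SD ``params.sigma_obs`` and (for relative output)
    re-closes each sample to sum 1.

    Returns a taxa x samples DataFrame with ISO-dated columns.
    """
    if sample_interval < 1:
        raise ValueError("sample_interval must be >= 1")
    if not 0.0 <= missing_fraction < 1.0:
        raise ValueError("missing_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    idx = np.arange(0, dataset.n_steps, sample_interval)
    if missing_fraction > 0:
        n_drop = int(round(missing_fraction * len(idx)))
        drop = rng.choice(len(idx), size=n_drop, replace=False)
        keep = np.setdiff1d(np.arange(len(idx)), drop)
        idx = idx[keep]
    vals = (dataset.P if relative else dataset.N)[idx].copy()
    sigma = dataset.params.sigma_obs
    if sigma > 0:
        vals = vals * np.exp(rng.normal(0.0, sigma, size=vals.shape))
    if relative:
        vals = vals / vals.sum(axis=1, keepdims=True)
    dates = pd.Timestamp(start) + pd.to_timedelta(dataset.times[idx] * step_days, unit="D")
    return pd.DataFrame(vals.T, index=dataset.taxon_ids, columns=dates)
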