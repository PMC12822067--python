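"""Self-contained validation benchmarks run against the simulator's ground truth.

These are the package's standing experiments: a Jacobian-recovery benchmark
on a sparse 12-taxon Ricker community (can the MDR S-map recover the true
time-varying interaction matrix from the trajectory alone?) and a null
control (does the strong-interaction classification stay quiet when no
interactions exist?).  Both are driven entirely by the synthetic community
module, so they run anywhere without external data.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .metrics import classify_pairs, strong_thresholds
from .model import MDRConfig, MDRSMap
from .simulate import CommunityParams, random_interaction_matrix, simulate_community

__all__ = ["benchmark_config", "recovery_run", "jacobian_recovery", "null_control"]


def benchmark_config(seed: int = 0) -> MDRConfig:
    """The model settings used for the standing benchmarks.

    A moderate search (50 candidate views, 7 retained, 3x3 hyperparameter
    grid scored on every 4th point) keeps a full 12-taxon, 400-bin run in
    the tens of seconds while leaving recovery quality essentially unchanged
    relative to the wider default grids.
    """
    return MDRConfig(
        e_cap=5,
        tau=1,
        n_candidate_views=50,
        k_top=7,
        theta_grid=(0.0, 0.5, 2.0),
        lambda_grid=(1e-3, 1e-2, 1e-1),
        alpha=0.5,
        cv_stride=4,
        seed=seed,
    )


def _stable_community(
    seed: int,
    n_taxa: int,
    connectance: float,
    sigma_proc: float,
    n_steps: int,
    burn_in: int = 100,
    max_attempts: int = 20,
):
    """Draw a community whose trajectory stays finite, plus that trajectory.

    Random interaction matrices occasionally produce explosive Ricker
    dynamics; a divergent trajectory carries no data to infer from, so the
    benchmark is defined over stable communities.  Unstable draws are
    discarded and redrawn from the same deterministic stream, keeping the
    procedure fully reproducible.
    """
    rng = np.random.default_rng([seed, 17])
    last_error = None
    for _ in range(max_attempts):
        A = random_interaction_matrix(n_taxa, connectance=connectance, rng=rng)
        params = CommunityParams(
            n_taxa=n_taxa,
            r0=0.8,
            r_temp_sens=0.01,
            A=A,
            sigma_proc=sigma_proc,
            seed=seed,
        )
        try:
            ds = simulate_community(params, n_steps, burn_in=burn_in)
        except RuntimeError as exc:  # divergent draw: redraw the matrix
            last_error = exc
            continue
        return params, ds
    raise RuntimeError(
        f"no stable community in {max_attempts} draws (last error: {last_error})"
    )


@dataclass
class RecoveryRun:
    pearson_r: float
    sign_agreement_pct: float
    n_links: int
    inferred_mean: np.ndarray
    true_mean: np.ndarray


def recovery_run(
    seed: int,
    n_taxa: int = 12,
    n_steps: int = 400,
    connectance: float = 0.10,
    sigma_proc: float = 0.05,
    config: MDRConfig | None = None,
) -> RecoveryRun:
    """One seed of the Jacobian-recovery benchmark.

    Simulates the community (absolute abundances; no compositional closure),
    z-scores it, infers interactions, and compares the time-mean inferred
    coefficients with the time-mean standardized true Jacobians over all
    ordered off-diagonal pairs: Pearson r, plus sign agreement on the pairs
    whose |true| value lies strictly above the 75th percentile (with sparse
    ground truth these are exactly the realized links).
    """
    params, ds = _stable_community(seed, n_taxa, connectance, sigma_proc, n_steps)
    data = pd.DataFrame(ds.N, columns=ds.taxon_ids)
    cfg = (config or benchmark_config()).replace(seed=seed)
    model = MDRSMap(data, temperature=ds.temperature, config=cfg)
    res = model.fit()
    tensor = res.interactions
    vt = tensor.valid_time_indices
    J_hat = tensor.taxa_values[vt].mean(axis=0)
    J_true = ds.standardized_true_jacobian()[vt].mean(axis=0)
    off = ~np.eye(n_taxa, dtype=bool)
    a, b = J_hat[off], J_true[off]
    r = float(np.corrcoef(a, b)[0, 1])
    thr = np.quantile(np.abs(b), 0.75)
    top = np.abs(b) > thr
    agree = float(np.mean(np.sign(a[top]) == np.sign(b[top]))) * 100 if top.any() else np.nan
    return RecoveryRun(
        pearson_r=r,
        sign_agreement_pct=agree,
        n_links=int(top.sum()),
        inferred_mean=J_hat,
        true_mean=J_true,
    )


def jacobian_recovery(
    seed: int = 0,
    n_seeds: int = 5,
    **kwargs,
) -> pd.DataFrame:
    """Multi-seed recovery benchmark; one row per seed."""
    rows = []
    for k in range(n_seeds):
        run = recovery_run(seed=int(np.random.default_rng([seed, k]).integers(2**31 - 1)), **kwargs)
        rows.append(
            {
                "seed_index": k,
                "pearson_r": run.pearson_r,
                "sign_agreement_pct": run.sign_agreement_pct,
                "n_links": run.n_links,
            }
        )
    return pd.DataFrame(rows)


def null_control(
    seed: int = 0,
    n_taxa: int = 12,
    n_steps: int = 300,
    sigma_proc: float = 0.05,
    config: MDRConfig | None = None,
) -> dict:
    """Zero-interaction control: fraction of ordered pairs called non-neutral.

    The community has no off-diagonal interactions (self-limitation only),
    so under data-driven strong-interaction thresholds the classification
    should label almost every ordered pair neutral.
    """
    params, ds = _stable_community(seed, n_taxa, connectance=0.0, sigma_proc=sigma_proc, n_steps=n_steps)
    data = pd.DataFrame(ds.N, columns=ds.taxon_ids)
    cfg = (config or benchmark_config()).replace(seed=seed)
    res = MDRSMap(data, temperature=ds.temperature, config=cfg).fit()
    tensor = res.interactions
    thresholds = strong_thresholds(tensor)
    cls = classify_pairs(tensor, thresholds)
    frac = float(cls["strong"].mean())
    return {
        "nonneutral_fraction": frac,
        "nonneutral_pct": 100.0 * frac,
        "n_pairs": int(len(cls)),
        "thresholds": thresholds,
        "classification": cls,
        "tensor": tensor,
    }
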