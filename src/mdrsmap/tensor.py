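"""The time x target x source interaction-coefficient container."""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["InteractionTensor", "TEMPERATURE_ID"]

#: reserved source id for the temperature-covariate column
TEMPERATURE_ID = "TEMPERATURE"


@dataclass
class InteractionTensor:
    """Time-varying interaction coefficients from the MDR S-map.

    ``values[t, i, j]`` is the standardized-scale coefficient of source j's
    current abundance in the local regression predicting target i's
    next-step abundance — an estimate of the Jacobian entry dZ_i(t+1)/dZ_j(t).
    When a temperature covariate was included the last source column holds
    its coefficient and is excluded from all taxon-taxon metrics.

    Coefficients exist for times ``t0 .. T-2`` (earlier points lack lagged
    embedding coordinates; the final point has no next step); elsewhere the
    array is NaN.
    """

    values: np.ndarray  # (T, S, S [+1])
    intercepts: np.ndarray  # (T, S)
    taxon_ids: list
    times: pd.Index
    t0: int
    has_temperature: bool
    diagnostics: pd.DataFrame  # per target: theta, lambda, rho, n_views, failed
    scale_record: pd.DataFrame | None = None

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    @property
    def n_times(self) -> int:
        return self.values.shape[0]

    @property
    def source_ids(self) -> list:
        return list(self.taxon_ids) + ([TEMPERATURE_ID] if self.has_temperature else [])

    @property
    def valid_time_indices(self) -> np.ndarray:
        """Indices of time points carrying coefficients (t0 .. T-2)."""
        return np.arange(self.t0, self.n_times - 1)

    @property
    def taxa_values(self) -> np.ndarray:
        """Coefficient block restricted to taxon sources (temperature dropped)."""
        return self.values[:, :, : self.n_taxa]

    def valid_taxa_values(self) -> np.ndarray:
        return self.taxa_values[self.valid_time_indices]

    def time_mean(self) -> np.ndarray:
        """Time-mean taxa x taxa coefficient matrix over valid times."""
        return self.valid_taxa_values().mean(axis=0)

    def temperature_coefficients(self) -> np.ndarray | None:
        if not self.has_temperature:
            return None
        return self.values[self.valid_time_indices][:, :, -1]

    def to_long(self) -> pd.DataFrame:
        """Long-format frame (bin_start, target_id, source_id, coefficient)."""
        vt = self.valid_time_indices
        src = self.source_ids
        recs = []
        for t in vt:
            for i, tid in enumerate(self.taxon_ids):
                row = self.values[t, i]
                for j, sid in enumerate(src):
                    recs.append((self.times[t], tid, sid, row[j]))
        return pd.DataFrame(recs, columns=["bin_start", "target_id", "source_id", "coefficient"])

    def save(self, path, diagnostics_path=None) -> None:
        """Write the long-format coefficients (gzip TSV when path ends .gz)."""
        # fixed mtime keeps gzip output bit-identical across reruns
        comp = {"method": "gzip", "mtime": 0} if str(path).endswith(".gz") else None
        self.to_long().to_csv(path, sep="\t", index=False, compression=comp)
        if diagnostics_path is not None:
            self.diagnostics.to_csv(diagnostics_path, sep="\t")

    @classmethod
    def load(cls, path, diagnostics_path=None) -> "InteractionTensor":
        comp = "gzip" if str(path).endswith(".gz") else None
        long = pd.read_csv(path, sep="\t", compression=comp)
        times = pd.Index(sorted(long["bin_start"].unique()))
        targets = list(pd.unique(long["target_id"]))
        sources = list(pd.unique(long["source_id"]))
        has_temp = TEMPERATURE_ID in sources
        taxa = [s for s in sources if s != TEMPERATURE_ID]
        S, nsrc = len(taxa), len(sources)
        # reconstruct a dense array; loaded tensors start at t0 = 0 and get a
        # trailing NaN row standing in for the unfitted final time point.
        vals = np.full((len(times) + 1, S, nsrc), np.nan)
        tpos = {t: k for k, t in enumerate(times)}
        ipos = {t: k for k, t in enumerate(taxa)}
        jpos = {s: k for k, s in enumerate(sources)}
        for t, tid, sid, c in long.itertuples(index=False):
            vals[tpos[t], ipos[tid], jpos[sid]] = c
        diags = (
            pd.read_csv(diagnostics_path, sep="\t", index_col=0)
            if diagnostics_path is not None
            else pd.DataFrame(index=taxa)
        )
        full_times = pd.Index(list(times) + ["<end>"])
        return cls(
            values=vals,
            intercepts=np.full((len(times) + 1, S), np.nan),
            taxon_ids=taxa,
            times=full_times,
            t0=0,
            has_temperature=has_temp,
            diagnostics=diags,
        )
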