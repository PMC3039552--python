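"""Shared in-memory containers for model inputs and outputs."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .config import MCMCConfig

__all__ = ["IncidenceDataset", "PosteriorDraws", "SmoothedEstimates"]


@dataclass(frozen=True)
class IncidenceDataset:
    """Observed counts y_i and expected counts e_i for one sex/cancer stratum.

    Under internal (indirect) standardisation sum(e) equals sum(y).
    """

    area_ids: tuple[str, ...]
    y: np.ndarray
    e: np.ndarray

    def __post_init__(self) -> None:
        y = np.asarray(self.y)
        e = np.asarray(self.e, dtype=float)
        n = len(self.area_ids)
        if y.shape != (n,) or e.shape != (n,):
            raise ValueError("y and e must be one value per area")
        if np.any(y < 0) or not np.allclose(y, np.round(y)):
            raise ValueError("observed counts must be non-negative integers")
        if np.any(e < 0):
            raise ValueError("expected counts must be non-negative")
        object.__setattr__(self, "y", y.astype(float))
        object.__setattr__(self, "e", e)

    @property
    def n_areas(self) -> int:
        return len(self.area_ids)


@dataclass(frozen=True)
class PosteriorDraws:
    """Thinned single-chain MCMC output.

    ``params`` maps parameter names to arrays with the draw index first:
    ``alpha`` (T,) for incidence or (T, J) for survival, ``beta`` (T, K),
    ``u`` and ``v`` (T, n), ``tau_u`` and ``tau_v`` (T,).  ``kind`` is
    ``"incidence"`` or ``"survival"``.
    """

    kind: str
    area_ids: tuple[str, ...]
    params: Mapping[str, np.ndarray]
    config: MCMCConfig
    seed: int

    def __post_init__(self) -> None:
        if self.kind not in ("incidence", "survival"):
            raise ValueError("kind must be 'incidence' or 'survival'")
        t = {v.shape[0] for v in self.params.values()}
        if len(t) != 1:
            raise ValueError("all parameter chains must share the draw dimension")
        if self.n_draws != self.config.n_draws:
            raise ValueError("stored draws do not match kept/thin")

    @property
    def n_draws(self) -> int:
        return next(iter(self.params.values())).shape[0]

    @property
    def n_areas(self) -> int:
        return len(self.area_ids)

    def theta(self) -> np.ndarray:
        """Per-area relative-risk chains theta_i = exp(alpha + u_i + v_i)
        (incidence model only)."""
        if self.kind != "incidence":
            raise ValueError("theta is defined for incidence draws")
        a = self.params["alpha"]
        return np.exp(a[:, None] + self.params["u"] + self.params["v"])

    def rer(self) -> np.ndarray:
        """Per-area relative-excess-risk chains exp(u_i + v_i)
        (survival model only)."""
        if self.kind != "survival":
            raise ValueError("rer is defined for survival draws")
        return np.exp(self.params["u"] + self.params["v"])


@dataclass(frozen=True)
class SmoothedEstimates:
    """Per-area posterior median with central 95% credible interval and the
    five-class map category."""

    area_ids: tuple[str, ...]
    median: np.ndarray
    lo95: np.ndarray
    hi95: np.ndarray
    category: tuple[str, ...]
    measure: str = "ratio"

    def __post_init__(self) -> None:
        n = len(self.area_ids)
        for name in ("median", "lo95", "hi95"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise ValueError(f"{name} must be one value per area")
            object.__setattr__(self, name, arr)
        if len(self.category) != n:
            raise ValueError("category must be one label per area")
        if np.any(self.lo95 > self.median + 1e-12) or np.any(
            self.median > self.hi95 + 1e-12
        ):
            raise ValueError("interval must bracket the median")

    @property
    def n_areas(self) -> int:
        return len(self.area_ids)

    def to_frame(self, scale: float = 1.0) -> pd.DataFrame:
        """Export table; ``scale=100`` prints 100 = regional average."""
        return pd.DataFrame(
            {
                "area_id": list(self.area_ids),
                "median": self.median * scale,
                "lo95": self.lo95 * scale,
                "hi95": self.hi95 * scale,
                "category": list(self.category),
            }
        )
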