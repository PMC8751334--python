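"""Run configuration and seeded random-number substreams.

All randomness in the package flows from a single integer seed.  Each
consumer (MP sampling, noise resampling, every simulation recipe) draws
from its own named substream so that, e.g., changing the number of
bootstrap draws never perturbs a simulation that shares the same seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

__all__ = ["RunConfig", "substream"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the named substream of ``seed``.

    The stream key is derived from a CRC32 of the name, so streams are
    stable across sessions and independent of call order.
    """
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(name.encode())]))


@dataclass
class RunConfig:
    """Settings shared by the full per-cluster pipeline.

    Parameters
    ----------
    noise_model:
        ``"additive"`` (measured matrix = noise + signal) or
        ``"multiplicative"`` (measured matrix = (I+P)^{1/2} X).
    alpha_tw:
        Significance level of the Tracy-Widom outlier threshold for the
        largest eigenvalue.
    alpha_sw:
        Significance level of the Shapiro-Wilk normality gate applied to
        cell-singular vectors (Benjamini-Hochberg adjusted across the
        threshold-passing components).
    n_boot:
        Number of resampled noise matrices used for the uncertainty
        estimate.
    seed:
        Master seed; all substreams derive from it.
    min_cluster_size_warn:
        Clusters smaller than this trigger a warning (the random-matrix
        null is asymptotic and small clusters sit far from it).
    covariates:
        Names of covariate columns to use in the confounder regression;
        empty means "all columns supplied".
    """

    noise_model: str = "additive"
    alpha_tw: float = 0.01
    alpha_sw: float = 0.05
    n_boot: int = 50
    seed: int = 0
    min_cluster_size_warn: int = 50
    covariates: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.noise_model not in ("additive", "multiplicative"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        if not (0.0 < self.alpha_tw < 1.0):
            raise ValueError("alpha_tw must lie in (0, 1)")
        if not (0.0 < self.alpha_sw < 1.0):
            raise ValueError("alpha_sw must lie in (0, 1)")
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")

    def rng(self, name: str) -> np.random.Generator:
        """Named substream of this run's seed."""
        return substream(self.seed, name)
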