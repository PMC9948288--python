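"""Z-prime assay quality statistics for droplet-scale assay development.

Labeled control droplet populations (assay alone = negative; assay plus a
positive-control compound = positive) are summarized by their Gaussian
moments, and assay quality is scored as

    Z' = 1 - 3 * (sigma_neg + sigma_pos) / |mu_neg - mu_pos|

Z' = 1 for a statistically perfect assay (zero variance); Z' > 0.5 marks an
assay as suitable for screening.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ControlPopulations",
    "population_stats",
    "z_prime",
    "assay_suitability",
    "qc_report",
]

#: Strict suitability cutoff for screening assays.
Z_PRIME_CUTOFF = 0.5


def _load_numeric(path: str | Path) -> np.ndarray:
    """Read a delimited numeric file (one value per line, or first column)."""
    arr = np.loadtxt(path, ndmin=2, delimiter=None)
    return arr[:, 0] if arr.ndim == 2 else arr


@dataclass
class ControlPopulations:
    """Negative- and positive-control droplet signal populations."""

    neg_signals: np.ndarray
    pos_signals: np.ndarray

    def __post_init__(self) -> None:
        self.neg_signals = np.asarray(self.neg_signals, dtype=float)
        self.pos_signals = np.asarray(self.pos_signals, dtype=float)
        if self.neg_signals.size < 2 or self.pos_signals.size < 2:
            raise ValueError("each control population needs at least 2 values")

    @classmethod
    def from_files(cls, neg_path: str | Path, pos_path: str | Path) -> "ControlPopulations":
        return cls(_load_numeric(neg_path), _load_numeric(pos_path))

    def z_prime(self) -> float:
        mu_n, sd_n = population_stats(self.neg_signals)
        mu_p, sd_p = population_stats(self.pos_signals)
        return z_prime(mu_n, sd_n, mu_p, sd_p)


def population_stats(signals) -> tuple[float, float]:
    """Sample mean and sample SD (n - 1 denominator) of a signal population."""
    x = np.asarray(signals, dtype=float)
    if x.size < 2:
        raise ValueError("at least 2 values are required")
    return float(x.mean()), float(x.std(ddof=1))


def z_prime(mu_neg: float, sigma_neg: float, mu_pos: float, sigma_pos: float) -> float:
    """Z' assay quality score; <= 1, symmetric in the two population labels."""
    if mu_neg == mu_pos:
        raise ValueError("Z' undefined for equal control means")
    return 1.0 - 3.0 * (sigma_neg + sigma_pos) / abs(mu_neg - mu_pos)


def assay_suitability(z_prime_value: float) -> bool:
    """True when the assay is suitable for screening (strictly Z' > 0.5)."""
    if not np.isfinite(z_prime_value):
        raise ValueError("Z' must be finite")
    return z_prime_value > Z_PRIME_CUTOFF


def qc_report(populations: ControlPopulations) -> pd.DataFrame:
    """One-row QC table: control moments, Z', and the suitability verdict."""
    mu_n, sd_n = population_stats(populations.neg_signals)
    mu_p, sd_p = population_stats(populations.pos_signals)
    z = z_prime(mu_n, sd_n, mu_p, sd_p)
    return pd.DataFrame(
        [
            {
                "mu_neg": mu_n,
                "sigma_neg": sd_n,
                "mu_pos": mu_p,
                "sigma_pos": sd_p,
                "z_prime": z,
                "verdict": "suitable" if assay_suitability(z) else "unsuitable",
            }
        ]
    )
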