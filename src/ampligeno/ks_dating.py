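"""Summaries of synonymous-substitution (Ks) distributions and dating.

Ks distributions of ortholog or paralog pairs carry the signature of
speciation and whole-genome-duplication events as density peaks.  The
module reports the median and the kernel-density peak of a capped Ks
sample, and converts between Ks, the synonymous substitution rate r
(substitutions per synonymous site per year) and divergence time T.

The default conversion is the single-path convention T = Ks / r.  The
textbook per-lineage convention T = Ks / (2r), which counts substitution
accumulation along both diverging lineages, is available via
``per_lineage=True``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import gaussian_kde

DEFAULT_INTERSPECIES_CAP = 0.6
DEFAULT_INTRASPECIES_CAP = 3.5

MIN_PEAK_SAMPLE = 10


class UndefinedKsError(ValueError):
    """Not enough Ks values below the cap to summarise."""


@dataclass(frozen=True)
class KsSample:
    """A collection of pairwise Ks values with an analysis cap.

    Values at or above ``ks_cap`` are excluded from the median and the
    density peak — saturated pairs dominate the tail and carry no
    dating signal.
    """

    values: tuple[float, ...]
    ks_cap: float = DEFAULT_INTERSPECIES_CAP

    def __post_init__(self) -> None:
        if self.ks_cap <= 0:
            raise ValueError("ks_cap must be positive")
        if any(v < 0 for v in self.values):
            raise ValueError("Ks values must be non-negative")

    def capped(self) -> np.ndarray:
        vals = np.asarray(self.values, dtype=float)
        return vals[vals < self.ks_cap]


def ks_median(sample: KsSample) -> float:
    """Median Ks over values below the cap."""
    vals = sample.capped()
    if vals.size == 0:
        raise UndefinedKsError("no Ks values below the cap")
    return float(np.median(vals))


def ks_peak(sample: KsSample, bandwidth: float | str | None = None, grid: int = 2048) -> float:
    """Mode of a Gaussian kernel density over the capped values.

    ``bandwidth`` follows scipy's gaussian_kde ``bw_method``
    (default Silverman's rule); the argmax is taken on a regular grid of
    ``grid`` points spanning [0, cap) and reported to 3 decimals.
    """
    vals = sample.capped()
    if vals.size < MIN_PEAK_SAMPLE:
        raise UndefinedKsError(
            f"peak estimation needs >= {MIN_PEAK_SAMPLE} values below the cap"
        )
    kde = gaussian_kde(vals, bw_method=bandwidth or "silverman")
    xs = np.linspace(0.0, sample.ks_cap, grid, endpoint=False)
    dens = kde(xs)
    return round(float(xs[int(np.argmax(dens))]), 3)


@dataclass(frozen=True)
class DatingResult:
    ks: float
    rate: float  # substitutions / synonymous site / year
    time: float  # years


def divergence_time(ks: float, rate: float, per_lineage: bool = False) -> float:
    """Divergence time in years from a Ks value and a substitution rate."""
    if rate <= 0:
        raise ValueError("substitution rate must be positive")
    if ks < 0:
        raise ValueError("Ks must be non-negative")
    return ks / ((2.0 if per_lineage else 1.0) * rate)


def substitution_rate(ks: float, time: float, per_lineage: bool = False) -> float:
    """Substitution rate per year from a Ks value and a divergence time."""
    if time <= 0:
        raise ValueError("divergence time must be positive")
    if ks < 0:
        raise ValueError("Ks must be non-negative")
    return ks / ((2.0 if per_lineage else 1.0) * time)


def date_sample(
    sample: KsSample,
    rate: float,
    bandwidth: float | str | None = None,
    per_lineage: bool = False,
) -> dict:
    """Median/peak summary of a Ks sample plus dated values."""
    med = ks_median(sample)
    out = {
        "n": int(sample.capped().size),
        "ks_cap": sample.ks_cap,
        "ks_median": med,
        "time_from_median": divergence_time(med, rate, per_lineage),
    }
    try:
        peak = ks_peak(sample, bandwidth=bandwidth)
    except UndefinedKsError:
        peak = None
    out["ks_peak"] = peak
    out["time_from_peak"] = (
        divergence_time(peak, rate, per_lineage) if peak is not None else None
    )
    return out


def load_ks_table(path) -> list[float]:
    """Read Ks values from a one- or two-column (pair, ks) TSV."""
    values: list[float] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            token = fields[-1]
            try:
                values.append(float(token))
            except ValueError:
                continue  # header line
    return values
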