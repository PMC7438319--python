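"""Density algebra linking 2D puncta counts to 3D synapse densities.

A punctum labeled in both channels must not be counted twice, so the total
density of distinct labeled puncta follows from the per-channel densities
and the colocalization index c:

    dTotal = (dPSD95 + dSAP102) / (1 + c),        dColoc = c * dTotal

The conversion factor k = (AS synapses / um^3) / (total puncta / 100 um^2)
calibrates the cheap 2D readout against volumetric ground truth, and
k * dTotal extrapolates *minimum* synapse-density estimates to any region
with known puncta densities (minimum, because unlabeled excitatory synapses
are invisible to the fluorescent readout).  Punctum/SAS size distributions
are fitted as log-normals by maximum likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class PunctaDensityRecord:
    """Per-unit puncta densities (per 100 um^2) and colocalization index."""

    unit: str
    dPSD95: float
    dSAP102: float
    c: float
    dTotal: float
    dColoc: float


@dataclass(frozen=True)
class ConversionFactor:
    """(synapses/um^3) per (puncta/100 um^2)."""

    k: float
    scope: str = "averaged"

    def __post_init__(self):
        if self.k < 0:
            raise ValueError("conversion factor must be non-negative")


@dataclass
class RegionEstimate:
    region: str
    dTotal: float
    est_density: float            # synapses / um^3
    flag: str = "minimum estimate"


@dataclass
class LogNormalFit:
    mu: float
    sigma: float
    n: int
    gof_stat: float               # one-sample KS against the fitted law
    gof_p: float

    def mean(self) -> float:
        """Mean of the fitted log-normal, exp(mu + sigma^2/2)."""
        return float(np.exp(self.mu + 0.5 * self.sigma ** 2))


# --------------------------------------------------------------------------

def total_density(dPSD95: float, dSAP102: float, c: float,
                  unit: str = "unit") -> PunctaDensityRecord:
    """Colocalization-corrected total puncta density."""
    if dPSD95 < 0 or dSAP102 < 0:
        raise ValueError("densities must be non-negative")
    if not 0.0 <= c <= 1.0:
        raise ValueError("colocalization index must lie in [0, 1]")
    d_total = (dPSD95 + dSAP102) / (1.0 + c)
    # note: c is not checked against the channel densities; on physically
    # consistent inputs (c x dTotal <= min(d1, d2)) the bounds
    # max(d1, d2) <= dTotal <= d1 + d2 hold automatically
    return PunctaDensityRecord(unit=unit, dPSD95=dPSD95, dSAP102=dSAP102,
                               c=c, dTotal=d_total, dColoc=c * d_total)


def conversion_factor(as_density: float, d_total: float,
                      scope: str = "averaged") -> ConversionFactor:
    """k = AS density (synapses/um^3) / total puncta density (/100 um^2)."""
    if d_total <= 0:
        raise ValueError("total puncta density must be positive")
    if as_density < 0:
        raise ValueError("AS density must be non-negative")
    return ConversionFactor(k=as_density / d_total, scope=scope)


def averaged_conversion_factor(layer_records, layer_as_densities,
                               mode="mean_of_layers") -> ConversionFactor:
    """Combine per-layer factors into one brain-wide factor.

    ``mode='mean_of_layers'`` (default): the mean of the layer factors
    computed from layer-mean densities.  ``mode='pooled'``: quotient of the
    across-layer mean AS density and mean total puncta density.
    """
    d_totals = [r.dTotal for r in layer_records]
    if mode == "mean_of_layers":
        ks = [conversion_factor(a, d).k
              for a, d in zip(layer_as_densities, d_totals)]
        return ConversionFactor(k=float(np.mean(ks)), scope="averaged")
    if mode == "pooled":
        return conversion_factor(float(np.mean(layer_as_densities)),
                                 float(np.mean(d_totals)), scope="averaged")
    raise ValueError(f"unknown mode {mode!r}")


def apply_conversion(region_table: pd.DataFrame, factor: ConversionFactor,
                     logger=None):
    """Minimum synapse-density estimates for a per-region density table.

    The table needs either a ``dTotal`` column or ``dPSD95, dSAP102, c``
    columns (from which dTotal is computed per row).  Rows with missing
    data are skipped with a logged warning; the run continues.
    """
    import logging

    log = logger or logging.getLogger(__name__)
    estimates = []
    for _, row in region_table.iterrows():
        name = str(row.get("region", f"row-{_}"))
        try:
            if "dTotal" in row and pd.notna(row["dTotal"]):
                d_total = float(row["dTotal"])
            else:
                d_total = total_density(float(row["dPSD95"]),
                                        float(row["dSAP102"]),
                                        float(row["c"])).dTotal
        except (KeyError, ValueError, TypeError) as exc:
            log.warning("skipping region %s: %s", name, exc)
            continue
        estimates.append(RegionEstimate(region=name, dTotal=d_total,
                                        est_density=factor.k * d_total))
    return estimates


def estimates_to_frame(estimates) -> pd.DataFrame:
    rows = [(e.region, e.dTotal, e.est_density, e.flag) for e in estimates]
    return pd.DataFrame(rows, columns=["region", "dTotal",
                                       "est_density", "flag"])


# --------------------------------------------------------------------------
# Size distributions
# --------------------------------------------------------------------------

def fit_lognormal(samples) -> LogNormalFit:
    """Maximum-likelihood log-normal fit on the nm^2 scale.

    mu is the mean of log samples; sigma the population (ddof=0) standard
    deviation of log samples.  Goodness of fit is a descriptive one-sample
    Kolmogorov-Smirnov test against the fitted distribution.
    """
    x = np.asarray(samples, dtype=np.float64)
    if x.size < 2:
        raise ValueError("need at least two samples")
    if np.any(x <= 0):
        raise ValueError("samples must be positive")
    logs = np.log(x)
    mu = float(logs.mean())
    sigma = float(logs.std(ddof=0))
    if sigma == 0:
        raise ValueError("degenerate sample: zero variance")
    ks = stats.kstest(x, stats.lognorm(s=sigma, scale=np.exp(mu)).cdf)
    return LogNormalFit(mu=mu, sigma=sigma, n=int(x.size),
                        gof_stat=float(ks.statistic), gof_p=float(ks.pvalue))


def size_histogram(samples, bin_width: float) -> pd.DataFrame:
    """Half-open [lo, hi) frequency table with fixed bin width."""
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    x = np.asarray(samples, dtype=np.float64)
    if x.size == 0:
        return pd.DataFrame(columns=["bin_lo", "bin_hi", "count"])
    lo = np.floor(x.min() / bin_width) * bin_width
    hi = np.floor(x.max() / bin_width) * bin_width + bin_width
    edges = np.arange(lo, hi + 0.5 * bin_width, bin_width)
    idx = np.floor((x - lo) / bin_width).astype(int)
    counts = np.bincount(idx, minlength=len(edges) - 1)
    return pd.DataFrame({"bin_lo": edges[:-1], "bin_hi": edges[1:],
                         "count": counts})
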