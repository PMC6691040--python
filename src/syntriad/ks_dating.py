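"""Gaussian Ks-peak fitting, lineage rate correction and event dating.

Each polyploidy or speciation event leaves a peak in the Ks distribution of
the gene pairs it created; with Ks assumed normal around the event, the peak
is fitted by nonlinear least squares of a Gaussian sum to the binned density.
Because lineages evolve at different speeds, the shared-triplication (ECH)
peak differs between species even though the event is the same.  Taking the
slowest lineage G (smallest ECH peak) as the standard, each lineage i gets

    r_i = (mu_i - mu_G) / mu_G,        lambda_i = 1 / (1 + r_i),

so the corrected distribution lambda_i * X_i has its ECH peak exactly at
mu_G.  For a cross-species pair (i, j) the correction coefficient is the
arithmetic mean lambda_ij = (lambda_i + lambda_j) / 2; when one member is
the standard itself, lambda_i alone applies.  Corrected event peaks are
converted to absolute ages by scaling the ECH calibration window linearly:
T = calibration * mu_event / mu_ECH.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize

__all__ = [
    "KsPeak",
    "RateCorrection",
    "DateEstimate",
    "fit_ks_peaks",
    "rate_correction",
    "date_event",
    "PeakFitError",
]


class PeakFitError(RuntimeError):
    """Raised when the Gaussian fit cannot be performed or does not converge."""


@dataclass
class KsPeak:
    mu: float
    sigma: float
    amplitude: float
    r_squared: float
    sse: float
    rmse: float
    source: str = ""


@dataclass
class RateCorrection:
    """Per-lineage rate factors relative to the slowest lineage."""

    reference: str
    mu: dict[str, float]
    r: dict[str, float]  # relative rate excess (mu_i - mu_G)/mu_G
    lam: dict[str, float]  # correction coefficient 1/(1+r)

    def lambda_pair(self, i: str, j: str) -> float:
        """Correction coefficient for a cross-species Ks distribution."""
        if i == self.reference:
            return self.lam[j]
        if j == self.reference:
            return self.lam[i]
        return 0.5 * (self.lam[i] + self.lam[j])

    def corrected_mu(self, species: str) -> float:
        return self.lam[species] * self.mu[species]


@dataclass
class DateEstimate:
    event: str
    corrected_mu: float
    calibration: tuple[float, float]
    t_low: float
    t_high: float


def fit_ks_peaks(
    ks_values: Sequence[float],
    n_components: int = 1,
    ks_range: tuple[float, float] = (0.005, 3.0),
    bin_width: float = 0.05,
    source: str = "",
) -> list[KsPeak]:
    """Fit a sum of Gaussians to the binned Ks density.

    Values outside ``ks_range`` (a saturation guard) and non-finite values
    are discarded; the rest are binned at ``bin_width`` and the density
    fitted by least squares.  Peaks come back sorted by mu.  Fewer than 100
    usable values triggers a warning; zero spread raises
    :class:`PeakFitError`.
    """
    vals = np.asarray(ks_values, dtype=float)
    vals = vals[np.isfinite(vals)]
    vals = vals[(vals >= ks_range[0]) & (vals <= ks_range[1])]
    if len(vals) < 100:
        import warnings

        warnings.warn(f"only {len(vals)} Ks values in range; peak fit is unstable",
                      stacklevel=2)
    if len(vals) < max(4, 3 * n_components):
        raise PeakFitError(f"too few Ks values ({len(vals)}) for {n_components} peaks")
    if np.ptp(vals) == 0:
        raise PeakFitError("zero variance in Ks values")

    edges = np.arange(ks_range[0], ks_range[1] + bin_width, bin_width)
    density, edges = np.histogram(vals, bins=edges, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])

    # initial guesses: split data into quantile slabs, one per component
    qs = np.quantile(vals, np.linspace(0, 1, n_components + 1))
    p0 = []
    lower, upper = [], []
    for c in range(n_components):
        sel = vals[(vals >= qs[c]) & (vals <= qs[c + 1])]
        mu0 = float(np.mean(sel)) if len(sel) else float(np.mean(vals))
        sig0 = float(np.std(sel)) if len(sel) > 1 and np.std(sel) > 0 else 0.1
        amp0 = float(density.max())
        p0 += [amp0, mu0, sig0]
        lower += [0.0, ks_range[0], bin_width / 10.0]
        upper += [np.inf, ks_range[1], ks_range[1]]

    def model(x, *params):
        y = np.zeros_like(x)
        for c in range(n_components):
            a, m, s = params[3 * c : 3 * c + 3]
            y = y + a * np.exp(-0.5 * ((x - m) / s) ** 2)
        return y

    try:
        popt, _ = optimize.curve_fit(
            model, centers, density, p0=p0, bounds=(lower, upper), maxfev=20000
        )
    except (RuntimeError, ValueError) as exc:
        raise PeakFitError(f"Gaussian fit failed: {exc}") from exc

    resid = density - model(centers, *popt)
    sse = float(np.sum(resid**2))
    sst = float(np.sum((density - density.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else float("nan")
    rmse = float(np.sqrt(sse / max(len(centers) - 3 * n_components, 1)))
    peaks = [
        KsPeak(
            mu=float(popt[3 * c + 1]),
            sigma=abs(float(popt[3 * c + 2])),
            amplitude=float(popt[3 * c]),
            r_squared=r2,
            sse=sse,
            rmse=rmse,
            source=source,
        )
        for c in range(n_components)
    ]
    peaks.sort(key=lambda p: p.mu)
    return peaks


def rate_correction(ech_peaks_per_species: Mapping[str, float]) -> RateCorrection:
    """Compute per-lineage rate factors from the shared-event Ks peaks.

    The species with the smallest peak is the standard (slowest lineage);
    for it r = 0 and lambda = 1.  Requires at least two species with
    positive peaks.
    """
    if len(ech_peaks_per_species) < 2:
        raise ValueError("need ECH peaks for at least two species")
    for sp, mu in ech_peaks_per_species.items():
        if not (mu > 0) or math.isnan(mu):
            raise ValueError(f"non-positive ECH peak for {sp!r}: {mu}")
    reference = min(ech_peaks_per_species, key=lambda sp: ech_peaks_per_species[sp])
    mu_g = ech_peaks_per_species[reference]
    r = {sp: (mu - mu_g) / mu_g for sp, mu in ech_peaks_per_species.items()}
    lam = {sp: 1.0 / (1.0 + ri) for sp, ri in r.items()}
    return RateCorrection(
        reference=reference, mu=dict(ech_peaks_per_species), r=r, lam=lam
    )


def date_event(
    event_peak_corrected_mu: float,
    ech_mu: float,
    ech_calibration: tuple[float, float] = (115.0, 130.0),
    event: str = "",
) -> DateEstimate:
    """Date an event by linear scaling against the ECH calibration window."""
    if not (event_peak_corrected_mu > 0 and ech_mu > 0):
        raise ValueError("peak values must be positive")
    lo, hi = sorted(ech_calibration)
    ratio = event_peak_corrected_mu / ech_mu
    return DateEstimate(
        event=event,
        corrected_mu=event_peak_corrected_mu,
        calibration=(lo, hi),
        t_low=lo * ratio,
        t_high=hi * ratio,
    )
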