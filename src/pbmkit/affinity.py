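"""Equilibrium affinity estimation and cross-validation against PBM values.

Titrations of equilibrium response versus protein concentration (SPR-style,
in resonance units) are fitted with the Langmuir isotherm

    R(C) = Rmax * C / (Kd + C)

yielding the apparent dissociation constant Kd (nM) and saturation response
Rmax.  Kinetic on/off-rate modelling is deliberately absent: on high-density
surfaces off-rates may be undetectably slow, so only the equilibrium plateau
is informative.  Relative affinities (1/Kd scaled to the set maximum) are
then regressed against PBM binding values to check that the microarray
reproduces the affinity ranking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .errors import ContractError, NonIdentifiableError

__all__ = [
    "TitrationSeries",
    "EquilibriumBindingModel",
    "AffinityPair",
    "fit_langmuir",
    "relative_affinities",
    "correlate_pbm_affinity",
    "bootstrap_kd_ci",
]


@dataclass
class TitrationSeries:
    """Paired concentration (nM) / equilibrium response (RU) measurements."""

    sequence_id: str
    concentrations: np.ndarray
    responses: np.ndarray

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.concentrations.shape != self.responses.shape:
            raise ContractError("concentrations and responses must be paired")
        if self.concentrations.size < 4:
            raise ContractError("a titration needs at least 4 points")
        if (self.concentrations < 0).any():
            raise ContractError("concentrations must be non-negative")
        if np.unique(self.concentrations).size < 3:
            raise ContractError("a titration needs at least 3 distinct concentrations")


@dataclass(frozen=True)
class EquilibriumBindingModel:
    """Fitted Langmuir isotherm: R(C) = rmax * C / (kd + C)."""

    sequence_id: str
    kd: float
    rmax: float
    residual_norm: float

    def predict(self, concentrations: np.ndarray) -> np.ndarray:
        c = np.asarray(concentrations, dtype=float)
        return self.rmax * c / (self.kd + c)


@dataclass(frozen=True)
class AffinityPair:
    """One sequence's relative affinity (1/Kd, scaled to (0, 1]) and PBM value."""

    sequence_id: str
    relative_affinity: float
    pbm_value: float


def fit_langmuir(series: TitrationSeries) -> EquilibriumBindingModel:
    """Least-squares Langmuir fit of one titration.

    Initialization: rmax0 = max response, kd0 = concentration nearest the
    half-maximal response.  The fit is declared non-identifiable when the
    responses carry no signal or no curvature over the measured range (a Kd
    far above the highest concentration is indistinguishable from a straight
    line through the origin).
    """
    c = series.concentrations
    r = series.responses
    if np.all(r <= 0) or np.isclose(r.max(), 0.0):
        raise NonIdentifiableError(
            f"titration '{series.sequence_id}': responses carry no signal"
        )
    rmax0 = float(r.max())
    positive = c > 0
    kd0 = float(c[positive][np.argmin(np.abs(r[positive] - rmax0 / 2.0))])
    kd0 = max(kd0, 1e-9)

    def residuals(theta: np.ndarray) -> np.ndarray:
        kd, rmax = theta
        return rmax * c / (kd + c) - r

    result = optimize.least_squares(
        residuals,
        x0=[kd0, rmax0],
        bounds=([1e-12, 1e-12], [np.inf, np.inf]),
        xtol=1e-12,
        ftol=1e-12,
        gtol=1e-12,
    )
    kd, rmax = map(float, result.x)
    if kd > 1e4 * c.max():
        raise NonIdentifiableError(
            f"titration '{series.sequence_id}': no curvature over the measured "
            f"concentration range (fitted Kd {kd:.3g} nM)"
        )
    return EquilibriumBindingModel(
        sequence_id=series.sequence_id,
        kd=kd,
        rmax=rmax,
        residual_norm=float(np.linalg.norm(result.fun)),
    )


def relative_affinities(models: list[EquilibriumBindingModel]) -> list[AffinityPair]:
    """Relative affinity 1/Kd per model, normalized so the maximum maps to 1.

    The returned pairs carry NaN PBM values; fill them before correlating.
    """
    if not models:
        raise ContractError("no models to normalize")
    inv = np.array([1.0 / m.kd for m in models])
    rel = inv / inv.max()
    return [
        AffinityPair(sequence_id=m.sequence_id, relative_affinity=float(a), pbm_value=np.nan)
        for m, a in zip(models, rel)
    ]


def correlate_pbm_affinity(pairs: list[AffinityPair]) -> tuple[float, float, float]:
    """OLS regression of PBM value on relative affinity.

    Returns (slope, intercept, Pearson r).  Mirrors the cross-validation of
    microarray binding values against independently measured affinities.
    """
    if len(pairs) < 3:
        raise ContractError("correlation needs at least 3 pairs")
    x = np.array([p.relative_affinity for p in pairs])
    y = np.array([p.pbm_value for p in pairs])
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        raise ContractError("zero variance in affinities or PBM values")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue)


def bootstrap_kd_ci(
    series: TitrationSeries,
    n_resamples: int = 200,
    seed: int = 0,
    level: float = 0.95,
) -> tuple[float, float]:
    """Percentile bootstrap confidence interval for Kd (resampling points)."""
    rng = np.random.default_rng(seed)
    n = series.concentrations.size
    kds = []
    for _ in range(n_resamples):
        idx = rng.integers(0, n, size=n)
        if np.unique(series.concentrations[idx]).size < 3:
            continue
        try:
            resampled = TitrationSeries(
                series.sequence_id,
                series.concentrations[idx],
                series.responses[idx],
            )
            kds.append(fit_langmuir(resampled).kd)
        except (ContractError, NonIdentifiableError):
            continue
    if len(kds) < max(10, n_resamples // 4):
        raise NonIdentifiableError("too few successful bootstrap fits for a CI")
    lo, hi = np.quantile(kds, [(1 - level) / 2, 1 - (1 - level) / 2])
    return float(lo), float(hi)
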