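"""Reliability and dimensionality statistics of a polytomous response matrix.

The dimension coefficient (DC) summarizes first-eigenvalue dominance of the
inter-item Pearson correlation matrix.  The default ``gap`` form is the
contrast between the two leading eigenvalues measured in excess of the third,

    DC = (l1 - l2) / (l1 + l2 - 2*l3),

where l3 benchmarks the noise level: in a design with at most two latent
traits every eigenvalue beyond the second is attributable to sampling noise,
so l3 is the noise ceiling.  DC is 1 when the second eigenvalue is
indistinguishable from noise (one dimension) and 0 when the two leading
eigenvalues are equal (two balanced dimensions).  Under a two-block
structure with between-block correlation rho and blocks of relative size
p/(1-p), the population value is sqrt((1-2p)^2 + 4p(1-p)rho^2); for equal
blocks that is rho itself, so DC reads as an estimate of the interrelation
between the two strongest dimensions and a cutoff of 0.70 mirrors the
"interrelation >= 0.7 is one dimension" convention.

The ``share`` form l1/(l1+l2) (first eigenvalue's share of the top two,
range [0.5, 1]) is kept as an alternative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DegenerateDataError",
    "EigenSpectrum",
    "ReliabilityReport",
    "cronbach_alpha",
    "eigen_spectrum",
    "dimension_coefficient",
    "composite_reliability",
    "reliability_report",
]


class DegenerateDataError(ValueError):
    """A statistic is undefined on this input (e.g. zero variance)."""


def _as_matrix(responses) -> np.ndarray:
    values = getattr(responses, "values", responses)
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise ValueError("responses must be a 2-d persons x items matrix")
    return values


@dataclass(frozen=True)
class EigenSpectrum:
    """Descending eigenvalues of the inter-item Pearson correlation matrix."""

    eigenvalues: np.ndarray
    n_items: int
    n_persons: int

    def __post_init__(self) -> None:
        ev = np.asarray(self.eigenvalues, dtype=float)
        if ev.ndim != 1 or ev.shape[0] != self.n_items:
            raise ValueError("one eigenvalue per item is required")


@dataclass(frozen=True)
class ReliabilityReport:
    alpha: float
    dc: float
    n_persons: int
    n_items: int
    cr: float | None = None


def cronbach_alpha(responses) -> float:
    """Cronbach's alpha, ``k/(k-1) * (1 - sum(var_i)/var_total)``.

    Sample variances use the n-1 denominator.  Raises
    :class:`DegenerateDataError` when the total score has zero variance.
    """
    values = _as_matrix(responses)
    n, k = values.shape
    if k < 2 or n < 2:
        raise ValueError("alpha requires at least 2 items and 2 persons")
    total_var = values.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise DegenerateDataError("total score has zero variance; alpha undefined")
    item_var = values.var(axis=0, ddof=1).sum()
    return float(k / (k - 1) * (1.0 - item_var / total_var))


def eigen_spectrum(responses) -> EigenSpectrum:
    """Eigenvalues of the item x item Pearson correlation matrix, descending.

    Raises :class:`DegenerateDataError` naming any constant item column.
    """
    values = _as_matrix(responses)
    n, k = values.shape
    if k < 2 or n < 2:
        raise ValueError("eigen spectrum requires at least 2 items and 2 persons")
    variances = values.var(axis=0)
    if np.any(variances == 0):
        bad = [f"item{j + 1}" for j in np.flatnonzero(variances == 0)]
        raise DegenerateDataError(
            f"constant item column(s): {', '.join(bad)}; correlations undefined"
        )
    corr = np.corrcoef(values, rowvar=False)
    eigenvalues = np.sort(np.linalg.eigvalsh(corr))[::-1]
    eigenvalues = np.clip(eigenvalues, 0.0, None)  # PSD up to round-off
    return EigenSpectrum(eigenvalues=eigenvalues, n_items=k, n_persons=n)


def dimension_coefficient(spectrum: EigenSpectrum, method: str = "gap") -> float:
    """Dimension coefficient from an eigenvalue spectrum.

    ``method="gap"`` (default): ``(l1-l2)/(l1+l2-2*l3)``, range [0, 1]; for
    two-item scales l3 is taken as 0.  ``method="share"``: ``l1/(l1+l2)``,
    range [0.5, 1].
    """
    ev = np.asarray(spectrum.eigenvalues, dtype=float)
    if ev.shape[0] < 2:
        raise ValueError("at least 2 eigenvalues are required")
    l1, l2 = float(ev[0]), float(ev[1])
    if method == "share":
        if l1 + l2 <= 0:
            raise DegenerateDataError("l1 + l2 = 0; dimension coefficient undefined")
        return l1 / (l1 + l2)
    if method == "gap":
        l3 = float(ev[2]) if ev.shape[0] > 2 else 0.0
        denom = l1 + l2 - 2.0 * l3
        if denom <= 0:
            # l1 = l2 = l3: no structure above the noise floor at all.
            return 0.0
        return max(0.0, (l1 - l2) / denom)
    raise ValueError(f"unknown method {method!r}; use 'gap' or 'share'")


def composite_reliability(loadings) -> float:
    """Composite reliability ``(sum l_i)^2 / ((sum l_i)^2 + sum e_i)``.

    ``l_i`` are standardized factor loadings in [-1, 1] and
    ``e_i = 1 - l_i^2`` the error variances.
    """
    lam = np.asarray(loadings, dtype=float)
    if lam.size == 0:
        raise ValueError("at least one loading is required")
    if np.any(np.abs(lam) > 1):
        raise ValueError("standardized loadings must lie in [-1, 1]")
    num = lam.sum() ** 2
    eps = (1.0 - lam**2).sum()
    if num + eps == 0:
        return 1.0  # all |loadings| = 1 with zero error
    return float(num / (num + eps))


def reliability_report(responses, dc_method: str = "gap") -> ReliabilityReport:
    """Alpha and DC of one response matrix, computed from the same pass."""
    spectrum = eigen_spectrum(responses)
    return ReliabilityReport(
        alpha=cronbach_alpha(responses),
        dc=dimension_coefficient(spectrum, method=dc_method),
        n_persons=spectrum.n_persons,
        n_items=spectrum.n_items,
    )
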