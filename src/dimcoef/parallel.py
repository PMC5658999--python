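"""Horn's parallel analysis against random-data eigenvalue references.

Observed eigenvalues are compared component-wise with eigenvalues obtained
from uncorrelated standard-normal data of the same persons x items shape.
Two reference rules are provided: the component-wise 95th percentile across
replicates, and the eigenvalues of a single ("individual") random dataset.
Counting stops at the first component that fails to exceed its reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .psychometrics import EigenSpectrum

__all__ = ["PAResult", "random_eigen_reference", "pa_decision", "parallel_analysis"]

METHODS = ("percentile95", "individual", "mean")


@dataclass(frozen=True)
class PAResult:
    observed: EigenSpectrum
    reference: np.ndarray
    n_replicates: int
    method: str
    n_retained: int


def _random_spectra(
    n_persons: int,
    n_items: int,
    n_replicates: int,
    rng: np.random.Generator,
    discretize: bool,
) -> np.ndarray:
    spectra = np.empty((n_replicates, n_items))
    for r in range(n_replicates):
        data = rng.standard_normal((n_persons, n_items))
        if discretize:
            # map to 5 roughly equiprobable ordered categories
            data = np.clip(np.floor((data + 2.5) / 1.0), 0, 4)
        corr = np.corrcoef(data, rowvar=False)
        spectra[r] = np.sort(np.linalg.eigvalsh(corr))[::-1]
    return np.clip(spectra, 0.0, None)


def random_eigen_reference(
    n_persons: int,
    n_items: int,
    n_replicates: int = 100,
    method: str = "percentile95",
    seed: int | np.random.Generator | None = None,
    discretize: bool = False,
) -> np.ndarray:
    """Reference eigenvalues from uncorrelated normal data.

    ``percentile95``: component-wise 95th percentile across replicates.
    ``individual``: eigenvalues of a single random dataset (uses exactly one
    replicate).  ``mean``: component-wise mean across replicates (offered as
    an alternative reading of the individual rule).  ``n_items > n_persons``
    is permitted; rank deficiency yields trailing zero eigenvalues.
    """
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}, got {method!r}")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    if method == "individual":
        return _random_spectra(n_persons, n_items, 1, rng, discretize)[0]
    spectra = _random_spectra(n_persons, n_items, n_replicates, rng, discretize)
    if method == "percentile95":
        return np.percentile(spectra, 95, axis=0)
    return spectra.mean(axis=0)


def pa_decision(
    observed: EigenSpectrum,
    reference: np.ndarray,
    method: str = "percentile95",
    n_replicates: int = 0,
) -> PAResult:
    """Retained-factor count: leading components whose observed eigenvalue
    strictly exceeds its reference; counting stops at the first failure."""
    obs = np.asarray(observed.eigenvalues, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if obs.shape != ref.shape:
        raise ValueError(
            f"observed ({obs.shape[0]}) and reference ({ref.shape[0]}) lengths differ"
        )
    n_retained = 0
    for o, r in zip(obs, ref):
        if o > r:
            n_retained += 1
        else:
            break
    return PAResult(
        observed=observed,
        reference=ref,
        n_replicates=n_replicates,
        method=method,
        n_retained=n_retained,
    )


def parallel_analysis(
    observed: EigenSpectrum,
    n_replicates: int = 100,
    method: str = "percentile95",
    seed: int | np.random.Generator | None = None,
) -> PAResult:
    """Convenience wrapper: build the reference and take the decision."""
    reference = random_eigen_reference(
        observed.n_persons,
        observed.n_items,
        n_replicates=n_replicates,
        method=method,
        seed=seed,
    )
    used = 1 if method == "individual" else n_replicates
    return pa_decision(observed, reference, method=method, n_replicates=used)
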