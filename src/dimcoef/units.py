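"""Per-unit, per-domain survey validity report.

Given a wide-format survey table (one row per respondent, a unit-identifier
column, 1-5 Likert item columns grouped into named domains), computes
Cronbach's alpha and the dimension coefficient for every (unit, domain)
pair.  Units with fewer than ``min_n`` respondents after listwise deletion
within the domain are flagged and skipped; zero-variance (degenerate)
domains are flagged rather than patched - a low or incomputable DC/alpha is
treated as a data-quality signal.

A synthetic multi-unit survey generator is included: a configurable
fraction of units ("contaminated") answer each domain from two weakly
correlated traits, the rest from a single trait.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .psychometrics import (
    DegenerateDataError,
    cronbach_alpha,
    dimension_coefficient,
    eigen_spectrum,
)
from .rsm import build_item_bank, draw_traits, simulate_responses

__all__ = ["unit_report", "fixture_survey_generator"]

REPORT_COLUMNS = ["unit_id", "domain", "n_respondents", "alpha", "dc", "status"]


def _validate_domain_map(survey: pd.DataFrame, domain_map: dict[str, list[str]]) -> None:
    if not domain_map:
        raise ValueError("domain_map must not be empty")
    missing = [
        col for items in domain_map.values() for col in items
        if col not in survey.columns
    ]
    if missing:
        raise KeyError(f"domain_map names unknown item column(s): {missing}")


def unit_report(
    survey: pd.DataFrame,
    domain_map: dict[str, list[str]],
    unit_col: str = "unit_id",
    min_n: int = 10,
    dc_method: str = "gap",
) -> pd.DataFrame:
    """One row per (unit, domain) with alpha, DC and a status flag.

    Responses coded 1-5 are mapped to the internal 0-4 convention;
    respondents with any missing item in a domain are dropped from that
    domain's computation (listwise deletion within the domain).
    """
    if min_n < 2:
        raise ValueError("min_n must be >= 2")
    if unit_col not in survey.columns:
        raise KeyError(f"unit column {unit_col!r} not found")
    _validate_domain_map(survey, domain_map)

    rows = []
    for unit, unit_frame in survey.groupby(unit_col, sort=True):
        for domain, items in domain_map.items():
            block = unit_frame[items].dropna().to_numpy(dtype=float)
            if block.size and block.min() >= 1 and block.max() <= 5:
                block = block - 1  # 1-5 Likert coding -> internal 0-4
            n = block.shape[0]
            row = {
                "unit_id": unit,
                "domain": domain,
                "n_respondents": n,
                "alpha": np.nan,
                "dc": np.nan,
                "status": "ok",
            }
            if n < min_n:
                row["status"] = "below_min_n"
            else:
                try:
                    row["alpha"] = cronbach_alpha(block)
                    row["dc"] = dimension_coefficient(
                        eigen_spectrum(block), method=dc_method
                    )
                except DegenerateDataError:
                    row["status"] = "degenerate"
                    row["alpha"] = np.nan
                    row["dc"] = np.nan
            rows.append(row)
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


def fixture_survey_generator(
    n_units: int,
    unit_size_range: tuple[int, int] = (5, 60),
    domain_spec: dict[str, int] | None = None,
    contamination: float = 0.3,
    contaminated_correlation: float = 0.3,
    seed: int | None = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Generate a synthetic multi-unit survey and the planted unit labels.

    Every unit answers each domain under the rating scale model; in clean
    units the domain is driven by a single trait (trait correlation 1), in
    contaminated units by two traits at ``contaminated_correlation``.  Unit
    sizes are drawn uniformly from ``unit_size_range`` (which may include
    sizes below a report's ``min_n``).  Returns the wide survey table with
    1-5 coded items and a boolean per-unit contamination Series.
    """
    if n_units < 1:
        raise ValueError("n_units must be >= 1")
    if not 0.0 <= contamination <= 1.0:
        raise ValueError("contamination fraction must be in [0, 1]")
    lo, hi = unit_size_range
    if not 2 <= lo <= hi:
        raise ValueError("unit_size_range must satisfy 2 <= lo <= hi")
    if domain_spec is None:
        domain_spec = {f"D{d + 1}": 6 for d in range(4)}

    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    n_bad = int(round(contamination * n_units))
    contaminated = np.zeros(n_units, dtype=bool)
    contaminated[rng.choice(n_units, size=n_bad, replace=False)] = True

    frames = []
    for u in range(n_units):
        size = int(rng.integers(lo, hi + 1))
        unit_cols = {"unit_id": np.repeat(f"unit{u + 1:03d}", size)}
        rho = contaminated_correlation if contaminated[u] else 1.0
        for domain, k in domain_spec.items():
            traits = draw_traits(size, rho, rng)
            bank = build_item_bank(k)
            block = simulate_responses(traits, bank, rng).values + 1  # 1-5 coding
            for j in range(k):
                unit_cols[f"{domain}_item{j + 1}"] = block[:, j]
        frames.append(pd.DataFrame(unit_cols))
    survey = pd.concat(frames, ignore_index=True)
    labels = pd.Series(
        contaminated, index=[f"unit{u + 1:03d}" for u in range(n_units)],
        name="contaminated",
    )
    return survey, labels


def domain_map_from_spec(domain_spec: dict[str, int]) -> dict[str, list[str]]:
    """Domain map matching :func:`fixture_survey_generator`'s column names."""
    return {
        d: [f"{d}_item{j + 1}" for j in range(k)] for d, k in domain_spec.items()
    }
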