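"""Orchestration of the full simulation experiment.

The default configuration is the study grid: trait correlations
{0.3, 0.5, 0.7, 0.9, 1.0} x item lengths 5..100 step 5 x sample sizes
50..1000 step 50 = 2000 scenarios.  For each cell the dataset is simulated,
alpha and DC are computed, both parallel-analysis variants are applied, and
all classification rules are recorded as one row.

Random-eigenvalue references depend only on the persons x items shape, so
one reference table per shape is computed and shared by the five
correlation strata (as a per-shape lookup table would be).  All randomness
derives from one master seed via named seed-sequence streams, so any cell
is reproducible in isolation.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .evaluation import ConfusionTable, ROCResult, confusion, youden_cutoff
from .parallel import pa_decision, random_eigen_reference
from .psychometrics import (
    DegenerateDataError,
    cronbach_alpha,
    dimension_coefficient,
    eigen_spectrum,
)
from .rsm import DEFAULT_THRESHOLDS, SimulationScenario, simulate_scenario
from .rules import (
    DC_CUTOFF,
    classify_combined,
    classify_dc,
    classify_pa,
    truth_label,
)

__all__ = ["GridConfig", "GridSummary", "run_grid", "summarize", "RESULT_COLUMNS"]

logger = logging.getLogger("dimcoef.grid")

DEFAULT_CORRELATIONS = (0.3, 0.5, 0.7, 0.9, 1.0)
DEFAULT_ITEM_LENGTHS = tuple(range(5, 101, 5))
DEFAULT_SAMPLE_SIZES = tuple(range(50, 1001, 50))

# Fixed column order of the results table, for downstream diffing.
RESULT_COLUMNS = [
    "trait_correlation",
    "n_items",
    "n_persons",
    "seed",
    "alpha",
    "dc",
    "pa95_retained",
    "pa_individual_retained",
    "pa95_label",
    "pa_individual_label",
    "dc_label",
    "combined_label",
    "truth_label",
    "status",
]

# Stream tags for deterministic seed expansion from the master seed.
_SCENARIO_STREAM = 1
_PA_STREAM = 2


@dataclass(frozen=True)
class GridConfig:
    correlations: tuple[float, ...] = DEFAULT_CORRELATIONS
    item_lengths: tuple[int, ...] = DEFAULT_ITEM_LENGTHS
    sample_sizes: tuple[int, ...] = DEFAULT_SAMPLE_SIZES
    master_seed: int = 0
    pa_replicates: int = 100
    dc_method: str = "gap"
    dc_cutoff: float = DC_CUTOFF
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    random_uniform_difficulties: bool = False

    @property
    def n_scenarios(self) -> int:
        return len(self.correlations) * len(self.item_lengths) * len(self.sample_sizes)


@dataclass(frozen=True)
class GridSummary:
    """The four ROC analyses plus the DC-vs-truth confusion at the cutoff."""

    dc_vs_truth: ROCResult
    dc_vs_pa95: ROCResult | None
    dc_vs_pa_individual: ROCResult | None
    dc_vs_combined: ROCResult | None
    confusion_dc_truth: ConfusionTable
    quadrant_percent: dict[str, float] = field(default_factory=dict)


def _scenario_seed(master_seed: int, index: int) -> int:
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(_SCENARIO_STREAM, index))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def _pa_rng(master_seed: int, n_persons: int, n_items: int, variant: int):
    ss = np.random.SeedSequence(
        entropy=master_seed, spawn_key=(_PA_STREAM, n_persons, n_items, variant)
    )
    return np.random.default_rng(ss)


def run_grid(config: GridConfig = GridConfig()) -> pd.DataFrame:
    """Run every grid cell and return the per-dataset results table.

    Degenerate cells (e.g. a constant item at extreme difficulty in a tiny
    sample) are flagged in ``status`` and retained as rows with NaN
    statistics rather than resampled, keeping the row-count contract.
    """
    references: dict[tuple[int, int, str], np.ndarray] = {}
    for n in config.sample_sizes:
        for k in config.item_lengths:
            references[(n, k, "percentile95")] = random_eigen_reference(
                n, k, config.pa_replicates, "percentile95",
                seed=_pa_rng(config.master_seed, n, k, 0),
            )
            references[(n, k, "individual")] = random_eigen_reference(
                n, k, 1, "individual", seed=_pa_rng(config.master_seed, n, k, 1),
            )

    rows = []
    index = 0
    t0 = time.perf_counter()
    for rho in config.correlations:
        for k in config.item_lengths:
            for n in config.sample_sizes:
                seed = _scenario_seed(config.master_seed, index)
                scenario = SimulationScenario(rho, k, n, seed)
                t_cell = time.perf_counter()
                row = {
                    "trait_correlation": rho,
                    "n_items": k,
                    "n_persons": n,
                    "seed": seed,
                    "truth_label": truth_label(rho).label,
                    "status": "ok",
                }
                try:
                    responses = simulate_scenario(
                        scenario,
                        thresholds=config.thresholds,
                        random_uniform_difficulties=config.random_uniform_difficulties,
                    )
                    spectrum = eigen_spectrum(responses)
                    dc = dimension_coefficient(spectrum, method=config.dc_method)
                    pa95 = pa_decision(
                        spectrum, references[(n, k, "percentile95")],
                        method="percentile95", n_replicates=config.pa_replicates,
                    )
                    pa_ind = pa_decision(
                        spectrum, references[(n, k, "individual")],
                        method="individual", n_replicates=1,
                    )
                    pa95_label = classify_pa(pa95).label
                    row.update(
                        alpha=cronbach_alpha(responses),
                        dc=dc,
                        pa95_retained=pa95.n_retained,
                        pa_individual_retained=pa_ind.n_retained,
                        pa95_label=pa95_label,
                        pa_individual_label=classify_pa(pa_ind).label,
                        dc_label=classify_dc(dc, config.dc_cutoff).label,
                        combined_label=classify_combined(
                            pa95_label, dc, config.dc_cutoff
                        ).label,
                    )
                except DegenerateDataError as exc:
                    logger.warning("scenario %s failed: %s", scenario, exc)
                    row["status"] = "degenerate"
                logger.debug(
                    "cell rho=%.1f k=%d n=%d done in %.3fs",
                    rho, k, n, time.perf_counter() - t_cell,
                )
                rows.append(row)
                index += 1
    logger.info(
        "grid of %d scenarios finished in %.1fs",
        index, time.perf_counter() - t0,
    )
    table = pd.DataFrame(rows)
    for col in RESULT_COLUMNS:
        if col not in table.columns:
            table[col] = np.nan
    return table[RESULT_COLUMNS]


def _roc_or_none(scores, labels, source: str) -> ROCResult | None:
    labels = np.asarray(labels, dtype=int)
    if labels.min() == labels.max():
        logger.warning("reference %s has a single class; ROC unavailable", source)
        return None
    return youden_cutoff(scores, labels, reference_source=source)


def summarize(rows: pd.DataFrame, dc_cutoff: float = DC_CUTOFF) -> GridSummary:
    """The four ROC analyses and the DC-vs-truth quadrants of a grid run."""
    ok = rows[rows["status"] == "ok"]
    if ok.empty:
        raise ValueError("no successful rows to summarize")
    dc = ok["dc"].to_numpy(dtype=float)
    truth = ok["truth_label"].to_numpy(dtype=int)
    if truth.min() == truth.max():
        raise ValueError("truth reference has a single class")

    dc_vs_truth = youden_cutoff(dc, truth, reference_source="truth")
    table = confusion((dc >= dc_cutoff).astype(int), truth)
    n = table.total
    quadrants = {
        "tp_percent": 100.0 * table.tp / n,
        "tn_percent": 100.0 * table.tn / n,
        "fp_percent": 100.0 * table.fp / n,
        "fn_percent": 100.0 * table.fn / n,
    }
    return GridSummary(
        dc_vs_truth=dc_vs_truth,
        dc_vs_pa95=_roc_or_none(dc, ok["pa95_label"], "pa95"),
        dc_vs_pa_individual=_roc_or_none(
            dc, ok["pa_individual_label"], "pa_individual"
        ),
        dc_vs_combined=_roc_or_none(dc, ok["combined_label"], "combined"),
        confusion_dc_truth=table,
        quadrant_percent=quadrants,
    )
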