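"""Rasch rating-scale-model (RSM) simulator with two correlated latent traits.

Datasets are generated from a two-trait design: person abilities for the
second trait are a trigonometric rotation of the first
(``theta2 = theta1*cos(a) + z*sin(a)`` with ``a = arccos(rho)``), so the
population correlation of the traits is exactly ``rho``.  The first third of
the items load on trait A, the remaining two thirds on trait B; responses are
drawn from the rating scale model with a shared set of category thresholds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_THRESHOLDS",
    "SimulationScenario",
    "LatentTraits",
    "ItemBank",
    "ResponseMatrix",
    "draw_traits",
    "build_item_bank",
    "rsm_category_probs",
    "simulate_responses",
    "simulate_scenario",
    "write_responses_csv",
    "read_responses_csv",
]

#: Default category thresholds (logits), shared by all items: symmetric and
#: equally spaced so that all five categories are used across the +-2 logit
#: difficulty range.
DEFAULT_THRESHOLDS = (-1.5, -0.5, 0.5, 1.5)

#: Difficulty range (logits) of the item bank.
DIFFICULTY_RANGE = (-2.0, 2.0)

N_CATEGORIES = 5


@dataclass(frozen=True)
class SimulationScenario:
    """One cell of the simulation grid."""

    trait_correlation: float
    n_items: int
    n_persons: int
    seed: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.trait_correlation <= 1.0:
            raise ValueError(
                f"trait_correlation must be in [0, 1], got {self.trait_correlation}"
            )
        if self.n_items < 2:
            raise ValueError(f"n_items must be >= 2, got {self.n_items}")
        if self.n_persons < 2:
            raise ValueError(f"n_persons must be >= 2, got {self.n_persons}")


@dataclass(frozen=True)
class LatentTraits:
    """Person abilities (logits) for the two traits."""

    theta1: np.ndarray
    theta2: np.ndarray
    target_correlation: float
    angle_degrees: float

    def __post_init__(self) -> None:
        if self.theta1.shape != self.theta2.shape:
            raise ValueError("theta1 and theta2 must have the same length")

    @property
    def n_persons(self) -> int:
        return self.theta1.shape[0]


@dataclass(frozen=True)
class ItemBank:
    """Item difficulties, shared thresholds and the per-item trait labels."""

    difficulties: np.ndarray
    thresholds: np.ndarray
    trait_assignment: np.ndarray  # boolean, True -> trait A

    def __post_init__(self) -> None:
        if self.thresholds.shape[0] != N_CATEGORIES - 1:
            raise ValueError("exactly 4 thresholds are required for 5 categories")

    @property
    def n_items(self) -> int:
        return self.difficulties.shape[0]

    @property
    def n_trait_a(self) -> int:
        return int(self.trait_assignment.sum())


@dataclass(frozen=True)
class ResponseMatrix:
    """Persons x items integer responses in {0..4}."""

    values: np.ndarray
    scenario: SimulationScenario | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 2:
            raise ValueError("responses must be a 2-d persons x items array")
        if v.size and (v.min() < 0 or v.max() > N_CATEGORIES - 1):
            raise ValueError("responses must lie in the 5-category range 0..4")

    @property
    def n_persons(self) -> int:
        return self.values.shape[0]

    @property
    def n_items(self) -> int:
        return self.values.shape[1]


def draw_traits(
    n_persons: int,
    correlation: float,
    seed: int | np.random.Generator,
) -> LatentTraits:
    """Draw two standard-normal ability vectors with the target correlation.

    ``theta1`` is i.i.d. N(0, 1); ``theta2 = theta1*cos(a) + z*sin(a)`` with
    independent standard-normal ``z`` and ``a = arccos(correlation)``, so
    ``corr(theta1, theta2) = cos(a) = correlation`` in the population and the
    marginal of ``theta2`` stays standard normal.
    """
    if not 0.0 <= correlation <= 1.0:
        raise ValueError(f"correlation must be in [0, 1], got {correlation}")
    if n_persons < 2:
        raise ValueError(f"n_persons must be >= 2, got {n_persons}")
    rng = np.random.default_rng(seed)
    angle = float(np.arccos(correlation))
    theta1 = rng.standard_normal(n_persons)
    z = rng.standard_normal(n_persons)
    theta2 = theta1 * np.cos(angle) + z * np.sin(angle)
    return LatentTraits(
        theta1=theta1,
        theta2=theta2,
        target_correlation=float(correlation),
        angle_degrees=float(np.degrees(angle)),
    )


def n_trait_a_items(n_items: int) -> int:
    """Number of items assigned to trait A: floor(n_items/3), at least 1."""
    return max(1, n_items // 3)


def build_item_bank(
    n_items: int,
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
    random_uniform: bool = False,
    seed: int | np.random.Generator | None = None,
) -> ItemBank:
    """Build an item bank with difficulties spread across +-2 logits.

    By default difficulties sit on a deterministic evenly spaced grid over
    [-2, +2] (endpoints inclusive); ``random_uniform=True`` draws them
    i.i.d. uniform on the same interval instead.  The first
    ``floor(n_items/3)`` items (minimum 1) belong to trait A, the remainder
    to trait B.
    """
    if n_items < 2:
        raise ValueError(f"n_items must be >= 2, got {n_items}")
    lo, hi = DIFFICULTY_RANGE
    if random_uniform:
        rng = np.random.default_rng(seed)
        difficulties = rng.uniform(lo, hi, n_items)
    else:
        difficulties = np.linspace(lo, hi, n_items)
    assignment = np.zeros(n_items, dtype=bool)
    assignment[: n_trait_a_items(n_items)] = True
    return ItemBank(
        difficulties=difficulties,
        thresholds=np.asarray(thresholds, dtype=float),
        trait_assignment=assignment,
    )


def rsm_category_probs(
    theta: float | np.ndarray,
    delta: float | np.ndarray,
    thresholds: np.ndarray | tuple[float, ...] = DEFAULT_THRESHOLDS,
) -> np.ndarray:
    """Category probabilities of the rating scale model.

    ``P(X = x) \\propto exp(sum_{j<=x} (theta - delta - tau_j))`` with an
    empty sum for the bottom category.  Broadcasts over ``theta``/``delta``;
    the last axis of the result indexes the five categories and sums to 1.
    """
    tau = np.asarray(thresholds, dtype=float)
    if tau.shape[-1] != N_CATEGORIES - 1:
        raise ValueError("thresholds must have length 4")
    eta = np.asarray(theta, dtype=float) - np.asarray(delta, dtype=float)
    cum = np.cumsum(eta[..., None] - tau, axis=-1)
    logits = np.concatenate([np.zeros_like(eta[..., None]), cum], axis=-1)
    logits -= logits.max(axis=-1, keepdims=True)
    p = np.exp(logits)
    return p / p.sum(axis=-1, keepdims=True)


def simulate_responses(
    traits: LatentTraits,
    bank: ItemBank,
    seed: int | np.random.Generator,
) -> ResponseMatrix:
    """Draw the response matrix: trait-A items use theta1, the rest theta2."""
    rng = np.random.default_rng(seed)
    n, k = traits.n_persons, bank.n_items
    theta = np.where(
        bank.trait_assignment[None, :],
        traits.theta1[:, None],
        traits.theta2[:, None],
    )
    probs = rsm_category_probs(theta, bank.difficulties[None, :], bank.thresholds)
    u = rng.random((n, k, 1))
    values = (probs.cumsum(axis=-1) < u).sum(axis=-1).astype(np.int8)
    return ResponseMatrix(values=values)


def simulate_scenario(
    scenario: SimulationScenario,
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
    random_uniform_difficulties: bool = False,
) -> ResponseMatrix:
    """Simulate one grid cell end to end, reproducibly from its seed.

    The scenario seed is expanded into independent streams for trait draws,
    (optional) difficulty draws and response draws.
    """
    ss = np.random.SeedSequence(scenario.seed)
    trait_rng, bank_rng, resp_rng = (np.random.default_rng(s) for s in ss.spawn(3))
    traits = draw_traits(scenario.n_persons, scenario.trait_correlation, trait_rng)
    bank = build_item_bank(
        scenario.n_items,
        thresholds=thresholds,
        random_uniform=random_uniform_difficulties,
        seed=bank_rng,
    )
    responses = simulate_responses(traits, bank, resp_rng)
    return ResponseMatrix(values=responses.values, scenario=scenario)


def write_responses_csv(responses: ResponseMatrix, path: str | Path) -> None:
    """Write persons-as-rows CSV (item labels in the header) + JSON sidecar."""
    path = Path(path)
    k = responses.n_items
    frame = pd.DataFrame(responses.values, columns=[f"item{j + 1}" for j in range(k)])
    frame.to_csv(path, index=False)
    if responses.scenario is not None:
        sc = responses.scenario
        sidecar = {
            "trait_correlation": sc.trait_correlation,
            "n_items": sc.n_items,
            "n_persons": sc.n_persons,
            "seed": sc.seed,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_responses_csv(path: str | Path) -> ResponseMatrix:
    """Read a response CSV; accepts 0..4 or 1..5 coding (mapped down)."""
    frame = pd.read_csv(path)
    values = frame.to_numpy()
    if values.size and values.min() >= 1 and values.max() == N_CATEGORIES:
        values = values - 1
    scenario = None
    sidecar = Path(path).with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        scenario = SimulationScenario(**meta)
    return ResponseMatrix(values=values.astype(np.int8), scenario=scenario)
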