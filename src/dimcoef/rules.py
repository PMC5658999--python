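"""Binary one-factor classification rules.

Label 1 means "one factor", 0 means "many factors".  Ground truth calls a
two-trait dataset one-dimensional when the trait interrelation is at least
0.7; the DC rule uses the same inclusive 0.70 cutoff; the combined rule is
``IF(PA = 1, 1, IF(DC >= 0.7, 1, 0))`` - the logical OR of the PA and DC
calls.
"""

from __future__ import annotations

from dataclasses import dataclass

from .parallel import PAResult

__all__ = [
    "DC_CUTOFF",
    "TRUTH_CUTOFF",
    "DimensionCall",
    "truth_label",
    "classify_dc",
    "classify_pa",
    "classify_combined",
]

DC_CUTOFF = 0.70
TRUTH_CUTOFF = 0.70


@dataclass(frozen=True)
class DimensionCall:
    label: int  # 1 = one factor, 0 = many factors
    source: str  # truth | dc | pa95 | pa_individual | combined

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError("label must be binary")


def truth_label(trait_correlation: float) -> DimensionCall:
    """Ground truth: one-dimensional iff the interrelation is >= 0.7."""
    if not 0.0 <= trait_correlation <= 1.0:
        raise ValueError("trait correlation must be in [0, 1]")
    return DimensionCall(int(trait_correlation >= TRUTH_CUTOFF), "truth")


def classify_dc(dc: float, cutoff: float = DC_CUTOFF) -> DimensionCall:
    """DC rule: one factor iff DC >= cutoff (boundary inclusive)."""
    if not 0.0 <= dc <= 1.0:
        raise ValueError("dc must be in [0, 1]")
    return DimensionCall(int(dc >= cutoff), "dc")


def classify_pa(pa: PAResult) -> DimensionCall:
    """PA rule: one factor iff exactly one component is retained."""
    source = "pa95" if pa.method == "percentile95" else "pa_individual"
    return DimensionCall(int(pa.n_retained == 1), source)


def classify_combined(pa_label: int, dc: float, cutoff: float = DC_CUTOFF) -> DimensionCall:
    """Combined rule: 1 if PA says one factor, else fall back to the DC rule."""
    if pa_label not in (0, 1):
        raise ValueError("pa_label must be binary")
    label = 1 if pa_label == 1 else int(dc >= cutoff)
    return DimensionCall(label, "combined")
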