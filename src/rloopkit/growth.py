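"""Growth percentages, multiplicative epistasis and the cell-death index.

Two perturbations act independently on proliferation when the growth of the
combined condition equals the product of the single-condition growth
percentages: V = %growth_a x %growth_b / 100.  The observed/predicted ratio
is the rescue fold (values > 1 indicate a rescue, i.e. positive epistasis).
The death index normalizes a cytotoxicity fluorescence readout by the
relative growth of the same well population, expressed as fold change over
the untreated control (which is 1 by construction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "IndependencePrediction",
    "DeathIndex",
    "percent_growth",
    "predicted_independent_growth",
    "rescue_fold",
    "cell_death_index",
    "summarize_plate",
]


@dataclass(frozen=True)
class IndependencePrediction:
    pct_a: float
    pct_b: float
    v_predicted: float  # percent
    observed_combined: float | None = None

    @property
    def rescue_fold(self) -> float | None:
        if self.observed_combined is None:
            return None
        return rescue_fold(self.observed_combined, self.v_predicted)


@dataclass(frozen=True)
class DeathIndex:
    death_normalized: float  # cytotoxicity fluorescence per unit relative growth
    fold_vs_untreated: float


def percent_growth(count_condition: float, count_control: float) -> float:
    """Growth of a condition as percent of its matched control."""
    if count_control <= 0:
        raise ValueError("control count must be > 0")
    if count_condition < 0:
        raise ValueError("condition count must be >= 0")
    return 100.0 * count_condition / count_control


def predicted_independent_growth(pct_a: float, pct_b: float) -> IndependencePrediction:
    """Expected combined growth if the two perturbations act independently.

    V = pct_a * pct_b / 100, on the percent scale (symmetric in its
    arguments; V(100, x) = x).
    """
    if pct_a < 0 or pct_b < 0:
        raise ValueError("growth percentages must be >= 0")
    return IndependencePrediction(pct_a, pct_b, pct_a * pct_b / 100.0)


def rescue_fold(observed_combined: float, v_predicted: float) -> float:
    """Observed combined growth over the multiplicative prediction."""
    if v_predicted <= 0:
        raise ValueError("predicted growth must be > 0")
    if observed_combined < 0:
        raise ValueError("observed growth must be >= 0")
    return observed_combined / v_predicted


def cell_death_index(
    cytotox: float,
    relative_growth: float,
    untreated_cytotox: float,
    untreated_growth: float,
) -> DeathIndex:
    """Growth-normalized cell death, as fold over the untreated control.

    death = cytotox / relative_growth; fold = death / death_untreated.  The
    untreated control versus itself is exactly 1.  Invariant to global
    rescaling of the fluorescence units.
    """
    if relative_growth <= 0 or untreated_growth <= 0:
        raise ValueError("relative growth must be > 0")
    if cytotox < 0 or untreated_cytotox <= 0:
        raise ValueError("cytotoxicity readouts must be positive")
    death = cytotox / relative_growth
    death_ref = untreated_cytotox / untreated_growth
    return DeathIndex(death_normalized=death, fold_vs_untreated=death / death_ref)


def summarize_plate(plate: pd.DataFrame, control: str = "control") -> dict:
    """Per-condition mean growth (% of control) and the epistasis readout.

    Expects a long table with ``condition`` and ``growth_frac`` columns, as
    produced by the plate simulator, containing the conditions ``control``,
    ``condition_a``, ``condition_b`` and ``combined``.
    """
    means = plate.groupby("condition")["growth_frac"].mean()
    required = {control, "condition_a", "condition_b", "combined"}
    missing = required - set(means.index)
    if missing:
        raise ValueError(f"plate is missing conditions: {sorted(missing)}")
    ctrl = float(means[control])
    if ctrl <= 0:
        raise ValueError("mean control growth must be > 0")
    pct = {c: percent_growth(float(means[c]), ctrl) for c in means.index}
    pred = predicted_independent_growth(pct["condition_a"], pct["condition_b"])
    return {
        "pct_growth": pct,
        "v_predicted": pred.v_predicted,
        "observed_combined": pct["combined"],
        "rescue_fold": rescue_fold(pct["combined"], pred.v_predicted),
        "n_wells": int(len(plate)),
    }
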