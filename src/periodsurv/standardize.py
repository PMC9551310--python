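"""Age standardization of relative survival with ICSS-style weights.

Age-specific relative survival estimates are combined into a single figure
using a fixed reference age distribution, so that comparisons across time
or between populations are not driven by shifts in the age mix.  The
shipped default weights are the published ICSS-1 reference distribution for
the five adult age bands 15-44, 45-54, 55-64, 65-74, 75+; any non-negative
weight vector summing to one may be supplied instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass(frozen=True)
class StandardWeights:
    """Reference age distribution: age-group label -> weight."""

    weights: dict[str, float]

    def __post_init__(self) -> None:
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("standard weights must be non-negative")
        total = sum(self.weights.values())
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"standard weights sum to {total!r}, not 1")

    def __getitem__(self, label: str) -> float:
        return self.weights[label]

    def items(self):
        return self.weights.items()


#: ICSS standard 1 (elderly-heavy cancers), collapsed to the five bands
#: used here. A stand-in default: choose the standard appropriate to the
#: cancer under study.
ICSS1_WEIGHTS = StandardWeights({
    "15-44": 0.07,
    "45-54": 0.12,
    "55-64": 0.23,
    "65-74": 0.29,
    "75+": 0.29,
})


def age_standardized_rs(
    by_age: dict[str, tuple[float, float]],
    weights: StandardWeights = ICSS1_WEIGHTS,
) -> tuple[float, float]:
    """Weighted-average relative survival and its standard error.

    ``by_age`` maps age-group labels to ``(R, se_R)``.  Returns
    ``(sum_a w_a R_a, sqrt(sum_a w_a^2 se_a^2))``.  If any group with a
    positive weight is missing or undefined, the standardized estimate is
    undefined (NaN, NaN).
    """
    R_std = 0.0
    var = 0.0
    for label, w in weights.items():
        if w == 0:
            continue
        if label not in by_age:
            return (float("nan"), float("nan"))
        R, se = by_age[label]
        if not (math.isfinite(R) and math.isfinite(se)):
            return (float("nan"), float("nan"))
        R_std += w * R
        var += w * w * se * se
    return (R_std, math.sqrt(var))
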