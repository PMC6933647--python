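"""Outcome catalogs for best-worst scaling (BWS) choice experiments.

An :class:`OutcomeCatalog` holds the attribute levels of an object-case
(Case-1) BWS experiment — here, clinical outcomes after surgically treated
fractures — together with a single reference level that anchors the utility
scale at zero.  The default catalog ships the ten outcomes elicited from
396 adult orthopaedic trauma patients, with "perfect health" as the
reference; :data:`PUBLISHED_UTILITIES` carries the corresponding published
population mean utilities and their 95% intervals so that composite-endpoint
weights can be computed without re-running a survey.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable


@dataclass(frozen=True)
class OutcomeCatalog:
    """Ordered set of outcome labels plus a reference (utility-zero) level.

    Parameters
    ----------
    outcomes
        Ordered, unique outcome labels.  Must contain at least 3 entries.
    reference
        The label anchoring the utility scale at zero.  Must be one of
        ``outcomes``.
    """

    outcomes: tuple[str, ...]
    reference: str = "Perfect health"

    def __post_init__(self) -> None:
        object.__setattr__(self, "outcomes", tuple(self.outcomes))
        if len(self.outcomes) < 3:
            raise ValueError("catalog needs at least 3 outcomes")
        if len(set(self.outcomes)) != len(self.outcomes):
            raise ValueError("outcome labels must be unique")
        if self.reference not in self.outcomes:
            raise ValueError(
                f"reference label {self.reference!r} not among outcomes"
            )

    def __len__(self) -> int:
        return len(self.outcomes)

    @property
    def non_reference(self) -> tuple[str, ...]:
        """Outcome labels excluding the reference level, catalog order."""
        return tuple(o for o in self.outcomes if o != self.reference)

    @property
    def reference_index(self) -> int:
        return self.outcomes.index(self.reference)

    def index(self, label: str) -> int:
        try:
            return self.outcomes.index(label)
        except ValueError:
            raise KeyError(f"unknown outcome label {label!r}") from None

    def to_json(self, path: str | Path) -> None:
        payload = {"outcomes": list(self.outcomes), "reference": self.reference}
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "OutcomeCatalog":
        payload = json.loads(Path(path).read_text())
        return cls(tuple(payload["outcomes"]), payload["reference"])

    @classmethod
    def from_labels(
        cls, labels: Iterable[str], reference: str | None = None
    ) -> "OutcomeCatalog":
        labels = tuple(labels)
        return cls(labels, reference if reference is not None else labels[-1])


#: The ten clinical outcomes of the orthopaedic trauma BWS questionnaire,
#: ordered from greatest to least population-level importance, with
#: "perfect health" as the zero anchor.
DEFAULT_CATALOG = OutcomeCatalog(
    outcomes=(
        "Death",
        "Amputation [above knee]",
        "Amputation [below knee]",
        "Severe pain",
        "Deep surgical site infection",
        "Bone healing complication",
        "Moderate pain",
        "Mild pain",
        "Superficial surgical site infection",
        "Perfect health",
    ),
    reference="Perfect health",
)

#: Published population mean utilities (and equal-tailed 95% intervals) for
#: the default catalog, elicited with a hierarchical Bayesian multinomial
#: logit from 396 respondents.  Keys are outcome labels; values are
#: (mean, lower95, upper95) on the perfect-health-zero scale.
PUBLISHED_UTILITIES: dict[str, tuple[float, float, float]] = {
    "Death": (-8.91, -9.23, -8.65),
    "Amputation [above knee]": (-7.66, -7.83, -7.48),
    "Amputation [below knee]": (-6.97, -7.14, -6.85),
    "Severe pain": (-5.90, -6.00, -5.80),
    "Deep surgical site infection": (-5.69, -5.81, -5.60),
    "Bone healing complication": (-5.20, -5.31, -5.09),
    "Moderate pain": (-4.59, -4.69, -4.57),
    "Mild pain": (-3.30, -3.46, -3.13),
    "Superficial surgical site infection": (-3.29, -3.39, -3.16),
    "Perfect health": (0.00, -0.37, 0.44),
}

#: Event profile of the hypothetical 1000-patient pilon fracture trial used
#: to illustrate composite weighting: per-arm sample sizes and per-component
#: event probabilities (events / arm size).
PILON_TRIAL_ARMS: dict[str, int] = {"A": 498, "B": 502}
PILON_TRIAL_EVENTS: dict[str, dict[str, int]] = {
    "A": {
        "Deep surgical site infection": 61,
        "Bone healing complication": 30,
        "Superficial surgical site infection": 98,
    },
    "B": {
        "Deep surgical site infection": 91,
        "Bone healing complication": 55,
        "Superficial surgical site infection": 42,
    },
}


def pilon_trial_probs() -> dict[str, dict[str, float]]:
    """Per-arm, per-component event probabilities of the pilon example."""
    return {
        arm: {c: n / PILON_TRIAL_ARMS[arm] for c, n in comps.items()}
        for arm, comps in PILON_TRIAL_EVENTS.items()
    }
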