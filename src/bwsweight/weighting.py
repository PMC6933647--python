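"""Composite-endpoint component weights from outcome utilities.

For a composite of k components with mean utilities ``u_1..u_k`` (on the
reference-zero scale, more negative = more severe), the weight of
component a is

    W_a = (sum_{j != a} exp(u_j)) / (sum_j exp(u_j)) = 1 - softmax_a(u)

i.e. one minus component a's softmax share.  For k = 3 this is exactly
``(e^{u_b} + e^{u_i}) / (e^{u_a} + e^{u_b} + e^{u_i})``.  Consequences used
throughout the tests: the weights sum to k - 1 exactly; every weight lies
in (0, 1); a more negative utility yields a strictly larger weight; and
the weights are invariant to adding a constant to every utility.

The denominator runs over the composite's components only — the reference
level is not part of a composite.  Severity weights for subpopulations are
obtained by overriding utilities with stratum-specific means before
applying the same formula.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.special import logsumexp

from .estimation import UtilityEstimates


@dataclass(frozen=True)
class ComponentWeights:
    """Weights for a chosen component set, with the utilities that made them."""

    components: tuple[str, ...]
    utilities_used: dict[str, float]
    weights: dict[str, float]
    overridden: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        k = len(self.components)
        total = sum(self.weights.values())
        if abs(total - (k - 1)) > 1e-9:
            raise ValueError(f"weights must sum to k-1={k-1}, got {total}")
        if any(not 0.0 < w < 1.0 for w in self.weights.values()):
            raise ValueError("every weight must lie strictly in (0, 1)")

    def __getitem__(self, label: str) -> float:
        return self.weights[label]

    def rounded(self, ndigits: int = 2) -> dict[str, float]:
        """Presentation rounding (the stored weights stay full precision)."""
        return {c: round(w, ndigits) for c, w in self.weights.items()}

    def to_json(self, path: str | Path) -> None:
        rows = [
            {
                "outcome": c,
                "utility": self.utilities_used[c],
                "weight": self.weights[c],
                "overridden": c in self.overridden,
            }
            for c in self.components
        ]
        Path(path).write_text(json.dumps(rows, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "ComponentWeights":
        rows = json.loads(Path(path).read_text())
        return cls(
            components=tuple(r["outcome"] for r in rows),
            utilities_used={r["outcome"]: r["utility"] for r in rows},
            weights={r["outcome"]: r["weight"] for r in rows},
            overridden=tuple(r["outcome"] for r in rows if r.get("overridden")),
        )


def _utility_map(utilities) -> dict[str, float]:
    if isinstance(utilities, UtilityEstimates):
        return dict(utilities.mean)
    return dict(utilities)


def _weights_from_values(values: np.ndarray) -> np.ndarray:
    # log-sum-exp stabilized softmax complement
    log_denom = logsumexp(values)
    return 1.0 - np.exp(values - log_denom)


def compute_weights(
    utilities: UtilityEstimates | Mapping[str, float],
    components: Sequence[str],
) -> ComponentWeights:
    """Weights for ``components`` from their mean utilities.

    ``utilities`` may be a fitted :class:`UtilityEstimates` or a plain
    label -> utility mapping.  Requires at least two components, all
    present in ``utilities``.
    """
    components = tuple(components)
    if len(components) < 2:
        raise ValueError("a composite needs at least 2 components")
    if len(set(components)) != len(components):
        raise ValueError("duplicate component labels")
    umap = _utility_map(utilities)
    missing = [c for c in components if c not in umap]
    if missing:
        raise KeyError(f"no utility for component(s): {missing}")
    values = np.array([umap[c] for c in components], dtype=float)
    w = _weights_from_values(values)
    return ComponentWeights(
        components=components,
        utilities_used={c: float(u) for c, u in zip(components, values)},
        weights={c: float(x) for c, x in zip(components, w)},
    )


def subgroup_adjusted_weights(
    utilities: UtilityEstimates | Mapping[str, float],
    components: Sequence[str],
    overrides: Mapping[str, float],
) -> ComponentWeights:
    """Recompute weights with stratum-specific utilities substituted.

    ``overrides`` maps outcome labels to subgroup mean utilities (e.g. the
    above-knee-amputation utility of respondents aged 65+).  Labels must
    exist in ``utilities``; the returned object records which components
    were overridden.
    """
    umap = _utility_map(utilities)
    unknown = [c for c in overrides if c not in umap]
    if unknown:
        raise KeyError(f"override for unknown outcome(s): {unknown}")
    umap.update({c: float(v) for c, v in overrides.items()})
    base = compute_weights(umap, components)
    return ComponentWeights(
        components=base.components,
        utilities_used=base.utilities_used,
        weights=base.weights,
        overridden=tuple(c for c in overrides if c in base.components),
    )


def weight_sensitivity(
    utilities: UtilityEstimates,
    components: Sequence[str],
    n_draws: int = 10_000,
    seed: int = 0,
) -> dict[str, tuple[float, float]]:
    """Monte-Carlo 95% intervals for the weights.

    Component utilities are sampled independently from normal distributions
    matched to each outcome's (mean, 95% interval) — an approximation, since
    posterior correlations between utilities are not carried — and the
    weight formula is re-applied per draw.  Returns label -> (2.5th, 97.5th)
    percentile of the weight.  Deterministic given ``seed``.
    """
    components = tuple(components)
    if n_draws < 100:
        raise ValueError("n_draws must be >= 100")
    for c in components:
        if c not in utilities.lower95 or c not in utilities.upper95:
            raise KeyError(f"no interval for component {c!r}")
    mean = np.array([utilities.mean[c] for c in components])
    half = np.array(
        [
            (utilities.upper95[c] - utilities.lower95[c]) / 2.0
            for c in components
        ]
    )
    sd = half / 1.959963984540054
    rng = np.random.default_rng(seed)
    draws = mean + sd * rng.standard_normal((n_draws, len(components)))
    log_denom = logsumexp(draws, axis=1, keepdims=True)
    w = 1.0 - np.exp(draws - log_denom)
    lo = np.percentile(w, 2.5, axis=0)
    hi = np.percentile(w, 97.5, axis=0)
    return {
        c: (float(a), float(b)) for c, a, b in zip(components, lo, hi)
    }
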