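"""Labeled-crypt mixture model and deterministic point estimates.

In a lineage-tracing pulse only a fraction ``v`` of crypts starts with a
labeled clonogenic stem cell; the rest never produce a clone.  The
crypt-level clone-size distribution is therefore the two-component
mixture

    Q_n(t) = (1 - v) delta_{0,n} + v p_n(t),

so the expected fraction of crypts scored positive for an observable
class is simply ``v`` times the corresponding single-clone drift
probability.  Inverting that relation on a pooled observed fraction
gives a deterministic point estimate of ``v``; the hierarchical
Bayesian treatment with mouse-level variability lives in
:mod:`cryptdrift.bayes`.

All APIs take and return proportions in [0, 1]; percent formatting
happens only in report strings.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .drift import DriftParams, Observable, clone_size_pmf, observable_prob

__all__ = [
    "LabelingMixture",
    "StemCellEquivalents",
    "DegenerateObservableError",
    "InconsistentFractionError",
    "mixture_pmf",
    "expected_observable_fraction",
    "invert_point_estimate",
    "stem_cell_equivalents",
]


class DegenerateObservableError(ValueError):
    """The observable has probability zero, so no fraction is invertible."""


class InconsistentFractionError(ValueError):
    """The observed fraction exceeds what any v in [0, 1] can explain."""

    def __init__(self, observed: float, max_explainable: float):
        self.observed = observed
        self.max_explainable = max_explainable
        super().__init__(
            f"observed fraction {observed:.6g} exceeds the maximum "
            f"explainable fraction {max_explainable:.6g} (v = 1)"
        )


@dataclass(frozen=True)
class LabelingMixture:
    """Initial labeled-crypt fraction ``v`` plus tissue drift constants."""

    v: float
    params: DriftParams

    def __post_init__(self) -> None:
        if not 0.0 <= self.v <= 1.0:
            raise ValueError(f"v must lie in [0, 1], got {self.v!r}")


def mixture_pmf(mix: LabelingMixture, t: float) -> np.ndarray:
    """Crypt-level clone-size probabilities Q_0..Q_N at drift time ``t``."""
    base = clone_size_pmf(mix.params, t).probs
    q = mix.v * base
    q[0] = (1.0 - mix.v) + mix.v * base[0]
    return q


def expected_observable_fraction(
    mix: LabelingMixture, t: float, kind: Observable | str
) -> float:
    """Expected fraction of crypts scored positive: v * P(observable)."""
    return mix.v * observable_prob(mix.params, t, kind)


def invert_point_estimate(
    observed_fraction: float,
    params: DriftParams,
    t: float,
    kind: Observable | str,
) -> float:
    """Deterministic estimate v-hat = observed / P(observable at t).

    Raises
    ------
    DegenerateObservableError
        If the observable probability is zero (e.g. whole crypts at
        t = 0), so any nonzero observation is unexplainable.
    InconsistentFractionError
        If the implied v-hat exceeds 1; the error carries the maximum
        fraction explainable at v = 1.
    """
    if not 0.0 <= observed_fraction <= 1.0:
        raise ValueError(
            f"observed_fraction must lie in [0, 1], got {observed_fraction!r}"
        )
    if not t > 0:
        raise ValueError(f"drift time t must be > 0 for inversion, got {t!r}")
    denom = observable_prob(params, t, kind)
    if denom == 0.0:
        raise DegenerateObservableError(
            f"observable {Observable.parse(kind).value} has probability 0 "
            f"at t={t}; cannot invert"
        )
    vhat = observed_fraction / denom
    if vhat > 1.0:
        raise InconsistentFractionError(observed_fraction, denom)
    return vhat


class StemCellEquivalents(NamedTuple):
    """Per-stem-cell restatement of a crypt-level labeled fraction."""

    fraction: float  # v / N: labeled fraction of the stem-cell pool
    exact_ratio: float  # N / v
    report: str  # "1 in X" with X = floor(N / v)


def stem_cell_equivalents(v: float, N: int) -> StemCellEquivalents:
    """Convert crypt fraction ``v`` into a '1 in X stem cells' report.

    A fraction v of crypts carrying one labeled cell of N means v/N of
    all stem cells are labeled, i.e. 1 in N/v.  The integer report
    floors the exact ratio (0.44 of crypts with N = 7 -> 15.9 -> "1 in
    15"); the exact ratio is returned alongside so nothing is lost.
    """
    if not 0.0 < v <= 1.0:
        raise ValueError(f"v must lie in (0, 1] for a ratio report, got {v!r}")
    if not (isinstance(N, (int, np.integer)) and N >= 2):
        raise ValueError(f"N must be an integer >= 2, got {N!r}")
    exact = N / v
    return StemCellEquivalents(
        fraction=v / N, exact_ratio=exact, report=f"1 in {int(np.floor(exact))}"
    )
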