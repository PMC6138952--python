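"""Closed-form clone-size distributions under neutral drift.

Intestinal crypts are maintained by a small pool of N equipotent stem
cells.  When one of them is heritably labeled, the labeled clone's size
performs an unbiased random walk on {0, 1, ..., N} as neighbours
stochastically replace each other at rate ``lam`` per cell per day, until
the clone is lost (size 0) or takes over the whole crypt (size N,
monoclonal conversion).  The walk has a spectral solution: the
probability that a clone founded by a single labeled stem cell has size
``0 < n < N`` after ``t`` days of drift is

    p_n(t) = (2/N) sum_{m=1}^{N-1} sin(pi m/N) sin(pi m n/N)
             exp(-4 lam sin^2(pi m / 2N) t)

and the fixation (whole-crypt) probability is

    p_N(t) = (2/N) sum_{m=1}^{N-1} (-1)^{m+1} cos^2(pi m / 2N)
             (1 - exp(-4 lam sin^2(pi m / 2N) t)),

which rises monotonically to the neutral limit 1/N.  The extinct mass
p_0(t) is the complement.

All functions here take *pure drift time* t.  The delay ``tau`` between
label induction and the onset of observable drift is subtracted exactly
once, in the simulation / fitting layer (``chase_day - tau``), never
here.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DriftParams",
    "CloneSizePMF",
    "Observable",
    "clone_size_prob",
    "fixation_prob",
    "clone_size_pmf",
    "observable_prob",
]

# round-off below this magnitude is clamped to zero; anything worse is a bug
_CLAMP_TOL = 1e-9


class Observable(str, enum.Enum):
    """Which crypt-level event counts as 'labeled' at scoring time.

    ANY_SURVIVING : any surviving clone, whole or partial (used for the
        small intestine, where ribbon clones are not size-resolved).
    PARTIAL_ONLY  : partly populated crypts, clone size 1..N-1.
    WHOLE_ONLY    : wholly populated (monoclonal) crypts, size N
        (used for the colon).
    """

    ANY_SURVIVING = "any_surviving"
    PARTIAL_ONLY = "partial_only"
    WHOLE_ONLY = "whole_only"

    @classmethod
    def parse(cls, value: "Observable | str") -> "Observable":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).strip().lower())
        except ValueError:
            valid = ", ".join(k.value for k in cls)
            raise ValueError(
                f"unknown observable kind {value!r}; valid kinds: {valid}"
            ) from None


@dataclass(frozen=True)
class DriftParams:
    """Fixed biological constants of one tissue.

    Parameters
    ----------
    N : int
        Number of functional stem cells per crypt (>= 2).
    lam : float
        Stem-cell replacement rate, per cell per day (> 0).
    tau : float
        Delay in days between induction and the start of traceable
        drift (>= 0); for the small intestine the time clone ribbons
        take to emerge from the crypt base.
    """

    N: int
    lam: float
    tau: float = 0.0

    def __post_init__(self) -> None:
        if not (isinstance(self.N, (int, np.integer)) and self.N >= 2):
            raise ValueError(f"N must be an integer >= 2, got {self.N!r}")
        if not self.lam > 0:
            raise ValueError(f"lam must be > 0, got {self.lam!r}")
        if self.tau < 0:
            raise ValueError(f"tau must be >= 0, got {self.tau!r}")


@dataclass(frozen=True)
class CloneSizePMF:
    """Distribution over clone sizes n = 0..N at drift time ``t``."""

    t: float
    probs: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", p)
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError("pmf entries outside [0, 1]")
        if abs(p.sum() - 1.0) > 1e-10:
            raise ValueError(f"pmf does not sum to 1 (sum={p.sum()!r})")

    @property
    def N(self) -> int:
        return len(self.probs) - 1

    def __getitem__(self, n: int) -> float:
        return float(self.probs[n])


def _check_time(t: float) -> float:
    t = float(t)
    if not t >= 0:
        raise ValueError(f"drift time t must be >= 0, got {t!r}")
    return t


def _decay_rates(params: DriftParams) -> tuple[np.ndarray, np.ndarray]:
    """Spectral modes m = 1..N-1 and their decay rates 4 lam sin^2(pi m/2N)."""
    m = np.arange(1, params.N)
    rates = 4.0 * params.lam * np.sin(np.pi * m / (2 * params.N)) ** 2
    return m, rates


def clone_size_prob(params: DriftParams, n: int, t: float) -> float:
    """Probability the clone has size ``n`` (0 < n < N) after ``t`` days."""
    t = _check_time(t)
    if not (isinstance(n, (int, np.integer)) and 0 < n < params.N):
        raise ValueError(
            f"clone size n must be an integer in (0, {params.N}), got {n!r}"
        )
    m, rates = _decay_rates(params)
    N = params.N
    p = (2.0 / N) * np.sum(
        np.sin(np.pi * m / N) * np.sin(np.pi * m * n / N) * np.exp(-rates * t)
    )
    return _clamp_prob(float(p), f"p_{n}({t})")


def fixation_prob(params: DriftParams, t: float) -> float:
    """Probability all N stem cells are labeled (monoclonal) by time ``t``."""
    t = _check_time(t)
    m, rates = _decay_rates(params)
    N = params.N
    signs = np.where(m % 2 == 1, 1.0, -1.0)  # (-1)^{m+1}
    p = (2.0 / N) * np.sum(
        signs * np.cos(np.pi * m / (2 * N)) ** 2 * (1.0 - np.exp(-rates * t))
    )
    return _clamp_prob(float(p), f"p_N({t})")


def _clamp_prob(p: float, label: str) -> float:
    if p < 0.0:
        if p < -_CLAMP_TOL:
            raise ArithmeticError(
                f"internal consistency failure: {label} = {p!r} < -{_CLAMP_TOL}"
            )
        return 0.0
    return min(p, 1.0)


def clone_size_pmf(params: DriftParams, t: float) -> CloneSizePMF:
    """Full clone-size distribution (sizes 0..N) at drift time ``t``.

    The extinct mass p_0 is defined by complement, so the vector sums to
    one exactly by construction.
    """
    t = _check_time(t)
    N = params.N
    probs = np.empty(N + 1)
    for n in range(1, N):
        probs[n] = clone_size_prob(params, n, t)
    probs[N] = fixation_prob(params, t)
    p0 = 1.0 - probs[1:].sum()
    probs[0] = _clamp_prob(p0, f"p_0({t})")
    return CloneSizePMF(t=t, probs=probs)


def observable_prob(
    params: DriftParams, t: float, kind: Observable | str
) -> float:
    """Probability a crypt seeded with one labeled stem cell is scored
    positive for the given observable class at drift time ``t``."""
    kind = Observable.parse(kind)
    pmf = clone_size_pmf(params, t)
    if kind is Observable.ANY_SURVIVING:
        return float(pmf.probs[1:].sum())
    if kind is Observable.PARTIAL_ONLY:
        return float(pmf.probs[1:-1].sum())
    return float(pmf.probs[-1])  # WHOLE_ONLY
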