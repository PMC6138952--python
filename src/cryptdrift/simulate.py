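"""Stochastic simulation of crypt clone dynamics and synthetic cohorts.

Two independent realisations of the drift process live here, used to
cross-check the spectral formulas in :mod:`cryptdrift.drift`:

* an exact event-driven (Gillespie) simulation of the clone-size random
  walk on {0, ..., N} — symmetric +-1 jumps, each at rate ``lam``,
  absorbing at 0 and N, whose generator has exactly the eigenvalues
  4 lam sin^2(pi m / 2N) appearing in the closed forms;
* the matrix exponential of that generator, an independent numerical
  oracle for the clone-size distribution.

On top of the single-clone process, :func:`simulate_cohort` generates
synthetic multi-mouse experiments with the statistical structure the
hierarchical model assumes: a fraction ``v_true`` of crypts starts with
one labeled stem cell, each mouse's expected positive fraction is
perturbed by truncated Student-t noise, and counts are binomial.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm
from scipy.special import stdtr, stdtrit

from .cohort import CohortTable
from .drift import CloneSizePMF, DriftParams, Observable
from .mixture import LabelingMixture, expected_observable_fraction

__all__ = [
    "SimCohortConfig",
    "generator_matrix",
    "pmf_via_matrix_exponential",
    "simulate_clone",
    "truncated_t_rvs",
    "simulate_cohort",
]


def generator_matrix(params: DriftParams) -> np.ndarray:
    """Rate matrix of the clone-size walk on states {0, ..., N}.

    Tridiagonal: transient states 1..N-1 jump up or down at rate
    ``lam`` each; 0 and N are absorbing (all-zero rows).  Rows sum to
    zero.
    """
    N, lam = params.N, params.lam
    A = np.zeros((N + 1, N + 1))
    for i in range(1, N):
        A[i, i - 1] = lam
        A[i, i + 1] = lam
        A[i, i] = -2.0 * lam
    return A


def pmf_via_matrix_exponential(params: DriftParams, t: float) -> CloneSizePMF:
    """Clone-size distribution by propagating delta_{n,1} through exp(At).

    Numerically independent of the spectral formulas; serves as their
    oracle in tests.
    """
    t = float(t)
    if not t >= 0:
        raise ValueError(f"drift time t must be >= 0, got {t!r}")
    A = generator_matrix(params)
    start = np.zeros(params.N + 1)
    start[1] = 1.0
    probs = start @ expm(A * t)
    probs = np.clip(probs, 0.0, 1.0)
    probs /= probs.sum()
    return CloneSizePMF(t=t, probs=probs)


def simulate_clone(
    params: DriftParams, t: float, rng: np.random.Generator
) -> int:
    """Exact event-driven realisation of one clone over ``t`` days.

    Starts from size 1; returns the clone size at time ``t``.  While the
    size is transient the next replacement event arrives after an
    Exponential(2 lam) waiting time and moves the size +-1 with equal
    probability; sizes 0 and N are absorbing.
    """
    t = float(t)
    if not t >= 0:
        raise ValueError(f"drift time t must be >= 0, got {t!r}")
    N = params.N
    total_rate = 2.0 * params.lam
    size = 1
    clock = 0.0
    while 0 < size < N:
        clock += rng.exponential(1.0 / total_rate)
        if clock > t:
            break
        size += 1 if rng.random() < 0.5 else -1
    return size


def truncated_t_rvs(
    dof: float,
    loc: float,
    scale: float,
    lower: float,
    upper: float,
    rng: np.random.Generator,
    size=None,
):
    """Sample a Student-t(dof, loc, scale) truncated to [lower, upper].

    Exact inverse-CDF sampling on the truncated interval: rejection-free
    for any location/scale, including locations far outside the bounds.
    """
    if not dof > 0 or not scale > 0:
        raise ValueError("dof and scale must be > 0")
    if not lower < upper:
        raise ValueError("need lower < upper")
    a = stdtr(dof, (lower - loc) / scale)
    b = stdtr(dof, (upper - loc) / scale)
    u = rng.uniform(a, b, size=size)
    return loc + scale * stdtrit(dof, u)


@dataclass(frozen=True)
class SimCohortConfig:
    """Ground-truth settings for one synthetic lineage-tracing cohort.

    ``eta_true`` / ``sigma_true`` set the mouse-level truncated
    Student-t noise (degrees of freedom / scale) around the model-
    predicted positive fraction; ``sigma_true = 0`` disables it.
    Defaults mirror a colon experiment: harvest at day 30 with modest
    mouse-to-mouse variability.
    """

    params: DriftParams
    v_true: float
    chase_day: float = 30.0
    n_mice: int = 6
    crypts_per_mouse: int | tuple[int, ...] = 900
    kind: Observable | str = Observable.WHOLE_ONLY
    eta_true: float = 20.0
    sigma_true: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", Observable.parse(self.kind))
        if not 0.0 <= self.v_true <= 1.0:
            raise ValueError(f"v_true must lie in [0, 1], got {self.v_true!r}")
        if self.sigma_true < 0:
            raise ValueError("sigma_true must be >= 0")
        if not self.eta_true > 0:
            raise ValueError("eta_true must be > 0")
        if self.n_mice < 1:
            raise ValueError("n_mice must be >= 1")
        if not self.chase_day - self.params.tau > 0:
            raise ValueError(
                f"chase_day ({self.chase_day}) must exceed tau "
                f"({self.params.tau})"
            )

    @property
    def crypt_counts(self) -> np.ndarray:
        c = self.crypts_per_mouse
        if np.isscalar(c):
            counts = np.full(self.n_mice, int(c))
        else:
            counts = np.asarray(c, dtype=int)
            if len(counts) != self.n_mice:
                raise ValueError(
                    "crypts_per_mouse length does not match n_mice"
                )
        if (counts < 1).any():
            raise ValueError("crypts_per_mouse must be positive")
        return counts


def simulate_cohort(config: SimCohortConfig) -> CohortTable:
    """Generate one synthetic cohort table.

    For each mouse the expected positive fraction is
    Q = v_true * P(observable at chase_day - tau); the realised mouse
    fraction R_i is drawn from Student-t(eta_true, Q, sigma_true)
    truncated to [0, 1] (R_i = Q exactly when sigma_true = 0), and the
    positive count is Binomial(C_i, R_i).  Per-mouse random streams are
    spawned deterministically from the root seed, so a mouse's draw does
    not depend on cohort ordering.
    """
    p = config.params
    t = config.chase_day - p.tau
    mix = LabelingMixture(v=config.v_true, params=p)
    q = expected_observable_fraction(mix, t, config.kind)
    counts = config.crypt_counts
    streams = np.random.SeedSequence(config.seed).spawn(config.n_mice)
    width = max(2, len(str(config.n_mice)))
    rows = []
    for i, (c_i, ss) in enumerate(zip(counts, streams)):
        rng = np.random.default_rng(ss)
        if config.sigma_true == 0.0:
            r_i = q
        else:
            r_i = float(
                truncated_t_rvs(
                    config.eta_true, q, config.sigma_true, 0.0, 1.0, rng
                )
            )
        kappa_i = int(rng.binomial(int(c_i), r_i))
        rows.append(
            (
                f"m{i + 1:0{width}d}",
                int(c_i),
                kappa_i,
                Observable.parse(config.kind).value,
                float(config.chase_day),
            )
        )
    return CohortTable.from_records(rows)
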