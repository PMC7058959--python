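"""Forward-time allele-frequency trajectories for arbitrary even ploidy.

A beneficial mutation arises in single copy (frequency 1/(kN)) in a
Wright-Fisher population of N individuals each carrying k chromosome
copies.  Genotype fitness is 1 + h(d)*s where d is the derived-allele
dosage, s is the fitness difference between the alternative homozygotes,
and the dominance coefficient h(d) = (d/k)**tau is controlled by a single
dominance scalar H in (-0.5, 0.5) through tau = 10**(-H):

* H = 0  -> tau = 1 -> h(d) = d/k (additive),
* H < 0  -> tau > 1 -> convex h (recessive-like),
* H > 0  -> tau < 1 -> concave h (dominant-like).

Trajectories conditioned on fixation are obtained by rejection sampling:
runs that lose the allele are discarded (and counted).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "SelectionModel",
    "Trajectory",
    "ConditioningError",
    "dominance_coefficients",
    "tau_from_H",
    "expected_frequency",
    "wright_fisher_step",
    "simulate_trajectory",
    "deterministic_trajectory",
    "fitness_moments",
    "fixation_stats",
    "fixation_probability",
    "write_trajectory",
    "read_trajectory",
    "write_trajectory_reversed",
]


class ConditioningError(RuntimeError):
    """Raised when rejection sampling fails to produce a fixed trajectory."""


def tau_from_H(H: float) -> float:
    """Dominance exponent tau = 10**(-H) for dominance scalar H in (-0.5, 0.5)."""
    if not -0.5 < H < 0.5:
        raise ValueError(f"dominance scalar H must lie in (-0.5, 0.5); got {H}")
    return 10.0 ** (-H)


def dominance_coefficients(
    H: float, k: int, tau_map: Callable[[float], float] = tau_from_H
) -> np.ndarray:
    """Dominance coefficient h(d) = (d/k)**tau for derived dosage d = 0..k.

    `tau_map` is the hook mapping the dominance scalar to the exponent;
    the default is 10**(-H).
    """
    if k < 2 or k % 2 != 0:
        raise ValueError(f"ploidy k must be an even integer >= 2; got {k}")
    tau = tau_map(H)
    d = np.arange(k + 1, dtype=float)
    h = (d / k) ** tau
    h[0] = 0.0
    h[-1] = 1.0
    return h


@dataclass(frozen=True)
class SelectionModel:
    """Selection and dominance model for one locus in a k-ploid population.

    Parameters
    ----------
    k : even integer >= 2, chromosome copies per individual.
    N : individuals in the population.
    s : selection coefficient (fitness difference between homozygotes).
    H : dominance scalar in (-0.5, 0.5).
    """

    k: int
    N: int
    s: float
    H: float = 0.0

    def __post_init__(self) -> None:
        if self.k < 2 or self.k % 2 != 0:
            raise ValueError(f"ploidy k must be an even integer >= 2; got {self.k}")
        if self.N < 2:
            raise ValueError(f"population size N must be >= 2; got {self.N}")
        if not -0.5 < self.H < 0.5:
            raise ValueError(f"H must lie in (-0.5, 0.5); got {self.H}")

    @property
    def tau(self) -> float:
        return tau_from_H(self.H)

    @property
    def h(self) -> np.ndarray:
        """Dominance vector indexed by derived dosage d = 0..k."""
        return dominance_coefficients(self.H, self.k)

    @property
    def p0(self) -> float:
        """Initial frequency of a new mutation: one copy among kN."""
        return 1.0 / (self.k * self.N)

    def _tables(self) -> tuple[list[float], list[float]]:
        """Per-dosage binomial coefficients and fitnesses (1 + h[d] s)."""
        h = self.h
        w = [math.comb(self.k, d) for d in range(self.k + 1)]
        f = [1.0 + h[d] * self.s for d in range(self.k + 1)]
        return w, f


@dataclass
class Trajectory:
    """A forward-time derived-allele frequency path, one entry per generation."""

    freqs: np.ndarray
    fixed: bool
    attempts: int = 0
    model: SelectionModel | None = None

    @property
    def length(self) -> int:
        """Fixation (or absorption) time T in generations."""
        return len(self.freqs) - 1

    def __len__(self) -> int:
        return len(self.freqs)


def expected_frequency(p: float, model: SelectionModel) -> float:
    """Deterministic next-generation derived frequency under selection.

    Weights each dosage-d genotype (binomial under random polysomic union)
    by its fitness and the fraction d/k of derived alleles it transmits,
    normalised by mean fitness.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"frequency must lie in [0, 1]; got {p}")
    if p == 0.0 or p == 1.0:
        return p
    k = model.k
    w, f = model._tables()
    q = 1.0 - p
    # genotype probability p^d q^(k-d) built incrementally
    num = 0.0
    den = 0.0
    pd = 1.0  # p**d
    for d in range(k + 1):
        g = w[d] * pd * q ** (k - d)
        wf = g * f[d]
        den += wf
        num += wf * (d / k)
        pd *= p
    if den <= 0.0:
        raise ValueError("mean fitness is non-positive (requires s <= -1)")
    return num / den


def _expected_frequency_vec(p: np.ndarray, model: SelectionModel) -> np.ndarray:
    """Vectorised expected_frequency over an array of frequencies."""
    k = model.k
    w, f = model._tables()
    q = 1.0 - p
    num = np.zeros_like(p)
    den = np.zeros_like(p)
    for d in range(k + 1):
        g = w[d] * p**d * q ** (k - d)
        wf = g * f[d]
        den += wf
        num += wf * (d / k)
    return num / den


def wright_fisher_step(
    phat: float, N: int, k: int, rng: np.random.Generator
) -> float:
    """One generation of genotype sampling: N binomial(k, phat) dosages.

    The sum of N iid Binomial(k, phat) draws is a single Binomial(N*k, phat)
    draw; the returned frequency is that total over kN, hence always a
    multiple of 1/(kN).
    """
    if not 0.0 <= phat <= 1.0:
        raise ValueError(f"expected frequency must lie in [0, 1]; got {phat}")
    if phat == 0.0:
        return 0.0
    if phat == 1.0:
        return 1.0
    return rng.binomial(N * k, phat) / (N * k)


def simulate_trajectory(
    model: SelectionModel,
    rng: np.random.Generator,
    max_attempts: int = 10**6,
) -> Trajectory:
    """A stochastic trajectory from 1/(kN) conditioned on fixation.

    Runs the expected-frequency recursion plus Wright-Fisher sampling until
    absorption; runs ending in loss are rejected and counted.  Raises
    :class:`ConditioningError` if no run fixes within `max_attempts`.
    """
    if max_attempts < 1:
        raise ValueError("max_attempts must be >= 1")
    N, k = model.N, model.k
    kN = N * k
    p0 = 1.0 / kN
    w, f = model._tables()
    tk = [d / k for d in range(k + 1)]
    for attempt in range(1, max_attempts + 1):
        freqs = [p0]
        p = p0
        while 0.0 < p < 1.0:
            # inline expected_frequency for speed
            q = 1.0 - p
            num = 0.0
            den = 0.0
            pd = 1.0
            for d in range(k + 1):
                wf = w[d] * pd * q ** (k - d) * f[d]
                den += wf
                num += wf * tk[d]
                pd *= p
            p = rng.binomial(kN, num / den) / kN
            freqs.append(p)
        if p == 1.0:
            return Trajectory(
                freqs=np.asarray(freqs), fixed=True, attempts=attempt - 1, model=model
            )
    raise ConditioningError(
        f"no fixation in {max_attempts} attempts "
        f"(k={model.k}, N={model.N}, s={model.s}, H={model.H})"
    )


def deterministic_trajectory(
    model: SelectionModel,
    p0: float | None = None,
    threshold: float | None = None,
    max_generations: int = 10**7,
) -> np.ndarray:
    """Infinite-population (expectation-only) frequency path.

    Iterates the selection recursion without sampling from `p0` (default
    1/(kN)) until the frequency reaches `threshold` (default 1 - 1/(kN)).
    """
    if p0 is None:
        p0 = model.p0
    if not 0.0 < p0 < 1.0:
        raise ValueError("p0 must lie strictly inside (0, 1)")
    if threshold is None:
        threshold = 1.0 - model.p0
    path = [p0]
    p = p0
    for _ in range(max_generations):
        if p >= threshold:
            return np.asarray(path)
        p = expected_frequency(p, model)
        path.append(p)
    raise RuntimeError(
        f"deterministic trajectory did not reach {threshold} "
        f"within {max_generations} generations (s={model.s}, H={model.H})"
    )


def fitness_moments(p: float, model: SelectionModel) -> tuple[float, float]:
    """Mean and variance of genotype fitness 1 + h(d) s at frequency p.

    Dosage d is Binomial(k, p) under random union of gametes.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"frequency must lie in [0, 1]; got {p}")
    k = model.k
    w, f = model._tables()
    q = 1.0 - p
    m1 = 0.0
    m2 = 0.0
    for d in range(k + 1):
        g = w[d] * p**d * q ** (k - d)
        m1 += g * f[d]
        m2 += g * f[d] * f[d]
    return m1, max(m2 - m1 * m1, 0.0)


@dataclass
class FixationSummary:
    """Monte-Carlo summary of conditioned fixation times."""

    mean_time: float
    median_time: float
    fixation_probability: float
    n_fixed: int
    n_attempts: int
    times: np.ndarray = field(repr=False)


def fixation_stats(
    model: SelectionModel,
    n_reps: int,
    rng: np.random.Generator,
    max_attempts: int = 10**6,
) -> FixationSummary:
    """Repeat simulate_trajectory and summarise fixation times and rates."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    times = np.empty(n_reps)
    attempts = 0
    for i in range(n_reps):
        traj = simulate_trajectory(model, rng, max_attempts=max_attempts)
        times[i] = traj.length
        attempts += traj.attempts + 1
    return FixationSummary(
        mean_time=float(times.mean()),
        median_time=float(np.median(times)),
        fixation_probability=n_reps / attempts,
        n_fixed=n_reps,
        n_attempts=attempts,
        times=times,
    )


def fixation_probability(
    model: SelectionModel, n_attempts: int, rng: np.random.Generator
) -> float:
    """Estimate P(fix) by running `n_attempts` independent origination trials.

    Trials are advanced in a vectorised batch: each generation applies the
    selection recursion and one Binomial(kN, .) draw per surviving trial.
    The branching-process approximation predicts P(fix) ~ 2 h(1) s, i.e.
    2s/k for additive mutations, when Ns >> 1 >> s.
    """
    if n_attempts < 1:
        raise ValueError("n_attempts must be >= 1")
    kN = model.N * model.k
    p = np.full(n_attempts, 1.0 / kN)
    fixed = 0
    while p.size:
        phat = _expected_frequency_vec(p, model)
        p = rng.binomial(kN, phat) / kN
        fixed += int(np.count_nonzero(p == 1.0))
        p = p[(p > 0.0) & (p < 1.0)]
    return fixed / n_attempts


# ---------------------------------------------------------------------------
# text I/O


def write_trajectory(traj: Trajectory, sink) -> None:
    """Write a trajectory as `# k N s H seed` header plus one frequency/line."""
    m = traj.model
    header = "# k N s H seed\n"
    if m is not None:
        header += f"# {m.k} {m.N} {m.s} {m.H} -\n"
    sink.write(header)
    for p in traj.freqs:
        sink.write(f"{p:.17g}\n")


def read_trajectory(source) -> Trajectory:
    """Read the forward-time trajectory text format written by write_trajectory."""
    model = None
    freqs: list[float] = []
    lines = source.read().splitlines()
    for ln in lines:
        ln = ln.strip()
        if not ln:
            continue
        if ln.startswith("#"):
            parts = ln[1:].split()
            if len(parts) >= 4 and parts[0] not in ("k",):
                try:
                    k, N = int(parts[0]), int(parts[1])
                    s, H = float(parts[2]), float(parts[3])
                    model = SelectionModel(k=k, N=N, s=s, H=H)
                except ValueError:
                    pass
            continue
        freqs.append(float(ln))
    arr = np.asarray(freqs)
    return Trajectory(freqs=arr, fixed=bool(arr.size and arr[-1] == 1.0), model=model)


def write_trajectory_reversed(traj: Trajectory, sink) -> None:
    """Two-column (generations-before-sampling, frequency) layout, backward time.

    This is the orientation consumed by the trajectory-conditioned
    coalescent: row 0 is the sampling generation (frequency 1 for a fixed
    sweep), the last row the origin of the mutation.
    """
    T = traj.length
    for i, p in enumerate(reversed(traj.freqs)):
        sink.write(f"{i}\t{p:.17g}\n")
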