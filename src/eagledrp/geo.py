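"""Golden Eagle Optimization: single-objective GEO and multi-objective MOGEO.

Each search agent (eagle) keeps a memory of the best position it has
visited.  Per iteration an eagle picks a prey — a remembered position of a
flock member (single-objective) or an archived non-dominated solution
selected by a sparsity-weighted roulette wheel (multi-objective) — and
moves along a combination of:

* the **attack vector** A = prey − position (exploitation), and
* the **cruise vector** C, a random direction inside the hyperplane through
  the eagle's position with normal A (exploration): the hyperplane constant
  is d = A·x, all free coordinates are drawn uniform on [0, 1], and the
  pivot coordinate c_k (a_k ≠ 0, chosen uniformly) is solved as
  c_k = (d − Σ_{j≠k} a_j c_j) / a_k, so A·C = 0 exactly.

The step is Δx = r₁ ∘ p_a·A/‖A‖ + r₂ ∘ p_c·C/‖C‖ with elementwise uniform
r₁, r₂ and attack/cruise propensities interpolated linearly (signed) from
their start to end values over the run.  Positions are clipped to the box
after every move.  MOGEO maintains a bounded external archive of mutually
non-dominated solutions; crowding is the printed second-difference density
index, sparsity S = 1 − clip(C, 0, 1), with extreme (boundary) members
assigned sparsity 1 so they are never eliminated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GEOConfig",
    "ArchiveMember",
    "ZeroAttackVector",
    "attack_vector",
    "cruise_destination",
    "step_vector",
    "transition_coefficients",
    "geo_minimize",
    "dominates",
    "crowding_distances",
    "sparsity_scores",
    "roulette_select",
    "archive_insert",
    "mogeo_minimize",
]


class ZeroAttackVector(ValueError):
    """The eagle already sits on its prey; no cruise hyperplane exists."""


@dataclass
class GEOConfig:
    pop_size: int = 50
    max_iter: int = 300
    pa0: float = 2.0
    paT: float = 0.0
    pc0: float = 1.0
    pcT: float = 0.0
    lower: np.ndarray = field(default_factory=lambda: np.array([-1.0]))
    upper: np.ndarray = field(default_factory=lambda: np.array([1.0]))
    seed: int = 0

    def __post_init__(self) -> None:
        self.lower = np.asarray(self.lower, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)
        if self.pop_size < 2:
            raise ValueError("pop_size must be >= 2")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.lower.shape != self.upper.shape or not np.all(self.lower < self.upper):
            raise ValueError("bounds must satisfy lower < upper elementwise")

    @property
    def dim(self) -> int:
        return self.lower.size


@dataclass
class ArchiveMember:
    position: np.ndarray
    objectives: np.ndarray
    crowding: float = 0.0
    sparsity: float = 1.0


def attack_vector(eagle: np.ndarray, prey: np.ndarray) -> np.ndarray:
    """A = prey − eagle (pointing from the eagle to its prey)."""
    eagle = np.asarray(eagle, dtype=float)
    prey = np.asarray(prey, dtype=float)
    if eagle.shape != prey.shape:
        raise ValueError("eagle and prey must share a dimension")
    return prey - eagle


def cruise_destination(
    attack: np.ndarray, eagle: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Cruise vector: destination − eagle, with the destination on the
    hyperplane A·x = A·eagle; orthogonal to the attack vector by
    construction."""
    attack = np.asarray(attack, dtype=float)
    eagle = np.asarray(eagle, dtype=float)
    nonzero = np.flatnonzero(attack)
    if nonzero.size == 0:
        raise ZeroAttackVector("attack vector is zero: eagle is at its prey")
    k = int(rng.choice(nonzero))
    d = float(attack @ eagle)
    c = rng.random(attack.size)
    others = np.arange(attack.size) != k
    c[k] = (d - attack[others] @ c[others]) / attack[k]
    return c - eagle


def step_vector(
    attack: np.ndarray,
    cruise: np.ndarray,
    pa_t: float,
    pc_t: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Δx = r₁∘p_a·Â + r₂∘p_c·Ĉ with unit-normalized terms; a zero-norm
    vector contributes nothing."""
    attack = np.asarray(attack, dtype=float)
    cruise = np.asarray(cruise, dtype=float)
    step = np.zeros_like(attack)
    na = np.linalg.norm(attack)
    if na > 0:
        step += rng.random(attack.size) * pa_t * attack / na
    nc = np.linalg.norm(cruise)
    if nc > 0:
        step += rng.random(cruise.size) * pc_t * cruise / nc
    return step


def transition_coefficients(t: int, cfg: GEOConfig) -> tuple[float, float]:
    """Signed linear interpolation of the attack/cruise propensities.

    t = 0 gives the start values, t = T the end values; T = 0 degenerates to
    the start values."""
    if cfg.max_iter == 0:
        return cfg.pa0, cfg.pc0
    frac = t / cfg.max_iter
    pa = cfg.pa0 + frac * (cfg.paT - cfg.pa0)
    pc = cfg.pc0 + frac * (cfg.pcT - cfg.pc0)
    return pa, pc


def _check_finite(value: float, position: np.ndarray) -> float:
    if not np.isfinite(value):
        raise ValueError(f"objective returned non-finite value at {position}")
    return float(value)


def geo_minimize(objective, cfg: GEOConfig) -> tuple[np.ndarray, float, list[float]]:
    """Single-objective GEO over a box.

    Prey are sampled uniformly from the flock's memories; memories update
    only on improvement, so the returned flock-best history is
    non-increasing.  Deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    dim = cfg.dim
    pos = rng.uniform(cfg.lower, cfg.upper, size=(cfg.pop_size, dim))
    fit = np.array([_check_finite(objective(p), p) for p in pos])
    mem_pos = pos.copy()
    mem_fit = fit.copy()
    history = [float(mem_fit.min())]
    for t in range(1, cfg.max_iter + 1):
        pa_t, pc_t = transition_coefficients(t, cfg)
        for i in range(cfg.pop_size):
            prey = mem_pos[rng.integers(cfg.pop_size)]
            A = attack_vector(pos[i], prey)
            if np.linalg.norm(A) == 0:
                continue  # already at the prey; no move this iteration
            C = cruise_destination(A, pos[i], rng)
            step = step_vector(A, C, pa_t, pc_t, rng)
            pos[i] = np.clip(pos[i] + step, cfg.lower, cfg.upper)
            f = _check_finite(objective(pos[i]), pos[i])
            if f < mem_fit[i]:
                mem_fit[i] = f
                mem_pos[i] = pos[i].copy()
        history.append(float(mem_fit.min()))
    best = int(np.argmin(mem_fit))
    return mem_pos[best].copy(), float(mem_fit[best]), history


# ---------------------------------------------------------------------------
# Multi-objective machinery


def dominates(fa: np.ndarray, fb: np.ndarray) -> bool:
    """Pareto dominance (minimization): fa ≤ fb everywhere, < somewhere."""
    fa = np.asarray(fa, dtype=float)
    fb = np.asarray(fb, dtype=float)
    if fa.shape != fb.shape:
        raise ValueError("objective vectors must share a length")
    return bool(np.all(fa <= fb) and np.any(fa < fb))


def crowding_distances(objectives: np.ndarray) -> np.ndarray:
    """Second-difference crowding index, averaged over objectives.

    For each objective j the archive is sorted by f_j and an interior
    member i contributes ((f_{i+1,j} − f_{i,j}) − (f_{i,j} − f_{i−1,j})) /
    (f_j^max − f_j^min).  Members extreme in any objective get crowding 0
    (maximal retention priority); a degenerate objective range contributes
    0.  The raw index can be negative; :func:`sparsity_scores` clips.
    """
    F = np.atleast_2d(np.asarray(objectives, dtype=float))
    n, n_obj = F.shape
    if n == 0:
        return np.zeros(0)
    crowd = np.zeros(n)
    boundary = np.zeros(n, dtype=bool)
    for j in range(n_obj):
        order = np.argsort(F[:, j], kind="stable")
        rng_j = F[order[-1], j] - F[order[0], j]
        boundary[order[0]] = True
        boundary[order[-1]] = True
        if rng_j == 0 or n < 3:
            continue
        fj = F[order, j]
        second = (fj[2:] - fj[1:-1]) - (fj[1:-1] - fj[:-2])
        crowd[order[1:-1]] += second / rng_j
    crowd /= n_obj
    crowd[boundary] = 0.0
    return crowd


def sparsity_scores(crowding: np.ndarray) -> np.ndarray:
    """S = 1 − C with C clipped to [0, 1]; used as roulette weights."""
    return 1.0 - np.clip(np.asarray(crowding, dtype=float), 0.0, 1.0)


def roulette_select(weights: np.ndarray, rng: np.random.Generator) -> int:
    """Index i with probability w_i / Σw; all-zero weights fall back to
    uniform."""
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("roulette weights must be nonnegative")
    total = w.sum()
    if total == 0:
        return int(rng.integers(w.size))
    return int(rng.choice(w.size, p=w / total))


def _refresh_density(archive: list[ArchiveMember]) -> None:
    if not archive:
        return
    F = np.array([m.objectives for m in archive])
    crowd = crowding_distances(F)
    spars = sparsity_scores(crowd)
    for m, c, s in zip(archive, crowd, spars):
        m.crowding = float(c)
        m.sparsity = float(s)


def archive_insert(
    archive: list[ArchiveMember],
    candidate: ArchiveMember,
    capacity: int,
    rng: np.random.Generator,
) -> list[ArchiveMember]:
    """Insert a candidate, preserving mutual non-dominance and the capacity.

    A dominated (or duplicate-objective) candidate is rejected; members the
    candidate dominates are removed; at capacity one incumbent is
    eliminated by roulette over crowdedness 1 − S (crowded members more
    likely, extremes protected)."""
    for m in archive:
        if dominates(m.objectives, candidate.objectives) or np.array_equal(
            m.objectives, candidate.objectives
        ):
            return archive
    kept = [m for m in archive if not dominates(candidate.objectives, m.objectives)]
    if len(kept) >= capacity:
        _refresh_density(kept)
        weights = np.array([1.0 - m.sparsity for m in kept])
        victim = roulette_select(weights, rng)
        kept.pop(victim)
    kept.append(candidate)
    _refresh_density(kept)
    return kept


def mogeo_minimize(
    objectives, cfg: GEOConfig, capacity: int = 25
) -> list[ArchiveMember]:
    """Multi-objective GEO with an external non-dominated archive.

    Prey selection is a roulette wheel over archive sparsity scores.  An
    eagle whose attack vector is zero adopts the prey as its solution for
    the iteration (no move).  Returns the final archive."""
    rng = np.random.default_rng(cfg.seed)
    dim = cfg.dim
    pos = rng.uniform(cfg.lower, cfg.upper, size=(cfg.pop_size, dim))
    archive: list[ArchiveMember] = []
    for p in pos:
        f = np.asarray(objectives(p), dtype=float)
        if not np.isfinite(f).all():
            raise ValueError(f"objectives returned non-finite values at {p}")
        archive = archive_insert(
            archive, ArchiveMember(position=p.copy(), objectives=f), capacity, rng
        )
    for t in range(1, cfg.max_iter + 1):
        pa_t, pc_t = transition_coefficients(t, cfg)
        for i in range(cfg.pop_size):
            weights = np.array([m.sparsity for m in archive])
            prey = archive[roulette_select(weights, rng)].position
            A = attack_vector(pos[i], prey)
            if np.linalg.norm(A) == 0:
                continue  # the prey itself is this eagle's solution
            C = cruise_destination(A, pos[i], rng)
            step = step_vector(A, C, pa_t, pc_t, rng)
            pos[i] = np.clip(pos[i] + step, cfg.lower, cfg.upper)
            f = np.asarray(objectives(pos[i]), dtype=float)
            if not np.isfinite(f).all():
                raise ValueError(f"objectives returned non-finite values at {pos[i]}")
            archive = archive_insert(
                archive,
                ArchiveMember(position=pos[i].copy(), objectives=f),
                capacity,
                rng,
            )
    return archive
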