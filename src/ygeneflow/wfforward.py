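"""Forward-in-time Wright-Fisher dynamics of a Y-linked allele.

A novel Y haplotype (e.g. one introduced by male-mediated introgression)
is tracked as a frequency among the population's Y copies.  With census
size ``N`` diploid individuals and an even sex ratio there are ``N/2`` Y
chromosomes.  Each generation applies deterministic haploid selection

    p' = p (1 + s) / (1 + p s)

followed by binomial resampling of the ``n_y_copies`` Y chromosomes.
This frequency-based model shares its diffusion limit with an
individual-based Y-chromosome simulation, so fixation probabilities can
be checked against the Kimura diffusion formula

    u(p0) = (1 - exp(-2 N s p0)) / (1 - exp(-2 N s))

with N the number of Y copies (haploid population size).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SelectionParams",
    "TrajectoryOutcome",
    "simulate_y_trajectory",
    "fixation_rate",
    "kimura_fixation_probability",
    "simulate_y_par_linkage",
]

FIXED = "fixed"
LOST = "lost"
SEGREGATING = "segregating"


@dataclass(frozen=True)
class SelectionParams:
    """Parameters of the Y-linked selection experiment.

    ``n_individuals`` is the diploid census size; with a 1:1 sex ratio
    the Y population holds ``n_individuals // 2`` copies.  ``s`` is the
    haploid selective advantage of carrier males, ``p0`` the initial
    frequency of the novel Y (equivalent to incoming male migration).
    """

    n_individuals: int
    s: float
    p0: float
    max_gens: int = 100_000

    def __post_init__(self):
        if self.n_individuals < 2:
            raise ValueError("n_individuals must be >= 2")
        if not 0.0 <= self.p0 <= 1.0:
            raise ValueError("p0 must be in [0, 1]")
        if self.s <= -1.0:
            raise ValueError("s must be > -1")
        if self.max_gens < 0:
            raise ValueError("max_gens must be >= 0")

    @property
    def n_y_copies(self) -> int:
        return self.n_individuals // 2

    @property
    def initial_copies(self) -> int:
        """Nearest-integer initial copy count, floored at 1 when p0 > 0."""
        if self.p0 == 0.0:
            return 0
        return max(1, round(self.p0 * self.n_y_copies))


@dataclass(frozen=True)
class TrajectoryOutcome:
    state: str
    generation_of_absorption: int
    final_frequency: float
    trajectory: np.ndarray | None = None

    def __post_init__(self):
        if self.state == FIXED and self.final_frequency != 1.0:
            raise ValueError("fixed outcome requires final frequency 1")
        if self.state == LOST and self.final_frequency != 0.0:
            raise ValueError("lost outcome requires final frequency 0")
        if self.state == SEGREGATING and not 0.0 < self.final_frequency < 1.0:
            raise ValueError("segregating outcome requires 0 < frequency < 1")


def _select(p: np.ndarray | float, s: float):
    return p * (1.0 + s) / (1.0 + p * s)


def simulate_y_trajectory(
    params: SelectionParams, seed: int, record_trajectory: bool = False
) -> TrajectoryOutcome:
    """Run one replicate to absorption or ``max_gens``."""
    rng = np.random.default_rng(seed)
    n = params.n_y_copies
    copies = params.initial_copies
    traj = [copies / n] if record_trajectory else None
    if copies == 0:
        return TrajectoryOutcome(LOST, 0, 0.0, np.array(traj) if traj else None)
    if copies == n:
        return TrajectoryOutcome(FIXED, 0, 1.0, np.array(traj) if traj else None)
    for gen in range(1, params.max_gens + 1):
        p = _select(copies / n, params.s)
        copies = rng.binomial(n, p)
        if record_trajectory:
            traj.append(copies / n)
        if copies == 0:
            return TrajectoryOutcome(LOST, gen, 0.0, np.array(traj) if traj else None)
        if copies == n:
            return TrajectoryOutcome(FIXED, gen, 1.0, np.array(traj) if traj else None)
    return TrajectoryOutcome(
        SEGREGATING,
        params.max_gens,
        copies / n,
        np.array(traj) if record_trajectory else None,
    )


def fixation_rate(params: SelectionParams, n_reps: int, seed: int) -> dict:
    """Fractions fixed / lost / segregating over independent replicates.

    Replicates run vectorised: a single binomial draw per generation
    covers all still-segregating replicates, which makes the full
    100,000-generation, 200,000-individual experiment a sub-minute
    computation.  Returns a 95% Wilson CI on the fixed fraction.
    """
    from scipy import stats

    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    n = params.n_y_copies
    copies = np.full(n_reps, params.initial_copies, dtype=np.int64)
    active = (copies > 0) & (copies < n)
    for _ in range(params.max_gens):
        if not active.any():
            break
        p = _select(copies[active] / n, params.s)
        copies[active] = rng.binomial(n, p)
        active = (copies > 0) & (copies < n)
    n_fixed = int((copies == n).sum())
    n_lost = int((copies == 0).sum())
    n_seg = n_reps - n_fixed - n_lost
    ci = stats.binomtest(n_fixed, n_reps).proportion_ci(0.95, method="wilson")
    return {
        "fraction_fixed": n_fixed / n_reps,
        "fraction_lost": n_lost / n_reps,
        "fraction_segregating": n_seg / n_reps,
        "n_fixed": n_fixed,
        "n_lost": n_lost,
        "n_segregating": n_seg,
        "n_reps": n_reps,
        "ci_fixed_low": float(ci.low),
        "ci_fixed_high": float(ci.high),
    }


def kimura_fixation_probability(n_y_copies: int, s: float, p0: float) -> float:
    """Diffusion-approximation fixation probability of a haploid allele.

    ``u(p0) = (1 - e^(-2 N s p0)) / (1 - e^(-2 N s))`` with ``N`` the
    number of Y copies; the neutral limit is ``u = p0``.  Evaluated with
    ``expm1`` and a log-space branch so it is overflow-safe for large
    ``|2 N s|``.
    """
    if n_y_copies <= 0:
        raise ValueError("n_y_copies must be > 0")
    if not 0.0 <= p0 <= 1.0:
        raise ValueError("p0 must be in [0, 1]")
    if s == 0.0:
        return p0
    a = 2.0 * n_y_copies * s
    # u = expm1(-a p0) / expm1(-a)
    if a > 0:
        # both arguments negative; expm1 is safe
        return math.expm1(-a * p0) / math.expm1(-a)
    # deleterious: -a > 0 may overflow; work with logs when large
    if -a > 700.0 or -a * p0 > 700.0:
        # expm1(x) ~ e^x for large x: u ~ e^{-a p0 - (-a)} = e^{a (1 - p0)}
        log_u = (-a * p0) - (-a)
        return math.exp(log_u) if log_u < 0 else 1.0
    return math.expm1(-a * p0) / math.expm1(-a)


def simulate_y_par_linkage(
    n_y_copies: int,
    p0: float,
    rec_prob_per_gen: float,
    max_gens: int,
    seed: int,
    record_every: int = 1,
) -> dict:
    """Two-locus model of linkage between a donor Y and its PAR allele.

    Every Y chromosome carries a pseudoautosomal allele.  A fraction
    ``p0`` of Y copies starts as donor Ys, each initially carrying a
    donor PAR allele; the X-borne PAR pool (three X copies per Y copy
    under an even sex ratio) starts with one donor allele per migrant
    male, who arrives carrying one X alongside his Y.  Each male
    meiosis swaps the Y-linked PAR allele with a random allele from the
    X pool with probability ``rec_prob_per_gen``; both pools then drift
    (binomial resampling).  With a large native pool, the association
    between donor-Y background and donor-PAR allele decays roughly as
    ``(1 - rec_prob)^t``.

    Returns trajectories of the donor-PAR frequency among donor-Y
    carriers, among all Ys, and in the X pool.
    """
    if not 0.0 <= rec_prob_per_gen <= 1.0:
        raise ValueError("rec_prob_per_gen must be in [0, 1]")
    if not 0.0 <= p0 <= 1.0:
        raise ValueError("p0 must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_y = int(n_y_copies)
    n_x = 3 * n_y  # X-borne PAR copies at 1:1 sex ratio
    donor_y = max(1, round(p0 * n_y)) if p0 > 0 else 0
    native_y = n_y - donor_y
    # PAR-donor allele counts on each Y background and in the X pool;
    # each migrant male contributes one donor X to the pool
    par_on_donor_y = donor_y
    par_on_native_y = 0
    par_on_x = min(donor_y, n_x)

    t_on_donor = [1.0 if donor_y else 0.0]
    t_overall = [par_on_donor_y / n_y if n_y else 0.0]
    t_x = [par_on_x / n_x if n_x else 0.0]
    for gen in range(1, max_gens + 1):
        qx = par_on_x / n_x
        # recombination: swaps between Y-linked PAR alleles and the X pool
        if rec_prob_per_gen > 0.0:
            rec_d = rng.binomial(donor_y, rec_prob_per_gen) if donor_y else 0
            rec_n = rng.binomial(native_y, rec_prob_per_gen) if native_y else 0
            # among recombining chromosomes, how many carried the donor allele
            qd = par_on_donor_y / donor_y if donor_y else 0.0
            qn = par_on_native_y / native_y if native_y else 0.0
            out_d = rng.binomial(rec_d, qd) if rec_d else 0
            out_n = rng.binomial(rec_n, qn) if rec_n else 0
            in_d = rng.binomial(rec_d, qx) if rec_d else 0
            in_n = rng.binomial(rec_n, qx) if rec_n else 0
            par_on_donor_y += in_d - out_d
            par_on_native_y += in_n - out_n
            par_on_x += out_d + out_n - in_d - in_n
            par_on_x = min(max(par_on_x, 0), n_x)
            par_on_donor_y = min(max(par_on_donor_y, 0), donor_y)
            par_on_native_y = min(max(par_on_native_y, 0), native_y)
        # drift within each compartment (Y haplotype frequencies held
        # fixed so the linkage decay is isolated from Y loss)
        if donor_y:
            par_on_donor_y = rng.binomial(donor_y, par_on_donor_y / donor_y)
        if native_y:
            par_on_native_y = rng.binomial(native_y, par_on_native_y / native_y)
        par_on_x = rng.binomial(n_x, par_on_x / n_x) if n_x else 0
        if gen % record_every == 0 or gen == max_gens:
            t_on_donor.append(par_on_donor_y / donor_y if donor_y else 0.0)
            t_overall.append((par_on_donor_y + par_on_native_y) / n_y)
            t_x.append(par_on_x / n_x)
    return {
        "donor_par_freq_on_donor_y": np.array(t_on_donor),
        "donor_par_freq_overall": np.array(t_overall),
        "donor_par_freq_x_pool": np.array(t_x),
        "generations": max_gens,
    }
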