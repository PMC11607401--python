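"""Demographic models with split events and introgression pulses.

A :class:`DemographicModel` describes a set of populations (terminal and
ancestral), backward-in-time split events that merge a derived population
into its ancestral population, and instantaneous unidirectional
introgression pulses that move each lineage of a destination population
into a source population with probability ``phi``.

All times are measured backward from the present in generations; years
are a reporting conversion only.  Effective population sizes are diploid
individuals.  A Y-linked version of an autosomal model divides every Ne
by four (Ne_Y / Ne_autosome = 0.25 under an even sex ratio) and, under
male-biased dispersal, doubles every pulse proportion (capped at 1).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace

import yaml

logger = logging.getLogger("ygeneflow")

AUTOSOMAL = "autosomal"
Y_LINKED = "y_linked"

#: default mutation rate, substitutions per bp per generation
DEFAULT_MU = 4.82e-9
#: default generation time, years
DEFAULT_GEN_TIME = 10.0
#: default diploid effective size used for every branch unless overridden
DEFAULT_NE = 200_000.0


class ModelValidationError(ValueError):
    """Raised when a demographic model violates its invariants."""


@dataclass(frozen=True)
class NeEpoch:
    """Constant-Ne interval ``[start_gen, end_gen)`` backward in time."""

    start_gen: float
    end_gen: float  # may be math.inf for the final epoch
    ne: float


@dataclass(frozen=True)
class Population:
    name: str
    epochs: tuple[NeEpoch, ...]

    def ne_at(self, t_gen: float) -> float:
        for ep in self.epochs:
            if ep.start_gen <= t_gen < ep.end_gen:
                return ep.ne
        # fall back to the last epoch for times beyond its end
        return self.epochs[-1].ne


@dataclass(frozen=True)
class Split:
    """At ``time_gen`` (backward) lineages in ``derived`` move to ``ancestral``."""

    time_gen: float
    derived: str
    ancestral: str


@dataclass(frozen=True)
class Pulse:
    """At ``time_gen`` each lineage in ``dest`` moves to ``source`` w.p. ``phi``.

    Backward in time this is the standard representation of forward
    migration from *source* into *dest* with proportion phi.
    """

    time_gen: float
    source: str
    dest: str
    phi: float


@dataclass(frozen=True)
class DemographicModel:
    populations: tuple[Population, ...]
    splits: tuple[Split, ...]
    pulses: tuple[Pulse, ...]
    mu: float = DEFAULT_MU
    gen_time: float = DEFAULT_GEN_TIME
    locus_ploidy_mode: str = AUTOSOMAL

    # -- lookup helpers -------------------------------------------------
    def population(self, name: str) -> Population:
        for p in self.populations:
            if p.name == name:
                return p
        raise KeyError(name)

    @property
    def population_names(self) -> list[str]:
        return [p.name for p in self.populations]

    def merge_time(self, name: str) -> float:
        """Backward time at which population ``name`` merges into its parent."""
        for s in self.splits:
            if s.derived == name:
                return s.time_gen
        return math.inf

    def parent(self, name: str) -> str | None:
        for s in self.splits:
            if s.derived == name:
                return s.ancestral
        return None

    def leaf_names(self) -> list[str]:
        ancestral = {s.ancestral for s in self.splits}
        return [p.name for p in self.populations if p.name not in ancestral]

    def is_alive(self, name: str, t_gen: float) -> bool:
        """True if the population exists (has not merged) at time ``t_gen``."""
        birth = max(
            (s.time_gen for s in self.splits if s.ancestral == name), default=0.0
        )
        return birth <= t_gen < self.merge_time(name)

    def mrca_time(self, a: str, b: str) -> float:
        """Backward time at which the branches of ``a`` and ``b`` join."""
        lineage_a, t = a, 0.0
        ancestors_a: dict[str, float] = {}
        while lineage_a is not None:
            ancestors_a[lineage_a] = t
            t = self.merge_time(lineage_a)
            lineage_a = self.parent(lineage_a)
        lineage_b = b
        while lineage_b is not None:
            if lineage_b in ancestors_a:
                return max(
                    ancestors_a[lineage_b],
                    0.0 if lineage_b == b else self._birth_time(lineage_b),
                )
            lineage_b = self.parent(lineage_b)
        raise ModelValidationError(f"populations {a!r} and {b!r} never join")

    def _birth_time(self, name: str) -> float:
        return max((s.time_gen for s in self.splits if s.ancestral == name), default=0.0)

    # -- validation -----------------------------------------------------
    def validate(self) -> None:
        names = self.population_names
        if len(set(names)) != len(names):
            raise ModelValidationError("duplicate population names")
        for pop in self.populations:
            if not pop.epochs:
                raise ModelValidationError(f"{pop.name}: no Ne epochs")
            for ep in pop.epochs:
                if ep.ne <= 0:
                    raise ModelValidationError(f"{pop.name}: Ne must be > 0")
                if ep.end_gen <= ep.start_gen:
                    raise ModelValidationError(f"{pop.name}: empty Ne epoch")
        known = set(names)
        derived_seen = set()
        for s in self.splits:
            if s.derived not in known or s.ancestral not in known:
                raise ModelValidationError(f"split references unknown population: {s}")
            if s.derived in derived_seen:
                raise ModelValidationError(f"{s.derived} merges twice")
            derived_seen.add(s.derived)
            if s.time_gen < 0:
                raise ModelValidationError("negative split time")
            parent_merge = self.merge_time(s.ancestral)
            if not s.time_gen < parent_merge:
                raise ModelValidationError(
                    f"split of {s.derived} at {s.time_gen} is not younger than the "
                    f"merge of its ancestor {s.ancestral} at {parent_merge}"
                )
        # single connected tree: exactly one root
        roots = [n for n in names if self.parent(n) is None]
        if len(roots) != 1:
            raise ModelValidationError(f"model must have exactly one root, got {roots}")
        for p in self.pulses:
            if not 0.0 <= p.phi <= 1.0:
                raise ModelValidationError(f"pulse phi {p.phi} outside [0, 1]")
            if p.time_gen < 0:
                raise ModelValidationError("negative pulse time")
            for side in (p.source, p.dest):
                if side not in known:
                    raise ModelValidationError(f"pulse references unknown population {side!r}")
                if not self.is_alive(side, p.time_gen):
                    raise ModelValidationError(
                        f"pulse at {p.time_gen}: population {side!r} not alive"
                    )
            if p.time_gen >= self.mrca_time(p.source, p.dest):
                raise ModelValidationError(
                    f"pulse at {p.time_gen} is older than the MRCA of "
                    f"{p.source!r} and {p.dest!r}"
                )
        if self.mu < 0:
            raise ModelValidationError("mu must be >= 0")
        if self.gen_time <= 0:
            raise ModelValidationError("gen_time must be > 0")
        if self.locus_ploidy_mode not in (AUTOSOMAL, Y_LINKED):
            raise ModelValidationError(
                f"unknown locus_ploidy_mode {self.locus_ploidy_mode!r}"
            )

    # -- (de)serialization ----------------------------------------------
    def to_dict(self) -> dict:
        return {
            "mu": self.mu,
            "gen_time": self.gen_time,
            "locus_ploidy_mode": self.locus_ploidy_mode,
            "populations": [
                {
                    "name": p.name,
                    "epochs": [
                        [e.start_gen, None if math.isinf(e.end_gen) else e.end_gen, e.ne]
                        for e in p.epochs
                    ],
                }
                for p in self.populations
            ],
            "splits": [[s.time_gen, s.derived, s.ancestral] for s in self.splits],
            "pulses": [[p.time_gen, p.source, p.dest, p.phi] for p in self.pulses],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DemographicModel":
        pops = tuple(
            Population(
                name=p["name"],
                epochs=tuple(
                    NeEpoch(e[0], math.inf if e[1] is None else e[1], e[2])
                    for e in p["epochs"]
                ),
            )
            for p in d["populations"]
        )
        model = cls(
            populations=pops,
            splits=tuple(Split(*s) for s in d["splits"]),
            pulses=tuple(Pulse(*p) for p in d["pulses"]),
            mu=float(d.get("mu", DEFAULT_MU)),
            gen_time=float(d.get("gen_time", DEFAULT_GEN_TIME)),
            locus_ploidy_mode=d.get("locus_ploidy_mode", AUTOSOMAL),
        )
        model.validate()
        return model

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "DemographicModel":
        return cls.from_dict(yaml.safe_load(text))

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


# ---------------------------------------------------------------------------
# scaling conventions
# ---------------------------------------------------------------------------

def scale_generations_to_years(t_gen: float, g: float) -> float:
    """Convert a time in generations to years (``t_gen * g``)."""
    if t_gen < 0:
        raise ValueError("t_gen must be >= 0")
    if g <= 0:
        raise ValueError("generation time must be > 0")
    return t_gen * g


def harmonic_mean_ne(segments: list[tuple[float, float]]) -> float:
    """Duration-weighted harmonic mean of Ne over branch segments.

    Collapses a chain of branches with differing Ne into the single Ne
    that yields the same total coalescent intensity, the standard way to
    summarise effective size along a lineage affected by gene flow.

    Parameters
    ----------
    segments:
        ``(duration_gen, ne)`` pairs; durations and Ne must be positive.
    """
    if not segments:
        raise ValueError("segments must be non-empty")
    total = 0.0
    inv = 0.0
    for dur, ne in segments:
        if dur <= 0 or ne <= 0:
            raise ValueError("durations and Ne must be > 0")
        total += dur
        inv += dur / ne
    return total / inv


def derive_y_model(auto_model: DemographicModel) -> DemographicModel:
    """Y-linked version of an autosomal model: Ne/4, pulse phi doubled.

    Split times are unchanged.  Doubled phi is capped at 1 (with a
    warning), reflecting purely male-mediated gene flow.
    """
    if auto_model.locus_ploidy_mode != AUTOSOMAL:
        raise ValueError("model is already y_linked")
    pops = tuple(
        Population(
            p.name,
            tuple(NeEpoch(e.start_gen, e.end_gen, e.ne / 4.0) for e in p.epochs),
        )
        for p in auto_model.populations
    )
    pulses = []
    for p in auto_model.pulses:
        phi = 2.0 * p.phi
        if phi > 1.0:
            logger.warning(
                "pulse at %s gen: doubled phi %.3f capped at 1", p.time_gen, phi
            )
            phi = 1.0
        pulses.append(replace(p, phi=phi))
    return replace(
        auto_model, populations=pops, pulses=tuple(pulses), locus_ploidy_mode=Y_LINKED
    )


# ---------------------------------------------------------------------------
# the default guenon model
# ---------------------------------------------------------------------------

#: taxa of the nine-species system: seven *Cercopithecus* guenons from the
#: mona, cephus and mitis species groups, *C. neglectus*, and the rhesus
#: macaque outgroup.
GUENON_TAXA = (
    "denti",
    "wolfi",
    "pogonias",
    "mona",
    "neglectus",
    "cephus",
    "nictitans",
    "mitis_opisthostictus",
    "macaque",
)

# backward split times in generations (10-year generations).  The
# denti/wolfi split (110 kgen) and the ~8 Mya mona/mitis crown are fitted
# values; the remaining internal times are plausible defaults consistent
# with the pulse schedule, overridable in config.
DEFAULT_SPLIT_TIMES = {
    "denti_wolfi": 110_000.0,
    "mona_east": 200_000.0,  # pogonias joins (denti, wolfi)
    "mitis_group": 250_000.0,  # nictitans / mitis_opisthostictus
    "mona_group": 380_000.0,  # mona joins the eastern mona clade
    "cephus_mitis": 650_000.0,
    "cercopithecus": 800_000.0,  # mona group / (cephus, mitis) ~ 8 Mya
    "neglectus_join": 900_000.0,
    "root": 1_350_000.0,  # macaque outgroup
}

#: pulse 1: mitis-group ancestor -> eastern mona clade ancestor, 2.1%
PULSE1 = (310_000.0, "anc_mitis_group", "anc_mona_east", 0.021)
#: pulse 2: cephus ancestor -> eastern mona clade ancestor, 8.5%
PULSE2 = (270_000.0, "cephus", "anc_mona_east", 0.085)
#: pulse 3 time: 10,000 generations after the denti/wolfi split
PULSE3_TIME = 100_000.0
#: fitted pulse-3 proportion (0.2%)
DEFAULT_PHI3 = 0.002


def default_guenon_model(
    phi3: float = DEFAULT_PHI3,
    ne: float = DEFAULT_NE,
    ne_overrides: dict[str, float] | None = None,
    mu: float = DEFAULT_MU,
    gen_time: float = DEFAULT_GEN_TIME,
    split_times: dict[str, float] | None = None,
    event1_phi: float = PULSE1[3],
) -> DemographicModel:
    """The fitted guenon demography with three unidirectional pulses.

    Parameters
    ----------
    phi3:
        Proportion of the pulse from *C. mitis opisthostictus* into
        *C. denti* 100,000 generations ago (the variable of interest).
    ne:
        Diploid Ne applied to every branch not overridden.
    ne_overrides:
        Per-population Ne, keyed by population name.
    event1_phi:
        Proportion of the mitis-ancestor pulse (an alternative event
        ordering gives 0.8% instead of 2.1%).
    """
    st = dict(DEFAULT_SPLIT_TIMES)
    if split_times:
        st.update(split_times)
    over = ne_overrides or {}

    def pop(name: str) -> Population:
        return Population(name, (NeEpoch(0.0, math.inf, over.get(name, ne)),))

    names = list(GUENON_TAXA) + [
        "anc_denti_wolfi",
        "anc_mona_east",
        "anc_mona_group",
        "anc_mitis_group",
        "anc_cephus_mitis",
        "anc_cercopithecus",
        "anc_guenon",
        "anc_root",
    ]
    splits = (
        Split(st["denti_wolfi"], "denti", "anc_denti_wolfi"),
        Split(st["denti_wolfi"], "wolfi", "anc_denti_wolfi"),
        Split(st["mona_east"], "anc_denti_wolfi", "anc_mona_east"),
        Split(st["mona_east"], "pogonias", "anc_mona_east"),
        Split(st["mitis_group"], "nictitans", "anc_mitis_group"),
        Split(st["mitis_group"], "mitis_opisthostictus", "anc_mitis_group"),
        Split(st["mona_group"], "anc_mona_east", "anc_mona_group"),
        Split(st["mona_group"], "mona", "anc_mona_group"),
        Split(st["cephus_mitis"], "cephus", "anc_cephus_mitis"),
        Split(st["cephus_mitis"], "anc_mitis_group", "anc_cephus_mitis"),
        Split(st["cercopithecus"], "anc_mona_group", "anc_cercopithecus"),
        Split(st["cercopithecus"], "anc_cephus_mitis", "anc_cercopithecus"),
        Split(st["neglectus_join"], "neglectus", "anc_guenon"),
        Split(st["neglectus_join"], "anc_cercopithecus", "anc_guenon"),
        Split(st["root"], "anc_guenon", "anc_root"),
        Split(st["root"], "macaque", "anc_root"),
    )
    pulses = [
        Pulse(PULSE1[0], PULSE1[1], PULSE1[2], event1_phi),
        Pulse(PULSE2[0], PULSE2[1], PULSE2[2], PULSE2[3]),
    ]
    if phi3 > 0:
        pulses.append(Pulse(PULSE3_TIME, "mitis_opisthostictus", "denti", phi3))
    model = DemographicModel(
        populations=tuple(pop(n) for n in names),
        splits=splits,
        pulses=tuple(pulses),
        mu=mu,
        gen_time=gen_time,
    )
    model.validate()
    return model


#: quartet used throughout for D statistics: (P1, P2, P3, outgroup)
D_QUARTET = ("wolfi", "denti", "mitis_opisthostictus", "macaque")
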