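"""Structured-coalescent simulation with introgression pulses.

Simulates gene trees backward in time over a :class:`~ygeneflow.demography.
DemographicModel`: within a population of diploid size ``Ne`` each pair of
lineages coalesces at rate ``1/(2 Ne)`` per generation (continuous-time
exponential waiting between event boundaries), at a pulse each lineage in
the destination population relocates to the source with probability
``phi``, and at a split all lineages of the derived population move to
the ancestral one.  Mutations are overlaid under the infinite-sites
model.  Intra-locus recombination is not simulated: loci are independent
non-recombining genealogies.

The inner per-locus loop is JIT-compiled (numba); the same kernel drives
single-tree simulation, monophyly counting and the batched ABBA/BABA
experiment used for the migration-grid D-statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .demography import AUTOSOMAL, DemographicModel, Y_LINKED

__all__ = [
    "GeneTree",
    "LocusSpec",
    "CompiledModel",
    "simulate_gene_tree",
    "overlay_mutations",
    "simulate_genotype_matrix",
    "monophyly_frequency",
    "par_linkage_profile",
    "child_seeds",
]


def child_seeds(seed: int, n: int) -> np.ndarray:
    """Derive ``n`` independent 32-bit child seeds from a user seed.

    Counter-based (numpy ``SeedSequence``): reproducible and
    order-independent, so replicate ``i`` always sees the same stream no
    matter how many replicates run.
    """
    return np.random.SeedSequence(int(seed)).generate_state(n, dtype=np.uint32)


# ---------------------------------------------------------------------------
# model compilation: names -> indices, events -> flat sorted arrays
# ---------------------------------------------------------------------------

_EV_PULSE = 0
_EV_SPLIT = 1
_EV_NE = 2


@dataclass(frozen=True)
class CompiledModel:
    """Flat, kernel-ready representation of a demographic model."""

    pop_index: dict
    ne0: np.ndarray
    ev_time: np.ndarray
    ev_kind: np.ndarray
    ev_a: np.ndarray
    ev_b: np.ndarray
    ev_phi: np.ndarray


def compile_model(model: DemographicModel) -> CompiledModel:
    model.validate()
    pop_index = {p.name: i for i, p in enumerate(model.populations)}
    ne0 = np.array([p.epochs[0].ne for p in model.populations], dtype=np.float64)
    events: list[tuple[float, int, int, int, float]] = []
    for p in model.pulses:
        # backward in time: lineages in dest move to source w.p. phi
        events.append((p.time_gen, _EV_PULSE, pop_index[p.dest], pop_index[p.source], p.phi))
    for s in model.splits:
        events.append((s.time_gen, _EV_SPLIT, pop_index[s.derived], pop_index[s.ancestral], 0.0))
    for p in model.populations:
        for ep in p.epochs[1:]:
            events.append((ep.start_gen, _EV_NE, pop_index[p.name], 0, ep.ne))
    events.sort(key=lambda e: (e[0], e[1]))
    return CompiledModel(
        pop_index=pop_index,
        ne0=ne0,
        ev_time=np.array([e[0] for e in events], dtype=np.float64),
        ev_kind=np.array([e[1] for e in events], dtype=np.int64),
        ev_a=np.array([e[2] for e in events], dtype=np.int64),
        ev_b=np.array([e[3] for e in events], dtype=np.int64),
        ev_phi=np.array([e[4] for e in events], dtype=np.float64),
    )


# ---------------------------------------------------------------------------
# the coalescent kernel
# ---------------------------------------------------------------------------

@njit(cache=True)
def _sim_tree_kernel(lin_pop0, n_pops, ne0, ev_time, ev_kind, ev_a, ev_b, ev_phi):
    """Simulate one genealogy; numba RNG state must be seeded by the caller.

    Returns ``(parent, node_time)`` over ``2n-1`` nodes: leaves
    ``0..n-1``, internal nodes appended in coalescence order (so a parent
    index always exceeds its children), root parent ``-1``.
    """
    n = lin_pop0.shape[0]
    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    node_time = np.zeros(n_nodes, dtype=np.float64)
    act_node = np.empty(n, dtype=np.int64)
    act_pop = np.empty(n, dtype=np.int64)
    for i in range(n):
        act_node[i] = i
        act_pop[i] = lin_pop0[i]
    n_act = n
    ne = ne0.copy()
    cnt = np.zeros(n_pops, dtype=np.int64)
    t = 0.0
    ei = 0
    n_ev = ev_time.shape[0]
    next_node = n
    while n_act > 1:
        for p in range(n_pops):
            cnt[p] = 0
        for i in range(n_act):
            cnt[act_pop[i]] += 1
        rate = 0.0
        for p in range(n_pops):
            k = cnt[p]
            if k >= 2:
                rate += k * (k - 1) / (4.0 * ne[p])
        t_ev = ev_time[ei] if ei < n_ev else np.inf
        if rate > 0.0:
            w = np.random.exponential(1.0 / rate)
        else:
            w = np.inf
        if t + w < t_ev:
            t = t + w
            # choose the population proportionally to its pair rate
            r = np.random.random() * rate
            acc = 0.0
            chosen = -1
            for p in range(n_pops):
                k = cnt[p]
                if k >= 2:
                    acc += k * (k - 1) / (4.0 * ne[p])
                    if r < acc:
                        chosen = p
                        break
            if chosen < 0:  # guard against float round-off
                for p in range(n_pops - 1, -1, -1):
                    if cnt[p] >= 2:
                        chosen = p
                        break
            # pick an unordered pair uniformly within the population
            k = cnt[chosen]
            a = int(np.random.random() * k)
            b = int(np.random.random() * (k - 1))
            if b >= a:
                b += 1
            ia = -1
            ib = -1
            seen = 0
            for i in range(n_act):
                if act_pop[i] == chosen:
                    if seen == a:
                        ia = i
                    if seen == b:
                        ib = i
                    seen += 1
            node = next_node
            next_node += 1
            node_time[node] = t
            parent[act_node[ia]] = node
            parent[act_node[ib]] = node
            act_node[ia] = node
            act_node[ib] = act_node[n_act - 1]
            act_pop[ib] = act_pop[n_act - 1]
            n_act -= 1
        elif ei < n_ev:
            t = t_ev
            kind = ev_kind[ei]
            if kind == 0:  # pulse: dest(a) -> source(b) w.p. phi
                for i in range(n_act):
                    if act_pop[i] == ev_a[ei] and np.random.random() < ev_phi[ei]:
                        act_pop[i] = ev_b[ei]
            elif kind == 1:  # split: derived(a) -> ancestral(b)
                for i in range(n_act):
                    if act_pop[i] == ev_a[ei]:
                        act_pop[i] = ev_b[ei]
            else:  # Ne change on population a
                ne[ev_a[ei]] = ev_phi[ei]
            ei += 1
        else:  # no events left and zero rate: lineages can never meet
            node_time[0] = -1.0
            return parent, node_time
    return parent, node_time


@njit(cache=True)
def _seeded_sim_tree(seed, lin_pop0, n_pops, ne0, ev_time, ev_kind, ev_a, ev_b, ev_phi):
    np.random.seed(seed)
    return _sim_tree_kernel(lin_pop0, n_pops, ne0, ev_time, ev_kind, ev_a, ev_b, ev_phi)


@njit(cache=True)
def _batch_abba_kernel(
    seeds,
    lin_pop0,
    n_pops,
    ne0,
    ev_time,
    ev_kind,
    ev_a,
    ev_b,
    ev_phi,
    group,       # int64[n_lineages]: 0..3 = P1,P2,P3,O; -1 = unused
    group_size,  # int64[4]
    mut_scale,   # mu * length_bp
):
    """Per-locus frequency-weighted ABBA and BABA sums for many loci.

    Every mutation on a branch yields the same site pattern (infinite
    sites), so each branch contributes ``Poisson(len * mu * L)`` copies
    of one pattern.  Sites where the outgroup is polymorphic are skipped;
    where the outgroup is fixed for the derived allele the site is
    flipped so the outgroup always carries the ancestral state.
    """
    n_loci = seeds.shape[0]
    n = lin_pop0.shape[0]
    n_nodes = 2 * n - 1
    abba = np.zeros(n_loci, dtype=np.float64)
    baba = np.zeros(n_loci, dtype=np.float64)
    desc = np.zeros((n_nodes, 4), dtype=np.int64)
    for li in range(n_loci):
        np.random.seed(seeds[li])
        parent, node_time = _sim_tree_kernel(
            lin_pop0, n_pops, ne0, ev_time, ev_kind, ev_a, ev_b, ev_phi
        )
        for v in range(n_nodes):
            for g in range(4):
                desc[v, g] = 0
        for v in range(n):
            g = group[v]
            if g >= 0:
                desc[v, g] = 1
        a_sum = 0.0
        b_sum = 0.0
        for v in range(n_nodes - 1):  # root (last node) has no branch above
            pa = parent[v]
            if pa >= 0:
                for g in range(4):
                    desc[pa, g] += desc[v, g]
                blen = node_time[pa] - node_time[v]
                if blen > 0.0:
                    m = np.random.poisson(blen * mut_scale)
                    if m > 0:
                        d_o = desc[v, 3]
                        if 0 < d_o < group_size[3]:
                            continue  # outgroup polymorphic: skip site
                        p1 = desc[v, 0] / group_size[0]
                        p2 = desc[v, 1] / group_size[1]
                        p3 = desc[v, 2] / group_size[2]
                        if d_o == group_size[3]:
                            # polarize: the outgroup carries the ancestral state
                            p1 = 1.0 - p1
                            p2 = 1.0 - p2
                            p3 = 1.0 - p3
                        a_sum += m * (1.0 - p1) * p2 * p3
                        b_sum += m * p1 * (1.0 - p2) * p3
        abba[li] = a_sum
        baba[li] = b_sum
    return abba, baba


@njit(cache=True)
def _batch_clade_kernel(
    seeds,
    lin_pop0,
    n_pops,
    ne0,
    ev_time,
    ev_kind,
    ev_a,
    ev_b,
    ev_phi,
    in_target,  # bool per leaf
):
    """Count simulations where the target leaves form an exclusive clade."""
    n_loci = seeds.shape[0]
    n = lin_pop0.shape[0]
    n_nodes = 2 * n - 1
    n_target = 0
    for i in range(n):
        if in_target[i]:
            n_target += 1
    hits = 0
    d_t = np.zeros(n_nodes, dtype=np.int64)
    d_a = np.zeros(n_nodes, dtype=np.int64)
    for li in range(n_loci):
        np.random.seed(seeds[li])
        parent, node_time = _sim_tree_kernel(
            lin_pop0, n_pops, ne0, ev_time, ev_kind, ev_a, ev_b, ev_phi
        )
        for v in range(n_nodes):
            d_t[v] = 0
            d_a[v] = 0
        for v in range(n):
            d_a[v] = 1
            if in_target[v]:
                d_t[v] = 1
        for v in range(n_nodes - 1):
            pa = parent[v]
            if pa >= 0:
                d_t[pa] += d_t[v]
                d_a[pa] += d_a[v]
        # the MRCA of the target set is the lowest node containing all of it
        for v in range(n_nodes):
            if d_t[v] == n_target:
                if d_a[v] == n_target:
                    hits += 1
                break
    return hits


# ---------------------------------------------------------------------------
# gene trees
# ---------------------------------------------------------------------------

@dataclass
class GeneTree:
    """Binary genealogy with coalescence times in generations.

    Leaves are nodes ``0..n-1``; internal node indices exceed their
    children's.  ``labels[i]`` is ``(sample_name, population)``.
    """

    parent: np.ndarray
    node_time: np.ndarray
    labels: list

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    def tmrca(self) -> float:
        return float(self.node_time[self.root])

    def branch_length(self, v: int) -> float:
        pa = self.parent[v]
        if pa < 0:
            return 0.0
        return float(self.node_time[pa] - self.node_time[v])

    def total_branch_length(self) -> float:
        return float(
            sum(self.branch_length(v) for v in range(self.n_nodes - 1))
        )

    def children(self) -> list[list[int]]:
        ch: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for v in range(self.n_nodes - 1):
            ch[self.parent[v]].append(v)
        return ch

    def leaf_sets(self) -> list[set]:
        """Descendant-leaf index set per node (children precede parents)."""
        sets: list[set] = [{v} if v < self.n_leaves else set() for v in range(self.n_nodes)]
        for v in range(self.n_nodes - 1):
            sets[self.parent[v]] |= sets[v]
        return sets

    def is_monophyletic(self, leaf_indices: set) -> bool:
        """True if ``leaf_indices`` form an exclusive clade."""
        target = set(leaf_indices)
        if not target:
            raise ValueError("empty leaf set")
        for s in self.leaf_sets():
            if s == target:
                return True
        return False

    def to_newick(self) -> str:
        ch = self.children()

        def rec(v: int) -> str:
            if v < self.n_leaves:
                name = self.labels[v][0]
            else:
                name = ""
            if ch[v]:
                inner = ",".join(rec(c) for c in ch[v])
                body = f"({inner}){name}"
            else:
                body = name
            pa = self.parent[v]
            if pa < 0:
                return body
            return f"{body}:{self.node_time[pa] - self.node_time[v]:.6g}"

        return rec(self.root) + ";"

    def validate(self) -> None:
        for v in range(self.n_nodes - 1):
            pa = self.parent[v]
            if pa < self.n_leaves or pa >= self.n_nodes:
                raise ValueError("parent indices must point at internal nodes")
            if not self.node_time[pa] > self.node_time[v]:
                raise ValueError("times must strictly increase root-ward")
        counts = np.zeros(self.n_nodes, dtype=int)
        for v in range(self.n_nodes - 1):
            counts[self.parent[v]] += 1
        if any(counts[self.n_leaves:] != 2):
            raise ValueError("tree must be binary")


@dataclass(frozen=True)
class LocusSpec:
    """Locus layout for genotype simulation."""

    length_bp: int
    n_loci: int
    mode: str = AUTOSOMAL

    def __post_init__(self):
        if self.length_bp <= 0:
            raise ValueError("length_bp must be > 0")
        if self.n_loci <= 0:
            raise ValueError("n_loci must be > 0")
        if self.mode not in (AUTOSOMAL, Y_LINKED):
            raise ValueError(f"unknown mode {self.mode!r}")


def _lineage_layout(model: DemographicModel, samples: dict, cm: CompiledModel):
    """Expand a {population: n_individuals} map into haploid lineages.

    A diploid individual contributes two lineages in autosomal mode and
    one in y_linked mode.
    """
    per_ind = 2 if model.locus_ploidy_mode == AUTOSOMAL else 1
    lin_pop = []
    labels = []
    for pop, count in samples.items():
        if pop not in cm.pop_index:
            raise ValueError(f"unknown population {pop!r}")
        if count < 0:
            raise ValueError("negative sample count")
        for i in range(count):
            for h in range(per_ind):
                suffix = f"_{h}" if per_ind == 2 else ""
                labels.append((f"{pop}_{i}{suffix}", pop))
                lin_pop.append(cm.pop_index[pop])
    if len(lin_pop) < 2:
        raise ValueError("need at least two lineages in total")
    return np.array(lin_pop, dtype=np.int64), labels


def _kernel_args(cm: CompiledModel):
    return (
        len(cm.ne0),
        cm.ne0,
        cm.ev_time,
        cm.ev_kind,
        cm.ev_a,
        cm.ev_b,
        cm.ev_phi,
    )


def simulate_gene_tree(
    model: DemographicModel, samples: dict, seed: int
) -> GeneTree:
    """Simulate one genealogy for the given sample configuration.

    ``samples`` maps population name to the number of sampled
    individuals.  The returned tree has branch lengths in generations.
    """
    if seed is None or int(seed) < 0:
        raise ValueError("seed must be a non-negative integer")
    cm = compile_model(model)
    lin_pop, labels = _lineage_layout(model, samples, cm)
    kseed = int(child_seeds(seed, 1)[0])
    parent, node_time = _seeded_sim_tree(kseed, lin_pop, *_kernel_args(cm))
    if node_time[0] < 0:
        raise RuntimeError("lineages cannot reach a common ancestor (disconnected model)")
    tree = GeneTree(parent=parent, node_time=node_time, labels=labels)
    return tree


def overlay_mutations(
    tree: GeneTree, length_bp: int, mu: float, seed: int
) -> np.ndarray:
    """Infinite-sites mutation overlay.

    Each branch receives ``Poisson(branch_length * mu * length_bp)``
    mutations, each at its own site.  Returns a ``(n_sites, n_leaves)``
    0/1 array of derived-allele patterns (one row per segregating site).
    """
    if mu < 0 or length_bp < 0:
        raise ValueError("mu and length_bp must be >= 0")
    rng = np.random.default_rng(seed)
    n = tree.n_leaves
    sets = tree.leaf_sets()
    rows = []
    for v in range(tree.n_nodes - 1):
        m = rng.poisson(tree.branch_length(v) * mu * length_bp)
        if m > 0:
            row = np.zeros(n, dtype=np.int8)
            row[list(sets[v])] = 1
            for _ in range(m):
                rows.append(row)
    if not rows:
        return np.zeros((0, n), dtype=np.int8)
    return np.vstack(rows)


def simulate_genotype_matrix(
    model: DemographicModel,
    locus_spec: LocusSpec,
    samples: dict,
    seed: int,
):
    """Simulate independent loci and stack their site patterns.

    Returns a :class:`~ygeneflow.popstats.GenotypeMatrix` whose
    chromosome field records the locus of origin (``locus_0`` ...) and
    whose positions are 1-based within the locus.  In autosomal mode the
    two lineages of each individual are paired into a diploid dosage; in
    y_linked mode dosages are haploid 0/1.  Deterministic given the seed.
    """
    from .popstats import GenotypeMatrix  # deferred: avoid import cycle

    if model.locus_ploidy_mode == AUTOSOMAL and locus_spec.mode == Y_LINKED:
        raise ValueError("y_linked locus spec requires a y_linked model (derive_y_model)")
    cm = compile_model(model)
    lin_pop, labels = _lineage_layout(model, samples, cm)
    per_ind = 2 if model.locus_ploidy_mode == AUTOSOMAL else 1
    n_lin = len(lin_pop)
    n_ind = n_lin // per_ind
    seeds = child_seeds(seed, 2 * locus_spec.n_loci)
    chroms: list[str] = []
    pos: list[int] = []
    dosage_rows = []
    kargs = _kernel_args(cm)
    for li in range(locus_spec.n_loci):
        parent, node_time = _seeded_sim_tree(int(seeds[2 * li]), lin_pop, *kargs)
        if node_time[0] < 0:
            raise RuntimeError("disconnected model")
        tree = GeneTree(parent=parent, node_time=node_time, labels=labels)
        patt = overlay_mutations(
            tree, locus_spec.length_bp, model.mu, int(seeds[2 * li + 1])
        )
        n_sites = patt.shape[0]
        if n_sites == 0:
            continue
        rng = np.random.default_rng(int(seeds[2 * li + 1]) + 1)
        n_avail = min(n_sites, locus_spec.length_bp)
        site_pos = np.sort(
            rng.choice(locus_spec.length_bp, size=n_avail, replace=False) + 1
        )
        patt = patt[:n_avail]
        if per_ind == 2:
            dos = patt.reshape(patt.shape[0], n_ind, 2).sum(axis=2)
        else:
            dos = patt
        dosage_rows.append(dos)
        chroms.extend([f"locus_{li}"] * n_avail)
        pos.extend(site_pos.tolist())
    sample_names = (
        [labels[2 * i][0].rsplit("_", 1)[0] for i in range(n_ind)]
        if per_ind == 2
        else [lab[0] for lab in labels]
    )
    pops = (
        [labels[2 * i][1] for i in range(n_ind)]
        if per_ind == 2
        else [lab[1] for lab in labels]
    )
    dosage = (
        np.vstack(dosage_rows).astype(np.float64)
        if dosage_rows
        else np.zeros((0, n_ind))
    )
    return GenotypeMatrix(
        chrom=np.array(chroms, dtype=object),
        pos=np.array(pos, dtype=np.int64),
        dosage=dosage,
        samples=sample_names,
        populations=dict(zip(sample_names, pops)),
        ploidy=per_ind,
        locus_length=locus_spec.length_bp,
    )


def batch_abba_baba(
    model: DemographicModel,
    quartet_samples: dict,
    groups: tuple[str, str, str, str],
    n_loci: int,
    length_bp: int,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus frequency-weighted (ABBA, BABA) sums over many loci.

    Fast path for D-statistic experiments: mutations on a branch all
    share one site pattern, so per-locus sums are accumulated directly
    from branch lengths and descendant counts without materialising
    genotypes.  ``groups`` names the (P1, P2, P3, outgroup) populations.
    """
    cm = compile_model(model)
    lin_pop, labels = _lineage_layout(model, quartet_samples, cm)
    group = np.full(len(lin_pop), -1, dtype=np.int64)
    for i, (_, pop) in enumerate(labels):
        if pop in groups:
            group[i] = groups.index(pop)
    group_size = np.array(
        [int((group == g).sum()) for g in range(4)], dtype=np.int64
    )
    if (group_size == 0).any():
        raise ValueError("every quartet population must be sampled")
    seeds = child_seeds(seed, n_loci).astype(np.int64)
    return _batch_abba_kernel(
        seeds,
        lin_pop,
        *_kernel_args(cm),
        group,
        group_size,
        model.mu * length_bp,
    )


def monophyly_frequency(
    model: DemographicModel,
    taxon_a: str,
    taxon_b: str,
    n_sims: int,
    seed: int,
    samples: dict | None = None,
) -> dict:
    """Fraction of simulated genealogies where two taxa form a clade.

    Simulates ``n_sims`` independent gene trees and counts those in which
    the union of samples from ``taxon_a`` and ``taxon_b`` is an exclusive
    clade.  Returns the fraction with a 95% binomial (Wilson) CI.
    """
    from scipy import stats

    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    if samples is None:
        samples = {name: 1 for name in model.leaf_names()}
    for t in (taxon_a, taxon_b):
        if samples.get(t, 0) < 1:
            raise ValueError(f"taxon {t!r} not sampled")
    cm = compile_model(model)
    lin_pop, labels = _lineage_layout(model, samples, cm)
    in_target = np.array(
        [pop in (taxon_a, taxon_b) for _, pop in labels], dtype=np.bool_
    )
    seeds = child_seeds(seed, n_sims).astype(np.int64)
    hits = int(
        _batch_clade_kernel(seeds, lin_pop, *_kernel_args(cm), in_target)
    )
    ci = stats.binomtest(hits, n_sims).proportion_ci(0.95, method="wilson")
    return {
        "fraction": hits / n_sims,
        "n_sims": n_sims,
        "hits": hits,
        "ci_low": float(ci.low),
        "ci_high": float(ci.high),
    }


def par_linkage_profile(
    model: DemographicModel,
    par_rec_multiplier: float,
    n_sims: int,
    seed: int,
    par_length_bp: int = 150_000,
    n_bins: int = 15,
    autosomal_rec_rate: float = 4.48e-9,
    phi: float = 0.01,
    n_y_copies: int = 100_000,
    max_gens: int = 10_000,
):
    """Donor-ancestry linkage along a PAR flanking an introgressed Y.

    The pseudoautosomal region is modelled as distance bins from the
    Y-linked boundary; the per-generation probability that a bin's allele
    recombines away from its Y background grows with distance
    (``multiplier * autosomal_rec_rate * distance``).  Each bin runs the
    two-locus forward model (:func:`ygeneflow.wfforward.
    simulate_y_par_linkage`) seeded with a donor-Y frequency of ``phi``.

    Returns a DataFrame with, per bin, the final donor-PAR-allele
    frequency among donor-Y carriers and overall, averaged over sims.
    """
    import pandas as pd

    from .wfforward import simulate_y_par_linkage

    if par_rec_multiplier <= 0:
        raise ValueError("par_rec_multiplier must be > 0")
    del model  # bin structure is model-independent; phi and Ne are explicit
    bin_edges = np.linspace(0, par_length_bp, n_bins + 1)
    mid = 0.5 * (bin_edges[:-1] + bin_edges[1:])
    seeds = child_seeds(seed, n_bins * n_sims)
    rows = []
    for bi, d in enumerate(mid):
        rec = min(1.0, par_rec_multiplier * autosomal_rec_rate * d)
        on_y = []
        overall = []
        for si in range(n_sims):
            res = simulate_y_par_linkage(
                n_y_copies=n_y_copies,
                p0=phi,
                rec_prob_per_gen=rec,
                max_gens=max_gens,
                seed=int(seeds[bi * n_sims + si]),
            )
            on_y.append(res["donor_par_freq_on_donor_y"][-1])
            overall.append(res["donor_par_freq_overall"][-1])
        rows.append(
            {
                "bin_start": bin_edges[bi],
                "bin_end": bin_edges[bi + 1],
                "distance_bp": d,
                "rec_prob_per_gen": rec,
                "donor_par_on_donor_y": float(np.mean(on_y)),
                "donor_par_overall": float(np.mean(overall)),
            }
        )
    return pd.DataFrame(rows)
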