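"""Sliding-window phylogenies and introgression-topology classification.

Per genomic window a pairwise distance matrix is built from genotypes
(p-distance, optionally Jukes-Cantor corrected), a neighbor-joining tree
is constructed, and the rooted topology is classified: a window is
``y_like`` when the focal taxon is nested inside a monophyletic donor-
group clade as sister to the donor species while its own species group
(without it) stays monophyletic — the signature of the introgressed-Y
genealogy.  Adjacent ``y_like`` windows merge into candidate regions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger("ygeneflow")

__all__ = [
    "NJTree",
    "TopologyClass",
    "window_distance_matrix",
    "neighbor_joining",
    "classify_window_topology",
    "scan_genome",
    "SaturationError",
]

Y_LIKE = "y_like"
SPECIES_LIKE = "species_like"
OTHER = "other"
UNRESOLVED = "unresolved"


class SaturationError(ValueError):
    """p-distance beyond the Jukes-Cantor domain (p >= 0.75)."""


def window_distance_matrix(
    genotypes: np.ndarray,
    ploidy: int = 2,
    model: str = "p_distance",
) -> np.ndarray:
    """Pairwise distances between samples from a (sites x samples) block.

    The per-site distance between two samples is the absolute dosage
    difference divided by the ploidy, averaged over sites where both are
    genotyped; this is the p-distance for haploid data and the expected
    allele mismatch fraction for diploids.  ``jc69`` applies the
    Jukes-Cantor correction ``-(3/4) ln(1 - 4 p / 3)``.

    Pairs with no comparable sites get ``NaN`` (the caller downgrades
    such windows to unresolved).
    """
    if model not in ("p_distance", "jc69"):
        raise ValueError(f"unknown distance model {model!r}")
    g = np.asarray(genotypes, dtype=float)
    if g.ndim != 2 or g.shape[1] < 3:
        raise ValueError("need a (sites x samples) block with >= 3 samples")
    n = g.shape[1]
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = ~np.isnan(g[:, i]) & ~np.isnan(g[:, j])
            if not both.any():
                dist[i, j] = dist[j, i] = np.nan
                continue
            p = float(np.abs(g[both, i] - g[both, j]).mean() / ploidy)
            if model == "jc69":
                if p >= 0.75:
                    raise SaturationError(
                        f"p-distance {p:.3f} >= 0.75: Jukes-Cantor saturated"
                    )
                p = -0.75 * math.log1p(-4.0 * p / 3.0)
            dist[i, j] = dist[j, i] = p
    return dist


def jc69_distance(p: float) -> float:
    """Jukes-Cantor corrected distance for a proportion of differences."""
    if p < 0:
        raise ValueError("p must be >= 0")
    if p >= 0.75:
        raise SaturationError(f"p-distance {p} >= 0.75")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


@dataclass
class NJTree:
    """Unrooted NJ tree: Newick string plus its split system.

    ``clades`` holds the leaf-name set of every internal edge side, which
    is all a rooted-clade query needs once an outgroup is chosen.
    """

    newick: str
    leaves: list
    clades: list  # list[frozenset[str]]

    def rooted_clades(self, outgroup_leaves) -> set:
        """Clades of the tree rooted on the outgroup.

        Every split contributes the side not containing the outgroup.
        """
        og = frozenset(outgroup_leaves)
        if not og <= frozenset(self.leaves):
            raise ValueError("outgroup leaves not all present in tree")
        all_leaves = frozenset(self.leaves)
        out = set()
        for c in self.clades:
            side = c if not (c & og) else all_leaves - c
            if side and not (side & og):
                out.add(side)
        # every leaf is trivially a clade
        for leaf in all_leaves - og:
            out.add(frozenset([leaf]))
        return out


def neighbor_joining(dist: np.ndarray, labels: list) -> NJTree:
    """Canonical Saitou-Nei neighbor joining.

    Ties in the Q criterion break toward the lowest (i, j) index pair;
    negative branch lengths are clamped to zero with the deficit
    transferred to the sister branch.  Missing distances are an error —
    callers downgrade such windows to unresolved.
    """
    d = np.array(dist, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n) or n < 3:
        raise ValueError("need a square matrix with >= 3 taxa")
    if np.isnan(d).any():
        raise ValueError("distance matrix contains missing values")
    if not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0.0):
        raise ValueError("matrix must be symmetric with zero diagonal")
    if len(labels) != n:
        raise ValueError("labels must match matrix size")

    nodes = [(str(lab), frozenset([str(lab)])) for lab in labels]
    clades: list[frozenset] = []
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        r = {i: sum(d[i, j] for j in active if j != i) for i in active}
        best = None
        best_q = math.inf
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * d[i, j] - r[i] - r[j]
                if q < best_q - 1e-12:
                    best_q = q
                    best = (ai, aj)
        ai, aj = best
        i, j = active[ai], active[aj]
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        new_set = nodes[i][1] | nodes[j][1]
        new_nwk = f"({nodes[i][0]}:{li:.10g},{nodes[j][0]}:{lj:.10g})"
        clades.append(new_set)
        # distances to the new node
        new_idx = d.shape[0]
        d = np.pad(d, ((0, 1), (0, 1)))
        for k in active:
            if k in (i, j):
                continue
            d[new_idx, k] = d[k, new_idx] = 0.5 * (d[i, k] + d[j, k] - d[i, j])
        nodes.append((new_nwk, new_set))
        active = [k for k in active if k not in (i, j)] + [new_idx]
    a, b, c = active
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    la, lb, lc = (max(0.0, x) for x in (la, lb, lc))
    newick = (
        f"({nodes[a][0]}:{la:.10g},{nodes[b][0]}:{lb:.10g},{nodes[c][0]}:{lc:.10g});"
    )
    for k in (a, b, c):
        clades.append(nodes[k][1])
    leaves = [str(lab) for lab in labels]
    return NJTree(newick=newick, leaves=leaves, clades=clades)


@dataclass(frozen=True)
class TopologyClass:
    label: str
    checks: dict


def classify_window_topology(
    tree: NJTree,
    species_map: dict,
    group_map: dict,
    focal: str,
    donor_species: str,
    outgroup: str,
    sister_species: str | None = None,
) -> TopologyClass:
    """Classify a window tree against the introgressed-Y topology.

    ``species_map`` assigns each leaf to a species; ``group_map`` assigns
    each species to a species group.  The window is ``y_like`` only if,
    after rooting on the outgroup, all three hold: the focal species is
    inside a monophyletic donor-group clade; it is sister to the donor
    species; and its own group without it remains monophyletic.  It is
    ``species_like`` when the focal species sits inside its own
    monophyletic group as sister to its species-tree sister.
    """
    missing = [l for l in tree.leaves if l not in species_map]
    if missing:
        raise ValueError(f"leaves without species assignment: {missing}")

    def leaves_of_species(sp) -> frozenset:
        return frozenset(l for l in tree.leaves if species_map[l] == sp)

    def leaves_of_group(gr) -> frozenset:
        return frozenset(
            l for l in tree.leaves if group_map[species_map[l]] == gr
        )

    og_leaves = leaves_of_species(outgroup)
    if not og_leaves:
        raise ValueError(f"outgroup {outgroup!r} absent from tree")
    focal_leaves = leaves_of_species(focal)
    donor_leaves = leaves_of_species(donor_species)
    if not focal_leaves or not donor_leaves:
        raise ValueError("focal or donor species absent from tree")
    donor_group = leaves_of_group(group_map[donor_species])
    own_group = leaves_of_group(group_map[focal])
    clades = tree.rooted_clades(og_leaves)

    checks = {
        "focal_in_donor_group_clade": (donor_group | focal_leaves) in clades,
        "focal_sister_to_donor": (donor_leaves | focal_leaves) in clades,
        "own_group_without_focal_monophyletic": (own_group - focal_leaves) in clades
        or len(own_group - focal_leaves) <= 1,
    }
    if all(checks.values()):
        return TopologyClass(Y_LIKE, checks)
    if sister_species is not None:
        sister_leaves = leaves_of_species(sister_species)
        checks["own_group_monophyletic"] = own_group in clades or len(own_group) <= 1
        checks["focal_sister_to_sister_species"] = (
            focal_leaves | sister_leaves
        ) in clades
        if checks["own_group_monophyletic"] and checks["focal_sister_to_sister_species"]:
            return TopologyClass(SPECIES_LIKE, checks)
    return TopologyClass(OTHER, checks)


def scan_genome(
    matrix,
    species_map: dict,
    group_map: dict,
    focal: str,
    donor_species: str,
    outgroup: str,
    sister_species: str | None = None,
    window_bp: int = 10_000,
    min_variable_sites: int = 20,
    max_missing: float = 0.5,
    distance_model: str = "p_distance",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify non-overlapping windows across a genotype matrix.

    Windows with more than ``max_missing`` missing genotype fraction or
    fewer than ``min_variable_sites`` variable sites are ``unresolved``.
    Returns the per-window class table and a BED-like table of merged
    ``y_like`` regions.
    """
    from .popstats import GenotypeMatrix  # typing/fixture convenience

    assert isinstance(matrix, GenotypeMatrix)
    rows = []
    variant = matrix.is_variant()
    for c in pd.unique(matrix.chrom):
        m = matrix.chrom == c
        length = matrix.locus_length or int(matrix.pos[m].max())
        for start in range(0, length, window_bp):
            end = min(start + window_bp, length)
            w = m & (matrix.pos - 1 >= start) & (matrix.pos - 1 < end)
            label = UNRESOLVED
            n_var = int((w & variant).sum())
            block = matrix.dosage[w]
            miss_frac = float(np.isnan(block).mean()) if block.size else 1.0
            if n_var >= min_variable_sites and miss_frac <= max_missing:
                try:
                    dist = window_distance_matrix(
                        block, ploidy=matrix.ploidy, model=distance_model
                    )
                    if np.isnan(dist).any():
                        raise ValueError("missing distances")
                    tree = neighbor_joining(dist, matrix.samples)
                    label = classify_window_topology(
                        tree,
                        species_map,
                        group_map,
                        focal,
                        donor_species,
                        outgroup,
                        sister_species,
                    ).label
                except (ValueError, SaturationError) as exc:
                    logger.debug("window %s:%d-%d unresolved: %s", c, start, end, exc)
                    label = UNRESOLVED
            rows.append(
                {
                    "chrom": c,
                    "start": start,
                    "end": end,
                    "n_variable_sites": n_var,
                    "class": label,
                }
            )
    table = pd.DataFrame(rows)
    regions = []
    for c, g in table.groupby("chrom", sort=False):
        g = g.sort_values("start")
        cur = None
        for _, r in g.iterrows():
            if r["class"] == Y_LIKE:
                if cur is not None and r["start"] == cur["end"]:
                    cur["end"] = r["end"]
                    cur["n_windows"] += 1
                else:
                    if cur is not None:
                        regions.append(cur)
                    cur = {
                        "chrom": c,
                        "start": r["start"],
                        "end": r["end"],
                        "n_windows": 1,
                    }
            else:
                if cur is not None:
                    regions.append(cur)
                    cur = None
        if cur is not None:
            regions.append(cur)
    region_table = pd.DataFrame(
        regions, columns=["chrom", "start", "end", "n_windows"]
    )
    return table, region_table
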