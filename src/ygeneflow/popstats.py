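"""Population-genetic site statistics on genotype matrices.

Implements the genotype masking rules (allele-balance and depth filters,
removal of Y-chromosomal sites with any heterozygote), frequency-weighted
ABBA/BABA counting with Patterson's D and its 20-blocks-per-chromosome
block-jackknife Z-score, the windowed f_d admixture-fraction statistic,
nucleotide divergence dXY with an invariant-site (pixy-style)
denominator, and the scaling of dXY to coalescence time,

    t = (dXY / (2 mu)) * g .

Windows are 0-based half-open internally; VCF positions are 1-based and
converted on read.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger("ygeneflow")

__all__ = [
    "GenotypeMatrix",
    "ABBACounts",
    "read_vcf",
    "write_vcf",
    "apply_site_filters",
    "abba_baba_counts",
    "d_statistic",
    "block_jackknife_z",
    "f_d_windows",
    "dxy_windows",
    "coalescence_time_from_dxy",
]


# ---------------------------------------------------------------------------
# genotype matrix
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Sites x samples derived-allele dosages with optional read metadata.

    ``dosage`` holds 0/1/2 for diploids (0/1 for haploid Y data) with
    ``NaN`` for missing calls.  ``depth`` and ``minor_fraction`` are
    optional per-site, per-sample arrays used by the genotype filters.
    ``positions`` are 1-based as in VCF.
    """

    chrom: np.ndarray
    pos: np.ndarray
    dosage: np.ndarray
    samples: list
    populations: dict
    ploidy: int = 2
    depth: np.ndarray | None = None
    minor_fraction: np.ndarray | None = None
    locus_length: int | None = None
    includes_invariant: bool = False

    def __post_init__(self):
        if self.dosage.shape != (len(self.chrom), len(self.samples)):
            raise ValueError("dosage shape must be (n_sites, n_samples)")
        with np.errstate(invalid="ignore"):
            if np.nanmax(self.dosage, initial=0) > self.ploidy:
                raise ValueError("dosage exceeds ploidy")

    @property
    def n_sites(self) -> int:
        return len(self.chrom)

    def sample_index(self, names) -> np.ndarray:
        idx = []
        for n in names:
            if n not in self.samples:
                raise KeyError(f"unknown sample {n!r}")
            idx.append(self.samples.index(n))
        return np.array(idx, dtype=int)

    def population_samples(self, pop: str) -> list:
        out = [s for s in self.samples if self.populations.get(s) == pop]
        if not out:
            raise KeyError(f"no samples assigned to population {pop!r}")
        return out

    def population_frequency(self, pop: str) -> np.ndarray:
        """Per-site derived-allele frequency in a population (NaN if no calls)."""
        cols = self.sample_index(self.population_samples(pop))
        d = self.dosage[:, cols]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(d, axis=1) / self.ploidy

    def is_variant(self) -> np.ndarray:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mx = np.nanmax(self.dosage, axis=1)
            mn = np.nanmin(self.dosage, axis=1)
        return np.nan_to_num(mx, nan=0.0) > 0

    def subset_sites(self, mask: np.ndarray) -> "GenotypeMatrix":
        return replace(
            self,
            chrom=self.chrom[mask],
            pos=self.pos[mask],
            dosage=self.dosage[mask],
            depth=None if self.depth is None else self.depth[mask],
            minor_fraction=None
            if self.minor_fraction is None
            else self.minor_fraction[mask],
        )

    def with_invariant_sites(self) -> "GenotypeMatrix":
        """Add fully genotyped all-ancestral rows for unlisted positions.

        Requires ``locus_length``; used on simulator output, where every
        position not carrying a mutation is known to be invariant.
        """
        if self.locus_length is None:
            raise ValueError("locus_length required to expand invariant sites")
        chroms_all = []
        pos_all = []
        rows = []
        for c in pd.unique(self.chrom):
            m = self.chrom == c
            present = set(self.pos[m].tolist())
            inv = [p for p in range(1, self.locus_length + 1) if p not in present]
            chroms_all.extend([c] * self.locus_length)
            pos_all.extend(sorted(present) + inv)
        # rebuild in position order per chromosome
        new_chrom = []
        new_pos = []
        dos_rows = []
        for c in pd.unique(self.chrom):
            m = self.chrom == c
            existing = {int(p): i for i, p in zip(np.where(m)[0], self.pos[m])}
            for p in range(1, self.locus_length + 1):
                new_chrom.append(c)
                new_pos.append(p)
                if p in existing:
                    dos_rows.append(self.dosage[existing[p]])
                else:
                    dos_rows.append(np.zeros(len(self.samples)))
        return replace(
            self,
            chrom=np.array(new_chrom, dtype=object),
            pos=np.array(new_pos, dtype=np.int64),
            dosage=np.vstack(dos_rows) if dos_rows else self.dosage,
            depth=None,
            minor_fraction=None,
            includes_invariant=True,
        )


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------

def write_vcf(matrix: GenotypeMatrix, path: str) -> None:
    """Write a minimal VCF; invariant sites get ``ALT='.'`` records."""
    variant = matrix.is_variant()
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in pd.unique(matrix.chrom):
            length = matrix.locus_length or int(matrix.pos[matrix.chrom == c].max())
            fh.write(f"##contig=<ID={c},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.samples)
            + "\n"
        )
        for i in range(matrix.n_sites):
            alt = "T" if variant[i] else "."
            gts = []
            for j in range(len(matrix.samples)):
                d = matrix.dosage[i, j]
                if np.isnan(d):
                    gts.append("./." if matrix.ploidy == 2 else ".")
                elif matrix.ploidy == 2:
                    gts.append({0: "0/0", 1: "0/1", 2: "1/1"}[int(d)])
                else:
                    gts.append(str(int(d)))
            fh.write(
                f"{matrix.chrom[i]}\t{matrix.pos[i]}\t.\tA\t{alt}\t.\tPASS\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


def read_vcf(path: str, populations: dict, ploidy: int = 2) -> GenotypeMatrix:
    """Read a (possibly invariant-site-containing) VCF into a matrix.

    ``populations`` maps sample name to population.  Multi-allelic and
    indel records are skipped with a log message.
    """
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    chroms = []
    pos = []
    rows = []
    n_skipped = 0
    saw_invariant = False
    for v in vcf:
        if len(v.ALT) > 1 or any(len(a) != 1 for a in v.ALT) or len(v.REF) != 1:
            n_skipped += 1
            continue
        if len(v.ALT) == 0:
            saw_invariant = True
        row = np.full(len(samples), np.nan)
        for j, g in enumerate(v.genotypes):
            alleles = [a for a in g[:-1] if a is not None]
            if not alleles or any(a < 0 for a in alleles):
                continue
            row[j] = float(sum(1 for a in alleles if a > 0))
        chroms.append(v.CHROM)
        pos.append(v.POS)
        rows.append(row)
    if n_skipped:
        logger.info("read_vcf: skipped %d multi-allelic/indel records", n_skipped)
    return GenotypeMatrix(
        chrom=np.array(chroms, dtype=object),
        pos=np.array(pos, dtype=np.int64),
        dosage=np.vstack(rows) if rows else np.zeros((0, len(samples))),
        samples=samples,
        populations=dict(populations),
        ploidy=ploidy,
        includes_invariant=saw_invariant,
    )


def read_popmap(path: str) -> dict:
    """Two-column TSV (sample, population) -> dict."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "population"])
    return dict(zip(df["sample"], df["population"]))


# ---------------------------------------------------------------------------
# genotype filtering
# ---------------------------------------------------------------------------

def apply_site_filters(
    matrix: GenotypeMatrix,
    mean_depth: dict,
    y_chroms: tuple = (),
) -> tuple[GenotypeMatrix, dict]:
    """Mask low-confidence genotypes and purge heterozygous Y sites.

    Heterozygous calls with minor-allele read fraction < 0.25 become
    missing; per-sample calls with depth below half or above twice the
    relevant mean (``mean_depth[sample]``, genome-wide or chromosome-wide
    as chosen by the caller) become missing, with both boundaries
    retained inclusively.  On chromosomes named in ``y_chroms`` any site
    left heterozygous in any sample is dropped for all samples.
    """
    if matrix.depth is None:
        raise ValueError("depth metadata absent: filters require 'depth'")
    if matrix.minor_fraction is None:
        raise ValueError(
            "allele-balance metadata absent: filters require 'minor_fraction'"
        )
    for s in matrix.samples:
        if s not in mean_depth:
            raise ValueError(f"mean_depth missing for sample {s!r}")
    dosage = matrix.dosage.copy()
    het = dosage == 1 if matrix.ploidy == 2 else np.zeros_like(dosage, dtype=bool)
    bad_balance = het & (matrix.minor_fraction < 0.25)
    means = np.array([mean_depth[s] for s in matrix.samples])
    bad_depth = (matrix.depth < 0.5 * means) | (matrix.depth > 2.0 * means)
    dosage[bad_balance | bad_depth] = np.nan
    report = {
        "masked_allele_balance": int(bad_balance.sum()),
        "masked_depth": int((bad_depth & ~np.isnan(matrix.dosage)).sum()),
        "dropped_y_het_sites": 0,
    }
    out = replace(matrix, dosage=dosage)
    if y_chroms:
        on_y = np.isin(matrix.chrom, list(y_chroms))
        het_after = (dosage == 1) & (matrix.ploidy == 2)
        site_het = het_after.any(axis=1)
        drop = on_y & site_het
        report["dropped_y_het_sites"] = int(drop.sum())
        out = out.subset_sites(~drop)
    return out, report


# ---------------------------------------------------------------------------
# ABBA/BABA and Patterson's D
# ---------------------------------------------------------------------------

@dataclass
class ABBACounts:
    """Frequency-weighted ABBA/BABA sums with per-block partial sums."""

    abba: float
    baba: float
    block_abba: np.ndarray
    block_baba: np.ndarray
    n_sites_used: int = 0

    def __post_init__(self):
        if not (
            math.isclose(self.block_abba.sum(), self.abba, rel_tol=1e-9, abs_tol=1e-9)
            and math.isclose(self.block_baba.sum(), self.baba, rel_tol=1e-9, abs_tol=1e-9)
        ):
            raise ValueError("block sums must total the global sums")


def _polarized_frequencies(matrix: GenotypeMatrix, pops: tuple):
    """Per-site derived freqs (p1, p2, p3) polarized by the outgroup.

    Sites where the outgroup is polymorphic or ungenotyped are masked
    out; where the outgroup is fixed for the derived allele the site is
    flipped so the outgroup always carries the ancestral state.
    """
    p1, p2, p3, po = (matrix.population_frequency(p) for p in pops)
    usable = ~(np.isnan(p1) | np.isnan(p2) | np.isnan(p3) | np.isnan(po))
    usable &= (po == 0.0) | (po == 1.0)
    flip = usable & (po == 1.0)
    for arr in (p1, p2, p3):
        arr[flip] = 1.0 - arr[flip]
    return p1, p2, p3, usable


def _chromosome_spans(matrix: GenotypeMatrix) -> dict:
    spans = {}
    for c in pd.unique(matrix.chrom):
        m = matrix.chrom == c
        end = matrix.locus_length or int(matrix.pos[m].max())
        spans[c] = end
    return spans


def abba_baba_counts(
    matrix: GenotypeMatrix,
    pops: tuple,
    blocks_per_chrom: int = 20,
) -> ABBACounts:
    """Frequency-weighted ABBA/BABA sums for a (P1, P2, P3, O) quartet.

    Per usable biallelic site,

        ABBA += (1 - p1) p2 p3 (1 - pO)
        BABA += p1 (1 - p2) p3 (1 - pO)

    with population derived-allele frequencies polarized by the outgroup
    (so pO = 0 after polarization).  Sums are accumulated into
    ``blocks_per_chrom`` equal-length genomic spans per chromosome for
    the block jackknife.
    """
    p1, p2, p3, usable = _polarized_frequencies(matrix, pops)
    w_abba = np.where(usable, (1 - p1) * p2 * p3, 0.0)
    w_baba = np.where(usable, p1 * (1 - p2) * p3, 0.0)
    if not usable.any():
        logger.warning("abba_baba_counts: no usable sites")
    spans = _chromosome_spans(matrix)
    chrom_list = list(spans)
    chrom_idx = {c: i for i, c in enumerate(chrom_list)}
    n_blocks = len(chrom_list) * blocks_per_chrom
    block_abba = np.zeros(n_blocks)
    block_baba = np.zeros(n_blocks)
    for c in chrom_list:
        m = matrix.chrom == c
        length = spans[c]
        width = max(1, math.ceil(length / blocks_per_chrom))
        local = np.minimum((matrix.pos[m] - 1) // width, blocks_per_chrom - 1)
        bidx = chrom_idx[c] * blocks_per_chrom + local
        np.add.at(block_abba, bidx, w_abba[m])
        np.add.at(block_baba, bidx, w_baba[m])
    return ABBACounts(
        abba=float(block_abba.sum()),
        baba=float(block_baba.sum()),
        block_abba=block_abba,
        block_baba=block_baba,
        n_sites_used=int(usable.sum()),
    )


def d_statistic(counts: ABBACounts) -> float:
    """Patterson's D = (ABBA - BABA) / (ABBA + BABA)."""
    denom = counts.abba + counts.baba
    if denom <= 0:
        logger.warning("d_statistic: zero denominator, D undefined")
        return float("nan")
    return (counts.abba - counts.baba) / denom


def block_jackknife_z(counts: ABBACounts) -> tuple[float, float]:
    """Delete-one-block jackknife SE of D and the Z-score D/SE.

    Empty blocks (no sites) are excluded from the jackknife.  With
    degenerate SE = 0, Z is 0 for D = 0 and signed infinity otherwise
    (with a warning).
    """
    occupied = (counts.block_abba + counts.block_baba) > 0
    n = int(occupied.sum())
    if n < 2:
        raise ValueError("block jackknife requires >= 2 non-empty blocks")
    d_full = d_statistic(counts)
    ab = counts.block_abba[occupied]
    bb = counts.block_baba[occupied]
    tot_a = ab.sum()
    tot_b = bb.sum()
    d_loo = (tot_a - ab - (tot_b - bb)) / (tot_a - ab + tot_b - bb)
    se = float(np.sqrt((n - 1) / n * np.sum((d_loo - d_loo.mean()) ** 2)))
    if se == 0.0:
        if d_full == 0.0:
            return 0.0, 0.0
        logger.warning("block_jackknife_z: SE = 0 with D != 0, Z infinite")
        return 0.0, math.copysign(math.inf, d_full)
    return se, d_full / se


def d_from_block_sums(block_abba: np.ndarray, block_baba: np.ndarray):
    """(D, SE, Z) directly from per-block sums (fast-path convenience)."""
    counts = ABBACounts(
        abba=float(np.sum(block_abba)),
        baba=float(np.sum(block_baba)),
        block_abba=np.asarray(block_abba, dtype=float),
        block_baba=np.asarray(block_baba, dtype=float),
    )
    d = d_statistic(counts)
    se, z = block_jackknife_z(counts)
    return d, se, z


# ---------------------------------------------------------------------------
# windowed f_d
# ---------------------------------------------------------------------------

def _window_edges(matrix: GenotypeMatrix, chrom, window_bp: int):
    m = matrix.chrom == chrom
    length = matrix.locus_length or int(matrix.pos[m].max())
    starts = np.arange(0, length, window_bp)
    return [(int(s), int(min(s + window_bp, length))) for s in starts]


def f_d_windows(
    matrix: GenotypeMatrix,
    pops: tuple,
    window_bp: int,
) -> pd.DataFrame:
    """Windowed f_d admixture-fraction estimate (Martin et al. form).

    Per window, ``f_d = S(P1, P2, P3, O) / S(P1, P_D, P_D, O)`` where
    ``S`` is the summed ABBA - BABA excess and ``P_D`` is, site by site,
    whichever of P2/P3 has the higher derived-allele frequency.  Windows
    with non-positive numerator report 0; windows with zero denominator
    report a missing value.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be > 0")
    p1, p2, p3, usable = _polarized_frequencies(matrix, pops)
    pd_freq = np.maximum(p2, p3)
    s_num = np.where(usable, (1 - p1) * p2 * p3 - p1 * (1 - p2) * p3, 0.0)
    s_den = np.where(
        usable, (1 - p1) * pd_freq * pd_freq - p1 * (1 - pd_freq) * pd_freq, 0.0
    )
    rows = []
    for c in pd.unique(matrix.chrom):
        m = matrix.chrom == c
        for start, end in _window_edges(matrix, c, window_bp):
            w = m & (matrix.pos - 1 >= start) & (matrix.pos - 1 < end)
            n_used = int((usable & w).sum())
            num = float(s_num[w].sum())
            den = float(s_den[w].sum())
            if den == 0.0:
                value = np.nan
            elif num <= 0.0:
                value = 0.0
            else:
                value = num / den
            rows.append(
                {"chrom": c, "start": start, "end": end, "n_sites_used": n_used, "f_d": value}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# dXY
# ---------------------------------------------------------------------------

def dxy_windows(
    matrix: GenotypeMatrix,
    pop_a: str,
    pop_b: str,
    window_bp: int = 50_000,
    min_sites: int = 100,
) -> pd.DataFrame:
    """Pairwise nucleotide divergence in non-overlapping windows.

    dXY for a window is the total number of differences over all
    cross-population allele pairs at comparable sites, divided by the
    total number of such comparisons (invariant sites included in the
    denominator, the pixy convention).  Missing genotypes shrink the
    denominator; they never inflate divergence.  Windows with fewer than
    ``min_sites`` comparable sites report a missing value.
    """
    if not matrix.includes_invariant:
        raise ValueError(
            "dxy requires a matrix with invariant sites "
            "(read a VCF containing them or call with_invariant_sites())"
        )
    cols_a = matrix.sample_index(matrix.population_samples(pop_a))
    cols_b = matrix.sample_index(matrix.population_samples(pop_b))
    da = matrix.dosage[:, cols_a]
    db = matrix.dosage[:, cols_b]
    na = matrix.ploidy * (~np.isnan(da)).sum(axis=1)
    nb = matrix.ploidy * (~np.isnan(db)).sum(axis=1)
    ca = np.nansum(da, axis=1)
    cb = np.nansum(db, axis=1)
    diffs = ca * (nb - cb) + (na - ca) * cb
    comps = na * nb
    comparable = (na > 0) & (nb > 0)
    rows = []
    for c in pd.unique(matrix.chrom):
        m = matrix.chrom == c
        for start, end in _window_edges(matrix, c, window_bp):
            w = m & (matrix.pos - 1 >= start) & (matrix.pos - 1 < end)
            n_comp = int((comparable & w).sum())
            if n_comp < min_sites:
                value = np.nan
            else:
                value = float(diffs[w & comparable].sum() / comps[w & comparable].sum())
            rows.append(
                {
                    "chrom": c,
                    "start": start,
                    "end": end,
                    "n_sites_used": n_comp,
                    "dxy": value,
                }
            )
    return pd.DataFrame(rows)


def coalescence_time_from_dxy(dxy: float, mu: float, g: float) -> float:
    """Scale nucleotide divergence to coalescence time in years.

    ``t = (dXY / (2 mu)) * g``: divergence accumulates along two
    branches at rate mu per generation, and generations are converted to
    years with the generation time ``g``.
    """
    if mu <= 0:
        raise ValueError("mu must be > 0")
    if g <= 0:
        raise ValueError("g must be > 0")
    if dxy < 0:
        raise ValueError("dxy must be >= 0")
    return (dxy / (2.0 * mu)) * g
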