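"""Synthetic inputs for every pipeline stage, with machine-readable truth.

Generates (a) genotype matrices/VCFs under the fitted nine-taxon guenon
demography with its three introgression pulses, (b) male/female coverage
tracks with a planted PAR plateau and planted copy-number regions, and
(c) per-gene CDS alignments with planted clade-fixed amino-acid
differences and optional internal stop codons.  Every generator is
deterministic given its seed and emits a truth file sufficient to score
the downstream module without reference to generator internals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import coalsim, demography
from .coveragescan import CoverageTrack
from .popstats import GenotypeMatrix, write_vcf

__all__ = [
    "GenotypeSpec",
    "CoverageSpec",
    "CDSSpec",
    "generate_study_genotypes",
    "generate_coverage_tracks",
    "generate_cds_fixtures",
]


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenotypeSpec:
    """Layout of a synthetic genotype fixture under the guenon demography."""

    phi3: float = demography.DEFAULT_PHI3
    n_loci: int = 20
    locus_length_bp: int = 10_000
    samples_per_taxon: int = 1
    mode: str = demography.AUTOSOMAL
    ne: float = demography.DEFAULT_NE


def generate_study_genotypes(
    spec: GenotypeSpec, seed: int, out_dir: str | Path | None = None
):
    """Simulate genotypes for the nine guenon taxa; optionally write files.

    Returns ``(matrix, truth)``.  When ``out_dir`` is given, writes
    ``genotypes.vcf`` (with explicit invariant-site records so dXY
    denominators are honest), ``popmap.tsv`` and ``truth.json``.
    """
    model = demography.default_guenon_model(phi3=spec.phi3, ne=spec.ne)
    if spec.mode == demography.Y_LINKED:
        model = demography.derive_y_model(model)
    samples = {t: spec.samples_per_taxon for t in demography.GUENON_TAXA}
    locus_spec = coalsim.LocusSpec(
        length_bp=spec.locus_length_bp, n_loci=spec.n_loci, mode=spec.mode
    )
    matrix = coalsim.simulate_genotype_matrix(model, locus_spec, samples, seed)
    truth = {
        "seed": int(seed),
        "phi3": spec.phi3,
        "mode": spec.mode,
        "n_loci": spec.n_loci,
        "locus_length_bp": spec.locus_length_bp,
        "pulses": [[p.time_gen, p.source, p.dest, p.phi] for p in model.pulses],
        "samples_per_taxon": spec.samples_per_taxon,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_vcf(matrix.with_invariant_sites(), str(out / "genotypes.vcf"))
        with open(out / "popmap.tsv", "w") as fh:
            for s in matrix.samples:
                fh.write(f"{s}\t{matrix.populations[s]}\n")
        (out / "truth.json").write_text(json.dumps(truth, indent=2))
    return matrix, truth


# ---------------------------------------------------------------------------
# coverage tracks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CoverageSpec:
    """Planted structure for male/female X-chromosome coverage tracks.

    The male baseline is half the autosomal depth outside the PAR and
    full depth inside it; CNV regions multiply the target sample's depth
    by their fold change.  Window depths are Poisson-noised.
    """

    chrom: str = "chrX"
    chrom_length_bp: int = 20_000_000
    window_bp: int = 10_000
    mean_depth: float = 30.0
    par_start: int = 0
    par_length_bp: int = 2_360_000
    cnv_regions: tuple = ()  # ((start, end, fold), ...)

    def __post_init__(self):
        spans = [(self.par_start, self.par_start + self.par_length_bp)]
        for s, e, _ in self.cnv_regions:
            for a, b in spans:
                if s < b and a < e:
                    raise ValueError("planted regions overlap")
            spans.append((s, e))


def _windows(spec: CoverageSpec):
    starts = np.arange(0, spec.chrom_length_bp, spec.window_bp)
    ends = np.minimum(starts + spec.window_bp, spec.chrom_length_bp)
    return starts, ends


def generate_coverage_tracks(
    spec: CoverageSpec,
    seed: int,
    samples: tuple = (("male_denti", "male", True), ("female_ref", "female", False)),
    out_dir: str | Path | None = None,
):
    """Poisson-noised per-window depths with planted PAR/CNV structure.

    ``samples`` is ``(name, sex, carries_cnv)`` triples: male samples
    drop to half depth outside the PAR; CNV folds apply only to samples
    flagged as carriers.  Returns ``(tracks, truth)``.
    """
    if spec.mean_depth <= 0:
        raise ValueError("mean depth must be > 0")
    rng = np.random.default_rng(seed)
    starts, ends = _windows(spec)
    mids = (starts + ends) / 2.0
    tracks = []
    for name, sex, carries in samples:
        base = np.full(len(starts), spec.mean_depth)
        if sex == "male":
            in_par = (mids >= spec.par_start) & (
                mids < spec.par_start + spec.par_length_bp
            )
            base = np.where(in_par, base, base / 2.0)
        if carries:
            for s, e, fold in spec.cnv_regions:
                base = np.where((mids >= s) & (mids < e), base * fold, base)
        depth = rng.poisson(base).astype(float)
        tracks.append(
            CoverageTrack(
                sample=name, sex=sex, chrom=spec.chrom,
                start=starts.copy(), end=ends.copy(), depth=depth,
            )
        )
    truth = {
        "seed": int(seed),
        "par": [spec.par_start, spec.par_start + spec.par_length_bp],
        "cnv_regions": [list(r) for r in spec.cnv_regions],
        "window_bp": spec.window_bp,
        "mean_depth": spec.mean_depth,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        rows = []
        for t in tracks:
            for s, e, dep in zip(t.start, t.end, t.depth):
                rows.append((t.sample, t.sex, t.chrom, int(s), int(e), dep))
        pd.DataFrame(
            rows, columns=["sample", "sex", "chrom", "start", "end", "depth"]
        ).to_csv(out / "coverage.tsv", sep="\t", index=False)
        with open(out / "truth.bed", "w") as fh:
            fh.write(f"{spec.chrom}\t{spec.par_start}\t{spec.par_start + spec.par_length_bp}\tPAR\n")
            for s, e, fold in spec.cnv_regions:
                fh.write(f"{spec.chrom}\t{s}\t{e}\tCNV_{fold}x\n")
        (out / "truth.json").write_text(json.dumps(truth, indent=2))
    return tracks, truth


# ---------------------------------------------------------------------------
# CDS fixtures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CDSSpec:
    """Planted per-gene fixed differences and stop-codon injections."""

    n_genes_with_differences: int = 13
    n_genes_without: int = 15
    n_codons: int = 120
    max_differences: int = 5
    n_stop_genes: int = 2
    clade_a: tuple = ("mitis_1", "denti_1")
    clade_b: tuple = ("wolfi_1", "pogonias_1")


def _random_sense_codon(rng) -> str:
    from Bio.Seq import Seq

    while True:
        codon = "".join(rng.choice(list("ACGT"), 3))
        if str(Seq(codon).translate()) != "*":
            return codon


def _codon_for_other_aa(rng, avoid_aa: str) -> str:
    from Bio.Seq import Seq

    while True:
        codon = _random_sense_codon(rng)
        if str(Seq(codon).translate()) != avoid_aa:
            return codon


def generate_cds_fixtures(
    spec: CDSSpec, seed: int, out_dir: str | Path | None = None
):
    """Build per-gene CDS alignments with known fixed-difference counts.

    Genes ``diffgene_*`` carry 1..max_differences planted clade-fixed
    amino-acid substitutions; ``nodiff_*`` genes carry none (but may
    carry within-clade polymorphism that must not count); ``stopgene_*``
    genes contain an internal stop codon in a focal sample and must be
    excluded by the screen.  Returns ``(alignments, truth_table)``.
    """
    from Bio.Seq import Seq

    from .codingscreen import CDSAlignment

    rng = np.random.default_rng(seed)
    all_samples = list(spec.clade_a) + list(spec.clade_b)
    alignments = []
    truth_rows = []

    def base_gene() -> list:
        return [_random_sense_codon(rng) for _ in range(spec.n_codons)]

    for gi in range(spec.n_genes_with_differences):
        codons = base_gene()
        n_diff = 1 + int(rng.integers(spec.max_differences))
        sites = rng.choice(spec.n_codons - 1, size=n_diff, replace=False)
        seqs = {s: list(codons) for s in all_samples}
        for site in sites:
            aa = str(Seq(codons[site]).translate())
            alt = _codon_for_other_aa(rng, aa)
            for s in spec.clade_a:
                seqs[s][site] = alt
        alignments.append(
            CDSAlignment(
                gene=f"diffgene_{gi}",
                sequences={s: "".join(c) for s, c in seqs.items()},
            )
        )
        truth_rows.append((f"diffgene_{gi}", n_diff, False))
    for gi in range(spec.n_genes_without):
        codons = base_gene()
        seqs = {s: list(codons) for s in all_samples}
        # within-clade polymorphism: a private change in one clade-A sample
        if spec.n_codons > 2 and len(spec.clade_a) > 1:
            site = int(rng.integers(spec.n_codons - 1))
            aa = str(Seq(codons[site]).translate())
            seqs[spec.clade_a[0]][site] = _codon_for_other_aa(rng, aa)
        alignments.append(
            CDSAlignment(
                gene=f"nodiff_{gi}",
                sequences={s: "".join(c) for s, c in seqs.items()},
            )
        )
        truth_rows.append((f"nodiff_{gi}", 0, False))
    for gi in range(spec.n_stop_genes):
        codons = base_gene()
        seqs = {s: list(codons) for s in all_samples}
        site = int(rng.integers(1, spec.n_codons - 1))
        seqs[spec.clade_a[0]][site] = "TAA"
        alignments.append(
            CDSAlignment(
                gene=f"stopgene_{gi}",
                sequences={s: "".join(c) for s, c in seqs.items()},
            )
        )
        truth_rows.append((f"stopgene_{gi}", 0, True))

    truth = pd.DataFrame(
        truth_rows, columns=["gene", "n_fixed_expected", "internal_stop"]
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for aln in alignments:
            with open(out / f"{aln.gene}.fasta", "w") as fh:
                for s, seq in aln.sequences.items():
                    fh.write(f">{s}\n{seq}\n")
        truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    return alignments, truth
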