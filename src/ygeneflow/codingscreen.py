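"""Screen coding genes for clade-fixed amino-acid differences.

Translates per-gene CDS alignments, excludes genes carrying an internal
stop codon in any focal sample, and counts alignment positions at which
one clade is fixed for one residue and the other clade for a different
one — the candidate substitutions that might underlie selection on an
introgressed Y chromosome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from Bio.Seq import Seq

logger = logging.getLogger("ygeneflow")

__all__ = [
    "CDSAlignment",
    "translate_cds",
    "fixed_aa_differences",
    "screen_genes",
    "read_gene_fastas",
]

MISSING_RESIDUES = {"X", "-"}


@dataclass
class CDSAlignment:
    """One gene's aligned coding sequences, keyed by sample name."""

    gene: str
    sequences: dict

    def __post_init__(self):
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise ValueError(f"{self.gene}: aligned sequences differ in length")
        if lengths and next(iter(lengths)) % 3 != 0:
            raise ValueError(f"{self.gene}: alignment length not divisible by 3")


def translate_cds(sequence: str, gene: str = "<unnamed>") -> tuple[str, bool]:
    """Translate a CDS with the standard code; flag internal stops.

    Ambiguous codons (any non-ACGT base, including gaps) translate to
    ``X``.  A stop codon anywhere before the final codon sets the
    internal-stop flag; a terminal stop is normal and not flagged.
    Returns ``(protein_with_terminal_stop_removed, internal_stop_flag)``.
    """
    seq = sequence.upper().replace("U", "T")
    if len(seq) % 3 != 0:
        raise ValueError(f"{gene}: CDS length {len(seq)} not divisible by 3")
    aas = []
    for i in range(0, len(seq), 3):
        codon = seq[i : i + 3]
        if set(codon) <= set("ACGT"):
            aas.append(str(Seq(codon).translate()))
        else:
            aas.append("X")
    internal_stop = "*" in aas[:-1]
    if aas and aas[-1] == "*":
        aas = aas[:-1]
    return "".join(aas), internal_stop


def fixed_aa_differences(
    alignment: CDSAlignment, clade_a: list, clade_b: list
) -> tuple[int, list]:
    """Count positions fixed for different residues between two clades.

    A position counts iff every non-missing clade-A residue is
    identical, every non-missing clade-B residue is identical, the two
    residues differ, and each clade has at least one non-missing call.
    ``X`` and gaps never count.  Returns ``(count, 1-based positions)``.
    """
    if not clade_a or not clade_b:
        raise ValueError("both clades need at least one sample")
    for s in list(clade_a) + list(clade_b):
        if s not in alignment.sequences:
            raise KeyError(f"{alignment.gene}: sample {s!r} absent from alignment")
    prots = {s: translate_cds(seq, alignment.gene)[0] for s, seq in alignment.sequences.items()}
    length = min(len(prots[s]) for s in list(clade_a) + list(clade_b))
    positions = []
    for i in range(length):
        res_a = {prots[s][i] for s in clade_a} - MISSING_RESIDUES
        res_b = {prots[s][i] for s in clade_b} - MISSING_RESIDUES
        if len(res_a) == 1 and len(res_b) == 1 and res_a != res_b:
            positions.append(i + 1)
    return len(positions), positions


def screen_genes(
    alignments: list,
    clade_a: list,
    clade_b: list,
) -> pd.DataFrame:
    """Run the fixed-difference screen over a gene set.

    Genes with an internal stop codon in any focal (clade A or B) sample
    are excluded entirely and reported with ``excluded_reason``.
    """
    rows = []
    focal = list(clade_a) + list(clade_b)
    for aln in alignments:
        stop_samples = [
            s
            for s in focal
            if s in aln.sequences and translate_cds(aln.sequences[s], aln.gene)[1]
        ]
        if stop_samples:
            rows.append(
                {
                    "gene": aln.gene,
                    "n_fixed": 0,
                    "positions": "",
                    "excluded_reason": f"internal stop in {','.join(sorted(stop_samples))}",
                }
            )
            continue
        n, pos = fixed_aa_differences(aln, clade_a, clade_b)
        rows.append(
            {
                "gene": aln.gene,
                "n_fixed": n,
                "positions": ",".join(map(str, pos)),
                "excluded_reason": "",
            }
        )
    return pd.DataFrame(rows, columns=["gene", "n_fixed", "positions", "excluded_reason"])


def read_gene_fastas(paths: list) -> list:
    """Read one FASTA alignment per gene (gene id = file stem)."""
    from pathlib import Path

    from Bio import SeqIO

    alignments = []
    for p in paths:
        p = Path(p)
        seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(p), "fasta")}
        alignments.append(CDSAlignment(gene=p.stem, sequences=seqs))
    return alignments
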