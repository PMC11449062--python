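"""Circadian cis-element scanning in upstream (promoter) regions.

Four clock-associated motifs are counted in 2-kb upstream regions of DE
genes and of all other curated (non-DE) genes: the Morning Element (MOE),
the Evening Element (EE), the CCA1-binding site (CBS) and the G-box.
Frequencies are expressed per kb with the fixed denominator 2.0 x number of
genes; DE-versus-background shifts are tested per motif with a two-sided
Mann-Whitney on per-promoter counts after subsampling the background to
5,000 genes.  Scanning is overlapping exact matching on the promoter's
sense strand (the G-box is its own reverse complement; the others are not);
a both-strand mode is available as a flag.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .enrichment_stats import StatResult, mann_whitney
from .io_formats import GeneModel, GenomeSequences

DEFAULT_MOTIFS = {
    "MOE": "CCACAC",
    "EE": "AAAATATC",
    "CBS": "AAAAATCT",
    "G-box": "CACGTG",
}

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def extract_upstream(gene: GeneModel, genome: GenomeSequences,
                     length: int = 2000) -> str:
    """Strand-aware upstream sequence of a gene, clipped at scaffold edges.

    '+' genes: [start-length, start) on the forward strand; '-' genes:
    [end, end+length) reverse-complemented, so the returned sequence always
    reads 5'->3' toward the gene.
    """
    seq = genome[gene.scaffold_id]
    if gene.strand == "+":
        lo = max(0, gene.start - length)
        return seq[lo:gene.start]
    hi = min(len(seq), gene.end + length)
    return reverse_complement(seq[gene.end:hi])


def count_motifs(sequence: str, motifs: dict[str, str] | None = None,
                 both_strands: bool = False) -> dict[str, int]:
    """Overlapping exact occurrences of each motif.

    Case is ignored (soft-masking does not hide a motif) but N never
    matches.  ``both_strands`` additionally scans the reverse complement.
    """
    motifs = motifs or DEFAULT_MOTIFS
    seqs = [sequence.upper()]
    if both_strands:
        seqs.append(reverse_complement(sequence).upper())
    counts = {}
    for name, pattern in motifs.items():
        total = 0
        for s in seqs:
            start = 0
            while True:
                k = s.find(pattern, start)
                if k == -1:
                    break
                total += 1
                start = k + 1
        counts[name] = total
    return counts


def perkb_frequency(total_counts: dict[str, int], n_genes: int,
                    length_per_gene: int = 2000,
                    paper_denominator: bool = True,
                    actual_total_bp: int | None = None) -> dict[str, float]:
    """Per-kb motif frequency over a gene set.

    The fixed denominator is (length_per_gene / 1000) x n_genes kb; with
    ``paper_denominator=False`` the actual summed promoter length is used
    (relevant when promoters were clipped at scaffold edges).
    """
    if n_genes == 0:
        raise ValueError("empty gene set")
    if paper_denominator:
        kb = length_per_gene / 1000.0 * n_genes
    else:
        if actual_total_bp is None:
            raise ValueError("actual_total_bp required when paper_denominator=False")
        kb = actual_total_bp / 1000.0
    return {m: c / kb for m, c in total_counts.items()}


def frequency_change(freq_de: float, freq_background: float) -> float:
    """Percent change of the DE-set frequency relative to background."""
    if freq_background == 0:
        return float("nan")
    return 100.0 * (freq_de - freq_background) / freq_background


def motif_mw_test(per_gene_counts_de: dict[str, np.ndarray],
                  per_gene_counts_bg: dict[str, np.ndarray],
                  subsample: int = 5000,
                  seed: int = 0) -> dict[str, StatResult]:
    """Per-motif two-sided Mann-Whitney of per-promoter counts, with the
    background subsampled without replacement to at most ``subsample``."""
    rng = np.random.default_rng(seed)
    out = {}
    for motif in per_gene_counts_de:
        de = np.asarray(per_gene_counts_de[motif])
        bg = np.asarray(per_gene_counts_bg[motif])
        if len(de) == 0 or len(bg) == 0:
            raise ValueError("empty gene set")
        if len(bg) > subsample:
            bg = rng.choice(bg, size=subsample, replace=False)
        res = mann_whitney(de, bg)
        res.notes["subsample_size"] = int(len(bg))
        res.notes["seed"] = seed
        out[motif] = res
    return out


def candidate_motif_table(candidate_genes, homolog_of: dict[str, str | None],
                          genes_by_id: dict[str, GeneModel],
                          genomes: dict[str, GenomeSequences],
                          genome_of: dict[str, str],
                          length: int = 3000,
                          motifs: dict[str, str] | None = None) -> pd.DataFrame:
    """Motif counts in the (default 3-kb) upstream region of each candidate
    gene and its homolog, side by side.  Candidates without a homolog get a
    row with missing homolog columns."""
    motifs = motifs or DEFAULT_MOTIFS
    rows = []
    for gid in candidate_genes:
        row: dict = {"gene_id": gid}
        gene = genes_by_id[gid]
        counts = count_motifs(
            extract_upstream(gene, genomes[genome_of[gid]], length), motifs)
        for m in motifs:
            row[f"{m}"] = counts[m]
        hid = homolog_of.get(gid)
        row["homolog_id"] = hid if hid else ""
        for m in motifs:
            row[f"homolog_{m}"] = np.nan
        if hid and hid in genes_by_id:
            hcounts = count_motifs(
                extract_upstream(genes_by_id[hid], genomes[genome_of[hid]], length),
                motifs)
            for m in motifs:
                row[f"homolog_{m}"] = hcounts[m]
        rows.append(row)
    return pd.DataFrame(rows)
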