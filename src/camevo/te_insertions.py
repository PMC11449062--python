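"""TE insertions in gene bodies and upstream regions, and their association
with differential expression.

Insertion counts are raw overlap counts (>= 1 bp, half-open intervals,
bedtools-intersect semantics) of known TE annotations with either the gene
span, the introns only, or the span extended 3 kb on the 5' side
(bedtools slop -l 3000 -r 0 -s semantics).  Two association tests follow
the study design: a chi-square on the proportion of genes carrying at least
one insertion (DE versus all curated genes) and a Mann-Whitney on per-gene
insertion counts (DE versus non-DE).
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np

from .enrichment_stats import StatResult, chi_square_2x2, fisher_exact_2x2, mann_whitney
from .io_formats import GeneModel, TEFeature

TE_CLASSES_TESTED = ("LTR-Copia", "LTR-Gypsy", "Helitron", "DNA transposon")


def slop_upstream(gene: GeneModel, scaffold_length: int,
                  extend: int = 3000) -> tuple[int, int]:
    """Extend the gene span ``extend`` bp on its 5' side only, clipped to
    the scaffold (strand-aware, like bedtools slop -l N -r 0 -s)."""
    if gene.strand == "+":
        return max(0, gene.start - extend), gene.end
    return gene.start, min(scaffold_length, gene.end + extend)


def _overlaps(iv: tuple[int, int], te: TEFeature) -> bool:
    return te.start < iv[1] and iv[0] < te.end


def intersect_te(gene_intervals: Mapping[str, list[tuple[str, int, int]]],
                 te_features: Sequence[TEFeature],
                 known_only: bool = True) -> dict[str, dict[str, int]]:
    """Per-gene, per-class TE overlap counts.

    ``gene_intervals`` maps gene_id to a list of (scaffold, start, end)
    query intervals (one for the span, several for introns-only mode).  A TE
    overlapping any query interval of a gene counts once per gene region
    set.  Returns {gene_id: {"total": n, class: n, ...}}.
    """
    tes = [te for te in te_features if te.known or not known_only]
    by_scaffold: dict[str, list[TEFeature]] = {}
    for te in tes:
        by_scaffold.setdefault(te.scaffold_id, []).append(te)
    for lst in by_scaffold.values():
        lst.sort(key=lambda t: t.start)
    out: dict[str, dict[str, int]] = {}
    for gid, intervals in gene_intervals.items():
        counts = {"total": 0}
        for cls in TE_CLASSES_TESTED:
            counts[cls] = 0
        seen: set[int] = set()
        for scaffold, start, end in intervals:
            for te in by_scaffold.get(scaffold, []):
                if te.start >= end:
                    break
                if _overlaps((start, end), te) and id(te) not in seen:
                    seen.add(id(te))
                    counts["total"] += 1
                    if te.te_class in counts:
                        counts[te.te_class] += 1
        out[gid] = counts
    return out


def gene_query_intervals(genes: Iterable[GeneModel],
                         scaffold_lengths: Mapping[str, int],
                         mode: str = "span",
                         upstream: int = 0) -> dict[str, list[tuple[str, int, int]]]:
    """Build the query intervals for :func:`intersect_te`.

    ``span``: the mRNA span, optionally 5'-extended by ``upstream`` bp;
    ``introns``: intron intervals only.
    """
    out = {}
    for g in genes:
        if mode == "span":
            if upstream:
                s, e = slop_upstream(g, scaffold_lengths[g.scaffold_id], upstream)
            else:
                s, e = g.start, g.end
            out[g.gene_id] = [(g.scaffold_id, s, e)]
        elif mode == "introns":
            out[g.gene_id] = [(g.scaffold_id, s, e) for s, e in g.introns()]
        else:
            raise ValueError(f"unknown mode {mode!r}")
    return out


def te_presence_test(counts_de: Sequence[int], counts_all: Sequence[int]) -> StatResult:
    """Chi-square on the 2x2 table of (>=1 TE insertion) x (DE vs full set);
    falls back to Fisher's exact when an expected cell is below 1."""
    a = sum(c >= 1 for c in counts_de)
    b = len(counts_de) - a
    c = sum(x >= 1 for x in counts_all)
    d = len(counts_all) - c
    table = np.array([[a, b], [c, d]], dtype=float)
    n = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / n if n else table
    if (expected < 1).any():
        res = fisher_exact_2x2(table.astype(int))
        res.notes["fallback"] = "fisher-exact (expected cell < 1)"
        return res
    return chi_square_2x2(table)


def te_rate_test(counts_de: Sequence[int], counts_non_de: Sequence[int]) -> StatResult:
    """Two-sided Mann-Whitney on per-gene insertion counts; group means and
    medians ride along in the notes."""
    return mann_whitney(np.asarray(counts_de, float), np.asarray(counts_non_de, float))


def flag_high_te(per_gene_counts: Mapping[str, int],
                 genome_mean: float,
                 ortholog_map: Mapping[str, str] | None = None,
                 counts_other_species: Mapping[str, int] | None = None) -> dict[str, dict]:
    """Genes with insertion count strictly above twice the genome-wide mean;
    where a one-to-one ortholog exists, the count difference (this species
    minus the other) is attached."""
    out = {}
    threshold = 2.0 * genome_mean
    for gid, n in per_gene_counts.items():
        if n > threshold:
            entry: dict = {"count": n}
            if ortholog_map and gid in ortholog_map and counts_other_species is not None:
                other = ortholog_map[gid]
                if other in counts_other_species:
                    entry["ortholog_id"] = other
                    entry["delta"] = n - counts_other_species[other]
            out[gid] = entry
    return out
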