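"""Gene-model curation: ROBUST classification, NO_ORTHOLOGY propagation,
organellar/ribosomal exclusion, and transcription-factor family calls.

A gene model is ROBUST if (i) every exon shows expression, or (ii) both a
start and a stop codon are present and the CDS is at least 50 amino acids.
Genes annotated as repeat-derived (transposons, viral sequences) are flagged
NO_ORTHOLOGY together with every ortholog in their orthogroup and excluded
downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .io_formats import GeneModel, OrthogroupRecord

ROBUST = "ROBUST"
NOT_ROBUST = "NOT-ROBUST"

MIN_CDS_AA = 50

#: Default vocabulary marking a repeat-derived functional annotation.
DEFAULT_REPEAT_LABELS = frozenset({
    "transposon", "transposase", "retrotransposon",
    "viral", "virus", "gag", "pol", "integrase",
})


def classify_robust(gene: GeneModel, exon_expressed: Sequence[bool]) -> str:
    """ROBUST iff all exons expressed, or start+stop present with CDS >= 50 aa."""
    if len(exon_expressed) != len(gene.exons):
        raise ValueError(
            f"gene {gene.gene_id}: {len(exon_expressed)} expression flags "
            f"for {len(gene.exons)} exons")
    all_expressed = len(exon_expressed) > 0 and all(exon_expressed)
    complete = gene.has_start_codon and gene.has_stop_codon and gene.cds_len_aa >= MIN_CDS_AA
    return ROBUST if (all_expressed or complete) else NOT_ROBUST


def exon_expression_flags(exon_counts: Mapping[str, int],
                          gene: GeneModel,
                          threshold: int = 0) -> list[bool]:
    """Per-exon expressed flags: summed raw count > threshold.

    ``exon_counts`` maps ``"<gene_id>.exon<k>"`` (1-based exon index after
    coordinate sorting) to the count summed over all samples.
    """
    return [
        exon_counts.get(f"{gene.gene_id}.exon{i}", 0) > threshold
        for i in range(1, len(gene.exons) + 1)
    ]


def flag_no_orthology(genes: Iterable[GeneModel],
                      orthogroups: Iterable[OrthogroupRecord],
                      repeat_labels: frozenset[str] = DEFAULT_REPEAT_LABELS) -> set[str]:
    """Genes with a repeat-derived label, plus all genes sharing their
    orthogroup.  The flag set is a union of whole orthogroups plus any
    unassigned repeat-labelled genes; propagation is idempotent."""
    labels = {l.lower() for l in repeat_labels}

    def is_repeat(g: GeneModel) -> bool:
        return any(
            any(tok in lab.lower() for tok in labels) for lab in g.functional_labels
        )

    seeds = {g.gene_id for g in genes if is_repeat(g)}
    flagged = set(seeds)
    for og in orthogroups:
        members = {gid for gl in og.genes_by_species.values() for gid in gl}
        if members & seeds:
            flagged |= members
    return flagged


def exclude_organellar_ribosomal(orthogroups: Sequence[OrthogroupRecord],
                                 genes_by_id: Mapping[str, GeneModel],
                                 plastid_hits: Iterable[str] = (),
                                 mito_hits: Iterable[str] = ()) -> list[OrthogroupRecord]:
    """Drop orthogroups containing an organellar BLAST hit or any gene
    labelled 'ribosomal' from family-size analyses."""
    hits = set(plastid_hits) | set(mito_hits)
    kept = []
    for og in orthogroups:
        members = [gid for gl in og.genes_by_species.values() for gid in gl]
        if any(gid in hits for gid in members):
            continue
        ribosomal = any(
            gid in genes_by_id and any(
                "ribosomal" in lab.lower() for lab in genes_by_id[gid].functional_labels)
            for gid in members
        )
        if ribosomal:
            continue
        kept.append(og)
    return kept


@dataclass
class TFIdentification:
    by_domain: set[str]      # orthogroup ids identified via InterPro domains
    by_homolog: set[str]     # orthogroup ids identified via known-TF homologs
    union: set[str]
    overlap_fraction: float  # share of domain-identified TFs also homolog-identified


def identify_tf_families(orthogroups: Sequence[OrthogroupRecord],
                         genes_by_id: Mapping[str, GeneModel],
                         interpro_tf_domains: Iterable[str],
                         known_tf_homologs: Iterable[str]) -> TFIdentification:
    """Call TF orthogroups from (a) characteristic InterPro domains on any
    member and (b) membership of a known-TF homolog; report both sets and
    the fraction of domain calls confirmed by homologs."""
    domains = set(interpro_tf_domains)
    homologs = set(known_tf_homologs)
    if not domains and not homologs:
        raise ValueError("both the domain list and the homolog list are empty")
    by_domain, by_homolog = set(), set()
    for og in orthogroups:
        members = [gid for gl in og.genes_by_species.values() for gid in gl]
        for gid in members:
            g = genes_by_id.get(gid)
            if g is not None and g.functional_labels & domains:
                by_domain.add(og.orthogroup_id)
                break
        if set(members) & homologs:
            by_homolog.add(og.orthogroup_id)
    overlap = (len(by_domain & by_homolog) / len(by_domain)) if by_domain else 0.0
    return TFIdentification(by_domain, by_homolog, by_domain | by_homolog, overlap)


def curation_report(statuses: Mapping[str, str], no_orthology: set[str]) -> dict:
    """Counts per curation category, for the JSON report."""
    return {
        "n_genes": len(statuses),
        "n_robust": sum(s == ROBUST for s in statuses.values()),
        "n_not_robust": sum(s == NOT_ROBUST for s in statuses.values()),
        "n_no_orthology": len(no_orthology),
    }
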