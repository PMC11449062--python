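"""Coverage-based correction of orthogroup gene counts and relative-size
categories.

Redundantly assembled haplotypes (haplotigs) inflate per-orthogroup gene
counts; because reads split between the two copies, each copy shows about
half the genome-wide single-copy coverage.  Counts are therefore corrected
by the ratio of observed total member coverage to the coverage expected if
every member were a true single copy:

    r = (sum of member coverages) / (n * mean single-copy coverage)
    corrected n = round(n * r) = round(sum cov / mean single-copy coverage)

rounded half away from zero and floored at 1 for non-empty orthogroups.
Correction applies only to orthogroups containing multicopy genes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .io_formats import GeneModel, OrthogroupRecord

SPECIES = ("A", "F", "L")


# ---------------------------------------------------------------------------
# Coverage
# ---------------------------------------------------------------------------

def mean_gene_coverage(per_base_coverage: Mapping[str, np.ndarray],
                       gene: GeneModel) -> float:
    """Arithmetic mean read depth over the gene span; absent positions are 0."""
    depth = per_base_coverage[gene.scaffold_id]
    if gene.end > len(depth):
        raise ValueError(f"gene {gene.gene_id} extends past scaffold coverage track")
    return float(np.mean(depth[gene.start:gene.end]))


@dataclass
class CoverageProfile:
    """Per-gene mean coverage for one species plus its single-copy baseline."""

    gene_coverage: dict[str, float]
    singlecopy_mean: float

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.gene_coverage.values()):
            raise ValueError("negative coverage")


def singlecopy_mean_coverage(orthogroups: Sequence[OrthogroupRecord],
                             gene_coverage: Mapping[str, float],
                             species: str) -> float:
    """Mean coverage over genes of ancestral single-copy orthogroups
    (exactly one gene in every species)."""
    covs = []
    for og in orthogroups:
        if all(og.count(sp) == 1 for sp in SPECIES):
            gid = og.genes_by_species[species][0]
            if gid in gene_coverage:
                covs.append(gene_coverage[gid])
    if not covs:
        raise ValueError(f"no single-copy genes with coverage for species {species}")
    return float(np.mean(covs))


# ---------------------------------------------------------------------------
# Orthogroup classes (per species)
# ---------------------------------------------------------------------------

def classify_orthogroup(record: OrthogroupRecord) -> dict[str, str]:
    """Per-species label: single-copy / multicopy, refined to ancestral
    single-copy (1 in all species), ancestral multicopy (>1 and equal in
    all) and unique multicopy (>1 here, 0 elsewhere)."""
    counts = {sp: record.count(sp) for sp in SPECIES}
    labels = {}
    for sp in SPECIES:
        n = counts[sp]
        others = [counts[o] for o in SPECIES if o != sp]
        if n == 1 and all(c == 1 for c in others):
            labels[sp] = "ancestral single-copy"
        elif n == 1:
            labels[sp] = "single-copy"
        elif n > 1 and all(c == n for c in others):
            labels[sp] = "ancestral multicopy"
        elif n > 1 and all(c == 0 for c in others):
            labels[sp] = "unique multicopy"
        elif n > 1:
            labels[sp] = "multicopy"
        else:
            labels[sp] = "absent"
    return labels


# ---------------------------------------------------------------------------
# Correction
# ---------------------------------------------------------------------------

def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def correct_family_size(record: OrthogroupRecord,
                        coverages: Mapping[str, CoverageProfile]) -> dict[str, int]:
    """Coverage-correct per-species counts of one orthogroup (see module doc).

    Only meaningful for orthogroups with multicopy members; the caller
    (:func:`correct_all`) enforces that scope.  Requires coverage for every
    member gene and a positive single-copy mean.
    """
    corrected = {}
    for sp, profile in coverages.items():
        genes = record.genes_by_species.get(sp, [])
        n = len(genes)
        if n == 0:
            corrected[sp] = 0
            continue
        if profile.singlecopy_mean <= 0:
            raise ValueError(f"species {sp}: single-copy mean coverage is not positive")
        missing = [g for g in genes if g not in profile.gene_coverage]
        if missing:
            raise ValueError(f"missing coverage for member gene(s) {missing}")
        total = sum(profile.gene_coverage[g] for g in genes)
        c = _round_half_away(total / profile.singlecopy_mean)
        corrected[sp] = max(c, 1) if total > 0 else c
        if corrected[sp] < 1 and n >= 1 and total > 0:
            corrected[sp] = 1
    return corrected


def correct_all(orthogroups: Sequence[OrthogroupRecord],
                coverages: Mapping[str, CoverageProfile]) -> None:
    """Apply coverage correction in place to orthogroups containing
    multicopy genes; all others keep raw counts."""
    for og in orthogroups:
        if any(og.count(sp) > 1 for sp in coverages):
            og.corrected = correct_family_size(og, coverages)


# ---------------------------------------------------------------------------
# Relative size categories and summary statistics
# ---------------------------------------------------------------------------

CATEGORY_SINGLE = "F=1:L=1"
CATEGORY_F_LARGER = "F>L"
CATEGORY_L_LARGER = "F<L"
CATEGORY_EQUAL_MULTI = "F=L(>1)"
CATEGORY_F_UNIQUE = "F-unique"
CATEGORY_L_UNIQUE = "L-unique"


def categorize_relative_size(F: int, L: int) -> str:
    """Relative family-size category from the two focal-species counts."""
    if F == 0 and L == 0:
        raise ValueError("empty orthogroup (F = L = 0)")
    if L == 0:
        return CATEGORY_F_UNIQUE
    if F == 0:
        return CATEGORY_L_UNIQUE
    if F == 1 and L == 1:
        return CATEGORY_SINGLE
    if F > L:
        return CATEGORY_F_LARGER
    if F < L:
        return CATEGORY_L_LARGER
    return CATEGORY_EQUAL_MULTI


def family_log_ratio(F: int, L: int) -> float:
    """ln(F/L); species-unique orthogroups are excluded with a warning."""
    if F <= 0 or L <= 0:
        warnings.warn("zero count: orthogroup excluded from log-ratio")
        return float("nan")
    return math.log(F / L)


def family_size_zscore(set_diffs, background_diffs) -> float:
    """Standardized family-size difference of a gene set against background.

    With d = F - L per orthogroup:
    z = (mean(d_set) - mean(d_bg)) / (sd(d_bg) / sqrt(|set|)).
    Negative z means the set tends toward larger families in species L.
    Undefined (NaN) for empty sets or zero background spread.
    """
    d_set = np.asarray(list(set_diffs), dtype=float)
    d_bg = np.asarray(list(background_diffs), dtype=float)
    if len(d_set) == 0 or len(d_bg) < 2:
        return float("nan")
    sd = float(np.std(d_bg, ddof=1))
    if sd == 0:
        return float("nan")
    return float((d_set.mean() - d_bg.mean()) / (sd / math.sqrt(len(d_set))))
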