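"""Readers and writers for the standard genomics formats the pipeline consumes.

All coordinates inside the package are 0-based half-open.  GFF3 (1-based
inclusive) is converted at this boundary and nowhere else; BED is written
0-based half-open as the format requires.  Soft-masking (repeat-derived
sequence) is carried as lowercase in the sequence itself, never as a
separate track.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_NUCLEOTIDES = set("ACGTNacgtn")

TE_CLASSES = ("LTR-Copia", "LTR-Gypsy", "Helitron", "DNA transposon", "other")


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class GenomeSequences:
    """Scaffold sequences keyed by id; lowercase bases are soft-masked."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        for sid, seq in self.sequences.items():
            bad = set(seq) - VALID_NUCLEOTIDES
            if bad:
                raise ParseError(
                    f"scaffold {sid!r} contains invalid characters {sorted(bad)}"
                )

    def __getitem__(self, scaffold_id: str) -> str:
        return self.sequences[scaffold_id]

    def __contains__(self, scaffold_id: str) -> bool:
        return scaffold_id in self.sequences

    def length(self, scaffold_id: str) -> int:
        return len(self.sequences[scaffold_id])

    @property
    def scaffold_ids(self) -> list[str]:
        return list(self.sequences)


@dataclass
class GeneModel:
    """A predicted gene: span, strand, exons, CDS completeness, annotations.

    ``start``/``end`` and every exon interval are 0-based half-open on the
    scaffold.  ``functional_labels`` holds GO ids, InterPro domain ids and
    free-text descriptions in one set.
    """

    gene_id: str
    scaffold_id: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds_len_aa: int = 0
    has_start_codon: bool = False
    has_stop_codon: bool = False
    functional_labels: set[str] = field(default_factory=set)
    orthogroup_id: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ParseError(f"gene {self.gene_id}: unknown strand {self.strand!r}")
        if not self.start < self.end:
            raise ParseError(f"gene {self.gene_id}: empty interval")
        prev_end = None
        for s, e in sorted(self.exons):
            if s < self.start or e > self.end:
                raise ParseError(f"gene {self.gene_id}: exon outside gene span")
            if prev_end is not None and s < prev_end:
                raise ParseError(f"gene {self.gene_id}: overlapping exons")
            prev_end = e

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def introns(self) -> list[tuple[int, int]]:
        """Gene span minus exons, as sorted 0-based half-open intervals."""
        out = []
        pos = self.start
        for s, e in sorted(self.exons):
            if s > pos:
                out.append((pos, s))
            pos = max(pos, e)
        if pos < self.end:
            out.append((pos, self.end))
        return out


@dataclass
class TEFeature:
    """A transposable-element annotation with its class label."""

    scaffold_id: str
    start: int
    end: int
    te_class: str
    known: bool = True

    def __post_init__(self) -> None:
        if self.te_class not in TE_CLASSES:
            raise ParseError(f"unknown TE class {self.te_class!r}")


@dataclass
class OrthogroupRecord:
    """One orthogroup: member genes per species plus A/F/L copy counts.

    ``A`` is the outgroup (Ananas comosus) count; ``F`` and ``L`` are the two
    focal-species counts (T. fasciculata, T. leiboldiana).  ``corrected``
    holds coverage-corrected counts once family-size correction has run.
    """

    orthogroup_id: str
    genes_by_species: dict[str, list[str]]
    corrected: dict[str, int] | None = None
    category: str | None = None

    def count(self, species: str) -> int:
        return len(self.genes_by_species.get(species, []))

    @property
    def A(self) -> int:
        return self.count("A")

    @property
    def F(self) -> int:
        return self.count("F")

    @property
    def L(self) -> int:
        return self.count("L")

    def effective_count(self, species: str) -> int:
        if self.corrected is not None and species in self.corrected:
            return self.corrected[species]
        return self.count(species)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> GenomeSequences:
    """Read a (possibly soft-masked) FASTA into a GenomeSequences container."""
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in sequences:
            raise ParseError(f"duplicate scaffold id {rec.id!r} in {path}")
        sequences[rec.id] = str(rec.seq)
    return GenomeSequences(sequences)


def write_fasta(genome: GenomeSequences, path: str | Path, width: int = 80) -> None:
    records = [
        SeqRecord(Seq(seq), id=sid, description="")
        for sid, seq in genome.sequences.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def _parse_attributes(text: str) -> dict[str, str]:
    attrs = {}
    for part in text.strip().split(";"):
        if not part:
            continue
        if "=" not in part:
            raise ParseError(f"malformed GFF3 attribute {part!r}")
        key, value = part.split("=", 1)
        attrs[key.strip()] = value.strip()
    return attrs


def _format_attributes(attrs: dict[str, str]) -> str:
    return ";".join(f"{k}={v}" for k, v in attrs.items())


def read_gff3_genes(path: str | Path) -> list[GeneModel]:
    """Parse gene/mRNA/exon/CDS features into GeneModel records.

    GFF3 1-based inclusive coordinates become 0-based half-open here.
    CDS completeness and functional labels are read from the gene line's
    attributes (``cds_len_aa``, ``has_start_codon``, ``has_stop_codon``,
    ``Note`` with comma-separated labels, ``orthogroup``).
    """
    genes: dict[str, GeneModel] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 columns, got {len(cols)}")
            scaffold, _source, ftype, start, end, _score, strand, _phase, attr_text = cols
            if strand not in {"+", "-"}:
                raise ParseError(f"{path}:{lineno}: unknown strand {strand!r}")
            attrs = _parse_attributes(attr_text)
            iv = (int(start) - 1, int(end))  # GFF3 1-based inclusive -> half-open
            if ftype == "gene":
                gid = attrs["ID"]
                labels = set()
                if attrs.get("Note"):
                    labels = {x for x in attrs["Note"].split(",") if x}
                genes[gid] = GeneModel(
                    gene_id=gid,
                    scaffold_id=scaffold,
                    start=iv[0],
                    end=iv[1],
                    strand=strand,
                    cds_len_aa=int(attrs.get("cds_len_aa", 0)),
                    has_start_codon=attrs.get("has_start_codon", "0") == "1",
                    has_stop_codon=attrs.get("has_stop_codon", "0") == "1",
                    functional_labels=labels,
                    orthogroup_id=attrs.get("orthogroup") or None,
                )
            elif ftype == "exon":
                parent = attrs["Parent"]
                exons.setdefault(parent, []).append(iv)
    out = []
    for gid, gene in genes.items():
        gene.exons = sorted(exons.get(gid, [(gene.start, gene.end)]))
        gene.__post_init__()
        out.append(gene)
    return out


def write_gff3_genes(genes: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = {
                "ID": g.gene_id,
                "cds_len_aa": str(g.cds_len_aa),
                "has_start_codon": "1" if g.has_start_codon else "0",
                "has_stop_codon": "1" if g.has_stop_codon else "0",
            }
            if g.functional_labels:
                attrs["Note"] = ",".join(sorted(g.functional_labels))
            if g.orthogroup_id:
                attrs["orthogroup"] = g.orthogroup_id
            fh.write(
                "\t".join(
                    [g.scaffold_id, "camevo", "gene", str(g.start + 1), str(g.end),
                     ".", g.strand, ".", _format_attributes(attrs)]
                ) + "\n"
            )
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write(
                    "\t".join(
                        [g.scaffold_id, "camevo", "exon", str(s + 1), str(e), ".",
                         g.strand, ".", _format_attributes(
                             {"ID": f"{g.gene_id}.exon{i}", "Parent": g.gene_id})]
                    ) + "\n"
                )


def read_gff3_te(path: str | Path) -> list[TEFeature]:
    """Parse TE features; class comes from the ``te_class`` attribute and
    known/novel status from ``known=0|1`` (default known)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 columns, got {len(cols)}")
            scaffold, _src, _ftype, start, end, _score, _strand, _phase, attr_text = cols
            attrs = _parse_attributes(attr_text)
            out.append(
                TEFeature(
                    scaffold_id=scaffold,
                    start=int(start) - 1,
                    end=int(end),
                    te_class=attrs.get("te_class", "other"),
                    known=attrs.get("known", "1") == "1",
                )
            )
    return out


def write_gff3_te(features: Sequence[TEFeature], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, te in enumerate(features, 1):
            attrs = {"ID": f"TE{i}", "te_class": te.te_class,
                     "known": "1" if te.known else "0"}
            fh.write(
                "\t".join(
                    [te.scaffold_id, "camevo", "transposable_element",
                     str(te.start + 1), str(te.end), ".", "+", ".",
                     _format_attributes(attrs)]
                ) + "\n"
            )


# ---------------------------------------------------------------------------
# BED / tables / orthogroups
# ---------------------------------------------------------------------------

def write_bed(intervals: Iterable[tuple[str, int, int]], path: str | Path) -> None:
    """Write (scaffold, start, end) triples; internal half-open == BED."""
    with open(path, "w") as fh:
        for scaffold, start, end in intervals:
            fh.write(f"{scaffold}\t{start}\t{end}\n")


def read_bed(path: str | Path) -> list[tuple[str, int, int]]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            scaffold, start, end = line.split()[:3]
            out.append((scaffold, int(start), int(end)))
    return out


def read_table(path: str | Path, required_columns: Sequence[str] = ()) -> pd.DataFrame:
    """Read a header-bearing TSV, validating that required columns exist."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in required_columns if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}")
    return df


def write_table(df: pd.DataFrame, path: str | Path, header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_orthogroups(path: str | Path,
                     species: Sequence[str] = ("A", "F", "L")) -> list[OrthogroupRecord]:
    """Read an orthogroup TSV: orthogroup_id + one comma-separated gene-list
    column per species (empty cell = no genes)."""
    df = read_table(path, ["orthogroup_id", *species])
    records = []
    for _, row in df.iterrows():
        genes = {}
        for sp in species:
            cell = row[sp]
            genes[sp] = [] if pd.isna(cell) or cell == "" else str(cell).split(",")
        records.append(OrthogroupRecord(str(row["orthogroup_id"]), genes))
    return records


def write_orthogroups(records: Sequence[OrthogroupRecord], path: str | Path,
                      species: Sequence[str] = ("A", "F", "L")) -> None:
    rows = []
    for r in records:
        row = {"orthogroup_id": r.orthogroup_id}
        for sp in species:
            row[sp] = ",".join(r.genes_by_species.get(sp, []))
        rows.append(row)
    write_table(pd.DataFrame(rows), path)


def read_config(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
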