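"""Deterministic, seeded generator of a paired-species dataset with planted
ground truth for every downstream stage.

The generator emulates the study's raw inputs at desk scale: two annotated
genomes with a GC gradient and soft-masked TE intervals, an orthogroup
table with a requested mix of relative-size categories and haplotig-inflated
copies, per-gene read coverage, negative-binomial diel exon counts with
species-specific amplitude or phase for planted DE genes, codon pairs
evolved under a chosen omega, promoters with planted motif rates, and
CAM-like versus flat metabolite curves.  Everything derives from one global
seed through fixed per-stream child seeds, so adding a stream never
perturbs another, and a fixed seed gives byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import GeneModel, GenomeSequences, OrthogroupRecord, TEFeature
from .molecular_evolution import (
    N_CODONS, SENSE_CODONS, build_rate_matrix, transition_matrix,
)

_STREAMS = {"genome": 0, "orthogroups": 1, "coverage": 2, "counts": 3,
            "codons": 4, "promoters": 5, "metabolites": 6}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(_STREAMS[stream],)))


# ---------------------------------------------------------------------------
# Configuration and truth
# ---------------------------------------------------------------------------

@dataclass
class GenomeConfig:
    n_scaffolds: int = 2
    scaffold_length: int = 500_000
    n_orthogroups: int = 300
    #: fractions of {1:1, F>L, F<L, F=L>1, unique} orthogroup categories
    category_fractions: tuple[float, ...] = (0.7, 0.1, 0.1, 0.05, 0.05)
    #: fraction of multicopy orthogroups carrying one artifactual haplotig copy
    haplotig_fraction: float = 0.2
    #: per-class TE features per 100 kb
    te_density: dict = field(default_factory=lambda: {
        "LTR-Copia": 3.0, "LTR-Gypsy": 3.0, "Helitron": 1.5,
        "DNA transposon": 1.5})
    te_length: int = 800
    #: fraction of measured genes planted as diel-DE between species
    de_fraction: float = 0.15
    de_amplitude: float = 1.5       # log-scale amplitude in species F for DE genes
    baseline_expression: float = 500.0
    nb_dispersion: float = 0.1


@dataclass
class SyntheticTruth:
    """Planted ground truth keyed to emitted entity ids."""

    true_counts: dict[str, dict[str, int]] = field(default_factory=dict)
    category: dict[str, str] = field(default_factory=dict)
    haplotig_genes: dict[str, str] = field(default_factory=dict)  # artifact -> partner
    haplotig_orthogroups: set[str] = field(default_factory=set)
    de_genes: dict[str, dict] = field(default_factory=dict)  # gene -> per-species A, phi
    gene_params: dict[str, dict] = field(default_factory=dict)  # all measured genes
    codon_pairs: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    motif_rates: dict[str, dict[str, float]] = field(default_factory=dict)
    metabolite_params: dict[str, dict] = field(default_factory=dict)


CATEGORY_NAMES = ("1:1", "F>L", "F<L", "F=L>1", "unique")


# ---------------------------------------------------------------------------
# Genome pair with orthogroups
# ---------------------------------------------------------------------------

def _random_sequence(rng, length: int, gc_start=0.30, gc_end=0.50) -> np.ndarray:
    """Nucleotide array with a linear GC gradient along the scaffold."""
    gc = np.linspace(gc_start, gc_end, length)
    probs = np.column_stack([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    u = rng.random(length)
    cum = np.cumsum(probs, axis=1)
    idx = (u[:, None] > cum).sum(axis=1)
    return np.array(list("ACGT"))[idx]


def generate_genome_pair(config: GenomeConfig | None = None, seed: int = 0):
    """Full synthetic input set: two genomes, gene models, TE features,
    orthogroups and the truth table.  Raises if the requested genes cannot
    fit on the configured scaffolds."""
    config = config or GenomeConfig()
    rng = _rng(seed, "genome")
    og_rng = _rng(seed, "orthogroups")

    fr = np.asarray(config.category_fractions, dtype=float)
    if fr.sum() <= 0 or len(fr) != 5:
        raise ValueError("need 5 non-negative category fractions")
    fr = fr / fr.sum()

    truth = SyntheticTruth()
    categories = og_rng.choice(len(CATEGORY_NAMES), size=config.n_orthogroups, p=fr)
    og_counts = []
    for i, cat_idx in enumerate(categories):
        cat = CATEGORY_NAMES[cat_idx]
        if cat == "1:1":
            A, F, L = 1, 1, 1
        elif cat == "F>L":
            L = int(og_rng.integers(1, 3))
            F = L + int(og_rng.integers(1, 3))
            A = 1
        elif cat == "F<L":
            F = int(og_rng.integers(1, 3))
            L = F + int(og_rng.integers(1, 3))
            A = 1
        elif cat == "F=L>1":
            F = L = int(og_rng.integers(2, 4))
            A = 1
        else:  # unique
            if og_rng.random() < 0.5:
                A, F, L = 0, int(og_rng.integers(2, 4)), 0
            else:
                A, F, L = 0, 0, int(og_rng.integers(2, 4))
        og_id = f"OG{i:05d}"
        truth.true_counts[og_id] = {"A": A, "F": F, "L": L}
        truth.category[og_id] = cat
        og_counts.append((og_id, A, F, L))

    # haplotig inflation: one artifactual extra copy in a multicopy species
    multicopy = [(og_id, F, L) for og_id, A, F, L in og_counts if F > 1 or L > 1]
    n_haplo = int(round(config.haplotig_fraction * len(multicopy)))
    haplo_idx = set(og_rng.choice(len(multicopy), size=n_haplo, replace=False)
                    ) if n_haplo else set()

    # materialize gene ids per species
    genes_per_species: dict[str, list[list[str]]] = {"A": [], "F": [], "L": []}
    counters = {"A": 0, "F": 0, "L": 0}
    prefix = {"A": "Acom", "F": "Tfas", "L": "Tlei"}

    def new_gene(sp: str) -> str:
        counters[sp] += 1
        return f"{prefix[sp]}_g{counters[sp]:05d}"

    orthogroups = []
    mc_pos = {og_id: k for k, (og_id, _, _) in enumerate(multicopy)}
    for og_id, A, F, L in og_counts:
        members = {sp: [new_gene(sp) for _ in range(n)]
                   for sp, n in (("A", A), ("F", F), ("L", L))}
        if og_id in mc_pos and mc_pos[og_id] in haplo_idx:
            sp = "F" if truth.true_counts[og_id]["F"] > 1 else "L"
            partner = members[sp][int(og_rng.integers(0, len(members[sp])))]
            artifact = new_gene(sp)
            members[sp].append(artifact)
            truth.haplotig_genes[artifact] = partner
            truth.haplotig_orthogroups.add(og_id)
        orthogroups.append(OrthogroupRecord(og_id, members))

    # genomes and gene models for the two focal species
    genomes, gene_models, te_features = {}, {}, {}
    for sp in ("F", "L"):
        gene_ids = [gid for og in orthogroups
                    for gid in og.genes_by_species.get(sp, [])]
        genome, models, tes = _build_genome(rng, config, sp, gene_ids)
        genomes[sp], gene_models[sp], te_features[sp] = genome, models, tes
    for og in orthogroups:
        for sp in ("F", "L"):
            for gid in og.genes_by_species.get(sp, []):
                if gid in gene_models[sp]:
                    gene_models[sp][gid].orthogroup_id = og.orthogroup_id

    _plant_de_truth(config, og_rng, orthogroups, truth)
    return (genomes, gene_models, te_features, orthogroups, truth)


def _build_genome(rng, config: GenomeConfig, sp: str, gene_ids: list[str]):
    """One species' scaffolds with placed genes and soft-masked TEs."""
    n_sc, length = config.n_scaffolds, config.scaffold_length
    slot = 2000  # exact per-gene stride: gene plus intergenic gap
    per_scaffold_cap = max(0, (length - 200) // slot)
    capacity = n_sc * per_scaffold_cap
    if len(gene_ids) > capacity:
        raise ValueError(
            f"{len(gene_ids)} genes exceed capacity {capacity} "
            f"({n_sc} x {length} bp scaffolds)")
    seqs = {f"{sp}_scaf{k+1}": _random_sequence(rng, length) for k in range(n_sc)}
    models: dict[str, GeneModel] = {}
    scaffold_ids = sorted(seqs)
    per_scaffold = int(np.ceil(len(gene_ids) / n_sc))
    it = iter(gene_ids)
    for sid in scaffold_ids:
        placed = 0
        pos = 200
        while placed < min(per_scaffold, per_scaffold_cap) and pos + slot <= length:
            try:
                gid = next(it)
            except StopIteration:
                break
            glen = int(rng.integers(600, 1601))
            start = pos
            end = start + glen
            n_ex = int(rng.integers(1, 9))
            bounds = np.sort(rng.choice(np.arange(1, glen), size=2 * n_ex - 2,
                                        replace=False)) if n_ex > 1 else np.array([])
            cuts = [start] + [start + int(b) for b in bounds] + [end]
            exons = [(cuts[2 * i], cuts[2 * i + 1]) for i in range(n_ex)]
            exons = [(s, e) for s, e in exons if e > s] or [(start, end)]
            strand = "+" if rng.random() < 0.5 else "-"
            cds_aa = max(20, sum(e - s for s, e in exons) // 3 // 3)
            models[gid] = GeneModel(
                gene_id=gid, scaffold_id=sid, start=start, end=end,
                strand=strand, exons=exons, cds_len_aa=cds_aa,
                has_start_codon=bool(rng.random() < 0.9),
                has_stop_codon=bool(rng.random() < 0.9))
            pos = start + slot
            placed += 1
    # TEs: uniformly placed per class at the configured density, soft-masked
    tes = []
    for sid in scaffold_ids:
        arr = seqs[sid]
        for cls, dens in config.te_density.items():
            n_te = rng.poisson(dens * length / 100_000)
            for _ in range(n_te):
                s = int(rng.integers(0, max(1, length - config.te_length)))
                e = min(length, s + config.te_length)
                arr[s:e] = np.char.lower(arr[s:e])
                tes.append(TEFeature(sid, s, e, cls,
                                     known=bool(rng.random() < 0.9)))
    genome = GenomeSequences({sid: "".join(seqs[sid]) for sid in scaffold_ids})
    return genome, models, tes


def _plant_de_truth(config: GenomeConfig, rng, orthogroups, truth: SyntheticTruth):
    """Choose the measured gene set (species-F single-copy-ish genes) and
    plant species-specific diel parameters for a DE fraction of it."""
    measured = [og.genes_by_species["F"][0] for og in orthogroups
                if og.count("F") >= 1]
    n_de = int(round(config.de_fraction * len(measured)))
    de_set = set(rng.choice(measured, size=n_de, replace=False)) if n_de else set()
    for gid in measured:
        phi = float(rng.uniform(0, 24))
        if gid in de_set:
            params = {"b": config.baseline_expression,
                      "A_F": config.de_amplitude, "A_L": 0.0,
                      "phi_F": phi, "phi_L": phi,
                      "dispersion": config.nb_dispersion}
            truth.de_genes[gid] = params
        else:
            amp = float(rng.uniform(0.0, 0.5))  # shared mild rhythm, no DE
            params = {"b": config.baseline_expression,
                      "A_F": amp, "A_L": amp, "phi_F": phi, "phi_L": phi,
                      "dispersion": config.nb_dispersion}
        truth.gene_params[gid] = params


# ---------------------------------------------------------------------------
# Coverage
# ---------------------------------------------------------------------------

def simulate_coverage(gene_ids, truth: SyntheticTruth, mean_cov: float = 30.0,
                      haplotig_fraction: float = 1.0, noise_sd: float = 0.1,
                      seed: int = 0) -> pd.DataFrame:
    """Per-gene mean coverage: haplotig pairs sit at about half the genome
    mean (reads split between the two copies), everything else at the mean,
    with multiplicative Gaussian noise of relative sd ``noise_sd``.

    ``haplotig_fraction`` selects the fraction of planted haplotig pairs
    that actually show the coverage drop (1 = all, 0 = none).
    """
    if mean_cov < 0:
        raise ValueError("negative coverage parameter")
    if not 0.0 <= haplotig_fraction <= 1.0:
        raise ValueError("haplotig_fraction outside [0, 1]")
    rng = _rng(seed, "coverage")
    artifacts = sorted(truth.haplotig_genes)
    n_eff = int(round(haplotig_fraction * len(artifacts)))
    affected = set(artifacts[:n_eff])
    halved = set()
    for art in affected:
        halved.add(art)
        halved.add(truth.haplotig_genes[art])
    rows = []
    for gid in gene_ids:
        base = mean_cov / 2.0 if gid in halved else mean_cov
        cov = max(0.0, base * (1.0 + rng.normal(0.0, noise_sd)))
        rows.append({"gene_id": gid, "mean_cov": cov})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Diel counts
# ---------------------------------------------------------------------------

def diel_mean(b: float, A: float, phi: float, t: float) -> float:
    """Expected expression b * exp(A * sin(2*pi*(t - phi)/24))."""
    return b * float(np.exp(A * np.sin(2 * np.pi * (t - phi) / 24.0)))


def simulate_diel_counts(genes: dict[str, GeneModel], truth: SyntheticTruth,
                         n_reps: int = 6,
                         timepoints=(0, 4, 8, 12, 16, 20),
                         seed: int = 0) -> pd.DataFrame:
    """Exon-level negative-binomial counts for both species.

    Samples are columns named ``<species>_g<rep>_t<hours>``; exon rows are
    ``<gene>.exon<k>`` and partition the simulated gene total by a
    multinomial on exon lengths (so summing exons recovers the gene count
    exactly).  Gene means follow the planted diel curve per species.
    """
    if n_reps < 2:
        raise ValueError("need at least 2 replicates per species x time")
    rng = _rng(seed, "counts")
    cols = [f"{sp}_g{r+1}_t{t}" for sp in ("F", "L")
            for r in range(n_reps) for t in timepoints]
    measured = [gid for gid in truth.gene_params if gid in genes]
    rows_index, data = [], []
    for gid in measured:
        params = truth.gene_params[gid]
        disp = params["dispersion"]
        gene = genes[gid]
        exon_len = np.array([e - s for s, e in gene.exons], dtype=float)
        exon_p = exon_len / exon_len.sum()
        gene_counts = []
        for sp in ("F", "L"):
            A, phi = params[f"A_{sp}"], params[f"phi_{sp}"]
            for _r in range(n_reps):
                for t in timepoints:
                    mu = diel_mean(params["b"], A, phi, t)
                    if disp > 0:
                        shape = 1.0 / disp
                        lam = rng.gamma(shape, mu / shape)
                    else:
                        lam = mu
                    gene_counts.append(rng.poisson(lam))
        gene_counts = np.asarray(gene_counts)
        exon_counts = np.array(
            [rng.multinomial(c, exon_p) for c in gene_counts]).T  # exons x samples
        for k in range(len(exon_p)):
            rows_index.append(f"{gid}.exon{k+1}")
            data.append(exon_counts[k])
    return pd.DataFrame(np.asarray(data), index=rows_index, columns=cols)


# ---------------------------------------------------------------------------
# Codon pairs
# ---------------------------------------------------------------------------

def simulate_codon_pair(n_codons: int, omega: float, kappa: float, t: float,
                        seed: int = 0) -> tuple[list[str], list[str]]:
    """A codon-aligned pair evolved under the scaled GY-type model: the
    ancestor is drawn uniformly from the 61 sense codons and the descendant
    from P(t); no stop codons can occur.  t is the total divergence in
    expected substitutions per codon."""
    if n_codons < 1:
        raise ValueError("n_codons must be >= 1")
    if min(omega, kappa) <= 0 or t < 0:
        raise ValueError("model parameters must be positive (t >= 0)")
    rng = _rng(seed, "codons")
    pi = np.full(N_CODONS, 1.0 / N_CODONS)
    anc_idx = rng.integers(0, N_CODONS, size=n_codons)
    if t == 0:
        codons = [SENSE_CODONS[i] for i in anc_idx]
        return list(codons), list(codons)
    Q = build_rate_matrix(pi, kappa, omega)
    P = transition_matrix(Q, pi, t)
    P = P / P.sum(axis=1, keepdims=True)
    des_idx = np.array([rng.choice(N_CODONS, p=P[i]) for i in anc_idx])
    return ([SENSE_CODONS[i] for i in anc_idx],
            [SENSE_CODONS[i] for i in des_idx])


# ---------------------------------------------------------------------------
# Promoters and motifs
# ---------------------------------------------------------------------------

def generate_promoters(n: int, length: int = 2000, seed: int = 0,
                       exclude_motifs=()) -> list[str]:
    """Background promoter sequences free of the given motifs (rejection
    over windows; motifs must be short for this to terminate quickly)."""
    rng = _rng(seed, "promoters")
    out = []
    motifs = [m.upper() for m in exclude_motifs]
    for _ in range(n):
        seq = "".join(rng.choice(list("ACGT"), size=length))
        for m in motifs:
            while m in seq:
                k = seq.find(m)
                repl = "".join(rng.choice(list("ACGT"), size=len(m)))
                seq = seq[:k] + repl + seq[k + len(m):]
        out.append(seq)
    return out


def plant_motifs(promoters: list[str], motif_rates: dict[str, float],
                 seed: int = 0) -> tuple[list[str], dict[str, int]]:
    """Plant Poisson-distributed motif occurrences at the stated per-kb rate.

    Occurrences are written into disjoint slots so planted strings never
    overwrite each other; returns the modified promoters and the number of
    planted occurrences per motif.  Raises if a motif is longer than the
    promoter.
    """
    rng = _rng(seed, "promoters")
    planted = {m: 0 for m in motif_rates}
    out = []
    slot = max((len(p) for p in motif_rates), default=8)
    for seq in promoters:
        arr = list(seq)
        for motif, rate in motif_rates.items():
            if len(motif) > len(seq):
                raise ValueError(f"motif {motif} longer than promoter")
            k = rng.poisson(rate * len(seq) / 1000.0)
            if k == 0:
                continue
            n_slots = len(seq) // slot
            k = min(k, n_slots)
            positions = rng.choice(n_slots, size=k, replace=False)
            for p in positions:
                start = int(p) * slot
                arr[start:start + len(motif)] = list(motif)
            planted[motif] += k
        out.append("".join(arr))
    return out, planted


# ---------------------------------------------------------------------------
# Metabolites
# ---------------------------------------------------------------------------

TIMEPOINTS_META = ("D+1", "D+5", "D+9", "N+1", "N+5", "N+9")
_HOURS = {"D+1": 1.0, "D+5": 5.0, "D+9": 9.0, "N+1": 13.0, "N+5": 17.0, "N+9": 21.0}


def simulate_metabolites(n_accessions: int = 6, compounds=("malate", "citrate",
                                                           "glucose", "fructose"),
                         cam_amplitude: float = 3.0, noise_cv: float = 0.2,
                         seed: int = 0) -> tuple[pd.DataFrame, dict]:
    """MTIC-normalized abundance table: species F shows a CAM-like malate
    curve peaking at midday with peak/trough ratio ``cam_amplitude``;
    species L is flat; other compounds share mild random rhythms.  Noise is
    lognormal with coefficient of variation ``noise_cv``."""
    rng = _rng(seed, "metabolites")
    sigma = float(np.sqrt(np.log(1 + noise_cv ** 2)))
    params = {}
    for comp in compounds:
        base = float(rng.uniform(0.5, 2.0))
        if comp == "malate":
            params[comp] = {"F": {"base": base, "amp": cam_amplitude, "peak": 5.0},
                            "L": {"base": base, "amp": 1.0, "peak": 5.0}}
        else:
            amp = float(rng.uniform(1.0, 1.3))
            peak = float(rng.uniform(0, 24))
            params[comp] = {"F": {"base": base, "amp": amp, "peak": peak},
                            "L": {"base": base, "amp": amp, "peak": peak}}
    rows = []
    for sp in ("F", "L"):
        for a in range(n_accessions):
            for tp in TIMEPOINTS_META:
                h = _HOURS[tp]
                row = {"species": sp, "accession": f"{sp}acc{a+1}", "timepoint": tp}
                for comp in compounds:
                    p = params[comp][sp]
                    # cosine curve with peak/trough ratio = amp
                    log_amp = 0.5 * np.log(p["amp"])
                    mu = p["base"] * np.exp(
                        log_amp * np.cos(2 * np.pi * (h - p["peak"]) / 24.0))
                    row[comp] = float(mu * rng.lognormal(-sigma ** 2 / 2, sigma))
                rows.append(row)
    return pd.DataFrame(rows), params
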