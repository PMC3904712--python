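"""Seeded synthetic data with machine-readable ground truth.

Every generator is deterministic given (parameters, seed) and emulates the
statistical structure the analysis stages assume:

* :func:`simulate_family` — an Hsf-like protein family: subfamilies
  diverged along a star guide tree, each member carrying a DNA-binding
  domain template (with the LNTY / GFRK anchor tetrapeptides), an HR-A/B
  heptad region, and a variable C-terminal tail; coding sequences are
  reverse-translated and expanded into homeologous triplets at a set
  pairwise divergence (defaults near the ~99% identity of the three
  bread-wheat subgenomes, deliberately below a 99.5% assembly threshold).
* :func:`simulate_ests` — error-bearing reads sampled from coding
  sequences with optional 5'/3' truncation, in both orientations.
* :func:`simulate_promoters` — iid-background promoters with planted HSE
  elements of each category at recorded coordinates and strands.  An
  8-nt C/G-only buffer flanks each planted element so background bases
  cannot chain onto it (no {C,G} triplet is within one mismatch of GAA or
  TTC).
* :func:`simulate_expression` — replicated qPCR Ct tables generated from
  the efficiency model with lognormal noise, and normalized array
  matrices with known fold changes.

The mimicry is structural only: no real codon usage, probe behaviour or
chromatogram error profiles are modelled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .assembly import revcomp
from .io import SequenceRecord

__all__ = [
    "FamilySimParams",
    "EstSimParams",
    "PromoterSimParams",
    "ExpressionDesign",
    "simulate_family",
    "simulate_ests",
    "simulate_promoters",
    "simulate_expression",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# One codon per amino acid is enough for structure-preserving reverse
# translation; drawing among synonymous codons is seeded anyway.
CODONS = {
    "A": ["GCT", "GCC", "GCA"], "C": ["TGT", "TGC"], "D": ["GAT", "GAC"],
    "E": ["GAG"], "F": ["TTT"], "G": ["GGT", "GGC", "GGA"],
    "H": ["CAT", "CAC"], "I": ["ATT", "ATC"], "K": ["AAG"],
    "L": ["CTT", "CTC", "CTG"], "M": ["ATG"], "N": ["AAT", "AAC"],
    "P": ["CCT", "CCC", "CCA"], "Q": ["CAG"], "R": ["CGT", "CGC"],
    "S": ["TCT", "TCC", "AGC"], "T": ["ACT", "ACC", "ACA"],
    "V": ["GTT", "GTC", "GTG"], "W": ["TGG"], "Y": ["TAT", "TAC"],
}

SUBCLASS_LABELS = ["A1", "A2", "A3", "A4", "A5", "A6", "A7", "A8", "B1", "B2", "B4", "C1", "C2"]

# --- protein templates -----------------------------------------------------

_DBD_PRE = "MDPATNSGGSQPPFVSKTHEMVDDPSTDSIVSWSPNNNS"      # 39 aa
_DBD_N_ANCHOR = "LNTY"                                      # anchors a large intron
_DBD_MID = "FPGKLWTAEGSDRSIVQTTE"                            # 20 aa
_DBD_C_ANCHOR = "GFRK"
_DBD_POST = "IDPDRWEFANEGFQRGQKHLQKNIHRRKT"                  # 29 aa
DBD_TEMPLATE = _DBD_PRE + _DBD_N_ANCHOR + _DBD_MID + _DBD_C_ANCHOR + _DBD_POST  # 96 aa

_HEPTAD = "LAAVEQT"  # a and d hydrophobic
HRAB_TEMPLATE = _HEPTAD * 4 + "SGSNQPESGS" + _HEPTAD * 3    # HR-A, linker, HR-B


def _protected_positions(protein: str) -> set:
    """Positions kept invariant under evolution: anchor tetrapeptides and
    heptad a/d residues (so domain detection stays solvable)."""
    protected: set[int] = set()
    for anchor in (_DBD_N_ANCHOR, _DBD_C_ANCHOR):
        i = protein.find(anchor)
        if i >= 0:
            protected.update(range(i, i + len(anchor)))
    j = protein.find(_HEPTAD * 2)
    if j >= 0:
        k = protein.find(HRAB_TEMPLATE[:7], j)
        for off in range(len(HRAB_TEMPLATE)):
            if off % 7 in (0, 3) and off < 28:
                protected.add(j + off)
    return protected


def _evolve(protein: str, rate: float, rng: np.random.Generator, protected: set) -> str:
    """Poisson-substitution evolution at the given expected subs/site."""
    mutable = [i for i in range(len(protein)) if i not in protected]
    n_subs = rng.poisson(rate * len(mutable))
    n_subs = min(n_subs, len(mutable))
    seq = list(protein)
    for i in rng.choice(len(mutable), size=n_subs, replace=False):
        pos = mutable[int(i)]
        choices = [a for a in AMINO_ACIDS if a != seq[pos]]
        seq[pos] = choices[int(rng.integers(len(choices)))]
    return "".join(seq)


def _reverse_translate(protein: str, rng: np.random.Generator) -> str:
    return "".join(CODONS[aa][int(rng.integers(len(CODONS[aa])))] for aa in protein)


@dataclass(frozen=True)
class FamilySimParams:
    n_subfamilies: int = 8
    members_per_subfamily: int = 2
    depth_between: float = 0.25   # subs/site root → subfamily founder
    depth_within: float = 0.04    # subs/site founder → member
    homeolog_divergence: float = 0.010  # pairwise nucleotide divergence
    n_homeologs: int = 3
    tail_length: tuple = (120, 220)
    labels: tuple = ()  # subclass labels; defaults to the field's convention

    def __post_init__(self):
        if self.n_subfamilies < 2:
            raise ValueError("need at least 2 subfamilies")
        if not (0 < self.homeolog_divergence < 0.05):
            raise ValueError("homeolog divergence must lie in (0, 0.05)")


@dataclass
class FamilySim:
    proteins: list            # SequenceRecord, one per member
    cds: list                 # SequenceRecord, one per homeolog copy
    references: list          # (id, region_sequence, subclass) founder references
    truth: pd.DataFrame       # per entity: gene, subclass, kind
    region_spans: dict        # protein id -> (start, end) of DBD→HR-A/B region


def simulate_family(params: FamilySimParams = FamilySimParams(), seed: int = 0) -> FamilySim:
    """Generate a labelled synthetic Hsf-like family with ground truth."""
    rng = np.random.default_rng(seed)
    if params.labels:
        if len(params.labels) != params.n_subfamilies:
            raise ValueError("labels length must equal n_subfamilies")
        labels = list(params.labels)
    else:
        labels = SUBCLASS_LABELS[: params.n_subfamilies]
        if len(labels) < params.n_subfamilies:
            labels = labels + [f"A{9 + i}" for i in range(params.n_subfamilies - len(labels))]

    tail_len = int(rng.integers(params.tail_length[0], params.tail_length[1] + 1))
    tail = "".join(AMINO_ACIDS[int(i)] for i in rng.integers(0, len(AMINO_ACIDS), size=tail_len))
    root = DBD_TEMPLATE + HRAB_TEMPLATE + tail
    region_span = (0, len(DBD_TEMPLATE) + len(HRAB_TEMPLATE))
    protected = _protected_positions(root)

    proteins: list[SequenceRecord] = []
    cds: list[SequenceRecord] = []
    references: list[tuple] = []
    truth_rows: list[dict] = []
    region_spans: dict[str, tuple] = {}

    for label in labels:
        founder = _evolve(root, params.depth_between, rng, protected)
        references.append((f"ref_{label}", founder[region_span[0] : region_span[1]], label))
        for m in range(params.members_per_subfamily):
            member = _evolve(founder, params.depth_within, rng, protected)
            gene_id = f"sim{label}{chr(ord('a') + m)}"
            proteins.append(SequenceRecord(gene_id, member, "protein"))
            region_spans[gene_id] = region_span
            truth_rows.append({"entity": gene_id, "gene": gene_id, "subclass": label,
                               "kind": "protein"})
            base_cds = _reverse_translate(member, rng)
            # Homeolog copies differ at evenly spaced diagnostic sites where
            # each subgenome copy carries a distinct allele, so every pair
            # diverges by ~homeolog_divergence and no long window is
            # identical between copies (real inter-subgenome SNPs cluster
            # more unevenly; regular spacing makes identity thresholds
            # behave uniformly across read overlaps).
            spacing = max(3, int(round(1.0 / params.homeolog_divergence)))
            phase = int(rng.integers(0, min(spacing, 100)))
            sites = list(range(phase, len(base_cds), spacing))
            for h in range(1, params.n_homeologs + 1):
                seq = list(base_cds)
                for site in sites:
                    alleles = [b for b in "ACGT" if b != base_cds[site]]
                    seq[site] = alleles[(h - 1) % 3]
                hid = f"{gene_id}_h{h}"
                cds.append(SequenceRecord(hid, "".join(seq), "dna"))
                truth_rows.append({"entity": hid, "gene": gene_id, "subclass": label,
                                   "kind": "cds_homeolog"})
    return FamilySim(proteins, cds, references, pd.DataFrame(truth_rows), region_spans)


# --- ESTs ------------------------------------------------------------------

@dataclass(frozen=True)
class EstSimParams:
    # error rate reflects end-trimmed EST quality (raw chromatogram ends,
    # which carry most errors, are assumed removed upstream)
    read_length: tuple = (400, 700)
    error_rate: float = 0.0005
    coverage: int = 5
    truncate_5p: float = 0.0   # per gene: expose only the 3' part (PartialC-like)
    truncate_3p: float = 0.0   # per gene: expose only the 5' part (PartialN-like)
    exposed_fraction: float = 0.6

    def __post_init__(self):
        if not (0 <= self.error_rate <= 0.01):
            raise ValueError("error rate must lie in [0, 0.01]")
        if self.coverage < 1:
            raise ValueError("coverage must be >= 1")


@dataclass
class EstSim:
    reads: list               # assembly.EstRead-compatible SequenceRecords
    truth: pd.DataFrame       # read_id, gene, start, end, strand, truncation


def simulate_ests(genes: Sequence[SequenceRecord], params: EstSimParams = EstSimParams(),
                  seed: int = 0) -> EstSim:
    """Sample error-bearing reads from coding sequences.

    Read starts are stratified across the exposed region so that reads of
    one gene tile it with overlaps (EST libraries are far less even; the
    stratification keeps the assembly ground truth well defined).
    """
    rng = np.random.default_rng(seed)
    reads: list[SequenceRecord] = []
    rows: list[dict] = []
    for gene in genes:
        glen = len(gene.residues)
        u = rng.random()
        if u < params.truncate_5p:
            region = (glen - int(glen * params.exposed_fraction), glen)
            trunc = "5p"
        elif u < params.truncate_5p + params.truncate_3p:
            region = (0, int(glen * params.exposed_fraction))
            trunc = "3p"
        else:
            region, trunc = (0, glen), "none"
        r0, r1 = region
        span = r1 - r0
        mean_len = sum(params.read_length) / 2
        n_reads = max(2, int(math.ceil(params.coverage * span / mean_len)))
        for k in range(n_reads):
            length = int(rng.integers(params.read_length[0], params.read_length[1] + 1))
            length = min(length, span)
            window = span - length
            lo = r0 + int(round(window * k / n_reads))
            hi = r0 + int(round(window * (k + 1) / n_reads))
            start = int(rng.integers(lo, max(lo + 1, hi + 1)))
            seq = list(gene.residues[start : start + length])
            n_err = rng.binomial(length, params.error_rate)
            for i in rng.choice(length, size=n_err, replace=False):
                alt = [b for b in "ACGT" if b != seq[int(i)]]
                seq[int(i)] = alt[int(rng.integers(3))]
            strand = "+" if rng.random() < 0.5 else "-"
            out = "".join(seq) if strand == "+" else revcomp("".join(seq))
            rid = f"{gene.id}_r{k}"
            reads.append(SequenceRecord(rid, out, "dna"))
            rows.append({"read_id": rid, "gene": gene.id, "start": start,
                         "end": start + length, "strand": strand, "truncation": trunc})
    return EstSim(reads, pd.DataFrame(rows))


# --- promoters -------------------------------------------------------------

@dataclass(frozen=True)
class PlantedElement:
    category: str             # perfect_triple | degenerate_triple | double | gapped
    rel_position: int         # start relative to translation start (negative)
    strand: str = "+"


@dataclass(frozen=True)
class PromoterSimParams:
    length: int = 1500
    base_composition: tuple = (0.25, 0.25, 0.25, 0.25)  # A C G T
    planted: tuple = ()

    def __post_init__(self):
        if abs(sum(self.base_composition) - 1.0) > 1e-9:
            raise ValueError("base composition must sum to 1")


@dataclass
class PromoterSim:
    record: SequenceRecord
    offset: int               # in-sequence coordinate of the ATG A
    truth: pd.DataFrame       # category, start, end, rel_start, strand
    gff3: str


_SAFE = "CG"  # no {C,G} triplet is within 1 mismatch of GAA or TTC


def _element_sequence(category: str, rng: np.random.Generator) -> str:
    spacer = lambda n=2: "".join(_SAFE[int(i)] for i in rng.integers(0, 2, size=n))
    if category == "perfect_triple":
        return "GAA" + spacer() + "TTC" + spacer() + "GAA"
    if category == "degenerate_triple":
        # middle core degenerate at position 3 (TTC → TTT), the permissive spot
        return "GAA" + spacer() + "TTT" + spacer() + "GAA"
    if category == "double":
        return "GAA" + spacer() + "TTC"
    if category == "gapped":
        return "GAA" + spacer() + "TTC" + spacer(5) + "GAA"
    raise ValueError(f"unknown planted category {category!r}")


def simulate_promoters(params: PromoterSimParams = PromoterSimParams(), seed: int = 0,
                       name: str = "sim_promoter") -> PromoterSim:
    """One promoter with planted HSEs; the translation start sits at the
    sequence end (coordinate ``length``), so planted positions are given
    upstream-negative."""
    rng = np.random.default_rng(seed)
    L = params.length
    offset = L
    bases = np.array(list("ACGT"))
    seq = list(rng.choice(bases, size=L, p=params.base_composition))

    occupied: list[tuple] = []
    rows = []
    buffer = 8
    for plant in params.planted:
        core = _element_sequence(plant.category, rng)
        if plant.strand == "-":
            core = revcomp(core)
        start = offset + plant.rel_position
        if start < buffer or start + len(core) + buffer > L:
            raise ValueError(f"planted element at {plant.rel_position} does not fit")
        lo, hi = start - buffer, start + len(core) + buffer
        for o_lo, o_hi in occupied:
            if lo < o_hi and o_lo < hi:
                raise ValueError("planted elements overlap")
        occupied.append((lo, hi))
        for i in range(lo, start):
            seq[i] = _SAFE[int(rng.integers(2))]
        for i, c in enumerate(core):
            seq[start + i] = c
        for i in range(start + len(core), hi):
            seq[i] = _SAFE[int(rng.integers(2))]
        rows.append({"category": plant.category, "start": start, "end": start + len(core),
                     "rel_start": plant.rel_position, "strand": plant.strand})
    truth = pd.DataFrame(rows, columns=["category", "start", "end", "rel_start", "strand"])
    record = SequenceRecord(name, "".join(seq), "dna")
    gff_lines = ["##gff-version 3"]
    for i, r in truth.iterrows():
        gff_lines.append("\t".join([
            name, "hsfkit-sim", "HSE", str(r.start + 1), str(r.end), ".",
            r.strand, ".", f"ID=planted{i + 1};category={r.category}",
        ]))
    return PromoterSim(record, offset, truth, "\n".join(gff_lines) + "\n")


# --- expression ------------------------------------------------------------

@dataclass(frozen=True)
class ExpressionDesign:
    genes: tuple = ("g1",)
    true_folds: tuple = (1.0,)
    n_control: int = 3
    n_treated: int = 3
    cv: float = 0.1
    er: float = 2.0
    et: float = 2.0
    f: float = 1.0
    control_level: float = 0.1      # relative to the reference gene
    ct_ref_mean: float = 20.0
    ct_ref_sd: float = 0.1
    array_control_mean: float = 200.0

    def __post_init__(self):
        if any(f <= 0 for f in self.true_folds):
            raise ValueError("fold changes must be positive")
        if len(self.genes) != len(self.true_folds):
            raise ValueError("genes and true_folds length mismatch")


@dataclass
class ExpressionSim:
    ct_table: pd.DataFrame    # sample, group, gene, replicate, ct_ref, ct_target
    array_matrix: pd.DataFrame
    groups: dict
    truth: pd.DataFrame


def simulate_expression(design: ExpressionDesign = ExpressionDesign(), seed: int = 0) -> ExpressionSim:
    """Ct tables and array matrices with known fold changes.

    Expression noise is lognormal at the design CV; Ct values are obtained
    by inverting the efficiency model Er^Ct(ref)/Et^Ct(target)×F = level.
    """
    rng = np.random.default_rng(seed)
    sigma = math.sqrt(math.log(1.0 + design.cv ** 2))
    ln_er, ln_et, ln_f = math.log(design.er), math.log(design.et), math.log(design.f)

    ct_rows = []
    array_cols: dict[str, dict] = {}
    groups: dict[str, str] = {}
    samples = [("control", i) for i in range(design.n_control)] + [
        ("treated", i) for i in range(design.n_treated)
    ]
    for group, rep in samples:
        sample = f"{group}{rep + 1}"
        groups[sample] = group
        ct_ref = design.ct_ref_mean + (
            rng.normal(0.0, design.ct_ref_sd) if design.ct_ref_sd > 0 else 0.0
        )
        col = {}
        for gene, fold in zip(design.genes, design.true_folds):
            level = design.control_level * (fold if group == "treated" else 1.0)
            level_obs = level * math.exp(rng.normal(0.0, sigma))
            ct_target = (ln_er * ct_ref + ln_f - math.log(level_obs)) / ln_et
            ct_rows.append({"sample": sample, "group": group, "gene": gene,
                            "replicate": rep + 1, "ct_ref": ct_ref, "ct_target": ct_target})
            array_mean = design.array_control_mean * (fold if group == "treated" else 1.0)
            col[gene] = array_mean * math.exp(rng.normal(0.0, sigma))
        array_cols[sample] = col
    truth = pd.DataFrame({"gene": design.genes, "true_fold": design.true_folds,
                          "er": design.er, "et": design.et, "f": design.f})
    return ExpressionSim(
        ct_table=pd.DataFrame(ct_rows),
        array_matrix=pd.DataFrame(array_cols),
        groups=groups,
        truth=truth,
    )
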