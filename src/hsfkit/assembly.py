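"""EST-to-gene-model assembly for a polyploid transcript collection.

Hexaploid wheat carries three near-identical homeologous copies of most
genes (typically >99% nucleotide identity), so contig assembly must merge
only reads that are more similar than homeologs are to each other.  The
procedure implemented here:

1. pairwise local alignment of reads (both orientations); reads sharing
   an overlap of at least ``min_overlap`` nt at **strictly more than**
   ``identity_threshold`` identity (default 0.995) are linked;
2. single-linkage clustering over that relation; per-cluster consensus by
   column-wise majority vote (ties become IUPAC ambiguity codes);
3. singletons with no supporting match in the genomic scaffolds are
   discarded as presumed low-quality reads;
4. validated contigs are extended with flanking genomic sequence.

The identity denominator is the number of aligned overlap columns,
counting internal gap columns as mismatches.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

from Bio import Align

from .io import SequenceRecord

__all__ = [
    "EstRead",
    "Contig",
    "GenomicScaffold",
    "AssemblyParams",
    "percent_identity",
    "assemble_contigs",
    "validate_against_genome",
    "extend_with_genome",
]

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

IUPAC_FROM_BASES = {
    frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G", frozenset("T"): "T",
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("GC"): "S", frozenset("AT"): "W",
    frozenset("GT"): "K", frozenset("AC"): "M", frozenset("CGT"): "B", frozenset("AGT"): "D",
    frozenset("ACT"): "H", frozenset("ACG"): "V", frozenset("ACGT"): "N",
}


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _rc_kmer(kmer: str) -> str:
    return kmer.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class EstRead:
    id: str
    residues: str
    source: str = ""

    def __len__(self):
        return len(self.residues)


@dataclass(frozen=True)
class GenomicScaffold:
    id: str
    residues: str

    def __post_init__(self):
        if not self.residues:
            raise ValueError(f"scaffold {self.id!r} is empty")


@dataclass(frozen=True)
class Contig:
    """Consensus sequence with per-column depth and member provenance."""

    id: str
    consensus: str
    members: tuple            # read ids
    depth: tuple              # per consensus column
    strands: tuple = ()       # '+'/'-' per member, template orientation
    flags: tuple = ()

    @property
    def is_singleton(self) -> bool:
        return len(self.members) == 1


@dataclass(frozen=True)
class AssemblyParams:
    """Knobs of the assembly/validation/extension procedure.

    ``identity_threshold`` is applied strictly (> θ): a pair at exactly the
    threshold is *not* merged, mirroring the ">99.5%" rule that keeps wheat
    homeologs apart.
    """

    identity_threshold: float = 0.995
    min_overlap: int = 100
    min_genome_identity: float = 0.95
    min_genome_match: int = 100
    extension_limit: int = 500
    min_read_length: int = 100
    # shared-k-mer gate before pairwise alignment; any pair that could pass
    # the identity rule shares far more than this, so the gate is lossless
    prescreen_k: int = 16
    prescreen_min_shared: int = 3
    prescreen: bool = True
    # pairs whose anchored ungapped identity falls within this band below
    # the threshold are re-checked by full local alignment (an indel can
    # raise alignment identity above the ungapped estimate); widen for
    # indel-rich data
    full_alignment_band: float = 0.004

    def __post_init__(self):
        if not (0 < self.identity_threshold < 1):
            raise ValueError("identity threshold must lie in (0, 1)")
        if min(self.min_overlap, self.min_genome_match, self.extension_limit) <= 0:
            raise ValueError("overlaps and limits must be positive")


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 2
    aligner.mismatch_score = -3
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -2
    return aligner


@dataclass(frozen=True)
class IdentityResult:
    identity: float
    overlap: int          # aligned overlap columns (incl. gap columns)
    strand: str           # orientation of b relative to a
    a_span: tuple = (0, 0)  # 0-based half-open on a
    b_span: tuple = (0, 0)  # on b, in b's original orientation for '+'


def _alignment_identity(alignment) -> tuple[float, int, tuple, tuple]:
    counts = alignment.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    if columns == 0:
        return 0.0, 0, (0, 0), (0, 0)
    a_span = (int(alignment.coordinates[0][0]), int(alignment.coordinates[0][-1]))
    b_span = (int(alignment.coordinates[1][0]), int(alignment.coordinates[1][-1]))
    return counts.identities / columns, columns, a_span, b_span


def percent_identity(
    a: str,
    b: str,
    min_overlap: int = 100,
    both_strands: bool = True,
    aligner: Optional[Align.PairwiseAligner] = None,
) -> Optional[IdentityResult]:
    """Best-local-alignment identity of two sequences over their overlap.

    Returns ``None`` when the best overlap is shorter than ``min_overlap``
    ("no overlap").  Gap columns inside the overlap count as mismatches.
    """
    if not a or not b:
        raise ValueError("empty input sequence")
    aligner = aligner or _make_aligner()
    best: Optional[IdentityResult] = None
    for strand, bseq in (("+", b), ("-", revcomp(b))) if both_strands else (("+", b),):
        alignments = aligner.align(a, bseq)
        if not len(alignments):
            continue
        ident, cols, a_span, b_span = _alignment_identity(alignments[0])
        if cols < min_overlap:
            continue
        cand = IdentityResult(ident, cols, strand, a_span, b_span)
        if best is None or (cand.identity, cand.overlap) > (best.identity, best.overlap):
            best = cand
    return best


class _ReadView:
    """Cached byte arrays and k-mer indexes of a read in both orientations."""

    __slots__ = ("seq", "rc_seq", "arr", "rc_arr", "kmers", "rc_kmers", "kpos", "rc_kpos", "k")

    def __init__(self, seq: str, k: int):
        import numpy as _np

        self.seq = seq
        self.rc_seq = revcomp(seq)
        self.arr = _np.frombuffer(seq.encode(), dtype=_np.uint8)
        self.rc_arr = _np.frombuffer(self.rc_seq.encode(), dtype=_np.uint8)
        self.k = k
        self.kpos = {}
        for p in range(len(seq) - k + 1):
            self.kpos.setdefault(seq[p : p + k], p)
        self.rc_kpos = {}
        for p in range(len(self.rc_seq) - k + 1):
            self.rc_kpos.setdefault(self.rc_seq[p : p + k], p)
        self.kmers = set(self.kpos)
        self.rc_kmers = set(self.rc_kpos)


def _anchored_identity(a: "_ReadView", b_arr, b_kpos, a_kmers_shared, min_overlap: int):
    """Best ungapped identity over anchor-implied offsets (substitution-only
    alignment; a lower bound on what full alignment could achieve)."""
    from collections import Counter

    offsets = Counter(a.kpos[m] - b_kpos[m] for m in a_kmers_shared)
    best = None
    for offset, _ in offsets.most_common(3):
        a0 = max(0, offset)
        b0 = max(0, -offset)
        length = min(len(a.arr) - a0, len(b_arr) - b0)
        if length < min_overlap:
            continue
        matches = int((a.arr[a0 : a0 + length] == b_arr[b0 : b0 + length]).sum())
        ident = matches / length
        if best is None or ident > best[0]:
            best = (ident, length)
    return best


def _pair_links(vi: "_ReadView", vj: "_ReadView", params: "AssemblyParams", aligner):
    """Decide whether two reads link under the identity rule.

    The shared-k-mer gate and the anchored ungapped identity decide clear
    cases; only near-threshold pairs (where an indel-aware alignment could
    change the verdict) fall back to full local alignment.
    """
    need_full = False
    strand_of_full = None
    for strand, kmers_j, kpos_j, arr_j in (
        ("+", vj.kmers, vj.kpos, vj.arr),
        ("-", vj.rc_kmers, vj.rc_kpos, vj.rc_arr),
    ):
        shared = vi.kmers & kmers_j
        if params.prescreen and len(shared) < params.prescreen_min_shared:
            continue
        best = _anchored_identity(vi, arr_j, kpos_j, shared, params.min_overlap) if shared else None
        if best is not None and best[0] > params.identity_threshold:
            return True, strand
        if best is None or best[0] > params.identity_threshold - params.full_alignment_band:
            need_full = True
            strand_of_full = strand
    if need_full:
        res = percent_identity(vi.seq, vj.seq, params.min_overlap, aligner=aligner)
        if res is not None and res.identity > params.identity_threshold:
            return True, res.strand
    return False, strand_of_full


class _UnionFind:
    def __init__(self, n):
        self.parent = list(range(n))

    def find(self, i):
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i, j):
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def _consensus(template: str, oriented: Sequence[str], aligner, k: int = 16) -> tuple[str, tuple]:
    """Column-wise majority vote of reads mapped onto the template.

    Reads are mapped by a shared-k-mer anchor offset when one clearly
    dominates (the common, substitution-only case) and by local alignment
    otherwise.
    """
    from collections import Counter

    tpos: dict[str, int] = {}
    for p in range(len(template) - k + 1):
        tpos.setdefault(template[p : p + k], p)
    votes: list[dict] = [dict() for _ in template]
    for seq in oriented:
        if seq == template:
            pairs = [(range(len(template)), range(len(seq)))]
        else:
            offsets = Counter(
                tpos[seq[p : p + k]] - p
                for p in range(len(seq) - k + 1)
                if seq[p : p + k] in tpos
            )
            common = offsets.most_common(2)
            if common and (len(common) == 1 or common[0][1] >= 5 * common[1][1]):
                offset = common[0][0]
                t0, q0 = max(0, offset), max(0, -offset)
                length = min(len(template) - t0, len(seq) - q0)
                pairs = [(range(t0, t0 + length), range(q0, q0 + length))]
            else:
                alns = aligner.align(template, seq)
                if not len(alns):
                    continue
                aln = alns[0]
                pairs = [
                    (range(int(t0), int(t1)), range(int(q0), int(q1)))
                    for (t0, t1), (q0, q1) in zip(aln.aligned[0], aln.aligned[1])
                ]
        for trange, qrange in pairs:
            for t, q in zip(trange, qrange):
                votes[t][seq[q]] = votes[t].get(seq[q], 0) + 1
    out = []
    depth = []
    for col, fallback in zip(votes, template):
        if not col:
            out.append(fallback)
            depth.append(1)
            continue
        top = max(col.values())
        winners = frozenset(b for b, c in col.items() if c == top)
        out.append(IUPAC_FROM_BASES.get(winners, "N") if len(winners) > 1 else next(iter(winners)))
        depth.append(sum(col.values()))
    return "".join(out), tuple(depth)


def assemble_contigs(
    reads: Sequence[EstRead],
    params: AssemblyParams = AssemblyParams(),
) -> tuple[list[Contig], list[Contig]]:
    """Single-linkage assembly of reads into contigs.

    Returns ``(contigs, singletons)``; both are :class:`Contig` objects
    (singletons have one member).  Cluster membership is independent of
    read input order: links are computed over all unordered pairs and the
    per-cluster template is the longest member (ties by id).
    """
    if not reads:
        raise ValueError("no reads supplied")
    short = [r.id for r in reads if len(r) < params.min_read_length]
    if short:
        raise ValueError(f"reads below minimum length {params.min_read_length}: {short}")
    aligner = _make_aligner()
    n = len(reads)
    uf = _UnionFind(n)
    strand_vs: dict[tuple, str] = {}
    views = [_ReadView(r.residues, params.prescreen_k) for r in reads]
    for i in range(n):
        for j in range(i + 1, n):
            link, strand = _pair_links(views[i], views[j], params, aligner)
            if link:
                uf.union(i, j)
                strand_vs[(i, j)] = strand

    clusters: dict[int, list[int]] = {}
    for i in range(n):
        clusters.setdefault(uf.find(i), []).append(i)

    # Orient members consistently within each cluster (BFS over link edges).
    adj: dict[int, list[tuple]] = {}
    for (i, j), s in strand_vs.items():
        adj.setdefault(i, []).append((j, s))
        adj.setdefault(j, []).append((i, s))

    contigs: list[Contig] = []
    singletons: list[Contig] = []
    for root in sorted(clusters, key=lambda r: min(reads[i].id for i in clusters[r])):
        idxs = clusters[root]
        template_idx = max(idxs, key=lambda i: (len(reads[i]), reads[i].id))
        orient = {template_idx: "+"}
        queue = [template_idx]
        while queue:
            cur = queue.pop()
            for nxt, s in adj.get(cur, ()):
                if nxt in orient:
                    continue
                orient[nxt] = orient[cur] if s == "+" else ("-" if orient[cur] == "+" else "+")
                queue.append(nxt)
        ordered = sorted(idxs, key=lambda i: reads[i].id)
        oriented_seqs = [
            reads[i].residues if orient.get(i, "+") == "+" else revcomp(reads[i].residues)
            for i in ordered
        ]
        consensus, depth = _consensus(reads[template_idx].residues, oriented_seqs, aligner)
        contig = Contig(
            id=f"contig_{reads[template_idx].id}",
            consensus=consensus,
            members=tuple(reads[i].id for i in ordered),
            depth=depth,
            strands=tuple(orient.get(i, "+") for i in ordered),
        )
        (singletons if contig.is_singleton else contigs).append(contig)
    return contigs, singletons


@dataclass(frozen=True)
class GenomeMatch:
    scaffold_id: str
    identity: float
    overlap: int
    scaffold_span: tuple  # 0-based half-open
    contig_span: tuple
    strand: str


def _best_genome_match(
    seq: str, scaffolds: Sequence[GenomicScaffold], params: AssemblyParams, aligner
) -> Optional[GenomeMatch]:
    best: Optional[GenomeMatch] = None
    for sc in scaffolds:
        res = percent_identity(
            sc.residues, seq, min_overlap=params.min_genome_match, aligner=aligner
        )
        if res is None:
            continue
        if res.identity < params.min_genome_identity:
            continue
        cand = GenomeMatch(sc.id, res.identity, res.overlap, res.a_span, res.b_span, res.strand)
        if best is None or (cand.identity, cand.overlap) > (best.identity, best.overlap):
            best = cand
    return best


def validate_against_genome(
    items: Sequence[Contig],
    scaffolds: Sequence[GenomicScaffold],
    params: AssemblyParams = AssemblyParams(),
) -> tuple[list[Contig], list[dict]]:
    """Screen assembled items against genomic scaffolds.

    Singletons without a qualifying genome match are discarded (reason
    recorded); multi-read contigs are always kept but flagged when
    unmatched.  Returns ``(kept, report)`` where the report has one row per
    input item (kept and discarded together cover the input).
    """
    if not scaffolds:
        warnings.warn("empty scaffold set: all singletons will be discarded", stacklevel=2)
    aligner = _make_aligner()
    kept: list[Contig] = []
    report: list[dict] = []
    for item in items:
        match = _best_genome_match(item.consensus, scaffolds, params, aligner) if scaffolds else None
        row = {
            "id": item.id,
            "n_members": len(item.members),
            "members": ",".join(item.members),
            "match_scaffold": match.scaffold_id if match else "",
            "match_identity": round(match.identity, 5) if match else "",
        }
        if match is None and item.is_singleton:
            row.update(status="discarded", reason="no genomic support")
        elif match is None:
            row.update(status="kept", reason="contig unmatched (flagged)")
            kept.append(replace(item, flags=item.flags + ("no_genome_match",)))
        else:
            row.update(status="kept", reason="")
            kept.append(item)
        report.append(row)
    return kept, report


def extend_with_genome(
    contig: Contig,
    scaffolds: Sequence[GenomicScaffold],
    params: AssemblyParams = AssemblyParams(),
) -> tuple[Contig, dict]:
    """Extend a validated contig with flanking genomic sequence.

    When the consensus matches a scaffold region at the configured
    criteria, up to ``extension_limit`` nt of flanking scaffold sequence is
    appended on each side (truncated, and noted, at scaffold ends).  An
    unmatched contig is returned unchanged with a flag.
    """
    aligner = _make_aligner()
    match = _best_genome_match(contig.consensus, scaffolds, params, aligner) if scaffolds else None
    if match is None:
        report = {"id": contig.id, "extended": False, "reason": "no genomic match"}
        return replace(contig, flags=contig.flags + ("not_extended",)), report

    sc = next(s for s in scaffolds if s.id == match.scaffold_id)
    genome = sc.residues
    s0, s1 = match.scaffold_span
    left_start = max(0, s0 - params.extension_limit)
    right_end = min(len(genome), s1 + params.extension_limit)
    left, right = genome[left_start:s0], genome[s1:right_end]
    if match.strand == "-":
        # contig aligned to the scaffold's reverse strand: flanks swap sides
        left, right = revcomp(right), revcomp(left)
    extended = Contig(
        id=contig.id,
        consensus=left + contig.consensus + right,
        members=contig.members,
        depth=(1,) * len(left) + contig.depth + (1,) * len(right),
        strands=contig.strands,
        flags=contig.flags + ("genome_extended",),
    )
    report = {
        "id": contig.id,
        "extended": True,
        "scaffold": match.scaffold_id,
        "strand": match.strand,
        "match_span": match.scaffold_span,
        "left_extension": len(left),
        "right_extension": len(right),
        "left_truncated": s0 - params.extension_limit < 0,
        "right_truncated": s1 + params.extension_limit > len(genome),
    }
    return extended, report
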