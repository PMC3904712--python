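"""Hsf protein domain annotation.

Heat shock factors are defined by an N-proximal DNA-binding domain (DBD,
a helix–turn–helix fold) followed by the HR-A/B oligomerization region of
hydrophobic heptad repeats.  Wheat Hsf transcripts are frequently partial:
a very large intron falls between the LNTY and GFRK anchor tetrapeptides
inside the DBD, so truncated cDNAs often carry only the N-side (through
LNTY) or the C-side (from GFRK) of the domain.

This module provides:

* :func:`find_dbd` — Smith–Waterman search of a query against labelled
  reference DBDs (BLOSUM62, affine gaps), thresholded on score and
  identity; thresholds are calibrated so residue-shuffled proteins pass
  at a rate ≤1%.
* :func:`call_completeness` — FullDBD / N_half / C_half / NoDBD calls from
  the reference-side coverage of the hit relative to the anchor positions
  (anchors are located on the *reference*, since query anchors may be
  mutated).
* :func:`find_hrab` — heptad-phase scan for the HR-A/B coiled-coil region
  downstream of the DBD.  The hydrophobic set used at heptad positions a/d
  is {L, I, V, M, F} — F is included as a scanner convention for
  coiled-coil detection.
* :func:`aha_score` — composition score of AHA-like activation motifs
  (aromatic W/Y/F – hydrophobic L/I/V/M – acidic D/E residue-rich windows).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .io import SequenceRecord

__all__ = [
    "ReferenceDomain",
    "ReferenceDomainSet",
    "ScoringScheme",
    "DomainHit",
    "CompletenessCall",
    "AhaMotifHit",
    "find_dbd",
    "call_completeness",
    "find_hrab",
    "aha_score",
    "parse_reference_fasta",
]

AROMATIC = frozenset("WYF")
AHA_HYDROPHOBIC = frozenset("LIVM")
ACIDIC = frozenset("DE")
HEPTAD_HYDROPHOBIC = frozenset("LIVMF")

N_ANCHOR = "LNTY"
C_ANCHOR = "GFRK"


@dataclass(frozen=True)
class ReferenceDomain:
    id: str
    residues: str
    subclass: str  # e.g. "A1"

    @property
    def hsf_class(self) -> str:
        return self.subclass[0]


@dataclass(frozen=True)
class ReferenceDomainSet:
    references: tuple

    def __post_init__(self):
        classes = {r.hsf_class for r in self.references}
        missing = {"A", "B", "C"} - classes
        if missing:
            raise ValueError(f"reference set lacks class(es) {sorted(missing)}")

    def __iter__(self):
        return iter(self.references)

    def __len__(self):
        return len(self.references)


def parse_reference_fasta(records: Sequence[SequenceRecord]) -> ReferenceDomainSet:
    """Build a reference set from FASTA records with ``|class=A1`` header tags."""
    refs = []
    for rec in records:
        tag = None
        for part in rec.description.split("|"):
            if part.strip().startswith("class="):
                tag = part.strip().split("=", 1)[1]
        if tag is None:
            raise ValueError(f"reference {rec.id!r} lacks a |class= header tag")
        refs.append(ReferenceDomain(rec.id, rec.residues, tag))
    return ReferenceDomainSet(tuple(refs))


@dataclass(frozen=True)
class ScoringScheme:
    """Alignment scoring and DBD acceptance thresholds."""

    matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    min_score: float = 75.0
    min_identity: float = 0.30

    def __post_init__(self):
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")

    def make_aligner(self) -> Align.PairwiseAligner:
        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.substitution_matrix = substitution_matrices.load(self.matrix)
        aligner.open_gap_score = -self.gap_open
        aligner.extend_gap_score = -self.gap_extend
        return aligner


DEFAULT_SCHEME = ScoringScheme()


@dataclass(frozen=True)
class DomainHit:
    query_span: tuple        # 0-based half-open residue coordinates
    ref_id: str
    score: float
    identity: float
    kind: str                # "DBD" or "HRAB"
    ref_span: tuple = (0, 0)
    ref_length: int = 0
    metadata: dict = field(default_factory=dict)


@dataclass(frozen=True)
class CompletenessCall:
    label: str               # FullDBD | N_half | C_half | NoDBD
    n_anchor_covered: bool = False
    c_anchor_covered: bool = False


def _identity_from_alignment(alignment) -> float:
    counts = alignment.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    return counts.identities / columns if columns else 0.0


def find_dbd(
    query: str,
    refs: ReferenceDomainSet,
    scheme: ScoringScheme = DEFAULT_SCHEME,
) -> Optional[DomainHit]:
    """Best local alignment of the query against all reference DBDs.

    Returns a hit only if both the score and identity thresholds pass.
    """
    if len(refs) == 0:
        raise ValueError("empty reference set")
    if len(query) < 20:
        raise ValueError("query shorter than 20 residues")
    aligner = scheme.make_aligner()
    best: Optional[DomainHit] = None
    for ref in refs:
        alignments = aligner.align(query, ref.residues)
        if not len(alignments) or alignments.score <= 0:
            continue
        aln = alignments[0]
        hit = DomainHit(
            query_span=(int(aln.coordinates[0][0]), int(aln.coordinates[0][-1])),
            ref_id=ref.id,
            score=float(aln.score),
            identity=_identity_from_alignment(aln),
            kind="DBD",
            ref_span=(int(aln.coordinates[1][0]), int(aln.coordinates[1][-1])),
            ref_length=len(ref.residues),
            metadata={"subclass": ref.subclass},
        )
        if best is None or hit.score > best.score:
            best = hit
    if best is None:
        return None
    if best.score < scheme.min_score or best.identity < scheme.min_identity:
        return None
    return best


def _anchor_span(reference: str, anchor: str) -> Optional[tuple]:
    i = reference.find(anchor)
    return None if i < 0 else (i, i + len(anchor))


def call_completeness(
    query: str,
    dbd: Optional[DomainHit],
    reference: Optional[str] = None,
    full_coverage: float = 0.9,
) -> CompletenessCall:
    """Call DBD completeness from reference-side hit coverage.

    FullDBD when the hit covers at least ``full_coverage`` of the
    reference (or both anchors); N_half / C_half when only the LNTY-side /
    GFRK-side of the reference is covered; NoDBD otherwise.  Exactly one
    label is always produced.
    """
    if dbd is None:
        return CompletenessCall("NoDBD")
    r0, r1 = dbd.ref_span
    ref_len = dbd.ref_length or (len(reference) if reference else 0)
    coverage = (r1 - r0) / ref_len if ref_len else 0.0
    n_span = _anchor_span(reference, N_ANCHOR) if reference else None
    c_span = _anchor_span(reference, C_ANCHOR) if reference else None
    if n_span is None or c_span is None:
        # anchors unavailable: fall back to the coverage midpoint
        mid = ref_len / 2 if ref_len else 0
        n_cov = r0 <= mid * 0.9 and r1 >= mid * 0.5
        c_cov = r1 >= mid * 1.1 and r0 <= mid * 1.5
    else:
        n_cov = r0 <= n_span[0] and r1 >= n_span[1]
        c_cov = r0 <= c_span[0] and r1 >= c_span[1]
    if coverage >= full_coverage or (n_cov and c_cov):
        return CompletenessCall("FullDBD", n_cov, c_cov)
    if n_cov:
        return CompletenessCall("N_half", True, False)
    if c_cov:
        return CompletenessCall("C_half", False, True)
    return CompletenessCall("NoDBD")


@dataclass(frozen=True)
class HeptadConfig:
    """HR-A/B scanner parameters: ≥ ``min_heptads`` repeats with hydrophobic
    occupancy at heptad a/d positions of at least ``min_occupancy``."""

    min_heptads: int = 3
    min_occupancy: float = 0.6
    max_linker: int = 60   # residues allowed between HR-A and HR-B


def _scan_heptads(region: str, config: HeptadConfig):
    """All qualifying (start, n_heptads, phase, occupancy) windows."""
    hits = []
    n = len(region)
    for phase in range(7):
        for start in range(phase, n - 7 * config.min_heptads + 1):
            if (start - phase) % 7:
                continue
            max_k = (n - start) // 7
            for k in range(config.min_heptads, max_k + 1):
                window = region[start : start + 7 * k]
                ad = [window[i] for i in range(len(window)) if i % 7 in (0, 3)]
                occ = sum(c in HEPTAD_HYDROPHOBIC for c in ad) / len(ad)
                if occ >= config.min_occupancy:
                    hits.append((start, k, phase, occ))
    return hits


def find_hrab(
    query: str,
    dbd_end: int,
    config: HeptadConfig = HeptadConfig(),
) -> Optional[DomainHit]:
    """Scan downstream of the DBD for the HR-A/B heptad-repeat region.

    The best window maximizes (occupancy, length); if a second qualifying
    window follows after a linker, the hit spans both and records the
    sub-windows and linker length (the bipartite HR-A … HR-B arrangement).
    """
    if dbd_end >= len(query):
        raise ValueError("dbd_end beyond query length")
    region = query[dbd_end:]
    hits = _scan_heptads(region, config)
    if not hits:
        return None
    best = max(hits, key=lambda h: (h[3], h[1], -h[0]))
    b_start, b_k, b_phase, b_occ = best
    b_end = b_start + 7 * b_k
    # second sub-window after a linker
    tail = [h for h in hits if h[0] >= b_end + 1 and h[0] - b_end <= config.max_linker]
    sub = None
    if tail:
        second = max(tail, key=lambda h: (h[3], h[1], -h[0]))
        sub = second
    span_start = dbd_end + b_start
    span_end = dbd_end + (sub[0] + 7 * sub[1] if sub else b_end)
    metadata = {
        "phase": b_phase,
        "occupancy": b_occ,
        "subwindows": [(dbd_end + b_start, dbd_end + b_end)],
    }
    if sub:
        metadata["subwindows"].append((dbd_end + sub[0], dbd_end + sub[0] + 7 * sub[1]))
        metadata["linker_length"] = sub[0] - b_end
    return DomainHit(
        query_span=(span_start, span_end),
        ref_id="heptad-scan",
        score=b_occ,
        identity=b_occ,
        kind="HRAB",
        metadata=metadata,
    )


@dataclass(frozen=True)
class AhaMotifHit:
    window_span: tuple
    score: float
    n_aromatic: int
    n_hydrophobic: int
    n_acidic: int


def aha_score(peptide: str, window: int = 25) -> Optional[AhaMotifHit]:
    """Best AHA-like composition window of a peptide.

    Score = (aromatic + hydrophobic + acidic) / window length; a window
    qualifies only with ≥1 aromatic and ≥1 acidic residue.  Returns the
    highest-scoring qualifying window, or None.
    """
    if not peptide:
        raise ValueError("empty peptide")
    w = min(window, len(peptide))
    best: Optional[AhaMotifHit] = None
    for start in range(len(peptide) - w + 1):
        win = peptide[start : start + w]
        na = sum(c in AROMATIC for c in win)
        nh = sum(c in AHA_HYDROPHOBIC for c in win)
        nd = sum(c in ACIDIC for c in win)
        if na < 1 or nd < 1:
            continue
        hit = AhaMotifHit((start, start + w), (na + nh + nd) / w, na, nh, nd)
        if best is None or hit.score > best.score:
            best = hit
    return best
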