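"""Heat shock element (HSE) grammar scanning of promoter sequences.

Trimeric Hsf binds promoter arrays of inverted nGAAn repeats: alternating
GAA / TTC core triplets separated by 2-nt spacers.  The grammar implemented
here follows the functional categories observed in Hsf binding work:

* ``perfect_triple`` — three alternating exact cores, both spacers 2 nt
  (e.g. ``GAAGCTTCGGGAA``), the canonical high-affinity element;
* ``degenerate_triple`` — three cores, spacers 2 nt, exactly one core with
  a single mismatch (e.g. ``GAACATTTTGGAA``, middle core TTT);
* ``double`` — exactly two exact cores at spacer 2 (weak binding, ≤10% of
  the perfect element by default);
* ``gapped`` — a chain with a lengthened spacer (little detectable
  binding by default);
* ``extended`` — more than three chained cores, reported as one element.

Single-nucleotide degeneracy is tolerated in at most one core per element
and only interior to a chain (between exact cores); position weights are
keyed in the strand-invariant GAA frame (default: position 1 permissive —
TTT for a TTC core, AAA for GAA — positions 2–3 restrictive) and are
scoring conventions reflecting qualitative binding outcomes, never
measured affinities.  Empirical relative-binding-activity (RBA) tables are
normalized so a chosen reference element is exactly 1 and a no-HSE
background is 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .io import DNA_ALPHABET

__all__ = [
    "HseModule",
    "HseElement",
    "ScanConfig",
    "find_modules",
    "assemble_elements",
    "score_element",
    "scan_promoter",
    "normalize_rba",
    "count_perfect_triple_windows",
    "elements_to_gff3",
]

CORES = {"GAA": "GAA", "TTC": "TTC"}
OPPOSITE = {"GAA": "TTC", "TTC": "GAA"}
_RC = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class HseModule:
    """One nGAAn / nTTCn core triplet on the forward strand."""

    start: int               # 0-based
    orientation: str         # "GAA" or "TTC"
    observed: str            # the triplet as read
    mismatches: int = 0      # 0 or 1 vs the perfect core
    mismatch_position: Optional[int] = None  # 1–3 vs the core as read

    @property
    def end(self) -> int:
        return self.start + 3

    @property
    def gaa_frame_position(self) -> Optional[int]:
        """Mismatch position read in the GAA frame (strand-invariant: a
        TTC-module mismatch at read position p is the same physical site
        as a GAA-frame mismatch at 4 − p)."""
        if self.mismatch_position is None:
            return None
        return self.mismatch_position if self.orientation == "GAA" else 4 - self.mismatch_position


@dataclass(frozen=True)
class HseElement:
    """A maximal chain of alternating cores with its category and score."""

    modules: tuple
    spacers: tuple           # nt between consecutive cores
    category: str
    total_mismatches: int
    score: float
    span: tuple              # 0-based half-open, first core start → last core end
    flank_left: str = ""
    flank_right: str = ""
    rel_span: Optional[tuple] = None  # relative to translation start (ATG A = 0)

    @property
    def n_modules(self) -> int:
        return len(self.modules)


@dataclass(frozen=True)
class ScanConfig:
    allow_degenerate: bool = True
    max_mismatched_modules: int = 1
    max_gap_extension: int = 3      # spacer may stretch to 2 + this
    min_modules: int = 2
    # keyed by the GAA-frame mismatch position (strand-invariant):
    # position 1 (TTT for a TTC core / AAA for GAA) is permissive, per the
    # functional atypical element; positions 2-3 are restrictive, per the
    # weakly bound synthetic variants.  Conventions, not measured affinity.
    position_weights: dict = field(default_factory=lambda: {1: 0.5, 2: 0.1, 3: 0.1})
    double_score: float = 0.1
    gapped_score: float = 0.0
    extended_score: float = 1.0
    flank_window: int = 1
    allow_tcc_core: bool = False    # treat TCC/GGA as additional degenerate cores

    def __post_init__(self):
        if any(not (0.0 <= w <= 1.0) for w in self.position_weights.values()):
            raise ValueError("position weights must lie in [0, 1]")


DEFAULT_SCAN = ScanConfig()


def _check_dna(seq: str) -> None:
    bad = set(seq.upper()) - DNA_ALPHABET
    if bad:
        raise ValueError(f"non-DNA characters in sequence: {sorted(bad)}")


def _core_candidate(seq: str, pos: int, orientation: str, allow_degenerate: bool) -> Optional[HseModule]:
    if pos < 0 or pos + 3 > len(seq):
        return None
    trip = seq[pos : pos + 3]
    core = CORES[orientation]
    mism = [i for i in range(3) if trip[i] != core[i]]
    if not mism:
        return HseModule(pos, orientation, trip, 0, None)
    if allow_degenerate and len(mism) == 1:
        return HseModule(pos, orientation, trip, 1, mism[0] + 1)
    return None


def _exact_modules(seq: str) -> list[HseModule]:
    out = []
    for i in range(len(seq) - 2):
        trip = seq[i : i + 3]
        if trip == "GAA":
            out.append(HseModule(i, "GAA", trip))
        elif trip == "TTC":
            out.append(HseModule(i, "TTC", trip))
    return out


def _exact_spacer2_chains(seq: str) -> list[list]:
    """Maximal chains of exact cores linked at spacer exactly 2.

    The successor position is unique, so these chains are fully
    deterministic and strand-symmetric.  Returns [modules, spacers] lists
    ordered by start position.
    """
    modules = _exact_modules(seq)
    by_pos = {m.start: m for m in modules}
    has_pred: set[int] = set()
    for m in modules:
        nxt = by_pos.get(m.end + 2)
        if nxt is not None and nxt.orientation == OPPOSITE[m.orientation]:
            has_pred.add(nxt.start)
    chains = []
    for m in modules:
        if m.start in has_pred:
            continue
        chain, spacers = [m], []
        while True:
            nxt = by_pos.get(chain[-1].end + 2)
            if nxt is None or nxt.orientation != OPPOSITE[chain[-1].orientation]:
                break
            chain.append(nxt)
            spacers.append(2)
        chains.append([chain, spacers])
    return chains


def _apply_merges(chains: list, candidates: list) -> list:
    """Apply sorted merge candidates.

    Chains are tracked by the identity of their current first and last
    modules, so a candidate stays applicable as long as the link site it
    was computed from is still a free chain end."""
    end_of = {id(c[0][-1]): k for k, c in enumerate(chains)}
    start_of = {id(c[0][0]): k for k, c in enumerate(chains)}
    for key_and_payload in sorted(candidates, key=lambda c: c[0]):
        _, ma, mb, bridge, spacers = key_and_payload
        i = end_of.get(id(ma))
        j = start_of.get(id(mb))
        if i is None or j is None or i == j or chains[i] is None or chains[j] is None:
            continue
        mods_a, spc_a = chains[i]
        mods_b, spc_b = chains[j]
        if bridge and (sum(m.mismatches for m in mods_a + mods_b) + 1) > 1:
            continue
        chains[j] = [mods_a + bridge + mods_b, spc_a + spacers + spc_b]
        chains[i] = None
        del end_of[id(ma)]
        del start_of[id(mb)]
        start_of[id(mods_a[0])] = j
        end_of[id(mods_b[-1])] = j
    return [c for c in chains if c is not None]


def _merge_degenerate_bridges(seq: str, chains: list, config: ScanConfig, gapped: bool) -> list:
    """Merge chains across one interior degenerate core.

    Degeneracy is recognized only between exact cores — a terminal
    single-mismatch triplet is indistinguishable from background — and at
    most one degenerate core per element.  With ``gapped=False`` only the
    canonical 2-nt spacers are considered; otherwise spacers may stretch
    by the configured gap extension.  Candidates are applied smallest-gap
    first with strand-symmetric tie-breaks.
    """
    if not config.allow_degenerate or len(chains) < 2:
        return chains
    max_g = config.max_gap_extension if gapped else 0
    candidates = []
    for i in range(len(chains)):
        for j in range(len(chains)):
            if i == j:
                continue
            ma, mb = chains[i][0][-1], chains[j][0][0]
            if not (7 <= mb.start - ma.end <= 7 + 2 * max_g):
                continue
            if ma.orientation != mb.orientation:
                continue
            if any(m.mismatches for m in chains[i][0] + chains[j][0]):
                continue
            opp = OPPOSITE[ma.orientation]
            for g1 in range(max_g + 1):
                pos = ma.end + 2 + g1
                g2 = mb.start - (pos + 3 + 2)
                if not (0 <= g2 <= max_g):
                    continue
                cand = _core_candidate(seq, pos, opp, allow_degenerate=True)
                if cand is not None and cand.mismatches == 1:
                    weight = config.position_weights.get(cand.gaa_frame_position, 0.0)
                    canonical = min(cand.observed, cand.observed.translate(_RC)[::-1])
                    key = (g1 + g2, max(g1, g2), -weight, canonical)
                    candidates.append((key, ma, mb, [cand], [2 + g1, 2 + g2]))
    return _apply_merges(chains, candidates)


def _merge_gap_links(chains: list, config: ScanConfig) -> list:
    """Merge chains directly linked by a lengthened spacer (no degeneracy)."""
    if config.max_gap_extension <= 0 or len(chains) < 2:
        return chains
    candidates = []
    for i in range(len(chains)):
        for j in range(len(chains)):
            if i == j:
                continue
            ma, mb = chains[i][0][-1], chains[j][0][0]
            spacer = mb.start - ma.end
            if not (3 <= spacer <= 2 + config.max_gap_extension):
                continue
            if mb.orientation != OPPOSITE[ma.orientation]:
                continue
            candidates.append(((spacer,), ma, mb, [], [spacer]))
    return _apply_merges(chains, candidates)


def _categorize(chain: Sequence[HseModule], spacers: Sequence[int]) -> Optional[str]:
    n = len(chain)
    mism = sum(m.mismatches for m in chain)
    if n < 2:
        return None
    if any(s > 2 for s in spacers):
        return "gapped" if n >= 3 else None
    if mism > 0 and n < 3:
        return None
    if n == 2:
        return "double"
    if n == 3:
        return "perfect_triple" if mism == 0 else "degenerate_triple"
    return "extended"


def score_element(element: "HseElement", config: ScanConfig = DEFAULT_SCAN) -> float:
    """Category score in [0, 1]; see the module docstring for the defaults."""
    if element.category == "perfect_triple":
        return 1.0
    if element.category == "degenerate_triple":
        bad = next(m for m in element.modules if m.mismatches)
        return config.position_weights.get(bad.gaa_frame_position, 0.0)
    if element.category == "double":
        return config.double_score
    if element.category == "gapped":
        return config.gapped_score
    return config.extended_score


def assemble_elements(seq: str, config: ScanConfig = DEFAULT_SCAN, offset: Optional[int] = None) -> list[HseElement]:
    """Maximal alternating-core chains of a sequence, categorized and scored.

    Exact cores chain deterministically (nearest valid successor); one
    interior degenerate core may bridge two exact chains.  Overlapping
    chains are deduplicated keeping the larger, then higher-scoring one.
    """
    seq = seq.upper()
    _check_dna(seq)
    chains = _exact_spacer2_chains(seq)
    chains = _merge_degenerate_bridges(seq, chains, config, gapped=False)
    chains = _merge_gap_links(chains, config)
    chains = _merge_degenerate_bridges(seq, chains, config, gapped=True)
    raw: list[tuple] = []
    for chain, spacers in chains:
        category = _categorize(chain, spacers)
        if category is None or len(chain) < config.min_modules:
            continue
        raw.append((tuple(chain), tuple(spacers), category))

    elements: list[HseElement] = []
    for chain, spacers, category in raw:
        span = (chain[0].start, chain[-1].end)
        stub = HseElement(chain, spacers, category, sum(m.mismatches for m in chain), 0.0, span)
        score = score_element(stub, config)
        fl = seq[max(0, span[0] - config.flank_window) : span[0]]
        fr = seq[span[1] : span[1] + config.flank_window]
        rel = (span[0] - offset, span[1] - offset) if offset is not None else None
        elements.append(
            HseElement(chain, spacers, category, stub.total_mismatches, score, span, fl, fr, rel)
        )

    # dedupe overlapping chains: larger, then higher-scoring, wins
    elements.sort(key=lambda e: (-e.n_modules, -e.score, e.span[0]))
    taken: set[int] = set()
    kept: list[HseElement] = []
    for el in elements:
        positions = {m.start for m in el.modules}
        if positions & taken:
            continue
        taken |= positions
        kept.append(el)
    kept.sort(key=lambda e: e.span[0])
    return kept


def find_modules(seq: str, config: ScanConfig = DEFAULT_SCAN) -> list[HseModule]:
    """All exact GAA/TTC cores, plus degenerate cores that chain into an
    element (degenerate triplets are ubiquitous in random sequence and are
    only meaningful inside a chain)."""
    seq = seq.upper()
    _check_dna(seq)
    modules = {(m.start, m.orientation): m for m in _exact_modules(seq)}
    if config.allow_degenerate:
        for el in assemble_elements(seq, config):
            for m in el.modules:
                modules.setdefault((m.start, m.orientation), m)
    return sorted(modules.values(), key=lambda m: m.start)


def scan_promoter(seq: str, config: ScanConfig = DEFAULT_SCAN, offset: Optional[int] = None) -> list[HseElement]:
    """Full promoter scan: find cores, chain them, score the elements.

    ``offset`` is the in-sequence coordinate of the translation start (the
    A of ATG = 0); element coordinates are then also reported relative to
    it, upstream negative.  An empty sequence yields an empty report.
    """
    if not seq:
        return []
    return assemble_elements(seq, config, offset=offset)


def count_perfect_triple_windows(elements: Sequence[HseElement]) -> int:
    """Number of perfect-triple windows (three consecutive exact cores at
    spacer 2) across elements — the quantity with the closed-form null
    expectation 2·(L−12)·4⁻⁹ on iid uniform sequence."""
    total = 0
    for el in elements:
        for i in range(el.n_modules - 2):
            if (
                el.spacers[i] == 2
                and el.spacers[i + 1] == 2
                and el.modules[i].mismatches == 0
                and el.modules[i + 1].mismatches == 0
                and el.modules[i + 2].mismatches == 0
            ):
                total += 1
    return total


def elements_to_gff3(elements: Sequence[HseElement], seqid: str) -> str:
    """GFF3 feature lines (type HSE, score = element score)."""
    lines = ["##gff-version 3"]
    for i, el in enumerate(elements, 1):
        attrs = (
            f"ID=hse{i};category={el.category};mismatches={el.total_mismatches};"
            f"spacers={','.join(map(str, el.spacers))};n_modules={el.n_modules}"
        )
        lines.append(
            "\t".join(
                [
                    seqid, "hsfkit", "HSE",
                    str(el.span[0] + 1), str(el.span[1]),  # GFF3 is 1-based inclusive
                    f"{el.score:g}", ".", ".", attrs,
                ]
            )
        )
    return "\n".join(lines) + "\n"


def elements_to_frame(elements: Sequence[HseElement], seqid: str = "") -> pd.DataFrame:
    rows = []
    for el in elements:
        rows.append(
            {
                "seqid": seqid,
                "start": el.span[0],
                "end": el.span[1],
                "rel_start": el.rel_span[0] if el.rel_span else pd.NA,
                "rel_end": el.rel_span[1] if el.rel_span else pd.NA,
                "category": el.category,
                "n_modules": el.n_modules,
                "mismatches": el.total_mismatches,
                "spacers": ",".join(map(str, el.spacers)),
                "score": el.score,
                "sequence": "",
            }
        )
    return pd.DataFrame(rows)


def normalize_rba(
    raw: pd.DataFrame,
    reference_id: str,
    background_id: str,
) -> pd.DataFrame:
    """Normalize raw binding replicates to relative binding activity.

    ``raw`` is long-format with columns ``element_id`` and ``value`` (one
    row per replicate).  RBA = (mean − background mean) / (reference mean −
    background mean), so the reference is exactly 1 and the background 0;
    negative values are clamped to 0 and flagged.
    """
    if not {"element_id", "value"} <= set(raw.columns):
        raise ValueError("raw table needs columns 'element_id' and 'value'")
    means = raw.groupby("element_id")["value"].agg(["mean", "count"])
    for required in (reference_id, background_id):
        if required not in means.index:
            raise ValueError(f"row {required!r} missing from RBA table")
    ref, bg = means.loc[reference_id, "mean"], means.loc[background_id, "mean"]
    if ref <= bg:
        raise ValueError("reference signal must exceed background")
    out = means.rename(columns={"mean": "raw_mean", "count": "n_replicates"}).copy()
    out["rba"] = (out["raw_mean"] - bg) / (ref - bg)
    out["clamped"] = out["rba"] < 0
    out.loc[out["clamped"], "rba"] = 0.0
    return out.reset_index()
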