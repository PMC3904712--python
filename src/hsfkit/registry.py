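"""Curated Hsf family registry: table parsing, summaries, protein statistics.

The wheat heat shock factor (Hsf) family is catalogued as a table of gene
records — name (e.g. ``TaHsfA2b``), coding-region completeness, and, for
full-length members, deduced-protein statistics (residue count, isoelectric
point, molecular weight) plus Affymetrix probe-set cross-references.  This
module parses and validates that table, reproduces its summary counts, and
computes the protein statistics from sequence.

Molecular weight is the sum of average residue masses plus one water; the
isoelectric point is found by bisection on the Henderson–Hasselbalch net
charge over the ionizable groups (termini, D, E, C, Y, H, K, R) using an
EMBOSS-style pKa convention.  Published family tables rarely name the pI
tool they used, so agreement is tolerance-based, not exact.
"""

from __future__ import annotations

import hashlib
import io as _io
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import pandas as pd

__all__ = [
    "HsfGeneRecord",
    "FamilyRegistry",
    "ProteinChemistryConfig",
    "parse_family_table",
    "summarize_registry",
    "protein_stats",
    "isoelectric_point",
    "net_charge",
    "packaged_family_table",
]

COMPLETENESS_TOKENS = {
    "full": "Full",
    "almost full": "AlmostFull",
    "partial (n)": "PartialN",
    "partial (c)": "PartialC",
}

_EXPECTED_COLUMNS = [
    "Gene",
    "Full or partial (C or N) ORF",
    "No. of amino acids",
    "pI",
    "Mol. wt (kDa)",
    "Affymetrix probe set ID (no. of probe matches)",
]

_NAME_RE = re.compile(r"^(?P<prefix>[A-Za-z]*Hsf)(?P<subclass>[ABC]\d+)(?P<allele>[a-z])$")
_PROBE_RE = re.compile(r"^(?P<id>\S+)\s*\((?P<n>\d+)\)$")


class FamilyTableError(ValueError):
    """Raised on a malformed family table."""


@dataclass(frozen=True)
class HsfGeneRecord:
    """One curated family member (a row of the family table)."""

    name: str
    hsf_class: str          # "A", "B" or "C"
    subclass: str           # e.g. "A2"
    completeness: str       # Full | AlmostFull | PartialN | PartialC
    n_residues: Optional[int] = None
    pI: Optional[float] = None
    mol_wt: Optional[float] = None  # kDa
    probe_sets: tuple = ()  # of (probe_set_id, n_probe_matches)

    def __post_init__(self):
        if self.hsf_class != self.subclass[0]:
            raise FamilyTableError(
                f"{self.name}: class {self.hsf_class!r} does not match subclass {self.subclass!r}"
            )
        for pid, n in self.probe_sets:
            if not (1 <= n <= 11):
                raise FamilyTableError(f"{self.name}: probe match count {n} outside 1–11 for {pid}")


@dataclass(frozen=True)
class FamilyRegistry:
    """The full set of curated records plus input provenance."""

    records: tuple
    source: str = "<memory>"
    checksum: str = ""

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def filter(self, completeness: str) -> "FamilyRegistry":
        kept = tuple(r for r in self.records if r.completeness == completeness)
        return FamilyRegistry(kept, source=self.source, checksum=self.checksum)

    def to_tsv(self) -> str:
        """Serialize back to the input table schema (round-trip safe)."""
        inverse = {v: k.title() if v != "Full" else "Full" for k, v in COMPLETENESS_TOKENS.items()}
        inverse = {"Full": "Full", "AlmostFull": "Almost full",
                   "PartialN": "Partial (N)", "PartialC": "Partial (C)"}
        lines = ["\t".join(_EXPECTED_COLUMNS)]
        for r in self.records:
            probe = ", ".join(f"{pid} ({n})" for pid, n in r.probe_sets)
            cells = [
                r.name,
                inverse[r.completeness],
                "NA" if r.n_residues is None else str(r.n_residues),
                "NA" if r.pI is None else _fmt_num(r.pI),
                "NA" if r.mol_wt is None else _fmt_num(r.mol_wt),
            ]
            lines.append("\t".join(cells + ([probe] if probe else [])))
        return "\n".join(lines) + "\n"


def _fmt_num(x: float) -> str:
    s = f"{x:g}"
    return s


def _parse_name(name: str) -> tuple[str, str]:
    m = _NAME_RE.match(name)
    if not m:
        raise FamilyTableError(f"cannot parse class/subclass from gene name {name!r}")
    sub = m.group("subclass")
    return sub[0], sub


def _parse_probe_cell(cell: str, name: str) -> tuple:
    cell = cell.strip()
    if not cell or cell == "NA":
        return ()
    out = []
    for part in cell.split(","):
        part = part.strip()
        m = _PROBE_RE.match(part)
        if not m:
            raise FamilyTableError(f"{name}: malformed probe-set cell entry {part!r}")
        out.append((m.group("id"), int(m.group("n"))))
    return tuple(out)


def parse_family_table(table: Union[str, Path, _io.TextIOBase]) -> FamilyRegistry:
    """Parse a tab-separated family table into a validated registry.

    The first row must carry the expected column schema; "NA" cells become
    absent values.  Numeric statistics are required exactly for rows marked
    Full and absent otherwise.
    """
    if isinstance(table, Path) or (isinstance(table, str) and "\t" not in table and "\n" not in table):
        path = Path(table)
        text = path.read_text()
        source = str(path)
    elif isinstance(table, str):
        text, source = table, "<string>"
    else:
        text, source = table.read(), "<stream>"
    checksum = hashlib.sha256(text.encode()).hexdigest()

    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise FamilyTableError("empty table")
    header = lines[0].rstrip("\n").split("\t")
    if [h.strip() for h in header[: len(_EXPECTED_COLUMNS)]] != _EXPECTED_COLUMNS:
        raise FamilyTableError(
            f"unexpected header {header!r}; expected columns {_EXPECTED_COLUMNS!r}"
        )

    records: list[HsfGeneRecord] = []
    seen: set[str] = set()
    for lineno, line in enumerate(lines[1:], start=2):
        cells = line.rstrip("\n").split("\t")
        cells += [""] * (len(_EXPECTED_COLUMNS) - len(cells))
        name, compl_raw, n_aa, pi, mw, probes = (c.strip() for c in cells[:6])
        if name in seen:
            raise FamilyTableError(f"duplicate gene name {name!r} (line {lineno})")
        seen.add(name)
        key = compl_raw.lower()
        if key not in COMPLETENESS_TOKENS:
            raise FamilyTableError(f"{name}: unknown completeness token {compl_raw!r}")
        completeness = COMPLETENESS_TOKENS[key]
        hsf_class, subclass = _parse_name(name)

        def _num(cell: str, cast):
            return None if cell in ("", "NA") else cast(cell)

        rec = HsfGeneRecord(
            name=name,
            hsf_class=hsf_class,
            subclass=subclass,
            completeness=completeness,
            n_residues=_num(n_aa, int),
            pI=_num(pi, float),
            mol_wt=_num(mw, float),
            probe_sets=_parse_probe_cell(probes, name),
        )
        if completeness == "Full" and (rec.n_residues is None or rec.pI is None or rec.mol_wt is None):
            raise FamilyTableError(f"{name}: Full record missing protein statistics")
        if completeness != "Full" and any(v is not None for v in (rec.n_residues, rec.pI, rec.mol_wt)):
            raise FamilyTableError(f"{name}: non-Full record carries protein statistics")
        records.append(rec)
    return FamilyRegistry(tuple(records), source=source, checksum=checksum)


def packaged_family_table() -> Path:
    """Path to the packaged curated wheat Hsf family table."""
    return Path(__file__).parent / "data" / "tahsf_family_table.tsv"


def summarize_registry(registry: FamilyRegistry) -> dict:
    """Summary counts: per class, per subclass, per completeness, probe sets.

    Counts always sum to the record count; an empty registry yields an
    all-zero summary.  Invariant under record reordering.
    """
    per_class: dict[str, int] = {}
    per_subclass: dict[str, int] = {}
    per_completeness: dict[str, int] = {}
    probe_ids: set[str] = set()
    for r in registry:
        per_class[r.hsf_class] = per_class.get(r.hsf_class, 0) + 1
        per_subclass[r.subclass] = per_subclass.get(r.subclass, 0) + 1
        per_completeness[r.completeness] = per_completeness.get(r.completeness, 0) + 1
        probe_ids.update(pid for pid, _ in r.probe_sets)
    subclasses_per_class = {
        c: sorted(s for s in per_subclass if s[0] == c) for c in sorted(per_class)
    }
    return {
        "n_records": len(registry),
        "per_class": dict(sorted(per_class.items())),
        "per_subclass": dict(sorted(per_subclass.items())),
        "per_completeness": dict(sorted(per_completeness.items())),
        "subclasses_per_class": subclasses_per_class,
        "n_subclasses_per_class": {c: len(v) for c, v in subclasses_per_class.items()},
        "distinct_probe_sets": sorted(probe_ids),
        "n_distinct_probe_sets": len(probe_ids),
    }


# ---------------------------------------------------------------------------
# Protein chemistry
# ---------------------------------------------------------------------------

# Average (isotope-abundance-weighted) residue masses, Da.
AVERAGE_RESIDUE_MASS = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594, "N": 114.1038,
    "D": 115.0886, "Q": 128.1307, "K": 128.1741, "E": 129.1155, "M": 131.1926,
    "H": 137.1411, "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}
WATER_MASS = 18.0153

# EMBOSS-style pKa convention.
EMBOSS_PKA = {
    "Nterm": 8.6, "Cterm": 3.6,
    "C": 8.5, "D": 3.9, "E": 4.1, "H": 6.5, "K": 10.8, "R": 12.5, "Y": 10.1,
}


@dataclass(frozen=True)
class ProteinChemistryConfig:
    """Residue masses, pKa set and pI bisection tolerance."""

    residue_masses: dict = field(default_factory=lambda: dict(AVERAGE_RESIDUE_MASS))
    water_mass: float = WATER_MASS
    pka: dict = field(default_factory=lambda: dict(EMBOSS_PKA))
    pi_tolerance: float = 1e-4

    def __post_init__(self):
        if any(m <= 0 for m in self.residue_masses.values()) or self.water_mass <= 0:
            raise ValueError("masses must be positive")
        if any(not (0 < v < 14) for v in self.pka.values()):
            raise ValueError("pKa values must lie in (0, 14)")


DEFAULT_CHEMISTRY = ProteinChemistryConfig()


@dataclass(frozen=True)
class ProteinStats:
    n_residues: int
    mass_da: float
    mol_wt_kda: float  # rounded to 1 decimal, the family-table convention


def protein_stats(residues: str, config: ProteinChemistryConfig = DEFAULT_CHEMISTRY) -> ProteinStats:
    """Residue count and molecular weight of a protein.

    Weight = sum of average residue masses + one water, reported both in
    Da and as kDa to 1 decimal.  Unknown residue codes raise with the
    offending position.
    """
    if not residues:
        raise ValueError("empty protein sequence")
    total = config.water_mass
    for i, aa in enumerate(residues.upper()):
        try:
            total += config.residue_masses[aa]
        except KeyError:
            raise ValueError(f"unknown residue code {aa!r} at position {i}") from None
    return ProteinStats(len(residues), total, round(total / 1000.0, 1))


def net_charge(residues: str, ph: float, config: ProteinChemistryConfig = DEFAULT_CHEMISTRY) -> float:
    """Henderson–Hasselbalch net charge of a peptide at the given pH.

    Strictly decreasing in pH (every peptide has the two termini, so some
    ionizable group is always present).
    """
    seq = residues.upper()
    counts = {aa: seq.count(aa) for aa in "CDEHKRY"}
    pka = config.pka
    pos = 1.0 / (1.0 + 10 ** (ph - pka["Nterm"]))
    for aa in ("K", "R", "H"):
        pos += counts[aa] / (1.0 + 10 ** (ph - pka[aa]))
    neg = 1.0 / (1.0 + 10 ** (pka["Cterm"] - ph))
    for aa in ("D", "E", "C", "Y"):
        neg += counts[aa] / (1.0 + 10 ** (pka[aa] - ph))
    return pos - neg


def isoelectric_point(residues: str, config: ProteinChemistryConfig = DEFAULT_CHEMISTRY) -> float:
    """pH at which the net charge crosses zero, by bisection.

    The charge function is strictly monotone decreasing in pH, so the root
    is unique; bisection runs to ``config.pi_tolerance``.
    """
    if not residues:
        raise ValueError("empty protein sequence")
    lo, hi = 0.0, 14.0
    f_lo = net_charge(residues, lo, config)
    f_hi = net_charge(residues, hi, config)
    if f_lo < 0 or f_hi > 0:  # pragma: no cover - termini make this unreachable
        raise ValueError("no zero crossing of net charge in pH 0–14")
    while hi - lo > config.pi_tolerance:
        mid = 0.5 * (lo + hi)
        if net_charge(residues, mid, config) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
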