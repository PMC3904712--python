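# hsfkit

Heat shock factors (Hsfs) are the transcription factors that switch on heat
shock protein (Hsp) chaperone genes when plants overheat. Cataloguing the
Hsf family of bread wheat (*Triticum aestivum*) is harder than in diploid
plants: the hexaploid genome carries three near-identical homeologous
copies of most genes (>99% nucleotide identity), the transcript evidence is
fragmentary ESTs, and the family splits into classes A, B, C with numbered
subclasses (A1–A8, B1/B2/B4, C1/C2) that can only be assigned by comparison
with labelled rice and *Arabidopsis* references.

`hsfkit` is a toolkit for that computational workflow, aimed at people
mining transcription-factor families in polyploid crops and at anyone who
needs a reproducible heat-shock-element (HSE) promoter scanner:

* **`hsfkit.registry`** — parse and validate the curated family table;
  recompute per-protein statistics: molecular weight (sum of average
  residue masses + water) and isoelectric point (bisection on the
  Henderson–Hasselbalch net charge with an EMBOSS-style pKa set).
* **`hsfkit.assembly`** — EST contig assembly by single-linkage clustering
  under the rule *identity > 99.5% over ≥ 100 nt of the best local
  alignment* (strictly greater, so homeologs stay apart), with
  majority-vote consensus, genome-scaffold validation of singletons, and
  genomic extension of partial cDNAs.
* **`hsfkit.domains`** — Smith–Waterman detection of the Hsf DNA-binding
  domain against labelled references, completeness calls (Full / N-half /
  C-half, using the LNTY and GFRK anchors that flank the domain's large
  intron), heptad-repeat (HR-A/B) coiled-coil scanning, and AHA
  activation-motif composition scores (aromatic W/Y/F – hydrophobic
  L/I/V/M – acidic D/E).
* **`hsfkit.phylogeny`** — Poisson-corrected distances with pairwise
  deletion, *d* = −ln(1−*p*); Neighbor–Joining with documented
  tie-breaking; column-bootstrap supports; subclass assignment by
  clade-majority vote with a highest-identity homology fallback for
  partial proteins.
* **`hsfkit.hse`** — the HSE grammar: chains of alternating GAA/TTC core
  triplets at 2-nt spacers, categorized as perfect / degenerate (one
  mismatched core, interior) / double / gapped / extended, with
  configurable category scores and normalization of relative binding
  activity (RBA) tables.
* **`hsfkit.qpcr`** — efficiency-corrected relative expression
  Er^Ct(ref)/Et^Ct(target)×F, efficiencies from dilution-series slopes
  (E = 10^(−1/m)), Welch-test group comparisons, and array re-analysis
  with a signal-<20 detectability rule.
* **`hsfkit.simulate`** — seeded generators for every input above, each
  with a machine-readable truth table.

## Worked example

Simulate a small Hsf-like family with homeologous triplets, sample ESTs
from it, and assemble them back:

```bash
cat > scenario.yaml <<'YAML'
family:
  n_subfamilies: 2
  members_per_subfamily: 1
ests: {}
YAML
hsfkit simulate --scenario scenario.yaml --seed 3 --outdir sim/
hsfkit assemble --reads sim/ests.fa --genome sim/family_cds.fa \
                --out contigs.fa --report report.tsv
```

which prints

```
synthetic data -> sim/
6 contigs, 0 singletons; kept 6
```

— the two genes × three homeologous copies were reconstructed as six
separate contigs: every copy's reads merged (they differ only by
sequencing error) while homeologs stayed apart (≈99.0% identity, below the
strict >99.5% rule). `report.tsv` lists each contig's members and its
supporting genome match.

Scanning the canonical and atypical promoter elements:

```bash
python - <<'PY'
from hsfkit.hse import scan_promoter
for seq in ("GAAGCTTCGGGAA", "GAACATTTTGGAA"):
    (el,) = scan_promoter(seq)
    print(seq, el.category, "mismatches:", el.total_mismatches, "score:", el.score)
PY
```

```
GAAGCTTCGGGAA perfect_triple mismatches: 0 score: 1.0
GAACATTTTGGAA degenerate_triple mismatches: 1 score: 0.5
```

The first is the perfect element (three exact cores, spacers 2); the
second is the functional atypical element whose middle core is TTT — one
mismatch at the permissive position, scored 0.5 instead of 1.0.

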