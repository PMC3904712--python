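import numpy as np
import pandas as pd
import pytest

from hsfkit.assembly import revcomp
from hsfkit.hse import (
    DEFAULT_SCAN,
    ScanConfig,
    assemble_elements,
    count_perfect_triple_windows,
    elements_to_gff3,
    find_modules,
    normalize_rba,
    scan_promoter,
    score_element,
)

PERFECT = "GAAGCTTCGGGAA"     # the canonical promoter element
DEGENERATE = "GAACATTTTGGAA"  # atypical element, middle core TTT
DOUBLE = "AGAAGGTTCT"         # two-core element


class TestFindModules:
    def test_perfect_element_cores(self):
        modules = find_modules(PERFECT)
        assert [(m.start, m.orientation) for m in modules] == [(0, "GAA"), (5, "TTC"), (10, "GAA")]

    def test_no_cores_in_homopolymer(self):
        assert find_modules("CCCCCCCC") == []

    def test_degenerate_core_only_reported_when_chained(self):
        # TTT alone is not a module; inside the chained element it is
        assert find_modules("CCTTTACC") == []
        chained = find_modules(DEGENERATE)
        assert (5, "TTC") in [(m.start, m.orientation) for m in chained]

    def test_non_dna_rejected(self):
        with pytest.raises(ValueError, match="non-DNA"):
            find_modules("GAAXGAA")

    @pytest.mark.parametrize("seq", [PERFECT, DEGENERATE, DOUBLE])
    def test_strand_symmetry_of_modules(self, seq):
        fwd = find_modules(seq)
        rev = find_modules(revcomp(seq))
        L = len(seq)
        mirrored = sorted((L - m.end, {"GAA": "TTC", "TTC": "GAA"}[m.orientation]) for m in rev)
        assert mirrored == sorted((m.start, m.orientation) for m in fwd)


class TestAssembleElements:
    def test_perfect_triple(self):
        (el,) = assemble_elements(PERFECT)
        assert el.category == "perfect_triple"
        assert el.n_modules == 3
        assert el.total_mismatches == 0
        assert el.spacers == (2, 2)
        assert el.score == 1.0

    def test_degenerate_triple_middle_core(self):
        (el,) = assemble_elements(DEGENERATE)
        assert el.category == "degenerate_triple"
        assert el.total_mismatches == 1
        bad = next(m for m in el.modules if m.mismatches)
        assert bad.observed == "TTT"
        assert bad.mismatch_position == 3

    def test_double_element(self):
        (el,) = assemble_elements(DOUBLE)
        assert el.category == "double"
        assert el.n_modules == 2
        assert el.score <= 0.1

    def test_gapped_element(self):
        seq = "GAAGCTTCGGGGGGAA"  # second spacer 5 nt
        (el,) = assemble_elements(seq)
        assert el.category == "gapped"
        assert max(el.spacers) > 2
        assert el.score == 0.0

    def test_extended_element_not_decomposed(self):
        seq = "GAAGCTTCGGGAACCTTC"  # four alternating cores
        (el,) = assemble_elements(seq)
        assert el.category == "extended"
        assert el.n_modules == 4

    def test_reconstructed_span_matches_input(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGT"), size=300))
            for el in assemble_elements(seq):
                sub = seq[el.span[0] : el.span[1]]
                rebuilt = []
                pos = el.span[0]
                for m, spacer in zip(el.modules, el.spacers + (None,)):
                    assert seq[m.start : m.end] == m.observed
                    rebuilt.append(m.observed)
                    if spacer is not None:
                        rebuilt.append(seq[m.end : m.end + spacer])
                assert "".join(rebuilt) == sub


class TestScoring:
    def test_degenerate_position_weights(self):
        """TTT for TTC (the functional atypical element) scores the
        permissive weight; GTC for TTC (a weakly bound synthetic variant)
        scores the restrictive one.  Weights are keyed in the
        strand-invariant GAA frame."""
        cfg = DEFAULT_SCAN
        (el_ttt,) = assemble_elements(DEGENERATE, cfg)    # TTT: GAA-frame position 1
        assert score_element(el_ttt, cfg) == cfg.position_weights[1] == 0.5
        (el_gtc,) = assemble_elements("GAAGCGTCGGGAA", cfg)  # GTC: GAA-frame position 3
        assert el_gtc.category == "degenerate_triple"
        assert score_element(el_gtc, cfg) == cfg.position_weights[3] == 0.1

    def test_invalid_weight_rejected(self):
        with pytest.raises(ValueError):
            ScanConfig(position_weights={1: 1.5, 2: 0.1, 3: 0.5})


class TestScanPromoter:
    def test_empty_sequence(self):
        assert scan_promoter("") == []

    def test_coordinates_relative_to_translation_start(self):
        seq = "C" * 100 + PERFECT + "C" * 87
        elements = scan_promoter(seq, offset=200)
        assert elements[0].rel_span == (-100, -87)

    def test_strand_symmetry_of_elements(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            seq = "".join(rng.choice(list("ACGT"), size=800))
            fwd = scan_promoter(seq)
            rev = scan_promoter(revcomp(seq))
            L = len(seq)
            f = sorted((e.span[0], e.category, round(e.score, 6)) for e in fwd)
            r = sorted((L - e.span[1], e.category, round(e.score, 6)) for e in rev)
            assert f == r

    def test_monte_carlo_null_matches_closed_form_small(self):
        """Perfect-triple count on random sequence follows 2(L-12)/4^9
        (small-n version; the full-depth check runs in the acceptance suite)."""
        rng = np.random.default_rng(2)
        cfg = ScanConfig(allow_degenerate=False)
        L, n = 1000, 4000
        total = sum(
            count_perfect_triple_windows(scan_promoter("".join(rng.choice(list("ACGT"), size=L)), cfg))
            for _ in range(n)
        )
        expected = n * 2 * (L - 12) * 4.0 ** -9
        assert abs(total - expected) <= 3 * np.sqrt(expected)

    def test_gff3_output_well_formed(self):
        elements = scan_promoter(PERFECT)
        gff = elements_to_gff3(elements, "prom1")
        line = gff.splitlines()[1].split("\t")
        assert line[0] == "prom1" and line[2] == "HSE"
        assert (int(line[3]), int(line[4])) == (1, 13)  # 1-based inclusive


class TestNormalizeRba:
    @pytest.fixture()
    def raw(self):
        rows = []
        for el, values in [("ref", [10, 11, 9]), ("bg", [2, 2, 2]), ("half", [6, 6, 6]),
                           ("weak", [1, 1, 1])]:
            rows += [{"element_id": el, "value": v} for v in values]
        return pd.DataFrame(rows)

    def test_reference_is_one_background_zero(self, raw):
        out = normalize_rba(raw, "ref", "bg").set_index("element_id")
        assert out.loc["ref", "rba"] == pytest.approx(1.0)
        assert out.loc["bg", "rba"] == pytest.approx(0.0)

    def test_midpoint_is_half(self, raw):
        out = normalize_rba(raw, "ref", "bg").set_index("element_id")
        assert out.loc["half", "rba"] == pytest.approx(0.5)

    def test_below_background_clamped_and_flagged(self, raw):
        out = normalize_rba(raw, "ref", "bg").set_index("element_id")
        assert out.loc["weak", "rba"] == 0.0
        assert bool(out.loc["weak", "clamped"])

    def test_reference_not_above_background_rejected(self, raw):
        with pytest.raises(ValueError, match="exceed"):
            normalize_rba(raw, "bg", "ref")

    def test_missing_row_rejected(self, raw):
        with pytest.raises(ValueError, match="missing"):
            normalize_rba(raw, "nope", "bg")
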