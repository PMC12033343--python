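import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from slocus_kit.codons import translate
from slocus_kit.io_formats import GeneModel, Interval
from slocus_kit.srnase_signature import (
    DEFAULT_PATTERNS,
    EMBOSS_PKA,
    PatternSpec,
    SignatureConfig,
    check_c3_lysine,
    classify_srnase,
    compute_pI,
    count_introns,
    find_patterns,
    is_full_length,
    net_charge,
)
from slocus_kit.synthetic_data import (
    SRNASE_ACTIVE_SITE,
    SRNASE_TEMPLATE,
    reference_srnase,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


def _model(n_exons, strand="+", cds="ATGGCTTAA"):
    exons = [Interval(i * 200, i * 200 + 100) for i in range(n_exons)]
    return GeneModel("g", "chr", strand, exons, exons, cds)


class TestIntrons:
    @pytest.mark.parametrize("n_exons,expected", [(1, 0), (2, 1), (3, 2)])
    def test_counts(self, n_exons, expected):
        assert count_introns(_model(n_exons)) == expected

    def test_strand_invariance(self):
        assert count_introns(_model(2, strand="-")) == 1

    def test_zero_exons_error(self):
        m = _model(1)
        m.exons = []
        with pytest.raises(ValueError):
            count_introns(m)


class TestFullLength:
    @pytest.mark.parametrize(
        "cds,ok,reason_part",
        [
            ("ATGGCTTAA", True, "ok"),
            ("ATGTAAGCTTAA", False, "internal stop"),
            ("ATGGCTTA", False, "divisible"),
            ("GTGGCTTAA", False, "ATG"),
            ("ATGGCTGCT", False, "terminal stop"),
        ],
    )
    def test_cases(self, cds, ok, reason_part):
        full, reason = is_full_length(cds)
        assert full is ok and reason_part in reason

    def test_empty_error(self):
        with pytest.raises(ValueError):
            is_full_length("")


@pytest.mark.filterwarnings("ignore:pattern4")
class TestPatterns:
    def test_pattern4_matches_cpqdad(self):
        r = find_patterns("AAACPQDADAAA", DEFAULT_PATTERNS)
        assert r["pattern4"]["present"] and r["pattern4"]["positions"] == [3]

    def test_pattern4_rejects_apqdad(self):
        r = find_patterns("AAAAPQDADAAA", DEFAULT_PATTERNS)
        assert not r["pattern4"]["present"]

    def test_window_restriction(self):
        # pattern-4 occurrence before the pattern-2 match must not count
        prot = "CPQDAD" + "A" * 10 + "KHGTC" + "A" * 10 + "NQLNPLK"
        spec = [s for s in DEFAULT_PATTERNS if s.name == "pattern4"]
        r = find_patterns(prot, spec, pattern2_end=21, c3_position=31)
        assert not r["pattern4"]["present"]
        with pytest.warns(UserWarning):
            r2 = find_patterns(prot, spec)  # window unknown -> whole protein
        assert r2["pattern4"]["present"]

    def test_malformed_spec_named_in_error(self):
        with pytest.raises(ValueError, match="p_bad"):
            PatternSpec("p_bad", "[XY")


class TestIsoelectricPoint:
    def test_glycine_midpoint(self):
        # only the two termini titrate: pI = (8.6 + 3.6) / 2
        assert compute_pI("G") == pytest.approx(6.10, abs=0.01)

    def test_grid_scan_oracle(self):
        rng = np.random.default_rng(17)
        grid = np.arange(0.0, 14.0001, 0.001)
        for _ in range(100):
            pep = "".join(rng.choice(list(AA), size=rng.integers(5, 60)))
            charges = np.array([net_charge(pep, p) for p in grid])
            oracle = grid[np.argmin(np.abs(charges))]
            assert compute_pI(pep) == pytest.approx(oracle, abs=0.01)

    @given(st.text(alphabet=AA, min_size=1, max_size=30))
    @settings(derandomize=True, max_examples=40)
    def test_lysine_never_decreases_pi(self, pep):
        assert compute_pI(pep + "K") >= compute_pI(pep) - 1e-3

    @given(st.text(alphabet=AA, min_size=1, max_size=30))
    @settings(derandomize=True, max_examples=40)
    def test_reversal_invariance(self, pep):
        assert compute_pI(pep) == pytest.approx(compute_pI(pep[::-1]), abs=1e-9)

    def test_empty_error(self):
        with pytest.raises(ValueError):
            compute_pI("")


class TestC3Lysine:
    def test_identical_intact(self):
        assert check_c3_lysine(SRNASE_TEMPLATE, reference_srnase()) == "intact"

    def test_k_to_t_substitution(self):
        p = list(SRNASE_TEMPLATE)
        p[SRNASE_ACTIVE_SITE] = "T"
        assert check_c3_lysine("".join(p), reference_srnase()) == "substituted:T"

    def test_deletion_unalignable(self):
        i = SRNASE_ACTIVE_SITE
        p = SRNASE_TEMPLATE[: i - 6] + SRNASE_TEMPLATE[i + 6 :]
        assert check_c3_lysine(p, reference_srnase()) == "unalignable"


def test_criteria_toml_loader(tmp_path):
    from slocus_kit.srnase_signature import load_signature_config

    cfg = load_signature_config()
    assert cfg.max_introns == 2 and (cfg.pi_min, cfg.pi_max) == (8.0, 10.0)
    assert [p.name for p in cfg.patterns] == ["pattern1", "pattern2", "pattern4"]
    custom = tmp_path / "c.toml"
    custom.write_text("max_introns = 1\npi_min = 7.0\npi_max = 11.0\n")
    cfg2 = load_signature_config(str(custom))
    assert cfg2.max_introns == 1 and cfg2.pi_min == 7.0


class TestClassifier:
    @pytest.fixture()
    def config(self):
        return SignatureConfig(reference=reference_srnase())

    def _template_model(self, cds):
        return GeneModel("g", "chr", "+", [Interval(0, len(cds))], [Interval(0, len(cds))], cds)

    def test_functional_template(self, config):
        from slocus_kit.codons import back_translate

        cds = back_translate(SRNASE_TEMPLATE)
        rep = classify_srnase(self._template_model(cds), SRNASE_TEMPLATE, "style_specific", config)
        assert rep.verdict == "functional_candidate" and rep.failed_criteria == []
        assert set(rep.domains_found) >= {"C1", "C2", "C3", "C4", "C5", "RHV"}

    def test_acidic_variant_fails_only_pi(self, config):
        from slocus_kit.codons import back_translate
        from slocus_kit.synthetic_data import _apply_defect

        prot, _ = _apply_defect(SRNASE_TEMPLATE, "acidic_pi", np.random.default_rng(0))
        cds = back_translate(prot)
        rep = classify_srnase(self._template_model(cds), prot, "style_specific", config)
        assert rep.verdict == "fails"
        assert len(rep.failed_criteria) == 1 and "isoelectric point" in rep.failed_criteria[0]

    def test_truncation_other_criteria_still_reported(self, config):
        from slocus_kit.codons import back_translate

        cds = back_translate(SRNASE_TEMPLATE)
        cds = cds[:-6] + "TAA" + cds[-3:]  # internal stop before terminal stop
        rep = classify_srnase(
            self._template_model(cds), translate(cds), "style_specific", config
        )
        assert not rep.full_length
        assert [c for c in rep.failed_criteria] == ["not full length (internal stop codon)"]
        assert rep.pattern1_present and rep.pI_basic  # still evaluated

    def test_deterministic_and_order_independent(self, config):
        from slocus_kit.codons import back_translate

        cds = back_translate(SRNASE_TEMPLATE)
        m = self._template_model(cds)
        r1 = classify_srnase(m, SRNASE_TEMPLATE, "style_specific", config)
        r2 = classify_srnase(m, SRNASE_TEMPLATE, "style_specific", config)
        assert r1 == r2
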