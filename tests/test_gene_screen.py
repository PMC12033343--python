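import numpy as np
import pytest

from slocus_kit.codons import revcomp, translate
from slocus_kit.gene_screen import (
    DEFAULT_PROFILES,
    DomainProfile,
    find_candidate_sgenes,
    local_align_protein,
    parse_residue_classes,
    scan_domains,
    six_frame_translations,
)
from slocus_kit.io_formats import SeqRecord
from slocus_kit.synthetic_data import (
    SRNASE_TEMPLATE,
    CassetteSpec,
    LocusDesign,
    default_pru_design,
    generate_locus,
    screen_references,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


def _sw_oracle(a, b, matrix, gap_open=11, gap_extend=1):
    """Brute-force affine-gap Smith-Waterman (Gotoh), score only."""
    n, m = len(a), len(b)
    NEG = -1e9
    M = np.zeros((n + 1, m + 1))
    X = np.full((n + 1, m + 1), NEG)  # gap in b (consume a)
    Y = np.full((n + 1, m + 1), NEG)  # gap in a
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = matrix[a[i - 1], b[j - 1]]
            M[i, j] = max(0, s + max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]))
            X[i, j] = max(M[i - 1, j] - gap_open, X[i - 1, j] - gap_extend)
            Y[i, j] = max(M[i, j - 1] - gap_open, Y[i, j - 1] - gap_extend)
            best = max(best, M[i, j])
    return best


class TestLocalAlign:
    def test_blosum62_diagonal_sum(self):
        pair = local_align_protein("HGLWP", "HGLWP")
        assert pair.score == 8 + 6 + 4 + 11 + 7

    def test_symmetry(self):
        a, b = "MKVLWAALKH", "MKILWGALRH"
        assert local_align_protein(a, b).score == local_align_protein(b, a).score

    def test_all_negative_floor_zero(self):
        pair = local_align_protein("WWWW", "PPPP")
        assert pair.score == 0 and pair.a_gapped == ""

    def test_non_residue_error(self):
        with pytest.raises(ValueError, match="non-residue"):
            local_align_protein("MKV1", "MKV")

    def test_matches_bruteforce_oracle(self):
        from slocus_kit.alignment import BLOSUM62_X0

        rng = np.random.default_rng(11)
        for _ in range(100):
            a = "".join(rng.choice(list(AA), size=rng.integers(5, 31)))
            b = "".join(rng.choice(list(AA), size=rng.integers(5, 31)))
            expected = _sw_oracle(a, b, BLOSUM62_X0)
            assert local_align_protein(a, b).score == pytest.approx(expected)


class TestDomains:
    def test_planted_motif_found_at_offset(self):
        prot = "A" * 30 + "FTIHGLWP" + "A" * 20
        hits = [h for h in scan_domains(prot, DEFAULT_PROFILES) if h.profile == "RNase_T2"]
        assert any(h.position == 30 for h in hits)

    def test_empty_protein_no_hits(self):
        assert scan_domains("", DEFAULT_PROFILES) == []

    def test_empty_profiles_error(self):
        with pytest.raises(ValueError):
            scan_domains("MKV", [])

    def test_malformed_pattern_error(self):
        with pytest.raises(ValueError, match="bad"):
            parse_residue_classes("[AB", name="bad")

    def test_shuffle_calibration(self):
        """Planted-motif hit rate on scrambled proteins stays below 5%."""
        rng = np.random.default_rng(5)
        prot = list("A" * 60 + "FTIHGLWP" + "KHGTC" + "A" * 60)
        hits = 0
        n = 100
        for _ in range(n):
            rng.shuffle(prot)
            found = scan_domains("".join(prot), DEFAULT_PROFILES)
            hits += any(h.profile == "RNase_T2" for h in found)
        assert hits / n <= 0.05


def test_profiles_toml_roundtrip(tmp_path):
    from slocus_kit.gene_screen import load_profiles

    custom = tmp_path / "p.toml"
    custom.write_text(
        '[[profile]]\nname = "X"\nmotifs = ["[AC]G"]\nmin_score = 1.0\n'
    )
    (prof,) = load_profiles(str(custom))
    assert prof.name == "X" and prof.min_score == 1.0
    assert scan_domains("AAGCC", [prof])[0].position == 1
    # packaged defaults load and match the in-code defaults
    assert [p.name for p in load_profiles()] == [p.name for p in DEFAULT_PROFILES]


class TestSixFrame:
    def test_revcomp_permutes_frames(self):
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("ACGT"), size=91))
        f = six_frame_translations(seq)
        g = six_frame_translations(revcomp(seq))
        for k in (1, 2, 3):
            assert g[k] == f[-k] and g[-k] == f[k]
        assert set(f.values()) == set(g.values())


class TestScreen:
    def test_pru_locus_truth_recovery(self, pru_locus, screen_refs):
        genome, models, truth = pru_locus
        hits = find_candidate_sgenes([genome], models, screen_refs)
        assert sorted(h.gene_id for h in hits) == sorted(r.gene_id for r in truth.rows)
        by_id = {h.gene_id: h for h in hits}
        assert by_id["pru_srnase1"].ref_class == "S-RNase"
        assert by_id["pru_sfb1"].ref_class == "F-box"

    def test_no_genes_empty(self, screen_refs):
        rng = np.random.default_rng(1)
        genome = SeqRecord("bg", "".join(rng.choice(list("ACGT"), size=8000)))
        assert find_candidate_sgenes([genome], [], screen_refs) == []

    def test_empty_references_error(self, pru_locus):
        genome, models, _ = pru_locus
        with pytest.raises(ValueError):
            find_candidate_sgenes([genome], models, [])

    def test_unannotated_cassette_recovered_by_six_frame(self, screen_refs):
        design = LocusDesign(
            name="chr_u",
            architecture="pru_like",
            cassettes=[
                CassetteSpec("u_srnase", "srnase", n_introns=1),
                CassetteSpec("u_sfb", "sfb", n_introns=0),
                CassetteSpec("u_slfl1", "slfl", n_introns=0, identity_to_template=92.0),
                CassetteSpec("u_slfl2", "slfl", n_introns=0, identity_to_template=90.0),
                CassetteSpec(
                    "u_hidden", "slfl", n_introns=0, annotated=False, strand="-",
                    identity_to_template=95.0,
                ),
            ],
            seed=7,
        )
        genome, models, truth = generate_locus(design)
        hits = find_candidate_sgenes([genome], models, screen_refs)
        hidden = truth.row("u_hidden")
        unannot = [h for h in hits if not h.gene_id]
        assert len(unannot) == 1
        h = unannot[0]
        assert h.frame != 0 and h.frame < 0  # minus-strand cassette
        assert h.interval.overlap(
            __import__("slocus_kit.io_formats", fromlist=["Interval"]).Interval(
                hidden.start, hidden.end
            )
        ) > 0.5 * (hidden.end - hidden.start)
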