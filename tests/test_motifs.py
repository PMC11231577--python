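"""PWM scoring, exact p-values, and window scanning."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from zinchrom.config import AnalysisConfig
from zinchrom.intervals import GenomicInterval, RegionSet
from zinchrom.motifs import (
    BASES,
    PWM,
    PwmScorer,
    encode_sequence,
    estimate_background,
    pvalue_table,
    read_meme,
    read_pwm_tsv,
    reverse_complement,
    scan_regions,
    score_window,
    write_meme,
)

UNIFORM = np.full((4, 4), 0.25)


def near_consensus_pwm(consensus_codes, motif_id="m", background=None, p=0.97):
    mat = np.full((len(consensus_codes), 4), (1 - p) / 3)
    mat[np.arange(len(consensus_codes)), consensus_codes] = p
    return PWM(motif_id, mat, background if background is not None else np.full(4, 0.25))


pwm_st = st.lists(st.integers(0, 3), min_size=2, max_size=8).map(
    lambda codes: near_consensus_pwm(np.array(codes))
)


class TestPwmModel:
    def test_columns_must_sum_to_one(self):
        bad = np.full((3, 4), 0.3)
        with pytest.raises(ValueError, match="sum to 1"):
            PWM("bad", bad)

    def test_consensus_string(self):
        pwm = near_consensus_pwm(np.array([0, 1, 2, 3]))
        assert pwm.consensus() == "ACGT"

    @given(pwm=pwm_st)
    def test_consensus_scores_at_least_any_other_word(self, pwm):
        best = score_window(pwm, pwm.consensus())
        rng = np.random.default_rng(0)
        for _ in range(20):
            word = "".join(rng.choice(list(BASES), size=pwm.width))
            assert score_window(pwm, word) <= best + 1e-12


class TestScoreWindow:
    def test_uniform_pwm_scores_zero_everywhere(self):
        pwm = PWM("u", UNIFORM)
        assert score_window(pwm, "ACGT") == pytest.approx(0.0, abs=1e-9)

    def test_single_column_log_odds_closed_form(self):
        pwm = PWM("one", np.array([[0.97, 0.01, 0.01, 0.01]]))
        # pseudocount 1e-4 then renormalization, against uniform background
        expected = math.log2(((0.97 + 1e-4) / 1.0004) / 0.25)
        assert score_window(pwm, "A") == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(1.956, abs=5e-4)

    def test_n_base_scores_minus_infinity(self):
        pwm = PWM("u", UNIFORM)
        assert score_window(pwm, "ACNT") == float("-inf")

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            score_window(PWM("u", UNIFORM), "ACG")

    @given(pwm=pwm_st)
    def test_strand_symmetry_of_scores(self, pwm):
        rng = np.random.default_rng(1)
        word = "".join(rng.choice(list(BASES), size=pwm.width))
        fwd = score_window(pwm, word)
        rc = score_window(pwm.reverse_complement(), reverse_complement(word))
        assert rc == pytest.approx(fwd, abs=1e-9)


class TestPvalueTable:
    def test_uniform_single_column_full_mass(self):
        sc = PwmScorer(PWM("u", np.full((1, 4), 0.25)))
        assert sc.pvalue(0.0) == pytest.approx(1.0)

    @pytest.mark.parametrize("width", [2, 4, 6])
    def test_matches_exhaustive_enumeration(self, width, rng):
        bg = np.array([0.3, 0.2, 0.2, 0.3])
        mat = rng.dirichlet([1.0] * 4, size=width)
        sc = PwmScorer(PWM("t", mat, bg))
        bins = sc.bins[:, :4]
        mass: dict[int, float] = {}
        for combo in itertools.product(range(4), repeat=width):
            s = int(sum(bins[k, b] for k, b in enumerate(combo)))
            p = float(np.prod([bg[b] for b in combo]))
            mass[s] = mass.get(s, 0.0) + p
        cum = 0.0
        for s in sorted(mass, reverse=True):
            cum += mass[s]
            assert sc.pvalue_of_bin(s) == pytest.approx(cum, abs=1e-10)

    def test_most_extreme_score_probability(self):
        bg = np.array([0.3, 0.2, 0.2, 0.3])
        pwm = near_consensus_pwm(np.array([0, 1, 2]), background=bg)
        sc = PwmScorer(pwm)
        p_max = sc.pvalue_of_bin(sc.max_bin)
        assert p_max == pytest.approx(0.3 * 0.2 * 0.2, rel=1e-9)

    def test_survival_function_monotone(self, rng):
        mat = rng.dirichlet([1.0] * 4, size=5)
        table = pvalue_table(PWM("t", mat))
        assert (np.diff(table["p_value"].to_numpy()) <= 1e-15).all()


def _one_region_genome(window_seq, halfwidth):
    """Genome holding one region whose scan window is exactly window_seq."""
    chrom = window_seq
    center = halfwidth
    region = GenomicInterval("chr1", center - 5, center + 5, "r0")
    return {"chr1": chrom}, RegionSet([region])


class TestScanRegions:
    def test_planted_consensus_found_at_center(self, rng):
        cfg = AnalysisConfig(scan_window_halfwidth=100, fimo_p_cutoff=1e-5)
        pwm = near_consensus_pwm(rng.integers(0, 4, size=14))
        flank = "".join(rng.choice(list(BASES), size=200))
        seq = list(flank)
        start = 100 - 7
        seq[start : start + 14] = pwm.consensus()
        genome, regions = _one_region_genome("".join(seq), 100)
        hits, indicator = scan_regions(genome, regions, [pwm], cfg)
        assert indicator.loc["r0", "m"]
        best = hits[hits.best]
        assert abs(int(best.offset.iloc[0])) <= 1
        assert float(best.p_value.iloc[0]) <= 1e-5

    def test_palindromic_pwm_scores_both_strands_equally(self):
        cfg = AnalysisConfig(scan_window_halfwidth=30, fimo_p_cutoff=1.0)
        pal = near_consensus_pwm(encode_sequence("ACGT"))  # revcomp(ACGT)=ACGT
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list(BASES), size=60))
        genome, regions = _one_region_genome(seq, 30)
        hits, _ = scan_regions(genome, regions, [pal], cfg)
        fwd = hits[hits.strand == "+"].set_index("offset")["score_bits"]
        rev = hits[hits.strand == "-"].set_index("offset")["score_bits"]
        common = fwd.index.intersection(rev.index)
        assert len(common) > 0
        assert np.allclose(fwd[common], rev[common])

    def test_cutoff_one_reports_every_position(self):
        cfg = AnalysisConfig(scan_window_halfwidth=25, fimo_p_cutoff=1.0)
        rng = np.random.default_rng(4)
        seq = "".join(rng.choice(list(BASES), size=50))
        genome, regions = _one_region_genome(seq, 25)
        pwm = near_consensus_pwm(np.array([0, 1, 2, 3]))
        hits, _ = scan_regions(genome, regions, [pwm], cfg)
        assert len(hits) == 2 * (50 - 4 + 1)

    def test_n_containing_windows_never_hit(self):
        cfg = AnalysisConfig(scan_window_halfwidth=25, fimo_p_cutoff=1.0)
        genome = {"chr1": "N" * 50}
        regions = RegionSet([GenomicInterval("chr1", 20, 30, "r0")])
        hits, indicator = scan_regions(genome, regions, [PWM("u", UNIFORM)], cfg)
        assert len(hits) == 0
        assert not indicator.loc["r0", "u"]

    def test_center_off_chromosome_rejected(self):
        genome = {"chr1": "ACGT" * 10}
        with pytest.raises(ValueError, match="outside"):
            regions = RegionSet([GenomicInterval("chr1", 35, 80, "r0")])
            scan_regions(genome, regions, [PWM("u", UNIFORM)], AnalysisConfig())

    def test_window_clipped_at_chromosome_start(self):
        cfg = AnalysisConfig(scan_window_halfwidth=50, fimo_p_cutoff=1.0)
        rng = np.random.default_rng(5)
        genome = {"chr1": "".join(rng.choice(list(BASES), size=80))}
        regions = RegionSet([GenomicInterval("chr1", 0, 20, "r0")])
        hits, _ = scan_regions(genome, regions, [PWM("u", UNIFORM)], cfg)
        # window [center-50, center+50) clipped to [0, 60): 57 positions/strand
        assert len(hits) == 2 * (60 - 4 + 1)


class TestMotifIO:
    def test_meme_roundtrip(self, tmp_path, rng):
        pwms = [
            PWM("m1", rng.dirichlet([2.0] * 4, size=6)),
            PWM("m2", rng.dirichlet([2.0] * 4, size=4)),
        ]
        path = tmp_path / "motifs.meme"
        write_meme(pwms, path)
        back = read_meme(path)
        assert [p.motif_id for p in back] == ["m1", "m2"]
        for orig, rt in zip(pwms, back):
            assert np.allclose(orig.matrix, rt.matrix, atol=1e-6)

    def test_tsv_dialect(self, tmp_path):
        lines = ["motif_id\tposition\tA\tC\tG\tT"]
        for k, row in enumerate([(0.97, 0.01, 0.01, 0.01), (0.01, 0.97, 0.01, 0.01)]):
            lines.append("mx\t%d\t%s" % (k, "\t".join(map(str, row))))
        path = tmp_path / "m.tsv"
        path.write_text("\n".join(lines) + "\n")
        (pwm,) = read_pwm_tsv(path)
        assert pwm.width == 2 and pwm.consensus() == "AC"


class TestBackground:
    def test_symmetrized_frequencies(self):
        genome = {"chr1": "GGGGCCCCAAAATTTTGGGG"}
        bg = estimate_background(genome)
        assert bg[0] == pytest.approx(bg[3])
        assert bg[1] == pytest.approx(bg[2])
        assert bg.sum() == pytest.approx(1.0)
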