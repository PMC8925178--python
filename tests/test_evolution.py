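import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from genefam.core_io import Alignment, SequenceSet
from genefam.evolution import (ClockConfig, back_translate,
                               bundled_kaks_table, divergence_time,
                               jukes_cantor, kaks_classify, nei_gojobori,
                               sliding_window_kaks, summarize_selection)
from genefam.synthetic import evolve_codon_pair

SENSE = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
         if a + b + c not in ("TAA", "TAG", "TGA")]
codon_seqs = st.integers(0, 2**31 - 1).map(
    lambda seed: "".join(np.random.default_rng(seed).choice(SENSE, size=30))
)


class TestBackTranslate:
    def test_gap_becomes_codon_gap(self):
        aln = Alignment([("x", "M-V"), ("y", "MGV")], "protein")
        cds = SequenceSet({"x": "ATGGTT", "y": "ATGGGGGTG"})
        codon = back_translate(aln, cds)
        assert dict(codon.rows) == {"x": "ATG---GTT", "y": "ATGGGGGTG"}

    def test_gapless_concatenation_is_cds(self):
        aln = Alignment([("x", "MVQ"), ("y", "MVQ")], "protein")
        cds = SequenceSet({"x": "ATGGTTCAA", "y": "ATGGTGCAG"})
        codon = back_translate(aln, cds)
        assert dict(codon.rows)["x"] == "ATGGTTCAA"

    def test_translation_mismatch_names_position(self):
        aln = Alignment([("x", "MVQ")], "protein")
        cds = SequenceSet({"x": "ATGGTTAAA"})  # translates MVK
        with pytest.raises(ValueError, match="x.*residue 3"):
            back_translate(aln, cds)


class TestNeiGojobori:
    def test_identical_sequences(self):
        r = nei_gojobori("ATGGTTCAA", "ATGGTTCAA")
        assert (r.ka, r.ks, r.sd, r.nd) == (0.0, 0.0, 0.0, 0.0)
        assert r.ratio is None and r.selection_class == "NA"

    def test_worked_example(self):
        """TTT->TTC is a synonymous third-position change; each GGG codon
        carries a full synonymous site at position 3."""
        r = nei_gojobori("TTTGGGGGG", "TTCGGGGGG")
        assert r.s_sites == pytest.approx(7 / 3)
        assert r.n_sites == pytest.approx(20 / 3)
        assert (r.sd, r.nd) == (1.0, 0.0)
        assert r.ps == pytest.approx(3 / 7)
        assert r.ks == pytest.approx(-0.75 * math.log(1 - 4 / 7), abs=1e-6)
        assert r.ks == pytest.approx(0.6355, abs=1e-4)
        assert r.ka == 0.0

    def test_saturated_proportion_gives_na(self):
        assert jukes_cantor(0.8) is None
        r = nei_gojobori("GGG", "GGA")  # ps = 1 on the single syn site
        assert r.ks is None and r.ratio is None

    def test_gapped_and_ambiguous_codons_excluded_pairwise(self):
        full = nei_gojobori("TTTGGG", "TTCGGG")
        gapped = nei_gojobori("TTTGGG---NNN", "TTCGGGAAAGGG")
        assert gapped.s_sites == full.s_sites
        assert gapped.sd == full.sd

    def test_no_comparable_codons_error(self):
        with pytest.raises(ValueError, match="comparable"):
            nei_gojobori("---", "AAA")

    @given(codon_seqs, codon_seqs)
    @settings(max_examples=30, deadline=None)
    def test_symmetry_and_site_conservation(self, a, b):
        r1 = nei_gojobori(a, b)
        r2 = nei_gojobori(b, a)
        assert r1 == r2
        assert r1.s_sites + r1.n_sites == pytest.approx(3 * 30, abs=1e-9)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_matches_independent_ng86_implementation(self, seed):
        """Cross-check against Biopython's NG86 on evolved pairs."""
        from Bio.Align import Alignment as BioAlignment
        from Bio.Align.analysis import calculate_dn_ds

        a, b, _ = evolve_codon_pair(60, 0.3, 0.1, seed=seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dn, ds = calculate_dn_ds(BioAlignment([a, b]), method="NG86")
        r = nei_gojobori(a, b)
        assert r.ka == pytest.approx(dn, abs=1e-9)
        assert r.ks == pytest.approx(ds, abs=1e-9)

    def test_window_partition_sums_to_whole(self):
        a, b, _ = evolve_codon_pair(90, 0.4, 0.1, seed=8)
        whole = nei_gojobori(a, b)
        parts = [
            nei_gojobori(a[i : i + 90], b[i : i + 90])
            for i in range(0, 270, 90)
        ]
        assert sum(p.sd for p in parts) == pytest.approx(whole.sd)
        assert sum(p.nd for p in parts) == pytest.approx(whole.nd)


class TestClassification:
    @pytest.mark.parametrize(
        "ratio, expected",
        [(1.9910, "positive"), (0.1070, "purifying"), (1.0, "neutral"),
         (None, "NA")],
    )
    def test_classes(self, ratio, expected):
        assert kaks_classify(ratio) == expected


class TestSlidingWindow:
    def test_window_count_formula(self):
        a, b, _ = evolve_codon_pair(120, 0.2, 0.05, seed=1)
        windows = sliding_window_kaks(a, b, window=30, step=3)
        assert len(windows) == (120 - 30) // 3 + 1 == 31

    def test_homogeneous_pair_is_flat(self):
        a, b, _ = evolve_codon_pair(300, 0.3, 0.3, seed=2)
        whole = nei_gojobori(a, b)
        ratios = [w[3] for w in sliding_window_kaks(a, b, window=150, step=30)
                  if w[3] is not None]
        assert ratios
        for r in ratios:
            assert r == pytest.approx(whole.ratio, rel=0.6)

    def test_elevated_region_found(self):
        flank_a, flank_b, _ = evolve_codon_pair(120, 0.15, 0.01, seed=5)
        hot_a, hot_b, _ = evolve_codon_pair(120, 0.15, 0.45, seed=6)
        lo, hi = 39, 60  # 0-based codon slice carrying the hot region
        a = flank_a[: lo * 3] + hot_a[lo * 3 : hi * 3] + flank_a[hi * 3 :]
        b = flank_b[: lo * 3] + hot_b[lo * 3 : hi * 3] + flank_b[hi * 3 :]
        windows = sliding_window_kaks(a, b, window=15, step=3)
        best = max((w for w in windows if w[3] is not None),
                   key=lambda w: w[3])
        start, end = best[0], best[0] + 15 - 1
        assert start <= hi and end >= lo + 1  # overlaps the planted region

    def test_invalid_window_params(self):
        a, b, _ = evolve_codon_pair(40, 0.1, 0.1, seed=0)
        with pytest.raises(ValueError):
            sliding_window_kaks(a, b, window=0)
        with pytest.raises(ValueError):
            sliding_window_kaks(a, b, window=100)


class TestDivergenceDating:
    @pytest.mark.parametrize(
        "ks, expected, tol",
        [(0.0163, 1.2538, 1e-4), (0.5821, 44.78, 5e-3), (0.0, 0.0, 0.0)],
    )
    def test_clock_values(self, ks, expected, tol):
        assert divergence_time(ks) == pytest.approx(expected, abs=tol or 1e-12)

    def test_na_propagates(self):
        assert divergence_time(None) is None

    @given(st.floats(0, 5), st.floats(1e-10, 1e-7))
    @settings(max_examples=40, deadline=None)
    def test_linear_in_ks_inverse_in_lambda(self, ks, lam):
        t = divergence_time(ks, ClockConfig(lam))
        assert divergence_time(2 * ks, ClockConfig(lam)) == pytest.approx(2 * t)
        assert divergence_time(ks, ClockConfig(2 * lam)) == pytest.approx(t / 2)


class TestSelectionSummary:
    def test_bundled_paralog_pairs(self):
        table = bundled_kaks_table()
        paralogs = [(p, r) for p, r in table
                    if p.split("/")[1].startswith("Ta")]
        assert len(paralogs) == 48
        s = summarize_selection(paralogs)
        assert s.counts["positive"] == 37
        assert s.counts["purifying"] == 11
        assert s.ks_min == pytest.approx(0.0163)
        assert s.ks_max == pytest.approx(1.5197)
        assert s.date_min == pytest.approx(1.2538, abs=1e-4)
        assert s.date_max == pytest.approx(116.8985, abs=0.01)

    def test_all_orthologs_under_positive_selection(self):
        table = bundled_kaks_table()
        orthologs = [(p, r) for p, r in table
                     if not p.split("/")[1].startswith("Ta")]
        assert len(orthologs) == 36
        s = summarize_selection(orthologs)
        assert s.counts["positive"] == 36
        assert s.counts["purifying"] == 0

    def test_empty_input_error(self):
        with pytest.raises(ValueError):
            summarize_selection([])


class TestParameterRecovery:
    def test_estimates_recover_targets(self):
        """NG86 on pairs evolved at (Ks, Ka) = (0.2, 0.05) over 500 codons
        recovers both targets within three standard errors (50 replicates)."""
        ks_est, ka_est = [], []
        for seed in range(50):
            a, b, _ = evolve_codon_pair(500, 0.2, 0.05, seed=seed)
            r = nei_gojobori(a, b)
            ks_est.append(r.ks)
            ka_est.append(r.ka)
        for estimates, target in ((ks_est, 0.2), (ka_est, 0.05)):
            mean = np.mean(estimates)
            se = np.std(estimates, ddof=1) / np.sqrt(len(estimates))
            assert abs(mean - target) <= 3 * se, (mean, target, se)
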