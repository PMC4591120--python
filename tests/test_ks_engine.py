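"""Estimator tests, anchored by an independent brute-force pathway oracle.

The oracle enumerates every shortest substitution pathway between two codons
explicitly, translating with Biopython, and never touches the production
counting tables.
"""

import numpy as np
import pytest

from oracles import SENSE, oracle_diffs, oracle_ng86_counts as oracle_ng86

from ksdater.ks_engine import (CodonAlignment, align_proteins, back_translate,
                               codon_align, estimate_pair, ng86, yn00)
from ksdater.synthetic_data import (EvolveConfig, _evolve_branch, evolve_pair,
                                    pair_alignment, random_cds)


def random_codon_pair_alignment(rng, n=30):
    ca = [SENSE[i] for i in rng.integers(0, len(SENSE), n)]
    cb = [SENSE[i] for i in rng.integers(0, len(SENSE), n)]
    return CodonAlignment(id_a="a", id_b="b", codons_a=ca, codons_b=cb)


class TestAlignment:
    def test_identical_proteins_no_gaps(self):
        a, b = align_proteins("MKVLW", "MKVLW")
        assert a == b == "MKVLW"

    def test_single_residue_gap(self):
        # exhaustive check of the 3x2 problem under BLOSUM62 + 10/0.5 gaps
        # shows M-V is the unique optimum
        assert align_proteins("MKV", "MV") == ("MKV", "M-V")

    def test_score_symmetry(self):
        from ksdater.ks_engine import _ALIGNER
        assert _ALIGNER.score("MKVLWAAR", "MKLWAR") == \
               _ALIGNER.score("MKLWAR", "MKVLWAAR")


class TestBackTranslate:
    def test_no_gap_identity(self):
        cds = "ATGAAAGTT"
        aln = back_translate("MKV", "MKV", cds, cds)
        assert "".join(aln.codons_a) == cds
        assert aln.n_cols == aln.n_ungapped == 3

    def test_gap_row(self):
        aln = back_translate("MKV", "M-V", "ATGAAAGTT", "ATGGTA")
        assert aln.codons_b == ["ATG", "---", "GTA"]
        assert aln.n_ungapped == 2

    def test_n_column_excluded_from_ungapped(self):
        aln = back_translate("MKV", "MKV", "ATGAANGTT", "ATGAAAGTT")
        assert aln.n_cols == 3
        assert aln.n_ungapped == 2

    def test_length_mismatch_is_error(self):
        with pytest.raises(ValueError):
            back_translate("MKV", "MKV", "ATGAAA", "ATGAAAGTT")


class TestNg86:
    def test_identical_pair_zero_distance(self):
        rec = random_cds(60, 3)
        est = ng86(pair_alignment(rec, rec))
        assert est.Sd == est.Nd == 0
        assert est.ks == pytest.approx(0) and est.ka == pytest.approx(0)

    def test_triple_difference_conserves_step_count(self):
        # all-position differences must distribute exactly 3 steps over
        # syn+nonsyn whenever at least one pathway is stop-free
        rng = np.random.default_rng(5)
        for _ in range(200):
            c1, c2 = (SENSE[i] for i in rng.integers(0, len(SENSE), 2))
            ndiff = sum(a != b for a, b in zip(c1, c2))
            d = oracle_diffs(c1, c2)
            if d is not None:
                assert d[0] + d[1] == pytest.approx(ndiff)

    def test_matches_brute_force_oracle_on_random_pairs(self):
        rng = np.random.default_rng(11)
        for _ in range(300):
            aln = random_codon_pair_alignment(rng, n=20)
            est = ng86(aln)
            if "pathway_fallback" in est.flags:
                continue
            S, N, sd, nd = oracle_ng86(aln.codons_a, aln.codons_b)
            assert est.S == pytest.approx(S, abs=1e-9)
            assert est.N == pytest.approx(N, abs=1e-9)
            assert est.Sd == pytest.approx(sd, abs=1e-9)
            assert est.Nd == pytest.approx(nd, abs=1e-9)

    def test_site_counts_sum_to_three_per_codon(self):
        rng = np.random.default_rng(2)
        aln = random_codon_pair_alignment(rng)
        est = ng86(aln)
        assert est.S + est.N == pytest.approx(3 * aln.n_ungapped, abs=1e-6)

    def test_symmetry(self):
        rng = np.random.default_rng(7)
        aln = random_codon_pair_alignment(rng)
        rev = CodonAlignment(id_a="b", id_b="a", codons_a=aln.codons_b,
                             codons_b=aln.codons_a)
        e1, e2 = ng86(aln), ng86(rev)
        for f in ("S", "N", "Sd", "Nd"):
            assert abs(getattr(e1, f) - getattr(e2, f)) < 1e-12

    def test_saturation_flagged_not_clamped(self):
        # maximally divergent synonymous-rich columns push pS past 3/4
        ca = ["GGA"] * 40
        cb = ["GGG"] * 40
        # same aa at every column; all diffs synonymous, pS = 40/S large
        est = ng86(CodonAlignment(id_a="a", id_b="b", codons_a=ca, codons_b=cb))
        assert est.ks is None and "saturated" in est.flags

    def test_purely_synonymous_pair_gives_zero_ka(self):
        ca = ["CTT", "GTT", "TCT"] * 10
        cb = ["CTC", "GTT", "TCT"] * 10
        est = ng86(CodonAlignment(id_a="a", id_b="b", codons_a=ca, codons_b=cb))
        assert est.ka == pytest.approx(0)
        assert est.ks > 0


class TestYn00:
    def test_identical_pair(self):
        rec = random_cds(60, 9)
        est = yn00(pair_alignment(rec, rec))
        assert est.ks == pytest.approx(0) and est.ka == pytest.approx(0)

    def test_limiting_case_equals_ng86_sites(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            aln = random_codon_pair_alignment(rng, n=30)
            e_ng = ng86(aln)
            e_yn = yn00(aln, fix_kappa=1.0, codon_freqs="uniform")
            assert e_yn.S == pytest.approx(e_ng.S, abs=1e-6)
            assert e_yn.N == pytest.approx(e_ng.N, abs=1e-6)

    def test_symmetry(self):
        rng = np.random.default_rng(17)
        codons = [SENSE[i] for i in rng.integers(0, len(SENSE), 100)]
        a, _, _ = _evolve_branch(codons, 0.1, 1.0, 0.3, 2.0, rng)
        b, _, _ = _evolve_branch(codons, 0.1, 1.0, 0.3, 2.0, rng)
        e1 = yn00(CodonAlignment(id_a="a", id_b="b", codons_a=a, codons_b=b))
        e2 = yn00(CodonAlignment(id_a="b", id_b="a", codons_a=b, codons_b=a))
        for f in ("S", "N", "Sd", "Nd", "kappa", "ks", "ka"):
            assert abs(getattr(e1, f) - getattr(e2, f)) < 1e-12

    def test_requires_minimum_columns(self):
        rec = random_cds(5, 1)
        with pytest.raises(ValueError):
            yn00(pair_alignment(rec, rec))

    def test_kappa_recovered_from_transition_biased_pair(self):
        rng = np.random.default_rng(23)
        codons = [SENSE[i] for i in rng.integers(0, len(SENSE), 800)]
        a, _, _ = _evolve_branch(codons, 0.25, 1.0, 0.2, 4.0, rng)
        b, _, _ = _evolve_branch(codons, 0.25, 1.0, 0.2, 4.0, rng)
        est = yn00(CodonAlignment(id_a="a", id_b="b", codons_a=a, codons_b=b))
        assert est.kappa > 1.8  # strongly transition-biased input


class TestRecoveryAndMonotonicity:
    def test_estimators_monotone_in_target_ks(self):
        means = {"ng86": [], "yn00": []}
        for target in (0.1, 0.3, 0.6):
            ests = {"ng86": [], "yn00": []}
            for r in range(25):
                cfg = EvolveConfig(n_codons=300, target_ks=target,
                                   seed=r, calibration_method="ng86")
                anc = random_cds(300, 900 + r)
                a, b, _ = evolve_pair(anc, cfg)
                aln = pair_alignment(a, b)
                for m, fn in (("ng86", ng86), ("yn00", yn00)):
                    e = fn(aln)
                    if e.ks is not None:
                        ests[m].append(e.ks)
            for m in means:
                means[m].append(np.mean(ests[m]))
        for m, seq in means.items():
            assert seq[0] < seq[1] < seq[2], (m, seq)

    def test_yn00_recovers_simulated_divergence(self):
        # parameter recovery under the production estimator's own calibration
        target, reps = 0.25, 120
        est = []
        for r in range(reps):
            cfg = EvolveConfig(n_codons=500, target_ks=target, seed=3000 + r,
                               calibration_method="yn00")
            anc = random_cds(500, 4000 + r)
            a, b, _ = evolve_pair(anc, cfg)
            e = yn00(pair_alignment(a, b))
            if e.ks is not None:
                est.append(e.ks)
        est = np.array(est)
        se = est.std(ddof=1) / np.sqrt(len(est))
        assert abs(est.mean() - target) < 3 * se

    def test_omega_zero_means_zero_ka(self):
        cfg = EvolveConfig(n_codons=200, target_ks=0.3, omega=0.0, seed=1)
        anc = random_cds(200, 77)
        a, b, counts = evolve_pair(anc, cfg)
        assert counts["nonsyn_a"] == counts["nonsyn_b"] == 0
        est = ng86(pair_alignment(a, b))
        assert est.ka == pytest.approx(0)


class TestEstimatePair:
    def test_full_path_from_cds(self):
        cfg = EvolveConfig(n_codons=100, target_ks=0.2, seed=5)
        anc = random_cds(100, 55)
        a, b, _ = evolve_pair(anc, cfg)
        est = estimate_pair(a.seq, b.seq, id_a=a.id, id_b=b.id, method="yn00")
        assert est.method == "YN00"
        assert 0 < est.ks < 1

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            estimate_pair("ATGAAA", "ATGAAA", method="codeml")
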