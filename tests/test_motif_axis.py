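import itertools
import math

import numpy as np
import pytest

from regswitch.motif_axis import (
    MotifHit,
    closest_motif_distance,
    compare_axis_between_species,
    default_pas_matrix,
    default_u1_matrix,
    read_matrix,
    scan_motif,
    tss_density_profile,
    u1_before_pas_fraction,
    write_matrix,
)

RC = str.maketrans("ACGT", "TGCA")


def revcomp(seq):
    return seq.translate(RC)[::-1]


def brute_force_scan(sequence, matrix):
    """Score every offset on both strands independently of the scanner."""
    hits = []
    L = matrix.length
    for strand in "+-":
        seq = sequence if strand == "+" else revcomp(sequence)
        for i in range(len(seq) - L + 1):
            score = matrix.score(seq[i : i + L])
            if score >= matrix.score_threshold:
                pos = i if strand == "+" else len(sequence) - L - i
                hits.append((pos, strand, round(score, 9)))
    return sorted(hits)


class TestScanner:
    def test_planted_forward_consensus(self):
        seq = "A" * 7 + "GTAAGT" + "A" * 20
        hits = scan_motif(seq, default_u1_matrix())
        assert [(h.position, h.strand) for h in hits] == [(7, "+")]

    def test_planted_reverse_complement(self):
        seq = "C" * 12 + revcomp("GTAAGT") + "C" * 10
        hits = scan_motif(seq, default_u1_matrix())
        assert [(h.position, h.strand) for h in hits] == [(12, "-")]

    def test_n_bases_never_match(self):
        seq = "GTANGT" + "A" * 10
        assert scan_motif(seq, default_u1_matrix()) == []

    def test_equivalent_to_brute_force_on_random_sequences(self):
        rng = np.random.default_rng(0)
        for matrix in (default_u1_matrix(), default_pas_matrix()):
            for _ in range(5):
                seq = "".join(rng.choice(list("ACGT"), size=2000))
                got = sorted(
                    (h.position, h.strand, round(h.score, 9))
                    for h in scan_motif(seq, matrix)
                )
                assert got == brute_force_scan(seq, matrix)

    def test_default_thresholds_reject_random_hexamers(self):
        """Each default matrix accepts its canonical variants and <1% of
        all hexamers."""
        for matrix, accepted in (
            (default_u1_matrix(), {"GTAAGT", "GTGAGT"}),
            (default_pas_matrix(), {"AATAAA", "ATTAAA"}),
        ):
            hits = {
                "".join(k)
                for k in itertools.product("ACGT", repeat=6)
                if matrix.score("".join(k)) >= matrix.score_threshold
            }
            assert accepted <= hits
            assert len(hits) / 4096 < 0.01

    def test_matrix_file_round_trip(self, tmp_path):
        m = default_u1_matrix()
        path = tmp_path / "u1.pwm"
        write_matrix(m, path)
        back = read_matrix(path)
        assert back.name == m.name
        assert back.score_threshold == m.score_threshold
        assert np.allclose(back.log_odds, m.log_odds)


class TestDensityProfile:
    def test_plus_strand_counts(self):
        hits = [MotifHit("c", p, "+", 1.0) for p in (5100, 5400, 5900)]
        prof = tss_density_profile(5000, "+", hits)
        assert prof.downstream_per_kb == pytest.approx(3.0)
        assert prof.upstream_per_kb == 0.0

    def test_minus_strand_mirrors(self):
        hits = [MotifHit("c", p, "+", 1.0) for p in (4100, 4600, 4900)]
        prof = tss_density_profile(5000, "-", hits)
        assert prof.downstream_per_kb == pytest.approx(3.0)
        assert prof.upstream_per_kb == 0.0

    def test_cumulative_window_membership(self):
        # a hit beyond the short window counts only in the long one
        hits = [MotifHit("c", 5900, "+", 1.0)]
        prof = tss_density_profile(5000, "+", hits, windows=(200, 1000))
        assert prof.cumulative[200][1] == 0.0
        assert prof.cumulative[1000][1] == pytest.approx(1.0)
        # a hit inside the short window contributes to both densities
        near = tss_density_profile(5000, "+", [MotifHit("c", 5100, "+", 1.0)], windows=(200, 1000))
        assert near.cumulative[200][1] == pytest.approx(5.0)

    def test_counts_conserved_across_disjoint_windows(self):
        rng = np.random.default_rng(1)
        hits = [MotifHit("c", int(p), "+", 1.0) for p in rng.integers(0, 10_000, 200)]
        prof = tss_density_profile(5000, "+", hits, windows=(500, 1000))
        inner = prof.cumulative[500][1] * 0.5
        outer = sum(1 for h in hits if 5500 <= h.position < 6000)
        assert inner + outer == pytest.approx(prof.cumulative[1000][1] * 1.0)

    def test_contig_truncation_uses_effective_length(self):
        hits = [MotifHit("c", 150, "+", 1.0)]
        prof = tss_density_profile(100, "+", hits, windows=(1000,), contig_length=600)
        # only 500 nt of downstream window exist
        assert prof.cumulative[1000][1] == pytest.approx(1 / 0.5)

    def test_mirror_symmetry_under_reverse_complement(self):
        """Scanning the reverse complement with the flipped TSS gives the
        same sense-oriented densities."""
        rng = np.random.default_rng(2)
        seq = "".join(rng.choice(list("ACGT"), size=4000))
        matrix = default_u1_matrix()
        tss = 2000
        fwd = tss_density_profile(tss, "+", scan_motif(seq, matrix))
        rc_hits = scan_motif(revcomp(seq), matrix)
        # hit starts shift by the motif length under reverse complement;
        # compare counts over closed windows using the mirrored TSS
        mirrored_tss = len(seq) - tss
        rev = tss_density_profile(mirrored_tss, "-", rc_hits)
        # total hit counts agree even though individual starts shift by
        # matrix.length - 1 at the window borders; use interior hits only
        assert abs(
            fwd.downstream_per_kb + fwd.upstream_per_kb
            - rev.downstream_per_kb - rev.upstream_per_kb
        ) <= 2 * (matrix.length - 1) / 1000 * 10


class TestClosestDistance:
    def test_both_sides(self):
        hits = [MotifHit("c", 5120, "+", 1.0), MotifHit("c", 4700, "+", 1.0)]
        assert closest_motif_distance(5000, "+", hits, "down") == 120
        assert closest_motif_distance(5000, "+", hits, "up") == 300

    def test_empty_side_is_none(self):
        hits = [MotifHit("c", 4700, "+", 1.0)]
        assert closest_motif_distance(5000, "+", hits, "down") is None

    def test_hit_at_tss_counts_downstream_zero(self):
        hits = [MotifHit("c", 5000, "+", 1.0)]
        assert closest_motif_distance(5000, "+", hits, "down") == 0
        assert closest_motif_distance(5000, "+", hits, "up") is None


class TestU1BeforePas:
    def test_u1_first_is_success(self):
        u1 = [MotifHit("c", 5050, "+", 1.0)]
        pas = [MotifHit("c", 5200, "+", 1.0)]
        frac, n = u1_before_pas_fraction([(5000, "+")], u1, pas)
        assert (frac, n) == (1.0, 1)

    def test_pas_first_is_failure(self):
        u1 = [MotifHit("c", 5200, "+", 1.0)]
        pas = [MotifHit("c", 5050, "+", 1.0)]
        frac, n = u1_before_pas_fraction([(5000, "+")], u1, pas)
        assert (frac, n) == (0.0, 1)

    def test_mixed_tss_list(self):
        u1 = [MotifHit("c", 5050, "+", 1.0), MotifHit("c", 9200, "+", 1.0)]
        pas = [MotifHit("c", 5200, "+", 1.0), MotifHit("c", 9050, "+", 1.0)]
        frac, n = u1_before_pas_fraction([(5000, "+"), (9000, "+")], u1, pas)
        assert (frac, n) == (0.5, 2)

    def test_neither_motif_excluded_from_denominator(self):
        with pytest.warns(UserWarning):
            frac, n = u1_before_pas_fraction([(5000, "+")], [], [])
        assert n == 0 and math.isnan(frac)

    def test_duplicated_hits_do_not_change_fraction(self):
        u1 = [MotifHit("c", 5050, "+", 1.0)] * 3
        pas = [MotifHit("c", 5200, "+", 1.0)] * 2
        frac, _ = u1_before_pas_fraction([(5000, "+")], u1, pas)
        assert frac == 1.0


class TestAxisComparison:
    def _profiles(self, rng, rate, n, prefix):
        out = []
        for i in range(n):
            counts = {
                w: (int(rng.poisson(2.0 * w / 1000)), int(rng.poisson(rate * w / 1000)))
                for w in (200, 400, 600, 800, 1000)
            }
            cum = {w: (u / (w / 1000), d / (w / 1000)) for w, (u, d) in counts.items()}
            out.append(
                type(
                    "P", (), {"element_id": f"{i}", "upstream_per_kb": cum[1000][0],
                              "downstream_per_kb": cum[1000][1], "cumulative": cum},
                )()
            )
        return out

    def test_planted_downstream_asymmetry_detected(self):
        """Promoter-side 3.0/kb vs enhancer-side 2.0/kb over 100 pairs:
        downstream significant, upstream not."""
        rng = np.random.default_rng(5)
        prom = self._profiles(rng, 3.0, 100, "p")
        enh = self._profiles(rng, 2.0, 100, "e")
        rows = compare_axis_between_species(enh, prom, paired=True)
        by_key = {(r["side"], r["window"]): r for r in rows}
        assert by_key[("down", 1000)]["p_adj"] < 0.01
        assert by_key[("up", 1000)]["p"] > 0.05

    def test_identical_profiles_p_one(self):
        rng = np.random.default_rng(6)
        prof = self._profiles(rng, 2.0, 10, "x")
        with pytest.warns(UserWarning):
            rows = compare_axis_between_species(prof, prof, paired=True)
        assert all(r["p_adj"] == 1.0 for r in rows if not math.isnan(r["p"]))

    def test_mismatched_ids_rejected(self):
        rng = np.random.default_rng(7)
        a = self._profiles(rng, 2.0, 4, "a")
        b = self._profiles(rng, 2.0, 3, "b")
        with pytest.raises(ValueError):
            compare_axis_between_species(a, b, paired=True)

    def test_single_pair_skipped_with_warning(self):
        rng = np.random.default_rng(8)
        a = self._profiles(rng, 2.0, 1, "a")
        b = self._profiles(rng, 3.0, 1, "b")
        with pytest.warns(UserWarning):
            rows = compare_axis_between_species(a, b, paired=True)
        assert all(math.isnan(r["p"]) for r in rows)
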