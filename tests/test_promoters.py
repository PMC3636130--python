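import itertools

import numpy as np
import pytest

from regarch import promoters as prom
from regarch.io import GenomeSequence
from regarch.promoters import (PWM, build_pwm, discover_motifs, gap_surprisal,
                               iseq, score_promoter)

BASES = "ACGT"


class TestBuildPWM:
    def test_identical_sites_zero_pseudocount(self):
        pwm, w = build_pwm(["TATAAT"] * 4, "minus10", pseudocount=0.0)
        for i, b in enumerate("TATAAT"):
            assert w.riw[BASES.index(b), i] == pytest.approx(2.0)

    def test_uniform_column_weights_zero(self):
        pwm, w = build_pwm(["AATAAT", "CATAAT", "GATAAT", "TATAAT"],
                           "minus10", pseudocount=0.0)
        assert np.allclose(w.riw[:, 0], 0.0)

    def test_hand_computed_matrix(self):
        """f and Riw match independent arithmetic on a 4-site alignment."""
        sites = ["TATAAT", "TATAAT", "TACAAT", "CATAAT"]
        pwm, w = build_pwm(sites, "minus10", pseudocount=0.5)
        # column 0: T x3, C x1 -> f = (3.5/6, 1.5/6, 0.5/6, 0.5/6)
        assert pwm.f[BASES.index("T"), 0] == pytest.approx(3.5 / 6)
        assert pwm.f[BASES.index("C"), 0] == pytest.approx(1.5 / 6)
        assert pwm.f[BASES.index("A"), 0] == pytest.approx(0.5 / 6)
        # column 2: T x3, C x1
        assert w.riw[BASES.index("C"), 2] == pytest.approx(2 + np.log2(1.5 / 6))
        assert np.allclose(pwm.f.sum(axis=0), 1.0)

    def test_width_mismatch(self):
        with pytest.raises(ValueError, match="width"):
            build_pwm(["TATAAT", "TATAA"], "minus10")

    def test_too_few_sites(self):
        with pytest.raises(ValueError, match="at least two"):
            build_pwm(["TATAAT"], "minus10")

    def test_pseudocount_never_exceeds_two_bits(self):
        from hypothesis import given, settings
        from hypothesis import strategies as st

        @settings(derandomize=True, max_examples=60)
        @given(st.lists(st.text(alphabet="ACGT", min_size=6, max_size=6),
                        min_size=2, max_size=30),
               st.floats(min_value=0.01, max_value=5.0))
        def check(sites, pc):
            _, w = build_pwm(sites, "minus10", pseudocount=pc)
            assert np.all(w.riw <= 2.0 + 1e-12)
            f = (2.0 ** (w.riw - 2.0))
            assert np.allclose(f.sum(axis=0), 1.0)

        check()


class TestIseq:
    def test_consensus_of_pure_pwm(self):
        _, w = build_pwm(["TATAAT"] * 3, "minus10", pseudocount=0.0)
        assert iseq("TATAAT", w) == pytest.approx(12.0)

    def test_uniform_pwm_scores_zero(self):
        pwm = PWM(element="minus10", f=np.full((4, 6), 0.25), n_sites=0,
                  pseudocount=0.0)
        assert iseq("ACGTAC", pwm.weights()) == pytest.approx(0.0)

    def test_length_mismatch(self):
        _, w = build_pwm(["TATAAT"] * 3, "minus10")
        with pytest.raises(ValueError):
            iseq("TATA", w)

    def test_consensus_is_exhaustive_maximum(self, rng):
        """Iseq is maximized by the PWM consensus over all 4^width seqs."""
        f = rng.dirichlet(np.ones(4), size=6).T
        pwm = PWM(element="minus10", f=f, n_sites=10, pseudocount=0.0)
        w = pwm.weights()
        cons_score = iseq(pwm.consensus(), w)
        best = max(iseq("".join(s), w)
                   for s in itertools.product(BASES, repeat=6))
        assert cons_score == pytest.approx(best)

    def test_mean_iseq_sampling_identity(self, rng):
        """Mean Iseq of sequences drawn from f equals sum_i (2 - H_i)."""
        f = rng.dirichlet(np.ones(4) * 2, size=6).T
        pwm = PWM(element="minus10", f=f, n_sites=0, pseudocount=0.0)
        w = pwm.weights()
        sites = pwm.sample_sites(10_000, rng)
        mean = np.mean([iseq(s, w) for s in sites])
        assert mean == pytest.approx(pwm.expected_information(), abs=0.05)


class TestGapSurprisal:
    def test_uniform_six_spacings(self):
        sm = gap_surprisal({d: 10 for d in range(15, 21)})
        for d in range(15, 21):
            assert sm.surprisal(d) == pytest.approx(np.log2(6))

    def test_two_equal_spacings(self):
        sm = gap_surprisal({17: 50, 18: 50})
        assert sm.surprisal(17) == pytest.approx(1.0)
        assert sm.surprisal(18) == pytest.approx(1.0)

    def test_entropy_identity(self, rng):
        counts = {d: int(rng.integers(1, 100)) for d in range(15, 21)}
        sm = gap_surprisal(counts)
        total = sum(counts.values())
        p = {d: c / total for d, c in counts.items()}
        entropy = -sum(v * np.log2(v) for v in p.values())
        assert sum(p[d] * sm.surprisal(d) for d in counts) == \
            pytest.approx(entropy)

    def test_out_of_range_spacing(self):
        with pytest.raises(ValueError, match="outside"):
            gap_surprisal({14: 5})

    def test_unobserved_spacing_undefined(self):
        sm = gap_surprisal({17: 10})
        assert sm.surprisal(16) is None
        assert sm.surprisal(17) == pytest.approx(0.0)

    def test_zero_total(self):
        with pytest.raises(ValueError, match="positive"):
            gap_surprisal({17: 0})


def _planted_window(rng, ext_site="TGGTATAAT", m35_site="TTGACA", d=17,
                    at=0.5):
    """A 44-nt upstream window with elements at the planted geometry:
    ext -10 nonamer 5' end at -16 (hexamer 5' at -13), -35 at d bp."""
    seq = list("".join(BASES[i] for i in rng.integers(0, 4, size=44)))
    seq[44 - 16: 44 - 7] = ext_site
    m35_start = 44 - 19 - d
    seq[m35_start: m35_start + 6] = m35_site
    return "".join(seq)


class TestScorePromoter:
    @pytest.fixture()
    def model(self):
        from regarch.simulate import default_pwms
        pwms = default_pwms(0.85)
        spacer = gap_surprisal({16: 10, 17: 40, 18: 20})
        return pwms, spacer

    def test_mode1_arithmetic(self, model, rng):
        """mode1 = Iseq(-10) + Iseq(-35) - GS(d) on a planted window."""
        pwms, spacer = model
        win = _planted_window(rng, d=17)
        s = score_promoter(win, pwms, spacer)
        assert s.mode1 == pytest.approx(
            s.iseq_minus10 + s.iseq_minus35 - spacer.surprisal(17))
        assert s.mode3 == pytest.approx(
            s.iseq_extended + s.iseq_minus35 - spacer.surprisal(17))
        assert s.mode2 == pytest.approx(s.iseq_extended)

    def test_component_values_from_f(self, model, rng):
        """Planted consensus elements score their closed-form Iseq."""
        pwms, spacer = model
        win = _planted_window(rng, d=17)
        s = score_promoter(win, pwms, spacer)
        per_col = 2 + np.log2(0.85)
        # ext: 8 consensus columns + 1 uniform column (0 bits); the
        # max-Iseq placement can only do better than the planted one
        assert s.iseq_extended >= 8 * per_col - 1e-9
        assert s.iseq_minus35 >= 6 * per_col - 1e-9

    def test_best_mode_two_when_minus35_hostile(self, model):
        pwms, spacer = model
        win = ("C" * 25) + "TGGTATAAT" + "ACGCAGCGTA"
        s = score_promoter(win, pwms, spacer)
        assert s.best_mode == 2

    def test_fixed_component_example(self):
        """Mode arithmetic on fixed component scores: 6 + 4 - 1 = 9."""
        # single-site PWMs make planted elements score 2 bits/column
        ext = PWM(element="extended_minus10",
                  f=_one_hot("TGGTATAAT", soft=0.99), n_sites=1, pseudocount=0)
        m35 = PWM(element="minus35", f=_one_hot("TTGACA", soft=0.99),
                  n_sites=1, pseudocount=0)
        m10 = PWM(element="minus10", f=ext.f[:, 3:], n_sites=1, pseudocount=0)
        spacer = gap_surprisal({17: 1, 18: 1})  # GS = 1 bit each
        rng = np.random.default_rng(5)
        win = _planted_window(rng, d=17)
        s = score_promoter(win, {"extended_minus10": ext, "minus10": m10,
                                 "minus35": m35}, spacer)
        assert s.mode1 == pytest.approx(s.iseq_minus10 + s.iseq_minus35 - 1.0)

    def test_window_too_long_raises(self, model):
        pwms, spacer = model
        with pytest.raises(ValueError):
            score_promoter("A" * 45, pwms, spacer)

    def test_short_window_partial_scoring(self, model):
        """A window missing the -35 region leaves modes 1/3 undefined."""
        pwms, spacer = model
        win = ("N" * 0) + "TGGTATAAT" + "ACGCAGCGTA"  # only last 19 nt
        s = score_promoter(win[-19:], pwms, spacer)
        assert s.mode1 is None and s.mode3 is None
        assert s.mode2 is not None and s.best_mode == 2

    def test_reverse_complement_invariance(self, small_dataset):
        """Scoring - strand TSSs on the flipped genome gives identical bits."""
        from regarch.promoters import upstream_window
        from regarch.simulate import default_pwms
        ds = small_dataset
        pwms = default_pwms(0.85)
        spacer = gap_surprisal({16: 10, 17: 40, 18: 20})
        n = ds.genome.length
        flipped = GenomeSequence(id="f", sequence=_rc(ds.genome.sequence),
                                 topology="circular")
        flip = {"+": "-", "-": "+"}
        for t in ds.tss_records[:40]:
            win1 = upstream_window(ds.genome, t.position, t.strand)
            win2 = upstream_window(flipped, n - 1 - t.position, flip[t.strand])
            assert win1 == win2
            s1 = score_promoter(win1, pwms, spacer)
            s2 = score_promoter(win2, pwms, spacer)
            assert s1.best_bits == pytest.approx(s2.best_bits)


def _one_hot(seq, soft=0.99):
    f = np.full((4, len(seq)), (1 - soft) / 3)
    for i, b in enumerate(seq):
        f[BASES.index(b), i] = soft
    return f


def _rc(s):
    return s.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


class TestDiscoverMotifs:
    def test_planted_motif_recovered(self, rng):
        seqs = []
        for _ in range(50):
            s = list("".join(BASES[i] for i in rng.integers(0, 4, size=44)))
            off = int(rng.integers(-13, -6))  # hexamer start within [-18,-1]
            s[44 + off: 44 + off + 6] = "TATAAT"
            seqs.append("".join(s))
        sites = discover_motifs(seqs, "minus10", restarts=4, seed=2)
        pwm, _ = build_pwm(sites, "minus10")
        assert pwm.consensus() == "TATAAT"

    def test_random_sequences_carry_less_information(self, rng):
        planted = []
        for _ in range(40):
            s = list("".join(BASES[i] for i in rng.integers(0, 4, size=44)))
            s[30:36] = "TATAAT"
            planted.append("".join(s))
        random_seqs = ["".join(BASES[i] for i in rng.integers(0, 4, size=44))
                       for _ in range(40)]
        def info(seqs):
            sites = discover_motifs(seqs, "minus10", restarts=3, seed=4)
            pwm, _ = build_pwm(sites, "minus10")
            return pwm.expected_information()
        assert info(planted) > info(random_seqs)

    def test_deterministic_given_seed(self, rng):
        seqs = ["".join(BASES[i] for i in rng.integers(0, 4, size=44))
                for _ in range(30)]
        a = discover_motifs(seqs, "minus35", restarts=3, seed=11)
        b = discover_motifs(seqs, "minus35", restarts=3, seed=11)
        assert a == b

    def test_window_narrower_than_width(self):
        with pytest.raises(ValueError, match="window"):
            discover_motifs(["ACGT" * 11] * 5, "minus10", window=(-5, -1))


class TestATProfile:
    def test_poly_at_genome(self):
        g = GenomeSequence(id="g", sequence="AT" * 500, topology="circular")
        profile = prom.at_profile(g, [(500, "+")], flank=50)
        assert np.allclose(profile, 1.0)

    def test_poly_gc_genome(self):
        g = GenomeSequence(id="g", sequence="GC" * 500, topology="circular")
        profile = prom.at_profile(g, [(500, "+")], flank=50)
        assert np.allclose(profile, 0.0)

    def test_random_genome_near_half(self, rng):
        seq = "".join(BASES[i] for i in rng.integers(0, 4, size=20_000))
        g = GenomeSequence(id="g", sequence=seq, topology="circular")
        anchors = [(int(p), "+") for p in rng.integers(0, 20_000, size=200)]
        profile = prom.at_profile(g, anchors, flank=20)
        assert np.all(np.abs(profile - 0.5) < 0.15)  # ~4 sigma binomial
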