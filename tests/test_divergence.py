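"""JTT maximum-likelihood distances and the three-point branch
decomposition."""

import shutil
import subprocess

import numpy as np
import pytest

from duplofate import jtt
from duplofate import divergence as dv


def simulate_pair(t, length, seed):
    rng = np.random.default_rng(seed)
    anc = jtt.sample_equilibrium(length, rng)
    desc = jtt.evolve(anc, t, rng)
    return dv.AlignedPair("a", "b", jtt.decode(anc), jtt.decode(desc))


def grid_search_distance(pair, step=1e-3, t_max=10.0):
    """Independent oracle: brute-force likelihood grid."""
    counts = dv._count_matrix(pair.seq_a, pair.seq_b)
    log_pi = np.log(jtt.equilibrium_frequencies())
    best_t, best_ll = None, -np.inf
    for t in np.arange(step, t_max, step):
        p = np.maximum(jtt.transition_matrix(t), 1e-300)
        ll = (counts * (log_pi[:, None] + np.log(p))).sum()
        if ll > best_ll:
            best_t, best_ll = t, ll
    return best_t


class TestJTTModel:
    def test_rate_matrix_properties(self):
        q = jtt.rate_matrix()
        pi = jtt.equilibrium_frequencies()
        assert np.allclose(q.sum(axis=1), 0, atol=1e-12)
        assert -(pi * np.diag(q)).sum() == pytest.approx(1.0)
        # detailed balance (time reversibility)
        flux = pi[:, None] * q
        assert np.allclose(flux, flux.T, atol=1e-12)

    def test_transition_matrix_limits(self):
        assert np.allclose(jtt.transition_matrix(0.0), np.eye(20),
                           atol=1e-12)
        # long branches converge to the equilibrium distribution
        p_long = jtt.transition_matrix(50.0)
        assert np.allclose(p_long, jtt.equilibrium_frequencies()[None, :],
                           atol=1e-6)


class TestJTTDistance:
    def test_identical_sequences(self):
        rng = np.random.default_rng(0)
        seq = jtt.decode(jtt.sample_equilibrium(200, rng))
        t, flags = dv.jtt_distance(dv.AlignedPair("a", "b", seq, seq))
        assert t < 1e-4 and flags == []

    def test_simulation_recovery_at_half_substitution(self):
        pair = simulate_pair(0.5, 10_000, seed=1)
        t, _ = dv.jtt_distance(pair)
        assert 0.45 <= t <= 0.55

    @pytest.mark.parametrize("seed,t_true", [(5, 0.3), (6, 0.8), (7, 1.5)])
    def test_matches_grid_search_oracle(self, seed, t_true):
        pair = simulate_pair(t_true, 100, seed=seed)
        t_opt, _ = dv.jtt_distance(pair)
        t_grid = grid_search_distance(pair)
        assert abs(t_opt - t_grid) <= 2e-3

    def test_symmetry_in_sequences(self):
        pair = simulate_pair(0.7, 300, seed=3)
        fwd, _ = dv.jtt_distance(pair)
        rev, _ = dv.jtt_distance(
            dv.AlignedPair("b", "a", pair.seq_b, pair.seq_a))
        assert fwd == pytest.approx(rev, abs=1e-9)

    def test_monotone_in_generating_branch_length(self):
        estimates = []
        for k, t_true in enumerate(np.arange(0.1, 2.01, 0.38)):
            pair = simulate_pair(float(t_true), 5000, seed=100 + k)
            estimates.append(dv.jtt_distance(pair)[0])
        assert all(a < b for a, b in zip(estimates, estimates[1:]))

    def test_gap_handling_and_errors(self):
        rng = np.random.default_rng(2)
        seq = jtt.decode(jtt.sample_equilibrium(40, rng))
        gapped = "-" * 20 + seq[20:]
        t_full, _ = dv.jtt_distance(dv.AlignedPair("a", "b", seq, seq))
        t_gap, flags = dv.jtt_distance(dv.AlignedPair("a", "b", gapped, seq))
        assert t_gap < 1e-4
        assert "low_confidence" in flags     # only 20 ungapped columns
        with pytest.raises(ValueError, match="ungapped"):
            dv.jtt_distance(dv.AlignedPair("a", "b", "-" * 10, seq[:10]))

    def test_saturated_pair_capped_and_flagged(self):
        rng = np.random.default_rng(9)
        a = jtt.decode(jtt.sample_equilibrium(60, rng))
        # a maximally implausible partner: every site the rarest residue
        b = "W" * 60
        t, flags = dv.jtt_distance(dv.AlignedPair("a", "b", a, b))
        assert t == dv.T_MAX and "saturated" in flags

    def test_agrees_with_phangorn_reference(self, tmp_path):
        """Cross-check against an independent phylogenetics implementation."""
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript unavailable")
        pair = simulate_pair(0.8, 400, seed=11)
        fasta = tmp_path / "pair.fasta"
        fasta.write_text(f">a\n{pair.seq_a}\n>b\n{pair.seq_b}\n")
        script = (
            'suppressMessages(library(phangorn));'
            f'aln <- read.phyDat("{fasta}", format="fasta", type="AA");'
            'cat(as.numeric(dist.ml(aln, model="JTT")))')
        try:
            out = subprocess.run(["Rscript", "-e", script], timeout=120,
                                 capture_output=True, text=True, check=True)
        except (subprocess.SubprocessError, OSError) as exc:
            pytest.skip(f"phangorn reference not runnable: {exc}")
        reference = float(out.stdout.strip().split()[-1])
        mine, _ = dv.jtt_distance(pair)
        assert mine == pytest.approx(reference, abs=1e-4)


class TestThreePointBranches:
    @pytest.mark.parametrize("triple,expected", [
        ((0.4, 0.6, 0.6), (0.2, 0.2)),
        ((0.4, 0.7, 0.5), (0.3, 0.1)),
    ])
    def test_direct_arithmetic(self, triple, expected):
        a, b, flags = dv.three_point_branches(dv.DistanceTriple(*triple))
        assert (a, b) == pytest.approx(expected)
        assert flags == []

    def test_clipping_preserves_sum(self):
        a, b, flags = dv.three_point_branches(
            dv.DistanceTriple(0.1, 0.2, 0.5))
        assert (a, b) == pytest.approx((0.0, 0.1))
        assert "clipped_a" in flags

    def test_sum_conserved_on_random_triples(self, rng):
        for _ in range(10_000):
            d = rng.uniform(0, 3, size=3)
            a, b, _ = dv.three_point_branches(dv.DistanceTriple(*d))
            assert a + b == pytest.approx(d[0], abs=1e-12)
            assert a >= 0 and b >= 0

    def test_additive_tree_recovered_exactly(self, rng):
        for _ in range(200):
            ta, tb, tc = rng.uniform(0.01, 1.5, size=3)
            triple = dv.DistanceTriple(ta + tb, ta + tc, tb + tc)
            a, b, flags = dv.three_point_branches(triple)
            assert a == pytest.approx(ta, abs=1e-12)
            assert b == pytest.approx(tb, abs=1e-12)
            assert flags == []

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            dv.DistanceTriple(-0.1, 0.2, 0.3)


class TestNormalizedDivergence:
    @pytest.mark.parametrize("ba,bb,asym,total", [
        (0.2, 0.2, 0.0, 0.4),
        (0.3, 0.1, 0.5, 0.4),
    ])
    def test_arithmetic(self, ba, bb, asym, total):
        assert dv.normalized_divergence(ba, bb, "asymmetry") \
            == pytest.approx(asym)
        assert dv.normalized_divergence(ba, bb, "total") \
            == pytest.approx(total)

    def test_swap_invariance_and_total_identity(self, rng):
        for _ in range(100):
            d = rng.uniform(0.01, 2, size=3)
            d = np.sort(d)[::-1]  # keep additive-ish, avoid clipping noise
            a, b, _ = dv.three_point_branches(
                dv.DistanceTriple(d[2], d[0], d[1]))
            asym = dv.normalized_divergence(a, b)
            assert asym == dv.normalized_divergence(b, a)
            assert 0 <= asym <= 1
            assert dv.normalized_divergence(a, b, "total") \
                == pytest.approx(d[2])

    def test_zero_total_undefined(self):
        assert dv.normalized_divergence(0.0, 0.0) is None


class TestTripleIO:
    def test_fasta_roundtrip_and_analysis(self, tmp_path):
        from duplofate import synthetic as syn
        cfg = syn.SimConfig(seed=4, n_triples=3, alignment_length=500,
                            branch_a=0.2, branch_b=0.2, branch_c=0.6)
        seqs, truth = syn.simulate_sequences(cfg)
        path = tmp_path / "aln.fasta"
        syn.write_fasta(seqs, path)
        df = dv.analyze_fasta(path)
        assert len(df) == 3
        assert (df["branch_a"] + df["branch_b"]).to_numpy() \
            == pytest.approx(df["d_ab"].to_numpy())
        # recovered totals near the generating d_ab = 0.4
        assert df["d_ab"].mean() == pytest.approx(0.4, abs=0.12)

    def test_bad_role_rejected(self, tmp_path):
        p = tmp_path / "bad.fasta"
        p.write_text(">pair1|x\nACDEF\n")
        with pytest.raises(ValueError, match="role"):
            dv.read_triples(p)
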