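"""Peak caller: clustering vs a brute-force oracle, the permutation null,
scoring rules, input subtraction and determinism."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ripcall as rc
from ripcall.peaks import simulate_null, score_peaks, peaks_to_bed

from conftest import make_gene


def R(start, end, strand="+", chrom="chrT", name=""):
    return rc.AlignedRead(chrom, start, end, strand, name)


def brute_force_peaks(reads):
    """Independent oracle: connected components of the pairwise >=1 bp
    overlap relation (quadratic union-find), heights from a per-base
    coverage array.  Book-ended reads overlap by 0 bp and stay separate."""
    if not reads:
        return []
    parent = list(range(len(reads)))

    def find(i):
        while parent[i] != i:
            i = parent[i]
        return i

    for i, a in enumerate(reads):
        for j, b in enumerate(reads):
            if i < j and a.start < b.end and b.start < a.end:
                parent[find(i)] = find(j)
    comps: dict[int, list] = {}
    for i in range(len(reads)):
        comps.setdefault(find(i), []).append(reads[i])
    out = []
    for members in comps.values():
        lo = min(r.start for r in members)
        hi = max(r.end for r in members)
        cov = np.zeros(hi - lo, dtype=int)
        for r in members:
            cov[r.start - lo : r.end - lo] += 1
        out.append((lo, hi, int(cov.max()), len(members)))
    return sorted(out)


class TestClusterReads:
    def test_overlap_closure_and_heights(self):
        peaks = rc.cluster_reads([R(0, 10), R(5, 15), R(20, 30)])
        assert [(p.start, p.end, p.height, p.support) for p in peaks] == [
            (0, 15, 2, 2),
            (20, 30, 1, 1),
        ]

    def test_bookended_reads_stay_separate(self):
        """'At least 1 bp overlap' is strict: [0,10) and [10,20) do not cluster."""
        peaks = rc.cluster_reads([R(0, 10), R(10, 20)])
        assert len(peaks) == 2

    def test_mixed_strand_rejected(self):
        with pytest.raises(ValueError):
            rc.cluster_reads([R(0, 10, "+"), R(5, 15, "-")])

    @given(data=st.data(), n=st.integers(1, 50))
    @settings(deadline=None, derandomize=True, max_examples=60)
    def test_matches_bruteforce_oracle(self, data, n):
        reads = []
        for _ in range(n):
            s = data.draw(st.integers(0, 200))
            reads.append(R(s, s + data.draw(st.integers(1, 50))))
        got = [(p.start, p.end, p.height, p.support) for p in rc.cluster_reads(reads)]
        assert got == brute_force_peaks(reads)


class TestSimulateNull:
    def test_forced_placement_when_read_fills_span(self):
        g = make_gene("G", "+", exons=[(0, 10)])
        null = simulate_null(g, [10], n_sims=20, seed=0, keep_placements=True)
        assert np.all(null.sim_max_heights == 1)
        for pl in null.placements:
            assert pl.tolist() == [[0, 10]]

    def test_two_reads_overlap_probability_matches_enumeration(self):
        """Two 50 bp reads in a 100 bp single-exon span: the frequency of a
        height-2 simulation matches exact enumeration over the 51x51 equally
        likely start pairs."""
        g = make_gene("G", "+", exons=[(0, 100)])
        null = simulate_null(g, [50, 50], n_sims=10_000, seed=42)
        pairs = [(a, b) for a in range(51) for b in range(51)]
        p_exact = sum(abs(a - b) < 50 for a, b in pairs) / len(pairs)
        freq = float(np.mean(null.sim_max_heights == 2))
        se = (p_exact * (1 - p_exact) / 10_000) ** 0.5
        assert abs(freq - p_exact) < 4 * se + 1e-9

    def test_default_runs_500_simulations(self):
        g = make_gene("G", "+", exons=[(0, 500)])
        null = simulate_null(g, [50, 60], seed=1)
        assert null.n_sims == 500
        assert len(null.sim_max_heights) == 500

    def test_each_simulation_conserves_count_and_length_multiset(self):
        g = make_gene("G", "+", exons=[(0, 300), (400, 800)])
        lengths = [30, 30, 50, 70, 120]
        null = simulate_null(g, lengths, n_sims=50, seed=2, keep_placements=True)
        for pl in null.placements:
            assert pl.shape[0] == len(lengths)
            assert sorted((pl[:, 1] - pl[:, 0]).tolist()) == sorted(lengths)

    def test_oversized_read_placed_flush_with_warning(self, caplog):
        g = make_gene("G", "+", exons=[(10, 20)])
        with caplog.at_level("WARNING"):
            null = simulate_null(g, [50], n_sims=5, seed=0, keep_placements=True)
        assert "flush" in caplog.text
        assert null.placements[0].tolist() == [[10, 20]]

    def test_null_reads_stay_within_exons(self):
        g = make_gene("G", "+", exons=[(0, 300), (500, 900)])
        null = simulate_null(g, [100] * 20, n_sims=30, seed=3, keep_placements=True)
        for pl in null.placements:
            for s, e in pl:
                assert (0 <= s and e <= 300) or (500 <= s and e <= 900)


class TestScorePeaks:
    def null_of(self, sim_maxima):
        arr = np.asarray(sim_maxima)
        return rc.NullModel("G", len(arr), arr, np.array([50]), (0,))

    def test_observed_above_all_maxima_is_selected(self):
        null = self.null_of([9] * 500)
        (pk,) = score_peaks([rc.Peak("c", 0, 10, "+", "G", height=10)], null)
        assert pk.p_empirical == 0.0 and pk.selected

    def test_p_counts_ties_against_the_peak(self):
        null = self.null_of([3] * 30 + [2] * 470)
        (pk,) = score_peaks([rc.Peak("c", 0, 10, "+", "G", height=3)], null,
                            select_rule="empirical_p")
        assert pk.p_empirical == pytest.approx(0.06)
        assert not pk.selected

    def test_strict_max_requires_exceeding_every_maximum(self):
        null = self.null_of([5] + [2] * 499)
        peaks = [rc.Peak("c", 0, 10, "+", "G", height=5),
                 rc.Peak("c", 20, 30, "+", "G", height=6)]
        score_peaks(peaks, null, select_rule="strict_max")
        assert [p.selected for p in peaks] == [False, True]

    def test_raising_alpha_never_shrinks_selection(self):
        rng = np.random.default_rng(0)
        null = self.null_of(rng.integers(1, 20, size=500))
        peaks = [rc.Peak("c", i * 50, i * 50 + 10, "+", "G", height=h)
                 for i, h in enumerate(rng.integers(1, 25, size=30))]
        prev: set = set()
        for alpha in (0.01, 0.05, 0.2, 0.5, 1.01):
            score_peaks(peaks, null, alpha=alpha, select_rule="empirical_p")
            cur = {id(p) for p in peaks if p.selected}
            assert prev <= cur
            prev = cur


class TestSubtractInput:
    def test_overlap_removes_and_bookend_retains(self):
        ip = [rc.Peak("c", 100, 200, "+", "A"), rc.Peak("c", 300, 400, "+", "B")]
        inp = [rc.Peak("c", 150, 160, "+", "x"), rc.Peak("c", 400, 450, "+", "y")]
        kept = rc.subtract_input(ip, inp)
        assert [p.gene_id for p in kept] == ["B"]  # [300,400) vs [400,450): 0 bp

    def test_strand_mismatch_does_not_remove(self):
        ip = [rc.Peak("c", 100, 200, "+", "A")]
        kept = rc.subtract_input(ip, [rc.Peak("c", 100, 200, "-", "x")])
        assert len(kept) == 1

    def test_empty_input_returns_ip_unchanged_with_warning(self, caplog):
        ip = [rc.Peak("c", 0, 10, "+", "A")]
        with caplog.at_level("WARNING"):
            assert rc.subtract_input(ip, []) == ip
        assert "empty" in caplog.text

    def test_adding_input_peaks_never_grows_retained_set(self):
        rng = np.random.default_rng(1)
        ip = [rc.Peak("c", int(s), int(s) + 50, "+", f"g{i}")
              for i, s in enumerate(rng.integers(0, 2000, size=40))]
        inp = [rc.Peak("c", int(s), int(s) + 30, "+", "x")
               for s in rng.integers(0, 2000, size=40)]
        kept_ids = None
        for k in range(0, 41, 10):
            kept = {(p.start, p.end) for p in rc.subtract_input(ip, inp[:k])}
            if kept_ids is not None:
                assert kept <= kept_ids
            kept_ids = kept


class TestCallTargets:
    def test_targets_are_owners_of_retained_peaks(self):
        peaks = [rc.Peak("c", 0, 10, "+", "A"), rc.Peak("c", 20, 30, "+", "A"),
                 rc.Peak("c", 50, 60, "+", "B")]
        assert rc.call_targets(peaks) == {"A", "B"}
        assert rc.call_targets([]) == set()


class TestDeterminism:
    CFG = dict(n_genes=40, n_target_genes=6, seed=3)

    def run_once(self, genes_order=None):
        sim = rc.simulate_dataset(rc.SimConfig(**self.CFG))
        genes = genes_order(sim.genes) if genes_order else sim.genes
        res = rc.run_rip_pipeline(sim.ip_reads, sim.input_reads, genes,
                                  n_sims=200, seed=7)
        return sim, res

    def test_identical_seed_gives_byte_identical_outputs(self, tmp_path):
        sim1, res1 = self.run_once()
        sim2, res2 = self.run_once()
        assert peaks_to_bed(res1.ip.peaks) == peaks_to_bed(res2.ip.peaks)
        assert sorted(res1.targets) == sorted(res2.targets)
        assert sim1.sites.equals(sim2.sites)

    def test_gene_order_permutation_leaves_outputs_unchanged(self):
        _, res1 = self.run_once()
        _, res2 = self.run_once(genes_order=lambda gs: list(reversed(gs)))
        assert peaks_to_bed(res1.ip.peaks) == peaks_to_bed(res2.ip.peaks)
        assert res1.targets == res2.targets
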