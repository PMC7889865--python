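"""Variant pruning, the parity model, clustering and phasing evaluation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phasembly.fragments import HetVariant, Molecule
from phasembly.haplotyping import (
    Parity,
    ParityObservation,
    PhaseBlock,
    PruneConfig,
    assign_molecule,
    build_phase_blocks,
    collect_parity_observations,
    evaluate_phasing,
    extend_phase_blocks,
    key_parity_probability,
    parity_posterior,
    prune_variants,
    recursive_cluster,
)


def hv(vid, pos=None, qual=50.0, depth=30, alt_count=15):
    return HetVariant(variant_id=vid, chrom="c", pos=pos or (vid + 1) * 1000,
                      ref_allele="A", alt_allele="G", qual=qual, depth=depth,
                      alt_count=alt_count)


def mol(mid, calls, p=0.99):
    m = Molecule(mid, f"BX{mid}", "c", 0, 10_000)
    m.allele_calls = {vid: (a, p) for vid, a in calls.items()}
    return m


class TestPrune:
    def test_low_alt_fraction_pruned(self):
        variants = [hv(i) for i in range(20)] + [hv(99, alt_count=6)]  # 0.20
        kept = prune_variants(variants)
        assert all(v.variant_id != 99 for v in kept)

    def test_low_quality_pruned(self):
        variants = [hv(i) for i in range(20)] + [hv(99, qual=12.0)]
        kept = prune_variants(variants)
        assert all(v.variant_id != 99 for v in kept)

    def test_boundaries_inclusive(self):
        variants = [hv(i, depth=20 + i) for i in range(21)]  # depths 20..40
        variants.append(hv(99, qual=13.0, depth=32, alt_count=8))  # alt fraction 0.25
        kept = prune_variants(variants)
        assert any(v.variant_id == 99 for v in kept)

    def test_depth_percentile_band(self):
        variants = [hv(i, depth=30 + i, alt_count=20) for i in range(50)]
        variants += [hv(100, depth=2, alt_count=1), hv(101, depth=500, alt_count=250)]
        kept_ids = {v.variant_id for v in prune_variants(variants)}
        assert 100 not in kept_ids and 101 not in kept_ids

    def test_empty_input(self):
        assert prune_variants([]) == []

    def test_literal_band_mode(self):
        cfg = PruneConfig(literal_coverage_band=True)
        variants = [hv(i, depth=30) for i in range(10)] + [hv(99, depth=28)]
        # literal band is 3..27 for mean depth ~30, so depth 28+ variants fail
        assert prune_variants(variants, cfg) == []


class TestParityPosterior:
    def test_unanimous_even_is_confident(self):
        obs = ParityObservation(pair=(0, 1), n00=3, n11=2)  # N=5, k=5
        assert parity_posterior(obs, 0.99, 0.99) is Parity.EVEN
        p_c = key_parity_probability(0.99, 0.99)
        post = p_c**5 / (p_c**5 + (1 - p_c) ** 5)
        assert post == pytest.approx(1 - 3.4e-9, abs=1e-9)

    def test_three_of_five_undetermined(self):
        obs = ParityObservation(pair=(0, 1), n00=3, n01=1, n10=1)  # k=3, N=5
        # posterior reduces to p_c = 0.9802 <= 0.99
        assert parity_posterior(obs, 0.99, 0.99) is Parity.UNDETERMINED

    def test_symmetry_gives_undetermined(self):
        obs = ParityObservation(pair=(0, 1), n00=3, n01=3)  # k = N/2
        assert parity_posterior(obs, 0.95, 0.95) is Parity.UNDETERMINED

    def test_empty_observation_undetermined(self):
        assert parity_posterior(ParityObservation(pair=(0, 1)), 0.9, 0.9) is Parity.UNDETERMINED

    def test_matches_bruteforce_two_hypothesis_posterior(self):
        alpha = 0.99
        for p in (0.9, 0.95, 0.99):
            p_c = p * p + (1 - p) * (1 - p)
            for N in range(1, 13):
                for k in range(N + 1):
                    like_even = math.comb(N, k) * p_c**k * (1 - p_c) ** (N - k)
                    like_odd = math.comb(N, k) * (1 - p_c) ** k * p_c ** (N - k)
                    post = like_even * 0.5 / (like_even * 0.5 + like_odd * 0.5)
                    if post > alpha:
                        want = Parity.EVEN
                    elif 1 - post > alpha:
                        want = Parity.ODD
                    else:
                        want = Parity.UNDETERMINED
                    obs = ParityObservation(pair=(0, 1), n00=k, n01=N - k)
                    assert parity_posterior(obs, p, p, alpha) is want

    def test_literal_quotient_can_exceed_one_but_decides_the_same_way(self):
        obs = ParityObservation(pair=(0, 1), n00=5)
        p_c = key_parity_probability(0.99, 0.99)
        assert 2.0**5 * p_c**5 > 1.0  # the printed formula is not a probability
        assert parity_posterior(obs, 0.99, 0.99, literal=True) is Parity.EVEN

    @settings(max_examples=100, deadline=None)
    @given(st.integers(1, 60), st.integers(0, 60), st.floats(0.51, 0.999))
    def test_normalized_posterior_always_in_unit_interval(self, N, k, p):
        k = min(k, N)
        p_c = key_parity_probability(p, p)
        log_even = k * math.log(p_c) + (N - k) * math.log1p(-p_c)
        log_odd = (N - k) * math.log(p_c) + k * math.log1p(-p_c)
        post = 1.0 / (1.0 + math.exp(min(log_odd - log_even, 700.0)))
        assert 0.0 <= post <= 1.0
        assert parity_posterior(ParityObservation(pair=(0, 1), n00=k, n01=N - k), p, p) in Parity


def synthetic_instance(rng, n_vars=12, n_mols=30, span=5):
    """Error-free molecules over two random haplotypes."""
    hap1 = rng.integers(0, 2, n_vars)
    mols = []
    for mid in range(n_mols):
        lo = int(rng.integers(0, n_vars - 2))
        hi = min(n_vars, lo + 2 + int(rng.integers(span)))
        hap = int(rng.integers(1, 3))
        calls = {v: int(hap1[v]) if hap == 1 else 1 - int(hap1[v]) for v in range(lo, hi)}
        mols.append(mol(mid, calls))
    return mols, hap1


def naive_fixed_point(mols, merge_support=3, order_seed=0):
    """Oracle: repeat merging in a shuffled order until stable."""
    from phasembly.haplotyping import _seed_clusters, per_variant_p

    obs = collect_parity_observations(mols)
    pv = per_variant_p(mols)
    decisions = {pair: parity_posterior(o, pv[pair[0]], pv[pair[1]])
                 for pair, o in obs.items()}
    clusters = _seed_clusters(obs, decisions)
    rng = np.random.default_rng(order_seed)
    changed = True
    while changed:
        changed = False
        idx = list(range(len(clusters)))
        rng.shuffle(idx)
        for ii, i in enumerate(idx):
            for j in idx[ii + 1:]:
                ci, cj = clusters[i], clusters[j]
                straight = len(ci.cluster_a & cj.cluster_a) + len(ci.cluster_b & cj.cluster_b)
                crossed = len(ci.cluster_a & cj.cluster_b) + len(ci.cluster_b & cj.cluster_a)
                if max(straight, crossed) < merge_support or straight == crossed:
                    continue
                if crossed > straight:
                    cj.cluster_a, cj.cluster_b = cj.cluster_b, cj.cluster_a
                    cj.hap_a = {v: 1 - a for v, a in cj.hap_a.items()}
                ci.cluster_a |= cj.cluster_a
                ci.cluster_b |= cj.cluster_b
                for v, a in cj.hap_a.items():
                    ci.hap_a.setdefault(v, a)
                clusters.pop(j if j > i else j)
                changed = True
                break
            if changed:
                break
    return clusters


class TestRecursiveCluster:
    def test_three_shared_molecules_merge(self):
        mols = [mol(i, {0: 0, 1: 0, 2: 0}) for i in range(3)]
        mols += [mol(i + 3, {0: 1, 1: 1, 2: 1}) for i in range(3)]
        clusters = recursive_cluster(mols)
        assert len(clusters) == 1
        assert clusters[0].hap_a.keys() == {0, 1, 2}

    def test_two_shared_molecules_do_not_merge(self):
        # neighbouring seed cluster pairs share exactly two molecules
        mols = [mol(0, {0: 0, 1: 0, 2: 0, 3: 0}), mol(1, {0: 1, 1: 1, 2: 1, 3: 1})]
        mols += [mol(2, {0: 0, 1: 0}), mol(3, {0: 1, 1: 1})]
        mols += [mol(4, {2: 0, 3: 0}), mol(5, {2: 1, 3: 1})]
        clusters = recursive_cluster(mols)
        # nothing merges below the support threshold: every seed pair survives
        assert len(clusters) == 3
        assert all(len(c.hap_a) == 2 for c in clusters)

    def test_matches_any_order_fixed_point_oracle(self, rng):
        mols, _ = synthetic_instance(rng)
        got = {frozenset(c.cluster_a | c.cluster_b) for c in recursive_cluster(mols)}
        for order_seed in (0, 1, 2):
            oracle = naive_fixed_point([mol(m.molecule_id, {v: a for v, (a, _) in m.allele_calls.items()})
                                        for m in mols], order_seed=order_seed)
            want = {frozenset(c.cluster_a | c.cluster_b) for c in oracle}
            assert got == want

    def test_raising_merge_support_never_increases_merges(self, rng):
        mols, _ = synthetic_instance(rng, n_mols=40)
        n3 = len(recursive_cluster(mols, merge_support=3))
        n4 = len(recursive_cluster([mol(m.molecule_id, {v: a for v, (a, _) in m.allele_calls.items()})
                                    for m in mols], merge_support=4))
        assert n4 >= n3

    def test_complementary_clusters_disjoint(self, rng):
        mols, _ = synthetic_instance(rng)
        for c in recursive_cluster(mols):
            assert not (c.cluster_a & c.cluster_b)


class TestPhaseBlocks:
    def test_unanimous_variant_phased_conflicting_excluded(self):
        mols = [mol(0, {0: 0, 1: 0}), mol(1, {0: 0, 1: 1}), mol(2, {0: 1, 1: 1})]
        from phasembly.haplotyping import HaplotypeClusterPair
        cp = HaplotypeClusterPair(cluster_a={0, 1}, cluster_b={2}, hap_a={0: 0, 1: 0})
        var_pos = {0: 1000, 1: 2000}
        blocks = build_phase_blocks([cp], mols, var_pos)
        assert len(blocks) == 0 or 1 not in blocks[0].variants
        # with the conflict removed the block forms and phases both sites
        mols[1].allele_calls[1] = (0, 0.99)
        blocks = build_phase_blocks([cp], mols, var_pos)
        assert blocks[0].variants == {0: 0, 1: 0}
        assert blocks[0].block_id == 1000

    def test_extend_requires_five_shared_variants(self):
        def block(vids, offset=0):
            return PhaseBlock(block_id=min(vids) * 10, variants={v: 0 for v in vids},
                              molecules={}, span=(min(vids) * 10, max(vids) * 10))

        b1 = block(range(0, 10))
        b2 = block(range(5, 15))  # shares 5
        merged = extend_phase_blocks([b1, b2], var_pos={v: v * 10 for v in range(15)})
        assert len(merged) == 1
        b3 = block(range(0, 10))
        b4 = block(range(6, 15))  # shares 4
        merged = extend_phase_blocks([b3, b4], var_pos={v: v * 10 for v in range(15)})
        assert len(merged) == 2

    def test_extend_chain_matches_union_find_oracle(self):
        var_pos = {v: v * 10 for v in range(25)}
        blocks = [
            PhaseBlock(0, {v: v % 2 for v in range(0, 10)}, {}, (0, 90)),
            PhaseBlock(50, {v: 1 - (v % 2) for v in range(5, 17)}, {}, (50, 160)),
            PhaseBlock(120, {v: v % 2 for v in range(12, 25)}, {}, (120, 240)),
        ]
        merged = extend_phase_blocks(blocks, var_pos=var_pos)
        assert len(merged) == 1  # A-B and B-C overlap by >= 5, so A-C merge transitively
        assert merged[0].variants.keys() == set(range(25))
        # orientation: block 2 was complemented relative to 1 and 3
        assert all(merged[0].variants[v] == v % 2 for v in range(25))

    def test_inconsistent_orientation_blocks_not_merged(self):
        var_pos = {v: v * 10 for v in range(12)}
        b1 = PhaseBlock(0, {v: 0 for v in range(0, 8)}, {}, (0, 70))
        bad = {v: 0 for v in range(3, 8)}
        bad[3] = 1  # one of five shared variants disagrees in orientation
        b2 = PhaseBlock(30, {**bad, **{v: 0 for v in range(8, 12)}}, {}, (30, 110))
        merged = extend_phase_blocks([b1, b2], var_pos=var_pos)
        assert len(merged) == 2


class TestAssignMolecule:
    def test_hand_computed_likelihood(self):
        block = PhaseBlock(1000, {0: 1, 1: 1, 2: 1}, {}, (1000, 3000))
        m = mol(0, {0: 1, 1: 1, 2: 1})
        res = assign_molecule(m, [block])
        assert res is not None
        block_id, hap, margin = res
        assert (block_id, hap) == (1000, 1)
        assert margin == pytest.approx(0.99**3 - 0.01**3)
        assert 0.99**3 == pytest.approx(0.970299)

    def test_single_het_call_unassigned(self):
        block = PhaseBlock(1000, {0: 1, 1: 1}, {}, (1000, 2000))
        assert assign_molecule(mol(0, {0: 1}), [block]) is None

    def test_balanced_evidence_unassigned(self):
        block = PhaseBlock(1000, {0: 1, 1: 0}, {}, (1000, 2000))
        m = mol(0, {0: 1, 1: 1})  # matches hap1 at site 0, hap2 at site 1
        assert assign_molecule(m, [block]) is None

    def test_complement_matching_molecule_goes_to_hap2(self):
        block = PhaseBlock(1000, {0: 1, 1: 1, 2: 1}, {}, (1000, 3000))
        res = assign_molecule(mol(0, {0: 0, 1: 0, 2: 0}), [block])
        assert res[1] == 2


class TestEvaluatePhasing:
    def run(self, pred, truth):
        n = len(pred)
        var_pos = {i: (i + 1) * 100 for i in range(n)}
        block = PhaseBlock(100, {i: pred[i] for i in range(n)}, {}, (100, n * 100))
        truth_phase = {i: (2 if truth[i] == 0 else 1) for i in range(n)}
        # truth_phase maps vid -> haplotype carrying the alt allele
        return evaluate_phasing([block], truth_phase, var_pos)

    def test_isolated_flip_is_one_mismatch(self):
        res = self.run([0, 1, 0, 0], [0, 0, 0, 0])
        assert res["mismatch_errors"] == 1
        assert res["long_switch_errors"] == 0

    def test_persistent_flip_is_one_long_switch(self):
        res = self.run([0, 0, 1, 1], [0, 0, 0, 0])
        assert res["mismatch_errors"] == 0
        assert res["long_switch_errors"] == 1

    def test_orientation_invariance(self):
        res = self.run([1, 0, 1, 1], [0, 0, 0, 0])  # complement of an isolated flip
        assert res["mismatch_errors"] == 1
        assert res["long_switch_errors"] == 0

    def test_injected_flip_rate_matches_expectation(self, rng):
        n, r = 400, 0.02
        truth = rng.integers(0, 2, n)
        flips = rng.random(n) < r
        pred = truth ^ flips
        res = self.run(list(pred), list(truth))
        expected = n * r * (1 - r) ** 2
        sigma = math.sqrt(expected)
        assert abs(res["mismatch_errors"] - expected) <= 3 * sigma

    def test_block_n50_and_max(self):
        var_pos = {0: 100, 1: 200, 2: 1000, 3: 5000}
        blocks = [PhaseBlock(100, {0: 0, 1: 0}, {}, (100, 200)),
                  PhaseBlock(1000, {2: 0, 3: 0}, {}, (1000, 5000))]
        res = evaluate_phasing(blocks, {i: 1 for i in range(4)}, var_pos)
        assert res["max_block"] == 4001
        assert res["block_N50"] == 4001
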