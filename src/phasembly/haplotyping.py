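"""Molecule haplotyping: variant pruning, parity calls, recursive clustering.

The phasing signal in linked reads lives in pairs of heterozygous SNPs
covered by the same molecule.  For a pair of het sites the two true
haplotypes form complementary two-site keys, either {00, 11} ("even
parity") or {01, 10} ("odd parity").  A Bayesian two-hypothesis test on
the molecule key counts decides the parity of each adjacent pair; pairs
with a confident parity seed small cluster pairs of molecules that are
then merged recursively (complementary clusters in lockstep) whenever
enough molecules support the same haplotype in both.  Converged cluster
pairs become phase blocks, blocks sharing enough consistently oriented
variants are merged again, and finally every molecule is assigned to the
block/haplotype maximising the likelihood of its allele calls.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .fragments import HetVariant, Molecule

DEFAULT_ALPHA = 0.99
DEFAULT_MERGE_SUPPORT = 3
DEFAULT_OVERLAP_SUPPORT = 5
DEFAULT_P_FLOOR = 0.95
ASSIGN_TIE_MARGIN = 1e-12


# ---------------------------------------------------------------------------
# pruning

@dataclass(slots=True)
class PruneConfig:
    min_alt_fraction: float = 0.25
    coverage_low_pct: float = 10.0
    coverage_high_pct: float = 90.0
    min_qual: float = 13.0
    # literal mode applies the band 0.1*mean_depth <= d <= 0.9*mean_depth
    # instead of depth percentiles
    literal_coverage_band: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_alt_fraction <= 1.0:
            raise ValueError("min_alt_fraction must lie in [0, 1]")
        if self.coverage_low_pct >= self.coverage_high_pct:
            raise ValueError("coverage_low_pct must be < coverage_high_pct")


def prune_variants(variants: list[HetVariant], cfg: PruneConfig | None = None) -> list[HetVariant]:
    """Drop unreliable het-SNP candidates before haplotyping.

    Kept variants have alternate-allele fraction >= 0.25, per-variant depth
    inside a two-tailed coverage band (10th-90th percentile by default) and
    call quality >= 13.  All cutoffs are boundary-inclusive.
    """
    cfg = cfg or PruneConfig()
    if not variants:
        return []
    depths = np.array([v.depth for v in variants], dtype=float)
    if cfg.literal_coverage_band:
        lo = cfg.coverage_low_pct / 100.0 * depths.mean()
        hi = cfg.coverage_high_pct / 100.0 * depths.mean()
    else:
        lo, hi = np.percentile(depths, [cfg.coverage_low_pct, cfg.coverage_high_pct])
    return [
        v for v in variants
        if v.alt_fraction >= cfg.min_alt_fraction
        and lo <= v.depth <= hi
        and v.qual >= cfg.min_qual
    ]


# ---------------------------------------------------------------------------
# parity model

class Parity(Enum):
    EVEN = "EVEN"
    ODD = "ODD"
    UNDETERMINED = "UNDETERMINED"


@dataclass(slots=True)
class ParityObservation:
    """Molecule counts over the four two-site keys for one het-SNP pair."""

    pair: tuple[int, int]
    n00: int = 0
    n01: int = 0
    n10: int = 0
    n11: int = 0
    mols: dict[tuple[int, int], list[int]] = field(default_factory=dict)

    @property
    def N(self) -> int:
        return self.n00 + self.n01 + self.n10 + self.n11

    @property
    def k(self) -> int:
        return self.n00 + self.n11


def key_parity_probability(p1: float, p2: float) -> float:
    """Probability p_c that an observed two-site key has the correct parity.

    The key keeps its parity when both allele calls are correct or both are
    wrong: p_c = p1*p2 + (1-p1)(1-p2).
    """
    return p1 * p2 + (1.0 - p1) * (1.0 - p2)


def parity_posterior(
    obs: ParityObservation,
    p1: float,
    p2: float,
    alpha: float = DEFAULT_ALPHA,
    literal: bool = False,
) -> Parity:
    """Decide even/odd parity for a het-SNP pair from molecule key counts.

    Under the even hypothesis the number of even keys k out of N is
    Binomial(N, p_c); under odd it is Binomial(N, 1-p_c).  With equal
    priors the posterior for even is

        p_c^k (1-p_c)^(N-k) / [p_c^k (1-p_c)^(N-k) + (1-p_c)^k p_c^(N-k)]

    (binomial coefficients cancel).  EVEN is returned when the posterior
    exceeds ``alpha``, ODD when its complement does, UNDETERMINED otherwise.

    ``literal=True`` instead evaluates the unnormalised Bayes quotient
    P(A|B)*P(B)/P(A) with P(B)=1 and P(A)=C(N,k)/2^N, which can exceed 1;
    the decision rule is the same threshold applied to that quantity for
    each hypothesis.
    """
    N, k = obs.N, obs.k
    if N == 0:
        return Parity.UNDETERMINED
    p_c = key_parity_probability(p1, p2)
    if literal:
        even_q = 2.0**N * p_c**k * (1.0 - p_c) ** (N - k)
        odd_q = 2.0**N * p_c ** (N - k) * (1.0 - p_c) ** k
        if even_q > alpha and even_q >= odd_q:
            return Parity.EVEN
        if odd_q > alpha and odd_q > even_q:
            return Parity.ODD
        return Parity.UNDETERMINED
    log_even = k * math.log(p_c) + (N - k) * math.log1p(-p_c)
    log_odd = (N - k) * math.log(p_c) + k * math.log1p(-p_c)
    posterior = 1.0 / (1.0 + math.exp(min(log_odd - log_even, 700.0)))
    if posterior > alpha:
        return Parity.EVEN
    if 1.0 - posterior > alpha:
        return Parity.ODD
    return Parity.UNDETERMINED


def collect_parity_observations(molecules: list[Molecule]) -> dict[tuple[int, int], ParityObservation]:
    """Count two-site keys for every pair of het sites adjacent on a molecule."""
    obs: dict[tuple[int, int], ParityObservation] = {}
    for m in molecules:
        vids = sorted(m.allele_calls)
        for vi, vj in zip(vids, vids[1:]):
            key = (m.allele_calls[vi][0], m.allele_calls[vj][0])
            o = obs.get((vi, vj))
            if o is None:
                o = obs[(vi, vj)] = ParityObservation(pair=(vi, vj))
            setattr(o, f"n{key[0]}{key[1]}", getattr(o, f"n{key[0]}{key[1]}") + 1)
            o.mols.setdefault(key, []).append(m.molecule_id)
    return obs


def per_variant_p(molecules: list[Molecule], floor: float = DEFAULT_P_FLOOR) -> dict[int, float]:
    """Mean allele-call correctness probability per variant, floored."""
    acc: dict[int, list[float]] = defaultdict(list)
    for m in molecules:
        for vid, (_, p) in m.allele_calls.items():
            acc[vid].append(p)
    return {vid: max(float(np.mean(ps)), floor) for vid, ps in acc.items()}


# ---------------------------------------------------------------------------
# recursive clustering

@dataclass(slots=True)
class HaplotypeClusterPair:
    """Two complementary molecule clusters spanning a set of phased variants.

    ``hap_a`` maps variant id -> allele carried by cluster A; cluster B
    carries the complement at every variant.
    """

    cluster_a: set[int]
    cluster_b: set[int]
    hap_a: dict[int, int]

    def anchor(self, var_pos: dict[int, int]) -> int:
        return min(var_pos[v] for v in self.hap_a) if self.hap_a else 0


def _seed_clusters(
    parity_obs: dict[tuple[int, int], ParityObservation],
    decisions: dict[tuple[int, int], Parity],
) -> list[HaplotypeClusterPair]:
    out = []
    for pair, o in parity_obs.items():
        d = decisions.get(pair, Parity.UNDETERMINED)
        if d is Parity.EVEN:
            a_keys, b_keys = [(0, 0)], [(1, 1)]
            hap_a = {pair[0]: 0, pair[1]: 0}
        elif d is Parity.ODD:
            a_keys, b_keys = [(0, 1)], [(1, 0)]
            hap_a = {pair[0]: 0, pair[1]: 1}
        else:
            continue
        a = {m for k in a_keys for m in o.mols.get(k, [])}
        b = {m for k in b_keys for m in o.mols.get(k, [])}
        if not a and not b:
            continue
        out.append(HaplotypeClusterPair(cluster_a=a, cluster_b=b, hap_a=hap_a))
    return out


def recursive_cluster(
    molecules: list[Molecule],
    parity_obs: dict[tuple[int, int], ParityObservation] | None = None,
    decisions: dict[tuple[int, int], Parity] | None = None,
    merge_support: int = DEFAULT_MERGE_SUPPORT,
    alpha: float = DEFAULT_ALPHA,
    var_pos: dict[int, int] | None = None,
) -> list[HaplotypeClusterPair]:
    """Merge seed cluster pairs to a fixed point.

    Two cluster pairs are merged when the number of molecules present in
    both and supporting the same haplotype reaches ``merge_support`` (3 by
    default); a molecule counts once per cluster pair however many variant
    pairs it supports.  Complementary clusters merge in lockstep, with the
    orientation chosen by the larger of the straight/crossed shared-molecule
    counts.  Merging repeats until no pair qualifies; the result does not
    depend on merge order for consistent data.
    """
    if parity_obs is None:
        parity_obs = collect_parity_observations(molecules)
    if decisions is None:
        pv = per_variant_p(molecules)
        decisions = {
            pair: parity_posterior(o, pv.get(pair[0], DEFAULT_P_FLOOR),
                                   pv.get(pair[1], DEFAULT_P_FLOOR), alpha=alpha)
            for pair, o in parity_obs.items()
        }
    clusters: dict[int, HaplotypeClusterPair] = dict(enumerate(_seed_clusters(parity_obs, decisions)))
    mol_to_cids: dict[int, set[int]] = defaultdict(set)
    for cid, c in clusters.items():
        for m in c.cluster_a | c.cluster_b:
            mol_to_cids[m].add(cid)

    def shared_counts(c1: HaplotypeClusterPair, c2: HaplotypeClusterPair) -> tuple[int, int]:
        straight = len(c1.cluster_a & c2.cluster_a) + len(c1.cluster_b & c2.cluster_b)
        crossed = len(c1.cluster_a & c2.cluster_b) + len(c1.cluster_b & c2.cluster_a)
        return straight, crossed

    changed = True
    while changed:
        changed = False
        # candidate pairs share at least one molecule
        pair_share: Counter[tuple[int, int]] = Counter()
        for cids in mol_to_cids.values():
            lst = sorted(cids)
            for i, a in enumerate(lst):
                for b in lst[i + 1 :]:
                    pair_share[(a, b)] += 1
        for (i, j), share in sorted(pair_share.items()):
            if share < merge_support or i not in clusters or j not in clusters:
                continue
            ci, cj = clusters[i], clusters[j]
            straight, crossed = shared_counts(ci, cj)
            if max(straight, crossed) < merge_support or straight == crossed:
                continue
            if crossed > straight:
                cj = HaplotypeClusterPair(cluster_a=cj.cluster_b, cluster_b=cj.cluster_a,
                                          hap_a={v: 1 - a for v, a in cj.hap_a.items()})
            new_a = ci.cluster_a | cj.cluster_a
            new_b = ci.cluster_b | cj.cluster_b
            both = new_a & new_b
            new_a -= both
            new_b -= both
            hap = dict(ci.hap_a)
            for v, a in cj.hap_a.items():
                if hap.setdefault(v, a) != a:
                    del hap[v]  # orientation conflict at this variant: drop it
            merged = HaplotypeClusterPair(cluster_a=new_a, cluster_b=new_b, hap_a=hap)
            clusters[i] = merged
            del clusters[j]
            for m, cids in mol_to_cids.items():
                if j in cids:
                    cids.discard(j)
                    if m in new_a or m in new_b:
                        cids.add(i)
            changed = True
    out = list(clusters.values())
    if var_pos:
        out.sort(key=lambda c: c.anchor(var_pos))
    return out


# ---------------------------------------------------------------------------
# phase blocks

@dataclass(slots=True)
class PhaseBlock:
    """Paired complementary haplotypes over a set of het variants.

    ``variants`` maps variant id -> allele on haplotype 1 (haplotype 2 is
    the complement); ``molecules`` maps molecule id -> haplotype in {1, 2}.
    ``block_id`` is the 1-based position of the leftmost phased variant.
    """

    block_id: int
    variants: dict[int, int]
    molecules: dict[int, int]
    span: tuple[int, int]

    @property
    def n_variants(self) -> int:
        return len(self.variants)


def build_phase_blocks(
    cluster_pairs: list[HaplotypeClusterPair],
    molecules: list[Molecule],
    var_pos: dict[int, int],
) -> list[PhaseBlock]:
    """Turn converged cluster pairs into phase blocks.

    A variant is phased in a block only when every assigned molecule that
    covers it agrees with the block haplotype; variants with conflicting
    support are excluded from further steps.
    """
    mol_by_id = {m.molecule_id: m for m in molecules}
    blocks: list[PhaseBlock] = []
    for cp in cluster_pairs:
        votes: dict[int, set[int]] = defaultdict(set)  # vid -> alleles implied on hap A
        for mid in cp.cluster_a:
            for vid, (allele, _) in mol_by_id[mid].allele_calls.items():
                votes[vid].add(allele)
        for mid in cp.cluster_b:
            for vid, (allele, _) in mol_by_id[mid].allele_calls.items():
                votes[vid].add(1 - allele)
        kept = {vid: next(iter(a)) for vid, a in votes.items() if len(a) == 1}
        if len(kept) < 2:
            continue
        positions = [var_pos[v] for v in kept]
        assignments = {mid: 1 for mid in cp.cluster_a}
        assignments.update({mid: 2 for mid in cp.cluster_b})
        blocks.append(PhaseBlock(
            block_id=min(positions),
            variants=kept,
            molecules=assignments,
            span=(min(positions), max(positions)),
        ))
    blocks.sort(key=lambda b: b.block_id)
    return blocks


class _OrientedUnionFind:
    """Union-find with a relative-orientation bit on each edge."""

    def __init__(self, n: int) -> None:
        self.parent = list(range(n))
        self.flip = [0] * n  # orientation relative to parent

    def find(self, x: int) -> tuple[int, int]:
        if self.parent[x] == x:
            return x, 0
        root, f = self.find(self.parent[x])
        self.parent[x] = root
        self.flip[x] ^= f
        return root, self.flip[x]

    def union(self, x: int, y: int, rel: int) -> None:
        rx, fx = self.find(x)
        ry, fy = self.find(y)
        if rx == ry:
            return
        self.parent[ry] = rx
        self.flip[ry] = fx ^ fy ^ rel


def extend_phase_blocks(
    blocks: list[PhaseBlock],
    overlap_support: int = DEFAULT_OVERLAP_SUPPORT,
    var_pos: dict[int, int] | None = None,
) -> list[PhaseBlock]:
    """Merge phase blocks that share enough consistently oriented variants.

    Two blocks merge when they overlap in at least ``overlap_support``
    variants (5 by default, bounding the merge error by p^5 for per-variant
    error p) and all shared variants agree on the same relative haplotype
    orientation.  Transitive merging is resolved with union-find, so the
    result is the fixed point regardless of order.
    """
    n = len(blocks)
    uf = _OrientedUnionFind(n)
    by_vid: dict[int, list[int]] = defaultdict(list)
    for i, b in enumerate(blocks):
        for vid in b.variants:
            by_vid[vid].append(i)
    pair_shared: dict[tuple[int, int], list[int]] = defaultdict(list)
    for vid, idxs in by_vid.items():
        for ii, i in enumerate(idxs):
            for j in idxs[ii + 1 :]:
                pair_shared[(min(i, j), max(i, j))].append(vid)
    for (i, j), vids in sorted(pair_shared.items()):
        if len(vids) < overlap_support:
            continue
        rels = {blocks[i].variants[v] ^ blocks[j].variants[v] for v in vids}
        if len(rels) != 1:
            continue  # inconsistent relative orientation
        uf.union(i, j, rels.pop())
    groups: dict[int, list[tuple[int, int]]] = defaultdict(list)
    for i in range(n):
        root, f = uf.find(i)
        groups[root].append((i, f))
    merged: list[PhaseBlock] = []
    for members in groups.values():
        variants: dict[int, int] = {}
        mols: dict[int, int] = {}
        spans: list[int] = []
        ok = True
        for i, f in members:
            b = blocks[i]
            for vid, a in b.variants.items():
                a2 = a ^ f
                if variants.setdefault(vid, a2) != a2:
                    del variants[vid]
            for mid, hp in b.molecules.items():
                mols[mid] = hp if f == 0 else 3 - hp
            spans.extend(b.span)
        if ok and variants:
            merged.append(PhaseBlock(
                block_id=min(spans),
                variants=variants,
                molecules=mols,
                span=(min(spans), max(spans)),
            ))
    # Make blocks disjoint in variant membership: sparse read coverage leaves
    # small redundant cluster pairs whose variants a larger block already
    # phases; larger blocks claim their variants first and remnants that no
    # longer phase at least two variants of their own are dropped.
    merged.sort(key=lambda b: (-b.n_variants, b.block_id))
    claimed: set[int] = set()
    final: list[PhaseBlock] = []
    for b in merged:
        fresh = {vid: a for vid, a in b.variants.items() if vid not in claimed}
        if len(fresh) < 2:
            continue
        claimed.update(fresh)
        b.variants = fresh
        if var_pos is not None:
            positions = [var_pos[v] for v in fresh]
            b.block_id = min(positions)
            b.span = (min(positions), max(positions))
        final.append(b)
    merged = final
    merged.sort(key=lambda b: b.block_id)
    return merged


# ---------------------------------------------------------------------------
# molecule assignment (maximum likelihood)

def molecule_likelihood(m: Molecule, hap_alleles: dict[int, int]) -> tuple[float, float]:
    """Likelihood of the molecule's calls under a haplotype and its complement.

    L(M | H) = prod_i [ theta(H_i, M_i) p_i + (1 - theta(H_i, M_i)) (1 - p_i) ]
    where theta is 1 when the molecule allele matches the haplotype allele
    and p_i is the per-call correctness probability.
    """
    like = like_c = 1.0
    for vid, (allele, p) in m.allele_calls.items():
        if vid not in hap_alleles:
            continue
        if hap_alleles[vid] == allele:
            like *= p
            like_c *= 1.0 - p
        else:
            like *= 1.0 - p
            like_c *= p
    return like, like_c


def assign_molecule(
    m: Molecule,
    blocks: list[PhaseBlock],
    tie_margin: float = ASSIGN_TIE_MARGIN,
) -> tuple[int, int, float] | None:
    """Assign a molecule to (block_id, haplotype) by maximum likelihood.

    Returns None (unassigned) for molecules with fewer than two het allele
    calls, with no informative block overlap, or with a likelihood margin
    below ``tie_margin``.
    """
    if len(m.allele_calls) < 2:
        return None
    best: tuple[float, int, int] | None = None
    for b in blocks:
        shared = m.allele_calls.keys() & b.variants.keys()
        if len(shared) < 2:
            continue
        like, like_c = molecule_likelihood(m, b.variants)
        score = like - like_c
        cand = (abs(score), b.block_id, 1 if score > 0 else 2)
        if best is None or cand[0] > best[0]:
            best = cand
    if best is None or best[0] < tie_margin:
        return None
    return best[1], best[2], best[0]


def assign_all_molecules(molecules: list[Molecule], blocks: list[PhaseBlock]) -> dict[int, tuple[int, int]]:
    """Map molecule id -> (block_id, haplotype) for assignable molecules."""
    out: dict[int, tuple[int, int]] = {}
    for m in molecules:
        res = assign_molecule(m, blocks)
        if res is not None:
            out[m.molecule_id] = (res[0], res[1])
    return out


# ---------------------------------------------------------------------------
# evaluation against truth

def evaluate_phasing(
    blocks: list[PhaseBlock],
    truth_phase: dict[int, int],
    var_pos: dict[int, int],
) -> dict[str, int | float]:
    """Compare predicted blocks with the truth haplotype of origin.

    After per-block orientation (hp1/hp2 labels are arbitrary), a run of
    exactly one disagreeing variant counts as a mismatch error (an isolated
    flip, i.e. two adjacent switches) and a run of two or more consecutive
    disagreeing variants counts as one long-switch error.
    """
    mismatch = long_switch = phased = 0
    spans: list[int] = []
    for b in blocks:
        vids = sorted((v for v in b.variants if v in truth_phase), key=lambda v: var_pos[v])
        if len(vids) < 2:
            continue
        phased += len(vids)
        spans.append(b.span[1] - b.span[0] + 1)
        pred = np.array([b.variants[v] for v in vids], dtype=bool)
        tru = np.array([truth_phase[v] == 1 for v in vids], dtype=bool)
        d = pred != tru
        if d.sum() * 2 > len(d):
            d = ~d
        run = 0
        for x in list(d) + [False]:
            if x:
                run += 1
            elif run:
                if run == 1:
                    mismatch += 1
                else:
                    long_switch += 1
                run = 0
    spans.sort(reverse=True)
    n50 = 0
    if spans:
        half = sum(spans) / 2.0
        acc = 0
        for s in spans:
            acc += s
            if acc >= half:
                n50 = s
                break
    return {
        "phased_count": phased,
        "mismatch_errors": mismatch,
        "long_switch_errors": long_switch,
        "block_N50": n50,
        "max_block": spans[0] if spans else 0,
    }


def phase_molecules(
    molecules: list[Molecule],
    het_variants: list[HetVariant],
    prune_cfg: PruneConfig | None = None,
    merge_support: int = DEFAULT_MERGE_SUPPORT,
    overlap_support: int = DEFAULT_OVERLAP_SUPPORT,
    alpha: float = DEFAULT_ALPHA,
) -> tuple[list[PhaseBlock], dict[int, tuple[int, int]], list[HetVariant]]:
    """Full haplotyping stage: prune, cluster, build/extend blocks, assign.

    Returns (phase blocks, molecule assignments, pruned variant list).
    """
    kept = prune_variants(het_variants, prune_cfg)
    keep_ids = {v.variant_id for v in kept}
    for m in molecules:
        m.allele_calls = {vid: c for vid, c in m.allele_calls.items() if vid in keep_ids}
    var_pos = {v.variant_id: v.pos for v in kept}
    clusters = recursive_cluster(molecules, merge_support=merge_support, alpha=alpha,
                                 var_pos=var_pos)
    blocks = build_phase_blocks(clusters, molecules, var_pos)
    blocks = extend_phase_blocks(blocks, overlap_support=overlap_support, var_pos=var_pos)
    assignments = assign_all_molecules(molecules, blocks)
    return blocks, assignments, kept
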