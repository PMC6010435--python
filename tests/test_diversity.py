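import itertools

import numpy as np
import pytest

from steppekin import diversity as dv, synthetic_data as sd
from steppekin.io_formats import MISSING, GeneticMap, GenotypeTable, SnpMeta


def _table(calls, chrom=None):
    calls = np.asarray(calls, dtype=np.int8)
    snps = [
        SnpMeta(f"s{j}", chrom[j] if chrom else 1, 1000 * (j + 1), 0.01 * j,
                ("A", "G"), freq_alt=0.5)
        for j in range(calls.shape[1])
    ]
    return GenotypeTable([f"i{k}" for k in range(calls.shape[0])], snps, calls)


def _asd_oracle(g1, g2):
    """Explicit per-site allele-sharing count."""
    shared = sites = 0
    for a, b in zip(g1, g2):
        if a == MISSING or b == MISSING:
            continue
        shared += 2 - abs(a - b)
        sites += 1
    return 1.0 - shared / (2 * sites)


def test_asd_identity_and_extremes():
    t = _table([[0, 1, 2, 1], [0, 1, 2, 1], [2, 1, 0, 1]])
    m = dv.asd_matrix(t)
    assert m.pair("i0", "i1") == 0.0
    t2 = _table([[0, 0, 0], [2, 2, 2]])
    assert dv.asd_matrix(t2).pair("i0", "i1") == 1.0


def test_asd_matches_counting_oracle():
    rng = np.random.default_rng(0)
    calls = rng.integers(0, 3, size=(10, 50)).astype(np.int8)
    calls[rng.random(calls.shape) < 0.05] = MISSING
    t = _table(calls)
    m = dv.asd_matrix(t)
    for i, j in itertools.combinations(range(10), 2):
        assert m.values[i, j] == pytest.approx(
            _asd_oracle(calls[i], calls[j]), abs=1e-12
        )
        assert m.values[i, j] == m.values[j, i]
    assert np.all(np.diag(m.values) == 0)


def test_kinship_parent_offspring_and_unrelated(small_panel):
    snps, _, _ = small_panel
    haps = sd.simulate_founders(400, snps, seed=9)
    # 50 parent-offspring pairs (one shared haplotype) + 50 unrelated pairs
    rows, po_pairs, un_pairs = [], [], []
    k = 0
    for p in range(50):
        parent = haps[4 * p] + haps[4 * p + 1]
        child = haps[4 * p] + haps[4 * p + 2]
        other = haps[4 * p + 3] + haps[(4 * p + 7) % 400]
        rows += [parent, child, other]
        po_pairs.append((k, k + 1))
        un_pairs.append((k, k + 2))
        k += 3
    t = _table(np.array(rows, dtype=np.int8))
    freqs = np.array([s.freq_alt for s in snps])
    phi = dv.pairwise_kinship(t, freqs=freqs)
    po = np.mean([phi[i, j] for i, j in po_pairs])
    un = np.mean([phi[i, j] for i, j in un_pairs])
    assert po == pytest.approx(0.25, abs=0.03)
    assert un == pytest.approx(0.0, abs=0.03)
    np.testing.assert_allclose(phi, phi.T)


def test_exclude_relatives_rules():
    samples = ["a", "b", "c", "d"]
    phi = np.zeros((4, 4))
    assert dv.exclude_relatives(phi, samples) == samples  # nothing to do

    phi2 = np.zeros((4, 4))
    phi2[0, 1] = phi2[1, 0] = 0.25  # one sib pair
    kept = dv.exclude_relatives(phi2, samples)
    assert len(kept) == 3 and ("a" in kept) != ("b" in kept)

    # mutual trio: removing the hub ('a', tie-broken by id) suffices
    phi3 = np.zeros((4, 4))
    for i, j in [(0, 1), (0, 2), (1, 2)]:
        phi3[i, j] = phi3[j, i] = 0.3
    kept = dv.exclude_relatives(phi3, samples)
    # exhaustive check on n=3: at least two of the trio must go
    best = None
    for r in range(4):
        for drop in itertools.combinations(range(3), r):
            keep = [i for i in range(4) if i not in drop]
            if all(phi3[i, j] <= 1 / 16 + 0.02
                   for i, j in itertools.combinations(keep, 2)):
                best = r
                break
        if best is not None:
            break
    assert len(kept) == 4 - best
    for a, b in itertools.combinations(kept, 2):
        i, j = samples.index(a), samples.index(b)
        assert phi3[i, j] <= 1 / 16 + 0.02


def test_exclude_relatives_postcondition_random():
    rng = np.random.default_rng(1)
    samples = [f"i{k}" for k in range(12)]
    phi = np.zeros((12, 12))
    for i, j in itertools.combinations(range(12), 2):
        if rng.random() < 0.15:
            phi[i, j] = phi[j, i] = rng.uniform(0.1, 0.4)
    kept = dv.exclude_relatives(phi, samples)
    for a, b in itertools.combinations(kept, 2):
        assert phi[samples.index(a), samples.index(b)] <= 1 / 16 + 0.02


def _map_with_rates(rates, spacing_bp=100_000):
    gm = GeneticMap()
    bp = np.arange(1, len(rates) * spacing_bp, spacing_bp)[: len(rates)]
    cm = np.concatenate([[0], np.cumsum(rates[:-1] * spacing_bp / 1e6)])
    gm.add_chrom(1, bp, cm, np.asarray(rates, dtype=float))
    return gm, bp


def test_low_recombination_blocks_construction():
    # 30 SNPs; rates high except a planted low-rate stretch at SNPs 10..19
    rates = np.full(30, 2.0)
    rates[10:20] = 0.1
    gm, bp = _map_with_rates(rates)
    calls = np.zeros((2, 30), dtype=np.int8)
    snps = [SnpMeta(f"s{j}", 1, int(bp[j]), float(j) * 0.01, ("A", "G"))
            for j in range(30)]
    t = GenotypeTable(["x", "y"], snps, calls)
    blocks = dv.low_recombination_blocks(t, gm, rate_cutoff=0.5, min_snps=5)
    assert len(blocks) == 1
    chrom, s_bp, e_bp, run = blocks[0]
    assert (run == np.arange(10, 20)).all()

    # uniform rate above the cutoff -> no blocks
    gm2, _ = _map_with_rates(np.full(30, 2.0))
    assert dv.low_recombination_blocks(t, gm2) == []


def test_low_recombination_blocks_match_scan_oracle():
    rng = np.random.default_rng(2)
    rates = rng.choice([0.1, 2.0], size=60, p=[0.4, 0.6])
    gm, bp = _map_with_rates(rates)
    snps = [SnpMeta(f"s{j}", 1, int(bp[j]), float(j) * 0.01, ("A", "G"))
            for j in range(60)]
    t = GenotypeTable(["x"], snps, np.zeros((1, 60), dtype=np.int8))
    blocks = dv.low_recombination_blocks(t, gm, rate_cutoff=0.5, min_snps=3)
    # O(n) oracle: maximal runs of low-rate SNPs
    low = rates < 0.5
    runs, start = [], None
    for k in range(61):
        if k < 60 and low[k]:
            start = k if start is None else start
        elif start is not None:
            if k - start >= 3:
                runs.append((start, k - 1))
            start = None
    assert [(r[0], r[-1]) for _, _, _, r in [
        (c, s, e, run) for c, s, e, run in blocks]] == runs


def test_block_heterozygosity_closed_forms():
    blocks = [(1, 1, 1000, np.arange(4))]
    same = np.zeros((6, 2, 4), dtype=np.int8)
    prof = dv.block_haplotype_heterozygosity(same, blocks)
    assert prof.mean_het == 0.0

    # two equi-frequent haplotypes among n=12 chromosomes
    haps = np.zeros((6, 2, 4), dtype=np.int8)
    haps[:, 1, :] = 1
    prof = dv.block_haplotype_heterozygosity(haps, blocks)
    n = 12
    assert prof.mean_het == pytest.approx(0.5 * n / (n - 1))


def test_heterozygosity_monotone_in_founder_diversity(small_panel):
    """More diverse founders -> higher block haplotype heterozygosity."""
    from dataclasses import replace

    snps, _, cl = small_panel
    blocks = [(1, 1, 10**9, np.flatnonzero(
        np.array([s.chrom for s in snps]) == 1)[:8])]
    hets = {}
    for label, rng_freq in [("low", (0.02, 0.10)), ("high", (0.35, 0.65))]:
        rng = np.random.default_rng(4)
        snps2 = [replace(s, freq_alt=float(rng.uniform(*rng_freq)))
                 for s in snps]
        haps = sd.simulate_founders(40, snps2, seed=5).reshape(20, 2, -1)
        hets[label] = dv.block_haplotype_heterozygosity(haps, blocks).mean_het
    assert hets["high"] > hets["low"]
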