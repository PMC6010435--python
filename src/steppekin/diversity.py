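"""Population genetic diversity: allele-sharing dissimilarity, kinship-based
relative exclusion, and haplotypic heterozygosity over low-recombination
blocks.

The block statistic needs phase; it is defined here on simulator-provided
haplotypes (real-data phasing is out of scope), which is sufficient to study
the statistic itself — notably its robustness to SNP ascertainment relative
to site-by-site measures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import MISSING, GeneticMap, GenotypeTable


@dataclass
class AsdMatrix:
    samples: list[str]
    values: np.ndarray  # symmetric, [0,1], diag 0; NaN where no shared sites

    def pair(self, a: str, b: str) -> float:
        i, j = self.samples.index(a), self.samples.index(b)
        return float(self.values[i, j])


@dataclass
class HetProfile:
    population: str
    per_autosome: dict[int, float]
    mean_het: float
    blocks: list[tuple[int, int, int]] = field(default_factory=list)  # chrom, start_bp, end_bp


def asd_matrix(table: GenotypeTable) -> AsdMatrix:
    """Allele-sharing dissimilarity between all sample pairs.

    Per site, two dosage calls g1, g2 share ``2 - |g1 - g2|`` of their 2x2
    alleles; ASD is 1 minus the shared fraction over pairwise-complete sites.
    A pair with no overlapping non-missing site gets NaN.
    """
    if table.n_samples < 2:
        raise ValueError("ASD needs at least 2 samples")
    g = table.calls.astype(np.float64)
    obs = table.calls != MISSING
    g[~obs] = 0.0
    n = table.n_samples
    vals = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(g[i] - g)  # (n, m)
        both = obs[i] & obs
        shared = np.where(both, 2.0 - diff, 0.0).sum(axis=1)
        cnt = both.sum(axis=1)
        with np.errstate(invalid="ignore"):
            vals[i] = 1.0 - shared / (2.0 * cnt)
        vals[i, cnt == 0] = np.nan
    np.fill_diagonal(vals, 0.0)
    return AsdMatrix(samples=list(table.samples), values=vals)


def pairwise_kinship(table: GenotypeTable, freqs: np.ndarray | None = None) -> np.ndarray:
    """Method-of-moments kinship estimates from dosages.

    Standard genomic-relationship estimator with the supplied (or observed)
    allele frequencies: phi_ij = mean_m (g_im - 2p_m)(g_jm - 2p_m) / (4 p_m q_m)
    over pairwise-complete polymorphic sites. Parent-offspring pairs are
    expected near 0.25, unrelated pairs near 0.
    """
    if freqs is None:
        freqs = table.alt_freqs()
    p = np.asarray(freqs, dtype=float)
    poly = (p > 0.01) & (p < 0.99)
    g = table.calls.astype(np.float64)
    obs = (table.calls != MISSING) & poly
    centred = np.where(obs, g - 2 * p, 0.0)
    denom_site = 4 * p * (1 - p)
    n = table.n_samples
    phi = np.zeros((n, n))
    for i in range(n):
        num = (centred[i] * centred * np.where(obs[i] & obs, 1.0, 0.0) / np.where(
            denom_site > 0, denom_site, 1.0)).sum(axis=1)
        cnt = (obs[i] & obs).sum(axis=1)
        with np.errstate(invalid="ignore"):
            # normalising by 4pq makes the expectation the kinship phi itself
            phi[i] = num / np.maximum(cnt, 1)
        phi[i, cnt == 0] = np.nan
    phi = (phi + phi.T) / 2.0
    return phi


def exclude_relatives(
    kinship: np.ndarray, samples: list[str], threshold_phi: float = 1.0 / 16.0,
    tolerance: float = 0.02,
) -> list[str]:
    """Greedy removal of close relatives (phi > threshold + tolerance).

    At each step the individual with the most over-threshold partners is
    removed (ties broken by sample-id order) until no pair remains over the
    threshold. The default keeps first-cousin pairs (phi = 1/16) and drops
    anything closer.
    """
    limit = threshold_phi + tolerance
    keep = list(range(len(samples)))
    while True:
        over = {
            i: sum(
                1 for j in keep if j != i and np.isfinite(kinship[i, j])
                and kinship[i, j] > limit
            )
            for i in keep
        }
        worst = max(over.values(), default=0)
        if worst == 0:
            break
        cands = sorted((i for i, c in over.items() if c == worst),
                       key=lambda i: samples[i])
        keep.remove(cands[0])
    return [samples[i] for i in keep]


def low_recombination_blocks(
    table: GenotypeTable, gmap: GeneticMap,
    rate_cutoff: float = 0.5, min_snps: int = 5,
) -> list[tuple[int, int, int, np.ndarray]]:
    """Maximal runs of consecutive SNPs in low-recombination regions.

    A SNP qualifies when the local map rate at its position is strictly below
    ``rate_cutoff`` (cM/Mb); runs shorter than ``min_snps`` are dropped.
    Returns ``(chrom, start_bp, end_bp, snp_indices)`` per block, with
    1-based closed physical intervals.
    """
    blocks = []
    for chrom in table.chromosomes():
        idx = table.chrom_indices(chrom)
        pos = np.array([table.snps[j].pos_bp for j in idx])
        low = np.asarray(gmap.rate_at(chrom, pos)) < rate_cutoff
        start = None
        for k in range(len(idx) + 1):
            inside = k < len(idx) and low[k]
            if inside and start is None:
                start = k
            elif not inside and start is not None:
                run = idx[start:k]
                if len(run) >= min_snps:
                    blocks.append(
                        (chrom, int(pos[start]), int(pos[k - 1]), run)
                    )
                start = None
    return blocks


def block_haplotype_heterozygosity(
    haplotypes: np.ndarray,
    blocks: list[tuple[int, int, int, np.ndarray]],
    population: str = "",
) -> HetProfile:
    """Unbiased haplotype heterozygosity averaged over blocks per autosome.

    ``haplotypes``: (n_samples, 2, n_snps) phased 0/1 alleles of one
    population. Per block, distinct multi-SNP haplotypes across the 2n
    chromosomes get frequencies p_h and H = n/(n-1) * (1 - sum p_h^2); the
    profile averages H per autosome, then across autosomes. Blocks with
    fewer than two haplotypes are skipped.
    """
    n_hap = haplotypes.shape[0] * 2
    flat = haplotypes.reshape(n_hap, -1)
    per_chrom: dict[int, list[float]] = {}
    kept: list[tuple[int, int, int]] = []
    for chrom, s_bp, e_bp, run in blocks:
        if n_hap < 2:
            continue
        sub = flat[:, run]
        _, counts = np.unique(sub, axis=0, return_counts=True)
        p = counts / n_hap
        h = n_hap / (n_hap - 1) * (1.0 - float((p**2).sum()))
        per_chrom.setdefault(chrom, []).append(h)
        kept.append((chrom, s_bp, e_bp))
    per_autosome = {c: float(np.mean(v)) for c, v in per_chrom.items()}
    mean_het = float(np.mean(list(per_autosome.values()))) if per_autosome else float("nan")
    return HetProfile(
        population=population, per_autosome=per_autosome,
        mean_het=mean_het, blocks=kept,
    )
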