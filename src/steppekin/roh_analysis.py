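"""Runs of homozygosity: sliding-window calling, fixed-threshold and
per-population mixture-based length classification, and the excess-of-
homozygosity statistic.

ROH calling follows the widely used sliding-window scan of array genotypes
(window of consecutive SNPs allowing a small number of heterozygous/missing
calls; a SNP is inside a ROH when enough of the windows covering it pass;
maximal qualifying runs are then filtered by SNP count, physical length,
SNP density and maximum gap). All parameters are exposed because sensible
values scale with array density.

Length classes: the fixed literature thresholds call 500-1,500 kb
"intermediate" and > 1,500 kb "long"; the model-based alternative fits a
three-component Gaussian mixture to log10 segment lengths per population and
cuts classes A/B/C where adjacent weighted component densities intersect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .io_formats import MISSING, GenotypeTable


@dataclass
class RohParams:
    """Scanner parameters (defaults sized for dense genome-wide arrays)."""

    window_snp: int = 50
    window_het: int = 1
    window_missing: int = 5
    hit_threshold: float = 0.05
    min_snp: int = 50
    min_kb: float = 500.0
    density_kb_per_snp: float = 50.0
    max_gap_kb: float = 1000.0


@dataclass
class RohSegment:
    sample_id: str
    chrom: int
    start_bp: int
    end_bp: int
    n_snps: int
    n_het_allowed_used: int = 0

    def __post_init__(self) -> None:
        if self.end_bp < self.start_bp:
            raise ValueError("end_bp < start_bp")

    @property
    def length_kb(self) -> float:
        return (self.end_bp - self.start_bp + 1) / 1000.0


@dataclass
class RohClassBoundaries:
    population: str
    boundary_AB_kb: float
    boundary_BC_kb: float
    weights: np.ndarray
    means_log10kb: np.ndarray
    sds_log10kb: np.ndarray
    n_components: int = 3
    loglik_trace: np.ndarray = field(default_factory=lambda: np.array([]))
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not self.boundary_AB_kb < self.boundary_BC_kb:
            raise ValueError("class boundaries must be strictly ordered")


@dataclass
class RohSummary:
    sample_id: str
    counts: dict[str, int]
    total_kb: dict[str, float]


# ---------------------------------------------------------------------------
# Calling


def call_rohs(
    table: GenotypeTable, params: Optional[RohParams] = None
) -> list[RohSegment]:
    """Sliding-window ROH scan over every sample and autosome."""
    params = params or RohParams()
    segments: list[RohSegment] = []
    pos_all = np.array([s.pos_bp for s in table.snps], dtype=np.int64)
    for chrom in table.chromosomes():
        idx = table.chrom_indices(chrom)
        pos = pos_all[idx]
        for i, sid in enumerate(table.samples):
            calls = table.calls[i, idx]
            segments.extend(_scan_one(sid, chrom, pos, calls, params))
    return segments


def _scan_one(
    sample_id: str, chrom: int, pos: np.ndarray, calls: np.ndarray, p: RohParams
) -> list[RohSegment]:
    m = len(pos)
    w = p.window_snp
    het = (calls == 1).astype(np.int32)
    mis = (calls == MISSING).astype(np.int32)
    in_roh = np.zeros(m, dtype=bool)
    if m >= w:
        ch = np.concatenate([[0], np.cumsum(het)])
        cm_ = np.concatenate([[0], np.cumsum(mis)])
        n_win = m - w + 1
        win_ok = (
            (ch[w:] - ch[:-w] <= p.window_het)
            & (cm_[w:] - cm_[:-w] <= p.window_missing)
        ).astype(np.int32)
        cw = np.concatenate([[0], np.cumsum(win_ok)])
        for j in range(m):
            lo = max(0, j - w + 1)
            hi = min(j, n_win - 1)
            if hi < lo:
                continue
            hits = cw[hi + 1] - cw[lo]
            if hits / (hi - lo + 1) > p.hit_threshold:
                in_roh[j] = True

    out: list[RohSegment] = []
    j = 0
    while j < m:
        if not in_roh[j]:
            j += 1
            continue
        k = j
        while (
            k + 1 < m
            and in_roh[k + 1]
            and (pos[k + 1] - pos[k]) <= p.max_gap_kb * 1000.0
        ):
            k += 1
        run = slice(j, k + 1)
        n_snps = k - j + 1
        length_kb = (pos[k] - pos[j] + 1) / 1000.0
        if (
            n_snps >= p.min_snp
            and length_kb >= p.min_kb
            and n_snps >= length_kb / p.density_kb_per_snp
        ):
            out.append(
                RohSegment(
                    sample_id=sample_id,
                    chrom=chrom,
                    start_bp=int(pos[j]),
                    end_bp=int(pos[k]),
                    n_snps=n_snps,
                    n_het_allowed_used=int(het[run].sum()),
                )
            )
        j = k + 1
    return out


# ---------------------------------------------------------------------------
# Classification


def _summarise(
    segments: Sequence[RohSegment], assign, classes: Sequence[str]
) -> dict[str, RohSummary]:
    out: dict[str, RohSummary] = {}
    for seg in segments:
        if seg.sample_id not in out:
            out[seg.sample_id] = RohSummary(
                sample_id=seg.sample_id,
                counts={c: 0 for c in classes},
                total_kb={c: 0.0 for c in classes},
            )
        cls = assign(seg.length_kb)
        if cls is None:
            continue
        out[seg.sample_id].counts[cls] += 1
        out[seg.sample_id].total_kb[cls] += seg.length_kb
    return out


def classify_fixed(segments: Sequence[RohSegment]) -> dict[str, RohSummary]:
    """Fixed literature classes: intermediate [500, 1500] kb, long > 1500 kb."""

    def assign(kb: float):
        if 500.0 <= kb <= 1500.0:
            return "intermediate"
        if kb > 1500.0:
            return "long"
        return None

    return _summarise(segments, assign, ["intermediate", "long"])


def classify_population(
    segments: Sequence[RohSegment], boundaries: RohClassBoundaries
) -> dict[str, RohSummary]:
    """Population-specific classes: A < AB-boundary <= B < BC-boundary <= C
    (a segment exactly at a boundary joins the upper class)."""

    def assign(kb: float):
        if kb < boundaries.boundary_AB_kb:
            return "A"
        if kb < boundaries.boundary_BC_kb:
            return "B"
        return "C"

    return _summarise(segments, assign, ["A", "B", "C"])


# ---------------------------------------------------------------------------
# Mixture fit


def _em_1d(
    x: np.ndarray, k: int, rng: np.random.Generator, tol: float = 1e-6,
    max_iter: int = 500,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """EM for a k-component 1D Gaussian mixture with unequal variances.

    Returns (weights, means, sds, loglik_trace); the trace is non-decreasing
    by construction of EM.
    """
    n = len(x)
    q = np.quantile(x, np.linspace(0.1, 0.9, k))
    mu = q + rng.normal(0, 0.05 * (x.std() + 1e-9), size=k)
    sd = np.full(k, max(x.std() / k, 1e-3))
    w = np.full(k, 1.0 / k)
    trace = []
    prev = -np.inf
    for _ in range(max_iter):
        dens = (
            w
            / (sd * math.sqrt(2 * math.pi))
            * np.exp(-0.5 * ((x[:, None] - mu) / sd) ** 2)
        )
        tot = dens.sum(axis=1)
        tot = np.maximum(tot, 1e-300)
        ll = float(np.log(tot).sum())
        trace.append(ll)
        r = dens / tot[:, None]
        nk = r.sum(axis=0)
        w = nk / n
        mu = (r * x[:, None]).sum(axis=0) / np.maximum(nk, 1e-12)
        var = (r * (x[:, None] - mu) ** 2).sum(axis=0) / np.maximum(nk, 1e-12)
        sd = np.sqrt(np.maximum(var, 1e-6))
        if ll - prev < tol and np.isfinite(prev):
            break
        prev = ll
    return w, mu, sd, np.array(trace)


def _component_intersection(
    w1: float, m1: float, s1: float, w2: float, m2: float, s2: float,
    tol_log10: float = 1e-5,
) -> float:
    """Bisection for the point between two component means where their
    weighted normal densities are equal."""

    def diff(x):
        d1 = w1 / s1 * math.exp(-0.5 * ((x - m1) / s1) ** 2)
        d2 = w2 / s2 * math.exp(-0.5 * ((x - m2) / s2) ** 2)
        return d1 - d2

    lo, hi = m1, m2
    flo = diff(lo)
    if flo <= 0 or diff(hi) >= 0:
        return 0.5 * (m1 + m2)  # densities do not cross between means
    while hi - lo > tol_log10:
        mid = 0.5 * (lo + hi)
        if diff(mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def fit_length_mixture(
    segments: Sequence[RohSegment],
    population: str = "",
    n_components: int = 3,
    n_restarts: int = 10,
    seed: int = 0,
    min_segments: int = 50,
) -> RohClassBoundaries:
    """Three-component Gaussian mixture of log10 segment lengths (kb).

    Best of ``n_restarts`` seeded EM runs; class boundaries are the
    intersections of adjacent (mean-ranked) weighted component densities.
    If any component degenerates (weight < 0.01) the fit is redone with two
    components and flagged.
    """
    lengths = np.array([s.length_kb for s in segments], dtype=float)
    if len(lengths) < min_segments:
        raise ValueError(
            f"need >= {min_segments} segments for a mixture fit, got {len(lengths)}"
        )
    x = np.log10(lengths)

    def best_fit(k: int):
        rng = np.random.default_rng(seed)
        best = None
        for _ in range(n_restarts):
            w, mu, sd, trace = _em_1d(x, k, rng)
            if best is None or trace[-1] > best[3][-1]:
                best = (w, mu, sd, trace)
        return best

    k = n_components
    w, mu, sd, trace = best_fit(k)
    degenerate = bool(np.any(w < 0.01))
    if degenerate and k == 3:
        k = 2
        w, mu, sd, trace = best_fit(k)
    order = np.argsort(mu)
    w, mu, sd = w[order], mu[order], sd[order]
    cuts = [
        _component_intersection(w[i], mu[i], sd[i], w[i + 1], mu[i + 1], sd[i + 1])
        for i in range(k - 1)
    ]
    if k == 2:
        b_ab, b_bc = cuts[0], cuts[0] + 1e-6
    else:
        b_ab, b_bc = cuts
    if not b_ab < b_bc:  # overlapping components: fall back to mean midpoints
        b_ab = 0.5 * (mu[0] + mu[1])
        b_bc = 0.5 * (mu[1] + mu[2]) if k == 3 else b_ab + 1e-6
    return RohClassBoundaries(
        population=population,
        boundary_AB_kb=float(10.0**b_ab),
        boundary_BC_kb=float(10.0**b_bc),
        weights=w,
        means_log10kb=mu,
        sds_log10kb=sd,
        n_components=k,
        loglik_trace=trace,
        degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# Excess homozygosity


def excess_homozygosity(
    table: GenotypeTable,
    sample_ids: Optional[Sequence[str]] = None,
    freqs: Optional[np.ndarray] = None,
) -> dict[str, float]:
    """Observed minus expected homozygote fraction per individual.

    Expectation is the within-population panmictic baseline with the
    small-sample correction: E_hom = sum_i (1 - 2 p_i (1-p_i) n_i/(n_i-1))
    over the individual's non-missing sites, with n_i the allele count at
    site i. Negative values mean fewer homozygotes than expected under
    random mating; inbred individuals trend positive.
    """
    ids = list(sample_ids) if sample_ids is not None else list(table.samples)
    rows = [table.sample_index(s) for s in ids]
    calls = table.calls[rows]
    obs = calls != MISSING
    if freqs is None:
        p = table.alt_freqs(rows)
    else:
        p = np.asarray(freqs, dtype=float)
    n_alleles = 2 * (calls != MISSING).sum(axis=0)
    corr = np.where(n_alleles > 1, n_alleles / np.maximum(n_alleles - 1, 1), 1.0)
    with np.errstate(invalid="ignore"):
        e_site = 1.0 - 2.0 * p * (1.0 - p) * corr
    e_site = np.nan_to_num(e_site, nan=1.0)
    out: dict[str, float] = {}
    for r, sid in enumerate(ids):
        mask = obs[r]
        n = int(mask.sum())
        if n == 0:
            out[sid] = math.nan
            continue
        o_hom = int(((calls[r] == 0) | (calls[r] == 2))[mask].sum())
        e_hom = float(e_site[mask].sum())
        out[sid] = (o_hom - e_hom) / n
    return out
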