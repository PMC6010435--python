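"""Per-individual inbreeding from a two-state IBD hidden Markov model.

The genome of an inbred individual alternates between autozygous (IBD) and
non-autozygous tracts. Marker by marker, the model has hidden states
{nonIBD, IBD} with stationary P(IBD) = f (the inbreeding coefficient) and a
distance-driven transition over d cM:

    P(IBD -> IBD)    = exp(-a d) + (1 - exp(-a d)) f
    P(nonIBD -> IBD) = (1 - exp(-a d)) f

so ``a`` (per cM) governs IBD segment turnover — smaller ``a`` means longer
segments, as produced by shorter inbreeding loops. Emissions: the nonIBD
state emits Hardy-Weinberg genotype probabilities; the IBD state emits only
homozygotes (ref with probability p, alt with 1-p); both are contaminated by
a genotyping-error rate eps that redistributes mass to the other genotypes.
Chains restart at stationarity on each chromosome; missing calls emit 1.

(f, a) are estimated by bounded quasi-Newton maximum likelihood on each of
many sparse submaps of markers spaced > 0.5 cM (approximate linkage
equilibrium), and summarised as F-Median / A-Median — the medians of the
per-submap estimates. A boundary likelihood-ratio test against f = 0 flags
individuals as inbred, and (F-Median, A-Median) together are matched against
simulated reference clouds to classify the parental mating type (AV, 2x1C,
1C, 2C, or OUT).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from numba import njit
from scipy import optimize, stats

from .io_formats import MISSING, GenotypeTable, SnpMeta
from .synthetic_data import gene_drop

F_BOUNDS = (1e-6, 0.5)
A_BOUNDS = (1e-3, 1.0)
DEFAULT_EPS = 1e-3

INBRED_TYPES = ["AV", "2x1C", "1C", "2C"]


@dataclass
class IbdHmmParams:
    f: float
    a: float
    eps: float = DEFAULT_EPS

    def __post_init__(self) -> None:
        if not (0.0 <= self.f <= 0.5):
            raise ValueError("f outside [0, 0.5]")
        if self.a <= 0:
            raise ValueError("a must be positive")
        if not (0.0 <= self.eps <= 0.05):
            raise ValueError("eps outside [0, 0.05]")


@dataclass
class IbdFit:
    """Per-individual submap estimates and their summary."""

    sample_id: str
    population: str = ""
    f_hats: np.ndarray = field(default_factory=lambda: np.array([]))
    a_hats: np.ndarray = field(default_factory=lambda: np.array([]))
    logliks: np.ndarray = field(default_factory=lambda: np.array([]))
    null_logliks: np.ndarray = field(default_factory=lambda: np.array([]))
    F_Median: float = math.nan
    A_Median: float = math.nan
    full_loglik: float = math.nan
    full_null_loglik: float = math.nan
    lrt_stat: float = math.nan
    lrt_p: float = math.nan
    inbred: bool = False
    mating_type: str = ""
    posteriors: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Likelihood


@njit(cache=True)
def _forward(em_non, em_ibd, dists, f, a):  # pragma: no cover - jitted
    ll = 0.0
    al_non = 1.0 - f
    al_ibd = f
    for i in range(dists.shape[0]):
        if dists[i] < 0.0:  # chromosome restart at stationarity
            p_non = 1.0 - f
            p_ibd = f
        else:
            e = math.exp(-a * dists[i])
            p_ibd = al_ibd * (e + (1.0 - e) * f) + al_non * (1.0 - e) * f
            p_non = al_ibd * (1.0 - e) * (1.0 - f) + al_non * (
                e + (1.0 - e) * (1.0 - f)
            )
        w_non = p_non * em_non[i]
        w_ibd = p_ibd * em_ibd[i]
        s = w_non + w_ibd
        if s <= 0.0:
            return -1e300
        ll += math.log(s)
        al_non = w_non / s
        al_ibd = w_ibd / s
    return ll


def _emissions(
    calls: np.ndarray, freqs: np.ndarray, eps: float
) -> tuple[np.ndarray, np.ndarray]:
    """Per-marker emission probabilities for the observed calls.

    Error model: the observed genotype equals the true one with probability
    1 - eps, otherwise one of the two other genotypes uniformly.
    """
    q = np.asarray(freqs, dtype=np.float64)  # alt frequency
    p = 1.0 - q
    hw = np.stack([p**2, 2 * p * q, q**2], axis=1)  # nonIBD: P(g=0,1,2)
    ibd = np.stack([p, np.zeros_like(p), q], axis=1)  # IBD
    conf = np.full((3, 3), eps / 2.0)
    np.fill_diagonal(conf, 1.0 - eps)
    hw_e = hw @ conf
    ibd_e = ibd @ conf
    m = len(calls)
    em_non = np.ones(m)
    em_ibd = np.ones(m)
    obs = calls != MISSING
    idx = np.flatnonzero(obs)
    em_non[idx] = hw_e[idx, calls[idx]]
    em_ibd[idx] = ibd_e[idx, calls[idx]]
    return em_non, em_ibd


def _distances(cm: np.ndarray, chrom: Optional[np.ndarray]) -> np.ndarray:
    cm = np.asarray(cm, dtype=np.float64)
    d = np.empty(len(cm))
    d[0] = -1.0
    if len(cm) > 1:
        d[1:] = np.diff(cm)
    if chrom is not None:
        chrom = np.asarray(chrom)
        restart = np.flatnonzero(np.diff(chrom) != 0) + 1
        d[restart] = -1.0
    if np.any(d[d >= 0] < 0) or np.any((d < 0) & (d != -1.0)):
        raise ValueError("markers must be sorted by cM within chromosome")
    if len(cm) > 1 and chrom is None and np.any(np.diff(cm) < 0):
        raise ValueError("markers must be sorted by cM")
    neg = (d != -1.0) & (d < 0)
    if np.any(neg):
        raise ValueError("negative inter-marker distance: markers unsorted")
    return d


def hmm_loglik(
    calls: np.ndarray,
    freqs: np.ndarray,
    cm: np.ndarray,
    params: IbdHmmParams,
    chrom: Optional[np.ndarray] = None,
) -> float:
    """Forward-algorithm log-likelihood of one individual's calls."""
    calls = np.asarray(calls, dtype=np.int64)
    em_non, em_ibd = _emissions(calls, freqs, params.eps)
    d = _distances(cm, chrom)
    return float(_forward(em_non, em_ibd, d, params.f, params.a))


def fit_festim(
    calls: np.ndarray,
    freqs: np.ndarray,
    cm: np.ndarray,
    eps: float = DEFAULT_EPS,
    chrom: Optional[np.ndarray] = None,
) -> tuple[float, float, float]:
    """Maximum-likelihood (f, a) by L-BFGS-B from a 3x3 grid of starts.

    Returns ``(f_hat, a_hat, loglik)`` of the best converged start; if no
    start converges the best boundary evaluation is returned with f at its
    bound (flagged via a warning in the caller's log).
    """
    calls = np.asarray(calls, dtype=np.int64)
    informative = int((calls != MISSING).sum())
    if informative < 50:
        raise ValueError(f"need >= 50 informative markers, got {informative}")
    em_non, em_ibd = _emissions(calls, freqs, eps)
    d = _distances(cm, chrom)

    def neg(x):
        return -_forward(em_non, em_ibd, d, x[0], x[1])

    starts = [(f0, a0) for f0 in (0.01, 0.06, 0.25) for a0 in (0.005, 0.05, 0.3)]
    best = None
    for x0 in starts:
        res = optimize.minimize(
            neg, x0=np.array(x0), method="L-BFGS-B",
            bounds=[F_BOUNDS, A_BOUNDS],
            options={"maxiter": 60, "ftol": 1e-9},
        )
        if best is None or res.fun < best.fun:
            best = res
    return float(best.x[0]), float(best.x[1]), float(-best.fun)


def null_loglik(
    calls: np.ndarray,
    freqs: np.ndarray,
    eps: float = DEFAULT_EPS,
) -> float:
    """Log-likelihood at f = 0 (pure Hardy-Weinberg product)."""
    calls = np.asarray(calls, dtype=np.int64)
    em_non, _ = _emissions(calls, freqs, eps)
    return float(np.log(em_non).sum())


# ---------------------------------------------------------------------------
# Submaps and F-Median


def sample_submaps(
    snps: Sequence[SnpMeta],
    n_submaps: int = 100,
    min_spacing_cM: float = 0.5,
    seed: int = 0,
) -> list[np.ndarray]:
    """Random sparse submaps of markers spaced more than ``min_spacing_cM``.

    Per chromosome: a random start among the markers of the leading spacing
    window, then greedy left-to-right acceptance of the next marker strictly
    more than the spacing away. Submaps differ through their random starts.
    """
    chrom = np.array([s.chrom for s in snps])
    cm = np.array([s.pos_cM for s in snps])
    rng = np.random.default_rng(seed)
    chroms = []
    for c in dict.fromkeys(chrom):
        idx = np.flatnonzero(chrom == c)
        chroms.append(idx[np.argsort(cm[idx], kind="stable")])
    out = []
    for _ in range(n_submaps):
        chosen: list[int] = []
        for idx in chroms:
            pos = cm[idx]
            window = np.flatnonzero(pos <= pos[0] + min_spacing_cM)
            k = int(rng.integers(0, len(window))) if len(window) else 0
            last = pos[k]
            chosen.append(idx[k])
            for j in range(k + 1, len(idx)):
                if pos[j] - last > min_spacing_cM:
                    chosen.append(idx[j])
                    last = pos[j]
        out.append(np.array(sorted(chosen), dtype=np.int64))
    return out


def leave_one_out_freqs(
    table: GenotypeTable, sample_id: str,
    population_samples: Optional[Sequence[str]] = None,
) -> np.ndarray:
    """Alt frequencies from the focal individual's population, excluding the
    focal individual, clipped away from 0/1 for emission stability."""
    pool = population_samples if population_samples is not None else table.samples
    idx = [table.sample_index(s) for s in pool if s != sample_id]
    if not idx:
        raise ValueError("no other samples to estimate frequencies from")
    f = table.alt_freqs(idx)
    n = 2 * len(idx)
    lo = 1.0 / (n + 1)
    return np.clip(np.nan_to_num(f, nan=0.5), lo, 1.0 - lo)


def fit_submaps(
    calls: np.ndarray,
    freqs: np.ndarray,
    cm: np.ndarray,
    chrom: np.ndarray,
    snps: Sequence[SnpMeta],
    n_submaps: int = 100,
    min_spacing_cM: float = 0.5,
    eps: float = DEFAULT_EPS,
    seed: int = 0,
    sample_id: str = "",
    population: str = "",
) -> IbdFit:
    """Submap (f, a) estimates plus a full-panel fit for one call vector."""
    calls = np.asarray(calls, dtype=np.int64)
    submaps = sample_submaps(snps, n_submaps, min_spacing_cM, seed)
    f_hats, a_hats, lls, nulls = [], [], [], []
    for sub in submaps:
        fh, ah, ll = fit_festim(calls[sub], freqs[sub], cm[sub], eps, chrom[sub])
        f_hats.append(fh)
        a_hats.append(ah)
        lls.append(ll)
        nulls.append(null_loglik(calls[sub], freqs[sub], eps))
    _, _, full_ll = fit_festim(calls, freqs, cm, eps, chrom)
    fit = IbdFit(
        sample_id=sample_id,
        population=population,
        f_hats=np.array(f_hats),
        a_hats=np.array(a_hats),
        logliks=np.array(lls),
        null_logliks=np.array(nulls),
        F_Median=float(np.median(f_hats)),
        A_Median=float(np.median(a_hats)),
        full_loglik=full_ll,
        full_null_loglik=null_loglik(calls, freqs, eps),
    )
    lrt_inbred(fit)
    return fit


def f_median(
    table: GenotypeTable,
    sample_id: str,
    freqs: Optional[np.ndarray] = None,
    n_submaps: int = 100,
    min_spacing_cM: float = 0.5,
    eps: float = DEFAULT_EPS,
    seed: int = 0,
    population_samples: Optional[Sequence[str]] = None,
    population: str = "",
) -> IbdFit:
    """F-Median / A-Median for one individual over random sparse submaps."""
    if freqs is None:
        freqs = leave_one_out_freqs(table, sample_id, population_samples)
    i = table.sample_index(sample_id)
    calls = table.calls[i].astype(np.int64)
    cm = np.array([s.pos_cM for s in table.snps])
    chrom = np.array([s.chrom for s in table.snps])
    return fit_submaps(
        calls, freqs, cm, chrom, table.snps, n_submaps, min_spacing_cM, eps,
        seed, sample_id=sample_id, population=population,
    )


def lrt_inbred(
    fit: IbdFit, alpha: float = 0.05, statistic: str = "full"
) -> tuple[float, float, bool]:
    """Boundary LRT of inbred (f free) vs outbred (f = 0).

    ``statistic='full'`` (default) uses the maximised log-likelihood of the
    whole marker panel, which keeps all the information the submaps split up
    (the chain models linkage through genetic distance, so the panel-wide
    likelihood is valid whenever emissions are close to linkage
    equilibrium). ``statistic='consensus'`` restricts the test to the submap
    whose f-hat is the per-submap median (lower middle for even counts) —
    the conservative choice for unpruned, strongly LD-structured arrays.
    The p-value comes from the boundary mixture 0.5 chi2_0 + 0.5 chi2_1.
    Updates and returns the fit's LRT fields.
    """
    if statistic == "full" and math.isfinite(fit.full_loglik):
        stat = 2.0 * (fit.full_loglik - fit.full_null_loglik)
    else:
        order = np.argsort(fit.f_hats, kind="stable")
        k = order[(len(order) - 1) // 2]
        stat = 2.0 * (fit.logliks[k] - fit.null_logliks[k])
    stat = max(stat, 0.0)
    p = 1.0 if stat == 0.0 else 0.5 * float(stats.chi2.sf(stat, df=1))
    fit.lrt_stat, fit.lrt_p, fit.inbred = float(stat), float(p), bool(p < alpha)
    return fit.lrt_stat, fit.lrt_p, fit.inbred


# ---------------------------------------------------------------------------
# Mating-type classification


def reference_distributions(
    snps: Sequence[SnpMeta],
    chrom_lengths: dict[int, float],
    mating_types: Sequence[str] = tuple(INBRED_TYPES),
    n_sims: int = 50,
    n_submaps: int = 20,
    eps: float = DEFAULT_EPS,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Simulated (F-Median, A-Median) clouds per mating type.

    Gene-drops ``n_sims`` offspring per type on the supplied panel and pushes
    each through the submap estimator with the panel's founder frequencies.
    """
    rng = np.random.default_rng(seed)
    freqs = np.array([s.freq_alt for s in snps], dtype=float)
    cm = np.array([s.pos_cM for s in snps])
    chrom = np.array([s.chrom for s in snps])
    clouds: dict[str, np.ndarray] = {}
    for mt in mating_types:
        pts = np.empty((n_sims, 2))
        for k in range(n_sims):
            calls, _, _ = gene_drop(
                mt, snps, chrom_lengths, seed=int(rng.integers(2**31))
            )
            submaps = sample_submaps(
                snps, n_submaps, seed=int(rng.integers(2**31))
            )
            fh, ah = [], []
            for sub in submaps:
                f1, a1, _ = fit_festim(
                    calls[sub].astype(np.int64), freqs[sub], cm[sub], eps, chrom[sub]
                )
                fh.append(f1)
                ah.append(a1)
            pts[k] = (float(np.median(fh)), float(np.median(ah)))
        clouds[mt] = pts
    return clouds


def classify_mating_type(
    fit: IbdFit, clouds: dict[str, np.ndarray]
) -> tuple[str, dict[str, float]]:
    """Assign the most likely parental mating type from (F-Median, A-Median).

    Two-step: the LRT decides OUT directly; otherwise a 2D Gaussian kernel
    density of each simulated cloud — on (F, log10 a), since the rate
    parameter is positive and right-skewed — is evaluated at the fit's
    coordinates and combined with a uniform prior over the inbred types.
    Updates the fit in place and returns ``(mating_type, posteriors)``.
    """
    if not fit.inbred:
        post = {t: 0.0 for t in clouds}
        post["OUT"] = 1.0
        fit.mating_type, fit.posteriors = "OUT", post
        return "OUT", post
    x = np.array([fit.F_Median, math.log10(max(fit.A_Median, A_BOUNDS[0]))])
    logd = {}
    for mt, pts in clouds.items():
        z = np.column_stack([pts[:, 0], np.log10(np.maximum(pts[:, 1], A_BOUNDS[0]))])
        try:
            kde = stats.gaussian_kde(z.T)
            logd[mt] = float(kde.logpdf(x)[0])
        except np.linalg.LinAlgError:  # degenerate cloud
            logd[mt] = -math.inf
    if all(not math.isfinite(v) for v in logd.values()):
        # far from every cloud: fall back to nearest centroid in (F, log10 a)
        cent = {
            mt: np.array([pts[:, 0].mean(), np.log10(pts[:, 1]).mean()])
            for mt, pts in clouds.items()
        }
        mt_best = min(cent, key=lambda t: float(np.sum((cent[t] - x) ** 2)))
        post = {t: (1.0 if t == mt_best else 0.0) for t in clouds}
    else:
        m = max(v for v in logd.values() if math.isfinite(v))
        w = {t: (math.exp(v - m) if math.isfinite(v) else 0.0) for t, v in logd.items()}
        s = sum(w.values())
        post = {t: v / s for t, v in w.items()}
        mt_best = max(post, key=post.get)
    post["OUT"] = 0.0
    fit.mating_type, fit.posteriors = mt_best, post
    return mt_best, post
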