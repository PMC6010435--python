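"""Synthetic cohorts with known ground truth.

Generates SNP-array-style genotypes by gene-dropping haplotypes through
small consanguineous pedigrees, together with a matching ethno-demographic
survey (birthplaces, spouse links, parental birthplaces) whose spousal
distances follow a bimodal endogamous/exogamous mixture. Because founder
haplotypes are labelled, the generator knows the exact autozygous
(identical-by-descent) segments of every focal individual, which gives every
downstream estimator — the IBD hidden Markov model, ROH calling, excess
homozygosity, the exogamy/inbreeding comparison — an exact truth table.

Recombination is a Poisson process on the genetic (cM) scale with no
interference and a sex-averaged map. No mutation and no genotyping error are
introduced at generation time; an optional post-hoc error process flips
calls at a configurable rate so that the HMM's error parameter is exercised
separately from the signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    MISSING,
    GeneticMap,
    GenotypeTable,
    SnpMeta,
    SurveyRecord,
)

EARTH_RADIUS_KM = 6371.0088

# expected autozygosity F and number of meioses around the inbreeding loop
# (through the focal individual) for each parental mating type
@dataclass(frozen=True)
class PedigreeSpec:
    mating_type: str
    expected_f: float
    loop_meioses: int


PEDIGREES: dict[str, PedigreeSpec] = {
    "OUT": PedigreeSpec("OUT", 0.0, 0),
    "2C": PedigreeSpec("2C", 1.0 / 64.0, 8),
    "1C": PedigreeSpec("1C", 1.0 / 16.0, 6),
    "2x1C": PedigreeSpec("2x1C", 1.0 / 8.0, 6),
    "AV": PedigreeSpec("AV", 1.0 / 8.0, 5),
}

MATING_TYPES = list(PEDIGREES)


@dataclass
class IbdTrack:
    """Exact autozygous segments of one focal individual, per chromosome (cM)."""

    segments: dict[int, list[tuple[float, float]]] = field(default_factory=dict)

    def total_cM(self) -> float:
        return sum(b - a for segs in self.segments.values() for a, b in segs)

    def fraction(self, chrom_lengths: dict[int, float]) -> float:
        total = sum(chrom_lengths.values())
        return self.total_cM() / total if total > 0 else 0.0

    def segments_bp(self, bp_per_cM: float) -> dict[int, list[tuple[int, int]]]:
        return {
            c: [(int(round(a * bp_per_cM)) + 1, int(round(b * bp_per_cM))) for a, b in segs]
            for c, segs in self.segments.items()
        }


@dataclass
class GeographyModel:
    """Bimodal spousal-distance model: endogamous mass near 0 km plus an
    exogamous lognormal tail.

    Defaults emulate an Inner-Asian-like regime: roughly half of couples
    marry within the village (km-scale distances) and the rest disperse with
    a median around 30 km and a tail reaching ~1,500 km.
    """

    endogamous_fraction: float = 0.5
    endogamous_scale_km: float = 0.5
    exogamous_logmean: float = math.log(30.0)  # natural-log km
    exogamous_logsd: float = 1.2

    def __post_init__(self) -> None:
        if not (0.0 <= self.endogamous_fraction <= 1.0):
            raise ValueError("endogamous_fraction outside [0, 1]")
        if self.endogamous_scale_km <= 0 or self.exogamous_logsd <= 0:
            raise ValueError("geography scales must be positive")

    def sample_distances(self, n: int, rng: np.random.Generator) -> np.ndarray:
        endo = rng.random(n) < self.endogamous_fraction
        d = rng.lognormal(self.exogamous_logmean, self.exogamous_logsd, size=n)
        d[endo] = rng.exponential(self.endogamous_scale_km, size=int(endo.sum()))
        return d


# ---------------------------------------------------------------------------
# SNP panels


def make_snp_panel(
    n_snps: int = 5000,
    n_chrom: int = 22,
    total_cM: float = 3500.0,
    bp_per_cM: float = 1e6,
    freq_range: tuple[float, float] = (0.05, 0.95),
    seed: int = 0,
) -> tuple[list[SnpMeta], GeneticMap, dict[int, float]]:
    """Random SNP positions on ``n_chrom`` equal-length chromosomes.

    Genetic positions are uniform over each chromosome; physical positions
    follow a constant ``bp_per_cM`` so the map has unit rate everywhere.
    Alt-allele frequencies are uniform over ``freq_range`` (array-like
    common-SNP ascertainment).
    """
    rng = np.random.default_rng(seed)
    chrom_len = total_cM / n_chrom
    chrom_lengths = {c: chrom_len for c in range(1, n_chrom + 1)}
    per_chrom = np.full(n_chrom, n_snps // n_chrom)
    per_chrom[: n_snps % n_chrom] += 1

    snps: list[SnpMeta] = []
    for ci, chrom in enumerate(range(1, n_chrom + 1)):
        cm = np.sort(rng.uniform(0, chrom_len, size=per_chrom[ci]))
        bp = np.maximum(1, np.round(cm * bp_per_cM).astype(np.int64))
        bp = np.maximum.accumulate(bp + np.arange(len(bp)))  # enforce strict order
        freqs = rng.uniform(*freq_range, size=per_chrom[ci])
        for k in range(per_chrom[ci]):
            snps.append(
                SnpMeta(
                    snp_id=f"rs{chrom}_{k}",
                    chrom=chrom,
                    pos_bp=int(bp[k]),
                    pos_cM=float(bp[k] / bp_per_cM),
                    alleles=("A", "G"),
                    freq_alt=float(freqs[k]),
                )
            )
    gmap = GeneticMap()
    for chrom in range(1, n_chrom + 1):
        knots_bp = np.array([1, int(chrom_len * bp_per_cM) + 1], dtype=np.int64)
        knots_cM = np.array([0.0, chrom_len])
        gmap.add_chrom(chrom, knots_bp, knots_cM, np.array([1e6 / bp_per_cM] * 2))
    return snps, gmap, chrom_lengths


def simulate_founders(
    n_haplotypes: int,
    snps: Sequence[SnpMeta],
    seed: int,
    ld_decay: float = 0.0,
) -> np.ndarray:
    """Draw founder haplotypes site-wise from each SNP's ``freq_alt``.

    ``ld_decay`` in [0, 1) adds first-order dependence between adjacent
    markers (probability that a site reuses the previous site's latent
    uniform draw); 0 means fully independent sites. Returns a
    ``(n_haplotypes, n_snps)`` 0/1 matrix.
    """
    freqs = np.array([s.freq_alt for s in snps], dtype=float)
    if np.any(np.isnan(freqs)) or np.any((freqs < 0) | (freqs > 1)):
        raise ValueError("all SNPs need freq_alt in [0, 1]")
    if not (0.0 <= ld_decay < 1.0):
        raise ValueError("ld_decay must be in [0, 1)")
    rng = np.random.default_rng(seed)
    u = rng.random((n_haplotypes, len(freqs)))
    if ld_decay > 0:
        reuse = rng.random((n_haplotypes, len(freqs))) < ld_decay
        for j in range(1, len(freqs)):
            u[:, j] = np.where(reuse[:, j], u[:, j - 1], u[:, j])
    return (u < freqs).astype(np.int8)


# ---------------------------------------------------------------------------
# Gene dropping
#
# A haplotype is, per chromosome, a pair (breaks, labels): ``breaks`` are the
# right edges (cM) of segments carrying founder-haplotype ``labels``.

Haplotype = dict[int, tuple[np.ndarray, np.ndarray]]


def _founder_haplotype(chrom_lengths: dict[int, float], label: int) -> Haplotype:
    return {
        c: (np.array([L]), np.array([label], dtype=np.int64))
        for c, L in chrom_lengths.items()
    }


def _meiosis(
    hap_a: Haplotype,
    hap_b: Haplotype,
    chrom_lengths: dict[int, float],
    rng: np.random.Generator,
) -> Haplotype:
    """One gamete: Poisson crossovers on the cM scale, no interference."""
    out: Haplotype = {}
    for c, L in chrom_lengths.items():
        n_x = rng.poisson(L / 100.0)
        xs = np.sort(rng.uniform(0, L, size=n_x))
        cur = rng.integers(2)  # 0 -> copy from hap_a first
        edges = np.concatenate([xs, [L]])
        breaks_out: list[float] = []
        labels_out: list[int] = []
        start = 0.0
        for edge in edges:
            src = (hap_a if cur == 0 else hap_b)[c]
            b, lab = src
            i0 = np.searchsorted(b, start, side="right")
            i1 = np.searchsorted(b, edge, side="left")
            for i in range(i0, i1 + 1):
                seg_end = min(b[i], edge)
                if seg_end > start:
                    if labels_out and labels_out[-1] == lab[i]:
                        breaks_out[-1] = seg_end
                    else:
                        breaks_out.append(seg_end)
                        labels_out.append(int(lab[i]))
                    start = seg_end
            cur = 1 - cur
            start = edge if start < edge else start
        out[c] = (np.array(breaks_out), np.array(labels_out, dtype=np.int64))
    return out


def _child(parent1, parent2, chrom_lengths, rng):
    return (
        _meiosis(parent1[0], parent1[1], chrom_lengths, rng),
        _meiosis(parent2[0], parent2[1], chrom_lengths, rng),
    )


def _pedigree_drop(
    mating_type: str, chrom_lengths: dict[int, float], rng: np.random.Generator
) -> tuple[Haplotype, Haplotype, int]:
    """Drop haplotype labels through one pedigree; returns the focal
    individual's two haplotypes and the number of founder haplotypes used."""
    counter = [0]

    def founder():
        a = _founder_haplotype(chrom_lengths, counter[0])
        b = _founder_haplotype(chrom_lengths, counter[0] + 1)
        counter[0] += 2
        return (a, b)

    ch = lambda p1, p2: _child(p1, p2, chrom_lengths, rng)  # noqa: E731

    if mating_type == "OUT":
        p1 = ch(founder(), founder())
        p2 = ch(founder(), founder())
    elif mating_type == "1C":
        gpa, gpb = founder(), founder()  # shared grandparental couple
        s1, s2 = ch(gpa, gpb), ch(gpa, gpb)
        p1 = ch(s1, founder())
        p2 = ch(s2, founder())
    elif mating_type == "2C":
        gga, ggb = founder(), founder()  # shared great-grandparental couple
        s1, s2 = ch(gga, ggb), ch(gga, ggb)
        t1 = ch(s1, founder())
        t2 = ch(s2, founder())
        p1 = ch(t1, founder())
        p2 = ch(t2, founder())
    elif mating_type == "AV":
        gpa, gpb = founder(), founder()
        s1, s2 = ch(gpa, gpb), ch(gpa, gpb)
        p1 = s1  # uncle
        p2 = ch(s2, founder())  # niece
    elif mating_type == "SIB":
        # full-sib mating (F = 1/4): not part of the survey's mating-type
        # alphabet, but useful as a strong-signal case in power analyses
        gpa, gpb = founder(), founder()
        p1, p2 = ch(gpa, gpb), ch(gpa, gpb)
    elif mating_type == "2x1C":
        # two sibships from two founder couples; the parents are cousins
        # through both of their parental lines
        gpa1, gpb1 = founder(), founder()
        gpa2, gpb2 = founder(), founder()
        s1, s2 = ch(gpa1, gpb1), ch(gpa1, gpb1)
        t1, t2 = ch(gpa2, gpb2), ch(gpa2, gpb2)
        p1 = ch(s1, t1)
        p2 = ch(s2, t2)
    else:
        raise ValueError(f"unknown mating type {mating_type!r}")
    focal = ch(p1, p2)
    return focal[0], focal[1], counter[0]


def _ibd_from_labels(hap_m: Haplotype, hap_p: Haplotype) -> IbdTrack:
    track = IbdTrack()
    for c in hap_m:
        bm, lm = hap_m[c]
        bp_, lp = hap_p[c]
        segs: list[tuple[float, float]] = []
        i = j = 0
        start = 0.0
        while i < len(bm) and j < len(bp_):
            end = min(bm[i], bp_[j])
            if lm[i] == lp[j] and end > start:
                if segs and segs[-1][1] == start:
                    segs[-1] = (segs[-1][0], end)
                else:
                    segs.append((start, end))
            start = end
            if bm[i] <= end:
                i += 1
            if bp_[j] <= end:
                j += 1
        track.segments[c] = segs
    return track


def _haplotype_alleles(
    hap: Haplotype, snp_cm: dict[int, np.ndarray], founder_alleles: np.ndarray,
    snp_idx: dict[int, np.ndarray],
) -> np.ndarray:
    """Alleles (0/1) carried by one haplotype at every SNP."""
    out = np.empty(founder_alleles.shape[1], dtype=np.int8)
    for c, cm in snp_cm.items():
        breaks, labels = hap[c]
        seg = np.minimum(np.searchsorted(breaks, cm, side="left"), len(labels) - 1)
        out[snp_idx[c]] = founder_alleles[labels[seg], snp_idx[c]]
    return out


def gene_drop(
    mating_type: str,
    snps: Sequence[SnpMeta],
    chrom_lengths: dict[int, float],
    seed: int,
    founder_alleles: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, np.ndarray, IbdTrack]:
    """Simulate one focal offspring of the given parental mating type.

    Returns ``(genotype, hap_pair, track)``: the focal alt-dosage vector, the
    two transmitted haplotype allele vectors (phased, shape ``(2, n_snps)``)
    and the exact autozygous :class:`IbdTrack`. ``founder_alleles`` may be
    provided (rows = founder haplotypes, enough rows for the pedigree);
    otherwise founders are drawn from each SNP's ``freq_alt``.
    """
    for s in snps:
        if s.chrom not in chrom_lengths:
            raise KeyError(f"chromosome {s.chrom} missing from chrom_lengths")
    rng = np.random.default_rng(seed)
    hap_m, hap_p, n_labels = _pedigree_drop(mating_type, chrom_lengths, rng)
    if founder_alleles is None:
        founder_alleles = simulate_founders(
            n_labels, snps, seed=int(rng.integers(2**31))
        )
    elif founder_alleles.shape[0] < n_labels:
        raise ValueError(
            f"{mating_type} pedigree needs {n_labels} founder haplotypes, "
            f"got {founder_alleles.shape[0]}"
        )
    snp_cm: dict[int, np.ndarray] = {}
    snp_idx: dict[int, np.ndarray] = {}
    chrom_arr = np.array([s.chrom for s in snps])
    cm_arr = np.array([s.pos_cM for s in snps])
    for c in chrom_lengths:
        idx = np.flatnonzero(chrom_arr == c)
        if len(idx):
            snp_cm[c] = cm_arr[idx]
            snp_idx[c] = idx
    a_m = _haplotype_alleles(hap_m, snp_cm, founder_alleles, snp_idx)
    a_p = _haplotype_alleles(hap_p, snp_cm, founder_alleles, snp_idx)
    track = _ibd_from_labels(hap_m, hap_p)
    return (a_m + a_p).astype(np.int8), np.stack([a_m, a_p]), track


def add_genotype_errors(
    calls: np.ndarray, eps: float, rng: np.random.Generator
) -> np.ndarray:
    """Flip each non-missing call to one of the other two genotypes w.p. ``eps``."""
    out = calls.copy()
    flip = (rng.random(out.shape) < eps) & (out != MISSING)
    alt = (out[flip] + 1 + rng.integers(0, 2, size=int(flip.sum()))) % 3
    out[flip] = alt.astype(out.dtype)
    return out


# ---------------------------------------------------------------------------
# Geographic placement


def destination_point(
    lat: float, lon: float, distance_km: float, bearing_deg: float
) -> tuple[float, float]:
    """Great-circle forward geodesic on a sphere of radius 6371.0088 km."""
    d = distance_km / EARTH_RADIUS_KM
    th = math.radians(bearing_deg)
    la1, lo1 = math.radians(lat), math.radians(lon)
    la2 = math.asin(
        math.sin(la1) * math.cos(d) + math.cos(la1) * math.sin(d) * math.cos(th)
    )
    lo2 = lo1 + math.atan2(
        math.sin(th) * math.sin(d) * math.cos(la1),
        math.cos(d) - math.sin(la1) * math.sin(la2),
    )
    lon_out = math.degrees(lo2)
    lon_out = (lon_out + 180.0) % 360.0 - 180.0
    return math.degrees(la2), lon_out


# ---------------------------------------------------------------------------
# Whole-cohort simulation


@dataclass
class PopulationConfig:
    code: str
    group: str  # e.g. "TurkoMongol" / "IndoIranian"
    n: int
    center: tuple[float, float]  # lat, lon (study region sits in 40-50N)
    mixture: dict[str, float] = field(
        # study-like mating-type mixture: mostly outbred, second-cousins the
        # dominant consanguineous class, first-cousins rarer, 2x1C marginal
        default_factory=lambda: {"OUT": 0.645, "2C": 0.29, "1C": 0.06, "2x1C": 0.005}
    )
    geography: GeographyModel = field(default_factory=GeographyModel)
    # optional per-distance-band mixture overrides for the *parental* couples:
    # list of ((lo_km, hi_km), mixture); first matching band wins
    band_mixtures: list[tuple[tuple[float, float], dict[str, float]]] = field(
        default_factory=list
    )


@dataclass
class SimulatedCohort:
    genotypes: GenotypeTable
    haplotypes: np.ndarray  # (n_samples, 2, n_snps) phased alleles
    survey: list[SurveyRecord]
    truth: pd.DataFrame
    tracks: dict[str, IbdTrack]
    chrom_lengths: dict[int, float]
    gmap: GeneticMap


def _normalized_mixture(mixture: dict[str, float]) -> tuple[list[str], np.ndarray]:
    types = list(mixture)
    w = np.array([mixture[t] for t in types], dtype=float)
    if np.any(w < 0):
        raise ValueError("mixture weights must be non-negative")
    s = w.sum()
    if not math.isclose(s, 1.0, abs_tol=1e-6):
        raise ValueError(f"mixture weights must sum to 1 (got {s})")
    return types, w / s


def simulate_cohort(
    populations: Sequence[PopulationConfig],
    snps: Optional[Sequence[SnpMeta]] = None,
    chrom_lengths: Optional[dict[int, float]] = None,
    gmap: Optional[GeneticMap] = None,
    seed: int = 0,
    error_rate: float = 0.0,
    panel_kwargs: Optional[dict] = None,
) -> SimulatedCohort:
    """Simulate a multi-population genotype + survey cohort.

    Each individual is gene-dropped through a pedigree whose mating type is
    drawn from the population mixture (optionally conditioned on the drawn
    parental-couple distance via ``band_mixtures``, which is how kinship
    endogamy at intermediate distances is planted). Survey rows carry
    birthplaces placed by exact spherical geodesics, so haversine recovers
    the drawn distances; consecutive same-population individuals are linked
    as spouses. Truth rows record mating type, exact autozygous fraction and
    the drawn parental distance.
    """
    rng = np.random.default_rng(seed)
    if snps is None:
        pk = dict(panel_kwargs or {})
        pk.setdefault("seed", int(rng.integers(2**31)))
        snps, gmap, chrom_lengths = make_snp_panel(**pk)
    if chrom_lengths is None or gmap is None:
        raise ValueError("chrom_lengths and gmap required when snps are supplied")
    snps = list(snps)

    samples: list[str] = []
    calls_rows: list[np.ndarray] = []
    hap_rows: list[np.ndarray] = []
    survey: list[SurveyRecord] = []
    truth_rows: list[dict] = []
    tracks: dict[str, IbdTrack] = {}

    for pop in populations:
        if pop.n <= 0:
            raise ValueError(f"population {pop.code}: n must be positive")
        parental_d = pop.geography.sample_distances(pop.n, rng)
        couple_d = pop.geography.sample_distances(pop.n, rng)
        for i in range(pop.n):
            iid = f"{pop.code}_{i:04d}"
            mixture = pop.mixture
            for (lo, hi), mx in pop.band_mixtures:
                if lo <= parental_d[i] < hi:
                    mixture = mx
                    break
            types, w = _normalized_mixture(mixture)
            mt = types[int(rng.choice(len(types), p=w))]
            g, haps, track = gene_drop(
                mt, snps, chrom_lengths, seed=int(rng.integers(2**31))
            )
            samples.append(iid)
            calls_rows.append(g)
            hap_rows.append(haps)
            tracks[iid] = track

            # geography: father's birthplace jitters around the population
            # centre; mother at the drawn parental distance; focal born at
            # the father's place (patrilocality); spouses paired below.
            f_lat, f_lon = destination_point(
                *pop.center, float(rng.exponential(1.0)), float(rng.uniform(0, 360))
            )
            m_lat, m_lon = destination_point(
                f_lat, f_lon, float(parental_d[i]), float(rng.uniform(0, 360))
            )
            survey.append(
                SurveyRecord(
                    individual_id=iid,
                    sex="M" if i % 2 == 0 else "F",
                    population=pop.code,
                    group=pop.group,
                    birthplace=(f_lat, f_lon),
                    father_birthplace=(f_lat, f_lon),
                    mother_birthplace=(m_lat, m_lon),
                )
            )
            truth_rows.append(
                {
                    "individual_id": iid,
                    "population": pop.code,
                    "group": pop.group,
                    "mating_type": mt,
                    "true_f": track.fraction(chrom_lengths),
                    "parental_distance_km": float(parental_d[i]),
                }
            )
        # link consecutive pairs as couples; move the wife's birthplace to
        # the drawn spousal distance from the husband's
        start = len(survey) - pop.n
        for i in range(0, pop.n - 1, 2):
            a, b = survey[start + i], survey[start + i + 1]
            a.spouse_id, b.spouse_id = b.individual_id, a.individual_id
            lat, lon = destination_point(
                *a.birthplace, float(couple_d[i // 2]), float(rng.uniform(0, 360))
            )
            b.birthplace = (lat, lon)
            truth_rows[start + i]["couple_distance_km"] = float(couple_d[i // 2])
            truth_rows[start + i + 1]["couple_distance_km"] = float(couple_d[i // 2])

    calls = np.vstack(calls_rows)
    if error_rate > 0:
        calls = add_genotype_errors(calls, error_rate, rng)
    table = GenotypeTable(samples=samples, snps=snps, calls=calls)
    return SimulatedCohort(
        genotypes=table,
        haplotypes=np.stack(hap_rows),
        survey=survey,
        truth=pd.DataFrame(truth_rows),
        tracks=tracks,
        chrom_lengths=chrom_lengths,
        gmap=gmap,
    )


def default_study_populations(
    n_populations: int = 16,
    n_per_population: int = 27,
    n_turko_mongol: int = 12,
    seed: int = 0,
) -> list[PopulationConfig]:
    """Study-design-like layout: 16 populations (12 Turko-Mongol, 4
    Indo-Iranian) of ~27 genotyped individuals, spread over a 40-50N band.

    Indo-Iranian populations get a more endogamous geography (smaller
    exogamous fraction), mirroring the contrast between the two groups.
    """
    rng = np.random.default_rng(seed)
    pops = []
    for k in range(n_populations):
        tm = k < n_turko_mongol
        geo = GeographyModel(endogamous_fraction=0.4 if tm else 0.72)
        pops.append(
            PopulationConfig(
                code=f"{'TM' if tm else 'II'}{k:02d}",
                group="TurkoMongol" if tm else "IndoIranian",
                n=n_per_population,
                center=(float(rng.uniform(40, 50)), float(rng.uniform(60, 95))),
                geography=geo,
            )
        )
    return pops
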