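"""Simulation-based calibration and validation harnesses.

Every estimator in the pipeline is exercised against the synthetic
generator's exact ground truth: parameter recovery of the IBD-HMM
inbreeding coefficient per mating type, size and power of the
inbred/outbred likelihood-ratio test, the mating-type confusion matrix,
agreement of called ROH totals with true autozygous fractions, and the
distance-binned "bell shape" design in which kinship endogamy is planted
at intermediate parental distances. These are package features (not test
plumbing) so that calibration can be re-run at any problem size.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import ibd_inbreeding as ibd
from . import roh_analysis as roh
from . import stats_report as sr
from .io_formats import GenotypeTable, SnpMeta
from .synthetic_data import (
    GeographyModel,
    PopulationConfig,
    gene_drop,
    make_snp_panel,
    simulate_cohort,
)


def simulate_and_fit(
    mating_type: str,
    n: int,
    snps: Sequence[SnpMeta],
    chrom_lengths: dict[int, float],
    n_submaps: int = 12,
    eps: float = ibd.DEFAULT_EPS,
    seed: int = 0,
) -> pd.DataFrame:
    """Gene-drop ``n`` offspring of one mating type and fit each with the
    submap F-Median estimator (emissions use the panel's founder
    frequencies). Returns one row per individual with truth and estimates."""
    rng = np.random.default_rng(seed)
    freqs = np.array([s.freq_alt for s in snps], dtype=float)
    cm = np.array([s.pos_cM for s in snps])
    chrom = np.array([s.chrom for s in snps])
    rows = []
    for k in range(n):
        calls, _, track = gene_drop(
            mating_type, snps, chrom_lengths, seed=int(rng.integers(2**31))
        )
        fit = _fit_calls(
            calls, freqs, cm, chrom, snps, n_submaps, eps,
            seed=int(rng.integers(2**31)),
        )
        rows.append(
            {
                "mating_type": mating_type,
                "true_f": track.fraction(chrom_lengths),
                "F_Median": fit.F_Median,
                "A_Median": fit.A_Median,
                "lrt_stat": fit.lrt_stat,
                "lrt_p": fit.lrt_p,
                "inbred": fit.inbred,
            }
        )
    return pd.DataFrame(rows)


def _fit_calls(calls, freqs, cm, chrom, snps, n_submaps, eps, seed) -> ibd.IbdFit:
    return ibd.fit_submaps(
        calls, freqs, cm, chrom, snps, n_submaps=n_submaps, eps=eps, seed=seed,
        sample_id="sim",
    )


def classification_experiment(
    snps: Sequence[SnpMeta],
    chrom_lengths: dict[int, float],
    n_per_type: int = 100,
    n_cloud: int = 40,
    n_submaps: int = 8,
    seed: int = 0,
    types: Sequence[str] = ("OUT", "2C", "1C", "2x1C", "AV"),
) -> pd.DataFrame:
    """Confusion table of the mating-type classifier.

    Builds reference clouds from ``n_cloud`` simulations per inbred type,
    then classifies ``n_per_type`` fresh simulations of every type.
    Returns rows (true_type, assigned_type, F_Median, A_Median).
    """
    clouds = ibd.reference_distributions(
        snps, chrom_lengths, mating_types=ibd.INBRED_TYPES, n_sims=n_cloud,
        n_submaps=n_submaps, seed=seed,
    )
    rows = []
    for t, mt in enumerate(types):
        fits = simulate_and_fit(
            mt, n_per_type, snps, chrom_lengths, n_submaps=n_submaps,
            seed=seed + 1000 + t,
        )
        for _, r in fits.iterrows():
            fit = ibd.IbdFit(
                sample_id="sim", F_Median=r.F_Median, A_Median=r.A_Median,
                inbred=bool(r.inbred),
            )
            assigned, _ = ibd.classify_mating_type(fit, clouds)
            rows.append(
                {
                    "true_type": mt,
                    "assigned_type": assigned,
                    "F_Median": r.F_Median,
                    "A_Median": r.A_Median,
                }
            )
    return pd.DataFrame(rows)


ADJACENT = {
    "OUT": {"2C"},
    "2C": {"OUT", "1C"},
    "1C": {"2C", "2x1C", "AV"},
    "2x1C": {"1C", "AV"},
    "AV": {"1C", "2x1C"},
}
"""Neighbourhoods on the relatedness ladder OUT - 2C - 1C - {2x1C, AV}."""


def recall_and_adjacency(conf: pd.DataFrame) -> pd.DataFrame:
    """Per-type recall and the share of errors landing in adjacent types."""
    rows = []
    for mt, sub in conf.groupby("true_type"):
        correct = (sub["assigned_type"] == mt).mean()
        errors = sub[sub["assigned_type"] != mt]
        adj = (
            errors["assigned_type"].isin(ADJACENT[mt]).mean()
            if len(errors)
            else 1.0
        )
        rows.append(
            {"true_type": mt, "recall": float(correct),
             "adjacent_error_share": float(adj), "n": len(sub)}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ROH vs truth


DENSE_PANEL_KW = dict(n_snps=5000, n_chrom=6, total_cM=600.0, bp_per_cM=1e6)
"""Physically dense desk-scale panel (1 SNP / ~120 kb) used wherever ROH
calling needs realistic SNP density per kb."""

DENSE_ROH_PARAMS = roh.RohParams(
    window_snp=25, window_het=1, window_missing=2, min_snp=25, min_kb=500.0,
    density_kb_per_snp=200.0, max_gap_kb=1500.0,
)
"""Scanner settings scaled to the dense desk panel's SNP spacing."""


def roh_truth_experiment(
    n: int = 50,
    mixture: Optional[dict[str, float]] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Mixed-cohort comparison of called ROH totals against exact IBD truth.

    Returns per-individual rows: true autozygous fraction, fixed-long ROH
    total / genome length, and class-C count/total kb under a pooled
    three-component mixture fit of segment lengths.
    """
    mixture = mixture or {"OUT": 0.4, "2C": 0.2, "1C": 0.3, "AV": 0.1}
    rng = np.random.default_rng(seed)
    snps, _, cl = make_snp_panel(**DENSE_PANEL_KW, seed=int(rng.integers(2**31)))
    genome_kb = sum(cl.values()) * 1000.0
    types, w = zip(*mixture.items())
    rows, all_segs = [], []
    for k in range(n):
        mt = types[int(rng.choice(len(types), p=np.array(w) / sum(w)))]
        calls, _, track = gene_drop(mt, snps, cl, seed=int(rng.integers(2**31)))
        t = GenotypeTable([f"i{k}"], list(snps), calls[None, :])
        segs = roh.call_rohs(t, DENSE_ROH_PARAMS)
        all_segs.extend(segs)
        rows.append(
            {
                "individual_id": f"i{k}",
                "mating_type": mt,
                "true_f": track.fraction(cl),
                "fixed_long_fraction": sum(
                    s.length_kb for s in segs if s.length_kb > 1500.0
                ) / genome_kb,
            }
        )
    df = pd.DataFrame(rows)
    df["classC_count"] = 0
    df["classC_kb"] = 0.0
    if len(all_segs) >= 50:
        bounds = roh.fit_length_mixture(all_segs, population="pooled", seed=seed)
        summ = roh.classify_population(all_segs, bounds)
        for sid, s in summ.items():
            df.loc[df["individual_id"] == sid, "classC_count"] = s.counts["C"]
            df.loc[df["individual_id"] == sid, "classC_kb"] = s.total_kb["C"]
    return df


# ---------------------------------------------------------------------------
# Bell-shape (kinship endogamy at intermediate distances)


MID_BAND_MIXTURE = {"OUT": 0.30, "1C": 0.45, "2C": 0.25}
BASE_MIXTURE = {"OUT": 0.85, "2C": 0.15}
NULL_MIXTURE = {"OUT": 0.65, "2C": 0.25, "1C": 0.10}


def bellshape_experiment(
    seed: int,
    planted: bool,
    n: int = 160,
    n_submaps: int = 6,
) -> sr.ExogamyInbreedingReport:
    """One cohort of the distance-binned design.

    ``planted=True`` elevates first/second-cousin matings among parental
    couples born 4-40 km apart (kinship endogamy); ``planted=False`` draws
    mating types independently of distance (the null design). The cohort is
    simulated on the dense panel, each individual is fitted with the submap
    estimator, ROHs are called and mixture-classified, and the
    distance-binned report is returned.
    """
    geo = GeographyModel(endogamous_fraction=0.45)
    pop = PopulationConfig(
        code="TM0",
        group="TurkoMongol",
        n=n,
        center=(46.0, 80.0),
        mixture=BASE_MIXTURE if planted else NULL_MIXTURE,
        geography=geo,
        band_mixtures=[((4.0, 40.0), MID_BAND_MIXTURE)] if planted else [],
    )
    cohort = simulate_cohort(
        [pop], seed=seed, panel_kwargs={**DENSE_PANEL_KW, "seed": seed}
    )
    table = cohort.genotypes
    snps = table.snps
    freqs = np.array([s.freq_alt for s in snps], dtype=float)
    cm = np.array([s.pos_cM for s in snps])
    chrom = np.array([s.chrom for s in snps])
    rng = np.random.default_rng(seed + 7)
    fit_rows = []
    for i, sid in enumerate(table.samples):
        fit = _fit_calls(
            table.calls[i], freqs, cm, chrom, snps, n_submaps,
            ibd.DEFAULT_EPS, seed=int(rng.integers(2**31)),
        )
        fit_rows.append(
            {"individual_id": sid, "F_Median": fit.F_Median,
             "inbred": fit.inbred}
        )
    fits = pd.DataFrame(fit_rows)

    segs = roh.call_rohs(table, DENSE_ROH_PARAMS)
    roh_df = pd.DataFrame(
        {"individual_id": table.samples, "classC_count": 0, "classC_kb": 0.0}
    )
    if len(segs) >= 50:
        try:
            bounds = roh.fit_length_mixture(segs, population="TM0", seed=seed)
            summ = roh.classify_population(segs, bounds)
            for sid, s in summ.items():
                roh_df.loc[roh_df["individual_id"] == sid, "classC_count"] = (
                    s.counts["C"]
                )
                roh_df.loc[roh_df["individual_id"] == sid, "classC_kb"] = (
                    s.total_kb["C"]
                )
        except ValueError:
            pass
    return sr.exogamy_inbreeding_report(
        cohort.survey, fits, roh_df, alternative="greater"
    )


def exogamy_recovery_experiment(
    n_couples: int = 400, exogamous_fraction: float = 0.6, seed: int = 0
) -> dict[str, float]:
    """Planted bimodal spousal-distance cohort: threshold and rate recovery.

    Endogamous mass sits at <= 1 km; the exogamous component is lognormal
    centred near 30 km. Returns the detected KDE antimode and the exogamy
    rate measured at the 4 km limit.
    """
    from . import geo_exogamy as ge

    rng = np.random.default_rng(seed)
    exo = rng.random(n_couples) < exogamous_fraction
    d = np.where(
        exo,
        rng.lognormal(math.log(30.0), 0.8, size=n_couples),
        rng.exponential(0.4, size=n_couples),
    )
    cds = [
        ge.CoupleDistance(f"c{i}", "P1", "TM", "current", float(x))
        for i, x in enumerate(d)
    ]
    grid_dens = ge.kde_log_distance(d)
    threshold = ge.find_exogamy_threshold([grid_dens])
    prof = ge.exogamy_rate(cds, 4.0)["P1"]
    return {
        "threshold_km": threshold,
        "exogamy_rate": prof.exogamy_rate,
        "planted_rate": float(exo.mean()),
        "n_couples": n_couples,
    }
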