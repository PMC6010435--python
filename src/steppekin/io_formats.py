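"""Shared data model and file I/O for the pipeline.

Supported external formats:

* PLINK text PED/MAP genotypes (biallelic autosomal SNPs only; binary BED is
  deliberately unsupported so every byte stays auditable).
* A whitespace-separated genetic map with columns
  ``chrom pos_bp rate_cM_per_Mb pos_cM`` (SHAPEIT-style dialect).
* An ethno-demographic survey CSV (one row per interviewed individual, with
  birthplace coordinates, spouse link and parental birthplaces).

Physical positions are 1-based inclusive throughout (PLINK convention) and
all reported intervals are closed ``[start_bp, end_bp]``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

MISSING = -1
"""Sentinel for a missing genotype call in :class:`GenotypeTable` matrices."""

SURVEY_COLUMNS = [
    "individual_id",
    "sex",
    "population",
    "group",
    "birth_lat",
    "birth_lon",
    "spouse_id",
    "father_birth_lat",
    "father_birth_lon",
    "mother_birth_lat",
    "mother_birth_lon",
]


class FormatError(ValueError):
    """Raised when an input file violates its documented layout."""


@dataclass
class SnpMeta:
    """Metadata for one biallelic autosomal SNP.

    ``alleles`` is ordered ``(ref, alt)``; calls count copies of ``alt``.
    """

    snp_id: str
    chrom: int
    pos_bp: int
    pos_cM: float
    alleles: tuple[str, str]
    freq_alt: Optional[float] = None

    def __post_init__(self) -> None:
        if not (1 <= self.chrom <= 22):
            raise ValueError(f"{self.snp_id}: chrom {self.chrom} is not an autosome")
        if self.pos_bp < 1:
            raise ValueError(f"{self.snp_id}: pos_bp must be >= 1")
        if self.pos_cM < 0:
            raise ValueError(f"{self.snp_id}: pos_cM must be >= 0")
        if self.freq_alt is not None and not (0.0 <= self.freq_alt <= 1.0):
            raise ValueError(f"{self.snp_id}: freq_alt outside [0, 1]")


@dataclass
class GenotypeTable:
    """Samples x SNPs alt-allele dosage matrix with SNP metadata.

    ``calls[i, j]`` is the number of alt alleles (0/1/2) carried by sample
    ``i`` at SNP ``j``, or :data:`MISSING`.
    """

    samples: list[str]
    snps: list[SnpMeta]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.snps)):
            raise ValueError(
                f"calls shape {self.calls.shape} != "
                f"({len(self.samples)}, {len(self.snps)})"
            )
        ok = np.isin(self.calls, (0, 1, 2, MISSING))
        if not ok.all():
            raise ValueError("calls must be in {0, 1, 2, missing}")
        self._check_sorted()

    def _check_sorted(self) -> None:
        last: dict[int, tuple[int, float]] = {}
        for s in self.snps:
            if s.chrom in last:
                bp, cm = last[s.chrom]
                if s.pos_bp <= bp:
                    raise ValueError(
                        f"{s.snp_id}: pos_bp not strictly increasing on chrom {s.chrom}"
                    )
                if s.pos_cM < cm:
                    raise ValueError(
                        f"{s.snp_id}: pos_cM decreasing on chrom {s.chrom}"
                    )
            last[s.chrom] = (s.pos_bp, s.pos_cM)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def sample_index(self, sample_id: str) -> int:
        return self.samples.index(sample_id)

    def chrom_indices(self, chrom: int) -> np.ndarray:
        return np.flatnonzero(np.array([s.chrom for s in self.snps]) == chrom)

    def chromosomes(self) -> list[int]:
        seen: list[int] = []
        for s in self.snps:
            if s.chrom not in seen:
                seen.append(s.chrom)
        return seen

    def alt_freqs(self, sample_idx: Optional[Sequence[int]] = None) -> np.ndarray:
        """Observed alt-allele frequency per SNP (missing calls skipped)."""
        calls = self.calls if sample_idx is None else self.calls[list(sample_idx)]
        obs = calls != MISSING
        n = 2 * obs.sum(axis=0)
        alt = np.where(obs, calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore"):
            return np.where(n > 0, alt / np.maximum(n, 1), np.nan)


@dataclass
class GeneticMap:
    """Per-chromosome arrays of physical position, genetic position and rate."""

    chroms: dict[int, dict[str, np.ndarray]] = field(default_factory=dict)

    def add_chrom(
        self, chrom: int, pos_bp: np.ndarray, pos_cM: np.ndarray, rate: np.ndarray
    ) -> None:
        pos_bp = np.asarray(pos_bp, dtype=np.int64)
        pos_cM = np.asarray(pos_cM, dtype=np.float64)
        rate = np.asarray(rate, dtype=np.float64)
        if np.any(np.diff(pos_bp) <= 0):
            raise ValueError(f"chrom {chrom}: pos_bp not strictly increasing")
        if np.any(np.diff(pos_cM) < 0):
            raise ValueError(f"chrom {chrom}: pos_cM decreasing")
        if np.any(rate < 0):
            raise ValueError(f"chrom {chrom}: negative recombination rate")
        self.chroms[chrom] = {"pos_bp": pos_bp, "pos_cM": pos_cM, "rate": rate}

    def interpolate_cM(self, chrom: int, pos_bp) -> np.ndarray | float:
        """Piecewise-linear genetic position, clamped at the map ends."""
        if chrom not in self.chroms:
            raise KeyError(f"genetic map has no chromosome {chrom}")
        c = self.chroms[chrom]
        out = np.interp(np.asarray(pos_bp, dtype=float), c["pos_bp"], c["pos_cM"])
        return float(out) if np.isscalar(pos_bp) else out

    def rate_at(self, chrom: int, pos_bp) -> np.ndarray | float:
        """Local recombination rate (cM/Mb): step function of the knot to the left."""
        if chrom not in self.chroms:
            raise KeyError(f"genetic map has no chromosome {chrom}")
        c = self.chroms[chrom]
        idx = np.clip(
            np.searchsorted(c["pos_bp"], np.asarray(pos_bp), side="right") - 1,
            0,
            len(c["pos_bp"]) - 1,
        )
        out = c["rate"][idx]
        return float(out) if np.isscalar(pos_bp) else out


@dataclass
class SurveyRecord:
    """One interviewed person: identity, geography and family links."""

    individual_id: str
    sex: str = "unknown"
    population: str = ""
    group: str = ""
    birthplace: Optional[tuple[float, float]] = None
    spouse_id: Optional[str] = None
    father_birthplace: Optional[tuple[float, float]] = None
    mother_birthplace: Optional[tuple[float, float]] = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("birthplace", "father_birthplace", "mother_birthplace"):
            pt = getattr(self, name)
            if pt is not None:
                _validate_latlon(pt, f"{self.individual_id}.{name}")


def _validate_latlon(pt: tuple[float, float], label: str) -> None:
    lat, lon = pt
    if not (-90.0 <= lat <= 90.0):
        raise FormatError(f"{label}: latitude {lat} outside [-90, 90]")
    if not (-180.0 <= lon <= 180.0):
        raise FormatError(f"{label}: longitude {lon} outside [-180, 180]")


# ---------------------------------------------------------------------------
# PED/MAP


def read_ped_map(ped_path, map_path, known_alleles=None) -> GenotypeTable:
    """Read PLINK text PED/MAP into a :class:`GenotypeTable`.

    Allele orientation: if ``known_alleles`` (a ``(ref, alt)`` pair per SNP,
    e.g. from an accompanying frequency file) is given it fixes the coding;
    otherwise alt is the *minor* allele over the file (ties broken by
    first-seen order). Monomorphic sites code the observed allele as ref.
    ``0 0`` is the missing genotype.
    """
    snps = _read_map(map_path)
    n_snps = len(snps)

    samples: list[str] = []
    raw_alleles: list[list[tuple[str, str]]] = []
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, start=1):
            tok = line.split()
            if not tok:
                continue
            if len(tok) != 6 + 2 * n_snps:
                raise FormatError(
                    f"{ped_path}:{ln}: expected {6 + 2 * n_snps} columns "
                    f"(6 + 2 x {n_snps} SNPs), found {len(tok)}"
                )
            samples.append(tok[1])
            g = tok[6:]
            raw_alleles.append([(g[2 * j], g[2 * j + 1]) for j in range(n_snps)])

    # determine the two observed alleles and their counts per site
    calls = np.full((len(samples), n_snps), MISSING, dtype=np.int8)
    for j in range(n_snps):
        counts: dict[str, int] = {}
        for row in raw_alleles:
            for a in row[j]:
                if a != "0":
                    counts[a] = counts.get(a, 0) + 1
        if len(counts) > 2:
            raise FormatError(
                f"SNP {snps[j].snp_id}: more than two alleles observed "
                f"({sorted(counts)})"
            )
        seen = list(counts)
        if known_alleles is not None:
            alleles = tuple(known_alleles[j])
            extra = [a for a in seen if a not in alleles]
            if extra:
                raise FormatError(
                    f"SNP {snps[j].snp_id}: allele(s) {extra} not in the "
                    f"declared pair {alleles}"
                )
        elif len(seen) == 0:
            alleles = ("0", "0")
        elif len(seen) == 1:
            alleles = (seen[0], ".")  # monomorphic: alt never observed
        else:
            # alt = minor allele; tie keeps first-seen order
            if counts[seen[1]] <= counts[seen[0]]:
                alleles = (seen[0], seen[1])
            else:
                alleles = (seen[1], seen[0])
        snps[j].alleles = alleles
        alt = alleles[1]
        for i, row in enumerate(raw_alleles):
            a1, a2 = row[j]
            if a1 == "0" or a2 == "0":
                continue
            calls[i, j] = (a1 == alt) + (a2 == alt)
    return GenotypeTable(samples=samples, snps=snps, calls=calls)


def _read_map(map_path) -> list[SnpMeta]:
    snps: list[SnpMeta] = []
    with open(map_path) as fh:
        for ln, line in enumerate(fh, start=1):
            tok = line.split()
            if not tok:
                continue
            if len(tok) != 4:
                raise FormatError(f"{map_path}:{ln}: MAP needs 4 columns")
            chrom, snp_id, cm, bp = tok
            snps.append(
                SnpMeta(
                    snp_id=snp_id,
                    chrom=int(chrom),
                    pos_cM=float(cm),
                    pos_bp=int(bp),
                    alleles=("A", "B"),
                )
            )
    return snps


def write_ped_map(table: GenotypeTable, ped_path, map_path) -> None:
    """Write a :class:`GenotypeTable` as PLINK text PED/MAP.

    Families are single-individual (FID = IID); missing calls become ``0 0``.
    """
    with open(map_path, "w") as fh:
        for s in table.snps:
            fh.write(f"{s.chrom}\t{s.snp_id}\t{s.pos_cM:.6f}\t{s.pos_bp}\n")
    with open(ped_path, "w") as fh:
        for i, sid in enumerate(table.samples):
            fields = [sid, sid, "0", "0", "0", "-9"]
            for j, s in enumerate(table.snps):
                ref, alt = s.alleles
                g = table.calls[i, j]
                if g == MISSING:
                    fields += ["0", "0"]
                elif g == 0:
                    fields += [ref, ref]
                elif g == 1:
                    fields += [ref, alt]
                else:
                    fields += [alt, alt]
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Genetic map file


def read_genetic_map(path) -> GeneticMap:
    """Read a ``chrom pos_bp rate_cM_per_Mb pos_cM`` whitespace table."""
    df = pd.read_csv(path, sep=r"\s+")
    expected = ["chrom", "pos_bp", "rate_cM_per_Mb", "pos_cM"]
    if list(df.columns) != expected:
        raise FormatError(f"{path}: header must be {' '.join(expected)}")
    gm = GeneticMap()
    for chrom, sub in df.groupby("chrom", sort=True):
        sub = sub.sort_values("pos_bp")
        gm.add_chrom(
            int(chrom),
            sub["pos_bp"].to_numpy(),
            sub["pos_cM"].to_numpy(),
            sub["rate_cM_per_Mb"].to_numpy(),
        )
    return gm


def write_genetic_map(gmap: GeneticMap, path) -> None:
    rows = []
    for chrom in sorted(gmap.chroms):
        c = gmap.chroms[chrom]
        for bp, cm, r in zip(c["pos_bp"], c["pos_cM"], c["rate"]):
            rows.append((chrom, bp, r, cm))
    df = pd.DataFrame(rows, columns=["chrom", "pos_bp", "rate_cM_per_Mb", "pos_cM"])
    df.to_csv(path, sep=" ", index=False)


def genetic_map_from_snps(
    snps: Sequence[SnpMeta], default_rate: float = 1.0
) -> GeneticMap:
    """Build a map whose knots are the SNPs themselves (rate from finite differences)."""
    gm = GeneticMap()
    by_chrom: dict[int, list[SnpMeta]] = {}
    for s in snps:
        by_chrom.setdefault(s.chrom, []).append(s)
    for chrom, ss in by_chrom.items():
        bp = np.array([s.pos_bp for s in ss], dtype=np.int64)
        cm = np.array([s.pos_cM for s in ss], dtype=np.float64)
        if len(bp) > 1:
            rate = np.empty(len(bp))
            rate[:-1] = np.diff(cm) / np.maximum(np.diff(bp) / 1e6, 1e-12)
            rate[-1] = rate[-2] if len(bp) > 2 else rate[0]
        else:
            rate = np.full(len(bp), default_rate)
        gm.add_chrom(chrom, bp, cm, rate)
    return gm


# ---------------------------------------------------------------------------
# Survey CSV


def _opt_point(row, lat_col: str, lon_col: str, line: int):
    lat, lon = row.get(lat_col), row.get(lon_col)
    if pd.isna(lat) or pd.isna(lon):
        return None
    try:
        return (float(lat), float(lon))
    except (TypeError, ValueError) as exc:
        raise FormatError(f"survey line {line}: bad coordinate pair") from exc


def read_survey(csv_path) -> list[SurveyRecord]:
    """Read the survey CSV (header :data:`SURVEY_COLUMNS`, extra columns kept).

    Raises :class:`FormatError` with the offending line number for coordinates
    outside their valid ranges, and checks that spouse links are symmetric
    whenever both members of a couple appear in the table.
    """
    df = pd.read_csv(csv_path, dtype={"individual_id": str, "spouse_id": str})
    missing_cols = [c for c in SURVEY_COLUMNS if c not in df.columns]
    if missing_cols:
        raise FormatError(f"{csv_path}: missing survey columns {missing_cols}")
    extra_cols = [c for c in df.columns if c not in SURVEY_COLUMNS]

    records: list[SurveyRecord] = []
    for i, row in df.iterrows():
        line = int(i) + 2  # header is line 1
        try:
            rec = SurveyRecord(
                individual_id=str(row["individual_id"]),
                sex=str(row["sex"]) if pd.notna(row["sex"]) else "unknown",
                population=str(row["population"]),
                group=str(row["group"]),
                birthplace=_opt_point(row, "birth_lat", "birth_lon", line),
                spouse_id=str(row["spouse_id"]) if pd.notna(row["spouse_id"]) else None,
                father_birthplace=_opt_point(
                    row, "father_birth_lat", "father_birth_lon", line
                ),
                mother_birthplace=_opt_point(
                    row, "mother_birth_lat", "mother_birth_lon", line
                ),
                extra={c: row[c] for c in extra_cols},
            )
        except FormatError as exc:
            raise FormatError(f"survey line {line}: {exc}") from exc
        records.append(rec)

    by_id = {r.individual_id: r for r in records}
    for r in records:
        if r.spouse_id is not None and r.spouse_id in by_id:
            back = by_id[r.spouse_id].spouse_id
            if back is not None and back != r.individual_id:
                raise FormatError(
                    f"asymmetric spouse link: {r.individual_id} -> {r.spouse_id} "
                    f"but {r.spouse_id} -> {back}"
                )
    return records


def write_survey(records: Sequence[SurveyRecord], csv_path) -> None:
    rows = []
    for r in records:
        row = {
            "individual_id": r.individual_id,
            "sex": r.sex,
            "population": r.population,
            "group": r.group,
            "birth_lat": r.birthplace[0] if r.birthplace else math.nan,
            "birth_lon": r.birthplace[1] if r.birthplace else math.nan,
            "spouse_id": r.spouse_id,
            "father_birth_lat": r.father_birthplace[0] if r.father_birthplace else math.nan,
            "father_birth_lon": r.father_birthplace[1] if r.father_birthplace else math.nan,
            "mother_birth_lat": r.mother_birthplace[0] if r.mother_birthplace else math.nan,
            "mother_birth_lon": r.mother_birthplace[1] if r.mother_birthplace else math.nan,
        }
        row.update(r.extra)
        rows.append(row)
    pd.DataFrame(rows).to_csv(csv_path, index=False)


def interpolate_cM(gmap: GeneticMap, chrom: int, pos_bp):
    """Functional alias for :meth:`GeneticMap.interpolate_cM`."""
    return gmap.interpolate_cM(chrom, pos_bp)
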