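"""Forward pedigree simulator for a CMS–restorer crossing design.

Generates genotype/phenotype/pedigree datasets with the statistical structure
the analysis assumes: biallelic markers coded by population of origin (S/M),
transmission-ratio-distortion (TRD) blocks produced by gametic selection at a
driving locus with linked hitchhiking, a restorer locus at the top of
chromosome 2 whose nonrestorer allele is over-transmitted, Bernoulli
restoration of nonrestorer homozygotes, and pollen-count phenotypes with the
discontinuity at 10 grains that separates male-sterile plants.

Alleles are origin codes: 0 = S (Spiterstulen-like, carries the restorer at
the Rf locus), 1 = M (Mayodan-like, nonrestoring).  Genotypes are stored
phased as maternal/paternal haplotype arrays, which the gamete simulator
requires.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import MA, SP_CMS, CytoplasmType, ModelParams

S, M = 0, 1
ORIGIN = np.array(["S", "M"])


# ---------------------------------------------------------------------------
# Map function


def kosambi_recfrac(d_cm: float | np.ndarray) -> float | np.ndarray:
    """Kosambi map function: recombination fraction for a distance in cM.

    r = 0.5 tanh(2d) with d in Morgans; allows positive interference.
    """
    d = np.asarray(d_cm, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be nonnegative")
    r = 0.5 * np.tanh(d / 50.0)
    return float(r) if np.isscalar(d_cm) else r


def kosambi_cm(r: float | np.ndarray) -> float | np.ndarray:
    """Inverse Kosambi: distance in cM for a recombination fraction < 0.5."""
    rr = np.asarray(r, dtype=float)
    if np.any((rr < 0) | (rr >= 0.5)):
        raise ValueError("recombination fraction must be in [0, 0.5)")
    d = 25.0 * np.log((1 + 2 * rr) / (1 - 2 * rr))
    return float(d) if np.isscalar(r) else d


# ---------------------------------------------------------------------------
# Marker map


@dataclass(frozen=True)
class MarkerMap:
    """Gene-level marker map: id, chromosome, Kosambi cM position, panel flag.

    ``in_panel`` marks loci exported to the genotype matrix; the Rf locus
    itself is carried as a hidden locus so simulation truth stays available
    while the SNP panel only brackets it, as in a real fine-mapping design.
    """

    table: pd.DataFrame  # index: marker id; columns: chrom, pos_cm, in_panel
    rf_locus: str | None = None
    restorer_origin: int = S  # which origin code carries the restorer allele

    def __post_init__(self) -> None:
        t = self.table
        for col in ("chrom", "pos_cm", "in_panel"):
            if col not in t.columns:
                raise ValueError(f"map table lacks column {col!r}")
        for _, sub in t.groupby("chrom", sort=False):
            if not sub["pos_cm"].is_monotonic_increasing or sub["pos_cm"].duplicated().any():
                raise ValueError("positions must be strictly increasing within chromosome")
        if self.rf_locus is not None and self.rf_locus not in t.index:
            raise ValueError(f"Rf locus {self.rf_locus!r} not in map")

    @property
    def markers(self) -> list[str]:
        return list(self.table.index)

    @property
    def n_loci(self) -> int:
        return len(self.table)

    @property
    def chromosomes(self) -> list:
        return list(dict.fromkeys(self.table["chrom"]))

    @property
    def panel_markers(self) -> list[str]:
        return list(self.table.index[self.table["in_panel"]])

    def index_of(self, marker: str) -> int:
        return int(self.table.index.get_loc(marker))


@dataclass(frozen=True)
class TrdSpec:
    """Gametic selection at a driving locus: the favored origin allele is
    transmitted by heterozygotes with probability tau; both sexes by default."""

    locus: str
    tau: float
    favored: int = M
    parents: str = "both"  # "both" | "mother" | "father"

    def __post_init__(self) -> None:
        if not 0.0 <= self.tau <= 1.0:
            raise ValueError(f"tau={self.tau} outside [0, 1]")
        if self.favored not in (S, M):
            raise ValueError("favored must be the S or M origin code")
        if self.parents not in ("both", "mother", "father"):
            raise ValueError(f"bad parents spec {self.parents!r}")


def default_marker_map(rf_tau_position: float = 3.2) -> MarkerMap:
    """The default 8-chromosome template: 75 panel genes spaced 10–20 cM with
    densification at the top of chromosome 2, plus the hidden Rf locus."""
    lengths = {1: 90, 2: 78, 3: 85, 4: 75, 5: 70, 6: 65, 7: 70, 8: 60}
    counts = {1: 11, 2: 13, 3: 10, 4: 8, 5: 9, 6: 7, 7: 9, 8: 8}  # = 75
    rows = []
    for c in range(1, 9):
        if c == 2:
            dense = [0.0, 1.5, 2.6, 4.1, 5.5, 8.0, 12.0]
            rest = list(np.linspace(20.0, lengths[2], counts[2] - len(dense)))
            pos = dense + rest
        else:
            pos = list(np.linspace(0.0, lengths[c], counts[c]))
        for i, p in enumerate(pos, start=1):
            rows.append((f"G{c}_{i:02d}", c, round(float(p), 3), True))
    rows.append(("RF", 2, rf_tau_position, False))
    df = pd.DataFrame(rows, columns=["marker", "chrom", "pos_cm", "in_panel"])
    df = df.sort_values(["chrom", "pos_cm"]).set_index("marker")
    return MarkerMap(df, rf_locus="RF", restorer_origin=S)


def default_trd_template(map_: MarkerMap, rf_tau: float = 0.575) -> tuple[TrdSpec, ...]:
    """Representative TRD blocks: S alleles favored on chromosomes 1, 3, 7, 8
    and M alleles on chromosomes 2 (the Rf block) and 4, with transmission in
    the 0.39–0.6 range.  The per-block values are template configuration, not
    a reconstruction of any observed genome-wide profile."""
    return (
        TrdSpec("G1_06", 0.56, favored=S),
        TrdSpec(map_.rf_locus or "RF", rf_tau, favored=M),
        TrdSpec("G3_05", 0.55, favored=S),
        TrdSpec("G4_04", 0.58, favored=M),
        TrdSpec("G7_04", 0.57, favored=S),
        TrdSpec("G8_04", 0.54, favored=S),
    )


# ---------------------------------------------------------------------------
# Individuals and cohorts


@dataclass(frozen=True)
class PhenotypeRecord:
    """Pollen counts from one 0.075 µl subsample.

    Viability (viable/total) is defined only for plants with at least 10
    grains; male-sterile plants have no viable-count entry.
    """

    pollen_total: int | None = None
    pollen_viable: int | None = None
    fertility_class: str = "unscored"

    def __post_init__(self) -> None:
        if self.pollen_total is not None and self.pollen_total < 0:
            raise ValueError("negative pollen count")
        if self.pollen_viable is not None:
            if self.pollen_total is None or not 0 <= self.pollen_viable <= self.pollen_total:
                raise ValueError("viable count must satisfy 0 <= viable <= total")
            if self.pollen_total < 10:
                raise ValueError("viability is reported only for totals >= 10")


@dataclass(frozen=True)
class Individual:
    """One simulated plant (a row view of a :class:`Cohort`)."""

    id: str
    cytoplasm: CytoplasmType
    genotype: Mapping[str, tuple[str, str]]  # marker -> (maternal, paternal) origin
    phenotype: PhenotypeRecord
    mother: str | None
    father: str | None

    def rf_class(self, map_: MarkerMap) -> str:
        if map_.rf_locus is None:
            raise ValueError("map has no Rf locus")
        a, b = self.genotype[map_.rf_locus]
        r = ORIGIN[map_.restorer_origin]
        n_r = (a == r) + (b == r)
        return ("mm", "Rm", "RR")[n_r]


class Cohort:
    """A set of same-cross individuals stored as phased haplotype arrays."""

    def __init__(
        self,
        ids: Sequence[str],
        cross: str,
        cytoplasm: CytoplasmType,
        mat: np.ndarray,
        pat: np.ndarray,
        map_: MarkerMap,
        mother_ids: Sequence[str | None],
        father_ids: Sequence[str | None],
        fertility: np.ndarray | None = None,
    ):
        n = len(ids)
        if mat.shape != (n, map_.n_loci) or pat.shape != (n, map_.n_loci):
            raise ValueError("haplotype array shape mismatch")
        self.ids = list(ids)
        self.cross = cross
        self.cytoplasm = cytoplasm
        self.mat = mat
        self.pat = pat
        self.map = map_
        self.mother_ids = list(mother_ids)
        self.father_ids = list(father_ids)
        self.fertility = fertility if fertility is not None else np.full(n, "", dtype="<U8")
        self.pollen_total = np.full(n, -1, dtype=int)  # -1 = unscored
        self.pollen_viable = np.full(n, -1, dtype=int)  # -1 = undefined

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def rf_index(self) -> int:
        if self.map.rf_locus is None:
            raise ValueError("map has no Rf locus")
        return self.map.index_of(self.map.rf_locus)

    def rf_classes(self) -> np.ndarray:
        """Restorer-locus genotype class per individual ('RR'/'Rm'/'mm')."""
        j, r = self.rf_index, self.map.restorer_origin
        n_r = (self.mat[:, j] == r).astype(int) + (self.pat[:, j] == r).astype(int)
        return np.array(["mm", "Rm", "RR"])[n_r]

    def genotype_codes(self, panel_only: bool = True) -> pd.DataFrame:
        """Unphased origin genotypes ('SS'/'SM'/'MM') as a DataFrame."""
        lo = np.minimum(self.mat, self.pat)
        hi = np.maximum(self.mat, self.pat)
        codes = np.char.add(ORIGIN[lo], ORIGIN[hi])
        df = pd.DataFrame(codes, index=self.ids, columns=self.map.markers)
        if panel_only:
            df = df[self.map.panel_markers]
        return df

    def subset(self, mask: np.ndarray) -> "Cohort":
        idx = np.flatnonzero(mask)
        sub = Cohort(
            [self.ids[i] for i in idx], self.cross, self.cytoplasm,
            self.mat[idx], self.pat[idx], self.map,
            [self.mother_ids[i] for i in idx], [self.father_ids[i] for i in idx],
            self.fertility[idx].copy(),
        )
        sub.pollen_total = self.pollen_total[idx].copy()
        sub.pollen_viable = self.pollen_viable[idx].copy()
        return sub

    def __getitem__(self, i: int) -> Individual:
        geno = {
            mk: (str(ORIGIN[self.mat[i, j]]), str(ORIGIN[self.pat[i, j]]))
            for j, mk in enumerate(self.map.markers)
        }
        tot = None if self.pollen_total[i] < 0 else int(self.pollen_total[i])
        via = None if self.pollen_viable[i] < 0 else int(self.pollen_viable[i])
        fert = self.fertility[i] or "unscored"
        return Individual(
            self.ids[i], self.cytoplasm, geno,
            PhenotypeRecord(tot, via, fert),
            self.mother_ids[i], self.father_ids[i],
        )

    def __iter__(self):
        return (self[i] for i in range(len(self)))


def founder(pop: int, cyt: CytoplasmType, map_: MarkerMap, id_: str, cross: str = "P") -> Cohort:
    """A homozygous founder individual of origin ``pop`` (S or M)."""
    hap = np.full((1, map_.n_loci), pop, dtype=np.uint8)
    c = Cohort([id_], cross, cyt, hap.copy(), hap.copy(), map_, [None], [None])
    c.fertility[:] = "H"
    return c


# ---------------------------------------------------------------------------
# Gamete and cross simulation


def _chrom_blocks(map_: MarkerMap, trd: Sequence[TrdSpec], parent_role: str):
    """Per-chromosome marker indices, interval rec fracs, and driver info."""
    blocks = []
    pos = map_.table["pos_cm"].to_numpy()
    for c in map_.chromosomes:
        idx = np.flatnonzero((map_.table["chrom"] == c).to_numpy())
        r = kosambi_recfrac(np.diff(pos[idx]))
        driver = None
        for spec in trd:
            if spec.parents not in ("both", parent_role):
                continue
            j = map_.index_of(spec.locus)
            if j in idx:
                if driver is not None:
                    raise ValueError(f"multiple TRD drivers on chromosome {c}")
                driver = (int(np.flatnonzero(idx == j)[0]), spec.tau, spec.favored)
        blocks.append((idx, np.atleast_1d(r), driver))
    return blocks


def _walk(start_hap: np.ndarray, recs: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Haplotype indicator along consecutive intervals from a start column."""
    n, k = start_hap.shape[0], recs.shape[0]
    if k == 0:
        return start_hap[:, None]
    switches = rng.random((n, k)) < recs[None, :]
    parity = np.cumsum(switches, axis=1) % 2
    return np.concatenate([start_hap[:, None], start_hap[:, None] ^ parity], axis=1)


def gametes_for(
    mat: np.ndarray,
    pat: np.ndarray,
    map_: MarkerMap,
    trd: Sequence[TrdSpec],
    rng: np.random.Generator,
    parent_role: str = "mother",
) -> np.ndarray:
    """One gamete per row of phased parent haplotypes.

    At a TRD driving locus the transmitted haplotype of a heterozygous parent
    carries the favored allele with probability tau; flanking markers are
    filled outward by interval-wise Kosambi recombination conditional on the
    drawn allele, so distortion hitchhikes and decays with map distance.
    """
    n, L = mat.shape
    out = np.empty((n, L), dtype=np.uint8)
    for idx, recs, driver in _chrom_blocks(map_, trd, parent_role):
        mat_c, pat_c = mat[:, idx], pat[:, idx]
        if driver is None:
            s = 0
            start = (rng.random(n) < 0.5).astype(np.uint8)
        else:
            s, tau, fav = driver
            het = mat_c[:, s] != pat_c[:, s]
            hap_fav = (pat_c[:, s] == fav).astype(np.uint8)  # 0 if maternal hap favored
            u = rng.random(n)
            coin = (rng.random(n) < 0.5).astype(np.uint8)
            start = np.where(het, np.where(u < tau, hap_fav, 1 - hap_fav), coin).astype(np.uint8)
        right = _walk(start, recs[s:], rng)            # columns s..end
        left = _walk(start, recs[:s][::-1], rng)       # columns s..0 mirrored
        hap = np.concatenate([left[:, :0:-1], right], axis=1)
        out[:, idx] = np.where(hap == 0, mat_c, pat_c)
    return out


def simulate_gamete(
    parent: Cohort | Individual,
    map_: MarkerMap,
    trd: Sequence[TrdSpec],
    rng: np.random.Generator,
    n: int = 1,
    parent_role: str = "mother",
) -> np.ndarray:
    """``n`` gametes from one parent; rows are origin-coded haplotypes."""
    if isinstance(parent, Individual):
        mat = np.array([[ORIGIN.tolist().index(parent.genotype[mk][0]) for mk in map_.markers]], dtype=np.uint8)
        pat = np.array([[ORIGIN.tolist().index(parent.genotype[mk][1]) for mk in map_.markers]], dtype=np.uint8)
    else:
        mat, pat = parent.mat[:1], parent.pat[:1]
    return gametes_for(
        np.repeat(mat, n, axis=0), np.repeat(pat, n, axis=0), map_, trd, rng, parent_role
    )


def _assign_fertility(
    cohort: Cohort, mother_carries_r: np.ndarray, params: ModelParams, rng: np.random.Generator
) -> None:
    n = len(cohort)
    if not cohort.cytoplasm.carries_cms:
        cohort.fertility[:] = "H"
        return
    carrier = cohort.rf_classes() != "mm"
    r = np.where(mother_carries_r, params.r_r, params.r_n)
    restored = rng.random(n) < r
    cohort.fertility[:] = np.where(carrier | restored, "H", "MS")


def simulate_cross(
    mother: Cohort,
    father: Cohort,
    n: int,
    params: ModelParams,
    rng: np.random.Generator,
    trd: Sequence[TrdSpec] = (),
    cross: str | None = None,
    id_prefix: str | None = None,
) -> Cohort:
    """``n`` offspring of one mother x one father (first row of each cohort).

    Offspring cytoplasm is the mother's; fertility class is assigned by the
    dominant-restorer rule with Bernoulli restoration of mm offspring (r_R if
    the mother carries a restorer allele, r_N otherwise).
    """
    if n < 0:
        raise ValueError("n must be nonnegative")
    map_ = mother.map
    label = cross or f"{mother.cross}x{father.cross}"
    prefix = id_prefix or label
    mat = gametes_for(np.repeat(mother.mat[:1], n, axis=0), np.repeat(mother.pat[:1], n, axis=0),
                      map_, trd, rng, "mother")
    pat = gametes_for(np.repeat(father.mat[:1], n, axis=0), np.repeat(father.pat[:1], n, axis=0),
                      map_, trd, rng, "father")
    out = Cohort(
        [f"{prefix}_{i:05d}" for i in range(n)], label, mother.cytoplasm,
        mat, pat, map_, [mother.ids[0]] * n, [father.ids[0]] * n,
    )
    mc = np.repeat(mother.rf_classes()[:1] != "mm", n)
    _assign_fertility(out, mc, params, rng)
    return out


def cross_per_mother(
    mothers: Cohort,
    father: Cohort,
    params: ModelParams,
    rng: np.random.Generator,
    trd: Sequence[TrdSpec] = (),
    cross: str | None = None,
    id_prefix: str | None = None,
) -> Cohort:
    """One offspring per mother row, all sired by one father."""
    n = len(mothers)
    map_ = mothers.map
    label = cross or f"{mothers.cross}x{father.cross}"
    prefix = id_prefix or label
    mat = gametes_for(mothers.mat, mothers.pat, map_, trd, rng, "mother")
    pat = gametes_for(np.repeat(father.mat[:1], n, axis=0), np.repeat(father.pat[:1], n, axis=0),
                      map_, trd, rng, "father")
    out = Cohort(
        [f"{prefix}_{i:05d}" for i in range(n)], label, mothers.cytoplasm,
        mat, pat, map_, list(mothers.ids), [father.ids[0]] * n,
    )
    _assign_fertility(out, mothers.rf_classes() != "mm", params, rng)
    return out


# ---------------------------------------------------------------------------
# Pollen phenotypes


@dataclass(frozen=True)
class PollenCalibration:
    """Target median pollen count, negative-binomial shape, and viability."""

    median: float
    shape: float = 2.5
    viability: float = 0.92


#: Medians/viabilities per group: parental cohorts by population, hybrids by
#: cytoplasm (F2-calibrated values stand in for all hybrid generations).
DEFAULT_CALIBRATION: dict[str, PollenCalibration] = {
    "P_Sp": PollenCalibration(75.9, 2.5, 0.914),
    "P_Ma": PollenCalibration(109.6, 2.5, 0.926),
    "cyt:Sp": PollenCalibration(59.7, 2.5, 0.914),
    "cyt:Sp4": PollenCalibration(59.7, 2.5, 0.914),
    "cyt:Ma": PollenCalibration(70.3, 2.5, 0.926),
}

_MS_WEIGHTS = 0.65 ** np.arange(10)
_MS_WEIGHTS = _MS_WEIGHTS / _MS_WEIGHTS.sum()


@lru_cache(maxsize=64)
def _nbinom_for_median(median: float, shape: float) -> tuple[float, float]:
    """(n, p) of a negative binomial whose median hits the target."""
    lo, hi = 1.0, max(10.0, 8.0 * median)
    for _ in range(80):
        mu = 0.5 * (lo + hi)
        p = shape / (shape + mu)
        if stats.nbinom.median(shape, p) < median:
            lo = mu
        else:
            hi = mu
    mu = 0.5 * (lo + hi)
    return shape, shape / (shape + mu)


def _resolve_calibration(cohort: Cohort, calibration: Mapping[str, PollenCalibration]) -> PollenCalibration:
    for key in (cohort.cross, f"cyt:{cohort.cytoplasm.label}"):
        if key in calibration:
            return calibration[key]
    raise KeyError(f"no pollen calibration for group {cohort.cross!r} / cytoplasm {cohort.cytoplasm.label!r}")


def simulate_phenotypes(
    cohort: Cohort,
    rng: np.random.Generator,
    calibration: Mapping[str, PollenCalibration] | None = None,
) -> Cohort:
    """Draw pollen counts in place: male-sterile plants from a low distribution
    on 0–9 grains (weighted toward 0), hermaphrodites from an overdispersed
    negative binomial truncated at >= 10 so the 10-grain discontinuity is
    exact; viable counts are binomial at the calibrated viability."""
    if np.any(cohort.fertility == ""):
        raise ValueError("fertility class must be assigned before phenotypes")
    cal = _resolve_calibration(cohort, calibration or DEFAULT_CALIBRATION)
    n = len(cohort)
    ms = cohort.fertility == "MS"
    total = np.empty(n, dtype=int)
    total[ms] = rng.choice(10, size=int(ms.sum()), p=_MS_WEIGHTS)
    k, p = _nbinom_for_median(cal.median, cal.shape)
    n_h = int((~ms).sum())
    lo = stats.nbinom.cdf(9, k, p)
    u = lo + rng.random(n_h) * (1.0 - lo)
    total[~ms] = stats.nbinom.ppf(u, k, p).astype(int)
    cohort.pollen_total = total
    viable = np.full(n, -1, dtype=int)
    viable[~ms] = rng.binomial(total[~ms], cal.viability)
    cohort.pollen_viable = viable
    return cohort


# ---------------------------------------------------------------------------
# Whole-study simulation


#: Flowering-plant counts of the main crossing family (reciprocal F2s, the
#: four BC1 pseudobackcrosses, BC2/BC3 split by maternal phenotype, parents
#: and F1 controls).
DEFAULT_SIZES: dict[str, int] = {
    "P_Sp": 127,
    "P_Ma": 117,
    "F1_SpMa": 237,
    "F1_MaSp": 305,
    "F2_SpMa": 694,
    "F2_MaSp": 1317,
    "BC1_[SpMa]Ma": 113,
    "BC1_[SpMa]Sp": 75,
    "BC1_[MaSp]Ma": 256,
    "BC1_[MaSp]Sp": 181,
    "BC2_H": 1031,
    "BC2_MS": 249,
    "BC3_H": 467,
    "BC3_MS": 242,
}


@dataclass(frozen=True)
class StudyConfig:
    """Design template + parameters for :func:`simulate_study`."""

    template: str = "main_family"
    params: ModelParams = field(default_factory=lambda: ModelParams(tau=0.575, r_r=0.4, r_n=0.4))
    sizes: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_SIZES))
    n_bc1_mothers: int = 91
    n_bc2_mothers: int = 37
    missing_rate: float = 0.016
    n_snps: int = 96
    n_outliers: int = 0
    rf_position_cm: float = 3.2

    def __post_init__(self) -> None:
        if self.template != "main_family":
            raise ValueError(f"unknown design template {self.template!r}")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate outside [0, 1)")

    @classmethod
    def from_dict(cls, d: Mapping) -> "StudyConfig":
        d = dict(d)
        if "params" in d and not isinstance(d["params"], ModelParams):
            d["params"] = ModelParams(**d["params"])
        return cls(**d)


@dataclass
class StudyResult:
    """Simulated study: per-cross cohorts plus the exported dataset tables."""

    cohorts: dict[str, Cohort]
    dataset: "object"  # cmsrf.io.Dataset; typed loosely to avoid import cycle
    map: MarkerMap
    trd: tuple[TrdSpec, ...]
    config: StudyConfig
    seed: int


def snp_panel(map_: MarkerMap, n_snps: int) -> pd.DataFrame:
    """Assign 1–2 SNPs per panel gene (``n_snps`` total), as in a design that
    genotypes multiple SNPs in some genes and combines them afterwards."""
    genes = map_.panel_markers
    extra = n_snps - len(genes)
    if extra < 0 or extra > len(genes):
        raise ValueError("n_snps must be between n_genes and 2*n_genes")
    rows = []
    for i, g in enumerate(genes):
        rows.append((f"{g}.1", g))
        if i < extra:
            rows.append((f"{g}.2", g))
    df = pd.DataFrame(rows, columns=["snp", "gene"]).set_index("snp")
    df["chrom"] = map_.table.loc[df["gene"], "chrom"].to_numpy()
    df["pos_cm"] = map_.table.loc[df["gene"], "pos_cm"].to_numpy()
    return df


def _expand_to_snps(gene_codes: pd.DataFrame, panel: pd.DataFrame) -> pd.DataFrame:
    return pd.DataFrame(
        {snp: gene_codes[gene] for snp, gene in panel["gene"].items()},
        index=gene_codes.index,
    )


def inject_singleton_switches(
    genotypes: pd.DataFrame,
    map_like: pd.DataFrame,
    individuals: Sequence[str],
    n_events: Sequence[int],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Corrupt chosen individuals with isolated genotype switches (apparent
    double recombinants), for QC testing.  ``map_like`` needs chrom/pos_cm."""
    out = genotypes.copy()
    order = map_like.sort_values(["chrom", "pos_cm"]).index
    order = [m for m in order if m in out.columns]
    chrom = map_like.loc[order, "chrom"].to_numpy()
    cycle = {"SS": "MM", "SM": "SS", "MM": "SM"}
    for ind, k in zip(individuals, n_events):
        interior = [
            j for j in range(1, len(order) - 1)
            if chrom[j - 1] == chrom[j] == chrom[j + 1]
        ]
        sites = rng.choice(len(interior), size=k, replace=False)
        for s in sites:
            mk = order[interior[s]]
            cur = out.at[ind, mk]
            if cur in cycle:
                out.at[ind, mk] = cycle[cur]
    return out


def simulate_study(config: StudyConfig | None = None, seed: int = 0) -> StudyResult:
    """Simulate the full crossing design and export dataset tables.

    Deterministic for a fixed seed.  The genotype matrix covers the SNP panel
    (gene-level genotypes repeated per SNP) with Bernoulli missingness at the
    configured rate; the pedigree table carries the true Rf genotype class of
    every plant for validation against marker-based inference.
    """
    from .io import Dataset  # local import; io has no compile-time dep on simulate

    config = config or StudyConfig()
    rng = np.random.default_rng(seed)
    params = config.params
    map_ = default_marker_map(config.rf_position_cm)
    trd = default_trd_template(map_, rf_tau=params.tau)
    sz = dict(DEFAULT_SIZES, **dict(config.sizes))

    sp = founder(S, SP_CMS, map_, "Sp_founder", cross="P_Sp")
    ma = founder(M, MA, map_, "Ma_founder", cross="P_Ma")
    sp_cy_ma = founder(S, MA, map_, "Sp_donor", cross="P_Sp")  # Sp pollen donor

    cohorts: dict[str, Cohort] = {}

    def parental(label: str, base: Cohort) -> Cohort:
        n = sz[label]
        c = Cohort(
            [f"{label}_{i:05d}" for i in range(n)], label, base.cytoplasm,
            np.repeat(base.mat, n, axis=0), np.repeat(base.pat, n, axis=0),
            map_, [None] * n, [None] * n,
        )
        c.fertility[:] = "H"
        return c

    cohorts["P_Sp"] = parental("P_Sp", sp)
    cohorts["P_Ma"] = parental("P_Ma", ma)

    # F1: reciprocal hybrids; heterozygous everywhere, cytoplasm from mother.
    f1_spma = simulate_cross(sp, ma, sz["F1_SpMa"], params, rng, trd, "F1_SpMa", "F1_SpMa")
    f1_masp = simulate_cross(ma, sp_cy_ma, sz["F1_MaSp"], params, rng, trd, "F1_MaSp", "F1_MaSp")
    cohorts["F1_SpMa"], cohorts["F1_MaSp"] = f1_spma, f1_masp

    f2_spma = simulate_cross(f1_spma, f1_masp, sz["F2_SpMa"], params, rng, trd, "F2_SpMa", "F2_SpMa")
    f2_masp = simulate_cross(f1_masp, f1_spma, sz["F2_MaSp"], params, rng, trd, "F2_MaSp", "F2_MaSp")
    cohorts["F2_SpMa"], cohorts["F2_MaSp"] = f2_spma, f2_masp

    cohorts["BC1_[SpMa]Ma"] = simulate_cross(f1_spma, ma, sz["BC1_[SpMa]Ma"], params, rng, trd,
                                             "BC1_[SpMa]Ma", "BC1a")
    cohorts["BC1_[SpMa]Sp"] = simulate_cross(f1_spma, sp_cy_ma, sz["BC1_[SpMa]Sp"], params, rng, trd,
                                             "BC1_[SpMa]Sp", "BC1b")
    cohorts["BC1_[MaSp]Ma"] = simulate_cross(f1_masp, ma, sz["BC1_[MaSp]Ma"], params, rng, trd,
                                             "BC1_[MaSp]Ma", "BC1c")
    cohorts["BC1_[MaSp]Sp"] = simulate_cross(f1_masp, sp_cy_ma, sz["BC1_[MaSp]Sp"], params, rng, trd,
                                             "BC1_[MaSp]Sp", "BC1d")

    def mother_pool(base_mothers: Cohort, more_fn) -> tuple[Cohort, Cohort]:
        """Split a mother pool by phenotype, topping up until both strata exist."""
        pool = base_mothers
        for _ in range(20):
            h = pool.subset(pool.fertility == "H")
            msk = pool.subset(pool.fertility == "MS")
            if len(h) >= 1 and len(msk) >= 1:
                return h, msk
            pool = _concat(pool, more_fn())
        raise RuntimeError("could not assemble phenotype-stratified mother pool")

    def progeny_of(mothers: Cohort, donors: Sequence[Cohort], total: int, label: str) -> Cohort:
        """``total`` offspring spread over the mother pool and pollen donors."""
        per = np.full(len(mothers), total // len(mothers))
        per[: total % len(mothers)] += 1
        parts = []
        for i in range(len(mothers)):
            if per[i] == 0:
                continue
            one = mothers.subset(np.arange(len(mothers)) == i)
            donor = donors[i % len(donors)]
            parts.append(
                simulate_cross(one, donor, int(per[i]), params, rng, trd, label, f"{label}m{i:03d}")
            )
        return _concat(*parts)

    # BC2: (SpMa)MaMa from a pool of [SpMa]Ma mothers stratified by phenotype.
    def more_bc1_mothers() -> Cohort:
        return simulate_cross(f1_spma, ma, config.n_bc1_mothers, params, rng, trd,
                              "BC2mother", "BC2mox")

    bc2_mother_base = simulate_cross(f1_spma, ma, config.n_bc1_mothers, params, rng, trd,
                                     "BC2mother", "BC2mo")
    h_mo, ms_mo = mother_pool(bc2_mother_base, more_bc1_mothers)
    cohorts["BC2_H"] = progeny_of(h_mo, [ma], sz["BC2_H"], "BC2_H")
    cohorts["BC2_MS"] = progeny_of(ms_mo, [ma], sz["BC2_MS"], "BC2_MS")

    # BC3: mothers are BC2 offspring of H BC1 mothers, again split H / MS.
    bc3_mother_base = progeny_of(h_mo, [ma], config.n_bc2_mothers, "BC3mother")
    h3, ms3 = mother_pool(bc3_mother_base, lambda: progeny_of(h_mo, [ma], config.n_bc2_mothers, "BC3motherx"))
    cohorts["BC3_H"] = progeny_of(h3, [ma], sz["BC3_H"], "BC3_H")
    cohorts["BC3_MS"] = progeny_of(ms3, [ma], sz["BC3_MS"], "BC3_MS")

    for c in cohorts.values():
        simulate_phenotypes(c, rng)

    panel = snp_panel(map_, config.n_snps)
    geno_parts, pheno_rows, ped_rows = [], [], []
    for label, c in cohorts.items():
        geno_parts.append(_expand_to_snps(c.genotype_codes(), panel))
        rf = c.rf_classes()
        for i in range(len(c)):
            tot = int(c.pollen_total[i])
            via = c.pollen_viable[i]
            pheno_rows.append(
                (c.ids[i], label, c.cytoplasm.label, c.fertility[i], tot,
                 int(via) if via >= 0 else None)
            )
            ped_rows.append(
                (c.ids[i], c.mother_ids[i], c.father_ids[i], label, c.cytoplasm.label, rf[i])
            )
    genotypes = pd.concat(geno_parts, axis=0)
    genotypes.index.name = "id"
    mask = rng.random(genotypes.shape) < config.missing_rate
    genotypes = genotypes.mask(mask, "NA")

    if config.n_outliers > 0:
        picks = rng.choice(len(genotypes), size=config.n_outliers, replace=False)
        events = rng.integers(5, 14, size=config.n_outliers)
        genotypes = inject_singleton_switches(
            genotypes, panel, [genotypes.index[i] for i in picks], events, rng
        )

    phenotypes = pd.DataFrame(
        pheno_rows, columns=["id", "cross", "cytoplasm", "fertility_class", "pollen_total", "pollen_viable"]
    ).set_index("id")
    pedigree = pd.DataFrame(
        ped_rows, columns=["id", "mother", "father", "cross", "cytoplasm", "rf_truth"]
    ).set_index("id")
    marker_table = panel.reset_index()[["snp", "gene", "chrom", "pos_cm"]]

    dataset = Dataset(
        genotypes=genotypes,
        phenotypes=phenotypes,
        pedigree=pedigree,
        marker_map=marker_table,
        provenance={"seed": int(seed), "template": config.template, "tool": "cmsrf"},
    )
    return StudyResult(cohorts, dataset, map_, trd, config, int(seed))


def _concat(*cohorts: Cohort) -> Cohort:
    first = cohorts[0]
    out = Cohort(
        [i for c in cohorts for i in c.ids], first.cross, first.cytoplasm,
        np.concatenate([c.mat for c in cohorts]), np.concatenate([c.pat for c in cohorts]),
        first.map,
        [m for c in cohorts for m in c.mother_ids], [f for c in cohorts for f in c.father_ids],
        np.concatenate([c.fertility for c in cohorts]),
    )
    out.pollen_total = np.concatenate([c.pollen_total for c in cohorts])
    out.pollen_viable = np.concatenate([c.pollen_viable for c in cohorts])
    return out


def simulate_design_fraction(
    design: str,
    params: ModelParams,
    n: int,
    seed: int,
    cytoplasm: CytoplasmType = SP_CMS,
) -> float:
    """Monte-Carlo H fraction for one study design, with an independent mother
    drawn per final offspring so the estimator is exactly binomial.

    ``design`` is one of F2, BC1, BC2(H), BC2(MS), BC3(H), BC3(MS) — the
    phenotype label conditions the relevant maternal generation(s).
    """
    rng = np.random.default_rng(seed)
    map_ = default_marker_map()
    trd = default_trd_template(map_, rf_tau=params.tau)
    sp = founder(S, cytoplasm, map_, "Sp0", "P_Sp")
    ma = founder(M, MA, map_, "Ma0", "P_Ma")
    ma_cyt = CytoplasmType("Ma", False) if cytoplasm.carries_cms else cytoplasm
    sp_d = founder(S, ma_cyt, map_, "Sp1", "P_Sp")
    f1 = simulate_cross(sp, ma, 1, params, rng, trd, "F1", "F1")
    f1_rec = simulate_cross(ma, sp_d, 1, params, rng, trd, "F1r", "F1r")

    if design == "F2":
        off = simulate_cross(f1, f1_rec, n, params, rng, trd, "F2", "F2")
        return float(np.mean(off.fertility == "H"))
    if design == "BC1":
        off = simulate_cross(f1, ma, n, params, rng, trd, "BC1", "BC1")
        return float(np.mean(off.fertility == "H"))

    conditions = {
        "BC2(H)": ("H",), "BC2(MS)": ("MS",),
        "BC3(H)": ("H", "H"), "BC3(MS)": ("H", "MS"),
    }
    if design not in conditions:
        raise ValueError(f"unknown design {design!r}")
    conds = conditions[design]

    def conditioned_mothers(want: int, conds: Sequence[str]) -> Cohort:
        got: Cohort | None = None
        while got is None or len(got) < want:
            batch = max(2048, int(1.6 * want))
            pool = simulate_cross(f1, ma, batch, params, rng, trd, "BC1", "BC1")
            pool = pool.subset(pool.fertility == conds[0])
            for cond in conds[1:]:
                pool = cross_per_mother(pool, ma, params, rng, trd)
                pool = pool.subset(pool.fertility == cond)
            got = pool if got is None else _concat(got, pool)
        return got.subset(np.arange(len(got)) < want)

    mothers = conditioned_mothers(n, conds)
    off = cross_per_mother(mothers, ma, params, rng, trd)
    return float(np.mean(off.fertility == "H"))
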