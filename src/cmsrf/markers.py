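"""Marker-level and phenotype-level statistics.

Sterility calling from pollen counts, SNP-to-gene marker combination,
transmission-ratio-distortion scan with Bonferroni correction,
double-recombination quality control, a nonparametric (Kruskal–Wallis)
single-marker association scan with genome-wide permutation thresholds, and
rank-based variance explained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

MISSING = "NA"
GENO_CLASSES = ("SS", "SM", "MM")


def call_fertility_class(pollen_total: int) -> str:
    """Male-sterile iff the subsample holds fewer than 10 pollen grains."""
    if pollen_total < 0:
        raise ValueError("pollen count must be nonnegative")
    return "MS" if pollen_total < 10 else "H"


def _normalise_code(code: str) -> str:
    if code in (None, "", MISSING) or (isinstance(code, float) and np.isnan(code)):
        return MISSING
    try:
        s = "".join(sorted(str(code), key="SM".index))
    except ValueError:
        raise ValueError(f"unknown genotype code {code!r}") from None
    if s not in GENO_CLASSES:
        raise ValueError(f"unknown genotype code {code!r}")
    return s


def combine_snps_to_gene(
    snp_calls: Sequence[str], gene: str = "?", individual: str = "?"
) -> str:
    """Combine the SNP calls within one gene into a gene-level genotype.

    Missing SNPs are ignored when another SNP is informative; conflicting
    calls yield a missing genotype and a logged conflict.
    """
    calls = {c for c in (_normalise_code(x) for x in snp_calls) if c != MISSING}
    if not calls:
        return MISSING
    if len(calls) > 1:
        logger.warning("conflicting SNP calls %s in gene %s, individual %s", sorted(calls), gene, individual)
        return MISSING
    return calls.pop()


def combine_matrix_to_genes(
    genotypes: pd.DataFrame, snp_to_gene: Mapping[str, str]
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Collapse a SNP genotype matrix to gene-level markers.

    Returns (gene matrix, conflict log entries as (individual, gene)).
    """
    conflicts: list[tuple[str, str]] = []
    genes: dict[str, list[str]] = {}
    for snp in genotypes.columns:
        if snp not in snp_to_gene:
            raise KeyError(f"SNP {snp!r} has no gene assignment")
        genes.setdefault(snp_to_gene[snp], []).append(snp)
    out = {}
    for gene, snps in genes.items():
        sub = genotypes[snps].map(_normalise_code)
        combined = []
        for ind, row in zip(sub.index, sub.to_numpy()):
            calls = {c for c in row if c != MISSING}
            if len(calls) == 1:
                combined.append(calls.pop())
            elif len(calls) == 0:
                combined.append(MISSING)
            else:
                logger.warning("conflicting SNP calls in gene %s, individual %s", gene, ind)
                conflicts.append((str(ind), gene))
                combined.append(MISSING)
        out[gene] = combined
    return pd.DataFrame(out, index=genotypes.index), conflicts


# ---------------------------------------------------------------------------
# TRD scan


_DESIGN_NULL = {
    "F2": {"SS": 0.25, "SM": 0.5, "MM": 0.25},
    "BC": None,  # 1:1 over the two classes present
}


def trd_scan(
    genotypes: pd.DataFrame,
    design: str | Mapping[str, float] = "F2",
    alpha: float = 0.05,
    min_calls: int = 20,
) -> pd.DataFrame:
    """Per-marker transmission-ratio-distortion tests with Bonferroni control.

    The genotype-class counts of every gene-level marker are tested against
    the design's null proportions (1:2:1 for an F2, 1:1 for a backcross) with
    a Pearson chi-square.  Allele-level (S vs M at 0.5) and heterozygote-excess
    tests are reported alongside, mirroring the three classic scan readouts.
    Markers with fewer than ``min_calls`` genotypes or a single observed class
    are flagged low-informative and excluded from the Bonferroni family.
    """
    if genotypes.shape[1] == 0:
        raise ValueError("empty genotype matrix")
    if isinstance(design, str):
        null = _DESIGN_NULL[design]
    else:
        null = dict(design)
    rows = []
    for marker in genotypes.columns:
        col = genotypes[marker].map(_normalise_code)
        counts = {g: int((col == g).sum()) for g in GENO_CLASSES}
        n = sum(counts.values())
        observed_classes = [g for g in GENO_CLASSES if counts[g] > 0]
        informative = n >= min_calls and len(observed_classes) >= 2
        n_s = 2 * counts["SS"] + counts["SM"]
        n_m = 2 * counts["MM"] + counts["SM"]
        freq_s = n_s / (2 * n) if n else np.nan
        het = counts["SM"] / n if n else np.nan

        chi2 = p = chi2_a = p_a = chi2_h = p_h = np.nan
        if informative:
            if null is None:
                present = [g for g in ("SS", "SM", "MM") if counts[g] > 0][:2]
                obs = np.array([counts[g] for g in present], dtype=float)
                exp = np.full(len(obs), obs.sum() / len(obs))
                df = len(obs) - 1
            else:
                obs = np.array([counts[g] for g in GENO_CLASSES], dtype=float)
                exp = np.array([null[g] * n for g in GENO_CLASSES], dtype=float)
                df = 2
            chi2 = float(np.sum((obs - exp) ** 2 / exp))
            p = float(stats.chi2.sf(chi2, df))
            chi2_a = float((n_s - n) ** 2 / n + (n_m - n) ** 2 / n)  # vs 0.5 on 2n alleles
            p_a = float(stats.chi2.sf(chi2_a, 1))
            e_het = (null["SM"] if null else 0.5) * n
            chi2_h = float((counts["SM"] - e_het) ** 2 / e_het
                           + ((n - counts["SM"]) - (n - e_het)) ** 2 / (n - e_het))
            p_h = float(stats.chi2.sf(chi2_h, 1))
        rows.append(
            (marker, counts["SS"], counts["SM"], counts["MM"], n, freq_s,
             1 - freq_s if n else np.nan, het, chi2, p, chi2_a, p_a, chi2_h, p_h, informative)
        )
    out = pd.DataFrame(
        rows,
        columns=["marker", "n_SS", "n_SM", "n_MM", "n", "freq_S", "freq_M", "freq_het",
                 "chi2_geno", "p_geno", "chi2_allele", "p_allele", "chi2_het", "p_het",
                 "informative"],
    ).set_index("marker")
    family = int(out["informative"].sum())
    out["bonferroni_family"] = family
    out["significant"] = out["informative"] & (out["p_geno"] * family < alpha)
    n_skip = int((~out["informative"]).sum())
    if n_skip:
        logger.info("trd_scan: %d low-informative markers excluded from Bonferroni family", n_skip)
    return out


# ---------------------------------------------------------------------------
# Double-recombination QC


def double_recomb_qc(
    genotypes: pd.DataFrame,
    marker_map: pd.DataFrame,
    threshold: float = 5,
) -> tuple[list[str], pd.Series]:
    """Count singleton genotype switches per individual and flag outliers.

    A singleton switch is a marker whose genotype differs from two identical
    non-missing flanking neighbours on the same chromosome — the unphased
    signature of an apparent double recombination.  Individuals with at least
    ``threshold`` events are flagged (mirrors removing plants with 5–13 such
    events).  ``marker_map`` needs columns chrom and pos_cm indexed by marker.
    """
    order = marker_map.sort_values(["chrom", "pos_cm"])
    if list(order.index) != list(marker_map.index):
        raise ValueError("marker map must be ordered by chromosome and position")
    markers = [m for m in order.index if m in genotypes.columns]
    chrom = order.loc[markers, "chrom"].to_numpy()
    g = genotypes[markers].map(_normalise_code).to_numpy()
    n, L = g.shape
    events = np.zeros(n, dtype=int)
    for j in range(1, L - 1):
        if chrom[j - 1] != chrom[j] or chrom[j] != chrom[j + 1]:
            continue
        prev, cur, nxt = g[:, j - 1], g[:, j], g[:, j + 1]
        ok = (prev != MISSING) & (cur != MISSING) & (nxt != MISSING)
        events += (ok & (prev == nxt) & (cur != prev)).astype(int)
    counts = pd.Series(events, index=genotypes.index, name="singleton_switches")
    flagged = list(counts.index[counts >= threshold])
    if flagged:
        logger.info("double_recomb_qc: flagged %d individuals", len(flagged))
    return flagged, counts


# ---------------------------------------------------------------------------
# Nonparametric association scan


def _kruskal_wallis(values: np.ndarray, classes: np.ndarray) -> tuple[float, int, int]:
    """Tie-corrected Kruskal–Wallis H for one marker; (H, df, n)."""
    n = values.shape[0]
    ranks = stats.rankdata(values)
    groups = np.unique(classes)
    h = 12.0 / (n * (n + 1)) * sum(
        (ranks[classes == g].sum()) ** 2 / (classes == g).sum() for g in groups
    ) - 3 * (n + 1)
    _, t = np.unique(values, return_counts=True)
    tie = 1.0 - (t**3 - t).sum() / (n**3 - n)
    if tie > 0:
        h /= tie
    return float(h), len(groups) - 1, n


def assoc_scan(
    genotypes: pd.DataFrame,
    phenotype: pd.Series,
    min_per_class: int = 1,
) -> pd.DataFrame:
    """Kruskal–Wallis rank statistic of the phenotype across genotype classes,
    per marker.  Markers with fewer than two populated classes are skipped
    with a log entry.  The statistic is invariant under monotone phenotype
    transformations (it depends on ranks only).
    """
    pheno = phenotype.reindex(genotypes.index)
    if pheno.isna().all():
        raise ValueError("phenotype has no values for these individuals")
    if pheno.dropna().nunique() <= 1:
        raise ValueError("phenotype is constant; rank test undefined")
    rows = []
    for marker in genotypes.columns:
        col = genotypes[marker].map(_normalise_code)
        ok = (col != MISSING) & pheno.notna().to_numpy()
        vals = pheno[ok].to_numpy(dtype=float)
        cls = col[ok].to_numpy()
        populated = [g for g in np.unique(cls) if (cls == g).sum() >= min_per_class]
        if len(populated) < 2:
            logger.info("assoc_scan: marker %s skipped (<2 genotype classes)", marker)
            rows.append((marker, np.nan, np.nan, 0, 0, np.nan))
            continue
        keep = np.isin(cls, populated)
        h, df, n = _kruskal_wallis(vals[keep], cls[keep])
        rows.append((marker, h, float(stats.chi2.sf(h, df)), df, n, h / (n - 1)))
    return pd.DataFrame(
        rows, columns=["marker", "statistic", "p_asymptotic", "df", "n", "variance_explained"]
    ).set_index("marker")


def permutation_threshold(
    genotypes: pd.DataFrame,
    phenotype: pd.Series,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Genome-wide threshold: the (1-alpha) quantile of the maximum
    Kruskal–Wallis statistic over markers under phenotype-label permutation.

    Deterministic for a fixed seed.  Requires n_perm >= 100 and enough
    permutations to resolve the requested tail (n_perm * alpha >= 1).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    if n_perm * alpha < 1:
        raise ValueError(f"n_perm={n_perm} too small for alpha={alpha}")
    rng = np.random.default_rng(seed)
    pheno = phenotype.reindex(genotypes.index).to_numpy(dtype=float)
    # precompute per-marker class labels and missingness once
    marker_cls = []
    for marker in genotypes.columns:
        col = genotypes[marker].map(_normalise_code)
        ok = (col != MISSING) & ~np.isnan(pheno)
        cls = col.to_numpy()
        if len(np.unique(cls[ok.to_numpy()])) >= 2:
            marker_cls.append((ok.to_numpy(), cls))
    if not marker_cls:
        raise ValueError("no informative markers")
    maxima = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(pheno)
        best = 0.0
        for ok, cls in marker_cls:
            vals, cc = perm[ok], cls[ok]
            if np.unique(cc).size < 2:
                continue
            h, _, _ = _kruskal_wallis(vals, cc)
            best = max(best, h)
        maxima[b] = best
    return float(np.quantile(maxima, 1.0 - alpha, method="higher"))


def variance_explained(genotype: pd.Series | Sequence[str], phenotype: Sequence[float]) -> float:
    """Rank-based eta squared: between-genotype-class share of rank variance.

    Equals the tie-corrected Kruskal–Wallis H divided by n-1, in [0, 1].
    """
    cls = pd.Series(genotype).map(_normalise_code).to_numpy()
    vals = np.asarray(phenotype, dtype=float)
    ok = (cls != MISSING) & ~np.isnan(vals)
    cls, vals = cls[ok], vals[ok]
    if np.unique(cls).size < 2:
        raise ValueError("need at least two genotype classes")
    if np.unique(vals).size <= 1:
        raise ValueError("phenotype is constant")
    h, _, n = _kruskal_wallis(vals, cls)
    return min(1.0, max(0.0, h / (n - 1)))
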