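"""Dataset container, delimited-text readers/writers and pipeline driver.

All tables are UTF-8 comma-separated text with a header row.  Genotypes are
coded by population of origin ({SS, SM, MM}) with ``NA`` as the single
missing-data sentinel; map positions are Kosambi cM.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

logger = logging.getLogger(__name__)

MISSING = "NA"
_FILES = {
    "genotypes": "genotypes.csv",
    "phenotypes": "phenotypes.csv",
    "pedigree": "pedigree.csv",
    "marker_map": "marker_map.csv",
    "provenance": "provenance.json",
}


class SchemaError(ValueError):
    """A dataset table violates the expected schema."""


@dataclass
class Dataset:
    """Genotype, phenotype and pedigree tables plus the SNP map.

    Invariants: individual ids agree across tables and every genotype column
    is a SNP present in the map.
    """

    genotypes: pd.DataFrame   # index id, columns SNP ids, values SS/SM/MM/NA
    phenotypes: pd.DataFrame  # index id
    pedigree: pd.DataFrame    # index id
    marker_map: pd.DataFrame  # columns snp, gene, chrom, pos_cm
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("genotypes", "phenotypes", "pedigree"):
            df = getattr(self, name)
            if df.index.duplicated().any():
                dup = df.index[df.index.duplicated()][0]
                raise SchemaError(f"duplicate individual id {dup!r} in {name}")
        ids = set(self.genotypes.index)
        for name in ("phenotypes", "pedigree"):
            other = set(getattr(self, name).index)
            if other != ids:
                missing = sorted(ids ^ other)[:5]
                raise SchemaError(f"individual ids differ between genotypes and {name}: {missing} ...")
        if self.marker_map.index.name == "snp":
            known = set(self.marker_map.index)
        else:
            if "snp" not in self.marker_map.columns:
                raise SchemaError("marker map lacks an 'snp' column")
            known = set(self.marker_map["snp"])
        unknown = [c for c in self.genotypes.columns if c not in known]
        if unknown:
            raise SchemaError(f"genotype column {unknown[0]!r} absent from marker map")

    @property
    def snp_to_gene(self) -> dict[str, str]:
        mm = self.marker_map.reset_index() if self.marker_map.index.name == "snp" else self.marker_map
        return dict(zip(mm["snp"], mm["gene"]))

    def gene_map(self) -> pd.DataFrame:
        """One row per gene with chromosome and position, map-ordered."""
        mm = self.marker_map.reset_index() if self.marker_map.index.name == "snp" else self.marker_map
        g = mm.groupby("gene", sort=False).agg(chrom=("chrom", "first"), pos_cm=("pos_cm", "first"))
        return g.sort_values(["chrom", "pos_cm"])

    def missing_fraction(self) -> float:
        return float((self.genotypes == MISSING).to_numpy().mean())


def write_dataset(dataset: Dataset, outdir: str | Path) -> dict[str, Path]:
    """Write all tables as CSV plus a JSON provenance block."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for attr in ("genotypes", "phenotypes", "pedigree"):
        p = out / _FILES[attr]
        getattr(dataset, attr).to_csv(p, index_label="id", na_rep=MISSING)
        paths[attr] = p
    p = out / _FILES["marker_map"]
    mm = dataset.marker_map.reset_index() if dataset.marker_map.index.name == "snp" else dataset.marker_map
    mm.to_csv(p, index=False)
    paths["marker_map"] = p
    prov = dict(dataset.provenance)
    prov.setdefault("tool", "cmsrf")
    p = out / _FILES["provenance"]
    p.write_text(json.dumps(prov, indent=2, sort_keys=True))
    paths["provenance"] = p
    return paths


def read_dataset(indir: str | Path) -> Dataset:
    """Read a dataset written by :func:`write_dataset`; round-trip identity."""
    ind = Path(indir)
    for key, fname in _FILES.items():
        if not (ind / fname).exists():
            raise FileNotFoundError(f"missing dataset file {fname}")
    geno = pd.read_csv(ind / _FILES["genotypes"], index_col="id", dtype=str,
                       keep_default_na=False)
    pheno = pd.read_csv(ind / _FILES["phenotypes"], index_col="id",
                        na_values=[MISSING], keep_default_na=False)
    ped = pd.read_csv(ind / _FILES["pedigree"], index_col="id", dtype=str,
                      na_values=[MISSING], keep_default_na=False)
    mm = pd.read_csv(ind / _FILES["marker_map"])
    prov = json.loads((ind / _FILES["provenance"]).read_text())
    if "pollen_viable" in pheno.columns:
        pheno["pollen_viable"] = pheno["pollen_viable"].astype("Int64")
    return Dataset(geno, pheno, ped, mm, prov)


def table1_fixture() -> pd.DataFrame:
    """The shipped observed H:MS table of the main crossing family
    (cross label, year, counts, printed best-fitting ratio where given)."""
    with resources.files("cmsrf.data").joinpath("table1_observed.csv").open() as fh:
        return pd.read_csv(fh, keep_default_na=False, na_values=[""])


def load_config(path: str | Path | None) -> dict:
    """Read a YAML run configuration; empty dict when no path is given."""
    if path is None:
        return {}
    text = Path(path).read_text()
    cfg = yaml.safe_load(text) or {}
    if not isinstance(cfg, dict):
        raise SchemaError("config file must hold a mapping")
    return cfg


def config_hash(cfg: Mapping) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:12]


def run_pipeline(
    config: Mapping | None = None,
    seed: int = 0,
    outdir: str | Path = "cmsrf_out",
    stages: tuple[str, ...] = ("simulate", "expect", "fit", "trd-scan", "assoc-scan", "report"),
    alpha: float = 0.05,
    n_perm: int = 1000,
) -> dict[str, Path]:
    """End-to-end driver: simulate a study, then run the analysis stages.

    Writes the dataset, Table-1-style and Table-2-style reports, TRD and
    association scan tables into ``outdir``; deterministic for a fixed seed.
    """
    from . import markers, report
    from .simulate import StudyConfig, simulate_study

    known = {"simulate", "expect", "fit", "trd-scan", "assoc-scan", "report"}
    bad = set(stages) - known
    if bad:
        raise ValueError(f"unknown stage(s): {sorted(bad)}")
    cfg = dict(config or {})
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    study = None
    if "simulate" in stages:
        study = simulate_study(StudyConfig.from_dict(cfg.get("study", {})), seed=seed)
        ds = study.dataset
        ds.provenance.update({"config_hash": config_hash(cfg), "seed": int(seed)})
        written.update(write_dataset(ds, out / "dataset"))
        logger.info("simulate: wrote dataset (%d individuals)", len(ds.genotypes))

    if "expect" in stages or "fit" in stages or "report" in stages:
        obs = table1_fixture()
        t1 = report.table1_report(obs, degenerate_tol=cfg.get("degenerate_tol", 0.06))
        p = out / "table1_report.csv"
        t1.to_csv(p, index=False)
        written["table1_report"] = p
        t2 = report.table2_report(tau=cfg.get("tau", 0.575), restoration=cfg.get("restoration", 0.4))
        p = out / "table2_report.csv"
        t2.to_csv(p, index=False)
        written["table2_report"] = p

    if study is not None and {"trd-scan", "assoc-scan"} & set(stages):
        ds = study.dataset
        gene_geno, _ = markers.combine_matrix_to_genes(ds.genotypes, ds.snp_to_gene)
        gene_geno = gene_geno[list(study.map.panel_markers)]
        f2_ids = ds.phenotypes.index[ds.phenotypes["cross"] == "F2_SpMa"]
        if "trd-scan" in stages:
            scan = markers.trd_scan(gene_geno.loc[f2_ids], design="F2", alpha=alpha)
            p = out / "trd_scan.csv"
            scan.to_csv(p)
            written["trd_scan"] = p
        if "assoc-scan" in stages:
            pheno = ds.phenotypes.loc[f2_ids, "pollen_total"].astype(float)
            scan = markers.assoc_scan(gene_geno.loc[f2_ids], pheno)
            thr = markers.permutation_threshold(
                gene_geno.loc[f2_ids], pheno, n_perm=n_perm, alpha=alpha, seed=seed
            )
            scan["threshold"] = thr
            scan["exceeds"] = scan["statistic"] > thr
            p = out / "assoc_scan.csv"
            scan.to_csv(p)
            written["assoc_scan"] = p

    prov = {"seed": int(seed), "stages": list(stages), "config_hash": config_hash(cfg),
            "alpha": alpha, "n_perm": n_perm, "tool": "cmsrf"}
    p = out / "run_provenance.json"
    p.write_text(json.dumps(prov, indent=2, sort_keys=True))
    written["run_provenance"] = p
    return written
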