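"""Readers and writers for the delimited-text and VCF formats used here.

Conventions: tab-delimited text with a header row (comma via ``delimiter``),
missing values encoded "NA", VCF positions 1-based, dosages counted on the
ALT allele.  Liability models serialize to a small JSON document that
round-trips exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .assoc import AssocResult, GenotypeMatrix
from .ltpub import PrevalenceTable
from .model import LiabilityModel
from .posterior import Cohort, PosteriorLiability

__all__ = [
    "read_model",
    "write_model",
    "read_prevalence_tables",
    "read_cohort",
    "write_cohort",
    "read_genotypes",
    "read_vcf",
    "read_dosage_matrix",
    "write_posterior",
    "write_results",
    "VcfReadReport",
    "packaged_prevalence_path",
    "load_published_model",
    "published_model_names",
]

_NA = "NA"


# ---------------------------------------------------------------------------
# liability model JSON
# ---------------------------------------------------------------------------

def write_model(model: LiabilityModel, path) -> None:
    Path(path).write_text(json.dumps(model.to_dict(), indent=2) + "\n")


def read_model(path) -> LiabilityModel:
    return LiabilityModel.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# prevalence tables
# ---------------------------------------------------------------------------

def _parse_prevalence(x) -> float:
    s = str(x).strip()
    if s.endswith("%"):
        return float(s[:-1]) / 100.0
    return float(s)


def read_prevalence_tables(path, delimiter: str = "\t") -> list[PrevalenceTable]:
    """Read prevalence curves: columns covariate, value, prevalence.

    Prevalence accepts proportions in (0,1) or percentages with a trailing
    "%"; one file may carry several covariates' curves.  An optional
    ``reference_mean`` column overrides the default (mean of the values).
    """
    df = pd.read_csv(path, sep=delimiter, dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    required = {"covariate", "value", "prevalence"}
    if not required.issubset(df.columns):
        raise ValueError(f"prevalence file must have columns {sorted(required)}")
    tables = []
    for name, grp in df.groupby("covariate", sort=False):
        ref = None
        if "reference_mean" in grp.columns:
            vals = grp["reference_mean"].dropna().unique()
            if len(vals):
                ref = float(vals[0])
        tables.append(
            PrevalenceTable(
                covariate_name=str(name),
                values=[float(v) for v in grp["value"]],
                prevalences=[_parse_prevalence(p) for p in grp["prevalence"]],
                reference_mean=ref,
            )
        )
    return tables


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

def read_cohort(path, delimiter: str = "\t", status_coding: str = "01") -> Cohort:
    """Read a cohort table: columns sample_id, status, then covariates.

    ``status_coding="plink"`` maps 1/2 (unaffected/affected) to 0/1.
    Unknown columns become covariates; "NA" marks missing values.
    """
    df = pd.read_csv(path, sep=delimiter, na_values=[_NA], dtype={0: str})
    cols = list(df.columns)
    if "sample_id" not in cols or "status" not in cols:
        raise ValueError("cohort file requires 'sample_id' and 'status' columns")
    ids = df["sample_id"].astype(str)
    if ids.duplicated().any():
        raise ValueError("duplicate sample IDs")
    status = df["status"].to_numpy()
    if status_coding == "plink":
        if not np.isin(status, (1, 2)).all():
            raise ValueError("plink status coding must be 1/2")
        status = status - 1
    elif status_coding != "01":
        raise ValueError(f"unknown status coding {status_coding!r}")
    cov_names = [c for c in cols if c not in ("sample_id", "status")]
    try:
        X = df[cov_names].astype(float).to_numpy() if cov_names else None
    except ValueError as e:
        raise ValueError(f"non-numeric covariate values: {e}") from e
    return Cohort(tuple(ids), status, tuple(cov_names), X)


def write_cohort(cohort: Cohort, path, delimiter: str = "\t") -> None:
    df = pd.DataFrame({"sample_id": cohort.sample_ids, "status": cohort.status})
    for j, name in enumerate(cohort.covariate_names):
        df[name] = cohort.covariates[:, j]
    df.to_csv(path, sep=delimiter, index=False, na_rep=_NA)


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

@dataclass
class VcfReadReport:
    n_kept: int = 0
    n_multiallelic_skipped: int = 0
    n_nonsnp_skipped: int = 0


def read_vcf(path) -> tuple[GenotypeMatrix, VcfReadReport]:
    """Read biallelic SNPs from a VCF into ALT-allele dosages.

    The DS (dosage) FORMAT field is preferred when present; otherwise GT is
    converted to 0/1/2 with missing genotypes as NaN.  Multi-allelic and
    non-SNP records are skipped and counted in the report.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = tuple(vcf.samples)
    report = VcfReadReport()
    snp_ids, chroms, poss, refs, alts, cols = [], [], [], [], [], []
    for var in vcf:
        if len(var.ALT) != 1:
            report.n_multiallelic_skipped += 1
            continue
        if len(var.REF) != 1 or len(var.ALT[0]) != 1:
            report.n_nonsnp_skipped += 1
            continue
        ds = None
        if "DS" in (var.FORMAT or []):
            ds = np.asarray(var.format("DS"), dtype=float).reshape(-1)
        else:
            gt = np.asarray(var.genotype.array())[:, :2]
            ds = np.where((gt < 0).any(axis=1), np.nan, (gt > 0).sum(axis=1)).astype(float)
        snp_ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        chroms.append(str(var.CHROM))
        poss.append(int(var.POS))
        refs.append(var.REF)
        alts.append(var.ALT[0])
        cols.append(ds)
        report.n_kept += 1
    vcf.close()
    D = np.column_stack(cols) if cols else np.empty((len(samples), 0))
    geno = GenotypeMatrix(samples, snp_ids, D, chroms, poss, refs, alts)
    return geno, report


def read_dosage_matrix(path, delimiter: str = "\t") -> GenotypeMatrix:
    """Read a dosage matrix: rows samples (first column sample_id), columns SNPs."""
    df = pd.read_csv(path, sep=delimiter, na_values=[_NA], dtype={0: str})
    ids = df.iloc[:, 0].astype(str)
    snps = list(df.columns[1:])
    D = df[snps].astype(float).to_numpy()
    return GenotypeMatrix(tuple(ids), tuple(snps), D)


def read_genotypes(path, fmt: str | None = None):
    """Dispatch on format: ``vcf`` or ``dosage`` (by extension if omitted).

    Returns ``(GenotypeMatrix, VcfReadReport | None)``.
    """
    if fmt is None:
        fmt = "vcf" if str(path).endswith((".vcf", ".vcf.gz")) else "dosage"
    if fmt == "vcf":
        return read_vcf(path)
    if fmt == "dosage":
        return read_dosage_matrix(path), None
    raise ValueError(f"unknown genotype format {fmt!r}")


def align_samples(cohort: Cohort, geno: GenotypeMatrix) -> tuple[Cohort, GenotypeMatrix]:
    """Restrict both objects to their shared samples, in cohort order."""
    shared = [s for s in cohort.sample_ids if s in set(geno.sample_ids)]
    if not shared:
        raise ValueError("no overlapping samples between cohort and genotypes")
    cidx = [cohort.sample_ids.index(s) for s in shared]
    gidx = [geno.sample_ids.index(s) for s in shared]
    cohort2 = Cohort(
        shared,
        cohort.status[cidx],
        cohort.covariate_names,
        cohort.covariates[cidx],
        cohort.onset_flags,
        None if cohort.imputed_mask is None else cohort.imputed_mask[cidx],
    )
    geno2 = GenotypeMatrix(
        shared, geno.snp_ids, geno.dosages[gidx], geno.chromosomes,
        geno.positions, geno.ref, geno.alt,
    )
    return cohort2, geno2


# ---------------------------------------------------------------------------
# outputs
# ---------------------------------------------------------------------------

def write_posterior(pm: PosteriorLiability, path, delimiter: str = "\t") -> None:
    df = pd.DataFrame(
        {
            "sample_id": pm.sample_ids,
            "threshold": pm.threshold,
            "posterior_mean": pm.posterior_mean,
            "mode": pm.mode,
        }
    )
    df.to_csv(path, sep=delimiter, index=False, float_format="%.12g")


RESULT_COLUMNS = [
    "snp_id", "chr", "pos", "n", "af", "statistic", "p",
    "effect_liability", "se", "or",
]


def write_results(
    results: Sequence[AssocResult],
    geno: GenotypeMatrix,
    path,
    delimiter: str = "\t",
    extra: pd.DataFrame | None = None,
) -> None:
    meta = {s: (c, p) for s, c, p in zip(geno.snp_ids, geno.chromosomes, geno.positions)}
    rows = []
    for r in results:
        chrom, pos = meta.get(r.snp_id, (".", 0))
        rows.append(
            [r.snp_id, chrom, pos, r.n_used, r.allele_freq, r.statistic, r.p_value,
             r.effect, r.stderr, r.or_estimate if r.or_estimate is not None else _NA]
        )
    df = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    if extra is not None:
        df = pd.concat([df, extra.reset_index(drop=True)], axis=1)
    df.to_csv(path, sep=delimiter, index=False, na_rep=_NA, float_format="%.10g")


# ---------------------------------------------------------------------------
# packaged reference data
# ---------------------------------------------------------------------------

def packaged_prevalence_path(name: str):
    """Path to a packaged prevalence curve: ``t2d_bmi`` or ``prostate_age``."""
    fname = {"t2d_bmi": "t2d_bmi_prevalence.tsv", "prostate_age": "prostate_age_prevalence.tsv"}
    if name not in fname:
        raise ValueError(f"unknown fixture {name!r}; choose from {sorted(fname)}")
    return resources.files("ltcond.data").joinpath(fname[name])


def _published_models() -> dict:
    text = resources.files("ltcond.data").joinpath("published_models.json").read_text()
    return json.loads(text)


def published_model_names() -> list[str]:
    return sorted(_published_models())


def load_published_model(name: str) -> LiabilityModel:
    """A reference liability model from the epidemiological fits shipped here."""
    models = _published_models()
    if name not in models:
        raise ValueError(f"unknown model {name!r}; choose from {sorted(models)}")
    return LiabilityModel.from_dict(models[name])
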