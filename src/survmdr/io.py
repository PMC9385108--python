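"""Readers and writers for the pipeline's interchange formats.

Genotypes travel in the PLINK .raw additive dialect: a whitespace-delimited
header ``FID IID PAT MAT SEX PHENOTYPE`` followed by one ``<SNPID>_<minor
allele>`` column per SNP, dosages coded 0/1/2 (count of the minor allele)
with ``NA`` for a missing call. Phenotypes and covariates travel as a TSV
keyed on subject_id. Readers reject malformed input with the offending
line/column named rather than coercing silently.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .types import MISSING, DataError, Dataset, GenotypeMatrix, SNP_META_COLUMNS

__all__ = [
    "read_plink_raw",
    "write_plink_raw",
    "read_phenotype_table",
    "write_phenotype_table",
    "write_report",
    "read_report",
    "format_cell",
]

RAW_FIXED = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
PHENO_COLUMNS = [
    "subject_id", "time_years", "event", "status5y", "included5y",
    "age", "stage", "msi", "location", "chemo", "radio",
]


def read_plink_raw(path) -> GenotypeMatrix:
    """Parse a PLINK .raw additive-dosage file."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().split()
        if header[: len(RAW_FIXED)] != RAW_FIXED:
            raise DataError(f"{path}: line 1: expected header starting {' '.join(RAW_FIXED)}")
        snp_cols = header[len(RAW_FIXED):]
        snp_ids, minors = [], []
        for col in snp_cols:
            if "_" not in col:
                raise DataError(f"{path}: line 1: SNP column {col!r} lacks the _<allele> suffix")
            snp_id, minor = col.rsplit("_", 1)
            snp_ids.append(snp_id)
            minors.append(minor)
        if len(set(snp_ids)) != len(snp_ids):
            dup = next(s for s in snp_ids if snp_ids.count(s) > 1)
            raise DataError(f"{path}: line 1: duplicated SNP column {dup!r}")
        subjects, rows = [], []
        for lineno, line in enumerate(fh, start=2):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != len(header):
                raise DataError(
                    f"{path}: line {lineno}: expected {len(header)} fields, found {len(parts)}"
                )
            subjects.append(parts[1])
            row = np.empty(len(snp_cols), dtype=np.int8)
            for j, tok in enumerate(parts[len(RAW_FIXED):]):
                if tok == "NA":
                    row[j] = MISSING
                elif tok in ("0", "1", "2"):
                    row[j] = int(tok)
                else:
                    raise DataError(
                        f"{path}: line {lineno}: non-integer dosage {tok!r} in column {snp_cols[j]}"
                    )
            rows.append(row)
    if not rows:
        raise DataError(f"{path}: no subject rows")
    snps = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "gene": "",
            "major_allele": "",
            "minor_allele": minors,
            "maf": np.nan,
            "input_index": np.arange(len(snp_ids)),
        },
        columns=SNP_META_COLUMNS,
    )
    return GenotypeMatrix(dosage=np.vstack(rows), subject_ids=np.array(subjects), snps=snps)


def write_plink_raw(geno: GenotypeMatrix, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        cols = [f"{r.snp_id}_{r.minor_allele or 'N'}" for r in geno.snps.itertuples()]
        fh.write(" ".join(RAW_FIXED + cols) + "\n")
        for i, sid in enumerate(geno.subject_ids):
            row = geno.dosage[i]
            toks = ["NA" if v == MISSING else str(int(v)) for v in row]
            fh.write(" ".join([str(sid), str(sid), "0", "0", "0", "-9"] + toks) + "\n")


def write_phenotype_table(dataset: Dataset, path) -> None:
    df = pd.DataFrame(
        {
            "subject_id": dataset.geno.subject_ids,
            "time_years": dataset.time,
            "event": dataset.event,
            "status5y": dataset.status5y if dataset.status5y is not None else "",
            "included5y": dataset.included5y if dataset.included5y is not None else "",
        }
    )
    for col in ("age", "stage", "msi", "location", "chemo", "radio"):
        if col in dataset.covariates:
            df[col] = dataset.covariates[col].to_numpy()
    df.to_csv(path, sep="\t", index=False)


def read_phenotype_table(path) -> pd.DataFrame:
    """Typed parse of the phenotype/covariate TSV; validates units and levels."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    required = ["subject_id", "time_years", "event"]
    for col in required:
        if col not in df.columns:
            raise DataError(f"{path}: missing required column {col!r}")
    known = set(PHENO_COLUMNS)
    extra = [c for c in df.columns if c not in known]
    if extra:
        import warnings

        warnings.warn(f"{path}: ignoring unknown columns {extra}", stacklevel=2)
    times = pd.to_numeric(df["time_years"], errors="coerce")
    if times.isna().any():
        row = int(np.flatnonzero(times.isna())[0]) + 2
        raise DataError(f"{path}: line {row}: non-numeric time_years")
    if (times <= 0).any():
        row = int(np.flatnonzero(times <= 0)[0]) + 2
        raise DataError(f"{path}: line {row}: time_years must be positive")
    events = df["event"]
    if not events.isin([0, 1]).all():
        row = int(np.flatnonzero(~events.isin([0, 1]))[0]) + 2
        raise DataError(f"{path}: line {row}: event must be 0 or 1")
    if "stage" in df.columns and not df["stage"].isin([1, 2, 3, 4]).all():
        row = int(np.flatnonzero(~df["stage"].isin([1, 2, 3, 4]))[0]) + 2
        raise DataError(f"{path}: line {row}: unknown stage level")
    for col in ("msi", "location", "chemo", "radio", "status5y", "included5y"):
        if col in df.columns and not df[col].isin([0, 1]).all():
            row = int(np.flatnonzero(~df[col].isin([0, 1]))[0]) + 2
            raise DataError(f"{path}: line {row}: {col} must be 0 or 1")
    return df


def load_dataset(raw_path, pheno_path) -> Dataset:
    """Inner join of a .raw genotype file and a phenotype TSV on subject id."""
    geno = read_plink_raw(raw_path)
    pheno = read_phenotype_table(pheno_path)
    pheno = pheno.set_index("subject_id")
    common = [s for s in geno.subject_ids if s in pheno.index]
    dropped = len(geno.subject_ids) - len(common)
    if dropped:
        import warnings

        warnings.warn(f"dropping {dropped} subjects absent from the phenotype table", stacklevel=2)
    keep = np.isin(geno.subject_ids, common)
    geno = GenotypeMatrix(dosage=geno.dosage[keep], subject_ids=geno.subject_ids[keep], snps=geno.snps)
    pheno = pheno.loc[geno.subject_ids]
    cov_cols = [c for c in ("age", "stage", "msi", "location", "chemo", "radio") if c in pheno]
    return Dataset(
        geno=geno,
        covariates=pheno[cov_cols].reset_index(drop=True),
        time=pheno["time_years"].to_numpy(float),
        event=pheno["event"].to_numpy(int),
        status5y=pheno["status5y"].to_numpy(int) if "status5y" in pheno else None,
        included5y=pheno["included5y"].to_numpy(int) if "included5y" in pheno else None,
    )


def format_cell(cell, snps: pd.DataFrame) -> str:
    """Human-readable genotype cell, e.g. ``(1GT,0TT)``.

    Each element is the minor-allele dosage digit followed by the genotype
    letters (0 = major homozygote, 1 = heterozygote, 2 = minor homozygote).
    """
    parts = []
    for dose, (_, row) in zip(cell, snps.iterrows()):
        major = row["major_allele"] or "N"
        minor = row["minor_allele"] or "N"
        genotype = {0: major + major, 1: minor + major, 2: minor + minor}[int(dose)]
        parts.append(f"{dose}{genotype}")
    return "(" + ",".join(parts) + ")"


def write_report(report, outdir) -> dict:
    """Write a PipelineReport as JSON plus human-readable TSV tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    payload = report.to_dict()
    paths["json"] = outdir / "report.json"
    with open(paths["json"], "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
    rows = []
    for section, recs in (("main_effect", payload["iterations"]), ("multiway", payload["multiway"])):
        for rec in recs:
            tm = rec["top_model"]
            reg = rec["regression"]
            rows.append(
                {
                    "section": section,
                    "iteration": rec["iteration"],
                    "k": rec["k"],
                    "snp_ids": ",".join(tm["snp_ids"]),
                    "high_risk_cells": " ".join(
                        "(" + ",".join(map(str, c)) + ")" for c in tm["high_cells"]
                    ),
                    "frequency": f"{tm['frequency']}/{tm['n_runs']}",
                    "mean_tba": tm["mean_tba"],
                    "cvc": tm["cvc"],
                    "permutation_p": rec["permutation_p_label"],
                    "regression_p": "" if reg is None else reg["p_value"],
                    "effect": "" if reg is None else f"{reg['effect_type']}={reg['estimate']:.3f}",
                    "ci95": "" if reg is None else f"{reg['ci_lower']:.3f}-{reg['ci_upper']:.3f}",
                    "removed_snp_ids": ",".join(rec["removed_snp_ids"]),
                    "stop_reason": rec["stop_reason"],
                }
            )
    table = pd.DataFrame(rows)
    paths["tsv"] = outdir / "report.tsv"
    table.to_csv(paths["tsv"], sep="\t", index=False)
    if not rows:
        with open(paths["tsv"], "w") as fh:
            fh.write("# no models evaluated\n")
    return paths


def read_report(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
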