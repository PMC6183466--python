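"""Readers and writers for the pipeline's file formats.

Genotypes travel as a CSV matrix (rows = individuals, first column the
individual id, remaining columns loci, cells 0/1/2 with empty = missing) or
as VCF (biallelic sites, GT field, dosage = ALT allele count, ./. missing).
Station metadata, fish records and otolith increments are plain CSVs with
documented headers; all outputs are TSV with locale-independent formatting.
"""

from __future__ import annotations

import datetime as dt
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "read_genotypes",
    "write_genotypes_csv",
    "write_genotypes_vcf",
    "read_stations",
    "read_survey",
    "read_otoliths",
    "write_table",
    "write_manifest",
]


def read_genotypes(path, format: str | None = None) -> pd.DataFrame:
    """Read a genotype matrix from CSV or VCF into individuals x loci dosages.

    Format is inferred from the suffix unless given. Cells are float 0/1/2
    with NaN for missing. Duplicate individual or locus ids raise.
    """
    path = Path(path)
    fmt = format or ("vcf" if path.suffix.lower() == ".vcf" else "csv")
    if fmt == "csv":
        df = pd.read_csv(path, index_col=0, comment="#")
        df = df.apply(pd.to_numeric, errors="raise").astype(float)
        bad = df.stack().pipe(lambda s: s[~s.isin([0.0, 1.0, 2.0])])
        if len(bad):
            r, c = bad.index[0]
            raise ValueError(f"malformed dosage {bad.iloc[0]!r} at row {r!r}, column {c!r}")
    elif fmt == "vcf":
        df = _read_vcf(path)
    else:
        raise ValueError(f"unknown genotype format {fmt!r}")
    if df.index.duplicated().any():
        raise ValueError("duplicate individual ids in genotype input")
    if df.columns.duplicated().any():
        raise ValueError("duplicate locus ids in genotype input")
    return df


def _read_vcf(path: Path) -> pd.DataFrame:
    import warnings

    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    loci, rows = [], []
    skipped = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            skipped += 1
            continue
        loci.append(rec.ID or f"{rec.CHROM}:{rec.POS}")
        # gt_types: 0=hom-ref 1=het 2=unknown 3=hom-alt
        g = np.array(rec.gt_types, dtype=float)
        dos = np.where(g == 3, 2.0, g)
        dos[g == 2] = np.nan
        rows.append(dos)
    if skipped:
        warnings.warn(f"skipped {skipped} non-biallelic VCF record(s)", RuntimeWarning)
    return pd.DataFrame(np.array(rows).T if rows else np.empty((len(samples), 0)),
                        index=samples, columns=loci)


def write_genotypes_csv(genotypes: pd.DataFrame, path) -> None:
    """Write the dosage matrix as CSV (empty cell = missing)."""
    out = genotypes.copy()
    out.index.name = "individual"
    with open(path, "w") as fh:
        fh.write("# genotype dosage matrix: allele-1 count per locus, empty = missing\n")
        out.to_csv(fh, float_format="%.0f", na_rep="")


def write_genotypes_vcf(genotypes: pd.DataFrame, path) -> None:
    """Write dosages as a minimal biallelic VCF (one sample per individual)."""
    inds = list(genotypes.index)
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("##contig=<ID=1>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(inds) + "\n")
        for pos, locus in enumerate(genotypes.columns, start=1):
            cells = [
                gt_map.get(v, "./.") if not pd.isna(v) else "./."
                for v in genotypes[locus]
            ]
            fh.write(f"1\t{pos}\t{locus}\tA\tG\t.\tPASS\t.\tGT\t" + "\t".join(cells) + "\n")


def read_stations(path) -> pd.DataFrame:
    """Station metadata CSV: station, region, distance_m, wave_exposure,
    veg_type, veg_cover."""
    df = pd.read_csv(path, comment="#")
    need = {"station", "region", "distance_m", "wave_exposure", "veg_type", "veg_cover"}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"station table missing columns: {sorted(missing)}")
    return df


def read_survey(path) -> pd.DataFrame:
    """Fish-record CSV: fish_id, station, year, length_cm (+ extras)."""
    df = pd.read_csv(path, comment="#")
    need = {"fish_id", "station", "year", "length_cm"}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"fish table missing columns: {sorted(missing)}")
    return df


def read_otoliths(path) -> pd.DataFrame:
    """Otolith increment CSV: fish_id, day_index, increment_width_um."""
    df = pd.read_csv(path, comment="#")
    need = {"fish_id", "day_index", "increment_width_um"}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"otolith table missing columns: {sorted(missing)}")
    return df


def write_table(df: pd.DataFrame, path, comment: str | None = None) -> None:
    """Write a TSV with an optional leading comment line; dot decimals,
    fixed column order."""
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def write_manifest(path, config: dict, seed: int, inputs: dict[str, str] | None = None) -> None:
    """Record the run configuration, seed and input digests as YAML."""
    import hashlib

    digests = {}
    for name, p in (inputs or {}).items():
        h = hashlib.sha256(Path(p).read_bytes()).hexdigest()[:16]
        digests[name] = {"path": str(p), "sha256_16": h}
    doc = {
        "created": dt.datetime.now().isoformat(timespec="seconds"),
        "seed": int(seed),
        "config": config,
        "inputs": digests,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
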