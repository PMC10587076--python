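"""Readers and writers for the package's interchange formats.

Genotypes travel either as VCF (hybrids as samples, biallelic SNPs only)
or as a CSV matrix (rows = hybrids, header = locus IDs, cells 0/1/2 or
empty for missing). All CSVs are comma-separated UTF-8 with period
decimals; every writer can stamp a provenance header line (seed and
config hash) as a leading ``#`` comment.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .genomics import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


class DataError(ValueError):
    """Schema violation in an input file, locating file/row/column."""


def write_genotypes_csv(g: GenotypeMatrix, path, header_comment: str | None = None) -> None:
    path = Path(path)
    codes = np.asarray(g.codes)
    df = pd.DataFrame(codes, index=g.hybrid_ids, columns=g.locus_ids)
    df = df.mask(codes == MISSING)
    with path.open("w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, index_label="hybrid", float_format="%g")


def read_genotypes_csv(path) -> GenotypeMatrix:
    path = Path(path)
    df = pd.read_csv(path, comment="#", index_col=0)
    codes = df.to_numpy(dtype=float)
    bad = ~(np.isnan(codes) | np.isin(codes, (0.0, 1.0, 2.0)))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise DataError(
            f"{path}: invalid genotype code {codes[i, j]!r} at row "
            f"{df.index[i]!r}, column {df.columns[j]!r}"
        )
    out = np.where(np.isnan(codes), MISSING, codes).astype(np.int8)
    return GenotypeMatrix(out, list(df.index.astype(str)), list(df.columns.astype(str)))


_GT_TO_CODE = {(0, 0): 0, (0, 1): 1, (1, 0): 1, (1, 1): 2}


def write_vcf(g: GenotypeMatrix, path, ref: str = "A", alt: str = "G") -> None:
    """Minimal VCF 4.2 with hybrids as samples; code = ALT-allele dosage."""
    path = Path(path)
    codes = np.asarray(np.rint(g.codes), dtype=int)
    gt_strings = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("##contig=<ID=1>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.hybrid_ids)
            + "\n"
        )
        for j, locus in enumerate(g.locus_ids):
            gts = "\t".join(gt_strings[int(c)] for c in codes[:, j])
            fh.write(f"1\t{j + 1}\t{locus}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{gts}\n")


def read_vcf(path) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF; multiallelic records are skipped."""
    from cyvcf2 import VCF

    path = str(path)
    vcf = VCF(path)
    samples = list(vcf.samples)
    cols = []
    ids = []
    n_multi = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        col = np.full(len(samples), MISSING, dtype=np.int8)
        for i, gt in enumerate(var.genotypes):
            a, b = gt[0], gt[1]
            if a < 0 or b < 0:
                continue
            col[i] = _GT_TO_CODE.get((min(a, b), max(a, b)), MISSING)
        cols.append(col)
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
    if n_multi:
        logger.info("read_vcf: skipped %d multiallelic records", n_multi)
    if not cols:
        raise DataError(f"{path}: no biallelic SNP records")
    return GenotypeMatrix(np.column_stack(cols), samples, ids)


def write_relationship_csv(matrix: np.ndarray, ids: list[str], path) -> None:
    pd.DataFrame(matrix, index=ids, columns=ids).to_csv(path, index_label="hybrid")


def read_relationship_csv(path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, index_col=0)
    return df.to_numpy(dtype=float), list(df.index.astype(str))


ENV_COLUMNS = [
    "timestamp",
    "temperature_C",
    "rh_percent",
    "vpd_kPa",
    "ppfd",
    "soil_water_potential_MPa",
]


def write_env_csv(env: pd.DataFrame, path) -> None:
    env[ENV_COLUMNS].to_csv(path, index=False)


def read_env_csv(path) -> pd.DataFrame:
    path = Path(path)
    env = pd.read_csv(path)
    missing = set(ENV_COLUMNS) - set(env.columns)
    if missing:
        raise DataError(f"{path}: missing environment columns {sorted(missing)}")
    return env


PLOT_COLUMNS = ["genotype", "replicate", "row", "column", "value"]


def read_plot_csv(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    missing = set(PLOT_COLUMNS) - set(df.columns)
    if missing:
        raise DataError(f"{path}: missing plot-table columns {sorted(missing)}")
    vals = pd.to_numeric(df["value"], errors="coerce")
    bad = vals.isna() & df["value"].notna()
    if bad.any():
        row = int(np.argmax(bad.to_numpy()))
        raise DataError(
            f"{path}: non-numeric value {df['value'].iloc[row]!r} at row {row}, "
            "column 'value'"
        )
    df["value"] = vals
    return df


def write_json_report(obj: dict, path, seed: int | None = None, config_hash: str | None = None) -> None:
    payload = dict(obj)
    if seed is not None or config_hash is not None:
        payload["_provenance"] = {"seed": seed, "config_hash": config_hash}
    Path(path).write_text(json.dumps(payload, indent=2, default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
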