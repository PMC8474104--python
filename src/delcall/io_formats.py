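"""Readers/writers for the text formats the pipeline touches.

HAPS/SAMPLE follow the SHAPEIT v2 dialect (HAPS: chrom, id, pos, allele0,
allele1 then two 0/1 columns per individual; SAMPLE: two header lines then
one row per individual). GEN is the 3-probabilities-per-individual IMPUTE
style. Everything round-trips at declared precision.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import HaplotypePanel, PanelError, RecombinationMap
from .tables import ETHNICITY_DEFAULT, IntensityTable, PhenotypeTable, TableError


class FormatError(ValueError):
    """Malformed input file."""


# ---------------------------------------------------------------- HAPS/SAMPLE

def write_haps_sample(panel: HaplotypePanel, haps_path, sample_path,
                      chrom: str = "16") -> None:
    haps_path, sample_path = Path(haps_path), Path(sample_path)
    with haps_path.open("w") as fh:
        for j in range(panel.n_variants):
            body = " ".join(str(int(a)) for a in panel.alleles[:, j])
            fh.write(f"{chrom} {panel.variant_ids[j]} {panel.positions_bp[j]} A G {body}\n")
    with sample_path.open("w") as fh:
        fh.write("ID_1 ID_2 missing\n0 0 0\n")
        for ind in panel.individual_ids:
            fh.write(f"{ind} {ind} 0\n")


def read_haps_sample(haps_path, sample_path) -> HaplotypePanel:
    haps_path, sample_path = Path(haps_path), Path(sample_path)
    with sample_path.open() as fh:
        lines = [ln.split() for ln in fh if ln.strip()]
    if len(lines) < 2:
        raise FormatError(f"{sample_path}: truncated SAMPLE file")
    individual_ids = [row[0] for row in lines[2:]]
    n_ind = len(individual_ids)

    variant_ids, positions, cols = [], [], []
    expected = 5 + 2 * n_ind
    with haps_path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != expected:
                raise FormatError(
                    f"{haps_path}:{lineno}: expected {expected} fields, got {len(parts)}")
            variant_ids.append(parts[1])
            positions.append(int(parts[2]))
            try:
                alleles = [int(v) for v in parts[5:]]
            except ValueError as exc:
                raise FormatError(f"{haps_path}:{lineno}: non-integer allele code") from exc
            if any(a not in (0, 1) for a in alleles):
                raise FormatError(f"{haps_path}:{lineno}: allele codes must be 0/1")
            cols.append(alleles)
    if not cols:
        raise FormatError(f"{haps_path}: no variant rows")
    positions = np.asarray(positions, dtype=np.int64)
    if np.any(np.diff(positions) <= 0):
        raise FormatError(f"{haps_path}: positions not strictly increasing")
    alleles = np.asarray(cols, dtype=np.int8).T  # chromosomes x variants
    del_index = variant_ids.index("DEL") if "DEL" in variant_ids else None
    return HaplotypePanel(alleles=alleles, variant_ids=variant_ids,
                          positions_bp=positions, del_index=del_index,
                          individual_ids=individual_ids)


# ------------------------------------------------------------------------ GEN

def write_gen(probabilities: np.ndarray, path, variant_id: str = "DEL",
              position: int = 0, chrom: str = "16") -> None:
    """One variant row, 3 genotype probabilities per individual, 6 decimals.

    probabilities: (n_individuals, 3) array ordered (WT, het, hom).
    """
    probs = np.asarray(probabilities, dtype=float)
    if probs.ndim != 2 or probs.shape[1] != 3:
        raise FormatError("probabilities must be (n, 3)")
    if (probs < 0).any() or (probs > 1).any():
        raise FormatError("genotype probabilities must lie in [0,1]")
    if (probs.sum(axis=1) > 1 + 1e-6).any():
        raise FormatError("genotype probabilities sum above 1")
    body = " ".join(f"{v:.6f}" for row in probs for v in row)
    with Path(path).open("w") as fh:
        fh.write(f"{chrom} {variant_id} {position} A G {body}\n")


def read_gen(path) -> tuple[str, int, np.ndarray]:
    with Path(path).open() as fh:
        parts = fh.readline().split()
    if len(parts) < 8 or (len(parts) - 5) % 3 != 0:
        raise FormatError(f"{path}: malformed GEN row")
    vals = np.asarray([float(v) for v in parts[5:]], dtype=float).reshape(-1, 3)
    return parts[1], int(parts[2]), vals


# ------------------------------------------------------------------ TSV files

def write_intensity_tsv(table: IntensityTable, path) -> None:
    table.df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_intensity_tsv(path) -> IntensityTable:
    df = pd.read_csv(path, sep="\t", dtype={"individual_id": str, "probe_id": str})
    try:
        return IntensityTable(df=df)
    except TableError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_phenotype_tsv(table: PhenotypeTable, path) -> None:
    table.df.to_csv(path, sep="\t", index=False)


def read_phenotype_tsv(path, known_ethnicities=ETHNICITY_DEFAULT) -> PhenotypeTable:
    df = pd.read_csv(path, sep="\t", dtype={"individual_id": str, "ethnicity": str})
    unknown = sorted(set(df.get("ethnicity", pd.Series(dtype=str))) - set(known_ethnicities))
    if unknown:
        warnings.warn(f"unknown ethnicity labels retained as own categories: {unknown}",
                      stacklevel=2)
    try:
        return PhenotypeTable(df=df)
    except TableError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_recomb_map(rmap: RecombinationMap, path) -> None:
    pd.DataFrame({
        "position_bp": rmap.positions_bp,
        "rate_cM_per_Mb": rmap.rate_cM_per_Mb,
        "cumulative_cM": rmap.cumulative_cM,
    }).to_csv(path, sep="\t", index=False, float_format="%.8f")


def read_recomb_map(path) -> RecombinationMap:
    df = pd.read_csv(path, sep="\t")
    required = {"position_bp", "rate_cM_per_Mb", "cumulative_cM"}
    if not required <= set(df.columns):
        raise FormatError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    try:
        return RecombinationMap(df["position_bp"].to_numpy(),
                                df["rate_cM_per_Mb"].to_numpy(),
                                df["cumulative_cM"].to_numpy())
    except PanelError as exc:
        raise FormatError(f"{path}: {exc}") from exc
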