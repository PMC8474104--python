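"""Tabular containers: per-probe two-channel intensities and phenotypes."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class TableError(ValueError):
    """Invalid intensity or phenotype table."""


@dataclass
class IntensityTable:
    """Long-format two-channel intensities: one row per (individual, probe).

    Columns: individual_id, probe_id, x, y. The summed signal s = x + y is
    the quantity most analyses operate on.
    """

    df: pd.DataFrame
    deletion_probes: list[str] = field(default_factory=list)

    REQUIRED = ("individual_id", "probe_id", "x", "y")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing:
            raise TableError(f"intensity table missing columns: {missing}")
        if self.df[["x", "y"]].isna().any().any():
            raise TableError("missing intensity values")
        if (self.df["x"] < 0).any() or (self.df["y"] < 0).any():
            raise TableError("negative intensity")
        dup = self.df.duplicated(subset=["individual_id", "probe_id"])
        if dup.any():
            pair = self.df.loc[dup.idxmax(), ["individual_id", "probe_id"]]
            raise TableError(f"duplicated intensity record for {tuple(pair)}")

    @property
    def individuals(self) -> list[str]:
        return list(pd.unique(self.df["individual_id"]))

    @property
    def probes(self) -> list[str]:
        return list(pd.unique(self.df["probe_id"]))

    def wide(self, channel: str = "s") -> pd.DataFrame:
        """Individuals x probes matrix of channel 'x', 'y' or summed 's'."""
        d = self.df.copy()
        if channel == "s":
            d["val"] = d["x"] + d["y"]
        elif channel in ("x", "y"):
            d["val"] = d[channel]
        else:
            raise TableError(f"unknown channel {channel!r}")
        w = d.pivot(index="individual_id", columns="probe_id", values="val")
        return w.loc[self.individuals]

    def summed(self, probe_id: str) -> np.ndarray:
        """Summed intensity s = x + y for one probe, in individual order."""
        sub = self.df[self.df["probe_id"] == probe_id].set_index("individual_id")
        if sub.empty:
            raise TableError(f"unknown probe {probe_id!r}")
        sub = sub.loc[[i for i in self.individuals if i in sub.index]]
        return (sub["x"] + sub["y"]).to_numpy(dtype=float)

    def feature_matrix(self, probes: list[str] | None = None,
                       mode: str = "xy_interaction") -> tuple[np.ndarray, list[str]]:
        """Model feature matrix per individual.

        mode 'xy_interaction': columns (x, y, x*y) per probe;
        mode 'sum': a single summed-intensity column per probe.
        """
        probes = list(probes) if probes is not None else self.probes
        xw = self.wide("x")
        yw = self.wide("y")
        cols, names = [], []
        for p in probes:
            if p not in xw.columns:
                raise TableError(f"unknown probe {p!r}")
            xv = xw[p].to_numpy(dtype=float)
            yv = yw[p].to_numpy(dtype=float)
            if mode == "xy_interaction":
                cols += [xv, yv, xv * yv]
                names += [f"{p}:x", f"{p}:y", f"{p}:xy"]
            elif mode == "sum":
                cols.append(xv + yv)
                names.append(f"{p}:s")
            else:
                raise TableError(f"unknown feature mode {mode!r}")
        return np.column_stack(cols), names


ETHNICITY_DEFAULT = ("Giriama", "Chonyi", "Kauma", "Other")


@dataclass
class PhenotypeTable:
    """Per-individual case/control status and covariates.

    Columns: individual_id, status (1=case), sex (0/1), ethnicity (label),
    rs334_genotype (allele dosage 0/1/2).
    """

    df: pd.DataFrame

    REQUIRED = ("individual_id", "status", "sex", "ethnicity", "rs334_genotype")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing:
            raise TableError(f"phenotype table missing columns: {missing}")
        dup = self.df["individual_id"].duplicated()
        if dup.any():
            raise TableError(
                f"duplicated individual_id {self.df.loc[dup.idxmax(), 'individual_id']!r}")
        if not set(np.unique(self.df["status"])) <= {0, 1}:
            raise TableError("status must be 0/1")
        if not set(np.unique(self.df["sex"])) <= {0, 1}:
            raise TableError("sex must be 0/1")
        if not set(np.unique(self.df["rs334_genotype"])) <= {0, 1, 2}:
            raise TableError("rs334_genotype must be in {0,1,2}")

    @property
    def individuals(self) -> list[str]:
        return list(self.df["individual_id"])

    def aligned(self, individual_ids) -> pd.DataFrame:
        sub = self.df.set_index("individual_id")
        missing = [i for i in individual_ids if i not in sub.index]
        if missing:
            raise TableError(f"phenotypes missing for individuals: {missing[:5]}")
        return sub.loc[list(individual_ids)].reset_index()
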