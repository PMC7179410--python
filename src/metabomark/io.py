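"""Feature-table I/O and packaged compound fixtures.

An aligned untargeted LC-MS experiment arrives as a feature table: one row per
detected feature (with m/z and retention time) and one abundance column per
sample, as exported by vendor alignment software.  In memory the analysis
convention is transposed — samples are rows, features are columns — because
every downstream model (t-tests, PCA, OPLS-DA, random forests) treats samples
as observations.

Missing measurements are blank cells on disk and NaN in memory; they are
preserved by the reader and only imputed explicitly by the preprocessing step.
"""

from __future__ import annotations

import importlib.resources
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

QC_LABEL = "qc"


class FeatureTableError(ValueError):
    """Structural or consistency problem in a feature table."""


@dataclass
class FeatureTable:
    """Samples x features abundance matrix with sample and feature metadata.

    Parameters
    ----------
    abundances : pandas.DataFrame
        Non-negative intensities, samples as rows (index = sample ids),
        features as columns (columns = feature ids).  NaN marks a missing
        (undetected) measurement.
    groups : pandas.Series
        Group label per sample, indexed like ``abundances``.  The label
        ``"qc"`` (case-insensitive) marks pooled quality-control injections;
        any other labels are biological groups.
    feature_mz, feature_rt : pandas.Series
        m/z (Th) and retention time (min) per feature, indexed by feature id.
    """

    abundances: pd.DataFrame
    groups: pd.Series
    feature_mz: pd.Series
    feature_rt: pd.Series

    def __post_init__(self) -> None:
        self.groups = self.groups.reindex(self.abundances.index)
        self.validate()

    # -- structure ---------------------------------------------------------

    def validate(self) -> None:
        ab = self.abundances
        if ab.index.duplicated().any():
            dupes = ab.index[ab.index.duplicated()].tolist()
            raise FeatureTableError(f"duplicate sample ids: {dupes}")
        if ab.columns.duplicated().any():
            dupes = ab.columns[ab.columns.duplicated()].tolist()
            raise FeatureTableError(f"duplicate feature ids: {dupes}")
        if self.groups.isna().any():
            missing = ab.index[self.groups.isna()].tolist()
            raise FeatureTableError(f"samples without group label: {missing}")
        vals = ab.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0:
            raise FeatureTableError("negative abundance values")
        for name, series in (("m/z", self.feature_mz), ("RT", self.feature_rt)):
            extra = series.index.difference(ab.columns)
            if len(extra) or len(ab.columns.difference(series.index)):
                raise FeatureTableError(f"feature {name} index does not match features")
        if (self.feature_mz <= 0).any():
            raise FeatureTableError("feature m/z must be positive")
        if (self.feature_rt < 0).any():
            raise FeatureTableError("feature RT must be non-negative")

    # -- convenience -------------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return list(self.abundances.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.abundances.columns)

    @property
    def n_samples(self) -> int:
        return self.abundances.shape[0]

    @property
    def n_features(self) -> int:
        return self.abundances.shape[1]

    def qc_mask(self) -> pd.Series:
        return self.groups.str.lower() == QC_LABEL

    def group_labels(self) -> list[str]:
        """The biological (non-QC) group labels, sorted for determinism."""
        return sorted(set(self.groups[~self.qc_mask()]))

    def biological(self) -> "FeatureTable":
        """The table restricted to biological (non-QC) samples."""
        keep = ~self.qc_mask()
        return self.select_samples(self.abundances.index[keep])

    def select_samples(self, sample_ids: Sequence[str]) -> "FeatureTable":
        return FeatureTable(
            abundances=self.abundances.loc[list(sample_ids)],
            groups=self.groups.loc[list(sample_ids)],
            feature_mz=self.feature_mz,
            feature_rt=self.feature_rt,
        )

    def select_features(self, feature_ids: Sequence[str]) -> "FeatureTable":
        cols = list(feature_ids)
        return FeatureTable(
            abundances=self.abundances[cols],
            groups=self.groups,
            feature_mz=self.feature_mz.loc[cols],
            feature_rt=self.feature_rt.loc[cols],
        )


def read_feature_table(path: str | Path, metadata_path: str | Path) -> FeatureTable:
    """Read a CSV feature table plus a YAML/JSON sample-metadata file.

    On disk the table is feature-per-row (columns: ``feature_id``, ``mz``,
    ``rt``, then one column per sample id); blank cells are missing.  The
    metadata file maps every sample id to its group label, either as a flat
    ``{sample_id: group}`` mapping or under a ``groups:`` key.
    """
    path, metadata_path = Path(path), Path(metadata_path)
    raw = pd.read_csv(path, dtype={"feature_id": str})
    required = {"feature_id", "mz", "rt"}
    if not required.issubset(raw.columns):
        raise FeatureTableError(f"feature table must have columns {sorted(required)}")
    if raw["feature_id"].duplicated().any():
        raise FeatureTableError("duplicate feature ids in feature table")
    raw = raw.set_index("feature_id")
    sample_cols = [c for c in raw.columns if c not in ("mz", "rt")]

    with open(metadata_path) as fh:
        meta = yaml.safe_load(fh)
    if isinstance(meta, dict) and "groups" in meta:
        meta = meta["groups"]
    if not isinstance(meta, dict):
        raise FeatureTableError("metadata must map sample ids to group labels")
    absent = [s for s in sample_cols if s not in meta]
    if absent:
        raise FeatureTableError(f"samples absent from metadata: {absent}")

    abundances = raw[sample_cols].T.astype(float)
    abundances.index.name = "sample_id"
    abundances.columns.name = None
    groups = pd.Series({s: str(meta[s]) for s in sample_cols}, name="group")
    return FeatureTable(
        abundances=abundances,
        groups=groups,
        feature_mz=raw["mz"].astype(float),
        feature_rt=raw["rt"].astype(float),
    )


def write_feature_table(
    table: FeatureTable, path: str | Path, metadata_path: str | Path
) -> None:
    """Write a FeatureTable back to the on-disk orientation (features as rows)."""
    out = pd.DataFrame(
        {"mz": table.feature_mz, "rt": table.feature_rt}
    ).join(table.abundances.T)
    out.index.name = "feature_id"
    out.to_csv(path)
    with open(metadata_path, "w") as fh:
        yaml.safe_dump({"groups": table.groups.to_dict()}, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# Packaged compound fixtures
# ---------------------------------------------------------------------------


class Adduct(Enum):
    """Negative-mode ion species observed for these compounds."""

    M_MINUS_H = "[M-H]"
    M_PLUS_FORMATE = "[M-H+HCOOH]"


_ADDUCT_ALIASES = {
    "[M-H]": Adduct.M_MINUS_H,
    "[M-H+HCOOH]": Adduct.M_PLUS_FORMATE,
    # one fixture row prints the formate adduct as [M-H+COOH]
    "[M-H+COOH]": Adduct.M_PLUS_FORMATE,
}


@dataclass
class CompoundRecord:
    """One printed row of the characterised-constituent / marker tables."""

    index: int
    name: str
    formula: str | None
    printed_mz: float
    adduct: Adduct | None
    adduct_text: str
    fragment_ions: list[float] = field(default_factory=list)
    rt: float = float("nan")
    in_scabra: bool = False
    in_rigescens: bool = False
    compound_class: str | None = None


def _parse_fragments(text: str) -> list[float]:
    if not text or not text.strip():
        return []
    out = []
    for tok in re.split(r"/", text):
        tok = tok.strip()
        if tok:
            out.append(float(tok))
    return out


def _data_file(name: str):
    return importlib.resources.files("metabomark.data").joinpath(name)


def load_compound_fixture(which: str) -> list[CompoundRecord]:
    """Load the packaged constituent table (``"table1"``) or marker table (``"table2"``).

    Every printed row becomes one :class:`CompoundRecord`; printed m/z values are
    preserved exactly, including the rows whose printed value is internally
    inconsistent with the formula (those are surfaced by the annotation audit,
    never corrected here).
    """
    if which not in ("table1", "table2"):
        raise ValueError("which must be 'table1' or 'table2'")
    fname = (
        "table1_constituents.csv" if which == "table1" else "table2_markers.csv"
    )
    try:
        with _data_file(fname).open() as fh:
            df = pd.read_csv(fh, dtype=str).fillna("")
    except FileNotFoundError as exc:  # pragma: no cover - packaging defect
        raise RuntimeError(f"packaged fixture {fname} missing") from exc

    records = []
    for _, row in df.iterrows():
        adduct_text = row.get("adduct", "")
        adduct = _ADDUCT_ALIASES.get(adduct_text) if adduct_text else None
        records.append(
            CompoundRecord(
                index=int(row["no"]),
                name=row["name"],
                formula=row["formula"] or None,
                printed_mz=float(row["mz"]),
                adduct=adduct,
                adduct_text=adduct_text,
                fragment_ions=_parse_fragments(row.get("fragment_ions", "")),
                rt=float(row["rt"]),
                in_scabra=row.get("scabra", "") == "+",
                in_rigescens=row.get("rigescens", "") == "+",
                compound_class=row.get("compound_class") or None,
            )
        )
    if which == "table1":
        for rec in records:
            if not (rec.in_scabra or rec.in_rigescens):
                raise RuntimeError(f"fixture row {rec.index} has no species flag")
    return records


def load_sample_design() -> pd.DataFrame:
    """The packaged sample-collection design: species, location, batch count.

    Returns a DataFrame with one row per collection site and an ``n_samples``
    column derived from the printed sample-number ranges (52 scabra batches
    and 34 rigescens batches; the running text mentions 54 scabra batches,
    which does not match the enumeration and is recorded only in docs).
    """
    with _data_file("table3_samples.csv").open() as fh:
        df = pd.read_csv(fh, dtype=str)

    def _count(rng: str) -> int:
        parts = rng.split("-")
        if len(parts) == 1:
            return 1
        return int(parts[1]) - int(parts[0]) + 1

    df["n_samples"] = df["sample_numbers"].map(_count)
    return df
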