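"""Tabular input/output and assembly of analysis-ready pair records.

All artifacts are UTF-8 tab-separated text with headers and '.' decimals.

* methylation (long/tidy): ``site_id  pair_id  twin_index  occasion  m_value``
* pairs: ``pair_id  zygosity  country  sex  age_t1  age_t2`` plus four 0/1
  observation columns ``obs_t1_1 obs_t2_1 obs_t1_2 obs_t2_2`` (occasion x twin)
* annotation: ``site_id  island_relation`` plus optional 0/1 set-membership
  flag columns; an Illumina-manifest importer maps ``IlmnID`` /
  ``Relation_to_UCSC_CpG_Island`` naming onto the same shape
* results: one row per site x model variant, written/read losslessly

The tidy layout makes missing slots explicit: an absent row simply marks the
slot unobserved.  A wide sites-by-samples importer is provided for
convenience.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .records import ISLAND_RELATIONS, SET_NAMES, SiteAnnotation, TwinPairRecord

__all__ = [
    "ParseError",
    "JoinError",
    "read_methylation",
    "read_pairs",
    "read_annotation",
    "read_site_set",
    "assemble_records",
    "load_dataset",
    "write_methylation",
    "write_pairs",
    "write_results",
    "read_results",
    "records_to_frames",
    "from_wide",
]

METH_COLUMNS = ["site_id", "pair_id", "twin_index", "occasion", "m_value"]
OBS_COLUMNS = ["obs_t1_1", "obs_t2_1", "obs_t1_2", "obs_t2_2"]  # slot order
PAIR_COLUMNS = ["pair_id", "zygosity", "country", "sex", "age_t1", "age_t2"] + OBS_COLUMNS

# Illumina manifest island nomenclature -> canonical labels
_ILLUMINA_ISLANDS = {
    "Island": "Island",
    "N_Shore": "North Shore",
    "S_Shore": "South Shore",
    "N_Shelf": "North Shelf",
    "S_Shelf": "South Shelf",
    "": "Open Seas",
}


class ParseError(ValueError):
    """A file violates the expected tabular contract (includes line numbers)."""


class JoinError(ValueError):
    """Cross-table identifiers do not line up."""


def _read_tsv(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty file") from exc


def _require_columns(df: pd.DataFrame, cols: Iterable[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")


def read_methylation(path) -> pd.DataFrame:
    """Read tidy M-value observations, validating every row.

    Line numbers in errors refer to the file (header = line 1).  Duplicate
    (site, pair, twin, occasion) observations are rejected.
    """
    df = _read_tsv(path)
    _require_columns(df, METH_COLUMNS, path)
    df = df[METH_COLUMNS].copy()
    lines = df.index.to_numpy() + 2
    for col, allowed in (("twin_index", {"1", "2"}), ("occasion", {"1", "2"})):
        bad = ~df[col].isin(allowed)
        if bad.any():
            raise ParseError(
                f"{path}: invalid {col} at line(s) {lines[bad.to_numpy()][:5].tolist()}"
            )
    values = pd.to_numeric(df["m_value"], errors="coerce")
    bad = values.isna().to_numpy()
    if bad.any():
        raise ParseError(
            f"{path}: non-numeric m_value at line(s) {lines[bad][:5].tolist()}"
        )
    df["twin_index"] = df["twin_index"].astype(int)
    df["occasion"] = df["occasion"].astype(int)
    df["m_value"] = values.to_numpy()
    dup = df.duplicated(subset=["site_id", "pair_id", "twin_index", "occasion"])
    if dup.any():
        raise ParseError(
            f"{path}: duplicate observations at line(s) {lines[dup.to_numpy()][:5].tolist()}"
        )
    return df


def read_pairs(path) -> pd.DataFrame:
    """Read and validate the pairs/demographics table."""
    df = _read_tsv(path)
    _require_columns(df, PAIR_COLUMNS, path)
    df = df[PAIR_COLUMNS].copy()
    lines = df.index.to_numpy() + 2
    bad = ~df["zygosity"].isin(["MZ", "DZ"])
    if bad.any():
        raise ParseError(
            f"{path}: zygosity must be MZ/DZ at line(s) {lines[bad.to_numpy()][:5].tolist()}"
        )
    for col in ("country", "sex"):
        bad = ~df[col].isin(["0", "1"])
        if bad.any():
            raise ParseError(
                f"{path}: {col} must be 0/1 at line(s) {lines[bad.to_numpy()][:5].tolist()}"
            )
        df[col] = df[col].astype(int)
    for col in ("age_t1", "age_t2"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna().to_numpy()
        if bad.any():
            raise ParseError(f"{path}: non-numeric {col} at line(s) {lines[bad][:5].tolist()}")
        df[col] = vals.to_numpy()
    for col in OBS_COLUMNS:
        bad = ~df[col].isin(["0", "1"])
        if bad.any():
            raise ParseError(
                f"{path}: {col} must be 0/1 at line(s) {lines[bad.to_numpy()][:5].tolist()}"
            )
        df[col] = df[col].astype(int)
    if df["pair_id"].duplicated().any():
        dups = df.loc[df["pair_id"].duplicated(), "pair_id"].tolist()
        raise ParseError(f"{path}: duplicate pair_id(s) {dups[:5]}")
    return df


def read_annotation(path, illumina: bool = False) -> dict[str, SiteAnnotation]:
    """Read CpG annotations; blank island fields map to 'Open Seas'.

    With ``illumina=True`` the importer accepts Illumina-manifest naming
    (``IlmnID``, ``Relation_to_UCSC_CpG_Island``).
    """
    df = _read_tsv(path)
    if illumina:
        _require_columns(df, ["IlmnID", "Relation_to_UCSC_CpG_Island"], path)
        ids = df["IlmnID"]
        islands = df["Relation_to_UCSC_CpG_Island"].map(
            lambda s: _ILLUMINA_ISLANDS.get(s.strip(), None)
        )
        if islands.isna().any():
            bad = df.loc[islands.isna(), "Relation_to_UCSC_CpG_Island"].unique()
            raise ParseError(f"{path}: unknown island relation value(s) {bad[:5].tolist()}")
    else:
        _require_columns(df, ["site_id", "island_relation"], path)
        ids = df["site_id"]
        islands = df["island_relation"].map(
            lambda s: "Open Seas" if not s.strip() else s.strip()
        )
        bad = ~islands.isin(ISLAND_RELATIONS)
        if bad.any():
            raise ParseError(
                f"{path}: unknown island relation value(s) "
                f"{islands[bad].unique()[:5].tolist()}"
            )
    out = {}
    for i, site_id in enumerate(ids):
        sets = frozenset(
            name for name in SET_NAMES if name in df.columns and df[name].iloc[i] == "1"
        )
        out[site_id] = SiteAnnotation(
            site_id=site_id, island_relation=islands.iloc[i], set_memberships=sets
        )
    return out


def read_site_set(path) -> set[str]:
    """Read a site-id list (one per line, or the first column of a TSV)."""
    ids = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            token = line.strip().split("\t")[0]
            if token and token != "site_id":
                ids.add(token)
    return ids


def match_site_set(site_set: set[str], known_sites: Iterable[str]) -> tuple[set, set]:
    """Split a set list into (usable, absent-from-data); absences are reported
    by the caller, never fatal."""
    known = set(known_sites)
    usable = site_set & known
    return usable, site_set - usable


def assemble_records(
    meth: pd.DataFrame, pairs: pd.DataFrame
) -> dict[str, list[TwinPairRecord]]:
    """Group tidy observations into per-site :class:`TwinPairRecord` lists.

    Every pair_id in the methylation table must exist in the pairs table; the
    declared observation mask must cover every observed value (no value is
    silently dropped).
    """
    unknown = sorted(set(meth["pair_id"]) - set(pairs["pair_id"]))
    if unknown:
        raise JoinError(f"pair_id(s) in methylation but not in pairs table: {unknown[:10]}")
    meta = pairs.set_index("pair_id")
    slot_of = {(1, 1): 0, (1, 2): 1, (2, 1): 2, (2, 2): 3}
    dataset: dict[str, list[TwinPairRecord]] = {}
    for site_id, site_df in meth.groupby("site_id", sort=True):
        records = []
        for pair_id, pdf in site_df.groupby("pair_id", sort=True):
            row = meta.loc[pair_id]
            y = np.full(4, np.nan)
            for twin, occ, val in zip(pdf["twin_index"], pdf["occasion"], pdf["m_value"]):
                slot = slot_of[(twin, occ)]
                declared = row[OBS_COLUMNS[slot]]
                if not declared:
                    raise JoinError(
                        f"site {site_id}, pair {pair_id}: observation at twin {twin} "
                        f"occasion {occ} contradicts the pairs-table mask"
                    )
                y[slot] = val
            records.append(
                TwinPairRecord(
                    pair_id=pair_id,
                    zygosity=row["zygosity"],
                    country=int(row["country"]),
                    sex=int(row["sex"]),
                    age_t1=float(row["age_t1"]),
                    age_t2=float(row["age_t2"]),
                    y=y,
                )
            )
        dataset[site_id] = records
    return dataset


def load_dataset(meth_path, pairs_path) -> dict[str, list[TwinPairRecord]]:
    """Convenience reader: methylation + pairs -> per-site records."""
    return assemble_records(read_methylation(meth_path), read_pairs(pairs_path))


def records_to_frames(
    dataset: Mapping[str, list[TwinPairRecord]]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Inverse of :func:`assemble_records`: tidy methylation + pairs tables."""
    meth_rows, pair_rows, seen = [], [], set()
    slot_meta = [(1, 1), (1, 2), (2, 1), (2, 2)]
    for site_id in sorted(dataset):
        for rec in dataset[site_id]:
            if rec.pair_id not in seen:
                seen.add(rec.pair_id)
                row = {
                    "pair_id": rec.pair_id,
                    "zygosity": rec.zygosity,
                    "country": rec.country,
                    "sex": rec.sex,
                    "age_t1": rec.age_t1,
                    "age_t2": rec.age_t2,
                }
                for slot, col in enumerate(OBS_COLUMNS):
                    row[col] = int(rec.mask[slot])
                pair_rows.append(row)
            for slot, (twin, occ) in enumerate(slot_meta):
                if rec.mask[slot]:
                    meth_rows.append(
                        {
                            "site_id": site_id,
                            "pair_id": rec.pair_id,
                            "twin_index": twin,
                            "occasion": occ,
                            "m_value": rec.y[slot],
                        }
                    )
    return pd.DataFrame(meth_rows, columns=METH_COLUMNS), pd.DataFrame(
        pair_rows, columns=PAIR_COLUMNS
    )


def _write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def write_methylation(df: pd.DataFrame, path) -> None:
    _write_tsv(df[METH_COLUMNS], path)


def write_pairs(df: pd.DataFrame, path) -> None:
    _write_tsv(df[PAIR_COLUMNS], path)


def write_results(results: pd.DataFrame, path) -> None:
    """Write the per-site x variant results table (numeric round-trip safe)."""
    _write_tsv(results, path)


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def from_wide(df: pd.DataFrame, pairs: pd.DataFrame) -> pd.DataFrame:
    """Convert a wide sites-by-samples matrix to the tidy layout.

    Columns other than ``site_id`` must be named ``<pair_id>.<twin>.<occasion>``;
    NaN cells mark unobserved slots.
    """
    if "site_id" not in df.columns:
        raise ParseError("wide matrix requires a site_id column")
    long = df.melt(id_vars="site_id", var_name="sample", value_name="m_value")
    long = long.dropna(subset=["m_value"])
    parts = long["sample"].str.rsplit(".", n=2, expand=True)
    if parts.shape[1] != 3:
        raise ParseError("wide column names must look like '<pair_id>.<twin>.<occasion>'")
    long["pair_id"] = parts[0]
    long["twin_index"] = parts[1].astype(int)
    long["occasion"] = parts[2].astype(int)
    out = long[METH_COLUMNS].reset_index(drop=True)
    unknown = sorted(set(out["pair_id"]) - set(pairs["pair_id"]))
    if unknown:
        raise JoinError(f"pair_id(s) in matrix but not in pairs table: {unknown[:10]}")
    return out
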