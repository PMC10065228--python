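"""Binary, time-sliced, multi-level feature construction.

Each feature is a presence flag for a (concept, specificity level, source,
time window) combination: *did this participant have at least one matching
event in the window before their index date?*  Frequency is deliberately
collapsed to presence so that high-volume codes (prescriptions, procedures)
do not outweigh one-off diagnoses.  Concepts are code prefixes (level = prefix
length, mirroring the hierarchical dictionary) or named aggregate groups
("pain" = any specific pain code).  Two window schemes are supported:

* ``age_bands`` — 5-year bands of age at the event ([15,20) ... [30,35)),
  anchored on the week-of-birth midpoint;
* ``preindex_years`` — yearly slices counting back from the index date.

Events on or after the index date never contribute.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

DAYS_PER_YEAR = 365.25

DEFAULT_AGE_BANDS: tuple[tuple[float, float], ...] = (
    (15.0, 20.0), (20.0, 25.0), (25.0, 30.0), (30.0, 35.0))


@dataclass(frozen=True)
class FeatureConfig:
    scheme: str = "age_bands"               # "age_bands" | "preindex_years"
    age_bands: tuple[tuple[float, float], ...] = DEFAULT_AGE_BANDS
    n_preindex_years: int = 3
    levels: tuple[int, ...] = (1, 2, 3, 4, 5)
    include_aggregates: bool = True
    min_count: int = 5                      # prune features flagged in fewer participants

    def validate(self) -> None:
        if self.scheme not in ("age_bands", "preindex_years"):
            raise ValueError(f"unknown window scheme {self.scheme!r}")
        if any(lv < 1 for lv in self.levels):
            raise ValueError("levels must be >= 1")
        if self.n_preindex_years < 1:
            raise ValueError("n_preindex_years must be >= 1")
        if self.min_count < 1:
            raise ValueError("min_count must be >= 1")


def truncate_code(code: str, level: int) -> str:
    """First `level` characters of a code; saturates at the full code."""
    if level < 1:
        raise ValueError("level must be >= 1")
    return code[:level]


def make_key(concept: str, level: int | str, source: str, window: str) -> str:
    lv = f"L{level}" if isinstance(level, int) else level
    return f"{concept}|{lv}|{source}|{window}"


def parse_key(key: str) -> tuple[str, str, str, str]:
    concept, level, source, window = key.split("|")
    return concept, level, source, window


def _band_label(lo: float, hi: float) -> str:
    return f"a{lo:g}-{hi:g}"


def build_features(events: pd.DataFrame, cohort_table: pd.DataFrame,
                   patients: pd.DataFrame, cfg: FeatureConfig | None = None,
                   aggmap: dict[str, frozenset[str]] | None = None) -> pd.DataFrame:
    """Build the binary feature matrix for every cohort unit.

    Parameters
    ----------
    cohort_table : rows with ``unit_id, patient_id, index_date`` (the cohort
        module's long format, or any frame with those columns).
    patients : demographics, for week-of-birth anchoring of age bands.
    aggmap : group name -> set of code prefixes; groups become level
        ``AGG`` / source ``ANY`` features.

    Returns a DataFrame indexed by unit_id (all units, including all-zero
    rows) with uint8 presence flags, columns pruned to features present in at
    least ``min_count`` participants.
    """
    cfg = cfg or FeatureConfig()
    cfg.validate()
    units = cohort_table[["unit_id", "patient_id", "index_date"]].copy()
    if units["index_date"].isna().any():
        bad = units.loc[units["index_date"].isna(), "unit_id"].iloc[0]
        raise ValueError(f"unit {bad!r} has no index date")

    ev = events.merge(units, on="patient_id", how="inner")
    ev = ev[ev["event_date"] < ev["index_date"]]

    if cfg.scheme == "age_bands":
        ev = ev.merge(patients[["patient_id", "week_of_birth"]], on="patient_id",
                      how="left")
        dob_mid = ev["week_of_birth"] + pd.Timedelta(days=3, hours=12)
        age = (ev["event_date"] - dob_mid).dt.total_seconds() / (DAYS_PER_YEAR * 86400)
        window = pd.Series(pd.NA, index=ev.index, dtype="object")
        for lo, hi in cfg.age_bands:
            window = window.mask((age >= lo) & (age < hi), _band_label(lo, hi))
    else:
        days_before = (ev["index_date"] - ev["event_date"]).dt.days
        slice_no = np.ceil(days_before / DAYS_PER_YEAR).astype(int)
        window = pd.Series(pd.NA, index=ev.index, dtype="object")
        ok = (slice_no >= 1) & (slice_no <= cfg.n_preindex_years)
        window = window.mask(ok, "y" + slice_no.astype(str))
    ev = ev.assign(window=window).dropna(subset=["window"])

    pairs = []
    codes = ev["code"].astype(str)
    for lv in sorted(set(cfg.levels)):
        concept = codes.str.slice(0, lv)
        key = concept + f"|L{lv}|" + ev["source"] + "|" + ev["window"]
        pairs.append(pd.DataFrame({"unit_id": ev["unit_id"], "key": key}))
    if cfg.include_aggregates and aggmap:
        for group in sorted(aggmap):
            mask = codes.str.startswith(tuple(sorted(aggmap[group])))
            if mask.any():
                sub = ev[mask]
                key = group + "|AGG|ANY|" + sub["window"]
                pairs.append(pd.DataFrame({"unit_id": sub["unit_id"], "key": key}))

    all_units = units["unit_id"].to_numpy()
    if not pairs:
        return pd.DataFrame(index=pd.Index(all_units, name="unit_id"), dtype=np.uint8)
    flat = pd.concat(pairs, ignore_index=True).drop_duplicates()
    keys = np.sort(flat["key"].unique())
    row = pd.Categorical(flat["unit_id"], categories=all_units).codes
    col = pd.Categorical(flat["key"], categories=keys).codes
    mat = np.zeros((len(all_units), len(keys)), dtype=np.uint8)
    mat[row, col] = 1
    out = pd.DataFrame(mat, index=pd.Index(all_units, name="unit_id"), columns=keys)
    out = out.loc[:, out.sum(axis=0) >= cfg.min_count]
    return out


def feature_dictionary(matrix: pd.DataFrame) -> pd.DataFrame:
    """Decode the matrix's column keys into their components."""
    rows = [(k, *parse_key(k)) for k in matrix.columns]
    return pd.DataFrame(rows, columns=["feature_key", "concept", "level",
                                       "source", "window"])


def write_matrix(matrix: pd.DataFrame, outdir: str | Path) -> dict[str, Path]:
    """Sparse triplet CSV (unit_id, feature_key, 1) + feature dictionary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    r, c = np.nonzero(matrix.to_numpy())
    triplets = pd.DataFrame({"unit_id": matrix.index.to_numpy()[r],
                             "feature_key": matrix.columns.to_numpy()[c],
                             "value": 1})
    paths = {"matrix": outdir / "feature_matrix.csv",
             "dictionary": outdir / "feature_dictionary.csv",
             "units": outdir / "feature_units.csv"}
    triplets.to_csv(paths["matrix"], index=False, lineterminator="\r\n")
    feature_dictionary(matrix).to_csv(paths["dictionary"], index=False,
                                      lineterminator="\r\n")
    pd.DataFrame({"unit_id": matrix.index}).to_csv(paths["units"], index=False,
                                                   lineterminator="\r\n")
    return paths


def read_matrix(indir: str | Path) -> pd.DataFrame:
    indir = Path(indir)
    triplets = pd.read_csv(indir / "feature_matrix.csv")
    units = pd.read_csv(indir / "feature_units.csv")["unit_id"].to_numpy()
    keys = pd.read_csv(indir / "feature_dictionary.csv")["feature_key"].to_numpy()
    mat = np.zeros((len(units), len(keys)), dtype=np.uint8)
    row = pd.Categorical(triplets["unit_id"], categories=units).codes
    col = pd.Categorical(triplets["feature_key"], categories=keys).codes
    mat[row, col] = 1
    return pd.DataFrame(mat, index=pd.Index(units, name="unit_id"), columns=keys)
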