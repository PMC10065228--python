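"""Matched case-control cohort construction.

Cases are patients carrying an ankylosing-spondylitis code in any source; the
diagnosis date is the first AS mention, optionally back-dated to a "suspected"
onset when an anti-TNF prescription, or an HLA-B27 test / spondyloarthropathy
diagnosis, precedes it.  Eligible cases (diagnosed ages 15-35, after a cutoff
year, with at least `case_pre_window` of prior registration) are matched
1:`ratio` to controls on sex and week of birth (within a tolerance), each
control receiving an index date with `control_pre_window` of registration
before it and `control_post_window` after.  Controls must carry no AS or axial
spondyloarthritis code anywhere in their record.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import codes as _codes

WEEK = 7  # days


@dataclass(frozen=True)
class CodeLists:
    """Prefix sets identifying case-defining and back-dating codes.

    Prefix semantics follow the hierarchical dictionary: an event code matches
    if it starts with any listed prefix.
    """

    as_prefixes: frozenset[str] = _codes.AS_CODE_PREFIXES
    axspa_prefixes: frozenset[str] = _codes.AXSPA_CODE_PREFIXES
    anti_tnf_prefixes: frozenset[str] = _codes.ANTI_TNF_PREFIXES
    hla_b27_prefixes: frozenset[str] = _codes.HLA_B27_PREFIXES
    spa_prefixes: frozenset[str] = _codes.SPA_PREFIXES


@dataclass(frozen=True)
class MatchConfig:
    ratio: int = 100
    birth_tolerance_weeks: int = 26          # "within 6 months" on a weekly field
    case_pre_window_years: int = 3
    control_pre_window_years: int = 3
    control_post_window_years: int = 3
    diagnosis_age_range: tuple[float, float] = (15.0, 35.0)  # inclusive
    earliest_diagnosis_year: int = 2000
    index_mode: str = "calendar"             # "calendar" | "uniform"
    seed: int = 0

    def validate(self) -> None:
        if self.ratio < 1:
            raise ValueError("ratio must be >= 1")
        if min(self.birth_tolerance_weeks, 0) < 0:
            raise ValueError("birth_tolerance_weeks must be >= 0")
        for name in ("case_pre_window_years", "control_pre_window_years",
                     "control_post_window_years"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.index_mode not in ("calendar", "uniform"):
            raise ValueError(f"index_mode must be calendar/uniform, got {self.index_mode!r}")


@dataclass
class MatchedCohort:
    """Long-format cohort: one row per participant role.

    ``table`` columns: unit_id, patient_id, role (case|control), control_set
    (1..ratio for controls, <NA> for cases), matched_case_id, index_date,
    split (train|test, assigned by :func:`split_train_test`).  ``unit_id``
    equals ``patient_id`` unless a control is reused for several cases, in
    which case later occurrences get an ``#k`` suffix so every row keys a
    distinct (patient, index date) unit.
    """

    table: pd.DataFrame
    ratio: int

    @property
    def case_ids(self) -> list[str]:
        t = self.table
        return sorted(t.loc[t["role"] == "case", "patient_id"])

    def control_set(self, k: int) -> pd.DataFrame:
        t = self.table
        return t[(t["role"] == "control") & (t["control_set"] == k)]


class MatchingError(ValueError):
    """Raised when a case cannot be matched; names the binding constraint."""


def _startswith(series: pd.Series, prefixes: frozenset[str]) -> pd.Series:
    return series.str.startswith(tuple(sorted(prefixes)))


# ---------------------------------------------------------------------------
# case identification
# ---------------------------------------------------------------------------

def identify_cases(events: pd.DataFrame,
                   code_lists: CodeLists | None = None) -> pd.DataFrame:
    """Find patients with an AS code; return per patient the earliest AS date
    across all sources (diagnosis_date) and a back-dated suspected_date where
    an anti-TNF prescription or an HLA-B27 test / spondyloarthropathy code
    precedes the first AS mention (NaT otherwise)."""
    cl = code_lists or CodeLists()
    as_events = events[_startswith(events["code"], cl.as_prefixes)]
    diag = as_events.groupby("patient_id")["event_date"].min().rename("diagnosis_date")

    pre = events.merge(diag, on="patient_id", how="inner")
    before = pre[pre["event_date"] < pre["diagnosis_date"]]
    qualifying = _startswith(before["code"], cl.anti_tnf_prefixes) \
        | _startswith(before["code"], cl.hla_b27_prefixes) \
        | _startswith(before["code"], cl.spa_prefixes)
    suspected = (before[qualifying]
                 .groupby("patient_id")["event_date"].min()
                 .rename("suspected_date"))

    out = diag.reset_index().merge(suspected, on="patient_id", how="left")
    return out.sort_values("patient_id").reset_index(drop=True)


# ---------------------------------------------------------------------------
# eligibility
# ---------------------------------------------------------------------------

def age_at(date: pd.Series, week_of_birth: pd.Series) -> pd.Series:
    """Age in years at `date`, from the week-of-birth midpoint."""
    dob_mid = week_of_birth + pd.Timedelta(days=3, hours=12)
    return (date - dob_mid).dt.total_seconds() / (365.25 * 86400)


def apply_eligibility(cases: pd.DataFrame, patients: pd.DataFrame,
                      cfg: MatchConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sequential eligibility filters with an attrition report.

    Retains cases aged within ``diagnosis_age_range`` (closed interval) at
    diagnosis, diagnosed in/after ``earliest_diagnosis_year``, and registered
    at least ``case_pre_window_years`` before diagnosis (closed boundary).
    Returns (eligible cases merged with demographics, attrition table).
    """
    cfg.validate()
    demo = patients[["patient_id", "sex", "week_of_birth", "reg_start", "reg_end"]]
    merged = cases.merge(demo, on="patient_id", how="left", validate="one_to_one")
    if merged["week_of_birth"].isna().any():
        missing = merged.loc[merged["week_of_birth"].isna(), "patient_id"].iloc[0]
        raise ValueError(f"case {missing!r} absent from patients table")

    steps: list[tuple[str, int]] = []
    n0 = len(merged)

    age = age_at(merged["diagnosis_date"], merged["week_of_birth"])
    lo, hi = cfg.diagnosis_age_range
    keep = (age >= lo) & (age <= hi)
    steps.append(("age_at_diagnosis", int((~keep).sum())))
    merged = merged[keep]

    keep = merged["diagnosis_date"].dt.year >= cfg.earliest_diagnosis_year
    steps.append(("diagnosis_year", int((~keep).sum())))
    merged = merged[keep]

    cutoff = merged["diagnosis_date"] - pd.offsets.DateOffset(years=cfg.case_pre_window_years)
    keep = merged["reg_start"] <= cutoff
    steps.append(("prior_registration", int((~keep).sum())))
    merged = merged[keep]

    attrition = pd.DataFrame(steps, columns=["filter", "n_removed"])
    attrition.loc[len(attrition)] = ("retained", len(merged))
    assert attrition.loc[attrition["filter"] != "retained", "n_removed"].sum() \
        == n0 - len(merged)
    return merged.reset_index(drop=True), attrition


# ---------------------------------------------------------------------------
# matching
# ---------------------------------------------------------------------------

def match_controls(cases: pd.DataFrame, patients: pd.DataFrame,
                   events: pd.DataFrame, cfg: MatchConfig,
                   code_lists: CodeLists | None = None) -> MatchedCohort:
    """Build the 1:`ratio` matched cohort.

    For each eligible case, `ratio` distinct controls of the same sex with
    week of birth within the tolerance are drawn uniformly without replacement
    (seeded); control set k holds the k-th match of every case.  In
    ``calendar`` index mode a control's index date is its case's diagnosis
    date (feasibility enforced); in ``uniform`` mode it is drawn uniformly
    from the feasible interval.  A control may serve different cases but never
    appears twice for the same case.
    """
    cfg.validate()
    cl = code_lists or CodeLists()
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))

    excluded_mask = _startswith(events["code"], cl.as_prefixes) \
        | _startswith(events["code"], cl.axspa_prefixes)
    carriers = set(events.loc[excluded_mask, "patient_id"])

    pool = patients[~patients["patient_id"].isin(carriers)].reset_index(drop=True)
    pre = pd.offsets.DateOffset(years=cfg.control_pre_window_years)
    post = pd.offsets.DateOffset(years=cfg.control_post_window_years)
    lo_idx = (pool["reg_start"] + pre).to_numpy()   # earliest feasible index date
    hi_idx = (pool["reg_end"] - post).to_numpy()    # latest feasible index date
    pool_sex = pool["sex"].to_numpy()
    pool_wob = pool["week_of_birth"].to_numpy()
    pool_ids = pool["patient_id"].to_numpy()
    tol = np.timedelta64(cfg.birth_tolerance_weeks * WEEK, "D")

    rows: list[tuple] = []
    cases_sorted = cases.sort_values("patient_id").reset_index(drop=True)
    for case in cases_sorted.itertuples(index=False):
        diag = np.datetime64(case.diagnosis_date, "ns")
        sex_ok = pool_sex == case.sex
        wob_ok = np.abs(pool_wob - np.datetime64(case.week_of_birth, "ns")) <= tol
        if cfg.index_mode == "calendar":
            feasible = (lo_idx <= diag) & (diag <= hi_idx)
        else:
            feasible = lo_idx <= hi_idx
        ok = sex_ok & wob_ok & feasible
        n_ok = int(ok.sum())
        if n_ok < cfg.ratio:
            raise MatchingError(
                f"case {case.patient_id}: only {n_ok} eligible controls for "
                f"ratio {cfg.ratio} (same sex: {int(sex_ok.sum())}, "
                f"+birth tolerance: {int((sex_ok & wob_ok).sum())}, "
                f"+index feasibility: {n_ok})")
        cand = np.sort(pool_ids[ok])
        picked = rng.choice(cand, size=cfg.ratio, replace=False)
        rows.append((case.patient_id, case.patient_id, "case", pd.NA,
                     case.patient_id, pd.Timestamp(case.diagnosis_date)))
        pick_pos = pd.Index(pool_ids).get_indexer(picked)
        if cfg.index_mode == "calendar":
            idx_dates = np.full(cfg.ratio, diag)
        else:
            lo = lo_idx[pick_pos].astype("datetime64[D]").astype(int)
            hi = hi_idx[pick_pos].astype("datetime64[D]").astype(int)
            idx_dates = (lo + rng.integers(0, hi - lo + 1)).astype("datetime64[D]")
        for k in range(cfg.ratio):
            rows.append((picked[k], picked[k], "control", k + 1,
                         case.patient_id, pd.Timestamp(idx_dates[k])))

    table = pd.DataFrame(rows, columns=["unit_id", "patient_id", "role",
                                        "control_set", "matched_case_id",
                                        "index_date"])
    # disambiguate controls reused across cases
    dup = table.groupby("patient_id").cumcount()
    reused = (dup > 0) & (table["role"] == "control")
    table.loc[reused, "unit_id"] = (
        table.loc[reused, "patient_id"] + "#" + dup[reused].astype(str))
    table["control_set"] = table["control_set"].astype("Int64")
    table["split"] = pd.NA
    return MatchedCohort(table=table, ratio=cfg.ratio)


def split_train_test(cohort: MatchedCohort, train_fraction: float = 0.7,
                     seed: int = 0) -> MatchedCohort:
    """Case-level 70/30 split; every control inherits its case's label so
    matched pairs stay intact.  Train count = round(n_cases * fraction)."""
    if not 0.0 < train_fraction < 1.0:
        raise ValueError(f"train_fraction must be in (0, 1), got {train_fraction}")
    case_ids = np.array(cohort.case_ids)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    perm = rng.permutation(len(case_ids))
    n_train = int(round(len(case_ids) * train_fraction))
    train_cases = set(case_ids[perm[:n_train]])
    table = cohort.table.copy()
    table["split"] = np.where(table["matched_case_id"].isin(train_cases),
                              "train", "test")
    return MatchedCohort(table=table, ratio=cohort.ratio)


def write_cohort(cohort: MatchedCohort, path) -> None:
    t = cohort.table.copy()
    t["index_date"] = t["index_date"].dt.strftime("%Y-%m-%d")
    t.to_csv(path, index=False, lineterminator="\r\n")


def read_cohort(path, ratio: int | None = None) -> MatchedCohort:
    t = pd.read_csv(path, parse_dates=["index_date"],
                    dtype={"control_set": "Int64"})
    r = ratio if ratio is not None else int(t["control_set"].max())
    return MatchedCohort(table=t, ratio=r)
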