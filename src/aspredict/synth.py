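"""Synthetic longitudinal coded-EHR generator.

Emulates the structure of linked primary-care / hospital / rheumatology
records: a demographics table (sex, week of birth, registration window) and a
dated event table of hierarchical 5-character codes from three sources.  Cases
carry plantable, sex-specific prodromal signatures — concept groups present in
stated age bands at higher penetrance than in controls — plus one
ankylosing-spondylitis diagnosis code at their diagnosis date.  Background
process-of-care codes occur at the same Poisson rate in everyone, so with all
signatures nulled the generator carries no case/control signal at all.

Two modes:

* **case-control** (default): ``n_cases`` cases plus, for each case, an
  oversampled pool of matchable controls (same sex, week of birth within the
  matching tolerance, 20-year registration span covering ages 15-35).
* **population**: ``population_size`` patients with a ``case_prevalence``
  fraction of cases, for generalisability experiments.

All randomness flows from a single integer seed; identical config + seed gives
byte-identical output tables.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .codes import (
    AS_CODES,
    ANTI_TNF_CODES,
    AXSPA_CODES,
    BACKGROUND_CODES,
    CONCEPT_CODES,
    HLA_B27_CODES,
    SignatureSpec,
    default_aggregation_map,
)

DAYS_PER_YEAR = 365.25

PATIENT_COLUMNS = [
    "patient_id", "sex", "week_of_birth", "reg_start", "reg_end",
    "true_status", "diagnosis_date",
]
EVENT_COLUMNS = ["patient_id", "code", "source", "kind", "event_date"]


@dataclass(frozen=True)
class SynthConfig:
    """Study-condition parameters of the generator.

    ``controls_per_case`` mirrors the 1:100 matched design; ``case_prevalence``
    (population mode) mirrors the ~0.09% general-population rate.  The
    diagnosis-age range defaults to the late twenties / early thirties so the
    whole prodromal decade (ages 15-30) precedes the index date.
    """

    n_cases: int = 100
    controls_per_case: int = 100
    control_pool_factor: float = 1.2   # oversampling of matchable controls
    population_size: int | None = None
    case_prevalence: float = 0.0009
    sex_ratio: float = 0.68            # fraction male (cases)
    seed: int = 0
    background_code_rate: float = 2.0  # mean background events / patient / year
    dob_start: str = "1982-01-05"
    dob_end: str = "1992-12-28"
    diag_age_range: tuple[float, float] = (26.0, 31.0)

    def validate(self) -> None:
        if self.n_cases < 1:
            raise ValueError("n_cases must be >= 1")
        if self.controls_per_case < 1:
            raise ValueError("controls_per_case must be >= 1")
        if self.control_pool_factor < 1.0:
            raise ValueError("control_pool_factor must be >= 1 so the matching "
                             "pool can satisfy the 1:ratio constraint")
        for name, frac in (("case_prevalence", self.case_prevalence),
                           ("sex_ratio", self.sex_ratio)):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {frac}")
        if self.background_code_rate < 0:
            raise ValueError("background_code_rate must be >= 0")
        lo, hi = self.diag_age_range
        if not (15.0 <= lo < hi <= 35.0):
            raise ValueError("diag_age_range must lie within [15, 35]")
        if self.population_size is not None:
            expected = self.population_size * self.case_prevalence
            if expected < 1:
                raise ValueError(
                    f"population too small: population_size * case_prevalence = "
                    f"{expected:.3f} < 1 expected case")


def _day(ts: str | pd.Timestamp) -> int:
    """Calendar date -> integer day number (days since 1970-01-01)."""
    return int(np.datetime64(pd.Timestamp(ts).date(), "D").astype(int))


def _to_dates(days: np.ndarray) -> np.ndarray:
    return days.astype("datetime64[D]")


def _week_start(days: np.ndarray) -> np.ndarray:
    """Snap day numbers to the Monday of their ISO week (day 0 = a Thursday)."""
    return days - (days + 3) % 7


def _sexes(n: int, frac_male: float) -> np.ndarray:
    n_male = int(round(n * frac_male))
    return np.array(["male"] * n_male + ["female"] * (n - n_male))


class PopulationTooSmallError(ValueError):
    """The requested cohort cannot be generated under the matching constraints."""


def generate_population(
    config: SynthConfig,
    signatures: tuple[SignatureSpec, ...] | list[SignatureSpec],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate (patients, events) tables.

    Returns
    -------
    patients : DataFrame with columns ``patient_id, sex, week_of_birth,
        reg_start, reg_end, true_status, diagnosis_date`` (dates as
        ``datetime64[ns]``; diagnosis_date is NaT for controls).
    events : DataFrame with columns ``patient_id, code, source, kind,
        event_date``, sorted by patient then date.
    """
    config.validate()
    sig_by_sex: dict[str, SignatureSpec] = {}
    for spec in signatures:
        spec.validate()
        sig_by_sex[spec.sex] = spec

    rng = np.random.default_rng(np.random.SeedSequence(config.seed))

    if config.population_size is not None:
        return _generate_population_mode(config, sig_by_sex, rng)
    return _generate_case_control(config, sig_by_sex, rng)


# ---------------------------------------------------------------------------
# internals
# ---------------------------------------------------------------------------

def _case_frame(config: SynthConfig, rng: np.random.Generator,
                n_cases: int, id_offset: int = 0) -> pd.DataFrame:
    dob_lo, dob_hi = _day(config.dob_start), _day(config.dob_end)
    sexes = _sexes(n_cases, config.sex_ratio)
    dob = _week_start(rng.integers(dob_lo, dob_hi + 1, size=n_cases))
    age_lo, age_hi = config.diag_age_range
    diag_age = rng.uniform(age_lo, age_hi, size=n_cases)
    diag = dob + np.round(diag_age * DAYS_PER_YEAR).astype(int)
    reg_start = dob + int(round(15 * DAYS_PER_YEAR))
    reg_end = diag + rng.integers(365, 1096, size=n_cases)
    ids = np.array([f"C{i + id_offset:06d}" for i in range(n_cases)])
    return pd.DataFrame({
        "patient_id": ids, "sex": sexes, "dob": dob,
        "reg_start": reg_start, "reg_end": reg_end,
        "true_status": "case", "diag": diag,
    })


def _control_frame_matched(config: SynthConfig, rng: np.random.Generator,
                           cases: pd.DataFrame) -> pd.DataFrame:
    """Per case, an oversampled pool of matchable controls: same sex, week of
    birth within +/-26 weeks, registered from age 15 to age 35."""
    m = math.ceil(config.controls_per_case * config.control_pool_factor)
    n = len(cases) * m
    case_dob = np.repeat(cases["dob"].to_numpy(), m)
    sexes = np.repeat(cases["sex"].to_numpy(), m)
    dob = _week_start(case_dob + 7 * rng.integers(-26, 27, size=n))
    reg_start = dob + int(round(15 * DAYS_PER_YEAR))
    reg_end = dob + int(round(35 * DAYS_PER_YEAR))
    ids = np.array([f"G{i:07d}" for i in range(n)])
    return pd.DataFrame({
        "patient_id": ids, "sex": sexes, "dob": dob,
        "reg_start": reg_start, "reg_end": reg_end,
        "true_status": "control", "diag": -1,
    })


def _control_frame_population(config: SynthConfig, rng: np.random.Generator,
                              n: int) -> pd.DataFrame:
    dob_lo, dob_hi = _day(config.dob_start), _day(config.dob_end)
    dob = _week_start(rng.integers(dob_lo - 183, dob_hi + 184, size=n))
    sexes = _sexes(n, config.sex_ratio)
    # heterogeneous coverage: some population members have short windows
    start_age = rng.uniform(15.0, 22.0, size=n)
    span = rng.uniform(6.5, 20.0, size=n)
    end_age = np.minimum(start_age + span, 35.0)
    reg_start = dob + np.round(start_age * DAYS_PER_YEAR).astype(int)
    reg_end = dob + np.round(end_age * DAYS_PER_YEAR).astype(int)
    ids = np.array([f"G{i:07d}" for i in range(n)])
    return pd.DataFrame({
        "patient_id": ids, "sex": sexes, "dob": dob,
        "reg_start": reg_start, "reg_end": reg_end,
        "true_status": "control", "diag": -1,
    })


def _background_events(config: SynthConfig, rng: np.random.Generator,
                       frame: pd.DataFrame) -> pd.DataFrame:
    """Poisson process of background codes over each registration window, at
    the same rate for cases and controls."""
    years = (frame["reg_end"].to_numpy() - frame["reg_start"].to_numpy()) / DAYS_PER_YEAR
    counts = rng.poisson(config.background_code_rate * years)
    total = int(counts.sum())
    pid = np.repeat(frame["patient_id"].to_numpy(), counts)
    lo = np.repeat(frame["reg_start"].to_numpy(), counts)
    hi = np.repeat(frame["reg_end"].to_numpy(), counts)
    dates = lo + rng.integers(0, np.maximum(hi - lo, 1))
    idx = rng.integers(0, len(BACKGROUND_CODES), size=total)
    codes = np.array([c.code for c in BACKGROUND_CODES])[idx]
    sources = np.array([c.source for c in BACKGROUND_CODES])[idx]
    kinds = np.array([c.kind for c in BACKGROUND_CODES])[idx]
    return pd.DataFrame({"patient_id": pid, "code": codes, "source": sources,
                         "kind": kinds, "event_date": dates})


def _signature_events(rng: np.random.Generator, frame: pd.DataFrame,
                      sig_by_sex: dict[str, SignatureSpec]) -> pd.DataFrame:
    """Bernoulli presence per (patient, signature item), dated uniformly inside
    the age band clipped to the registration window and, for cases, to the day
    before diagnosis.  Items whose clipped window is empty are skipped."""
    aggmap = default_aggregation_map()
    by_group = {g: [c for c in CONCEPT_CODES if c.code in members]
                for g, members in aggmap.items()}
    pieces = []
    for sex, spec in sig_by_sex.items():
        sub = frame[frame["sex"] == sex]
        if sub.empty:
            continue
        dob = sub["dob"].to_numpy()
        reg_start = sub["reg_start"].to_numpy()
        reg_end = sub["reg_end"].to_numpy()
        diag = sub["diag"].to_numpy()
        is_case = sub["true_status"].to_numpy() == "case"
        cap = np.where(is_case, diag - 1, reg_end)  # strictly pre-diagnosis
        for item in spec.items:
            members = by_group.get(item.concept)
            if not members:
                raise ValueError(f"unknown concept group {item.concept!r}")
            lo = np.maximum(dob + np.round(item.age_band[0] * DAYS_PER_YEAR).astype(int),
                            reg_start)
            hi = np.minimum(dob + np.round(item.age_band[1] * DAYS_PER_YEAR).astype(int) - 1,
                            cap)
            feasible = hi >= lo
            pen = np.where(is_case, item.penetrance_case, item.penetrance_control)
            present = feasible & (rng.random(len(sub)) < pen)
            n = int(present.sum())
            if n == 0:
                continue
            dates = lo[present] + rng.integers(0, hi[present] - lo[present] + 1)
            idx = rng.integers(0, len(members), size=n)
            pieces.append(pd.DataFrame({
                "patient_id": sub["patient_id"].to_numpy()[present],
                "code": np.array([c.code for c in members])[idx],
                "source": np.array([c.source for c in members])[idx],
                "kind": np.array([c.kind for c in members])[idx],
                "event_date": dates,
            }))
    if not pieces:
        return pd.DataFrame(columns=EVENT_COLUMNS[:1] + EVENT_COLUMNS[1:])
    return pd.concat(pieces, ignore_index=True)


def _as_diagnosis_events(rng: np.random.Generator, cases: pd.DataFrame) -> pd.DataFrame:
    """One AS code per case at its diagnosis date, from GP / hospital /
    rheumatology sources in a 70/25/5 mix."""
    idx = rng.choice(len(AS_CODES), size=len(cases), p=[0.70, 0.25, 0.05])
    return pd.DataFrame({
        "patient_id": cases["patient_id"].to_numpy(),
        "code": np.array([c.code for c in AS_CODES])[idx],
        "source": np.array([c.source for c in AS_CODES])[idx],
        "kind": np.array([c.kind for c in AS_CODES])[idx],
        "event_date": cases["diag"].to_numpy(),
    })


def _finalise(cases: pd.DataFrame, controls: pd.DataFrame,
              events: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    frame = pd.concat([cases, controls], ignore_index=True)
    patients = pd.DataFrame({
        "patient_id": frame["patient_id"],
        "sex": frame["sex"],
        "week_of_birth": pd.to_datetime(_to_dates(frame["dob"].to_numpy())),
        "reg_start": pd.to_datetime(_to_dates(frame["reg_start"].to_numpy())),
        "reg_end": pd.to_datetime(_to_dates(frame["reg_end"].to_numpy())),
        "true_status": frame["true_status"],
        "diagnosis_date": pd.to_datetime(
            _to_dates(np.where(frame["diag"] >= 0, frame["diag"], -10**6))
        ).where(frame["diag"].to_numpy() >= 0),
    })
    events = events.copy()
    events["event_date"] = pd.to_datetime(_to_dates(events["event_date"].to_numpy().astype(int)))
    events = events.sort_values(["patient_id", "event_date", "code"],
                                kind="mergesort").reset_index(drop=True)
    return patients, events[EVENT_COLUMNS]


def _check_signatures(sig_by_sex: dict[str, SignatureSpec], sexes: np.ndarray) -> None:
    for sex in pd.unique(sexes):
        if sex not in sig_by_sex:
            raise ValueError(f"cases of sex {sex!r} requested but no signature "
                             "spec supplied for that sex")


def _generate_case_control(config: SynthConfig, sig_by_sex: dict[str, SignatureSpec],
                           rng: np.random.Generator):
    cases = _case_frame(config, rng, config.n_cases)
    _check_signatures(sig_by_sex, cases["sex"].to_numpy())
    controls = _control_frame_matched(config, rng, cases)
    frame = pd.concat([cases, controls], ignore_index=True)
    events = pd.concat([
        _background_events(config, rng, frame),
        _signature_events(rng, frame, sig_by_sex),
        _as_diagnosis_events(rng, cases),
    ], ignore_index=True)
    return _finalise(cases, controls, events)


def _generate_population_mode(config: SynthConfig, sig_by_sex: dict[str, SignatureSpec],
                              rng: np.random.Generator):
    n_cases = int(round(config.population_size * config.case_prevalence))
    if n_cases < 1:
        raise PopulationTooSmallError(
            "population_size * case_prevalence < 1: no cases can be generated")
    cases = _case_frame(config, rng, n_cases)
    _check_signatures(sig_by_sex, cases["sex"].to_numpy())
    controls = _control_frame_population(config, rng, config.population_size - n_cases)
    frame = pd.concat([cases, controls], ignore_index=True)
    events = pd.concat([
        _background_events(config, rng, frame),
        _signature_events(rng, frame, sig_by_sex),
        _as_diagnosis_events(rng, cases),
    ], ignore_index=True)
    return _finalise(cases, controls, events)


# ---------------------------------------------------------------------------
# suspected-AS pathway injection
# ---------------------------------------------------------------------------

def inject_suspected_pathway(patients: pd.DataFrame, events: pd.DataFrame,
                             fraction: float, seed: int) -> pd.DataFrame:
    """For a Bernoulli(fraction) subset of cases, insert codes that precede the
    first AS mention and trigger suspected-onset back-dating downstream: either
    an anti-TNF prescription, or an HLA-B27 test plus a spondyloarthropathy
    diagnosis.  Returns a new event table."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction must be in [0, 1], got {fraction}")
    cases = patients[patients["true_status"] == "case"]
    if cases.empty:
        raise ValueError("no cases present")
    if fraction == 0.0:
        return events
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    chosen = cases[rng.random(len(cases)) < fraction]
    if chosen.empty:
        return events
    diag = chosen["diagnosis_date"].values.astype("datetime64[D]").astype(int)
    reg_start = chosen["reg_start"].values.astype("datetime64[D]").astype(int)
    lead = rng.integers(30, 366, size=len(chosen))
    date1 = np.maximum(diag - lead, reg_start)
    use_tnf = rng.random(len(chosen)) < 0.5
    rows = []
    tnf = ANTI_TNF_CODES[0]
    hla = HLA_B27_CODES[0]
    spa = AXSPA_CODES[0]
    pids = chosen["patient_id"].to_numpy()
    for i in range(len(chosen)):
        d = pd.Timestamp(np.datetime64(int(date1[i]), "D"))
        if use_tnf[i]:
            rows.append((pids[i], tnf.code, tnf.source, tnf.kind, d))
        else:
            rows.append((pids[i], hla.code, hla.source, hla.kind, d))
            d2 = pd.Timestamp(np.datetime64(int(min(date1[i] + 14, diag[i] - 1)), "D"))
            rows.append((pids[i], spa.code, spa.source, spa.kind, d2))
    extra = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    out = pd.concat([events, extra], ignore_index=True)
    return out.sort_values(["patient_id", "event_date", "code"],
                           kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_tables(patients: pd.DataFrame, events: pd.DataFrame, outdir: str | Path,
                 config: SynthConfig | None = None) -> dict[str, Path]:
    """Write patients/events as RFC-4180 CSV (ISO-8601 dates) plus a
    provenance log (config hash, seed, package version)."""
    from . import __version__
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"patients": outdir / "patients.csv", "events": outdir / "events.csv"}
    pat = patients.copy()
    for col in ("week_of_birth", "reg_start", "reg_end", "diagnosis_date"):
        pat[col] = pat[col].dt.strftime("%Y-%m-%d")
    pat.to_csv(paths["patients"], index=False, lineterminator="\r\n")
    ev = events.copy()
    ev["event_date"] = ev["event_date"].dt.strftime("%Y-%m-%d")
    ev.to_csv(paths["events"], index=False, lineterminator="\r\n")
    if config is not None:
        blob = repr(sorted(asdict(config).items())).encode()
        log = (f"config_sha256: {hashlib.sha256(blob).hexdigest()}\n"
               f"seed: {config.seed}\nversion: {__version__}\n")
        paths["provenance"] = outdir / "provenance.txt"
        paths["provenance"].write_text(log)
    return paths


def read_tables(indir: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    indir = Path(indir)
    patients = pd.read_csv(indir / "patients.csv",
                           parse_dates=["week_of_birth", "reg_start", "reg_end",
                                        "diagnosis_date"])
    events = pd.read_csv(indir / "events.csv", parse_dates=["event_date"])
    validate_tables(patients, events)
    return patients, events


def validate_tables(patients: pd.DataFrame, events: pd.DataFrame) -> None:
    """Structural validation at the I/O boundary: schema, non-empty codes,
    events inside their patient's registration window."""
    missing = set(PATIENT_COLUMNS) - set(patients.columns)
    if missing:
        raise ValueError(f"patients table missing columns: {sorted(missing)}")
    missing = set(EVENT_COLUMNS) - set(events.columns)
    if missing:
        raise ValueError(f"events table missing columns: {sorted(missing)}")
    if events["code"].astype(str).str.len().min() == 0:
        raise ValueError("empty code in events table")
    merged = events.merge(patients[["patient_id", "reg_start", "reg_end"]],
                          on="patient_id", how="left", validate="many_to_one")
    if merged["reg_start"].isna().any():
        orphan = merged.loc[merged["reg_start"].isna(), "patient_id"].iloc[0]
        raise ValueError(f"event for unknown patient {orphan!r}")
    bad = (merged["event_date"] < merged["reg_start"]) | (merged["event_date"] > merged["reg_end"])
    if bad.any():
        pid = merged.loc[bad, "patient_id"].iloc[0]
        raise ValueError(f"event outside registration window for patient {pid!r}")
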