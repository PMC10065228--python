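"""Synthetic clinical code dictionary and default prodromal signature profiles.

The UK primary-care Read dictionary is licensed and is not shipped; instead the
package carries a small synthetic dictionary of 5-character hierarchical codes
whose prefixes define the specificity levels (level 1 = first character, level
5 = full code), mirroring the Read-code structure.  Only the exemplar
ankylosing-spondylitis identifiers that are public knowledge (GP Read ``N100``,
hospital ICD-10 ``M45``) appear as real prefixes; everything else is invented
but shaped like the real thing.

Sources are ``GP`` (primary care), ``HOSP`` (hospital admissions, ICD-10
analogue) and ``RHEUM`` (a rheumatology clinical system); kinds are ``DIAG``,
``MED``, ``PROC`` and ``TEST``.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class CodeEntry:
    code: str
    source: str  # GP | HOSP | RHEUM
    kind: str    # DIAG | MED | PROC | TEST
    label: str
    groups: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# Case-defining codes
# ---------------------------------------------------------------------------

AS_CODES = (
    CodeEntry("N1000", "GP", "DIAG", "ankylosing spondylitis (GP)"),
    CodeEntry("M4500", "HOSP", "DIAG", "ankylosing spondylitis (ICD-10 M45)"),
    CodeEntry("sAS00", "RHEUM", "DIAG", "ankylosing spondylitis (rheumatology)"),
)

AXSPA_CODES = (
    CodeEntry("N1010", "GP", "DIAG", "spondyloarthropathy, unspecified", ("axspa",)),
    CodeEntry("M4600", "HOSP", "DIAG", "axial spondyloarthritis (ICD-10 M46 analogue)", ("axspa",)),
)

ANTI_TNF_CODES = (
    CodeEntry("dTNF1", "GP", "MED", "adalimumab prescription", ("anti_tnf",)),
    CodeEntry("dTNF2", "GP", "MED", "etanercept prescription", ("anti_tnf",)),
)

HLA_B27_CODES = (
    CodeEntry("43HB7", "GP", "TEST", "HLA-B27 test", ("hla_b27",)),
)

# Prefix sets used by cohort identification.  Prefix matching mirrors the
# hierarchical dictionary: any child of N100 / M45 counts as an AS code.
AS_CODE_PREFIXES = frozenset({"N100", "M45", "sAS"})
AXSPA_CODE_PREFIXES = frozenset({"N101", "M46"})
ANTI_TNF_PREFIXES = frozenset({"dTNF"})
HLA_B27_PREFIXES = frozenset({"43HB"})
SPA_PREFIXES = AXSPA_CODE_PREFIXES


# ---------------------------------------------------------------------------
# Prodromal concept codes (plantable signal)
# ---------------------------------------------------------------------------

CONCEPT_CODES = (
    # back pain and related pain diagnoses
    CodeEntry("N1451", "GP", "DIAG", "low back pain", ("back_pain", "pain")),
    CodeEntry("N1452", "GP", "DIAG", "backache, unspecified", ("back_pain", "pain")),
    CodeEntry("N1421", "GP", "DIAG", "sciatica", ("back_pain", "pain")),
    CodeEntry("N1411", "GP", "DIAG", "vertebral column syndrome", ("back_pain", "pain")),
    # musculoskeletal / connective tissue diagnoses
    CodeEntry("N2001", "GP", "DIAG", "arthropathy, unspecified", ("msk",)),
    CodeEntry("N2002", "GP", "DIAG", "connective tissue disorder", ("msk",)),
    CodeEntry("M7900", "HOSP", "DIAG", "soft tissue disorder (ICD-10 M79 analogue)", ("msk",)),
    # pain relief medication
    CodeEntry("dNSA1", "GP", "MED", "ibuprofen prescription", ("nsaid", "pain_med")),
    CodeEntry("dNSA2", "GP", "MED", "diclofenac sodium prescription", ("nsaid", "pain_med")),
    CodeEntry("dPAR1", "GP", "MED", "paracetamol prescription", ("pain_med",)),
    CodeEntry("dCOD1", "GP", "MED", "co-dydramol prescription", ("pain_med",)),
    # laboratory tests (test *results* are never simulated, only "had test")
    CodeEntry("42A01", "GP", "TEST", "ESR test", ("blood_test",)),
    CodeEntry("42P01", "GP", "TEST", "plasma viscosity", ("blood_test",)),
    CodeEntry("43F01", "GP", "TEST", "serum CRP level", ("blood_test",)),
    CodeEntry("43RF1", "GP", "TEST", "rheumatoid factor", ("blood_test",)),
    # imaging
    CodeEntry("52A01", "GP", "PROC", "lumbar spine x-ray", ("xray_spine",)),
    CodeEntry("52A02", "GP", "PROC", "pelvic x-ray", ("xray_spine",)),
    # uveitis (extra-articular manifestation)
    CodeEntry("F4401", "GP", "DIAG", "acute anterior uveitis", ("uveitis",)),
    CodeEntry("H2000", "HOSP", "DIAG", "iridocyclitis (ICD-10 H20 analogue)", ("uveitis",)),
)

# Background process-of-care codes: occur at the same rate in cases and
# controls (blood-pressure checks, admin contacts).  Their leading characters
# (2, 6, 8) are disjoint from every signal concept's prefixes so that, at any
# truncation level, a background feature never overlaps a planted one.
BACKGROUND_CODES = (
    CodeEntry("24601", "GP", "PROC", "blood pressure check"),
    CodeEntry("24602", "GP", "PROC", "blood pressure monitoring"),
    CodeEntry("68W01", "GP", "PROC", "screening attendance"),
    CodeEntry("65E01", "GP", "PROC", "influenza vaccination"),
    CodeEntry("8B3A1", "GP", "PROC", "medication review"),
    CodeEntry("62200", "GP", "PROC", "patient review"),
)

ALL_CODES: tuple[CodeEntry, ...] = (
    AS_CODES + AXSPA_CODES + ANTI_TNF_CODES + HLA_B27_CODES + CONCEPT_CODES + BACKGROUND_CODES
)

CODE_INDEX: dict[str, CodeEntry] = {c.code: c for c in ALL_CODES}


def default_aggregation_map() -> dict[str, frozenset[str]]:
    """Concept-group name -> set of member code prefixes (a code may belong
    to several groups, e.g. sciatica is both ``back_pain`` and ``pain``)."""
    groups: dict[str, set[str]] = {}
    for entry in CONCEPT_CODES:
        for g in entry.groups:
            groups.setdefault(g, set()).add(entry.code)
    return {g: frozenset(v) for g, v in groups.items()}


# ---------------------------------------------------------------------------
# Default signature profiles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SignatureItem:
    """One plantable prodromal signal: a concept group observed in an age band
    with different presence probabilities (penetrances) in cases vs controls."""

    concept: str
    age_band: tuple[float, float]  # [lo, hi) in years, within [15, 35)
    penetrance_case: float
    penetrance_control: float

    def validate(self) -> None:
        lo, hi = self.age_band
        if not (15.0 <= lo < hi <= 35.0):
            raise ValueError(f"age band {self.age_band} must lie within [15, 35)")
        for p in (self.penetrance_case, self.penetrance_control):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"penetrance {p} outside [0, 1]")
        if self.penetrance_case < self.penetrance_control:
            raise ValueError(
                f"planted signal item {self.concept}: case penetrance "
                f"{self.penetrance_case} < control penetrance {self.penetrance_control}"
            )


@dataclass(frozen=True)
class SignatureSpec:
    sex: str  # "male" | "female"
    items: tuple[SignatureItem, ...] = field(default_factory=tuple)

    def validate(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be male/female, got {self.sex!r}")
        for item in self.items:
            item.validate()


def male_signature() -> SignatureSpec:
    """Male prodromal profile: teenage lower back pain, NSAID use and spinal
    x-rays under 20, uveitis and musculoskeletal codes in the early twenties,
    repeated blood tests thereafter."""
    return SignatureSpec(
        sex="male",
        items=(
            SignatureItem("back_pain", (15.0, 20.0), 0.60, 0.10),
            SignatureItem("nsaid", (15.0, 20.0), 0.55, 0.12),
            SignatureItem("xray_spine", (15.0, 20.0), 0.30, 0.05),
            SignatureItem("uveitis", (20.0, 25.0), 0.20, 0.01),
            SignatureItem("msk", (20.0, 25.0), 0.45, 0.10),
            SignatureItem("blood_test", (20.0, 25.0), 0.50, 0.15),
            SignatureItem("blood_test", (25.0, 30.0), 0.45, 0.15),
            SignatureItem("pain_med", (25.0, 30.0), 0.35, 0.10),
        ),
    )


def female_signature() -> SignatureSpec:
    """Female prodromal profile: later symptom presentation than males, with
    back pain, multiple pain-relief prescriptions, blood tests and imaging
    concentrated in the twenties; no uveitis signal."""
    return SignatureSpec(
        sex="female",
        items=(
            SignatureItem("msk", (15.0, 20.0), 0.35, 0.08),
            SignatureItem("back_pain", (20.0, 25.0), 0.45, 0.10),
            SignatureItem("pain_med", (20.0, 25.0), 0.50, 0.12),
            SignatureItem("blood_test", (20.0, 25.0), 0.45, 0.15),
            SignatureItem("back_pain", (25.0, 30.0), 0.50, 0.12),
            SignatureItem("xray_spine", (25.0, 30.0), 0.30, 0.05),
            SignatureItem("pain_med", (25.0, 30.0), 0.45, 0.12),
            SignatureItem("blood_test", (25.0, 30.0), 0.40, 0.15),
        ),
    )


def default_signatures() -> tuple[SignatureSpec, SignatureSpec]:
    return male_signature(), female_signature()
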