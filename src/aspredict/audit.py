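"""Classify feature keys against the planted signature profile.

Used to audit a selection run on synthetic data: which selected features are
the planted aggregate signals themselves, which are merely *signal-related*
(member codes or prefixes of a planted concept in that window, or
case-defining / back-dating codes), and which are genuinely null (background
process-of-care codes planted at equal rates in cases and controls).
"""

from __future__ import annotations

import pandas as pd

from . import codes as _codes
from .codes import SignatureSpec, default_aggregation_map
from .features import parse_key

_PATHWAY_PREFIXES = (_codes.AS_CODE_PREFIXES | _codes.AXSPA_CODE_PREFIXES
                     | _codes.ANTI_TNF_PREFIXES | _codes.HLA_B27_PREFIXES)


def _band_label(band: tuple[float, float]) -> str:
    return f"a{band[0]:g}-{band[1]:g}"


def planted_feature_keys(spec: SignatureSpec) -> list[str]:
    """The aggregate feature key each planted signature item should surface
    as: ``<concept>|AGG|ANY|a<lo>-<hi>``."""
    return [f"{item.concept}|AGG|ANY|{_band_label(item.age_band)}"
            for item in spec.items
            if item.penetrance_case > item.penetrance_control]


def _overlaps(prefix_a: str, prefix_b: str) -> bool:
    return prefix_a.startswith(prefix_b) or prefix_b.startswith(prefix_a)


def classify_features(feature_keys, spec: SignatureSpec,
                      aggmap: dict[str, frozenset[str]] | None = None) -> pd.DataFrame:
    """Label every feature key as ``planted`` / ``signal_related`` / ``null``.

    A key is signal-related when its concept (a code prefix, or an aggregate
    group's member codes) overlaps any code of a signature item planted in
    the same age band, or overlaps a case-defining or suspected-pathway code
    in any window.
    """
    aggmap = aggmap or default_aggregation_map()
    planted = set(planted_feature_keys(spec))
    planted_codes_by_band: dict[str, set[str]] = {}
    for item in spec.items:
        if item.penetrance_case > item.penetrance_control:
            band = _band_label(item.age_band)
            planted_codes_by_band.setdefault(band, set()).update(
                aggmap[item.concept])

    rows = []
    for key in feature_keys:
        concept, level, source, window = parse_key(key)
        if key in planted:
            cls = "planted"
        else:
            concepts = aggmap.get(concept, frozenset({concept})) \
                if level == "AGG" else frozenset({concept})
            pathway = any(_overlaps(c, p) for c in concepts
                          for p in _PATHWAY_PREFIXES)
            band_codes = planted_codes_by_band.get(window, set())
            signal = any(_overlaps(c, code) for c in concepts
                         for code in band_codes)
            cls = "signal_related" if (pathway or signal) else "null"
        rows.append((key, cls))
    return pd.DataFrame(rows, columns=["feature_key", "class"])
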