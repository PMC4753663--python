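"""Nine-way metabolite classification from VIP scores and coefficient signs.

Each metabolite carries four numbers: VIP and autoscaled PLS coefficient
for the butanol-rate response (VIPb, Coeffb) and for the growth-rate
response (VIPg, Coeffg). VIP is compared to the threshold first; a
coefficient's sign is consulted only for responses whose VIP exceeds the
threshold. The nine labels partition the score space:

    A: neither significant
    B: butanol only, negative          C: butanol only, positive
    D: both, growth +, butanol -       G: both, growth -, butanol +
    E: growth only, positive           F: growth only, negative
    H: both positive                   I: both negative

A VIP exactly equal to the threshold counts as not significant. A zero
coefficient on a significant response is flagged ambiguous and its sign
is borrowed from the other response's coefficient (positive fallback).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["TypedMetabolite", "classify", "type_code", "TYPE_LABELS"]

TYPE_LABELS = ("A", "B", "C", "D", "E", "F", "G", "H", "I")

#: two-character display codes: first slot growth response, second butanol.
#: "*" marks an insignificant slot.
_TYPE_CODES = {
    "A": "**",
    "B": "*-",
    "C": "*+",
    "D": "+-",
    "E": "+*",
    "F": "-*",
    "G": "-+",
    "H": "++",
    "I": "--",
}


@dataclass(frozen=True)
class TypedMetabolite:
    metabolite: str
    vip_b: float
    coeff_b: float
    vip_g: float
    coeff_g: float
    type_label: str
    type_code: str
    kegg_id: str | None = None
    ambiguous: bool = False


def type_code(type_label: str) -> str:
    """Display code for a type label (growth slot first, butanol second)."""
    try:
        return _TYPE_CODES[type_label]
    except KeyError:
        raise ValueError(f"unknown type label {type_label!r}") from None


def _label(sig_b: bool, sign_b: int, sig_g: bool, sign_g: int) -> str:
    if not sig_b and not sig_g:
        return "A"
    if sig_b and not sig_g:
        return "B" if sign_b < 0 else "C"
    if not sig_b and sig_g:
        return "E" if sign_g > 0 else "F"
    # both significant
    if sign_g > 0 and sign_b < 0:
        return "D"
    if sign_g < 0 and sign_b > 0:
        return "G"
    return "H" if sign_b > 0 else "I"


def _sign(coeff: float, other: float) -> tuple[int, bool]:
    """Sign of a significant response's coefficient; zero borrows the other's."""
    if coeff > 0:
        return 1, False
    if coeff < 0:
        return -1, False
    borrowed = 1 if other >= 0 else -1
    return borrowed, True


def classify(scores: pd.DataFrame, vip_threshold: float = 1.0) -> list[TypedMetabolite]:
    """Assign every metabolite exactly one of the nine type labels.

    Parameters
    ----------
    scores:
        One row per metabolite with columns ``metabolite``, ``vip_b``,
        ``coeff_b``, ``vip_g``, ``coeff_g`` and optionally ``kegg_id``.
    vip_threshold:
        Significance cut; VIP strictly above it counts as significant.

    Raises
    ------
    ValueError
        If any score is NaN/non-finite — reported per metabolite, never
        silently dropped.
    """
    required = ["metabolite", "vip_b", "coeff_b", "vip_g", "coeff_g"]
    missing = [c for c in required if c not in scores.columns]
    if missing:
        raise ValueError(f"scores table missing columns: {missing}")
    vals = scores[["vip_b", "coeff_b", "vip_g", "coeff_g"]].to_numpy(dtype=float)
    bad = np.where(~np.isfinite(vals).all(axis=1))[0]
    if bad.size:
        names = scores["metabolite"].iloc[bad].tolist()
        raise ValueError(f"non-finite scores for metabolites {names}; cannot classify")

    out: list[TypedMetabolite] = []
    for row in scores.itertuples(index=False):
        sig_b = row.vip_b > vip_threshold
        sig_g = row.vip_g > vip_threshold
        ambiguous = False
        sign_b = sign_g = 0
        if sig_b:
            sign_b, amb = _sign(row.coeff_b, row.coeff_g)
            ambiguous |= amb
        if sig_g:
            sign_g, amb = _sign(row.coeff_g, row.coeff_b)
            ambiguous |= amb
        label = _label(sig_b, sign_b, sig_g, sign_g)
        out.append(
            TypedMetabolite(
                metabolite=str(row.metabolite),
                vip_b=float(row.vip_b),
                coeff_b=float(row.coeff_b),
                vip_g=float(row.vip_g),
                coeff_g=float(row.coeff_g),
                type_label=label,
                type_code=type_code(label),
                kegg_id=getattr(row, "kegg_id", None),
                ambiguous=ambiguous,
            )
        )
    return out


def typed_frame(typed: list[TypedMetabolite]) -> pd.DataFrame:
    """Tabular view of a classification result."""
    return pd.DataFrame(
        {
            "metabolite": [t.metabolite for t in typed],
            "kegg_id": [t.kegg_id if t.kegg_id else "NA" for t in typed],
            "vip_b": [t.vip_b for t in typed],
            "coeff_b": [t.coeff_b for t in typed],
            "vip_g": [t.vip_g for t in typed],
            "coeff_g": [t.coeff_g for t in typed],
            "type_label": [t.type_label for t in typed],
            "type_code": [t.type_code for t in typed],
            "ambiguous": [t.ambiguous for t in typed],
        }
    )


def members_by_type(typed: list[TypedMetabolite]) -> dict[str, list[str]]:
    """Per-type metabolite lists (every label present, possibly empty)."""
    out: dict[str, list[str]] = {label: [] for label in TYPE_LABELS}
    for t in typed:
        out[t.type_label].append(t.metabolite)
    return out
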