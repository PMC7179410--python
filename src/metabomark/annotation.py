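"""Formula-based negative-mode mass arithmetic for compound annotation.

The computable part of structural annotation: parse an elemental formula,
compute the neutral monoisotopic mass from standard atomic masses, derive the
deprotonated ([M-H]⁻) or formate-adduct ([M-H+HCOOH]⁻) m/z, and explain
precursor→fragment mass differences as one or two neutral losses from a small
library (water, formaldehyde, ketene, CO₂, C₃H₆O₃, anhydroglucose, ...).

Comparisons against printed literature values use the 2-decimal convention of
those tables; printed values that disagree with the exact arithmetic are
*flagged* by :func:`audit_fixture_mz`, never corrected.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd

from .io import Adduct, CompoundRecord

#: Monoisotopic atomic masses (u). Carbon-12 defines the scale.
ATOMIC_MASSES = {
    "C": 12.0,
    "H": 1.00782503,
    "N": 14.00307401,
    "O": 15.99491462,
    "S": 31.97207117,
    "P": 30.97376200,
}

#: Mass removed on deprotonation: the proton, with the electron mass folded in
#: (the distinction is invisible at the 2-decimal reporting precision).
PROTON_MASS = 1.00727646


class FormulaError(ValueError):
    pass


@dataclass(frozen=True)
class Formula:
    """Elemental composition as an element -> count mapping."""

    counts: tuple[tuple[str, int], ...]

    @classmethod
    def from_counts(cls, counts: dict[str, int]) -> "Formula":
        clean = {e: int(n) for e, n in counts.items() if n > 0}
        if not clean:
            raise FormulaError("formula is empty")
        return cls(tuple(sorted(clean.items())))

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)

    def __add__(self, other: "Formula") -> "Formula":
        merged = self.as_dict()
        for e, n in other.as_dict().items():
            merged[e] = merged.get(e, 0) + n
        return Formula.from_counts(merged)

    def monoisotopic_mass(self) -> float:
        return sum(ATOMIC_MASSES[e] * n for e, n in self.counts)

    def __str__(self) -> str:
        order = ["C", "H"] + sorted(e for e, _ in self.counts if e not in ("C", "H"))
        d = self.as_dict()
        return "".join(f"{e}{d[e] if d[e] != 1 else ''}" for e in order if e in d)


_TOKEN = re.compile(r"([A-Z][a-z]?)_?(\d*)_?")


def parse_formula(text: str) -> Formula:
    """Parse an elemental formula such as ``C19H18O11``.

    Tolerates the underscore-subscript dialect used in transcribed tables
    (``C_19_H_18_O_11_``, including partially underscored variants).
    """
    stripped = text.strip().replace(" ", "")
    if not stripped:
        raise FormulaError("empty formula string")
    counts: dict[str, int] = {}
    pos = 0
    for m in _TOKEN.finditer(stripped):
        if m.start() != pos:
            raise FormulaError(f"malformed formula {text!r} at position {pos}")
        pos = m.end()
        element, num = m.group(1), m.group(2)
        if element not in ATOMIC_MASSES:
            raise FormulaError(f"unknown element {element!r} in {text!r}")
        counts[element] = counts.get(element, 0) + (int(num) if num else 1)
    if pos != len(stripped):
        raise FormulaError(f"malformed formula {text!r} at position {pos}")
    return Formula.from_counts(counts)


_FORMATE = parse_formula("CH2O2")  # HCOOH, 46.00548 u


def monoisotopic_mz(formula: Formula | str, adduct: Adduct = Adduct.M_MINUS_H) -> float:
    """Negative-mode ion m/z for a neutral formula.

    ``[M-H]⁻ = M - proton``; ``[M-H+HCOOH]⁻ = M + mass(HCOOH) - proton``.
    Full precision is returned; compare to printed tables at 2 decimals.
    """
    if isinstance(formula, str):
        formula = parse_formula(formula)
    mass = formula.monoisotopic_mass()
    if adduct is Adduct.M_PLUS_FORMATE:
        mass += _FORMATE.monoisotopic_mass()
    elif adduct is not Adduct.M_MINUS_H:
        raise FormulaError(f"unsupported adduct {adduct!r}")
    return mass - PROTON_MASS


# ---------------------------------------------------------------------------
# Neutral losses
# ---------------------------------------------------------------------------

#: Default neutral-loss library: the detachable moieties recurring in
#: seco-iridoid / flavonoid-glycoside fragmentation.
DEFAULT_NEUTRAL_LOSSES: dict[str, float] = {
    "H2O": 18.0106,
    "CH2O": 30.0106,
    "C2H2O": 42.0106,          # ketene (deacetylation)
    "CO2": 43.9898,
    "C3H6O3": 90.0317,
    "anhydroglucose": 162.0528,  # glycosidic C6H10O5
    "anhydro-dihydroxybenzoyl": 136.0160,
    "caffeoyl": 162.0317,
}


@dataclass
class LossExplanation:
    fragment_mz: float
    delta: float
    losses: tuple[str, ...]     # empty tuple means unexplained
    error: float = float("nan")

    @property
    def explained(self) -> bool:
        return bool(self.losses)


def explain_losses(
    precursor_mz: float,
    fragment_mzs: list[float],
    library: dict[str, float] | None = None,
    tol: float = 0.02,
) -> list[LossExplanation]:
    """Explain each fragment as one or two neutral losses from the precursor.

    For each fragment, the mass difference to the precursor is matched against
    single library losses, then against all two-loss combinations, keeping the
    smallest absolute mass error within ``tol`` (Th).  Unmatched fragments are
    returned with an empty loss tuple.
    """
    library = library if library is not None else DEFAULT_NEUTRAL_LOSSES
    singles = sorted(library.items())
    out = []
    for frag in fragment_mzs:
        if frag >= precursor_mz:
            raise FormulaError(
                f"fragment {frag} is not below precursor {precursor_mz}"
            )
        delta = precursor_mz - frag
        best: tuple[float, tuple[str, ...]] | None = None
        for name, mass in singles:
            err = abs(delta - mass)
            if err <= tol and (best is None or err < best[0]):
                best = (err, (name,))
        if best is None:
            for i, (n1, m1) in enumerate(singles):
                for n2, m2 in singles[i:]:
                    err = abs(delta - (m1 + m2))
                    if err <= tol and (best is None or err < best[0]):
                        best = (err, (n1, n2))
        if best is None:
            out.append(LossExplanation(fragment_mz=frag, delta=delta, losses=()))
        else:
            out.append(
                LossExplanation(
                    fragment_mz=frag, delta=delta, losses=best[1], error=best[0]
                )
            )
    return out


# ---------------------------------------------------------------------------
# Fixture audit
# ---------------------------------------------------------------------------


@dataclass
class MzAuditRow:
    index: int
    name: str
    formula: str
    adduct: str
    printed_mz: float
    computed_mz: float
    abs_error: float
    flagged: bool


def audit_fixture_mz(
    records: list[CompoundRecord], tol: float = 0.02
) -> pd.DataFrame:
    """Compare each record's printed m/z with the exact adduct arithmetic.

    Records deviating by more than ``tol`` (Th) are flagged — several printed
    table rows are internally inconsistent, and the audit surfaces them
    without altering the fixture.  Records without a formula or a recognised
    adduct are skipped.
    """
    rows = []
    for rec in records:
        if not rec.formula or rec.adduct is None:
            continue
        computed = monoisotopic_mz(parse_formula(rec.formula), rec.adduct)
        err = abs(round(computed, 2) - rec.printed_mz)
        rows.append(
            MzAuditRow(
                index=rec.index,
                name=rec.name,
                formula=rec.formula,
                adduct=rec.adduct.value,
                printed_mz=rec.printed_mz,
                computed_mz=round(computed, 4),
                abs_error=round(err, 4),
                flagged=err > tol,
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows]).set_index("index")
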