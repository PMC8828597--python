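"""Shorthand lipid nomenclature: parsing, validation and canonical ordering.

Lipid variables from direct-infusion MS are named at the species level as
``CLASS(C:D)`` where ``C`` is the total number of acyl carbons and ``D`` the
total number of carbon-carbon double bonds, e.g. ``PC(34:1)`` or ``TG(48:0)``.
Cholesterol has no acyl composition and is written bare (``Chol``).

The class vocabulary is a controlled list: unknown class tokens raise rather
than being coerced, because downstream analyses are restricted by class and a
silently mis-binned variable would corrupt them.  The vocabulary can be
extended per call for annotation dialects not covered by the default list.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "LipidVariable",
    "LipidNameError",
    "LIPID_CLASSES",
    "parse_lipid_name",
    "canonical_order",
]

#: Controlled vocabulary, in canonical reporting order.  Glycerides first
#: (neutral storage lipids), then glycerophospholipids, sphingolipids,
#: sterols, lyso-species, and a catch-all for user-extended tokens.
LIPID_CLASSES: tuple[str, ...] = (
    "TG",
    "DG",
    "MG",
    "PC",
    "PE",
    "PS",
    "PI",
    "PG",
    "PA",
    "SM",
    "CE",
    "Chol",
    "LPC",
    "LPE",
    "other",
)

_CLASS_RANK = {c: i for i, c in enumerate(LIPID_CLASSES)}

# CLASS token, optional "(C:D)" composition suffix; whitespace tolerated
# around and inside the parentheses.
_NAME_RE = re.compile(
    r"""^\s*
        (?P<cls>[A-Za-z][A-Za-z0-9\-]*?)
        \s*
        (?:\(\s*(?P<c>\d+)\s*:\s*(?P<d>\d+)\s*\))?
        \s*$""",
    re.VERBOSE,
)


class LipidNameError(ValueError):
    """Raised when a lipid variable name cannot be parsed or validated."""


@dataclass(frozen=True, order=False)
class LipidVariable:
    """A parsed lipid variable identity.

    Attributes
    ----------
    raw_name:
        The header text as read from the input table.
    lipid_class:
        Class token from the controlled vocabulary (``TG``, ``PC``, ...).
    carbons, double_bonds:
        Total acyl carbons and double bonds; ``None`` when the name carries
        no composition suffix (e.g. ``Chol``).
    ionisation_mode:
        ``"positive"``, ``"negative"`` or ``"unspecified"`` — carried as
        metadata from the input file, never parsed from the name.
    """

    raw_name: str
    lipid_class: str
    carbons: int | None = None
    double_bonds: int | None = None
    ionisation_mode: str = field(default="unspecified", compare=False)

    def __post_init__(self) -> None:
        if self.carbons is not None and self.carbons <= 0:
            raise LipidNameError(
                f"{self.raw_name!r}: composition suffix requires carbons > 0"
            )
        if (self.carbons is None) != (self.double_bonds is None):
            raise LipidNameError(
                f"{self.raw_name!r}: carbons and double_bonds must be given together"
            )

    @property
    def canonical_name(self) -> str:
        """Whitespace-free canonical rendering, e.g. ``PC(34:1)``."""
        if self.carbons is None:
            return self.lipid_class
        return f"{self.lipid_class}({self.carbons}:{self.double_bonds})"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.canonical_name

    @property
    def sort_key(self) -> tuple:
        return (
            _CLASS_RANK.get(self.lipid_class, len(LIPID_CLASSES)),
            self.lipid_class,
            self.carbons if self.carbons is not None else -1,
            self.double_bonds if self.double_bonds is not None else -1,
            self.raw_name.strip(),
        )


def parse_lipid_name(
    name: str,
    ionisation_mode: str = "unspecified",
    extra_classes: Iterable[str] = (),
) -> LipidVariable:
    """Parse a shorthand lipid name such as ``"PC(34:1)"``.

    Parameters
    ----------
    name:
        Header text; surrounding and internal whitespace is tolerated
        (``" PC ( 34 : 1 ) "`` parses like ``"PC(34:1)"``).
    ionisation_mode:
        Metadata attached to the parsed variable.
    extra_classes:
        Additional class tokens to accept beyond the default vocabulary.

    Raises
    ------
    LipidNameError
        On malformed names (``"PC34-1"``) or unknown class tokens; the
        message identifies the offending header and, for unknown tokens,
        lists the accepted vocabulary.
    """
    if not isinstance(name, str) or not name.strip():
        raise LipidNameError("lipid variable name must be non-empty text")
    m = _NAME_RE.match(name)
    if m is None:
        raise LipidNameError(
            f"cannot parse lipid variable name {name!r}: expected "
            "'CLASS' or 'CLASS(C:D)' shorthand such as 'PC(34:1)'"
        )
    cls = m.group("cls")
    vocab = set(LIPID_CLASSES) | set(extra_classes)
    if cls not in vocab:
        raise LipidNameError(
            f"unknown lipid class token {cls!r} in header {name!r}; "
            f"accepted tokens: {', '.join(sorted(vocab))}"
        )
    carbons = m.group("c")
    dbonds = m.group("d")
    if carbons is None and cls not in ("Chol", "other"):
        raise LipidNameError(
            f"lipid variable {name!r}: class {cls!r} requires a '(C:D)' "
            "composition suffix"
        )
    return LipidVariable(
        raw_name=name.strip(),
        lipid_class=cls,
        carbons=int(carbons) if carbons is not None else None,
        double_bonds=int(dbonds) if dbonds is not None else None,
        ionisation_mode=ionisation_mode,
    )


def canonical_order(variables: Iterable[LipidVariable]) -> list[LipidVariable]:
    """Deterministic total order over lipid variables.

    Sorts by class (vocabulary order), then carbons, then double bonds,
    falling back to the raw name so that isomeric annotations never collide
    silently.  Idempotent and invariant to the input ordering; duplicates
    (by identity) are removed.
    """
    return sorted(set(variables), key=lambda v: v.sort_key)


def parse_headers(
    headers: Sequence[str], ionisation_mode: str = "unspecified"
) -> list[LipidVariable]:
    """Parse a sequence of column headers, reporting all failures at once."""
    out: list[LipidVariable] = []
    errors: list[str] = []
    for h in headers:
        try:
            out.append(parse_lipid_name(h, ionisation_mode=ionisation_mode))
        except LipidNameError as e:
            errors.append(str(e))
    if errors:
        raise LipidNameError("; ".join(errors))
    return out
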