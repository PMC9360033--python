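"""Controlled vocabulary of coded cytogenetic lesions.

Cytogenetics enter the framework as pre-coded lesion tokens (one column /
token per recurrent abnormality), not free-text ISCN karyotype strings.
Each token carries the two attributes the classifier needs: a structural
category and whether the abnormality is unbalanced (unbalanced lesions are
what the complex-karyotype rule counts).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass


class LesionCategory(str, enum.Enum):
    FUSION = "fusion"        # balanced rearrangement (translocation/inversion)
    GAIN = "gain"            # whole-chromosome gain (trisomy)
    LOSS = "loss"            # whole-chromosome loss (monosomy)
    DELETION = "deletion"    # segmental deletion
    OTHER = "other"          # residual structural abnormality


@dataclass(frozen=True)
class LesionCode:
    """One coded cytogenetic abnormality.

    Attributes
    ----------
    code : str
        Token from the controlled vocabulary, e.g. ``"t(15;17)"`` or ``"-7"``.
    category : LesionCategory
    unbalanced : bool
        True for gains, losses, deletions and other unbalanced structural
        changes; False for reciprocal translocations and inversions.
    """

    code: str
    category: LesionCategory
    unbalanced: bool


def _fusion(code: str) -> LesionCode:
    return LesionCode(code, LesionCategory.FUSION, unbalanced=False)


def _gain(code: str) -> LesionCode:
    return LesionCode(code, LesionCategory.GAIN, unbalanced=True)


def _loss(code: str) -> LesionCode:
    return LesionCode(code, LesionCategory.LOSS, unbalanced=True)


def _deletion(code: str) -> LesionCode:
    return LesionCode(code, LesionCategory.DELETION, unbalanced=True)


#: The controlled vocabulary, keyed by token.
VOCABULARY: dict[str, LesionCode] = {
    lc.code: lc
    for lc in [
        _fusion("t(15;17)"),
        _fusion("inv(16)"),
        _fusion("t(8;21)"),
        _fusion("t(11;x)"),
        _fusion("t(6;9)"),
        _fusion("inv(3)"),
        _gain("+8"),
        _gain("+11"),
        _gain("+13"),
        _gain("+21"),
        _gain("+22"),
        _deletion("del(5q)"),
        _loss("-7"),
        _deletion("del(7q)"),
        _deletion("del(17p)"),
        _loss("-17"),
        _deletion("del(9q)"),
        _loss("-X/-Y"),
        LesionCode("other_unbalanced", LesionCategory.OTHER, unbalanced=True),
        LesionCode("other_balanced", LesionCategory.OTHER, unbalanced=False),
    ]
}

#: Autosomal monosomies, for the monosomal-karyotype rule (sex-chromosome
#: loss does not count).
AUTOSOMAL_MONOSOMIES: frozenset[str] = frozenset({"-7", "-17"})

#: Tokens indicating loss of the TP53 locus on 17p (multi-hit criterion).
TP53_LOCUS_LOSS: frozenset[str] = frozenset({"del(17p)", "-17"})


class UnknownLesionError(ValueError):
    """Raised when a cytogenetic token is not in the controlled vocabulary."""


def get_lesion(code: str) -> LesionCode:
    """Look up a token, raising :class:`UnknownLesionError` if absent."""
    try:
        return VOCABULARY[code]
    except KeyError:
        raise UnknownLesionError(
            f"unknown cytogenetic lesion code {code!r}; "
            f"known codes: {sorted(VOCABULARY)}"
        ) from None
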