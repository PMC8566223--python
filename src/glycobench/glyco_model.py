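"""Canonical glycan compositions, glycan classification and glycopeptide identity.

Glycan compositions are residue-count formulas over the five monosaccharide
classes relevant to mammalian serum glycosylation: hexose (Hex), N-acetyl-
hexosamine (HexNAc), deoxyhexose/fucose (Fuc, also written dHex), N-acetyl-
neuraminic acid (NeuAc, also written Sia) and N-glycolylneuraminic acid
(NeuGc).  No linkage or topology information is carried: two glycans with the
same residue counts are the same composition.

A glycopeptide identity is the pair (peptide sequence, canonical composition).
Alkali-metal adducted forms (Na+/K+) of the same glycopeptide collapse to the
nonadducted identity, mirroring how heterogeneous team reports are merged
before any counting or scoring.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace

__all__ = [
    "GlycanComposition",
    "GlycanClassification",
    "GlycopeptideID",
    "CompositionParseError",
    "PeptideError",
    "MONOSACCHARIDES",
    "RESIDUE_MASSES",
    "ADDUCTS",
    "parse_composition",
    "classify",
    "make_glycopeptide_id",
]

#: Monosaccharide classes, in canonical string order.
MONOSACCHARIDES = ("hex", "hexnac", "fuc", "neuac", "neugc")

#: Monoisotopic residue masses (Da), i.e. the mass added to a glycan chain
#: per residue (free monosaccharide minus water).
RESIDUE_MASSES = {
    "hex": 162.0528,
    "hexnac": 203.0794,
    "fuc": 146.0579,
    "neuac": 291.0954,
    "neugc": 307.0903,
}

#: Recognised precursor adduct labels. ``None``/"none" denote the protonated form.
ADDUCTS = ("none", "Na", "K")

_AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

# Token dialects seen in team reports.  Longest tokens first so that e.g.
# "HexNAc" is never consumed as "Hex" followed by garbage.
_TOKEN_ALIASES = {
    "hexnac": "hexnac",
    "neuac": "neuac",
    "neugc": "neugc",
    "dhex": "fuc",
    "hex": "hex",
    "fuc": "fuc",
    "sia": "neuac",
}
_TOKEN_RE = re.compile(r"(HexNAc|NeuAc|NeuGc|dHex|Hex|Fuc|Sia)(\d+)", re.IGNORECASE)


class CompositionParseError(ValueError):
    """A glycan composition string could not be parsed."""


class PeptideError(ValueError):
    """A peptide sequence is empty or contains non-amino-acid characters."""


@dataclass(frozen=True, order=True)
class GlycanComposition:
    """Residue-count glycan composition.

    Equality and ordering are count-wise; the order of monosaccharide tokens
    in an input string never affects identity.
    """

    hex: int = 0
    hexnac: int = 0
    fuc: int = 0
    neuac: int = 0
    neugc: int = 0

    def __post_init__(self) -> None:
        for name in MONOSACCHARIDES:
            value = getattr(self, name)
            if not isinstance(value, int) or isinstance(value, bool):
                raise TypeError(f"{name} count must be an integer, got {value!r}")
            if value < 0:
                raise ValueError(f"{name} count must be >= 0, got {value}")

    def canonical(self) -> str:
        """Canonical string form ``Hex<h>HexNAc<n>Fuc<f>NeuAc<a>`` (NeuGc only when > 0)."""
        text = f"Hex{self.hex}HexNAc{self.hexnac}Fuc{self.fuc}NeuAc{self.neuac}"
        if self.neugc:
            text += f"NeuGc{self.neugc}"
        return text

    def __str__(self) -> str:
        return self.canonical()

    @property
    def residue_mass(self) -> float:
        """Summed monoisotopic residue mass of the glycan, Da."""
        return sum(RESIDUE_MASSES[name] * getattr(self, name) for name in MONOSACCHARIDES)

    @property
    def total_residues(self) -> int:
        return sum(getattr(self, name) for name in MONOSACCHARIDES)

    def replace(self, **counts: int) -> "GlycanComposition":
        return replace(self, **counts)


def parse_composition(text: str) -> GlycanComposition:
    """Parse a composition string such as ``"HexNAc4Hex5NeuAc2"``.

    Tokens may appear in any order; underscores and whitespace are tolerated
    (``"HexNAc_4_Hex_5_NeuAc_2"``); ``dHex`` is an alias of ``Fuc`` and
    ``Sia`` of ``NeuAc``.  Absent tokens read as zero.

    Raises
    ------
    CompositionParseError
        On an unknown token (naming the offending span), a duplicate token,
        or a token without a count.
    """
    if not isinstance(text, str):
        raise CompositionParseError(f"composition must be a string, got {type(text).__name__}")
    compact = re.sub(r"[\s_]+", "", text)
    if not compact:
        raise CompositionParseError("empty composition string")
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(compact):
        match = _TOKEN_RE.match(compact, pos)
        if match is None:
            span = compact[pos : pos + 12]
            raise CompositionParseError(
                f"unrecognised token at {span!r} in composition {text!r}"
            )
        name = _TOKEN_ALIASES[match.group(1).lower()]
        if name in counts:
            raise CompositionParseError(
                f"duplicate monosaccharide token {match.group(1)!r} in {text!r}"
            )
        counts[name] = int(match.group(2))
        pos = match.end()
    return GlycanComposition(**counts)


@dataclass(frozen=True)
class GlycanClassification:
    """Structural class and feature label of a glycan composition.

    ``feature_label`` follows the priority order multiFuc > NeuGc > NeuAc >
    neutral, so a composition belonging to several feature classes is binned
    once, into the highest-priority one.
    """

    structural_class: str  # oligomannose | truncated | complex
    feature_label: str  # multiFuc | NeuGc | NeuAc | neutral
    is_multi_fuc: bool
    has_neugc: bool
    has_neuac: bool


def classify(
    comp: GlycanComposition,
    analyte: str = "N",
    *,
    oligomannose_min_hex: int = 4,
) -> GlycanClassification:
    """Classify a glycan composition.

    N-glycans are split three ways:

    * oligomannose — two core HexNAc, >= ``oligomannose_min_hex`` Hex, and no
      Fuc or sialic acid (the standard Man4+ biosynthetic series);
    * truncated — Hex < 4 and HexNAc < 3 and Fuc < 2 (paucimannosidic/
      chitobiose-core remnants);
    * complex — everything else (hybrid-type glycans are binned here).

    O-glycans have no comparable structural taxonomy at composition level and
    are reported as ``complex``; they are distinguished by feature label only.
    Oligomannose wins over truncated in the (normally empty) overlap.
    """
    if analyte not in ("N", "O"):
        raise ValueError(f"analyte must be 'N' or 'O', got {analyte!r}")
    is_multi_fuc = comp.fuc >= 2
    has_neugc = comp.neugc >= 1
    has_neuac = comp.neuac >= 1
    if is_multi_fuc:
        feature = "multiFuc"
    elif has_neugc:
        feature = "NeuGc"
    elif has_neuac:
        feature = "NeuAc"
    else:
        feature = "neutral"

    if analyte == "O":
        structural = "complex"
    elif (
        comp.hexnac == 2
        and comp.hex >= oligomannose_min_hex
        and comp.fuc == 0
        and comp.neuac == 0
        and comp.neugc == 0
    ):
        structural = "oligomannose"
    elif comp.hex < 4 and comp.hexnac < 3 and comp.fuc < 2:
        structural = "truncated"
    else:
        structural = "complex"
    return GlycanClassification(
        structural_class=structural,
        feature_label=feature,
        is_multi_fuc=is_multi_fuc,
        has_neugc=has_neugc,
        has_neuac=has_neuac,
    )


@dataclass(frozen=True, order=True)
class GlycopeptideID:
    """Adduct-invariant glycopeptide identity: peptide sequence + canonical composition."""

    peptide: str
    composition: GlycanComposition

    def __str__(self) -> str:
        return f"{self.peptide}_{self.composition.canonical()}"


def _validate_peptide(peptide: str) -> str:
    if not isinstance(peptide, str) or not peptide:
        raise PeptideError(f"peptide must be a nonempty string, got {peptide!r}")
    upper = peptide.upper()
    bad = set(upper) - _AMINO_ACIDS
    if bad:
        raise PeptideError(
            f"peptide {peptide!r} contains non-amino-acid characters: {sorted(bad)}"
        )
    return upper


def make_glycopeptide_id(
    peptide: str,
    comp: GlycanComposition | str,
    adduct: str | None = None,
) -> GlycopeptideID:
    """Build the adduct-invariant identity of a reported glycopeptide.

    The adduct label (``None``/"none"/"Na"/"K") is validated and discarded:
    adducted forms are merged with the nonadducted composition.  The peptide
    is uppercased; a string composition is parsed and canonicalised.
    """
    if adduct is not None and adduct not in ADDUCTS:
        raise ValueError(f"unknown adduct {adduct!r}; expected one of {ADDUCTS}")
    if isinstance(comp, str):
        comp = parse_composition(comp)
    return GlycopeptideID(peptide=_validate_peptide(peptide), composition=comp)
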