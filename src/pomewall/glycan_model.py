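"""Oligosaccharide composition nomenclature and sodiated-ion mass model.

Two nomenclatures are supported, as used for MALDI-TOF annotation of
enzymatic digests of fruit cell walls:

* the xyloglucan letter code (G/X/L/F), where each uppercase letter is a
  backbone 1->4-linked beta-D-glucose together with its pendant side chain
  (G bare Glc; X adds an alpha-D-xylosyl branch; L extends the xylose with a
  beta-D-galactosyl; F extends the galactose with an alpha-L-fucosyl), with
  an optional trailing ``aN`` acetyl-ester suffix, e.g. ``XXFGa1``;

* the composition code ``HexN`` / ``PenN`` with optional ``U`` (hexuronic
  acid), ``m`` (methyl ester) and ``a`` (acetyl ester) counts, e.g.
  ``Pen5U1m1a1`` = 5 pentoses + 1 uronic acid + 1 methyl + 1 acetyl.

Ions are modelled as sodiated, unreduced oligosaccharides, [M+Na]+.
Two mass scales are exposed: the exact monoisotopic mass in Da
(:func:`sodiated_mass`) and the nominal m/z obtained by summing integer
nominal residue masses (:func:`nominal_mz`), which is the scale on which
MALDI-TOF glycan fingerprints are conventionally reported.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

__all__ = [
    "OligoComposition",
    "XygoCode",
    "ResidueMassTable",
    "MONOISOTOPIC",
    "GlycanParseError",
    "GlycanFormatError",
    "parse_xygo_code",
    "parse_composition_code",
    "sodiated_mass",
    "nominal_mz",
    "enumerate_compositions",
    "format_code",
    "XYGO_LETTER_EXPANSIONS",
]


class GlycanParseError(ValueError):
    """A composition or letter code could not be parsed."""


class GlycanFormatError(ValueError):
    """A composition has no representation in the requested nomenclature."""


@dataclass(frozen=True, order=True)
class OligoComposition:
    """Counts of glycosyl residues and ester modifiers for one oligomer.

    Residue counts are anhydro residues (water is added once per molecule,
    at the terminus, by the mass model).
    """

    n_hex: int = 0
    n_pen: int = 0
    n_dhex: int = 0
    n_hexA: int = 0
    n_methyl: int = 0
    n_acetyl: int = 0

    def __post_init__(self) -> None:
        for name in ("n_hex", "n_pen", "n_dhex", "n_hexA", "n_methyl", "n_acetyl"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")

    @property
    def n_residues(self) -> int:
        return self.n_hex + self.n_pen + self.n_dhex + self.n_hexA

    def is_annotatable(self) -> bool:
        return self.n_residues >= 1


@dataclass(frozen=True)
class XygoCode:
    """A xyloglucan letter code: ordered letters over {G,X,L,F} + acetyl count."""

    letters: str
    n_acetyl: int = 0

    def __post_init__(self) -> None:
        if not self.letters:
            raise ValueError("letters must be non-empty")
        for ch in self.letters:
            if ch not in "GXLF":
                raise ValueError(f"invalid letter {ch!r}; allowed: G, X, L, F")
        if self.n_acetyl < 0:
            raise ValueError("n_acetyl must be >= 0")

    def __str__(self) -> str:
        return self.letters + (f"a{self.n_acetyl}" if self.n_acetyl else "")


# (n_hex, n_pen, n_dhex) contributed by each backbone letter
XYGO_LETTER_EXPANSIONS: dict[str, tuple[int, int, int]] = {
    "G": (1, 0, 0),  # bare Glc
    "X": (1, 1, 0),  # Glc + Xyl
    "L": (2, 1, 0),  # Glc + Xyl + Gal
    "F": (2, 1, 1),  # Glc + Xyl + Gal + Fuc
}


# atomic monoisotopic masses (CODATA/AME), from which the residue masses
# are assembled so that elementally identical compositions (e.g. 3 Hex +
# 1 acetyl vs 4 Pen, both C20H32O16) are exactly isobaric in floating point
_H = 1.00782503207
_C = 12.0
_O = 15.99491461956
_NA = 22.9897692809


@dataclass(frozen=True)
class ResidueMassTable:
    """Residue and group masses (Da) for the sodiated-ion mass model.

    ``nominal`` gives the integer residue masses used for nominal m/z.
    """

    hexose: float = 6 * _C + 10 * _H + 5 * _O        # 162.0528
    pentose: float = 5 * _C + 8 * _H + 4 * _O        # 132.0423
    deoxyhexose: float = 6 * _C + 10 * _H + 4 * _O   # 146.0579
    hexuronic_acid: float = 6 * _C + 8 * _H + 6 * _O  # 176.0321
    acetyl: float = 2 * _C + 2 * _H + _O             # 42.0106
    methyl: float = _C + 2 * _H                      # 14.0157
    water: float = 2 * _H + _O                       # 18.0106
    sodium: float = _NA
    nominal: dict = field(
        default_factory=lambda: {
            "hexose": 162,
            "pentose": 132,
            "deoxyhexose": 146,
            "hexuronic_acid": 176,
            "acetyl": 42,
            "methyl": 14,
            "water": 18,
            "sodium": 23,
        }
    )

    def __post_init__(self) -> None:
        ch2o = 30.01057  # hexose and pentose differ by one CH2O
        if abs((self.hexose - self.pentose) - ch2o) > 1e-4:
            raise ValueError("hexose - pentose must equal the CH2O mass 30.0106")
        for name in ("hexose", "pentose", "deoxyhexose", "hexuronic_acid",
                     "acetyl", "methyl", "water", "sodium"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} mass must be > 0")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ResidueMassTable":
        """Load an override table: two columns (residue name, mass in Da)."""
        overrides: dict[str, float] = {}
        for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) != 2:
                raise GlycanParseError(f"{path}:{i}: expected 'residue<TAB>mass'")
            name, value = parts
            try:
                overrides[name] = float(value)
            except ValueError as exc:
                raise GlycanParseError(f"{path}:{i}: non-numeric mass {value!r}") from exc
        return cls(**overrides)


MONOISOTOPIC = ResidueMassTable()

_XYGO_RE = re.compile(r"^(?P<letters>[GXLF]+)(?:a(?P<ac>[0-9]+))?$")
_COMP_RE = re.compile(
    r"^(?P<fam>Hex|Pen)(?P<n>[0-9]+)"
    r"(?:U(?P<u>[0-9]+))?(?:m(?P<m>[0-9]+))?(?:a(?P<a>[0-9]+))?$"
)


def parse_xygo_code(code: str) -> OligoComposition:
    """Parse a xyloglucan letter code (e.g. ``XXFGa1``) to its composition.

    The acetyl suffix digits are read greedily, so ``a12`` means 12 acetyls.

    Raises
    ------
    GlycanParseError
        If the code is empty, contains a letter outside {G,X,L,F}, or has a
        misplaced suffix; the message names the offending character.
    """
    if not code:
        raise GlycanParseError("empty code")
    m = _XYGO_RE.match(code)
    if m is None:
        for i, ch in enumerate(code):
            if ch not in "GXLF":
                raise GlycanParseError(
                    f"invalid character {ch!r} at position {i} in code {code!r}"
                )
        raise GlycanParseError(f"malformed code {code!r}")
    n_hex = n_pen = n_dhex = 0
    for ch in m.group("letters"):
        dh, dp, dd = XYGO_LETTER_EXPANSIONS[ch]
        n_hex += dh
        n_pen += dp
        n_dhex += dd
    return OligoComposition(
        n_hex=n_hex, n_pen=n_pen, n_dhex=n_dhex, n_acetyl=int(m.group("ac") or 0)
    )


def parse_composition_code(code: str) -> OligoComposition:
    """Parse a Hex/Pen composition code (e.g. ``Pen5U1m1a1``).

    Raises
    ------
    GlycanParseError
        On an unknown token or a missing leading family count.
    """
    if not code:
        raise GlycanParseError("empty code")
    m = _COMP_RE.match(code)
    if m is None:
        raise GlycanParseError(
            f"malformed composition code {code!r}; expected Hex/Pen N [U N] [m N] [a N]"
        )
    n = int(m.group("n"))
    return OligoComposition(
        n_hex=n if m.group("fam") == "Hex" else 0,
        n_pen=n if m.group("fam") == "Pen" else 0,
        n_hexA=int(m.group("u") or 0),
        n_methyl=int(m.group("m") or 0),
        n_acetyl=int(m.group("a") or 0),
    )


def parse_code(code: str) -> OligoComposition:
    """Parse either nomenclature (composition codes tried first)."""
    if code[:3] in ("Hex", "Pen"):
        return parse_composition_code(code)
    return parse_xygo_code(code)


def sodiated_mass(comp: OligoComposition, masses: ResidueMassTable = MONOISOTOPIC) -> float:
    """Monoisotopic [M+Na]+ mass in Da of an unreduced oligosaccharide."""
    return (
        comp.n_hex * masses.hexose
        + comp.n_pen * masses.pentose
        + comp.n_dhex * masses.deoxyhexose
        + comp.n_hexA * masses.hexuronic_acid
        + comp.n_methyl * masses.methyl
        + comp.n_acetyl * masses.acetyl
        + masses.water
        + masses.sodium
    )


def nominal_mz(comp: OligoComposition, masses: ResidueMassTable = MONOISOTOPIC) -> int:
    """Nominal [M+Na]+ m/z: the sum of integer nominal residue masses.

    This is the integer scale on which glycan fingerprint peaks are
    conventionally labelled; for oligomers above ~1.5 kDa it differs from
    the rounded monoisotopic mass because the per-residue mass defect
    accumulates past half a dalton.
    """
    n = masses.nominal
    return (
        comp.n_hex * n["hexose"]
        + comp.n_pen * n["pentose"]
        + comp.n_dhex * n["deoxyhexose"]
        + comp.n_hexA * n["hexuronic_acid"]
        + comp.n_methyl * n["methyl"]
        + comp.n_acetyl * n["acetyl"]
        + n["water"]
        + n["sodium"]
    )


#: search families accepted by :func:`enumerate_compositions`
FAMILIES = frozenset({"hexose-series", "pentose-series", "xygo-grammar", "unconstrained"})


# series ceilings reflect the digests' observed annotation space:
# hexo-oligomers (gluco/galactoglucomannan fragments) run DP 1-8 with 0-2
# acetyls; pento-oligomers (arabinoxylan fragments) reach 5 pentoses with
# at most one glucuronosyl substituent (GlcA is sparse on short xylan
# fragments), methyls on uronic acids only and 0-2 acetyls.  The
# unconstrained family searches far beyond these bounds.
_MAX_HEX_DP = 8
_MAX_PEN_DP = 5
_MAX_SERIES_ACETYL = 2
_MAX_SERIES_URONIC = 1


def _hexose_series(max_residues: int):
    for nh in range(1, min(_MAX_HEX_DP, max_residues) + 1):
        for na in range(0, min(_MAX_SERIES_ACETYL, nh) + 1):
            yield OligoComposition(n_hex=nh, n_acetyl=na)


def _pentose_series(max_residues: int):
    for np_ in range(1, min(_MAX_PEN_DP, max_residues) + 1):
        for nu in range(0, min(_MAX_SERIES_URONIC, np_, max_residues - np_) + 1):
            for nm in range(0, nu + 1):
                for na in range(0, min(_MAX_SERIES_ACETYL, np_) + 1):
                    yield OligoComposition(
                        n_pen=np_, n_hexA=nu, n_methyl=nm, n_acetyl=na
                    )


def _xygo_grammar(max_residues: int):
    # compositions reachable from some letter sequence: a multiset of
    # G/X/L/F letters plus an acetyl count; order does not change composition
    seen = set()
    max_letters = max_residues  # each letter contributes >= 1 residue
    for ng in range(0, max_letters + 1):
        for nx in range(0, max_letters + 1 - ng):
            for nl in range(0, max_letters + 1 - ng - nx):
                for nf in range(0, max_letters + 1 - ng - nx - nl):
                    if ng + nx + nl + nf == 0:
                        continue
                    n_hex = ng + nx + 2 * nl + 2 * nf
                    n_pen = nx + nl + nf
                    n_dhex = nf
                    if n_hex + n_pen + n_dhex > max_residues:
                        continue
                    for na in range(0, min(_MAX_SERIES_ACETYL, n_hex + n_pen) + 1):
                        c = OligoComposition(
                            n_hex=n_hex, n_pen=n_pen, n_dhex=n_dhex, n_acetyl=na
                        )
                        if c not in seen:
                            seen.add(c)
                            yield c


def _unconstrained(max_residues: int):
    # hexuronic acids occur as glucuronosyl substituents of the xylan
    # backbone in these digests, so their count never exceeds the pentose
    # count; this structural ceiling also bounds the search
    for nh in range(0, max_residues + 1):
        for np_ in range(0, max_residues + 1 - nh):
            for nd in range(0, max_residues + 1 - nh - np_):
                for nu in range(0, min(np_, max_residues - nh - np_ - nd) + 1):
                    if nh + np_ + nd + nu == 0:
                        continue
                    for nm in range(0, nu + 1):
                        for na in range(0, nh + np_ + 1):
                            yield OligoComposition(
                                n_hex=nh, n_pen=np_, n_dhex=nd,
                                n_hexA=nu, n_methyl=nm, n_acetyl=na,
                            )


_FAMILY_GENERATORS = {
    "hexose-series": _hexose_series,
    "pentose-series": _pentose_series,
    "xygo-grammar": _xygo_grammar,
    "unconstrained": _unconstrained,
}


def enumerate_compositions(
    mz: float,
    tol: float,
    families: set[str] | frozenset[str] = frozenset({"unconstrained"}),
    masses: ResidueMassTable = MONOISOTOPIC,
    max_residues: int = 12,
) -> list[tuple[OligoComposition, float]]:
    """All compositions in the requested families with |mass - mz| <= tol.

    Modifier ceilings bound the search: acetyls <= hexose+pentose residues,
    methyls <= uronic acids, total residues <= ``max_residues``.  Results are
    (composition, signed mass error) pairs sorted by |error| then by
    composition for determinism.
    """
    if not families:
        raise ValueError("families must be a non-empty set")
    unknown = set(families) - FAMILIES
    if unknown:
        raise ValueError(f"unknown families: {sorted(unknown)}; allowed: {sorted(FAMILIES)}")
    if mz <= masses.water + masses.sodium:
        return []
    if tol <= 0:
        raise ValueError("tol must be > 0")

    out: dict[OligoComposition, float] = {}
    for fam in families:
        for comp in _FAMILY_GENERATORS[fam](max_residues):
            err = sodiated_mass(comp, masses) - mz
            if abs(err) <= tol:
                out.setdefault(comp, err)
    return sorted(out.items(), key=lambda ce: (abs(ce[1]), ce[0]))


def composition_label(comp: OligoComposition) -> str:
    """Human-readable label for any composition, e.g. ``Hex5Pen3dHex1a1``.

    Unlike :func:`format_code` this never fails, but mixed labels are not
    parseable codes; they are for display only.
    """
    parts = []
    for count, token in ((comp.n_hex, "Hex"), (comp.n_pen, "Pen"),
                         (comp.n_dhex, "dHex"), (comp.n_hexA, "U"),
                         (comp.n_methyl, "m"), (comp.n_acetyl, "a")):
        if count:
            parts.append(f"{token}{count}")
    return "".join(parts) or "empty"


def format_code(comp: OligoComposition) -> str:
    """Canonical Hex/Pen composition code for a composition.

    Round-trips with :func:`parse_composition_code` whenever the composition
    has no deoxyhexose and a single backbone family.

    Raises
    ------
    GlycanFormatError
        If the composition contains deoxyhexose (use the letter code) or
        mixes Hex and Pen backbones (no composition-code representation).
    """
    if comp.n_dhex:
        raise GlycanFormatError(
            "deoxyhexose-containing compositions have no Hex/Pen code; "
            "use a xyloglucan letter code (XygoCode) instead"
        )
    if comp.n_hex and comp.n_pen:
        raise GlycanFormatError("mixed Hex/Pen compositions have no composition code")
    if comp.n_hex:
        head = f"Hex{comp.n_hex}"
    elif comp.n_pen:
        head = f"Pen{comp.n_pen}"
    else:
        raise GlycanFormatError("composition has no backbone residues")
    parts = [head]
    if comp.n_hexA:
        parts.append(f"U{comp.n_hexA}")
    if comp.n_methyl:
        parts.append(f"m{comp.n_methyl}")
    if comp.n_acetyl:
        parts.append(f"a{comp.n_acetyl}")
    return "".join(parts)
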