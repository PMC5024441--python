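"""Cell-wall composition accounting with explicit unit semantics.

The bookkeeping follows the standard fractionation of fruit cell walls:
alcohol-insoluble material (AIM) is the crude wall preparation; starch is
deducted from total AIM sugars to give non-starch polysaccharides (NSP);
individual sugars and ester groups are then expressed as a percentage of
NSP; the degree of methylesterification (DM) converts methanol and
galacturonic-acid mass fractions to a molar ratio.  Values carry unit tags
(``%AIM``, ``%NSP``, dimensionless DM) and arithmetic across unit systems
without explicit conversion is rejected.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .spectrum_annotation import STAGES

__all__ = [
    "UnitError",
    "CompositionTable",
    "DigestReleaseTable",
    "TREATMENTS",
    "compute_nsp",
    "pct_of_nsp",
    "degree_methylesterification",
    "release_fraction",
    "stage_anova",
    "STAGE_CONTRASTS",
    "MOLAR_MASS_METHANOL",
    "MOLAR_MASS_ANHYDRO_GALA",
]

#: fixed sequential-digest treatment order
TREATMENTS = ("WS", "PS", "mannanase", "xylanase", "glucanase")

#: molar masses used by the DM computation (g/mol)
MOLAR_MASS_METHANOL = 32.042
#: anhydro-galacturonosyl residue (the in-chain form measured by the UA assay)
MOLAR_MASS_ANHYDRO_GALA = 176.126

#: pairwise stage contrasts reported alongside the ANOVA (a/b/c letters)
STAGE_CONTRASTS = {"a": ("60DAF", "H"), "b": ("H", "2M"), "c": ("60DAF", "2M")}


class UnitError(ValueError):
    """Arithmetic attempted across %AIM / %NSP unit systems."""


@dataclass
class CompositionTable:
    """Stage x analyte table of mean +/- sd values with per-column unit tags."""

    values: pd.DataFrame  # rows = stages, columns = analytes (means)
    sds: pd.DataFrame | None = None
    units: Mapping[str, str] = None  # analyte -> "%AIM" | "%NSP" | "DM"

    def __post_init__(self) -> None:
        if self.units is None:
            raise ValueError("units mapping is required")
        missing = set(self.values.columns) - set(self.units)
        if missing:
            raise ValueError(f"columns without unit tags: {sorted(missing)}")
        if (self.values.to_numpy(dtype=float) < 0).any():
            raise ValueError("composition values must be >= 0")
        bad_stage = set(self.values.index) - set(STAGES)
        if bad_stage:
            raise ValueError(f"unknown stages: {sorted(bad_stage)}")
        nsp_cols = [c for c in self.values.columns if self.units[c] == "%NSP"
                    and c not in ("acetyl ester", "methyl ester")]
        if nsp_cols:
            sums = self.values[nsp_cols].sum(axis=1)
            over = sums[sums > 105]
            if len(over):
                raise ValueError(
                    f"sugar %NSP sums exceed analytical tolerance 105: {dict(over.round(1))}"
                )

    def column(self, analyte: str, expect_unit: str) -> pd.Series:
        """Fetch a column, enforcing its unit tag."""
        unit = self.units[analyte]
        if unit != expect_unit:
            raise UnitError(
                f"column {analyte!r} is in {unit}, not {expect_unit}; convert explicitly"
            )
        return self.values[analyte]

    def to_tsv(self, path) -> None:
        out = self.values.copy()
        out.columns = [f"{c} [{self.units[c]}]" for c in out.columns]
        out.to_csv(path, sep="\t", index_label="stage")

    @classmethod
    def from_tsv(cls, path) -> "CompositionTable":
        raw = pd.read_csv(path, sep="\t", index_col="stage")
        units = {}
        cols = []
        for c in raw.columns:
            if "[" not in c or not c.endswith("]"):
                raise ValueError(f"column {c!r} lacks a '[unit]' tag")
            name, unit = c[:-1].rsplit("[", 1)
            name = name.strip()
            units[name] = unit.strip()
            cols.append(name)
        raw.columns = cols
        return cls(values=raw, units=units)


@dataclass
class DigestReleaseTable:
    """Treatment x analyte table in % of initial NSP, fixed treatment order."""

    values: pd.DataFrame  # index = treatments, columns = analytes

    def __post_init__(self) -> None:
        idx = list(self.values.index)
        expected = [t for t in TREATMENTS if t in idx]
        if idx != expected:
            raise ValueError(
                f"treatments must appear in protocol order {TREATMENTS}, got {idx}"
            )
        if (self.values.to_numpy(dtype=float) < 0).any():
            raise ValueError("release values must be >= 0")


def compute_nsp(total_sugars_pct_aim: float, starch_pct_aim: float) -> float:
    """Non-starch polysaccharides (%AIM): total sugars minus starch glucose."""
    if starch_pct_aim < 0 or total_sugars_pct_aim < 0:
        raise ValueError("inputs must be >= 0")
    if total_sugars_pct_aim > 110:
        raise ValueError(f"total sugars {total_sugars_pct_aim} beyond analytical tolerance")
    if starch_pct_aim > total_sugars_pct_aim:
        raise ValueError(
            f"starch ({starch_pct_aim}) exceeds total sugars ({total_sugars_pct_aim})"
        )
    return max(total_sugars_pct_aim - starch_pct_aim, 0.0)


def pct_of_nsp(analyte_pct_aim: float, nsp_pct_aim: float, stage: str = "?") -> float:
    """Re-express an analyte from %AIM to % of the NSP fraction."""
    if nsp_pct_aim <= 0:
        raise ZeroDivisionError(f"NSP is 0 at stage {stage}; %NSP undefined")
    return analyte_pct_aim / nsp_pct_aim * 100.0


def degree_methylesterification(methanol_pct_nsp: float, gala_pct_nsp: float) -> float:
    """DM: moles of methanol per 100 moles of anhydro-galacturonic acid.

    Both inputs are mass percentages on the same basis (%NSP); the basis
    cancels in the molar ratio.
    """
    if gala_pct_nsp <= 0:
        raise ZeroDivisionError("GalA content must be > 0 to compute DM")
    if methanol_pct_nsp < 0:
        raise ValueError("methanol content must be >= 0")
    mol_meoh = methanol_pct_nsp / MOLAR_MASS_METHANOL
    mol_gala = gala_pct_nsp / MOLAR_MASS_ANHYDRO_GALA
    return mol_meoh / mol_gala * 100.0


def release_fraction(released_pct_nsp: float, initial_pct_nsp: float) -> float:
    """Released sugar as % of its initial content in the NSP fraction.

    A zero *initial* content makes the fraction undefined and raises
    (flagged, not zeroed); zero *release* is simply 0.
    """
    if released_pct_nsp < 0:
        raise ValueError("released amount must be >= 0")
    if initial_pct_nsp <= 0:
        raise ZeroDivisionError("initial sugar content is 0; release fraction undefined")
    return released_pct_nsp / initial_pct_nsp * 100.0


def stage_anova(
    groups: Mapping[str, Sequence[float]],
    alpha: float = 1e-4,
    contrasts: Mapping[str, tuple[str, str]] | None = None,
) -> dict:
    """One-way fixed-effects ANOVA across stages plus named pairwise contrasts.

    Returns ``{"F", "p", "significant", "contrasts": {label: bool}}``; each
    contrast is a two-group ANOVA between the named stage pair, flagged at
    the same ``alpha`` (default 1e-4).
    """
    if len(groups) < 2:
        raise ValueError("need >= 2 stage groups")
    for stage, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(f"stage {stage!r} has < 2 observations")
    arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    if np.ptp(np.concatenate(arrays)) == 0:
        f_stat, p = 0.0, 1.0
    else:
        f_stat, p = stats.f_oneway(*arrays)
        if np.isnan(f_stat):  # zero within-group variance, identical means
            f_stat, p = 0.0, 1.0
    result = {"F": float(f_stat), "p": float(p), "significant": bool(p < alpha)}
    flags = {}
    for label, (s1, s2) in (contrasts or STAGE_CONTRASTS).items():
        if s1 in groups and s2 in groups:
            a = np.asarray(groups[s1], dtype=float)
            b = np.asarray(groups[s2], dtype=float)
            if np.ptp(np.concatenate([a, b])) == 0:
                flags[label] = False
                continue
            f2, p2 = stats.f_oneway(a, b)
            flags[label] = bool((not np.isnan(p2)) and p2 < alpha)
    result["contrasts"] = flags
    return result
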