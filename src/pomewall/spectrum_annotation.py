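"""Digest peak-list reading, composition assignment and intensity matrices.

Peak lists come from MALDI-TOF fingerprints of sequential enzymatic digests
(mannanase, xylanase, glucanase) of cell-wall material.  Each digest has a
reference ion to which intensities are normalized (glucanase: m/z 1085,
XXXG; mannanase: 731, Hex4a1; xylanase: 655, Pen3U1a1), and a default
annotation library reflecting the oligomer families that enzyme releases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .glycan_model import (
    MONOISOTOPIC,
    OligoComposition,
    ResidueMassTable,
    enumerate_compositions,
    parse_code,
    sodiated_mass,
)

logger = logging.getLogger(__name__)

__all__ = [
    "DIGESTS",
    "STAGES",
    "REFERENCE_IONS",
    "ACQUISITION_WINDOW",
    "Peak",
    "Spectrum",
    "AnnotatedPeak",
    "PeaklistError",
    "NormalizationError",
    "read_peaklist",
    "annotate_spectrum",
    "normalize_to_reference",
    "build_intensity_matrix",
    "digest_default_library",
]

DIGESTS = ("mannanase", "xylanase", "glucanase")
STAGES = ("60DAF", "110DAF", "H", "1M", "2M")

#: digest -> nominal m/z of the intensity-normalization reference ion
REFERENCE_IONS = {"glucanase": 1085.0, "mannanase": 731.0, "xylanase": 655.0}

#: acquisition window of the recorded spectra, closed interval in m/z
ACQUISITION_WINDOW = (500.0, 3000.0)


class PeaklistError(ValueError):
    """A peak-list file could not be parsed."""


class NormalizationError(ValueError):
    """The digest's reference ion is missing from a spectrum."""


@dataclass(frozen=True)
class Peak:
    mz: float
    intensity: float

    def __post_init__(self) -> None:
        if self.intensity < 0:
            raise ValueError(f"intensity must be >= 0, got {self.intensity}")


@dataclass(frozen=True)
class Spectrum:
    """A centroided peak list tagged with its digest and sample metadata."""

    digest: str
    sample_id: str
    stage: str
    replicate: int
    peaks: tuple[Peak, ...]
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.digest not in DIGESTS:
            raise ValueError(f"unknown digest {self.digest!r}; allowed: {DIGESTS}")
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; allowed: {STAGES}")
        mzs = [p.mz for p in self.peaks]
        if any(b - a < 1e-6 for a, b in zip(mzs, mzs[1:])):
            raise ValueError("peaks must be sorted by m/z with no duplicates within 1e-6")

    @property
    def mz(self) -> np.ndarray:
        return np.array([p.mz for p in self.peaks])

    @property
    def intensity(self) -> np.ndarray:
        return np.array([p.intensity for p in self.peaks])


@dataclass(frozen=True)
class AnnotatedPeak:
    peak: Peak
    assignments: tuple[tuple[OligoComposition, float], ...]  # (comp, mass error Da)

    @property
    def ambiguous(self) -> bool:
        return len(self.assignments) > 1

    @property
    def assigned(self) -> bool:
        return len(self.assignments) > 0


def read_peaklist(
    path: str | Path,
    digest: str,
    sample_id: str = "",
    stage: str = "H",
    replicate: int = 1,
    enforce_window: bool = True,
) -> Spectrum:
    """Read a 2-column (m/z, intensity) peak list; '#' lines are comments.

    Columns may be tab- or whitespace-delimited.  With ``enforce_window``
    peaks outside the closed acquisition interval [500, 3000] are dropped
    and the dropped count is logged.
    """
    path = Path(path)
    rows: list[tuple[float, float]] = []
    for i, line in enumerate(path.read_text().splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        parts = stripped.split("\t") if "\t" in stripped else stripped.split()
        if len(parts) < 2:
            raise PeaklistError(f"{path}:{i}: expected 2 columns, got {len(parts)}")
        try:
            rows.append((float(parts[0]), float(parts[1])))
        except ValueError as exc:
            raise PeaklistError(f"{path}:{i}: non-numeric field in {stripped!r}") from exc
    if not rows:
        raise PeaklistError(f"{path}: empty peak list")
    if enforce_window:
        lo, hi = ACQUISITION_WINDOW
        kept = [(mz, it) for mz, it in rows if lo <= mz <= hi]
        dropped = len(rows) - len(kept)
        if dropped:
            logger.info("%s: dropped %d peak(s) outside m/z [%g, %g]", path, dropped, lo, hi)
        rows = kept
    rows.sort(key=lambda r: r[0])
    return Spectrum(
        digest=digest,
        sample_id=sample_id or path.stem,
        stage=stage,
        replicate=replicate,
        peaks=tuple(Peak(mz, it) for mz, it in rows),
    )


def digest_default_library(digest: str) -> set[str]:
    """Composition search families expected in each digest's products.

    Mannanase releases hexo-oligomers (gluco/galactoglucomannan fragments)
    plus pento-oligomers from a contaminating xylanase activity; xylanase
    releases pento-oligomers; glucanase releases xyloglucan oligomers plus
    both other families (observed through its side activities).
    """
    if digest == "mannanase":
        return {"hexose-series", "pentose-series"}
    if digest == "xylanase":
        return {"pentose-series"}
    if digest == "glucanase":
        return {"xygo-grammar", "hexose-series", "pentose-series"}
    raise ValueError(f"unknown digest {digest!r}")


def annotate_spectrum(
    spec: Spectrum,
    tol: float = 0.3,
    library_mode: str | Sequence[str] = "digest-default",
    masses: ResidueMassTable = MONOISOTOPIC,
    max_residues: int = 12,
) -> list[AnnotatedPeak]:
    """Assign every library composition within ``tol`` Da to each peak.

    ``library_mode`` is ``"digest-default"`` (families per digest),
    ``"unconstrained"``, or an explicit sequence of composition codes.
    Unassigned peaks carry empty assignment lists.
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")
    if isinstance(library_mode, str):
        if library_mode == "digest-default":
            families = digest_default_library(spec.digest)
        elif library_mode == "unconstrained":
            families = {"unconstrained"}
        else:
            raise ValueError(f"unknown library_mode {library_mode!r}")
        out = []
        for peak in spec.peaks:
            hits = enumerate_compositions(
                peak.mz, tol, families, masses=masses, max_residues=max_residues
            )
            out.append(AnnotatedPeak(peak=peak, assignments=tuple(hits)))
        return out
    # explicit code list
    library = [(code, parse_code(code)) for code in library_mode]
    masses_of = [(comp, sodiated_mass(comp, masses)) for _, comp in library]
    out = []
    for peak in spec.peaks:
        hits = sorted(
            ((comp, m - peak.mz) for comp, m in masses_of if abs(m - peak.mz) <= tol),
            key=lambda ce: (abs(ce[1]), ce[0]),
        )
        out.append(AnnotatedPeak(peak=peak, assignments=tuple(hits)))
    return out


def normalize_to_reference(spec: Spectrum, tol: float = 0.5) -> Spectrum:
    """Divide all intensities by the digest's reference-ion intensity.

    The reference peak is the most intense peak within ``tol`` of the
    digest's reference m/z (reference ions are major fragments, so ties
    between nearby peaks resolve to the dominant one).  Idempotent: the
    reference peak maps to 1.0, so renormalizing changes nothing.
    """
    ref_mz = REFERENCE_IONS[spec.digest]
    candidates = [p for p in spec.peaks if abs(p.mz - ref_mz) <= tol]
    if not candidates:
        raise NormalizationError(
            f"{spec.digest} spectrum {spec.sample_id!r} has no peak within "
            f"{tol} of the reference ion m/z {ref_mz:g}"
        )
    ref = max(candidates, key=lambda p: p.intensity)
    if ref.intensity == 0:
        raise NormalizationError(
            f"reference peak at m/z {ref.mz:g} has zero intensity"
        )
    scaled = tuple(Peak(p.mz, p.intensity / ref.intensity) for p in spec.peaks)
    return replace(spec, peaks=scaled, normalized=True)


def build_intensity_matrix(
    annotated: Iterable[tuple[Spectrum, list[AnnotatedPeak]]],
    roster: Sequence[str],
    tol: float = 0.3,
    masses: ResidueMassTable = MONOISOTOPIC,
) -> pd.DataFrame:
    """Assemble a samples x ions matrix of (normalized) intensities.

    Rows are individual spectra (replicates kept separate), indexed by
    (sample_id, stage, digest, replicate); columns follow the ion roster of
    composition codes.  An ion absent from a spectrum contributes 0; a
    roster ion observed in no spectrum at all is kept as a zero column with
    a warning.  When several peaks match one roster ion their intensities
    are summed.
    """
    roster_masses = [(code, sodiated_mass(parse_code(code), masses)) for code in roster]
    rows = []
    index = []
    for spec, ann in annotated:
        row = dict.fromkeys(roster, 0.0)
        for ap in ann:
            for code, m in roster_masses:
                if abs(ap.peak.mz - m) <= tol:
                    row[code] += ap.peak.intensity
        rows.append(row)
        index.append((spec.sample_id, spec.stage, spec.digest, spec.replicate))
    df = pd.DataFrame(
        rows,
        index=pd.MultiIndex.from_tuples(
            index, names=["sample_id", "stage", "digest", "replicate"]
        ),
        columns=list(roster),
    )
    for code in df.columns[(df == 0).all(axis=0)]:
        logger.warning("roster ion %s never observed; zero column retained", code)
    return df
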