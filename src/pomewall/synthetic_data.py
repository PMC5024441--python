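"""Synthetic study inputs with known ground truth.

The generators emulate the study design end to end: MALDI-TOF digest
spectra planted at the sodiated monoisotopic masses of known composition
codes (with m/z jitter, multiplicative lognormal intensity noise and
optional decoy peaks); expression matrices over 5 developmental stages
(60DAF, 110DAF, H, 1M, 2M) x 8 genotypes x 2 orchard plots, with planted
"cluster A" genes (high early: 60DAF/110DAF) and "cluster B" genes (high
at ripening/storage: H/1M/2M); and cell-wall composition tables whose
stage trends interpolate the study's endpoints (galactose declining
18.7 -> 7.2 %NSP, uronic acids rising 22.4 -> 29.0 %NSP, xylose rising
4.8 -> 7.6, mannose declining 4.4 -> 3.1, fucose rising 0.8 -> 1.2).

Every generator is a pure function of its scenario and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .glycan_model import parse_code, sodiated_mass
from .spectrum_annotation import (
    ACQUISITION_WINDOW,
    DIGESTS,
    REFERENCE_IONS,
    STAGES,
    Peak,
    Spectrum,
)
from .transcriptome_stats import GENOTYPES, PLOTS, ExpressionMatrix
from .wall_composition import CompositionTable

__all__ = [
    "SpectrumScenario",
    "ExpressionScenario",
    "BiochemScenario",
    "DIGEST_REFERENCE_CODES",
    "DEFAULT_MANNANASE_IONS",
    "DEFAULT_GLUCANASE_IONS",
    "DEFAULT_BIOCHEM_TRENDS",
    "gen_spectrum",
    "gen_expression",
    "gen_biochem",
]

#: reference-ion composition code per digest
DIGEST_REFERENCE_CODES = {
    "glucanase": "XXXG",
    "mannanase": "Hex4a1",
    "xylanase": "Pen3U1a1",
}

#: mannanase-digest roster: hexo-oligomer (galactoglucomannan) fragments
#: with the reference ion dominant, plus minor pento-oligomers
DEFAULT_MANNANASE_IONS: tuple[tuple[str, float], ...] = (
    ("Hex4a1", 1.0), ("Hex4a2", 0.6), ("Hex5a1", 0.7), ("Hex5a2", 0.5),
    ("Hex6a1", 0.5), ("Hex4", 0.3), ("Hex5", 0.25), ("Hex7a1", 0.2),
    ("Hex8a1", 0.12), ("Pen3U1", 0.15), ("Pen3U1a1", 0.12), ("Pen4U1m1", 0.1),
)

#: glucanase-digest roster: xyloglucan oligomers with the XXXG reference
DEFAULT_GLUCANASE_IONS: tuple[tuple[str, float], ...] = (
    ("XXXG", 1.0), ("XXFGa1", 0.9), ("XLFGa1", 0.8), ("XXG", 0.3),
    ("XLG", 0.25), ("GFG", 0.2), ("XFG", 0.25), ("XLXG", 0.35),
    ("XXFG", 0.5), ("XXFGa2", 0.4), ("XLFGa2", 0.3), ("Hex6a1", 0.15),
)

DEFAULT_XYLANASE_IONS: tuple[tuple[str, float], ...] = (
    ("Pen3U1a1", 1.0), ("Pen3U1", 0.6), ("Pen4a1", 0.4), ("Pen4U1m1", 0.5),
    ("Pen4U1m1a1", 0.45), ("Pen5a1", 0.3), ("Pen5U1m1a1", 0.25),
)

_DEFAULT_IONS = {
    "mannanase": DEFAULT_MANNANASE_IONS,
    "glucanase": DEFAULT_GLUCANASE_IONS,
    "xylanase": DEFAULT_XYLANASE_IONS,
}


@dataclass(frozen=True)
class SpectrumScenario:
    """Recipe for one synthetic digest spectrum."""

    digest: str = "glucanase"
    ions: tuple[tuple[str, float], ...] = None  # (code, relative abundance)
    mz_jitter_sd: float = 0.05
    n_decoys: int = 0
    intensity_cv: float = 0.1
    seed: int = 0
    stage: str = "H"
    sample_id: str = "synthetic"
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.digest not in DIGESTS:
            raise ValueError(f"unknown digest {self.digest!r}")
        if self.ions is None:
            object.__setattr__(self, "ions", _DEFAULT_IONS[self.digest])
        if any(ab <= 0 for _, ab in self.ions):
            raise ValueError("abundances must be > 0")
        if self.mz_jitter_sd < 0 or self.intensity_cv < 0 or self.n_decoys < 0:
            raise ValueError("noise parameters must be >= 0")
        codes = [c for c, _ in self.ions]
        ref = DIGEST_REFERENCE_CODES[self.digest]
        if ref not in codes:
            raise ValueError(
                f"scenario must include the {self.digest} reference ion {ref}"
            )


def gen_spectrum(scenario: SpectrumScenario) -> tuple[Spectrum, dict[float, str]]:
    """Generate a spectrum and its ground-truth {observed m/z -> code} map.

    Planted peaks sit at sodiated_mass(code) + N(0, jitter); intensities are
    abundance x lognormal(cv); decoys are uniform over the acquisition
    window (re-drawn if within 1 Da of a planted ion, so the truth map stays
    unambiguous).
    """
    rng = np.random.default_rng(scenario.seed)
    for code, _ in scenario.ions:
        parse_code(code)  # fail before generating anything
    truth: dict[float, str] = {}
    peaks: list[Peak] = []
    planted_mz = []
    sigma = np.sqrt(np.log(1.0 + scenario.intensity_cv**2)) if scenario.intensity_cv else 0.0
    for code, abundance in scenario.ions:
        true_mz = sodiated_mass(parse_code(code))
        obs_mz = true_mz + rng.normal(0.0, scenario.mz_jitter_sd) if scenario.mz_jitter_sd else true_mz
        inten = abundance * (np.exp(rng.normal(-sigma**2 / 2, sigma)) if sigma else 1.0)
        peaks.append(Peak(float(obs_mz), float(inten) * 1000.0))
        truth[float(obs_mz)] = code
        planted_mz.append(true_mz)
    lo, hi = ACQUISITION_WINDOW
    made = 0
    while made < scenario.n_decoys:
        mz = float(rng.uniform(lo, hi))
        if min(abs(mz - m) for m in planted_mz) < 1.0:
            continue
        peaks.append(Peak(mz, float(rng.uniform(10.0, 200.0))))
        made += 1
    peaks.sort(key=lambda p: p.mz)
    spec = Spectrum(
        digest=scenario.digest,
        sample_id=scenario.sample_id,
        stage=scenario.stage,
        replicate=scenario.replicate,
        peaks=tuple(peaks),
    )
    return spec, truth


@dataclass(frozen=True)
class ExpressionScenario:
    """Recipe for a genes x samples log2 expression matrix.

    Cluster A genes get +effect at the two early stages; cluster B genes
    +effect at the three ripening/storage stages; the rest are flat.
    """

    n_genes: int = 1000
    frac_cluster_a: float = 0.05
    frac_cluster_b: float = 0.05
    effect: float = 2.0          # log2 shift
    residual_sd: float = 0.5
    baseline: float = 8.0
    genotypes: tuple[str, ...] = GENOTYPES
    plots: tuple[str, ...] = PLOTS
    stages: tuple[str, ...] = STAGES
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frac_cluster_a + self.frac_cluster_b > 1:
            raise ValueError("cluster fractions must sum to <= 1")
        if self.effect < 0 or self.residual_sd < 0:
            raise ValueError("effect and residual sd must be >= 0")
        unknown = set(self.genotypes) - set(GENOTYPES)
        if unknown:
            raise ValueError(f"unknown genotypes {sorted(unknown)}")


EARLY_STAGES = ("60DAF", "110DAF")
LATE_STAGES = ("H", "1M", "2M")


def gen_expression(scenario: ExpressionScenario) -> tuple[ExpressionMatrix, pd.Series]:
    """Generate an expression matrix and the true per-gene cluster labels.

    Labels are "A", "B" or "flat" (no planted stage effect).
    """
    rng = np.random.default_rng(scenario.seed)
    n_a = int(round(scenario.n_genes * scenario.frac_cluster_a))
    n_b = int(round(scenario.n_genes * scenario.frac_cluster_b))
    labels = np.array(["A"] * n_a + ["B"] * n_b + ["flat"] * (scenario.n_genes - n_a - n_b))
    genes = [f"gene{i:05d}" for i in range(scenario.n_genes)]

    sample_rows = []
    for stage in scenario.stages:
        for genotype in scenario.genotypes:
            for plot in scenario.plots:
                sample_rows.append(
                    {"sample": f"{stage}_{genotype}_{plot}", "stage": stage,
                     "genotype": genotype, "plot": plot}
                )
    samples = pd.DataFrame(sample_rows)
    is_early = samples["stage"].isin(EARLY_STAGES).to_numpy()

    mean = np.full((scenario.n_genes, len(samples)), scenario.baseline)
    mean[labels == "A"] += np.where(is_early, scenario.effect, 0.0)
    mean[labels == "B"] += np.where(is_early, 0.0, scenario.effect)
    values = mean + rng.normal(0.0, scenario.residual_sd, size=mean.shape)
    matrix = ExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=samples["sample"]),
        samples=samples,
    )
    return matrix, pd.Series(labels, index=genes, name="cluster")


#: stage-trend defaults (%NSP endpoints at 60DAF and 2M, noise sd)
DEFAULT_BIOCHEM_TRENDS: dict[str, tuple[float, float, float]] = {
    "Gal": (18.7, 7.2, 0.5),
    "UA": (22.4, 29.0, 0.7),
    "Xyl": (4.8, 7.6, 0.2),
    "Man": (4.4, 3.1, 0.15),
    "Fuc": (0.8, 1.2, 0.05),
}


@dataclass(frozen=True)
class BiochemScenario:
    """Recipe for a composition table with linear stage trends + noise."""

    trends: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BIOCHEM_TRENDS)
    )
    n_replicates: int = 3
    stages: tuple[str, ...] = STAGES
    seed: int = 0

    def __post_init__(self) -> None:
        for name, (start, end, sd) in self.trends.items():
            if start < 0 or end < 0 or sd < 0:
                raise ValueError(f"trend for {name!r} has negative parameters")
        if self.n_replicates < 1:
            raise ValueError("need >= 1 replicate")


def gen_biochem(
    scenario: BiochemScenario,
) -> tuple[CompositionTable, pd.DataFrame]:
    """Generate a composition table and the replicate-level values.

    Templates interpolate linearly from the 60DAF endpoint to the 2M
    endpoint across the stage axis; replicates add Gaussian noise.  A
    draw that lands negative is resampled rather than clipped, so the
    noise distribution is truncated, never massed at zero.

    Returns (table of means +/- sd with %NSP unit tags,
    replicates as variables x (stage, replicate) DataFrame).
    """
    rng = np.random.default_rng(scenario.seed)
    n_stage = len(scenario.stages)
    reps: dict[tuple[str, int], dict[str, float]] = {}
    for si, stage in enumerate(scenario.stages):
        frac = si / (n_stage - 1) if n_stage > 1 else 0.0
        for rep in range(1, scenario.n_replicates + 1):
            row = {}
            for analyte, (start, end, sd) in scenario.trends.items():
                template = start + (end - start) * frac
                value = rng.normal(template, sd) if sd else template
                while value < 0:
                    value = rng.normal(template, sd)
                row[analyte] = value
            reps[(stage, rep)] = row
    rep_df = pd.DataFrame(reps)  # variables x (stage, replicate)
    rep_df.columns = pd.MultiIndex.from_tuples(rep_df.columns, names=["stage", "replicate"])
    means = rep_df.T.groupby(level="stage", sort=False).mean().T
    sds = rep_df.T.groupby(level="stage", sort=False).std().T
    units = {analyte: "%NSP" for analyte in rep_df.index}
    table = CompositionTable(
        values=means.T.loc[list(scenario.stages)],
        sds=sds.T.loc[list(scenario.stages)],
        units=units,
    )
    return table, rep_df
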