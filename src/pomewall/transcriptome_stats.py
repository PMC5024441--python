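"""Expression normalization, moderated differential testing and clustering.

The differential-testing engine is a two-group empirical-Bayes moderated
t-test: per-gene residual variances s_g^2 (d_g degrees of freedom each) are
shrunk toward a prior variance s_0^2 with prior degrees of freedom d_0,
both estimated from the ensemble of variances by moment matching on
log s_g^2 using digamma/trigamma identities for the log scaled-chi-square
distribution.  The moderated statistic

    t_g = effect_g / (s_post,g * c),   s_post,g^2 = (d0 s0^2 + d_g s_g^2)/(d0 + d_g)

is referred to a t distribution with d0 + d_g degrees of freedom (c is the
design standard-error factor, sqrt(1/n1 + 1/n2) for two groups).

Also provided: lowess detrending of two-channel log-ratios, quantile
normalization, correlation-distance average-linkage clustering and
qPCR relative expression (2^-dCt with a 3-reference-gene normalization
factor).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

__all__ = [
    "GENOTYPES",
    "ExpressionMatrix",
    "ModeratedTestResult",
    "QpcrRecord",
    "lowess_normalize",
    "subtract_background",
    "quantile_normalize",
    "moderated_ttest",
    "select_differential",
    "hierarchical_cluster",
    "relative_expression",
    "fold_change",
    "trigamma_inverse",
]

GENOTYPES = ("H074", "H097", "I016", "I062", "I095", "V034", "V083", "W029")
PLOTS = ("PH", "P12")


@dataclass
class ExpressionMatrix:
    """log2-scale genes x samples matrix plus a sample sheet.

    The sample sheet (one row per column of ``values``) carries stage,
    genotype, plot and an optional dye tag; stage and genotype vocabularies
    are closed.
    """

    values: pd.DataFrame
    samples: pd.DataFrame  # columns: sample, stage, genotype, plot[, dye]

    def __post_init__(self) -> None:
        from .spectrum_annotation import STAGES

        if list(self.samples["sample"]) != list(self.values.columns):
            raise ValueError("sample sheet order must match matrix columns")
        if self.samples[["stage", "genotype"]].isna().any().any():
            raise ValueError("stage/genotype labels must not be missing")
        bad = set(self.samples["stage"]) - set(STAGES)
        if bad:
            raise ValueError(f"unknown stages: {sorted(bad)}")
        bad = set(self.samples["genotype"]) - set(GENOTYPES)
        if bad:
            raise ValueError(f"unknown genotypes: {sorted(bad)}")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("expression values must be finite")

    def to_tsv(self, values_path, samples_path) -> None:
        self.values.to_csv(values_path, sep="\t", index_label="gene")
        self.samples.to_csv(samples_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, values_path, samples_path) -> "ExpressionMatrix":
        values = pd.read_csv(values_path, sep="\t", index_col="gene")
        samples = pd.read_csv(samples_path, sep="\t")
        return cls(values=values, samples=samples)


def lowess_normalize(
    red: np.ndarray, green: np.ndarray, frac: float = 0.3
) -> tuple[np.ndarray, np.ndarray]:
    """Detrend two-channel log-ratios against mean log-intensity (MA lowess).

    M = log2(red/green) is regressed on A = (log2 red + log2 green)/2 by
    locally weighted regression and the fit subtracted, removing smooth
    intensity-dependent dye bias.  Returns (corrected M, A).
    """
    red = np.asarray(red, dtype=float)
    green = np.asarray(green, dtype=float)
    bad = np.flatnonzero((red <= 0) | (green <= 0))
    if bad.size:
        raise ValueError(f"non-positive intensities at probe indices {bad[:10].tolist()}")
    m = np.log2(red) - np.log2(green)
    a = 0.5 * (np.log2(red) + np.log2(green))
    if np.ptp(m) == 0:  # no trend to fit; lowess of a constant is itself
        return m - m, a
    fit = _sm_lowess(m, a, frac=frac, return_sorted=False)
    return m - fit, a


def subtract_background(
    intensities: np.ndarray, background: np.ndarray, floor: float = 0.5
) -> np.ndarray:
    """Per-probe background subtraction floored at a small positive value.

    A deliberately simple estimator: the original processing chain
    subtracts a background estimate before quantile normalization but does
    not document its estimator, so this stand-in keeps the operation
    explicit and monotone.  The floor keeps downstream log transforms
    finite.
    """
    if floor <= 0:
        raise ValueError("floor must be > 0")
    intensities = np.asarray(intensities, dtype=float)
    background = np.asarray(background, dtype=float)
    if intensities.shape != background.shape:
        raise ValueError("intensities and background must have equal shape")
    return np.maximum(intensities - background, floor)


def quantile_normalize(matrix: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Force every column onto the common distribution of rank-wise means.

    Each rank maps to the mean across columns of that rank's values; ties
    within a column share the average of their mapped values.  Idempotent
    and rank-preserving per column.
    """
    df = pd.DataFrame(matrix).copy()
    if df.isna().any().any():
        raise ValueError("missing values not allowed")
    arr = df.to_numpy(dtype=float)
    order = np.argsort(arr, axis=0, kind="mergesort")
    sorted_vals = np.take_along_axis(arr, order, axis=0)
    mean_dist = sorted_vals.mean(axis=1)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        ranks = stats.rankdata(arr[:, j], method="average")  # 1-based, ties averaged
        out[:, j] = np.interp(ranks, np.arange(1, arr.shape[0] + 1), mean_dist)
    result = pd.DataFrame(out, index=df.index, columns=df.columns)
    if isinstance(matrix, np.ndarray):
        return result.to_numpy()
    return result


def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


@dataclass
class ModeratedTestResult:
    """Per-gene moderated-t results plus the shared prior (d0, s0)."""

    effect: np.ndarray       # mean log-ratio (group1 - group2)
    s_g: np.ndarray          # per-gene residual sd
    df_residual: float       # d_g, common to all genes in a balanced fit
    prior_df: float          # d0
    prior_s: float           # s0
    s_post: np.ndarray       # posterior (moderated) sd
    t: np.ndarray
    p: np.ndarray
    genes: pd.Index | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"effect": self.effect, "s_g": self.s_g, "s_post": self.s_post,
             "t": self.t, "p": self.p},
            index=self.genes,
        )


def _fit_prior(s2: np.ndarray, d_g: float) -> tuple[float, float]:
    """Estimate (d0, s0^2) from per-gene variances by log-variance moments.

    For s_g^2 ~ s0^2 * chi^2_{d_g}/d_g scaled by a chi^2_{d0} prior,
    z_g = log s_g^2 has mean log s0^2 + digamma(d_g/2) - log(d_g/2)
    - digamma(d0/2) + log(d0/2) ... rearranged so that
    e_g = z_g - digamma(d_g/2) + log(d_g/2) has
    mean log s0^2 - digamma(d0/2) + log(d0/2) and
    variance trigamma(d_g/2) + trigamma(d0/2).
    """
    z = np.log(np.maximum(s2, 1e-300))
    e = z - special.digamma(d_g / 2.0) + np.log(d_g / 2.0)
    e_mean = float(e.mean())
    e_var = float(np.var(e, ddof=1)) - float(special.polygamma(1, d_g / 2.0))
    if e_var <= 0:
        return np.inf, float(np.exp(e_mean))
    d0 = 2.0 * trigamma_inverse(e_var)
    s0_sq = np.exp(
        e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)
    )
    return float(d0), float(s0_sq)


def moderated_ttest(
    matrix: pd.DataFrame | np.ndarray,
    group1: list | np.ndarray,
    group2: list | np.ndarray,
    prior_df: float | None = None,
) -> ModeratedTestResult:
    """Two-group empirical-Bayes moderated t-test, one test per gene (row).

    ``group1``/``group2`` are column labels (DataFrame) or indices.
    ``prior_df`` overrides the estimated d0: ``0`` disables moderation
    (ordinary two-sample t), ``numpy.inf`` pools all genes to the common
    prior variance.
    """
    df = pd.DataFrame(matrix)
    x1 = df[group1].to_numpy(dtype=float) if not isinstance(matrix, np.ndarray) \
        else np.asarray(matrix, dtype=float)[:, group1]
    x2 = df[group2].to_numpy(dtype=float) if not isinstance(matrix, np.ndarray) \
        else np.asarray(matrix, dtype=float)[:, group2]
    n1, n2 = x1.shape[1], x2.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("need >= 2 samples per group")
    d_g = n1 + n2 - 2
    if d_g <= 0:
        raise ValueError("zero residual degrees of freedom")
    effect = x1.mean(axis=1) - x2.mean(axis=1)
    ss = ((x1 - x1.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (x2 - x2.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    s2 = ss / d_g
    if prior_df is None:
        d0, s0_sq = _fit_prior(s2, d_g)
    elif prior_df == 0:
        d0, s0_sq = 0.0, float(np.median(s2))
    elif np.isinf(prior_df):
        _, s0_sq = _fit_prior(s2, d_g)
        d0 = np.inf
    else:
        d0 = float(prior_df)
        _, s0_sq = _fit_prior(s2, d_g)
    if np.isinf(d0):
        s_post_sq = np.full_like(s2, s0_sq)
        df_total = np.inf
    else:
        s_post_sq = (d0 * s0_sq + d_g * s2) / (d0 + d_g)
        df_total = d0 + d_g
    se = np.sqrt(s_post_sq * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, effect / se, 0.0)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    genes = df.index if not isinstance(matrix, np.ndarray) else None
    return ModeratedTestResult(
        effect=effect, s_g=np.sqrt(s2), df_residual=float(d_g),
        prior_df=float(d0), prior_s=float(np.sqrt(s0_sq)),
        s_post=np.sqrt(s_post_sq), t=t, p=p, genes=genes,
    )


def select_differential(
    result: ModeratedTestResult, alpha: float = 0.01
) -> dict[str, np.ndarray]:
    """Genes with p < alpha, partitioned by effect sign (up / down)."""
    if not (0 < alpha <= 1):
        raise ValueError("alpha must be in (0, 1]")
    sig = result.p < alpha
    idx = result.genes if result.genes is not None else pd.RangeIndex(len(result.p))
    return {
        "up": np.asarray(idx[sig & (result.effect > 0)]),
        "down": np.asarray(idx[sig & (result.effect < 0)]),
        "all": np.asarray(idx[sig]),
    }


def hierarchical_cluster(
    profiles: pd.DataFrame | np.ndarray, k: int | None = None
) -> dict:
    """Average-linkage (UPGMA) clustering with 1 - Pearson r distance.

    Rows are profiles.  Returns ``{"linkage", "labels", "index"}``; flat
    ``labels`` are present when ``k`` is given.  The Pearson distance makes
    the result invariant to per-profile affine scaling.  Zero-variance
    profiles are rejected by name.
    """
    df = pd.DataFrame(profiles)
    if df.shape[0] < 2 or df.shape[1] < 3:
        raise ValueError("need >= 2 profiles of >= 3 points")
    arr = df.to_numpy(dtype=float)
    sd = arr.std(axis=1)
    if (sd == 0).any():
        bad = list(df.index[sd == 0])
        raise ValueError(f"zero-variance profiles: {bad[:5]}")
    centered = arr - arr.mean(axis=1, keepdims=True)
    normed = centered / np.linalg.norm(centered, axis=1, keepdims=True)
    corr = np.clip(normed @ normed.T, -1.0, 1.0)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    out = {"linkage": z, "index": df.index}
    if k is not None:
        out["labels"] = hierarchy.fcluster(z, t=k, criterion="maxclust")
    return out


@dataclass(frozen=True)
class QpcrRecord:
    ct_target: float
    ct_ref: float
    delta_ct: float
    relative_expression: float


def relative_expression(ct_target: float, ct_refs: tuple[float, float, float]) -> QpcrRecord:
    """Relative expression 2^-dCt against a 3-reference-gene factor.

    The normalization factor Ct_ref is the arithmetic mean of the three
    reference-gene Cts; dCt = Ct_target - Ct_ref.
    """
    for ct in (ct_target, *ct_refs):
        if not (0 < ct < 45):
            raise ValueError(f"Ct {ct} outside the valid range (0, 45)")
    if len(ct_refs) != 3:
        raise ValueError("exactly three reference-gene Cts required")
    ct_ref = float(np.mean(ct_refs))
    delta = ct_target - ct_ref
    return QpcrRecord(
        ct_target=ct_target, ct_ref=ct_ref, delta_ct=delta,
        relative_expression=float(2.0 ** (-delta)),
    )


def fold_change(delta_ct_1: float, delta_ct_2: float) -> float:
    """Fold change 2^-(ddCt) between two conditions' dCt values."""
    return float(2.0 ** (-(delta_ct_1 - delta_ct_2)))
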