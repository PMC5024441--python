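"""PCA, genotype pooling and thresholded Pearson correlation networks.

Integrates the biochemical and transcriptomic layers: PCA of ion-intensity
fingerprints separates developmental stages; genotype pooling averages
expression over three fixed genotype pools so the 5-stage expression series
can be paired with the 3 biochemical replicates per stage; gene-gene and
gene-biochemistry Pearson correlations are thresholded (gene networks:
r > 0.7 and p < 0.01, positive-only; integration: |r| > threshold because
negative biochemistry correlations are informative) and assembled into
networks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DEFAULT_POOLS",
    "PcaResult",
    "CorrelationEdge",
    "CorrelationNetwork",
    "pca",
    "pool_genotypes",
    "pearson_with_p",
    "build_network",
    "correlate_biochem_transcript",
]

#: fixed genotype pooling scheme: three pools matched to the three
#: biochemical replicates
DEFAULT_POOLS: dict[str, tuple[str, ...]] = {
    "Pool1": ("V034", "I062", "V083"),
    "Pool2": ("W029", "I095", "H097"),
    "Pool3": ("H074", "I016"),
}


@dataclass
class PcaResult:
    scores: pd.DataFrame          # samples x k
    loadings: pd.DataFrame        # variables x k
    explained_variance_ratio: np.ndarray

    def __post_init__(self) -> None:
        load = self.loadings.to_numpy()
        gram = load.T @ load
        if not np.allclose(gram, np.eye(gram.shape[0]), atol=1e-8):
            raise ValueError("loadings must be orthonormal")
        evr = self.explained_variance_ratio
        if evr.sum() > 1 + 1e-8 or (np.diff(evr) > 1e-12).any():
            raise ValueError("explained-variance ratios must be non-increasing, sum <= 1")


def pca(
    matrix: pd.DataFrame | np.ndarray,
    n_components: int | None = None,
    center: bool = True,
    scale: bool = False,
) -> PcaResult:
    """Principal component analysis via SVD of the (centered, scaled) data.

    Scores are the projections of the rows on the loadings; loadings
    columns are unit-norm.  Column signs are fixed so each loading's
    largest-magnitude entry is positive, making results deterministic.
    """
    df = pd.DataFrame(matrix)
    if df.shape[0] < 2 or df.shape[1] < 2:
        raise ValueError("need >= 2 rows and >= 2 columns")
    x = df.to_numpy(dtype=float)
    if center:
        x = x - x.mean(axis=0)
    if scale:
        sd = x.std(axis=0, ddof=1)
        zero = np.flatnonzero(sd == 0)
        if zero.size:
            raise ValueError(
                f"zero-variance columns cannot be scaled: {list(df.columns[zero][:5])}"
            )
        x = x / sd
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    k = n_components or min(x.shape)
    k = min(k, len(s))
    # sign convention: dominant entry of each loading positive
    for j in range(k):
        i = np.argmax(np.abs(vt[j]))
        if vt[j, i] < 0:
            vt[j] *= -1
            u[:, j] *= -1
    var = s**2 / max(x.shape[0] - 1, 1)
    total = var.sum()
    evr = var[:k] / total if total > 0 else np.zeros(k)
    comp_names = [f"PC{j + 1}" for j in range(k)]
    return PcaResult(
        scores=pd.DataFrame((u[:, :k] * s[:k]), index=df.index, columns=comp_names),
        loadings=pd.DataFrame(vt[:k].T, index=df.columns, columns=comp_names),
        explained_variance_ratio=evr,
    )


def pool_genotypes(
    expr: pd.DataFrame,
    samples: pd.DataFrame,
    pools: Mapping[str, Sequence[str]] = None,
) -> pd.DataFrame:
    """Average expression per (stage, genotype pool).

    ``samples`` maps the columns of ``expr`` to stage and genotype; the
    result has one column per stage x pool (MultiIndex), the arithmetic
    mean over all member-genotype samples at that stage.
    """
    from .transcriptome_stats import GENOTYPES

    pools = dict(pools or DEFAULT_POOLS)
    for name, members in pools.items():
        unknown = set(members) - set(GENOTYPES)
        if unknown:
            raise ValueError(f"pool {name!r} has unknown genotypes {sorted(unknown)}")
    meta = samples.set_index("sample")
    cols = {}
    for stage in meta["stage"].unique():
        for pool_name, members in pools.items():
            sel = meta.index[(meta["stage"] == stage) & meta["genotype"].isin(members)]
            if len(sel) == 0:
                raise ValueError(f"no samples for stage {stage}, pool {pool_name}")
            cols[(stage, pool_name)] = expr[sel].mean(axis=1)
    out = pd.DataFrame(cols)
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["stage", "pool"])
    return out


def pearson_with_p(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, int]:
    """Pearson r with a two-sided p-value from the t transform.

    p comes from t = r * sqrt(n-2) / sqrt(1-r^2) referred to t_{n-2}.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need n >= 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input has undefined correlation")
    xc = x - x.mean()
    yc = y - y.mean()
    r = float(xc @ yc / np.sqrt((xc @ xc) * (yc @ yc)))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0, n
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return r, p, n


@dataclass(frozen=True)
class CorrelationEdge:
    node1: str
    node2: str
    r: float
    p: float
    n: int


@dataclass
class CorrelationNetwork:
    graph: nx.Graph
    r_min: float
    p_max: float
    signed_mode: str  # "positive" | "absolute"
    edges: list[CorrelationEdge] = field(default_factory=list)

    def components(self) -> list[set]:
        return sorted(nx.connected_components(self.graph), key=len, reverse=True)

    def to_edge_list(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.node1, e.node2, e.r, e.p, e.n) for e in self.edges],
            columns=["node1", "node2", "r", "p", "n"],
        )

    def to_graphml(self, path) -> None:
        nx.write_graphml(self.graph, path)


def build_network(
    profiles: pd.DataFrame,
    r_min: float = 0.7,
    p_max: float = 0.01,
    signed_mode: str = "positive",
    node_role: str = "gene",
) -> CorrelationNetwork:
    """All-pairs thresholded Pearson correlation network over profile rows.

    ``signed_mode="positive"`` admits edges with r > r_min (gene co-expression
    default); ``"absolute"`` admits |r| > r_min (integration default, where
    anti-correlation is meaningful).  Every retained edge also needs
    p < p_max.  No multiple-testing correction is applied by default.
    """
    if signed_mode not in ("positive", "absolute"):
        raise ValueError("signed_mode must be 'positive' or 'absolute'")
    df = pd.DataFrame(profiles)
    if df.shape[0] < 2:
        raise ValueError("need >= 2 profiles")
    g = nx.Graph()
    for node in df.index:
        g.add_node(str(node), role=node_role)
    edges: list[CorrelationEdge] = []
    idx = list(df.index)
    arr = df.to_numpy(dtype=float)
    for i in range(len(idx)):
        for j in range(i + 1, len(idx)):
            r, p, n = pearson_with_p(arr[i], arr[j])
            keep = (r > r_min) if signed_mode == "positive" else (abs(r) > r_min)
            if keep and p < p_max:
                e = CorrelationEdge(str(idx[i]), str(idx[j]), r, p, n)
                edges.append(e)
                g.add_edge(e.node1, e.node2, r=r, p=p, n=n)
    return CorrelationNetwork(
        graph=g, r_min=r_min, p_max=p_max, signed_mode=signed_mode, edges=edges
    )


def correlate_biochem_transcript(
    biochem: pd.DataFrame,
    pooled_expr: pd.DataFrame,
    p_max: float = 0.01,
) -> pd.DataFrame:
    """Pearson correlation of each gene with each biochemical variable.

    ``biochem``: variables x (stage, replicate) values; ``pooled_expr``:
    genes x (stage, pool).  Pairing is positional by stage and by
    replicate-vs-pool index, so both must cover the same stages with the
    same number of series per stage.  Returns a long table with r, p, n
    and a significance flag at ``p_max``; the sign of r is retained.
    """
    b_cols = list(biochem.columns)
    e_cols = list(pooled_expr.columns)
    if len(b_cols) != len(e_cols):
        raise ValueError(
            f"axis mismatch: biochemistry has {len(b_cols)} series, "
            f"expression has {len(e_cols)}"
        )
    b_stages = [c[0] for c in b_cols]
    e_stages = [c[0] for c in e_cols]
    if sorted(b_stages) != sorted(e_stages):
        raise ValueError("stage axes differ between biochemistry and expression")
    # align expression columns to the biochemical (stage, replicate) order
    order = []
    used = set()
    for stage in b_stages:
        for k, c in enumerate(e_cols):
            if k not in used and c[0] == stage:
                order.append(c)
                used.add(k)
                break
    expr_aligned = pooled_expr[order]
    rows = []
    for gene in pooled_expr.index:
        gvals = expr_aligned.loc[gene].to_numpy(dtype=float)
        for var in biochem.index:
            bvals = biochem.loc[var].to_numpy(dtype=float)
            r, p, n = pearson_with_p(gvals, bvals)
            rows.append((gene, var, r, p, n, p < p_max))
    return pd.DataFrame(
        rows, columns=["gene", "variable", "r", "p", "n", "significant"]
    )


def qualitative_sign_structure(seed: int) -> bool:
    """One seeded end-to-end run of the default synthetic study design.

    Generates default expression and biochemistry scenarios, pools
    genotypes, correlates planted cluster genes with the analyte trends,
    and reports whether the expected sign structure holds: cluster-A
    (early-expressed) genes correlate positively with the declining
    galactose and mannose series and negatively with the rising xylose and
    fucose series; cluster-B genes show the opposite signs.  "Holds" means
    the median correlation over the cluster's genes has the expected sign
    for every analyte.
    """
    from .synthetic_data import BiochemScenario, ExpressionScenario, gen_biochem, gen_expression

    em, labels = gen_expression(ExpressionScenario(seed=seed))
    _, reps = gen_biochem(BiochemScenario(seed=seed))
    pooled = pool_genotypes(em.values, em.samples)
    planted = labels.index[labels != "flat"]
    out = correlate_biochem_transcript(reps, pooled.loc[planted])
    out = out.merge(labels.rename("cluster"), left_on="gene", right_index=True)
    expected = {"Gal": +1, "Man": +1, "Xyl": -1, "Fuc": -1}
    for cluster, flip in (("A", +1), ("B", -1)):
        med = out[out["cluster"] == cluster].groupby("variable")["r"].median()
        for analyte, sign in expected.items():
            if np.sign(med[analyte]) != sign * flip:
                return False
    return True
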