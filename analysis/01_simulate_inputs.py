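#!/usr/bin/env python
"""Generate the synthetic study inputs: digest peak lists for every stage
and replicate, the expression matrix with planted early/late clusters, and
the stage-trend composition table.  Everything downstream reads these files.
"""

import json
from pathlib import Path

from pomewall.spectrum_annotation import STAGES
from pomewall.synthetic_data import (
    _DEFAULT_IONS,
    BiochemScenario,
    ExpressionScenario,
    SpectrumScenario,
    gen_biochem,
    gen_expression,
    gen_spectrum,
)

SEED = 1
OUT = Path(__file__).resolve().parents[1] / "scratch" / "simulated"
EARLY = {"60DAF", "110DAF"}


# marker ions whose relative intensity distinguishes the stages: acetylated
# hexo/pento-oligomers characterize early development, several xyloglucan
# oligomers the mature fruit.  Reference ions are never scaled so the
# normalization denominator stays stage-invariant.
EARLY_MARKERS = {"Hex4", "Hex5", "Hex4a2", "Hex5a1", "Hex5a2", "Hex6a1",
                 "Hex7a1", "Hex8a1", "Pen3U1a1", "Pen4U1m1", "Pen4U1m1a1",
                 "Pen5U1m1a1"}
MATURE_MARKERS = {"XXG", "GFG", "XLXG", "XXFGa2", "XLFGa2"}


def stage_ions(digest: str, stage: str) -> tuple[tuple[str, float], ...]:
    """Shift per-ion abundances by stage, emulating the fine-structure
    change of hemicelluloses between early development and ripening."""
    out = []
    for code, abundance in _DEFAULT_IONS[digest]:
        factor = 1.0
        if code in EARLY_MARKERS:
            factor = 2.0 if stage in EARLY else 0.5
        elif code in MATURE_MARKERS:
            factor = 0.5 if stage in EARLY else 2.0
        out.append((code, abundance * factor))
    return tuple(out)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    truth_all = {}
    n_files = 0
    for digest in ("mannanase", "glucanase"):
        for si, stage in enumerate(STAGES):
            for rep in (1, 2, 3):
                scen = SpectrumScenario(
                    digest=digest, stage=stage, replicate=rep,
                    sample_id=f"{stage}_r{rep}", ions=stage_ions(digest, stage),
                    seed=SEED * 1000 + si * 10 + rep, n_decoys=5,
                )
                spec, truth = gen_spectrum(scen)
                name = f"{digest}_{stage}_r{rep}"
                lines = [f"{p.mz:.4f}\t{p.intensity:.4f}" for p in spec.peaks]
                (OUT / f"{name}.peaks.tsv").write_text("\n".join(lines) + "\n")
                truth_all[name] = {f"{mz:.4f}": code for mz, code in truth.items()}
                n_files += 1
    (OUT / "spectra_truth.json").write_text(json.dumps(truth_all, indent=2))
    print(f"wrote {n_files} digest peak lists (5 stages x 3 replicates x 2 digests)")

    expr, labels = gen_expression(ExpressionScenario(seed=SEED))
    expr.to_tsv(OUT / "expression.tsv", OUT / "samples.tsv")
    labels.to_csv(OUT / "true_clusters.tsv", sep="\t")
    n_a, n_b = (labels == "A").sum(), (labels == "B").sum()
    print(f"expression: {expr.values.shape[0]} genes x {expr.values.shape[1]} samples; "
          f"planted {n_a} cluster-A and {n_b} cluster-B genes")

    table, reps = gen_biochem(BiochemScenario(seed=SEED))
    table.to_tsv(OUT / "composition.tsv")
    reps.to_csv(OUT / "composition_replicates.tsv", sep="\t")
    print("biochemistry: stage trends "
          + ", ".join(f"{a} {table.values[a].iloc[0]:.1f}->{table.values[a].iloc[-1]:.1f} %NSP"
                      for a in table.values.columns))


if __name__ == "__main__":
    main()
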