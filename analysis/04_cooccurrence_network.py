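#!/usr/bin/env python
"""Co-occurrence network and isolated-vs-co-occurring fitness contrasts.

Builds the gene- and category-level mutation co-occurrence networks
across the pooled synthetic cohorts and tests whether mutations
occurring alone in a clone carry different log fitness than co-occurring
ones (Brunner-Munzel, Benjamini-Yekutieli corrected).
"""

import pathlib

import pandas as pd

from clonedyn.io import apply_variant_filters, build_trajectories
from clonedyn.network import build_network, compare_isolated_vs_cooccurring, export_network
from clonedyn.pipeline import analyze_cohort

BASE = pathlib.Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    import importlib.util

    spec = importlib.util.spec_from_file_location(
        "infer", pathlib.Path(__file__).parent / "02_infer_structures.py"
    )
    infer = importlib.util.module_from_spec(spec)
    spec.loader.exec_module(infer)

    estimates = []
    for template in ("LBC", "SardiNIA", "WHI"):
        obs = infer.load_observations(BASE / "synthetic" / template / "variants.tsv")
        kept, _ = apply_variant_filters(obs)
        ests, _ = analyze_cohort(build_trajectories(kept))
        estimates.extend(e for e in ests.values() if e is not None)

    outdir = BASE / "network"
    outdir.mkdir(parents=True, exist_ok=True)
    for level in ("gene", "category"):
        net = build_network(estimates, level=level)
        export_network(net, outdir / f"{level}.graphml", outdir / f"{level}.json")
        net.nodes.to_csv(outdir / f"{level}_nodes.tsv", sep="\t", index=False)
        net.edges.to_csv(outdir / f"{level}_edges.tsv", sep="\t", index=False)
        print(f"{level}-level network: {len(net.nodes)} nodes, {len(net.edges)} edges")

    results = compare_isolated_vs_cooccurring(estimates, grouping="category")
    df = pd.DataFrame([vars(r) for r in results])
    df.to_csv(outdir / "fitness_contrasts.tsv", sep="\t", index=False)
    tested = df[df["p_raw"].notna()]
    print(
        f"fitness contrasts: {len(tested)} tested, "
        f"{(tested['p_adjusted'] < 0.05).sum()} significant after BY at 0.05"
    )


if __name__ == "__main__":
    main()
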