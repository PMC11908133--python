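#!/usr/bin/env python
"""Simulate the three cohort designs with known ground truth.

Generates synthetic LBC (3 waves near ages 70/76/82), SardiNIA (5 waves
over ~20 years) and WHI (postmenopausal women, visits at years 1/3/6/9
plus a late-life visit) cohorts with gene-dependent fitness, clone
co-occurrence, binomial read noise, marker trajectories and survival
times, and writes the tables the downstream stages consume.
"""

import pathlib

from clonedyn.simulate import simulate_cohort

OUT = pathlib.Path(__file__).resolve().parents[1] / "results" / "synthetic"
SEED = 20260924
N = {"LBC": 120, "SardiNIA": 120, "WHI": 120}


def main() -> None:
    for offset, (template, n) in enumerate(N.items()):
        tables = simulate_cohort(template, n, seed=SEED + offset)
        outdir = OUT / template
        outdir.mkdir(parents=True, exist_ok=True)
        for name, df in tables.items():
            df.to_csv(outdir / f"{name}.tsv", sep="\t", index=False)
        n_var = tables["truth"]["variant"].count()
        n_co = (tables["truth"].groupby(["participant_id", "block"]).size() > 1).sum()
        print(
            f"{template}: {n} participants, {n_var} variants "
            f"({n_co} co-occurring clone memberships) -> {outdir}"
        )


if __name__ == "__main__":
    main()
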