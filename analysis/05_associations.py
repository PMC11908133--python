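#!/usr/bin/env python
"""Marker mixed-model and Cox survival association stages.

Standardizes the synthetic blood markers per cohort (outlier fences,
optimal normality transform, z-scoring), fits the longitudinal linear
mixed model per marker against the inferred CH metrics with two-stage
BH correction, and fits the pooled Cox proportional-hazards model of
survival on z-scored max VAF, max fitness, MACS120, age and sex.
"""

import pathlib

import pandas as pd

from clonedyn.associations import (
    fit_cox,
    fit_cox_stratified,
    fit_marker_lmm,
    normalize_marker_table,
)

BASE = pathlib.Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    markers, metrics, surv = [], [], []
    for template in ("LBC", "SardiNIA", "WHI"):
        markers.append(
            pd.read_csv(BASE / "synthetic" / template / "markers.tsv", sep="\t",
                        dtype={"participant_id": str})
        )
        metrics.append(
            pd.read_csv(BASE / "inference" / template / "metrics.tsv", sep="\t",
                        dtype={"participant_id": str})
        )
        cov = pd.read_csv(BASE / "synthetic" / template / "covariates.tsv", sep="\t",
                          dtype={"participant_id": str})
        surv.append(cov.rename(columns={"followup_years": "time"}))
    markers = pd.concat(markers, ignore_index=True)
    surv = pd.concat(surv, ignore_index=True)
    # pooled scope: re-z-score the metrics across the combined cohorts
    from clonedyn.metrics import zscore_metrics

    metrics = zscore_metrics(pd.concat(metrics, ignore_index=True)
                             .drop(columns=["max_vaf_z", "max_fitness_z", "macs120_z"]))

    outdir = BASE / "associations"
    outdir.mkdir(parents=True, exist_ok=True)

    std, report = normalize_marker_table(markers)
    report.to_csv(outdir / "marker_transforms.tsv", sep="\t", index=False)
    lmm = fit_marker_lmm(std, metrics)
    lmm_df = pd.DataFrame([vars(r) for r in lmm])
    lmm_df.to_csv(outdir / "marker_lmm.tsv", sep="\t", index=False)
    sig = lmm_df[(lmm_df["p_adjusted"].notna()) & (lmm_df["p_adjusted"] < 0.05)]
    print(f"marker LMM: {len(lmm_df)} marker-predictor pairs, {len(sig)} significant:")
    for _, r in sig.iterrows():
        print(f"  {r['outcome']} ~ {r['predictor']}: beta={r['beta']:+.3f} "
              f"[{r['ci_low']:+.3f}, {r['ci_high']:+.3f}], q={r['p_adjusted']:.3g}")

    cox, concordance = fit_cox(surv, metrics)
    pd.DataFrame([vars(r) for r in cox]).to_csv(outdir / "cox.tsv", sep="\t", index=False)
    print(f"Cox (pooled, concordance {concordance:.3f}):")
    for r in cox:
        print(f"  {r.predictor}: LPH={r.beta:+.3f} [{r.ci_low:+.3f}, {r.ci_high:+.3f}], "
              f"p={r.p_raw:.3g}")

    strata = fit_cox_stratified(surv, metrics, by="age_bin")
    rows = []
    for stratum, (results, conc) in strata.items():
        for r in results:
            d = vars(r)
            d["concordance"] = conc
            rows.append(d)
    if rows:
        pd.DataFrame(rows).to_csv(outdir / "cox_age_strata.tsv", sep="\t", index=False)
        print(f"age-stratified Cox fits: {sorted(strata)}")


if __name__ == "__main__":
    main()
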