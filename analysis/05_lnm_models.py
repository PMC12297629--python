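"""Train and compare the LNM prediction models M1 and M2.

Splits the cohort 8:2 stratified on nodal status, trains the TIL-augmented
model M1 (age, T stage, TIL score, sTILC) and the clinical-only model M2
(age, T stage) with cross-validated hyperparameters, and runs the full
evaluation battery: AUC, DeLong test, Brier score, exact Shapley
attributions, decision-curve net benefit, and the PCA-feature ablation.
"""

import json
from pathlib import Path

import pandas as pd
from matplotlib import pyplot as plt

from stilmap.models import (
    FEATURES_M1,
    FEATURES_M2,
    compare_models,
    run_ablation_scenarios,
    split_cohort,
    train_model,
)

COHORT = Path("results/cohort")
OUT = Path("results")
SPLIT_SEED, MODEL_SEED = 4, 5

if __name__ == "__main__":
    clinical = pd.read_csv(COHORT / "clinical.csv")
    stilc = pd.read_csv(OUT / "stilc_assignments.csv")
    stilc["patient_id"] = stilc.slide_id.str.rsplit("-", n=1).str[0]
    stilc["stilc_code"] = (stilc.stilc == "sTILC2").astype(int) + 1
    clinical = clinical.drop(columns="stilc").merge(
        stilc[["patient_id", "stilc_code"]].rename(columns={"stilc_code": "stilc"}),
        on="patient_id")

    train, val = split_cohort(clinical, seed=SPLIT_SEED)
    m1 = train_model(train, FEATURES_M1, seed=MODEL_SEED)
    m2 = train_model(train, FEATURES_M2, seed=MODEL_SEED)
    print(f"M1 hyperparameters: {m1.best_params} (CV AUC {m1.cv_auc:.3f})")
    print(f"M2 hyperparameters: {m2.best_params} (CV AUC {m2.cv_auc:.3f})")

    report = compare_models(m1, m2, {"training": train, "validation": val},
                            max_shapley_records=100, seed=MODEL_SEED)
    print(report.metrics.round(3).to_string(index=False))
    print("mean |Shapley| per feature:",
          {k: round(v, 4) for k, v in report.shapley_mean_abs.items()})

    with open(OUT / "model_report.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
    report.shapley_values.to_csv(OUT / "shapley_values.csv", index=False)

    fig, ax = plt.subplots(figsize=(5, 4))
    dca = report.net_benefit["validation"]
    ax.plot(dca.threshold, dca.nb_model, label="M1 (TIL features)")
    ax.plot(dca.threshold, dca.nb_m2, label="M2 (clinical only)")
    ax.plot(dca.threshold, dca.nb_all, ":", label="treat all")
    ax.axhline(0, color="k", lw=0.8, label="treat none")
    ax.set_xlabel("threshold probability")
    ax.set_ylabel("net benefit")
    ax.set_ylim(-0.1, 0.5)
    ax.legend()
    fig.tight_layout()
    (OUT / "figures").mkdir(parents=True, exist_ok=True)
    fig.savefig(OUT / "figures" / "decision_curves.png", dpi=150)

    # ablation: replace the sTILC label by PCA components
    pcs = pd.read_csv(OUT / "pca_components.csv")
    pcs["patient_id"] = pcs.slide_id.str.rsplit("-", n=1).str[0]
    pc_cols = [c for c in pcs.columns if c.startswith("pc")]
    merged = {nm: df.merge(pcs[["patient_id"] + pc_cols], on="patient_id")
              for nm, df in (("training", train), ("validation", val))}
    ablation = run_ablation_scenarios(
        merged["training"].drop(columns=pc_cols),
        merged["validation"].drop(columns=pc_cols), None,
        {"training": merged["training"][pc_cols],
         "validation": merged["validation"][pc_cols]},
        seed=MODEL_SEED)
    ablation.to_csv(OUT / "ablation_aucs.csv", index=False)
    print(ablation.round(3).to_string(index=False))
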