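"""Simulate the study cohort: TIL lattices plus clinical and truth tables.

Generates a 200-patient synthetic cohort under the default two-archetype,
logistic-outcome model and writes the patch table, clinical table and truth
table under results/cohort/. Downstream scripts start from these files.
"""

from pathlib import Path

from stilmap.simulate import CohortSpec, generate_cohort, write_cohort

OUTDIR = Path("results/cohort")
SEED = 20250923

if __name__ == "__main__":
    spec = CohortSpec(n_patients=200, seed=SEED)
    cohort = generate_cohort(spec)
    paths = write_cohort(cohort, OUTDIR)
    prev = cohort.clinical.lnm.mean()
    n_cold = (cohort.truth.archetype == "cold").sum()
    print(f"simulated {spec.n_patients} patients "
          f"({n_cold} cold / {spec.n_patients - n_cold} hot archetype)")
    print(f"LNM prevalence: {prev:.3f}")
    for name, p in paths.items():
        print(f"  {name}: {p}")
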