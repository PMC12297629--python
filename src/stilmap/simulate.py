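"""Synthetic TIL lattices and clinical cohorts with known ground truth.

Real inputs to the pipeline are per-patch TIL labels from classified whole
slide images plus clinical covariates; neither is redistributable, so this
module generates cohorts that exercise every stage with known truth:

* a connected blob-shaped tissue mask (union of randomly grown discs);
* a spatially autocorrelated binary TIL-positive field on the mask, built by
  thresholding separably smoothed noise at the quantile that yields a target
  positive fraction — density (target fraction) and clumpiness (correlation
  length) are controlled independently;
* two archetypes mirroring the observed dichotomy: "cold" slides with sparse,
  weakly clustered infiltrate and "hot" slides with dense, strongly clustered
  infiltrate; a small fraction of tissue patches is relabeled necrotic/other
  uniformly at random;
* a patient cohort whose lymph-node-metastasis outcome follows a logistic
  model in T stage, age category, TIL score, and the cold-archetype
  indicator, with protective TIL effects (negative coefficient on the TIL
  score) so model comparison has a known direction of truth.

Everything is deterministic per seed (independent child streams are spawned
per patient from the cohort seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

from .lattice import PatchGrid, PatchLabel, compute_til_score

__all__ = [
    "ArchetypeSpec",
    "CohortSpec",
    "SimulatedCohort",
    "COLD",
    "HOT",
    "generate_tissue_mask",
    "generate_til_lattice",
    "generate_cohort",
    "write_cohort",
]


@dataclass(frozen=True)
class ArchetypeSpec:
    """One spatial TIL archetype: density, clumpiness, necrosis, mask fill."""

    name: str
    target_pos_fraction: float
    correlation_length: int
    necrotic_rate: float = 0.05
    mask_fill: float = 0.6

    def __post_init__(self) -> None:
        if not 0 < self.target_pos_fraction < 1:
            raise ValueError("target_pos_fraction must lie in (0, 1)")
        if self.correlation_length < 1:
            raise ValueError("correlation_length must be >= 1 patch")
        if not 0 <= self.necrotic_rate < 1:
            raise ValueError("necrotic_rate must lie in [0, 1)")


#: sparse, weakly clustered infiltrate ("TIL-cold" ground truth)
COLD = ArchetypeSpec("cold", target_pos_fraction=0.08, correlation_length=2)
#: dense, strongly clustered infiltrate ("TIL-hot" ground truth)
HOT = ArchetypeSpec("hot", target_pos_fraction=0.45, correlation_length=8)


@dataclass(frozen=True)
class CohortSpec:
    """Cohort-level generator settings and the true outcome model.

    The outcome is Bernoulli with
    logit p = b0 + b_t * t_stage + b_age * age_cat + b_til * til_score
              + b_cold * 1[cold archetype],
    so low TIL scores and the cold archetype raise metastasis risk.
    Covariate marginals loosely follow a lung-adenocarcinoma case mix
    (mostly T1/T2, mostly over 45).
    """

    n_patients: int = 500
    archetype_mixture: tuple[float, float] = (0.5, 0.5)  # (cold, hot)
    grid_size: tuple[int, int] = (48, 48)
    b0: float = -1.0
    b_t: float = 0.6
    b_age: float = 0.1
    b_til: float = -3.0
    b_cold: float = 0.7
    age_marginals: tuple[float, ...] = (0.05, 0.47, 0.48)
    t_marginals: tuple[float, ...] = (0.35, 0.45, 0.13, 0.07)
    cold: ArchetypeSpec = COLD
    hot: ArchetypeSpec = HOT
    seed: int = 0

    def __post_init__(self) -> None:
        for name, probs in (("archetype_mixture", self.archetype_mixture),
                            ("age_marginals", self.age_marginals),
                            ("t_marginals", self.t_marginals)):
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortSpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("archetype_mixture", "grid_size", "age_marginals", "t_marginals"):
            if key in raw:
                raw[key] = tuple(raw[key])
        for key in ("cold", "hot"):
            if key in raw:
                raw[key] = ArchetypeSpec(name=key, **raw[key])
        return cls(**raw)


def generate_tissue_mask(
    grid_size: tuple[int, int] = (48, 48),
    mask_fill: float = 0.6,
    seed: int = 0,
) -> np.ndarray:
    """Connected blob-like tissue mask covering roughly ``mask_fill`` of the grid.

    Discs of random radius are grown from points of the current mask starting
    at the grid center, which keeps the union connected; the largest connected
    component is kept (a formality here). Deterministic per seed.
    """
    nr, nc = grid_size
    if nr < 8 or nc < 8:
        raise ValueError("grid must be at least 8x8")
    if not 0 < mask_fill <= 1:
        raise ValueError("mask_fill must lie in (0, 1]")
    if mask_fill >= 0.999:
        return np.ones((nr, nc), dtype=bool)

    rng = np.random.default_rng(seed)
    rr, cc = np.mgrid[0:nr, 0:nc]
    mask = np.zeros((nr, nc), dtype=bool)

    def add_disc(r0: int, c0: int, radius: float) -> None:
        mask[(rr - r0) ** 2 + (cc - c0) ** 2 <= radius**2] = True

    add_disc(nr // 2, nc // 2, max(3, min(nr, nc) // 8))
    target = mask_fill * nr * nc
    for _ in range(10_000):
        if mask.sum() >= target:
            break
        pts = np.flatnonzero(mask)
        p = pts[rng.integers(len(pts))]
        add_disc(p // nc, p % nc, rng.integers(2, 6))

    labeled, n_comp = ndimage.label(mask)
    if n_comp > 1:
        sizes = ndimage.sum_labels(mask, labeled, index=np.arange(1, n_comp + 1))
        mask = labeled == (1 + int(np.argmax(sizes)))
    return mask


def generate_til_lattice(
    mask: np.ndarray,
    archetype: ArchetypeSpec,
    seed: int = 0,
    slide_id: str = "sim-slide",
    patient_id: str = "sim-patient",
) -> PatchGrid:
    """Spatially autocorrelated TIL lattice on a tissue mask.

    Standard-normal noise is smoothed with a separable moving average of
    window ``correlation_length`` (window 1 leaves the field iid) and
    thresholded at the quantile that yields ``target_pos_fraction`` positives
    among tissue patches; ``necrotic_rate`` of the tissue patches is then
    relabeled necrotic/other uniformly at random, leaving the positive
    fraction among the remaining (scoreable) patches at the target in
    expectation.
    """
    mask = np.asarray(mask, dtype=bool)
    n_tissue = int(mask.sum())
    if n_tissue == 0:
        raise ValueError("tissue mask is empty")
    if n_tissue * min(archetype.target_pos_fraction,
                      1 - archetype.target_pos_fraction) < 1:
        raise ValueError("target fraction unreachable: mask too small")

    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(mask.shape)
    if archetype.correlation_length > 1:
        noise = ndimage.uniform_filter(noise, size=archetype.correlation_length,
                                       mode="reflect")
    values = noise[mask]
    threshold = np.quantile(values, 1.0 - archetype.target_pos_fraction)
    pos = values > threshold

    labels = np.where(pos, PatchLabel.TIL_POS, PatchLabel.TIL_NEG).astype(object)
    n_nec = int(round(archetype.necrotic_rate * n_tissue))
    if n_nec:
        nec_idx = rng.choice(n_tissue, size=n_nec, replace=False)
        labels[nec_idx] = PatchLabel.NECROTIC_OTHER

    rows, cols = np.nonzero(mask)
    return PatchGrid(
        slide_id=slide_id, patient_id=patient_id,
        rows=rows, cols=cols, labels=labels,
        n_rows=mask.shape[0], n_cols=mask.shape[1],
    )


@dataclass
class SimulatedCohort:
    """Generator output: patch grids plus clinical and truth tables."""

    grids: list[PatchGrid]
    clinical: pd.DataFrame  # patient_id, age_cat, t_stage, til_score, stilc, lnm
    truth: pd.DataFrame  # patient_id, archetype, linear_predictor, true_til_score
    spec: CohortSpec


def generate_cohort(spec: CohortSpec) -> SimulatedCohort:
    """Generate a full synthetic cohort under the stated outcome model.

    One slide per patient. The clinical table's ``stilc`` column carries the
    ground-truth archetype coding (1 = cold, 2 = hot); pipelines that
    re-derive sTILCs from images overwrite it. Deterministic per seed.
    """
    if spec.n_patients < 20:
        raise ValueError("need at least 20 patients for downstream splits")

    root = np.random.SeedSequence(spec.seed)
    cohort_rng = np.random.default_rng(root.spawn(1)[0])
    patient_seeds = root.spawn(spec.n_patients)

    grids: list[PatchGrid] = []
    clin_rows = []
    truth_rows = []
    for i in range(spec.n_patients):
        pid = f"P{i:04d}"
        ss = patient_seeds[i]
        s_mask, s_field, s_draws = (np.random.default_rng(s) for s in ss.spawn(3))

        is_cold = s_draws.random() < spec.archetype_mixture[0]
        archetype = spec.cold if is_cold else spec.hot
        mask = generate_tissue_mask(spec.grid_size, archetype.mask_fill,
                                    seed=s_mask.integers(2**31))
        grid = generate_til_lattice(mask, archetype, seed=s_field.integers(2**31),
                                    slide_id=f"{pid}-S1", patient_id=pid)
        til = compute_til_score(grid).value

        age = int(s_draws.choice(len(spec.age_marginals), p=spec.age_marginals))
        t = int(s_draws.choice(len(spec.t_marginals), p=spec.t_marginals))
        lp = (spec.b0 + spec.b_t * t + spec.b_age * age
              + spec.b_til * til + spec.b_cold * float(is_cold))
        lnm = int(s_draws.random() < 1.0 / (1.0 + np.exp(-lp)))

        grids.append(grid)
        clin_rows.append({"patient_id": pid, "age_cat": age, "t_stage": t,
                          "til_score": til, "stilc": 1 if is_cold else 2,
                          "lnm": lnm})
        truth_rows.append({"patient_id": pid, "archetype": archetype.name,
                           "linear_predictor": lp, "true_til_score": til})

    return SimulatedCohort(
        grids=grids,
        clinical=pd.DataFrame(clin_rows),
        truth=pd.DataFrame(truth_rows),
        spec=spec,
    )


def write_cohort(cohort: SimulatedCohort, outdir: str | Path) -> dict[str, Path]:
    """Write patch_table.csv, clinical.csv and truth.csv; returns the paths."""
    from .lattice import write_patch_table

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "patch_table": outdir / "patch_table.csv",
        "clinical": outdir / "clinical.csv",
        "truth": outdir / "truth.csv",
    }
    write_patch_table(cohort.grids, paths["patch_table"])
    cohort.clinical.to_csv(paths["clinical"], index=False)
    cohort.truth.to_csv(paths["truth"], index=False)
    return paths
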