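"""Patch-label lattices and TIL scores.

A whole slide image is tiled upstream into non-overlapping 150x150-pixel
patches at 20x magnification, and each tissue patch is classified as
TIL-positive, TIL-negative, or necrotic/other. This module holds the sparse
lattice of those labels (background patches are simply absent) and computes
the slide-level TIL score

    score = n_TIL_pos / (n_TIL_pos + n_TIL_neg),

i.e. the fraction of TIL-positive patches among non-necrotic tissue patches.
A patient with several slides gets the unweighted mean of slide scores.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PatchLabel",
    "PatchGrid",
    "TILScore",
    "read_patch_table",
    "write_patch_table",
    "compute_til_score",
    "aggregate_patient_score",
    "score_table",
]


class PatchLabel(enum.Enum):
    """The three tissue-patch categories; background is absence, not a label."""

    TIL_POS = "TIL_POS"
    TIL_NEG = "TIL_NEG"
    NECROTIC_OTHER = "NECROTIC_OTHER"

    @classmethod
    def parse(cls, raw: str) -> "PatchLabel":
        """Canonicalize a label string (case/whitespace-insensitive).

        Unknown strings are hard errors; nothing is silently coerced.
        """
        key = str(raw).strip().upper()
        try:
            return cls[key]
        except KeyError:
            raise ValueError(f"unknown patch label {raw!r}") from None


@dataclass
class PatchGrid:
    """Sparse masked lattice of per-patch TIL labels for one slide.

    Coordinates are 0-based ``(row, col)``, row-major, origin at the slide's
    top-left tile. Only tissue patches appear; ``n_rows``/``n_cols`` bound the
    lattice (inferred from the data unless declared to preserve margins).
    """

    slide_id: str
    patient_id: str
    rows: np.ndarray
    cols: np.ndarray
    labels: np.ndarray  # array of PatchLabel (object dtype)
    n_rows: int | None = None
    n_cols: int | None = None
    patch_size_px: int = 150
    magnification: str = "20x"

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=np.int64)
        self.cols = np.asarray(self.cols, dtype=np.int64)
        self.labels = np.asarray(self.labels, dtype=object)
        if not (len(self.rows) == len(self.cols) == len(self.labels)):
            raise ValueError("rows, cols and labels must have equal length")
        if len(self.rows) == 0:
            raise ValueError(f"slide {self.slide_id!r}: empty grids are rejected")
        if self.n_rows is None:
            self.n_rows = int(self.rows.max()) + 1
        if self.n_cols is None:
            self.n_cols = int(self.cols.max()) + 1
        if self.rows.min() < 0 or self.cols.min() < 0:
            raise ValueError(f"slide {self.slide_id!r}: negative patch coordinates")
        if self.rows.max() >= self.n_rows or self.cols.max() >= self.n_cols:
            raise ValueError(
                f"slide {self.slide_id!r}: patch coordinates exceed declared "
                f"grid size {self.n_rows}x{self.n_cols}"
            )
        coords = set(zip(self.rows.tolist(), self.cols.tolist()))
        if len(coords) != len(self.rows):
            raise ValueError(f"slide {self.slide_id!r}: duplicate patch coordinates")
        for lab in self.labels:
            if not isinstance(lab, PatchLabel):
                raise TypeError(f"labels must be PatchLabel, got {lab!r}")

    @property
    def n_patches(self) -> int:
        return len(self.rows)

    def label_counts(self) -> dict[PatchLabel, int]:
        counts = {lab: 0 for lab in PatchLabel}
        for lab in self.labels:
            counts[lab] += 1
        return counts

    @classmethod
    def from_patches(
        cls,
        slide_id: str,
        patient_id: str,
        patches: Iterable[tuple[int, int, PatchLabel]],
        **kwargs,
    ) -> "PatchGrid":
        pts = list(patches)
        rows = [p[0] for p in pts]
        cols = [p[1] for p in pts]
        labels = [p[2] for p in pts]
        return cls(slide_id, patient_id, np.array(rows, dtype=np.int64),
                   np.array(cols, dtype=np.int64), np.array(labels, dtype=object),
                   **kwargs)


@dataclass(frozen=True)
class TILScore:
    """A slide-level TIL score with its defining counts."""

    value: float
    n_pos: int
    n_tissue_nonnecrotic: int


def read_patch_table(path: str | Path, grid_sizes: dict[str, tuple[int, int]] | None = None) -> list[PatchGrid]:
    """Read a patch-label CSV into one :class:`PatchGrid` per slide.

    The table must have header columns ``slide_id,patient_id,row,col,label``.
    Labels are canonicalized case-insensitively; an unknown label or duplicate
    coordinate is rejected naming the offending row. ``grid_sizes`` may declare
    ``(n_rows, n_cols)`` per slide_id to preserve empty margins; otherwise
    dimensions are inferred as max coordinate + 1.
    """
    df = pd.read_csv(path, dtype={"slide_id": str, "patient_id": str, "label": str})
    required = ["slide_id", "patient_id", "row", "col", "label"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"patch table {path}: missing columns {missing}")

    labels = np.empty(len(df), dtype=object)
    for i, raw in enumerate(df["label"]):
        try:
            labels[i] = PatchLabel.parse(raw)
        except ValueError as exc:
            # +2: one for the header line, one for 1-based file rows
            raise ValueError(f"patch table {path}, data row {i + 2}: {exc}") from None
    df = df.assign(_label=labels)

    dup = df.duplicated(subset=["slide_id", "row", "col"])
    if dup.any():
        i = int(np.flatnonzero(dup.to_numpy())[0])
        rec = df.iloc[i]
        raise ValueError(
            f"patch table {path}, data row {i + 2}: duplicate patch "
            f"({rec['slide_id']}, {rec['row']}, {rec['col']})"
        )

    grids: list[PatchGrid] = []
    for slide_id, sub in df.groupby("slide_id", sort=True):
        patients = sub["patient_id"].unique()
        if len(patients) > 1:
            raise ValueError(f"slide {slide_id!r} maps to multiple patients: {list(patients)}")
        size = (grid_sizes or {}).get(str(slide_id), (None, None))
        grids.append(
            PatchGrid(
                slide_id=str(slide_id),
                patient_id=str(patients[0]),
                rows=sub["row"].to_numpy(dtype=np.int64),
                cols=sub["col"].to_numpy(dtype=np.int64),
                labels=sub["_label"].to_numpy(dtype=object),
                n_rows=size[0],
                n_cols=size[1],
            )
        )
    return grids


def write_patch_table(grids: Sequence[PatchGrid], path: str | Path) -> None:
    """Write grids to the canonical patch-table CSV (round-trips with read)."""
    frames = []
    for g in grids:
        frames.append(
            pd.DataFrame(
                {
                    "slide_id": g.slide_id,
                    "patient_id": g.patient_id,
                    "row": g.rows,
                    "col": g.cols,
                    "label": [lab.value for lab in g.labels],
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def compute_til_score(grid: PatchGrid) -> TILScore:
    """TIL-positive fraction among non-necrotic tissue patches of one slide."""
    counts = grid.label_counts()
    n_pos = counts[PatchLabel.TIL_POS]
    n_tissue = n_pos + counts[PatchLabel.TIL_NEG]
    if n_tissue == 0:
        raise ValueError(f"slide {grid.slide_id!r}: no scoreable tissue "
                         "(only necrotic/other patches present)")
    return TILScore(value=n_pos / n_tissue, n_pos=n_pos, n_tissue_nonnecrotic=n_tissue)


def aggregate_patient_score(scores: Sequence[TILScore | float]) -> float:
    """Patient-level TIL score: unweighted mean over that patient's slides."""
    if len(scores) == 0:
        raise ValueError("cannot aggregate an empty list of slide scores")
    vals = [s.value if isinstance(s, TILScore) else float(s) for s in scores]
    return float(np.mean(vals))


def score_table(grids: Sequence[PatchGrid]) -> pd.DataFrame:
    """Per-slide score table: ``patient_id,slide_id,til_score,n_pos,n_tissue``."""
    recs = []
    for g in grids:
        s = compute_til_score(g)
        recs.append(
            {
                "patient_id": g.patient_id,
                "slide_id": g.slide_id,
                "til_score": s.value,
                "n_pos": s.n_pos,
                "n_tissue": s.n_tissue_nonnecrotic,
            }
        )
    return pd.DataFrame.from_records(recs)
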