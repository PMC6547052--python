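"""Subject data I/O, feature-matrix assembly, and kernel-family groupings.

A study dataset is a subjects × features matrix assembled by concatenating
blocks from heterogeneous sources: one block per image modality (in-mask
voxel intensities read from NIfTI volumes) and one block of clinical /
demographic variables read from a delimited table.  Each block keeps its
provenance in a :class:`FeatureSource`, which is what lets downstream code
partition the columns into base-kernel families.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "FeatureSource",
    "LabeledDataset",
    "KernelGrouping",
    "FAMILY_CODES",
    "load_masked_volumes",
    "load_clinical_table",
    "assemble_dataset",
    "build_grouping",
    "subset_features",
    "write_weight_volume",
    "load_study_dir",
]

#: Recognized kernel-family codes.
#:
#: I      one kernel over all image columns;
#: C      one kernel over all clinical columns;
#: I_plus_C                 a single kernel over every column (concatenation);
#: images_and_clinical_block  one kernel per image plus one kernel holding
#:                            the whole clinical block;
#: images_and_clinical      one kernel per image plus one singleton kernel
#:                          per clinical feature;
#: V      one singleton kernel per voxel column;
#: V_and_C  one singleton kernel per voxel column plus one per clinical
#:          feature — the fully fragmented family the feature-selection
#:          method is designed for.
FAMILY_CODES = (
    "I",
    "C",
    "I_plus_C",
    "images_and_clinical_block",
    "images_and_clinical",
    "V",
    "V_and_C",
)


@dataclass
class FeatureSource:
    """Provenance of a contiguous block of columns in the assembled matrix.

    Parameters
    ----------
    name : str
        Short identifier (e.g. ``"smri"`` or ``"clinical"``).
    modality : {"image", "clinical"}
    column_span : tuple of int
        Half-open ``(start, stop)`` range of columns in the assembled matrix.
    image_index : int
        Ordinal of the image this block came from (image sources only).
    voxel_coords : ndarray of shape (span, 3), optional
        ``(i, j, k)`` voxel index of each column (image sources only).
    column_names : list of str, optional
        Per-column names (clinical sources).
    """

    name: str
    modality: str
    column_span: tuple[int, int]
    image_index: int = 0
    voxel_coords: np.ndarray | None = None
    column_names: list[str] | None = None

    def __post_init__(self) -> None:
        if self.modality not in ("image", "clinical"):
            raise ValueError(f"unknown modality {self.modality!r}")
        start, stop = self.column_span
        if stop <= start:
            raise ValueError("empty column span")
        if self.voxel_coords is not None and len(self.voxel_coords) != stop - start:
            raise ValueError("voxel_coords length must equal span length")

    @property
    def n_columns(self) -> int:
        return self.column_span[1] - self.column_span[0]

    @property
    def columns(self) -> np.ndarray:
        return np.arange(*self.column_span)


@dataclass
class LabeledDataset:
    """Subjects × features matrix with labels, provenance and optional age.

    Labels are stored as ±1; ``{0, 1}`` input is recoded (0 → −1) on
    assembly.
    """

    X: np.ndarray
    y: np.ndarray
    sources: list[FeatureSource]
    subject_ids: list[str]
    age: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        if len(self.y) != self.X.shape[0]:
            raise ValueError("y length must match number of rows of X")
        if len(self.subject_ids) != self.X.shape[0]:
            raise ValueError("subject_ids length must match number of rows")
        total_span = sum(s.n_columns for s in self.sources)
        if total_span != self.X.shape[1]:
            raise ValueError(
                f"source spans cover {total_span} columns, X has {self.X.shape[1]}"
            )
        if not np.isfinite(self.X).all():
            raise ValueError("X contains non-finite values")
        self.y = _coerce_labels(self.y)
        if self.age is not None:
            self.age = np.asarray(self.age, dtype=float)
            if len(self.age) != self.X.shape[0]:
                raise ValueError("age length must match number of rows")

    @property
    def n_subjects(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def image_sources(self) -> list[FeatureSource]:
        return [s for s in self.sources if s.modality == "image"]

    def clinical_sources(self) -> list[FeatureSource]:
        return [s for s in self.sources if s.modality == "clinical"]


@dataclass
class KernelGrouping:
    """Partition of feature columns into base-kernel groups.

    ``groups[r]`` lists the column indices feeding base kernel ``r``; the
    number of groups ``R`` is the size of the kernel family.
    """

    family_code: str
    groups: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.family_code not in FAMILY_CODES:
            raise ValueError(f"unknown family code {self.family_code!r}")
        self.groups = [np.asarray(g, dtype=np.intp) for g in self.groups]
        if not self.groups:
            raise ValueError("grouping must contain at least one group")
        sizes = np.array([g.size for g in self.groups])
        if (sizes == 0).any():
            raise ValueError(f"group {int(np.flatnonzero(sizes == 0)[0])} is empty")
        # vectorized disjointness check: fast even for ~10^6 singleton groups
        allcols = np.concatenate(self.groups)
        if np.unique(allcols).size != allcols.size:
            raise ValueError("groups must be disjoint")

    @property
    def R(self) -> int:
        """Number of base kernels in the family."""
        return len(self.groups)

    def column_group_ids(self, m: int) -> np.ndarray:
        """Map each of ``m`` columns to its group id (−1 if ungrouped)."""
        ids = np.full(m, -1, dtype=np.intp)
        sizes = np.array([g.size for g in self.groups])
        ids[np.concatenate(self.groups)] = np.repeat(
            np.arange(len(self.groups)), sizes
        )
        return ids


def _coerce_labels(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y)
    vals = set(np.unique(y).tolist())
    if vals <= {0, 1}:
        return np.where(y == 1, 1, -1).astype(int)
    if vals <= {-1, 1}:
        return y.astype(int)
    raise ValueError(f"labels must be coded {{0,1}} or {{-1,+1}}, got {sorted(vals)}")


# ---------------------------------------------------------------------------
# NIfTI volumes


def _mask_order(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """In-mask voxel coordinates in the fixed raster order.

    Order is ascending (z, y, x): the slowest-varying key is the third
    (slice) axis, then the second, then the first.  Returns ``(coords,
    flat)`` where ``coords`` is (n, 3) int ``(i, j, k)`` and ``flat`` the
    matching flat indices into the volume array.
    """
    coords = np.argwhere(mask != 0)
    order = np.lexsort((coords[:, 0], coords[:, 1], coords[:, 2]))
    coords = coords[order]
    flat = np.ravel_multi_index((coords[:, 0], coords[:, 1], coords[:, 2]), mask.shape)
    return coords, flat


def load_masked_volumes(
    volume_paths: Sequence[str | Path],
    mask_path: str | Path,
    *,
    name: str = "image",
    image_index: int = 0,
) -> tuple[np.ndarray, FeatureSource]:
    """Read one 3-D volume per subject and extract in-mask voxels.

    Voxels are ordered by the fixed raster order: ascending (z, y, x)
    index of the in-mask voxels.  The returned source records each
    column's voxel coordinate so weight maps can be written back out.

    Returns
    -------
    block : ndarray, shape (n_subjects, n_in_mask_voxels)
    source : FeatureSource
    """
    mask_img = nib.load(str(mask_path))
    mask = np.asarray(mask_img.dataobj)
    if mask.ndim != 3:
        raise ValueError("mask must be a 3-D volume")
    coords, flat = _mask_order(mask)
    if coords.shape[0] == 0:
        raise ValueError("mask selects no voxels")

    rows = []
    for p in volume_paths:
        img = nib.load(str(p))
        data = np.asarray(img.dataobj, dtype=float)
        if data.shape != mask.shape:
            raise ValueError(
                f"volume {p} has shape {data.shape}, mask has {mask.shape}"
            )
        rows.append(data.reshape(-1)[flat])
    block = np.vstack(rows)
    source = FeatureSource(
        name=name,
        modality="image",
        column_span=(0, block.shape[1]),
        image_index=image_index,
        voxel_coords=coords,
    )
    return block, source


def write_weight_volume(
    weights: np.ndarray,
    source: FeatureSource,
    mask_path: str | Path,
    out_path: str | Path,
) -> None:
    """Write a per-voxel weight vector back into mask space as NIfTI.

    Out-of-mask voxels are zero; in-mask voxels receive ``weights`` in the
    same raster order used by :func:`load_masked_volumes`, so a
    load → write → load round trip is the identity.
    """
    weights = np.asarray(weights, dtype=float)
    if source.voxel_coords is None:
        raise ValueError("source has no voxel coordinates")
    if weights.shape != (source.n_columns,):
        raise ValueError(
            f"expected {source.n_columns} weights, got {weights.shape}"
        )
    mask_img = nib.load(str(mask_path))
    vol = np.zeros(mask_img.shape, dtype=float)
    c = source.voxel_coords
    vol[c[:, 0], c[:, 1], c[:, 2]] = weights
    nib.save(nib.Nifti1Image(vol, mask_img.affine), str(out_path))


# ---------------------------------------------------------------------------
# Clinical tables


def load_clinical_table(
    path: str | Path,
    *,
    id_column: str | None = None,
    subject_ids: Sequence[str] | None = None,
    impute_missing: bool = False,
    name: str = "clinical",
) -> tuple[np.ndarray, FeatureSource, list[str] | None]:
    """Read a delimited clinical/demographic table (header row required).

    Parameters
    ----------
    id_column : str, optional
        Column holding subject identifiers.  When given, rows are aligned
        to ``subject_ids`` (if also given) rather than taken in file order.
    impute_missing : bool
        Replace missing cells by the column mean.  By default missing
        cells are an error; when imputation is used inside cross-validation
        the caller must restrict the table to training rows first.

    Returns
    -------
    block : ndarray (n_subjects, n_features)
    source : FeatureSource with ``column_names`` set
    ids : list of str or None
        Subject ids in row order, when ``id_column`` was given.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"{path}: table is empty")

    ids: list[str] | None = None
    if id_column is not None:
        if id_column not in df.columns:
            raise ValueError(f"{path}: no column named {id_column!r}")
        ids = df[id_column].astype(str).tolist()
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"{path}: duplicated subject ids {dupes}")
        df = df.drop(columns=[id_column])
        if subject_ids is not None:
            lookup = {s: i for i, s in enumerate(ids)}
            missing = [s for s in subject_ids if s not in lookup]
            if missing:
                raise ValueError(f"{path}: subjects not in table: {missing}")
            df = df.iloc[[lookup[s] for s in subject_ids]].reset_index(drop=True)
            ids = list(subject_ids)
    if df.shape[1] == 0:
        raise ValueError(f"{path}: table has no feature columns")

    values = np.full(df.shape, np.nan)
    for j, col in enumerate(df.columns):
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"{path}: non-numeric value {df[col].iloc[row]!r} "
                f"in row {row}, column {col!r}"
            )
        values[:, j] = parsed.to_numpy(dtype=float)

    nan_cells = np.argwhere(np.isnan(values))
    if nan_cells.size:
        if impute_missing:
            col_means = np.nanmean(values, axis=0)
            if np.isnan(col_means).any():
                empty = [df.columns[j] for j in np.flatnonzero(np.isnan(col_means))]
                raise ValueError(f"{path}: columns entirely missing: {empty}")
            idx = np.isnan(values)
            values[idx] = np.take(col_means, np.nonzero(idx)[1])
        else:
            cells = [
                f"(row {i}, column {df.columns[j]!r})" for i, j in nan_cells[:10]
            ]
            raise ValueError(f"{path}: missing cells at {', '.join(cells)}")

    source = FeatureSource(
        name=name,
        modality="clinical",
        column_span=(0, values.shape[1]),
        column_names=[str(c) for c in df.columns],
    )
    return values, source, ids


# ---------------------------------------------------------------------------
# Assembly and grouping


def assemble_dataset(
    blocks: Sequence[tuple[np.ndarray, FeatureSource]],
    y: Sequence[int],
    subject_ids: Sequence[str] | None = None,
    age: Sequence[float] | None = None,
) -> LabeledDataset:
    """Concatenate source blocks (in declared order) into a LabeledDataset.

    Column spans of the sources are recomputed so that they tile the
    assembled matrix; assembly is order-stable, i.e. the same blocks in the
    same order always yield the same column indices.
    """
    if not blocks:
        raise ValueError("no blocks to assemble")
    n = blocks[0][0].shape[0]
    mats, sources = [], []
    offset = 0
    for block, src in blocks:
        block = np.asarray(block, dtype=float)
        if block.shape[0] != n:
            raise ValueError("all blocks must have the same number of rows")
        width = block.shape[1]
        sources.append(
            FeatureSource(
                name=src.name,
                modality=src.modality,
                column_span=(offset, offset + width),
                image_index=src.image_index,
                voxel_coords=src.voxel_coords,
                column_names=src.column_names,
            )
        )
        mats.append(block)
        offset += width
    if subject_ids is None:
        subject_ids = [f"sub-{i:04d}" for i in range(n)]
    return LabeledDataset(
        X=np.hstack(mats),
        y=np.asarray(y),
        sources=sources,
        subject_ids=list(subject_ids),
        age=None if age is None else np.asarray(age, dtype=float),
    )


def build_grouping(dataset: LabeledDataset, family_code: str) -> KernelGrouping:
    """Partition the dataset's columns into one of the base-kernel families.

    See :data:`FAMILY_CODES` for the seven family definitions.  For the
    fully fragmented families (``V``, ``V_and_C``) the number of base
    kernels R equals the number of voxel (plus clinical) columns.
    """
    if family_code not in FAMILY_CODES:
        raise ValueError(f"unknown family code {family_code!r}")
    imgs = dataset.image_sources()
    clins = dataset.clinical_sources()
    needs_image = family_code in (
        "I", "I_plus_C", "images_and_clinical_block", "images_and_clinical",
        "V", "V_and_C",
    )
    needs_clinical = family_code in (
        "C", "I_plus_C", "images_and_clinical_block", "images_and_clinical",
        "V_and_C",
    )
    if needs_image and not imgs:
        raise ValueError(f"family {family_code!r} requires an image source")
    if needs_clinical and not clins:
        raise ValueError(f"family {family_code!r} requires a clinical source")

    img_cols = [s.columns for s in imgs]
    clin_cols = [s.columns for s in clins]
    all_img = np.concatenate(img_cols) if img_cols else np.empty(0, dtype=np.intp)
    all_clin = np.concatenate(clin_cols) if clin_cols else np.empty(0, dtype=np.intp)

    groups: list[np.ndarray]
    if family_code == "I":
        groups = [all_img]
    elif family_code == "C":
        groups = [all_clin]
    elif family_code == "I_plus_C":
        groups = [np.concatenate([all_img, all_clin])]
    elif family_code == "images_and_clinical_block":
        groups = list(img_cols) + [all_clin]
    elif family_code == "images_and_clinical":
        groups = list(img_cols) + _singletons(all_clin)
    elif family_code == "V":
        groups = _singletons(all_img)
    else:  # V_and_C
        groups = _singletons(all_img) + _singletons(all_clin)
    return KernelGrouping(family_code=family_code, groups=groups)


def load_study_dir(path: str | Path) -> LabeledDataset:
    """Load a study from a directory.

    Expected layout: ``labels.csv`` (columns subject_id, label and
    optionally age), ``mask.nii``, one ``<subject_id>_image<k>.nii`` per
    subject per image index k, and optionally ``clinical.csv`` (column
    subject_id plus numeric features).  Images are assembled first (in
    image-index order), then the clinical block.
    """
    path = Path(path)
    labels = pd.read_csv(path / "labels.csv")
    subject_ids = labels["subject_id"].astype(str).tolist()
    y = labels["label"].to_numpy()
    age = labels["age"].to_numpy(dtype=float) if "age" in labels.columns else None

    blocks: list[tuple[np.ndarray, FeatureSource]] = []
    mask_path = path / "mask.nii"
    if mask_path.exists():
        img_idx = 0
        while (path / f"{subject_ids[0]}_image{img_idx}.nii").exists():
            vols = [path / f"{s}_image{img_idx}.nii" for s in subject_ids]
            missing = [str(v) for v in vols if not v.exists()]
            if missing:
                raise ValueError(f"missing volumes: {missing[:5]}")
            block, src = load_masked_volumes(
                vols, mask_path, name=f"image{img_idx}", image_index=img_idx
            )
            blocks.append((block, src))
            img_idx += 1

    clin_path = path / "clinical.csv"
    if clin_path.exists():
        block, src, _ = load_clinical_table(
            clin_path, id_column="subject_id", subject_ids=subject_ids
        )
        blocks.append((block, src))
    if not blocks:
        raise ValueError(f"{path}: no image volumes or clinical table found")
    return assemble_dataset(blocks, y, subject_ids=subject_ids, age=age)


def _singletons(cols: np.ndarray) -> list[np.ndarray]:
    # list of length-1 views; much faster than np.array([c]) per column
    return list(np.asarray(cols, dtype=np.intp).reshape(-1, 1))


def subset_features(dataset: LabeledDataset, keep: np.ndarray) -> LabeledDataset:
    """Restrict a dataset to a subset of feature columns.

    ``keep`` is a sorted array of column indices; sources are narrowed (and
    dropped when no column survives).  Used by the strict in-fold mode of
    the clinical pre-filter.
    """
    keep = np.asarray(keep, dtype=np.intp)
    blocks = []
    for src in dataset.sources:
        lo, hi = src.column_span
        local = keep[(keep >= lo) & (keep < hi)] - lo
        if local.size == 0:
            continue
        blocks.append(
            (
                dataset.X[:, local + lo],
                FeatureSource(
                    name=src.name,
                    modality=src.modality,
                    column_span=(0, local.size),
                    image_index=src.image_index,
                    voxel_coords=None
                    if src.voxel_coords is None
                    else src.voxel_coords[local],
                    column_names=None
                    if src.column_names is None
                    else [src.column_names[i] for i in local],
                ),
            )
        )
    return assemble_dataset(
        blocks, dataset.y, subject_ids=dataset.subject_ids, age=dataset.age
    )
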