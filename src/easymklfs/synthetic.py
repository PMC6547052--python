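"""Synthetic multimodal datasets emulating small-sample neuroimaging studies.

The generator produces, for two diagnostic groups, one or more 3-D
"brain" images per subject (standard-Gaussian background voxels with a
sparse regional class signal planted in spherical blobs), a block of
clinical/demographic features of which a few carry signal, an age
covariate, and a controllable label-noise rate emulating unreliable
psychiatric diagnoses.  It covers the data shapes of both study designs
being emulated: a single structural image per subject, or four
task-contrast images per subject.

Everything is reproducible from the seed, and the ground-truth signal
locations are returned so that feature-selection quality can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_data import FeatureSource, LabeledDataset, assemble_dataset
from .maps import AtlasLabels

__all__ = ["SimulationSpec", "SyntheticData", "generate", "truth_overlap"]


@dataclass
class SimulationSpec:
    """Parameters of the synthetic study.

    ``effect_size`` is the standardized mean difference d between classes
    at signal voxels (class means sit at ±d/2 with unit noise);
    ``label_noise_rate`` flips exactly round(rate·ℓ) labels after the
    signal is planted.  ``n_signal_voxels``, when set, fixes the exact
    number of planted voxels per image by growing each blob in
    nearest-voxel order; otherwise a blob is all voxels within
    ``blob_radius`` of its center.
    """

    n_per_class: int = 50
    grid_dims: tuple[int, int, int] = (12, 12, 12)
    n_images: int = 1
    n_signal_blobs: int = 2
    blob_radius: float = 1.5
    n_signal_voxels: int | None = None
    effect_size: float = 1.5
    n_clinical: int = 20
    n_informative_clinical: int = 3
    clinical_effect_size: float = 1.5
    label_noise_rate: float = 0.0
    age_mean: float = 65.0
    age_sd: float = 8.0
    age_confound: float = 0.0   # years added to the +1 class mean age
    ellipsoid_mask: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_per_class, self.n_images, self.n_clinical) < 0:
            raise ValueError("counts must be nonnegative")
        if not 0.0 <= self.label_noise_rate < 0.5:
            raise ValueError("label_noise_rate must lie in [0, 0.5)")
        if self.n_informative_clinical > self.n_clinical:
            raise ValueError("informative clinical features exceed total")


@dataclass
class SyntheticData:
    """Generated dataset with its ground truth."""

    dataset: LabeledDataset
    signal_columns: np.ndarray          # columns of X carrying image signal
    informative_clinical_columns: np.ndarray
    atlas: AtlasLabels                  # per voxel column of one image
    mask: np.ndarray                    # 3-D binary mask
    voxel_coords: np.ndarray            # (n_voxels, 3) raster-ordered
    true_labels: np.ndarray             # labels before noise flips
    spec: SimulationSpec = field(repr=False, default=None)


def _mask_and_coords(spec: SimulationSpec) -> tuple[np.ndarray, np.ndarray]:
    dims = spec.grid_dims
    if spec.ellipsoid_mask:
        c = (np.array(dims) - 1) / 2.0
        i, j, k = np.indices(dims)
        mask = (
            ((i - c[0]) / (dims[0] / 2.0)) ** 2
            + ((j - c[1]) / (dims[1] / 2.0)) ** 2
            + ((k - c[2]) / (dims[2] / 2.0)) ** 2
        ) <= 1.0
    else:
        mask = np.ones(dims, dtype=bool)
    coords = np.argwhere(mask)
    order = np.lexsort((coords[:, 0], coords[:, 1], coords[:, 2]))
    return mask, coords[order]


def _plant_blobs(
    spec: SimulationSpec, coords: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Choose signal voxels (as indices into the raster-ordered columns).

    Returns (signal_voxel_indices, per-voxel blob id, 0 = background).
    """
    dims = np.array(spec.grid_dims)
    n_vox = coords.shape[0]
    blob_of = np.zeros(n_vox, dtype=int)
    if spec.n_signal_blobs == 0:
        return np.empty(0, dtype=np.intp), blob_of
    margin = int(np.ceil(spec.blob_radius))
    if np.any(dims <= 2 * margin):
        raise ValueError("signal blobs do not fit in the grid")
    per_blob = None
    if spec.n_signal_voxels is not None:
        base, extra = divmod(spec.n_signal_voxels, spec.n_signal_blobs)
        per_blob = [base + (b < extra) for b in range(spec.n_signal_blobs)]
    taken = np.zeros(n_vox, dtype=bool)
    for b in range(spec.n_signal_blobs):
        center = np.array(
            [rng.integers(margin, d - margin) for d in dims], dtype=float
        )
        dist = np.linalg.norm(coords - center, axis=1)
        if per_blob is None:
            members = np.flatnonzero((dist <= spec.blob_radius) & ~taken)
        else:
            # nearest-voxel growth to an exact count (ties by raster order)
            order = np.lexsort((np.arange(n_vox), dist))
            order = order[~taken[order]]
            members = order[: per_blob[b]]
        blob_of[members] = b + 1
        taken[members] = True
    return np.flatnonzero(blob_of > 0), blob_of


def _background_atlas(coords: np.ndarray, dims: tuple[int, int, int],
                      blob_of: np.ndarray, n_blobs: int) -> AtlasLabels:
    """Blobs get their own region id; background voxels are split by octant."""
    half = np.array(dims) / 2.0
    octant = (
        (coords[:, 0] >= half[0]).astype(int)
        + 2 * (coords[:, 1] >= half[1]).astype(int)
        + 4 * (coords[:, 2] >= half[2]).astype(int)
    )
    labels = n_blobs + 1 + octant
    labels[blob_of > 0] = blob_of[blob_of > 0]
    names = {b: f"Signal-{b}" for b in range(1, n_blobs + 1)}
    names.update(
        {n_blobs + 1 + o: f"Background-O{o}" for o in range(8)}
    )
    return AtlasLabels(labels=labels, region_names=names)


def generate(spec: SimulationSpec, out_dir: str | Path | None = None) -> SyntheticData:
    """Draw one synthetic study; byte-identical for identical specs.

    When ``out_dir`` is given, volumes, mask, atlas, clinical table and
    labels are also written to disk in the formats the I/O layer reads
    (NIfTI + CSV).
    """
    rng = np.random.default_rng(spec.seed)
    mask, coords = _mask_and_coords(spec)
    n_vox = coords.shape[0]
    n = 2 * spec.n_per_class
    y_true = np.concatenate(
        [np.ones(spec.n_per_class, dtype=int), -np.ones(spec.n_per_class, dtype=int)]
    )

    signal_vox, blob_of = _plant_blobs(spec, coords, rng)
    shift = spec.effect_size / 2.0

    blocks: list[tuple[np.ndarray, FeatureSource]] = []
    signal_cols: list[np.ndarray] = []
    offset = 0
    image_blocks = []
    for img in range(spec.n_images):
        block = rng.standard_normal((n, n_vox))
        block[:, signal_vox] += np.outer(y_true, np.full(signal_vox.size, shift))
        image_blocks.append(block)
        src = FeatureSource(
            name=f"image{img}",
            modality="image",
            column_span=(0, n_vox),
            image_index=img,
            voxel_coords=coords,
        )
        blocks.append((block, src))
        signal_cols.append(signal_vox + offset)
        offset += n_vox

    clin = rng.standard_normal((n, spec.n_clinical))
    info = np.arange(spec.n_informative_clinical)
    clin[:, info] += np.outer(
        y_true, np.full(info.size, spec.clinical_effect_size / 2.0)
    )
    if spec.n_clinical > 0:
        blocks.append(
            (
                clin,
                FeatureSource(
                    name="clinical",
                    modality="clinical",
                    column_span=(0, spec.n_clinical),
                    column_names=[f"clin{i:02d}" for i in range(spec.n_clinical)],
                ),
            )
        )

    y = y_true.copy()
    n_flip = round(spec.label_noise_rate * n)
    flip = rng.choice(n, size=n_flip, replace=False)
    y[flip] *= -1

    age = rng.normal(spec.age_mean, spec.age_sd, size=n)
    age += np.where(y_true > 0, spec.age_confound, 0.0)

    dataset = assemble_dataset(blocks, y, age=age)
    atlas = _background_atlas(coords, spec.grid_dims, blob_of, spec.n_signal_blobs)
    data = SyntheticData(
        dataset=dataset,
        signal_columns=np.concatenate(signal_cols)
        if signal_cols
        else np.empty(0, dtype=np.intp),
        informative_clinical_columns=offset + info,
        atlas=atlas,
        mask=mask,
        voxel_coords=coords,
        true_labels=y_true,
        spec=spec,
    )
    if out_dir is not None:
        _write_to_disk(data, image_blocks, clin, Path(out_dir))
    return data


def _write_to_disk(data: SyntheticData, image_blocks, clin, out_dir: Path) -> None:
    import nibabel as nib
    import pandas as pd

    out_dir.mkdir(parents=True, exist_ok=True)
    spec = data.spec
    affine = np.eye(4)
    nib.save(
        nib.Nifti1Image(data.mask.astype(np.uint8), affine), out_dir / "mask.nii"
    )
    atlas_vol = np.zeros(spec.grid_dims, dtype=np.int16)
    c = data.voxel_coords
    atlas_vol[c[:, 0], c[:, 1], c[:, 2]] = data.atlas.labels
    nib.save(nib.Nifti1Image(atlas_vol, affine), out_dir / "atlas.nii")
    pd.DataFrame(
        {"region_id": list(data.atlas.region_names),
         "region": list(data.atlas.region_names.values())}
    ).to_csv(out_dir / "atlas_labels.csv", index=False)

    ds = data.dataset
    for img, block in enumerate(image_blocks):
        for s in range(ds.n_subjects):
            vol = np.zeros(spec.grid_dims)
            vol[c[:, 0], c[:, 1], c[:, 2]] = block[s]
            nib.save(
                nib.Nifti1Image(vol, affine),
                out_dir / f"{ds.subject_ids[s]}_image{img}.nii",
            )
    clin_df = pd.DataFrame(
        clin, columns=[f"clin{i:02d}" for i in range(clin.shape[1])]
    )
    clin_df.insert(0, "subject_id", ds.subject_ids)
    clin_df.to_csv(out_dir / "clinical.csv", index=False)
    pd.DataFrame(
        {"subject_id": ds.subject_ids, "label": ds.y, "age": ds.age}
    ).to_csv(out_dir / "labels.csv", index=False)


def truth_overlap(
    selected: np.ndarray, truth: np.ndarray
) -> tuple[float, float]:
    """Set precision and recall of a selected feature set against the truth."""
    selected = set(np.asarray(selected, dtype=int).tolist())
    truth = set(np.asarray(truth, dtype=int).tolist())
    hits = len(selected & truth)
    precision = hits / len(selected) if selected else 0.0
    recall = hits / len(truth) if truth else 0.0
    return precision, recall
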