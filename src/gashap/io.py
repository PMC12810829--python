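"""Domain containers and NIfTI / tabular I/O.

The unit of analysis is a single-channel 3D scalar volume (an ``80**3``
skull-stripped MRI crop at full scale, a small synthetic phantom at desk
scale) together with an integer-labelled parcellation atlas that names each
anatomical region.  Everything downstream — attribution, region scoring,
mask morphology, the genetic algorithm — operates on these two grids, so
this module pins down the conventions once:

* voxel indices are 0-based; volumes and atlases are aligned purely by
  having the same grid shape (no resampling is attempted);
* atlas background is label 0, region IDs are strictly positive and are
  re-indexed internally to ``1..R`` (original IDs are kept for reporting);
* normalized volumes have zero mean and unit variance.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "Volume",
    "LabelAtlas",
    "LabeledDataset",
    "FormatError",
    "read_volume",
    "write_volume",
    "normalize",
    "read_atlas",
    "write_atlas",
    "split_dataset",
    "read_manifest",
    "write_manifest",
]

SPLITS = ("train", "val", "test")


class FormatError(ValueError):
    """An input file violates the expected on-disk format."""


@dataclass
class Volume:
    """A 3D scalar image plus the spatial metadata it was read with.

    ``affine`` is carried through unchanged; the analysis itself never uses
    it (alignment is by grid shape), but writing results back as NIfTI
    keeps them overlayable on the source image.
    """

    data: np.ndarray
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise FormatError(
                f"volume payload must be 3D with positive dims, got shape {self.data.shape}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]


@dataclass
class LabelAtlas:
    """Integer parcellation with region names.

    ``labels`` uses internal IDs ``1..R`` (0 = background).  ``region_ids``
    holds the original file IDs in internal order, i.e. internal region
    ``i`` (1-based) corresponds to original ID ``region_ids[i-1]`` named
    ``region_names[i-1]``.
    """

    labels: np.ndarray
    region_ids: np.ndarray
    region_names: list[str]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise FormatError("atlas labels must be integer-valued")
        if self.labels.ndim != 3:
            raise FormatError("atlas labels must be 3D")
        self.region_ids = np.asarray(self.region_ids)
        present = np.unique(self.labels)
        present = present[present != 0]
        if (present < 0).any():
            raise FormatError("negative atlas labels are not allowed")
        if len(self.region_ids) != len(self.region_names):
            raise FormatError("region_ids and region_names disagree in length")
        if self.R and not np.array_equal(present, np.arange(1, self.R + 1)):
            raise FormatError(
                "internal atlas labels must be exactly 1..R with every region nonempty"
            )

    @property
    def R(self) -> int:
        return len(self.region_ids)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def region_support(self, internal_id: int) -> np.ndarray:
        """Boolean support of internal region ``internal_id`` (1-based)."""
        return self.labels == internal_id

    def region_sizes(self) -> np.ndarray:
        """Voxel count per region, internal order (length R)."""
        return np.bincount(self.labels.ravel(), minlength=self.R + 1)[1:]

    def names_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "internal_id": np.arange(1, self.R + 1),
                "region_id": self.region_ids,
                "name": self.region_names,
            }
        )


@dataclass
class LabeledDataset:
    """Volumes with binary class labels (0 = control, 1 = case) and splits."""

    volumes: list[Volume]
    labels: np.ndarray
    split: np.ndarray  # per-volume entry from SPLITS
    paths: list[str] | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.split = np.asarray(self.split, dtype=object)
        n = len(self.volumes)
        if len(self.labels) != n or len(self.split) != n:
            raise ValueError("volumes, labels and split must have equal length")
        bad = set(self.split) - set(SPLITS)
        if bad:
            raise ValueError(f"unknown split names: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.volumes)

    def subset(self, which: str) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(stacked data (n, nx, ny, nz), labels)`` for one split."""
        idx = np.flatnonzero(self.split == which)
        data = np.stack([self.volumes[i].data for i in idx]) if len(idx) else np.empty((0,))
        return data, self.labels[idx]


# ---------------------------------------------------------------------------
# volume I/O


def read_volume(path: str | Path) -> Volume:
    """Read a NIfTI volume; a singleton 4th axis is squeezed away."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3D payload, got ndim={data.ndim}")
    if not np.issubdtype(data.dtype, np.number):
        raise FormatError(f"{path}: non-scalar datatype {data.dtype}")
    return Volume(data=np.asarray(data, dtype=np.float32), affine=np.asarray(img.affine))


def write_volume(v: Volume, path: str | Path) -> Path:
    path = Path(path)
    affine = v.affine if v.affine is not None else np.eye(4)
    nib.save(nib.Nifti1Image(v.data.astype(np.float32), affine), str(path))
    return path


def normalize(v: Volume) -> Volume:
    """Standardize one volume to zero mean, unit (population) variance."""
    data = v.data.astype(np.float64)
    if not np.isfinite(data).all():
        raise FormatError("volume contains non-finite values")
    sd = data.std()
    if sd < 1e-12:
        raise ValueError("cannot normalize a (near-)constant volume")
    out = (data - data.mean()) / sd
    return Volume(data=out.astype(np.float32), affine=v.affine)


# ---------------------------------------------------------------------------
# atlas I/O


def _read_names_table(names_path: Path) -> pd.DataFrame:
    """Two-column (ID, name) table, tab- or comma-delimited, header optional."""
    text = names_path.read_text().strip()
    if not text:
        raise FormatError(f"{names_path}: empty names table")
    sep = "\t" if "\t" in text.splitlines()[0] else ","
    df = pd.read_csv(names_path, sep=sep, header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise FormatError(f"{names_path}: need two columns (ID, name)")
    first = str(df.iloc[0, 0]).strip()
    try:
        int(first)
    except ValueError:  # header row
        df = df.iloc[1:]
    if df.empty:
        raise FormatError(f"{names_path}: no data rows")
    return pd.DataFrame(
        {"region_id": df.iloc[:, 0].astype(int).to_numpy(), "name": df.iloc[:, 1].astype(str)}
    )


def read_atlas(label_path: str | Path, names_path: str | Path) -> LabelAtlas:
    """Read a parcellation image and its ID→name lookup table.

    Original IDs need not be contiguous; they are re-indexed to ``1..R`` in
    ascending original-ID order, the original IDs being retained for
    reporting.
    """
    label_path, names_path = Path(label_path), Path(names_path)
    img = nib.load(str(label_path))
    raw = np.asanyarray(img.dataobj)
    if raw.ndim == 4 and raw.shape[3] == 1:
        raw = raw[..., 0]
    if raw.ndim != 3:
        raise FormatError(f"{label_path}: expected a 3D label image")
    if not np.issubdtype(raw.dtype, np.integer):
        rounded = np.rint(raw)
        if not np.allclose(raw, rounded, atol=1e-6):
            raise FormatError(f"{label_path}: label image is not integer-valued")
        raw = rounded.astype(np.int64)
    raw = raw.astype(np.int64)
    names = _read_names_table(names_path)
    return atlas_from_arrays(raw, names["region_id"].to_numpy(), list(names["name"]))


def atlas_from_arrays(
    raw_labels: np.ndarray, table_ids: np.ndarray, table_names: list[str]
) -> LabelAtlas:
    """Build a :class:`LabelAtlas` from an arbitrary-ID label grid and a name table."""
    present = np.unique(raw_labels)
    present = present[present != 0]
    missing = sorted(set(present.tolist()) - set(np.asarray(table_ids).tolist()))
    if missing:
        raise FormatError(f"name table is missing atlas IDs: {missing}")
    name_of = dict(zip(np.asarray(table_ids).tolist(), table_names))
    # re-index to 1..R, ascending original ID
    lut = np.zeros(int(present.max()) + 1 if len(present) else 1, dtype=np.int64)
    for internal, orig in enumerate(present, start=1):
        lut[orig] = internal
    labels = lut[raw_labels]
    return LabelAtlas(
        labels=labels,
        region_ids=present.copy(),
        region_names=[name_of[int(i)] for i in present],
    )


def write_atlas(atlas: LabelAtlas, label_path: str | Path, names_path: str | Path) -> None:
    """Write the atlas with its *original* IDs restored in the label image."""
    restore = np.zeros(atlas.R + 1, dtype=np.int32)
    restore[1:] = atlas.region_ids
    nib.save(
        nib.Nifti1Image(restore[atlas.labels].astype(np.int32), np.eye(4)), str(label_path)
    )
    pd.DataFrame({"region_id": atlas.region_ids, "name": atlas.region_names}).to_csv(
        names_path, sep="\t", index=False, header=False
    )


# ---------------------------------------------------------------------------
# dataset splitting


def _per_class_counts(n: int, fractions: np.ndarray, class_pos: int) -> np.ndarray:
    """Largest-remainder allocation of ``n`` samples over splits.

    Remainder ties are rotated by the class position so that, e.g., two
    balanced classes with fractions (0.7, 0.15, 0.15) land on overall split
    sizes 98/21/21 rather than 98/22/20.
    """
    exact = n * fractions
    counts = np.floor(exact).astype(int)
    leftover = n - counts.sum()
    k = len(fractions)
    order = sorted(
        range(k), key=lambda i: (-(exact[i] - counts[i]), (i + class_pos) % k, i)
    )
    for i in order[:leftover]:
        counts[i] += 1
    return counts


def split_dataset(
    volumes: list[Volume],
    class_labels: np.ndarray,
    fractions: tuple[float, float, float] = (0.7, 0.15, 0.15),
    seed: int = 0,
    paths: list[str] | None = None,
) -> LabeledDataset:
    """Class-balanced train/val/test partition, deterministic for a seed."""
    fractions = np.asarray(fractions, dtype=float)
    if len(fractions) != len(SPLITS):
        raise ValueError("exactly three split fractions expected (train, val, test)")
    if (fractions < 0).any() or abs(fractions.sum() - 1.0) > 1e-9:
        raise ValueError("split fractions must be nonnegative and sum to 1")
    class_labels = np.asarray(class_labels, dtype=np.int64)
    if len(class_labels) != len(volumes):
        raise ValueError("one class label per volume required")
    n_active = int((fractions > 0).sum())
    rng = np.random.default_rng(seed)
    split = np.empty(len(volumes), dtype=object)
    classes = np.unique(class_labels)
    for pos, c in enumerate(classes):
        idx = np.flatnonzero(class_labels == c)
        if len(idx) < n_active:
            raise ValueError(
                f"class {c} has {len(idx)} samples, fewer than the {n_active} nonempty splits"
            )
        counts = _per_class_counts(len(idx), fractions, pos)
        idx = rng.permutation(idx)
        start = 0
        for name, cnt in zip(SPLITS, counts):
            split[idx[start : start + cnt]] = name
            start += cnt
    return LabeledDataset(volumes=list(volumes), labels=class_labels, split=split, paths=paths)


# ---------------------------------------------------------------------------
# manifest


def write_manifest(ds: LabeledDataset, path: str | Path) -> Path:
    if ds.paths is None:
        raise ValueError("dataset has no file paths to write")
    pd.DataFrame({"path": ds.paths, "class": ds.labels, "split": ds.split}).to_csv(
        path, index=False
    )
    return Path(path)


def read_manifest(path: str | Path, root: str | Path | None = None) -> LabeledDataset:
    """Load a (path, class, split) manifest, reading every referenced volume."""
    df = pd.read_csv(path)
    for col in ("path", "class", "split"):
        if col not in df.columns:
            raise FormatError(f"manifest missing column {col!r}")
    base = Path(root) if root is not None else Path(path).parent
    vol_paths = [str(p) if Path(p).is_absolute() else str(base / p) for p in df["path"]]
    volumes = [read_volume(p) for p in vol_paths]
    return LabeledDataset(
        volumes=volumes,
        labels=df["class"].to_numpy(),
        split=df["split"].to_numpy(dtype=object),
        paths=list(df["path"]),
    )
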