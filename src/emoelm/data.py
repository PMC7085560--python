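"""Hyperspectral scenes: synthetic generation, flattening, and file I/O.

A scene is a hypercube (height x width x bands) plus a ground-truth map
of the same spatial shape, where label 0 marks unlabeled pixels and
classes are numbered from 1.  Pixels are the samples: flattening turns
labeled pixels into rows of a sample matrix in row-major spatial order,
with per-band min-max scaling to [0, 1] by default (sigmoid encoders
need bounded inputs).

The synthetic generator emulates an agricultural-style labeled scene:
each class has a smooth random spectral signature (a low-frequency
sinusoid mixture over bands), the spatial layout is a Voronoi patchwork
of class regions, and pixels carry additive Gaussian noise correlated
across neighboring bands — the dominant noise structure of pushbroom
imaging spectrometers.  What it does *not* emulate: mixed pixels at
field borders, per-class covariance differences, atmospheric absorption
bands, or spatial noise correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.io import loadmat, savemat

__all__ = [
    "SampleMatrix",
    "HyperspectralScene",
    "SyntheticSceneSpec",
    "generate_scene",
    "flatten_scene",
    "read_matrix",
    "write_matrix",
    "read_scene",
    "write_scene",
]


@dataclass
class SampleMatrix:
    """N x n matrix of samples (pixels) by features (bands).

    ``labels`` (optional) are integer classes in 1..C; ``coords``
    (optional) are the (row, col) scene coordinates of each sample, kept
    so per-pixel results can be painted back into the scene.
    """

    values: np.ndarray
    labels: np.ndarray | None = None
    coords: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValueError(f"values must be a nonempty 2-D matrix")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("sample matrix contains non-finite entries")
        if self.labels is not None:
            self.labels = np.asarray(self.labels).astype(int).ravel()
            if len(self.labels) != len(self.values):
                raise ValueError("labels length does not match sample count")
            if self.labels.min() < 1:
                raise ValueError("labels must be >= 1 (0 marks unlabeled pixels)")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


@dataclass
class HyperspectralScene:
    """Cube (H x W x B) plus ground truth (H x W, 0 = unlabeled)."""

    cube: np.ndarray
    ground_truth: np.ndarray
    class_names: list | None = None

    def __post_init__(self):
        self.cube = np.asarray(self.cube, dtype=float)
        self.ground_truth = np.asarray(self.ground_truth).astype(int)
        if self.cube.ndim != 3:
            raise ValueError(f"cube must be 3-D, got shape {self.cube.shape}")
        if self.ground_truth.shape != self.cube.shape[:2]:
            raise ValueError(
                f"cube spatial shape {self.cube.shape[:2]} does not match "
                f"ground truth shape {self.ground_truth.shape}"
            )
        if self.ground_truth.min() < 0:
            raise ValueError("ground-truth labels must be >= 0")

    @property
    def n_bands(self) -> int:
        return self.cube.shape[2]

    @property
    def n_classes(self) -> int:
        return int(self.ground_truth.max())


@dataclass(frozen=True)
class SyntheticSceneSpec:
    """Parameters of the synthetic labeled scene.

    Defaults give a 40x40, 30-band, 5-class scene with noise standard
    deviation 0.05 on signatures of order-one amplitude and inter-band
    correlation length of 5 bands — separable but not trivially so, in
    the spirit of the small AVIRIS benchmark crops.
    """

    n_classes: int = 5
    n_bands: int = 30
    height: int = 40
    width: int = 40
    noise_std: float = 0.05
    corr_length: float = 5.0
    labeled_fraction: float = 1.0
    n_patches: int | None = None  # default 3 per class
    seed: int | None = None

    def __post_init__(self):
        if self.n_classes < 2 or self.n_bands < 2:
            raise ValueError("need at least 2 classes and 2 bands")
        if self.noise_std < 0:
            raise ValueError("noise_std must be >= 0")
        if not 0.0 < self.labeled_fraction <= 1.0:
            raise ValueError("labeled_fraction must lie in (0, 1]")


def _class_signatures(C: int, B: int, rng) -> np.ndarray:
    """Smooth per-class spectra: random low-frequency sinusoid mixtures."""
    t = np.linspace(0.0, 1.0, B)
    sigs = np.empty((C, B))
    for c in range(C):
        freqs = rng.uniform(0.5, 2.5, size=4)
        phases = rng.uniform(0.0, 2 * np.pi, size=4)
        amps = rng.normal(0.0, 0.2, size=4) / np.arange(1, 5)
        curve = 0.5 + sum(
            a * np.sin(2 * np.pi * f * t + p)
            for a, f, p in zip(amps, freqs, phases)
        )
        sigs[c] = np.clip(curve, 0.05, 0.95)
    return sigs


def generate_scene(spec: SyntheticSceneSpec) -> HyperspectralScene:
    """Generate a reproducible labeled synthetic scene.

    Spatial layout is a Voronoi patchwork: random seed points each carry
    a class (every class gets at least one patch) and each pixel takes
    the class of its nearest seed.  Pixel spectra are the class
    signature plus zero-mean Gaussian noise with inter-band covariance
    sigma^2 exp(-|i-j| / corr_length).  With ``labeled_fraction`` < 1 a
    random pixel subset keeps its label and the rest are set to 0.
    """
    rng = np.random.default_rng(spec.seed)
    C, B, H, W = spec.n_classes, spec.n_bands, spec.height, spec.width
    sigs = _class_signatures(C, B, rng)

    n_patches = spec.n_patches if spec.n_patches is not None else 3 * C
    if n_patches < C:
        raise ValueError(f"need at least {C} patches for {C} classes")
    seeds = rng.uniform(0.0, 1.0, size=(n_patches, 2)) * [H, W]
    patch_class = np.concatenate(
        [np.arange(1, C + 1), rng.integers(1, C + 1, size=n_patches - C)]
    )
    rr, cc = np.meshgrid(np.arange(H), np.arange(W), indexing="ij")
    pix = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
    nearest = np.argmin(
        ((pix[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2), axis=1
    )
    gt = patch_class[nearest].reshape(H, W)

    cube = sigs[gt.ravel() - 1].reshape(H, W, B).copy()
    if spec.noise_std > 0:
        idx = np.arange(B)
        cov = np.exp(-np.abs(idx[:, None] - idx[None, :]) / spec.corr_length)
        chol = np.linalg.cholesky(cov)
        z = rng.standard_normal((H * W, B))
        cube += (spec.noise_std * z @ chol.T).reshape(H, W, B)

    if spec.labeled_fraction < 1.0:
        keep = rng.random((H, W)) < spec.labeled_fraction
        if not keep.any():
            keep.flat[rng.integers(H * W)] = True
        gt = np.where(keep, gt, 0)
    return HyperspectralScene(cube=cube, ground_truth=gt)


def flatten_scene(
    scene: HyperspectralScene,
    scale: bool = True,
    include_unlabeled: bool = False,
) -> SampleMatrix:
    """Labeled pixels as rows, row-major spatial order.

    Per-band min-max scaling to [0, 1] (computed over the returned
    pixels) is applied unless ``scale=False``; a constant band maps to
    0.  Coordinates are recorded so rows invert back to pixels.
    """
    gt = scene.ground_truth
    mask = np.ones_like(gt, dtype=bool) if include_unlabeled else gt > 0
    if not mask.any():
        raise ValueError("scene has no labeled pixels")
    coords = np.argwhere(mask)  # row-major order
    X = scene.cube[mask].astype(float)
    if scale:
        lo = X.min(axis=0)
        rng_ = X.max(axis=0) - lo
        rng_[rng_ == 0] = 1.0
        X = (X - lo) / rng_
    labels = gt[mask]
    return SampleMatrix(
        values=X,
        labels=labels if (labels > 0).all() else None,
        coords=coords,
    )


# -- file formats --------------------------------------------------------


def read_matrix(path, labels_column: str | None = None) -> SampleMatrix:
    """Read a CSV sample matrix (no header); optional last-column labels.

    ``labels_column="last"`` treats the final column as integer class
    labels.
    """
    data = np.loadtxt(path, delimiter=",", ndmin=2)
    if labels_column == "last":
        return SampleMatrix(values=data[:, :-1], labels=data[:, -1])
    if labels_column is not None:
        raise ValueError(f"unsupported labels_column {labels_column!r}")
    return SampleMatrix(values=data)


def write_matrix(X, path, labels=None) -> None:
    """Write a matrix (optionally with a trailing label column) as CSV.

    Uses %.17g so float64 values round-trip exactly.
    """
    X = np.asarray(X, dtype=float)
    if labels is not None:
        X = np.column_stack([X, np.asarray(labels, dtype=float)])
    np.savetxt(path, X, delimiter=",", fmt="%.17g")


def _pick_variables(contents: dict, data_var, gt_var):
    arrays = {
        k: v
        for k, v in contents.items()
        if not k.startswith("__") and isinstance(v, np.ndarray)
    }
    if data_var is None:
        cubes = {k: v for k, v in arrays.items() if v.ndim == 3}
        if len(cubes) != 1:
            raise ValueError(
                "cannot auto-detect the data cube; pass data_var explicitly "
                f"(3-D candidates: {sorted(cubes) or 'none'}, "
                f"variables present: {sorted(arrays)})"
            )
        (data_var,) = cubes
    elif data_var not in arrays:
        raise ValueError(
            f"data variable {data_var!r} not found; file has {sorted(arrays)}"
        )
    cube = arrays[data_var]
    if gt_var is None:
        maps = {
            k: v
            for k, v in arrays.items()
            if k != data_var and v.ndim == 2 and v.shape == cube.shape[:2]
        }
        if len(maps) != 1:
            raise ValueError(
                "cannot auto-detect the ground-truth map; pass gt_var "
                f"explicitly (2-D candidates matching {cube.shape[:2]}: "
                f"{sorted(maps) or 'none'}, variables present: {sorted(arrays)})"
            )
        (gt_var,) = maps
    elif gt_var not in arrays:
        raise ValueError(
            f"ground-truth variable {gt_var!r} not found; file has {sorted(arrays)}"
        )
    return cube, arrays[gt_var]


def read_scene(path, data_var=None, gt_var=None) -> HyperspectralScene:
    """Load a MAT-container scene (cube + ground truth).

    Variable names are auto-detected when not given: the single 3-D
    array is the cube, the single 2-D array matching its spatial shape
    is the ground truth — the convention of the public AVIRIS scene
    files.
    """
    contents = loadmat(path)
    cube, gt = _pick_variables(contents, data_var, gt_var)
    if gt.shape != cube.shape[:2]:
        raise ValueError(
            f"cube spatial shape {cube.shape[:2]} does not match "
            f"ground truth shape {gt.shape}"
        )
    return HyperspectralScene(cube=cube, ground_truth=gt)


def write_scene(scene: HyperspectralScene, path) -> None:
    """Write a scene as a MAT v5 container with variables data/gt."""
    savemat(path, {"data": scene.cube, "gt": scene.ground_truth})
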