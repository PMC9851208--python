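"""Dataset container, synthetic blob generator, and external-format readers.

The synthetic generator produces separable Gaussian-cluster classification
problems with a known geometry: class centroids are placed in the unit
hypercube with pairwise distance at least ``separation * noise_sd``, so
``separation`` is the centroid spacing in noise standard deviations and the
pairwise Bayes error of two neighbouring classes is at most
``Phi(-separation / 2)``.  Features are min-max scaled to [0, 1] — the
operating range of the sigmoid dynamics — and the split is stratified.

External readers cover the two standard benchmark containers: IDX
(big-endian, the MNIST distribution format) and the CIFAR-10 pickled
batches.  Nothing is ever downloaded; paths are user-supplied.
"""

from __future__ import annotations

import dataclasses
import hashlib
import pathlib
import pickle
import struct

import numpy as np
from sklearn.model_selection import train_test_split

from .errors import FormatError, ValidationError

__all__ = ["Dataset", "make_blobs", "read_idx", "read_cifar_batches", "load_mnist"]


@dataclasses.dataclass
class Dataset:
    """Inputs in [0, 1], one-hot targets, split labels, and provenance.

    ``inputs`` is ``(n, d)`` for dense models or ``(n, C, H, W)`` for the
    convolutional one; ``targets`` is ``(n, k)`` one-hot; ``split`` holds
    the string ``"train"`` or ``"test"`` per row.
    """

    inputs: np.ndarray
    targets: np.ndarray
    split: np.ndarray
    provenance: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.inputs = np.asarray(self.inputs, dtype=float)
        self.targets = np.asarray(self.targets, dtype=float)
        self.split = np.asarray(self.split)
        self.validate()

    def validate(self) -> None:
        n = self.inputs.shape[0]
        if self.targets.shape[0] != n or self.split.shape[0] != n:
            raise ValidationError(
                f"row counts disagree: inputs {n}, targets {self.targets.shape[0]}, "
                f"split {self.split.shape[0]}"
            )
        if self.targets.ndim != 2:
            raise ValidationError("targets must be a 2-D one-hot matrix")
        if not np.all(np.isfinite(self.inputs)):
            raise ValidationError("non-finite inputs")
        if np.any(self.inputs < 0) or np.any(self.inputs > 1):
            raise ValidationError("inputs must lie in [0, 1]")
        if not np.allclose(self.targets.sum(axis=1), 1.0) or not np.all(
            np.isin(self.targets, (0.0, 1.0))
        ):
            raise ValidationError("each target row must be one-hot")
        if not np.all(np.isin(self.split, ("train", "test"))):
            raise ValidationError("split labels must be 'train' or 'test'")

    # ------------------------------------------------------------------
    @property
    def n_classes(self) -> int:
        return self.targets.shape[1]

    @property
    def n_features(self) -> int:
        return int(np.prod(self.inputs.shape[1:]))

    def train_test(self):
        """(X_train, Y_train, X_test, Y_test) views of the rows."""
        tr = self.split == "train"
        te = self.split == "test"
        return self.inputs[tr], self.targets[tr], self.inputs[te], self.targets[te]

    def flattened(self) -> "Dataset":
        """Copy with image inputs flattened to ``(n, d)``."""
        return Dataset(
            self.inputs.reshape(self.inputs.shape[0], -1),
            self.targets,
            self.split,
            dict(self.provenance),
        )

    # -- container round-trip -------------------------------------------
    def save(self, path: str | pathlib.Path) -> None:
        import json

        np.savez_compressed(
            path,
            inputs=self.inputs,
            targets=self.targets,
            split=self.split,
            provenance=np.frombuffer(json.dumps(self.provenance).encode(), dtype=np.uint8),
        )

    @classmethod
    def load(cls, path: str | pathlib.Path) -> "Dataset":
        import json

        with np.load(path, allow_pickle=False) as f:
            prov = json.loads(bytes(f["provenance"]).decode()) if "provenance" in f else {}
            return cls(f["inputs"], f["targets"], f["split"], prov)


# ----------------------------------------------------------------------
# Synthetic generator
# ----------------------------------------------------------------------

def _place_centroids(k: int, d: int, min_dist: float, rng: np.random.Generator) -> np.ndarray:
    """Centroids in the unit hypercube with pairwise distance >= min_dist."""
    if min_dist > np.sqrt(d) and k > 1:
        raise ValidationError(
            f"cannot place {k} centroids at pairwise distance {min_dist:.3g} "
            f"inside the unit {d}-cube (diameter {np.sqrt(d):.3g})"
        )
    # sphere-packing bound: balls of radius min_dist/2 around the centroids
    # are disjoint and fit in the cube inflated by min_dist/2 on every side
    if min_dist > 0:
        from scipy.special import gammaln

        log_ball = (d / 2) * np.log(np.pi) + d * np.log(min_dist / 2) - gammaln(d / 2 + 1)
        log_bound = d * np.log1p(min_dist) - log_ball
        if np.log(k) > log_bound:
            raise ValidationError(
                f"infeasible geometry: {k} classes cannot be packed in {d} dimensions "
                f"with centroid separation {min_dist:.3g}"
            )
    for _ in range(200):  # restarts
        pts: list[np.ndarray] = []
        for _ in range(k):
            for _ in range(500):  # tries per point
                cand = rng.uniform(0.0, 1.0, size=d)
                if all(np.linalg.norm(cand - p) >= min_dist for p in pts):
                    pts.append(cand)
                    break
            else:
                break
        if len(pts) == k:
            return np.array(pts)
    raise ValidationError(
        f"could not place {k} centroids at separation {min_dist:.3g} in {d} dimensions"
    )


def make_blobs(
    n: int,
    d: int,
    k: int,
    separation: float = 3.0,
    noise_sd: float = 0.05,
    seed: int = 0,
    test_fraction: float = 0.25,
) -> Dataset:
    """Seeded Gaussian-cluster classification data with known separability.

    ``separation`` is the minimum centroid spacing in units of ``noise_sd``
    (isotropic class noise), so neighbouring classes overlap with pairwise
    Bayes error at most ``Phi(-separation / 2)``.  The split is stratified;
    the full generating recipe is recorded in ``provenance``.
    """
    if k < 2 or n < k:
        raise ValidationError(f"need n >= k >= 2, got n={n}, k={k}")
    if separation <= 0:
        raise ValidationError(f"separation must be > 0, got {separation}")
    if noise_sd < 0:
        raise ValidationError(f"noise_sd must be >= 0, got {noise_sd}")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xB10B]))
    min_dist = separation * (noise_sd if noise_sd > 0 else 0.05)
    centroids = _place_centroids(k, d, min_dist, rng)

    counts = np.full(k, n // k)
    counts[: n % k] += 1
    labels = np.repeat(np.arange(k), counts)
    X = centroids[labels] + rng.normal(0.0, noise_sd, size=(n, d))

    lo, hi = X.min(axis=0), X.max(axis=0)
    rng_span = np.where(hi - lo < 1e-12, 1.0, hi - lo)
    X = np.clip((X - lo) / rng_span, 0.0, 1.0)

    Y = np.eye(k)[labels]
    idx = np.arange(n)
    idx_tr, idx_te = train_test_split(
        idx,
        test_size=test_fraction,
        stratify=labels,
        random_state=int(seed) % (2**32),
        shuffle=True,
    )
    split = np.empty(n, dtype=object)
    split[idx_tr] = "train"
    split[idx_te] = "test"
    return Dataset(
        X,
        Y,
        split.astype(str),
        provenance={
            "generator": "make_blobs",
            "n": n,
            "d": d,
            "k": k,
            "separation": separation,
            "noise_sd": noise_sd,
            "seed": int(seed),
            "test_fraction": test_fraction,
        },
    )


# ----------------------------------------------------------------------
# IDX (MNIST) reader
# ----------------------------------------------------------------------

def _read_idx_array(path: str | pathlib.Path) -> np.ndarray:
    raw = pathlib.Path(path).read_bytes()
    if len(raw) < 4:
        raise FormatError(f"{path}: file too short for an IDX header ({len(raw)} bytes)")
    zero1, zero2, dtype_code, ndim = struct.unpack(">BBBB", raw[:4])
    if zero1 != 0 or zero2 != 0:
        raise FormatError(f"{path}: bad IDX magic at offset 0: {raw[:4].hex()}")
    dtypes = {0x08: np.uint8, 0x09: np.int8, 0x0B: ">i2", 0x0C: ">i4", 0x0D: ">f4", 0x0E: ">f8"}
    if dtype_code not in dtypes:
        raise FormatError(f"{path}: unknown IDX dtype code 0x{dtype_code:02x} at offset 2")
    header_len = 4 + 4 * ndim
    if len(raw) < header_len:
        raise FormatError(f"{path}: truncated IDX dimension header (offset {len(raw)})")
    dims = struct.unpack(f">{ndim}I", raw[4:header_len])
    arr = np.frombuffer(raw, dtype=dtypes[dtype_code], offset=header_len)
    expected = int(np.prod(dims))
    if arr.size != expected:
        raise FormatError(
            f"{path}: payload holds {arr.size} values, header promises {expected} "
            f"(dims {dims}, data starts at offset {header_len})"
        )
    return arr.reshape(dims)


def read_idx(
    images_path: str | pathlib.Path,
    labels_path: str | pathlib.Path,
    split: str = "train",
    n_classes: int | None = None,
) -> Dataset:
    """Read an IDX image/label file pair into a Dataset (pixels to [0, 1])."""
    images = _read_idx_array(images_path)
    labels = _read_idx_array(labels_path)
    if images.ndim != 3:
        raise FormatError(f"{images_path}: expected 3-D image tensor, got {images.ndim}-D")
    if labels.ndim != 1:
        raise FormatError(f"{labels_path}: expected 1-D label vector, got {labels.ndim}-D")
    if images.shape[0] != labels.shape[0]:
        raise ValidationError(
            f"{images.shape[0]} images but {labels.shape[0]} labels"
        )
    X = images.reshape(images.shape[0], -1).astype(float) / 255.0
    labels = labels.astype(int)
    k = n_classes if n_classes is not None else int(labels.max()) + 1
    Y = np.eye(k)[labels]
    digest = hashlib.sha256(pathlib.Path(images_path).read_bytes()).hexdigest()[:16]
    return Dataset(
        X,
        Y,
        np.full(X.shape[0], split),
        provenance={"source": str(images_path), "sha256_16": digest, "format": "idx"},
    )


def load_mnist(directory: str | pathlib.Path, n_classes: int = 10) -> Dataset:
    """Load the four standard MNIST IDX files from a directory."""
    directory = pathlib.Path(directory)
    names = {
        "train_images": "train-images-idx3-ubyte",
        "train_labels": "train-labels-idx1-ubyte",
        "test_images": "t10k-images-idx3-ubyte",
        "test_labels": "t10k-labels-idx1-ubyte",
    }
    missing = [v for v in names.values() if not (directory / v).exists()]
    if missing:
        raise FileNotFoundError(f"missing MNIST files in {directory}: {missing}")
    tr = read_idx(directory / names["train_images"], directory / names["train_labels"], "train", n_classes)
    te = read_idx(directory / names["test_images"], directory / names["test_labels"], "test", n_classes)
    return Dataset(
        np.concatenate([tr.inputs, te.inputs]),
        np.concatenate([tr.targets, te.targets]),
        np.concatenate([tr.split, te.split]),
        provenance={"source": str(directory), "format": "mnist-idx"},
    )


# ----------------------------------------------------------------------
# CIFAR-10 pickled batches
# ----------------------------------------------------------------------

def read_cifar_batches(directory: str | pathlib.Path, n_classes: int = 10) -> Dataset:
    """Read CIFAR-10 pickled batches into channel-height-width tensors.

    Loads whichever of ``data_batch_1..5`` exist (``data_batch_1`` is
    required) as the train split and ``test_batch`` (optional) as the test
    split; pixels are scaled to [0, 1].
    """
    directory = pathlib.Path(directory)
    first = directory / "data_batch_1"
    if not first.exists():
        expected = [f"data_batch_{i}" for i in range(1, 6)] + ["test_batch"]
        raise FileNotFoundError(
            f"no CIFAR-10 batches in {directory}; expected files like {expected[0]} "
            f"(full set: {expected})"
        )

    def load_batch(path: pathlib.Path):
        with open(path, "rb") as f:
            d = pickle.load(f, encoding="bytes")
        data = np.asarray(d[b"data"])
        labels = np.asarray(d[b"labels"], dtype=int)
        if data.ndim != 2 or data.shape[1] % 3 != 0:
            raise FormatError(f"{path}: unexpected data shape {data.shape}")
        side = int(np.sqrt(data.shape[1] // 3))
        return data.reshape(-1, 3, side, side).astype(float) / 255.0, labels

    Xs, ys, splits = [], [], []
    for i in range(1, 6):
        p = directory / f"data_batch_{i}"
        if p.exists():
            X, y = load_batch(p)
            Xs.append(X)
            ys.append(y)
            splits.append(np.full(len(y), "train"))
    test = directory / "test_batch"
    if test.exists():
        X, y = load_batch(test)
        Xs.append(X)
        ys.append(y)
        splits.append(np.full(len(y), "test"))
    X = np.concatenate(Xs)
    y = np.concatenate(ys)
    return Dataset(
        X,
        np.eye(n_classes)[y],
        np.concatenate(splits),
        provenance={"source": str(directory), "format": "cifar10-batches"},
    )
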