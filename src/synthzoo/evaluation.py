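"""Fréchet-distance evaluation of generative models: FID, FIDrr, and rFID.

The Fréchet inception distance (FID) compares two image sets through the
Wasserstein-2 distance between multivariate Gaussians fitted to deep
features of each set,

    FD(X, Y) = ||mu_X - mu_Y||^2 + tr(Sigma_X + Sigma_Y - 2 (Sigma_X Sigma_Y)^{1/2}),

where (mu, Sigma) are the feature mean and covariance of each set. Which
network extracts the features is a free choice that biases the score, so
extractors are pluggable here (see :class:`FeatureExtractor`) and every
report records which one was used, together with the normalization mode.

Because the FID between two disjoint samples of the *real* data is not
zero, that real-real distance FIDrr is an empirical lower bound for any
real-synthetic FIDrs on the same data. The FID ratio

    rFID = 1 - (FIDrs - FIDrr) / FIDrs,   rFID in [0, 1],

expresses how much of the real-synthetic distance is explained by the
intrinsic variation of the real data: values near 1 mean the synthetic
set is about as far from the real set as the real set is from itself.
"""

from __future__ import annotations

import csv
import io
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from skimage.transform import resize as _sk_resize

from .errors import NumericalError

__all__ = [
    "FeatureMatrix", "GaussianSummary", "FeatureExtractor", "FidReport",
    "fit_gaussian", "frechet_distance", "normalize_images", "prepare_images",
    "compute_fid", "fid_lower_bound", "SplitFid", "rfid", "evaluate_model",
    "report_table", "ReportTable",
]


# ---------------------------------------------------------------------------
# containers


@dataclass
class FeatureMatrix:
    """n x d feature matrix plus the id of the extractor that produced it."""

    values: np.ndarray
    extractor_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[0] < 2:
            raise ValueError("a feature matrix needs at least 2 rows (n >= 2)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite entries")


@dataclass
class GaussianSummary:
    """Mean vector and covariance matrix summarizing one feature set."""

    mean: np.ndarray
    cov: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.atleast_1d(np.asarray(self.mean, dtype=float))
        self.cov = np.atleast_2d(np.asarray(self.cov, dtype=float))
        d = self.mean.shape[0]
        if self.cov.shape != (d, d):
            raise ValueError(
                f"covariance shape {self.cov.shape} inconsistent with mean length {d}"
            )
        if not np.allclose(self.cov, self.cov.T, atol=1e-8):
            raise ValueError("covariance matrix must be symmetric (tolerance 1e-8)")


@dataclass
class FeatureExtractor:
    """Contract for a deterministic image-set -> feature-matrix map.

    ``expected_input`` is ``(height, width, channels)``; images are
    resized and channel-adapted to it before ``fn`` is applied to the
    stacked ``(n, H, W, C)`` array.
    """

    id: str
    expected_input: tuple[int, int, int]
    fn: Callable[[np.ndarray], np.ndarray]

    def apply(self, images: np.ndarray) -> FeatureMatrix:
        feats = np.asarray(self.fn(images), dtype=float)
        return FeatureMatrix(values=feats, extractor_id=self.id)


@dataclass
class FidReport:
    """One model's FID evaluation with full provenance."""

    model_id: str
    fid_rr: float
    fid_rs: float
    rfid: float
    n_real: int
    n_syn: int
    normalized: bool
    extractor_id: str
    seed: int
    normalize_mode: str = ""
    split_sizes: tuple[int, int] = (0, 0)

    FIELDS = (
        "model_id", "fid_rr", "fid_rs", "rfid", "n_real", "n_syn",
        "normalized", "extractor_id", "seed", "normalize_mode",
    )


# ---------------------------------------------------------------------------
# Gaussian fitting and the Fréchet distance


def fit_gaussian(features: FeatureMatrix | np.ndarray) -> GaussianSummary:
    """Fit a multivariate Gaussian to feature rows.

    Uses column means and the unbiased sample covariance (divisor n-1).
    Requires at least two rows.
    """
    values = features.values if isinstance(features, FeatureMatrix) else np.asarray(features, float)
    values = np.atleast_2d(values)
    if values.shape[0] < 2:
        raise ValueError("fit_gaussian requires n >= 2 samples")
    mean = values.mean(axis=0)
    cov = np.atleast_2d(np.cov(values, rowvar=False, ddof=1))
    return GaussianSummary(mean=mean, cov=cov)


def _trace_sqrt_product(cov_a: np.ndarray, cov_b: np.ndarray) -> float:
    """tr((Sigma_a Sigma_b)^{1/2}) via the symmetric eigenvalue route.

    The product Sigma_a Sigma_b is similar to the symmetric PSD matrix
    sqrt(Sigma_a) Sigma_b sqrt(Sigma_a), so the trace of its square root
    is the sum of the square roots of that matrix's eigenvalues. Working
    through ``eigh`` keeps everything real and is exact (to rounding) in
    the identical-covariance case; eigenvalues pushed slightly negative
    by rounding on near-singular covariances are clipped to zero.
    """
    d = cov_a.shape[0]
    wa, va = np.linalg.eigh(cov_a)
    sqrt_a = (va * np.sqrt(np.clip(wa, 0.0, None))) @ va.T
    inner = sqrt_a @ cov_b @ sqrt_a
    eigs = np.linalg.eigvalsh((inner + inner.T) / 2.0)
    if not np.all(np.isfinite(eigs)):
        raise NumericalError("covariance square root produced non-finite eigenvalues")
    # rank-deficient covariances (n < d) leave noise eigenvalues of order
    # eps * lambda_max whose square roots would not be negligible; zero them
    tol = max(eigs.max(), 0.0) * d * np.finfo(float).eps
    eigs = np.where(eigs < tol, 0.0, eigs)
    return float(np.sqrt(eigs).sum())


def frechet_distance(a: GaussianSummary, b: GaussianSummary) -> float:
    """Wasserstein-2 distance between two Gaussians.

    ``||mu_a - mu_b||^2 + tr(Sigma_a + Sigma_b - 2 (Sigma_a Sigma_b)^{1/2})``,
    clamped to 0 when the numerical result is within 1e-6 below zero.
    """
    if a.mean.shape != b.mean.shape:
        raise ValueError(
            f"dimension mismatch: {a.mean.shape[0]} vs {b.mean.shape[0]}"
        )
    diff = a.mean - b.mean
    value = float(
        diff @ diff
        + np.trace(a.cov) + np.trace(b.cov)
        - 2.0 * _trace_sqrt_product(a.cov, b.cov)
    )
    if value < 0.0:
        if value > -1e-6:
            return 0.0
        raise NumericalError(f"Fréchet distance came out negative ({value:.3e})")
    return value


# ---------------------------------------------------------------------------
# image preparation


def _stack(images: Sequence[np.ndarray] | np.ndarray) -> np.ndarray:
    arr = np.stack([np.asarray(im) for im in images]) if not isinstance(images, np.ndarray) else images
    if arr.ndim == 3:  # (n, H, W) -> (n, H, W, 1)
        arr = arr[..., None]
    if arr.ndim != 4:
        raise ValueError(f"expected a set of 2-D images, got array of shape {arr.shape}")
    return arr


def normalize_images(
    images: Sequence[np.ndarray] | np.ndarray,
    mode: str = "bitdepth",
    bit_depth: int = 8,
) -> np.ndarray:
    """Scale an image set into [0, 1].

    ``bitdepth`` divides by the dtype maximum (255 for 8-bit integers;
    ``2**bit_depth - 1`` for float input, with a warning when the data
    already looks normalized). ``minmax`` rescales by the *dataset-wide*
    min and max; a constant dataset maps to all zeros.
    """
    arr = _stack(images).astype(float, copy=True)
    if mode == "bitdepth":
        src = _stack(images)
        if np.issubdtype(src.dtype, np.integer):
            denom = float(np.iinfo(src.dtype).max)
        else:
            denom = float(2 ** bit_depth - 1)
            if arr.size and np.nanmax(arr) <= 1.0:
                warnings.warn(
                    "bitdepth normalization of data already within [0, 1]: "
                    f"values shrink by {denom:g}", stacklevel=2,
                )
        return arr / denom
    if mode == "minmax":
        lo, hi = float(arr.min()), float(arr.max())
        if hi == lo:
            return np.zeros_like(arr)
        return (arr - lo) / (hi - lo)
    raise ValueError(f"unknown normalization mode {mode!r}")


def prepare_images(
    images: Sequence[np.ndarray] | np.ndarray,
    extractor: FeatureExtractor,
    normalize: str | bool | None = None,
) -> np.ndarray:
    """Normalize (optional) then fit the set to the extractor's input.

    Resizing is bilinear and anti-aliased, applied after normalization.
    Grayscale images are replicated to three channels when the extractor
    expects RGB; RGB is averaged down when it expects one channel.
    """
    if normalize:
        mode = "bitdepth" if normalize is True else str(normalize)
        arr = normalize_images(_stack(images), mode)
    else:
        arr = _stack(images).astype(float)
    h, w, c = extractor.expected_input
    if arr.shape[1:3] != (h, w):
        arr = np.stack([
            _sk_resize(im, (h, w), order=1, anti_aliasing=True, preserve_range=True)
            for im in arr
        ])
    if arr.shape[3] != c:
        if arr.shape[3] == 1 and c == 3:
            arr = np.repeat(arr, 3, axis=3)
        elif arr.shape[3] == 3 and c == 1:
            arr = arr.mean(axis=3, keepdims=True)
        else:
            raise ValueError(
                f"cannot adapt {arr.shape[3]}-channel images to {c} channels"
            )
    return arr


def compute_fid(
    set_a: Sequence[np.ndarray] | np.ndarray,
    set_b: Sequence[np.ndarray] | np.ndarray,
    extractor: FeatureExtractor,
    normalize: str | bool | None = None,
) -> float:
    """FID between two image sets under one extractor and normalization."""
    a = _stack(set_a)
    b = _stack(set_b)
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("compute_fid requires at least 2 images per set")
    feats_a = extractor.apply(prepare_images(a, extractor, normalize))
    feats_b = extractor.apply(prepare_images(b, extractor, normalize))
    return frechet_distance(fit_gaussian(feats_a), fit_gaussian(feats_b))


# ---------------------------------------------------------------------------
# FIDrr / rFID


@dataclass
class SplitFid:
    """Real-real FID with the sizes of the two disjoint halves."""

    value: float
    n_first: int
    n_second: int
    seed: int


def fid_lower_bound(
    real_set: Sequence[np.ndarray] | np.ndarray,
    extractor: FeatureExtractor,
    normalize: str | bool | None = None,
    seed: int = 0,
    split_indices: tuple[Sequence[int], Sequence[int]] | None = None,
) -> SplitFid:
    """FIDrr: the FID between two disjoint halves of the real set.

    The set is shuffled with ``seed`` and split into halves of sizes
    floor(n/2) and ceil(n/2) — a single split, not averaged over repeats.
    ``split_indices`` overrides the shuffle for controlled experiments.
    """
    arr = _stack(real_set)
    n = arr.shape[0]
    if n < 4:
        raise ValueError("fid_lower_bound requires at least 4 real images")
    if split_indices is None:
        perm = np.random.default_rng(seed).permutation(n)
        first, second = perm[: n // 2], perm[n // 2:]
    else:
        first, second = (np.asarray(ix, dtype=int) for ix in split_indices)
    value = compute_fid(arr[first], arr[second], extractor, normalize)
    return SplitFid(value=value, n_first=len(first), n_second=len(second), seed=seed)


def rfid(fid_rs: float, fid_rr: float) -> float:
    """FID ratio: 1 - (FIDrs - FIDrr)/FIDrs, bounded in [0, 1].

    Requires FIDrs > 0 and FIDrr >= 0. Should the empirical lower bound
    exceed FIDrs, the ratio is clamped to 1.0 with a warning, keeping the
    stated bound.
    """
    if fid_rs <= 0:
        raise ValueError(f"fid_rs must be positive, got {fid_rs}")
    if fid_rr < 0:
        raise ValueError(f"fid_rr must be non-negative, got {fid_rr}")
    value = 1.0 - (fid_rs - fid_rr) / fid_rs
    if value > 1.0:
        warnings.warn(
            f"FIDrr ({fid_rr:g}) exceeds FIDrs ({fid_rs:g}); rFID clamped to 1.0",
            stacklevel=2,
        )
        return 1.0
    return value


def evaluate_model(
    model_id: str,
    registry,
    real_set: Sequence[np.ndarray] | np.ndarray,
    n_syn: int,
    extractor: FeatureExtractor,
    normalize: str | bool | None = None,
    seed: int = 0,
    cache_dir=None,
) -> FidReport:
    """Generate synthetic samples and report FIDrr, FIDrs, and rFID.

    Synthetic samples come from the executor (``n_syn`` of them, seeded);
    FIDrr is a seeded half-split of the real set; FIDrs compares real
    against synthetic with set sizes matched by seeded subsampling of the
    larger side.
    """
    from . import executor as _executor  # local import keeps library import light

    real = _stack(real_set)
    rng = np.random.default_rng(seed)

    samples = _executor.generate(
        _executor.GenerationRequest(model_id=model_id, num_samples=n_syn, seed=seed),
        registry, cache_dir,
    )
    syn = _stack([s.image for s in samples])

    rr = fid_lower_bound(real, extractor, normalize, seed=seed)

    n_match = min(real.shape[0], syn.shape[0])
    real_rs = real if real.shape[0] == n_match else real[
        rng.choice(real.shape[0], n_match, replace=False)]
    syn_rs = syn if syn.shape[0] == n_match else syn[
        rng.choice(syn.shape[0], n_match, replace=False)]
    rs = compute_fid(real_rs, syn_rs, extractor, normalize)

    return FidReport(
        model_id=model_id,
        fid_rr=rr.value,
        fid_rs=rs,
        rfid=rfid(rs, rr.value) if rs > 0 else 1.0,
        n_real=real.shape[0],
        n_syn=syn.shape[0],
        normalized=bool(normalize),
        extractor_id=extractor.id,
        seed=seed,
        normalize_mode="" if not normalize else ("bitdepth" if normalize is True else str(normalize)),
        split_sizes=(rr.n_first, rr.n_second),
    )


# ---------------------------------------------------------------------------
# reporting


@dataclass
class ReportTable:
    """CSV text plus (FIDrr, FIDrs) scatter pairs and their linear trend."""

    csv_text: str
    pairs: list[tuple[float, float]] = field(default_factory=list)
    slope: float | None = None
    intercept: float | None = None

    def write(self, path) -> None:
        with open(path, "w", encoding="utf-8", newline="") as fh:
            fh.write(self.csv_text)


def report_table(reports: Sequence[FidReport]) -> ReportTable:
    """Tabulate FID reports as CSV and fit a least-squares FIDrr-FIDrs trend."""
    if not reports:
        raise ValueError("report_table needs at least one report")
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(FidReport.FIELDS)
    for r in reports:
        writer.writerow([getattr(r, f) for f in FidReport.FIELDS])
    pairs = [(r.fid_rr, r.fid_rs) for r in reports]
    slope = intercept = None
    xs = np.array([p[0] for p in pairs])
    ys = np.array([p[1] for p in pairs])
    if len(pairs) >= 2 and np.ptp(xs) > 0:
        slope, intercept = (float(v) for v in np.polyfit(xs, ys, 1))
    return ReportTable(csv_text=buf.getvalue(), pairs=pairs, slope=slope, intercept=intercept)
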