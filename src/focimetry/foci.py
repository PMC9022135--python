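"""Focus (spot) detection and Fisher-linear-discriminant classification.

Candidate foci are local maxima of the scale-normalised multi-scale
Laplacian-of-Gaussian response inside segmented nuclei, detected at
deliberately low stringency; a trainable Fisher Linear Discriminant (FLD)
then separates true foci from background detections.  The FLD keeps its
per-class sufficient statistics (count, mean, scatter), so fine-tuning on
additional labelled examples is exactly equivalent to retraining on the
pooled data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .io import ChannelImage

__all__ = [
    "SpotDetectionParams",
    "SpotCandidate",
    "FldModel",
    "detect_candidates",
    "fld_train",
    "fld_classify",
    "fld_finetune",
    "DEFAULT_FEATURES",
]

#: classification feature set: intensity, shape and context of a candidate.
#: Intensity-derived features enter on a log scale — focus amplitudes are
#: log-normal, spanning decades, and the linear discriminant separates far
#: better in log space.
DEFAULT_FEATURES = (
    "log_integrated_intensity",
    "log_peak_intensity",
    "log_contrast",
    "area_px",
    "roundness",
    "scale_px",
)

_EPS = 1e-9


@dataclass
class SpotDetectionParams:
    """Low-stringency multi-scale LoG detector settings.

    ``response_threshold`` applies to the scale-normalised LoG response
    (sigma^2 * |LoG|), in A.U.; the default is permissive by design — the
    classifier prunes false positives.
    """

    min_sigma_px: float = 1.0
    max_sigma_px: float = 3.0
    n_scales: int = 5
    response_threshold: float = 3.0
    background_annulus_px: tuple[float, float] = (4.0, 8.0)
    max_candidates_per_nucleus: int = 200

    def __post_init__(self) -> None:
        if not 0 < self.min_sigma_px < self.max_sigma_px:
            raise ValueError("need 0 < min_sigma_px < max_sigma_px")
        if self.response_threshold < 0:
            raise ValueError("response_threshold must be >= 0")

    @property
    def sigmas(self) -> np.ndarray:
        return np.linspace(self.min_sigma_px, self.max_sigma_px, self.n_scales)


@dataclass
class SpotCandidate:
    """One candidate focus with the features the classifier sees."""

    nucleus_label: int
    centroid_px: tuple[float, float]
    scale_px: float
    response: float
    peak_intensity: float
    integrated_intensity: float
    area_px: int
    contrast: float
    roundness: float
    score: float = float("nan")
    accepted: bool = False

    @property
    def log_integrated_intensity(self) -> float:
        return float(np.log1p(self.integrated_intensity))

    @property
    def log_peak_intensity(self) -> float:
        return float(np.log1p(max(self.peak_intensity, 0.0)))

    @property
    def log_contrast(self) -> float:
        return float(np.log1p(max(self.contrast, 0.0)))

    def feature_vector(self, names: tuple[str, ...] = DEFAULT_FEATURES) -> np.ndarray:
        try:
            return np.array([getattr(self, n) for n in names], dtype=np.float64)
        except AttributeError as exc:
            raise KeyError(f"candidate is missing feature {exc.name!r}") from exc


def candidates_to_frame(candidates: list[SpotCandidate]) -> pd.DataFrame:
    cols = ["nucleus_label", "row", "col", "scale_px", "response", "peak_intensity",
            "integrated_intensity", "area_px", "contrast", "roundness", "score", "accepted"]
    rows = [
        {
            "nucleus_label": c.nucleus_label,
            "row": c.centroid_px[0],
            "col": c.centroid_px[1],
            "scale_px": c.scale_px,
            "response": c.response,
            "peak_intensity": c.peak_intensity,
            "integrated_intensity": c.integrated_intensity,
            "area_px": c.area_px,
            "contrast": c.contrast,
            "roundness": c.roundness,
            "score": c.score,
            "accepted": c.accepted,
        }
        for c in candidates
    ]
    return pd.DataFrame(rows, columns=cols)


def _annulus_background(pixels: np.ndarray, r0: int, c0: int, radii: tuple[float, float]) -> float:
    """Median intensity in an annulus around (r0, c0), clipped to the image."""
    rin, rout = radii
    h, w = pixels.shape
    half = int(np.ceil(rout))
    rlo, rhi = max(0, r0 - half), min(h, r0 + half + 1)
    clo, chi = max(0, c0 - half), min(w, c0 + half + 1)
    rr, cc = np.mgrid[rlo:rhi, clo:chi]
    d2 = (rr - r0) ** 2 + (cc - c0) ** 2
    sel = (d2 >= rin**2) & (d2 <= rout**2)
    if not sel.any():
        return float(pixels[r0, c0])
    return float(np.median(pixels[rlo:rhi, clo:chi][sel]))


def _featurize(pixels: np.ndarray, r0: int, c0: int, sigma: float, response: float,
               nucleus_label: int, params: SpotDetectionParams) -> SpotCandidate:
    h, w = pixels.shape
    half = int(np.ceil(3 * sigma)) + 1
    rlo, rhi = max(0, r0 - half), min(h, r0 + half + 1)
    clo, chi = max(0, c0 - half), min(w, c0 + half + 1)
    window = pixels[rlo:rhi, clo:chi]
    background = _annulus_background(pixels, r0, c0, params.background_annulus_px)
    peak = float(pixels[r0, c0])

    rr, cc = np.mgrid[rlo:rhi, clo:chi]
    in_disk = (rr - r0) ** 2 + (cc - c0) ** 2 <= (3 * sigma) ** 2
    # unclipped sum keeps pure-noise integrals centred on zero; only the
    # total is floored to honour the non-negativity of the feature
    integrated = float(max((window - background)[in_disk].sum(), 0.0))

    # pixels above half-max (relative to local background) within the window
    half_max = background + 0.5 * (peak - background)
    above = (window >= half_max) & in_disk
    area = int(above.sum())
    if area >= 2:
        ar, ac = np.nonzero(above)
        cov = np.cov(np.vstack([ar, ac]).astype(float))
        evals = np.linalg.eigvalsh(np.atleast_2d(cov))
        roundness = float(np.sqrt(max(evals[0], 0.0) / (evals[-1] + _EPS)))
    else:
        roundness = 1.0
    contrast = float((peak - background) / (background + _EPS))
    return SpotCandidate(
        nucleus_label=nucleus_label,
        centroid_px=(float(r0), float(c0)),
        scale_px=float(sigma),
        response=float(response),
        peak_intensity=peak,
        integrated_intensity=integrated,
        area_px=area,
        contrast=contrast,
        roundness=min(roundness, 1.0),
    )


def detect_candidates(
    image: ChannelImage | np.ndarray,
    labelmap: np.ndarray,
    params: SpotDetectionParams | None = None,
) -> list[SpotCandidate]:
    """Multi-scale LoG candidate detection inside nuclei.

    Local maxima of the scale-normalised negative-LoG response above the
    threshold are kept; duplicates across scales closer than the detection
    sigma are merged (highest response wins); candidates outside all nuclei
    are discarded.
    """
    params = params or SpotDetectionParams()
    pixels = np.asarray(image.pixels if isinstance(image, ChannelImage) else image,
                        dtype=np.float64)
    labelmap = np.asarray(labelmap)
    if pixels.shape != labelmap.shape:
        raise ValueError(f"image shape {pixels.shape} != label map shape {labelmap.shape}")

    raw_hits: list[tuple[float, int, int, float]] = []  # (response, r, c, sigma)
    for sigma in params.sigmas:
        # scale-normalised blob response; positive at bright blobs
        response = -(sigma**2) * ndi.gaussian_laplace(pixels, sigma)
        local_max = (response == ndi.maximum_filter(response, size=3)) & (
            response > params.response_threshold
        )
        local_max &= labelmap > 0
        for r, c in zip(*np.nonzero(local_max)):
            raw_hits.append((float(response[r, c]), int(r), int(c), float(sigma)))

    # merge across scales: strongest first; a weaker maximum is a duplicate
    # of a kept one when they are closer than twice the larger detection
    # sigma — the footprint of the already-detected blob, below which two
    # Gaussians cannot produce separate intensity maxima anyway
    raw_hits.sort(reverse=True)
    kept: list[tuple[float, int, int, float]] = []
    for resp, r, c, sigma in raw_hits:
        if all(
            (r - r2) ** 2 + (c - c2) ** 2 >= (2 * max(sigma, s2)) ** 2
            for _, r2, c2, s2 in kept
        ):
            kept.append((resp, r, c, sigma))

    per_nucleus: dict[int, int] = {}
    candidates: list[SpotCandidate] = []
    for resp, r, c, sigma in kept:
        lab = int(labelmap[r, c])
        if per_nucleus.get(lab, 0) >= params.max_candidates_per_nucleus:
            continue
        per_nucleus[lab] = per_nucleus.get(lab, 0) + 1
        candidates.append(_featurize(pixels, r, c, sigma, resp, lab, params))
    return candidates


# ---------------------------------------------------------------------------
# Fisher Linear Discriminant


class DegenerateTrainingError(ValueError):
    """Class means coincide: no discriminant direction exists."""


class SingularScatterError(np.linalg.LinAlgError):
    """Within-class scatter is singular; retrain with a positive ridge."""


@dataclass
class FldModel:
    """Two-class Fisher Linear Discriminant with stored sufficient statistics.

    ``w = (S_W + ridge*I)^-1 (mu1 - mu0)`` with ``S_W`` the summed
    within-class scatter; the decision threshold is the midpoint of the
    projected class means.  A candidate is a focus iff ``w.x > t``.
    """

    feature_names: tuple[str, ...]
    w: np.ndarray
    threshold: float
    mu_focus: np.ndarray
    mu_background: np.ndarray
    scatter_within: np.ndarray
    ridge: float
    n_focus: int
    n_background: int
    scatter_focus: np.ndarray = field(repr=False, default=None)
    scatter_background: np.ndarray = field(repr=False, default=None)

    def project(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=np.float64) @ self.w

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        return self.project(X) - self.threshold

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "feature_names": list(self.feature_names),
            "w": self.w.tolist(),
            "threshold": self.threshold,
            "mu_focus": self.mu_focus.tolist(),
            "mu_background": self.mu_background.tolist(),
            "scatter_within": self.scatter_within.tolist(),
            "scatter_focus": self.scatter_focus.tolist(),
            "scatter_background": self.scatter_background.tolist(),
            "ridge": self.ridge,
            "n_focus": self.n_focus,
            "n_background": self.n_background,
        }
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(payload, indent=2))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "FldModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            feature_names=tuple(payload["feature_names"]),
            w=np.array(payload["w"]),
            threshold=float(payload["threshold"]),
            mu_focus=np.array(payload["mu_focus"]),
            mu_background=np.array(payload["mu_background"]),
            scatter_within=np.array(payload["scatter_within"]),
            scatter_focus=np.array(payload["scatter_focus"]),
            scatter_background=np.array(payload["scatter_background"]),
            ridge=float(payload["ridge"]),
            n_focus=int(payload["n_focus"]),
            n_background=int(payload["n_background"]),
        )


def _class_stats(X: np.ndarray) -> tuple[int, np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("examples must be a 2D (n, d) array")
    n = X.shape[0]
    mu = X.mean(axis=0)
    dev = X - mu
    return n, mu, dev.T @ dev


def _fld_from_stats(
    n1: int, mu1: np.ndarray, s1: np.ndarray,
    n0: int, mu0: np.ndarray, s0: np.ndarray,
    ridge: float | None,
    feature_names: tuple[str, ...],
) -> FldModel:
    d = mu1.shape[0]
    if np.allclose(mu1, mu0):
        raise DegenerateTrainingError("class means coincide; cannot train a discriminant")
    s_w = s1 + s0
    if ridge is None:
        ridge = 1e-6 * np.trace(s_w) / d
    if ridge == 0:
        if np.linalg.matrix_rank(s_w) < d:
            raise SingularScatterError(
                "within-class scatter is singular; pass a positive ridge"
            )
        w = np.linalg.solve(s_w, mu1 - mu0)
    else:
        w = np.linalg.solve(s_w + ridge * np.eye(d), mu1 - mu0)
    t = float(0.5 * (w @ mu1 + w @ mu0))
    return FldModel(
        feature_names=feature_names,
        w=w,
        threshold=t,
        mu_focus=mu1,
        mu_background=mu0,
        scatter_within=s_w,
        ridge=float(ridge),
        n_focus=n1,
        n_background=n0,
        scatter_focus=s1,
        scatter_background=s0,
    )


def fld_train(
    focus_examples: np.ndarray,
    background_examples: np.ndarray,
    ridge: float | None = None,
    feature_names: tuple[str, ...] = DEFAULT_FEATURES,
) -> FldModel:
    """Train the FLD on labelled feature matrices (rows = examples).

    ``ridge=None`` uses the default ``1e-6 * trace(S_W)/d``; ``ridge=0``
    requests the exact closed form and raises if ``S_W`` is singular.
    """
    n1, mu1, s1 = _class_stats(focus_examples)
    n0, mu0, s0 = _class_stats(background_examples)
    if n1 < 2 or n0 < 2:
        raise ValueError("need >= 2 examples per class")
    if mu1.shape != mu0.shape:
        raise ValueError("feature dimensions differ between classes")
    if len(feature_names) != mu1.shape[0]:
        feature_names = tuple(f"f{i}" for i in range(mu1.shape[0]))
    return _fld_from_stats(n1, mu1, s1, n0, mu0, s0, ridge, feature_names)


def fld_finetune(
    model: FldModel,
    new_focus: np.ndarray | None = None,
    new_background: np.ndarray | None = None,
    ridge: float | None = None,
) -> FldModel:
    """Retrain on the union of stored statistics and new examples.

    Per-class count, mean and scatter are additive, so this equals training
    on the pooled data exactly.  Passing examples for only one class keeps
    the other class's statistics.
    """

    def merge(n_a, mu_a, s_a, X):
        if X is None or len(X) == 0:
            return n_a, mu_a, s_a
        n_b, mu_b, s_b = _class_stats(X)
        n = n_a + n_b
        mu = (n_a * mu_a + n_b * mu_b) / n
        delta = mu_b - mu_a
        s = s_a + s_b + (n_a * n_b / n) * np.outer(delta, delta)
        return n, mu, s

    n1, mu1, s1 = merge(model.n_focus, model.mu_focus, model.scatter_focus, new_focus)
    n0, mu0, s0 = merge(model.n_background, model.mu_background,
                        model.scatter_background, new_background)
    return _fld_from_stats(n1, mu1, s1, n0, mu0, s0,
                           model.ridge if ridge is None else ridge,
                           model.feature_names)


def fld_classify(model: FldModel, candidates: list[SpotCandidate]) -> list[SpotCandidate]:
    """Score candidates in place (order preserved): accepted iff ``w.x - t > 0``."""
    for cand in candidates:
        x = cand.feature_vector(model.feature_names)
        cand.score = float(model.w @ x - model.threshold)
        cand.accepted = cand.score > 0
    return candidates
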