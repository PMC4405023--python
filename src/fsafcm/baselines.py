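"""Reference spatially regularized FCM baselines behind one interface.

Five classical algorithms are provided for comparison against the
self-adaptive method: plain FCM, FCM_S (neighborhood term in the objective),
EnFCM (FCM over the gray-level histogram of a linearly filtered image),
FGFCM (histogram clustering of a similarity-filtered image) and FLICM
(parameter-free fuzzy local information factor).  All five share the
package's initialization, center-based convergence test, defuzzification and
bright-cluster foreground rule, so iteration-count comparisons measure the
algorithms rather than the harness.

Default parameters are the comparison settings used throughout: ``m = 2``,
``alpha = 0.85``, ``epsilon = 0.001``, ``lambda_g = 6`` and ``N_R = 9``
(3x3 windows).  FGFCM's spatial scale ``lambda_s`` defaults to 3, the value
recommended by its original publication.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import correlate, uniform_filter

from .core import (
    FuzzyState,
    SegmentationResult,
    defuzzify,
    fcm_membership,
    fcm_objective,
    initial_centers,
    update_centers,
)
from .errors import MissingTraceError, ParameterError
from .imaging import NeighborhoodModel, _padded_views, as_gray_image

__all__ = ["BaselineConfig", "baseline_segment", "objective_trace", "ALGORITHMS"]

ALGORITHMS = ("fcm", "fcm_s", "enfcm", "fgfcm", "flicm")


@dataclass
class BaselineConfig:
    """Shared parameter set of the five comparison algorithms."""

    algorithm: str = "fcm"
    C: int = 2
    m: float = 2.0
    alpha: float = 0.85
    lambda_g: float = 6.0
    lambda_s: float = 3.0
    N_R: int = 9
    epsilon: float = 1e-3
    L_max: int = 100
    seed: int = 0
    trace: bool = True

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ParameterError(
                f"unknown algorithm {self.algorithm!r}; choose from {ALGORITHMS}"
            )
        if self.C < 2:
            raise ParameterError(f"cluster count C must be >= 2, got {self.C}")
        if self.m <= 1.0:
            raise ParameterError(f"fuzzifier m must be > 1, got {self.m}")
        if self.alpha < 0:
            raise ParameterError(f"alpha must be >= 0, got {self.alpha}")
        if self.lambda_g <= 0 or self.lambda_s <= 0:
            raise ParameterError("lambda_g and lambda_s must be > 0")
        side = round(self.N_R**0.5)
        if side * side != self.N_R or side % 2 == 0 or side < 3:
            raise ParameterError(
                f"N_R must be an odd square window size (9, 25, ...), got {self.N_R}"
            )
        if self.epsilon <= 0 or self.L_max < 1:
            raise ParameterError("epsilon must be > 0 and L_max >= 1")

    @property
    def window_radius(self) -> int:
        return (round(self.N_R**0.5) - 1) // 2


def _membership_from_distance2(D2: np.ndarray, m: float) -> np.ndarray:
    """Memberships from per-cluster squared distances, with the zero-distance rule."""
    zero = D2 == 0.0
    has_zero = zero.any(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        w = D2 ** (-1.0 / (m - 1.0))
        U = w / w.sum(axis=0)
    if has_zero.any():
        U[:, has_zero] = zero[:, has_zero] / zero[:, has_zero].sum(axis=0)
    return U


def _finalize(
    cfg: BaselineConfig,
    shape: tuple[int, int],
    U: np.ndarray,
    V: np.ndarray,
    iterations: int,
    converged: bool,
    trace: list[float] | None,
) -> SegmentationResult:
    labels = defuzzify(U).reshape(shape)
    fg = int(np.argmax(V))
    state = FuzzyState(
        U=U,
        U_fused=U,
        V=V,
        iteration=iterations,
        objective=trace[-1] if trace else float("nan"),
    )
    return SegmentationResult(
        labels=labels,
        foreground_mask=labels == fg,
        state=state,
        iterations_run=iterations,
        converged=converged,
        seed=cfg.seed,
        algorithm=cfg.algorithm,
        trace=trace,
    )


def _run_fcm(x: np.ndarray, cfg: BaselineConfig):
    V = initial_centers(x, cfg.C, cfg.m, cfg.seed)
    trace: list[float] | None = [] if cfg.trace else None
    U = None
    converged = False
    iterations = 0
    for it in range(1, cfg.L_max + 1):
        iterations = it
        U = fcm_membership(x, V, cfg.m)
        V_new = update_centers(x, None, U, cfg.m, "plain")
        if trace is not None:
            trace.append(fcm_objective(x, U, V_new, cfg.m))
        delta = float(np.abs(V_new - V).max())
        V = V_new
        if delta < cfg.epsilon:
            converged = True
            break
    return U, V, iterations, converged, trace


def _run_fcm_s(x: np.ndarray, shape, cfg: BaselineConfig):
    side = 2 * cfg.window_radius + 1
    img2d = x.reshape(shape)
    xbar = uniform_filter(img2d, size=side, mode="nearest").ravel()
    msq = uniform_filter(img2d**2, size=side, mode="nearest").ravel()
    a = cfg.alpha
    V = initial_centers(x, cfg.C, cfg.m, cfg.seed)
    trace: list[float] | None = [] if cfg.trace else None
    U = None
    converged = False
    iterations = 0
    for it in range(1, cfg.L_max + 1):
        iterations = it
        # (alpha/N_R) sum_r (x_r - v)^2 expands to alpha*(E[x^2] - 2 v E[x] + v^2)
        nbr = np.clip(msq[None, :] - 2.0 * V[:, None] * xbar[None, :] + V[:, None] ** 2, 0.0, None)
        D2 = (x[None, :] - V[:, None]) ** 2 + a * nbr
        U = _membership_from_distance2(D2, cfg.m)
        w = U**cfg.m
        V_new = (w @ (x + a * xbar)) / ((1.0 + a) * w.sum(axis=1))
        if trace is not None:
            trace.append(fcm_objective(x, U, V_new, cfg.m))
        delta = float(np.abs(V_new - V).max())
        V = V_new
        if delta < cfg.epsilon:
            converged = True
            break
    return U, V, iterations, converged, trace


def _histogram_fcm(xi: np.ndarray, cfg: BaselineConfig):
    """FCM over the gray-level histogram of a filtered image ``xi``.

    Iterates over the (at most L) distinct rounded levels, weighting each by
    its pixel count; memberships are expanded back to pixels at the end.
    """
    levels_img = np.rint(xi).astype(np.int64)
    vals, inverse, gamma = np.unique(
        levels_img.ravel(), return_inverse=True, return_counts=True
    )
    lv = vals.astype(np.float64)
    gw = gamma.astype(np.float64)
    V = initial_centers(lv, cfg.C, cfg.m, cfg.seed, weights=gw)
    trace: list[float] | None = [] if cfg.trace else None
    U = None
    converged = False
    iterations = 0
    for it in range(1, cfg.L_max + 1):
        iterations = it
        U = fcm_membership(lv, V, cfg.m)
        w = U**cfg.m * gw[None, :]
        V_new = (w @ lv) / w.sum(axis=1)
        if trace is not None:
            trace.append(float((w * (lv[None, :] - V_new[:, None]) ** 2).sum()))
        delta = float(np.abs(V_new - V).max())
        V = V_new
        if delta < cfg.epsilon:
            converged = True
            break
    U_pix = U[:, inverse]
    return U_pix, V, iterations, converged, trace


def _run_enfcm(x: np.ndarray, shape, cfg: BaselineConfig):
    side = 2 * cfg.window_radius + 1
    xbar = uniform_filter(x.reshape(shape), size=side, mode="nearest").ravel()
    xi = (x + cfg.alpha * xbar) / (1.0 + cfg.alpha)
    return _histogram_fcm(xi.reshape(shape), cfg)


def _fgfcm_filtered_image(img2d: np.ndarray, cfg: BaselineConfig) -> np.ndarray:
    """FGFCM's nonlinearly filtered image.

    Each pixel is replaced by a similarity-weighted mean of its window
    *neighbors* (center excluded), with similarity the product of a spatial
    kernel ``exp(-max(|dy|,|dx|)/lambda_s)`` and a gray kernel
    ``exp(-(x_j - x_r)^2 / (lambda_g * sigma_j^2))`` where ``sigma_j^2`` is
    the mean squared gray difference to the window neighbors.
    """
    rb = cfg.window_radius
    nb = NeighborhoodModel(rb)
    offsets = nb.offsets()
    views = list(_padded_views(img2d, nb))
    diffs2 = []
    for (dy, dx), view in zip(offsets, views):
        if dy == 0 and dx == 0:
            diffs2.append(None)
            continue
        diffs2.append((img2d - view) ** 2)
    sigma2 = sum(d for d in diffs2 if d is not None) / (nb.window_size - 1)
    sigma2_safe = np.where(sigma2 > 0, sigma2, 1.0)
    num = np.zeros_like(img2d)
    den = np.zeros_like(img2d)
    for (dy, dx), view, d2 in zip(offsets, views, diffs2):
        if d2 is None:
            continue
        s_spatial = np.exp(-max(abs(dy), abs(dx)) / cfg.lambda_s)
        s_gray = np.where(sigma2 > 0, np.exp(-d2 / (cfg.lambda_g * sigma2_safe)), 1.0)
        S = s_spatial * s_gray
        num += S * view
        den += S
    return num / den


def _run_fgfcm(x: np.ndarray, shape, cfg: BaselineConfig):
    xi = _fgfcm_filtered_image(x.reshape(shape), cfg)
    return _histogram_fcm(xi, cfg)


def _run_flicm(x: np.ndarray, shape, cfg: BaselineConfig):
    rb = cfg.window_radius
    side = 2 * rb + 1
    ky, kx = np.mgrid[-rb : rb + 1, -rb : rb + 1]
    kernel = 1.0 / (1.0 + np.hypot(ky, kx))
    kernel[rb, rb] = 0.0  # the fuzzy factor runs over neighbors only
    rng = np.random.default_rng(cfg.seed)
    U = rng.random((cfg.C, x.size))
    U /= U.sum(axis=0)
    w0 = U**cfg.m
    V = (w0 @ x) / w0.sum(axis=1)
    trace: list[float] | None = [] if cfg.trace else None
    converged = False
    iterations = 0
    for it in range(1, cfg.L_max + 1):
        iterations = it
        D2 = np.empty((cfg.C, x.size))
        for i in range(cfg.C):
            Q = ((1.0 - U[i]) ** cfg.m * (x - V[i]) ** 2).reshape(shape)
            G = correlate(Q, kernel, mode="nearest").ravel()
            D2[i] = (x - V[i]) ** 2 + G
        U = _membership_from_distance2(D2, cfg.m)
        w = U**cfg.m
        V_new = (w @ x) / w.sum(axis=1)
        if trace is not None:
            trace.append(fcm_objective(x, U, V_new, cfg.m))
        delta = float(np.abs(V_new - V).max())
        V = V_new
        if delta < cfg.epsilon:
            converged = True
            break
    return U, V, iterations, converged, trace


_RUNNERS = {
    "fcm": lambda x, shape, cfg: _run_fcm(x, cfg),
    "fcm_s": _run_fcm_s,
    "enfcm": _run_enfcm,
    "fgfcm": _run_fgfcm,
    "flicm": _run_flicm,
}


def baseline_segment(image, config: BaselineConfig | None = None) -> SegmentationResult:
    """Segment an image with one of the five comparison algorithms.

    Returns the same :class:`~fsafcm.core.SegmentationResult` contract as
    :func:`~fsafcm.core.fsafcm_segment`; the run is reproducible from
    ``config.seed``.
    """
    config = config or BaselineConfig()
    img = as_gray_image(image)
    x = img.pixels.ravel()
    if np.ptp(x) == 0.0:
        warnings.warn(
            "constant image: segmentation is degenerate, all pixels labeled 0",
            stacklevel=2,
        )
        U = np.zeros((config.C, x.size))
        U[0] = 1.0
        V = np.full(config.C, float(x[0]))
        res = _finalize(config, img.shape, U, V, 0, True, [] if config.trace else None)
        res.foreground_mask = np.zeros(img.shape, dtype=bool)
        return res
    U, V, iterations, converged, trace = _RUNNERS[config.algorithm](x, img.shape, config)
    return _finalize(config, img.shape, U, V, iterations, converged, trace)


def objective_trace(result: SegmentationResult) -> list[float]:
    """Per-iteration objective values of a run made with tracing enabled."""
    if result.trace is None:
        raise MissingTraceError("run was made with trace disabled")
    return result.trace
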