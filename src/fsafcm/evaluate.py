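"""Quantitative evaluation of segmentations against ground truth.

Two figures of merit are used throughout the package:

* the signed area error rate ``100 * (e_m - e_a) / e_m`` between the
  reference (manual/truth) measure ``e_m`` and the algorithm measure
  ``e_a`` — positive for undersegmentation (algorithm region smaller than
  the reference), negative for oversegmentation;
* the plain misclassification fraction, i.e. the share of pixels whose
  foreground/background assignment disagrees with the truth mask.

``e`` is taken as segmented nodule *area* in pixels by default — the
convention under which the sign reading above is coherent — with a
boundary-length mode available for perimeter-based comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.measure import perimeter

from .core import FsafcmConfig, SegmentationResult, fsafcm_segment
from .baselines import ALGORITHMS, BaselineConfig, baseline_segment
from .errors import ConsistencyError, ParameterError
from .phantoms import Phantom

__all__ = [
    "ErrorRateReport",
    "error_rate",
    "misclassification",
    "segment_with",
    "run_comparison",
    "error_rate_histogram",
    "proportion_within",
    "save_error_rate_histogram",
]


@dataclass
class ErrorRateReport:
    """Signed segmentation error rate and its direction."""

    e_m: float
    e_a: float
    rate_percent: float
    direction: str  # "under" | "over" | "exact"


def error_rate(auto_mask, truth_mask, measure: str = "area") -> ErrorRateReport:
    """Signed error rate ``100 * (e_m - e_a) / e_m`` between two binary masks.

    ``measure="area"`` compares pixel counts (default); ``"boundary"``
    compares mask perimeters.  Raises ``ZeroDivisionError`` when the truth
    measure is zero.
    """
    auto = np.asarray(auto_mask, dtype=bool)
    truth = np.asarray(truth_mask, dtype=bool)
    if auto.shape != truth.shape:
        raise ConsistencyError("masks have different shapes")
    if measure == "area":
        e_m, e_a = float(truth.sum()), float(auto.sum())
    elif measure == "boundary":
        e_m, e_a = float(perimeter(truth)), float(perimeter(auto))
    else:
        raise ParameterError(f"unknown measure {measure!r}; use 'area' or 'boundary'")
    if e_m == 0.0:
        raise ZeroDivisionError("truth mask measure is zero")
    rate = 100.0 * (e_m - e_a) / e_m
    direction = "exact" if rate == 0.0 else ("under" if rate > 0.0 else "over")
    return ErrorRateReport(e_m=e_m, e_a=e_a, rate_percent=rate, direction=direction)


def misclassification(foreground_mask, truth_mask) -> float:
    """Fraction of pixels whose foreground/background assignment is wrong."""
    fg = np.asarray(foreground_mask, dtype=bool)
    truth = np.asarray(truth_mask, dtype=bool)
    if fg.shape != truth.shape:
        raise ConsistencyError("masks have different shapes")
    return float(np.mean(fg != truth))


def segment_with(algorithm: str, image, seed: int = 0, **overrides) -> SegmentationResult:
    """Dispatch an image to the named algorithm ('fsafcm' or a baseline)."""
    if algorithm == "fsafcm":
        return fsafcm_segment(image, FsafcmConfig(seed=seed, **overrides))
    if algorithm in ALGORITHMS:
        return baseline_segment(
            image, BaselineConfig(algorithm=algorithm, seed=seed, **overrides)
        )
    raise ParameterError(f"unknown algorithm {algorithm!r}")


def run_comparison(
    phantom_suite: list[Phantom],
    algorithms: list[str],
    seeds: list[int],
    **overrides,
) -> pd.DataFrame:
    """Run every (phantom, algorithm, seed) cell and tabulate the outcomes.

    Returns a long-format table with one row per cell: phantom index and
    kind, algorithm, seed, iterations, misclassification, signed error rate
    and convergence flag.  A failing cell is recorded with missing metrics
    and the run continues.
    """
    if not phantom_suite:
        raise ParameterError("phantom suite is empty")
    rows = []
    for idx, ph in enumerate(phantom_suite):
        for algorithm in algorithms:
            for seed in seeds:
                row = {
                    "phantom": idx,
                    "kind": ph.kind,
                    "algorithm": algorithm,
                    "seed": seed,
                    "iterations": np.nan,
                    "misclassification": np.nan,
                    "error_rate": np.nan,
                    "converged": False,
                }
                try:
                    res = segment_with(algorithm, ph.image, seed=seed, **overrides)
                    row["iterations"] = res.iterations_run
                    row["misclassification"] = misclassification(
                        res.foreground_mask, ph.truth_mask
                    )
                    row["error_rate"] = error_rate(
                        res.foreground_mask, ph.truth_mask
                    ).rate_percent
                    row["converged"] = res.converged
                except Exception:  # noqa: BLE001 - one failed cell must not stop the sweep
                    pass
                rows.append(row)
    return pd.DataFrame(rows)


def error_rate_histogram(
    rates, bin_width: float = 50.0, lo: float = -200.0, hi: float = 100.0
):
    """Histogram of signed error rates in fixed percentage bands.

    The default bands step by 50 percentage points between -200 and +100,
    the range over which clinical error-rate distributions are reported.
    Returns ``(counts, edges)``.
    """
    if bin_width <= 0:
        raise ParameterError("bin width must be > 0")
    edges = np.arange(lo, hi + bin_width, bin_width)
    counts, _ = np.histogram(np.asarray(rates, dtype=float), bins=edges)
    return counts, edges


def proportion_within(rates, lo: float = -50.0, hi: float = 50.0) -> float:
    """Share of error rates falling inside the band ``[lo, hi]`` percent."""
    r = np.asarray(rates, dtype=float)
    r = r[np.isfinite(r)]
    if r.size == 0:
        raise ParameterError("no finite error rates given")
    return float(np.mean((r >= lo) & (r <= hi)))


def save_error_rate_histogram(rates, path, bin_width: float = 50.0) -> None:
    """Write a PNG bar chart of the banded error-rate distribution."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    counts, edges = error_rate_histogram(rates, bin_width=bin_width)
    centers = (edges[:-1] + edges[1:]) / 2.0
    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.bar(centers, counts, width=0.9 * bin_width, color="#4878b0", edgecolor="black")
    ax.set_xlabel("rate of wrong segmentation (%)")
    ax.set_ylabel("number of nodules")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
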