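"""Editor-to-editor comparison by total least squares.

Two editors measured on the same library give paired per-member efficiencies
(x, y), both subject to measurement error, so the relationship is fitted by
total least squares (orthogonal regression) rather than ordinary least
squares, which would be attenuated toward zero.  The line is constrained
through the origin, y = beta * x; the average fold change between editors is
the reciprocal of the regression weight, 1 / beta.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .library import C_TO_T
from .quantify import QuantResults


@dataclass
class TLSFit:
    """Origin-constrained orthogonal regression fit y = slope * x."""

    slope: float
    n_points: int
    orthogonal_rms: float
    intercept: float = 0.0
    #: percentile bootstrap CI over members for the fold change, if requested
    fold_change_ci: tuple[float, float] | None = None

    @property
    def fold_change(self) -> float:
        """Average fold change of x relative to y: 1 / slope."""
        if self.slope == 0:
            return float("nan")
        return 1.0 / self.slope

    def summary(self) -> str:
        lines = [
            "Total least squares (orthogonal) regression",
            f"  n = {self.n_points} members",
            f"  slope        {self.slope:.4f}",
            f"  fold change  {self.fold_change:.4f}  (reciprocal of slope)",
            f"  orthogonal RMS residual {self.orthogonal_rms:.4g}",
        ]
        if self.intercept != 0.0:
            lines.insert(3, f"  intercept    {self.intercept:.4f}")
        if self.fold_change_ci is not None:
            lo, hi = self.fold_change_ci
            lines.append(f"  fold change 95% CI  [{lo:.4f}, {hi:.4f}]")
        return "\n".join(lines)


def _tls_slope(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Slope through the origin minimising squared orthogonal distances.

    Closed form from the eigen-decomposition of the 2x2 second-moment matrix:
    the best-fit direction is the leading eigenvector, and the summed squared
    orthogonal distance is the trailing eigenvalue.
    """
    m = np.array([[x @ x, x @ y], [x @ y, y @ y]])
    evals, evecs = np.linalg.eigh(m)  # ascending
    v = evecs[:, -1]
    if v[0] == 0:
        raise ValueError("degenerate point cloud: best-fit line is vertical")
    slope = v[1] / v[0]
    rms = float(np.sqrt(max(evals[0], 0.0) / len(x)))
    return float(slope), rms


def tls_fit(
    x,
    y,
    intercept: bool = False,
    bootstrap: int = 0,
    rng_seed: int = 0,
) -> TLSFit:
    """Fit y = beta * x by total least squares.

    Parameters
    ----------
    x, y
        Paired per-member efficiencies of editors A and B.
    intercept
        Fit the mean-centered (Deming, equal error variances) variant and
        report the implied intercept; the default is origin-constrained so
        that the fold change 1/beta is meaningful.
    bootstrap
        If > 0, percentile-bootstrap the fold change over members with this
        many resamples (seeded).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and aligned")
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if len(x) < 3:
        raise ValueError("need >= 3 paired observations")
    if np.all(x == 0) and np.all(y == 0):
        raise ValueError("degenerate point cloud: all points at the origin")

    if intercept:
        mx, my = x.mean(), y.mean()
        slope, rms = _tls_slope(x - mx, y - my)
        fit = TLSFit(
            slope=slope, n_points=len(x), orthogonal_rms=rms,
            intercept=float(my - slope * mx),
        )
    else:
        slope, rms = _tls_slope(x, y)
        fit = TLSFit(slope=slope, n_points=len(x), orthogonal_rms=rms)

    if bootstrap > 0:
        rng = np.random.default_rng(rng_seed)
        folds = []
        for _ in range(bootstrap):
            idx = rng.integers(0, len(x), len(x))
            try:
                s, _ = _tls_slope(x[idx], y[idx])
            except ValueError:
                continue
            if s != 0:
                folds.append(1.0 / s)
        if folds:
            lo, hi = np.percentile(folds, [2.5, 97.5])
            fit.fold_change_ci = (float(lo), float(hi))
    return fit


def compare_editors(
    results_a: QuantResults,
    results_b: QuantResults,
    mutation: tuple[str, str] = C_TO_T,
    target_pos: int = 6,
    intercept: bool = False,
    bootstrap: int = 0,
    rng_seed: int = 0,
) -> dict:
    """Side-by-side comparison of two editors quantified on the same library.

    Fits TLS on member-level pooled efficiencies of ``mutation`` at the
    designed target position (x = editor A, y = editor B) and reports both
    editors' peak/average efficiencies and editing windows.
    """
    ref, alt = mutation
    eff_a = _target_efficiencies(results_a, mutation, target_pos)
    eff_b = _target_efficiencies(results_b, mutation, target_pos)
    if eff_a.empty:
        raise ValueError("editor A has no usable member efficiencies")
    if eff_b.empty:
        raise ValueError("editor B has no usable member efficiencies")
    joined = pd.concat([eff_a.rename("a"), eff_b.rename("b")], axis=1, join="inner")
    if joined.empty:
        raise ValueError("editors share no library members")
    fit = tls_fit(
        joined["a"], joined["b"],
        intercept=intercept, bootstrap=bootstrap, rng_seed=rng_seed,
    )
    return {
        "mutation": f"{ref}2{alt}",
        "tls": fit,
        "n_members": int(len(joined)),
        "editor_a": _editor_summary(results_a),
        "editor_b": _editor_summary(results_b),
    }


def _target_efficiencies(
    results: QuantResults, mutation: tuple[str, str], target_pos: int = 6
) -> pd.Series:
    ref, alt = mutation
    pooled = results.pooled
    sel = pooled[
        (pooled["ref_base"] == ref)
        & (pooled["alt_base"] == alt)
        & np.isfinite(pooled["efficiency"])
        & (pooled["position"] == target_pos)
    ]
    return sel.set_index("member_id")["efficiency"]


def _editor_summary(results: QuantResults) -> dict:
    return {
        "peak_position": int(results.peak_position),
        "peak_efficiency": float(results.peak_efficiency),
        "window": sorted(int(p) for p in results.window),
        "average_efficiency": {
            k: float(v) for k, v in results.average_efficiency.items()
        },
        "selectivity": float(results.selectivity),
    }
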