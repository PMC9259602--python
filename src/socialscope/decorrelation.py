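"""Pattern-decorrelation statistics on pairwise correlation distributions.

For one (session, stimulus) epoch the dF/F traces are restricted to the
concatenated interaction-bout frames and the Pearson correlation of every
unordered neuron pair is pooled into a distribution.  Its width is
summarized by the full width at half maximum (FWHM) of a Gaussian-kernel
density estimate; a narrower distribution for the preferred stimulus is
the signature of pattern decorrelation.  Delta-FWHM per session is related
to the behavioral discrimination index by ordinary least squares across
subjects.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .behavior import PREFERRED_STIMULUS, InteractionBout
from .events import TraceMatrix

__all__ = [
    "CorrelationDistribution",
    "epoch_correlations",
    "fwhm",
    "strong_pairs",
    "top_fraction",
    "delta_fwhm",
    "decorr_regression",
]

GAUSSIAN_FWHM_FACTOR = 2.0 * math.sqrt(2.0 * math.log(2.0))  # 2.3548...


@dataclass
class CorrelationDistribution:
    """Pooled pairwise Pearson r for one (session, stimulus) epoch set."""

    session_id: str
    stimulus: str
    values: np.ndarray  # n(n-1)/2 coefficients
    n_frames: int
    n_neurons: int
    fwhm: float | None = None
    ok: bool = True
    note: str = ""
    estimator: dict = field(default_factory=dict)


def epoch_correlations(
    traces: TraceMatrix,
    bouts: list[InteractionBout],
    stimulus: str,
    session_id: str = "S1",
    min_frames: int = 50,
    compute_fwhm: bool = True,
    min_values_for_fwhm: int = 100,
) -> CorrelationDistribution:
    """Pairwise Pearson r over the concatenated bout frames of one stimulus.

    Neurons with zero variance over the epoch are excluded (logged in the
    result note).  With fewer than ``min_frames`` epoch frames the result
    is flagged not-ok and carries no FWHM.
    """
    frames = np.concatenate(
        [np.arange(b.start, b.end) for b in bouts if b.stimulus == stimulus]
        or [np.empty(0, dtype=int)]
    ).astype(int)
    if frames.size < min_frames:
        return CorrelationDistribution(
            session_id=session_id,
            stimulus=stimulus,
            values=np.empty(0),
            n_frames=int(frames.size),
            n_neurons=traces.n_neurons,
            ok=False,
            note=f"only {frames.size} epoch frames < min_frames={min_frames}",
        )
    sub = traces.values[:, frames]
    var = sub.var(axis=1)
    keep = var > 0
    n_dropped = int((~keep).sum())
    sub = sub[keep]
    if sub.shape[0] < 2:
        return CorrelationDistribution(
            session_id=session_id,
            stimulus=stimulus,
            values=np.empty(0),
            n_frames=int(frames.size),
            n_neurons=traces.n_neurons,
            ok=False,
            note="fewer than 2 neurons with variance over the epoch",
        )
    R = np.corrcoef(sub)
    iu = np.triu_indices_from(R, k=1)
    values = R[iu]
    dist = CorrelationDistribution(
        session_id=session_id,
        stimulus=stimulus,
        values=values,
        n_frames=int(frames.size),
        n_neurons=int(sub.shape[0]),
        note=f"{n_dropped} zero-variance neurons dropped" if n_dropped else "",
    )
    if compute_fwhm and values.size >= min_values_for_fwhm:
        dist.fwhm, dist.estimator = _fwhm_with_meta(values)
    return dist


def _fwhm_with_meta(
    values: np.ndarray, grid_points: int = 512, bw_method="silverman"
) -> tuple[float, dict]:
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise ValueError("empty input")
    if np.ptp(values) == 0:
        warnings.warn("degenerate input for FWHM (all values identical); returning 0")
        return 0.0, {"degenerate": True}
    kde = stats.gaussian_kde(values, bw_method=bw_method)
    bw_sd = float(np.sqrt(kde.covariance[0, 0]))
    lo = min(-1.0, values.min() - 3 * bw_sd)
    hi = max(1.0, values.max() + 3 * bw_sd)
    grid = np.linspace(lo, hi, grid_points)
    density = kde(grid)
    peak = int(np.argmax(density))
    half = density[peak] / 2.0
    above = density >= half
    left = int(np.argmax(above))  # outermost left crossing
    right = int(len(above) - 1 - np.argmax(above[::-1]))
    # linear interpolation of each crossing
    def _interp(i_out: int, i_in: int) -> float:
        d0, d1 = density[i_out], density[i_in]
        if d1 == d0:
            return grid[i_in]
        frac = (half - d0) / (d1 - d0)
        return grid[i_out] + frac * (grid[i_in] - grid[i_out])

    x_left = grid[0] if left == 0 else _interp(left - 1, left)
    x_right = grid[-1] if right == len(grid) - 1 else _interp(right + 1, right)
    meta = {
        "grid": (lo, hi, grid_points),
        "bandwidth_sd": bw_sd,
        "mode": float(grid[peak]),
        "half_max": float(half),
    }
    return float(x_right - x_left), meta


def fwhm(values: np.ndarray, grid_points: int = 512, bw_method="silverman") -> float:
    """FWHM of a Gaussian-KDE density (Silverman bandwidth by default).

    The width is the distance between the outermost half-maximum crossings
    around the global mode, located by linear interpolation on a
    ``grid_points`` grid covering at least [-1, 1].  For Normal(0, sigma)
    samples this converges to 2 sqrt(2 ln 2) sigma.
    """
    return _fwhm_with_meta(values, grid_points, bw_method)[0]


def strong_pairs(values: np.ndarray, threshold: float = 0.2) -> np.ndarray:
    """Keep strongly correlated pairs: |r| >= threshold."""
    values = np.asarray(values, dtype=float)
    return values[np.abs(values) >= threshold]


def top_fraction(values: np.ndarray, fraction: float = 0.05) -> np.ndarray:
    """The ceil(fraction x n) largest values (stable order among ties)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty input")
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    k = math.ceil(fraction * values.size)
    order = np.argsort(-values, kind="stable")
    return values[order[:k]]


def delta_fwhm(
    session_id: str,
    fwhm_by_stimulus: dict[str, float | None],
    preferred_positive: bool = True,
) -> float:
    """FWHM(non-preferred) - FWHM(preferred) for one session.

    S1/S2 compare object O against mouse M1 (preferred M1); S3 compares
    familiar M1 against novel M2 (preferred M2).  A positive value under
    the default convention means the correlation distribution was narrower
    (more decorrelated) for the preferred-class stimulus.  Flip the sign
    with ``preferred_positive=False``.  Missing FWHMs yield NaN.
    """
    pref = PREFERRED_STIMULUS[session_id]
    others = [s for s in fwhm_by_stimulus if s != pref]
    if pref not in fwhm_by_stimulus or len(others) != 1:
        raise ValueError(
            f"session {session_id}: need FWHM for {pref} and exactly one other stimulus, "
            f"got {sorted(fwhm_by_stimulus)}"
        )
    f_pref = fwhm_by_stimulus[pref]
    f_other = fwhm_by_stimulus[others[0]]
    if f_pref is None or f_other is None or not np.isfinite([f_pref, f_other]).all():
        warnings.warn(f"delta FWHM undefined for session {session_id}")
        return float("nan")
    d = f_other - f_pref
    return d if preferred_positive else -d


def decorr_regression(delta_fwhms: np.ndarray, dis: np.ndarray) -> dict:
    """OLS fit and Pearson correlation of delta-FWHM against DI across subjects.

    Returns ``{"slope", "intercept", "r", "p", "n", "defined"}``; undefined
    when either variable has zero variance or fewer than 3 subjects remain
    after dropping non-finite pairs.
    """
    x = np.asarray(dis, dtype=float)
    y = np.asarray(delta_fwhms, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if x.size < 3:
        raise ValueError(f"need >= 3 subjects with finite values, got {x.size}")
    if np.std(x) == 0 or np.std(y) == 0:
        warnings.warn("regression undefined: zero variance")
        return {
            "slope": float("nan"),
            "intercept": float("nan"),
            "r": float("nan"),
            "p": float("nan"),
            "n": int(x.size),
            "defined": False,
        }
    fit = stats.linregress(x, y)
    return {
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "r": float(fit.rvalue),
        "p": float(fit.pvalue),
        "n": int(x.size),
        "defined": True,
    }
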