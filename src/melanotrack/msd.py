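"""Time-averaged mean-square displacement and power-law exponent fitting.

For a track r(t) sampled every Δt, the time-averaged MSD at lag τ = m·Δt is
the mean of |r(t+τ) − r(t)|² over all overlapping ordered frame pairs. The
curve is summarized by the power law MSD(τ) ≈ b·τ^α fitted by least squares
in log–log space; the exponent α is the motion descriptor: α ≈ 1 diffusive,
α → 2 directed, α < 1 tethered/confined (or noise-dominated).

By default the fit uses the first 10 positive lags of the curve. Long-lag
time-averaged MSD values are built from few effectively independent
displacement pairs; their relative sampling variance grows like
2m/(3(N−m)), and because the log of a noisy estimate is biased downward this
bends the log–log curve down and biases α low when long lags enter the fit.
Restricting to short lags keeps the fitted α of diffusive ensembles centred
on 1. The full range (``n_lags=None``) and inverse-variance weighting
(``weights="invvar"``) are available for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .core import Trajectory
from .errors import DescriptorError, InvalidParameterError


@dataclass
class MSDCurve:
    """Time-averaged MSD of one track: values (μm²) over lags (s)."""

    lags: np.ndarray          # seconds, ascending, > 0
    values: np.ndarray        # μm²
    n_pairs: np.ndarray       # displacement pairs averaged per lag
    track_id: str = ""
    n_frames: int = 0         # frames of the source track (for variance models)

    def __len__(self):
        return len(self.lags)


def compute_msd(traj: Trajectory, max_lag_fraction: float = 0.25) -> MSDCurve:
    """Time-averaged MSD over all integer lags up to a fraction of the duration.

    Uses every overlapping ordered pair (t, t+τ); ``n_pairs[m-1] = n − m``.
    Requires a contiguous trajectory of at least 3 frames.
    """
    if traj.n_frames < 3:
        raise DescriptorError(f"track {traj.track_id}: MSD needs >= 3 frames")
    if not traj.is_contiguous:
        raise DescriptorError(f"track {traj.track_id}: MSD requires contiguous frames")
    if not (0 < max_lag_fraction <= 1):
        raise InvalidParameterError("max_lag_fraction must be in (0, 1]")
    n = traj.n_frames
    max_m = max(1, int(np.floor(max_lag_fraction * (n - 1))))
    pos = traj.positions
    values = np.empty(max_m)
    n_pairs = np.empty(max_m, dtype=np.int64)
    for m in range(1, max_m + 1):
        d = pos[m:] - pos[:-m]
        values[m - 1] = np.mean(d[:, 0] ** 2 + d[:, 1] ** 2)
        n_pairs[m - 1] = n - m
    lags = np.arange(1, max_m + 1) * traj.settings.frame_interval
    return MSDCurve(lags=lags, values=values, n_pairs=n_pairs,
                    track_id=traj.track_id, n_frames=n)


def msd_at_lag(traj: Trajectory, tau: float) -> float:
    """Time-averaged MSD at a single lag τ (must be a multiple of Δt)."""
    dt = traj.settings.frame_interval
    m = tau / dt
    if abs(m - round(m)) > 1e-9 or round(m) < 1:
        raise InvalidParameterError(f"lag {tau} s is not a positive multiple of Δt={dt} s")
    m = int(round(m))
    if m > traj.n_frames - 1:
        raise InvalidParameterError(f"lag {tau} s exceeds the observed duration")
    if not traj.is_contiguous:
        raise DescriptorError(f"track {traj.track_id}: MSD requires contiguous frames")
    d = traj.positions[m:] - traj.positions[:-m]
    return float(np.mean(d[:, 0] ** 2 + d[:, 1] ** 2))


class MSDPowerLaw:
    """Power-law model MSD(τ) = b·τ^α for one MSD curve.

    Parameters
    ----------
    curve : MSDCurve
        The time-averaged MSD to fit.

    Examples
    --------
    >>> model = MSDPowerLaw.from_trajectory(traj)
    >>> res = model.fit()
    >>> res.alpha, res.b
    """

    def __init__(self, curve: MSDCurve):
        self.curve = curve

    @classmethod
    def from_trajectory(cls, traj: Trajectory, max_lag_fraction: float = 0.25):
        return cls(compute_msd(traj, max_lag_fraction=max_lag_fraction))

    def fit(self, n_lags: Optional[int] = 10, weights: Optional[str] = None
            ) -> "MSDPowerLawResults":
        """Least-squares fit of log(MSD) on log(τ).

        Parameters
        ----------
        n_lags : int or None
            Fit window: the first ``n_lags`` lags of the curve (default 10);
            ``None`` uses the whole curve.
        weights : {None, "invvar", "npairs"}
            ``None``: ordinary least squares. ``"invvar"``: weights inverse to
            the diffusive-reference sampling variance of log MSD,
            var ∝ 2m/(3(N−m)). ``"npairs"``: weights equal to the pair count.

        Zero-valued lags are excluded (log undefined); with fewer than 3
        positive lags in the window the fit is degenerate, with α and b NaN.
        """
        c = self.curve
        window = slice(None) if n_lags is None else slice(0, n_lags)
        lags = c.lags[window]
        vals = c.values[window]
        np_pairs = c.n_pairs[window]
        keep = vals > 0
        lags, vals, np_pairs = lags[keep], vals[keep], np_pairs[keep]
        if len(lags) < 3:
            return MSDPowerLawResults(
                model=self, b=np.nan, alpha=np.nan, bse=(np.nan, np.nan),
                residual=np.nan, fit_lag_range=(np.nan, np.nan),
                n_lags_used=len(lags), status="degenerate",
            )
        x = np.log(lags)
        y = np.log(vals)
        if weights is None:
            w = np.ones_like(x)
        elif weights == "npairs":
            w = np_pairs.astype(float)
        elif weights == "invvar":
            if c.n_frames < 2:
                raise InvalidParameterError("invvar weights need curve.n_frames")
            m = np.rint(lags / c.lags[0]).astype(int)  # lag index in frames
            # relative variance of the 2D overlapping time-averaged MSD
            var_rel = 2.0 * m / (3.0 * (c.n_frames - m))
            w = 1.0 / var_rel
        else:
            raise InvalidParameterError("weights must be None, 'invvar' or 'npairs'")
        X = np.column_stack([np.ones_like(x), x])
        sw = np.sqrt(w)
        beta, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
        resid = y - X @ beta
        rss = float(np.sum(w * resid**2))
        dof = len(x) - 2
        xtx_inv = np.linalg.inv((X * w[:, None]).T @ X)
        s2 = rss / dof if dof > 0 else 0.0
        bse = np.sqrt(np.clip(np.diag(xtx_inv) * s2, 0.0, None))
        return MSDPowerLawResults(
            model=self,
            b=float(np.exp(beta[0])),
            alpha=float(beta[1]),
            bse=(float(bse[0]), float(bse[1])),
            residual=rss,
            fit_lag_range=(float(lags[0]), float(lags[-1])),
            n_lags_used=len(lags),
            status="ok",
        )


@dataclass
class MSDPowerLawResults:
    """Fitted power law: amplitude ``b`` (μm²·s^−α) and exponent ``alpha``."""

    model: MSDPowerLaw
    b: float
    alpha: float
    bse: tuple              # (se of log b, se of alpha) from the fit
    residual: float         # (weighted) RSS in log space
    fit_lag_range: tuple    # (τ_min, τ_max) seconds actually used
    n_lags_used: int
    status: str             # "ok" | "degenerate"

    @property
    def alpha_se(self) -> float:
        return self.bse[1]

    def predict(self, lags: np.ndarray) -> np.ndarray:
        """Model MSD values b·τ^α at the given lags."""
        return self.b * np.asarray(lags, dtype=float) ** self.alpha

    def summary(self) -> str:
        c = self.model.curve
        lines = [
            "MSD power-law fit (log-log least squares)",
            f"  track:        {c.track_id or '<unnamed>'}",
            f"  status:       {self.status}",
            f"  alpha:        {self.alpha:.6g}  (se {self.alpha_se:.3g})",
            f"  b [um^2/s^a]: {self.b:.6g}",
            f"  fit lags [s]: {self.fit_lag_range[0]:.3g} .. {self.fit_lag_range[1]:.3g}"
            f"  ({self.n_lags_used} lags)",
            f"  residual:     {self.residual:.3g}",
        ]
        return "\n".join(lines)


def fit_power_law(curve: MSDCurve, n_lags: Optional[int] = 10,
                  weights: Optional[str] = None) -> MSDPowerLawResults:
    """Functional wrapper around :meth:`MSDPowerLaw.fit`."""
    return MSDPowerLaw(curve).fit(n_lags=n_lags, weights=weights)


@dataclass
class AlphaDistribution:
    """Fitted MSD exponents of a population, with its empirical CDF."""

    label: str
    alphas: np.ndarray
    n_degenerate: int = 0
    _sorted: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        self.alphas = np.asarray(self.alphas, dtype=float)
        self._sorted = np.sort(self.alphas)

    def cdf(self, x) -> np.ndarray:
        """Empirical CDF evaluated at x (right-continuous)."""
        return np.searchsorted(self._sorted, np.asarray(x, dtype=float), side="right") / len(
            self._sorted
        )

    def plot_cdf(self, ax=None, **kwargs):
        """Step plot of the empirical CDF of α."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        xs = np.concatenate([[self._sorted[0]], self._sorted])
        ys = np.concatenate([[0.0], np.arange(1, len(self._sorted) + 1) / len(self._sorted)])
        ax.step(xs, ys, where="post", label=self.label, **kwargs)
        ax.set_xlabel(r"MSD exponent $\alpha$")
        ax.set_ylabel("cdf")
        return ax


def alpha_distribution(
    trajs: Sequence[Trajectory],
    label: str = "",
    max_lag_fraction: float = 0.25,
    n_lags: Optional[int] = 10,
    weights: Optional[str] = None,
) -> AlphaDistribution:
    """Fit α for every trajectory; degenerate fits are excluded and counted."""
    alphas, n_deg = [], 0
    for t in trajs:
        res = MSDPowerLaw.from_trajectory(t, max_lag_fraction).fit(n_lags=n_lags, weights=weights)
        if res.status == "ok":
            alphas.append(res.alpha)
        else:
            n_deg += 1
    if not alphas:
        raise DescriptorError("all trajectories gave degenerate MSD fits")
    return AlphaDistribution(label=label, alphas=np.array(alphas), n_degenerate=n_deg)


def compare_alpha(dist_a: AlphaDistribution, dist_b: AlphaDistribution):
    """Two-sided unpaired rank-sum comparison of two α samples."""
    from .stats import compare_groups

    return compare_groups(dist_a.alphas, dist_b.alphas, test="mann_whitney",
                          labels=(dist_a.label, dist_b.label))
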