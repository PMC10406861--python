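"""Background subtraction, acceptor cross-talk correction, and FRET ratios.

Raw per-frame intensities from the three spectral channels (Cy3, Cy5,
Cy5.5) are compounded by a constant per-channel background and by leakage
between the two acceptor channels.  With leakage factors

* ``r5``   — fraction of Cy5 emission registered in the Cy5.5 channel,
* ``r5_5`` — fraction of Cy5.5 emission registered in the Cy5 channel,

the apparent (background-subtracted) acceptor-channel intensities are

    Ia1 = (1 − r5)·I5 + r5_5·I5_5        (Cy5 channel)
    Ia2 = r5·I5 + (1 − r5_5)·I5_5        (Cy5.5 channel)

which invert, for r5 + r5_5 < 1, to

    I5   = [(1 − r5_5)·Ia1 − r5_5·Ia2] / (1 − r5 − r5_5)
    I5_5 = [−r5·Ia1 + (1 − r5)·Ia2] / (1 − r5 − r5_5)

Acceptor-specific apparent FRET efficiencies are ratios of the corrected
intensities:

    FRET_Cy5   = I5   / (I3 + I5 + I5_5)
    FRET_Cy5.5 = I5_5 / (I3 + I5 + I5_5)

The calibrated leakage factors for this setup average r5 = 0.31 and
r5_5 = 0.27.  Donor (Cy3→acceptor) leakage is assumed removed upstream:
the cross-talk corrected here is between the two acceptor channels only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

DEFAULT_R5 = 0.31
DEFAULT_R5_5 = 0.27

#: Minimum number of baseline frames needed for a background estimate.
MIN_BASELINE_FRAMES = 10


class BaselineError(ValueError):
    """Raised when a trace offers no post-bleach or dark segment."""


@dataclass(frozen=True)
class LeakageFactors:
    """Acceptor cross-talk pair defining the 2x2 channel-mixing system."""

    r5: float = DEFAULT_R5
    r5_5: float = DEFAULT_R5_5

    def __post_init__(self) -> None:
        if not (0.0 <= self.r5 < 1.0 and 0.0 <= self.r5_5 < 1.0):
            raise ValueError("leakage factors must lie in [0, 1)")
        if self.r5 + self.r5_5 >= 1.0:
            raise ValueError(
                f"r5 + r5_5 = {self.r5 + self.r5_5} >= 1: mixing system singular"
            )

    @property
    def matrix(self) -> np.ndarray:
        """Forward mixing matrix M with (Ia1, Ia2) = M @ (I5, I5_5)."""
        return np.array(
            [[1.0 - self.r5, self.r5_5], [self.r5, 1.0 - self.r5_5]]
        )


def forward_leakage(I5, I5_5, lf: LeakageFactors = LeakageFactors()):
    """Apply acceptor cross-talk: true intensities -> channel signals."""
    I5 = np.asarray(I5, dtype=float)
    I5_5 = np.asarray(I5_5, dtype=float)
    Ia1 = (1.0 - lf.r5) * I5 + lf.r5_5 * I5_5
    Ia2 = lf.r5 * I5 + (1.0 - lf.r5_5) * I5_5
    return Ia1, Ia2


def invert_leakage(Ia1, Ia2, lf: LeakageFactors = LeakageFactors()):
    """Recover true acceptor intensities from channel signals.

    Uses the closed-form inverse of the 2x2 mixing system; the determinant
    is 1 − r5 − r5_5 (0.42 with the default factors).
    """
    det = 1.0 - lf.r5 - lf.r5_5
    if det <= 0:
        raise ValueError("r5 + r5_5 >= 1: mixing system is singular")
    Ia1 = np.asarray(Ia1, dtype=float)
    Ia2 = np.asarray(Ia2, dtype=float)
    I5 = ((1.0 - lf.r5_5) * Ia1 - lf.r5_5 * Ia2) / det
    I5_5 = (-lf.r5 * Ia1 + (1.0 - lf.r5) * Ia2) / det
    return I5, I5_5


def compute_fret(I3, I5, I5_5) -> Tuple[np.ndarray, np.ndarray]:
    """Acceptor-specific FRET efficiencies from corrected intensities.

    Frames whose summed intensity is non-positive are undefined (NaN);
    no exception is raised for them.
    """
    I3 = np.asarray(I3, dtype=float)
    I5 = np.asarray(I5, dtype=float)
    I5_5 = np.asarray(I5_5, dtype=float)
    total = I3 + I5 + I5_5
    with np.errstate(divide="ignore", invalid="ignore"):
        f5 = np.where(total > 0, I5 / total, np.nan)
        f55 = np.where(total > 0, I5_5 / total, np.nan)
    return f5, f55


def _baseline_frames(df: pd.DataFrame) -> np.ndarray:
    """Boolean mask of frames usable for background estimation.

    Dark-phase frames are preferred; failing that, green-phase frames after
    the last step-like drop of the summed intensity are used (all
    fluorophores bleached).
    """
    dark = (df["phase"] == "dark").to_numpy()
    if dark.sum() >= MIN_BASELINE_FRAMES:
        return dark
    green = (df["phase"] == "green").to_numpy()
    total = (
        df["i_cy3_raw"] + df["i_cy5_raw"] + df["i_cy55_raw"]
    ).to_numpy()[green]
    if len(total) < 2 * MIN_BASELINE_FRAMES:
        raise BaselineError("no baseline segment: trace too short")
    from .classify import _best_step  # local import avoids a cycle

    c, drop, resid_sd = _best_step(total)
    scale = float(np.max(np.abs(total)))
    significant = (
        c is not None
        and drop > max(4.0 * resid_sd, 1e-9 + 1e-6 * scale)
    )
    if not significant or len(total) - c < MIN_BASELINE_FRAMES:
        raise BaselineError(
            "no baseline segment: no dark phase and no detectable bleach"
        )
    mask = np.zeros(len(df), dtype=bool)
    green_idx = np.flatnonzero(green)
    mask[green_idx[c:]] = True
    return mask


def estimate_background(trace) -> dict:
    """Per-channel constant baseline from post-bleach (or dark) frames.

    The baseline is the median of the baseline-segment frames in each
    channel, robust to residual intensity blips.

    Raises
    ------
    BaselineError
        If the trace has neither a dark phase nor a detectable post-bleach
        segment of at least 10 frames.
    """
    df = _as_frame(trace)
    mask = _baseline_frames(df)
    if mask.sum() < MIN_BASELINE_FRAMES:
        raise BaselineError("no baseline segment of >= 10 frames")
    sub = df.loc[mask]
    return {
        "cy3": float(sub["i_cy3_raw"].median()),
        "cy5": float(sub["i_cy5_raw"].median()),
        "cy55": float(sub["i_cy55_raw"].median()),
        "noise_sd": {
            "cy3": float(sub["i_cy3_raw"].std(ddof=1)),
            "cy5": float(sub["i_cy5_raw"].std(ddof=1)),
            "cy55": float(sub["i_cy55_raw"].std(ddof=1)),
        },
        "n_frames": int(mask.sum()),
    }


@dataclass
class CorrectedTrace:
    """A trace after background and leakage correction.

    ``frames`` carries the raw columns plus ``i_cy3, i_cy5, i_cy55``
    (corrected intensities, retained un-clamped), ``fret_cy5, fret_cy55``
    (clipped into [0,1]), ``undefined_flag`` (non-green phase or
    non-positive total), and ``negative_flag`` (some corrected channel was
    negative on that frame).
    """

    frames: pd.DataFrame
    background: dict
    leakage: LeakageFactors
    meta: dict = field(default_factory=dict)

    @property
    def noise_sd(self) -> float:
        return float(max(self.background["noise_sd"].values()))


class LeakageCorrector(BaseEstimator, TransformerMixin):
    """Transformer turning raw three-channel traces into corrected ones.

    ``fit`` estimates the per-channel constant background of a trace from
    its post-bleach (or dark) frames; ``transform`` subtracts it, inverts
    the acceptor cross-talk, and computes the per-frame FRET efficiencies
    on green-excitation frames.

    Parameters
    ----------
    r5, r5_5 : float
        Leakage factors (defaults 0.31 and 0.27).

    Attributes
    ----------
    background_ : dict
        Per-channel baselines and baseline-segment noise SDs.
    """

    def __init__(self, r5: float = DEFAULT_R5, r5_5: float = DEFAULT_R5_5):
        self.r5 = r5
        self.r5_5 = r5_5

    def fit(self, X, y=None):
        self.leakage_ = LeakageFactors(self.r5, self.r5_5)
        self.background_ = estimate_background(X)
        return self

    def transform(self, X) -> CorrectedTrace:
        if not hasattr(self, "background_"):
            raise RuntimeError("LeakageCorrector is not fitted")
        df = _as_frame(X).copy()
        bg = self.background_
        i3 = df["i_cy3_raw"].to_numpy(float) - bg["cy3"]
        ia1 = df["i_cy5_raw"].to_numpy(float) - bg["cy5"]
        ia2 = df["i_cy55_raw"].to_numpy(float) - bg["cy55"]
        i5, i55 = invert_leakage(ia1, ia2, self.leakage_)

        green = (df["phase"] == "green").to_numpy()
        f5, f55 = compute_fret(i3, i5, i55)
        undefined = ~green | ~np.isfinite(f5)
        f5 = np.where(undefined, np.nan, f5)
        f55 = np.where(undefined, np.nan, f55)
        clipped = (~undefined) & (
            (f5 < 0) | (f5 > 1) | (f55 < 0) | (f55 > 1)
        )
        f5 = np.clip(f5, 0.0, 1.0)
        f55 = np.clip(f55, 0.0, 1.0)

        df["i_cy3"] = i3
        df["i_cy5"] = i5
        df["i_cy55"] = i55
        df["fret_cy5"] = f5
        df["fret_cy55"] = f55
        df["undefined_flag"] = undefined
        df["negative_flag"] = (i3 < 0) | (i5 < 0) | (i55 < 0)
        df["clip_flag"] = clipped
        meta = dict(getattr(X, "meta", {}) or {})
        return CorrectedTrace(frames=df, background=bg,
                              leakage=self.leakage_, meta=meta)


def correct_trace(
    trace,
    lf: Optional[LeakageFactors] = None,
) -> CorrectedTrace:
    """Background-subtract, leakage-correct, and compute FRET for a trace."""
    lf = lf or LeakageFactors()
    return LeakageCorrector(r5=lf.r5, r5_5=lf.r5_5).fit(trace).transform(trace)


def _as_frame(trace) -> pd.DataFrame:
    if isinstance(trace, pd.DataFrame):
        return trace
    frames = getattr(trace, "frames", None)
    if isinstance(frames, pd.DataFrame):
        return frames
    raise TypeError("expected a trace DataFrame or an object with .frames")
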