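"""Molecule QC, photobleach detection, species classification, and census.

Each surface-immobilized molecule is accepted only if it behaves like a
single nucleosome: its channels show zero intensity after photobleaching
(single-step bleaching), the photobleaching lifetime of the DNA-label
fluorophores exceeds 10 s, and the signal-to-noise ratio exceeds 4.  The
10 s lifetime gate is applied to the Cy3/Cy5 (DNA-label) fluorophores:
Cy5.5 on exchanged histones bleaches much faster and exchanged molecules
must remain countable despite that.

Classification is by the per-molecule FRET signature: intact molecules sit
near FRET_Cy5 ≈ 0.6 with zero FRET_Cy5.5; proximal-exchanged molecules
funnel nearly all transfer to Cy5.5 (near-zero Cy3 and Cy5); distal-
exchanged molecules show low-mid FRET_Cy5 together with a sustained
non-zero FRET_Cy5.5.  Only distal-exchanged molecules enter the census
numerator — proximal events photobleach too quickly to count reliably —
while the denominator is configurable (all qualifying molecules, or
intact + distal only).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .correction import CorrectedTrace, invert_leakage

CHANNELS = ("cy3", "cy5", "cy55")
CLASS_LABELS = ("intact", "proximal_exchanged", "distal_exchanged", "ambiguous")


@dataclass
class QCThresholds:
    """Acceptance gates for single-molecule traces."""

    min_lifetime: float = 10.0  # s; earliest Cy3/Cy5 bleach must exceed this
    min_snr: float = 4.0
    post_bleach_zero_tolerance: Optional[float] = None  # default: 3 x noise SD
    single_molecule_requirement: bool = True

    def __post_init__(self) -> None:
        if self.min_lifetime <= 0 or self.min_snr <= 0:
            raise ValueError("QC thresholds must be positive")


@dataclass
class ClassificationRules:
    """FRET-signature windows separating the three species classes."""

    intact_center: float = 0.6
    intact_window: float = 0.15
    epsilon: float = 0.1  # max FRET_cy5.5 for intact
    theta_55: float = 0.15  # min FRET_cy5.5 for distal
    theta_5_low: float = 0.5  # max FRET_cy5 for distal
    theta_high: float = 0.6  # min FRET_cy5.5 for proximal
    cy3_cy5_max: float = 0.15  # near-zero Cy3/Cy5 shares for proximal
    m_frames: int = 5  # sustained frames required for distal (1 s at 200 ms)
    min_median_frames: int = 3

    def __post_init__(self) -> None:
        for name in ("epsilon", "theta_55", "theta_5_low", "theta_high"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0,1), got {v}")
        if self.m_frames < 1:
            raise ValueError("m_frames must be >= 1")


@dataclass
class ChannelStep:
    frame: Optional[int]  # first frame of the post-step segment (green index)
    multi_step: bool
    drop: float


@dataclass
class QCResult:
    passed: bool
    reasons: List[str]
    lifetime_s: float
    snr: float


# ---------------------------------------------------------------------------
# changepoint machinery
# ---------------------------------------------------------------------------

def _best_step(y: np.ndarray, min_seg: int = 5):
    """Best two-segment split of ``y`` by least squares.

    Returns ``(c, drop, resid_sd)`` where segment 2 starts at index ``c``
    and ``drop`` is mean(seg1) − mean(seg2); ``(None, 0, sd)`` if the
    series is too short.
    """
    n = len(y)
    if n < 2 * min_seg:
        return None, 0.0, float(np.std(y))
    s1 = np.concatenate([[0.0], np.cumsum(y)])
    s2 = np.concatenate([[0.0], np.cumsum(y * y)])
    cs = np.arange(min_seg, n - min_seg + 1)
    sse_left = s2[cs] - s1[cs] ** 2 / cs
    nr = n - cs
    sse_right = (s2[n] - s2[cs]) - (s1[n] - s1[cs]) ** 2 / nr
    cost = sse_left + sse_right
    best = int(np.argmin(cost))
    c = int(cs[best])
    drop = float(s1[c] / c - (s1[n] - s1[c]) / (n - c))
    resid_sd = float(np.sqrt(max(cost[best], 0.0) / max(n - 2, 1)))
    return c, drop, resid_sd


def _find_steps(y: np.ndarray, noise_sd: float, min_seg: int = 5,
                z: float = 4.0, _depth: int = 0) -> List[int]:
    """Recursively locate significant downward steps in ``y``."""
    c, drop, resid_sd = _best_step(y, min_seg)
    if c is None:
        return []
    scale = float(np.max(np.abs(y))) if len(y) else 0.0
    thresh = max(z * noise_sd, 1e-9 + 1e-6 * scale)
    if drop <= thresh:
        return []
    steps = [c]
    if _depth < 4:
        steps = (
            _find_steps(y[:c], noise_sd, min_seg, z, _depth + 1)
            + [c]
            + [c + s for s in _find_steps(y[c:], noise_sd, min_seg, z, _depth + 1)]
        )
    return steps


def detect_bleach_steps(trace: CorrectedTrace,
                        min_seg: int = 5) -> Dict[str, ChannelStep]:
    """Locate the photobleach step of each channel by changepoint fitting.

    Works on the background-corrected green-phase intensities, whose
    post-bleach level is zero by construction.  A channel with more than
    one significant downward step is flagged ``multi_step`` (aggregate, not
    a single molecule); a channel with no significant step reports
    ``frame=None``.
    """
    df = trace.frames
    green = df["phase"] == "green"
    if green.sum() < 20:
        raise ValueError("need >= 20 green-phase frames for step detection")
    out: Dict[str, ChannelStep] = {}
    col = {"cy3": "i_cy3", "cy5": "i_cy5", "cy55": "i_cy55"}
    for ch in CHANNELS:
        y = df.loc[green, col[ch]].to_numpy(float)
        sd = trace.background["noise_sd"][ch]
        sd = sd if np.isfinite(sd) else 0.0
        steps = _find_steps(y, sd, min_seg)
        if not steps:
            out[ch] = ChannelStep(frame=None, multi_step=False, drop=0.0)
        else:
            last = steps[-1]
            drop = float(np.mean(y[:last]) - np.mean(y[last:]))
            out[ch] = ChannelStep(frame=last, multi_step=len(steps) > 1,
                                  drop=drop)
    return out


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def qc_filter(trace: CorrectedTrace, thr: Optional[QCThresholds] = None,
              steps: Optional[Dict[str, ChannelStep]] = None) -> QCResult:
    """Apply the single-molecule acceptance gates to one corrected trace."""
    thr = thr or QCThresholds()
    steps = steps if steps is not None else detect_bleach_steps(trace)
    df = trace.frames
    green = df["phase"] == "green"
    dt = float(np.median(np.diff(df["time_s"].to_numpy(float))))
    col = {"cy3": "i_cy3", "cy5": "i_cy5", "cy55": "i_cy55"}
    reasons: List[str] = []

    # observation lifetime: earliest bleach of the DNA-label fluorophores
    dna_steps = [steps[ch].frame for ch in ("cy3", "cy5")
                 if steps[ch].frame is not None]
    lifetime = (min(dna_steps) * dt) if dna_steps else float(green.sum() * dt)
    if lifetime <= thr.min_lifetime:
        reasons.append("lifetime")

    # SNR: best channel's pre-bleach mean over its baseline noise SD
    snr = 0.0
    for ch in CHANNELS:
        y = df.loc[green, col[ch]].to_numpy(float)
        end = steps[ch].frame if steps[ch].frame is not None else len(y)
        if end < 2:
            continue
        mean = float(np.mean(y[:end]))
        sd = trace.background["noise_sd"][ch]
        if not np.isfinite(sd) or sd <= 0:
            ch_snr = np.inf if mean > 0 else 0.0
        else:
            ch_snr = mean / sd
        snr = max(snr, ch_snr)
    if snr <= thr.min_snr:
        reasons.append("snr")

    # single molecules show zero intensity after photobleaching
    for ch in CHANNELS:
        st = steps[ch]
        if st.frame is None:
            continue
        y = df.loc[green, col[ch]].to_numpy(float)
        resid = abs(float(np.mean(y[st.frame:])))
        sd = trace.background["noise_sd"][ch]
        tol = (thr.post_bleach_zero_tolerance
               if thr.post_bleach_zero_tolerance is not None
               else max(3.0 * (sd if np.isfinite(sd) else 0.0), 1e-6))
        if resid > tol:
            reasons.append("residual")
            break

    if thr.single_molecule_requirement and any(
        steps[ch].multi_step for ch in CHANNELS
    ):
        reasons.append("multi_step")

    return QCResult(passed=not reasons, reasons=reasons,
                    lifetime_s=lifetime, snr=float(snr))


@dataclass
class RedExcitationStatus:
    cy5_present: Optional[bool]
    cy55_present: Optional[bool]
    status: str  # cy5_present | cy55_present | both_present | bleached | unknown


def verify_red_excitation(trace, background: Optional[dict] = None,
                          z: float = 5.0) -> RedExcitationStatus:
    """Check acceptor survival from the red-excitation phase.

    The 635 nm phase directly excites Cy5 and Cy5.5; leakage-inverted mean
    red-phase intensities above ``z``/√n noise SDs of baseline mark the
    acceptor as still present.  Traces without a red phase return status
    ``unknown`` (still classifiable, but unverified).
    """
    from .correction import estimate_background, _as_frame, LeakageFactors

    df = _as_frame(trace)
    red = df["phase"] == "red"
    n_red = int(red.sum())
    if n_red == 0:
        return RedExcitationStatus(None, None, "unknown")
    bg = background or getattr(trace, "background", None) or estimate_background(df)
    lf = getattr(trace, "leakage", None) or LeakageFactors()
    raw5 = "i_cy5_raw" if "i_cy5_raw" in df else "i_cy5"
    raw55 = "i_cy55_raw" if "i_cy55_raw" in df else "i_cy55"
    off5 = bg["cy5"] if "i_cy5_raw" in df else 0.0
    off55 = bg["cy55"] if "i_cy55_raw" in df else 0.0
    ia1 = float(df.loc[red, raw5].mean()) - off5
    ia2 = float(df.loc[red, raw55].mean()) - off55
    i5, i55 = invert_leakage(ia1, ia2, lf)
    sd5 = bg["noise_sd"]["cy5"]
    sd55 = bg["noise_sd"]["cy55"]
    thr5 = max(z * (sd5 if np.isfinite(sd5) else 0.0) / np.sqrt(n_red), 1e-6)
    thr55 = max(z * (sd55 if np.isfinite(sd55) else 0.0) / np.sqrt(n_red), 1e-6)
    p5, p55 = bool(i5 > thr5), bool(i55 > thr55)
    status = {(True, True): "both_present", (True, False): "cy5_present",
              (False, True): "cy55_present", (False, False): "bleached"}[(p5, p55)]
    return RedExcitationStatus(p5, p55, status)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def _longest_true_run(mask: np.ndarray) -> int:
    best = run = 0
    for v in mask:
        run = run + 1 if v else 0
        best = max(best, run)
    return best


def classify_molecule(trace: CorrectedTrace,
                      rules: Optional[ClassificationRules] = None,
                      steps: Optional[Dict[str, ChannelStep]] = None) -> str:
    """Assign intact / proximal_exchanged / distal_exchanged / ambiguous.

    Median FRET values are taken over the green frames preceding the
    earliest bleach of any fluorophore; the distal signature additionally
    requires ``m_frames`` consecutive frames of non-zero FRET_Cy5.5 with
    lowered FRET_Cy5 anywhere before the DNA-label fluorophores bleach,
    so that fast Cy5.5 photobleaching does not erase a real exchange
    signature.
    """
    rules = rules or ClassificationRules()
    steps = steps if steps is not None else detect_bleach_steps(trace)
    df = trace.frames
    green = (df["phase"] == "green").to_numpy()
    f5 = df["fret_cy5"].to_numpy(float)[green]
    f55 = df["fret_cy55"].to_numpy(float)[green]

    all_steps = [s.frame for s in steps.values() if s.frame is not None]
    pre_all = min(all_steps) if all_steps else len(f5)
    dna_steps = [steps[ch].frame for ch in ("cy3", "cy5")
                 if steps[ch].frame is not None]
    pre_dna = min(dna_steps) if dna_steps else len(f5)

    w5, w55 = f5[:pre_all], f55[:pre_all]
    ok = np.isfinite(w5) & np.isfinite(w55)
    if ok.sum() < rules.min_median_frames:
        return "ambiguous"
    m5 = float(np.median(w5[ok]))
    m55 = float(np.median(w55[ok]))
    m3 = 1.0 - m5 - m55

    if m55 >= rules.theta_high and m5 <= rules.cy3_cy5_max and m3 <= rules.cy3_cy5_max:
        return "proximal_exchanged"

    o5, o55 = f5[:pre_dna], f55[:pre_dna]
    sig = (
        np.isfinite(o5) & np.isfinite(o55)
        & (o55 >= rules.theta_55) & (o5 <= rules.theta_5_low)
    )
    if _longest_true_run(sig) >= rules.m_frames:
        return "distal_exchanged"

    if abs(m5 - rules.intact_center) <= rules.intact_window and m55 <= rules.epsilon:
        return "intact"
    return "ambiguous"


class TraceClassifier(BaseEstimator):
    """Rule-based per-molecule QC + species classifier.

    ``predict`` maps corrected traces to class labels; :meth:`analyze`
    additionally runs the QC gates and returns a per-molecule table
    suitable for the census.  The classifier is fully specified by its
    rules (no training), so ``fit`` only validates and freezes them.
    """

    def __init__(self, rules: Optional[ClassificationRules] = None,
                 qc: Optional[QCThresholds] = None):
        self.rules = rules
        self.qc = qc

    def fit(self, X=None, y=None):
        self.rules_ = self.rules or ClassificationRules()
        self.qc_ = self.qc or QCThresholds()
        return self

    def predict(self, X: Iterable[CorrectedTrace]) -> np.ndarray:
        if not hasattr(self, "rules_"):
            self.fit()
        return np.array([classify_molecule(tr, self.rules_) for tr in X])

    def analyze(self, X: Iterable[CorrectedTrace]) -> pd.DataFrame:
        """QC + classify each trace; returns one row per molecule."""
        if not hasattr(self, "rules_"):
            self.fit()
        rows = []
        for tr in X:
            steps = detect_bleach_steps(tr)
            qc = qc_filter(tr, self.qc_, steps)
            cls = classify_molecule(tr, self.rules_, steps)
            meta = tr.meta or {}
            rows.append(
                {
                    "molecule_id": meta.get("molecule_id", ""),
                    "timepoint_h": meta.get("timepoint_h", np.nan),
                    "replicate": meta.get("replicate", 0),
                    "qc_pass": qc.passed,
                    "reasons": ";".join(qc.reasons),
                    "lifetime_s": qc.lifetime_s,
                    "snr": qc.snr,
                    "class": cls,
                    "true_class": meta.get("true_class", ""),
                }
            )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# histograms and census
# ---------------------------------------------------------------------------

@dataclass
class FretHistograms:
    bin_edges: np.ndarray
    counts_fret_cy5: np.ndarray
    counts_fret_cy55: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_left": self.bin_edges[:-1],
                "bin_right": self.bin_edges[1:],
                "count_fret_cy5": self.counts_fret_cy5,
                "count_fret_cy55": self.counts_fret_cy55,
            }
        )


def build_histograms(traces: Sequence[CorrectedTrace],
                     bin_width: float = 0.02) -> FretHistograms:
    """Per-frame FRET histograms over all qualifying traces on [0, 1]."""
    nbins = int(round(1.0 / bin_width))
    edges = np.linspace(0.0, 1.0, nbins + 1)
    v5, v55 = [], []
    for tr in traces:
        df = tr.frames
        ok = ~df["undefined_flag"].to_numpy(bool)
        v5.append(df["fret_cy5"].to_numpy(float)[ok])
        v55.append(df["fret_cy55"].to_numpy(float)[ok])
    if v5:
        c5, _ = np.histogram(np.concatenate(v5), bins=edges)
        c55, _ = np.histogram(np.concatenate(v55), bins=edges)
    else:
        c5 = np.zeros(nbins, dtype=int)
        c55 = np.zeros(nbins, dtype=int)
    return FretHistograms(edges, c5, c55)


@dataclass
class TimeCourse:
    """Per-time-point distal-exchanged fractions with replicate dispersion."""

    by_replicate: pd.DataFrame  # time_h, replicate, n_qualifying, n_distal, fraction
    summary: pd.DataFrame  # time_h, n_qualifying, n_distal, fraction, sd
    denominator: str

    @property
    def time_s(self) -> np.ndarray:
        return self.summary["time_h"].to_numpy(float) * 3600.0

    @property
    def fraction(self) -> np.ndarray:
        return self.summary["fraction"].to_numpy(float)

    @property
    def sd(self) -> np.ndarray:
        return self.summary["sd"].to_numpy(float)


def compute_census(classified: pd.DataFrame,
                   denominator: str = "all") -> TimeCourse:
    """Count distal-exchanged fractions per time point and replicate.

    ``classified`` needs columns timepoint_h, replicate, class and
    optionally qc_pass (failing molecules are dropped).  Ambiguous
    molecules never count.  ``denominator`` is ``"all"`` (intact +
    proximal + distal qualifying molecules) or ``"intact_distal"``.
    """
    if denominator not in ("all", "intact_distal"):
        raise ValueError(f"unknown denominator convention {denominator!r}")
    denom_classes = (
        {"intact", "proximal_exchanged", "distal_exchanged"}
        if denominator == "all"
        else {"intact", "distal_exchanged"}
    )
    df = classified
    if "qc_pass" in df:
        df = df[df["qc_pass"].astype(bool)]
    df = df[df["class"].isin(denom_classes)]

    rep_rows = []
    for (t_h, rep), grp in df.groupby(["timepoint_h", "replicate"], sort=True):
        n_q = len(grp)
        n_d = int((grp["class"] == "distal_exchanged").sum())
        rep_rows.append(
            {
                "time_h": float(t_h),
                "replicate": rep,
                "n_qualifying": n_q,
                "n_distal": n_d,
                "fraction": n_d / n_q if n_q else np.nan,
            }
        )
    by_rep = pd.DataFrame(rep_rows)

    sum_rows = []
    if len(by_rep):
        for t_h, grp in by_rep.groupby("time_h", sort=True):
            n_q = int(grp["n_qualifying"].sum())
            n_d = int(grp["n_distal"].sum())
            fracs = grp["fraction"].dropna()
            sd = float(fracs.std(ddof=1)) if len(fracs) >= 2 else np.nan
            sum_rows.append(
                {
                    "time_h": float(t_h),
                    "n_qualifying": n_q,
                    "n_distal": n_d,
                    "fraction": n_d / n_q if n_q else np.nan,
                    "sd": sd,
                }
            )
    summary = pd.DataFrame(
        sum_rows, columns=["time_h", "n_qualifying", "n_distal", "fraction", "sd"]
    )
    return TimeCourse(by_replicate=by_rep, summary=summary,
                      denominator=denominator)
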