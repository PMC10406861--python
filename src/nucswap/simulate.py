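"""Synthetic data generation: exchange kinetics and three-channel traces.

Two generators are provided.

* A well-mixed **collision Monte Carlo** of dimer exchange between
  individual nucleosomes.  Each collision picks an unordered particle pair
  uniformly at random, independently picks one H2A-H2B slot (proximal or
  distal, probability 1/2 each) in each partner, and swaps the label states
  of the two chosen slots.  The total collision propensity is
  k · C_total · N / 2, so a specific unordered pair collides at rate
  ≈ k · C_total / N and the mean-field species kinetics carry the same
  statistical 1/2 factors as the closed-form model.  Exchange conserves the
  total number of labeled dimers by construction (asserted).

* A per-molecule **trace synthesizer** producing raw three-channel
  intensity time series with the experiment's corruptions: the class's
  signature FRET partitioning of a fixed emission budget, independent
  exponential photobleaching per fluorophore (Cy5.5 much faster than Cy5),
  post-bleach rerouting of the lost acceptor's FRET share to the surviving
  fluorophores in proportion to their shares, acceptor-channel cross-talk,
  constant per-channel background offsets, and zero-mean Gaussian noise.
  Each trace ends with a dark phase and a red-excitation phase that
  directly probes acceptor survival.

Defaults reproduce the study conditions: 200 ms frames, labeling
efficiency F = 0.537, 400 nM total nucleosome, time points 0-24 h.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .correction import LeakageFactors, forward_leakage
from .kinetics import ExchangeModel, closed_form_fraction, exponent_coefficient

SPECIES_CLASSES = ("intact", "proximal_exchanged", "distal_exchanged")

#: Signature (FRET_cy5, FRET_cy5.5) targets per molecule class.  Intact
#: nucleosomes show ~0.6 FRET_cy5 and zero FRET_cy5.5; proximal exchange
#: funnels nearly all excitation to Cy5.5; distal exchange gives low-mid
#: FRET_cy5 with a clearly non-zero FRET_cy5.5.
DEFAULT_SIGNATURES: Dict[str, Tuple[float, float]] = {
    "intact": (0.6, 0.0),
    "proximal_exchanged": (0.05, 0.90),
    "distal_exchanged": (0.35, 0.30),
}


@dataclass
class TraceSimulationParams:
    """Knobs of the per-molecule trace synthesizer.

    Intensities are in arbitrary camera units (a.u.); times in seconds.
    """

    frame_interval: float = 0.2
    n_frames_green: int = 300
    n_frames_dark: int = 25
    n_frames_red: int = 50
    emission_budget: float = 500.0
    red_excitation_budget: float = 300.0
    background: Tuple[float, float, float] = (50.0, 40.0, 30.0)
    noise_sd: float = 15.0
    # mean photobleach lifetimes (s); Cy5.5 bleaches much faster than Cy5.
    # math.inf disables bleaching for a fluorophore.
    bleach_lifetime: Dict[str, float] = field(
        default_factory=lambda: {"cy3": 60.0, "cy5": 40.0, "cy55": 12.0}
    )
    leakage: LeakageFactors = field(default_factory=LeakageFactors)
    signatures: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_SIGNATURES)
    )

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if min(self.n_frames_green, self.n_frames_dark, self.n_frames_red) < 0:
            raise ValueError("frame counts must be non-negative")
        if not self.bleach_lifetime["cy55"] < self.bleach_lifetime["cy5"]:
            raise ValueError(
                "Cy5.5 mean bleach lifetime must be strictly less than Cy5's"
            )
        for cls, (f5, f55) in self.signatures.items():
            if not (0 <= f5 <= 1 and 0 <= f55 <= 1 and f5 + f55 <= 1):
                raise ValueError(f"invalid FRET signature for {cls!r}")

    @property
    def n_frames(self) -> int:
        return self.n_frames_green + self.n_frames_dark + self.n_frames_red

    def without_corruptions(self) -> "TraceSimulationParams":
        """Copy with zero noise and bleaching disabled (idealized traces)."""
        kw = asdict(self)
        kw["leakage"] = self.leakage
        kw["noise_sd"] = 0.0
        # Cy5.5 finite-but-astronomical keeps the lifetime-ordering invariant
        kw["bleach_lifetime"] = {"cy3": math.inf, "cy5": math.inf, "cy55": 1e30}
        return TraceSimulationParams(**kw)


@dataclass
class TimeCourseDesign:
    """Design of a full exchange time-course experiment."""

    time_points_h: Sequence[float] = (0, 1, 2, 4, 6, 8, 12, 18, 24)
    n_molecules_per_replicate: int = 100
    n_replicates: int = 4
    k_true: float = 356.0  # M^-1 s^-1
    C_total: float = 4e-7  # molar (400 nM)
    F: float = 0.537
    seed: int = 0

    def __post_init__(self) -> None:
        tp = np.asarray(self.time_points_h, dtype=float)
        if np.any(tp < 0) or np.any(np.diff(tp) <= 0):
            raise ValueError("time points must be non-negative, strictly increasing")
        if self.C_total <= 0:
            raise ValueError("C_total must be positive")
        if self.k_true < 0:
            raise ValueError("k_true must be >= 0")
        if not 0 <= self.F <= 1:
            raise ValueError("F must be in [0,1]")
        if self.n_molecules_per_replicate < 1 or self.n_replicates < 1:
            raise ValueError("molecule and replicate counts must be >= 1")

    def model(self) -> ExchangeModel:
        return ExchangeModel(k=self.k_true, F=self.F, C_total=self.C_total)


@dataclass
class RawTrace:
    """Per-molecule raw three-channel trace plus ground-truth metadata."""

    frames: pd.DataFrame
    meta: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# collision Monte Carlo
# ---------------------------------------------------------------------------

class ConfigError(ValueError):
    pass


def simulate_exchange_stochastic(
    design: TimeCourseDesign,
    n_particles: int,
    times_s: Optional[Sequence[float]] = None,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Collision Monte Carlo of dimer exchange among ``n_particles``.

    Half the particles are DNA-labeled (observable), half histone-labeled
    with each slot carrying a Cy5.5 label independently with probability F.
    The number of collisions in each reporting interval is Poisson with
    mean k · C_total · N/2 · Δt; each collision swaps the label states of
    one uniformly chosen slot in each member of a uniformly chosen
    particle pair.

    Returns a DataFrame with one row per requested time and columns
    ``time_s`` plus the fractions of the DNA-labeled pool in states
    A (unlabeled), b (proximal-only), e (distal-only), B' (both labeled),
    which sum to 1 at every time.
    """
    if n_particles < 100 or n_particles % 2:
        raise ConfigError("n_particles must be even and >= 100")
    rng = rng if rng is not None else np.random.default_rng(design.seed)
    if times_s is None:
        times_s = np.asarray(design.time_points_h, dtype=float) * 3600.0
    times_s = np.asarray(times_s, dtype=float)
    if np.any(times_s < 0) or np.any(np.diff(times_s) <= 0):
        raise ConfigError("report times must be non-negative, strictly increasing")

    n = n_particles
    half = n // 2
    # slot label states: columns (proximal, distal); rows 0..half-1 are the
    # DNA-labeled pool, the rest the histone-labeled pool
    slots = np.zeros((n, 2), dtype=bool)
    slots[half:, :] = rng.random((half, 2)) < design.F
    n_labels = int(slots.sum())

    rate = design.k_true * design.C_total * n / 2.0  # collisions per second
    rows = []
    t_prev = 0.0
    for t in times_s:
        n_events = rng.poisson(rate * (t - t_prev)) if rate > 0 else 0
        if n_events:
            i = rng.integers(0, n, size=n_events)
            j = rng.integers(0, n - 1, size=n_events)
            j = j + (j >= i)  # uniform over pairs with j != i
            si = rng.integers(0, 2, size=n_events)
            sj = rng.integers(0, 2, size=n_events)
            for a, b, sa, sb in zip(i, j, si, sj):
                slots[a, sa], slots[b, sb] = slots[b, sb], slots[a, sa]
        assert int(slots.sum()) == n_labels, "exchange must conserve labels"
        prox, dist = slots[:half, 0], slots[:half, 1]
        rows.append(
            {
                "time_s": t,
                "A": float(np.mean(~prox & ~dist)),
                "b": float(np.mean(prox & ~dist)),
                "e": float(np.mean(~prox & dist)),
                "B'": float(np.mean(prox & dist)),
            }
        )
        t_prev = t
    return pd.DataFrame(rows)


def equilibrium_report_times(design: TimeCourseDesign,
                             n_relax: float = 12.0,
                             n_snapshots: int = 5) -> np.ndarray:
    """Report times spanning the last relaxation times before ``n_relax`` τ.

    τ = 1/((1+F)/2 · k · C_total) is the closed-form relaxation time;
    snapshots at least one τ apart keep the equilibrium estimate nearly
    independent between snapshots.
    """
    rate = exponent_coefficient(design.F) * design.k_true * design.C_total
    if rate <= 0:
        raise ConfigError("need k_true > 0 to define a relaxation time")
    tau = 1.0 / rate
    return tau * np.linspace(n_relax - (n_snapshots - 1), n_relax, n_snapshots)


def sample_counts(fraction: float, n: int, seed: int) -> int:
    """Binomial draw of the number of successes among ``n`` molecules."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction must be in [0,1], got {fraction}")
    if n < 1:
        raise ValueError("n must be >= 1")
    return int(np.random.default_rng(seed).binomial(n, fraction))


# ---------------------------------------------------------------------------
# trace synthesis
# ---------------------------------------------------------------------------

def _route_emissions(f5: float, f55: float, alive: Dict[str, bool],
                     has_cy55: bool, budget: float) -> Tuple[float, float, float]:
    """True per-frame emissions given survivor set and signature shares.

    A bleached acceptor's FRET share is redistributed to the surviving
    fluorophores in proportion to their shares (total budget preserved);
    once the donor Cy3 is bleached nothing is excited.
    """
    if not alive["cy3"]:
        return 0.0, 0.0, 0.0
    s3 = 1.0 - f5 - f55
    s5 = f5 if alive["cy5"] else 0.0
    s55 = f55 if (has_cy55 and alive["cy55"]) else 0.0
    tot = s3 + s5 + s55
    if tot <= 0:
        return budget, 0.0, 0.0  # no acceptor path left: donor emits all
    scale = budget / tot
    return s3 * scale, s5 * scale, s55 * scale


def synthesize_trace(
    species_class: str,
    params: TraceSimulationParams,
    seed,
) -> RawTrace:
    """Simulate one molecule's raw three-channel trace.

    ``seed`` may be an int, a SeedSequence, or a Generator.  Ground truth
    (class, per-fluorophore bleach frames) is recorded in ``meta``.
    """
    if species_class not in SPECIES_CLASSES:
        raise ValueError(f"unknown species class {species_class!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    f5, f55 = params.signatures[species_class]
    has_cy55 = species_class != "intact"
    dt = params.frame_interval
    nf = params.n_frames

    fluors = ["cy3", "cy5"] + (["cy55"] if has_cy55 else [])
    bleach_t = {}
    for fl in fluors:
        tau = params.bleach_lifetime[fl]
        bleach_t[fl] = rng.exponential(tau) if math.isfinite(tau) else math.inf
    # first frame index on which the fluorophore is dark
    bleach_frame = {
        fl: (int(t // dt) if math.isfinite(t) else None)
        for fl, t in bleach_t.items()
    }

    phase = np.array(
        ["green"] * params.n_frames_green
        + ["dark"] * params.n_frames_dark
        + ["red"] * params.n_frames_red
    )
    i3_true = np.zeros(nf)
    i5_true = np.zeros(nf)
    i55_true = np.zeros(nf)
    for f in range(nf):
        alive = {
            fl: (bleach_frame.get(fl) is None or f < bleach_frame[fl])
            for fl in ("cy3", "cy5", "cy55")
        }
        if phase[f] == "green":
            i3_true[f], i5_true[f], i55_true[f] = _route_emissions(
                f5, f55, alive, has_cy55, params.emission_budget
            )
        elif phase[f] == "red":
            # direct acceptor excitation probes survival
            i5_true[f] = params.red_excitation_budget if alive["cy5"] else 0.0
            i55_true[f] = (
                params.red_excitation_budget if (has_cy55 and alive["cy55"]) else 0.0
            )

    ia1, ia2 = forward_leakage(i5_true, i55_true, params.leakage)
    b3, b5, b55 = params.background
    noise = (
        rng.normal(0.0, params.noise_sd, size=(3, nf))
        if params.noise_sd > 0
        else np.zeros((3, nf))
    )
    df = pd.DataFrame(
        {
            "frame": np.arange(nf),
            "time_s": np.arange(nf) * dt,
            "phase": phase,
            "i_cy3_raw": i3_true + b3 + noise[0],
            "i_cy5_raw": ia1 + b5 + noise[1],
            "i_cy55_raw": ia2 + b55 + noise[2],
        }
    )
    meta = {
        "true_class": species_class,
        "true_bleach_frames": {
            fl: bleach_frame.get(fl) for fl in fluors
        },
        "signature": {"fret_cy5": f5, "fret_cy55": f55},
    }
    return RawTrace(frames=df, meta=meta)


# ---------------------------------------------------------------------------
# benchmark dataset
# ---------------------------------------------------------------------------

def class_probabilities(t_s: float, model: ExchangeModel) -> Dict[str, float]:
    """Population class probabilities among observable molecules at time t.

    The distal- and proximal-exchanged fractions are both f_e(t) by the
    proximal/distal symmetry of the exchange event; the doubly-labeled
    state is negligible over the fitted time range and folded into the
    proximal signature class.
    """
    fe = float(closed_form_fraction(t_s, model))
    return {
        "intact": 1.0 - 2.0 * fe,
        "proximal_exchanged": fe,
        "distal_exchanged": fe,
    }


@dataclass
class BenchmarkDataset:
    traces: List[RawTrace]
    manifest: pd.DataFrame
    design: TimeCourseDesign
    params: TraceSimulationParams


def generate_benchmark_dataset(
    design: TimeCourseDesign,
    params: Optional[TraceSimulationParams] = None,
    out_dir: Optional[Path] = None,
    population: str = "closed_form",
    write_traces: bool = True,
) -> BenchmarkDataset:
    """Simulate a full labeled time-course dataset.

    For each time point and replicate, draws each molecule's class from the
    population model (closed-form by default; ``population="stochastic"``
    uses the collision Monte Carlo as the population oracle) and
    synthesizes its trace.  A manifest records the ground truth.  The whole
    dataset derives deterministically from ``design.seed`` via per-molecule
    child seeds.
    """
    params = params or TraceSimulationParams()
    if population not in ("closed_form", "stochastic"):
        raise ConfigError(f"unknown population model {population!r}")

    ss = np.random.SeedSequence(design.seed)
    pop_rng = np.random.default_rng(ss.spawn(1)[0])
    times_s = np.asarray(design.time_points_h, dtype=float) * 3600.0

    if population == "stochastic":
        nonzero_t = times_s[times_s > 0]
        frac_df = (
            simulate_exchange_stochastic(design, 10000, times_s=nonzero_t,
                                         rng=pop_rng)
            if len(nonzero_t)
            else None
        )

        def probs(ti, t):
            if t == 0:
                return {"intact": 1.0, "proximal_exchanged": 0.0,
                        "distal_exchanged": 0.0}
            row = frac_df.loc[np.isclose(frac_df["time_s"], t)].iloc[0]
            return {"intact": float(row["A"]),
                    "proximal_exchanged": float(row["b"] + row["B'"]),
                    "distal_exchanged": float(row["e"])}
    else:
        model = design.model()
        def probs(ti, t):
            return class_probabilities(t, model)

    classes = list(SPECIES_CLASSES)
    records = []
    traces: List[RawTrace] = []
    mol_seeds = ss.spawn(
        len(times_s) * design.n_replicates * design.n_molecules_per_replicate + 1
    )[1:]

    if out_dir is not None:
        out_dir = Path(out_dir)
        (out_dir / "traces").mkdir(parents=True, exist_ok=True)

    idx = 0
    for ti, (t_h, t_s) in enumerate(zip(design.time_points_h, times_s)):
        p = probs(ti, t_s)
        pvec = np.array([p[c] for c in classes])
        pvec = pvec / pvec.sum()
        for rep in range(design.n_replicates):
            for m in range(design.n_molecules_per_replicate):
                child = mol_seeds[idx]
                rng = np.random.default_rng(child)
                cls = classes[rng.choice(len(classes), p=pvec)]
                trace = synthesize_trace(cls, params, rng)
                mol_id = f"t{t_h:g}h_r{rep}_m{m:04d}"
                trace.meta.update(
                    molecule_id=mol_id, timepoint_h=float(t_h), replicate=rep,
                )
                path = None
                if out_dir is not None and write_traces:
                    from .io import write_trace_csv

                    path = out_dir / "traces" / f"{mol_id}.csv"
                    write_trace_csv(trace, path)
                records.append(
                    {
                        "molecule_id": mol_id,
                        "timepoint_h": float(t_h),
                        "replicate": rep,
                        "true_class": cls,
                        "true_bleach_frames": json.dumps(
                            trace.meta["true_bleach_frames"], sort_keys=True
                        ),
                        "file": str(path) if path is not None else "",
                    }
                )
                traces.append(trace)
                idx += 1
    manifest = pd.DataFrame(records)
    if out_dir is not None:
        from .io import write_manifest

        write_manifest(manifest, Path(out_dir) / "manifest.jsonl")
    return BenchmarkDataset(traces=traces, manifest=manifest,
                            design=design, params=params)
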