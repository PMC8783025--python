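"""Termination efficiency, termination-point calling and stoichiometries.

The termination efficiency of a valve is the fractional drop in read depth
across it,

    T_e = (R(x_s) - R(x_e)) / R(x_s),

where R(x) is the read depth at reference position x and [x_s, x_e) bounds
the valve.  Raw T_e is reported unclamped (slightly negative values on noisy
profiles are diagnostic); the corrected value subtracts the deviation
predicted by a forward-simulation model of library-prep distortions and is
clamped to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .align import DEFAULT_SCORING, ScoringScheme
from .parts import Design, GuideArray
from .profiles import DepthProfile, build_depth_profile, filter_reads, map_read, normalize_and_delta
from .simulate import SimulationConfig, TruthModel, simulate_pool


def compute_te(profile: DepthProfile | np.ndarray, x_s: int, x_e: int) -> float:
    """Fractional read-depth drop across the valve (unclamped)."""
    depth = profile.depth if isinstance(profile, DepthProfile) else np.asarray(profile)
    if not 0 <= x_s < x_e < len(depth):
        raise ValueError("valve bounds must satisfy 0 <= x_s < x_e < reference length")
    r_s = float(depth[x_s])
    if r_s <= 0:
        raise ValueError("zero read depth at valve start")
    return (r_s - float(depth[x_e])) / r_s


# ---------------------------------------------------------------------------
# Deviation model: forward-simulated measured-vs-true Te map
# ---------------------------------------------------------------------------


@dataclass
class DeviationModel:
    """Fitted map from true to measured T_e under a distortion model.

    ``te_true`` is the fitting grid over [0, 1]; ``te_measured`` the mean
    measured value at each grid point.  ``deviation_at(t)`` interpolates
    measured - true; correction inverts the measured->true map by monotone
    linear interpolation.
    """

    te_true: np.ndarray
    te_measured: np.ndarray
    config: dict = field(default_factory=dict)

    def __post_init__(self):
        self.te_true = np.asarray(self.te_true, dtype=float)
        self.te_measured = np.asarray(self.te_measured, dtype=float)
        if self.te_true.size < 2:
            raise ValueError("deviation grid must have at least 2 points")
        if self.te_true[0] > 0.0 or self.te_true[-1] < 1.0:
            raise ValueError("deviation grid must cover [0, 1]")
        if np.any(np.diff(self.te_true) <= 0):
            raise ValueError("te_true grid must be strictly increasing")

    def deviation_at(self, te: float) -> float:
        return float(np.interp(te, self.te_true, self.te_measured - self.te_true))

    def is_monotone(self) -> bool:
        return bool(np.all(np.diff(self.te_measured) >= -1e-12))

    def to_dict(self) -> dict:
        return {"te_true": self.te_true.tolist(), "te_measured": self.te_measured.tolist(),
                "config": self.config}

    @classmethod
    def from_dict(cls, d: dict) -> "DeviationModel":
        return cls(np.array(d["te_true"]), np.array(d["te_measured"]), d.get("config", {}))


def measure_pool_te(designs: list[Design], models: dict[str, TruthModel],
                    config: SimulationConfig, scoring: ScoringScheme = DEFAULT_SCORING,
                    terminator_margin: int = 20,
                    with_empirical: bool = False):
    """Simulate a pool and push it through mapping, filtering and T_e.

    Demultiplexing is skipped (each read is mapped to its true design): this
    isolates profile-level distortions, which is what the deviation model is
    for.  Returns measured raw T_e per design; with ``with_empirical`` each
    value is the pair (measured T_e, realized terminated fraction), so the
    Bernoulli sampling noise can be separated from pipeline distortion.
    """
    from .align import ReferenceIndex

    reads, _truth = simulate_pool(designs, models, config)
    out = {}
    by_design: dict[str, list] = {d.id: [] for d in designs}
    for r in reads:
        by_design[r.design_id].append(r)
    for d in designs:
        mapped = []
        index = ReferenceIndex(d.reference_sequence, scoring.word_size, design_id=d.id)
        for r in by_design[d.id]:
            mr = map_read(r.id, r.sequence, index, scoring, cassette=d.cassette)
            if mr is not None:
                mapped.append(mr)
        kept, _log = filter_reads(mapped, d, terminator_margin)
        profile = build_depth_profile(kept, len(d.reference_sequence), d.id)
        te = compute_te(profile, d.x_s, d.x_e)
        if with_empirical:
            empirical = float(np.mean([r.is_terminated for r in by_design[d.id]]))
            out[d.id] = (te, empirical)
        else:
            out[d.id] = te
    return out


def fit_deviation_model(
    designs: list[Design],
    config: SimulationConfig,
    te_grid: np.ndarray | None = None,
    reads_per_point: int = 1000,
    scoring: ScoringScheme = DEFAULT_SCORING,
) -> DeviationModel:
    """Fit measured-vs-true T_e on a grid by forward simulation.

    For each true T_e on the grid every design is simulated with that
    efficiency and run through the measurement pipeline.  The deviation at a
    grid point is the mean of (measured T_e - realized terminated fraction)
    across designs — comparing against the realized fraction rather than the
    nominal grid value cancels the Bernoulli sampling noise, so with no
    distortion configured the deviation is identically zero (the
    distortion-free pipeline is exact).
    """
    from .simulate import default_truth_model

    if te_grid is None:
        te_grid = np.round(np.arange(0.0, 1.0001, 0.05), 10)
    te_grid = np.asarray(te_grid, dtype=float)
    if te_grid.size < 2:
        raise ValueError("deviation grid must have at least 2 points")
    measured = np.empty_like(te_grid)
    for g, te_true in enumerate(te_grid):
        models = {d.id: default_truth_model(d, float(te_true)) for d in designs}
        cfg = SimulationConfig(
            substitution_rate=config.substitution_rate,
            truncation_prob=config.truncation_prob,
            reads_per_design=reads_per_point,
            seed=config.seed + g + 1,
            min_keep=config.min_keep,
        )
        pairs = measure_pool_te(designs, models, cfg, scoring, with_empirical=True)
        deviation = float(np.mean([te - emp for te, emp in pairs.values()]))
        measured[g] = float(te_true) + deviation
    return DeviationModel(te_grid, measured, config={
        "substitution_rate": config.substitution_rate,
        "truncation_prob": config.truncation_prob,
        "reads_per_point": reads_per_point,
        "n_designs": len(designs),
    })


def correct_te(te_raw: float, model: DeviationModel) -> float:
    """Invert the fitted measured->true map; result clamped to [0, 1].

    Equivalent to subtracting the predicted deviation at the matching true
    T_e; evaluated by monotone linear interpolation of the inverse map, which
    behaves better than evaluating the deviation at the raw value when
    deviations are large.
    """
    if not -0.5 <= te_raw <= 1.5:
        raise ValueError(f"te_raw = {te_raw} outside [-0.5, 1.5]; upstream profile corrupt?")
    if not model.is_monotone():
        raise ValueError("fitted measured-vs-true map is not monotone; refit with more reads")
    corrected = float(np.interp(te_raw, model.te_measured, model.te_true))
    return min(1.0, max(0.0, corrected))


def correction_experiment(
    designs: list[Design],
    config: SimulationConfig,
    model: DeviationModel | None = None,
    eval_grid: np.ndarray | None = None,
    reads_per_point: int = 1500,
    scoring: ScoringScheme = DEFAULT_SCORING,
) -> tuple[pd.DataFrame, DeviationModel]:
    """Recovery experiment: fit a deviation model, then measure fresh pools.

    For each true T_e on ``eval_grid`` a new pool (seeds disjoint from the
    fitting pools) is simulated and measured; the per-point measured T_e is
    the mean over designs, matching what the deviation model predicts.
    Returns a table (te_true, te_raw, te_corrected) plus the model.
    """
    if model is None:
        model = fit_deviation_model(designs, config, reads_per_point=reads_per_point,
                                    scoring=scoring)
    if eval_grid is None:
        eval_grid = np.round(np.arange(0.0, 1.0001, 0.1), 10)
    from .simulate import default_truth_model

    rows = []
    for g, te_true in enumerate(np.asarray(eval_grid, dtype=float)):
        models = {d.id: default_truth_model(d, float(te_true)) for d in designs}
        cfg = SimulationConfig(
            substitution_rate=config.substitution_rate,
            truncation_prob=config.truncation_prob,
            reads_per_design=reads_per_point,
            seed=config.seed + 1000 + g,
            min_keep=config.min_keep,
        )
        tes = measure_pool_te(designs, models, cfg, scoring)
        te_raw = float(np.mean(list(tes.values())))
        rows.append((float(te_true), te_raw, correct_te(te_raw, model)))
    return pd.DataFrame(rows, columns=["te_true", "te_raw", "te_corrected"]), model


# ---------------------------------------------------------------------------
# Termination points and U-tracts
# ---------------------------------------------------------------------------


def call_termination_points(drop: np.ndarray, x_s: int, x_e: int,
                            secondary_fraction: float = 0.25):
    """Call termination positions from a Δ-profile.

    The dominant position is the argmax of the drop over the valve interval
    (x_s, x_e]; secondary positions are local maxima reaching at least
    ``secondary_fraction`` of the maximum drop.  Weights are the drop values
    renormalized over called points.  Ties break toward the 5'-most position.
    Returns ``(points, dominant, max_drop)`` where points is a list of
    (position, weight); an all-non-positive window yields ``([], None, 0.0)``.
    """
    drop = np.asarray(drop, dtype=float)
    lo, hi = x_s + 1, x_e + 1
    window = drop[lo:hi]
    if window.size == 0 or np.max(window) <= 0:
        return [], None, 0.0
    max_drop = float(np.max(window))
    dominant = int(lo + np.argmax(window))
    threshold = secondary_fraction * max_drop
    points = []
    for t in range(window.size):
        v = window[t]
        if v <= 0 or v < threshold:
            continue
        left = window[t - 1] if t > 0 else -np.inf
        right = window[t + 1] if t < window.size - 1 else -np.inf
        if v > left and v >= right:
            points.append(lo + t)
    if dominant not in points:
        points.append(dominant)
        points.sort()
    total = sum(drop[p] for p in points)
    return [(p, float(drop[p] / total)) for p in points], dominant, max_drop


def count_u_tract(reference: str, position: int, include_final: bool = True) -> int:
    """Number of U residues in the 8-nt U-tract at a termination position.

    ``position`` is the exclusive end of the terminated transcript (final
    transcribed nucleotide at ``position - 1``).  The window is the 8 bases
    ending at the final nucleotide inclusive; ``include_final=False`` shifts
    the window one base upstream.
    """
    end = position if include_final else position - 1
    if end < 8:
        raise ValueError("termination position too close to the 5' end for an 8-nt window")
    return reference[end - 8 : end].count("T")


# ---------------------------------------------------------------------------
# Stoichiometries
# ---------------------------------------------------------------------------


def isoform_stoichiometry(te: float) -> float:
    """Terminated:read-through isoform ratio, as the real number r in r:1."""
    if not 0.0 <= te < 1.0:
        raise ValueError("te must lie in [0, 1); te = 1 leaves no read-through isoform")
    return te / (1.0 - te)


def array_stoichiometry(valve_te) -> np.ndarray:
    """Relative abundance of each unit in a valve-separated array.

    Unit i (1-indexed) has abundance prod_{j<i} (1 - te_j); unit 1 is 1.
    """
    valve_te = np.asarray(valve_te, dtype=float)
    if np.any((valve_te < 0) | (valve_te > 1)):
        raise ValueError("valve te values must lie in [0, 1]")
    return np.concatenate([[1.0], np.cumprod(1.0 - valve_te)])


# ---------------------------------------------------------------------------
# Per-design measurement record
# ---------------------------------------------------------------------------


@dataclass
class ValveMeasurement:
    design_id: str
    n_reads: int
    depth_at_xs: int
    depth_at_xe: int
    te_raw: float
    te_corrected: float | None
    termination_positions: list[tuple[int, float]]
    dominant_position: int | None
    max_drop: float
    u_count: int | None


def measure_valve(profile: DepthProfile, design: Design,
                  model: DeviationModel | None = None,
                  secondary_fraction: float = 0.25) -> ValveMeasurement:
    """Assemble the full measurement record for one design's profile."""
    te_raw = compute_te(profile, design.x_s, design.x_e)
    _normalized, drop = normalize_and_delta(profile, design.x_s)
    points, dominant, max_drop = call_termination_points(drop, design.x_s, design.x_e,
                                                         secondary_fraction)
    u_count = None
    if dominant is not None and dominant >= 8:
        u_count = count_u_tract(design.reference_sequence, dominant)
    te_corrected = correct_te(te_raw, model) if model is not None else None
    return ValveMeasurement(
        design_id=design.id,
        n_reads=profile.n_reads,
        depth_at_xs=int(profile.depth[design.x_s]),
        depth_at_xe=int(profile.depth[design.x_e]),
        te_raw=te_raw,
        te_corrected=te_corrected,
        termination_positions=points,
        dominant_position=dominant,
        max_drop=max_drop,
        u_count=u_count,
    )


def measurements_table(measurements: list[ValveMeasurement]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "design_id": [m.design_id for m in measurements],
            "n_reads": [m.n_reads for m in measurements],
            "depth_xs": [m.depth_at_xs for m in measurements],
            "depth_xe": [m.depth_at_xe for m in measurements],
            "te_raw": [m.te_raw for m in measurements],
            "te_corrected": [m.te_corrected for m in measurements],
            "dominant_position": [m.dominant_position for m in measurements],
            "max_drop": [m.max_drop for m in measurements],
            "u_count": [m.u_count for m in measurements],
            "termination_points": [
                ";".join(f"{p}:{w:.4f}" for p, w in m.termination_positions)
                for m in measurements
            ],
        }
    )


@dataclass
class ArrayMeasurement:
    array_id: str
    valve_te: list[float]
    abundances: np.ndarray


def measure_array(profile: DepthProfile, array: GuideArray) -> ArrayMeasurement:
    """Measured per-valve T_e and resulting unit abundances for an array."""
    tes = [compute_te(profile, vs, ve) for vs, ve in array.valves]
    clamped = [min(1.0, max(0.0, t)) for t in tes]
    return ArrayMeasurement(array.id, tes, array_stoichiometry(clamped))
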