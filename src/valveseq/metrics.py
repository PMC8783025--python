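"""Group-level metrics and the end-to-end simulation-study harness.

These summarize a characterized library: tunability (percentage deviation of
a design's T_e from its core-terminator group median, as a percentage of the
maximum attainable deviation in that direction), insulation (coefficient of
variation of T_e across spacer variants), replicate agreement, and deviations
between predicted and measured design frequencies.  ``run_sim_study`` wires
the whole pipeline together — library synthesis, read simulation,
demultiplexing, profiling, T_e measurement — and reports assignment accuracy
and T_e recovery error per substitution rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .align import DEFAULT_SCORING, ScoringScheme
from .demux import DesignLibrary, demultiplex_pool
from .parts import Design, Role, enumerate_designs
from .profiles import build_depth_profile, filter_reads, map_pool
from .simulate import (SimulationConfig, default_truth_model, simulate_pool,
                       synthetic_part_set)
from .termination import compute_te


def coverage_fold(n_colonies: float, n_designs: int) -> float:
    """Library fold coverage: sampled colonies per unique design."""
    if n_designs <= 0:
        raise ValueError("n_designs must be positive")
    return n_colonies / n_designs


def percentage_deviation(te: float, group_median: float) -> float:
    """Signed deviation of ``te`` from the group median, as a percentage of
    the maximum attainable deviation in that direction (1 - m upward, m
    downward)."""
    m = group_median
    if not 0.0 <= m <= 1.0:
        raise ValueError("group median must lie in [0, 1]")
    if te == m:
        return 0.0
    if te >= m:
        denom = 1.0 - m
    else:
        denom = m
    if denom == 0.0:
        return 100.0 if te > m else -100.0
    return 100.0 * (te - m) / denom


def cv_across_spacers(te_values) -> float:
    """Coefficient of variation (sample SD / mean) of T_e across spacers."""
    v = np.asarray(te_values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values")
    mean = float(v.mean())
    if mean <= 0:
        raise ValueError("mean must be positive for a CV")
    return float(v.std(ddof=1)) / mean


def replicate_agreement(a, b, threshold: float = 0.05) -> dict:
    """Squared Pearson correlation and the fraction of designs whose T_e
    differs by less than ``threshold`` between replicates."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    frac = float(np.mean(np.abs(a - b) < threshold))
    if a.std() == 0 or b.std() == 0:
        return {"r_squared": None, "fraction_within_threshold": frac}
    r = float(np.corrcoef(a, b)[0, 1])
    return {"r_squared": r * r, "fraction_within_threshold": frac}


def frequency_deviation_report(measured: dict, predicted: dict, cutoff: float = 20.0) -> pd.DataFrame:
    """Absolute percentage deviation per design between measured and predicted
    frequencies, flagging designs above ``cutoff`` percent.  Designs with a
    predicted frequency of zero are flagged ``unpredicted`` and excluded from
    the percentage."""
    if set(measured) != set(predicted):
        raise ValueError("measured and predicted must cover the same designs")
    rows = []
    for did in sorted(measured):
        p, m = predicted[did], measured[did]
        if p == 0:
            rows.append((did, m, p, np.nan, False, True))
        else:
            dev = abs(m - p) / p * 100.0
            rows.append((did, m, p, dev, dev > cutoff, False))
    return pd.DataFrame(rows, columns=["design_id", "measured", "predicted",
                                       "abs_pct_deviation", "flagged", "unpredicted"])


def grouped_te_table(designs: list[Design], te_by_design: dict[str, float]) -> pd.DataFrame:
    """Long-format T_e records with part ids, for grouping by core terminator."""
    rows = []
    for d in designs:
        if d.id not in te_by_design:
            continue
        rows.append(
            (
                d.id,
                d.part_ids.get(Role.SPACER),
                d.part_ids.get(Role.MODIFIER),
                d.part_ids.get(Role.TERMINATOR),
                te_by_design[d.id],
            )
        )
    return pd.DataFrame(rows, columns=["design_id", "spacer", "modifier", "terminator", "te"])


def group_medians(table: pd.DataFrame, by: str = "terminator") -> pd.Series:
    return table.groupby(by)["te"].median()


# ---------------------------------------------------------------------------
# Simulation study
# ---------------------------------------------------------------------------


@dataclass
class SimStudyConfig:
    n_spacers: int = 4
    n_modifiers: int = 5
    n_terminators: int = 5
    reads_per_design: int = 100
    substitution_rates: tuple = (0.0, 0.15)
    truncation_prob: float = 0.0
    flank5_length: int = 50
    flank3_length: int = 50
    seed: int = 0
    scoring: ScoringScheme = DEFAULT_SCORING

    def validate(self):
        bad = []
        if self.n_terminators < 1:
            bad.append("n_terminators")
        if self.reads_per_design < 0:
            bad.append("reads_per_design")
        if any(not 0 <= r <= 1 for r in self.substitution_rates):
            bad.append("substitution_rates")
        if not 0 <= self.truncation_prob <= 1:
            bad.append("truncation_prob")
        if bad:
            raise ValueError(f"inconsistent sim-study config keys: {bad}")


@dataclass
class SimStudyResult:
    config: SimStudyConfig
    accuracy: pd.DataFrame
    recovery: pd.DataFrame
    te_table: pd.DataFrame
    confusion_by_distance: pd.DataFrame


def synthetic_design_library(n_spacers: int, n_modifiers: int, n_terminators: int,
                             seed: int = 0, flank5_length: int = 50,
                             flank3_length: int = 50) -> list[Design]:
    """A random part set enumerated into a design library with fixed flanks."""
    parts = synthetic_part_set(n_spacers, n_modifiers, n_terminators, seed)
    rng = np.random.default_rng([seed, 9_001])
    bases = list("ACGT")
    flank5 = "".join(rng.choice(bases, size=flank5_length))
    flank3 = "".join(rng.choice(bases, size=flank3_length))
    return enumerate_designs(parts, (flank5, flank3))


def _levenshtein(a: str, b: str) -> int:
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def _design_distance(d1: Design, d2: Design, cache: dict) -> int:
    key = (d1.id, d2.id)
    if key not in cache:
        dist = 0
        for role in (Role.SPACER, Role.MODIFIER, Role.TERMINATOR):
            s1 = d1.part_sequence(role) if role in d1.intervals else ""
            s2 = d2.part_sequence(role) if role in d2.intervals else ""
            if s1 != s2:
                dist += _levenshtein(s1, s2)
        cache[key] = dist
    return cache[key]


def run_sim_study(config: SimStudyConfig) -> SimStudyResult:
    """Simulate, demultiplex and measure a synthetic library at several
    substitution rates; fully seeded and reproducible."""
    config.validate()
    designs = synthetic_design_library(config.n_spacers, config.n_modifiers,
                                       config.n_terminators, config.seed,
                                       config.flank5_length, config.flank3_length)
    by_id = {d.id: d for d in designs}
    te_rng = np.random.default_rng([config.seed, 7_321])
    true_te = {did: float(te_rng.uniform(0, 1)) for did in sorted(by_id)}
    models = {did: default_truth_model(by_id[did], t) for did, t in true_te.items()}
    library = DesignLibrary(designs, config.scoring)

    acc_rows, rec_rows, te_rows, conf_rows = [], [], [], []
    dist_cache: dict = {}
    for rate_idx, rate in enumerate(config.substitution_rates):
        sim_cfg = SimulationConfig(
            substitution_rate=rate,
            truncation_prob=config.truncation_prob,
            reads_per_design=config.reads_per_design,
            seed=config.seed * 1000 + rate_idx,
        )
        reads, truth = simulate_pool(designs, models, sim_cfg)
        table, _per_design, summary = demultiplex_pool(
            ((r.id, r.sequence) for r in reads), library, config.scoring
        )
        merged = table.merge(truth[["read_id", "design_id"]].rename(
            columns={"design_id": "true_design"}), on="read_id")
        assigned = merged[merged["status"] == "assigned"]
        n_total = len(merged)
        n_assigned = len(assigned)
        n_correct = int((assigned["design_id"] == assigned["true_design"]).sum())
        acc_rows.append((rate, n_total, n_assigned / n_total if n_total else 0.0,
                         n_correct / n_total if n_total else 0.0,
                         n_correct / n_assigned if n_assigned else 0.0))
        for _, row in assigned[assigned["design_id"] != assigned["true_design"]].iterrows():
            dist = _design_distance(by_id[row["true_design"]], by_id[row["design_id"]],
                                    dist_cache)
            conf_rows.append((rate, row["true_design"], row["design_id"], dist))
        # Te recovery through the real pipeline on assigned reads
        reads_by_id = {r.id: r.sequence for r in reads}
        mapped, _unmappable = map_pool(table, reads_by_id, designs, config.scoring)
        errs = []
        for d in designs:
            kept, _log = filter_reads(mapped[d.id], d)
            profile = build_depth_profile(kept, len(d.reference_sequence), d.id)
            if profile.depth[d.x_s] <= 0:
                continue
            te_raw = compute_te(profile, d.x_s, d.x_e)
            te_rows.append((rate, d.id, d.part_ids.get(Role.SPACER),
                            d.part_ids.get(Role.MODIFIER), d.part_ids.get(Role.TERMINATOR),
                            true_te[d.id], te_raw))
            errs.append(te_raw - true_te[d.id])
        errs = np.array(errs)
        rec_rows.append((rate, len(errs), float(np.sqrt(np.mean(errs**2))),
                         float(np.mean(np.abs(errs)))))

    return SimStudyResult(
        config=config,
        accuracy=pd.DataFrame(acc_rows, columns=["rate", "n_reads", "frac_assigned",
                                                 "accuracy_overall", "accuracy_assigned"]),
        recovery=pd.DataFrame(rec_rows, columns=["rate", "n_designs", "rmse", "mean_abs_error"]),
        te_table=pd.DataFrame(te_rows, columns=["rate", "design_id", "spacer", "modifier",
                                                "terminator", "true_te", "te_raw"]),
        confusion_by_distance=pd.DataFrame(conf_rows, columns=["rate", "true_design",
                                                               "assigned_design", "part_distance"]),
    )
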