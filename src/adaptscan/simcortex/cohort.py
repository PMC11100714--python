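"""Synthetic cohorts emulating the study's three groups and effect structure.

The cohort comprises typically developing (TD) controls contributing both
hemispheres, control patients (resection sparing ventral occipitotemporal
cortex) and OTC patients, each contributing a single preserved hemisphere.
Two complementary generators are provided:

* :func:`simulate_cohort` / :func:`simulate_hemisphere_data` — full BOLD
  time-series simulation per hemisphere region (category-tuned voxel clusters
  with a repetition-fatigue mechanism), feeding the GLM/ROI stages; and
* :func:`simulate_measures` — the same group/participant effect structure
  drawn directly at the level of the derived dependent measures (CS
  amplitude, responsivity, RS magnitude, RSA model fit, accuracy), used by
  the statistical calibration and recovery suites where hundreds of replicate
  cohorts are needed.

Default magnitudes are anchored to the study's reported estimates: TD CS
amplitude near 1.54 % signal, RS magnitude near 0.27, responsivity means of
0.74/0.54/0.82 for faces/objects/words, and the reported group x task
accuracy table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .._seeds import derive_rng
from .designs import (
    ADAPTATION_BLOCK_TYPES,
    ADAPTATION_CATEGORIES,
    ADAPTATION_CONDITIONS,
    AdaptationTiming,
    LocalizerTiming,
    build_adaptation_design,
    build_localizer_design,
)
from .signal import (
    TimeSeriesDataset,
    VoxelTuningParams,
    expected_condition_attenuation,
    simulate_timeseries,
)

__all__ = [
    "GROUPS",
    "CohortSpec",
    "participant_records",
    "simulate_hemisphere_data",
    "simulate_cohort",
    "simulate_measures",
    "simulate_activation_patterns",
    "DEFAULT_ACCURACY",
    "DEFAULT_TRIALS",
]

GROUPS = ("TD", "control_patient", "OTC_patient")

#: group x task accuracy probabilities (study's reported estimates)
DEFAULT_ACCURACY: dict[str, dict[str, float]] = {
    "TD": {"faces": 0.90, "objects": 0.79, "words": 0.96},
    "control_patient": {"faces": 0.90, "objects": 0.71, "words": 0.96},
    "OTC_patient": {"faces": 0.73, "objects": 0.55, "words": 0.93},
}
#: trials per task: face task 60, word task 96; object-task total is an
#: artifact choice mirroring the face task
DEFAULT_TRIALS = {"faces": 60, "objects": 60, "words": 96}

#: per-category CS amplitude targets (% signal; mean 1.54, faces > words)
CS_TARGETS = {"faces": 1.70, "objects": 1.52, "words": 1.40}
#: per-category mean adaptation responsivity targets (% signal)
RESPONSIVITY_TARGETS = {"faces": 0.74, "objects": 0.54, "words": 0.82}
#: RS magnitude target (different - same median, % signal)
RS_TARGET = 0.27
#: RSA model-fit (Fisher z) targets by model kind
MODEL_FIT_TARGETS = {"CS": 0.68, "RS": 0.30, "CS_RS": 0.76}


@dataclass(frozen=True)
class CohortSpec:
    """Sizes, demographics and injected group effects of a synthetic cohort."""

    n_td: int = 21
    n_control_patients: int = 12
    n_otc_patients: int = 9
    age_mean: float = 16.0
    age_sd: float = 5.0
    age_range: tuple[float, float] = (7.0, 38.0)
    #: effect_deltas[group][measure] -> additive shift (scalar, or per-category
    #: mapping for "accuracy")
    effect_deltas: Mapping[str, Mapping[str, object]] = field(default_factory=dict)
    grid_shape: tuple[int, int, int] = (8, 6, 4)
    n_localizer_runs: int = 3
    n_adaptation_runs: int = 6
    noise_sd: float = 5.0
    ar1: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_td, self.n_control_patients, self.n_otc_patients) < 1:
            raise ValueError("all group sizes must be >= 1")
        if self.age_sd <= 0 or self.age_range[0] >= self.age_range[1]:
            raise ValueError("invalid age distribution")

    def delta(self, group: str, measure: str, category: str | None = None) -> float:
        d = self.effect_deltas.get(group, {}).get(measure, 0.0)
        if isinstance(d, Mapping):
            return float(d.get(category, 0.0))
        return float(d)

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.grid_shape))


def _truncated_ages(spec: CohortSpec, rng: np.random.Generator, n: int) -> np.ndarray:
    lo, hi = spec.age_range
    a, b = (lo - spec.age_mean) / spec.age_sd, (hi - spec.age_mean) / spec.age_sd
    return stats.truncnorm.rvs(
        a, b, loc=spec.age_mean, scale=spec.age_sd, size=n, random_state=rng
    )


def participant_records(spec: CohortSpec) -> pd.DataFrame:
    """Participant table: id, group, preserved hemisphere(s), age, gender.

    TD controls carry both hemispheres (`preserved_hemisphere = "both"`);
    patients alternate LH/RH preservation within group.
    """
    rng = derive_rng(spec.seed, "participants")
    rows = []
    counts = {
        "TD": spec.n_td,
        "control_patient": spec.n_control_patients,
        "OTC_patient": spec.n_otc_patients,
    }
    idx = 0
    for group, n in counts.items():
        ages = _truncated_ages(spec, rng, n)
        for i in range(n):
            hemi = "both" if group == "TD" else ("LH" if i % 2 == 0 else "RH")
            rows.append(
                {
                    "participant_id": f"sub-{idx:03d}",
                    "group": group,
                    "preserved_hemisphere": hemi,
                    "age": float(ages[i]),
                    "gender": "female" if rng.integers(2) else "male",
                }
            )
            idx += 1
    return pd.DataFrame(rows)


def hemispheres_of(record: Mapping[str, object]) -> tuple[str, ...]:
    h = record["preserved_hemisphere"]
    return ("LH", "RH") if h == "both" else (str(h),)


# --------------------------------------------------------------------------
# time-series level generation


def solve_adaptation_tuning(
    mean_responsivity: float, rs_magnitude: float, n_stims: int = 12
) -> tuple[float, float]:
    """Fatigue factor and selectivity reproducing a target mean responsivity
    (over the three conditions) and RS magnitude (different - same), under the
    exemplar-memory fatigue model.

    Returns ``(fatigue, selectivity)`` where fitted β (% signal) for condition
    c is ``0.1 * selectivity * attenuation(c)`` at the default baseline of
    1000 scanner units.
    """
    if not (0 < rs_magnitude < 3 * mean_responsivity):
        raise ValueError("rs_magnitude must be positive and < 3x mean responsivity")
    ratio = rs_magnitude / mean_responsivity

    def gap(f: float) -> float:
        gs = expected_condition_attenuation("same", n_stims, f)
        ga = expected_condition_attenuation("alternating", n_stims, f)
        return (1.0 - gs) - ratio * (1.0 + ga + gs) / 3.0

    f = float(optimize.brentq(gap, 1e-6, 1.0 - 1e-9))
    gs = expected_condition_attenuation("same", n_stims, f)
    sel = rs_magnitude / (0.1 * (1.0 - gs))
    return f, sel


def _planted_clusters(grid: tuple[int, int, int]) -> dict[str, np.ndarray]:
    """Index sets of the category-selective voxel clusters within the grid."""
    nx, ny, nz = grid
    flat = np.arange(np.prod(grid)).reshape(grid)
    depth = min(2, nz)
    spans = {
        "faces": (slice(0, 3), slice(0, 3)),
        "objects": (slice(0, 3), slice(max(ny - 3, 3), ny)),
        "words": (slice(max(nx - 3, 3), nx), slice(0, 3)),
    }
    return {
        cat: flat[sx, sy, :depth].ravel() for cat, (sx, sy) in spans.items()
    }


def _voxel_labels(grid: tuple[int, int, int], hemisphere: str) -> pd.DataFrame:
    ii, jj, kk = np.unravel_index(np.arange(np.prod(grid)), grid)
    return pd.DataFrame(
        {
            "i": ii,
            "j": jj,
            "k": kk,
            "hemisphere": hemisphere,
            "ventral": True,
        }
    )


def _hemisphere_tuning(
    spec: CohortSpec,
    group: str,
    rng: np.random.Generator,
    paradigm: str,
) -> list[VoxelTuningParams]:
    """Voxel tuning for one hemisphere region of one participant."""
    grid = spec.grid_shape
    clusters = _planted_clusters(grid)
    n_vox = spec.n_voxels
    base_sel = 4.0  # non-specific visual response (0.4 % signal)
    tuning: list[VoxelTuningParams] = []
    if paradigm == "localizer":
        cats = ("faces", "objects", "words", "houses", "scrambled")
        sel_pref = {}
        for cat in ("faces", "objects", "words"):
            target = CS_TARGETS[cat] + spec.delta(group, "cs_amplitude", cat)
            target += rng.normal(0.0, 0.25)  # participant-level variation
            sel_pref[cat] = base_sel + 10.0 * max(target, 0.1)
        member = {}
        for cat, idx in clusters.items():
            for v in idx:
                member[v] = cat
        for v in range(n_vox):
            sel = {c: base_sel for c in cats}
            if v in member:
                sel[member[v]] = sel_pref[member[v]]
            tuning.append(
                VoxelTuningParams(
                    baseline=1000.0,
                    selectivity=sel,
                    fatigue=1.0,
                    noise_sd=spec.noise_sd,
                    ar1=spec.ar1,
                )
            )
    else:
        fat, sel_amp = {}, {}
        for cat in ADAPTATION_CATEGORIES:
            rs = RS_TARGET + spec.delta(group, "rs_magnitude", cat)
            rs += rng.normal(0.0, 0.03)
            mean_resp = RESPONSIVITY_TARGETS[cat] + spec.delta(group, "responsivity", cat)
            rs = float(np.clip(rs, 0.02, 2.5 * mean_resp))
            fat[cat], sel_amp[cat] = solve_adaptation_tuning(mean_resp, rs)
        member = {}
        for cat, idx in clusters.items():
            for v in idx:
                member[v] = cat
        for v in range(n_vox):
            if v in member:
                cat = member[v]
                sel = {c: 0.15 * sel_amp[cat] for c in ADAPTATION_CATEGORIES}
                sel[cat] = sel_amp[cat]
                f = fat[cat]
            else:
                sel = {c: 0.3 * base_sel for c in ADAPTATION_CATEGORIES}
                f = 0.95
            tuning.append(
                VoxelTuningParams(
                    baseline=1000.0,
                    selectivity=sel,
                    fatigue=f,
                    noise_sd=spec.noise_sd,
                    ar1=spec.ar1,
                )
            )
    return tuning


def simulate_hemisphere_data(
    spec: CohortSpec,
    participant_id: str,
    group: str,
    hemisphere: str,
    localizer_timing: LocalizerTiming | None = None,
    adaptation_timing: AdaptationTiming | None = None,
) -> dict[str, list[TimeSeriesDataset]]:
    """All runs (both paradigms) for one hemisphere of one participant."""
    labels = _voxel_labels(spec.grid_shape, hemisphere)
    out: dict[str, list[TimeSeriesDataset]] = {"localizer": [], "adaptation": []}
    rng_loc = derive_rng(spec.seed, "tuning", participant_id, hemisphere, "localizer")
    rng_ada = derive_rng(spec.seed, "tuning", participant_id, hemisphere, "adaptation")
    tuning_loc = _hemisphere_tuning(spec, group, rng_loc, "localizer")
    tuning_ada = _hemisphere_tuning(spec, group, rng_ada, "adaptation")
    for r in range(spec.n_localizer_runs):
        design = build_localizer_design(localizer_timing, run_index=r)
        out["localizer"].append(
            simulate_timeseries(
                design,
                tuning_loc,
                seed=int(
                    derive_rng(
                        spec.seed, "ts", participant_id, hemisphere, "loc", str(r)
                    ).integers(2**31)
                ),
                voxel_labels=labels,
                grid_shape=spec.grid_shape,
            )
        )
    for r in range(spec.n_adaptation_runs):
        design = build_adaptation_design(
            adaptation_timing, run_index=r, seed=spec.seed + 1000
        )
        out["adaptation"].append(
            simulate_timeseries(
                design,
                tuning_ada,
                seed=int(
                    derive_rng(
                        spec.seed, "ts", participant_id, hemisphere, "ada", str(r)
                    ).integers(2**31)
                ),
                voxel_labels=labels,
                grid_shape=spec.grid_shape,
            )
        )
    return out


def simulate_cohort(
    spec: CohortSpec,
) -> tuple[pd.DataFrame, dict[tuple[str, str], dict[str, list[TimeSeriesDataset]]]]:
    """Full time-series cohort: participant records + per-hemisphere datasets.

    TD participants contribute two hemisphere datasets, patients one.  Memory
    scales with cohort size; for large pipelines prefer iterating
    :func:`simulate_hemisphere_data` participant by participant.
    """
    records = participant_records(spec)
    datasets: dict[tuple[str, str], dict[str, list[TimeSeriesDataset]]] = {}
    for rec in records.to_dict("records"):
        for hemi in hemispheres_of(rec):
            datasets[(rec["participant_id"], hemi)] = simulate_hemisphere_data(
                spec, rec["participant_id"], rec["group"], hemi
            )
    return records, datasets


# --------------------------------------------------------------------------
# measure-level generation

#: between-participant / within-participant residual SDs per measure
MEASURE_SDS = {
    "cs_amplitude": (0.40, 0.45),
    "responsivity": (0.15, 0.20),
    "rs_magnitude": (0.12, 0.08),
    "model_fit": (0.11, 0.08),
}


def simulate_measures(
    spec: CohortSpec,
    seed: int | None = None,
    accuracy_probs: Mapping[str, Mapping[str, float]] | None = None,
    age_slopes: Mapping[str, float] | None = None,
    records: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Draw a long-format dependent-measure table with the cohort's effect
    structure, without simulating BOLD data.

    Values are ``target + group delta + age slope * centred age + participant
    intercept + residual``; accuracy rows are binomial draws.  With all
    effect deltas zero (and shared accuracy probabilities) the groups are
    exchangeable, so permutation nulls calibrate exactly.
    """
    seed = spec.seed if seed is None else seed
    rng = derive_rng(seed, "measures")
    if records is None:
        records = participant_records(
            spec if seed == spec.seed else _respec_seed(spec, seed)
        )
    probs = accuracy_probs or {
        g: dict(DEFAULT_ACCURACY[g]) for g in GROUPS
    }
    slopes = dict(age_slopes or {})
    mean_age = float(records["age"].mean())
    rows: list[dict] = []
    rs_half = {
        "same": -RS_TARGET / 2.0,
        "alternating": 0.0,
        "different": RS_TARGET / 2.0,
    }
    for rec in records.to_dict("records"):
        pid, group, age = rec["participant_id"], rec["group"], rec["age"]
        cage = age - mean_age
        u = {m: rng.normal(0.0, MEASURE_SDS[m][0]) for m in MEASURE_SDS}
        for hemi in hemispheres_of(rec):
            for cat in ADAPTATION_CATEGORIES:
                val = (
                    CS_TARGETS[cat]
                    + spec.delta(group, "cs_amplitude", cat)
                    + slopes.get("cs_amplitude", 0.0) * cage
                    + u["cs_amplitude"]
                    + rng.normal(0.0, MEASURE_SDS["cs_amplitude"][1])
                )
                rows.append(
                    _row(pid, group, hemi, age, "cs_amplitude", val, category=cat)
                )
                for cond in ADAPTATION_CONDITIONS:
                    val = (
                        RESPONSIVITY_TARGETS[cat]
                        + rs_half[cond]
                        + spec.delta(group, "responsivity", cat)
                        + slopes.get("responsivity", 0.0) * cage
                        + u["responsivity"]
                        + rng.normal(0.0, MEASURE_SDS["responsivity"][1])
                    )
                    rows.append(
                        _row(
                            pid, group, hemi, age, "responsivity", val,
                            category=cat, condition=cond,
                        )
                    )
                val = (
                    RS_TARGET
                    + spec.delta(group, "rs_magnitude", cat)
                    + slopes.get("rs_magnitude", 0.0) * cage
                    + u["rs_magnitude"]
                    + rng.normal(0.0, MEASURE_SDS["rs_magnitude"][1])
                )
                rows.append(
                    _row(pid, group, hemi, age, "rs_magnitude", val, category=cat)
                )
            for kind, target in MODEL_FIT_TARGETS.items():
                val = (
                    target
                    + spec.delta(group, "model_fit")
                    + slopes.get("model_fit", 0.0) * cage
                    + u["model_fit"]
                    + rng.normal(0.0, MEASURE_SDS["model_fit"][1])
                )
                rows.append(
                    _row(pid, group, hemi, age, "model_fit", val, model_kind=kind)
                )
        for task in ADAPTATION_CATEGORIES:
            p = float(
                np.clip(
                    probs[group][task] + spec.delta(group, "accuracy", task), 0.0, 1.0
                )
            )
            n = DEFAULT_TRIALS[task]
            k = int(rng.binomial(n, p))
            row = _row(
                pid,
                group,
                rec["preserved_hemisphere"] if group != "TD" else pd.NA,
                age,
                "accuracy",
                k / n,
                category=task,
            )
            row["n_trials"], row["n_correct"] = n, k
            rows.append(row)
    return pd.DataFrame(rows)


def _respec_seed(spec: CohortSpec, seed: int) -> CohortSpec:
    from dataclasses import replace

    return replace(spec, seed=seed)


def _row(
    pid: str,
    group: str,
    hemisphere,
    age: float,
    measure: str,
    value: float,
    category=pd.NA,
    condition=pd.NA,
    model_kind=pd.NA,
) -> dict:
    return {
        "participant_id": pid,
        "group": group,
        "hemisphere": hemisphere,
        "age": age,
        "measure": measure,
        "category": category,
        "condition": condition,
        "model_kind": model_kind,
        "value": value,
        "n_trials": pd.NA,
        "n_correct": pd.NA,
    }


# --------------------------------------------------------------------------
# RSA pattern generation

#: within-category condition-pair correlations of the generative CS-RS
#: structure, mirroring the theoretical similarity values (scaled by 1/2 to
#: keep the matrix positive definite): one-step condition pairs (same-alt,
#: alt-diff) correlate at 0.5, while same-vs-different pairs — like all
#: across-category pairs — carry no shared signal.
RSA_STRUCTURE = {"one_step": 0.50, "two_step": 0.0, "across": 0.0}


def rsa_target_covariance(structure: Mapping[str, float] | None = None) -> np.ndarray:
    """Target 9x9 correlation matrix of block-type voxel patterns."""
    s = dict(RSA_STRUCTURE, **(structure or {}))
    n = len(ADAPTATION_BLOCK_TYPES)
    cov = np.full((n, n), s["across"])
    for a in range(n):
        cov[a, a] = 1.0
        for b in range(a + 1, n):
            cat_a, cond_a = ADAPTATION_BLOCK_TYPES[a].rsplit("_", 1)
            cat_b, cond_b = ADAPTATION_BLOCK_TYPES[b].rsplit("_", 1)
            if cat_a == cat_b:
                da = abs(
                    ADAPTATION_CONDITIONS.index(cond_a)
                    - ADAPTATION_CONDITIONS.index(cond_b)
                )
                cov[a, b] = cov[b, a] = s["one_step"] if da == 1 else s["two_step"]
    # guard: the pinned structure is comfortably positive definite
    w = np.linalg.eigvalsh(cov)
    if w.min() <= 1e-8:
        raise ValueError("RSA structure parameters yield a non-PSD covariance")
    return cov


def simulate_activation_patterns(
    n_voxels: int,
    rng: np.random.Generator,
    structure: Mapping[str, float] | None = None,
    noise_sd: float = 0.6,
) -> np.ndarray:
    """Voxel x 9 block-type β patterns with the CS-RS covariance structure.

    Patterns are drawn from N(mean, Σ) across voxels, where Σ encodes the
    combined category-selectivity + repetition-suppression similarity and the
    means are the condition responsivity targets; independent measurement
    noise with SD ``noise_sd`` is added per entry.
    """
    cov = rsa_target_covariance(structure)
    chol = np.linalg.cholesky(cov)
    z = rng.standard_normal((n_voxels, len(ADAPTATION_BLOCK_TYPES)))
    x = z @ chol.T
    means = np.array(
        [
            RESPONSIVITY_TARGETS[bt.rsplit("_", 1)[0]]
            + {"same": -RS_TARGET / 2, "alternating": 0.0, "different": RS_TARGET / 2}[
                bt.rsplit("_", 1)[1]
            ]
            for bt in ADAPTATION_BLOCK_TYPES
        ]
    )
    x = x + means
    if noise_sd > 0:
        x = x + rng.normal(0.0, noise_sd, size=x.shape)
    return x
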