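"""End-to-end analysis pipeline over a synthetic cohort.

``run_pipeline`` simulates a cohort of BOLD datasets, fits run-level GLMs,
defines cluster-corrected category-selective ROIs from held-in localizer
runs, derives the dependent measures (CS amplitude on held-out runs,
adaptation responsivity, RS magnitude, RSA model fits, task accuracy),
and runs the group statistics: mixed-model selection and Wald tests,
permutation tests of group effects, single-case comparisons of each OTC
patient against the TD controls, demographic matching and group-RDM
comparison.  Everything is seeded through the configuration, and
``write_results`` emits TSV/JSON artifacts plus a provenance block with the
configuration hash.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _version
from ._seeds import derive_rng, derive_seed
from .adaptation import MeasureRecord, records_to_frame, responsivity, rs_magnitude
from .casecontrol import batch_case_control
from .glm import BetaMap, build_design_matrix, fit_glm, scale_and_censor
from .groupstats import (
    ModelSpec,
    bic_bayes_factor,
    demographic_matching,
    emmeans_contrasts,
    fit_lmem,
    permute_group_effect,
    select_model,
    wald_terms,
)
from .io import write_json, write_table
from .roi import ClusterNull, cs_amplitude, define_cs_roi, estimate_cluster_threshold
from .rsa import (
    RDM,
    activation_rdm,
    fit_rdm_model,
    group_rdm_permutation,
    model_rdm,
)
from .simcortex.behavior import CHANCE_LEVELS, simulate_behavior
from .simcortex.cohort import (
    ADAPTATION_CATEGORIES,
    CohortSpec,
    hemispheres_of,
    participant_records,
    simulate_hemisphere_data,
)

__all__ = [
    "PipelineConfig",
    "ResultBundle",
    "average_beta_maps",
    "score_behavior",
    "run_pipeline",
    "write_results",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Cohort generation plus analysis parameters of one pipeline run."""

    cohort: CohortSpec = field(default_factory=CohortSpec)
    voxel_p: float = 0.001
    cluster_alpha: float = 0.05
    cluster_iter: int = 10_000
    smoothing_fwhm: float = 2.0
    roi_definition_runs: tuple[int, ...] = (0,)
    n_permutations: int = 1000
    rdm_permutations: int = 200
    run_rdm_comparison: bool = True

    def __post_init__(self) -> None:
        bad = set(self.roi_definition_runs) - set(range(self.cohort.n_localizer_runs))
        if bad:
            raise ValueError(f"roi_definition_runs outside the localizer runs: {sorted(bad)}")
        if len(self.roi_definition_runs) >= self.cohort.n_localizer_runs:
            raise ValueError("at least one localizer run must be held out for amplitude")

    # ---- YAML round-trip -------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["cohort"]["effect_deltas"] = {
            g: {m: v for m, v in ms.items()}
            for g, ms in self.cohort.effect_deltas.items()
        }
        return d

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(yaml.safe_dump(_plain(self.to_dict()), sort_keys=True))
        return path

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        d = dict(d)
        cd = dict(d.pop("cohort", {}))
        for key in ("age_range", "grid_shape"):
            if key in cd:
                cd[key] = tuple(cd[key])
        cohort = CohortSpec(**cd)
        if "roi_definition_runs" in d:
            d["roi_definition_runs"] = tuple(d["roi_definition_runs"])
        return cls(cohort=cohort, **d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        blob = json.dumps(_plain(self.to_dict()), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _plain(obj):
    if isinstance(obj, Mapping):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


@dataclass
class ResultBundle:
    """Everything a pipeline run produces, ready for serialisation."""

    config: PipelineConfig
    records: pd.DataFrame
    measures: pd.DataFrame
    behavior: pd.DataFrame
    roi_table: pd.DataFrame
    selection_trail: pd.DataFrame
    wald_table: pd.DataFrame
    emm_cells: pd.DataFrame
    emm_contrasts: pd.DataFrame
    bf01_group: float
    permutation: dict
    case_control: pd.DataFrame
    matching: dict
    rdm_comparison: dict
    group_summary: pd.DataFrame
    provenance: dict


def average_beta_maps(maps: Sequence[BetaMap]) -> BetaMap:
    """Condition-wise mean of per-run BetaMaps (shared voxel geometry)."""
    if not maps:
        raise ValueError("need at least one BetaMap")
    first = maps[0]
    for m in maps[1:]:
        if m.conditions != first.conditions:
            raise ValueError("BetaMaps disagree on conditions")
        if m.betas.shape != first.betas.shape:
            raise ValueError("BetaMaps disagree on voxel count")
    betas = np.mean([m.betas for m in maps], axis=0)
    runs = tuple(sorted({r for m in maps for r in m.runs}))
    return BetaMap(
        betas=betas,
        conditions=first.conditions,
        resid_var=np.mean([np.atleast_1d(m.resid_var) for m in maps], axis=0)
        / len(maps),
        df=int(sum(m.df for m in maps)),
        cov_task=first.cov_task,
        voxel_coords=first.voxel_coords,
        grid_shape=first.grid_shape,
        voxel_info=first.voxel_info,
        runs=runs,
    )


def score_behavior(behavior: pd.DataFrame) -> pd.DataFrame:
    """Flag task performances at or below chance for exclusion."""
    out = behavior.copy()
    out["chance"] = out["task"].map(CHANCE_LEVELS)
    out["excluded"] = out["accuracy"] <= out["chance"]
    return out


def _fit_run(dataset, ar1: float | None) -> BetaMap:
    scaled, mask = scale_and_censor(dataset)
    X = build_design_matrix(dataset.design, motion=dataset.motion)
    return fit_glm(scaled, X, mask=mask, ar1=ar1)


def _hemisphere_measures(
    config: PipelineConfig,
    rec: Mapping,
    hemi: str,
    null: ClusterNull,
) -> tuple[list[MeasureRecord], list[dict], RDM]:
    spec = config.cohort
    pid, group, age = rec["participant_id"], rec["group"], float(rec["age"])
    data = simulate_hemisphere_data(spec, pid, group, hemi)
    ar1 = spec.ar1 if spec.ar1 > 0 else None
    mask = np.ones(spec.grid_shape, dtype=bool)

    loc_maps = [_fit_run(d, ar1) for d in data["localizer"]]
    def_map = average_beta_maps([loc_maps[r] for r in config.roi_definition_runs])
    held_out = [
        loc_maps[r]
        for r in range(spec.n_localizer_runs)
        if r not in config.roi_definition_runs
    ]
    ada_maps = [_fit_run(d, ar1) for d in data["adaptation"]]
    ada_mean = average_beta_maps(ada_maps)

    records: list[MeasureRecord] = []
    roi_rows: list[dict] = []
    for cat in ADAPTATION_CATEGORIES:
        roi = define_cs_roi(def_map, cat, null, mask, hemisphere=hemi)
        roi_rows.append(
            {
                "participant_id": pid,
                "hemisphere": hemi,
                "category": cat,
                "n_voxels": roi.n_voxels,
                "n_clusters": len(roi.cluster_sizes),
                "k_min": roi.k_min,
            }
        )
        amps = [cs_amplitude(m, roi) for m in held_out]
        records.append(
            MeasureRecord(
                participant_id=pid,
                group=group,
                hemisphere=hemi,
                measure="cs_amplitude",
                value=float(np.nanmean(amps)) if amps else float("nan"),
                age=age,
                category=cat,
            )
        )
        for cond in ("same", "alternating", "different"):
            records.append(
                responsivity(
                    ada_mean, roi, cat, cond,
                    participant_id=pid, group=group, hemisphere=hemi, age=age,
                )
            )
        records.append(
            rs_magnitude(
                ada_mean, roi, cat,
                participant_id=pid, group=group, hemisphere=hemi, age=age,
            )
        )
    rdm = activation_rdm(ada_mean)
    for kind in ("CS", "RS", "CS_RS"):
        fit = fit_rdm_model(rdm, model_rdm(kind), participant_id=pid, hemisphere=hemi)
        records.append(
            MeasureRecord(
                participant_id=pid,
                group=group,
                hemisphere=hemi,
                measure="model_fit",
                value=fit.fisher_z,
                age=age,
                model_kind=kind,
            )
        )
    return records, roi_rows, rdm


def summarize_measures(measures: pd.DataFrame) -> pd.DataFrame:
    """Group x measure (x category) mean/SD table in the style of a cohort
    summary."""
    keys = ["group", "measure", "category"]
    g = measures.groupby(keys, dropna=False)["value"]
    out = g.agg(["mean", "std", "count"]).reset_index()
    return out.rename(columns={"count": "n"})


def run_pipeline(config: PipelineConfig) -> ResultBundle:
    """Execute the full simulate-analyse pipeline for one configuration."""
    spec = config.cohort
    records = participant_records(spec)

    mask = np.ones(spec.grid_shape, dtype=bool)
    null = estimate_cluster_threshold(
        mask,
        fwhm=config.smoothing_fwhm,
        voxel_p=config.voxel_p,
        alpha=config.cluster_alpha,
        n_iter=config.cluster_iter,
        seed=derive_seed(spec.seed, "cluster_null"),
    )

    measure_records: list[MeasureRecord] = []
    roi_rows: list[dict] = []
    rdms: list[RDM] = []
    rdm_groups: list[str] = []
    for rec in records.to_dict("records"):
        for hemi in hemispheres_of(rec):
            recs, rois, rdm = _hemisphere_measures(config, rec, hemi, null)
            measure_records.extend(recs)
            roi_rows.extend(rois)
            rdms.append(rdm)
            rdm_groups.append(rec["group"])
    measures = records_to_frame(measure_records)

    behavior = score_behavior(
        simulate_behavior(spec, records=records, seed=derive_seed(spec.seed, "behavior"))
    )

    # ---- group statistics on RS magnitude -------------------------------
    rs_spec = ModelSpec(response="rs_magnitude", factors=("group", "category"))
    selection = select_model(rs_spec, measures)
    wald = pd.DataFrame(
        [
            {"term": ":".join(w.term), "chi_sq": w.chi_sq, "df": w.df, "p": w.p}
            for w in wald_terms(selection.fit)
        ]
    )
    sel_terms = selection.fit.spec.expanded_terms()
    bf_spec = (
        selection.fit.spec
        if any("group" in t for t in sel_terms)
        else rs_spec.with_terms(rs_spec.expanded_terms())
    )
    without = bf_spec.with_terms(
        [t for t in bf_spec.expanded_terms() if "group" not in t]
    )
    bf01 = bic_bayes_factor(
        fit_lmem(bf_spec, measures, method="ml"),
        fit_lmem(without, measures, method="ml"),
    ).bf01
    emm_fit = (
        selection.fit
        if any("group" in t for t in sel_terms)
        else fit_lmem(bf_spec, measures)
    )
    emm_cells, emm_contrasts = emmeans_contrasts(emm_fit, ["group"])

    perm = permute_group_effect(
        rs_spec,
        measures,
        n_iter=config.n_permutations,
        seed=derive_seed(spec.seed, "perm"),
    )

    # ---- single-case comparisons vs TD controls -------------------------
    cc_measures = measures[measures["measure"].isin(["cs_amplitude", "rs_magnitude"])]
    cases = cc_measures[cc_measures["group"] == "OTC_patient"]
    controls = cc_measures[cc_measures["group"] == "TD"]
    case_control = batch_case_control(
        cases, controls, measure_cols=("measure", "category")
    )

    matching = demographic_matching(
        records,
        n_iter=min(config.n_permutations, 500),
        seed=derive_seed(spec.seed, "matching"),
    )

    if config.run_rdm_comparison:
        rdm_cmp = group_rdm_permutation(
            rdms, rdm_groups, n_iter=config.rdm_permutations,
            seed=derive_seed(spec.seed, "rdm_perm"),
        )
        rdm_dict = {
            "observed_tau": {" vs ".join(k): v for k, v in rdm_cmp.observed_tau.items()},
            "within_envelope": {
                " vs ".join(k): bool(v) for k, v in rdm_cmp.within_envelope.items()
            },
            "n_iter": rdm_cmp.n_iter,
        }
    else:
        rdm_dict = {}

    provenance = {
        "config_hash": config.config_hash(),
        "seed": spec.seed,
        "version": _version,
        "cluster_k_min": null.k_min,
    }
    return ResultBundle(
        config=config,
        records=records,
        measures=measures,
        behavior=behavior,
        roi_table=pd.DataFrame(roi_rows),
        selection_trail=selection.trail_table(),
        wald_table=wald,
        emm_cells=emm_cells,
        emm_contrasts=emm_contrasts,
        bf01_group=float(bf01),
        permutation={
            "statistic": perm.statistic,
            "df": perm.df,
            "p": perm.p,
            "p_smoothed": perm.p_smoothed,
            "n_iter": perm.n_iter,
        },
        case_control=case_control,
        matching={
            "covariate": matching.covariate,
            "statistic": matching.statistic,
            "p": matching.p,
            "n_iter": matching.n_iter,
        },
        rdm_comparison=rdm_dict,
        group_summary=summarize_measures(measures),
        provenance=provenance,
    )


def write_results(bundle: ResultBundle, out_dir: str | Path) -> Path:
    """Write all tables (TSV) and the scalar summary (JSON) to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_table(bundle.records, out / "participants.tsv")
    write_table(bundle.measures, out / "measures.tsv")
    write_table(bundle.behavior, out / "behavior.tsv")
    write_table(bundle.roi_table, out / "rois.tsv")
    write_table(bundle.selection_trail, out / "model_selection.tsv")
    write_table(bundle.wald_table, out / "wald_tests.tsv")
    write_table(bundle.emm_cells, out / "emm_cells.tsv")
    write_table(bundle.emm_contrasts, out / "emm_contrasts.tsv")
    write_table(bundle.case_control, out / "case_control.tsv")
    write_table(bundle.group_summary, out / "group_summary.tsv")
    bundle.config.to_yaml(out / "config.yaml")
    write_json(
        {
            "provenance": bundle.provenance,
            "bf01_group": bundle.bf01_group,
            "permutation": bundle.permutation,
            "matching": bundle.matching,
            "rdm_comparison": bundle.rdm_comparison,
        },
        out / "summary.json",
    )
    return out
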