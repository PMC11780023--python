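"""End-to-end experiment orchestration under one seeded configuration.

Stages: cohort (simulate or ingest) -> preprocessing -> radiomics tables
(+ two-reader ICC filter) -> Max-ROI slice stacks -> deep embeddings ->
per-modality z-score + LASSO selection -> fusion with Spearman pruning ->
classifier bank -> evaluation on the internal (and, when present,
external) test split -> summary CSV.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .deep import BackendSpec, embed_cohort
from .evaluation import (
    EvalReport,
    ModelSpec,
    SplitAssignment,
    evaluate,
    stratified_split,
)
from .io_preproc import preprocess_volume, read_nifti_mask, read_nifti_volume
from .model import LesionClassifier
from .radiomics import RadiomicsConfig, extract_table
from .selection import fuse_and_prune, icc_filter, lasso_select, zscore
from .slices import extract_stack
from .synthetic import CaseRecord, PhantomSpec, generate_cohort

logger = logging.getLogger("dlradiomics")

__all__ = ["ExperimentConfig", "run_experiment", "ingest_manifest", "recovery_experiment"]

PHASES = ("AP", "PP")


@dataclasses.dataclass
class ExperimentConfig:
    """Everything a full run needs; every random stage carries its seed."""

    phantom: PhantomSpec | None = None
    manifest_path: str | None = None
    radiomics: RadiomicsConfig = dataclasses.field(default_factory=RadiomicsConfig)
    backends: tuple[str, ...] = ("pseudo",)
    backend_weights: str = "random"
    backend_seed: int = 0
    pseudo_embed_dim: int = 64
    classifiers: tuple[str, ...] = ("svm",)
    phases: tuple[str, ...] = ("AP", "PP", "combined")
    icc_enabled: bool = True
    icc_n_cases: int = 30
    icc_threshold: float = 0.8
    icc_seed: int = 0
    split_test_frac: float = 0.2
    split_seed: int = 0
    lasso_folds: int = 5
    lasso_seed: int = 0
    lasso_n_lambdas: int = 25
    rho_max: float = 0.9
    n_bootstrap: int = 500
    eval_seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if (self.phantom is None) == (self.manifest_path is None):
            raise ValueError("configure exactly one of phantom | manifest_path")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "phantom" in raw and raw["phantom"] is not None:
            raw["phantom"] = PhantomSpec(**raw["phantom"])
        if "radiomics" in raw and raw["radiomics"] is not None:
            raw["radiomics"] = RadiomicsConfig(**raw["radiomics"])
        for key in ("backends", "classifiers", "phases"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.radiomics is not None:
            d["radiomics"] = self.radiomics.to_dict()
        return d


def ingest_manifest(path: str | Path) -> list[CaseRecord]:
    """Load and validate a cohort manifest CSV into case records."""
    path = Path(path)
    df = pd.read_csv(path)
    required = {"case_id", "cohort_tag", "label", "ap_path", "pp_path", "mask_path"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest lacks columns: {sorted(missing)}")
    errors = []
    records = []
    for i, row in df.iterrows():
        try:
            if int(row["label"]) not in (0, 1, 2):
                raise ValueError(f"label {row['label']} not in {{0,1,2}}")
            vols = {}
            for key in ("ap_path", "pp_path"):
                p = Path(row[key])
                if not p.is_absolute():
                    p = path.parent / p
                if not p.exists():
                    raise FileNotFoundError(str(p))
                vols[key] = read_nifti_volume(p)
            mp = Path(row["mask_path"])
            if not mp.is_absolute():
                mp = path.parent / mp
            if not mp.exists():
                raise FileNotFoundError(str(mp))
            mask = read_nifti_mask(mp)
            for key, v in vols.items():
                if v.shape != mask.shape:
                    raise ValueError(f"{key} grid {v.shape} != mask grid {mask.shape}")
            extras = {}
            for key, attr in (
                ("reader2_mask_path", "reader2_mask"),
                ("reader1_repeat_mask_path", "reader1_repeat_mask"),
            ):
                if key in df.columns and isinstance(row.get(key), str):
                    extras[attr] = read_nifti_mask(row[key])
            records.append(
                CaseRecord(
                    case_id=str(row["case_id"]),
                    cohort_tag=str(row["cohort_tag"]),
                    label=int(row["label"]),
                    ap_volume=vols["ap_path"],
                    pp_volume=vols["pp_path"],
                    mask=mask,
                    **extras,
                )
            )
        except Exception as err:  # collect all row problems, report together
            errors.append(f"row {i} ({row.get('case_id', '?')}): {err}")
    if errors:
        raise ValueError("manifest validation failed:\n" + "\n".join(errors))
    return records


# ---------------------------------------------------------------------------


def _phase_columns(table: pd.DataFrame, phase: str) -> pd.DataFrame:
    if phase == "combined":
        return table
    return table.loc[:, [c for c in table.columns if c.startswith(f"{phase}_")]]


_CURRENT_STAGE = "init"


def _stage(name):
    global _CURRENT_STAGE
    _CURRENT_STAGE = name
    logger.info("stage: %s", name)
    return time.time()


class ExperimentResult:
    """Bundle of per-model reports, the summary table, and stage artifacts."""

    def __init__(self):
        self.reports: dict[str, dict[str, EvalReport]] = {}
        self.summary: pd.DataFrame | None = None
        self.selections: dict[str, list[str]] = {}
        self.split: SplitAssignment | None = None
        self.icc_retained: list[str] | None = None


def run_experiment(config: ExperimentConfig) -> ExperimentResult:
    """Run the full pipeline; see the module docstring for the stage list.

    A failure in any stage aborts with an error naming that stage;
    outputs written by earlier stages are retained.
    """
    try:
        return _run_experiment(config)
    except Exception as err:
        raise RuntimeError(f"pipeline stage {_CURRENT_STAGE!r} failed: {err}") from err


def _run_experiment(config: ExperimentConfig) -> ExperimentResult:
    result = ExperimentResult()
    out = Path(config.out_dir) if config.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
        (out / "config.yaml").write_text(yaml.safe_dump(config.to_dict()))

    t = _stage("cohort")
    if config.phantom is not None:
        records = generate_cohort(config.phantom)
    else:
        records = ingest_manifest(config.manifest_path)
    labels = pd.Series({r.case_id: r.label for r in records})
    tags = {r.case_id: r.cohort_tag for r in records}
    logger.info("cohort: %d cases (%.1fs)", len(records), time.time() - t)

    t = _stage("preprocess")
    pre: dict[str, dict] = {}
    for rec in records:
        ap, mask = preprocess_volume(rec.ap_volume, rec.mask)
        pp, _ = preprocess_volume(rec.pp_volume, rec.mask)
        pre[rec.case_id] = {"AP": ap, "PP": pp, "mask": mask}
    logger.info("preprocess done (%.1fs)", time.time() - t)

    t = _stage("radiomics")
    rad_table = extract_table(records, config.radiomics)
    logger.info("radiomics table %s (%.1fs)", rad_table.shape, time.time() - t)

    if config.icc_enabled:
        t = _stage("icc filter")
        rng = np.random.default_rng(config.icc_seed)
        pool = [r for r in records if r.cohort_tag != "external"
                and r.reader2_mask is not None and r.reader1_repeat_mask is not None]
        k = min(config.icc_n_cases, len(pool))
        chosen = [pool[i] for i in rng.permutation(len(pool))[:k]]
        if k >= 10:
            r1 = rad_table.loc[[r.case_id for r in chosen]]
            r2 = extract_table(chosen, config.radiomics, mask_attr="reader2_mask")
            rr = extract_table(chosen, config.radiomics, mask_attr="reader1_repeat_mask")
            icc = icc_filter(r1, r2.loc[r1.index], rr.loc[r1.index], config.icc_threshold)
            result.icc_retained = icc.retained_names
            if out:
                pd.DataFrame(
                    {
                        "inter_reader_icc": icc.inter_reader_icc,
                        "intra_reader_icc": icc.intra_reader_icc,
                        "retained": icc.retained,
                    }
                ).to_csv(out / "icc_filter.csv", index_label="feature")
            if icc.retained_names:
                rad_table = rad_table.loc[:, icc.retained_names]
            logger.info(
                "icc retained %d/%d features (%.1fs)",
                len(icc.retained_names), len(icc.retained.index), time.time() - t,
            )
        else:
            logger.warning("too few reader-annotated cases for ICC; filter skipped")

    t = _stage("slices + embeddings")
    stacks = []
    for rec in records:
        for phase in PHASES:
            stacks.append(
                extract_stack(
                    pre[rec.case_id][phase], pre[rec.case_id]["mask"], rec.case_id, phase
                )
            )
    deep_tables = {}
    for name in config.backends:
        backend = BackendSpec(
            name=name,
            weights=config.backend_weights,
            embed_dim=config.pseudo_embed_dim if name == "pseudo" else None,
            seed=config.backend_seed,
        )
        deep_tables[name] = embed_cohort(stacks, backend)
    logger.info("embeddings done (%.1fs)", time.time() - t)

    t = _stage("split")
    ids = [r.case_id for r in records]
    split = stratified_split(
        ids,
        labels[ids].to_numpy(),
        [tags[i] for i in ids],
        test_frac=config.split_test_frac,
        seed=config.split_seed,
    )
    result.split = split
    train_ids = split.ids("train")
    internal_ids = split.ids("internal_test")
    external_ids = split.ids("external_test")

    # ----- selection per modality/phase --------------------------------
    t = _stage("selection")
    selections: dict[tuple[str, str, str | None], tuple[pd.DataFrame, pd.DataFrame, list[str]]] = {}

    def select_block(table: pd.DataFrame, phase: str) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
        block = _phase_columns(table, phase)
        train_z, rest_z = zscore(block.loc[train_ids], block.drop(index=train_ids))
        sel = lasso_select(
            train_z,
            labels[train_ids].to_numpy(),
            n_folds=config.lasso_folds,
            seed=config.lasso_seed,
            n_lambdas=config.lasso_n_lambdas,
        )
        names = sel.selected_names
        return train_z, rest_z, names

    for phase in config.phases:
        selections[("radiomics", phase, None)] = select_block(rad_table, phase)
        for name in config.backends:
            selections[("dtl", phase, name)] = select_block(deep_tables[name], phase)
    logger.info("selection done (%.1fs)", time.time() - t)

    # ----- model bank ---------------------------------------------------
    t = _stage("train/evaluate")
    all_internal: list[EvalReport] = []
    for (modality, phase, backend), (train_z, rest_z, names) in list(selections.items()):
        _fit_slot(
            result, config, modality, phase, backend,
            train_z, rest_z, names, labels, internal_ids, external_ids, all_internal,
        )

    for phase in config.phases:
        rad_train, rad_rest, rad_names = selections[("radiomics", phase, None)]
        for name in config.backends:
            dtl_train, dtl_rest, dtl_names = selections[("dtl", phase, name)]
            fused_train = pd.concat([rad_train, dtl_train], axis=1)
            fused_rest = pd.concat([rad_rest, dtl_rest], axis=1)
            fusion = fuse_and_prune(rad_names, dtl_names, fused_train, config.rho_max)
            result.selections[f"fusion-{name}-{phase}"] = fusion.members
            _fit_slot(
                result, config, "fusion", phase, name,
                fused_train, fused_rest, fusion.members,
                labels, internal_ids, external_ids, all_internal,
            )
    logger.info("train/evaluate done (%.1fs)", time.time() - t)

    result.summary = _summarize(result)
    if out:
        result.summary.to_csv(out / "summary.csv", index=False)
        reports_json = {
            m: {s: r.to_dict() for s, r in splits.items()}
            for m, splits in result.reports.items()
        }
        (out / "reports.json").write_text(json.dumps(reports_json, indent=2))
        (out / "selections.json").write_text(json.dumps(result.selections, indent=2))
    return result


def recovery_experiment(
    n_cases: int = 300,
    seed: int = 0,
    null: bool = False,
    classifier: str = "svm",
) -> tuple["ExperimentResult", float]:
    """Combined-phase radiomics recovery run on a phantom cohort.

    Under the strong-effect phantom the combined radiomics model should
    separate the classes well on the internal test split; under the null
    phantom it should sit at chance.  Returns the experiment result and
    the internal-test macro-AUC of the combined radiomics model.
    """
    phantom = (
        PhantomSpec.null(n_cases=n_cases, seed=seed)
        if null
        else PhantomSpec.strong_effect(n_cases=n_cases, seed=seed)
    )
    config = ExperimentConfig(
        phantom=phantom,
        backends=(),
        phases=("combined",),
        classifiers=(classifier,),
        split_seed=seed,
        lasso_seed=seed,
        icc_seed=seed,
        eval_seed=seed,
        n_bootstrap=200,
    )
    result = run_experiment(config)
    report = result.reports[f"radiomics-combined-{classifier}"]["internal_test"]
    return result, float(report.macro_auc)


def _fit_slot(
    result, config, modality, phase, backend,
    train_z, rest_z, names, labels, internal_ids, external_ids, all_internal,
):
    key_base = {"modality": modality, "phase": phase, "backend": backend}
    sel_key = "-".join(filter(None, [modality, backend, phase]))
    result.selections.setdefault(sel_key, names)
    for clf in config.classifiers:
        spec = ModelSpec(classifier=clf, seed=config.eval_seed, **key_base)
        if names:
            train_X = train_z.loc[:, names]
            rest_X = rest_z.loc[:, names]
        else:
            # empty selection: intercept-only via a constant feature
            train_X = pd.DataFrame(0.0, index=train_z.index, columns=["_const"])
            rest_X = pd.DataFrame(0.0, index=rest_z.index, columns=["_const"])
        fitted = LesionClassifier(train_X, labels[train_X.index].to_numpy(), spec).fit()
        reports = {}
        for split_name, ids in (
            ("internal_test", internal_ids),
            ("external_test", external_ids),
        ):
            if not ids:
                continue
            rep = fitted.evaluate(
                rest_X.loc[ids],
                labels[ids].to_numpy(),
                split_name=split_name,
                n_bootstrap=config.n_bootstrap,
                seed=config.eval_seed,
            )
            reports[split_name] = rep
            if split_name == "internal_test":
                all_internal.append(rep)
        result.reports[spec.name] = reports


def _summarize(result: ExperimentResult) -> pd.DataFrame:
    rows = []
    for model_name, splits in sorted(result.reports.items()):
        for split_name, r in sorted(splits.items()):
            rows.append(
                {
                    "model": model_name,
                    "split": split_name,
                    "n": r.n,
                    "macro_auc": round(r.macro_auc, 6),
                    "ci_low": round(r.ci_95[0], 6),
                    "ci_high": round(r.ci_95[1], 6),
                    "micro_auc": round(r.micro_auc, 6),
                    "accuracy": round(r.accuracy, 6),
                    "precision": round(r.precision_macro, 6),
                    "recall": round(r.recall_macro, 6),
                    "f1": round(r.f1_macro, 6),
                }
            )
    return pd.DataFrame(rows)
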