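"""End-user workflows: model bundles, virtual screening, per-compound
analysis, and the full train-validate pipeline.

A :class:`ModelBundle` couples a tuned model with its featurization (a
fingerprint type, optionally a fitted descriptor selector) and, for
regression, a leverage applicability domain, so predictions can be made
straight from SMILES.  Bundles persist as directories holding an opaque
``model.bin`` plus JSON sidecars (``spec.json``, ``cv_stats.json``,
``fitted_state.json``), and reload to bit-identical predictions on the
same platform.

``vs_screen`` is the high-throughput path (binary model only, streamed
CSV); ``analyze`` is the deep path running all four production models
(binary activity, pIC50 regression, SIRT1/2 and SIRT2/3 selectivity) with
confidence flags, atom-contribution maps, and nearest-neighbor lookup.
``run_pipeline`` executes the whole protocol: curate, featurize, split,
rebalance, tune/train, validate internally and externally, benchmark on
decoys, fit the applicability domain, and write a machine-readable report.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import joblib
import numpy as np
import pandas as pd

from . import datasets as ds
from .applicability import (
    LeverageDomain,
    in_confidence_zone,
    similarity_map,
    tanimoto_nearest,
)
from .features import FeatureType, fingerprint_matrix
from .modeling import (
    QSARClassifier,
    QSARRegressor,
    y_scramble,
)
from .optimize import Categorical, Integer
from .synthetic import (
    SyntheticSARConfig,
    generate_candidate_pool,
    generate_synthetic_sar,
)
from .validation import (
    classification_report,
    evaluate_on_decoys,
    generate_decoys,
    regression_report,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ModelBundle",
    "PredictionRecord",
    "PipelineConfig",
    "vs_screen",
    "analyze",
    "run_pipeline",
]


@dataclass
class ModelBundle:
    """A deployable model: featurization + estimator (+ AD for regression)."""

    task: str  # "regression" | "binary" | "multiclass"
    feature_type: FeatureType
    model: object
    selector: object | None = None
    leverage: LeverageDomain | None = None
    positive_class: str | None = None
    metadata: dict = field(default_factory=dict)

    def featurize(self, smiles_list) -> np.ndarray:
        if self.feature_type is FeatureType.DESCRIPTORS_2D:
            from .features import descriptor_matrix

            X = descriptor_matrix(smiles_list)
            return self.selector.transform(X)
        return fingerprint_matrix(smiles_list, self.feature_type)

    def predict_from_smiles(self, smiles_list):
        X = self.featurize(smiles_list)
        if self.task == "regression":
            return self.model.predict(X)
        return self.model.predict_proba(X)

    def active_probability(self, proba_row: np.ndarray) -> float:
        classes = list(self.model.classes_)
        return float(proba_row[classes.index(self.positive_class)])

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        joblib.dump(self, directory / "model.bin")
        spec = {
            "schema_version": 1,
            "task": self.task,
            "feature_type": self.feature_type.value,
            "algorithm": getattr(self.model, "algorithm", None),
            "best_params": getattr(self.model, "best_params_", None),
            "positive_class": self.positive_class,
            "metadata": self.metadata,
        }
        (directory / "spec.json").write_text(json.dumps(spec, indent=2, default=str))
        stats = getattr(self.model, "cv_stats_", None)
        if stats is not None:
            (directory / "cv_stats.json").write_text(
                json.dumps(asdict(stats), indent=2, default=float)
            )
        state = {"feature_type": self.feature_type.value}
        if self.selector is not None:
            state.update(self.selector.fitted_state())
        (directory / "fitted_state.json").write_text(
            json.dumps(state, indent=2, default=float)
        )

    @staticmethod
    def load(directory: str | Path) -> "ModelBundle":
        path = Path(directory) / "model.bin"
        if not path.exists():
            raise FileNotFoundError(f"no model bundle at {directory}")
        return joblib.load(path)


@dataclass
class PredictionRecord:
    """Per-compound output of the four production models."""

    compound_id: str
    canonical_smiles: str
    binary_probability: float
    binary_label: str  # "Yes" iff active probability > 0.5
    binary_confident: bool
    pic50: float | None = None
    pic50_leverage: float | None = None
    pic50_in_domain: bool | None = None
    sirt12_probabilities: dict | None = None
    sirt12_confident: bool | None = None
    sirt23_probabilities: dict | None = None
    sirt23_confident: bool | None = None
    nearest_reference_id: str | None = None
    nearest_reference_similarity: float | None = None
    radar: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        d = asdict(self)
        for key in ("sirt12_probabilities", "sirt23_probabilities", "radar"):
            d[key] = json.dumps(d[key]) if d[key] is not None else ""
        return d


def _find_smiles_column(columns) -> str:
    for c in columns:
        if c.strip().lower() == "smiles":
            return c
    raise ValueError(
        f"no SMILES column found; expected a header named 'smiles', got {list(columns)}"
    )


def vs_screen(
    input_csv: str | Path,
    bundle: ModelBundle | str | Path,
    output_csv: str | Path,
    chunk_size: int = 5000,
) -> dict:
    """Screen a SMILES CSV with the binary model; one output row per valid row.

    Rows whose SMILES fail standardization go to ``<output>.rejects.csv``
    with a reason.  The output label is "Yes" exactly when the active-class
    probability exceeds 0.5; ``ad_flag`` applies the indeterminate-zone
    rule.  Re-running with identical inputs produces identical bytes.
    """
    if not isinstance(bundle, ModelBundle):
        bundle = ModelBundle.load(bundle)
    if bundle.task != "binary":
        raise ValueError("vs_screen requires a binary classification bundle")
    output_csv = Path(output_csv)
    n_ok = n_rejected = 0
    out_rows: list[dict] = []
    reject_rows: list[dict] = []
    for chunk in pd.read_csv(input_csv, chunksize=chunk_size, dtype=str):
        smiles_col = _find_smiles_column(chunk.columns)
        id_col = next((c for c in chunk.columns
                       if c.strip().lower() in ("id", "compound_id", "name")), None)
        valid_idx, canon = [], []
        for i, smi in zip(chunk.index, chunk[smiles_col]):
            try:
                canon.append(ds.standardize_structure(str(smi)))
                valid_idx.append(i)
            except ds.StandardizationError as exc:
                reject_rows.append({**chunk.loc[i].to_dict(), "reason": str(exc)})
                n_rejected += 1
        if not valid_idx:
            continue
        proba = bundle.predict_from_smiles(canon)
        for row_i, smi, p_row in zip(valid_idx, canon, proba):
            p = bundle.active_probability(p_row)
            out_rows.append({
                "compound_id": (chunk.loc[row_i, id_col] if id_col
                                else f"ROW{row_i}"),
                "canonical_smiles": smi,
                "probability_active": round(p, 6),
                "label": "Yes" if p > 0.5 else "No",
                "ad_flag": "in" if in_confidence_zone("binary", p_row) else "out",
            })
            n_ok += 1
    pd.DataFrame(out_rows).to_csv(output_csv, index=False)
    if reject_rows:
        pd.DataFrame(reject_rows).to_csv(
            output_csv.with_suffix(".rejects.csv"), index=False
        )
    return {"n_screened": n_ok, "n_rejected": n_rejected,
            "output": str(output_csv)}


def analyze(
    smiles_list,
    bundles: dict[str, ModelBundle],
    reference_library: pd.DataFrame | None = None,
) -> tuple[list[PredictionRecord], dict]:
    """Run all four production models on each compound.

    ``bundles`` must provide keys ``binary``, ``regression``, ``sirt12``,
    ``sirt23``.  Returns the prediction records plus per-compound artifacts
    (atom-contribution weights for the binary and regression models, and
    probability histogram data).  An empty input yields an empty report.
    """
    required = ("binary", "regression", "sirt12", "sirt23")
    missing = [k for k in required if k not in bundles]
    if missing:
        raise ValueError(f"missing model bundle(s): {missing}")
    records: list[PredictionRecord] = []
    artifacts: dict[str, dict] = {}
    if not len(smiles_list):
        return records, {"histogram": {"binary_probabilities": []}}
    canon = [ds.standardize_structure(s) for s in smiles_list]
    b = bundles["binary"]
    r = bundles["regression"]
    proba_bin = b.predict_from_smiles(canon)
    pic50 = r.predict_from_smiles(canon)
    proba12 = bundles["sirt12"].predict_from_smiles(canon)
    proba23 = bundles["sirt23"].predict_from_smiles(canon)
    lev = r.leverage.leverage(r.featurize(canon)) if r.leverage is not None else None
    for i, smi in enumerate(canon):
        p_act = b.active_probability(proba_bin[i])
        rec = PredictionRecord(
            compound_id=f"A{i:04d}",
            canonical_smiles=smi,
            binary_probability=p_act,
            binary_label="Yes" if p_act > 0.5 else "No",
            binary_confident=in_confidence_zone("binary", proba_bin[i]),
            pic50=float(pic50[i]),
        )
        if lev is not None:
            rec.pic50_leverage = float(lev[i])
            rec.pic50_in_domain = bool(lev[i] <= r.leverage.h_star_)
        for key, proba, attr in (("sirt12", proba12, "sirt12"),
                                 ("sirt23", proba23, "sirt23")):
            classes = [str(c) for c in bundles[key].model.classes_]
            probs = {c: float(p) for c, p in zip(classes, proba[i])}
            setattr(rec, f"{attr}_probabilities", probs)
            setattr(rec, f"{attr}_confident",
                    in_confidence_zone("multiclass", proba[i]))
        if reference_library is not None and len(reference_library):
            ident, sim = tanimoto_nearest(
                smi,
                reference_library["smiles"].tolist(),
                reference_library["compound_id"].tolist(),
            )
            rec.nearest_reference_id = str(ident)
            rec.nearest_reference_similarity = sim
        # Radar axes: probabilities are native [0, 1]; pIC50 min-max scaled
        # over the conventional 4-8 reporting range.
        rec.radar = {
            "binary_probability": p_act,
            "pic50_scaled": float(np.clip((rec.pic50 - 4.0) / 4.0, 0.0, 1.0)),
            "sirt12_top": max(rec.sirt12_probabilities.values()),
            "sirt23_top": max(rec.sirt23_probabilities.values()),
        }
        records.append(rec)

        bin_classes = list(b.model.classes_)
        pos = bin_classes.index(b.positive_class)
        atom_maps = {}
        if b.feature_type is not FeatureType.DESCRIPTORS_2D:
            atom_maps["binary"] = similarity_map(
                lambda fp: b.model.predict_proba(fp.reshape(1, -1))[0, pos],
                smi, b.feature_type,
            ).to_rows()
        if r.feature_type is not FeatureType.DESCRIPTORS_2D:
            atom_maps["regression"] = similarity_map(
                lambda fp: r.model.predict(fp.reshape(1, -1))[0],
                smi, r.feature_type,
            ).to_rows()
        artifacts[rec.compound_id] = {"atom_contributions": atom_maps}
    artifacts["histogram"] = {
        "binary_probabilities": [float(b.active_probability(p)) for p in proba_bin]
    }
    return records, artifacts


# --------------------------------------------------------------------------
# Full pipeline


@dataclass
class PipelineConfig:
    """Configuration of the train-validate protocol.

    Search spaces are deliberately compact versions of the family defaults
    so a full run stays desk-sized; they are user-overridable.  Seeds are
    explicit: there is no hidden global randomness.
    """

    workdir: str = "qsar_run"
    input_csv: str | None = None  # when None, the synthetic fixture is used
    synthetic: SyntheticSARConfig = field(default_factory=SyntheticSARConfig)
    test_fraction: float = 0.3
    budget: int = 8
    cv: int = 5
    n_scramble: int = 100
    decoy_n_actives: int = 15
    decoy_per_active: int = 40
    decoy_pool_multiple: int = 50
    leverage_repeats: int = 30
    seed: int = 0

    def rf_space(self):
        return {"n_estimators": Integer(100, 300), "max_depth": Integer(4, 25)}

    def rf_regression_space(self):
        # sqrt feature sampling keeps forests fast on 1024-bit fingerprints
        return {
            "n_estimators": Integer(100, 200),
            "max_depth": Integer(8, 25),
            "max_features": Categorical(("sqrt", 0.05)),
        }


def _encode_datasets(compounds: list[ds.CuratedCompound]) -> dict[str, pd.DataFrame]:
    """Build the four modelling tables from curated compounds."""
    reg, binary, sel12, sel23 = [], [], [], []
    for c in compounds:
        r2 = c.records.get(ds.Isoform.SIRT2)
        if r2 is None:
            continue
        cls2 = ds.assign_sirt2_class(r2)
        if r2.kind is ds.MeasurementKind.IC50:
            reg.append({"smiles": c.canonical_smiles,
                        "pic50": ds.to_pic50(r2.value)})
        if cls2 is not ds.ActivityClass.TWILIGHT:
            binary.append({"smiles": c.canonical_smiles, "label": cls2.value})
        for iso, rows in ((ds.Isoform.SIRT1, sel12), (ds.Isoform.SIRT3, sel23)):
            ro = c.records.get(iso)
            if ro is None:
                continue
            sel = ds.assign_selectivity_class(cls2, ds.assign_sirt2_class(ro))
            if sel is not ds.SelectivityClass.EXCLUDED:
                rows.append({"smiles": c.canonical_smiles, "label": sel.value})
    return {
        "regression": pd.DataFrame(reg),
        "binary": pd.DataFrame(binary),
        "sirt12": pd.DataFrame(sel12),
        "sirt23": pd.DataFrame(sel23),
    }


def _split(table: pd.DataFrame, cfg: PipelineConfig, regression: bool):
    labels = table["pic50"] if regression else table["label"]
    assignment = ds.stratified_split(labels, cfg.test_fraction, cfg.seed,
                                    regression=regression)
    return table[assignment == "TRAIN"], table[assignment == "TEST"]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute curate -> featurize -> split -> rebalance -> train -> validate.

    Returns (and writes to ``<workdir>/run_report.json``) a machine-readable
    report with every validation statistic, quality-gate flag, and artifact
    path.  Any stage failure raises with the stage name attached.
    """
    cfg = config
    workdir = Path(cfg.workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": {"seed": cfg.seed, "budget": cfg.budget,
                               "n_scramble": cfg.n_scramble},
                    "stages": {}, "artifacts": {}}
    t_all = time.time()

    def stage(name):
        logger.info("stage %s", name)
        return _StageTimer(name, report)

    if True:
        with stage("ingest"):
            if cfg.input_csv is None:
                records, truth = generate_synthetic_sar(cfg.synthetic)
                raw_csv = workdir / "raw_records.csv"
                records.to_csv(raw_csv, index=False)
            else:
                raw_csv = Path(cfg.input_csv)
        with stage("curate"):
            compounds, curation_log = ds.curate(raw_csv, workdir / "curated.csv")
            report["curation"] = curation_log
            report["artifacts"]["curated_csv"] = str(workdir / "curated.csv")
        with stage("encode"):
            tables = _encode_datasets(compounds)
            report["dataset_sizes"] = {k: int(len(v)) for k, v in tables.items()}

        bundles: dict[str, ModelBundle] = {}

        with stage("train_binary"):
            train, test = _split(tables["binary"], cfg, regression=False)
            Xtr = fingerprint_matrix(train["smiles"], FeatureType.ECFP4)
            Xte = fingerprint_matrix(test["smiles"], FeatureType.ECFP4)
            clf = QSARClassifier(
                "random_forest", search_space=cfg.rf_space(), budget=cfg.budget,
                cv=cfg.cv, rebalance=True, random_state=cfg.seed,
            ).fit(Xtr, train["label"].to_numpy())
            proba = clf.predict_proba(Xte)
            rep = classification_report(test["label"].to_numpy(), proba,
                                        list(clf.classes_))
            report["binary"] = {
                "cv": asdict(clf.cv_stats_),
                "external": rep.to_dict(),
                "best_params": clf.best_params_,
            }
            bundles["binary"] = ModelBundle(
                task="binary", feature_type=FeatureType.ECFP4, model=clf,
                positive_class=ds.ActivityClass.ACTIVE.value,
            )
            binary_test = test

        with stage("decoy_benchmark"):
            actives_test = binary_test[
                binary_test["label"] == ds.ActivityClass.ACTIVE.value
            ]["smiles"].tolist()
            rng = np.random.default_rng(cfg.seed)
            take = min(cfg.decoy_n_actives, len(actives_test))
            chosen = [actives_test[i] for i in
                      np.sort(rng.choice(len(actives_test), take, replace=False))]
            pool = generate_candidate_pool(
                cfg.decoy_pool_multiple * cfg.decoy_per_active * take,
                seed=cfg.seed + 1,
            )
            decoys = generate_decoys(chosen, pool, cfg.decoy_per_active,
                                     seed=cfg.seed + 2)
            clf = bundles["binary"].model
            pos = list(clf.classes_).index(ds.ActivityClass.ACTIVE.value)
            bench = evaluate_on_decoys(
                clf,
                fingerprint_matrix(chosen, FeatureType.ECFP4),
                fingerprint_matrix(decoys, FeatureType.ECFP4),
                confident_fn=lambda row: in_confidence_zone("binary", row),
                positive_index=pos,
            )
            report["decoy"] = {
                "n_actives": take, "n_decoys": len(decoys),
                "all": bench["all"].to_dict(),
                "ad_filtered": (bench["ad_filtered"].to_dict()
                                if bench.get("ad_filtered") else None),
            }

        with stage("train_regression"):
            train, test = _split(tables["regression"], cfg, regression=True)
            Xtr = fingerprint_matrix(train["smiles"], FeatureType.ECFP4)
            Xte = fingerprint_matrix(test["smiles"], FeatureType.ECFP4)
            ytr = train["pic50"].to_numpy()
            yte = test["pic50"].to_numpy()
            regm = QSARRegressor(
                "random_forest", search_space=cfg.rf_regression_space(),
                budget=cfg.budget, cv=cfg.cv, random_state=cfg.seed,
            ).fit(Xtr, ytr)
            rep = regression_report(yte, regm.predict(Xte), ytr)
            report["regression"] = {
                "cv": asdict(regm.cv_stats_),
                "gates": regm.cv_stats_.gates(),
                "external": rep.to_dict(),
                "best_params": regm.best_params_,
            }

        with stage("applicability"):
            domain = LeverageDomain(
                n_repeats=cfg.leverage_repeats, importance_max_samples=128,
                random_state=cfg.seed,
            ).fit(regm, Xtr, ytr)
            lev_test = domain.leverage(Xte)
            report["applicability"] = {
                "m": domain.m_, "p": domain.p_, "h_star": domain.h_star_,
                "test_out_of_domain": int(np.sum(lev_test > domain.h_star_)),
                "train_leverage_sum": float(domain.train_leverages_.sum()),
                "rank": domain.rank_,
            }
            bundles["regression"] = ModelBundle(
                task="regression", feature_type=FeatureType.ECFP4, model=regm,
                leverage=domain,
            )

        with stage("y_scramble"):
            scr = y_scramble(regm, Xtr, ytr, n_reps=cfg.n_scramble,
                             random_state=cfg.seed)
            report["y_scramble"] = {
                "n_reps": cfg.n_scramble,
                "true_q2": scr.true_stat,
                "mean_scrambled_q2": scr.mean_scrambled,
                "max_scrambled_q2": float(np.max(scr.scrambled_stats)),
            }

        for key in ("sirt12", "sirt23"):
            with stage(f"train_{key}"):
                table = tables[key]
                train, test = _split(table, cfg, regression=False)
                Xtr = fingerprint_matrix(train["smiles"], FeatureType.ECFP4)
                Xte = fingerprint_matrix(test["smiles"], FeatureType.ECFP4)
                clf = QSARClassifier(
                    "random_forest", search_space=cfg.rf_space(),
                    budget=max(1, cfg.budget // 2), cv=cfg.cv, rebalance=True,
                    random_state=cfg.seed,
                ).fit(Xtr, train["label"].to_numpy())
                rep = classification_report(test["label"].to_numpy(),
                                            clf.predict_proba(Xte),
                                            list(clf.classes_))
                report[key] = {"cv": asdict(clf.cv_stats_),
                               "external": rep.to_dict(),
                               "best_params": clf.best_params_}
                bundles[key] = ModelBundle(task="multiclass",
                                           feature_type=FeatureType.ECFP4,
                                           model=clf)

        with stage("persist"):
            for key, bundle in bundles.items():
                path = workdir / f"bundle_{key}"
                bundle.save(path)
                report["artifacts"][f"bundle_{key}"] = str(path)

    report["elapsed_s"] = round(time.time() - t_all, 2)
    report_path = workdir / "run_report.json"
    report_path.write_text(json.dumps(report, indent=2, default=float))
    report["artifacts"]["run_report"] = str(report_path)
    return report


class _StageTimer:
    def __init__(self, name, report):
        self.name = name
        self.report = report

    def __enter__(self):
        self.t0 = time.time()
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc_type is not None:
            # Partial artifacts stay on disk for debugging.
            raise RuntimeError(f"pipeline stage {self.name!r} failed: {exc}") from exc
        self.report["stages"][self.name] = round(time.time() - self.t0, 2)
        return False
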