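"""Study orchestration: data loading, train/test splitting, descriptor
selection, fitting, validation, applicability domain, and the packaged
reference fixtures (the published model, its 243-IL dataset of experimental
and predicted toxicities, and the two external worked examples)."""

from __future__ import annotations

import hashlib
import json
import shutil
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .descriptors import (
    DescriptorTable,
    drop_all_zero_bins,
    read_dataset,
    read_descriptor_file,
    read_ion_profiles,
    build_descriptor_table,
    all_bin_names,
)
from .domain import ADReport, h_star, williams
from .mlr import MLRModel, fit_ols, predict, published_model
from .selection import BreakingPointTable, GAConfig, SelectionResult, breaking_point, ga_select
from .synthetic import SyntheticSpec, gen_dataset
from .validation import (
    ExternalReport,
    MetricReport,
    ScrambleResult,
    external_metrics,
    internal_report,
    regression_metrics,
    y_scramble,
)

_FIXTURES = ("table2", "table7", "eq13")


def load_fixture(name: str):
    """Packaged reference data.

    ``table2``: the 243-IL dataset (name, experimental and model-predicted
    Log 1/EC50, train/test membership).  ``table7``: two external ILs with
    their 11 descriptor values and experimental/predicted responses.
    ``eq13``: the published 11-descriptor model.
    """
    if name not in _FIXTURES:
        raise ValueError(f"unknown fixture {name!r}; valid: {_FIXTURES}")
    if name == "eq13":
        return published_model()
    ref = resources.files("ilqsar.data").joinpath(f"{name}.csv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path)


def reproduce_paper(tol_metrics: float = 0.01, tol_pred: float = 0.01) -> pd.DataFrame:
    """Recompute every published statistic reachable from the packaged
    fixtures and compare against the printed values.

    The training block and external battery are recomputed from the
    experimental and predicted columns of the 243-IL table (predictions
    printed at 2 decimals); the two worked examples apply the published
    model to their printed descriptor rows.  The external R2 is the squared
    Pearson correlation of experimental vs predicted, the convention the
    source software reports for test sets.  Returns a comparison frame
    with one row per quantity.
    """
    t2 = load_fixture("table2")
    tr = t2[t2.set == "train"]
    te = t2[t2.set == "test"]
    p = 11
    m_tr = regression_metrics(tr.log_inv_ec50_exp, tr.log_inv_ec50_pred, p)
    m_te = regression_metrics(te.log_inv_ec50_exp, te.log_inv_ec50_pred, p)
    ext = external_metrics(tr.log_inv_ec50_exp, te.log_inv_ec50_exp,
                           te.log_inv_ec50_pred)
    from .validation import concordance_ccc
    ccc_tr = concordance_ccc(tr.log_inv_ec50_exp.to_numpy(),
                             tr.log_inv_ec50_pred.to_numpy())
    r_te = np.corrcoef(te.log_inv_ec50_exp, te.log_inv_ec50_pred)[0, 1]

    model = published_model()
    t7 = load_fixture("table7")
    t7_pred = predict(model, t7.set_index("il_id")[model.descriptor_names])

    rows = [
        # (quantity, computed, printed, tolerance)
        ("train_r2", m_tr.r2, 0.821, 0.005),
        ("train_r2_adj", m_tr.r2_adj, 0.810, 0.005),
        ("train_f", m_tr.fisher_f, 71.49, 2.0),
        ("train_s", m_tr.s, 0.2908, 0.005),
        ("train_rmse", m_tr.rmse, 0.2811, 0.005),
        ("train_aad", m_tr.aad, 0.222, 0.005),
        ("train_aard_pct", m_tr.aard_pct, 13.5, 0.2),
        ("train_ccc", ccc_tr, 0.902, 0.005),
        ("test_r2_pearson", r_te ** 2, 0.751, 0.005),
        ("test_rmse", m_te.rmse, 0.3500, 0.005),
        ("test_aad", m_te.aad, 0.234, 0.005),
        ("test_aard_pct", m_te.aard_pct, 17.6, 0.2),
        ("test_ccc", ext.ccc, 0.853, 0.005),
        ("test_q2_f1", ext.q2_f1, 0.734, tol_metrics),
        ("test_q2_f2", ext.q2_f2, 0.729, tol_metrics),
        ("test_q2_f3", ext.q2_f3, 0.724, tol_metrics),
        ("test_r2m_avg", ext.r2m_avg, 0.648, 0.02),
        ("test_r2m_delta", ext.r2m_delta, 0.205, 0.02),
        ("h_star", h_star(p, len(tr)), 0.197, 0.0005),
        ("pred_new_il_1", t7_pred.iloc[0], -2.49, tol_pred),
        ("pred_new_il_2", t7_pred.iloc[1], -0.67, tol_pred),
    ]
    df = pd.DataFrame(rows, columns=["quantity", "computed", "printed", "tol"])
    df["ok"] = (df.computed - df.printed).abs() <= df.tol
    return df


# ---------------------------------------------------------------------------
# full study driver

@dataclass
class StudyConfig:
    """One of ``synthetic``, ``descriptor_path`` or (``ions_path`` and
    ``dataset_path``) supplies the data."""

    synthetic: SyntheticSpec | None = None
    descriptor_path: str | None = None
    ions_path: str | None = None
    dataset_path: str | None = None
    split: str = "fixed-labels"  # fixed-labels | random | leave-cation-out | leave-anion-out
    split_frac: float = 0.75
    split_seed: int = 0
    k: int = 11
    k_range: tuple[int, ...] | None = None
    breaking_delta: float = 0.01
    ga: GAConfig = field(default_factory=GAConfig)
    lmo_frac: float = 0.2
    lmo_iterations: int = 1000
    scramble_iterations: int = 1000
    out_dir: str | None = None

    def __post_init__(self) -> None:
        sources = [self.synthetic is not None, self.descriptor_path is not None,
                   self.ions_path is not None or self.dataset_path is not None]
        if sum(sources) != 1:
            raise ValueError("exactly one input source must be configured")


@dataclass
class StudyReport:
    selection: SelectionResult
    model: MLRModel
    train_metrics: MetricReport
    external: ExternalReport
    scramble: ScrambleResult
    ad: ADReport
    breaking: BreakingPointTable | None
    predictions: pd.DataFrame
    provenance: dict


def _load_table(config: StudyConfig):
    if config.synthetic is not None:
        table, details = gen_dataset(config.synthetic, return_details=True)
        return table, details["records"]
    if config.descriptor_path is not None:
        return read_descriptor_file(config.descriptor_path), None
    records, labels = read_dataset(config.dataset_path)
    profiles = read_ion_profiles(config.ions_path)
    table = build_descriptor_table(records, profiles, bins=all_bin_names(),
                                   set_labels=labels or None)
    return table, records


def _apply_split(table: DescriptorTable, records, config: StudyConfig) -> DescriptorTable:
    if config.split == "fixed-labels":
        if table.set_label is None or not len(table.set_label):
            raise ValueError("fixed-labels split needs a set column")
        return table
    rng = np.random.default_rng(config.split_seed)
    ids = table.il_ids
    if config.split == "random":
        n_test = int(np.floor((1.0 - config.split_frac) * len(ids)))
        test = set(rng.choice(len(ids), size=n_test, replace=False))
        labels = pd.Series(["test" if i in test else "train"
                            for i in range(len(ids))], index=ids)
    elif config.split in ("leave-cation-out", "leave-anion-out"):
        if records is None:
            raise ValueError(f"{config.split} split needs ion-pair records")
        attr = "cation_id" if config.split == "leave-cation-out" else "anion_id"
        by_ion = pd.Series({r.il_id: getattr(r, attr) for r in records})
        ions = by_ion.unique()
        rng.shuffle(ions)
        target = (1.0 - config.split_frac) * len(ids)
        test_ions, count = set(), 0
        for ion in ions:
            if count >= target:
                break
            test_ions.add(ion)
            count += int((by_ion == ion).sum())
        labels = by_ion.map(lambda i: "test" if i in test_ions else "train")
    else:
        raise ValueError(f"unknown split scheme {config.split!r}")
    return DescriptorTable(data=table.data, response=table.response,
                           set_label=labels)


def run_study(config: StudyConfig) -> StudyReport:
    """Run the full modelling study: split, (optional) breaking-point scan,
    GA descriptor selection, OLS fit, internal validation (LOO, LMO,
    Y-scrambling), external validation, and applicability domain.

    Descriptor selection and fitting see only the training rows.  When
    ``out_dir`` is set, the model, metrics, per-compound predictions,
    Williams table and breaking-point curve are persisted there; partial
    outputs are removed if any stage fails.
    """
    out_dir = Path(config.out_dir) if config.out_dir else None
    created = False
    if out_dir is not None and not out_dir.exists():
        out_dir.mkdir(parents=True)
        created = True

    stage = "load"
    try:
        table, records = _load_table(config)
        stage = "split"
        table = _apply_split(table, records, config)
        train = table.subset("train")
        test = table.subset("test")
        train = drop_all_zero_bins(train)
        pool = train.descriptor_names

        stage = "breaking-point"
        breaking = None
        if config.k_range:
            breaking = breaking_point(train, pool, config.k_range,
                                      config=config.ga, delta=config.breaking_delta)

        stage = "selection"
        selection = ga_select(train, pool, config.k, config.ga)
        model = selection.model

        stage = "internal-validation"
        train_metrics, _ = internal_report(
            train, selection.chosen_names, lmo_frac=config.lmo_frac,
            lmo_iterations=config.lmo_iterations, seed=config.ga.seed)
        scramble = y_scramble(train, selection.chosen_names,
                              n_iter=config.scramble_iterations, seed=config.ga.seed)

        stage = "external-validation"
        yhat_test = predict(model, test.data[selection.chosen_names])
        external = external_metrics(
            train.response.to_numpy(),
            test.response.loc[yhat_test.index].to_numpy(),
            yhat_test.to_numpy())

        stage = "applicability-domain"
        test_named = DescriptorTable(data=test.data[selection.chosen_names],
                                     response=test.response, set_label=None)
        train_named = DescriptorTable(data=train.data[selection.chosen_names],
                                      response=train.response, set_label=None)
        ad = williams(train_named, test_named, model)

        stage = "report"
        yhat_train = predict(model, train.data[selection.chosen_names])
        preds = pd.concat([
            pd.DataFrame({"set": "train", "y_exp": train.response,
                          "y_pred": yhat_train}),
            pd.DataFrame({"set": "test",
                          "y_exp": test.response.loc[yhat_test.index],
                          "y_pred": yhat_test}),
        ])
        cfg_digest = hashlib.sha256(
            json.dumps(_config_dict(config), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]
        report = StudyReport(
            selection=selection, model=model, train_metrics=train_metrics,
            external=external, scramble=scramble, ad=ad, breaking=breaking,
            predictions=preds,
            provenance={"config_sha256": cfg_digest, "seed": config.ga.seed,
                        "n_train": len(train.il_ids), "n_test": len(test.il_ids),
                        "p": len(selection.chosen_names)},
        )
        if out_dir is not None:
            _persist(report, out_dir)
        return report
    except Exception as exc:
        if out_dir is not None and created:
            shutil.rmtree(out_dir, ignore_errors=True)
        raise RuntimeError(f"study stage {stage!r} failed: {exc}") from exc


def _config_dict(config: StudyConfig) -> dict:
    d = dict(config.__dict__)
    d["ga"] = dict(config.ga.__dict__)
    if config.synthetic is not None:
        s = dict(config.synthetic.__dict__)
        s["planted_model"] = config.synthetic.planted_model.coefficients
        d["synthetic"] = s
    return d


def _persist(report: StudyReport, out_dir: Path) -> None:
    report.model.to_json(out_dir / "model.json")
    metrics = {
        "train": report.train_metrics.__dict__,
        "external": report.external.__dict__,
        "scramble": {"n_iterations": report.scramble.n_iterations,
                     "mean_r2": report.scramble.mean_r2},
        "ad": report.ad.summary(),
        "selection": {"chosen": report.selection.chosen_names,
                      "fitness": report.selection.fitness_value},
        "provenance": report.provenance,
    }
    (out_dir / "metrics.json").write_text(json.dumps(metrics, indent=2))
    report.ad.to_csv(out_dir / "williams.csv")
    report.predictions.to_csv(out_dir / "predictions.csv", index_label="il_id")
    if report.breaking is not None:
        report.breaking.to_csv(out_dir / "breaking_point.csv")
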