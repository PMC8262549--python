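"""The full federated-vs-centralized benchmark, statsmodels style.

:class:`VFLBenchmark` is built from a labeled, balanced dataset, a vertical
plan and the two network configs; ``fit(seed)`` executes the whole protocol
— one stratified split shared by every arm, a central baseline on raw
features, per-site baselines on raw slices, per-site autoencoders encoding
train and test rows, per-site latent models, and the aggregated-latent
central model — and returns a :class:`BenchmarkResults` carrying every
arm's held-out accuracy/AUROC, the relative percent differences, and a
``summary()`` grid shaped like the study's results table.
"""

from __future__ import annotations

import json
import warnings as _warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .autoencoder import AutoencoderConfig, encode, train_autoencoder
from .classifier import ClassifierConfig, EvalResult, evaluate, train_classifier
from .dataset import TabularDataset, split_train_test, vertical_split
from .errors import InputError, OvercompletenessError
from .federation import aggregate
from .preprocess import post_embedding_width
from .schema import VerticalPlan

__all__ = [
    "ArmResult",
    "BenchmarkResults",
    "VFLBenchmark",
    "relative_difference",
    "run_benchmark",
    "sweep_code_dim",
]


def relative_difference(before: float, after: float) -> float:
    """Signed relative percent change 100 * (after - before) / before,
    rounded to 2 decimals for reporting (0.83 -> 0.82 gives -1.20)."""
    if before <= 0:
        raise InputError(f"relative difference undefined for before={before}")
    return round(100.0 * (after - before) / before, 2)


@dataclass
class ArmResult:
    """Before/after metrics for one arm plus their relative differences."""

    before: EvalResult
    after: EvalResult
    accuracy_diff: float = field(init=False)
    auroc_diff: float = field(init=False)

    def __post_init__(self) -> None:
        self.accuracy_diff = relative_difference(self.before.accuracy, self.after.accuracy)
        self.auroc_diff = relative_difference(self.before.auroc, self.after.auroc)


@dataclass
class BenchmarkResults:
    """Everything one benchmark run produced.

    ``arms`` maps 'central' and 'site_<i>' to their before/after results;
    metadata records the plan, configs, seed and the shared test row IDs so
    the run is auditable and the difference columns recomputable.
    """

    arms: dict[str, ArmResult]
    metadata: dict

    def arm_names(self) -> list[str]:
        return list(self.arms)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, arm in self.arms.items():
            rows.append(
                {
                    "arm": name,
                    "accuracy_before": arm.before.accuracy,
                    "accuracy_after": arm.after.accuracy,
                    "accuracy_diff_pct": arm.accuracy_diff,
                    "auroc_before": arm.before.auroc,
                    "auroc_after": arm.after.auroc,
                    "auroc_diff_pct": arm.auroc_diff,
                }
            )
        return pd.DataFrame(rows).set_index("arm")

    def summary(self) -> str:
        """Text grid: per arm, accuracy and AUROC before/after the federated
        transform and the relative percent differences."""
        lines = [
            "Vertical federated learning benchmark",
            f"  sites: {self.metadata['n_sites']}   "
            f"rows: {self.metadata['n_rows']} (test {self.metadata['n_test']})   "
            f"seed: {self.metadata['seed']}",
            "",
            f"{'arm':<10}{'metric':<10}{'before':>8}{'after':>8}{'diff %':>9}",
            "-" * 45,
        ]
        for name, arm in self.arms.items():
            lines.append(
                f"{name:<10}{'accuracy':<10}{arm.before.accuracy:>8.2f}"
                f"{arm.after.accuracy:>8.2f}{arm.accuracy_diff:>+9.2f}"
            )
            lines.append(
                f"{'':<10}{'AUROC':<10}{arm.before.auroc:>8.2f}"
                f"{arm.after.auroc:>8.2f}{arm.auroc_diff:>+9.2f}"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        out = {"metadata": {k: v for k, v in self.metadata.items()}, "arms": {}}
        out["metadata"]["test_row_ids"] = [
            int(i) for i in self.metadata["test_row_ids"]
        ]
        for name, arm in self.arms.items():
            out["arms"][name] = {
                "before": {
                    "accuracy": arm.before.accuracy,
                    "auroc": arm.before.auroc,
                    "n_eval": arm.before.n_eval,
                },
                "after": {
                    "accuracy": arm.after.accuracy,
                    "auroc": arm.after.auroc,
                    "n_eval": arm.after.n_eval,
                },
                "accuracy_diff_pct": arm.accuracy_diff,
                "auroc_diff_pct": arm.auroc_diff,
            }
        return out

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


class VFLBenchmark:
    """Model object for the whole protocol on one dataset and plan.

    Parameters
    ----------
    dataset : TabularDataset
        Labeled (ideally class-balanced) table.
    plan : VerticalPlan
        Assignment of feature columns to sites.
    ae_config, clf_config :
        Network configurations shared by every arm.
    test_fraction : float
        Held-out fraction for the single stratified split all arms share.
    """

    def __init__(
        self,
        dataset: TabularDataset,
        plan: VerticalPlan,
        ae_config: Optional[AutoencoderConfig] = None,
        clf_config: Optional[ClassifierConfig] = None,
        test_fraction: float = 0.2,
    ):
        plan.validate(dataset.schema)
        dataset.label_array()  # fail fast when unlabeled
        self.dataset = dataset
        self.plan = plan
        self.ae_config = ae_config or AutoencoderConfig()
        self.clf_config = clf_config or ClassifierConfig()
        self.test_fraction = test_fraction

    def fit(self, seed: int = 0) -> BenchmarkResults:
        """Run every arm on one shared split and collect the report.

        Autoencoders are fit on training rows only (test rows are merely
        encoded) with per-site seeds ``seed + site_index`` so sites differ
        but runs reproduce; classifiers share one seed across arms.
        """
        train, test = split_train_test(self.dataset, self.test_fraction, seed)
        y_tr, y_te = train.label_array(), test.label_array()
        parts_tr = vertical_split(train, self.plan)
        parts_te = vertical_split(test, self.plan)

        def arm(features_tr, features_te) -> EvalResult:
            model = train_classifier(features_tr, y_tr, self.clf_config, seed=seed)
            return evaluate(model, features_te, y_te)

        central_before = arm(train.without_labels(), test.without_labels())
        site_before, site_after, lat_tr_all, lat_te_all = [], [], [], []
        for i in range(self.plan.n_sites):
            site_before.append(arm(parts_tr[i].dataset, parts_te[i].dataset))
            ae = train_autoencoder(parts_tr[i], self.ae_config, seed=seed + i)
            lat_tr = encode(ae, parts_tr[i])
            lat_te = encode(ae, parts_te[i])
            lat_tr_all.append(lat_tr)
            lat_te_all.append(lat_te)
            site_after.append(arm(lat_tr.codes, lat_te.codes))
        central_after = arm(aggregate(lat_tr_all), aggregate(lat_te_all))

        arms = {"central": ArmResult(central_before, central_after)}
        for i in range(self.plan.n_sites):
            arms[f"site_{i}"] = ArmResult(site_before[i], site_after[i])
        metadata = {
            "seed": seed,
            "n_sites": self.plan.n_sites,
            "n_rows": self.dataset.n_rows,
            "n_test": test.n_rows,
            "test_fraction": self.test_fraction,
            "plan": [list(a) for a in self.plan.site_assignments],
            "ae_config": self.ae_config.__dict__.copy(),
            "clf_config": self.clf_config.__dict__.copy(),
            "test_row_ids": test.row_ids,
        }
        return BenchmarkResults(arms, metadata)

    def sweep_code_dim(
        self, code_dims: list[int], seed: int = 0
    ) -> tuple[pd.DataFrame, list[str]]:
        """Re-run the benchmark across code-layer widths.

        For each width m the autoencoder becomes [m/2, m, m/2]; widths below
        any site's post-embedding input violate overcompleteness and are
        skipped with a recorded warning.  Returns the table of
        (code_dim, central-after accuracy, AUROC), ordered by code_dim,
        plus the warnings.
        """
        min_width = max(
            post_embedding_width(
                self.dataset.schema.subset(cols), self.ae_config.embedding_rule
            )
            for cols in self.plan.site_assignments
        )
        rows, warnings = [], []
        for m in sorted(code_dims):
            if m < min_width:
                msg = (
                    f"code_dim {m} below max site input width {min_width}; skipped"
                )
                warnings.append(msg)
                _warnings.warn(msg)
                continue
            ae = AutoencoderConfig(
                hidden_dims=(max(1, m // 2), m, max(1, m // 2)),
                initial_lr=self.ae_config.initial_lr,
                lr_decay=self.ae_config.lr_decay,
                weight_decay=self.ae_config.weight_decay,
                epochs=self.ae_config.epochs,
                batch_size=self.ae_config.batch_size,
                embedding_rule=self.ae_config.embedding_rule,
            )
            res = VFLBenchmark(
                self.dataset, self.plan, ae, self.clf_config, self.test_fraction
            ).fit(seed)
            central = res.arms["central"].after
            rows.append(
                {"code_dim": m, "accuracy": central.accuracy, "auroc": central.auroc}
            )
        return pd.DataFrame(rows, columns=["code_dim", "accuracy", "auroc"]), warnings


def run_benchmark(
    dataset: TabularDataset,
    plan: VerticalPlan,
    ae_config: Optional[AutoencoderConfig] = None,
    clf_config: Optional[ClassifierConfig] = None,
    seed: int = 0,
    test_fraction: float = 0.2,
) -> BenchmarkResults:
    """Functional one-call form of :class:`VFLBenchmark`."""
    return VFLBenchmark(dataset, plan, ae_config, clf_config, test_fraction).fit(seed)


def sweep_code_dim(
    dataset: TabularDataset,
    plan: VerticalPlan,
    code_dims: list[int],
    clf_config: Optional[ClassifierConfig] = None,
    seed: int = 0,
    ae_config: Optional[AutoencoderConfig] = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Functional one-call form of :meth:`VFLBenchmark.sweep_code_dim`."""
    return VFLBenchmark(dataset, plan, ae_config, clf_config).sweep_code_dim(
        code_dims, seed
    )
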