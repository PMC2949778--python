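"""5x2 cross-validation of the perceptron on a chosen variable subset.

Five seeded stratified halvings of the cohort; each halving is used in
both directions (train on a / test on b, then train on b / test on a)
with freshly initialised networks whose weights are frozen before the
held-out half is scored — ten independent classification experiments,
reported as a table of sensitivity, specificity, global accuracy and ROC
AUC plus their arithmetic means.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .cohort import EncodedMatrix
from .metrics import MetricsRecord, confusion_and_metrics
from .mlp import Perceptron, TrainConfig
from .seeds import split_seed

METRIC_FIELDS = ("sensitivity", "specificity", "global_accuracy", "roc_auc")


def stratified_halves(y, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Split indices into two disjoint, exhaustive, class-stratified halves.

    Per class the two halves differ in size by at most one; for odd class
    counts the extra member's side is decided by the seeded stream.
    """
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    a_parts, b_parts = [], []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        if len(idx) < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 members; cannot halve")
        idx = rng.permutation(idx)
        na = len(idx) // 2
        if len(idx) % 2 == 1 and rng.random() < 0.5:
            na += 1
        a_parts.append(idx[:na])
        b_parts.append(idx[na:])
    a = np.sort(np.concatenate(a_parts))
    b = np.sort(np.concatenate(b_parts))
    return a, b


@dataclass
class ResultsTable:
    """Ten run rows ("run i, a->b" / "run i, b->a") plus the mean row."""

    rows: list[tuple[str, MetricsRecord]]

    @property
    def mean_row(self) -> MetricsRecord:
        vals = {}
        for f in METRIC_FIELDS:
            xs = [getattr(rec, f) for _, rec in self.rows]
            if any(x is None for x in xs):
                vals[f] = None
            else:
                vals[f] = float(np.mean(xs))
        return MetricsRecord(
            vals["sensitivity"], vals["specificity"], vals["global_accuracy"],
            vals["roc_auc"], None,
        )

    def to_dataframe(self) -> pd.DataFrame:
        recs = [{"run": label, **rec.as_row()} for label, rec in self.rows]
        recs.append({"run": "mean", **self.mean_row.as_row()})
        return pd.DataFrame(recs)

    def to_tsv(self, path=None):
        df = self.to_dataframe().rename(
            columns={
                "run": "ANN",
                "sensitivity": "Sensitivity",
                "specificity": "Specificity",
                "global_accuracy": "Global accuracy",
                "roc_auc": "ROC AUC",
            }
        )
        return df.to_csv(path, sep="\t", index=False, float_format="%.4f")

    def to_json(self) -> str:
        payload = [
            {"run": label, **rec.as_row(), "confusion": rec.confusion}
            for label, rec in self.rows
        ]
        payload.append({"run": "mean", **self.mean_row.as_row(), "confusion": None})
        return json.dumps(payload, indent=2)

    def summary(self) -> str:
        return self.to_tsv()


def run_5x2(
    em: EncodedMatrix,
    feature_subset: list[str],
    train_cfg: TrainConfig | None = None,
    seeds: tuple[int, ...] = (1, 2, 3, 4, 5),
    hidden: int = 4,
    hook=None,
) -> ResultsTable:
    """The 5x2 protocol on the given variable subset.

    ``seeds`` are the five halving seeds (distinct). Each of the ten
    experiments trains a fresh network with a run-specific seed derived
    from the master training seed, freezes its weights, and scores only
    the held-out half. ``hook(label, train_idx, test_idx)`` is called per
    run for instrumentation.
    """
    if not feature_subset:
        raise ValueError("feature_subset must be non-empty")
    if len(seeds) != 5 or len(set(seeds)) != 5:
        raise ValueError("exactly 5 distinct seeds are required")
    train_cfg = train_cfg or TrainConfig()
    X = em.columns(list(feature_subset))
    y = em.y
    rows: list[tuple[str, MetricsRecord]] = []
    for i, s in enumerate(seeds):
        a, b = stratified_halves(y, s)
        for direction, (tr, te) in (("a-b", (a, b)), ("b-a", (b, a))):
            label = f"run {i + 1}, {direction}"
            if hook is not None:
                hook(label, tr, te)
            run_cfg = replace(train_cfg, seed=split_seed(train_cfg.seed, i, 0 if direction == "a-b" else 1))
            res = Perceptron(y[tr], X[tr], hidden=hidden).fit(run_cfg)
            scores = res.predict(X[te])  # weights frozen; held-out half only
            rows.append((label, confusion_and_metrics(scores, y[te])))
    return ResultsTable(rows)
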