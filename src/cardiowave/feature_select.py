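"""Elastic-net feature selection and selection-distribution summaries.

Selection fits an elastic-net-penalized logistic regression (features
z-scored first) along a log-spaced penalty path, scores each penalty by
cross-validated deviance, and picks the strongest penalty whose mean
deviance is within one standard error of the best ("1-SE rule") — the
conventional recipe for stable sparse sets.  Selected features are
those with nonzero coefficients at the chosen penalty after refitting
on the full table.  For multi-class tables, selection runs one-vs-rest
per class and the selected set is the union of the per-class sets.

Summaries mirror the usual reporting of such selections: counts by
frequency band (< 10 Hz, 10-20 Hz, > 20 Hz), by statistic, and by
signal source, each with a Pareto (cumulative-percentage) curve over
categories sorted by descending count.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold

from .exceptions import DegenerateLabelsError, InvalidArgumentError
from .synthetic import CHANNELS
from .timefreq import STATS, parse_feature_name

logger = logging.getLogger(__name__)

FREQUENCY_BANDS = ("<10 Hz", "10-20 Hz", ">20 Hz")


@dataclasses.dataclass
class FeatureTable:
    """Segments x features matrix with subject ids and class labels."""

    matrix: np.ndarray
    feature_names: list[str]
    subject_ids: list[str]
    labels: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n, p = self.matrix.shape
        if len(self.feature_names) != p:
            raise InvalidArgumentError("feature name count != column count")
        if len(self.subject_ids) != n or len(self.labels) != n:
            raise InvalidArgumentError("row / subject / label counts disagree")
        if len(set(self.feature_names)) != p:
            raise InvalidArgumentError("feature names must be unique")
        if not np.all(np.isfinite(self.matrix)):
            raise InvalidArgumentError("feature matrix contains non-finite values")

    @property
    def task(self) -> str:
        return "BINARY" if len(set(self.labels)) == 2 else "MULTICLASS"

    @property
    def n_segments(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    def subset_rows(self, idx: np.ndarray) -> "FeatureTable":
        return FeatureTable(
            matrix=self.matrix[idx],
            feature_names=list(self.feature_names),
            subject_ids=[self.subject_ids[i] for i in idx],
            labels=[self.labels[i] for i in idx],
        )

    def select_columns(self, names: Sequence[str]) -> "FeatureTable":
        pos = {n: j for j, n in enumerate(self.feature_names)}
        idx = [pos[n] for n in names]
        return FeatureTable(
            matrix=self.matrix[:, idx],
            feature_names=list(names),
            subject_ids=list(self.subject_ids),
            labels=list(self.labels),
        )

    def filter_channels(self, channels: Sequence[str]) -> "FeatureTable":
        """Keep only features whose name parses to one of ``channels``."""
        keep = [n for n in self.feature_names
                if parse_feature_name(n)[0] in set(channels)]
        return self.select_columns(keep)

    def to_frame(self):
        import pandas as pd

        frame = pd.DataFrame(self.matrix, columns=self.feature_names)
        frame.insert(0, "subject_id", self.subject_ids)
        frame.insert(1, "class_label", self.labels)
        return frame

    @classmethod
    def from_frame(cls, frame) -> "FeatureTable":
        cols = [c for c in frame.columns if c not in ("subject_id", "class_label")]
        return cls(
            matrix=frame[cols].to_numpy(dtype=float),
            feature_names=cols,
            subject_ids=frame["subject_id"].astype(str).tolist(),
            labels=frame["class_label"].astype(str).tolist(),
        )


@dataclasses.dataclass(frozen=True)
class SelectionResult:
    selected_names: list[str]
    coefficients: dict[str, float]       # nonzero coefficients at the chosen penalty
    n_original: int

    @property
    def n_selected(self) -> int:
        return len(self.selected_names)

    @property
    def reduction_pct(self) -> float:
        return 100.0 * (1.0 - self.n_selected / self.n_original)


@dataclasses.dataclass(frozen=True)
class DistributionSummary:
    frequency_bands: dict[str, int]
    statistic_counts: dict[str, int]
    source_counts: dict[str, int]
    pareto: dict[str, list[tuple[str, float]]]   # family -> (category, cum %)


def _binary_path_selection(
    X: np.ndarray,
    y: np.ndarray,
    l1_ratio: float,
    cv_folds: int,
    seed: int,
    n_penalties: int,
    one_se: bool,
) -> np.ndarray:
    """Coefficient vector at the CV-chosen penalty for a 0/1 response.

    The penalty path starts at the smallest C able to produce any
    nonzero coefficient (KKT condition at w = 0: ``|C * X^T(y - ybar)|
    <= l1_ratio`` componentwise) and spans three decades upward.
    """
    grad0 = np.abs(X.T @ (y - y.mean()))
    c0 = l1_ratio / max(grad0.max(), 1e-12)
    # One point sits below the activation threshold so the empty
    # (intercept-only) model is on the path: with flat null CV curves
    # the 1-SE rule can then legitimately select nothing.
    cs = np.concatenate([[0.3 * c0], c0 * np.logspace(0.0, 3.0, n_penalties - 1)])

    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    path = LogisticRegressionCV(
        Cs=cs, cv=skf, l1_ratios=[l1_ratio], solver="saga",
        scoring="neg_log_loss", max_iter=3000, tol=1e-4, random_state=seed,
    )
    path.fit(X, y)
    # scores_: (folds, Cs, l1_ratios) of neg log-loss, columns follow Cs_
    deviance = -path.scores_[path.classes_[1]][:, :, 0]
    mean_dev = deviance.mean(axis=0)
    se_dev = deviance.std(axis=0, ddof=1) / np.sqrt(cv_folds)
    best = int(np.argmin(mean_dev))
    if one_se:
        ok = np.flatnonzero(mean_dev <= mean_dev[best] + se_dev[best])
        chosen = int(ok.min())          # smallest C = strongest penalty
    else:
        chosen = best
    final = LogisticRegression(
        solver="saga", l1_ratio=l1_ratio, C=cs[chosen],
        max_iter=3000, tol=1e-4, random_state=seed,
    )
    final.fit(X, y)
    return final.coef_.ravel()


def elastic_net_select(
    table: FeatureTable,
    l1_ratio: float = 0.5,
    cv_folds: int = 5,
    seed: int = 0,
    n_penalties: int = 25,
    one_se: bool = True,
) -> SelectionResult:
    """Cross-validated elastic-net selection on a feature table.

    Deterministic in ``seed``.  Constant feature columns cannot be
    z-scored and are dropped with a warning before fitting.
    """
    classes = sorted(set(table.labels))
    if len(classes) < 2:
        raise DegenerateLabelsError("need at least two classes for selection")
    if table.n_segments < 2 * cv_folds:
        raise InvalidArgumentError("too few rows for the requested folds")

    sd = table.matrix.std(axis=0)
    keep = sd > 0
    if not keep.all():
        logger.warning("dropping %d constant feature columns", int((~keep).sum()))
    names = [n for n, k in zip(table.feature_names, keep) if k]
    X = (table.matrix[:, keep] - table.matrix[:, keep].mean(axis=0)) / sd[keep]

    label_arr = np.asarray(table.labels)
    coef_map: dict[str, float] = {}
    targets = [classes[1]] if len(classes) == 2 else classes
    for cls in targets:
        y = (label_arr == cls).astype(int)
        coefs = _binary_path_selection(X, y, l1_ratio, cv_folds, seed, n_penalties, one_se)
        for name, w in zip(names, coefs):
            if w != 0.0 and abs(w) > abs(coef_map.get(name, 0.0)):
                coef_map[name] = float(w)

    selected = [n for n in names if n in coef_map]
    return SelectionResult(
        selected_names=selected,
        coefficients={n: coef_map[n] for n in selected},
        n_original=table.n_features,
    )


def _pareto(counts: dict[str, int]) -> list[tuple[str, float]]:
    total = sum(counts.values())
    if total == 0:
        return []
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    out, cum = [], 0
    for cat, cnt in ordered:
        cum += cnt
        out.append((cat, 100.0 * cum / total))
    return out


def summarize_selection(result: SelectionResult) -> DistributionSummary:
    """Band / statistic / source histograms with Pareto curves."""
    bands = dict.fromkeys(FREQUENCY_BANDS, 0)
    stats = dict.fromkeys(STATS, 0)
    sources = dict.fromkeys(CHANNELS, 0)
    for name in result.selected_names:
        channel, stat, freq = parse_feature_name(name)
        if freq < 10.0:
            bands["<10 Hz"] += 1
        elif freq <= 20.0:
            bands["10-20 Hz"] += 1
        else:
            bands[">20 Hz"] += 1
        stats[stat] += 1
        sources[channel] += 1
    return DistributionSummary(
        frequency_bands=bands,
        statistic_counts=stats,
        source_counts=sources,
        pareto={
            "frequency": _pareto(bands),
            "statistic": _pareto(stats),
            "source": _pareto(sources),
        },
    )


def summary_to_frame(summary: DistributionSummary):
    """Long-format CSV layout of the three count families."""
    import pandas as pd

    rows = []
    for family, counts in (("frequency", summary.frequency_bands),
                           ("statistic", summary.statistic_counts),
                           ("source", summary.source_counts)):
        pareto = dict(summary.pareto[family])
        for cat, cnt in counts.items():
            rows.append({"family": family, "category": cat, "count": cnt,
                         "cumulative_pct": pareto.get(cat, float("nan"))})
    return pd.DataFrame(rows)


def plot_summary(summary: DistributionSummary, out_path) -> None:
    """Bar + Pareto panels for the three category families."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(14, 4))
    for ax, (family, counts) in zip(axes, (
        ("frequency", summary.frequency_bands),
        ("statistic", summary.statistic_counts),
        ("source", summary.source_counts),
    )):
        ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        cats = [c for c, _ in ordered]
        vals = [v for _, v in ordered]
        ax.bar(cats, vals, color="#4878a8")
        ax2 = ax.twinx()
        pareto = summary.pareto[family]
        ax2.plot([c for c, _ in pareto], [p for _, p in pareto], "o-", color="#c44e52")
        ax2.set_ylim(0, 105)
        ax.set_title(family)
        ax.tick_params(axis="x", rotation=45)
    fig.tight_layout()
    fig.savefig(out_path, dpi=100)
    plt.close(fig)
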