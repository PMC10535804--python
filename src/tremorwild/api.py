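"""Model/Results front end tying the pipeline together.

`TremorDetector` is built from raw recordings + subject metadata (or an
already-computed feature matrix); `fit()` runs preprocessing, windowed
feature extraction, the stratified 70/30 split, fivefold cross-validation
of the Bi-LSTM-with-attention classifier and a final train/test fit, and
returns a `TremorDetectorResults` carrying per-fold and held-out metrics,
training histories and a `summary()` table.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np

from . import features as feat
from . import io_preprocess as iop
from . import train_eval as te
from .features import FeatureWindow, WindowConfig, standardize, to_arrays
from .io_preprocess import PreprocessConfig, Recording, SubjectMeta
from .model import BiLSTMAttentionClassifier, ModelSpec
from .train_eval import FoldMetrics, TrainConfig


class TremorDetector:
    """Binary PD-vs-control detector over phone-call accelerometer windows."""

    def __init__(
        self,
        windows: list[FeatureWindow],
        spec: ModelSpec | None = None,
        train_config: TrainConfig | None = None,
    ):
        if not windows:
            raise ValueError("no feature windows")
        self.windows = windows
        self.spec = spec or ModelSpec()
        self.train_config = train_config or TrainConfig()

    @classmethod
    def from_recordings(
        cls,
        recordings: list[Recording],
        meta: list[SubjectMeta],
        max_updrs16: int = 1,
        preprocess_config: PreprocessConfig | None = None,
        window_config: WindowConfig | None = None,
        spec: ModelSpec | None = None,
        train_config: TrainConfig | None = None,
    ) -> "TremorDetector":
        """Full front door: cohort selection, conditioning, feature extraction."""
        cohort = iop.filter_cohort(meta, max_updrs16)
        keep = {m.subject_id for m in cohort}
        recs = [r for r in recordings if r.subject_id in keep]
        recs = iop.preprocess_dataset(recs, preprocess_config)
        windows = feat.build_feature_matrix(recs, cohort, window_config)
        return cls(windows, spec=spec, train_config=train_config)

    @classmethod
    def from_directory(
        cls, data_dir: str | Path, **kwargs
    ) -> "TremorDetector":
        """Load ``signals/`` + ``metadata.csv`` under ``data_dir``."""
        data_dir = Path(data_dir)
        recs, meta = iop.load_dataset(data_dir / "signals", data_dir / "metadata.csv")
        return cls.from_recordings(recs, meta, **kwargs)

    def fit(self, crossvalidate: bool = True) -> "TremorDetectorResults":
        cfg = self.train_config
        train_w, test_w = te.split_train_test(self.windows, cfg)
        folds = te.crossvalidate(train_w, self.spec, cfg) if crossvalidate else []

        X_tr, y_tr = to_arrays(train_w)
        X_te, y_te = to_arrays(test_w)
        if cfg.standardize:
            X_tr, mu, sd = standardize(X_tr)
            X_te, _, _ = standardize(X_te, mu, sd)
        else:
            mu = sd = None
        model, hist = te.train_model(X_tr, y_tr, X_te, y_te, self.spec, cfg)
        p_te = model.predict_proba(X_te)
        test_metrics = te.compute_metrics(y_te, p_te, cfg.threshold)
        fpr, tpr, auc = te.roc_auc(y_te, p_te)
        test_metrics.auc = auc
        return TremorDetectorResults(
            detector=self,
            model=model,
            fold_metrics=folds,
            test_metrics=test_metrics,
            test_roc=(fpr, tpr),
            history=hist,
            standardization=(mu, sd),
            n_train=len(train_w),
            n_test=len(test_w),
        )


class TremorDetectorResults:
    """Fit artefacts: the trained classifier, CV fold metrics, held-out
    test metrics and per-epoch training history."""

    def __init__(self, detector, model, fold_metrics, test_metrics, test_roc,
                 history, standardization, n_train, n_test):
        self.detector = detector
        self.model = model
        self.fold_metrics: list[FoldMetrics] = fold_metrics
        self.test_metrics: FoldMetrics = test_metrics
        self.test_roc = test_roc
        self.history = history
        self.standardization = standardization
        self.n_train = n_train
        self.n_test = n_test

    @property
    def cv_aggregate(self) -> dict:
        return te.aggregate_metrics(self.fold_metrics) if self.fold_metrics else {}

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        mu, sd = self.standardization
        if mu is not None:
            X, _, _ = standardize(X, mu, sd)
        return self.model.predict_proba(X)

    def summary(self) -> str:
        """Plain-text summary table of CV and held-out performance."""
        lines = [
            "Bi-LSTM + attention tremor detector",
            "=" * 54,
            f"windows: {self.n_train} train / {self.n_test} test "
            f"(split unit: {self.detector.train_config.split_unit})",
            f"trainable parameters: {self.model.count_parameters():,}",
            "",
        ]
        names = ("accuracy", "precision", "recall", "specificity", "f1", "auc")
        if self.fold_metrics:
            agg = self.cv_aggregate
            lines.append(f"{self.detector.train_config.folds}-fold cross-validation "
                         "(mean ± sd)")
            for n in names:
                lines.append(f"  {n:<12s} {agg[n]['mean']:.3f} ± {agg[n]['sd']:.3f}")
            lines.append("")
        lines.append("held-out test set")
        for n in names:
            lines.append(f"  {n:<12s} {getattr(self.test_metrics, n):.3f}")
        return "\n".join(lines)

    def export_report(self, outdir: str | Path) -> dict[str, Path]:
        folds = self.fold_metrics or [self.test_metrics]
        return te.export_report(folds, outdir)

    def save_model(self, path: str | Path) -> None:
        self.model.save(path)
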