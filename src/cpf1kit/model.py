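"""Model/Results surface tying the toolkit together.

`Cpf1ActivityModel` and `Cpf1OffTargetModel` are built from data (records,
a DataFrame, or pre-encoded matrices); ``fit()`` runs the seeded CNN
training and returns a :class:`ClassifierResults` carrying the trained
network, training diagnostics and a ``summary()`` table.  Cross-validation,
permutation importance and library design hang off the results object.

Example
-------
>>> from cpf1kit import synthetic, model
>>> recs = synthetic.simulate_on_target(synthetic.GeneratorConfig(n=500, seed=1))
>>> res = model.Cpf1ActivityModel.from_records(recs).fit(epochs=20, seed=1)
>>> scores = res.score_sequences([recs[0].sequence])
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import evaluation, importance as importance_mod, nn
from .encodings import (
    MismatchRecord,
    TargetRecord,
    encode_mismatch_pair,
    encode_order_k,
)

__all__ = ["Cpf1ActivityModel", "Cpf1OffTargetModel", "ClassifierResults"]


class _BaseModel:
    """Shared fit machinery: holds encoded inputs + binary labels + NetSpec."""

    #: filled by subclasses
    _row_labels: tuple[str, ...] | None = None

    def __init__(self, endog: np.ndarray, exog: np.ndarray,
                 spec: nn.NetSpec | None = None):
        exog = np.asarray(exog, dtype=np.float32)
        endog = np.asarray(endog)
        if exog.ndim != 3:
            raise ValueError("exog must be (n, rows, cols) encoded matrices")
        if exog.shape[0] != endog.shape[0]:
            raise ValueError("endog and exog lengths differ")
        self.endog = endog.astype(np.int64)
        self.exog = exog
        self.spec = spec or self._default_spec(exog.shape[1:])
        if tuple(self.spec.input_shape) != exog.shape[1:]:
            raise ValueError(
                f"spec input shape {self.spec.input_shape} does not match "
                f"encoded data {exog.shape[1:]}"
            )

    def _default_spec(self, shape) -> nn.NetSpec:
        raise NotImplementedError

    @property
    def nobs(self) -> int:
        return self.exog.shape[0]

    def fit(self, epochs: int | None = None, seed: int | None = None
            ) -> "ClassifierResults":
        """Train the classifier; returns a results object."""
        clf = nn.TrainedClassifier.initialize(self.spec)
        trained = nn.train_classifier(clf, self.exog, self.endog,
                                      epochs=epochs, seed=seed)
        return ClassifierResults(self, trained)

    def trainer(self, epochs: int | None = None, seed: int | None = None):
        """A (X, y) -> score-function callback for external_cv/cutoff_grid."""

        def _train(X, y):
            clf = nn.TrainedClassifier.initialize(self.spec)
            trained = nn.train_classifier(clf, X, y, epochs=epochs, seed=seed)
            return lambda Xt: nn.predict(trained, Xt)

        return _train

    def cross_validate(self, k: int = 5, seed: int = 0,
                       epochs: int | None = None) -> evaluation.CVReport:
        """k-fold external cross-validation on this model's data."""
        return self.external_cv_on(self.exog, self.endog, k=k, seed=seed,
                                   epochs=epochs)

    def external_cv_on(self, X, y, k: int = 5, seed: int = 0,
                       epochs: int | None = None) -> evaluation.CVReport:
        return evaluation.external_cv(
            X, y, self.trainer(epochs=epochs, seed=seed), k=k, seed=seed
        )


class Cpf1ActivityModel(_BaseModel):
    """On-target activity classifier over order-k encoded matched targets.

    The canonical configuration is the order-2 encoding of the 27-nt site
    (16 x 26 input, 50 filters of 5 x 5, dense width 650); order-1 swaps in
    a 4 x 1 kernel with 1 x 2 pooling because a 5 x 5 kernel does not fit
    the 4 x 27 input.
    """

    def __init__(self, endog, exog, spec=None, order: int = 2):
        self.order = order
        self._row_labels = tuple(encode_order_k("A" * 27, order).row_labels)
        super().__init__(endog, exog, spec)

    def _default_spec(self, shape) -> nn.NetSpec:
        if self.order == 1:
            return nn.NetSpec(input_shape=shape, n_filters=50, kernel=(4, 1),
                              pool=(1, 2), dense_units=650)
        return nn.NetSpec(input_shape=shape, n_filters=50, kernel=(5, 5),
                          dense_units=650)

    @classmethod
    def from_records(cls, records: list[TargetRecord], top_frac: float = 0.2,
                     bottom_frac: float = 0.2, order: int = 2
                     ) -> "Cpf1ActivityModel":
        """Label ranked records by efficacy extremes and encode them.

        The top fraction of the indel-frequency ranking becomes class 1,
        the bottom fraction class 0, the middle is excluded.
        """
        chosen, labels = evaluation.label_by_cutoffs(records, top_frac,
                                                     bottom_frac)
        X = np.stack([encode_order_k(r.sequence, order).entries
                      for r in chosen])
        m = cls(labels, X, order=order)
        m.records = chosen
        return m

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, sequence_col: str = "sequence",
                       frequency_col: str = "indel_frequency", **kwargs
                       ) -> "Cpf1ActivityModel":
        records = [
            TargetRecord(sequence=s, indel_frequency=float(f))
            for s, f in zip(df[sequence_col], df[frequency_col])
        ]
        return cls.from_records(records, **kwargs)

    def encode(self, sequences) -> np.ndarray:
        return np.stack([encode_order_k(s, self.order).entries
                         for s in sequences])


class Cpf1OffTargetModel(_BaseModel):
    """Off-target specificity classifier over 12 x 27 mismatch encodings.

    The positive class is "high activity off-target sites": the top
    fraction (default 20%) of mismatched pairs ranked by indel frequency;
    the remaining pairs are the low-activity class.
    """

    _row_labels = tuple(
        encode_mismatch_pair("A" * 27, "A" * 27).row_labels
    )

    def _default_spec(self, shape) -> nn.NetSpec:
        return nn.NetSpec(input_shape=shape, n_filters=35, kernel=(7, 7),
                          dense_units=300)

    @classmethod
    def from_records(cls, records: list[MismatchRecord],
                     top_frac: float = 0.2) -> "Cpf1OffTargetModel":
        chosen, labels = evaluation.label_by_cutoffs(records, top_frac,
                                                     1.0 - top_frac)
        X = np.stack([encode_mismatch_pair(r.guide, r.target).entries
                      for r in chosen])
        m = cls(labels, X)
        m.records = chosen
        return m

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, guide_col: str = "guide",
                       target_col: str = "target",
                       frequency_col: str = "indel_frequency", **kwargs
                       ) -> "Cpf1OffTargetModel":
        records = [
            MismatchRecord(guide=g, target=t, indel_frequency=float(f))
            for g, t, f in zip(df[guide_col], df[target_col], df[frequency_col])
        ]
        return cls.from_records(records, **kwargs)

    def encode(self, pairs) -> np.ndarray:
        return np.stack([encode_mismatch_pair(g, t).entries for g, t in pairs])


@dataclass
class ClassifierResults:
    """A fitted classifier plus its training diagnostics."""

    model: _BaseModel
    classifier: nn.TrainedClassifier

    @property
    def spec(self) -> nn.NetSpec:
        return self.classifier.spec

    @property
    def loss_history(self) -> list[float]:
        return self.classifier.loss_history

    @property
    def fittedvalues(self) -> np.ndarray:
        """Positive-class scores on the training data."""
        return nn.predict(self.classifier, self.model.exog)

    def predict(self, X) -> np.ndarray:
        """Scores for pre-encoded matrices (n, rows, cols)."""
        return nn.predict(self.classifier, np.asarray(X, dtype=np.float32))

    def score_sequences(self, sequences) -> np.ndarray:
        """Scores for raw sequences (activity model) or (guide, target)
        pairs (off-target model)."""
        return self.predict(self.model.encode(sequences))

    def training_metrics(self) -> evaluation.MetricsReport:
        return evaluation.evaluate_scores(
            self.fittedvalues, self.model.endog, self.classifier.threshold
        )

    def permutation_importance(self, X=None, y=None, n_repeats: int = 5,
                               seed: int = 0, criterion: str = "auc",
                               top_n: int = 50
                               ) -> importance_mod.ImportanceMap:
        """Neuron importances + input-heatmap projection (training data by
        default)."""
        X = self.model.exog if X is None else X
        y = self.model.endog if y is None else y
        scores = importance_mod.permutation_importance(
            self.classifier, X, y, n_repeats=n_repeats, seed=seed,
            criterion=criterion,
        )
        return importance_mod.project_top_features(
            scores, top_n, self.spec, row_labels=self.model._row_labels
        )

    def save(self, path) -> None:
        nn.save_classifier(self.classifier, path)

    def summary(self) -> str:
        """Plain-text summary of architecture, training and fit quality."""
        spec = self.spec
        m = self.training_metrics()
        rows, cols = spec.input_shape
        ch, cw = spec.conv_shape
        pr, pc = spec.pooled_shape
        lines = [
            f"{type(self.model).__name__} fit summary",
            "=" * 44,
            f"observations            {self.model.nobs}",
            f"positive class          {int(self.model.endog.sum())}",
            f"input matrix            {rows} x {cols}",
            f"conv filters            {spec.n_filters} @ "
            f"{spec.kernel[0]} x {spec.kernel[1]} -> maps {ch} x {cw}",
            f"sum pool                {spec.pool[0]} x {spec.pool[1]} "
            f"-> maps {pr} x {pc}",
            f"flatten / dense units   {spec.flatten_size} / {spec.dense_units}",
            f"optimizer               SGD lr={spec.learning_rate} "
            f"momentum={spec.momentum} batch={spec.batch_size}",
            f"epochs run              {len(self.loss_history)}",
        ]
        if self.loss_history:
            lines.append(f"loss first -> last      "
                         f"{self.loss_history[0]:.4f} -> {self.loss_history[-1]:.4f}")
        lines += [
            f"training AUC            {m.auc:.3f}",
            f"training F1 @ {self.classifier.threshold:.2f}      {m.f1:.3f}",
        ]
        return "\n".join(lines)
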