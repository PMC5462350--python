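"""The coarse-to-fine recognizer as a scikit-learn estimator, plus evaluation.

:class:`JDSRClassifier` operates on vectorized binary orientation images
(rows of an (n, D) 0/1 matrix).  ``fit`` stores the labeled training vectors;
``predict`` runs, per test sample, the full decision chain:

1. average Jaccard coefficient against every training class;
2. shortlist of the S highest-scoring classes (default S = C // 2);
3. dictionary of the shortlisted training vectors;
4. Jaccard-distance-weighted l1 solve;
5. per-class residuals and smallest-residual decision.

Raw photographs are handled by composing with
:class:`~leafjdsr.preprocessing.OrientationTransformer` in an sklearn
``Pipeline``; :func:`recognize` and :func:`cross_validate` are convenience
wrappers for single-image use and repeated stratified-fold evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted

from .coarse import CandidateShortlist, default_S, select_candidates
from .exceptions import InvalidInputError
from .jaccard import average_class_coefficient
from .preprocessing import PreprocessConfig, preprocess_image, vectorize
from .wsrc import Dictionary, SolverConfig, WsrcSolution, build_dictionary, fine_classify

__all__ = ["JDSRClassifier", "PipelineConfig", "RecognitionReport", "recognize",
           "cross_validate"]


class JDSRClassifier(BaseEstimator, ClassifierMixin):
    """Coarse-to-fine leaf classifier on binary orientation vectors.

    Parameters
    ----------
    n_candidates : int or "half"
        Shortlist size S for the coarse stage; "half" resolves to
        ``C // 2`` (at least 1) at predict time.
    mu : float
        l1 regularization weight of the sparse solve (default 0.001).
    weighted : bool
        If True (default) penalty weights are Jaccard distances (JDSR);
        if False all weights are 1 and the fine stage is classical SRC.
    tol, max_iter, weight_floor, backend
        Forwarded to the solver; see :class:`~leafjdsr.wsrc.SolverConfig`.
    permissive_jaccard : bool
        Treat all-zero/all-zero comparisons as identical instead of raising.

    Attributes
    ----------
    X_ : (n, D) uint8 training matrix
    y_ : (n,) training labels
    classes_ : sorted unique labels
    """

    def __init__(
        self,
        n_candidates="half",
        mu: float = 1e-3,
        weighted: bool = True,
        tol: float = 1e-6,
        max_iter: int = 10_000,
        weight_floor: float = 1e-8,
        backend: str = "cd",
        permissive_jaccard: bool = False,
    ):
        self.n_candidates = n_candidates
        self.mu = mu
        self.weighted = weighted
        self.tol = tol
        self.max_iter = max_iter
        self.weight_floor = weight_floor
        self.backend = backend
        self.permissive_jaccard = permissive_jaccard

    def _solver_config(self) -> SolverConfig:
        return SolverConfig(mu=self.mu, tol=self.tol, max_iter=self.max_iter,
                            weight_floor=self.weight_floor, backend=self.backend)

    def fit(self, X, y):
        X = np.asarray(X)
        if X.ndim != 2 or X.shape[0] == 0:
            raise InvalidInputError("X must be a non-empty (n_samples, D) binary matrix")
        if not np.isin(X, (0, 1)).all():
            raise InvalidInputError("X must be binary (vectorized orientation images)")
        y = np.asarray(list(y), dtype=object)
        if y.size != X.shape[0]:
            raise InvalidInputError(f"{X.shape[0]} samples but {y.size} labels")
        classes = sorted({str(c) for c in y})
        if len(classes) < 2:
            raise InvalidInputError("need training samples from at least 2 classes")
        self.X_ = X.astype(np.uint8)
        self.y_ = y
        self.classes_ = np.asarray(classes, dtype=object)
        self._solver_cfg_ = self._solver_config()
        return self

    def _resolve_S(self) -> int:
        C = len(self.classes_)
        if self.n_candidates == "half":
            return max(default_S(C), 1)
        S = int(self.n_candidates)
        if not (1 <= S <= C):
            raise InvalidInputError(f"n_candidates must be in [1, {C}], got {S}")
        return S

    def shortlist(self, x) -> CandidateShortlist:
        """Coarse stage for one probe vector."""
        check_is_fitted(self, "X_")
        table = average_class_coefficient(np.asarray(x).ravel(), self.X_, self.y_,
                                          permissive=self.permissive_jaccard)
        return select_candidates(table, self._resolve_S())

    def recognize_sample(self, x) -> tuple[object, WsrcSolution, CandidateShortlist]:
        """Full decision chain for one probe: (predicted label, solution, shortlist)."""
        check_is_fitted(self, "X_")
        x = np.asarray(x).ravel()
        shortlist = self.shortlist(x)
        dictionary = build_dictionary(shortlist, self.X_, self.y_)
        solution = fine_classify(dictionary, x, self._solver_cfg_,
                                 weighted=self.weighted,
                                 permissive=self.permissive_jaccard)
        return solution.predicted_class, solution, shortlist

    def predict(self, X):
        check_is_fitted(self, "X_")
        X = np.asarray(X)
        if X.ndim == 1:
            X = X[None, :]
        return np.asarray([self.recognize_sample(x)[0] for x in X], dtype=object)


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end configuration: preprocessing + shortlist + solver + evaluation."""

    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    n_candidates: object = "half"
    solver: SolverConfig = field(default_factory=SolverConfig)
    weighted: bool = True
    folds: int = 5
    repeats: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.folds < 2:
            raise InvalidInputError("folds must be >= 2")
        if self.repeats < 1:
            raise InvalidInputError("repeats must be >= 1")

    def classifier(self) -> JDSRClassifier:
        return JDSRClassifier(
            n_candidates=self.n_candidates, mu=self.solver.mu, weighted=self.weighted,
            tol=self.solver.tol, max_iter=self.solver.max_iter,
            weight_floor=self.solver.weight_floor, backend=self.solver.backend,
        )


@dataclass
class RecognitionReport:
    """Results of repeated stratified k-fold evaluation.

    ``records`` holds one row per (repeat, fold, test sample); per-class
    recognition rates are percentages of correctly recognized test samples of
    that class pooled over all repeats and folds, and ``macro_rate`` is their
    unweighted mean.  ``run_rates`` are per-(repeat, fold) macro rates, whose
    mean and standard deviation summarize run-to-run variability.
    """

    records: pd.DataFrame
    per_class_rates: dict
    macro_rate: float
    run_rates: list
    seed: int
    folds: int
    repeats: int

    @property
    def mean_rate(self) -> float:
        return float(np.mean(self.run_rates))

    @property
    def std_rate(self) -> float:
        return float(np.std(self.run_rates))


def recognize(image, train_images: Sequence, train_labels: Sequence,
              cfg: PipelineConfig | None = None):
    """Classify one raw color leaf photograph against raw training photographs.

    Returns (predicted label, WsrcSolution, CandidateShortlist).
    """
    cfg = cfg or PipelineConfig()
    Xtr = np.stack([vectorize(preprocess_image(im, cfg.preprocess)) for im in train_images])
    clf = cfg.classifier().fit(Xtr, train_labels)
    x = vectorize(preprocess_image(image, cfg.preprocess))
    return clf.recognize_sample(x)


def cross_validate(
    X,
    y,
    folds: int = 5,
    repeats: int = 1,
    seed: int = 0,
    clf: Optional[JDSRClassifier] = None,
) -> RecognitionReport:
    """Repeated stratified k-fold evaluation on preprocessed binary vectors.

    Each repeat partitions every class's samples into ``folds`` equal parts
    with a seed-derived shuffle; each fold is held out once while the rest
    train the classifier.  Fold assignment is the only source of randomness —
    everything downstream is deterministic — so a fixed seed reproduces the
    report exactly.
    """
    X = np.asarray(X)
    y = np.asarray(list(y), dtype=object)
    counts = pd.Series(y).value_counts()
    if (counts < folds).any():
        small = counts[counts < folds].index.tolist()
        raise InvalidInputError(f"classes {small} have fewer samples than folds={folds}")
    proto = clf if clf is not None else JDSRClassifier()
    rows = []
    run_rates = []
    for rep in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=(seed + rep) % 2**31)
        for fold_i, (tr, te) in enumerate(skf.split(X, y.astype(str))):
            model = clone(proto).fit(X[tr], y[tr])
            fold_rows = []
            for idx in te:
                pred, sol, short = model.recognize_sample(X[idx])
                fold_rows.append({
                    "repeat": rep, "fold": fold_i, "index": int(idx),
                    "true_class": y[idx], "predicted_class": pred,
                    "shortlist_hit": y[idx] in short.selected_classes,
                    "min_residual": min(sol.residuals.values()),
                })
            rows.extend(fold_rows)
            df = pd.DataFrame(fold_rows)
            df["correct"] = df["predicted_class"] == df["true_class"]
            run_rates.append(100.0 * float(df.groupby("true_class")["correct"].mean().mean()))
    records = pd.DataFrame(rows)
    per_class = {}
    for lab, g in records.groupby("true_class"):
        per_class[lab] = 100.0 * float((g["predicted_class"] == g["true_class"]).mean())
    macro = float(np.mean(list(per_class.values())))
    return RecognitionReport(records=records, per_class_rates=per_class,
                             macro_rate=macro, run_rates=run_rates, seed=seed,
                             folds=folds, repeats=repeats)
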