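"""Anomaly scoring and classification on top of latent-space projection.

The premise: a generator trained only on lesion-free images can reconstruct
normal anatomy but not lesions, so the pixelwise difference between a test
image and its multi-seed reconstruction highlights anomalies.  The anomaly
score is the sum of the (absolute) difference map over the breast mask divided
by the breast area, making scores comparable across breast sizes.  The
operating threshold maximises the Youden J index (sensitivity + specificity −
1) over the score set, with the convention score ≥ threshold ⇒ cancer.

The threshold is fit on the same evaluation set that is scored (mirroring a
single held-out test set with no separate calibration split), so the reported
accuracy/sensitivity/specificity are optimistic; AUC is threshold-free.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .metrics import (
    POSITIVE_LABEL,
    NEGATIVE_LABEL,
    ConfusionMatrix,
    confusion_metrics,
    roc_auc,
)
from .preprocess import NormalizedImage, PreprocessConfig, preprocess_phantom, preprocess_record
from .projection import MultiSeedProjection, PerceptualExtractor, multi_seed_project
from .stylegen import GeneratorModel


class AnomalyError(ValueError):
    pass


@dataclass
class DifferenceMap:
    values: np.ndarray  # non-negative floats
    source: tuple[str, str] = ("", "")


@dataclass
class AnomalyScore:
    case_id: str
    score: float
    n_seeds: int
    breast_area: int


@dataclass(frozen=True)
class Threshold:
    value: float
    youden_j: float
    convention: str = "score >= value => cancer"


@dataclass
class AnomalyReport:
    """Per-case scores and labels plus the derived classification metrics."""

    case_ids: list[str]
    scores: list[float]
    true_labels: list[str]
    predicted_labels: list[str]
    threshold: Threshold
    confusion: ConfusionMatrix
    metrics: dict[str, float]
    auc: float
    roc_points: np.ndarray
    n_seeds: int

    def to_dict(self) -> dict:
        return {
            "n_seeds": self.n_seeds,
            "threshold": self.threshold.value,
            "youden_j": self.threshold.youden_j,
            "auc": self.auc,
            "confusion": {
                "tp": self.confusion.tp,
                "tn": self.confusion.tn,
                "fp": self.confusion.fp,
                "fn": self.confusion.fn,
            },
            "metrics": self.metrics,
            "cases": [
                {"id": cid, "score": s, "true": t, "predicted": p}
                for cid, s, t, p in zip(
                    self.case_ids, self.scores, self.true_labels, self.predicted_labels
                )
            ],
        }


def difference_map(target, mean_image, source=("", "")) -> DifferenceMap:
    """Pixelwise absolute difference of 8-bit intensities, as floats."""
    a = np.asarray(target.pixels if isinstance(target, NormalizedImage) else target)
    b = np.asarray(mean_image)
    if a.shape != b.shape:
        raise AnomalyError(f"shape mismatch: {a.shape} vs {b.shape}")
    values = np.abs(a.astype(np.float64) - b.astype(np.float64))
    return DifferenceMap(values=values, source=tuple(source))


def anomaly_score(
    dmap: DifferenceMap | np.ndarray,
    mask: np.ndarray,
    area: int,
    case_id: str = "",
    n_seeds: int = 0,
) -> AnomalyScore:
    """Sum of the difference map inside the breast mask divided by breast area."""
    values = dmap.values if isinstance(dmap, DifferenceMap) else np.asarray(dmap, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != values.shape:
        raise AnomalyError("mask shape does not match difference map")
    if area <= 0:
        raise AnomalyError("breast area must be positive")
    score = float(values[mask].sum() / area)
    return AnomalyScore(case_id=case_id, score=score, n_seeds=n_seeds, breast_area=int(area))


def _normalize_labels(labels) -> list[str]:
    out = []
    for lab in labels:
        if isinstance(lab, str):
            if lab not in (POSITIVE_LABEL, NEGATIVE_LABEL):
                raise AnomalyError(f"unknown label {lab!r}")
            out.append(lab)
        else:
            out.append(POSITIVE_LABEL if lab else NEGATIVE_LABEL)
    return out


def youden_threshold(scores, labels) -> Threshold:
    """Threshold maximising J = sensitivity + specificity − 1.

    Candidates are the midpoints between consecutive distinct sorted scores
    plus ±infinity sentinels; ties in J resolve to the lowest threshold.
    """
    scores = [float(s) for s in scores]
    labs = _normalize_labels(labels)
    if len(scores) != len(labs):
        raise AnomalyError("scores and labels differ in length")
    pos = [s for s, l in zip(scores, labs) if l == POSITIVE_LABEL]
    neg = [s for s, l in zip(scores, labs) if l == NEGATIVE_LABEL]
    if not pos or not neg:
        raise AnomalyError("both classes must be present to fit a threshold")
    distinct = sorted(set(scores))
    candidates = [-math.inf]
    candidates += [(a + b) / 2.0 for a, b in zip(distinct, distinct[1:])]
    candidates.append(math.inf)
    best_t, best_j = None, -math.inf
    for t in candidates:  # ascending, so ties keep the lowest threshold
        sens = sum(s >= t for s in pos) / len(pos)
        spec = sum(s < t for s in neg) / len(neg)
        j = sens + spec - 1.0
        if j > best_j:
            best_t, best_j = t, j
    return Threshold(value=best_t, youden_j=best_j)


def classify(scores, threshold: Threshold) -> list[str]:
    return [POSITIVE_LABEL if s >= threshold.value else NEGATIVE_LABEL for s in scores]


def confusion_from_labels(true_labels, predicted_labels) -> ConfusionMatrix:
    t = _normalize_labels(true_labels)
    p = _normalize_labels(predicted_labels)
    tp = sum(a == POSITIVE_LABEL and b == POSITIVE_LABEL for a, b in zip(t, p))
    tn = sum(a == NEGATIVE_LABEL and b == NEGATIVE_LABEL for a, b in zip(t, p))
    fp = sum(a == NEGATIVE_LABEL and b == POSITIVE_LABEL for a, b in zip(t, p))
    fn = sum(a == POSITIVE_LABEL and b == NEGATIVE_LABEL for a, b in zip(t, p))
    return ConfusionMatrix(tp=tp, tn=tn, fp=fp, fn=fn)


def _to_normalized(case, config: PreprocessConfig) -> NormalizedImage:
    if isinstance(case, NormalizedImage):
        return case
    if hasattr(case, "params"):  # PhantomRecord
        return preprocess_phantom(case, config)
    return preprocess_record(case, config)


def score_case(
    image: NormalizedImage,
    model: GeneratorModel,
    seeds,
    steps: int,
    extractor: PerceptualExtractor | None,
    case_id: str = "",
) -> tuple[AnomalyScore, MultiSeedProjection]:
    proj = multi_seed_project(image, model, seeds=seeds, steps=steps, extractor=extractor)
    dmap = difference_map(image, proj.mean_image, source=(case_id, f"seeds={list(seeds)}"))
    score = anomaly_score(
        dmap, image.breast_mask, image.breast_area, case_id=case_id, n_seeds=len(proj.per_seed)
    )
    return score, proj


def run_pipeline(
    test_records,
    model: GeneratorModel,
    n_seeds: int = 9,
    steps: int = 300,
    extractor: PerceptualExtractor | None = None,
    config: PreprocessConfig = PreprocessConfig(),
    labels=None,
    progress: bool = False,
) -> AnomalyReport:
    """Full anomaly-detection workflow on a labelled test set.

    Each case is preprocessed, projected from seeds {0..n_seeds−1}, scored via
    its breast-area-normalised difference map, then the Youden threshold is
    fitted on the full score set and the confusion metrics and ROC/AUC are
    derived.  Fully deterministic.
    """
    test_records = list(test_records)
    if not test_records:
        raise AnomalyError("test set is empty")
    if n_seeds < 1:
        raise AnomalyError("n_seeds must be >= 1")
    if labels is None:
        labels = []
        for rec in test_records:
            if hasattr(rec, "params"):
                labels.append(POSITIVE_LABEL if rec.params.lesion_present else NEGATIVE_LABEL)
            elif isinstance(rec, NormalizedImage) and rec.is_lesioned is not None:
                labels.append(POSITIVE_LABEL if rec.is_lesioned else NEGATIVE_LABEL)
            else:
                raise AnomalyError("labels are required for records without ground truth")
    true_labels = _normalize_labels(labels)
    if len(true_labels) != len(test_records):
        raise AnomalyError("labels and test records differ in length")

    seeds = list(range(n_seeds))
    iterator = enumerate(test_records)
    if progress:
        from tqdm import tqdm

        iterator = tqdm(list(iterator), desc="score", leave=False)
    case_ids, scores = [], []
    for idx, rec in iterator:
        img = _to_normalized(rec, config)
        cid = img.provenance or f"case-{idx}"
        s, _ = score_case(img, model, seeds, steps, extractor, case_id=cid)
        case_ids.append(cid)
        scores.append(s.score)

    threshold = youden_threshold(scores, true_labels)
    predicted = classify(scores, threshold)
    cm = confusion_from_labels(true_labels, predicted)
    auc, points = roc_auc(scores, true_labels)
    return AnomalyReport(
        case_ids=case_ids,
        scores=scores,
        true_labels=true_labels,
        predicted_labels=predicted,
        threshold=threshold,
        confusion=cm,
        metrics=confusion_metrics(cm),
        auc=auc,
        roc_points=points,
        n_seeds=n_seeds,
    )


class GanAnomalyDetector:
    """scikit-learn-style detector wrapping projection-based scoring.

    ``score_samples`` returns breast-area-normalised anomaly scores (higher =
    more anomalous); ``fit`` additionally fits the Youden threshold from
    labelled scores, after which ``predict`` returns 'cancer'/'normal' labels.
    """

    def __init__(
        self,
        generator: GeneratorModel | None = None,
        n_seeds: int = 9,
        steps: int = 300,
        extractor: PerceptualExtractor | None = None,
        preprocess_config: PreprocessConfig = PreprocessConfig(),
    ):
        self.generator = generator
        self.n_seeds = n_seeds
        self.steps = steps
        self.extractor = extractor
        self.preprocess_config = preprocess_config

    def get_params(self, deep: bool = True) -> dict:
        return {
            "generator": self.generator,
            "n_seeds": self.n_seeds,
            "steps": self.steps,
            "extractor": self.extractor,
            "preprocess_config": self.preprocess_config,
        }

    def set_params(self, **params) -> "GanAnomalyDetector":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def score_samples(self, X) -> np.ndarray:
        if self.generator is None:
            raise AnomalyError("a trained generator is required")
        seeds = list(range(self.n_seeds))
        out = []
        for idx, rec in enumerate(X):
            img = _to_normalized(rec, self.preprocess_config)
            s, _ = score_case(
                img, self.generator, seeds, self.steps, self.extractor, case_id=f"case-{idx}"
            )
            out.append(s.score)
        return np.asarray(out)

    decision_function = score_samples

    def fit(self, X, y) -> "GanAnomalyDetector":
        scores = self.score_samples(X)
        self.threshold_ = youden_threshold(scores, y)
        self.scores_ = scores
        return self

    def predict(self, X) -> list[str]:
        if not hasattr(self, "threshold_"):
            raise AnomalyError("detector is not fitted; call fit(X, y) first")
        return classify(self.score_samples(X), self.threshold_)
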