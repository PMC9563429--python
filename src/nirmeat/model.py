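"""Model/Results facade tying the pipeline together.

``AdulterationClassifier`` is built from a point-spectrum table and a choice
of averaging scheme, convolution kernel size and classifier head; ``fit``
runs preprocessing, the SPXY split, CNN training and head fitting, and
returns an ``AdulterationResults`` object carrying the accuracies, the
confusion matrix, prediction timings and a ``summary()`` table.
"""

from __future__ import annotations

import time
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import classifiers as cls
from . import evaluate as ev
from . import nn
from . import partition as part
from . import preprocess as pp
from .synth import CLASS_LABELS

SCHEMES = ("per-direction", "four-direction")
HEADS = ("softmax", "elm", "svm")
KERNELS = (3, 5, 7)


def encode_labels(class_names) -> np.ndarray:
    """Class-name strings to integer codes in canonical class order."""
    lut = {c: i for i, c in enumerate(CLASS_LABELS)}
    try:
        return np.array([lut[c] for c in class_names], dtype=int)
    except KeyError as e:
        raise ValueError(f"unknown class label {e.args[0]!r}") from e


@dataclass
class PipelineBundle:
    """A trained CNN plus one classifier head, with a uniform predict API."""

    cnn: nn.CNN
    head: str
    head_model: object | None = None

    def extract_features(self, matrices: np.ndarray) -> np.ndarray:
        return self.cnn.extract_features(matrices)

    def predict_head(self, features: np.ndarray) -> np.ndarray:
        if self.head == "softmax":
            out = self.cnn.layers[-1].forward(features, False)
            return nn.softmax(out).argmax(axis=1)
        if self.head == "elm":
            return cls.elm_predict(self.head_model, features)
        if self.head == "svm":
            return cls.svm_predict(self.head_model, features)
        raise ValueError(f"unknown head {self.head!r}")

    def predict(self, matrices: np.ndarray) -> np.ndarray:
        return self.predict_head(self.extract_features(matrices))


@dataclass(frozen=True)
class FitOptions:
    """Training-stage knobs that are not part of the scientific design."""

    epochs: int = 500
    batch_size: int = 32
    filter_counts: tuple[int, int, int] = (16, 32, 64)
    fc_hidden: int = 128
    elm_search: bool = True
    elm_neurons: int = 175          # used when the neuron search is off
    elm_holdout_fraction: float = 0.25
    ga: cls.GAConfig | None = None  # None => GAConfig() defaults at fit time
    cv_folds: int | None = None     # None skips cross-validation
    cv_epochs: int | None = None    # reduced epochs inside CV folds


class AdulterationClassifier:
    """Five-class minced-mutton authentication model over NIR point spectra.

    Parameters
    ----------
    data
        Point-spectrum table (one row per sample/direction/point) in the
        package's CSV dialect, e.g. from :func:`nirmeat.synth.generate_dataset`
        or :func:`nirmeat.io.read_spectra_csv`.
    scheme
        Spectral information fed to the model: ``"per-direction"`` (four
        mean spectra per sample) or ``"four-direction"`` (one).
    kernel_size
        Convolution kernel side used in all three layers (3, 5 or 7).
    head
        Classifier head: ``"softmax"``, ``"elm"`` or ``"svm"``.
    n_calibration
        SPXY calibration-set size in samples; defaults to 75 % of samples.
    """

    def __init__(self, data: pd.DataFrame, scheme: str = "per-direction",
                 kernel_size: int = 7, head: str = "elm",
                 n_calibration: int | None = None,
                 options: FitOptions | None = None):
        if scheme not in SCHEMES:
            raise ValueError(f"scheme must be one of {SCHEMES}")
        if head not in HEADS:
            raise ValueError(f"head must be one of {HEADS}")
        if kernel_size not in KERNELS:
            raise ValueError(f"kernel_size must be one of {KERNELS}")
        self.data = data
        self.scheme = scheme
        self.kernel_size = kernel_size
        self.head = head
        self.n_calibration = n_calibration
        self.options = FitOptions() if options is None else options

    @classmethod
    def from_csv(cls, path, **kwargs) -> "AdulterationClassifier":
        from .io import read_spectra_csv
        return cls(read_spectra_csv(path), **kwargs)

    # -- fitting ------------------------------------------------------------

    def _prepare(self):
        """Preprocess both averaging levels and compute the SPXY split."""
        per_dir = pp.preprocess_table(self.data, scheme="per-direction")
        four_dir = pp.preprocess_table(self.data, scheme="four-direction")
        wl_cols = [c for c in four_dir.columns if c not in pp.META_COLUMNS]
        n = len(four_dir)
        n_cal = self.n_calibration or int(round(0.75 * n))
        split = part.spxy_split(four_dir[wl_cols].to_numpy(float),
                                four_dir["class"].to_numpy(),
                                four_dir["sample_id"].to_numpy(), n_cal)
        return per_dir, four_dir, split

    def fit(self, seed: int = 0, verbose: bool = False) -> "AdulterationResults":
        opts = self.options
        per_dir, four_dir, split = self._prepare()
        train_table = per_dir if self.scheme == "per-direction" else four_dir

        # training matrices: calibration rows of the chosen averaging scheme
        side = part.propagate(split, train_table)
        cal_table = train_table[(side == "cal").to_numpy()]
        ev.audit_no_leakage(cal_table["sample_id"], split.validation_ids)
        mats_cal, meta_cal = pp.matrices_from_table(cal_table)
        y_cal = encode_labels(meta_cal["class"])

        spec = nn.CNNSpec(input_size=mats_cal.shape[1],
                          kernel_size=self.kernel_size,
                          filter_counts=opts.filter_counts,
                          fc_hidden=opts.fc_hidden,
                          epochs=opts.epochs, batch_size=opts.batch_size,
                          seed=seed)
        t0 = time.perf_counter()
        cnn = nn.build(spec).train(mats_cal, nn.one_hot(y_cal),
                                   verbose=verbose)
        train_seconds = time.perf_counter() - t0
        bundle = self._fit_head(cnn, mats_cal, y_cal,
                                meta_cal["sample_id"].to_numpy(), seed)

        # validation set 1: four-direction means; set 2: per-direction means
        v1 = four_dir[(part.propagate(split, four_dir) == "val").to_numpy()]
        v2 = per_dir[(part.propagate(split, per_dir) == "val").to_numpy()]
        mats_v1, meta_v1 = pp.matrices_from_table(v1)
        mats_v2, meta_v2 = pp.matrices_from_table(v2)
        for meta in (meta_v1, meta_v2):
            ev.audit_no_leakage(meta_cal["sample_id"], meta["sample_id"])

        pred_cal = bundle.predict(mats_cal)
        pred_v1 = bundle.predict(mats_v1)
        pred_v2, head_s, feat_s = ev.timed_predict(bundle, mats_v2)
        y_v1 = encode_labels(meta_v1["class"])
        y_v2 = encode_labels(meta_v2["class"])

        cv_mean, cv_folds = None, ()
        if opts.cv_folds:
            cv_mean, cv_folds = self._cross_validate(mats_cal, y_cal,
                                                     meta_cal, seed)

        report = ev.EvaluationReport(
            scheme=self.scheme, kernel_size=self.kernel_size, head=self.head,
            calibration_accuracy=ev.accuracy(pred_cal, y_cal),
            validation1_accuracy=ev.accuracy(pred_v1, y_v1),
            validation2_accuracy=ev.accuracy(pred_v2, y_v2),
            cross_validation_accuracy=cv_mean, cv_fold_accuracies=cv_folds,
            confusion_validation2=ev.confusion(pred_v2, y_v2),
            head_predict_seconds=head_s, feature_extract_seconds=feat_s)
        return AdulterationResults(model=self, bundle=bundle, split=split,
                                   report=report, seed=seed,
                                   train_seconds=train_seconds)

    def _fit_head(self, cnn, mats_cal, y_cal, cal_ids, seed) -> PipelineBundle:
        opts = self.options
        if self.head == "softmax":
            return PipelineBundle(cnn, "softmax")
        feats = cnn.extract_features(mats_cal)
        if self.head == "elm":
            L = opts.elm_neurons
            if opts.elm_search:
                L = self._search_neurons(feats, y_cal, cal_ids, seed)
            model = cls.elm_fit(feats, nn.one_hot(y_cal), L, seed=seed)
            return PipelineBundle(cnn, "elm", model)
        ga = opts.ga if opts.ga is not None else cls.GAConfig(seed=seed)
        model, _ = cls.svm_fit_ga(feats, y_cal, ga)
        return PipelineBundle(cnn, "svm", model)

    def _search_neurons(self, feats, y, sample_ids, seed):
        """Hold out a grouped fraction of calibration samples for the
        ELM neuron-grid search, then return the winning size."""
        ids = np.unique(sample_ids)
        rng = np.random.default_rng(seed)
        held = set(rng.choice(ids, max(1, int(len(ids) *
                   self.options.elm_holdout_fraction)), replace=False))
        mask = np.array([s in held for s in sample_ids])
        if mask.all() or not mask.any():
            return self.options.elm_neurons
        best_L, _, _ = cls.elm_neuron_search(feats[~mask], y[~mask],
                                             feats[mask], y[mask], seed=seed)
        return best_L

    def _cross_validate(self, mats_cal, y_cal, meta_cal, seed):
        opts = self.options
        epochs = opts.cv_epochs or opts.epochs

        def fit_predict(train_m, train_y, test_m):
            spec = nn.CNNSpec(input_size=train_m.shape[1],
                              kernel_size=self.kernel_size,
                              filter_counts=opts.filter_counts,
                              fc_hidden=opts.fc_hidden, epochs=epochs,
                              batch_size=opts.batch_size, seed=seed)
            cnn = nn.build(spec).train(train_m, nn.one_hot(train_y))
            b = self._fit_head(cnn, train_m, train_y,
                               np.arange(len(train_y)).astype(str), seed)
            return b.predict(test_m)

        return ev.cross_validate(fit_predict, mats_cal, y_cal,
                                 meta_cal["sample_id"].to_numpy(),
                                 k=opts.cv_folds, seed=seed)


@dataclass
class AdulterationResults:
    """Fit outcome: trained bundle, split, scores and diagnostics."""

    model: AdulterationClassifier
    bundle: PipelineBundle
    split: part.SplitResult
    report: ev.EvaluationReport
    seed: int
    train_seconds: float

    def predict(self, matrices: np.ndarray) -> np.ndarray:
        return self.bundle.predict(matrices)

    def summary(self) -> str:
        r = self.report
        lines = [
            "Minced-mutton adulteration classification",
            "=" * 57,
            f"scheme:              {r.scheme}",
            f"kernel size:         {r.kernel_size} x {r.kernel_size}",
            f"classifier head:     {r.head}",
            f"calibration samples: {len(self.split.calibration_ids)}",
            f"validation samples:  {len(self.split.validation_ids)}",
            f"CNN training time:   {self.train_seconds:.1f} s",
            "-" * 57,
            f"calibration accuracy:      {r.calibration_accuracy:8.4f}",
            f"validation set 1 accuracy: {r.validation1_accuracy:8.4f}",
            f"validation set 2 accuracy: {r.validation2_accuracy:8.4f}",
        ]
        if r.cross_validation_accuracy is not None:
            lines.append(f"cross-validation accuracy: "
                         f"{r.cross_validation_accuracy:8.4f}")
        lines += [
            f"head prediction time:      {r.head_predict_seconds:8.4f} s",
            f"feature extraction time:   {r.feature_extract_seconds:8.4f} s",
            "=" * 57,
        ]
        return "\n".join(lines)


def run_experiment(data: pd.DataFrame, schemes=SCHEMES, heads=("softmax",),
                   kernel_size: int = 7, seed: int = 0,
                   options: FitOptions | None = None,
                   n_calibration: int | None = None):
    """Fit one model per (scheme, head) pair and return the comparison.

    Returns ``(list of AdulterationResults, comparison DataFrame)``; the
    comparison is sorted best-first and carries per-head maximum
    inter-scheme accuracy differences in ``df.attrs``.
    """
    results = []
    for scheme in schemes:
        for head in heads:
            m = AdulterationClassifier(data, scheme=scheme,
                                       kernel_size=kernel_size, head=head,
                                       n_calibration=n_calibration,
                                       options=options)
            results.append(m.fit(seed=seed))
    table = ev.compare_models([r.report for r in results])
    return results, table
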