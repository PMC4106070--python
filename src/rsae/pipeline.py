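"""End-to-end experiments: split, band selection, features, pretraining,
fine-tuning, and segment-level sensitivity/specificity with multi-trial
aggregation.

One experiment fixes the dataset and the train/test split, then repeats
training ``n_trials`` times varying only the network initialization, and
reports mean +/- standard deviation per metric — sensitivity is the fraction
of true seizure segments detected, specificity the fraction of nonseizure
segments correctly classified.  Band selection and feature scaling are
fitted strictly on the training split.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

from rsae import autoencoder as ae
from rsae import spectral
from rsae.io import SEIZURE, Segment, split_train_test
from rsae.spectral import ALPHA, BETA, THETA, Band, FeatureScaler, WelchParams
from rsae.synth import SynthConfig, make_labeled_dataset


@dataclass
class DetectionMetrics:
    """Single-trial segment-level detection quality, both in [0, 1]."""

    sensitivity: float
    specificity: float


def sensitivity_specificity(predicted: np.ndarray, truth: np.ndarray) -> DetectionMetrics:
    """TP/(TP+FN) and TN/(TN+FP) with 1 = seizure, 0 = nonseizure."""
    predicted = np.asarray(predicted, dtype=int)
    truth = np.asarray(truth, dtype=int)
    if predicted.shape != truth.shape:
        raise ValueError("predicted and truth must have equal length")
    pos = truth == 1
    if not pos.any() or pos.all():
        raise ValueError("truth must contain both classes")
    sens = float(np.mean(predicted[pos] == 1))
    spec = float(np.mean(predicted[~pos] == 0))
    return DetectionMetrics(sensitivity=sens, specificity=spec)


@dataclass
class ExperimentConfig:
    """Everything one experiment needs.

    ``synth`` describes the data source when ``segments`` are not supplied
    directly.  ``layer_sizes`` defaults to [N^2, 50, q] with q = 10; the
    first entry must equal the squared channel count.  ``ae`` carries the
    autoencoder loss and regularization settings shared by every stage.
    """

    synth: SynthConfig = field(default_factory=SynthConfig)
    n_seizure: int = 1000
    n_nonseizure: int = 4000
    window_s: float = 5.0
    n_train_per_class: int = 750
    candidate_bands: tuple[Band, ...] = (THETA, ALPHA, BETA)
    welch: WelchParams = field(default_factory=WelchParams)
    csd_mode: Literal["magnitude", "real"] = "magnitude"
    hidden_units: int = 50
    q: int = 10
    ae: ae.AEConfig = field(default_factory=ae.AEConfig)
    finetune_max_iter: int = 400
    n_trials: int = 10
    seed: int = 0

    @property
    def layer_sizes(self) -> list[int]:
        return [self.synth.n_channels ** 2, self.hidden_units, self.q]


@dataclass
class PreparedData:
    """Split, band and scaled features — everything that is fixed across
    the trials of one experiment."""

    band: Band
    scaler: FeatureScaler
    train_X: np.ndarray
    train_y: np.ndarray
    test_X: np.ndarray
    test_y: np.ndarray


def prepare_experiment(config: ExperimentConfig,
                       segments: Sequence[Segment] | None = None) -> PreparedData:
    """Generate (or accept) segments, split, select the band on the training
    split, extract cross-power features and fit the scaler on training only."""
    if segments is None:
        segments = make_labeled_dataset(config.synth, config.n_seizure,
                                        config.n_nonseizure, config.window_s)
    fs = config.synth.fs
    train, test = split_train_test(segments, config.n_train_per_class, seed=config.seed)
    band = spectral.select_band(train, config.candidate_bands, fs, config.welch,
                                config.csd_mode)
    train_X, train_y = spectral.segment_features(train, band, fs, config.welch, config.csd_mode)
    test_X, test_y = spectral.segment_features(test, band, fs, config.welch, config.csd_mode)
    scaler = FeatureScaler.fit(train_X)
    return PreparedData(band=band, scaler=scaler,
                        train_X=scaler.transform(train_X), train_y=train_y,
                        test_X=scaler.transform(test_X), test_y=test_y)


@dataclass
class TrialResult:
    metrics: DetectionMetrics              # after fine-tuning
    metrics_preft: DetectionMetrics        # softmax on frozen pretrained stack
    fdr_top_pre: float                     # pooled FDR of top features, pre-FT
    fdr_top_post: float
    net: ae.StackedNet
    band: Band


def _pooled_feature_fdr(F: np.ndarray, y: np.ndarray) -> float:
    return spectral.fdr_score(F[y == 1].ravel(), F[y == 0].ravel())


def _trial_seed(master: int, trial: int) -> int:
    return int(np.random.SeedSequence([master, trial]).generate_state(1)[0] % 2**31)


def run_trial(config: ExperimentConfig, trial_seed: int,
              prepared: PreparedData | None = None) -> TrialResult:
    """One full training run: pretrain the stack, train the softmax head on
    frozen features (the before-fine-tuning model), then fine-tune jointly.
    Deterministic given config, trial_seed and prepared data."""
    if prepared is None:
        prepared = prepare_experiment(config)
    cfg = replace(config.ae, seed=trial_seed)
    net = ae.pretrain_stack(prepared.train_X, config.layer_sizes, cfg)
    net = ae.train_softmax(net, prepared.train_X, prepared.train_y, cfg)
    pre_metrics = sensitivity_specificity(ae.predict(net, prepared.test_X), prepared.test_y)
    fdr_pre = _pooled_feature_fdr(ae.extract_features(net, prepared.test_X), prepared.test_y)
    net = ae.fine_tune(net, prepared.train_X, prepared.train_y, cfg,
                       max_iter=config.finetune_max_iter)
    post_metrics = sensitivity_specificity(ae.predict(net, prepared.test_X), prepared.test_y)
    fdr_post = _pooled_feature_fdr(ae.extract_features(net, prepared.test_X), prepared.test_y)
    return TrialResult(metrics=post_metrics, metrics_preft=pre_metrics,
                       fdr_top_pre=fdr_pre, fdr_top_post=fdr_post,
                       net=net, band=prepared.band)


@dataclass
class ExperimentResult:
    """Per-trial metrics with mean +/- std aggregation."""

    trials: list[TrialResult]
    band: Band

    def _stats(self, values: list[float]) -> tuple[float, float]:
        arr = np.asarray(values)
        return float(arr.mean()), float(arr.std())

    @property
    def sensitivity(self) -> tuple[float, float]:
        return self._stats([t.metrics.sensitivity for t in self.trials])

    @property
    def specificity(self) -> tuple[float, float]:
        return self._stats([t.metrics.specificity for t in self.trials])

    @property
    def sensitivity_preft(self) -> tuple[float, float]:
        return self._stats([t.metrics_preft.sensitivity for t in self.trials])

    @property
    def specificity_preft(self) -> tuple[float, float]:
        return self._stats([t.metrics_preft.specificity for t in self.trials])

    def summary(self) -> str:
        lines = [f"selected band: {self.band.name} ({self.band.lb:g}-{self.band.ub:g} Hz)",
                 f"trials: {len(self.trials)}"]
        for name, (m, s) in (("sensitivity", self.sensitivity),
                             ("specificity", self.specificity),
                             ("sensitivity (pre-FT)", self.sensitivity_preft),
                             ("specificity (pre-FT)", self.specificity_preft)):
            lines.append(f"{name}: {format_pm(m, s)}")
        return "\n".join(lines)


def format_pm(mean: float, std: float) -> str:
    """Render mean +/- std the way detection tables print it,
    e.g. ``0.97 ± 1.3 × 10⁻²``."""
    if std == 0:
        return f"{mean:.2f} ± 0"
    exp = int(np.floor(np.log10(abs(std))))
    mant = std / 10 ** exp
    sup = str(exp).translate(str.maketrans("-0123456789", "⁻⁰¹²³⁴⁵⁶⁷⁸⁹"))
    return f"{mean:.2f} ± {mant:.1f} × 10{sup}"


def run_experiment(config: ExperimentConfig,
                   segments: Sequence[Segment] | None = None,
                   prepared: PreparedData | None = None) -> ExperimentResult:
    """Fixed dataset and split; ``n_trials`` training runs differing only in
    initialization seeds derived from the master seed."""
    if config.n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if prepared is None:
        prepared = prepare_experiment(config, segments)
    trials = [run_trial(config, _trial_seed(config.seed, t), prepared)
              for t in range(config.n_trials)]
    return ExperimentResult(trials=trials, band=prepared.band)


def compare_losses(config: ExperimentConfig,
                   segments: Sequence[Segment] | None = None,
                   prepared: PreparedData | None = None,
                   ) -> dict[str, ExperimentResult]:
    """Paired R-SAE vs S-SAE comparison: identical dataset, split, band,
    scaler and per-trial initialization seeds; only the reconstruction loss
    differs."""
    if prepared is None:
        prepared = prepare_experiment(config, segments)
    out: dict[str, ExperimentResult] = {}
    for loss in ("mcc", "mse"):
        cfg = replace(config, ae=replace(config.ae, loss_type=loss))
        out[loss] = run_experiment(cfg, prepared=prepared)
    return out


def sweep(config: ExperimentConfig, parameter: Literal["q", "sigma"],
          values: Sequence[float], segments: Sequence[Segment] | None = None,
          ) -> list[dict]:
    """One experiment per parameter value, all else fixed.  Returns tidy rows
    with before- and after-fine-tuning metrics."""
    if parameter not in ("q", "sigma"):
        raise ValueError("parameter must be 'q' or 'sigma'")
    prepared = prepare_experiment(config, segments)
    rows: list[dict] = []
    for v in values:
        if parameter == "q":
            cfg = replace(config, q=int(v))
        else:
            cfg = replace(config, ae=replace(config.ae, sigma=float(v)))
        res = run_experiment(cfg, prepared=prepared)
        rows.append({
            parameter: v,
            "sensitivity_mean": res.sensitivity[0], "sensitivity_std": res.sensitivity[1],
            "specificity_mean": res.specificity[0], "specificity_std": res.specificity[1],
            "sensitivity_preft_mean": res.sensitivity_preft[0],
            "sensitivity_preft_std": res.sensitivity_preft[1],
            "specificity_preft_mean": res.specificity_preft[0],
            "specificity_preft_std": res.specificity_preft[1],
        })
    return rows
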