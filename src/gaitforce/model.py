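"""Model / Results interface tying the pipeline together.

:class:`MuscleForceModel` is constructed from supervised pairs (feature
sequences and reference muscle-force traces), owns the normalizer fitted
on its training data, and ``fit()`` returns a
:class:`MuscleForceResults` carrying the trained network, loss history
and evaluation helpers — the same model-object idiom as statsmodels:

    model = MuscleForceModel.from_dataset(dataset, spec=ModelSpec("cnn_lstm"))
    res = model.fit(TrainConfig(epochs=60, seed=0))
    forces = res.predict(features)      # newtons, (T, 4)
    print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from gaitforce.features import (
    FeatureSequence,
    Normalizer,
    assemble_features,
    fit_normalizer,
    normalize,
    scale_forces,
    unscale_forces,
)
from gaitforce.gait import GaitDataset
from gaitforce.musculoskeletal import (
    TARGET_MUSCLES,
    MuscleForceTrace,
    reference_forces,
)
from gaitforce.nn.network import (
    ModelSpec,
    Network,
    TrainConfig,
    build_model,
    predict as _nn_predict,
    train as _nn_train,
)


def supervised_pairs(dataset: GaitDataset, split: str,
                     muscles: list | None = None):
    """(features, reference forces) for every cycle in a dataset split.

    Features come from the sensor-observed kinematics; reference forces
    from the clean truth kinematics, as in a lab where the optical
    system rather than the IMUs drives the musculoskeletal analysis.
    """
    feats, forces = [], []
    for lc in dataset.labelled(split):
        subject = dataset.subject(lc.cycle.subject_id)
        feats.append(assemble_features(lc.cycle, subject))
        forces.append(reference_forces(lc.clean, subject, muscles))
    return feats, forces


class MuscleForceModel:
    """A muscle-force estimator specified by architecture and data.

    Parameters
    ----------
    train_features, train_forces
        Supervised training pairs (unnormalized features, forces in N).
    spec
        Network architecture (``cnn``, ``lstm`` or ``cnn_lstm``).
    val_features, val_forces
        Optional held-out pairs used for early stopping.
    normalizer
        Pre-fitted normalizer; by default fitted on the training pairs.
    """

    def __init__(self, train_features: list, train_forces: list,
                 spec: ModelSpec | None = None,
                 val_features: list | None = None,
                 val_forces: list | None = None,
                 normalizer: Normalizer | None = None) -> None:
        if len(train_features) != len(train_forces) or not train_features:
            raise ValueError("training features/forces must be nonempty "
                             "and the same length")
        self.spec = spec or ModelSpec()
        self.train_features = train_features
        self.train_forces = train_forces
        self.val_features = val_features
        self.val_forces = val_forces
        self.normalizer = normalizer or fit_normalizer(train_features,
                                                       train_forces)
        self.n_timesteps = train_features[0].values.shape[0]

    @classmethod
    def from_dataset(cls, dataset: GaitDataset,
                     spec: ModelSpec | None = None,
                     muscles: list | None = None,
                     val_split: str = "validation") -> "MuscleForceModel":
        """Build from a synthetic dataset's train/validation splits."""
        tf, tr = supervised_pairs(dataset, "train", muscles)
        vf, vr = supervised_pairs(dataset, val_split, muscles)
        return cls(tf, tr, spec=spec,
                   val_features=vf or None, val_forces=vr or None)

    def _arrays(self, features: list, forces: list):
        X = np.stack([normalize(f, self.normalizer).values
                      for f in features])
        Y = np.stack([scale_forces(tr, self.normalizer) for tr in forces])
        return X, Y

    def fit(self, cfg: TrainConfig | None = None) -> "MuscleForceResults":
        cfg = cfg or TrainConfig()
        network = build_model(self.spec, self.n_timesteps,
                              self.train_features[0].values.shape[1],
                              seed=cfg.seed)
        train_data = self._arrays(self.train_features, self.train_forces)
        val_data = None
        if self.val_features:
            val_data = self._arrays(self.val_features, self.val_forces)
        history = _nn_train(network, train_data, val_data, cfg)
        return MuscleForceResults(model=self, network=network, cfg=cfg,
                                  history=history)


@dataclass
class MuscleForceResults:
    """Fitted estimator: trained network, history and prediction."""

    model: MuscleForceModel
    network: Network
    cfg: TrainConfig
    history: dict = field(default_factory=dict)

    @property
    def spec(self) -> ModelSpec:
        return self.model.spec

    @property
    def normalizer(self) -> Normalizer:
        return self.model.normalizer

    @property
    def epochs_run(self) -> int:
        return len(self.history.get("train_mae", []))

    def predict(self, features: FeatureSequence) -> np.ndarray:
        """Estimated forces in newtons, shape (T, 4), clipped at 0."""
        x = normalize(features, self.normalizer).values
        scaled = _nn_predict(self.network, x)
        return unscale_forces(scaled, self.normalizer)

    def predict_trace(self, features: FeatureSequence) -> MuscleForceTrace:
        return MuscleForceTrace(forces=self.predict(features),
                                subject_id=features.subject_id,
                                speed=features.speed)

    def evaluate(self, features: list, forces: list) -> dict:
        """Per-muscle Pearson r and RMSE%, averaged across cycles."""
        from gaitforce.evaluation import metrics_over_cycles
        preds = [self.predict(f) for f in features]
        refs = [tr.forces for tr in forces]
        return metrics_over_cycles(refs, preds)

    def plot_prediction(self, features: FeatureSequence,
                        reference: MuscleForceTrace | None = None,
                        fig=None):
        """Plot estimated (and optionally reference) muscle forces.

        One panel per muscle over the gait cycle.  Requires matplotlib
        (the ``plots`` extra).  Returns the figure.
        """
        import matplotlib.pyplot as plt

        pred = self.predict(features)
        if fig is None:
            fig, axes = plt.subplots(2, 2, figsize=(9, 6), sharex=True)
        else:
            axes = np.array(fig.subplots(2, 2, sharex=True))
        pct = np.linspace(0, 100, pred.shape[0])
        for ax, mi in zip(axes.ravel(), range(4)):
            ax.plot(pct, pred[:, mi], label="estimated", color="C3")
            if reference is not None:
                ax.plot(pct, reference.forces[:, mi], label="reference",
                        color="C2")
            ax.set_title(TARGET_MUSCLES[mi])
            ax.set_ylabel("force (N)")
        for ax in axes.ravel()[2:]:
            ax.set_xlabel("gait cycle (%)")
        axes.ravel()[0].legend(loc="upper right", fontsize=8)
        fig.suptitle(f"{self.spec.kind} muscle-force estimate")
        fig.tight_layout()
        return fig

    def summary(self) -> str:
        """Text summary in the spirit of statsmodels results."""
        lines = [
            "Muscle-Force Estimation Results",
            "=" * 46,
            f"{'Architecture:':<24}{self.spec.kind}",
            f"{'Trainable parameters:':<24}{self.network.n_params}",
            f"{'Training sequences:':<24}{len(self.model.train_features)}",
            f"{'Sequence length:':<24}{self.model.n_timesteps}",
            f"{'Epochs run:':<24}{self.epochs_run}",
            f"{'Final train MAE:':<24}"
            f"{self.history['train_mae'][-1]:.4f} (normalized)",
        ]
        if self.history.get("val_mae"):
            best = min(self.history["val_mae"])
            lines.append(f"{'Best validation MAE:':<24}{best:.4f} "
                         "(normalized)")
        if self.model.val_features:
            met = self.evaluate(self.model.val_features,
                                self.model.val_forces)
            lines.append("-" * 46)
            lines.append(f"{'Muscle':<10}{'r':>10}{'RMSE%':>12}")
            for m in TARGET_MUSCLES:
                lines.append(f"{m:<10}{met[m]['r']:>10.4f}"
                             f"{met[m]['rmse_percent']:>12.2f}")
            avg_r = np.mean([met[m]["r"] for m in TARGET_MUSCLES])
            avg_e = np.mean([met[m]["rmse_percent"]
                             for m in TARGET_MUSCLES])
            lines.append(f"{'Average':<10}{avg_r:>10.4f}{avg_e:>12.2f}")
        lines.append("=" * 46)
        return "\n".join(lines)
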