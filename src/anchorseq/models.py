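"""The black-box model contract and prediction-based dataset splitting.

The pipeline is model-agnostic: anything exposing a batch ``predict``
over :class:`~anchorseq.samples.SequenceSample` lists can be explained.
Model-specific encodings (BLOSUM, SMILES, physicochemical factors, ...)
are the adapter's responsibility behind this contract.  Probabilistic
adapters should threshold at 0.5 unless they document their own decision
rule; the pipeline only ever sees the two class labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol, Sequence, runtime_checkable

import pandas as pd

from .samples import ContractViolation, SequenceSample, check_frame

#: the closed label set
BINDING = "binding"
NON_BINDING = "non-binding"
CLASS_LABELS = (BINDING, NON_BINDING)


@runtime_checkable
class BlackBoxModel(Protocol):
    """Batch classifier contract: one label per sample, order-preserving,
    deterministic for a fixed input batch."""

    def predict(self, samples: Sequence[SequenceSample]) -> list[str]:
        ...


@dataclass(frozen=True)
class ConstantModel:
    """Trivial adapter predicting one class for every sample."""

    label: str = BINDING
    metadata: str = "constant model"

    def predict(self, samples: Sequence[SequenceSample]) -> list[str]:
        return [self.label] * len(samples)


@dataclass
class PredictionSplit:
    """Binding / non-binding partition of a dataset under a model."""

    binding: list[str]
    non_binding: list[str]
    label_of: dict[str, str]

    def ids_of(self, split: str) -> list[str]:
        if split == BINDING:
            return self.binding
        if split == NON_BINDING:
            return self.non_binding
        raise ContractViolation(f"unknown split {split!r}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"id": list(self.label_of), "predicted_class": list(self.label_of.values())}
        )

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path: str | Path) -> "PredictionSplit":
        df = pd.read_csv(path, sep="\t", dtype=str)
        labels = dict(zip(df["id"], df["predicted_class"]))
        return split_by_prediction_ids(list(labels), [labels[i] for i in labels])


def predict_labels(model: BlackBoxModel, samples: Sequence[SequenceSample],
                   frame_length: int | None = None) -> list[str]:
    """Run the model's batch predict with contract checks."""
    if not samples:
        return []
    check_frame(samples, frame_length)
    labels = list(model.predict(samples))
    if len(labels) != len(samples):
        raise ContractViolation(
            f"model returned {len(labels)} labels for {len(samples)} samples")
    for sample, label in zip(samples, labels):
        if label not in CLASS_LABELS:
            raise ContractViolation(
                f"model returned unknown label {label!r} for sample {sample.id!r}")
    return labels


def split_by_prediction(samples: Sequence[SequenceSample],
                        labels: Sequence[str]) -> PredictionSplit:
    """Partition samples into binding / non-binding by predicted label."""
    if len(samples) != len(labels):
        raise ContractViolation(
            f"{len(samples)} samples but {len(labels)} labels")
    return split_by_prediction_ids([s.id for s in samples], labels)


def split_by_prediction_ids(ids: Sequence[str], labels: Sequence[str]) -> PredictionSplit:
    binding, non_binding, label_of = [], [], {}
    for sid, label in zip(ids, labels):
        if label == BINDING:
            binding.append(sid)
        elif label == NON_BINDING:
            non_binding.append(sid)
        else:
            raise ContractViolation(f"unknown class label {label!r}")
        label_of[sid] = label
    return PredictionSplit(binding=binding, non_binding=non_binding, label_of=label_of)
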