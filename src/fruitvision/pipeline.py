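"""End-to-end orchestration: segment, describe, reduce, train, evaluate.

The pipeline mirrors the recognition system's flowchart: images are
segmented by split-and-merge, summarized by the 79-dimensional hybrid
descriptor, standardized and reduced by PCA at a 95% energy threshold,
and classified by a bank of kernel SVMs evaluated with stratified K-fold
cross validation.  Every report embeds the full configuration and all
seeds so runs are reproducible.
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from fruitvision import evaluation, mcsvm, synthetic
from fruitvision.descriptors import (
    FEATURE_NAMES,
    DescriptorConfig,
    extract_features,
)
from fruitvision.segmentation import (
    SegmentationConfig,
    SegmentationError,
    read_mask,
    read_rgb,
    split_and_merge,
)


class PipelineError(RuntimeError):
    """A stage failure annotated with the stage and sample that caused it."""


@dataclass
class PipelineConfig:
    """Complete configuration of one pipeline run (echoed into reports)."""

    # segmentation
    split_tolerance: float = 20.0
    merge_tolerance: float = 10.0
    min_size: int = 4
    connectivity: int = 4
    use_groundtruth_masks: bool = False
    # descriptors
    bins_per_channel: int = 4
    displacement: tuple[int, int] = (1, 1)
    texture_levels: int = 64
    # reduction
    energy: float = 0.95
    # classifier
    scheme: str = "MWV"
    kernel: str = "GRB"
    degree: int = 2
    gamma: float = 0.0          # 0 means the data-driven default scale
    C_reg: float = 1.0
    # evaluation
    K: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.scheme.upper() not in mcsvm.SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.kernel.upper() not in mcsvm.KERNEL_NAMES:
            raise ValueError(f"unknown kernel {self.kernel!r}")
        if not 0 < self.energy <= 1:
            raise ValueError("energy must lie in (0, 1]")
        if self.K < 2:
            raise ValueError("K must be >= 2")

    def segmentation_config(self) -> SegmentationConfig:
        return SegmentationConfig(
            split_tolerance=self.split_tolerance,
            merge_tolerance=self.merge_tolerance,
            min_size=self.min_size,
            connectivity=self.connectivity,
        )

    def descriptor_config(self) -> DescriptorConfig:
        return DescriptorConfig(
            bins_per_channel=self.bins_per_channel,
            displacement=tuple(self.displacement),
            texture_levels=self.texture_levels,
        )

    def kernel_spec(self, X: np.ndarray | None = None) -> mcsvm.KernelSpec | None:
        """Resolve the configured kernel; GRB with gamma=0 defers to the
        data-driven per-fold default (signalled by returning None)."""
        name = self.kernel.upper()
        if name == "GRB":
            if self.gamma > 0:
                return mcsvm.KernelSpec("GRB", gamma=self.gamma)
            if X is not None:
                return mcsvm.KernelSpec("GRB", gamma=mcsvm.default_gamma(X))
            return None
        if name in ("HPOL", "IPOL"):
            return mcsvm.KernelSpec(name, degree=self.degree)
        return mcsvm.KernelSpec(name)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "displacement" in data:
            data["displacement"] = tuple(data["displacement"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["displacement"] = list(d["displacement"])
        return d


# ---------------------------------------------------------------------------
# feature table I/O


def write_features_csv(path, X: np.ndarray, labels: np.ndarray | None = None) -> None:
    """79-column feature CSV with a fixed header (plus optional label column)."""
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    header = list(FEATURE_NAMES) + (["label"] if labels is not None else [])
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for i, row in enumerate(X):
            out = [repr(float(v)) for v in row]
            if labels is not None:
                out.append(int(labels[i]))
            writer.writerow(out)


def read_features_csv(path) -> tuple[np.ndarray, np.ndarray | None]:
    with open(path) as fh:
        reader = csv.reader(fh)
        header = next(reader)
        has_label = header and header[-1] == "label"
        feat_cols = len(header) - (1 if has_label else 0)
        if header[:feat_cols] != FEATURE_NAMES[:feat_cols]:
            raise ValueError("feature CSV header does not match the fixed layout")
        X, y = [], []
        for row in reader:
            X.append([float(v) for v in row[:feat_cols]])
            if has_label:
                y.append(int(row[-1]))
    return np.array(X), (np.array(y, dtype=np.int64) if has_label else None)


# ---------------------------------------------------------------------------
# dataset loading and feature extraction


@dataclass
class LoadedDataset:
    images: list[np.ndarray]
    labels: np.ndarray
    masks: list[np.ndarray | None] = field(default_factory=list)


def load_manifest(path) -> LoadedDataset:
    """Read a manifest CSV of image path, integer label, optional mask path."""
    base = Path(path).parent
    images, labels, masks = [], [], []
    with open(path) as fh:
        for row in csv.DictReader(fh):
            p = Path(row["path"])
            images.append(read_rgb(p if p.is_absolute() else base / p))
            labels.append(int(row["label"]))
            mp = row.get("mask_path") or ""
            if mp:
                mpp = Path(mp)
                masks.append(read_mask(mpp if mpp.is_absolute() else base / mpp))
            else:
                masks.append(None)
    return LoadedDataset(
        images=images, labels=np.array(labels, dtype=np.int64), masks=masks
    )


def compute_features(
    images: list[np.ndarray],
    masks: list[np.ndarray | None] | None,
    config: PipelineConfig,
) -> np.ndarray:
    """Segment (unless ground-truth masks are used) and describe each image."""
    seg_cfg = config.segmentation_config()
    desc_cfg = config.descriptor_config()
    rows = []
    for idx, image in enumerate(images):
        try:
            if config.use_groundtruth_masks and masks is not None and masks[idx] is not None:
                fg = masks[idx]
            else:
                fg = split_and_merge(image, seg_cfg).foreground
            rows.append(extract_features(image, fg, desc_cfg))
        except (SegmentationError, ValueError) as exc:
            raise PipelineError(f"feature stage failed on sample {idx}: {exc}") from exc
    return np.array(rows)


# ---------------------------------------------------------------------------
# reports


def run_pipeline(
    config: PipelineConfig,
    dataset: LoadedDataset | synthetic.SyntheticDataset,
) -> dict:
    """Execute segment -> describe -> reduce -> train -> cross-validate.

    Returns a JSON-serializable report: per-fold and mean accuracy, the
    pooled confusion matrix (rows = predicted, columns = target),
    per-class rates, the PCA dimensions selected per fold, and a verbatim
    echo of the configuration.
    """
    labels = np.asarray(dataset.labels, dtype=np.int64)
    masks = list(dataset.masks) if dataset.masks else None
    X = compute_features(list(dataset.images), masks, config)
    plan = evaluation.stratified_kfold(labels, K=config.K, seed=config.seed)
    result = evaluation.cross_validate(
        X,
        labels,
        plan,
        scheme=config.scheme.upper(),
        kernel=config.kernel_spec(),
        C_reg=config.C_reg,
        energy=config.energy,
    )
    rates, overall = evaluation.class_accuracy(result.confusion, decimals=1)
    return {
        "config": config.to_dict(),
        "n_samples": int(len(labels)),
        "n_features": int(X.shape[1]),
        "feature_layout": FEATURE_NAMES,
        "selected_k": result.selected_k,
        "fold_accuracies": result.fold_accuracies,
        "mean_accuracy": result.mean_accuracy,
        "confusion_matrix": result.confusion.counts.tolist(),
        "per_class_rates_pct": rates,
        "overall_accuracy": overall,
    }


def save_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)


def load_report(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def train_full(
    X: np.ndarray, labels: np.ndarray, config: PipelineConfig
) -> tuple:
    """Fit reduction + multiclass SVM on all provided data (for `predict`)."""
    from fruitvision import reduction as red_mod

    red = red_mod.fit_reduction(X, energy=config.energy)
    Z = red.transform(X)
    spec = config.kernel_spec(Z)
    model = mcsvm.train_multiclass(
        Z, labels, config.scheme.upper(), spec, config.C_reg
    )
    return red, model


# ---------------------------------------------------------------------------
# model bundle (reduction + classifier + feature layout) persistence


def save_model_bundle(path, red, model: mcsvm.MulticlassModel, config: PipelineConfig) -> None:
    """One versioned JSON file holding everything `predict` needs."""
    from fruitvision import reduction as red_mod

    payload = {
        "version": 1,
        "kind": "pipeline_model",
        "feature_layout": FEATURE_NAMES,
        "config": config.to_dict(),
        "reduction": red_mod.reduction_to_dict(red),
        "classifier": mcsvm.multiclass_to_dict(model),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model_bundle(path):
    from fruitvision import reduction as red_mod

    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("kind") != "pipeline_model":
        raise ValueError("not a pipeline model file")
    if payload["feature_layout"] != FEATURE_NAMES:
        raise ValueError("model was fitted under a different feature layout")
    red = red_mod.reduction_from_dict(payload["reduction"])
    model = mcsvm.multiclass_from_dict(payload["classifier"])
    config = PipelineConfig(
        **{**payload["config"], "displacement": tuple(payload["config"]["displacement"])}
    )
    return red, model, config
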