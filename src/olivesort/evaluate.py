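"""Train/test protocol: capped training, repeated random test draws.

The protocol mirrors how the hardware classifier was assessed on the
pitting machine: train a fresh network on at most 300 examples per class
(an empirical cap against overtraining), then run 10 repetitions, each
presenting 300 randomly drawn test pockets per class — 3000 presentations
per case in total — and report per-repetition error rates, their mean as
the total error, the confusion matrices and the number of committed
neurons.

Pockets that the pixel-area prefilter diverts (doubles, small parts) never
reach the network; they are tallied separately and excluded from network
scoring.  Uncertain outcomes are resolved by winner-takes-all and unknown
outcomes (no neuron fires) by the nearest prototype overall — the chip's
KNN fallback; either counts as an error only when the resolved category is
wrong.  Both outcomes keep dedicated confusion-matrix columns.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .labeler import SCHEMES, scheme_classes
from .preprocess import (
    DEFAULT_ROI,
    PocketImage,
    PrefilterConfig,
    ResolutionProfile,
    RoiSpec,
    crop_roi,
    prefilter,
    to_feature_vector,
)
from .rce import NetworkProfile, RceNetwork
from .synthetic import Sample

__all__ = [
    "ProtocolConfig",
    "ProtocolResult",
    "run_protocol",
    "confusion_matrix",
    "report",
    "parse_report",
    "resolution_sweep",
]

OUTCOME_COLUMNS = ("unknown", "uncertain")


@dataclass(frozen=True)
class ProtocolConfig:
    """Sizing and network choices for one protocol run."""

    scheme: str = "simple"
    network: str = "cm1k"
    resolution: tuple[int, int] = (16, 16)
    train_cap: int = 300  # max training examples per class
    reps: int = 10
    test_per_case: int = 300
    seed: int = 0
    roi: RoiSpec = DEFAULT_ROI
    prefilter: PrefilterConfig = field(default_factory=PrefilterConfig)
    epochs: int | None = None  # None: re-present the training set until stable

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if min(self.train_cap, self.reps, self.test_per_case) < 1:
            raise ValueError("train_cap, reps and test_per_case must be positive")
        # the 256-byte raster only fits the full-size chip profile
        self.resolution_profile()  # validates vector_len <= profile capacity

    def resolution_profile(self) -> ResolutionProfile:
        w, h = self.resolution
        return ResolutionProfile(out_w=w, out_h=h, network=self.network)

    def network_profile(self) -> NetworkProfile:
        # the chip accepts any vector up to its byte capacity; the working
        # vector length is the raster size
        chip = NetworkProfile.builtin(self.network)
        return NetworkProfile(
            name=chip.name,
            vector_len=self.resolution_profile().vector_len,
            max_neurons=chip.max_neurons,
            min_if=chip.min_if,
            max_if=chip.max_if,
        )


@dataclass
class ProtocolResult:
    """Per-repetition and aggregate outcome of one protocol run."""

    config: ProtocolConfig
    rep_errors: list[float]  # fraction in [0, 1], one per repetition
    committed_neurons: int
    confusions: list[pd.DataFrame]
    presented_per_case: int  # per class, summed over repetitions
    diverted: dict[str, int]  # prefilter tallies over the input dataset
    drew_with_replacement: bool

    @property
    def total_error(self) -> float:
        """Mean of the repetition error rates."""
        return float(np.mean(self.rep_errors))

    def to_dict(self) -> dict:
        return {
            "scheme": self.config.scheme,
            "network": self.config.network,
            "resolution": list(self.config.resolution),
            "rep_errors": [round(e, 10) for e in self.rep_errors],
            "total_error": round(self.total_error, 10),
            "committed_neurons": self.committed_neurons,
            "presented_per_case": self.presented_per_case,
            "diverted": dict(self.diverted),
            "drew_with_replacement": self.drew_with_replacement,
        }


def _features(samples: Sequence[Sample], cfg: ProtocolConfig):
    """Prefilter + vectorize every sample once; returns (kept, diverted)."""
    res = cfg.resolution_profile()
    kept: list[tuple[str, np.ndarray]] = []  # (class, vector)
    diverted: dict[str, int] = {"double": 0, "small_part": 0}
    for s in samples:
        roi = crop_roi(s.image, cfg.roi)
        verdict = prefilter(roi, cfg.prefilter).verdict
        if verdict != "pass":
            diverted[verdict] += 1
            continue
        kept.append((s.label, to_feature_vector(roi, res)))
    return kept, diverted


def run_protocol(dataset: Sequence[Sample], cfg: ProtocolConfig) -> ProtocolResult:
    """Run the capped-training / repeated-draw protocol on a labelled dataset.

    The per-class pools are shuffled once; the first ``train_cap`` samples
    train a fresh network, the remainder form the test pool from which each
    repetition draws ``test_per_case`` samples per class (with replacement,
    flagged, when the pool is smaller).
    """
    classes = scheme_classes(cfg.scheme)
    rng = np.random.default_rng(cfg.seed)

    kept, diverted = _features(dataset, cfg)
    by_class: dict[str, list[np.ndarray]] = {c: [] for c in classes}
    for label, vec in kept:
        if label not in by_class:
            raise ValueError(
                f"dataset label {label!r} is not a class of scheme {cfg.scheme!r}"
            )
        by_class[label].append(vec)
    for c in classes:
        if not by_class[c]:
            raise ValueError(f"class {c!r} absent from the dataset")

    train: list[tuple[np.ndarray, str]] = []
    test_pool: dict[str, list[np.ndarray]] = {}
    for c in classes:
        pool = by_class[c]
        order = rng.permutation(len(pool))
        n_train = min(cfg.train_cap, len(pool))
        train.extend((pool[i], c) for i in order[:n_train])
        # disjoint draw; when the whole pool trains, test falls back to it
        test_pool[c] = [pool[i] for i in order[n_train:]] or [pool[i] for i in order]

    net = RceNetwork(cfg.network_profile())
    train_order = rng.permutation(len(train))
    net.fit([train[i][0] for i in train_order],
            [train[i][1] for i in train_order], epochs=cfg.epochs)

    replacement = any(len(test_pool[c]) < cfg.test_per_case for c in classes)
    rep_errors: list[float] = []
    confusions: list[pd.DataFrame] = []
    for _rep in range(cfg.reps):
        truths: list[str] = []
        outcomes: list[str] = []
        errors = 0
        presented = 0
        for c in classes:
            pool = test_pool[c]
            idx = rng.choice(len(pool), size=cfg.test_per_case,
                             replace=len(pool) < cfg.test_per_case)
            for i in idx:
                rec = net.classify_rbf(pool[i])
                presented += 1
                truths.append(c)
                if rec.status == "unknown":
                    # nothing fired: fall back to the nearest prototype
                    # (the chip's KNN mode), still reported as unknown
                    outcomes.append("unknown")
                    if net.classify_knn(pool[i], 1).category != c:
                        errors += 1
                else:
                    outcomes.append(rec.status if rec.status == "uncertain"
                                    else rec.category)
                    if rec.category != c:  # winner-takes-all fallback
                        errors += 1
        rep_errors.append(errors / presented)
        confusions.append(confusion_matrix(outcomes, truths, classes))

    return ProtocolResult(
        config=cfg,
        rep_errors=rep_errors,
        committed_neurons=len(net),
        confusions=confusions,
        presented_per_case=cfg.reps * cfg.test_per_case,
        diverted=diverted,
        drew_with_replacement=replacement,
    )


def confusion_matrix(predictions: Sequence[str], truths: Sequence[str],
                     classes: Sequence[str]) -> pd.DataFrame:
    """Truth-by-prediction count table.

    Rows are true classes; columns are the scheme classes plus dedicated
    ``unknown`` and ``uncertain`` outcome columns, so row sums equal the
    per-class presented counts.
    """
    if len(predictions) != len(truths):
        raise ValueError("predictions and truths must have equal length")
    cols = list(classes) + list(OUTCOME_COLUMNS)
    mat = pd.DataFrame(0, index=list(classes), columns=cols, dtype=int)
    for p, t in zip(predictions, truths):
        if t not in mat.index:
            raise ValueError(f"truth label {t!r} outside the scheme classes")
        if p not in cols:
            raise ValueError(f"prediction {p!r} outside the scheme classes")
        mat.loc[t, p] += 1
    return mat


def report(result: ProtocolResult) -> tuple[str, dict]:
    """Human table (per-repetition rows, totals, neurons) + JSON-able twin."""
    buf = io.StringIO()
    cfg = result.config
    buf.write(
        f"Protocol: scheme={cfg.scheme} network={cfg.network} "
        f"resolution={cfg.resolution[0]}x{cfg.resolution[1]}\n"
    )
    buf.write(f"Committed neurons: {result.committed_neurons}\n")
    buf.write("Repeatability  Error\n")
    for i, e in enumerate(result.rep_errors, start=1):
        buf.write(f"{i:>13d}  {100 * e:.2f}%\n")
    buf.write(f"{'Totals':>13}  {100 * result.total_error:.2f}%\n")
    if result.diverted.get("double") or result.diverted.get("small_part"):
        buf.write(
            f"Prefilter diverted: {result.diverted['double']} double, "
            f"{result.diverted['small_part']} small_part\n"
        )
    return buf.getvalue(), result.to_dict()


def parse_report(data: dict | str) -> ProtocolResult:
    """Rebuild a ProtocolResult from the machine-readable report twin."""
    if isinstance(data, str):
        data = json.loads(data)
    cfg = ProtocolConfig(
        scheme=data["scheme"],
        network=data["network"],
        resolution=tuple(data["resolution"]),
    )
    classes = scheme_classes(cfg.scheme)
    return ProtocolResult(
        config=cfg,
        rep_errors=[float(e) for e in data["rep_errors"]],
        committed_neurons=int(data["committed_neurons"]),
        confusions=[confusion_matrix([], [], classes)
                    for _ in data["rep_errors"]],
        presented_per_case=int(data["presented_per_case"]),
        diverted={k: int(v) for k, v in data["diverted"].items()},
        drew_with_replacement=bool(data["drew_with_replacement"]),
    )


def resolution_sweep(
    make_dataset,
    resolutions: Sequence[tuple[int, int]] = ((16, 16), (11, 11), (10, 10)),
    seeds: Sequence[int] = tuple(range(10)),
    scheme: str = "intermediate",
    network: str = "cm1k",
    train_cap: int = 120,
    reps: int = 3,
    test_per_case: int = 120,
) -> pd.DataFrame:
    """Mean total error per raster resolution, averaged over protocol seeds.

    ``make_dataset(seed)`` must return a labelled dataset for the scheme.
    Feature vectors are re-extracted per resolution from the same images, so
    the comparison isolates the raster size.
    """
    rows = []
    for seed in seeds:
        dataset = make_dataset(seed)
        for res in resolutions:
            cfg = ProtocolConfig(
                scheme=scheme, network=network, resolution=tuple(res),
                train_cap=train_cap, reps=reps, test_per_case=test_per_case,
                seed=seed,
            )
            r = run_protocol(dataset, cfg)
            rows.append({
                "seed": seed,
                "resolution": f"{res[0]}x{res[1]}",
                "total_error": r.total_error,
                "committed_neurons": r.committed_neurons,
            })
    df = pd.DataFrame(rows)
    return (
        df.groupby("resolution", sort=False)
        .agg(mean_error=("total_error", "mean"),
             mean_neurons=("committed_neurons", "mean"))
        .reset_index()
    )
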