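"""Software emulation of a CM1K-style prototype neural network.

The network is a restricted-Coulomb-energy (RCE) classifier: each committed
neuron stores a prototype byte vector, a category, and an *active influence
field* (AIF) — a distance radius within which the neuron "fires".  Training
is incremental: presenting a labelled example shrinks the AIF of any
wrong-category neuron that fires on it, and commits a new neuron when no
same-category neuron fires.  Recognition offers two modes, matching the
hardware family this emulates:

* RBF mode — only firing neurons participate; the winner (smallest distance,
  ties by commitment order) takes all.  Disagreement among firing neurons is
  reported as an *uncertain* outcome; no firing neuron at all is *unknown*.
* KNN mode — the k nearest prototypes regardless of influence fields.

Distances are Manhattan (L1) over unsigned bytes, so every quantity in the
model is integer-exact and the whole machine is deterministic.

Two built-in capacity profiles mirror the commercial chips: ``cm1k``
(1024 neurons, 256-byte vectors) and ``curie`` (128 neurons, 128-byte
vectors).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "NetworkProfile",
    "Neuron",
    "Recognition",
    "KnnResult",
    "RceNetwork",
    "CapacityError",
    "VectorLengthError",
    "ModelFormatError",
    "distance",
    "save_model",
    "load_model",
]

DEFAULT_MIN_IF = 2
DEFAULT_MAX_IF = 16384


class CapacityError(RuntimeError):
    """Raised when learning would commit a neuron beyond ``max_neurons``."""


class VectorLengthError(ValueError):
    """Raised when a vector's length does not match the profile."""


class ModelFormatError(ValueError):
    """Raised when a model file cannot be parsed; names the offending field."""


@dataclass(frozen=True)
class NetworkProfile:
    """Capacity constants of one network variant.

    Parameters
    ----------
    name : str
        Profile label; ``"cm1k"`` and ``"curie"`` are the built-ins.
    vector_len : int
        Bytes per prototype (the chip's input-vector width).
    max_neurons : int
        Hard neuron capacity.
    min_if, max_if : int
        Floor and initial/ceiling value of the active influence field,
        in L1 distance units.
    """

    name: str
    vector_len: int
    max_neurons: int
    min_if: int = DEFAULT_MIN_IF
    max_if: int = DEFAULT_MAX_IF

    def __post_init__(self) -> None:
        if self.vector_len < 1:
            raise ValueError(f"vector_len must be >= 1, got {self.vector_len}")
        if self.max_neurons < 1:
            raise ValueError(f"max_neurons must be >= 1, got {self.max_neurons}")
        if not (0 < self.min_if <= self.max_if):
            raise ValueError(
                f"need 0 < min_if <= max_if, got min_if={self.min_if} max_if={self.max_if}"
            )

    @classmethod
    def builtin(cls, name: str, *, min_if: int = DEFAULT_MIN_IF,
                max_if: int = DEFAULT_MAX_IF) -> "NetworkProfile":
        try:
            vector_len, max_neurons = _BUILTIN_PROFILES[name]
        except KeyError:
            raise KeyError(
                f"unknown profile {name!r}; built-ins: {sorted(_BUILTIN_PROFILES)}"
            ) from None
        return cls(name, vector_len, max_neurons, min_if=min_if, max_if=max_if)


# chip family capacities: CM1K has 1024 neurons of 256 bytes; the Curie
# module is the diminished variant with 128 neurons of 128 bytes
_BUILTIN_PROFILES = {"cm1k": (256, 1024), "curie": (128, 128)}


@dataclass
class Neuron:
    """One committed prototype: byte vector, category, and influence field."""

    prototype: np.ndarray
    category: str
    aif: int
    commit_index: int


@dataclass(frozen=True)
class Recognition:
    """Outcome of an RBF-mode query.

    ``status`` is ``"identified"`` (all firing neurons agree),
    ``"uncertain"`` (firing neurons disagree; ``category`` is still the
    winner-takes-all choice), or ``"unknown"`` (nothing fired).
    ``firing`` lists ``(commit_index, category, distance)`` for every firing
    neuron, sorted by distance then commitment order.
    """

    status: str
    category: str | None
    distance: int
    firing: tuple[tuple[int, str, int], ...] = field(default_factory=tuple)

    @property
    def identified(self) -> bool:
        return self.status == "identified"


@dataclass(frozen=True)
class KnnResult:
    """Ranked KNN neighbours; ``truncated`` flags a k larger than the model."""

    neighbors: tuple[tuple[str, int], ...]
    truncated: bool = False

    @property
    def category(self) -> str | None:
        return self.neighbors[0][0] if self.neighbors else None


def _as_byte_vector(v: Sequence[int] | np.ndarray) -> np.ndarray:
    arr = np.asarray(v)
    if arr.ndim != 1:
        raise VectorLengthError(f"expected a 1-D byte vector, got shape {arr.shape}")
    if arr.size and (arr.min() < 0 or arr.max() > 255):
        raise ValueError("byte vector components must lie in [0, 255]")
    return arr.astype(np.int64)


def distance(a: Sequence[int] | np.ndarray, b: Sequence[int] | np.ndarray) -> int:
    """L1 (Manhattan) distance between two byte vectors of equal length."""
    av, bv = _as_byte_vector(a), _as_byte_vector(b)
    if av.shape != bv.shape:
        raise VectorLengthError(
            f"incompatible vectors: lengths {av.size} and {bv.size}"
        )
    return int(np.abs(av - bv).sum())


class RceNetwork:
    """Capacity-bounded collection of prototype neurons under one profile.

    The neuron store is kept as a dense ``(n, vector_len)`` int64 matrix plus
    parallel aif/category arrays so that every query is a single vectorised
    distance computation.
    """

    def __init__(self, profile: NetworkProfile):
        self.profile = profile
        self._protos = np.empty((0, profile.vector_len), dtype=np.int64)
        self._aifs: list[int] = []
        self._categories: list[str] = []

    # ------------------------------------------------------------------ basics

    def __len__(self) -> int:
        return len(self._categories)

    @property
    def neurons(self) -> list[Neuron]:
        return [
            Neuron(self._protos[i].astype(np.uint8), self._categories[i],
                   self._aifs[i], i)
            for i in range(len(self))
        ]

    @property
    def categories(self) -> list[str]:
        """Distinct categories in commitment order."""
        seen: dict[str, None] = {}
        for c in self._categories:
            seen.setdefault(c)
        return list(seen)

    def _check_vector(self, vector) -> np.ndarray:
        v = _as_byte_vector(vector)
        if v.size != self.profile.vector_len:
            raise VectorLengthError(
                f"vector length {v.size} != profile vector_len "
                f"{self.profile.vector_len}"
            )
        return v

    def _distances(self, v: np.ndarray) -> np.ndarray:
        if not len(self):
            return np.empty(0, dtype=np.int64)
        return np.abs(self._protos - v).sum(axis=1)

    # ---------------------------------------------------------------- learning

    def learn(self, vector, category: str) -> bool:
        """Present one labelled example; return True if a neuron was committed.

        Wrong-category neurons firing on the example have their AIF shrunk to
        the example's distance (floored at ``min_if``); a new neuron is
        committed iff no same-category neuron fires.  The new neuron's AIF is
        the distance to the nearest different-category neuron, clamped into
        ``[min_if, max_if]``.  Raises :class:`CapacityError`, leaving the
        model untouched, if the commit would exceed capacity.
        """
        p = self.profile
        v = self._check_vector(vector)
        d = self._distances(v)
        aifs = np.asarray(self._aifs, dtype=np.int64)
        cats = np.asarray(self._categories, dtype=object)
        firing = d < aifs
        same_cat_fires = bool(np.any(firing & (cats == category))) if len(self) else False

        commit = not same_cat_fires
        if commit and len(self) >= p.max_neurons:
            raise CapacityError(
                f"network full: {p.max_neurons} neurons committed "
                f"(profile {p.name!r}); cannot learn category {category!r}"
            )

        # shrink wrong-category firing neurons down to the example
        for i in np.flatnonzero(firing):
            if self._categories[i] != category:
                self._aifs[i] = max(p.min_if, int(d[i]))

        if commit:
            other = cats != category
            if len(self) and bool(other.any()):
                nearest_other = int(d[other].min())
            else:
                nearest_other = p.max_if
            aif = int(np.clip(nearest_other, p.min_if, p.max_if))
            self._protos = np.vstack([self._protos, v[None, :]])
            self._aifs.append(aif)
            self._categories.append(category)
        return commit

    def fit(self, vectors, categories, epochs: int | None = None,
            max_epochs: int = 64) -> int:
        """Train on a sequence of examples; return neurons committed.

        With ``epochs=None`` (default) the sequence is re-presented until a
        full pass changes nothing — no commit and no influence-field shrink.
        A single pass can leave a later-committed neuron of one category
        covering an earlier example of another (its own neuron may have been
        shrunk in between); at the stable point no wrong-category neuron
        fires on any training example, so re-presenting a trained example
        can never be *identified* with the wrong category.  Termination is
        guaranteed: fields only shrink and commits are capacity-bounded.
        """
        before = len(self)
        pairs = list(zip(vectors, categories, strict=True))
        n_passes = max_epochs if epochs is None else epochs
        for _ in range(n_passes):
            state = (len(self), sum(self._aifs))
            for v, c in pairs:
                self.learn(v, c)
            if epochs is None and (len(self), sum(self._aifs)) == state:
                break
        return len(self) - before

    # ------------------------------------------------------------- recognition

    def classify_rbf(self, vector) -> Recognition:
        """RBF recognition with the winner-takes-all decision rule."""
        v = self._check_vector(vector)
        d = self._distances(v)
        aifs = np.asarray(self._aifs, dtype=np.int64)
        idx = np.flatnonzero(d < aifs) if len(self) else np.empty(0, dtype=int)
        if idx.size == 0:
            return Recognition("unknown", None, 0)
        order = sorted(idx.tolist(), key=lambda i: (int(d[i]), i))
        firing = tuple((i, self._categories[i], int(d[i])) for i in order)
        winner = order[0]
        cats = {self._categories[i] for i in order}
        status = "identified" if len(cats) == 1 else "uncertain"
        return Recognition(status, self._categories[winner], int(d[winner]), firing)

    def classify_knn(self, vector, k: int) -> KnnResult:
        """The k nearest prototypes by L1 distance, influence fields ignored."""
        if k < 1:
            raise ValueError(f"k must be >= 1, got {k}")
        v = self._check_vector(vector)
        d = self._distances(v)
        truncated = k > len(self)
        kk = min(k, len(self))
        order = sorted(range(len(self)), key=lambda i: (int(d[i]), i))[:kk]
        return KnnResult(
            tuple((self._categories[i], int(d[i])) for i in order), truncated
        )

    # ------------------------------------------------------------ construction

    @classmethod
    def from_neurons(cls, profile: NetworkProfile,
                     neurons: Sequence[Neuron]) -> "RceNetwork":
        """Build a network directly from committed neurons (e.g. a loaded file)."""
        net = cls(profile)
        if len(neurons) > profile.max_neurons:
            raise CapacityError(
                f"{len(neurons)} neurons exceed profile capacity {profile.max_neurons}"
            )
        for n in sorted(neurons, key=lambda n: n.commit_index):
            v = net._check_vector(n.prototype)
            if not (profile.min_if <= n.aif <= profile.max_if):
                raise ValueError(
                    f"neuron {n.commit_index}: aif {n.aif} outside "
                    f"[{profile.min_if}, {profile.max_if}]"
                )
            net._protos = np.vstack([net._protos, v[None, :]])
            net._aifs.append(int(n.aif))
            net._categories.append(str(n.category))
        return net


# ---------------------------------------------------------------- persistence

_MODEL_FORMAT = "olivesort-rce-model"
_MODEL_VERSION = 1


def save_model(model: RceNetwork, path: str | Path) -> None:
    """Serialize a network to a self-describing JSON text file."""
    p = model.profile
    doc = {
        "format": _MODEL_FORMAT,
        "version": _MODEL_VERSION,
        "profile": {
            "name": p.name,
            "vector_len": p.vector_len,
            "max_neurons": p.max_neurons,
            "min_if": p.min_if,
            "max_if": p.max_if,
        },
        "neurons": [
            {
                "commit_index": n.commit_index,
                "category": n.category,
                "aif": n.aif,
                "prototype": n.prototype.astype(int).tolist(),
            }
            for n in model.neurons
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")


def _require(doc: dict, key: str, where: str):
    if key not in doc:
        raise ModelFormatError(f"model file: missing field {key!r} in {where}")
    return doc[key]


def load_model(path: str | Path) -> RceNetwork:
    """Load a network saved by :func:`save_model`."""
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise ModelFormatError(f"model file is not valid JSON: {e}") from e
    if not isinstance(doc, dict) or doc.get("format") != _MODEL_FORMAT:
        raise ModelFormatError("model file: missing or wrong 'format' field")
    prof_doc = _require(doc, "profile", "document")
    profile = NetworkProfile(
        name=str(_require(prof_doc, "name", "profile")),
        vector_len=int(_require(prof_doc, "vector_len", "profile")),
        max_neurons=int(_require(prof_doc, "max_neurons", "profile")),
        min_if=int(_require(prof_doc, "min_if", "profile")),
        max_if=int(_require(prof_doc, "max_if", "profile")),
    )
    neurons = []
    for i, nd in enumerate(_require(doc, "neurons", "document")):
        proto = np.asarray(_require(nd, "prototype", f"neuron {i}"), dtype=np.int64)
        neurons.append(
            Neuron(
                prototype=proto,
                category=str(_require(nd, "category", f"neuron {i}")),
                aif=int(_require(nd, "aif", f"neuron {i}")),
                commit_index=int(_require(nd, "commit_index", f"neuron {i}")),
            )
        )
    return RceNetwork.from_neurons(profile, neurons)
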