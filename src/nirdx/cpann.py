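"""Counter-propagation artificial neural network (CP-ANN).

A CP-ANN is a supervised self-organizing map: a square S x S Kohonen layer
clusters the inputs by competitive learning, while a coupled output layer of
the same topology accumulates class membership per neuron.  Training moves
both layers at once — for each input the winning neuron (minimal Euclidean
distance in the Kohonen layer) and its topological neighborhood are pulled
toward the input vector and toward the input's one-hot class vector.
Prediction assigns a new input the class weights of its winning neuron.

Training schedule (the classic counter-propagation recipe):

* learning rate decays linearly from ``lr_start`` to ``lr_end`` over epochs;
* neighborhood radius shrinks linearly from S/2 to 0 (non-toroidal map,
  Chebyshev topological distance);
* the neighborhood factor is triangular:
  ``h = (radius + 1 - d) / (radius + 1)`` for topological distance
  ``d <= radius``, else 0 — so the winner always moves with factor 1.

Because each update is a convex combination of the current weight and the
target, output-layer weights stay in [0, 1] and keep summing to 1 per neuron.
Everything is deterministic given the model seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Hashable, Sequence

import numpy as np

from .errors import DataError, LabelError, ParameterError, StateError
from .spectra_io import SpectrumMeta

MAP_SIDES = (10, 12, 15)

DEFAULT_EPOCHS = 100
DEFAULT_LR_START = 0.5
DEFAULT_LR_END = 0.01


@dataclass
class CPANNModel:
    """Square Kohonen map with a coupled class-output layer."""

    size: int
    n_inputs: int
    n_classes: int
    kohonen_w: np.ndarray  # (S, S, d)
    output_w: np.ndarray  # (S, S, C)
    seed: int
    epochs: int = DEFAULT_EPOCHS
    lr_start: float = DEFAULT_LR_START
    lr_end: float = DEFAULT_LR_END
    trained: bool = False
    classes: tuple[Hashable, ...] | None = None

    def save(self, path: str | Path) -> None:
        np.savez(
            path,
            kohonen_w=self.kohonen_w,
            output_w=self.output_w,
            size=self.size,
            n_inputs=self.n_inputs,
            n_classes=self.n_classes,
            seed=self.seed,
            epochs=self.epochs,
            lr_start=self.lr_start,
            lr_end=self.lr_end,
            trained=self.trained,
            classes=np.asarray(
                [str(c) for c in self.classes] if self.classes else [], dtype=object
            ),
        )

    @classmethod
    def load(cls, path: str | Path) -> "CPANNModel":
        with np.load(path, allow_pickle=True) as data:
            classes = tuple(data["classes"].tolist()) or None
            return cls(
                size=int(data["size"]),
                n_inputs=int(data["n_inputs"]),
                n_classes=int(data["n_classes"]),
                kohonen_w=data["kohonen_w"],
                output_w=data["output_w"],
                seed=int(data["seed"]),
                epochs=int(data["epochs"]),
                lr_start=float(data["lr_start"]),
                lr_end=float(data["lr_end"]),
                trained=bool(data["trained"]),
                classes=classes,
            )


@dataclass
class MapPlacement:
    """Where one spectrum lands on the trained map."""

    sample_id: str
    replicate: int
    row: int
    col: int
    true_label: Hashable
    predicted_label: Hashable
    correct: bool
    role: str  # "calibration" or "validation"
    marker: str  # Fig-4 style letter: M/m (mutant cal/val), W/w, "o" appended if wrong


@dataclass
class MapReport:
    """Per-neuron class regions plus per-spectrum placements (projection map)."""

    size: int
    regions: np.ndarray  # (S, S) class indices by output-weight argmax
    placements: list[MapPlacement]
    classes: tuple[Hashable, ...]

    def render_text(self) -> str:
        """ASCII rendering: one cell per neuron, region letter + occupant count."""
        S = self.size
        counts = np.zeros((S, S), dtype=int)
        wrong = np.zeros((S, S), dtype=bool)
        for p in self.placements:
            counts[p.row, p.col] += 1
            wrong[p.row, p.col] |= not p.correct
        lines = []
        region_letter = {0: "M", 1: "W"}
        for r in range(S):
            cells = []
            for c in range(S):
                letter = region_letter.get(int(self.regions[r, c]), "?")
                body = f"{letter}{counts[r, c] if counts[r, c] else '.'}"
                if wrong[r, c]:
                    body += "o"
                cells.append(f"{body:>4s}")
            lines.append(" ".join(cells))
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# construction and training


def one_hot(labels: Sequence[Hashable], classes: Sequence[Hashable]) -> np.ndarray:
    """One-hot encode ``labels`` in the given class order."""
    index = {c: i for i, c in enumerate(classes)}
    try:
        rows = [index[l] for l in labels]
    except KeyError as exc:
        raise LabelError(f"label {exc.args[0]!r} not in classes {tuple(classes)!r}")
    out = np.zeros((len(rows), len(classes)))
    out[np.arange(len(rows)), rows] = 1.0
    return out


def init_map(S: int, d: int, C: int = 2, seed: int = 0) -> CPANNModel:
    """Initialize an untrained S x S map.

    Kohonen weights start uniform in [0, 1] per dimension and are rescaled to
    the per-dimension score range when training starts; output weights start
    at the uninformative 1/C.
    """
    if S < 1 or d < 1 or C < 2:
        raise ParameterError(f"invalid map dimensions S={S}, d={d}, C={C}")
    rng = np.random.default_rng(seed)
    return CPANNModel(
        size=S,
        n_inputs=d,
        n_classes=C,
        kohonen_w=rng.uniform(size=(S, S, d)),
        output_w=np.full((S, S, C), 1.0 / C),
        seed=seed,
    )


def train(
    model: CPANNModel,
    scores: np.ndarray,
    labels: np.ndarray,
    epochs: int | None = None,
    lr_start: float | None = None,
    lr_end: float | None = None,
    classes: Sequence[Hashable] | None = None,
    shuffle: bool = True,
) -> CPANNModel:
    """Train a copy of ``model`` on score vectors and one-hot labels.

    ``labels`` must be an (n, C) one-hot matrix; ``classes`` optionally names
    the class order so :func:`predict` can return labels instead of indices.
    Presentation order is reshuffled each epoch from the model seed
    (``shuffle=False`` keeps the given order, useful for closed-form checks).
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    labels = np.atleast_2d(np.asarray(labels, dtype=float))
    if scores.shape[0] == 0:
        raise DataError("cannot train on an empty score matrix")
    if scores.shape[0] != labels.shape[0]:
        raise DataError(
            f"{scores.shape[0]} score rows but {labels.shape[0]} label rows"
        )
    if labels.shape[1] != model.n_classes:
        raise LabelError(
            f"labels have {labels.shape[1]} columns, model expects {model.n_classes}"
        )
    is_binary = np.isin(labels, (0.0, 1.0)).all()
    if not is_binary or not np.allclose(labels.sum(axis=1), 1.0):
        raise LabelError("label rows must be one-hot")
    if scores.shape[1] != model.n_inputs:
        raise DataError(
            f"scores have {scores.shape[1]} dims, model expects {model.n_inputs}"
        )

    epochs = model.epochs if epochs is None else int(epochs)
    lr_start = model.lr_start if lr_start is None else float(lr_start)
    lr_end = model.lr_end if lr_end is None else float(lr_end)
    if epochs < 1:
        raise ParameterError("epochs must be >= 1")

    S = model.size
    n = scores.shape[0]
    # rescale the unit-uniform initial weights onto the data ranges
    w = model.kohonen_w.reshape(S * S, -1).copy()
    if not model.trained:
        lo = scores.min(axis=0)
        hi = scores.max(axis=0)
        w = lo + w * np.where(hi > lo, hi - lo, 1.0)
    o = model.output_w.reshape(S * S, -1).copy()

    rows, cols = np.divmod(np.arange(S * S), S)
    rng = np.random.default_rng(model.seed + 1)
    for epoch in range(epochs):
        frac = epoch / (epochs - 1) if epochs > 1 else 1.0
        lr = lr_start + (lr_end - lr_start) * frac
        radius = (S / 2.0) * (1.0 - frac)
        order = rng.permutation(n) if shuffle else np.arange(n)
        for i in order:
            x = scores[i]
            y = labels[i]
            d2 = ((w - x) ** 2).sum(axis=1)
            winner = int(np.argmin(d2))  # first minimum = lowest (row, col) lex
            topo = np.maximum(np.abs(rows - rows[winner]), np.abs(cols - cols[winner]))
            h = np.clip((radius + 1.0 - topo) / (radius + 1.0), 0.0, None)
            step = (lr * h)[:, np.newaxis]
            w += step * (x - w)
            o += step * (y - o)

    out = CPANNModel(
        size=S,
        n_inputs=model.n_inputs,
        n_classes=model.n_classes,
        kohonen_w=w.reshape(S, S, -1),
        output_w=o.reshape(S, S, -1),
        seed=model.seed,
        epochs=epochs,
        lr_start=lr_start,
        lr_end=lr_end,
        trained=True,
        classes=tuple(classes) if classes is not None else model.classes,
    )
    return out


def predict(
    model: CPANNModel, scores: np.ndarray
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Winning-neuron class for each score vector.

    Returns ``(labels, winner_coords)``: labels are taken from
    ``model.classes`` when set (else class indices); the predicted class is
    the argmax of the winner's output weights, ties resolved toward the lower
    class index.
    """
    if not model.trained:
        raise StateError("model must be trained before predicting")
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    if scores.shape[1] != model.n_inputs:
        raise DataError(
            f"scores have {scores.shape[1]} dims, model expects {model.n_inputs}"
        )
    S = model.size
    w = model.kohonen_w.reshape(S * S, -1)
    o = model.output_w.reshape(S * S, -1)
    d2 = ((scores[:, np.newaxis, :] - w[np.newaxis, :, :]) ** 2).sum(axis=2)
    winners = d2.argmin(axis=1)
    coords = [(int(win // S), int(win % S)) for win in winners]
    idx = o[winners].argmax(axis=1)  # np.argmax takes the first (lowest) index on ties
    if model.classes is not None:
        labels = np.asarray([model.classes[i] for i in idx], dtype=object)
    else:
        labels = idx
    return labels, coords


def accuracy_pct(model: CPANNModel, scores: np.ndarray, labels: Sequence[Hashable]) -> float:
    """Percent of score vectors whose predicted class equals ``labels``."""
    predicted, _ = predict(model, scores)
    return 100.0 * float(np.mean([p == t for p, t in zip(predicted, labels)]))


def project_map(
    model: CPANNModel,
    scores: np.ndarray,
    meta: Sequence[SpectrumMeta],
    labels: Sequence[Hashable] | None = None,
    role: str = "calibration",
) -> MapReport:
    """Projection-map report: neuron class regions + per-spectrum placements.

    Each neuron belongs to the class with the larger output weight, so the
    regions partition the S x S map; each spectrum is placed at its winning
    neuron with a correctness flag (the misassigned-sample marker).
    """
    if not model.trained:
        raise StateError("model must be trained before projecting")
    if labels is None:
        labels = [m.label for m in meta]
    predicted, coords = predict(model, scores)
    S = model.size
    regions = model.output_w.reshape(S, S, -1).argmax(axis=2)
    classes = model.classes or tuple(range(model.n_classes))
    placements = []
    for m, lab, pred, (r, c) in zip(meta, labels, predicted, coords):
        correct = pred == lab
        letter = "M" if str(getattr(lab, "value", lab)).startswith("mut") else "W"
        if role == "validation":
            letter = letter.lower()
        placements.append(
            MapPlacement(
                sample_id=m.sample_id,
                replicate=m.replicate,
                row=r,
                col=c,
                true_label=lab,
                predicted_label=pred,
                correct=bool(correct),
                role=role,
                marker=letter if correct else letter + "o",
            )
        )
    return MapReport(size=S, regions=regions, placements=placements, classes=classes)


# ---------------------------------------------------------------------------
# cross-validation


def _grouped_stratified_folds(
    sample_ids: Sequence[str],
    labels: Sequence[Hashable],
    folds: int,
    seed: int,
) -> list[np.ndarray]:
    """Spectrum-index folds grouping replicates by sample, stratified by class."""
    first_index: dict[str, int] = {}
    sample_label: dict[str, Hashable] = {}
    members: dict[str, list[int]] = {}
    for i, (sid, lab) in enumerate(zip(sample_ids, labels)):
        if sid not in first_index:
            first_index[sid] = i
            sample_label[sid] = lab
        members.setdefault(sid, []).append(i)
    samples = sorted(first_index, key=first_index.get)
    if folds > len(samples):
        raise ParameterError(f"{folds} folds for only {len(samples)} samples")
    rng = np.random.default_rng(seed)
    fold_of: dict[str, int] = {}
    for lab in dict.fromkeys(sample_label[s] for s in samples):
        group = [s for s in samples if sample_label[s] == lab]
        rng.shuffle(group)
        for j, sid in enumerate(group):
            fold_of[sid] = j % folds
    out = []
    for f in range(folds):
        idx = [i for sid in samples if fold_of[sid] == f for i in members[sid]]
        out.append(np.asarray(sorted(idx), dtype=int))
    return out


def cross_validate(
    scores: np.ndarray,
    labels: Sequence[Hashable],
    meta: Sequence[SpectrumMeta] | None,
    folds: int = 5,
    *,
    size: int = 12,
    epochs: int = DEFAULT_EPOCHS,
    lr_start: float = DEFAULT_LR_START,
    lr_end: float = DEFAULT_LR_END,
    seed: int = 0,
    sample_ids: Sequence[str] | None = None,
) -> float:
    """Sample-grouped, class-stratified k-fold CV accuracy (CACV, percent).

    All replicate spectra of one sample share a fold, so a sample never
    appears on both sides of a split.  Held-out predictions are pooled over
    folds and scored per spectrum.
    """
    if folds < 2:
        raise ParameterError("folds must be >= 2")
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    labels = list(labels)
    if sample_ids is None:
        if meta is None:
            raise DataError("need meta or sample_ids to group replicates")
        sample_ids = [m.sample_id for m in meta]
    classes = list(dict.fromkeys(labels))
    fold_indices = _grouped_stratified_folds(sample_ids, labels, folds, seed)
    correct = 0
    total = 0
    all_idx = np.arange(scores.shape[0])
    for f, held in enumerate(fold_indices):
        held_set = set(held.tolist())
        train_idx = np.asarray([i for i in all_idx if i not in held_set])
        # grouping guard: a sample's replicates never straddle the split
        assert {sample_ids[i] for i in held}.isdisjoint(
            {sample_ids[i] for i in train_idx}
        )
        model = init_map(size, scores.shape[1], len(classes), seed=seed)
        model = train(
            model,
            scores[train_idx],
            one_hot([labels[i] for i in train_idx], classes),
            epochs=epochs,
            lr_start=lr_start,
            lr_end=lr_end,
            classes=classes,
        )
        predicted, _ = predict(model, scores[held])
        correct += sum(p == labels[i] for p, i in zip(predicted, held))
        total += held.size
    return 100.0 * correct / total
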