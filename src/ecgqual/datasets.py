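"""Corpus assembly at controlled class ratios, and train/val/test splitting.

The class ratio of a training corpus materially shifts the headline F1 of
a quality classifier, so ratios here are constructed explicitly — by
keeping all of the limiting class and uniformly subsampling the other —
and splits can optionally be group-aware so that all leads cut from one
source recording land in the same partition (otherwise leads of a single
12-lead recording may leak between train and test).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterable, Sequence

import numpy as np

from .errors import DataError, InvalidArgumentError, SplitError
from .signal_io import QualityLabel

__all__ = ["Corpus", "build_ratio_corpus", "split", "class_ratio"]

CorpusItem = tuple[Any, QualityLabel, str]  # (segment-or-spectrogram, label, group_id)


@dataclass
class Corpus:
    """A labeled collection of segments or spectrograms with group ids."""

    items: list[CorpusItem] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self):
        return iter(self.items)

    @property
    def ratio(self) -> tuple[float, float]:
        """(fraction acceptable, fraction unacceptable), recomputed on access."""
        return class_ratio(self)

    def payloads(self) -> list[Any]:
        return [item[0] for item in self.items]

    def labels(self) -> np.ndarray:
        return np.array([int(item[1]) for item in self.items], dtype=np.int64)

    def group_ids(self) -> list[str]:
        return [item[2] for item in self.items]

    def subset(self, indices: Iterable[int]) -> "Corpus":
        return Corpus(items=[self.items[i] for i in indices])

    def by_label(self, label: QualityLabel) -> "Corpus":
        return Corpus(items=[it for it in self.items if it[1] == label])


def class_ratio(corpus: Corpus) -> tuple[float, float]:
    """Exact (acceptable, unacceptable) proportions, summing to 1."""
    n = len(corpus)
    if n == 0:
        raise DataError("class_ratio of an empty corpus is undefined")
    n_acc = int(np.sum(corpus.labels() == int(QualityLabel.ACCEPTABLE)))
    return n_acc / n, (n - n_acc) / n


def build_ratio_corpus(
    acceptable_pool: Corpus,
    unacceptable_pool: Corpus,
    ratio_acceptable: float,
    seed: int,
) -> Corpus:
    """Largest corpus at the requested acceptable fraction.

    The limiting class is kept in full; the other class is uniformly
    subsampled (never duplicated — oversampling would fabricate data).
    Resulting class counts match ``ratio_acceptable`` to within one item.
    """
    if not (0.0 < ratio_acceptable < 1.0):
        raise InvalidArgumentError(
            f"ratio_acceptable must lie in (0, 1), got {ratio_acceptable}"
        )
    n_a, n_u = len(acceptable_pool), len(unacceptable_pool)
    if n_a == 0 or n_u == 0:
        raise DataError(
            f"both pools must be non-empty (acceptable={n_a}, unacceptable={n_u})"
        )
    rng = np.random.default_rng(seed)
    r = ratio_acceptable
    # If the unacceptable pool limits: keep all of it, draw round(u*r/(1-r)) acceptable.
    want_a = round(n_u * r / (1.0 - r))
    if want_a <= n_a:
        keep_a = sorted(rng.choice(n_a, size=want_a, replace=False))
        items = [acceptable_pool.items[i] for i in keep_a] + list(unacceptable_pool.items)
    else:
        want_u = round(n_a * (1.0 - r) / r)
        if want_u > n_u or want_u == 0:
            raise DataError(
                f"ratio {r} unachievable from pools {n_a}/{n_u} by subsampling"
            )
        keep_u = sorted(rng.choice(n_u, size=want_u, replace=False))
        items = list(acceptable_pool.items) + [unacceptable_pool.items[i] for i in keep_u]
    order = rng.permutation(len(items))
    return Corpus(items=[items[i] for i in order])


def _partition_sizes(n: int, fractions: Sequence[float]) -> list[int]:
    """Largest-remainder apportionment; the last (test) partition absorbs
    residual ties so train/val stay at their nominal sizes."""
    base = [int(n * f) for f in fractions]
    remainders = [n * f - b for f, b in zip(fractions, base)]
    leftover = n - sum(base)
    # ties broken toward later partitions (test) by sorting on (-rem, -index)
    order = sorted(range(len(fractions)), key=lambda i: (-remainders[i], -i))
    for i in order[:leftover]:
        base[i] += 1
    return base


def split(
    corpus: Corpus,
    fractions: tuple[float, float, float],
    seed: int,
    group_aware: bool = False,
) -> tuple[Corpus, Corpus, Corpus]:
    """Partition a corpus into (train, val, test).

    Sizes follow the fractions to within one item (largest-remainder
    rounding). With ``group_aware`` every group_id lands entirely in one
    partition, at the cost of slightly looser size adherence; groups are
    assigned greedily, largest first, to the partition with the largest
    remaining deficit.
    """
    if len(corpus) == 0:
        raise DataError("cannot split an empty corpus")
    if len(fractions) != 3:
        raise InvalidArgumentError("fractions must be a (train, val, test) triple")
    if fractions[0] <= 0 or any(f < 0 for f in fractions):
        raise InvalidArgumentError(f"train fraction must be > 0 and none negative: {fractions}")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise InvalidArgumentError(f"fractions must sum to 1, got {sum(fractions)}")

    n = len(corpus)
    sizes = _partition_sizes(n, fractions)
    rng = np.random.default_rng(seed)

    if not group_aware:
        order = rng.permutation(n)
        bounds = np.cumsum([0] + sizes)
        parts = [
            corpus.subset(order[bounds[i] : bounds[i + 1]]) for i in range(3)
        ]
        return parts[0], parts[1], parts[2]

    groups: dict[str, list[int]] = {}
    for i, (_, _, gid) in enumerate(corpus.items):
        groups.setdefault(gid, []).append(i)
    gids = sorted(groups)
    rng.shuffle(gids)
    # largest groups first so small ones can fill residual deficits
    gids.sort(key=lambda g: -len(groups[g]))
    biggest = len(groups[gids[0]])
    if biggest > sizes[0]:
        raise SplitError(
            f"group {gids[0]!r} has {biggest} items, exceeding the train partition ({sizes[0]})"
        )
    assigned: list[list[int]] = [[], [], []]
    deficits = list(sizes)
    for gid in gids:
        k = int(np.argmax(deficits))
        assigned[k].extend(groups[gid])
        deficits[k] -= len(groups[gid])
    parts = [corpus.subset(sorted(ix)) for ix in assigned]
    return parts[0], parts[1], parts[2]
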