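"""Dataset containers shared by every part of the package.

A :class:`DatasetView` holds one dataset's gene-by-feature matrix together
with its declared type and the per-type metadata needed by the matching
component likelihood:

``timecourse``
    real matrix, columns indexed by a strictly increasing numeric time grid;
``categorical``
    integer category codes per feature, with a declared (or inferred)
    alphabet per feature — binary data is the two-letter special case;
``bag_of_words``
    non-negative integer counts over a shared vocabulary.

All views entering a joint model must carry identical gene identifiers in
identical order; :func:`align_views` restricts a collection to the common
genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

DATA_TYPES = ("timecourse", "categorical", "bag_of_words")


@dataclass
class DatasetView:
    """One dataset: observation matrix plus type and metadata.

    Parameters
    ----------
    name : str
        Label used in reports and output tables.
    data_type : {"timecourse", "categorical", "bag_of_words"}
    matrix : ndarray of shape (n_genes, n_features)
        Raw observations; dtype float for time courses, integer codes or
        counts for the discrete types.
    gene_ids : sequence of str
        Row identifiers, unique, shared (same order) across all views of a
        joint model.
    time : ndarray, optional
        Strictly increasing time grid (time courses only).
    alphabets : list of ndarray, optional
        Per-feature category alphabets (categorical only).  Inferred from
        the data when omitted.
    vocabulary : sequence of str, optional
        Word labels (bag-of-words only); defaults to ``w0..w{p-1}``.
    """

    name: str
    data_type: str
    matrix: np.ndarray
    gene_ids: list = field(default_factory=list)
    time: np.ndarray | None = None
    alphabets: list | None = None
    vocabulary: list | None = None

    def __post_init__(self) -> None:
        if self.data_type not in DATA_TYPES:
            raise ValueError(
                f"unknown data_type {self.data_type!r}; expected one of {DATA_TYPES}"
            )
        self.matrix = np.asarray(self.matrix)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-D (genes x features)")
        n, p = self.matrix.shape
        if p == 0:
            raise ValueError(f"dataset {self.name!r} has zero features")
        self.gene_ids = [str(g) for g in self.gene_ids]
        if len(self.gene_ids) != n:
            raise ValueError(
                f"{len(self.gene_ids)} gene ids for {n} rows in dataset {self.name!r}"
            )
        if len(set(self.gene_ids)) != n:
            dupes = sorted({g for g in self.gene_ids if self.gene_ids.count(g) > 1})
            raise ValueError(f"duplicate gene ids in {self.name!r}: {dupes[:5]}")

        if self.data_type == "timecourse":
            self.matrix = self.matrix.astype(float)
            if not np.all(np.isfinite(self.matrix)):
                raise ValueError(f"non-finite values in time-course dataset {self.name!r}")
            if self.time is None:
                self.time = np.arange(p, dtype=float)
            self.time = np.asarray(self.time, dtype=float)
            if self.time.shape != (p,):
                raise ValueError("time grid length must match the number of columns")
            if p > 1 and not np.all(np.diff(self.time) > 0):
                raise ValueError(
                    f"time grid of {self.name!r} is not strictly increasing: {self.time}"
                )
        elif self.data_type == "categorical":
            mat = np.asarray(self.matrix)
            if self.alphabets is None:
                self.alphabets = [np.unique(mat[:, j]) for j in range(p)]
            if len(self.alphabets) != p:
                raise ValueError("one alphabet per feature is required")
            codes = np.empty((n, p), dtype=np.int64)
            for j, alpha in enumerate(self.alphabets):
                alpha = np.asarray(alpha)
                if alpha.size == 0:
                    raise ValueError(f"empty alphabet for feature {j} of {self.name!r}")
                pos = {v: a for a, v in enumerate(alpha.tolist())}
                for i in range(n):
                    v = mat[i, j]
                    if v not in pos:
                        raise ValueError(
                            f"unknown category {v!r} at gene {self.gene_ids[i]!r}, "
                            f"feature {j} of {self.name!r}; alphabet {alpha.tolist()}"
                        )
                    codes[i, j] = pos[v]
                self.alphabets[j] = alpha
            self.codes = codes
        else:  # bag_of_words
            mat = np.asarray(self.matrix)
            if not np.all(np.isfinite(mat.astype(float))):
                raise ValueError(f"non-finite counts in {self.name!r}")
            counts = mat.astype(np.int64)
            if np.any(counts.astype(float) != mat.astype(float)):
                raise ValueError(f"non-integer counts in bag-of-words dataset {self.name!r}")
            if counts.min() < 0:
                i, j = np.argwhere(counts < 0)[0]
                raise ValueError(
                    f"negative count at gene {self.gene_ids[i]!r}, word {j} of {self.name!r}"
                )
            self.matrix = counts
            if self.vocabulary is None:
                self.vocabulary = [f"w{j}" for j in range(p)]
            if len(self.vocabulary) != p:
                raise ValueError("vocabulary length must match the number of columns")

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    def subset(self, order: Sequence[int]) -> "DatasetView":
        """Return a view restricted/reordered to the given row positions."""
        order = list(order)
        return DatasetView(
            name=self.name,
            data_type=self.data_type,
            matrix=self.matrix[order],
            gene_ids=[self.gene_ids[i] for i in order],
            time=self.time,
            alphabets=self.alphabets,
            vocabulary=self.vocabulary,
        )


def align_views(views: Sequence[DatasetView]) -> list:
    """Restrict views to their common genes, ordered as in the first view.

    Genes missing from any view are dropped (and logged per view).  Raises
    if fewer than two genes survive.
    """
    if len(views) < 2:
        raise ValueError("need at least two views to align")
    common = set(views[0].gene_ids)
    for v in views[1:]:
        common &= set(v.gene_ids)
    order = [g for g in views[0].gene_ids if g in common]
    if len(order) < 2:
        raise ValueError("gene-id intersection across views has fewer than 2 genes")
    out = []
    for v in views:
        dropped = [g for g in v.gene_ids if g not in common]
        if dropped:
            logger.info(
                "align_views: dropping %d gene(s) from %r (e.g. %s)",
                len(dropped), v.name, dropped[:3],
            )
        pos = {g: i for i, g in enumerate(v.gene_ids)}
        out.append(v.subset([pos[g] for g in order]))
    return out


def check_aligned(views: Sequence[DatasetView]) -> None:
    """Raise unless all views share identical gene ids in identical order."""
    ids = views[0].gene_ids
    for v in views[1:]:
        if v.gene_ids != ids:
            raise ValueError(
                f"views {views[0].name!r} and {v.name!r} do not share an identical "
                "gene index; call align_views first"
            )
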