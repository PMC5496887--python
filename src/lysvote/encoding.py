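"""Binary feature vectors: one-hot sequence blocks plus functional bits."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .annotations import AnnotationTable, FeatureSpace
from .sequence import STANDARD_AA, SiteSet, SiteWindow

_AA_INDEX = {aa: i for i, aa in enumerate(STANDARD_AA)}

_LABEL_TO_Y = {"positive": 1, "negative": -1}


@dataclass
class SampleMatrix:
    """Encoded site windows with their labels and the space that defines them."""

    X: np.ndarray  # (n_sites, dimension) float64 of 0/1
    y: np.ndarray | None  # (n_sites,) of {+1, -1}, None for unlabeled sets
    feature_space: FeatureSpace

    def __post_init__(self) -> None:
        if self.X.ndim != 2 or self.X.shape[1] != self.feature_space.dimension:
            raise ValueError(
                f"matrix width {self.X.shape} != feature-space dimension "
                f"{self.feature_space.dimension}"
            )

    def __len__(self) -> int:
        return self.X.shape[0]


def encode_window(
    site: SiteWindow,
    tables: Mapping[str, AnnotationTable],
    space: FeatureSpace,
) -> np.ndarray:
    """Encode one site as a 0/1 vector of ``space.dimension``.

    Sequence part: one 20-bit block per position in alphabet order
    ``ACDEFGHIKLMNPQRSTVWY``; ambiguity codes give an all-zero block.
    Functional part: bit ``j`` is 1 iff the site's protein carries
    ``space.selected[j]`` (presence, regardless of enrichment direction).
    """
    if len(site.window) != space.L:
        raise ValueError(
            f"window length {len(site.window)} does not match feature-space "
            f"L={space.L}"
        )
    vec = np.zeros(space.dimension, dtype=np.float64)
    offset = 0
    if space.include_seq:
        for pos, aa in enumerate(site.window):
            idx = _AA_INDEX.get(aa)
            if idx is not None:
                vec[pos * 20 + idx] = 1.0
        offset = 20 * space.L
    for j, (source, term) in enumerate(space.selected):
        table = tables.get(source)
        if table is not None and term in table.terms_of(site.protein_id):
            vec[offset + j] = 1.0
    return vec


def encode_set(
    sites: SiteSet,
    tables: Mapping[str, AnnotationTable],
    space: FeatureSpace,
    for_training: bool = True,
) -> SampleMatrix:
    """Encode a site set row by row, preserving order.

    Labels map positive -> +1 and negative -> -1. With ``for_training`` an
    unlabeled site is an error; otherwise ``y`` is None.
    """
    X = np.zeros((len(sites), space.dimension), dtype=np.float64)
    for i, w in enumerate(sites):
        X[i] = encode_window(w, tables, space)
    if not for_training:
        return SampleMatrix(X, None, space)
    labels = []
    for w in sites:
        if w.label not in _LABEL_TO_Y:
            raise ValueError(
                f"unlabeled site {w.site} in a training set"
            )
        labels.append(_LABEL_TO_Y[w.label])
    return SampleMatrix(X, np.asarray(labels, dtype=np.int64), space)


def dump_matrix_tsv(sites: SiteSet, matrix: SampleMatrix, path) -> None:
    """Debug dump: one row per site, bit columns after protein_id/position."""
    import pandas as pd

    cols = [f"b{i}" for i in range(matrix.feature_space.dimension)]
    df = pd.DataFrame(matrix.X.astype(int), columns=cols)
    df.insert(0, "position", [w.position for w in sites])
    df.insert(0, "protein_id", [w.protein_id for w in sites])
    df.to_csv(path, sep="\t", index=False)
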