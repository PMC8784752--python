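"""Within-sample binary pair scores over DEirlncRNAs and the frequency filter.

A pair (A, B) in canonical orientation (A lexicographically smaller) scores
1 in a sample iff expression of A strictly exceeds expression of B, else 0.
Because the score depends only on the within-sample ordering, the pair
matrix is invariant to any strictly increasing per-sample transform of the
expression values — the property that makes the signature portable across
platforms. The mirrored pair carries the complementary score, so each
unordered pair is represented exactly once.

Pairs whose score-1 frequency across samples falls outside [low, high]
(default [0.2, 0.8], boundaries inclusive) carry too little rank variation
to discriminate survival and are removed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .io import DataError, ExpressionMatrix

logger = logging.getLogger("irlpair")

#: above this many genes the pair builder streams chunks through the filter
DENSE_GENE_LIMIT = 2000


class PairDef(NamedTuple):
    """Unordered gene pair in canonical orientation (gene_a < gene_b)."""

    gene_a: str
    gene_b: str

    @classmethod
    def canonical(cls, a: str, b: str) -> "PairDef":
        if a == b:
            raise DataError(f"pair members must differ (got {a!r} twice)")
        return cls(a, b) if a < b else cls(b, a)

    @property
    def label(self) -> str:
        return f"{self.gene_a}|{self.gene_b}"

    @classmethod
    def from_label(cls, label: str) -> "PairDef":
        a, _, b = label.partition("|")
        if not b:
            raise DataError(f"malformed pair label {label!r}")
        return cls.canonical(a, b)


@dataclass
class PairScoreMatrix:
    """Binary pairs x samples matrix; index is ``GENEA|GENEB`` labels."""

    scores: pd.DataFrame

    def __post_init__(self) -> None:
        if self.scores.index.has_duplicates:
            dup = self.scores.index[self.scores.index.duplicated()][0]
            raise DataError(f"duplicate pair {dup!r}")
        arr = self.scores.to_numpy()
        if arr.size and not np.isin(arr, (0, 1)).all():
            raise DataError("pair scores must be 0/1")

    @property
    def pairs(self) -> list[PairDef]:
        return [PairDef.from_label(lbl) for lbl in self.scores.index]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.scores.columns)

    @property
    def n_pairs(self) -> int:
        return self.scores.shape[0]

    def frequencies(self) -> pd.Series:
        """Score-1 frequency per pair."""
        return self.scores.mean(axis=1)


def score_pair(e_a: float, e_b: float) -> int:
    """1 iff ``e_a > e_b`` (strict); ties score 0."""
    if not (math.isfinite(e_a) and math.isfinite(e_b)):
        raise DataError("pair scoring requires finite expression values")
    return int(e_a > e_b)


def _pair_rows(gene_ids: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Index arrays (a, b) over all C(g,2) canonical pairs of sorted ids."""
    g = len(gene_ids)
    return np.triu_indices(g, k=1)


def build_pair_matrix(em: ExpressionMatrix, sample_ids=None) -> PairScoreMatrix:
    """All C(g, 2) canonical pair scores over the matrix's genes.

    ``sample_ids`` restricts the columns (e.g. tumor samples only). Genes are
    sorted lexicographically before pairing so orientation is canonical.
    """
    if sample_ids is not None:
        em = em.subset_samples(sample_ids)
    genes = sorted(em.gene_ids)
    if len(genes) < 2:
        raise DataError("pairing requires at least 2 genes")
    if len(genes) > DENSE_GENE_LIMIT:
        raise DataError(
            f"dense pair matrix over {len(genes)} genes is too large; "
            "use build_filtered_pair_matrix to stream pairs through the filter"
        )
    X = em.values.loc[genes].to_numpy()
    if not np.isfinite(X).all():
        raise DataError("pair scoring requires finite expression values")
    ia, ib = _pair_rows(genes)
    scores = (X[ia] > X[ib]).astype(np.int8)
    labels = [f"{genes[a]}|{genes[b]}" for a, b in zip(ia, ib)]
    df = pd.DataFrame(scores, index=pd.Index(labels, name="pair"),
                      columns=em.sample_ids)
    return PairScoreMatrix(df)


def frequency_filter(
    pm: PairScoreMatrix, low: float = 0.2, high: float = 0.8
) -> PairScoreMatrix:
    """Keep pairs with score-1 frequency in [low, high] (inclusive)."""
    if pm.scores.shape[1] < 1:
        raise DataError("frequency filter needs at least one sample")
    freq = pm.scores.to_numpy().mean(axis=1)
    keep = (freq >= low) & (freq <= high)
    return PairScoreMatrix(pm.scores.loc[keep])


def build_filtered_pair_matrix(
    em: ExpressionMatrix,
    sample_ids=None,
    low: float = 0.2,
    high: float = 0.8,
    chunk_pairs: int = 500_000,
) -> PairScoreMatrix:
    """Pair construction fused with the frequency filter, streaming in chunks.

    Equivalent to ``frequency_filter(build_pair_matrix(em, sample_ids))`` but
    never materializes more than ``chunk_pairs`` unfiltered rows at a time,
    so it stays bounded for gene counts beyond :data:`DENSE_GENE_LIMIT`.
    """
    if sample_ids is not None:
        em = em.subset_samples(sample_ids)
    genes = sorted(em.gene_ids)
    if len(genes) < 2:
        raise DataError("pairing requires at least 2 genes")
    X = em.values.loc[genes].to_numpy()
    if not np.isfinite(X).all():
        raise DataError("pair scoring requires finite expression values")
    ia, ib = _pair_rows(genes)
    kept_blocks: list[pd.DataFrame] = []
    for start in range(0, len(ia), chunk_pairs):
        sl = slice(start, start + chunk_pairs)
        sa, sb = ia[sl], ib[sl]
        scores = (X[sa] > X[sb]).astype(np.int8)
        freq = scores.mean(axis=1)
        keep = (freq >= low) & (freq <= high)
        if keep.any():
            labels = [f"{genes[a]}|{genes[b]}"
                      for a, b in zip(sa[keep], sb[keep])]
            kept_blocks.append(pd.DataFrame(
                scores[keep], index=pd.Index(labels, name="pair"),
                columns=em.sample_ids))
    if kept_blocks:
        df = pd.concat(kept_blocks)
    else:
        df = pd.DataFrame(np.empty((0, em.shape[1]), dtype=np.int8),
                          index=pd.Index([], name="pair"),
                          columns=em.sample_ids)
    logger.info("pair filter kept %d of %d pairs", len(df), len(ia))
    return PairScoreMatrix(df)


def pair_scores_for(pairs, em: ExpressionMatrix) -> PairScoreMatrix:
    """Scores for a fixed pair list on (possibly new) samples.

    Used to score held-out or external samples with an already-fitted
    signature; ``pairs`` may be PairDefs or ``A|B`` labels.
    """
    defs = [p if isinstance(p, PairDef) else PairDef.from_label(p) for p in pairs]
    needed = sorted({g for p in defs for g in p})
    sub = em.subset_genes(needed)
    X = sub.values.to_numpy()
    pos = {g: i for i, g in enumerate(sub.gene_ids)}
    rows = np.array([
        X[pos[p.gene_a]] > X[pos[p.gene_b]] for p in defs
    ], dtype=np.int8)
    df = pd.DataFrame(rows, index=pd.Index([p.label for p in defs], name="pair"),
                      columns=em.sample_ids)
    return PairScoreMatrix(df)


def write_pair_matrix(pm: PairScoreMatrix, path) -> None:
    pm.scores.to_csv(path, sep="\t")


def read_pair_matrix(path) -> PairScoreMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return PairScoreMatrix(df.astype(np.int8))
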