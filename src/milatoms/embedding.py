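"""Instance-based similarity embedding of bags and its window-length expansion.

Every training instance (optionally refined by MILR) is treated as a target
*concept*; a bag's feature vector is its similarity to every concept,

    s(d^k, B_r) = max_t exp(-||d_rt - d^k||^2 / sigma^2),

a value in [0, 1] that reaches 1 exactly when the bag contains the concept.
Stacking bags gives the similarity block S_tau for one window length tau;
horizontally concatenating the blocks of a contiguous range of window
lengths tau = q*dtau .. p*dtau yields the expanded embedding Delta_pq,
whose columns are book-kept back to (tau, concept, source trial, source
window) so sparse selection weights can be mapped onto time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist, pdist

from .csp import AtomBag
from .exceptions import DataError, ParameterError

__all__ = [
    "ConceptDictionary",
    "SimilarityParams",
    "SimilarityBlock",
    "ExpandedEmbedding",
    "build_dictionary",
    "similarity",
    "embed_bags",
    "expand",
    "select_sigma",
    "n_expansion_configs",
]


@dataclass
class ConceptDictionary:
    """Target concepts: the instance pool of the training bags at one tau."""

    concepts: np.ndarray  # (K, dim)
    source_index: list[tuple[int, int]]  # (trial, window) per concept
    tau: float

    def __post_init__(self) -> None:
        self.concepts = np.asarray(self.concepts, dtype=np.float64)
        if self.concepts.ndim != 2 or self.concepts.shape[0] < 1:
            raise DataError("concept dictionary must be a non-empty (K, dim) array")

    @property
    def n_concepts(self) -> int:
        return self.concepts.shape[0]


def build_dictionary(bags: list[AtomBag], tau: float | None = None) -> ConceptDictionary:
    """Pool all instances of the given (training) bags as concepts."""
    if not bags:
        raise DataError("no bags")
    tau = bags[0].tau if tau is None else tau
    concepts = np.concatenate([b.instances for b in bags], axis=0)
    source = [(b.trial, t) for b in bags for t in range(b.n_instances)]
    return ConceptDictionary(concepts=concepts, source_index=source, tau=tau)


@dataclass(frozen=True)
class SimilarityParams:
    """Gaussian similarity kernel bandwidth."""

    sigma: float
    rule: str = "fixed"

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ParameterError("sigma must be positive")


def similarity(concept: np.ndarray, bag: AtomBag, params: SimilarityParams) -> float:
    """Most-likely-cause similarity between one concept and one bag."""
    concept = np.asarray(concept, dtype=np.float64)
    if concept.shape[0] != bag.instances.shape[1]:
        raise DataError("concept and instance lengths differ")
    d2 = np.sum((bag.instances - concept[None, :]) ** 2, axis=1)
    return float(np.exp(-d2.min() / params.sigma ** 2))


@dataclass
class SimilarityBlock:
    """Bags-by-concepts similarity matrix for one window length."""

    matrix: np.ndarray  # (n_bags, K), entries in [0, 1]
    tau: float
    dictionary: ConceptDictionary | None = None
    #: center time (s) of each concept's source window, parallel to columns
    concept_times: np.ndarray | None = None

    @property
    def n_bags(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_concepts(self) -> int:
        return self.matrix.shape[1]


def embed_bags(
    bags: list[AtomBag],
    dictionary: ConceptDictionary,
    params: SimilarityParams,
    concept_times: np.ndarray | None = None,
) -> SimilarityBlock:
    """Similarity of every bag to every concept (vectorized over instances)."""
    if not bags:
        raise DataError("no bags")
    dim = dictionary.concepts.shape[1]
    for b in bags:
        if b.instances.shape[1] != dim:
            raise DataError("bag instance length does not match dictionary")
    X = np.concatenate([b.instances for b in bags], axis=0)
    d2 = cdist(X, dictionary.concepts, metric="sqeuclidean")
    sims = np.exp(-d2 / params.sigma ** 2)
    sizes = [b.n_instances for b in bags]
    bounds = np.cumsum([0] + sizes)
    matrix = np.stack(
        [sims[bounds[i]:bounds[i + 1]].max(axis=0) for i in range(len(bags))]
    )
    return SimilarityBlock(matrix=matrix, tau=bags[0].tau,
                           dictionary=dictionary, concept_times=concept_times)


@dataclass
class ExpandedEmbedding:
    """Similarity blocks concatenated over a contiguous range of window sizes."""

    features: np.ndarray  # (n_bags, total columns)
    blocks: list[tuple[float, tuple[int, int]]]  # (tau, (col_start, col_stop))
    q_index: int
    p_index: int
    delta_tau: float
    #: per column: (tau, concept index within block, source trial, source window)
    column_info: list[tuple[float, int, int, int]]
    #: per column: center time (s) of the concept's source window (nan if unknown)
    column_times: np.ndarray

    @property
    def n_columns(self) -> int:
        return self.features.shape[1]

    def column_to_block(self, j: int) -> tuple[float, int]:
        """Map a column index back to its (tau, within-block concept index)."""
        for tau, (a, b) in self.blocks:
            if a <= j < b:
                return tau, j - a
        raise IndexError(j)


def expand(
    blocks_by_index: dict[int, SimilarityBlock],
    q_index: int,
    p_index: int,
    delta_tau: float = 0.1,
) -> ExpandedEmbedding:
    """Concatenate the similarity blocks for tau = q*dtau .. p*dtau.

    ``blocks_by_index`` is keyed by the integer window-size index (tau as a
    multiple of ``delta_tau``).  Blocks are stacked in increasing tau and
    every output column is book-kept to (tau, concept, source trial, source
    window) so the mapping is a bijection.
    """
    if q_index > p_index:
        raise ParameterError("q_index must not exceed p_index")
    feats, blocks, col_info, col_times = [], [], [], []
    col = 0
    n_bags = None
    for i in range(q_index, p_index + 1):
        if i not in blocks_by_index:
            raise DataError(f"missing similarity block for window-size index {i}")
        blk = blocks_by_index[i]
        if n_bags is None:
            n_bags = blk.n_bags
        elif blk.n_bags != n_bags:
            raise DataError("blocks disagree on bag count")
        feats.append(blk.matrix)
        blocks.append((blk.tau, (col, col + blk.n_concepts)))
        times = (blk.concept_times if blk.concept_times is not None
                 else np.full(blk.n_concepts, np.nan))
        for k in range(blk.n_concepts):
            src = (blk.dictionary.source_index[k]
                   if blk.dictionary is not None else (-1, -1))
            col_info.append((blk.tau, k, src[0], src[1]))
        col_times.append(np.asarray(times, dtype=float))
        col += blk.n_concepts
    return ExpandedEmbedding(
        features=np.concatenate(feats, axis=1),
        blocks=blocks,
        q_index=q_index,
        p_index=p_index,
        delta_tau=delta_tau,
        column_info=col_info,
        column_times=np.concatenate(col_times),
    )


def n_expansion_configs(n_sizes: int) -> int:
    """Number of admissible contiguous (q, p) ranges over ``n_sizes`` sizes."""
    return n_sizes * (n_sizes + 1) // 2


def select_sigma(
    pool: np.ndarray,
    rule: str = "median",
    seed: int = 0,
    max_points: int = 2000,
    sigma: float | None = None,
) -> SimilarityParams:
    """Kernel bandwidth from the instance pool.

    ``median`` sets sigma^2 to the median squared pairwise distance over a
    seeded subsample of at most ``max_points`` instances — the standard
    median heuristic, equivariant under global scaling of the atoms.
    ``fixed`` passes ``sigma`` through.
    """
    if rule == "fixed":
        if sigma is None:
            raise ParameterError("fixed rule requires an explicit sigma")
        return SimilarityParams(sigma=float(sigma), rule="fixed")
    if rule != "median":
        raise ParameterError(f"unknown sigma rule {rule!r}")
    pool = np.asarray(pool, dtype=np.float64)
    if pool.ndim != 2 or pool.shape[0] < 2:
        raise ParameterError("need at least two instances to set sigma")
    if pool.shape[0] > max_points:
        rng = np.random.default_rng(seed)
        pool = pool[rng.choice(pool.shape[0], max_points, replace=False)]
    d2 = pdist(pool, metric="sqeuclidean")
    med = float(np.median(d2))
    if med <= 0:
        raise ParameterError("degenerate instance pool (all instances identical)")
    return SimilarityParams(sigma=float(np.sqrt(med)), rule="median")
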