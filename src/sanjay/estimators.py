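"""scikit-learn-style estimators wrapping the embedding pipeline.

:class:`SanjayEmbedding` is the full synthesizer: threshold-network
construction, community detection, structural representation, bit-vector
synthesis and anchor placement behind a single ``fit``/``fit_transform``
surface.  :class:`ClassicalMDS` and :class:`RandomProjectionEmbedding` are
the two baselines with the same surface, so all three compose with sklearn
pipelines and model selection.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils import check_array, check_random_state

from . import evaluate, network, placement, structure, synthesis
from .io import HDPointCloud
from .structure import DistanceMatrix

__all__ = ["SanjayEmbedding", "ClassicalMDS", "RandomProjectionEmbedding"]


class SanjayEmbedding(BaseEstimator):
    """Low-distortion 2D/3D embedding synthesized by a decision procedure.

    Parameters
    ----------
    n_components : {2, 3}, default=2
        Target dimension of the visualization.
    n_bits : int, default=10
        Grid coordinate width b; coordinates live in ``[0, 2**n_bits - 1]``.
    block_bits : int, default=2
        Bits l fixed per refinement iteration (must divide ``n_bits``).
    epsilon : "auto" or float, default="auto"
        Multiplicative tolerance of the squared-distance band; ``"auto"``
        bisects for the smallest feasible value.
    epsilon_tol : float, default=0.01
        Resolution of the ``"auto"`` bisection.
    metric : {"manhattan", "euclidean"}, default="manhattan"
        Distance in the original channel space.
    strategy : {"auto", "direct", "network"}, default="auto"
        ``"direct"`` synthesizes the input points themselves (the small-
        sample benchmark regime); ``"network"`` runs the full
        threshold-network / community / structural-point pipeline and places
        every cell by multilateration; ``"auto"`` picks ``"direct"`` for at
        most 16 points.
    threshold : "auto" or float, default="auto"
        Network edge threshold T; ``"auto"`` maximizes degree entropy.
    walk_length : int, default=4
        Random-walk length of the community detection.
    node_budget : int, default=200_000
        Search budget per refinement step.
    random_state : int, default=0
        Master seed for all randomized substeps.

    Attributes
    ----------
    embedding_ : ndarray of shape (n_samples, n_components)
        Low-dimensional coordinates in data units.
    grid_embedding_ : GridEmbedding
        Integer grid coordinates of the structural points with scale/epsilon.
    epsilon_ : float
        Band tolerance actually used.
    scale_ : float
        Grid units per data unit.
    threshold_ : float or None
        Selected network threshold (network strategy only).
    labels_ : ndarray or None
        0-based community label per cell (network strategy only).
    """

    def __init__(
        self,
        n_components: int = 2,
        n_bits: int = 10,
        block_bits: int = 2,
        epsilon="auto",
        epsilon_tol: float = 0.01,
        metric: str = "manhattan",
        strategy: str = "auto",
        threshold="auto",
        walk_length: int = 4,
        node_budget: int = 200_000,
        random_state: int = 0,
    ):
        self.n_components = n_components
        self.n_bits = n_bits
        self.block_bits = block_bits
        self.epsilon = epsilon
        self.epsilon_tol = epsilon_tol
        self.metric = metric
        self.strategy = strategy
        self.threshold = threshold
        self.walk_length = walk_length
        self.node_budget = node_budget
        self.random_state = random_state

    def _synthesize(self, D: DistanceMatrix) -> None:
        kwargs = dict(
            target_dim=self.n_components,
            bits=self.n_bits,
            block=self.block_bits,
            node_budget=self.node_budget,
        )
        if self.epsilon == "auto":
            self.epsilon_, self.grid_embedding_ = synthesis.find_min_epsilon(
                D, tol=self.epsilon_tol, **kwargs
            )
        else:
            self.grid_embedding_ = synthesis.synthesize_embedding(
                D, epsilon=float(self.epsilon), **kwargs
            )
            self.epsilon_ = float(self.epsilon)
        self.scale_ = self.grid_embedding_.scale

    def fit(self, X, y=None):
        """Synthesize the embedding of X (events x channels)."""
        if self.n_components not in (2, 3):
            raise ValueError("n_components must be 2 or 3")
        X = check_array(X, dtype=np.float64, ensure_min_samples=2)
        seed = check_random_state(self.random_state).randint(2**31)
        cloud = HDPointCloud(X, tuple(f"c{i}" for i in range(X.shape[1])))

        strategy = self.strategy
        if strategy == "auto":
            strategy = "direct" if cloud.n_cells <= 16 else "network"
        if strategy == "direct":
            D = structure.pairwise_distance_matrix(
                structure.StructuralPoints(
                    cloud.values,
                    tuple("Q" for _ in range(cloud.n_cells)),
                    tuple(1 for _ in range(cloud.n_cells)),
                    1,
                ),
                self.metric,
            )
            self._synthesize(D)
            self.embedding_ = self.grid_embedding_.data_units
            self.threshold_ = None
            self.labels_ = None
            self.n_communities_ = None
        elif strategy == "network":
            if self.threshold == "auto":
                self.threshold_ = network.select_threshold(cloud, metric="manhattan")
            else:
                self.threshold_ = float(self.threshold)
            net = network.build_tfcn(cloud, self.threshold_, metric="manhattan")
            part = network.detect_communities(net, self.walk_length, seed)
            self.labels_ = part.labels - 1
            self.n_communities_ = part.n_communities
            sp = structure.build_structural_points(
                cloud, part, self.n_components, seed
            )
            self.structural_points_ = sp
            D = structure.pairwise_distance_matrix(sp, self.metric)
            self._synthesize(D)
            placed = placement.project_all_points(
                cloud, part, sp, self.grid_embedding_, self.metric
            )
            self.embedding_ = placed.data_units
        else:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        self.n_iter_ = self.grid_embedding_.iterations
        return self

    def fit_transform(self, X, y=None):
        """Fit and return the low-dimensional coordinates in data units."""
        return self.fit(X).embedding_

    def score(self, X=None, y=None):
        """Negative maximum additive distortion of the fitted embedding."""
        if X is None:
            raise ValueError("score requires the fitted data X")
        rep = evaluate.distortion_summary(
            np.asarray(X, dtype=float), self.embedding_, self.metric
        )
        return -rep.max_distortion


class ClassicalMDS(BaseEstimator):
    """Torgerson classical scaling with the same surface as the synthesizer.

    Parameters
    ----------
    n_components : int, default=2
    dissimilarity : {"manhattan", "euclidean", "precomputed"}, default="manhattan"
        Metric used to form the distance matrix, or "precomputed" if X
        already is one.
    """

    def __init__(self, n_components: int = 2, dissimilarity: str = "manhattan"):
        self.n_components = n_components
        self.dissimilarity = dissimilarity

    def fit(self, X, y=None):
        X = check_array(X, dtype=np.float64)
        if self.dissimilarity == "precomputed":
            D = X
        else:
            D = network.pairwise_distances(X, self.dissimilarity)
        self.dissimilarity_matrix_ = D
        self.embedding_ = evaluate.classical_mds(D, self.n_components)
        return self

    def fit_transform(self, X, y=None):
        return self.fit(X).embedding_


class RandomProjectionEmbedding(TransformerMixin, BaseEstimator):
    """Gaussian random projection onto ``n_components`` dimensions.

    The projection matrix has i.i.d. N(0, 1/n_components) entries, so
    squared Euclidean distances are preserved in expectation
    (Johnson-Lindenstrauss).  A true transformer: the fitted matrix applies
    to new data.
    """

    def __init__(self, n_components: int = 2, random_state: int = 0):
        self.n_components = n_components
        self.random_state = random_state

    def fit(self, X, y=None):
        X = check_array(X, dtype=np.float64)
        m = X.shape[1]
        if not self.n_components < m:
            raise ValueError(
                f"n_components={self.n_components} must be below the input dimension {m}"
            )
        from ._utils import substream

        rng = substream(int(self.random_state or 0), "rp")
        self.components_ = rng.standard_normal((m, self.n_components)) / np.sqrt(
            self.n_components
        )
        self.n_features_in_ = m
        return self

    def transform(self, X):
        X = check_array(X, dtype=np.float64)
        return X @ self.components_
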