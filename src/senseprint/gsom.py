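"""Growing Self-Organizing Map (GSOM).

A SOM variant that starts from a minimal 2x2 lattice and inserts nodes
wherever accumulated quantization error exceeds a growth threshold

    GT = -D * ln(SF),

with D the input dimensionality and SF the spread factor in (0, 1).
Higher spread factors give lower thresholds, hence larger, more detailed
maps; lower spread factors keep only the most prominent structure.

Training has two phases.  The growing phase presents inputs in a seeded
shuffled order; each presentation updates the best-matching unit (BMU)
and its lattice neighbours with a Gaussian neighbourhood kernel and adds
the matching error to the BMU's accumulated error.  A BMU whose
accumulated error exceeds GT either spawns nodes into all free
4-neighbour positions (boundary node) or, when fully surrounded, halves
its error and distributes it to its lattice neighbours.  The smoothing
phase then refines weights at a low learning rate with the neighbourhood
shrunk to radius 1 and no growth.

Inputs are expected in [0, 1] (see :mod:`senseprint.preprocess`); all
weights remain in [0, 1] throughout, since updates are convex
combinations and spawned weights are clipped.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_is_fitted

_NEIGHBOUR_OFFSETS = ((1, 0), (-1, 0), (0, 1), (0, -1))


def growth_threshold(spread_factor: float, n_features: int) -> float:
    """GT = -D * ln(SF): the accumulated-error level that triggers growth.

    Strictly decreasing in the spread factor and linear in the feature
    count, so wider inputs tolerate proportionally more error per node.
    """
    if not 0.0 < spread_factor < 1.0:
        raise ValueError(f"spread_factor must lie in (0, 1), got {spread_factor}")
    if n_features < 1:
        raise ValueError(f"n_features must be >= 1, got {n_features}")
    return -float(n_features) * float(np.log(spread_factor))


class GrowingSOM(ClusterMixin, BaseEstimator):
    """Growing Self-Organizing Map over a 2D integer lattice.

    Parameters
    ----------
    spread_factor : float in (0, 1), default 0.9
        Controls map growth through ``GT = -D ln(SF)``.
    growing_epochs, smoothing_epochs : int
        Passes over the data in the growing / smoothing phase.
    initial_learning_rate : float in (0, 1]
        Growing-phase learning rate; decays linearly to 0 across epochs.
    smoothing_learning_rate : float in (0, 1]
        Constant learning rate of the smoothing phase.
    initial_radius : float
        Neighbourhood radius at the first growing epoch; decays linearly
        to 1, and is fixed at 1 during smoothing.
    error_distribution_factor : float in (0, 1)
        Fraction of error passed to each neighbour when a saturated
        (non-boundary) node exceeds the growth threshold.
    random_state : int
        Seed for weight initialization, presentation order and spawn
        perturbations; training is deterministic given data and params.

    Attributes
    ----------
    positions_ : (n_nodes, 2) int array of lattice coordinates.
    weights_ : (n_nodes, n_features) array in [0, 1].
    accumulated_error_ : (n_nodes,) array.
    hit_counts_ : (n_nodes,) int array, BMU hits of the training data on
        the final map.
    labels_ : (n_samples,) BMU index of each training row.
    """

    def __init__(
        self,
        spread_factor: float = 0.9,
        growing_epochs: int = 30,
        smoothing_epochs: int = 20,
        initial_learning_rate: float = 0.3,
        smoothing_learning_rate: float = 0.05,
        initial_radius: float = 3.0,
        error_distribution_factor: float = 0.5,
        random_state: int = 0,
    ):
        self.spread_factor = spread_factor
        self.growing_epochs = growing_epochs
        self.smoothing_epochs = smoothing_epochs
        self.initial_learning_rate = initial_learning_rate
        self.smoothing_learning_rate = smoothing_learning_rate
        self.initial_radius = initial_radius
        self.error_distribution_factor = error_distribution_factor
        self.random_state = random_state

    # ------------------------------------------------------------------ fit

    def _validate_params_(self):
        if not 0.0 < self.spread_factor < 1.0:
            raise ValueError(f"spread_factor must lie in (0, 1), got {self.spread_factor}")
        for name in ("initial_learning_rate", "smoothing_learning_rate"):
            lr = getattr(self, name)
            if not 0.0 < lr <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1], got {lr}")
        if self.growing_epochs < 1 or self.smoothing_epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not 0.0 < self.error_distribution_factor < 1.0:
            raise ValueError("error_distribution_factor must lie in (0, 1)")

    def fit(self, X, y=None):
        """Train the map on rows of ``X`` (values in [0, 1])."""
        self._validate_params_()
        X = np.asarray(getattr(X, "values", X), dtype=float)
        if X.ndim != 2 or X.shape[0] < 1:
            raise ValueError("X must be a non-empty 2D array")
        if X.min() < -1e-12 or X.max() > 1 + 1e-12:
            raise ValueError("GSOM inputs must be normalized to [0, 1]")
        n, d = X.shape
        rng = np.random.default_rng(self.random_state)
        gt = growth_threshold(self.spread_factor, d)

        # initial 2x2 lattice with uniform-random weights
        positions = [(0, 0), (1, 0), (0, 1), (1, 1)]
        occupied = set(positions)
        pos = np.array(positions, dtype=int)
        W = rng.random((4, d))
        err = np.zeros(4)

        def bmu_index(x):
            d2 = ((W - x) ** 2).sum(axis=1)
            best = d2.min()
            ties = np.flatnonzero(d2 == best)
            if len(ties) == 1:
                return ties[0], best
            # lexicographically smallest (y, x) position wins
            win = min(ties, key=lambda i: (pos[i, 1], pos[i, 0]))
            return int(win), best

        def neighbourhood_update(x, bi, lr, radius):
            nonlocal W
            ld2 = ((pos - pos[bi]) ** 2).sum(axis=1).astype(float)
            within = ld2 <= radius * radius + 1e-12
            sigma2 = max(radius, 1e-9) ** 2 / 2.0
            h = np.exp(-ld2[within] / (2.0 * sigma2))
            W[within] += lr * h[:, None] * (x - W[within])

        def spawn(parent_idx):
            """Grow into every free 4-neighbour of a boundary node."""
            nonlocal pos, W, err, occupied
            px, py = pos[parent_idx]
            new_rows = []
            for dx, dy in _NEIGHBOUR_OFFSETS:
                tgt = (px + dx, py + dy)
                if tgt in occupied:
                    continue
                w_new = self._new_weight(pos, W, occupied, parent_idx, (dx, dy), rng)
                occupied.add(tgt)
                new_rows.append((tgt, w_new))
            if new_rows:
                pos = np.vstack([pos, np.array([r[0] for r in new_rows], dtype=int)])
                W = np.vstack([W, np.array([r[1] for r in new_rows])])
                err = np.concatenate([err, np.zeros(len(new_rows))])
            return bool(new_rows)

        pos_lookup = None  # rebuilt lazily for neighbour error distribution

        # growing phase
        ge = self.growing_epochs
        for t in range(ge):
            lr = self.initial_learning_rate * (1.0 - t / ge)
            if ge > 1:
                radius = self.initial_radius + (1.0 - self.initial_radius) * t / (ge - 1)
            else:
                radius = self.initial_radius
            radius = max(radius, 1.0)
            for i in rng.permutation(n):
                x = X[i]
                bi, best_d2 = bmu_index(x)
                neighbourhood_update(x, bi, lr, radius)
                err[bi] += np.sqrt(best_d2)
                if err[bi] > gt:
                    grew = spawn(bi)
                    if grew:
                        err[bi] = gt / 2.0
                    else:
                        # saturated node: halve and push error to neighbours
                        err[bi] /= 2.0
                        pos_lookup = {tuple(p): j for j, p in enumerate(pos)}
                        px, py = pos[bi]
                        for dx, dy in _NEIGHBOUR_OFFSETS:
                            j = pos_lookup.get((px + dx, py + dy))
                            if j is not None:
                                err[j] *= 1.0 + self.error_distribution_factor
        self.n_nodes_after_growth_ = len(pos)
        self.quantization_error_after_growth_ = float(
            np.mean(
                [np.sqrt(((W - x) ** 2).sum(axis=1).min()) for x in X]
            )
        )

        # smoothing phase: no growth, fixed small LR, radius 1
        for _ in range(self.smoothing_epochs):
            for i in rng.permutation(n):
                x = X[i]
                bi, _ = bmu_index(x)
                neighbourhood_update(x, bi, self.smoothing_learning_rate, 1.0)

        W = np.clip(W, 0.0, 1.0)
        self.positions_ = pos
        self.weights_ = W
        self.accumulated_error_ = err
        self.n_features_in_ = d
        self.labels_ = self.predict(X)
        self.hit_counts_ = np.bincount(self.labels_, minlength=len(pos))
        return self

    @staticmethod
    def _new_weight(pos, W, occupied, parent_idx, direction, rng):
        """Weight for a node spawned from ``parent_idx`` toward ``direction``.

        Case 1: a neighbour opposite the growth direction exists ->
        linear extrapolation ``2 w_parent - w_opposite``.  Case 2: a
        neighbour on the orthogonal axis exists -> average with it.
        Case 3: isolated -> parent plus a small seeded perturbation.
        Result clipped to [0, 1].
        """
        lookup = {tuple(p): j for j, p in enumerate(pos)}
        px, py = pos[parent_idx]
        dx, dy = direction
        opposite = lookup.get((px - dx, py - dy))
        if opposite is not None:
            w = 2.0 * W[parent_idx] - W[opposite]
        else:
            # orthogonal axis neighbours of the parent
            ortho = [(px + dy, py + dx), (px - dy, py - dx)]
            cand = next((lookup[o] for o in ortho if o in lookup), None)
            if cand is not None:
                w = 0.5 * (W[parent_idx] + W[cand])
            else:
                pert = rng.standard_normal(W.shape[1])
                pert /= np.linalg.norm(pert)
                w = W[parent_idx] + 0.05 * pert
        return np.clip(w, 0.0, 1.0)

    def new_node_weights(self, parent: int, position: tuple[int, int]) -> np.ndarray:
        """Weight vector a node spawned from ``parent`` at ``position``
        would receive (see :meth:`_new_weight` for the three cases).

        ``position`` must be a free 4-neighbour of the parent node.
        """
        check_is_fitted(self, "weights_")
        px, py = self.positions_[parent]
        dx, dy = position[0] - px, position[1] - py
        if (abs(dx), abs(dy)) not in ((0, 1), (1, 0)):
            raise ValueError(f"{position} is not a 4-neighbour of node {parent}")
        occupied = {tuple(p) for p in self.positions_}
        if tuple(position) in occupied:
            raise ValueError(f"position {position} is already occupied")
        return self._new_weight(
            self.positions_, self.weights_, occupied, parent, (dx, dy),
            np.random.default_rng(self.random_state),
        )

    # ------------------------------------------------------- inference API

    def predict(self, X) -> np.ndarray:
        """BMU (node index) of each row of ``X``."""
        check_is_fitted(self, "weights_")
        X = np.asarray(getattr(X, "values", X), dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X must have {self.n_features_in_} columns, got shape {X.shape}"
            )
        labels = np.empty(len(X), dtype=int)
        for i, x in enumerate(X):
            d2 = ((self.weights_ - x) ** 2).sum(axis=1)
            best = d2.min()
            ties = np.flatnonzero(d2 == best)
            if len(ties) == 1:
                labels[i] = ties[0]
            else:
                labels[i] = min(
                    ties, key=lambda j: (self.positions_[j, 1], self.positions_[j, 0])
                )
        return labels

    def best_matching_unit(self, x) -> tuple[int, float]:
        """BMU index and Euclidean distance for a single feature vector.

        Ties are broken by the lexicographically smallest (y, x) lattice
        position.
        """
        check_is_fitted(self, "weights_")
        x = np.asarray(x, dtype=float)
        if x.shape != (self.n_features_in_,):
            raise ValueError(
                f"x must have shape ({self.n_features_in_},), got {x.shape}"
            )
        idx = int(self.predict(x[None, :])[0])
        return idx, float(np.linalg.norm(self.weights_[idx] - x))

    def quantization_error(self, X) -> float:
        """Mean Euclidean distance from rows of ``X`` to their BMUs."""
        check_is_fitted(self, "weights_")
        X = np.asarray(getattr(X, "values", X), dtype=float)
        if X.ndim != 2 or len(X) == 0:
            raise ValueError("X must be a non-empty 2D array")
        labels = self.predict(X)
        return float(np.mean(np.linalg.norm(X - self.weights_[labels], axis=1)))

    @property
    def n_nodes_(self) -> int:
        check_is_fitted(self, "weights_")
        return len(self.weights_)

    def to_frame(self):
        """Node map as a DataFrame: node_id, pos_x, pos_y, hit_count, weight_*."""
        import pandas as pd

        check_is_fitted(self, "weights_")
        df = pd.DataFrame(
            {
                "node_id": np.arange(self.n_nodes_),
                "pos_x": self.positions_[:, 0],
                "pos_y": self.positions_[:, 1],
                "hit_count": self.hit_counts_,
            }
        )
        for j in range(self.n_features_in_):
            df[f"weight_{j}"] = self.weights_[:, j]
        return df
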