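"""Worm-like-chain conformations of surface-deposited DNA.

DNA equilibrated on mica is modelled as a discrete 2D worm-like chain:
per-step turning angles are zero-mean Gaussians with variance
``segment_length / persistence_length``, which gives the 2D tangent
correlation ``<t(0).t(s)> = exp(-s / 2P)`` and the closed-form mean
squared end-to-end distance

    <R^2> = 4 P L (1 - (2P/L) (1 - exp(-L / 2P)))

used as the independent oracle for the sampler.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import InvalidConfigError, InvalidSiteError

__all__ = [
    "ChainConformation",
    "sample_chain",
    "sample_wlc_chain",
    "impose_bend",
    "mean_sq_end_to_end_2d",
]


@dataclass(frozen=True)
class ChainConformation:
    """Ordered 2D backbone of one DNA molecule.

    ``nodes`` is an ``(n_nodes, 2)`` array of (x, y) positions in nm with
    constant spacing ``segment_length`` along the backbone.
    """

    nodes: np.ndarray
    segment_length: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "nodes",
                           np.asarray(self.nodes, dtype=float))
        if self.nodes.ndim != 2 or self.nodes.shape[1] != 2:
            raise InvalidConfigError("nodes must be an (n, 2) array")
        if self.nodes.shape[0] < 3:
            raise InvalidConfigError("a chain needs at least 2 segments")
        if not self.segment_length > 0:
            raise InvalidConfigError("segment_length must be > 0")

    @property
    def n_segments(self) -> int:
        return self.nodes.shape[0] - 1

    @property
    def arclength(self) -> np.ndarray:
        """Cumulative arclength per node (nm); strictly increasing."""
        return np.arange(self.nodes.shape[0]) * self.segment_length

    @property
    def contour_length(self) -> float:
        """Exactly n_segments * segment_length."""
        return self.n_segments * self.segment_length

    def end_to_end_distance(self) -> float:
        return float(np.hypot(*(self.nodes[-1] - self.nodes[0])))


def sample_chain(n_segments: int, segment_length: float,
                 persistence_length: float,
                 rng: np.random.Generator) -> ChainConformation:
    """Sample one 2D-equilibrated worm-like chain starting at the origin."""
    if n_segments < 2:
        raise InvalidConfigError("need at least 2 segments")
    if not (segment_length > 0 and persistence_length > 0):
        raise InvalidConfigError("lengths must be > 0")
    sigma = np.sqrt(segment_length / persistence_length)
    turns = rng.normal(0.0, sigma, size=n_segments - 1)
    heading0 = rng.uniform(0.0, 2.0 * np.pi)
    headings = heading0 + np.concatenate(([0.0], np.cumsum(turns)))
    steps = segment_length * np.column_stack(
        (np.cos(headings), np.sin(headings)))
    nodes = np.vstack((np.zeros(2), np.cumsum(steps, axis=0)))
    return ChainConformation(nodes=nodes, segment_length=segment_length)


def sample_wlc_chain(config, rng: np.random.Generator) -> ChainConformation:
    """Sample a chain with the substrate geometry of a generator config.

    One node per base pair: 505 bp at 0.34 nm rise gives a 171.7 nm
    contour exactly.
    """
    return sample_chain(config.dna_length_bp, config.rise_per_bp,
                        config.persistence_length, rng)


def _signed_turn(v_in: np.ndarray, v_out: np.ndarray) -> float:
    """Signed deflection from collinearity between two segment vectors."""
    return float(np.arctan2(v_in[0] * v_out[1] - v_in[1] * v_out[0],
                            v_in @ v_out))


def impose_bend(chain: ChainConformation, node_index: int,
                angle_deg: float, direction: float = 1.0) -> ChainConformation:
    """Rigidly rotate the downstream arm so the local deflection from
    collinearity at ``node_index`` equals ``angle_deg``.

    ``direction`` selects the turning sense (+1 counter-clockwise).
    Arclengths are preserved exactly (rigid rotation).  The node must be
    interior to the chain.
    """
    n = chain.nodes.shape[0]
    if not (0 < node_index < n - 1):
        raise InvalidSiteError(
            f"bend site {node_index} must be interior to the chain (1..{n - 2})")
    nodes = chain.nodes.copy()
    pivot = nodes[node_index]
    v_in = pivot - nodes[node_index - 1]
    v_out = nodes[node_index + 1] - pivot
    current = _signed_turn(v_in, v_out)
    target = np.sign(direction if direction != 0 else 1.0) * np.deg2rad(
        abs(angle_deg))
    rot = target - current
    c, s = np.cos(rot), np.sin(rot)
    R = np.array([[c, -s], [s, c]])
    downstream = nodes[node_index + 1:] - pivot
    nodes[node_index + 1:] = downstream @ R.T + pivot
    return ChainConformation(nodes=nodes, segment_length=chain.segment_length)


def mean_sq_end_to_end_2d(contour_length: float,
                          persistence_length: float) -> float:
    """Closed-form <R^2> of a 2D worm-like chain (nm^2)."""
    L, P = float(contour_length), float(persistence_length)
    if not (L > 0 and P > 0):
        raise InvalidConfigError("lengths must be > 0")
    x = L / (2.0 * P)
    return 4.0 * P * L * (1.0 - (1.0 / x) * (1.0 - np.exp(-x)))
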