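"""Loopy sum-product belief propagation on pairwise Markov random fields.

Variables carry a unary potential over a finite domain; edges carry an
explicit pairwise potential matrix. Messages are passed variable-to-variable
in a fixed flooding schedule (sorted edge order) with damping, so runs are
deterministic. On acyclic graphs the fixed point is the exact marginal.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np


@dataclass
class BPResult:
    marginals: list[np.ndarray]
    iterations: int
    converged: bool
    final_delta: float


@dataclass
class PairwiseMRF:
    unaries: list[np.ndarray] = field(default_factory=list)
    edges: dict[tuple[int, int], np.ndarray] = field(default_factory=dict)

    def add_variable(self, unary) -> int:
        u = np.asarray(unary, dtype=float)
        if u.ndim != 1 or np.any(u < 0) or u.sum() == 0:
            raise ValueError("unary potential must be a non-negative 1-D array "
                             "with positive mass")
        self.unaries.append(u / u.sum())
        return len(self.unaries) - 1

    def add_edge(self, i: int, j: int, psi) -> None:
        """Attach pairwise potential psi[x_i, x_j] between variables i < j."""
        if i == j:
            raise ValueError("self-edges are not allowed")
        if i > j:
            i, j, psi = j, i, np.asarray(psi, dtype=float).T
        psi = np.asarray(psi, dtype=float)
        expected = (len(self.unaries[i]), len(self.unaries[j]))
        if psi.shape != expected:
            raise ValueError(f"psi shape {psi.shape} != {expected}")
        if (i, j) in self.edges:
            self.edges[(i, j)] = self.edges[(i, j)] * psi
        else:
            self.edges[(i, j)] = psi

    # ------------------------------------------------------------------
    def run_bp(self, max_iters: int = 200, damping: float = 0.5,
               message_tol: float = 1e-6) -> BPResult:
        """Damped flooding sum-product; returns normalized marginals."""
        directed = []
        for (i, j), psi in sorted(self.edges.items()):
            directed.append((i, j, psi))
            directed.append((j, i, psi.T))
        messages = {(a, b): np.ones_like(self.unaries[b]) / len(self.unaries[b])
                    for a, b, _ in directed}
        tiny = 1e-300
        final_delta = 0.0
        iterations = 0
        converged = False
        base_damping = damping
        beliefs = [None] * len(self.unaries)
        for it in range(1, max_iters + 1):
            iterations = it
            # escalate damping on stubborn (oscillating) graphs
            if it > max_iters // 3:
                damping = max(base_damping, 0.7)
            if it > (2 * max_iters) // 3:
                damping = max(base_damping, 0.9)
            # node beliefs once per sweep, then divide out the reverse message
            for v, u in enumerate(self.unaries):
                belief = u.copy()
                beliefs[v] = belief
            for (src, dst), msg in messages.items():
                beliefs[dst] = beliefs[dst] * msg
            new_messages = {}
            delta = 0.0
            for a, b, psi in directed:
                pre = beliefs[a] / np.maximum(messages[(b, a)], tiny)
                m = psi.T @ pre
                z = m.sum()
                m = m / z if z > 0 else np.ones_like(m) / len(m)
                old = messages[(a, b)]
                m = damping * old + (1.0 - damping) * m
                delta = max(delta, float(np.max(np.abs(m - old))))
                new_messages[(a, b)] = m
            messages = new_messages
            final_delta = delta
            if delta < message_tol:
                converged = True
                break
        marginals = []
        for v, u in enumerate(self.unaries):
            belief = u.copy()
            for (src, dst), msg in messages.items():
                if dst == v:
                    belief = belief * msg
            z = belief.sum()
            marginals.append(belief / z if z > 0 else np.ones_like(belief) / len(belief))
        return BPResult(marginals, iterations, converged, final_delta)

    # ------------------------------------------------------------------
    def enumerate_exact(self) -> list[np.ndarray]:
        """Exact marginals by summing over every joint configuration.

        Independent oracle for the message-passing code; only feasible for
        tiny models.
        """
        sizes = [len(u) for u in self.unaries]
        marginals = [np.zeros(s) for s in sizes]
        total = 0.0
        for config in itertools.product(*(range(s) for s in sizes)):
            w = 1.0
            for v, x in enumerate(config):
                w *= self.unaries[v][x]
            for (i, j), psi in self.edges.items():
                w *= psi[config[i], config[j]]
            total += w
            for v, x in enumerate(config):
                marginals[v][x] += w
        if total == 0.0:
            return [np.ones(s) / s for s in sizes]
        return [m / total for m in marginals]
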