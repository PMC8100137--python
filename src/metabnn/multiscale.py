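"""Multi-timescale metaplastic synapse: a diffusion chain of hidden variables.

Each synapse carries a chain ``u_1 ... u_N``.  Only ``u_1`` receives training
updates and only ``sign(u_1)`` is read out as the binary weight; deeper
levels exchange value with their neighbours through coupling conductances
that decay geometrically with depth (``g_k ~ 2^(-2k)``), so they integrate
the training history on progressively slower timescales.  Consolidation
stored deep in the chain leaks back slowly, which turns the hard, definitive
consolidation of the scalar hidden weight into a graceful steady-state
forgetting: old tasks fade first while the most recent stays sharpest.

The flow between levels can be modulated by a gain function of the local
state (neutral gain 1 recovers the plain diffusion chain); this is the hook
for richer metaplastic rules.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

__all__ = ["ChainSynapse", "geometric_couplings"]


def geometric_couplings(n_levels: int, g0: float = 1.0, ratio: float = 0.25):
    """Couplings ``g_{k,k+1} = g0 * ratio^k`` (default ratio ``2^-2``),
    positive and strictly decreasing with depth."""
    if n_levels < 2:
        raise ValueError("a chain needs at least 2 levels")
    return g0 * ratio ** np.arange(n_levels - 1)


@dataclass
class ChainSynapse:
    """A tensor of beaker-chain synapses.

    ``u`` has shape ``(N, *shape)``; ``u[0]`` is the hidden weight.  ``gain``
    maps the flow magnitude array to a multiplicative modulation (default
    neutral).
    """

    u: np.ndarray
    couplings: np.ndarray
    gain: Optional[Callable[[np.ndarray], np.ndarray]] = None

    @classmethod
    def zeros(cls, shape, n_levels: int = 4, g0: float = 1.0, ratio: float = 0.25,
              gain=None):
        return cls(u=np.zeros((n_levels, *shape)),
                   couplings=geometric_couplings(n_levels, g0, ratio), gain=gain)

    @property
    def n_levels(self) -> int:
        return self.u.shape[0]

    @property
    def hidden(self) -> np.ndarray:
        return self.u[0]

    def binary(self) -> np.ndarray:
        return np.where(self.u[0] >= 0.0, 1.0, -1.0)

    def step(self, external_update: np.ndarray | float = 0.0, dt: float = 1.0):
        """Apply the training update to ``u_1`` then relax the chain.

        Interior levels follow the discrete diffusion
        ``du_k = dt * [g_{k-1,k} (u_{k-1} - u_k) + g_{k,k+1} (u_{k+1} - u_k)]``
        with one-sided boundary terms; the modulation gain multiplies each
        inter-level flow.
        """
        if not np.all(np.isfinite(self.u)):
            raise ValueError("chain state is non-finite")
        u = self.u
        u[0] += external_update
        flows = []
        for k in range(self.n_levels - 1):
            flow = self.couplings[k] * (u[k] - u[k + 1])
            if self.gain is not None:
                flow = flow * self.gain(flow)
            flows.append(flow)
        new = u.copy()
        for k in range(self.n_levels):
            if k < self.n_levels - 1:
                new[k] -= dt * flows[k]
            if k > 0:
                new[k] += dt * flows[k - 1]
        u[...] = new  # in place, so external views of u[0] stay valid
        return self.u
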