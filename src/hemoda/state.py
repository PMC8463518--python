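"""Flatten staggered velocity fields to state vectors and back.

The assimilation state contains the free interior face velocities only
(faces strictly between two fluid cells).  Wall faces are identically zero and
port faces are boundary conditions, so neither belongs in the state; the codec
restores them from a template field when unpacking.  Each state component has
a physical coordinate used for observation localization.
"""

from __future__ import annotations

import numpy as np

from .geometry import GeometryMask
from .solver import FlowSolver, VelocityField


class StateIndex:
    """Bidirectional map between VelocityField free faces and a flat vector."""

    def __init__(self, geom: GeometryMask, solver: FlowSolver | None = None):
        self.geom = geom
        sol = solver if solver is not None else FlowSolver(geom)
        self.u_free = sol.u_free
        self.v_free = sol.v_free
        self.n_u = int(self.u_free.sum())
        self.n_v = int(self.v_free.sum())
        self.size = self.n_u + self.n_v
        h = geom.spacing
        iu, ju = np.nonzero(self.u_free)
        iv, jv = np.nonzero(self.v_free)
        self.coords = np.concatenate(
            [
                np.column_stack([iu * h, (ju + 0.5) * h]),
                np.column_stack([(iv + 0.5) * h, jv * h]),
            ]
        )

    def pack(self, field: VelocityField) -> np.ndarray:
        return np.concatenate([field.u[self.u_free], field.v[self.v_free]])

    def unpack(self, vec: np.ndarray, template: VelocityField) -> VelocityField:
        """Rebuild a field: free faces from ``vec``, walls zero, port faces and
        pressure copied from ``template``."""
        out = template.copy()
        out.u[self.u_free] = vec[: self.n_u]
        out.v[self.v_free] = vec[self.n_u :]
        return out
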