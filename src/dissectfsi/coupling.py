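"""Implicit velocity-correction immersed-boundary coupling.

No-slip on moving walls is enforced implicitly: with the intermediate
velocity v* from the collide/stream pass, the marker corrections dV solve

    A dV = V_wall - I(v*),        A = I o S,

where I interpolates Eulerian fields to markers with a 4-point Peskin
cosine kernel and S spreads marker quantities back with the axisymmetric
metric (ds * R / r), making S the adjoint of I in the cylindrical inner
product.  After applying dv = S(dV) the interpolated fluid velocity equals
the wall velocity to solver tolerance.  The Eulerian force density follows
from f = 2 rho dv / dt and the reaction on the wall is F_L = -2 rho dV / dt
per unit wall area (exact action-reaction by construction).

Markers are ordered once by rest axial position, which makes A banded: only
markers within one kernel support (4 lattice units) interact, including
pairs on different walls (septum vs. outer wall) when they come close.
The banded system is re-assembled and factorized every step by a compiled
LU without pivoting; at marker spacings above one lattice unit A is well
conditioned (sub-lattice spacing would make neighboring markers
indistinguishable on the grid and A numerically singular).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from dissectfsi import _kernels as K


@dataclass(frozen=True)
class IBKernel:
    """Regularized delta kernel (family + support width in lattice units)."""

    name: str = "peskin4"
    support: int = 4

    def __call__(self, q):
        q = np.asarray(q, dtype=float)
        out = np.where(np.abs(q) <= 2.0, 0.25 * (1.0 + np.cos(0.5 * np.pi * q)), 0.0)
        return out


def interpolate(field, markers, nx=None, nr=None):
    """Kernel-weighted interpolation of an Eulerian field to marker points.

    ``markers`` are lattice coordinates (x, r) with node j at r = j + 1/2.
    """
    field = np.asarray(field, dtype=float)
    markers = np.atleast_2d(np.asarray(markers, dtype=float))
    nx = field.shape[0] if nx is None else nx
    nr = field.shape[1] if nr is None else nr
    n = markers.shape[0]
    ii = np.empty((n, 4), dtype=np.int64)
    jj = np.empty((n, 4), dtype=np.int64)
    wx = np.empty((n, 4))
    wr = np.empty((n, 4))
    K.ib_weights(markers, nx, nr, ii, jj, wx, wr)
    out = np.empty(n)
    K.ib_interpolate(field, ii, jj, wx, wr, out)
    return out


def spread(values, markers, ds, shape):
    """Adjoint of :func:`interpolate`: spread marker values (weighted by the
    arclength element ds and the marker radius R) onto the grid."""
    markers = np.atleast_2d(np.asarray(markers, dtype=float))
    values = np.asarray(values, dtype=float)
    ds = np.broadcast_to(np.asarray(ds, dtype=float), (markers.shape[0],))
    nx, nr = shape
    n = markers.shape[0]
    ii = np.empty((n, 4), dtype=np.int64)
    jj = np.empty((n, 4), dtype=np.int64)
    wx = np.empty((n, 4))
    wr = np.empty((n, 4))
    K.ib_weights(markers, nx, nr, ii, jj, wx, wr)
    field = np.zeros(shape)
    K.ib_spread(field, values, ii, jj, wx, wr, ds * markers[:, 1])
    return field


class CouplingSystem:
    """Square velocity-correction system for a fixed set of markers.

    The marker population (counts and rest positions) is fixed at
    construction; positions and velocities are updated every step.
    """

    def __init__(self, nx, nr, X_rest, support=4, bw_margin=2, solid=None):
        self.nx, self.nr = int(nx), int(nr)
        self.solid = (np.zeros((self.nx, self.nr), dtype=np.bool_)
                      if solid is None else solid.astype(np.bool_))
        X_rest = np.asarray(X_rest, dtype=float)
        self.n = X_rest.shape[0]
        if self.n < 1:
            raise ValueError("need at least one marker")
        # fixed ordering by rest axial position -> banded interaction matrix
        self.perm = np.argsort(X_rest[:, 0], kind="stable")
        self.iperm = np.argsort(self.perm, kind="stable")
        self.active = np.ones(self.n, dtype=bool)
        self.support = support
        self.bw_margin = float(bw_margin)
        self.ii = np.empty((self.n, 4), dtype=np.int64)
        self.jj = np.empty((self.n, 4), dtype=np.int64)
        self.wx = np.empty((self.n, 4))
        self.wr = np.empty((self.n, 4))
        self._Ab = None
        self._bw = 0
        self.last_residual = 0.0

    def update_markers(self, X, ds):
        """Refresh kernel weights and the banded matrix for current marker
        positions (lattice units); duplicate markers make A singular and are
        reported."""
        Xp = np.asarray(X, dtype=float)[self.perm]
        dsp = np.asarray(ds, dtype=float)[self.perm]
        x = Xp[:, 0]
        # needed bandwidth: furthest pair closer than one kernel support
        reach = self.support + self.bw_margin
        bw = int(K.ib_bandwidth(x, reach))
        if self._Ab is None or bw != self._bw:
            self._bw = bw
            self._Ab = np.empty((2 * bw + 1, self.n))
        # deduplicate: markers that (transiently, e.g. in hard contact)
        # come within a fraction of a lattice unit of an already-kept
        # marker are deactivated for this step - their no-slip constraint
        # is indistinguishable from the neighbor's and would make the
        # square system singular
        self.active = np.ones(self.n, dtype=np.bool_)
        K.ib_dedup(x, Xp[:, 1], max(self._bw, 8), self.active)
        K.ib_weights(Xp, self.nx, self.nr, self.ii, self.jj, self.wx, self.wr)
        # solid lattice nodes are excluded consistently from interpolation,
        # spreading and the assembled operator: momentum deposited on
        # bounce-back nodes is discarded by the collision step, and keeping
        # it in A would make markers near rigid masks overcorrect
        self._w2 = K.ib_mask_weights(self.ii, self.jj, self.wx, self.wr, self.solid)
        self._dsR = dsp * Xp[:, 1]
        K.ib_assemble_banded2(self.ii, self.jj, self._w2, self._dsR, bw, self._Ab)
        # row sums of A (smooth-mode reaction scale, used for the implicit
        # interface drag on the structural side), in original marker order
        rows = np.empty(self.n)
        K.ib_rowsums(self._Ab, bw, rows)
        self.row_sum = np.empty(self.n)
        self.row_sum[self.perm] = rows
        # deactivated markers: identity row (zero correction)
        inact = np.where(~self.active)[0]
        for m in inact:
            lo = max(0, m - bw)
            hi = min(self.n, m + bw + 1)
            for l in range(lo, hi):
                self._Ab[bw + m - l, l] = 0.0
                self._Ab[bw + l - m, m] = 0.0
            self._Ab[bw, m] = 1.0
        diag = self._Ab[bw]
        if np.any(diag <= 0.0) or not np.all(np.isfinite(diag)):
            bad = np.where(~(diag > 0.0))[0]
            raise RuntimeError(
                f"singular coupling matrix (duplicate/degenerate markers) at "
                f"sorted indices {bad[:5]}"
            )
        K.banded_lu(self._Ab, bw)

    def marker_values(self, field):
        """Interpolate an Eulerian field to the current markers (original
        marker order)."""
        out = np.empty(self.n)
        K.ib_interpolate2(field, self.ii, self.jj, self._w2, out)
        res = np.empty(self.n)
        res[self.perm] = out
        return res

    def solve_velocity_correction(self, vx, vr, Vx, Vr):
        """Marker velocity corrections dV with A dV = V - I(v*)."""
        bx = np.empty(self.n)
        br = np.empty(self.n)
        K.ib_interpolate2(vx, self.ii, self.jj, self._w2, bx)
        K.ib_interpolate2(vr, self.ii, self.jj, self._w2, br)
        bx = np.asarray(Vx, dtype=float)[self.perm] - bx
        br = np.asarray(Vr, dtype=float)[self.perm] - br
        bx[~self.active] = 0.0
        br[~self.active] = 0.0
        K.banded_solve(self._Ab, self._bw, bx)
        K.banded_solve(self._Ab, self._bw, br)
        return bx, br  # in sorted order (internal)

    def correct(self, vx, vr, Vx, Vr, fEx, fEr):
        """Full correction pass, in place.

        Interpolates v*, solves for dV, spreads dv onto the velocity fields
        and writes the Eulerian force density fE = 2 dv (lattice units,
        dt = rho = 1).  Returns the marker force per unit wall area,
        F_L = -2 dV, in the original marker order.
        """
        bx0 = np.empty(self.n)
        br0 = np.empty(self.n)
        K.ib_interpolate2(vx, self.ii, self.jj, self._w2, bx0)
        K.ib_interpolate2(vr, self.ii, self.jj, self._w2, br0)
        rhs_x = np.asarray(Vx, dtype=float)[self.perm] - bx0
        rhs_r = np.asarray(Vr, dtype=float)[self.perm] - br0
        rhs_x[~self.active] = 0.0
        rhs_r[~self.active] = 0.0
        dVx = rhs_x.copy()
        dVr = rhs_r.copy()
        K.banded_solve(self._Ab, self._bw, dVx)
        K.banded_solve(self._Ab, self._bw, dVr)
        dvx = np.zeros((self.nx, self.nr))
        dvr = np.zeros((self.nx, self.nr))
        K.ib_spread2(dvx, dVx, self.ii, self.jj, self._w2, self._dsR)
        K.ib_spread2(dvr, dVr, self.ii, self.jj, self._w2, self._dsR)
        vx += dvx
        vr += dvr
        fEx[:, :] = 2.0 * dvx
        fEr[:, :] = 2.0 * dvr
        # no-slip check on the corrected field
        rx = np.empty(self.n)
        rr = np.empty(self.n)
        K.ib_interpolate2(vx, self.ii, self.jj, self._w2, rx)
        K.ib_interpolate2(vr, self.ii, self.jj, self._w2, rr)
        rx -= np.asarray(Vx, dtype=float)[self.perm]
        rr -= np.asarray(Vr, dtype=float)[self.perm]
        rx[~self.active] = 0.0
        rr[~self.active] = 0.0
        self.last_residual = float(max(np.abs(rx).max(), np.abs(rr).max()))
        Fx = -2.0 * dVx[self.iperm]
        Fr = -2.0 * dVr[self.iperm]
        F = np.column_stack([Fx, Fr])
        self.last_rhs = np.column_stack([rhs_x[self.iperm], rhs_r[self.iperm]])
        return F


def lagrangian_force(fEx, fEr, markers):
    """Marker force (per unit area) by interpolating the Eulerian force
    density back to the markers: F_L = -I(f)."""
    return np.column_stack(
        [-interpolate(fEx, markers), -interpolate(fEr, markers)]
    )
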