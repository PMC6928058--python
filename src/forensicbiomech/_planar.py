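"""Planar articulated rigid-body dynamics engine.

A linkage is a tree of rigid links connected by in-plane pin joints,
described in generalized coordinates: for a free-floating base the vector
``q`` is ``[x, y, theta0, q_1, ..., q_nj]`` (base-link CoM position, base
link absolute angle, joint angles); for a pinned base the translational
coordinates are absent.  Joint angles are zero in the reference (rest)
posture.

Each link's CoM position is a chain of fixed-length vectors

    p_i = base + sum_t  a_t * u(c_t + sum_{k in D_t} q_k),

with ``u(a) = (cos a, sin a)``, which gives closed-form Jacobians and
closed-form Coriolis/centrifugal terms: differentiating twice in time with
``qddot = 0`` leaves only ``-a_t u(alpha_t) alphadot_t^2`` per term.  The
equations of motion are assembled mass-matrix style,

    M(q) qddot = Q_applied(q, qdot) - sum_i m_i Jv_i^T a0_i,

with M = sum_i (m_i Jv_i^T Jv_i + I_i w_i w_i^T); in the plane the
gyroscopic terms vanish.

Contact with the terrain (planes and boxes) is impulse based: sample
spheres along each link are tested against the terrain solids each step,
and penetrating, approaching contacts receive Newton-restitution normal
impulses plus Coulomb-friction tangential impulses via a sequential
impulse solver.  Residual penetration is removed by a small velocity-free
positional projection so that the stabilization does not pump energy into
the motion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import SimulationFailure
from .integrate import integrate_adaptive, kutta_merson_step

__all__ = [
    "LinkSpec",
    "PlanarLinkage",
    "Quadrant",
    "Box",
    "Terrain",
    "ContactSettings",
    "StepSettings",
    "RawTrajectory",
    "simulate_linkage",
]


# ---------------------------------------------------------------------------
# linkage description


@dataclass
class LinkSpec:
    """One rigid link of a planar linkage.

    ``terms`` is the vector chain from the base reference to the link CoM:
    a list of ``(length, angle_offset, dep_indices)`` tuples where
    ``dep_indices`` are the generalized coordinates whose sum (plus the
    offset) gives the term's absolute direction.  ``ang_indices`` /
    ``ang_offset`` give the link's own absolute angle the same way.
    ``s_bounds`` is the arc interval (relative to the CoM, along the link
    axis) covered by contact sample spheres of radius ``radius``;
    ``extra_samples`` adds off-axis spheres at body-frame offsets
    ``(along, perp)`` from the CoM (e.g. a foot plate on a shank link).
    """

    name: str
    mass: float
    inertia: float
    length: float
    terms: list[tuple[float, float, tuple[int, ...]]]
    ang_indices: tuple[int, ...]
    ang_offset: float
    s_bounds: tuple[float, float]
    radius: float = 0.03
    extra_samples: tuple[tuple[float, float], ...] = ()


class PlanarLinkage:
    """Assembled planar linkage with precomputed kinematic index arrays."""

    def __init__(
        self,
        links: list[LinkSpec],
        nq: int,
        free_base: bool = True,
        base_point: tuple[float, float] = (0.0, 0.0),
        gravity: float = 9.81,
        spring: np.ndarray | None = None,
        damper: np.ndarray | None = None,
        rest: np.ndarray | None = None,
        limit_lo: np.ndarray | None = None,
        limit_hi: np.ndarray | None = None,
        limit_spring: np.ndarray | None = None,
        limit_damper: np.ndarray | None = None,
        contact_spacing: float = 0.09,
    ):
        self.links = links
        self.nq = nq
        self.free_base = free_base
        self.base_point = np.asarray(base_point, dtype=float)
        self.gravity = gravity
        self.spring = np.zeros(nq) if spring is None else np.asarray(spring, float)
        self.damper = np.zeros(nq) if damper is None else np.asarray(damper, float)
        self.rest = np.zeros(nq) if rest is None else np.asarray(rest, float)
        # one-sided range stops: penalty spring/damper engaged beyond [lo, hi]
        self.limit_lo = np.full(nq, -np.inf) if limit_lo is None else np.asarray(limit_lo, float)
        self.limit_hi = np.full(nq, np.inf) if limit_hi is None else np.asarray(limit_hi, float)
        self.limit_spring = (
            np.zeros(nq) if limit_spring is None else np.asarray(limit_spring, float)
        )
        self.limit_damper = (
            np.zeros(nq) if limit_damper is None else np.asarray(limit_damper, float)
        )

        self.masses = np.array([l.mass for l in links])
        self.inertias = np.array([l.inertia for l in links])
        self.radii = np.array([l.radius for l in links])
        self.total_mass = float(self.masses.sum())

        # per-link term arrays
        self._tlen, self._toff, self._tdep = [], [], []
        self._ang_row, self._ang_off = [], []
        self._samples = []  # per-link arc offsets of contact sample spheres
        for l in links:
            n = len(l.terms)
            lens = np.array([t[0] for t in l.terms]) if n else np.zeros(0)
            offs = np.array([t[1] for t in l.terms]) if n else np.zeros(0)
            dep = np.zeros((n, nq))
            for j, t in enumerate(l.terms):
                dep[j, list(t[2])] = 1.0
            self._tlen.append(lens)
            self._toff.append(offs)
            self._tdep.append(dep)
            row = np.zeros(nq)
            row[list(l.ang_indices)] = 1.0
            self._ang_row.append(row)
            self._ang_off.append(l.ang_offset)
            s0, s1 = l.s_bounds
            ns = max(2, int(math.ceil((s1 - s0) / contact_spacing)) + 1)
            axis = np.column_stack([np.linspace(s0, s1, ns), np.zeros(ns)])
            if l.extra_samples:
                axis = np.vstack([axis, np.asarray(l.extra_samples, float)])
            self._samples.append(axis)  # body-frame (along, perp) offsets
        self._ang_rows = np.array(self._ang_row)  # (nl, nq)
        # generalized force held constant over one integration (sub)step;
        # used by the simulation loop for resting-contact normal forces
        self._ext_force = np.zeros(nq)

    # -- kinematics ---------------------------------------------------------

    def _base(self, q: np.ndarray) -> np.ndarray:
        return q[:2] if self.free_base else self.base_point

    def link_angles(self, q: np.ndarray) -> np.ndarray:
        return np.array(self._ang_off) + self._ang_rows @ q

    def com_positions(self, q: np.ndarray) -> np.ndarray:
        base = self._base(q)
        out = np.empty((len(self.links), 2))
        for i in range(len(self.links)):
            alpha = self._toff[i] + self._tdep[i] @ q
            out[i, 0] = base[0] + np.dot(self._tlen[i], np.cos(alpha))
            out[i, 1] = base[1] + np.dot(self._tlen[i], np.sin(alpha))
        return out

    def com_jacobians(self, q: np.ndarray) -> np.ndarray:
        """CoM translational Jacobians, shape (nl, 2, nq)."""
        nl = len(self.links)
        J = np.zeros((nl, 2, self.nq))
        for i in range(nl):
            alpha = self._toff[i] + self._tdep[i] @ q
            ax = -self._tlen[i] * np.sin(alpha)
            ay = self._tlen[i] * np.cos(alpha)
            J[i, 0, :] = ax @ self._tdep[i]
            J[i, 1, :] = ay @ self._tdep[i]
            if self.free_base:
                J[i, 0, 0] += 1.0
                J[i, 1, 1] += 1.0
        return J

    def bias_accelerations(self, q: np.ndarray, qdot: np.ndarray) -> np.ndarray:
        """CoM accelerations at qddot = 0, shape (nl, 2)."""
        nl = len(self.links)
        a0 = np.zeros((nl, 2))
        for i in range(nl):
            if len(self._tlen[i]) == 0:
                continue
            alpha = self._toff[i] + self._tdep[i] @ q
            ad = self._tdep[i] @ qdot
            w = self._tlen[i] * ad**2
            a0[i, 0] = -np.dot(w, np.cos(alpha))
            a0[i, 1] = -np.dot(w, np.sin(alpha))
        return a0

    # -- dynamics -----------------------------------------------------------

    def mass_matrix(self, q: np.ndarray, Jv: np.ndarray | None = None) -> np.ndarray:
        if Jv is None:
            Jv = self.com_jacobians(q)
        M = np.zeros((self.nq, self.nq))
        for i in range(len(self.links)):
            M += self.masses[i] * Jv[i].T @ Jv[i]
            row = self._ang_rows[i]
            M += self.inertias[i] * np.outer(row, row)
        return M

    def applied_forces(self, q: np.ndarray, qdot: np.ndarray, Jv: np.ndarray) -> np.ndarray:
        Q = np.zeros(self.nq)
        # gravity on every link CoM
        for i in range(len(self.links)):
            Q += Jv[i, 1, :] * (-self.masses[i] * self.gravity)
        # torsional springs/dampers act directly on joint coordinates
        Q += -self.spring * (q - self.rest) - self.damper * qdot
        # one-sided range stops: restoring spring plus damping while engaged
        over = np.maximum(q - self.limit_hi, 0.0)
        under = np.maximum(self.limit_lo - q, 0.0)
        engaged = (over > 0) | (under > 0)
        Q += -self.limit_spring * (over - under)
        Q -= np.where(engaged, self.limit_damper * qdot, 0.0)
        return Q

    def accelerations(self, q: np.ndarray, qdot: np.ndarray) -> np.ndarray:
        Jv = self.com_jacobians(q)
        M = self.mass_matrix(q, Jv)
        Q = self.applied_forces(q, qdot, Jv) + self._ext_force
        a0 = self.bias_accelerations(q, qdot)
        for i in range(len(self.links)):
            Q -= self.masses[i] * (Jv[i].T @ a0[i])
        return np.linalg.solve(M, Q)

    def deriv(self, t: float, y: np.ndarray) -> np.ndarray:
        q, qdot = y[: self.nq], y[self.nq :]
        return np.concatenate([qdot, self.accelerations(q, qdot)])

    # -- diagnostics --------------------------------------------------------

    def kinetic_energy(self, q: np.ndarray, qdot: np.ndarray) -> float:
        return 0.5 * float(qdot @ self.mass_matrix(q) @ qdot)

    def potential_energy(self, q: np.ndarray) -> float:
        coms = self.com_positions(q)
        grav = float(np.dot(self.masses, coms[:, 1]) * self.gravity)
        spring = 0.5 * float(np.dot(self.spring, (q - self.rest) ** 2))
        over = np.maximum(q - self.limit_hi, 0.0)
        under = np.maximum(self.limit_lo - q, 0.0)
        stops = 0.5 * float(np.dot(self.limit_spring, over**2 + under**2))
        return grav + spring + stops

    def total_energy(self, q: np.ndarray, qdot: np.ndarray) -> float:
        return self.kinetic_energy(q, qdot) + self.potential_energy(q)

    def system_com(self, q: np.ndarray) -> np.ndarray:
        coms = self.com_positions(q)
        return (self.masses[:, None] * coms).sum(axis=0) / self.total_mass

    def angular_momentum_about_com(self, q: np.ndarray, qdot: np.ndarray) -> float:
        """Total angular momentum of the linkage about the system CoM."""
        coms = self.com_positions(q)
        Jv = self.com_jacobians(q)
        R = self.system_com(q)
        Vcom = (self.masses[:, None] * np.einsum("ijk,k->ij", Jv, qdot)).sum(axis=0) / self.total_mass
        L = 0.0
        for i in range(len(self.links)):
            r = coms[i] - R
            v = Jv[i] @ qdot - Vcom
            omega = float(self._ang_rows[i] @ qdot)
            L += self.masses[i] * (r[0] * v[1] - r[1] * v[0]) + self.inertias[i] * omega
        return float(L)

    # -- contact geometry ---------------------------------------------------

    def sample_points(self, q: np.ndarray):
        """Contact sample spheres: (positions (ns,2), link index, body-frame
        offsets (ns,2))."""
        coms = self.com_positions(q)
        angles = self.link_angles(q)
        pts, link_ix, svals = [], [], []
        for i, s in enumerate(self._samples):
            u = np.array([math.cos(angles[i]), math.sin(angles[i])])
            perp = np.array([-u[1], u[0]])
            pts.append(coms[i][None, :] + s[:, :1] * u[None, :] + s[:, 1:] * perp[None, :])
            link_ix.append(np.full(len(s), i, dtype=int))
            svals.append(s)
        return np.vstack(pts), np.concatenate(link_ix), np.vstack(svals)

    def point_jacobian(self, q, link: int, offset, Jv: np.ndarray | None = None) -> np.ndarray:
        """Jacobian of a material point at body-frame ``(along, perp)``
        offset from the CoM of ``link``; a bare float means on-axis."""
        if Jv is None:
            Jv = self.com_jacobians(q)
        a, b = (offset, 0.0) if np.isscalar(offset) else offset
        angle = self._ang_off[link] + float(self._ang_rows[link] @ q)
        u = np.array([math.cos(angle), math.sin(angle)])
        perp = np.array([-u[1], u[0]])
        return Jv[link] + np.outer(a * perp - b * u, self._ang_rows[link])


# ---------------------------------------------------------------------------
# terrain


@dataclass(frozen=True)
class Quadrant:
    """Solid quarter-plane ``{sx*(x - x0) <= 0, y <= y0}``; ``sx=+1`` keeps
    material to the left of x0 (a road ending at x0), ``sx=-1`` to the
    right."""

    name: str
    material: str
    x0: float
    y0: float
    sx: int = 1

    def query(self, p: np.ndarray):
        """Signed distance (negative inside) and outward normal per point."""
        x, y = p[:, 0], p[:, 1]
        dx = self.sx * (x - self.x0)  # > 0 means beyond the edge
        dy = y - self.y0  # > 0 means above the surface
        dist = np.empty(len(p))
        normal = np.zeros((len(p), 2))
        inside_x = dx <= 0
        above = dy > 0
        # above the surface, within the slab: plain plane
        m = inside_x & above
        dist[m] = dy[m]
        normal[m] = [0.0, 1.0]
        # beyond the edge, above the corner level: corner distance
        m = ~inside_x & above
        dist[m] = np.hypot(dx[m], dy[m])
        normal[m, 0] = self.sx * dx[m] / dist[m]
        normal[m, 1] = dy[m] / dist[m]
        # beyond the edge, below corner level: vertical face
        m = ~inside_x & ~above
        dist[m] = dx[m]
        normal[m, 0] = float(self.sx)
        # inside: negative distance toward the nearest face
        m = inside_x & ~above
        face_y = -dy[m]  # depth below surface
        face_x = -dx[m]  # depth from edge face
        use_y = face_y <= face_x
        dist[m] = -np.where(use_y, face_y, face_x)
        normal[m, 0] = np.where(use_y, 0.0, float(self.sx))
        normal[m, 1] = np.where(use_y, 1.0, 0.0)
        return dist, normal


@dataclass(frozen=True)
class Box:
    """Solid axis-aligned rectangle [x0, x1] x [y0, y1]."""

    name: str
    material: str
    x0: float
    x1: float
    y0: float
    y1: float

    def query(self, p: np.ndarray):
        x, y = p[:, 0], p[:, 1]
        cx = np.clip(x, self.x0, self.x1)
        cy = np.clip(y, self.y0, self.y1)
        dx, dy = x - cx, y - cy
        dist = np.hypot(dx, dy)
        outside = dist > 0
        normal = np.zeros((len(p), 2))
        normal[outside, 0] = dx[outside] / dist[outside]
        normal[outside, 1] = dy[outside] / dist[outside]
        if np.any(~outside):
            # inside: nearest face
            ix = np.where(~outside)[0]
            for i in ix:
                cand = np.array(
                    [x[i] - self.x0, self.x1 - x[i], y[i] - self.y0, self.y1 - y[i]]
                )
                j = int(np.argmin(cand))
                dist[i] = -cand[j]
                normal[i] = [(-1.0, 0.0), (1.0, 0.0), (0.0, -1.0), (0.0, 1.0)][j]
        return dist, normal


@dataclass
class Terrain:
    """A collection of terrain solids."""

    solids: list

    def query_all(self, p: np.ndarray):
        """Per-solid distances/normals for the given points."""
        return [(s, *s.query(p)) for s in self.solids]


# ---------------------------------------------------------------------------
# contact resolution


@dataclass(frozen=True)
class ContactSettings:
    """Impulse-solver settings and material coefficients.

    ``restitution`` maps a terrain material name to its Newton restitution
    coefficient.  Restitution applies only above ``bounce_threshold``
    approach speed; slower contacts resolve plastically, which lets bodies
    come to rest.  ``friction`` is either a single Coulomb coefficient or a
    material-name map like ``restitution``.
    """

    restitution: dict
    friction: float | dict = 0.8
    bounce_threshold: float = 0.2  # m/s
    iterations: int = 30
    baumgarte: float = 0.2
    slop: float = 0.002  # m
    rest_velocity_gain: float = 0.5  # resting-contact normal-velocity feedback


@dataclass
class _Contact:
    link: int
    s: tuple[float, float]  # body-frame (along, perp) offset of the sphere
    point: np.ndarray
    normal: np.ndarray
    depth: float
    solid_name: str
    material: str


def _detect_contacts(linkage: PlanarLinkage, terrain: Terrain, q: np.ndarray) -> list[_Contact]:
    pts, link_ix, svals = linkage.sample_points(q)
    radii = linkage.radii[link_ix]
    contacts = []
    for solid, dist, normal in terrain.query_all(pts):
        pen = radii - dist
        for j in np.where(pen > 0)[0]:
            contacts.append(
                _Contact(
                    link=int(link_ix[j]),
                    s=(float(svals[j, 0]), float(svals[j, 1])),
                    point=pts[j],
                    normal=normal[j],
                    depth=float(pen[j]),
                    solid_name=solid.name,
                    material=solid.material,
                )
            )
    return contacts


def _resolve_contacts(
    linkage: PlanarLinkage,
    q: np.ndarray,
    v: np.ndarray,
    contacts: list[_Contact],
    settings: ContactSettings,
):
    """Sequential-impulse velocity resolution; mutates ``v`` in place.

    Returns per-contact accumulated normal impulses.
    """
    nq = linkage.nq
    Jv = linkage.com_jacobians(q)
    M = linkage.mass_matrix(q, Jv)
    Minv = np.linalg.inv(M)

    n = len(contacts)
    Jn = np.zeros((n, nq))
    Jt = np.zeros((n, nq))
    for i, c in enumerate(contacts):
        Jp = linkage.point_jacobian(q, c.link, c.s, Jv)
        Jn[i] = c.normal @ Jp
        tang = np.array([-c.normal[1], c.normal[0]])
        Jt[i] = tang @ Jp
    MJn = Jn @ Minv  # rows: Minv @ Jn[i]
    MJt = Jt @ Minv
    mn = np.einsum("ij,ij->i", Jn, MJn)
    mt = np.einsum("ij,ij->i", Jt, MJt)
    mn[mn <= 0] = np.inf
    mt[mt <= 0] = np.inf

    vn0 = Jn @ v
    bounce = np.where(
        vn0 < -settings.bounce_threshold,
        -np.array([settings.restitution.get(c.material, 0.0) for c in contacts]) * vn0,
        0.0,
    )

    lam_n = np.zeros(n)
    lam_t = np.zeros(n)
    if isinstance(settings.friction, dict):
        mus = np.array([settings.friction.get(c.material, 0.0) for c in contacts])
    else:
        mus = np.full(n, settings.friction)
    for _ in range(settings.iterations):
        for i in range(n):
            mu = mus[i]
            vn = Jn[i] @ v
            dl = (bounce[i] - vn) / mn[i]
            new = max(lam_n[i] + dl, 0.0)
            dl = new - lam_n[i]
            lam_n[i] = new
            v += MJn[i] * dl
            if mu > 0:
                vt = Jt[i] @ v
                dt_ = -vt / mt[i]
                hi = mu * lam_n[i]
                new_t = min(max(lam_t[i] + dt_, -hi), hi)
                dt_ = new_t - lam_t[i]
                lam_t[i] = new_t
                v += MJt[i] * dt_
    return lam_n


def _positional_correction(
    linkage: PlanarLinkage,
    q: np.ndarray,
    contacts: list[_Contact],
    settings: ContactSettings,
):
    """Velocity-free penetration projection; returns the corrected q.

    The corrections are solved as a coupled non-negative system (projected
    Gauss-Seidel on the position-level contact equations, the "split
    impulse" scheme) rather than summed independently per contact.  With
    many simultaneous contacts on differently-oriented faces, independent
    corrections fight one another: each step they re-lift the body against
    gravity and the joint springs without ever clearing the slop, which
    pumps a small amount of potential energy into the system every step
    and can sustain a permanent high-frequency vibration.  The coupled
    solve drives all depths to the slop simultaneously, after which the
    projection becomes inactive.
    """
    targets = np.array(
        [settings.baumgarte * max(c.depth - settings.slop, 0.0) for c in contacts]
    )
    if not contacts or not np.any(targets > 0):
        return q
    Jv = linkage.com_jacobians(q)
    Minv = np.linalg.inv(linkage.mass_matrix(q, Jv))
    n = len(contacts)
    Jn = np.zeros((n, linkage.nq))
    for i, c in enumerate(contacts):
        Jp = linkage.point_jacobian(q, c.link, c.s, Jv)
        Jn[i] = c.normal @ Jp
    MJn = Jn @ Minv
    mn = np.einsum("ij,ij->i", Jn, MJn)
    mn[mn <= 0] = np.inf
    lam = np.zeros(n)
    dq = np.zeros(linkage.nq)
    for _ in range(settings.iterations):
        for i in range(n):
            resid = targets[i] - Jn[i] @ dq
            new = max(lam[i] + resid / mn[i], 0.0)
            dl = new - lam[i]
            lam[i] = new
            dq += MJn[i] * dl
    return q + dq


def _resting_forces(
    linkage: PlanarLinkage,
    q: np.ndarray,
    v: np.ndarray,
    contacts: list[_Contact],
    settings: ContactSettings,
    step: float,
) -> np.ndarray:
    """Generalized normal forces supporting resting contacts.

    Impulse-based contacts exert no force during the smooth part of a
    step, so a body lying on the terrain free-falls for one step, is
    stopped impulsively, and is lifted back by the positional projection
    — a cycle that feeds energy into the slop layer every step and keeps
    a settled body vibrating indefinitely.  To let bodies genuinely rest,
    contacts whose approach speed is below the bounce threshold receive a
    non-negative normal force computed from acceleration-level
    complementarity (f >= 0, normal acceleration >= 0, projected
    Gauss-Seidel), held constant over the integration (sub)step.  Fast
    approaching contacts are left to the impulse solver.
    """
    rest = [c for c in contacts if c.depth > 0]
    if not rest:
        return np.zeros(linkage.nq)
    Jv = linkage.com_jacobians(q)
    M = linkage.mass_matrix(q, Jv)
    Minv = np.linalg.inv(M)
    Q = linkage.applied_forces(q, v, Jv)
    a0 = linkage.bias_accelerations(q, v)
    for i in range(len(linkage.links)):
        Q -= linkage.masses[i] * (Jv[i].T @ a0[i])
    qdd0 = Minv @ Q
    rows = []
    vns = []
    for c in rest:
        Jp = linkage.point_jacobian(q, c.link, c.s, Jv)
        vn = float(c.normal @ Jp @ v)
        if vn < -settings.bounce_threshold:
            continue  # impacting: handled impulsively after the step
        rows.append(c.normal @ Jp)
        vns.append(vn)
    if not rows:
        return np.zeros(linkage.nq)
    Jn = np.array(rows)
    MJn = Jn @ Minv
    mn = np.einsum("ij,ij->i", Jn, MJn)
    mn[mn <= 0] = np.inf
    # normal-velocity feedback: holding the start-of-step force constant
    # over the step would feed a contact-point oscillation (the force is
    # sampled out of phase, like explicit Euler on a spring), so bias the
    # target acceleration to also drive the residual normal velocity to
    # zero within ~one step.  Approaching contacts get more force,
    # separating ones less, so the feedback only removes energy.
    an = Jn @ qdd0 + settings.rest_velocity_gain * np.asarray(vns) / step
    f = np.zeros(len(rows))
    for _ in range(settings.iterations):
        for i in range(len(rows)):
            df = -an[i] / mn[i]
            new = max(f[i] + df, 0.0)
            df = new - f[i]
            f[i] = new
            an += (MJn @ Jn[i]) * df
    return Jn.T @ f


# ---------------------------------------------------------------------------
# simulation loop


@dataclass(frozen=True)
class StepSettings:
    """Integration and termination settings for :func:`simulate_linkage`."""

    step: float = 0.01
    max_time: float = 10.0
    ke_threshold: float = 0.1  # J
    quiet_time: float = 0.5  # s
    max_substep_depth: int = 5
    adaptive: bool = False
    adaptive_tol: float = 1e-6


@dataclass
class ContactEvent:
    """A recorded impact: first step at which a link/solid pair carried a
    normal impulse above threshold."""

    time: float
    link: str
    surface: str
    impulse: float  # N s


@dataclass
class RawTrajectory:
    """Low-level sampled trajectory of a linkage simulation."""

    times: np.ndarray  # (T,)
    q: np.ndarray  # (T, nq)
    qdot: np.ndarray  # (T, nq)
    link_poses: np.ndarray  # (T, nl, 3): x, y, angle
    link_velocities: np.ndarray  # (T, nl, 3): vx, vy, omega
    com: np.ndarray  # (T, 2)
    kinetic_energy: np.ndarray  # (T,), sampled after contact resolution
    events: list = field(default_factory=list)
    energy_audit: list = field(default_factory=list)  # (t, E_pre, E_post) per resolution
    terminated: bool = False


def simulate_linkage(
    linkage: PlanarLinkage,
    terrain: Terrain | None,
    contact_settings: ContactSettings | None,
    q0: np.ndarray,
    v0: np.ndarray,
    step_settings: StepSettings,
) -> RawTrajectory:
    """Fixed-step forward dynamics with impulse-based contact.

    Each base step integrates the smooth dynamics with the Kutta–Merson
    scheme; if the step lands a fresh sample deeply inside the terrain the
    step is re-run in halves (down to ``max_substep_depth``) so impacts are
    resolved close to the contact time.  Contact impulses are applied after
    each (sub)step; the per-resolution total mechanical energy before and
    after the impulse solve is recorded in ``energy_audit``.
    """
    nq = linkage.nq
    q = np.asarray(q0, float).copy()
    v = np.asarray(v0, float).copy()
    h = step_settings.step
    t = 0.0

    times, qs, vs, kes = [], [], [], []
    events: list[ContactEvent] = []
    audit = []
    active_pairs: set[tuple[int, str]] = set()
    quiet_since: float | None = None
    terminated = False

    def check_finite(arr, when):
        if not np.all(np.isfinite(arr)):
            raise SimulationFailure(
                f"non-finite state during integration at t = {when:.4f} s",
                last_valid_time=when,
            )

    def resolve_at(tnow, qq, vv):
        """Detect and resolve contacts at state (qq, vv)."""
        if terrain is None or contact_settings is None:
            return qq, vv, set()
        contacts = _detect_contacts(linkage, terrain, qq)
        pairs = {(c.link, c.solid_name) for c in contacts}
        if contacts:
            e_pre = linkage.total_energy(qq, vv)
            lam = _resolve_contacts(linkage, qq, vv, contacts, contact_settings)
            e_post = linkage.total_energy(qq, vv)
            audit.append((tnow, e_pre, e_post))
            for c, l in zip(contacts, lam):
                pair = (c.link, c.solid_name)
                if l > 1e-3 and pair not in active_pairs:
                    events.append(
                        ContactEvent(
                            time=tnow,
                            link=linkage.links[c.link].name,
                            surface=c.solid_name,
                            impulse=float(l),
                        )
                    )
                    active_pairs.add(pair)
            qq = _positional_correction(linkage, qq, contacts, contact_settings)
        return qq, vv, pairs

    def advance(tnow, qq, vv, hh, depth):
        """One (sub)step plus contact handling; returns (q, v, pairs)."""
        if terrain is not None and contact_settings is not None:
            pre = _detect_contacts(linkage, terrain, qq)
            linkage._ext_force = _resting_forces(
                linkage, qq, vv, pre, contact_settings, hh
            )
        y = np.concatenate([qq, vv])
        if step_settings.adaptive:
            y1 = integrate_adaptive(
                linkage.deriv, tnow, y, tnow + hh, hh, tol=step_settings.adaptive_tol
            )
        else:
            y1, _ = kutta_merson_step(linkage.deriv, tnow, y, hh)
        linkage._ext_force = np.zeros(nq)
        check_finite(y1, tnow + hh)
        q1, v1 = y1[:nq], y1[nq:]
        if terrain is not None and contact_settings is not None and depth < step_settings.max_substep_depth:
            contacts = _detect_contacts(linkage, terrain, q1)
            fresh_deep = any(
                c.depth > 0.5 * linkage.radii[c.link]
                and (c.link, c.solid_name) not in active_pairs
                for c in contacts
            )
            if fresh_deep:
                qa, va, _ = advance(tnow, qq, vv, hh / 2, depth + 1)
                return advance(tnow + hh / 2, qa, va, hh / 2, depth + 1)
        q1, v1, pairs = resolve_at(tnow + hh, q1, v1)
        return q1, v1, pairs

    # record the initial state (after resolving any initial penetration)
    q, v, pairs = resolve_at(0.0, q, v)
    active_pairs = pairs

    def record(tnow, qq, vv):
        times.append(tnow)
        qs.append(qq.copy())
        vs.append(vv.copy())
        kes.append(linkage.kinetic_energy(qq, vv))

    record(t, q, v)

    while t < step_settings.max_time - 1e-12:
        hh = min(h, step_settings.max_time - t)
        q, v, pairs = advance(t, q, v, hh, 0)
        active_pairs = pairs
        t += hh
        record(t, q, v)
        ke = kes[-1]
        if ke < step_settings.ke_threshold:
            if quiet_since is None:
                quiet_since = t
            elif t - quiet_since >= step_settings.quiet_time:
                terminated = True
                break
        else:
            quiet_since = None

    times = np.asarray(times)
    qs = np.asarray(qs)
    vs = np.asarray(vs)
    T = len(times)
    nl = len(linkage.links)
    poses = np.empty((T, nl, 3))
    vels = np.empty((T, nl, 3))
    com = np.empty((T, 2))
    for k in range(T):
        coms = linkage.com_positions(qs[k])
        poses[k, :, :2] = coms
        poses[k, :, 2] = linkage.link_angles(qs[k])
        Jv = linkage.com_jacobians(qs[k])
        vels[k, :, :2] = np.einsum("ijk,k->ij", Jv, vs[k])
        vels[k, :, 2] = linkage._ang_rows @ vs[k]
        com[k] = (linkage.masses[:, None] * coms).sum(axis=0) / linkage.total_mass

    return RawTrajectory(
        times=times,
        q=qs,
        qdot=vs,
        link_poses=poses,
        link_velocities=vels,
        com=com,
        kinetic_energy=np.asarray(kes),
        events=events,
        energy_audit=audit,
        terminated=terminated,
    )
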