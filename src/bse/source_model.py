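"""Spherical-shell source model, forward fields and the L2 minimum-norm inverse.

The source space is a shell of dipole sites at 87% of the head radius
(roughly grey-matter depth), sampled quasi-uniformly with a deterministic
Fibonacci lattice.  MEG uses two tangential orientations per site (a radial
dipole in a spherical conductor is magnetically silent), EEG uses three.

Forward solutions use the standard spherical-conductor results: the analytic
dipole field for MEG (Sarvas' closed form) and the Legendre-series potential
of a current dipole in a homogeneous conducting sphere for EEG, with an
average reference applied.

The inverse is the plain L2 minimum-norm estimate with Tikhonov
regularization, ``W = L' (L L' + lam * s * I)^-1`` where ``s`` scales the
Gram matrix so that ``lam`` is dimensionless (0.1 for MEG, 0.2 for EEG by
convention here).  Source activity is reported as the orientation-vector
length per site, which is direction independent and nonnegative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MU0_OVER_4PI = 1e-7  # T*m/A
DEFAULT_CONDUCTIVITY = 0.33  # S/m, brain-like homogeneous sphere


class GeometryError(ValueError):
    """Raised for inconsistent sensor/source geometry."""


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere lattice, shape (n, 3)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    i = np.arange(n)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    z = 1.0 - (2.0 * i + 1.0) / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    theta = golden * i
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def _tangential_basis(unit_positions: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal tangent vectors (e_theta, e_phi) per unit position."""
    x, y, z = unit_positions.T
    rho = np.hypot(x, y)
    # Fibonacci lattices never hit the exact poles, but guard anyway
    safe = rho > 1e-12
    e_phi = np.zeros_like(unit_positions)
    e_phi[safe] = np.column_stack(
        [-y[safe] / rho[safe], x[safe] / rho[safe], np.zeros(safe.sum())]
    )
    e_phi[~safe] = [0.0, 1.0, 0.0]
    e_theta = np.cross(e_phi, unit_positions)
    return e_theta, e_phi


@dataclass
class SourceSpace:
    """Shell of dipole sites inside a spherical head.

    positions : (n_sites, 3) m; orientations : (n_sites, n_orient, 3) unit
    vectors (2 tangential for MEG use, +radial for EEG).
    """

    positions: np.ndarray
    orientations: np.ndarray
    head_radius: float
    radius_fraction: float

    @property
    def n_sites(self) -> int:
        return self.positions.shape[0]

    @property
    def n_orient(self) -> int:
        return self.orientations.shape[1]

    @property
    def shell_radius(self) -> float:
        return self.head_radius * self.radius_fraction


def build_source_shell(
    head_radius: float = 0.09,
    n_sites: int = 350,
    radius_fraction: float = 0.87,
    n_orient: int = 2,
) -> SourceSpace:
    """Quasi-uniform dipole shell at ``radius_fraction`` of the head radius.

    ``n_orient=2`` gives the tangential dipole pairs used for MEG,
    ``n_orient=3`` adds the radial orientation for EEG (dipole triples).
    """
    if n_sites < 4:
        raise ValueError("n_sites must be >= 4")
    if not 0.0 < radius_fraction < 1.0:
        raise ValueError("radius_fraction must lie in (0, 1)")
    if n_orient not in (2, 3):
        raise ValueError("n_orient must be 2 (MEG) or 3 (EEG)")
    unit = fibonacci_sphere(n_sites)
    e_theta, e_phi = _tangential_basis(unit)
    if n_orient == 2:
        orientations = np.stack([e_theta, e_phi], axis=1)
    else:
        orientations = np.stack([e_theta, e_phi, unit], axis=1)
    return SourceSpace(
        positions=unit * head_radius * radius_fraction,
        orientations=orientations,
        head_radius=head_radius,
        radius_fraction=radius_fraction,
    )


@dataclass
class SensorLayout:
    """Sensors on (or above) the scalp sphere.

    positions : (n_sensors, 3) m; orientations : (n_sensors, 3) unit vectors,
    used for MEG field projection (radial magnetometer approximation);
    ignored for EEG electrodes.
    """

    positions: np.ndarray
    orientations: np.ndarray
    modality: str  # "meg" | "eeg"
    names: list[str] = field(default_factory=list)

    @property
    def n_sensors(self) -> int:
        return self.positions.shape[0]


def make_sensor_layout(
    n_sensors: int = 64,
    modality: str = "meg",
    head_radius: float = 0.09,
    cap_fraction: float = 0.65,
) -> SensorLayout:
    """Helmet-like cap of sensors covering the upper ``cap_fraction`` of the sphere.

    MEG sensors sit 20% above the scalp with radial orientations (an
    axial-magnetometer stand-in); EEG electrodes sit on the scalp.
    """
    if modality not in ("meg", "eeg"):
        raise ValueError("modality must be 'meg' or 'eeg'")
    i = np.arange(n_sensors)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    z_min = 1.0 - 2.0 * cap_fraction
    z = 1.0 - (1.0 - z_min) * (2.0 * i + 1.0) / (2.0 * n_sensors)
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    theta = golden * i
    unit = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    radius = head_radius * (1.2 if modality == "meg" else 1.0)
    prefix = "MEG" if modality == "meg" else "EEG"
    return SensorLayout(
        positions=unit * radius,
        orientations=unit.copy(),
        modality=modality,
        names=[f"{prefix}{k:03d}" for k in range(n_sensors)],
    )


# ---------------------------------------------------------------------------
# forward solutions
# ---------------------------------------------------------------------------

def sarvas_field(r_sensor: np.ndarray, r_dipole: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Magnetic field (T) of a current dipole in a spherical conductor.

    Sarvas' closed form; the sphere is centred at the origin.  Vectorized
    over sensors: ``r_sensor`` (n, 3), single dipole position/moment (A*m).
    """
    r = np.atleast_2d(r_sensor).astype(float)
    r0 = np.asarray(r_dipole, dtype=float)
    q = np.asarray(q, dtype=float)
    a_vec = r - r0
    a = np.linalg.norm(a_vec, axis=1)
    rn = np.linalg.norm(r, axis=1)
    r0_dot_r = r @ r0
    f = a * (rn * a + rn**2 - r0_dot_r)
    a_dot_r = np.einsum("ij,ij->i", a_vec, r)
    grad_f = (
        (a**2 / rn + a_dot_r / a + 2.0 * a + 2.0 * rn)[:, None] * r
        - (a + 2.0 * rn + a_dot_r / a)[:, None] * r0[None, :]
    )
    q_cross_r0 = np.cross(q, r0)
    b = MU0_OVER_4PI / f[:, None] ** 2 * (
        f[:, None] * q_cross_r0[None, :]
        - (r @ q_cross_r0)[:, None] * grad_f
    )
    return b


def sphere_potential(
    r_sensor: np.ndarray,
    r_dipole: np.ndarray,
    q: np.ndarray,
    sphere_radius: float,
    conductivity: float = DEFAULT_CONDUCTIVITY,
    n_terms: int = 150,
) -> np.ndarray:
    """Surface potential (V) of a dipole in a homogeneous conducting sphere.

    Legendre-series solution for electrodes on the sphere surface; converges
    geometrically in (|r_dipole| / sphere_radius)^n.  No reference applied.
    """
    r = np.atleast_2d(r_sensor).astype(float)
    r0 = np.asarray(r_dipole, dtype=float)
    q = np.asarray(q, dtype=float)
    b = np.linalg.norm(r0)
    big_r = float(sphere_radius)
    r_hat = r / np.linalg.norm(r, axis=1, keepdims=True)
    if b < 1e-12:
        # central dipole: only the n=1 term survives
        return 3.0 * (r_hat @ q) / (4.0 * np.pi * conductivity * big_r**2)
    r0_hat = r0 / b
    cosg = np.clip(r_hat @ r0_hat, -1.0, 1.0)
    # tangent direction at the dipole, in the plane of (r0, sensor)
    t_vec = r_hat - cosg[:, None] * r0_hat[None, :]
    t_norm = np.linalg.norm(t_vec, axis=1)
    ok = t_norm > 1e-12
    t_hat = np.zeros_like(t_vec)
    t_hat[ok] = t_vec[ok] / t_norm[ok, None]
    m_r = float(q @ r0_hat)
    m_t = t_hat @ q
    f_ratio = b / big_r
    # recurrences for P_n(c) and the derivative-based P_n^1(c) = sin(g) P_n'(c)
    sing = np.sqrt(np.clip(1.0 - cosg**2, 0.0, None))
    p_prev = np.ones_like(cosg)   # P_0
    p_cur = cosg.copy()           # P_1
    dp_cur = np.ones_like(cosg)   # P_1'
    v = np.zeros(r.shape[0])
    fpow = 1.0  # f^(n-1)
    for n in range(1, n_terms + 1):
        pn1 = sing * dp_cur
        v += (2.0 * n + 1.0) / n * fpow * (n * m_r * p_cur + m_t * pn1)
        # advance to n+1
        p_next = ((2 * n + 1) * cosg * p_cur - n * p_prev) / (n + 1)
        dp_next = dp_cur * cosg + (n + 1) * p_cur  # P_{n+1}' = x P_n' + (n+1) P_n
        p_prev, p_cur, dp_cur = p_cur, p_next, dp_next
        fpow *= f_ratio
    return v / (4.0 * np.pi * conductivity * big_r**2)


@dataclass
class Leadfield:
    """Linear forward map, shape (n_sensors, n_sites, n_orient).

    MEG entries in T/(A*m), EEG in V/(A*m) (average-referenced).
    """

    matrix: np.ndarray
    modality: str
    source_space: SourceSpace
    layout: SensorLayout

    @property
    def matrix2d(self) -> np.ndarray:
        n_sens = self.matrix.shape[0]
        return self.matrix.reshape(n_sens, -1)


def forward_leadfield(
    source_space: SourceSpace,
    layout: SensorLayout,
    modality: str | None = None,
    conductivity: float = DEFAULT_CONDUCTIVITY,
) -> Leadfield:
    """Leadfield for every site/orientation of the shell.

    MEG projects the Sarvas field on the sensor orientation; EEG uses the
    homogeneous-sphere potential with an average reference (columns sum to
    zero across electrodes).
    """
    modality = modality or layout.modality
    sens_r = np.linalg.norm(layout.positions, axis=1)
    if np.any(sens_r <= source_space.shell_radius * (1.0 + 1e-9)):
        raise GeometryError("sensors must lie outside the source shell")
    n_sens = layout.n_sensors
    n_sites, n_orient = source_space.n_sites, source_space.n_orient
    lf = np.zeros((n_sens, n_sites, n_orient))
    for s in range(n_sites):
        for o in range(n_orient):
            q = source_space.orientations[s, o]
            if modality == "meg":
                b = sarvas_field(layout.positions, source_space.positions[s], q)
                lf[:, s, o] = np.einsum("ij,ij->i", b, layout.orientations)
            else:
                lf[:, s, o] = sphere_potential(
                    layout.positions,
                    source_space.positions[s],
                    q,
                    sphere_radius=source_space.head_radius,
                    conductivity=conductivity,
                )
    if modality == "eeg":
        lf -= lf.mean(axis=0, keepdims=True)  # average reference
    return Leadfield(matrix=lf, modality=modality, source_space=source_space, layout=layout)


# ---------------------------------------------------------------------------
# L2 minimum-norm inverse
# ---------------------------------------------------------------------------

@dataclass
class InverseOperator:
    """Minimum-norm inverse, shape (n_sites * n_orient, n_sensors)."""

    matrix: np.ndarray
    lam: float
    n_sites: int
    n_orient: int


def mne_inverse_operator(leadfield: Leadfield | np.ndarray, lam: float = 0.1) -> InverseOperator:
    """Tikhonov-regularized minimum-norm operator W = L'(LL' + lam*s*I)^-1.

    ``s = trace(LL')/n_sensors`` makes ``lam`` dimensionless; ``lam=0``
    reduces to the Moore-Penrose pseudoinverse for full-row-rank L.
    """
    if lam < 0:
        raise ValueError("lam must be >= 0")
    if isinstance(leadfield, Leadfield):
        l2d = leadfield.matrix2d
        n_sites, n_orient = leadfield.source_space.n_sites, leadfield.source_space.n_orient
    else:
        l2d = np.asarray(leadfield, dtype=float)
        n_sites, n_orient = l2d.shape[1], 1
    if not np.any(l2d):
        raise ValueError("leadfield is identically zero")
    gram = l2d @ l2d.T
    n_sens = l2d.shape[0]
    scale = np.trace(gram) / n_sens
    reg = gram + lam * scale * np.eye(n_sens)
    try:
        w = np.linalg.solve(reg, l2d).T
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "sensor Gram matrix is singular; use lam > 0"
        ) from exc
    if lam == 0:
        # guard against silently inverting a numerically singular system
        cond = np.linalg.cond(gram)
        if not np.isfinite(cond) or cond > 1e12:
            raise np.linalg.LinAlgError(
                "leadfield is rank deficient at lam=0; use lam > 0"
            )
    return InverseOperator(matrix=w, lam=lam, n_sites=n_sites, n_orient=n_orient)


def apply_inverse(inverse: InverseOperator, data: np.ndarray) -> np.ndarray:
    """Dipole moments (n_sites, n_orient, n_times) from sensor data (n_sensors, n_times)."""
    data = np.asarray(data, dtype=float)
    if np.isnan(data).any():
        raise ValueError("sensor data contains NaN")
    if data.ndim == 1:
        data = data[:, None]
    moments = inverse.matrix @ data
    return moments.reshape(inverse.n_sites, inverse.n_orient, -1)


def activity_magnitude(moments: np.ndarray) -> np.ndarray:
    """Direction-independent activity: vector length over orientations.

    (n_sites, n_orient, n_times) -> (n_sites, n_times), units of the moments
    (nAm when moments are in nAm).
    """
    return np.linalg.norm(np.asarray(moments), axis=1)


def source_estimate(
    inverse: InverseOperator, data: np.ndarray
) -> np.ndarray:
    """Convenience: sensor data -> per-site activity magnitude."""
    return activity_magnitude(apply_inverse(inverse, data))
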