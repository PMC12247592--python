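"""Remnant static-field characterisation and coil nulling.

Inside a shielded room a small static field remains after degaussing.  OPMs
are vector sensors: when the helmet moves through that field, each channel
sees ``b_i(t) = n_i(t) . (B0 + G x_i(t))`` where ``n_i`` / ``x_i`` are the
sensor's sensitive axis and position in the room frame, ``B0`` the uniform
remnant field and ``G`` its first-order gradient.  Motion-synchronised OPM
data therefore determine the 8 free field parameters (3 uniform + 5
gradient; in a source-free region G is symmetric and traceless) by linear
least squares, and wall-mounted coils can be driven to oppose the fitted
field.

All field quantities in this module are expressed in nanotesla (nT) and
nT/m; positions in metres.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .io_bundle import ChannelInfo, MotionTrace

#: symmetric-traceless basis for the gradient tensor, parameters ordered
#: (Gxx, Gyy, Gxy, Gxz, Gyz); Gzz = -(Gxx + Gyy).
_G_BASIS = np.array(
    [
        [[1, 0, 0], [0, 0, 0], [0, 0, -1]],
        [[0, 0, 0], [0, 1, 0], [0, 0, -1]],
        [[0, 1, 0], [1, 0, 0], [0, 0, 0]],
        [[0, 0, 1], [0, 0, 0], [1, 0, 0]],
        [[0, 0, 0], [0, 0, 1], [0, 1, 0]],
    ],
    dtype=float,
)

N_FIELD_PARAMS = 8


@dataclass
class FieldModel:
    """Uniform field B0 (nT) plus symmetric traceless gradient G (nT/m)."""

    B0: np.ndarray = field(default_factory=lambda: np.zeros(3))
    G: np.ndarray = field(default_factory=lambda: np.zeros((3, 3)))

    def __post_init__(self) -> None:
        self.B0 = np.asarray(self.B0, dtype=float).reshape(3)
        self.G = np.asarray(self.G, dtype=float).reshape(3, 3)
        if not np.allclose(self.G, self.G.T, atol=1e-12):
            raise ValueError("gradient tensor must be symmetric")
        if abs(np.trace(self.G)) > 1e-12 * max(1.0, np.abs(self.G).max()):
            raise ValueError("gradient tensor must be traceless")

    @classmethod
    def from_params(cls, params: np.ndarray) -> "FieldModel":
        """Build from the 8-vector (B0x, B0y, B0z, Gxx, Gyy, Gxy, Gxz, Gyz)."""
        params = np.asarray(params, dtype=float).reshape(N_FIELD_PARAMS)
        G = np.tensordot(params[3:], _G_BASIS, axes=(0, 0))
        return cls(B0=params[:3], G=G)

    def to_params(self) -> np.ndarray:
        g = self.G
        return np.array(
            [*self.B0, g[0, 0], g[1, 1], g[0, 1], g[0, 2], g[1, 2]], dtype=float
        )

    def field_at(self, x: np.ndarray) -> np.ndarray:
        """Field vector(s) B0 + G x at position(s) x (... x 3, metres)."""
        x = np.asarray(x, dtype=float)
        return self.B0 + x @ self.G.T


@dataclass
class SphereSpec:
    """Spherical surface (radius/centre in metres) for the RMS field metric."""

    radius: float = 0.25
    centre: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("sphere radius must be positive")
        self.centre = np.asarray(self.centre, dtype=float).reshape(3)


@dataclass
class CoilCalibration:
    """Per-coil field response: unit current -> 8 field parameters.

    ``matrix`` is 8 x n_coils, rows in the parameter order of
    :meth:`FieldModel.to_params` (nT/A for the uniform rows, nT/m/A for the
    gradient rows).
    """

    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        if self.matrix.shape[0] != N_FIELD_PARAMS:
            raise ValueError("calibration matrix must have 8 rows")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("calibration matrix must be finite")

    @property
    def n_coils(self) -> int:
        return self.matrix.shape[1]

    @property
    def condition_number(self) -> float:
        return float(np.linalg.cond(self.matrix))

    @classmethod
    def ideal(cls) -> "CoilCalibration":
        """Eight ideal coils spanning the parameter space exactly."""
        return cls(matrix=np.eye(N_FIELD_PARAMS))

    @classmethod
    def window_coils(
        cls, n_coils: int = 27, seed: int = 7, miscalibration: float = 0.0,
        rng: np.random.Generator | None = None,
    ) -> "CoilCalibration":
        """A generic wall-coil system: random well-conditioned responses.

        ``miscalibration`` adds multiplicative Gaussian error of that
        fractional size to each response entry — modelling the difference
        between the assumed and the true coil behaviour.
        """
        if rng is None:
            rng = np.random.default_rng(seed)
        base = rng.standard_normal((N_FIELD_PARAMS, n_coils))
        if miscalibration:
            base = base * (1.0 + miscalibration * rng.standard_normal(base.shape))
        return cls(matrix=base)


# ---------------------------------------------------------------------------
# forward model
# ---------------------------------------------------------------------------


def rigid_transform_geometry(
    motion: MotionTrace, positions: np.ndarray, orientations: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Map helmet-frame sensor geometry into the room frame per sample.

    Returns ``(x_room, n_room)`` with shape (samples, channels, 3).  The
    motion trace gives the helmet origin's translation and (optionally) its
    rotation quaternion per sample.
    """
    pos = np.asarray(positions, dtype=float)
    ori = np.asarray(orientations, dtype=float)
    t = motion.position[:, None, :]
    if motion.rotation is not None:
        rot = Rotation.from_quat(motion.rotation)
        mats = rot.as_matrix()  # samples x 3 x 3
        x_room = np.einsum("sij,cj->sci", mats, pos) + t
        n_room = np.einsum("sij,cj->sci", mats, ori)
    else:
        x_room = pos[None, :, :] + t
        n_room = np.broadcast_to(ori[None, :, :], x_room.shape).copy()
    return x_room, n_room


def forward_field(
    model: FieldModel, x_room: np.ndarray, n_room: np.ndarray
) -> np.ndarray:
    """Channel readings n . (B0 + G x), shape (samples, channels), nT."""
    b_vec = model.field_at(x_room)
    return np.einsum("...i,...i->...", n_room, b_vec)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def _design_matrix(x_room: np.ndarray, n_room: np.ndarray) -> np.ndarray:
    """Rows of the least-squares design for each (sample, channel) reading."""
    s, c, _ = x_room.shape
    cols = [n_room[..., k].reshape(-1) for k in range(3)]
    for basis in _G_BASIS:
        gx = x_room @ basis.T
        cols.append(np.einsum("sci,sci->sc", n_room, gx).reshape(-1))
    return np.column_stack(cols)


def fit_field_model(
    opm: np.ndarray,
    motion: MotionTrace,
    geometry: list[ChannelInfo],
    min_rotation_axes: int = 2,
) -> tuple[FieldModel, float]:
    """Fit uniform field + first-order gradient from motion-synchronised data.

    ``opm`` is channels x samples (nT), sampled on the motion time base.
    Raises if the motion does not excite at least ``min_rotation_axes``
    rotation axes (the gradient is then unidentifiable) unless the gradient
    truly is absent from the data — in that case callers should pass
    ``min_rotation_axes=0``.
    """
    opm = np.atleast_2d(np.asarray(opm, dtype=float))
    n_ch, n_s = opm.shape
    if motion.n_samples != n_s:
        raise ValueError("motion trace must cover the recording sample-for-sample")
    if len(geometry) != n_ch:
        raise ValueError("geometry must list one ChannelInfo per OPM channel")
    positions = np.stack([c.position for c in geometry])
    orientations = np.stack([c.orientation for c in geometry])

    static = _is_static(motion)
    if not static and motion.rotation is not None:
        rotvecs = Rotation.from_quat(motion.rotation).as_rotvec()
        excited = np.sum(rotvecs.std(axis=0) > 1e-9)
        if excited < min_rotation_axes:
            raise ValueError(
                f"insufficient motion: only {excited} rotation axes excited"
            )

    x_room, n_room = rigid_transform_geometry(motion, positions, orientations)
    A = _design_matrix(x_room, n_room)
    b = opm.T.reshape(-1)  # sample-major to match design rows

    if static:
        # Reduced model: only B0 identifiable; report zero gradient.
        warnings.warn(
            "static motion trace: gradient unidentifiable, returning G = 0",
            stacklevel=2,
        )
        sol, *_ = np.linalg.lstsq(A[:, :3], b, rcond=None)
        params = np.concatenate([sol, np.zeros(5)])
        resid = b - A[:, :3] @ sol
        return FieldModel.from_params(params), float(np.sqrt(np.mean(resid**2)))

    rank = np.linalg.matrix_rank(A)
    if rank < N_FIELD_PARAMS:
        _, _, vt = np.linalg.svd(A, full_matrices=False)
        null = vt[rank:]
        raise ValueError(
            f"rank-deficient design (rank {rank} < {N_FIELD_PARAMS}); "
            f"null-space directions:\n{np.round(null, 3)}"
        )
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    resid = b - A @ sol
    return FieldModel.from_params(sol), float(np.sqrt(np.mean(resid**2)))


def _is_static(motion: MotionTrace) -> bool:
    if np.ptp(motion.position, axis=0).max() > 1e-12:
        return False
    if motion.rotation is not None and np.ptp(motion.rotation, axis=0).max() > 1e-12:
        return False
    return True


# ---------------------------------------------------------------------------
# RMS field on a sphere
# ---------------------------------------------------------------------------


def rms_on_sphere(model: FieldModel, sphere: SphereSpec | None = None) -> float:
    """RMS of |B0 + G r| over a spherical surface, closed form, nT.

    For symmetric traceless G the surface mean of |B(r)|^2 is
    |B0 + G c|^2 + R^2 ||G||_F^2 / 3 with c the sphere centre (the cross
    term averages to zero over the surface).
    """
    if sphere is None:
        sphere = SphereSpec()
    b_centre = model.field_at(sphere.centre)
    g_norm2 = float(np.sum(model.G**2))
    return float(
        np.sqrt(np.dot(b_centre, b_centre) + sphere.radius**2 * g_norm2 / 3.0)
    )


def rms_on_sphere_montecarlo(
    model: FieldModel,
    sphere: SphereSpec | None = None,
    n_points: int = 1_000_000,
    seed: int = 0,
) -> float:
    """Monte-Carlo surface estimate of the RMS field (validation oracle)."""
    if sphere is None:
        sphere = SphereSpec()
    rng = np.random.default_rng(seed)
    u = rng.standard_normal((n_points, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    r = sphere.centre + sphere.radius * u
    b = model.field_at(r)
    return float(np.sqrt(np.mean(np.sum(b**2, axis=1))))


# ---------------------------------------------------------------------------
# coil nulling
# ---------------------------------------------------------------------------


def solve_null_currents(
    model: FieldModel, cal: CoilCalibration, cond_limit: float = 1e8
) -> tuple[np.ndarray, FieldModel]:
    """Least-squares coil currents opposing the fitted field.

    Minimises ``|m + M c|`` over currents c, where m is the 8-parameter
    field vector and M the calibration matrix.  Returns the currents and
    the predicted residual field model m + M c.
    """
    if cal.condition_number > cond_limit:
        raise ValueError(
            f"calibration matrix ill-conditioned (cond = {cal.condition_number:.3g}); "
            "regularise or recalibrate"
        )
    m = model.to_params()
    currents, *_ = np.linalg.lstsq(cal.matrix, -m, rcond=None)
    residual = m + cal.matrix @ currents
    return currents, FieldModel.from_params(residual)


@dataclass
class NullingStep:
    fitted: FieldModel
    currents: np.ndarray
    rms_before: float
    rms_after: float


def nulling_cycle(
    field: FieldModel,
    geometry: list[ChannelInfo],
    cal: CoilCalibration,
    iterations: int = 2,
    *,
    true_cal: CoilCalibration | None = None,
    movement_amplitude: tuple[float, float] = (0.03, 0.2),
    duration: float = 20.0,
    noise: float = 0.01,
    sphere: SphereSpec | None = None,
    seed: int = 0,
) -> list[NullingStep]:
    """Iterated map–solve–apply field nulling (simulated coil application).

    Each iteration simulates a head-movement field-mapping run in the
    current remnant field, fits the 8-parameter model, solves for opposing
    coil currents with the *assumed* calibration ``cal``, and applies them
    through the *true* calibration ``true_cal`` (defaults to ``cal``;
    passing a perturbed true calibration models coil miscalibration).  The
    returned trajectory includes a final map after the last application,
    mirroring the fit–null–fit–null–map protocol.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    if true_cal is None:
        true_cal = cal
    from .synthetic import generate_fieldmap_session  # local: avoid cycle

    steps: list[NullingStep] = []
    current_params = FieldModel(field.B0.copy(), field.G.copy()).to_params()
    prev_rms = None
    for it in range(iterations):
        current = FieldModel.from_params(current_params)
        opm, motion = generate_fieldmap_session(
            current,
            geometry=geometry,
            movement_amplitude=movement_amplitude,
            duration=duration,
            noise=noise,
            seed=seed + 1000 * it,
        )
        fitted, _ = fit_field_model(opm, motion, geometry)
        currents, _ = solve_null_currents(fitted, cal)
        rms_before = rms_on_sphere(current, sphere)
        current_params = current_params + true_cal.matrix @ currents
        rms_after = rms_on_sphere(FieldModel.from_params(current_params), sphere)
        if prev_rms is not None and rms_after > prev_rms:
            warnings.warn("divergent nulling: RMS increased", stacklevel=2)
        prev_rms = rms_after
        steps.append(
            NullingStep(
                fitted=fitted,
                currents=currents,
                rms_before=rms_before,
                rms_after=rms_after,
            )
        )
    return steps
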